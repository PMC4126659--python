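# krillselect

Morphology-based prediction and estimation of trawl mesh size selectivity
for Antarctic krill (*Euphausia superba*).

Krill trawlers fish with small diamond-mesh netting, and little is known
about which body sizes escape through it.  Sea trials for every candidate
netting are impractical, so this package implements the alternative:
describe the animal's decisive cross sections geometrically, simulate
whether those rigid shapes can pass a mesh opening of a given size and
opening angle, and connect the simulations to experimental catch data
through standard selectivity statistics.  It is aimed at fisheries
scientists and gear technologists who need selectivity estimates
(`L50`, `SR`) for netting configurations that have never been tested at
sea.

## What it computes

* **Cross-section models** — closed three-parameter curves
  (`flexellipse`/`flexdrope` families: half-width `c1`, half-height `c2`,
  flex `c3`) fitted to digitised outlines and selected by AIC; bilinear
  coefficient models `c = a0 + a1 b + a2 h + a3 b h` with backward
  elimination; body-length regressions for cross-section width and
  height; virtual populations built from the full chain.
* **Mesh penetration** — exact support-function test of whether a rigid
  cross section (or the rigid CS1+CS2 pair at one shared rotation) fits
  a diamond opening `w = m sin(oa/2)` by `h = m cos(oa/2)`, with optimal
  or fixed rotation and attack-angle projection; design guides
  (iso-`L50` over mesh size × opening angle), rotation and attack-angle
  sweeps.
* **Selection statistics** — the logistic curve
  `r(l) = 1/(1 + exp(-ln 9 (l - L50)/SR))`; covered-codend ML fits of
  simulated data; the paired-gear likelihood with split parameter `SP`
  (`p_l = SP r(l) / (SP r(l) + 1 - SP)`); deviance-based goodness of
  fit; double-bootstrap confidence intervals; retention lengths
  `Li = L50 + SR ln(i/(100-i))/ln 9`.
* **Opening-angle mixtures** — simplex-constrained weights over an
  opening-angle grid whose mixed simulated curves reproduce an observed
  selection curve, and propagation of those weights to predict `L50`/`SR`
  for other mesh sizes.
* **Synthetic data** — generators for morphometric tables, paired-haul
  catch data (the exact generative inverse of the paired-gear
  likelihood) and digitised mesh points, so the whole pipeline is
  testable without any field data.

Reference values estimated for krill off the South Orkney Islands
(coefficient models, length regressions, the experimental selection
curve of a 15.4 mm commercial trawl) ship in `krillselect.reference` as
defaults.

## Worked example

```python
import numpy as np
from krillselect import (
    DiamondMesh, build_virtual_population, fit_mixture, fit_paired_gear,
    predict_for_mesh_sizes, reference, retention_length, simulate_oa_curves,
)
from krillselect.synthetic import SyntheticConfig, gen_paired_catch

# 1. Fit the paired-gear model to (here: synthetic) catch data
data = gen_paired_catch(SyntheticConfig(seed=7))
fit = fit_paired_gear(data)
print(f"L50 = {fit.l50:.2f} mm, SR = {fit.sr:.2f} mm, SP = {fit.sp:.2f}, "
      f"p = {fit.p_value:.2f}")

# 2. Retention lengths of the experimental 15.4 mm curve
curve = reference.EXPERIMENTAL_CURVE
print(f"L10 = {retention_length(10, curve):.2f} mm, "
      f"L90 = {retention_length(90, curve):.2f} mm")

# 3. Calibrate opening-angle weights and predict a 16 mm netting
pop = build_virtual_population(
    np.arange(10, 70.1, 0.5), 8,
    reference.KRILL_LENGTH_REGRESSIONS, reference.KRILL_COEFF_MODELS, seed=11,
)
comps = simulate_oa_curves(15.4, reference.DEFAULT_OA_GRID, pop)
mix = fit_mixture(curve, comps)
pred = predict_for_mesh_sizes(mix, [16.0], pop)
print(f"16 mm mesh: L50 = {pred['l50'].iloc[0]:.1f} mm")
```

Output:

```
L50 = 32.81 mm, SR = 4.01 mm, SP = 0.55, p = 0.68
L10 = 27.87 mm, L90 = 37.57 mm
16 mm mesh: L50 = 34.0 mm
```

The first line is the maximum-likelihood fit to one synthetic paired-gear
experiment generated at truth (32.72, 4.85, 0.55) — the estimates sit
within sampling error of the truth, and p > 0.05 means the logistic model
is not rejected.  The second line evaluates the retention-length formula:
L10 and L90 are exactly `L50 ∓ SR`.  The third line calibrates
opening-angle weights so that simulated curves for the 15.4 mm commercial
netting reproduce its experimental selection curve, then reuses those
weights to predict that a 16 mm netting would have `L50 ≈ 34 mm`.

A command-line interface wraps the same stages
(`krillselect synth | morphology-fit | mesh-fit | design-guide |
rotation-sweep | attack-sweep | fit-paired | mixture-fit |
predict-mesh-sizes`), each taking `--config`, `--seed`, `--out-dir` and
writing CSV/JSON outputs plus a run manifest with output digests.

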