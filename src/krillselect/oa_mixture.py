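"""Opening-angle mixtures of simulated selection curves.

During fishing a trawl presents a distribution of mesh opening angles
(oa) rather than a single value.  An observed selection curve can be
expressed as a convex combination of simulated single-oa curves for the
same mesh size: nonnegative weights summing to one are fitted so the
mixture retention matches the target retention at the 19 quantile
lengths L05, L10, ..., L95.  The fitted weights are then propagated to
other mesh sizes to predict their selectivity (L50, SR).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, minimize, nnls
from scipy.special import expit

from .mesh_geometry import DiamondMesh
from .penetration import _fit_l50, simulate_selection
from .selectivity import LN9, SelectionCurve, retention_length

DEFAULT_OA_GRID = (15, 20, 25, 30, 35, 40, 45, 50)


@dataclass(frozen=True)
class ComponentCurve:
    """Simulated selection curve for one (mesh size, oa) cell.

    ``kind`` is ``"logistic"`` for a fitted curve, or ``"all_retained"`` /
    ``"all_escaped"`` for cells where the population shows no selection
    (retention identically 1 or 0 over the simulated length span).
    """

    oa: float
    kind: str
    curve: SelectionCurve | None = None

    def retention(self, length):
        l = np.asarray(length, dtype=float)
        if self.kind == "logistic":
            return self.curve.retention(l)
        if self.kind == "all_retained":
            return np.ones_like(l)
        return np.zeros_like(l)


@dataclass(frozen=True)
class OAMixture:
    """Nonnegative weights over an opening-angle grid, summing to one."""

    oa_grid: tuple
    weights: tuple
    residual: float = float("nan")

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if len(w) != len(self.oa_grid):
            raise ValueError("weights and oa grid must have equal length")
        if np.any(w < -1e-12):
            raise ValueError("weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")

    def weight_for(self, oa) -> float:
        return float(self.weights[list(self.oa_grid).index(oa)])


def simulate_oa_curves(
    m: float,
    oa_grid=DEFAULT_OA_GRID,
    population=None,
    contact_mode: str = "CS1_CS2",
) -> list[ComponentCurve]:
    """Covered-codend logistic fit of simulated penetration per oa value."""
    if not population:
        raise ValueError("population must be non-empty")
    out = []
    for oa in oa_grid:
        rec = simulate_selection(population, DiamondMesh(m, oa), contact_mode)
        l50, sr, flag = _fit_l50(rec)
        if flag in ("all_retained", "all_escaped"):
            out.append(ComponentCurve(oa=oa, kind=flag))
        else:
            out.append(
                ComponentCurve(oa=oa, kind="logistic", curve=SelectionCurve(l50, sr))
            )
    return out


def fit_mixture(
    target_curve: SelectionCurve, components: list[ComponentCurve]
) -> OAMixture:
    """Simplex-constrained least-squares weights matching the target curve.

    The target retention is evaluated at its 19 quantile lengths L05..L95
    (5% steps); weights minimise the summed squared difference between
    the weighted component retentions and the target retentions at those
    lengths.  Solved by nonnegative least squares with a sum-to-one
    augmentation, then refined under the exact simplex constraint.
    """
    if len(components) < 2:
        raise ValueError("need at least 2 component curves")
    percents = np.arange(5, 100, 5)
    lengths = np.array([retention_length(i, target_curve) for i in percents])
    y = np.asarray(target_curve.retention(lengths), dtype=float)
    A = np.column_stack([c.retention(lengths) for c in components])

    lam = 10.0  # soft sum-to-one row for the NNLS warm start
    w0, _ = nnls(
        np.vstack([A, lam * np.ones(A.shape[1])]), np.concatenate([y, [lam]])
    )
    if w0.sum() <= 0:
        w0 = np.full(A.shape[1], 1.0 / A.shape[1])
    w0 = w0 / w0.sum()

    res = minimize(
        lambda w: float(np.sum((A @ w - y) ** 2)),
        w0,
        jac=lambda w: 2.0 * A.T @ (A @ w - y),
        method="SLSQP",
        bounds=[(0.0, 1.0)] * A.shape[1],
        constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0}],
        options={"ftol": 1e-14, "maxiter": 500},
    )
    if not res.success and not np.isfinite(res.fun):
        raise RuntimeError("mixture optimisation failed")
    w = np.clip(res.x, 0.0, None)
    w = w / w.sum()
    residual = float(np.sum((A @ w - y) ** 2))
    return OAMixture(
        oa_grid=tuple(c.oa for c in components),
        weights=tuple(float(v) for v in w),
        residual=residual,
    )


def mixture_retention(
    mixture: OAMixture, components: list[ComponentCurve], length
) -> np.ndarray:
    """Weighted mixture retention over the component curves."""
    l = np.asarray(length, dtype=float)
    return sum(
        w * c.retention(l) for w, c in zip(mixture.weights, components)
    )


def predict_for_mesh_sizes(
    mixture: OAMixture,
    mesh_sizes,
    population,
    contact_mode: str = "CS1_CS2",
) -> pd.DataFrame:
    """Predicted (L50, SR) for other mesh sizes under the fitted oa weights.

    For each mesh size, single-oa curves are re-simulated on the virtual
    population, mixed with the calibrated weights, and a logistic curve
    is fitted to the mixture retention on a 0.1-mm length grid.  Mesh
    sizes whose mixture curve does not cross 0.5 within the population
    length span are flagged.
    """
    lengths = np.array(sorted({ind.length for ind in population}))
    grid = np.arange(lengths.min(), lengths.max() + 0.1, 0.1)
    rows = []
    for m in mesh_sizes:
        comps = simulate_oa_curves(m, mixture.oa_grid, population, contact_mode)
        r = mixture_retention(mixture, comps, grid)
        if r.min() > 0.5 or r.max() < 0.5:
            rows.append({"m": m, "l50": np.nan, "sr": np.nan, "flag": "no_crossing"})
            continue
        l50_0 = float(grid[np.argmin(np.abs(r - 0.5))])

        def logistic(l, l50, sr):
            return expit(LN9 * (l - l50) / sr)

        try:
            popt, _ = curve_fit(
                logistic, grid, r, p0=[l50_0, 3.0],
                bounds=([grid.min() - 50.0, 1e-3], [grid.max() + 50.0, 100.0]),
                maxfev=10000,
            )
            rows.append({"m": m, "l50": float(popt[0]), "sr": float(popt[1]), "flag": "ok"})
        except RuntimeError:
            rows.append({"m": m, "l50": np.nan, "sr": np.nan, "flag": "no_convergence"})
    return pd.DataFrame(rows)
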