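"""Morphometric models linking krill body length to cross-section shapes.

The chain is: body length ``L`` -> width ``b`` and height ``h`` at two
transverse cross sections (linear regressions) -> shape parameters
``c1, c2, c3`` of the parametric cross-section curves (bilinear
coefficient models in ``b`` and ``h``).  A virtual population built from
this chain, with Gaussian residual variation around the regressions,
feeds the mesh-penetration simulations.

Cross sections:

* CS1 — anterior section containing the maximum body width,
* CS2 — posterior section containing (with CS1) the limiting height,
* CS3 — the curled-body contact mode (supported structurally; no default
  length regressions are shipped for it).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import linregress

from .shapes import CrossSectionModel, InvalidShapeError, shape_boundary

TERM_NAMES = ("a0", "a1", "a2", "a3")  # multipliers: 1, b, h, b*h


@dataclass(frozen=True)
class CrossSectionMeasurement:
    """Per-individual morphometrics at one cross section."""

    length: float  # body length, mm ("Discovery" measure: eye to telson tip)
    b: float  # maximum width at the cross section, mm
    h: float  # maximum height at the cross section, mm
    cross_section_id: str  # "CS1" | "CS2" | "CS3"
    boundary: np.ndarray | None = None  # optional digitised outline, (n, 2) mm

    def __post_init__(self):
        if not (self.length > 0 and self.b > 0 and self.h > 0):
            raise ValueError("length, b and h must all be positive")
        if self.cross_section_id not in ("CS1", "CS2", "CS3"):
            raise ValueError(f"unknown cross section {self.cross_section_id!r}")
        if self.boundary is not None and len(self.boundary) < 20:
            raise ValueError("digitised boundary needs >= 20 points")


def _design_columns(b: np.ndarray, h: np.ndarray) -> dict[str, np.ndarray]:
    return {"a0": np.ones_like(b), "a1": b, "a2": h, "a3": b * h}


@dataclass(frozen=True)
class BilinearCoefficientModel:
    """Bilinear model ``c = a0 + a1*b + a2*h + a3*b*h`` with optional terms.

    Only the retained terms appear in ``coef``; units are mm for ``a0``,
    dimensionless for ``a1``/``a2`` and 1/mm for ``a3``.
    """

    coef: dict[str, float]
    se: dict[str, float] | None = None
    pvalues: dict[str, float] | None = None
    r2: float | None = None
    df_resid: int | None = None
    intercept_only: bool = False

    def __post_init__(self):
        if not self.coef:
            raise ValueError("at least one term must be retained")
        unknown = set(self.coef) - set(TERM_NAMES)
        if unknown:
            raise ValueError(f"unknown terms {unknown}")

    def predict(self, b, h):
        b = np.asarray(b, dtype=float)
        h = np.asarray(h, dtype=float)
        cols = _design_columns(b, h)
        out = sum(v * cols[k] for k, v in self.coef.items())
        return out if out.shape else float(out)


@dataclass(frozen=True)
class CoefficientModelSet:
    """The three per-coefficient bilinear models for one cross section."""

    c1: BilinearCoefficientModel
    c2: BilinearCoefficientModel
    c3: BilinearCoefficientModel
    family: str = "flexellipse_1"
    b_range: tuple[float, float] | None = None
    h_range: tuple[float, float] | None = None


def fit_coefficient_model(
    b, h, c, alpha: float = 0.05
) -> BilinearCoefficientModel:
    """OLS of a shape coefficient on {1, b, h, b*h} with backward elimination.

    Starting from the full bilinear model, the term with the largest
    p-value is removed while that p-value exceeds ``alpha``, refitting
    after each removal (the intercept is eligible).  If everything is
    eliminated an intercept-only model is returned with a warning.
    """
    b = np.asarray(b, dtype=float)
    h = np.asarray(h, dtype=float)
    c = np.asarray(c, dtype=float)
    if len(b) < 10:
        raise ValueError("need at least 10 records")
    cols = _design_columns(b, h)
    terms = list(TERM_NAMES)
    scale_c = max(float(np.std(c)), 1e-12)
    while True:
        X = np.column_stack([cols[k] for k in terms])
        fit = sm.OLS(c, X).fit()
        # On (near) noise-free data p-values degenerate; drop terms whose
        # contribution to the response is numerically negligible first.
        contrib = np.abs(fit.params) * np.maximum(np.std(X, axis=0), np.abs(X).mean(axis=0))
        negligible = contrib < 1e-8 * scale_c
        if negligible.any() and len(terms) > 1:
            terms.pop(int(np.argmin(contrib)))
            continue
        worst = int(np.argmax(fit.pvalues))
        if fit.pvalues[worst] > alpha and len(terms) > 1:
            terms.pop(worst)
            continue
        if fit.pvalues[worst] > alpha and len(terms) == 1:
            warnings.warn(
                "all bilinear terms non-significant; retaining intercept only",
                stacklevel=2,
            )
            X = cols["a0"][:, None]
            fit = sm.OLS(c, X).fit()
            return BilinearCoefficientModel(
                coef={"a0": float(fit.params[0])},
                se={"a0": float(fit.bse[0])},
                pvalues={"a0": float(fit.pvalues[0])},
                r2=float(fit.rsquared),
                df_resid=int(fit.df_resid),
                intercept_only=True,
            )
        break
    # Uncentred R^2 (no-intercept models are the norm here).
    rss = float(np.sum(fit.resid**2))
    tss = float(np.sum((c - c.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    return BilinearCoefficientModel(
        coef={k: float(v) for k, v in zip(terms, fit.params)},
        se={k: float(v) for k, v in zip(terms, fit.bse)},
        pvalues={k: float(v) for k, v in zip(terms, fit.pvalues)},
        r2=r2,
        df_resid=int(fit.df_resid),
    )


def predict_c_params(
    b: float, h: float, models: CoefficientModelSet
) -> tuple[float, float, float]:
    """Evaluate the retained coefficient-model terms at (b, h).

    Raises on non-positive predicted ``c1`` or ``c2``; warns softly when
    (b, h) fall outside 0.5x–1.5x the fitted range (if a range is known).
    """
    for rng, val, name in ((models.b_range, b, "b"), (models.h_range, h, "h")):
        if rng is not None and not (0.5 * rng[0] <= val <= 1.5 * rng[1]):
            warnings.warn(
                f"{name}={val} outside 0.5-1.5x the fitted range {rng}", stacklevel=2
            )
    c1 = float(models.c1.predict(b, h))
    c2 = float(models.c2.predict(b, h))
    c3 = float(models.c3.predict(b, h))
    if c1 <= 0 or c2 <= 0:
        raise ValueError(f"non-positive predicted shape size: c1={c1}, c2={c2}")
    return c1, c2, c3


@dataclass(frozen=True)
class LengthDimensionRegression:
    """Linear length->dimension regressions per (cross section, dimension).

    ``entries`` maps ``(cs, dim)`` with ``dim in {"width", "height"}`` to
    ``(slope, intercept, r2)``; dimension = slope*L + intercept, in mm.
    """

    entries: dict[tuple[str, str], tuple[float, float, float]]

    def predict(self, cs: str, dim: str, length) -> np.ndarray | float:
        a, b, _ = self.entries[(cs, dim)]
        return a * np.asarray(length, dtype=float) + b

    def dims(self, length) -> tuple:
        """(b1, h1, b2, h2) at a body length (CS1 width/height, CS2 width/height)."""
        return (
            self.predict("CS1", "width", length),
            self.predict("CS1", "height", length),
            self.predict("CS2", "width", length),
            self.predict("CS2", "height", length),
        )


def dims_from_length(length: float, reg: LengthDimensionRegression) -> tuple:
    """(b1, h1, b2, h2) in mm at the given body length."""
    if np.any(np.asarray(length) < 0):
        raise ValueError("length must be non-negative")
    return reg.dims(length)


def fit_length_regressions(df: pd.DataFrame) -> LengthDimensionRegression:
    """Fit length->width and length->height regressions from a morphometrics table.

    ``df`` needs columns ``length_mm``, ``cs``, ``b_mm``, ``h_mm``.
    """
    entries = {}
    for cs, sub in df.groupby("cs"):
        for dim, col in (("width", "b_mm"), ("height", "h_mm")):
            res = linregress(sub["length_mm"], sub[col])
            entries[(cs, dim)] = (
                float(res.slope),
                float(res.intercept),
                float(res.rvalue**2),
            )
    return LengthDimensionRegression(entries)


def default_residual_sds(
    reg: LengthDimensionRegression, length_sd: float = 7.7
) -> dict[tuple[str, str], float]:
    """Residual standard deviations implied by each regression's R^2.

    For a regression with slope ``a`` and coefficient of determination
    ``R^2`` fitted on lengths with standard deviation ``length_sd``, the
    residual sd consistent with that R^2 is ``a*length_sd*sqrt(1/R^2 - 1)``.
    """
    return {
        key: abs(a) * length_sd * np.sqrt(max(1.0 / r2 - 1.0, 0.0))
        for key, (a, _b, r2) in reg.entries.items()
        if r2 > 0
    }


@dataclass
class VirtualIndividual:
    """One simulated krill: body length, cross-section dimensions and shapes."""

    length: float
    b1: float
    h1: float
    b2: float
    h2: float
    cs1: CrossSectionModel
    cs2: CrossSectionModel
    cs3: CrossSectionModel | None = None
    id: int = 0
    _cache: dict = field(default_factory=dict, repr=False, compare=False)


def build_virtual_population(
    length_grid,
    n_per_length: int,
    reg: LengthDimensionRegression,
    coeff_models: dict[str, CoefficientModelSet],
    residual_sds: dict[tuple[str, str], float] | None = None,
    seed: int | np.random.Generator | None = 0,
) -> list[VirtualIndividual]:
    """Build a virtual population along a length grid.

    For each length, ``n_per_length`` individuals are drawn: cross-section
    dimensions come from the regressions plus Gaussian residuals (sd per
    (cs, dimension); sd = 0 gives a deterministic, seed-independent
    population), then shape parameters via the coefficient models.  Draws
    yielding non-positive dimensions or invalid shapes are redrawn (at
    most 100 attempts each).
    """
    lengths = np.asarray(length_grid, dtype=float)
    if np.any(lengths < 10.0) or np.any(lengths > 70.0):
        raise ValueError("length grid must lie within 10-70 mm")
    if n_per_length < 1:
        raise ValueError("n_per_length must be >= 1")
    if residual_sds is None:
        residual_sds = default_residual_sds(reg)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    sds = [
        residual_sds.get(("CS1", "width"), 0.0),
        residual_sds.get(("CS1", "height"), 0.0),
        residual_sds.get(("CS2", "width"), 0.0),
        residual_sds.get(("CS2", "height"), 0.0),
    ]
    cs1_set = coeff_models["CS1"]
    cs2_set = coeff_models["CS2"]
    pop: list[VirtualIndividual] = []
    idx = 0
    for L in lengths:
        base = np.asarray(reg.dims(L), dtype=float)
        for _ in range(n_per_length):
            for attempt in range(100):
                dims = base + rng.normal(0.0, sds) if any(sds) else base.copy()
                if np.any(dims <= 0):
                    continue
                b1, h1, b2, h2 = dims
                try:
                    # the virtual grid deliberately extrapolates the fitted
                    # (b, h) range, so the soft range warning is silenced
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", UserWarning)
                        p1 = predict_c_params(b1, h1, cs1_set)
                        p2 = predict_c_params(b2, h2, cs2_set)
                    cs1 = CrossSectionModel(cs1_set.family, *p1)
                    cs2 = CrossSectionModel(cs2_set.family, *p2)
                except (ValueError, InvalidShapeError):
                    continue
                pop.append(
                    VirtualIndividual(
                        length=float(L), b1=b1, h1=h1, b2=b2, h2=h2,
                        cs1=cs1, cs2=cs2, id=idx,
                    )
                )
                idx += 1
                break
            else:
                raise RuntimeError(
                    f"no valid individual after 100 draws at length {L}"
                )
    return pop


__all__ = [
    "CrossSectionMeasurement",
    "BilinearCoefficientModel",
    "CoefficientModelSet",
    "LengthDimensionRegression",
    "VirtualIndividual",
    "fit_coefficient_model",
    "predict_c_params",
    "dims_from_length",
    "fit_length_regressions",
    "default_residual_sds",
    "build_virtual_population",
    "CrossSectionModel",
    "shape_boundary",
]
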