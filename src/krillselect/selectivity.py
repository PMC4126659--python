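"""Logistic size-selection models and their estimation.

Retention follows the standard logistic selection curve

    r(l) = 1 / (1 + exp(-ln(9) * (l - L50) / SR)),

where ``L50`` is the length with 50% retention probability and the
selection range ``SR = L75 - L25`` measures curve steepness (the ln(9)
slope convention ties SR to exactly that quantile difference).

Two estimation settings are covered:

* covered-codend data — per-individual (length, retained) outcomes, fitted
  by binomial maximum likelihood; used on simulated penetration data;
* paired-gear data — test vs control counts per 1-mm length class, fitted
  by minimising the conditional negative log-likelihood with an extra
  split parameter ``SP`` (the relative fishing power of the test gear):

      p_l = SP * r(l) / (SP * r(l) + (1 - SP)),
      -sum_l [ nt_l * ln p_l + nc_l * ln(1 - p_l) ].

Uncertainty is quantified by a double bootstrap (hauls, then individuals
within hauls) with percentile intervals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import chi2

LN9 = math.log(9.0)
_SR_FLOOR = 1e-3  # mm; knife-edge fallback


class DegenerateSelectionError(ValueError):
    """Raised when the data contain a single outcome (no selection signal)."""


@dataclass(frozen=True)
class SelectionCurve:
    """Logistic selection curve with parameters L50 and SR (both mm)."""

    l50: float
    sr: float

    def __post_init__(self):
        if not self.sr > 0:
            raise ValueError("SR must be positive")

    def retention(self, length):
        l = np.asarray(length, dtype=float)
        out = expit(LN9 * (l - self.l50) / self.sr)
        return out if out.shape else float(out)


def logistic_retention(length, curve: SelectionCurve):
    """Retention probability r(l) of the logistic selection curve."""
    return curve.retention(length)


def retention_length(percent: float, curve: SelectionCurve) -> float:
    """Length Li at which retention probability equals ``percent`` %.

    Exact inverse of :func:`logistic_retention`:
    ``Li = L50 + SR * ln(i/(100-i)) / ln(9)``.
    """
    if not 0.0 < percent < 100.0:
        raise ValueError("percent must lie strictly between 0 and 100")
    return curve.l50 + curve.sr * math.log(percent / (100.0 - percent)) / LN9


@dataclass
class CoveredCodendFit:
    curve: SelectionCurve
    knife_edge: bool
    converged: bool
    n: int
    loglik: float | None = None


def fit_covered_codend(lengths, retained) -> CoveredCodendFit:
    """Binomial ML fit of the logistic curve to covered-codend outcomes.

    ``retained`` are 0/1 per individual.  Complete separation (knife-edge
    selection) is detected up front and returns L50 at the separation
    midpoint with SR at the 1e-3 mm floor, flagged.
    """
    l = np.asarray(lengths, dtype=float)
    y = np.asarray(retained, dtype=float)
    if len(l) != len(y) or len(l) == 0:
        raise ValueError("lengths and retained must be equal-length, non-empty")
    if y.min() == y.max():
        raise DegenerateSelectionError(
            "all individuals retained" if y[0] else "all individuals escaped"
        )
    max_escape = l[y == 0].max()
    min_retain = l[y == 1].min()
    if min_retain > max_escape:  # complete separation
        mid = (min_retain + max_escape) / 2.0
        return CoveredCodendFit(
            SelectionCurve(mid, _SR_FLOOR), knife_edge=True, converged=True, n=len(l)
        )
    # Aggregate to length classes for speed, then ML in (L50, ln SR).
    classes, inv = np.unique(l, return_inverse=True)
    k = np.bincount(inv, weights=y, minlength=len(classes))
    n = np.bincount(inv, minlength=len(classes)).astype(float)

    def nll(p):
        l50, log_sr = p
        r = expit(LN9 * (classes - l50) / np.exp(log_sr))
        r = np.clip(r, 1e-12, 1.0 - 1e-12)
        return -np.sum(k * np.log(r) + (n - k) * np.log(1.0 - r))

    x0 = np.array([(min_retain + max_escape) / 2.0, np.log(3.0)])
    res = minimize(nll, x0, method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
    l50, sr = float(res.x[0]), float(np.exp(res.x[1]))
    return CoveredCodendFit(
        SelectionCurve(l50, max(sr, _SR_FLOOR)),
        knife_edge=sr <= _SR_FLOOR * 1.01,
        converged=bool(res.success),
        n=len(l),
        loglik=-float(res.fun),
    )


@dataclass
class CatchData:
    """Paired-gear catch counts per 1-mm length class (optionally per haul).

    ``frame`` has columns ``haul``, ``length`` (class midpoint, mm),
    ``nt`` (test-gear count) and ``nc`` (control-gear count).
    """

    frame: pd.DataFrame
    seed: int | None = None

    def __post_init__(self):
        f = self.frame
        required = {"haul", "length", "nt", "nc"}
        if not required.issubset(f.columns):
            raise ValueError(f"CatchData frame needs columns {sorted(required)}")
        if (f["nt"] < 0).any() or (f["nc"] < 0).any():
            raise ValueError("counts must be non-negative")
        pooled = self.pooled()
        if (pooled["nt"] + pooled["nc"] > 0).sum() < 3:
            raise ValueError("need at least 3 non-empty length classes")

    @classmethod
    def from_counts(cls, length, nt, nc, haul=None, seed=None) -> "CatchData":
        f = pd.DataFrame({
            "haul": haul if haul is not None else 1,
            "length": np.asarray(length, dtype=float),
            "nt": np.asarray(nt, dtype=int),
            "nc": np.asarray(nc, dtype=int),
        })
        return cls(f, seed=seed)

    def pooled(self) -> pd.DataFrame:
        return (
            self.frame.groupby("length", as_index=False)[["nt", "nc"]]
            .sum()
            .sort_values("length", ignore_index=True)
        )

    @property
    def hauls(self):
        return sorted(self.frame["haul"].unique())


@dataclass
class PairedGearResult:
    l50: float
    sr: float
    sp: float
    deviance: float
    dof: int
    p_value: float
    loglik: float
    converged: bool
    sp_at_bound: bool = False
    ci: dict[str, tuple[float, float]] | None = None

    @property
    def curve(self) -> SelectionCurve:
        return SelectionCurve(self.l50, self.sr)


def _paired_nll(theta, length, nt, nc):
    l50, log_sr, logit_sp = theta
    sr = max(np.exp(log_sr), 1e-8)  # knife-edge floor keeps the ratio finite
    sp = expit(logit_sp)
    r = expit(LN9 * (length - l50) / sr)
    p = sp * r / (sp * r + (1.0 - sp))
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return -np.sum(nt * np.log(p) + nc * np.log(1.0 - p))


def fit_paired_gear(data: CatchData, n_starts: int = 8) -> PairedGearResult:
    """Maximum-likelihood fit of (L50, SR, SP) to pooled paired-gear counts.

    Hauls are pooled before fitting.  The objective is minimised by a
    derivative-free simplex from multiple starting points (L50 across the
    observed length range, SR in {1, 3, 6, 10} mm, SP in {0.3, 0.7});
    goodness of fit is reported as the deviance against the saturated
    model on a chi-square with dof = (#non-empty classes) - 3.
    """
    pooled = data.pooled()
    mask = (pooled["nt"] + pooled["nc"]) > 0
    length = pooled.loc[mask, "length"].to_numpy(dtype=float)
    nt = pooled.loc[mask, "nt"].to_numpy(dtype=float)
    nc = pooled.loc[mask, "nc"].to_numpy(dtype=float)

    lo, hi = length.min(), length.max()
    l50_starts = (lo + 0.35 * (hi - lo), lo + 0.65 * (hi - lo))
    starts = [
        (l50, math.log(sr), math.log(sp / (1 - sp)))
        for l50 in l50_starts
        for sr in (1.0, 6.0)
        for sp in (0.3, 0.7)
    ][:n_starts]

    best = None
    for x0 in starts:
        res = minimize(
            _paired_nll, np.asarray(x0), args=(length, nt, nc),
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-8, "maxiter": 5000},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("paired-gear fit failed to converge from all starts")
    l50 = float(best.x[0])
    sr = max(float(np.exp(best.x[1])), _SR_FLOOR)
    sp = float(expit(best.x[2]))

    # Deviance vs the saturated model p_hat = nt / (nt + nc).
    tot = nt + nc
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(nt > 0, nt * np.log(nt / tot), 0.0)
        t2 = np.where(nc > 0, nc * np.log(nc / tot), 0.0)
    sat = float(np.sum(np.nan_to_num(t1) + np.nan_to_num(t2)))
    loglik = -float(best.fun)
    deviance = float(2.0 * (sat - loglik))
    dof = int(mask.sum()) - 3
    p_value = float(chi2.sf(deviance, dof)) if dof > 0 else float("nan")
    return PairedGearResult(
        l50=l50, sr=sr, sp=sp, deviance=deviance, dof=dof, p_value=p_value,
        loglik=loglik, converged=bool(best.success),
        sp_at_bound=not (1e-3 < sp < 1.0 - 1e-3),
    )


_LI_PERCENTS = tuple(range(5, 100, 5))


@dataclass
class BootstrapResult:
    estimate: PairedGearResult
    ci: dict[str, tuple[float, float]]
    li_ci: dict[int, tuple[float, float]]
    curve_band: pd.DataFrame  # length, r_hat, ci_low, ci_high
    n_failed: int
    reps: int
    seed: int
    replicates: pd.DataFrame = field(repr=False, default=None)


def bootstrap_ci(
    data: CatchData,
    reps: int = 1000,
    seed: int = 0,
    length_grid: np.ndarray | None = None,
) -> BootstrapResult:
    """Double-bootstrap percentile CIs for the paired-gear fit.

    Hauls are resampled with replacement, then individuals within each
    selected haul (per gear); each replicate is refitted.  With a single
    haul only the inner resampling is performed (with a warning).
    Replicate fits that fail are dropped and counted; more than 20%
    failures raises.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100")
    rng = np.random.default_rng(seed)
    estimate = fit_paired_gear(data)
    hauls = data.hauls
    if len(hauls) == 1:
        warnings.warn("single haul: inner-only bootstrap", stacklevel=2)
    pooled = data.pooled()
    classes = pooled["length"].to_numpy(dtype=float)
    if length_grid is None:
        length_grid = np.arange(classes.min(), classes.max() + 0.5, 0.5)

    # per-haul (class x gear) count matrices aligned to the pooled classes
    index = {l: i for i, l in enumerate(classes)}
    haul_cells, haul_probs, haul_totals = [], [], []
    for _h, g in data.frame.groupby("haul"):
        arr = np.zeros((len(classes), 2))
        idx = np.array([index[l] for l in g["length"]], dtype=int)
        np.add.at(arr[:, 0], idx, g["nt"].to_numpy(dtype=float))
        np.add.at(arr[:, 1], idx, g["nc"].to_numpy(dtype=float))
        cells = arr.ravel()
        total = int(cells.sum())
        haul_cells.append(cells)
        haul_totals.append(total)
        haul_probs.append(cells / total if total > 0 else cells)

    x0 = np.array([
        estimate.l50, math.log(estimate.sr),
        math.log(estimate.sp / (1 - estimate.sp)),
    ])
    n_hauls = len(hauls)
    rows, curves, n_failed = [], [], 0
    for _ in range(reps):
        chosen = (
            rng.integers(0, n_hauls, n_hauls) if n_hauls > 1 else range(n_hauls)
        )
        pool = np.zeros(2 * len(classes))
        for j in chosen:
            if haul_totals[j] > 0:
                pool += rng.multinomial(haul_totals[j], haul_probs[j])
        pool = pool.reshape(-1, 2)
        nt, nc = pool[:, 0], pool[:, 1]
        mask = (nt + nc) > 0
        try:
            if mask.sum() < 3:
                raise RuntimeError("degenerate replicate")
            res = minimize(
                _paired_nll, x0,
                args=(classes[mask], nt[mask], nc[mask]),
                method="Nelder-Mead",
                options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 2000},
            )
            if not np.isfinite(res.fun):
                raise RuntimeError("non-finite objective")
            l50 = float(res.x[0])
            sr = max(float(np.exp(res.x[1])), _SR_FLOOR)
            sp = float(expit(res.x[2]))
        except (ValueError, RuntimeError):
            n_failed += 1
            continue
        curve = SelectionCurve(l50, sr)
        rows.append(
            [l50, sr, sp] + [retention_length(i, curve) for i in _LI_PERCENTS]
        )
        curves.append(curve.retention(length_grid))
    if n_failed > 0.2 * reps:
        raise RuntimeError(f"{n_failed}/{reps} bootstrap replicates failed")
    cols = ["l50", "sr", "sp"] + [f"l{i:02d}" for i in _LI_PERCENTS]
    repl = pd.DataFrame(rows, columns=cols)

    def pct(series):
        return (float(np.percentile(series, 2.5)), float(np.percentile(series, 97.5)))

    ci = {k: pct(repl[k]) for k in ("l50", "sr", "sp")}
    li_ci = {i: pct(repl[f"l{i:02d}"]) for i in _LI_PERCENTS}
    band = np.percentile(np.asarray(curves), [2.5, 97.5], axis=0)
    curve_band = pd.DataFrame({
        "length": length_grid,
        "r_hat": estimate.curve.retention(length_grid),
        "ci_low": band[0],
        "ci_high": band[1],
    })
    estimate.ci = ci
    return BootstrapResult(
        estimate=estimate, ci=ci, li_ci=li_ci, curve_band=curve_band,
        n_failed=n_failed, reps=reps, seed=seed, replicates=repl,
    )
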