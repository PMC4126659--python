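"""Synthetic-data generators for every pipeline input.

The generators emulate the statistical structure the analysis assumes:

* morphometric tables — body lengths from a truncated normal (defaults
  mean 44.7 mm, sd 7.7 mm, range 19-55 mm), cross-section dimensions from
  the reference length regressions plus Gaussian residuals, shape
  parameters from the reference coefficient models plus small noise,
  optionally with digitised outline point clouds;
* paired-gear catches — the exact generative inverse of the paired-gear
  likelihood: per haul, encountering lengths are drawn and binned to 1-mm
  classes, and each class total is split binomially between test and
  control gear with probability ``p_l = SP*r(l) / (SP*r(l) + 1 - SP)``;
* mesh digitisations — diamond corner points under random rigid motion
  plus Gaussian noise.

All generators are reproducible under a fixed seed, which is recorded in
the output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .mesh_geometry import DiamondMesh, mesh_polygon
from .morphology import (
    CoefficientModelSet,
    LengthDimensionRegression,
    predict_c_params,
)
from .selectivity import CatchData, SelectionCurve
from .shapes import CrossSectionModel, shape_boundary
from . import reference


@dataclass
class SyntheticConfig:
    """Study-condition parameters for the synthetic generators."""

    seed: int = 0
    # morphometrics
    n_individuals: int = 83
    length_range: tuple = (19.0, 55.0)
    length_dist: str = "normal"  # "normal" (truncated) or "uniform"
    length_mean: float = reference.KRILL_LENGTH_MEAN
    length_sd: float = reference.KRILL_LENGTH_SD
    residual_sds: dict | None = None  # default: reference.KRILL_RESIDUAL_SDS
    c_noise_sd: float = 0.02  # mm-scale noise on shape parameters
    boundary_points: int = 0  # per cross section; 0 disables outlines
    boundary_noise_sd: float = 0.05  # mm radial noise on outlines
    # paired-gear experiment
    true_l50: float = reference.EXPERIMENTAL_CURVE.l50
    true_sr: float = reference.EXPERIMENTAL_CURVE.sr
    true_sp: float = reference.EXPERIMENTAL_SP
    n_hauls: int = reference.EXPERIMENTAL_N_HAULS
    test_total: int = reference.EXPERIMENTAL_TEST_TOTAL
    control_total: int = reference.EXPERIMENTAL_CONTROL_TOTAL
    catch_length_range: tuple = (20.0, 55.0)
    # mesh digitisation
    mesh_m: float = reference.COMMERCIAL_MESH_MM
    mesh_oa: float = 34.0
    n_meshes: int = 5
    mesh_noise_sd: float = 0.0

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _draw_lengths(cfg: SyntheticConfig, n: int, rng, length_range=None) -> np.ndarray:
    lo, hi = length_range if length_range is not None else cfg.length_range
    if cfg.length_dist == "uniform":
        return rng.uniform(lo, hi, size=n)
    a = (lo - cfg.length_mean) / cfg.length_sd
    b = (hi - cfg.length_mean) / cfg.length_sd
    return truncnorm.rvs(
        a, b, loc=cfg.length_mean, scale=cfg.length_sd, size=n, random_state=rng
    )


def gen_morphometrics(
    cfg: SyntheticConfig,
    reg: LengthDimensionRegression = reference.KRILL_LENGTH_REGRESSIONS,
    coeff_models: dict[str, CoefficientModelSet] = reference.KRILL_COEFF_MODELS,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Synthetic per-individual morphometrics (and optional outlines).

    Returns ``(table, boundaries)`` where the table has one row per
    (individual, cross section) with columns ``id, length_mm, cs, b_mm,
    h_mm, c1, c2, c3`` and boundaries (or None) has ``id, cs,
    point_index, x_mm, y_mm``.
    """
    rng = cfg.rng()
    sds = cfg.residual_sds if cfg.residual_sds is not None else reference.KRILL_RESIDUAL_SDS
    lengths = _draw_lengths(cfg, cfg.n_individuals, rng)
    rows, brows = [], []
    for i, L in enumerate(lengths):
        for cs in ("CS1", "CS2"):
            a_w, b_w, _ = reg.entries[(cs, "width")]
            a_h, b_h, _ = reg.entries[(cs, "height")]
            sd_w = sds.get((cs, "width"), 0.0)
            sd_h = sds.get((cs, "height"), 0.0)
            for _ in range(100):
                b = a_w * L + b_w + (rng.normal(0.0, sd_w) if sd_w else 0.0)
                h = a_h * L + b_h + (rng.normal(0.0, sd_h) if sd_h else 0.0)
                if b > 0 and h > 0:
                    break
            else:
                raise RuntimeError("could not draw positive dimensions")
            c1, c2, c3 = predict_c_params(b, h, coeff_models[cs])
            if cfg.c_noise_sd:
                c1 = abs(c1 + rng.normal(0.0, cfg.c_noise_sd))
                c2 = abs(c2 + rng.normal(0.0, cfg.c_noise_sd))
                c3 = c3 + rng.normal(0.0, cfg.c_noise_sd)
            rows.append({
                "id": i, "length_mm": L, "cs": cs,
                "b_mm": b, "h_mm": h, "c1": c1, "c2": c2, "c3": c3,
            })
            if cfg.boundary_points:
                model = CrossSectionModel(coeff_models[cs].family, c1, c2, c3)
                pts = shape_boundary(model, cfg.boundary_points)
                if cfg.boundary_noise_sd:
                    r = np.hypot(pts[:, 0], pts[:, 1])
                    scale = 1.0 + rng.normal(0.0, cfg.boundary_noise_sd, len(pts)) / np.maximum(r, 1e-9)
                    pts = pts * scale[:, None]
                for j, (x, y) in enumerate(pts):
                    brows.append({
                        "id": i, "cs": cs, "point_index": j, "x_mm": x, "y_mm": y,
                    })
    table = pd.DataFrame(rows)
    table.attrs["seed"] = cfg.seed
    boundaries = None
    if brows:
        boundaries = pd.DataFrame(brows)
        boundaries.attrs["seed"] = cfg.seed
    return table, boundaries


def split_probability(length, l50: float, sr: float, sp: float):
    """P(test gear | caught at length l) under the paired-gear model."""
    r = SelectionCurve(l50, sr).retention(length)
    return sp * r / (sp * r + (1.0 - sp))


def gen_paired_catch(cfg: SyntheticConfig, rng=None) -> CatchData:
    """Synthetic paired-haul catch data from the generative split model.

    The combined encounter total (test_total + control_total) is split
    evenly across hauls; encountering lengths are drawn per haul, binned
    to 1-mm classes labelled by their integer midpoint, and each class is
    split binomially between gears.  Gear-wise totals are therefore
    random with expectation governed by SP and the selection curve.
    """
    if rng is None:
        rng = cfg.rng()
    n_total = cfg.test_total + cfg.control_total
    per_haul = np.full(cfg.n_hauls, n_total // cfg.n_hauls)
    per_haul[: n_total % cfg.n_hauls] += 1
    frames = []
    for haul, n in enumerate(per_haul, start=1):
        lengths = _draw_lengths(cfg, int(n), rng, cfg.catch_length_range)
        classes = np.round(lengths).astype(int)
        uniq, counts = np.unique(classes, return_counts=True)
        p = split_probability(uniq.astype(float), cfg.true_l50, cfg.true_sr, cfg.true_sp)
        nt = rng.binomial(counts, p)
        frames.append(pd.DataFrame({
            "haul": haul, "length": uniq.astype(float), "nt": nt, "nc": counts - nt,
        }))
    frame = pd.concat(frames, ignore_index=True)
    return CatchData(frame, seed=cfg.seed)


def gen_mesh_points(cfg: SyntheticConfig, rng=None) -> pd.DataFrame:
    """Digitised diamond-mesh corner points under random rigid motion + noise."""
    if rng is None:
        rng = cfg.rng()
    if cfg.mesh_noise_sd < 0:
        raise ValueError("mesh noise sd must be >= 0")
    rows = []
    for mesh_id in range(1, cfg.n_meshes + 1):
        corners = mesh_polygon(DiamondMesh(cfg.mesh_m, cfg.mesh_oa))
        # digitisations mark corners plus bar midpoints (8 points per mesh)
        mids = (corners + np.roll(corners, -1, axis=0)) / 2.0
        poly = np.vstack([np.column_stack([corners, mids]).reshape(-1, 2)])
        phi = rng.uniform(0.0, 2.0 * np.pi)
        c, s = np.cos(phi), np.sin(phi)
        pts = poly @ np.array([[c, s], [-s, c]]) + rng.uniform(-20.0, 20.0, 2)
        if cfg.mesh_noise_sd:
            pts = pts + rng.normal(0.0, cfg.mesh_noise_sd, pts.shape)
        for j, (x, y) in enumerate(pts):
            rows.append({"mesh_id": mesh_id, "point_index": j, "x_mm": x, "y_mm": y})
    out = pd.DataFrame(rows)
    out.attrs["seed"] = cfg.seed
    return out


def with_seed(cfg: SyntheticConfig, seed: int) -> SyntheticConfig:
    """Copy of a config with a different seed."""
    return replace(cfg, seed=seed)
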