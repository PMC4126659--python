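"""Parametric cross-section outline families for krill morphometrics.

Krill cross sections are modelled as closed three-parameter curves: ``c1``
is the half-width (mm), ``c2`` the half-height (mm), and ``c3`` a
dimensionless "flex" term that deforms the basic ellipse.  Three families
are provided:

``flexellipse_1``
    Ellipse with a vertical egg-type asymmetry, ``y = c2*sin(t) +
    c3*sin(t)**2``.  Valid for ``|c3| < c2``.
``flexellipse_3``
    Ellipse whose width tapers linearly with height,
    ``x = c1*cos(t)*(1 - c3*sin(t))``.  Valid for ``|c3| < 1``.
``flexdrope_2``
    Drop shape: an ellipse with a one-sided linear width taper,
    ``x = c1*cos(t)*(1 - c3*(1 + sin(t))/2)``.  Valid for ``|c3| < 1``.
``ellipse``
    Plain ellipse (``c3`` ignored); mostly useful as a fitting baseline.

All families are affinely normalised after evaluation so that the
discretised boundary has bounding box exactly ``[-c1, c1] x [-c2, c2]``,
centred at the origin.  This keeps the meaning of ``c1``/``c2`` identical
across families, which is what allows width/height regressions on body
length to drive every family through the same two parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from shapely.geometry import LinearRing, Polygon


class InvalidShapeError(ValueError):
    """Raised when family parameters produce a degenerate or self-intersecting curve."""


def _raw_ellipse(t, c1, c2, c3):
    return c1 * np.cos(t), c2 * np.sin(t)


def _raw_flexellipse_1(t, c1, c2, c3):
    s = np.sin(t)
    return c1 * np.cos(t), c2 * s + c3 * s * s


def _raw_flexellipse_3(t, c1, c2, c3):
    s = np.sin(t)
    return c1 * np.cos(t) * (1.0 - c3 * s), c2 * s


def _raw_flexdrope_2(t, c1, c2, c3):
    s = np.sin(t)
    return c1 * np.cos(t) * (1.0 - c3 * (1.0 + s) / 2.0), c2 * s


_FAMILIES = {
    "ellipse": _raw_ellipse,
    "flexellipse_1": _raw_flexellipse_1,
    "flexellipse_3": _raw_flexellipse_3,
    "flexdrope_2": _raw_flexdrope_2,
}

FAMILY_NAMES = tuple(_FAMILIES)


def _check_params(family: str, c1: float, c2: float, c3: float) -> None:
    if family not in _FAMILIES:
        raise InvalidShapeError(f"unknown cross-section family {family!r}")
    if not (c1 > 0 and c2 > 0):
        raise InvalidShapeError(
            f"{family}: half-width c1 and half-height c2 must be positive "
            f"(got c1={c1}, c2={c2})"
        )
    if family == "flexellipse_1" and not abs(c3) < c2:
        raise InvalidShapeError(
            f"flexellipse_1: |c3| must be < c2 for a simple curve (c3={c3}, c2={c2})"
        )
    if family in ("flexellipse_3", "flexdrope_2") and not abs(c3) < 1.0:
        raise InvalidShapeError(
            f"{family}: |c3| must be < 1 for a simple curve (c3={c3})"
        )


@dataclass(frozen=True)
class CrossSectionModel:
    """A parametric closed cross-section curve.

    Parameters
    ----------
    family : str
        One of :data:`FAMILY_NAMES`.
    c1, c2 : float
        Half-width and half-height in mm (the discretised boundary has
        bounding box ``2*c1`` by ``2*c2`` exactly).
    c3 : float
        Dimensionless flex parameter; ``c3 = 0`` reduces every family to
        the plain ellipse.
    """

    family: str
    c1: float
    c2: float
    c3: float = 0.0

    def __post_init__(self):
        _check_params(self.family, self.c1, self.c2, self.c3)

    def boundary(self, n_points: int = 256) -> np.ndarray:
        return shape_boundary(self, n_points)


def shape_boundary(model: CrossSectionModel, n_points: int = 256) -> np.ndarray:
    """Discretise a cross-section model into an ordered closed polygon.

    Returns an ``(n_points, 2)`` array of (x, y) mm points, uniform in the
    curve parameter, not repeating the first point.  The polygon is simple,
    bilaterally symmetric about the vertical axis, and its bounding box is
    exactly ``[-c1, c1] x [-c2, c2]``.
    """
    if n_points < 32:
        raise ValueError("n_points must be >= 32")
    _check_params(model.family, model.c1, model.c2, model.c3)
    t = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    x, y = _FAMILIES[model.family](t, model.c1, model.c2, model.c3)
    # Affine normalisation: exact bounding box [-c1, c1] x [-c2, c2].
    for arr, half in ((x, model.c1), (y, model.c2)):
        lo, hi = arr.min(), arr.max()
        span = hi - lo
        if span <= 0:
            raise InvalidShapeError(
                f"{model.family}: degenerate boundary (c3={model.c3})"
            )
        arr -= (hi + lo) / 2.0
        arr *= 2.0 * half / span
    pts = np.column_stack([x, y])
    if not LinearRing(pts).is_simple:  # pragma: no cover - guarded by _check_params
        raise InvalidShapeError(
            f"{model.family}: self-intersecting boundary for c3={model.c3}"
        )
    return pts


def _polygon_centroid_area(pts: np.ndarray) -> tuple[np.ndarray, float]:
    """Shoelace centroid and signed area of a closed polygon (first point not repeated)."""
    x, y = pts[:, 0], pts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area = cross.sum() / 2.0
    if abs(area) < 1e-12:
        raise ValueError("degenerate boundary: zero enclosed area")
    cx = ((x + xn) * cross).sum() / (6.0 * area)
    cy = ((y + yn) * cross).sum() / (6.0 * area)
    return np.array([cx, cy]), area


def polygon_area(pts: np.ndarray) -> float:
    """Absolute shoelace area of a closed polygon."""
    return abs(_polygon_centroid_area(np.asarray(pts, dtype=float))[1])


def _model_radius_interp(model: CrossSectionModel, angles: np.ndarray, n_dense: int = 1024):
    """Radius of the model curve, about its own centroid, at given polar angles."""
    pts = shape_boundary(model, n_dense)
    c, _ = _polygon_centroid_area(pts)
    d = pts - c
    theta = np.arctan2(d[:, 1], d[:, 0])
    r = np.hypot(d[:, 0], d[:, 1])
    order = np.argsort(theta)
    theta, r = theta[order], r[order]
    # Periodic interpolation over (-pi, pi].
    theta_ext = np.concatenate([theta - 2 * np.pi, theta, theta + 2 * np.pi])
    r_ext = np.concatenate([r, r, r])
    return np.interp(angles, theta_ext, r_ext)


_C3_FIT_BOUNDS = {
    "ellipse": (-1e-9, 1e-9),
    "flexellipse_1": (-5.0, 5.0),  # additionally constrained by |c3| < c2 via penalty
    "flexellipse_3": (-0.95, 0.95),
    "flexdrope_2": (-0.95, 0.95),
}


def fit_shape_model(
    boundary: np.ndarray, family: str
) -> tuple[CrossSectionModel, float, float]:
    """Least-squares fit of a curve family to a digitised cross-section outline.

    The residuals are radial: data points and the model curve are expressed
    in polar coordinates about the outline centroid and compared at the
    data-point angles.  Returns ``(model, r_squared, aic)`` with
    ``aic = n*ln(RSS/n) + 2k`` for ``k = 3`` parameters.
    """
    pts = np.asarray(boundary, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 8:
        raise ValueError("boundary must be an (n, 2) array with n >= 8")
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    c, _ = _polygon_centroid_area(pts)
    d = pts - c
    ang = np.arctan2(d[:, 1], d[:, 0])
    r_data = np.hypot(d[:, 0], d[:, 1])

    half_w = (pts[:, 0].max() - pts[:, 0].min()) / 2.0
    half_h = (pts[:, 1].max() - pts[:, 1].min()) / 2.0
    lo3, hi3 = _C3_FIT_BOUNDS[family]

    def resid(p):
        c1, c2, c3 = p
        if family == "flexellipse_1" and abs(c3) >= c2:
            return np.full(len(r_data), 1e3 * (1.0 + abs(c3) - c2))
        model = CrossSectionModel(family, c1, c2, c3)
        return r_data - _model_radius_interp(model, ang)

    res = least_squares(
        resid,
        x0=[max(half_w, 1e-3), max(half_h, 1e-3), 0.0],
        bounds=([1e-6, 1e-6, lo3], [np.inf, np.inf, hi3]),
        xtol=1e-12,
        ftol=1e-12,
    )
    c1, c2, c3 = res.x
    model = CrossSectionModel(family, c1, c2, c3)
    rss = float(np.sum(res.fun**2))
    tss = float(np.sum((r_data - r_data.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    n = len(r_data)
    aic = n * np.log(max(rss, 1e-300) / n) + 2 * 3
    return model, r2, float(aic)


def select_best_model(fits) -> str:
    """Pick the family with the lowest AIC; ties broken by higher R^2, then name.

    ``fits`` is a sequence of ``(family, r_squared, aic)`` tuples.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("empty fit list")
    return min(fits, key=lambda f: (f[2], -f[1], f[0]))[0]


def boundary_polygon(model: CrossSectionModel, n_points: int = 256) -> Polygon:
    """Shapely polygon of the discretised boundary (convenience)."""
    return Polygon(shape_boundary(model, n_points))
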