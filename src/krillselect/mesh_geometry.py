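"""Diamond-mesh opening geometry and fitting of digitised meshes.

A diamond mesh is parameterised by its stretched inside mesh size ``m``
(mm, twice the bar length) and the opening angle ``oa`` (degrees), the
full angle between the two bars meeting at the transverse knot.  The
opening quadrilateral has vertices

    (+-(m/2) sin(oa/2), 0)   and   (0, +-(m/2) cos(oa/2)),

so the transverse opening width is ``w = m sin(oa/2)`` and the
along-netting (towing-direction) opening is ``h = m cos(oa/2)``; ``oa =
90`` gives a square opening.  By convention the mesh length axis (the
cos component) is aligned with the towing direction, so projecting the
opening for a non-perpendicular attack angle shrinks ``h``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from shapely.geometry import LinearRing, Point


@dataclass(frozen=True)
class DiamondMesh:
    """Diamond netting mesh: size ``m`` (mm) and opening angle ``oa`` (degrees)."""

    m: float
    oa: float

    def __post_init__(self):
        if not self.m > 0:
            raise ValueError("mesh size must be positive")
        if not 0 < self.oa <= 180:
            raise ValueError("opening angle must lie in (0, 180] degrees")
        if self.oa > 90:
            warnings.warn(
                f"opening angle {self.oa} deg exceeds 90 (wider-than-square opening)",
                stacklevel=2,
            )

    @property
    def width(self) -> float:
        """Transverse opening w = m*sin(oa/2), mm."""
        return self.m * math.sin(math.radians(self.oa) / 2.0)

    @property
    def height(self) -> float:
        """Along-length opening h = m*cos(oa/2), mm."""
        return self.m * math.cos(math.radians(self.oa) / 2.0)

    @property
    def area(self) -> float:
        """Opening area = w*h/2, mm^2."""
        return self.width * self.height / 2.0


def mesh_polygon(mesh: DiamondMesh) -> np.ndarray:
    """Vertices (4, 2) of the opening quadrilateral, centroid at the origin."""
    w2, h2 = mesh.width / 2.0, mesh.height / 2.0
    if w2 <= 0 or h2 <= 0:
        raise ValueError("degenerate mesh opening")
    return np.array([[w2, 0.0], [0.0, h2], [-w2, 0.0], [0.0, -h2]])


def project_mesh(polygon: np.ndarray, attack_angle: float) -> np.ndarray:
    """Project an opening polygon for a given attack angle (degrees).

    The attack angle is measured between the animal's direction of travel
    and the netting plane; at 90 degrees the opening is seen unprojected.
    The along-tow coordinate (y by convention) is scaled by
    ``sin(attack_angle)``; the transverse coordinate is unchanged.
    """
    if not 0 < attack_angle <= 90:
        raise ValueError("attack angle must lie in (0, 90] degrees")
    poly = np.asarray(polygon, dtype=float).copy()
    poly[:, 1] *= math.sin(math.radians(attack_angle))
    return poly


@dataclass(frozen=True)
class MeshDigitization:
    """Digitised mesh corner/boundary points (x, y) in mm from an image."""

    points: np.ndarray
    mesh_id: int | str | None = None

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 4:
            raise ValueError("need at least 4 (x, y) points")
        object.__setattr__(self, "points", pts)


def _diamond_vertices(cx, cy, phi, m, oa_rad):
    w2 = m * math.sin(oa_rad / 2.0) / 2.0
    h2 = m * math.cos(oa_rad / 2.0) / 2.0
    base = np.array([[w2, 0.0], [0.0, h2], [-w2, 0.0], [0.0, -h2]])
    c, s = math.cos(phi), math.sin(phi)
    rot = base @ np.array([[c, s], [-s, c]])
    return rot + np.array([cx, cy])


def fit_diamond(dig: MeshDigitization) -> tuple[float, float, float]:
    """Fit the 4-vertex diamond template to digitised points.

    Free parameters: centre, axis orientation, mesh size ``m`` and opening
    angle ``oa``.  With exactly four points, point-to-vertex
    correspondence is optimised over the cyclic relabellings; with more,
    residuals are point-to-boundary distances.  Returns ``(m, oa, r2)``
    with ``m`` the stretched inside measure (2x bar length).
    """
    pts = dig.points
    centre = pts.mean(axis=0)
    rad = np.linalg.norm(pts - centre, axis=1)
    sv = np.linalg.svd(pts - centre, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        raise ValueError("collinear digitised points")

    m0 = 2.0 * rad.mean()
    axis = _principal_axis(pts)
    phi0 = math.atan2(axis[1], axis[0]) - math.pi / 2.0

    def solve(resid_fn, phi_init):
        return least_squares(
            resid_fn,
            x0=[centre[0], centre[1], phi_init, m0, math.radians(40.0)],
            bounds=(
                [-np.inf, -np.inf, -2 * math.pi, 1e-6, math.radians(1.0)],
                [np.inf, np.inf, 2 * math.pi, np.inf, math.radians(179.0)],
            ),
            xtol=1e-14, ftol=1e-14,
        )

    best = None
    if len(pts) == 4:
        for shift in range(4):
            for flip in (False, True):
                order = np.roll(np.arange(4)[::-1] if flip else np.arange(4), shift)

                def resid(p, order=order):
                    v = _diamond_vertices(*p[:3], p[3], p[4])
                    return (pts[order] - v).ravel()

                for dphi in (0.0, math.pi / 2.0):
                    res = solve(resid, phi0 + dphi)
                    if best is None or res.cost < best.cost:
                        best = res
    else:
        def resid(p):
            ring = LinearRing(_diamond_vertices(*p[:3], p[3], p[4]))
            return np.array([ring.distance(Point(q)) for q in pts])

        for dphi in (0.0, math.pi / 4.0, math.pi / 2.0):
            res = solve(resid, phi0 + dphi)
            if best is None or res.cost < best.cost:
                best = res

    m = float(best.x[3])
    oa = float(math.degrees(best.x[4]))
    # (m, oa) and (m, 180-oa) describe the same diamond rotated by 90 deg;
    # with free orientation they are indistinguishable, so report oa <= 90.
    if oa > 90.0:
        oa = 180.0 - oa
    rss = float(2.0 * best.cost)
    tss = float(np.sum((rad - rad.mean()) ** 2))
    # Fall back to total point scatter when the radius spread is degenerate.
    if tss < 1e-12:
        tss = float(np.sum((pts - centre) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    return m, oa, r2


def _principal_axis(pts: np.ndarray) -> np.ndarray:
    d = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(d, full_matrices=False)
    return vt[0]


def mean_mesh_size(mesh_sizes) -> float:
    """Arithmetic mean of per-mesh fitted sizes (summary utility)."""
    return float(np.mean(np.asarray(mesh_sizes, dtype=float)))
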