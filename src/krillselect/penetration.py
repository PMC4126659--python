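"""Rigid-shape mesh-penetration simulation.

A krill cross section (a rigid closed curve — the exoskeleton does not
compress) passes through a mesh opening iff some allowed in-plane
rotation and free translation place every boundary point inside the
opening polygon.  Because the opening is convex, containment of a shape
is equivalent to containment of its convex hull, and for an opening with
two pairs of parallel edges (any diamond/parallelogram, including
attack-angle projections of a diamond) the existence of a feasible
translation reduces exactly to two slab conditions:

    directional width of the hull along each edge-normal  <=  slab width,

where the slab width of a diamond with transverse opening ``w`` and
along-length opening ``h`` is ``w*h / sqrt(w**2 + h**2)`` for both edge
pairs.  The combined CS1+CS2 contact mode places both cross sections
concentrically on the body axis with a single shared rotation and
translation; that is equivalent to testing the convex hull of the union
of the two outlines.

The optimal-rotation policy scans rotations on a 0.25 degree grid over
[0, 180) and refines the best candidate with a bounded scalar
minimisation of the exact clearance function; fits are declared with a
1e-6 mm clearance tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linprog, minimize_scalar
from scipy.spatial import ConvexHull

from .mesh_geometry import DiamondMesh, mesh_polygon, project_mesh
from .morphology import VirtualIndividual
from .selectivity import DegenerateSelectionError, fit_covered_codend
from .shapes import shape_boundary

CLEARANCE_TOL = 1e-6  # mm
ROTATION_STEP = 0.25  # degrees

N_BOUNDARY_POINTS = 256


def _hull_points(boundary: np.ndarray) -> np.ndarray:
    pts = np.asarray(boundary, dtype=float)
    hull = ConvexHull(pts)
    return pts[hull.vertices]


def _polygon_is_convex(poly: np.ndarray) -> bool:
    d = np.roll(poly, -1, axis=0) - poly
    cross = d[:, 0] * np.roll(d, -1, axis=0)[:, 1] - d[:, 1] * np.roll(d, -1, axis=0)[:, 0]
    return bool(np.all(cross >= -1e-12) or np.all(cross <= 1e-12))


def _slab_geometry(poly: np.ndarray):
    """Edge-pair slab description of a centrally symmetric quadrilateral.

    Returns (normal angles (2,), slab widths (2,)) or None if the polygon
    is not a parallelogram/diamond.
    """
    poly = np.asarray(poly, dtype=float)
    if len(poly) != 4:
        return None
    centre = poly.mean(axis=0)
    if not np.allclose(poly[0] + poly[2], 2 * centre, atol=1e-9) or not np.allclose(
        poly[1] + poly[3], 2 * centre, atol=1e-9
    ):
        return None
    angles, widths = [], []
    for i in range(2):
        edge = poly[i + 1] - poly[i]
        n = np.array([edge[1], -edge[0]])
        n /= np.linalg.norm(n)
        offsets = (poly - centre) @ n
        widths.append(offsets.max() - offsets.min())
        angles.append(math.atan2(n[1], n[0]))
    return np.array(angles), np.array(widths)


def _widths_at_angles(hull: np.ndarray, angles: np.ndarray) -> np.ndarray:
    """Directional widths of a point set along unit vectors at given angles (rad)."""
    u = np.column_stack([np.cos(angles), np.sin(angles)])
    proj = hull @ u.T
    return proj.max(axis=0) - proj.min(axis=0)


def _rotate(pts: np.ndarray, angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    c, s = math.cos(a), math.sin(a)
    return pts @ np.array([[c, s], [-s, c]])


def _clearance_fixed(hull: np.ndarray, slab, rotation_deg: float) -> float:
    """Signed clearance (negative = fits) at one fixed shape rotation."""
    alphas, widths = slab
    ang = alphas - math.radians(rotation_deg)
    return float(np.max(_widths_at_angles(hull, ang) - widths))


def _min_clearance(hull: np.ndarray, slab, step_deg: float = ROTATION_STEP) -> float:
    """Minimum clearance over rotations in [0, 180), grid + local refinement."""
    alphas, widths = slab
    thetas = np.arange(0.0, 180.0, step_deg)
    ang = alphas[:, None] - np.radians(thetas)[None, :]
    w = _widths_at_angles(hull, ang.ravel()).reshape(2, -1)
    g = (w - widths[:, None]).max(axis=0)
    k = int(np.argmin(g))
    gmin = float(g[k])
    res = minimize_scalar(
        lambda t: _clearance_fixed(hull, slab, t),
        bounds=(thetas[k] - step_deg, thetas[k] + step_deg),
        method="bounded",
        options={"xatol": 1e-4},
    )
    return min(gmin, float(res.fun))


def _clearance_lp(hull: np.ndarray, poly: np.ndarray, rotation_deg: float) -> float:
    """Signed clearance for a general convex polygon via a small LP."""
    rot = _rotate(hull, rotation_deg)
    edges = np.roll(poly, -1, axis=0) - poly
    normals = np.column_stack([edges[:, 1], -edges[:, 0]])
    # orient outward (polygon centroid inside)
    centre = poly.mean(axis=0)
    signs = np.sign(np.einsum("ij,ij->i", normals, poly - centre))
    signs[signs == 0] = 1.0
    normals *= signs[:, None]
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    d = np.einsum("ij,ij->i", normals, poly)
    h_s = (rot @ normals.T).max(axis=0)
    # max delta s.t. n_i . t + delta <= d_i - h_i
    res = linprog(
        c=[0.0, 0.0, -1.0],
        A_ub=np.column_stack([normals, np.ones(len(d))]),
        b_ub=d - h_s,
        bounds=[(None, None)] * 3,
        method="highs",
    )
    if res.status != 0:  # pragma: no cover - LP on bounded feasible set
        raise RuntimeError("clearance LP failed")
    return -float(res.fun)


def shape_fits_polygon(boundary, polygon, rotation="optimal") -> bool:
    """True iff some allowed rotation + free translation fits the shape inside.

    ``rotation`` is either ``"optimal"`` (search over 0-180 degrees at
    0.25 degree resolution with local refinement) or a fixed angle in
    degrees.  The polygon must be convex.
    """
    poly = np.asarray(polygon, dtype=float)
    if not _polygon_is_convex(poly):
        raise ValueError("non-convex mesh opening polygons are out of scope")
    hull = _hull_points(boundary)
    slab = _slab_geometry(poly)
    if slab is not None:
        if rotation == "optimal":
            return _min_clearance(hull, slab) <= CLEARANCE_TOL
        return _clearance_fixed(hull, slab, float(rotation)) <= CLEARANCE_TOL
    if rotation != "optimal":
        return _clearance_lp(hull, poly, float(rotation)) >= -CLEARANCE_TOL
    thetas = np.arange(0.0, 180.0, ROTATION_STEP)
    clear = np.array([_clearance_lp(hull, poly, t) for t in thetas])
    if clear.max() >= -CLEARANCE_TOL:
        return True
    k = int(np.argmax(clear))
    res = minimize_scalar(
        lambda t: -_clearance_lp(hull, poly, t),
        bounds=(thetas[k] - ROTATION_STEP, thetas[k] + ROTATION_STEP),
        method="bounded",
        options={"xatol": 1e-4},
    )
    return -float(res.fun) >= -CLEARANCE_TOL


def _contact_hull(ind: VirtualIndividual, contact_mode: str) -> np.ndarray:
    """Convex hull of the penetrating outline(s) for a contact mode (cached)."""
    key = ("hull", contact_mode)
    if key in ind._cache:
        return ind._cache[key]
    if contact_mode == "CS1_CS2":
        if ind.cs1 is None or ind.cs2 is None:
            raise ValueError("contact mode CS1_CS2 requires both cross-section models")
        pts = np.vstack([
            shape_boundary(ind.cs1, N_BOUNDARY_POINTS),
            shape_boundary(ind.cs2, N_BOUNDARY_POINTS),
        ])
    elif contact_mode == "CS3":
        if ind.cs3 is None:
            raise ValueError("contact mode CS3 requires a CS3 model")
        pts = shape_boundary(ind.cs3, N_BOUNDARY_POINTS)
    else:
        raise ValueError(f"unknown contact mode {contact_mode!r}")
    hull = _hull_points(pts)
    ind._cache[key] = hull
    return hull


def _mesh_slab(mesh: DiamondMesh, attack_angle: float):
    poly = mesh_polygon(mesh)
    if attack_angle != 90.0:
        poly = project_mesh(poly, attack_angle)
    slab = _slab_geometry(poly)
    assert slab is not None
    return slab


@dataclass(frozen=True)
class PenetrationResult:
    individual_id: int
    mesh: DiamondMesh
    contact_mode: str
    rotation: str | float
    attack_angle: float
    escapes: bool
    clearance: float


def can_escape(
    ind: VirtualIndividual,
    mesh: DiamondMesh,
    contact_mode: str = "CS1_CS2",
    attack_angle: float = 90.0,
    rotation="optimal",
) -> PenetrationResult:
    """Decide whether one individual passes the (possibly projected) mesh.

    For the CS1_CS2 mode both cross sections must fit at a single shared
    rotation and translation (one rigid body); geometrically this is the
    convex hull of the union of the two outlines.
    """
    hull = _contact_hull(ind, contact_mode)
    slab = _mesh_slab(mesh, attack_angle)
    if rotation == "optimal":
        clearance = _min_clearance(hull, slab)
    else:
        # Fixed body orientation: rotation is the angle of the dorso-ventral
        # axis from the mesh transverse axis (90 deg = height along the
        # mesh length axis, the upright/optimal-by-symmetry placement).
        clearance = _clearance_fixed(hull, slab, 90.0 - float(rotation))
    return PenetrationResult(
        individual_id=ind.id, mesh=mesh, contact_mode=contact_mode,
        rotation=rotation, attack_angle=attack_angle,
        escapes=clearance <= CLEARANCE_TOL, clearance=clearance,
    )


def _escape_mask(
    population,
    mesh: DiamondMesh,
    contact_mode: str = "CS1_CS2",
    attack_angle: float = 90.0,
    rotation="optimal",
    step_deg: float = ROTATION_STEP,
) -> np.ndarray:
    """Vectorised escape decision for a whole population."""
    slab = _mesh_slab(mesh, attack_angle)
    alphas, widths = slab
    out = np.empty(len(population), dtype=bool)
    if rotation == "optimal":
        thetas = np.arange(0.0, 180.0, step_deg)
        ang = (alphas[:, None] - np.radians(thetas)[None, :]).ravel()
        u = np.column_stack([np.cos(ang), np.sin(ang)])
        margin = 0.02 * widths.max()
        for i, ind in enumerate(population):
            hull = _contact_hull(ind, contact_mode)
            proj = hull @ u.T
            g = ((proj.max(axis=0) - proj.min(axis=0)).reshape(2, -1)
                 - widths[:, None]).max(axis=0)
            gmin = float(g.min())
            if gmin > margin:
                out[i] = False
                continue
            if gmin <= -margin:
                out[i] = True
                continue
            out[i] = _min_clearance(hull, slab, step_deg) <= CLEARANCE_TOL
    else:
        phi = 90.0 - float(rotation)
        for i, ind in enumerate(population):
            hull = _contact_hull(ind, contact_mode)
            out[i] = _clearance_fixed(hull, slab, phi) <= CLEARANCE_TOL
    return out


def simulate_selection(
    population,
    mesh: DiamondMesh,
    contact_mode: str = "CS1_CS2",
    attack_angle: float = 90.0,
    rotation="optimal",
) -> pd.DataFrame:
    """Per-individual penetration outcomes as covered-codend style records.

    Returns a frame with columns ``length`` and ``retained`` (retained =
    did not escape).
    """
    if len(population) == 0:
        raise ValueError("empty population")
    esc = _escape_mask(population, mesh, contact_mode, attack_angle, rotation)
    return pd.DataFrame({
        "length": [ind.length for ind in population],
        "retained": (~esc).astype(int),
    })


def _fit_l50(records: pd.DataFrame):
    """Covered-codend logistic fit of simulated records -> (l50, sr, flag)."""
    try:
        fit = fit_covered_codend(records["length"], records["retained"])
    except DegenerateSelectionError:
        if records["retained"].iloc[0]:
            return math.nan, math.nan, "all_retained"
        return math.nan, math.nan, "all_escaped"
    if not fit.converged:
        return math.nan, math.nan, "no_convergence"
    flag = "knife_edge" if fit.knife_edge else "ok"
    return fit.curve.l50, fit.curve.sr, flag


def rotation_sweep(
    population,
    m: float,
    oa_set=(25, 30, 35, 40, 45),
    theta_grid=tuple(range(0, 100, 10)),
    contact_mode: str = "CS1_CS2",
    include_optimal: bool = True,
) -> pd.DataFrame:
    """L50 for fixed body rotations (degrees) across opening angles.

    ``theta = 0`` is the dorso-ventral (normal swimming) orientation with
    the body height across the mesh's transverse axis; ``theta = 90``
    aligns the body height with the mesh length axis.  Attack angle is
    the optimal 90 degrees throughout.  Non-convergent cells are flagged,
    not fatal.
    """
    rows = []
    thetas = list(theta_grid) + (["optimal"] if include_optimal else [])
    for oa in oa_set:
        mesh = DiamondMesh(m, oa)
        for theta in thetas:
            rot = "optimal" if theta == "optimal" else float(theta)
            rec = simulate_selection(population, mesh, contact_mode, 90.0, rot)
            l50, sr, flag = _fit_l50(rec)
            rows.append({"oa": oa, "theta": theta, "l50": l50, "sr": sr, "flag": flag})
    return pd.DataFrame(rows)


def attack_sweep(
    population,
    mesh: DiamondMesh,
    angle_grid=tuple(range(10, 100, 10)),
    contact_mode: str = "CS1_CS2",
) -> pd.DataFrame:
    """L50 as a function of attack angle, optimal rotation in the projected mesh."""
    rows = []
    for angle in angle_grid:
        if not 0 < angle <= 90:
            raise ValueError("attack angles must lie in (0, 90]")
        rec = simulate_selection(population, mesh, contact_mode, float(angle), "optimal")
        l50, sr, flag = _fit_l50(rec)
        rows.append({"attack_angle": angle, "l50": l50, "sr": sr, "flag": flag})
    return pd.DataFrame(rows)


def design_guide(
    mesh_sizes,
    oa_grid,
    population,
    contact_mode: str = "CS1_CS2",
) -> pd.DataFrame:
    """L50 over a mesh-size x opening-angle grid (iso-L50 design guide).

    Cells without selection over the population's length span (all
    retained or all escaped) are flagged with NaN L50.
    """
    rows = []
    for m in mesh_sizes:
        for oa in oa_grid:
            rec = simulate_selection(population, DiamondMesh(m, oa), contact_mode)
            l50, sr, flag = _fit_l50(rec)
            rows.append({"m": m, "oa": oa, "l50": l50, "sr": sr, "flag": flag})
    return pd.DataFrame(rows)
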