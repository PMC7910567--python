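"""Alpha-shape volume/area, periodic-image distance and ice-front tracking.

The alpha shape is the union of Delaunay simplices whose circumradius is
at most the alpha radius (default 0.17 nm).  Volumes are reported in
cubic angstrom, areas in nm^2, to match the conventions the growth
figures use.  Input coordinates are expected unwrapped (no imaging).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay, QhullError

from .core import Configuration, DegenerateInputError, IceKitError
from .icedetect import IceLabels, largest_cluster_atom_indices

__all__ = [
    "AlphaShapeResult",
    "FrontProfile",
    "alpha_shape_volume",
    "alpha_area_2d",
    "contact_area",
    "min_image_distance",
    "front_profile",
    "front_advancement",
    "surface_coverage",
]

_POLYMER_HEAVY_ROLES = ("methylene_C", "backbone_C", "hydroxyl_O", "amine_N")


@dataclass
class AlphaShapeResult:
    """Occupied volume and/or projected contact area of an atom set."""

    alpha: float
    n_vertices: int
    volume_A3: float | None = None
    area_nm2: float | None = None


@dataclass
class FrontProfile:
    """Ice fraction along z and the two front positions."""

    z_centers: np.ndarray
    ice_fraction: np.ndarray
    lower_front: float
    upper_front: float


def _circumradii(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    """Circumradius of each simplex (triangles in 2D, tetrahedra in 3D).

    Solves |c - p0|^2 = |c - pi|^2 for the circumcenter c.
    """
    p0 = points[simplices[:, 0]]
    rest = points[simplices[:, 1:]]
    a = 2.0 * (rest - p0[:, None, :])
    b = np.sum(rest**2, axis=2) - np.sum(p0**2, axis=1)[:, None]
    radii = np.full(len(simplices), np.inf)
    dets = np.linalg.det(a)
    ok = np.abs(dets) > 1e-300
    if np.any(ok):
        centers = np.linalg.solve(a[ok], b[ok][..., None])[..., 0]
        radii[ok] = np.linalg.norm(centers - p0[ok], axis=1)
    return radii


def _simplex_measure(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    """Area (2D) or volume (3D) of each simplex."""
    d = points.shape[1]
    p0 = points[simplices[:, 0]]
    edges = points[simplices[:, 1:]] - p0[:, None, :]
    if d == 2:
        det = edges[:, 0, 0] * edges[:, 1, 1] - edges[:, 0, 1] * edges[:, 1, 0]
        return np.abs(det) / 2.0
    return np.abs(np.einsum("ij,ij->i", edges[:, 0], np.cross(edges[:, 1], edges[:, 2]))) / 6.0


def _alpha_complex_measure(points: np.ndarray, alpha: float, seed: int = 0) -> float:
    """Total measure of Delaunay simplices with circumradius <= alpha.

    Degenerate (cospherical) point sets are perturbed by a deterministic
    1e-9 nm jitter before tetrahedralisation.
    """
    pts = points
    try:
        tri = Delaunay(pts)
    except QhullError:
        # cospherical/degenerate input: deterministic 1e-9 nm jitter
        rng = np.random.default_rng(seed)
        pts = points + rng.normal(scale=1e-9, size=points.shape)
        try:
            tri = Delaunay(pts)
        except QhullError as err:
            raise DegenerateInputError(f"degenerate point set: {err}") from None
    radii = _circumradii(pts, tri.simplices)
    keep = radii <= alpha
    return float(np.sum(_simplex_measure(pts, tri.simplices[keep])))


def alpha_shape_volume(points, alpha: float = 0.17, seed: int = 0) -> AlphaShapeResult:
    """Alpha-shape occupied volume of a 3D point set (reported in A^3)."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) < 4:
        raise DegenerateInputError("alpha-shape volume needs >= 4 points")
    if alpha <= 0:
        raise IceKitError("alpha must be positive")
    vol_nm3 = _alpha_complex_measure(pts, alpha, seed)
    return AlphaShapeResult(alpha=alpha, n_vertices=len(pts), volume_A3=vol_nm3 * 1000.0)


def alpha_area_2d(points_xy, alpha: float = 0.17, seed: int = 0) -> AlphaShapeResult:
    """Alpha-shape area of a 2D point set (nm^2); collinear sets have 0."""
    pts = np.asarray(points_xy, dtype=float).reshape(-1, 2)
    if len(pts) < 3:
        raise DegenerateInputError("alpha-shape area needs >= 3 projected points")
    if alpha <= 0:
        raise IceKitError("alpha must be positive")
    try:
        area = _alpha_complex_measure(pts, alpha, seed)
    except DegenerateInputError:
        area = 0.0  # collinear projection encloses no area
    return AlphaShapeResult(alpha=alpha, n_vertices=len(pts), area_nm2=area)


def _polymer_heavy_indices(config: Configuration) -> np.ndarray:
    return np.flatnonzero(np.isin(config.role, _POLYMER_HEAVY_ROLES))


def contact_area(
    config: Configuration,
    labels: IceLabels | None = None,
    alpha: float = 0.17,
    bound_only: bool = True,
    hbonds=None,
    proximity: float = 0.35,
) -> AlphaShapeResult:
    """xy-projected polymer-ice contact area.

    With ``bound_only`` (default) the projection uses polymer heavy atoms
    "bound on ice": within ``proximity`` of a largest-cluster water, or —
    stricter — the polymer atoms of an :class:`icekit.hbond.HBondSet` when
    one is supplied.  Otherwise all polymer heavy atoms project.
    """
    heavy = _polymer_heavy_indices(config)
    if len(heavy) == 0:
        raise IceKitError("configuration contains no polymer heavy atoms")
    if bound_only:
        if hbonds is not None:
            members = set(hbonds.partners())
            heavy = np.asarray([i for i in heavy if int(i) in members], dtype=int)
        else:
            if labels is None:
                raise IceKitError("bound_only contact_area needs labels or an HBondSet")
            cluster = largest_cluster_atom_indices(labels)
            if len(cluster) == 0:
                heavy = np.empty(0, dtype=int)
            else:
                from .core import pair_distance_matrix

                dist = pair_distance_matrix(
                    config.positions[heavy],
                    config.positions[cluster],
                    config.box,
                    config.pbc_mode,
                )
                heavy = heavy[np.min(dist, axis=1) < proximity]
    if len(heavy) < 3:
        raise DegenerateInputError("fewer than 3 projected points for contact area")
    return alpha_area_2d(config.positions[heavy][:, :2], alpha)


def min_image_distance(
    config: Configuration,
    atom_indices=None,
) -> float:
    """Minimum distance rMI between the polymer and its periodic images.

    Considers the 8 in-plane neighbor images under ``pbc_mode="xy"`` and
    all 26 images under ``"xyz"``; the zero shift is excluded but an atom
    may pair with its own image.
    """
    if atom_indices is None:
        atom_indices = _polymer_heavy_indices(config)
        if len(atom_indices) == 0:
            atom_indices = np.arange(len(config))
    pts = config.positions[np.asarray(atom_indices, dtype=int)]
    if len(pts) == 0:
        raise IceKitError("no atoms selected for rMI")
    if config.pbc_mode == "xy":
        zs = (0,)
    elif config.pbc_mode == "xyz":
        zs = (-1, 0, 1)
    else:
        raise IceKitError("rMI needs at least one periodic direction")
    best = np.inf
    for sx in (-1, 0, 1):
        for sy in (-1, 0, 1):
            for sz in zs:
                if sx == sy == 0 and sz == 0:
                    continue
                shift = np.array([sx, sy, sz]) * config.box
                d = pts[:, None, :] - (pts + shift)[None, :, :]
                best = min(best, float(np.sqrt(np.min(np.sum(d * d, axis=-1)))))
    return best


def front_profile(
    config: Configuration,
    labels: IceLabels,
    bin_width: float = 0.05,
) -> FrontProfile:
    """Ice fraction per z-bin and the outermost 0.5-crossing fronts."""
    cluster = largest_cluster_atom_indices(labels)
    if len(cluster) == 0:
        raise IceKitError("no ice cluster; front undefined")
    lz = config.box[2]
    edges = np.arange(0.0, lz + bin_width, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    z_wat = config.positions[labels.water_indices][:, 2]
    z_ice = config.positions[cluster][:, 2]
    n_wat, _ = np.histogram(z_wat, bins=edges)
    n_ice, _ = np.histogram(z_ice, bins=edges)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n_wat > 0, n_ice / np.maximum(n_wat, 1), 0.0)
    above = np.flatnonzero(frac >= 0.5)
    if len(above) == 0:
        raise IceKitError("ice fraction never reaches 0.5; front undefined")
    hi, lo = above[-1], above[0]
    if hi == len(frac) - 1:
        upper = lz
    else:
        f1, f2 = frac[hi], frac[hi + 1]
        upper = centers[hi] + (f1 - 0.5) / max(f1 - f2, 1e-12) * bin_width
    if lo == 0:
        lower = 0.0
    else:
        f1, f2 = frac[lo], frac[lo - 1]
        lower = centers[lo] - (f1 - 0.5) / max(f1 - f2, 1e-12) * bin_width
    return FrontProfile(centers, frac, float(lower), float(upper))


def front_advancement(profiles: list[FrontProfile]) -> np.ndarray:
    """Mean outward front motion vs frame 0, in angstrom per frame entry."""
    if not profiles:
        raise IceKitError("no front profiles")
    u0, l0 = profiles[0].upper_front, profiles[0].lower_front
    out = np.array(
        [((p.upper_front - u0) + (l0 - p.lower_front)) / 2.0 for p in profiles]
    )
    return out * 10.0


def surface_coverage(n_polymers: int, box) -> float:
    """Polymers per nm^2 of one xy ice face."""
    box = np.asarray(box, dtype=float)
    if box[0] <= 0 or box[1] <= 0:
        raise IceKitError("xy box lengths must be positive")
    return float(n_polymers) / float(box[0] * box[1])
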