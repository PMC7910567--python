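"""Disordered liquid-water generator (random sequential insertion)."""

from __future__ import annotations

import numpy as np

from ..core import Configuration, DensityInfeasibleError, IceKitError, minimum_image
from .lattice import OH_BOND_LENGTH, _water_config

__all__ = ["build_liquid_slab", "random_water_orientations", "insert_points"]

#: H-O-H angle of generated waters, degrees.
HOH_ANGLE_DEG = 104.52


def random_water_orientations(n: int, rng: np.random.Generator) -> np.ndarray:
    """(n, 2, 3) O->H offsets with fixed O-H length and H-O-H angle."""
    # random orthonormal pair (e1, e2) per molecule
    a = rng.normal(size=(n, 3))
    a /= np.linalg.norm(a, axis=1, keepdims=True)
    b = rng.normal(size=(n, 3))
    b -= np.sum(a * b, axis=1, keepdims=True) * a
    b /= np.linalg.norm(b, axis=1, keepdims=True)
    half = np.deg2rad(HOH_ANGLE_DEG / 2.0)
    h1 = np.cos(half) * a + np.sin(half) * b
    h2 = np.cos(half) * a - np.sin(half) * b
    return OH_BOND_LENGTH * np.stack([h1, h2], axis=1)


def insert_points(
    n: int,
    box: np.ndarray,
    min_dist: float,
    rng: np.random.Generator,
    pbc_mode: str = "xyz",
    z_range: tuple[float, float] | None = None,
    avoid: np.ndarray | None = None,
    avoid_dist: float | None = None,
    max_attempts_per_point: int = 500,
) -> np.ndarray:
    """Random sequential insertion of ``n`` points with a hard-core distance.

    Points are uniform in the box (optionally restricted to ``z_range``) and
    keep a minimum-image distance >= ``min_dist`` from each other and
    >= ``avoid_dist`` from the optional ``avoid`` sites.
    """
    box = np.asarray(box, dtype=float)
    lo = np.zeros(3)
    hi = box.copy()
    if z_range is not None:
        lo[2], hi[2] = z_range
    accepted: list[np.ndarray] = []
    acc = np.empty((0, 3))
    attempts_left = max(1000, max_attempts_per_point * n)
    while len(accepted) < n:
        if attempts_left <= 0:
            raise DensityInfeasibleError(
                f"inserted only {len(accepted)}/{n} points at min_dist={min_dist}"
            )
        attempts_left -= 1
        p = lo + rng.random(3) * (hi - lo)
        if len(accepted):
            d = minimum_image(p - acc, box, pbc_mode)
            if np.min(np.sum(d * d, axis=1)) < min_dist**2:
                continue
        if avoid is not None and len(avoid) and avoid_dist:
            d = minimum_image(p - avoid, box, pbc_mode)
            if np.min(np.sum(d * d, axis=1)) < avoid_dist**2:
                continue
        accepted.append(p)
        acc = np.asarray(accepted)
    return acc if len(accepted) else np.empty((0, 3))


def build_liquid_slab(
    box,
    number_density: float,
    min_dist: float = 0.26,
    seed: int = 0,
    pbc_mode: str = "xyz",
    z_range: tuple[float, float] | None = None,
) -> Configuration:
    """Random (ideal-gas-like) water slab at a target oxygen number density.

    ``N = round(density * volume)`` oxygens with pairwise minimum-image
    distances >= ``min_dist``; two hydrogens per oxygen at fixed geometry
    and random orientation.
    """
    box = np.asarray(box, dtype=float)
    if number_density < 0:
        raise IceKitError("number density must be >= 0")
    if min_dist < 0:
        raise IceKitError("min_dist must be >= 0")
    vol = float(np.prod(box))
    if z_range is not None:
        vol *= (z_range[1] - z_range[0]) / box[2]
    n = int(round(number_density * vol))
    rng = np.random.default_rng(seed)
    if n == 0:
        return Configuration(
            np.empty((0, 3)), np.empty(0, dtype="U4"), np.empty(0, dtype="U16"),
            box, pbc_mode=pbc_mode, bonds=np.empty((0, 2), dtype=int),
        )
    # crude jamming guard for random sequential insertion of hard spheres
    if number_density * min_dist**3 > 0.7:
        raise DensityInfeasibleError(
            f"density {number_density}/nm^3 with min_dist {min_dist} nm exceeds "
            "the random-insertion jamming guard (density*min_dist^3 <= 0.7)"
        )
    o_sites = insert_points(n, box, min_dist, rng, pbc_mode=pbc_mode, z_range=z_range)
    h_off = random_water_orientations(n, rng)
    return _water_config(o_sites, o_sites[:, None, :] + h_off, box, pbc_mode=pbc_mode)
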