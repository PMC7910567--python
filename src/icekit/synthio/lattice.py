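"""Hexagonal-ice slab generator.

The generator cell is an orthorhombic 4-molecule cell of the ice Ih oxygen
sublattice (ideal wurtzite-type positions), oriented so that a primary
prismatic plane lies in the xy-plane and the growth normal is z:

* x : hexagonal ``a`` axis (default 0.45 nm)
* y : hexagonal ``c`` axis (default 0.732 nm)
* z : prism normal; the cell height is ``sqrt(3)/2 * a`` and consecutive
  z-cells alternate their in-plane registry (ABAB stacking), so the full
  lattice is reproduced for any cell count.  With an odd ``cells_z`` the
  z-periodic seam carries a stacking fault; slabs are meant to be used
  with ``pbc_mode="xy"`` where this is irrelevant.

Hydrogens are placed on the O-O connecting lines at a fixed O-H length with
a random two-of-four occupancy per oxygen (not Bernal-Fowler exact).
"""

from __future__ import annotations

import numpy as np

from ..core import Configuration, IceKitError, minimum_image

__all__ = ["build_ice_ih", "ih_oxygen_lattice", "ih_neighbor_vectors", "OH_BOND_LENGTH"]

#: O-H bond length used for all generated waters (nm).
OH_BOND_LENGTH = 0.09572

# Fractional coordinates of the 4 oxygens in the generator cell
# (x in units of a, y in units of c, z in units of sqrt(3)/2 * a).
_BASIS = np.array(
    [
        [0.0, 0.0, 2.0 / 3.0],
        [0.0, 3.0 / 8.0, 2.0 / 3.0],
        [0.5, 0.5, 1.0 / 3.0],
        [0.5, 7.0 / 8.0, 1.0 / 3.0],
    ]
)


def ih_oxygen_lattice(
    cells_x: int, cells_y: int, cells_z: int, a_lattice: float, c_lattice: float
) -> tuple[np.ndarray, np.ndarray]:
    """Oxygen sites and box of an ice Ih slab (prismatic face in xy).

    Returns ``(sites, box)`` with 4 oxygens per cell.
    """
    if min(cells_x, cells_y, cells_z) < 1:
        raise IceKitError("cell counts must be >= 1")
    if a_lattice <= 0 or c_lattice <= 0:
        raise IceKitError("lattice constants must be positive")
    cell = np.array([a_lattice, c_lattice, np.sqrt(3.0) / 2.0 * a_lattice])
    sites = []
    for iz in range(cells_z):
        basis = _BASIS.copy()
        if iz % 2 == 1:  # ABAB registry shift
            basis[:, 0] = np.mod(basis[:, 0] + 0.5, 1.0)
        for ix in range(cells_x):
            for iy in range(cells_y):
                frac = basis + np.array([ix, iy, iz])
                sites.append(frac * cell)
    box = cell * np.array([cells_x, cells_y, cells_z])
    return np.concatenate(sites), box


def ih_neighbor_vectors(
    sites: np.ndarray, box: np.ndarray, pbc_mode: str = "xyz", k: int = 4
) -> np.ndarray:
    """Unit vectors from each oxygen to its ``k`` nearest oxygen neighbors.

    Shape ``(N, k, 3)``.  Periodic images are handled with explicit ghost
    copies, so cells smaller than twice the bond length (where one
    neighbor is two different images of the same site) work too.
    """
    from scipy.spatial import cKDTree

    margin = 0.35  # > O-O bond length
    shifts = [(0, 0, 0)]
    z_shifts = (-1, 0, 1) if pbc_mode == "xyz" else (0,)
    for sx in (-1, 0, 1):
        for sy in (-1, 0, 1):
            for sz in z_shifts:
                if (sx, sy, sz) != (0, 0, 0):
                    shifts.append((sx, sy, sz))
    all_pos = [sites]
    for s in shifts[1:]:
        ghost = sites + np.asarray(s) * box
        inside = np.all(
            (ghost > -margin) & (ghost < box + margin), axis=1
        )
        if np.any(inside):
            all_pos.append(ghost[inside])
    pool = np.vstack(all_pos)
    tree = cKDTree(pool)
    # query k+1: the nearest hit is the site itself (distance 0)
    dist, idx = tree.query(sites, k=k + 1)
    out = pool[idx[:, 1:]] - sites[:, None, :]
    return out / np.linalg.norm(out, axis=2, keepdims=True)


def place_water_hydrogens(
    sites: np.ndarray,
    neighbor_units: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Pick 2 random neighbor directions per O; H at fixed O-H length.

    Returns ``(N, 2, 3)`` hydrogen positions.
    """
    n, k, _ = neighbor_units.shape
    hpos = np.empty((n, 2, 3))
    for i in range(n):
        pick = rng.choice(k, size=2, replace=False)
        hpos[i] = sites[i] + OH_BOND_LENGTH * neighbor_units[i, pick]
    return hpos


def _water_config(
    o_sites: np.ndarray,
    h_sites: np.ndarray,
    box: np.ndarray,
    pbc_mode: str = "xyz",
    time: float | None = None,
) -> Configuration:
    """Assemble an O,H,H-ordered water configuration with O-H bonds."""
    n = len(o_sites)
    pos = np.empty((3 * n, 3))
    pos[0::3] = o_sites
    pos[1::3] = h_sites[:, 0]
    pos[2::3] = h_sites[:, 1]
    species = np.tile(["O", "H", "H"], n)
    role = np.tile(["water_O", "water_H", "water_H"], n)
    o_idx = 3 * np.arange(n)
    bonds = np.column_stack(
        [np.repeat(o_idx, 2), np.ravel(np.column_stack([o_idx + 1, o_idx + 2]))]
    )
    return Configuration(pos, species, role, box, pbc_mode=pbc_mode, time=time, bonds=bonds)


def build_ice_ih(
    cells_x: int,
    cells_y: int,
    cells_z: int,
    a_lattice: float = 0.45,
    c_lattice: float = 0.732,
    seed: int = 0,
) -> Configuration:
    """Generate a proton-disordered hexagonal-ice slab.

    4 water molecules per cell; box = cell counts times cell lengths.
    The prismatic plane is parallel to xy; growth normal is +/- z.
    """
    sites, box = ih_oxygen_lattice(cells_x, cells_y, cells_z, a_lattice, c_lattice)
    units = ih_neighbor_vectors(sites, box)
    rng = np.random.default_rng(seed)
    hpos = place_water_hydrogens(sites, units, rng)
    return _water_config(sites, hpos, box)
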