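"""Core data model: configurations, trajectories, periodic boundaries.

Units are nm / ps / amu throughout; GRO conventions are canonical.
All indices are 0-based in memory (1-based only inside GRO/PDB text).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

__all__ = [
    "ROLES",
    "ATOMIC_MASSES",
    "Configuration",
    "Trajectory",
    "IceKitError",
    "DegenerateInputError",
    "DensityInfeasibleError",
    "NoNeighborsError",
    "TopologyError",
    "FormatError",
    "minimum_image",
    "pair_distance_matrix",
    "neighbor_pairs",
    "wrap_positions",
]

#: Recognised per-atom role tags.
ROLES = frozenset(
    {
        "water_O",
        "water_H",
        "hydroxyl_O",
        "hydroxyl_H",
        "amine_N",
        "amine_H",
        "methylene_C",
        "backbone_C",
        "generic",
    }
)

#: Atomic masses in amu for the species this package generates.
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
}


class IceKitError(Exception):
    """Base class for all icekit errors."""


class DegenerateInputError(IceKitError):
    """Raised when a geometric operation receives too few / degenerate points."""


class DensityInfeasibleError(IceKitError):
    """Raised when random sequential insertion cannot reach the requested density."""


class NoNeighborsError(IceKitError):
    """Raised when an order-parameter sum has zero total switching weight."""


class TopologyError(IceKitError):
    """Raised on inconsistent bonding / role topology."""


class FormatError(IceKitError):
    """Raised on malformed structure files; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass
class Configuration:
    """A single molecular configuration in an orthorhombic box.

    Parameters
    ----------
    positions : (N, 3) float array, nm
    species : (N,) str array of chemical elements
    role : (N,) str array drawn from :data:`ROLES`
    box : (3,) float array of box lengths, nm
    pbc_mode : {"xyz", "xy"}
        ``"xy"`` is the slab mode: no imaging along z.
    time : float or None, ps
    bonds : (M, 2) int array or None
        Covalent bonds (heavy atom, hydrogen) needed for H-bond donors.
    """

    positions: np.ndarray
    species: np.ndarray
    role: np.ndarray
    box: np.ndarray
    pbc_mode: str = "xyz"
    time: float | None = None
    bonds: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.species = np.asarray(self.species, dtype="U4")
        self.role = np.asarray(self.role, dtype="U16")
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        if self.bonds is not None:
            self.bonds = np.asarray(self.bonds, dtype=int).reshape(-1, 2)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        n = len(self.positions)
        if len(self.species) != n or len(self.role) != n:
            raise IceKitError("positions/species/role length mismatch")
        if not np.all(np.isfinite(self.positions)):
            raise IceKitError("non-finite positions")
        if np.any(self.box <= 0):
            raise IceKitError("box lengths must be positive")
        if self.pbc_mode not in ("xyz", "xy"):
            raise IceKitError(f"unknown pbc_mode {self.pbc_mode!r}")
        bad = set(self.role) - ROLES
        if bad:
            raise IceKitError(f"unknown roles: {sorted(bad)}")

    # -- convenience selections -------------------------------------------
    def __len__(self) -> int:
        return len(self.positions)

    def indices(self, role: str) -> np.ndarray:
        """0-based indices of all atoms carrying ``role``."""
        return np.flatnonzero(self.role == role)

    @property
    def n_waters(self) -> int:
        return int(np.sum(self.role == "water_O"))

    def masses(self) -> np.ndarray:
        return np.array([ATOMIC_MASSES.get(s, 0.0) for s in self.species])

    def copy(self) -> "Configuration":
        return replace(
            self,
            positions=self.positions.copy(),
            species=self.species.copy(),
            role=self.role.copy(),
            box=self.box.copy(),
            bonds=None if self.bonds is None else self.bonds.copy(),
        )

    def attached_hydrogens(self) -> dict[int, list[int]]:
        """Map heavy-atom index -> list of bonded hydrogen indices."""
        out: dict[int, list[int]] = {}
        if self.bonds is None:
            return out
        for a, b in self.bonds:
            ha, hb = self.species[a] == "H", self.species[b] == "H"
            if ha and not hb:
                out.setdefault(int(b), []).append(int(a))
            elif hb and not ha:
                out.setdefault(int(a), []).append(int(b))
        return out


@dataclass
class Trajectory:
    """An ordered sequence of frames with a common topology."""

    frames: list[Configuration] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.frames:
            return
        n0 = len(self.frames[0])
        for k, f in enumerate(self.frames):
            if len(f) != n0:
                raise IceKitError(f"frame {k}: atom count {len(f)} != {n0}")
        times = [f.time for f in self.frames if f.time is not None]
        if len(times) == len(self.frames) and len(times) > 1:
            if not np.all(np.diff(times) > 0):
                raise IceKitError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Configuration]:
        return iter(self.frames)

    def __getitem__(self, i):
        return self.frames[i]

    @property
    def times(self) -> np.ndarray:
        return np.array(
            [f.time if f.time is not None else float(k) for k, f in enumerate(self.frames)]
        )


# ---------------------------------------------------------------------------
# Periodic-boundary helpers
# ---------------------------------------------------------------------------

def _pbc_mask(pbc_mode: str) -> np.ndarray:
    if pbc_mode == "xyz":
        return np.array([True, True, True])
    if pbc_mode == "xy":
        return np.array([True, True, False])
    raise IceKitError(f"unknown pbc_mode {pbc_mode!r}")


def minimum_image(dvec: np.ndarray, box: np.ndarray, pbc_mode: str = "xyz") -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors.

    Only periodic directions are wrapped (no z-imaging under ``"xy"``).
    """
    dvec = np.asarray(dvec, dtype=float)
    box = np.asarray(box, dtype=float)
    out = dvec.copy()
    mask = _pbc_mask(pbc_mode)
    for d in range(3):
        if mask[d]:
            out[..., d] -= box[d] * np.round(out[..., d] / box[d])
    return out


def wrap_positions(positions: np.ndarray, box: np.ndarray, pbc_mode: str = "xyz") -> np.ndarray:
    """Wrap coordinates into [0, L) along periodic directions."""
    pos = np.array(positions, dtype=float)
    mask = _pbc_mask(pbc_mode)
    for d in range(3):
        if mask[d]:
            pos[..., d] = np.mod(pos[..., d], box[d])
    return pos


def pair_distance_matrix(
    pos_a: np.ndarray,
    pos_b: np.ndarray,
    box: np.ndarray,
    pbc_mode: str = "xyz",
) -> np.ndarray:
    """Dense (len(a), len(b)) minimum-image distance matrix."""
    d = pos_a[:, None, :] - pos_b[None, :, :]
    d = minimum_image(d, box, pbc_mode)
    return np.sqrt(np.sum(d * d, axis=-1))


def neighbor_pairs(
    positions: np.ndarray,
    box: np.ndarray,
    pbc_mode: str,
    r_cut: float,
    chunk: int = 512,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """All ordered pairs (i, j), i != j, with minimum-image distance < r_cut.

    Returns ``(i, j, dist, dvec)`` where ``dvec = r_j - r_i`` (minimum image).
    Chunked O(N^2); intended for the few-thousand-molecule scale this
    package targets.
    """
    pos = np.asarray(positions, dtype=float)
    n = len(pos)
    ii: list[np.ndarray] = []
    jj: list[np.ndarray] = []
    dd: list[np.ndarray] = []
    vv: list[np.ndarray] = []
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        d = pos[None, :, :] - pos[start:stop, None, :]
        d = minimum_image(d, box, pbc_mode)
        dist = np.sqrt(np.sum(d * d, axis=-1))
        sub_i, sub_j = np.nonzero(dist < r_cut)
        keep = (sub_i + start) != sub_j
        sub_i, sub_j = sub_i[keep], sub_j[keep]
        ii.append(sub_i + start)
        jj.append(sub_j)
        dd.append(dist[sub_i, sub_j])
        vv.append(d[sub_i, sub_j])
    if not ii:
        e = np.empty(0, dtype=int)
        return e, e.copy(), np.empty(0), np.empty((0, 3))
    return (
        np.concatenate(ii),
        np.concatenate(jj),
        np.concatenate(dd),
        np.concatenate(vv),
    )
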