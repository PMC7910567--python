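"""Ice/liquid classification via the s6 Steinhardt order parameter.

A water molecule i is characterised by its 6th-order Steinhardt vector

    q6m(i) = sum_j sigma(|rij|) Y6m(r_ij) / sum_j sigma(|rij|)

and the neighbor-correlation order parameter

    s6(i) = sum_j sigma(|rij|) sum_m q6m*(i).q6m(j) / sum_j sigma(|rij|),

with sums over water oxygens only and the minimum-image convention applied
on the periodic directions.  With ``normalize=True`` (default) the 13-
vectors are scaled to unit norm before the dot product, so identical
environments score exactly 1 and the 0.45 ice threshold is meaningful.

The switching function is the rational form (1-x^n)/(1-x^m) with
x = (r-d0)/r0, clamped to 1 for r <= d0 and truncated to 0 at ``r_cut``
(default d0 + 3*r0).  The truncation is a deliberate finite-range
definition: the pure rational tail decays only as x^(n-m).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.special import sph_harm_y

from .core import (
    Configuration,
    IceKitError,
    NoNeighborsError,
    neighbor_pairs,
    pair_distance_matrix,
)

__all__ = [
    "SwitchingParams",
    "IceLabels",
    "SolvationShellReport",
    "rational_switch",
    "q6_vector",
    "s6",
    "s6_values",
    "classify_ice",
    "largest_ice_cluster",
    "largest_cluster_atom_indices",
    "rdf",
    "solvation_shell",
]


@dataclass(frozen=True)
class SwitchingParams:
    """Rational switching function parameters (nm)."""

    r0: float = 0.35
    d0: float = 0.0
    n: int = 6
    m: int = 12
    r_cut: float | None = None  # None -> d0 + 3*r0

    def __post_init__(self) -> None:
        if self.r0 <= 0:
            raise IceKitError("r0 must be positive")
        if not (self.m > self.n > 0):
            raise IceKitError("switching exponents must satisfy m > n > 0")

    @property
    def effective_r_cut(self) -> float:
        return self.d0 + 3.0 * self.r0 if self.r_cut is None else self.r_cut


def rational_switch(r, params: SwitchingParams | None = None):
    """Evaluate the switching weight in [0, 1] (vectorized)."""
    p = params or SwitchingParams()
    r = np.asarray(r, dtype=float)
    x = (r - p.d0) / p.r0
    with np.errstate(divide="ignore", invalid="ignore"):
        num = 1.0 - x**p.n
        den = 1.0 - x**p.m
        w = np.where(np.abs(den) > 1e-12, num / np.where(den == 0, 1.0, den),
                     float(p.n) / float(p.m))
    w = np.where(r <= p.d0, 1.0, w)
    w = np.where(r >= p.effective_r_cut, 0.0, w)
    return w if w.ndim else float(w)


@dataclass
class IceLabels:
    """Per-water classification results.

    ``water_indices`` are atom indices into the parent configuration;
    all other per-molecule arrays are aligned with it.  ``cluster_id`` is
    -1 for liquid molecules; id 0 is the largest cluster (ties broken by
    lowest member atom index).
    """

    water_indices: np.ndarray
    s6: np.ndarray
    ice: np.ndarray
    threshold: float
    cluster_id: np.ndarray | None = None
    largest_cluster_size: int = 0
    params: SwitchingParams = field(default_factory=SwitchingParams)

    @property
    def n_ice(self) -> int:
        return int(np.sum(self.ice))


@dataclass
class SolvationShellReport:
    """Waters in the first solvation shell of each methylene carbon."""

    methylene_indices: np.ndarray
    n_ice_like: np.ndarray
    n_liquid_like: np.ndarray
    cutoff: float

    @property
    def n_total(self) -> np.ndarray:
        return self.n_ice_like + self.n_liquid_like


# ---------------------------------------------------------------------------
# q6 / s6
# ---------------------------------------------------------------------------

def _q6_s6_all(
    config: Configuration,
    params: SwitchingParams,
    normalize: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized q6 and s6 for every water oxygen.

    Returns ``(water_indices, q6 (M,13), s6 (M,), has_neighbors (M,))``;
    s6 is NaN where a molecule has zero switching weight.
    """
    ow = config.indices("water_O")
    m_wat = len(ow)
    if m_wat == 0:
        raise IceKitError("configuration contains no water molecules")
    pos = config.positions[ow]
    i_idx, j_idx, dist, dvec = neighbor_pairs(
        pos, config.box, config.pbc_mode, params.effective_r_cut
    )
    w = rational_switch(dist, params)
    keep = w > 0.0
    i_idx, j_idx, dist, dvec, w = (
        i_idx[keep], j_idx[keep], dist[keep], dvec[keep], w[keep]
    )
    denom = np.bincount(i_idx, weights=w, minlength=m_wat)
    has = denom > 0.0

    q6 = np.zeros((m_wat, 13), dtype=complex)
    if len(i_idx):
        u = dvec / dist[:, None]
        theta = np.arccos(np.clip(u[:, 2], -1.0, 1.0))
        phi = np.arctan2(u[:, 1], u[:, 0])
        for mm in range(-6, 7):
            y = sph_harm_y(6, mm, theta, phi)
            re = np.bincount(i_idx, weights=w * y.real, minlength=m_wat)
            im = np.bincount(i_idx, weights=w * y.imag, minlength=m_wat)
            q6[:, mm + 6] = re + 1j * im
    q6[has] /= denom[has, None]

    qv = q6.copy()
    if normalize:
        norms = np.linalg.norm(qv, axis=1)
        ok = norms > 0
        qv[ok] /= norms[ok, None]

    s6v = np.full(m_wat, np.nan)
    if len(i_idx):
        dots = np.real(np.sum(np.conj(qv[i_idx]) * qv[j_idx], axis=1))
        num = np.bincount(i_idx, weights=w * dots, minlength=m_wat)
        s6v[has] = num[has] / denom[has]
    return ow, q6, s6v, has


def q6_vector(config: Configuration, i: int, params: SwitchingParams | None = None) -> np.ndarray:
    """13 complex components (m = -6..6) of the q6 vector of water ``i``.

    ``i`` is an atom index of a water oxygen.
    """
    p = params or SwitchingParams()
    ow, q6, _, has = _q6_s6_all(config, p, normalize=False)
    where = np.flatnonzero(ow == i)
    if len(where) == 0:
        raise IceKitError(f"atom {i} is not a water oxygen")
    k = int(where[0])
    if not has[k]:
        raise NoNeighborsError(f"water {i} has zero total switching weight")
    return q6[k]


def s6(
    config: Configuration,
    i: int,
    params: SwitchingParams | None = None,
    normalize: bool = True,
) -> float:
    """s6 order parameter of water ``i`` (atom index of its oxygen)."""
    p = params or SwitchingParams()
    ow, _, s6v, has = _q6_s6_all(config, p, normalize=normalize)
    where = np.flatnonzero(ow == i)
    if len(where) == 0:
        raise IceKitError(f"atom {i} is not a water oxygen")
    k = int(where[0])
    if not has[k]:
        raise NoNeighborsError(f"water {i} has zero total switching weight")
    return float(s6v[k])


def s6_values(
    config: Configuration,
    params: SwitchingParams | None = None,
    normalize: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """``(water_indices, s6)`` for all waters; NaN marks isolated molecules."""
    p = params or SwitchingParams()
    ow, _, s6v, _ = _q6_s6_all(config, p, normalize=normalize)
    return ow, s6v


def classify_ice(
    config: Configuration,
    params: SwitchingParams | None = None,
    threshold: float = 0.45,
    normalize: bool = True,
) -> IceLabels:
    """Flag each water as ice (s6 strictly above threshold) or liquid.

    Molecules with no neighbors inside the switching range are liquid.
    """
    p = params or SwitchingParams()
    ow, _, s6v, _ = _q6_s6_all(config, p, normalize=normalize)
    ice = np.where(np.isnan(s6v), False, s6v > threshold)
    return IceLabels(ow, s6v, ice, threshold, params=p)


def largest_ice_cluster(
    config: Configuration,
    labels: IceLabels,
    link_cutoff: float = 0.35,
) -> IceLabels:
    """Connected components of ice molecules (O-O distance < link_cutoff).

    Returns a copy of ``labels`` with ``cluster_id`` (id 0 = largest
    cluster, ties broken by lowest member atom index; -1 for liquid) and
    ``largest_cluster_size`` filled in.
    """
    ice_pos = config.positions[labels.water_indices[labels.ice]]
    n_ice = len(ice_pos)
    cluster_id = np.full(len(labels.water_indices), -1, dtype=int)
    largest = 0
    if n_ice > 0:
        i_idx, j_idx, _, _ = neighbor_pairs(
            ice_pos, config.box, config.pbc_mode, link_cutoff
        )
        graph = sparse.csr_matrix(
            (np.ones(len(i_idx)), (i_idx, j_idx)), shape=(n_ice, n_ice)
        )
        _, comp = connected_components(graph, directed=False)
        sizes = np.bincount(comp)
        ice_atom_idx = labels.water_indices[labels.ice]
        min_member = np.full(len(sizes), np.iinfo(np.int64).max, dtype=np.int64)
        np.minimum.at(min_member, comp, ice_atom_idx)
        order = np.lexsort((min_member, -sizes))
        rank = np.empty(len(sizes), dtype=int)
        rank[order] = np.arange(len(sizes))
        cluster_id[labels.ice] = rank[comp]
        largest = int(sizes.max())
    return IceLabels(
        labels.water_indices,
        labels.s6,
        labels.ice,
        labels.threshold,
        cluster_id=cluster_id,
        largest_cluster_size=largest,
        params=labels.params,
    )


def largest_cluster_atom_indices(labels: IceLabels) -> np.ndarray:
    """Atom indices (water oxygens) belonging to the largest ice cluster."""
    if labels.cluster_id is None:
        raise IceKitError("run largest_ice_cluster first")
    return labels.water_indices[labels.cluster_id == 0]


# ---------------------------------------------------------------------------
# RDF / solvation shell
# ---------------------------------------------------------------------------

def rdf(
    config: Configuration,
    center_role: str,
    other_role: str,
    r_max: float,
    bin_width: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """Radial distribution function g(r) between two role sets.

    Returns ``(r_centers, g)``.  Normalisation assumes a homogeneous
    other-role density over the full box volume.
    """
    centers = config.indices(center_role)
    others = config.indices(other_role)
    if len(centers) == 0 or len(others) == 0:
        raise IceKitError("both role sets must be non-empty")
    if r_max > np.min(config.box) / 2.0:
        raise IceKitError("r_max exceeds half the smallest box length")
    dist = pair_distance_matrix(
        config.positions[centers], config.positions[others], config.box, config.pbc_mode
    )
    if center_role == other_role:
        np.fill_diagonal(dist, np.inf)
    dist = dist[dist < r_max]
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    hist, edges = np.histogram(dist, bins=edges)
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    n_other = len(others) - (1 if center_role == other_role else 0)
    rho = n_other / float(np.prod(config.box))
    g = hist / (len(centers) * rho * shell_vol)
    r_centers = 0.5 * (edges[:-1] + edges[1:])
    return r_centers, g


def solvation_shell(
    config: Configuration,
    labels: IceLabels,
    cutoff: float = 0.45,
) -> SolvationShellReport:
    """Count shell waters around each methylene carbon, split by ice flag.

    Strict inequality at the cutoff (a water at exactly ``cutoff`` is
    excluded).
    """
    methyl = config.indices("methylene_C")
    if len(methyl) == 0:
        raise IceKitError("configuration contains no methylene_C atoms")
    wat = labels.water_indices
    dist = pair_distance_matrix(
        config.positions[methyl], config.positions[wat], config.box, config.pbc_mode
    )
    within = dist < cutoff
    n_ice = np.sum(within & labels.ice[None, :], axis=1)
    n_liq = np.sum(within & ~labels.ice[None, :], axis=1)
    return SolvationShellReport(methyl, n_ice.astype(int), n_liq.astype(int), cutoff)
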