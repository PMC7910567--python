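"""Geometric hydrogen-bond detection and polymer-ice binding analysis.

A donor-hydrogen-acceptor triplet is a hydrogen bond when the
donor-acceptor minimum-image distance is strictly below 0.3 nm and the
D-H-A angle is within the window around linearity.  The printed window
160-200 degrees folds to "angle >= 160" since a three-point angle lies in
[0, 180].

"Bonded to the ice surface" means the water partner belongs to the largest
connected ice cluster.  Protonated amines act as donors only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .core import Configuration, IceKitError, TopologyError, Trajectory, minimum_image
from .icedetect import (
    IceLabels,
    classify_ice,
    largest_cluster_atom_indices,
    largest_ice_cluster,
)
from .synthio.polymer import PolymerTopology

__all__ = [
    "HBondCriterion",
    "HBond",
    "HBondSet",
    "BindingSeries",
    "detect_hbonds",
    "polymer_ice_bonds",
    "bound_fraction_series",
    "binding_time",
    "moving_average",
    "hbond_count_distribution",
]


@dataclass(frozen=True)
class HBondCriterion:
    """Geometric criterion: D-A distance < max, folded DHA angle >= min."""

    max_da_distance: float = 0.3
    min_angle_deg: float = 160.0

    def __post_init__(self) -> None:
        if self.max_da_distance <= 0:
            raise IceKitError("max_da_distance must be positive")
        if not (0.0 < self.min_angle_deg <= 180.0):
            raise IceKitError("min_angle_deg must fold into (0, 180]")


class HBond(NamedTuple):
    donor: int
    hydrogen: int
    acceptor: int
    da_distance: float
    dha_angle: float


@dataclass
class HBondSet:
    """Detected hydrogen bonds of one frame."""

    bonds: list[HBond] = field(default_factory=list)
    time: float | None = None

    def __len__(self) -> int:
        return len(self.bonds)

    def __iter__(self):
        return iter(self.bonds)

    def donors(self) -> set[int]:
        return {b.donor for b in self.bonds}

    def partners(self) -> set[int]:
        out: set[int] = set()
        for b in self.bonds:
            out.add(b.donor)
            out.add(b.acceptor)
        return out


@dataclass
class BindingSeries:
    """Per-frame polymer-ice binding statistics."""

    times: np.ndarray
    fraction_hydroxyl: np.ndarray
    fraction_amine: np.ndarray
    n_bonds_hydroxyl: np.ndarray
    n_bonds_amine: np.ndarray
    t0: float | None = None


def _fold_angle_deg(theta: float | np.ndarray):
    """Fold an angle into [0, 180]."""
    t = np.mod(np.asarray(theta, dtype=float), 360.0)
    return np.where(t > 180.0, 360.0 - t, t)


def detect_hbonds(
    config: Configuration,
    donors,
    acceptors,
    criterion: HBondCriterion | None = None,
    hydrogens: dict[int, list[int]] | None = None,
    time: float | None = None,
) -> HBondSet:
    """All (D, H, A) triplets satisfying the geometric criterion, D != A.

    ``donors``/``acceptors`` are atom indices of heavy atoms.  Attached
    hydrogens come from ``config.bonds`` unless an explicit map is given.
    """
    crit = criterion or HBondCriterion()
    donors = np.asarray(donors, dtype=int)
    acceptors = np.asarray(acceptors, dtype=int)
    if hydrogens is None:
        hydrogens = config.attached_hydrogens()
    for d in donors:
        if not hydrogens.get(int(d)):
            raise TopologyError(f"donor atom {int(d)} has no attached hydrogens")
    out = HBondSet(time=time if time is not None else config.time)
    if len(donors) == 0 or len(acceptors) == 0:
        return out
    pos = config.positions
    seen: set[tuple[int, int]] = set()
    dvec = pos[acceptors][None, :, :] - pos[donors][:, None, :]
    dvec = minimum_image(dvec, config.box, config.pbc_mode)
    dist = np.sqrt(np.sum(dvec * dvec, axis=-1))
    di, ai = np.nonzero(dist < crit.max_da_distance)
    for k in range(len(di)):
        d = int(donors[di[k]])
        a = int(acceptors[ai[k]])
        if d == a:
            continue
        for h in hydrogens[d]:
            if h == a:
                continue
            v1 = minimum_image(pos[d] - pos[h], config.box, config.pbc_mode)
            v2 = minimum_image(pos[a] - pos[h], config.box, config.pbc_mode)
            n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
            if n1 < 1e-12 or n2 < 1e-12:
                continue
            cosang = np.dot(v1, v2) / (n1 * n2)
            ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            if ang >= crit.min_angle_deg and (h, a) not in seen:
                seen.add((h, a))
                out.bonds.append(HBond(d, h, a, float(dist[di[k], ai[k]]), ang))
    return out


def polymer_ice_bonds(
    config: Configuration,
    labels: IceLabels,
    topology: PolymerTopology | None = None,
    criterion: HBondCriterion | None = None,
) -> HBondSet:
    """Hydrogen bonds between polymer functional groups and the largest ice
    cluster, considering both donor directions (amine N donor-only)."""
    cluster_o = largest_cluster_atom_indices(labels)
    hydrox_o = config.indices("hydroxyl_O")
    amine_n = config.indices("amine_N")
    hydrogens = config.attached_hydrogens()
    merged = HBondSet(time=config.time)
    seen: set[tuple[int, int]] = set()
    if len(cluster_o) == 0 or (len(hydrox_o) == 0 and len(amine_n) == 0):
        return merged
    poly_donors = [d for d in np.concatenate([hydrox_o, amine_n]) if hydrogens.get(int(d))]
    water_donors = [d for d in cluster_o if hydrogens.get(int(d))]
    sets = [
        detect_hbonds(config, poly_donors, cluster_o, criterion, hydrogens),
        detect_hbonds(config, water_donors, hydrox_o, criterion, hydrogens),
    ]
    for hs in sets:
        for b in hs:
            if (b.hydrogen, b.acceptor) not in seen:
                seen.add((b.hydrogen, b.acceptor))
                merged.bonds.append(b)
    return merged


def _frame_labels(config: Configuration, params) -> IceLabels:
    from .params import AnalysisParams

    p = params or AnalysisParams()
    labels = classify_ice(config, p.switching, p.threshold, p.normalize)
    return largest_ice_cluster(config, labels, p.link_cutoff)


def bound_fraction_series(
    traj: Trajectory,
    topology: PolymerTopology | None = None,
    params=None,
    labels_list: list[IceLabels] | None = None,
) -> BindingSeries:
    """Per-frame fraction of distinct hydroxyl groups with >= 1 ice bond.

    Amine groups are tracked in parallel.  ``labels_list`` may carry
    precomputed clustered :class:`IceLabels` (one per frame) to avoid
    re-classification.
    """
    from .params import AnalysisParams

    p = params or AnalysisParams()
    if len(traj) == 0:
        raise IceKitError("empty trajectory")
    n_oh = int(np.sum(traj[0].role == "hydroxyl_O"))
    n_nh = int(np.sum(traj[0].role == "amine_N"))
    if n_oh == 0 and n_nh == 0:
        raise TopologyError("trajectory contains no hydroxyl or amine groups")
    times = traj.times
    f_oh = np.zeros(len(traj))
    f_nh = np.zeros(len(traj))
    n_b_oh = np.zeros(len(traj), dtype=int)
    n_b_nh = np.zeros(len(traj), dtype=int)
    for k, frame in enumerate(traj):
        labels = labels_list[k] if labels_list is not None else _frame_labels(frame, p)
        hs = polymer_ice_bonds(frame, labels, topology, p.criterion)
        oh_set = set(frame.indices("hydroxyl_O"))
        nh_set = set(frame.indices("amine_N"))
        bound_oh = {a for b in hs for a in (b.donor, b.acceptor) if a in oh_set}
        bound_nh = {b.donor for b in hs if b.donor in nh_set}
        n_b_oh[k] = sum(1 for b in hs if b.donor in oh_set or b.acceptor in oh_set)
        n_b_nh[k] = sum(1 for b in hs if b.donor in nh_set)
        if n_oh:
            f_oh[k] = len(bound_oh) / n_oh
        if n_nh:
            f_nh[k] = len(bound_nh) / n_nh
    t0 = binding_time((times, f_oh), p.binding_threshold) if n_oh else None
    return BindingSeries(times, f_oh, f_nh, n_b_oh, n_b_nh, t0=t0)


def binding_time(series, threshold: float = 0.20) -> float | None:
    """First time the instantaneous bound fraction reaches the threshold."""
    if isinstance(series, BindingSeries):
        times, fracs = series.times, series.fraction_hydroxyl
    else:
        times, fracs = series
    times = np.asarray(times, dtype=float)
    fracs = np.asarray(fracs, dtype=float)
    if len(times) == 0:
        raise IceKitError("empty binding series")
    hits = np.flatnonzero(fracs >= threshold)
    return float(times[hits[0]]) if len(hits) else None


def moving_average(values, window: int) -> np.ndarray:
    """Centered boxcar mean with shrinking edges; length preserved."""
    if window < 1 or window % 2 == 0:
        raise IceKitError("window must be odd and >= 1")
    v = np.asarray(values, dtype=float)
    h = window // 2
    out = np.empty_like(v)
    for i in range(len(v)):
        lo = max(0, i - h)
        out[i] = v[lo : i + h + 1].mean()
    return out


def hbond_count_distribution(
    traj: Trajectory,
    topology: PolymerTopology | None = None,
    group: str = "hydroxyl",
    params=None,
    labels_list: list[IceLabels] | None = None,
) -> dict[int, float]:
    """Probability mass of the per-frame group-ice bond count."""
    if group not in ("hydroxyl", "amine"):
        raise IceKitError("group must be 'hydroxyl' or 'amine'")
    if len(traj) == 0:
        raise IceKitError("empty trajectory")
    series = bound_fraction_series(traj, topology, params, labels_list=labels_list)
    counts = series.n_bonds_hydroxyl if group == "hydroxyl" else series.n_bonds_amine
    vals, freq = np.unique(counts, return_counts=True)
    return {int(v): float(f) / len(counts) for v, f in zip(vals, freq)}
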