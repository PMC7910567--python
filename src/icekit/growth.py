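"""Ice-count time series, the 100-ns growth metric and overgrowth status.

The "overgrown" call is this artifact's operational rule (the source
figures only mark it): a polymer is overgrown when, for at least
``persist`` consecutive frames, at least ``embed_fraction`` of its heavy
atoms each have >= ``min_neighbors`` largest-cluster waters within
``neighbor_cutoff``.  A polymer with a binding time that is never
overgrown is "active"; without a binding time it is "unbound".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import IceKitError, Trajectory, pair_distance_matrix
from .hbond import bound_fraction_series, moving_average
from .icedetect import IceLabels, classify_ice, largest_cluster_atom_indices, largest_ice_cluster

__all__ = [
    "GrowthSeries",
    "per_frame_labels",
    "growth_curve",
    "growth_in_window",
    "classify_overgrowth",
    "growth_rate",
]

_POLYMER_HEAVY_ROLES = ("methylene_C", "backbone_C", "hydroxyl_O", "amine_N")


@dataclass
class GrowthSeries:
    """Largest-ice-cluster size vs time."""

    times: np.ndarray  # ps
    n_ice: np.ndarray  # molecules in the largest cluster
    t0: float | None = None  # ps
    status: str | None = None  # active | overgrown | unbound


def per_frame_labels(traj: Trajectory, params=None) -> list[IceLabels]:
    """Clustered ice labels for every frame (shared by the growth ops)."""
    from .params import AnalysisParams

    p = params or AnalysisParams()
    out = []
    for frame in traj:
        labels = classify_ice(frame, p.switching, p.threshold, p.normalize)
        out.append(largest_ice_cluster(frame, labels, p.link_cutoff))
    return out


def growth_curve(
    traj: Trajectory,
    params=None,
    topology=None,
    labels_list: list[IceLabels] | None = None,
) -> GrowthSeries:
    """Largest-cluster size per frame; t0 attached when a polymer is present."""
    if len(traj) < 2:
        raise IceKitError("growth curve needs >= 2 frames")
    if labels_list is None:
        labels_list = per_frame_labels(traj, params)
    counts = np.array([lab.largest_cluster_size for lab in labels_list])
    t0 = None
    has_polymer = bool(
        np.sum(traj[0].role == "hydroxyl_O") + np.sum(traj[0].role == "amine_N")
    )
    if has_polymer:
        series = bound_fraction_series(traj, topology, params, labels_list=labels_list)
        t0 = series.t0
    return GrowthSeries(traj.times, counts, t0=t0)


def growth_in_window(
    series: GrowthSeries,
    t0: float | None = None,
    window_ns: float = 100.0,
) -> float:
    """Cluster-size change over ``window_ns`` starting at t0 (linear
    interpolation between frames)."""
    t0 = series.t0 if t0 is None else t0
    if t0 is None:
        raise IceKitError("no binding time; growth window undefined")
    t1 = t0 + window_ns * 1000.0
    if t1 > series.times[-1] + 1e-9:
        raise IceKitError("trajectory does not extend a full window past t0")
    c0 = float(np.interp(t0, series.times, series.n_ice))
    c1 = float(np.interp(t1, series.times, series.n_ice))
    return c1 - c0


def classify_overgrowth(
    traj: Trajectory,
    series: GrowthSeries | None = None,
    params=None,
    embed_fraction: float = 0.9,
    neighbor_cutoff: float = 0.35,
    min_neighbors: int = 4,
    persist: int = 5,
    labels_list: list[IceLabels] | None = None,
) -> str:
    """Classify the polymer fate: ``overgrown``, ``active`` or ``unbound``."""
    heavy = np.flatnonzero(np.isin(traj[0].role, _POLYMER_HEAVY_ROLES))
    if len(heavy) == 0:
        raise IceKitError("trajectory contains no polymer")
    if labels_list is None:
        labels_list = per_frame_labels(traj, params)
    if series is None:
        series = growth_curve(traj, params, labels_list=labels_list)
    run = 0
    overgrown = False
    for frame, labels in zip(traj, labels_list):
        cluster = largest_cluster_atom_indices(labels)
        embedded = False
        if len(cluster) >= min_neighbors:
            dist = pair_distance_matrix(
                frame.positions[heavy], frame.positions[cluster],
                frame.box, frame.pbc_mode,
            )
            n_close = np.sum(dist < neighbor_cutoff, axis=1)
            embedded = np.mean(n_close >= min_neighbors) >= embed_fraction
        run = run + 1 if embedded else 0
        if run >= persist:
            overgrown = True
            break
    if overgrown:
        return "overgrown"
    return "active" if series.t0 is not None else "unbound"


def growth_rate(series: GrowthSeries, smoothing_window: int = 5) -> np.ndarray:
    """Centered finite-difference growth rate in molecules/ns after boxcar
    smoothing of the count series."""
    if len(series.times) < 3:
        raise IceKitError("growth rate needs >= 3 frames")
    smooth = moving_average(series.n_ice.astype(float), smoothing_window)
    t_ns = series.times / 1000.0
    return np.gradient(smooth, t_ns)
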