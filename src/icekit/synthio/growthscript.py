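"""Scripted frame-by-frame ice "growth movies".

A full hexagonal-ice template spans the box; an initial slab of template
sites around the box mid-plane starts as ice and a random liquid fills the
rest.  Each frame relocates the scheduled number of liquid molecules onto
the template sites nearest the growth front, so the crystal grows along
+/- z with a conserved atom count.  A polymer can be scripted to bind at a
programmed frame (a chosen fraction of its hydroxyls is placed in ideal
hydrogen-bond geometry to surface ice waters), to stall the front for a
window, and optionally to be engulfed (its heavy atoms are re-seated on
vacant lattice sites and conversion resumes around it).

After binding, any non-engulfing growth is restricted to the face away
from the polymer so that the bound face genuinely stalls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..core import Configuration, IceKitError, Trajectory, minimum_image
from .lattice import OH_BOND_LENGTH, ih_neighbor_vectors, ih_oxygen_lattice
from .liquid import insert_points, random_water_orientations
from .polymer import PolymerTopology

__all__ = ["GrowthScript", "build_growth_trajectory"]

_ICE_GAP = 0.44   # liquid clearance from occupied lattice sites at t=0 (nm)
_CLASH = 0.42     # liquid-ice clash distance; kept above the 0.35 cluster
                  # link cutoff (stray liquid can never bridge into the
                  # crystal cluster) and at the first-shell switching range
                  # (liquid does not dilute the s6 of front molecules)
_POLY_CLASH = 0.28  # liquid-polymer clash distance (nm)
_SITE_SEP = 0.30  # min separation of polymer-occupied lattice sites (nm)


@dataclass
class GrowthScript:
    """Parameters of a scripted growth trajectory."""

    n_frames: int
    dt_ps: float = 1000.0
    cells_x: int = 6
    cells_y: int = 4
    cells_z: int = 24
    slab_extent_nm: float = 1.6
    schedule: object = 0  # int (constant per frame) or (n_frames,) sequence
    bind_frame: int | None = None
    stall_frames: int = 0
    engulf: bool = False
    bind_fraction: float = 0.4
    liquid_density: float = 24.0
    min_dist: float = 0.27
    seed: int = 0
    a_lattice: float = 0.45
    c_lattice: float = 0.732

    def schedule_array(self) -> np.ndarray:
        if np.isscalar(self.schedule):
            sched = np.full(self.n_frames, int(self.schedule))
        else:
            sched = np.asarray(self.schedule, dtype=int)
            if len(sched) != self.n_frames:
                raise IceKitError("schedule length must equal n_frames")
        if np.any(sched < 0):
            raise IceKitError("schedule must be non-negative")
        return sched

    def validate(self) -> None:
        if self.n_frames < 1:
            raise IceKitError("n_frames must be >= 1")
        self.schedule_array()
        if self.bind_frame is not None and not (0 <= self.bind_frame < self.n_frames):
            raise IceKitError("programmed binding frame must be < n_frames")
        if self.stall_frames < 0:
            raise IceKitError("stall duration must be >= 0")
        if self.engulf and self.bind_frame is None:
            raise IceKitError("engulf requires a programmed binding frame")


class _GrowthState:
    """Mutable bookkeeping while frames are emitted."""

    def __init__(self, script: GrowthScript, polymer):
        script.validate()
        self.script = script
        self.rng = np.random.default_rng(script.seed)
        self.sites, self.box = ih_oxygen_lattice(
            script.cells_x, script.cells_y, script.cells_z,
            script.a_lattice, script.c_lattice,
        )
        self.units = ih_neighbor_vectors(self.sites, self.box)
        zc = self.box[2] / 2.0
        dz = np.abs(self.sites[:, 2] - zc)
        self.zc = zc
        self.dz = dz
        self.init_site_idx = np.flatnonzero(dz <= script.slab_extent_nm / 2.0)
        if len(self.init_site_idx) == 0:
            raise IceKitError("initial slab extent selects no lattice sites")
        rest = np.flatnonzero(dz > script.slab_extent_nm / 2.0)
        self.pool = list(rest[np.argsort(dz[rest], kind="stable")])
        self.site_state = np.zeros(len(self.sites), dtype=np.int8)  # 0 free 1 ice 2 polymer
        self.site_state[self.init_site_idx] = 1
        # template adjacency (4 bonded neighbor sites each, no z imaging)
        n_sites = len(self.sites)
        self.adj = np.empty((n_sites, 4), dtype=int)
        chunk = 512
        for start in range(0, n_sites, chunk):
            stop = min(start + chunk, n_sites)
            d = minimum_image(
                self.sites[None, :, :] - self.sites[start:stop, None, :], self.box, "xy"
            )
            dist = np.sqrt(np.sum(d * d, axis=-1))
            dist[np.arange(stop - start), np.arange(start, stop)] = np.inf
            self.adj[start:stop] = np.argsort(dist, axis=1)[:, :4]

        self.polymer_cfg = None
        self.topology: PolymerTopology | None = None
        if polymer is not None:
            self.polymer_cfg, self.topology = polymer
        self._setup_waters()
        self._setup_polymer_poses()

    # -- initial waters ---------------------------------------------------
    def _setup_waters(self) -> None:
        s = self.script
        ice_o = self.sites[self.init_site_idx]
        vol_liq = (
            self.box[2] - s.slab_extent_nm - 2.0 * _ICE_GAP
        ) * self.box[0] * self.box[1]
        n_liq = int(round(s.liquid_density * vol_liq))
        avoid = ice_o
        if self.polymer_cfg is not None:
            avoid = np.vstack([avoid, self._pose_far])
        liq_o = insert_points(
            n_liq, self.box, s.min_dist, self.rng, pbc_mode="xy",
            avoid=avoid, avoid_dist=_ICE_GAP,
        )
        self.n_ice0 = len(ice_o)
        self.o_pos = np.vstack([ice_o, liq_o])
        self.is_ice = np.zeros(len(self.o_pos), dtype=bool)
        self.is_ice[: self.n_ice0] = True
        self.h_off = random_water_orientations(len(self.o_pos), self.rng)
        for row, si in enumerate(self.init_site_idx):
            self.h_off[row] = OH_BOND_LENGTH * self.units[si][
                self.rng.choice(4, size=2, replace=False)
            ]
        self.truncated = False

    # -- polymer poses ----------------------------------------------------
    @property
    def _pose_far(self) -> np.ndarray:
        cfg = self.polymer_cfg
        rel = cfg.positions - cfg.positions.mean(axis=0)
        ext = rel[:, 2].max() - rel[:, 2].min()
        z_far = self.box[2] - 0.45 - ext / 2.0
        if z_far - ext / 2.0 < self.zc:
            raise IceKitError("box too short to keep the unbound polymer away from ice")
        target = np.array([self.box[0] / 2.0, self.box[1] / 2.0, z_far])
        return rel + target

    def _setup_polymer_poses(self) -> None:
        s = self.script
        self.pose_far = None if self.polymer_cfg is None else self._pose_far
        self.pose_bound = None
        self.pose_engulf = None
        self.engulf_frame = None
        self.embed_sites: np.ndarray | None = None
        if self.polymer_cfg is not None and s.bind_frame is not None and s.engulf:
            self.engulf_frame = s.bind_frame + s.stall_frames

    def _make_bound_pose(self) -> None:
        """Anchor a spread subset of hydroxyls to the current top ice layer."""
        s = self.script
        ice_idx = np.flatnonzero(self.site_state == 1)
        top_z = self.sites[ice_idx, 2].max()
        top = ice_idx[self.sites[ice_idx, 2] > top_z - 0.1]
        oh = self.topology.indices("hydroxyl_O")
        n_oh = len(oh)
        if n_oh == 0:
            raise IceKitError("scripted binding requires a polymer with hydroxyls")
        m = max(1, int(np.ceil(s.bind_fraction * n_oh)))
        if m > len(top):
            raise IceKitError("not enough surface sites to anchor the requested hydroxyls")
        order = np.lexsort((self.sites[top, 1], self.sites[top, 0]))
        anchors = top[order[np.linspace(0, len(top) - 1, m).round().astype(int)]]
        bind_oh = oh[np.linspace(0, n_oh - 1, m).round().astype(int)]

        cfg = self.polymer_cfg
        rel = cfg.positions - cfg.positions.mean(axis=0)
        heavy = self.topology.heavy_indices
        dzmin = rel[heavy, 2].min()
        target = np.array(
            [self.box[0] / 2.0, self.box[1] / 2.0, top_z + 0.45 - dzmin]
        )
        pose = rel + target
        hmap = {
            int(mono["hydroxyl_O"]): int(mono["hydroxyl_H"][0])
            for mono in self.topology.atoms
            if "hydroxyl_O" in mono
        }
        for o_idx, site in zip(bind_oh, anchors):
            apos = self.sites[site]
            pose[o_idx] = apos + np.array([0.0, 0.0, 0.28])
            pose[hmap[int(o_idx)]] = apos + np.array([0.0, 0.0, 0.28 - OH_BOND_LENGTH])
        self.pose_bound = pose
        self.bound_anchor_sites = anchors

    def _assign_engulf_sites(self) -> None:
        """Seat each polymer heavy atom on a vacant lattice site near the front."""
        cand = [si for si in self.pool if self.sites[si, 2] > self.zc]
        cand.sort(key=lambda si: tuple(self.sites[si][[2, 0, 1]]))
        heavy = self.topology.heavy_indices
        assigned: list[int] = []
        for si in cand:  # pack low layers first; keeps the engulf region compact
            if len(assigned) == len(heavy):
                break
            p = self.sites[si]
            if assigned:
                sep = minimum_image(p - self.sites[np.asarray(assigned)], self.box, "xy")
                if np.min(np.sum(sep * sep, axis=1)) < _SITE_SEP**2:
                    continue
            assigned.append(si)
        if len(assigned) < len(heavy):
            raise IceKitError("could not seat polymer atoms on lattice sites for engulfment")
        self.embed_sites = np.asarray(assigned, dtype=int)
        self.site_state[self.embed_sites] = 2
        self.pool = [si for si in self.pool if self.site_state[si] != 2]
        # engulfed pose: heavy atoms on sites, hydrogens hang off their parents
        cfg = self.polymer_cfg
        pose = np.array(cfg.positions)
        for h_idx, site in zip(heavy, self.embed_sites):
            pose[h_idx] = self.sites[site]
        hyd = cfg.attached_hydrogens() if cfg.bonds is not None else {}
        parent_of = {h: heavy_i for heavy_i, hs in hyd.items() for h in hs}
        for a in range(len(pose)):
            if cfg.species[a] == "H":
                par = parent_of.get(a)
                if par is None:
                    continue
                u = self.rng.normal(size=3)
                u /= np.linalg.norm(u)
                pose[a] = pose[par] + 0.10 * u
        self.pose_engulf = pose

    # -- frame emission ---------------------------------------------------
    def _pick_sites(self, candidates: list[int], k: int, cost: np.ndarray) -> list[int]:
        """Greedy crystal-growth ordering: prefer sites already touching
        >= 2 ice neighbors, then smallest cost; chosen sites count as ice
        for subsequent picks within the frame."""
        chosen: list[int] = []
        cand = [si for si in candidates if self.site_state[si] == 0]
        for _ in range(k):
            best, best_key = None, None
            for si in cand:
                if self.site_state[si] != 0:
                    continue
                nn = int(np.sum(self.site_state[self.adj[si]] == 1))
                key = (-min(nn, 2), cost[si])
                if best_key is None or key < best_key:
                    best, best_key = si, key
            if best is None:
                break
            self.site_state[best] = 1
            chosen.append(best)
        return chosen

    def _frame_conversion_sites(self, frame: int, k: int) -> list[int]:
        s = self.script
        if k <= 0 or not self.pool:
            if k > 0:
                self.truncated = True
            return []
        if s.bind_frame is None or frame < s.bind_frame:
            chosen = self._pick_sites(self.pool, k, self.dz)
        elif frame < s.bind_frame + s.stall_frames:
            return []
        elif s.engulf:
            cost = np.full(len(self.sites), np.inf)
            for si in self.pool:
                dv = minimum_image(
                    self.sites[si] - self.sites[self.embed_sites], self.box, "xy"
                )
                cost[si] = float(np.min(np.sum(dv * dv, axis=1)))
            chosen = self._pick_sites(self.pool, k, cost)
        else:  # grow only on the face away from the bound polymer
            lower = [si for si in self.pool if self.sites[si, 2] < self.zc]
            chosen = self._pick_sites(lower, k, self.dz)
        for si in chosen:
            self.pool.remove(si)
        if len(chosen) < k:
            self.truncated = True
        return chosen

    def _convert(self, site_indices: list[int], polymer_pose: np.ndarray | None) -> None:
        for si in site_indices:
            liquid = np.flatnonzero(~self.is_ice)
            if len(liquid) == 0:
                self.truncated = True
                return
            d = minimum_image(self.o_pos[liquid] - self.sites[si], self.box, "xy")
            pick = liquid[int(np.argmin(np.sum(d * d, axis=1)))]
            self.o_pos[pick] = self.sites[si]
            self.h_off[pick] = OH_BOND_LENGTH * self.units[si][
                self.rng.choice(4, size=2, replace=False)
            ]
            self.is_ice[pick] = True
            self.site_state[si] = 1
        self._cleanup_clashes(polymer_pose)

    def _cleanup_clashes(self, polymer_pose: np.ndarray | None) -> None:
        """Relocate liquid molecules overlapping ice or the polymer."""
        liquid = np.flatnonzero(~self.is_ice)
        if len(liquid) == 0:
            return
        ice_o = self.o_pos[self.is_ice]
        d = minimum_image(
            self.o_pos[liquid][:, None, :] - ice_o[None, :, :], self.box, "xy"
        )
        bad_mask = np.min(np.sum(d * d, axis=-1), axis=1) < _CLASH**2
        if polymer_pose is not None:
            d = minimum_image(
                self.o_pos[liquid][:, None, :] - polymer_pose[None, :, :], self.box, "xy"
            )
            bad_mask |= np.min(np.sum(d * d, axis=-1), axis=1) < _POLY_CLASH**2
        bad = liquid[bad_mask]
        for w in bad:
            placed = False
            for _ in range(2000):
                p = self.rng.random(3) * self.box
                keep = np.ones(len(self.o_pos), dtype=bool)
                keep[w] = False
                dd = minimum_image(p - self.o_pos[keep], self.box, "xy")
                if np.min(np.sum(dd * dd, axis=1)) < self.script.min_dist**2:
                    continue
                dd = minimum_image(p - self.sites[self.site_state > 0], self.box, "xy")
                if np.min(np.sum(dd * dd, axis=1)) < (_CLASH + 0.01) ** 2:
                    continue
                if polymer_pose is not None:
                    dd = minimum_image(p - polymer_pose, self.box, "xy")
                    if np.min(np.sum(dd * dd, axis=1)) < _POLY_CLASH**2:
                        continue
                self.o_pos[w] = p
                self.h_off[w] = random_water_orientations(1, self.rng)[0]
                placed = True
                break
            if not placed:
                self.truncated = True

    def polymer_pose(self, frame: int) -> np.ndarray | None:
        if self.polymer_cfg is None:
            return None
        s = self.script
        if s.bind_frame is None or frame < s.bind_frame:
            return self.pose_far
        if self.engulf_frame is not None and frame >= self.engulf_frame:
            return self.pose_engulf
        return self.pose_bound

    def snapshot(self, frame: int) -> Configuration:
        n = len(self.o_pos)
        pose = self.polymer_pose(frame)
        n_poly = 0 if pose is None else len(pose)
        pos = np.empty((3 * n + n_poly, 3))
        pos[0 : 3 * n : 3] = self.o_pos
        pos[1 : 3 * n : 3] = self.o_pos + self.h_off[:, 0]
        pos[2 : 3 * n : 3] = self.o_pos + self.h_off[:, 1]
        species = np.empty(3 * n + n_poly, dtype="U4")
        role = np.empty(3 * n + n_poly, dtype="U16")
        species[: 3 * n] = np.tile(["O", "H", "H"], n)
        role[: 3 * n] = np.tile(["water_O", "water_H", "water_H"], n)
        o_idx = 3 * np.arange(n)
        bonds = [
            np.column_stack(
                [np.repeat(o_idx, 2), np.ravel(np.column_stack([o_idx + 1, o_idx + 2]))]
            )
        ]
        if pose is not None:
            pos[3 * n :] = pose
            species[3 * n :] = self.polymer_cfg.species
            role[3 * n :] = self.polymer_cfg.role
            if self.polymer_cfg.bonds is not None and len(self.polymer_cfg.bonds):
                bonds.append(self.polymer_cfg.bonds + 3 * n)
        return Configuration(
            pos, species, role, self.box, pbc_mode="xy",
            time=frame * self.script.dt_ps,
            bonds=np.vstack(bonds),
        )


def build_growth_trajectory(script: GrowthScript, polymer=None) -> Trajectory:
    """Run a :class:`GrowthScript` and return the synthetic trajectory.

    ``polymer`` is an optional ``(Configuration, PolymerTopology)`` pair as
    produced by :func:`icekit.synthio.build_polymer`.  If the schedule
    exhausts the available liquid (or lattice sites) the trajectory is
    truncated and ``trajectory.meta["truncated"]`` is set.
    """
    state = _GrowthState(script, polymer)
    sched = script.schedule_array()
    frames = []
    for t in range(script.n_frames):
        pose_changed = False
        if polymer is not None and script.bind_frame is not None and t == script.bind_frame:
            state._make_bound_pose()
            pose_changed = True
        if state.engulf_frame is not None and t == state.engulf_frame:
            state._assign_engulf_sites()
            pose_changed = True
        chosen = state._frame_conversion_sites(t, int(sched[t]))
        state._convert(chosen, state.polymer_pose(t))
        if pose_changed:
            state._cleanup_clashes(state.polymer_pose(t))
        frames.append(state.snapshot(t))
    traj = Trajectory(frames)
    traj.meta["truncated"] = state.truncated
    traj.meta["n_ice_initial"] = state.n_ice0
    if polymer is not None:
        traj.meta["polymer_offset"] = 3 * len(state.o_pos)
    return traj
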