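"""Vinyl-alcohol / vinyl-amine polymer builders and radius of gyration.

Each monomer contributes a backbone methylene carbon (CH2, ``methylene_C``),
a backbone CH carbon (``backbone_C``) and either a hydroxyl (-OH, VA) or a
protonated amine (-NH3+, VAm) side group attached to the CH carbon.
Coordinates are a decorated self-avoiding walk, not force-field geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..core import ATOMIC_MASSES, Configuration, IceKitError

__all__ = ["PolymerTopology", "build_polymer", "radius_of_gyration", "parse_block_layout"]

_CC_BOND = 0.154  # nm
_CO_BOND = 0.143
_CN_BOND = 0.147
_OH_BOND = 0.0957
_NH_BOND = 0.101
_STERIC_MIN = 0.08  # nm; below this a scaled conformation is rejected


@dataclass
class PolymerTopology:
    """Monomer-resolved atom map of a single chain.

    ``atoms[k]`` maps role -> atom index (``amine_H``/``hydroxyl_H`` map to a
    list).  ``bonds`` lists all covalent bonds (heavy-heavy and heavy-H).
    """

    block_layout: list[str]
    atoms: list[dict] = field(default_factory=list)
    bonds: list[tuple[int, int]] = field(default_factory=list)

    @property
    def dp(self) -> int:
        return len(self.block_layout)

    def indices(self, role: str) -> np.ndarray:
        out: list[int] = []
        for mono in self.atoms:
            v = mono.get(role)
            if v is None:
                continue
            out.extend(v if isinstance(v, list) else [v])
        return np.asarray(out, dtype=int)

    @property
    def all_indices(self) -> np.ndarray:
        out: list[int] = []
        for mono in self.atoms:
            for v in mono.values():
                out.extend(v if isinstance(v, list) else [v])
        return np.asarray(sorted(out), dtype=int)

    @property
    def heavy_indices(self) -> np.ndarray:
        out: list[int] = []
        for mono in self.atoms:
            for role, v in mono.items():
                if role.endswith("_H"):
                    continue
                out.extend(v if isinstance(v, list) else [v])
        return np.asarray(sorted(out), dtype=int)

    def to_json(self, path: str) -> None:
        import json

        with open(path, "w") as fh:
            json.dump(
                {
                    "block_layout": self.block_layout,
                    "atoms": self.atoms,
                    "bonds": [list(map(int, b)) for b in self.bonds],
                },
                fh,
            )

    @classmethod
    def from_json(cls, path: str) -> "PolymerTopology":
        import json

        with open(path) as fh:
            data = json.load(fh)
        return cls(
            block_layout=data["block_layout"],
            atoms=data["atoms"],
            bonds=[tuple(b) for b in data["bonds"]],
        )

    def validate(self) -> None:
        for kind, mono in zip(self.block_layout, self.atoms):
            if kind == "VA":
                if "hydroxyl_O" not in mono or len(mono.get("hydroxyl_H", [])) != 1:
                    raise IceKitError("VA monomer must own one hydroxyl_O and one hydroxyl_H")
            elif kind == "VAm":
                if "amine_N" not in mono or len(mono.get("amine_H", [])) != 3:
                    raise IceKitError("VAm monomer must own one amine_N and three amine_H")
            else:
                raise IceKitError(f"unknown monomer type {kind!r}")


def parse_block_layout(spec: str) -> list[str]:
    """Parse e.g. ``"VA*5+VAm*5"`` or ``"VA:20"`` into a monomer list."""
    layout: list[str] = []
    for part in spec.replace(":", "*").split("+"):
        part = part.strip()
        if "*" in part:
            name, count = part.split("*")
            layout.extend([name.strip()] * int(count))
        elif part:
            layout.append(part)
    return layout


def radius_of_gyration(config: Configuration, atom_subset=None) -> float:
    """Mass-weighted RMS distance from the center of mass (nm)."""
    idx = np.arange(len(config)) if atom_subset is None else np.asarray(atom_subset, dtype=int)
    if len(idx) == 0:
        raise IceKitError("radius_of_gyration: empty atom subset")
    pos = config.positions[idx]
    mass = config.masses()[idx]
    if np.sum(mass) <= 0:
        raise IceKitError("radius_of_gyration: zero total mass")
    com = np.average(pos, axis=0, weights=mass)
    return float(np.sqrt(np.average(np.sum((pos - com) ** 2, axis=1), weights=mass)))


def _perp_unit(v: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    w = rng.normal(size=3)
    w -= np.dot(w, v) * v
    nrm = np.linalg.norm(w)
    if nrm < 1e-12:
        return _perp_unit(v, rng)
    return w / nrm


def _backbone_walk(
    n_carbons: int, conformation: str, rng: np.random.Generator
) -> np.ndarray:
    """Self-avoiding backbone walk with fixed C-C bond length."""
    pos = np.zeros((n_carbons, 3))
    if conformation == "extended":
        # near-planar zigzag along x with small noise
        theta = np.deg2rad(111.0 / 2.0)
        for i in range(1, n_carbons):
            step = np.array(
                [np.sin(theta), (np.cos(theta) if i % 2 else -np.cos(theta)), 0.0]
            )
            step = step + rng.normal(scale=0.02, size=3)
            step /= np.linalg.norm(step)
            pos[i] = pos[i - 1] + _CC_BOND * step
        return pos
    bias = 0.6 if conformation == "compact" else 0.0
    for i in range(1, n_carbons):
        for _ in range(400):
            step = rng.normal(size=3)
            step /= np.linalg.norm(step)
            if bias and i > 2:
                com = pos[:i].mean(axis=0)
                inward = com - pos[i - 1]
                nrm = np.linalg.norm(inward)
                if nrm > 1e-9:
                    step = step + bias * inward / nrm
                    step /= np.linalg.norm(step)
            cand = pos[i - 1] + _CC_BOND * step
            if i >= 2:
                d2 = np.sum((pos[: i - 1] - cand) ** 2, axis=1)
                if np.min(d2) < 0.20**2:
                    continue
            pos[i] = cand
            break
        else:
            raise IceKitError("self-avoiding walk failed; try another seed")
    return pos


def build_polymer(
    block_layout,
    conformation: str = "coil",
    target_rg: float | None = None,
    seed: int = 0,
    box=None,
) -> tuple[Configuration, PolymerTopology]:
    """Build a labeled polymer chain.

    Parameters
    ----------
    block_layout : sequence of "VA"/"VAm" (or a spec string, see
        :func:`parse_block_layout`)
    conformation : {"coil", "compact", "extended"}
        "coil" is unrestrained; "compact"/"extended" default their target
        radius of gyration to 0.5 / 0.95 nm unless ``target_rg`` overrides.
    target_rg : float or None
        If given, coordinates are affinely scaled about the center of mass so
        the mass-weighted radius of gyration matches to well within 2%.
    """
    if isinstance(block_layout, str):
        block_layout = parse_block_layout(block_layout)
    block_layout = list(block_layout)
    if len(block_layout) < 2:
        raise IceKitError("degree of polymerisation must be >= 2")
    if conformation not in ("coil", "compact", "extended"):
        raise IceKitError(f"unknown conformation {conformation!r}")
    if target_rg is None and conformation != "coil":
        target_rg = 0.5 if conformation == "compact" else 0.95
    rng = np.random.default_rng(seed)
    backbone = _backbone_walk(2 * len(block_layout), conformation, rng)

    positions: list[np.ndarray] = []
    species: list[str] = []
    roles: list[str] = []
    topo = PolymerTopology(block_layout)
    for k, kind in enumerate(block_layout):
        c2, c1 = backbone[2 * k], backbone[2 * k + 1]
        mono: dict = {}
        i_c2 = len(positions)
        positions.append(c2)
        species.append("C")
        roles.append("methylene_C")
        mono["methylene_C"] = i_c2
        i_c1 = len(positions)
        positions.append(c1)
        species.append("C")
        roles.append("backbone_C")
        mono["backbone_C"] = i_c1
        topo.bonds.append((i_c2, i_c1))
        if k > 0:
            topo.bonds.append((i_c2 - 1, i_c2))  # previous backbone_C - this methylene_C
        # side group direction: perpendicular-ish choice with max clearance
        axis = c1 - c2
        axis /= np.linalg.norm(axis)
        placed = np.asarray(positions) if positions else np.empty((0, 3))
        obstacles = np.vstack([backbone, placed]) if len(placed) else backbone
        best_side, best_clearance = None, -1.0
        for _ in range(16):
            cand = _perp_unit(axis, rng)
            probe = c1 + _CO_BOND * cand
            clear = float(np.min(np.linalg.norm(obstacles - probe, axis=1)))
            if clear > best_clearance:
                best_side, best_clearance = cand, clear
        side = best_side
        if kind == "VA":
            o = c1 + _CO_BOND * side
            h = o + _OH_BOND * side
            i_o = len(positions)
            positions.extend([o, h])
            species.extend(["O", "H"])
            roles.extend(["hydroxyl_O", "hydroxyl_H"])
            mono["hydroxyl_O"] = i_o
            mono["hydroxyl_H"] = [i_o + 1]
            topo.bonds.extend([(i_c1, i_o), (i_o, i_o + 1)])
        else:  # VAm
            npos = c1 + _CN_BOND * side
            i_n = len(positions)
            positions.append(npos)
            species.append("N")
            roles.append("amine_N")
            mono["amine_N"] = i_n
            mono["amine_H"] = []
            u = _perp_unit(side, rng)
            v = np.cross(side, u)
            for j, ang in enumerate((0.0, 2.0 * np.pi / 3.0, 4.0 * np.pi / 3.0)):
                hdir = 0.5 * side + np.cos(ang) * u + np.sin(ang) * v
                hdir /= np.linalg.norm(hdir)
                positions.append(npos + _NH_BOND * hdir)
                species.append("H")
                roles.append("amine_H")
                mono["amine_H"].append(i_n + 1 + j)
                topo.bonds.append((i_n, i_n + 1 + j))
            topo.bonds.append((i_c1, i_n))
        topo.atoms.append(mono)
    topo.validate()

    pos = np.asarray(positions)
    mass = np.array([ATOMIC_MASSES[s] for s in species])
    com = np.average(pos, axis=0, weights=mass)
    if target_rg is not None:
        rg = np.sqrt(np.average(np.sum((pos - com) ** 2, axis=1), weights=mass))
        scale = target_rg / rg
        scaled = com + (pos - com) * scale
        heavy = topo.heavy_indices
        hp = scaled[heavy]
        d = hp[:, None, :] - hp[None, :, :]
        dist2 = np.sum(d * d, axis=-1)
        np.fill_diagonal(dist2, np.inf)
        d2min = float(np.min(dist2))
        if d2min < _STERIC_MIN**2:
            raise IceKitError(
                f"target_Rg {target_rg} nm is below the steric minimum for this chain"
            )
        pos = scaled
        com = np.average(pos, axis=0, weights=mass)

    # center chain in a box with margin
    extent = pos.max(axis=0) - pos.min(axis=0)
    if box is None:
        box = np.maximum(extent + 2.0, 2.0)
    box = np.asarray(box, dtype=float)
    pos = pos - com + box / 2.0
    h_bonds = [(a, b) for a, b in topo.bonds if species[a] == "H" or species[b] == "H"]
    config = Configuration(
        pos,
        np.asarray(species),
        np.asarray(roles),
        box,
        pbc_mode="xyz",
        bonds=np.asarray(h_bonds, dtype=int).reshape(-1, 2),
    )
    return config, topo
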