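"""GRO / PDB / extended-XYZ readers and writers.

Role labels travel through the residue/atom-name dialect below, so a
written file round-trips positions (to format precision), species, roles,
box and pbc mode:

======== ========== =================
residue  atom name  role
======== ========== =================
SOL      OW         water_O
SOL      HW1, HW2   water_H
PVA      C1 / C2    backbone_C / methylene_C
PVA      OH / HO    hydroxyl_O / hydroxyl_H
PVM      C1 / C2    backbone_C / methylene_C
PVM      N1 / HN*   amine_N / amine_H
GEN      (element)  generic
======== ========== =================

GRO is the canonical format (fixed columns, nm, 0.001 nm precision).  PDB
requires a CRYST1 record (coordinates in angstrom).  Extended XYZ carries
the box, time and pbc mode on the comment line and the role as a fifth
column.  Trajectories are concatenated frames in GRO or XYZ.
"""

from __future__ import annotations

import os
import re

import numpy as np

from ..core import Configuration, FormatError, Trajectory

__all__ = [
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
]

_ROLE_TO_NAMES = {
    "water_O": ("SOL", "OW"),
    "water_H": ("SOL", "HW"),
    "backbone_C": (None, "C1"),
    "methylene_C": (None, "C2"),
    "hydroxyl_O": ("PVA", "OH"),
    "hydroxyl_H": ("PVA", "HO"),
    "amine_N": ("PVM", "N1"),
    "amine_H": ("PVM", "HN"),
    "generic": ("GEN", None),
}

_NAME_TO_ROLE = {
    ("SOL", "OW"): "water_O",
    ("SOL", "HW1"): "water_H",
    ("SOL", "HW2"): "water_H",
    ("PVA", "C1"): "backbone_C",
    ("PVA", "C2"): "methylene_C",
    ("PVA", "OH"): "hydroxyl_O",
    ("PVA", "HO"): "hydroxyl_H",
    ("PVM", "C1"): "backbone_C",
    ("PVM", "C2"): "methylene_C",
    ("PVM", "N1"): "amine_N",
    ("PVM", "HN1"): "amine_H",
    ("PVM", "HN2"): "amine_H",
    ("PVM", "HN3"): "amine_H",
}


# ---------------------------------------------------------------------------
# residue grouping / naming
# ---------------------------------------------------------------------------

def _group_residues(config: Configuration) -> list[tuple[str, list[int]]]:
    """Split atoms into (resname, atom indices) residues by role pattern."""
    residues: list[tuple[str, list[int]]] = []
    i, n = 0, len(config)
    roles = config.role
    while i < n:
        r = roles[i]
        if r == "water_O":
            members = [i]
            j = i + 1
            while j < n and roles[j] == "water_H" and len(members) < 3:
                members.append(j)
                j += 1
            residues.append(("SOL", members))
            i = j
        elif r in ("methylene_C", "backbone_C"):
            members = [i]
            j = i + 1
            while j < n and roles[j] in (
                "backbone_C", "hydroxyl_O", "hydroxyl_H", "amine_N", "amine_H"
            ):
                members.append(j)
                j += 1
            resname = "PVM" if any(roles[k] == "amine_N" for k in members) else "PVA"
            residues.append((resname, members))
            i = j
        else:
            residues.append(("GEN", [i]))
            i += 1
    return residues


def _atom_names(config: Configuration, resname: str, members: list[int]) -> list[str]:
    names = []
    h_water = 0
    h_amine = 0
    for idx in members:
        role = config.role[idx]
        if role == "water_H":
            h_water += 1
            names.append(f"HW{h_water}")
        elif role == "amine_H":
            h_amine += 1
            names.append(f"HN{h_amine}")
        elif role == "generic":
            names.append(str(config.species[idx]))
        else:
            names.append(_ROLE_TO_NAMES[role][1])
    return names


def _role_from_names(resname: str, atomname: str, line_no: int) -> str:
    if resname == "GEN":
        return "generic"
    role = _NAME_TO_ROLE.get((resname, atomname))
    if role is None:
        raise FormatError(
            f"unknown residue/atom name combination {resname!r}/{atomname!r}", line_no
        )
    return role


def _species_from(atomname: str, role: str) -> str:
    if role == "generic":
        return atomname[:2].strip().capitalize() if atomname else "X"
    for ch in atomname:
        if ch.isalpha():
            return ch.upper()
    return "X"


def _infer_bonds(role: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Reconstruct heavy-H bonds from role ordering (writer conventions)."""
    bonds: list[tuple[int, int]] = []
    last_heavy: dict[str, int] = {}
    for i, r in enumerate(role):
        if r in ("water_O", "hydroxyl_O", "amine_N"):
            last_heavy[r[-1] if r == "amine_N" else "O"] = i
            last_heavy[r] = i
        elif r == "water_H" and "water_O" in last_heavy:
            bonds.append((last_heavy["water_O"], i))
        elif r == "hydroxyl_H" and "hydroxyl_O" in last_heavy:
            bonds.append((last_heavy["hydroxyl_O"], i))
        elif r == "amine_H" and "amine_N" in last_heavy:
            bonds.append((last_heavy["amine_N"], i))
    return np.asarray(bonds, dtype=int).reshape(-1, 2)


def _title(config: Configuration) -> str:
    title = f"icekit pbc={config.pbc_mode}"
    if config.time is not None:
        title += f" t= {config.time:.4f}"
    return title


def _parse_title(title: str) -> tuple[str, float | None]:
    pbc = "xyz"
    m = re.search(r"pbc=(\w+)", title)
    if m and m.group(1) in ("xy", "xyz"):
        pbc = m.group(1)
    time = None
    m = re.search(r"t=\s*([-\d.eE+]+)", title)
    if m:
        time = float(m.group(1))
    return pbc, time


# ---------------------------------------------------------------------------
# GRO
# ---------------------------------------------------------------------------

def _write_gro_frame(config: Configuration, fh) -> None:
    fh.write(_title(config) + "\n")
    fh.write(f"{len(config):5d}\n")
    resid = 0
    for resname, members in _group_residues(config):
        resid += 1
        names = _atom_names(config, resname, members)
        for idx, name in zip(members, names):
            x, y, z = config.positions[idx]
            fh.write(
                f"{resid % 100000:5d}{resname:<5s}{name:>5s}{(idx + 1) % 100000:5d}"
                f"{x:8.3f}{y:8.3f}{z:8.3f}\n"
            )
    fh.write(f"{config.box[0]:10.5f}{config.box[1]:10.5f}{config.box[2]:10.5f}\n")


def _read_gro_frame(lines: list[str], offset: int) -> tuple[Configuration, int]:
    if offset >= len(lines) or not lines[offset].strip():
        raise FormatError("empty file or missing title line", offset + 1)
    pbc, time = _parse_title(lines[offset])
    try:
        n = int(lines[offset + 1].strip())
    except (IndexError, ValueError):
        raise FormatError("expected atom count", offset + 2) from None
    if offset + 2 + n + 1 > len(lines):
        raise FormatError("truncated GRO frame", len(lines))
    pos = np.empty((n, 3))
    species = np.empty(n, dtype="U4")
    role = np.empty(n, dtype="U16")
    for k in range(n):
        ln = offset + 2 + k
        line = lines[ln]
        try:
            resname = line[5:10].strip()
            atomname = line[10:15].strip()
            pos[k] = [float(line[20:28]), float(line[28:36]), float(line[36:44])]
        except (ValueError, IndexError):
            raise FormatError("malformed GRO atom record", ln + 1) from None
        role[k] = _role_from_names(resname, atomname, ln + 1)
        species[k] = _species_from(atomname, role[k])
    box_line = lines[offset + 2 + n].split()
    try:
        box = np.array([float(v) for v in box_line[:3]])
    except (ValueError, IndexError):
        raise FormatError("malformed GRO box line", offset + 3 + n) from None
    cfg = Configuration(
        pos, species, role, box, pbc_mode=pbc, time=time,
        bonds=_infer_bonds(role, pos),
    )
    return cfg, offset + 3 + n


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _write_pdb_frame(config: Configuration, fh) -> None:
    b = config.box * 10.0
    fh.write(
        f"CRYST1{b[0]:9.3f}{b[1]:9.3f}{b[2]:9.3f}"
        f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n"
    )
    fh.write(f"REMARK   1 {_title(config)}\n")
    resid = 0
    serial = 0
    for resname, members in _group_residues(config):
        resid += 1
        names = _atom_names(config, resname, members)
        for idx, name in zip(members, names):
            serial += 1
            x, y, z = config.positions[idx] * 10.0
            fh.write(
                f"ATOM  {serial % 100000:5d} {name:<4s} {resname:<3s}  "
                f"{resid % 10000:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                f"  1.00  0.00          {config.species[idx]:>2s}\n"
            )
    fh.write("END\n")


def _read_pdb(lines: list[str]) -> Configuration:
    box = None
    pbc, time = "xyz", None
    pos, species, role = [], [], []
    for ln, line in enumerate(lines, start=1):
        rec = line[:6].strip()
        if rec == "CRYST1":
            try:
                box = np.array(
                    [float(line[6:15]), float(line[15:24]), float(line[24:33])]
                ) / 10.0
            except ValueError:
                raise FormatError("malformed CRYST1 record", ln) from None
        elif rec == "REMARK":
            p, t = _parse_title(line)
            if "pbc=" in line:
                pbc = p
            if t is not None:
                time = t
        elif rec in ("ATOM", "HETATM"):
            try:
                atomname = line[12:16].strip()
                resname = line[17:21].strip()
                xyz = [float(line[30:38]), float(line[38:46]), float(line[46:54])]
            except (ValueError, IndexError):
                raise FormatError("malformed ATOM record", ln) from None
            r = _role_from_names(resname, atomname, ln)
            pos.append(np.array(xyz) / 10.0)
            role.append(r)
            species.append(_species_from(atomname, r))
    if box is None:
        raise FormatError("PDB file has no CRYST1 record")
    if not pos:
        raise FormatError("PDB file contains no atoms")
    pos = np.asarray(pos)
    role = np.asarray(role)
    return Configuration(
        pos, np.asarray(species), role, box, pbc_mode=pbc, time=time,
        bonds=_infer_bonds(role, pos),
    )


# ---------------------------------------------------------------------------
# extended XYZ
# ---------------------------------------------------------------------------

def _write_xyz_frame(config: Configuration, fh) -> None:
    b = config.box
    comment = (
        f'Lattice="{b[0]:.6f} 0.0 0.0 0.0 {b[1]:.6f} 0.0 0.0 0.0 {b[2]:.6f}" '
        f"Properties=species:S:1:pos:R:3:role:S:1 "
        f'pbc="T T {"T" if config.pbc_mode == "xyz" else "F"}"'
    )
    if config.time is not None:
        comment += f" Time={config.time:.4f}"
    fh.write(f"{len(config)}\n{comment}\n")
    for i in range(len(config)):
        x, y, z = config.positions[i]
        fh.write(
            f"{config.species[i]:<3s} {x:14.8f} {y:14.8f} {z:14.8f} {config.role[i]}\n"
        )


def _read_xyz_frame(lines: list[str], offset: int) -> tuple[Configuration, int]:
    if offset >= len(lines) or not lines[offset].strip():
        raise FormatError("empty file or missing atom count", offset + 1)
    try:
        n = int(lines[offset].strip())
    except ValueError:
        raise FormatError("expected atom count", offset + 1) from None
    if offset + 2 + n > len(lines):
        raise FormatError("truncated XYZ frame", len(lines))
    comment = lines[offset + 1]
    m = re.search(r'Lattice="([^"]+)"', comment)
    if not m:
        raise FormatError("XYZ comment line lacks a Lattice entry", offset + 2)
    lat = [float(v) for v in m.group(1).split()]
    box = np.array([lat[0], lat[4], lat[8]])
    pbc = "xyz"
    m = re.search(r'pbc="([^"]+)"', comment)
    if m and m.group(1).split()[-1].upper().startswith("F"):
        pbc = "xy"
    time = None
    m = re.search(r"Time=([-\d.eE+]+)", comment)
    if m:
        time = float(m.group(1))
    pos = np.empty((n, 3))
    species = np.empty(n, dtype="U4")
    role = np.empty(n, dtype="U16")
    for k in range(n):
        ln = offset + 2 + k
        parts = lines[ln].split()
        if len(parts) < 5:
            raise FormatError("XYZ atom line needs species x y z role", ln + 1)
        species[k] = parts[0]
        try:
            pos[k] = [float(parts[1]), float(parts[2]), float(parts[3])]
        except ValueError:
            raise FormatError("malformed XYZ coordinates", ln + 1) from None
        role[k] = parts[4]
    bad = sorted(set(role) - set(
        ["water_O", "water_H", "hydroxyl_O", "hydroxyl_H", "amine_N",
         "amine_H", "methylene_C", "backbone_C", "generic"]
    ))
    if bad:
        raise FormatError(f"unknown role names: {bad}")
    cfg = Configuration(
        pos, species, role, box, pbc_mode=pbc, time=time,
        bonds=_infer_bonds(role, pos),
    )
    return cfg, offset + 2 + n


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def _detect_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        f = fmt.upper()
        if f not in ("GRO", "PDB", "XYZ"):
            raise FormatError(f"unknown format {fmt!r}")
        return f
    ext = os.path.splitext(path)[1].lower().lstrip(".")
    if ext in ("gro", "pdb", "xyz"):
        return ext.upper()
    raise FormatError(f"cannot infer format from {path!r}; pass format=")


def read_structure(path: str, format: str | None = None) -> Configuration:
    """Read a single configuration from a GRO/PDB/XYZ file."""
    fmt = _detect_format(path, format)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not any(line.strip() for line in lines):
        raise FormatError("empty file")
    if fmt == "GRO":
        cfg, _ = _read_gro_frame(lines, 0)
        return cfg
    if fmt == "PDB":
        return _read_pdb(lines)
    cfg, _ = _read_xyz_frame(lines, 0)
    return cfg


def write_structure(config: Configuration, path: str, format: str | None = None) -> None:
    """Write a configuration; format inferred from the extension if omitted."""
    fmt = _detect_format(path, format)
    with open(path, "w") as fh:
        if fmt == "GRO":
            _write_gro_frame(config, fh)
        elif fmt == "PDB":
            _write_pdb_frame(config, fh)
        else:
            _write_xyz_frame(config, fh)


def write_trajectory(traj: Trajectory, path: str, format: str | None = None) -> None:
    """Write a trajectory as concatenated GRO or XYZ frames."""
    fmt = _detect_format(path, format)
    if fmt == "PDB":
        raise FormatError("trajectories are written as GRO or XYZ")
    with open(path, "w") as fh:
        for frame in traj:
            if fmt == "GRO":
                _write_gro_frame(frame, fh)
            else:
                _write_xyz_frame(frame, fh)


def read_trajectory(path: str, format: str | None = None) -> Trajectory:
    """Read a concatenated GRO or XYZ trajectory."""
    fmt = _detect_format(path, format)
    if fmt == "PDB":
        raise FormatError("trajectories are read from GRO or XYZ")
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not any(line.strip() for line in lines):
        raise FormatError("empty file")
    frames = []
    offset = 0
    while offset < len(lines) and lines[offset].strip():
        if fmt == "GRO":
            cfg, offset = _read_gro_frame(lines, offset)
        else:
            cfg, offset = _read_xyz_frame(lines, offset)
        frames.append(cfg)
    return Trajectory(frames)
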