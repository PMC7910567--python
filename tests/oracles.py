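"""Independent brute-force reference implementations used by the tests.

These deliberately avoid the library code paths they check: spherical
harmonics are closed-form polynomials (derived symbolically, hard-coded),
clustering is pure-Python union-find, hydrogen bonds a triple loop, the
radius of gyration a pairwise double sum, and rMI an explicit image
enumeration.
"""

from __future__ import annotations

import math

import numpy as np

_SQPI = math.sqrt(math.pi)


def y6m_closed(m: int, u: np.ndarray) -> np.ndarray:
    """Y6m from unit vectors via explicit polynomials in cos(theta)."""
    x = np.clip(u[..., 2], -1.0, 1.0)  # cos(theta)
    s2 = 1.0 - x * x
    phi = np.arctan2(u[..., 1], u[..., 0])
    am = abs(m)
    if am == 0:
        base = np.sqrt(13) * (231 * x**6 - 315 * x**4 + 105 * x**2 - 5) / (32 * _SQPI)
    elif am == 1:
        base = x * np.sqrt(546 * s2) * (-33 * x**4 + 30 * x**2 - 5) / (32 * _SQPI)
    elif am == 2:
        base = np.sqrt(1365) * (-33 * x**6 + 51 * x**4 - 19 * x**2 + 1) / (64 * _SQPI)
    elif am == 3:
        base = -np.sqrt(1365) * x * s2**1.5 * (11 * x**2 - 3) / (32 * _SQPI)
    elif am == 4:
        base = 3 * np.sqrt(182) * s2**2 * (11 * x**2 - 1) / (64 * _SQPI)
    elif am == 5:
        base = -3 * np.sqrt(1001) * x * s2**2.5 / (32 * _SQPI)
    elif am == 6:
        base = np.sqrt(3003) * s2**3 / (64 * _SQPI)
    else:
        raise ValueError(f"|m| must be <= 6, got {m}")
    y = base * np.exp(1j * am * phi)
    if m < 0:
        y = (-1) ** am * np.conj(y)
    return y


def min_image(d: np.ndarray, box: np.ndarray, pbc_mode: str) -> np.ndarray:
    """Minimum-image displacement.

    Uses round-half-to-even like the library so that pairs at exactly half
    the box length (which occur in perfect lattices) resolve to the same
    image; at such ties both images are equally "minimum" and the tie-break
    is part of the operation's definition.
    """
    d = np.array(d, dtype=float)
    ndim = 3 if pbc_mode == "xyz" else 2
    for k in range(ndim):
        d[..., k] -= box[k] * np.round(d[..., k] / box[k])
    return d


def switch_weight(r: float, r0: float, d0: float, n: int, m: int, r_cut: float) -> float:
    if r >= r_cut:
        return 0.0
    if r <= d0:
        return 1.0
    x = (r - d0) / r0
    if abs(x - 1.0) < 1e-12:
        return n / m
    return (1.0 - x**n) / (1.0 - x**m)


def brute_s6(config, params, normalize: bool = True):
    """Per-water q6 and s6 by direct summation (per-molecule loop).

    Returns ``(water_indices, q6 (M,13), s6 (M,))``; s6 is NaN for
    molecules with zero total weight.
    """
    ow = np.flatnonzero(config.role == "water_O")
    pos = config.positions[ow]
    box = config.box
    r_cut = params.d0 + 3.0 * params.r0 if params.r_cut is None else params.r_cut
    n_mol = len(ow)
    q6 = np.zeros((n_mol, 13), dtype=complex)
    weights = []
    for i in range(n_mol):
        d = min_image(pos - pos[i], box, config.pbc_mode)
        r = np.sqrt(np.sum(d * d, axis=1))
        w = np.array(
            [
                0.0 if j == i else switch_weight(r[j], params.r0, params.d0, params.n, params.m, r_cut)
                for j in range(n_mol)
            ]
        )
        weights.append(w)
        tot = w.sum()
        if tot <= 0:
            continue
        sel = np.flatnonzero(w > 0)
        u = d[sel] / r[sel][:, None]
        for mm in range(-6, 7):
            q6[i, mm + 6] = np.sum(w[sel] * y6m_closed(mm, u))
        q6[i] /= tot
    qv = q6.copy()
    if normalize:
        for i in range(n_mol):
            nrm = np.linalg.norm(qv[i])
            if nrm > 0:
                qv[i] = qv[i] / nrm
    s6 = np.full(n_mol, np.nan)
    for i in range(n_mol):
        w = weights[i]
        tot = w.sum()
        if tot <= 0:
            continue
        acc = 0.0
        for j in np.flatnonzero(w > 0):
            acc += w[j] * np.real(np.sum(np.conj(qv[i]) * qv[j]))
        s6[i] = acc / tot
    return ow, q6, s6


def brute_clusters(config, water_indices, ice_flags, link_cutoff: float):
    """Union-find connected components of ice molecules (strict < cutoff).

    Returns a list of frozensets of atom indices.
    """
    idx = [int(a) for a, f in zip(water_indices, ice_flags) if f]
    parent = {a: a for a in idx}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    pos = config.positions
    for ii in range(len(idx)):
        for jj in range(ii + 1, len(idx)):
            d = min_image(pos[idx[jj]] - pos[idx[ii]], config.box, config.pbc_mode)
            if math.sqrt(float(np.dot(d, d))) < link_cutoff:
                union(idx[ii], idx[jj])
    groups: dict[int, set[int]] = {}
    for a in idx:
        groups.setdefault(find(a), set()).add(a)
    return [frozenset(g) for g in groups.values()]


def brute_hbonds(config, donors, acceptors, hydrogens, max_da: float, min_angle: float):
    """Triple-loop H-bond scan; returns a set of (D, H, A) triplets."""
    out = set()
    pos = config.positions
    for d in donors:
        for a in acceptors:
            if d == a:
                continue
            dv = min_image(pos[a] - pos[d], config.box, config.pbc_mode)
            if math.sqrt(float(np.dot(dv, dv))) >= max_da:
                continue
            for h in hydrogens.get(int(d), []):
                v1 = min_image(pos[d] - pos[h], config.box, config.pbc_mode)
                v2 = min_image(pos[a] - pos[h], config.box, config.pbc_mode)
                cosang = float(np.dot(v1, v2)) / (
                    math.sqrt(float(np.dot(v1, v1))) * math.sqrt(float(np.dot(v2, v2)))
                )
                ang = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
                if ang >= min_angle:
                    out.add((int(d), int(h), int(a)))
    return out


def brute_rmi(positions, box, pbc_mode: str) -> float:
    """Exhaustive periodic-image minimum distance."""
    zs = (-1, 0, 1) if pbc_mode == "xyz" else (0,)
    best = math.inf
    n = len(positions)
    for sx in (-1, 0, 1):
        for sy in (-1, 0, 1):
            for sz in zs:
                if sx == 0 and sy == 0 and sz == 0:
                    continue
                shift = np.array([sx * box[0], sy * box[1], sz * box[2]])
                for i in range(n):
                    for j in range(n):
                        d = positions[i] - (positions[j] + shift)
                        best = min(best, math.sqrt(float(np.dot(d, d))))
    return best


def brute_rg(positions, masses) -> float:
    """Mass-weighted Rg via the pairwise double-sum identity."""
    m = np.asarray(masses, dtype=float)
    total = m.sum()
    acc = 0.0
    for i in range(len(positions)):
        for j in range(len(positions)):
            dij = positions[i] - positions[j]
            acc += m[i] * m[j] * float(np.dot(dij, dij))
    return math.sqrt(acc / (2.0 * total**2))
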