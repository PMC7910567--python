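"""Well-tempered metadynamics: hills parsing, bias and free-energy profile.

The deposited bias is a plain Gaussian sum,

    V(s, t) = sum_{k: t_k < t} W_k exp(-(s - c_k)^2 / (2 sigma_k^2)),

with hill heights taken exactly as recorded (well-tempered decay is the
log producer's business).  The free energy over the collective variable is

    dG(s) = -gamma/(gamma - 1) * V(s, t_end),

shifted so its minimum is zero.  The optional error band is a block
average over deposition-time segments (a substitute for the reweighting
estimate the source analysis cites), and is labeled as such.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import FormatError, IceKitError

__all__ = [
    "HillsLog",
    "FESProfile",
    "parse_hills",
    "write_hills",
    "bias_potential",
    "wt_fes",
    "barrier_scan",
]

HILLS_HEADER = "#! FIELDS time rg sigma_rg height biasf"


@dataclass
class HillsLog:
    """Ordered deposited-Gaussian records (times ps, centers/widths nm,
    heights kJ/mol) plus the bias factor gamma."""

    times: np.ndarray
    centers: np.ndarray
    sigmas: np.ndarray
    heights: np.ndarray
    gamma: float = 100.0
    cv_name: str = "rg"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.centers = np.asarray(self.centers, dtype=float)
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)
        n = len(self.times)
        if not (len(self.centers) == len(self.sigmas) == len(self.heights) == n):
            raise IceKitError("hills columns must have equal length")
        if n and np.any(np.diff(self.times) < 0):
            raise IceKitError("hill deposition times must be non-decreasing")
        if np.any(self.sigmas <= 0):
            raise IceKitError("hill widths must be positive")
        if np.any(self.heights < 0):
            raise IceKitError("hill heights must be non-negative")
        if self.gamma <= 1:
            raise IceKitError("bias factor gamma must exceed 1")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class FESProfile:
    """Free-energy profile over the CV grid, min-shifted to zero."""

    grid: np.ndarray
    delta_g: np.ndarray  # kJ/mol
    error: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.grid) <= 0):
            raise IceKitError("FES grid must be strictly increasing")


def parse_hills(path: str) -> HillsLog:
    """Parse a whitespace hills log (``time center sigma height biasf``)."""
    times, centers, sigmas, heights, gammas = [], [], [], [], []
    cv_name = "rg"
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line.lstrip("#!").split()
                if parts[:1] == ["FIELDS"] and len(parts) >= 3:
                    cv_name = parts[2]
                continue
            parts = line.split()
            if len(parts) < 5:
                raise FormatError("expected 5 columns: time center sigma height biasf", ln)
            try:
                t, c, s, w, g = (float(v) for v in parts[:5])
            except ValueError:
                raise FormatError("non-numeric hills record", ln) from None
            if s <= 0:
                raise FormatError(f"non-positive Gaussian width {s}", ln)
            if w < 0:
                raise FormatError(f"negative Gaussian height {w}", ln)
            times.append(t)
            centers.append(c)
            sigmas.append(s)
            heights.append(w)
            gammas.append(g)
    gamma = gammas[-1] if gammas else 100.0
    return HillsLog(
        np.asarray(times), np.asarray(centers), np.asarray(sigmas),
        np.asarray(heights), gamma=gamma, cv_name=cv_name,
    )


def write_hills(log: HillsLog, path: str) -> None:
    """Write a hills log in the dialect :func:`parse_hills` reads."""
    with open(path, "w") as fh:
        fh.write(HILLS_HEADER.replace("rg", log.cv_name) + "\n")
        for t, c, s, w in zip(log.times, log.centers, log.sigmas, log.heights):
            fh.write(f"{t:.6f} {c:.9f} {s:.9f} {w:.9f} {log.gamma:.3f}\n")


def bias_potential(log: HillsLog, s, t: float | None = None):
    """Accumulated bias V(s, t); hills with deposition time < t contribute.

    ``t=None`` sums every recorded hill.  Vectorized over ``s``.
    """
    s_arr = np.atleast_1d(np.asarray(s, dtype=float))
    if not np.all(np.isfinite(s_arr)):
        raise IceKitError("bias grid points must be finite")
    if t is None:
        sel = slice(None)
    else:
        sel = log.times < t
    c, sig, w = log.centers[sel], log.sigmas[sel], log.heights[sel]
    if len(c) == 0:
        v = np.zeros_like(s_arr)
    else:
        v = np.sum(
            w[None, :] * np.exp(-((s_arr[:, None] - c[None, :]) ** 2) / (2.0 * sig[None, :] ** 2)),
            axis=1,
        )
    return v if np.ndim(s) else float(v[0])


def default_grid(log: HillsLog, n_points: int = 200) -> np.ndarray:
    """200 points spanning [min center - 3 sigma, max center + 3 sigma]."""
    if len(log) == 0:
        return np.linspace(0.0, 1.0, n_points)
    lo = float(np.min(log.centers - 3.0 * log.sigmas))
    hi = float(np.max(log.centers + 3.0 * log.sigmas))
    return np.linspace(lo, hi, n_points)


def wt_fes(log: HillsLog, grid=None, n_blocks: int = 0) -> FESProfile:
    """Well-tempered free-energy profile over the CV grid.

    With ``n_blocks > 1`` a block-averaged standard-error band over
    deposition-time segments is attached.
    """
    if log.gamma <= 1:
        raise IceKitError("bias factor gamma must exceed 1")
    grid = default_grid(log) if grid is None else np.asarray(grid, dtype=float)
    factor = log.gamma / (log.gamma - 1.0)
    v = bias_potential(log, grid)
    dg = -factor * np.atleast_1d(v)
    dg -= dg.min()
    err = None
    if n_blocks > 1 and len(log) >= n_blocks:
        edges = np.linspace(0, len(log), n_blocks + 1).astype(int)
        profiles = []
        for b in range(n_blocks):
            sub = HillsLog(
                log.times[: edges[b + 1]], log.centers[: edges[b + 1]],
                log.sigmas[: edges[b + 1]], log.heights[: edges[b + 1]],
                gamma=log.gamma, cv_name=log.cv_name,
            )
            p = -factor * np.atleast_1d(bias_potential(sub, grid))
            profiles.append(p - p.min())
        err = np.std(profiles, axis=0, ddof=1) / np.sqrt(n_blocks)
    return FESProfile(grid, dg, error=err)


def barrier_scan(profile: FESProfile, kT: float = 2.203) -> list[dict]:
    """Local minima and the barriers between adjacent minima.

    Minima come from sign changes of the first difference; each entry
    reports the left minimum position, the barrier height (lowest
    intervening maximum minus the shallower adjacent minimum) and the
    barrier in kT units.  ``kT`` defaults to 265 K in kJ/mol.
    """
    if len(profile.grid) < 3:
        raise IceKitError("barrier scan needs >= 3 grid points")
    g = profile.delta_g
    diff = np.diff(g)
    minima: list[int] = []
    if diff[0] > 0:  # left terminal minimum
        minima.append(0)
    minima.extend(
        k + 1
        for k in range(len(diff) - 1)
        if diff[k] < 0 and diff[k + 1] > 0
    )
    if diff[-1] < 0:  # right terminal minimum
        minima.append(len(g) - 1)
    out = []
    for pos, nxt in zip(minima, minima[1:] + [None]):
        entry = {
            "position": float(profile.grid[pos]),
            "dg_kj_mol": float(g[pos]),
            "barrier_kj_mol": None,
            "barrier_kT": None,
        }
        if nxt is not None:
            barrier_top = float(np.max(g[pos : nxt + 1]))
            height = barrier_top - float(max(g[pos], g[nxt]))
            entry["barrier_kj_mol"] = height
            entry["barrier_kT"] = height / kT
        out.append(entry)
    return out
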