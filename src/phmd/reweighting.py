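"""Reweighting of boosted trajectories into unbiased PMF grids.

A boosted ensemble sampled with boost dV reweights to the unbiased one
with per-frame weights exp(beta*dV).  Binning the reaction coordinates
(1D or 2D) gives per-bin reweighted probabilities

    p*(bin)  proportional to  count(bin) * <exp(beta*dV)>_bin,

and the potential of mean force PMF = -kB*T*ln p*, normalized so the
lowest reliable bin sits at 0.  The bin-average is estimated either by
exponential averaging (exact in expectation, noisy) or by the
second-order cumulant expansion

    ln <exp(beta*dV)>  ~  beta*C1 + beta^2*C2/2,

with C1 the bin mean and C2 the bin variance of dV — exact when dV is
Gaussian within the bin, which is what the boost construction aims for.

Bins are half-open [lo, hi); bins holding fewer than ``min_samples``
frames are flagged unreliable and carry no PMF estimate (NaN), mirroring
state tables that only print occupied bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .constants import KB

DEFAULT_BIN_WIDTHS = (0.5, 1.0)   # A: (BRRMSD, D3) granularity of the state tables


@dataclass
class BinnedFrames:
    """Frames assigned to grid cells, plus per-frame boost energies."""

    edges: tuple
    counts: np.ndarray           # frames per cell
    cell_index: np.ndarray       # flat cell index per in-grid frame
    dv: np.ndarray               # boost energy per in-grid frame
    overflow: int                # frames outside the grid

    @property
    def shape(self) -> tuple:
        return self.counts.shape


def _frames_to_arrays(frames, ndim: int) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(frames, pd.DataFrame):
        rc = frames[["rc1", "rc2"][:ndim]].to_numpy(dtype=float)
        dv = frames["dv"].to_numpy(dtype=float) if "dv" in frames else np.zeros(len(frames))
    else:
        arr = np.asarray(frames, dtype=float)
        rc = arr[:, :ndim]
        dv = arr[:, ndim] if arr.shape[1] > ndim else np.zeros(arr.shape[0])
    if np.any(dv < -1e-12):
        raise ValueError("boost energies must be >= 0")
    if not np.all(np.isfinite(rc)):
        raise ValueError("reaction coordinates must be finite")
    return rc, np.clip(dv, 0.0, None)


def bin_frames(frames, edges) -> BinnedFrames:
    """Assign frames to half-open grid cells [lo, hi).

    ``edges`` is one strictly increasing edge array per axis (1 or 2 axes).
    A frame exactly on an interior edge belongs to the right-hand bin;
    frames outside the grid are counted in ``overflow``.
    """
    edges = tuple(np.asarray(e, dtype=float) for e in (edges if isinstance(edges, (tuple, list)) else (edges,)))
    for e in edges:
        if e.ndim != 1 or e.size < 2 or np.any(np.diff(e) <= 0):
            raise ValueError("bin edges must be strictly increasing 1D arrays")
    ndim = len(edges)
    rc, dv = _frames_to_arrays(frames, ndim)
    shape = tuple(e.size - 1 for e in edges)
    inside = np.ones(rc.shape[0], dtype=bool)
    idx_per_axis = []
    for ax, e in enumerate(edges):
        i = np.digitize(rc[:, ax], e) - 1
        inside &= (rc[:, ax] >= e[0]) & (rc[:, ax] < e[-1])
        idx_per_axis.append(np.clip(i, 0, shape[ax] - 1))
    flat = idx_per_axis[0] if ndim == 1 else idx_per_axis[0] * shape[1] + idx_per_axis[1]
    flat = flat[inside]
    counts = np.bincount(flat, minlength=int(np.prod(shape))).reshape(shape)
    return BinnedFrames(
        edges=edges,
        counts=counts,
        cell_index=flat,
        dv=dv[inside],
        overflow=int((~inside).sum()),
    )


@dataclass
class PMFGrid:
    """Binned free-energy surface over 1 or 2 reaction coordinates.

    ``pmf`` is NaN where no estimate exists (empty or unreliable bins);
    the minimum over reliable occupied bins is exactly 0.
    """

    edges: tuple
    pmf: np.ndarray
    counts: np.ndarray
    reliable: np.ndarray
    temperature: float
    method: str
    overflow: int = 0

    @property
    def centers(self) -> tuple:
        return tuple(0.5 * (e[:-1] + e[1:]) for e in self.edges)

    @property
    def ndim(self) -> int:
        return len(self.edges)

    def to_frame(self) -> pd.DataFrame:
        """Machine-readable state grid: one row per occupied cell."""
        cs = self.centers
        if self.ndim == 1:
            rc1 = cs[0]
            rc2 = np.zeros_like(rc1)
            pmf, counts, rel = self.pmf, self.counts, self.reliable
        else:
            g1, g2 = np.meshgrid(cs[0], cs[1], indexing="ij")
            rc1, rc2 = g1.ravel(), g2.ravel()
            pmf, counts, rel = self.pmf.ravel(), self.counts.ravel(), self.reliable.ravel()
        df = pd.DataFrame(
            {"rc1_center": rc1, "rc2_center": rc2, "pmf": pmf, "count": counts, "reliable": rel}
        )
        return df[df["count"] > 0].reset_index(drop=True)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _finalize(binned: BinnedFrames, log_factor: np.ndarray, temperature: float,
              min_samples: int, method: str) -> PMFGrid:
    counts = binned.counts
    flat_counts = counts.ravel()
    reliable = flat_counts >= min_samples
    kbt = KB * temperature
    with np.errstate(divide="ignore"):
        lnp = np.where(flat_counts > 0, np.log(np.maximum(flat_counts, 1)), -np.inf) + log_factor
    lnp[~reliable] = -np.inf
    if not np.any(np.isfinite(lnp)):
        raise ValueError("no reliable occupied bins to normalize")
    ref = lnp.max()
    pmf = np.where(np.isfinite(lnp), -kbt * (lnp - ref), np.nan)
    return PMFGrid(
        edges=binned.edges,
        pmf=pmf.reshape(counts.shape),
        counts=counts,
        reliable=reliable.reshape(counts.shape),
        temperature=temperature,
        method=method,
        overflow=binned.overflow,
    )


def _bin_moments(binned: BinnedFrames) -> tuple[np.ndarray, np.ndarray]:
    n_cells = binned.counts.size
    n = np.bincount(binned.cell_index, minlength=n_cells).astype(float)
    s1 = np.bincount(binned.cell_index, weights=binned.dv, minlength=n_cells)
    s2 = np.bincount(binned.cell_index, weights=binned.dv**2, minlength=n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        c1 = np.where(n > 0, s1 / np.maximum(n, 1), 0.0)
        c2 = np.where(n > 0, s2 / np.maximum(n, 1) - c1**2, 0.0)
    return c1, np.clip(c2, 0.0, None)


def reweight_cumulant2(
    frames, edges, temperature: float = 310.0, min_samples: int = 10
) -> PMFGrid:
    """Second-order cumulant reweighting to an unbiased PMF grid.

    Per-bin reweighting factor exp(beta*C1 + beta^2*C2/2) with C1/C2 the
    bin mean/variance of dV.  With dV identically zero this reduces to the
    raw histogram PMF -kB*T*ln(count/max count).
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    binned = frames if isinstance(frames, BinnedFrames) else bin_frames(frames, edges)
    beta = 1.0 / (KB * temperature)
    c1, c2 = _bin_moments(binned)
    return _finalize(binned, beta * c1 + 0.5 * beta**2 * c2, temperature, min_samples, "cumulant2")


def reweight_exponential(
    frames, edges, temperature: float = 310.0, min_samples: int = 10
) -> PMFGrid:
    """Exponential-average reweighting (exact in expectation, noisier).

    Per-bin factor <exp(beta*dV)>; the reference estimator used to
    cross-validate the cumulant expansion.
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    binned = frames if isinstance(frames, BinnedFrames) else bin_frames(frames, edges)
    beta = 1.0 / (KB * temperature)
    n_cells = binned.counts.size
    n = np.bincount(binned.cell_index, minlength=n_cells).astype(float)
    # log-sum-exp per cell for numerical stability
    log_factor = np.zeros(n_cells)
    occupied = n > 0
    if binned.dv.size:
        order = np.argsort(binned.cell_index, kind="stable")
        ci = binned.cell_index[order]
        bdv = beta * binned.dv[order]
        splits = np.flatnonzero(np.diff(ci)) + 1
        groups = np.split(bdv, splits)
        cells = ci[np.concatenate([[0], splits])] if ci.size else np.array([], dtype=int)
        for cell, g in zip(cells, groups):
            m = g.max()
            log_factor[cell] = m + np.log(np.mean(np.exp(g - m)))
    log_factor[~occupied] = 0.0
    return _finalize(binned, log_factor, temperature, min_samples, "exponential")


def reweight_none(frames, edges, temperature: float = 310.0, min_samples: int = 1) -> PMFGrid:
    """Raw histogram PMF of unbiased frames (boost energies ignored)."""
    binned = frames if isinstance(frames, BinnedFrames) else bin_frames(frames, edges)
    return _finalize(binned, np.zeros(binned.counts.size), temperature, min_samples, "none")


def edges_from_widths(
    lo_hi: Sequence[tuple], widths: Sequence[float] = DEFAULT_BIN_WIDTHS
) -> tuple:
    """Edge arrays from per-axis (lo, hi) ranges and bin widths."""
    out = []
    for (lo, hi), w in zip(lo_hi, widths):
        n = max(1, int(round((hi - lo) / w)))
        out.append(lo + w * np.arange(n + 1))
    return tuple(out)
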