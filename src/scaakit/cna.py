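"""Low-pass WGS copy number: joint segmentation and purity/integer-CN fit.

Binned log2 coverage ratios from all samples of a patient are segmented
jointly (shared breakpoints, per-sample piecewise-constant means) by
penalized least squares: exact dynamic programming per contig up to a bin
cap, greedy binary segmentation beyond.  Segment means are then converted
to continuous copy number by inverting the standard purity/ploidy mixture
relation for sequencing data (gamma = 1),

    n_cont = (2^r * (2(1-rho) + rho*psi_t) - 2(1-rho)) / rho,

and the purity is fit by grid search over rho in [0.1, 1]: the goodness of
fit at each rho is the bin-length-weighted sum of squared distances of
n_cont to the nearest non-negative integer.  The chosen purity is the
local minimum with the best fit; if no strict local minimum exists the
purity is taken to be 1.  Negative integer states are clamped to 0.
Tumour ploidy psi_t is a required input (from paired deep WGS, or the
simulator's ground truth).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SegmentSet",
    "CNFit",
    "segment_joint",
    "continuous_cn",
    "fit_purity",
]


@dataclass
class SegmentSet:
    """Shared breakpoints; per (sample, segment) mean log2 ratio."""

    segments: pd.DataFrame  # chrom, start, end, n_bins, segment_id
    means: pd.DataFrame  # sample, segment_id, mean_log2ratio


@dataclass
class CNFit:
    sample: str
    rho_grid: np.ndarray
    gof: np.ndarray
    chosen_rho: float
    segments: pd.DataFrame  # segment_id, n_bins, mean_log2ratio, n_cont, n_int
    recentre: float = 0.0  # log2-ratio offset absorbed at the chosen purity


def _segment_costs(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative sums enabling O(1) SSE of any [i, j) across samples."""
    cs = np.concatenate([np.zeros((x.shape[0], 1)), np.cumsum(x, axis=1)], axis=1)
    cs2 = np.concatenate([np.zeros((x.shape[0], 1)), np.cumsum(x**2, axis=1)], axis=1)
    return cs, cs2


def _sse(cs, cs2, i, j):
    n = j - i
    s = cs[:, j] - cs[:, i]
    s2 = cs2[:, j] - cs2[:, i]
    return float(np.sum(s2 - s**2 / n))


def _dp_breakpoints(x: np.ndarray, penalty: float) -> list[int]:
    """Exact optimal breakpoints minimising SSE + penalty * #breakpoints."""
    n = x.shape[1]
    cs, cs2 = _segment_costs(x)
    best = np.full(n + 1, np.inf)
    prev = np.zeros(n + 1, dtype=int)
    best[0] = -penalty  # first segment incurs no penalty
    for j in range(1, n + 1):
        for i in range(j):
            c = best[i] + penalty + _sse(cs, cs2, i, j)
            if c < best[j]:
                best[j] = c
                prev[j] = i
    cuts = []
    j = n
    while j > 0:
        i = prev[j]
        if i > 0:
            cuts.append(i)
        j = i
    return sorted(cuts)


def _greedy_breakpoints(x: np.ndarray, penalty: float) -> list[int]:
    """Binary segmentation: split while the SSE reduction exceeds penalty."""
    n = x.shape[1]
    cs, cs2 = _segment_costs(x)
    out: list[int] = []
    stack = [(0, n)]
    while stack:
        i, j = stack.pop()
        if j - i < 2:
            continue
        base = _sse(cs, cs2, i, j)
        best_gain, best_k = 0.0, -1
        for k in range(i + 1, j):
            gain = base - _sse(cs, cs2, i, k) - _sse(cs, cs2, k, j)
            if gain > best_gain:
                best_gain, best_k = gain, k
        if best_k > 0 and best_gain > penalty:
            out.append(best_k)
            stack.append((i, best_k))
            stack.append((best_k, j))
    return sorted(out)


def segment_joint(
    bins: pd.DataFrame,
    penalty: float = 10.0,
    dp_max_bins: int = 300,
) -> SegmentSet:
    """Joint segmentation of all samples on a shared bin grid.

    ``bins``: long DataFrame (sample, chrom, start, end, log2ratio); every
    sample must carry the identical grid.  Breakpoints minimise the summed
    squared error across samples plus ``penalty`` per breakpoint (exact DP
    per contig up to ``dp_max_bins`` bins, greedy binary segmentation
    beyond).
    """
    piv = bins.pivot_table(
        index=["chrom", "start", "end"], columns="sample", values="log2ratio"
    )
    if piv.isna().any().any():
        raise ValueError("inconsistent bin grids across samples")
    # penalty is in noise-variance units: standardize each sample by a
    # robust noise SD from successive differences (jumps are sparse, so
    # the median |diff| reflects noise, not copy-number steps)
    scales = {}
    for s in piv.columns:
        d = np.diff(piv[s].to_numpy())
        sd = 1.4826 * np.median(np.abs(d)) / np.sqrt(2.0) if len(d) else 0.0
        scales[s] = max(sd, 1e-8)
    seg_rows = []
    mean_rows = []
    seg_id = 0
    samples = list(piv.columns)
    for chrom in bins.chrom.unique():
        sub = piv.loc[chrom].sort_index()
        x = sub.to_numpy().T  # samples x bins
        x_std = x / np.array([scales[s] for s in samples])[:, None]
        starts = sub.index.get_level_values("start").to_numpy()
        ends = sub.index.get_level_values("end").to_numpy()
        n = x.shape[1]
        if n <= dp_max_bins:
            cuts = _dp_breakpoints(x_std, penalty)
        else:
            cuts = _greedy_breakpoints(x_std, penalty)
        edges = [0] + cuts + [n]
        for i, j in zip(edges[:-1], edges[1:]):
            seg_rows.append(
                {
                    "segment_id": f"seg{seg_id:04d}",
                    "chrom": chrom,
                    "start": int(starts[i]),
                    "end": int(ends[j - 1]),
                    "n_bins": j - i,
                }
            )
            for si, s in enumerate(samples):
                mean_rows.append(
                    {
                        "sample": s,
                        "segment_id": f"seg{seg_id:04d}",
                        "mean_log2ratio": float(x[si, i:j].mean()),
                    }
                )
            seg_id += 1
    return SegmentSet(pd.DataFrame(seg_rows), pd.DataFrame(mean_rows))


def continuous_cn(r, rho, psi_t):
    """Continuous copy number of a bin/segment at purity ``rho``."""
    rho = np.asarray(rho, dtype=float)
    if np.any(rho <= 0):
        raise ValueError("rho must be > 0")
    r = np.asarray(r, dtype=float)
    return (2.0**r * (2.0 * (1.0 - rho) + rho * psi_t) - 2.0 * (1.0 - rho)) / rho


def fit_purity(
    segments: SegmentSet,
    sample: str,
    psi_t: int,
    rho_step: float = 0.01,
    rho_min: float = 0.1,
    recentre_max: float = 0.08,
    recentre_step: float = 0.005,
) -> CNFit:
    """Grid-search purity and integer copy-number states for one sample.

    Median-centring of the log ratios leaves a small residual offset when
    the gained and lost fractions of the genome are unbalanced; a
    re-centring offset within +/-``recentre_max`` log2 units is therefore
    fitted jointly with the purity (profiled out at every grid point).
    Local minima are grid points with goodness of fit strictly lower than
    both neighbours; ties across local minima break toward higher purity
    (fewer degenerate sub-clonal interpretations).  With no local minimum
    the purity is assumed to be 1.
    """
    if psi_t < 1 or int(psi_t) != psi_t:
        raise ValueError("psi_t must be an integer >= 1")
    sub = segments.means[segments.means["sample"] == sample].merge(
        segments.segments, on="segment_id"
    )
    if sub.empty:
        raise ValueError(f"no segments for sample {sample!r}")
    r = sub.mean_log2ratio.to_numpy()
    w = sub.n_bins.to_numpy().astype(float)

    offsets = (
        np.round(
            np.arange(-recentre_max, recentre_max + recentre_step / 2, recentre_step),
            10,
        )
        if recentre_max > 0
        else np.array([0.0])
    )
    grid = np.round(np.arange(rho_min, 1.0 + rho_step / 2, rho_step), 10)
    gof = np.empty(len(grid))
    best_offset = np.zeros(len(grid))
    for i, rho in enumerate(grid):
        # vectorized over candidate offsets: (offsets, segments)
        nc = continuous_cn(r[None, :] - offsets[:, None], rho, psi_t)
        ni = np.maximum(np.round(nc), 0.0)
        g = np.sum(w[None, :] * (nc - ni) ** 2, axis=1)
        j = int(np.argmin(g))
        gof[i] = float(g[j])
        best_offset[i] = offsets[j]

    interior = np.arange(1, len(grid) - 1)
    is_min = (gof[interior] < gof[interior - 1]) & (gof[interior] < gof[interior + 1])
    minima = interior[is_min]
    if len(minima) == 0:
        chosen_i = len(grid) - 1
        chosen = 1.0
    else:
        best_gof = gof[minima].min()
        # ties toward higher rho
        chosen_i = int(minima[gof[minima] <= best_gof][-1])
        chosen = float(grid[chosen_i])

    c = float(best_offset[chosen_i])
    nc = continuous_cn(r - c, chosen, psi_t)
    ni = np.maximum(np.round(nc), 0.0).astype(int)
    out = sub[["segment_id", "chrom", "start", "end", "n_bins", "mean_log2ratio"]].copy()
    out["n_cont"] = nc
    out["n_int"] = ni
    return CNFit(sample=sample, rho_grid=grid, gof=gof, chosen_rho=chosen,
                 segments=out, recentre=c)


def fit_patient(
    bins: pd.DataFrame,
    psi_t: int,
    penalty: float = 10.0,
    rho_step: float = 0.01,
) -> dict[str, CNFit]:
    """Segment a patient's samples jointly, then fit each sample."""
    segs = segment_joint(bins, penalty=penalty)
    return {
        s: fit_purity(segs, s, psi_t, rho_step=rho_step)
        for s in bins["sample"].unique()
    }
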