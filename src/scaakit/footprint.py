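"""Genome-wide TF-binding-site accessibility signatures.

For each TF and sample an insertion-size x distance matrix of Tn5 cut
counts around the motif centres is built, row-normalized by the
genome-wide count of reads of the same size and background-corrected
against the 750-1,000-bp flanks.  The central block (insertion sizes
25-120 bp, distances within +/-100 bp) integrates the open-chromatin
footprint; its difference against a pooled normal matrix is the per-sample
differential TF signal, which is regressed on purity (per patient or per
region) with TSS-enrichment covariates, and the resulting coefficient
matrix is clustered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.cluster import hierarchy

__all__ = [
    "InsertionMatrix",
    "stratify_sites",
    "filter_homotypic",
    "build_insertion_matrix",
    "pool_matrices",
    "differential_signal",
    "regress_tf_signal",
    "cluster_tf_coefficients",
]

WINDOW = 1000  # bp either side of the motif centre
SIZE_BIN = 5  # bp insertion-size bins
SIZE_MAX = 625
CENTRAL_SIZES = (25, 120)
CENTRAL_DIST = 100
FLANK = (750, 1000)
HOMOTYPIC_MIN_DIST = 1000

SIZE_EDGES = np.arange(0, SIZE_MAX + SIZE_BIN, SIZE_BIN)
N_SIZE_BINS = len(SIZE_EDGES) - 1
N_DIST = 2 * WINDOW + 1


@dataclass
class InsertionMatrix:
    """rows: 5-bp insertion-size bins; cols: distance -1000..+1000."""

    values: np.ndarray  # (N_SIZE_BINS, N_DIST), normalized + corrected
    raw: np.ndarray  # raw insertion counts on the same grid
    n_sites: int
    n_reads: float  # total cut sites of the sample (weighting for pooling)


def stratify_sites(sites: pd.DataFrame, tss: pd.DataFrame, peaks: pd.DataFrame | None = None) -> pd.DataFrame:
    """Assign each site to one of six strata: TSS-distance class x peak overlap.

    proximal: d <= 2,000 bp; close: 2,000 < d <= 10,000; distal: d > 10,000.
    """
    out = sites.copy()
    dist = np.full(len(sites), np.inf)
    for chrom, sub in sites.groupby("chrom"):
        tpos = np.sort(tss.loc[tss.chrom == chrom, "pos"].to_numpy())
        if len(tpos) == 0:
            continue
        c = sub.center.to_numpy()
        j = np.searchsorted(tpos, c)
        for off in (-1, 0):
            jj = np.clip(j + off, 0, len(tpos) - 1)
            dist[sub.index] = np.minimum(dist[sub.index], np.abs(tpos[jj] - c))
    cls = np.where(dist <= 2000, "proximal", np.where(dist <= 10_000, "close", "distal"))
    in_peak = np.zeros(len(sites), dtype=bool)
    if peaks is not None:
        for chrom, sub in sites.groupby("chrom"):
            p = peaks[peaks.chrom == chrom]
            if p.empty:
                continue
            starts = np.sort(p.start.to_numpy())
            ends = p.end.to_numpy()[np.argsort(p.start.to_numpy())]
            c = sub.center.to_numpy()
            j = np.searchsorted(starts, c, side="right") - 1
            ok = j >= 0
            in_peak[sub.index[ok]] = c[ok] < ends[j[ok]]
    out["tss_class"] = cls
    out["in_peak"] = in_peak
    out["stratum"] = out["tss_class"] + np.where(in_peak, ":in_peak", ":off_peak")
    return out


def filter_homotypic(sites: pd.DataFrame, min_dist: int = HOMOTYPIC_MIN_DIST) -> pd.DataFrame:
    """Drop same-TF sites closer than ``min_dist`` to their neighbour."""
    keep = []
    for (_, _), sub in sites.groupby(["tf", "chrom"]):
        pos = sub.sort_values("center")
        c = pos.center.to_numpy()
        bad = np.zeros(len(c), dtype=bool)
        if len(c) > 1:
            close = np.diff(c) < min_dist
            bad[:-1] |= close
            bad[1:] |= close
        keep.extend(pos.index[~bad])
    return sites.loc[sorted(keep)]


def _cut_sites(fragments: pd.DataFrame) -> pd.DataFrame:
    """Both Tn5 cuts of each fragment, tagged with the insertion size."""
    size = (fragments["end"] - fragments["start"]).to_numpy()
    fwd = pd.DataFrame(
        {"chrom": fragments["chrom"], "pos": fragments["start"] - 4, "size": size}
    )
    rev = pd.DataFrame(
        {"chrom": fragments["chrom"], "pos": fragments["end"] + 5, "size": size}
    )
    return pd.concat([fwd, rev], ignore_index=True)


def build_insertion_matrix(
    fragments: pd.DataFrame,
    sites: pd.DataFrame,
    genome_hist: np.ndarray | None = None,
) -> InsertionMatrix:
    """Tally insertions around site centres, normalize, background-correct.

    Distances are strand-oriented (flipped for minus-strand sites).  Each
    row is divided by the genome-wide count of insertions with that size
    (``genome_hist``; computed from all supplied fragments when None), then
    the per-row mean over the 750-1,000-bp flanks is subtracted, so a
    signal-free matrix is ~0 everywhere.
    """
    cuts = _cut_sites(fragments)
    bins = np.clip(cuts["size"].to_numpy() // SIZE_BIN, 0, N_SIZE_BINS - 1).astype(int)
    if genome_hist is None:
        genome_hist = np.bincount(bins, minlength=N_SIZE_BINS).astype(float)
    raw = np.zeros((N_SIZE_BINS, N_DIST))
    n_reads = float(len(cuts))
    if len(sites) == 0:
        raise ValueError("need at least one TF site")
    if len(cuts):
        for chrom, sub in sites.groupby("chrom"):
            cc = cuts[cuts.chrom == chrom]
            if cc.empty:
                continue
            pos = cc["pos"].to_numpy()
            order = np.argsort(pos)
            pos = pos[order]
            b = bins[cc.index.to_numpy()][order]
            for center, strand in zip(sub["center"], sub["strand"]):
                lo = np.searchsorted(pos, center - WINDOW)
                hi = np.searchsorted(pos, center + WINDOW, side="right")
                if hi <= lo:
                    continue
                d = pos[lo:hi] - center
                if strand == "-":
                    d = -d
                np.add.at(raw, (b[lo:hi], d + WINDOW), 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = np.where(genome_hist[:, None] > 0, raw / genome_hist[:, None], 0.0)
    dist = np.arange(-WINDOW, WINDOW + 1)
    flank = (np.abs(dist) >= FLANK[0]) & (np.abs(dist) <= FLANK[1])
    corrected = norm - norm[:, flank].mean(axis=1, keepdims=True)
    return InsertionMatrix(values=corrected, raw=raw, n_sites=len(sites), n_reads=n_reads)


def pool_matrices(matrices: list[InsertionMatrix]) -> InsertionMatrix:
    """Read-weighted mean of per-sample matrices (the pooled normal)."""
    w = np.array([m.n_reads for m in matrices], dtype=float)
    w = w / w.sum()
    vals = np.sum([wi * m.values for wi, m in zip(w, matrices)], axis=0)
    raw = np.sum([m.raw for m in matrices], axis=0)
    return InsertionMatrix(
        values=vals, raw=raw, n_sites=matrices[0].n_sites,
        n_reads=float(sum(m.n_reads for m in matrices)),
    )


def differential_signal(sample: InsertionMatrix, pool: InsertionMatrix) -> float:
    """Central-block integral of (sample - pool).

    Sizes within [25, 120] bp, distances within [-100, +100] bp.
    """
    if sample.values.shape != pool.values.shape:
        raise ValueError("matrices are on different grids")
    rows = (SIZE_EDGES[:-1] >= CENTRAL_SIZES[0]) & (SIZE_EDGES[1:] <= CENTRAL_SIZES[1])
    dist = np.arange(-WINDOW, WINDOW + 1)
    cols = np.abs(dist) <= CENTRAL_DIST
    diff = sample.values - pool.values
    return float(diff[np.ix_(rows, cols)].sum())


def regress_tf_signal(
    signals: pd.DataFrame,
    model: str = "patient",
) -> pd.DataFrame:
    """Weighted least squares of TF signal on covariates and purity.

    ``signals``: long DataFrame with columns tf, sample, signal, tsse,
    tsse_nf, purity, reads and a ``patient`` (or ``region``) column.  The
    design is tsse * tsse_nf (main effects + interaction) plus a
    purity-by-group interaction (one slope per patient or region; normal
    samples have purity 0 and anchor the baseline), weighted by the square
    root of the read count.  Returns per (tf, group) purity coefficients
    with t-test p-values.  Rank-deficient columns are dropped.
    """
    if model not in ("patient", "region"):
        raise ValueError("model must be 'patient' or 'region'")
    rows = []
    for tf, sub in signals.groupby("tf"):
        groups = sorted(sub.loc[~sub["is_normal"], model].unique())
        base = np.column_stack(
            [
                np.ones(len(sub)),
                sub["tsse"].to_numpy(),
                sub["tsse_nf"].to_numpy(),
                sub["tsse"].to_numpy() * sub["tsse_nf"].to_numpy(),
            ]
        )
        inter = np.column_stack(
            [
                sub["purity"].to_numpy() * (sub[model] == g).to_numpy()
                for g in groups
            ]
        )
        X = np.column_stack([base, inter])
        # statsmodels resolves rank deficiency via pinv; coefficients of
        # dropped directions come back 0 with p = nan
        res = sm.WLS(
            sub["signal"].to_numpy(), X, weights=np.sqrt(sub["reads"].to_numpy())
        ).fit()
        for gi, g in enumerate(groups):
            j = base.shape[1] + gi
            rows.append(
                {
                    "tf": tf,
                    model: g,
                    "coef": float(res.params[j]),
                    "p": float(res.pvalues[j]),
                }
            )
    return pd.DataFrame(rows)


def cluster_tf_coefficients(
    coefs: pd.DataFrame,
    top_k: int = 150,
    n_clusters: int = 3,
    sig_alpha: float = 0.05,
) -> tuple[np.ndarray, pd.Series, list[str]]:
    """Hierarchical clustering of per-patient TF purity coefficients.

    Selects the ``top_k`` TFs most frequently showing a significant purity
    association, builds the patients x TFs coefficient matrix and clusters
    the TFs with Euclidean distance and complete linkage.  Returns
    (linkage matrix, flat cluster labels per TF, selected TF names).
    """
    freq = (
        coefs.assign(sig=coefs["p"] < sig_alpha)
        .groupby("tf")["sig"]
        .sum()
        .sort_values(ascending=False)
    )
    chosen = list(freq.index[: min(top_k, len(freq))])
    group_col = "patient" if "patient" in coefs.columns else "region"
    mat = coefs[coefs.tf.isin(chosen)].pivot_table(
        index=group_col, columns="tf", values="coef"
    )[chosen]
    Z = hierarchy.linkage(mat.to_numpy().T, method="complete", metric="euclidean")
    labels = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    return Z, pd.Series(labels, index=chosen, name="cluster"), chosen
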