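"""Cohort-level statistics: Fisher comparisons, MSI calls, burden tests,
SCAA heritability.

The burden comparison subsamples each carcinoma's reads (multivariate
hypergeometric, i.e. without replacement) down to the adenoma read total
before recounting detected SCAAs, so sequencing depth cannot masquerade as
epigenetic burden.  Heritability is assessed on pairwise SCAA distances
with permutation p-values (Mantel-style), since pairwise distances are not
independent observations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "fisher_exact_two_sided",
    "msi_classify",
    "BurdenRecord",
    "burden_comparison",
    "heritability_tests",
]

MSI_THRESHOLD = 0.30


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    The p-value sums hypergeometric probabilities, over tables with the
    observed margins, of all tables no more probable than the observed one.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("counts must be non-negative integers")
    return float(sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def msi_classify(fraction_mutated: float, override: str | None = None) -> str:
    """MSI if more than 30% of microsatellites are mutated (strict >).

    ``override`` reproduces clinical reclassification of low-purity cases.
    """
    if not 0.0 <= fraction_mutated <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    if override is not None:
        if override not in ("MSI", "MSS"):
            raise ValueError("override must be 'MSI' or 'MSS'")
        return override
    return "MSI" if fraction_mutated > MSI_THRESHOLD else "MSS"


@dataclass
class BurdenRecord:
    """Per-lesion read totals and counts over recurrent SCAA peaks."""

    lesion: str
    lesion_type: str  # "adenoma" | "carcinoma"
    total_reads: int
    gain_counts: np.ndarray  # reads in each recurrent gained peak
    loss_counts: np.ndarray  # reads in each recurrent lost peak


@dataclass
class BurdenResult:
    t_gain: float
    p_gain: float
    t_loss: float
    p_loss: float
    per_lesion: pd.DataFrame
    n_unsubsampled: int


def _subsample_counts(counts: np.ndarray, total: int, target: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Multivariate hypergeometric subsample of peak counts.

    ``total`` includes reads outside the listed peaks (a residual class),
    so per-peak proportions are preserved in expectation.
    """
    residual = total - int(counts.sum())
    if residual < 0:
        raise ValueError("peak counts exceed total reads")
    pop = np.append(counts.astype(np.int64), residual)
    draw = rng.multivariate_hypergeometric(pop, target)
    return draw[:-1]


def burden_comparison(
    records: list[BurdenRecord],
    seed: int = 0,
    detect_min_count: int = 10,
) -> BurdenResult:
    """Adenoma vs carcinoma SCAA burden after read subsampling.

    Carcinoma read sets are subsampled without replacement to the mean
    adenoma read total, detected SCAAs are recounted per lesion (count >=
    ``detect_min_count``), and Welch two-sided t-tests compare the two
    groups separately for gains and losses.  Carcinomas with fewer reads
    than the target are used unsubsampled and tallied.
    """
    rng = np.random.default_rng(seed)
    adeno = [r for r in records if r.lesion_type == "adenoma"]
    carc = [r for r in records if r.lesion_type == "carcinoma"]
    if len(adeno) < 2 or len(carc) < 2:
        raise ValueError("need >= 2 lesions per group")
    target = int(np.mean([r.total_reads for r in adeno]))

    rows = []
    n_unsub = 0
    for r in records:
        g, l = r.gain_counts, r.loss_counts
        if r.lesion_type == "carcinoma" and r.total_reads > target:
            g = _subsample_counts(np.asarray(g), r.total_reads, target, rng)
            l = _subsample_counts(np.asarray(l), r.total_reads, target, rng)
        elif r.lesion_type == "carcinoma":
            n_unsub += 1
        rows.append(
            {
                "lesion": r.lesion,
                "lesion_type": r.lesion_type,
                "n_gains": int(np.sum(np.asarray(g) >= detect_min_count)),
                "n_losses": int(np.sum(np.asarray(l) >= detect_min_count)),
            }
        )
    per_lesion = pd.DataFrame(rows)
    ad = per_lesion[per_lesion.lesion_type == "adenoma"]
    ca = per_lesion[per_lesion.lesion_type == "carcinoma"]

    def _welch(x, y):
        if np.var(x) == 0 and np.var(y) == 0:
            # degenerate: identical constants are indistinguishable
            same = float(np.mean(x)) == float(np.mean(y))
            return (0.0, 1.0) if same else (np.inf, 0.0)
        t, p = sps.ttest_ind(x, y, equal_var=False)
        return float(t), float(p)

    t_g, p_g = _welch(ca.n_gains, ad.n_gains)
    t_l, p_l = _welch(ca.n_losses, ad.n_losses)
    return BurdenResult(
        t_gain=float(t_g), p_gain=float(p_g),
        t_loss=float(t_l), p_loss=float(p_l),
        per_lesion=per_lesion, n_unsubsampled=n_unsub,
    )


def _pair_index(n: int):
    i, j = np.triu_indices(n, k=1)
    return i, j


def _same_region_stat(dist: np.ndarray, same: np.ndarray, covs: np.ndarray) -> float:
    """t statistic of the same-region indicator in an OLS of pairwise
    distances on the indicator plus covariate differences."""
    X = np.column_stack([np.ones(len(dist)), same.astype(float), covs])
    beta, *_ = np.linalg.lstsq(X, dist, rcond=None)
    resid = dist - X @ beta
    dof = max(len(dist) - X.shape[1], 1)
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.pinv(X.T @ X)
    se = np.sqrt(cov[1, 1])
    return float(beta[1] / se) if se > 0 else 0.0


def heritability_tests(
    profiles: pd.DataFrame,
    regions: pd.Series,
    covariates: pd.DataFrame,
    genetic_dist: np.ndarray | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> dict:
    """Within- vs between-region SCAA divergence and genetic correlation.

    ``profiles``: samples x peaks normalized signals; ``regions``: region
    label per sample; ``covariates``: per-sample tsse and total_reads (and
    purity when ``genetic_dist`` is given).  Pairwise Euclidean SCAA
    distances are regressed on a same-region indicator controlling for
    TSS-enrichment and read-count differences; the one-sided p (within <
    between) comes from permuting region labels.  When a genetic distance
    matrix is supplied, the partial Pearson correlation of genetic and
    epigenetic distances controlling for purity differences is reported
    with a Mantel permutation p.  Identical profiles everywhere yield an
    untestable (NaN) result.
    """
    samples = list(profiles.index)
    n = len(samples)
    if n < 4:
        raise ValueError("need >= 4 samples")
    X = profiles.to_numpy(dtype=float)
    from scipy.spatial.distance import squareform, pdist

    D = squareform(pdist(X))
    i, j = _pair_index(n)
    dist = D[i, j]
    if dist.std() == 0:
        return {"anova_t": float("nan"), "anova_p": float("nan"),
                "partial_r": float("nan"), "partial_p": float("nan"),
                "verdict": "untestable"}

    reg = regions.loc[samples].to_numpy()
    covs = np.column_stack(
        [
            np.abs(covariates.loc[samples, "tsse"].to_numpy()[i]
                   - covariates.loc[samples, "tsse"].to_numpy()[j]),
            np.abs(covariates.loc[samples, "total_reads"].to_numpy()[i]
                   - covariates.loc[samples, "total_reads"].to_numpy()[j]),
        ]
    )
    same = reg[i] == reg[j]
    t_obs = _same_region_stat(dist, same, covs)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        rp = reg[perm]
        t = _same_region_stat(dist, rp[i] == rp[j], covs)
        if t <= t_obs:  # one-sided: within-region less divergent
            count += 1
    anova_p = (count + 1) / (n_perm + 1)

    partial_r = float("nan")
    partial_p = float("nan")
    if genetic_dist is not None:
        G = np.asarray(genetic_dist, dtype=float)
        g = G[i, j]
        drho = np.abs(covariates.loc[samples, "purity"].to_numpy()[i]
                      - covariates.loc[samples, "purity"].to_numpy()[j])
        Z = np.column_stack([np.ones(len(g)), drho])
        re_ = dist - Z @ np.linalg.lstsq(Z, dist, rcond=None)[0]
        rg = g - Z @ np.linalg.lstsq(Z, g, rcond=None)[0]
        if re_.std() > 0 and rg.std() > 0:
            partial_r = float(np.corrcoef(re_, rg)[0, 1])
            count = 0
            for _ in range(n_perm):
                perm = rng.permutation(n)
                gp = G[np.ix_(perm, perm)][i, j]
                rgp = gp - Z @ np.linalg.lstsq(Z, gp, rcond=None)[0]
                r = float(np.corrcoef(re_, rgp)[0, 1])
                if r >= partial_r:
                    count += 1
            partial_p = (count + 1) / (n_perm + 1)

    return {
        "anova_t": t_obs,
        "anova_p": float(anova_p),
        "within_less_divergent": bool(t_obs < 0),
        "partial_r": partial_r,
        "partial_p": partial_p,
        "verdict": "tested",
    }
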