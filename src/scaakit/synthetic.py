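"""Synthetic multi-region gland cohort with known ground truth.

Emulates the sampling design of a single-gland multi-omic study of
colorectal tumours: each patient contributes four spatially distant tumour
regions (A-D) and one distant normal region (E), each sampled as individual
glands.  Every downstream stage of the pipeline (purity estimation, low-pass
copy-number fitting, SCAA calling, TF footprinting, mutational signatures)
can be exercised against planted, identifier-addressable effects.

The genome is a small set of named contigs (5 x 10 Mb) with a fabricated
TSS map and trinucleotide content table; no external reference is needed.
A single global seed fans out to per-stage child seeds via
:func:`stage_rng` so stages can be re-run independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfigError",
    "InvalidSiteError",
    "CohortConfig",
    "GroundTruth",
    "stage_rng",
    "simulate_cohort",
    "make_snv_sites",
    "simulate_allele_counts",
    "simulate_peak_counts",
    "simulate_fragments",
    "simulate_lowpass_bins",
    "simulate_mutation_catalogue",
    "synthetic_signatures",
    "genome_trinuc_content",
    "CHANNELS",
    "TRINUC32",
    "CHANNEL_TRINUC",
    "GENOME",
    "BIN_SIZE",
    "TUMOUR_REGIONS",
    "NORMAL_REGION",
]


class ConfigError(ValueError):
    """Raised when a :class:`CohortConfig` field is invalid."""


class InvalidSiteError(ValueError):
    """Raised for SNV sites with multiplicity exceeding copy number."""


# ---------------------------------------------------------------------------
# Fabricated genome
# ---------------------------------------------------------------------------

GENOME: Mapping[str, int] = {f"chr{i}": 10_000_000 for i in range(1, 6)}
BIN_SIZE = 500_000
TUMOUR_REGIONS = ("A", "B", "C", "D")
NORMAL_REGION = "E"

# effect sizes for planted somatic chromatin accessibility alterations
GAIN_EFFECT = 3.0
LOSS_EFFECT = 1.0 / 3.0
# fraction of patients carrying each cohort-recurrent planted SCAA
RECURRENT_PATIENT_FRAC = 0.3
# NB(mean) baseline for peak insertion counts: lognormal(log 50, 0.6)
PEAK_BASELINE_LOG_MEAN = np.log(50.0)
PEAK_BASELINE_LOG_SD = 0.6
SIZE_FACTOR_LOG_SD = 0.2

_STAGE_KEYS = {
    "cohort": 0,
    "alleles": 1,
    "peaks": 2,
    "fragments": 3,
    "lowpass": 4,
    "mutations": 5,
    "signatures": 6,
    "sites": 7,
}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent per-stage generator derived from one global seed."""
    key = _STAGE_KEYS[stage]
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def tss_table() -> pd.DataFrame:
    """Fabricated transcription start sites: one every 100 kb per contig."""
    rows = []
    i = 0
    for chrom, size in GENOME.items():
        for pos in range(50_000, size, 100_000):
            rows.append((chrom, pos, "+" if i % 2 == 0 else "-", f"g{i:04d}"))
            i += 1
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "gene"])


# ---------------------------------------------------------------------------
# 96-channel substitution catalogue conventions
# ---------------------------------------------------------------------------

_SUBS = [("C", "A"), ("C", "G"), ("C", "T"), ("T", "A"), ("T", "C"), ("T", "G")]
_BASES = "ACGT"

CHANNELS: list[str] = [
    f"{l}[{r}>{a}]{g}" for r, a in _SUBS for l in _BASES for g in _BASES
]
#: trinucleotide context (pyrimidine-centred) of each of the 96 channels
CHANNEL_TRINUC: list[str] = [
    f"{l}{r}{g}" for r, a in _SUBS for l in _BASES for g in _BASES
]
#: the 32 distinct pyrimidine-centred trinucleotide contexts
TRINUC32: list[str] = sorted(set(CHANNEL_TRINUC))


def genome_trinuc_content() -> pd.Series:
    """Fabricated genome-wide trinucleotide frequencies (uniform)."""
    return pd.Series(1.0 / len(TRINUC32), index=TRINUC32, name="freq")


def synthetic_signatures(k: int = 4, seed: int = 0, support: int = 20) -> pd.DataFrame:
    """Random sparse 96-channel signature profiles (synthetic stand-ins).

    Each signature is a Dirichlet draw restricted to ``support`` random
    channels, so distinct signatures have nearly disjoint support and are
    well separated in cosine distance.
    """
    rng = stage_rng(seed, "signatures")
    mat = np.zeros((k, 96))
    for i in range(k):
        idx = rng.choice(96, size=support, replace=False)
        mat[i, idx] = rng.dirichlet(np.full(support, 0.5))
    return pd.DataFrame(mat, index=[f"S{i + 1}" for i in range(k)], columns=CHANNELS)


# ---------------------------------------------------------------------------
# Configuration and ground truth containers
# ---------------------------------------------------------------------------


@dataclass
class CohortConfig:
    """Study-design parameters for one synthetic cohort.

    Defaults mirror the multi-region gland design: 4 tumour regions plus a
    normal region per patient, a handful of glands per region (the real
    study profiled 21-55 tumour samples per patient), ATAC coverage of ~30
    reads per SNV site, and a modest planted-SCAA rate.
    """

    n_patients: int = 4
    regions_per_tumour: int = 4
    glands_per_region: int = 5
    purity_range: tuple[float, float] = (0.3, 0.95)
    sequencing_depth: float = 30.0
    peak_count: int = 2000
    scaa_fraction: float = 0.1
    subclonal_fraction: float = 0.2
    nb_dispersion: float = 0.05
    ploidy: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        if not 1 <= self.regions_per_tumour <= len(TUMOUR_REGIONS):
            raise ConfigError("regions_per_tumour must be in 1..4")
        if self.glands_per_region < 2:
            raise ConfigError(
                "glands_per_region must be >= 2 (biological replicates "
                "are needed for the subclonality test)"
            )
        lo, hi = self.purity_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigError("purity_range must be an interval within [0, 1]")
        if self.sequencing_depth <= 0:
            raise ConfigError("sequencing_depth must be > 0")
        if self.peak_count < 1:
            raise ConfigError("peak_count must be >= 1")
        for name in ("scaa_fraction", "subclonal_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be > 0")
        if self.ploidy < 1:
            raise ConfigError("ploidy must be a positive integer")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["purity_range"] = list(self.purity_range)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        d = dict(d)
        if "purity_range" in d:
            d["purity_range"] = tuple(d["purity_range"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Every planted effect, retrievable by stable identifier."""

    config: CohortConfig
    samples: pd.DataFrame  # sample, patient, region, is_normal, purity, ...
    segments: pd.DataFrame  # patient, chrom, start, end, cn
    ploidy: pd.Series  # patient -> integer tumour ploidy
    peaks: pd.DataFrame  # peak_id, chrom, start, end, is_promoter
    effects: pd.DataFrame  # patient, peak_id, direction, effect, regions
    tf_sites: pd.DataFrame  # tf, chrom, center, strand
    tf_effects: pd.Series  # tf -> footprint effect factor
    signatures: pd.DataFrame = field(default_factory=pd.DataFrame)
    exposures: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def seed(self) -> int:
        return self.config.seed


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


def _simulate_segments(rng: np.random.Generator, patient: str, ploidy: int) -> pd.DataFrame:
    """Segment-constant copy-number truth shared across a patient's samples.

    At most one aberrant segment per contig keeps >50% of bins at ploidy so
    that per-sample median-centring of the log ratios is a near no-op.
    """
    rows = []
    n_bins = {c: s // BIN_SIZE for c, s in GENOME.items()}
    aberrant = 0
    for chrom, nb in n_bins.items():
        if rng.random() < 0.95:
            length = int(rng.integers(4, 13))
            start_bin = int(rng.integers(0, nb - length + 1))
            delta = rng.choice([-1, 1, 2], p=[0.40, 0.40, 0.20])
            cn = max(int(ploidy + delta), 0)
            segs = []
            if start_bin > 0:
                segs.append((0, start_bin, ploidy))
            segs.append((start_bin, start_bin + length, cn))
            if start_bin + length < nb:
                segs.append((start_bin + length, nb, ploidy))
            aberrant += 1
        else:
            segs = [(0, nb, ploidy)]
        for b0, b1, cn in segs:
            rows.append((patient, chrom, b0 * BIN_SIZE, b1 * BIN_SIZE, cn))
    df = pd.DataFrame(rows, columns=["patient", "chrom", "start", "end", "cn"])
    if aberrant < 2:  # keep the purity grid identifiable
        flat = df.index[(df.cn == ploidy) & (df.chrom == "chr1")]
        df.loc[flat[:1], "cn"] = ploidy + 1
    return df


def simulate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate gland samples and full ground truth for one cohort.

    Deterministic given ``config.seed``.  Tumour gland purities are drawn
    uniformly over ``purity_range`` (a modelling convenience; the
    within-tumour purity distribution is not otherwise constrained);
    normal-region glands have purity 0.
    """
    config.validate()
    rng = stage_rng(config.seed, "cohort")

    regions = TUMOUR_REGIONS[: config.regions_per_tumour]
    sample_rows = []
    seg_frames = []
    ploidies = {}
    patients = [f"P{i + 1:02d}" for i in range(config.n_patients)]
    for patient in patients:
        ploidies[patient] = config.ploidy
        seg_frames.append(_simulate_segments(rng, patient, config.ploidy))
        for region in list(regions) + [NORMAL_REGION]:
            is_normal = region == NORMAL_REGION
            for g in range(config.glands_per_region):
                purity = 0.0 if is_normal else float(
                    rng.uniform(*config.purity_range)
                )
                tsse = float(np.clip(rng.normal(7.0, 1.5), 2.0, None))
                sample_rows.append(
                    {
                        "sample": f"{patient}_{region}{g + 1}_G",
                        "patient": patient,
                        "region": region,
                        "is_normal": is_normal,
                        "purity": purity,
                        "tsse": tsse,
                        "tsse_nf": tsse + float(rng.normal(0.0, 0.5)),
                        "total_reads": float(rng.lognormal(np.log(1e6), 0.4)),
                    }
                )
    samples = pd.DataFrame(sample_rows)

    # --- peak intervals -------------------------------------------------
    tss = tss_table()
    n_prom = config.peak_count * 3 // 10
    prom_tss = tss.sample(
        n=min(n_prom, len(tss)), random_state=int(rng.integers(2**31)), replace=False
    )
    centers, chroms = [], []
    for _, t in prom_tss.iterrows():
        chroms.append(t.chrom)
        centers.append(int(t.pos))
    for _ in range(config.peak_count - len(centers)):
        chrom = rng.choice(list(GENOME))
        chroms.append(str(chrom))
        centers.append(int(rng.integers(1000, GENOME[chrom] - 1000)))
    peaks = pd.DataFrame(
        {
            "chrom": chroms,
            "start": np.array(centers) - 250,
            "end": np.array(centers) + 250,
        }
    )
    peaks = peaks.sort_values(["chrom", "start"]).reset_index(drop=True)
    peaks.insert(0, "peak_id", [f"pk{i:06d}" for i in range(len(peaks))])
    mid = (peaks.start + peaks.end) // 2
    is_prom = np.zeros(len(peaks), dtype=bool)
    for chrom, sub in peaks.groupby("chrom"):
        tpos = np.sort(tss.loc[tss.chrom == chrom, "pos"].to_numpy())
        m = mid[sub.index].to_numpy()
        j = np.searchsorted(tpos, m)
        dist = np.full(len(m), np.inf)
        for off in (-1, 0):
            jj = np.clip(j + off, 0, len(tpos) - 1)
            dist = np.minimum(dist, np.abs(tpos[jj] - m))
        is_prom[sub.index] = dist <= 1000
    peaks["is_promoter"] = is_prom

    # --- planted SCAAs --------------------------------------------------
    n_scaa = int(round(config.scaa_fraction * config.peak_count))
    scaa_ids = rng.choice(peaks.peak_id.to_numpy(), size=n_scaa, replace=False)
    n_recur = n_scaa // 2
    n_hit = max(1, int(round(RECURRENT_PATIENT_FRAC * config.n_patients)))
    eff_rows = []
    for i, pid in enumerate(scaa_ids):
        direction = "gain" if i % 2 == 0 else "loss"
        effect = GAIN_EFFECT if direction == "gain" else LOSS_EFFECT
        if i < n_recur:
            hit = rng.choice(patients, size=n_hit, replace=False)
        else:
            hit = [rng.choice(patients)]
        for patient in hit:
            if rng.random() < config.subclonal_fraction and len(regions) > 1:
                k = int(rng.integers(1, len(regions)))
                aff = tuple(sorted(rng.choice(regions, size=k, replace=False)))
            else:
                aff = tuple(regions)
            eff_rows.append(
                {
                    "patient": patient,
                    "peak_id": pid,
                    "direction": direction,
                    "effect": effect,
                    "regions": ",".join(aff),
                    "clonal": len(aff) == len(regions),
                }
            )
    effects = pd.DataFrame(
        eff_rows,
        columns=["patient", "peak_id", "direction", "effect", "regions", "clonal"],
    )

    # --- TF binding sites and footprint effects ------------------------
    tf_names = [f"TF{i + 1:02d}" for i in range(8)]
    tf_truth = {}
    site_rows = []
    for i, tf in enumerate(tf_names):
        tf_truth[tf] = [1.0, 2.0, 0.5][i % 3] if i else 1.0
        for _ in range(200):
            chrom = str(rng.choice(list(GENOME)))
            # homotypic spacing: sites of one TF on a coarse jittered grid
            base = int(rng.integers(1, GENOME[chrom] // 2000 - 1)) * 2000
            site_rows.append(
                (tf, chrom, base + int(rng.integers(0, 800)),
                 "+" if rng.random() < 0.5 else "-")
            )
    tf_sites = (
        pd.DataFrame(site_rows, columns=["tf", "chrom", "center", "strand"])
        .drop_duplicates(["tf", "chrom", "center"])
        .reset_index(drop=True)
    )
    # enforce the >= 1 kb same-TF spacing invariant
    keep = []
    for (tf, chrom), sub in tf_sites.groupby(["tf", "chrom"]):
        pos = sub.sort_values("center")
        last = -10_000
        for idx, c in zip(pos.index, pos.center):
            if c - last >= 1000:
                keep.append(idx)
                last = c
    tf_sites = tf_sites.loc[sorted(keep)].reset_index(drop=True)

    # --- signature truth ------------------------------------------------
    signatures = synthetic_signatures(k=4, seed=config.seed)
    exp_rows = []
    for patient in patients:
        for clonality in ("clonal", "subclonal"):
            e = rng.dirichlet(np.ones(len(signatures)))
            exp_rows.append([patient, clonality, *e])
    exposures = pd.DataFrame(
        exp_rows, columns=["patient", "clonality", *signatures.index]
    )

    truth = GroundTruth(
        config=config,
        samples=samples,
        segments=pd.concat(seg_frames, ignore_index=True),
        ploidy=pd.Series(ploidies, name="psi_t"),
        peaks=peaks,
        effects=effects,
        tf_sites=tf_sites,
        tf_effects=pd.Series(tf_truth, name="effect"),
        signatures=signatures,
        exposures=exposures,
    )
    return samples, truth


# ---------------------------------------------------------------------------
# SNV allele counts
# ---------------------------------------------------------------------------


def make_snv_sites(
    n_sites: int,
    seed: int = 0,
    states: Sequence[tuple[int, int]] = ((1, 2), (1, 3), (2, 4)),
    weights: Sequence[float] = (0.7, 0.2, 0.1),
) -> pd.DataFrame:
    """Clonal SNV sites with multiplicity/copy-number context.

    ``states`` are (multiplicity m, total copy number c) pairs; every site
    is flagged clonal so it can enter purity estimation.
    """
    rng = stage_rng(seed, "sites")
    chroms = rng.choice(list(GENOME), size=n_sites)
    pos = np.array([rng.integers(1, GENOME[c]) for c in chroms])
    idx = rng.choice(len(states), size=n_sites, p=np.asarray(weights) / np.sum(weights))
    m = np.array([states[i][0] for i in idx])
    c = np.array([states[i][1] for i in idx])
    ref = rng.choice(list("ACGT"), size=n_sites)
    alt = np.array(
        [rng.choice([b for b in "ACGT" if b != r]) for r in ref]
    )
    return pd.DataFrame(
        {
            "site_id": [f"snv{i:05d}" for i in range(n_sites)],
            "chrom": chroms,
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "multiplicity": m,
            "copy_number": c,
            "clonal": True,
        }
    )


def expected_alt_fraction(rho: np.ndarray, m: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Expected ATAC variant allele fraction rho*m / (rho*c + 2 - 2*rho)."""
    rho = np.asarray(rho, dtype=float)
    denom = rho * c + 2.0 - 2.0 * rho
    return np.where(denom > 0, rho * m / np.where(denom > 0, denom, 1.0), 0.0)


def simulate_allele_counts(
    samples: pd.DataFrame,
    sites: pd.DataFrame,
    depth: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Per (site, sample) ref/alt read counts.

    Depth at each site is Poisson(``depth``); alt counts are binomial with
    success probability rho*m/(rho*c + 2 - 2*rho).  Raises
    :class:`InvalidSiteError` if any site has m > c or m < 1.
    """
    if depth <= 0:
        raise ConfigError("depth must be > 0")
    m = sites.multiplicity.to_numpy()
    c = sites.copy_number.to_numpy()
    bad = (m > c) | (m < 1)
    if bad.any():
        raise InvalidSiteError(
            f"{bad.sum()} site(s) with multiplicity > copy number (first: "
            f"{sites.site_id.to_numpy()[bad][0]})"
        )
    rng = stage_rng(seed, "alleles")
    rho = samples.purity.to_numpy()[:, None]  # samples x sites
    p = expected_alt_fraction(rho, m[None, :], c[None, :])
    n = rng.poisson(depth, size=(len(samples), len(sites)))
    k = rng.binomial(n, p)
    out = []
    for i, s in enumerate(samples["sample"]):
        df = sites[["site_id", "chrom", "pos", "ref", "alt",
                    "multiplicity", "copy_number", "clonal"]].copy()
        df["sample"] = s
        df["ref_count"] = n[i] - k[i]
        df["alt_count"] = k[i]
        out.append(df)
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# Peak insertion counts
# ---------------------------------------------------------------------------


def cn_mixture_factor(rho, pi, psi):
    """(2(1-rho) + pi*rho) / (2(1-rho) + psi*rho): CNA effect on signal."""
    rho = np.asarray(rho, dtype=float)
    num = 2.0 * (1.0 - rho) + np.asarray(pi, float) * rho
    den = 2.0 * (1.0 - rho) + np.asarray(psi, float) * rho
    return num / den


def _peak_locus_cn(truth: GroundTruth) -> pd.DataFrame:
    """True tumour copy number at each peak midpoint, per patient."""
    mid = ((truth.peaks.start + truth.peaks.end) // 2).to_numpy()
    chrom = truth.peaks.chrom.to_numpy()
    out = {}
    for patient, segs in truth.segments.groupby("patient"):
        cn = np.full(len(mid), float(truth.ploidy[patient]))
        for _, s in segs.iterrows():
            mask = (chrom == s.chrom) & (mid >= s.start) & (mid < s.end)
            cn[mask] = s.cn
        out[patient] = cn
    return pd.DataFrame(out, index=truth.peaks.peak_id)


def simulate_peak_counts(
    truth: GroundTruth,
    samples: pd.DataFrame | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """NB-distributed insertion counts for every (peak, sample).

    Mean model: sf_s * S_N,p * effect * (2(1-rho)+pi*rho) / (2(1-rho)+psi*rho)
    with per-peak baseline S_N, per-sample size factor sf, planted effect
    (>1 gains, <1 losses, 1 unchanged) applied only in affected regions of
    carrier patients.  Returns (counts peaks x samples, size factors,
    baselines).
    """
    samples = truth.samples if samples is None else samples
    seed = truth.seed if seed is None else seed
    rng = stage_rng(seed, "peaks")
    cfg = truth.config

    n_peaks = len(truth.peaks)
    baseline = pd.Series(
        rng.lognormal(PEAK_BASELINE_LOG_MEAN, PEAK_BASELINE_LOG_SD, n_peaks),
        index=truth.peaks.peak_id,
        name="baseline",
    )
    sf = pd.Series(
        rng.lognormal(0.0, SIZE_FACTOR_LOG_SD, len(samples)),
        index=samples["sample"],
        name="size_factor",
    )
    if (sf <= 0).any():
        raise ConfigError("non-positive size factor")
    locus_cn = _peak_locus_cn(truth)

    eff_lookup: dict[tuple[str, str], tuple[float, tuple[str, ...]]] = {}
    for _, e in truth.effects.iterrows():
        eff_lookup[(e.patient, e.peak_id)] = (e.effect, tuple(e.regions.split(",")))

    counts = np.zeros((n_peaks, len(samples)), dtype=np.int64)
    peak_ids = truth.peaks.peak_id.to_numpy()
    for j, (_, smp) in enumerate(samples.iterrows()):
        rho = smp.purity
        if smp.is_normal:
            mu = sf[smp["sample"]] * baseline.to_numpy()
        else:
            psi = float(truth.ploidy.get(smp.patient, cfg.ploidy))
            pi = (
                locus_cn[smp.patient].to_numpy()
                if smp.patient in locus_cn
                else np.full(n_peaks, psi)
            )
            effect = np.ones(n_peaks)
            for i, pid in enumerate(peak_ids):
                hit = eff_lookup.get((smp.patient, pid))
                if hit is not None and smp.region in hit[1]:
                    effect[i] = hit[0]
            mu = (
                sf[smp["sample"]]
                * baseline.to_numpy()
                * effect
                * cn_mixture_factor(rho, pi, psi)
            )
        counts[:, j] = rng.negative_binomial(
            1.0 / cfg.nb_dispersion, 1.0 / (1.0 + cfg.nb_dispersion * mu)
        )
    counts_df = pd.DataFrame(counts, index=truth.peaks.peak_id, columns=samples["sample"])
    return counts_df, sf, baseline


# ---------------------------------------------------------------------------
# ATAC fragments around TF binding sites
# ---------------------------------------------------------------------------


def _open_sizes(rng: np.random.Generator, n: int) -> np.ndarray:
    # sub-100-bp open-chromatin component: shifted exponential, mode ~60 bp
    return 60.0 + rng.exponential(18.0, n)


def _background_sizes(rng: np.random.Generator, n: int) -> np.ndarray:
    comp = rng.choice(3, size=n, p=[0.6, 0.3, 0.1])
    out = np.empty(n)
    out[comp == 0] = _open_sizes(rng, int((comp == 0).sum()))
    out[comp == 1] = rng.normal(200.0, 25.0, int((comp == 1).sum()))
    out[comp == 2] = rng.normal(400.0, 35.0, int((comp == 2).sum()))
    return np.clip(out, 38.0, 620.0)


def simulate_fragments(
    tf_sites: pd.DataFrame,
    tf_effects: Mapping[str, float],
    samples: pd.DataFrame,
    seed: int = 0,
    central_rate: float = 20.0,
    background_rate: float = 30.0,
    distal_rate: float = 150.0,
) -> pd.DataFrame:
    """Fragment records (chrom, start, end, sample) around TF sites.

    Each site receives Poisson(``background_rate``) fragments placed
    uniformly within +/-1 kb whose insertion sizes follow the full
    open/nucleosomal mixture, plus Poisson(central_rate * f) open-chromatin
    fragments centred on the site, where f = 1 + (effect - 1) * purity
    scales the central sub-100-bp density linearly with purity.  A further
    Poisson(``distal_rate`` * n_sites) fragments per sample are scattered
    uniformly over the genome so the genome-wide insertion-size histogram
    (the row normalizer of the footprint matrices) is dominated by
    signal-free background, as it is in a real library.
    """
    rng = stage_rng(seed, "fragments")
    rows = []
    contigs = list(GENOME)
    contig_sizes = np.array([GENOME[c] for c in contigs], dtype=float)
    contig_p = contig_sizes / contig_sizes.sum()
    site_tf = tf_sites.tf.to_numpy()
    site_chrom = tf_sites.chrom.to_numpy()
    site_center = tf_sites.center.to_numpy()
    for _, smp in samples.iterrows():
        rho = smp.purity
        for tf, chrom, center in zip(site_tf, site_chrom, site_center):
            effect = float(tf_effects.get(tf, 1.0)) if not smp.is_normal else 1.0
            f = max(1.0 + (effect - 1.0) * rho, 0.0)
            n_bg = rng.poisson(background_rate)
            n_ct = rng.poisson(central_rate * f)
            if n_bg:
                sizes = _background_sizes(rng, n_bg)
                centres = center + rng.uniform(-1000, 1000, n_bg)
                starts = np.maximum(np.round(centres - sizes / 2).astype(int), 0)
                ends = starts + np.round(sizes).astype(int)
                for s, e in zip(starts, ends):
                    rows.append((chrom, s, e, smp["sample"], tf))
            if n_ct:
                sizes = _open_sizes(rng, n_ct)
                centres = center + rng.normal(0.0, 30.0, n_ct)
                starts = np.maximum(np.round(centres - sizes / 2).astype(int), 0)
                ends = starts + np.round(sizes).astype(int)
                for s, e in zip(starts, ends):
                    rows.append((chrom, s, e, smp["sample"], tf))
        n_distal = rng.poisson(distal_rate * len(tf_sites))
        if n_distal:
            sizes = _background_sizes(rng, n_distal)
            ci = rng.choice(len(contigs), size=n_distal, p=contig_p)
            centres = rng.uniform(0, contig_sizes[ci])
            starts = np.maximum(np.round(centres - sizes / 2).astype(int), 0)
            ends = starts + np.round(sizes).astype(int)
            for k in range(n_distal):
                rows.append(
                    (contigs[ci[k]], starts[k], ends[k], smp["sample"], "distal")
                )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "sample", "tf"])


# ---------------------------------------------------------------------------
# Low-pass WGS bins
# ---------------------------------------------------------------------------


def simulate_lowpass_bins(
    truth: GroundTruth,
    samples: pd.DataFrame | None = None,
    noise_sd: float = 0.05,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Median-centred binned log2 coverage ratios per sample.

    r = log2((2(1-rho) + rho*n_true) / (2(1-rho) + rho*psi_t)) + noise,
    then the per-sample median is subtracted (and returned so it can be
    undone).
    """
    samples = truth.samples if samples is None else samples
    seed = truth.seed if seed is None else seed
    rng = stage_rng(seed, "lowpass")

    grid_rows = []
    for chrom, size in GENOME.items():
        for start in range(0, size, BIN_SIZE):
            grid_rows.append((chrom, start, start + BIN_SIZE))
    grid = pd.DataFrame(grid_rows, columns=["chrom", "start", "end"])
    mid = ((grid.start + grid.end) // 2).to_numpy()
    chrom_arr = grid.chrom.to_numpy()

    out = []
    medians = {}
    for _, smp in samples.iterrows():
        rho = smp.purity
        psi = float(truth.ploidy.get(smp.patient, truth.config.ploidy))
        cn = np.full(len(grid), float(truth.config.ploidy))
        segs = truth.segments[truth.segments.patient == smp.patient]
        for _, s in segs.iterrows():
            mask = (chrom_arr == s.chrom) & (mid >= s.start) & (mid < s.end)
            cn[mask] = s.cn
        num = 2.0 * (1.0 - rho) + rho * cn
        den = 2.0 * (1.0 - rho) + rho * psi
        r = np.log2(num / den)
        if noise_sd > 0:
            r = r + rng.normal(0.0, noise_sd, len(r))
        med = float(np.median(r))
        medians[smp["sample"]] = med
        df = grid.copy()
        df["sample"] = smp["sample"]
        df["log2ratio"] = r - med
        out.append(df)
    bins = pd.concat(out, ignore_index=True)[
        ["sample", "chrom", "start", "end", "log2ratio"]
    ]
    return bins, pd.Series(medians, name="median_log2ratio")


# ---------------------------------------------------------------------------
# Mutation catalogues
# ---------------------------------------------------------------------------


def simulate_mutation_catalogue(
    signatures: pd.DataFrame,
    exposures: Sequence[float],
    n_mut: int,
    region_content: pd.Series | None = None,
    genome_content: pd.Series | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Multinomial 96-channel catalogue from an exposure-weighted mixture.

    Channel probabilities are re-weighted by the region trinucleotide
    content relative to the genome before drawing, emulating how a region's
    sequence composition shapes its observed spectrum.
    """
    e = np.asarray(exposures, dtype=float)
    if (e < 0).any():
        raise ConfigError("exposures must be non-negative")
    if abs(e.sum() - 1.0) > 1e-6:
        raise ConfigError(f"exposures must sum to 1 (got {e.sum():.8f})")
    S = signatures.to_numpy() if isinstance(signatures, pd.DataFrame) else np.asarray(signatures)
    p = e @ S
    if region_content is not None:
        genome_content = (
            genome_trinuc_content() if genome_content is None else genome_content
        )
        w = np.array(
            [region_content[t] / genome_content[t] for t in CHANNEL_TRINUC]
        )
        p = p * w
    total = p.sum()
    if n_mut == 0 or total == 0:
        return np.zeros(96, dtype=np.int64)
    rng = stage_rng(seed, "mutations")
    return rng.multinomial(n_mut, p / total)
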