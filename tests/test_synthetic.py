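"""Generator contracts: determinism, planted-effect bookkeeping, and the
closed-form means each simulator advertises."""

import numpy as np
import pandas as pd
import pytest

from scaakit import io as skio
from scaakit.synthetic import (
    CHANNELS,
    CohortConfig,
    ConfigError,
    GENOME,
    InvalidSiteError,
    TRINUC32,
    cn_mixture_factor,
    genome_trinuc_content,
    make_snv_sites,
    simulate_allele_counts,
    simulate_cohort,
    simulate_fragments,
    simulate_lowpass_bins,
    simulate_mutation_catalogue,
    simulate_peak_counts,
    synthetic_signatures,
)


class TestCohort:
    def test_deterministic_under_fixed_seed(self):
        cfg = CohortConfig(n_patients=2, peak_count=100, seed=42)
        s1, t1 = simulate_cohort(cfg)
        s2, t2 = simulate_cohort(CohortConfig(n_patients=2, peak_count=100, seed=42))
        pd.testing.assert_frame_equal(s1, s2)
        pd.testing.assert_frame_equal(t1.effects, t2.effects)
        pd.testing.assert_frame_equal(t1.segments, t2.segments)

    def test_sample_count_arithmetic(self):
        # 2 patients x (4 regions x 5 glands + 5 normal glands) = 50
        cfg = CohortConfig(n_patients=2, regions_per_tumour=4, glands_per_region=5,
                           peak_count=50, seed=0)
        samples, _ = simulate_cohort(cfg)
        assert len(samples) == 50
        assert samples.is_normal.sum() == 10

    def test_degenerate_purity_range(self):
        cfg = CohortConfig(n_patients=1, purity_range=(1.0, 1.0), peak_count=50, seed=3)
        samples, _ = simulate_cohort(cfg)
        tum = samples[~samples.is_normal]
        assert (tum.purity == 1.0).all()
        assert (samples.loc[samples.is_normal, "purity"] == 0.0).all()

    @pytest.mark.parametrize(
        "field,value",
        [
            ("glands_per_region", 1),
            ("purity_range", (0.5, 0.2)),
            ("sequencing_depth", 0.0),
            ("scaa_fraction", 1.5),
            ("nb_dispersion", 0.0),
        ],
    )
    def test_invalid_config_names_field(self, field, value):
        cfg = CohortConfig(**{field: value})
        with pytest.raises(ConfigError):
            cfg.validate()

    def test_clonal_effects_cover_all_regions(self, small_cohort):
        _, _, truth = small_cohort
        clonal = truth.effects[truth.effects.clonal]
        for _, e in clonal.iterrows():
            assert e.regions == "A,B,C,D"

    def test_every_effect_addresses_a_known_peak(self, small_cohort):
        _, _, truth = small_cohort
        assert set(truth.effects.peak_id) <= set(truth.peaks.peak_id)


class TestAlleleCounts:
    def test_zero_purity_means_zero_alt(self, small_cohort):
        _, samples, _ = small_cohort
        normals = samples[samples.is_normal].head(2)
        sites = make_snv_sites(40, seed=1)
        ac = simulate_allele_counts(normals, sites, depth=30, seed=1)
        assert (ac.alt_count == 0).all()

    def test_pure_diploid_het_vaf_half(self):
        samples = pd.DataFrame(
            [{"sample": "s", "purity": 1.0, "is_normal": False}]
        )
        sites = make_snv_sites(2000, seed=2, states=[(1, 2)], weights=[1.0])
        ac = simulate_allele_counts(samples, sites, depth=50, seed=2)
        vaf = ac.alt_count.sum() / (ac.alt_count + ac.ref_count).sum()
        assert abs(vaf - 0.5) < 0.01

    def test_mean_vaf_matches_formula(self):
        # rho=0.5, m=1, c=3 -> p = 0.5/(1.5+1) = 0.2 (hand-evaluated)
        samples = pd.DataFrame([{"sample": "s", "purity": 0.5, "is_normal": False}])
        sites = make_snv_sites(100_000, seed=3, states=[(1, 3)], weights=[1.0])
        ac = simulate_allele_counts(samples, sites, depth=10, seed=3)
        vaf = ac.alt_count.sum() / (ac.alt_count + ac.ref_count).sum()
        assert abs(vaf - 0.2) < 0.005

    def test_multiplicity_above_copy_number_rejected(self):
        samples = pd.DataFrame([{"sample": "s", "purity": 0.5, "is_normal": False}])
        sites = make_snv_sites(5, seed=4)
        sites.loc[0, "multiplicity"] = 5
        with pytest.raises(InvalidSiteError):
            simulate_allele_counts(samples, sites, depth=10, seed=4)


class TestPeakCounts:
    def test_normal_mean_ignores_copy_number(self, small_cohort):
        _, samples, truth = small_cohort
        counts, sf, base = simulate_peak_counts(truth)
        normals = samples.loc[samples.is_normal, "sample"]
        expected = np.outer(base, sf[normals])
        observed = counts[normals].to_numpy()
        # pooled over all peaks and normals the ratio should be ~1
        assert abs(observed.sum() / expected.sum() - 1.0) < 0.02

    def test_cn_factor_identities(self):
        assert cn_mixture_factor(0.0, 7, 2) == 1.0
        assert cn_mixture_factor(0.77, 3, 3) == 1.0
        assert cn_mixture_factor(1.0, 4, 2) == 2.0

    def test_planted_gain_mean_ratio(self):
        # effect 3 at rho=1, neutral CN: tumour/normal mean ratio -> 3*pi/psi = 3
        cfg = CohortConfig(n_patients=1, glands_per_region=4,
                           purity_range=(1.0, 1.0), peak_count=400,
                           scaa_fraction=0.3, subclonal_fraction=0.0, seed=7)
        samples, truth = simulate_cohort(cfg)
        counts, sf, base = simulate_peak_counts(truth)
        gains = truth.effects[truth.effects.direction == "gain"].peak_id
        cn = truth.segments
        tum = samples.loc[~samples.is_normal, "sample"]
        norm = samples.loc[samples.is_normal, "sample"]
        ratios = []
        for pid in gains:
            pk = truth.peaks.set_index("peak_id").loc[pid]
            seg = cn[(cn.chrom == pk.chrom) & (cn.start <= pk.start) & (cn.end >= pk.end)]
            if len(seg) != 1 or seg.cn.iloc[0] != 2:
                continue  # restrict to CN-neutral loci
            t = (counts.loc[pid, tum] / sf[tum]).mean()
            n = (counts.loc[pid, norm] / sf[norm]).mean()
            ratios.append(t / n)
        assert len(ratios) > 10
        assert abs(np.mean(ratios) - 3.0) < 0.35


class TestLowpass:
    def test_flat_diploid_is_zero(self, small_cohort):
        _, samples, truth = small_cohort
        flat = truth.segments.copy()
        flat["cn"] = 2
        truth2 = type(truth)(**{**truth.__dict__, "segments": flat})
        bins, med = simulate_lowpass_bins(truth2, samples.head(2), noise_sd=0.0)
        assert np.allclose(bins.log2ratio, 0.0, atol=1e-12)

    def test_single_gain_formula(self, small_cohort):
        # rho=1, psi=2, n=3 -> log2(1.5) before centring
        _, samples, truth = small_cohort
        smp = samples[~samples.is_normal].head(1).copy()
        smp["purity"] = 1.0
        bins, med = simulate_lowpass_bins(truth, smp, noise_sd=0.0)
        s = smp["sample"].iloc[0]
        patient = smp.patient.iloc[0]
        segs = truth.segments[(truth.segments.patient == patient)
                              & (truth.segments.cn == 3)]
        if segs.empty:
            pytest.skip("no CN-3 segment in this patient")
        seg = segs.iloc[0]
        sel = bins[(bins["sample"] == s) & (bins.chrom == seg.chrom)
                   & (bins.start >= seg.start) & (bins.end <= seg.end)]
        uncentred = sel.log2ratio + med[s]
        assert np.allclose(uncentred, np.log2(1.5), atol=1e-12)


class TestFragments:
    def test_roundtrip_through_bed(self, tmp_path):
        sites = pd.DataFrame(
            {"tf": "TF1", "chrom": "chr1", "center": [5000, 9000], "strand": ["+", "-"]}
        )
        samples = pd.DataFrame(
            [{"sample": "a", "purity": 0.5, "is_normal": False}]
        )
        frags = simulate_fragments(sites, {"TF1": 2.0}, samples, seed=5,
                                   distal_rate=5.0)
        path = tmp_path / "frags.bed"
        skio.write_fragments_bed(frags, path)
        back = skio.read_fragments_bed(path)
        pd.testing.assert_frame_equal(
            frags[["chrom", "start", "end", "sample"]].reset_index(drop=True), back
        )

    def test_central_density_scales_with_effect(self):
        """With effect f at purity 1, the central open-fragment count is f
        times the null expectation (checked by direct counting)."""
        rng = np.random.default_rng(0)
        sites = pd.DataFrame(
            {"tf": "TF1", "chrom": "chr1",
             "center": np.arange(400) * 20_000 + 10_000,
             "strand": "+"}
        )
        samples = pd.DataFrame(
            [{"sample": "t", "purity": 1.0, "is_normal": False},
             {"sample": "n", "purity": 0.0, "is_normal": True}]
        )
        frags = simulate_fragments(sites, {"TF1": 2.0}, samples, seed=6,
                                   distal_rate=0.0)
        frags = frags[frags.tf == "TF1"]
        size = frags.end - frags.start
        mid = (frags.start + frags.end) / 2
        centres = sites.center.to_numpy()
        idx = np.searchsorted(centres, mid)
        d = np.minimum(
            np.abs(centres[np.clip(idx, 0, len(centres) - 1)] - mid),
            np.abs(centres[np.clip(idx - 1, 0, len(centres) - 1)] - mid),
        )
        central = (d < 100) & (size <= 100)
        n_t = (central & (frags["sample"] == "t")).sum()
        n_n = (central & (frags["sample"] == "n")).sum()
        # expected ratio: (background_central + 2*central_rate)/(bg + central)
        # background contributes little inside +/-100bp: ~30*0.06*0.6 open
        ratio = n_t / n_n
        assert 1.75 < ratio < 2.15


class TestMutationCatalogue:
    def test_single_signature_lln(self):
        S = synthetic_signatures(k=3, seed=1)
        cat = simulate_mutation_catalogue(S, [1.0, 0.0, 0.0], 100_000, seed=1)
        s0 = S.iloc[0].to_numpy()
        cos = cat @ s0 / (np.linalg.norm(cat) * np.linalg.norm(s0))
        assert cos >= 0.99

    def test_empty_catalogue(self):
        S = synthetic_signatures(k=2, seed=2)
        assert simulate_mutation_catalogue(S, [0.5, 0.5], 0, seed=1).sum() == 0

    def test_orthogonal_mixture_splits_mass(self):
        S = synthetic_signatures(k=2, seed=3)
        sup0 = S.iloc[0].to_numpy() > 0
        sup1 = S.iloc[1].to_numpy() > 0
        overlap = sup0 & sup1
        cat = simulate_mutation_catalogue(S, [0.5, 0.5], 50_000, seed=4)
        m0 = cat[sup0 & ~overlap].sum()
        m1 = cat[sup1 & ~overlap].sum()
        frac = m0 / (m0 + m1)
        expect = S.iloc[0][sup0 & ~overlap].sum() / (
            S.iloc[0][sup0 & ~overlap].sum() + S.iloc[1][sup1 & ~overlap].sum()
        )
        assert abs(frac - expect) < 0.01

    def test_bad_exposures_rejected(self):
        S = synthetic_signatures(k=2, seed=5)
        with pytest.raises(ConfigError):
            simulate_mutation_catalogue(S, [0.7, 0.4], 100, seed=1)

    def test_channel_conventions(self):
        assert len(CHANNELS) == 96
        assert len(TRINUC32) == 32
        assert abs(genome_trinuc_content().sum() - 1.0) < 1e-12


class TestIORoundTrips:
    def test_allele_counts_roundtrip(self, tmp_path, small_cohort):
        _, samples, _ = small_cohort
        sites = make_snv_sites(20, seed=6)
        ac = simulate_allele_counts(samples.head(2), sites, depth=20, seed=6)
        path = tmp_path / "ac.tsv"
        skio.write_allele_counts(ac, path)
        back = skio.read_allele_counts(path)
        for col in ("chrom", "pos", "sample", "ref_count", "alt_count",
                    "multiplicity", "copy_number", "clonal"):
            assert list(back[col]) == list(ac[col])

    def test_bins_roundtrip(self, tmp_path, small_cohort):
        _, samples, truth = small_cohort
        bins, _ = simulate_lowpass_bins(truth, samples.head(1), noise_sd=0.05)
        path = tmp_path / "bins.bed"
        s = samples["sample"].iloc[0]
        skio.write_bins_bed(bins, path, sample=s)
        back = skio.read_bins_bed(path, sample=s)
        pd.testing.assert_frame_equal(
            bins.reset_index(drop=True), back, check_dtype=False
        )

    def test_config_roundtrip(self, tmp_path):
        cfg = CohortConfig(n_patients=3, purity_range=(0.2, 0.8), seed=9)
        path = tmp_path / "config.yaml"
        skio.write_config(cfg, path)
        assert skio.read_config(path) == cfg

    def test_peaks_roundtrip(self, tmp_path, small_cohort):
        _, samples, truth = small_cohort
        counts, _, _ = simulate_peak_counts(truth)
        skio.write_peaks(truth.peaks, counts, tmp_path / "peaks")
        bed, back = skio.read_peaks(tmp_path / "peaks")
        assert list(bed.peak_id) == list(truth.peaks.peak_id)
        assert np.array_equal(back.to_numpy(), counts.to_numpy())
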