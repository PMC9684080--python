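"""SCAA pipeline: cut sites, peak merging, normalization, count tests,
recurrence and subclonality rules."""

import numpy as np
import pandas as pd
import pytest

from scaakit import scaa


class TestShiftCutSites:
    def test_shift_offsets(self):
        frags = pd.DataFrame(
            {"chrom": ["chr1"], "start": [100], "end": [200], "sample": ["s"]}
        )
        track = scaa.shift_cut_sites(frags)
        assert sorted(track.sites.pos) == [96, 205]  # -4 forward, +5 reverse

    def test_mid_size_fragment_dropped(self):
        frags = pd.DataFrame(
            {"chrom": ["chr1"] * 3, "start": [0, 0, 0], "end": [80, 150, 300],
             "sample": ["s"] * 3}
        )
        track = scaa.shift_cut_sites(frags)
        # sizes: 80 -> nucleosome-free, 150 -> dropped, 300 -> nucleosome
        assert len(track.sites) == 4
        assert set(track.sites.size_class) == {"nucleosome_free", "nucleosome"}

    def test_empty_input(self):
        frags = pd.DataFrame(columns=["chrom", "start", "end", "sample"])
        assert len(scaa.shift_cut_sites(frags).sites) == 0

    def test_negative_positions_clipped(self):
        frags = pd.DataFrame(
            {"chrom": ["chr1"], "start": [2], "end": [90], "sample": ["s"]}
        )
        track = scaa.shift_cut_sites(frags)
        assert track.n_clipped == 1
        assert (track.sites.pos >= 0).all()


def _calls(intervals, q=1e-5, enrichment=10.0):
    return pd.DataFrame(
        [{"chrom": "chr1", "start": s, "end": e,
          "q": qq, "enrichment": enrichment}
         for (s, e), qq in zip(intervals, np.atleast_1d(q).repeat(
             len(intervals)) if np.ndim(q) == 0 else q)]
    )


class TestFilterAndMergePeaks:
    def test_identical_lists_merge_to_one(self):
        calls = {r: _calls([(100, 200)]) for r in "ABC"}
        out = scaa.filter_and_merge_peaks(calls)
        assert len(out) == 1
        assert out.support.iloc[0] == 3
        assert bool(out.retained.iloc[0])

    def test_two_region_support_dropped(self):
        calls = {"A": _calls([(100, 200)]), "B": _calls([(100, 200)])}
        out = scaa.filter_and_merge_peaks(calls)
        assert not bool(out.retained.iloc[0])

    def test_normal_panel_rescues(self):
        calls = {"A": _calls([(100, 200)])}
        out = scaa.filter_and_merge_peaks(calls, normal_calls=_calls([(150, 250)]))
        assert bool(out.retained.iloc[0])

    def test_quality_filters(self):
        bad_q = _calls([(0, 100)], q=0.5)
        bad_e = _calls([(200, 300)], enrichment=1.0)
        good = _calls([(400, 500)])
        merged = scaa.filter_and_merge_peaks(
            {"A": pd.concat([bad_q, bad_e, good]), "B": good, "C": good}
        )
        assert len(merged) == 1
        assert merged.start.iloc[0] == 400

    def test_chain_keeps_most_significant_representative(self):
        """A-B-C overlap chain where only B overlaps both: the most
        significant peak absorbs its own overlaps; the chain's far end
        survives separately (iterative merging, not transitive clustering)."""
        a = _calls([(0, 100)], q=1e-9)
        b = _calls([(90, 190)], q=1e-5)
        c = _calls([(180, 280)], q=1e-4)
        out = scaa.filter_and_merge_peaks({"A": a, "B": b, "C": c},
                                          min_region_support=1)
        assert len(out) == 2
        assert list(out.start) == [0, 180]

    def test_matches_bruteforce_on_random_intervals(self, rng):
        """Independent O(n^2) re-implementation of iterative merging."""
        for _ in range(10):
            n = 50
            starts = rng.integers(0, 5000, n)
            ends = starts + rng.integers(50, 400, n)
            qs = rng.uniform(1e-12, 1e-4, n)
            df = pd.DataFrame(
                {"chrom": "chr1", "start": starts, "end": ends,
                 "q": qs, "enrichment": 10.0}
            )
            out = scaa.filter_and_merge_peaks({"A": df}, min_region_support=1)

            # oracle: repeatedly take the most significant remaining peak
            remaining = df.sort_values("q").reset_index(drop=True)
            reps = []
            while len(remaining):
                top = remaining.iloc[0]
                ov = (remaining.start < top.end) & (remaining.end > top.start)
                reps.append((top.start, top.end))
                remaining = remaining[~ov]
            assert sorted(zip(out.start, out.end)) == sorted(reps)

    def test_output_non_overlapping(self, rng):
        starts = rng.integers(0, 2000, 80)
        df = pd.DataFrame(
            {"chrom": "chr1", "start": starts, "end": starts + 150,
             "q": rng.uniform(1e-9, 1e-4, 80), "enrichment": 8.0}
        )
        out = scaa.filter_and_merge_peaks({"A": df}, min_region_support=1)
        out = out.sort_values("start")
        assert (out.start.to_numpy()[1:] >= out.end.to_numpy()[:-1]).all()


class TestCNAdjust:
    @pytest.mark.parametrize(
        "rho,pi,psi,expected",
        [(0.0, 5, 2, 1.0), (0.8, 3, 3, 1.0), (0.5, 4, 2, 1.5), (1.0, 4, 2, 2.0)],
    )
    def test_values(self, rho, pi, psi, expected):
        assert scaa.cn_adjust_factor(rho, pi, psi) == pytest.approx(expected)

    def test_degenerate_raises(self):
        with pytest.raises(ValueError):
            scaa.cn_adjust_factor(1.0, 2, 0)

    def test_pooled_weighted_average(self):
        f = scaa.pooled_cn_adjust([0.5, 0.0], [4, 4], [2, 2], [3, 1])
        assert f == pytest.approx((1.5 * 3 + 1.0 * 1) / 4)


class TestSizeFactors:
    def test_identical_columns_unit_factors(self, rng):
        col = rng.poisson(40, 300)
        counts = pd.DataFrame({f"s{i}": col for i in range(5)})
        f = scaa.size_factors(counts)
        assert np.allclose(f, 1.0)

    def test_doubled_column(self, rng):
        col = rng.poisson(40, 500)
        data = {f"s{i}": col for i in range(20)}
        data["dbl"] = 2 * col
        f = scaa.size_factors(pd.DataFrame(data))
        assert f["dbl"] / f["s0"] == pytest.approx(2.0, rel=0.02)

    def test_geometric_mean_one(self, rng):
        counts = pd.DataFrame(rng.poisson(30, (200, 6)),
                              columns=[f"s{i}" for i in range(6)])
        f = scaa.size_factors(counts)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_sample_named(self):
        counts = pd.DataFrame({"good": [1, 2], "empty": [0, 0]})
        with pytest.raises(ValueError, match="empty"):
            scaa.size_factors(counts)


class TestRecurrence:
    def _calls(self, rows):
        return pd.DataFrame(rows, columns=["patient", "peak_id", "lfc", "p",
                                           "direction", "significant"])

    def test_thirty_percent_recurrent(self):
        rows = [(f"P{i}", "pk1", 1.0, 0.001, "gain", True) for i in range(8)]
        rec = scaa.recurrence(self._calls(rows), n_cases=26)
        assert bool(rec.recurrent.iloc[0])  # 8 >= ceil(0.2*26)=6

    def test_two_of_26_not_recurrent(self):
        rows = [(f"P{i}", "pk1", 1.0, 0.001, "gain", True) for i in range(2)]
        rec = scaa.recurrence(self._calls(rows), n_cases=26)
        assert not bool(rec.recurrent.iloc[0])

    def test_four_of_26_recurrent(self):
        rows = [(f"P{i}", "pk1", -1.0, 0.005, "loss", True) for i in range(4)]
        rec = scaa.recurrence(self._calls(rows), n_cases=26)
        # the default 20% rule gives ceil(0.2 * 26) = 6 cases; a literal
        # 4-of-26 threshold is reachable by passing min_frac = 4/26
        rec2 = scaa.recurrence(self._calls(rows), n_cases=26, min_frac=4 / 26)
        assert bool(rec2.recurrent.iloc[0])
        assert not bool(rec.recurrent.iloc[0])

    def test_opposite_directions_not_pooled(self):
        rows = [(f"P{i}", "pk1", 1.0, 0.001, "gain", True) for i in range(3)]
        rows += [(f"P{i+3}", "pk1", -1.0, 0.001, "loss", True) for i in range(3)]
        rec = scaa.recurrence(self._calls(rows), n_cases=10, min_frac=0.5)
        assert not rec.recurrent.any()

    def test_empty(self):
        rec = scaa.recurrence(self._calls([]), n_cases=26)
        assert rec.empty


class TestSubclonality:
    def test_single_region_untestable(self, rng):
        y = rng.poisson(50, 6)
        res = scaa.test_subclonality(y, np.full(6, 0.7), np.repeat("A", 6),
                                     np.ones(6), 0.05)
        assert res["verdict"] == "untestable"

    def test_planted_subclonal_detected_with_pattern(self, rng):
        region = np.repeat(list("ABCD"), 5)
        rho = rng.uniform(0.5, 0.9, 20)
        sf = rng.lognormal(0, 0.2, 20)
        eff = np.where(np.isin(region, ["A", "B"]), 3.0, 1.0)
        mu = sf * 50 * eff
        y = rng.negative_binomial(1 / 0.05, 1 / (1 + 0.05 * mu))
        res = scaa.test_subclonality(y, rho, region, sf, 0.05)
        df = pd.DataFrame([{**res, "event_id": "e", "bulk_direction": "gain",
                            "peak_within_500bp": True}])
        out = scaa.subclonality_calls(df)
        assert out.final_verdict.iloc[0] == "subclonal"
        assert out.region_pattern.iloc[0] == "A,B"

    def test_gain_without_nearby_peak_filtered(self, rng):
        region = np.repeat(list("AB"), 5)
        eff = np.where(region == "A", 4.0, 1.0)
        mu = 50 * eff
        y = rng.negative_binomial(1 / 0.05, 1 / (1 + 0.05 * mu))
        res = scaa.test_subclonality(y, np.full(10, 0.7), region, np.ones(10), 0.05)
        df = pd.DataFrame([{**res, "event_id": "e", "bulk_direction": "gain",
                            "peak_within_500bp": False}])
        out = scaa.subclonality_calls(df)
        assert out.final_verdict.iloc[0] == "clonal"


class TestExpressionFilters:
    def test_filter_expressed_genes_rules(self, rng):
        n = 40
        cols = [f"s{i}" for i in range(n)]
        purity = pd.Series(rng.uniform(0.2, 0.9, n), index=cols)
        patient = pd.Series(np.repeat(["P1", "P2"], n // 2), index=cols)
        is_tum = pd.Series(True, index=cols)
        silent = np.zeros(n)
        flat = rng.uniform(20, 40, n)
        rare = np.r_[np.full(1, 15.0), np.zeros(n - 1)]
        neg = 60 * (1 - purity.to_numpy()) + rng.normal(0, 0.5, n)
        tpm = pd.DataFrame(
            [silent, flat, rare, neg],
            index=["silent", "flat", "rare", "contamination"],
            columns=cols,
        )
        kept = scaa.filter_expressed_genes(tpm, is_tum, purity, patient)
        assert "flat" in kept
        assert "silent" not in kept  # 0 TPM everywhere
        assert "rare" not in kept  # expressed in < 5% of samples
        assert "contamination" not in kept  # negative purity slope

    def test_expression_association_power_and_skip(self, rng):
        genes = [f"g{i}" for i in range(30)]
        cols = [f"s{i}" for i in range(24)]
        pat = pd.Series(np.repeat([f"P{i}" for i in range(8)], 3), index=cols)
        altered = {f"P{i}" for i in range(4)}
        lib = rng.lognormal(0, 0.1, 24)
        rows = []
        for g in genes:
            base = rng.lognormal(np.log(100), 0.3)
            shift = 2.5 if g == "g0" else 1.0
            mu = lib * base * np.array(
                [shift if pat[c] in altered else 1.0 for c in cols]
            )
            rows.append(rng.negative_binomial(1 / 0.05, 1 / (1 + 0.05 * mu)))
        expr = pd.DataFrame(rows, index=genes, columns=cols)
        peak_gene = pd.DataFrame(
            {"peak_id": ["pk0", "pk_nogene"], "gene": ["g0", "absent_gene"]}
        )
        out = scaa.expression_association(
            expr, pat, peak_gene, {"pk0": altered, "pk_nogene": altered},
            {"pk0": "gain"}, {"pk0": True}, normal_samples=set(),
        )
        assert list(out.peak_id) == ["pk0"]  # unannotated gene skipped
        assert out.p.iloc[0] < 0.01
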