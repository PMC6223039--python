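"""Peak counting, expectation, goodness of fit, overlap and annotation."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nucarch.chromenrich import (
    GenomeTable,
    annotate_peaks,
    chrom_enrichment,
    count_peaks_per_chrom,
    differential_overlap,
    expected_counts,
    goodness_of_fit,
    mouse_genome,
    read_bed,
    validate_peaks,
    write_bed,
)


def _peaks(records):
    return pd.DataFrame(records, columns=["chrom", "start", "end"])


TWO_CHROM = GenomeTable.from_dict({"chr1": 2_000_000, "chr2": 1_000_000})


class TestCounting:
    def test_empty_table_gives_all_zero(self):
        obs = count_peaks_per_chrom(_peaks([]), TWO_CHROM)
        assert (obs == 0).all()

    def test_simple_tally(self):
        peaks = _peaks(
            [("chr1", i * 10, i * 10 + 5) for i in range(5)]
            + [("chr2", i * 10, i * 10 + 5) for i in range(3)]
        )
        obs = count_peaks_per_chrom(peaks, TWO_CHROM)
        assert obs.to_dict() == {"chr1": 5, "chr2": 3}

    def test_unknown_chromosome_listed_in_error(self):
        peaks = _peaks([("chrM", 0, 10)])
        with pytest.raises(ValueError, match="chrM"):
            count_peaks_per_chrom(peaks, TWO_CHROM)

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(0)
        genome = mouse_genome()
        names = genome.names
        for _ in range(10):
            chroms = rng.choice(names, size=50)
            peaks = _peaks([(c, 0, 10) for c in chroms])
            obs = count_peaks_per_chrom(peaks, genome)
            tally = {n: 0 for n in names}
            for c in chroms:
                tally[c] += 1
            assert obs.to_dict() == tally


class TestExpectedCounts:
    def test_size_proportional_split(self):
        exp = expected_counts(30, TWO_CHROM.weights("size"))
        assert exp.to_dict() == {"chr1": 20.0, "chr2": 10.0}

    def test_gene_count_weights(self):
        g = GenomeTable.from_dict(
            {"chr1": 10, "chr2": 10}, gene_counts={"chr1": 100, "chr2": 300}
        )
        exp = expected_counts(40, g.weights("genes"))
        assert exp.to_dict() == {"chr1": 10.0, "chr2": 30.0}

    def test_uniform_weights_split_evenly(self):
        w = pd.Series({f"c{i}": 1.0 for i in range(4)})
        assert (expected_counts(10, w) == 2.5).all()

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError):
            expected_counts(10, pd.Series({"a": 1.0, "b": 0.0}))

    @settings(deadline=None, max_examples=50)
    @given(
        total=st.integers(0, 10_000),
        weights=st.lists(st.floats(0.01, 1e6), min_size=1, max_size=30),
    )
    def test_expectation_sums_exactly_to_total(self, total, weights):
        w = pd.Series(weights, index=[f"c{i}" for i in range(len(weights))])
        exp = expected_counts(total, w)
        assert exp.sum() == pytest.approx(total, rel=1e-12, abs=1e-9)


class TestGoodnessOfFit:
    def test_perfect_fit_has_zero_statistic_and_p_one(self):
        obs = pd.Series({"a": 10, "b": 20})
        res = goodness_of_fit(obs, obs.astype(float), method="chi-square")
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_textbook_two_cell_statistic(self):
        obs = pd.Series({"a": 25, "b": 5})
        exp = pd.Series({"a": 15.0, "b": 15.0})
        res = goodness_of_fit(obs, exp, method="chi-square")
        assert res.statistic == pytest.approx(100 / 15 + 100 / 15)
        assert res.df == 1

    def test_monte_carlo_agrees_with_chi_square_at_large_expected(self):
        rng = np.random.default_rng(1)
        w = pd.Series({"a": 1.0, "b": 2.0, "c": 1.5})
        obs = pd.Series(
            rng.multinomial(1000, (w / w.sum()).to_numpy()), index=w.index
        )
        exp = expected_counts(1000, w)
        chisq = goodness_of_fit(obs, exp, method="chi-square")
        n_sim = 10_000
        mc = goodness_of_fit(obs, exp, method="monte-carlo", n_sim=n_sim, seed=0)
        se = np.sqrt(chisq.p_value * (1 - chisq.p_value) / n_sim)
        assert abs(mc.p_value - chisq.p_value) <= 2 * se + 1e-4

    def test_auto_switches_to_monte_carlo_below_expected_five(self):
        obs = pd.Series({"a": 3, "b": 5})
        exp = expected_counts(8, pd.Series({"a": 1.0, "b": 1.0}))
        assert goodness_of_fit(obs, exp, seed=0).method == "monte-carlo"
        obs2 = pd.Series({"a": 30, "b": 50})
        exp2 = expected_counts(80, pd.Series({"a": 1.0, "b": 1.0}))
        assert goodness_of_fit(obs2, exp2).method == "chi-square"

    def test_zero_expectation_with_observed_rejected(self):
        obs = pd.Series({"a": 3, "b": 5})
        exp = pd.Series({"a": 0.0, "b": 8.0})
        with pytest.raises(ValueError):
            goodness_of_fit(obs, exp)

    def test_total_mismatch_rejected(self):
        with pytest.raises(ValueError, match="totals"):
            goodness_of_fit(
                pd.Series({"a": 10}), pd.Series({"a": 12.0}), method="chi-square"
            )


class TestDifferentialOverlap:
    def _with_direction(self, records):
        df = pd.DataFrame(records, columns=["chrom", "start", "end", "direction"])
        return df

    def test_identical_tables_fully_overlap_and_agree(self):
        a = self._with_direction(
            [("chr1", 100, 200, "gain"), ("chr1", 500, 700, "loss")]
        )
        res = differential_overlap(a, a.copy())
        assert (res.n_overlap, res.n_same_direction) == (2, 2)

    def test_disjoint_tables_share_nothing(self):
        a = self._with_direction([("chr1", 100, 200, "gain")])
        b = self._with_direction([("chr1", 300, 400, "gain")])
        res = differential_overlap(a, b)
        assert (res.n_overlap, res.n_same_direction) == (0, 0)

    def test_toy_tables_match_all_pairs_brute_force(self):
        a = self._with_direction(
            [
                ("chr1", 100, 200, "gain"),
                ("chr1", 900, 1000, "loss"),
                ("chr2", 50, 150, "gain"),
                ("chr3", 10, 20, "loss"),
            ]
        )
        b = self._with_direction(
            [
                ("chr1", 150, 250, "gain"),   # overlaps a0, same direction
                ("chr2", 100, 120, "loss"),   # overlaps a2, opposite
                ("chr3", 100, 200, "gain"),   # no overlap
            ]
        )
        res = differential_overlap(a, b)
        assert (res.n_overlap, res.n_same_direction) == (2, 1)
        # brute force oracle over all pairs
        n_ov = n_same = 0
        for _, ra in a.iterrows():
            partners = [
                rb
                for _, rb in b.iterrows()
                if rb["chrom"] == ra["chrom"]
                and min(ra["end"], rb["end"]) - max(ra["start"], rb["start"]) >= 1
            ]
            if partners:
                n_ov += 1
                first = sorted(partners, key=lambda r: (r["start"], r["end"]))[0]
                n_same += first["direction"] == ra["direction"]
        assert (res.n_overlap, res.n_same_direction) == (n_ov, n_same)

    def test_random_tables_match_brute_force(self):
        rng = np.random.default_rng(7)
        for trial in range(10):
            def rand_table(n):
                starts = rng.integers(0, 2000, size=n)
                return pd.DataFrame(
                    {
                        "chrom": rng.choice(["chr1", "chr2"], size=n),
                        "start": starts,
                        "end": starts + rng.integers(20, 200, size=n),
                        "direction": rng.choice(["gain", "loss"], size=n),
                    }
                )

            a, b = rand_table(15), rand_table(12)
            res = differential_overlap(a, b)
            a_s, b_s = validate_peaks(a), validate_peaks(b)
            n_ov = n_same = 0
            for _, ra in a_s.iterrows():
                partners = [
                    rb
                    for _, rb in b_s.iterrows()
                    if rb["chrom"] == ra["chrom"]
                    and min(ra["end"], rb["end"]) - max(ra["start"], rb["start"]) >= 1
                ]
                if partners:
                    n_ov += 1
                    n_same += partners[0]["direction"] == ra["direction"]
            assert (res.n_overlap, res.n_same_direction) == (n_ov, n_same)

    def test_missing_direction_column_rejected(self):
        a = _peaks([("chr1", 0, 10)])
        with pytest.raises(ValueError, match="direction"):
            differential_overlap(a, a)

    def test_overlap_bounded_by_table_sizes(self):
        a = self._with_direction([("chr1", 0, 100, "gain")] )
        b = self._with_direction(
            [("chr1", 10, 20, "gain"), ("chr1", 30, 40, "loss")]
        )
        res = differential_overlap(a, b)
        assert res.n_same_direction <= res.n_overlap <= min(res.n_a, res.n_b)


class TestAnnotatePeaks:
    GENES = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr2"],
            "txStart": [10_000, 50_000, 20_000],
            "txEnd": [20_000, 60_000, 30_000],
            "strand": ["+", "-", "+"],
        }
    )

    def test_midpoint_at_plus_strand_txstart_is_tss(self):
        peaks = _peaks([("chr1", 9_950, 10_050)])  # midpoint 10_000
        cats, _ = annotate_peaks(peaks, self.GENES)
        assert cats.iloc[0] == "tss"

    def test_midpoint_upstream_of_plus_strand_tss_is_promoter(self):
        peaks = _peaks([("chr1", 9_450, 9_550)])  # midpoint 9_500
        cats, _ = annotate_peaks(peaks, self.GENES)
        assert cats.iloc[0] == "promoter"

    def test_hand_worked_six_peak_fixture(self):
        peaks = _peaks(
            [
                ("chr1", 9_950, 10_050),    # tss (+ strand, mid 10_000)
                ("chr1", 9_400, 9_600),     # promoter (mid 9_500)
                ("chr1", 15_000, 15_100),   # gene body
                ("chr1", 60_200, 60_400),   # promoter of - strand gene (mid 60_300)
                ("chr2", 25_000, 25_100),   # gene body
                ("chr2", 500_000, 500_100), # intergenic
            ]
        )
        cats, counts = annotate_peaks(peaks, self.GENES)
        assert list(cats) == [
            "tss", "promoter", "gene_body", "promoter", "gene_body", "intergenic"
        ]
        assert counts == {
            "tss": 1, "promoter": 2, "gene_body": 2, "intergenic": 1
        }
        assert sum(counts.values()) == len(peaks)

    def test_tss_takes_precedence_over_gene_body(self):
        peaks = _peaks([("chr1", 10_000, 10_100)])  # mid 10_050, inside gene too
        cats, _ = annotate_peaks(peaks, self.GENES)
        assert cats.iloc[0] == "tss"


class TestBedIO:
    def test_round_trip_preserves_coordinates(self, tmp_path):
        df = _peaks([("chr1", 100, 200), ("chr2", 5, 50)])
        path = tmp_path / "peaks.bed"
        write_bed(df, path)
        back = read_bed(path)
        pd.testing.assert_frame_equal(back, validate_peaks(df))

    def test_direction_derived_from_score_sign(self):
        buf = io.StringIO("chr1\t10\t20\tp1\t2.5\nchr1\t30\t40\tp2\t-1.0\n")
        df = read_bed(buf, direction=True)
        assert list(df["direction"]) == ["gain", "loss"]

    def test_invalid_intervals_rejected(self):
        with pytest.raises(ValueError):
            validate_peaks(_peaks([("chr1", 200, 100)]))


class TestChromEnrichment:
    def test_expected_sum_matches_observed_sum(self):
        genome = mouse_genome()
        from nucarch.synthetic import sample_peak_table

        peaks = sample_peak_table(500, genome.sizes, seed=3)
        res = chrom_enrichment(peaks, genome, method="chi-square")
        assert res.table["expected"].sum() == pytest.approx(
            res.table["observed"].sum()
        )
        assert (res.table["enrichment_score"] >= 0).all()

    def test_fold_recovery_within_sampling_error(self):
        from nucarch.synthetic import sample_peak_table

        genome = mouse_genome()
        fold = 4.0
        peaks = sample_peak_table(
            2000, genome.sizes, fold_map={"chr7": fold}, seed=5
        )
        res = chrom_enrichment(peaks, genome, method="chi-square")
        # Renormalisation deflates the nominal fold: score f' = f / E[w].
        w = genome.weights("size")
        p = w / w.sum()
        deflate = 1 + (fold - 1) * p["chr7"]
        target = fold / deflate
        got = res.table.loc["chr7", "enrichment_score"]
        exp7 = res.table.loc["chr7", "expected"]
        assert got == pytest.approx(target, abs=3 * np.sqrt(target / exp7))
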