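import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import twocchip as tc
from twocchip.qc import qc_report

from oracle import quadratic_overlap_counts, rank_formula_spearman
from test_quantify import make_table


def make_track(intervals, values):
    df = pd.DataFrame(
        [(c, s, e) for c, s, e in intervals], columns=["chrom", "start", "end"],
        index=pd.Index([f"p{i:03d}" for i in range(len(intervals))],
                       name="probe_id"))
    df["value"] = list(values)
    return tc.NormalizedTrack(df)


class TestRunQC:
    def test_all_product_reads(self):
        table = make_table({"lib": {"A": 7, "B": 3}})
        q = tc.run_qc(table)
        assert q.product_fraction == 1.0
        assert q.off_diagonal_fraction_all == 0.0
        assert q.off_diagonal_fraction_unexpected == 0.0

    def test_off_diagonal_share_of_unexpected(self):
        table = make_table({"lib": {"A": 90}},
                           categories={("off_diagonal", "lib"): 9,
                                       ("unmapped", "__run__"): 1})
        q = tc.run_qc(table)
        assert q.product_fraction == pytest.approx(0.90)
        assert q.off_diagonal_fraction_unexpected == pytest.approx(0.9)
        assert q.off_diagonal_fraction_all == pytest.approx(0.09)

    def test_simulation_off_diagonal_estimate_within_binomial_error(
            self, reference, panel):
        n, rate = 20_000, 0.05
        prof = tc.flat_profile(panel)
        reads, _ = tc.simulate_library(reference, prof, "BC01", n,
                                       off_diagonal_rate=rate, seed=17)
        table = tc.tabulate(
            tc.split_by_barcode(tc.two_step_assign(reads, reference)), reference)
        q = tc.run_qc(table)
        sigma = np.sqrt(rate * (1 - rate) / n)
        assert q.off_diagonal_fraction_all == pytest.approx(rate, abs=3 * sigma)

    def test_report_renders(self):
        table = make_table({"lib": {"A": 5}})
        text = qc_report(tc.run_qc(table))
        assert "on-diagonal" in text and "off-diagonal" in text


class TestWindowAverage:
    track = staticmethod(lambda: make_track(
        [("chr1", 100, 200), ("chr1", 300, 400), ("chr1", 2000, 2100)],
        [1.0, 3.0, 9.0]))

    def test_single_probe_window(self):
        assert tc.window_average(self.track(), center=150, width=100) == 1.0

    def test_two_probe_mean(self):
        assert tc.window_average(self.track(), center=250, width=1000) == 2.0

    def test_empty_window_is_missing(self):
        assert tc.window_average(self.track(), center=10_000, width=500) is None

    def test_midpoint_versus_overlap_membership(self):
        t = self.track()
        # window [150, 350): probe 1 midpoint 150 in, probe 2 midpoint 350 out
        assert tc.window_average(t, center=250, width=200) == 1.0
        # but probe 2's interval [300,400) overlaps the window
        assert tc.window_average(t, center=250, width=200,
                                 membership="overlap") == 2.0


class TestSpearman:
    def test_monotone_agreement_and_reversal(self):
        x = [1, 2, 5, 9]
        assert tc.spearman(x, [10, 20, 30, 40]) == pytest.approx(1.0)
        assert tc.spearman(x, [40, 30, 20, 10]) == pytest.approx(-1.0)

    def test_ties_match_rank_formula(self):
        x, y = [1, 2, 2, 3], [1, 2, 3, 4]
        assert tc.spearman(x, y) == pytest.approx(rank_formula_spearman(x, y))

    def test_random_data_matches_rank_formula(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 10, 50).astype(float)
        y = x + rng.normal(0, 2, 50)
        assert tc.spearman(x, y) == pytest.approx(rank_formula_spearman(x, y))

    def test_zero_pairs_dropped_on_request(self):
        x = [0.0, 1, 2, 3, 4]
        y = [99.0, 1, 2, 3, 4]
        with_zero = tc.spearman(x, y)
        without = tc.spearman(x, y, drop_zeros=True)
        assert without == pytest.approx(1.0)
        assert with_zero < 1.0

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="3"):
            tc.spearman([0, 0, 1, 2], [1, 2, 3, 0], drop_zeros=True)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 1000))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        rho = tc.spearman(x, y)
        assert tc.spearman(np.exp(x), y) == pytest.approx(rho)
        assert tc.spearman(x, 3 * y + 2) == pytest.approx(rho)


class TestChipseqOverlap:
    def test_exact_cover_counts_one(self):
        t = make_track([("chr1", 100, 200), ("chr1", 300, 400)], [1, 1])
        reads = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [200]})
        counts = tc.chipseq_overlap_score(t, reads)
        assert list(counts) == [1, 0]

    def test_abutting_read_does_not_overlap(self):
        t = make_track([("chr1", 100, 200)], [1])
        reads = pd.DataFrame({"chrom": ["chr1", "chr1"],
                              "start": [200, 50], "end": [250, 100]})
        assert list(tc.chipseq_overlap_score(t, reads)) == [0]

    def test_matches_quadratic_oracle_on_random_intervals(self):
        rng = np.random.default_rng(8)
        probes = [("chr%d" % rng.integers(1, 3), int(s), int(s) + int(rng.integers(20, 80)))
                  for s in rng.integers(0, 5000, 60)]
        reads = [("chr%d" % rng.integers(1, 3), int(s), int(s) + int(rng.integers(10, 200)))
                 for s in rng.integers(0, 5000, 400)]
        t = make_track(probes, np.ones(len(probes)))
        reads_df = pd.DataFrame(reads, columns=["chrom", "start", "end"])
        fast = list(tc.chipseq_overlap_score(t, reads_df))
        slow = quadratic_overlap_counts(probes, reads)
        assert fast == slow


class TestAssessLinearity:
    def test_exact_power_law_returns_full_range(self):
        amounts = [0.1, 0.3, 1.0, 3.0, 10.0]
        series = tc.TitrationSeries(amounts, amounts)  # slope exactly 1
        res = tc.assess_linearity(series)
        assert (res.lo_ng, res.hi_ng) == (0.1, 10.0)
        assert res.r2 == pytest.approx(1.0)
        assert res.slope == pytest.approx(1.0)

    def test_saturated_points_excluded(self):
        amounts = [0.1, 0.3, 1.0, 3.0, 10.0]
        yields = [0.1, 0.3, 1.0, 1.0, 1.0]  # flat above 1 ng
        res = tc.assess_linearity(tc.TitrationSeries(amounts, yields))
        assert res.hi_ng == 1.0 and res.lo_ng == 0.1

    def test_no_linear_range_reported_not_raised(self):
        res = tc.assess_linearity(tc.TitrationSeries([1, 2, 3], [5.0, 5.0, 5.0]))
        assert not res.has_linear_range
        assert res.lo_ng is None

    def test_simulated_breakpoint_recovered_within_one_step(self):
        amounts = [0.016, 0.05, 0.16, 0.5, 1.6, 5.0, 16.0]
        df = tc.simulate_titration(amounts, seed=2, noise_sigma=0.03,
                                   saturation_ng=1.6)
        res = tc.assess_linearity(tc.TitrationSeries.from_frame(df))
        assert res.has_linear_range
        assert res.hi_ng in (0.5, 1.6)  # within one titration step of 1.6


class TestReplicateCorrelation:
    def test_identical_and_scaled_tracks_give_r2_one(self):
        t = make_track([("c", i * 100, i * 100 + 50) for i in range(10)],
                       np.arange(10, dtype=float) + 1)
        t2 = make_track([("c", i * 100, i * 100 + 50) for i in range(10)],
                        2 * (np.arange(10, dtype=float) + 1))
        assert tc.replicate_correlation(t, t) == pytest.approx(1.0)
        assert tc.replicate_correlation(t, t2) == pytest.approx(1.0)

    def test_independent_noise_gives_near_zero_r2(self):
        rng = np.random.default_rng(12)
        iv = [("c", i * 10, i * 10 + 5) for i in range(200)]
        a = make_track(iv, rng.lognormal(0, 1, 200))
        b = make_track(iv, rng.lognormal(0, 1, 200))
        assert tc.replicate_correlation(a, b) < 0.05

    def test_too_few_shared_probes_rejected(self):
        a = make_track([("c", 0, 10), ("c", 20, 30)], [1, 2])
        with pytest.raises(ValueError, match="shared"):
            tc.replicate_correlation(a, a)
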