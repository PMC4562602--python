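"""dnapet_qc: classification, insert size, coverage, gap sizes, breakpoints."""

import itertools

import numpy as np
import pytest

from petforge import dnapet_qc, simdata
from petforge.core_io import AssemblyGap, LibraryProfile, ScaffoldRecord
from petforge.dnapet_qc import PetClass

from conftest import LIB_10K, LIB_17K, concordant_pair, make_pair
from oracles import per_base_stab_count, truth_table_pet_class


class TestClassify:
    def test_concordant_span_in_10k_range(self, lib_10k):
        p = concordant_pair("p", "s", 1000, 10_000)
        assert dnapet_qc.classify_pair(p, lib_10k) is PetClass.CPET

    def test_different_scaffolds(self, lib_10k):
        p = make_pair("p", "a", 0, "+", "b", 0, "+")
        assert dnapet_qc.classify_pair(p, lib_10k) is PetClass.DPET_DIFF_REF

    def test_span_beyond_17k_range(self, lib_17k):
        p = concordant_pair("p", "s", 0, 30_000)
        assert dnapet_qc.classify_pair(p, lib_17k) is PetClass.DPET_SAME_REF

    def test_opposite_strands_discordant(self, lib_10k):
        p = make_pair("p", "s", 0, "+", "s", 9_000, "-")
        assert dnapet_qc.classify_pair(p, lib_10k) is PetClass.DPET_SAME_REF

    def test_wrong_order_discordant(self, lib_10k):
        # tag1 downstream of tag2 on '+': violates 5'->3' ordering
        p = make_pair("p", "s", 9_000, "+", "s", 0, "+")
        assert dnapet_qc.classify_pair(p, lib_10k) is PetClass.DPET_SAME_REF

    @pytest.mark.parametrize("lib", [LIB_10K, LIB_17K],
                             ids=["IXT010", "IXT011"])
    def test_exhaustive_truth_table(self, lib):
        """All (ref, strand, order, span bucket) combos match the oracle."""
        spans = [
            100, lib.concordant_span_min - 1, lib.concordant_span_min,
            int(lib.expected_insert_mean), lib.concordant_span_max,
            lib.concordant_span_max + 1, 40_000,
        ]
        for refs, st1, st2, first, span in itertools.product(
                [("a", "a"), ("a", "b")], "+-", "+-", [1, 2], spans):
            lo, hi = 5_000, 5_000 + span - 27
            if hi <= lo:
                continue
            t1pos, t2pos = (lo, hi) if first == 1 else (hi, lo)
            p = make_pair("p", refs[0], t1pos, st1, refs[1], t2pos, st2)
            got = dnapet_qc.classify_pair(p, lib).value
            want = truth_table_pet_class(
                (refs[0], t1pos, t1pos + 27, st1),
                (refs[1], t2pos, t2pos + 27, st2),
                lib.concordant_span_min, lib.concordant_span_max)
            assert got == want

    def test_partition_property(self, lib_10k):
        _, truth = simdata.simulate_genome(1, chrom_len=200_000, n_fragments=4)
        pairs, _ = simdata.simulate_dnapet(
            truth, lib_10k, insert_sd=500, coverage=10, seed=2,
            chimera_rate=0.1)
        classes = dnapet_qc.classify_pairs(pairs, lib_10k)
        assert sum(len(v) for v in classes.values()) == len(pairs)

    def test_dedupe_collapses_identical_coordinates(self):
        a = concordant_pair("a", "s", 0, 9_600)
        b = concordant_pair("b", "s", 0, 9_600)
        c = concordant_pair("c", "s", 5, 9_600)
        assert len(dnapet_qc.dedupe_pairs([a, b, c])) == 2


class TestInsertSize:
    def test_constant_spans(self):
        cpets = [concordant_pair(i, "s", i * 10, 9_600) for i in range(40)]
        mean, sd = dnapet_qc.estimate_insert_size(cpets)
        assert mean == 9_600
        assert sd == 0

    def test_too_few_pairs_error(self):
        cpets = [concordant_pair(i, "s", i, 9_600) for i in range(10)]
        with pytest.raises(ValueError):
            dnapet_qc.estimate_insert_size(cpets)

    def test_normal_spans_within_sampling_error(self):
        rng = np.random.default_rng(0)
        n, mu, sigma = 10_000, 9_600, 500
        spans = rng.normal(mu, sigma, size=n).round().astype(int)
        cpets = [concordant_pair(i, "s", 0, int(sp))
                 for i, sp in enumerate(spans)]
        mean, sd = dnapet_qc.estimate_insert_size(cpets)
        assert abs(mean - mu) < 3 * sigma / np.sqrt(n)
        # 5%-trimmed sd of a normal is ~0.79 sigma
        assert 0.7 * sigma < sd < sigma


class TestCoverage:
    def test_no_pairs_all_zero(self):
        track = dnapet_qc.coverage_track([], "s", length=100_000)
        assert not track.counts.any()

    def test_single_fragment_per_base(self):
        p = concordant_pair("p", "s", 0, 10_000)
        cov = dnapet_qc.per_base_fragment_coverage([p], "s", length=15_000)
        assert (cov[:10_000] == 1).all()
        assert (cov[10_000:] == 0).all()

    def test_per_base_matches_stabbing_oracle(self):
        rng = np.random.default_rng(3)
        length = 5_000
        pairs = []
        for i in range(100):
            s = int(rng.integers(0, length - 600))
            pairs.append(concordant_pair(i, "s", s, int(rng.integers(100, 600))))
        cov = dnapet_qc.per_base_fragment_coverage(pairs, "s", length=length)
        ivs = [(p.fragment_interval()[1], p.fragment_interval()[2])
               for p in pairs]
        assert cov.tolist() == per_base_stab_count(ivs, length)

    def test_window_mode_counts_overlaps(self):
        p = concordant_pair("p", "s", 25_000, 10_000)  # covers [25k, 35k)
        track = dnapet_qc.coverage_track([p], "s", window_size=20_000,
                                         length=100_000)
        # windows start every 5k; those overlapping [25k,35k) are starts 10k..30k
        starts = np.arange(len(track.counts)) * track.step
        expect = ((starts < 35_000) & (starts + 20_000 > 25_000)).astype(int)
        assert track.counts.tolist() == expect.tolist()

    def test_window_larger_than_scaffold_single_window(self):
        track = dnapet_qc.coverage_track([], "s", window_size=20_000,
                                         length=4_000)
        assert len(track.counts) == 1


class TestCorrelation:
    def _track(self, counts):
        return dnapet_qc.CoverageTrack("s", 20_000, 5_000,
                                       np.array(counts), "window_count")

    def test_identical_tracks(self):
        t = self._track([1, 2, 3, 4])
        assert dnapet_qc.library_coverage_correlation(t, t) == pytest.approx(1)

    def test_negated_tracks(self):
        a = np.array([1.0, 2, 3, 4])
        b = 2 * a.mean() - a
        r = dnapet_qc.library_coverage_correlation(
            self._track(a), self._track(b))
        assert r == pytest.approx(-1)

    def test_zero_variance_is_nan(self):
        r = dnapet_qc.library_coverage_correlation(
            self._track([2, 2, 2]), self._track([1, 2, 3]))
        assert np.isnan(r)

    def test_replicate_tracks_highly_correlated(self, lib_10k):
        """Two sequencing passes over ONE fragment pool give r > 0.9.

        Independent uniform re-sampling would be uncorrelated Poisson
        noise; the shared-process property requires both tracks to
        observe the same physical fragments (here with 5% independent
        dropout per pass, as in re-sequencing one library).
        """
        _, truth = simdata.simulate_genome(8, chrom_len=1_000_000,
                                           n_fragments=1)
        pool, _ = simdata.simulate_dnapet(
            truth, lib_10k, insert_sd=500, coverage=20, seed=1)
        cpets = dnapet_qc.classify_pairs(pool, lib_10k)[PetClass.CPET]
        rng = np.random.default_rng(2)
        tracks = []
        for _ in range(2):
            keep = [p for p in cpets if rng.random() < 0.95]
            tracks.append(dnapet_qc.coverage_track(
                keep, "scaffold_0", 20_000,
                length=truth.scaffold_lengths["scaffold_0"]))
        r = dnapet_qc.library_coverage_correlation(*tracks)
        assert r > 0.9


class TestGapSizes:
    def _gap_setup(self, annotated=50, at=50_000, length=120_000):
        gap = AssemblyGap("s", at, at + annotated)
        return [gap]

    def test_no_discrepancy_keeps_annotated(self, lib_10k):
        gaps = self._gap_setup()
        cpets = [concordant_pair(i, "s", 46_000 + i * 7, 9_600)
                 for i in range(10)]
        dnapet_qc.estimate_gap_sizes(cpets, gaps, lib_10k,
                                     expected_insert_mean=9_600)
        (est,) = gaps[0].estimates
        assert est.mean_len == pytest.approx(50, abs=1e-9)
        assert est.component_weight == 1.0

    def test_under_support_flagged(self, lib_10k):
        gaps = self._gap_setup()
        cpets = [concordant_pair(i, "s", 46_000 + i, 9_600) for i in range(3)]
        report = dnapet_qc.estimate_gap_sizes(cpets, gaps, lib_10k)
        assert gaps[0].estimates == []
        assert report.n_no_support == 1

    def test_simulated_true_length_recovered(self, lib_10k):
        """True 500bp gap annotated 50: spans = insert - 450 + noise."""
        rng = np.random.default_rng(4)
        gaps = self._gap_setup()
        n, sigma = 40, 500
        cpets = []
        for i in range(n):
            span = int(rng.normal(9_600, sigma)) - 450
            start = int(rng.integers(50_050 - span + 100, 49_900))
            cpets.append(concordant_pair(i, "s", start, span))
        dnapet_qc.estimate_gap_sizes(cpets, gaps, lib_10k,
                                     expected_insert_mean=9_600)
        est = gaps[0].estimates[0]
        assert abs(est.mean_len - 500) < 3 * sigma / np.sqrt(n)

    def test_balanced_mixture_recovered(self, lib_17k):
        """Half the spans imply ~500, half ~4500: two components, ~0.5/0.5."""
        rng = np.random.default_rng(5)
        gaps = self._gap_setup()
        sigma = 600
        cpets = []
        for i in range(40):
            true_len = 500 if i % 2 == 0 else 4_500
            span = int(rng.normal(17_500, sigma)) - (true_len - 50)
            start = int(rng.integers(50_050 - span + 100, 49_900))
            cpets.append(concordant_pair(i, "s", start, span, lib="IXT011"))
        dnapet_qc.estimate_gap_sizes(cpets, gaps, lib_17k,
                                     expected_insert_mean=17_500)
        ests = gaps[0].estimates
        assert len(ests) == 2
        means = sorted(e.mean_len for e in ests)
        assert abs(means[0] - 500) < 500
        assert abs(means[1] - 4_500) < 500
        weights = [e.component_weight for e in ests]
        assert sum(weights) == pytest.approx(1.0, abs=1e-9)
        assert min(weights) > 0.3

    def test_pair_spanning_two_gaps_unused(self, lib_10k):
        gaps = [AssemblyGap("s", 50_000, 50_050),
                AssemblyGap("s", 52_000, 52_050)]
        cpets = [concordant_pair(i, "s", 45_000 + i, 9_600) for i in range(10)]
        report = dnapet_qc.estimate_gap_sizes(cpets, gaps, lib_10k)
        assert report.n_estimated == 0
        assert report.n_no_support == 2

    def test_negative_estimate_polymorphism_flag(self, lib_10k):
        gaps = self._gap_setup()
        # spans much longer than expected => implied length negative
        cpets = [concordant_pair(i, "s", 46_000 + i * 3, 10_600)
                 for i in range(10)]
        dnapet_qc.estimate_gap_sizes(cpets, gaps, lib_10k,
                                     expected_insert_mean=9_600)
        est = gaps[0].estimates[0]
        assert est.mean_len == pytest.approx(-950)
        assert est.polymorphic

    def test_unbiased_over_replicates(self, lib_10k):
        """Gap estimator unbiased on unimodal simulated gaps."""
        rng = np.random.default_rng(6)
        sigma, n = 500, 20
        errors = []
        for _ in range(100):
            true_len = int(rng.integers(200, 2_000))
            gaps = [AssemblyGap("s", 50_000, 50_050)]
            cpets = []
            for i in range(n):
                span = int(rng.normal(9_600, sigma)) - (true_len - 50)
                start = int(rng.integers(50_050 - span + 60, 49_960))
                cpets.append(concordant_pair(i, "s", start, span))
            dnapet_qc.estimate_gap_sizes(cpets, gaps, lib_10k,
                                         expected_insert_mean=9_600)
            errors.append(gaps[0].estimates[0].mean_len - true_len)
        assert abs(np.mean(errors)) < 3 * sigma / np.sqrt(100 * n)


class TestBreakpoints:
    def _track(self, cov):
        return dnapet_qc.CoverageTrack("s", 0, 1, np.asarray(cov),
                                       "per_base_fragment")

    def test_no_zero_no_breakpoint(self, lib_10k):
        cov = np.full(40_000, 3)
        assert dnapet_qc.detect_breakpoints(
            self._track(cov), [], [], lib_10k) == []

    def test_terminal_margin_excluded(self, lib_10k):
        cov = np.ones(40_000)
        cov[:lib_10k.concordant_span_max] = 0  # zeros only within margin
        assert dnapet_qc.detect_breakpoints(
            self._track(cov), [], [], lib_10k) == []

    def test_interior_zero_run_reported_with_gap(self, lib_10k):
        cov = np.ones(40_000)
        cov[20_000:20_050] = 0
        gap = AssemblyGap("s", 20_000, 20_050)
        (bp,) = dnapet_qc.detect_breakpoints(
            self._track(cov), [gap], [], lib_10k)
        assert (bp.start, bp.end) == (20_000, 20_050)
        assert bp.at_gap is gap

    def test_every_breakpoint_is_rechecked_zero(self, lib_10k):
        rng = np.random.default_rng(12)
        cov = rng.integers(0, 3, size=60_000)
        bps = dnapet_qc.detect_breakpoints(self._track(cov), [], [], lib_10k)
        for b in bps:
            assert (cov[b.start:b.end] == 0).all()
            # maximality within the interior
            lo = lib_10k.concordant_span_max
            hi = 60_000 - lib_10k.concordant_span_max
            if b.start > lo:
                assert cov[b.start - 1] != 0
            if b.end < hi:
                assert cov[b.end] != 0

    def test_planted_chimera_junction_found(self, lib_10k):
        scaf, truth = simdata.simulate_genome(
            21, n_chrom=2, chrom_len=120_000, n_fragments=2, n_chimeras=2)
        pairs, _ = simdata.simulate_dnapet(
            truth, lib_10k, insert_sd=500, coverage=20, seed=22)
        classes = dnapet_qc.classify_pairs(pairs, lib_10k)
        cpets = classes[PetClass.CPET]
        dpets = classes[PetClass.DPET_DIFF_REF]
        junctions = {(g.scaffold, g.start)
                     for g in truth.gaps if g.at_junction}
        found = set()
        for s in scaf:
            cov = dnapet_qc.per_base_fragment_coverage(cpets, s)
            track = dnapet_qc.CoverageTrack(s.name, 0, 1, cov,
                                            "per_base_fragment")
            for b in dnapet_qc.detect_breakpoints(track, s.gaps, dpets,
                                                  lib_10k):
                for sc, gs in junctions:
                    if sc == b.scaffold and b.start <= gs + 50 and gs <= b.end:
                        found.add((sc, gs))
        assert found == junctions
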