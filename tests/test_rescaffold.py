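"""rescaffold: splitting, masking, edge building, chaining, statistics."""

import numpy as np
import pytest

from petforge import dnapet_qc, rescaffold, simdata
from petforge.core_io import AssemblyGap, LibraryProfile, ScaffoldRecord
from petforge.dnapet_qc import Breakpoint, PetClass
from petforge.rescaffold import HEAD, TAIL, GraphEdge, ScaffoldFragment

from conftest import LIB_10K, concordant_pair, make_pair
from oracles import exhaustive_best_chain_score


def scaffold_with_gap(name, length, gap_start, gap_len):
    gap = AssemblyGap(name, gap_start, gap_start + gap_len)
    return ScaffoldRecord(name, length, [gap])


class TestSplitAtGaps:
    def test_large_unspanned_gap_splits(self):
        sc = scaffold_with_gap("s", 60_000, 24_000, 12_000)
        frags, removed = rescaffold.split_at_gaps([sc], [])
        assert [(f.parent_start, f.parent_end) for f in frags] == \
               [(0, 24_000), (36_000, 60_000)]
        assert len(removed) == 1

    def test_small_gap_not_split(self):
        sc = scaffold_with_gap("s", 60_000, 24_000, 5_000)
        frags, removed = rescaffold.split_at_gaps([sc], [])
        assert len(frags) == 1
        assert removed == []

    def test_spanned_gap_not_split(self):
        sc = scaffold_with_gap("s", 60_000, 24_000, 10_500)
        spanning = concordant_pair("p", "s", 23_000, 13_000)
        frags, _ = rescaffold.split_at_gaps([sc], [spanning])
        assert len(frags) == 1

    def test_conservation_of_non_gap_length(self):
        sc = scaffold_with_gap("s", 60_000, 24_000, 12_000)
        frags, removed = rescaffold.split_at_gaps([sc], [])
        assert sum(f.length for f in frags) == 60_000 - 12_000


class TestSplitAtBreakpoints:
    def test_interior_breakpoint_splits_with_provenance(self):
        frags = [ScaffoldFragment("s:0-50000", "s", 0, 50_000)]
        bp = Breakpoint("s", 25_000, 25_000)
        out, prov, ignored = rescaffold.split_at_breakpoints(frags, [bp])
        assert len(out) == 2
        assert prov == [("s:0-25000", "s:25000-50000")]
        assert ignored == 0

    def test_breakpoint_at_gap_drops_n_run(self):
        frags = [ScaffoldFragment("s:0-50000", "s", 0, 50_000)]
        gap = AssemblyGap("s", 25_000, 25_050)
        bp = Breakpoint("s", 25_000, 25_050, at_gap=gap)
        out, _, _ = rescaffold.split_at_breakpoints(frags, [bp])
        assert [(f.parent_start, f.parent_end) for f in out] == \
               [(0, 25_000), (25_050, 50_000)]

    def test_breakpoint_in_removed_region_ignored(self):
        # already split at this gap: breakpoint falls between fragments
        frags = [
            ScaffoldFragment("s:0-20000", "s", 0, 20_000),
            ScaffoldFragment("s:32000-50000", "s", 32_000, 50_000),
        ]
        bp = Breakpoint("s", 25_000, 25_050)
        out, prov, ignored = rescaffold.split_at_breakpoints(frags, [bp])
        assert out == frags
        assert ignored == 1

    def test_counting_oracle_on_many_breakpoints(self):
        rng = np.random.default_rng(3)
        frags = [ScaffoldFragment("s:0-1000000", "s", 0, 1_000_000)]
        positions = sorted(rng.choice(
            np.arange(10_000, 990_000, 1_000), size=30, replace=False))
        bps = [Breakpoint("s", int(p), int(p)) for p in positions]
        out, prov, ignored = rescaffold.split_at_breakpoints(frags, bps)
        assert len(out) == len(positions) + 1  # k interior cuts -> k+1 pieces
        assert len(prov) == len(positions)
        assert ignored == 0


class TestMaskRepeats:
    def test_dense_window_masked(self):
        tags = [("s", 1_500) for _ in range(600)]
        masked = rescaffold.mask_repeats(tags)
        assert masked == {"s": [(1_000, 2_000)]}

    def test_boundary_strictly_greater(self):
        tags = [("s", 1_500) for _ in range(500)]
        assert rescaffold.mask_repeats(tags) == {}

    def test_uniform_coverage_masks_nothing(self, lib_10k):
        _, truth = simdata.simulate_genome(5, chrom_len=500_000, n_fragments=1)
        pairs, _ = simdata.simulate_dnapet(
            truth, lib_10k, insert_sd=500, coverage=20, seed=6)
        tags = [(t.ref, t.start) for p in pairs for t in (p.tag1, p.tag2)]
        assert rescaffold.mask_repeats(tags) == {}

    def test_masked_pairs_excluded_whole(self):
        masked = {"s": [(1_000, 2_000)]}
        inside = make_pair("a", "s", 1_500, "+", "t", 0, "+")
        outside = make_pair("b", "s", 5_000, "+", "t", 0, "+")
        kept = rescaffold.exclude_masked_pairs([inside, outside], masked)
        assert [p.pair_id for p in kept] == ["b"]


class TestBuildEdges:
    def _fragments(self):
        return [
            ScaffoldFragment("A:0-50000", "A", 0, 50_000),
            ScaffoldFragment("B:0-40000", "B", 0, 40_000),
        ]

    def _linking_pair(self, i, a_pos, b_pos):
        # tag1 '+' near A's tail (mate right), tag2 '+' near B's head
        return make_pair(i, "A", a_pos, "+", "B", b_pos, "+")

    def test_five_agreeing_dpets_make_edge(self):
        pairs = [self._linking_pair(i, 48_000 + i * 10, 1_000 + i * 10)
                 for i in range(5)]
        edges = rescaffold.build_edges(pairs, self._fragments(),
                                       {"IXT010": LIB_10K})
        assert len(edges) == 1
        (e,) = edges
        assert e.weight == 5
        assert {e.node_a, e.node_b} == {("A:0-50000", TAIL), ("B:0-40000", HEAD)}

    def test_three_dpets_discarded(self):
        pairs = [self._linking_pair(i, 48_000 + i * 10, 1_000) for i in range(3)]
        edges = rescaffold.build_edges(pairs, self._fragments(),
                                       {"IXT010": LIB_10K})
        assert edges == []

    def test_duplicates_collapsed_before_weighting(self):
        pairs = [self._linking_pair("x", 48_000, 1_000) for _ in range(10)]
        edges = rescaffold.build_edges(pairs, self._fragments(),
                                       {"IXT010": LIB_10K})
        assert edges == []  # one non-redundant pair only

    def test_tag_far_from_end_excluded(self):
        # tag on A is > span_max from A's tail
        far = make_pair("far", "A", 10_000, "+", "B", 1_000, "+")
        near = [self._linking_pair(i, 48_000 + i, 1_000) for i in range(4)]
        edges = rescaffold.build_edges([far] + near, self._fragments(),
                                       {"IXT010": LIB_10K})
        assert edges[0].weight == 4

    def test_simulated_adjacency_link_length(self, lib_10k):
        """Planted 2000bp inter-scaffold gap recovered by est_link_len."""
        _, truth = simdata.simulate_genome(
            9, chrom_len=400_000, n_fragments=4, inter_scaffold_gap=2_000)
        pairs, _ = simdata.simulate_dnapet(
            truth, lib_10k, insert_sd=500, coverage=20, seed=10)
        dpets = dnapet_qc.classify_pairs(pairs, lib_10k)[PetClass.DPET_DIFF_REF]
        frags = [
            ScaffoldFragment(f"{n}:0-{L}", n, 0, L)
            for n, L in truth.scaffold_lengths.items()
        ]
        edges = rescaffold.build_edges(dpets, frags, {"IXT010": lib_10k})
        assert len(edges) == 3
        for e in edges:
            se = 3 * 500 / np.sqrt(e.weight)
            assert abs(e.est_link_len - 2_000) < se + 54  # tag-length slop


def random_edge_instance(rng, n_frags=None):
    """A random small edge set for oracle comparison."""
    n = int(rng.integers(3, 9)) if n_frags is None else n_frags
    frag_ids = [f"f{i}" for i in range(n)]
    edges = []
    seen = set()
    for _ in range(int(rng.integers(2, 11))):
        a, b = rng.choice(n, size=2, replace=False)
        na = (frag_ids[a], HEAD if rng.random() < 0.5 else TAIL)
        nb = (frag_ids[b], HEAD if rng.random() < 0.5 else TAIL)
        key = tuple(sorted((na, nb)))
        if key in seen:
            continue
        seen.add(key)
        edges.append(GraphEdge(na, nb, int(rng.integers(4, 25)), "lib"))
    return edges


class TestChaining:
    def test_single_edge_chain(self):
        e = GraphEdge(("A", TAIL), ("B", HEAD), 10, "lib")
        chains = rescaffold.chain_scaffolds([e])
        (chain,) = [c for c in chains if len(c) == 2]
        assert chain.score == 10
        assert chain.fragments in (
            [("A", "+"), ("B", "+")], [("B", "-"), ("A", "-")])

    def test_competing_edge_resolved_by_weight(self):
        strong = GraphEdge(("A", TAIL), ("B", HEAD), 10, "lib")
        weak = GraphEdge(("A", TAIL), ("C", HEAD), 5, "lib")
        chains = rescaffold.chain_scaffolds([strong, weak])
        (chain,) = [c for c in chains if len(c) == 2]
        assert {f for f, _ in chain.fragments} == {"A", "B"}
        assert chain.score == 10 - 5
        # matches the exhaustive optimum
        oracle = exhaustive_best_chain_score(
            [(e.node_a, e.node_b, e.weight) for e in (strong, weak)])
        accepted, processed = rescaffold.heuristic_solution([strong, weak])
        assert rescaffold.solution_score(processed, accepted) == oracle

    def test_cycle_rejected(self):
        edges = [
            GraphEdge(("A", TAIL), ("B", HEAD), 10, "lib"),
            GraphEdge(("B", TAIL), ("A", HEAD), 9, "lib"),
        ]
        chains = rescaffold.chain_scaffolds(edges)
        assert max(len(c) for c in chains) == 2  # path, not a ring

    def test_provenance_only_when_unclaimed(self):
        dpet = GraphEdge(("A", TAIL), ("B", HEAD), 10, "lib")
        prov = GraphEdge(("A", TAIL), ("C", HEAD), 1, "prov", "provenance")
        accepted, processed = rescaffold.heuristic_solution([dpet, prov])
        by_key = {e.key(): e for e in processed}
        kinds = {by_key[k].kind for k in accepted}
        assert kinds == {"dpet"}

    def test_heuristic_matches_exhaustive_on_random_graphs(self):
        rng = np.random.default_rng(14)
        n_optimal = 0
        for _ in range(100):
            edges = random_edge_instance(rng)
            accepted, processed = rescaffold.heuristic_solution(edges)
            got = rescaffold.solution_score(processed, accepted)
            best = exhaustive_best_chain_score(
                [(e.node_a, e.node_b, e.weight) for e in processed])
            assert got <= best  # never exceeds the true optimum
            n_optimal += got == best
        assert n_optimal >= 95

    def test_each_fragment_in_exactly_one_chain(self, lib_10k):
        scaf, truth = simdata.simulate_genome(
            15, chrom_len=1_000_000, n_fragments=20)
        pairs, _ = simdata.simulate_dnapet(
            truth, lib_10k, insert_sd=500, coverage=20, seed=16)
        classes = dnapet_qc.classify_pairs(pairs, lib_10k)
        frags, _ = rescaffold.split_at_gaps(scaf, classes[PetClass.CPET])
        edges = rescaffold.build_edges(
            classes[PetClass.DPET_DIFF_REF], frags, {"IXT010": lib_10k})
        chains = rescaffold.chain_scaffolds(edges, frags)
        seen = [f for c in chains for f, _ in c.fragments]
        assert sorted(seen) == sorted(f.fragment_id for f in frags)

    def test_mirror_symmetry_under_reverse_complement(self, lib_10k):
        """Flipping every scaffold yields mirror-image chains."""
        scaf, truth = simdata.simulate_genome(
            17, chrom_len=600_000, n_fragments=8)
        pairs, _ = simdata.simulate_dnapet(
            truth, lib_10k, insert_sd=500, coverage=20, seed=18)
        lengths = truth.scaffold_lengths

        def mirror(pairs):
            from petforge.core_io import MappedTagPair, TagAlignment
            out = []
            for p in pairs:
                tags = []
                for t in (p.tag1, p.tag2):
                    L = lengths[t.ref]
                    tags.append(TagAlignment(
                        t.ref, L - t.end, L - t.start,
                        "-" if t.strand == "+" else "+"))
                out.append(MappedTagPair(p.pair_id, p.library_id, *tags))
            return out

        def adjacency_set(chains):
            adj = set()
            for c in chains:
                for (f1, o1), (f2, o2) in zip(c.fragments, c.fragments[1:]):
                    fwd = ((f1, o1), (f2, o2))
                    rev = ((f2, "+" if o2 == "-" else "-"),
                           (f1, "+" if o1 == "-" else "-"))
                    adj.add(min(fwd, rev))
            return adj

        frags = [ScaffoldFragment(f"{n}:0-{L}", n, 0, L)
                 for n, L in lengths.items()]
        libmap = {"IXT010": lib_10k}

        def chains_for(pair_set):
            dpets = dnapet_qc.classify_pairs(
                pair_set, lib_10k)[PetClass.DPET_DIFF_REF]
            edges = rescaffold.build_edges(dpets, frags, libmap)
            return rescaffold.chain_scaffolds(edges, frags)

        fwd = adjacency_set(chains_for(pairs))
        mirrored = {
            (( a[0], "+" if a[1] == "-" else "-"),
             ( b[0], "+" if b[1] == "-" else "-"))
            for a, b in adjacency_set(chains_for(mirror(pairs)))
        }
        mirrored = {min(x, ((x[1][0], "+" if x[1][1] == "-" else "-"),
                            (x[0][0], "+" if x[0][1] == "-" else "-")))
                    for x in mirrored}
        assert fwd == mirrored


class TestFillGaps:
    def _setup(self):
        frags = [
            ScaffoldFragment("P:0-30000", "P", 0, 30_000),
            ScaffoldFragment("P:42000-70000", "P", 42_000, 70_000),
            ScaffoldFragment("Q:0-10000", "Q", 0, 10_000),
        ]
        gap = AssemblyGap("P", 30_000, 42_000)
        return frags, [("P", gap)]

    def test_interleaved_fragment_reported_as_fill(self):
        frags, removed = self._setup()
        chain = rescaffold.ChainPath(
            [("P:0-30000", "+"), ("Q:0-10000", "+"), ("P:42000-70000", "+")])
        (fill,) = rescaffold.fill_gaps([chain], removed, frags)
        assert fill["parent"] == "P"
        assert fill["fillers"] == ["Q:0-10000"]

    def test_no_interleaving_no_fill(self):
        frags, removed = self._setup()
        chain = rescaffold.ChainPath(
            [("P:0-30000", "+"), ("P:42000-70000", "+")])
        assert rescaffold.fill_gaps([chain], removed, frags) == []


class TestStats:
    def test_n50_definition_oracle(self):
        assert rescaffold.n50([1, 2, 3, 4, 10]) == 10
        # brute-force oracle over random sets
        rng = np.random.default_rng(19)
        for _ in range(20):
            lengths = rng.integers(1, 1_000, size=12).tolist()
            got = rescaffold.n50(lengths)
            total = sum(lengths)
            covered = sum(x for x in lengths if x >= got)
            assert covered >= total / 2
            bigger = [x for x in lengths if x > got]
            assert sum(bigger) < total / 2

    def test_identical_assemblies_zero_delta(self):
        stats = rescaffold.assembly_stats([5, 10], [5, 10])
        assert stats["count_reduction"] == 0
        assert stats["n50_gain"] == 1

    def test_join_all_reduction(self):
        stats = rescaffold.assembly_stats([1, 2, 3, 4, 10], [20])
        assert stats["count_reduction"] == pytest.approx(0.8)
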