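"""Graph-based re-scaffolding from different-reference discordant pairs.

Workflow: split scaffolds at large unspanned N-runs and at coverage
breakpoints, mask repeat-dense windows, group discordant pairs into
weighted edges between oriented fragment ends, then chain fragments into
hyper-scaffolds with a greedy + local-swap heuristic maximising

    score = sum(weights of traversed edges) - sum(weights of conflicting edges)

where an edge conflicts with a solution when it is incident to a fragment
end already occupied by a traversed edge.  Chains are acyclic paths; each
fragment end joins at most one neighbour.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np

from .core_io import AssemblyGap, LibraryProfile, MappedTagPair, ScaffoldRecord

__all__ = [
    "ScaffoldFragment",
    "GraphEdge",
    "ChainPath",
    "split_at_gaps",
    "split_at_breakpoints",
    "mask_repeats",
    "exclude_masked_pairs",
    "build_edges",
    "merge_parallel_edges",
    "heuristic_solution",
    "chain_scaffolds",
    "solution_score",
    "fill_gaps",
    "n50",
    "assembly_stats",
]

HEAD = "head"
TAIL = "tail"


@dataclass(frozen=True)
class ScaffoldFragment:
    """A piece of an original scaffold, in parent coordinates."""

    fragment_id: str
    parent_scaffold: str
    parent_start: int
    parent_end: int

    @property
    def length(self) -> int:
        return self.parent_end - self.parent_start


def _frag_id(parent: str, start: int, end: int) -> str:
    return f"{parent}:{start}-{end}"


@dataclass
class GraphEdge:
    """A weighted link between two oriented fragment ends."""

    node_a: tuple[str, str]  # (fragment_id, HEAD|TAIL)
    node_b: tuple[str, str]
    weight: int
    library_id: str
    kind: str = "dpet"  # dpet | provenance
    est_link_len: float | None = None

    def __post_init__(self) -> None:
        if self.weight < 1:
            raise ValueError("edge weight must be >= 1")
        if self.kind == "provenance" and self.weight != 1:
            raise ValueError("provenance edges carry weight exactly 1")

    @property
    def orientation_class(self) -> tuple[str, str]:
        return (self.node_a[1], self.node_b[1])

    def key(self) -> tuple:
        a, b = sorted((self.node_a, self.node_b))
        return (a, b)


@dataclass
class ChainPath:
    """An ordered, oriented run of fragments (a hyper-scaffold)."""

    fragments: list[tuple[str, str]]  # (fragment_id, '+'|'-')
    gap_estimates: list[float | None] = field(default_factory=list)
    score: int = 0

    def __len__(self) -> int:
        return len(self.fragments)


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def split_at_gaps(
    scaffolds: list[ScaffoldRecord],
    cpets: list[MappedTagPair],
    min_n_run: int = 10_000,
) -> tuple[list[ScaffoldFragment], list[tuple[str, AssemblyGap]]]:
    """Split at N-runs >= ``min_n_run`` with no spanning concordant fragment.

    The N-run itself is dropped (to be refilled by re-scaffolding).
    Returns the fragments and the list of removed (parent, gap) records.
    """
    spans_by_ref: dict[str, list[tuple[int, int]]] = {}
    for p in cpets:
        try:
            ref, fs, fe = p.fragment_interval()
        except ValueError:
            continue
        spans_by_ref.setdefault(ref, []).append((fs, fe))

    fragments: list[ScaffoldFragment] = []
    removed: list[tuple[str, AssemblyGap]] = []
    for sc in scaffolds:
        cut_gaps = []
        spans = spans_by_ref.get(sc.name, ())
        for g in sc.gaps:
            if g.annotated_len < min_n_run:
                continue
            spanned = any(fs <= g.start and g.end <= fe for fs, fe in spans)
            if not spanned:
                cut_gaps.append(g)
        pos = 0
        for g in cut_gaps:
            if g.start > pos:
                fragments.append(
                    ScaffoldFragment(_frag_id(sc.name, pos, g.start),
                                     sc.name, pos, g.start)
                )
            removed.append((sc.name, g))
            pos = g.end
        if pos < sc.length:
            fragments.append(
                ScaffoldFragment(_frag_id(sc.name, pos, sc.length),
                                 sc.name, pos, sc.length)
            )
    return fragments, removed


def split_at_breakpoints(
    fragments: list[ScaffoldFragment],
    breakpoints,
) -> tuple[list[ScaffoldFragment], list[tuple[str, str]], int]:
    """Split fragments at interior breakpoints.

    When the breakpoint sits at an assembly gap, the N-run is dropped;
    otherwise the cut is made at the breakpoint start so that no sequence
    is lost.  Returns (fragments, provenance pairs of fragment ids,
    number of breakpoints ignored because they fell outside fragments).
    """
    by_parent: dict[str, list[ScaffoldFragment]] = {}
    for f in fragments:
        by_parent.setdefault(f.parent_scaffold, []).append(f)
    for fl in by_parent.values():
        fl.sort(key=lambda f: f.parent_start)

    cuts: dict[str, list[tuple[int, int]]] = {}  # fragment_id -> [(cut_s, cut_e)]
    ignored = 0
    for b in breakpoints:
        if b.at_gap is not None:
            cs, ce = b.at_gap.start, b.at_gap.end
        else:
            cs, ce = b.start, b.start
        host = None
        for f in by_parent.get(b.scaffold, ()):
            if f.parent_start < cs and ce < f.parent_end:
                host = f
                break
        if host is None:
            ignored += 1
            continue
        cuts.setdefault(host.fragment_id, []).append((cs, ce))

    out: list[ScaffoldFragment] = []
    provenance: list[tuple[str, str]] = []
    for f in fragments:
        if f.fragment_id not in cuts:
            out.append(f)
            continue
        pieces = []
        pos = f.parent_start
        for cs, ce in sorted(cuts[f.fragment_id]):
            if cs <= pos:
                continue
            pieces.append(
                ScaffoldFragment(_frag_id(f.parent_scaffold, pos, cs),
                                 f.parent_scaffold, pos, cs)
            )
            pos = max(pos, ce)
        pieces.append(
            ScaffoldFragment(_frag_id(f.parent_scaffold, pos, f.parent_end),
                             f.parent_scaffold, pos, f.parent_end)
        )
        for left, right in zip(pieces, pieces[1:]):
            provenance.append((left.fragment_id, right.fragment_id))
        out.extend(pieces)
    return out, provenance, ignored


# ---------------------------------------------------------------------------
# repeat masking
# ---------------------------------------------------------------------------

def mask_repeats(
    tag_positions,
    window: int = 1_000,
    max_density: int = 500,
) -> dict[str, list[tuple[int, int]]]:
    """Mask non-overlapping windows with strictly more than ``max_density`` tags.

    ``tag_positions`` yields (ref, position) for every mapped tag (not
    pairs).  Returns masked windows per reference, BED-style.
    """
    counts: dict[tuple[str, int], int] = {}
    for ref, pos in tag_positions:
        counts[(ref, pos // window)] = counts.get((ref, pos // window), 0) + 1
    masked: dict[str, list[tuple[int, int]]] = {}
    for (ref, w), n in sorted(counts.items()):
        if n > max_density:
            masked.setdefault(ref, []).append((w * window, (w + 1) * window))
    return masked


def exclude_masked_pairs(
    pairs: list[MappedTagPair],
    masked: dict[str, list[tuple[int, int]]],
) -> list[MappedTagPair]:
    """Drop whole pairs with either tag inside a masked window."""
    if not masked:
        return list(pairs)
    starts = {ref: [s for s, _ in ivs] for ref, ivs in masked.items()}

    def hit(tag) -> bool:
        ivs = masked.get(tag.ref)
        if not ivs:
            return False
        i = bisect_right(starts[tag.ref], tag.start) - 1
        return i >= 0 and ivs[i][0] <= tag.start < ivs[i][1]

    return [p for p in pairs if not (hit(p.tag1) or hit(p.tag2))]


# ---------------------------------------------------------------------------
# edge building
# ---------------------------------------------------------------------------

def _attachment(
    tag, is_tag1: bool, frag: ScaffoldFragment
) -> tuple[str, int]:
    """Which fragment end the mate lies beyond, and the tag's distance to it.

    Same-strand mate-pair geometry: tag1 is the fragment's 5' tag, so its
    mate lies downstream of it on the tag strand; tag2's mate lies
    upstream.
    """
    mate_right = (is_tag1) == (tag.strand == "+")
    if mate_right:
        return TAIL, frag.parent_end - tag.start
    return HEAD, tag.end - frag.parent_start


def build_edges(
    dpets_diff_ref: list[MappedTagPair],
    fragments: list[ScaffoldFragment],
    libs: dict[str, LibraryProfile],
    min_weight: int = 4,
) -> list[GraphEdge]:
    """Group deduplicated discordant pairs into weighted fragment-end edges.

    Tags must fall within the library's ``concordant_span_max`` of the
    attachment end.  Edges are kept per library and dropped when their
    weight is <= ``min_weight - 1`` (the weight > 3 default filter).
    ``est_link_len`` is the mean over the group of
    ``expected_insert_mean - dist_a - dist_b``.
    """
    by_parent: dict[str, list[ScaffoldFragment]] = {}
    for f in fragments:
        by_parent.setdefault(f.parent_scaffold, []).append(f)
    for fl in by_parent.values():
        fl.sort(key=lambda f: f.parent_start)
    fstarts = {r: [f.parent_start for f in fl] for r, fl in by_parent.items()}

    def locate(tag) -> ScaffoldFragment | None:
        fl = by_parent.get(tag.ref)
        if not fl:
            return None
        i = bisect_right(fstarts[tag.ref], tag.start) - 1
        if i >= 0 and fl[i].parent_start <= tag.start and tag.end <= fl[i].parent_end:
            return fl[i]
        return None

    groups: dict[tuple, list[float]] = {}
    seen: set[tuple] = set()
    for p in dpets_diff_ref:
        k = p.coord_key()
        if k in seen:
            continue
        seen.add(k)
        lib = libs.get(p.library_id)
        if lib is None:
            raise KeyError(f"no library profile for {p.library_id}")
        fa = locate(p.tag1)
        fb = locate(p.tag2)
        if fa is None or fb is None or fa.fragment_id == fb.fragment_id:
            continue
        end_a, dist_a = _attachment(p.tag1, True, fa)
        end_b, dist_b = _attachment(p.tag2, False, fb)
        if dist_a > lib.concordant_span_max or dist_b > lib.concordant_span_max:
            continue
        link = lib.expected_insert_mean - dist_a - dist_b
        na, nb = (fa.fragment_id, end_a), (fb.fragment_id, end_b)
        if nb < na:
            na, nb = nb, na
        groups.setdefault((na, nb, p.library_id), []).append(link)

    edges: list[GraphEdge] = []
    for (na, nb, lib_id), links in sorted(groups.items()):
        if len(links) < min_weight:
            continue
        edges.append(
            GraphEdge(na, nb, len(links), lib_id, "dpet",
                      float(np.mean(links)))
        )
    return edges


def merge_parallel_edges(edges: list[GraphEdge]) -> list[GraphEdge]:
    """Sum per-library edges joining the same oriented end pair."""
    merged: dict[tuple, GraphEdge] = {}
    for e in edges:
        k = e.key() + (e.kind,)
        if k in merged:
            m = merged[k]
            links = [
                x for x in (m.est_link_len, e.est_link_len) if x is not None
            ]
            weights = [m.weight, e.weight]
            est = (
                float(np.average(links[:len(weights)], weights=weights[:len(links)]))
                if links else None
            )
            merged[k] = GraphEdge(m.node_a, m.node_b, m.weight + e.weight,
                                  m.library_id + "+" + e.library_id,
                                  m.kind, est)
        else:
            merged[k] = e
    return list(merged.values())


# ---------------------------------------------------------------------------
# chaining
# ---------------------------------------------------------------------------

def solution_score(edges: list[GraphEdge], accepted: set[tuple]) -> int:
    """Traversed weight minus the weight of edges blocked by occupied ends."""
    used_ends: set[tuple[str, str]] = set()
    score = 0
    by_key = {e.key(): e for e in edges}
    for k in accepted:
        e = by_key[k]
        score += e.weight
        used_ends.add(e.node_a)
        used_ends.add(e.node_b)
    for e in edges:
        if e.key() in accepted:
            continue
        if e.node_a in used_ends or e.node_b in used_ends:
            score -= e.weight
    return score


class _UnionFind:
    def __init__(self):
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        self.parent[self.find(a)] = self.find(b)


def _valid_solution(edges_by_key: dict, accepted: set[tuple]) -> bool:
    used: set[tuple[str, str]] = set()
    uf = _UnionFind()
    for k in accepted:
        e = edges_by_key[k]
        if e.node_a in used or e.node_b in used:
            return False
        if uf.find(e.node_a[0]) == uf.find(e.node_b[0]):
            return False
        used.add(e.node_a)
        used.add(e.node_b)
        uf.union(e.node_a[0], e.node_b[0])
    return True


def _sort_key(e: GraphEdge):
    link = abs(e.est_link_len) if e.est_link_len is not None else float("inf")
    return (-e.weight, link, e.node_a, e.node_b)


def _greedy_pass(component: list[GraphEdge],
                 accepted: set[tuple], used_ends: set, uf: "_UnionFind",
                 dpet_claimed: set | None = None) -> None:
    for e in sorted(component, key=_sort_key):
        if dpet_claimed is not None and (
                e.node_a in dpet_claimed or e.node_b in dpet_claimed):
            continue
        if e.node_a in used_ends or e.node_b in used_ends:
            continue
        if uf.find(e.node_a[0]) == uf.find(e.node_b[0]):
            continue
        accepted.add(e.key())
        used_ends.add(e.node_a)
        used_ends.add(e.node_b)
        uf.union(e.node_a[0], e.node_b[0])


def _exact_component(component: list[GraphEdge]) -> set[tuple]:
    """Exhaustive max-score edge subset for one small connected component."""
    n = len(component)
    best_score = 0
    best: set[tuple] = set()

    def rec(i: int, chosen: list[int], used: set, parent: dict) -> None:
        nonlocal best_score, best
        if i == n:
            keys = {component[j].key() for j in chosen}
            s = solution_score(component, keys)
            if s > best_score:
                best_score = s
                best = keys
            return
        rec(i + 1, chosen, used, parent)
        e = component[i]
        if e.node_a in used or e.node_b in used:
            return

        def find(x):
            while parent.get(x, x) != x:
                x = parent[x]
            return x

        ra, rb = find(e.node_a[0]), find(e.node_b[0])
        if ra == rb:
            return
        parent2 = dict(parent)
        parent2[ra] = rb
        rec(i + 1, chosen + [i], used | {e.node_a, e.node_b}, parent2)

    rec(0, [], set(), {})
    return best


def _local_search(component: list[GraphEdge], accepted: set[tuple],
                  max_swap_rounds: int) -> set[tuple]:
    """Single-edge swap/removal moves with greedy refill, to a fixed point."""
    by_key = {e.key(): e for e in component}
    ordered = sorted(component, key=_sort_key)

    def greedy_fill(candidate: set[tuple], skip: set[tuple]) -> set[tuple]:
        out = set(candidate)
        used = set()
        uf2 = _UnionFind()
        for k in out:
            e = by_key[k]
            used.add(e.node_a)
            used.add(e.node_b)
            uf2.union(e.node_a[0], e.node_b[0])
        for e in ordered:
            k = e.key()
            if k in out or k in skip:
                continue
            if e.node_a in used or e.node_b in used:
                continue
            if uf2.find(e.node_a[0]) == uf2.find(e.node_b[0]):
                continue
            out.add(k)
            used.add(e.node_a)
            used.add(e.node_b)
            uf2.union(e.node_a[0], e.node_b[0])
        return out

    current = solution_score(component, accepted)
    for _ in range(max_swap_rounds):
        improved = False
        for e in ordered:
            k = e.key()
            if k in accepted:
                base = accepted - {k}
                candidates = [base, greedy_fill(base, {k})]
            else:
                blockers = {
                    bk for bk in accepted
                    if by_key[bk].node_a in (e.node_a, e.node_b)
                    or by_key[bk].node_b in (e.node_a, e.node_b)
                }
                base = (accepted - blockers) | {k}
                if not _valid_solution(by_key, base):
                    continue
                candidates = [base, greedy_fill(base, blockers)]
            for candidate in candidates:
                s = solution_score(component, candidate)
                if s > current:
                    accepted = candidate
                    current = s
                    improved = True
        if not improved:
            break
    return accepted


def heuristic_solution(
    edges: list[GraphEdge],
    max_swap_rounds: int = 50,
    exact_max_edges: int = 14,
) -> tuple[set[tuple], list[GraphEdge]]:
    """Search for a high-scoring edge subset, component by component.

    The conflict-aware score decomposes exactly over connected components
    of the fragment graph, so each component is solved independently:
    exhaustively when it has at most ``exact_max_edges`` edges, otherwise
    by a greedy descending-weight pass followed by single-edge swap and
    removal moves.  Returns the accepted edge keys and the processed edge
    list (parallel per-library edges merged) the keys refer to.
    """
    dpet = merge_parallel_edges([e for e in edges if e.kind == "dpet"])
    prov = [e for e in edges if e.kind == "provenance"]
    all_edges = dpet + prov

    # connected components over fragments
    uf = _UnionFind()
    for e in all_edges:
        uf.union(e.node_a[0], e.node_b[0])
    components: dict[str, list[GraphEdge]] = {}
    for e in all_edges:
        components.setdefault(uf.find(e.node_a[0]), []).append(e)

    accepted: set[tuple] = set()
    for root in sorted(components):
        comp = components[root]
        comp_dpet = [e for e in comp if e.kind == "dpet"]
        comp_prov = [e for e in comp if e.kind == "provenance"]
        if len(comp) <= exact_max_edges:
            chosen = _exact_component(comp_dpet)
            if comp_prov:
                used_ends = set()
                uf_c = _UnionFind()
                by_key = {e.key(): e for e in comp_dpet}
                for k in chosen:
                    e = by_key[k]
                    used_ends.add(e.node_a)
                    used_ends.add(e.node_b)
                    uf_c.union(e.node_a[0], e.node_b[0])
                _greedy_pass(comp_prov, chosen, used_ends, uf_c,
                             set(used_ends))
            accepted |= chosen
            continue
        chosen: set[tuple] = set()
        used_ends: set = set()
        uf_c = _UnionFind()
        _greedy_pass(comp_dpet, chosen, used_ends, uf_c)
        dpet_claimed = set(used_ends)
        _greedy_pass(comp_prov, chosen, used_ends, uf_c, dpet_claimed)
        accepted |= _local_search(comp, chosen, max_swap_rounds)
    return accepted, all_edges


def chain_scaffolds(
    edges: list[GraphEdge],
    fragments: list[ScaffoldFragment] | None = None,
    max_swap_rounds: int = 50,
) -> list[ChainPath]:
    """Chain fragments into acyclic paths maximising the conflict-aware score.

    Greedy pass over candidate edges in descending weight (ties broken by
    smaller absolute link estimate, then lexicographic ids), accepting an
    edge when both ends are free and it closes no cycle; provenance edges
    are only traversed when no discordant edge claims either end; then
    single-edge swaps until a fixed point.
    """
    accepted, all_edges = heuristic_solution(edges, max_swap_rounds)
    by_key = {e.key(): e for e in all_edges}

    # rebuild chains from the accepted matching
    nbr: dict[tuple[str, str], tuple[tuple[str, str], tuple]] = {}
    frag_ids: set[str] = set()
    for k in accepted:
        e = by_key[k]
        nbr[e.node_a] = (e.node_b, k)
        nbr[e.node_b] = (e.node_a, k)
        frag_ids.add(e.node_a[0])
        frag_ids.add(e.node_b[0])
    if fragments is not None:
        frag_ids |= {f.fragment_id for f in fragments}

    chains: list[ChainPath] = []
    visited: set[str] = set()

    def other_end(node: tuple[str, str]) -> tuple[str, str]:
        return (node[0], TAIL if node[1] == HEAD else HEAD)

    # endpoints: fragments with exactly one used end
    for fid in sorted(frag_ids):
        if fid in visited:
            continue
        head_used = (fid, HEAD) in nbr
        tail_used = (fid, TAIL) in nbr
        if head_used and tail_used:
            continue  # interior fragment; reached from an endpoint
        visited.add(fid)
        if not head_used and not tail_used:
            chains.append(ChainPath([(fid, "+")], [], 0))
            continue
        exit_end = TAIL if tail_used else HEAD
        orient = "+" if exit_end == TAIL else "-"
        path = [(fid, orient)]
        gaps: list[float | None] = []
        score = 0
        node = (fid, exit_end)
        while node in nbr:
            nxt, k = nbr[node]
            e = by_key[k]
            score += e.weight
            gaps.append(e.est_link_len)
            nfid, nend = nxt
            visited.add(nfid)
            path.append((nfid, "+" if nend == HEAD else "-"))
            node = other_end(nxt)
        # conflicting edges incident to this chain's used ends
        chain_ends = set()
        for ak in accepted:
            e = by_key[ak]
            if e.node_a[0] in {f for f, _ in path}:
                chain_ends.add(e.node_a)
                chain_ends.add(e.node_b)
        for e in all_edges:
            if e.key() in accepted:
                continue
            if e.node_a in chain_ends or e.node_b in chain_ends:
                score -= e.weight
        chains.append(ChainPath(path, gaps, score))
    return chains


# ---------------------------------------------------------------------------
# gap fill-in and statistics
# ---------------------------------------------------------------------------

def fill_gaps(
    chains: list[ChainPath],
    removed: list[tuple[str, AssemblyGap]],
    fragments: list[ScaffoldFragment],
) -> list[dict]:
    """Report removed gaps re-filled by fragments of other scaffolds.

    A removed gap of parent P is filled when a chain routes one or more
    other-parent fragments between the two P-fragments flanking that gap.
    """
    by_id = {f.fragment_id: f for f in fragments}
    flank: dict[tuple[str, str], AssemblyGap] = {}
    by_parent: dict[str, list[ScaffoldFragment]] = {}
    for f in fragments:
        by_parent.setdefault(f.parent_scaffold, []).append(f)
    for fl in by_parent.values():
        fl.sort(key=lambda f: f.parent_start)
    for parent, gap in removed:
        left = right = None
        for f in by_parent.get(parent, ()):
            if f.parent_end <= gap.start:
                left = f
            if right is None and f.parent_start >= gap.end:
                right = f
        if left and right:
            flank[(left.fragment_id, right.fragment_id)] = gap

    fills: list[dict] = []
    for chain in chains:
        ids = [fid for fid, _ in chain.fragments]
        for i, fid_i in enumerate(ids):
            fi = by_id.get(fid_i)
            if fi is None:
                continue
            for j in range(i + 1, len(ids)):
                fj = by_id.get(ids[j])
                if fj is None or fj.parent_scaffold != fi.parent_scaffold:
                    continue
                pair = ((fid_i, ids[j]) if fi.parent_start < fj.parent_start
                        else (ids[j], fid_i))
                gap = flank.get(pair)
                between = ids[i + 1:j]
                if gap is not None and between and all(
                    by_id[b].parent_scaffold != fi.parent_scaffold
                    for b in between if b in by_id
                ):
                    fills.append(
                        {
                            "parent": fi.parent_scaffold,
                            "gap_start": gap.start,
                            "gap_end": gap.end,
                            "fillers": between,
                        }
                    )
                break
    return fills


def n50(lengths) -> int:
    """Smallest length such that pieces at least that long hold half the total."""
    arr = sorted(lengths, reverse=True)
    if not arr:
        return 0
    half = sum(arr) / 2.0
    acc = 0
    for x in arr:
        acc += x
        if acc >= half:
            return x
    return arr[-1]


def assembly_stats(before_lengths, after_lengths) -> dict:
    """Scaffold count / N50 / max-length comparison between two assemblies."""
    def summarize(lengths):
        ls = list(lengths)
        return {
            "count": len(ls),
            "total": int(sum(ls)),
            "n50": n50(ls),
            "max": max(ls) if ls else 0,
        }

    b, a = summarize(before_lengths), summarize(after_lengths)
    return {
        "before": b,
        "after": a,
        "count_reduction": 1.0 - a["count"] / b["count"] if b["count"] else 0.0,
        "n50_gain": a["n50"] / b["n50"] if b["n50"] else float("inf"),
    }
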