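"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately re-derive results by enumeration or direct definition,
without reusing the package's algorithmic code paths.
"""

from __future__ import annotations

import itertools


def hamming_signature_found(read: str, signature: str, max_mismatch: int) -> bool:
    """Exhaustive scan of every window by direct Hamming distance."""
    m = len(signature)
    if len(read) < m:
        return False
    read = read.upper()
    for off in range(len(read) - m + 1):
        d = sum(1 for a, b in zip(read[off:off + m], signature) if a != b)
        if d <= max_mismatch:
            return True
    return False


def truth_table_pet_class(tag1, tag2, span_min, span_max) -> str:
    """Direct restatement of the concordance definition.

    tag = (ref, start, end, strand).  Concordant: same ref, same strand,
    correct 5'->3' order, span within [span_min, span_max].
    """
    r1, s1, e1, st1 = tag1
    r2, s2, e2, st2 = tag2
    if r1 != r2:
        return "dPET_diff_ref"
    if st1 != st2:
        return "dPET_same_ref"
    if st1 == "+" and not s1 <= s2:
        return "dPET_same_ref"
    if st1 == "-" and not s2 <= s1:
        return "dPET_same_ref"
    span = max(e1, e2) - min(s1, s2)
    if span_min <= span <= span_max:
        return "cPET"
    return "dPET_same_ref"


def per_base_stab_count(intervals, length: int) -> list[int]:
    """Naive interval-stabbing count at every base."""
    out = [0] * length
    for s, e in intervals:
        for i in range(max(0, s), min(length, e)):
            out[i] += 1
    return out


def _solution_valid(edges, subset) -> bool:
    used = set()
    comp: dict[str, str] = {}

    def find(x):
        comp.setdefault(x, x)
        while comp[x] != x:
            comp[x] = comp[comp[x]]
            x = comp[x]
        return x

    for i in subset:
        a, b = edges[i][0], edges[i][1]
        if a in used or b in used:
            return False
        ra, rb = find(a[0]), find(b[0])
        if ra == rb:
            return False
        used.add(a)
        used.add(b)
        comp[ra] = rb
    return True


def _solution_score(edges, subset) -> int:
    used = set()
    score = 0
    for i in subset:
        score += edges[i][2]
        used.add(edges[i][0])
        used.add(edges[i][1])
    for j, (a, b, w) in enumerate(edges):
        if j in subset:
            continue
        if a in used or b in used:
            score -= w
    return score


def exhaustive_best_chain_score(edges) -> int:
    """Maximum conflict-aware path-cover score over all edge subsets.

    ``edges`` is a list of ((frag, end), (frag, end), weight).  Feasible
    subsets use each fragment end at most once and close no cycle; the
    score is traversed weight minus the weight of edges incident to a
    used end.  Exponential: only for small instances.
    """
    best = 0  # the empty solution scores 0
    n = len(edges)
    for r in range(1, n + 1):
        for subset in itertools.combinations(range(n), r):
            if _solution_valid(edges, subset):
                best = max(best, _solution_score(edges, set(subset)))
    return best
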