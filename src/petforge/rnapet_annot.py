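"""Ditag-based transcript-boundary annotation.

Stages: signature search (HT/TT/HH classification), orientation of HT
pairs, greedy 5'-tag clustering under stringent and relaxed parameters,
promotion of the longest non-over-clustered model per transcription unit,
span and read-support noise filters, coalescing of clusters into gene
models with TSS/TTS sets, and comparison against an existing annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import GeneAnnotation, MappedTagPair

__all__ = [
    "DEFAULT_SIGNATURE",
    "DitagOrientation",
    "OrientedDitag",
    "TranscriptCluster",
    "GeneModel",
    "classify_ditag",
    "signature_found",
    "orient_pairs",
    "cluster_pets",
    "ClusterParams",
    "reads_per_kb",
    "promote",
    "filter_clusters",
    "coalesce",
    "compare_annotation",
    "detect_split_genes",
]

DEFAULT_SIGNATURE = "AACTGCTG"


@dataclass(frozen=True)
class DitagOrientation:
    """Signature-search outcome for one read pair.

    HT: exactly one read carries the 3'-end signature (usable evidence);
    TT: both do; HH: neither.
    """

    value: str               # "HT" | "TT" | "HH"
    signature_end: str       # "1" | "2" | "both" | "none"
    mismatches: tuple[int, int]  # best mismatch count per read (8 = not searchable)


def signature_found(read: str, signature: str = DEFAULT_SIGNATURE,
                    max_mismatch: int = 2) -> tuple[bool, int]:
    """Best ungapped alignment of the signature anywhere in the read.

    Scoring is match +1 / mismatch -1 with indels disallowed over the
    signature window, which reduces to the minimum Hamming distance over
    all offsets; found iff that distance is <= ``max_mismatch``.  A read
    shorter than the signature can never carry it.
    """
    m = len(signature)
    if len(read) < m:
        return False, m
    read = read.upper()
    best = m
    for off in range(len(read) - m + 1):
        d = 0
        window = read[off:off + m]
        for a, b in zip(window, signature):
            if a != b:
                d += 1
                if d >= best:
                    break
        best = min(best, d)
        if best == 0:
            break
    return best <= max_mismatch, best


def classify_ditag(read1_seq: str, read2_seq: str,
                   signature: str = DEFAULT_SIGNATURE,
                   max_mismatch: int = 2) -> DitagOrientation:
    """Classify a read pair as HT / TT / HH by signature presence."""
    f1, d1 = signature_found(read1_seq, signature, max_mismatch)
    f2, d2 = signature_found(read2_seq, signature, max_mismatch)
    if f1 and f2:
        return DitagOrientation("TT", "both", (d1, d2))
    if f1:
        return DitagOrientation("HT", "1", (d1, d2))
    if f2:
        return DitagOrientation("HT", "2", (d1, d2))
    return DitagOrientation("HH", "none", (d1, d2))


@dataclass(frozen=True)
class OrientedDitag:
    """An HT pair with resolved 5'/3' roles, genomic coordinates."""

    pair_id: str
    ref5: str
    ref3: str
    strand: str
    five_start: int
    five_end: int
    three_start: int
    three_end: int

    @property
    def split(self) -> bool:
        return self.ref5 != self.ref3

    @property
    def tss(self) -> int:
        return self.five_start if self.strand == "+" else self.five_end - 1

    @property
    def span_interval(self) -> tuple[int, int]:
        return (min(self.five_start, self.three_start),
                max(self.five_end, self.three_end))


def orient_pairs(
    pairs: list[MappedTagPair],
    signature: str = DEFAULT_SIGNATURE,
    max_mismatch: int = 2,
) -> tuple[list[OrientedDitag], dict[str, int]]:
    """Keep HT pairs and assign 5'/3' roles from signature position.

    The read carrying the signature is the 3' tag; transcript strand is
    taken from the 5' tag's mapped strand.  Returns oriented ditags and
    HT/TT/HH counts.
    """
    counts = {"HT": 0, "TT": 0, "HH": 0}
    out: list[OrientedDitag] = []
    for p in pairs:
        if p.payload is None:
            raise ValueError(f"pair {p.pair_id} carries no read sequences")
        cls = classify_ditag(p.payload[0], p.payload[1], signature, max_mismatch)
        counts[cls.value] += 1
        if cls.value != "HT":
            continue
        if cls.signature_end == "1":
            three, five = p.tag1, p.tag2
        else:
            three, five = p.tag2, p.tag1
        out.append(
            OrientedDitag(
                p.pair_id, five.ref, three.ref, five.strand,
                five.start, five.end, three.start, three.end,
            )
        )
    return out, counts


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusterParams:
    """Greedy clustering parameters; slack 0 is the stringent set."""

    slack: int = 0
    name: str = "stringent"


@dataclass
class TranscriptCluster:
    """A group of ditags sharing overlapping 5' tags."""

    ref: str
    start: int
    end: int
    strand: str
    pet_count: int
    parameter_set: str
    tss_positions: list[int] = field(default_factory=list)
    tts_positions: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("cluster end must exceed start")
        if self.pet_count < 1:
            raise ValueError("pet_count must be >= 1")

    @property
    def span(self) -> int:
        return self.end - self.start


def cluster_pets(
    oriented: list[OrientedDitag],
    params: ClusterParams = ClusterParams(),
) -> list[TranscriptCluster]:
    """Single-pass greedy aggregation of ditags by overlapping 5' tags.

    Input is canonically sorted (ref, strand, 5' tag start) so the result
    is independent of the caller's ordering.  A ditag joins the open
    cluster when its 5' tag overlaps the cluster's current 5'-tag window
    extended by ``params.slack``.  Split ditags (5'/3' on different
    references) are skipped here.
    """
    usable = sorted(
        (d for d in oriented if not d.split),
        key=lambda d: (d.ref5, d.strand, d.five_start, d.five_end, d.pair_id),
    )
    clusters: list[TranscriptCluster] = []
    group: list[OrientedDitag] = []
    win_lo = win_hi = 0

    def flush() -> None:
        if not group:
            return
        lo = min(d.span_interval[0] for d in group)
        hi = max(d.span_interval[1] for d in group)
        strand = group[0].strand
        tss = sorted({d.tss for d in group})
        tts = sorted(
            {d.three_end - 1 if strand == "+" else d.three_start for d in group}
        )
        clusters.append(
            TranscriptCluster(group[0].ref5, lo, hi, strand, len(group),
                              params.name, tss, tts)
        )

    for d in usable:
        if group and (d.ref5, d.strand) == (group[0].ref5, group[0].strand) \
                and d.five_start < win_hi + params.slack:
            group.append(d)
            win_lo = min(win_lo, d.five_start)
            win_hi = max(win_hi, d.five_end)
        else:
            flush()
            group = [d]
            win_lo, win_hi = d.five_start, d.five_end
    flush()
    return clusters


def reads_per_kb(coverage: np.ndarray, start: int, end: int,
                 read_len: int = 75) -> float:
    """Read density over [start, end) implied by per-base coverage."""
    if end <= start:
        return 0.0
    mass = float(np.sum(coverage[start:end]))
    return (mass / read_len) / ((end - start) / 1000.0)


# ---------------------------------------------------------------------------
# promotion and filtering
# ---------------------------------------------------------------------------

def promote(
    stringent: list[TranscriptCluster],
    relaxed: list[TranscriptCluster],
    rnaseq_cov: dict[str, np.ndarray],
    *,
    min_sep: int = 1_000,
    min_reads_per_kb: float = 5.0,
    read_len: int = 75,
) -> list[TranscriptCluster]:
    """Pick the longest model per transcription unit without over-clustering.

    For each relaxed cluster, the stringent clusters it contains are
    inspected: when it merges two or more of them across an internal
    window of at least ``min_sep`` bp whose RNA-Seq density falls below
    ``min_reads_per_kb``, the merge is judged spurious and the stringent
    models are kept instead; otherwise the (longer) relaxed model wins.
    """
    by_unit: dict[tuple[str, str], list[TranscriptCluster]] = {}
    for c in stringent:
        by_unit.setdefault((c.ref, c.strand), []).append(c)
    out: list[TranscriptCluster] = []
    claimed: set[int] = set()
    for r in relaxed:
        members = [
            s for s in by_unit.get((r.ref, r.strand), ())
            if s.start < r.end and r.start < s.end
        ]
        members.sort(key=lambda s: s.start)
        over_clustered = False
        if len(members) >= 2:
            cov = rnaseq_cov.get(r.ref)
            for a, b in zip(members, members[1:]):
                gap_lo, gap_hi = a.end, b.start
                if gap_hi - gap_lo < min_sep:
                    continue
                density = (
                    reads_per_kb(cov, gap_lo, gap_hi, read_len)
                    if cov is not None else 0.0
                )
                if density < min_reads_per_kb:
                    over_clustered = True
                    break
        if over_clustered:
            for s in members:
                if id(s) not in claimed:
                    claimed.add(id(s))
                    out.append(s)
        else:
            out.append(r)
            for s in members:
                claimed.add(id(s))
    # stringent clusters untouched by any relaxed model survive as-is
    for units in by_unit.values():
        for s in units:
            if id(s) not in claimed:
                out.append(s)
    out.sort(key=lambda c: (c.ref, c.strand, c.start, c.end))
    return out


def filter_clusters(
    clusters: list[TranscriptCluster],
    rnaseq_cov: dict[str, np.ndarray] | None = None,
    min_span: int = 2_000,
    min_reads_per_kb: float = 5.0,
    read_len: int = 75,
) -> list[TranscriptCluster]:
    """Drop low-span noise clusters and clusters without read support.

    Clusters with span < ``min_span`` (the low-PET-count noise mode) are
    discarded, then clusters whose RNA-Seq density over their span is
    below ``min_reads_per_kb``.
    """
    out = []
    for c in clusters:
        if c.span < min_span:
            continue
        if rnaseq_cov is not None:
            cov = rnaseq_cov.get(c.ref)
            density = (
                reads_per_kb(cov, c.start, c.end, read_len)
                if cov is not None else 0.0
            )
            if density < min_reads_per_kb:
                continue
        out.append(c)
    return out


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """A locus-level model coalesced from overlapping clusters."""

    gene_id: str
    ref: str
    start: int
    end: int
    strand: str
    clusters: list[TranscriptCluster] = field(default_factory=list)
    tss_set: list[int] = field(default_factory=list)
    tts_set: list[int] = field(default_factory=list)

    @property
    def span(self) -> int:
        return self.end - self.start


def _dedupe_positions(positions: list[int], radius: int) -> list[int]:
    out: list[int] = []
    for p in sorted(positions):
        if not out or p - out[-1] > radius:
            out.append(p)
    return out


def coalesce(
    clusters: list[TranscriptCluster],
    merge_radius: int = 10,
) -> list[GeneModel]:
    """Merge same-reference same-strand overlapping clusters into genes.

    Genes are the connected components of the span-overlap graph; TSS/TTS
    sets are the distinct 5'/3' boundary positions, deduplicated within
    ``merge_radius``.
    """
    by_unit: dict[tuple[str, str], list[TranscriptCluster]] = {}
    for c in clusters:
        by_unit.setdefault((c.ref, c.strand), []).append(c)
    genes: list[GeneModel] = []
    idx = 0
    for (ref, strand) in sorted(by_unit):
        cl = sorted(by_unit[(ref, strand)], key=lambda c: (c.start, c.end))
        group: list[TranscriptCluster] = []
        group_end = -1
        for c in cl + [None]:
            if c is not None and group and c.start < group_end:
                group.append(c)
                group_end = max(group_end, c.end)
                continue
            if group:
                tss = _dedupe_positions(
                    [p for g in group for p in g.tss_positions], merge_radius)
                tts = _dedupe_positions(
                    [p for g in group for p in g.tts_positions], merge_radius)
                genes.append(
                    GeneModel(
                        f"gene_{idx}", ref,
                        min(g.start for g in group),
                        max(g.end for g in group),
                        strand, list(group), tss, tts,
                    )
                )
                idx += 1
            if c is not None:
                group = [c]
                group_end = c.end
    return genes


# ---------------------------------------------------------------------------
# comparison with an existing annotation
# ---------------------------------------------------------------------------

def _overlap(a_start, a_end, b_start, b_end) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def compare_annotation(
    genes: list[GeneModel],
    existing: list[GeneAnnotation],
    rnaseq_cov: dict[str, np.ndarray] | None = None,
    *,
    extension_ratio: float = 1.3,
    extension_bp: int = 5_000,
) -> dict:
    """Match new models to an existing annotation and report extensions.

    Matching is reciprocal best overlap on the same reference and strand.
    A matched gene is flagged extended when new/old length > 1.3 or the
    absolute growth exceeds 5Kb.  When coverage is supplied, the fraction
    of RNA-Seq signal inside each annotation's spans is reported.
    """
    best_for_gene: dict[str, tuple[int, int]] = {}
    best_for_old: dict[int, tuple[int, int]] = {}
    for gi, g in enumerate(genes):
        for oi, o in enumerate(existing):
            if o.ref != g.ref or o.strand != g.strand:
                continue
            ov = _overlap(g.start, g.end, o.start, o.end)
            if ov <= 0:
                continue
            if ov > best_for_gene.get(g.gene_id, (0, -1))[0]:
                best_for_gene[g.gene_id] = (ov, oi)
            if ov > best_for_old.get(oi, (0, -1))[0]:
                best_for_old[oi] = (ov, gi)

    matches = []
    matched_old: set[int] = set()
    for gi, g in enumerate(genes):
        got = best_for_gene.get(g.gene_id)
        if got is None:
            continue
        _, oi = got
        if best_for_old.get(oi, (0, -1))[1] != gi:
            continue
        o = existing[oi]
        matched_old.add(oi)
        ratio = g.span / o.span
        extended = ratio > extension_ratio or (g.span - o.span) > extension_bp
        matches.append(
            {
                "gene_id": g.gene_id,
                "old_id": o.gene_id,
                "new_span": g.span,
                "old_span": o.span,
                "ratio": ratio,
                "extended": extended,
            }
        )

    report = {
        "matches": matches,
        "n_matched": len(matches),
        "n_novel": len(genes) - len(matches),
        "n_silent": len(existing) - len(matched_old),
        "extended_fraction": (
            sum(m["extended"] for m in matches) / len(matches)
            if matches else float("nan")
        ),
    }
    if rnaseq_cov is not None:
        total = sum(float(c.sum()) for c in rnaseq_cov.values())

        def mass_inside(intervals) -> float:
            by_ref: dict[str, list[tuple[int, int]]] = {}
            for ref, s, e in intervals:
                by_ref.setdefault(ref, []).append((s, e))
            inside = 0.0
            for ref, ivs in by_ref.items():
                cov = rnaseq_cov.get(ref)
                if cov is None:
                    continue
                mask = np.zeros(len(cov), dtype=bool)
                for s, e in ivs:
                    mask[max(0, s):min(len(cov), e)] = True
                inside += float(cov[mask].sum())
            return inside / total if total else float("nan")

        report["rnaseq_fraction_new"] = mass_inside(
            (g.ref, g.start, g.end) for g in genes)
        report["rnaseq_fraction_old"] = mass_inside(
            (o.ref, o.start, o.end) for o in existing)
    return report


def detect_split_genes(
    oriented: list[OrientedDitag],
    chains,
    min_support: int = 2,
) -> list[dict]:
    """Report transcripts whose 5' and 3' tags map to different scaffolds.

    ``chains`` are re-scaffolding ChainPath objects over fragments named
    ``parent:start-end``; a split gene is rescued when its two scaffolds
    co-occur in one chain.
    """
    frag_chain: dict[str, int] = {}
    for ci, chain in enumerate(chains):
        for fid, _ in chain.fragments:
            parent = fid.split(":")[0]
            frag_chain[parent] = ci
    groups: dict[tuple[str, str], int] = {}
    for d in oriented:
        if not d.split:
            continue
        key = (d.ref5, d.ref3)
        groups[key] = groups.get(key, 0) + 1
    out = []
    for (r5, r3), n in sorted(groups.items()):
        if n < min_support:
            continue
        same_chain = (
            r5 in frag_chain and r3 in frag_chain
            and frag_chain[r5] == frag_chain[r3]
        )
        out.append({"ref5": r5, "ref3": r3, "n_pets": n,
                    "same_chain": same_chain})
    return out
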