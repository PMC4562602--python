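"""Ground-truth synthetic data: genome, mate-pair libraries, ditags, RNA-Seq.

Every generator is fully deterministic under its ``seed``.  The central
record is :class:`SyntheticTruth`, which keeps the exact mapping between
"true" chromosome coordinates and the coordinates of the emitted (possibly
fragmented, gap-riddled, mis-joined, reverse-complemented) scaffolds, so
that downstream recovery can be scored against planted truth.

Emitted scaffolds deliberately mimic the pathologies of a draft assembly:

* assembly gaps annotated at a fixed placeholder length (default 50bp)
  while their true length is drawn from a log-normal (median ~500bp);
* a fraction of gaps biallelic (two true lengths segregating in the
  sequenced sample) for bimodality tests;
* chimeric scaffolds joining pieces of two different chromosomes at a
  junction gap, for breakpoint tests;
* optional random reverse-complement orientation per scaffold.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np

from .core_io import (
    AssemblyGap,
    GeneAnnotation,
    LibraryProfile,
    MappedTagPair,
    ScaffoldRecord,
    TagAlignment,
)

__all__ = [
    "PlantedGap",
    "MapSegment",
    "TranscriptTruth",
    "SyntheticTruth",
    "simulate_genome",
    "simulate_dnapet",
    "simulate_transcriptome_and_ditags",
    "SimulatedTranscriptome",
    "random_sequence",
    "revcomp",
]

_COMP = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_sequence(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


@dataclass
class PlantedGap:
    """Truth record for one emitted assembly gap (scaffold coordinates)."""

    scaffold: str
    start: int
    end: int          # start + annotated_len
    annotated_len: int
    true_len: int
    alt_len: int | None = None   # second allele length, if biallelic
    alt_frac: float = 0.0        # fraction of fragments carrying alt_len
    at_junction: bool = False    # chimeric junction marker

    @property
    def biallelic(self) -> bool:
        return self.alt_len is not None and self.alt_frac > 0


@dataclass(frozen=True)
class MapSegment:
    """A sequenced stretch mapping true coords to scaffold coords.

    strand '+' : true t -> s_start + (t - t_start)
    strand '-' : true t -> s_start + (t_end - 1 - t)
    """

    chrom: str
    t_start: int
    t_end: int
    scaffold: str
    s_start: int
    strand: str

    @property
    def length(self) -> int:
        return self.t_end - self.t_start


@dataclass
class TranscriptTruth:
    """Planted transcript, in both true and scaffold coordinates."""

    gene_id: str
    chrom: str
    t_start: int
    t_end: int
    strand: str              # strand on the true chromosome
    ref5: str                # scaffold carrying the 5' tag
    ref3: str                # scaffold carrying the 3' tag
    s_start: int             # scaffold interval when ref5 == ref3
    s_end: int
    s_strand: str
    tss: int                 # scaffold coordinate of the first transcribed base
    tts: int
    n_ditags: int
    expressed: bool
    truncated: bool
    old: GeneAnnotation | None = None

    @property
    def split(self) -> bool:
        return self.ref5 != self.ref3


@dataclass
class SyntheticTruth:
    """Everything needed to score recovery against planted ground truth."""

    chromosomes: dict[str, str]
    segments: list[MapSegment]
    scaffold_lengths: dict[str, int]
    scaffold_order: dict[str, list[tuple[str, str]]]  # chrom -> [(scaffold, orient)]
    inter_scaffold_gap: int
    gaps: list[PlantedGap] = field(default_factory=list)
    transcripts: list[TranscriptTruth] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_chrom: dict[str, list[MapSegment]] = {}
        for seg in self.segments:
            self._by_chrom.setdefault(seg.chrom, []).append(seg)
        for segs in self._by_chrom.values():
            segs.sort(key=lambda s: s.t_start)
        self._starts = {
            c: [s.t_start for s in segs] for c, segs in self._by_chrom.items()
        }

    # -- projection -------------------------------------------------------
    def segment_at(self, chrom: str, pos: int) -> MapSegment | None:
        segs = self._by_chrom.get(chrom)
        if not segs:
            return None
        i = bisect_right(self._starts[chrom], pos) - 1
        if i >= 0 and segs[i].t_start <= pos < segs[i].t_end:
            return segs[i]
        return None

    def project_tag(self, chrom: str, start: int, end: int,
                    strand: str) -> TagAlignment | None:
        """Project a true-coordinate tag onto scaffold coordinates.

        Returns None if the tag does not lie wholly inside one sequenced
        segment (it fell into a gap or an unsequenced inter-scaffold run).
        """
        seg = self.segment_at(chrom, start)
        if seg is None or end > seg.t_end:
            return None
        if seg.strand == "+":
            s = seg.s_start + (start - seg.t_start)
            return TagAlignment(seg.scaffold, s, s + (end - start), strand)
        s = seg.s_start + (seg.t_end - end)
        flipped = "-" if strand == "+" else "+"
        return TagAlignment(seg.scaffold, s, s + (end - start), flipped)

    def project_interval(self, chrom: str, start: int,
                         end: int) -> tuple[str, int, int] | None:
        """Project a true interval wholly inside one segment (any length)."""
        seg = self.segment_at(chrom, start)
        if seg is None or end > seg.t_end:
            return None
        if seg.strand == "+":
            s = seg.s_start + (start - seg.t_start)
        else:
            s = seg.s_start + (seg.t_end - end)
        return seg.scaffold, s, s + (end - start)

    def true_adjacencies(self) -> list[tuple[tuple[str, str], tuple[str, str]]]:
        """Consecutive (scaffold, orientation) pairs along each chromosome."""
        out = []
        for order in self.scaffold_order.values():
            for a, b in zip(order, order[1:]):
                out.append((a, b))
        return out

    def gaps_for(self, scaffold: str) -> list[PlantedGap]:
        return sorted(
            (g for g in self.gaps if g.scaffold == scaffold),
            key=lambda g: g.start,
        )

    # -- serialization ----------------------------------------------------
    def save(self, path) -> None:
        import dataclasses
        import json

        doc = {
            "chromosomes": self.chromosomes,
            "segments": [dataclasses.asdict(s) for s in self.segments],
            "scaffold_lengths": self.scaffold_lengths,
            "scaffold_order": self.scaffold_order,
            "inter_scaffold_gap": self.inter_scaffold_gap,
            "gaps": [dataclasses.asdict(g) for g in self.gaps],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def load(cls, path) -> "SyntheticTruth":
        import json

        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            chromosomes=doc["chromosomes"],
            segments=[MapSegment(**s) for s in doc["segments"]],
            scaffold_lengths=doc["scaffold_lengths"],
            scaffold_order={
                c: [tuple(x) for x in v]
                for c, v in doc["scaffold_order"].items()
            },
            inter_scaffold_gap=doc["inter_scaffold_gap"],
            gaps=[PlantedGap(**g) for g in doc["gaps"]],
        )


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def _default_gap_true_len(rng: np.random.Generator) -> int:
    # log-normal, median ~500bp
    return max(1, int(round(rng.lognormal(math.log(500.0), 0.5))))


def _cut_points(rng: np.random.Generator, length: int, n: int) -> list[int]:
    """n-1 interior cut points with +-10% jitter around even spacing."""
    if n <= 1:
        return []
    step = length / n
    pts = []
    for i in range(1, n):
        jitter = rng.uniform(-0.1, 0.1) * step
        pts.append(int(round(i * step + jitter)))
    pts = sorted(set(min(max(p, 1), length - 1) for p in pts))
    return pts


def simulate_genome(
    seed: int,
    n_chrom: int = 1,
    chrom_len: int = 1_000_000,
    n_fragments: int = 1,
    *,
    inter_scaffold_gap: int = 0,
    gap_every: int | None = None,
    gap_annotated_len: int = 50,
    gap_true_len=None,
    gap_margin: int = 2_000,
    biallelic_frac: float = 0.0,
    allele_delta: int = 3_000,
    allele_frac: float = 0.5,
    n_chimeras: int = 0,
    chimera_gap_len: int = 50,
    random_orientation: bool = False,
    with_sequence: bool = True,
) -> tuple[list[ScaffoldRecord], SyntheticTruth]:
    """Generate chromosomes and cut them into draft-like scaffolds.

    Parameters mirror the pathologies being planted; see module docstring.
    ``gap_every`` plants an intra-scaffold gap roughly every that many true
    bp (annotated at ``gap_annotated_len`` regardless of true length).
    ``n_chimeras`` joins the first segments of chromosome 0 and 1 pairwise
    into mis-assembled scaffolds with a junction gap.
    """
    if n_fragments < 1 or chrom_len < 1 or n_chrom < 1:
        raise ValueError("parameters must be positive")
    if n_chimeras > 0 and n_chrom < 2:
        raise ValueError("chimeras require at least two chromosomes")
    if n_chimeras > n_fragments:
        raise ValueError("more chimeras than fragments per chromosome")
    rng = np.random.default_rng(seed)
    true_len_sampler = gap_true_len or _default_gap_true_len

    chroms = {
        f"chrom_{c}": random_sequence(rng, chrom_len) for c in range(n_chrom)
    }

    # true segment intervals per chromosome
    seg_ivs: dict[str, list[tuple[int, int]]] = {}
    for cname in chroms:
        pts = _cut_points(rng, chrom_len, n_fragments)
        bounds = [0] + pts + [chrom_len]
        ivs = []
        for a, b in zip(bounds, bounds[1:]):
            # drop inter_scaffold_gap true bp at the downstream side
            ivs.append((a, b))
        if inter_scaffold_gap:
            ivs = [
                (a, max(a + 1, b - inter_scaffold_gap)) if i < len(ivs) - 1 else (a, b)
                for i, (a, b) in enumerate(ivs)
            ]
        seg_ivs[cname] = ivs

    scaffolds: list[ScaffoldRecord] = []
    segments: list[MapSegment] = []
    planted: list[PlantedGap] = []
    scaffold_lengths: dict[str, int] = {}
    order: dict[str, list[tuple[str, str]]] = {c: [] for c in chroms}
    counter = 0

    def build_scaffold(parts, junction_gap_len=None):
        """Assemble one scaffold from (chrom, t_start, t_end) parts.

        Consecutive parts are joined by a junction gap.  Intra-part gaps
        are planted per ``gap_every``.  Returns the scaffold name.
        """
        nonlocal counter
        name = f"scaffold_{counter}"
        counter += 1
        seq_chunks: list[str] = []
        local_segments: list[MapSegment] = []
        local_gaps: list[PlantedGap] = []
        pos = 0
        for pi, (chrom, a, b) in enumerate(parts):
            if pi > 0:
                gl = junction_gap_len or chimera_gap_len
                local_gaps.append(
                    PlantedGap(name, pos, pos + gl, gl, gl, at_junction=True)
                )
                seq_chunks.append("N" * gl)
                pos += gl
            # plant intra-part gaps
            cut_at: list[tuple[int, int]] = []   # (true_start, true_len)
            if gap_every is not None:
                t = a + gap_margin
                while t + gap_margin < b:
                    tl = true_len_sampler(rng)
                    if t + tl + gap_margin < b:
                        cut_at.append((t, tl))
                    t += gap_every
            cursor = a
            for g_t, tl in cut_at:
                seg_len = g_t - cursor
                local_segments.append(
                    MapSegment(chrom, cursor, g_t, name, pos, "+")
                )
                seq_chunks.append(chroms[chrom][cursor:g_t])
                pos += seg_len
                alt = None
                afrac = 0.0
                if biallelic_frac and rng.random() < biallelic_frac:
                    alt = tl + allele_delta
                    afrac = allele_frac
                local_gaps.append(
                    PlantedGap(name, pos, pos + gap_annotated_len,
                               gap_annotated_len, tl, alt, afrac)
                )
                seq_chunks.append("N" * gap_annotated_len)
                pos += gap_annotated_len
                cursor = g_t + tl
            local_segments.append(MapSegment(chrom, cursor, b, name, pos, "+"))
            seq_chunks.append(chroms[chrom][cursor:b])
            pos += b - cursor
        length = pos
        orient = "+"
        if random_orientation and rng.random() < 0.5:
            orient = "-"
            seq_chunks = [revcomp(c) for c in reversed(seq_chunks)]
            local_segments = [
                MapSegment(s.chrom, s.t_start, s.t_end, name,
                           length - (s.s_start + s.length), "-")
                for s in local_segments
            ]
            local_gaps = [
                PlantedGap(g.scaffold, length - g.end, length - g.start,
                           g.annotated_len, g.true_len, g.alt_len, g.alt_frac,
                           g.at_junction)
                for g in local_gaps
            ]
        sequence = "".join(seq_chunks) if with_sequence else None
        gap_objs = [
            AssemblyGap(name, g.start, g.end)
            for g in sorted(local_gaps, key=lambda g: g.start)
        ]
        scaffolds.append(ScaffoldRecord(name, length, gap_objs, sequence))
        segments.extend(local_segments)
        planted.extend(local_gaps)
        scaffold_lengths[name] = length
        return name, orient

    chrom_names = list(chroms)
    if n_chimeras:
        c0, c1 = chrom_names[0], chrom_names[1]
        for i in range(n_chimeras):
            a0, b0 = seg_ivs[c0][i]
            a1, b1 = seg_ivs[c1][i]
            build_scaffold([(c0, a0, b0), (c1, a1, b1)],
                           junction_gap_len=chimera_gap_len)
        seg_ivs[c0] = seg_ivs[c0][n_chimeras:]
        seg_ivs[c1] = seg_ivs[c1][n_chimeras:]

    for cname in chrom_names:
        for a, b in seg_ivs[cname]:
            name, orient = build_scaffold([(cname, a, b)])
            order[cname].append((name, orient))

    truth = SyntheticTruth(
        chromosomes=chroms,
        segments=segments,
        scaffold_lengths=scaffold_lengths,
        scaffold_order=order,
        inter_scaffold_gap=inter_scaffold_gap,
        gaps=planted,
    )
    return scaffolds, truth


# ---------------------------------------------------------------------------
# DNA mate pairs
# ---------------------------------------------------------------------------

def simulate_dnapet(
    truth: SyntheticTruth,
    lib: LibraryProfile,
    *,
    insert_sd: float,
    coverage: float,
    seed: int,
    chimera_rate: float = 0.0,
    tag_len: int = 27,
) -> tuple[list[MappedTagPair], dict[str, int]]:
    """Simulate a mate-pair library on true coordinates, then project.

    Fragments are drawn on the true chromosomes with insert length
    ~ Normal(lib.expected_insert_mean, insert_sd) and a random genomic
    strand; tags are 27bp at the fragment ends (same-strand mate-pair
    geometry: tag1 is the fragment's 5' tag, tag2 its 3' tag, both
    reported on the fragment strand).  Tags are projected independently
    to scaffold coordinates, so fragments straddling an inter-scaffold
    junction naturally become different-reference discordant pairs.
    ``chimera_rate`` injects fully random artefactual pairs as noise.
    """
    rng = np.random.default_rng(seed)
    chrom_names = list(truth.chromosomes)
    chrom_lens = np.array([len(truth.chromosomes[c]) for c in chrom_names], float)
    weights = chrom_lens / chrom_lens.sum()
    total = chrom_lens.sum()
    n_pairs = int(round(coverage * total / lib.expected_insert_mean))

    # biallelic gaps by scaffold for the haplotype span shift
    biallelic: dict[str, list[PlantedGap]] = {}
    for g in truth.gaps:
        if g.biallelic:
            biallelic.setdefault(g.scaffold, []).append(g)
    gaps_by_scaffold: dict[str, list[tuple[int, int]]] = {}
    for g in truth.gaps:
        gaps_by_scaffold.setdefault(g.scaffold, []).append((g.start, g.end))

    def random_tag() -> TagAlignment | None:
        for _ in range(20):
            ci = rng.choice(len(chrom_names), p=weights)
            chrom = chrom_names[ci]
            L = int(chrom_lens[ci])
            s = int(rng.integers(0, max(1, L - tag_len)))
            tag = truth.project_tag(chrom, s, s + tag_len,
                                    "+" if rng.random() < 0.5 else "-")
            if tag is not None:
                return tag
        return None

    pairs: list[MappedTagPair] = []
    stats = {"n_pairs": 0, "n_dropped_unmapped": 0, "n_noise": 0,
             "n_dropped_allele": 0}
    for i in range(n_pairs):
        pid = f"{lib.library_id}:{i}"
        if chimera_rate and rng.random() < chimera_rate:
            t1, t2 = random_tag(), random_tag()
            if t1 is None or t2 is None:
                stats["n_dropped_unmapped"] += 1
                continue
            pairs.append(MappedTagPair(pid, lib.library_id, t1, t2))
            stats["n_noise"] += 1
            stats["n_pairs"] += 1
            continue
        ci = rng.choice(len(chrom_names), p=weights)
        chrom = chrom_names[ci]
        L = int(chrom_lens[ci])
        ins = int(round(rng.normal(lib.expected_insert_mean, insert_sd)))
        ins = max(2 * tag_len + 1, min(ins, L - 1))
        s = int(rng.integers(0, L - ins))
        strand = "+" if rng.random() < 0.5 else "-"
        left = (s, s + tag_len)
        right = (s + ins - tag_len, s + ins)
        if strand == "+":
            raw1, raw2 = left, right
        else:
            raw1, raw2 = right, left
        t1 = truth.project_tag(chrom, raw1[0], raw1[1], strand)
        t2 = truth.project_tag(chrom, raw2[0], raw2[1], strand)
        if t1 is None or t2 is None:
            stats["n_dropped_unmapped"] += 1
            continue
        # haplotype shift across biallelic gaps (same-scaffold pairs only)
        if t1.ref == t2.ref and t1.ref in biallelic:
            lo = min(t1.start, t2.start)
            hi = max(t1.end, t2.end)
            delta = 0
            for g in biallelic[t1.ref]:
                if lo <= g.start and g.end <= hi and rng.random() < g.alt_frac:
                    delta += g.alt_len - g.true_len
            if delta:
                # shift the downstream tag toward/away from the upstream one
                down, up = (t1, t2) if t1.start >= t2.start else (t2, t1)
                ns, ne = down.start - delta, down.end - delta
                ok = ne <= truth.scaffold_lengths[down.ref] and ns >= up.end
                if ok:
                    for gs, ge in gaps_by_scaffold.get(down.ref, ()):
                        if ns < ge and gs < ne:
                            ok = False
                            break
                if not ok:
                    stats["n_dropped_allele"] += 1
                    continue
                moved = TagAlignment(down.ref, ns, ne, down.strand)
                if down is t1:
                    t1 = moved
                else:
                    t2 = moved
        pairs.append(MappedTagPair(pid, lib.library_id, t1, t2))
        stats["n_pairs"] += 1
    return pairs, stats


# ---------------------------------------------------------------------------
# transcriptome + ditags + RNA-Seq
# ---------------------------------------------------------------------------

def _min_hamming(read: str, motif: str, skip_offset: int | None = None) -> int:
    best = len(motif)
    for off in range(len(read) - len(motif) + 1):
        if off == skip_offset:
            continue
        d = sum(a != b for a, b in zip(read[off:off + len(motif)], motif))
        best = min(best, d)
    return best


def _apply_errors(rng: np.random.Generator, read: str, rate: float) -> str:
    if rate <= 0:
        return read
    bases = "ACGT"
    out = list(read)
    for i, b in enumerate(out):
        if rng.random() < rate:
            out[i] = bases[(bases.index(b) + 1 + int(rng.integers(0, 3))) % 4]
    return "".join(out)


@dataclass
class SimulatedTranscriptome:
    ditags: list[MappedTagPair]
    coverage: dict[str, np.ndarray]
    old_annotation: list[GeneAnnotation]
    transcripts: list[TranscriptTruth]


def simulate_transcriptome_and_ditags(
    truth: SyntheticTruth,
    *,
    n_genes: int,
    seed: int,
    span_range: tuple[int, int] = (3_000, 12_000),
    spacing: int = 2_000,
    ditag_mean: float = 10.0,
    ditag_min: int = 5,
    error_rate: float = 0.0,
    rnaseq_reads_per_kb: float = 20.0,
    rnaseq_read_len: int = 75,
    truncate_frac: float = 0.4,
    truncate_ratio: float = 1.5,
    silent_frac: float = 0.0,
    signature: str = "AACTGCTG",
    tag_len: int = 27,
    read_len: int = 36,
    allow_split: bool = False,
) -> SimulatedTranscriptome:
    """Plant transcripts on the true genome and emit ditags + RNA-Seq.

    Each expressed transcript emits ``max(ditag_min, Poisson(ditag_mean))``
    ditags: 27bp 5'/3' tags padded to ``read_len``, the 3' read carrying
    the signature immediately after the tag.  Read backgrounds are
    rejection-sampled to stay Hamming distance >= 4 from the signature so
    that classification outcomes are controlled by planted truth (random
    36-mers would otherwise contain spurious near-signatures ~10% of the
    time).  A deliberately truncated "old" annotation is emitted for
    extension-report tests: a ``truncate_frac`` fraction of genes is
    shrunk by ``truncate_ratio`` (> the 1.3x reporting threshold), the
    rest by 1.08x (below it).

    RNA-Seq coverage is built from uniform reads over each expressed
    transcript span at ``rnaseq_reads_per_kb``.
    """
    rng = np.random.default_rng(seed)
    chrom_names = list(truth.chromosomes)
    coverage = {
        name: np.zeros(length, dtype=float)
        for name, length in truth.scaffold_lengths.items()
    }
    transcripts: list[TranscriptTruth] = []
    ditags: list[MappedTagPair] = []
    old: list[GeneAnnotation] = []

    def tag_seqs(chrom: str, a: int, b: int, strand: str) -> tuple[str, str]:
        seq = truth.chromosomes[chrom]
        if strand == "+":
            return seq[a:a + tag_len], seq[b - tag_len:b]
        return revcomp(seq[b - tag_len:b]), revcomp(seq[a:a + tag_len])

    def placement_ok(chrom: str, a: int, b: int, strand: str):
        """Return projected 5'/3' tag alignments or None."""
        if strand == "+":
            iv5, iv3 = (a, a + tag_len), (b - tag_len, b)
        else:
            iv5, iv3 = (b - tag_len, b), (a, a + tag_len)
        p5 = truth.project_tag(chrom, iv5[0], iv5[1], strand)
        p3 = truth.project_tag(chrom, iv3[0], iv3[1], strand)
        if p5 is None or p3 is None:
            return None
        if not allow_split and p5.ref != p3.ref:
            return None
        t5, t3 = tag_seqs(chrom, a, b, strand)
        # genomic near-signatures inside or at the edge of the 5' tag
        # cannot always be patched by the filler; reject the placement
        if _min_hamming(t5, signature) < 4:
            return None
        try:
            clean_filler(read_len - tag_len, t5)
        except RuntimeError:
            return None
        return p5, p3, t5, t3

    gene_idx = 0
    filler_alphabet = "ACGT"

    def clean_filler(n: int, prefix: str) -> str:
        """Random filler keeping every window of prefix+filler far from signature."""
        for _ in range(50):
            f = "".join(
                filler_alphabet[int(x)] for x in rng.integers(0, 4, size=n)
            )
            if _min_hamming(prefix[-(len(signature) - 1):] + f, signature) >= 4:
                return f
        raise RuntimeError("could not draw clean filler")

    def random_filler(n: int) -> str:
        return "".join(
            filler_alphabet[int(x)] for x in rng.integers(0, 4, size=n)
        )

    for ci, chrom in enumerate(chrom_names):
        L = len(truth.chromosomes[chrom])
        cursor = spacing
        while gene_idx < n_genes and cursor + span_range[1] + spacing < L:
            span = int(rng.integers(span_range[0], span_range[1] + 1))
            a, b = cursor, cursor + span
            strand = "+" if rng.random() < 0.5 else "-"
            placed = placement_ok(chrom, a, b, strand)
            if placed is None:
                cursor += spacing
                continue
            p5, p3, t5seq, t3seq = placed
            gene_id = f"tx_{gene_idx}"
            expressed = rng.random() >= silent_frac
            n_dt = max(ditag_min, int(rng.poisson(ditag_mean))) if expressed else 0

            if p5.ref == p3.ref:
                s_lo = min(p5.start, p3.start)
                s_hi = max(p5.end, p3.end)
                s_strand = p5.strand
                tss = p5.start if s_strand == "+" else p5.end - 1
                tts = p3.end - 1 if s_strand == "+" else p3.start
            else:
                s_lo, s_hi = 0, 0
                s_strand = p5.strand
                tss = p5.start if p5.strand == "+" else p5.end - 1
                tts = p3.end - 1 if p3.strand == "+" else p3.start

            # ditag reads
            for k in range(n_dt):
                r5 = t5seq + clean_filler(read_len - tag_len, t5seq)
                r3 = t3seq + signature + random_filler(
                    read_len - tag_len - len(signature))
                r5 = _apply_errors(rng, r5, error_rate)
                r3 = _apply_errors(rng, r3, error_rate)
                if rng.random() < 0.5:
                    pair = MappedTagPair(f"{gene_id}:{k}", "rnapet",
                                         p5, p3, payload=(r5, r3))
                else:
                    pair = MappedTagPair(f"{gene_id}:{k}", "rnapet",
                                         p3, p5, payload=(r3, r5))
                ditags.append(pair)

            # RNA-Seq coverage (single-scaffold transcripts only)
            if expressed and p5.ref == p3.ref:
                n_reads = int(round(rnaseq_reads_per_kb * span / 1000.0))
                for _ in range(n_reads):
                    rs = int(rng.integers(a, max(a + 1, b - rnaseq_read_len)))
                    pr = truth.project_interval(
                        chrom, rs, min(rs + rnaseq_read_len, b))
                    if pr is not None:
                        ref, ps, pe = pr
                        coverage[ref][ps:pe] += 1.0

            # truncated old annotation (anchored at the 5' end)
            truncated = bool(rng.random() < truncate_frac)
            old_ann = None
            if p5.ref == p3.ref:
                new_span = s_hi - s_lo
                factor = truncate_ratio if truncated else 1.08
                old_span = max(200, int(round(new_span / factor)))
                if s_strand == "+":
                    o_lo, o_hi = s_lo, s_lo + old_span
                else:
                    o_lo, o_hi = s_hi - old_span, s_hi
                old_ann = GeneAnnotation(f"old_{gene_id}", p5.ref, o_lo, o_hi,
                                         s_strand, source="existing")
                old.append(old_ann)

            transcripts.append(
                TranscriptTruth(
                    gene_id, chrom, a, b, strand, p5.ref, p3.ref,
                    s_lo, s_hi, s_strand, tss, tts, n_dt, expressed,
                    truncated, old_ann,
                )
            )
            gene_idx += 1
            cursor = b + spacing
        if gene_idx >= n_genes:
            break
    if gene_idx < n_genes:
        raise ValueError(
            f"could only place {gene_idx} of {n_genes} transcripts; "
            "increase chromosome length"
        )
    return SimulatedTranscriptome(ditags, coverage, old, transcripts)
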