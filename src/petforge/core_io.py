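"""Domain types shared by all stages, plus readers/writers for standard formats.

Internal coordinate convention is 0-based half-open everywhere.  BED and
bedGraph are native to that convention; GFF3 and AGP are converted to
1-based inclusive on write (and back on read).

A "tag" is one mapped end of a sequenced fragment; a :class:`MappedTagPair`
is the atom of both the mate-pair (genomic) and the ditag (transcript)
analyses.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GapEstimate",
    "AssemblyGap",
    "ScaffoldRecord",
    "TagAlignment",
    "MappedTagPair",
    "LibraryProfile",
    "GeneAnnotation",
    "TagPairStats",
    "read_assembly",
    "write_assembly",
    "read_tag_pairs",
    "write_tag_table",
    "write_sam",
    "read_bed",
    "write_bed",
    "read_gff3",
    "write_gff3",
    "read_agp",
    "write_agp",
    "read_bedgraph",
    "write_bedgraph",
]

_GAP_RE = re.compile(r"[Nn]+")

MAX_TAG_LEN = 36


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GapEstimate:
    """One length estimate for an assembly gap.

    ``mean_len`` may legitimately be negative (structural polymorphism
    between the sequenced sample and the reference); negative values are
    flagged rather than clamped.
    """

    mean_len: float
    median_len: float
    n_support: int
    component_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.n_support < 1:
            raise ValueError("n_support must be >= 1")
        if not (0.0 <= self.component_weight <= 1.0):
            raise ValueError("component_weight must be in [0, 1]")

    @property
    def polymorphic(self) -> bool:
        """True when the estimated length is negative."""
        return self.mean_len < 0


@dataclass
class AssemblyGap:
    """A run of N's inside a scaffold, 0-based half-open."""

    scaffold: str
    start: int
    end: int
    estimates: list[GapEstimate] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"gap end must exceed start ({self.start}, {self.end})")

    @property
    def annotated_len(self) -> int:
        return self.end - self.start


@dataclass
class ScaffoldRecord:
    """A scaffold with its ordered assembly gaps.

    ``sequence`` is optional; when present it must agree with ``length``
    and every gap interval must contain only N/n.
    """

    name: str
    length: int
    gaps: list[AssemblyGap] = field(default_factory=list)
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"scaffold {self.name}: length must be >= 1")
        prev_end = 0
        for i, g in enumerate(self.gaps):
            if g.scaffold != self.name:
                raise ValueError(f"gap {i} belongs to {g.scaffold}, not {self.name}")
            if g.start < prev_end:
                raise ValueError(f"scaffold {self.name}: gaps overlap or unsorted")
            if g.end > self.length:
                raise ValueError(f"scaffold {self.name}: gap outside scaffold")
            prev_end = g.end
        if self.sequence is not None:
            if len(self.sequence) != self.length:
                raise ValueError(f"scaffold {self.name}: sequence/length mismatch")
            for g in self.gaps:
                if set(self.sequence[g.start:g.end]) - {"N", "n"}:
                    raise ValueError(
                        f"scaffold {self.name}: gap [{g.start},{g.end}) not all N"
                    )

    @property
    def is_degenerate(self) -> bool:
        """True when the scaffold is a single gap (all-N record)."""
        return len(self.gaps) == 1 and self.gaps[0].annotated_len == self.length


@dataclass(frozen=True)
class TagAlignment:
    """One mapped tag: reference, 0-based half-open interval, strand."""

    ref: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("tag end must exceed start")
        if self.end - self.start > MAX_TAG_LEN:
            raise ValueError(f"tag longer than {MAX_TAG_LEN}bp")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be + or -")


@dataclass
class MappedTagPair:
    """Two mapped tags from one sequenced fragment.

    ``payload`` optionally carries the two read sequences (used by the
    ditag signature search).
    """

    pair_id: str
    library_id: str
    tag1: TagAlignment
    tag2: TagAlignment
    payload: tuple[str, str] | None = None

    def span(self) -> int:
        """Fragment span on the reference, valid only for same-ref pairs."""
        if self.tag1.ref != self.tag2.ref:
            raise ValueError("span undefined for pairs on different references")
        return max(self.tag1.end, self.tag2.end) - min(self.tag1.start, self.tag2.start)

    def fragment_interval(self) -> tuple[str, int, int]:
        """(ref, start, end) covered by the implied fragment (same-ref only)."""
        if self.tag1.ref != self.tag2.ref:
            raise ValueError("fragment interval undefined across references")
        return (
            self.tag1.ref,
            min(self.tag1.start, self.tag2.start),
            max(self.tag1.end, self.tag2.end),
        )

    def coord_key(self) -> tuple:
        """Deduplication key: both tag coordinates and strands."""
        t1 = (self.tag1.ref, self.tag1.start, self.tag1.end, self.tag1.strand)
        t2 = (self.tag2.ref, self.tag2.start, self.tag2.end, self.tag2.strand)
        return (t1, t2)


@dataclass(frozen=True)
class LibraryProfile:
    """Insert-size expectations for one mate-pair library."""

    library_id: str
    expected_insert_mean: float
    concordant_span_min: int
    concordant_span_max: int

    def __post_init__(self) -> None:
        if not (0 < self.concordant_span_min < self.expected_insert_mean
                < self.concordant_span_max):
            raise ValueError(
                "require 0 < span_min < expected_insert_mean < span_max"
            )


@dataclass
class GeneAnnotation:
    """A gene interval from an existing or newly derived annotation."""

    gene_id: str
    ref: str
    start: int
    end: int
    strand: str
    source: str = "existing"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("gene end must exceed start")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be + or -")

    @property
    def span(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _gaps_from_sequence(name: str, seq: str) -> list[AssemblyGap]:
    return [AssemblyGap(name, m.start(), m.end()) for m in _GAP_RE.finditer(seq)]


def read_assembly(fasta_path: str | Path) -> list[ScaffoldRecord]:
    """Read a draft assembly; every maximal N/n run becomes an AssemblyGap.

    Raises ``ValueError`` on duplicate scaffold names or an empty file.
    """
    records: list[ScaffoldRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate scaffold name: {rec.id}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"scaffold {rec.id} has empty sequence")
        records.append(
            ScaffoldRecord(rec.id, len(seq), _gaps_from_sequence(rec.id, seq), seq)
        )
    if not records:
        raise ValueError(f"no sequences found in {fasta_path}")
    return records


def write_assembly(path: str | Path, scaffolds: Iterable[ScaffoldRecord]) -> None:
    recs = []
    for s in scaffolds:
        if s.sequence is None:
            raise ValueError(f"scaffold {s.name} has no sequence to write")
        recs.append(SeqRecord(Seq(s.sequence), id=s.name, description=""))
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# tag pairs (TSV tag table and SAM)
# ---------------------------------------------------------------------------

TAG_TABLE_COLUMNS = (
    "pair_id", "lib",
    "ref1", "start1", "end1", "strand1",
    "ref2", "start2", "end2", "strand2",
)
# two optional trailing columns carry the read sequences (ditag payloads)
TAG_TABLE_PAYLOAD_COLUMNS = TAG_TABLE_COLUMNS + ("read1", "read2")


@dataclass
class TagPairStats:
    """Bookkeeping from a tag-pair read pass."""

    n_pairs: int = 0
    n_orphans: int = 0
    n_unknown_ref: int = 0


def write_tag_table(path: str | Path, pairs: Iterable[MappedTagPair],
                    include_payload: bool = False) -> None:
    """Write pairs as a TSV tag table (with header).

    ``include_payload`` appends the two read sequences as extra columns
    (used for ditag data, where the signature search needs the reads).
    """
    cols = TAG_TABLE_PAYLOAD_COLUMNS if include_payload else TAG_TABLE_COLUMNS
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(cols) + "\n")
        for p in pairs:
            fields = [
                p.pair_id, p.library_id,
                p.tag1.ref, p.tag1.start, p.tag1.end, p.tag1.strand,
                p.tag2.ref, p.tag2.start, p.tag2.end, p.tag2.strand,
            ]
            if include_payload:
                if p.payload is None:
                    raise ValueError(f"pair {p.pair_id} has no payload")
                fields.extend(p.payload)
            fh.write("\t".join(str(x) for x in fields) + "\n")


def _read_tag_table(path: str | Path, known_refs: set[str] | None,
                    stats: TagPairStats) -> list[MappedTagPair]:
    out: list[MappedTagPair] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) not in (len(TAG_TABLE_COLUMNS),
                              len(TAG_TABLE_PAYLOAD_COLUMNS)):
                raise ValueError(f"malformed tag-table line: {line!r}")
            pid, lib, r1, s1, e1, st1, r2, s2, e2, st2 = f[:10]
            payload = (f[10], f[11]) if len(f) == 12 else None
            if known_refs is not None and (r1 not in known_refs or r2 not in known_refs):
                stats.n_unknown_ref += 1
                continue
            out.append(
                MappedTagPair(
                    pid, lib,
                    TagAlignment(r1, int(s1), int(e1), st1),
                    TagAlignment(r2, int(s2), int(e2), st2),
                    payload=payload,
                )
            )
            stats.n_pairs += 1
    return out


def _read_sam(path: str | Path, known_refs: set[str] | None, library_id: str,
              stats: TagPairStats) -> list[MappedTagPair]:
    import pysam

    by_name: dict[str, list] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.reference_name is None:
                stats.n_orphans += 1
                continue
            by_name.setdefault(aln.query_name, []).append(aln)
    out: list[MappedTagPair] = []
    for name in sorted(by_name):
        alns = by_name[name]
        if len(alns) != 2:
            stats.n_orphans += len(alns)
            continue
        a, b = alns
        if a.is_read2 and b.is_read1:
            a, b = b, a
        refs = (a.reference_name, b.reference_name)
        if known_refs is not None and any(r not in known_refs for r in refs):
            stats.n_unknown_ref += 1
            continue
        lib = a.get_tag("RG") if a.has_tag("RG") else library_id
        out.append(
            MappedTagPair(
                name, lib,
                TagAlignment(a.reference_name, a.reference_start,
                             a.reference_end, "-" if a.is_reverse else "+"),
                TagAlignment(b.reference_name, b.reference_start,
                             b.reference_end, "-" if b.is_reverse else "+"),
            )
        )
        stats.n_pairs += 1
    return out


def read_tag_pairs(path: str | Path, fmt: str = "table",
                   known_refs: set[str] | None = None,
                   library_id: str = "lib0",
                   ) -> tuple[list[MappedTagPair], TagPairStats]:
    """Read mapped tag pairs from a TSV tag table or a SAM file.

    Only pairs with both mates mapped are returned; orphans and pairs on
    unknown references are counted in the returned :class:`TagPairStats`.
    """
    stats = TagPairStats()
    if fmt == "table":
        pairs = _read_tag_table(path, known_refs, stats)
    elif fmt in ("sam", "alignment"):
        pairs = _read_sam(path, known_refs, library_id, stats)
    else:
        raise ValueError(f"unknown tag-pair format: {fmt}")
    return pairs, stats


def write_sam(path: str | Path, pairs: Iterable[MappedTagPair],
              ref_lengths: dict[str, int]) -> None:
    """Write pairs as paired SAM records (testing/interoperability helper)."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": length} for name, length in ref_lengths.items()],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        tid = {name: i for i, name in enumerate(ref_lengths)}
        for p in pairs:
            for idx, tag in ((1, p.tag1), (2, p.tag2)):
                a = pysam.AlignedSegment()
                a.query_name = p.pair_id
                a.reference_id = tid[tag.ref]
                a.reference_start = tag.start
                a.cigarstring = f"{tag.end - tag.start}M"
                a.query_sequence = "A" * (tag.end - tag.start)
                a.flag = (
                    0x1 | (0x40 if idx == 1 else 0x80)
                    | (0x10 if tag.strand == "-" else 0)
                )
                a.set_tag("RG", p.library_id)
                out.write(a)


# ---------------------------------------------------------------------------
# BED / bedGraph
# ---------------------------------------------------------------------------

def write_bed(path: str | Path,
              intervals: Iterable[tuple]) -> None:
    """Write BED records.

    Each interval is ``(ref, start, end)`` or BED6
    ``(ref, start, end, name, score, strand)``.
    """
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write("\t".join(str(x) for x in iv) + "\n")


def read_bed(path: str | Path) -> list[tuple]:
    """Read BED3/BED6 records, numeric fields converted."""
    out: list[tuple] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) >= 6:
                out.append((f[0], int(f[1]), int(f[2]), f[3], int(f[4]), f[5]))
            else:
                out.append((f[0], int(f[1]), int(f[2])))
    return out


def write_bedgraph(path: str | Path, tracks: dict[str, Sequence[float]]) -> None:
    """Write per-base coverage arrays as run-length-compressed bedGraph."""
    with open(path, "w") as fh:
        for ref in sorted(tracks):
            vals = tracks[ref]
            run_start = 0
            for i in range(1, len(vals) + 1):
                if i == len(vals) or vals[i] != vals[run_start]:
                    v = vals[run_start]
                    if v != 0:
                        fh.write(f"{ref}\t{run_start}\t{i}\t{v:g}\n")
                    run_start = i


def read_bedgraph(path: str | Path, ref_lengths: dict[str, int]):
    """Read a bedGraph into dense per-base float arrays (zeros elsewhere)."""
    import numpy as np

    tracks = {ref: np.zeros(n, dtype=float) for ref, n in ref_lengths.items()}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            ref, s, e, v = line.rstrip("\n").split("\t")
            if ref not in tracks:
                raise ValueError(f"bedGraph reference {ref} not in assembly")
            tracks[ref][int(s):int(e)] = float(v)
    return tracks


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def write_gff3(path: str | Path, genes: Iterable[GeneAnnotation],
               source: str = "petforge") -> None:
    """Write gene intervals as GFF3 (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id};source_tag={g.source}"
            fh.write(
                "\t".join(
                    [g.ref, source, "gene", str(g.start + 1), str(g.end),
                     ".", g.strand, ".", attrs]
                )
                + "\n"
            )


def read_gff3(path: str | Path) -> list[GeneAnnotation]:
    out: list[GeneAnnotation] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 9 or f[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            out.append(
                GeneAnnotation(
                    attrs.get("ID", "."), f[0], int(f[3]) - 1, int(f[4]),
                    f[6], attrs.get("source_tag", "existing"),
                )
            )
    return out


# ---------------------------------------------------------------------------
# AGP v2.0
# ---------------------------------------------------------------------------

def write_agp(path: str | Path, objects: Iterable[tuple]) -> None:
    """Write AGP v2.0.

    ``objects`` yields ``(object_name, components)`` where components is an
    ordered list mixing ``("W", comp_id, comp_len, orient)`` sequence parts
    and ``("U", gap_len)`` / ``("N", gap_len)`` gap parts.  Object
    coordinates are derived. Gap lengths must be >= 1.
    """
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.0\n")
        for obj_name, components in objects:
            pos = 0
            for i, comp in enumerate(components, start=1):
                kind = comp[0]
                if kind == "W":
                    _, comp_id, comp_len, orient = comp
                    if comp_len < 1:
                        raise ValueError("component length must be >= 1")
                    fh.write(
                        "\t".join(
                            [obj_name, str(pos + 1), str(pos + comp_len), str(i),
                             "W", comp_id, "1", str(comp_len), orient]
                        )
                        + "\n"
                    )
                    pos += comp_len
                elif kind in ("N", "U"):
                    gap_len = comp[1]
                    if gap_len < 1:
                        raise ValueError("AGP gap length must be >= 1")
                    fh.write(
                        "\t".join(
                            [obj_name, str(pos + 1), str(pos + gap_len), str(i),
                             kind, str(gap_len), "scaffold", "yes", "paired-ends"]
                        )
                        + "\n"
                    )
                    pos += gap_len
                else:
                    raise ValueError(f"unknown AGP component kind {kind}")


def read_agp(path: str | Path) -> list[tuple]:
    """Inverse of :func:`write_agp` (round-trip on the fields it carries)."""
    objects: dict[str, list] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            name = f[0]
            if name not in objects:
                objects[name] = []
                order.append(name)
            if f[4] == "W":
                objects[name].append(("W", f[5], int(f[7]), f[8]))
            else:
                objects[name].append((f[4], int(f[5])))
    return [(name, objects[name]) for name in order]
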