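"""End-to-end workflows with config validation and run manifests."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from . import core_io, dnapet_qc, metagene, rescaffold, rnapet_annot
from .core_io import LibraryProfile

__all__ = ["RunConfig", "run_rescaffold_pipeline", "run_annotation_pipeline"]


@dataclass
class RunConfig:
    """Resolved parameters for one pipeline run.

    Unknown keys are rejected at load time; every run writes a manifest
    echoing the resolved config and tool version next to its outputs.
    """

    out_dir: str = "petforge_out"
    seed: int = 0
    # inputs
    assembly: str | None = None
    dnapet_tables: list[str] = field(default_factory=list)
    libraries: list[dict] = field(default_factory=list)  # LibraryProfile kwargs
    insert_sd: float | None = None
    rnapet_table: str | None = None
    rnaseq_bedgraph: str | None = None
    existing_gff3: str | None = None
    # stage parameters (documented defaults)
    window: int = 20_000
    min_support: int = 5
    min_n_run: int = 10_000
    repeat_window: int = 1_000
    repeat_max: int = 500
    min_edge_weight: int = 4
    signature: str = rnapet_annot.DEFAULT_SIGNATURE
    max_mismatch: int = 2
    min_span: int = 2_000
    min_reads_per_kb: float = 5.0
    slack_relaxed: int = 1_000
    merge_radius: int = 10
    rnaseq_read_len: int = 75
    body_bins: int = 100
    flank_bp: int = 10_000

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc)

    def library_profiles(self) -> list[LibraryProfile]:
        return [LibraryProfile(**kw) for kw in self.libraries]

    def write_manifest(self, out_dir: Path, stage: str, extra: dict) -> None:
        manifest = {
            "tool": "petforge",
            "version": __version__,
            "stage": stage,
            "config": dataclasses.asdict(self),
            **extra,
        }
        with open(out_dir / f"manifest_{stage}.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)


def _require(value, name: str, stage: str):
    if value is None or value == []:
        raise FileNotFoundError(f"stage {stage}: missing input '{name}'")
    return value


def run_rescaffold_pipeline(config: RunConfig) -> dict:
    """classify -> insert-size -> gap-estimate -> breakpoints -> split ->
    mask -> edges -> chains -> stats, writing all artifacts to out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scaffolds = core_io.read_assembly(
        _require(config.assembly, "assembly", "rescaffold"))
    refs = {s.name for s in scaffolds}
    lengths = {s.name: s.length for s in scaffolds}
    libs = config.library_profiles()
    _require(libs, "libraries", "rescaffold")
    tables = _require(config.dnapet_tables, "dnapet_tables", "rescaffold")

    all_gaps = [g for s in scaffolds for g in s.gaps]
    per_lib = {}
    cpets_all: list = []
    dpets_diff: list = []
    all_tags: list = []
    gap_rows = []
    for lib, table in zip(libs, tables):
        pairs, stats = core_io.read_tag_pairs(table, "table", known_refs=refs)
        pairs = dnapet_qc.dedupe_pairs(pairs)
        classes = dnapet_qc.classify_pairs(pairs, lib)
        cpets = classes[dnapet_qc.PetClass.CPET]
        insert_mean, insert_sd = (
            dnapet_qc.estimate_insert_size(cpets)
            if len(cpets) >= 30 else (lib.expected_insert_mean, float("nan"))
        )
        report = dnapet_qc.estimate_gap_sizes(
            cpets, all_gaps, lib, config.min_support,
            expected_insert_mean=insert_mean)
        for g in all_gaps:
            for est in g.estimates:
                gap_rows.append(
                    (g.scaffold, g.start, g.end, g.annotated_len,
                     lib.library_id, f"{est.mean_len:.1f}",
                     f"{est.median_len:.1f}", est.n_support,
                     f"{est.component_weight:.3f}")
                )
        per_lib[lib.library_id] = {
            "n_pairs": len(pairs),
            "n_cpet": len(cpets),
            "n_dpet_same": len(classes[dnapet_qc.PetClass.DPET_SAME_REF]),
            "n_dpet_diff": len(classes[dnapet_qc.PetClass.DPET_DIFF_REF]),
            "insert_mean": insert_mean,
            "insert_sd": insert_sd,
            "gap_report": dataclasses.asdict(report),
            "read_stats": dataclasses.asdict(stats),
        }
        cpets_all.extend(cpets)
        dpets_diff.extend(classes[dnapet_qc.PetClass.DPET_DIFF_REF])
        for p in pairs:
            all_tags.append((p.tag1.ref, p.tag1.start))
            all_tags.append((p.tag2.ref, p.tag2.start))

    with open(out / "gap_estimates.tsv", "w") as fh:
        fh.write("#scaffold\tstart\tend\tannotated\tlib\test_mean\t"
                 "est_median\tn\tweight\n")
        for row in gap_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")

    margin = max(l.concordant_span_max for l in libs)
    breakpoints = []
    for s in scaffolds:
        cov = dnapet_qc.per_base_fragment_coverage(cpets_all, s)
        track = dnapet_qc.CoverageTrack(s.name, 0, 1, cov, "per_base_fragment")
        breakpoints.extend(
            dnapet_qc.detect_breakpoints(track, s.gaps, dpets_diff, libs[0],
                                         terminal_margin=margin)
        )
    core_io.write_bed(
        out / "breakpoints.bed",
        [(b.scaffold, b.start, b.end) for b in breakpoints],
    )

    fragments, removed = rescaffold.split_at_gaps(
        scaffolds, cpets_all, config.min_n_run)
    fragments, provenance, _ = rescaffold.split_at_breakpoints(
        fragments, breakpoints)
    masked = rescaffold.mask_repeats(
        all_tags, config.repeat_window, config.repeat_max)
    dpets_use = rescaffold.exclude_masked_pairs(dpets_diff, masked)
    edges = rescaffold.build_edges(
        dpets_use, fragments, {l.library_id: l for l in libs},
        config.min_edge_weight)
    prov_edges = [
        rescaffold.GraphEdge((a, rescaffold.TAIL), (b, rescaffold.HEAD),
                             1, "provenance", "provenance")
        for a, b in provenance
    ]
    chains = rescaffold.chain_scaffolds(edges + prov_edges, fragments)

    frag_len = {f.fragment_id: f.length for f in fragments}
    agp_objects = []
    chain_rows = []
    for ci, chain in enumerate(chains):
        comps: list[tuple] = []
        for k, (fid, orient) in enumerate(chain.fragments):
            comps.append(("W", fid, frag_len[fid], orient))
            if k < len(chain.gap_estimates):
                est = chain.gap_estimates[k]
                gap_len = max(1, int(round(est))) if est is not None else 100
                comps.append(("U", gap_len))
        agp_objects.append((f"hyperscaffold_{ci}", comps))
        chain_rows.append(
            (f"hyperscaffold_{ci}", len(chain), chain.score,
             ",".join(f"{f}{o}" for f, o in chain.fragments))
        )
    core_io.write_agp(out / "hyperscaffolds.agp", agp_objects)
    with open(out / "chains.tsv", "w") as fh:
        fh.write("#chain\tn_fragments\tscore\tpath\n")
        for row in chain_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")

    fills = rescaffold.fill_gaps(chains, removed, fragments)
    after_lengths = [
        sum(frag_len[f] for f, _ in chain.fragments) for chain in chains
    ]
    stats = rescaffold.assembly_stats(lengths.values(), after_lengths)
    result = {
        "per_library": per_lib,
        "n_breakpoints": len(breakpoints),
        "n_fragments": len(fragments),
        "n_edges": len(edges),
        "n_chains": len(chains),
        "n_gap_fills": len(fills),
        "assembly_stats": stats,
    }
    config.write_manifest(out, "rescaffold", {"result_summary": {
        k: v for k, v in result.items() if k != "per_library"}})
    with open(out / "rescaffold_report.json", "w") as fh:
        json.dump(result, fh, indent=2, sort_keys=True, default=float)
    return result


def run_annotation_pipeline(config: RunConfig) -> dict:
    """classify -> cluster (both sets) -> promote -> filter -> coalesce ->
    compare -> metagene, writing all artifacts to out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pairs, _ = core_io.read_tag_pairs(
        _require(config.rnapet_table, "rnapet_table", "annotation"), "table")
    oriented, ht_counts = rnapet_annot.orient_pairs(
        pairs, config.signature, config.max_mismatch)
    if not oriented:
        import sys

        print("petforge: warning: no HT ditags found; "
              "gene set will be empty", file=sys.stderr)
    stringent = rnapet_annot.cluster_pets(
        oriented, rnapet_annot.ClusterParams(0, "stringent"))
    relaxed = rnapet_annot.cluster_pets(
        oriented, rnapet_annot.ClusterParams(config.slack_relaxed, "relaxed"))

    coverage: dict[str, np.ndarray] = {}
    if config.rnaseq_bedgraph:
        ref_lengths: dict[str, int] = {}
        if config.assembly:
            ref_lengths = {
                s.name: s.length
                for s in core_io.read_assembly(config.assembly)
            }
        else:
            for c in stringent + relaxed:
                ref_lengths[c.ref] = max(ref_lengths.get(c.ref, 0), c.end + 1)
        coverage = core_io.read_bedgraph(config.rnaseq_bedgraph, ref_lengths)

    promoted = rnapet_annot.promote(
        stringent, relaxed, coverage,
        min_reads_per_kb=config.min_reads_per_kb,
        read_len=config.rnaseq_read_len)
    kept = rnapet_annot.filter_clusters(
        promoted, coverage if coverage else None, config.min_span,
        config.min_reads_per_kb, config.rnaseq_read_len)
    genes = rnapet_annot.coalesce(kept, config.merge_radius)

    core_io.write_gff3(
        out / "genes.gff3",
        [core_io.GeneAnnotation(g.gene_id, g.ref, g.start, g.end, g.strand,
                                "rnapet") for g in genes],
    )
    core_io.write_bed(
        out / "tss.bed",
        [(g.ref, p, p + 1, g.gene_id, 0, g.strand)
         for g in genes for p in g.tss_set],
    )
    core_io.write_bed(
        out / "tts.bed",
        [(g.ref, p, p + 1, g.gene_id, 0, g.strand)
         for g in genes for p in g.tts_set],
    )

    result: dict = {
        "ht_counts": ht_counts,
        "n_clusters_stringent": len(stringent),
        "n_clusters_relaxed": len(relaxed),
        "n_clusters_kept": len(kept),
        "n_genes": len(genes),
        "n_tss": sum(len(g.tss_set) for g in genes),
    }
    if config.existing_gff3:
        existing = core_io.read_gff3(config.existing_gff3)
        comparison = rnapet_annot.compare_annotation(
            genes, existing, coverage if coverage else None)
        with open(out / "comparison.tsv", "w") as fh:
            fh.write("#gene_id\told_id\tnew_span\told_span\tratio\textended\n")
            for m in comparison["matches"]:
                fh.write(
                    f"{m['gene_id']}\t{m['old_id']}\t{m['new_span']}\t"
                    f"{m['old_span']}\t{m['ratio']:.3f}\t{int(m['extended'])}\n"
                )
        result["comparison"] = {
            k: v for k, v in comparison.items() if k != "matches"}
        if coverage:
            profile = metagene.metagene_profile(
                coverage, existing, config.body_bins, config.flank_bp)
            with open(out / "metagene.tsv", "w") as fh:
                fh.write("#bin\tdensity\n")
                for i, d in enumerate(profile.densities):
                    fh.write(f"{i}\t{d:.6g}\n")
            result["metagene_n_genes"] = profile.n_genes
    config.write_manifest(out, "annotation", {"result_summary": {
        k: v for k, v in result.items() if k != "comparison"}})
    with open(out / "annotation_report.json", "w") as fh:
        json.dump(result, fh, indent=2, sort_keys=True, default=float)
    return result
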