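# petforge

A toolkit for improving draft genome assemblies and gene annotations with
paired-end-tag (PET) sequencing data:

* **DNA mate pairs (DNA-PET)** — classify pairs as concordant/discordant,
  re-estimate the true lengths of placeholder assembly gaps (including
  biallelic, bimodal cases), detect mis-assembly breakpoints from
  zero-coverage intervals, and chain scaffold fragments into
  hyper-scaffolds through a conflict-aware weighted graph.
* **Transcript ditags (RNA-PET)** — recognise the 3'-end signature
  (`AACTGCTG`, ≤2 mismatches) to orient ditags, cluster 5' tags into
  transcript-boundary clusters under stringent/relaxed parameters with a
  promotion step, filter noise (span < 2Kb, < 5 RNA-Seq reads/Kb),
  coalesce clusters into gene models with TSS/TTS sets, and compare
  against an existing annotation (>×1.3 or >5Kb extension reporting).
* **Metagene profiles** — mass-preserving density profiles over
  normalized gene bodies with fixed 10Kb flanks, and TSS-proximal
  peak-offset measurement.
* **Synthetic data** — a fully deterministic generator for ground-truth
  genomes (fragmented scaffolds, mis-annotated gaps, chimeric mis-joins,
  reverse-complemented scaffolds), mate-pair libraries, signature-bearing
  ditags and RNA-Seq coverage, with exact coordinate maps for
  parameter-recovery tests.

## Layout

```
src/petforge/
  core_io.py       domain types + FASTA/SAM/TSV/BED/GFF3/AGP/bedGraph IO
  dnapet_qc.py     pair classification, insert size, coverage, gap sizes,
                   breakpoints
  rescaffold.py    scaffold splitting, repeat masking, edge building,
                   chain search, assembly statistics
  rnapet_annot.py  signature search, clustering, promotion, filtering,
                   coalescing, annotation comparison
  metagene.py      metagene profiles and TSS peak offsets
  simdata.py       synthetic-truth generators
  pipeline.py      end-to-end workflows with YAML config + manifests
  cli.py           `petforge` command-line entry point
```

## CLI

```bash
petforge simulate genome --seed 1 --chrom-len 1000000 --n-fragments 20 \
    --out-fasta genome.fa --out-truth truth.json
petforge simulate dnapet --truth truth.json --seed 2 --out pairs.tsv
petforge dnapet classify pairs.tsv --lib-mean 9600 --span-min 5997 --span-max 11961
petforge dnapet gapsize pairs.tsv --assembly genome.fa \
    --lib-mean 9600 --span-min 5997 --span-max 11961 --out gaps.tsv
petforge rescaffold --config run.yaml     # full re-scaffolding pipeline
petforge rnapet --config run.yaml         # full annotation pipeline
petforge metagene --bedgraph cov.bg --genes genes.gff3 --assembly genome.fa \
    --out profile.tsv
petforge run --config run.yaml            # both pipelines
```

`run.yaml` holds a `RunConfig` (see `petforge/pipeline.py` for all keys
and defaults); unknown keys are rejected and every run writes a manifest
JSON echoing the resolved configuration.

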