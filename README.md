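# genefam

A tested, reusable pipeline for gene-family census and
duplication/divergence analysis of an annotated plant genome:

- **domain census** — profile-matrix scanning of a proteome against a
  packaged domain model, with a per-sequence shuffle null (E<1-style
  acceptance), truncation filtering and best-reference ortholog naming;
- **phylogeny** — affine-gap pairwise alignment, progressive multiple
  alignment, p-distances with pairwise gap deletion, neighbor joining
  with bootstrap supports, subfamily cutting and paralog-pair (cherry)
  extraction;
- **genome organization** — tandem-duplicate detection (≤5 intervening
  loci within 100 kb), identity confirmation of tandem pairs,
  homeologous-block retention classification
  (both-retained / one-sided / outside) and per-pair duplication-origin
  calls (tandem / segmental / untraceable-scaffold / divergent-blocks /
  outside-blocks);
- **gene structure** — exon/intron architecture, intron phases
  (cumulative CDS length mod 3) and structure-conservation comparison of
  duplicate pairs;
- **motifs** — ZOOPS (zero-or-one occurrence per sequence)
  expectation-maximization motif discovery with mask-and-repeat, motif
  maps and pair composition comparison;
- **expression** — digital-northern EST counting (identity > 96 %,
  alignment ≥ 100 bp), probe-median collapse, row-max / log2
  normalization, average-linkage clustering on 1 − Pearson distance,
  peak-tissue calls, duplicate-pair divergence classes
  (conserved / partially redundant / diverged) and ΔCt qPCR relative
  quantification;
- **synthetic data forge** — fully deterministic generator of annotated
  genomes with a planted domain family (subfamilies, paralog pairs,
  tandem arrays, homeologous blocks with partial retention, truncated
  pseudogene decoys), tissue-tagged EST libraries with planted near-miss
  identities, and expression matrices with controlled pair correlation —
  every downstream stage is tested against this planted truth.

## Command line

```sh
genefam --seed 1 --outdir out run-all          # forge inputs, run all stages
genefam --seed 1 --outdir out forge            # just forge inputs
genefam --outdir out census out/inputs/proteins.fasta \
        --references out/inputs/references.fasta
genefam --outdir out phylo out/inputs/proteins.fasta
genefam --outdir out structure out/inputs/genome.gff3
genefam --outdir out motifs out/inputs/proteins.fasta
genefam --outdir out expression out/inputs/expression.tsv
```

`run-all` accepts `--input-dir` with prepared files (`proteins.fasta`,
`cds.fasta`, `genome.gff3`, `blocks.tsv`, `est_manifest.tsv` + per-library
FASTA, `expression.tsv`, optional `probe_matrix.tsv`/`probe_map.tsv`,
`qpcr.tsv`); without it a synthetic genome is forged from the master
seed.  Reports are written as TSV/JSON under `--outdir`; `summary.json`
is byte-identical across reruns with the same config and seed.  Stage
thresholds live in a single JSON config (`--config`), defaulting to the
documented desk-scale values.

## Conventions

All genomic coordinates are GFF3-style 1-based inclusive.  Chromosome
labels starting with `LG_` are linkage groups; anything else is treated
as an unplaced scaffold and excluded from linkage-group statistics.
Percentages in reports use round-half-up and are audited against their
printed counts at report time.
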