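# chirpkit

Reusable pipeline for dual-probe ChIRP-seq consensus binding-site
inference with probe decontamination, genomic annotation, target-gene
expression integration, and Perseus-style label-free proteomics (LFQ)
enrichment statistics. Every stage can be exercised on fully synthetic,
seeded data — no downloads required.

## What it does

* **Coverage algebra** — bedGraph tracks as piecewise-constant signals;
  the "take-lower" merge (per-base minimum of the even and odd probe-set
  tracks) and summit localization.
* **Peak calling & consensus** — a simple Poisson scan-statistic caller
  (external narrowPeak files are accepted instead), even/odd pairing
  with a 200-bp maximum summit separation, and a three-replicate
  consensus intersection.
* **Probe decontamination** — each hybridization oligo becomes a
  log-odds matrix with an *exact* score-to-p-value table (dynamic
  programming over the discretized score distribution); sites matching
  a probe at p < 1e-8 on either strand are removed.
* **Annotation** — summit-based classification (promoter > TTS > exon >
  repeat class > intron > intergenic) and nearest-gene assignment.
* **Expression integration** — DE-status filters (FDR < 0.05,
  |stat| > 2), control-day-5 normalization, two-cluster hierarchical
  structure of putative targets, per-day lncRNA–target Pearson
  correlation, and a neural-candidate screen.
* **LFQ enrichment** — flag filtering, five-of-five completeness,
  down-shifted Gaussian imputation (d = 2, w = 0.2), the s0-moderated
  t statistic (s0 = 0.1) with a fully enumerated balanced-permutation
  FDR, fold-change/p-value enrichment classification (fc > 2,
  p < 0.002) and nuclear-compartment summaries. A worked-example
  interactor table ships with the package
  (`chirpkit.lfq.load_interactor_table`).
* **Synthetic data** — seeded generators for genomes, gene models,
  repeats, replicate coverage tracks with planted sites and
  probe-contaminant loci, expression matrices with planted regulation,
  and LFQ matrices with intensity-dependent missingness, all with truth
  tables.

## CLI

```sh
chirpkit simulate      --seed 1 --out sim/           # synthetic dataset
chirpkit merge-tracks  --even sim/chirp_rep1_even.bedgraph \
                       --odd  sim/chirp_rep1_odd.bedgraph \
                       --genome sim/genome.fa --out merged.bedgraph
chirpkit call-peaks    --track merged.bedgraph --genome sim/genome.fa --out rep1.narrowPeak
chirpkit consensus     --even e1.narrowPeak --odd o1.narrowPeak ... --out sites.bed
chirpkit probe-filter  --sites sites.bed --genome sim/genome.fa \
                       --probes sim/probes.fa --out filtered.bed
chirpkit annotate      --sites filtered.bed --genes sim/genes.gtf \
                       --repeats sim/repeats.bed --out annotations.tsv
chirpkit integrate     --expression sim/expression_tpm.tsv --samples sim/samples.tsv \
                       --de-day5 sim/de_day5.tsv --de-day7 sim/de_day7.tsv \
                       --targets annotations.tsv --lnc-gene lncG0000 --out targets.tsv
chirpkit lfq-enrich    --matrix sim/lfq_proteingroups.tsv --out enrichment.tsv
chirpkit run-all       --seed 1 --out run/            # everything end to end
```

`run-all` writes a `manifest.json` recording every parameter used and
input digests; reruns with the same seed are byte-identical.

## Conventions

All internal coordinates are 0-based half-open (BED); GTF is converted
at the parsing boundary. Chromosome names are taken verbatim — a
mismatch between input files is an error, never silently normalized.
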