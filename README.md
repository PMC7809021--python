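# tadlink

Linking differential chromatin accessibility to differential gene
expression through the 3D genome, with transcription-factor motif and
binding-redistribution statistics.

## The problem

When a cell changes state — here the motivating system is an oncogene-
transformed epithelial line compared against its parental line — thousands
of ATAC-seq peaks appear or disappear, and hundreds of genes change
expression. Assigning each regulatory element to its target gene by linear
proximity is wrong for distal enhancers. `tadlink` instead uses
**topologically associating domains (TADs)** as the regulatory unit: TAD
calls from several cell lines are merged into one (nested) reference set,
each gene is assigned to the *smallest* TAD overlapping its body, and
regulatory elements are interpreted within the TAD of the genes they
accompany.

On that scaffold the package implements the full integrative analysis:

- **Differential accessibility (DARs).** Read starts are Tn5-adjusted
  (+4/−5 bp), peaks are called with a sliding-window local-Poisson test
  (window 150 bp, shift 75 bp, local λ over 25 kb, p < 1e−4), and a
  *comparative* call — each condition tested against the other's local
  rate, scaled for depth — splits peaks into **gained** (transformed-
  specific), **lost** (parental-specific) and shared. A peak is a DAR only
  if it is significant in both its solo call and the comparative call.
- **Direction segregation of TADs.** A TAD is "up" if it contains
  up-regulated genes and no down-regulated ones (FDR < 0.05,
  |log2FC| > 0.5), "down" symmetrically, "mixed" if both. The statistic is
  the genomic overlap, in Mb, between the up-TAD and down-TAD footprints;
  a label permutation over the DE genes gives the empirical p-value
  p = (1 + #{null ≤ observed}) / (n_perm + 1). Low observed overlap means
  up- and down-regulated genes occupy distinct domains.
- **Peak density** per TAD (peaks/Mb) compared between up- and down-TADs
  by two-sided Mann–Whitney (exact for combined n ≤ 12 without ties).
- **Motif enrichment with swapped backgrounds.** Each peak's 150-bp
  max-count summit window is scanned on both strands with a log-odds PWM
  whose score threshold is calibrated *exactly* (dynamic programming on
  the discretised null score distribution, target 1e−4/bp/strand). The
  fraction of gained-DAR summits carrying a motif is tested against the
  lost-DAR summits (one-sided hypergeometric) and vice versa.
- **ChIP co-occupancy.** Binding sites are partitioned into shared and
  cell-type-specific by ≥1-bp overlap; DAR/ChIP overlap rates are
  compared gained-vs-lost with the two-proportion chi-square test (R
  `prop.test` semantics, Yates correction); signal heatmap matrices
  (±2 kb, 50-bp bins) are ordered by deterministic k-means.
- **p53-responsiveness stratification.** Down-regulated genes whose TAD
  harbours a lost DAR with a p53-motif summit are compared against all
  expressed genes on |log2FC| after Nutlin-3a treatment.
- **4C profiles.** Per-restriction-site counts summed in 50-kb windows
  with 25-kb steps.

Because the study's deposited sequencing data are not required, a
first-class **synthetic-data generator** produces a miniature genome with
TADs, genes, direction-segregated expression, planted DARs, motif-bearing
summit sequences, co-located ChIP peaks and a Nutlin table — together with
the machine-readable ground truth, so every stage is tested by parameter
recovery and null calibration rather than by fixtures.

## Worked example

```python
from tadlink import PipelineConfig, run
from tadlink.simulate import SimParams

cfg = PipelineConfig(sim=SimParams(seed=1), n_perm=1000, seed=1)
rep = run(cfg).report
```

With the default simulation (two 10-Mb chromosomes, 400 planted DARs,
direction homogeneity π = 0.95, 8× mean accessibility fold), the report's
key entries, formatted one per line, read:

```
DE genes: 11 up, 13 down
DARs: 203 gained, 203 lost, 127 shared
TADs: 7 up, 5 down
segregation: observed 0.00 Mb vs null mean 2.74 Mb, p = 0.000999
gained-DAR motif: 37.9% vs 5.4% in lost, p = 1.33e-16
lost-DAR motif: 43.8% vs 3.0% in gained, p = 3.66e-25
ChIP overlap: 68.5% of gained vs 6.4% of lost DARs, p = 1.29e-37
Nutlin |log2FC|, p53-linked down genes vs all: p = 1.36e-06
DAR recovery Jaccard vs planted truth: 0.985
```

Reading: up- and down-regulated genes segregate into non-overlapping TADs
(0 Mb shared footprint where ~2.7 Mb would be expected at random); the
motif planted in gained-DAR summits at rate 0.4 is recovered at 37.9%
against a ~5% background; ChIP peaks planted at 0.7/0.1 co-location come
back at 68.5%/6.4%; and the pipeline re-identifies 98.5% of the planted
DARs with matching direction.

A command-line interface mirrors the stages:

```bash
tadlink simulate --config sim.yaml --out data/
tadlink run --data data/ --seed 1 --out results/
tadlink call-peaks --data data/ --condition parental --out peaks.bed
tadlink dars --data data/ --out dars.bed
tadlink segregation --data data/ --n-perm 1000 --seed 1
tadlink fourc --sites sites.tsv --out profile.bedgraph
```

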