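# Methods

This note records the models, parameter choices and numerical conventions
behind `tadlink`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Coordinates and interval algebra

All coordinates are 0-based half-open (BED convention) everywhere in
memory; any 1-based dialect must be converted at the reader boundary.
Overlap between two intervals requires at least 1 bp — half-open abutment
is not overlap. Chromosome names match by exact string equality; no
"chr" aliasing is applied. These conventions remove the usual off-by-one
ambiguities from every downstream count.

## Differential expression

The DE table (gene, log2FC, FDR) is an input; only thresholding is done
here. A gene is *up* iff FDR < 0.05 and log2FC > 0.5, *down* iff
FDR < 0.05 and log2FC < −0.5, else *stable*. Both inequalities are strict,
so boundary genes are stable. The thresholds are configurable
(`DEThresholds`); an alternative convention of >1.3-fold with p < 0.05 can
be expressed as `DEThresholds(0.05, log2(1.3))`.

## Peak calling

A transparent fixed-window local-Poisson scan stands in for MACS, using
MACS's published parameter values (window 150 bp, step = window/2, shift
75 bp, llocal 25 kb, p < 1e−4, merge gap 100 bp). Design choices:

- Read starts are shifted to the Tn5 insertion centre: +4 bp on the plus
  strand, end −5 bp on the minus strand (configurable).
- Each 150-bp window counts reads within the ±75-bp-extended span
  (emulating `--shiftsize` with `--nomodel`). λ uses that same 300-bp
  span: λ = max(genome-wide rate, 25-kb local rate) × span. Using the bare
  window length for λ while counting over the extended span would
  mis-calibrate the null by ~2× and is deliberately avoided.
- A window is significant when the Poisson upper tail P(X ≥ k) falls below
  1e−4; overlapping or near-adjacent (≤100 bp) significant windows merge
  into one peak. The summit is the leftmost max-count 150-bp window inside
  the peak, found exhaustively.
- The comparative (DAR) call replaces λ with the *other* condition's rate,
  depth-scaled, taken as the maximum over four scales: genome-wide, the
  same 300-bp span, 5 kb and 25 kb. Including the small scales is what
  makes the comparative test reject regions equally enriched in both
  conditions (identical tracks produce zero DARs); using only the 25-kb
  scale would dilute a shared peak into its neighbourhood and miscall it.
  A peak is *gained* iff it appears in the transformed solo call and
  overlaps (≥1 bp) a significant transformed-over-parental comparative
  region; *lost* symmetrically; all remaining solo peaks are *shared*.

This caller is a stated approximation: it reproduces the published
parameters and the local-Poisson logic, not MACS's candidate-region
heuristics bit-for-bit.

## Gene-feature annotation

Promoters are strand-aware windows [TSS−1000, TSS+500) (mirrored on the
minus strand); mid-range regulatory windows span ±100 kb of the TSS. Each
peak receives exactly one label with priority promoter > midrange > far.

## TAD assignment and segregation

TAD sets from several cell lines are concatenated (exact-coordinate
duplicates dropped), deliberately keeping nested calls. Each gene gets the
*smallest* TAD overlapping its body by ≥1 bp; ties break by leftmost
start, then source label. TAD direction follows the DE calls of its
assigned genes (up / down / mixed / none).

The segregation statistic is the intersection, in Mb, of the up-TAD and
down-TAD genomic footprints, computed as |A| + |B| − |A ∪ B| over interval
unions. Mixed TADs belong to both footprints for this statistic (they are
the overlap) but are excluded from the up/down strata used by the density
and DAR-linkage analyses. The null shuffles up/down labels over the DE
genes, preserving the counts and the gene→TAD structure — the occupancy
pattern is the confounder being conditioned on. The empirical p-value uses
the +1 correction and is therefore never zero. A DE set with only one
direction is degenerate: observed and all permuted overlaps are 0 and the
test reports p = 1 rather than failing.

## Statistical kernel

- *Two-proportion test*: the 2×2 chi-square with Yates continuity
  correction, matching R's `prop.test` to 12 significant digits (verified
  against R 4.3); `correction=False` and a Fisher-exact fallback are
  provided.
- *Enrichment*: one-sided hypergeometric upper tail via `scipy`.
- *Mann–Whitney*: exact enumeration of all group assignments when
  combined n ≤ 12 and no ties; otherwise the normal approximation with
  tie correction and 0.5 continuity correction. A pooled sample with zero
  rank variance returns p = 1.
- *BH adjustment* is applied across motif panels in reports.

## Motif model

PWMs are log2-odds matrices over a background composition (default
uniform), pseudocount 0.25 per cell. The score threshold for scanning is
calibrated exactly: per-column scores are discretised at 0.01 bits, the
null score distribution of a random background k-mer is built by
convolution, and the threshold is the smallest grid score whose upper tail
is ≤ the target rate (default 1e−4 per bp per strand). Both strands of
each 150-bp summit window are scanned; windows containing N are skipped;
a window counts once regardless of the number of hits. Enrichment
contrasts the gained-DAR summits against the lost-DAR summits (and vice
versa) — the background *is* the opposing set, so no GC matching is
attempted, and the generator uses a single uniform base composition to
keep the calibration exact.

## ChIP, k-means and 4C

Shared vs cell-type-specific binding is presence/absence by ≥1-bp overlap
(an edgeR-style count model is out of scope). Signal matrices cover ±2 kb
around each summit in 50-bp bins; k-means (default k = 2) runs on rows
scaled to unit total, with farthest-point initialisation from a seeded
first pick, L2 metric, ≤100 iterations; clusters are renumbered by
decreasing mean raw signal so the ordering is deterministic given the
seed. 4C profiles sum per-restriction-site counts over 50-kb windows at
25-kb steps, windows anchored at multiples of the step.

## Nutlin stratification

`hras_down_p53` = down-regulated genes whose assigned TAD overlaps a lost
DAR whose summit carries a p53-motif hit. The response statistic is
|log2FC| after Nutlin-3a; each group is compared against all expressed
genes (which include the DE genes — the inclusive reading, exposed as the
natural set operations) and the p53-linked subset against all down genes.
Groups with fewer than two covered genes are excluded and flagged.

## Synthetic data: what it emulates, and with which numbers

Defaults (all in `SimParams`): two 10-Mb chromosomes; TADs 0.3–1.5 Mb;
3 cell-line variants, each splitting a random 30% of TADs (this exercises
the smallest-TAD rule); 3–8 genes per TAD (the human genome averages
roughly 7 genes per ~1-Mb TAD); DE concentrated in 35% of TADs with the
marginal DE fraction held at 0.2; TAD-level direction homogeneity π = 0.95,
interpolated so that π = 0.5 is *exactly* iid per-gene labels — i.e. the
permutation test's own null, which is what makes the null-calibration
suite meaningful; background 0.02 reads/bp per condition split over two
replicates; 200 planted DARs per direction plus 100 shared regions, 2 kb
each, mean fold 8× with lognormal dispersion (sd 0.5 log-units, floor 3×) —
the dispersion is what gives replicate-correlation QC its between-peak
variance; planted reads concentrate around the region centre (Gaussian,
sd 75 bp) so called summits localise like real nucleosome-free regions and
cover the planted motif; motif consensi planted at the centre of DAR
summits at rate 0.4 (foreground) vs 0.05 (background); ChIP peaks (300 bp)
co-located with DARs at 0.7 (concordant condition) vs 0.1 (discordant),
plus 50 unrelated background sites per condition; Nutlin |log2FC| noise
sd 0.3 with a +0.5 magnitude shift planted in the p53-linked down group.
A quarter of gained/lost DARs are placed at up-/down-gene promoters, and
80% of the rest inside TADs of the matching direction.

`null_variant` removes every planted association (π = 0.5, equal motif
rates, unbiased placement, equalised ChIP co-location, zero Nutlin
effect) and is the substrate of the type-I-error suite.

What passing these tests shows: the pipeline's logic, calibration and
power under the generator's idealised conditions. What it does not show:
robustness to GC and mappability structure, fragment-length effects,
copy-number variation, duplicate reads, or annotation errors — none of
which the generator emulates.

## Problem sizes in the test suite

The acceptance-style tests run the same structure at a reduced scale —
two 6-Mb chromosomes with 0.18–0.7-Mb TADs (≈28 TADs, matching the
default genome's TAD count) and the default planted-effect parameters —
so that 50 pipeline runs and 200 null replicates complete in about two
minutes. The replicate counts (50 recovery runs, 200 calibration
replicates, 200 permutations per test) are fixed by the acceptance
criteria; the genome size is the package's own choice.

## Known limitations

- The peak caller is not bit-compatible with MACS; boundary placement
  differs, which is why recovery is scored at region level (≥1-bp
  direction-matched overlap Jaccard).
- The comparative DAR test inherits Poisson assumptions; overdispersion
  between biological replicates is not modelled (replicas are pooled, as
  in the analysis this package reimplements).
- Motif scanning uses a single background composition and no higher-order
  sequence model; thresholds are exact only for iid backgrounds.
- The permutation null conditions on gene→TAD occupancy but not on gene
  expression strength; alternative nulls (randomising positions) would
  answer a different question.
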