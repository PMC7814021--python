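# Methods

This note documents the models, conventions and numerical choices behind
`crckit`, and what the synthetic benchmark does and does not emulate.

## Coordinates and I/O

All coordinates are 0-based half-open (BED dialect); overlap between two
spans is `max(0, min(ends) - max(starts))`.  Readers that accept 1-based
input must convert at the boundary.  BED/bedGraph writers emit
tab-delimited, LF-terminated, headerless text; tables are headered TSV.
Replicate consensus follows the merged-overlapping-peaks convention: the
pooled peaks are partitioned into connected components of the ≥1 bp
overlap graph, and every component containing peaks from both replicates
yields one interval spanning the component union.  (Whether consensus
should take the union or the intersection span is not dictated by the
underlying protocol; union was chosen because it preserves constituent
evidence for downstream stitching, and the overlap-graph components are
what HOMER's mergePeaks produces.)

## Super-enhancer calling

* **Stitching.** Constituent H3K27ac peaks are merged whenever a chain of
  gaps each ≤ 12,500 bp connects them (gap measured between half-open
  spans; overlapping peaks always merge).  TSS exclusion (dropping
  constituents fully inside TSS ± 2,500 bp before stitching) is available
  but off by default, matching the "default parameters" usage of the
  ROSE-style workflow.  Stitching is order-invariant and raising the
  stitch distance can only merge, never split.
* **Quantification.** Signal is the sum of per-base coverage over the
  *merged* constituent spans (units: coverage × bp), minus the control
  sum when a control track is supplied, floored at zero per enhancer.
  A per-base floor is available as a switch; the enhancer-sum floor is the
  default because it is the most direct reading of "background-subtracted
  signal".
* **Cutoff.** Enhancers are sorted ascending by signal; the rank index
  and the signal are each rescaled to [0, 1].  Scanning from the
  low-signal end, the first segment whose discrete forward slope reaches 1
  sets the cutoff at the segment's *lower* endpoint; enhancers with signal
  strictly above it are SEs.  On a flat curve (all signals equal) the
  slope never reaches 1 away from degeneracy and zero SEs are called.
  The lower-endpoint convention makes the boundary enhancer itself typical
  and everything above it super, which reproduces the geometric
  "tangent slope 1" definition of the published hockey-stick plots.
* **Gene assignment.** Each SE maps to all genes with TSS within
  span ± 50 kb; if none, to the single nearest gene.  Nearest-gene
  assignment elsewhere measures distance from the interval midpoint to the
  TSS, ties broken by lexicographically smaller gene id.

## Motif scanning

Scores are log-odds in bits against a background (default uniform);
pseudocount 1e-3 is added to PWM columns at construction.  An ambiguous
base (N) contributes the background-weighted mean of its column's scores
(zero when the column matches the background).

P-values are exact: per-position scores are discretised to an integer grid
(granularity 1e-4 bits) and the full score distribution under the
background is obtained by dynamic programming (convolution across
positions); the p-value of a score is the tail mass at its grid point.
Scanning computes scores on the same integer grid, so every reported hit
p-value is exactly consistent with this distribution — the test suite
verifies agreement with exhaustive 4^w enumeration at width 6 to 1e-6.
The reverse strand is scored by scanning with the reverse-complemented
matrix, which is exactly equivalent to scoring reverse-complemented
windows.  Overlapping hits of one PWM on one strand are deduplicated to
the best-scoring offset (leftmost on ties).  The default hit threshold is
p ≤ 1e-4 per PWM; the window conventions for stand-alone enrichment
analyses are ±1 kb around SE/TE-overlapping peak centers, ±100 bp around
TF peak centers and ±50 bp around ATAC peak centers (center = summit when
known, else midpoint; windows are clipped at chromosome bounds).  CRC edge
evidence uses the raw ATAC ∩ SE overlap segments without extension.

## CRC network

A TF is admitted iff it is expressed (TPM ≥ 10 by default; the threshold
is a parameter because published workflows filter to "expressed" TFs
without stating a cutoff) and at least one SE is assigned to its gene.
Edge s→t exists iff ≥ 1 hit of s's motif lies in a search region of an SE
proximal to t.  In-degree counts distinct source TFs (self included);
out-degree counts distinct SEs carrying the TF's motif among admitted
targets' proximal SEs (self included) — distinct-SE counting follows the
"number of SEs bound by a node TF" definition.  Cliques are computed on
the undirected support graph (edge where both directions exist) restricted
to auto-regulated nodes, via Bron–Kerbosch maximal-clique enumeration with
pivoting (networkx); cliques have size ≥ 2, members sorted alphabetically,
list sorted by size then lexicographically.  CES(TF) = fraction of cliques
containing the TF; with zero cliques the scores are reported missing, not
zero.  Exponential worst-case enumeration is acceptable because TF
networks here have < 100 nodes.

## Differential signal

Counts are normalised by median-of-ratios size factors (geometric mean 1;
total-count fallback with a warning when no region is all-nonzero).  Per
region, NB dispersion is estimated by per-condition moment matching
(`α_c = (var_c − q_c/sf̄)/q_c²`, dof-weighted across conditions — using
condition means keeps the estimate unbiased under a true fold change), a
mean–dispersion trend `α(μ) = a0 + a1/μ` is fitted across regions, and the
*trend value* is used as the working dispersion: with two replicates per
condition the per-region moment estimate is so noisy that plugging it in
makes the Wald test anticonservative, while the trend keeps the null
p < 0.05 fraction at ~0.05 and ≥ 80% power for 4-fold drops at mean 200.
The Wald statistic is the log fold change of condition means over its
delta-method standard error; BH step-up gives the FDR; significance
requires |log2FC| ≥ 1 and FDR < 0.05 (the fold-change-≥2, FDR<0.05 rule).
All-zero regions are reported missing and never significant; a zero
condition mean is moderated by half a normalised count before taking logs.
When only coverage is available, approximate counts are obtained by
integrating coverage over the region divided by the fragment length
(default 200 bp).

**Transitions.** WT and KD enhancer sets are matched by best span overlap.
A WT SE that matches a non-SE KD locus is SE→TE; a WT TE absent from the
KD enhancer set is TE→primed when its H3K4me1 mean is above the
enhancer-wide median and its H3K27me3 mean is at or below it (ties at the
median count as "lacking" the mark, since the H3K27me3 track is
zero-inflated over enhancers); unmatched or inconsistent loci are labelled
`other` with a reason.  A `reduced` flag marks matched loci whose KD/WT
signal ratio is ≤ 0.5; the knockdown summaries count an SE as affected if
it is SE→TE *or* reduced.  The median-split thresholds are deliberately
simple and exposed in configuration; qualitative "high/lacking"
definitions do not pin down numeric cutoffs.

## Co-occupancy

Venn classes are computed on merged components of the pooled peak union
(region-level counting, matching overlap reporting after replicate
consensus); a per-peak counting mode exists for sensitivity checks.  A TF
binds an SE iff ≥ 1 peak overlaps its span; summary fractions are reported
for ≥ 1, ≥ 2 and all TFs.  Hotspots are components co-occupied by ≥ k
TFs (default: all supplied sets) with nearest-gene assignment.  The
pipeline runs co-occupancy on the members of the largest inferred clique
when one exists, since the published co-binding figures concern the core
trio.

## Synthetic epigenome

The generator emulates the *structure* of an H3K27ac/ATAC/TF-ChIP study of
a stem-cell population on one ~10 Mb chromosome:

* 500 enhancer loci: 480 isolated TE constituents (width ≈ N(1100, 100) bp,
  amplitude LogNormal(ln 10, 0.25) coverage units → total signal median
  ≈ 1.1e4, maximum over 480 loci ≈ 2–3e4) and 20 planted SEs (3–6
  constituents of ~0.9–1.5 kb within stitch distance).
* SE total signals sit on a linear grid from 1.1e5 to 2.6e7 with ±5%
  multiplicative jitter.  The linear grid (rather than a heavy-tailed
  draw) is what makes the tangent-slope-1 cutoff behave deterministically:
  in WT the first slope ≥ 1 segment is the TE-top → weakest-SE gap
  (boundary gap ≈ 7e4 ≥ smax/499 ≈ 5e4), so exactly the 20 planted SEs are
  called; after a fold-0.25 knockdown the weakest scaled SE (~2.6e4) falls
  into the TE tail while the next gap still triggers the cutoff, so the
  KD SE count is strictly below WT.  These bounds were fixed from this
  design analysis.
* Each SE constituent nests one 260 bp ATAC peak (pileup
  LogNormal(ln 90, 0.3), nearly always ≥ 40); half the TE constituents get
  a weaker ATAC peak and some background peaks fall below the pileup-40
  filter, exercising it.
* Three clique TFs (PAX6, RUNX1, SMAD3) own three of the SEs; each clique
  SE carries the planted consensus words (width 8–10, consensus
  probability 0.88) of *all three* TFs inside its ATAC peaks.  Background
  TFs exercise the admission and clique rules: TP63 auto-regulates but is
  only fed one-way by RUNX1; KLF5 exchanges words with TP63 but lacks a
  self edge; GRHL2 owns an SE but is expressed below the TPM threshold;
  FOSL2/EHF are expressed without a proximal SE.  Hence the unique
  expected CRC is {PAX6, RUNX1, SMAD3}.
* The knockdown TF (RUNX1) has ChIP peaks at every planted SE
  (master-regulator behaviour: in the motivating biology the depleted TF
  reduced H3K27ac at the large majority of SEs); `simulate_knockdown`
  scales H3K27ac coverage, constituent amplitudes and NB count means over
  bound-SE constituents by the fold (default 0.25) and leaves H3K4me1 and
  H3K27me3 untouched.  Counts are NB with mean = signal/100 and dispersion
  0.1, two replicates per condition.
* The genome sequence is i.i.d. uniform ACGT with the planted words
  overwritten; everything is drawn from one seeded generator and identical
  seeds give byte-identical output files.

What the simulation does **not** emulate: read-level noise, GC/mappability
bias, fragment-size effects, repeat structure, a continuous SE/TE signal
continuum, inter-chromosomal structure, or biological co-variation between
marks.  Passing the recovery tests therefore demonstrates correctness of
the algorithms under clean planted structure, not performance on real
sequencing data.

## Problem sizes and runtime

The default study conditions (500 loci, 20 planted SEs, 20 seeds for the
recovery runs; 2,000 regions × 2v2 for the differential simulations;
width-6 PWMs for exhaustive enumeration) run the full test suite in well
under a minute of compute per stage on a single CPU; the complete pipeline
on the default synthetic spec takes a few seconds and is bit-reproducible
under a fixed seed.

## Known limitations

* The inflection cutoff assumes ≥ 2 enhancers and a non-flat curve; flat
  curves return zero SEs by definition.
* The NB engine uses a single two-level condition factor (no covariates,
  no interaction designs) and a delta-method Wald test; it is calibrated
  for the desk-scale designs it targets, not a general DESeq2 replacement.
* Motif hit deduplication keeps one best offset per overlapping chain per
  strand; closely spaced repeated motifs are reported once.
* `se_cobinding` treats any ≥ 1 bp peak/SE overlap as binding, with no
  summit or affinity weighting.
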