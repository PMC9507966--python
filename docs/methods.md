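# Methods

This note documents the models and procedures implemented in `hp5kit`, the
defaults and why they were chosen, what the synthetic data do and do not
emulate, and the numerical choices that matter.

## 1. TSS cluster calling

**Cluster areas.** Per chromosome strand, pooled 5′-end counts are
segmented by the maximal-scoring-segment recursion of the paraclu peak
caller: a segment of sites scores `total − d·span` (span in bases,
including internal gaps), and as the density penalty `d` decreases optimal
segments merge, producing a laminar hierarchy in which each segment is
optimal for a density interval `[d_min, d_max)`.  A segment's break
density is the density at which its weakest prefix or suffix — including
the gap it drags along — stops paying for itself.  Segments are kept if
`d_max/d_min ≥ 2`, total count ≥ 30 and span ≤ 200 bp (the published
defaults of the original tool, all configurable), and nested survivors
collapse to the outermost passing segment, so areas are disjoint.  The
implementation is tested for exact agreement with a brute-force
fixed-density segmentation oracle on all inputs of ≤ 20 sites.

**Subpeaks and boundaries.** Within an area, summits are plateau-aware
local maxima at ≥ 10% of the area maximum and ≥ 5 bp apart (greedy by
height; ties resolved toward the transcript 5′ end).  Internal boundaries
sit at the midpoint between adjacent summits, `(s1+s2+1)//2`, left-closed.
After filtering, surviving summits are mapped back onto their parent areas
and boundaries are re-drawn the same way, so the final clusters partition
each area exactly.

**Filters.** A cluster's non-genomic-G statistic is the count-weighted
mean of per-base G fractions ("proportion of reads" semantics, not
per-base voting).  Non-mitochondrial clusters below 15% are removed as
internal-priming artifacts; mitochondrial mRNAs are uncapped, so their
clusters are exempt from the G rule but must overlap an annotated start.
Minor isoforms are dropped when their read count is ≤ 10% of the gene's
most abundant cluster in *every* analysis set (a cluster above threshold
anywhere survives).  Both filters are idempotent.

**Gene and transcript assignment.** A cluster joins the gene whose locus,
extended by 50 bp on both sides, covers its summit on the matching strand;
ties go to the nearest annotated TSS, then the 5′-most gene.  The
representative transcript is the gene transcript with the annotated TSS
nearest the summit (tie → longer CDS).  The isoform sequence runs from the
summit through that transcript's exon chain (an extension upstream of the
first exon is genomic/unspliced; a summit in an intron starts at the next
exonic base).  If the summit lies downstream of the annotated start codon,
the CDS start moves to the most upstream in-frame AUG before the stop; if
none exists the CDS is undefined and flagged.

## 2. Spike-in normalization and MRL

Size factors are median-of-ratios computed on the spike-in rows only:
reference = per-row geometric mean across samples (rows containing any
zero are excluded from the reference), factor = per-sample median of
count/reference.  Because a fixed amount of external control RNA is added
to every fraction sample, these factors convert read counts to relative
RNA mass independently of global shifts in translation.  MRL is
`Σ i·c_i / Σ c_i` over normalized fraction counts (`i = 1..8`; fraction 8
pools ≥ 8 ribosomes); it is scale-invariant, bounded in [1, 8], and
undefined (NaN, never 0) on an all-zero profile.  MRL is computed per
replicate and averaged within condition (a pooled-counts mode exists
behind a flag); unequal replicate numbers enter as simple unweighted
means.  Isoforms need a raw count of ≥ 6 in more than six (≥ 7) samples of
the comparison set to be quantified.  Gene-level profiles are per-fraction
sums over isoforms; the gene MRL is then exactly the usage-weighted mean
of isoform MRLs.

## 3. TSS-resolved mRNA features

A TSS is an interval, so each feature is evaluated per base — for the
isoform starting at every base of the cluster with nonzero 5′-end
abundance — and averaged with abundance weights.  Count-like features
(uORF number, TOP start/length, segment lengths) are rounded to the
nearest integer, a rounded 0 meaning absence; continuous scores (Kozak,
structure) stay unrounded, since "absence at 0" is meaningless for them.

* **uORFs**: AUG strictly 5′ of the CDS start with its first in-frame stop
  anywhere downstream (a stop may fall inside the CDS).  The reported
  count is the maximum number of non-overlapping uORFs, selected by the
  earliest-stop greedy rule — the interval-scheduling algorithm, which is
  provably maximal and deterministic.
* **Kozak**: a transparent positional match to gccRccAUGG with the −3
  purine and +4 G carrying triple weight, normalized so a perfect context
  scores 1.  The test suite asserts ordering properties, not absolute
  values, so any calibrated PWM can be substituted.
* **TOP motif**: position of the 5′-most pyrimidine (1-based) and the
  length of the uninterrupted pyrimidine tract from it.
* **Structure**: a Nussinov maximum base-pairing dynamic program
  (Watson–Crick + GU, minimum hairpin loop 3), reported as the negated
  pair count so more negative = more structured.  It preserves the
  structured/unstructured ordering that thermodynamic folding would give
  at a fraction of the cost and with no external dependency; the engine is
  pluggable, and `precomputed_structure_engine` adapts external folding
  output.  The cap window is the first 75 nt; the distal window is the
  5′UTR minus those 75 nt.
* **Expressed isoforms** are those strictly above 10% of the gene's top
  isoform in either condition.

## 4. Differential analyses

**TSS usage.** After the abundance prefilter (TSS: count ≥ 5 and
proportion ≥ 0.05 in ≥ 2 samples; gene: total ≥ 20 in ≥ 2 samples; ≥ 2
surviving TSSs), each gene is tested by a Dirichlet-multinomial
likelihood-ratio test: proportions per condition versus shared, with a
common estimated concentration, df = K−1.  Reported proportions are shrunk
by one uniform pseudo-count profile per condition (one pseudo-read per
TSS).  Per-TSS p values come from TSS-vs-rest beta-binomial LRTs at the
gene's concentration.  The two-stage adjustment screens genes by
Benjamini–Hochberg at the overall FDR target (0.1), then confirms TSSs
within screened genes by Holm scaled by the screening fraction; TSSs of
unscreened genes get q = 1 and a TSS q is never below its gene q.  Usage
log2 fold changes carry delta-method standard errors with the
Dirichlet-multinomial design effect and are shrunk by an empirical-Bayes
normal prior whose scale is fit by marginal likelihood; shrinkage is
conservative (|shrunken| ≤ |raw|), and 95% Wald intervals on the shrunken
estimates back the CI-overlap stringency filter.  The alternative TSS of a
significant gene is the significant TSS with the largest |shrunken
log2FC| (ties → smaller q, then 5′-most); the base TSS is the most-used
TSS in the reference condition (reassigned to the next-highest if it
coincides with the alternative).  The stringency flag requires
Δproportion > 5%, |FC| > 1.5 and non-overlapping CIs, all strict.

**Expression.** A negative-binomial Wald test with internal
median-of-ratios size factors.  Dispersions are moment estimates that
account for size factors in the shot-noise term, shrunk toward a fitted
`a₁/μ + a₀` trend with eight pseudo-degrees of freedom.  Calls require
FDR < 0.1 and |log2FC| strictly greater than log2(1.5).

**Polysome distribution.** The fraction × condition interaction is tested
by an NB LRT: full model = free (condition, fraction) cell means, null =
fraction and condition main effects, both with per-sample internal size
factors, df = 7.  Replicate noise of a polysome profile acts on the
proportion scale, so a single per-gene NB dispersion is wrong — tail
fractions carrying a small share of the gene's mRNA are relatively far
noisier.  The dispersion is therefore structured as
`α_gf = a_g / share_gf` with the per-gene proportion-dispersion `a_g` a
moment estimate shrunk 50/50 toward the cohort median, and the statistic
is referred to an F(df, residual-df) distribution rather than chi-squared
to account for the estimated dispersions at three replicates.  This
combination is calibrated to ~1× nominal at α = 0.01 on 2,000-gene null
cohorts.  Significant genes (BH FDR < 0.1) are classified hypersensitive
or resistant according to whether their log2 ΔMRL falls below or above the
median over all tested genes; non-significant genes stay unclassified.
The same LRT applied to (isoform, rest-of-gene) count blocks implements
the isoform-versus-rest polysome test (`test_isoform_vs_rest`), which
pairs with the stagewise adjustment for overall-FDR control across genes
and isoforms.

**Class comparisons.** Two-sided Mann–Whitney U (independent) or Wilcoxon
signed-rank (paired) per class versus a reference or the rest, Holm
adjustment across the family, and the matched-pairs rank-biserial
correlation r = (W⁺ − W⁻)/(W⁺ + W⁻) as the paired effect size.

## 5. Decomposition of ΔMRL

With per-isoform MRLs and percent abundances in two conditions, the
measured gene-level change is
`log2[Σ MRL_B,i·%ab_B,i / Σ MRL_A,i·%ab_A,i]` — algebraically identical to
the log-ratio of gene MRLs from per-fraction sums (asserted numerically to
1e-12).  `omit_te` replaces each isoform's MRL by its two-condition
average (a missing value is excluded from the average, so the defined one
is used); `omit_usage` replaces percent abundances by their average and
excludes genes with any missing isoform MRL — the two formulas carry
different missing-data rules by design.  Percent abundances are isoform
shares of the gene's unfractionated 5′-end counts; when isoforms are
missing in one condition the percentages are renormalized over the defined
ones and the gene flagged.  Both counterfactuals are antisymmetric under
condition swap.  `attribute_mode` reports Pearson r and OLS slope of each
simulation against the measured values; the dominant regulatory mode shows
the higher r.

## 6. Additive model of MRL

Rows require 5′UTR length > 0 nt and CDS length > 100 nt; lengths are
log10-transformed and structure scores divided by their window length.
Each term is a cubic B-spline smooth (default basis size 10; quantile
knots; a near-discrete feature falls back to a centred linear term) with a
second-difference penalty plus a small identity shrinkage component
(0.05), so a term can be penalized entirely to zero — the "shrinkage
smooth" semantics.  Per-term smoothing parameters are selected by GCV
coordinate descent on a log grid with the effective degrees of freedom
inflated by γ = 2, the standard guard against GCV's tendency to keep
spurious wiggle in pure-noise terms (REML would be the natural
alternative; GCV with inflation gives the same behaviour for these 1-D
smooths at far lower complexity).  Cross-validation draws 4 chromosomes at
random per repeat, trains on everything else, and evaluates R² = 1 −
SSE/SST on the rows of the top-50%-expressed genes (by total
unfractionated counts) of the held-out chromosomes; the median over 10
repeats is reported, train/test chromosome disjointness is asserted every
repeat, and an empty test draw is redrawn and logged.

## 7. Synthetic data: what it emulates, and what not

The generator plants, per gene: 1–4 single-exon transcripts with annotated
TSSs ≥ 60 bp apart, a shared in-frame CDS (AUG…stop, coding length > 100
nt, no internal in-frame stop) and a 5′UTR ≥ 20 nt; per-isoform usage from
a floored simplex (every isoform ≥ ~12% of its gene, so that the planted
truth is recoverable past the 10% minor-isoform rule, whose behaviour is
tested with dedicated constructions instead); true MRLs in [1, 8] per
condition; usage-shift genes that swap their two top isoforms between
conditions; TE-shift genes that move all isoform MRLs by a common offset;
and internal-priming artifact clusters inside the CDS at 15–35% of gene
output.  5′ ends spread around the true TSS with a discretized Gaussian of
sd 1.2 bp (the real positional spread is not well characterized; this is a
free parameter).  Per-base non-genomic-G fractions come from Beta(8,4)
truncated to ≥ 0.3 for capped starts and Beta(1,19) for artifacts —
cleanly separated around the 15% threshold at cluster level with
occasional borderline bases.

The polysome experiment spreads each isoform's RNA mass over fractions
with a discretized logit-normal (σ = 1) whose location is root-found to
hit the target MRL; replicate noise is a Dirichlet draw around those
weights with concentration 1/dispersion (default dispersion 0.002,
i.e. a few percent replicate CV of fraction shares, typical of replicate
polysome preparations).  Every fraction is sequenced as its own library to
`library_size/8` reads times a lognormal library factor (sd 0.15), with
equal spike-in mass (~0.1% of reads overall, 20 species) added per
fraction — so spike counts genuinely carry the mass scale the way external
controls do in the assay.

Not emulated: multi-exon splicing within the simulated genes (the
annotation reader and sequence extraction support exon chains and are
tested on hand-built multi-exon fixtures), sequencing errors, UMIs,
mappability, promoter sequence composition (TATA/CpG), correlated
usage-and-TE changes, batch effects, and biological overdispersion of TSS
usage between replicates (unfractionated tracks are multinomial given the
planted usage).  Passing tests therefore demonstrate correctness of the
algorithms and calibration under these idealized conditions, not
performance on real libraries.

## 8. Numerical choices and degenerate inputs

* Dirichlet-multinomial fits use L-BFGS on softmax logits plus log
  concentration with analytic gradients; concentration is bounded in
  [1e-2, 1e6]; LRT statistics are floored at 0.
* All-zero MRL profiles, genes with a single surviving TSS, genes with
  all-zero counts, and empty cluster areas are flagged/skipped with
  reasons, never silently zeroed.
* Boundary conventions: strict inequalities exactly where stated (<15% G;
  ≤10% minor isoform; >10% expressed isoform; >5% proportional change;
  |FC|>1.5; CDS>100 nt; 5′UTR>0 nt); "more than six samples" = ≥ 7.
* Integer feature rounding is half-away-from-zero.
* Fraction-weight root finding brackets the logit-normal location in
  [−40, 40] with targets of exactly 1 or 8 mapped to one-hot profiles.
* Determinism: every stochastic component draws from
  `numpy.random.Generator` seeded through `SeedSequence` children of one
  master seed; pipeline outputs are byte-identical across reruns.

## 9. Problem sizes used in the bundled studies

The packaged simulation studies use a 50-gene genome at 10⁶ reads for
clustering recovery, ~1,000 isoform-condition pairs at ≥ 10⁴ reads for MRL
accuracy, 2,000-gene null cohorts for the calibration of both LRTs,
200-gene planted cohorts for power, and 5,000-row feature tables for the
model harness — sizes at which the measured quantities are stable across
seeds while a full run stays in the tens of seconds on one CPU.

## 10. Known limitations

* The usage LRT relies on chi-squared asymptotics; with very sparse TSS
  counts (below the prefilter thresholds) it would be anticonservative —
  the prefilter is part of the method, not an optimization.
* The polysome LRT's structured dispersion assumes proportion-scale
  replicate noise; strongly count-level (e.g. PCR-jackpot) noise would
  call for a different structure.
* The Nussinov scorer is not a thermodynamic folding energy; absolute
  values are not comparable to MFE predictions, only orderings.
* Representative-transcript choice by nearest annotated TSS cannot
  discover unannotated 5′ structure; with read-level data a targeted
  assembly would do better.
* GCV smoothing selection, even inflated, can differ from REML for very
  small data sets; the cross-validated R² is the quantity to trust.
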