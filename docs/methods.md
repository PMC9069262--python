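# Methods

chronoscan implements the inference chain used to ask whether seasonal
allele-frequency structure at a migration monitoring station reflects
heritable early/late *chronotypes* within one panmictic population, or
genetically distinct populations passing through at different times.  The
chain is: a permissive F_ST outlier scan between resident and migratory
breeding groups; designability filtering of candidate SNPs for targeted
genotyping assays; ordinal (optimal-scaling) PCA of candidate-gene
genotypes; regressions of passage date on the leading component and on
weekly allele-frequency trajectories; mixture-model assignment of
migrants to breeding populations; and an explicit decision rule combining
those lines of evidence.

## Divergence scan

Per locus, the Weir–Cockerham variance components for diploid biallelic
data are computed from per-group sample sizes, counted-allele frequencies
and observed heterozygosities: `a` (among groups), `b` (among individuals
within groups), `c` (within individuals), with theta = a/(a+b+c).
Negative estimates are retained, as usual for this estimator; loci that
are monomorphic overall (a+b+c = 0) or have fewer than `min_calls`
(default 5) called individuals in any group are excluded before
thresholding.  The default grouping pools sites into two classes —
resident versus migratory + partially migratory — matching the contrast
the scan is meant to capture; a per-site grouping is available.  Sites of
ambiguous migratory status can be excluded by name.

The outlier rule is deliberately permissive: the threshold is the
empirical quantile (linear interpolation) of theta over usable loci at a
configurable percentile (default 0.90), ties included on the selected
side.  The aim is to carry forward many loci of potentially small effect,
not to control a false-positive rate.  The multi-locus ratio-of-sums
estimator sum(a)/sum(a+b+c) is exposed for calibration; on
Balding–Nichols data it recovers the divergence parameter within ±0.01
at 5000 loci.  Note that pooling several independently drifted
populations into one group averages out part of the per-population
divergence (about half, with two populations per group), so the pooled
between-group theta sits below the per-population parameter; this is a
property of the design, not a bias of the estimator.

## Assay designability

A candidate SNP is designable when its flanking context passes four
rules: GC fraction below 0.65 (strict: exactly 0.65 fails), no indel
within 30 bp of the target, no other variant within 20 bp, and uniquely
mapping primer seeds.  Distance windows are inclusive ("within N bp"
means <= N), the conservative reading.  GC is evaluated over a symmetric
±50 bp window around the target by default (the window is configurable;
no standard window is canonical), with ambiguity codes excluded from
numerator and denominator and an all-N window failing conservatively.
Primer uniqueness is approximated by exact lookup of the two k-mers
(default k = 20) immediately flanking the target, on both strands of the
supplied reference; this is deterministic and needs no aligner, at the
cost of missing inexact multi-mapping.  Without a reference the rule is
reported "not evaluated" and does not fail the assay.

## Ordinal PCA

Genotype categories (0 < 1 < 2 copies) are replaced by monotone numeric
quantifications chosen to maximise the variance captured by a rank-d
representation — the optimal-scaling / homogeneity-analysis treatment of
ordered categorical data.  The alternating least squares fit cycles
three exact steps: per-locus category quantification (weighted category
means of the current reconstruction target, projected onto the monotone
cone by pool-adjacent-violators, then standardised to mean 0, variance
1), object scores by orthogonal Procrustes (X'X = nI), and loadings
A = Q'X/n.  The recorded loss is the mean squared residual between the
quantified matrix Q and its rank-d reconstruction, equal to
(m − ||A||²_F)/m at each recording point; it is non-increasing across
iterations and convergence is declared when it changes by less than
`tol` (default 1e-8, `max_iter` 2000).  Initialisation is deterministic,
from classical PCA of the standardised numeric codes, so the fit is
seed-independent; the config seed exists only for degenerate
tie-breaking.

Variance accounted for is reported per dimension as eigenvalue/m × 100,
with eigenvalues those of Q'Q/n (the correlation matrix of the
quantified data).  Two exact limits pin the implementation down: with
two observed categories per locus the monotone constraint is vacuous and
the eigenvalues equal classical PCA of the standardised codes to 1e-8;
perfectly rank-1 data gives a first-dimension VAF of 100%.  Missing
genotypes are imputed to the locus modal category by default (a
drop-samples-above-threshold policy is available); loci monomorphic
after imputation are dropped with a warning, and the VAF denominator is
the count of active loci.  Component signs are arbitrary; `fix_sign`
anchors each dimension to a positive loading on a chosen locus.

## Passage-date models

Capture day-of-year is regressed (OLS) on the PC1 score with sex (F = 0,
M = 1) as a covariate and an optional PC × sex interaction; migrants of
unknown sex are dropped when a sex term is requested.  The
sex-differential check is OLS of capture day on sex alone.

Weekly allele-frequency trajectories use 7-day bins anchored at the
earliest migrant capture day (reproducible without a calendar
convention), frequencies plotted at bin start + 3 with binomial standard
errors.  Before binning, each locus is re-polarised so the counted
allele is the major allele over the full migrant sample — defined once,
not per week, so polarity cannot flip between bins; an exact 0.5 tie
keeps the original polarity and the operation is idempotent.

Linear and polynomial trends in frequency versus midpoint day are
compared by a likelihood ratio test on nested Gaussian OLS fits
(maximum-likelihood variance).  The full-model degree defaults to 2;
weekly points are unweighted by default, with sample-size-weighted WLS
and a binomial GLM available for sensitivity.  For nested Gaussian OLS
the LRT statistic 2(llf_full − llf_reduced) = n·log(RSS_r/RSS_f) is a
monotone transform of the exact F statistic, so `LrtResult` carries two
p-values: the asymptotic chi-square p (`p_chisq`) and the exact
finite-sample F-based p (`p_value`, the default used downstream).  At
the dozen-or-so weekly points a season provides, the chi-square
approximation rejects at roughly twice its nominal level while the
F-based p is exactly calibrated (verified by null simulation: rejection
rate 0.042 at nominal 0.05, p-values KS-uniform); both are reported so
either convention can be inspected.  One geometric caveat: a
chronotype-driven seasonal shift is close to a sigmoid that is odd about
mid-season, so its departure from a straight line loads mostly on the
cubic term; the quadratic default detects asymmetric early-season
shifts, and passing `degree_full=3` is the sharper test against
symmetric sigmoids.

## Mixture assignment

Baseline allele frequencies per population are posterior means with a
1/2-per-allele prior — (count + 0.5)/(total + 1) — so no frequency is
ever exactly 0 or 1 and private alleles cannot zero out a likelihood.
Individuals are scored by Hardy–Weinberg genotype log-likelihoods
(missing loci contribute nothing); mixture proportions start uniform and
are estimated by EM (E-step posteriors ∝ pi·likelihood, M-step pi =
posterior means), stopping when the observed-data log-likelihood changes
by < 1e-8.  The trace is non-decreasing by the EM guarantee.  Each
migrant gets a posterior over populations, a maximum-a-posteriori label
and a "confident" flag at a configurable posterior threshold (default
0.8; no standard cutoff exists, so the raw posteriors are always
reported).  Baseline quality is assessed by leave-one-out
self-assignment, rescoring each reference individual against frequencies
recomputed without its own genotypes.  Migrant loci absent from the
baseline are dropped (logged), not imputed.

## Scenario classification

Three statistics feed an explicit, re-derivable verdict:

1. the fraction of confidently assigned migrants mapping to the modal
   population;
2. OLS associations of PC1 and of each candidate locus's genotype with
   breeding latitude, Holm-adjusted across the tests (raw p-values are
   also reported);
3. a two-sided Mann–Whitney comparison of capture days between minority-
   and modal-assigned confident migrants (with fewer than three minority
   birds, only their day-range coverage is reported, flagged low power).

`chronotype_consistent` requires modal fraction >= `modal_min` (default
0.9), no Holm-adjusted latitude test significant at `alpha` (default
0.05), and no temporal clustering of minority assignments;
`population_passage_consistent` requires at least one significant
latitude association plus minority clustering; anything else is
`indeterminate`.  The thresholds are configuration, the report always
carries the raw statistics, and recomputing the verdict from the report
reproduces it.  The latitude tests default to *all* breeding samples
rather than only the modal cluster's: the population-passage signature
is a cline *between* source populations, which a modal-only subset
cannot see (a `latitude_subset="modal"` option restricts it anyway).

## Synthetic data

The generators define the study conditions the tests run under; all are
deterministic given their seed.

**Baseline.**  Ancestral frequencies are uniform on (0.1, 0.9) by
default; population frequencies follow the Balding–Nichols model
(Beta-distributed around the ancestral frequency with divergence
parameter F, whose expectation equals F_ST), and genotypes are binomial
in Hardy–Weinberg proportions.  Defaults: 2 populations × 60 diploids —
for the scan configuration, 2000 loci at F = 0.05; for the candidate
panel, 100 loci.  Planted outlier loci receive *exactly* the requested
between-group differential (group frequencies p0 ± delta/2, feasibility
enforced by re-drawing p0); drift noise is deliberately not layered on
top, so the planted effect size is the stated one.  Populations carry
names, resident/migratory labels and optional latitude distributions,
because the downstream latitude tests need them.

**Migration series.**  150 migrants over a 90-day autumn season (days
230–320).  In the chronotype scenario all migrants come from one source;
a per-individual standard-normal liability shifts the allele-sampling
probability of every timing locus jointly on the logit scale
(`liability_weight`, default 1.5), giving the cross-gene collinearity
that lets one component summarise the chronotype, and expected capture
day is season midpoint + sum over timing loci of `effect_days` × (code −
1) (default −5 days per copy) plus Normal(0, 7 days) noise, truncated to
the season (truncation rate logged).  In the population-confound
scenario two sources with a 21-day passage-date offset, a 0.4
allele-frequency differential at the timing loci and distinct breeding
latitudes (48°N vs 42°N bands) mix 60:40, with no within-source timing
effects.  In the chronotype configuration the two baseline clusters
share one latitude distribution (an east/west split, like the study
system), so drift alone produces no latitude cline.

**Flank contexts.**  Each context assigns at most one planted violation
(GC-rich window, indel within 30 bp, SNP within 20 bp, or a duplicated
primer seed in the toy reference); passing contexts get decoy variants
just outside the windows to exercise the boundaries, and GC labels are
verified against the filter's own window during generation so truth
labels are exact by construction.

**What the generators do not emulate:** background linkage
disequilibrium, genotyping error, locus-specific missingness patterns,
multi-year structure, or selection.  Passing tests therefore show the
estimators and decision rules behave correctly under their stated
models, not that real data meet those models.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale sizes chosen to keep Monte-Carlo
error well inside the asserted tolerances: 5000 loci for estimator
calibration, 1000 random tables for oracle equivalence, 1000 replicates
for LRT calibration, 50 seeds for mixture recovery and for each
disambiguation scenario.  Scenario classification accuracy is about
92–100% per scenario at defaults; the dominant error mode in the
chronotype arm is a familywise false positive among the five latitude
tests, which Holm adjustment holds near 5%.  Tolerances: oracle
agreement 1e-12 (exact arithmetic path), classical-PCA equivalence 1e-8,
ALS loss monotonicity 1e-10, EM monotonicity 1e-8.  Degenerate inputs
are handled explicitly: monomorphic loci yield NaN theta and are
excluded from quantiles; an anti-monotone quantification target that
collapses under PAVA falls back to the standardised numeric codes; a
baseline population with no calls at a locus falls back to the prior
(posterior 0.5); identical nested models give LRT statistic 0 with p = 1.

## Known limitations

Primer uniqueness is a k-mer proxy, not an alignment.  The ordinal PCA
implements the ordinal scaling level only (no nominal or spline
quantifications).  The EM assignment gives point estimates without
credible intervals.  The verdict rule is a formalisation of a
qualitative argument; its thresholds are conventions, and on real data
the report's raw statistics matter more than the label.  Weekly-bin
frequencies at the season edges rest on few birds and are noisy;
unweighted trend fits treat them like any other point (the weighted
options mitigate this).
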