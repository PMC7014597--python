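# Methods

This note documents the statistical procedures, their defaults, the
synthetic-data model used to validate them, and the numerical and design
choices that were genuinely open.

## Compositional expression divergence

Relative expression (TPM) lives on a simplex: each sample's values sum to
10⁶, so one transcript's increase is everyone else's decrease.  All
between-sample comparisons therefore run in centered log-ratio (CLR)
coordinates, clr(x)ᵢ = ln xᵢ − mean_j(ln x_j), computed per sample over the
full transcript set (toxins and nontoxins share the geometric-mean
reference, keeping both on the scale the null is built from).

**Zero replacement.**  CLR needs strictly positive input.  Zeros are
replaced multiplicatively: each zero becomes `delta_fraction` (default 0.5)
times the smallest nonzero value in its sample, and the nonzero values are
rescaled by `(total − replaced)/total` so the sample total is preserved.
This is the simple multiplicative variant of the count-zero replacement
family; it is deterministic, and the method and parameter are recorded with
the output.  Structural zeros (a paralog that does not exist in a species)
are excluded from replacement.

**Orthogonal fit and null band.**  For a sample pair, the line minimising
the summed squared perpendicular distances (total least squares,
error-variance ratio 1 — equivalently the principal axis of the 2×2
covariance) is fitted through the *nontoxin* points.  The signed residual of
a point is `(y − m·x − b)/√(1+m²)`, positive above the line.  The null band
is the empirical central `level` (default 0.99) of the nontoxin residuals
with equal 0.5% tails; a toxin is an outlier when its residual is strictly
outside, and its direction is the sample on whose side of the line it falls.
Two-sided banding matches the directional over-expression calls the method
produces; a one-sided variant is a parameter away.  Points exactly on a
boundary are inside (conservative).  Out-of-sample exceedance of an
empirical quantile band from n background points is (1−level)·(n+1)/n-ish
per construction — about 1.13% rather than 1.00% at n = 1500 — which the
calibration measurements reflect.

**Family composition** is the family's share of total toxin TPM per sample,
in percent; the species average is the arithmetic mean of per-sample
percentages.  Averaging per-sample percentages and computing percentages of
averaged TPM give different numbers on divergent samples; both are
implemented (`scope=`), per-sample being the default.

## Assembly and expression QC

**Presence/absence.**  A transcript is absent in a sample when the fraction
of bases with depth below `min_depth` (5×) strictly exceeds
`max_low_fraction` (10%).  The rule is monotone in both thresholds.

**Chimera screen.**  At a true mis-join no read spans the junction, so reads
covering a nearby site pile up on one side.  For each site at least one mean
read length from both ends and covered by ≥3 reads, the mean left overhang
(site − start) and mean right overhang (end − site − 1) over covering reads
are compared; the site is flagged when |left − right| > 0.5 × mean read
length.  Overhang means are ill-defined near termini, hence the eligibility
window; flagged sequences are reported for review, never auto-removed.  The
covering-read interpretation (rather than a window of all reads) is an
interpretive choice recorded here.

**k-mer cross-talk filter.**  Index hopping leaves k-mers that are abundant
in their source sample and rare in a co-multiplexed recipient.  Canonical
21-mer counts are normalised per million k-mers within each sample; for a
sample pair a k-mer is flagged when (higher + 0.5)/(lower + 0.5) strictly
exceeds 500 (pseudo-count 0.5 makes absent k-mers comparable), and reads in
the *lower*-count sample containing a flagged k-mer are removed — the
low-count side is the presumed bleed-through recipient.  k = 21, the
normalisation, and the removal side are this package's documented choices;
identical spectra are never filtered.

**Identity clustering.**  Greedy centroid clustering at 98%
global-alignment identity (matches / alignment columns; match +1, mismatch
−1, gap open −2, extend −0.5).  Sequences are processed longest-first with
lexicographic tie-breaks, so the clustering is independent of input order;
the representative is the longest member.

## Orthology turnover

With two species, orthogroup member counts (m_A, m_B) determine everything:
1:1 is a one-to-one ortholog pair; m:1 (m>1) charges m−1 duplication events
to the multi-member species and labels every member of the group a
duplication member; m:0 yields one loss event in the empty species.  A
two-taxon comparison cannot distinguish loss-here from gain-there; the event
record carries that note.  For cross-species merging, 1:1 pairs collapse to
a single row drawing each species' columns from its own transcript (no
structural zeros); every other member keeps its own row, zero-filled and
masked as structural where the species lacks it.  The ortholog-vs-paralog
expression test is a two-way fixed-effects ANOVA (type II sums of squares,
because the design is unbalanced) on CLR expression with toxin type
(one-to-one vs other) and species as factors, with interaction.

## Differential expression ("deseq2-like, simplified")

Size factors are median-of-ratios over transcripts with all-positive
counts.  Counts are modelled NB(μ, α) with Var = μ + αμ²; α is a pooled
within-group method-of-moments estimate per transcript, truncated below at
10⁻⁸.  The Wald statistic is log₂(m₂/m₁) over its delta-method standard
error, √(Σ_g Var(m_g)/m_g²)/ln 2, with a zero group mean replaced by half
the smallest nonzero group mean; p-values are two-sided normal tails with
Benjamini–Hochberg adjustment (missing p-values propagate and are excluded
from the test count).  Dispersion shrinkage, outlier filtering, and
independent filtering are deliberately not implemented: the stage is
validated by simulation properties (type-I error, power on planted fold
changes), not by matching any external tool's numbers.  The truncation of
negative moment estimates makes the test mildly conservative on
Poisson-like data (measured type-I ≈ 0.04 at n = 5/group).

Utilities for published DE tables parse `<0.001` as 0.0005 (any value below
the threshold gives identical significance counts), keep `NA` as missing
(never counted), and recompute Wald statistics from printed LFC/SE columns.
Printed tables carry 3-decimal rounding: recomputed statistics agree with
printed ones within the bounds that rounding propagates, which for a few
rows is slightly wider than ±0.005.

## Coexpression submodules

Expression is transformed log₂(TPM+1); per-transcript variance is regressed
on the mean (lowess) and transcripts ranked by the residual, decoupling
dispersion from expression level; the top `filter_quantile` fraction
(default 0.5) is retained and zero-variance transcripts always drop.
Adjacency is |cor|^β (Pearson, β = 10) — unsigned by default, with
((1+cor)/2)^β behind `signed=True`.  Topological overlap is
TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij), diagonal 1.
Modules come from average-linkage clustering of 1 − TOM, cut at the height
(0.05…0.95, step 0.05) maximising mean silhouette; clusters below
`min_module_size` (default 1) become background (module 0), and surviving
modules are renumbered by size.  Module profiles are mean transformed
expression per venom-type treatment.

Two consequences of the unsigned default worth knowing: perfectly
anti-correlated blocks are indistinguishable to |cor|^β and merge into one
module (use `signed=True` to separate them), and recovery guarantees are
stated for blocks with uncorrelated profiles.  Correlations from few samples
are noise: the stage refuses fewer than 4 samples and warns below 8.  The
silhouette-chosen static cut is this package's substitute for dynamic
tree-cutting; all knobs are exposed, and validation is by planted-module
recovery, not by reproducing any particular empirical module count.

## Pairwise dN/dS (NG86 counting)

Synonymous site counts per codon are the expected fraction of single-base
changes preserving the amino acid, with changes to stop codons excluded
from numerator and denominator (a codon from which no stop is reachable
contributes N + S = 3).  Site totals are averaged over the two sequences.
Observed differences per codon are averaged over all orderings of the
differing positions whose intermediates avoid stops, equally weighted; if
every ordering passes through a stop (rare), counting falls back to
including them so the pair remains defined.  Proportions are Jukes–Cantor
corrected, d = −(3/4)ln(1 − 4p/3) (undefined at p ≥ 3/4), and ω = dN/dS
only when dS > 0.  Pairs with dS < 0.001 (ω explodes on near-zero
synonymous distance) or dS > 0.10 (misidentified orthologs) are excluded;
the filter is idempotent.  Counting estimates are deterministic and
desk-verifiable but not numerically comparable to maximum-likelihood codon
models beyond rank order — outputs are labelled accordingly.

The toxin-vs-nontoxin contrast is an unpaired two-sample Wilcoxon rank-sum
(normal approximation with tie correction): the groups are independent and
of unequal size, so the paired signed-rank form does not apply (it remains
available for genuinely paired designs).  Percentile flags mark toxins
strictly above the nontoxin 95th percentile, computed on the dS-filtered
set by default, with the per-quantity flag sets and their intersection
reported.

## Synthetic data: what it emulates, what it does not

The generators produce every input the pipeline consumes with planted,
exactly recoverable truth: two-replicate compositional expression (shared
per-transcript level, N(0, noise_sd) replicate noise, closure to 10⁶, with
outlier toxins shifted `outlier_shift` in one sample), uniformly tiled read
alignments with optional junctions (no spanning read) and zero-coverage
regions, codon pairs differing by exact synonymous/nonsynonymous counts
(one single-base edit per codon, never a stop), orthogroup tables with
planted 1:1/duplication/loss structure, and treatment-structured
coexpression blocks whose pairwise within-module correlation equals
`within_cor` in expectation (standardised shared factor mixed with private
noise).  Defaults model the study scale: two samples per species, ~40
toxins in ~14 families against ~1500 nontoxins, 100-base reads at 20×,
three venom-type treatments.  The outlier effect size (shift 5 CLR units
over 0.5 CLR units of replicate noise) is a calibration choice — an
over-expression an order of magnitude beyond replicate drift — not an
empirical estimate.

Deliberately not modelled: sequencing error and quality profiles, RSEM
estimation noise and multi-mapping ambiguity, library-size artefacts,
phylogenetic correlation among transcripts, and dispersion heterogeneity
beyond the NB model.  Passing planted-truth tests therefore demonstrates
the *statistics* behave as specified under their assumptions, not that real
venom-gland data satisfy those assumptions.

## Problem sizes and numerical choices

Validation measurements use: 10,000 Monte-Carlo null toxins (20 replicates
× 500, each with a fresh 1500-nontoxin band); 100 planted-junction and
several hundred clean tilings for the chimera screen; a 200-scenario random
sweep for orthology inversion; every 1- and 2-difference non-stop codon
pair against an independent pathway enumerator; 100–200 replicates of 2000
Poisson-null transcripts at n = 5/group for DE type-I; and 100 replicates
of two-block module recovery at within-correlation 0.9.  Ties at decision
boundaries always resolve conservatively (band boundary inside, percentile
boundary unflagged, k-mer ratio at exactly the fold retained).  Quantiles
are numpy's linear-interpolation empirical quantiles.  All randomness flows
through explicit integer seeds; equal configs and seeds give byte-identical
stage outputs.

## Known limitations

* Two-species parsimony cannot orient gain vs loss; events are reported as
  losses in the empty lineage with the ambiguity noted.
* The DE stage is a calibration-validated stand-in, not a DESeq2
  re-implementation; its LFC/SE values are not comparable to shrunken
  estimates.
* NG86 counting underestimates divergence at high substitution rates
  (Jukes–Cantor saturates at p = 3/4) and ignores transition/transversion
  and codon-frequency biases.
* Module detection on 4-sample designs is noisy by construction; results
  there are hypotheses, not findings.
* The unsigned network cannot separate anti-correlated modules; choose the
  signed variant when that distinction matters.
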