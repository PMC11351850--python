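# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `dielortho`, and what the synthetic benchmark does and
does not establish about real data.

## Count model and normalization

Counts are modelled as negative binomial with mean μ and variance
μ + φμ² (φ the dispersion; φ = 0 recovers Poisson). Normalization factors
are absolute per-sample size factors: normalized counts are counts divided
by the factor. Two estimators are provided:

- **TMM-flavored factors** — the reference sample is the column whose 75th
  percentile of counts-per-total is closest to the mean of those
  percentiles; per sample the factor is 2^(precision-weighted trimmed mean
  of M = log2(count/reference count)), trimming 30% of the M distribution
  and 5% of the A distribution on each side, over genes nonzero in both;
  factors are rescaled to product 1. Note this differs from the classic TMM
  convention, whose factors capture only compositional bias relative to
  library size; here the library-size ratio is folded into the factor so
  both estimators share one semantics (divide by the factor).
- **Median-of-ratios** — the median across genes of count / per-gene
  geometric mean, using only genes nonzero in every sample, with a TMM
  fallback (and a warning) when no such gene exists.

## Dispersion estimation

Per-gene φ is estimated by method of moments on normalized counts and
shrunk toward a mean–dispersion trend:

- raw estimate: pooled within-group variance divided by a *debiased* mean of
  squared group means (E[m̄²] = μ² + s²/n, so s²/n is subtracted). Using the
  grand mean here — the more obvious choice — inflates φ by 1.5–3× for
  strongly DE genes because the grand mean sits between the two group means;
  the debiased per-group denominator is unbiased under arbitrary group
  differences (verified by simulation at n = 3+3 over μ ∈ [20, 400],
  φ ∈ {0.05, 0.2}).
- trend: lowess of the raw estimates on log abundance, **non-robust**
  (`it=0`) because the raw estimator is strongly right-skewed and a robust
  fit tracks its median (≈ −15% at 4 df), which measurably inflates type-I
  error. Robustness against genuinely hyper-variable minorities is provided
  instead by an iterated cap: after a first fit, raw values are capped at
  χ²₀.₉₉(df)/df times the local trend and the fit is repeated (twice).
- trend abscissa: the **geometric mean of the group means**, not the grand
  mean. For null genes the two coincide; for strongly DE genes the geometric
  mean equals their baseline abundance, so they borrow strength from their
  true abundance peers. With the grand mean, strong DE genes cluster at the
  sparse top of the abundance range and the local trend there becomes
  unreliable, which directly weakens the p-values of exactly the genes the
  pipeline cares most about.
- shrinkage: φ = w·raw + (1−w)·trend with w = df/(df + prior_df),
  prior_df = 10 by default (heavy moderation, appropriate at 3 replicates
  per group).

Calibration under these defaults (10⁴ null NB genes, φ = 0.2, n = 3 per
group): the fraction of p < 0.05 is ≈ 0.056 for the exact test and ≈ 0.061
for the Wald test.

## Differential expression

**Exact test.** Samples are rescaled to a common effective library size by
dividing by their factors and rounding half-to-even. Conditioning on a
gene's grand total T, the group totals follow NB distributions whose sizes
add (n_k/φ); the two-sided p-value sums the probabilities of every split of
T whose probability does not exceed the observed split's. All of this runs
in natural-log space (log-sum-exp), so extremely significant genes keep
finite, ordered log p-values instead of underflowing to 0 — the adjusted
p-values are also carried as log10 values. φ = 0 uses the Poisson limit
(conditional binomial). For grand totals ≤ 50 the implementation agrees
exactly with an independent enumeration oracle built directly on
scipy's pmf.

**Wald test.** Per gene, log μ = offset + β₀ + β₁·night with offset
log(factor), fitted by IRLS vectorized across genes (weights μ/(1+φμ),
closed-form 2×2 solve per iteration, 100 iterations max, tolerance 1e-8).
p is the two-sided normal tail of β₁/SE with SE from the observed
information. Genes with an all-zero group are refitted on counts + 0.5, a
documented fallback that keeps the estimate finite; wholly zero genes report
p = 1.

**Fold change.** log2((night mean + 0.5)/(day mean + 0.5)) on normalized
counts — the 0.5 pseudo-count only affects the reported fold change, not the
tests. Positive = night overexpression; relabeling day↔night negates every
log2FC exactly.

**Significance and consensus.** BH (computed in log space, identical to the
standard step-up on ordinary values), significant ⇔ adjusted p < 0.05 and
|log2FC| ≥ 2 (log2 units; the exclusion window −2 < FC < 2 is read in log2
units since linear fold changes below −1 are impossible). The consensus set
is the intersection of the two methods' significant gene ids.

## Orthology

Pairwise similarity is full Smith–Waterman under BLOSUM62 with gap open 11 /
extend 1; identity = matches / aligned columns. Reciprocal best hits (RBH)
tie-break by identity then lexicographic id. For large proteomes an exact
all-vs-all scan is quadratic and dominates the runtime, so candidates are
shortlisted by shared 4-mer counts (top 8 candidates per query) before full
alignment; exhaustive scanning is used automatically below 250 000 sequence
pairs and can be forced. On the generator's proteomes (point-substituted
copies at 5% per residue) the shortlist loses no planted pair: recovery of
planted 1:1 orthologs is 100% at default settings, and the planted
transcript → reference map is reproduced essentially without error.

Orthogroups are connected components of the RBH graphs (species↔reference
and species↔species) containing exactly one reference gene; components with
several reference genes are split by best-hit assignment (logged), and
reference-free components are retained as direct pairwise links so flips
without a reference anchor are still discoverable. Representatives per
species maximize identity to the reference, with length breaking ties within
0.01 identity and lexicographic id last ("longest and most similar", with
similarity taking precedence because the reference anchors annotation).

## Collapse, flips, coincidence, candidates

Collapse keeps, per species and reference gene, the transcript with the
smallest adjusted p (ties: largest |log2FC|, then id). Pattern classes over
the two species' results are mutually exclusive: concordant_day/night (both
significant, same sign), flipped (both significant, opposite signs),
single_species_strong (one significant at |log2FC| ≥ 5), else not_shared.
Diel coincidence is the active-phase reading — day-up (negative log2FC) in
the diurnal species and night-up (positive) in the nocturnal one; the
rest-phase mirror is available for sensitivity analysis. A zero or missing
fold change makes the call undefined (reported as such).

Candidates score one point per criterion: DE in both species, coincident,
and any GO term mapping to the six functional categories. Ranking is score
descending, then **combined evidence** — the sum of per-species log10
adjusted p — then largest |log2FC|, then id. Min adjusted p (the more
common rank key) is reported but not used for ordering: at the effect sizes
this pipeline targets, double-precision p-values underflow and min-p cannot
order the strongest candidates, and it also rewards a lucky single species
over consistent strength in both.

## Enrichment

Classic one-sided hypergeometric over-representation; the background is the
expressed-and-annotated set (not the whole annotation universe), BH within
GO namespace (global optional), terms with fewer than 3 background hits
skipped. Graph-aware decorrelation (the "elim" family of algorithms) is not
implemented. The permutation null is slightly conservative (discrete test):
about 3% of term tests reach p < 0.05 at nominal 5%.

## Co-expression network

Expression is log2(normalized count + 1), z-scored per gene; the combined
analysis concatenates both species' samples over the shared reference-gene
set. Adjacency is **signed**, ((1+cor)/2)^β: with exactly two species,
"elevated in A" and "elevated in B" modules are mirror contrasts of the same
species indicator, and an unsigned network merges them by construction; the
signed network keeps them apart, matching the two separate species-specific
clusters this analysis is designed to expose. β is the smallest candidate
whose connectivity distribution fits a power law with R² ≥ 0.8 (10
equal-width bins, negative slope required), with an argmax fallback.

TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij); modules come from
average-linkage clustering on 1 − TOM with a static cut at 0.85 × the
maximum merge height, minimum size 10, followed by one pass of
module-membership pruning: genes whose correlation with their module's
eigengene is below 0.8 return to grey. The cut height and pruning threshold
were calibrated on planted-truth simulations (a bare static cut attaches
chance-correlated noise genes to real modules at 12 samples); the dynamic
tree cut used by the reference implementation of weighted network analysis
is deliberately not reimplemented. Eigengenes are the first principal
component of the standardized member matrix, oriented so the mean member
correlation is positive, unit variance; they match an independent SVD
oracle up to sign. Module–trait association is the Pearson correlation of
each eigengene with the binary phase and species indicators.

## Conservation

Per alignment column, raw = (1 − H/ln 20)·(1 − gap fraction), with H the
Shannon entropy (natural log) of non-gap residue frequencies; the ln 20
normalization is fixed regardless of the observed alphabet so scores are
comparable across columns. Smoothing is a centered moving mean of window 5
with truncated edges; grades 1–9 are noniles of the smoothed score (9 most
conserved). Conserved blocks are maximal runs of ≥ 30 columns with smoothed
score ≥ 0.8. Focal-pair mutations are columns where both focal residues are
non-gap and differ; columns where exactly one is a gap are reported
separately as indel sites. This is a deliberate sequence-level replacement
for Bayesian evolutionary-rate estimation with structural context: "in a
conserved block" here is a conservation-only criterion and may not match a
structure-aware definition of a functional region.

One caveat: column entropy is not monotone under adding sequences —
duplicating a minority sequence can lower a column's score — so the test
surface asserts order-invariance and whole-alignment-duplication invariance
instead of monotonicity.

## Synthetic study conditions

Defaults describe the emulated design: 2 species (one diurnal, one
nocturnal) × day/night × 3 replicates; 2000 reference genes (80% 1:1, 10%
many-to-1, 10% species-specific); log-normal baselines (ln-mean 4.5, ln-sd
1.0, i.e. typical counts around 100) shared across species for orthologs;
NB dispersion 0.1 (biological replicates of lab-reared insects); library
sizes log-normal with CV 0.2. Planted effects: 50 coincident flips at
summed magnitude 6 log2 (±3 per species), 30 concordant genes, 20
single-species responders at ±6; one key candidate planted as the strongest
coincident flip (±6 per species, fixed baseline e⁶ ≈ 400, always carrying a
circadian GO term) — by scenario definition the headline gene is robustly
expressed with very large fold changes in both species. Four modules of 50
genes (two species-specific, one diel, one shared latent) with amplitude
1.5 and bounded factors; the shared latent is scaled to 0.5·N(0,1) so module
swings are comparable to the planted DE effects. GO: 18 category terms + 12
others at base rate 0.02, circadian terms enriched 10× among flipped genes.
Protein family: 18 background species plus two focal sequences over 400
gap-free columns, one conserved block (columns 100–210), substitution rates
0.02 in-block / 0.30 outside, and exactly 3 in-block + 20 out-of-block focal
differences.

What passing these benchmarks does **not** show: the generator draws
independent genes (no correlation beyond the planted modules), emits gap-free
alignments (no indel handling), uses a single dispersion for all genes, has
no batch or lane effects, no isoform-level switching within genes, and the
orthology proteins diverge by point substitution only. Real cross-species
data violate all of these to some degree; the benchmark validates the
machinery, not field performance.

## Problem sizes

The validation suite uses the study-scale defaults throughout: 10⁴ genes for
null calibration, 20 simulated studies for flip recovery and candidate
ranking, 20 for module recovery, 200 permutations for the enrichment null.
The reproduction script (`scripts/acceptance.py`) uses 10 studies for the
recovery metrics and 5 for module recovery, which keeps a full run in the
single-digit minutes on one CPU while leaving the Monte-Carlo error on each
reported rate below a few percent.
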