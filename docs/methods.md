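# Methods

This note records the statistical model, the estimators actually
implemented, the synthetic-data generator's assumptions, the numerical
choices, and the known limitations. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The hierarchical allele-frequency model

Pool-seq gives, per SNP *j* and population *i*, reference/alternate read
counts; p̂<sub>ij</sub> = alt/(ref+alt) estimates the population allele
frequency. With π<sub>j</sub> the unweighted across-population mean (the
population, not the read, is the unit of replication), the scaled
deviations y<sub>ij</sub> = (p<sub>ij</sub> − π<sub>j</sub>)/√(π<sub>j</sub>(1−π<sub>j</sub>))
are modelled as **y**<sub>j</sub> ~ N(0, **Ω**). **Ω** absorbs shared
demographic history: whitening by its Cholesky factor removes the
population-structure component from every downstream statistic.

The full Bayesian treatment of this model (MCMC over **Ω**, π and the
SNP effects) is deliberately replaced by a moment/closed-form pipeline
that preserves the estimand structure at desk scale; the `estimator` tag
on the Ω object records the variant.

### Ω estimation and the identifiability caveat

Centering at the sample mean makes the columns of **y** sum to zero, so
the raw moment matrix **M** = S⁻¹Σ**y**<sub>j</sub>**y**<sub>j</sub>ᵀ
estimates **HΩH** with **H** = **I** − **11**ᵀ/K: the component of **Ω**
along the all-ones vector cannot be identified from frequency data.
We complete the estimate as **Ω̂** = **M** + γ**11**ᵀ with
γ = −median(offdiag **M**), floored at a small positive value. The anchor
encodes the assumption that the *typical* pair of populations shares no
drift beyond the global mean; it is exact for an independent-populations
truth and for equal-block structures where between-block covariance is
zero, and it guarantees positive-definiteness for any γ > 0.

Two consequences worth knowing:

* every whitened-domain statistic of a mean-zero vector (X<sup>T</sup>X,
  BFdB, whitened covariates) is *invariant* to γ, so the scan does not
  depend on the completion — only the reported **Ω̂** matrix does;
* for densely correlated truths (e.g. a smooth spatial decay where most
  pairs do covary) the median anchor under-reports the common covariance
  level. The projection **HΩ̂H** is still consistent, which is the part
  the scan uses.

A `shrinkage` option blends **Ω̂** toward its diagonal with a Ledoit-style
intensity for small-SNP regimes.

### X<sup>T</sup>X degrees-of-freedom correction

Centering at π̂ removes one degree of freedom: the raw
**z**ᵀ**z** has null mean exactly K−1 under the self-consistent moment
**Ω̂** (a trace identity, not an approximation). The reported statistic is
therefore (K/(K−1))·**z**ᵀ**z**, restoring the χ²<sub>K</sub> scale with
null mean K. The correction is on by default and switchable
(`xtx(..., df_correction=False)`).

### The Bayes factor

With **ẽ** = **L**<sup>−1</sup>(standardized covariate) and prior
β ~ N(0, τ):

BF = (1 + τ‖**ẽ**‖²)<sup>−1/2</sup> · exp( τ(**ẽ**ᵀ**z**)² / (2(1 + τ‖**ẽ**‖²)) ),
reported in decibels. This is the exact marginal-likelihood ratio for the
conjugate linear model (verified against numerical quadrature to 1e-6
relative error in the tests). τ defaults to 0.1 — a weak effect prior on
the standardized scale; BFdB magnitudes scale with τ but the *ranking*
across SNPs (which is what the local score consumes) does not, so zone
calling and enrichment are τ-insensitive. The scan splits SNPs into 19
contiguous chunks computed independently and merged in genome order; with
a fixed global **Ω̂** and a deterministic estimator, chunking and the
three-run averaging are exact no-ops (logged as such).

## Local score

Per variable, BFdB values are ranked over the full SNP set (rank 1 =
largest; ties broken by genomic position) into pseudo-p-values
p = rank/N, giving site scores x = −log₁₀ p − ξ with ξ = 3 (only SNPs in
the top 10⁻³ fraction contribute positively). The Lindley process
h<sub>i</sub> = max(0, h<sub>i−1</sub> + x<sub>i</sub>) runs per scaffold
and resets across scaffold boundaries; it is computed via the closed form
h = S − running min S, which the tests check against the brute-force
max-subarray definition.

**Thresholds.** The null for a scaffold's maximal Lindley score is built
by resampling site scores from the genome-wide score pool (site scores
are exchangeable across the genome under the rank-uniform null), taking
the (1−α) quantile of the resampled maxima at α = 0.05; scaffolds of
equal SNP count share one null. A within-scaffold permutation was
considered and rejected: conditioning on the scaffold's own score multiset
makes the observed maximum tie with its permutation distribution whenever
a single large score dominates, driving the type-I rate to ~0 instead of
α. A Gumbel option fits location/scale to the same resampled maxima for a
distributional threshold. Zones are maximal runs of h > 0 whose peak
exceeds the scaffold threshold and which contain more than three SNPs
(`min_zone_snps = 4`); zone extent is the full positive run, reported
1-based inclusive internally and 0-based half-open in BED exports.

## Enrichment

Top tails are the ⌈N·f⌉ largest scores at f = 0.05% (boundary ties broken
by position). The association tail defaults to the Lindley-corrected
track (a flag switches to raw BFdB). Expected overlap is |A||B|/N — the
hypergeometric mean, asserted exactly in the tests. Significance comes
from rotating A's positions along the concatenated genome (scaffolds in
descending size order) by a nonzero uniform offset, which preserves |A|
and its internal spacing and therefore respects clustering. The reported
p-value uses the add-one estimator (never zero, slightly conservative on
the discrete overlap count); a `mid-p` variant (half weight to ties) is
exposed because the add-one estimator is sub-uniform by construction on a
discrete statistic — the calibration suite uses mid-p, and does so at
tail sizes large enough (|A| = |B| = 1000 of N = 10,000) for a
continuous-uniform KS reference to be meaningful. Stars follow the
conventional 0.05/0.01/0.001 cutpoints.

## Ecology

The eight species-level network indices are computed from the
populations × categories visitation matrix with natural logarithms
throughout; q is the availability distribution (column totals). The d′
index uses the Kullback–Leibler divergence d = Σ p ln(p/q) normalized by
the analytic maximum ln(1/q<sub>min</sub>) (all visits on the rarest
available partner), with d<sub>min</sub> = 0 so that d′ = 0 exactly when
a population uses partners in proportion to availability. Species
specificity is the coefficient of variation of the interaction counts
(population sd) normalized by √(C−1) so a single-category specialist
scores exactly 1. With integer counts and fixed marginals the exact
combinatorial extremes of d are narrower than the analytic bounds, so
observed d′ rarely approaches 1 — acceptable for comparing populations,
not for absolute cross-study comparison.

Visitation BLUPs come from the one-way random-effects model fitted by
REML (statsmodels MixedLM); predictions are μ +
shrink<sub>k</sub>(ȳ<sub>k</sub> − μ) with shrink<sub>k</sub> =
σ²<sub>pop</sub>/(σ²<sub>pop</sub> + σ²<sub>res</sub>/n<sub>k</sub>),
cross-checked against the model's own BLUPs. Spearman pruning scans
offending pairs (|ρ| ≥ 0.8) by descending |ρ| then lexical pair order and
drops the later-in-input-order member unless the pair is already
resolved; constant variables are excluded from decisions and retained.
PCA standardizes variables (correlation-matrix eigendecomposition) with
the largest-magnitude loading forced positive; the genomic ordination is
an SVD of the centered populations × SNPs matrix of *raw* frequencies
(deliberately uncorrected, to expose the structure the scan removes).

## The synthetic-data generator

The generator emulates the study conditions the pipeline is built for:

* **21 populations** on a unit-spaced 1-D transect; **Ω** =
  scale · (nugget·**I** + (1−nugget)·exp(−d/range)) with defaults
  scale 0.15, nugget 0.1, range 8 — strongly structured, as real regional
  population systems are. The scale is the drift variance of scaled
  frequencies since the ancestral population (an F<sub>ST</sub>-like
  quantity; 0.05–0.3 is the realistic regional band). Identity and
  equal-block structures are available for estimator validation.
* **Ancestral frequencies** π ~ U(0.05, 0.95); frequencies are generated
  on the natural scale as clamp(π + √(π(1−π))·y, 0.005, 0.995). The clamp
  keeps cells away from degenerate Bernoulli draws but truncates the
  normal tails where π is near the boundary and drift is large — at the
  defaults this attenuates the recoverable variance by a few percent,
  which is why estimator-recovery experiments run in the interior
  frequency regime (π ∈ (0.2, 0.8)) where the generator is linear.
* **Reads**: per cell, depth ~ Poisson(mean depth), alternate count ~
  Binomial(depth, p); zero-depth cells become missingness events. Poisson
  depth (not fixed) exercises the mean-depth filter realistically.
* **Environment**: a latitude-like gradient (confounded with the
  transect, emulating geography-aligned variables) plus
  population-specific noise variables. The spiked (causal) variable is a
  population-specific one by default, matching systems where measured
  ecological variables correlate only weakly with the leading genomic
  axis. Spiking adds β·standardized(env) to the frequencies of
  `n_adaptive` SNPs, optionally in blocks of adjacent SNPs — the
  positional clustering stands in for linkage disequilibrium, which the
  generator does not otherwise model.
* **Visitation**: negative-binomial counts per (population, category)
  with configurable dispersion (Poisson in the limit), plus an optional
  per-plant decomposition with a population random effect for BLUP
  testing.

What passing tests on these data do **not** show: robustness to
reference/mapping artefacts, indel-adjacent miscalls, unequal pool sizes,
real LD decay, or ecological sampling error in the covariates — none of
which the generator emulates.

## Problem sizes and numerical choices

The calibration and power experiments run at 21 populations × 100k SNPs
(depth 60 null, depth 100 spiked; β = 0.2; 50 adaptive SNPs in five
10-SNP blocks), with power aggregated over four seeded replicates (20
blocks); Ω recovery uses 50k SNPs of block structure. The scaffold
type-I experiment uses 400 scaffolds of 250 i.i.d.-uniform site tracks.
All linear algebra is dense vectorized numpy; the full suite and the
acceptance script each complete in well under a minute on one CPU.

Other conventions: π is clamped to [0.01, 0.99] only in the scale
denominator (centering stays exact, keeping column sums of y at zero);
missing frequencies are mean-imputed after filtering (≤ 2 populations per
retained SNP) and so contribute exactly zero to y; an indefinite moment
matrix is repaired by an eigenvalue-floor ridge with a warning; filter
steps run in a fixed sequential order (non-biallelic, indel, mean depth
outside [6, 100] over non-missing pools, missingness > 2 populations,
scaffold whitelist) with each step counted on the survivors of the
previous one; VCF/GFF coordinates are 1-based inclusive at interfaces and
zones convert to 0-based half-open only in BED output.

## Known limitations

* The Ω completion understates dense common covariance (above); only the
  **H**-projected part is consistent in that regime.
* BFdB values are not comparable to MCMC-based Bayes factors from the
  full hierarchical model — the ranking is the supported interface.
* Pseudo-p-values are rank-based by construction, so one variable's
  Lindley track is never comparable in absolute height to another's with
  different N.
* The circular permutation null assumes exchangeability of the top-SNP
  positions up to rotation; strong scaffold-length heterogeneity plus
  boundary effects are only approximately handled by concatenation.
* d′ normalization uses analytic (not combinatorial) extremes; see above.
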