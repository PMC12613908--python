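# Methods

## The analysis

`psynet` implements a symptom-network analysis of psychosocial
questionnaire data, of the kind used to study how depression, anxiety,
loneliness, self-esteem, perceived social support, sociosexual
orientation and internalized homonegativity interrelate in a
cross-sectional sample, and how structurally central problems relate to
a composite high-risk sexual-behavior score.

The pipeline has six stages.

1. **Scoring.** Seven instruments contribute 58 items. PHQ-9, GAD-7,
   UCLA-3 and RSES enter the network item-by-item (29 nodes); MSPSS,
   SOI-R (attitude and desire facets) and SIHS enter as subscale scores
   (8 nodes), for p = 37 nodes. Negatively worded items (five RSES
   items, SOI-R item 6) are reverse-coded for scoring; item *nodes* are
   by default also aligned to a common direction (`item_polarity:
   aligned|raw`). The SOI-R behavior facet is excluded from the network
   because it overlaps with the outcome. The composite risk score is the
   sum of the condom-use code (1–4) and partner-count code (1–5).

2. **Network estimation.** Pairwise Spearman correlations (chosen for
   ordinal items) feed an l1-penalized Gaussian likelihood (graphical
   lasso, diagonal unpenalized). The penalty is selected on a 100-point
   log-spaced grid (`lambda_min/lambda_max = 0.01`, `lambda_max =
   max |off-diagonal correlation|`) by the extended BIC with sparsity
   weight gamma = 0.5 — the conventional default when the source
   analysis names the method but no tuning constants. Edge weights are
   partial correlations `-k_ij / sqrt(k_ii k_jj)` of the selected
   precision matrix. Node predictability is the OLS R² of each
   (standardized) node on its selected neighbors.

3. **Centrality.** Strength (sum |w|), one-step expected influence
   (sum w), and betweenness/closeness on the distance graph with edge
   lengths 1/|w| (the standard convention for association networks;
   closeness is the inverse *mean* shortest-path distance, with
   unreachable pairs excluded rather than propagated as infinities, and
   isolated nodes set to 0). Betweenness counts unordered pairs,
   endpoints excluded, with fractional credit for tied paths. The
   z-standardization uses the population (denominator-n) convention.

4. **Stability.** Edge accuracy by nonparametric bootstrap (resampling
   participants with replacement, percentile 2.5/97.5 intervals);
   centrality stability by case-dropping subset bootstrap. The CS
   coefficient is the largest drop proportion q at which >= 95% of
   subsample-vs-full centrality correlations are >= 0.7; the default
   drop grid is 8 evenly spaced proportions in [0.05, 0.75]. Penalty
   selection is re-run inside every resample so selection uncertainty is
   propagated. When a subsample yields an empty network, its centrality
   correlation is recorded as 0 (counted as unstable), which makes CS = 0
   the expected outcome on independent data.

5. **Network comparison.** Two-group permutation test: structure
   invariance M = max |W1 - W2|, global strength S = |sum|W1| - sum|W2||,
   and per-edge differences, with group labels permuted over the pooled
   sample preserving sizes and both networks re-estimated per
   permutation. P-values use the plus-one estimator (1 + #{stat* >=
   stat}) / (1 + B) and are never zero. Per-edge tests cover only edges
   nonzero in at least one observed network and are Holm-corrected at
   0.05 (raw p-values are also exported). A caveat observed in
   simulation: edges absent from both groups have a point-mass
   permutation null under sparse re-estimation, so small noise edges can
   occasionally be co-flagged next to a genuinely different edge.

6. **Linkage ("connection values").** Each node's Spearman correlation
   with the composite risk score, per stratum (total, age < 33,
   age >= 33; 33 approximates the sample mean age). Connection value is
   then regressed (OLS) on expected-influence centrality across the 37
   nodes, with a LOWESS trend (fraction 2/3, 3 robustifying iterations).
   Both the raw slope and the standardized coefficient are reported
   because the published convention is ambiguous.

## The solver

The graphical lasso is solved by the standard block coordinate descent
(row/column lasso subproblems solved by coordinate descent), jit-compiled
with numba and warm-started along the penalty path. This makes one full
EBIC path on 37 nodes cost ~40 ms, which is what allows the resampling
stages (tens of thousands of re-estimations) to run on one CPU. The
solver is cross-checked in the test suite against
`sklearn.covariance.graphical_lasso` (agreement to ~1e-3 on the partial
correlation scale at matched tolerances) and against exact matrix
inversion at zero penalty. Convergence is declared when the mean
absolute change of the working covariance per sweep falls below 1e-4 of
the mean absolute off-diagonal input (max 200 sweeps). Edges below 1e-8
in absolute value are structural zeros. Non-PSD Spearman matrices are
repaired by eigenvalue clipping at 1e-6 followed by re-standardization.

## The synthetic cohort generator

No raw data are distributable, so the generator emulates the study
conditions; its defaults *are* those conditions and downstream tests
interpret them as fixed.

* **Ground truth.** A 37x37 partial-correlation template combines
  (a) fully connected within-construct blocks whose exchangeable-block
  partial correlation `omega = r / (1 + (k-2) r)` is derived from a
  target inter-item correlation r per scale, jittered ±5% per pair —
  targets are set so the *observed* ordinal reliabilities land near the
  published Cronbach's alphas (0.76–0.93); (b) the nine published
  cross-construct bridge edges at their printed weights (0.23 anhedonia–
  nervous, 0.25 companionship–desire, ..., 0.08 gay-identity-comfort–
  family-support); and (c) a sparse random-sign cross-construct
  background (density 0.05, weights 0.02–0.05) reflecting the density of
  the published network (node predictability 39–64%). If the implied
  precision I - Theta is not positive definite with margin 0.01, all
  off-diagonals are shrunk by a common recorded factor.

* **Age groups.** Age is a two-component normal mixture (means
  24.3/43.6, SDs 4.3/7.9, mixed 213:192, clipped to 16–76); rows with
  age >= 33 follow the older-group truth. The printed weights are
  total-sample estimates, so cross-cluster entries are scaled
  `young = 2/(1+a)`, `old = 2a/(1+a)` around the template (pooled value
  = printed, old/young ratio = attenuation a, default 0.5). Depression
  and anxiety form one "emotional" cluster exempt from attenuation, and
  three depression–anxiety ties (tired–irritable, psychomotor–worrying,
  sleep–nervous) get +0.05 in the older group, mirroring the reported
  age pattern.

* **Measurement.** Latent node values are multivariate normal with the
  correlation implied by the group truth; items are thresholded into
  their integer ranges (Gaussian copula) with per-scale category
  probabilities matching the published sample means (e.g. depression
  total ~4.6/27, support subscales ~4.7/7, 19% UAI, 69% MSP). Items of
  subscale nodes load 0.9 on their node latent; SOI-R behavior items
  load 0.6 on the desire node. Reverse-keyed items are stored as raw
  (reverse-keyed) responses so the scoring path is genuinely exercised.

* **Risk behavior.** A latent risk r = w'z + noise (weights negative on
  emotional symptoms, support and acceptance of one's orientation;
  positive on loneliness and especially sociosexual desire) is cut at
  empirical quantiles into the two behavior codes, one independent noise
  draw per code so the codes are not artificially comonotone.

**What the generator does not reproduce.** A Gaussian copula with the
published (heavily skewed) marginals attenuates rank correlations by
roughly a factor 0.7–0.85 relative to the latent values, so observed
inter-item correlations cannot reach the very highest published
reliabilities without making the within-construct blocks numerically
singular; real questionnaire data evidently carry stronger (likely
tail-dependent, heterogeneous-loading) dependence than the copula can
encode at these marginals. Consequently, at n = 405 the weakest printed
bridge edges (|w| ~ 0.08–0.11, further halved in the older group) sit
below the selection threshold of the EBIC (gamma = 0.5) graphical lasso
more often than in the source analysis: the end-to-end recovery suite
finds a median 7 of 9 bridge edges in the selected graph (all 9 on
continuous latent data), with true-vs-estimated edge-vector correlation
~0.90. Passing tests therefore demonstrate sign- and rank-faithful
recovery of the printed backbone, not the detectability of every
individual weak edge at this sample size.

## Monte-Carlo problem sizes

Resampling defaults follow the source analysis (1,000 bootstrap /
permutation iterations); the test suite and the acceptance script use
reduced sizes chosen to keep a full run on one CPU within minutes, as is
standard for CI-scale simulation: NCT type-I calibration uses 100 null
replicates x 200 permutations on the 16 emotional-item columns
(permutation calibration does not depend on node count), NCT power uses
20 seeds x 100 permutations at the full 37 nodes, case-dropping
stability uses B = 250 (strong-signal check at n = 2000; noise check on
a 12-node subset), and the acceptance script uses B = 200 permutations
and B = 100 case-dropping resamples. Reduced lambda grids (25–40 points)
are used inside resampling loops; the EBIC optimum is insensitive to
grid resolution at this scale.

## Numerical and design choices

* Spearman ties use average ranks; zero-variance nodes are an error
  naming the node.
* lambda = 0 falls back to exact matrix inversion (used by the oracle
  tests on p <= 4 problems).
* EBIC ties prefer the larger penalty (sparser model).
* The chi-square test for Table-1 style group comparisons is Pearson's
  without continuity correction; t-tests assume equal variances;
  zero-variance variables report NaN rather than raising.
* Loneliness prevalence uses UCLA-3 total >= 6 (a common screening
  convention; the source reports a prevalence without a cutoff).
* Abstinence ("no sexual activity", code 1) ranks below consistent
  condom use on the risk item — preserved as published, not re-designed.
* The printed SIHS-public-identification x SOI-attitude edge (-0.11)
  contradicts its verbal description ("positively associated"); the
  numeric value is used and is configurable.
* Listwise deletion treats all 58 items, both behavior codes and age as
  key variables.

A related consequence: the permutation comparison's max-edge-difference
statistic has little power against the generator's bridge-attenuation
age alternative at n ~ 200/group — the true maximum group difference
(~0.26) sits inside the statistic's permutation null (median ~0.22),
which is dominated by sampling noise of sparse re-estimated networks.
The calibration suite therefore verifies the test's type-I error (which
is exact by construction and measures ~5-8% at nominal 5%), while
detecting the age contrast at this effect size is not reliably
achievable under the copula conditions.

## Known limitations

* Polychoric correlations are not implemented; all 37 nodes get one
  rank-based treatment regardless of whether they are ordinal items or
  quasi-continuous subscale scores.
* No bridge centrality, community detection, moderated or Bayesian
  networks; no centrality-invariance test in the comparison module.
* The generator emulates the printed network backbone and marginals,
  not the study's full (unpublished) covariance structure.
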