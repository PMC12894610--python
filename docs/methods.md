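# Methods

## Data model

A stimulus table has one row per emotion-eliciting video: validated category
(disgust, fear, amusement, sexual_desire, neutral), mean valence and arousal
on the 1–9 Likert scale (5 = neutral anchor), per-label endorsement
fractions (multi-select with an optional "none of the above" column, so rows
need not sum to 1), and a five-class classifier probability vector
constrained to the simplex within 1e-6 per row. Subject-level ratings are a
long-format (subject, video, valence, arousal) table; missing entries are
allowed and ignored in means. The optional none-of-the-above column is
stored but excluded from every predictor set. Category tokens are fixed
lowercase snake_case; CSVs are UTF-8, comma-separated, "." decimal, header
required.

## Synthetic-data generator

The generator emulates a study with 5 balanced categories × 26 videos
(130 stimuli) rated by 110 subjects. It exists so every downstream stage is
testable under *known* ground truth in each of the two competing regimes:

- **Discrete regime.** Probability vectors are Dirichlet draws with mean
  centroid 0.6 on the own class and 0.1 elsewhere, concentration κ
  (default 30, giving own-class sd ≈ 0.09 — clearly clustered but
  overlapping, comparable to a moderately good classifier). The five
  centroids span four simplex dimensions, so no 2-D representation can be
  sufficient. Endorsements follow a category profile (own label
  0.08 + 0.62·fidelity, default fidelity 0.9 → ≈ 0.64, in the range of the
  observed self-report diagonal; off labels 0.08) plus N(0, 0.08) jitter,
  clipped to [0, 1].
- **Core-affect regime.** A latent (v, a) is drawn per stimulus around its
  category affect mean with sd σₑ and clipped to [1, 9]; category logits are
  the affine map γ(2 x·μ_c − ‖μ_c‖²) (γ = 0.5), which is the affine form of
  a Gaussian-affinity rule around the category affect means; probabilities
  are the softmax of these logits plus N(0, 0.5) noise. Endorsements are a
  clipped affine function of the centered noise-free logits with a slope
  (0.04) small enough that the clip essentially never binds: a monotone link
  that, by construction, carries no information beyond (v, a). A logistic or
  saturating link would inject genuinely nonlinear features of (v, a) and
  would falsify the regime's defining property that adding endorsements to
  (v, a) cannot improve prediction of the probabilities.

A note on dimensionality: the softmax of an affine 2-D map lies on a curved
two-dimensional manifold of the simplex, not a 2-plane, so the *centered
probability matrix* of a noise-free core-affect run has rank 4, not 2. The
exact rank-2 statement holds in log-ratio geometry: the column-centered
centered-log-ratio (clr) transform of the noise-free probabilities has rank
≤ 2, which is what the tests assert. Raw-probability PCA in this regime is
2-component *dominated* (top-2 ratio ≈ 0.8 at the defaults), not 2-component
exact.

Category valence means default to the reported stimulus-validation values
(disgust 2.82, fear 3.73, amusement 6.57, sexual desire 5.51, neutral 5.21).
No arousal summaries are reported anywhere, so arousal means are free
parameters chosen once to separate the low-activation neutral category
(2.5) from the emotional ones (5.5–6.5). One σₑ (default 0.8 Likert points)
serves as both the stimulus-level affect spread and the per-rater noise in
subject ratings. The root seed is fanned out through `SeedSequence` into
independent substreams (affect, probabilities, endorsements, subjects), so
adding a stage never perturbs earlier draws; identical config + seed gives
bit-identical tables.

## Cluster evaluation

Features are z-scored per column (sample sd, n−1; zero-variance columns are
an error). Clustering is agglomerative complete linkage on Euclidean
distances (scipy), cut by `maxclust`; cluster codes are relabeled in order
of first appearance for determinism. With continuous features, equal-distance
merge ties have probability zero; the implementation is checked against an
exhaustive greedy-merge oracle on all instances with n ≤ 7.

NMI uses arithmetic-mean normalization 2·MI/(H_r + H_c) with natural
logarithms (the variant is unstated in the source analyses; this choice is
the common symmetric default, and NMI is base-invariant under matched
normalization). A contingency table with a single-cluster marginal returns
0 by convention. The permutation comparison of two representations holds
both clusterings fixed and jointly permutes the truth labels B times
(default 10,000 in the statistical API; the pipeline config defaults to 999
to keep a full run interactive), with the one-sided p-value
(1 + #{≥ observed})/(B + 1); ties count toward the null. Permuting labels
conditions the test exactly on the two clusterings, which is the contrast
actually reported ("does representation A fit the categories better than
B?"). Majority labeling of clusters breaks ties by canonical category order
and flags them.

## PCA and t-SNE

PCA is the column-centered eigendecomposition of the sample covariance
(sklearn full SVD), components ordered by variance, with the sign convention
that each component's largest-magnitude loading is positive. When called
from the pipeline the features are already z-scored, so covariance and
correlation PCA coincide. t-SNE (perplexity 10, PCA init, fixed seed) is
provided for figures only and takes no part in any quantitative result.

## Model comparison

Folds are stratified by category and dealt shuffled-least-filled, so fold
sizes differ by at most one and each fold holds 2–3 stimuli per category at
130/5/10; the same fold assignment is shared by every model in a comparison.
Predictors are standardized with training-fold statistics. One model is fit
per outcome column; predicted probability columns are not renormalized to
the simplex (matching independent per-target fits). A rank-deficient linear
design falls back to ridge with penalty 1e-6 and a logged warning — this is
the expected path for the combined predictor set in the core-affect regime,
where endorsements are collinear with (v, a) by construction.

Pooled R² = 1 − ΣSSR/ΣSST across targets. The SST baseline is the grand
observed mean per target for the headline value and the test fold's own
means for per-fold values; both are reported because the original
convention is unrecoverable. CV is k-fold alone (the alternative reading,
a separate holdout plus CV, is not implemented). SVR hyperparameters are
tuned by random search over log-uniform ranges (C ∈ [1e-2, 1e3],
γ ∈ [1e-3, 10], ε ∈ [1e-3, 1], degree ∈ {2, 3, 4}) scored by inner 5-fold
CV within each training fold only — a conservative nested protocol chosen
to avoid optimistic leakage, at the cost of possible divergence from any
non-nested original. Note that with few draws random search can select
worse-than-default hyperparameters; the tuning contract is mean-level
("does not hurt, up to sampling error") and is tested that way. Fold-paired
model comparison reports mean per-fold test differences with an exact
one-sided sign-flip p-value (all 2ⁿ sign patterns for n ≤ 12 folds).

## Reliability

Each run splits the rater sample into two disjoint equal halves (an odd
rater is dropped at random), computes per-video mean valence/arousal per
half ignoring missing entries, and correlates the halves across videos
(Pearson by default, Spearman optional). The reported value is the mean of
per-run correlations (default 10 runs). Under the variance-components model
(true stimulus-mean variance τ², rater noise σₑ², m raters in total), the
expectation is τ²/(τ² + 2σₑ²/m); simulation at τ = 1, σₑ = 1, m = 100
reproduces 1/1.02 ≈ 0.980 to within Monte-Carlo error.

## Problem sizes and what the tests show

Unit and property tests run at small n (tens to 130 stimuli); Monte-Carlo
checks use 500 null replicates at B = 199 for permutation calibration, 50
synthetic replicates per regime for regime recovery (10 for the SVR
variant), and 30 simulated rater samples for the reliability closed form.
These sizes make the suite complete in about a minute on one CPU while
leaving binomial error bands well inside the asserted ranges.

Passing regime-recovery tests show that the pipeline *separates the two
generative hypotheses when they are true by construction* — discrete-regime
data yield higher discrete-predictor R² and a real 5D-over-2D clustering
advantage, core-affect-regime data do not. They do not show that real
facial-physiology data follow either regime, and none of the reported
statistics of the original stimulus set (its NMI values, R² table, PCA
loadings or reliability) are reproduced here: those require the original
data, which are available only on request. The generator also idealizes in
known ways: balanced categories, Gaussian rater noise, independence of
rater noise across subjects and videos, and no missing ratings.

## Degenerate inputs and numerical choices

Probability rows must reach the simplex within 1e-6; z-scoring and pooled
R² refuse zero-variance columns by name; NMI clips tiny negative floating
residue into [0, 1]; argmax confusion resolves ties to the first canonical
category and reports the tie count; `fcluster` output is relabeled
deterministically; manifest checksums are SHA-256 over artifact bytes, and
manifests contain no timestamps so identical runs are byte-identical.
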