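# affectdim

Are the facial patterns that distinguish discrete emotions reducible to
valence and arousal? `affectdim` implements the stimulus-level statistical
pipeline for answering that question from the outputs of a five-class
facial-physiology classifier, together with a synthetic-data generator that
emulates the study design under both competing hypotheses.

## The scientific problem

An upstream classifier maps facial recordings of people watching
emotion-eliciting videos (disgust, fear, amusement, sexual desire, neutral)
to a probability vector p ∈ Δ⁴ over the five categories. The "core affect"
view holds that such bodily signals convey only two dimensions — valence v
and arousal a — so p should be explainable as a (possibly noisy, nonlinear)
function of (v, a). The maximalist alternative holds that the face carries
discrete-category information beyond core affect. The package quantifies
which view the data support, using three complementary statistics:

- **Cluster validity.** After z-scoring the five features, complete-linkage
  hierarchical clustering is cut at k clusters and compared with the
  validated categories by normalized mutual information,
  `NMI = 2·MI / (H_truth + H_clusters)` (natural logs, arithmetic-mean
  normalization). If category structure lives in only two dimensions,
  clustering the leading two PCA component scores should fit about as well
  as clustering the full five dimensions; the difference
  `NMI_5D − NMI_2D` is tested by permuting the category labels with both
  clusterings held fixed, `p = (1 + #{permuted ≥ observed}) / (B + 1)`.
- **Pooled cross-validated R².** One regression per outcome column
  (OLS, or ε-insensitive SVR with radial/linear/polynomial/sigmoid kernels
  tuned by nested random search), fit on shared stratified 10-fold splits,
  with fit pooled across the five targets as
  `R² = 1 − ΣₜSSRₜ / ΣₜSSTₜ` on out-of-fold predictions. Predictor sets:
  core affect (v, a), discrete (five label-endorsement fractions), or both.
- **Split-half reliability.** Raters are repeatedly split into halves;
  per-video mean valence/arousal from the two halves are correlated across
  videos (expectation `τ² / (τ² + 2σ²ₑ/m)` under a variance-components
  model with an m-rater sample).

Because the original study's data are not publicly deposited, the package
ships a generator for both regimes: *discrete* (Dirichlet draws around five
simplex centroids that span four dimensions, concentration κ) and
*core affect* (p = softmax of an affine map of latent (v, a) plus Gaussian
logit noise — exactly two underlying dimensions by construction).

## Worked example

```bash
python analysis/01_simulate.py --seed 0        # both regimes -> results/data/
python analysis/03_cluster_structure.py        # NMI curve, k=5 contingency
python analysis/04_dimensionality.py           # PCA + 5D-vs-2D permutation test
```

On the discrete-regime dataset (130 stimuli, κ = 30, σₑ = 0.8, seed 0) this
prints:

```
 k    nmi
 2 0.5897
 5 1.0000
 7 0.9549
k=5 solution: NMI = 1.0000
leading two components explain 51.9% of the variance
NMI(k=5): 5-D features 1.0000 vs. 2-component scores 0.8505;
one-sided permutation p = 0.001 (B = 999)
```

i.e. the five-cluster solution matches the categories exactly, the NMI curve
peaks at k = 5, and collapsing to two principal components loses real
category information (the permutation test rejects at its minimal attainable
p). `analysis/05_model_comparison.py` completes the argument: discrete
predictors reach mean test pooled R² ≈ 0.85 vs. ≈ 0.34 for core affect on
the same folds, while in the core-affect regime adding discrete predictors
to (v, a) gains nothing. `analysis/06_reliability.py` reports split-half
correlations ≈ 0.99 for the 110-rater synthetic sample.

The same stages are available as a CLI
(`affectdim simulate|check|cluster|dimred|compare|reliability|run`); the
`run` subcommand executes the whole pipeline from one YAML/JSON config and
writes a manifest with SHA-256 checksums of every artifact.

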