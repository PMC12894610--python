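"""Pooled cross-validated R² model comparison.

The central statistic: predict a five-dimensional outcome (self-reported
label endorsements, or the classifier's probability vector) from a predictor
set — core affect (valence, arousal), discrete labels (the five endorsement
fractions), or both concatenated — with one regression per outcome column,
and pool fit quality across the five regressions:

    pooled R² = 1 - (sum_t SSR_t) / (sum_t SST_t)

computed on out-of-fold predictions from stratified k-fold cross-validation.
SST for the headline value is taken about each target's grand observed mean;
per-fold values use the test fold's own means. Families: ordinary least
squares ("linear") and epsilon-insensitive support vector regression
("kernel") with radial / linear / polynomial / sigmoid kernels, tuned by
random search over log-uniform ranges with an inner 5-fold split of each
training fold (no leakage into held-out folds).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression, Ridge
from sklearn.svm import SVR

from .errors import ValidationError
from .io import StimulusTable

logger = logging.getLogger(__name__)

PREDICTOR_SETS = ("core_affect", "discrete", "combined")
OUTCOMES = ("self_report_labels", "classifier_output")
KERNELS = ("radial", "linear", "polynomial", "sigmoid")
_SKLEARN_KERNEL = {
    "radial": "rbf",
    "linear": "linear",
    "polynomial": "poly",
    "sigmoid": "sigmoid",
}

# random-search ranges (log-uniform except degree)
_SEARCH_RANGES = {
    "C": (1e-2, 1e3),
    "gamma": (1e-3, 10.0),
    "epsilon": (1e-3, 1.0),
}
_DEGREES = (2, 3, 4)


@dataclass(frozen=True)
class RegressionSpec:
    predictor_set: str
    outcome: str
    family: str = "linear"  # "linear" | "kernel"
    kernel: str | None = None
    hyperparameters: dict = field(default_factory=dict)
    n_folds: int = 10
    tuning_draws: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.predictor_set not in PREDICTOR_SETS:
            raise ValidationError(f"unknown predictor set {self.predictor_set!r}")
        if self.outcome not in OUTCOMES:
            raise ValidationError(f"unknown outcome {self.outcome!r}")
        if self.family not in ("linear", "kernel"):
            raise ValidationError(f"unknown family {self.family!r}")
        if self.family == "kernel" and self.kernel not in KERNELS:
            raise ValidationError(f"kernel family requires kernel in {KERNELS}")
        if self.n_folds < 2:
            raise ValidationError("n_folds must be >= 2")
        if self.outcome == "self_report_labels" and self.predictor_set != "core_affect":
            raise ValidationError(
                "predictor and outcome column sets must be disjoint: "
                "self-report labels can only be predicted from core affect"
            )


@dataclass(frozen=True)
class PooledR2Result:
    pooled_r2: float
    per_fold_r2: np.ndarray | None  # test-fold-mean baseline, or None
    ssr_per_target: np.ndarray
    sst_per_target: np.ndarray


@dataclass(frozen=True)
class TuneResult:
    hyperparameters: dict
    score: float  # mean inner-CV pooled R² of the winning draw
    all_scores: np.ndarray


@dataclass(frozen=True)
class ModelComparison:
    per_fold_test: pd.DataFrame  # fold x model, pooled R² (fold-mean baseline)
    per_fold_train: pd.DataFrame
    summary: pd.DataFrame  # model x {train/test means, pooled test R²}
    pairwise: pd.DataFrame  # fold-paired mean differences + sign-flip p


# ---------------------------------------------------------------------------
# data plumbing


def predictor_matrix(table: StimulusTable, predictor_set: str) -> np.ndarray:
    """Extract the X matrix for a named predictor set (none_of_the_above excluded)."""
    if predictor_set == "core_affect":
        return table.affect
    if predictor_set == "discrete":
        return table.endorsements
    if predictor_set == "combined":
        return np.hstack([table.affect, table.endorsements])
    raise ValidationError(f"unknown predictor set {predictor_set!r}")


def outcome_matrix(table: StimulusTable, outcome: str) -> np.ndarray:
    if outcome == "self_report_labels":
        return table.endorsements
    if outcome == "classifier_output":
        return table.probabilities
    raise ValidationError(f"unknown outcome {outcome!r}")


def make_folds(n: int, n_folds: int, strata=None, seed: int = 0) -> np.ndarray:
    """Stratified fold assignment; fold sizes differ by at most one.

    Within each stratum (order of first appearance) items are shuffled and
    dealt to the currently least-filled fold, which balances folds globally
    and keeps strata spread 'floor/ceil' across folds. Strata smaller than
    n_folds trigger a warning and are simply dealt the same way
    (effectively unstratified for that stratum).
    """
    if n_folds > n:
        raise ValidationError(f"n_folds={n_folds} exceeds n={n}")
    if strata is None:
        strata = np.zeros(n, int)
    strata = np.asarray(strata)
    if strata.shape[0] != n:
        raise ValidationError("strata length must equal n")
    rng = np.random.default_rng(seed)
    folds = np.empty(n, int)
    fill = np.zeros(n_folds, int)
    seen = pd.unique(strata)
    for s in seen:
        idx = np.flatnonzero(strata == s)
        if idx.size < n_folds:
            warnings.warn(
                f"stratum {s!r} has {idx.size} < {n_folds} items; "
                "falling back to unstratified assignment for it",
                stacklevel=2,
            )
        idx = rng.permutation(idx)
        for i in idx:
            f = int(fill.argmin())
            folds[i] = f
            fill[f] += 1
    return folds


# ---------------------------------------------------------------------------
# fitting


def _make_model(spec: RegressionSpec, X_train: np.ndarray):
    if spec.family == "linear":
        rank = np.linalg.matrix_rank(X_train - X_train.mean(axis=0))
        if rank < X_train.shape[1]:
            logger.warning(
                "rank-deficient design (rank %d < %d columns); ridge fallback",
                rank,
                X_train.shape[1],
            )
            return Ridge(alpha=1e-6)
        return LinearRegression()
    hp = spec.hyperparameters
    return SVR(
        kernel=_SKLEARN_KERNEL[spec.kernel],
        C=hp.get("C", 1.0),
        gamma=hp.get("gamma", "scale"),
        epsilon=hp.get("epsilon", 0.1),
        degree=int(hp.get("degree", 3)),
    )


def fit_predict_per_target(
    spec: RegressionSpec,
    X,
    Y,
    folds,
    return_train: bool = False,
):
    """Out-of-fold predictions, one independent model per outcome column.

    Predictors are standardized with training-fold statistics. Predicted
    probability columns are NOT renormalized to the simplex. When
    ``return_train`` is set, also returns {fold: (train_row_indices,
    train_predictions)} for train-side diagnostics.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    folds = np.asarray(folds, int)
    if X.shape[0] != Y.shape[0] or X.shape[0] != folds.shape[0]:
        raise ValidationError("X, Y and folds must cover the same items")
    yhat = np.empty_like(Y)
    train_preds: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for f in np.unique(folds):
        te = folds == f
        tr = ~te
        mu = X[tr].mean(axis=0)
        sd = X[tr].std(axis=0)
        sd[sd == 0] = 1.0
        Xtr = (X[tr] - mu) / sd
        Xte = (X[te] - mu) / sd
        preds_tr = np.empty_like(Y[tr])
        for t in range(Y.shape[1]):
            model = _make_model(spec, Xtr)
            model.fit(Xtr, Y[tr, t])
            yhat[te, t] = model.predict(Xte)
            if return_train:
                preds_tr[:, t] = model.predict(Xtr)
        if return_train:
            train_preds[int(f)] = (np.flatnonzero(tr), preds_tr)
    if return_train:
        return yhat, train_preds
    return yhat


def pooled_r2(Y, Y_hat, folds=None) -> PooledR2Result:
    """Pooled R² across targets; optional per-fold values with fold-mean SST."""
    Y = np.asarray(Y, float)
    Yh = np.asarray(Y_hat, float)
    if Y.ndim == 1:
        Y, Yh = Y[:, None], Yh[:, None]
    if Y.shape != Yh.shape:
        raise ValidationError("observed and predicted shapes differ")
    sst = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    zero = np.flatnonzero(sst == 0)
    if zero.size:
        raise ValidationError(f"zero total sum of squares for target(s) {zero.tolist()}")
    ssr = ((Y - Yh) ** 2).sum(axis=0)
    pooled = 1.0 - ssr.sum() / sst.sum()
    per_fold = None
    if folds is not None:
        folds = np.asarray(folds, int)
        vals = []
        for f in np.unique(folds):
            m = folds == f
            sst_f = ((Y[m] - Y[m].mean(axis=0)) ** 2).sum()
            ssr_f = ((Y[m] - Yh[m]) ** 2).sum()
            vals.append(1.0 - ssr_f / sst_f if sst_f > 0 else np.nan)
        per_fold = np.array(vals)
    return PooledR2Result(
        pooled_r2=float(pooled),
        per_fold_r2=per_fold,
        ssr_per_target=ssr,
        sst_per_target=sst,
    )


# ---------------------------------------------------------------------------
# tuning


def _sample_draw(rng: np.random.Generator, kernel: str) -> dict:
    draw = {
        name: float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        for name, (lo, hi) in _SEARCH_RANGES.items()
    }
    if kernel == "polynomial":
        draw["degree"] = int(rng.choice(_DEGREES))
    return draw


def random_search_tune(
    spec: RegressionSpec, X, Y, folds, n_draws: int, seed: int = 0
) -> TuneResult:
    """Random-search SVR hyperparameters with nested inner 5-fold evaluation.

    Each draw is scored by the mean, over outer training folds, of the pooled
    R² of inner 5-fold out-of-fold predictions computed on that training fold
    only — held-out outer folds never inform the selection.
    """
    if spec.family != "kernel":
        raise ValidationError("tuning applies to the kernel family only")
    if n_draws < 1:
        raise ValidationError("n_draws must be >= 1")
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    folds = np.asarray(folds, int)
    rng = np.random.default_rng(seed)
    draws = [_sample_draw(rng, spec.kernel) for _ in range(n_draws)]
    inner_seed = int(rng.integers(2**31 - 1))
    scores = np.empty(n_draws)
    outer = np.unique(folds)
    inner_folds_by_outer = {}
    for f in outer:
        tr = np.flatnonzero(folds != f)
        inner_folds_by_outer[int(f)] = (
            tr,
            make_folds(tr.size, 5, seed=inner_seed + int(f)),
        )
    for d, hp in enumerate(draws):
        cand = replace(spec, hyperparameters=hp)
        vals = []
        for f in outer:
            tr, inner = inner_folds_by_outer[int(f)]
            yhat = fit_predict_per_target(cand, X[tr], Y[tr], inner)
            vals.append(pooled_r2(Y[tr], yhat).pooled_r2)
        scores[d] = float(np.mean(vals))
    best = int(scores.argmax())
    return TuneResult(hyperparameters=draws[best], score=float(scores[best]), all_scores=scores)


# ---------------------------------------------------------------------------
# comparison


def _sign_flip_p(diffs: np.ndarray, max_exact: int = 12, seed: int = 0) -> float:
    """One-sided fold-paired sign-flip p for mean(diffs) > 0 under exchange."""
    n = diffs.size
    obs = diffs.mean()
    if n <= max_exact:
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
        means = (signs * diffs).mean(axis=1)
        return float(np.count_nonzero(means >= obs - 1e-12) / signs.shape[0])
    rng = np.random.default_rng(seed)
    signs = rng.choice((1.0, -1.0), size=(10_000, n))
    means = (signs * diffs).mean(axis=1)
    return float((1 + np.count_nonzero(means >= obs - 1e-12)) / (10_001))


def compare_models(named_specs, Y, folds) -> ModelComparison:
    """Fold-paired comparison of models sharing folds and outcome.

    ``named_specs`` is a sequence of (name, RegressionSpec, X) triples. All
    models are fit on identical folds; the summary reports train/test mean
    per-fold pooled R² plus the headline pooled test R² (grand-mean SST), and
    the pairwise table gives fold-paired mean differences with a one-sided
    sign-flip p-value.
    """
    folds = np.asarray(folds, int)
    Y = np.asarray(Y, float)
    per_fold_test = {}
    per_fold_train = {}
    summary_rows = []
    fold_ids = np.unique(folds)
    for name, spec, X in named_specs:
        yhat, train_preds = fit_predict_per_target(spec, X, Y, folds, return_train=True)
        res = pooled_r2(Y, yhat, folds=folds)
        per_fold_test[name] = res.per_fold_r2
        train_vals = []
        for f in fold_ids:
            rows, preds = train_preds[int(f)]
            train_vals.append(pooled_r2(Y[rows], preds).pooled_r2)
        per_fold_train[name] = np.array(train_vals)
        summary_rows.append(
            {
                "model": name,
                "mean_train_r2": float(np.mean(train_vals)),
                "mean_test_r2": float(np.nanmean(res.per_fold_r2)),
                "pooled_test_r2": res.pooled_r2,
            }
        )
    test_df = pd.DataFrame(per_fold_test, index=pd.Index(fold_ids, name="fold"))
    train_df = pd.DataFrame(per_fold_train, index=pd.Index(fold_ids, name="fold"))
    summary = pd.DataFrame(summary_rows).set_index("model")
    pairs = []
    names = list(test_df.columns)
    for a, b in itertools.combinations(names, 2):
        d = (test_df[a] - test_df[b]).to_numpy()
        d = d[~np.isnan(d)]
        pairs.append(
            {
                "model_a": a,
                "model_b": b,
                "mean_test_diff": float(d.mean()),
                "p_sign_flip_a_gt_b": _sign_flip_p(d),
            }
        )
    pairwise = pd.DataFrame(pairs)
    return ModelComparison(
        per_fold_test=test_df,
        per_fold_train=train_df,
        summary=summary,
        pairwise=pairwise,
    )
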