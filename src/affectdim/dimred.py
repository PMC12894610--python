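"""PCA reduction of classifier outputs to a core-affect-dimensional space.

If the five-class probability vectors were a function of two latent
core-affect dimensions, clustering the leading two principal-component scores
should fit the emotion categories about as well as clustering the full
five-dimensional features. The pipeline therefore fits a column-centered PCA,
projects to two components, and hands the scores back to the clustering
stage.

t-SNE is available for visualization only; it takes no part in any
quantitative comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .errors import ValidationError


@dataclass(frozen=True)
class PCAResult:
    loadings: np.ndarray  # (n_features, n_components)
    explained_variance_ratio: np.ndarray  # (n_components,)
    scores: np.ndarray  # (n_items, n_components)
    mean: np.ndarray  # (n_features,) column means removed before rotation


def pca_fit(features) -> PCAResult:
    """Column-centered PCA of the sample covariance.

    Components are ordered by explained variance; the sign of each component
    is fixed so its largest-magnitude loading is positive.
    """
    X = np.asarray(features, float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError("need at least 2 items")
    if np.allclose(X.std(axis=0), 0.0):
        raise ValidationError("all columns are constant")
    pca = PCA(svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T  # (features, components)
    for j in range(loadings.shape[1]):
        i = int(np.abs(loadings[:, j]).argmax())
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0
    return PCAResult(
        loadings=loadings,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        scores=scores,
        mean=pca.mean_.copy(),
    )


def pca_project(result: PCAResult, n_components: int) -> np.ndarray:
    """Scores restricted to the leading ``n_components`` components."""
    avail = result.scores.shape[1]
    if not 1 <= n_components <= avail:
        raise ValidationError(f"n_components={n_components} outside [1, {avail}]")
    return result.scores[:, :n_components]


def tsne_embed(features, seed: int, perplexity: float = 10.0) -> np.ndarray:
    """2-D t-SNE embedding for plotting (excluded from all quantitative checks)."""
    X = np.asarray(features, float)
    n = X.shape[0]
    if n < 5:
        raise ValidationError("t-SNE needs at least 5 items")
    perplexity = min(perplexity, max(2.0, (n - 1) / 3.0))
    emb = TSNE(
        n_components=2,
        perplexity=perplexity,
        init="pca",
        random_state=seed,
    ).fit_transform(X)
    if not np.all(np.isfinite(emb)):
        raise ValidationError("t-SNE produced non-finite coordinates")
    return emb
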