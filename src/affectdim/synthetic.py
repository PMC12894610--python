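"""Synthetic stimulus-level data under two competing generative regimes.

The study question is whether five-class classifier probability vectors carry
discrete-emotion information beyond the two core-affect dimensions (valence,
arousal). The generator therefore emulates the stimulus-level data under both
hypotheses:

``discrete``
    Classifier probabilities are drawn from five category-specific Dirichlet
    distributions whose mean centroids place most mass on the own class. The
    five centroids span four simplex dimensions, so no 2-D representation can
    capture the category structure.

``core_affect``
    A latent (valence, arousal) point is sampled per stimulus around its
    category's affect mean, and the probability vector is a softmax of an
    affine map of that 2-D point plus Gaussian logit noise — i.e. the
    classifier output is, by construction, a noisy function of exactly two
    dimensions. The affine map ``logit_c = gamma * (2 x . mu_c - |mu_c|^2)``
    is the affine form of a Gaussian-affinity rule around the category affect
    means, so softmax probabilities concentrate on affect-nearby categories.

Defaults mirror the emulated study: 5 balanced categories of 26 videos
(130 total) and 110 rating subjects. Category valence means follow the
reported stimulus validation (neutral 5.21, amusement 6.57, fear 3.73,
disgust 2.82, sexual desire 5.51); no arousal summaries are reported, so
arousal means are free parameters documented in the methods note.

A root seed is fanned out into independent per-stage substreams
(affect, probabilities, endorsements, subject ratings) so that adding a stage
never perturbs earlier draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import (
    CATEGORIES,
    ENDORSEMENT_COLUMNS,
    NONE_COLUMN,
    PROB_COLUMNS,
    StimulusTable,
    SubjectRatings,
)

#: (valence, arousal) per category; valence anchored to reported means.
DEFAULT_AFFECT_MEANS: dict[str, tuple[float, float]] = {
    "disgust": (2.82, 5.5),
    "fear": (3.73, 6.5),
    "amusement": (6.57, 5.8),
    "sexual_desire": (5.51, 6.2),
    "neutral": (5.21, 2.5),
}

# Endorsement profile constants (discrete regime): own-label endorsement
# scales with fidelity, off-labels sit at a low base, plus clipped Gaussian
# jitter. At fidelity 0.9 the own-label mean is ~0.64, in the range of the
# observed self-report diagonal.
_END_OFF = 0.08
_END_OWN_GAIN = 0.62
_END_NOISE_SD = 0.08
# Endorsement link constants (core-affect regime): clipped affine function of
# the centered category logits, so endorsements add no information beyond the
# two latent affect dimensions. The slope is small relative to the logit
# spread so the link essentially never saturates — saturation would act as a
# nonlinear feature of (v, a) and break the regime's 2-D claim.
_END_LINK_INTERCEPT = 0.5
_END_LINK_SLOPE = 0.04
_NONE_LEVEL = 0.05


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic dataset; see module docstring for units."""

    regime: str = "discrete"  # "discrete" | "core_affect"
    n_per_category: int = 26
    n_subjects: int = 110
    affect_means: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_AFFECT_MEANS)
    )
    sigma_e: float = 0.8  # Likert-scale sd: stimulus-level affect spread and rater noise
    kappa: float = 30.0  # Dirichlet concentration (discrete regime)
    own_mass: float = 0.6  # centroid mass on the own class (discrete regime)
    logit_noise_sd: float = 0.5  # Gaussian logit noise (core-affect regime)
    logit_gain: float = 0.5  # gamma of the affine affect->logit map
    endorsement_fidelity: float = 0.9
    noise_free: bool = False  # degenerate limit: no probability/endorsement noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in ("discrete", "core_affect"):
            raise ValidationError(f"unknown regime {self.regime!r}")
        if self.n_per_category < 1 or self.n_subjects < 1:
            raise ValidationError("counts must be positive")
        if self.kappa <= 0:
            raise ValidationError("kappa must be > 0")
        if self.sigma_e < 0:
            raise ValidationError("sigma_e must be >= 0")
        if not 0 < self.endorsement_fidelity <= 1:
            raise ValidationError("endorsement_fidelity must be in (0, 1]")
        if not 0.2 < self.own_mass < 1:
            raise ValidationError("own_mass must be in (0.2, 1)")
        missing = set(CATEGORIES) - set(self.affect_means)
        if missing:
            raise ValidationError(f"affect_means missing categories: {sorted(missing)}")
        for c, (v, a) in self.affect_means.items():
            if not (1 <= v <= 9 and 1 <= a <= 9):
                raise ValidationError(f"affect mean for {c!r} outside [1, 9]")


@dataclass(frozen=True)
class GroundTruthParams:
    """Realized generative parameters of a dataset, kept for recovery tests."""

    regime: str
    affect_means: np.ndarray  # (5, 2) in canonical category order
    centroids: np.ndarray | None  # (5, 5) Dirichlet mean centroids (discrete)
    logit_weights: np.ndarray | None  # (5, 2) affine map weights (core_affect)
    logit_bias: np.ndarray | None  # (5,) affine map bias (core_affect)
    seed: int


def _streams(config: SyntheticConfig) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(config.seed).spawn(4)
    names = ("affect", "probabilities", "endorsements", "subjects")
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def _affect_matrix(config: SyntheticConfig) -> np.ndarray:
    return np.array([config.affect_means[c] for c in CATEGORIES], float)


def _sample_affect(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    mu = _affect_matrix(config)
    n = config.n_per_category
    per_cat = [mu[i] + rng.normal(0.0, config.sigma_e, size=(n, 2)) for i in range(5)]
    return np.clip(np.vstack(per_cat), 1.0, 9.0)


def _assemble(
    config: SyntheticConfig,
    affect: np.ndarray,
    endorsements: np.ndarray,
    none_col: np.ndarray,
    probs: np.ndarray,
) -> StimulusTable:
    n = config.n_per_category
    df = pd.DataFrame(
        {
            "video_id": [f"v{i:03d}" for i in range(5 * n)],
            "category": np.repeat(list(CATEGORIES), n),
            "valence": affect[:, 0],
            "arousal": affect[:, 1],
        }
    )
    for j, col in enumerate(ENDORSEMENT_COLUMNS):
        df[col] = endorsements[:, j]
    df[NONE_COLUMN] = none_col
    for j, col in enumerate(PROB_COLUMNS):
        df[col] = probs[:, j]
    return StimulusTable.from_frame(df)


def discrete_centroids(own_mass: float = 0.6) -> np.ndarray:
    """(5, 5) matrix: row c is the mean probability vector of category c."""
    off = (1.0 - own_mass) / 4.0
    return np.full((5, 5), off) + np.eye(5) * (own_mass - off)


def generate_discrete_regime(
    config: SyntheticConfig,
) -> tuple[StimulusTable, GroundTruthParams]:
    """Classifier probabilities from category-specific Dirichlet centroids."""
    if config.regime != "discrete":
        raise ValidationError("config.regime must be 'discrete'")
    rngs = _streams(config)
    n = config.n_per_category
    affect = _sample_affect(config, rngs["affect"])

    centroids = discrete_centroids(config.own_mass)
    if config.noise_free:
        probs = np.repeat(centroids, n, axis=0)
    else:
        rows = []
        for i in range(5):
            alpha = config.kappa * centroids[i]
            rows.append(rngs["probabilities"].dirichlet(alpha, size=n))
        probs = np.vstack(rows)

    own = _END_OFF + _END_OWN_GAIN * config.endorsement_fidelity
    profile = np.full((5, 5), _END_OFF) + np.eye(5) * (own - _END_OFF)
    endorsements = np.repeat(profile, n, axis=0)
    none_col = np.full(5 * n, _NONE_LEVEL)
    if not config.noise_free:
        endorsements = endorsements + rngs["endorsements"].normal(
            0.0, _END_NOISE_SD, size=endorsements.shape
        )
        none_col = none_col + rngs["endorsements"].normal(0.0, _END_NOISE_SD, size=5 * n)
    endorsements = np.clip(endorsements, 0.0, 1.0)
    none_col = np.clip(none_col, 0.0, 1.0)

    table = _assemble(config, affect, endorsements, none_col, probs)
    truth = GroundTruthParams(
        regime="discrete",
        affect_means=_affect_matrix(config),
        centroids=centroids,
        logit_weights=None,
        logit_bias=None,
        seed=config.seed,
    )
    return table, truth


def core_affect_logits(
    affect: np.ndarray, affect_means: np.ndarray, gain: float
) -> np.ndarray:
    """Affine map (v, a) -> five category logits: gamma*(2 x.mu_c - |mu_c|^2)."""
    return gain * (2.0 * affect @ affect_means.T - (affect_means**2).sum(axis=1))


def generate_core_affect_regime(
    config: SyntheticConfig,
) -> tuple[StimulusTable, GroundTruthParams]:
    """Classifier probabilities as a noisy function of latent (v, a) only."""
    if config.regime != "core_affect":
        raise ValidationError("config.regime must be 'core_affect'")
    rngs = _streams(config)
    affect = _sample_affect(config, rngs["affect"])
    mu = _affect_matrix(config)

    clean_logits = core_affect_logits(affect, mu, config.logit_gain)
    logits = clean_logits
    if not config.noise_free:
        logits = logits + rngs["probabilities"].normal(
            0.0, config.logit_noise_sd, size=logits.shape
        )
    shifted = logits - logits.max(axis=1, keepdims=True)
    expl = np.exp(shifted)
    probs = expl / expl.sum(axis=1, keepdims=True)

    # Endorsements: clipped affine link of the centered *clean* logits — a
    # fixed monotone function of (v, a) carrying no extra information.
    centered = clean_logits - clean_logits.mean(axis=1, keepdims=True)
    endorsements = np.clip(
        _END_LINK_INTERCEPT
        + _END_LINK_SLOPE * config.endorsement_fidelity * centered,
        0.0,
        1.0,
    )
    none_col = np.full(len(affect), _NONE_LEVEL)

    table = _assemble(config, affect, endorsements, none_col, probs)
    truth = GroundTruthParams(
        regime="core_affect",
        affect_means=mu,
        centroids=None,
        logit_weights=2.0 * config.logit_gain * mu,
        logit_bias=-config.logit_gain * (mu**2).sum(axis=1),
        seed=config.seed,
    )
    return table, truth


def generate(config: SyntheticConfig) -> tuple[StimulusTable, GroundTruthParams]:
    """Dispatch on ``config.regime``."""
    if config.regime == "discrete":
        return generate_discrete_regime(config)
    return generate_core_affect_regime(config)


def generate_subject_ratings(
    config: SyntheticConfig, table: StimulusTable
) -> SubjectRatings:
    """Per-subject ratings: stimulus mean + N(0, sigma_e), clipped to [1, 9]."""
    rng = _streams(config)["subjects"]
    n = len(table)
    frames = []
    affect = table.affect
    for s in range(config.n_subjects):
        noisy = np.clip(affect + rng.normal(0.0, config.sigma_e, size=(n, 2)), 1.0, 9.0)
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": f"s{s:03d}",
                    "video_id": table.video_ids,
                    "valence": noisy[:, 0],
                    "arousal": noisy[:, 1],
                }
            )
        )
    return SubjectRatings.from_frame(pd.concat(frames, ignore_index=True))
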