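"""Split-half reliability of aggregated valence and arousal ratings.

Per run, the rater sample is randomly divided into two disjoint equal halves
(an odd subject is dropped at random), per-video mean ratings are computed
within each half, and the two mean vectors are correlated across videos. The
reported reliability per affect dimension is the arithmetic mean of the
per-run correlations.

Under a simple variance-components model — true stimulus means with variance
tau^2, independent rater noise with variance sigma_e^2, a full sample of m
raters split into halves of m/2 — each half mean carries noise variance
sigma_e^2/(m/2), so the expected split-half correlation is
tau^2 / (tau^2 + 2 sigma_e^2 / m), which the tests use as a closed-form
oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io import SubjectRatings

logger = logging.getLogger(__name__)

DIMENSIONS = ("valence", "arousal")


@dataclass(frozen=True)
class ReliabilityResult:
    mean_correlation: pd.Series  # per dimension
    per_run: pd.DataFrame  # run x dimension
    n_runs: int


def split_half_bootstrap(
    ratings: SubjectRatings,
    n_runs: int = 10,
    seed: int = 0,
    method: str = "pearson",
) -> ReliabilityResult:
    """Mean split-half correlation of per-video mean ratings, per dimension."""
    if method not in ("pearson", "spearman"):
        raise ValidationError(f"unknown correlation method {method!r}")
    wide = {d: ratings.wide(d) for d in DIMENSIONS}
    n_subjects = wide["valence"].shape[1]
    n_videos = wide["valence"].shape[0]
    if n_subjects < 4:
        raise ValidationError(f"need >= 4 subjects, got {n_subjects}")
    if n_videos < 3:
        raise ValidationError(f"need >= 3 stimuli, got {n_videos}")
    mats = {d: wide[d].to_numpy(float) for d in DIMENSIONS}
    rng = np.random.default_rng(seed)
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    rows = []
    for run in range(n_runs):
        perm = rng.permutation(n_subjects)
        if n_subjects % 2:
            logger.debug("run %d: odd rater count, dropping one at random", run)
            perm = perm[:-1]
        half = perm.size // 2
        h1, h2 = perm[:half], perm[half:]
        rec = {"run": run}
        for d in DIMENSIONS:
            m = mats[d]
            with np.errstate(invalid="ignore"):
                m1 = np.nanmean(m[:, h1], axis=1)
                m2 = np.nanmean(m[:, h2], axis=1)
            ok = np.isfinite(m1) & np.isfinite(m2)
            if ok.sum() < 3:
                raise ValidationError("fewer than 3 stimuli rated in both halves")
            rec[d] = float(corr(m1[ok], m2[ok])[0])
        rows.append(rec)
    per_run = pd.DataFrame(rows).set_index("run")
    return ReliabilityResult(
        mean_correlation=per_run.mean().rename("mean_correlation"),
        per_run=per_run,
        n_runs=n_runs,
    )


def expected_split_half_correlation(tau: float, sigma_e: float, m: int) -> float:
    """Closed-form expectation tau^2 / (tau^2 + 2 sigma_e^2 / m).

    ``m`` is the size of the full rater sample; each half holds m/2 raters.
    """
    return tau**2 / (tau**2 + 2.0 * sigma_e**2 / m)
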