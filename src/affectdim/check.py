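"""Manipulation-check summaries: endorsement matrices, accuracy rates, argmax confusion.

The accuracy rate of a category is the probability of a video being labeled
(by self-report, a human judge, or the classifier's argmax) according to its
validated category; the overall rate reported here is the unweighted macro
mean of the five per-category rates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import CATEGORIES, StimulusTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AccuracySummary:
    per_category: pd.Series  # indexed by category, rates in [0, 1]
    macro: float  # unweighted mean of per-category rates


@dataclass(frozen=True)
class ArgmaxConfusion:
    matrix: pd.DataFrame  # row-normalized, truth x predicted
    tie_count: int  # rows whose maximum probability was not unique


def _require_all_categories(categories: np.ndarray) -> None:
    present = set(categories)
    for c in CATEGORIES:
        if c not in present:
            raise ValidationError(f"no stimuli for category {c!r}")


def endorsement_matrix(table: StimulusTable) -> pd.DataFrame:
    """Category x label matrix of mean endorsement fractions.

    Entry (c, l) is the mean endorsement of label l over stimuli of category
    c. Rows need not sum to 1 (endorsements are multi-select).
    """
    _require_all_categories(table.categories)
    df = pd.DataFrame(table.endorsements, columns=list(CATEGORIES))
    df["category"] = table.categories
    out = df.groupby("category", sort=False).mean().loc[list(CATEGORIES)]
    out.index.name = "category"
    return out


def accuracy_summary(rates_or_matrix) -> AccuracySummary:
    """Per-category accuracy (diagonal) and its unweighted macro mean.

    Accepts either a square category x label DataFrame with aligned axes or a
    1-D sequence of per-category rates (aligned to canonical order).
    """
    if isinstance(rates_or_matrix, pd.DataFrame):
        m = rates_or_matrix
        if list(m.index) != list(m.columns):
            raise ValidationError(
                "category x label matrix must have identically ordered axes"
            )
        per = pd.Series(np.diag(m.to_numpy(float)), index=m.index, name="accuracy")
    else:
        arr = np.asarray(rates_or_matrix, float).ravel()
        idx = list(CATEGORIES) if arr.size == len(CATEGORIES) else list(range(arr.size))
        per = pd.Series(arr, index=idx, name="accuracy")
    return AccuracySummary(per_category=per, macro=float(per.mean()))


def classifier_argmax_confusion(table: StimulusTable) -> ArgmaxConfusion:
    """Row-normalized confusion of argmax classifier predictions vs. truth.

    Ties in the probability vector resolve to the first category in canonical
    order; the number of tied rows is logged and returned.
    """
    _require_all_categories(table.categories)
    probs = table.probabilities
    pred = probs.argmax(axis=1)
    is_max = probs == probs.max(axis=1, keepdims=True)
    tie_count = int((is_max.sum(axis=1) > 1).sum())
    if tie_count:
        logger.warning(
            "argmax ties in %d/%d rows; resolved to first canonical category",
            tie_count,
            len(probs),
        )
    truth = table.category_codes
    counts = np.zeros((5, 5))
    np.add.at(counts, (truth, pred), 1.0)
    norm = counts / counts.sum(axis=1, keepdims=True)
    matrix = pd.DataFrame(norm, index=list(CATEGORIES), columns=list(CATEGORIES))
    matrix.index.name = "category"
    return ArgmaxConfusion(matrix=matrix, tie_count=tie_count)
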