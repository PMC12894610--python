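"""Validated containers and CSV readers/writers for stimulus-level data.

The central object is the :class:`StimulusTable`: one row per emotion-eliciting
video, holding the validated emotion category, mean valence/arousal ratings on
the 1-9 Likert scale (5 = neutral anchor), per-label endorsement fractions
(multi-select, so rows need not sum to 1) and the five-class classifier
probability vector (compositional: each row sums to 1).

Subject-level valence/arousal ratings live in :class:`SubjectRatings`
(long format, missing entries permitted) and feed the reliability analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError, ValidationError

#: Canonical category order, used everywhere a category axis appears.
CATEGORIES: tuple[str, ...] = (
    "disgust",
    "fear",
    "amusement",
    "sexual_desire",
    "neutral",
)

PROB_COLUMNS: tuple[str, ...] = tuple(f"prob_{c}" for c in CATEGORIES)
ENDORSEMENT_COLUMNS: tuple[str, ...] = tuple(f"endorse_{c}" for c in CATEGORIES)
#: Optional multi-select escape option; stored but excluded from predictor sets.
NONE_COLUMN = "endorse_none_of_the_above"

RATING_MIN, RATING_MAX = 1.0, 9.0
PROB_SUM_TOL = 1e-6

_REQUIRED_COLUMNS = (
    ("video_id", "category", "valence", "arousal")
    + ENDORSEMENT_COLUMNS
    + PROB_COLUMNS
)


@dataclass(frozen=True)
class StimulusTable:
    """One row per video; validated on construction via :meth:`from_frame`."""

    data: pd.DataFrame

    @classmethod
    def from_frame(cls, df: pd.DataFrame, *, prob_tol: float = PROB_SUM_TOL) -> "StimulusTable":
        missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        cols = list(_REQUIRED_COLUMNS)
        if NONE_COLUMN in df.columns:
            cols.append(NONE_COLUMN)
        out = df.loc[:, cols].reset_index(drop=True).copy()
        out["video_id"] = out["video_id"].astype(str)
        out["category"] = out["category"].astype(str)
        _validate_stimulus_frame(out, prob_tol=prob_tol)
        return cls(out)

    # -- accessors ---------------------------------------------------------
    @property
    def video_ids(self) -> np.ndarray:
        return self.data["video_id"].to_numpy()

    @property
    def categories(self) -> np.ndarray:
        return self.data["category"].to_numpy()

    @property
    def affect(self) -> np.ndarray:
        """(n, 2) array of [valence, arousal]."""
        return self.data[["valence", "arousal"]].to_numpy(float)

    @property
    def endorsements(self) -> np.ndarray:
        """(n, 5) label-endorsement fractions in canonical category order."""
        return self.data[list(ENDORSEMENT_COLUMNS)].to_numpy(float)

    @property
    def probabilities(self) -> np.ndarray:
        """(n, 5) classifier probability vectors in canonical category order."""
        return self.data[list(PROB_COLUMNS)].to_numpy(float)

    @property
    def category_codes(self) -> np.ndarray:
        """Integer truth labels in canonical category order."""
        lut = {c: i for i, c in enumerate(CATEGORIES)}
        return np.array([lut[c] for c in self.categories], dtype=int)

    def __len__(self) -> int:
        return len(self.data)


def _validate_stimulus_frame(df: pd.DataFrame, *, prob_tol: float) -> None:
    ids = df["video_id"]
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise ValidationError(f"duplicate video_id: {dup!r}")
    bad_cat = set(df["category"]) - set(CATEGORIES)
    if bad_cat:
        raise ValidationError(
            f"unknown category value(s): {sorted(bad_cat)}; expected one of {CATEGORIES}"
        )
    for col in ("valence", "arousal"):
        vals = df[col].to_numpy(float)
        out = (vals < RATING_MIN) | (vals > RATING_MAX) | ~np.isfinite(vals)
        if out.any():
            vid = df["video_id"].iloc[int(np.flatnonzero(out)[0])]
            raise ValidationError(
                f"{col} outside [{RATING_MIN:g}, {RATING_MAX:g}] for video_id {vid!r}"
            )
    end_cols = list(ENDORSEMENT_COLUMNS) + ([NONE_COLUMN] if NONE_COLUMN in df else [])
    emat = df[end_cols].to_numpy(float)
    if ((emat < 0) | (emat > 1) | ~np.isfinite(emat)).any():
        row = int(np.flatnonzero(((emat < 0) | (emat > 1) | ~np.isfinite(emat)).any(axis=1))[0])
        raise ValidationError(
            f"endorsement outside [0, 1] for video_id {df['video_id'].iloc[row]!r}"
        )
    pmat = df[list(PROB_COLUMNS)].to_numpy(float)
    if ((pmat < 0) | ~np.isfinite(pmat)).any():
        row = int(np.flatnonzero(((pmat < 0) | ~np.isfinite(pmat)).any(axis=1))[0])
        raise ValidationError(
            f"negative or non-finite classifier probability for video_id "
            f"{df['video_id'].iloc[row]!r}"
        )
    if len(pmat):
        sums = pmat.sum(axis=1)
        off = np.abs(sums - 1.0) > prob_tol
        if off.any():
            row = int(np.flatnonzero(off)[0])
            raise ValidationError(
                f"classifier probabilities sum to {sums[row]:.6f} (not 1 within "
                f"{prob_tol:g}) for video_id {df['video_id'].iloc[row]!r}"
            )


def read_stimulus_table(path: str | Path) -> StimulusTable:
    """Read and validate a stimulus-level CSV (header required)."""
    df = pd.read_csv(path)
    return StimulusTable.from_frame(df)


def write_stimulus_table(table: StimulusTable, path: str | Path) -> None:
    """Write a CSV re-readable by :func:`read_stimulus_table` at full precision."""
    table.data.to_csv(path, index=False)


@dataclass(frozen=True)
class SubjectRatings:
    """Long-format subject x stimulus valence/arousal ratings; NaN = missing."""

    data: pd.DataFrame  # columns: subject_id, video_id, valence, arousal

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SubjectRatings":
        required = ("subject_id", "video_id", "valence", "arousal")
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        out = df.loc[:, list(required)].reset_index(drop=True).copy()
        out["subject_id"] = out["subject_id"].astype(str)
        out["video_id"] = out["video_id"].astype(str)
        dup = out.duplicated(subset=["subject_id", "video_id"])
        if dup.any():
            r = out.loc[dup].iloc[0]
            raise ValidationError(
                f"duplicate rating for (subject {r['subject_id']!r}, video {r['video_id']!r})"
            )
        for col in ("valence", "arousal"):
            vals = out[col].to_numpy(float)
            bad = (~np.isnan(vals)) & ((vals < RATING_MIN) | (vals > RATING_MAX))
            if bad.any():
                r = out.iloc[int(np.flatnonzero(bad)[0])]
                raise ValidationError(
                    f"{col} outside [{RATING_MIN:g}, {RATING_MAX:g}] for "
                    f"(subject {r['subject_id']!r}, video {r['video_id']!r})"
                )
        return cls(out)

    @property
    def subjects(self) -> np.ndarray:
        return self.data["subject_id"].unique()

    @property
    def videos(self) -> np.ndarray:
        return self.data["video_id"].unique()

    def wide(self, dimension: str) -> pd.DataFrame:
        """Pivot one dimension to a video x subject matrix (NaN = missing)."""
        if dimension not in ("valence", "arousal"):
            raise ValueError(f"unknown dimension {dimension!r}")
        return self.data.pivot(index="video_id", columns="subject_id", values=dimension)


def read_subject_ratings(path: str | Path) -> SubjectRatings:
    """Read a long-format (subject_id, video_id, valence, arousal) CSV."""
    return SubjectRatings.from_frame(pd.read_csv(path))


def write_subject_ratings(ratings: SubjectRatings, path: str | Path) -> None:
    ratings.data.to_csv(path, index=False)


def aggregate_ratings(ratings: SubjectRatings) -> pd.DataFrame:
    """Per-stimulus arithmetic mean valence/arousal over non-missing subjects.

    Returns a DataFrame indexed by video_id with columns valence, arousal,
    in order of first appearance. Raises if any stimulus has zero non-missing
    ratings on either dimension.
    """
    df = ratings.data
    order = df["video_id"].drop_duplicates().tolist()
    means = df.groupby("video_id", sort=False)[["valence", "arousal"]].mean()
    counts = df.groupby("video_id", sort=False)[["valence", "arousal"]].count()
    empty = counts[(counts == 0).any(axis=1)].index.tolist()
    if empty:
        raise ValidationError(f"stimuli with no usable ratings: {empty}")
    return means.loc[order]


@dataclass(frozen=True)
class JudgeConfusion:
    """True-category x chosen-category matrix from the human-judging study."""

    matrix: pd.DataFrame  # index/columns = CATEGORIES, proportions or counts

    @classmethod
    def from_frame(cls, df: pd.DataFrame, *, proportions: bool = True) -> "JudgeConfusion":
        if list(df.index) != list(CATEGORIES) or list(df.columns) != list(CATEGORIES):
            raise SchemaError(
                "judge confusion must be indexed by the five canonical categories "
                "on both axes"
            )
        vals = df.to_numpy(float)
        if (vals < 0).any():
            raise ValidationError("judge confusion entries must be nonnegative")
        if proportions and (vals > 1).any():
            raise ValidationError("judge confusion proportions must lie in [0, 1]")
        return cls(df.astype(float))


@dataclass
class AnalysisConfig:
    """Knobs for a full pipeline run. Paths may be None when simulating."""

    stimulus_path: str | None = None
    ratings_path: str | None = None
    regime: str | None = None  # simulate this regime when stimulus_path is None
    n_clusters: int = 5
    k_range: tuple[int, int] = (2, 10)
    n_permutations: int = 999
    n_folds: int = 10
    families: tuple[str, ...] = ("linear",)
    kernels: tuple[str, ...] = ("radial",)
    n_search_draws: int = 10
    reliability_runs: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 99:
            raise ValidationError("permutation count must be >= 99")
        if self.n_folds < 2:
            raise ValidationError("fold count must be >= 2")
        lo, hi = self.k_range
        if lo < 2 or hi < lo:
            raise ValidationError("k_range must satisfy 2 <= lo <= hi")
        if self.stimulus_path is None and self.regime is None:
            raise ValidationError("either stimulus_path or a simulation regime is required")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        text = Path(path).read_text()
        raw = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        if "k_range" in raw:
            raw["k_range"] = tuple(raw["k_range"])
        for key in ("families", "kernels"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)
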