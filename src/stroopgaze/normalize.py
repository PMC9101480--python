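"""Subject-wise centering and [0,1] feature scaling.

Gaze variables carry strong between-subject baselines.  Centering subtracts,
per subject and per feature, the mean over that subject's conditions — a
within-subject transform that uses no labels of other subjects and can
therefore be applied before any train/test split.  Min-max scaling to [0,1]
is fitted on training rows only and applied to held-out rows (which may then
fall outside [0,1]; optional clipping).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES
from .records import ValidationError

log = logging.getLogger(__name__)


def subject_center(table: pd.DataFrame, features: list[str] | None = None) -> pd.DataFrame:
    """Subtract each subject's across-condition mean from their feature rows.

    After centering, every subject's per-feature mean over their own rows is
    zero.  Subjects with a single condition become all-zero rows (warned).
    """
    features = list(features or FEATURE_NAMES)
    out = table.copy()
    singles = table.groupby("subject").size()
    for subj in singles.index[singles == 1]:
        log.warning("subject %s has a single condition; centering zeroes their row", subj)
    means = table.groupby("subject")[features].transform("mean")
    out[features] = table[features] - means
    return out


@dataclass
class MinMaxState:
    """Per-feature min and max learned from training rows."""

    features: list[str]
    min_: np.ndarray
    max_: np.ndarray


def fit_minmax(train_rows: pd.DataFrame, features: list[str] | None = None) -> MinMaxState:
    features = list(features or FEATURE_NAMES)
    if train_rows.empty:
        raise ValidationError("fit_minmax requires at least one training row")
    values = train_rows[features].to_numpy(dtype=float)
    lo = np.nanmin(values, axis=0)
    hi = np.nanmax(values, axis=0)
    for f, l, h in zip(features, lo, hi):
        if l == h:
            log.warning("feature %s is constant on the training rows; mapped to 0", f)
    return MinMaxState(features=features, min_=lo, max_=hi)


def apply_minmax(state: MinMaxState, rows: pd.DataFrame, clip: bool = False) -> pd.DataFrame:
    """Map rows into the training [0,1] range; constant features map to 0."""
    out = rows.copy()
    values = rows[state.features].to_numpy(dtype=float)
    span = state.max_ - state.min_
    safe = np.where(span == 0, 1.0, span)
    scaled = (values - state.min_) / safe
    scaled[:, span == 0] = 0.0
    if clip:
        scaled = np.clip(scaled, 0.0, 1.0)
    out[state.features] = scaled
    return out
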