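"""The 29 per-trial oculomotor variables.

Seven variables describe fixations (counts, duration statistics, reading
regressions) and 22 describe saccades (direction frequencies and min /
average / max over duration, velocity, amplitude, angle, distance and
slope).  Angles are measured against the horizontal axis with *upward*
positive, i.e. ``atan2(-dy, dx)`` in screen coordinates, range (-180, 180].
Distances and amplitudes are expressed in degrees of visual angle using a
viewing-geometry conversion.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import AoiGrid
from .records import FixationRecord, SaccadeRecord, Trial, ValidationError

log = logging.getLogger(__name__)

FIXATION_FEATURES: tuple[str, ...] = (
    "n_fix",
    "fix_mean",
    "fix_max",
    "norm_fix_mean",
    "norm_fix_max",
    "x_regressions",
    "y_regressions",
)

SACCADE_FEATURES: tuple[str, ...] = (
    "up_freq",
    "down_freq",
    "left_freq",
    "right_freq",
    "min_duration",
    "avg_duration",
    "max_duration",
    "min_vel",
    "avg_vel",
    "max_vel",
    "min_ampl",
    "avg_ampl",
    "max_ampl",
    "min_angle",
    "avg_angle",
    "max_angle",
    "min_distance",
    "avg_distance",
    "max_distance",
    "min_slope",
    "avg_slope",
    "max_slope",
)

FEATURE_NAMES: tuple[str, ...] = FIXATION_FEATURES + SACCADE_FEATURES

#: Named feature subsets used by the classification experiments.
FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "fix": FIXATION_FEATURES,
    "saccades": SACCADE_FEATURES,
    "fix+saccades": FEATURE_NAMES,
    "fix+saccades-norm": FEATURE_NAMES,  # same columns, subject-centered
}

#: Sentinel slope magnitude for vertical saccades (dx == 0), signed by dy.
VERTICAL_SLOPE_SENTINEL = 1e6


@dataclass(frozen=True)
class ViewingGeometry:
    """Screen geometry for the pixel -> degrees-of-visual-angle conversion.

    Defaults: a 1920-px-wide display of 376 mm physical width viewed from
    490 mm (midpoint of the 46-52 cm seating range).
    """

    screen_width_mm: float = 376.0
    screen_width_px: int = 1920
    distance_mm: float = 490.0

    @property
    def mm_per_px(self) -> float:
        return self.screen_width_mm / self.screen_width_px

    def px_to_deg(self, d_px: float) -> float:
        """Visual angle (degrees) subtended by a screen distance in pixels."""
        return math.degrees(2.0 * math.atan(d_px * self.mm_per_px / (2.0 * self.distance_mm)))


def count_regressions(
    fixations: list[FixationRecord], grid: AoiGrid
) -> tuple[int, int]:
    """Horizontal and vertical reading regressions over a fixation sequence.

    Reading order is left-to-right within a row and top-to-bottom across
    rows.  A horizontal regression is a consecutive pair whose x decreases
    while the grid row is unchanged; pairs where the row increases (a line
    change) are excluded from the horizontal count.  A vertical regression
    is a consecutive pair whose y decreases (an upward step).
    """
    if len(fixations) < 2:
        return (0, 0)
    x_reg = 0
    y_reg = 0
    for prev, cur in zip(fixations, fixations[1:]):
        if prev.aoi is None or cur.aoi is None:
            raise ValidationError("count_regressions requires fixations with an aoi")
        row_prev = grid.rowcol(prev.aoi)[0]
        row_cur = grid.rowcol(cur.aoi)[0]
        if row_cur == row_prev and cur.x < prev.x:
            x_reg += 1
        if cur.y < prev.y:
            y_reg += 1
    return (x_reg, y_reg)


def fixation_features(trial: Trial, grid: AoiGrid) -> dict[str, float]:
    """The 7 fixation variables of one cleaned trial.

    Durations are summarised raw (``fix_mean``, ``fix_max``) and normalised
    by the active viewing time — the span from the first fixation onset to
    the last fixation end after cleaning (``norm_fix_mean``,
    ``norm_fix_max``).  A trial with no surviving fixations reports
    ``n_fix = 0`` and NaN elsewhere.
    """
    fixs = trial.fixations
    if not fixs:
        log.warning("trial %s has no fixations after cleaning", trial.key)
        return {"n_fix": 0.0, **{k: float("nan") for k in FIXATION_FEATURES[1:]}}
    durations = np.array([f.duration for f in fixs], dtype=float)
    span = fixs[-1].t_end - fixs[0].t_start
    x_reg, y_reg = count_regressions(fixs, grid)
    fix_mean = float(durations.mean())
    fix_max = float(durations.max())
    return {
        "n_fix": float(len(fixs)),
        "fix_mean": fix_mean,
        "fix_max": fix_max,
        "norm_fix_mean": fix_mean / span if span > 0 else float("nan"),
        "norm_fix_max": fix_max / span if span > 0 else float("nan"),
        "x_regressions": float(x_reg),
        "y_regressions": float(y_reg),
    }


def classify_direction(saccade: SaccadeRecord) -> str | None:
    """Dominant-axis direction of a saccade: up, down, left or right.

    Ties (|dx| == |dy|) go to the horizontal axis.  Screen coordinates:
    dy > 0 is a downward movement.  Zero displacement returns None and is
    excluded from direction frequencies.
    """
    dx, dy = saccade.dx, saccade.dy
    if dx == 0 and dy == 0:
        return None
    if abs(dx) >= abs(dy):
        return "right" if dx > 0 else "left"
    return "down" if dy > 0 else "up"


def _slope(dx: float, dy: float) -> float:
    if dx == 0.0:
        if dy == 0.0:
            return 0.0
        return math.copysign(VERTICAL_SLOPE_SENTINEL, dy)
    return dy / dx


def saccade_features(trial: Trial, geometry: ViewingGeometry) -> dict[str, float]:
    """The 22 saccade variables of one cleaned trial.

    Direction frequencies are counts per direction normalised by the number
    of nonzero-displacement saccades.  The six statistic triples summarise
    per-saccade duration (ms), velocity (deg/s), amplitude (deg), angle
    (degrees against the horizontal, upward positive), start-to-end distance
    (deg) and slope (dy/dx, with vertical saccades mapped to +/-1e6).
    A trial with no saccades reports NaN throughout.
    """
    saccs = trial.saccades
    if not saccs:
        log.warning("trial %s has no saccades after cleaning", trial.key)
        return {k: float("nan") for k in SACCADE_FEATURES}

    counts = {"up": 0, "down": 0, "left": 0, "right": 0}
    n_directional = 0
    for s in saccs:
        d = classify_direction(s)
        if d is None:
            log.debug("trial %s: zero-displacement saccade %d excluded from directions",
                      trial.key, s.index)
            continue
        counts[d] += 1
        n_directional += 1

    per = {
        "duration": np.array([s.duration for s in saccs], dtype=float),
        "vel": np.array([s.velocity for s in saccs], dtype=float),
        "ampl": np.array([s.amplitude for s in saccs], dtype=float),
        "angle": np.array(
            [math.degrees(math.atan2(-s.dy, s.dx)) if (s.dx, s.dy) != (0.0, 0.0) else 0.0
             for s in saccs], dtype=float),
        "distance": np.array(
            [geometry.px_to_deg(math.hypot(s.dx, s.dy)) for s in saccs], dtype=float),
        "slope": np.array([_slope(s.dx, s.dy) for s in saccs], dtype=float),
    }

    out: dict[str, float] = {}
    for d in ("up", "down", "left", "right"):
        out[f"{d}_freq"] = counts[d] / n_directional if n_directional else float("nan")
    for stat, values in per.items():
        out[f"min_{stat}"] = float(values.min())
        out[f"avg_{stat}"] = float(values.mean())
        out[f"max_{stat}"] = float(values.max())
    # column names use the short forms min_duration / min_vel / min_ampl etc.
    return {k: out[k] for k in SACCADE_FEATURES}


def trial_features(
    trial: Trial, grid: AoiGrid, geometry: ViewingGeometry
) -> dict[str, float]:
    """All 29 variables of one cleaned trial, in canonical column order."""
    row = fixation_features(trial, grid)
    row.update(saccade_features(trial, geometry))
    return {k: row[k] for k in FEATURE_NAMES}


def extract_table(
    trials: list[Trial],
    grid: AoiGrid | None = None,
    geometry: ViewingGeometry | None = None,
) -> pd.DataFrame:
    """Feature table with one row per trial, keyed by (subject, condition).

    Raises on duplicate (subject, condition) pairs: the design has exactly
    one trial per subject per condition.
    """
    grid = grid or AoiGrid()
    geometry = geometry or ViewingGeometry()
    rows = []
    seen: set[tuple[str, str]] = set()
    for t in trials:
        key = (t.subject_id, t.condition)
        if key in seen:
            raise ValidationError(f"duplicate (subject, condition) row {key}")
        seen.add(key)
        rows.append({"subject": t.subject_id, "condition": t.condition,
                     **trial_features(t, grid, geometry)})
    return pd.DataFrame(rows, columns=["subject", "condition", *FEATURE_NAMES])
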