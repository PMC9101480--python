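"""Trial cleaning cascade.

Raw event streams carry task-irrelevant segments and instrumental noise:
the initial trigger dwell (the "head"), the fixations between the last word
and the space-key press (the "tail"), fixations landing outside the word
grid, very short fixations, and abnormally long ones.  The cascade removes
them in a fixed order:

    trim_head -> trim_tail(k) -> filter_offgrid -> filter_duration

Time-window cuts come first so the statistical duration filter sees only
task-period fixations.  Every stage is idempotent and never adds events.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .records import CANVAS, FixationRecord, Trial, ValidationError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AoiGrid:
    """A rows x cols grid of areas of interest tiling the stimulus canvas.

    Cells are half-open rectangles [x0, x1) x [y0, y1), indexed row-major
    (cell = row * cols + col).  ``margin`` expands every cell outward by
    that many pixels; with the default 0 the cells tile the canvas exactly,
    so only off-canvas fixations fall outside all cells.
    """

    canvas: tuple[int, int] = CANVAS
    rows: int = 4
    cols: int = 4
    margin: float = 0.0

    @property
    def cell_width(self) -> float:
        return self.canvas[0] / self.cols

    @property
    def cell_height(self) -> float:
        return self.canvas[1] / self.rows

    @property
    def n_cells(self) -> int:
        return self.rows * self.cols

    def cell_rect(self, index: int) -> tuple[float, float, float, float]:
        """(x0, y0, x1, y1) of a cell, margin-expanded."""
        row, col = divmod(index, self.cols)
        return (
            col * self.cell_width - self.margin,
            row * self.cell_height - self.margin,
            (col + 1) * self.cell_width + self.margin,
            (row + 1) * self.cell_height + self.margin,
        )

    def cell_center(self, index: int) -> tuple[float, float]:
        row, col = divmod(index, self.cols)
        return ((col + 0.5) * self.cell_width, (row + 0.5) * self.cell_height)

    def rowcol(self, index: int) -> tuple[int, int]:
        return divmod(index, self.cols)


def assign_aoi(fixation: FixationRecord, grid: AoiGrid) -> int | None:
    """Grid-cell index containing the fixation, or None if outside all cells.

    Interior points get the unique tiling cell; points within ``margin`` of
    the canvas edge are assigned to the nearest cell.
    """
    x, y = fixation.x, fixation.y
    if not (math.isfinite(x) and math.isfinite(y)):
        return None
    w, h = grid.canvas
    m = grid.margin
    if x < -m or x >= w + m or y < -m or y >= h + m:
        return None
    col = min(max(int(x // grid.cell_width), 0), grid.cols - 1)
    row = min(max(int(y // grid.cell_height), 0), grid.rows - 1)
    return row * grid.cols + col


@dataclass
class CleaningConfig:
    """Parameters of the cleaning cascade.

    min_fixation_ms
        Fixations shorter than this are dropped (reading fixations of
        interest start around 200 ms).
    z_max
        Among the survivors, fixations whose duration z-score is >= z_max
        are dropped (keep-if z < z_max, single pass).
    tail_fixations_dropped
        Number of trailing fixations removed as end-of-trial noise.
    aoi_margin_px
        Tolerance around each grid cell when deciding "off grid".
    z_scope
        Sample over which the duration z-score is computed: "trial"
        (default), "subject", or "cohort".
    iterative_z
        If True, repeat the z-step until no fixation is removed.
    """

    min_fixation_ms: float = 200.0
    z_max: float = 3.0
    tail_fixations_dropped: int = 5
    aoi_margin_px: float = 0.0
    z_scope: str = "trial"
    iterative_z: bool = False

    def __post_init__(self) -> None:
        if self.min_fixation_ms <= 0:
            raise ValidationError("min_fixation_ms must be > 0")
        if self.z_max <= 0:
            raise ValidationError("z_max must be > 0")
        if self.tail_fixations_dropped < 0:
            raise ValidationError("tail_fixations_dropped must be >= 0")
        if self.z_scope not in ("trial", "subject", "cohort"):
            raise ValidationError(f"unknown z_scope {self.z_scope!r}")


def trim_head(trial: Trial) -> Trial:
    """Remove all events that start before the trigger dwell completed."""
    if trial.trigger_end is None:
        raise ValidationError(
            f"trial {trial.key} has no trigger_end; cannot trim the head segment"
        )
    t0 = trial.trigger_end
    return trial.with_events(
        fixations=[f for f in trial.fixations if f.t_start >= t0],
        saccades=[s for s in trial.saccades if s.t_start >= t0],
    )


def trim_tail(trial: Trial, k: int) -> Trial:
    """Drop the last ``k`` fixations and any saccade starting after them."""
    if k == 0:
        return trial
    fixations = sorted(trial.fixations, key=lambda f: f.t_start)
    if len(fixations) <= k:
        if fixations:
            log.warning(
                "trial %s has only %d fixation(s); tail trim of %d removes all",
                trial.key, len(fixations), k,
            )
        return trial.with_events(fixations=[], saccades=[])
    kept = fixations[:-k]
    cutoff = kept[-1].t_end
    return trial.with_events(
        fixations=kept,
        saccades=[s for s in trial.saccades if s.t_start <= cutoff],
    )


def filter_offgrid(trial: Trial, grid: AoiGrid) -> Trial:
    """Drop fixations outside every AOI cell; survivors carry their cell index."""
    kept = []
    for f in trial.fixations:
        aoi = assign_aoi(f, grid)
        if aoi is None:
            continue
        if f.aoi != aoi:
            f = FixationRecord(**{**f.__dict__, "aoi": aoi})
        kept.append(f)
    return trial.with_events(fixations=kept)


def zscore_survivors(durations: np.ndarray, scope: np.ndarray, z_max: float) -> np.ndarray:
    """Boolean keep-mask for the duration z-filter.

    ``scope`` is the sample the mean/sd are estimated from (may be larger
    than the trial, e.g. all of a subject's fixations).  Sample sd (ddof=1);
    a degenerate scope (size < 2 or zero sd) keeps everything.
    """
    if scope.size < 2:
        log.warning("z-score scope has %d value(s); skipping the z-filter", scope.size)
        return np.ones(durations.shape, dtype=bool)
    sd = float(np.std(scope, ddof=1))
    if sd == 0.0:
        return np.ones(durations.shape, dtype=bool)
    z = (durations - float(np.mean(scope))) / sd
    return z < z_max


def filter_duration(
    trial: Trial,
    config: CleaningConfig,
    scope_durations: np.ndarray | None = None,
) -> Trial:
    """Duration floor, then z-score outlier retention.

    Fixations below ``min_fixation_ms`` are dropped.  Among the survivors,
    fixations with duration z-score >= ``z_max`` are dropped, where the z
    statistics come from ``scope_durations`` when given (subject- or
    cohort-scoped cleaning) and otherwise from the trial's own survivors.
    """
    survivors = [f for f in trial.fixations if f.duration >= config.min_fixation_ms]
    while True:
        durations = np.array([f.duration for f in survivors], dtype=float)
        scope = durations if scope_durations is None else np.asarray(scope_durations, float)
        keep = zscore_survivors(durations, scope, config.z_max)
        if keep.all():
            break
        survivors = [f for f, k in zip(survivors, keep) if k]
        if not config.iterative_z or scope_durations is not None:
            break
    return trial.with_events(fixations=survivors)


def clean(
    trial: Trial,
    grid: AoiGrid | None = None,
    config: CleaningConfig | None = None,
    scope_durations: np.ndarray | None = None,
) -> Trial:
    """Full cascade: head, tail, off-grid, duration.  Never adds events."""
    grid = grid or AoiGrid()
    config = config or CleaningConfig()
    if grid.margin != config.aoi_margin_px:
        grid = AoiGrid(canvas=grid.canvas, rows=grid.rows, cols=grid.cols,
                       margin=config.aoi_margin_px)
    t = trim_head(trial)
    t = trim_tail(t, config.tail_fixations_dropped)
    t = filter_offgrid(t, grid)
    t = filter_duration(t, config, scope_durations=scope_durations)
    return t


def clean_cohort(
    trials: list[Trial],
    grid: AoiGrid | None = None,
    config: CleaningConfig | None = None,
) -> list[Trial]:
    """Clean every trial, honouring the configured z-score scope.

    For ``z_scope="trial"`` each trial is cleaned independently.  For
    "subject" / "cohort" the duration z statistics are pooled over all
    post-floor fixations of the subject / the whole cohort.
    """
    grid = grid or AoiGrid()
    config = config or CleaningConfig()
    if config.z_scope == "trial":
        return [clean(t, grid, config) for t in trials]

    # First pass up to the duration floor, to build the pooled scope sample.
    partial = []
    for t in trials:
        p = trim_head(t)
        p = trim_tail(p, config.tail_fixations_dropped)
        p = filter_offgrid(p, grid if grid.margin == config.aoi_margin_px else
                           AoiGrid(grid.canvas, grid.rows, grid.cols, config.aoi_margin_px))
        partial.append(p)
    pools: dict[str | None, list[float]] = {}
    for p in partial:
        key = p.subject_id if config.z_scope == "subject" else None
        pools.setdefault(key, []).extend(
            f.duration for f in p.fixations if f.duration >= config.min_fixation_ms
        )
    out = []
    for p in partial:
        key = p.subject_id if config.z_scope == "subject" else None
        scope = np.array(pools.get(key, []), dtype=float)
        out.append(filter_duration(p, config, scope_durations=scope))
    return out


def cleaning_summary(before: Trial, after: Trial) -> dict:
    """Per-trial event-removal counts, for pipeline logging."""
    return {
        "subject": before.subject_id,
        "condition": before.condition,
        "trial": before.trial_id,
        "fixations_in": len(before.fixations),
        "fixations_out": len(after.fixations),
        "saccades_in": len(before.saccades),
        "saccades_out": len(after.saccades),
    }
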