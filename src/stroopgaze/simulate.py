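"""Synthetic scanpath generator for a grid-reading Stroop experiment.

The generator emulates the recordings the analysis pipeline expects: 64
subjects, each viewing four 4x4 word grids on a 1024x768 px canvas — the
Naming and Reading tasks with and without colour-word interference (NWI,
NWoI, RWI, RWoI).  A trial is a word-grid walk in reading order
(left-to-right, top-to-bottom) with stochastic refixations, within-row
backward excursions (horizontal regressions) and upward excursions between
rows (vertical regressions).  Fixation durations are log-normal per condition
with a multiplicative per-subject random effect; saccades connect
consecutive fixations with geometrically consistent endpoints.  Recording
artifacts are included deliberately, because the cleaning cascade exists to
remove them: a trigger-dwell head segment at the top-left, a tail of noise
fixations after the last word, and off-canvas noise fixations at a
configurable rate.

Condition effects (the frozen defaults): Naming is slower and more
effortful than Reading, so Naming conditions have longer fixations, more
refixations and more regressions; interference adds strongly to Naming and
only weakly to Reading.  Mean fixation duration is ordered
RWoI < RWI < NWoI < NWI.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .features import ViewingGeometry
from .preprocess import AoiGrid
from .records import CANVAS, CONDITIONS, FixationRecord, SaccadeRecord, Trial, ValidationError
from .report_io import META_COLUMNS, write_fixation_report, write_saccade_report, write_trial_meta


@dataclass(frozen=True)
class ConditionParams:
    """Generative parameters of one experimental condition.

    fix_median_ms / fix_sigma
        Median and log-scale sigma of the log-normal fixation-duration
        distribution.
    p_refixate / p_regress_x / p_regress_y
        Probabilities, per visited word, of refixating it (geometric in the
        number of repeats), of a backward excursion within the row, and of
        an upward excursion to the previous row.
    sacc_dur_mean_ms / sacc_dur_sd_ms
        Normal saccade-duration parameters (truncated at 8 ms).
    offgrid_rate
        Probability of injecting an off-canvas noise fixation after each
        walk fixation.
    head_dwell_ms
        Trigger dwell before the trial proper (the protocol requires at
        least 100 ms on the trigger dot).
    tail_fixations
        Number of post-task noise fixations appended after the last word.
    """

    fix_median_ms: float
    fix_sigma: float
    p_refixate: float
    p_regress_x: float
    p_regress_y: float
    sacc_dur_mean_ms: float
    sacc_dur_sd_ms: float = 8.0
    offgrid_rate: float = 0.05
    head_dwell_ms: float = 150.0
    tail_fixations: int = 5

    def __post_init__(self) -> None:
        for p in (self.p_refixate, self.p_regress_x, self.p_regress_y, self.offgrid_rate):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"probabilities must be in [0,1], got {p}")
        if self.fix_median_ms <= 0 or self.fix_sigma <= 0 or self.sacc_dur_mean_ms <= 0:
            raise ValidationError("scale parameters must be > 0")
        if self.head_dwell_ms < 100.0:
            raise ValidationError("trigger dwell must be at least 100 ms")


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level configuration: condition effects and subject variability.

    ``subject_duration_sd`` is the log-scale sd of a per-subject
    multiplicative offset on fixation durations; ``subject_regress_sd`` is
    the logit-scale sd of per-subject additive offsets on the refixation and
    regression probabilities.  Both model the strong inter-subject
    variability of gaze behaviour.
    """

    n_subjects: int = 64
    canvas: tuple[int, int] = CANVAS
    grid_rows: int = 4
    grid_cols: int = 4
    conditions: dict = field(default_factory=dict)  # condition -> ConditionParams
    subject_duration_sd: float = 0.15
    subject_regress_sd: float = 0.4
    subject_saccade_sd: float = 0.15
    fixation_jitter_px: float = 14.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")
        for c in self.conditions:
            if c not in CONDITIONS:
                raise ValidationError(f"unknown condition {c!r} in SimConfig")

    def aoi_grid(self, margin: float = 0.0) -> AoiGrid:
        return AoiGrid(canvas=self.canvas, rows=self.grid_rows,
                       cols=self.grid_cols, margin=margin)


def calibrate_defaults() -> SimConfig:
    """The frozen default condition effects.

    Naming conditions have longer fixations and more fixations than
    Reading; interference adds regressions and fixation count strongly
    within Naming and weakly within Reading, and lengthens saccade
    durations most in NWI.  These values are qualitative calibrations — the
    study reports no per-condition descriptive statistics to anchor them
    quantitatively.
    """
    return SimConfig(conditions={
        "RWoI": ConditionParams(fix_median_ms=230.0, fix_sigma=0.25,
                                p_refixate=0.10, p_regress_x=0.03, p_regress_y=0.010,
                                sacc_dur_mean_ms=30.0),
        "RWI": ConditionParams(fix_median_ms=250.0, fix_sigma=0.25,
                               p_refixate=0.14, p_regress_x=0.05, p_regress_y=0.020,
                               sacc_dur_mean_ms=32.0),
        "NWoI": ConditionParams(fix_median_ms=290.0, fix_sigma=0.27,
                                p_refixate=0.25, p_regress_x=0.08, p_regress_y=0.030,
                                sacc_dur_mean_ms=34.0),
        "NWI": ConditionParams(fix_median_ms=340.0, fix_sigma=0.28,
                               p_refixate=0.38, p_regress_x=0.16, p_regress_y=0.080,
                               sacc_dur_mean_ms=38.0),
    })


def null_config() -> SimConfig:
    """A zero-effect cohort: all four conditions share the same parameters.

    Used for calibration — downstream ANOVA p-values should be uniform and
    classifiers should sit at the 0.5 chance baseline.
    """
    shared = ConditionParams(fix_median_ms=260.0, fix_sigma=0.26,
                             p_refixate=0.18, p_regress_x=0.06, p_regress_y=0.025,
                             sacc_dur_mean_ms=34.0)
    return SimConfig(conditions={c: shared for c in CONDITIONS})


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject random effects, reproducible from (seed, subject index)."""

    subject_id: str
    duration_factor: float  # multiplies every fixation duration
    regress_shift: float  # logit-scale shift on walk probabilities
    saccade_factor: float = 1.0  # multiplies saccade durations


def draw_profile(subject_index: int, config: SimConfig, rng: np.random.Generator) -> SubjectProfile:
    return SubjectProfile(
        subject_id=f"S{subject_index:03d}",
        duration_factor=float(np.exp(rng.normal(0.0, config.subject_duration_sd))),
        regress_shift=float(rng.normal(0.0, config.subject_regress_sd)),
        saccade_factor=float(np.exp(rng.normal(0.0, config.subject_saccade_sd))),
    )


def _shift_prob(p: float, logit_shift: float) -> float:
    if p <= 0.0 or p >= 1.0:
        return p
    logit = math.log(p / (1.0 - p)) + logit_shift
    return 1.0 / (1.0 + math.exp(-logit))


def _walk_cells(params: ConditionParams, shift: float, n_cells: int, cols: int,
                rng: np.random.Generator) -> list[int]:
    """Reading-order walk over grid cells with regression excursions.

    The gaze visits every word left-to-right, top-to-bottom.  At each word
    it may refixate (geometrically, probability ``p_refixate`` per repeat),
    step back one word within the row and return (a horizontal regression),
    or step up one row and return (a vertical regression).  Excursions are
    single-step with an immediate return, mirroring the re-reading pattern
    of regressive eye movements, so the walk length is linear in the grid
    size and the walk always terminates.
    """
    p_refix = min(_shift_prob(params.p_refixate, shift), 0.9)
    p_rx = min(_shift_prob(params.p_regress_x, shift), 0.9)
    p_ry = min(_shift_prob(params.p_regress_y, shift), 0.9)
    path: list[int] = []
    for cell in range(n_cells):
        row, col = divmod(cell, cols)
        path.append(cell)
        while rng.random() < p_refix:
            path.append(cell)
        if col > 0 and rng.random() < p_rx:
            path.extend((cell - 1, cell))
        if row > 0 and rng.random() < p_ry:
            path.extend((cell - cols, cell))
    return path


def simulate_trial(
    profile: SubjectProfile,
    condition: str,
    config: SimConfig,
    rng: np.random.Generator,
    geometry: ViewingGeometry | None = None,
) -> Trial:
    """Generate one trial: head dwell, grid walk, tail noise, saccades.

    Saccade endpoints coincide exactly with the flanking fixation
    coordinates; amplitude is the start-to-end distance in degrees of
    visual angle and velocity its mean speed over the saccade duration.
    """
    params: ConditionParams = config.conditions[condition]
    geometry = geometry or ViewingGeometry()
    grid = config.aoi_grid()
    trial_id = f"{profile.subject_id}-{condition}"
    jitter = config.fixation_jitter_px
    w, h = config.canvas

    # -- fixation positions ------------------------------------------------
    positions: list[tuple[float, float]] = []
    durations: list[float] = []

    def log_normal_duration() -> float:
        return float(np.exp(np.log(params.fix_median_ms)
                            + rng.normal(0.0, params.fix_sigma))) * profile.duration_factor

    # head: trigger dwell at the top-left corner (split into 1-2 fixations)
    trigger_xy = (18.0, 18.0)
    n_head = int(rng.integers(1, 3))
    head_durs = [max(60.0, params.head_dwell_ms / n_head + float(rng.normal(0, 10)))
                 for _ in range(n_head)]
    for d in head_durs:
        positions.append((trigger_xy[0] + float(rng.normal(0, 3)),
                          trigger_xy[1] + float(rng.normal(0, 3))))
        durations.append(d)
    n_head_fix = len(positions)

    # task walk over the word grid
    path = _walk_cells(params, profile.regress_shift, grid.n_cells, grid.cols, rng)
    for cell in path:
        cx, cy = grid.cell_center(cell)
        half_w = grid.cell_width / 2.0 - 2.0
        half_h = grid.cell_height / 2.0 - 2.0
        x = cx + float(np.clip(rng.normal(0.0, jitter), -half_w, half_w))
        y = cy + float(np.clip(rng.normal(0.0, jitter), -half_h, half_h))
        positions.append((x, y))
        durations.append(log_normal_duration())
        if rng.random() < params.offgrid_rate:
            # instrumental noise: a short fixation off the canvas edge
            side = rng.integers(0, 4)
            off = float(rng.uniform(8.0, 60.0))
            nx, ny = {
                0: (-off, rng.uniform(0, h)),
                1: (w + off, rng.uniform(0, h)),
                2: (rng.uniform(0, w), -off),
                3: (rng.uniform(0, w), h + off),
            }[int(side)]
            positions.append((float(nx), float(ny)))
            durations.append(float(rng.uniform(80.0, 250.0)))

    # tail: noise fixations between the last word and the space-key press
    for _ in range(params.tail_fixations):
        positions.append((float(rng.uniform(0.55 * w, w - 1)),
                          float(rng.uniform(0.55 * h, h - 1))))
        durations.append(float(rng.uniform(120.0, 400.0)))

    # -- timestamps and saccades ------------------------------------------
    fixations: list[FixationRecord] = []
    saccades: list[SaccadeRecord] = []
    t = 0.0
    trigger_end = None
    for i, ((x, y), dur) in enumerate(zip(positions, durations)):
        fixations.append(FixationRecord(
            subject_id=profile.subject_id, condition=condition, trial_id=trial_id,
            index=i, t_start=t, duration=dur, x=x, y=y,
        ))
        t += dur
        if i == n_head_fix - 1:
            trigger_end = t
        if i < len(positions) - 1:
            x2, y2 = positions[i + 1]
            sdur = max(8.0, float(rng.normal(
                params.sacc_dur_mean_ms * profile.saccade_factor, params.sacc_dur_sd_ms)))
            dist_deg = geometry.px_to_deg(math.hypot(x2 - x, y2 - y))
            saccades.append(SaccadeRecord(
                subject_id=profile.subject_id, condition=condition, trial_id=trial_id,
                index=i, t_start=t, duration=sdur,
                x_start=x, y_start=y, x_end=x2, y_end=y2,
                amplitude=dist_deg, velocity=dist_deg / (sdur / 1000.0),
            ))
            t += sdur
    trial_end = t + float(rng.uniform(50.0, 300.0))

    return Trial(
        subject_id=profile.subject_id, condition=condition, trial_id=trial_id,
        fixations=fixations, saccades=saccades,
        trigger_end=trigger_end, trial_end=trial_end, canvas=config.canvas,
    )


def simulate_cohort(
    config: SimConfig | None = None,
    seed: int = 0,
    geometry: ViewingGeometry | None = None,
) -> tuple[list[FixationRecord], list[SaccadeRecord], pd.DataFrame]:
    """Simulate n_subjects x 4 trials; fully determined by the seed.

    Returns flat fixation and saccade record lists plus the trial meta
    table (trigger and end times), ready for :func:`report_io.assemble_trials`.
    """
    config = config or calibrate_defaults()
    if set(config.conditions) != set(CONDITIONS):
        raise ValidationError("SimConfig must define all four conditions")
    rng = np.random.default_rng(seed)
    fixations: list[FixationRecord] = []
    saccades: list[SaccadeRecord] = []
    meta_rows = []
    for i in range(config.n_subjects):
        profile = draw_profile(i, config, rng)
        for condition in CONDITIONS:
            trial = simulate_trial(profile, condition, config, rng, geometry)
            fixations.extend(trial.fixations)
            saccades.extend(trial.saccades)
            meta_rows.append({
                "subject": trial.subject_id, "condition": condition,
                "trial": trial.trial_id,
                "trigger_end_ms": trial.trigger_end,
                "trial_end_ms": trial.trial_end,
            })
    meta = pd.DataFrame(meta_rows, columns=META_COLUMNS)
    return fixations, saccades, meta


def simulate_trials(
    config: SimConfig | None = None,
    seed: int = 0,
    geometry: ViewingGeometry | None = None,
) -> list[Trial]:
    """Convenience: simulate a cohort and return assembled Trial objects."""
    from .report_io import assemble_trials

    fixations, saccades, meta = simulate_cohort(config, seed, geometry)
    return assemble_trials(fixations, saccades, meta)


def config_to_dict(config: SimConfig) -> dict:
    d = dataclasses.asdict(config)
    d["conditions"] = {c: dataclasses.asdict(p) for c, p in config.conditions.items()}
    d["canvas"] = list(config.canvas)
    return d


def config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    d["conditions"] = {c: ConditionParams(**p) for c, p in d.get("conditions", {}).items()}
    if "canvas" in d:
        d["canvas"] = tuple(d["canvas"])
    return SimConfig(**d)


def write_cohort(
    out_dir: str | Path,
    config: SimConfig | None = None,
    seed: int = 0,
) -> dict[str, Path]:
    """Simulate and serialize a cohort to report files in ``out_dir``.

    Writes fixation_report.tsv, saccade_report.tsv, meta.tsv and
    config_used.yaml; byte-identical for identical (config, seed).
    """
    config = config or calibrate_defaults()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fixations, saccades, meta = simulate_cohort(config, seed)
    paths = {
        "fixations": out_dir / "fixation_report.tsv",
        "saccades": out_dir / "saccade_report.tsv",
        "meta": out_dir / "meta.tsv",
        "config": out_dir / "config_used.yaml",
    }
    write_fixation_report(fixations, paths["fixations"])
    write_saccade_report(saccades, paths["saccades"])
    write_trial_meta(meta, paths["meta"])
    with open(paths["config"], "w") as fh:
        yaml.safe_dump({"seed": seed, **config_to_dict(config)}, fh, sort_keys=True)
    return paths
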