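"""Core event and trial containers for gaze recordings.

All times are milliseconds relative to trial onset.  Coordinates are screen
pixels with the origin at the top-left corner and y increasing downward, so a
*downward* gaze step has a positive y displacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

#: The four experimental conditions: Naming / Reading, each With / Without
#: Interference.  Any other label is rejected at parse time.
CONDITIONS: tuple[str, ...] = ("NWoI", "NWI", "RWoI", "RWI")

#: Default stimulus canvas in pixels (width, height).
CANVAS: tuple[int, int] = (1024, 768)


class StroopGazeError(Exception):
    """Base class for all errors raised by this package."""


class ConfigError(StroopGazeError):
    """A configuration problem (e.g. an unresolvable report column)."""


class ValidationError(StroopGazeError):
    """An input record violates a structural invariant."""


def check_condition(label: str) -> str:
    if label not in CONDITIONS:
        raise ValidationError(
            f"unknown condition label {label!r}; expected one of {CONDITIONS}"
        )
    return label


@dataclass
class FixationRecord:
    """A single fixation: the eye nearly stationary, sampling information."""

    subject_id: str
    condition: str
    trial_id: str
    index: int
    t_start: float  # ms from trial onset
    duration: float  # ms
    x: float  # px
    y: float  # px
    aoi: int | None = None  # grid cell 0-15, row-major; None = off grid

    def validate(self) -> "FixationRecord":
        check_condition(self.condition)
        if not self.duration > 0:
            raise ValidationError(
                f"fixation duration must be > 0, got {self.duration} "
                f"(subject {self.subject_id}, trial {self.trial_id}, index {self.index})"
            )
        if self.t_start < 0:
            raise ValidationError(f"fixation t_start must be >= 0, got {self.t_start}")
        if self.aoi is not None and not 0 <= self.aoi <= 15:
            raise ValidationError(f"aoi must be in [0, 15] or None, got {self.aoi}")
        return self

    @property
    def t_end(self) -> float:
        return self.t_start + self.duration


@dataclass
class SaccadeRecord:
    """A single saccade: a ballistic gaze jump between two fixations."""

    subject_id: str
    condition: str
    trial_id: str
    index: int
    t_start: float  # ms
    duration: float  # ms
    x_start: float  # px
    y_start: float
    x_end: float
    y_end: float
    amplitude: float  # degrees of visual angle
    velocity: float  # degrees / second

    def validate(self) -> "SaccadeRecord":
        check_condition(self.condition)
        if not self.duration > 0:
            raise ValidationError(
                f"saccade duration must be > 0, got {self.duration} "
                f"(subject {self.subject_id}, trial {self.trial_id}, index {self.index})"
            )
        if self.amplitude < 0:
            raise ValidationError(f"saccade amplitude must be >= 0, got {self.amplitude}")
        if self.velocity < 0:
            raise ValidationError(f"saccade velocity must be >= 0, got {self.velocity}")
        return self

    @property
    def dx(self) -> float:
        return self.x_end - self.x_start

    @property
    def dy(self) -> float:
        return self.y_end - self.y_start


@dataclass
class Trial:
    """One subject x condition recording.

    ``trigger_end`` is the moment the initial trigger dwell completed (the
    trial "head" ends here); ``trial_end`` is the space-key press concluding
    the trial.  Event lists are kept sorted by onset time.
    """

    subject_id: str
    condition: str
    trial_id: str
    fixations: list[FixationRecord] = field(default_factory=list)
    saccades: list[SaccadeRecord] = field(default_factory=list)
    trigger_end: float | None = None
    trial_end: float | None = None
    canvas: tuple[int, int] = CANVAS

    def sorted(self) -> "Trial":
        return replace(
            self,
            fixations=sorted(self.fixations, key=lambda f: f.t_start),
            saccades=sorted(self.saccades, key=lambda s: s.t_start),
        )

    def with_events(
        self,
        fixations: list[FixationRecord] | None = None,
        saccades: list[SaccadeRecord] | None = None,
    ) -> "Trial":
        return replace(
            self,
            fixations=self.fixations if fixations is None else fixations,
            saccades=self.saccades if saccades is None else saccades,
        )

    @property
    def n_fixations(self) -> int:
        return len(self.fixations)

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.subject_id, self.condition, self.trial_id)
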