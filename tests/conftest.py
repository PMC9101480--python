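import numpy as np
import pytest

import stroopgaze as sg
from stroopgaze.records import FixationRecord, SaccadeRecord, Trial


@pytest.fixture(scope="session")
def grid() -> sg.AoiGrid:
    return sg.AoiGrid()


@pytest.fixture(scope="session")
def geometry() -> sg.ViewingGeometry:
    return sg.ViewingGeometry()


def make_fixation(i=0, t=0.0, dur=250.0, x=100.0, y=100.0, subject="S000",
                  condition="NWoI", trial="T0", aoi=None) -> FixationRecord:
    return FixationRecord(subject_id=subject, condition=condition, trial_id=trial,
                          index=i, t_start=t, duration=dur, x=x, y=y, aoi=aoi)


def make_saccade(i=0, t=0.0, dur=30.0, x0=100.0, y0=100.0, x1=300.0, y1=100.0,
                 ampl=2.0, vel=60.0, subject="S000", condition="NWoI",
                 trial="T0") -> SaccadeRecord:
    return SaccadeRecord(subject_id=subject, condition=condition, trial_id=trial,
                         index=i, t_start=t, duration=dur, x_start=x0, y_start=y0,
                         x_end=x1, y_end=y1, amplitude=ampl, velocity=vel)


def make_trial(durations, xs=None, ys=None, trigger_end=0.0, gap=30.0,
               condition="NWoI", subject="S000") -> Trial:
    """Build a trial from fixation durations (and optional coordinates),
    with saccades linking consecutive fixations."""
    n = len(durations)
    xs = xs if xs is not None else [100.0 + 50.0 * i for i in range(n)]
    ys = ys if ys is not None else [100.0] * n
    fixations, saccades = [], []
    t = 0.0
    for i, (d, x, y) in enumerate(zip(durations, xs, ys)):
        fixations.append(make_fixation(i=i, t=t, dur=d, x=x, y=y,
                                       subject=subject, condition=condition))
        t += d
        if i < n - 1:
            saccades.append(make_saccade(i=i, t=t, dur=gap, x0=x, y0=y,
                                         x1=xs[i + 1], y1=ys[i + 1],
                                         subject=subject, condition=condition))
            t += gap
    return Trial(subject_id=subject, condition=condition, trial_id="T0",
                 fixations=fixations, saccades=saccades,
                 trigger_end=trigger_end, trial_end=t + 100.0)


@pytest.fixture
def trial_factory():
    return make_trial


@pytest.fixture(scope="session")
def effect_table():
    """Feature table of a default-effect 32-subject cohort (cleaned)."""
    import dataclasses
    config = dataclasses.replace(sg.calibrate_defaults(), n_subjects=32)
    trials = sg.simulate_trials(config, seed=11)
    return sg.extract_table(sg.clean_cohort(trials))


@pytest.fixture(scope="session")
def random_clean_trials():
    """100 simulated, cleaned trials with varied conditions (oracle checks)."""
    import dataclasses
    config = dataclasses.replace(sg.calibrate_defaults(), n_subjects=25)
    trials = sg.simulate_trials(config, seed=23)
    return sg.clean_cohort(trials)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
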