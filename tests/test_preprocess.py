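import dataclasses

import numpy as np
import pytest

import stroopgaze as sg
from stroopgaze import preprocess
from stroopgaze.records import ValidationError

from conftest import make_fixation, make_trial
from oracles import oracle_assign_aoi, oracle_duration_filter


class TestAssignAoi:
    @pytest.mark.parametrize("xy,expected", [
        ((0, 0), 0),
        ((1023, 767), 15),
        ((255.9, 191.9), 0),
        ((256.0, 0.0), 1),  # half-open cells: the boundary belongs rightward
        ((0.0, 192.0), 4),
        ((-50, -50), None),
        ((1024.0, 100.0), None),
    ])
    def test_examples(self, grid, xy, expected):
        assert sg.assign_aoi(make_fixation(x=xy[0], y=xy[1]), grid) == expected

    def test_random_points_match_rectangle_search(self, grid, rng):
        xs = rng.uniform(0, grid.canvas[0], size=1000)
        ys = rng.uniform(0, grid.canvas[1], size=1000)
        for x, y in zip(xs, ys):
            got = sg.assign_aoi(make_fixation(x=x, y=y), grid)
            assert got is not None
            assert got == oracle_assign_aoi(x, y, grid)

    def test_margin_extends_beyond_canvas_edge(self):
        grid = sg.AoiGrid(margin=10.0)
        assert sg.assign_aoi(make_fixation(x=-5.0, y=-5.0), grid) == 0
        assert sg.assign_aoi(make_fixation(x=1030.0, y=760.0), grid) == 15
        assert sg.assign_aoi(make_fixation(x=-15.0, y=0.0), grid) is None


class TestTrimHead:
    def test_removes_pre_trigger_events(self, trial_factory):
        trial = trial_factory([100.0] * 10)
        trial = dataclasses.replace(trial, trigger_end=trial.fixations[2].t_start)
        out = preprocess.trim_head(trial)
        assert len(out.fixations) == 8
        assert all(f.t_start >= trial.trigger_end for f in out.fixations)
        assert all(s.t_start >= trial.trigger_end for s in out.saccades)

    def test_zero_trigger_is_identity(self, trial_factory):
        trial = trial_factory([100.0] * 5, trigger_end=0.0)
        assert preprocess.trim_head(trial) == trial

    def test_missing_trigger_end_errors(self, trial_factory):
        trial = dataclasses.replace(trial_factory([100.0] * 3), trigger_end=None)
        with pytest.raises(ValidationError, match="trigger_end"):
            preprocess.trim_head(trial)


class TestTrimTail:
    def test_drops_last_k(self, trial_factory):
        trial = trial_factory([100.0] * 12)
        out = preprocess.trim_tail(trial, 5)
        assert len(out.fixations) == 7
        cutoff = out.fixations[-1].t_end
        assert all(s.t_start <= cutoff for s in out.saccades)

    def test_k_zero_identity(self, trial_factory):
        trial = trial_factory([100.0] * 4)
        assert preprocess.trim_tail(trial, 0) == trial

    def test_fewer_fixations_than_k_empties_with_warning(self, trial_factory, caplog):
        trial = trial_factory([100.0] * 3)
        with caplog.at_level("WARNING"):
            out = preprocess.trim_tail(trial, 5)
        assert out.fixations == [] and out.saccades == []
        assert any("tail" in r.message for r in caplog.records)


class TestFilterOffgrid:
    def test_offcanvas_fixation_removed(self, grid, trial_factory):
        trial = trial_factory([250.0, 250.0], xs=[-50.0, 100.0], ys=[-50.0, 100.0])
        out = preprocess.filter_offgrid(trial, grid)
        assert len(out.fixations) == 1
        assert out.fixations[0].aoi == 0

    def test_all_on_grid_keeps_everything(self, grid, trial_factory):
        trial = trial_factory([250.0] * 5)
        out = preprocess.filter_offgrid(trial, grid)
        assert len(out.fixations) == 5
        assert all(f.aoi is not None for f in out.fixations)

    def test_injected_noise_rate_recovered(self, grid):
        """Off-grid injection at 10% per walk fixation: the removed fraction
        of noise fixations should match the binomial 99% band."""
        params = {c: dataclasses.replace(p, offgrid_rate=0.10)
                  for c, p in sg.calibrate_defaults().conditions.items()}
        config = dataclasses.replace(sg.calibrate_defaults(), n_subjects=30,
                                     conditions=params)
        trials = sg.simulate_trials(config, seed=3)
        n_walk = 0
        n_noise = 0
        for t in trials:
            body = preprocess.trim_tail(preprocess.trim_head(t), 5)
            kept = preprocess.filter_offgrid(body, grid)
            removed = len(body.fixations) - len(kept.fixations)
            n_noise += removed
            n_walk += len(kept.fixations)
        rate = n_noise / n_walk
        se = np.sqrt(0.10 * 0.90 / n_walk)
        assert abs(rate - 0.10) < 2.58 * se + 0.01


class TestFilterDuration:
    def test_floor_is_inclusive_at_200(self):
        trial = make_trial([150.0, 199.0, 200.0, 250.0])
        out = preprocess.filter_duration(trial, sg.CleaningConfig())
        assert [f.duration for f in out.fixations] == [200.0, 250.0]

    def test_equal_durations_keep_all(self):
        trial = make_trial([300.0] * 6)
        out = preprocess.filter_duration(trial, sg.CleaningConfig())
        assert len(out.fixations) == 6

    def test_matches_bruteforce_oracle_with_implanted_extremes(self, rng):
        durations = list(rng.lognormal(np.log(260.0), 0.3, size=200))
        durations[10] = 2500.0
        durations[50] = 3000.0
        durations[90] = 5000.0
        trial = make_trial(durations)
        out = preprocess.filter_duration(trial, sg.CleaningConfig())
        expected = oracle_duration_filter(durations, 200.0, 3.0)
        assert [f.duration for f in out.fixations] == expected
        assert len(expected) < sum(d >= 200.0 for d in durations)

    def test_tiny_scope_skips_z_with_warning(self, caplog):
        trial = make_trial([250.0])
        with caplog.at_level("WARNING"):
            out = preprocess.filter_duration(trial, sg.CleaningConfig())
        assert len(out.fixations) == 1
        assert any("z-" in r.message for r in caplog.records)


class TestCleanCascade:
    def test_already_clean_trial_is_fixed_point(self, grid):
        trial = make_trial([250.0, 260.0, 270.0, 280.0])
        once = sg.clean(trial, grid)
        assert sg.clean(once, grid) == once

    def test_window_and_spatial_stages_idempotent(self, grid):
        """trim_head and filter_offgrid are fixed-point stages; applying
        them twice changes nothing.  (trim_tail drops the last k fixations
        on every application, and the one-pass z-filter recomputes its
        statistics on the survivors, so those two are re-applied only once
        inside the cascade by design.)"""
        trials = sg.simulate_trials(
            dataclasses.replace(sg.calibrate_defaults(), n_subjects=3), seed=9)
        for t in trials:
            for stage in (preprocess.trim_head,
                          lambda x: preprocess.filter_offgrid(x, grid)):
                once = stage(t)
                assert stage(once) == once

    def test_clean_composition_is_stable_after_tail_padding(self, grid):
        """Re-cleaning a cleaned trial with tail trimming disabled (its tail
        is already gone) must leave it unchanged."""
        config = sg.CleaningConfig()
        recheck = sg.CleaningConfig(tail_fixations_dropped=0)
        trials = sg.simulate_trials(
            dataclasses.replace(sg.calibrate_defaults(), n_subjects=3), seed=9)
        for t in trials:
            once = sg.clean(t, grid, config)
            assert sg.clean(once, grid, recheck) == once

    def test_monotone_and_order_preserving(self, grid):
        trials = sg.simulate_trials(
            dataclasses.replace(sg.calibrate_defaults(), n_subjects=4), seed=10)
        for t in trials:
            out = sg.clean(t, grid)
            assert len(out.fixations) <= len(t.fixations)
            assert len(out.saccades) <= len(t.saccades)
            starts = [f.t_start for f in out.fixations]
            assert starts == sorted(starts)
            in_starts = [f.t_start for f in t.fixations]
            assert set(starts) <= set(in_starts)

    def test_cohort_scope_pools_durations(self, grid):
        config = sg.CleaningConfig(z_scope="cohort")
        trials = sg.simulate_trials(
            dataclasses.replace(sg.calibrate_defaults(), n_subjects=4), seed=4)
        out = preprocess.clean_cohort(trials, grid, config)
        assert len(out) == len(trials)
        pooled = [f.duration for t in trials
                  for f in sg.clean(t, grid, sg.CleaningConfig(z_max=1e9)).fixations]
        mean, sd = np.mean(pooled), np.std(pooled, ddof=1)
        for t in out:
            for f in t.fixations:
                assert (f.duration - mean) / sd < 3.0
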