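import math

import numpy as np
import pytest

import stroopgaze as sg
from stroopgaze import features
from stroopgaze.records import ValidationError

from conftest import make_fixation, make_saccade, make_trial
from oracles import oracle_fixation_features, oracle_regressions, oracle_saccade_features


def test_schema_is_seven_plus_twentytwo():
    assert len(sg.FEATURE_NAMES) == 29
    assert len(sg.FIXATION_FEATURES) == 7
    assert len(sg.SACCADE_FEATURES) == 22
    assert set(sg.FIXATION_FEATURES) | set(sg.SACCADE_FEATURES) == set(sg.FEATURE_NAMES)


class TestFixationFeatures:
    def test_arithmetic(self, grid):
        trial = sg.clean(make_trial([200.0, 300.0, 400.0]), grid,
                         sg.CleaningConfig(tail_fixations_dropped=0))
        out = features.fixation_features(trial, grid)
        assert out["n_fix"] == 3
        assert out["fix_mean"] == pytest.approx(300.0)
        assert out["fix_max"] == pytest.approx(400.0)
        span = trial.fixations[-1].t_end - trial.fixations[0].t_start
        assert out["norm_fix_mean"] == pytest.approx(300.0 / span)
        assert out["norm_fix_max"] == pytest.approx(400.0 / span)

    def test_single_fixation(self, grid):
        trial = sg.clean(make_trial([250.0]), grid,
                         sg.CleaningConfig(tail_fixations_dropped=0))
        out = features.fixation_features(trial, grid)
        assert out["fix_mean"] == out["fix_max"]
        assert out["x_regressions"] == 0 and out["y_regressions"] == 0

    def test_empty_trial_flags_nan(self, grid, trial_factory):
        trial = trial_factory([100.0]).with_events(fixations=[], saccades=[])
        out = features.fixation_features(trial, grid)
        assert out["n_fix"] == 0
        assert all(math.isnan(out[k]) for k in sg.FIXATION_FEATURES[1:])


class TestCountRegressions:
    def _seq(self, grid, coords):
        fixs = []
        for i, (x, y) in enumerate(coords):
            f = make_fixation(i=i, t=300.0 * i, x=x, y=y)
            fixs.append(make_fixation(i=i, t=300.0 * i, x=x, y=y,
                                      aoi=sg.assign_aoi(f, grid)))
        return fixs

    def test_same_row_leftward_step(self, grid):
        fixs = self._seq(grid, [(100, 90), (300, 90), (250, 90), (500, 90)])
        assert features.count_regressions(fixs, grid) == (1, 0)

    def test_line_change_not_a_horizontal_regression(self, grid):
        fixs = self._seq(grid, [(900, 90), (100, 290)])
        x_reg, _ = features.count_regressions(fixs, grid)
        assert x_reg == 0

    def test_upward_step_counts_vertically(self, grid):
        fixs = self._seq(grid, [(100, 290), (300, 90)])
        assert features.count_regressions(fixs, grid) == (0, 1)

    def test_fewer_than_two_fixations(self, grid):
        assert features.count_regressions([], grid) == (0, 0)

    def test_random_walks_match_oracle(self, grid, rng):
        for _ in range(100):
            n = int(rng.integers(2, 40))
            coords = list(zip(rng.uniform(0, 1023, n), rng.uniform(0, 767, n)))
            fixs = self._seq(grid, coords)
            assert features.count_regressions(fixs, grid) == oracle_regressions(fixs, grid)

    def test_missing_aoi_is_an_error(self, grid):
        fixs = [make_fixation(i=0, x=10, y=10, aoi=None),
                make_fixation(i=1, x=20, y=10, aoi=None)]
        with pytest.raises(ValidationError, match="aoi"):
            features.count_regressions(fixs, grid)


class TestClassifyDirection:
    @pytest.mark.parametrize("delta,expected", [
        ((10, 3), "right"),
        ((3, -10), "up"),
        ((5, 5), "right"),  # tie goes to the horizontal axis
        ((-5, 5), "left"),
        ((-3, 10), "down"),
        ((0, -8), "up"),
        ((0, 0), None),
    ])
    def test_dominant_axis_rule(self, delta, expected):
        s = make_saccade(x0=100, y0=100, x1=100 + delta[0], y1=100 + delta[1])
        assert features.classify_direction(s) == expected


class TestSaccadeFeatures:
    def test_one_saccade_per_sector(self, geometry):
        deltas = [(10, 0), (-5, 0), (0, 8), (0, -3)]
        saccades = [make_saccade(i=i, t=100.0 * i, x0=500, y0=380,
                                 x1=500 + dx, y1=380 + dy)
                    for i, (dx, dy) in enumerate(deltas)]
        trial = make_trial([250.0]).with_events(saccades=saccades)
        out = features.saccade_features(trial, geometry)
        for d in ("up", "down", "left", "right"):
            assert out[f"{d}_freq"] == pytest.approx(0.25)

    def test_single_saccade_collapses_triples(self, geometry):
        trial = make_trial([250.0, 250.0])
        out = features.saccade_features(trial, geometry)
        for stat in ("duration", "vel", "ampl", "angle", "distance", "slope"):
            assert out[f"min_{stat}"] == out[f"avg_{stat}"] == out[f"max_{stat}"]

    def test_no_saccades_is_all_nan(self, geometry):
        trial = make_trial([250.0])
        out = features.saccade_features(trial, geometry)
        assert all(math.isnan(v) for v in out.values())

    def test_vertical_saccade_slope_sentinel(self, geometry):
        saccades = [make_saccade(x0=100, y0=100, x1=100, y1=300),
                    make_saccade(i=1, t=200, x0=100, y0=300, x1=100, y1=100)]
        trial = make_trial([250.0]).with_events(saccades=saccades)
        out = features.saccade_features(trial, geometry)
        assert out["max_slope"] == features.VERTICAL_SLOPE_SENTINEL
        assert out["min_slope"] == -features.VERTICAL_SLOPE_SENTINEL


class TestOracleEquivalence:
    def test_all_29_features_match_bruteforce(self, grid, geometry, random_clean_trials):
        assert len(random_clean_trials) == 100
        for trial in random_clean_trials:
            if not trial.fixations or not trial.saccades:
                continue
            got = features.trial_features(trial, grid, geometry)
            want = {**oracle_fixation_features(trial, grid),
                    **oracle_saccade_features(trial, geometry)}
            for name in sg.FEATURE_NAMES:
                assert got[name] == pytest.approx(want[name], rel=1e-12), name


class TestExtractTable:
    def test_cohort_shape_and_invariants(self, effect_table):
        assert list(effect_table.columns) == ["subject", "condition", *sg.FEATURE_NAMES]
        assert len(effect_table) == 32 * 4
        freqs = effect_table[["up_freq", "down_freq", "left_freq", "right_freq"]].sum(axis=1)
        assert np.allclose(freqs, 1.0, atol=1e-12)
        for stat in ("duration", "vel", "ampl", "angle", "distance", "slope"):
            assert (effect_table[f"min_{stat}"] <= effect_table[f"avg_{stat}"] + 1e-12).all()
            assert (effect_table[f"avg_{stat}"] <= effect_table[f"max_{stat}"] + 1e-12).all()

    def test_order_invariance(self, grid, geometry, random_clean_trials):
        fwd = sg.extract_table(random_clean_trials, grid, geometry)
        rev = sg.extract_table(random_clean_trials[::-1], grid, geometry)
        rev_sorted = rev.sort_values(["subject", "condition"]).reset_index(drop=True)
        fwd_sorted = fwd.sort_values(["subject", "condition"]).reset_index(drop=True)
        assert fwd_sorted.equals(rev_sorted)

    def test_empty_input_keeps_schema(self, grid, geometry):
        table = sg.extract_table([], grid, geometry)
        assert len(table) == 0
        assert list(table.columns) == ["subject", "condition", *sg.FEATURE_NAMES]

    def test_duplicate_subject_condition_errors(self, grid, geometry, random_clean_trials):
        with pytest.raises(ValidationError, match="duplicate"):
            sg.extract_table([random_clean_trials[0], random_clean_trials[0]],
                             grid, geometry)
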