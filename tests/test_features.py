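"""Feature extraction: MAP, peaks, AUCi, recovery, responder rule, KNN."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tsst_resilience.features import (
    PhysioTrajectory,
    auc_increase,
    classify_responder,
    knn_impute,
    mean_arterial_pressure,
    peak_value,
    recovery_value,
)

CORT_LABELS = ("T1", "T2", "T3", "T4", "T5", "T6")


def _cortisol_traj(values, times=(0, 20, 40, 60, 80, 100)):
    return PhysioTrajectory("p1", "cortisol", np.asarray(times, float), values, CORT_LABELS)


class TestMeanArterialPressure:
    @pytest.mark.parametrize(
        "sbp,dbp,expected",
        [(120, 80, 93.3333333333), (150, 90, 110.0), (100, 100, 100.0)],
    )
    def test_formula(self, sbp, dbp, expected):
        assert mean_arterial_pressure(sbp, dbp) == pytest.approx(expected, abs=1e-9)

    def test_lies_between_dbp_and_sbp(self, rng):
        dbp = rng.uniform(50, 100, 200)
        sbp = dbp + rng.uniform(0, 80, 200)
        m = mean_arterial_pressure(sbp, dbp)
        assert np.all(m >= dbp) and np.all(m <= sbp)

    def test_rejects_inverted_reading(self):
        with pytest.raises(ValueError):
            mean_arterial_pressure(80, 120)


class TestAucIncrease:
    @pytest.mark.parametrize(
        "times,values,expected",
        [
            ([0, 10, 20], [1, 3, 1], 20.0),
            ([0, 10, 20], [2, 1, 1], -15.0),
            ([0, 10, 20, 30], [5, 5, 5, 5], 0.0),
        ],
    )
    def test_hand_examples(self, times, values, expected):
        assert auc_increase(times, values) == pytest.approx(expected, abs=1e-12)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            auc_increase([0], [1])
        with pytest.raises(ValueError):
            auc_increase([0, 0, 10], [1, 2, 3])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        shift=st.floats(-50, 50),
        scale=st.floats(0.1, 10),
        seed=st.integers(0, 10_000),
    )
    def test_shift_invariance_and_time_scaling(self, shift, scale, seed):
        """AUCi ignores constant shifts and scales linearly with time units."""
        r = np.random.default_rng(seed)
        t = np.sort(r.uniform(0, 100, 6))
        t += np.arange(6) * 1e-6  # ensure strictly increasing
        v = r.uniform(0.1, 10, 6)
        base = auc_increase(t, v)
        assert auc_increase(t, v + shift) == pytest.approx(base, abs=1e-8 * (1 + abs(base)))
        assert auc_increase(t * scale, v) == pytest.approx(scale * base, rel=1e-9)

    def test_matches_fine_grid_integral(self, rng):
        """Trapezoid minus baseline rectangle == integral of interpolant."""
        for _ in range(50):
            t = np.sort(rng.uniform(0, 100, 7))
            t += np.arange(7) * 1e-4
            v = rng.uniform(0.1, 20, 7)
            grid = np.union1d(np.linspace(t[0], t[-1], 10_001), t)
            interp = np.interp(grid, t, v)
            oracle = np.trapezoid(interp - v[0], grid)
            assert auc_increase(t, v) == pytest.approx(oracle, abs=1e-9 * (1 + abs(oracle)))


class TestPeakAndRecovery:
    def test_table_mean_series_peak(self):
        traj = _cortisol_traj([1.38, 2.49, 3.16, 2.03, 1.46, 1.16])
        value, time = peak_value(traj, CORT_LABELS)
        assert value == pytest.approx(3.16)
        assert time == 40.0  # the sample 20 min post-stressor

    def test_tie_breaks_to_earliest(self):
        traj = _cortisol_traj([2.0, 2.0, 2.0, 2.0, 2.0, 2.0])
        value, time = peak_value(traj, CORT_LABELS)
        assert (value, time) == (2.0, 0.0)

    def test_map_window_excludes_baseline(self):
        traj = PhysioTrajectory(
            "p1",
            "MAP",
            [0, 5, 10, 15, 50],
            [120.0, 100.0, 110.0, 105.0, 90.0],
            ("baseline", "preparation", "speech", "calculation", "recovery"),
        )
        value, _ = peak_value(traj, ("preparation", "speech", "calculation"))
        assert value == 110.0  # baseline 120 not eligible

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            peak_value(_cortisol_traj([1, 2, 3, 2, 1, 1]), ())

    def test_recovery_values(self):
        assert recovery_value(_cortisol_traj([1.38, 2.49, 3.16, 2.03, 1.46, 1.16])) == 1.16
        hr = PhysioTrajectory(
            "p1",
            "HR",
            [0, 5, 10, 15, 50],
            [67.75, 78.72, 92.62, 85.99, 67.41],
            ("baseline", "preparation", "speech", "calculation", "recovery"),
        )
        assert recovery_value(hr) == 67.41


class TestResponderRule:
    @pytest.mark.parametrize(
        "baseline,peak,expected",
        [
            (1.38, 3.61, True),  # clear responder (rise ~162 %)
            (1.0, 1.0, False),  # zero rise
            (2.0, 2.31, True),  # exactly 15.5 %: strict-< reads as responder
            (1.0, 1.154, False),  # just below threshold
        ],
    )
    def test_rule(self, baseline, peak, expected):
        assert classify_responder(baseline, peak) is expected

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        baseline=st.floats(0.05, 20),
        rel=st.floats(0.0, 3.0),
        c=st.floats(0.01, 100),
    )
    def test_scale_invariance(self, baseline, rel, c):
        peak = baseline * (1.0 + rel)
        assert classify_responder(baseline, peak) == classify_responder(
            c * baseline, c * peak
        )

    def test_rejects_nonpositive_baseline(self):
        with pytest.raises(ValueError):
            classify_responder(0.0, 1.0)


class TestKnnImpute:
    def test_identity_without_missingness(self, rng):
        df = pd.DataFrame(rng.normal(size=(20, 4)))
        out = knn_impute(df, k=3)
        pd.testing.assert_frame_equal(out, df)

    def test_k_all_rows_gives_column_mean(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 3)))
        df.iloc[0, 1] = np.nan
        out = knn_impute(df, k=29)
        expected = df.iloc[1:, 1].mean()
        assert out.iloc[0, 1] == pytest.approx(expected)

    def test_observed_cells_never_altered(self, rng):
        df = pd.DataFrame(rng.normal(size=(40, 5)))
        mask = rng.random(df.shape) < 0.02
        dirty = df.mask(mask)
        out = knn_impute(dirty, k=5)
        observed = ~mask
        assert np.allclose(out.to_numpy()[observed], df.to_numpy()[observed])
        assert not out.isna().any().any()

    def test_beats_mean_imputation_on_correlated_data(self, rng):
        """KNN exploits row similarity that column means ignore."""
        wins = 0
        for rep in range(30):
            r = np.random.default_rng(rep)
            latent = r.normal(size=(80, 1))
            truth = latent + 0.3 * r.normal(size=(80, 6))
            mask = r.random(truth.shape) < 0.01
            if not mask.any():
                continue
            dirty = pd.DataFrame(truth).mask(mask)
            knn = knn_impute(dirty, k=5).to_numpy()
            mean_fill = dirty.fillna(dirty.mean()).to_numpy()
            err_knn = np.sqrt(np.mean((knn[mask] - truth[mask]) ** 2))
            err_mean = np.sqrt(np.mean((mean_fill[mask] - truth[mask]) ** 2))
            wins += err_knn < err_mean
        assert wins >= 24  # KNN clearly better on most replicates

    def test_rejects_all_missing_row(self):
        df = pd.DataFrame(np.ones((30, 2)) + np.arange(30)[:, None])
        df.iloc[0] = np.nan
        with pytest.raises(ValueError):
            knn_impute(df)


class TestTrajectoryValidation:
    def test_rejects_nonpositive_cortisol(self):
        with pytest.raises(ValueError):
            _cortisol_traj([1.0, -0.5, 1.0, 1.0, 1.0, 1.0])

    def test_rejects_unsorted_times(self):
        with pytest.raises(ValueError):
            PhysioTrajectory("p", "HR", [0, 0, 10], [60, 61, 62], ("a", "b", "c"))
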