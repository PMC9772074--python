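"""Cleaning-chain behaviour: FD, censoring, regression, filtering, networks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from loadmapper.preprocess import (
    NETWORKS,
    CensorMask,
    ParcelTimeSeries,
    aggregate_networks,
    build_censor_mask,
    clean_timeseries,
    compute_fd,
)


def _ts(data, nets=None, tr=2.0, boundaries=None):
    n, p = data.shape
    ids = [f"p{i}" for i in range(p)]
    if nets is None:
        nets = {pid: NETWORKS[i % len(NETWORKS)] for i, pid in enumerate(ids)}
    return ParcelTimeSeries(data=data, tr_seconds=tr,
                            run_boundaries=boundaries or [0, n],
                            parcel_ids=ids, parcel_to_network=nets)


class TestFramewiseDisplacement:
    def test_constant_parameters_give_zero(self):
        fd = compute_fd(np.ones((10, 6)))
        np.testing.assert_array_equal(fd, np.zeros(10))

    def test_translation_step(self):
        m = np.zeros((5, 6))
        m[2:, 0] = 0.1  # 0.1 mm step in x at frame 2
        fd = compute_fd(m)
        np.testing.assert_allclose(fd, [0, 0, 0.1, 0, 0])

    def test_rotation_step_uses_50mm_radius(self):
        m = np.zeros((4, 6))
        m[1:, 4] = 0.002  # radians
        fd = compute_fd(m)
        np.testing.assert_allclose(fd, [0, 0.1, 0, 0])

    def test_rejects_bad_shapes_and_values(self):
        with pytest.raises(ValueError):
            compute_fd(np.zeros((5, 5)))
        with pytest.raises(ValueError):
            compute_fd(np.full((5, 6), np.nan))


class TestCensorMask:
    def test_hand_worked_example(self):
        fd = np.array([0, 0.1, 0.25, 0.1, 0.1])
        mask = build_censor_mask(fd, [0, 5], threshold=0.2, back=1, forward=2)
        assert set(np.nonzero(mask.flags)[0]) == {1, 2, 3, 4}

    def test_all_below_threshold_is_empty(self):
        mask = build_censor_mask(np.full(10, 0.05), [0, 10])
        assert mask.n_censored == 0

    def test_spike_at_frame_zero_clips_backward(self):
        fd = np.array([0.3, 0.0, 0.0, 0.0, 0.0])
        mask = build_censor_mask(fd, [0, 5])
        assert set(np.nonzero(mask.flags)[0]) == {0, 1, 2}

    def test_dilation_respects_run_boundary(self):
        fd = np.zeros(10)
        fd[4] = 0.5  # last frame of run 0
        mask = build_censor_mask(fd, [0, 5, 10], back=1, forward=2)
        assert set(np.nonzero(mask.flags)[0]) == {3, 4}  # no leak into run 1

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            build_censor_mask(np.zeros(5), [0, 5], threshold=-0.1)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(0, 0.5), min_size=8, max_size=40), st.integers(0, 3),
           st.integers(0, 3))
    def test_dilation_idempotent(self, fd, back, forward):
        """Re-dilating an already dilated mask with back=forward=0 is a no-op."""
        fd = np.array(fd)
        mask = build_censor_mask(fd, [0, len(fd)], threshold=0.2, back=back,
                                 forward=forward)
        fake_fd = np.where(mask.flags, 1.0, 0.0)
        again = build_censor_mask(fake_fd, [0, len(fd)], threshold=0.5, back=0,
                                  forward=0)
        np.testing.assert_array_equal(mask.flags, again.flags)


class TestCleanTimeseries:
    def _motion(self, n, seed=0):
        return np.random.default_rng(seed).normal(0, 0.001, (n, 6))

    def test_pure_linear_trend_removed(self):
        n = 120
        trend = np.linspace(0, 5, n)[:, None] * np.ones((1, 3))
        ts = _ts(trend + 10.0)
        mask = CensorMask(np.zeros(n, bool), 0.2, 1, 2)
        clean = clean_timeseries(ts, [np.zeros((n, 6))], mask)
        assert np.abs(clean.data).max() < 1e-8

    def test_motion_regressor_column_removed(self):
        n = 120
        motion = self._motion(n, seed=3)
        data = np.column_stack([motion[:, 0], motion[:, 5]]) * 50 + 7
        ts = _ts(data)
        mask = CensorMask(np.zeros(n, bool), 0.2, 1, 2)
        clean = clean_timeseries(ts, [motion], mask)
        assert np.abs(clean.data).max() < 1e-8

    def test_bandpass_attenuates_stopband_by_20db(self):
        n, tr = 400, 2.0
        t = np.arange(n) * tr
        fast = np.sin(2 * np.pi * 0.15 * t)[:, None]
        slow = np.sin(2 * np.pi * 0.03 * t)[:, None]
        mask = CensorMask(np.zeros(n, bool), 0.2, 1, 2)
        motion = [np.zeros((n, 6))]
        out_fast = clean_timeseries(_ts(fast, {"p0": "Vis"}), motion, mask).data
        out_slow = clean_timeseries(_ts(slow, {"p0": "Vis"}), motion, mask).data
        # compare passband vs stopband power (dB) on the interior to avoid edges
        sl = slice(50, -50)
        ratio = 10 * np.log10(np.mean(out_slow[sl] ** 2) / np.mean(out_fast[sl] ** 2))
        assert ratio >= 20

    def test_output_frame_count_and_label_carry_through(self):
        n = 100
        rng = np.random.default_rng(8)
        ts = _ts(rng.normal(size=(n, 3)))
        fd = np.zeros(n)
        fd[[20, 60]] = 1.0
        mask = build_censor_mask(fd, [0, n])
        labels = pd.DataFrame({
            "frame": np.arange(n), "run": 0, "block": -1,
            "load": "none", "anxiety": "none", "phase": "fixation",
        })
        labels.loc[40:, "phase"] = "letters"
        clean = clean_timeseries(ts, [self._motion(n)], mask, labels=labels)
        assert clean.n_frames == n - mask.n_censored
        # retained labels match the original timeline at the retained indices
        pd.testing.assert_frame_equal(
            clean.retained_labels,
            labels.iloc[clean.retained_indices].reset_index(drop=True))

    def test_linearity(self):
        n = 150
        rng = np.random.default_rng(4)
        X = rng.normal(size=(n, 4))
        Y = rng.normal(size=(n, 4))
        motion = [self._motion(n, seed=5)]
        fd = np.zeros(n)
        fd[30] = 1.0
        mask = build_censor_mask(fd, [0, n])
        a, b = 1.7, -0.4
        out_comb = clean_timeseries(_ts(a * X + b * Y), motion, mask).data
        out_x = clean_timeseries(_ts(X), motion, mask).data
        out_y = clean_timeseries(_ts(Y), motion, mask).data
        np.testing.assert_allclose(out_comb, a * out_x + b * out_y, atol=1e-9)

    def test_fully_censored_run_raises(self):
        n = 50
        ts = _ts(np.zeros((n, 2)))
        mask = CensorMask(np.ones(n, bool), 0.2, 1, 2)
        with pytest.raises(ValueError, match="retained"):
            clean_timeseries(ts, [np.zeros((n, 6))], mask)

    def test_band_outside_nyquist_rejected(self):
        n = 50
        ts = _ts(np.zeros((n, 2)))
        mask = CensorMask(np.zeros(n, bool), 0.2, 1, 2)
        with pytest.raises(ValueError, match="band"):
            clean_timeseries(ts, [np.zeros((n, 6))], mask, band=(0.009, 0.3))


class TestAggregateNetworks:
    def _clean(self, data, nets):
        from loadmapper.preprocess import CleanSeries

        ids = [f"p{i}" for i in range(data.shape[1])]
        return CleanSeries(data=data, retained_indices=np.arange(len(data)),
                           tr_seconds=2.0, run_boundaries=[0, len(data)],
                           parcel_ids=ids,
                           parcel_to_network=dict(zip(ids, nets)))

    def test_constant_network_passthrough_and_identity(self):
        data = np.column_stack([np.full(10, 3.0), np.full(10, 3.0), np.arange(10.0)])
        nets = ["Vis", "Vis", "Cont"]
        out = aggregate_networks(self._clean(data, nets), networks=("Vis", "Cont"))
        np.testing.assert_allclose(out["Vis"], 3.0)  # constant parcels
        np.testing.assert_allclose(out["Cont"], np.arange(10.0))  # singleton net

    def test_matches_brute_force_groupby(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(40, 21))
        nets = [NETWORKS[i % 7] for i in range(21)]
        out = aggregate_networks(self._clean(data, nets))
        expected = pd.DataFrame(data).T.groupby(np.array(nets)).mean().T
        for net in NETWORKS:
            np.testing.assert_allclose(out[net], expected[net])

    def test_unmapped_parcel_rejected(self):
        clean = self._clean(np.zeros((5, 2)), ["Vis", "Nope"])
        with pytest.raises(ValueError):
            aggregate_networks(clean)
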