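"""Track cleaning: likelihood cut, Hampel outliers, spline refill, smoothing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from videba.errors import ValidationError
from videba.trajectory_qc import (
    filter_by_likelihood,
    hampel_flag,
    qc_pipeline,
    running_mean,
    spline_interpolate,
)
from videba.types import EDGE_DROPPED, INTERPOLATED, KEPT, LIKELIHOOD_REMOVED, CleanTrack, QCParams

from conftest import make_pose


def brute_force_hampel(x, window, k):
    """Independent per-index recomputation of the Hampel rule.

    Mirrors the documented semantics: NaNs ignored inside windows, strict
    inequality, and no flagging within half a window of the series edges.
    """
    x = np.asarray(x, float)
    n = len(x)
    half = window // 2
    out = np.zeros(n, dtype=bool)
    for i in range(half, n - half):
        if not np.isfinite(x[i]):
            continue
        w = x[max(0, i - half): i + half + 1]
        w = w[np.isfinite(w)]
        out[i] = abs(x[i] - np.median(w)) > k * np.std(w)
    return out


class TestLikelihoodFilter:
    def test_below_threshold_removed(self):
        pose = make_pose([10, 11, 12], [20, 21, 22], [0.99, 0.95, 0.40])
        track = filter_by_likelihood(pose, "eye", 0.6)
        assert list(track.flags) == [KEPT, KEPT, LIKELIHOOD_REMOVED]
        assert np.isnan(track.u[2]) and np.isfinite(track.u[:2]).all()

    def test_threshold_zero_keeps_everything(self):
        pose = make_pose([1, 2, 3], [1, 2, 3], [0.0, 0.5, 1.0])
        assert (filter_by_likelihood(pose, "eye", 0.0).flags == KEPT).all()

    def test_threshold_one_removes_all_below_one(self):
        pose = make_pose([1, 2, 3], [1, 2, 3], [0.2, 0.999, 1.0])
        flags = filter_by_likelihood(pose, "eye", 1.0).flags
        assert list(flags) == [LIKELIHOOD_REMOVED, LIKELIHOOD_REMOVED, KEPT]


class TestHampel:
    def test_single_spike_on_constant_flagged_exactly(self):
        x = np.zeros(200)
        x[50] = 100.0
        assert set(np.flatnonzero(hampel_flag(x, 29, 1.0))) == {50}

    def test_constant_series_flags_nothing(self):
        assert not hampel_flag(np.full(100, 3.14), 29, 1.0).any()

    def test_window_larger_than_series_rejected(self):
        with pytest.raises(ValidationError):
            hampel_flag(np.zeros(10), 29, 1.0)

    def test_spike_recall_on_noisy_sinusoid(self, rng):
        # slow station-holding drift: within a 29-sample window the signal is
        # nearly flat, so the window s.d. is noise-dominated and 10-sigma
        # spikes stand out
        n = 5000
        sigma = 0.5
        t = np.arange(n) / 90.0
        x = 5 * np.sin(2 * np.pi * 0.05 * t) + rng.normal(0, sigma, n)
        spikes = rng.choice(n, 20, replace=False)
        x[spikes] += 10 * sigma * rng.choice([-1, 1], 20)
        flags = hampel_flag(x, 29, 1.0)
        assert np.mean(flags[spikes]) >= 0.95
        assert np.array_equal(flags, brute_force_hampel(x, 29, 1.0))

    @settings(deadline=None, max_examples=50)
    @given(
        data=st.lists(st.floats(-1e3, 1e3) | st.just(np.nan), min_size=5, max_size=200),
        window=st.sampled_from([5, 9, 29]).filter(lambda w: True),
        k=st.floats(0.5, 3.0),
    )
    def test_matches_bruteforce_oracle(self, data, window, k):
        x = np.asarray(data)
        if window > len(x):
            window = 5
        if window > len(x):
            return
        assert np.array_equal(hampel_flag(x, window, k), brute_force_hampel(x, window, k))


class TestSpline:
    def test_exact_on_cubic(self):
        t = np.arange(10, dtype=float)
        u = t**3
        flags = np.full(10, KEPT, dtype=np.uint8)
        u_g = u.copy()
        u_g[4:6] = np.nan
        flags[4:6] = LIKELIHOOD_REMOVED
        track = CleanTrack(u=u_g, v=u_g.copy(), flags=flags)
        filled = spline_interpolate(track)
        assert np.allclose(filled.u[4:6], [64.0, 125.0], atol=1e-9)
        assert list(filled.flags[4:6]) == [INTERPOLATED, INTERPOLATED]

    def test_identity_without_gaps(self):
        u = np.linspace(0, 1, 20)
        track = CleanTrack(u=u.copy(), v=u.copy(), flags=np.full(20, KEPT, np.uint8))
        out = spline_interpolate(track)
        assert np.array_equal(out.u, u) and (out.flags == KEPT).all()

    def test_leading_gap_becomes_edge_dropped(self):
        u = np.arange(10, dtype=float)
        u[:2] = np.nan
        flags = np.full(10, KEPT, np.uint8)
        flags[:2] = LIKELIHOOD_REMOVED
        out = spline_interpolate(CleanTrack(u=u, v=u.copy(), flags=flags))
        assert list(out.flags[:2]) == [EDGE_DROPPED, EDGE_DROPPED]
        assert np.isnan(out.u[:2]).all()

    def test_random_deletions_on_smooth_track_refill_below_half_pixel(self, rng):
        t = np.arange(900) / 90.0
        u = 960 + 40 * np.sin(2 * np.pi * 1.5 * t) + 10 * np.sin(2 * np.pi * 0.3 * t)
        truth = u.copy()
        kill = rng.choice(np.arange(5, 895), 90, replace=False)
        u_g = u.copy()
        u_g[kill] = np.nan
        flags = np.full(900, KEPT, np.uint8)
        flags[kill] = LIKELIHOOD_REMOVED
        out = spline_interpolate(CleanTrack(u=u_g, v=u_g.copy(), flags=flags))
        assert np.max(np.abs(out.u[kill] - truth[kill])) < 0.5

    def test_too_few_valid_samples_rejected(self):
        u = np.full(10, np.nan)
        u[:3] = 1.0
        with pytest.raises(ValidationError):
            spline_interpolate(CleanTrack(u=u, v=u.copy(), flags=np.full(10, KEPT, np.uint8)))


class TestRunningMean:
    def test_constant_unchanged(self):
        u = np.full(50, 7.0)
        out = running_mean(CleanTrack(u=u.copy(), v=u.copy(), flags=np.full(50, KEPT, np.uint8)), 5)
        assert np.allclose(out.u, 7.0)

    def test_centre_of_isolated_pulse(self):
        u = np.array([0.0, 0, 5, 0, 0])
        out = running_mean(CleanTrack(u=u.copy(), v=u.copy(), flags=np.full(5, KEPT, np.uint8)), 5)
        assert out.u[2] == pytest.approx(1.0)

    def test_linear_ramp_unchanged_away_from_edges(self):
        u = np.arange(30, dtype=float)
        out = running_mean(CleanTrack(u=u.copy(), v=u.copy(), flags=np.full(30, KEPT, np.uint8)), 5)
        assert np.allclose(out.u[2:-2], u[2:-2])


class TestPipeline:
    def test_clean_track_passes_through_as_smoothed(self):
        t = np.arange(300) / 90.0
        u = 960 + 30 * np.sin(2 * np.pi * 1.0 * t)
        v = 540 + 20 * np.cos(2 * np.pi * 1.0 * t)
        pose = make_pose(u, v, np.full(300, 0.99))
        clean, report = qc_pipeline(pose, QCParams())
        trk = clean["eye"]
        smoothed = running_mean(CleanTrack(u=u.copy(), v=v.copy(), flags=np.full(300, KEPT, np.uint8)), 5)
        assert np.allclose(trk.u, smoothed.u, atol=1e-9)
        assert report["points"]["eye"]["likelihood_removed"] == 0

    def test_dropouts_and_spikes_get_non_kept_flags(self, rng):
        n = 2000
        t = np.arange(n) / 90.0
        u = 960 + 30 * np.sin(2 * np.pi * 1.2 * t)
        v = 540 + 20 * np.sin(2 * np.pi * 0.8 * t)
        lik = np.full(n, 0.98)
        drop = rng.choice(np.arange(50, n - 50), 100, replace=False)
        lik[drop] = 0.1
        spikes = rng.choice(np.setdiff1d(np.arange(50, n - 50), drop), 20, replace=False)
        u2, v2 = u.copy(), v.copy()
        u2[spikes] += 40.0
        pose = make_pose(u2, v2, lik)
        clean, _ = qc_pipeline(pose, QCParams())
        trk = clean["eye"]
        assert (trk.flags[drop] != KEPT).all()
        assert np.mean(trk.flags[spikes] != KEPT) >= 0.95

    def test_flag_counts_conserved(self, rng):
        n = 500
        u = 960 + rng.normal(0, 1, n).cumsum() * 0.01
        lik = np.where(rng.random(n) < 0.05, 0.2, 0.99)
        pose = make_pose(u, u.copy(), lik)
        clean, report = qc_pipeline(pose, QCParams())
        counts = report["points"]["eye"]["final_flags"]
        assert sum(counts.values()) == n == len(clean["eye"])
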