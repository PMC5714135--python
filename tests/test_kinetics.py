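"""Time-courses, decay fitting, cluster radius series."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import recascan as rs
from recascan.classification import StateCounts
from recascan.kinetics import (
    cluster_series,
    dispersion_ratio,
    fit_decay,
    radius_of_gyration,
    timecourse,
)

from conftest import SUITE_SEED


def _counts(t, n, n_any, n_post):
    return StateCounts(
        timepoint_s=t,
        n_total_included=n,
        n_bare=n - n_any,
        n_with_synaptic=n_any - n_post,
        n_post_singular=n_post,
    )


class TestTimecourse:
    def test_wilson_interval_at_92_pct_of_1000(self):
        tc = timecourse([_counts(600.0, 1000, 920, 44)])
        p = next(x for x in tc.points if x.category == "any_joint")
        assert p.fraction == pytest.approx(0.92)
        half = (p.ci_high - p.ci_low) / 2
        assert half == pytest.approx(0.009, abs=0.002)  # the "+-1%" regime

    def test_wilson_interval_at_55_pct_of_130(self):
        tc = timecourse([_counts(1200.0, 130, 72, 5)])
        p = next(x for x in tc.points if x.category == "any_joint")
        assert p.fraction == pytest.approx(72 / 130)
        half = (p.ci_high - p.ci_low) / 2
        assert half == pytest.approx(0.044, abs=0.006)  # the "+-4%" regime

    def test_zero_successes(self):
        tc = timecourse([_counts(0.0, 100, 0, 0)])
        p = next(x for x in tc.points if x.category == "any_joint")
        assert p.fraction == 0.0
        assert p.ci_low == 0.0

    def test_intervals_shrink_like_sqrt_n(self):
        halves = []
        for n in (100, 400, 1600):
            tc = timecourse([_counts(0.0, n, n // 2, 0)])
            p = next(x for x in tc.points if x.category == "any_joint")
            halves.append((p.ci_high - p.ci_low) / 2)
        assert halves[0] / halves[1] == pytest.approx(2.0, rel=0.05)
        assert halves[1] / halves[2] == pytest.approx(2.0, rel=0.05)

    def test_wilson_68_coverage_at_half(self):
        """68% intervals cover p=0.5 about 68% of the time at n=1000."""
        rng = np.random.default_rng(SUITE_SEED)
        n, p_true, reps = 1000, 0.5, 1500
        covered = 0
        for k in rng.binomial(n, p_true, size=reps):
            tc = timecourse([_counts(0.0, n, int(k), 0)])
            pt = next(x for x in tc.points if x.category == "any_joint")
            covered += pt.ci_low <= p_true <= pt.ci_high
        assert 0.62 <= covered / reps <= 0.74

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            timecourse([])


class TestFitDecay:
    def test_noiseless_exponential_exact(self):
        t = np.linspace(0, 500, 10)
        fit = fit_decay(t, np.exp(-t / 100.0), seed=0)
        assert fit.tau_s == pytest.approx(100.0, abs=1e-4)
        assert fit.amplitude == pytest.approx(1.0, abs=1e-6)

    def test_offset_variant(self):
        t = np.linspace(0, 2000, 12)
        y = 0.5 * np.exp(-t / 400.0) + 0.43
        fit = fit_decay(t, y, with_offset=True, seed=1)
        assert fit.tau_s == pytest.approx(400.0, rel=1e-3)
        assert fit.offset == pytest.approx(0.43, abs=1e-3)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        scale=st.floats(min_value=0.01, max_value=100.0),
        shift=st.floats(min_value=0.0, max_value=5000.0),
    )
    def test_scale_and_shift_equivariance(self, scale, shift):
        """Scaling values scales the amplitude only; shifting times leaves
        tau unchanged (offset-free model)."""
        t = np.linspace(0, 600, 8)
        y = np.exp(-t / 150.0)
        base = fit_decay(t, y, seed=2)
        scaled = fit_decay(t, scale * y, seed=2)
        shifted = fit_decay(t + shift, y, seed=2)
        assert scaled.tau_s == pytest.approx(base.tau_s, rel=1e-4)
        assert scaled.amplitude == pytest.approx(
            scale * base.amplitude, rel=1e-4
        )
        assert shifted.tau_s == pytest.approx(base.tau_s, rel=1e-3)

    def test_binomial_noise_recovery_sweep(self):
        """Simulate-and-refit: binomial sampling noise at n=1000, taus from
        60 to 1200 s; median absolute relative error <= 5%."""
        rng = np.random.default_rng(SUITE_SEED)
        n = 1000
        errors = []
        for tau in (60.0, 300.0, 600.0, 1200.0):
            times = np.linspace(tau / 4, 3 * tau, 6)
            for _ in range(5):
                y = rng.binomial(n, np.exp(-times / tau)) / n
                fit = fit_decay(times, y, seed=3)
                errors.append(abs(fit.tau_s - tau) / tau)
        assert float(np.median(errors)) <= 0.05

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_decay([0.0, 1.0], [1.0, 0.5], seed=0)


class TestClusterSeries:
    def test_square_corner_radius(self):
        a = 10.0
        pts = np.array([[0, 0], [a, 0], [0, a], [a, a]], dtype=float)
        assert radius_of_gyration(pts) == pytest.approx(a / math.sqrt(2))

    def test_mass_weighting_recovers_merged_points(self):
        pts = np.array([[0.0, 0.0], [10.0, 0.0], [-10.0, 0.0]])
        merged = np.array([[0.0, 0.0], [0.0, 10.0]])
        # 3 points merged at the origin => weight 3
        w = np.array([3.0, 1.0])
        full = np.vstack([np.zeros((3, 2)), [[0.0, 10.0]]])
        assert radius_of_gyration(merged, w) == pytest.approx(
            radius_of_gyration(full)
        )

    def test_normalised_inverse_starts_at_one(self):
        rng = np.random.default_rng(4)
        frames = [rng.normal(0, s, (8, 2)) for s in (10, 20, 40)]
        series = cluster_series(frames, [0.0, 10.0, 20.0], 1000.0)
        assert series.normalized_inverse[0] == 1.0

    def test_truncates_when_cluster_dissolves(self):
        rng = np.random.default_rng(5)
        frames = [rng.normal(0, 10, (8, 2)) for _ in range(3)]
        frames.append(rng.normal(0, 10, (2, 2)))  # too few points
        with pytest.warns(UserWarning, match="truncated"):
            series = cluster_series(
                frames, [0.0, 10.0, 20.0, 30.0], 1000.0
            )
        assert len(series.times_s) == 3
        assert series.truncated

    def test_fragmented_frame_truncates(self):
        tight = np.random.default_rng(6).normal(0, 5, (9, 2))
        spread = np.vstack([tight, [[500.0, 500.0], [520.0, 500.0]]])
        with pytest.warns(UserWarning, match="truncated"):
            series = cluster_series(
                [tight, tight, tight, spread],
                [0.0, 1.0, 2.0, 3.0],
                linkage_cutoff_nm=100.0,
            )
        assert len(series.times_s) == 3

    def test_too_few_frames_rejected(self):
        pts = np.zeros((5, 2))
        with pytest.raises(ValueError):
            cluster_series([pts, pts], [0.0, 1.0], 100.0)


class TestDispersionRatio:
    def test_printed_decay_times_give_about_six(self):
        f580 = rs.DecayFit(1.0, 580.0, 0.0, 0.0, None, 6)
        f94 = rs.DecayFit(1.0, 94.0, 0.0, 0.0, None, 10)
        assert dispersion_ratio(f580, f94) == pytest.approx(6.17, abs=0.01)

    def test_equal_taus_give_one(self):
        f = rs.DecayFit(1.0, 100.0, 0.0, 0.0, None, 5)
        assert dispersion_ratio(f, f) == 1.0
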