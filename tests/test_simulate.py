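"""Simulator checks: survival function, curve generation, gaps, trajectories."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import wormcast as wc
from wormcast.simulate import HorizonError


class TestWeibullSurvival:
    def test_survival_starts_at_one(self):
        assert wc.weibull_survival(0, 5, 14) == 1.0

    @pytest.mark.parametrize("a,b", [(1.0, 5.0), (5.0, 14.0), (50.0, 30.0)])
    def test_survival_at_scale_is_inverse_e(self, a, b):
        assert wc.weibull_survival(b, a, b) == pytest.approx(np.exp(-1), rel=1e-12)

    def test_closed_form_value(self):
        # (7/14)^2 = 0.25
        assert wc.weibull_survival(7, 2, 14) == pytest.approx(np.exp(-0.25), rel=1e-12)

    def test_strictly_decreasing(self):
        t = np.linspace(0.1, 40, 100)
        s = wc.weibull_survival(t, 4.0, 18.0)
        assert np.all(np.diff(s) < 0)

    @pytest.mark.parametrize("a,b", [(0, 5), (-1, 5), (5, 0), (5, -2)])
    def test_rejects_non_positive_parameters(self, a, b):
        with pytest.raises(ValueError):
            wc.weibull_survival(1.0, a, b)


class TestGenerateCurve:
    def test_initial_count_and_extinction(self):
        params = wc.SimulatorParams(n_worms=12, a=5, b=15, max_days=40, seed=1)
        curve = wc.generate_curve(params)
        assert curve.live_counts[0] == 12
        assert curve.live_counts[-1] == 0
        assert np.all(np.diff(curve.live_counts) <= 0)

    def test_seeded_determinism(self):
        params = wc.SimulatorParams(n_worms=14, a=4, b=20, max_days=60, seed=42)
        c1 = wc.generate_curve(params)
        c2 = wc.generate_curve(params)
        np.testing.assert_array_equal(c1.live_counts, c2.live_counts)

    def test_sharp_shape_concentrates_deaths_at_scale(self):
        # a=50 makes the survival drop a near-step at t=b=14
        params = wc.SimulatorParams(n_worms=10, a=50, b=14, max_days=30, seed=3)
        curve = wc.generate_curve(params)
        counts = curve.live_counts
        assert np.all(counts[:12] == 10)
        assert curve.last_day <= 15

    def test_horizon_error_when_max_days_too_small(self):
        with pytest.raises(HorizonError):
            wc.SimulatorParams(n_worms=10, a=5, b=20, max_days=10, seed=0)
        # long-tailed draw beyond a tight horizon
        params = wc.SimulatorParams(n_worms=15, a=2, b=20, max_days=21, seed=5)
        with pytest.raises(HorizonError):
            wc.generate_curve(params)
        truncated = wc.generate_curve(params, on_horizon="truncate")
        assert truncated.last_day <= 21 and truncated.extinct

    def test_deterministic_method_tracks_expected_curve(self):
        params = wc.SimulatorParams(n_worms=15, a=5, b=20, max_days=40, seed=0)
        curve = wc.generate_curve(params, method="deterministic")
        t = curve.days
        expected = np.rint(15 * wc.weibull_survival(t.astype(float), 5, 20))
        np.testing.assert_allclose(curve.live_counts, expected)

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000), n=st.integers(10, 15),
           a=st.floats(3, 10), b=st.floats(10, 25))
    def test_curve_invariants_hold_for_random_parameters(self, seed, n, a, b):
        params = wc.SimulatorParams(n_worms=n, a=a, b=b, max_days=90, seed=seed)
        curve = wc.generate_curve(params, on_horizon="truncate")
        assert curve.live_counts[0] == n
        assert curve.extinct
        assert np.all(np.diff(curve.live_counts) <= 0)


class TestCaptureGaps:
    def test_hold_then_catch_up(self):
        curve = wc.LifespanCurve(days=np.arange(6), live_counts=[10, 9, 8, 7, 5, 0],
                                 initial_count=10)
        gapped = wc.apply_capture_gaps(curve, wc.GapSpec(gap_days=2, period=7, prob=1.0),
                                       rng=np.random.default_rng(0))
        # wherever a gap sits, the previous captured value is held
        assert np.all(np.diff(gapped.live_counts) <= 0)
        assert gapped.live_counts[0] == 10 and gapped.live_counts[-1] == 0
        held = gapped.live_counts != curve.live_counts
        assert held.any()  # prob=1 guarantees distortion on a 6-day curve
        for i in np.nonzero(held)[0]:
            assert gapped.live_counts[i] == gapped.live_counts[i - 1]

    def test_no_gap_spec_is_identity(self):
        curve = wc.LifespanCurve(days=np.arange(3), live_counts=[5, 2, 0], initial_count=5)
        out = wc.apply_capture_gaps(curve, None, rng=0)
        np.testing.assert_array_equal(out.live_counts, curve.live_counts)

    def test_gap_probability_zero_is_identity(self):
        curve = wc.LifespanCurve(days=np.arange(4), live_counts=[5, 4, 2, 0], initial_count=5)
        out = wc.apply_capture_gaps(curve, wc.GapSpec(prob=0.0), rng=1)
        np.testing.assert_array_equal(out.live_counts, curve.live_counts)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 1000))
    def test_gaps_preserve_monotonicity_and_totals(self, seed):
        params = wc.SimulatorParams(n_worms=12, a=5, b=15, max_days=40, seed=seed)
        curve = wc.generate_curve(params)
        gapped = wc.apply_capture_gaps(curve, wc.GapSpec(prob=1.0), rng=seed)
        assert np.all(np.diff(gapped.live_counts) <= 0)
        assert np.all(gapped.live_counts <= curve.initial_count)
        assert gapped.live_counts[-1] == curve.live_counts[-1]
        assert gapped.live_counts[0] == curve.initial_count


class TestTrajectories:
    def test_alive_counts_match_curve(self, plate_curve):
        trajectories = wc.sample_trajectories(plate_curve, wc.ArenaSpec(side=32), rng=0)
        assert len(trajectories) == plate_curve.initial_count
        for d in range(len(plate_curve.days)):
            alive = sum(tr.alive_mask[d] for tr in trajectories)
            assert alive == plate_curve.live_counts[d]

    def test_dead_worms_never_move(self, plate_curve):
        trajectories = wc.sample_trajectories(plate_curve, wc.ArenaSpec(side=32), rng=1)
        for tr in trajectories:
            if tr.death_day is not None:
                frozen = tr.positions[tr.death_day]
                assert np.all(tr.positions[tr.death_day :] == frozen)

    def test_alive_worms_move_every_day(self):
        curve = wc.LifespanCurve(days=np.arange(3), live_counts=[3, 3, 0], initial_count=3)
        trajectories = wc.sample_trajectories(curve, wc.ArenaSpec(side=64), rng=2)
        # all three move between day 0 and 1; none moves between day 1 and 2
        for tr in trajectories:
            assert not np.array_equal(tr.positions[0], tr.positions[1])
            np.testing.assert_array_equal(tr.positions[1], tr.positions[2])

    def test_positions_inside_food_lawn(self, plate_curve):
        arena = wc.ArenaSpec(side=48, lawn_fraction=0.5)
        trajectories = wc.sample_trajectories(plate_curve, arena, rng=3)
        centre, radius = 24.0, 0.5 * 48 / 2
        for tr in trajectories:
            r = np.hypot(tr.positions[:, 0] - centre, tr.positions[:, 1] - centre)
            assert np.all(r <= radius + 1e-9)

    def test_seeded_reproducibility(self, plate_curve):
        t1 = wc.sample_trajectories(plate_curve, wc.ArenaSpec(side=32), rng=9)
        t2 = wc.sample_trajectories(plate_curve, wc.ArenaSpec(side=32), rng=9)
        for a, b in zip(t1, t2):
            np.testing.assert_array_equal(a.positions, b.positions)


def test_empirical_survival_converges_to_weibull():
    """Pooled live fraction over many plates tracks S(t) within MC error."""
    n_plates, n_worms, a, b = 300, 15, 5.0, 20.0
    rng = np.random.default_rng(123)
    max_days = 40
    totals = np.zeros(max_days + 1)
    for _ in range(n_plates):
        params = wc.SimulatorParams(n_worms=n_worms, a=a, b=b, max_days=max_days,
                                    seed=int(rng.integers(2**31)))
        curve = wc.generate_curve(params, on_horizon="truncate")
        padded = np.zeros(max_days + 1)
        padded[: len(curve.live_counts)] = curve.live_counts
        totals += padded
    frac = totals / (n_plates * n_worms)
    expected = wc.weibull_survival(np.arange(max_days + 1).astype(float), a, b)
    n = n_plates * n_worms
    tol = 4 * np.sqrt(expected * (1 - expected) / n) + 1e-3
    assert np.all(np.abs(frac - expected) < tol)
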