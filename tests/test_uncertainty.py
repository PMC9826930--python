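"""Input-perturbation uncertainty and plate-to-condition error propagation."""

import numpy as np
import pytest
from scipy import special

import wormcast as wc
from conftest import MAX_DAYS, StubPredictor


class TestPerturbInput:
    def test_noise_is_zero_mean(self):
        """Per-element perturbation mean tends to 0 (law of large numbers)."""
        noise = wc.NoiseSpec(n_replicates=2, sigma=1.0, seed=1)
        prefix = np.full(5, 50.0)  # far from the clip boundary
        n = 10_000
        total = np.zeros(5)
        for i in range(n):
            total += wc.perturb_input(prefix, noise, i) - prefix
        assert np.all(np.abs(total / n) < 4.0 / np.sqrt(n))

    def test_clipping_at_zero(self):
        noise = wc.NoiseSpec(n_replicates=2, sigma=5.0, seed=0)
        out = np.stack([wc.perturb_input(np.zeros(4), noise, i) for i in range(200)])
        assert np.all(out >= 0)
        assert out.max() > 0  # noise actually applied

    def test_replicates_differ_but_reproduce(self):
        noise = wc.NoiseSpec(n_replicates=2, sigma=1.0, seed=3)
        prefix = np.array([10.0, 9.0, 7.0])
        a0 = wc.perturb_input(prefix, noise, 0)
        a1 = wc.perturb_input(prefix, noise, 1)
        assert not np.array_equal(a0, a1)
        np.testing.assert_array_equal(a0, wc.perturb_input(prefix, noise, 0))

    def test_sigma_validation(self):
        with pytest.raises(ValueError):
            wc.NoiseSpec(sigma=0.0)
        with pytest.raises(ValueError):
            wc.NoiseSpec(n_replicates=1)


class TestEstimatePlate:
    def test_constant_predictor_has_zero_std(self, constant_predictor):
        prefix = np.array([10.0, 9.0, 8.0])
        pred = wc.estimate_plate(constant_predictor, prefix,
                                 noise=wc.NoiseSpec(n_replicates=10, seed=0))
        assert np.all(pred.std_curve == 0)
        # post-processing anchors the future at the last observed count: the
        # constant zero raw output becomes 0 from day k+1 on
        np.testing.assert_array_equal(pred.mean_curve[:3], prefix)
        assert np.all(pred.mean_curve[3:] == 0)

    def test_mean_and_std_match_replicates(self):
        # predictor echoing its (noisy) last count everywhere in the future
        stub = StubPredictor(lambda p: np.full(MAX_DAYS, p[-1]))
        prefix = np.array([50.0, 45.0, 40.0])
        noise = wc.NoiseSpec(n_replicates=40, sigma=1.0, seed=5)
        pred = wc.estimate_plate(stub, prefix, noise=noise)
        np.testing.assert_allclose(pred.mean_curve,
                                   pred.replicate_curves.mean(axis=0), rtol=1e-12)
        np.testing.assert_allclose(pred.std_curve,
                                   pred.replicate_curves.std(axis=0, ddof=1),
                                   rtol=1e-9, atol=1e-12)
        assert np.all(pred.std_curve[:3] == 0)  # observed days have no spread

    def test_linear_predictor_std_matches_closed_form(self):
        """For f(x) = w.x the output std under N(0, sigma^2 I) noise is
        sigma*||w||; checked at large N against the sample std."""
        w = np.array([0.3, -0.2, 0.5])
        # output pinned mid-range so neither the input clip (>=0) nor the
        # output post-processing (clip to [0, initial], running min) bites
        stub = StubPredictor(lambda p: np.full(MAX_DAYS, 50.0 + w @ (p - 100.0)))
        prefix = np.full(3, 100.0)
        noise = wc.NoiseSpec(n_replicates=4000, sigma=1.0, seed=7)
        pred = wc.estimate_plate(stub, prefix, noise=noise)
        expected = np.linalg.norm(w)
        day = 5  # a future day: raw output passes through untouched
        assert pred.std_curve[day] == pytest.approx(expected, rel=0.05)

    def test_position_jitter_mode(self):
        """counts+positions jitters blob centres: replicate frames differ,
        stay in bounds, and the mode demands the raw positions."""
        captured = []

        class Recorder:
            config = wc.ModelConfig(mode="counts_only",
                                    image_spec=wc.ImageSpec(side=24),
                                    max_days=MAX_DAYS)

            def predict(self, samples):
                captured.extend(samples)
                return np.zeros((len(samples), MAX_DAYS))

        positions = np.full((3, 5, 2), 12.0)  # 5 worms at centre, 3 days
        noise = wc.NoiseSpec(n_replicates=4, sigma=1.0, target="counts+positions",
                             position_sigma=2.0, seed=2)
        wc.estimate_plate(Recorder(), np.array([5.0, 4.0, 3.0]), None, noise,
                          positions=positions)
        frames = [s.frame_prefix.frames for s in captured]
        assert len(frames) == 4
        assert any(not np.array_equal(frames[0], f) for f in frames[1:])
        with pytest.raises(ValueError, match="positions"):
            wc.estimate_plate(Recorder(), np.array([5.0, 4.0]), None, noise)

    def test_replicate_count_contract(self, constant_predictor):
        pred = wc.estimate_plate(constant_predictor, np.array([5.0, 4.0]),
                                 noise=wc.NoiseSpec(n_replicates=7, seed=0))
        assert pred.replicate_curves.shape[0] == 7


class TestPropagateCondition:
    def _plate(self, mean, std, k=2, initial=10.0):
        mean = np.asarray(mean, float)
        std = np.asarray(std, float)
        return wc.PlatePrediction(mean_curve=mean, std_curve=std,
                                  replicate_curves=np.stack([mean, mean]),
                                  k=k, initial_count=initial)

    def test_three_four_five(self):
        """stds 3 and 4 on two plates combine to exactly 5."""
        days = 4
        p1 = self._plate(np.full(days, 6.0), np.full(days, 3.0))
        p2 = self._plate(np.full(days, 6.0), np.full(days, 4.0))
        band = wc.propagate_condition([p1, p2], alpha=0.05)
        np.testing.assert_allclose(band.std_curve, 5.0)
        np.testing.assert_allclose(band.mean_curve, 12.0)

    def test_single_plate_passthrough(self):
        p = self._plate([8.0, 6.0, 4.0], [0.5, 1.0, 1.5])
        band = wc.propagate_condition([p], alpha=0.05)
        np.testing.assert_allclose(band.std_curve, p.std_curve)

    def test_sqrt_k_scaling_for_equal_plates(self):
        plates = [self._plate(np.full(3, 5.0), np.full(3, 2.0)) for _ in range(9)]
        band = wc.propagate_condition(plates, alpha=0.05)
        np.testing.assert_allclose(band.std_curve, 2.0 * 3.0)  # sqrt(9) * 2

    def test_z_quantile_against_independent_formula(self):
        """z_{alpha/2} via the inverse complementary error function."""
        p1 = self._plate(np.full(2, 50.0), np.full(2, 1.0), initial=100.0)
        band = wc.propagate_condition([p1], alpha=0.05)
        z_independent = np.sqrt(2) * special.erfcinv(0.05)
        assert z_independent == pytest.approx(1.95996, abs=1e-5)
        half = band.mean_curve - band.ci_lower
        np.testing.assert_allclose(half, z_independent * 1.0, rtol=1e-9)

    def test_ci_width_monotone_in_alpha(self):
        p = self._plate(np.full(3, 20.0), np.full(3, 2.0), initial=40.0)
        widths = []
        for alpha in (0.2, 0.1, 0.05, 0.01):
            band = wc.propagate_condition([p], alpha=alpha)
            widths.append((band.ci_upper - band.ci_lower)[0])
        assert np.all(np.diff(widths) > 0)  # halving alpha widens the band

    def test_sqrt_n_divisor_flag(self):
        plates = [self._plate(np.full(2, 10.0), np.full(2, 2.0), initial=50.0)
                  for _ in range(4)]
        with_div = wc.propagate_condition(plates, alpha=0.05)
        without = wc.propagate_condition(plates, alpha=0.05, sqrt_n_divisor=False)
        ratio = (without.ci_upper - without.mean_curve) / (
            with_div.ci_upper - with_div.mean_curve)
        np.testing.assert_allclose(ratio, 2.0)  # sqrt(4)

    def test_bounds_clipped_to_count_range(self):
        p1 = self._plate(np.full(2, 1.0), np.full(2, 50.0), initial=10.0)
        p2 = self._plate(np.full(2, 1.0), np.full(2, 50.0), initial=10.0)
        band = wc.propagate_condition([p1, p2], alpha=0.05)
        assert np.all(band.ci_lower >= 0)
        assert np.all(band.ci_upper <= 20.0)
        assert np.all(band.ci_lower <= band.mean_curve)
        assert np.all(band.mean_curve <= band.ci_upper)

    def test_misaligned_day_axes_rejected(self):
        p1 = self._plate(np.zeros(3), np.zeros(3))
        p2 = self._plate(np.zeros(4), np.zeros(4))
        with pytest.raises(ValueError, match="day axis"):
            wc.propagate_condition([p1, p2])


def test_propagation_matches_joint_monte_carlo():
    """Root-sum-of-squares equals the brute-force std of the summed
    prediction when plates are perturbed jointly and independently."""
    rng = np.random.default_rng(11)
    weights = [rng.uniform(-0.5, 0.5, size=4) for _ in range(3)]
    prefixes = [np.full(4, 100.0) for _ in range(3)]
    n = 10_000
    day = 6

    # analytic per-plate stds via the propagation path
    stubs = [StubPredictor(lambda p, w=w: np.full(MAX_DAYS, 50.0 + w @ (p - 100.0)))
             for w in weights]
    plates = [wc.estimate_plate(stub, pref,
                                noise=wc.NoiseSpec(n_replicates=2000, sigma=1.0, seed=s))
              for s, (stub, pref) in enumerate(zip(stubs, prefixes))]
    band = wc.propagate_condition(plates, alpha=0.05)

    # joint Monte-Carlo of the sum
    sums = np.zeros(n)
    for i in range(n):
        total = 0.0
        for w, pref in zip(weights, prefixes):
            noisy = pref + rng.normal(0, 1.0, size=4)
            total += 300.0 + w @ (noisy - 100.0)
        sums[i] = total
    assert band.std_curve[day] == pytest.approx(sums.std(ddof=1), rel=0.05)
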