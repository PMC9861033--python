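"""Tests of the goodness-of-fit statistics."""

import numpy as np
import pytest

from golgikin import (AcquisitionModel, GroundTruth, align_and_average,
                      chisq_gof, correct_trace, detect_breakpoint_r2scan,
                      gaussianity_check, generate_replicate_set, ks_compare,
                      normalize, parallelism_test)
from golgikin.families import evaluate_family


class TestChisqGof:
    def test_identical_curves_statistic_zero(self):
        y = np.linspace(100.0, 10.0, 40)
        res = chisq_gof(y, y)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert not res.reject

    def test_invariant_to_common_rescaling(self):
        rng = np.random.default_rng(0)
        o = np.abs(rng.normal(50, 5, 30)) + 10
        e = np.linspace(60.0, 40.0, 30)
        r1 = chisq_gof(o, e)
        r2 = chisq_gof(3.0 * o, 3.0 * e)
        # the statistic scales with mass; the comparison as distributions is
        # preserved when both curves are rescaled together and re-normalized
        assert r2.statistic == pytest.approx(3.0 * r1.statistic)

    def test_type_one_error_calibrated(self):
        """Noise with variance equal to the expected value (the regime in
        which the Pearson statistic is chi-squared): rejection rate ~ alpha."""
        rng = np.random.default_rng(5)
        t = np.arange(60) * 6.0
        e = evaluate_family(2, {"a": 900.0, "k": 0.008, "c": 100.0}, t)
        rej = sum(chisq_gof(e + rng.normal(0, np.sqrt(e)), e).reject
                  for _ in range(500))
        assert 0.05 * 500 - 3 * np.sqrt(500 * 0.05 * 0.95) < rej \
            < 0.05 * 500 + 3 * np.sqrt(500 * 0.05 * 0.95)

    def test_wrong_family_rejected_with_power(self):
        """Family-3 data against a family-2 theoretical curve is rejected in
        at least 95% of noisy replicates."""
        rng = np.random.default_rng(6)
        t = np.arange(60) * 6.0
        o_clean = evaluate_family(3, {"y0": 100.0, "t_b": 60.0, "k": 0.01,
                                      "c": 0.0}, t)
        e = evaluate_family(2, {"a": 100.0, "k": 0.01, "c": 0.0}, t) + 1e-9
        rej = sum(chisq_gof(np.abs(o_clean + rng.normal(0, 2.0, 60)), e).reject
                  for _ in range(100))
        assert rej >= 95

    def test_nonpositive_expected_rejected(self):
        with pytest.raises(ValueError):
            chisq_gof(np.ones(5), np.array([1.0, 0.0, 1.0, 1.0, 1.0]))


class TestKsCompare:
    def test_identical_curves_statistic_zero(self):
        y = np.linspace(100.0, 5.0, 50)
        assert ks_compare(y, y).statistic == pytest.approx(0.0, abs=1e-15)

    def test_matches_closed_form_geometric_cumulative(self):
        """Exponentials with rates k and 2k: the statistic equals the
        closed-form sup-difference of the normalized cumulative curves."""
        k, dt, n = 0.01, 6.0, 60
        t = np.arange(n) * dt
        res = ks_compare(np.exp(-k * t), np.exp(-2 * k * t))

        def cum(rate, j):
            q = np.exp(-rate * dt)
            return (1 - q ** (j + 1)) / (1 - q ** n)

        j = np.arange(n)
        oracle = np.max(np.abs(cum(k, j) - cum(2 * k, j)))
        assert res.statistic == pytest.approx(oracle, abs=1e-6)

    def test_invariant_to_common_rescaling(self):
        rng = np.random.default_rng(2)
        a = np.abs(rng.normal(50, 5, 30))
        b = np.linspace(60.0, 10.0, 30)
        assert ks_compare(a, b).statistic == \
            pytest.approx(ks_compare(5 * a, 5 * b).statistic, abs=1e-12)

    def test_empty_vs_full_protocol_shapes_differ(self):
        """Plateau-exponential vs pure exponential (the empty- vs full-Golgi
        signature) is detected at alpha = 0.05."""
        t = np.arange(60) * 6.0
        empty = evaluate_family(3, {"y0": 100.0, "t_b": 120.0, "k": 0.015,
                                    "c": 0.0}, t)
        full = evaluate_family(2, {"a": 100.0, "k": 0.015, "c": 0.0}, t)
        assert ks_compare(empty, full).reject

    def test_zero_mass_curve_rejected(self):
        with pytest.raises(ValueError):
            ks_compare(np.zeros(10), np.ones(10))


class TestParallelism:
    def test_same_rate_different_amplitude_parallel(self):
        t = np.arange(60) * 6.0
        res = parallelism_test(t, 100 * np.exp(-0.005 * t),
                               t, 37 * np.exp(-0.005 * t))
        assert res.parallel
        assert res.slope_a == pytest.approx(res.slope_b, abs=1e-12)
        assert res.slope_a == pytest.approx(-0.005, abs=1e-12)

    def test_doubled_rate_not_parallel_with_exact_slope_ratio(self):
        t = np.arange(60) * 6.0
        res = parallelism_test(t, 100 * np.exp(-0.005 * t),
                               t, 50 * np.exp(-0.010 * t))
        assert not res.parallel
        assert res.slope_b / res.slope_a == pytest.approx(2.0, abs=1e-9)

    def test_type_one_error_calibrated(self):
        """Equal true slopes with log-normal noise: rejection rate ~ alpha."""
        rng = np.random.default_rng(7)
        t = np.arange(60) * 6.0
        rej = 0
        n = 500
        for _ in range(n):
            ya = 100 * np.exp(-0.005 * t + rng.normal(0, 0.05, 60))
            yb = 40 * np.exp(-0.005 * t + rng.normal(0, 0.05, 60))
            rej += not parallelism_test(t, ya, t, yb).parallel
        band = 3 * np.sqrt(n * 0.05 * 0.95)
        assert 0.05 * n - band < rej < 0.05 * n + band

    def test_power_against_ten_percent_rate_difference(self):
        """k vs 1.1k at 2% multiplicative noise: power over 200 seeds is
        reported with a binomial CI and is a proper frequency."""
        rng = np.random.default_rng(8)
        t = np.arange(60) * 6.0
        hits = 0
        n = 200
        for _ in range(n):
            ya = 100 * np.exp(-0.005 * t + rng.normal(0, 0.02, 60))
            yb = 100 * np.exp(-0.0055 * t + rng.normal(0, 0.02, 60))
            hits += not parallelism_test(t, ya, t, yb).parallel
        power = hits / n
        ci = 1.96 * np.sqrt(power * (1 - power) / n)
        assert 0.0 < power <= 1.0
        assert ci < 0.1

    def test_nonpositive_values_rejected(self):
        t = np.arange(10.0)
        with pytest.raises(ValueError):
            parallelism_test(t, np.linspace(1, -1, 10), t, np.ones(10))


class TestGaussianity:
    def _aligned(self, noise_sd, seed=0, heavy_tail=False, n_frames=60):
        truth = GroundTruth(3, {"y0": 100.0, "t_b": 60.0, "k": 0.01,
                                "c": 0.0})
        acq = AcquisitionModel(n_frames=n_frames, noise_sd=noise_sd, seed=0)
        reps = generate_replicate_set(truth, acq, n_reps=6, seed=seed)
        norms = [normalize(correct_trace(r)) for r in reps]
        if heavy_tail:
            # inject a scale-mixture (heavy-tailed) contamination
            rng = np.random.default_rng(seed)
            for nm in norms:
                scale = np.where(rng.uniform(size=n_frames) < 0.15, 12.0, 0.3)
                nm.value_pct += rng.normal(0, 1.0, n_frames) * scale
        bps = [detect_breakpoint_r2scan(nm) for nm in norms]
        return align_and_average(norms, bps)

    def test_gaussian_noise_mostly_passes(self):
        g = gaussianity_check(self._aligned(noise_sd=2.0, seed=21))
        assert g[0].detail["pass_fraction"] >= 0.90

    def test_zero_noise_reported_not_applicable(self):
        g = gaussianity_check(self._aligned(noise_sd=0.0))
        assert all(not r.applicable for r in g)

    def test_heavy_tailed_noise_lowers_pass_fraction(self):
        clean = gaussianity_check(self._aligned(noise_sd=2.0, seed=21))
        dirty = gaussianity_check(self._aligned(noise_sd=0.5, seed=21,
                                                heavy_tail=True))
        assert dirty[0].detail["pass_fraction"] < clean[0].detail["pass_fraction"]

    def test_too_few_replicates_rejected(self):
        aligned = self._aligned(noise_sd=1.0)
        aligned.values = aligned.values[:2]
        with pytest.raises(ValueError):
            gaussianity_check(aligned)
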