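"""Closed-form checks of the Dirichlet-product metamotif mathematics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metamotif.model import (
    PWM,
    DirichletParams,
    Metamotif,
    from_mean_precision,
    information_content,
    log_column_density,
    mean_and_precision,
    metamotif_log_density,
    multinomial_beta_log,
    reverse_complement,
    sample_pwm,
)


@pytest.mark.parametrize(
    "alpha, expected",
    [
        ((1, 1, 1, 1), math.log(1 / 6)),  # Gamma(1)^4 / Gamma(4)
        ((0.5, 0.5, 0.5, 0.5), math.log(math.pi**2)),  # Gamma(1/2) = sqrt(pi)
        ((2, 2, 2, 2), math.log(1 / 5040)),  # Gamma(2)^4 / Gamma(8)
    ],
)
def test_multinomial_beta_closed_forms(alpha, expected):
    assert multinomial_beta_log(np.array(alpha, float)) == pytest.approx(
        expected, abs=1e-9
    )


def test_multinomial_beta_rejects_nonpositive():
    with pytest.raises(ValueError):
        multinomial_beta_log(np.array([1.0, 0.0, 1.0, 1.0]))


class TestColumnDensity:
    def test_uniform_dirichlet_density_is_constant_log6(self, rng):
        for _ in range(20):
            x = rng.dirichlet(np.ones(4) * rng.uniform(0.3, 5.0))
            assert log_column_density(x, np.ones(4)) == pytest.approx(
                math.log(6), abs=1e-9
            )

    def test_symmetric_alpha2_at_barycentre(self):
        val = log_column_density([0.25] * 4, np.full(4, 2.0))
        assert val == pytest.approx(math.log(5040 / 256), abs=1e-9)

    def test_boundary_column_is_finite(self):
        val = log_column_density([1.0, 0.0, 0.0, 0.0], np.array([2.0, 3.0, 1.0, 1.0]))
        assert np.isfinite(val)

    def test_unnormalisable_column_rejected(self):
        with pytest.raises(ValueError):
            log_column_density([0.0, 0.0, 0.0, 0.0], np.ones(4))

    @pytest.mark.parametrize(
        "alpha",
        [np.ones(4), np.full(4, 2.0), np.array([3.0, 1.0, 1.5, 2.5])],
    )
    def test_monte_carlo_simplex_integral_is_one(self, alpha, rng):
        # E_uniform[f(x)] * Vol(simplex) with Vol = 1/6 for the 3-simplex;
        # density evaluated vectorised with the same flooring as
        # log_column_density
        x = rng.dirichlet(np.ones(4), size=100_000)
        from scipy.special import gammaln

        logb = gammaln(alpha).sum() - gammaln(alpha.sum())
        xs = np.maximum(x, 1e-4)
        xs = xs / xs.sum(axis=1, keepdims=True)
        dens = np.exp(-logb + np.log(xs) @ (alpha - 1.0))
        assert dens.mean() / 6.0 == pytest.approx(1.0, abs=0.02)


class TestMetamotifDensity:
    def test_length_one_equals_column_density(self, rng):
        alpha = rng.uniform(0.5, 10, 4)
        x = rng.dirichlet(np.ones(4))
        pwm = PWM("p", x[None, :])
        mm = Metamotif("m", alpha[None, :])
        assert metamotif_log_density(pwm, mm) == pytest.approx(
            log_column_density(x, alpha), abs=1e-9
        )

    def test_uniform_two_column_metamotif(self, rng):
        pwm = PWM("p", rng.dirichlet(np.ones(4), size=2))
        mm = Metamotif("m", np.ones((2, 4)))
        assert metamotif_log_density(pwm, mm) == pytest.approx(
            2 * math.log(6), abs=1e-9
        )

    def test_density_factorises_over_columns(self, rng):
        pwm = PWM("p", rng.dirichlet(np.ones(4) * 0.8, size=5))
        mm = Metamotif("m", rng.uniform(0.2, 20, size=(5, 4)))
        per_column = sum(
            log_column_density(pwm.weights[i], mm.alpha[i]) for i in range(5)
        )
        assert metamotif_log_density(pwm, mm) == pytest.approx(per_column, rel=1e-12)

    def test_length_mismatch_rejected(self, rng):
        pwm = PWM("p", rng.dirichlet(np.ones(4), size=3))
        mm = Metamotif("m", np.ones((4, 4)))
        with pytest.raises(ValueError):
            metamotif_log_density(pwm, mm)


class TestMeanPrecision:
    def test_symmetric_column(self):
        mm = Metamotif("m", np.full((1, 4), 2.0))
        means, precisions = mean_and_precision(mm)
        np.testing.assert_allclose(means[0], 0.25)
        assert precisions[0] == pytest.approx(8.0)

    def test_forced_arithmetic(self):
        mm = from_mean_precision([[0.7, 0.1, 0.1, 0.1]], [10.0])
        np.testing.assert_allclose(mm.alpha[0], [7.0, 1.0, 1.0, 1.0], atol=1e-12)

    def test_round_trip_identity(self, rng):
        mm = Metamotif("m", rng.uniform(0.1, 40, size=(6, 4)))
        back = from_mean_precision(*mean_and_precision(mm), name="m")
        np.testing.assert_allclose(back.alpha, mm.alpha, atol=1e-12)

    def test_zero_precision_rejected(self):
        with pytest.raises(ValueError):
            from_mean_precision([[0.25] * 4], [0.0])


class TestSampling:
    def test_samples_are_valid_pwms(self, rng):
        mm = Metamotif("m", rng.uniform(0.1, 40, size=(7, 4)))
        pwm = sample_pwm(mm, rng)
        assert len(pwm) == 7
        np.testing.assert_allclose(pwm.weights.sum(axis=1), 1.0, atol=1e-9)

    def test_empirical_mean_matches_dirichlet_mean(self, rng):
        mm = Metamotif("m", np.array([[8.0, 4.0, 2.0, 2.0]]))
        draws = np.vstack([sample_pwm(mm, rng).weights[0] for _ in range(10_000)])
        np.testing.assert_allclose(
            draws.mean(axis=0), [0.5, 0.25, 0.125, 0.125], atol=0.02
        )

    def test_high_precision_concentrates_on_mean(self, rng):
        mean = np.array([0.4, 0.3, 0.2, 0.1])
        mm = from_mean_precision(mean[None, :], [4000.0])
        for _ in range(50):
            w = sample_pwm(mm, rng).weights[0]
            assert np.all(np.abs(w - mean) < 0.05)

    def test_empirical_covariance_matches_closed_form(self, rng):
        alpha = np.array([3.0, 2.0, 1.0, 4.0])
        mm = Metamotif("m", alpha[None, :])
        draws = np.vstack([sample_pwm(mm, rng).weights[0] for _ in range(20_000)])
        a0 = alpha.sum()
        mean = alpha / a0
        var = mean * (1 - mean) / (a0 + 1)
        np.testing.assert_allclose(draws.var(axis=0), var, rtol=0.1)


class TestReverseComplement:
    def test_single_column_swaps(self):
        mm = Metamotif("m", np.array([[7.0, 1.0, 2.0, 3.0]]))
        rc = reverse_complement(mm)
        np.testing.assert_allclose(rc.alpha[0], [3.0, 2.0, 1.0, 7.0])

    @given(st.integers(min_value=1, max_value=9), st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_involution_and_density_symmetry(self, length, seed):
        rng = np.random.default_rng(seed)
        mm = Metamotif("m", rng.uniform(0.1, 40, size=(length, 4)))
        pwm = PWM("p", rng.dirichlet(np.ones(4), size=length))
        twice = reverse_complement(reverse_complement(mm))
        np.testing.assert_allclose(twice.alpha, mm.alpha)
        assert metamotif_log_density(
            reverse_complement(pwm), reverse_complement(mm)
        ) == pytest.approx(metamotif_log_density(pwm, mm), rel=1e-12)


def test_pwm_invariants_enforced():
    with pytest.raises(ValueError):
        PWM("bad", np.array([[0.5, 0.4, 0.05, 0.0]]))  # sums to 0.95
    with pytest.raises(ValueError):
        Metamotif("bad", np.array([[1.0, -0.1, 1.0, 1.0]]))


def test_information_content_bounds():
    assert information_content(np.full((1, 4), 0.25))[0] == pytest.approx(0.0, abs=1e-9)
    sharp = information_content(np.array([[0.9997, 0.0001, 0.0001, 0.0001]]))[0]
    assert 1.9 < sharp <= 2.0
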