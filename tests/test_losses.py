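"""CLUB / TCE losses, the temperature constraint, and the combined objective."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from climat import nn
from climat.losses import (
    TemperatureState,
    club,
    consistency_loss,
    constrain_temperatures,
    cross_entropy,
    prognosis_loss,
    temperature_scaled_ce,
    total_loss,
)


class TestCrossEntropy:
    def test_uniform_logits_give_log_nc(self):
        assert float(cross_entropy(np.zeros(4), 2)) == pytest.approx(np.log(4))

    def test_numerically_stable_at_extreme_logits(self):
        val = float(cross_entropy(np.array([1000.0, 0.0]), 0))
        assert 0 <= val < 1e-6

    def test_direct_formula_oracle(self):
        # -log(e^2 / (e^2 + e^0)) = log(1 + e^-2)
        assert float(cross_entropy(np.array([2.0, 0.0]), 0)) == pytest.approx(
            np.log(1 + np.exp(-2))
        )

    def test_label_out_of_range(self):
        with pytest.raises(ValueError):
            cross_entropy(np.zeros(3), 3)


class TestTemperatureScaledCE:
    def test_tau_one_reduces_to_ce(self, rng):
        logits = rng.normal(size=5)
        assert float(temperature_scaled_ce(logits, 3, 1.0)) == pytest.approx(
            float(cross_entropy(logits, 3)), abs=1e-12
        )

    def test_uniform_logits_invariant_to_tau(self):
        for tau in (0.1, 0.5, 1.0):
            assert float(temperature_scaled_ce(np.ones(6) * 2.5, 0, tau)) == pytest.approx(
                np.log(6)
            )

    def test_direct_formula_oracle(self):
        # logits [2,0], tau=0.5 -> CE on [1,0]: log(1 + e^-1)
        assert float(temperature_scaled_ce(np.array([2.0, 0.0]), 0, 0.5)) == pytest.approx(
            np.log(1 + np.exp(-1))
        )

    def test_invalid_tau(self):
        with pytest.raises(ValueError):
            temperature_scaled_ce(np.zeros(3), 0, 0.0)
        with pytest.raises(ValueError):
            temperature_scaled_ce(np.zeros(3), 0, 1.5)


class TestClub:
    def test_tau_one_equals_ce(self, rng):
        logits = rng.normal(size=4)
        assert float(club(logits, 1, 1.0)) == pytest.approx(
            float(cross_entropy(logits, 1)), abs=1e-12
        )

    def test_tau_zero_is_log_nc_regardless_of_logits(self, rng):
        assert float(club(rng.normal(size=7) * 10, 2, 0.0)) == pytest.approx(np.log(7))

    def test_direct_formula_oracle(self):
        expected = 0.5 * np.log(1 + np.exp(-2)) + 0.5 * np.log(2)
        assert float(club(np.array([2.0, 0.0]), 0, 0.5, 2)) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=100)
    @given(
        seed=st.integers(0, 10**6),
        nc=st.integers(2, 10),
        tau=st.floats(0.01, 1.0),
    )
    def test_club_upper_bounds_tce(self, seed, nc, tau):
        """Reverse-Hoelder bound: CLUB >= TCE on (0, 1], equality iff tau = 1."""
        logits = np.random.default_rng(seed).normal(size=nc) * 3
        c = float(club(logits, 0, tau, nc))
        t = float(temperature_scaled_ce(logits, 0, tau))
        assert c >= t - 1e-10
        if tau == 1.0:
            assert c == pytest.approx(t, abs=1e-7)

    def test_strict_inequality_below_tau_one(self, rng):
        logits = rng.normal(size=5) * 2
        assert float(club(logits, 0, 0.6, 5)) > float(
            temperature_scaled_ce(logits, 0, 0.6)
        ) + 1e-6


class TestGradientIdentities:
    def test_logit_gradient_is_tau_times_ce_gradient(self, rng):
        """d CLUB / d logits = tau * d CE / d logits (finite differences)."""
        for _ in range(50):
            nc = int(rng.integers(2, 8))
            logits = rng.normal(size=nc) * 2
            label = int(rng.integers(nc))
            tau = float(rng.uniform(0.05, 1.0))
            x = nn.Tensor(logits, requires_grad=True)
            club(x, label, tau, nc).backward()
            eps = 1e-6
            ce_grad = np.zeros(nc)
            for i in range(nc):
                lp, lm = logits.copy(), logits.copy()
                lp[i] += eps
                lm[i] -= eps
                ce_grad[i] = (
                    float(cross_entropy(lp, label)) - float(cross_entropy(lm, label))
                ) / (2 * eps)
            rel = np.max(np.abs(x.grad - tau * ce_grad)) / (np.max(np.abs(tau * ce_grad)) + 1e-12)
            assert rel < 1e-4

    def test_tau_gradient_is_ce_minus_log_nc(self, rng):
        """d CLUB / d tau = CE - log Nc."""
        for _ in range(50):
            nc = int(rng.integers(2, 8))
            logits = rng.normal(size=nc) * 2
            label = int(rng.integers(nc))
            tau0 = float(rng.uniform(0.1, 0.9))
            tau = nn.Tensor(tau0, requires_grad=True)
            club(logits, label, tau, nc).backward()
            expected = float(cross_entropy(logits, label)) - np.log(nc)
            assert tau.grad == pytest.approx(expected, rel=1e-10)


class TestConstrainTemperatures:
    def test_equal_sigmas_give_all_ones(self):
        for n in (1, 3, 7):
            tau = constrain_temperatures(np.full(n, 1.7)).data
            assert np.allclose(tau, 1.0)

    def test_single_task(self):
        assert constrain_temperatures(np.array([2.3])).data.tolist() == [1.0]

    def test_hand_computed_softmax_oracle(self):
        sigma, eps = np.array([1.0, 2.0]), 1e-6
        rho = 1.0 / (sigma**2 + eps)
        rho_tilde = np.exp(rho) / np.exp(rho).sum()
        expected = rho_tilde / rho_tilde.max()
        out = constrain_temperatures(sigma, eps).data
        assert np.allclose(out, expected, atol=1e-12)
        assert out[0] == pytest.approx(1.0)
        assert out[1] == pytest.approx(0.4723, abs=1e-3)

    @settings(derandomize=True, max_examples=100)
    @given(seed=st.integers(0, 10**6), n=st.integers(1, 9))
    def test_constraint_invariants(self, seed, n):
        sigma = np.random.default_rng(seed).uniform(0.05, 10, size=n)
        tau = constrain_temperatures(sigma).data
        assert tau.max() == pytest.approx(1.0)
        assert np.all(tau > 0) and np.all(tau <= 1.0 + 1e-12)

    def test_differentiable_in_sigma(self):
        s = nn.Tensor([0.5, 1.5, 3.0], requires_grad=True)
        constrain_temperatures(s).sum().backward()
        assert np.all(np.isfinite(s.grad))
        assert np.any(s.grad != 0)

    def test_invalid_eps(self):
        with pytest.raises(ValueError):
            constrain_temperatures(np.ones(3), eps=0.0)

    def test_temperature_state_detach_flag(self):
        state = TemperatureState(3, detach_tau=True)
        assert not state.tau().requires_grad
        state2 = TemperatureState(3)
        assert state2.tau().requires_grad


class TestPrognosisLoss:
    def test_single_observed_task_equals_its_club(self, rng):
        logits = [rng.normal(size=(1, 4)) for _ in range(3)]
        tau = [0.7, 0.9, 1.0]
        out = prognosis_loss(logits, [[2, 0, 0]], [[True, False, False]], tau)
        assert float(out) == pytest.approx(float(club(logits[0][0], 2, 0.7, 4)))

    def test_all_observed_tau_one_is_mean_ce(self, rng):
        logits = [rng.normal(size=(1, 3)) for _ in range(4)]
        labels = [[0, 1, 2, 0]]
        out = prognosis_loss(logits, labels, [[True] * 4], np.ones(4))
        expected = np.mean(
            [float(cross_entropy(logits[t][0], labels[0][t])) for t in range(4)]
        )
        assert float(out) == pytest.approx(expected)

    def test_brute_force_sum_oracle(self, rng):
        # batch of 3 samples, 3 tasks, random masks: independent summation
        tau = rng.uniform(0.2, 1.0, size=3)
        logits = [rng.normal(size=(3, 5)) for _ in range(3)]
        labels = rng.integers(0, 5, size=(3, 3))
        mask = np.array([[1, 0, 1], [1, 1, 1], [1, 0, 0]], dtype=bool)
        out = float(prognosis_loss(logits, labels, mask, tau))
        per_sample = []
        for i in range(3):
            terms = [
                tau[t] * float(cross_entropy(logits[t][i], labels[i, t]))
                + (1 - tau[t]) * np.log(5)
                for t in range(3)
                if mask[i, t]
            ]
            per_sample.append(np.mean(terms))
        assert out == pytest.approx(np.mean(per_sample))

    def test_invariant_to_masked_entries(self, rng):
        logits = [nn.Tensor(rng.normal(size=(2, 4))) for _ in range(3)]
        labels = np.array([[1, 0, 2], [3, 1, 0]])
        mask = np.array([[True, False, True], [True, True, False]])
        base = float(prognosis_loss(logits, labels, mask, np.ones(3)))
        # perturb masked logits and labels arbitrarily
        logits[1].data[0] += 100
        logits[2].data[1] -= 50
        labels2 = labels.copy()
        labels2[0, 1] = 3
        labels2[1, 2] = 2
        assert float(prognosis_loss(logits, labels2, mask, np.ones(3))) == pytest.approx(base)

    def test_all_masked_batch_is_error(self, rng):
        logits = [rng.normal(size=(2, 3))]
        with pytest.raises(ValueError):
            prognosis_loss(logits, [[0], [0]], [[False], [False]], [1.0])


class TestConsistencyAndTotal:
    def test_identical_logits_zero(self):
        assert float(consistency_loss(np.ones(4), np.ones(4))) == 0.0

    def test_hand_arithmetic(self):
        assert float(consistency_loss(np.array([1.0, 0.0]), np.array([0.0, 1.0]))) == 2.0

    def test_batch_matches_elementwise_recomputation(self, rng):
        a, b = rng.normal(size=(8, 5)), rng.normal(size=(8, 5))
        assert float(consistency_loss(a, b)) == pytest.approx(
            np.abs(a - b).sum(axis=1).mean()
        )

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            consistency_loss(np.zeros(3), np.zeros(4))

    def test_total_loss_combination(self):
        assert float(total_loss(0.7, 0.3, 0.0)) == pytest.approx(0.7)
        assert float(total_loss(0.7, 0.3, 1.0)) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            total_loss(0.7, 0.3, -0.1)
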