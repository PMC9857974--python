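"""Loss terms: analytic values, brute-force oracles, gradient checks."""

import numpy as np
import pytest

from camr._autodiff import Tensor
from camr.data_model import SurvivalLabels
from camr.objectives import (LossWeights, adversarial_fake_loss,
                             adversarial_true_loss, cox_loss,
                             orthogonality_loss, reconstruction_loss,
                             total_loss)
from conftest import random_labels

# ------------------------------------------------------ independent oracles


def cox_nll_enumeration(risk, time, event):
    """O(n^2) negative log partial likelihood: risk sets built explicitly."""
    nll = 0.0
    for i in np.flatnonzero(event == 1):
        riskset = [j for j in range(len(time)) if time[j] >= time[i]]
        nll -= risk[i] - np.log(np.sum(np.exp([risk[j] for j in riskset])))
    return nll


def orth_bruteforce(h_c_list, h_u_list):
    total = 0.0
    for hc, hu in zip(h_c_list, h_u_list):
        m = np.zeros((hc.shape[1], hu.shape[1]))
        for a in range(hc.shape[1]):
            for b in range(hu.shape[1]):
                for i in range(hc.shape[0]):
                    m[a, b] += hc[i, a] * hu[i, b]
        total += np.sum(m**2)
    return total


# ------------------------------------------------------- adversarial losses


class TestAdversarialLosses:
    def test_uninformative_discriminator_equilibria(self):
        half = np.full(8, 0.5)
        assert adversarial_fake_loss(half, half) == pytest.approx(
            2 * np.log(2), abs=1e-12)
        assert adversarial_true_loss(half, half, half, half) == pytest.approx(
            4 * np.log(2), abs=1e-12)

    def test_fake_loss_single_sample(self):
        assert adversarial_fake_loss(np.array([0.8]), np.array([0.4])) == \
            pytest.approx(-np.log(0.8) - np.log(0.4), abs=1e-12)

    def test_fake_loss_vanishes_when_sources_fool_discriminators(self):
        near_one = np.full(4, 1.0 - 1e-7)
        assert adversarial_fake_loss(near_one, near_one) < 1e-5

    def test_true_loss_matches_term_by_term_oracle(self):
        rng = np.random.default_rng(0)
        p1, g1, c2, g2 = (rng.uniform(0.05, 0.95, 6) for _ in range(4))
        expected = np.mean(-np.log(1 - p1) - np.log(g1)
                           - np.log(1 - c2) - np.log(g2))
        assert adversarial_true_loss(p1, g1, c2, g2) == pytest.approx(
            expected, abs=1e-12)

    def test_perfect_discriminator_reaches_clamp_floor(self):
        zeros, ones = np.zeros(3), np.ones(3)
        val = adversarial_true_loss(zeros, ones, zeros, ones)
        assert val == pytest.approx(-4 * np.log(1 - 1e-7), abs=1e-12)

    def test_out_of_range_probabilities_rejected(self):
        with pytest.raises(ValueError):
            adversarial_fake_loss(np.array([1.2]), np.array([0.5]))


# ------------------------------------------------ orthogonality and recon


class TestOrthogonalityLoss:
    def test_orthogonal_column_spaces_give_zero(self):
        # columns of H_c are orthogonal (over patients) to columns of H_u
        h_c = np.array([[1.0, 0.0], [1.0, 0.0]])
        h_u = np.array([[1.0, 2.0], [-1.0, -2.0]])
        assert orthogonality_loss([h_c], [h_u]) == pytest.approx(0.0, abs=1e-12)

    def test_single_row_hand_case(self):
        row = np.array([[1.0, 0.0]])
        assert orthogonality_loss([row], [row]) == pytest.approx(1.0, abs=1e-12)

    def test_matches_entrywise_bruteforce(self):
        rng = np.random.default_rng(1)
        h_c = [rng.standard_normal((4, 3)) for _ in range(3)]
        h_u = [rng.standard_normal((4, 3)) for _ in range(3)]
        assert orthogonality_loss(h_c, h_u) == pytest.approx(
            orth_bruteforce(h_c, h_u), abs=1e-10)


class TestReconstructionLoss:
    def test_perfect_reconstruction_is_zero(self):
        x = [np.random.default_rng(2).standard_normal((3, 4)) for _ in range(3)]
        assert reconstruction_loss(x, [a.copy() for a in x]) == 0.0

    def test_all_ones_residual_hand_case(self):
        f = np.zeros((1, 4))
        fh = np.ones((1, 4))
        zero = np.zeros((1, 4))
        assert reconstruction_loss([fh, zero, zero], [f, zero, zero]) == \
            pytest.approx(4.0, abs=1e-12)

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(3)
        f = [rng.standard_normal((5, 6)) for _ in range(3)]
        fh = [rng.standard_normal((5, 6)) for _ in range(3)]
        expected = sum(np.mean(np.sum((a - b) ** 2, axis=1))
                       for a, b in zip(fh, f))
        assert reconstruction_loss(fh, f) == pytest.approx(expected, abs=1e-10)


# --------------------------------------------------------------- Cox loss


class TestCoxLoss:
    def test_zero_risk_closed_form(self):
        labels = SurvivalLabels([1.0, 2.0, 3.0], [1, 1, 1], ["a", "b", "c"])
        nll = cox_loss(np.zeros(3), labels, reduction="sum")
        assert nll == pytest.approx(np.log(3) + np.log(2), abs=1e-12)

    def test_shift_invariance(self):
        rng = np.random.default_rng(4)
        labels = random_labels(rng, 15)
        r = rng.standard_normal(15)
        assert cox_loss(r, labels) == pytest.approx(
            cox_loss(r + 100.0, labels), abs=1e-8)

    def test_matches_riskset_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            n = 20
            labels = random_labels(rng, n)
            r = rng.standard_normal(n)
            expected = cox_nll_enumeration(r, labels.time, labels.event)
            assert cox_loss(r, labels, reduction="sum") == pytest.approx(
                expected, abs=1e-10)

    def test_l1_term_added(self):
        labels = SurvivalLabels([1.0, 2.0], [1, 1], ["a", "b"])
        base = cox_loss(np.array([0.1, -0.2]), labels)
        with_l1 = cox_loss(np.array([0.1, -0.2]), labels,
                           lambda_l1=0.5, params_l1_norm=3.0)
        assert with_l1 == pytest.approx(base + 1.5, abs=1e-12)

    def test_zero_events_rejected(self):
        labels = SurvivalLabels([1.0, 2.0], [0, 0], ["a", "b"])
        with pytest.raises(ValueError):
            cox_loss(np.zeros(2), labels)

    def test_tied_times_use_breslow_risk_sets(self):
        # both events at t=1 share the full risk set of size 2
        labels = SurvivalLabels([1.0, 1.0], [1, 1], ["a", "b"])
        nll = cox_loss(np.zeros(2), labels, reduction="sum")
        assert nll == pytest.approx(2 * np.log(2), abs=1e-12)


def test_breslow_reference_implementation_agrees():
    """Cross-check against an established Breslow partial-likelihood
    implementation evaluated at a fixed coefficient of 1."""
    from statsmodels.duration.hazard_regression import PHReg

    rng = np.random.default_rng(6)
    n = 40
    labels = random_labels(rng, n)
    r = rng.standard_normal(n)
    model = PHReg(labels.time, r[:, None], status=labels.event, ties="breslow")
    reference = -model.loglike(np.array([1.0]))
    assert cox_loss(r, labels, reduction="sum") == pytest.approx(
        reference, abs=1e-6)


# ------------------------------------------------------------- total loss


class TestTotalLoss:
    def test_zero_components(self):
        w = LossWeights()
        assert total_loss(0.0, 0.0, 0.0, 0.0, w) == 0.0

    def test_reference_weights_combination(self):
        w = LossWeights(alpha=0.6, beta=0.8, gamma=0.05)
        assert total_loss(1.0, 1.0, 1.0, 1.0, w) == pytest.approx(2.45, abs=1e-12)

    def test_gamma_zero_reduces_to_three_terms(self):
        w = LossWeights(alpha=0.5, beta=0.25, gamma=0.0)
        assert total_loss(2.0, 4.0, 8.0, 100.0, w) == pytest.approx(
            2.0 + 2.0 + 2.0, abs=1e-12)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            total_loss(np.inf, 0.0, 0.0, 0.0, LossWeights())


# ------------------------------------------------------- gradient checks


def _finite_diff_check(fn, arrays, rel_tol=1e-4):
    """Compare analytic gradients of fn(*tensors) with central differences."""
    tensors = [Tensor(a.copy(), requires_grad=True) for a in arrays]
    out = fn(*tensors)
    out.backward()
    h = 1e-5
    for t in tensors:
        grad = t.grad
        assert grad is not None
        numeric = np.zeros_like(t.value)
        it = np.nditer(t.value, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = t.value[idx]
            t.value[idx] = orig + h
            up = fn(*[Tensor(x.value) for x in tensors]).item()
            t.value[idx] = orig - h
            down = fn(*[Tensor(x.value) for x in tensors]).item()
            t.value[idx] = orig
            numeric[idx] = (up - down) / (2 * h)
        scale = max(np.abs(grad).max(), np.abs(numeric).max(), 1e-8)
        np.testing.assert_allclose(grad, numeric, atol=rel_tol * scale)


class TestGradientCorrectness:
    def test_adversarial_fake(self):
        rng = np.random.default_rng(10)
        p = rng.uniform(0.1, 0.9, 5)
        q = rng.uniform(0.1, 0.9, 5)
        _finite_diff_check(adversarial_fake_loss, [p, q])

    def test_adversarial_true(self):
        rng = np.random.default_rng(11)
        ps = [rng.uniform(0.1, 0.9, 4) for _ in range(4)]
        _finite_diff_check(adversarial_true_loss, ps)

    def test_orthogonality(self):
        rng = np.random.default_rng(12)
        mats = [rng.standard_normal((4, 3)) for _ in range(6)]
        _finite_diff_check(
            lambda *ts: orthogonality_loss(list(ts[:3]), list(ts[3:])), mats)

    def test_reconstruction(self):
        rng = np.random.default_rng(13)
        mats = [rng.standard_normal((3, 4)) for _ in range(6)]
        _finite_diff_check(
            lambda *ts: reconstruction_loss(list(ts[:3]), list(ts[3:])), mats)

    def test_cox(self):
        rng = np.random.default_rng(14)
        labels = random_labels(rng, 12)
        r = rng.standard_normal(12)
        _finite_diff_check(lambda t: cox_loss(t, labels), [r])
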