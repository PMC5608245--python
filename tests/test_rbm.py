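from itertools import product

import numpy as np
import pytest

from petsae.rbm import (
    RBMParams,
    cd1_update,
    cond_prob_hidden,
    cond_prob_visible,
    energy,
    exact_log_likelihood,
    initialize_rbm,
)


def test_energy_closed_forms():
    p = RBMParams(W=np.array([[0.5], [-0.25]]), b=np.array([0.1, 0.1]), c=np.array([0.2]))
    assert energy([0, 0], [0], p) == 0.0
    assert energy([1, 1], [1], p) == pytest.approx(-0.65, abs=1e-12)
    pz = RBMParams(W=np.zeros((2, 2)), b=np.array([0.3, 0.4]), c=np.array([0.1, 0.2]))
    assert energy([1, 1], [1, 1], pz) == pytest.approx(-(0.7 + 0.3), abs=1e-12)
    with pytest.raises(ValueError):
        energy([1, 1, 1], [1], p)


def test_conditional_probabilities():
    zero = RBMParams(W=np.zeros((2, 3)), b=np.zeros(2), c=np.zeros(3))
    assert np.allclose(cond_prob_hidden(np.array([1.0, 0.0]), zero), 0.5)
    assert np.allclose(cond_prob_visible(np.array([1.0, 1.0, 0.0]), zero), 0.5)
    p = RBMParams(W=np.array([[0.5], [-0.25]]), b=np.zeros(2), c=np.array([0.1]))
    got = cond_prob_hidden(np.array([1.0, 1.0]), p)
    assert got[0] == pytest.approx(1 / (1 + np.exp(-0.35)), abs=1e-12)
    # bias-only case
    pb = RBMParams(W=np.zeros((2, 1)), b=np.array([0.7, -0.3]), c=np.zeros(1))
    got_v = cond_prob_visible(np.zeros(1), pb)
    assert np.allclose(got_v, 1 / (1 + np.exp(-pb.b)))


def test_conditionals_match_bayes_rule_on_enumerated_joint(rng):
    # factorized conditionals must agree with brute-force Bayes computation
    params = initialize_rbm(3, 2, seed=rng, scale=0.8)
    all_h = np.array(list(product((0.0, 1.0), repeat=2)))
    for v in product((0.0, 1.0), repeat=3):
        v = np.array(v)
        w = np.array([np.exp(-energy(v, h, params)) for h in all_h])
        bayes = np.array([w[all_h[:, j] == 1].sum() / w.sum() for j in range(2)])
        assert np.allclose(cond_prob_hidden(v, params), bayes, atol=1e-12)


def test_cd1_determinism_and_validation(tiny_rbm):
    params, data = tiny_rbm["params"], tiny_rbm["data"]
    a = cd1_update(data, params, 0.1, seed=7)
    b = cd1_update(data, params, 0.1, seed=7)
    assert np.array_equal(a.W, b.W) and np.array_equal(a.b, b.b)
    with pytest.raises(ValueError):
        cd1_update(np.empty((0, 4)), params, 0.1, seed=0)
    with pytest.raises(ValueError):
        cd1_update(data * 2.0, params, 0.1, seed=0)  # outside [0, 1]


def test_cd1_expected_update_vanishes_at_symmetric_point():
    # all-zero parameters reproduce any 0.5-batch on average: mean CD step ~ 0
    params = RBMParams(W=np.zeros((3, 2)), b=np.zeros(3), c=np.zeros(2))
    batch = np.full((4, 3), 0.5)
    steps = np.array(
        [cd1_update(batch, params, 1.0, seed=s).W for s in range(500)]
    )
    assert np.abs(steps.mean(axis=0)).max() < 0.02


def test_large_penalty_shrinks_weights():
    rng = np.random.default_rng(3)
    params = RBMParams(
        W=rng.standard_normal((4, 3)), b=np.zeros(4), c=np.zeros(3), lambda_reg=20.0
    )
    batch = np.full((4, 4), 0.5)
    norms = [np.linalg.norm(params.W)]
    p = params
    for s in range(5):
        p = cd1_update(batch, p, 0.05, seed=s)
        norms.append(np.linalg.norm(p.W))
    assert all(b < a for a, b in zip(norms, norms[1:]))


def test_exact_likelihood_uniform_at_zero_parameters():
    p = RBMParams(W=np.zeros((4, 2)), b=np.zeros(4), c=np.zeros(2))
    data = np.array([[1.0, 0.0, 1.0, 0.0]])
    assert exact_log_likelihood(p, data) == pytest.approx(-4 * np.log(2), abs=1e-12)


def test_penalty_term_is_additive():
    rng = np.random.default_rng(5)
    W = rng.standard_normal((3, 2))
    data = np.array([[1.0, 0.0, 1.0], [0.0, 1.0, 0.0]])
    base = RBMParams(W=W, b=np.zeros(3), c=np.zeros(2), lambda_reg=0.0)
    pen = RBMParams(W=W, b=np.zeros(3), c=np.zeros(2), lambda_reg=0.7)
    gap = exact_log_likelihood(base, data) - exact_log_likelihood(pen, data)
    assert gap == pytest.approx(0.7 / 2 * np.sum(W**2), abs=1e-12)


def test_state_space_guard():
    p = RBMParams(W=np.zeros((15, 10)), b=np.zeros(15), c=np.zeros(10))
    with pytest.raises(ValueError):
        exact_log_likelihood(p, np.zeros((1, 15)))


def test_cd1_training_increases_exact_likelihood(tiny_rbm):
    params, data = tiny_rbm["params"], tiny_rbm["data"]
    ll0 = exact_log_likelihood(params, data)
    rng = np.random.default_rng(42)
    p = params
    for _ in range(200):
        p = cd1_update(data, p, 0.1, rng)
    assert exact_log_likelihood(p, data) > ll0


def test_mean_cd_step_aligns_with_exact_gradient():
    # direction check: mean CD-1 weight update vs enumerated likelihood gradient
    params = initialize_rbm(4, 3, seed=2, scale=0.3)
    data = np.array([[1.0, 1.0, 0.0, 0.0], [0.0, 0.0, 1.0, 1.0], [1.0, 0.0, 1.0, 0.0]])
    all_v = np.array(list(product((0.0, 1.0), repeat=4)))
    all_h = np.array(list(product((0.0, 1.0), repeat=3)))
    E = np.array([[energy(v, h, params) for h in all_h] for v in all_v])
    P = np.exp(-E)
    P /= P.sum()
    model_corr = sum(
        P[i, j] * np.outer(all_v[i], all_h[j])
        for i in range(len(all_v))
        for j in range(len(all_h))
    )
    data_corr = data.T @ cond_prob_hidden(data, params) / len(data)
    exact_grad = data_corr - model_corr
    mean_step = np.mean(
        [cd1_update(data, params, 1.0, seed=s).W - params.W for s in range(300)], axis=0
    )
    cos = np.sum(exact_grad * mean_step) / (
        np.linalg.norm(exact_grad) * np.linalg.norm(mean_step)
    )
    assert cos > 0.8
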