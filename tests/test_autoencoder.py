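import dataclasses

import numpy as np
import pytest

from petsae.autoencoder import (
    AEParams,
    SparsityConfig,
    decode,
    encode,
    filter_images,
    gradients,
    initialize_params,
    kl_sparsity,
    objective,
    train_autoencoder,
)


def _zero_params(n_in, n_hidden, n_out):
    return AEParams(
        np.zeros((n_in, n_hidden)), np.zeros(n_hidden), np.zeros((n_hidden, n_out)), np.zeros(n_out)
    )


def test_encode_decode_closed_forms(rng):
    p = _zero_params(4, 3, 4)
    assert np.allclose(encode(np.ones(4), p), 0.5)
    assert np.allclose(decode(np.ones(3), p), 0.5)
    # scalar sigmoid limits
    ps = AEParams(np.array([[1.0]]), np.zeros(1), np.array([[1.0]]), np.zeros(1))
    assert encode(np.array([0.0]), ps)[0] == 0.5
    assert encode(np.array([50.0]), ps)[0] == pytest.approx(1.0, abs=1e-12)
    # random case vs direct evaluation
    p4 = initialize_params(4, 3, 4, seed=rng)
    x = rng.random(4)
    manual = 1 / (1 + np.exp(-(x @ p4.W_enc + p4.b_enc)))
    assert np.allclose(encode(x, p4), manual, atol=1e-14)
    with pytest.raises(ValueError):
        encode(np.ones(5), p)


def test_kl_sparsity_values():
    assert kl_sparsity(np.full(7, 0.25), 0.25) == 0.0
    expect = 0.5 * np.log(2) + 0.5 * np.log(2 / 3)
    assert kl_sparsity(np.array([0.5]), 0.25) == pytest.approx(expect, abs=1e-12)
    assert kl_sparsity(np.array([0.3, 0.7]), 0.5) > 0
    with pytest.raises(ValueError):
        kl_sparsity(np.array([0.5]), 1.5)


def test_objective_components():
    cfg0 = SparsityConfig(alpha1=0.0, alpha2=0.0, rho0=0.05)
    # zero params on 0.5-batch: perfect reconstruction, KL = d * KL(0.5 || rho0)
    d = 6
    p = _zero_params(d, 4, d)
    batch = np.full((3, d), 0.5)
    assert objective(p, batch, cfg0) == pytest.approx(0.0, abs=1e-12)
    cfg = SparsityConfig(alpha1=0.0, alpha2=1.0, rho0=0.2)
    per_unit = 0.5 * np.log(0.5 / 0.2) + 0.5 * np.log(0.5 / 0.8)
    assert objective(p, batch, cfg) == pytest.approx(4 * per_unit, abs=1e-12)
    with pytest.raises(ValueError):
        objective(p, np.empty((0, d)), cfg)


@pytest.mark.parametrize(
    "alpha1,alpha2",
    [(0.0, 0.0), (1e-2, 0.0), (0.0, 0.5), (1e-2, 0.5)],
)
def test_gradients_match_central_finite_differences(gradcheck_net, alpha1, alpha2):
    params, batch = gradcheck_net["params"], gradcheck_net["batch"]
    cfg = SparsityConfig(alpha1=alpha1, alpha2=alpha2, rho0=0.05)
    g = gradients(params, batch, cfg)
    eps = 1e-6
    rng = np.random.default_rng(0)
    for attr in ("W_enc", "b_enc", "W_dec", "b_dec"):
        arr = getattr(g, attr)
        flat_idx = rng.choice(arr.size, size=min(10, arr.size), replace=False)
        for fi in flat_idx:
            idx = np.unravel_index(fi, arr.shape)
            for sign, store in ((+1, "fp"), (-1, "fm")):
                w = getattr(params, attr).copy()
                w[idx] += sign * eps
                pert = dataclasses.replace(params, **{attr: w})
                if sign > 0:
                    fp = objective(pert, batch, cfg)
                else:
                    fm = objective(pert, batch, cfg)
            num = (fp - fm) / (2 * eps)
            denom = max(abs(num), abs(arr[idx]), 1e-8)
            assert abs(arr[idx] - num) / denom < 1e-6


def test_objective_invariant_under_hidden_permutation(rng):
    params = initialize_params(6, 4, 6, seed=rng)
    batch = rng.random((5, 6))
    cfg = SparsityConfig(alpha1=1e-3, alpha2=0.3, rho0=0.1)
    perm = rng.permutation(4)
    permuted = AEParams(
        params.W_enc[:, perm], params.b_enc[perm], params.W_dec[perm, :], params.b_dec
    )
    assert objective(params, batch, cfg) == pytest.approx(
        objective(permuted, batch, cfg), rel=1e-12
    )


def test_training_decreases_objective(rng):
    batch = rng.uniform(0.1, 0.9, size=(50, 10))
    cfg = SparsityConfig(alpha1=1e-4, alpha2=0.05, rho0=0.1)
    _, history = train_autoencoder(
        batch, 6, cfg, learning_rate=0.3, epochs=60, rbm_init=False, seed=1
    )
    assert history[-1] < history[0]


def test_identity_approximation_on_repeated_patch(rng):
    # the reconstruction term drives F(W, b) toward the identity on its input
    patch = rng.uniform(0.2, 0.8, size=12)
    batch = np.tile(patch, (200, 1))
    cfg = SparsityConfig(alpha1=0.0, alpha2=0.0, rho0=0.05)
    params, _ = train_autoencoder(
        batch, 8, cfg, learning_rate=0.5, epochs=300, rbm_init=False, seed=0
    )
    o = decode(encode(patch, params), params)
    assert np.sum((o - patch) ** 2) < 1e-2


def test_training_determinism_without_rbm(rng):
    batch = rng.random((30, 8))
    kw = dict(learning_rate=0.2, epochs=20, rbm_init=False, seed=11)
    p1, h1 = train_autoencoder(batch, 5, None, **kw)
    p2, h2 = train_autoencoder(batch, 5, None, **kw)
    assert np.array_equal(p1.W_enc, p2.W_enc) and h1 == h2


def test_strong_sparsity_penalty_suppresses_activations(rng):
    batch = rng.uniform(0.0, 1.0, size=(100, 16))
    cfg = SparsityConfig(alpha1=0.0, alpha2=2.0, rho0=0.05)
    params, _ = train_autoencoder(
        batch, 10, cfg, learning_rate=0.3, epochs=100, rbm_init=False, seed=2
    )
    assert encode(batch, params).mean() < 0.2


def test_filter_images_layout(rng):
    params = initialize_params(3 * 49, 5, 3 * 49, seed=rng)
    imgs = filter_images(params, (7, 7))
    assert imgs.shape == (5, 3, 7, 7)
    assert np.array_equal(imgs[2, 1], params.W_enc[49:98, 2].reshape(7, 7))
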