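"""Restricted Boltzmann machine with CD-1 training, used to initialize
autoencoder layers.

The RBM is the standard bipartite energy model over visible units v and
hidden units h,

    E(v, h) = -b.v - c.h - v.W.h,      P(v, h) = exp(-E) / Z,

with factorized conditionals P(h_j=1|v) = sigma(W[:,j].v + c_j) and
P(v_i=1|h) = sigma(W[i,:].h + b_i).  Training maximizes the per-sample
data log-likelihood minus a Frobenius weight penalty,

    L = (1/N) sum_n log P(v_n) - (lambda/N) ||W||_F^2,

approximating the likelihood gradient by one step of contrastive
divergence.  Inputs in [0, 1] are treated as Bernoulli probabilities,
the usual convention when pretraining sigmoid layers on continuous data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import product

import numpy as np
from scipy.special import logsumexp

from ._utils import as_rng, sigmoid

__all__ = [
    "RBMParams",
    "energy",
    "cond_prob_hidden",
    "cond_prob_visible",
    "cd1_update",
    "exact_log_likelihood",
    "train_rbm",
]


@dataclass
class RBMParams:
    """Weights and biases: W (n_visible x n_hidden), b visible, c hidden."""

    W: np.ndarray
    b: np.ndarray
    c: np.ndarray
    lambda_reg: float = 0.0

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        self.b = np.asarray(self.b, dtype=float).ravel()
        self.c = np.asarray(self.c, dtype=float).ravel()
        if self.W.shape != (self.b.size, self.c.size):
            raise ValueError("W must be (len(b), len(c))")
        if not (np.all(np.isfinite(self.W)) and np.all(np.isfinite(self.b)) and np.all(np.isfinite(self.c))):
            raise ValueError("parameters must be finite")
        if self.lambda_reg < 0:
            raise ValueError("lambda_reg must be nonnegative")

    @property
    def n_visible(self) -> int:
        return self.b.size

    @property
    def n_hidden(self) -> int:
        return self.c.size


def initialize_rbm(
    n_visible: int, n_hidden: int, seed, scale: float = 0.01, lambda_reg: float = 0.0
) -> RBMParams:
    """Small-Gaussian weight init, zero biases."""
    rng = as_rng(seed)
    return RBMParams(
        W=scale * rng.standard_normal((n_visible, n_hidden)),
        b=np.zeros(n_visible),
        c=np.zeros(n_hidden),
        lambda_reg=lambda_reg,
    )


def energy(v: np.ndarray, h: np.ndarray, params: RBMParams) -> float:
    """E(v, h) = -b.v - c.h - v^T W h."""
    v = np.asarray(v, dtype=float).ravel()
    h = np.asarray(h, dtype=float).ravel()
    if v.size != params.n_visible or h.size != params.n_hidden:
        raise ValueError("v/h lengths do not match the RBM")
    return float(-params.b @ v - params.c @ h - v @ params.W @ h)


def cond_prob_hidden(v: np.ndarray, params: RBMParams) -> np.ndarray:
    """P(h_j = 1 | v) = sigma(sum_i W_ij v_i + c_j); accepts batches."""
    v = np.asarray(v, dtype=float)
    if v.shape[-1] != params.n_visible:
        raise ValueError("visible length mismatch")
    return sigmoid(v @ params.W + params.c)


def cond_prob_visible(h: np.ndarray, params: RBMParams) -> np.ndarray:
    """P(v_i = 1 | h) = sigma(sum_j W_ij h_j + b_i); accepts batches."""
    h = np.asarray(h, dtype=float)
    if h.shape[-1] != params.n_hidden:
        raise ValueError("hidden length mismatch")
    return sigmoid(h @ params.W.T + params.b)


def cd1_update(
    batch: np.ndarray, params: RBMParams, learning_rate: float, seed
) -> RBMParams:
    """One contrastive-divergence-1 step on a batch of visible vectors.

    Positive phase uses hidden probabilities given the data; the Gibbs
    half-cycle samples binary hiddens, reconstructs visibles mean-field,
    and recomputes hidden probabilities.  The weight gradient is
    <v h>_data - <v' h'>_recon minus the penalty gradient 2*lambda/N * W.
    """
    batch = np.atleast_2d(np.asarray(batch, dtype=float))
    if batch.size == 0:
        raise ValueError("empty batch")
    if np.any(batch < 0) or np.any(batch > 1):
        raise ValueError("batch values must lie in [0, 1]")
    if learning_rate <= 0:
        raise ValueError("learning_rate must be positive")
    rng = as_rng(seed)
    n = batch.shape[0]

    ph = cond_prob_hidden(batch, params)
    h_sample = (rng.random(ph.shape) < ph).astype(float)
    v_recon = cond_prob_visible(h_sample, params)
    ph_recon = cond_prob_hidden(v_recon, params)

    gW = (batch.T @ ph - v_recon.T @ ph_recon) / n - 2.0 * params.lambda_reg / n * params.W
    gb = (batch - v_recon).mean(axis=0)
    gc = (ph - ph_recon).mean(axis=0)
    return replace(
        params,
        W=params.W + learning_rate * gW,
        b=params.b + learning_rate * gb,
        c=params.c + learning_rate * gc,
    )


def _free_energy(params: RBMParams, v: np.ndarray) -> np.ndarray:
    """Unnormalized log p(v) = b.v + sum_j log(1 + exp(v.W_j + c_j))."""
    v = np.atleast_2d(v)
    act = v @ params.W + params.c
    return v @ params.b + np.sum(np.logaddexp(0.0, act), axis=1)


def exact_log_likelihood(params: RBMParams, data: np.ndarray) -> float:
    """Regularized data log-likelihood by exhaustive enumeration of Z.

    Only feasible on tiny machines (n_visible + n_hidden <= 20); used as
    the independent oracle for CD training.
    """
    if params.n_visible + params.n_hidden > 20:
        raise ValueError("state space too large for exact enumeration")
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n = data.shape[0]
    all_v = np.array(list(product((0.0, 1.0), repeat=params.n_visible)))
    log_z = logsumexp(_free_energy(params, all_v))
    mean_ll = float(np.mean(_free_energy(params, data) - log_z))
    return mean_ll - params.lambda_reg / n * float(np.sum(params.W**2))


def train_rbm(
    data: np.ndarray,
    n_hidden: int,
    epochs: int = 10,
    learning_rate: float = 0.1,
    batch_size: int | None = 128,
    lambda_reg: float = 0.0,
    seed=0,
) -> RBMParams:
    """Mini-batch CD-1 training, the pretraining pass for one AE layer."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    rng = as_rng(seed)
    params = initialize_rbm(data.shape[1], n_hidden, rng, lambda_reg=lambda_reg)
    n = data.shape[0]
    bs = n if batch_size is None else min(batch_size, n)
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, bs):
            params = cd1_update(data[order[start : start + bs]], params, learning_rate, rng)
    return params
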