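"""Single sparse autoencoder: encode/decode, three-term objective, exact
gradients, and training.

The objective on a batch {x_m} is

    (1/M) sum_m ||o_m - x_m||^2
        + alpha1 * (||W_enc||_F + ||W_dec||_F)
        + alpha2 * KL(rho_hat || rho0)

with h = sigma(W_enc^T x + b_enc), o = sigma(W_dec^T h + b_dec),
rho_hat the batch-mean hidden activation per unit, and

    KL(rho_hat||rho0) = sum_j [ rho_j log(rho_j/rho0)
                                + (1-rho_j) log((1-rho_j)/(1-rho0)) ].

The Frobenius term is unsquared by default (a squared variant is a config
switch); its gradient uses the convention d||W||_F = W/||W||_F, 0 at W=0.
Gradients are exact analytic backpropagation, including the KL term's
dependence on the encoder through rho_hat.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._utils import as_rng, sigmoid
from .rbm import train_rbm

__all__ = [
    "AEParams",
    "SparsityConfig",
    "encode",
    "decode",
    "kl_sparsity",
    "objective",
    "gradients",
    "train_autoencoder",
    "initialize_params",
    "filter_images",
]

_EPS = 1e-8


@dataclass
class AEParams:
    """Encoder/decoder weights.  W_enc: (n_in, n_hidden); W_dec: (n_hidden, n_out)."""

    W_enc: np.ndarray
    b_enc: np.ndarray
    W_dec: np.ndarray
    b_dec: np.ndarray

    def __post_init__(self):
        self.W_enc = np.asarray(self.W_enc, dtype=float)
        self.b_enc = np.asarray(self.b_enc, dtype=float).ravel()
        self.W_dec = np.asarray(self.W_dec, dtype=float)
        self.b_dec = np.asarray(self.b_dec, dtype=float).ravel()
        n_in, n_hidden = self.W_enc.shape
        if self.b_enc.size != n_hidden:
            raise ValueError("b_enc length must equal the hidden size")
        if self.W_dec.shape[0] != n_hidden:
            raise ValueError("W_dec rows must equal the hidden size")
        if self.b_dec.size != self.W_dec.shape[1]:
            raise ValueError("b_dec length must equal the output size")
        for arr in (self.W_enc, self.b_enc, self.W_dec, self.b_dec):
            if not np.all(np.isfinite(arr)):
                raise ValueError("parameters must be finite")

    @property
    def n_in(self) -> int:
        return self.W_enc.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.W_enc.shape[1]

    @property
    def n_out(self) -> int:
        return self.W_dec.shape[1]


@dataclass
class SparsityConfig:
    """Penalty weights: alpha1 (weight norm), alpha2 (KL sparsity), rho0 target."""

    alpha1: float = 1e-4
    alpha2: float = 0.1
    rho0: float = 0.05
    squared_frobenius: bool = False

    def __post_init__(self):
        if self.alpha1 < 0 or self.alpha2 < 0:
            raise ValueError("alpha1 and alpha2 must be nonnegative")
        if not 0.0 < self.rho0 < 1.0:
            raise ValueError("rho0 must lie in (0, 1)")


def encode(x: np.ndarray, params: AEParams) -> np.ndarray:
    """Hidden activations sigma(W_enc^T x + b_enc); accepts batches."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != params.n_in:
        raise ValueError(f"input length {x.shape[-1]} != n_in {params.n_in}")
    return sigmoid(x @ params.W_enc + params.b_enc)


def decode(h: np.ndarray, params: AEParams) -> np.ndarray:
    """Output activations sigma(W_dec^T h + b_dec); accepts batches."""
    h = np.asarray(h, dtype=float)
    if h.shape[-1] != params.n_hidden:
        raise ValueError(f"hidden length {h.shape[-1]} != n_hidden {params.n_hidden}")
    return sigmoid(h @ params.W_dec + params.b_dec)


def kl_sparsity(rho_hat: np.ndarray, rho0: float) -> float:
    """Bernoulli KL divergence of mean activations from the target rho0."""
    if not 0.0 < rho0 < 1.0:
        raise ValueError("rho0 must lie in (0, 1)")
    r = np.clip(np.asarray(rho_hat, dtype=float), _EPS, 1.0 - _EPS)
    return float(
        np.sum(r * np.log(r / rho0) + (1.0 - r) * np.log((1.0 - r) / (1.0 - rho0)))
    )


def _frob_penalty(W: np.ndarray, squared: bool) -> float:
    return float(np.sum(W**2)) if squared else float(np.linalg.norm(W))


def _frob_grad(W: np.ndarray, squared: bool) -> np.ndarray:
    if squared:
        return 2.0 * W
    norm = np.linalg.norm(W)
    return W / norm if norm > 0 else np.zeros_like(W)


def objective(params: AEParams, batch: np.ndarray, config: SparsityConfig) -> float:
    batch = np.atleast_2d(np.asarray(batch, dtype=float))
    if batch.size == 0:
        raise ValueError("empty batch")
    h = encode(batch, params)
    o = decode(h, params)
    rec = float(np.mean(np.sum((o - batch) ** 2, axis=1)))
    reg = config.alpha1 * (
        _frob_penalty(params.W_enc, config.squared_frobenius)
        + _frob_penalty(params.W_dec, config.squared_frobenius)
    )
    sparse = config.alpha2 * kl_sparsity(h.mean(axis=0), config.rho0)
    return rec + reg + sparse


def gradients(params: AEParams, batch: np.ndarray, config: SparsityConfig) -> AEParams:
    """Exact gradient of `objective`, packed in an AEParams-shaped structure."""
    batch = np.atleast_2d(np.asarray(batch, dtype=float))
    if batch.size == 0:
        raise ValueError("empty batch")
    m = batch.shape[0]
    h = encode(batch, params)
    o = decode(h, params)

    # reconstruction term
    delta_out = (2.0 / m) * (o - batch) * o * (1.0 - o)
    gW_dec = h.T @ delta_out
    gb_dec = delta_out.sum(axis=0)
    dh = delta_out @ params.W_dec.T

    # KL sparsity term through rho_hat = mean_m h
    rho = h.mean(axis=0)
    inside = (rho > _EPS) & (rho < 1.0 - _EPS)
    r = np.clip(rho, _EPS, 1.0 - _EPS)
    dkl = np.where(
        inside,
        np.log(r / config.rho0) - np.log((1.0 - r) / (1.0 - config.rho0)),
        0.0,  # clipped region: flat
    )
    dh = dh + config.alpha2 * dkl / m

    delta_hidden = dh * h * (1.0 - h)
    gW_enc = batch.T @ delta_hidden
    gb_enc = delta_hidden.sum(axis=0)

    gW_enc += config.alpha1 * _frob_grad(params.W_enc, config.squared_frobenius)
    gW_dec += config.alpha1 * _frob_grad(params.W_dec, config.squared_frobenius)
    return AEParams(gW_enc, gb_enc, gW_dec, gb_dec)


def initialize_params(
    n_in: int, n_hidden: int, n_out: int | None = None, seed=0, scale: float | None = None
) -> AEParams:
    """Seeded random init with the usual 1/sqrt(fan-in) scaling."""
    n_out = n_in if n_out is None else n_out
    rng = as_rng(seed)
    s1 = scale if scale is not None else 1.0 / np.sqrt(n_in)
    s2 = scale if scale is not None else 1.0 / np.sqrt(n_hidden)
    return AEParams(
        W_enc=s1 * rng.standard_normal((n_in, n_hidden)),
        b_enc=np.zeros(n_hidden),
        W_dec=s2 * rng.standard_normal((n_hidden, n_out)),
        b_dec=np.zeros(n_out),
    )


def train_autoencoder(
    batch: np.ndarray,
    n_hidden: int,
    config: SparsityConfig | None = None,
    learning_rate: float = 0.1,
    epochs: int = 400,
    batch_size: int | None = None,
    momentum: float = 0.9,
    rbm_init: bool = True,
    rbm_epochs: int = 5,
    rbm_learning_rate: float = 0.05,
    seed=0,
) -> tuple[AEParams, list[float]]:
    """Train one sparse autoencoder by (mini-batch) gradient descent with
    classical momentum.

    With ``rbm_init`` the encoder starts from CD-1-pretrained RBM weights
    (encoder gets (W, c), decoder (W^T, b)); otherwise from a seeded
    random init.  Returns the parameters and the per-epoch objective log.

    Raises if the objective becomes non-finite (divergence).
    """
    batch = np.atleast_2d(np.asarray(batch, dtype=float))
    if batch.size == 0:
        raise ValueError("empty training batch")
    if n_hidden < 1:
        raise ValueError("n_hidden must be positive")
    config = config or SparsityConfig()
    rng = as_rng(seed)

    if rbm_init:
        rbm = train_rbm(
            batch, n_hidden, epochs=rbm_epochs, learning_rate=rbm_learning_rate, seed=rng
        )
        params = AEParams(rbm.W, rbm.c, rbm.W.T.copy(), rbm.b)
    else:
        params = initialize_params(batch.shape[1], n_hidden, batch.shape[1], seed=rng)

    n = batch.shape[0]
    bs = n if batch_size is None else min(batch_size, n)
    history: list[float] = []
    vel = [np.zeros_like(a) for a in (params.W_enc, params.b_enc, params.W_dec, params.b_dec)]
    for _ in range(epochs):
        order = rng.permutation(n) if bs < n else np.arange(n)
        for start in range(0, n, bs):
            sub = batch[order[start : start + bs]]
            g = gradients(params, sub, config)
            grads = (g.W_enc, g.b_enc, g.W_dec, g.b_dec)
            vel = [momentum * v - learning_rate * gr for v, gr in zip(vel, grads)]
            params = AEParams(
                params.W_enc + vel[0],
                params.b_enc + vel[1],
                params.W_dec + vel[2],
                params.b_dec + vel[3],
            )
        obj = objective(params, batch, config)
        if not np.isfinite(obj):
            raise FloatingPointError(
                f"training diverged (objective={obj}); lower the learning rate"
            )
        history.append(obj)
    return params, history


def filter_images(params: AEParams, patch_size: tuple[int, int]) -> np.ndarray:
    """Render each hidden unit's input weights as patch images ("filters").

    For an input that concatenates F patches of shape (l, k), returns an
    array (n_hidden, F, l, k); hot pixels show which input structure the
    unit responds to (edges, blobs, gradients).
    """
    l, k = patch_size
    per = l * k
    if params.n_in % per != 0:
        raise ValueError("input size is not a multiple of the patch size")
    f = params.n_in // per
    return params.W_enc.T.reshape(params.n_hidden, f, l, k)
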