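"""Stacked sparse autoencoder training for dynamic-frame patch fusion.

Training inputs are patch rows: for a target frame i and an N-frame
temporal window (default N=3: frames i-1, i, i+1), the l x k patches at
one image position are flattened and concatenated frame-by-frame into one
row of length N*l*k.  Labels are the ground-truth patches of frame i at
the same position.  The stack is pretrained greedily — each layer is a
sparse autoencoder on the previous layer's hidden activations, with RBM
initialization — then a sigmoid output layer (h_s -> l*k) is appended and
the whole network is fine-tuned end to end against the labels by
mean-squared-error backpropagation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from ._utils import as_rng, sigmoid
from .autoencoder import SparsityConfig, train_autoencoder
from .mlem import ReconSeries

__all__ = [
    "PatchDataset",
    "SAEModel",
    "IdentityPatchModel",
    "extract_patches",
    "build_input_rows",
    "window_indices",
    "greedy_pretrain",
    "finetune",
    "predict_patch",
    "save_model",
    "load_model",
]


def window_indices(frame_index: int, n_frames: int, n_window: int = 3) -> list[int]:
    """Frame indices of the temporal window around ``frame_index``.

    The window is centered (n_window odd); at sequence boundaries the edge
    frame is replicated so the interface stays total.
    """
    if n_window < 1 or n_window % 2 == 0:
        raise ValueError("n_window must be a positive odd count")
    if not 0 <= frame_index < n_frames:
        raise ValueError("frame_index out of range")
    half = n_window // 2
    return [min(max(frame_index + off, 0), n_frames - 1) for off in range(-half, half + 1)]


@dataclass
class PatchDataset:
    """Concatenated per-frame patch rows with optional ground-truth labels.

    ``normalization`` stores the affine map (vmin, vmax) under which
    values were brought to [0, 1]; predictions are mapped back through its
    inverse.
    """

    inputs: np.ndarray  # (M, n_frames_in * l * k), in [0, 1]
    labels: np.ndarray | None  # (M, l * k), in [0, 1]
    patch_size: tuple[int, int]
    n_frames_in: int
    frame_index: int
    normalization: tuple[float, float]

    def __post_init__(self):
        l, k = self.patch_size
        if self.inputs.shape[1] != self.n_frames_in * l * k:
            raise ValueError("input row length must be n_frames_in * l * k")
        if self.labels is not None and self.labels.shape != (self.inputs.shape[0], l * k):
            raise ValueError("labels must be (M, l * k)")

    @property
    def n_rows(self) -> int:
        return self.inputs.shape[0]


def normalize(values: np.ndarray, normalization: tuple[float, float]) -> np.ndarray:
    vmin, vmax = normalization
    span = vmax - vmin
    if span <= 0:
        return np.zeros_like(np.asarray(values, dtype=float))
    return (np.asarray(values, dtype=float) - vmin) / span


def denormalize(values: np.ndarray, normalization: tuple[float, float]) -> np.ndarray:
    vmin, vmax = normalization
    return np.asarray(values, dtype=float) * (vmax - vmin) + vmin


def _frame_stack(recon) -> np.ndarray:
    if isinstance(recon, ReconSeries):
        return recon.images
    arr = np.asarray(recon, dtype=float)
    if arr.ndim != 3:
        raise ValueError("expected a (n_frames, rows, cols) stack")
    return arr


def _patch_rows(image: np.ndarray, patch_size: tuple[int, int], stride: int) -> np.ndarray:
    l, k = patch_size
    win = np.lib.stride_tricks.sliding_window_view(image, (l, k))[::stride, ::stride]
    return win.reshape(-1, l * k)


def build_input_rows(
    frames: np.ndarray,
    frame_index: int,
    patch_size: tuple[int, int] = (7, 7),
    stride: int = 1,
    n_frames_in: int = 3,
) -> np.ndarray:
    """Raw (unnormalized) input rows for every interior patch position.

    Row layout: the window frames in temporal order, each patch flattened
    row-major.  Position order is row-major over patch top-left corners.
    """
    frames = _frame_stack(frames)
    l, k = patch_size
    rows_img, cols_img = frames.shape[1:]
    if l > rows_img or k > cols_img:
        raise ValueError("patch larger than the image")
    idx = window_indices(frame_index, frames.shape[0], n_frames_in)
    return np.concatenate(
        [_patch_rows(frames[j], patch_size, stride) for j in idx], axis=1
    )


def extract_patches(
    recon,
    truth=None,
    frame_index: int = 1,
    patch_size: tuple[int, int] = (7, 7),
    stride: int = 1,
    n_frames_in: int = 3,
    normalization: tuple[float, float] | None = None,
) -> PatchDataset:
    """Build a patch dataset from a reconstruction series (frames are
    0-indexed).

    When ``truth`` (a DynamicPhantom or frame stack) is given, labels are
    the truth patches of frame ``frame_index``.  ``normalization`` may be
    supplied to share one affine map across several phantoms; by default
    it is computed as (0, max over inputs and labels).
    """
    frames = _frame_stack(recon)
    inputs = build_input_rows(frames, frame_index, patch_size, stride, n_frames_in)
    labels = None
    if truth is not None:
        t = _frame_stack(getattr(truth, "frames", truth))
        if t.shape != frames.shape:
            raise ValueError("truth and reconstruction shapes differ")
        labels = _patch_rows(t[frame_index], patch_size, stride)
    if normalization is None:
        vmax = max(float(inputs.max()), float(labels.max()) if labels is not None else 0.0)
        normalization = (0.0, vmax if vmax > 0 else 1.0)
    inputs = np.clip(normalize(inputs, normalization), 0.0, 1.0)
    if labels is not None:
        labels = np.clip(normalize(labels, normalization), 0.0, 1.0)
    return PatchDataset(
        inputs=inputs,
        labels=labels,
        patch_size=patch_size,
        n_frames_in=n_frames_in,
        frame_index=frame_index,
        normalization=normalization,
    )


def concat_datasets(datasets: list[PatchDataset]) -> PatchDataset:
    """Stack datasets that share patch geometry and normalization."""
    first = datasets[0]
    for d in datasets[1:]:
        if (
            d.patch_size != first.patch_size
            or d.n_frames_in != first.n_frames_in
            or d.normalization != first.normalization
        ):
            raise ValueError("datasets must share geometry and normalization")
    labels = None
    if all(d.labels is not None for d in datasets):
        labels = np.concatenate([d.labels for d in datasets])
    return PatchDataset(
        inputs=np.concatenate([d.inputs for d in datasets]),
        labels=labels,
        patch_size=first.patch_size,
        n_frames_in=first.n_frames_in,
        frame_index=first.frame_index,
        normalization=first.normalization,
    )


@dataclass
class SAEModel:
    """Trained encoder stack plus supervised output layer.

    ``encoders`` is the ordered list of (W, b) sigmoid layers
    (n_in -> h_1 -> ... -> h_s); ``W_out``/``b_out`` map h_s to the l*k
    output patch through a final sigmoid.
    """

    encoders: list[tuple[np.ndarray, np.ndarray]]
    W_out: np.ndarray
    b_out: np.ndarray
    config: SparsityConfig
    patch_size: tuple[int, int]
    n_frames_in: int
    frame_index: int
    normalization: tuple[float, float]
    seed: int | None = None
    history: list[float] = field(default_factory=list, repr=False)

    @property
    def n_in(self) -> int:
        return self.encoders[0][0].shape[0]

    @property
    def hidden_sizes(self) -> tuple[int, ...]:
        return tuple(w.shape[1] for w, _ in self.encoders)

    def forward(self, rows: np.ndarray) -> np.ndarray:
        """Normalized rows -> normalized predicted patches in [0, 1]."""
        a = np.atleast_2d(np.asarray(rows, dtype=float))
        if a.shape[1] != self.n_in:
            raise ValueError(f"row length {a.shape[1]} != model input {self.n_in}")
        for w, b in self.encoders:
            a = sigmoid(a @ w + b)
        return sigmoid(a @ self.W_out + self.b_out)

    def predict(self, rows: np.ndarray, denorm: bool = False) -> np.ndarray:
        out = self.forward(rows)
        return denormalize(out, self.normalization) if denorm else out


class IdentityPatchModel:
    """Oracle model that returns the middle-frame patch of its input row.

    Shares the SAEModel prediction interface; used to validate the patch
    sweep independently of any training.
    """

    def __init__(self, patch_size=(7, 7), n_frames_in=3, frame_index=0,
                 normalization=(0.0, 1.0)):
        self.patch_size = tuple(patch_size)
        self.n_frames_in = n_frames_in
        self.frame_index = frame_index
        self.normalization = tuple(normalization)

    def predict(self, rows: np.ndarray, denorm: bool = False) -> np.ndarray:
        rows = np.atleast_2d(np.asarray(rows, dtype=float))
        per = self.patch_size[0] * self.patch_size[1]
        mid = self.n_frames_in // 2
        out = rows[:, mid * per : (mid + 1) * per]
        return denormalize(out, self.normalization) if denorm else out


def greedy_pretrain(
    dataset: PatchDataset,
    hidden_sizes: tuple[int, ...] = (200, 100),
    config: SparsityConfig | None = None,
    learning_rate: float = 0.1,
    epochs: int = 50,
    batch_size: int | None = 256,
    rbm_init: bool = True,
    rbm_epochs: int = 5,
    seed=0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Layer-wise sparse-AE pretraining of the encoder stack.

    Layer t is trained on the hidden activations of layer t-1 (layer 1 on
    the raw rows); intermediate decoders are discarded.  With a single
    hidden size this is exactly one `train_autoencoder` call.
    """
    if not hidden_sizes:
        raise ValueError("hidden_sizes must be nonempty")
    config = config or SparsityConfig()
    rng = as_rng(seed)
    x = dataset.inputs
    encoders = []
    for h in hidden_sizes:
        params, _ = train_autoencoder(
            x,
            h,
            config=config,
            learning_rate=learning_rate,
            epochs=epochs,
            batch_size=batch_size,
            rbm_init=rbm_init,
            rbm_epochs=rbm_epochs,
            seed=rng,
        )
        encoders.append((params.W_enc, params.b_enc))
        x = sigmoid(x @ params.W_enc + params.b_enc)
    return encoders


def _forward_all(rows, layers):
    acts = [np.atleast_2d(np.asarray(rows, dtype=float))]
    for w, b in layers:
        acts.append(sigmoid(acts[-1] @ w + b))
    return acts


def finetune(
    encoders: list[tuple[np.ndarray, np.ndarray]],
    dataset: PatchDataset,
    config: SparsityConfig | None = None,
    learning_rate: float = 0.1,
    epochs: int = 100,
    batch_size: int | None = 256,
    momentum: float = 0.9,
    lr_decay: float = 1.0,
    update_all: bool = True,
    seed=0,
) -> SAEModel:
    """Append the supervised output layer and fine-tune against labels.

    Minimizes the mean squared error between predicted and ground-truth
    patches by momentum backpropagation through the whole stack (or
    through the output layer alone when ``update_all`` is off).  The
    output bias starts at the logit of the mean label value so the net
    begins at the right overall intensity.  Aborts on NaN loss.
    """
    if dataset.labels is None:
        raise ValueError("fine-tuning needs ground-truth labels")
    config = config or SparsityConfig()
    rng = as_rng(seed)
    l, k = dataset.patch_size
    h_s = encoders[-1][0].shape[1]
    layers = [(w.copy(), b.copy()) for w, b in encoders]
    ybar = np.clip(dataset.labels.mean(axis=0), 1e-4, 1.0 - 1e-4)
    layers.append(
        (rng.standard_normal((h_s, l * k)) / np.sqrt(h_s), np.log(ybar / (1.0 - ybar)))
    )

    x, y = dataset.inputs, dataset.labels
    n = x.shape[0]
    bs = n if batch_size is None else min(batch_size, n)
    history = []
    vel = [(np.zeros_like(w), np.zeros_like(b)) for w, b in layers]
    lr = learning_rate
    for _ in range(epochs):
        order = rng.permutation(n) if bs < n else np.arange(n)
        for start in range(0, n, bs):
            sub = order[start : start + bs]
            acts = _forward_all(x[sub], layers)
            m = len(sub)
            delta = (2.0 / m) * (acts[-1] - y[sub]) * acts[-1] * (1.0 - acts[-1])
            lowest = 0 if update_all else len(layers) - 1
            for t in range(len(layers) - 1, lowest - 1, -1):
                w, b = layers[t]
                gw = acts[t].T @ delta
                gb = delta.sum(axis=0)
                if t > lowest:
                    delta = (delta @ w.T) * acts[t] * (1.0 - acts[t])
                vw, vb = vel[t]
                vw = momentum * vw - lr * gw
                vb = momentum * vb - lr * gb
                vel[t] = (vw, vb)
                layers[t] = (w + vw, b + vb)
        lr *= lr_decay
        loss = float(np.mean(np.sum((_forward_all(x, layers)[-1] - y) ** 2, axis=1)))
        if not np.isfinite(loss):
            raise FloatingPointError("fine-tuning diverged (loss is not finite)")
        history.append(loss)

    return SAEModel(
        encoders=layers[:-1],
        W_out=layers[-1][0],
        b_out=layers[-1][1],
        config=config,
        patch_size=dataset.patch_size,
        n_frames_in=dataset.n_frames_in,
        frame_index=dataset.frame_index,
        normalization=dataset.normalization,
        history=history,
    )


def predict_patch(model: SAEModel, input_row: np.ndarray, denorm: bool = False) -> np.ndarray:
    """Forward one (or a batch of) normalized input row(s) through the model."""
    out = model.predict(input_row, denorm=denorm)
    return out[0] if np.asarray(input_row).ndim == 1 else out


def save_model(model: SAEModel, path: str) -> None:
    with h5py.File(path, "w") as f:
        for t, (w, b) in enumerate(model.encoders):
            g = f.create_group(f"encoder_{t}")
            g.create_dataset("W", data=w)
            g.create_dataset("b", data=b)
        g = f.create_group("output")
        g.create_dataset("W", data=model.W_out)
        g.create_dataset("b", data=model.b_out)
        if model.history:
            f.create_dataset("history", data=np.asarray(model.history))
        f.attrs.update(
            {
                "n_encoders": len(model.encoders),
                "patch_size": model.patch_size,
                "n_frames_in": model.n_frames_in,
                "frame_index": model.frame_index,
                "normalization": model.normalization,
                "alpha1": model.config.alpha1,
                "alpha2": model.config.alpha2,
                "rho0": model.config.rho0,
                "squared_frobenius": model.config.squared_frobenius,
            }
        )
        if model.seed is not None:
            f.attrs["seed"] = model.seed


def load_model(path: str) -> SAEModel:
    with h5py.File(path, "r") as f:
        encoders = [
            (f[f"encoder_{t}/W"][()], f[f"encoder_{t}/b"][()])
            for t in range(int(f.attrs["n_encoders"]))
        ]
        return SAEModel(
            encoders=encoders,
            W_out=f["output/W"][()],
            b_out=f["output/b"][()],
            config=SparsityConfig(
                alpha1=float(f.attrs["alpha1"]),
                alpha2=float(f.attrs["alpha2"]),
                rho0=float(f.attrs["rho0"]),
                squared_frobenius=bool(f.attrs["squared_frobenius"]),
            ),
            patch_size=tuple(int(v) for v in f.attrs["patch_size"]),
            n_frames_in=int(f.attrs["n_frames_in"]),
            frame_index=int(f.attrs["frame_index"]),
            normalization=tuple(float(v) for v in f.attrs["normalization"]),
            seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
            history=list(f["history"][()]) if "history" in f else [],
        )
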