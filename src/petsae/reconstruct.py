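"""Patch-sweep reconstruction: run every patch position of an MLEM series
through the trained network and assemble the target-frame estimate.

At each interior center position the temporal-window input row is built
exactly as during training, predicted, de-normalized, and condensed to a
scalar by a Gaussian-weighted average of the predicted patch ("center"
mode, the default).  An overlap-add mode that accumulates whole weighted
patches is available for comparison.  The border band that no full patch
covers is filled from the MLEM image of the target frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mlem import ReconSeries
from .sae import build_input_rows, normalize, _frame_stack

__all__ = ["GaussianKernel", "gaussian_kernel", "reconstruct_frame"]


@dataclass
class GaussianKernel:
    """Normalized, center-symmetric l x k weighting window."""

    weights: np.ndarray
    sigma: float

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0):
            raise ValueError("kernel weights must be nonnegative")
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("kernel weights must sum to 1")


def gaussian_kernel(patch_size: tuple[int, int], sigma: float) -> GaussianKernel:
    """Isotropic Gaussian window exp(-d^2/(2 sigma^2)), normalized to sum 1.

    Patch sides must be odd so the center pixel is defined.  sigma -> inf
    tends to uniform weights; sigma -> 0 to a delta at the center.
    """
    l, k = patch_size
    if l % 2 == 0 or k % 2 == 0:
        raise ValueError("patch sides must be odd (center pixel undefined otherwise)")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    r0, c0 = l // 2, k // 2
    rr, cc = np.mgrid[0:l, 0:k]
    d2 = (rr - r0) ** 2 + (cc - c0) ** 2
    w = np.exp(-d2 / (2.0 * sigma**2))
    if w.sum() == 0:  # extreme underflow: keep the center
        w[r0, c0] = 1.0
    return GaussianKernel(weights=w / w.sum(), sigma=float(sigma))


def reconstruct_frame(
    model,
    recon: ReconSeries,
    frame_index: int,
    kernel: GaussianKernel | None = None,
    mode: str = "center",
    batch_size: int = 4096,
) -> np.ndarray:
    """Estimate the activity image of one frame from the MLEM series.

    Parameters
    ----------
    model : SAEModel or any object with patch metadata and a
        ``predict(rows, denorm=...)`` method.
    recon : the per-frame MLEM reconstruction series (or a frame stack).
    frame_index : 0-based target frame.
    kernel : Gaussian window; default sigma = (patch side)/4.
    mode : 'center' condenses each predicted patch to one scalar at its
        center; 'overlap' accumulates kernel-weighted whole patches and
        normalizes by the accumulated weight.
    """
    frames = _frame_stack(recon)
    l, k = model.patch_size
    if kernel is None:
        kernel = gaussian_kernel((l, k), sigma=l / 4.0)
    if kernel.weights.shape != (l, k):
        raise ValueError("kernel shape does not match the model patch size")
    if mode not in ("center", "overlap"):
        raise ValueError(f"unknown aggregation mode: {mode!r}")
    rows_img, cols_img = frames.shape[1:]
    if l > rows_img or k > cols_img:
        raise ValueError("patch larger than the image")

    raw = build_input_rows(frames, frame_index, (l, k), 1, model.n_frames_in)
    rows = np.clip(normalize(raw, model.normalization), 0.0, 1.0)
    preds = np.concatenate(
        [
            model.predict(rows[s : s + batch_size], denorm=True)
            for s in range(0, rows.shape[0], batch_size)
        ]
    )

    out = frames[frame_index].astype(float).copy()  # border band = MLEM passthrough
    n_r, n_c = rows_img - l + 1, cols_img - k + 1
    if mode == "center":
        centers = preds @ kernel.weights.ravel()
        out[l // 2 : l // 2 + n_r, k // 2 : k // 2 + n_c] = centers.reshape(n_r, n_c)
    else:
        acc = np.zeros_like(out)
        wacc = np.zeros_like(out)
        patches = preds.reshape(n_r, n_c, l, k)
        for dr in range(l):
            for dc in range(k):
                acc[dr : dr + n_r, dc : dc + n_c] += (
                    kernel.weights[dr, dc] * patches[:, :, dr, dc]
                )
                wacc[dr : dr + n_r, dc : dc + n_c] += kernel.weights[dr, dc]
        covered = wacc > 0
        out[covered] = acc[covered] / wacc[covered]
    return np.maximum(out, 0.0)
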