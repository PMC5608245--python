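"""Image-quality indexes: SNR (dB), bias, and variance, per ROI and frame.

With reconstruction values u, ground truth u_hat and ROI size n:

    SNR      = 20 log10( peak / RMSE ),   RMSE = sqrt( mean (u - u_hat)^2 )
    Bias     = mean( (u - u_hat) / u_hat )
    Variance = mean( ((u - u_bar) / u_hat)^2 ),  u_bar = ROI mean of u

SNR follows the standard peak-signal convention with peak 255 after both
images are mapped to the 0-255 range (truth maximum -> 255); a literal
no-square-root variant is available.  Pixels with zero truth are excluded
from bias/variance (the ratio is undefined there) and the exclusion count
is reported.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["compute_snr", "compute_bias", "compute_variance", "roi_report"]


def compute_snr(
    u: np.ndarray, u_hat: np.ndarray, peak: float = 255.0, sqrt_mse: bool = True
) -> float:
    """Peak-signal-to-noise ratio in dB; +inf when u equals u_hat exactly."""
    u = np.asarray(u, dtype=float).ravel()
    u_hat = np.asarray(u_hat, dtype=float).ravel()
    if u.size == 0:
        raise ValueError("empty input")
    if u.shape != u_hat.shape:
        raise ValueError("shape mismatch")
    mse = float(np.mean((u - u_hat) ** 2))
    if mse == 0.0:
        return np.inf
    denom = np.sqrt(mse) if sqrt_mse else mse
    return float(20.0 * np.log10(peak / denom))


def _ratio_inputs(u, u_hat):
    u = np.asarray(u, dtype=float).ravel()
    u_hat = np.asarray(u_hat, dtype=float).ravel()
    if u.shape != u_hat.shape:
        raise ValueError("shape mismatch")
    keep = u_hat > 0
    if not np.any(keep):
        raise ValueError("no pixels with positive ground truth")
    return u[keep], u_hat[keep], int(np.sum(~keep))


def compute_bias(u: np.ndarray, u_hat: np.ndarray) -> float:
    """Mean relative error; zero-truth pixels are excluded."""
    uu, hh, _ = _ratio_inputs(u, u_hat)
    return float(np.mean((uu - hh) / hh))


def compute_variance(u: np.ndarray, u_hat: np.ndarray) -> float:
    """Mean squared truth-relative deviation of u from its own ROI mean."""
    uu, hh, _ = _ratio_inputs(u, u_hat)
    return float(np.mean(((uu - uu.mean()) / hh) ** 2))


def roi_report(
    recon_frames: np.ndarray,
    truth_frames: np.ndarray,
    masks: dict[str, np.ndarray],
    peak: float = 255.0,
    sqrt_mse: bool = True,
) -> pd.DataFrame:
    """All three indexes for every (ROI, frame) pair.

    For SNR both images of a frame are rescaled so the truth maximum maps
    to ``peak``; bias and variance are scale-invariant and use raw values.
    Empty masks are skipped with a warning.
    """
    recon_frames = np.asarray(recon_frames, dtype=float)
    truth_frames = np.asarray(truth_frames, dtype=float)
    if recon_frames.shape != truth_frames.shape:
        raise ValueError("reconstruction and truth shapes differ")
    rows = []
    for name, mask in masks.items():
        if not np.any(mask):
            warnings.warn(f"empty mask {name!r}: row skipped")
            continue
        for i in range(recon_frames.shape[0]):
            u, u_hat = recon_frames[i][mask], truth_frames[i][mask]
            tmax = truth_frames[i].max()
            factor = peak / tmax if tmax > 0 else 1.0
            uu, hh, n_excl = _ratio_inputs(u, u_hat)
            rows.append(
                {
                    "roi": name,
                    "frame": i,
                    "snr_db": compute_snr(u * factor, u_hat * factor, peak, sqrt_mse),
                    "bias": float(np.mean((uu - hh) / hh)),
                    "variance": float(np.mean(((uu - uu.mean()) / hh) ** 2)),
                    "n_pixels": int(np.sum(mask)),
                    "n_excluded": n_excl,
                }
            )
    return pd.DataFrame(rows)
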