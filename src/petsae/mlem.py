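"""Per-frame MLEM reconstruction of dynamic sinograms.

Implements the classical Shepp–Vardi multiplicative update for the Poisson
emission model y_q ~ Poisson((G x)_q):

    x  <-  (x / s) * G^T ( y / (G x) ),    s = G^T 1.

Each EM iteration provably does not decrease the Poisson log-likelihood,
and under strictly positive sensitivity it preserves total counts
(sum of G x equals sum of y after every full update).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .projection import SinogramSeries, SystemMatrix

__all__ = [
    "ReconSeries",
    "mlem_reconstruct",
    "poisson_log_likelihood",
    "save_recon",
    "load_recon",
]


@dataclass
class ReconSeries:
    """Nonnegative per-frame reconstructed activity maps."""

    images: np.ndarray  # (n_frames, rows, cols)
    n_iterations: int
    n_angles: int
    n_radial_bins: int
    grid_size: tuple[int, int]
    log_likelihood: np.ndarray | None = field(default=None, repr=False)
    # (n_frames, n_iterations) likelihood trace when tracking is on

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=float)
        if self.images.ndim != 3:
            raise ValueError("images must be (n_frames, rows, cols)")
        if np.any(self.images < 0):
            raise ValueError("reconstructed activity must be nonnegative")

    @property
    def n_frames(self) -> int:
        return self.images.shape[0]


def poisson_log_likelihood(
    G: SystemMatrix, image: np.ndarray, counts: np.ndarray
) -> float:
    """Poisson log-likelihood sum_q [ y_q log(ybar_q) - ybar_q ].

    The data-only log(y!) term is dropped.  Bins with ybar = 0 and y = 0
    contribute zero; ybar = 0 with y > 0 yields -inf (impossible data under
    the model).
    """
    image = np.asarray(image, dtype=float)
    counts = np.asarray(counts, dtype=float).ravel()
    if image.size != G.n_voxels:
        raise ValueError("image size does not match the system matrix")
    if counts.size != G.n_bins:
        raise ValueError("counts size does not match the system matrix")
    if np.any(image < 0):
        raise ValueError("image must be nonnegative")
    ybar = G.project(image)
    ll = 0.0
    pos = ybar > 0
    ll += float(np.sum(counts[pos] * np.log(ybar[pos]) - ybar[pos]))
    bad = (~pos) & (counts > 0)
    if np.any(bad):
        warnings.warn("zero expectation in bins with observed counts; likelihood -inf")
        return -np.inf
    return ll


def mlem_reconstruct(
    G: SystemMatrix,
    sinogram: SinogramSeries,
    n_iterations: int = 50,
    init: np.ndarray | None = None,
    track_likelihood: bool = False,
    rel_tol: float | None = None,
) -> ReconSeries:
    """Run MLEM independently on every frame of a sinogram series.

    Parameters
    ----------
    n_iterations : maximum EM iterations per frame (default 50).
    init : optional strictly positive starting image (on the support of the
        sensitivity).  Default is a uniform image with value
        sum(y) / sum(sensitivity), which starts the iteration at the
        correct total activity.
    track_likelihood : record the per-iteration Poisson log-likelihood.
    rel_tol : optional early stop when the relative likelihood increase
        falls below this value (implies tracking).
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    y_all = sinogram.data
    if np.any(y_all < 0):
        raise ValueError("negative counts are not valid Poisson data")
    if y_all.shape[1] != G.n_bins:
        raise ValueError("sinogram bins do not match the system matrix")

    sens = G.sensitivity().ravel()
    alive = sens > 0
    if not np.all(alive):
        warnings.warn(
            f"{int(np.sum(~alive))} voxels have zero sensitivity and are held at 0"
        )
    sens_safe = np.where(alive, sens, 1.0)

    track = track_likelihood or rel_tol is not None
    n_frames = y_all.shape[0]
    images = np.zeros((n_frames, *G.grid_size))
    traces = np.full((n_frames, n_iterations), np.nan) if track else None

    for i in range(n_frames):
        y = y_all[i]
        if init is None:
            total = y.sum()
            x = np.where(alive, total / sens.sum() if total > 0 else 0.0, 0.0)
        else:
            x = np.asarray(init, dtype=float).ravel().copy()
            if x.size != G.n_voxels:
                raise ValueError("init image size mismatch")
            if np.any(x[alive] <= 0) and y.sum() > 0:
                raise ValueError("init must be strictly positive on the support")
            x[~alive] = 0.0
        prev_ll = -np.inf
        for it in range(n_iterations):
            proj = G.weights @ x
            ratio = np.divide(y, proj, out=np.zeros_like(proj), where=proj > 0)
            x = x / sens_safe * (G.weights.T @ ratio)
            x[~alive] = 0.0
            if track:
                ll = poisson_log_likelihood(G, x, y)
                traces[i, it] = ll
                if rel_tol is not None and np.isfinite(prev_ll):
                    denom = max(abs(prev_ll), 1.0)
                    if (ll - prev_ll) / denom < rel_tol:
                        break
                prev_ll = ll
        images[i] = np.maximum(x, 0.0).reshape(G.grid_size)

    return ReconSeries(
        images=images,
        n_iterations=n_iterations,
        n_angles=sinogram.n_angles,
        n_radial_bins=sinogram.n_radial_bins,
        grid_size=G.grid_size,
        log_likelihood=traces,
    )


def save_recon(recon: ReconSeries, path: str) -> None:
    """Persist a reconstruction series as NIfTI (frames on the 3rd axis)."""
    vol = np.moveaxis(recon.images, 0, -1)
    img = nib.Nifti1Image(vol, affine=np.eye(4))
    img.header["descrip"] = f"mlem iters={recon.n_iterations}".encode()
    nib.save(img, path)


def load_recon(path: str, n_angles: int = 0, n_radial_bins: int = 0) -> ReconSeries:
    vol = np.asarray(nib.load(path).dataobj, dtype=float)
    images = np.moveaxis(vol, -1, 0)
    return ReconSeries(
        images=images,
        n_iterations=0,
        n_angles=n_angles,
        n_radial_bins=n_radial_bins,
        grid_size=images.shape[1:],
    )
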