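"""Parallel-beam system matrix, noiseless projection, and Poisson sampling.

This module is the desk-scale stand-in for a full Monte Carlo scanner
simulation.  The system matrix ``G`` holds exact ray/pixel intersection
lengths for a parallel-beam geometry: rays span [0, pi) uniformly in angle
and cross the grid at uniformly spaced radial offsets.  Expected sinograms
are ``G @ vec(frame)`` per frame; observed sinograms are independent
Poisson draws around the expectation after rescaling to a total-count
budget (the "counting rate").

Pixel convention: unit pixels, image coordinates with the origin at the
grid corner, pixel (r, c) covering [r, r+1) x [c, c+1); rays are measured
from the grid center.  The field of view is the inscribed circle.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
import scipy.sparse as sp

from .phantoms import DynamicPhantom

__all__ = [
    "SystemMatrix",
    "SinogramSeries",
    "build_system_matrix",
    "forward_project",
    "scale_to_counts",
    "sample_poisson",
    "fov_mask",
    "save_sinogram",
    "load_sinogram",
]


@dataclass
class SystemMatrix:
    """Nonnegative sparse (n_bins x n_voxels) projection weights.

    Entry (q, p) is the intersection length of ray q with pixel p — the
    geometric surrogate for the probability that a photon emitted in voxel
    p is detected in bin q.
    """

    weights: sp.csr_matrix
    n_angles: int
    n_radial_bins: int
    grid_size: tuple[int, int]

    @property
    def n_bins(self) -> int:
        return self.n_angles * self.n_radial_bins

    @property
    def n_voxels(self) -> int:
        return self.grid_size[0] * self.grid_size[1]

    def project(self, image: np.ndarray) -> np.ndarray:
        """Forward-project one image (any shape flattening to n_voxels)."""
        return self.weights @ np.asarray(image, dtype=float).ravel()

    def backproject(self, sino: np.ndarray) -> np.ndarray:
        """Transpose operation, returned on the image grid."""
        return (self.weights.T @ np.asarray(sino, dtype=float).ravel()).reshape(
            self.grid_size
        )

    def sensitivity(self) -> np.ndarray:
        """Backprojection of ones: per-pixel detection sensitivity."""
        return self.backproject(np.ones(self.n_bins))


@dataclass
class SinogramSeries:
    """Per-frame detector counts and/or their expectation.

    ``counts`` holds observed (Poisson-sampled, whole-number) data;
    ``expected`` the noiseless mean.  Either may be absent.
    """

    counts: np.ndarray | None
    expected: np.ndarray | None
    n_angles: int
    n_radial_bins: int
    grid_size: tuple[int, int]
    seed: int | None = None
    total_counts: float | None = None
    scale: float = 1.0  # factor applied to reach the count budget

    def __post_init__(self):
        if self.counts is None and self.expected is None:
            raise ValueError("need counts or expected")
        for name in ("counts", "expected"):
            arr = getattr(self, name)
            if arr is None:
                continue
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2:
                raise ValueError(f"{name} must be (n_frames, n_bins)")
            if np.any(arr < 0):
                raise ValueError(f"{name} must be nonnegative")
            setattr(self, name, arr)
        if (
            self.counts is not None
            and self.expected is not None
            and self.counts.shape != self.expected.shape
        ):
            raise ValueError("counts and expected shapes differ")

    @property
    def n_frames(self) -> int:
        arr = self.counts if self.counts is not None else self.expected
        return arr.shape[0]

    @property
    def data(self) -> np.ndarray:
        """Observed counts if present, else the noiseless expectation."""
        return self.counts if self.counts is not None else self.expected


def _ray_pixel_lengths(theta: float, tau: float, grid_size: tuple[int, int]):
    """Exact intersection lengths of one ray with every pixel it crosses.

    The ray is the line {x cos(theta) + y sin(theta) = tau} with tau
    measured from the grid center; x is the column coordinate, y the row
    coordinate.  Returns (flat pixel indices, lengths).
    """
    rows, cols = grid_size
    ct, st = np.cos(theta), np.sin(theta)
    # point on the line nearest the grid center, then march along direction d
    cx, cy = cols / 2.0, rows / 2.0
    px, py = cx + tau * ct, cy + tau * st
    dx, dy = -st, ct

    ts = []
    # entry/exit with the bounding box via slab clipping
    t0, t1 = -np.inf, np.inf
    for p, d, lo, hi in ((px, dx, 0.0, float(cols)), (py, dy, 0.0, float(rows))):
        if abs(d) < 1e-14:
            if p < lo or p > hi:
                return np.empty(0, dtype=int), np.empty(0)
        else:
            ta, tb = (lo - p) / d, (hi - p) / d
            t0, t1 = max(t0, min(ta, tb)), min(t1, max(ta, tb))
    if not t1 > t0:
        return np.empty(0, dtype=int), np.empty(0)

    ts.append(t0)
    ts.append(t1)
    if abs(dx) > 1e-14:
        i = np.arange(0, cols + 1)
        ts.extend(((i - px) / dx).tolist())
    if abs(dy) > 1e-14:
        j = np.arange(0, rows + 1)
        ts.extend(((j - py) / dy).tolist())
    ts = np.asarray(ts)
    ts = np.unique(ts[(ts >= t0 - 1e-12) & (ts <= t1 + 1e-12)])
    if ts.size < 2:
        return np.empty(0, dtype=int), np.empty(0)

    mids = 0.5 * (ts[:-1] + ts[1:])
    lens = np.diff(ts)
    mx, my = px + mids * dx, py + mids * dy
    col = np.floor(mx).astype(int)
    row = np.floor(my).astype(int)
    keep = (col >= 0) & (col < cols) & (row >= 0) & (row < rows) & (lens > 1e-12)
    return (row[keep] * cols + col[keep]), lens[keep]


def build_system_matrix(
    n_angles: int, n_radial_bins: int, grid_size: tuple[int, int]
) -> SystemMatrix:
    """Build the parallel-beam system matrix for a (rows, cols) grid.

    Angles are uniform over [0, pi); radial offsets are centered on the
    grid with spacing max(rows, cols)/n_radial_bins, so n_radial_bins equal
    to the grid side gives unit-spaced rays through pixel centers.
    """
    rows, cols = grid_size
    if rows < 1 or cols < 1:
        raise ValueError("degenerate grid")
    if n_angles < 1 or n_radial_bins < 1:
        raise ValueError("need at least one angle and one radial bin")

    spacing = max(rows, cols) / n_radial_bins
    taus = (np.arange(n_radial_bins) - (n_radial_bins - 1) / 2.0) * spacing
    thetas = np.arange(n_angles) * np.pi / n_angles

    data, indices, indptr = [], [], [0]
    for theta in thetas:
        for tau in taus:
            idx, lens = _ray_pixel_lengths(theta, tau, grid_size)
            indices.extend(idx.tolist())
            data.extend(lens.tolist())
            indptr.append(len(indices))
    weights = sp.csr_matrix(
        (np.asarray(data), np.asarray(indices, dtype=int), np.asarray(indptr, dtype=int)),
        shape=(n_angles * n_radial_bins, rows * cols),
    )
    return SystemMatrix(weights, n_angles, n_radial_bins, grid_size)


def fov_mask(grid_size: tuple[int, int]) -> np.ndarray:
    """Boolean mask of the inscribed-circle field of view."""
    rows, cols = grid_size
    rr, cc = np.mgrid[0:rows, 0:cols]
    cy, cx = rows / 2.0 - 0.5, cols / 2.0 - 0.5
    return (rr - cy) ** 2 + (cc - cx) ** 2 <= (min(rows, cols) / 2.0) ** 2


def forward_project(G: SystemMatrix, phantom: DynamicPhantom) -> SinogramSeries:
    """Noiseless expected sinogram: expected[i] = G @ vec(frame_i)."""
    if phantom.grid_size != G.grid_size:
        raise ValueError(
            f"phantom grid {phantom.grid_size} does not match system matrix {G.grid_size}"
        )
    expected = np.stack([G.project(f) for f in phantom.frames])
    return SinogramSeries(
        counts=None,
        expected=expected,
        n_angles=G.n_angles,
        n_radial_bins=G.n_radial_bins,
        grid_size=G.grid_size,
    )


def scale_to_counts(sino: SinogramSeries, total_counts: float) -> SinogramSeries:
    """Rescale the expectation so its grand total equals the count budget.

    The returned series records the applied factor in ``scale`` so ground
    truth can be brought to the same intensity scale for evaluation.
    """
    if sino.expected is None:
        raise ValueError("scale_to_counts needs an expected sinogram")
    if total_counts <= 0:
        raise ValueError("total_counts must be positive")
    s = float(sino.expected.sum())
    if s == 0:
        raise ValueError("cannot scale an all-zero sinogram")
    factor = total_counts / s
    return SinogramSeries(
        counts=None,
        expected=sino.expected * factor,
        n_angles=sino.n_angles,
        n_radial_bins=sino.n_radial_bins,
        grid_size=sino.grid_size,
        total_counts=float(total_counts),
        scale=sino.scale * factor,
    )


def sample_poisson(sino: SinogramSeries, seed: int) -> SinogramSeries:
    """Draw independent Poisson counts around the expectation (seeded)."""
    if sino.expected is None:
        raise ValueError("sample_poisson needs an expected sinogram")
    if isinstance(seed, np.random.Generator):
        rng, seed_attr = seed, None
    else:
        rng, seed_attr = np.random.default_rng(seed), int(seed)
    counts = rng.poisson(sino.expected).astype(float)
    return SinogramSeries(
        counts=counts,
        expected=sino.expected,
        n_angles=sino.n_angles,
        n_radial_bins=sino.n_radial_bins,
        grid_size=sino.grid_size,
        seed=seed_attr,
        total_counts=sino.total_counts,
        scale=sino.scale,
    )


def save_sinogram(sino: SinogramSeries, path: str) -> None:
    with h5py.File(path, "w") as f:
        if sino.counts is not None:
            f.create_dataset("counts", data=sino.counts)
        if sino.expected is not None:
            f.create_dataset("expected", data=sino.expected)
        f.attrs["n_angles"] = sino.n_angles
        f.attrs["n_radial_bins"] = sino.n_radial_bins
        f.attrs["grid_size"] = sino.grid_size
        f.attrs["scale"] = sino.scale
        if sino.seed is not None:
            f.attrs["seed"] = sino.seed
        if sino.total_counts is not None:
            f.attrs["total_counts"] = sino.total_counts


def load_sinogram(path: str) -> SinogramSeries:
    with h5py.File(path, "r") as f:
        counts = f["counts"][()] if "counts" in f else None
        expected = f["expected"][()] if "expected" in f else None
        return SinogramSeries(
            counts=counts,
            expected=expected,
            n_angles=int(f.attrs["n_angles"]),
            n_radial_bins=int(f.attrs["n_radial_bins"]),
            grid_size=tuple(int(v) for v in f.attrs["grid_size"]),
            seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
            total_counts=float(f.attrs["total_counts"])
            if "total_counts" in f.attrs
            else None,
            scale=float(f.attrs.get("scale", 1.0)),
        )
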