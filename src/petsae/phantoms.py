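"""Synthetic dynamic phantoms with region structure and time-activity curves.

A dynamic phantom is a short sequence of 2-D activity maps on a fixed grid,
piecewise constant over a set of labeled regions (ROIs).  Each region's
activity follows a time-activity curve (TAC): constant, mono-exponential
decay ``A e^{-lambda t}`` or gamma-variate uptake ``A t^alpha e^{-beta t}``.
The construction is exact: the region mean at frame ``i`` equals the TAC
value at the frame midpoint, which makes the phantoms usable as ground
truth for reconstruction metrics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "DynamicPhantom",
    "make_dynamic_phantom",
    "roi_masks",
    "tac_value",
    "save_phantom",
    "load_phantom",
]


@dataclass
class DynamicPhantom:
    """Ground-truth activity image per frame plus an ROI label map.

    Attributes
    ----------
    frames : ndarray, shape (n_frames, rows, cols)
        Nonnegative activity maps, one per time frame (arbitrary units).
    roi_labels : ndarray of int, shape (rows, cols)
        Region labels; 0 is background.
    frame_durations : ndarray, shape (n_frames,), optional
        Frame lengths in seconds (uniform 1 s if omitted).
    tac_params : list of dict, optional
        The per-region curve parameters the phantom was built from.
    """

    frames: np.ndarray
    roi_labels: np.ndarray
    frame_durations: np.ndarray | None = None
    tac_params: list | None = field(default=None, repr=False)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.roi_labels = np.asarray(self.roi_labels)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, rows, cols) array")
        if self.frames.shape[1:] != self.roi_labels.shape:
            raise ValueError("roi_labels shape must match the frame grid")
        if np.any(self.frames < 0):
            raise ValueError("activity values must be nonnegative")
        if self.frame_durations is not None:
            self.frame_durations = np.asarray(self.frame_durations, dtype=float)
            if self.frame_durations.shape != (self.n_frames,) or np.any(
                self.frame_durations <= 0
            ):
                raise ValueError("frame_durations must be n_frames positive scalars")

    @property
    def grid_size(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def tac_value(params: dict, t: np.ndarray) -> np.ndarray:
    """Evaluate a region's time-activity curve at times ``t`` (seconds).

    ``params['kind']`` selects the family:

    - ``constant``: A
    - ``monoexp``:  A * exp(-rate * t)            (washout)
    - ``gammavar``: A * t**alpha * exp(-beta * t) (uptake then washout)
    """
    t = np.asarray(t, dtype=float)
    kind = params.get("kind", "constant")
    A = float(params.get("amplitude", 1.0))
    if A < 0:
        raise ValueError("TAC amplitude must be nonnegative")
    if kind == "constant":
        return np.full_like(t, A)
    if kind == "monoexp":
        rate = float(params.get("rate", 0.1))
        if rate < 0:
            raise ValueError("monoexp rate must be nonnegative")
        return A * np.exp(-rate * t)
    if kind == "gammavar":
        alpha = float(params.get("alpha", 2.0))
        beta = float(params.get("beta", 0.3))
        if alpha < 0 or beta < 0:
            raise ValueError("gammavar alpha/beta must be nonnegative")
        # normalize so the curve peak equals A (peak at t = alpha/beta)
        tpk = alpha / beta if beta > 0 else 1.0
        peak = tpk**alpha * np.exp(-beta * tpk) if tpk > 0 else 1.0
        return A * np.power(t, alpha) * np.exp(-beta * t) / peak
    raise ValueError(f"unknown TAC kind: {kind!r}")


def _default_tacs(n_regions: int, rng: np.random.Generator) -> list[dict]:
    # Mix of washout and uptake regions with distinct amplitudes; values are
    # chosen so early frames are hot and late frames count-starved, the
    # regime where frame-by-frame reconstruction struggles.
    tacs = []
    for r in range(n_regions):
        amp = float(rng.uniform(2.0, 8.0))
        if r % 2 == 0:
            tacs.append({"kind": "monoexp", "amplitude": amp, "rate": float(rng.uniform(0.03, 0.12))})
        else:
            tacs.append(
                {
                    "kind": "gammavar",
                    "amplitude": amp,
                    "alpha": float(rng.uniform(1.5, 3.0)),
                    "beta": float(rng.uniform(0.2, 0.5)),
                }
            )
    return tacs


def _place_disks(grid_size, n_regions, rng):
    rows, cols = grid_size
    labels = np.zeros(grid_size, dtype=int)
    rr, cc = np.mgrid[0:rows, 0:cols]
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    fov_r = 0.48 * min(rows, cols)
    placed = []
    for label in range(1, n_regions + 1):
        ok = False
        for attempt in range(2000):
            shrink = 0.998**attempt
            rad = rng.uniform(0.10, 0.22) * min(rows, cols) * shrink
            if rad < 1.0:
                break
            ang = rng.uniform(0, 2 * np.pi)
            d = rng.uniform(0, max(fov_r - rad - 1, 0.0))
            y, x = cy + d * np.sin(ang), cx + d * np.cos(ang)
            if all(np.hypot(y - py, x - px) > rad + pr + 1 for py, px, pr in placed):
                labels[(rr - y) ** 2 + (cc - x) ** 2 <= rad**2] = label
                placed.append((y, x, rad))
                ok = True
                break
        if not ok:
            raise ValueError(
                f"could not place {n_regions} disjoint regions on a {rows}x{cols} grid"
            )
    return labels


def _place_brain_like(grid_size, n_regions, rng):
    # concentric annuli (cortex-like rim + inner matter) plus interior blobs
    rows, cols = grid_size
    labels = np.zeros(grid_size, dtype=int)
    rr, cc = np.mgrid[0:rows, 0:cols]
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    r2 = (rr - cy) ** 2 + (cc - cx) ** 2
    r_out = 0.45 * min(rows, cols)
    r_in = 0.80 * r_out
    labels[r2 <= r_out**2] = 1  # outer annulus (rim)
    if n_regions >= 2:
        labels[r2 <= r_in**2] = 2  # interior
    for label in range(3, n_regions + 1):
        for attempt in range(400):
            rad = rng.uniform(0.06, 0.13) * min(rows, cols) * (0.92**attempt)
            if rad < 1.0:
                raise ValueError("too many interior regions for this grid")
            ang = rng.uniform(0, 2 * np.pi)
            d = rng.uniform(0, r_in - rad - 1)
            y, x = cy + d * np.sin(ang), cx + d * np.cos(ang)
            blob = (rr - y) ** 2 + (cc - x) ** 2 <= rad**2
            if np.all(labels[blob] == 2):
                labels[blob] = label
                break
        else:
            raise ValueError("too many interior regions for this grid")
    return labels


def _place_torso_like(grid_size, n_regions, rng):
    rows, cols = grid_size
    labels = np.zeros(grid_size, dtype=int)
    rr, cc = np.mgrid[0:rows, 0:cols]
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    a, b = 0.46 * cols, 0.36 * rows  # body ellipse semi-axes
    body = ((cc - cx) / a) ** 2 + ((rr - cy) / b) ** 2 <= 1.0
    labels[body] = 1
    for label in range(2, n_regions + 1):
        for attempt in range(400):
            ra = rng.uniform(0.08, 0.16) * cols * (0.92**attempt)
            rb = rng.uniform(0.08, 0.16) * rows * (0.92**attempt)
            if min(ra, rb) < 1.0:
                raise ValueError("too many organ regions for this grid")
            y = cy + rng.uniform(-0.5, 0.5) * b
            x = cx + rng.uniform(-0.6, 0.6) * a
            organ = ((cc - x) / ra) ** 2 + ((rr - y) / rb) ** 2 <= 1.0
            if np.all(labels[organ] == 1):
                labels[organ] = label
                break
        else:
            raise ValueError("too many organ regions for this grid")
    return labels


_PLACERS = {"disks": _place_disks, "brain_like": _place_brain_like, "torso_like": _place_torso_like}


def make_dynamic_phantom(
    kind: str = "disks",
    grid_size: tuple[int, int] = (64, 64),
    n_frames: int = 18,
    n_regions: int = 3,
    tac_params: list | None = None,
    seed: int = 0,
    frame_durations: np.ndarray | None = None,
) -> DynamicPhantom:
    """Generate a seeded dynamic phantom.

    Parameters
    ----------
    kind : {'disks', 'brain_like', 'torso_like'}
        Region geometry.  ``disks`` scatters disjoint disks in a circular
        field of view; ``brain_like`` builds a rim + interior + blobs;
        ``torso_like`` a body ellipse with offset organs.
    grid_size : (rows, cols), at least 16x16.
    n_frames : number of time frames, at least 3.
    n_regions : number of labeled regions (>= 1).
    tac_params : optional list of per-region TAC dicts (see `tac_value`);
        seeded defaults mix washout and uptake curves.
    seed : controls both geometry and default kinetics; identical inputs
        give bit-identical phantoms.
    frame_durations : optional positive frame lengths in seconds
        (uniform 1 s frames by default).
    """
    rows, cols = grid_size
    if rows < 16 or cols < 16:
        raise ValueError("grid_size must be at least 16x16")
    if n_frames < 3:
        raise ValueError("n_frames must be at least 3")
    if n_regions < 1:
        raise ValueError("n_regions must be at least 1")
    if kind not in _PLACERS:
        raise ValueError(f"unknown phantom kind: {kind!r}")

    rng = np.random.default_rng(seed)
    labels = _PLACERS[kind]((rows, cols), n_regions, rng)
    if tac_params is None:
        tac_params = _default_tacs(n_regions, rng)
    elif len(tac_params) != n_regions:
        raise ValueError("tac_params must supply one curve per region")

    if frame_durations is None:
        durations = np.ones(n_frames)
    else:
        durations = np.asarray(frame_durations, dtype=float)
    edges = np.concatenate([[0.0], np.cumsum(durations)])
    midpoints = 0.5 * (edges[:-1] + edges[1:])

    frames = np.zeros((n_frames, rows, cols))
    for label in range(1, n_regions + 1):
        mask = labels == label
        values = tac_value(tac_params[label - 1], midpoints)
        frames[:, mask] = values[:, None]

    return DynamicPhantom(
        frames=frames,
        roi_labels=labels,
        frame_durations=durations if frame_durations is not None else None,
        tac_params=tac_params,
    )


def roi_masks(phantom: DynamicPhantom) -> dict[str, np.ndarray]:
    """Boolean mask per ROI label plus a ``Total`` mask.

    ``Total`` is the union of all nonzero labels; with an all-zero label
    map it degenerates to the whole grid.
    """
    labels = phantom.roi_labels
    out: dict[str, np.ndarray] = {}
    for label in sorted(np.unique(labels)):
        if label == 0:
            continue
        out[f"ROI{label}"] = labels == label
    if out:
        out["Total"] = labels > 0
    else:
        out["Total"] = np.ones_like(labels, dtype=bool)
    return out


def save_phantom(phantom: DynamicPhantom, path: str) -> None:
    """Write a phantom as NIfTI (frames on the 3rd axis) + JSON sidecar."""
    vol = np.moveaxis(phantom.frames, 0, -1)
    nib.save(nib.Nifti1Image(vol, affine=np.eye(4)), path)
    side = {
        "roi_labels": phantom.roi_labels.tolist(),
        "tac_params": phantom.tac_params,
        "frame_durations": None
        if phantom.frame_durations is None
        else phantom.frame_durations.tolist(),
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(side, fh)


def load_phantom(path: str) -> DynamicPhantom:
    vol = np.asarray(nib.load(path).dataobj, dtype=float)
    with open(_sidecar_path(path)) as fh:
        side = json.load(fh)
    durations = side.get("frame_durations")
    return DynamicPhantom(
        frames=np.moveaxis(vol, -1, 0),
        roi_labels=np.asarray(side["roi_labels"], dtype=int),
        frame_durations=None if durations is None else np.asarray(durations),
        tac_params=side.get("tac_params"),
    )


def _sidecar_path(path: str) -> str:
    for ext in (".nii.gz", ".nii"):
        if path.endswith(ext):
            return path[: -len(ext)] + ".json"
    return path + ".json"
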