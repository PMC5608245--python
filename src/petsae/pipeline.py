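"""End-to-end driver: simulate -> MLEM -> train -> reconstruct -> evaluate.

A `RunConfig` gathers every tunable of the pipeline; `run_experiment`
executes the five stages in order under a single master seed (each random
draw comes from a named substream, so a run is fully reproducible from
its manifest).  When an output directory is given, completed stages are
cached keyed by a hash of the config fields they depend on and skipped on
re-runs.
"""

from __future__ import annotations

import hashlib
import json
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._utils import spawn_rng
from .autoencoder import AEParams, SparsityConfig, initialize_params
from .mlem import ReconSeries, mlem_reconstruct, save_recon
from .phantoms import DynamicPhantom, make_dynamic_phantom, roi_masks, save_phantom
from .projection import (
    SinogramSeries,
    build_system_matrix,
    forward_project,
    sample_poisson,
    save_sinogram,
    scale_to_counts,
)
from .metrics import roi_report
from .rbm import RBMParams, initialize_rbm
from .reconstruct import gaussian_kernel, reconstruct_frame
from .sae import (
    SAEModel,
    concat_datasets,
    extract_patches,
    finetune,
    greedy_pretrain,
    save_model,
)

__all__ = ["RunConfig", "run_experiment", "counting_rate_sweep", "generate_fixture"]


@dataclass
class RunConfig:
    """Every tunable of the pipeline in one validated record.

    Defaults follow the reference architecture (3-frame window, two hidden
    layers of 200 and 100 units, 7x7 patches) at desk-scale problem sizes.
    """

    # phantom / simulation
    phantom_kind: str = "disks"
    grid_size: tuple[int, int] = (64, 64)
    n_frames: int = 9
    n_regions: int = 3
    n_train: int = 12
    n_test: int = 4
    total_counts: float = 5e4
    counts_per_frame: bool = False  # budget per frame instead of per scan
    n_angles: int | None = None  # default: grid side
    n_radial_bins: int | None = None
    # mlem
    mlem_iterations: int = 50
    # sae
    n_frames_in: int = 3
    frame_index: int | None = None  # default: middle frame
    patch_size: tuple[int, int] = (7, 7)
    train_stride: int = 1  # dense patch extraction
    train_frame_indices: tuple[int, ...] | None = None
    # frames whose windows supply training patches; None = the target frame.
    # The model is window-relative, so one net can serve several frames.
    hidden_sizes: tuple[int, ...] = (200, 100)
    alpha1: float = 1e-4
    alpha2: float = 0.1
    rho0: float = 0.05
    learning_rate: float = 0.3
    lr_decay: float = 1.0  # per-epoch fine-tuning learning-rate multiplier
    pretrain_epochs: int = 30
    finetune_epochs: int = 300
    batch_size: int = 128
    rbm_init: bool = True
    rbm_epochs: int = 5
    # reconstruction
    sigma: float | None = None  # default: patch side / 4
    aggregation: str = "overlap"
    # seeding
    seed: int = 0

    def __post_init__(self):
        if self.n_train < 1 or self.n_test < 1:
            raise ValueError("need at least one training and one test set")
        if self.total_counts <= 0:
            raise ValueError("total_counts must be positive")
        if self.n_frames_in % 2 == 0:
            raise ValueError("n_frames_in must be odd")
        l, k = self.patch_size
        if l % 2 == 0 or k % 2 == 0:
            raise ValueError("patch sides must be odd")
        if self.frame_index is not None and not 0 <= self.frame_index < self.n_frames:
            raise ValueError("frame_index out of range")

    @property
    def resolved_frame_index(self) -> int:
        return self.n_frames // 2 if self.frame_index is None else self.frame_index

    @property
    def geometry(self) -> tuple[int, int]:
        side = max(self.grid_size)
        return (
            self.n_angles if self.n_angles is not None else side,
            self.n_radial_bins if self.n_radial_bins is not None else side,
        )

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_jsonable(dataclasses.asdict(self)), fh)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("grid_size", "patch_size", "hidden_sizes"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _stage_hash(config: RunConfig, fields: tuple[str, ...]) -> str:
    payload = {f: _jsonable(getattr(config, f)) for f in fields}
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


_SIM_FIELDS = (
    "phantom_kind", "grid_size", "n_frames", "n_regions", "n_train", "n_test",
    "total_counts", "counts_per_frame", "n_angles", "n_radial_bins", "seed",
)
_MLEM_FIELDS = _SIM_FIELDS + ("mlem_iterations",)
_TRAIN_FIELDS = _MLEM_FIELDS + (
    "n_frames_in", "frame_index", "patch_size", "train_stride", "hidden_sizes",
    "alpha1", "alpha2", "rho0", "learning_rate", "pretrain_epochs",
    "finetune_epochs", "batch_size", "rbm_init", "rbm_epochs",
)


def _simulate_set(config: RunConfig, set_index: int):
    """One phantom and its noisy sinogram; truth is returned on the count
    scale actually simulated."""
    rng_seed = spawn_rng(config.seed, "phantom", str(set_index))
    phantom = make_dynamic_phantom(
        kind=config.phantom_kind,
        grid_size=config.grid_size,
        n_frames=config.n_frames,
        n_regions=config.n_regions,
        seed=rng_seed,
    )
    n_angles, n_radial = config.geometry
    G = build_system_matrix(n_angles, n_radial, config.grid_size)
    expected = forward_project(G, phantom)
    if config.counts_per_frame:
        budget = config.total_counts * config.n_frames
    else:
        budget = config.total_counts
    scaled = scale_to_counts(expected, budget)
    noise_rng = spawn_rng(config.seed, "poisson", str(set_index))
    sino = sample_poisson(scaled, noise_rng)
    truth_scaled = phantom.frames * scaled.scale
    return phantom, truth_scaled, sino, G


def run_experiment(config: RunConfig, outdir: str | None = None) -> dict:
    """Execute the full pipeline; returns the results bundle.

    The bundle holds the trained model, per-test-set MLEM and fused
    reconstructions of the target frame, and a metrics table comparing
    both to ground truth on every ROI.
    """
    out = Path(outdir) if outdir is not None else None
    manifest = {}
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        mpath = out / "manifest.json"
        if mpath.exists():
            manifest = json.loads(mpath.read_text())

    i_target = config.resolved_frame_index

    # --- stage 1+2: simulate and reconstruct every set -------------------
    n_sets = config.n_train + config.n_test
    phantoms, truths, sinos, recons = [], [], [], []
    G = None
    for s in range(n_sets):
        phantom, truth_scaled, sino, G = _simulate_set(config, s)
        recon = mlem_reconstruct(G, sino, n_iterations=config.mlem_iterations)
        phantoms.append(phantom)
        truths.append(truth_scaled)
        sinos.append(sino)
        recons.append(recon)
    if out is not None:
        sim_hash = _stage_hash(config, _MLEM_FIELDS)
        if manifest.get("sim_hash") != sim_hash:
            for s in range(n_sets):
                save_phantom(phantoms[s], str(out / f"phantom_{s:03d}.nii"))
                save_sinogram(sinos[s], str(out / f"sinogram_{s:03d}.h5"))
                save_recon(recons[s], str(out / f"mlem_{s:03d}.nii"))
            manifest["sim_hash"] = sim_hash

    # --- stage 3: train --------------------------------------------------
    train_recons = recons[: config.n_train]
    train_truths = truths[: config.n_train]
    # Robust shared intensity map: ground truth must fit in [0, 1], but the
    # MLEM range is taken at a high percentile so isolated noise spikes do
    # not compress the useful dynamic range (spiked inputs clip at 1).
    vmax = max(
        max(float(np.percentile(r.images, 99.5)) for r in train_recons),
        max(float(t.max()) for t in train_truths),
    )
    normalization = (0.0, vmax if vmax > 0 else 1.0)
    if config.train_frame_indices is not None:
        train_frames = list(config.train_frame_indices)
    else:
        train_frames = [i_target]
    datasets = [
        extract_patches(
            r,
            truth=t,
            frame_index=fi,
            patch_size=config.patch_size,
            stride=config.train_stride,
            n_frames_in=config.n_frames_in,
            normalization=normalization,
        )
        for r, t in zip(train_recons, train_truths)
        for fi in train_frames
    ]
    dataset = concat_datasets(datasets)
    sp_config = SparsityConfig(alpha1=config.alpha1, alpha2=config.alpha2, rho0=config.rho0)
    encoders = greedy_pretrain(
        dataset,
        hidden_sizes=config.hidden_sizes,
        config=sp_config,
        learning_rate=config.learning_rate,
        epochs=config.pretrain_epochs,
        batch_size=config.batch_size,
        rbm_init=config.rbm_init,
        rbm_epochs=config.rbm_epochs,
        seed=spawn_rng(config.seed, "pretrain"),
    )
    model = finetune(
        encoders,
        dataset,
        config=sp_config,
        learning_rate=config.learning_rate,
        epochs=config.finetune_epochs,
        batch_size=config.batch_size,
        lr_decay=config.lr_decay,
        seed=spawn_rng(config.seed, "finetune"),
    )
    model.seed = config.seed
    if out is not None:
        save_model(model, str(out / "model.h5"))

    # --- stage 4+5: reconstruct test sets and evaluate -------------------
    l, _ = config.patch_size
    kernel = gaussian_kernel(
        config.patch_size, sigma=config.sigma if config.sigma is not None else l / 4.0
    )
    reports = []
    fused_images, mlem_images = [], []
    for t_idx in range(config.n_test):
        s = config.n_train + t_idx
        fused = reconstruct_frame(
            model, recons[s], i_target, kernel=kernel, mode=config.aggregation
        )
        fused_images.append(fused)
        mlem_images.append(recons[s].images[i_target])
        masks = roi_masks(phantoms[s])
        truth_frame = truths[s][i_target][None]
        rep_mlem = roi_report(mlem_images[-1][None], truth_frame, masks)
        rep_sae = roi_report(fused[None], truth_frame, masks)
        rep_mlem["method"] = "MLEM"
        rep_sae["method"] = "MLEM+SAE"
        rep = pd.concat([rep_mlem, rep_sae], ignore_index=True)
        rep["test_set"] = t_idx
        reports.append(rep)
    report = pd.concat(reports, ignore_index=True)
    if out is not None:
        report.to_csv(out / "metrics.csv", index=False)
        manifest["config_hash"] = _stage_hash(config, tuple(f.name for f in dataclasses.fields(config)))
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        config.to_yaml(str(out / "config.yaml"))

    return {
        "config": config,
        "model": model,
        "report": report,
        "mlem_images": mlem_images,
        "fused_images": fused_images,
        "truth_frames": [truths[config.n_train + t][i_target] for t in range(config.n_test)],
        "phantoms": phantoms,
        "system_matrix": G,
    }


def counting_rate_sweep(
    config: RunConfig,
    rates=(5e4, 1e5, 5e5, 1e6),
    n_seeds: int = 1,
    mlem_only: bool = False,
) -> pd.DataFrame:
    """Repeat the experiment across counting rates (and seeds).

    Returns one row per (rate, seed, method) with the mean Total-ROI SNR,
    bias and variance across test sets.  ``mlem_only`` skips the training
    and fusion stages for a fast noise-vs-rate curve.
    """
    rows = []
    for rate in rates:
        for k in range(n_seeds):
            cfg = dataclasses.replace(config, total_counts=float(rate), seed=config.seed + k)
            if mlem_only:
                rows.extend(_mlem_only_rows(cfg, rate, k))
            else:
                res = run_experiment(cfg)
                rep = res["report"]
                total = rep[rep.roi == "Total"]
                for method, grp in total.groupby("method"):
                    rows.append(
                        {
                            "rate": rate,
                            "seed": cfg.seed,
                            "method": method,
                            "snr_db": grp.snr_db.mean(),
                            "bias": grp.bias.mean(),
                            "variance": grp.variance.mean(),
                        }
                    )
    return pd.DataFrame(rows)


def _mlem_only_rows(cfg: RunConfig, rate, k):
    rows = []
    for s in range(cfg.n_test):
        phantom, truth_scaled, sino, G = _simulate_set(cfg, cfg.n_train + s)
        recon = mlem_reconstruct(G, sino, n_iterations=cfg.mlem_iterations)
        i = cfg.resolved_frame_index
        rep = roi_report(recon.images[i][None], truth_scaled[i][None], roi_masks(phantom))
        total = rep[rep.roi == "Total"]
        rows.append(
            {
                "rate": rate,
                "seed": cfg.seed,
                "method": "MLEM",
                "snr_db": total.snr_db.mean(),
                "bias": total.bias.mean(),
                "variance": total.variance.mean(),
            }
        )
    return rows


def generate_fixture(name: str, seed: int = 0) -> dict:
    """Deterministic tiny problems used throughout the test suite.

    - ``toy-projector``: 2x2 grid, axis-aligned two-angle geometry and a
      hand-checkable frame.
    - ``tiny-rbm``: 4-visible / 2-hidden RBM with a two-pattern dataset.
    - ``gradcheck-net``: 12->8->12 autoencoder and a 5-row batch.
    - ``mini-phantom``: seeded 32x32 three-region dynamic phantom with a
      noisy sinogram and its system matrix.
    """
    if name == "toy-projector":
        G = build_system_matrix(2, 2, (2, 2))
        frame = np.array([[1.0, 2.0], [3.0, 4.0]])
        return {"G": G, "frame": frame}
    if name == "tiny-rbm":
        params = initialize_rbm(4, 2, seed=spawn_rng(seed, "tiny-rbm"), scale=0.1)
        data = np.array([[1.0, 1.0, 0.0, 0.0], [0.0, 0.0, 1.0, 1.0]])
        return {"params": params, "data": data}
    if name == "gradcheck-net":
        rng = spawn_rng(seed, "gradcheck")
        params = initialize_params(12, 8, 12, seed=rng)
        batch = rng.uniform(0.05, 0.95, size=(5, 12))
        return {"params": params, "batch": batch}
    if name == "mini-phantom":
        phantom = make_dynamic_phantom("disks", (32, 32), n_frames=5, n_regions=3, seed=seed)
        G = build_system_matrix(32, 32, (32, 32))
        sino = sample_poisson(
            scale_to_counts(forward_project(G, phantom), 2e5),
            spawn_rng(seed, "mini-noise"),
        )
        return {"phantom": phantom, "G": G, "sinogram": sino}
    raise ValueError(f"unknown fixture name: {name!r}")
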