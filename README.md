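# petsae

Dynamic PET reconstruction that pairs classical per-frame MLEM with a
stacked sparse autoencoder (SAE) fusing adjacent time frames patch by
patch.

## The problem

Dynamic positron emission tomography splits an acquisition into short
time frames to follow tracer kinetics.  Short frames collect few
coincidence events, so frame-by-frame maximum-likelihood
expectation-maximization (MLEM) reconstructions are dominated by Poisson
noise and the checkerboard artifact.  Neighbouring frames, however, image
the same anatomy under a smoothly varying activity, so they carry strong
prior information about each other.

`petsae` exploits that redundancy.  For a target frame *i*, the 7×7
patches of the MLEM reconstructions of frames *i−1, i, i+1* are
concatenated into a 147-vector and mapped through a trained network

    147 → 200 → 100 → 49   (sigmoid layers throughout)

whose output is an estimate of the ground-truth 7×7 patch of frame *i*.
Sweeping the patch window over every pixel position and combining the
overlapping predictions with a Gaussian weighting yields the fused frame
estimate ("MLEM+SAE").

The network is built from sparse autoencoder templates.  A single
template minimizes

    ‖o − x‖² + α₁‖W‖_F + α₂ KL(ρ̂ ‖ ρ₀)

where `o = σ(W′ σ(Wx + b) + b′)` and the Kullback–Leibler term drives the
batch-mean hidden activation ρ̂ of every unit toward a small target ρ₀.
Templates are stacked greedily — each layer is trained on the previous
layer's hidden code — with weights initialized by a restricted Boltzmann
machine trained by one-step contrastive divergence (CD-1).  Finally a
supervised output layer is appended and the whole stack is fine-tuned by
backpropagation against ground-truth patches of the target frame.

Because no public dynamic-PET training corpus is bundled, the package
ships a full desk-scale simulator: seeded multi-region dynamic phantoms
with configurable time-activity curves, an exact parallel-beam projector
(ray/pixel intersection lengths), count-budget scaling, and Poisson
sampling.  Everything — data, training, evaluation — is reproducible from
one master seed.

## Worked example

```python
import petsae as ps

cfg = ps.RunConfig(grid_size=(32, 32), n_frames=5, n_train=6, n_test=2,
                   total_counts=1e5, patch_size=(5, 5), hidden_sizes=(60, 30),
                   pretrain_epochs=15, finetune_epochs=200, seed=7)
res = ps.run_experiment(cfg)
total = res["report"][res["report"].roi == "Total"]
print(total.groupby("method")[["snr_db", "bias", "variance"]].mean().round(3))
```

prints (about nine seconds on one CPU):

```
          snr_db   bias  variance
method
MLEM      12.696 -0.024     0.331
MLEM+SAE  18.348 -0.018     0.196
```

Six phantoms train the network; two held-out phantoms are fused.  Over
the union of all labeled regions ("Total" ROI) the fused reconstruction
gains 5.7 dB of peak SNR over plain MLEM while reducing both the mean
relative bias and the truth-normalized variance.  The `report` dataframe
also holds the same three indexes per individual ROI and per test set.

A command-line interface mirrors the pipeline stages:

```bash
petsae simulate --grid 64 --frames 9 --counts 5e4 --seed 1 \
    --phantom-out ph.nii --sinogram-out sino.h5
petsae mlem --sinogram sino.h5 --mlem-iters 50 --out recon.nii
petsae train --outdir run/            # simulate + reconstruct + train
petsae reconstruct --model run/model.h5 --recon recon.nii --frame-index 4 --out fused.nii
petsae evaluate --recon fused.nii --phantom ph.nii --out report.csv
petsae sweep --rates 5e4,1e5,5e5 --mlem-only --out sweep.csv
```

## Layout

| module | contents |
| --- | --- |
| `petsae.phantoms` | seeded dynamic phantoms, time-activity curves, ROI masks, NIfTI I/O |
| `petsae.projection` | parallel-beam system matrix, forward projection, count scaling, Poisson sampling, HDF5 I/O |
| `petsae.mlem` | per-frame MLEM, Poisson log-likelihood |
| `petsae.rbm` | restricted Boltzmann machine, CD-1, exact enumeration oracle |
| `petsae.autoencoder` | sparse autoencoder: objective, exact gradients, training |
| `petsae.sae` | patch extraction, greedy pretraining, supervised fine-tuning, model I/O |
| `petsae.reconstruct` | Gaussian-weighted patch-sweep reconstruction |
| `petsae.metrics` | SNR / bias / variance per ROI and frame |
| `petsae.pipeline` | end-to-end driver, counting-rate sweep, test fixtures |
| `petsae.cli` | `petsae` command-line entry point |

See `docs/methods.md` for the modeling assumptions, parameter defaults,
and numerical conventions.
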