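import numpy as np
import pytest

from petsae.autoencoder import SparsityConfig, train_autoencoder
from petsae.phantoms import make_dynamic_phantom
from petsae.sae import (
    IdentityPatchModel,
    concat_datasets,
    extract_patches,
    finetune,
    greedy_pretrain,
    load_model,
    predict_patch,
    save_model,
    window_indices,
)
from petsae._utils import sigmoid, spawn_rng


def _toy_dataset(rng, n=200, grid=16, frames=4, patch=5, identity_labels=True):
    stack = rng.uniform(0.0, 1.0, size=(frames, grid, grid))
    truth = stack if identity_labels else rng.uniform(0.0, 1.0, size=stack.shape)
    return extract_patches(
        stack, truth=truth, frame_index=2, patch_size=(patch, patch), stride=2
    )


def test_window_indices_replicate_edges():
    assert window_indices(4, 9, 3) == [3, 4, 5]
    assert window_indices(0, 9, 3) == [0, 0, 1]
    assert window_indices(8, 9, 3) == [7, 8, 8]
    with pytest.raises(ValueError):
        window_indices(9, 9, 3)
    with pytest.raises(ValueError):
        window_indices(1, 9, 4)


def test_patch_count_and_row_length():
    stack = np.zeros((9, 64, 64))
    ds = extract_patches(stack + 1.0, frame_index=4, patch_size=(7, 7), stride=1)
    assert ds.n_rows == 58 * 58  # (64 - 7 + 1)^2 interior positions
    assert ds.inputs.shape[1] == 3 * 49  # 147 input nodes for a 3-frame window


def test_constant_frames_give_identical_rows():
    stack = np.full((5, 20, 20), 2.0)
    ds = extract_patches(stack, frame_index=2, patch_size=(5, 5), stride=1)
    assert np.all(ds.inputs == ds.inputs[0])


def test_row_layout_is_window_order_then_row_major():
    stack = np.zeros((3, 8, 8))
    for i in range(3):
        stack[i] = i * 100 + np.arange(64).reshape(8, 8)
    ds = extract_patches(stack, frame_index=1, patch_size=(3, 3), stride=1,
                         normalization=(0.0, 300.0))
    row0 = ds.inputs[0] * 300.0
    per = 9
    for f in range(3):
        patch = stack[f][:3, :3].ravel()
        assert np.allclose(row0[f * per : (f + 1) * per], patch)


def test_patch_too_large_rejected():
    with pytest.raises(ValueError):
        extract_patches(np.zeros((3, 6, 6)), frame_index=1, patch_size=(7, 7))


def test_labels_come_from_target_truth_frame(rng):
    ds = _toy_dataset(rng)
    l, k = ds.patch_size
    per = l * k
    mid = ds.n_frames_in // 2
    # identity labels: label patch equals the middle block of each input row
    assert np.allclose(ds.labels, ds.inputs[:, mid * per : (mid + 1) * per])


def test_greedy_single_layer_equals_train_autoencoder(rng):
    ds = _toy_dataset(rng)
    cfg = SparsityConfig()
    seed = 123
    enc = greedy_pretrain(ds, (6,), cfg, learning_rate=0.2, epochs=5,
                          batch_size=64, seed=spawn_rng(seed, "x"))
    params, _ = train_autoencoder(ds.inputs, 6, cfg, learning_rate=0.2, epochs=5,
                                  batch_size=64, seed=spawn_rng(seed, "x"))
    assert np.array_equal(enc[0][0], params.W_enc)
    assert np.array_equal(enc[0][1], params.b_enc)


def test_stack_dimensions_chain(rng):
    ds = _toy_dataset(rng)
    enc = greedy_pretrain(ds, (10, 4), None, epochs=2, batch_size=64, seed=0)
    assert enc[0][0].shape == (ds.inputs.shape[1], 10)
    assert enc[1][0].shape == (10, 4)  # layer-2 input dimensionality is h1


def test_finetune_learns_identity_mapping():
    # noiseless structured inputs with label == middle-frame patch: the
    # stack must drive the training MSE to (near) zero
    ph = make_dynamic_phantom("disks", (16, 16), 4, 2, seed=2)
    stack = ph.frames / ph.frames.max()
    ds = extract_patches(stack, truth=stack, frame_index=2, patch_size=(5, 5), stride=1)
    cfg = SparsityConfig(alpha1=0.0, alpha2=0.01, rho0=0.05)
    enc = greedy_pretrain(ds, (40,), cfg, learning_rate=0.3, epochs=30,
                          batch_size=64, seed=1)
    model = finetune(enc, ds, learning_rate=0.3, epochs=500, batch_size=64, seed=1)
    assert model.history[-1] / ds.patch_size[0] ** 2 < 1e-3  # per-pixel MSE
    assert model.history[-1] < model.history[0]


def test_finetune_requires_labels(rng):
    stack = rng.random((4, 16, 16))
    ds = extract_patches(stack, frame_index=2, patch_size=(5, 5), stride=2)
    with pytest.raises(ValueError):
        finetune([(np.zeros((75, 4)), np.zeros(4))], ds)


def test_prediction_matches_layerwise_composition(rng):
    ds = _toy_dataset(rng)
    enc = greedy_pretrain(ds, (8, 5), None, epochs=2, batch_size=64, seed=3)
    model = finetune(enc, ds, epochs=2, batch_size=64, seed=3)
    row = ds.inputs[7]
    a = row
    for w, b in model.encoders:
        a = sigmoid(a @ w + b)
    manual = sigmoid(a @ model.W_out + model.b_out)
    assert np.allclose(predict_patch(model, row), manual, atol=1e-14)
    # batch prediction equals row-by-row prediction
    batch_out = model.predict(ds.inputs[:5])
    for i in range(5):
        assert np.allclose(batch_out[i], model.predict(ds.inputs[i])[0])


def test_identity_patch_model_returns_middle_block():
    m = IdentityPatchModel(patch_size=(3, 3), n_frames_in=3)
    row = np.arange(27, dtype=float) / 27.0
    assert np.allclose(m.predict(row)[0], row[9:18])


def test_model_round_trip_is_bit_identical(tmp_path, rng):
    ds = _toy_dataset(rng)
    enc = greedy_pretrain(ds, (6,), None, epochs=2, batch_size=64, seed=5)
    model = finetune(enc, ds, epochs=3, batch_size=64, seed=5)
    path = str(tmp_path / "model.h5")
    save_model(model, path)
    back = load_model(path)
    assert np.array_equal(back.W_out, model.W_out)
    for (w1, b1), (w2, b2) in zip(back.encoders, model.encoders):
        assert np.array_equal(w1, w2) and np.array_equal(b1, b2)
    assert back.normalization == model.normalization
    x = rng.random((3, ds.inputs.shape[1]))
    assert np.array_equal(back.predict(x), model.predict(x))


def test_concat_datasets_checks_compatibility(rng):
    a = _toy_dataset(rng)
    b = extract_patches(
        rng.random((4, 16, 16)), truth=rng.random((4, 16, 16)), frame_index=2,
        patch_size=(5, 5), stride=2, normalization=a.normalization,
    )
    merged = concat_datasets([a, b])
    assert merged.n_rows == a.n_rows + b.n_rows
    c = extract_patches(rng.random((4, 16, 16)), frame_index=2, patch_size=(3, 3))
    with pytest.raises(ValueError):
        concat_datasets([a, c])


def test_smooth_inputs_yield_sparser_codes_than_structured(rng):
    # smooth-field patches need fewer active features than edge-rich patches
    smooth = np.tile(np.linspace(0.3, 0.7, 18), (18, 1))[None].repeat(3, axis=0)
    structured = make_dynamic_phantom("disks", (18, 18), 3, 2, seed=8).frames
    structured = structured / max(structured.max(), 1e-9)
    cfg = SparsityConfig(alpha1=0.0, alpha2=0.5, rho0=0.05)
    acts = []
    for stack in (smooth, structured):
        ds = extract_patches(stack, frame_index=1, patch_size=(5, 5), stride=1,
                             normalization=(0.0, 1.0))
        params, _ = train_autoencoder(ds.inputs, 12, cfg, learning_rate=0.3,
                                      epochs=60, batch_size=128, rbm_init=False, seed=4)
        acts.append(sigmoid(ds.inputs @ params.W_enc + params.b_enc).mean())
    assert acts[0] < acts[1]
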