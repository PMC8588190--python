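"""Network construction, training mechanics, and prediction."""

import numpy as np
import pytest

from apicalnet import _layers as L
from apicalnet.classifier import (
    LayerSpec,
    NetworkBuildError,
    NetworkConfig,
    TrainingConfig,
    build_network,
    dataset_to_arrays,
    default_network_config,
    predict,
    train,
)
from apicalnet.dataset import LabeledDataset, LabeledSample
from apicalnet.synthetic import generate_tooth_dataset


EXPECTED_SHAPES = [
    ("input", (200, 100, 3)),
    ("convolution", (50, 25, 48)),
    ("relu", (50, 25, 48)),
    ("normalization", (50, 25, 48)),
    ("maxpooling", (25, 13, 48)),
    ("convolution", (13, 7, 48)),
    ("relu", (13, 7, 48)),
    ("normalization", (13, 7, 48)),
    ("maxpooling", (13, 7, 48)),
    ("fully_connected", (1, 1, 2184)),
    ("relu", (1, 1, 2184)),
    ("dropout", (1, 1, 2184)),
    ("fully_connected", (1, 1, 2184)),
    ("relu", (1, 1, 2184)),
    ("dropout", (1, 1, 2184)),
    ("fully_connected", (1, 1, 2)),
    ("softmax", (1, 1, 2)),
    ("class_output", (2,)),
]


def _tooth_dataset(n_per_class, seed=0):
    return generate_tooth_dataset(n_per_class, n_per_class, (200, 100), seed)


def test_canonical_layer_stack_shapes():
    net = build_network()
    assert net.layer_output_shapes() == EXPECTED_SHAPES


def test_fully_connected_sizes():
    net = build_network()
    dense = [l for l in net.layers if isinstance(l, L.Dense)]
    assert [(d.in_units, d.out_units) for d in dense] == [
        (4368, 2184), (2184, 2184), (2184, 2),
    ]


def test_forward_probabilities_normalize(rng):
    net = build_network()
    net.initialize(0)
    x = rng.normal(0, 50, (3, 3, 200, 100)).astype(np.float32)
    probs = net.predict_proba(x)
    assert probs.shape == (3, 2)
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)


def test_build_error_names_deviating_layer():
    config = default_network_config()
    bad = list(config.layers)
    bad[4] = LayerSpec("maxpooling", (26, 13, 48), {"kernel": 3, "stride": 2, "pad": 1})
    with pytest.raises(NetworkBuildError, match="layer 5"):
        build_network(NetworkConfig(layers=tuple(bad)))


def test_config_structure_validation():
    layers = list(default_network_config().layers)
    with pytest.raises(ValueError):
        NetworkConfig(layers=tuple(layers[1:]))  # no input layer
    with pytest.raises(ValueError):
        NetworkConfig(layers=tuple(layers[:-2] + [layers[-1]]))  # softmax missing


def test_training_config_defaults_match_recipe():
    cfg = TrainingConfig()
    assert cfg.momentum == 0.9
    assert cfg.initial_learning_rate == 6e-5
    assert cfg.l2_regularization == 1e-4
    assert cfg.gradient_threshold_method == "l2norm"
    assert np.isinf(cfg.gradient_threshold)
    assert cfg.max_epochs == 100
    assert cfg.mini_batch_size == 128


def test_zero_learning_rate_keeps_initial_weights():
    ds = _tooth_dataset(4, seed=1)
    net = build_network()
    cfg = TrainingConfig(initial_learning_rate=0.0, max_epochs=2,
                         mini_batch_size=8, seed=5)
    net, log = train(net, ds, ds, cfg)
    ref = build_network()
    ref.initialize(cfg.seed)
    for got, want in zip(net.layers, ref.layers):
        for (_, a, _), (_, b, _) in zip(got.params(), want.params()):
            assert np.array_equal(a, b)


def test_epoch_touches_every_sample_exactly_once():
    ds = _tooth_dataset(5, seed=2)  # 10 samples
    seen: list[np.ndarray] = []
    cfg = TrainingConfig(max_epochs=2, mini_batch_size=4, seed=3)
    train(build_network(), ds, ds, cfg,
          batch_hook=lambda it, idx: seen.append(idx))
    flat = np.concatenate(seen)
    assert len(flat) == 2 * len(ds)
    per_epoch = np.split(flat, 2)
    for epoch_indices in per_epoch:
        assert sorted(epoch_indices.tolist()) == list(range(len(ds)))


def test_oversized_batch_warns_and_trains_full_batch():
    ds = _tooth_dataset(3, seed=4)  # 6 samples < 128
    net, log = train(build_network(), ds, ds,
                     TrainingConfig(max_epochs=1, seed=0))
    assert log.warnings
    assert log.rows[-1][1] == 1  # one iteration: a single full batch


def test_log_has_the_seven_verbose_columns():
    ds = _tooth_dataset(3, seed=4)
    _, log = train(build_network(), ds, ds,
                   TrainingConfig(max_epochs=1, mini_batch_size=6, seed=0))
    df = log.to_dataframe()
    assert list(df.columns) == [
        "Epoch", "Iteration", "Time Elapsed", "Mini-Batch Accuracy",
        "Validation Accuracy", "Mini-Batch Loss", "Validation Loss",
    ]
    assert df["Validation Accuracy"].between(0, 100).all()
    assert df["Iteration"].is_monotonic_increasing


def test_training_is_reproducible():
    ds = _tooth_dataset(6, seed=6)
    cfg = TrainingConfig(max_epochs=3, mini_batch_size=6, seed=9)
    net1, log1 = train(build_network(), ds, ds, cfg)
    net2, log2 = train(build_network(), ds, ds, cfg)
    assert log1.rows == log2.rows
    for a, b in zip(net1.layers, net2.layers):
        for (_, wa, _), (_, wb, _) in zip(a.params(), b.params()):
            assert np.array_equal(wa, wb)


def test_zero_images_stay_finite_under_l2():
    blank = LabeledDataset(
        [LabeledSample(np.zeros((200, 100), dtype=np.uint8),
                       "normal" if i % 2 == 0 else "lesion", f"z{i}")
         for i in range(4)]
    )
    cfg = TrainingConfig(max_epochs=100, mini_batch_size=4, seed=1)
    net, log = train(build_network(), blank, blank, cfg)
    assert np.isfinite(log.rows[-1][5]) and np.isfinite(log.rows[-1][6])
    for layer in net.layers:
        for _, value, _ in layer.params():
            assert np.all(np.isfinite(value))
            assert np.abs(value).max() < 10.0


def test_gradient_clipping_accepts_only_l2norm():
    ds = _tooth_dataset(3, seed=4)
    cfg = TrainingConfig(max_epochs=1, mini_batch_size=6,
                         gradient_threshold=1.0,
                         gradient_threshold_method="value")
    with pytest.raises(ValueError):
        train(build_network(), ds, ds, cfg)


def test_predict_requires_training():
    net = build_network()
    with pytest.raises(RuntimeError):
        predict(net, np.zeros((200, 100), dtype=np.uint8))


def test_predict_probabilities_and_determinism():
    ds = _tooth_dataset(4, seed=8)
    net, _ = train(build_network(), ds, ds,
                   TrainingConfig(max_epochs=1, mini_batch_size=8, seed=2))
    img = ds[0].image
    p1, label1 = predict(net, img)
    p2, label2 = predict(net, img)
    assert np.array_equal(p1, p2) and label1 == label2
    assert p1.sum() == pytest.approx(1.0, abs=1e-6)
    assert label1 in ("normal", "lesion")
    # off-resolution input is resized rather than rejected
    p3, _ = predict(net, ds[1].image[::2, ::2])
    assert p3.sum() == pytest.approx(1.0, abs=1e-6)


def test_save_load_roundtrip(tmp_path):
    ds = _tooth_dataset(3, seed=9)
    net, _ = train(build_network(), ds, ds,
                   TrainingConfig(max_epochs=1, mini_batch_size=6, seed=4))
    path = tmp_path / "model.npz"
    net.save(path)
    clone = build_network()
    clone.load_weights(path)
    img = ds[2].image
    assert np.array_equal(predict(net, img)[0], predict(clone, img)[0])


def test_dataset_to_arrays_replicates_channels():
    ds = _tooth_dataset(2, seed=3)
    xs, ys = dataset_to_arrays(ds)
    assert xs.shape == (4, 3, 200, 100)
    assert np.array_equal(xs[:, 0], xs[:, 1]) and np.array_equal(xs[:, 1], xs[:, 2])
    assert sorted(ys.tolist()) == [0, 0, 1, 1]
    bad = LabeledDataset([LabeledSample(np.zeros((10, 10), np.uint8), "normal")])
    with pytest.raises(ValueError):
        dataset_to_arrays(bad)
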