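import numpy as np
import pytest

from conftest import PUBLISHED_SPECIES_CONFUSION, SPECIES_ORDER
from copepodid.ann_classifier import (
    ConfusionMatrix,
    CopepodClassifier,
    NetworkConfig,
    SplitSpec,
    TrainedNetwork,
    collapse_to_genus,
    confusion_and_accuracy,
    forward,
    mse_and_gradient,
    normalize_inputs,
    predict,
    scg_minimize,
    scg_train,
    split_dataset,
    _init_weights,
    _pack,
    _unpack,
)
import pandas as pd


# ------------------------------------------------------------------ splits


def test_240_samples_split_168_36_36():
    labels = np.repeat(SPECIES_ORDER, 30)
    tr, va, te = split_dataset(labels, SplitSpec(seed=0))
    assert (len(tr), len(va), len(te)) == (168, 36, 36)
    combined = np.concatenate([tr, va, te])
    assert len(np.unique(combined)) == 240  # disjoint and exhaustive
    # stratified: every class contributes 21 training rows
    for cls in SPECIES_ORDER:
        assert (labels[tr] == cls).sum() == 21


def test_small_class_partition_and_determinism():
    labels = ["x"] * 10
    a = split_dataset(labels, SplitSpec(seed=5))
    b = split_dataset(labels, SplitSpec(seed=5))
    for p, q in zip(a, b):
        np.testing.assert_array_equal(p, q)
    sizes = tuple(len(s) for s in a)
    assert sum(sizes) == 10
    assert sizes[1] in (1, 2) and sizes[2] in (1, 2)


def test_class_below_three_cannot_stratify():
    with pytest.raises(ValueError, match="class too small to stratify"):
        split_dataset(["a", "a", "b", "b", "b"], SplitSpec())


# ----------------------------------------------------------------- forward


def _random_net(rng, n_in=5, n_hid=4, n_out=3):
    w = _init_weights(rng, n_in, n_hid, n_out)
    W1, b1, W2, b2 = _unpack(w, n_in, n_hid, n_out)
    lo = np.zeros(n_in)
    hi = np.ones(n_in)
    return TrainedNetwork(W1, b1, W2, b2, lo, hi)


def test_zero_network_outputs_one_half():
    net = TrainedNetwork(
        np.zeros((4, 3)), np.zeros(4), np.zeros((2, 4)), np.zeros(2),
        np.zeros(3), np.ones(3),
    )
    np.testing.assert_allclose(forward(net, np.array([0.3, 0.5, 0.9])), 0.5)


def test_normalization_endpoints_map_to_plus_minus_one():
    lo = np.array([1.0, -2.0])
    hi = np.array([3.0, 4.0])
    np.testing.assert_allclose(normalize_inputs(lo[None, :], lo, hi), -1.0)
    np.testing.assert_allclose(normalize_inputs(hi[None, :], lo, hi), 1.0)
    # out-of-range values clip at +-1.2
    far = np.array([[100.0, -100.0]])
    np.testing.assert_allclose(normalize_inputs(far, lo, hi), [[1.2, -1.2]])


def test_forward_matches_per_neuron_loop_oracle():
    rng = np.random.default_rng(7)
    net = _random_net(rng)
    x = rng.random(5)
    xn = np.clip(2 * (x - net.norm_lo) / (net.norm_hi - net.norm_lo) - 1,
                 -1.2, 1.2)

    def sig(z):
        return 1 / (1 + np.exp(-z))

    h = [sig(sum(net.W1[j, i] * xn[i] for i in range(5)) + net.b1[j])
         for j in range(4)]
    y = [sig(sum(net.W2[k, j] * h[j] for j in range(4)) + net.b2[k])
         for k in range(3)]
    np.testing.assert_allclose(forward(net, x)[0], y, atol=1e-12)


def test_dimension_mismatch_errors():
    net = _random_net(np.random.default_rng(0))
    with pytest.raises(ValueError, match="feature dimension error"):
        forward(net, np.zeros(7))


# ---------------------------------------------------------------- gradient


def test_zero_error_gives_zero_mse_and_output_gradient():
    # contrive targets equal to outputs
    rng = np.random.default_rng(1)
    n_in, n_hid, n_out = 3, 2, 2
    w = _init_weights(rng, n_in, n_hid, n_out)
    Xn = rng.normal(size=(4, n_in))
    from copepodid.ann_classifier import _sigmoid

    W1, b1, W2, b2 = _unpack(w, n_in, n_hid, n_out)
    H = _sigmoid(Xn @ W1.T + b1)
    T = _sigmoid(H @ W2.T + b2)
    mse, g = mse_and_gradient(w, Xn, T, n_hid)
    assert mse == 0.0
    np.testing.assert_allclose(g, 0.0, atol=1e-15)


@pytest.mark.parametrize("seed", range(20))
def test_gradient_matches_central_finite_differences(seed):
    rng = np.random.default_rng(seed)
    n_in, n_hid, n_out = 7, 3, 2
    Xn = rng.normal(size=(5, n_in))
    T = rng.random((5, n_out))
    w = rng.normal(size=n_hid * n_in + n_hid + n_out * n_hid + n_out) * 0.5
    _, g = mse_and_gradient(w, Xn, T, n_hid)
    num = np.empty_like(w)
    for i in range(w.size):
        e = np.zeros_like(w)
        e[i] = 1e-6
        num[i] = (mse_and_gradient(w + e, Xn, T, n_hid)[0]
                  - mse_and_gradient(w - e, Xn, T, n_hid)[0]) / 2e-6
    np.testing.assert_allclose(num, g, rtol=1e-5, atol=1e-9)


def test_duplicating_samples_leaves_mse_and_gradient_unchanged():
    rng = np.random.default_rng(2)
    Xn = rng.normal(size=(6, 4))
    T = rng.random((6, 3))
    w = rng.normal(size=3 * 4 + 3 + 3 * 3 + 3) * 0.4
    a = mse_and_gradient(w, Xn, T, 3)
    b = mse_and_gradient(w, np.vstack([Xn, Xn]), np.vstack([T, T]), 3)
    assert a[0] == pytest.approx(b[0], rel=1e-12)
    np.testing.assert_allclose(a[1], b[1], rtol=1e-10)


# --------------------------------------------------------------------- SCG


@pytest.mark.parametrize("seed", range(5))
def test_scg_reaches_quadratic_minimum_in_n_plus_5_iterations(seed):
    rng = np.random.default_rng(seed)
    n = 8
    A = rng.normal(size=(n, n))
    A = A @ A.T + np.eye(n)
    b = rng.normal(size=n)
    fun = lambda w: (0.5 * w @ A @ w - b @ w, A @ w - b)
    w, f = scg_minimize(fun, np.zeros(n), max_iter=n + 5)
    wopt = np.linalg.solve(A, b)
    assert f - fun(wopt)[0] <= 1e-8
    np.testing.assert_allclose(w, wopt, atol=1e-4)


def test_xor_learned_by_most_seeds():
    X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], float)
    T = np.array([[1, 0], [0, 1], [0, 1], [1, 0]], float)
    ok = 0
    for seed in range(5):
        cfg = NetworkConfig(n_inputs=2, n_hidden=10, n_outputs=2,
                            max_epochs=500, max_validation_failures=500,
                            n_restarts=1, seed=seed)
        net = scg_train(X, T, X, T, cfg, class_labels=["even", "odd"])
        ok += net.training_record["best_val_mse"] < 0.01
    assert ok >= 4


def test_linearly_separable_blobs_reach_perfect_training_accuracy():
    rng = np.random.default_rng(4)
    X = np.vstack([rng.normal(0, 1, (50, 2)), rng.normal(5, 1, (50, 2))])
    labels = np.array(["lo"] * 50 + ["hi"] * 50)
    T = np.column_stack([labels == "lo", labels == "hi"]).astype(float)
    cfg = NetworkConfig(n_inputs=2, n_hidden=4, n_outputs=2, max_epochs=300,
                        n_restarts=2, seed=0)
    net = scg_train(X, T, X, T, cfg, class_labels=["lo", "hi"])
    assert (predict(net, X) == labels).all()


def test_early_stopping_returns_best_validation_epoch():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(60, 3))
    T = np.column_stack([X[:, 0] > 0, X[:, 0] <= 0]).astype(float)
    # validation drawn from a different distribution: overfitting sets in
    Xv = rng.normal(2.0, 0.5, size=(30, 3))
    Tv = np.column_stack([Xv[:, 1] > 2, Xv[:, 1] <= 2]).astype(float)
    cfg = NetworkConfig(n_inputs=3, n_hidden=8, n_outputs=2, max_epochs=200,
                        max_validation_failures=6, n_restarts=1, seed=1)
    net = scg_train(X, T, Xv, Tv, cfg, class_labels=["a", "b"])
    rec = net.training_record
    assert rec["best_val_mse"] == pytest.approx(min(rec["val_mse"]), rel=1e-12)
    # returned weights really achieve the recorded minimum
    from copepodid.ann_classifier import normalize_inputs as norm

    Xn = norm(Xv, net.norm_lo, net.norm_hi)
    w = _pack(net.W1, net.b1, net.W2, net.b2)
    mse, _ = mse_and_gradient(w, Xn, Tv, cfg.n_hidden)
    assert mse == pytest.approx(rec["best_val_mse"], rel=1e-12)


# ----------------------------------------------------------- prediction


def test_predict_argmax_and_tie_break():
    net = TrainedNetwork(
        np.zeros((2, 2)), np.zeros(2), np.zeros((3, 2)), np.zeros(3),
        np.zeros(2), np.ones(2), class_labels=["A", "B", "C"],
    )
    # all outputs exactly 0.5 -> tie -> lowest index
    assert predict(net, np.array([0.5, 0.5]))[0] == "A"
    net.b2 = np.array([0.0, 2.0, 0.0])
    assert predict(net, np.array([0.5, 0.5]))[0] == "B"


# ----------------------------------------------------------- evaluation


def _sequences_from_counts(counts, labels):
    true, pred = [], []
    for i, ti in enumerate(labels):
        for j, pj in enumerate(labels):
            true += [ti] * counts[i][j]
            pred += [pj] * counts[i][j]
    return true, pred


def test_published_confusion_matrix_accuracies():
    """Recomputing accuracy from the published species-level confusion
    table: 149/160 correct -> 93.13% overall after half-up rounding."""
    true, pred = _sequences_from_counts(PUBLISHED_SPECIES_CONFUSION,
                                        SPECIES_ORDER)
    cm, per_class, overall = confusion_and_accuracy(true, pred, SPECIES_ORDER)
    assert overall == 93.13
    assert per_class["Tf"] == 85.0
    assert per_class["Tb"] == 95.0
    assert per_class["As"] == 100.0
    assert cm.total == 160


def test_published_matrix_collapses_to_genus_accuracy():
    cm = ConfusionMatrix(PUBLISHED_SPECIES_CONFUSION, SPECIES_ORDER)
    genus = collapse_to_genus(cm)
    assert genus.overall_accuracy() == 98.13
    assert genus.total == 160  # counts conserved
    assert genus.class_labels == ["Acartia", "Bestiolina", "Oithona",
                                  "Parvocalanus", "Tortanus"]
    assert genus.per_class_accuracy()["Tortanus"] == 100.0


def test_identity_predictions_are_all_100():
    true = SPECIES_ORDER * 3
    cm, per_class, overall = confusion_and_accuracy(true, true, SPECIES_ORDER)
    assert overall == 100.0
    assert all(v == 100.0 for v in per_class.values())
    genus = collapse_to_genus(cm)
    assert np.count_nonzero(genus.counts - np.diag(np.diag(genus.counts))) == 0


def test_unknown_label_rejected():
    with pytest.raises(ValueError, match="unknown label"):
        confusion_and_accuracy(["As"], ["Zz"], SPECIES_ORDER)
    cm = ConfusionMatrix(np.eye(2, dtype=int), ["As", "Zz"])
    with pytest.raises(ValueError, match="unknown label"):
        collapse_to_genus(cm)


def test_model_results_roundtrip_and_summary():
    rng = np.random.default_rng(6)
    X = pd.DataFrame(
        np.vstack([rng.normal(i, 0.3, (12, 3)) for i in range(3)]),
        columns=["u", "v", "w"],
    )
    labels = np.repeat(["p", "q", "r"], 12)
    cfg = NetworkConfig(n_inputs=3, n_hidden=6, n_outputs=3, max_epochs=200,
                        n_restarts=2, seed=3)
    results = CopepodClassifier(X, labels, config=cfg).fit()
    cm, _, overall = results.evaluate(X, labels)
    assert overall > 90.0
    text = results.summary()
    assert "3-6-3" in text and "p, q, r" in text
    # JSON round trip preserves predictions
    net2 = TrainedNetwork.from_json(results.network.to_json())
    np.testing.assert_array_equal(
        predict(net2, X.to_numpy(float)), results.predict(X)
    )
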