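"""Two-layer sigmoid pattern-recognition network for copepod features.

Architecture: n_inputs -> 10 logistic hidden units -> 8 logistic
output units (one per species), trained full-batch on mean squared
error against 0/1 one-hot targets with Moller's scaled conjugate
gradient (SCG).  Inputs are min-max normalised to [-1, 1] using the
training partition's per-feature bounds; values outside the training
range are clipped to [-1.2, 1.2] after mapping so the sigmoids cannot
be driven far into saturation by an outlier.

Training uses validation-based early stopping: the validation MSE is
tracked every epoch and training stops after ``max_validation_failures``
consecutive epochs without a new validation minimum, returning the
weights from the best-validation epoch.  Because SCG from a random
start is not guaranteed to find a good minimum, training restarts
``n_restarts`` times from derived seeds and keeps the restart with the
lowest validation MSE.

The model/results surface follows the statsmodels convention:
``CopepodClassifier(features, labels, config).fit()`` returns a
:class:`ClassifierResults` that holds the trained network, the
training record, and evaluation helpers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .image_io import DEFAULT_GENUS_MAP

__all__ = [
    "NetworkConfig",
    "SplitSpec",
    "TrainedNetwork",
    "ConfusionMatrix",
    "CopepodClassifier",
    "ClassifierResults",
    "split_dataset",
    "forward",
    "mse_and_gradient",
    "scg_minimize",
    "scg_train",
    "predict",
    "confusion_and_accuracy",
    "collapse_to_genus",
    "DEFAULT_GENUS_MAP",
]


# --------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class NetworkConfig:
    n_inputs: int = 7
    n_hidden: int = 10
    n_outputs: int = 8
    max_epochs: int = 1000
    max_validation_failures: int = 6
    n_restarts: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_inputs", "n_hidden", "n_outputs", "max_epochs",
                     "max_validation_failures", "n_restarts"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass(frozen=True)
class SplitSpec:
    """70/15/15 stratified train/validation/test split."""

    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


# --------------------------------------------------------------------
# dataset splitting


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_dataset(labels, spec: SplitSpec = SplitSpec()):
    """Disjoint, exhaustive, per-class stratified index sets.

    Global partition sizes are round(fraction * n) for validation and
    test, with the remainder going to training.  Within the
    stratification those totals are met by largest-remainder
    allocation; the leftover validation slots go to the first classes
    in label order and the leftover test slots to the last, so no class
    is shorted on training data twice.  Assignment within a class is a
    seeded shuffle, so the same seed reproduces the same split.
    """
    labels = np.asarray(labels)
    n = len(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if spec.stratified and counts.min() < 3:
        raise ValueError("class too small to stratify")
    _, f_val, f_test = spec.fractions
    total_val = _round_half_away(f_val * n)
    total_test = _round_half_away(f_test * n)

    base_val = np.floor(f_val * counts).astype(int)
    base_test = np.floor(f_test * counts).astype(int)
    n_val = base_val.copy()
    n_test = base_test.copy()
    for i in range(total_val - base_val.sum()):  # extras ascending
        n_val[i % len(classes)] += 1
    for i in range(total_test - base_test.sum()):  # extras descending
        n_test[len(classes) - 1 - (i % len(classes))] += 1

    rng = np.random.default_rng(spec.seed)
    train_idx, val_idx, test_idx = [], [], []
    for k, cls in enumerate(classes):
        idx = np.nonzero(labels == cls)[0]
        idx = rng.permutation(idx)
        val_idx.extend(idx[: n_val[k]])
        test_idx.extend(idx[n_val[k]: n_val[k] + n_test[k]])
        train_idx.extend(idx[n_val[k] + n_test[k]:])
    return (
        np.sort(np.array(train_idx, dtype=int)),
        np.sort(np.array(val_idx, dtype=int)),
        np.sort(np.array(test_idx, dtype=int)),
    )


# --------------------------------------------------------------------
# network


@dataclass
class TrainedNetwork:
    """Weights, input-normalisation bounds and label order of one net."""

    W1: np.ndarray  # (n_hidden, n_inputs)
    b1: np.ndarray  # (n_hidden,)
    W2: np.ndarray  # (n_outputs, n_hidden)
    b2: np.ndarray  # (n_outputs,)
    norm_lo: np.ndarray  # per-feature training minima
    norm_hi: np.ndarray  # per-feature training maxima
    class_labels: list[str] = field(default_factory=list)
    training_record: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in asdict(self).items()
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TrainedNetwork":
        d = json.loads(text)
        for k in ("W1", "b1", "W2", "b2", "norm_lo", "norm_hi"):
            d[k] = np.asarray(d[k], dtype=float)
        return cls(**d)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def normalize_inputs(X: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Map features to [-1, 1] by training min/max, clipping to [-1.2, 1.2]."""
    span = np.where(hi > lo, hi - lo, 1.0)
    Xn = 2.0 * (X - lo) / span - 1.0
    return np.clip(Xn, -1.2, 1.2)


def forward(net: TrainedNetwork, X: np.ndarray) -> np.ndarray:
    """Network outputs for raw (unnormalised) feature rows."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != net.W1.shape[1]:
        raise ValueError("feature dimension error")
    Xn = normalize_inputs(X, net.norm_lo, net.norm_hi)
    h = _sigmoid(Xn @ net.W1.T + net.b1)
    return _sigmoid(h @ net.W2.T + net.b2)


# flat parameter vector <-> weight matrices

def _unpack(w: np.ndarray, n_in: int, n_hid: int, n_out: int):
    i = 0
    W1 = w[i:i + n_hid * n_in].reshape(n_hid, n_in); i += n_hid * n_in
    b1 = w[i:i + n_hid]; i += n_hid
    W2 = w[i:i + n_out * n_hid].reshape(n_out, n_hid); i += n_out * n_hid
    b2 = w[i:i + n_out]
    return W1, b1, W2, b2


def _pack(W1, b1, W2, b2) -> np.ndarray:
    return np.concatenate([W1.ravel(), b1, W2.ravel(), b2])


def mse_and_gradient(w: np.ndarray, Xn: np.ndarray, T: np.ndarray,
                     n_hid: int) -> tuple[float, np.ndarray]:
    """Full-batch MSE and its gradient by backpropagation.

    ``Xn`` is already normalised; the MSE is the mean over samples and
    output nodes of (y - t)^2.
    """
    n, n_in = Xn.shape
    n_out = T.shape[1]
    W1, b1, W2, b2 = _unpack(w, n_in, n_hid, n_out)
    H = _sigmoid(Xn @ W1.T + b1)
    Y = _sigmoid(H @ W2.T + b2)
    E = Y - T
    mse = float(np.mean(E * E))
    # d mse / dY = 2 E / (n * n_out)
    dZ2 = (2.0 / (n * n_out)) * E * Y * (1.0 - Y)
    gW2 = dZ2.T @ H
    gb2 = dZ2.sum(axis=0)
    dH = dZ2 @ W2
    dZ1 = dH * H * (1.0 - H)
    gW1 = dZ1.T @ Xn
    gb1 = dZ1.sum(axis=0)
    return mse, _pack(gW1, gb1, gW2, gb2)


# --------------------------------------------------------------------
# scaled conjugate gradient (Moller 1993)


def scg_minimize(fun, w0: np.ndarray, max_iter: int = 1000,
                 grad_tol: float = 1e-8, sigma: float = 1e-4,
                 lambda_init: float = 1e-6, callback=None):
    """Minimise fun(w) -> (value, gradient) by scaled conjugate gradient.

    A Hessian-free conjugate-gradient method: curvature along the
    search direction is estimated by a finite difference of gradients
    with step ``sigma``/|p|, and a Levenberg-Marquardt-style scaling
    ``lambda`` keeps the quadratic model trust-region positive
    definite.  ``callback(k, w, value)`` runs after every accepted
    step and may return True to stop early.
    """
    w = w0.astype(float).copy()
    n_params = w.size
    f, g = fun(w)
    r = -g
    p = r.copy()
    lam = lambda_init
    lam_bar = 0.0
    success = True
    delta = 0.0
    s = np.zeros_like(w)
    for k in range(1, max_iter + 1):
        p2 = float(p @ p)
        if p2 == 0.0 or np.linalg.norm(r) < grad_tol:
            break
        if success:
            sigma_k = sigma / np.sqrt(p2)
            _, g_plus = fun(w + sigma_k * p)
            s = (g_plus - g) / sigma_k
            delta = float(p @ s)
        delta_k = delta + (lam - lam_bar) * p2
        if delta_k <= 0:  # make the Hessian model positive definite
            lam_bar = 2.0 * (lam - delta_k / p2)
            delta_k = -delta_k + lam * p2
            lam = lam_bar
        mu = float(p @ r)
        alpha = mu / delta_k
        f_new, g_new = fun(w + alpha * p)
        comparison = 2.0 * delta_k * (f - f_new) / (mu * mu)
        if comparison >= 0 and np.isfinite(f_new):
            w = w + alpha * p
            f = f_new
            g = g_new
            r_new = -g
            lam_bar = 0.0
            success = True
            if k % n_params == 0:
                p = r_new.copy()  # periodic restart along steepest descent
            else:
                beta = float((r_new @ r_new - r_new @ r) / mu)
                p = r_new + beta * p
            r = r_new
            if comparison >= 0.75:
                lam = max(lam * 0.25, 1e-20)
            if callback is not None and callback(k, w, f):
                break
        else:
            lam_bar = lam
            success = False
        if comparison < 0.25:
            lam = lam + delta_k * (1.0 - comparison) / p2
        if not np.isfinite(lam) or lam > 1e100:
            break
    return w, f


# --------------------------------------------------------------------
# training


def _init_weights(rng: np.random.Generator, n_in: int, n_hid: int,
                  n_out: int) -> np.ndarray:
    W1 = rng.uniform(-0.5, 0.5, (n_hid, n_in)) / np.sqrt(n_in)
    b1 = rng.uniform(-0.5, 0.5, n_hid) / np.sqrt(n_in)
    W2 = rng.uniform(-0.5, 0.5, (n_out, n_hid)) / np.sqrt(n_hid)
    b2 = rng.uniform(-0.5, 0.5, n_out) / np.sqrt(n_hid)
    return _pack(W1, b1, W2, b2)


def _one_hot(labels, class_labels) -> np.ndarray:
    index = {c: i for i, c in enumerate(class_labels)}
    T = np.zeros((len(labels), len(class_labels)))
    for i, lab in enumerate(labels):
        T[i, index[lab]] = 1.0
    return T


def scg_train(X_train, T_train, X_val, T_val,
              config: NetworkConfig = NetworkConfig(),
              class_labels=None) -> TrainedNetwork:
    """Train with SCG + early stopping, best of ``n_restarts`` restarts.

    ``X_train``/``X_val`` are raw feature rows; normalisation bounds
    are taken from the training partition only.  Returns the network
    whose weights minimised validation MSE.
    """
    X_train = np.asarray(X_train, dtype=float)
    X_val = np.asarray(X_val, dtype=float)
    T_train = np.asarray(T_train, dtype=float)
    T_val = np.asarray(T_val, dtype=float)
    if X_train.size == 0 or X_val.size == 0:
        raise ValueError("train and validation sets must be non-empty")
    n_in, n_hid, n_out = X_train.shape[1], config.n_hidden, T_train.shape[1]
    lo = X_train.min(axis=0)
    hi = X_train.max(axis=0)
    Xn_tr = normalize_inputs(X_train, lo, hi)
    Xn_va = normalize_inputs(X_val, lo, hi)

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_restarts)
    best: dict | None = None
    restarts_record = []
    for ridx, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        w0 = _init_weights(rng, n_in, n_hid, n_out)

        state = {
            "best_val": np.inf, "best_w": w0.copy(), "fails": 0,
            "train_mse": [], "val_mse": [],
        }

        def track(k, w, f_train, state=state):
            val_mse, _ = mse_and_gradient(w, Xn_va, T_val, n_hid)
            state["train_mse"].append(f_train)
            state["val_mse"].append(val_mse)
            if val_mse < state["best_val"]:
                state["best_val"] = val_mse
                state["best_w"] = w.copy()
                state["fails"] = 0
            else:
                state["fails"] += 1
            return state["fails"] >= config.max_validation_failures

        scg_minimize(
            lambda w: mse_and_gradient(w, Xn_tr, T_train, n_hid),
            w0, max_iter=config.max_epochs, callback=track,
        )
        if not state["val_mse"]:  # no step accepted; fall back to w0
            state["best_val"], _ = mse_and_gradient(w0, Xn_va, T_val, n_hid)
        restarts_record.append(
            {"restart": ridx, "epochs": len(state["val_mse"]),
             "best_val_mse": float(state["best_val"])}
        )
        if best is None or state["best_val"] < best["best_val"]:
            best = state | {"restart": ridx}

    W1, b1, W2, b2 = _unpack(best["best_w"], n_in, n_hid, n_out)
    return TrainedNetwork(
        W1=W1, b1=b1, W2=W2, b2=b2, norm_lo=lo, norm_hi=hi,
        class_labels=list(class_labels) if class_labels is not None else [],
        training_record={
            "train_mse": [float(v) for v in best["train_mse"]],
            "val_mse": [float(v) for v in best["val_mse"]],
            "best_val_mse": float(best["best_val"]),
            "chosen_restart": best["restart"],
            "restarts": restarts_record,
        },
    )


def predict(net: TrainedNetwork, X) -> np.ndarray:
    """Class labels by argmax output; ties go to the lowest class index."""
    Y = forward(net, X)
    idx = np.argmax(Y, axis=1)
    labels = net.class_labels or [str(i) for i in range(Y.shape[1])]
    return np.asarray([labels[i] for i in idx])


# --------------------------------------------------------------------
# evaluation


def _pct(numer: int, denom: int) -> float:
    """Exact percentage rounded half-away-from-zero to 2 decimals."""
    if denom == 0:
        return float("nan")
    q = (Decimal(100 * numer) / Decimal(denom)).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP
    )
    return float(q)


@dataclass
class ConfusionMatrix:
    """True x predicted count table with accuracy accessors."""

    counts: np.ndarray
    class_labels: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        g = len(self.class_labels)
        if self.counts.shape != (g, g):
            raise ValueError("counts must be square over class_labels")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def per_class_accuracy(self) -> dict[str, float]:
        out = {}
        for i, lab in enumerate(self.class_labels):
            out[lab] = _pct(int(self.counts[i, i]), int(self.counts[i].sum()))
        return out

    def overall_accuracy(self) -> float:
        return _pct(int(np.trace(self.counts)), self.total)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.class_labels, columns=self.class_labels
        )


def confusion_and_accuracy(true_labels, predicted_labels, class_labels):
    """Confusion counts plus per-class and overall accuracy (percent)."""
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label sequences must have equal length")
    index = {c: i for i, c in enumerate(class_labels)}
    unknown = set(true_labels) | set(predicted_labels)
    unknown -= set(class_labels)
    if unknown:
        raise ValueError(f"unknown label: {sorted(unknown)}")
    g = len(class_labels)
    counts = np.zeros((g, g), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        counts[index[t], index[p]] += 1
    cm = ConfusionMatrix(counts, list(class_labels))
    return cm, cm.per_class_accuracy(), cm.overall_accuracy()


def collapse_to_genus(cm: ConfusionMatrix, genus_map: dict | None = None) -> ConfusionMatrix:
    """Sum species counts into genera on both axes.

    Genus order follows first appearance in the species label order.
    """
    genus_map = genus_map or DEFAULT_GENUS_MAP
    missing = [lab for lab in cm.class_labels if lab not in genus_map]
    if missing:
        raise ValueError(f"unknown label: {missing}")
    genera: list[str] = []
    for lab in cm.class_labels:
        if genus_map[lab] not in genera:
            genera.append(genus_map[lab])
    gidx = {g: i for i, g in enumerate(genera)}
    counts = np.zeros((len(genera), len(genera)), dtype=int)
    for i, ti in enumerate(cm.class_labels):
        for j, tj in enumerate(cm.class_labels):
            counts[gidx[genus_map[ti]], gidx[genus_map[tj]]] += cm.counts[i, j]
    return ConfusionMatrix(counts, genera)


# --------------------------------------------------------------------
# model / results


class CopepodClassifier:
    """Pattern-recognition model over a feature table.

    Parameters
    ----------
    features : DataFrame
        One row per specimen, feature columns only.
    labels : array-like
        Species code per row.
    config : NetworkConfig
    split : SplitSpec
        How to partition rows into train/validation/(internal) test.
    """

    def __init__(self, features: pd.DataFrame, labels,
                 config: NetworkConfig | None = None,
                 split: SplitSpec | None = None) -> None:
        self.features = features.reset_index(drop=True)
        self.labels = np.asarray(labels)
        self.class_labels = sorted(np.unique(self.labels))
        self.config = config or NetworkConfig(
            n_inputs=features.shape[1], n_outputs=len(self.class_labels)
        )
        self.split = split or SplitSpec(seed=self.config.seed)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, feature_columns,
                       label_column: str = "species_code", **kw):
        return cls(frame[list(feature_columns)], frame[label_column].to_numpy(), **kw)

    def fit(self) -> "ClassifierResults":
        X = self.features.to_numpy(dtype=float)
        tr, va, te = split_dataset(self.labels, self.split)
        T = _one_hot(self.labels, self.class_labels)
        net = scg_train(X[tr], T[tr], X[va], T[va], self.config,
                        class_labels=self.class_labels)
        return ClassifierResults(self, net, tr, va, te)


class ClassifierResults:
    """Fit artefacts: trained network, split indices, evaluation."""

    def __init__(self, model: CopepodClassifier, network: TrainedNetwork,
                 train_idx, val_idx, test_idx) -> None:
        self.model = model
        self.network = network
        self.train_idx = train_idx
        self.val_idx = val_idx
        self.test_idx = test_idx

    def predict(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.model.features.columns].to_numpy(dtype=float)
        return predict(self.network, X)

    def evaluate(self, X, true_labels):
        """(species ConfusionMatrix, per-class %, overall %) on new data."""
        calls = self.predict(X)
        return confusion_and_accuracy(true_labels, calls,
                                      self.model.class_labels)

    def internal_confusion(self) -> ConfusionMatrix:
        """Confusion over all rows seen at fit time (train+val+test)."""
        calls = self.predict(self.model.features)
        cm, _, _ = confusion_and_accuracy(self.model.labels, calls,
                                          self.model.class_labels)
        return cm

    def summary(self) -> str:
        rec = self.network.training_record
        lines = [
            "Copepod pattern-recognition network",
            f"  architecture : {self.network.W1.shape[1]}-"
            f"{self.network.W1.shape[0]}-{self.network.W2.shape[0]} (logistic)",
            f"  classes      : {', '.join(self.model.class_labels)}",
            f"  split        : {len(self.train_idx)}/{len(self.val_idx)}/"
            f"{len(self.test_idx)} (train/val/test)",
            f"  epochs run   : {len(rec.get('val_mse', []))} "
            f"(restart {rec.get('chosen_restart')} of "
            f"{len(rec.get('restarts', []))})",
            f"  best val MSE : {rec.get('best_val_mse'):.6g}",
        ]
        cm = self.internal_confusion()
        lines.append(f"  fit-set overall accuracy: {cm.overall_accuracy():.2f}%")
        return "\n".join(lines)
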