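"""The 2D fully convolutional residual contact network, its 1D
secondary-structure sibling, training, and the split/weight ensemble.

The contact network takes the L x L x 51 feature tensor and emits, for
every residue pair, a 3-class softmax over {non-contact, contact, ignored}.
Its default architecture is an entry convolution plus 19 residual blocks of
two convolutions each plus a final 3-channel convolution — 40 convolutional
layers, 64 filters of size 3 x 3 each, about 1.4 million trainable
parameters.  The feature map is averaged with its transpose before the last
convolution and the output logits are averaged with their transpose again,
so predicted probabilities are exactly symmetric in (i, j).

Training minimises cross-entropy with a configurable weight on the contact
class (the benchmark protocol uses weights 1 and 4); pairs labelled
``ignored`` carry zero weight.  The production protocol splits the training
set five times with pairwise-disjoint validation subsets and trains one
model per (split, weight) combination; the ensemble prediction is the
arithmetic mean of the ten probability maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .core import ContactMap, IGNORED
from .nnet import ResidualCNN

SS_INPUT_CHANNELS = 40  # 20 profile + 20 one-hot sequence


@dataclass
class NetworkConfig:
    """Architecture hyper-parameters of the residual networks."""

    in_channels: int = 51
    n_filters: int = 64
    kernel_size: int = 3
    n_blocks: int = 19
    out_channels: int = 3
    ss_layers: int = 10  # conv layers of the 1D secondary-structure variant

    def __post_init__(self) -> None:
        for name in ("in_channels", "n_filters", "kernel_size", "n_blocks",
                     "out_channels", "ss_layers"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.ss_layers % 2 != 0:
            raise ValueError("ss_layers must be even (entry + blocks + final)")

    @property
    def n_conv_layers(self) -> int:
        """Entry + 2 per residual block + final."""
        return 2 * self.n_blocks + 2

    @property
    def n_parameters(self) -> int:
        """Closed-form trainable parameter count of the 2D network."""
        k2 = self.kernel_size ** 2
        entry = k2 * self.in_channels * self.n_filters + self.n_filters
        block = 2 * (k2 * self.n_filters * self.n_filters + self.n_filters)
        final = k2 * self.n_filters * self.out_channels + self.out_channels
        return entry + self.n_blocks * block + final


@dataclass
class TrainConfig:
    """Optimisation hyper-parameters; the seed is mandatory."""

    seed: int
    contact_weight: float = 1.0
    learning_rate: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 1e-4
    epochs: int = 30

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a random seed is required")
        if self.contact_weight <= 0:
            raise ValueError("contact_weight must be positive")


def build_contact_network(cfg: NetworkConfig | None = None, seed: int = 0,
                          dtype=np.float32) -> ResidualCNN:
    """Assemble the 2D contact network from a config."""
    cfg = cfg or NetworkConfig()
    k = cfg.kernel_size
    return ResidualCNN(cfg.in_channels, cfg.n_filters, cfg.n_blocks,
                       cfg.out_channels, kernel=(k, k), symmetrize=True,
                       seed=seed, dtype=dtype)


def build_ss_network(cfg: NetworkConfig | None = None, seed: int = 0,
                     n_filters: int | None = None,
                     dtype=np.float32) -> ResidualCNN:
    """Assemble the 1D secondary-structure network (10 conv layers)."""
    cfg = cfg or NetworkConfig()
    blocks = (cfg.ss_layers - 2) // 2
    return ResidualCNN(SS_INPUT_CHANNELS, n_filters or cfg.n_filters, blocks,
                       3, kernel=(1, cfg.kernel_size), symmetrize=False,
                       seed=seed, dtype=dtype)


def _labels_array(labels) -> np.ndarray:
    if isinstance(labels, ContactMap):
        return labels.states.astype(np.int64)
    return np.asarray(labels, dtype=np.int64)


def _features_to_input(features: np.ndarray, c_in: int, dtype) -> np.ndarray:
    f = np.asarray(features)
    if f.ndim != 3 or f.shape[0] != f.shape[1] or f.shape[2] != c_in:
        raise ValueError(
            f"feature tensor must be (L, L, {c_in}); got {f.shape}"
        )
    return np.ascontiguousarray(f.transpose(2, 0, 1)).astype(dtype)


def predict_contact_map(model: ResidualCNN, features: np.ndarray,
                        full: bool = False) -> np.ndarray:
    """Contact-probability map for one target; exactly symmetric.

    Returns the (L, L) contact-class probability, or with ``full=True`` the
    (L, L, 3) per-pair class probabilities (non-contact, contact, ignored),
    which sum to one at every pair.  The reported P is the raw contact-class
    probability, not renormalised over the ignore class.
    """
    x = _features_to_input(features, model.c_in, model.entry.W.dtype)
    probs = model.forward(x)  # (3, L, L)
    if full:
        return probs.transpose(1, 2, 0)
    return probs[1]


def train_model(model: ResidualCNN, dataset, cfg: TrainConfig,
                validation=None) -> dict:
    """Train in place with momentum SGD; returns the loss trace.

    ``dataset`` is a sequence of (feature tensor, ternary label map) pairs;
    label maps may be ContactMap objects or integer arrays.  Targets whose
    labels are entirely ``ignored`` are skipped with a warning.  Class
    weights are (1, contact_weight, 0): ignored pairs contribute zero loss
    and zero gradient.  Deterministic given ``cfg.seed``.
    """
    if len(dataset) == 0:
        raise ValueError("empty training dataset")
    class_weights = np.array([1.0, cfg.contact_weight, 0.0])
    items = []
    for features, labels in dataset:
        y = _labels_array(labels)
        if (y == IGNORED).all():
            warnings.warn("skipping target whose labels are entirely ignored")
            continue
        items.append((_features_to_input(features, model.c_in,
                                         model.entry.W.dtype), y))
    if not items:
        raise ValueError("no trainable targets in dataset")
    rng = np.random.default_rng(cfg.seed)
    trace = {"train_loss": [], "val_loss": []}
    for _ in range(cfg.epochs):
        order = rng.permutation(len(items))
        losses = []
        for idx in order:
            x, y = items[idx]
            probs = model.forward(x, train=True)
            loss, dlogits = model.loss_and_grad(probs, y, class_weights)
            model.zero_grad()
            model.backward(dlogits)
            model.sgd_step(cfg.learning_rate, cfg.momentum, cfg.weight_decay)
            losses.append(loss)
        trace["train_loss"].append(float(np.mean(losses)))
        if validation:
            vlosses = []
            for features, labels in validation:
                x = _features_to_input(features, model.c_in,
                                       model.entry.W.dtype)
                y = _labels_array(labels)
                probs = model.forward(x)
                vloss, _ = model.loss_and_grad(probs, y, class_weights)
                vlosses.append(vloss)
            trace["val_loss"].append(float(np.mean(vlosses)))
    return trace


def ensemble_predict(models, features: np.ndarray) -> np.ndarray:
    """Arithmetic mean of the members' contact-probability maps."""
    if len(models) == 0:
        raise ValueError("ensemble needs at least one model")
    maps = []
    for model in models:
        p = predict_contact_map(model, features)
        if maps and p.shape != maps[0].shape:
            raise ValueError("ensemble members produced incompatible shapes")
        maps.append(p)
    return np.mean(maps, axis=0)


@dataclass(frozen=True)
class EnsembleJob:
    """One (training split, contact-class weight) training job."""

    split_index: int
    contact_weight: float
    train_ids: tuple
    validation_ids: tuple


def make_ensemble_splits(ids, n_splits: int = 5, validation_size: int = 800,
                         weights=(1.0, 4.0), seed: int = 0) -> list[EnsembleJob]:
    """Build the (5 splits) x (weights {1, 4}) = 10 training jobs.

    Validation subsets are pairwise disjoint: the id list is shuffled once
    and consecutive blocks of ``validation_size`` ids become the validation
    subsets; each job trains on all remaining ids.
    """
    ids = list(ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate target ids")
    if n_splits * validation_size > len(ids):
        raise ValueError(
            f"{n_splits} disjoint validation subsets of {validation_size} "
            f"need {n_splits * validation_size} ids; got {len(ids)}"
        )
    rng = np.random.default_rng(seed)
    shuffled = [ids[k] for k in rng.permutation(len(ids))]
    jobs = []
    for s in range(n_splits):
        val = tuple(shuffled[s * validation_size:(s + 1) * validation_size])
        val_set = set(val)
        train = tuple(t for t in shuffled if t not in val_set)
        for w in weights:
            jobs.append(EnsembleJob(split_index=s, contact_weight=float(w),
                                    train_ids=train, validation_ids=val))
    return jobs


def save_model(path, model: ResidualCNN, config: dict | None = None) -> None:
    """Checkpoint a network as .npz with its architecture embedded."""
    arrays = {}
    for k, layer in enumerate(model.conv_layers):
        arrays[f"W{k}"] = layer.W
        arrays[f"b{k}"] = layer.b
    meta = {
        "c_in": model.c_in,
        "c_out": model.c_out,
        "n_filters": model.entry.c_out,
        "n_blocks": len(model.blocks),
        "kernel": [model.entry.kh, model.entry.kw],
        "symmetrize": model.symmetrize,
    }
    if config:
        meta["config"] = config
    import json

    np.savez(path, _meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_model(path) -> ResidualCNN:
    import json

    with np.load(path) as data:
        meta = json.loads(bytes(data["_meta"]).decode())
        model = ResidualCNN(meta["c_in"], meta["n_filters"], meta["n_blocks"],
                            meta["c_out"], kernel=tuple(meta["kernel"]),
                            symmetrize=meta["symmetrize"])
        weights = []
        for k in range(model.n_conv_layers):
            weights.extend((data[f"W{k}"], data[f"b{k}"]))
    model.set_weights(weights)
    return model


class ContactNetwork(BaseEstimator):
    """Residue-residue contact predictor (scikit-learn style estimator).

    ``fit(X, y)`` takes a list of (L, L, 51) feature tensors and a list of
    ternary label maps; lengths may differ between targets (the network is
    fully convolutional, batch size 1).  ``predict(X)`` returns one exactly
    symmetric (L, L) contact-probability map per target.

    Parameters mirror :class:`NetworkConfig` and :class:`TrainConfig`; the
    defaults are the production architecture (64 filters, 19 blocks).  Use
    a smaller ``n_filters`` / ``n_blocks`` for desk-scale experiments.
    """

    def __init__(self, n_filters: int = 64, n_blocks: int = 19,
                 kernel_size: int = 3, in_channels: int = 51,
                 contact_weight: float = 1.0, learning_rate: float = 0.01,
                 momentum: float = 0.9, weight_decay: float = 1e-4,
                 epochs: int = 30, random_state: int = 0):
        self.n_filters = n_filters
        self.n_blocks = n_blocks
        self.kernel_size = kernel_size
        self.in_channels = in_channels
        self.contact_weight = contact_weight
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.epochs = epochs
        self.random_state = random_state

    def _config(self) -> NetworkConfig:
        return NetworkConfig(in_channels=self.in_channels,
                             n_filters=self.n_filters,
                             kernel_size=self.kernel_size,
                             n_blocks=self.n_blocks)

    def fit(self, X, y, validation=None):
        cfg = self._config()
        self.model_ = build_contact_network(cfg, seed=self.random_state)
        tcfg = TrainConfig(seed=self.random_state,
                           contact_weight=self.contact_weight,
                           learning_rate=self.learning_rate,
                           momentum=self.momentum,
                           weight_decay=self.weight_decay,
                           epochs=self.epochs)
        self.loss_trace_ = train_model(self.model_, list(zip(X, y)), tcfg,
                                       validation=validation)
        self.n_parameters_ = self.model_.n_parameters
        return self

    def predict(self, X):
        """(L, L) contact-probability map per target."""
        return [predict_contact_map(self.model_, f) for f in X]

    def predict_proba(self, X):
        """(L, L, 3) class-probability tensor per target."""
        return [predict_contact_map(self.model_, f, full=True) for f in X]


class SecondaryStructureNetwork(BaseEstimator):
    """1D residual network predicting 3-state secondary structure.

    Input per target: (L, 40) — the 20-column sequence profile concatenated
    with the one-hot sequence (see :func:`ss_network_input`).  Output:
    (L, 3) probabilities over helix / strand / coil.
    """

    def __init__(self, n_filters: int = 32, layers: int = 10,
                 kernel_size: int = 3, learning_rate: float = 0.01,
                 momentum: float = 0.9, weight_decay: float = 1e-4,
                 epochs: int = 50, random_state: int = 0):
        self.n_filters = n_filters
        self.layers = layers
        self.kernel_size = kernel_size
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.epochs = epochs
        self.random_state = random_state

    def fit(self, X, y):
        cfg = NetworkConfig(kernel_size=self.kernel_size, ss_layers=self.layers)
        self.model_ = build_ss_network(cfg, seed=self.random_state,
                                       n_filters=self.n_filters)
        class_weights = np.array([1.0, 1.0, 1.0])
        rng = np.random.default_rng(self.random_state)
        items = []
        for features, labels in zip(X, y):
            f = np.asarray(features, dtype=float)
            if f.ndim != 2 or f.shape[1] != SS_INPUT_CHANNELS:
                raise ValueError(
                    f"SS input must be (L, {SS_INPUT_CHANNELS}); got {f.shape}"
                )
            x = f.T[:, None, :].astype(self.model_.entry.W.dtype)
            items.append((x, np.asarray(labels, dtype=np.int64)[None, :]))
        self.loss_trace_ = []
        for _ in range(self.epochs):
            losses = []
            for idx in rng.permutation(len(items)):
                x, lab = items[idx]
                probs = self.model_.forward(x, train=True)
                loss, dlogits = self.model_.loss_and_grad(probs, lab,
                                                          class_weights)
                self.model_.zero_grad()
                self.model_.backward(dlogits)
                self.model_.sgd_step(self.learning_rate, self.momentum,
                                     self.weight_decay)
                losses.append(loss)
            self.loss_trace_.append(float(np.mean(losses)))
        return self

    def predict_proba(self, X):
        out = []
        for features in X:
            f = np.asarray(features, dtype=float)
            x = f.T[:, None, :].astype(self.model_.entry.W.dtype)
            probs = self.model_.forward(x)  # (3, 1, L)
            out.append(probs[:, 0, :].T)
        return out

    def predict(self, X):
        return [p.argmax(axis=1) for p in self.predict_proba(X)]


class ContactEnsemble(BaseEstimator):
    """Arithmetic-mean consensus over fitted contact networks."""

    def __init__(self, members=None):
        self.members = members

    def fit(self, X=None, y=None):
        if not self.members:
            raise ValueError("ensemble needs at least one member")
        self.models_ = [m.model_ if isinstance(m, ContactNetwork) else m
                        for m in self.members]
        return self

    def predict(self, X):
        if not hasattr(self, "models_"):
            self.fit()
        return [ensemble_predict(self.models_, f) for f in X]


def ss_network_input(profile: np.ndarray, sequence: str) -> np.ndarray:
    """Concatenate the profile with the one-hot sequence -> (L, 40)."""
    from .core import AA_INDEX

    profile = np.asarray(profile, dtype=float)
    L = len(sequence)
    if profile.shape != (L, 20):
        raise ValueError("profile must be (L, 20)")
    onehot = np.zeros((L, 20), dtype=float)
    for i, a in enumerate(sequence):
        k = AA_INDEX.get(a)
        if k is not None:
            onehot[i, k] = 1.0
    return np.concatenate([profile, onehot], axis=1)
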