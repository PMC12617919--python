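"""Fully connected word decoders over flattened neurograms.

Two fixed architectures probe how decoder capacity interacts with
peripheral neural loss: NN1 is shallow and wide (5 hidden layers of 128
ReLU units), NN2 deep and narrow (16 hidden layers of 32 units). Both
use dropout 0.03 after every hidden layer, a 25-way softmax output,
Glorot-uniform initialization, Adam at its default settings, sparse
categorical cross-entropy, minibatches of 32 with reshuffling before
each epoch, and a fixed number of epochs (10 for NN1, 500 for NN2) with
no early stopping.

Inputs are neurograms time-downsampled by block mean (default factor
100: 71 x 600 bins), flattened, and z-scored per feature with
training-set statistics. Training is plain numpy (float32) and is
deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from cndspeech.neurogram import CNDProfile, build_neurograms_multi, downsample_neurogram
from cndspeech.periphery import PeripheryConfig
from cndspeech.stimuli import Corpus

SNR_BINS = (("10..0", 10.0, 0.0), ("-5..-15", -5.0, -15.0), ("-20..-30", -20.0, -30.0))

_ARCHS = {"nn1": (5, 128, 10), "nn2": (16, 32, 500)}


@dataclass
class DecoderConfig:
    arch: str = "nn1"
    n_classes: int = 25
    dropout: float = 0.03
    batch_size: int = 32
    epochs: int | None = None  # None -> architecture default (10 / 500)
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-7
    seed: int = 0

    def __post_init__(self):
        if self.arch not in _ARCHS:
            raise ValueError(f"unknown architecture {self.arch!r}")
        if self.epochs is None:
            self.epochs = _ARCHS[self.arch][2]

    @property
    def hidden_layers(self) -> list:
        depth, width, _ = _ARCHS[self.arch]
        return [width] * depth


class MLP:
    """Minimal dense network: ReLU hidden layers, inverted dropout,
    softmax output trained with sparse categorical cross-entropy."""

    def __init__(self, config: DecoderConfig, input_dim: int):
        self.config = config
        self.input_dim = int(input_dim)
        dims = [self.input_dim] + config.hidden_layers + [config.n_classes]
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0)))
        self.weights, self.biases = [], []
        for fan_in, fan_out in zip(dims[:-1], dims[1:]):
            limit = np.sqrt(6.0 / (fan_in + fan_out))  # Glorot uniform
            self.weights.append(rng.uniform(-limit, limit, (fan_in, fan_out)).astype(np.float32))
            self.biases.append(np.zeros(fan_out, dtype=np.float32))

    @property
    def layer_widths(self) -> list:
        return [w.shape[1] for w in self.weights]

    def _forward(self, X, train=False, rng=None):
        acts = [X]
        masks = []
        h = X
        p = self.config.dropout
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = h @ W + b
            if i < len(self.weights) - 1:
                h = np.maximum(z, 0.0)
                if train and p > 0:
                    mask = (rng.random(h.shape) >= p).astype(np.float32) / (1.0 - p)
                    h = h * mask
                    masks.append(mask)
                else:
                    masks.append(None)
                acts.append(h)
            else:
                acts.append(z)
        return acts, masks

    def logits(self, X) -> np.ndarray:
        return self._forward(np.asarray(X, dtype=np.float32))[0][-1]

    def predict_proba(self, X) -> np.ndarray:
        z = self.logits(X).astype(np.float64)
        z -= z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        return np.argmax(self.logits(X), axis=1)


def build_decoder(config: DecoderConfig, input_dim: int) -> MLP:
    """Untrained network with exactly the configured topology."""
    return MLP(config, input_dim)


def sparse_categorical_cross_entropy(logits: np.ndarray, y: np.ndarray) -> float:
    z = logits.astype(np.float64)
    z = z - z.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    return float(-logp[np.arange(len(y)), y].mean())


@dataclass
class TrainedDecoder:
    model: MLP
    history: "pd.DataFrame"  # per-epoch loss / accuracy (train + optional test)
    config: DecoderConfig
    mean: np.ndarray | None = None  # per-feature standardization (train stats)
    std: np.ndarray | None = None

    def transform(self, X):
        X = np.asarray(X, dtype=np.float32)
        if self.mean is not None:
            X = (X - self.mean) / self.std
        return X

    def predict(self, X):
        return self.model.predict(self.transform(X))


def train_decoder(config: DecoderConfig, X, y, seed: int | None = None,
                  X_val=None, y_val=None, standardize: bool = True) -> TrainedDecoder:
    """Train a decoder; per-epoch curves are recorded by evaluating the full
    training set (and optional held-out set) after each epoch."""
    import pandas as pd

    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y, dtype=np.int64)
    if len(X) == 0:
        raise ValueError("empty training set")
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes")
    if seed is None:
        seed = config.seed
    mean = std = None
    if standardize:
        mean = X.mean(axis=0)
        std = X.std(axis=0)
        std = np.where(std > 0, std, 1.0).astype(np.float32)
        X = (X - mean) / std
        if X_val is not None:
            X_val = (np.asarray(X_val, dtype=np.float32) - mean) / std
    model = MLP(config, X.shape[1])
    rng = np.random.default_rng(np.random.SeedSequence((seed, 1)))
    m = [np.zeros_like(w) for w in model.weights] + [np.zeros_like(b) for b in model.biases]
    v = [np.zeros_like(p) for p in m]
    t = 0
    rows = []
    n = len(X)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            t += 1
            _adam_step(model, X[idx], y[idx], m, v, t, rng, config)
        logits = model.logits(X)
        row = {
            "epoch": epoch + 1,
            "loss": sparse_categorical_cross_entropy(logits, y),
            "accuracy": float((np.argmax(logits, axis=1) == y).mean()),
        }
        if X_val is not None:
            lv = model.logits(X_val)
            row["val_loss"] = sparse_categorical_cross_entropy(lv, np.asarray(y_val))
            row["val_accuracy"] = float((np.argmax(lv, axis=1) == np.asarray(y_val)).mean())
        rows.append(row)
    return TrainedDecoder(model=model, history=pd.DataFrame(rows), config=config,
                          mean=mean, std=std)


def _adam_step(model: MLP, Xb, yb, m, v, t, rng, cfg: DecoderConfig):
    acts, masks = model._forward(Xb, train=True, rng=rng)
    nb = len(Xb)
    z = acts[-1].astype(np.float64)
    z -= z.max(axis=1, keepdims=True)
    p = np.exp(z)
    p /= p.sum(axis=1, keepdims=True)
    delta = p.astype(np.float32)
    delta[np.arange(nb), yb] -= 1.0
    delta /= nb
    grads_w = [None] * len(model.weights)
    grads_b = [None] * len(model.biases)
    for i in range(len(model.weights) - 1, -1, -1):
        grads_w[i] = acts[i].T @ delta
        grads_b[i] = delta.sum(axis=0)
        if i > 0:
            delta = delta @ model.weights[i].T
            if masks[i - 1] is not None:
                delta *= masks[i - 1]
            delta *= (acts[i] > 0)
    params = model.weights + model.biases
    grads = grads_w + grads_b
    lr_t = cfg.learning_rate * np.sqrt(1 - cfg.beta2**t) / (1 - cfg.beta1**t)
    for k, (par, g) in enumerate(zip(params, grads)):
        m[k] = cfg.beta1 * m[k] + (1 - cfg.beta1) * g
        v[k] = cfg.beta2 * v[k] + (1 - cfg.beta2) * g * g
        par -= lr_t * m[k] / (np.sqrt(v[k]) + cfg.eps)


@dataclass
class EvalReport:
    """Decoder evaluation: percent correct, confusion counts (rows = true
    label, columns = predicted) and accuracy per SNR bin."""

    accuracy: float
    confusion: np.ndarray
    per_snr_bin: dict = field(default_factory=dict)
    n_test: int = 0
    arch: str = ""
    profile: str = ""


def evaluate(decoder: TrainedDecoder, X, y, snrs_db=None,
             n_classes: int | None = None) -> EvalReport:
    y = np.asarray(y, dtype=np.int64)
    if n_classes is None:
        n_classes = decoder.config.n_classes
    if np.any(y < 0) or np.any(y >= n_classes):
        raise ValueError("label outside the decoder lexicon")
    pred = decoder.predict(X)
    conf = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(conf, (y, pred), 1)
    acc = 100.0 * float((pred == y).mean())
    per_bin = {}
    if snrs_db is not None:
        snrs_db = np.asarray(snrs_db, dtype=float)
        for name, hi, lo in SNR_BINS:
            mask = (snrs_db <= hi) & (snrs_db >= lo)
            if mask.any():
                per_bin[name] = 100.0 * float((pred[mask] == y[mask]).mean())
    return EvalReport(accuracy=acc, confusion=conf, per_snr_bin=per_bin,
                      n_test=len(y), arch=decoder.config.arch)


# --- corpus -> feature pipeline -------------------------------------------

def neurogram_features(corpus: Corpus, items, profiles,
                       config: PeripheryConfig | None = None, seed: int = 0,
                       downsample: int = 100, duration: float = 3.0):
    """Single-presentation neurogram features for corpus items under one or
    more CND profiles sharing the front-end computation.

    Returns (features: dict profile -> float32 array (n_items, n_cf*n_bins),
    labels, snrs). Labels index the corpus lexicon.
    """
    if config is None:
        config = PeripheryConfig()
    lex = {w: i for i, w in enumerate(corpus.spec.lexicon)}
    feats = {p.name: [] for p in profiles}
    labels, snrs = [], []
    for item in items:
        tok = corpus.realize(item)
        ngs = build_neurograms_multi(tok, profiles, config,
                                     seed=int((seed + item.seed) % 2**31),
                                     duration=duration)
        for p in profiles:
            ng = downsample_neurogram(ngs[p.name], downsample)
            feats[p.name].append(ng.v.astype(np.float32).ravel())
        labels.append(lex[item.word])
        snrs.append(item.snr_db)
    features = {name: np.stack(rows) for name, rows in feats.items()}
    return features, np.asarray(labels), np.asarray(snrs)


def cnd_experiment(corpus: Corpus, profiles, archs=("nn1", "nn2"),
                   config: PeripheryConfig | None = None, seed: int = 0,
                   downsample: int = 100, epochs: dict | None = None) -> dict:
    """Train one decoder per (architecture, profile) on the same corpus split
    and evaluate on the held-out set.

    Returns {(arch, profile_name): (TrainedDecoder, EvalReport)}.
    """
    profiles = [p if isinstance(p, CNDProfile) else None for p in profiles]
    if any(p is None for p in profiles):
        raise TypeError("profiles must be CNDProfile instances")
    Xtr, ytr, _ = neurogram_features(corpus, corpus.train_items, profiles, config, seed, downsample)
    Xte, yte, snr_te = neurogram_features(corpus, corpus.test_items, profiles, config, seed, downsample)
    out = {}
    n_classes = len(corpus.spec.lexicon)
    for arch in archs:
        for p in profiles:
            cfg = DecoderConfig(arch=arch, n_classes=n_classes, seed=seed,
                                epochs=None if epochs is None else epochs.get(arch))
            trained = train_decoder(cfg, Xtr[p.name], ytr)
            report = evaluate(trained, Xte[p.name], yte, snr_te, n_classes)
            report.profile = p.name
            out[(arch, p.name)] = (trained, report)
    return out
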