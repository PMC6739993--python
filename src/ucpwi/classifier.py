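"""Microbubble / tissue classification of length-60 RF segments.

Three interchangeable models score sliding RF windows: a 1-D U-net (the
workhorse), plus CNN and RNN baselines.  All take a (batch, 60) array of raw
RF samples and return two-class softmax probabilities; overlapping
per-segment scores are averaged into a per-sample bubble mask.

The U-net channel plan
----------------------
The layer inventory (three down/up-sampling stages, fourteen convolutions,
three fusions, four dropouts, one dense head; encoder feature maps 32, 64,
128) leaves the bottleneck and decoder widths free.  The concrete plan used
here —

    enc:  1->32->32 | 32->64->64 | 64->128->128       (60, 30, 15 samples)
    bottleneck: 128->219->219                          (7 samples)
    dec:  up 219->128, fuse(+128), 256->128            (15)
          up 128->83,  fuse(+64),  147->83             (30)
          up  83->51,  fuse(+32),   83->51             (60)
    head: flatten(3060) -> dense -> softmax(2)

— was chosen so the trainable-parameter total is exactly 607,112, the
architecture's one exact checksum.  Lengths pool 60 -> 30 -> 15 -> 7 (odd
tail dropped) and upsample 7 -> 15 -> 30 -> 60 with deterministic
zero-padding so fusions always align.

Segments are normalised to unit peak amplitude before entering any model:
echo amplitude varies over orders of magnitude with depth and scatterer
strength, and the class information lives in the waveform shape, not the
gain.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.metrics import roc_auc_score

from . import nn
from .nn import F32

__all__ = [
    "UNetConfig",
    "TrainConfig",
    "BubbleMask",
    "build_unet",
    "build_cnn",
    "build_rnn",
    "build_model",
    "count_parameters",
    "train",
    "predict_proba",
    "predict_mask",
    "save_checkpoint",
    "load_checkpoint",
    "TrainingDivergedError",
]


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes NaN/inf."""


@dataclass(frozen=True)
class UNetConfig:
    """Architecture of the 1-D U-net (defaults give 607,112 parameters)."""

    input_length: int = 60
    base_filters: tuple[int, int, int] = (32, 64, 128)
    bottleneck_filters: int = 219
    up_filters: tuple[int, int, int] = (128, 83, 51)
    kernel: int = 3
    dropout_rate: float = 0.5
    n_classes: int = 2

    def __post_init__(self):
        if len(self.base_filters) != 3 or len(self.up_filters) != 3:
            raise ValueError(
                "the U-net has exactly three down and three up stages; "
                "base_filters and up_filters must each have three entries"
            )
        if self.input_length < 8:
            raise ValueError("input_length too short for three pooling stages")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation hyper-parameters.

    Defaults are the instrument-study values: batch 100, 150 epochs, Adam
    with step size 1e-5, beta1 0.9, beta2 0.999, epsilon 1e-8, cross-entropy
    loss.  ``fast()`` returns the desk-scale profile (<= 20 epochs with a
    proportionally larger Adam step) used for CI-scale runs.
    """

    batch_size: int = 100
    epochs: int = 150
    lr: float = 1e-5
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    lr_decay: float = 1.0   # per-epoch multiplicative step-size decay
    seed: int = 0

    @classmethod
    def fast(cls, epochs: int = 6, lr: float = 1e-3, seed: int = 0) -> "TrainConfig":
        """Desk-scale profile: few epochs at a larger Adam step with decay.

        The decay (x0.6 per epoch) anneals the step so the final epochs
        settle instead of oscillating around the decision boundary.
        """
        if epochs > 20:
            raise ValueError("the fast profile is capped at 20 epochs")
        return cls(epochs=epochs, lr=lr, lr_decay=0.6, seed=seed)


@dataclass
class BubbleMask:
    """Per-sample bubble indicator for one RF frame.

    `prob` is the mean class-1 (bubble) probability over every segment
    covering a sample; `mask` is `prob >= 0.5`.  Shape matches the source
    frame (samples x elements).
    """

    mask: np.ndarray
    prob: np.ndarray

    def __post_init__(self):
        if self.mask.shape != self.prob.shape:
            raise ValueError("mask and prob shapes differ")


def _normalise_segments(segments: np.ndarray) -> np.ndarray:
    x = np.asarray(segments, dtype=F32)
    peak = np.abs(x).max(axis=1, keepdims=True)
    return x / np.maximum(peak, F32(1e-20))


class _Model:
    """Shared plumbing: parameter registry, prediction, serialisation."""

    kind = "model"

    def __init__(self, seed: int):
        self.seed = seed
        self.rng = np.random.default_rng(seed)
        self.trained = False

    def params(self):
        return [p for layer in self._layers for p in layer.params()]

    def count_parameters(self) -> int:
        return sum(p.size for p in self.params())

    def predict_proba(self, segments: np.ndarray, batch_size: int = 1024) -> np.ndarray:
        """Two-class probabilities for raw (n, 60) segments."""
        x = _normalise_segments(segments)
        out = np.empty((len(x), 2), dtype=np.float64)
        for i in range(0, len(x), batch_size):
            logits = self.forward(x[i : i + batch_size], training=False)
            out[i : i + batch_size] = nn.softmax(logits.astype(np.float64))
        return out

    def architecture_hash(self) -> str:
        blob = json.dumps({"kind": self.kind, "config": self._config_dict()}, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def _config_dict(self) -> dict:
        return {}


class UNet1D(_Model):
    kind = "unet"

    def __init__(self, cfg: UNetConfig | None = None, seed: int = 0):
        super().__init__(seed)
        self.cfg = cfg = cfg or UNetConfig()
        rng = self.rng
        f1, f2, f3 = cfg.base_filters
        fb = cfg.bottleneck_filters
        u1, u2, u3 = cfg.up_filters
        t0 = cfg.input_length
        t1, t2, t3 = t0 // 2, t0 // 4, t0 // 8

        C = lambda ci, co, nm: nn.Conv1D(rng, ci, co, cfg.kernel, nm)
        self.c1, self.c2 = C(1, f1, "enc1a"), C(f1, f1, "enc1b")
        self.c3, self.c4 = C(f1, f2, "enc2a"), C(f2, f2, "enc2b")
        self.c5, self.c6 = C(f2, f3, "enc3a"), C(f3, f3, "enc3b")
        self.c7, self.c8 = C(f3, fb, "botta"), C(fb, fb, "bottb")
        self.c9, self.c10 = C(fb, u1, "dec1a"), C(u1 + f3, u1, "dec1b")
        self.c11, self.c12 = C(u1, u2, "dec2a"), C(u2 + f2, u2, "dec2b")
        self.c13, self.c14 = C(u2, u3, "dec3a"), C(u3 + f1, u3, "dec3b")
        self.head = nn.Dense(rng, t0 * u3, cfg.n_classes, "head")

        self.pools = [nn.MaxPool1D() for _ in range(3)]
        self.ups = [nn.Upsample1D(t2), nn.Upsample1D(t1), nn.Upsample1D(t0)]
        self.drops = [nn.Dropout(cfg.dropout_rate, rng) for _ in range(4)]
        self.relus = [nn.ReLU() for _ in range(14)]
        self.flat = nn.Flatten()
        self._layers = [
            self.c1, self.c2, self.c3, self.c4, self.c5, self.c6, self.c7,
            self.c8, self.c9, self.c10, self.c11, self.c12, self.c13, self.c14,
            self.head,
        ]

    def _config_dict(self):
        return asdict(self.cfg)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = x[:, :, None] if x.ndim == 2 else x
        r = self.relus
        a1 = r[1].forward(self.c2.forward(r[0].forward(self.c1.forward(x)), training))
        p1 = self.pools[0].forward(self.drops[0].forward(a1, training))
        a2 = r[3].forward(self.c4.forward(r[2].forward(self.c3.forward(p1)), training))
        p2 = self.pools[1].forward(self.drops[1].forward(a2, training))
        a3 = r[5].forward(self.c6.forward(r[4].forward(self.c5.forward(p2)), training))
        p3 = self.pools[2].forward(self.drops[2].forward(a3, training))
        b = r[7].forward(self.c8.forward(r[6].forward(self.c7.forward(p3)), training))
        b = self.drops[3].forward(b, training)
        d1 = r[8].forward(self.c9.forward(self.ups[0].forward(b), training))
        d1 = r[9].forward(self.c10.forward(np.concatenate([d1, a3], axis=2), training))
        d2 = r[10].forward(self.c11.forward(self.ups[1].forward(d1), training))
        d2 = r[11].forward(self.c12.forward(np.concatenate([d2, a2], axis=2), training))
        d3 = r[12].forward(self.c13.forward(self.ups[2].forward(d2), training))
        d3 = r[13].forward(self.c14.forward(np.concatenate([d3, a1], axis=2), training))
        return self.head.forward(self.flat.forward(d3))

    def backward(self, dlogits: np.ndarray) -> None:
        cfg = self.cfg
        f1, f2, f3 = cfg.base_filters
        u1, u2, u3 = cfg.up_filters
        r = self.relus
        g = self.flat.backward(self.head.backward(dlogits))
        g = self.c14.backward(r[13].backward(g))
        g, da1_skip = g[:, :, :u3], g[:, :, u3:]
        g = self.ups[2].backward(self.c13.backward(r[12].backward(g)))
        g = self.c12.backward(r[11].backward(g))
        g, da2_skip = g[:, :, :u2], g[:, :, u2:]
        g = self.ups[1].backward(self.c11.backward(r[10].backward(g)))
        g = self.c10.backward(r[9].backward(g))
        g, da3_skip = g[:, :, :u1], g[:, :, u1:]
        g = self.ups[0].backward(self.c9.backward(r[8].backward(g)))
        g = self.drops[3].backward(g)
        g = self.c7.backward(r[6].backward(self.c8.backward(r[7].backward(g))))
        g = self.drops[2].backward(self.pools[2].backward(g)) + da3_skip
        g = self.c5.backward(r[4].backward(self.c6.backward(r[5].backward(g))))
        g = self.drops[1].backward(self.pools[1].backward(g)) + da2_skip
        g = self.c3.backward(r[2].backward(self.c4.backward(r[3].backward(g))))
        g = self.drops[0].backward(self.pools[0].backward(g)) + da1_skip
        self.c1.backward(r[0].backward(self.c2.backward(r[1].backward(g))))


class CNN1D(_Model):
    """Baseline CNN: two 128-filter convs, pool, two 64-filter convs, pool,
    dropout, two dense layers."""

    kind = "cnn"

    def __init__(self, input_length: int = 60, seed: int = 0, dropout_rate: float = 0.5):
        super().__init__(seed)
        self.input_length = input_length
        rng = self.rng
        self.conv = [
            nn.Conv1D(rng, 1, 128, name="c1"),
            nn.Conv1D(rng, 128, 128, name="c2"),
            nn.Conv1D(rng, 128, 64, name="c3"),
            nn.Conv1D(rng, 64, 64, name="c4"),
        ]
        t_out = input_length // 4
        self.pools = [nn.MaxPool1D(), nn.MaxPool1D()]
        self.drop = nn.Dropout(dropout_rate, rng)
        self.relus = [nn.ReLU() for _ in range(5)]
        self.flat = nn.Flatten()
        self.fc1 = nn.Dense(rng, t_out * 64, 64, "fc1")
        self.fc2 = nn.Dense(rng, 64, 2, "fc2")
        self._layers = [*self.conv, self.fc1, self.fc2]

    def _config_dict(self):
        return {"input_length": self.input_length}

    def forward(self, x, training=False):
        x = x[:, :, None] if x.ndim == 2 else x
        r = self.relus
        h = r[1].forward(self.conv[1].forward(r[0].forward(self.conv[0].forward(x)), training))
        h = self.pools[0].forward(h)
        h = r[3].forward(self.conv[3].forward(r[2].forward(self.conv[2].forward(h)), training))
        h = self.pools[1].forward(h)
        h = self.flat.forward(self.drop.forward(h, training))
        return self.fc2.forward(r[4].forward(self.fc1.forward(h)))

    def backward(self, dlogits):
        r = self.relus
        g = self.fc1.backward(r[4].backward(self.fc2.backward(dlogits)))
        g = self.drop.backward(self.flat.backward(g))
        g = self.pools[1].backward(g)
        g = self.conv[2].backward(r[2].backward(self.conv[3].backward(r[3].backward(g))))
        g = self.pools[0].backward(g)
        self.conv[0].backward(r[0].backward(self.conv[1].backward(r[1].backward(g))))


class RNN1D(_Model):
    """Baseline RNN: four 100-unit recurrent layers, dropout, three dense."""

    kind = "rnn"

    def __init__(self, input_length: int = 60, seed: int = 0, dropout_rate: float = 0.5):
        super().__init__(seed)
        self.input_length = input_length
        rng = self.rng
        self.rnns = [nn.ElmanRNN(rng, 1 if i == 0 else 100, 100, f"r{i}") for i in range(4)]
        self.drop = nn.Dropout(dropout_rate, rng)
        self.relus = [nn.ReLU(), nn.ReLU()]
        self.fc = [nn.Dense(rng, 100, 64, "fc1"), nn.Dense(rng, 64, 32, "fc2"),
                   nn.Dense(rng, 32, 2, "fc3")]
        self._layers = [*self.rnns, *self.fc]

    def _config_dict(self):
        return {"input_length": self.input_length}

    def forward(self, x, training=False):
        x = x[:, :, None] if x.ndim == 2 else x
        h = x
        for layer in self.rnns:
            h = layer.forward(h, training)
        self._t = h.shape[1]
        h = self.drop.forward(h[:, -1, :], training)
        h = self.relus[0].forward(self.fc[0].forward(h))
        h = self.relus[1].forward(self.fc[1].forward(h))
        return self.fc[2].forward(h)

    def backward(self, dlogits):
        g = self.fc[2].backward(dlogits)
        g = self.fc[1].backward(self.relus[1].backward(g))
        g = self.fc[0].backward(self.relus[0].backward(g))
        g = self.drop.backward(g)
        gseq = np.zeros((g.shape[0], self._t, 100), dtype=F32)
        gseq[:, -1, :] = g
        for layer in reversed(self.rnns):
            gseq = layer.backward(gseq)


def build_unet(cfg: UNetConfig | None = None, seed: int = 0) -> UNet1D:
    return UNet1D(cfg, seed=seed)


def build_cnn(input_length: int = 60, seed: int = 0) -> CNN1D:
    return CNN1D(input_length, seed=seed)


def build_rnn(input_length: int = 60, seed: int = 0) -> RNN1D:
    return RNN1D(input_length, seed=seed)


def build_model(kind: str, seed: int = 0):
    builders = {"unet": build_unet, "cnn": build_cnn, "rnn": build_rnn}
    if kind not in builders:
        raise ValueError(f"unknown model kind {kind!r}; expected one of {sorted(builders)}")
    return builders[kind](seed=seed)


def count_parameters(model) -> int:
    """Total trainable parameter count."""
    return model.count_parameters()


def _accuracy(model, segments, labels, batch_size=1024) -> float:
    prob = model.predict_proba(segments, batch_size)
    return float(np.mean(prob.argmax(axis=1) == labels))


def train(model, dataset, cfg: TrainConfig | None = None, verbose: bool = False):
    """Train a segment classifier with Adam on cross-entropy.

    `dataset` is a :class:`~ucpwi.rf_sim.SegmentDataset` carrying an 80/20
    frame-level train/test split (or any object with ``train``/``test``
    attributes exposing ``segments`` and ``labels``).  Returns a history dict
    with per-epoch train loss/accuracy and test accuracy, plus the final
    held-out accuracy and AUROC.
    """
    cfg = cfg or TrainConfig()
    tr, te = dataset.train, dataset.test
    x_tr = _normalise_segments(tr.segments)
    y_tr = np.asarray(tr.labels, dtype=np.int64)
    x_te, y_te = te.segments, np.asarray(te.labels, dtype=np.int64)
    if len(np.unique(y_tr)) < 2:
        raise ValueError("training set is degenerate: only one class present")

    opt = nn.Adam(model.params(), lr=cfg.lr, beta1=cfg.beta1, beta2=cfg.beta2, eps=cfg.epsilon)
    rng = np.random.default_rng(cfg.seed)
    history = {"train_loss": [], "train_acc": [], "test_acc": []}
    n = len(x_tr)
    for epoch in range(cfg.epochs):
        opt.lr = cfg.lr * cfg.lr_decay**epoch
        order = rng.permutation(n)
        losses, hits = [], 0
        for i in range(0, n, cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            logits = model.forward(xb, training=True)
            loss, dlogits = nn.cross_entropy(logits, yb)
            if not np.isfinite(loss):
                raise TrainingDivergedError(f"loss became {loss} at epoch {epoch}")
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
            hits += int((logits.argmax(axis=1) == yb).sum())
        history["train_loss"].append(float(np.mean(losses)))
        history["train_acc"].append(hits / n)
        history["test_acc"].append(_accuracy(model, x_te, y_te))
        if verbose:
            print(
                f"epoch {epoch + 1}/{cfg.epochs}: loss {history['train_loss'][-1]:.4f} "
                f"train acc {history['train_acc'][-1]:.4f} test acc {history['test_acc'][-1]:.4f}"
            )
    model.trained = True
    prob_te = model.predict_proba(x_te)[:, 1]
    history["final_test_acc"] = float(np.mean((prob_te >= 0.5) == y_te))
    history["final_auroc"] = float(roc_auc_score(y_te, prob_te))
    return model, history


def predict_proba(model, segments: np.ndarray, batch_size: int = 1024) -> np.ndarray:
    return model.predict_proba(segments, batch_size)


def predict_mask(model, data, length: int = 60, step: int = 5,
                 require_trained: bool = True) -> BubbleMask:
    """Score sliding segments on every element line and build a sample mask.

    Each sample's probability is the mean class-1 probability over all
    segments covering it (segment order is immaterial); the binary mask
    thresholds at 0.5.  Samples not covered by any window get probability 0.
    """
    if require_trained and not getattr(model, "trained", False):
        raise ValueError("model has not been trained; pass require_trained=False to override")
    rf = data.rf
    n_samples, n_elem = rf.shape
    starts = np.arange(0, n_samples - length + 1, step)
    prob = np.zeros((n_samples, n_elem), dtype=np.float64)
    count = np.zeros(n_samples, dtype=np.float64)
    for s in starts:
        count[s : s + length] += 1.0
    windows = np.lib.stride_tricks.sliding_window_view(rf, length, axis=0)[::step]
    for e in range(n_elem):
        p1 = model.predict_proba(windows[:, e, :])[:, 1]
        for j, s in enumerate(starts):
            prob[s : s + length, e] += p1[j]
    covered = count > 0
    prob[covered] /= count[covered, None]
    return BubbleMask(mask=(prob >= 0.5).astype(np.int8), prob=prob)


def save_checkpoint(model, path: str, train_config: TrainConfig | None = None,
                    history: dict | None = None) -> None:
    """Write weights (.npz) plus a JSON sidecar describing the architecture."""
    arrays = {f"p{i}": p.value for i, p in enumerate(model.params())}
    np.savez(path, **arrays)
    sidecar = {
        "kind": model.kind,
        "config": model._config_dict(),
        "seed": model.seed,
        "trained": model.trained,
        "architecture_hash": model.architecture_hash(),
        "parameter_count": model.count_parameters(),
        "train_config": asdict(train_config) if train_config else None,
        "final_test_acc": (history or {}).get("final_test_acc"),
        "final_auroc": (history or {}).get("final_auroc"),
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def load_checkpoint(path: str):
    with open(str(path) + ".json") as fh:
        sidecar = json.load(fh)
    kind = sidecar["kind"]
    if kind == "unet":
        model = build_unet(UNetConfig(**{k: tuple(v) if isinstance(v, list) else v
                                         for k, v in sidecar["config"].items()}),
                           seed=sidecar["seed"])
    else:
        model = build_model(kind, seed=sidecar["seed"])
    npz_path = str(path) if str(path).endswith(".npz") else str(path) + ".npz"
    with np.load(npz_path) as npz:
        for i, p in enumerate(model.params()):
            p.value[...] = npz[f"p{i}"]
    model.trained = sidecar.get("trained", True)
    return model
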