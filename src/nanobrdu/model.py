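"""Three-layer BiGRU classifier over {A, BrdU, C, G, T}.

The network consumes a 5 x 7 feature window (five consecutive events, seven
features each), runs it through three stacked bidirectional GRU layers (the
first two return full 5-step sequences of concatenated forward/backward
states, the third returns the concatenated final states), and maps the
resulting vector through a dense layer with softmax into probabilities over
the five classes [A, BrdU, C, G, T].

Training minimizes categorical cross-entropy with Adam, stopping early when
validation loss stops improving and restoring the best-validation-loss
weights.  All arithmetic is NumPy float64, so training under a fixed seed is
bit-reproducible on a single device.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .featurize import FEATURE_DIM, N_CLASSES, WindowSet
from .gru import BiGRULayer, GRUParams
from .pore_model import CLASS_SYMBOLS, KMER_LEN


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training hyperparameters.

    Defaults match the published configuration: three stacked BiGRU layers of
    128 units per direction, batch size 128, at most 30 epochs with early
    stopping on validation loss.  Optimizer and learning rate are Adam at
    1e-3 (the loss — categorical cross-entropy — is forced by the softmax
    output head).
    """

    n_layers: int = 3
    units_per_direction: int = 128
    input_dim: int = FEATURE_DIM
    timesteps: int = KMER_LEN
    n_classes: int = N_CLASSES
    batch_size: int = 128
    max_epochs: int = 30
    early_stop_patience: int = 3
    learning_rate: float = 1e-3
    train_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_layers", "units_per_direction", "input_dim", "timesteps",
                     "n_classes", "batch_size", "max_epochs", "early_stop_patience"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.timesteps != KMER_LEN:
            raise ValueError(f"timesteps must be {KMER_LEN} for R9 5-mer mode")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class BiGRUNetwork:
    """Stacked BiGRU layers + dense softmax head (sequence-to-one)."""

    def __init__(self, layers: list[BiGRULayer], dense_w: np.ndarray, dense_b: np.ndarray):
        self.layers = layers
        self.dense_w = dense_w
        self.dense_b = dense_b

    @classmethod
    def init(cls, rng: np.random.Generator, config: ModelConfig) -> "BiGRUNetwork":
        layers = []
        in_dim = config.input_dim
        for i in range(config.n_layers):
            last = i == config.n_layers - 1
            layers.append(
                BiGRULayer.init(rng, in_dim, config.units_per_direction,
                                return_sequences=not last)
            )
            in_dim = 2 * config.units_per_direction
        lim = np.sqrt(6.0 / (in_dim + config.n_classes))
        dense_w = rng.uniform(-lim, lim, size=(in_dim, config.n_classes))
        dense_b = np.zeros(config.n_classes)
        return cls(layers, dense_w, dense_b)

    def forward(self, X: np.ndarray, with_cache: bool = False):
        caches = []
        out = X
        for layer in self.layers:
            out, cache = layer.forward(out)
            caches.append(cache)
        logits = out @ self.dense_w + self.dense_b
        probs = _softmax(logits)
        if with_cache:
            return probs, (caches, out)
        return probs

    def backward(self, probs: np.ndarray, Y: np.ndarray, cache):
        """Gradients of mean categorical cross-entropy; returns flat array list."""
        caches, feat = cache
        B = probs.shape[0]
        dlogits = (probs - Y) / B
        g_dense_w = feat.T @ dlogits
        g_dense_b = dlogits.sum(axis=0)
        d_out = dlogits @ self.dense_w.T
        layer_grads = []
        for layer, c in zip(reversed(self.layers), reversed(caches)):
            d_out, g = layer.backward(d_out, c)
            layer_grads.append(g)
        grads: list[np.ndarray] = []
        for gf, gb in reversed(layer_grads):
            grads.extend(gf.arrays())
            grads.extend(gb.arrays())
        grads.append(g_dense_w)
        grads.append(g_dense_b)
        return grads

    def params(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for layer in self.layers:
            out.extend(layer.fw.params.arrays())
            out.extend(layer.bw.params.arrays())
        out.append(self.dense_w)
        out.append(self.dense_b)
        return out

    def set_params(self, values: list[np.ndarray]) -> None:
        for p, v in zip(self.params(), values):
            p[...] = v


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        lr_t = self.lr * np.sqrt(1 - b2**self.t) / (1 - b1**self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)


class EarlyStopper:
    """Stop when the monitored loss fails to improve for `patience` epochs."""

    def __init__(self, patience: int, min_delta: float = 0.0):
        self.patience = patience
        self.min_delta = min_delta
        self.best = np.inf
        self.best_epoch = -1
        self.wait = 0

    def update(self, loss: float, epoch: int) -> bool:
        """Record an epoch's loss; returns True when training should stop."""
        if loss < self.best - self.min_delta:
            self.best = loss
            self.best_epoch = epoch
            self.wait = 0
            return False
        self.wait += 1
        return self.wait >= self.patience


@dataclass
class TrainedModel:
    """A trained classifier: config, parameters, and the per-epoch training log."""

    config: ModelConfig
    network: BiGRUNetwork
    training_log: list[dict] = field(default_factory=list)
    stopped_early: bool = False


def _check_labeled(ws: WindowSet, what: str) -> np.ndarray:
    y = ws.y
    if np.isnan(y).any():
        raise ValueError(f"{what} set contains unlabeled windows")
    return y


def _eval_loss_acc(net: BiGRUNetwork, X: np.ndarray, Y: np.ndarray, batch: int = 1024):
    loss = 0.0
    correct = 0
    n = X.shape[0]
    for i in range(0, n, batch):
        p = net.forward(X[i : i + batch])
        yb = Y[i : i + batch]
        loss += -np.sum(yb * np.log(np.clip(p, 1e-12, None)))
        correct += int((p.argmax(axis=1) == yb.argmax(axis=1)).sum())
    return loss / n, correct / n


def train(train_set: WindowSet, val_set: WindowSet, config: ModelConfig = ModelConfig()) -> TrainedModel:
    """Fit the classifier; restores the best-validation-loss parameters.

    Both sets must be fully labeled.  The training log records loss and
    accuracy on both sets for every epoch run.
    """
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("training and validation sets must be non-empty")
    Xtr = np.asarray(train_set.X, dtype=float)
    Ytr = _check_labeled(train_set, "training")
    Xva = np.asarray(val_set.X, dtype=float)
    Yva = _check_labeled(val_set, "validation")

    rng = np.random.default_rng(config.train_seed)
    net = BiGRUNetwork.init(rng, config)
    opt = _Adam(net.params(), config.learning_rate)
    stopper = EarlyStopper(config.early_stop_patience)
    best_params = [p.copy() for p in net.params()]
    log: list[dict] = []
    stopped_early = False
    n = Xtr.shape[0]

    for epoch in range(config.max_epochs):
        perm = rng.permutation(n)
        ep_loss = 0.0
        ep_correct = 0
        for i in range(0, n, config.batch_size):
            idx = perm[i : i + config.batch_size]
            xb, yb = Xtr[idx], Ytr[idx]
            probs, cache = net.forward(xb, with_cache=True)
            ep_loss += -np.sum(yb * np.log(np.clip(probs, 1e-12, None)))
            ep_correct += int((probs.argmax(axis=1) == yb.argmax(axis=1)).sum())
            grads = net.backward(probs, yb, cache)
            opt.step(grads)
        val_loss, val_acc = _eval_loss_acc(net, Xva, Yva)
        log.append(
            {
                "epoch": epoch,
                "train_loss": ep_loss / n,
                "train_acc": ep_correct / n,
                "val_loss": float(val_loss),
                "val_acc": float(val_acc),
            }
        )
        if val_loss < stopper.best:
            best_params = [p.copy() for p in net.params()]
        if stopper.update(val_loss, epoch):
            stopped_early = True
            break

    net.set_params(best_params)
    return TrainedModel(config=config, network=net, training_log=log, stopped_early=stopped_early)


def forward(window_x: np.ndarray, model: TrainedModel) -> np.ndarray:
    """Class probabilities [A, BrdU, C, G, T] for one 5 x 7 window."""
    x = np.asarray(window_x, dtype=float)
    if x.shape != (model.config.timesteps, model.config.input_dim):
        raise ValueError(f"window must be {model.config.timesteps} x {model.config.input_dim}")
    return model.network.forward(x[None])[0]


def predict(model: TrainedModel, windows: WindowSet, batch: int = 1024) -> pd.DataFrame:
    """Argmax calls plus per-class probabilities, one row per window.

    Ties break toward the earlier class in [A, BrdU, C, G, T].
    """
    n = len(windows)
    probs = np.empty((n, model.config.n_classes))
    X = np.asarray(windows.X, dtype=float)
    for i in range(0, n, batch):
        probs[i : i + batch] = model.network.forward(X[i : i + batch])
    calls = np.array(CLASS_SYMBOLS)[probs.argmax(axis=1)]
    out = pd.DataFrame(
        {
            "read_id": windows.read_ids,
            "center_pos": windows.center_pos,
            "call": calls,
            "p_A": probs[:, 0],
            "p_BrdU": probs[:, 1],
            "p_C": probs[:, 2],
            "p_G": probs[:, 3],
            "p_T": probs[:, 4],
        }
    )
    return out


# ---------------------------------------------------------------------------
# persistence: weights.npz + a JSON sidecar with the config

def save_model(model: TrainedModel, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    sidecar = {
        "format": "nanobrdu-bigru-v1",
        "config": asdict(model.config),
        "training_log": model.training_log,
        "stopped_early": model.stopped_early,
    }
    (path / "config.json").write_text(json.dumps(sidecar, indent=2))
    arrays = {f"p{i:03d}": p for i, p in enumerate(model.network.params())}
    np.savez(path / "weights.npz", **arrays)


def load_model(path) -> TrainedModel:
    path = Path(path)
    sidecar = json.loads((path / "config.json").read_text())
    if sidecar.get("format") != "nanobrdu-bigru-v1":
        raise ValueError("unrecognized model directory format")
    config = ModelConfig(**sidecar["config"])  # re-validates timesteps == 5
    rng = np.random.default_rng(0)
    net = BiGRUNetwork.init(rng, config)
    with np.load(path / "weights.npz") as npz:
        values = [npz[f"p{i:03d}"] for i in range(len(net.params()))]
    net.set_params(values)
    return TrainedModel(
        config=config,
        network=net,
        training_log=sidecar.get("training_log", []),
        stopped_early=sidecar.get("stopped_early", False),
    )
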