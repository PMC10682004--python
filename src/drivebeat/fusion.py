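"""Snippet classifiers for the three fusion architectures and the hybrid vote.

Each architecture is a small 1-D CNN ending in a single sigmoid unit that
binary-classifies a 501-sample multimodal snippet as containing a heartbeat
(class 1) or not (class 0):

* **early fusion** — one convolution over the stacked n-signal input (the
  modalities merge in the convolutional layer);
* **sensor-based late fusion** — one conv/dropout/pool branch per signal,
  feature maps concatenated before the dense layer;
* **signal-based late fusion** — two independent conv branches per signal
  (each pair receiving identical input), concatenated before the dense
  layer; for the same inputs it always carries more parameters than the
  sensor-based variant.

Every branch is: conv (2 filters, kernel 20, linear activation) -> dropout
(rate 0.5, training only) -> max-pool (size 2) -> flatten; the concatenated
features feed one dense sigmoid unit.  Training minimises binary
cross-entropy with Adam (lr 0.001).  The network is implemented directly in
NumPy with explicit backpropagation; training is deterministic for a fixed
config seed.

The **hybrid** approach is not a network: it majority-votes the three
architectures' per-snippet labels (label 1 iff at least ``min_votes`` of the
three vote 1) and is independent of the underlying models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .preprocess import SnippetSet
from .types import SignalError

__all__ = [
    "FusionConfig",
    "VoteMatrix",
    "ModelHandle",
    "build_model",
    "train",
    "predict_proba",
    "predict_labels",
    "hybrid_vote",
    "count_parameters",
    "APPROACHES",
]

APPROACHES = ("early", "signal_late", "sensor_late", "hybrid")


@dataclass(frozen=True)
class FusionConfig:
    """Hyperparameters of one fusion classifier.

    Defaults are the study's published choices (2 filters, kernel 20,
    dropout 0.5, pool 2, Adam lr 0.001, sigmoid output); epochs, batch size
    and decision threshold are exposed because they are free choices.
    ``class_weight`` enables inverse-frequency weighting of the binary
    cross-entropy (off by default: heartbeat snippets are the minority
    class, but the unweighted loss is the baseline condition).
    """

    approach: str = "early"
    n_filters: int = 2
    kernel: int = 20
    dropout: float = 0.5
    pool: int = 2
    lr: float = 0.001
    epochs: int = 10
    batch_size: int = 32
    threshold: float = 0.5
    class_weight: bool = False
    calibrate: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.approach not in APPROACHES:
            raise SignalError(f"unknown approach {self.approach!r}")
        if not 0 < self.threshold < 1:
            raise SignalError("threshold must lie in (0, 1)")
        if not 0 <= self.dropout < 1:
            raise SignalError("dropout rate must lie in [0, 1)")


@dataclass
class VoteMatrix:
    """Per-approach, per-snippet predicted labels (rows: approaches)."""

    labels: np.ndarray
    approaches: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise SignalError("vote matrix must be [n_approaches, n_snippets]")
        if not np.isin(self.labels, (0, 1)).all():
            raise SignalError("vote matrix entries must be binary")


@dataclass
class _Branch:
    """One conv/dropout/pool branch: which input channels it reads + weights."""

    channels: tuple[int, ...]
    W: np.ndarray  # [kernel, n_in_channels, n_filters]
    b: np.ndarray  # [n_filters]


@dataclass
class ModelHandle:
    """A (possibly trained) fusion network."""

    approach: str
    n_signals: int
    branches: list[_Branch]
    Wd: np.ndarray  # [n_features]
    bd: float
    cfg: FusionConfig
    signals: Optional[tuple[str, ...]] = None
    loss_history: list[float] = field(default_factory=list)
    trained: bool = False
    threshold: Optional[float] = None  # calibrated override of cfg.threshold
    train_prevalence: Optional[float] = None  # positive fraction seen in training

    def parameters(self) -> list[np.ndarray]:
        out = []
        for br in self.branches:
            out += [br.W, br.b]
        out += [self.Wd, np.atleast_1d(np.float64(self.bd))]
        return out

    def copy(self) -> "ModelHandle":
        return ModelHandle(
            self.approach,
            self.n_signals,
            [_Branch(br.channels, br.W.copy(), br.b.copy()) for br in self.branches],
            self.Wd.copy(),
            float(self.bd),
            self.cfg,
            self.signals,
            list(self.loss_history),
            self.trained,
            self.threshold,
            self.train_prevalence,
        )


def count_parameters(model: ModelHandle) -> int:
    return sum(p.size for p in model.parameters())


def _branch_plan(approach: str, n_signals: int) -> list[tuple[int, ...]]:
    if approach == "early":
        return [tuple(range(n_signals))]
    if approach == "sensor_late":
        return [(s,) for s in range(n_signals)]
    if approach == "signal_late":
        # two CNN branches per signal, each receiving identical input
        return [(s,) for s in range(n_signals) for _ in range(2)]
    raise SignalError(f"approach {approach!r} has no single-network plan")


def build_model(
    cfg: FusionConfig, n_signals: int, snippet_len: int = 501
) -> ModelHandle:
    """Initialize a fusion network (Glorot-uniform weights, seeded)."""
    if n_signals not in (1, 2, 3):
        raise SignalError("n_signals must be 1, 2 or 3")
    if cfg.approach == "hybrid":
        raise SignalError(
            "hybrid is a vote over the three trained approaches, not a network"
        )
    rng = np.random.default_rng(cfg.seed)
    conv_len = snippet_len - cfg.kernel + 1
    if conv_len % cfg.pool:
        conv_len -= conv_len % cfg.pool
    feat_per_branch = (conv_len // cfg.pool) * cfg.n_filters

    branches = []
    for channels in _branch_plan(cfg.approach, n_signals):
        fan_in = cfg.kernel * len(channels)
        limit = np.sqrt(6.0 / (fan_in + cfg.n_filters))
        W = rng.uniform(-limit, limit, size=(cfg.kernel, len(channels), cfg.n_filters))
        branches.append(_Branch(tuple(channels), W, np.zeros(cfg.n_filters)))

    n_feat = feat_per_branch * len(branches)
    limit = np.sqrt(6.0 / (n_feat + 1))
    Wd = rng.uniform(-limit, limit, size=n_feat)
    return ModelHandle(cfg.approach, n_signals, branches, Wd, 0.0, cfg)


def _windows(X: np.ndarray, k: int) -> np.ndarray:
    """im2col view of [n, L, c]: [n, L-k+1, c, k] sliding windows."""
    return np.lib.stride_tricks.sliding_window_view(X, k, axis=1)


def _conv_valid(X: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Valid-mode conv of [n, L, c] with [k, c, f] -> [n, L-k+1, f]."""
    k, c, f = W.shape
    n = X.shape[0]
    L_out = X.shape[1] - k + 1
    cols = np.ascontiguousarray(_windows(X, k)).reshape(n * L_out, c * k)
    Wr = W.transpose(1, 0, 2).reshape(c * k, f)
    return (cols @ Wr).reshape(n, L_out, f) + b


def _forward(
    model: ModelHandle,
    X: np.ndarray,
    rng: Optional[np.random.Generator] = None,
    want_cache: bool = False,
):
    """Forward pass; with ``rng`` set, applies inverted dropout (training)."""
    cfg = model.cfg
    pool = cfg.pool
    feats = []
    cache = []
    for br in model.branches:
        conv = _conv_valid(X[:, :, br.channels], br.W, br.b)
        if rng is not None and cfg.dropout > 0:
            mask = (rng.random(conv.shape) >= cfg.dropout) / (1.0 - cfg.dropout)
            conv_d = conv * mask
        else:
            mask = None
            conv_d = conv
        L = (conv_d.shape[1] // pool) * pool
        blocks = conv_d[:, :L].reshape(conv_d.shape[0], L // pool, pool, -1)
        arg = blocks.argmax(axis=2)
        pooled = np.take_along_axis(blocks, arg[:, :, None, :], axis=2)[:, :, 0, :]
        feats.append(pooled.reshape(X.shape[0], -1))
        if want_cache:
            cache.append((mask, arg, blocks.shape))
    feat = np.concatenate(feats, axis=1)
    z = feat @ model.Wd + model.bd
    p = 1.0 / (1.0 + np.exp(-z))
    if want_cache:
        return p, feat, cache
    return p


def _backward(
    model: ModelHandle,
    X: np.ndarray,
    dz: np.ndarray,
    feat: np.ndarray,
    cache,
):
    """Gradients of the mean loss w.r.t. all parameters, given dL/dz."""
    cfg = model.cfg
    pool = cfg.pool
    grads = {"Wd": feat.T @ dz, "bd": dz.sum(), "branches": []}
    dfeat = np.outer(dz, model.Wd)
    offset = 0
    for br, (mask, arg, bshape) in zip(model.branches, cache):
        n, n_pool, _, f = bshape
        width = n_pool * f
        dpooled = dfeat[:, offset : offset + width].reshape(n, n_pool, f)
        offset += width
        dblocks = np.zeros(bshape)
        np.put_along_axis(dblocks, arg[:, :, None, :], dpooled[:, :, None, :], axis=2)
        dconv = dblocks.reshape(n, n_pool * pool, f)
        L_conv = X.shape[1] - cfg.kernel + 1
        if dconv.shape[1] < L_conv:  # pooling truncated an odd tail
            pad = np.zeros((n, L_conv - dconv.shape[1], f))
            dconv = np.concatenate([dconv, pad], axis=1)
        if mask is not None:
            dconv = dconv * mask
        Xb = X[:, :, br.channels]
        k, c = cfg.kernel, len(br.channels)
        cols = np.ascontiguousarray(_windows(Xb, k)).reshape(n * L_conv, c * k)
        dW = (cols.T @ dconv.reshape(n * L_conv, f)).reshape(c, k, f)
        grads["branches"].append((dW.transpose(1, 0, 2), dconv.sum(axis=(0, 1))))
    return grads


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]):
        self.t += 1
        out = []
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1**self.t)
            vh = self.v[i] / (1 - self.b2**self.t)
            out.append(p - self.lr * mh / (np.sqrt(vh) + self.eps))
        return out


def train(
    model: ModelHandle, data: SnippetSet, cfg: Optional[FusionConfig] = None
) -> ModelHandle:
    """Train a fusion network on labeled snippets (Adam, binary cross-entropy).

    Deterministic for a fixed config seed: weight initialisation, epoch
    shuffling and dropout masks all flow from one generator.  Raises on
    single-class data.
    """
    cfg = cfg or model.cfg
    y = np.asarray(data.y, dtype=np.float64)
    if np.unique(y).size < 2:
        raise SignalError("training data must contain both classes")
    model = model.copy()
    model.cfg = cfg
    X = np.asarray(data.X, dtype=np.float64)
    n = X.shape[0]

    if cfg.class_weight:
        n_pos = max(1.0, y.sum())
        n_neg = max(1.0, n - y.sum())
        w_pos, w_neg = n / (2 * n_pos), n / (2 * n_neg)
    else:
        w_pos = w_neg = 1.0

    rng = np.random.default_rng(cfg.seed + 1)
    params = model.parameters()
    opt = _Adam(params, cfg.lr)

    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo : lo + cfg.batch_size]
            Xb, yb = X[idx], y[idx]
            p, feat, cache = _forward(model, Xb, rng=rng, want_cache=True)
            w = np.where(yb == 1, w_pos, w_neg)
            eps = 1e-12
            loss = -np.mean(
                w * (yb * np.log(p + eps) + (1 - yb) * np.log(1 - p + eps))
            )
            epoch_loss += loss * idx.size
            dz = w * (p - yb) / idx.size
            g = _backward(model, Xb, dz, feat, cache)
            flat_grads = []
            for dW, db in g["branches"]:
                flat_grads += [dW, db]
            flat_grads += [g["Wd"], np.atleast_1d(g["bd"])]
            new = opt.step(model.parameters(), flat_grads)
            for br, Wn, bn in zip(model.branches, new[0::2], new[1::2]):
                br.W, br.b = Wn, bn
            model.Wd, model.bd = new[-2], float(new[-1][0])
        model.loss_history.append(epoch_loss / n)

    model.signals = data.signals
    model.trained = True
    model.train_prevalence = float(y.mean())
    if cfg.calibrate:
        model.threshold = calibrate_threshold(model, data)
    return model


def _prevalence_threshold(p: np.ndarray, prevalence: float) -> float:
    """Threshold putting a ``prevalence`` fraction of outputs above it."""
    n_pos = int(round(prevalence * p.size))
    if n_pos <= 0:
        return 1.0
    if n_pos >= p.size:
        return 0.0
    s = np.sort(p)
    thr = 0.5 * (s[p.size - n_pos - 1] + s[p.size - n_pos])
    return float(np.clip(thr, 1e-6, 1 - 1e-6))


def calibrate_threshold(model: ModelHandle, data: SnippetSet) -> float:
    """Prevalence-matched decision threshold from training data.

    Dropout sits before max-pooling, so inference-mode sigmoid outputs run
    systematically lower than the training-time activations the dense layer
    was fitted against; a fixed 0.5 cut can then under-call positives.  The
    remedy is to place the threshold so the predicted positive rate matches
    the training prevalence (labels enter only through that single
    fraction).  Returns the midpoint between the two order statistics
    straddling the (1 - prevalence) quantile, clipped away from 0 and 1.
    """
    p = predict_proba(model, data)
    n_pos = int(np.asarray(data.y).sum())
    if n_pos == 0 or n_pos >= p.size:
        return model.cfg.threshold
    return _prevalence_threshold(p, n_pos / p.size)


def predict_proba(
    model: ModelHandle, data: SnippetSet, chunk: int = 4096
) -> np.ndarray:
    """Sigmoid outputs per snippet (dropout disabled), computed in chunks."""
    if model.signals is not None and data.signals != model.signals:
        raise SignalError(
            f"snippet modality order {data.signals} does not match the "
            f"training order {model.signals}"
        )
    n = data.X.shape[0]
    out = np.empty(n)
    for lo in range(0, n, chunk):
        out[lo : lo + chunk] = _forward(
            model, np.asarray(data.X[lo : lo + chunk], dtype=np.float64)
        )
    return out


#: minimum batch size for transductive (per-batch) prevalence matching
_MIN_TRANSDUCTIVE = 200


def predict_labels(
    model: ModelHandle, data: SnippetSet, threshold: Optional[float] = None
) -> np.ndarray:
    """Binary labels: 1 iff the sigmoid output exceeds the threshold.

    Precedence: an explicit ``threshold`` argument wins.  Otherwise, a
    calibrated model (``cfg.calibrate``) thresholds each sufficiently large
    batch at its own prevalence-matched quantile — the fraction of positive
    labels is pinned to the training prevalence, which makes the operating
    point invariant to the between-subject scale/confidence shifts that
    move sigmoid outputs around (no labels of ``data`` are consulted).
    Small batches fall back to the stored training-set threshold; an
    uncalibrated model uses the config threshold (0.5).
    """
    p = predict_proba(model, data)
    if threshold is None:
        if (
            model.cfg.calibrate
            and model.train_prevalence is not None
            and p.size >= _MIN_TRANSDUCTIVE
        ):
            threshold = _prevalence_threshold(p, model.train_prevalence)
        elif model.threshold is not None:
            threshold = model.threshold
        else:
            threshold = model.cfg.threshold
    return (p > threshold).astype(np.int8)


def save_model(model: ModelHandle, path) -> None:
    """Checkpoint: .npz weights + .json manifest (approach, signals, config)."""
    import json
    from dataclasses import asdict
    from pathlib import Path

    path = Path(path)
    arrays = {"Wd": model.Wd, "bd": np.atleast_1d(model.bd)}
    for i, br in enumerate(model.branches):
        arrays[f"branch{i}_W"] = br.W
        arrays[f"branch{i}_b"] = br.b
    np.savez_compressed(path.with_suffix(".npz"), **arrays)
    manifest = {
        "approach": model.approach,
        "n_signals": model.n_signals,
        "signals": None if model.signals is None else list(model.signals),
        "branch_channels": [list(br.channels) for br in model.branches],
        "config": asdict(model.cfg),
        "trained": model.trained,
        "threshold": model.threshold,
        "train_prevalence": model.train_prevalence,
        "loss_history": model.loss_history,
    }
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=2) + "\n")


def load_model(path) -> ModelHandle:
    """Inverse of :func:`save_model`."""
    import json
    from pathlib import Path

    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    cfg = FusionConfig(**manifest["config"])
    with np.load(path.with_suffix(".npz")) as z:
        branches = [
            _Branch(tuple(channels), z[f"branch{i}_W"], z[f"branch{i}_b"])
            for i, channels in enumerate(manifest["branch_channels"])
        ]
        Wd, bd = z["Wd"], float(z["bd"][0])
    model = ModelHandle(
        manifest["approach"], manifest["n_signals"], branches, Wd, bd, cfg,
        None if manifest["signals"] is None else tuple(manifest["signals"]),
        list(manifest["loss_history"]), manifest["trained"],
        manifest["threshold"], manifest.get("train_prevalence"),
    )
    return model


def hybrid_vote(votes: VoteMatrix | np.ndarray, min_votes: int = 2) -> np.ndarray:
    """Per-snippet majority vote over the fusion approaches' labels.

    ``label_j = 1`` iff at least ``min_votes`` approaches vote 1 for snippet
    j.  Permutation-invariant across approaches and independent of the
    networks that produced the votes.
    """
    labels = votes.labels if isinstance(votes, VoteMatrix) else np.asarray(votes)
    if labels.ndim != 2:
        raise SignalError("votes must be [n_approaches, n_snippets]")
    if not np.isin(labels, (0, 1)).all():
        raise SignalError("votes must be binary")
    if not 1 <= min_votes <= labels.shape[0]:
        raise SignalError("min_votes must lie in [1, n_approaches]")
    return (labels.sum(axis=0) >= min_votes).astype(np.int8)
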