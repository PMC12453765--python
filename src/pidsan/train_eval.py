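"""Training and evaluation: splits, metrics, CI statistics, noise robustness.

The evaluation vocabulary is the standard binary-classifier set — accuracy,
sensitivity (recall of the positive class), specificity, precision,
F-measure (harmonic mean of precision and sensitivity) and G-mean
(sqrt(sensitivity * specificity)) — plus the standard error of a proportion
SEM = sqrt(p(1-p)/N) and the normal-approximation confidence interval
p +/- z * SEM (z = 1.96 for 95%).

Robustness is probed by re-evaluating under additive zero-mean Gaussian
pixel noise whose standard deviation is a percentage of the [0, 1] dynamic
range (levels such as 1%, 3%, 5%).
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold

from .nn import SGDM, BatchNorm2d, Tensor, no_grad
from .pidsan4 import Pidsan4, Pidsan4Config, class_weights, weighted_cross_entropy
from .vit import TinyViT, VitConfig

__all__ = [
    "SplitSpec", "MetricReport", "CiResult", "TrainHistory",
    "stratified_split", "kfold_plan", "confusion_and_metrics", "sem_ci",
    "add_gaussian_noise", "train_loop", "evaluate",
    "quick_validation_accuracy", "save_checkpoint", "load_checkpoint",
]


# -- splitting ----------------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    """Train/test/validation percentages (must sum to exactly 100)."""
    train: float = 70.0
    test: float = 20.0
    val: float = 10.0
    seed: int = 0
    stratified: bool = True

    def __post_init__(self):
        for name, v in (("train", self.train), ("test", self.test), ("val", self.val)):
            if not 0.0 < v < 100.0:
                raise ValueError(f"{name} percentage must be in (0, 100), got {v}")
        if self.train + self.test + self.val != 100.0:
            raise ValueError(
                f"percentages must sum to 100, got {self.train + self.test + self.val}")


def _allocate(n: int, fractions: np.ndarray) -> np.ndarray:
    """Largest-remainder allocation of n items to len(fractions) buckets."""
    raw = fractions * n
    base = np.floor(raw).astype(int)
    remainder = n - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:remainder]] += 1
    return base


def stratified_split(labels, spec: SplitSpec):
    """Return (train_idx, test_idx, val_idx): disjoint, exhaustive, stratified.

    Per-class proportions match the spec within one sample; identical seeds
    give identical index sets.
    """
    labels = np.asarray(labels)
    fractions = np.array([spec.train, spec.test, spec.val]) / 100.0
    rng = np.random.default_rng(spec.seed)
    parts = [[], [], []]
    classes = np.unique(labels)
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        if len(idx) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")
        idx = rng.permutation(idx)
        counts = _allocate(len(idx), fractions)
        start = 0
        for part, c in zip(parts, counts):
            part.extend(idx[start:start + c].tolist())
            start += c
    return tuple(np.sort(np.array(p, dtype=int)) for p in parts)


def kfold_plan(labels, k: int = 10, seed: int = 0):
    """Stratified k-fold test-index sets (disjoint, exhaustive, sizes +/-1)."""
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    counts = np.bincount(np.searchsorted(np.unique(labels), labels))
    if k > counts.min():
        raise ValueError(f"k={k} exceeds the smallest class count {counts.min()}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros(len(labels)), labels)]


# -- metrics ------------------------------------------------------------------

@dataclass
class MetricReport:
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f_measure: float
    g_mean: float
    undefined: tuple = ()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["undefined"] = list(self.undefined)
        return d


def confusion_and_metrics(y_true, y_pred, positive_label=1) -> MetricReport:
    """Confusion counts and the six standard metrics for binary labels.

    Ratios with a zero denominator are reported as 0 and flagged in
    ``report.undefined``.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    t = (y_true == positive_label).astype(int)
    p = (y_pred == positive_label).astype(int)
    tn, fp, fn, tp = confusion_matrix(t, p, labels=[0, 1]).ravel()
    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    n = tp + tn + fp + fn
    acc = ratio(tp + tn, n, "accuracy")
    sens = ratio(tp, tp + fn, "sensitivity")
    spec = ratio(tn, tn + fp, "specificity")
    prec = ratio(tp, tp + fp, "precision")
    f = ratio(2.0 * prec * sens, prec + sens, "f_measure")
    g = float(np.sqrt(sens * spec))
    if undefined:
        warnings.warn(f"metrics with zero denominator reported as 0: {undefined}",
                      stacklevel=2)
    return MetricReport(tp=int(tp), tn=int(tn), fp=int(fp), fn=int(fn),
                        accuracy=acc, sensitivity=sens, specificity=spec,
                        precision=prec, f_measure=f, g_mean=g,
                        undefined=tuple(undefined))


@dataclass(frozen=True)
class CiResult:
    p: float
    err: float
    sem: float
    z: float
    lower: float
    upper: float


def sem_ci(p: float, n: int | None = None, sem_override: float | None = None,
           z: float = 1.96) -> CiResult:
    """SEM and normal confidence interval for a proportion.

    ``sem = sqrt(p(1-p)/n)`` unless an explicit ``sem_override`` is supplied
    (e.g. to reproduce a published table); CI = p +/- z*sem.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if sem_override is not None:
        sem = float(sem_override)
        if sem < 0:
            raise ValueError(f"sem must be non-negative, got {sem}")
    else:
        if n is None or n < 1:
            raise ValueError("supply a sample size n >= 1 or an explicit sem_override")
        sem = float(np.sqrt(p * (1.0 - p) / n))
    return CiResult(p=p, err=1.0 - p, sem=sem, z=z,
                    lower=p - z * sem, upper=p + z * sem)


# -- noise protocol -----------------------------------------------------------

def add_gaussian_noise(img: np.ndarray, level_pct: float, seed=None) -> np.ndarray:
    """Add zero-mean Gaussian noise with sigma = level_pct% of the dynamic range."""
    if level_pct < 0:
        raise ValueError(f"noise level must be >= 0, got {level_pct}")
    img = np.asarray(img, dtype=np.float64)
    if level_pct == 0:
        return img.copy()
    rng = np.random.default_rng(seed)
    noisy = img + rng.normal(0.0, level_pct / 100.0, size=img.shape)
    return np.clip(noisy, 0.0, 1.0)


# -- training -----------------------------------------------------------------

@dataclass
class TrainHistory:
    train_loss: list = field(default_factory=list)
    train_accuracy: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_accuracy: list = field(default_factory=list)


@dataclass
class DataBundle:
    """In-memory dataset: channel-last images in [0, 1] plus integer labels."""
    train_images: np.ndarray
    train_labels: np.ndarray
    val_images: np.ndarray
    val_labels: np.ndarray

    @property
    def n_classes(self) -> int:
        return int(max(self.train_labels.max(), self.val_labels.max())) + 1


def _onehot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((len(labels), n_classes))
    out[np.arange(len(labels)), labels] = 1.0
    return out


def _batch_tensor(images: np.ndarray, dtype) -> Tensor:
    return Tensor(np.ascontiguousarray(np.transpose(images, (0, 3, 1, 2))).astype(dtype))


def _eval_loss_acc(model, images, labels, weights, batch_size=32):
    losses, correct = [], 0
    n_classes = int(weights.shape[0])
    for start in range(0, len(images), batch_size):
        xb = images[start:start + batch_size]
        yb = labels[start:start + batch_size]
        probs = model.predict_proba(xb)
        losses.append(weighted_cross_entropy(probs, _onehot(yb, n_classes), weights)
                      * len(xb))
        correct += int((probs.argmax(axis=1) == yb).sum())
    return float(np.sum(losses) / len(images)), correct / len(images)


def _walk_modules(module):
    yield module
    for sub in module._submodules():
        yield from _walk_modules(sub)


def recalibrate_batchnorm(model, images: np.ndarray, batch_size: int = 32):
    """Re-estimate batch-norm running moments over `images` with frozen weights.

    After a short training run the exponential running statistics lag the
    final weights, which degrades eval-mode predictions; this pass replaces
    them with the exact average of the per-batch moments (cumulative moving
    average, i.e. momentum 1/i on batch i).
    """
    bns = [m for m in _walk_modules(model) if isinstance(m, BatchNorm2d)]
    if not bns:
        return
    for bn in bns:
        bn.running_mean.data = np.zeros_like(bn.running_mean.data)
        bn.running_var.data = np.zeros_like(bn.running_var.data)
    saved = [bn.momentum for bn in bns]
    dtype = model.parameters()[0].data.dtype
    model.train()
    try:
        with no_grad():
            for i, start in enumerate(range(0, len(images), batch_size)):
                for bn in bns:
                    bn.momentum = 1.0 / (i + 1)
                model(_batch_tensor(images[start:start + batch_size], dtype))
    finally:
        for bn, m in zip(bns, saved):
            bn.momentum = m
        model.eval()


def train_loop(model, bundle: DataBundle, hyperparams: dict | None = None,
               seed: int = 0, verbose: bool = False):
    """Train with SGDM on class-weighted categorical cross-entropy.

    ``hyperparams`` keys (all optional): learning_rate (default 0.001),
    batch_size (16), epochs (200), momentum (0.9), l2 (0.0), clip_norm
    (global gradient-norm clip, default 5.0; None disables).  Class weights
    are recomputed from the training-label counts each run.  Per-epoch
    shuffling is seeded; a NaN loss aborts with a diagnostic.  The final
    epoch ends with a batch-norm recalibration pass over the training set.
    """
    hp = dict(hyperparams or {})
    lr = float(hp.get("learning_rate", 0.001))
    batch_size = int(hp.get("batch_size", 16))
    epochs = int(hp.get("epochs", 200))
    momentum = float(hp.get("momentum", 0.9))
    l2 = float(hp.get("l2", 0.0))
    clip_norm = hp.get("clip_norm", 5.0)
    n_classes = bundle.n_classes
    weights = class_weights(np.bincount(bundle.train_labels, minlength=n_classes))
    opt = SGDM(model.parameters(), lr=lr, momentum=momentum, l2=l2,
               clip_norm=clip_norm)
    rng = np.random.default_rng(seed)
    dtype = model.parameters()[0].data.dtype
    history = TrainHistory()
    n = len(bundle.train_images)
    for epoch in range(epochs):
        model.train()
        order = rng.permutation(n)
        epoch_loss, correct = 0.0, 0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            xb = _batch_tensor(bundle.train_images[idx], dtype)
            yb = bundle.train_labels[idx]
            probs = model(xb)
            loss = weighted_cross_entropy(probs, _onehot(yb, n_classes), weights)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}, batch {start // batch_size}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
            correct += int((probs.data.argmax(axis=1) == yb).sum())
        history.train_loss.append(epoch_loss / n)
        history.train_accuracy.append(correct / n)
        if epoch == epochs - 1:
            recalibrate_batchnorm(model, bundle.train_images)
        vl, va = _eval_loss_acc(model, bundle.val_images, bundle.val_labels, weights)
        history.val_loss.append(vl)
        history.val_accuracy.append(va)
        if verbose:
            print(f"epoch {epoch + 1}/{epochs}: train loss {history.train_loss[-1]:.4f} "
                  f"acc {history.train_accuracy[-1]:.3f} | val loss {vl:.4f} acc {va:.3f}")
    return model, history


def quick_validation_accuracy(model, bundle: DataBundle, hyperparams: dict) -> float:
    """Short training run used as the GWO tuning objective."""
    hp = dict(hyperparams)
    hp.setdefault("epochs", 3)
    _, history = train_loop(model, bundle, hp, seed=int(hp.get("seed", 0)))
    return history.val_accuracy[-1]


def evaluate(model, images: np.ndarray, labels: np.ndarray,
             noise_levels=(0.0,), positive_label: int = 1, seed: int = 0):
    """MetricReport per Gaussian-noise level (0 = clean); returns a dict
    mapping level -> MetricReport."""
    if len(images) == 0:
        raise ValueError("cannot evaluate on an empty dataset")
    reports = {}
    for level in noise_levels:
        if level > 0:
            noisy = np.stack([add_gaussian_noise(img, level, seed=seed + i)
                              for i, img in enumerate(images)])
        else:
            noisy = images
        preds = []
        for start in range(0, len(noisy), 32):
            probs = model.predict_proba(noisy[start:start + 32])
            preds.append(probs.argmax(axis=1))
        reports[level] = confusion_and_metrics(labels, np.concatenate(preds),
                                               positive_label=positive_label)
    return reports


# -- checkpoints --------------------------------------------------------------

def save_checkpoint(model, path: str | os.PathLike, metadata: dict | None = None):
    """Serialize weights + config + metadata; round-trips value-exact."""
    cfg = model.cfg
    kind = "pidsan4" if isinstance(model, Pidsan4) else "tinyvit"
    meta = {"kind": kind, "config": cfg.to_dict(), "metadata": metadata or {}}
    state = model.state_dict()
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **state)


def load_checkpoint(path: str | os.PathLike):
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    if meta["kind"] == "pidsan4":
        model = Pidsan4(Pidsan4Config.from_dict(meta["config"]))
    else:
        model = TinyViT(VitConfig.from_dict(meta["config"]))
    model.load_state_dict(state)
    model.eval()
    return model, meta["metadata"]
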