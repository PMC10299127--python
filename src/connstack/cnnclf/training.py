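"""Transfer-learning classification of channel stacks.

Phase 1 trains a dropout + single-sigmoid head on features from a frozen
backbone; phase 2 optionally unfreezes everything and continues end-to-end at
a much lower learning rate.  Subject-level evaluation uses stratified k-fold
cross-validation and the confusion-count accuracy (TP+TN)/(TP+TN+FP+FN).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import nn
from .backbones import BackboneError, TinyConvBackbone, get_backbone_spec

__all__ = [
    "TrainSchedule",
    "ConfusionCounts",
    "CvReport",
    "min_max_scale",
    "prepare_input",
    "extract_features",
    "build_head",
    "DropoutHead",
    "train_transfer",
    "accuracy",
    "confusion_counts",
    "cross_validate",
]

POSITIVE_LABEL = "case"


class TrainingError(ValueError):
    pass


@dataclass
class TrainSchedule:
    """Hyperparameters of the two training phases (conventional defaults)."""

    lr_head: float = 1e-3
    lr_finetune: float = 1e-5
    epochs_head: int = 200
    epochs_finetune: int = 30
    patience: int = 10
    batch_size: int = 16
    dropout_rate: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate < 1.0:
            raise TrainingError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        if self.lr_finetune >= self.lr_head:
            raise TrainingError("fine-tune learning rate must be below the head rate")


@dataclass
class ConfusionCounts:
    TP: int = 0
    FP: int = 0
    TN: int = 0
    FN: int = 0

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "TN", "FN"):
            if getattr(self, name) < 0:
                raise TrainingError(f"{name} must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class CvReport:
    """Per-fold confusion counts and accuracies plus their mean."""

    k: int
    per_fold: list[tuple[ConfusionCounts, float]]
    mean_accuracy: float
    fingerprint: str
    seed: int

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "seed": self.seed,
            "fingerprint": self.fingerprint,
            "mean_accuracy": self.mean_accuracy,
            "per_fold": [
                {"TP": c.TP, "FP": c.FP, "TN": c.TN, "FN": c.FN, "accuracy": a}
                for c, a in self.per_fold
            ],
        }


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    if c.total == 0:
        raise TrainingError("accuracy undefined: all confusion counts are zero")
    return (c.TP + c.TN) / c.total


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    """Binary counts with 1 = positive (case)."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    return ConfusionCounts(
        TP=int(np.sum((y_true == 1) & (y_pred == 1))),
        FP=int(np.sum((y_true == 0) & (y_pred == 1))),
        TN=int(np.sum((y_true == 0) & (y_pred == 0))),
        FN=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


# ---------------------------------------------------------------------------
# input preparation and feature extraction

def min_max_scale(channels: np.ndarray) -> np.ndarray:
    """One shared linear map sending [min, max] of the stack to [0, 255]."""
    x = np.asarray(channels, dtype=float)
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        raise TrainingError("constant stack: min-max scaling undefined")
    return (x - lo) * (255.0 / (hi - lo))


def prepare_input(stack) -> np.ndarray:
    """Min-max scale to [0, 255] then apply the canonical [-1, 1] input
    normalization; no spatial resizing."""
    scaled = min_max_scale(getattr(stack, "channels", stack))
    return scaled / 127.5 - 1.0


def extract_features(tensor: np.ndarray, backbone, seed: int = 0) -> np.ndarray:
    """Run the frozen convolutional stage on an (N, N, 3) or (B, N, N, 3) tensor.

    Only the TinyConv surrogate can run offline; the named ImageNet
    architectures expose geometry only (their pretrained weights cannot be
    shipped with this artifact).
    """
    spec = backbone if hasattr(backbone, "min_input_side") else get_backbone_spec(str(backbone))
    x = np.asarray(tensor, dtype=float)
    squeeze = x.ndim == 3
    if squeeze:
        x = x[None]
    side = x.shape[1]
    if side < spec.min_input_side:
        raise BackboneError(
            f"{spec.name} requires input side >= {spec.min_input_side}, got {side}"
        )
    if spec.name != "TinyConv":
        raise BackboneError(
            f"offline feature extraction is only available for TinyConv; "
            f"{spec.name} supports geometry queries via feature_geometry()"
        )
    net = TinyConvBackbone(in_channels=x.shape[3], seed=seed)
    feats = net.forward(x)
    return feats[0] if squeeze else feats


class DropoutHead:
    """flatten -> dropout -> dense(1) -> sigmoid, binary cross-entropy."""

    def __init__(self, feature_shape, dropout_rate: float = 0.5, seed: int = 0) -> None:
        if not 0.0 <= dropout_rate < 1.0:
            raise TrainingError(f"dropout_rate must be in [0, 1), got {dropout_rate}")
        self.feature_shape = tuple(feature_shape)
        self.n_features = int(np.prod(self.feature_shape))
        self.dropout_rate = dropout_rate
        rng = np.random.default_rng(seed)
        self.W = rng.standard_normal((self.n_features, 1)) * np.sqrt(1.0 / self.n_features)
        self.b = np.zeros(1)

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    def forward(self, feats: np.ndarray, rng=None, train: bool = False):
        flat = feats.reshape(feats.shape[0], -1)
        dropped, c_drop = nn.dropout_forward(flat, self.dropout_rate, rng, train)
        z, c_dense = nn.dense_forward(dropped, self.W, self.b)
        p = nn.sigmoid(z[:, 0])
        return p, (c_drop, c_dense, feats.shape)

    def backward(self, p: np.ndarray, y: np.ndarray, cache):
        c_drop, c_dense, feats_shape = cache
        dz = ((p - y) / len(y))[:, None]  # d BCE / d logit
        dflat, dW, db = nn.dense_backward(dz, self.W, c_dense)
        dflat = nn.dropout_backward(dflat, c_drop)
        return dflat.reshape(feats_shape), [dW, db]

    def predict_proba(self, feats: np.ndarray) -> np.ndarray:
        p, _ = self.forward(feats, train=False)
        return p


def build_head(feature_shape, dropout_rate: float = 0.5, seed: int = 0) -> DropoutHead:
    return DropoutHead(feature_shape, dropout_rate, seed)


@dataclass
class FittedModel:
    backbone: TinyConvBackbone
    head: DropoutHead
    schedule: TrainSchedule
    history: dict = field(default_factory=dict)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        feats = self.backbone.forward(x)
        return self.head.predict_proba(feats)

    def predict(self, x: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(x) >= threshold).astype(int)


def _epoch_batches(n: int, batch_size: int, rng) -> list[np.ndarray]:
    order = rng.permutation(n)
    return [order[i:i + batch_size] for i in range(0, n, batch_size)]


def train_transfer(
    train_x: np.ndarray,
    train_y: np.ndarray,
    val_x: np.ndarray,
    val_y: np.ndarray,
    backbone: TinyConvBackbone | None = None,
    head: DropoutHead | None = None,
    schedule: TrainSchedule | None = None,
    fine_tune: bool = False,
    seed: int = 0,
) -> FittedModel:
    """Two-phase transfer training on prepared input tensors.

    Phase 1 freezes the backbone and fits the head on its features with
    early stopping on validation loss; phase 2 (``fine_tune``) unfreezes
    everything and continues at the low fine-tuning rate.
    """
    train_y = np.asarray(train_y, dtype=float)
    val_y = np.asarray(val_y, dtype=float)
    if len(train_y) == 0:
        raise TrainingError("empty training set")
    if len(set(train_y.tolist())) < 2:
        raise TrainingError("training set contains a single class")
    schedule = schedule or TrainSchedule()
    rng = np.random.default_rng(seed)
    if backbone is None:
        backbone = TinyConvBackbone(in_channels=train_x.shape[3], seed=seed)
    if head is None:
        side = train_x.shape[1]
        head = DropoutHead(backbone.feature_shape(side), schedule.dropout_rate, seed=seed + 1)

    # ---- phase 1: frozen backbone, features computed once
    train_f = backbone.forward(train_x)
    val_f = backbone.forward(val_x) if len(val_y) else np.empty((0,) + train_f.shape[1:])
    opt = nn.Adam(head.params, lr=schedule.lr_head)
    hist1 = _fit_head(head, opt, train_f, train_y, val_f, val_y, schedule, rng)

    hist2: dict = {}
    if fine_tune:
        hist2 = _fit_end_to_end(backbone, head, train_x, train_y, val_x, val_y, schedule, rng)
    return FittedModel(
        backbone=backbone,
        head=head,
        schedule=schedule,
        history={"phase1": hist1, "phase2": hist2},
    )


def _val_metrics(head, backbone, val_x, val_f, val_y):
    if len(val_y) == 0:
        return None, None
    feats = val_f if val_f is not None else backbone.forward(val_x)
    p = head.predict_proba(feats)
    return nn.bce_loss(p, val_y), float(np.mean((p >= 0.5) == (val_y == 1)))


def _fit_head(head, opt, train_f, train_y, val_f, val_y, schedule, rng) -> dict:
    best_loss, best_params, wait = np.inf, None, 0
    val_acc_hist, val_loss_hist = [], []
    for _ in range(schedule.epochs_head):
        for idx in _epoch_batches(len(train_y), schedule.batch_size, rng):
            p, cache = head.forward(train_f[idx], rng=rng, train=True)
            _, grads = head.backward(p, train_y[idx], cache)
            opt.step(grads)
        vloss, vacc = _val_metrics(head, None, None, val_f, val_y)
        if vloss is None:
            continue
        val_loss_hist.append(vloss)
        val_acc_hist.append(vacc)
        if vloss < best_loss - 1e-6:
            best_loss, wait = vloss, 0
            best_params = [p.copy() for p in head.params]
        else:
            wait += 1
            if wait >= schedule.patience:
                break
    if best_params is not None:
        head.W[...] = best_params[0]
        head.b[...] = best_params[1]
    return {"val_loss": val_loss_hist, "val_accuracy": val_acc_hist}


def _fit_end_to_end(backbone, head, train_x, train_y, val_x, val_y, schedule, rng) -> dict:
    params = backbone.params + head.params
    opt = nn.Adam(params, lr=schedule.lr_finetune)
    best_loss, best_params, wait = np.inf, None, 0
    val_acc_hist, val_loss_hist = [], []
    for _ in range(schedule.epochs_finetune):
        for idx in _epoch_batches(len(train_y), schedule.batch_size, rng):
            feats, caches = backbone.forward(train_x[idx], want_cache=True)
            p, hcache = head.forward(feats, rng=rng, train=True)
            dfeats, hgrads = head.backward(p, train_y[idx], hcache)
            bgrads = backbone.backward(dfeats, caches)
            opt.step(bgrads + hgrads)
        vloss, vacc = _val_metrics(head, backbone, val_x, None, val_y)
        if vloss is None:
            continue
        val_loss_hist.append(vloss)
        val_acc_hist.append(vacc)
        if vloss < best_loss - 1e-6:
            best_loss, wait = vloss, 0
            best_params = [p.copy() for p in params]
        else:
            wait += 1
            if wait >= schedule.patience:
                break
    if best_params is not None:
        for p, bp in zip(params, best_params):
            p[...] = bp
    return {"val_loss": val_loss_hist, "val_accuracy": val_acc_hist}


def _labels_to_binary(labels) -> np.ndarray:
    return np.asarray([1 if lab == POSITIVE_LABEL else 0 for lab in labels], dtype=int)


def _config_fingerprint(payload: dict) -> str:
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def cross_validate(
    stacks,
    labels,
    backbone: str = "TinyConv",
    k: int = 10,
    seed: int = 0,
    fine_tune: bool = False,
    schedule: TrainSchedule | None = None,
    stack_builder=None,
    predictor=None,
) -> CvReport:
    """Stratified k-fold cross-validation over subjects.

    Per fold, the non-test folds are split 8:1 into training and validation.
    ``stack_builder(train_indices)`` may rebuild stacks per fold (e.g. tangent
    connectivity fitted on the training subjects only).  ``predictor`` replaces
    the CNN with a callable ``(train_x, train_y, test_x) -> predictions`` for
    testing.
    """
    labels = list(labels)
    y = _labels_to_binary(labels)
    n = len(y)
    if n < k:
        raise TrainingError(f"need at least k={k} subjects, got {n}")
    for cls in (0, 1):
        if int(np.sum(y == cls)) < k:
            raise TrainingError(
                f"stratified {k}-fold needs >= {k} subjects per class"
            )
    schedule = schedule or TrainSchedule()
    fingerprint = _config_fingerprint(
        {
            "backbone": backbone,
            "k": k,
            "seed": seed,
            "fine_tune": fine_tune,
            "schedule": asdict(schedule),
            "n": n,
        }
    )

    def tensors_for(stack_list) -> np.ndarray:
        return np.stack([prepare_input(s) for s in stack_list])

    x_all = tensors_for(stacks) if stack_builder is None else None

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    per_fold: list[tuple[ConfusionCounts, float]] = []
    for fold, (trainval_idx, test_idx) in enumerate(skf.split(np.zeros(n), y)):
        if stack_builder is not None:
            x_all_fold = tensors_for(stack_builder(trainval_idx))
        else:
            x_all_fold = x_all
        train_idx, val_idx = train_test_split(
            trainval_idx,
            test_size=1.0 / (k - 1),
            random_state=seed * 1000 + fold,
            stratify=y[trainval_idx],
        )
        if predictor is not None:
            preds = np.asarray(
                predictor(x_all_fold[trainval_idx], y[trainval_idx], x_all_fold[test_idx]),
                dtype=int,
            )
        else:
            model = train_transfer(
                x_all_fold[train_idx], y[train_idx],
                x_all_fold[val_idx], y[val_idx],
                schedule=schedule,
                fine_tune=fine_tune,
                seed=seed * 1000 + fold,
            )
            preds = model.predict(x_all_fold[test_idx])
        counts = confusion_counts(y[test_idx], preds)
        per_fold.append((counts, accuracy(counts)))
    mean_acc = float(np.mean([a for _, a in per_fold]))
    return CvReport(k=k, per_fold=per_fold, mean_accuracy=mean_acc,
                    fingerprint=fingerprint, seed=seed)
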