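"""Training and evaluation protocol.

The reference protocol trains with Adam (learning rate 1e-4, batch
size 8) for up to 200 epochs under a cosine learning-rate schedule
(T_max = 50) with early stopping on the validation focal loss
(patience 50), evaluated by stratified five-fold cross-validation on
the training split; each fold's best model is additionally scored on
the single held-out test split.  All randomness (fold carving,
parameter init, batch order) derives from one master seed by fixed
offsets, so a rerun with the same seed reproduces every number.

Scaled-down configurations (fewer epochs/subjects, the ``test`` encoder
preset, a larger learning rate suited to short schedules) use the same
code path; see the package methods notes for the sizes used in the
bundled checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .autodiff import Tensor, flop_counter, no_grad
from .metrics import MetricsReport, compute_metrics, confusion_from_predictions
from .network import FocalLossConfig, ModelConfig, TriLightNet, focal_loss_from_logits
from .nn import Adam
from .splits import FoldPlan

__all__ = [
    "TrainConfig",
    "ArrayDataset",
    "cosine_lr",
    "train_one_fold",
    "evaluate",
    "run_cv",
    "count_params_flops",
]

# fixed offsets deriving per-purpose seeds from the master seed
_SEED_SPLIT, _SEED_FOLDS, _SEED_INIT, _SEED_ORDER = 11, 13, 17, 19


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 200
    batch_size: int = 8
    lr: float = 1e-4
    t_max: int = 50
    patience: int = 50
    seed: int = 0
    k: int = 5
    loss: FocalLossConfig = field(default_factory=FocalLossConfig)

    def __post_init__(self):
        if min(self.epochs, self.batch_size, self.t_max, self.k) < 1 or self.lr <= 0:
            raise ValueError("train config fields must be positive")
        if self.patience < 0:
            raise ValueError("patience must be >= 0")


@dataclass
class ArrayDataset:
    """In-memory cohort: normalized volumes, standardized clinical
    features, labels and subject ids (all index-aligned)."""

    mri: np.ndarray  # [N, 1, D, H, W] float32
    pet: np.ndarray
    clinical: np.ndarray  # [N, 7] float32
    labels: np.ndarray  # [N] int
    ids: list[str]

    def __post_init__(self):
        n = len(self.ids)
        if not (len(self.mri) == len(self.pet) == len(self.clinical) == len(self.labels) == n):
            raise ValueError("dataset arrays are not index-aligned")

    def __len__(self):
        return len(self.ids)

    def index_of(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.ids)}
        return np.array([lookup[s] for s in ids], dtype=int)


def cosine_lr(epoch: int, lr0: float, t_max: int) -> float:
    """lr0 * (1 + cos(pi * (epoch mod T_max) / T_max)) / 2."""
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    return lr0 * (1.0 + math.cos(math.pi * (epoch % t_max) / t_max)) / 2.0


def _batch(data: ArrayDataset, idx: np.ndarray):
    return (
        Tensor(data.mri[idx]),
        Tensor(data.pet[idx]),
        Tensor(data.clinical[idx]),
        data.labels[idx],
    )


def _dataset_loss(model: TriLightNet, data: ArrayDataset, idx: np.ndarray, cfg: TrainConfig) -> float:
    model.eval()
    total = 0.0
    with no_grad():
        for start in range(0, len(idx), cfg.batch_size):
            sel = idx[start : start + cfg.batch_size]
            mri, pet, cli, y = _batch(data, sel)
            logits = model(mri, pet, cli)
            loss = focal_loss_from_logits(logits, y, cfg.loss)
            total += float(loss.data) * len(sel)
    return total / len(idx)


def train_one_fold(
    data: ArrayDataset,
    train_idx,
    val_idx,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    fold: int = 0,
) -> tuple[TriLightNet, dict]:
    """Train one model; returns it loaded with the best-validation
    parameters plus a history of per-epoch losses and learning rates.

    With ``val_idx=None`` the model is fitted on the full schedule with
    no early stopping and the final-epoch parameters are returned
    (used when every available subject should contribute gradients).
    """
    train_idx = np.asarray(train_idx, dtype=int)
    has_val = val_idx is not None
    if has_val:
        val_idx = np.asarray(val_idx, dtype=int)
        if len(val_idx) == 0:
            raise ValueError("empty validation set")
        if set(train_idx) & set(val_idx):
            raise ValueError("train and validation indices overlap")
    if len(train_idx) == 0:
        raise ValueError("empty train set")
    model = TriLightNet(model_cfg, seed=train_cfg.seed + _SEED_INIT + fold)
    order_rng = np.random.default_rng(train_cfg.seed + _SEED_ORDER + fold)
    opt = Adam(model.parameters(), lr=train_cfg.lr)
    history = {"train_loss": [], "val_loss": [], "lr": []}
    best_val = math.inf
    best_state = model.state_dict()
    stale = 0
    for epoch in range(train_cfg.epochs):
        lr = cosine_lr(epoch, train_cfg.lr, train_cfg.t_max)
        opt.lr = lr
        model.train()
        perm = order_rng.permutation(len(train_idx))
        epoch_loss = 0.0
        for start in range(0, len(perm), train_cfg.batch_size):
            sel = train_idx[perm[start : start + train_cfg.batch_size]]
            mri, pet, cli, y = _batch(data, sel)
            logits = model(mri, pet, cli)
            loss = focal_loss_from_logits(logits, y, train_cfg.loss)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(sel)
        history["train_loss"].append(epoch_loss / len(train_idx))
        history["lr"].append(lr)
        if not has_val:
            continue
        val_loss = _dataset_loss(model, data, val_idx, train_cfg)
        history["val_loss"].append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state_dict()
            stale = 0
        else:
            stale += 1
            if stale > train_cfg.patience:
                break
    if has_val:
        model.load_state_dict(best_state)
        history["best_val_loss"] = best_val
    return model, history


def evaluate(model: TriLightNet, data: ArrayDataset, idx, batch_size: int = 8):
    """Evaluation-mode probabilities and labels for the given indices."""
    idx = np.asarray(idx, dtype=int)
    model.eval()
    probs = []
    with no_grad():
        for start in range(0, len(idx), batch_size):
            sel = idx[start : start + batch_size]
            mri, pet, cli, _ = _batch(data, sel)
            logits = model(mri, pet, cli).data
            probs.append(1.0 / (1.0 + np.exp(-logits)))
    return np.concatenate(probs), data.labels[idx]


def _score(probs, labels) -> MetricsReport:
    return compute_metrics(confusion_from_predictions(probs, labels), probs, labels)


@dataclass
class CvResult:
    fold_reports: list[MetricsReport]
    test_reports: list[MetricsReport]
    histories: list[dict]
    summary: dict[str, tuple[float, float]]  # metric -> (mean, sd) over folds


def run_cv(
    data: ArrayDataset,
    folds: FoldPlan,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    test_idx=None,
) -> CvResult:
    """k trainings, one per fold; each fold's model is scored on its
    validation fold and (optionally) on the held-out test split."""
    fold_reports: list[MetricsReport] = []
    test_reports: list[MetricsReport] = []
    histories: list[dict] = []
    for fold in range(1, folds.k + 1):
        val_ids = folds.fold_ids(fold)
        train_ids = [i for i in folds.assignments if folds.assignments[i] != fold]
        model, hist = train_one_fold(
            data,
            data.index_of(train_ids),
            data.index_of(val_ids),
            model_cfg,
            replace(train_cfg, seed=train_cfg.seed),
            fold=fold,
        )
        probs, labels = evaluate(model, data, data.index_of(val_ids), train_cfg.batch_size)
        fold_reports.append(_score(probs, labels))
        if test_idx is not None:
            tp, tl = evaluate(model, data, np.asarray(test_idx), train_cfg.batch_size)
            test_reports.append(_score(tp, tl))
        histories.append(hist)
    summary = {}
    for metric in ("accuracy", "sensitivity", "precision", "auroc", "f1", "balanced_accuracy"):
        vals = np.array([getattr(r, metric) for r in fold_reports], dtype=float)
        summary[metric] = (float(np.nanmean(vals)), float(np.nanstd(vals)))
    return CvResult(fold_reports, test_reports, histories, summary)


def count_params_flops(model_cfg: ModelConfig) -> tuple[int, int]:
    """Exact parameter count by traversal plus FLOPs (2 x MACs of every
    convolution, linear map and attention matrix product) for one
    forward pass at the configured input shape, batch size 1."""
    model = TriLightNet(model_cfg, seed=0)
    n_params = sum(int(np.prod(p.data.shape)) for p in model.parameters())
    d, h, w = model_cfg.input_shape
    vol = np.zeros((1, 1, d, h, w), dtype=np.float32)
    cli = np.zeros((1, model_cfg.tabular.in_dim), dtype=np.float32)
    model.eval()
    with no_grad(), flop_counter() as flops:
        model(Tensor(vol), Tensor(vol.copy()), Tensor(cli))
    return n_params, int(flops[0])
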