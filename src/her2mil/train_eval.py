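"""Optimization loop, early stopping, cross-validated experiments, and AUROC evaluation.

Training follows fixed hyper-parameters across all folds: Adam (learning rate
1e-4, weight decay 1e-4), at most 200 epochs, one slide (bag) per optimizer
step, early stopping on validation loss. The checkpoint returned is the
best-validation-loss epoch. Evaluation reports AUROC on the positive class
for binary partitions and macro (optionally micro) one-vs-rest AUROC for
3-class partitions, plus precision-recall curves; fold tables are summarized
as median ± SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import precision_recall_curve, roc_auc_score

from .cohort_labels import SplitPlan, build_partition, make_splits
from .mil_model import MILConfig, MILParams, forward, loss_and_grads


@dataclass(frozen=True)
class TrainConfig:
    max_epochs: int = 200
    learning_rate: float = 1e-4
    weight_decay: float = 1e-4
    patience: int = 20
    min_epochs: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")


class Adam:
    """Adam with decoupled-from-nothing L2 weight decay folded into the gradient."""

    def __init__(self, params: MILParams, lr: float, weight_decay: float = 0.0,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = params.zeros_like()
        self.v = params.zeros_like()

    def step(self, grads: dict) -> None:
        self.t += 1
        bias1 = 1.0 - self.b1**self.t
        bias2 = 1.0 - self.b2**self.t
        for k, p in self.params.tensors().items():
            g = grads[k] + self.wd * p
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            p -= self.lr * (self.m[k] / bias1) / (np.sqrt(self.v[k] / bias2) + self.eps)


@dataclass
class FoldResult:
    params: MILParams  # best-validation-loss checkpoint
    history: pd.DataFrame  # epoch, train_loss, val_loss
    best_epoch: int
    best_val_loss: float


def _mean_loss(bags, labels, params) -> float:
    return float(
        np.mean([loss_and_grads(b, y, params)[0].total for b, y in zip(bags, labels)])
    )


def train_fold(train_bags, train_labels, val_bags, val_labels,
               model_config: MILConfig, train_config: TrainConfig) -> FoldResult:
    """Train one fold to the early-stopping criterion; fully seeded.

    Stops after any epoch ≥ ``min_epochs`` at which the validation loss has
    not improved for ``patience`` consecutive epochs (patience 0 therefore
    stops at the first eligible epoch).
    """
    labels = np.asarray(train_labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("training set must contain at least 2 classes")
    rng = np.random.default_rng(train_config.seed)
    params = MILParams.init(model_config, seed=int(rng.integers(2**31)))
    opt = Adam(params, train_config.learning_rate, train_config.weight_decay)

    best = None
    best_val = np.inf
    best_epoch = -1
    since_best = 0
    rows = []
    for epoch in range(1, train_config.max_epochs + 1):
        order = rng.permutation(len(train_bags))
        train_losses = []
        for i in order:
            parts, grads = loss_and_grads(train_bags[i], int(labels[i]), params)
            opt.step(grads)
            train_losses.append(parts.total)
        val_loss = _mean_loss(val_bags, val_labels, params)
        rows.append((epoch, float(np.mean(train_losses)), val_loss))
        if val_loss < best_val:
            best_val = val_loss
            best = params.copy()
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
        if epoch >= train_config.min_epochs and since_best >= train_config.patience:
            break
    history = pd.DataFrame(rows, columns=["epoch", "train_loss", "val_loss"])
    return FoldResult(params=best, history=history, best_epoch=best_epoch, best_val_loss=best_val)


def predict_probs(params: MILParams, bags) -> np.ndarray:
    return np.stack([forward(b, params).probs for b in bags])


@dataclass
class EvalReport:
    auroc: float
    per_class_auroc: dict
    probs: np.ndarray
    labels: np.ndarray
    pr_curves: dict = field(default_factory=dict)


def evaluate(params: MILParams, bags, labels, average: str = "macro") -> EvalReport:
    """AUROC / PR evaluation of a checkpoint on a labeled bag set.

    Binary partitions use the class-1 probability; 3-class partitions report
    one-vs-rest AUROC aggregated by ``average`` (macro default).
    """
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("evaluation requires at least 2 classes present")
    probs = predict_probs(params, bags)
    n_classes = probs.shape[1]
    per_class, pr = {}, {}
    for k in range(n_classes):
        mask = y == k
        if 0 < mask.sum() < y.size:
            per_class[k] = float(roc_auc_score(mask.astype(int), probs[:, k]))
            pr[k] = precision_recall_curve(mask.astype(int), probs[:, k])
    if n_classes == 2:
        auroc = float(roc_auc_score(y, probs[:, 1]))
    else:
        auroc = float(
            roc_auc_score(y, probs, multi_class="ovr", average=average, labels=np.arange(n_classes))
        )
    return EvalReport(auroc=auroc, per_class_auroc=per_class, probs=probs, labels=y, pr_curves=pr)


@dataclass
class ExperimentResult:
    fold_table: pd.DataFrame  # model_id, fold, auroc, best_epoch, seed
    summary: pd.DataFrame  # model_id, median_auroc, sd_auroc (Table-3 style)
    checkpoints: dict  # (model_id, fold) -> MILParams


def run_experiment(manifest: pd.DataFrame, bags: dict, model_ids,
                   model_config: MILConfig, train_config: TrainConfig,
                   plan: SplitPlan | None = None, average: str = "macro") -> ExperimentResult:
    """Cross-validated training and hold-out evaluation of a set of partitions.

    For every requested model the partition subset is drawn, patient-level
    splits are made on it, each fold is trained to early stopping, and the
    fold checkpoint is scored on the shared hold-out set. Deterministic given
    the plan/train seeds.
    """
    plan = plan or SplitPlan(seed=train_config.seed)
    rows, checkpoints = [], {}
    for model_id in model_ids:
        subset, spec = build_partition(model_id, manifest)
        if subset.empty:
            raise ValueError(f"partition {model_id} selects no slides")
        splits = make_splits(subset, plan)
        label_of = dict(zip(subset["slide_id"], subset["label"]))
        cfg = replace(model_config, n_classes=spec.n_classes)

        def pack(slide_ids):
            return (
                [bags[s].features for s in slide_ids],
                [spec.class_index(label_of[s]) for s in slide_ids],
            )

        hold_bags, hold_labels = pack(splits.holdout)
        for fold, (train_ids, val_ids) in enumerate(splits.folds):
            tb, tl = pack(train_ids)
            vb, vl = pack(val_ids)
            fold_seed = int(np.random.default_rng((train_config.seed, fold)).integers(2**31))
            result = train_fold(tb, tl, vb, vl, cfg, replace(train_config, seed=fold_seed))
            report = evaluate(result.params, hold_bags, hold_labels, average=average)
            ext_auroc = np.nan
            if splits.external:
                eb, el = pack(splits.external)
                if len(set(el)) >= 2:
                    ext_auroc = evaluate(result.params, eb, el, average=average).auroc
            rows.append((model_id, fold, report.auroc, ext_auroc, result.best_epoch, fold_seed))
            checkpoints[(model_id, fold)] = result.params
    fold_table = pd.DataFrame(
        rows, columns=["model_id", "fold", "auroc", "external_auroc", "best_epoch", "seed"]
    )
    summary = (
        fold_table.groupby("model_id")["auroc"]
        .agg(median_auroc="median", sd_auroc="std")
        .reset_index()
    )
    return ExperimentResult(fold_table=fold_table, summary=summary, checkpoints=checkpoints)
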