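"""Training harness: AdamW, early stopping on validation accuracy,
best-checkpoint restoration, multi-seed aggregation.

Defaults follow the fixed protocol: batch size 8, initial learning rate
5e-4, weight decay 1e-5, at most 50 epochs, patience 10, five seeds, AdamW
with cross-entropy loss and no learning-rate schedule.  "Improvement" means
strictly greater validation accuracy; the restored checkpoint is the
earliest epoch attaining the maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .dataset import SplitResult
from .evaluate import EvalReport, evaluate_predictions
from .net.layers import cross_entropy
from .net.model import Model, compile_network
from .net.optim import AdamW
from .net.spec import NetworkSpec

__all__ = ["TrainConfig", "RunHistory", "SummaryReport", "fit_loop", "train_once", "run_multiseed"]


@dataclass
class TrainConfig:
    batch_size: int = 8
    learning_rate: float = 5e-4
    weight_decay: float = 1e-5
    max_epochs: int = 50
    patience: int = 10
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4)

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")
        if len(set(self.seeds)) != len(self.seeds):
            raise ValueError("seeds must be distinct")


@dataclass
class RunHistory:
    """Per-epoch record of one training run (epochs are 1-based)."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    best_epoch: int = 0
    stopped_early: bool = False
    seed: int | None = None

    @property
    def n_epochs(self) -> int:
        return len(self.val_accuracy)


def fit_loop(
    train_epoch: Callable[[int], float],
    evaluate: Callable[[], tuple[float, float]],
    snapshot: Callable[[], object],
    max_epochs: int,
    patience: int,
) -> tuple[object, RunHistory]:
    """Generic early-stopping loop.

    Runs ``train_epoch(epoch)`` then ``evaluate() -> (val_loss, val_acc)``
    per epoch; keeps the snapshot of the earliest epoch attaining the best
    validation accuracy, and stops once ``patience`` consecutive epochs pass
    without strict improvement.  Returns (best snapshot, history).
    """
    history = RunHistory()
    best_acc = -np.inf
    best_state: object = None
    since_improvement = 0
    for epoch in range(1, max_epochs + 1):
        tl = train_epoch(epoch)
        vl, va = evaluate()
        if not np.isfinite(tl) or not np.isfinite(vl):
            raise FloatingPointError(
                f"non-finite loss at epoch {epoch}: train={tl}, val={vl}"
            )
        history.train_loss.append(float(tl))
        history.val_loss.append(float(vl))
        history.val_accuracy.append(float(va))
        if va > best_acc:
            best_acc = va
            best_state = snapshot()
            history.best_epoch = epoch
            since_improvement = 0
        else:
            since_improvement += 1
        if since_improvement >= patience:
            history.stopped_early = True
            break
    return best_state, history


def _as_arrays(splits) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Accept a SplitResult or a (Xtr, ytr, Xva, yva) tuple of arrays."""
    if isinstance(splits, SplitResult):
        return (
            splits.train.reflectance,
            splits.train.labels,
            splits.val.reflectance,
            splits.val.labels,
        )
    Xtr, ytr, Xva, yva = splits
    return np.asarray(Xtr), np.asarray(ytr), np.asarray(Xva), np.asarray(yva)


def train_once(
    spec: NetworkSpec,
    splits,
    cfg: TrainConfig,
    seed: int = 0,
) -> tuple[Model, RunHistory]:
    """Train one network on one split with one seed; reproducible bit-for-bit.

    The seed drives weight initialisation, mini-batch shuffling, and dropout.
    Training halts when validation accuracy fails to improve for
    ``cfg.patience`` consecutive epochs (or at ``cfg.max_epochs``); the
    returned model carries the weights of the best-validation epoch.
    """
    Xtr, ytr, Xva, yva = _as_arrays(splits)
    if Xva.shape[0] == 0:
        raise ValueError("validation set is empty")
    if Xtr.shape[1] != spec.n_bands:
        raise ValueError(f"data has {Xtr.shape[1]} bands but spec expects {spec.n_bands}")
    xtr = Xtr[:, None, :]  # (n, 1, L)
    xva = Xva[:, None, :]

    rng = np.random.default_rng(seed)
    model = compile_network(spec, rng)
    opt = AdamW(model, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    n = xtr.shape[0]

    def train_epoch(epoch: int) -> float:
        order = rng.permutation(n)
        total, batches = 0.0, 0
        for i in range(0, n, cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            opt.zero_grad()
            total += model.loss_and_grad(xtr[idx], ytr[idx])
            opt.step()
            batches += 1
        return total / batches

    def evaluate() -> tuple[float, float]:
        logits = model.forward(xva, train=False)
        loss, _ = cross_entropy(logits, yva)
        acc = float((logits.argmax(axis=1) == yva).mean())
        return loss, acc

    best_state, history = fit_loop(
        train_epoch, evaluate, model.state_dict, cfg.max_epochs, cfg.patience
    )
    history.seed = seed
    if best_state is not None:
        model.load_state_dict(best_state)
    return model, history


@dataclass
class SummaryReport:
    """Mean +/- sample-std aggregation of per-seed evaluation reports."""

    seeds: list[int]
    val_reports: list[EvalReport]
    test_reports: list[EvalReport]
    histories: list[RunHistory]

    def aggregate(self, which: str = "test") -> dict[str, tuple[float, float]]:
        reports = self.test_reports if which == "test" else self.val_reports
        out = {}
        for metric in ("accuracy", "macro_precision", "macro_recall", "macro_f1"):
            vals = np.array([getattr(r, metric) for r in reports])
            std = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
            out[metric] = (float(vals.mean()), std)
        return out

    def to_dict(self) -> dict:
        return {
            "seeds": list(self.seeds),
            "val": {k: {"mean": m, "std": s} for k, (m, s) in self.aggregate("val").items()},
            "test": {k: {"mean": m, "std": s} for k, (m, s) in self.aggregate("test").items()},
            "per_seed_test_accuracy": [r.accuracy for r in self.test_reports],
            "best_epochs": [h.best_epoch for h in self.histories],
        }


def run_multiseed(
    spec_builder: Callable[[], NetworkSpec] | NetworkSpec,
    splits: SplitResult,
    cfg: TrainConfig,
) -> SummaryReport:
    """One train/evaluate cycle per configured seed, aggregated mean +/- std."""
    K = splits.train.n_classes
    val_reports, test_reports, histories = [], [], []
    for seed in cfg.seeds:
        spec = spec_builder() if callable(spec_builder) else spec_builder
        model, history = train_once(spec, splits, cfg, seed=seed)
        histories.append(history)
        for part, sink in ((splits.val, val_reports), (splits.test, test_reports)):
            y_pred = model.predict(part.reflectance[:, None, :])
            sink.append(evaluate_predictions(part.labels, y_pred, K))
    return SummaryReport(list(cfg.seeds), val_reports, test_reports, histories)
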