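"""Classification evaluation: confusion matrices, accuracy, macro P/R/F1,
and the model x dataset benchmark/ablation grids.

Per-class precision, recall and F1 follow the usual one-vs-rest counts
(TP, FP, FN read off the confusion matrix); summary values are macro
(unweighted) averages over classes, with per-class values always retained.
Degenerate denominators yield 0 with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import SpectralDataset, stratified_split
from .dimreduce import nonlinear_embed, pca_fit, pca_transform
from .net.spec import NetworkSpec

__all__ = [
    "EvalReport",
    "confusion_matrix",
    "metrics_from_cm",
    "evaluate_predictions",
    "make_classical_model",
    "specs_differ_only_in_eca",
    "benchmark_grid",
    "CLASSICAL_MODELS",
]


def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int) -> np.ndarray:
    """K x K count matrix; rows are true classes, columns predictions."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    for name, y in (("y_true", y_true), ("y_pred", y_pred)):
        if y.size and (y.min() < 0 or y.max() >= n_classes):
            raise ValueError(f"{name} contains labels outside [0, {n_classes})")
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


@dataclass
class EvalReport:
    """Accuracy plus per-class and macro precision/recall/F1."""

    accuracy: float
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float
    cm: np.ndarray

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "precision": self.precision.tolist(),
            "recall": self.recall.tolist(),
            "f1": self.f1.tolist(),
            "confusion_matrix": self.cm.tolist(),
        }


def metrics_from_cm(cm: np.ndarray) -> EvalReport:
    """Accuracy and per-class/macro P, R, F1 from a confusion matrix.

    accuracy = trace / total; per class i, P_i = TP_i/(TP_i+FP_i),
    R_i = TP_i/(TP_i+FN_i), F1_i = 2 P_i R_i / (P_i + R_i); macro values are
    unweighted class means.  A class with a zero denominator scores 0.
    """
    cm = np.asarray(cm)
    total = cm.sum()
    if total <= 0:
        raise ValueError("confusion matrix is empty")
    K = cm.shape[0]
    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp

    precision = np.zeros(K)
    recall = np.zeros(K)
    f1 = np.zeros(K)
    for i in range(K):
        if tp[i] + fp[i] > 0:
            precision[i] = tp[i] / (tp[i] + fp[i])
        else:
            warnings.warn(f"class {i}: no predicted samples; precision set to 0")
        if tp[i] + fn[i] > 0:
            recall[i] = tp[i] / (tp[i] + fn[i])
        else:
            warnings.warn(f"class {i}: no true samples; recall set to 0")
        if precision[i] + recall[i] > 0:
            f1[i] = 2 * precision[i] * recall[i] / (precision[i] + recall[i])

    return EvalReport(
        accuracy=float(tp.sum() / total),
        precision=precision,
        recall=recall,
        f1=f1,
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
        cm=cm,
    )


def evaluate_predictions(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int) -> EvalReport:
    return metrics_from_cm(confusion_matrix(y_true, y_pred, n_classes))


# ----------------------------------------------------------------------
# Classical baselines (delegated implementations, fixed hyperparameters)
# ----------------------------------------------------------------------

CLASSICAL_MODELS = ("lda", "rf", "knn", "svm")


def make_classical_model(name: str, seed: int = 0):
    """Classical baseline with fixed, documented hyperparameters.

    KNN (5 neighbours) and SVM (RBF kernel, C=1) get train-fitted
    standardisation; RF uses 100 trees; LDA runs without shrinkage.
    """
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    name = name.lower()
    if name == "lda":
        return LinearDiscriminantAnalysis()
    if name == "rf":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if name == "knn":
        return make_pipeline(StandardScaler(), KNeighborsClassifier(n_neighbors=5))
    if name == "svm":
        return make_pipeline(StandardScaler(), SVC(kernel="rbf", C=1.0, random_state=seed))
    raise ValueError(f"unknown classical model {name!r}; choose from {CLASSICAL_MODELS}")


# ----------------------------------------------------------------------
# Structural ablation check
# ----------------------------------------------------------------------

def specs_differ_only_in_eca(a: NetworkSpec, b: NetworkSpec) -> bool:
    """True when two specs are identical apart from attention flags
    (and the architecture label)."""
    da, db = a.to_dict(), b.to_dict()
    da.pop("architecture")
    db.pop("architecture")
    for d in (da, db):
        for blk in d["blocks"]:
            blk.pop("eca")
            blk.pop("eca_kernel")
    return da == db


# ----------------------------------------------------------------------
# Benchmark grid
# ----------------------------------------------------------------------

@dataclass
class GridCell:
    model: str
    dataset: str
    reports: list[EvalReport] = field(default_factory=list)
    error: str | None = None

    def aggregate(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for metric in ("accuracy", "macro_precision", "macro_recall", "macro_f1"):
            vals = np.array([getattr(r, metric) for r in self.reports])
            out[f"{metric}_mean"] = float(vals.mean()) if vals.size else float("nan")
            out[f"{metric}_std"] = (
                float(vals.std(ddof=1)) if vals.size > 1 else 0.0 if vals.size else float("nan")
            )
        return out


def _featurize(split, features: str, n_components: int, seed: int):
    """Map a SplitResult onto (train, val, test) feature matrices, fitting
    any reducer on the training partition only."""
    Xtr, Xva, Xte = (s.reflectance for s in (split.train, split.val, split.test))
    if features == "full":
        return Xtr, Xva, Xte
    if features == "pca":
        model = pca_fit(Xtr, n_components=n_components)
        return tuple(pca_transform(model, X) for X in (Xtr, Xva, Xte))
    if features == "umap":
        rest = np.vstack([Xva, Xte])
        emb_tr, emb_rest = nonlinear_embed(Xtr, rest, n_components=n_components, seed=seed)
        n_va = Xva.shape[0]
        return emb_tr, emb_rest[:n_va], emb_rest[n_va:]
    raise ValueError(f"unknown feature mode {features!r}")


def benchmark_grid(
    models: Mapping[str, object],
    datasets: Mapping[str, SpectralDataset],
    cfg,
    features: str = "full",
    n_components: int = 20,
    ratios: Sequence[float] = (0.6, 0.2, 0.2),
    preprocess: Sequence | None = None,
) -> pd.DataFrame:
    """One mean +/- std evaluation per (model, dataset) cell.

    ``models`` maps display names to either a classical model name (str in
    ``CLASSICAL_MODELS``) or a callable ``(n_bands, n_classes) -> NetworkSpec``.
    Each seed in ``cfg.seeds`` re-splits the dataset, refits preprocessing and
    any reducer on train, trains/fits the model, and evaluates the test
    partition.  Cell failures are recorded, not raised.
    """
    from .preprocess import PreprocessPipeline
    from .train import train_once

    cells: list[GridCell] = []
    for ds_name, ds in datasets.items():
        for model_name, model_like in models.items():
            cell = GridCell(model=model_name, dataset=ds_name)
            try:
                for seed in cfg.seeds:
                    split = stratified_split(ds, ratios=ratios, seed=seed)
                    Xtr, Xva, Xte = (s.reflectance for s in (split.train, split.val, split.test))
                    if preprocess:
                        pipe = PreprocessPipeline(list(preprocess)).fit(Xtr)
                        Xtr, Xva, Xte = pipe.apply(Xtr), pipe.apply(Xva), pipe.apply(Xte)
                    if features != "full":
                        tmp_split = _ReflectanceView(split, Xtr, Xva, Xte)
                        Xtr, Xva, Xte = _featurize(tmp_split, features, n_components, seed)
                    ytr, yva, yte = split.train.labels, split.val.labels, split.test.labels
                    K = ds.n_classes
                    if isinstance(model_like, str):
                        clf = make_classical_model(model_like, seed=seed)
                        clf.fit(Xtr, ytr)
                        y_pred = clf.predict(Xte)
                    else:
                        spec = model_like(Xtr.shape[1], K)
                        model, _ = train_once(
                            spec, (Xtr, ytr, Xva, yva), cfg, seed=seed
                        )
                        y_pred = model.predict(Xte[:, None, :])
                    cell.reports.append(evaluate_predictions(yte, y_pred, K))
            except Exception as exc:  # keep the grid running
                cell.error = f"{type(exc).__name__}: {exc}"
            cells.append(cell)

    rows = []
    for cell in cells:
        row = {"model": cell.model, "dataset": cell.dataset, "error": cell.error}
        row.update(cell.aggregate())
        rows.append(row)
    return pd.DataFrame(rows)


class _ReflectanceView:
    """Minimal stand-in exposing .train/.val/.test with replaced matrices."""

    def __init__(self, split, Xtr, Xva, Xte):
        self.train = _XView(Xtr)
        self.val = _XView(Xva)
        self.test = _XView(Xte)


class _XView:
    def __init__(self, X):
        self.reflectance = X
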