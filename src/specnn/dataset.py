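"""Labelled spectral datasets: loading, validation, trimming, summarising, splitting.

A dataset is a matrix of reflectance spectra (samples x bands) on a strictly
increasing wavelength grid, with an integer class label per sample.  On-disk
format is a delimited text table whose header carries the wavelengths in nm
plus a label column and optional ``sample_id`` / ``fruit_id`` columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpectralDataset",
    "SplitResult",
    "load_spectra",
    "save_spectra",
    "trim_bands",
    "stratified_split",
    "class_mean_spectra",
]

_RESERVED_COLUMNS = ("sample_id", "fruit_id")


@dataclass
class SpectralDataset:
    """A labelled matrix of reflectance spectra on a common wavelength grid.

    Parameters
    ----------
    reflectance : ndarray, shape (n_samples, n_bands)
        Unitless reflectance values; must be finite.
    wavelengths : ndarray, shape (n_bands,)
        Strictly increasing band centres in nm.
    labels : ndarray of int, shape (n_samples,)
        Class ids in ``{0..K-1}``.
    class_names : list of str
        Display name per class id, in first-appearance order.
    sample_ids : list of str
        Unique per-sample identifiers.
    fruit_ids : list of str, optional
        Per-sample group tags (several spectra may share one fruit).
    """

    reflectance: np.ndarray
    wavelengths: np.ndarray
    labels: np.ndarray
    class_names: list[str]
    sample_ids: list[str]
    fruit_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        n, b = self.reflectance.shape
        if self.wavelengths.shape != (b,):
            raise ValueError(
                f"wavelength grid length {self.wavelengths.shape} does not match "
                f"{b} reflectance columns"
            )
        if len(self.labels) != n or len(self.sample_ids) != n:
            raise ValueError("labels/sample_ids length does not match sample count")
        if self.fruit_ids is not None and len(self.fruit_ids) != n:
            raise ValueError("fruit_ids length does not match sample count")
        if not np.all(np.isfinite(self.reflectance)):
            bad = np.argwhere(~np.isfinite(self.reflectance))[0]
            raise ValueError(
                f"non-finite reflectance at sample {bad[0]}, band {bad[1]}"
            )
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths not increasing")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids are not unique")
        if n and (self.labels.min() < 0 or self.labels.max() >= self.n_classes):
            raise ValueError("label out of range for class_names")

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_bands(self) -> int:
        return self.reflectance.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def subset(self, idx: np.ndarray) -> "SpectralDataset":
        """Row subset by integer index, preserving class table and grid."""
        idx = np.asarray(idx, dtype=int)
        return SpectralDataset(
            reflectance=self.reflectance[idx],
            wavelengths=self.wavelengths,
            labels=self.labels[idx],
            class_names=list(self.class_names),
            sample_ids=[self.sample_ids[i] for i in idx],
            fruit_ids=None if self.fruit_ids is None else [self.fruit_ids[i] for i in idx],
        )

    def with_reflectance(self, X: np.ndarray) -> "SpectralDataset":
        """Same metadata with a replaced (shape-identical) spectra matrix."""
        X = np.asarray(X, dtype=float)
        if X.shape != self.reflectance.shape:
            raise ValueError("replacement matrix must preserve shape")
        return SpectralDataset(
            reflectance=X,
            wavelengths=self.wavelengths,
            labels=self.labels,
            class_names=list(self.class_names),
            sample_ids=list(self.sample_ids),
            fruit_ids=None if self.fruit_ids is None else list(self.fruit_ids),
        )


@dataclass
class SplitResult:
    """Train/validation/test partition of a :class:`SpectralDataset`."""

    train: SpectralDataset
    val: SpectralDataset
    test: SpectralDataset
    ratios: tuple[float, float, float]
    seed: int

    def manifests(self) -> dict[str, list[str]]:
        return {
            "train": list(self.train.sample_ids),
            "val": list(self.val.sample_ids),
            "test": list(self.test.sample_ids),
        }


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------

def load_spectra(path: str | Path, label_column: str = "label", sep: str = ",") -> SpectralDataset:
    """Read a delimited spectra table into a validated :class:`SpectralDataset`.

    The header row must contain the label column, optional ``sample_id`` /
    ``fruit_id`` columns, and one numeric wavelength (nm) per spectral band.
    Class names are assigned ids in order of first appearance.
    """
    df = pd.read_csv(path, sep=sep)
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not found in {path}")
    meta_cols = {label_column}
    sample_ids: list[str]
    if "sample_id" in df.columns:
        meta_cols.add("sample_id")
        sample_ids = [str(s) for s in df["sample_id"]]
    else:
        sample_ids = [f"s{i:06d}" for i in range(len(df))]
    fruit_ids = None
    if "fruit_id" in df.columns:
        meta_cols.add("fruit_id")
        fruit_ids = [str(s) for s in df["fruit_id"]]

    band_cols = [c for c in df.columns if c not in meta_cols]
    try:
        wavelengths = np.array([float(c) for c in band_cols])
    except ValueError as exc:
        raise ValueError(f"non-numeric wavelength header: {exc}") from None
    if np.any(np.diff(wavelengths) <= 0):
        raise ValueError("wavelengths not increasing")

    X = df[band_cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        bad = np.argwhere(~np.isfinite(X))[0]
        raise ValueError(f"non-finite reflectance at row {bad[0]}, band {band_cols[bad[1]]}")

    raw_labels = [str(v) for v in df[label_column]]
    class_names: list[str] = []
    ids = {}
    for v in raw_labels:
        if v not in ids:
            ids[v] = len(class_names)
            class_names.append(v)
    labels = np.array([ids[v] for v in raw_labels], dtype=int)

    return SpectralDataset(X, wavelengths, labels, class_names, sample_ids, fruit_ids)


def save_spectra(ds: SpectralDataset, path: str | Path, sep: str = ",") -> None:
    """Write a dataset back to the delimited text format read by :func:`load_spectra`."""
    cols: dict[str, object] = {"sample_id": ds.sample_ids}
    if ds.fruit_ids is not None:
        cols["fruit_id"] = ds.fruit_ids
    cols["label"] = [ds.class_names[k] for k in ds.labels]
    df = pd.DataFrame(cols)
    spec = pd.DataFrame(ds.reflectance, columns=[format(w, "g") for w in ds.wavelengths])
    pd.concat([df, spec], axis=1).to_csv(path, sep=sep, index=False)


# ----------------------------------------------------------------------
# Operations
# ----------------------------------------------------------------------

def trim_bands(ds: SpectralDataset, lo: float, hi: float) -> SpectralDataset:
    """Keep exactly the bands with wavelength in the closed interval [lo, hi] nm."""
    if lo >= hi:
        raise ValueError(f"invalid trim interval: lo={lo} >= hi={hi}")
    keep = (ds.wavelengths >= lo) & (ds.wavelengths <= hi)
    if not keep.any():
        raise ValueError(f"no bands remain in [{lo}, {hi}] nm")
    return SpectralDataset(
        reflectance=ds.reflectance[:, keep],
        wavelengths=ds.wavelengths[keep],
        labels=ds.labels,
        class_names=list(ds.class_names),
        sample_ids=list(ds.sample_ids),
        fruit_ids=None if ds.fruit_ids is None else list(ds.fruit_ids),
    )


def _allocate_counts(n: int, ratios: Sequence[float]) -> list[int]:
    """Largest-remainder allocation of n items over ratios; leftovers go to
    the earliest partition (train first)."""
    ideal = [n * r for r in ratios]
    counts = [int(np.floor(v)) for v in ideal]
    short = n - sum(counts)
    remainders = [(v - c, -i) for i, (v, c) in enumerate(zip(ideal, counts))]
    order = sorted(range(len(ratios)), key=lambda i: remainders[i], reverse=True)
    for i in order[:short]:
        counts[i] += 1
    return counts


def stratified_split(
    ds: SpectralDataset,
    ratios: Sequence[float] = (0.6, 0.2, 0.2),
    seed: int = 0,
    allow_empty: bool = False,
) -> SplitResult:
    """Stratified train/val/test split at the spectral (per-sample) level.

    Per-class counts follow largest-remainder rounding of ``n_class * ratios``
    so every partition matches the target proportions to within one sample per
    class.  The same seed always yields the same partition.

    Set ``allow_empty=True`` to permit degenerate ratios such as (1, 0, 0).
    """
    ratios = tuple(float(r) for r in ratios)
    if len(ratios) != 3 or any(r < 0 for r in ratios):
        raise ValueError("ratios must be three non-negative fractions")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1 (got {sum(ratios)})")
    if not allow_empty and min(ratios) <= 0:
        raise ValueError("zero ratio produces an empty partition; pass allow_empty=True")

    rng = np.random.default_rng(seed)
    parts: list[list[int]] = [[], [], []]
    for k in range(ds.n_classes):
        idx = np.flatnonzero(ds.labels == k)
        if not allow_empty and len(idx) < 3:
            raise ValueError(
                f"class {ds.class_names[k]!r} has only {len(idx)} samples; need >= 3"
            )
        rng.shuffle(idx)
        counts = _allocate_counts(len(idx), ratios)
        start = 0
        for p, c in enumerate(counts):
            parts[p].extend(idx[start : start + c].tolist())
            start += c
    train, val, test = (ds.subset(np.sort(np.array(p, dtype=int))) for p in parts)
    return SplitResult(train=train, val=val, test=test, ratios=ratios, seed=seed)


def grouped_split(
    ds: SpectralDataset,
    ratios: Sequence[float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> SplitResult:
    """Fruit-level split: all spectra sharing a ``fruit_id`` stay together.

    Groups are allocated per class by largest remainder on group counts, so
    class balance holds at the group level (sample-level balance is only
    approximate when group sizes vary).
    """
    if ds.fruit_ids is None:
        raise ValueError("grouped_split requires fruit_ids")
    ratios = tuple(float(r) for r in ratios)
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1 (got {sum(ratios)})")
    rng = np.random.default_rng(seed)
    parts: list[list[int]] = [[], [], []]
    for k in range(ds.n_classes):
        groups: dict[str, list[int]] = {}
        for i in np.flatnonzero(ds.labels == k):
            groups.setdefault(ds.fruit_ids[i], []).append(int(i))
        names = sorted(groups)
        order = rng.permutation(len(names))
        counts = _allocate_counts(len(names), ratios)
        start = 0
        for p, c in enumerate(counts):
            for j in order[start : start + c]:
                parts[p].extend(groups[names[j]])
            start += c
    train, val, test = (ds.subset(np.sort(np.array(p, dtype=int))) for p in parts)
    return SplitResult(train=train, val=val, test=test, ratios=ratios, seed=seed)


def class_mean_spectra(ds: SpectralDataset) -> np.ndarray:
    """Arithmetic mean spectrum per class; shape (K, n_bands)."""
    out = np.empty((ds.n_classes, ds.n_bands))
    for k in range(ds.n_classes):
        idx = ds.labels == k
        if not idx.any():
            raise ValueError(f"class {ds.class_names[k]!r} is empty")
        out[k] = ds.reflectance[idx].mean(axis=0)
    return out
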