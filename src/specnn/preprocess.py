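"""Spectral pretreatments: Savitzky-Golay smoothing, SNV, MSC.

All transforms operate on a spectra matrix of shape (n_samples, n_bands) and
preserve its shape.  MSC carries fitted state (the reference spectrum, the
column mean of the training partition); SG and SNV are stateless.  The
:class:`PreprocessPipeline` composes steps with fit-on-train / apply-anywhere
semantics so validation and test statistics never leak into fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "sg_smooth",
    "snv",
    "msc_fit",
    "msc_apply",
    "PreprocessStep",
    "PreprocessPipeline",
    "parse_steps",
]


def sg_smooth(X: np.ndarray, window: int = 5, order: int = 3) -> np.ndarray:
    """Savitzky-Golay smoothing along the band axis.

    Each spectrum is replaced by the value at the window centre of a
    least-squares polynomial of degree ``order`` fitted over a sliding window
    of ``window`` points.  Edges are filled by evaluating the polynomial
    fitted to the nearest full window at the edge offsets.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if window % 2 == 0:
        raise ValueError(f"window must be odd (got {window})")
    if order >= window:
        raise ValueError(f"order ({order}) must be < window ({window})")
    if X.shape[1] < window:
        raise ValueError(f"need at least {window} bands, got {X.shape[1]}")
    return savgol_filter(X, window_length=window, polyorder=order, axis=1, mode="interp")


def snv(X: np.ndarray) -> np.ndarray:
    """Standard normal variate: centre and scale each spectrum to mean 0, sd 1.

    Uses the sample standard deviation (n-1 denominator).  A constant
    spectrum has zero sd and raises, identifying the offending row.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    zero = np.flatnonzero(sd.ravel() == 0)
    if zero.size:
        raise ValueError(f"constant spectrum at row {zero[0]}: SNV undefined")
    return (X - mu) / sd


def msc_fit(X_train: np.ndarray) -> np.ndarray:
    """Reference spectrum for MSC: the column mean of the training spectra."""
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    return X_train.mean(axis=0)


def msc_apply(X: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Multiplicative scatter correction against a fitted reference.

    Each spectrum x is regressed as ``x ~ a * ref + b`` by ordinary least
    squares and corrected to ``(x - b) / a``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    ref = np.asarray(reference, dtype=float)
    if ref.ndim != 1 or ref.shape[0] != X.shape[1]:
        raise ValueError("reference length does not match band count")
    rc = ref - ref.mean()
    denom = rc @ rc
    if denom == 0:
        raise ValueError("reference spectrum is constant; MSC undefined")
    xc = X - X.mean(axis=1, keepdims=True)
    a = (xc @ rc) / denom
    if np.any(np.abs(a) < 1e-12):
        bad = int(np.flatnonzero(np.abs(a) < 1e-12)[0])
        raise ValueError(f"fitted slope ~ 0 for row {bad}; cannot correct")
    b = X.mean(axis=1) - a * ref.mean()
    return (X - b[:, None]) / a[:, None]


# ----------------------------------------------------------------------
# Pipelines
# ----------------------------------------------------------------------

@dataclass
class PreprocessStep:
    """One named transform with parameters: kind in {'sg', 'snv', 'msc'}."""

    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("sg", "snv", "msc"):
            raise ValueError(f"unknown preprocessing step {self.kind!r}")
        if self.kind == "sg":
            w = int(self.params.get("window", 5))
            o = int(self.params.get("order", 3))
            if w % 2 == 0 or o >= w:
                raise ValueError(f"invalid SG parameters window={w}, order={o}")
            self.params = {"window": w, "order": o}


class PreprocessPipeline:
    """Ordered composition of preprocessing steps with fit/apply semantics.

    ``fit`` runs the pipeline over the training matrix, recording the MSC
    reference at the position where the ``msc`` step sits (so the reference
    reflects any preceding transforms).  ``apply`` replays the steps on any
    matrix using only fitted state.
    """

    def __init__(self, steps: Sequence[PreprocessStep | str]):
        self.steps = [s if isinstance(s, PreprocessStep) else PreprocessStep(s) for s in steps]
        self.msc_reference_: np.ndarray | None = None
        self._fitted = not any(s.kind == "msc" for s in self.steps)

    def fit(self, X_train: np.ndarray) -> "PreprocessPipeline":
        X = np.atleast_2d(np.asarray(X_train, dtype=float))
        for step in self.steps:
            if step.kind == "msc":
                self.msc_reference_ = msc_fit(X)
                X = msc_apply(X, self.msc_reference_)
            else:
                X = self._apply_stateless(step, X)
        self._fitted = True
        return self

    def apply(self, X: np.ndarray) -> np.ndarray:
        if not self._fitted:
            raise RuntimeError("pipeline contains MSC and must be fitted before apply")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        for step in self.steps:
            if step.kind == "msc":
                assert self.msc_reference_ is not None
                X = msc_apply(X, self.msc_reference_)
            else:
                X = self._apply_stateless(step, X)
        return X

    def fit_apply(self, X_train: np.ndarray) -> np.ndarray:
        self.fit(X_train)
        return self.apply(X_train)

    @staticmethod
    def _apply_stateless(step: PreprocessStep, X: np.ndarray) -> np.ndarray:
        if step.kind == "sg":
            return sg_smooth(X, **step.params)
        if step.kind == "snv":
            return snv(X)
        raise AssertionError(step.kind)

    def __repr__(self) -> str:  # pragma: no cover
        return f"PreprocessPipeline({[s.kind for s in self.steps]})"


def parse_steps(text: str) -> list[PreprocessStep]:
    """Parse a CLI step string like ``"sg:5:3,snv"`` into steps."""
    steps = []
    for token in text.split(","):
        token = token.strip()
        if not token:
            continue
        parts = token.split(":")
        kind = parts[0].lower()
        if kind == "sg":
            window = int(parts[1]) if len(parts) > 1 else 5
            order = int(parts[2]) if len(parts) > 2 else 3
            steps.append(PreprocessStep("sg", {"window": window, "order": order}))
        elif kind in ("snv", "msc"):
            if len(parts) > 1:
                raise ValueError(f"step {kind!r} takes no parameters: {token!r}")
            steps.append(PreprocessStep(kind))
        else:
            raise ValueError(f"unknown preprocessing step {kind!r}")
    if not steps:
        raise ValueError("no preprocessing steps given")
    return steps
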