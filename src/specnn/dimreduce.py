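"""Dimensionality reduction: in-house PCA (via SVD) and a manifold-embedding wrapper.

PCA is fitted on the training partition only; the same train mean and
loadings are reused to transform validation/test data.  The nonlinear
embedding delegates to umap-learn when available and exposes the same
fit-on-train, transform-out-of-sample contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PcaModel", "pca_fit", "pca_transform", "pca_inverse_transform", "nonlinear_embed"]


@dataclass
class PcaModel:
    """Fitted principal-component model.

    ``components`` rows are orthonormal loadings (n_components x n_bands),
    ordered by decreasing singular value with a fixed sign convention: the
    largest-magnitude loading of each component is positive.
    """

    mean: np.ndarray
    components: np.ndarray
    explained_variance_ratio: np.ndarray

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


def pca_fit(X_train: np.ndarray, n_components: int = 20) -> PcaModel:
    """Fit PCA by singular-value decomposition of the mean-centred matrix."""
    X = np.atleast_2d(np.asarray(X_train, dtype=float))
    n, p = X.shape
    max_rank = min(n - 1, p)
    if not 1 <= n_components <= max_rank:
        raise ValueError(
            f"n_components={n_components} out of range [1, {max_rank}] for shape {X.shape}"
        )
    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2  # proportional to explained variance
    ratios = var / var.sum()
    components = vt[:n_components]
    # sign convention: largest-|loading| entry of each component positive
    for i in range(n_components):
        j = np.argmax(np.abs(components[i]))
        if components[i, j] < 0:
            components[i] = -components[i]
    return PcaModel(mean=mean, components=components,
                    explained_variance_ratio=ratios[:n_components])


def pca_transform(model: PcaModel, X: np.ndarray) -> np.ndarray:
    """Project spectra onto the fitted components: (X - mean) @ components.T."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.mean.shape[0]:
        raise ValueError("band count does not match fitted model")
    return (X - model.mean) @ model.components.T


def pca_inverse_transform(model: PcaModel, scores: np.ndarray) -> np.ndarray:
    """Reconstruct spectra from scores (exact when all components are kept)."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    return scores @ model.components + model.mean


def nonlinear_embed(
    X_train: np.ndarray,
    X_other: np.ndarray | None = None,
    n_components: int = 3,
    seed: int = 0,
    **umap_kwargs,
) -> tuple[np.ndarray, np.ndarray | None]:
    """UMAP embedding fitted on train with out-of-sample transform.

    Returns ``(train_embedding, other_embedding)``; the second element is
    None when ``X_other`` is not given.  Deterministic under a fixed seed.
    Raises a clear error if umap-learn is not installed (this stage is
    optional for the rest of the pipeline).
    """
    try:
        import umap
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise RuntimeError(
            "umap-learn is not installed; the nonlinear embedding stage is "
            "optional — install the 'umap' extra or use PCA instead"
        ) from exc
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    reducer = umap.UMAP(n_components=n_components, random_state=seed, **umap_kwargs)
    emb_train = np.asarray(reducer.fit_transform(X_train), dtype=float)
    emb_other = None
    if X_other is not None:
        emb_other = np.asarray(reducer.transform(np.atleast_2d(X_other)), dtype=float)
    return emb_train, emb_other
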