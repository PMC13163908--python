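"""Synthetic three-class reflectance datasets.

Each class has a smooth mean-reflectance template (shared logistic baseline
plus Gaussian peaks/valleys), and samples are drawn under a multiplicative +
additive scatter model with white noise:

    x_i = a_i * template_k + b_i + eps_i

with ``a_i`` log-normal (median 1), ``b_i`` Gaussian and ``eps_i`` i.i.d.
Gaussian per band.  This is exactly the linear model that multiplicative
scatter correction inverts, which makes parameter-recovery tests possible.

Two wavelength presets are provided:

``visnir``
    381-1016 nm, 123 bands.  Templates share a reflectance peak near 600 nm
    and a red-edge valley near 700 nm; the three classes differ by smooth
    perturbations concentrated in the 400-670 nm region, so the classes are
    well separated at the default ``delta``.

``swir``
    959-1684 nm, 267 bands.  Templates share a reflection peak near 1100 nm
    and an absorption valley near 1450 nm.  Two of the three classes receive
    nearly identical perturbations, so this preset is deliberately harder to
    classify than ``visnir`` at the same ``delta``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import SpectralDataset

__all__ = ["SimSpec", "PRESETS", "preset_grid", "make_templates", "generate"]

#: (lo_nm, hi_nm, n_bands) per named preset
PRESETS: dict[str, tuple[float, float, int]] = {
    "visnir": (381.0, 1016.0, 123),
    "swir": (959.0, 1684.0, 267),
}

_CLASS_NAMES = ("origin_A", "origin_B", "origin_C")


def preset_grid(name: str) -> np.ndarray:
    """Wavelength grid (nm) for a named preset."""
    try:
        lo, hi, n = PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}") from None
    return np.linspace(lo, hi, n)


@dataclass
class SimSpec:
    """Parameters of the synthetic spectra generator.

    ``preset`` selects a wavelength grid (or pass ``wavelengths`` directly);
    ``delta`` scales the class-template differences, ``scatter_mult_sd`` /
    ``scatter_add_sd`` the per-sample scatter, ``noise_sd`` the white noise.
    """

    preset: str = "visnir"
    wavelengths: np.ndarray | None = None
    n_classes: int = 3
    delta: float = 0.08
    scatter_mult_sd: float = 0.05
    scatter_add_sd: float = 0.01
    noise_sd: float = 0.005
    n_per_class: int = 220
    spectra_per_fruit: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.wavelengths is None:
            self.wavelengths = preset_grid(self.preset)
        else:
            self.wavelengths = np.asarray(self.wavelengths, dtype=float)
            self.preset = "custom"
        for name in ("delta", "scatter_mult_sd", "scatter_add_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if self.spectra_per_fruit < 1:
            raise ValueError("spectra_per_fruit must be >= 1")


def _gauss(w: np.ndarray, centre: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((w - centre) / width) ** 2)


def _baseline(w: np.ndarray, preset: str) -> np.ndarray:
    # Constants are code fixtures chosen to place the shared peak/valley
    # landmarks inside the documented windows; clamped to (0.02, 0.98).
    if preset == "swir" or (preset == "custom" and w[0] > 900):
        base = (
            0.45
            + 0.30 * _gauss(w, 1100.0, 90.0)
            - 0.38 * _gauss(w, 1450.0, 70.0)
            + 0.05 * _gauss(w, 1650.0, 60.0)
        )
    else:
        base = (
            0.18
            + 0.42 / (1.0 + np.exp(-(w - 715.0) / 18.0))
            + 0.16 * _gauss(w, 600.0, 38.0)
            - 0.10 * _gauss(w, 700.0, 14.0)
        )
    return np.clip(base, 0.02, 0.98)


def _perturbations(spec: SimSpec) -> np.ndarray:
    """Smooth unit-scale class perturbation curves, shape (K, n_bands).

    For the ``swir`` preset the first two classes are nearly identical
    (their curves differ by a small fraction of a third direction), making
    them hard to separate; the ``visnir`` curves are mutually well spread.
    """
    w = spec.wavelengths
    if spec.preset == "swir":
        p_shared = _gauss(w, 1200.0, 55.0) - 0.8 * _gauss(w, 1500.0, 45.0)
        q = _gauss(w, 1620.0, 35.0) - _gauss(w, 1420.0, 30.0)
        p_far = -_gauss(w, 1150.0, 60.0) + _gauss(w, 1550.0, 50.0)
        curves = [p_shared, p_shared + 0.5 * q, p_far]
    else:
        curves = [
            _gauss(w, 600.0, 28.0) - 0.5 * _gauss(w, 460.0, 45.0),
            -_gauss(w, 640.0, 30.0) + 0.4 * _gauss(w, 540.0, 35.0),
            _gauss(w, 450.0, 50.0) - 0.7 * _gauss(w, 610.0, 40.0),
        ]
    base = [c / np.linalg.norm(c) * np.sqrt(len(w) / 123.0) for c in curves]
    if spec.n_classes <= len(base):
        return np.array(base[: spec.n_classes])
    # extra classes beyond 3: deterministic smooth bumps spread over the grid
    extra = []
    for k in range(len(base), spec.n_classes):
        c = _gauss(w, w[0] + (k + 0.5) * (w[-1] - w[0]) / (spec.n_classes + 1), 40.0)
        extra.append(c / np.linalg.norm(c) * np.sqrt(len(w) / 123.0))
    return np.array(base + extra)


def make_templates(spec: SimSpec) -> np.ndarray:
    """Class mean-reflectance templates, shape (K, n_bands), values in (0, 1).

    ``delta=0`` makes all templates identical; the between-class L2 distance
    grows linearly in ``delta``.
    """
    base = _baseline(spec.wavelengths, spec.preset)
    pert = _perturbations(spec)
    templates = base[None, :] + spec.delta * pert
    return np.clip(templates, 0.02, 0.98)


def generate(spec: SimSpec) -> SpectralDataset:
    """Draw a labelled synthetic dataset under the scatter + noise model."""
    if spec.n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(spec.seed)
    templates = make_templates(spec)
    K, n_bands = templates.shape
    n = K * spec.n_per_class

    X = np.empty((n, n_bands))
    labels = np.empty(n, dtype=int)
    sample_ids: list[str] = []
    fruit_ids: list[str] = []
    row = 0
    for k in range(K):
        a = np.exp(rng.normal(0.0, spec.scatter_mult_sd, size=spec.n_per_class))
        b = rng.normal(0.0, spec.scatter_add_sd, size=spec.n_per_class)
        eps = rng.normal(0.0, spec.noise_sd, size=(spec.n_per_class, n_bands))
        X[row : row + spec.n_per_class] = a[:, None] * templates[k] + b[:, None] + eps
        labels[row : row + spec.n_per_class] = k
        for j in range(spec.n_per_class):
            sample_ids.append(f"c{k}_s{j:05d}")
            fruit_ids.append(f"c{k}_f{j // spec.spectra_per_fruit:05d}")
        row += spec.n_per_class

    class_names = [
        _CLASS_NAMES[k] if k < len(_CLASS_NAMES) else f"origin_{k}" for k in range(K)
    ]
    return SpectralDataset(
        reflectance=X,
        wavelengths=spec.wavelengths,
        labels=labels,
        class_names=class_names,
        sample_ids=sample_ids,
        fruit_ids=fruit_ids,
    )
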