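"""Compile a :class:`NetworkSpec` into a runnable NumPy model."""

from __future__ import annotations

import copy

import numpy as np

from .layers import (
    ECA,
    BatchNorm1d,
    Conv1d,
    Dropout,
    Flatten,
    GlobalAvgPool1d,
    Layer,
    Linear,
    MaxPool1d,
    ReLU,
    ResidualBlock1d,
    cross_entropy,
    softmax,
)
from .spec import NetworkSpec

__all__ = ["Model", "compile_network"]


class Model:
    """A sequential stack of layers with explicit forward/backward passes."""

    def __init__(self, layers: list[Layer], spec: NetworkSpec | None = None):
        self.layers = layers
        self.spec = spec

    # -- execution -----------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def loss_and_grad(self, x: np.ndarray, y: np.ndarray) -> float:
        """One forward/backward pass; leaves gradients accumulated."""
        logits = self.forward(x, train=True)
        loss, dlogits = cross_entropy(logits, y)
        self.backward(dlogits)
        return loss

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Class probabilities in evaluation mode (running BN stats, no dropout)."""
        outs = []
        for i in range(0, x.shape[0], batch_size):
            outs.append(softmax(self.forward(x[i : i + batch_size], train=False)))
        return np.vstack(outs)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)

    # -- parameters ----------------------------------------------------
    def _flat_layers(self) -> list[tuple[str, Layer]]:
        out: list[tuple[str, Layer]] = []
        for i, layer in enumerate(self.layers):
            if isinstance(layer, ResidualBlock1d):
                for j, child in enumerate(layer.children()):
                    out.append((f"layer{i}.{j}", child))
            else:
                out.append((f"layer{i}", layer))
        return out

    def named_parameters(self):
        for name, layer in self._flat_layers():
            for key in layer.params:
                yield f"{name}.{key}", layer.params[key], layer.grads[key]

    @property
    def n_parameters(self) -> int:
        return sum(p.size for _, p, _ in self.named_parameters())

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    # -- state ---------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for name, layer in self._flat_layers():
            for key, val in layer.params.items():
                state[f"{name}.{key}"] = val.copy()
            if isinstance(layer, BatchNorm1d):
                state[f"{name}.running_mean"] = layer.running_mean.copy()
                state[f"{name}.running_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, layer in self._flat_layers():
            for key in layer.params:
                layer.params[key][...] = state[f"{name}.{key}"]
            if isinstance(layer, BatchNorm1d):
                layer.running_mean[...] = state[f"{name}.running_mean"]
                layer.running_var[...] = state[f"{name}.running_var"]

    def save_weights(self, path) -> None:
        np.savez(path, **self.state_dict())

    def load_weights(self, path) -> None:
        with np.load(path) as data:
            self.load_state_dict({k: data[k] for k in data.files})


def compile_network(spec: NetworkSpec, seed: int | np.random.Generator = 0) -> Model:
    """Instantiate a model from its declarative spec.

    All weight initialisation draws from a single generator keyed to
    ``seed``; dropout layers share that generator so a run seed pins every
    stochastic source.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    layers: list[Layer] = []
    in_channels = 1
    length = spec.n_bands
    for block in spec.blocks:
        pad = (block.kernel_size - 1) // 2
        if block.residual:
            layers.append(
                ResidualBlock1d(in_channels, block.out_channels, block.kernel_size,
                                eca_kernel=block.effective_eca_kernel(), rng=rng)
            )
        else:
            for _ in range(block.n_convs):
                layers.append(Conv1d(in_channels, block.out_channels,
                                     block.kernel_size, pad, rng))
                layers.append(BatchNorm1d(block.out_channels))
                layers.append(ReLU())
                in_channels = block.out_channels
            if block.eca:
                layers.append(ECA(block.out_channels, block.effective_eca_kernel(), rng))
        layers.append(MaxPool1d(block.pool_size))
        if block.dropout > 0:
            layers.append(Dropout(block.dropout, rng))
        in_channels = block.out_channels
        length //= block.pool_size

    if spec.head_pool == "gap":
        layers.append(GlobalAvgPool1d())
        features = in_channels
    else:
        layers.append(Flatten())
        features = in_channels * length
    if spec.head_hidden:
        layers.append(Linear(features, spec.head_hidden, rng))
        layers.append(ReLU())
        if spec.head_dropout > 0:
            layers.append(Dropout(spec.head_dropout, rng))
        features = spec.head_hidden
    layers.append(Linear(features, spec.n_classes, rng))
    return Model(layers, spec)
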