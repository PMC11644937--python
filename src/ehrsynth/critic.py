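"""Wasserstein critic: minibatch discrimination, spectrally-normalized denses.

The critic scores each transformed row with one unbounded scalar; by
convention higher scores mean "more likely synthetic". Minibatch
discrimination comes first so the critic can penalize low-diversity
(collapsed) batches; every dense layer is wrapped in spectral normalization
as the Lipschitz surrogate for Wasserstein training; the final dense has no
activation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (
    BatchNorm1d,
    Dropout,
    MinibatchDiscrimination,
    Module,
    SpectralNormDense,
    Tensor,
)
from .nn.layers import minibatch_features, spectral_normalize  # re-export surface

__all__ = [
    "CriticSpec",
    "TabularCritic",
    "build_critic",
    "minibatch_features",
    "spectral_normalize",
]


@dataclass(frozen=True)
class CriticSpec:
    """Architecture hyperparameters for the critic."""

    input_width: int
    dense_widths: tuple[int, ...] = (256, 128)
    n_kernels: int = 16
    kernel_dim: int = 8
    leaky_slope: float = 0.2
    dropout: float = 0.3
    power_iterations: int = 1
    batchnorm: bool = True

    def __post_init__(self) -> None:
        if self.input_width < 1 or any(w < 1 for w in self.dense_widths):
            raise ValueError("widths must be >= 1")
        if self.n_kernels < 1 or self.kernel_dim < 1:
            raise ValueError("minibatch kernel counts must be >= 1")

    def to_dict(self) -> dict:
        return {
            "input_width": self.input_width,
            "dense_widths": list(self.dense_widths),
            "n_kernels": self.n_kernels,
            "kernel_dim": self.kernel_dim,
            "leaky_slope": self.leaky_slope,
            "dropout": self.dropout,
            "power_iterations": self.power_iterations,
            "batchnorm": self.batchnorm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CriticSpec":
        return cls(
            input_width=d["input_width"],
            dense_widths=tuple(d["dense_widths"]),
            n_kernels=d["n_kernels"],
            kernel_dim=d["kernel_dim"],
            leaky_slope=d["leaky_slope"],
            dropout=d["dropout"],
            power_iterations=d["power_iterations"],
            batchnorm=d["batchnorm"],
        )


class TabularCritic(Module):
    def __init__(self, spec: CriticSpec, rng_seed: int = 0):
        super().__init__()
        self.spec = spec
        ss = np.random.SeedSequence(rng_seed)
        init_rng, dropout_rng = [np.random.default_rng(s) for s in ss.spawn(2)]
        self.minibatch = MinibatchDiscrimination(
            spec.input_width, spec.n_kernels, spec.kernel_dim, init_rng
        )
        d = spec.input_width + spec.n_kernels
        self.denses: list[SpectralNormDense] = []
        self.norms: list[BatchNorm1d | None] = []
        self.drops: list[Dropout] = []
        for w in spec.dense_widths:
            self.denses.append(
                SpectralNormDense(d, w, init_rng,
                                  train_steps=spec.power_iterations, eval_steps=5)
            )
            self.norms.append(BatchNorm1d(w) if spec.batchnorm else None)
            self.drops.append(Dropout(spec.dropout, dropout_rng))
            d = w
        self.head = SpectralNormDense(
            d, 1, init_rng, train_steps=spec.power_iterations, eval_steps=5
        )

    def __call__(self, batch: np.ndarray | Tensor) -> Tensor:
        x = batch if isinstance(batch, Tensor) else Tensor(batch)
        if x.data.ndim != 2 or x.data.shape[1] != self.spec.input_width:
            raise ValueError(
                f"batch width {x.data.shape[-1]} != critic input width "
                f"{self.spec.input_width}"
            )
        x = self.minibatch(x)
        for dense, norm, drop in zip(self.denses, self.norms, self.drops):
            x = dense(x).leaky_relu(self.spec.leaky_slope)
            if norm is not None:
                x = norm(x)
            x = drop(x)
        return self.head(x).reshape(x.data.shape[0])  # no final activation

    def spectral_norms(self) -> list[float]:
        """Largest singular value of each normalized weight (diagnostic)."""
        out = []
        for layer in [*self.denses, self.head]:
            W_hat = layer.normalized_weight().data
            out.append(float(np.linalg.svd(W_hat, compute_uv=False)[0]))
        return out


def build_critic(spec: CriticSpec, rng_seed: int = 0) -> TabularCritic:
    return TabularCritic(spec, rng_seed=rng_seed)
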