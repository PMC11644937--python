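"""Neural layers for the tabular GAN, built on the autograd engine.

Includes the two components that make the critic architecture distinctive:
minibatch discrimination (batch-similarity features that let the critic
detect low-diversity, mode-collapsed batches) and spectral normalization
(dividing each dense weight by a power-iteration estimate of its largest
singular value to bound the layer's Lipschitz constant).
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat, embedding_lookup, minibatch_similarity

__all__ = [
    "Module",
    "Dense",
    "BatchNorm1d",
    "Dropout",
    "Embedding",
    "MinibatchDiscrimination",
    "SpectralNormDense",
    "spectral_normalize",
    "minibatch_features",
]


class Module:
    """Base class: parameter collection, train/eval mode, zero_grad."""

    def __init__(self) -> None:
        self.training = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def submodules(self) -> list["Module"]:
        mods: list[Module] = []
        for value in self.__dict__.values():
            if isinstance(value, Module):
                mods.append(value)
                mods.extend(value.submodules())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        mods.append(item)
                        mods.extend(item.submodules())
        return mods

    def train(self) -> "Module":
        self.training = True
        for m in self.submodules():
            m.training = True
        return self

    def eval(self) -> "Module":
        self.training = False
        for m in self.submodules():
            m.training = False
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name -> array mapping of parameters and buffers, for archiving."""
        out: dict[str, np.ndarray] = {}

        def walk(mod: Module, prefix: str) -> None:
            for name, value in mod.__dict__.items():
                key = f"{prefix}{name}"
                if isinstance(value, Tensor):
                    out[key] = value.data
                elif isinstance(value, np.ndarray):
                    out[key] = value
                elif isinstance(value, Module):
                    walk(value, key + ".")
                elif isinstance(value, (list, tuple)):
                    for i, item in enumerate(value):
                        if isinstance(item, Module):
                            walk(item, f"{key}.{i}.")
                        elif isinstance(item, Tensor):
                            out[f"{key}.{i}"] = item.data
                        elif isinstance(item, np.ndarray):
                            out[f"{key}.{i}"] = item

        walk(self, "")
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        def walk(mod: Module, prefix: str) -> None:
            for name, value in mod.__dict__.items():
                key = f"{prefix}{name}"
                if isinstance(value, Tensor):
                    value.data = np.array(state[key])
                elif isinstance(value, np.ndarray):
                    setattr(mod, name, np.array(state[key]))
                elif isinstance(value, Module):
                    walk(value, key + ".")
                elif isinstance(value, (list, tuple)):
                    for i, item in enumerate(value):
                        if isinstance(item, Module):
                            walk(item, f"{key}.{i}.")
                        elif isinstance(item, Tensor):
                            item.data = np.array(state[f"{key}.{i}"])

        walk(self, "")


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class Dense(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        self.W = Tensor(glorot_uniform(rng, in_dim, out_dim), requires_grad=True)
        self.b = Tensor(np.zeros(out_dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class BatchNorm1d(Module):
    """Feature-wise batch normalization with running statistics for eval."""

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        if self.training and x.data.shape[0] > 1:
            mu = x.mean(axis=0, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=0, keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean
                + self.momentum * mu.data.ravel()
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var
                + self.momentum * var.data.ravel()
            )
            xhat = (x - mu) / (var + self.eps).sqrt()
        else:
            xhat = (x - Tensor(self.running_mean)) / Tensor(
                np.sqrt(self.running_var + self.eps)
            )
        return xhat * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0:
            return x
        keep = 1.0 - self.rate
        mask = self.rng.binomial(1, keep, size=x.data.shape) / keep
        return x * Tensor(mask)


class Embedding(Module):
    """Learned dense vectors for categorical indices."""

    def __init__(self, n_classes: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.W = Tensor(rng.normal(0, 0.1, size=(n_classes, dim)), requires_grad=True)

    def __call__(self, indices: np.ndarray) -> Tensor:
        return embedding_lookup(self.W, indices)


def minibatch_features(batch: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Reference (non-differentiable) minibatch-discrimination transform.

    Each row is projected through ``kernel`` (d, B, C) into B matrices of
    dimension C; the appended feature b is the summed exp(-L1) similarity of
    the row to every other row in the batch under projection b.
    """
    batch = np.asarray(batch, dtype=float)
    kernel = np.asarray(kernel, dtype=float)
    if batch.ndim != 2 or kernel.ndim != 3 or batch.shape[1] != kernel.shape[0]:
        raise ValueError("batch (n, d) and kernel (d, B, C) shapes do not match")
    n, d = batch.shape
    _, B, C = kernel.shape
    M = np.einsum("nd,dbc->nbc", batch, kernel)
    diff = np.abs(M[:, None] - M[None, :]).sum(axis=-1)  # (n, n, B)
    sims = np.exp(-diff).sum(axis=1) - 1.0
    return np.concatenate([batch, sims], axis=1)


class MinibatchDiscrimination(Module):
    """Appends learnable batch-similarity statistics to each row."""

    def __init__(self, in_dim: int, n_kernels: int, kernel_dim: int,
                 rng: np.random.Generator):
        super().__init__()
        if n_kernels < 1 or kernel_dim < 1:
            raise ValueError("n_kernels and kernel_dim must be >= 1")
        self.in_dim = in_dim
        self.n_kernels = n_kernels
        self.kernel_dim = kernel_dim
        self.T = Tensor(
            rng.normal(0, 0.1, size=(in_dim, n_kernels * kernel_dim)),
            requires_grad=True,
        )

    def __call__(self, x: Tensor) -> Tensor:
        n = x.data.shape[0]
        M = (x @ self.T).reshape(n, self.n_kernels, self.kernel_dim)
        sims = minibatch_similarity(M)
        return concat([x, sims], axis=1)


def spectral_normalize(
    W: np.ndarray, u: np.ndarray | None = None, steps: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Divide ``W`` by the power-iteration estimate of its largest singular value.

    ``u`` is the persistent left iterate (length = W.shape[0]); it is updated
    in place of the returned copy so repeated calls converge. Returns
    ``(W_hat, u)``.
    """
    W = np.asarray(W, dtype=float)
    if not np.any(W):
        raise ValueError("cannot spectrally normalize an all-zero matrix")
    if u is None:
        u = np.random.default_rng(0).normal(size=W.shape[0])
        u /= np.linalg.norm(u)
    v = None
    for _ in range(max(1, steps)):
        v = W.T @ u
        v /= max(np.linalg.norm(v), 1e-12)
        u = W @ v
        u /= max(np.linalg.norm(u), 1e-12)
    sigma = float(u @ W @ v)
    return W / sigma, u


class SpectralNormDense(Module):
    """Dense layer whose weight is spectrally normalized at every forward pass.

    One power iteration per training forward (the persistent ``u`` vector
    makes successive estimates converge); ``eval_steps`` iterations in eval
    mode for a tighter estimate. The normalization constant sigma = u' W v is
    built into the graph so gradients account for it.
    """

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 train_steps: int = 1, eval_steps: int = 5):
        super().__init__()
        self.W = Tensor(glorot_uniform(rng, in_dim, out_dim), requires_grad=True)
        self.b = Tensor(np.zeros(out_dim), requires_grad=True)
        u = rng.normal(size=in_dim)
        self.u = u / np.linalg.norm(u)
        self.train_steps = train_steps
        self.eval_steps = eval_steps

    def _power_iterate(self) -> tuple[np.ndarray, np.ndarray]:
        steps = self.train_steps if self.training else self.eval_steps
        W = self.W.data
        u = self.u
        for _ in range(steps):
            v = W.T @ u
            v /= max(np.linalg.norm(v), 1e-12)
            u = W @ v
            u /= max(np.linalg.norm(u), 1e-12)
        self.u = u
        return u, v

    def normalized_weight(self) -> Tensor:
        u, v = self._power_iterate()
        # sigma as a graph node: gradient flows through W in u' W v
        sigma = (Tensor(u.reshape(1, -1)) @ self.W @ Tensor(v.reshape(-1, 1))).reshape(())
        return self.W / sigma

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.normalized_weight() + self.b
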