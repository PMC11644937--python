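"""Conditional generator with separate continuous and categorical pathways.

Each continuous column has its own sub-network. The network is conditioned
by concatenation: a slice of the shared noise vector z, the one-hot of the
mixture mode sampled for that column, and the selected component's (mu_k,
sigma_k) standardized against the column's overall mixture mean/std. The
head is a tanh scaled by 0.99, so generated normalized values respect the
[-0.99, 0.99] clip range by construction.

Categorical columns share one trunk: the sampled class index of every
categorical column is embedded, the embeddings are concatenated with a noise
slice, pushed through dense/ReLU/batch-norm/dropout stages, and per-column
softmax heads emit probability blocks. The conditioned mode one-hots are
copied verbatim into the output layout (not re-predicted), which keeps the
inverse transformation well-defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (
    BatchNorm1d,
    Dense,
    Dropout,
    Embedding,
    Module,
    Tensor,
    concat,
)
from .schema import DataTable
from .transform import CLIP, TableTransformer

__all__ = [
    "GeneratorSpec",
    "ConditionVector",
    "ConditionSampler",
    "TabularGenerator",
    "sample_condition",
    "build_generator",
    "generate_table",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """Architecture hyperparameters for the generator."""

    z_dim: int = 128
    continuous_widths: tuple[int, ...] = (64, 64)
    categorical_widths: tuple[int, ...] = (64, 64)
    embedding_dim_max: int = 8
    leaky_slope: float = 0.2
    dropout: float = 0.2

    def __post_init__(self) -> None:
        if self.z_dim < 1:
            raise ValueError("z_dim must be >= 1")
        if not 0 < self.leaky_slope < 1:
            raise ValueError("leaky_slope must be in (0, 1)")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")

    def to_dict(self) -> dict:
        return {
            "z_dim": self.z_dim,
            "continuous_widths": list(self.continuous_widths),
            "categorical_widths": list(self.categorical_widths),
            "embedding_dim_max": self.embedding_dim_max,
            "leaky_slope": self.leaky_slope,
            "dropout": self.dropout,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorSpec":
        return cls(
            z_dim=d["z_dim"],
            continuous_widths=tuple(d["continuous_widths"]),
            categorical_widths=tuple(d["categorical_widths"]),
            embedding_dim_max=d["embedding_dim_max"],
            leaky_slope=d["leaky_slope"],
            dropout=d["dropout"],
        )


@dataclass
class ConditionVector:
    """Sampled GMM modes and category indices steering one generated batch.

    ``modes`` is (n, k) — one mixture-component index per continuous column;
    ``classes`` is (n, l) — one category index per categorical column.
    """

    modes: np.ndarray
    classes: np.ndarray

    @property
    def n(self) -> int:
        return int(self.modes.shape[0]) if self.modes.size else int(
            self.classes.shape[0]
        )


class ConditionSampler:
    """Draws condition vectors: modes from the fitted GMM weights, category
    indices from the empirical frequencies observed in the training table."""

    def __init__(
        self,
        transformer: TableTransformer,
        categorical_frequencies: dict[str, np.ndarray],
    ):
        self.transformer = transformer
        self.frequencies: dict[str, np.ndarray] = {}
        for spec in transformer.schema.categorical:
            freq = np.asarray(categorical_frequencies[spec.name], dtype=float)
            n_classes = transformer.categorical_meta[spec.name].n_classes
            if freq.size != n_classes:
                raise ValueError(
                    f"frequency length {freq.size} != vocabulary size "
                    f"{n_classes} for column {spec.name!r}"
                )
            if np.any(freq < 0) or not np.isclose(freq.sum(), 1.0, atol=1e-6):
                raise ValueError(f"frequencies for {spec.name!r} must be a simplex")
            self.frequencies[spec.name] = freq / freq.sum()

    @classmethod
    def from_table(
        cls, transformer: TableTransformer, table: DataTable
    ) -> "ConditionSampler":
        freqs = {}
        for spec in transformer.schema.categorical:
            meta = transformer.categorical_meta[spec.name]
            counts = np.zeros(meta.n_classes)
            for v in table.column(spec.name):
                counts[meta.index(v)] += 1
            freqs[spec.name] = (
                counts / counts.sum() if counts.sum() else
                np.full(meta.n_classes, 1.0 / meta.n_classes)
            )
        return cls(transformer, freqs)

    def sample(self, n: int, rng: np.random.Generator) -> ConditionVector:
        schema = self.transformer.schema
        modes = np.zeros((n, schema.k), dtype=int)
        for i, spec in enumerate(schema.continuous):
            w = self.transformer.continuous_meta[spec.name].weights
            modes[:, i] = rng.choice(w.size, size=n, p=w)
        classes = np.zeros((n, schema.l), dtype=int)
        for j, spec in enumerate(schema.categorical):
            f = self.frequencies[spec.name]
            classes[:, j] = rng.choice(f.size, size=n, p=f)
        return ConditionVector(modes=modes, classes=classes)


def sample_condition(
    transformer: TableTransformer,
    categorical_frequencies: dict[str, np.ndarray],
    n: int,
    rng_seed: int | np.random.Generator,
) -> ConditionVector:
    """Functional form of :meth:`ConditionSampler.sample`."""
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    return ConditionSampler(transformer, categorical_frequencies).sample(n, rng)


class _ContinuousSubnet(Module):
    def __init__(self, in_dim: int, spec: GeneratorSpec, rng, dropout_rng):
        super().__init__()
        self.spec = spec
        self.layers: list[Module] = []
        d = in_dim
        for w in spec.continuous_widths:
            self.layers.append(Dense(d, w, rng))
            self.layers.append(BatchNorm1d(w))
            self.layers.append(Dropout(spec.dropout, dropout_rng))
            d = w
        self.head = Dense(d, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
            if isinstance(layer, Dense):
                x = x.leaky_relu(self.spec.leaky_slope)
        return self.head(x).tanh() * CLIP


class _CategoricalPathway(Module):
    def __init__(self, n_classes_list: list[int], z_slice: int,
                 spec: GeneratorSpec, rng, dropout_rng):
        super().__init__()
        self.embeddings = [
            Embedding(nc, min(spec.embedding_dim_max, nc), rng)
            for nc in n_classes_list
        ]
        emb_total = sum(min(spec.embedding_dim_max, nc) for nc in n_classes_list)
        d = emb_total + z_slice
        w0, w1 = spec.categorical_widths
        self.fc1 = Dense(d, w0, rng)
        self.bn = BatchNorm1d(w0)
        self.drop = Dropout(spec.dropout, dropout_rng)
        self.fc2 = Dense(w0, w1, rng)
        self.heads = [Dense(w1, nc, rng) for nc in n_classes_list]

    def __call__(self, z_slice: Tensor, classes: np.ndarray) -> list[Tensor]:
        parts = [emb(classes[:, j]) for j, emb in enumerate(self.embeddings)]
        parts.append(z_slice)
        h = self.fc1(concat(parts, axis=1)).relu()
        h = self.drop(self.bn(h))
        h = self.fc2(h)
        return [head(h).softmax(axis=1) for head in self.heads]


class TabularGenerator(Module):
    """Dual-pathway conditional generator emitting transformed-layout rows."""

    def __init__(self, transformer: TableTransformer, spec: GeneratorSpec,
                 rng_seed: int = 0):
        super().__init__()
        if not transformer.fitted:
            raise ValueError("transformer must be fitted before building networks")
        self.transformer = transformer
        self.spec = spec
        schema = transformer.schema
        ss = np.random.SeedSequence(rng_seed)
        init_rng, self.dropout_rng = [
            np.random.default_rng(s) for s in ss.spawn(2)
        ]

        n_paths = schema.k + (1 if schema.l else 0)
        if n_paths == 0:
            raise ValueError("schema has no columns")
        base = max(1, spec.z_dim // n_paths)
        bounds = [min(i * base, spec.z_dim - 1) for i in range(n_paths)] + [spec.z_dim]
        self._z_slices = [(bounds[i], max(bounds[i + 1], bounds[i] + 1))
                          for i in range(n_paths)]

        # per-component (mu, sigma) conditioning is standardized against the
        # column's overall mixture mean/std, derived from the metadata alone
        self._cond_stats: list[tuple[float, float]] = []
        self.continuous_nets: list[_ContinuousSubnet] = []
        for i, cspec in enumerate(schema.continuous):
            meta = transformer.continuous_meta[cspec.name]
            gmean = float(np.dot(meta.weights, meta.means))
            gvar = float(
                np.dot(meta.weights, meta.stds**2 + meta.means**2) - gmean**2
            )
            gstd = max(np.sqrt(max(gvar, 0.0)), 1e-6)
            self._cond_stats.append((gmean, gstd))
            z_lo, z_hi = self._z_slices[i]
            in_dim = (z_hi - z_lo) + meta.n_modes + 2
            self.continuous_nets.append(
                _ContinuousSubnet(in_dim, spec, init_rng, self.dropout_rng)
            )
        self.categorical_path: _CategoricalPathway | None = None
        if schema.l:
            z_lo, z_hi = self._z_slices[-1]
            n_classes_list = [
                transformer.categorical_meta[c.name].n_classes
                for c in schema.categorical
            ]
            self.categorical_path = _CategoricalPathway(
                n_classes_list, z_hi - z_lo, spec, init_rng, self.dropout_rng
            )

    @property
    def output_width(self) -> int:
        return self.transformer.width

    def __call__(self, z: np.ndarray, cond: ConditionVector) -> Tensor:
        schema = self.transformer.schema
        n = z.shape[0]
        if z.shape[1] != self.spec.z_dim:
            raise ValueError(f"z width {z.shape[1]} != z_dim {self.spec.z_dim}")
        blocks: list[Tensor] = []
        for i, cspec in enumerate(schema.continuous):
            meta = self.transformer.continuous_meta[cspec.name]
            kk = cond.modes[:, i]
            onehot = np.zeros((n, meta.n_modes))
            onehot[np.arange(n), kk] = 1.0
            gmean, gstd = self._cond_stats[i]
            mu = (meta.means[kk] - gmean) / gstd
            sd = meta.stds[kk] / gstd
            z_lo, z_hi = self._z_slices[i]
            x = Tensor(
                np.concatenate(
                    [z[:, z_lo:z_hi], onehot, mu[:, None], sd[:, None]], axis=1
                )
            )
            v = self.continuous_nets[i](x)
            blocks.append(v)
            blocks.append(Tensor(onehot))  # conditioned mode, passed through
        if self.categorical_path is not None:
            z_lo, z_hi = self._z_slices[-1]
            blocks.extend(
                self.categorical_path(Tensor(z[:, z_lo:z_hi]), cond.classes)
            )
        return concat(blocks, axis=1)

    def generate(
        self,
        sampler: ConditionSampler,
        n: int,
        rng_seed: int,
        categorical_mode: str = "sample",
    ) -> DataTable:
        if n < 1:
            raise ValueError("n must be >= 1")
        ss = np.random.SeedSequence(rng_seed)
        cond_rng, z_rng, decode_rng = [np.random.default_rng(s) for s in ss.spawn(3)]
        was_training = self.training
        self.eval()
        try:
            cond = sampler.sample(n, cond_rng)
            z = z_rng.standard_normal((n, self.spec.z_dim))
            flat = self(z, cond).data
        finally:
            if was_training:
                self.train()
        return self.transformer.inverse_from_matrix(
            flat, cond.modes, categorical_mode=categorical_mode, rng=decode_rng
        )


def build_generator(
    transformer: TableTransformer, spec: GeneratorSpec | None = None,
    rng_seed: int = 0,
) -> TabularGenerator:
    return TabularGenerator(transformer, spec or GeneratorSpec(), rng_seed=rng_seed)


def generate_table(
    generator: TabularGenerator,
    sampler: ConditionSampler,
    n: int,
    rng_seed: int,
    categorical_mode: str = "sample",
) -> DataTable:
    """Draw ``n`` synthetic records; identical seeds give identical tables."""
    return generator.generate(sampler, n, rng_seed, categorical_mode=categorical_mode)
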