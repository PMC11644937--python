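"""Reversible representation of mixed-type tables for the adversarial networks.

Continuous columns are modelled with a Bayesian Gaussian mixture whose
component count adapts to the data: each cell ``c`` is standardized by the
mean and standard deviation of the component most responsible for it,

    v = (c - mu_k) / sigma_k,   k = argmax_k p(k | c),

then clipped to [-0.99, 0.99] for numerical stability. The transformed cell
carries the clipped value, the hard mode assignment (as a one-hot, which is
what the networks consume) and the full responsibility vector. Categorical
columns are one-hot encoded over a sorted vocabulary.

The flat row layout is ``[v, onehot(mode)]`` per continuous column followed
by one one-hot block per categorical column, giving a total width of
``sum_i (1 + n_modes_i) + sum_j n_classes_j``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.mixture import BayesianGaussianMixture

from .schema import ColumnSpec, DataTable, TableSchema

__all__ = [
    "SIGMA_FLOOR",
    "WEIGHT_FLOOR",
    "CLIP",
    "ContinuousColumnMeta",
    "CategoricalColumnMeta",
    "TransformedTable",
    "fit_continuous_meta",
    "normalize_value",
    "denormalize_value",
    "fit_categorical_meta",
    "encode_onehot",
    "decode_onehot",
    "TableTransformer",
]

SIGMA_FLOOR = 1e-6
WEIGHT_FLOOR = 1e-3
CLIP = 0.99


@dataclass(frozen=True)
class ContinuousColumnMeta:
    """Gaussian-mixture metadata for one continuous column.

    ``means``/``stds`` are in the column's own units; ``weights`` is a
    probability vector over the retained components.
    """

    means: np.ndarray
    stds: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        means = np.asarray(self.means, dtype=float)
        stds = np.asarray(self.stds, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        if not (means.shape == stds.shape == weights.shape) or means.ndim != 1:
            raise ValueError("means, stds and weights must be equal-length 1-D")
        if means.size < 1:
            raise ValueError("need at least one mixture component")
        if np.any(stds < SIGMA_FLOOR):
            raise ValueError(f"all stds must be >= sigma floor {SIGMA_FLOOR}")
        if np.any(weights < 0) or abs(weights.sum() - 1.0) > 1e-6:
            raise ValueError("weights must be non-negative and sum to 1")
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "stds", stds)
        object.__setattr__(self, "weights", weights)

    @property
    def n_modes(self) -> int:
        return int(self.means.size)

    def to_dict(self) -> dict:
        return {
            "means": self.means.tolist(),
            "stds": self.stds.tolist(),
            "weights": self.weights.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ContinuousColumnMeta":
        return cls(np.array(d["means"]), np.array(d["stds"]), np.array(d["weights"]))


@dataclass(frozen=True)
class CategoricalColumnMeta:
    """One-hot vocabulary for a categorical column (sorted, deterministic)."""

    categories: tuple[str, ...]

    def __post_init__(self) -> None:
        cats = tuple(str(c) for c in self.categories)
        if len(cats) < 1:
            raise ValueError("need at least one category")
        if len(set(cats)) != len(cats):
            raise ValueError("categories must be unique")
        object.__setattr__(self, "categories", cats)

    @property
    def n_classes(self) -> int:
        return len(self.categories)

    def index(self, value: str) -> int:
        try:
            return self.categories.index(str(value))
        except ValueError:
            raise KeyError(f"unknown category {value!r}") from None

    def to_dict(self) -> dict:
        return {"categories": list(self.categories)}

    @classmethod
    def from_dict(cls, d: dict) -> "CategoricalColumnMeta":
        return cls(tuple(d["categories"]))


def fit_continuous_meta(
    values: Sequence[float], max_modes: int = 10, seed: int = 0
) -> ContinuousColumnMeta:
    """Fit a Bayesian Gaussian mixture to one continuous column.

    Up to ``max_modes`` components are fitted with a Dirichlet weight prior
    of 1/max_modes; components whose posterior weight falls below
    ``WEIGHT_FLOOR`` are pruned and the remaining weights renormalized, so
    the effective number of modes adapts to the data. Deterministic for a
    given ``seed``.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty column")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite value in continuous column")
    if max_modes < 1:
        raise ValueError("max_modes must be >= 1")

    n_distinct = np.unique(x).size
    if n_distinct == 1:
        return ContinuousColumnMeta(
            means=np.array([x[0]]), stds=np.array([SIGMA_FLOOR]), weights=np.array([1.0])
        )

    n_comp = min(max_modes, n_distinct)
    gmm = BayesianGaussianMixture(
        n_components=n_comp,
        weight_concentration_prior=1.0 / max_modes,
        n_init=1,
        max_iter=500,
        tol=1e-3,
        random_state=int(seed),
    )
    gmm.fit(x.reshape(-1, 1))

    means = gmm.means_.ravel()
    stds = np.sqrt(gmm.covariances_.ravel())
    weights = gmm.weights_.ravel()

    keep = weights >= WEIGHT_FLOOR
    if not np.any(keep):  # pathological; keep the dominant component
        keep = weights == weights.max()
    means, stds, weights = means[keep], stds[keep], weights[keep]
    order = np.argsort(means)
    means, stds, weights = means[order], stds[order], weights[order]
    stds = np.maximum(stds, SIGMA_FLOOR)
    weights = weights / weights.sum()
    return ContinuousColumnMeta(means=means, stds=stds, weights=weights)


def _responsibilities(c: np.ndarray, meta: ContinuousColumnMeta) -> np.ndarray:
    """Per-component posterior p(k | c) for each value in ``c`` — (n, n_modes)."""
    c = np.atleast_1d(np.asarray(c, dtype=float))
    log_w = np.log(np.maximum(meta.weights, 1e-300))
    z = (c[:, None] - meta.means[None, :]) / meta.stds[None, :]
    log_pdf = -0.5 * z**2 - np.log(meta.stds)[None, :] - 0.5 * np.log(2 * np.pi)
    log_post = log_w[None, :] + log_pdf
    log_post -= logsumexp(log_post, axis=1, keepdims=True)
    return np.exp(log_post)


def normalize_value(
    c: float, meta: ContinuousColumnMeta
) -> tuple[float, int, np.ndarray]:
    """Mode-specific normalization of one value.

    Returns ``(v, k, posterior)`` where ``k`` is the most responsible
    component (ties break to the lowest index) and ``v`` the standardized
    value clipped to [-0.99, 0.99].
    """
    if not np.isfinite(c):
        raise ValueError("non-finite value")
    post = _responsibilities(np.array([c]), meta)[0]
    k = int(np.argmax(post))
    v = float(np.clip((c - meta.means[k]) / meta.stds[k], -CLIP, CLIP))
    return v, k, post


def denormalize_value(v: float, k: int, meta: ContinuousColumnMeta) -> float:
    """Inverse of :func:`normalize_value` given the mode assignment."""
    if not 0 <= k < meta.n_modes:
        raise IndexError(f"mode index {k} out of range for {meta.n_modes} modes")
    return float(v) * float(meta.stds[k]) + float(meta.means[k])


def fit_categorical_meta(values: Sequence[str]) -> CategoricalColumnMeta:
    """Vocabulary = sorted distinct labels (lexicographic, reproducible)."""
    vals = [str(v) for v in values]
    if not vals:
        raise ValueError("empty column")
    return CategoricalColumnMeta(categories=tuple(sorted(set(vals))))


def encode_onehot(value: str, meta: CategoricalColumnMeta) -> np.ndarray:
    vec = np.zeros(meta.n_classes)
    vec[meta.index(value)] = 1.0
    return vec


def decode_onehot(
    vector: Sequence[float],
    meta: CategoricalColumnMeta,
    mode: str = "argmax",
    seed: int | np.random.Generator | None = None,
) -> str:
    """Map a probability / one-hot vector back to a label.

    ``argmax`` breaks ties toward the lowest index; ``sample`` draws a label
    proportionally to the entries (deterministic per seed).
    """
    vec = np.asarray(vector, dtype=float).ravel()
    if vec.size != meta.n_classes:
        raise ValueError(
            f"vector length {vec.size} != n_classes {meta.n_classes}"
        )
    if np.any(vec < 0) or vec.sum() <= 0:
        raise ValueError("entries must be >= 0 with positive sum")
    if mode == "argmax":
        return meta.categories[int(np.argmax(vec))]
    if mode == "sample":
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        idx = rng.choice(meta.n_classes, p=vec / vec.sum())
        return meta.categories[int(idx)]
    raise ValueError(f"unknown decode mode {mode!r}")


@dataclass
class TransformedTable:
    """Network-facing representation of a table.

    ``values``/``modes`` are (n, k) arrays for the continuous columns,
    ``posteriors`` a list of (n, n_modes_i) responsibility matrices and
    ``onehots`` a list of (n, n_classes_j) indicator matrices. ``matrix()``
    assembles the flat layout fed to the critic.
    """

    values: np.ndarray
    modes: np.ndarray
    posteriors: list[np.ndarray]
    onehots: list[np.ndarray]

    @property
    def n(self) -> int:
        if self.values.size or self.values.shape[0]:
            return int(self.values.shape[0])
        return int(self.onehots[0].shape[0]) if self.onehots else 0

    @property
    def width(self) -> int:
        w = sum(1 + p.shape[1] for p in self.posteriors)
        w += sum(o.shape[1] for o in self.onehots)
        return w

    def matrix(self) -> np.ndarray:
        """Flat (n, width) layout: [v, onehot(mode)]* then categorical one-hots."""
        n = self.n
        blocks: list[np.ndarray] = []
        for i, post in enumerate(self.posteriors):
            n_modes = post.shape[1]
            onehot_k = np.zeros((n, n_modes))
            if n:
                onehot_k[np.arange(n), self.modes[:, i].astype(int)] = 1.0
            blocks.append(self.values[:, i : i + 1])
            blocks.append(onehot_k)
        blocks.extend(self.onehots)
        if not blocks:
            return np.zeros((n, 0))
        return np.concatenate(blocks, axis=1)


class TableTransformer:
    """Fits per-column metadata and maps tables to/from the flat layout."""

    def __init__(self, schema: TableSchema, max_modes: int = 10, seed: int = 0):
        self.schema = schema
        self.max_modes = max_modes
        self.seed = int(seed)
        self.continuous_meta: dict[str, ContinuousColumnMeta] = {}
        self.categorical_meta: dict[str, CategoricalColumnMeta] = {}

    # -- fitting -----------------------------------------------------------
    def fit(self, table: DataTable) -> "TableTransformer":
        if table.schema != self.schema:
            raise ValueError("table schema does not match transformer schema")
        ss = np.random.SeedSequence(self.seed)
        seeds = ss.generate_state(max(self.schema.k, 1))
        for i, spec in enumerate(self.schema.continuous):
            self.continuous_meta[spec.name] = fit_continuous_meta(
                table.column(spec.name), self.max_modes, seed=int(seeds[i] % (2**31))
            )
        for spec in self.schema.categorical:
            # vocabulary is pinned by the schema so unseen-at-fit labels stay valid
            self.categorical_meta[spec.name] = CategoricalColumnMeta(spec.categories)
        return self

    @property
    def fitted(self) -> bool:
        return len(self.continuous_meta) == self.schema.k and len(
            self.categorical_meta
        ) == self.schema.l

    def _require_fitted(self) -> None:
        if not self.fitted:
            raise RuntimeError("transformer is not fitted")

    @property
    def width(self) -> int:
        self._require_fitted()
        w = sum(
            1 + self.continuous_meta[c.name].n_modes for c in self.schema.continuous
        )
        w += sum(
            self.categorical_meta[c.name].n_classes for c in self.schema.categorical
        )
        return w

    # -- forward -----------------------------------------------------------
    def transform(self, table: DataTable) -> TransformedTable:
        self._require_fitted()
        n = table.n
        k = self.schema.k
        values = np.zeros((n, k))
        modes = np.zeros((n, k), dtype=int)
        posteriors: list[np.ndarray] = []
        for i, spec in enumerate(self.schema.continuous):
            meta = self.continuous_meta[spec.name]
            col = table.column(spec.name).astype(float)
            post = (
                _responsibilities(col, meta) if n else np.zeros((0, meta.n_modes))
            )
            kk = np.argmax(post, axis=1) if n else np.zeros(0, dtype=int)
            if n:
                v = (col - meta.means[kk]) / meta.stds[kk]
                values[:, i] = np.clip(v, -CLIP, CLIP)
                modes[:, i] = kk
            posteriors.append(post)
        onehots: list[np.ndarray] = []
        for spec in self.schema.categorical:
            meta = self.categorical_meta[spec.name]
            block = np.zeros((n, meta.n_classes))
            if n:
                idx = [meta.index(v) for v in table.column(spec.name)]
                block[np.arange(n), idx] = 1.0
            onehots.append(block)
        return TransformedTable(values, modes, posteriors, onehots)

    # -- inverse -----------------------------------------------------------
    def inverse_transform(
        self,
        ttable: TransformedTable,
        categorical_mode: str = "argmax",
        rng: np.random.Generator | None = None,
    ) -> DataTable:
        self._require_fitted()
        n = ttable.n
        data: dict[str, np.ndarray | list] = {}
        for i, spec in enumerate(self.schema.continuous):
            meta = self.continuous_meta[spec.name]
            if ttable.posteriors[i].shape[1] != meta.n_modes:
                raise ValueError(f"block width mismatch for column {spec.name!r}")
            kk = ttable.modes[:, i].astype(int)
            if n and (kk.min() < 0 or kk.max() >= meta.n_modes):
                raise IndexError(f"mode index out of range for column {spec.name!r}")
            data[spec.name] = ttable.values[:, i] * meta.stds[kk] + meta.means[kk]
        for j, spec in enumerate(self.schema.categorical):
            meta = self.categorical_meta[spec.name]
            block = ttable.onehots[j]
            if block.shape[1] != meta.n_classes:
                raise ValueError(f"block width mismatch for column {spec.name!r}")
            data[spec.name] = [
                decode_onehot(block[r], meta, mode=categorical_mode, seed=rng)
                for r in range(n)
            ]
        frame = pd.DataFrame(data, columns=self.schema.names)
        return DataTable(schema=self.schema, frame=frame)

    def inverse_from_matrix(
        self,
        flat: np.ndarray,
        modes: np.ndarray,
        categorical_mode: str = "argmax",
        rng: np.random.Generator | None = None,
    ) -> DataTable:
        """Inverse-transform generator output: flat rows plus conditioned modes."""
        self._require_fitted()
        flat = np.asarray(flat, dtype=float)
        n = flat.shape[0]
        if flat.shape[1] != self.width:
            raise ValueError(f"flat width {flat.shape[1]} != layout width {self.width}")
        values = np.zeros((n, self.schema.k))
        posteriors = []
        pos = 0
        for i, spec in enumerate(self.schema.continuous):
            meta = self.continuous_meta[spec.name]
            values[:, i] = flat[:, pos]
            pos += 1 + meta.n_modes
            posteriors.append(np.zeros((n, meta.n_modes)))
        onehots = []
        for spec in self.schema.categorical:
            meta = self.categorical_meta[spec.name]
            onehots.append(flat[:, pos : pos + meta.n_classes])
            pos += meta.n_classes
        tt = TransformedTable(values, np.asarray(modes, dtype=int), posteriors, onehots)
        return self.inverse_transform(tt, categorical_mode=categorical_mode, rng=rng)

    # -- persistence -------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "max_modes": self.max_modes,
            "seed": self.seed,
            "columns": [
                {
                    "name": c.name,
                    "kind": c.kind.value,
                    "categories": list(c.categories) if c.categories else None,
                }
                for c in self.schema.columns
            ],
            "continuous_meta": {
                k: v.to_dict() for k, v in self.continuous_meta.items()
            },
            "categorical_meta": {
                k: v.to_dict() for k, v in self.categorical_meta.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TableTransformer":
        from .schema import ColumnKind

        cols = tuple(
            ColumnSpec(
                c["name"],
                ColumnKind(c["kind"]),
                tuple(c["categories"]) if c["categories"] else None,
            )
            for c in d["columns"]
        )
        tr = cls(TableSchema(cols), max_modes=d["max_modes"], seed=d["seed"])
        tr.continuous_meta = {
            k: ContinuousColumnMeta.from_dict(v) for k, v in d["continuous_meta"].items()
        }
        tr.categorical_meta = {
            k: CategoricalColumnMeta.from_dict(v)
            for k, v in d["categorical_meta"].items()
        }
        return tr

    def save_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load_json(cls, path: str | Path) -> "TableTransformer":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
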