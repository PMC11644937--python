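"""Fidelity metrics comparing a real table against a synthetic one.

Continuous marginals are scored with the two-sample Kolmogorov–Smirnov
statistic D = sup |F_real - F_synth| (0 = identical, 1 = disjoint),
categorical columns with the Jaccard coefficient of the *sets* of observed
categories, and pairwise structure with a correlation preservation rate:
the percentage of continuous column pairs whose Pearson correlation moved
by at most a tolerance tau between the real and synthetic tables. The
preservation rate is this package's own construction (tau is always
reported with it) and is not numerically comparable to other definitions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .schema import DataTable

__all__ = [
    "EvaluationReport",
    "ks_statistic",
    "jaccard_categories",
    "correlation_preservation_rate",
    "evaluate",
    "export_distribution_data",
]


def ks_statistic(x, y) -> float:
    """Two-sample KS statistic: sup over pooled points of |ECDF_x - ECDF_y|."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("samples must be non-empty")
    return float(stats.ks_2samp(x, y, method="asymp").statistic)


def jaccard_categories(real_col, synth_col) -> float:
    """|A ∩ B| / |A ∪ B| over the sets of distinct observed labels."""
    a = set(str(v) for v in real_col)
    b = set(str(v) for v in synth_col)
    if not a or not b:
        raise ValueError("columns must be non-empty")
    return len(a & b) / len(a | b)


def _pearson_matrix(table: DataTable, drop: set[str]) -> tuple[np.ndarray, list[str]]:
    names = [c.name for c in table.schema.continuous if c.name not in drop]
    mat = table.frame[names].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(mat, rowvar=False)
    return np.atleast_2d(corr), names


def correlation_preservation_rate(
    real: DataTable, synth: DataTable, tau: float = 0.1
) -> float:
    """Percentage of continuous pairs with |r_real - r_synth| <= tau."""
    if real.n < 3 or synth.n < 3:
        raise ValueError("need at least 3 rows to estimate correlations")
    drop: set[str] = set()
    for t in (real, synth):
        for c in t.schema.continuous:
            if np.std(t.column(c.name).astype(float)) == 0:
                warnings.warn(
                    f"constant column {c.name!r} excluded from correlation analysis"
                )
                drop.add(c.name)
    r_mat, names = _pearson_matrix(real, drop)
    s_mat, _ = _pearson_matrix(synth, drop)
    if len(names) < 2:
        raise ValueError("need at least 2 non-constant continuous columns")
    pairs = list(combinations(range(len(names)), 2))
    preserved = sum(
        1 for i, j in pairs if abs(r_mat[i, j] - s_mat[i, j]) <= tau
    )
    return 100.0 * preserved / len(pairs)


@dataclass
class EvaluationReport:
    """Per-column fidelity metrics plus summary quantities."""

    ks: dict[str, float]
    mean_ks: float
    jaccard: dict[str, float]
    real_corr: pd.DataFrame
    synth_corr: pd.DataFrame
    preservation_rate: float
    tau: float

    def to_dict(self) -> dict:
        return {
            "ks": self.ks,
            "mean_ks": self.mean_ks,
            "jaccard": self.jaccard,
            "real_corr": self.real_corr.round(6).to_dict(),
            "synth_corr": self.synth_corr.round(6).to_dict(),
            "preservation_rate": self.preservation_rate,
            "tau": self.tau,
        }

    def save_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def summary(self) -> str:
        lines = ["Continuous columns (two-sample KS, lower is better):"]
        for name, d in self.ks.items():
            lines.append(f"  {name:<14s} D = {d:.4f}")
        lines.append(f"  mean KS        = {self.mean_ks:.4f}")
        lines.append("Categorical columns (Jaccard of observed category sets):")
        for name, j in self.jaccard.items():
            lines.append(f"  {name:<14s} J = {j:.2f}")
        lines.append(
            f"Correlation preservation: {self.preservation_rate:.2f}% of pairs "
            f"within tau = {self.tau}"
        )
        return "\n".join(lines)


def evaluate(real: DataTable, synth: DataTable, tau: float = 0.1) -> EvaluationReport:
    """Full fidelity report; both tables must share one schema."""
    if real.schema != synth.schema:
        raise ValueError("real and synthetic tables must share a schema")
    ks = {
        c.name: ks_statistic(real.column(c.name), synth.column(c.name))
        for c in real.schema.continuous
    }
    mean_ks = float(np.mean(list(ks.values()))) if ks else float("nan")
    jac = {
        c.name: jaccard_categories(real.column(c.name), synth.column(c.name))
        for c in real.schema.categorical
    }
    drop: set[str] = set()
    for t in (real, synth):
        for c in t.schema.continuous:
            if np.std(t.column(c.name).astype(float)) == 0:
                drop.add(c.name)
    r_mat, names = _pearson_matrix(real, drop)
    s_mat, _ = _pearson_matrix(synth, drop)
    rate = correlation_preservation_rate(real, synth, tau=tau)
    return EvaluationReport(
        ks=ks,
        mean_ks=mean_ks,
        jaccard=jac,
        real_corr=pd.DataFrame(r_mat, index=names, columns=names),
        synth_corr=pd.DataFrame(s_mat, index=names, columns=names),
        preservation_rate=rate,
        tau=tau,
    )


def export_distribution_data(
    real: DataTable, synth: DataTable, out_path: str | Path
) -> list[Path]:
    """Write the data behind CDF and category-frequency comparison plots.

    Per continuous column: CSV of (value, real_cdf, synth_cdf) evaluated at
    the pooled sample points. Per categorical column: CSV of
    (category, real_count, synth_count).
    """
    if real.n == 0 or synth.n == 0:
        raise ValueError("tables must be non-empty")
    if real.schema != synth.schema:
        raise ValueError("real and synthetic tables must share a schema")
    out = Path(out_path)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for c in real.schema.continuous:
        xr = np.sort(real.column(c.name).astype(float))
        xs = np.sort(synth.column(c.name).astype(float))
        grid = np.unique(np.concatenate([xr, xs]))
        cdf_r = np.searchsorted(xr, grid, side="right") / xr.size
        cdf_s = np.searchsorted(xs, grid, side="right") / xs.size
        path = out / f"cdf_{_safe(c.name)}.csv"
        pd.DataFrame(
            {"value": grid, "real_cdf": cdf_r, "synth_cdf": cdf_s}
        ).to_csv(path, index=False)
        written.append(path)
    for c in real.schema.categorical:
        cats = list(c.categories)
        rc = pd.Series(real.column(c.name)).value_counts()
        sc = pd.Series(synth.column(c.name)).value_counts()
        path = out / f"freq_{_safe(c.name)}.csv"
        pd.DataFrame(
            {
                "category": cats,
                "real_count": [int(rc.get(k, 0)) for k in cats],
                "synth_count": [int(sc.get(k, 0)) for k in cats],
            }
        ).to_csv(path, index=False)
        written.append(path)
    return written


def _safe(name: str) -> str:
    return "".join(ch if ch.isalnum() else "_" for ch in name)
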