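"""Contingency-table association statistics.

Plain Pearson chi-square with Cramér's V, unweighted Cohen's kappa, and the
pooled two-proportion z-test. No continuity corrections are applied by
default; the chi-square test exposes an optional Yates correction for 2x2
tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ContingencyTable",
    "StatResult",
    "StatsError",
    "chi_square_independence",
    "cohens_kappa",
    "two_proportion_z",
]


class StatsError(ValueError):
    """Degenerate input for which the requested statistic is undefined."""


@dataclass(frozen=True)
class StatResult:
    statistic: float
    p_value: float
    df: int | None = None
    effect_size: float | None = None
    effect_name: str | None = None

    def __str__(self) -> str:
        parts = [f"statistic={self.statistic:.6g}"]
        if self.df is not None:
            parts.append(f"df={self.df}")
        parts.append(f"p={self.p_value:.4g}")
        if self.effect_size is not None:
            parts.append(f"{self.effect_name}={self.effect_size:.4g}")
        return ", ".join(parts)


@dataclass(frozen=True)
class ContingencyTable:
    """r x c grid of nonnegative integer counts with row/column labels."""

    counts: tuple[tuple[int, ...], ...]
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        arr = self.to_array()
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise StatsError("contingency table must be at least 2x2")
        if (arr < 0).any():
            raise StatsError("contingency table counts must be nonnegative")
        if arr.sum() == 0:
            raise StatsError("contingency table is empty")
        if len(self.row_labels) != arr.shape[0] or len(self.col_labels) != arr.shape[1]:
            raise StatsError("label lengths do not match table shape")

    @classmethod
    def from_counts(
        cls,
        counts: Sequence[Sequence[int]],
        row_labels: Sequence[str] | None = None,
        col_labels: Sequence[str] | None = None,
    ) -> "ContingencyTable":
        r, c = len(counts), len(counts[0])
        return cls(
            counts=tuple(tuple(int(x) for x in row) for row in counts),
            row_labels=tuple(row_labels) if row_labels else tuple(f"r{i}" for i in range(r)),
            col_labels=tuple(col_labels) if col_labels else tuple(f"c{j}" for j in range(c)),
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ContingencyTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls.from_counts(
            df.to_numpy().tolist(),
            row_labels=[str(x) for x in df.index],
            col_labels=[str(x) for x in df.columns],
        )

    def to_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)


def chi_square_independence(t: ContingencyTable, yates: bool = False) -> StatResult:
    """Pearson chi-square test of independence with Cramér's V.

    Expected counts come from the row/column marginals; a zero marginal is
    rejected by name. ``yates`` applies the continuity correction
    (|O-E| - 0.5, floored at 0) and is only meaningful for 2x2 tables.
    """
    obs = t.to_array()
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    for marg, labels, kind in ((row, t.row_labels, "row"), (col, t.col_labels, "column")):
        zeros = [labels[i] for i in np.flatnonzero(marg == 0)]
        if zeros:
            raise StatsError(f"zero {kind} marginal for {zeros}")
    n = obs.sum()
    expected = np.outer(row, col) / n
    dev = np.abs(obs - expected)
    if yates:
        dev = np.maximum(dev - 0.5, 0.0)
    chi2 = float((dev**2 / expected).sum())
    r, c = obs.shape
    df = (r - 1) * (c - 1)
    v = float(np.sqrt(chi2 / (n * min(r - 1, c - 1))))
    return StatResult(
        statistic=chi2,
        p_value=float(sps.chi2.sf(chi2, df)),
        df=df,
        effect_size=v,
        effect_name="cramers_v",
    )


def cohens_kappa(t: ContingencyTable) -> StatResult:
    """Unweighted Cohen's kappa for a square table with matched labels.

    kappa = (p_o - p_e) / (1 - p_e), where p_o is the observed diagonal
    fraction and p_e the chance agreement from the marginals.
    """
    obs = t.to_array()
    r, c = obs.shape
    if r != c:
        raise StatsError(f"kappa needs a square table, got {r}x{c}")
    if t.row_labels != t.col_labels:
        raise StatsError("kappa needs identical row and column label order")
    n = obs.sum()
    p_o = float(np.trace(obs) / n)
    p_e = float((obs.sum(axis=1) * obs.sum(axis=0)).sum() / n**2)
    if p_e >= 1.0:
        raise StatsError("chance agreement is 1 (both ratings constant); kappa undefined")
    kappa = (p_o - p_e) / (1 - p_e)
    # normal-approximation p-value against kappa == 0
    se0 = float(np.sqrt(p_e / (n * (1 - p_e))))
    z = kappa / se0
    return StatResult(
        statistic=float(z),
        p_value=float(2 * sps.norm.sf(abs(z))),
        df=None,
        effect_size=float(kappa),
        effect_name="kappa",
    )


def two_proportion_z(x1: int, n1: int, x2: int, n2: int) -> StatResult:
    """Pooled two-proportion z-test, two-sided.

    z = (p1 - p2) / sqrt(p (1 - p) (1/n1 + 1/n2)) with the pooled
    p = (x1 + x2) / (n1 + n2); the sign follows p1 - p2.
    """
    for x, n, tag in ((x1, n1, "first"), (x2, n2, "second")):
        if n <= 0:
            raise StatsError(f"{tag} sample size must be positive")
        if not 0 <= x <= n:
            raise StatsError(f"{tag} count {x} outside [0, {n}]")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        raise StatsError("pooled proportion is degenerate (0 or 1); z undefined")
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = float((p1 - p2) / se)
    return StatResult(statistic=z, p_value=float(2 * sps.norm.sf(abs(z))))
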