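"""Baseline cohort statistics: chi-square tests, t-tests, stratified split.

Mirrors the standard "Table 1" workflow for a surgical cohort: Pearson
chi-square (no continuity correction) on categorical contingency tables,
two-sample t-tests on continuous variables, and a stratified train/test
partition that preserves outcome prevalence to within one count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ContingencyTable",
    "SplitResult",
    "pearson_chi_square",
    "two_sample_t",
    "stratified_split",
    "baseline_table",
]


@dataclass(frozen=True)
class ContingencyTable:
    counts: np.ndarray
    row_labels: tuple[str, ...] | None = None
    col_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
            raise ValueError("contingency table must be at least 2x2")
        if (counts < 0).any():
            raise ValueError("contingency table counts must be non-negative")
        if counts.sum() <= 0:
            raise ValueError("contingency table grand total must be > 0")


@dataclass(frozen=True)
class SplitResult:
    train_indices: np.ndarray
    test_indices: np.ndarray
    ratio: float


def pearson_chi_square(
    table: ContingencyTable | np.ndarray | list,
) -> tuple[float, int, float]:
    """Pearson chi-square test of independence, no continuity correction.

    Returns ``(statistic, df, p_value)`` with ``statistic = sum (O-E)^2/E``,
    ``E_ij = row_i * col_j / N`` and ``df = (r-1)(c-1)``.
    """
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable(np.asarray(table))
    counts = table.counts
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("zero row or column total: expected counts undefined")
    res = sps.chi2_contingency(counts, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def two_sample_t(
    a: np.ndarray, b: np.ndarray, pooled: bool = True
) -> tuple[float, float, float]:
    """Two-sample t-test; pooled-variance Student t by default, Welch otherwise.

    Returns ``(statistic, df, p_value)`` with a two-tailed p.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("samples must be finite")
    if pooled:
        sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (
            len(a) + len(b) - 2
        )
        if sp2 == 0:
            raise ValueError("zero pooled variance: t statistic undefined")
    res = sps.ttest_ind(a, b, equal_var=pooled)
    return float(res.statistic), float(res.df), float(res.pvalue)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def stratified_split(
    table: pd.DataFrame,
    ratio: float,
    outcome_column: str = "ppc",
    seed: int = 0,
) -> SplitResult:
    """Stratified train/test partition by outcome class.

    The global train size is round-half-up of ``ratio * n``; it is allocated
    across strata by the largest-remainder rule (floor of ``ratio * size``
    per stratum, leftover counts to the largest fractional remainders), so
    each part's prevalence is within one count of perfectly proportional.
    Assignment within a stratum is a seeded uniform shuffle.  A 286-row
    cohort at ratio 0.8 yields 229 train / 57 test.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError(f"ratio must be in (0, 1), got {ratio}")
    if outcome_column not in table.columns:
        raise ValueError(f"outcome column {outcome_column!r} not in table")
    rng = np.random.default_rng(seed)
    outcome = table[outcome_column].to_numpy()
    strata = sorted(pd.unique(outcome).tolist())

    sizes = {s: int((outcome == s).sum()) for s in strata}
    if min(sizes.values()) < 2:
        raise ValueError("every stratum needs at least 2 rows to split")
    target = _round_half_up(ratio * len(table))
    n_train = {s: math.floor(ratio * sz) for s, sz in sizes.items()}
    leftover = target - sum(n_train.values())
    by_remainder = sorted(
        strata, key=lambda s: (ratio * sizes[s]) % 1.0, reverse=True
    )
    for s in by_remainder[:leftover]:
        n_train[s] += 1

    train_parts, test_parts = [], []
    for s in strata:
        idx = np.flatnonzero(outcome == s)
        rng.shuffle(idx)
        train_parts.append(idx[: n_train[s]])
        test_parts.append(idx[n_train[s]:])
    train = np.sort(np.concatenate(train_parts))
    test = np.sort(np.concatenate(test_parts))
    return SplitResult(train_indices=train, test_indices=test, ratio=ratio)


def baseline_table(
    df: pd.DataFrame,
    group_column: str,
    continuous: list[str],
    categorical: list[str],
) -> pd.DataFrame:
    """Table-1-style report comparing two groups.

    One row per variable: group summaries (mean +/- sd or counts), the test
    statistic (pooled t or Pearson chi-square) and its p-value.
    """
    groups = sorted(pd.unique(df[group_column]).tolist())
    if len(groups) != 2:
        raise ValueError("baseline table requires exactly two groups")
    g0 = df[df[group_column] == groups[0]]
    g1 = df[df[group_column] == groups[1]]
    rows = []
    for var in continuous:
        a, b = g0[var].dropna(), g1[var].dropna()
        stat, _, p = two_sample_t(a.to_numpy(), b.to_numpy())
        rows.append(
            {
                "variable": var,
                "kind": "continuous",
                f"group_{groups[0]}": f"{a.mean():.2f} ± {a.std(ddof=1):.2f}",
                f"group_{groups[1]}": f"{b.mean():.2f} ± {b.std(ddof=1):.2f}",
                "statistic": abs(stat),
                "p_value": p,
            }
        )
    for var in categorical:
        ct = pd.crosstab(df[var], df[group_column])
        stat, _, p = pearson_chi_square(ct.to_numpy())
        rows.append(
            {
                "variable": var,
                "kind": "categorical",
                f"group_{groups[0]}": "; ".join(
                    f"{k}: {v}" for k, v in ct[groups[0]].items()
                ),
                f"group_{groups[1]}": "; ".join(
                    f"{k}: {v}" for k, v in ct[groups[1]].items()
                ),
                "statistic": stat,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)
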