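"""Spearman rank-correlation screening of baseline features against outcome scores.

Candidate features (by default the DBM atrophy regions) are correlated with
the raw year-t outcome score; features with two-sided p < 0.05 are retained.
No multiple-testing correction is applied — the screen is a raw 0.05
threshold.  The correlation is Spearman's rho: the Pearson correlation of
mid-ranks (ties receive average ranks), with the p-value from the usual
t-approximation t = rho * sqrt((n-2) / (1-rho^2)) on n-2 degrees of freedom.
An exact permutation p-value is available for very small samples.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable


def spearman_rho(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks.

    With no ties this equals the closed form 1 - 6*sum(d^2)/(n*(n^2-1)).
    Raises on length mismatch, n < 3, missing values, or a constant input
    (rho is undefined there, never silently 0).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("inputs must not contain missing values")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman rho is undefined for a constant input")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def spearman_pvalue(rho: float, n: int) -> float:
    """Two-sided p for an observed rho at sample size n (t-approximation).

    ``t = rho * sqrt((n-2)/(1-rho^2))`` referred to Student's t with n-2
    degrees of freedom; rho = +-1 gives p = 0 exactly.
    """
    if n < 4:
        raise ValueError("t-approximation needs n >= 4")
    if not (-1 <= rho <= 1):
        raise ValueError("rho must lie in [-1, 1]")
    if abs(rho) == 1:
        return 0.0
    t = rho * math.sqrt((n - 2) / (1 - rho * rho))
    return float(2 * stats.t.sf(abs(t), df=n - 2))


def spearman_pvalue_exact(x, y, max_n: int = 10) -> float:
    """Exact two-sided permutation p-value for Spearman rho (small n only).

    Enumerates all n! permutations of y and counts those with
    |rho_perm| >= |rho_observed| (to within 1e-12).  Intended as the
    small-sample oracle; refuses n > *max_n*.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n > max_n:
        raise ValueError(f"exact permutation limited to n <= {max_n}")
    rho_obs = abs(spearman_rho(x, y))
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    denom_x = math.sqrt(rx @ rx)
    perms = np.array(list(itertools.permutations(range(n))))
    ry_perm = (ry - ry.mean())[perms]  # (n!, n)
    denom_y = np.sqrt((ry_perm**2).sum(axis=1))
    rhos = ry_perm @ rx / (denom_x * denom_y)
    count = int(np.sum(np.abs(rhos) >= rho_obs - 1e-12))
    return count / len(perms)


@dataclass
class ScreenResult:
    """One feature's screening outcome against a target score."""

    feature: str
    rho: float
    p_value: float
    selected: bool


def select_features(
    table: CohortTable,
    target_scores,
    candidate_features,
    alpha: float = 0.05,
    method: str = "t",
) -> list[ScreenResult]:
    """Screen *candidate_features* of *table* against *target_scores*.

    Returns one :class:`ScreenResult` per candidate, ordered by descending
    |rho| with ties broken by feature name; ``selected`` is ``p < alpha``.
    ``method`` is ``"t"`` (default) or ``"exact"`` (permutation, small n).
    """
    candidate_features = list(candidate_features)
    if not candidate_features:
        raise ValueError("candidate feature list is empty")
    missing = [c for c in candidate_features if c not in table.values.columns]
    if missing:
        raise ValueError(f"candidates not in table: {missing}")
    y = np.asarray(target_scores, float)
    if len(y) != len(table.values):
        raise ValueError("target_scores must align with table subjects")
    results = []
    for name in candidate_features:
        x = table.values[name].to_numpy(float)
        rho = spearman_rho(x, y)
        if method == "exact":
            p = spearman_pvalue_exact(x, y)
        else:
            p = spearman_pvalue(rho, len(y))
        results.append(ScreenResult(name, rho, p, bool(p < alpha)))
    results.sort(key=lambda r: (-abs(r.rho), r.feature))
    return results


def screening_table(results: list[ScreenResult], table: CohortTable) -> pd.DataFrame:
    """Screening output as a table with Predictor / Type / Side / R Value /
    p Value columns (the usual per-year, per-modality report layout)."""
    meta = table.feature_meta.set_index("name")
    rows = []
    for r in results:
        rows.append({
            "Predictor": r.feature,
            "Type": meta.loc[r.feature, "modality"],
            "Side": meta.loc[r.feature, "hemisphere"],
            "R Value": round(r.rho, 3),
            "p Value": round(r.p_value, 4),
            "Selected": r.selected,
        })
    return pd.DataFrame(rows)


def write_screening_csv(results: list[ScreenResult], table: CohortTable, path) -> None:
    screening_table(results, table).to_csv(Path(path), index=False)
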