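"""Disease-severity stratification: Spearman rank correlation of each
metric against the clinical severity ranking, exact permutation or
t-approximation p-values, and Benjamini-Hochberg selection at a given
false discovery rate.

With eight subjects the full permutation null (8! = 40320 orderings) is
enumerated, making the p-value exact and convention-free.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd


@dataclass
class StratTable:
    """Aligned per-subject metric values and severity ranks."""

    metrics: dict          # name -> array of length n
    severity: np.ndarray   # permutation of 1..n
    groups: dict = None    # name -> class label (optional)

    def __post_init__(self) -> None:
        self.severity = np.asarray(self.severity, dtype=float)
        n = len(self.severity)
        if sorted(self.severity) != list(range(1, n + 1)):
            raise ValueError("severity must be a permutation of 1..n")
        for name, vals in self.metrics.items():
            if len(vals) != n:
                raise ValueError(f"metric {name} has wrong length")


def midranks(x) -> np.ndarray:
    """Average (mid-) ranks, 1-based; ties share the mean of their ranks."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x))
    sx = x[order]
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def spearman_rho(x, y) -> float:
    """Spearman's rank correlation: Pearson correlation of midranks.

    Equals 1 - 6*sum(d^2)/(n(n^2-1)) when there are no ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length arrays of length >= 3")
    rx, ry = midranks(x), midranks(y)
    sx, sy = np.std(rx), np.std(ry)
    if sx == 0 or sy == 0:
        raise ValueError("zero rank variance: correlation undefined")
    n = len(x)
    if len(set(rx)) == n and len(set(ry)) == n:
        # tie-free: the closed form is numerically exact
        d = rx - ry
        return float(1.0 - 6.0 * np.sum(d * d) / (n * (n * n - 1)))
    return float(np.mean((rx - rx.mean()) * (ry - ry.mean())) / (sx * sy))


@lru_cache(maxsize=8)
def _perm_matrix(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.intp)


def _exact_null_rhos(rx: tuple, ry: tuple) -> np.ndarray:
    rx = np.asarray(rx, dtype=float)
    ry = np.asarray(ry, dtype=float)
    perms = _perm_matrix(len(rx))
    ry_c = ry - ry.mean()
    rx_c = rx - rx.mean()
    denom = len(rx) * np.std(rx) * np.std(ry)
    return (ry_c[perms] @ rx_c) / denom


def spearman_pvalue(rho: float, n: int, method: str = None,
                    x=None, y=None) -> float:
    """Two-sided p-value for an observed Spearman rho.

    ``exact_perm`` (default for n <= 9) enumerates all n! orderings;
    ties are handled by permuting the actual midranks when x and y are
    supplied.  ``t_approx`` uses t = rho*sqrt((n-2)/(1-rho^2)) with
    n - 2 degrees of freedom.
    """
    if method is None:
        method = "exact_perm" if n <= 9 else "t_approx"
    if method == "exact_perm":
        if n < 4:
            raise ValueError("exact permutation needs n >= 4")
        if n > 9:
            raise ValueError("exact enumeration limited to n <= 9")
        rx = midranks(x) if x is not None else np.arange(1.0, n + 1)
        ry = midranks(y) if y is not None else np.arange(1.0, n + 1)
        null = _exact_null_rhos(tuple(rx), tuple(ry))
        return float(np.mean(np.abs(null) >= abs(rho) - 1e-12))
    if method == "t_approx":
        if n < 5:
            raise ValueError("t approximation needs n >= 5")
        if abs(rho) >= 1.0:
            return 0.0
        from scipy.stats import t as t_dist
        t_stat = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
        return float(2.0 * t_dist.sf(abs(t_stat), n - 2))
    raise ValueError(f"unknown method {method!r}")


def bh_critical_values(m: int, q: float = 0.10) -> np.ndarray:
    """Benjamini-Hochberg critical values i*q/m for i = 1..m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.arange(1, m + 1) * q / m


def bh_select(p_values, q: float = 0.10) -> np.ndarray:
    """Step-up BH selection: boolean mask of significant hypotheses.

    All hypotheses with rank <= the largest i such that p_(i) <= i*q/m
    are selected.
    """
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    crit = bh_critical_values(m, q)
    passed = np.where(p[order] <= crit)[0]
    mask = np.zeros(m, dtype=bool)
    if len(passed):
        mask[order[:passed[-1] + 1]] = True
    return mask


def stratify(table: StratTable, q: float = 0.10,
             m_total: int = None) -> pd.DataFrame:
    """Per-metric Spearman rho against severity, exact p-value, BH
    critical value and significance flag; rows sorted by |rho| descending
    (ties by metric name).

    ``m_total`` overrides the number of tests m in the BH denominators
    when the table is a subset of a larger metric family.  Metrics with
    missing values are excluded with a warning.
    """
    sev = table.severity
    rows = []
    for name in sorted(table.metrics):
        vals = np.asarray(table.metrics[name], dtype=float)
        if np.any(~np.isfinite(vals)):
            warnings.warn(f"metric {name}: missing values, excluded")
            continue
        try:
            rho = spearman_rho(vals, sev)
        except ValueError:
            warnings.warn(f"metric {name}: zero rank variance, excluded")
            continue
        p = spearman_pvalue(rho, len(sev), x=vals, y=sev)
        rows.append({"metric": name, "rho": rho, "p_value": p})
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    m = m_total if m_total is not None else len(df)
    df = df.sort_values("p_value", kind="mergesort").reset_index(drop=True)
    df["bh_critical"] = (df.index + 1) * q / m
    # step-up selection on the (possibly global) critical values
    passed = np.where(df["p_value"].to_numpy() <= df["bh_critical"].to_numpy())[0]
    cutoff = passed[-1] if len(passed) else -1
    df["significant"] = df.index <= cutoff
    df["abs_rho"] = df["rho"].abs()
    df = df.sort_values(["abs_rho", "metric"], ascending=[False, True],
                        kind="mergesort").drop(columns="abs_rho")
    return df.reset_index(drop=True)
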