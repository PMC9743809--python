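"""Nonparametric condition comparisons and table assembly.

The analysis schema: a Shapiro–Wilk normality gate, then two-sample
Mann–Whitney–Wilcoxon comparisons reported with the *rank-sum* W
convention (W = sum of the pooled-sample ranks of the first sample),
Spearman correlation for the capture-rate/astigmatism relationship,
and result tables with the column order
``Measure, N back, N, Mean, SD, Median, W, p-value``.

The exact two-sided Mann–Whitney p-value is computed by enumerating the
null distribution of W over all size-n1 rank subsets when
``n1 + n2 <= 16`` and there are no ties; otherwise a normal
approximation with midrank tie correction and continuity correction is
used.  Midranks handle ties throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from math import comb
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .errors import DegenerateInputError, InvalidInputError

__all__ = [
    "NormalityResult",
    "TestResult",
    "CorrelationResult",
    "shapiro_wilk",
    "mann_whitney",
    "spearman",
    "comparison_table",
    "significance_flag",
]


@dataclass(frozen=True)
class NormalityResult:
    statistic: float
    p: float
    alpha: float = 0.05

    @property
    def nonparametric(self) -> bool:
        """True when the gate routes to the nonparametric path."""
        return self.p < self.alpha


@dataclass(frozen=True)
class TestResult:
    """Mann–Whitney–Wilcoxon comparison of two samples.

    ``W`` is the sum of the pooled-sample midranks of the first sample.
    """

    n1: int
    n2: int
    mean1: float
    sd1: float
    median1: float
    mean2: float
    sd2: float
    median2: float
    W: float
    p: float
    method: str = "mann_whitney"
    exact: bool = False

    @property
    def significance(self) -> str:
        return significance_flag(self.p)


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p: float
    n: int
    method: str = "spearman"


def significance_flag(p: float) -> str:
    """Stars at the 0.05 / 0.01 / 0.001 levels."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def shapiro_wilk(values: Sequence[float], alpha: float = 0.05) -> NormalityResult:
    """Shapiro–Wilk normality test, used as the parametric/nonparametric gate."""
    x = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("values must be finite")
    if not 3 <= len(x) <= 5000:
        raise InvalidInputError(f"Shapiro–Wilk supports 3 <= n <= 5000, got {len(x)}")
    if np.ptp(x) == 0:
        raise DegenerateInputError("all values identical; normality undefined")
    stat, p = sstats.shapiro(x)
    return NormalityResult(float(stat), float(p), alpha)


def _exact_ranksum_p(w: int, n1: int, n2: int) -> float:
    """Two-sided exact p for the rank-sum W with untied ranks 1..n.

    Enumerates (via subset-sum counting) the number of size-n1 subsets
    of {1..n} at each possible rank sum; p = 2*min(P(W<=w), P(W>=w)),
    capped at 1.  The null distribution is symmetric, so this equals
    the |W - E[W]|-based two-sided definition.
    """
    n = n1 + n2
    max_s = n * (n + 1) // 2
    counts = np.zeros((n1 + 1, max_s + 1), dtype=float)
    counts[0, 0] = 1.0
    for r in range(1, n + 1):
        for k in range(min(r, n1), 0, -1):
            counts[k, r:] += counts[k - 1, : max_s + 1 - r]
    dist = counts[n1]
    total = comb(n, n1)
    p_le = dist[: w + 1].sum() / total
    p_ge = dist[w:].sum() / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def mann_whitney(
    x: Sequence[float],
    y: Sequence[float],
    *,
    exact_limit: int = 16,
    continuity: bool = True,
) -> TestResult:
    """Two-sample Mann–Whitney–Wilcoxon test with rank-sum W.

    ``W`` is the sum of pooled midranks of ``x``.  The two-sided p is
    exact (enumeration) for small untied samples, otherwise a normal
    approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise InvalidInputError("both samples must be nonempty")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InvalidInputError("values must be finite")
    n1, n2 = len(x), len(y)
    n = n1 + n2
    pooled = np.concatenate([x, y])
    ranks = sstats.rankdata(pooled)
    W = float(ranks[:n1].sum())
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool(np.any(tie_counts > 1))

    if n <= exact_limit and not has_ties:
        p = _exact_ranksum_p(int(round(W)), n1, n2)
        exact = True
    else:
        mu = n1 * (n + 1) / 2.0
        tie_term = float(np.sum(tie_counts**3 - tie_counts))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var <= 0:
            raise DegenerateInputError("all pooled values identical")
        diff = W - mu
        if continuity:
            diff -= 0.5 * np.sign(diff)
        z = diff / np.sqrt(var)
        p = float(min(1.0, 2.0 * sstats.norm.sf(abs(z))))
        exact = False

    return TestResult(
        n1=n1, n2=n2,
        mean1=float(x.mean()), sd1=float(x.std(ddof=1)) if n1 > 1 else 0.0,
        median1=float(np.median(x)),
        mean2=float(y.mean()), sd2=float(y.std(ddof=1)) if n2 > 1 else 0.0,
        median2=float(np.median(y)),
        W=W, p=p, exact=exact,
    )


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    *,
    exact_limit: int = 8,
) -> CorrelationResult:
    """Spearman rank correlation.

    rho is the Pearson correlation of midranks.  The p-value is an
    exact permutation p for ``n <= exact_limit`` and the usual
    t-approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise InvalidInputError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise InvalidInputError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("constant vector; correlation undefined")
    rx = sstats.rankdata(x)
    ry = sstats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_limit:
        # permutation null: all orderings of y's ranks against x's
        rx_c = rx - rx.mean()
        denom = np.sqrt((rx_c**2).sum())
        count = 0
        total = 0
        for perm in permutations(ry):
            ry_p = np.asarray(perm) - ry.mean()
            r = float(rx_c @ ry_p) / (denom * np.sqrt((ry_p**2).sum()))
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
            total += 1
        p = count / total
    else:
        t = rho * np.sqrt((n - 2) / max(1e-300, 1.0 - rho**2))
        p = float(min(1.0, 2.0 * sstats.t.sf(abs(t), df=n - 2)))
    return CorrelationResult(rho=rho, p=p, n=n)


TABLE_COLUMNS = ["Measure", "N back", "N", "Mean", "SD", "Median", "W", "p-value"]


def comparison_table(
    data: pd.DataFrame,
    *,
    measures: Optional[Sequence[str]] = None,
    measure_col: str = "measure",
    group_col: str = "condition",
    value_col: str = "value",
    group_order: Sequence = ("low", "high"),
    group_display: Optional[dict] = None,
    adjust: str = "none",
) -> pd.DataFrame:
    """Assemble a comparison table, one row pair per measure.

    ``data`` is long-form with one observation per row.  The first row
    of each pair carries the W statistic, p-value and significance
    flag.  Measures missing a group get flagged rows with no test.
    ``adjust`` is ``none`` (default), ``holm`` or ``bh``.
    """
    if group_display is None:
        group_display = {"low": 1, "high": 2}
    if measures is None:
        measures = list(pd.unique(data[measure_col]))
    rows: list[dict] = []
    pvals: list[Optional[float]] = []
    for m in measures:
        sub = data[data[measure_col] == m]
        groups = [
            sub.loc[sub[group_col] == g, value_col].to_numpy(dtype=float)
            for g in group_order
        ]
        result: Optional[TestResult] = None
        flag = ""
        if all(len(g) > 0 for g in groups):
            try:
                result = mann_whitney(groups[0], groups[1])
            except DegenerateInputError:
                flag = "degenerate"
        else:
            flag = "missing-group"
        for j, g in enumerate(group_order):
            vals = groups[j]
            row = {
                "Measure": m,
                "N back": group_display.get(g, g),
                "N": len(vals),
                "Mean": float(np.mean(vals)) if len(vals) else np.nan,
                "SD": float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan,
                "Median": float(np.median(vals)) if len(vals) else np.nan,
                "W": np.nan,
                "p-value": np.nan,
                "sig": "",
                "flag": flag,
            }
            if j == 0 and result is not None:
                row["W"] = result.W
                row["p-value"] = result.p
                row["sig"] = result.significance
            rows.append(row)
        pvals.append(result.p if result is not None else None)

    table = pd.DataFrame(rows, columns=TABLE_COLUMNS + ["sig", "flag"])
    if adjust != "none":
        from statsmodels.stats.multitest import multipletests

        method = {"holm": "holm", "bh": "fdr_bh"}.get(adjust)
        if method is None:
            raise InvalidInputError(f"unknown adjustment {adjust!r}")
        idx = [i for i, p in enumerate(pvals) if p is not None]
        adj = np.full(len(pvals), np.nan)
        if idx:
            adj[idx] = multipletests([pvals[i] for i in idx], method=method)[1]
        padj_col = np.full(len(table), np.nan)
        padj_col[::2][: len(adj)] = adj  # first row of each pair
        table["p-adjusted"] = padj_col
    return table
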