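"""Significance testing of expression differences on the ΔCT scale.

The tested quantity is the per-row ΔCT = CT(target) − CT(reference
gene).  The difference in mean ΔCT between a condition and the
reference (control) group is exactly the ΔΔCT, so every method below
estimates ΔΔCT with a p-value and confidence interval; negative
estimates mean up-regulation of the target in the condition.

Methods
-------
``t_test``
    Two-sample t-test (Welch by default; ``pooled=True`` for the
    classical equal-variance variant).
``wilcoxon``
    Wilcoxon rank-sum (Mann–Whitney) test with the Hodges–Lehmann
    location estimate — the median of all pairwise
    treatment-minus-control ΔCT differences — and the matching interval
    obtained by inverting the rank-sum test over the ordered pairwise
    differences.
``linear_model``
    OLS of ΔCT on group indicators with the reference group as
    baseline; supports more than two groups, each non-baseline
    coefficient being that group's ΔΔCT.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .data_io import CtTable

__all__ = [
    "TestResult",
    "delta_ct_by_row",
    "hodges_lehmann",
    "rank_sum_interval",
    "two_group_test",
    "tests_to_frame",
]

METHODS = ("t_test", "wilcoxon", "linear_model")
EXACT_LIMIT = 400  # largest n*m for the exact rank-sum null distribution


@dataclass(frozen=True)
class TestResult:
    gene: str
    estimate: float   # delta-delta-CT, cycles
    p_value: float
    lower: float
    upper: float
    method: str
    term: str = ""


def delta_ct_by_row(table: CtTable, reference_gene: str) -> pd.DataFrame:
    """Per-row ΔCT of every non-reference gene, with group labels.

    Rows missing either the target or the reference CT are dropped with
    a warning (the pairing is broken).
    """
    if reference_gene not in table.genes:
        raise ValueError(f"unknown reference gene {reference_gene!r}")
    ref = table.values[reference_gene]
    frames = []
    for gene in table.genes:
        if gene == reference_gene:
            continue
        d = table.values[gene] - ref
        df = pd.DataFrame({"row": d.index, "gene": gene, "delta_ct": d})
        if table.group is not None:
            df.insert(0, "group", table.group)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    n_na = int(out["delta_ct"].isna().sum())
    if n_na:
        warnings.warn(f"dropped {n_na} row(s) with missing CT", UserWarning, stacklevel=2)
        out = out.dropna(subset=["delta_ct"]).reset_index(drop=True)
    return out


def hodges_lehmann(x, y) -> float:
    """Median of the n·m pairwise differences yᵢ − xⱼ (y relative to x)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    return float(np.median(np.subtract.outer(y, x)))


@lru_cache(maxsize=None)
def _rank_sum_cdf(n: int, m: int) -> np.ndarray:
    """Null CDF of the Mann–Whitney U statistic for sample sizes n, m.

    Standard counting recurrence
    c(u; n, m) = c(u − m; n − 1, m) + c(u; n, m − 1); exact and O(n·m·nm).
    """
    table = np.zeros((n + 1, m + 1, n * m + 1))
    table[0, :, 0] = 1.0
    table[:, 0, 0] = 1.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            table[i, j, :] = table[i, j - 1, :]
            shifted = np.zeros(n * m + 1)
            shifted[j:] = table[i - 1, j, : n * m + 1 - j]
            table[i, j, :] += shifted
    pmf = table[n, m]
    pmf /= pmf.sum()
    return np.cumsum(pmf)


def _rank_sum_quantile(alpha: float, n: int, m: int) -> int:
    """Smallest u with P(U ≤ u) ≥ alpha under the exact null."""
    cdf = _rank_sum_cdf(n, m)
    return int(np.searchsorted(cdf, alpha - 1e-12, side="left"))


def rank_sum_interval(x, y, conf_level: float = 0.95) -> tuple[float, float, float]:
    """Hodges–Lehmann estimate and rank-sum-inverted CI for y − x.

    Exact null distribution when n·m ≤ 400; otherwise the normal
    approximation u ≈ nm/2 − z·√(nm(n+m+1)/12) picks the order
    statistics of the sorted pairwise differences.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = x.size, y.size
    diffs = np.sort(np.subtract.outer(y, x).ravel())
    est = float(np.median(diffs))
    alpha = 1.0 - conf_level
    if n * m <= EXACT_LIMIT:
        qu = _rank_sum_quantile(alpha / 2.0, n, m)
    else:
        z = stats.norm.ppf(alpha / 2.0)
        qu = int(np.floor(n * m / 2.0 + z * np.sqrt(n * m * (n + m + 1) / 12.0)))
        qu = max(qu, 0)
    qu = max(qu, 1)  # never an empty interval
    lower = float(diffs[qu - 1])
    upper = float(diffs[n * m - qu])
    return est, lower, upper


def two_group_test(
    table: CtTable,
    reference_gene: str,
    reference_group: str,
    method: str = "t_test",
    conf_level: float = 0.95,
    pooled: bool = False,
    adjust_p: bool = False,
) -> list[TestResult]:
    """Test each target gene's ΔΔCT against zero.

    ``t_test`` and ``wilcoxon`` require exactly two groups;
    ``linear_model`` accepts any number, reporting one result per
    non-reference group coefficient.  ``adjust_p=True`` applies a
    Benjamini–Hochberg correction across target genes.
    """
    if method == "lm":
        method = "linear_model"
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS} (or 'lm')")
    if table.group is None:
        raise ValueError("table has no group labels")
    labels = list(pd.unique(pd.Series(table.group)))
    if reference_group not in labels:
        raise ValueError(f"unknown reference group {reference_group!r}")
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    if method in ("t_test", "wilcoxon") and len(labels) != 2:
        raise ValueError(f"{method} requires exactly 2 groups; use linear_model")

    dct = delta_ct_by_row(table, reference_gene)
    alpha = 1.0 - conf_level
    results: list[TestResult] = []
    for gene, sub in dct.groupby("gene", sort=False):
        by = {lab: g["delta_ct"].to_numpy() for lab, g in sub.groupby("group")}
        if any(v.size < 2 for v in by.values()):
            raise ValueError(f"gene {gene}: every group needs at least 2 delta-CT values")
        ctrl = by[reference_group]
        if method == "t_test":
            (treat_lab,) = [lab for lab in labels if lab != reference_group]
            treat = by[treat_lab]
            if np.ptp(treat) == 0 and np.ptp(ctrl) == 0:
                raise ValueError(f"gene {gene}: zero variance in both groups")
            res = stats.ttest_ind(treat, ctrl, equal_var=pooled)
            ci = res.confidence_interval(conf_level)
            results.append(
                TestResult(gene, float(treat.mean() - ctrl.mean()), float(res.pvalue),
                           float(ci.low), float(ci.high), "t_test")
            )
        elif method == "wilcoxon":
            (treat_lab,) = [lab for lab in labels if lab != reference_group]
            treat = by[treat_lab]
            ties = len(np.unique(np.concatenate([treat, ctrl]))) < treat.size + ctrl.size
            exact = treat.size * ctrl.size <= EXACT_LIMIT and not ties
            mw = stats.mannwhitneyu(
                treat, ctrl, alternative="two-sided",
                method="exact" if exact else "asymptotic",
                use_continuity=True,
            )
            est, lo, hi = rank_sum_interval(ctrl, treat, conf_level)
            results.append(TestResult(gene, est, float(mw.pvalue), lo, hi, "wilcoxon"))
        else:
            # explicit treatment-coded design with the reference group as baseline
            others = [lab for lab in labels if lab != reference_group]
            grp = sub["group"].to_numpy()
            X = np.column_stack(
                [np.ones(len(sub))] + [(grp == lab).astype(float) for lab in others]
            )
            fit = sm.OLS(sub["delta_ct"].to_numpy(), X).fit()
            ci = fit.conf_int(alpha=alpha)
            for i, lab in enumerate(others, start=1):
                results.append(
                    TestResult(gene, float(fit.params[i]), float(fit.pvalues[i]),
                               float(ci[i, 0]), float(ci[i, 1]),
                               "linear_model", term=f"group[T.{lab}]")
                )
    if adjust_p and len(results) > 1:
        from statsmodels.stats.multitest import multipletests

        padj = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        results = [
            TestResult(r.gene, r.estimate, float(p), r.lower, r.upper, r.method, r.term)
            for r, p in zip(results, padj)
        ]
    return results


def tests_to_frame(results: Sequence[TestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"gene": r.gene, "estimate": r.estimate, "p_value": r.p_value,
             "lower": r.lower, "upper": r.upper, "term": r.term, "method": r.method}
            for r in results
        ]
    )
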