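"""Relative quantification of target-gene expression.

Two models, each normalizing a target gene by a reference (housekeeping)
gene and calibrating against a reference group:

* **Comparative (ΔΔCT)** — assumes near-perfect, equal amplification
  efficiency of all genes.  ΔCT = CT(target) − CT(reference) within a
  group, ΔΔCT = ΔCT(group) − ΔCT(calibrator group), and the relative
  expression is 2^(−ΔΔCT).  The SD of a CT difference combines the two
  SDs as s = √(s₁² + s₂²).
* **Relative standard curve** — uses per-gene calibration lines fit from
  a dilution series to convert each CT to an input amount,
  amount = 10^((CT − b)/m), then works with ratios of amounts.  Errors
  of ratios combine on the coefficient-of-variation scale,
  cv = √(cv₁² + cv₂²), with s = cv · X̄.

Both models come in two modes.  ``separate_tube`` (default): target and
reference genes were measured in different reactions, so genes are
averaged per group first and then combined.  ``same_tube``: each row is
one reaction measuring both genes, so the per-row pairing is preserved —
subtract (or ratio) within a row first, then average; a row missing
either gene is dropped entirely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_io import CtTable

__all__ = [
    "ExpressionResult",
    "propagate_sd",
    "combine_cv",
    "delta_delta_ct",
    "relative_curve",
    "results_to_frame",
]

MODES = ("separate_tube", "same_tube")


@dataclass(frozen=True)
class ExpressionResult:
    """Relative expression of one target gene in one group.

    ``normalized`` is the ΔCT (cycles) under the comparative model or
    the amount ratio target/reference under the curve model;
    ``calibrated`` is the ΔΔCT or the amount relative to the calibrator
    group; ``fold_change`` is 2^(−ΔΔCT) or that same relative amount.
    ``lower``/``upper`` bound a ±1 SD interval on the fold-change scale.
    """

    group: str
    gene: str
    normalized: float
    calibrated: float
    fold_change: float
    error: float
    lower: float
    upper: float


def propagate_sd(s1: float, s2: float) -> float:
    """SD of a difference of independent means: √(s₁² + s₂²)."""
    if s1 < 0 or s2 < 0:
        raise ValueError("standard deviations must be non-negative")
    return math.hypot(s1, s2)


def combine_cv(cv1: float, cv2: float) -> float:
    """CV of a ratio of independent quantities: √(cv₁² + cv₂²)."""
    if cv1 < 0 or cv2 < 0:
        raise ValueError("coefficients of variation must be non-negative")
    return math.hypot(cv1, cv2)


def _check_design(table: CtTable, reference_gene: str, reference_group: str, mode: str):
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if table.group is None:
        raise ValueError("table has no group labels")
    if reference_gene not in table.genes:
        raise ValueError(f"unknown reference gene {reference_gene!r}")
    labels = list(pd.unique(pd.Series(table.group)))
    if reference_group not in labels:
        raise ValueError(f"unknown reference group {reference_group!r}")
    for lab in labels:
        if int(np.sum(table.group == lab)) < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 replicates; SD undefined")
    # calibrator first so per-group results are computed against it
    labels.remove(reference_group)
    return [reference_group] + labels


def delta_delta_ct(
    table: CtTable,
    reference_gene: str,
    reference_group: str,
    mode: str = "separate_tube",
) -> list[ExpressionResult]:
    """Comparative ΔΔCT quantification of every non-reference gene.

    Per group: ``separate_tube`` takes ΔCT as the difference of the two
    genes' mean CTs with SD √(s₁² + s₂²); ``same_tube`` averages per-row
    ΔCTs and uses their sample SD.  ΔΔCT subtracts the calibrator
    group's ΔCT; each group's interval carries its *own* SD only (the
    calibrator's error is not re-propagated), so the calibrator reports
    ΔΔCT = 0 and fold change 1 exactly, with interval
    (2^(−s), 2^(+s)) reflecting its replicate scatter.
    """
    groups = _check_design(table, reference_gene, reference_group, mode)
    per_group: dict[str, tuple[float, float]] = {}
    for lab in groups:
        sub = table.values[table.group == lab]
        ref = sub[reference_gene]
        out = {}
        for gene in table.genes:
            if gene == reference_gene:
                continue
            if mode == "separate_tube":
                dct = sub[gene].mean() - ref.mean()
                s = propagate_sd(sub[gene].std(ddof=1), ref.std(ddof=1))
            else:
                d = (sub[gene] - ref).dropna()
                if len(d) < 2:
                    raise ValueError(f"group {lab!r}, gene {gene}: fewer than 2 paired rows")
                dct, s = d.mean(), d.std(ddof=1)
            out[gene] = (float(dct), float(s))
        per_group[lab] = out

    results = []
    for lab in groups:
        for gene, (dct, s) in per_group[lab].items():
            if lab == reference_group:
                ddct = 0.0
            else:
                ddct = dct - per_group[reference_group][gene][0]
            results.append(
                ExpressionResult(
                    group=lab,
                    gene=gene,
                    normalized=dct,
                    calibrated=ddct,
                    fold_change=2.0**-ddct,
                    error=s,
                    lower=2.0 ** -(ddct + s),
                    upper=2.0 ** -(ddct - s),
                )
            )
    return results


def _as_curve_map(curves) -> dict[str, tuple[float, float]]:
    """Accept list of CurveFit-likes or mapping gene -> (slope, intercept)."""
    if isinstance(curves, Mapping):
        out = {g: (float(m), float(b)) for g, (m, b) in curves.items()}
    else:
        out = {c.gene: (float(c.slope), float(c.intercept)) for c in curves}
    for gene, (m, _) in out.items():
        if m == 0:
            raise ValueError(f"curve for {gene!r} has zero slope")
    return out


def ct_to_amount(ct, slope: float, intercept: float):
    """Invert a standard curve: amount = 10^((CT − b)/m)."""
    if slope == 0:
        raise ValueError("zero slope")
    return 10.0 ** ((np.asarray(ct, dtype=float) - intercept) / slope)


def relative_curve(
    table: CtTable,
    reference_gene: str,
    reference_group: str,
    curves,
    mode: str = "separate_tube",
) -> list[ExpressionResult]:
    """Relative standard-curve quantification.

    Every CT is converted to an input amount via its gene's calibration
    line; the target amount is normalized by the reference gene's and
    calibrated by the reference group's normalized value.  Error
    combines CVs: the normalized amount's SD is √(cv₁² + cv₂²) · X̄, and
    a group's relative expression carries that group's own CV (the
    calibrator's is not re-propagated).  The interval is
    fold_change ± SD, floored at 0 on the lower side (amounts are
    positive by construction).
    """
    groups = _check_design(table, reference_gene, reference_group, mode)
    cmap = _as_curve_map(curves)
    missing = [g for g in table.genes if g not in cmap]
    if missing:
        raise ValueError(f"no curve supplied for gene(s) {missing}")

    per_group: dict[str, dict[str, tuple[float, float]]] = {}
    for lab in groups:
        sub = table.values[table.group == lab]
        amounts = {
            gene: pd.Series(ct_to_amount(sub[gene], *cmap[gene]), index=sub.index)
            for gene in table.genes
        }
        ref = amounts[reference_gene]
        out = {}
        for gene in table.genes:
            if gene == reference_gene:
                continue
            if mode == "separate_tube":
                a, r = amounts[gene].dropna(), ref.dropna()
                norm = a.mean() / r.mean()
                cv = combine_cv(a.std(ddof=1) / a.mean(), r.std(ddof=1) / r.mean())
            else:
                ratio = (amounts[gene] / ref).dropna()
                if len(ratio) < 2:
                    raise ValueError(f"group {lab!r}, gene {gene}: fewer than 2 paired rows")
                norm = ratio.mean()
                cv = ratio.std(ddof=1) / ratio.mean()
            out[gene] = (float(norm), float(cv))
        per_group[lab] = out

    results = []
    for lab in groups:
        for gene, (norm, cv) in per_group[lab].items():
            if lab == reference_group:
                rel = 1.0
            else:
                rel = norm / per_group[reference_group][gene][0]
            err = cv * rel
            results.append(
                ExpressionResult(
                    group=lab,
                    gene=gene,
                    normalized=norm,
                    calibrated=rel,
                    fold_change=rel,
                    error=err,
                    lower=max(rel - err, 0.0),
                    upper=rel + err,
                )
            )
    return results


def results_to_frame(results: Sequence[ExpressionResult]) -> pd.DataFrame:
    """Tabulate expression results (fold change column named
    ``relative_expression``)."""
    return pd.DataFrame(
        [
            {
                "group": r.group,
                "gene": r.gene,
                "normalized": r.normalized,
                "calibrated": r.calibrated,
                "relative_expression": r.fold_change,
                "error": r.error,
                "lower": r.lower,
                "upper": r.upper,
            }
            for r in results
        ]
    )
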