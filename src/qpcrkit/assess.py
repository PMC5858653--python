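"""Quality assessment from serial-dilution experiments.

Two checks are computed from a dilution series:

* **Standard curves** — per-gene ordinary least squares of CT on
  log10(input amount).  The slope ``m`` gives the amplification
  efficiency ``E = 10^(−1/m)``; perfect doubling gives ``m ≈ −3.32`` and
  ``E = 2``, and ``R²`` should be close to 1.
* **Efficiency (ΔΔCT-model assumption) check** — the trend of
  ΔCT = CT(target) − CT(reference) against log10(amount).  When target
  and reference amplify equally efficiently the ΔCT is independent of
  input amount, so the slope should be very small (|slope| ≤ 0.1 is the
  conventional rule of thumb).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import CtTable
from .quantify import propagate_sd

__all__ = [
    "CurveFit",
    "EfficiencyReport",
    "EfficiencyAssessment",
    "fit_line",
    "standard_curve",
    "assess_efficiency",
    "delta_ct_summary",
]


class LineFit(NamedTuple):
    slope: float
    intercept: float
    r_squared: float


@dataclass(frozen=True)
class CurveFit:
    """Per-gene calibration line of CT on log10 input amount."""

    gene: str
    slope: float       # cycles per log10 ng
    intercept: float   # cycles at 1 ng
    r_squared: float
    efficiency: float  # 10^(-1/slope); 2 = perfect doubling

    @property
    def efficiency_percent(self) -> float:
        """Efficiency on the (E − 1) × 100 percentage scale."""
        return (self.efficiency - 1.0) * 100.0


@dataclass(frozen=True)
class EfficiencyReport:
    """Trend of ΔCT(target − reference) against log10 input amount."""

    gene: str
    slope: float
    intercept: float
    r_squared: float


@dataclass
class EfficiencyAssessment:
    """ΔCT trends per target gene plus all per-gene standard curves."""

    trends: list[EfficiencyReport]
    curves: list[CurveFit]
    warnings: list[str] = field(default_factory=list)


def fit_line(x, y) -> LineFit:
    """Ordinary least squares of y on x with R² = squared Pearson r.

    Replicate y values at each x are fit at replicate level.  Raises if
    fewer than two distinct x values remain (degenerate design).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 2 or np.ptp(x) == 0:
        raise ValueError("degenerate design: need at least 2 distinct x values")
    res = stats.linregress(x, y)
    r2 = res.rvalue**2
    if np.isnan(r2):  # constant y: horizontal line, no variance to explain
        r2 = 0.0
    return LineFit(float(res.slope), float(res.intercept), float(r2))


def _require_amount(table: CtTable) -> np.ndarray:
    if table.amount is None:
        raise ValueError("table has no input-amount annotation")
    if len(np.unique(table.amount)) < 2:
        raise ValueError("need at least 2 dilution levels")
    return np.log10(table.amount)


def standard_curve(table: CtTable) -> list[CurveFit]:
    """Fit a CT-vs-log10(amount) line per gene over all replicates."""
    logx = _require_amount(table)
    fits = []
    for gene in table.genes:
        line = fit_line(logx, table.values[gene])
        eff = 10.0 ** (-1.0 / line.slope) if line.slope != 0 else float("nan")
        fits.append(CurveFit(gene, line.slope, line.intercept, line.r_squared, eff))
    return fits


def assess_efficiency(
    table: CtTable,
    reference_gene: str,
    max_trend_slope: float = 0.1,
    efficiency_range: tuple[float, float] = (1.8, 2.2),
) -> EfficiencyAssessment:
    """ΔCT-trend check for the comparative (ΔΔCT) method.

    ΔCT is computed per replicate row (target minus reference within the
    same row of the dilution level) and regressed on log10(amount); each
    gene's standard-curve efficiency is reported alongside.  Quality
    thresholds are advisory only: findings outside them are listed in
    ``assessment.warnings``, never enforced.
    """
    if reference_gene not in table.genes:
        raise ValueError(f"unknown reference gene {reference_gene!r}")
    logx = _require_amount(table)
    curves = standard_curve(table)
    trends: list[EfficiencyReport] = []
    warns: list[str] = []
    ref = table.values[reference_gene].to_numpy()
    for gene in table.genes:
        if gene == reference_gene:
            continue
        dct = table.values[gene].to_numpy() - ref
        line = fit_line(logx, dct)
        trends.append(EfficiencyReport(gene, line.slope, line.intercept, line.r_squared))
        if abs(line.slope) > max_trend_slope:
            warns.append(
                f"{gene}: |dCT trend slope| = {abs(line.slope):.3g} exceeds "
                f"{max_trend_slope:g}; amplification efficiencies may differ"
            )
    lo, hi = efficiency_range
    for cf in curves:
        if not (lo <= cf.efficiency <= hi):
            warns.append(
                f"{cf.gene}: efficiency {cf.efficiency:.3g} outside [{lo:g}, {hi:g}]"
            )
    return EfficiencyAssessment(trends, curves, warns)


def delta_ct_summary(table: CtTable, reference_gene: str) -> pd.DataFrame:
    """Per-dilution ΔCT mean ± SD for each target gene.

    The SD combines the two genes' per-dilution sample SDs as
    √(s₁² + s₂²) (separate-tube convention).  This is the numeric
    content of the ΔCT-trend diagnostic plot.
    """
    if table.amount is None:
        raise ValueError("table has no input-amount annotation")
    if reference_gene not in table.genes:
        raise ValueError(f"unknown reference gene {reference_gene!r}")
    rows = []
    df = table.values.assign(_amount=table.amount)
    for amount, sub in df.groupby("_amount", sort=False):
        ref_m = sub[reference_gene].mean()
        ref_s = sub[reference_gene].std(ddof=1)
        for gene in table.genes:
            if gene == reference_gene:
                continue
            rows.append(
                {
                    "gene": gene,
                    "amount": amount,
                    "delta_ct": sub[gene].mean() - ref_m,
                    "sd": propagate_sd(sub[gene].std(ddof=1), ref_s),
                }
            )
    return pd.DataFrame(rows).sort_values(["gene", "amount"], ascending=[True, False]).reset_index(drop=True)


def curves_to_frame(curves: list[CurveFit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": c.gene,
                "slope": c.slope,
                "intercept": c.intercept,
                "r_squared": c.r_squared,
                "efficiency": c.efficiency,
            }
            for c in curves
        ]
    )


def trends_to_frame(trends: list[EfficiencyReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"gene": t.gene, "slope": t.slope, "intercept": t.intercept,
             "r_squared": t.r_squared}
            for t in trends
        ]
    )
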