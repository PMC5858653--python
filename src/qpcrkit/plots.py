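"""Plot-ready data frames and matplotlib figures.

Every figure has a numeric companion: the ``*_plot_data`` functions
return exactly the points, error bars and fitted lines drawn, so
figures can be tested and re-styled without image comparison.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .assess import CurveFit, delta_ct_summary
from .data_io import CtTable
from .quantify import ExpressionResult, results_to_frame

__all__ = [
    "dilution_plot_data",
    "plot_standard_curves",
    "plot_efficiency_trend",
    "plot_expression",
]


def dilution_plot_data(table: CtTable) -> pd.DataFrame:
    """Per-(gene, dilution) mean ± SD of CT, for standard-curve panels."""
    if table.amount is None:
        raise ValueError("table has no input-amount annotation")
    df = table.values.assign(_amount=table.amount)
    agg = (
        df.melt(id_vars="_amount", var_name="gene", value_name="ct")
        .groupby(["gene", "_amount"])["ct"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1))
        .reset_index()
        .rename(columns={"_amount": "amount"})
    )
    return agg.sort_values(["gene", "amount"], ascending=[True, False]).reset_index(drop=True)


def plot_standard_curves(table: CtTable, curves: list[CurveFit], ax=None):
    """Per-dilution mean ± SD points with the fitted line per gene."""
    data = dilution_plot_data(table)
    if ax is None:
        _, ax = plt.subplots()
    for cf in curves:
        sub = data[data["gene"] == cf.gene]
        x = np.log10(sub["amount"])
        ax.errorbar(x, sub["mean"], yerr=sub["sd"], fmt="o", capsize=3, label=cf.gene)
        xx = np.linspace(x.min(), x.max(), 50)
        ax.plot(xx, cf.intercept + cf.slope * xx, "-", lw=1)
    ax.set_xlabel("log10 input amount (ng)")
    ax.set_ylabel("CT (cycles)")
    ax.legend()
    return ax


def plot_efficiency_trend(table: CtTable, reference_gene: str, trends, ax=None):
    """ΔCT mean ± SD per dilution with the fitted trend per target gene."""
    data = delta_ct_summary(table, reference_gene)
    if ax is None:
        _, ax = plt.subplots()
    for tr in trends:
        sub = data[data["gene"] == tr.gene]
        x = np.log10(sub["amount"])
        ax.errorbar(x, sub["delta_ct"], yerr=sub["sd"], fmt="o", capsize=3, label=tr.gene)
        xx = np.linspace(x.min(), x.max(), 50)
        ax.plot(xx, tr.intercept + tr.slope * xx, "-", lw=1)
    ax.set_xlabel("log10 input amount (ng)")
    ax.set_ylabel(f"delta CT (target − {reference_gene})")
    ax.legend()
    return ax


def plot_expression(results: list[ExpressionResult], ax=None):
    """Grouped bars of relative expression with error bars."""
    df = results_to_frame(results)
    if ax is None:
        _, ax = plt.subplots()
    pos = np.arange(len(df))
    yerr = np.vstack(
        [df["relative_expression"] - df["lower"], df["upper"] - df["relative_expression"]]
    )
    ax.bar(pos, df["relative_expression"], yerr=np.maximum(yerr, 0), capsize=4)
    ax.set_xticks(pos)
    ax.set_xticklabels([f"{g}\n{t}" for g, t in zip(df["group"], df["gene"])])
    ax.set_ylabel("relative expression")
    return ax
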