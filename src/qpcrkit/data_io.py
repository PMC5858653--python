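"""Data model and CSV I/O for cycle-threshold (CT) tables.

A :class:`CtTable` holds replicate-level CT measurements in wide layout:
rows are samples (reactions / cDNA preparations), columns are genes.  A
table optionally carries exactly one per-row annotation — a categorical
group label (control-vs-condition experiments) or a known input-RNA
amount in ng (serial-dilution experiments).
"""

from __future__ import annotations

import csv
import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CtTable",
    "Issue",
    "ValidationReport",
    "read_ct_table",
    "validate",
    "write_table",
]


class CtTableError(ValueError):
    """Malformed CT table or annotation."""


@dataclass
class CtTable:
    """Replicate-level CT measurements, rows = samples, columns = genes.

    Parameters
    ----------
    values :
        DataFrame of CT values (cycles); NaN marks a missing/undetermined
        reaction.  Column order is the gene order.
    group :
        Optional per-row categorical label (e.g. ``"brain"`` / ``"kidney"``).
    amount :
        Optional per-row input RNA amount in ng (positive), for
        serial-dilution experiments.  Mutually exclusive with ``group``.
    """

    values: pd.DataFrame
    group: np.ndarray | None = None
    amount: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = pd.DataFrame(self.values)
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()]
            raise CtTableError(f"duplicate gene columns: {sorted(set(dupes))}")
        self.values = self.values.astype(float).reset_index(drop=True)
        if (self.values.to_numpy() < 0).any():
            raise CtTableError("CT values must be non-negative or missing")
        if self.group is not None and self.amount is not None:
            raise CtTableError("a table carries either group labels or amounts, not both")
        if self.group is not None:
            self.group = np.asarray(self.group, dtype=object)
            if len(self.group) != self.n_rows:
                raise CtTableError(
                    f"group has length {len(self.group)}, table has {self.n_rows} rows"
                )
        if self.amount is not None:
            self.amount = np.asarray(self.amount, dtype=float)
            if len(self.amount) != self.n_rows:
                raise CtTableError(
                    f"amount has length {len(self.amount)}, table has {self.n_rows} rows"
                )
            if not np.all(self.amount > 0):
                raise CtTableError("input amounts must be positive")

    @property
    def genes(self) -> list[str]:
        return [str(g) for g in self.values.columns]

    @property
    def n_rows(self) -> int:
        return len(self.values)

    def copy(self) -> "CtTable":
        return CtTable(
            self.values.copy(),
            None if self.group is None else self.group.copy(),
            None if self.amount is None else self.amount.copy(),
        )


@dataclass(frozen=True)
class Issue:
    severity: str  # "warning" | "error"
    code: str
    message: str
    location: str = ""


@dataclass
class ValidationReport:
    issues: list[Issue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    @property
    def errors(self) -> list[Issue]:
        return [i for i in self.issues if i.severity == "error"]

    @property
    def warnings(self) -> list[Issue]:
        return [i for i in self.issues if i.severity == "warning"]

    def add(self, severity: str, code: str, message: str, location: str = "") -> None:
        self.issues.append(Issue(severity, code, message, location))


def _read_text(source) -> str:
    if hasattr(source, "read"):
        return source.read()
    return Path(source).read_text(encoding="utf-8")


def read_ct_table(
    source,
    group_var: str | Sequence | None = None,
    amount: str | Sequence | None = None,
    long_format: bool = False,
) -> CtTable:
    """Read a CT table from a CSV path or text stream.

    The default (wide) layout expects a header row of gene names and a
    numeric body; non-numeric cells (``"undetermined"`` etc.) become
    missing values and a :class:`UserWarning` is emitted.  With
    ``long_format=True`` the file must have columns ``sample,gene,ct``
    and is pivoted to wide layout.

    ``group_var`` / ``amount`` may be a column name present in the CSV
    (the column is removed from the CT matrix) or a sequence of per-row
    values supplied directly.
    """
    text = _read_text(source)
    header = next(csv.reader(io.StringIO(text)))
    if len(header) != len(set(header)):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise CtTableError(f"duplicate gene columns in header: {dupes}")
    df = pd.read_csv(io.StringIO(text), dtype=str, skipinitialspace=True)

    if long_format:
        need = {"sample", "gene", "ct"}
        if not need.issubset(df.columns):
            raise CtTableError("long format requires columns sample,gene,ct")
        df = df.pivot(index="sample", columns="gene", values="ct").reset_index(drop=True)
        df.columns.name = None

    def _pop(spec, kind):
        if spec is None or not isinstance(spec, str):
            return df, spec
        if spec not in df.columns:
            raise CtTableError(f"{kind} column {spec!r} not found in CSV")
        col = df[spec]
        return df.drop(columns=[spec]), col.to_numpy()

    df, group_vals = _pop(group_var, "group")
    df, amount_vals = _pop(amount, "amount")
    if group_vals is None and group_var is not None:
        group_vals = np.asarray(list(group_var), dtype=object)
    if amount_vals is None and amount is not None:
        amount_vals = np.asarray(list(amount), dtype=float)

    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        n_bad = int(bad.to_numpy().sum())
        warnings.warn(
            f"{n_bad} non-numeric CT cell(s) treated as missing", UserWarning, stacklevel=2
        )
    return CtTable(numeric, group=group_vals, amount=amount_vals)


def validate(
    table: CtTable,
    reference_gene: str | None = None,
    reference_group: str | None = None,
) -> ValidationReport:
    """Check a table against the requirements of downstream analyses.

    All problems are returned in the report — nothing raises.  Errors:
    unknown reference gene/group, fewer than two genes for normalized
    analysis, any group with fewer than two rows (sample SD undefined).
    Warnings: missing cells, unbalanced group sizes.
    """
    rep = ValidationReport()
    if reference_gene is not None:
        if reference_gene not in table.genes:
            rep.add("error", "unknown-reference",
                    f"reference gene {reference_gene!r} not among {table.genes}")
        elif len(table.genes) < 2:
            rep.add("error", "too-few-genes",
                    "reference-normalized analysis needs at least 2 genes")
    if reference_group is not None:
        if table.group is None:
            rep.add("error", "no-groups", "reference_group given but table has no group labels")
        elif reference_group not in set(table.group):
            rep.add("error", "unknown-reference-group",
                    f"reference group {reference_group!r} not among {sorted(set(map(str, table.group)))}")
    if table.group is not None:
        sizes = pd.Series(table.group).value_counts()
        for label, n in sizes.items():
            if n < 2:
                rep.add("error", "too-few-replicates",
                        f"group {label!r} has {n} row(s); sample SD needs at least 2",
                        location=str(label))
        if sizes.nunique() > 1:
            rep.add("warning", "unbalanced-groups",
                    f"group sizes differ: {dict(sizes)}")
    na = table.values.isna()
    if na.to_numpy().any():
        cells = [f"(row {r}, {c})" for r, c in zip(*np.where(na.to_numpy()))]
        rep.add("warning", "missing-cells",
                f"{len(cells)} missing CT cell(s)", location="; ".join(cells[:10]))
    return rep


def write_table(result, dest) -> None:
    """Write a tabular result to CSV with a stable column order.

    ``result`` may be a DataFrame or a list of result dataclasses (any of
    the package's *Result / *Fit types).  Numeric values are written at 6
    significant digits so a write→read→write cycle is byte-identical.
    """
    df = _as_frame(result)
    if df is None or len(df) == 0:
        raise ValueError("refusing to write an empty result")
    df.to_csv(dest, index=False, float_format="%.6g")


def _as_frame(result) -> pd.DataFrame | None:
    if isinstance(result, pd.DataFrame):
        return result
    if isinstance(result, CtTable):
        return result.values
    if isinstance(result, Iterable):
        rows = list(result)
        if not rows:
            return None
        from dataclasses import asdict, is_dataclass

        if all(is_dataclass(r) for r in rows):
            return pd.DataFrame([asdict(r) for r in rows])
        return pd.DataFrame(rows)
    raise TypeError(f"cannot serialise {type(result).__name__}")
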