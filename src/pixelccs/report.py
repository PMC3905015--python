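"""Predicted-vs-measured and method-comparison reporting.

Joins predicted CCS values against measured CCS (from ion mobility) and,
optionally, against reference predictions from projection approximation (PA)
and exact hard-sphere scattering (EHSS) calculators.  PA/EHSS values are
carried as supplied inputs, never recomputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd


class ReportError(ValueError):
    pass


def percent_of_measured(predicted: float, measured: float) -> float:
    """Predicted as a percentage of measured, truncated to one decimal.

    Truncation (floor at one decimal place), not rounding: the convention
    reported alongside the reference predicted/measured pairs is reproduced
    by truncation only.
    """
    if measured <= 0:
        raise ReportError(f"measured CCS must be > 0, got {measured}")
    # round away last-ulp noise so equal ratios truncate identically
    return math.floor(round(1000.0 * predicted / measured, 6)) / 10.0


@dataclass(frozen=True)
class ComparisonRow:
    """One protein's predicted/measured/reference comparison."""

    protein: str
    predicted_ccs: float  # Å²
    measured_ccs: float  # Å²
    percent_of_measured: float  # one decimal, truncated
    reference_pa: float | None = None  # Å²
    reference_ehss: float | None = None  # Å²
    between_pa_ehss: bool | None = None  # None when references missing
    annotation: str = ""


def build_comparison(predictions: pd.DataFrame, measured_table: pd.DataFrame,
                     reference_table: pd.DataFrame | None = None
                     ) -> tuple[list[ComparisonRow], dict]:
    """Join per-protein tables and compute the between-PA/EHSS fraction.

    predictions      : columns protein, predicted_A2
    measured_table   : columns protein, measured_A2 (optional column
                       ``annotation`` is carried through)
    reference_table  : optional, columns protein, pa_A2, ehss_A2

    "Between" uses the closed interval min(PA, EHSS) <= predicted <=
    max(PA, EHSS); proteins without both references are excluded from the
    fraction's denominator and flagged n/a.
    """
    for df, cols, label in ((predictions, ("protein", "predicted_A2"), "predictions"),
                            (measured_table, ("protein", "measured_A2"), "measured")):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ReportError(f"{label} table missing column(s) {missing}")
    merged = predictions.merge(measured_table, on="protein", how="inner")
    if merged.empty:
        raise ReportError("no proteins common to predictions and measured tables")
    if reference_table is not None:
        merged = merged.merge(reference_table, on="protein", how="left")
    else:
        merged = merged.assign(pa_A2=float("nan"), ehss_A2=float("nan"))

    rows: list[ComparisonRow] = []
    n_with_refs = 0
    n_between = 0
    for r in merged.itertuples(index=False):
        pa = float(r.pa_A2) if pd.notna(r.pa_A2) else None
        ehss = float(r.ehss_A2) if pd.notna(r.ehss_A2) else None
        between: bool | None = None
        if pa is not None and ehss is not None:
            between = min(pa, ehss) <= float(r.predicted_A2) <= max(pa, ehss)
            n_with_refs += 1
            n_between += int(between)
        rows.append(ComparisonRow(
            protein=str(r.protein),
            predicted_ccs=float(r.predicted_A2),
            measured_ccs=float(r.measured_A2),
            percent_of_measured=percent_of_measured(float(r.predicted_A2),
                                                    float(r.measured_A2)),
            reference_pa=pa,
            reference_ehss=ehss,
            between_pa_ehss=between,
            annotation=str(getattr(r, "annotation", "") or ""),
        ))
    summary = {
        "n_proteins": len(rows),
        "n_with_references": n_with_refs,
        "n_between_pa_ehss": n_between,
        "fraction_between_pa_ehss":
            (n_between / n_with_refs) if n_with_refs else None,
    }
    return rows, summary


def comparison_to_frame(rows: Sequence[ComparisonRow]) -> pd.DataFrame:
    return pd.DataFrame({
        "protein": [r.protein for r in rows],
        "predicted_A2": [r.predicted_ccs for r in rows],
        "measured_A2": [r.measured_ccs for r in rows],
        "percent_of_measured": [r.percent_of_measured for r in rows],
        "pa_A2": [r.reference_pa for r in rows],
        "ehss_A2": [r.reference_ehss for r in rows],
        "between_pa_ehss": ["n/a" if r.between_pa_ehss is None
                            else str(r.between_pa_ehss).lower() for r in rows],
        "annotation": [r.annotation for r in rows],
    })


def write_comparison_csv(rows: Sequence[ComparisonRow], path: str | Path) -> None:
    """Deterministic CSV output: same rows, byte-identical file."""
    df = comparison_to_frame(rows)
    with open(path, "w", newline="") as fh:
        df.to_csv(fh, index=False, float_format="%.6g", lineterminator="\n")


def comparison_to_markdown(rows: Sequence[ComparisonRow], summary: dict) -> str:
    lines = [
        "| Protein | Predicted (Å²) | Measured (Å²) | % of measured | PA (Å²) | EHSS (Å²) | Between |",
        "|---|---|---|---|---|---|---|",
    ]
    for r in rows:
        pa = f"{r.reference_pa:g}" if r.reference_pa is not None else "-"
        eh = f"{r.reference_ehss:g}" if r.reference_ehss is not None else "-"
        bt = "n/a" if r.between_pa_ehss is None else str(r.between_pa_ehss).lower()
        lines.append(f"| {r.protein} | {r.predicted_ccs:g} | {r.measured_ccs:g} "
                     f"| {r.percent_of_measured:.1f} | {pa} | {eh} | {bt} |")
    frac = summary["fraction_between_pa_ehss"]
    if frac is not None:
        lines.append("")
        lines.append(f"{summary['n_between_pa_ehss']}/{summary['n_with_references']} "
                     f"predictions ({100 * frac:.0f}%) lie between PA and EHSS.")
    return "\n".join(lines) + "\n"
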