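"""S-layer proteome ratio analysis.

Label-free quantities (iBAQ) of surface-layer(-associated) proteins are
compared between strains/conditions as log2 ratios and fold changes, with
"not detected" (ND) propagated as a distinct state — an ND input yields an
ND ratio, never an infinity or an imputed zero.  The shipped fixture
carries the published comparison of an amylopullulanase-deficient and a
-sufficient strain across carbon sources (galactose, glucose, glycogen).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "ND",
    "RatioResult",
    "load_quant_table",
    "load_table1",
    "log2_ratio",
    "fold_change",
    "fold_display",
    "contrast_table",
    "fraction_of_group",
]

#: Sentinel spelled in quantity tables for "below the detection limit".
ND = "ND"

_META_COLUMNS = {"accession", "description", "peptides"}


def _is_nd(x) -> bool:
    if x is None or x == ND:
        return True
    try:
        return math.isnan(float(x))
    except (TypeError, ValueError):
        return True


def _check(x, name: str) -> float | None:
    if _is_nd(x):
        return None
    v = float(x)
    if v < 0:
        raise ValueError(f"{name} quantity must be non-negative, got {v}")
    return v


def log2_ratio(a, b) -> float | None:
    """log2(a/b); None (ND) when either input is ND or zero."""
    a, b = _check(a, "numerator"), _check(b, "denominator")
    if not a or not b:
        return None
    return math.log2(a / b)


def fold_change(a, b) -> float | None:
    """a/b; None (ND) when either input is ND or zero."""
    a, b = _check(a, "numerator"), _check(b, "denominator")
    if not a or not b:
        return None
    return a / b


def fold_display(fc: float | None) -> str:
    """Phrase a fold change the way results text does: nearest ten above 50."""
    if fc is None:
        return ND
    n = round(fc / 10) * 10 if fc >= 50 else round(fc)
    return f"{n:g}-fold"


@dataclass(frozen=True)
class RatioResult:
    accession: str
    contrast: str
    log2_ratio: float | None
    fold_change: float | None


def load_quant_table(path: str | Path) -> pd.DataFrame:
    """Read a protein quantity TSV (ND cells become NaN).

    Expected columns: ``accession``, ``description``, ``peptides``, then one
    column per condition; extra columns (e.g. printed reference ratios) pass
    through untouched.
    """
    df = pd.read_csv(path, sep="\t", na_values=[ND], keep_default_na=False)
    if "accession" not in df.columns:
        raise ValueError(f"{path}: missing 'accession' column")
    return df


def load_table1() -> pd.DataFrame:
    """The shipped S-layer proteome fixture (28 proteins x 4 conditions)."""
    with resources.as_file(
            resources.files("pulascreen").joinpath("data/table1.tsv")) as p:
        return load_quant_table(p)


def contrast_table(rows: pd.DataFrame,
                   contrast: tuple[str, str]) -> list[RatioResult]:
    """Per-protein ratios for (numerator condition, denominator condition).

    Sorted by log2 ratio descending, ND rows last.  Swapping the contrast
    negates every detected log2 ratio (antisymmetry).
    """
    num, den = contrast
    for cond in (num, den):
        if cond not in rows.columns:
            raise KeyError(f"unknown condition label {cond!r}")
    out = []
    for _, row in rows.iterrows():
        lr = log2_ratio(row[num], row[den])
        fc = fold_change(row[num], row[den])
        out.append(RatioResult(accession=row["accession"],
                               contrast=f"{num}/{den}",
                               log2_ratio=lr, fold_change=fc))
    out.sort(key=lambda r: (r.log2_ratio is None,
                            -(r.log2_ratio if r.log2_ratio is not None else 0),
                            r.accession))
    return out


def fraction_of_group(rows: pd.DataFrame,
                      group_totals: Mapping[str, float]) -> dict[str, float]:
    """Group quantity sums as fractions of supplied per-condition totals."""
    out = {}
    for cond, total in group_totals.items():
        if total <= 0:
            raise ValueError(f"total for {cond!r} must be positive")
        if cond not in rows.columns:
            raise KeyError(f"unknown condition label {cond!r}")
        out[cond] = float(rows[cond].fillna(0).sum()) / float(total)
    return out
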