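"""Compartmentalised histology biomarkers from per-cell tables.

A cell table has one row per segmented cell with a ``compartment`` column
(epithelial / stromal), one ordinal staining category per IHC marker
(negative / weak / moderate / strong) and one non-negative integer copy
count per RNAscope gene.  "Positive" means any non-negative staining
category (weak, moderate or strong summed), with no intensity weighting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "STAIN_LEVELS",
    "POSITIVE_LEVELS",
    "CompartmentSummary",
    "percent_positive",
    "mct4_epi_stroma_ratio",
    "combined_epithelial_ldh",
    "expression_ratios",
    "cell_counts",
    "summarise_roi",
]

STAIN_LEVELS = ("negative", "weak", "moderate", "strong")
POSITIVE_LEVELS = frozenset({"weak", "moderate", "strong"})

MARKERS = ("MCT1", "MCT4", "HIF1A_nuclear")
GENES = ("LDHA", "LDHB", "PDHA1")


class UndefinedRatioError(ZeroDivisionError):
    """A ratio with a zero denominator; flagged, never silently infinite."""


@dataclass
class CompartmentSummary:
    """One row of derived biomarkers for a single histology ROI."""

    epithelial_cells: int
    stromal_cells: int
    epi_stroma_count_ratio: float
    percent_positive: dict[str, dict[str, float]]  # marker -> compartment -> %
    mean_copies: dict[str, dict[str, float]]  # gene -> compartment -> copies/cell
    combined_ldh_total: float
    combined_ldh_per_cell: float
    mct4_epi_stroma_ratio: float


def _select(cells: pd.DataFrame, compartment: str | None) -> pd.DataFrame:
    if compartment is None or compartment == "all":
        return cells
    sel = cells[cells["compartment"] == compartment]
    if sel.empty:
        raise ValueError(f"no cells in compartment {compartment!r}")
    return sel


def percent_positive(cells: pd.DataFrame, marker: str, compartment: str | None = None) -> float:
    """Percentage of cells with weak/moderate/strong staining for a marker.

    For nuclear HIF-1a the input column already encodes the nuclear
    staining category, so the same positivity rule applies.
    """
    sel = _select(cells, compartment)
    if sel.empty:
        raise ValueError("empty cell selection")
    pos = sel[marker].isin(POSITIVE_LEVELS).sum()
    return 100.0 * float(pos) / float(len(sel))


def mct4_epi_stroma_ratio(cells: pd.DataFrame) -> float:
    """Tumour epithelium-to-stroma MCT4 positivity ratio."""
    epi = percent_positive(cells, "MCT4", "epithelial")
    stroma = percent_positive(cells, "MCT4", "stromal")
    if stroma == 0:
        raise UndefinedRatioError("stromal MCT4 positivity is zero")
    return epi / stroma


def combined_epithelial_ldh(cells: pd.DataFrame) -> tuple[float, float]:
    """Combined epithelial LDH: summed LDHA + LDHB copies in epithelial cells.

    Returns ``(total, per_cell)``; the total is the primary definition, the
    per-cell value (total / epithelial cell count) aids cross-ROI
    comparability.
    """
    epi = _select(cells, "epithelial")
    total = float(epi["LDHA"].sum() + epi["LDHB"].sum())
    return total, total / float(len(epi))


def expression_ratios(cells: pd.DataFrame, compartment: str = "epithelial") -> dict[str, float]:
    """LDHA/LDHB and LDHA/PDHA1 ratios of mean copies per cell.

    LDHA/PDHA1 indexes glycolytic versus oxidative pyruvate handling.
    """
    sel = _select(cells, compartment)
    means = {g: float(sel[g].mean()) for g in GENES}
    out = {}
    for num, den, name in (("LDHA", "LDHB", "LDHA/LDHB"), ("LDHA", "PDHA1", "LDHA/PDHA1")):
        if means[den] == 0:
            raise UndefinedRatioError(f"mean {den} is zero in {compartment}")
        out[name] = means[num] / means[den]
    return out


def cell_counts(cells: pd.DataFrame) -> tuple[int, int, float]:
    """(epithelial count, stromal count, epithelium-to-stroma count ratio)."""
    if cells.empty:
        raise ValueError("empty cell table")
    n_epi = int((cells["compartment"] == "epithelial").sum())
    n_str = int((cells["compartment"] == "stromal").sum())
    if n_str == 0:
        raise UndefinedRatioError("stromal cell count is zero")
    return n_epi, n_str, n_epi / n_str


def summarise_roi(cells: pd.DataFrame) -> CompartmentSummary:
    """All compartment metrics for one ROI in a single pass."""
    n_epi, n_str, ratio = cell_counts(cells)
    pct = {
        m: {c: percent_positive(cells, m, c) for c in ("epithelial", "stromal", "all")}
        for m in MARKERS
    }
    means = {
        g: {c: float(_select(cells, c)[g].mean()) for c in ("epithelial", "stromal")}
        for g in GENES
    }
    total, per_cell = combined_epithelial_ldh(cells)
    try:
        mct4_ratio = mct4_epi_stroma_ratio(cells)
    except UndefinedRatioError:
        mct4_ratio = float("nan")
    return CompartmentSummary(
        epithelial_cells=n_epi,
        stromal_cells=n_str,
        epi_stroma_count_ratio=ratio,
        percent_positive=pct,
        mean_copies=means,
        combined_ldh_total=total,
        combined_ldh_per_cell=per_cell,
        mct4_epi_stroma_ratio=mct4_ratio,
    )
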