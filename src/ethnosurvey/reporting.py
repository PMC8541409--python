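"""Rendering and export of analysis outputs.

Rounding is applied only at render time; CSV/JSON artefacts written by the
pipeline keep full precision unless stated otherwise.  Display profile:
RFC to 2 decimals, Smith's S and CV to 3, JI and Fic to 2, p-values to 4
(with very small values shown as "p < 0.001").
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

from . import comparison, indices
from .records import CATEGORY_ORDER, InterviewSet, UseCategory

__all__ = [
    "DISPLAY_DECIMALS",
    "format_p",
    "k_for_fraction",
    "build_jaccard_report",
    "render_rank_table",
    "render_consensus_table",
    "export_index_table",
    "export_consensus_table",
]

#: Decimal places used when a table is rendered for reading.
DISPLAY_DECIMALS: dict[str, int] = {
    "FC": 0,
    "UR": 0,
    "RFC": 2,
    "S": 3,
    "CV": 3,
    "JI": 2,
    "fic": 2,
}


def format_p(p: float, decimals: int = 4) -> str:
    """Two-sided p-value for display; values that would print as 0 become
    ``p < 0.001``."""
    if math.isnan(p):
        return "p = NA"
    if p < 0.001:
        return "p < 0.001"
    return f"p = {p:.{decimals}f}"


def k_for_fraction(n_taxa: int, fraction: float) -> int:
    """Top-k cutoff for a fraction of the inventory, rounding half up
    (so 50% of 157 taxa → 79 and 20% → 31)."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    return max(1, int(fraction * n_taxa + 0.5))


def build_jaccard_report(
    data: InterviewSet,
    fractions: Iterable[float] = (1.0, 0.5, 0.2),
    category_mode: str = "taxa",
) -> dict:
    """All Jaccard comparisons for a two-area dataset: the full inventories,
    the top-k curve at the requested FC fractions, and one entry per use
    category (categories absent from both areas are reported as null)."""
    areas = sorted(data.areas)
    sets = {a: set(indices.citation_frequency(data, a)) for a in areas}
    overall = comparison.jaccard_taxa(sets[areas[0]], sets[areas[1]])
    n_taxa = len(data.taxa)
    report: dict = {
        "areas": areas,
        "overall": overall.as_dict(),
        "union": comparison.union_count(
            int(overall.a_count), int(overall.b_count), int(overall.shared)
        ),
        "top_fraction": {},
        "by_category": {},
        "category_mode": category_mode,
    }
    for frac in fractions:
        k = k_for_fraction(n_taxa, frac)
        result = comparison.jaccard_topk(data, k)
        report["top_fraction"][f"{frac:g}"] = {"k": k, **result.as_dict()}
    for cat in CATEGORY_ORDER:
        try:
            result = comparison.jaccard_by_use_category(
                data, cat, mode=category_mode
            )
            report["by_category"][cat.value] = result.as_dict()
        except ValueError:
            report["by_category"][cat.value] = None
    return report


def _fmt(value: float, decimals: Optional[int]) -> str:
    if isinstance(value, float) and math.isnan(value):
        return ""
    if decimals is None:
        return str(value)
    if decimals == 0:
        return str(int(round(value)))
    return f"{value:.{decimals}f}"


def render_rank_table(table: pd.DataFrame) -> str:
    """Plain-text rendering of a :func:`~ethnosurvey.comparison.rank_table`
    output with aligned columns."""
    index = table.attrs.get("index", "")
    decimals = DISPLAY_DECIMALS.get(index)
    headers = list(table.columns)
    rows = [
        [
            _fmt(v, decimals) if isinstance(v, float) else str(v)
            for v in row
        ]
        for row in table.itertuples(index=False)
    ]
    widths = [
        max(len(h), *(len(r[i]) for r in rows)) if rows else len(h)
        for i, h in enumerate(headers)
    ]
    lines = [
        "  ".join(h.ljust(w) for h, w in zip(headers, widths)),
        "  ".join("-" * w for w in widths),
    ]
    lines += ["  ".join(c.ljust(w) for c, w in zip(r, widths)) for r in rows]
    return "\n".join(lines) + "\n"


def render_consensus_table(table: pd.DataFrame) -> str:
    """Plain-text consensus (Fic) table; undefined Fic shown as NA."""
    lines = [f"{'category':<10}{'n_ur':>8}{'n_taxa':>8}{'Fic':>8}"]
    for code, row in table.iterrows():
        fic = "NA" if math.isnan(row["fic"]) else f"{row['fic']:.2f}"
        lines.append(
            f"{code:<10}{int(row['n_ur']):>8}{int(row['n_taxa']):>8}{fic:>8}"
        )
    return "\n".join(lines) + "\n"


def export_index_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write an index table as CSV with the fixed column order
    (taxon, FC, RFC, UR, S, CV, IUc_E..IUc_O), full precision."""
    path = Path(path)
    cols = ["taxon", "FC", "RFC", "UR", "S", "CV"] + [
        f"IUc_{c.value}" for c in CATEGORY_ORDER
    ]
    table[cols].to_csv(path, index=False, encoding="utf-8", lineterminator="\n")
    return path


def export_consensus_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.reset_index().to_csv(
        path, index=False, encoding="utf-8", lineterminator="\n"
    )
    return path


def write_json(payload: Mapping, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
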