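"""Per-taxon citation indices and per-category informant consensus.

All indices take an :class:`~ethnosurvey.records.InterviewSet` and a *scope*
("all" or one area label) and use N = number of interviews in scope as the
denominator:

* FC   — citation frequency: distinct interviews citing the taxon.
* RFC  — relative frequency of citation, FC / N.
* UR   — use reports: Σ over use categories of the number of interviews
  reporting the (taxon, category) pair.
* S    — Smith's salience: mean over all N lists of (L − R + 1) / L, with L
  the informant's own list length, R the taxon's free-list rank, and 0 for
  lists not citing the taxon.
* CV   — cultural value: (uses/7) · (FC/N) · Σ_u IUc_u/N, where IUc_u is the
  number of interviews reporting use u of the taxon.
* Fic  — informant consensus factor per use category,
  (n_ur − n_taxa) / (n_ur − 1), undefined (NaN) when n_ur < 2.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .records import CATEGORY_ORDER, InterviewSet, UseCategory

__all__ = [
    "N_CATEGORIES",
    "citation_frequency",
    "rfc",
    "use_reports",
    "smiths_s",
    "cultural_value",
    "category_informant_counts",
    "informant_consensus",
    "index_table",
]

#: Number of use categories the cultural-value coefficient normalises by.
N_CATEGORIES = 7


def _scope_n(data: InterviewSet, scope: str) -> int:
    n = data.n_interviews(scope)
    if n == 0:
        raise ValueError(f"scope {scope!r} contains no interviews")
    return n


def citation_frequency(data: InterviewSet, scope: str = "all") -> dict[str, int]:
    """FC: number of distinct interviews in scope citing each taxon."""
    df = data.scope_frame(scope)
    if df.empty:
        return {}
    return df.groupby("taxon")["interview_id"].nunique().to_dict()


def rfc(data: InterviewSet, scope: str = "all") -> dict[str, float]:
    """Relative frequency of citation, FC / N(scope)."""
    n = _scope_n(data, scope)
    return {t: fc / n for t, fc in citation_frequency(data, scope).items()}


def use_reports(data: InterviewSet, scope: str = "all") -> dict[str, int]:
    """UR: number of (interview, use-category) reports per taxon."""
    df = data.scope_frame(scope)
    if df.empty:
        return {}
    # triples are unique by validation, so each row is one report
    return df.groupby("taxon").size().to_dict()


def smiths_s(data: InterviewSet, scope: str = "all") -> dict[str, float]:
    """Smith's salience index per taxon.

    Uses each interview's own original free-list length L (preserved through
    filtering), so a taxon at rank R in a list of length L contributes
    (L − R + 1)/L and absent lists contribute 0; the sum is divided by N.
    """
    n = _scope_n(data, scope)
    df = data.scope_frame(scope)
    if df.empty:
        return {}
    mentions = df[["interview_id", "taxon", "rank"]].drop_duplicates()
    lengths = mentions["interview_id"].map(data.list_length)
    if (mentions["rank"] > lengths).any():
        bad = mentions.loc[mentions["rank"] > lengths, "interview_id"].iloc[0]
        raise ValueError(f"interview {bad!r}: rank exceeds its list length")
    weights = (lengths - mentions["rank"] + 1) / lengths
    return (weights.groupby(mentions["taxon"]).sum() / n).to_dict()


def cultural_value(data: InterviewSet, scope: str = "all") -> dict[str, float]:
    """Cultural value coefficient CV = (uses/7) · (FC/N) · (UR/N).

    The third factor is Σ over categories of the proportion of interviews
    reporting that use, which equals UR/N.
    """
    n = _scope_n(data, scope)
    df = data.scope_frame(scope)
    if df.empty:
        return {}
    uses = df.groupby("taxon")["use_category"].nunique()
    fc = df.groupby("taxon")["interview_id"].nunique()
    ur = df.groupby("taxon").size()
    cv = (uses / N_CATEGORIES) * (fc / n) * (ur / n)
    return cv.to_dict()


def category_informant_counts(data: InterviewSet, scope: str = "all") -> pd.DataFrame:
    """IUc numerators: interviews reporting each (taxon, category) pair.

    Returns a taxon × category table of integer counts with the seven
    category columns in canonical order (zero-filled).
    """
    df = data.scope_frame(scope)
    codes = [c.value for c in CATEGORY_ORDER]
    if df.empty:
        return pd.DataFrame(columns=codes, dtype=int)
    counts = (
        df.groupby(["taxon", "use_category"])["interview_id"]
        .nunique()
        .unstack(fill_value=0)
    )
    return counts.reindex(columns=codes, fill_value=0).astype(int)


def informant_consensus(data: InterviewSet, scope: str = "all") -> pd.DataFrame:
    """Per-category consensus table (n_ur, n_taxa, fic).

    Fic = (n_ur − n_taxa)/(n_ur − 1) when a category has at least two use
    reports, else NaN.  All seven categories appear as rows, in canonical
    order, with zero counts where a category was never reported.
    """
    data._check_scope(scope)
    df = data.scope_frame(scope)
    codes = [c.value for c in CATEGORY_ORDER]
    if df.empty:
        grouped = pd.DataFrame({"n_ur": 0, "n_taxa": 0}, index=pd.Index(codes))
    else:
        grouped = df.groupby("use_category").agg(
            n_ur=("taxon", "size"), n_taxa=("taxon", "nunique")
        )
        grouped = grouped.reindex(codes, fill_value=0)
    fic = np.where(
        grouped["n_ur"] >= 2,
        (grouped["n_ur"] - grouped["n_taxa"]) / np.maximum(grouped["n_ur"] - 1, 1),
        np.nan,
    )
    out = grouped.assign(fic=fic)
    out.index.name = "use_category"
    out.attrs["scope"] = scope
    return out


def index_table(data: InterviewSet, scope: str = "all") -> pd.DataFrame:
    """Joined per-taxon table of FC, RFC, UR, S, CV and the IUc counts.

    Sorted by descending RFC with an alphabetical tie-break.  Columns:
    taxon, FC, RFC, UR, S, CV, IUc_E .. IUc_O.
    """
    data._check_scope(scope)
    iuc = category_informant_counts(data, scope)
    cols = ["taxon", "FC", "RFC", "UR", "S", "CV"] + [
        f"IUc_{c.value}" for c in CATEGORY_ORDER
    ]
    if data.scope_frame(scope).empty:
        return pd.DataFrame(columns=cols)
    table = pd.DataFrame(
        {
            "FC": citation_frequency(data, scope),
            "RFC": rfc(data, scope),
            "UR": use_reports(data, scope),
            "S": smiths_s(data, scope),
            "CV": cultural_value(data, scope),
        }
    )
    iuc = iuc.rename(columns={c.value: f"IUc_{c.value}" for c in CATEGORY_ORDER})
    table = table.join(iuc)
    table.index.name = "taxon"
    table = table.reset_index()
    table = table.sort_values(["RFC", "taxon"], ascending=[False, True]).reset_index(
        drop=True
    )
    table.attrs["scope"] = scope
    return table[cols]
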