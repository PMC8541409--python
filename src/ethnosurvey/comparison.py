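"""Cross-area comparison: Jaccard similarity, list-length summaries,
group-mean tests and ranked survey-style listings.

The Jaccard index is reported as a percentage, JI = 100·C/(A + B − C),
with A and B the per-area counts and C the shared count.  For inventories
these are set cardinalities; an alternative "frequency" mode replaces them
with use-report counts (multiset semantics, shared count = per-taxon minimum).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import indices
from .records import InterviewSet, UseCategory

__all__ = [
    "JaccardResult",
    "jaccard_taxa",
    "jaccard_topk",
    "jaccard_by_use_category",
    "union_count",
    "ListLengthSummary",
    "mean_citations_per_interview",
    "pooled_mean",
    "MeanComparison",
    "compare_group_means",
    "rank_table",
]


@dataclass(frozen=True)
class JaccardResult:
    """Jaccard similarity between two areas, as the percentage JI."""

    a_count: float
    b_count: float
    shared: float
    ji: float

    def as_dict(self) -> dict:
        return {
            "A": self.a_count,
            "B": self.b_count,
            "C": self.shared,
            "JI": self.ji,
        }


def _jaccard(a_count: float, b_count: float, shared: float) -> JaccardResult:
    union = a_count + b_count - shared
    if union <= 0:
        raise ValueError("Jaccard undefined: both collections are empty")
    if shared > min(a_count, b_count) + 1e-9:
        raise ValueError(
            f"shared count {shared} exceeds min({a_count}, {b_count})"
        )
    return JaccardResult(a_count, b_count, shared, 100.0 * shared / union)


def jaccard_taxa(set_a: Iterable[str], set_b: Iterable[str]) -> JaccardResult:
    """JI between two taxon inventories (exact set arithmetic, symmetric)."""
    sa, sb = set(set_a), set(set_b)
    return _jaccard(len(sa), len(sb), len(sa & sb))


def _two_areas(data: InterviewSet) -> tuple[str, str]:
    areas = sorted(data.areas)
    if len(areas) != 2:
        raise ValueError(
            f"cross-area comparison needs exactly 2 areas, found {areas}"
        )
    return areas[0], areas[1]


def jaccard_topk(data: InterviewSet, k: int) -> JaccardResult:
    """JI of the per-area presence sets restricted to the k most frequently
    cited taxa (pooled FC, alphabetical tie-break)."""
    area_a, area_b = _two_areas(data)
    fc = indices.citation_frequency(data, "all")
    if not 1 <= k <= len(fc):
        raise ValueError(f"k must be in 1..{len(fc)}, got {k}")
    top = sorted(fc, key=lambda t: (-fc[t], t))[:k]
    selected = set(top)
    in_a = {t for t in indices.citation_frequency(data, area_a) if t in selected}
    in_b = {t for t in indices.citation_frequency(data, area_b) if t in selected}
    return jaccard_taxa(in_a, in_b)


def jaccard_by_use_category(
    data: InterviewSet,
    category: UseCategory,
    mode: Literal["taxa", "frequency"] = "taxa",
) -> JaccardResult:
    """JI between the two areas for one use category.

    mode="taxa" (default): A/B are the numbers of taxa reported with the
    category in each area and C the taxa carrying it in both.
    mode="frequency": A/B are the use-report counts of the category per
    area; C sums, over taxa reported in both, the smaller of the two
    per-area report counts (multiset intersection).
    """
    category = UseCategory(category)
    area_a, area_b = _two_areas(data)
    df = data.to_frame()
    df = df[df["use_category"] == category.value]
    if df.empty:
        raise ValueError(f"category {category.value!r} has no reports in either area")
    counts = df.groupby(["area", "taxon"]).size().unstack("area", fill_value=0)
    counts = counts.reindex(columns=[area_a, area_b], fill_value=0)
    if mode == "taxa":
        in_a = counts.index[counts[area_a] > 0]
        in_b = counts.index[counts[area_b] > 0]
        return jaccard_taxa(in_a, in_b)
    if mode == "frequency":
        a = int(counts[area_a].sum())
        b = int(counts[area_b].sum())
        c = int(counts.min(axis=1).sum())
        return _jaccard(a, b, c)
    raise ValueError(f"unknown mode {mode!r}")


def union_count(a_count: int, b_count: int, shared: int) -> int:
    """|A ∪ B| from the two inventory sizes and their overlap."""
    if shared > min(a_count, b_count):
        raise ValueError(
            f"shared count {shared} exceeds min({a_count}, {b_count})"
        )
    return a_count + b_count - shared


@dataclass(frozen=True)
class ListLengthSummary:
    n: int
    mean: float
    median: float
    minimum: int
    maximum: int


def mean_citations_per_interview(
    data: InterviewSet, scope: str = "all"
) -> ListLengthSummary:
    """Summary of the number of distinct taxa cited per interview in scope."""
    ids = data.interview_ids(scope)
    if not ids:
        raise ValueError(f"scope {scope!r} contains no interviews")
    df = data.scope_frame(scope)
    counts = df.groupby("interview_id")["taxon"].nunique()
    counts = counts.reindex(ids, fill_value=0)
    return ListLengthSummary(
        n=len(ids),
        mean=float(counts.mean()),
        median=float(counts.median()),
        minimum=int(counts.min()),
        maximum=int(counts.max()),
    )


def pooled_mean(means: Sequence[float], sizes: Sequence[int]) -> float:
    """Size-weighted pooled mean of group means (equal sizes → plain average)."""
    if len(means) != len(sizes) or not means:
        raise ValueError("means and sizes must be equal-length and non-empty")
    if any(n <= 0 for n in sizes):
        raise ValueError("group sizes must be positive")
    return float(np.average(means, weights=sizes))


@dataclass(frozen=True)
class MeanComparison:
    """Two-sample comparison of per-unit means between areas."""

    statistic: str
    area_a: str
    area_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    difference: float
    t: float
    p: float


def _per_unit_values(data: InterviewSet, area: str, statistic: str) -> np.ndarray:
    if statistic == "taxa-per-interview":
        df = data.scope_frame(area)
        counts = df.groupby("interview_id")["taxon"].nunique()
        counts = counts.reindex(data.interview_ids(area), fill_value=0)
        return counts.to_numpy(dtype=float)
    if statistic == "uses-per-taxon":
        df = data.scope_frame(area)
        if df.empty:
            return np.array([], dtype=float)
        return (
            df.groupby("taxon")["use_category"].nunique().to_numpy(dtype=float)
        )
    raise ValueError(f"unknown statistic {statistic!r}")


def compare_group_means(
    data: InterviewSet,
    area_a: str,
    area_b: str,
    statistic: str = "taxa-per-interview",
    equal_var: bool = True,
) -> MeanComparison:
    """Two-sample t-test on per-interview list lengths or per-taxon use
    breadth between two areas.  Student's equal-variance test by default;
    ``equal_var=False`` selects Welch."""
    for area in (area_a, area_b):
        data._check_scope(area)
    xa = _per_unit_values(data, area_a, statistic)
    xb = _per_unit_values(data, area_b, statistic)
    min_n = 2
    if len(xa) < min_n or len(xb) < min_n:
        raise ValueError(
            f"need at least {min_n} units per group, got {len(xa)} and {len(xb)}"
        )
    if np.var(xa) == 0 and np.var(xb) == 0 and len(xa) + len(xb) <= 4:
        t_stat, p_val = (0.0, math.nan) if np.mean(xa) == np.mean(xb) else (
            math.inf, math.nan
        )
    else:
        with np.errstate(all="ignore"):
            t_stat, p_val = stats.ttest_ind(xa, xb, equal_var=equal_var)
        if math.isnan(t_stat) and np.allclose(xa.mean(), xb.mean()):
            t_stat, p_val = 0.0, 1.0
    return MeanComparison(
        statistic=statistic,
        area_a=area_a,
        area_b=area_b,
        n_a=len(xa),
        n_b=len(xb),
        mean_a=float(xa.mean()),
        mean_b=float(xb.mean()),
        difference=float(xa.mean() - xb.mean()),
        t=float(t_stat),
        p=float(p_val),
    )


def rank_table(
    data: InterviewSet,
    index: str = "RFC",
    top_n: int = 10,
    decimals: Optional[int] = None,
) -> pd.DataFrame:
    """Aligned top-``top_n`` listing of one index for the pooled sample and
    each area, in the shape of the published ranking tables.

    Taxa appearing in both areas' top lists carry a ``+`` marker in the
    pooled column.  Values are rounded for display when ``decimals`` is
    given (full precision otherwise).
    """
    from .reporting import DISPLAY_DECIMALS  # local import avoids a cycle

    if index not in {"FC", "RFC", "UR", "S", "CV"}:
        raise ValueError(f"unknown index {index!r}")
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if decimals is None:
        decimals = DISPLAY_DECIMALS.get(index)

    scopes = ["all"] + sorted(data.areas)
    tops: dict[str, pd.DataFrame] = {}
    for scope in scopes:
        table = indices.index_table(data, scope)
        table = table.sort_values([index, "taxon"], ascending=[False, True])
        if top_n > len(table):
            warnings.warn(
                f"top_n={top_n} exceeds the {len(table)} taxa in scope "
                f"{scope!r}; truncating",
                stacklevel=2,
            )
        tops[scope] = table.head(top_n).reset_index(drop=True)

    area_scopes = scopes[1:]
    if len(area_scopes) == 2:
        shared_top = set(tops[area_scopes[0]]["taxon"]) & set(
            tops[area_scopes[1]]["taxon"]
        )
    else:
        shared_top = set()

    n_rows = max(len(t) for t in tops.values())
    out: dict[str, list] = {}
    for scope in scopes:
        names, values = [], []
        for i in range(n_rows):
            if i < len(tops[scope]):
                name = tops[scope]["taxon"].iloc[i]
                value = tops[scope][index].iloc[i]
                if scope == "all" and name in shared_top:
                    name += " +"
                if decimals is not None:
                    value = round(float(value), decimals)
                names.append(name)
                values.append(value)
            else:
                names.append("")
                values.append(math.nan)
        label = "all" if scope == "all" else scope
        out[f"taxon_{label}"] = names
        out[f"{index}_{label}"] = values
    result = pd.DataFrame(out)
    result.insert(0, "rank", range(1, n_rows + 1))
    result.attrs["index"] = index
    result.attrs["shared_top"] = sorted(shared_top)
    return result
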