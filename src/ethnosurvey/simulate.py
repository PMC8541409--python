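"""Seeded generator of two-area free-list interview datasets.

The generator emulates the structure of a two-municipality wild-plant survey:
two areas of ~30 interviews each, per-interview free lists whose lengths
follow a clipped negative binomial (per-area means 28.63 and 21.67, range
[10, 76]), a taxon pool of 199 names partitioned into shared and area-private
subsets (70% shared, targeting an overall filtered Jaccard similarity near
69%), Zipf-skewed taxon popularity with a lognormal per-taxon area bias, and
seven non-exclusive use categories dominated by food/drink.

Everything is driven by a single integer seed; identical configurations
produce byte-identical CSV output.  Per-interview substreams are spawned
deterministically so a dataset's interviews are individually reproducible.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .records import (
    CATEGORY_ORDER,
    CitationRecord,
    InterviewSet,
    UseCategory,
)

__all__ = ["SimConfig", "generate", "benchmark_fixture", "realized_summary"]

#: Default per-category inclusion probability given that a taxon is cited.
DEFAULT_CATEGORY_PROBS: dict[UseCategory, float] = {
    UseCategory.FOOD: 0.80,
    UseCategory.MEDICINE: 0.35,
    UseCategory.ALCOHOL: 0.25,
    UseCategory.ANIMAL_FEED: 0.10,
    UseCategory.TOOL: 0.05,
    UseCategory.OTHER: 0.15,
    UseCategory.CEREMONIAL: 0.03,
}

_GENERA = (
    "Adriatica", "Borealis", "Carsia", "Dolina", "Euphrasia",
    "Flyschia", "Gmajna", "Histria", "Illyrica", "Jadranka",
    "Kraska", "Littoralis", "Maquisia", "Nanosia", "Obala",
    "Primorska", "Quercetalia", "Rupestris", "Submediterranea", "Terrarossa",
)


def _taxon_name(i: int) -> str:
    return f"{_GENERA[i % len(_GENERA)]} specimen{i:03d}"


@dataclass(frozen=True)
class SimConfig:
    """Full parameterisation of the synthetic survey generator.

    Attributes
    ----------
    seed:
        Master seed; every random draw descends from it.
    n_interviews_per_area:
        Interviews conducted in each of the two areas.
    pool_size:
        Total number of taxa that exist in the regional pool.
    shared_fraction:
        Fraction of the pool known in both areas; the remainder is split
        evenly into area-private taxa.
    list_length_means:
        Per-area mean free-list length (negative binomial).
    list_length_dispersion:
        Negative-binomial size parameter r (variance = m + m²/r); the
        default gives a list-length SD ≈ 11.
    list_length_range:
        Hard clip applied to drawn lengths.
    citation_skew:
        Zipf exponent of taxon popularity (weight ∝ 1/rank^skew).
    category_probs:
        Per-category inclusion probability conditional on citation; a cited
        taxon that draws no category is assigned food/drink (E).
    area_bias_sigma:
        σ of the lognormal per-taxon preference multiplier between areas.
    area_names:
        Labels of the two areas, in (A, B) order matching
        ``list_length_means``.
    """

    seed: int
    n_interviews_per_area: int = 30
    pool_size: int = 199
    shared_fraction: float = 0.70
    list_length_means: tuple[float, float] = (28.63, 21.67)
    list_length_dispersion: float = 6.4
    list_length_range: tuple[int, int] = (10, 76)
    citation_skew: float = 1.0
    category_probs: Mapping[UseCategory, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_PROBS)
    )
    area_bias_sigma: float = 0.5
    area_names: tuple[str, str] = ("Komen", "Izola")

    def __post_init__(self) -> None:
        if self.n_interviews_per_area < 1:
            raise ValueError("n_interviews_per_area must be >= 1")
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError("shared_fraction must be in [0, 1]")
        for cat, p in self.category_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"category probability for {cat} not in [0, 1]")
        lo, hi = self.list_length_range
        if not 1 <= lo <= hi:
            raise ValueError("list_length_range must satisfy 1 <= lo <= hi")
        if len(self.area_names) != 2 or self.area_names[0] == self.area_names[1]:
            raise ValueError("area_names must be two distinct labels")


def _partition_pool(config: SimConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n_shared = int(round(config.shared_fraction * config.pool_size))
    n_private = config.pool_size - n_shared
    n_a_only = (n_private + 1) // 2
    idx = np.arange(config.pool_size)
    shared = idx[:n_shared]
    a_only = idx[n_shared : n_shared + n_a_only]
    b_only = idx[n_shared + n_a_only :]
    return shared, a_only, b_only


def _draw_length(rng: np.random.Generator, mean: float, config: SimConfig) -> int:
    r = config.list_length_dispersion
    p = r / (r + mean)
    lo, hi = config.list_length_range
    return int(np.clip(rng.negative_binomial(r, p), lo, hi))


def _draw_categories(
    rng: np.random.Generator, probs: Sequence[float]
) -> list[UseCategory]:
    mask = rng.random(len(CATEGORY_ORDER)) < np.asarray(probs)
    cats = [c for c, hit in zip(CATEGORY_ORDER, mask) if hit]
    if not cats:
        cats = [UseCategory.FOOD]  # every cited taxon carries >= 1 category
    return cats


def generate(config: SimConfig) -> InterviewSet:
    """Generate a synthetic two-area survey dataset.

    The pool is partitioned by ``shared_fraction``; popularity follows a
    shuffled Zipf law shared by both areas, modulated per taxon by a
    lognormal area bias.  Each interview draws a list length, samples that
    many taxa without replacement with probability ∝ popularity × bias, and
    assigns free-list ranks in draw order; use categories are then drawn per
    (interview, taxon).  The output always passes InterviewSet validation.
    """
    master = np.random.SeedSequence(config.seed)
    n = config.n_interviews_per_area
    setup_seq, *interview_seqs = master.spawn(1 + 2 * n)
    setup_rng = np.random.default_rng(setup_seq)

    shared, a_only, b_only = _partition_pool(config)
    popularity_rank = setup_rng.permutation(config.pool_size)
    zipf = 1.0 / np.power(popularity_rank + 1.0, config.citation_skew)
    bias = np.exp(setup_rng.normal(0.0, config.area_bias_sigma, config.pool_size))

    area_pools = {
        config.area_names[0]: np.concatenate([shared, a_only]),
        config.area_names[1]: np.concatenate([shared, b_only]),
    }
    area_weights = {
        config.area_names[0]: zipf * bias,
        config.area_names[1]: zipf / bias,
    }
    probs_vector = [config.category_probs.get(c, 0.0) for c in CATEGORY_ORDER]

    records: list[CitationRecord] = []
    seq_iter = iter(interview_seqs)
    for area, mean in zip(config.area_names, config.list_length_means):
        pool = area_pools[area]
        if len(pool) == 0:
            raise ValueError(f"area {area!r} has an empty taxon pool")
        weights = area_weights[area][pool]
        probs = weights / weights.sum()
        for i in range(n):
            rng = np.random.default_rng(next(seq_iter))
            length = _draw_length(rng, mean, config)
            if length > len(pool):
                warnings.warn(
                    f"list length {length} exceeds the {len(pool)}-taxon pool "
                    f"of area {area!r}; truncating",
                    stacklevel=2,
                )
                length = len(pool)
            chosen = rng.choice(pool, size=length, replace=False, p=probs)
            interview_id = f"{area}-{i + 1:03d}"
            for rank, taxon_idx in enumerate(chosen, start=1):
                for cat in _draw_categories(rng, probs_vector):
                    records.append(
                        CitationRecord(
                            interview_id=interview_id,
                            area=area,
                            taxon=_taxon_name(int(taxon_idx)),
                            rank=rank,
                            use_category=cat,
                        )
                    )
    return InterviewSet(records)


def benchmark_fixture() -> InterviewSet:
    """Deterministic benchmark dataset with an exactly known overlap
    structure.

    Presence sets are assigned constructively: after the standard FC >= 2
    filter the two areas hold 147 and 119 taxa of which 109 are shared
    (union 157, overall JI = 69.43%), and 42 further singleton taxa are
    mentioned exactly once so the unfiltered pool has 199 taxa.  Citations
    are spread over 30 interviews per area; use categories follow the
    default category probabilities.  Always returns the same dataset.
    """
    rng = np.random.default_rng(20190301)
    area_a, area_b = "Komen", "Izola"
    n = 30
    shared = [_taxon_name(i) for i in range(109)]
    a_only = [_taxon_name(i) for i in range(109, 147)]       # 38 taxa
    b_only = [_taxon_name(i) for i in range(147, 157)]       # 10 taxa
    singles = [_taxon_name(i) for i in range(157, 199)]      # 42 taxa

    lists: dict[tuple[str, int], list[str]] = {
        (area, i): [] for area in (area_a, area_b) for i in range(n)
    }

    def cite(area: str, taxon: str, count: int, anchor: Optional[int] = None) -> None:
        chosen: list[int] = []
        if anchor is not None:
            chosen.append(anchor % n)
        remaining = [i for i in range(n) if i not in chosen]
        extra = rng.choice(len(remaining), size=count - len(chosen), replace=False)
        chosen.extend(remaining[int(e)] for e in extra)
        for i in chosen:
            lists[(area, i)].append(taxon)

    for j, taxon in enumerate(shared):
        # anchor the first citation round-robin so every interview is non-empty
        cite(area_a, taxon, int(rng.integers(1, 4)), anchor=j)
        cite(area_b, taxon, int(rng.integers(1, 4)), anchor=j)
    for taxon in a_only:
        cite(area_a, taxon, int(rng.integers(2, 5)))
    for taxon in b_only:
        cite(area_b, taxon, int(rng.integers(2, 5)))
    for j, taxon in enumerate(singles):
        cite(area_a if j % 2 == 0 else area_b, taxon, 1)

    probs_vector = [DEFAULT_CATEGORY_PROBS.get(c, 0.0) for c in CATEGORY_ORDER]
    records: list[CitationRecord] = []
    for (area, i), taxa in sorted(lists.items()):
        order = rng.permutation(len(taxa))
        interview_id = f"{area}-{i + 1:03d}"
        for rank, idx in enumerate(order, start=1):
            for cat in _draw_categories(rng, probs_vector):
                records.append(
                    CitationRecord(
                        interview_id=interview_id,
                        area=area,
                        taxon=taxa[int(idx)],
                        rank=rank,
                        use_category=cat,
                    )
                )
    return InterviewSet(records)


def realized_summary(data: InterviewSet, min_fc: int = 2) -> dict:
    """Summary statistics of a (typically simulated) dataset: per-area list
    lengths, category marginals, and the filtered inventory overlap."""
    from . import comparison
    from .records import filter_min_citations

    areas = sorted(data.areas)
    summary: dict = {
        "n_interviews": {a: data.n_interviews(a) for a in areas},
        "n_taxa_unfiltered": len(data.taxa),
        "list_length": {},
        "category_share": {},
    }
    for scope in ["all"] + areas:
        s = comparison.mean_citations_per_interview(data, scope)
        summary["list_length"][scope] = {
            "mean": s.mean,
            "median": s.median,
            "min": s.minimum,
            "max": s.maximum,
        }
    df = data.to_frame()
    pairs = df[["interview_id", "taxon"]].drop_duplicates()
    n_pairs = len(pairs)
    for cat in CATEGORY_ORDER:
        n_cat = len(df[df["use_category"] == cat.value])
        summary["category_share"][cat.value] = n_cat / n_pairs if n_pairs else 0.0
    filtered = filter_min_citations(data, min_fc)
    summary["n_taxa_filtered"] = len(filtered.taxa)
    if len(areas) == 2 and filtered.taxa:
        sets = [set(r.taxon for r in filtered.records if r.area == a) for a in areas]
        if sets[0] or sets[1]:
            ji = comparison.jaccard_taxa(sets[0], sets[1])
            summary["jaccard_filtered"] = ji.as_dict()
    return summary
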