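"""Independent straight-loop reference implementations used as oracles.

These deliberately avoid pandas and the package's own grouping logic: every
quantity is computed by explicit nested loops over the raw records so that a
bug in the implementation cannot hide in a shared code path.
"""

from __future__ import annotations

import numpy as np

from ethnosurvey.records import (
    CATEGORY_ORDER,
    CitationRecord,
    InterviewSet,
    UseCategory,
)


def _in_scope(rec: CitationRecord, scope: str) -> bool:
    return scope == "all" or rec.area == scope


def oracle_fc(data: InterviewSet, scope: str = "all") -> dict[str, int]:
    out: dict[str, set[str]] = {}
    for rec in data.records:
        if _in_scope(rec, scope):
            out.setdefault(rec.taxon, set()).add(rec.interview_id)
    return {t: len(s) for t, s in out.items()}


def oracle_rfc(data: InterviewSet, scope: str = "all") -> dict[str, float]:
    n = data.n_interviews(scope)
    return {t: fc / n for t, fc in oracle_fc(data, scope).items()}


def oracle_ur(data: InterviewSet, scope: str = "all") -> dict[str, int]:
    out: dict[str, int] = {}
    for taxon in {r.taxon for r in data.records if _in_scope(r, scope)}:
        total = 0
        for cat in CATEGORY_ORDER:
            interviews = {
                r.interview_id
                for r in data.records
                if _in_scope(r, scope)
                and r.taxon == taxon
                and r.use_category == cat
            }
            total += len(interviews)
        out[taxon] = total
    return out


def oracle_smiths_s(data: InterviewSet, scope: str = "all") -> dict[str, float]:
    n = data.n_interviews(scope)
    out: dict[str, float] = {}
    for taxon in {r.taxon for r in data.records if _in_scope(r, scope)}:
        total = 0.0
        for iid in data.interview_ids(scope):
            ranks = {
                r.rank
                for r in data.records
                if r.interview_id == iid and r.taxon == taxon
            }
            if ranks:
                (rank,) = ranks
                length = data.list_length(iid)
                total += (length - rank + 1) / length
        out[taxon] = total / n
    return out


def oracle_cv(data: InterviewSet, scope: str = "all") -> dict[str, float]:
    n = data.n_interviews(scope)
    out: dict[str, float] = {}
    for taxon in {r.taxon for r in data.records if _in_scope(r, scope)}:
        cats = {
            r.use_category
            for r in data.records
            if _in_scope(r, scope) and r.taxon == taxon
        }
        citing = {
            r.interview_id
            for r in data.records
            if _in_scope(r, scope) and r.taxon == taxon
        }
        sum_iuc = 0.0
        for cat in cats:
            reporting = {
                r.interview_id
                for r in data.records
                if _in_scope(r, scope)
                and r.taxon == taxon
                and r.use_category == cat
            }
            sum_iuc += len(reporting) / n
        out[taxon] = (len(cats) / 7) * (len(citing) / n) * sum_iuc
    return out


def oracle_consensus(
    data: InterviewSet, scope: str = "all"
) -> dict[str, tuple[int, int, float | None]]:
    out: dict[str, tuple[int, int, float | None]] = {}
    for cat in CATEGORY_ORDER:
        n_ur = 0
        taxa = set()
        for taxon in {r.taxon for r in data.records if _in_scope(r, scope)}:
            interviews = {
                r.interview_id
                for r in data.records
                if _in_scope(r, scope)
                and r.taxon == taxon
                and r.use_category == cat
            }
            if interviews:
                taxa.add(taxon)
                n_ur += len(interviews)
        fic = (n_ur - len(taxa)) / (n_ur - 1) if n_ur >= 2 else None
        out[cat.value] = (n_ur, len(taxa), fic)
    return out


def random_instance(
    rng: np.random.Generator,
    max_interviews: int = 10,
    max_taxa: int = 15,
    n_areas: int = 2,
) -> InterviewSet:
    """A small random but valid survey: each interview lists a random subset
    of the taxon pool in random order with 1-3 categories per mention."""
    pool = [f"Taxon number{i:02d}" for i in range(1, max_taxa + 1)]
    n_interviews = int(rng.integers(1, max_interviews + 1))
    areas = [f"area{chr(ord('A') + k)}" for k in range(n_areas)]
    records = []
    for i in range(n_interviews):
        area = areas[i % n_areas]
        length = int(rng.integers(1, len(pool) + 1))
        taxa = rng.choice(pool, size=length, replace=False)
        for rank, taxon in enumerate(taxa, start=1):
            n_cats = int(rng.integers(1, 4))
            cats = rng.choice(len(CATEGORY_ORDER), size=n_cats, replace=False)
            for c in cats:
                records.append(
                    CitationRecord(
                        interview_id=f"int{i:02d}",
                        area=area,
                        taxon=str(taxon),
                        rank=rank,
                        use_category=CATEGORY_ORDER[int(c)],
                    )
                )
    return InterviewSet(records)
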