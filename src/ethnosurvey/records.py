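"""Domain model for long-format free-list citation data.

An ethnobotanical survey is recorded as one row per (interview, taxon,
use-category) mention.  Within an interview the informant enumerates taxa in
spontaneous order; that position is the free-list *rank* and is shared by all
use-category rows of the same taxon.  The interview is the counting unit N of
every downstream index.

The module provides the validated container (:class:`InterviewSet`), the CSV
reader/writer for the long format, and the minimum-citation filter used before
the quantitative analysis.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "UseCategory",
    "CATEGORY_ORDER",
    "PART_VOCABULARY",
    "SchemaError",
    "ValidationError",
    "CitationRecord",
    "InterviewSet",
    "canonical_taxon",
    "read_citations",
    "write_citations",
    "filter_min_citations",
]


class UseCategory(str, Enum):
    """The seven non-exclusive use modalities of the survey protocol."""

    FOOD = "E"          # eating or drinking
    ALCOHOL = "A"       # production of alcoholic beverages
    MEDICINE = "M"      # medicinal use
    TOOL = "T"          # use as a tool
    CEREMONIAL = "C"    # ceremonial use
    ANIMAL_FEED = "AF"  # animal feed
    OTHER = "O"         # other types of use

    @classmethod
    def from_code(cls, code: str) -> "UseCategory":
        try:
            return cls(code.strip())
        except ValueError:
            raise ValidationError(
                f"unknown use_category code {code!r}; expected one of "
                f"{[c.value for c in cls]}"
            ) from None


#: Canonical display / serialisation order of the categories.
CATEGORY_ORDER: tuple[UseCategory, ...] = (
    UseCategory.FOOD,
    UseCategory.ALCOHOL,
    UseCategory.MEDICINE,
    UseCategory.TOOL,
    UseCategory.CEREMONIAL,
    UseCategory.ANIMAL_FEED,
    UseCategory.OTHER,
)

_CATEGORY_POSITION = {c.value: i for i, c in enumerate(CATEGORY_ORDER)}

#: Controlled vocabulary for the plant part recorded with a mention.
PART_VOCABULARY = frozenset(
    {
        "leaf", "flower", "aerial", "seed", "shoot", "taproot",
        "bulb", "stalk", "sap", "bark", "fruit", "wood", "other",
    }
)


class SchemaError(ValueError):
    """The input table is missing a required column."""


class ValidationError(ValueError):
    """The input rows violate a free-list invariant."""


def canonical_taxon(name: str) -> str:
    """Canonicalize a scientific name: trim, collapse whitespace, capitalize
    the genus and lower-case the rest (``'  taraxacum   OFFICINALE '`` →
    ``'Taraxacum officinale'``).  No synonym resolution is attempted."""
    parts = name.split()
    if not parts:
        raise ValidationError("taxon name is empty")
    head = parts[0].capitalize()
    rest = [p.lower() for p in parts[1:]]
    return " ".join([head, *rest])


@dataclass(frozen=True)
class CitationRecord:
    """One (interview, taxon, use-category) mention."""

    interview_id: str
    area: str
    taxon: str
    rank: int
    use_category: UseCategory
    part_used: Optional[str] = None
    local_name: Optional[str] = None
    preparation: Optional[str] = None

    def key(self) -> tuple[str, str, str]:
        return (self.interview_id, self.taxon, self.use_category.value)


def _check_record(rec: CitationRecord) -> None:
    if not isinstance(rec.rank, int) or rec.rank < 1:
        raise ValidationError(
            f"rank must be an integer >= 1, got {rec.rank!r} "
            f"(interview {rec.interview_id}, taxon {rec.taxon})"
        )
    if not isinstance(rec.use_category, UseCategory):
        raise ValidationError(
            f"use_category must be a UseCategory, got {rec.use_category!r}"
        )
    if rec.part_used is not None and rec.part_used not in PART_VOCABULARY:
        raise ValidationError(
            f"part_used {rec.part_used!r} not in controlled vocabulary "
            f"(interview {rec.interview_id}, taxon {rec.taxon})"
        )
    if not rec.area:
        raise ValidationError(f"empty area label (interview {rec.interview_id})")


class InterviewSet:
    """Validated collection of citation records grouped by area.

    The set carries an interview *roster* (interview_id → area) and the
    original free-list length of every interview.  Both survive filtering, so
    that N (the denominator of RFC, S, CV) and the list lengths L used by
    Smith's salience refer to the survey as conducted, not to whichever
    records a filter kept.

    Parameters
    ----------
    records:
        The citation records.
    roster:
        Optional mapping interview_id → area.  When given it may contain
        interviews with no surviving records (they still count toward N).
        Defaults to the interviews present in ``records``.
    list_lengths:
        Optional mapping interview_id → original list length.  When omitted,
        lengths are derived from the records and ranks are required to be
        contiguous ``1..L`` within each interview.  When given (i.e. the set
        descends from a filtered ancestor), ranks need only satisfy
        ``1 <= rank <= L``.
    """

    def __init__(
        self,
        records: Iterable[CitationRecord],
        *,
        roster: Optional[Mapping[str, str]] = None,
        list_lengths: Optional[Mapping[str, int]] = None,
    ) -> None:
        self._records: tuple[CitationRecord, ...] = tuple(records)
        for rec in self._records:
            _check_record(rec)

        interview_area: dict[str, str] = dict(roster) if roster is not None else {}
        for rec in self._records:
            seen = interview_area.get(rec.interview_id)
            if seen is None:
                interview_area[rec.interview_id] = rec.area
            elif seen != rec.area:
                raise ValidationError(
                    f"interview {rec.interview_id!r} assigned to two areas: "
                    f"{seen!r} and {rec.area!r}"
                )

        # (interview, taxon) -> rank must be single-valued; triples unique.
        rank_of: dict[tuple[str, str], int] = {}
        seen_triples: set[tuple[str, str, str]] = set()
        for rec in self._records:
            key = (rec.interview_id, rec.taxon)
            if rank_of.setdefault(key, rec.rank) != rec.rank:
                raise ValidationError(
                    f"conflicting ranks for taxon {rec.taxon!r} in interview "
                    f"{rec.interview_id!r}"
                )
            triple = rec.key()
            if triple in seen_triples:
                raise ValidationError(
                    f"duplicate (interview, taxon, use_category) triple "
                    f"{triple!r}"
                )
            seen_triples.add(triple)

        # Per interview: distinct taxa must hold distinct ranks.
        per_interview: dict[str, dict[str, int]] = {}
        for (iid, taxon), rank in rank_of.items():
            per_interview.setdefault(iid, {})[taxon] = rank
        for iid, taxa in per_interview.items():
            ranks = sorted(taxa.values())
            if len(set(ranks)) != len(ranks):
                dupes = [r for r, g in itertools.groupby(ranks) if len(list(g)) > 1]
                raise ValidationError(
                    f"interview {iid!r}: rank(s) {dupes} assigned to more than "
                    f"one taxon"
                )

        if list_lengths is None:
            # Fresh data: ranks must be contiguous 1..L.
            lengths: dict[str, int] = {}
            for iid, taxa in per_interview.items():
                ranks = sorted(taxa.values())
                if ranks != list(range(1, len(ranks) + 1)):
                    raise ValidationError(
                        f"interview {iid!r}: ranks {ranks} are not contiguous "
                        f"1..{len(ranks)}"
                    )
                lengths[iid] = len(ranks)
            for iid in interview_area:
                lengths.setdefault(iid, 0)
        else:
            lengths = dict(list_lengths)
            for iid, taxa in per_interview.items():
                if iid not in lengths:
                    raise ValidationError(
                        f"interview {iid!r} missing from list_lengths"
                    )
                bad = [r for r in taxa.values() if r > lengths[iid]]
                if bad:
                    raise ValidationError(
                        f"interview {iid!r}: rank(s) {sorted(bad)} exceed the "
                        f"original list length {lengths[iid]}"
                    )

        self._interview_area = interview_area
        self._list_lengths = lengths
        self._frame: Optional[pd.DataFrame] = None

    # -- introspection -----------------------------------------------------

    @property
    def records(self) -> tuple[CitationRecord, ...]:
        return self._records

    @property
    def areas(self) -> frozenset[str]:
        return frozenset(self._interview_area.values())

    @property
    def taxa(self) -> frozenset[str]:
        return frozenset(r.taxon for r in self._records)

    def interview_ids(self, scope: str = "all") -> tuple[str, ...]:
        self._check_scope(scope)
        return tuple(
            sorted(
                iid
                for iid, area in self._interview_area.items()
                if scope == "all" or area == scope
            )
        )

    def n_interviews(self, scope: str = "all") -> int:
        return len(self.interview_ids(scope))

    def area_of(self, interview_id: str) -> str:
        return self._interview_area[interview_id]

    def list_length(self, interview_id: str) -> int:
        """Original free-list length L of an interview (survives filtering)."""
        return self._list_lengths[interview_id]

    def _check_scope(self, scope: str) -> None:
        if scope != "all" and scope not in self.areas:
            raise KeyError(
                f"unknown scope {scope!r}; expected 'all' or one of "
                f"{sorted(self.areas)}"
            )

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: one row per record, category as its letter code."""
        if self._frame is None:
            self._frame = pd.DataFrame(
                {
                    "interview_id": [r.interview_id for r in self._records],
                    "area": [r.area for r in self._records],
                    "taxon": [r.taxon for r in self._records],
                    "rank": [r.rank for r in self._records],
                    "use_category": [r.use_category.value for r in self._records],
                    "part_used": [r.part_used for r in self._records],
                    "local_name": [r.local_name for r in self._records],
                    "preparation": [r.preparation for r in self._records],
                }
            )
        return self._frame.copy()

    def scope_frame(self, scope: str = "all") -> pd.DataFrame:
        self._check_scope(scope)
        df = self.to_frame()
        if scope != "all":
            df = df[df["area"] == scope].reset_index(drop=True)
        return df

    def __len__(self) -> int:
        return len(self._records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InterviewSet):
            return NotImplemented
        return sorted(self._records, key=_sort_key) == sorted(
            other._records, key=_sort_key
        )

    def __repr__(self) -> str:
        return (
            f"InterviewSet({len(self._records)} records, "
            f"{self.n_interviews()} interviews, {len(self.taxa)} taxa, "
            f"areas={sorted(self.areas)})"
        )


# -- CSV I/O ---------------------------------------------------------------

_REQUIRED_COLUMNS = ("interview_id", "area", "taxon", "rank", "use_category")
_OPTIONAL_COLUMNS = ("part_used", "local_name", "preparation")


def _sort_key(rec: CitationRecord) -> tuple:
    return (
        rec.area,
        rec.interview_id,
        rec.rank,
        _CATEGORY_POSITION[rec.use_category.value],
    )


def read_citations(path: str | Path, **csv_options) -> InterviewSet:
    """Read and validate a long-format citation CSV.

    Required columns: interview_id, area, taxon, rank, use_category.
    Optional: part_used, local_name, preparation (other columns, e.g.
    informant metadata, are ignored).  Taxon names are canonicalized.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, **csv_options)
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    records = []
    for row in df.itertuples(index=False):
        try:
            rank = int(getattr(row, "rank"))
        except ValueError:
            raise ValidationError(
                f"non-integer rank {getattr(row, 'rank')!r} "
                f"(interview {getattr(row, 'interview_id')!r})"
            ) from None

        def _opt(col: str) -> Optional[str]:
            val = getattr(row, col, "") if col in df.columns else ""
            val = (val or "").strip()
            return val or None

        records.append(
            CitationRecord(
                interview_id=str(getattr(row, "interview_id")).strip(),
                area=str(getattr(row, "area")).strip(),
                taxon=canonical_taxon(str(getattr(row, "taxon"))),
                rank=rank,
                use_category=UseCategory.from_code(str(getattr(row, "use_category"))),
                part_used=_opt("part_used"),
                local_name=_opt("local_name"),
                preparation=_opt("preparation"),
            )
        )
    return InterviewSet(records)


def write_citations(data: InterviewSet, path: str | Path) -> Path:
    """Write the long-format CSV with deterministic row order
    (area, interview_id, rank, category order E,A,M,T,C,AF,O)."""
    path = Path(path)
    rows = sorted(data.records, key=_sort_key)
    df = pd.DataFrame(
        {
            "interview_id": [r.interview_id for r in rows],
            "area": [r.area for r in rows],
            "taxon": [r.taxon for r in rows],
            "rank": [r.rank for r in rows],
            "use_category": [r.use_category.value for r in rows],
            "part_used": [r.part_used or "" for r in rows],
            "local_name": [r.local_name or "" for r in rows],
            "preparation": [r.preparation or "" for r in rows],
        },
        columns=list(_REQUIRED_COLUMNS[:4]) + ["use_category"] + list(_OPTIONAL_COLUMNS),
    )
    df = df[["interview_id", "area", "taxon", "rank", "use_category",
             "part_used", "local_name", "preparation"]]
    df.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")
    return path


# -- filtering -------------------------------------------------------------

def filter_min_citations(data: InterviewSet, min_fc: int) -> InterviewSet:
    """Keep only taxa cited by at least ``min_fc`` distinct interviews.

    FC is computed on the *pooled* data (all areas together); per-area tables
    are then built from the filtered set.  The interview roster and original
    list lengths are preserved: N and the free-list ranks are unchanged, so
    indices computed downstream keep the survey-as-conducted denominators.
    """
    if min_fc < 1:
        raise ValueError(f"min_fc must be >= 1, got {min_fc}")
    fc: dict[str, set[str]] = {}
    for rec in data.records:
        fc.setdefault(rec.taxon, set()).add(rec.interview_id)
    keep = {taxon for taxon, interviews in fc.items() if len(interviews) >= min_fc}
    return InterviewSet(
        (r for r in data.records if r.taxon in keep),
        roster={iid: data.area_of(iid) for iid in data.interview_ids()},
        list_lengths={iid: data.list_length(iid) for iid in data.interview_ids()},
    )


def renumber_ranks(data: InterviewSet) -> InterviewSet:
    """Compress each interview's surviving ranks to contiguous 1..L'.

    Used by the alternative salience mode in which filtering is applied
    *before* rank weighting, so that L reflects the filtered list.
    """
    new_rank: dict[tuple[str, str], int] = {}
    per_interview: dict[str, list[tuple[int, str]]] = {}
    for rec in data.records:
        per_interview.setdefault(rec.interview_id, [])
    for rec in data.records:
        pairs = per_interview[rec.interview_id]
        if (rec.rank, rec.taxon) not in pairs:
            pairs.append((rec.rank, rec.taxon))
    for iid, pairs in per_interview.items():
        for new, (_, taxon) in enumerate(sorted(pairs), start=1):
            new_rank[(iid, taxon)] = new
    records = [
        CitationRecord(
            interview_id=r.interview_id,
            area=r.area,
            taxon=r.taxon,
            rank=new_rank[(r.interview_id, r.taxon)],
            use_category=r.use_category,
            part_used=r.part_used,
            local_name=r.local_name,
            preparation=r.preparation,
        )
        for r in data.records
    ]
    return InterviewSet(
        records,
        roster={iid: data.area_of(iid) for iid in data.interview_ids()},
    )
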