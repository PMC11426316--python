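"""Four-way mislabeling classification of DNA-barcoded market samples.

Each sample couples the market name a product was sold under with the set of
species its COI barcode matched.  Comparing the two against the authority
list yields one of five categories:

``properly_labeled``
    The name is regulated (directly or through an alias chain ending
    on-list is *not* enough - see ``semantic``) and at least one barcode
    candidate is acceptable under it.
``semantic``
    The name is off-list, but resolves through the alias table to an on-list
    name whose acceptable set meets the barcode ("unagi" containing American
    eel).  Counted in total but not conservative mislabeling.
``invalid_name``
    The name is off-list and carries no usable alias; the barcode is, at
    best, what the odd name hinted at.  Conservative mislabeling.
``product_substitution``
    The barcode identifies a species outside everything the (resolved or
    expected) name allows.  Conservative mislabeling.
``unregulated``
    The name falls outside the authority list entirely (mixed products);
    kept in denominators as not-mislabeled, excluded from precision work.

A multi-species barcode that overlaps the acceptable set passes as properly
labeled: the barcode simply lacked the resolution to prove anything worse.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .authority import (
    Authority,
    AuthorityError,
    StatusRegistry,
    UnknownMarketNameError,
    UnregulatedNameError,
    normalize_name,
)

__all__ = [
    "CATEGORIES",
    "CONSERVATIVE_CATEGORIES",
    "TOTAL_CATEGORIES",
    "SampleRecord",
    "MislabelCall",
    "AuditSummary",
    "ContingencyTable",
    "DegenerateTableError",
    "classify_sample",
    "classify_all",
    "summarize",
    "crosstab",
]

CATEGORIES = (
    "properly_labeled",
    "semantic",
    "invalid_name",
    "product_substitution",
    "unregulated",
)
#: Conservative mislabeling: invalid names + product substitutions.
CONSERVATIVE_CATEGORIES = frozenset({"invalid_name", "product_substitution"})
#: Total mislabeling additionally counts semantic cases.
TOTAL_CATEGORIES = CONSERVATIVE_CATEGORIES | {"semantic"}


@dataclass(frozen=True)
class SampleRecord:
    """One market product: label name plus DNA-barcode candidate species."""

    sample_id: str
    year: int
    cohort: str  # "invertebrate" | "finfish"
    market_name_raw: str
    barcode_candidates: frozenset[str]
    taxon_group: str | None = None
    sequence_length: int | None = None

    def __post_init__(self) -> None:
        if not self.barcode_candidates:
            raise ValueError(
                f"{self.sample_id}: empty barcode candidate set (records with "
                "failed barcodes are excluded upstream)"
            )
        if self.cohort not in {"invertebrate", "finfish"}:
            raise ValueError(f"{self.sample_id}: unknown cohort {self.cohort!r}")


@dataclass(frozen=True)
class MislabelCall:
    """Classification outcome with a human-readable decision trace."""

    category: str
    rationale: str

    @property
    def conservative_mislabeled(self) -> bool:
        return self.category in CONSERVATIVE_CATEGORIES

    @property
    def total_mislabeled(self) -> bool:
        return self.category in TOTAL_CATEGORIES


def classify_sample(record: SampleRecord, authority: Authority) -> MislabelCall:
    """Classify one sample against the authority list.

    The decision procedure is a pure function of the market name, the
    candidate set and the authority tables.
    """
    try:
        entry = authority.lookup(record.market_name_raw)
    except UnknownMarketNameError:
        raise AuthorityError(
            f"record {record.sample_id}: market name "
            f"{record.market_name_raw!r} is missing from every authority "
            "table; add an on-list, alias, invalid or unregulated row"
        ) from None

    cands = record.barcode_candidates
    name = entry.market_name

    if entry.list_status == "unregulated":
        return MislabelCall(
            "unregulated", f"{name!r} is not regulated by the authority list"
        )

    if entry.list_status == "invalid":
        if entry.species or entry.genera:
            if any(entry.accepts(sp) for sp in cands):
                return MislabelCall(
                    "invalid_name",
                    f"{name!r} is not an interpretable market name, though the "
                    "barcode matches what the name hinted at",
                )
            return MislabelCall(
                "product_substitution",
                f"{name!r} is an invalid market name and the barcode "
                f"({', '.join(sorted(cands))}) is not even what it hinted at",
            )
        return MislabelCall(
            "invalid_name", f"{name!r} permits no inference about the contents"
        )

    resolved = authority.resolve(record.market_name_raw)
    via_alias = entry.list_status == "alias"
    overlap = sorted(sp for sp in cands if resolved.accepts(sp))

    if overlap:
        if via_alias:
            return MislabelCall(
                "semantic",
                f"{name!r} is off-list but reads as {resolved.market_name!r}, "
                f"and the barcode ({', '.join(overlap)}) fits that reading",
            )
        return MislabelCall(
            "properly_labeled",
            f"barcode overlaps the acceptable set of {name!r} "
            f"({', '.join(overlap)})",
        )
    target = f" (read as {resolved.market_name!r})" if via_alias else ""
    return MislabelCall(
        "product_substitution",
        f"no barcode candidate ({', '.join(sorted(cands))}) may be sold "
        f"under {name!r}{target}",
    )


def classify_all(
    records: Sequence[SampleRecord],
    authority: Authority,
    registry: StatusRegistry | None = None,
) -> pd.DataFrame:
    """Classify every record; one row per sample.

    Adds precision and, when a registry is supplied, worst-case conservation
    columns.  Records excluded from an analysis carry ``excluded`` /
    empty markers rather than being dropped, so the frame keeps one row per
    input sample in input order.
    """
    rows = []
    for rec in records:
        call = classify_sample(rec, authority)
        try:
            precision = authority.classify_precision(rec.market_name_raw)
        except UnregulatedNameError:
            precision = "excluded"
        row = {
            "sample_id": rec.sample_id,
            "year": rec.year,
            "cohort": rec.cohort,
            "market_name": normalize_name(rec.market_name_raw),
            "taxon_group": rec.taxon_group,
            "barcode_candidates": ";".join(sorted(rec.barcode_candidates)),
            "category": call.category,
            "total_mislabeled": call.total_mislabeled,
            "conservative_mislabeled": call.conservative_mislabeled,
            "precision": precision,
            "rationale": call.rationale,
        }
        if registry is not None:
            assignment = registry.assign_status(rec.barcode_candidates)
            row["iucn_status"] = assignment.status
            row["concern"] = assignment.concern
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class AuditSummary:
    """Per-group audit tallies mirroring the survey's year-by-year table."""

    group: str
    n: int
    counts: dict[str, int]
    pct_total_mislabeled: float
    pct_conservative_mislabeled: float

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n:
            raise ValueError("category counts do not sum to n")


def _summary_for(group: str, cats: pd.Series) -> AuditSummary:
    counts = {c: int((cats == c).sum()) for c in CATEGORIES}
    n = len(cats)
    total = sum(counts[c] for c in TOTAL_CATEGORIES)
    cons = sum(counts[c] for c in CONSERVATIVE_CATEGORIES)
    return AuditSummary(
        group=group,
        n=n,
        counts=counts,
        pct_total_mislabeled=100.0 * total / n,
        pct_conservative_mislabeled=100.0 * cons / n,
    )


def summarize(classified: pd.DataFrame, by: str | None = None) -> list[AuditSummary]:
    """Aggregate classified records into per-group audit summaries.

    ``by`` is ``None`` (single overall row) or a column of the classified
    frame (``year``, ``cohort``, ``taxon_group``).  Unregulated records stay
    in every denominator as not-mislabeled; groups without records are
    omitted.  Percentages are exact (no rounding); render at one decimal to
    match the survey's tables.
    """
    if classified.empty:
        raise ValueError("no classified records to summarize")
    if by is None:
        return [_summary_for("all", classified["category"])]
    out = [
        _summary_for(str(key), sub["category"])
        for key, sub in classified.groupby(by, sort=True, dropna=True)
    ]
    return out


class DegenerateTableError(ValueError):
    """A 2x2 table with an empty row or column; association tests refuse it."""


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 integer counts with labels, the common currency of the stats layer."""

    counts: tuple[tuple[int, int], tuple[int, int]]
    row_labels: tuple[str, str] = ("row0", "row1")
    col_labels: tuple[str, str] = ("col0", "col1")
    n_dropped: int = 0  # records lost to exclusions while building the table

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.shape != (2, 2) or (arr < 0).any():
            raise ValueError("counts must be a 2x2 non-negative table")
        if arr.sum() < 1:
            raise ValueError("empty table")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)

    def require_nondegenerate(self) -> None:
        arr = self.array
        if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
            raise DegenerateTableError(
                "table has an empty row or column; no association test can run"
            )


_FACTORS = {
    "cohort": lambda df: df["cohort"].map(
        {"invertebrate": "invertebrate", "finfish": "finfish"}
    ),
    "total_mislabeled": lambda df: df["total_mislabeled"].map(
        {True: "mislabeled", False: "not_mislabeled"}
    ),
    "conservative_mislabeled": lambda df: df["conservative_mislabeled"].map(
        {True: "mislabeled", False: "not_mislabeled"}
    ),
    "precision": lambda df: df["precision"].where(
        df["precision"] != "excluded", other=pd.NA
    ),
    "concern": lambda df: df["concern"].where(
        df["concern"] != "excluded", other=pd.NA
    ),
}

_LEVELS = {
    "cohort": ("invertebrate", "finfish"),
    "total_mislabeled": ("mislabeled", "not_mislabeled"),
    "conservative_mislabeled": ("mislabeled", "not_mislabeled"),
    "precision": ("ambiguous", "precise"),
    "concern": ("concern", "least_concern"),
}


def crosstab(
    classified: pd.DataFrame, row_factor: str, col_factor: str
) -> ContingencyTable:
    """Build the 2x2 table of two dichotomous factors after exclusions.

    Unregulated records drop out of the precision factor and NA/DD records
    out of the conservation factor; the number of dropped records is kept on
    the table.  An empty row or column raises
    :class:`DegenerateTableError` immediately.
    """
    for factor in (row_factor, col_factor):
        if factor not in _FACTORS:
            raise ValueError(
                f"unknown factor {factor!r}; choose from {sorted(_FACTORS)}"
            )
    rows = _FACTORS[row_factor](classified)
    cols = _FACTORS[col_factor](classified)
    keep = rows.notna() & cols.notna()
    rlev, clev = _LEVELS[row_factor], _LEVELS[col_factor]
    counts = tuple(
        tuple(int(((rows == r) & (cols == c) & keep).sum()) for c in clev)
        for r in rlev
    )
    table = ContingencyTable(
        counts=counts,
        row_labels=rlev,
        col_labels=clev,
        n_dropped=int((~keep).sum()),
    )
    table.require_nondegenerate()
    return table
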