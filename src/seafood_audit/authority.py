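"""Market-name authority list and conservation-status registry.

The authority list is a snapshot in the style of the CFIA Fish List: it maps
each *market name* (the name a seafood product is sold under) to the set of
species that may acceptably be sold under that name.  Four kinds of entry are
distinguished:

``on_list``
    A regulated market name with a non-empty acceptable-species set.  Species
    may be given as Latin binomials or intensionally as whole genera
    (``genus:Sebastes`` means "any species of *Sebastes*").
``alias``
    An off-list name that a consumer would reasonably read as one particular
    on-list name ("unagi" -> "eel").  Aliases resolve transitively to exactly
    one on-list entry.
``invalid``
    An off-list name too unusual for any appeal to the list; the entry may
    carry the species a buyer could conceivably have expected, which is used
    to separate an invalid *name* from an outright product substitution.
``unregulated``
    A name legally outside the list (mixed products such as "seafood medley").

Conservation categories follow the IUCN Red List seven-value scale.  The
registry assigns each species one category and products that barcode to
several species take the *worst case* (most severe) category among their
candidates; data-based categories (LC-CR) always dominate NA/DD.
"""

from __future__ import annotations

import csv
import io
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "IUCN_CATEGORIES",
    "CONCERN_CATEGORIES",
    "AuthorityEntry",
    "Authority",
    "ConservationAssignment",
    "StatusRegistry",
    "AuthorityError",
    "UnknownMarketNameError",
    "UnregulatedNameError",
    "normalize_name",
    "load_authority",
    "load_status_registry",
]

#: Severity order, least to most severe.  "Not Applicable" (absent from the
#: Red List) and "Data Deficient" sort below every data-based category.
IUCN_CATEGORIES = ("NA", "DD", "LC", "NT", "VU", "EN", "CR")
_SEVERITY = {cat: i for i, cat in enumerate(IUCN_CATEGORIES)}

#: Categories counting as "conservation concern" (vulnerable or higher).
CONCERN_CATEGORIES = frozenset({"VU", "EN", "CR"})
#: Categories excluded from conservation analyses (no data-based status).
EXCLUDED_CATEGORIES = frozenset({"NA", "DD"})

LIST_STATUSES = ("on_list", "alias", "invalid", "unregulated")


class AuthorityError(ValueError):
    """Malformed authority or status table."""


class UnknownMarketNameError(KeyError):
    """Market name absent from every authority table."""


class UnregulatedNameError(ValueError):
    """Raised when a precision call is requested for an unregulated name."""


def normalize_name(raw: str) -> str:
    """Canonicalize a market name into a lookup key.

    Lowercases, strips diacritics, replaces every non-alphanumeric character
    (punctuation, dashes, slashes, parentheses) with a space and collapses
    runs of whitespace.  Deterministic and idempotent.

    >>> normalize_name("Malpeque Oyster")
    'malpeque oyster'
    >>> normalize_name("Hamachi– Yellow Tail Tuna")
    'hamachi yellow tail tuna'
    """
    if not isinstance(raw, str) or not raw.strip():
        raise AuthorityError("market name is empty or not text")
    text = unicodedata.normalize("NFKD", raw)
    text = "".join(ch for ch in text if not unicodedata.combining(ch))
    text = "".join(ch if ch.isalnum() else " " for ch in text.lower())
    return " ".join(text.split())


def _genus_of(binomial: str) -> str:
    return binomial.split()[0]


@dataclass(frozen=True)
class AuthorityEntry:
    """One market name and the species acceptably sold under it.

    ``species`` holds explicit Latin binomials; ``genera`` holds genus-wide
    allowances.  For ``invalid`` entries the two fields carry the *expected*
    species instead (what a buyer could conceivably have meant), and for
    ``alias`` entries they are empty - the alias target's set applies.
    """

    market_name: str
    list_status: str
    species: frozenset[str] = frozenset()
    genera: frozenset[str] = frozenset()
    alias_of: str | None = None
    multi_referent: bool = False
    taxon_group: str | None = None
    cohort: str | None = None

    def __post_init__(self) -> None:
        if self.list_status not in LIST_STATUSES:
            raise AuthorityError(
                f"{self.market_name!r}: unknown list_status {self.list_status!r}"
            )
        if self.list_status == "on_list" and not (self.species or self.genera):
            raise AuthorityError(
                f"{self.market_name!r}: on-list entry with empty acceptable set"
            )
        if self.list_status == "alias" and not self.alias_of:
            raise AuthorityError(f"{self.market_name!r}: alias without target")

    def accepts(self, binomial: str) -> bool:
        """Whether ``binomial`` may acceptably be sold under this name."""
        return binomial in self.species or _genus_of(binomial) in self.genera

    @property
    def genus_level(self) -> bool:
        return bool(self.genera)


class Authority:
    """Validated collection of authority entries keyed by normalized name."""

    def __init__(self, entries: Iterable[AuthorityEntry]):
        self._entries: dict[str, AuthorityEntry] = {}
        for entry in entries:
            if entry.market_name in self._entries:
                raise AuthorityError(f"duplicate market name {entry.market_name!r}")
            self._entries[entry.market_name] = entry
        self._validate_aliases()

    def _validate_aliases(self) -> None:
        for entry in self._entries.values():
            if entry.list_status != "alias":
                continue
            seen = {entry.market_name}
            target = entry
            while target.list_status == "alias":
                nxt = self._entries.get(normalize_name(target.alias_of))
                if nxt is None:
                    raise AuthorityError(
                        f"alias {entry.market_name!r} points at unknown "
                        f"name {target.alias_of!r}"
                    )
                if nxt.market_name in seen:
                    raise AuthorityError(
                        f"cyclic alias chain through {entry.market_name!r}"
                    )
                seen.add(nxt.market_name)
                target = nxt
            if target.list_status != "on_list":
                raise AuthorityError(
                    f"alias {entry.market_name!r} resolves to "
                    f"{target.market_name!r} which is not on-list"
                )

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries.values())

    def get(self, name: str) -> AuthorityEntry | None:
        try:
            return self._entries.get(normalize_name(name))
        except AuthorityError:
            return None

    def lookup(self, name: str) -> AuthorityEntry:
        """Return the entry for ``name``; aliases are *not* resolved here."""
        entry = self.get(name)
        if entry is None:
            raise UnknownMarketNameError(name)
        return entry

    def resolve(self, name: str) -> AuthorityEntry:
        """Return the effective entry: aliases resolved to their on-list target."""
        entry = self.lookup(name)
        while entry.list_status == "alias":
            entry = self.lookup(entry.alias_of)
        return entry

    def classify_precision(self, name: str) -> str:
        """``precise`` or ``ambiguous`` for a regulated or adjudicated name.

        A name is precise iff exactly one species can be sold under it.
        Genus-wide allowances and designated multi-referent off-list names
        ("Pacific rockfish", "red tuna") are ambiguous.  Unregulated names
        have no precision; asking for one raises :class:`UnregulatedNameError`.
        """
        entry = self.lookup(name)
        if entry.list_status == "unregulated":
            raise UnregulatedNameError(
                f"{name!r} is not regulated by the authority list; "
                "excluded from precision analyses"
            )
        if entry.multi_referent:
            return "ambiguous"
        resolved = entry if entry.list_status == "invalid" else self.resolve(name)
        if resolved.multi_referent or resolved.genus_level:
            return "ambiguous"
        return "precise" if len(resolved.species) == 1 else "ambiguous"


@dataclass(frozen=True)
class ConservationAssignment:
    """Worst-case IUCN category for a product plus its concern dichotomy."""

    status: str
    concern: str = field(init=False)

    def __post_init__(self) -> None:
        if self.status not in _SEVERITY:
            raise AuthorityError(f"unknown IUCN category {self.status!r}")
        if self.status in CONCERN_CATEGORIES:
            concern = "concern"
        elif self.status in EXCLUDED_CATEGORIES:
            concern = "excluded"
        else:
            concern = "least_concern"
        object.__setattr__(self, "concern", concern)


class StatusRegistry:
    """Species -> IUCN category table with worst-case assignment."""

    def __init__(self, categories: Mapping[str, str]):
        for sp, cat in categories.items():
            if cat not in _SEVERITY:
                raise AuthorityError(f"{sp!r}: unknown IUCN category {cat!r}")
        self._categories = dict(categories)

    def __len__(self) -> int:
        return len(self._categories)

    def category(self, species: str) -> str:
        """Category for one species; unlisted species are Not Applicable."""
        return self._categories.get(species, "NA")

    def assign_status(self, candidates: Iterable[str]) -> ConservationAssignment:
        """Worst-case category over a barcode candidate set.

        With several candidate species the most severe category wins under
        the order NA < DD < LC < NT < VU < EN < CR, so any assessed category
        beats NA/DD.  Order- and duplication-invariant.
        """
        cands = list(candidates)
        if not cands:
            raise AuthorityError("empty barcode candidate set")
        worst = max((self.category(sp) for sp in cands), key=_SEVERITY.__getitem__)
        return ConservationAssignment(worst)


def severity(category: str) -> int:
    """Rank of a category in the severity order (0 = NA ... 6 = CR)."""
    try:
        return _SEVERITY[category]
    except KeyError:
        raise AuthorityError(f"unknown IUCN category {category!r}") from None


def _parse_species_field(text: str) -> tuple[frozenset[str], frozenset[str]]:
    species, genera = set(), set()
    for token in filter(None, (t.strip() for t in text.split(";"))):
        if token.startswith("genus:"):
            genera.add(token.removeprefix("genus:").strip())
        else:
            species.add(token)
    return frozenset(species), frozenset(genera)


def _open_rows(source) -> Iterable[dict]:
    if isinstance(source, (str, Path)):
        handle = open(source, newline="", encoding="utf-8")
    elif isinstance(source, io.StringIO):
        handle = source
    else:
        handle = io.StringIO(source.read())
    with handle:
        yield from csv.DictReader(handle, delimiter="\t")


def load_authority(source) -> Authority:
    """Read an authority table from TSV.

    Columns: ``market_name``, ``list_status``, ``species`` (semicolon-joined
    binomials or ``genus:<Name>`` tokens), ``alias_of``, ``multi_referent``
    (0/1), optional ``taxon_group`` and ``cohort``.  Errors carry the
    offending line number.
    """
    entries = []
    for lineno, row in enumerate(_open_rows(source), start=2):
        try:
            species, genera = _parse_species_field(row.get("species") or "")
            entries.append(
                AuthorityEntry(
                    market_name=normalize_name(row["market_name"]),
                    list_status=(row["list_status"] or "").strip(),
                    species=species,
                    genera=genera,
                    alias_of=(row.get("alias_of") or "").strip() or None,
                    multi_referent=(row.get("multi_referent") or "0").strip()
                    in {"1", "true", "True"},
                    taxon_group=(row.get("taxon_group") or "").strip() or None,
                    cohort=(row.get("cohort") or "").strip() or None,
                )
            )
        except (KeyError, AuthorityError) as exc:
            raise AuthorityError(f"authority table line {lineno}: {exc}") from exc
    return Authority(entries)


def load_status_registry(source) -> StatusRegistry:
    """Read a species -> IUCN category TSV (columns ``species``, ``category``)."""
    categories: dict[str, str] = {}
    for lineno, row in enumerate(_open_rows(source), start=2):
        sp = (row.get("species") or "").strip()
        cat = (row.get("category") or "").strip()
        if not sp or cat not in _SEVERITY:
            raise AuthorityError(
                f"status table line {lineno}: bad species/category "
                f"({sp!r}, {cat!r})"
            )
        if sp in categories:
            raise AuthorityError(f"status table line {lineno}: duplicate {sp!r}")
        categories[sp] = cat
    return StatusRegistry(categories)
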