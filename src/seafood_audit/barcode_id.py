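"""Local stand-in for web-based COI barcode identification.

Assigns a candidate species set to a query sequence by percent identity
under Needleman-Wunsch global alignment against a reference collection
(FASTA with ``accession|Genus_species`` headers).  This is a transparent,
auditable substitute for a full identification engine: fixed scoring
(match +1, mismatch -1, linear gap -2), deterministic tie-breaking and
explicit QC flags, with no claim of equivalence to any online service.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO

__all__ = [
    "ALPHABET",
    "ReferenceDB",
    "IdentificationResult",
    "global_identity",
    "identify",
    "qc_sequence",
    "MIN_IDENTITY",
    "TIE_WINDOW",
    "MIN_LENGTH",
]

ALPHABET = frozenset("ACGTN")
MATCH, MISMATCH, GAP = 1, -1, -2

#: Default thresholds; exposed so a run configuration can override them.
MIN_IDENTITY = 97.0
TIE_WINDOW = 0.5
MIN_LENGTH = 200
MAX_N_FRACTION = 0.05


def _check_sequence(seq: str, label: str) -> str:
    seq = seq.upper()
    if not seq:
        raise ValueError(f"{label}: empty sequence")
    for pos, ch in enumerate(seq):
        if ch not in ALPHABET:
            raise ValueError(
                f"{label}: illegal character {ch!r} at position {pos}"
            )
    return seq


def global_identity(a: str, b: str) -> float:
    """Percent identity of the optimal global alignment of two sequences.

    Needleman-Wunsch with match +1, mismatch -1, linear gap -2; ``N``
    matches nothing and scores as a mismatch.  Identity is 100 x matched
    columns / total alignment columns of one optimal alignment; DP ties are
    broken deterministically (diagonal over up over left) so the value is
    reproducible and symmetric.
    """
    a = _check_sequence(a, "first sequence")
    b = _check_sequence(b, "second sequence")
    n, m = len(a), len(b)
    arr_a = np.frombuffer(a.encode(), dtype=np.uint8)
    arr_b = np.frombuffer(b.encode(), dtype=np.uint8)
    n_code = ord("N")

    score = np.empty((n + 1, m + 1), dtype=np.int32)
    score[0, :] = GAP * np.arange(m + 1)
    score[:, 0] = GAP * np.arange(n + 1)
    sub = np.where(
        (arr_a[:, None] == arr_b[None, :])
        & (arr_a[:, None] != n_code),
        MATCH,
        MISMATCH,
    ).astype(np.int32)
    # Linear gaps let the left-gap recursion collapse into a running max:
    # row[j] = GAP*j + max over k <= j of (best_diag_up[k] - GAP*k).
    jarr = np.arange(1, m + 1, dtype=np.int32)
    u = np.empty(m + 1, dtype=np.int32)
    for i in range(1, n + 1):
        diag = score[i - 1, :-1] + sub[i - 1]
        up = score[i - 1, 1:] + GAP
        best_du = np.maximum(diag, up)
        u[0] = score[i, 0]
        u[1:] = best_du - GAP * jarr
        score[i, 1:] = GAP * jarr + np.maximum.accumulate(u)[1:]

    # Traceback, preferring diagonal, then up, then left.
    i, j = n, m
    matches = columns = 0
    while i > 0 or j > 0:
        if i > 0 and j > 0 and score[i, j] == score[i - 1, j - 1] + sub[i - 1, j - 1]:
            matches += int(sub[i - 1, j - 1] == MATCH)
            i, j = i - 1, j - 1
        elif i > 0 and score[i, j] == score[i - 1, j] + GAP:
            i -= 1
        else:
            j -= 1
        columns += 1
    return 100.0 * matches / columns


@dataclass(frozen=True)
class ReferenceDB:
    """Reference collection of (accession, species, sequence) entries."""

    entries: tuple[tuple[str, str, str], ...]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("empty reference database")
        seen = set()
        for acc, species, seq in self.entries:
            if acc in seen:
                raise ValueError(f"duplicate accession {acc!r}")
            seen.add(acc)
            _check_sequence(seq, acc)

    @property
    def species(self) -> frozenset[str]:
        return frozenset(sp for _, sp, _ in self.entries)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceDB":
        """Load a FASTA whose headers read ``accession|Genus_species``."""
        entries = []
        for rec in SeqIO.parse(str(path), "fasta"):
            if "|" not in rec.id:
                raise ValueError(
                    f"{rec.id!r}: header must be 'accession|Genus_species'"
                )
            acc, species = rec.id.split("|", 1)
            entries.append((acc, species.replace("_", " "), str(rec.seq)))
        return cls(entries=tuple(entries))

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for acc, species, seq in self.entries:
                fh.write(f">{acc}|{species.replace(' ', '_')}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")


@dataclass(frozen=True)
class IdentificationResult:
    """Candidate species for one query with its best identity and QC flags."""

    query_id: str
    candidates: frozenset[str]
    best_identity: float
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not (0.0 <= self.best_identity <= 100.0):
            raise ValueError("identity outside [0, 100]")
        empty_expected = bool({"too_short", "low_identity"} & self.flags)
        if bool(self.candidates) == empty_expected:
            raise ValueError(
                "candidates must be empty exactly when the query is too "
                "short or below the identity floor"
            )


def qc_sequence(
    query: str,
    min_length: int = MIN_LENGTH,
    max_n_fraction: float = MAX_N_FRACTION,
) -> frozenset[str]:
    """Deterministic sequence QC: length and ambiguity-content flags."""
    query = _check_sequence(query, "query")
    flags = set()
    if len(query) < min_length:
        flags.add("too_short")
    if query.count("N") / len(query) > max_n_fraction:
        flags.add("high_ambiguity")
    return frozenset(flags)


def identify(
    query: str,
    db: ReferenceDB,
    query_id: str = "query",
    min_identity: float = MIN_IDENTITY,
    tie_window: float = TIE_WINDOW,
    min_length: int = MIN_LENGTH,
) -> IdentificationResult:
    """Assign candidate species to a COI query by percent identity.

    Candidates are the species of every reference whose identity reaches
    ``max(best - tie_window, min_identity)``, mirroring how a barcode can
    legitimately match several species.  Queries shorter than ``min_length``
    are flagged ``too_short`` and return no candidates (short fragments are
    how contamination slips through); queries whose best identity falls
    below ``min_identity`` are flagged ``low_identity``.
    """
    query = _check_sequence(query, query_id)
    qc = qc_sequence(query, min_length=min_length)
    flags = set(qc - {"high_ambiguity"})
    if "high_ambiguity" in qc:
        flags.add("suspect_contaminant")

    identities: dict[str, float] = {}
    best = 0.0
    for _, species, seq in db.entries:
        ident = global_identity(query, seq)
        best = max(best, ident)
        identities[species] = max(identities.get(species, 0.0), ident)

    if "too_short" in flags:
        return IdentificationResult(
            query_id=query_id,
            candidates=frozenset(),
            best_identity=best,
            flags=frozenset(flags),
        )
    if best < min_identity:
        flags.add("low_identity")
        return IdentificationResult(
            query_id=query_id,
            candidates=frozenset(),
            best_identity=best,
            flags=frozenset(flags),
        )
    floor = max(best - tie_window, min_identity)
    candidates = frozenset(
        sp for sp, ident in identities.items() if ident >= floor
    )
    if len(candidates) > 1:
        flags.add("tie_multi_species")
    return IdentificationResult(
        query_id=query_id,
        candidates=candidates,
        best_identity=best,
        flags=frozenset(flags),
    )


def identify_all(
    queries: Iterable[tuple[str, str]],
    db: ReferenceDB,
    **kwargs,
) -> list[IdentificationResult]:
    """Identify a batch of (query_id, sequence) pairs."""
    return [identify(seq, db, query_id=qid, **kwargs) for qid, seq in queries]
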