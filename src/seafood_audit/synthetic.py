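"""Packaged survey fixture and parameterized synthetic surveys.

Two sources of test input, both download-free:

* :func:`load_fixture` returns the packaged transcription of the Calgary
  market survey (109 invertebrate / 347 finfish products with their
  authority-list and conservation-status snapshots).  Fixture files are
  content-addressed; a checksum mismatch is an error.
* :func:`generate_survey` draws a synthetic survey with *known truth*:
  configurable semantic/invalid/substitution rates, market-name ambiguity
  fraction and per-cell conservation-concern probabilities, for recovery
  and coverage tests.  One seeded generator is threaded through every draw;
  the same config and seed reproduce the same survey byte for byte.
* :func:`generate_refdb` builds a small COI-like reference database with
  species-level clades for exercising the identification stand-in.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .authority import (
    Authority,
    AuthorityEntry,
    StatusRegistry,
    load_authority,
    load_status_registry,
    normalize_name,
)
from .barcode_id import ReferenceDB
from .classify import SampleRecord

__all__ = [
    "FixtureBundle",
    "SurveyConfig",
    "FixtureIntegrityError",
    "load_fixture",
    "generate_survey",
    "generate_refdb",
]

_FIXTURE_PKG = "seafood_audit._fixtures"


class FixtureIntegrityError(RuntimeError):
    """A packaged fixture file does not match its recorded checksum."""


@dataclass(frozen=True)
class FixtureBundle:
    """One cohort of the packaged survey fixture."""

    cohort: str
    records: tuple[SampleRecord, ...]
    authority: Authority
    status_registry: StatusRegistry
    expected: pd.DataFrame  # per-record frame incl. the survey's adjudication
    table_counts: pd.DataFrame  # per-market-name S/IN/PS transcription
    year_counts: pd.DataFrame  # year-by-year tallies with printed percentages


def _fixture_root() -> Path:
    return Path(__file__).resolve().parent / "_fixtures"


def _read_checked(name: str, root: Path, manifest: dict) -> Path:
    path = root / name
    if name not in manifest:
        raise FixtureIntegrityError(f"{name} missing from fixture manifest")
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    if digest != manifest[name]:
        raise FixtureIntegrityError(
            f"{name}: checksum mismatch (expected {manifest[name][:12]}..., "
            f"got {digest[:12]}...); fixture files are content-addressed"
        )
    return path


def load_fixture(name: str, root: Path | None = None) -> FixtureBundle:
    """Load one packaged survey cohort: ``invertebrates`` or ``finfish``.

    Every file is verified against the sha256 manifest before parsing.
    """
    cohorts = {"invertebrates": "invertebrate", "finfish": "finfish"}
    if name not in cohorts:
        raise ValueError(f"unknown fixture {name!r}; choose from {sorted(cohorts)}")
    cohort = cohorts[name]
    root = root if root is not None else _fixture_root()
    manifest = json.loads((root / "manifest.json").read_text(encoding="utf-8"))

    records_file = (
        "records_invertebrates.tsv" if cohort == "invertebrate"
        else "records_finfish.tsv"
    )
    frame = pd.read_csv(
        _read_checked(records_file, root, manifest), sep="\t", dtype=str
    )
    frame["year"] = frame["year"].astype(int)
    frame["imputed"] = frame["imputed"].astype(int).astype(bool)
    records = tuple(
        SampleRecord(
            sample_id=row.sample_id,
            year=int(row.year),
            cohort=row.cohort,
            market_name_raw=row.market_name_raw,
            taxon_group=row.taxon_group,
            barcode_candidates=frozenset(row.barcode_candidates.split(";")),
        )
        for row in frame.itertuples()
    )
    authority = load_authority(_read_checked("authority.tsv", root, manifest))
    registry = load_status_registry(_read_checked("status.tsv", root, manifest))
    table_counts = pd.read_csv(
        _read_checked("table_counts.tsv", root, manifest), sep="\t"
    )
    year_counts = pd.read_csv(
        _read_checked("year_counts.tsv", root, manifest), sep="\t"
    )
    return FixtureBundle(
        cohort=cohort,
        records=records,
        authority=authority,
        status_registry=registry,
        expected=frame,
        table_counts=table_counts[table_counts["cohort"] == cohort].reset_index(
            drop=True
        ),
        year_counts=year_counts[year_counts["cohort"] == cohort].reset_index(
            drop=True
        ),
    )


# -- Synthetic surveys ------------------------------------------------------


@dataclass(frozen=True)
class SurveyConfig:
    """Generating conditions for one synthetic survey.

    ``concern_probability`` maps the four (precision, accuracy) cells to the
    probability that the barcoded species is of conservation concern; keys
    are (is_ambiguous, is_conservative_mislabeled) booleans.  Equivalently a
    2x2x2 logistic model's cell probabilities.
    """

    n_samples: int = 500
    rate_semantic: float = 0.05
    rate_invalid: float = 0.02
    rate_substitution: float = 0.20
    ambiguous_fraction: float = 0.6
    # Default cell probabilities follow the fitted finfish model's cell
    # log-odds (intercept -2.11, precision +3.39, accuracy +3.21,
    # interaction -3.39 on the logit scale).
    concern_probability: dict = field(
        default_factory=lambda: {
            (False, False): 0.108,
            (False, True): 0.750,
            (True, False): 0.783,
            (True, True): 0.750,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        rates = (self.rate_semantic, self.rate_invalid, self.rate_substitution)
        if any(not 0 <= r <= 1 for r in rates) or sum(rates) > 1:
            raise ValueError("mislabeling rates must lie in [0,1] and sum <= 1")
        if not 0 <= self.ambiguous_fraction <= 1:
            raise ValueError("ambiguous_fraction must lie in [0, 1]")
        for key, p in self.concern_probability.items():
            if not 0 <= p <= 1:
                raise ValueError(f"concern probability {key} outside [0, 1]")
        if self.n_samples < 1:
            raise ValueError("need at least one sample")


def _species_name(k: int) -> str:
    return f"Simulatus sp{k:05d}"


def generate_survey(
    config: SurveyConfig,
) -> tuple[list[SampleRecord], Authority, StatusRegistry, pd.DataFrame]:
    """Draw a synthetic survey with a full latent truth table.

    Every sample gets its own market name (precise or ambiguous) and its own
    barcoded species, so per-record draws are independent and the generating
    rates are exactly the Bernoulli parameters the classifier should
    recover.  Mislabeling type is drawn per record; the barcode candidate
    set is then constructed to *be* that type under the emitted authority
    table:

    * proper: a species acceptable under the name;
    * semantic: the record is sold under an alias of the name and barcodes
      to an acceptable species of the alias target;
    * invalid: the record is sold under an uninterpretable name whose
      expectation covers the barcode;
    * substitution: a species outside everything the name allows.

    Conservation concern is drawn from the (precision, accuracy) cell
    probability and realized as a VU (concern) or LC (least concern) status
    of the barcoded species.
    """
    rng = np.random.default_rng(config.seed)
    entries: list[AuthorityEntry] = []
    categories: dict[str, str] = {}
    records: list[SampleRecord] = []
    truth_rows = []
    type_p = [
        config.rate_semantic,
        config.rate_invalid,
        config.rate_substitution,
    ]
    type_p.append(1.0 - sum(type_p))
    species_counter = 0

    def new_species(concern: bool) -> str:
        nonlocal species_counter
        species_counter += 1
        sp = _species_name(species_counter)
        categories[sp] = "VU" if concern else "LC"
        return sp

    for i in range(config.n_samples):
        ambiguous = bool(rng.random() < config.ambiguous_fraction)
        mislabel_type = ("semantic", "invalid", "substitution", "proper")[
            int(rng.choice(4, p=type_p))
        ]
        conservative = mislabel_type in {"invalid", "substitution"}
        concern = bool(
            rng.random() < config.concern_probability[(ambiguous, conservative)]
        )
        barcoded = new_species(concern)
        # Acceptable set of the on-list name: the barcoded species for
        # accurate outcomes plus filler species when the name is ambiguous.
        fillers = [new_species(False) for _ in range(2 if ambiguous else 0)]
        base_name = f"survey fish {i:05d}"
        if mislabel_type in {"proper", "semantic", "substitution"}:
            acceptable = fillers + (
                [barcoded] if mislabel_type != "substitution" else []
            )
            if not acceptable:  # precise substitution: one decoy referent
                acceptable = [new_species(False)]
            entries.append(
                AuthorityEntry(
                    market_name=normalize_name(base_name),
                    list_status="on_list",
                    species=frozenset(acceptable),
                )
            )
            if mislabel_type == "semantic":
                sold_under = f"alias {i:05d}"
                entries.append(
                    AuthorityEntry(
                        market_name=normalize_name(sold_under),
                        list_status="alias",
                        alias_of=normalize_name(base_name),
                    )
                )
            else:
                sold_under = base_name
        else:  # invalid name
            sold_under = f"mystery label {i:05d}"
            expectation = [barcoded] + fillers
            entries.append(
                AuthorityEntry(
                    market_name=normalize_name(sold_under),
                    list_status="invalid",
                    species=frozenset(expectation),
                    multi_referent=len(expectation) > 1,
                )
            )
        records.append(
            SampleRecord(
                sample_id=f"SYN-{i:05d}",
                year=2020,
                cohort="finfish",
                market_name_raw=sold_under,
                barcode_candidates=frozenset([barcoded]),
                taxon_group="synthetic",
            )
        )
        truth_rows.append(
            {
                "sample_id": f"SYN-{i:05d}",
                "market_name": normalize_name(sold_under),
                "true_type": mislabel_type,
                "true_ambiguous": ambiguous,
                "true_concern": concern,
                "barcoded_species": barcoded,
            }
        )
    authority = Authority(entries)
    registry = StatusRegistry(categories)
    truth = pd.DataFrame(truth_rows)
    return records, authority, registry, truth


# -- Synthetic reference database -------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    hits = np.flatnonzero(rng.random(seq.size) < rate)
    if hits.size:
        # Substitute with a uniformly drawn *different* base.
        shift = rng.integers(1, 4, size=hits.size)
        idx = (np.searchsorted(_BASES, out[hits]) + shift) % 4
        out[hits] = _BASES[idx]
    return out


def generate_refdb(
    n_species: int = 5,
    n_per_species: int = 3,
    seq_length: int = 600,
    divergence: float = 0.10,
    seed: int = 0,
) -> ReferenceDB:
    """Synthetic COI-like reference database with species-level clades.

    Each species descends from a shared ancestor mutated at ``divergence``
    per site; members within a species differ at ``divergence / 20`` per
    site, keeping within-species identity well above between-species
    identity so that identification is well-posed.  A divergence below about
    1% is refused - clades would overlap the within-species noise.
    """
    if not 0.0 < divergence < 0.5:
        raise ValueError("divergence must lie in (0, 0.5)")
    if divergence < 0.01:
        raise ValueError(
            "divergence below 1% makes species clades indistinguishable "
            "from within-species variation"
        )
    rng = np.random.default_rng(seed)
    ancestor = rng.choice(_BASES, size=seq_length)
    entries = []
    for s in range(n_species):
        species = f"Refgenus species{s:03d}"
        consensus = _mutate(ancestor, divergence, rng)
        for m in range(n_per_species):
            member = _mutate(consensus, divergence / 20.0, rng)
            entries.append(
                (f"REF{s:03d}-{m:02d}", species, member.tobytes().decode())
            )
    return ReferenceDB(entries=tuple(entries))
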