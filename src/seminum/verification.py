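"""Two-step taxon-name verification and status harmonization.

Each unique name is checked against a provider checklist in two steps:

1. **Exact search** — authority-free exact lookup.  A single hit yields the
   provider's status mapped into the harmonized vocabulary; more than one hit
   (homonyms) yields ``Ambiguous``.
2. **Relaxed search** — only if step 1 returned nothing: all names at the
   next higher rank (congeners, or names under the binomial) are screened
   with Levenshtein distance, keeping candidates closer than 3 edits.  A
   single candidate spelling is adopted as the alternative name and carries
   its record's status; several candidate spellings yield ``Ambiguous``;
   none leaves the name unverified (``NA``).

The harmonized status vocabulary is TPL's four statuses (Accepted, Synonym,
Unresolved, Misapplied) extended by ``Ambiguous`` for homonyms or spelling
collisions and ``NA`` for "not found by this provider".  COL's "Accepted
name" and "Provisionally accepted name" both map to Accepted.  EOL returns
no status with a search result, so a verified EOL hit carries status NA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence, TextIO

import edlib

from .checklist import ChecklistRecord, ChecklistStore
from .names import CanonicalName

logger = logging.getLogger(__name__)

#: default bound: distances strictly below 3 are "very similar"
MAX_DISTANCE = 2


class Status(str, Enum):
    ACCEPTED = "Accepted"
    SYNONYM = "Synonym"
    UNRESOLVED = "Unresolved"
    MISAPPLIED = "Misapplied"
    AMBIGUOUS = "Ambiguous"
    NA = "NA"


class MatchType(str, Enum):
    EXACT = "exact"
    RELAXED = "relaxed"
    NONE = "none"


_COL_MAP = {
    "Accepted name": Status.ACCEPTED,
    "Provisionally accepted name": Status.ACCEPTED,
    "Synonym": Status.SYNONYM,
}
_TPL_MAP = {s.value: s for s in (Status.ACCEPTED, Status.SYNONYM, Status.UNRESOLVED, Status.MISAPPLIED)}


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (insert/delete/substitute), case-insensitive."""
    a, b = a.casefold(), b.casefold()
    if a == b:
        return 0
    return edlib.align(a, b, task="distance")["editDistance"]


def harmonize_status(provider: str, raw_status: str, n_matches: int) -> Status:
    """Map a provider's raw status into the harmonized vocabulary.

    More than one match forces ``Ambiguous`` regardless of the raw status.
    Providers that return no status with their results (EOL) yield ``NA``.
    """
    if n_matches < 1:
        raise ValueError("harmonize_status requires at least one match")
    if provider == "EOL":
        return Status.NA
    if n_matches > 1:
        return Status.AMBIGUOUS
    table = _COL_MAP if provider == "COL" else _TPL_MAP
    try:
        return table[raw_status]
    except KeyError:
        raise ValueError(f"unknown {provider} status {raw_status!r}") from None


@dataclass(frozen=True)
class VerificationResult:
    """Outcome of verifying one name against one provider."""

    query_name: CanonicalName
    provider: str
    verified: bool
    match_type: MatchType
    matched_record_ids: tuple[str, ...] = ()
    alternative_name: str = ""
    status: Status = Status.NA
    edit_distance: int | None = None


@dataclass
class VerificationAudit:
    """Instrumentation: proves relaxed search runs only after an exact miss."""

    exact_attempts: int = 0
    relaxed_attempts: int = 0
    relaxed_after_exact_hit: int = 0

    def ok(self) -> bool:
        return self.relaxed_after_exact_hit == 0


def _status_of_spelling(provider: str, records: Sequence[ChecklistRecord]) -> Status:
    """Harmonized status of one candidate spelling.

    Homonym duplicates of a single spelling do not by themselves force
    ambiguity in the relaxed step; but if their statuses disagree the result
    is Ambiguous.
    """
    statuses = {harmonize_status(provider, r.raw_status, 1) for r in records}
    return statuses.pop() if len(statuses) == 1 else Status.AMBIGUOUS


def verify_name(
    store: ChecklistStore,
    name: CanonicalName,
    max_distance: int = MAX_DISTANCE,
    audit: VerificationAudit | None = None,
) -> VerificationResult:
    """Verify one canonical name against one provider store (two-step)."""
    provider = store.dialect.provider
    if audit is not None:
        audit.exact_attempts += 1
    hits = store.exact_search(name)
    if hits:
        status = harmonize_status(provider, hits[0].raw_status, len(hits))
        return VerificationResult(
            query_name=name,
            provider=provider,
            verified=True,
            match_type=MatchType.EXACT,
            matched_record_ids=tuple(r.record_id for r in hits),
            status=status,
        )
    if audit is not None:
        audit.relaxed_attempts += 1
        if hits:
            audit.relaxed_after_exact_hit += 1
    candidates: dict[str, list[ChecklistRecord]] = {}
    distances: dict[str, int] = {}
    for rec in store.sibling_names(name):
        d = levenshtein(name.text, rec.name)
        if 0 < d <= max_distance:
            key = rec.name.casefold()
            candidates.setdefault(key, []).append(rec)
            distances[key] = d
    if not candidates:
        return VerificationResult(
            query_name=name, provider=provider, verified=False, match_type=MatchType.NONE
        )
    if len(candidates) == 1:
        ((key, recs),) = candidates.items()
        status = Status.NA if provider == "EOL" else _status_of_spelling(provider, recs)
        return VerificationResult(
            query_name=name,
            provider=provider,
            verified=True,
            match_type=MatchType.RELAXED,
            matched_record_ids=tuple(r.record_id for r in recs),
            alternative_name=recs[0].name,
            status=status,
            edit_distance=distances[key],
        )
    # several distinct candidate spellings: no tie-break on distance
    all_recs = [r for recs in candidates.values() for r in recs]
    nearest = min(distances.values())
    return VerificationResult(
        query_name=name,
        provider=provider,
        verified=True,
        match_type=MatchType.RELAXED,
        matched_record_ids=tuple(r.record_id for r in all_recs),
        alternative_name="",
        status=Status.NA if provider == "EOL" else Status.AMBIGUOUS,
        edit_distance=nearest,
    )


@dataclass
class NameCollection:
    """The scientific name collection: one result per (name, provider)."""

    results: list[VerificationResult] = field(default_factory=list)
    audit: VerificationAudit = field(default_factory=VerificationAudit)

    def by_provider(self, provider: str) -> list[VerificationResult]:
        return [r for r in self.results if r.provider == provider]

    def for_name(self, name: CanonicalName) -> dict[str, VerificationResult]:
        key = name.key
        return {r.provider: r for r in self.results if r.query_name.key == key}

    def providers(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.results:
            seen.setdefault(r.provider, None)
        return list(seen)

    def combined_verified(self) -> list[CanonicalName]:
        """Names verified by at least one provider, first-seen order."""
        out: dict[tuple[str, str], CanonicalName] = {}
        for r in self.results:
            if r.verified and r.query_name.key not in out:
                out[r.query_name.key] = r.query_name
        return list(out.values())

    def unverified(self) -> list[CanonicalName]:
        verified = {n.key for n in self.combined_verified()}
        out: dict[tuple[str, str], CanonicalName] = {}
        for r in self.results:
            if r.query_name.key not in verified:
                out.setdefault(r.query_name.key, r.query_name)
        return list(out.values())


def verify_all(
    stores: dict[str, ChecklistStore],
    unl: Iterable[CanonicalName],
    max_distance: int = MAX_DISTANCE,
) -> NameCollection:
    """Verify every UNL name against every provider store."""
    if not stores:
        raise ValueError("verify_all requires at least one provider store")
    coll = NameCollection()
    for name in unl:
        for store in stores.values():
            coll.results.append(verify_name(store, name, max_distance, audit=coll.audit))
    assert coll.audit.ok(), "relaxed search ran despite an exact hit"
    return coll


def read_collection(fh: TextIO) -> NameCollection:
    """Re-load a verification CSV written by :func:`write_collection`."""
    import csv

    from .names import canonical_from_text

    coll = NameCollection()
    for row in csv.DictReader(fh):
        match_type = MatchType(row["match_type"])
        ids = tuple(filter(None, row["record_id"].split(";")))
        coll.results.append(
            VerificationResult(
                query_name=canonical_from_text(row["name"]),
                provider=row["provider"],
                verified=match_type is not MatchType.NONE,
                match_type=match_type,
                matched_record_ids=ids,
                alternative_name=row["alternative_name"],
                status=Status(row["status"]),
            )
        )
    return coll


VERIFICATION_HEADER = "name,provider,record_id,match_type,alternative_name,status"


def write_collection(coll: NameCollection, fh: TextIO) -> None:
    import csv

    w = csv.writer(fh)
    w.writerow(VERIFICATION_HEADER.split(","))
    for r in coll.results:
        w.writerow(
            [
                r.query_name.text,
                r.provider,
                ";".join(r.matched_record_ids),
                r.match_type.value,
                r.alternative_name,
                r.status.value,
            ]
        )
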