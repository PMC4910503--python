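"""Uniform local store for provider checklist snapshots.

Checklist providers (The Plant List, Catalogue of Life, Encyclopedia of Life,
…) are represented as local CSV snapshots loaded into an in-process indexed
store.  Provider quirks are captured by a :class:`ProviderDialect`: the
declared taxonomic-status vocabulary, and whether the name field may embed
the authority (an EOL trait that defeats naive exact search).  The store
answers the two queries verification needs: exact name lookup (authority
ignored) and enumeration of all names at the next higher rank — congeners
for a species query, infraspecific names under the binomial for an
infraspecific query.
"""

from __future__ import annotations

import csv
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, TextIO

from .names import CanonicalName, Rank

logger = logging.getLogger(__name__)

CHECKLIST_HEADER = [
    "provider",
    "record_id",
    "name",
    "authority",
    "status",
    "accepted_record_id",
    "genus",
    "species_epithet",
    "infraspecific_epithet",
    "confidence",
]

TPL_VOCABULARY = ["Accepted", "Synonym", "Unresolved", "Misapplied"]
COL_VOCABULARY = ["Accepted name", "Provisionally accepted name", "Synonym"]

#: raw statuses that denote a synonym and therefore require an accepted-name link
_SYNONYM_STATUSES = {"Synonym"}


@dataclass(frozen=True)
class ProviderDialect:
    provider: str
    status_vocabulary: tuple[str, ...]
    name_field_may_contain_authority: bool = False
    returns_status: bool = True


DIALECTS: dict[str, ProviderDialect] = {
    "TPL": ProviderDialect("TPL", tuple(TPL_VOCABULARY)),
    "COL": ProviderDialect("COL", tuple(COL_VOCABULARY)),
    # EOL embeds the authority in the name field of some records and returns
    # no taxonomic status with a search result.
    "EOL": ProviderDialect(
        "EOL", ("",), name_field_may_contain_authority=True, returns_status=False
    ),
}


@dataclass(frozen=True)
class ChecklistRecord:
    """One provider row of a checklist snapshot."""

    provider: str
    record_id: str
    name: str
    authority: str = ""
    raw_status: str = ""
    accepted_record_id: str = ""
    genus: str = ""
    species_epithet: str = ""
    infraspecific_epithet: str = ""
    confidence: str = ""


class DuplicateRecordError(ValueError):
    """Two rows of one snapshot share a record_id."""


class ChecklistStore:
    """Indexed in-memory checklist for one provider."""

    def __init__(self, dialect: ProviderDialect):
        self.dialect = dialect
        self.records: dict[str, ChecklistRecord] = {}
        self._by_name: dict[str, list[ChecklistRecord]] = defaultdict(list)
        self._by_genus: dict[str, list[ChecklistRecord]] = defaultdict(list)
        self._by_binomial: dict[tuple[str, str], list[ChecklistRecord]] = defaultdict(list)
        self.rejected_rows: list[tuple[int, str]] = []

    def __len__(self) -> int:
        return len(self.records)

    def add(self, rec: ChecklistRecord) -> None:
        if rec.record_id in self.records:
            raise DuplicateRecordError(
                f"{self.dialect.provider}: duplicate record_id {rec.record_id!r}"
            )
        self.records[rec.record_id] = rec
        self._by_name[rec.name.casefold()].append(rec)
        genus = (rec.genus or rec.name.split()[0]).casefold()
        self._by_genus[genus].append(rec)
        if rec.species_epithet:
            self._by_binomial[(genus, rec.species_epithet.casefold())].append(rec)

    # -- queries ---------------------------------------------------------

    def exact_search(self, name: CanonicalName | str) -> list[ChecklistRecord]:
        """All records matching the query name exactly, authority ignored.

        For dialects whose name field may embed the authority, a record also
        matches when its name field begins with the query followed by a word
        boundary.
        """
        text = name.text if isinstance(name, CanonicalName) else name
        query = text.casefold()
        hits = list(self._by_name.get(query, []))
        if self.dialect.name_field_may_contain_authority:
            seen = {id(r) for r in hits}
            genus = query.split()[0]
            for rec in self._by_genus.get(genus, []):
                if id(rec) in seen:
                    continue
                rn = rec.name.casefold()
                if rn.startswith(query) and len(rn) > len(query) and rn[len(query)] == " ":
                    hits.append(rec)
        return hits

    def sibling_names(self, name: CanonicalName) -> list[ChecklistRecord]:
        """Records at the next higher rank: congeners for a species query,
        names under the binomial for an infraspecific query.  Hybrids are
        treated at species rank within their genus."""
        if name.rank_marker in (Rank.SUBSP, Rank.VAR, Rank.F):
            key = (name.genus.casefold(), name.species_epithet.casefold())
            return list(self._by_binomial.get(key, []))
        return list(self._by_genus.get(name.genus.casefold(), []))

    # -- persistence -----------------------------------------------------

    def dump(self, fh: TextIO) -> None:
        w = csv.writer(fh, quoting=csv.QUOTE_MINIMAL)
        w.writerow(CHECKLIST_HEADER)
        for rec in self.records.values():
            w.writerow(
                [
                    rec.provider,
                    rec.record_id,
                    rec.name,
                    rec.authority,
                    rec.raw_status,
                    rec.accepted_record_id,
                    rec.genus,
                    rec.species_epithet,
                    rec.infraspecific_epithet,
                    rec.confidence,
                ]
            )


def load_checklist(source: str | TextIO, dialect: ProviderDialect) -> ChecklistStore:
    """Load a checklist CSV snapshot, validating against the dialect.

    Rows with a status outside the dialect's vocabulary are rejected and
    logged with their row number; a duplicate record_id is a hard error.
    """
    store = ChecklistStore(dialect)
    own = isinstance(source, str)
    fh = open(source, newline="", encoding="utf-8") if own else source
    try:
        rd = csv.DictReader(fh)
        missing = set(CHECKLIST_HEADER) - set(rd.fieldnames or [])
        if missing:
            raise ValueError(f"checklist CSV missing columns: {sorted(missing)}")
        for rowno, row in enumerate(rd, start=2):
            status = row["status"] or ""
            if status not in dialect.status_vocabulary:
                logger.warning(
                    "%s row %d rejected: unknown status %r",
                    dialect.provider,
                    rowno,
                    status,
                )
                store.rejected_rows.append((rowno, status))
                continue
            if status in _SYNONYM_STATUSES and not row["accepted_record_id"]:
                logger.warning(
                    "%s row %d rejected: synonym without accepted_record_id",
                    dialect.provider,
                    rowno,
                )
                store.rejected_rows.append((rowno, status))
                continue
            store.add(
                ChecklistRecord(
                    provider=row["provider"],
                    record_id=row["record_id"],
                    name=row["name"],
                    authority=row["authority"],
                    raw_status=status,
                    accepted_record_id=row["accepted_record_id"],
                    genus=row["genus"],
                    species_epithet=row["species_epithet"],
                    infraspecific_epithet=row["infraspecific_epithet"],
                    confidence=row["confidence"],
                )
            )
    finally:
        if own:
            fh.close()
    return store


def store_from_records(
    records: Iterable[ChecklistRecord], dialect: ProviderDialect
) -> ChecklistStore:
    store = ChecklistStore(dialect)
    for rec in records:
        store.add(rec)
    return store
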