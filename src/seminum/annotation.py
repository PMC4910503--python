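"""Annotation of verified names with conservation, invasiveness and barcode data.

Four annotation domains are queried per unique verified name:

* **Red List** — IUCN-style conservation category, with the red list's own
  internal synonymy as a second chance;
* **GISIN** — occurrence records flagged exotic/harmful, classed Invasive
  (exotic *and* harmful), Exotic, or Neither;
* **DAISIE** — membership of a European alien-taxa list, with a
  worst-invaders sublist;
* **BOLD** — a two-step barcode lookup: does the taxon exist in the
  taxonomy, and if so how many public sequence records does it carry.

Whenever the original name yields nothing, the *alternative names* of the
taxon — its accepted name and all synonyms according to the TPL-like
checklist — are queried instead (accepted first, then synonyms,
alphabetically).  Every annotation records its provenance: which name
variant produced the hit.  Alternatives are never consulted when the
original name hits; an audit object counts both paths so pipelines can
assert that discipline.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

from .checklist import ChecklistStore
from .names import CanonicalName

logger = logging.getLogger(__name__)

REDLIST_CATEGORIES = (
    "EX", "EW", "CR", "EN", "VU", "NT", "LR/nt", "LR/lc", "LR/cd", "LC", "DD",
)
THREATENED_CATEGORIES = ("CR", "EN", "VU")


# ---------------------------------------------------------------------------
# alternative-name expansion


@dataclass(frozen=True)
class AlternativeNameSet:
    """Accepted name and synonyms of a UNL name, from the TPL-like store."""

    original: str
    accepted: str = ""
    synonyms: tuple[str, ...] = ()

    def query_order(self) -> list[str]:
        """Alternatives in deterministic query order: accepted, then synonyms."""
        out = [self.accepted] if self.accepted else []
        out.extend(self.synonyms)
        return out


def expand_alternatives(tpl_store: ChecklistStore, name: CanonicalName | str) -> AlternativeNameSet:
    """Resolve a name in the TPL-like store and collect its alternative names.

    A synonym record contributes the name of its accepted record plus every
    other record pointing there; an accepted record contributes every record
    pointing to it.  A name absent from the store yields an empty set (the
    fallback is disabled and the miss logged).
    """
    text = name.text if isinstance(name, CanonicalName) else name
    hits = tpl_store.exact_search(text)
    if not hits:
        logger.info("TPL expansion: %r not in store, no alternatives", text)
        return AlternativeNameSet(original=text)
    rec = hits[0]
    if len(hits) > 1:
        logger.info("TPL expansion: %r matches %d records, using the first", text, len(hits))
    if rec.accepted_record_id:
        accepted_rec = tpl_store.records.get(rec.accepted_record_id)
        accepted = accepted_rec.name if accepted_rec else ""
        anchor = rec.accepted_record_id
    else:
        accepted = ""
        anchor = rec.record_id
    lower = text.casefold()
    synonyms = sorted(
        {
            r.name
            for r in tpl_store.records.values()
            if r.accepted_record_id == anchor and r.name.casefold() != lower
        }
    )
    if accepted and accepted.casefold() == lower:
        accepted = ""
    return AlternativeNameSet(original=text, accepted=accepted, synonyms=tuple(synonyms))


@dataclass
class FallbackAudit:
    """Counts per domain: hits via the original name, via alternatives, misses."""

    original_hits: dict[str, int] = field(default_factory=dict)
    alternative_hits: dict[str, int] = field(default_factory=dict)
    misses: dict[str, int] = field(default_factory=dict)
    violations: int = 0

    def record(self, domain: str, provenance: str) -> None:
        bucket = (
            self.original_hits
            if provenance == "original"
            else self.misses
            if provenance == "none"
            else self.alternative_hits
        )
        bucket[domain] = bucket.get(domain, 0) + 1

    def total(self, domain: str) -> int:
        return (
            self.original_hits.get(domain, 0)
            + self.alternative_hits.get(domain, 0)
            + self.misses.get(domain, 0)
        )


# ---------------------------------------------------------------------------
# red list


class RedListStore:
    """Red-list snapshot: primary names with categories plus internal synonyms."""

    HEADER = ["name", "category", "role", "primary_name"]

    def __init__(self) -> None:
        self._primary: dict[str, str] = {}  # name -> category
        self._synonym: dict[str, str] = {}  # synonym name -> primary name

    def add_primary(self, name: str, category: str) -> None:
        if category not in REDLIST_CATEGORIES:
            raise ValueError(f"unknown red-list category {category!r}")
        self._primary[name.casefold()] = category

    def add_synonym(self, name: str, primary_name: str) -> None:
        self._synonym[name.casefold()] = primary_name

    def __len__(self) -> int:
        return len(self._primary)

    def lookup(self, name: str) -> tuple[str, str] | None:
        """(category, 'RL'|'RLsynonym') for a name, primary names first."""
        key = name.casefold()
        if key in self._primary:
            return self._primary[key], "RL"
        if key in self._synonym:
            primary = self._synonym[key]
            cat = self._primary.get(primary.casefold())
            if cat is not None:
                return cat, "RLsynonym"
        return None

    def dump(self, fh: TextIO) -> None:
        w = csv.writer(fh)
        w.writerow(self.HEADER)
        for name, cat in self._primary.items():
            w.writerow([name, cat, "primary", ""])
        for syn, primary in self._synonym.items():
            w.writerow([syn, "", "synonym", primary])

    @classmethod
    def load(cls, source: str | TextIO) -> "RedListStore":
        store = cls()
        own = isinstance(source, str)
        fh = open(source, newline="", encoding="utf-8") if own else source
        try:
            for row in csv.DictReader(fh):
                if row["role"] == "primary":
                    store.add_primary(row["name"], row["category"])
                else:
                    store.add_synonym(row["name"], row["primary_name"])
        finally:
            if own:
                fh.close()
        return store


@dataclass(frozen=True)
class RedListAnnotation:
    name: str
    category: str = "none"
    source: str = "none"  # RL | RLsynonym | TPLsynonym | TPLaccepted | none

    def __post_init__(self) -> None:
        if (self.category == "none") != (self.source == "none"):
            raise ValueError("category is none exactly when source is none")


def annotate_redlist(
    redlist_store: RedListStore,
    tpl_store: ChecklistStore,
    name: CanonicalName | str,
    audit: FallbackAudit | None = None,
) -> RedListAnnotation:
    """Red-list category with provenance; first hit in query order wins.

    Order: primary red-list name (RL), red-list-internal synonym (RLsynonym),
    then TPL alternatives — accepted name (TPLaccepted) before synonyms
    (TPLsynonym).
    """
    text = name.text if isinstance(name, CanonicalName) else name
    hit = redlist_store.lookup(text)
    if hit is not None:
        category, source = hit
        if audit is not None:
            audit.record("redlist", "original")
        return RedListAnnotation(name=text, category=category, source=source)
    alts = expand_alternatives(tpl_store, text)
    for alt in alts.query_order():
        alt_hit = redlist_store.lookup(alt)
        if alt_hit is not None:
            source = "TPLaccepted" if alt == alts.accepted else "TPLsynonym"
            if audit is not None:
                audit.record("redlist", source)
            return RedListAnnotation(name=text, category=alt_hit[0], source=source)
    if audit is not None:
        audit.record("redlist", "none")
    return RedListAnnotation(name=text)


# ---------------------------------------------------------------------------
# GISIN


@dataclass(frozen=True)
class OccurrenceRecord:
    exotic: bool
    harmful: bool


class GisinStore:
    """GISIN-style occurrence records keyed by taxon name."""

    HEADER = ["name", "exotic", "harmful"]

    def __init__(self) -> None:
        self._records: dict[str, list[OccurrenceRecord]] = {}

    def add(self, name: str, exotic: bool, harmful: bool) -> None:
        self._records.setdefault(name.casefold(), []).append(OccurrenceRecord(exotic, harmful))

    def __len__(self) -> int:
        return len(self._records)

    def lookup(self, name: str) -> list[OccurrenceRecord]:
        return list(self._records.get(name.casefold(), []))

    def dump(self, fh: TextIO) -> None:
        w = csv.writer(fh)
        w.writerow(self.HEADER)
        for name, recs in self._records.items():
            for r in recs:
                w.writerow([name, str(r.exotic).lower(), str(r.harmful).lower()])

    @classmethod
    def load(cls, source: str | TextIO) -> "GisinStore":
        store = cls()
        own = isinstance(source, str)
        fh = open(source, newline="", encoding="utf-8") if own else source
        try:
            for row in csv.DictReader(fh):
                store.add(row["name"], row["exotic"] == "true", row["harmful"] == "true")
        finally:
            if own:
                fh.close()
        return store


def classify_gisin(records: Sequence[OccurrenceRecord]) -> str:
    """Class of one taxon's occurrence records (order-independent).

    Any record both exotic and harmful makes the taxon potentially Invasive
    in its exotic range; any exotic record alone makes it Exotic; otherwise
    Neither.
    """
    if any(r.exotic and r.harmful for r in records):
        return "Invasive"
    if any(r.exotic for r in records):
        return "Exotic"
    return "Neither"


@dataclass(frozen=True)
class InvasivenessAnnotation:
    name: str
    gisin_class: str = "none"  # Invasive | Exotic | Neither | none
    gisin_provenance: str = "none"  # original | Accepted | Synonym | Unresolved | none
    daisie_alien: bool = False
    daisie_worst: bool = False

    def __post_init__(self) -> None:
        if self.daisie_worst and not self.daisie_alien:
            raise ValueError("worst invaders are a subset of alien taxa")
        if (self.gisin_class == "none") != (self.gisin_provenance == "none"):
            raise ValueError("class is none exactly when no record was found")


def annotate_gisin(
    gisin_store: GisinStore,
    tpl_store: ChecklistStore,
    name: CanonicalName | str,
    audit: FallbackAudit | None = None,
) -> tuple[str, str]:
    """(gisin_class, provenance) for a name, alternatives on original miss.

    The provenance of an alternative hit is the TPL status of the name that
    hit (Accepted, Synonym or Unresolved), mirroring how such recoveries are
    reported.
    """
    text = name.text if isinstance(name, CanonicalName) else name
    records = gisin_store.lookup(text)
    if records:
        if audit is not None:
            audit.record("gisin", "original")
        return classify_gisin(records), "original"
    alts = expand_alternatives(tpl_store, text)
    for alt in alts.query_order():
        records = gisin_store.lookup(alt)
        if records:
            alt_recs = tpl_store.exact_search(alt)
            provenance = alt_recs[0].raw_status if alt_recs else "Synonym"
            if audit is not None:
                audit.record("gisin", provenance)
            return classify_gisin(records), provenance
    if audit is not None:
        audit.record("gisin", "none")
    return "none", "none"


# ---------------------------------------------------------------------------
# DAISIE


class DaisieStore:
    """European alien-taxa list with a worst-invaders sublist."""

    HEADER = ["name", "worst"]

    def __init__(self) -> None:
        self._alien: set[str] = set()
        self._worst: set[str] = set()

    def add(self, name: str, worst: bool = False) -> None:
        key = name.casefold()
        self._alien.add(key)
        if worst:
            self._worst.add(key)

    def __len__(self) -> int:
        return len(self._alien)

    @property
    def n_worst(self) -> int:
        return len(self._worst)

    def dump(self, fh: TextIO) -> None:
        w = csv.writer(fh)
        w.writerow(self.HEADER)
        for name in sorted(self._alien):
            w.writerow([name, str(name in self._worst).lower()])

    @classmethod
    def load(cls, source: str | TextIO) -> "DaisieStore":
        store = cls()
        own = isinstance(source, str)
        fh = open(source, newline="", encoding="utf-8") if own else source
        try:
            for row in csv.DictReader(fh):
                store.add(row["name"], row["worst"] == "true")
        finally:
            if own:
                fh.close()
        return store

    def membership(self, name: str) -> tuple[bool, bool]:
        key = name.casefold()
        return key in self._alien, key in self._worst


def annotate_daisie(daisie_store: DaisieStore, name: CanonicalName | str) -> tuple[bool, bool]:
    """(alien, worst) membership flags on the canonical name."""
    text = name.text if isinstance(name, CanonicalName) else name
    return daisie_store.membership(text)


# ---------------------------------------------------------------------------
# BOLD


class BoldStore:
    """BOLD-style taxonomy with public-record counts per taxon name."""

    HEADER = ["name", "public_records"]

    def __init__(self) -> None:
        self._counts: dict[str, int] = {}

    def add(self, name: str, public_records: int) -> None:
        if public_records < 0:
            raise ValueError("public_records must be non-negative")
        self._counts[name.casefold()] = public_records

    def __len__(self) -> int:
        return len(self._counts)

    def taxon_exists(self, name: str) -> bool:
        return name.casefold() in self._counts

    def record_count(self, name: str) -> int:
        return self._counts[name.casefold()]

    def dump(self, fh: TextIO) -> None:
        w = csv.writer(fh)
        w.writerow(self.HEADER)
        for name, count in self._counts.items():
            w.writerow([name, count])

    @classmethod
    def load(cls, source: str | TextIO) -> "BoldStore":
        store = cls()
        own = isinstance(source, str)
        fh = open(source, newline="", encoding="utf-8") if own else source
        try:
            for row in csv.DictReader(fh):
                store.add(row["name"], int(row["public_records"]))
        finally:
            if own:
                fh.close()
        return store


@dataclass(frozen=True)
class BarcodeAnnotation:
    name: str
    taxon_found: bool = False
    public_records: int = 0
    provenance: str = "none"  # original | TPLsynonym | TPLaccepted | none

    def __post_init__(self) -> None:
        if self.public_records > 0 and not self.taxon_found:
            raise ValueError("records imply the taxon was found")


def annotate_bold(
    bold_store: BoldStore,
    tpl_store: ChecklistStore,
    name: CanonicalName | str,
    audit: FallbackAudit | None = None,
) -> BarcodeAnnotation:
    """Two-step barcode lookup: taxon existence, then public-record count."""
    text = name.text if isinstance(name, CanonicalName) else name
    if bold_store.taxon_exists(text):
        if audit is not None:
            audit.record("bold", "original")
        return BarcodeAnnotation(
            name=text, taxon_found=True, public_records=bold_store.record_count(text),
            provenance="original",
        )
    alts = expand_alternatives(tpl_store, text)
    for alt in alts.query_order():
        if bold_store.taxon_exists(alt):
            provenance = "TPLaccepted" if alt == alts.accepted else "TPLsynonym"
            if audit is not None:
                audit.record("bold", provenance)
            return BarcodeAnnotation(
                name=text, taxon_found=True, public_records=bold_store.record_count(alt),
                provenance=provenance,
            )
    if audit is not None:
        audit.record("bold", "none")
    return BarcodeAnnotation(name=text)


# ---------------------------------------------------------------------------
# batch annotation + output


@dataclass
class AnnotationSet:
    """All annotation outcomes for one pipeline run."""

    redlist: list[RedListAnnotation] = field(default_factory=list)
    invasiveness: list[InvasivenessAnnotation] = field(default_factory=list)
    barcodes: list[BarcodeAnnotation] = field(default_factory=list)
    audit: FallbackAudit = field(default_factory=FallbackAudit)


def annotate_all(
    unl: Iterable[CanonicalName],
    tpl_store: ChecklistStore,
    redlist_store: RedListStore | None = None,
    gisin_store: GisinStore | None = None,
    daisie_store: DaisieStore | None = None,
    bold_store: BoldStore | None = None,
) -> AnnotationSet:
    """Run every configured annotation domain over the unique verified names."""
    out = AnnotationSet()
    for name in unl:
        if redlist_store is not None:
            out.redlist.append(annotate_redlist(redlist_store, tpl_store, name, out.audit))
        gisin_class, gisin_prov = ("none", "none")
        alien, worst = False, False
        if gisin_store is not None:
            gisin_class, gisin_prov = annotate_gisin(gisin_store, tpl_store, name, out.audit)
        if daisie_store is not None:
            alien, worst = annotate_daisie(daisie_store, name)
        if gisin_store is not None or daisie_store is not None:
            text = name.text if isinstance(name, CanonicalName) else name
            out.invasiveness.append(
                InvasivenessAnnotation(
                    name=text,
                    gisin_class=gisin_class,
                    gisin_provenance=gisin_prov,
                    daisie_alien=alien,
                    daisie_worst=worst,
                )
            )
        if bold_store is not None:
            out.barcodes.append(annotate_bold(bold_store, tpl_store, name, out.audit))
    return out


def write_redlist(annotations: Iterable[RedListAnnotation], fh: TextIO) -> None:
    w = csv.writer(fh)
    w.writerow(["name", "category", "source"])
    for a in annotations:
        w.writerow([a.name, a.category, a.source])


def write_gisin(annotations: Iterable[InvasivenessAnnotation], fh: TextIO) -> None:
    w = csv.writer(fh)
    w.writerow(["name", "class", "type"])
    for a in annotations:
        w.writerow([a.name, a.gisin_class, a.gisin_provenance])


def write_daisie(annotations: Iterable[InvasivenessAnnotation], fh: TextIO) -> None:
    w = csv.writer(fh)
    w.writerow(["name", "alien", "worst"])
    for a in annotations:
        w.writerow([a.name, str(a.daisie_alien).lower(), str(a.daisie_worst).lower()])


def write_bold(annotations: Iterable[BarcodeAnnotation], fh: TextIO) -> None:
    w = csv.writer(fh)
    w.writerow(["name", "found", "public_records", "type"])
    for a in annotations:
        w.writerow([a.name, str(a.taxon_found).lower(), a.public_records, a.provenance])
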