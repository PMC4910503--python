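"""Parsing and normalisation of taxon names from seed-catalogue text.

A seed catalogue (*index seminum*) is a plain-text list of taxon names, one
candidate name per line.  The parser accepts the name categories commonly
offered by botanic gardens — species, subspecies, varieties, forms,
cultivars and hybrids of the form ``Genus x species`` — and skips (with a
logged line number) anything that does not fit that restricted grammar.
Parsed names are normalised to canonical form (no authority, single spacing,
one fixed hybrid sign) and deduplicated into the unique name list (UNL) that
all downstream verification and annotation consumes.
"""

from __future__ import annotations

import logging
import re
from collections import OrderedDict
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, TextIO

logger = logging.getLogger(__name__)

HYBRID_SIGN = "×"  # canonical rendering of the hybrid marker


class Rank(str, Enum):
    """Rank marker of a parsed name (``none`` means plain binomial)."""

    NONE = "none"
    SUBSP = "subsp"
    VAR = "var"
    F = "f"
    CV = "cv"
    HYBRID = "hybrid"


#: accepted spellings of infraspecific rank markers -> canonical marker
_RANK_TOKENS = {
    "subsp.": Rank.SUBSP,
    "subsp": Rank.SUBSP,
    "ssp.": Rank.SUBSP,
    "ssp": Rank.SUBSP,
    "var.": Rank.VAR,
    "var": Rank.VAR,
    "f.": Rank.F,
    "forma": Rank.F,
}

_RANK_ABBREV = {Rank.SUBSP: "subsp.", Rank.VAR: "var.", Rank.F: "f."}

# tokens are lowercase or ALL-CAPS; mixed case ("Link") marks an authority
_GENUS_RE = r"[A-Z](?:[a-zà-ÿ-]+|[A-ZÀ-Þ-]+)"
_EPITHET_RE = r"(?:[a-zà-ÿ][a-zà-ÿ-]*|[A-ZÀ-Þ][A-ZÀ-Þ-]+)"

_LINE_RE = re.compile(
    rf"""^\s*
    (?P<genus>{_GENUS_RE})
    (?:\s+(?P<hybrid>[x×])(?=\s))?
    \s+(?P<epithet>{_EPITHET_RE})
    (?:\s+(?P<rank>subsp\.?|ssp\.?|var\.?|f\.|forma)\s+(?P<infra>{_EPITHET_RE}))?
    (?:\s+'(?P<cultivar>[^']+)')?
    (?:\s+(?P<authority>\S.*?))?
    \s*$""",
    re.VERBOSE,
)


@dataclass(frozen=True)
class ParsedName:
    """One taxon name as extracted from a catalogue line."""

    genus: str
    species_epithet: str
    rank_marker: Rank = Rank.NONE
    infraspecific_epithet: str = ""
    cultivar_name: str = ""
    authority: str = ""
    source_catalogue: str = ""
    raw_line: str = ""

    def __post_init__(self) -> None:
        if not self.genus or not self.genus[0].isupper():
            raise ValueError(f"genus must be capitalized, got {self.genus!r}")
        if not self.species_epithet and self.rank_marker is not Rank.HYBRID:
            raise ValueError("species epithet required for non-hybrid names")
        if (self.rank_marker is Rank.CV) != bool(self.cultivar_name):
            raise ValueError("cultivar name present iff rank marker is cv")
        infra_ranks = {Rank.SUBSP, Rank.VAR, Rank.F}
        if (self.rank_marker in infra_ranks) != bool(self.infraspecific_epithet):
            raise ValueError("infraspecific epithet present iff rank is subsp/var/f")


@dataclass(frozen=True)
class CanonicalName:
    """Normalised scientific name without authority; the UNL key."""

    text: str
    rank_marker: Rank = Rank.NONE
    hybrid_flag: bool = False

    @property
    def genus(self) -> str:
        return self.text.split()[0]

    @property
    def species_epithet(self) -> str:
        parts = [p for p in self.text.split() if p != HYBRID_SIGN]
        return parts[1] if len(parts) > 1 else ""

    @property
    def infraspecific_epithet(self) -> str:
        parts = self.text.split()
        return parts[-1] if self.rank_marker in (Rank.SUBSP, Rank.VAR, Rank.F) else ""

    @property
    def key(self) -> tuple[str, str]:
        """Uniqueness key: case-folded text plus rank marker."""
        return (self.text.casefold(), self.rank_marker.value)


@dataclass
class UniqueName:
    """A UNL entry: one canonical name with its provenance across catalogues."""

    canonical: CanonicalName
    occurrences: int = 0
    catalogues: set[str] = field(default_factory=set)
    authorities: set[str] = field(default_factory=set)


def parse_line(line: str, catalogue_id: str = "") -> ParsedName | None:
    """Parse one catalogue line; return ``None`` when the grammar does not match."""
    if not line.strip():
        return None
    m = _LINE_RE.match(line)
    if m is None:
        return None
    rank = Rank.NONE
    infra = ""
    cultivar = m.group("cultivar") or ""
    authority = (m.group("authority") or "").strip()
    if m.group("hybrid"):
        rank = Rank.HYBRID
    elif m.group("rank"):
        tok = m.group("rank")
        if tok not in _RANK_TOKENS:
            return None
        rank = _RANK_TOKENS[tok]
        infra = m.group("infra") or ""
    if cultivar:
        if rank not in (Rank.NONE, Rank.HYBRID):
            # 'Genus species var. x Cultivar' is outside the grammar
            return None
        rank = Rank.CV
    try:
        return ParsedName(
            genus=m.group("genus"),
            species_epithet=m.group("epithet").casefold(),
            rank_marker=rank,
            infraspecific_epithet=infra.casefold(),
            cultivar_name=cultivar,
            authority=authority,
            source_catalogue=catalogue_id,
            raw_line=line.rstrip("\n"),
        )
    except ValueError:
        return None


def parse_catalogue(raw_text: str | bytes, catalogue_id: str = "") -> list[ParsedName]:
    """Extract all parseable taxon names from catalogue text, in order.

    Lines that do not match the restricted name grammar are skipped and logged
    with their line number; blank lines are skipped silently.  Byte input that
    is not valid UTF-8 raises :class:`UnicodeDecodeError` naming the offset.
    """
    if isinstance(raw_text, bytes):
        raw_text = raw_text.decode("utf-8")  # raises with byte offset on failure
    out: list[ParsedName] = []
    for lineno, line in enumerate(raw_text.splitlines(), start=1):
        if not line.strip():
            continue
        parsed = parse_line(line, catalogue_id)
        if parsed is None:
            logger.info("%s:%d: skipped unparseable line: %r", catalogue_id, lineno, line)
        else:
            out.append(parsed)
    return out


def normalize(p: ParsedName) -> CanonicalName:
    """Render a parsed name as its canonical text (authority and quotes dropped).

    Deterministic: case is folded then the genus re-capitalised, runs of
    whitespace collapse to single spaces, and both ``x`` and the multiplication
    sign render as one fixed hybrid symbol.
    """
    genus = p.genus.casefold().capitalize()
    parts = [genus]
    if p.rank_marker is Rank.HYBRID:
        parts.append(HYBRID_SIGN)
    parts.append(p.species_epithet.casefold())
    if p.rank_marker in _RANK_ABBREV:
        parts += [_RANK_ABBREV[p.rank_marker], p.infraspecific_epithet.casefold()]
    return CanonicalName(
        text=" ".join(parts),
        rank_marker=p.rank_marker,
        hybrid_flag=p.rank_marker is Rank.HYBRID,
    )


def exclude_cultivars(names: Iterable[ParsedName]) -> list[ParsedName]:
    """Drop cultivar entries; order of the remaining names is preserved."""
    return [p for p in names if p.rank_marker is not Rank.CV]


def compile_unique_names(names: Iterable[ParsedName]) -> list[UniqueName]:
    """Deduplicate parsed names into the unique name list (UNL).

    The key is the canonical text plus rank marker; authority variants of one
    canonical name collapse to a single entry that records every authority and
    source catalogue seen, plus the total occurrence count.
    """
    unl: OrderedDict[tuple[str, str], UniqueName] = OrderedDict()
    for p in names:
        canon = normalize(p)
        entry = unl.setdefault(canon.key, UniqueName(canonical=canon))
        entry.occurrences += 1
        if p.source_catalogue:
            entry.catalogues.add(p.source_catalogue)
        if p.authority:
            entry.authorities.add(p.authority)
    return list(unl.values())


def canonical_from_text(text: str) -> CanonicalName:
    """Rebuild a :class:`CanonicalName` from its rendered text."""
    tokens = text.split()
    if HYBRID_SIGN in tokens or "x" in tokens[1:2]:
        return CanonicalName(text=text, rank_marker=Rank.HYBRID, hybrid_flag=True)
    for marker, rank in (("subsp.", Rank.SUBSP), ("var.", Rank.VAR), ("f.", Rank.F)):
        if marker in tokens:
            return CanonicalName(text=text, rank_marker=rank)
    return CanonicalName(text=text)


UNL_HEADER = "canonical_name,rank,hybrid,occurrences,catalogues,authorities"


def write_unl(unl: Iterable[UniqueName], fh: TextIO) -> None:
    """Write the UNL as CSV (multi-valued fields are ``;``-joined, sorted)."""
    import csv

    w = csv.writer(fh)
    w.writerow(UNL_HEADER.split(","))
    for u in unl:
        w.writerow(
            [
                u.canonical.text,
                u.canonical.rank_marker.value,
                str(u.canonical.hybrid_flag).lower(),
                u.occurrences,
                ";".join(sorted(u.catalogues)),
                ";".join(sorted(u.authorities)),
            ]
        )


def read_unl(fh: TextIO) -> list[UniqueName]:
    import csv

    rd = csv.DictReader(fh)
    out = []
    for row in rd:
        canon = CanonicalName(
            text=row["canonical_name"],
            rank_marker=Rank(row["rank"]),
            hybrid_flag=row["hybrid"] == "true",
        )
        out.append(
            UniqueName(
                canonical=canon,
                occurrences=int(row["occurrences"]),
                catalogues=set(filter(None, row["catalogues"].split(";"))),
                authorities=set(filter(None, row["authorities"].split(";"))),
            )
        )
    return out
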