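"""Reproducible synthetic worlds for the verification/annotation pipeline.

A *world* is a master taxonomy of accepted pseudo-Latin names with synonyms
and planted homonyms, from which the generator derives: per-provider
checklist snapshots (TPL-, COL- and EOL-dialect) with controlled coverage
and status flips, annotation stores (red list, GISIN occurrences, DAISIE
alien list, BOLD record counts) where a controlled fraction of taxa is
reachable only via alternative names, and seed catalogues whose names carry
injected typos at controlled edit distance.  Alongside the data the
generator emits a ground-truth table with the expected verification and
annotation outcome of every generated catalogue name, so pipeline runs can
be scored exactly.

Names are built from syllable templates.  Within a genus all epithets are
kept at least 7 edits apart, so a corruption of at most 2 edits has exactly
one sibling within the Levenshtein bound (unique recovery) while a
corruption of 3+ edits has none.  Corruptions touch only the epithet, which
keeps genus routing — and therefore sibling enumeration — meaningful.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .annotation import BoldStore, DaisieStore, GisinStore, RedListStore
from .checklist import DIALECTS, ChecklistRecord, ChecklistStore, store_from_records

logger = logging.getLogger(__name__)

_MIN_EPITHET_SEPARATION = 7

_SYLLABLES = [
    "ba", "ce", "di", "fo", "gu", "la", "me", "ni", "po", "ru",
    "sa", "te", "vi", "xo", "ze", "ca", "do", "fe", "gi", "lu",
    "ma", "ne", "pi", "ro", "su", "ta", "ve", "mi", "no", "pa",
]
_EPITHET_ENDINGS = ["us", "a", "um", "is", "ii", "ensis", "oides", "atum", "osa"]
_GENUS_ENDINGS = ["ia", "us", "um", "ella", "opsis", "anthus"]

#: empirical red-list category mix (LC-heavy, a thin extinct tail)
_REDLIST_CATEGORIES = ["EX", "EW", "CR", "EN", "VU", "NT", "LR/nt", "LR/cd", "LC", "LR/lc", "DD"]
_REDLIST_WEIGHTS = [0.001, 0.003, 0.04, 0.08, 0.10, 0.07, 0.02, 0.005, 0.50, 0.031, 0.07]


def _dp_levenshtein(a: str, b: str) -> int:
    """Plain dynamic-programming edit distance; the generator's own oracle."""
    a, b = a.casefold(), b.casefold()
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


@dataclass
class WorldConfig:
    """Knobs of the synthetic world; defaults mirror the proportions observed
    in large botanic seed-exchange name sets."""

    n_accepted: int = 500
    mean_synonyms_per_taxon: float = 1.5
    homonym_rate: float = 0.05
    provider_coverage: dict[str, float] = field(
        default_factory=lambda: {"TPL": 0.92, "COL": 0.88, "EOL": 0.91}
    )
    status_disagreement_rate: float = 0.13
    typo_rate: float = 0.05
    typo_distance_range: tuple[int, int] = (1, 2)
    unrecoverable_rate: float = 0.01
    redlist_fraction: float = 0.076
    redlist_synonym_only_fraction: float = 0.176
    redlist_internal_synonym_fraction: float = 0.10
    invasive_fraction: float = 0.013
    exotic_only_fraction: float = 0.027
    neither_fraction: float = 0.003
    gisin_alt_only_fraction: float = 0.122
    alien_fraction: float = 0.196
    daisie_worst_fraction: float = 0.004
    bold_taxon_fraction: float = 0.576
    bold_alt_only_fraction: float = 0.102
    barcode_lambda: float = 2.0
    n_catalogues: int = 8
    catalogue_size: int = 120
    synonym_usage_rate: float = 0.25
    authority_line_rate: float = 0.5
    eol_embedded_authority_rate: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        probs = {
            "homonym_rate": self.homonym_rate,
            "status_disagreement_rate": self.status_disagreement_rate,
            "typo_rate": self.typo_rate,
            "unrecoverable_rate": self.unrecoverable_rate,
            "redlist_fraction": self.redlist_fraction,
            "redlist_synonym_only_fraction": self.redlist_synonym_only_fraction,
            "redlist_internal_synonym_fraction": self.redlist_internal_synonym_fraction,
            "invasive_fraction": self.invasive_fraction,
            "exotic_only_fraction": self.exotic_only_fraction,
            "neither_fraction": self.neither_fraction,
            "gisin_alt_only_fraction": self.gisin_alt_only_fraction,
            "alien_fraction": self.alien_fraction,
            "daisie_worst_fraction": self.daisie_worst_fraction,
            "bold_taxon_fraction": self.bold_taxon_fraction,
            "bold_alt_only_fraction": self.bold_alt_only_fraction,
            "synonym_usage_rate": self.synonym_usage_rate,
            "authority_line_rate": self.authority_line_rate,
            "eol_embedded_authority_rate": self.eol_embedded_authority_rate,
            **{f"provider_coverage[{k}]": v for k, v in self.provider_coverage.items()},
        }
        for key, value in probs.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{key} must lie in [0, 1], got {value}")
        if self.n_accepted < 1:
            raise ValueError("n_accepted must be at least 1")
        if self.homonym_rate > 0 and self.n_accepted < 2:
            raise ValueError("homonyms need at least two accepted taxa")
        lo, hi = self.typo_distance_range
        if not (1 <= lo <= hi <= 2):
            raise ValueError("typo_distance_range must lie within [1, 2]")
        if self.mean_synonyms_per_taxon < 0 or self.barcode_lambda < 0:
            raise ValueError("rates must be non-negative")
        if self.typo_rate + self.unrecoverable_rate > 1:
            raise ValueError("typo_rate + unrecoverable_rate must not exceed 1")

    # flat key=value persistence ----------------------------------------

    def to_file(self, path: str | Path) -> None:
        lines = []
        for key, value in vars(self).items():
            if key == "provider_coverage":
                for prov, cov in value.items():
                    lines.append(f"provider_coverage.{prov}={cov}")
            elif key == "typo_distance_range":
                lines.append(f"typo_distance_range={value[0]},{value[1]}")
            else:
                lines.append(f"{key}={value}")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def from_file(cls, path: str | Path) -> "WorldConfig":
        cfg = cls()
        coverage: dict[str, float] = {}
        for raw in Path(path).read_text(encoding="utf-8").splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            value = value.strip()
            if key.startswith("provider_coverage."):
                coverage[key.split(".", 1)[1]] = float(value)
            elif key == "typo_distance_range":
                lo, hi = value.split(",")
                setattr(cfg, key, (int(lo), int(hi)))
            elif key in ("n_accepted", "n_catalogues", "catalogue_size", "seed"):
                setattr(cfg, key, int(value))
            elif hasattr(cfg, key):
                setattr(cfg, key, float(value))
            else:
                raise ValueError(f"unknown config key {key!r}")
        if coverage:
            cfg.provider_coverage = coverage
        cfg.validate()
        return cfg


@dataclass
class SyntheticWorld:
    """Everything one pipeline run needs, plus the ground truth to score it."""

    config: WorldConfig
    stores: dict[str, ChecklistStore]
    redlist: RedListStore
    gisin: GisinStore
    daisie: DaisieStore
    bold: BoldStore
    catalogues: dict[str, str]
    truth: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.config.to_file(out / "world.cfg")
        for provider, store in self.stores.items():
            with open(out / f"checklist_{provider.lower()}.csv", "w", encoding="utf-8", newline="") as fh:
                store.dump(fh)
        for name, store in (
            ("redlist", self.redlist),
            ("gisin", self.gisin),
            ("daisie", self.daisie),
            ("bold", self.bold),
        ):
            with open(out / f"{name}.csv", "w", encoding="utf-8", newline="") as fh:
                store.dump(fh)
        cat_dir = out / "catalogues"
        cat_dir.mkdir(exist_ok=True)
        for cat_id, text in self.catalogues.items():
            (cat_dir / f"{cat_id}.txt").write_text(text, encoding="utf-8")
        self.truth.to_csv(out / "ground_truth.csv", index=False)


# ---------------------------------------------------------------------------
# name material


class _NameFactory:
    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self._taken_genera: set[str] = set()

    def _word(self, n_syllables: int) -> str:
        parts = self.rng.choice(_SYLLABLES, size=n_syllables)
        return "".join(parts)

    def genus(self) -> str:
        for _ in range(1000):
            stem = self._word(int(self.rng.integers(2, 4)))
            name = (stem + str(self.rng.choice(_GENUS_ENDINGS))).capitalize()
            if all(_dp_levenshtein(name, g) >= 3 for g in self._taken_genera):
                self._taken_genera.add(name)
                return name
        raise RuntimeError("could not place a new genus name")

    def epithet(self, taken: Iterable[str]) -> str:
        taken = list(taken)
        for _ in range(1000):
            cand = self._word(int(self.rng.integers(2, 5))) + str(
                self.rng.choice(_EPITHET_ENDINGS)
            )
            if all(_dp_levenshtein(cand, t) >= _MIN_EPITHET_SEPARATION for t in taken):
                return cand
        raise RuntimeError("could not place a new epithet")

    def authority(self) -> str:
        return self._word(int(self.rng.integers(1, 3))).capitalize() + "."


def _corrupt_epithet(
    rng: np.random.Generator, epithet: str, n_edits: int
) -> str:
    letters = "abcdefghijklmnopqrstuvwxyz"
    chars = list(epithet)
    for _ in range(n_edits):
        op = rng.choice(["sub", "ins", "del"]) if len(chars) > 3 else rng.choice(["sub", "ins"])
        pos = int(rng.integers(0, len(chars)))
        if op == "sub":
            chars[pos] = str(rng.choice(list(letters.replace(chars[pos], ""))))
        elif op == "ins":
            chars.insert(pos, str(rng.choice(list(letters))))
        else:
            chars.pop(pos)
    return "".join(chars)


# ---------------------------------------------------------------------------
# generation


@dataclass
class _Taxon:
    taxon_id: str
    accepted: str  # canonical accepted name
    synonyms: list[str] = field(default_factory=list)
    has_homonym: bool = False


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Generate a deterministic synthetic world from the configuration."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    factory = _NameFactory(rng)

    # --- master taxonomy -------------------------------------------------
    n_genera = max(3, config.n_accepted // 6)
    genera = [factory.genus() for _ in range(n_genera)]
    epithets_by_genus: dict[str, list[str]] = {g: [] for g in genera}

    def new_name(genus: str) -> str:
        epithet = factory.epithet(epithets_by_genus[genus])
        epithets_by_genus[genus].append(epithet)
        return f"{genus} {epithet}"

    taxa: list[_Taxon] = []
    master: list[ChecklistRecord] = []
    name_to_taxon: dict[str, _Taxon] = {}
    name_kind: dict[str, str] = {}  # canonical (casefolded) -> accepted|synonym
    record_authority: dict[str, str] = {}

    for i in range(config.n_accepted):
        genus = genera[int(rng.integers(0, n_genera))]
        accepted = new_name(genus)
        taxon = _Taxon(taxon_id=f"T{i}", accepted=accepted)
        taxa.append(taxon)
        auth = factory.authority()
        master.append(
            ChecklistRecord(
                provider="TPL",
                record_id=taxon.taxon_id,
                name=accepted,
                authority=auth,
                raw_status="Accepted",
                genus=genus,
                species_epithet=accepted.split()[1],
                confidence=str(rng.choice(["high", "moderate", "low"])),
            )
        )
        record_authority[taxon.taxon_id] = auth
        name_to_taxon[accepted.casefold()] = taxon
        name_kind[accepted.casefold()] = "accepted"

    syn_counts = rng.poisson(config.mean_synonyms_per_taxon, size=config.n_accepted)
    syn_serial = 0
    for taxon, n_syn in zip(taxa, syn_counts):
        for _ in range(int(n_syn)):
            genus = (
                taxon.accepted.split()[0]
                if rng.random() < 0.5
                else genera[int(rng.integers(0, n_genera))]
            )
            syn_name = new_name(genus)
            rec_id = f"S{syn_serial}"
            syn_serial += 1
            master.append(
                ChecklistRecord(
                    provider="TPL",
                    record_id=rec_id,
                    name=syn_name,
                    authority=factory.authority(),
                    raw_status="Synonym",
                    accepted_record_id=taxon.taxon_id,
                    genus=genus,
                    species_epithet=syn_name.split()[1],
                    confidence=str(rng.choice(["high", "moderate", "low"])),
                )
            )
            taxon.synonyms.append(syn_name)
            name_to_taxon[syn_name.casefold()] = taxon
            name_kind[syn_name.casefold()] = "synonym"

    # planted homonyms: a second TPL record with the same spelling but
    # different authorship; exact search then returns two records
    for idx, taxon in enumerate(taxa):
        if rng.random() < config.homonym_rate:
            taxon.has_homonym = True
            master.append(
                ChecklistRecord(
                    provider="TPL",
                    record_id=f"H{idx}",
                    name=taxon.accepted,
                    authority=factory.authority(),
                    raw_status="Unresolved",
                    genus=taxon.accepted.split()[0],
                    species_epithet=taxon.accepted.split()[1],
                    confidence="low",
                )
            )

    # --- provider snapshots ---------------------------------------------
    tpl_records = [r for r in master if rng.random() < config.provider_coverage.get("TPL", 1.0)]

    col_selected = [
        r
        for r in master
        if r.record_id[0] != "H" and rng.random() < config.provider_coverage.get("COL", 1.0)
    ]
    col_flipped: set[str] = set()
    col_records: list[ChecklistRecord] = []
    col_accepted_ids = [
        r.record_id
        for r in col_selected
        if r.raw_status == "Accepted"
    ]
    for r in col_selected:
        flip = rng.random() < config.status_disagreement_rate
        if r.raw_status == "Accepted":
            if flip and col_accepted_ids:
                target = col_accepted_ids[int(rng.integers(0, len(col_accepted_ids)))]
                if target == r.record_id:
                    flip = False
            if flip and col_accepted_ids:
                col_flipped.add(r.name.casefold())
                col_records.append(
                    replace(
                        r,
                        provider="COL",
                        record_id=f"COL-{r.record_id}",
                        raw_status="Synonym",
                        accepted_record_id=f"COL-{target}",
                        confidence="",
                    )
                )
            else:
                status = "Accepted name" if rng.random() < 0.9 else "Provisionally accepted name"
                col_records.append(
                    replace(
                        r,
                        provider="COL",
                        record_id=f"COL-{r.record_id}",
                        raw_status=status,
                        accepted_record_id="",
                        confidence="",
                    )
                )
        elif r.raw_status == "Synonym":
            if flip:
                col_flipped.add(r.name.casefold())
                col_records.append(
                    replace(
                        r,
                        provider="COL",
                        record_id=f"COL-{r.record_id}",
                        raw_status="Accepted name",
                        accepted_record_id="",
                        confidence="",
                    )
                )
            else:
                col_records.append(
                    replace(
                        r,
                        provider="COL",
                        record_id=f"COL-{r.record_id}",
                        raw_status="Synonym",
                        accepted_record_id=f"COL-{r.accepted_record_id}",
                        confidence="",
                    )
                )
        # Unresolved master records (homonym twins) never enter COL

    eol_records: list[ChecklistRecord] = []
    eol_canonical: dict[str, int] = {}  # canonical -> n records
    for r in master:
        if rng.random() >= config.provider_coverage.get("EOL", 1.0):
            continue
        name_field = r.name
        if rng.random() < config.eol_embedded_authority_rate:
            name_field = f"{r.name} {r.authority}"
        eol_records.append(
            ChecklistRecord(
                provider="EOL",
                record_id=f"EOL-{r.record_id}",
                name=name_field,
                authority="",
                raw_status="",
                genus=r.genus,
                species_epithet=r.species_epithet,
            )
        )
        key = r.name.casefold()
        eol_canonical[key] = eol_canonical.get(key, 0) + 1

    stores = {
        "TPL": store_from_records(tpl_records, DIALECTS["TPL"]),
        "COL": store_from_records(col_records, DIALECTS["COL"]),
        "EOL": store_from_records(eol_records, DIALECTS["EOL"]),
    }

    # generator-side name indexes, independent of the store implementation
    provider_names: dict[str, dict[str, list[ChecklistRecord]]] = {"TPL": {}, "COL": {}}
    for prov, recs in (("TPL", tpl_records), ("COL", col_records)):
        for r in recs:
            provider_names[prov].setdefault(r.name.casefold(), []).append(r)
    provider_genus_names: dict[str, dict[str, set[str]]] = {}
    for prov, recs in (("TPL", tpl_records), ("COL", col_records), ("EOL", eol_records)):
        by_genus: dict[str, set[str]] = {}
        for r in recs:
            # relaxed matching runs on the emitted name field, which for the
            # EOL dialect may embed the authority
            by_genus.setdefault(r.genus.casefold(), set()).add(r.name)
        provider_genus_names[prov] = by_genus

    tpl_by_id = {r.record_id: r for r in tpl_records}

    # --- annotation stores ----------------------------------------------
    redlist = RedListStore()
    rl_key: dict[str, str] = {}  # taxon_id -> primary red-list name
    rl_category: dict[str, str] = {}
    rl_internal_syn: dict[str, str] = {}  # rl synonym name -> taxon_id
    rl_alt_keyed: set[str] = set()
    cat_probs = np.array(_REDLIST_WEIGHTS) / sum(_REDLIST_WEIGHTS)
    for taxon in taxa:
        if rng.random() >= config.redlist_fraction:
            continue
        category = str(rng.choice(_REDLIST_CATEGORIES, p=cat_probs))
        key_name = taxon.accepted
        if taxon.synonyms and rng.random() < config.redlist_synonym_only_fraction:
            key_name = taxon.synonyms[int(rng.integers(0, len(taxon.synonyms)))]
            rl_alt_keyed.add(taxon.taxon_id)
        redlist.add_primary(key_name, category)
        rl_key[taxon.taxon_id] = key_name
        rl_category[taxon.taxon_id] = category
        if (
            key_name == taxon.accepted
            and len(taxon.synonyms) > 1
            and rng.random() < config.redlist_internal_synonym_fraction
        ):
            syn = taxon.synonyms[-1]
            redlist.add_synonym(syn, key_name)
            rl_internal_syn[syn.casefold()] = taxon.taxon_id

    gisin = GisinStore()
    gisin_key: dict[str, str] = {}
    gisin_class_of: dict[str, str] = {}
    for taxon in taxa:
        u = rng.random()
        if u < config.invasive_fraction:
            klass = "Invasive"
        elif u < config.invasive_fraction + config.exotic_only_fraction:
            klass = "Exotic"
        elif u < config.invasive_fraction + config.exotic_only_fraction + config.neither_fraction:
            klass = "Neither"
        else:
            continue
        key_name = taxon.accepted
        if taxon.synonyms and rng.random() < config.gisin_alt_only_fraction:
            key_name = taxon.synonyms[int(rng.integers(0, len(taxon.synonyms)))]
        if klass == "Invasive":
            gisin.add(key_name, exotic=True, harmful=True)
            gisin.add(key_name, exotic=True, harmful=False)
        elif klass == "Exotic":
            gisin.add(key_name, exotic=True, harmful=False)
        else:
            gisin.add(key_name, exotic=False, harmful=False)
        gisin_key[taxon.taxon_id] = key_name
        gisin_class_of[taxon.taxon_id] = klass

    daisie = DaisieStore()
    daisie_alien: set[str] = set()
    daisie_worst: set[str] = set()
    for taxon in taxa:
        if rng.random() < config.alien_fraction:
            worst = rng.random() < config.daisie_worst_fraction / max(config.alien_fraction, 1e-9)
            daisie.add(taxon.accepted, worst=worst)
            daisie_alien.add(taxon.taxon_id)
            if worst:
                daisie_worst.add(taxon.taxon_id)

    bold = BoldStore()
    bold_key: dict[str, str] = {}
    bold_counts: dict[str, int] = {}
    for taxon in taxa:
        if rng.random() >= config.bold_taxon_fraction:
            continue
        key_name = taxon.accepted
        if taxon.synonyms and rng.random() < config.bold_alt_only_fraction:
            key_name = taxon.synonyms[int(rng.integers(0, len(taxon.synonyms)))]
        count = int(rng.poisson(config.barcode_lambda))
        bold.add(key_name, count)
        bold_key[taxon.taxon_id] = key_name
        bold_counts[taxon.taxon_id] = count

    # --- expected-outcome helpers ---------------------------------------

    def tpl_alternatives(query: str) -> tuple[str, list[str]]:
        """Accepted name and synonyms of `query` as the emitted TPL snapshot
        resolves them (accepted first, synonyms sorted)."""
        recs = provider_names["TPL"].get(query.casefold())
        if not recs:
            return "", []
        rec = recs[0]
        if rec.accepted_record_id:
            anchor = rec.accepted_record_id
            acc_rec = tpl_by_id.get(anchor)
            accepted = acc_rec.name if acc_rec else ""
        else:
            anchor = rec.record_id
            accepted = ""
        synonyms = sorted(
            {
                r.name
                for r in tpl_records
                if r.accepted_record_id == anchor and r.name.casefold() != query.casefold()
            }
        )
        if accepted and accepted.casefold() == query.casefold():
            accepted = ""
        return accepted, synonyms

    def query_order(query: str) -> list[tuple[str, str]]:
        accepted, synonyms = tpl_alternatives(query)
        out = [(accepted, "accepted")] if accepted else []
        out.extend((s, "synonym") for s in synonyms)
        return out

    _COL_STATUS = {
        "Accepted name": "Accepted",
        "Provisionally accepted name": "Accepted",
        "Synonym": "Synonym",
    }

    def expected_verification(prov: str, canonical: str, genus: str, distance: int):
        """(match_type, status, alternative) expected from a provider."""
        key = canonical.casefold()
        if prov == "EOL":
            n = eol_canonical.get(key, 0)
            if n:
                return "exact", "NA", ""
        else:
            recs = provider_names[prov].get(key, [])
            if recs:
                if len(recs) > 1:
                    return "exact", "Ambiguous", ""
                status = _COL_STATUS[recs[0].raw_status] if prov == "COL" else recs[0].raw_status
                return "exact", status, ""
        # relaxed step over the genus pool
        pool = provider_genus_names[prov].get(genus.casefold(), set())
        cands = sorted(n for n in pool if 0 < _dp_levenshtein(canonical, n) <= 2)
        if not cands:
            return "none", "NA", ""
        if len(cands) > 1:
            return "relaxed", "NA" if prov == "EOL" else "Ambiguous", ""
        alt = cands[0]
        if prov == "EOL":
            return "relaxed", "NA", alt
        recs = provider_names[prov][alt.casefold()]
        statuses = {
            _COL_STATUS[r.raw_status] if prov == "COL" else r.raw_status for r in recs
        }
        status = statuses.pop() if len(statuses) == 1 else "Ambiguous"
        if len(recs) > 1 and len({r.raw_status for r in recs}) > 1:
            status = "Ambiguous"
        return "relaxed", status, alt

    def expected_redlist(query: str, taxon: _Taxon | None):
        if taxon is None:
            return "none", "none"
        key = query.casefold()
        primary = rl_key.get(taxon.taxon_id)
        if primary is not None and key == primary.casefold():
            return rl_category[taxon.taxon_id], "RL"
        if key in rl_internal_syn:
            return rl_category[rl_internal_syn[key]], "RLsynonym"
        for alt, kind in query_order(query):
            alt_taxon = name_to_taxon.get(alt.casefold())
            if alt_taxon is None:
                continue
            alt_primary = rl_key.get(alt_taxon.taxon_id)
            hit = (alt_primary is not None and alt.casefold() == alt_primary.casefold()) or (
                alt.casefold() in rl_internal_syn
            )
            if hit:
                cat = (
                    rl_category[alt_taxon.taxon_id]
                    if alt_primary is not None and alt.casefold() == alt_primary.casefold()
                    else rl_category[rl_internal_syn[alt.casefold()]]
                )
                return cat, "TPLaccepted" if kind == "accepted" else "TPLsynonym"
        return "none", "none"

    def expected_gisin(query: str, taxon: _Taxon | None):
        if taxon is None:
            return "none", "none"
        key = query.casefold()
        keyed = gisin_key.get(taxon.taxon_id)
        if keyed is not None and key == keyed.casefold():
            return gisin_class_of[taxon.taxon_id], "original"
        for alt, _kind in query_order(query):
            alt_taxon = name_to_taxon.get(alt.casefold())
            if alt_taxon is None:
                continue
            alt_keyed = gisin_key.get(alt_taxon.taxon_id)
            if alt_keyed is not None and alt.casefold() == alt_keyed.casefold():
                recs = provider_names["TPL"].get(alt.casefold())
                provenance = recs[0].raw_status if recs else "Synonym"
                return gisin_class_of[alt_taxon.taxon_id], provenance
        return "none", "none"

    def expected_bold(query: str, taxon: _Taxon | None):
        if taxon is None:
            return False, 0, "none"
        key = query.casefold()
        keyed = bold_key.get(taxon.taxon_id)
        if keyed is not None and key == keyed.casefold():
            return True, bold_counts[taxon.taxon_id], "original"
        for alt, kind in query_order(query):
            alt_taxon = name_to_taxon.get(alt.casefold())
            if alt_taxon is None:
                continue
            alt_keyed = bold_key.get(alt_taxon.taxon_id)
            if alt_keyed is not None and alt.casefold() == alt_keyed.casefold():
                return (
                    True,
                    bold_counts[alt_taxon.taxon_id],
                    "TPLaccepted" if kind == "accepted" else "TPLsynonym",
                )
        return False, 0, "none"

    # --- catalogues and ground truth -------------------------------------
    accepted_pool = sorted({t.accepted for t in taxa})
    synonym_pool = sorted({s for t in taxa for s in t.synonyms})
    auth_of: dict[str, str] = {}
    for r in master:
        auth_of.setdefault(r.name.casefold(), r.authority)

    catalogues: dict[str, str] = {}
    rows: list[dict] = []
    lo, hi = config.typo_distance_range
    for c in range(config.n_catalogues):
        cat_id = f"IS{c:03d}"
        lines = [f"=== {cat_id} ===", "(seed exchange list)"]
        for _ in range(config.catalogue_size):
            # catalogues mostly carry current names; synonyms at a lower rate
            if synonym_pool and rng.random() < config.synonym_usage_rate:
                source = synonym_pool[int(rng.integers(0, len(synonym_pool)))]
            else:
                source = accepted_pool[int(rng.integers(0, len(accepted_pool)))]
            genus, epithet = source.split()
            u = rng.random()
            injected = 0
            canonical = source
            recoverable = True
            if u < config.typo_rate:
                target = int(rng.integers(lo, hi + 1))
                siblings = [f"{genus} {e}" for e in epithets_by_genus[genus]]
                for _try in range(200):
                    cand = _corrupt_epithet(rng, epithet, target)
                    canonical = f"{genus} {cand}"
                    d = _dp_levenshtein(canonical, source)
                    others_ok = all(
                        _dp_levenshtein(canonical, s) >= 3
                        for s in siblings
                        if s.casefold() != source.casefold()
                    )
                    if 0 < d <= 2 and others_ok:
                        injected = d
                        break
                else:  # pragma: no cover - separation makes this unreachable
                    canonical, injected = source, 0
            elif u < config.typo_rate + config.unrecoverable_rate:
                siblings = [f"{genus} {e}" for e in epithets_by_genus[genus]]
                for _try in range(200):
                    cand = _corrupt_epithet(rng, epithet, int(rng.integers(3, 5)))
                    canonical = f"{genus} {cand}"
                    if all(_dp_levenshtein(canonical, s) >= 3 for s in siblings):
                        injected = _dp_levenshtein(canonical, source)
                        recoverable = False
                        break
                else:  # pragma: no cover
                    canonical, injected = source, 0

            line = canonical
            if rng.random() < config.authority_line_rate:
                line = f"{canonical} {auth_of.get(source.casefold(), 'Anon.')}"
            lines.append(line)

            clean = injected == 0
            taxon = name_to_taxon.get(source.casefold())
            row: dict = {
                "catalogue": cat_id,
                "line": len(lines),
                "raw_line": line,
                "canonical": canonical,
                "genus": genus,
                "source_taxon": taxon.taxon_id if taxon else "",
                "source_name": source,
                "name_kind": name_kind.get(source.casefold(), ""),
                "injected_distance": injected,
                "recoverable": recoverable,
                "clean": clean,
            }
            for prov in ("TPL", "COL", "EOL"):
                mt, status, alt = expected_verification(prov, canonical, genus, injected)
                row[f"expected_match_{prov.lower()}"] = mt
                row[f"expected_status_{prov.lower()}"] = status
                row[f"expected_alt_{prov.lower()}"] = alt
            row["col_flipped"] = source.casefold() in col_flipped and clean
            row["eligible_disagreement"] = (
                clean
                and row["expected_match_tpl"] == "exact"
                and row["expected_match_col"] == "exact"
                and row["expected_status_tpl"] != "Ambiguous"
            )
            q_taxon = taxon if clean else None
            cat_exp, src_exp = expected_redlist(canonical, q_taxon)
            row["rl_expected_category"] = cat_exp
            row["rl_expected_source"] = src_exp
            row["rl_alt_keyed_eligible"] = (
                clean
                and taxon is not None
                and name_kind.get(source.casefold()) == "accepted"
                and taxon.taxon_id in rl_key
                and bool(taxon.synonyms)
                and cat_exp != "none"
            )
            row["rl_alt_keyed"] = taxon is not None and taxon.taxon_id in rl_alt_keyed
            g_class, g_type = expected_gisin(canonical, q_taxon)
            row["gisin_expected_class"] = g_class
            row["gisin_expected_type"] = g_type
            row["daisie_expected_alien"] = bool(
                clean and taxon and taxon.taxon_id in daisie_alien and name_kind.get(source.casefold()) == "accepted"
            )
            row["daisie_expected_worst"] = bool(
                clean and taxon and taxon.taxon_id in daisie_worst and name_kind.get(source.casefold()) == "accepted"
            )
            b_found, b_count, b_type = expected_bold(canonical, q_taxon)
            row["bold_expected_found"] = b_found
            row["bold_expected_records"] = b_count
            row["bold_expected_type"] = b_type
            rows.append(row)
        catalogues[cat_id] = "\n".join(lines) + "\n"

    truth = pd.DataFrame(rows)
    return SyntheticWorld(
        config=config,
        stores=stores,
        redlist=redlist,
        gisin=gisin,
        daisie=daisie,
        bold=bold,
        catalogues=catalogues,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# scoring


@dataclass
class TruthReport:
    """Pipeline outputs scored against the generated ground truth.

    Rates are fractions in [0, 1]; ``n_*`` fields are the denominators so
    confidence bounds can be computed by the caller.
    """

    n_names: int = 0
    match_accuracy: dict[str, float] = field(default_factory=dict)
    status_accuracy: dict[str, float] = field(default_factory=dict)
    exact_recovery_rate: float = float("nan")
    n_exact_expected: int = 0
    relaxed_recovery_rate: float = float("nan")
    n_relaxed_expected: int = 0
    na_rate_unrecoverable: float = float("nan")
    n_unrecoverable: int = 0
    false_ambiguity_count: int = 0
    false_ambiguity_rate: float = float("nan")
    observed_disagreement_rate: float = float("nan")
    n_disagreement_eligible: int = 0
    n_disagreement_observed: int = 0
    redlist_alt_keyed_rate: float = float("nan")
    n_redlist_alt_eligible: int = 0
    n_redlist_alt_observed: int = 0
    provenance_accuracy: dict[str, float] = field(default_factory=dict)


def truth_check(collection, annotations, truth: pd.DataFrame) -> TruthReport:
    """Score a pipeline run (verification collection + annotations) against
    the ground-truth table of the world it ran on."""
    from .verification import MatchType, Status  # local import avoids a cycle

    rows = truth.drop_duplicates(subset="canonical").set_index(
        truth.drop_duplicates(subset="canonical")["canonical"].str.casefold()
    )
    report = TruthReport(n_names=len(rows))

    results: dict[tuple[str, str], object] = {}
    for r in collection.results:
        results[(r.query_name.text.casefold(), r.provider)] = r

    for prov in ("TPL", "COL", "EOL"):
        pl = prov.lower()
        n = match_ok = status_ok = 0
        for key, row in rows.iterrows():
            res = results.get((key, prov))
            if res is None:
                continue
            n += 1
            if res.match_type.value == row[f"expected_match_{pl}"]:
                match_ok += 1
            if res.status.value == row[f"expected_status_{pl}"]:
                status_ok += 1
        if n:
            report.match_accuracy[prov] = match_ok / n
            report.status_accuracy[prov] = status_ok / n

    # exact verification of clean names present in the provider
    n_exact = ok_exact = 0
    n_relax = ok_relax = 0
    n_unrec = ok_unrec = 0
    false_amb = 0
    for key, row in rows.iterrows():
        for prov in ("TPL", "COL", "EOL"):
            pl = prov.lower()
            res = results.get((key, prov))
            if res is None:
                continue
            expected = row[f"expected_match_{pl}"]
            if row["clean"] and expected == "exact":
                n_exact += 1
                ok_exact += res.match_type is MatchType.EXACT
            if not row["clean"] and row["recoverable"] and expected == "relaxed":
                n_relax += 1
                ok_relax += (
                    res.match_type is MatchType.RELAXED
                    and res.alternative_name.casefold()
                    == str(row[f"expected_alt_{pl}"]).casefold()
                )
            if not row["recoverable"]:
                n_unrec += 1
                ok_unrec += res.match_type is MatchType.NONE
            if (
                res.status is Status.AMBIGUOUS
                and row[f"expected_status_{pl}"] != "Ambiguous"
            ):
                false_amb += 1
    report.n_exact_expected = n_exact
    report.exact_recovery_rate = ok_exact / n_exact if n_exact else float("nan")
    report.n_relaxed_expected = n_relax
    report.relaxed_recovery_rate = ok_relax / n_relax if n_relax else float("nan")
    report.n_unrecoverable = n_unrec
    report.na_rate_unrecoverable = ok_unrec / n_unrec if n_unrec else float("nan")
    report.false_ambiguity_count = false_amb
    total_results = sum(
        1 for key in rows.index for p in ("TPL", "COL", "EOL") if (key, p) in results
    )
    report.false_ambiguity_rate = false_amb / total_results if total_results else float("nan")

    # planted status-disagreement recovery
    n_elig = n_disc = 0
    for key, row in rows.iterrows():
        if not row["eligible_disagreement"]:
            continue
        rt = results.get((key, "TPL"))
        rc = results.get((key, "COL"))
        if rt is None or rc is None:
            continue
        if rt.status is Status.NA or rc.status is Status.NA:
            continue
        n_elig += 1
        n_disc += rt.status != rc.status
    report.n_disagreement_eligible = n_elig
    report.n_disagreement_observed = n_disc
    report.observed_disagreement_rate = n_disc / n_elig if n_elig else float("nan")

    # annotation provenance
    if annotations is not None:
        rl_by_name = {a.name.casefold(): a for a in annotations.redlist}
        inv_by_name = {a.name.casefold(): a for a in annotations.invasiveness}
        bold_by_name = {a.name.casefold(): a for a in annotations.barcodes}

        def _accuracy(domain: str, check) -> None:
            n = ok = 0
            for key, row in rows.iterrows():
                verdict = check(key, row)
                if verdict is None:
                    continue
                n += 1
                ok += verdict
            if n:
                report.provenance_accuracy[domain] = ok / n

        _accuracy(
            "redlist",
            lambda key, row: (
                None
                if key not in rl_by_name
                else rl_by_name[key].category == row["rl_expected_category"]
                and rl_by_name[key].source == row["rl_expected_source"]
            ),
        )
        _accuracy(
            "gisin",
            lambda key, row: (
                None
                if key not in inv_by_name
                else inv_by_name[key].gisin_class == row["gisin_expected_class"]
                and inv_by_name[key].gisin_provenance == row["gisin_expected_type"]
            ),
        )
        _accuracy(
            "daisie",
            lambda key, row: (
                None
                if key not in inv_by_name
                else inv_by_name[key].daisie_alien == row["daisie_expected_alien"]
                and inv_by_name[key].daisie_worst == row["daisie_expected_worst"]
            ),
        )
        _accuracy(
            "bold",
            lambda key, row: (
                None
                if key not in bold_by_name
                else bold_by_name[key].taxon_found == row["bold_expected_found"]
                and bold_by_name[key].public_records == row["bold_expected_records"]
                and bold_by_name[key].provenance == row["bold_expected_type"]
            ),
        )

        # planted redlist_synonym_only_fraction recovery
        n_alt_elig = n_alt_obs = 0
        for key, row in rows.iterrows():
            if not row["rl_alt_keyed_eligible"] or key not in rl_by_name:
                continue
            ann = rl_by_name[key]
            if ann.source == "none":
                continue
            n_alt_elig += 1
            n_alt_obs += ann.source == "TPLsynonym"
        report.n_redlist_alt_eligible = n_alt_elig
        report.n_redlist_alt_observed = n_alt_obs
        report.redlist_alt_keyed_rate = (
            n_alt_obs / n_alt_elig if n_alt_elig else float("nan")
        )

    return report
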