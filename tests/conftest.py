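import logging

import pytest

from seminum import annotation as ann
from seminum import names as nm
from seminum import reconcile as rc
from seminum import verification as vf
from seminum.checklist import DIALECTS, ChecklistRecord, store_from_records
from seminum.synthetic import WorldConfig, generate_world

logging.getLogger("seminum").setLevel(logging.ERROR)


def _rec(provider, record_id, name, status, accepted="", authority="", infra=""):
    parts = [p for p in name.split() if p not in ("subsp.", "var.", "f.")]
    return ChecklistRecord(
        provider=provider,
        record_id=record_id,
        name=name,
        authority=authority,
        raw_status=status,
        accepted_record_id=accepted,
        genus=parts[0],
        species_epithet=parts[1] if len(parts) > 1 else "",
        infraspecific_epithet=infra,
    )


@pytest.fixture
def tpl_store():
    """Small TPL-dialect store with a homonym pair, a synonym ring and an
    infraspecific name."""
    records = [
        _rec("TPL", "T1", "Acacia dealbata", "Accepted", authority="Link"),
        _rec("TPL", "H1", "Acacia dealbata", "Unresolved", authority="Mill."),
        _rec("TPL", "T2", "Bromus bromoideus", "Accepted"),
        _rec("TPL", "T3", "Bromus arvensis", "Accepted"),
        _rec("TPL", "I1", "Bromus arvensis subsp. parviflorus", "Accepted", infra="parviflorus"),
        _rec("TPL", "T4", "Cnidoscolus aconitifolius", "Accepted"),
        _rec("TPL", "S1", "Cnidoscolus fragrans", "Synonym", accepted="T4"),
        _rec("TPL", "S2", "Cnidoscolus napifolius", "Synonym", accepted="T4"),
        _rec("TPL", "T5", "Euphrasia minima", "Accepted"),
    ]
    return store_from_records(records, DIALECTS["TPL"])


@pytest.fixture
def col_store():
    records = [
        _rec("COL", "C1", "Acacia dealbata", "Accepted name"),
        _rec("COL", "C2", "Bromus bromoideus", "Provisionally accepted name"),
        _rec("COL", "C3", "Cnidoscolus aconitifolius", "Synonym", accepted="C1"),
        _rec("COL", "C4", "Euphrasia minima", "Accepted name"),
    ]
    return store_from_records(records, DIALECTS["COL"])


@pytest.fixture
def eol_store():
    records = [
        _rec("EOL", "E1", "Acacia dealbata Link", ""),
        _rec("EOL", "E2", "Bromus bromoideus", ""),
    ]
    # the embedded-authority record still carries clean genus/species fields
    return store_from_records(records, DIALECTS["EOL"])


@pytest.fixture
def redlist_store():
    store = ann.RedListStore()
    store.add_primary("Cnidoscolus fragrans", "EX")
    store.add_primary("Bromus bromoideus", "EW")
    store.add_primary("Euphrasia mendoncae", "EX")
    store.add_synonym("Euphrasia minima", "Euphrasia mendoncae")
    return store


@pytest.fixture
def annotation_stores(redlist_store):
    gisin = ann.GisinStore()
    gisin.add("Acacia dealbata", exotic=True, harmful=True)
    gisin.add("Acacia dealbata", exotic=True, harmful=False)
    gisin.add("Cnidoscolus fragrans", exotic=True, harmful=False)
    daisie = ann.DaisieStore()
    daisie.add("Acacia dealbata", worst=True)
    daisie.add("Euphrasia minima", worst=False)
    bold = ann.BoldStore()
    bold.add("Cnidoscolus fragrans", 5)
    bold.add("Bromus bromoideus", 0)
    return {"redlist": redlist_store, "gisin": gisin, "daisie": daisie, "bold": bold}


@pytest.fixture(scope="session")
def default_world():
    return generate_world(WorldConfig(seed=11))


@pytest.fixture(scope="session")
def default_run(default_world):
    """The full pipeline executed once on the default synthetic world."""
    world = default_world
    parsed = [
        p
        for cat_id, text in world.catalogues.items()
        for p in nm.parse_catalogue(text, cat_id)
    ]
    unl = [u.canonical for u in nm.compile_unique_names(nm.exclude_cultivars(parsed))]
    coll = vf.verify_all(world.stores, unl)
    discrepancies, agreements = rc.collect_discrepancies(coll)
    annotations = ann.annotate_all(
        coll.combined_verified(),
        world.stores["TPL"],
        redlist_store=world.redlist,
        gisin_store=world.gisin,
        daisie_store=world.daisie,
        bold_store=world.bold,
    )
    return {
        "world": world,
        "unl": unl,
        "collection": coll,
        "discrepancies": discrepancies,
        "agreements": agreements,
        "annotations": annotations,
    }
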