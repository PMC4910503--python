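"""Alternative-name expansion and the four annotation domains."""

import pytest

from seminum import annotation as ann


class TestExpandAlternatives:
    def test_synonym_resolves_to_accepted_and_cosynonyms(self, tpl_store):
        alts = ann.expand_alternatives(tpl_store, "Cnidoscolus fragrans")
        assert alts.accepted == "Cnidoscolus aconitifolius"
        assert alts.synonyms == ("Cnidoscolus napifolius",)

    def test_accepted_name_collects_its_synonyms(self, tpl_store):
        alts = ann.expand_alternatives(tpl_store, "Cnidoscolus aconitifolius")
        assert alts.accepted == ""
        assert set(alts.synonyms) == {"Cnidoscolus fragrans", "Cnidoscolus napifolius"}

    def test_two_synonyms_expand_to_same_closure(self, tpl_store):
        a = ann.expand_alternatives(tpl_store, "Cnidoscolus fragrans")
        b = ann.expand_alternatives(tpl_store, "Cnidoscolus napifolius")
        closure_a = {a.original, a.accepted, *a.synonyms}
        closure_b = {b.original, b.accepted, *b.synonyms}
        assert closure_a == closure_b

    def test_accepted_without_synonyms(self, tpl_store):
        alts = ann.expand_alternatives(tpl_store, "Euphrasia minima")
        assert alts.accepted == "" and alts.synonyms == ()

    def test_absent_name_disables_fallback(self, tpl_store):
        alts = ann.expand_alternatives(tpl_store, "Zea mays")
        assert alts.query_order() == []


class TestRedList:
    def test_hit_via_tpl_synonym_returns_extinct(self, redlist_store, tpl_store):
        a = ann.annotate_redlist(redlist_store, tpl_store, "Cnidoscolus aconitifolius")
        assert (a.category, a.source) == ("EX", "TPLsynonym")

    def test_direct_primary_hit(self, redlist_store, tpl_store):
        a = ann.annotate_redlist(redlist_store, tpl_store, "Bromus bromoideus")
        assert (a.category, a.source) == ("EW", "RL")

    def test_redlist_internal_synonym_precedes_tpl(self, redlist_store, tpl_store):
        a = ann.annotate_redlist(redlist_store, tpl_store, "Euphrasia minima")
        assert (a.category, a.source) == ("EX", "RLsynonym")

    def test_total_miss(self, redlist_store, tpl_store):
        a = ann.annotate_redlist(redlist_store, tpl_store, "Bromus arvensis")
        assert (a.category, a.source) == ("none", "none")

    def test_annotation_invariant(self):
        with pytest.raises(ValueError):
            ann.RedListAnnotation(name="X y", category="EX", source="none")


@pytest.mark.parametrize(
    "records,expected",
    [
        ([(True, True)], "Invasive"),
        ([(True, False)], "Exotic"),
        ([(False, False)], "Neither"),
        ([(True, False), (True, True), (False, False)], "Invasive"),
        ([], "Neither"),
    ],
)
def test_classify_gisin(records, expected):
    recs = [ann.OccurrenceRecord(e, h) for e, h in records]
    assert ann.classify_gisin(recs) == expected
    assert ann.classify_gisin(list(reversed(recs))) == expected  # order-independent


class TestGisin:
    def test_original_hit(self, annotation_stores, tpl_store):
        klass, prov = ann.annotate_gisin(
            annotation_stores["gisin"], tpl_store, "Acacia dealbata"
        )
        assert (klass, prov) == ("Invasive", "original")

    def test_hit_via_synonym_carries_tpl_status(self, annotation_stores, tpl_store):
        klass, prov = ann.annotate_gisin(
            annotation_stores["gisin"], tpl_store, "Cnidoscolus aconitifolius"
        )
        assert (klass, prov) == ("Exotic", "Synonym")

    def test_no_hit(self, annotation_stores, tpl_store):
        assert ann.annotate_gisin(
            annotation_stores["gisin"], tpl_store, "Bromus arvensis"
        ) == ("none", "none")


def test_daisie_membership(annotation_stores):
    daisie = annotation_stores["daisie"]
    assert ann.annotate_daisie(daisie, "Acacia dealbata") == (True, True)
    assert ann.annotate_daisie(daisie, "Euphrasia minima") == (True, False)
    assert ann.annotate_daisie(daisie, "Zea mays") == (False, False)


def test_worst_implies_alien_invariant():
    with pytest.raises(ValueError):
        ann.InvasivenessAnnotation(
            name="X y", gisin_class="none", gisin_provenance="none",
            daisie_alien=False, daisie_worst=True,
        )


class TestBold:
    def test_taxon_found_with_zero_records(self, annotation_stores, tpl_store):
        a = ann.annotate_bold(annotation_stores["bold"], tpl_store, "Bromus bromoideus")
        assert (a.taxon_found, a.public_records, a.provenance) == (True, 0, "original")

    def test_hit_via_synonym(self, annotation_stores, tpl_store):
        a = ann.annotate_bold(
            annotation_stores["bold"], tpl_store, "Cnidoscolus aconitifolius"
        )
        assert (a.taxon_found, a.public_records, a.provenance) == (True, 5, "TPLsynonym")

    def test_miss(self, annotation_stores, tpl_store):
        a = ann.annotate_bold(annotation_stores["bold"], tpl_store, "Zea mays")
        assert (a.taxon_found, a.public_records, a.provenance) == (False, 0, "none")


def test_annotation_store_round_trips(tmp_path, annotation_stores):
    for key, store in annotation_stores.items():
        path = tmp_path / f"{key}.csv"
        with open(path, "w", newline="") as fh:
            store.dump(fh)
        back = type(store).load(str(path))
        assert len(back) == len(store)
    back_rl = ann.RedListStore.load(str(tmp_path / "redlist.csv"))
    assert back_rl.lookup("Euphrasia minima") == ("EX", "RLsynonym")
    back_bold = ann.BoldStore.load(str(tmp_path / "bold.csv"))
    assert back_bold.record_count("Cnidoscolus fragrans") == 5


def test_fallback_partition_sums_to_unl(annotation_stores, tpl_store):
    unl = [
        "Acacia dealbata",
        "Bromus bromoideus",
        "Cnidoscolus aconitifolius",
        "Euphrasia minima",
        "Zea mays",
    ]
    result = ann.annotate_all(
        unl,
        tpl_store,
        redlist_store=annotation_stores["redlist"],
        gisin_store=annotation_stores["gisin"],
        daisie_store=annotation_stores["daisie"],
        bold_store=annotation_stores["bold"],
    )
    for domain in ("redlist", "gisin", "bold"):
        assert result.audit.total(domain) == len(unl)
    assert result.audit.violations == 0


def test_alternatives_only_after_original_miss(annotation_stores, tpl_store):
    """Any annotation with alternative provenance must come from a name whose
    original query genuinely misses the store."""
    unl = ["Acacia dealbata", "Cnidoscolus aconitifolius", "Euphrasia minima"]
    result = ann.annotate_all(
        unl,
        tpl_store,
        redlist_store=annotation_stores["redlist"],
        gisin_store=annotation_stores["gisin"],
        daisie_store=annotation_stores["daisie"],
        bold_store=annotation_stores["bold"],
    )
    for a in result.redlist:
        if a.source in ("TPLsynonym", "TPLaccepted"):
            assert annotation_stores["redlist"].lookup(a.name) is None
    for a in result.invasiveness:
        if a.gisin_provenance not in ("original", "none"):
            assert annotation_stores["gisin"].lookup(a.name) == []
    for a in result.barcodes:
        if a.provenance in ("TPLsynonym", "TPLaccepted"):
            assert not annotation_stores["bold"].taxon_exists(a.name)
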