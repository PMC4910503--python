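"""Levenshtein matching, status harmonization and two-step verification."""

import io

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import dp_levenshtein
from seminum import verification as vf
from seminum.names import CanonicalName
from seminum.verification import MatchType, Status

WORDS = st.text(alphabet="abcdefguvxyz ×é", min_size=0, max_size=14)


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ("Euphrasia minima", "Euphrasia minima", 0),
        ("Bromus bromoideus", "Bromus bromoides", 1),
        ("abc", "", 3),
        ("Acacia dealbata", "ACACIA DEALBATA", 0),
    ],
)
def test_levenshtein_examples(a, b, expected):
    assert vf.levenshtein(a, b) == expected


@settings(max_examples=300, derandomize=True)
@given(WORDS, WORDS)
def test_levenshtein_agrees_with_dp_oracle(a, b):
    assert vf.levenshtein(a, b) == dp_levenshtein(a, b)


@settings(max_examples=200, derandomize=True)
@given(WORDS, WORDS, WORDS)
def test_levenshtein_is_a_metric(a, b, c):
    assert vf.levenshtein(a, b) == vf.levenshtein(b, a)
    assert (vf.levenshtein(a, b) == 0) == (a.casefold() == b.casefold())
    assert vf.levenshtein(a, c) <= vf.levenshtein(a, b) + vf.levenshtein(b, c)


@pytest.mark.parametrize(
    "provider,raw,n,expected",
    [
        ("COL", "Provisionally accepted name", 1, Status.ACCEPTED),
        ("COL", "Accepted name", 1, Status.ACCEPTED),
        ("COL", "Accepted name", 2, Status.AMBIGUOUS),
        ("COL", "Synonym", 1, Status.SYNONYM),
        ("TPL", "Synonym", 1, Status.SYNONYM),
        ("TPL", "Misapplied", 1, Status.MISAPPLIED),
        ("TPL", "Accepted", 5, Status.AMBIGUOUS),
        ("EOL", "", 1, Status.NA),
        ("EOL", "", 3, Status.NA),
    ],
)
def test_harmonize_status(provider, raw, n, expected):
    assert vf.harmonize_status(provider, raw, n) is expected


def test_harmonize_status_rejects_unknown_vocabulary():
    with pytest.raises(ValueError, match="Bogus"):
        vf.harmonize_status("TPL", "Bogus", 1)
    with pytest.raises(ValueError):
        vf.harmonize_status("COL", "Accepted", 0)


class TestVerifyName:
    def test_exact_hit_accepted(self, col_store):
        res = vf.verify_name(col_store, CanonicalName("Euphrasia minima"))
        assert (res.match_type, res.status) == (MatchType.EXACT, Status.ACCEPTED)
        assert res.verified and res.edit_distance is None

    def test_exact_homonym_pair_is_ambiguous(self, tpl_store):
        res = vf.verify_name(tpl_store, CanonicalName("Acacia dealbata"))
        assert (res.match_type, res.status) == (MatchType.EXACT, Status.AMBIGUOUS)
        assert set(res.matched_record_ids) == {"T1", "H1"}

    def test_relaxed_single_candidate(self, tpl_store):
        res = vf.verify_name(tpl_store, CanonicalName("Bromus bromoides"))
        assert (res.match_type, res.status) == (MatchType.RELAXED, Status.ACCEPTED)
        assert res.alternative_name == "Bromus bromoideus"
        assert res.edit_distance == 1

    def test_miss_is_na(self, tpl_store):
        res = vf.verify_name(tpl_store, CanonicalName("Zea mays"))
        assert not res.verified
        assert (res.match_type, res.status) == (MatchType.NONE, Status.NA)

    def test_eol_verified_without_status(self, eol_store):
        res = vf.verify_name(eol_store, CanonicalName("Acacia dealbata"))
        assert res.verified and res.match_type is MatchType.EXACT
        assert res.status is Status.NA


def test_relaxed_two_candidates_is_ambiguous():
    from conftest import _rec
    from seminum.checklist import DIALECTS, store_from_records

    store = store_from_records(
        [
            _rec("TPL", "A", "Salvia officinalis", "Accepted"),
            _rec("TPL", "B", "Salvia officinalas", "Synonym", accepted="A"),
        ],
        DIALECTS["TPL"],
    )
    res = vf.verify_name(store, CanonicalName("Salvia officinalus"))
    assert (res.match_type, res.status) == (MatchType.RELAXED, Status.AMBIGUOUS)
    assert res.alternative_name == ""


def test_raising_distance_bound_never_unverifies(tpl_store):
    names = [
        CanonicalName(t)
        for t in ("Bromus bromoides", "Acacia dealbata", "Zea mays", "Euphrasia minina")
    ]
    for name in names:
        at2 = vf.verify_name(tpl_store, name, max_distance=2)
        for k in (3, 4, 6):
            atk = vf.verify_name(tpl_store, name, max_distance=k)
            if at2.verified:
                assert atk.verified


def test_verify_all_cardinality_and_union(tpl_store, col_store, eol_store):
    unl = [CanonicalName("Euphrasia minima"), CanonicalName("Cnidoscolus fragrans")]
    coll = vf.verify_all({"TPL": tpl_store, "COL": col_store, "EOL": eol_store}, unl)
    assert len(coll.results) == 6
    # fragrans exists only in TPL; still combined-verified by the union rule
    assert {n.text for n in coll.combined_verified()} == {
        "Euphrasia minima",
        "Cnidoscolus fragrans",
    }
    assert coll.audit.ok()


def test_verify_all_requires_a_store():
    with pytest.raises(ValueError):
        vf.verify_all({}, [CanonicalName("Acacia dealbata")])


def test_collection_round_trips_through_csv(tpl_store, col_store):
    unl = [CanonicalName("Acacia dealbata"), CanonicalName("Bromus bromoides")]
    coll = vf.verify_all({"TPL": tpl_store, "COL": col_store}, unl)
    buf = io.StringIO()
    vf.write_collection(coll, buf)
    buf.seek(0)
    back = vf.read_collection(buf)
    for orig, re in zip(coll.results, back.results):
        assert (orig.query_name.text, orig.provider) == (re.query_name.text, re.provider)
        assert (orig.match_type, orig.status) == (re.match_type, re.status)
        assert orig.matched_record_ids == re.matched_record_ids
        assert orig.alternative_name == re.alternative_name
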