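"""Synthetic-world generation: determinism, validity, ground-truth consistency."""

import io

import pytest

from oracles import dp_levenshtein
from seminum import names as nm
from seminum import verification as vf
from seminum.checklist import DIALECTS, load_checklist
from seminum.synthetic import SyntheticWorld, WorldConfig, generate_world, truth_check


def test_same_seed_reproduces_world():
    a = generate_world(WorldConfig(n_accepted=60, seed=7))
    b = generate_world(WorldConfig(n_accepted=60, seed=7))
    assert a.catalogues == b.catalogues
    assert a.truth.equals(b.truth)
    for prov in a.stores:
        assert {r.record_id: r for r in a.stores[prov].records.values()} == {
            r.record_id: r for r in b.stores[prov].records.values()
        }


def test_different_seed_differs():
    a = generate_world(WorldConfig(n_accepted=60, seed=7))
    b = generate_world(WorldConfig(n_accepted=60, seed=8))
    assert a.catalogues != b.catalogues


@pytest.mark.parametrize(
    "kwargs",
    [
        {"n_accepted": 0},
        {"n_accepted": 1, "homonym_rate": 0.5},
        {"typo_rate": 1.5},
        {"typo_distance_range": (1, 5)},
        {"typo_rate": 0.8, "unrecoverable_rate": 0.4},
        {"mean_synonyms_per_taxon": -1},
    ],
)
def test_impossible_configs_rejected(kwargs):
    with pytest.raises(ValueError):
        generate_world(WorldConfig(**kwargs))


def test_emitted_stores_pass_load_time_validation(tmp_path, default_world):
    default_world.write(tmp_path / "world")
    for prov in ("TPL", "COL", "EOL"):
        store = load_checklist(
            str(tmp_path / "world" / f"checklist_{prov.lower()}.csv"), DIALECTS[prov]
        )
        assert store.rejected_rows == []
        assert len(store) == len(default_world.stores[prov])


def test_config_round_trips_through_flat_file(tmp_path):
    cfg = WorldConfig(n_accepted=77, seed=5, typo_rate=0.2, typo_distance_range=(2, 2))
    cfg.to_file(tmp_path / "w.cfg")
    back = WorldConfig.from_file(tmp_path / "w.cfg")
    assert back == cfg


def test_injected_distances_verified_by_oracle(default_world):
    truth = default_world.truth
    corrupted = truth[truth["injected_distance"] > 0]
    assert len(corrupted) > 0
    for _, row in corrupted.iterrows():
        d = dp_levenshtein(row["canonical"], row["source_name"])
        assert d == row["injected_distance"]
        if row["recoverable"]:
            assert 1 <= d <= 2
        else:
            assert d >= 3


def test_clean_world_verifies_everything_exactly():
    cfg = WorldConfig(
        n_accepted=120,
        typo_rate=0.0,
        unrecoverable_rate=0.0,
        provider_coverage={"TPL": 1.0, "COL": 1.0, "EOL": 1.0},
        seed=3,
    )
    world = generate_world(cfg)
    parsed = [
        p for cid, t in world.catalogues.items() for p in nm.parse_catalogue(t, cid)
    ]
    unl = [u.canonical for u in nm.compile_unique_names(nm.exclude_cultivars(parsed))]
    coll = vf.verify_all(world.stores, unl)
    assert all(r.match_type is vf.MatchType.EXACT for r in coll.results)
    report = truth_check(coll, None, world.truth)
    assert report.exact_recovery_rate == 1.0
    assert report.false_ambiguity_count == 0


def test_ground_truth_is_self_consistent(default_world):
    """Replaying the expected outcomes through the scorer is a perfect score."""
    from seminum.names import CanonicalName
    from seminum.verification import (
        MatchType,
        NameCollection,
        Status,
        VerificationResult,
    )

    coll = NameCollection()
    seen = set()
    for _, row in default_world.truth.iterrows():
        key = row["canonical"].casefold()
        if key in seen:
            continue
        seen.add(key)
        for prov in ("TPL", "COL", "EOL"):
            pl = prov.lower()
            mt = MatchType(row[f"expected_match_{pl}"])
            coll.results.append(
                VerificationResult(
                    query_name=CanonicalName(row["canonical"]),
                    provider=prov,
                    verified=mt is not MatchType.NONE,
                    match_type=mt,
                    alternative_name=row[f"expected_alt_{pl}"],
                    status=Status(row[f"expected_status_{pl}"]),
                )
            )
    report = truth_check(coll, None, default_world.truth)
    assert report.match_accuracy == {"TPL": 1.0, "COL": 1.0, "EOL": 1.0}
    assert report.status_accuracy == {"TPL": 1.0, "COL": 1.0, "EOL": 1.0}
    assert report.false_ambiguity_count == 0


def test_world_write_is_text_only(tmp_path, default_world):
    out = tmp_path / "world"
    default_world.write(out)
    for path in out.rglob("*"):
        if path.is_file():
            path.read_text(encoding="utf-8")  # raises on anything non-text
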