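"""Catalogue parsing, canonical normalisation and UNL compilation."""

import pytest

from seminum import names as nm
from seminum.names import Rank


@pytest.mark.parametrize(
    "line,genus,epithet,rank,infra,cultivar,authority",
    [
        ("Acacia dealbata Link", "Acacia", "dealbata", Rank.NONE, "", "", "Link"),
        ("Euphrasia minima Jacq. ex DC.", "Euphrasia", "minima", Rank.NONE, "", "", "Jacq. ex DC."),
        ("Genus x species", "Genus", "species", Rank.HYBRID, "", "", ""),
        ("Genus × species", "Genus", "species", Rank.HYBRID, "", "", ""),
        ("Bromus arvensis subsp. parviflorus", "Bromus", "arvensis", Rank.SUBSP, "parviflorus", "", ""),
        ("Bromus arvensis ssp. parviflorus", "Bromus", "arvensis", Rank.SUBSP, "parviflorus", "", ""),
        ("Mentha aquatica var. crispa L.", "Mentha", "aquatica", Rank.VAR, "crispa", "", "L."),
        ("Betula pendula f. dalecarlica", "Betula", "pendula", Rank.F, "dalecarlica", "", ""),
        ("Rosa canina 'Kiese'", "Rosa", "canina", Rank.CV, "", "Kiese", ""),
    ],
)
def test_parse_line_grammar(line, genus, epithet, rank, infra, cultivar, authority):
    p = nm.parse_line(line)
    assert p is not None
    assert (p.genus, p.species_epithet, p.rank_marker) == (genus, epithet, rank)
    assert (p.infraspecific_epithet, p.cultivar_name, p.authority) == (infra, cultivar, authority)


@pytest.mark.parametrize(
    "line",
    ["", "   ", "=== IS001 ===", "(seed exchange list)", "lowercase start", "Single"],
)
def test_unparseable_lines_skipped(line):
    assert nm.parse_line(line) is None


def test_parse_catalogue_conserves_lines(caplog):
    text = "Acacia dealbata Link\n\n=== header ===\nBromus arvensis\n"
    with caplog.at_level("INFO", logger="seminum.names"):
        parsed = nm.parse_catalogue(text, "IS001")
    assert [p.species_epithet for p in parsed] == ["dealbata", "arvensis"]
    # the non-name line is logged with its line number
    assert any("3" in r.message for r in caplog.records)


def test_parse_catalogue_rejects_bad_bytes():
    with pytest.raises(UnicodeDecodeError):
        nm.parse_catalogue(b"Acacia dealbata\xff\n")


@pytest.mark.parametrize(
    "raw,expected",
    [
        ("ACACIA DEALBATA", "Acacia dealbata"),
        ("Acacia  dealbata", "Acacia dealbata"),
        ("Genus x species", "Genus × species"),
        ("Genus × species", "Genus × species"),
    ],
)
def test_normalize_canonical_text(raw, expected):
    p = nm.parse_line(raw)
    assert nm.normalize(p).text == expected


def test_normalize_drops_authority_and_quotes():
    assert nm.normalize(nm.parse_line("Acacia dealbata Link")).text == "Acacia dealbata"
    assert nm.normalize(nm.parse_line("Rosa canina 'Kiese'")).text == "Rosa canina"


def test_exclude_cultivars():
    names = [
        nm.parse_line("Acacia dealbata"),
        nm.parse_line("Rosa canina 'Kiese'"),
        nm.parse_line("Bromus arvensis"),
        nm.parse_line("Malus domestica 'Gala'"),
        nm.parse_line("Genus x species"),
    ]
    kept = nm.exclude_cultivars(names)
    assert len(kept) == 3
    assert all(p.rank_marker is not Rank.CV for p in kept)
    assert nm.exclude_cultivars([]) == []


def test_compile_unique_names_collapses_authority_variants():
    lines = [
        ("Euphrasia minima Jacq. ex DC.", "cat1"),
        ("Euphrasia minima Schleich.", "cat2"),
        ("Euphrasia minima", "cat3"),
    ]
    parsed = [nm.parse_line(t, c) for t, c in lines]
    unl = nm.compile_unique_names(parsed)
    assert len(unl) == 1
    entry = unl[0]
    assert entry.occurrences == 3
    assert entry.catalogues == {"cat1", "cat2", "cat3"}
    assert entry.authorities == {"Jacq. ex DC.", "Schleich."}


def test_compile_unique_names_identity_on_disjoint_input():
    parsed = [nm.parse_line(t) for t in ("Acacia dealbata", "Bromus arvensis")]
    assert len(nm.compile_unique_names(parsed)) == 2


def test_pipeline_idempotent_on_own_output():
    text = "ACACIA  DEALBATA Link\nGenus x species\nBromus arvensis subsp. parviflorus\n"
    unl1 = nm.compile_unique_names(nm.parse_catalogue(text, "a"))
    rendered = "\n".join(u.canonical.text for u in unl1)
    unl2 = nm.compile_unique_names(nm.parse_catalogue(rendered, "b"))
    assert [u.canonical for u in unl1] == [u.canonical for u in unl2]


def test_unl_round_trips_through_csv(tmp_path):
    parsed = [
        nm.parse_line("Acacia dealbata Link", "cat1"),
        nm.parse_line("Genus x species", "cat2"),
        nm.parse_line("Acacia dealbata", "cat2"),
    ]
    unl = nm.compile_unique_names(parsed)
    path = tmp_path / "unl.csv"
    with open(path, "w", newline="") as fh:
        nm.write_unl(unl, fh)
    with open(path, newline="") as fh:
        back = nm.read_unl(fh)
    assert [u.canonical for u in back] == [u.canonical for u in unl]
    assert [u.occurrences for u in back] == [u.occurrences for u in unl]
    assert [u.authorities for u in back] == [u.authorities for u in unl]
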