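import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cypmine.errors import (
    AmbiguousClusterTypeError,
    NotAFerredoxinError,
    UndefinedStatisticError,
    ValidationError,
)
from cypmine.ferredoxin import (
    FdxConfig,
    FeSMotifMatch,
    FerredoxinAnnotation,
    SubtypeRegistry,
    annotate_ferredoxins,
    assign_cluster_type,
    detect_fes_motifs,
    ferredoxin_group_census,
    parse_signature,
    spacing_signature,
)
from cypmine.records import SpeciesRecord


@pytest.mark.parametrize(
    "positions,expected",
    [
        ([10, 13, 16, 20], "C-x2-C-x2-C-x3-C"),
        ([5, 10, 13, 47], "C-x4-C-x2-C-x33-C"),
        ([0, 1], "C-x0-C"),
    ],
)
def test_spacing_signature(positions, expected):
    assert spacing_signature(positions) == expected


@pytest.mark.parametrize("positions", [[3], [], [5, 5], [7, 3]])
def test_spacing_signature_degenerate(positions):
    with pytest.raises(ValidationError):
        spacing_signature(positions)


@settings(max_examples=100, deadline=None)
@given(st.lists(st.integers(min_value=0, max_value=60), min_size=1, max_size=8))
def test_signature_gap_round_trip(gaps):
    """Parsing a signature string back recovers the gap list."""
    positions = [0]
    for g in gaps:
        positions.append(positions[-1] + g + 1)
    assert parse_signature(spacing_signature(positions)) == gaps


def test_detect_bacterial_4fe4s():
    seq = "AA" + "CAACAACAAACP" + "AA"
    matches = detect_fes_motifs(seq)
    assert len(matches) == 1
    assert matches[0].motif_kind == "bact_4Fe4S"
    assert matches[0].cys_positions == (2, 5, 8, 12)


def test_detect_two_motifs_and_no_motifs():
    motif = "CAACAACAAACP"
    seq = "GG" + motif + "A" * 12 + motif + "GG"
    matches = detect_fes_motifs(seq)
    assert [m.motif_kind for m in matches] == ["bact_4Fe4S", "bact_4Fe4S"]
    assert detect_fes_motifs("MKTLV" * 10) == []


def test_detect_plant_and_3fe4s():
    plant = "C" + "A" * 4 + "C" + "AA" + "C" + "A" * 25 + "C"
    (m,) = detect_fes_motifs("GG" + plant + "GG")
    assert m.motif_kind == "plant_2Fe2S"
    three = "C" + "AA" + "C" + "A" * 7 + "CP"
    (m,) = detect_fes_motifs("GG" + three + "GG")
    assert m.motif_kind == "bact_3Fe4S"


def _m(kind, positions):
    return FeSMotifMatch(kind, tuple(positions))


@pytest.mark.parametrize(
    "matches,expected",
    [
        ([_m("plant_2Fe2S", [0, 5, 8, 30])], "2Fe-2S"),
        ([_m("bact_3Fe4S", [0, 3, 11])], "3Fe-4S"),
        ([_m("bact_4Fe4S", [0, 3, 6, 10])], "4Fe-4S"),
        # canonical twin spacing: inter-motif gap of 7 residues
        ([_m("bact_4Fe4S", [0, 3, 6, 10]), _m("bact_4Fe4S", [18, 21, 24, 28])], "2[4Fe-4S]"),
        # Alvin promotion: insertion between the motifs exceeds 20 residues
        ([_m("bact_4Fe4S", [0, 3, 6, 10]), _m("bact_4Fe4S", [41, 44, 47, 51])], "2[4Fe-4S]Alv"),
        ([_m("bact_3Fe4S", [0, 3, 11]), _m("bact_4Fe4S", [30, 33, 36, 40])], "7Fe-8S"),
    ],
)
def test_assign_cluster_type(matches, expected):
    assert assign_cluster_type(matches) == expected


def test_assign_cluster_type_signals():
    with pytest.raises(NotAFerredoxinError):
        assign_cluster_type([])
    triple = [_m("bact_4Fe4S", [i, i + 3, i + 6, i + 10]) for i in (0, 20, 40)]
    with pytest.raises(AmbiguousClusterTypeError):
        assign_cluster_type(triple)


def test_registry_seeding_and_next_free():
    reg = SubtypeRegistry()
    reg.seed("C-x2-C-x2-C-x3-C", "4Fe-4S", 34)
    assert reg.assign("C-x2-C-x2-C-x3-C", "4Fe-4S") == 34  # seeded number sticks
    assert reg.next_free("4Fe-4S") == 35
    assert reg.assign("C-x2-C-x2-C-x4-C", "4Fe-4S") == 35  # novel -> next free
    assert reg.next_free("4Fe-4S") == 36
    assert reg.assign("C-x2-C-x2-C-x4-C", "4Fe-4S") == 35  # idempotent on repeat


def test_registry_namespaces_are_per_cluster_type():
    reg = SubtypeRegistry()
    sig = "C-x2-C-x2-C-x3-C"
    assert reg.assign(sig, "4Fe-4S") == 1
    assert reg.assign(sig, "2Fe-2S") == 1  # independent numbering per type


def test_registry_tsv_round_trip(tmp_path):
    reg = SubtypeRegistry()
    reg.seed("C-x4-C-x2-C-x28-C", "2Fe-2S", 18)
    reg.assign("C-x4-C-x2-C-x30-C", "2Fe-2S")
    path = tmp_path / "registry.tsv"
    reg.to_tsv(path)
    back = SubtypeRegistry.from_tsv(path)
    assert back.get("C-x4-C-x2-C-x28-C", "2Fe-2S") == 18
    assert back.get("C-x4-C-x2-C-x30-C", "2Fe-2S") == 19
    assert back.next_free("2Fe-2S") == 20


def test_registry_monotonic_rerun(cohort):
    """Re-annotating the same proteome yields identical subtype assignments."""
    proteins = cohort.all_proteins()
    a1, _ = annotate_ferredoxins(proteins, SubtypeRegistry())
    a2, _ = annotate_ferredoxins(proteins, SubtypeRegistry())
    assert [(x.protein_id, x.subtype) for x in a1] == [(x.protein_id, x.subtype) for x in a2]


def test_planted_cluster_types_recovered_exactly(cohort, pipeline):
    manifest = cohort.manifest
    by_id = {a.protein_id: a for a in pipeline["fdx_annotations"]}
    planted = manifest[manifest["kind"] == "ferredoxin"]
    for row in planted.itertuples():
        ann = by_id[row.protein_id]
        assert ann.cluster_type == row.cluster_type
        assert ann.signature == row.signature
    decoys = set(manifest[manifest["kind"] == "decoy"]["protein_id"])
    assert not decoys & set(by_id)


def _census_annotations(per_type):
    out = []
    i = 0
    for ctype, n in per_type.items():
        for _ in range(n):
            out.append(FerredoxinAnnotation(f"f{i}", f"sp{i % 104}", ctype, "C-x2-C", 1))
            i += 1
    return out


def test_group_census_mass_and_average():
    per_type = {"2Fe-2S": 136, "3Fe-4S": 6, "4Fe-4S": 11, "2[4Fe-4S]": 9, "2[4Fe-4S]Alv": 107}
    species = [SpeciesRecord(f"sp{i}", f"S{i}", "G", "grp", f"T{i}") for i in range(104)]
    census = ferredoxin_group_census(_census_annotations(per_type), species)
    assert census.total == 269
    assert sum(census.per_type.values()) == 269
    for ctype, n in per_type.items():
        assert census.per_type[ctype] == n
    assert census.per_type["7Fe-8S"] == 0
    assert census.average.display == "2.6"


def test_group_census_empty_and_undefined():
    species = [SpeciesRecord(f"sp{i}", f"S{i}", "G", "grp", f"T{i}") for i in range(5)]
    census = ferredoxin_group_census([], species)
    assert census.total == 0
    assert all(v == 0 for v in census.per_type.values())
    assert census.average.display == "0.0"
    with pytest.raises(UndefinedStatisticError):
        ferredoxin_group_census([], [])


def test_large_fes_enzymes_are_not_candidates():
    from cypmine.records import ProteinRecord

    long_seq = "A" * 150 + "CAACAACAAACP" + "A" * 150  # 312 aa > max_length
    anns, _ = annotate_ferredoxins([ProteinRecord("p", "sp", long_seq)])
    assert anns == []
    anns, _ = annotate_ferredoxins(
        [ProteinRecord("p", "sp", long_seq)], config=FdxConfig(max_length=400)
    )
    assert len(anns) == 1
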