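import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cypmine.errors import ConsistencyError, UndefinedStatisticError
from cypmine.nomenclature import P450Annotation
from cypmine.records import SpeciesRecord
from cypmine.stats import (
    ABSENT,
    PRESENT,
    average_p450s,
    build_group_summary,
    build_presence_matrix,
    diversity_percentage,
    group_summary_frame,
    hierarchical_cluster,
    PresenceMatrix,
    shared_sets,
)
import pandas as pd


def _ann(pid, code, family, subfamily="A"):
    return P450Annotation(pid, code, family, subfamily, "r1", 80.0, "known_subfamily")


def _species(n, label="grp"):
    return [SpeciesRecord(f"sp{i}", f"S {i}", "G", label, f"T{i}") for i in range(n)]


@pytest.mark.parametrize(
    "P,S,expected",
    [(277, 1261, "0.2"), (5460, 203, "27"), (98, 77, "1"), (0, 7, "0.0")],
)
def test_average_p450s_display(P, S, expected):
    assert average_p450s(P, S).display == expected


@pytest.mark.parametrize(
    "F,P,S,expected",
    [(21, 98, 77, "0.28"), (14, 712, 229, "0.01"), (1, 1, 1, "100.00")],
)
def test_diversity_percentage_display(F, P, S, expected):
    assert diversity_percentage(F, P, S).display == expected


def test_zero_denominators_error():
    with pytest.raises(UndefinedStatisticError):
        average_p450s(10, 0)
    with pytest.raises(UndefinedStatisticError):
        diversity_percentage(1, 0, 5)


def test_diversity_monotonicity():
    """Diversity grows with F and shrinks with P and with S."""
    base = diversity_percentage(20, 100, 50).value
    assert diversity_percentage(21, 100, 50).value > base
    assert diversity_percentage(20, 101, 50).value < base
    assert diversity_percentage(20, 100, 51).value < base


def test_presence_matrix_basics():
    anns = [_ann("p1", "sp1", "CYPA"), _ann("p2", "sp2", "CYPA")]
    pm = build_presence_matrix(anns)
    assert pm.df.shape == (1, 2)
    assert (pm.df.to_numpy() == PRESENT).all()


def test_presence_matrix_binarises_multiple_members():
    anns = [_ann("p1", "sp1", "CYPA"), _ann("p2", "sp1", "CYPA")]
    pm = build_presence_matrix(anns)
    assert pm.presence_row_sums()["CYPA"] == 1
    assert set(np.unique(pm.df.to_numpy())) <= {PRESENT, ABSENT}


def test_presence_matrix_co_occurrence():
    anns = []
    for i in range(8):
        anns.append(_ann(f"a{i}", f"sp{i}", "CYP1103"))
        anns.append(_ann(f"b{i}", f"sp{i}", "CYP236"))
    anns.append(_ann("c0", "sp8", "CYP236"))
    pm = build_presence_matrix(anns)
    assert pm.co_occurrence("CYP1103", "CYP236") == 8


def test_presence_matrix_unknown_species_rejected():
    with pytest.raises(ConsistencyError):
        build_presence_matrix([_ann("p1", "spX", "CYPA")], _species(2))


def _pm(rows, labels):
    df = pd.DataFrame(rows, index=labels, columns=[f"c{i}" for i in range(len(rows[0]))])
    return PresenceMatrix(df)


def test_identical_rows_merge_first():
    pm = _pm([[3, 3, -3], [3, 3, -3], [-3, 3, 3]], ["a", "b", "c"])
    result = hierarchical_cluster(pm)
    first = result.row_linkage[0]
    assert {int(first[0]), int(first[1])} == {0, 1}
    assert first[2] == 0.0  # merged at distance zero


def test_antipodal_rows_do_not_merge_first():
    """Rows (3,3,-3) and (-3,-3,3) are maximally distant; a closer pair wins."""
    pm = _pm([[3, 3, -3], [-3, -3, 3], [3, -3, -3]], ["r1", "r2", "r3"])
    result = hierarchical_cluster(pm)
    first = result.row_linkage[0]
    # hand-computed Euclidean distances: d(r1,r3)=6, d(r2,r3)=sqrt(72), d(r1,r2)=sqrt(108)
    assert {int(first[0]), int(first[1])} == {0, 2}
    assert first[2] == pytest.approx(6.0)


def test_cluster_permutation_invariance():
    rng = np.random.default_rng(3)
    rows = rng.choice([-3, 3], size=(6, 10))
    labels = [f"f{i}" for i in range(6)]
    pm1 = _pm(rows.tolist(), labels)
    perm = rng.permutation(10)
    pm2 = PresenceMatrix(pm1.df.iloc[:, perm])
    z1 = hierarchical_cluster(pm1).row_linkage
    z2 = hierarchical_cluster(pm2).row_linkage
    assert np.allclose(z1, z2)  # same merge tree: distances are column-order free


def test_single_row_and_column_identity_ordering():
    pm = _pm([[3]], ["only"])
    result = hierarchical_cluster(pm)
    assert result.row_order == ["only"]
    assert result.column_order == ["c0"]
    assert result.row_linkage is None and result.column_linkage is None


def test_shared_sets_named_families():
    a = {"CYP102", "CYP107", "CYP109", "CYP152", "CYP236"}
    b = {"CYP102", "CYP107", "CYP109", "CYP152", "CYP51"}
    result = shared_sets(a, b)
    assert len(result.shared) == 4
    assert result.a_only == {"CYP236"}
    assert result.b_only == {"CYP51"}


def test_shared_sets_disjoint_and_identical():
    assert shared_sets({"x"}, {"y"}).counts == (1, 0, 1)
    result = shared_sets({"x", "y"}, {"x", "y"})
    assert result.a_only == frozenset() and result.b_only == frozenset()


@settings(max_examples=100, deadline=None)
@given(st.sets(st.integers(0, 30)), st.sets(st.integers(0, 30)))
def test_shared_sets_partition_identity(a, b):
    result = shared_sets(a, b)
    assert len(result.a_only) + len(result.shared) == len(a)
    assert len(result.b_only) + len(result.shared) == len(b)
    assert result.a_only | result.shared == frozenset(a)


def _table2_like_annotations():
    """98 P450s over 77 species in 21 families (the group's printed counts)."""
    anns = []
    for i in range(77):
        anns.append(_ann(f"p{i}", f"sp{i}", f"CYP{100 + i % 21}"))
    for i in range(21):
        anns.append(_ann(f"q{i}", f"sp{i}", f"CYP{100 + i}"))
    return anns


def test_build_group_summary_printed_displays():
    anns = _table2_like_annotations()
    summary = build_group_summary("grp", _species(334), anns, n_p450s_in_bgcs=8)
    assert (summary.n_p450s, summary.n_species_with_p450s, summary.n_families) == (98, 77, 21)
    assert summary.average_p450s.display == "1"
    assert summary.diversity_percentage.display == "0.28"
    assert summary.percent_p450s_in_bgcs.display == "8"
    frame = group_summary_frame([summary])
    assert frame.loc["P450 diversity percentage", "grp"] == "0.28"


def test_build_group_summary_errors():
    with pytest.raises(UndefinedStatisticError):
        build_group_summary("grp", _species(3), [])
    with pytest.raises(ConsistencyError):
        build_group_summary("grp", _species(1), [_ann("p", "sp9", "CYPA")])


def test_group_summary_on_cohort(cohort, pipeline):
    """Summary arithmetic agrees with the generator manifest."""
    manifest = cohort.manifest
    planted = manifest[manifest["kind"] == "p450"]
    summary = build_group_summary(
        cohort.spec.group_label,
        cohort.species,
        pipeline["annotations"],
        n_p450s_in_bgcs=len(pipeline["links"]),
    )
    assert summary.n_p450s == len(planted)
    assert summary.n_species_with_p450s == planted["species_code"].nunique()
    assert summary.n_p450s_in_bgcs == int(planted["in_bgc"].sum())
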