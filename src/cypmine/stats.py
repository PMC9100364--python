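"""Comparative group statistics, presence/absence matrices and clustering.

The three defined statistics are

* average number of P450s        ``P / S``
* P450 diversity percentage      ``100 * F / (P * S)``
* percentage of P450s in BGCs    ``100 * n_in_bgc / P``

with F = number of P450 families, P = number of P450s and S the species
denominator the caller chooses (typically species with P450s).  The
diversity denominator is the *product* P x S: family richness relative to
both gene count and carrier count.

Presence/absence matrices encode presence as 3 and absence as -3 (the
MeV heat-map convention) and are clustered agglomeratively on Euclidean
distances of those +/-3 vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .errors import ConsistencyError, UndefinedStatisticError
from .nomenclature import P450Annotation, family_census
from .records import SpeciesRecord
from .rounding import Stat, display

PRESENT = 3
ABSENT = -3


def average_p450s(P: int, S: int) -> Stat:
    """P450s per species. Display: nearest integer when >=1, else one decimal."""
    if S == 0:
        raise UndefinedStatisticError("species denominator is zero")
    raw = P / S
    return Stat(raw, display(raw, 0) if raw >= 1 else display(raw, 1))


def diversity_percentage(F: int, P: int, S: int) -> Stat:
    """100 * F / (P * S), displayed to two decimals."""
    if P == 0 or S == 0:
        raise UndefinedStatisticError("diversity denominator is zero")
    raw = 100.0 * F / (P * S)
    return Stat(raw, display(raw, 2))


@dataclass(frozen=True)
class PresenceMatrix:
    """Binary family-by-species matrix in the +/-3 export encoding."""

    df: pd.DataFrame  # rows: families (or subtypes); columns: species codes

    @property
    def row_labels(self) -> list[str]:
        return list(self.df.index)

    @property
    def column_labels(self) -> list[str]:
        return list(self.df.columns)

    def presence_row_sums(self) -> pd.Series:
        return (self.df == PRESENT).sum(axis=1)

    def co_occurrence(self, row_a: str, row_b: str) -> int:
        both = (self.df.loc[row_a] == PRESENT) & (self.df.loc[row_b] == PRESENT)
        return int(both.sum())

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index_label="family")


def build_presence_matrix(
    annotations: Sequence[P450Annotation],
    species: Sequence[SpeciesRecord] | None = None,
) -> PresenceMatrix:
    """One row per family, one column per species with >=1 P450.

    Multiple members of a family in one species still give a single
    presence (binarisation).  When a species table is given, annotation
    species codes must resolve in it.
    """
    if species is not None:
        known = {s.species_code for s in species}
        unknown = sorted({a.species_code for a in annotations} - known)
        if unknown:
            raise ConsistencyError(f"annotations reference unknown species {unknown}")
    families = sorted({a.family for a in annotations})
    codes = sorted({a.species_code for a in annotations})
    df = pd.DataFrame(ABSENT, index=families, columns=codes, dtype=int)
    for a in annotations:
        df.loc[a.family, a.species_code] = PRESENT
    return PresenceMatrix(df)


@dataclass(frozen=True)
class ClusterResult:
    row_order: list[str]
    column_order: list[str]
    row_linkage: np.ndarray | None  # scipy linkage matrix (merge tree)
    column_linkage: np.ndarray | None


def hierarchical_cluster(matrix: PresenceMatrix, method: str = "average") -> ClusterResult:
    """Agglomerative clustering of both axes on Euclidean distance.

    Returns leaf orders for rows and columns plus the scipy merge trees.
    A single row (or column) yields the identity ordering with no tree.
    """
    df = matrix.df

    def _axis(values: np.ndarray, labels: list[str]):
        if len(labels) < 2:
            return list(labels), None
        Z = linkage(pdist(values.astype(float), metric="euclidean"), method=method)
        order = [labels[i] for i in leaves_list(Z)]
        return order, Z

    row_order, row_Z = _axis(df.to_numpy(), list(df.index))
    col_order, col_Z = _axis(df.to_numpy().T, list(df.columns))
    return ClusterResult(row_order, col_order, row_Z, col_Z)


@dataclass(frozen=True)
class SharedSets:
    """Exact partition of two label sets into A-only / shared / B-only."""

    a_only: frozenset
    shared: frozenset
    b_only: frozenset

    @property
    def counts(self) -> tuple[int, int, int]:
        return len(self.a_only), len(self.shared), len(self.b_only)


def shared_sets(set_a, set_b) -> SharedSets:
    a, b = frozenset(set_a), frozenset(set_b)
    return SharedSets(a - b, a & b, b - a)


@dataclass(frozen=True)
class GroupSummary:
    """The per-group statistics bundle (one report column per group)."""

    group_label: str
    n_species_analyzed: int
    n_species_with_p450s: int  # S
    n_p450s: int  # P
    n_families: int  # F
    n_subfamilies: int
    dominant_family: str
    dominant_family_tied: bool
    average_p450s: Stat
    diversity_percentage: Stat
    n_p450s_in_bgcs: int
    percent_p450s_in_bgcs: Stat

    def __post_init__(self) -> None:
        if self.n_species_with_p450s > self.n_species_analyzed:
            raise ConsistencyError("S cannot exceed the number of species analysed")
        if self.n_families > self.n_p450s:
            raise ConsistencyError("family count cannot exceed P450 count")


def build_group_summary(
    group_label: str,
    species: Sequence[SpeciesRecord],
    annotations: Sequence[P450Annotation],
    n_p450s_in_bgcs: int = 0,
) -> GroupSummary:
    """Assemble the summary for one group from its annotation table.

    All annotation species codes must resolve in the group's species
    table; an empty annotation set is an undefined-statistic error (no
    species with P450s).
    """
    from .bgc import percentage_p450s_in_bgcs  # local import avoids a cycle

    codes = {s.species_code for s in species}
    unknown = sorted({a.species_code for a in annotations} - codes)
    if unknown:
        raise ConsistencyError(f"annotations reference unknown species {unknown}")
    if not annotations:
        raise UndefinedStatisticError(f"group {group_label!r} has no species with P450s")

    P = len(annotations)
    S = len({a.species_code for a in annotations})
    census = family_census(annotations)
    F = len(census.families)
    n_sub = len(census.subfamilies)
    top = census.families.iloc[0]
    tied = int((census.families["count"] == top["count"]).sum()) > 1
    return GroupSummary(
        group_label=group_label,
        n_species_analyzed=len(species),
        n_species_with_p450s=S,
        n_p450s=P,
        n_families=F,
        n_subfamilies=n_sub,
        dominant_family=str(top["family"]),
        dominant_family_tied=tied,
        average_p450s=average_p450s(P, S),
        diversity_percentage=diversity_percentage(F, P, S),
        n_p450s_in_bgcs=n_p450s_in_bgcs,
        percent_p450s_in_bgcs=percentage_p450s_in_bgcs(n_p450s_in_bgcs, P),
    )


def group_summary_frame(summaries: Sequence[GroupSummary]) -> pd.DataFrame:
    """Table-shaped report: one column per group, raw values kept alongside."""
    rows = [
        "Total no. of species analyzed",
        "No. of species with P450s",
        "No. of P450s",
        "No. of families",
        "No. of subfamilies",
        "Dominant P450 family",
        "Average no. of P450s",
        "Average no. of P450s (raw)",
        "P450 diversity percentage",
        "P450 diversity percentage (raw)",
        "No. of P450s part of BGCs",
        "Percentage of P450s part of BGCs",
        "Percentage of P450s part of BGCs (raw)",
    ]
    data = {}
    for s in summaries:
        data[s.group_label] = [
            s.n_species_analyzed,
            s.n_species_with_p450s,
            s.n_p450s,
            s.n_families,
            s.n_subfamilies,
            s.dominant_family + (" (tied)" if s.dominant_family_tied else ""),
            s.average_p450s.display,
            s.average_p450s.value,
            s.diversity_percentage.display,
            s.diversity_percentage.value,
            s.n_p450s_in_bgcs,
            s.percent_p450s_in_bgcs.display,
            s.percent_p450s_in_bgcs.value,
        ]
    return pd.DataFrame(data, index=rows)
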