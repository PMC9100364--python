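"""Ferredoxin detection, Fe-S cluster typing and spacing-signature subtyping.

Ferredoxins are small (<= ~200 aa) iron-sulfur electron carriers.  The
cofactor architecture is inferred from the cysteine binding motifs:

* plant-type 2Fe-2S      ``C-x4-C-x2-C-x(20-40)-C``
* bacterial 4Fe-4S       ``C-x2-C-x2-C-x3-C-P``
* bacterial 3Fe-4S       ``C-x2-C-x(5-9)-C-P`` (a 4Fe-4S motif lacking its
  second cysteine)

One motif alone gives 2Fe-2S, 3Fe-4S or 4Fe-4S; two bacterial 4Fe-4S
motifs give the twin cluster 2[4Fe-4S], promoted to the Alvin type
2[4Fe-4S]Alv when the insertion between the two motifs exceeds the Alvin
gap threshold (Alvin-type ferredoxins carry a characteristic loop
extension); a 3Fe-4S motif together with a 4Fe-4S motif gives 7Fe-8S.
The motif gap bounds are configurable decisions, not literature constants.

Within a cluster type, ferredoxins are subtyped by the exact spacing
signature between the motif cysteines (e.g. ``C-x2-C-x2-C-x3-C``); subtype
numbers come from an extensible registry so published numbering can be
continued via a seed file.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import (
    AmbiguousClusterTypeError,
    NotAFerredoxinError,
    UndefinedStatisticError,
    ValidationError,
)
from .records import ProteinRecord, SpeciesRecord
from .rounding import Stat, display

CLUSTER_TYPES = ["2Fe-2S", "3Fe-4S", "4Fe-4S", "2[4Fe-4S]", "2[4Fe-4S]Alv", "7Fe-8S"]


@dataclass(frozen=True)
class FdxConfig:
    """Motif gap bounds, size cutoff and the Alvin promotion threshold."""

    max_length: int = 200  # ferredoxins are small; screens out large Fe-S enzymes
    alvin_gap_threshold: int = 20  # residues between the twin 4Fe-4S motifs
    plant_gap3_min: int = 20
    plant_gap3_max: int = 40
    bact3_gap2_min: int = 5
    bact3_gap2_max: int = 9


@dataclass(frozen=True)
class FeSMotifMatch:
    motif_kind: str  # plant_2Fe2S | bact_4Fe4S | bact_3Fe4S
    cys_positions: tuple[int, ...]  # 0-based, strictly increasing

    def __post_init__(self) -> None:
        for i, j in zip(self.cys_positions, self.cys_positions[1:]):
            if j <= i:
                raise ValidationError("cysteine positions must be strictly increasing")


@dataclass(frozen=True)
class FerredoxinAnnotation:
    protein_id: str
    species_code: str
    cluster_type: str
    signature: str
    subtype: int


def spacing_signature(cys_positions: Sequence[int]) -> str:
    """``C-x<g1>-C-x<g2>-...`` with gaps g_i = pos[i+1] - pos[i] - 1."""
    if len(cys_positions) < 2:
        raise ValidationError("need at least two cysteine positions")
    parts = ["C"]
    for i, j in zip(cys_positions, cys_positions[1:]):
        gap = j - i - 1
        if gap < 0:
            raise ValidationError("cysteine positions must be strictly increasing")
        parts.append(f"x{gap}")
        parts.append("C")
    return "-".join(parts)


def parse_signature(signature: str) -> list[int]:
    """Inverse of :func:`spacing_signature`: the list of gaps."""
    m = re.fullmatch(r"C(?:-x(\d+)-C)+", signature)
    if not m:
        raise ValidationError(f"malformed spacing signature {signature!r}")
    return [int(g) for g in re.findall(r"x(\d+)", signature)]


def _patterns(config: FdxConfig) -> list[tuple[str, re.Pattern, str]]:
    # order is the match priority at each scan position; the 4Fe-4S pattern
    # must come first because its tail also satisfies the 3Fe-4S pattern
    return [
        ("bact_4Fe4S", re.compile(r"C.{2}C.{2}C.{3}CP"), "CP"),
        (
            "bact_3Fe4S",
            re.compile(rf"C.{{2}}C.{{{config.bact3_gap2_min},{config.bact3_gap2_max}}}CP"),
            "CP",
        ),
        (
            "plant_2Fe2S",
            re.compile(rf"C.{{4}}C.{{2}}C.{{{config.plant_gap3_min},{config.plant_gap3_max}}}C"),
            "C",
        ),
    ]


def detect_fes_motifs(sequence: str, config: FdxConfig | None = None) -> list[FeSMotifMatch]:
    """Left-to-right greedy, non-overlapping scan for Fe-S binding motifs."""
    config = config or FdxConfig()
    patterns = _patterns(config)
    matches: list[FeSMotifMatch] = []
    pos = 0
    n = len(sequence)
    while pos < n:
        hit = None
        for kind, pattern, tail in patterns:
            m = pattern.match(sequence, pos)
            if m:
                span = m.group(0)
                # cysteines: every C that belongs to the motif scaffold; gaps
                # are wildcards, so recover positions from the fixed offsets
                if kind == "bact_4Fe4S":
                    rel = [0, 3, 6, len(span) - 2]
                elif kind == "bact_3Fe4S":
                    rel = [0, 3, len(span) - 2]
                else:
                    rel = [0, 5, 8, len(span) - 1]
                hit = FeSMotifMatch(kind, tuple(m.start() + r for r in rel))
                pos = m.end()
                break
        if hit is not None:
            matches.append(hit)
        else:
            pos += 1
    return matches


def assign_cluster_type(
    matches: Sequence[FeSMotifMatch], config: FdxConfig | None = None
) -> str:
    """Map a motif combination to a cluster type.

    Raises :class:`NotAFerredoxinError` for zero matches and
    :class:`AmbiguousClusterTypeError` for combinations outside the
    mapping (reported by callers, never silently dropped).
    """
    config = config or FdxConfig()
    if not matches:
        raise NotAFerredoxinError("no Fe-S binding motif found")
    kinds = sorted(m.motif_kind for m in matches)
    if kinds == ["plant_2Fe2S"]:
        return "2Fe-2S"
    if kinds == ["bact_3Fe4S"]:
        return "3Fe-4S"
    if kinds == ["bact_4Fe4S"]:
        return "4Fe-4S"
    if kinds == ["bact_4Fe4S", "bact_4Fe4S"]:
        first, second = sorted(matches, key=lambda m: m.cys_positions[0])
        gap = second.cys_positions[0] - first.cys_positions[-1] - 1
        if gap > config.alvin_gap_threshold:
            return "2[4Fe-4S]Alv"
        return "2[4Fe-4S]"
    if kinds == ["bact_3Fe4S", "bact_4Fe4S"]:
        return "7Fe-8S"
    raise AmbiguousClusterTypeError(f"unrecognised motif combination {kinds}")


class SubtypeRegistry:
    """Signature -> subtype number, one namespace per cluster type.

    Numbers are stable: once a signature is registered its number never
    changes, and new signatures receive the next free number of their
    cluster type.  A seed TSV (columns signature, cluster_type, subtype)
    lets published numbering be continued explicitly.
    """

    def __init__(self) -> None:
        self._entries: dict[str, dict[str, int]] = {}
        self._next_free: dict[str, int] = {}

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SubtypeRegistry":
        reg = cls()
        df = pd.read_csv(path, sep="\t", dtype={"signature": str, "cluster_type": str})
        for col in ("signature", "cluster_type", "subtype"):
            if col not in df.columns:
                raise ValidationError(f"{path}: registry seed missing column {col!r}")
        for row in df.itertuples():
            reg.seed(row.signature, row.cluster_type, int(row.subtype))
        return reg

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            (sig, ctype, num)
            for ctype, entries in sorted(self._entries.items())
            for sig, num in sorted(entries.items(), key=lambda kv: kv[1])
        ]
        pd.DataFrame(rows, columns=["signature", "cluster_type", "subtype"]).to_csv(
            path, sep="\t", index=False
        )

    def seed(self, signature: str, cluster_type: str, subtype: int) -> None:
        entries = self._entries.setdefault(cluster_type, {})
        if signature in entries and entries[signature] != subtype:
            raise ValidationError(
                f"signature {signature!r} already registered as "
                f"{entries[signature]} (got {subtype})"
            )
        if subtype in entries.values() and entries.get(signature) != subtype:
            raise ValidationError(
                f"subtype number {subtype} already used in {cluster_type!r}"
            )
        entries[signature] = subtype
        nf = self._next_free.get(cluster_type, 1)
        self._next_free[cluster_type] = max(nf, subtype + 1)

    def assign(self, signature: str, cluster_type: str) -> int:
        """Existing signature -> its number; new -> next free (mutates)."""
        entries = self._entries.setdefault(cluster_type, {})
        if signature in entries:
            return entries[signature]
        num = self._next_free.get(cluster_type, 1)
        entries[signature] = num
        self._next_free[cluster_type] = num + 1
        return num

    def get(self, signature: str, cluster_type: str) -> int | None:
        return self._entries.get(cluster_type, {}).get(signature)

    def next_free(self, cluster_type: str) -> int:
        return self._next_free.get(cluster_type, 1)


def annotate_ferredoxins(
    proteins: Iterable[ProteinRecord],
    registry: SubtypeRegistry | None = None,
    config: FdxConfig | None = None,
) -> tuple[list[FerredoxinAnnotation], list[tuple[ProteinRecord, str]]]:
    """Screen a proteome for ferredoxins and annotate them.

    Returns (annotations, ambiguous) where ``ambiguous`` carries proteins
    whose motif combination could not be typed, with the reason.
    Proteins longer than ``config.max_length`` or without motifs are not
    ferredoxin candidates and are skipped.
    """
    config = config or FdxConfig()
    registry = registry if registry is not None else SubtypeRegistry()
    annotations: list[FerredoxinAnnotation] = []
    ambiguous: list[tuple[ProteinRecord, str]] = []
    for protein in proteins:
        if protein.length > config.max_length:
            continue
        matches = detect_fes_motifs(protein.sequence, config)
        if not matches:
            continue
        try:
            ctype = assign_cluster_type(matches, config)
        except AmbiguousClusterTypeError as exc:
            ambiguous.append((protein, str(exc)))
            continue
        all_cys = sorted(p for m in matches for p in m.cys_positions)
        signature = spacing_signature(all_cys)
        subtype = registry.assign(signature, ctype)
        annotations.append(
            FerredoxinAnnotation(
                protein.protein_id, protein.species_code, ctype, signature, subtype
            )
        )
    return annotations, ambiguous


@dataclass(frozen=True)
class FerredoxinCensus:
    per_type: dict[str, int]
    per_subtype: pd.DataFrame  # columns: cluster_type, subtype, signature, count
    total: int
    n_species: int
    average: Stat


def ferredoxin_group_census(
    annotations: Sequence[FerredoxinAnnotation], species: Sequence[SpeciesRecord]
) -> FerredoxinCensus:
    """Per-cluster-type and per-subtype counts plus the per-species average.

    The average is total ferredoxins / number of species, displayed to one
    decimal (nearest).
    """
    n_species = len(species)
    if n_species == 0:
        raise UndefinedStatisticError("no species analysed")
    per_type = {t: 0 for t in CLUSTER_TYPES}
    for a in annotations:
        per_type[a.cluster_type] = per_type.get(a.cluster_type, 0) + 1
    total = len(annotations)
    df = pd.DataFrame(
        [(a.cluster_type, a.subtype, a.signature) for a in annotations],
        columns=["cluster_type", "subtype", "signature"],
    )
    if total:
        per_subtype = (
            df.groupby(["cluster_type", "subtype", "signature"])
            .size()
            .reset_index(name="count")
            .sort_values(["cluster_type", "subtype"])
            .reset_index(drop=True)
        )
    else:
        per_subtype = pd.DataFrame(columns=["cluster_type", "subtype", "signature", "count"])
    avg = total / n_species
    return FerredoxinCensus(per_type, per_subtype, total, n_species, Stat(avg, display(avg, 1)))


def ferredoxins_to_frame(annotations: Sequence[FerredoxinAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (a.protein_id, a.species_code, a.cluster_type, a.signature, a.subtype)
            for a in annotations
        ],
        columns=["protein_id", "species_code", "cluster_type", "signature", "subtype"],
    )
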