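"""Family/subfamily assignment by percent identity to a labelled reference set.

The nomenclature rule: a query sharing >55% identity with a reference
belongs to the same subfamily; >40% to the same family; at or below 40% it
founds a new family.  Both inequalities are strict, so identity exactly
40.0 is a new family and exactly 55.0 a new subfamily.

A repository cannot mint official committee names, so new families receive
the placeholders ``CYPNEW1, CYPNEW2, ...`` (in query input order); new
subfamilies within a known family take the next unused letter after the
family's existing subfamilies.  By default, novel queries that share >40%
mutual identity are merged into one new family (matching how several
members can end up in a single newly named family).
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .align import global_identity
from .errors import ConfigurationError, ValidationError
from .mining import P450Candidate
from .records import ReferenceP450
from .rounding import round_half_away


@dataclass(frozen=True)
class NomenclatureConfig:
    family_threshold: float = 40.0
    subfamily_threshold: float = 55.0
    gap_open: float = 10.0
    gap_extend: float = 1.0
    substitution_matrix_name: str = "BLOSUM62"
    merge_novel: bool = True  # merge mutually >40%-identical novel queries

    def __post_init__(self) -> None:
        if not (0 < self.family_threshold < self.subfamily_threshold < 100):
            raise ConfigurationError(
                "thresholds must satisfy 0 < family < subfamily < 100"
            )


@dataclass(frozen=True)
class P450Annotation:
    protein_id: str
    species_code: str
    family: str
    subfamily: str
    best_ref_id: str | None
    best_identity: float
    novelty: str  # known_subfamily | new_subfamily | new_family


def percent_identity(a: str, b: str, config: NomenclatureConfig | None = None) -> float:
    """Percent identity under the package's global-alignment definition."""
    config = config or NomenclatureConfig()
    return global_identity(
        a,
        b,
        matrix_name=config.substitution_matrix_name,
        gap_open=config.gap_open,
        gap_extend=config.gap_extend,
    )


def _novelty(identity: float, config: NomenclatureConfig) -> str:
    if identity > config.subfamily_threshold:
        return "known_subfamily"
    if identity > config.family_threshold:
        return "new_subfamily"
    return "new_family"


def _letter_series():
    for n in itertools.count(1):
        for combo in itertools.product(string.ascii_uppercase, repeat=n):
            yield "".join(combo)


def _next_letter(used: set[str]) -> str:
    for letter in _letter_series():
        if letter not in used:
            return letter
    raise AssertionError("unreachable")


class _Namer:
    """Naming state threaded through a batch of assignments."""

    def __init__(self, references: Sequence[ReferenceP450]):
        self.known_subfams: dict[str, set[str]] = {}
        for ref in references:
            self.known_subfams.setdefault(ref.family, set()).add(ref.subfamily)
        # family -> list of (subfamily letter, exemplar sequence) for novel subfamilies
        self.novel_subfams: dict[str, list[tuple[str, str]]] = {}
        # list of dicts for minted new families
        self.new_families: list[dict] = []
        self._next_new = 1

    def new_subfamily(self, family: str, seq: str, config: NomenclatureConfig) -> str:
        """Letter for a novel subfamily inside a known family.

        Novel queries sharing >subfamily_threshold identity with an earlier
        novel exemplar of the same family reuse its letter.
        """
        for letter, exemplar in self.novel_subfams.get(family, []):
            if percent_identity(seq, exemplar, config) > config.subfamily_threshold:
                return letter
        used = set(self.known_subfams.get(family, set()))
        used |= {letter for letter, _ in self.novel_subfams.get(family, [])}
        letter = _next_letter(used)
        self.novel_subfams.setdefault(family, []).append((letter, seq))
        return letter

    def new_family(self, seq: str, config: NomenclatureConfig) -> tuple[str, str]:
        """(family name, subfamily letter) for a novel-family query."""
        if config.merge_novel:
            for fam in self.new_families:
                if percent_identity(seq, fam["exemplar"], config) > config.family_threshold:
                    for letter, exemplar in fam["subfams"]:
                        if (
                            percent_identity(seq, exemplar, config)
                            > config.subfamily_threshold
                        ):
                            return fam["name"], letter
                    letter = _next_letter({l for l, _ in fam["subfams"]})
                    fam["subfams"].append((letter, seq))
                    return fam["name"], letter
        name = f"CYPNEW{self._next_new}"
        self._next_new += 1
        self.new_families.append({"name": name, "exemplar": seq, "subfams": [("A", seq)]})
        return name, "A"


def assign(
    candidate: P450Candidate,
    references: Sequence[ReferenceP450],
    config: NomenclatureConfig | None = None,
    namer: _Namer | None = None,
) -> P450Annotation:
    """Assign family/subfamily to one complete candidate.

    The best reference is the identity argmax; ties go to the first
    reference in file order.  For batch runs use :func:`annotate`, which
    threads consistent new-family naming through all queries.
    """
    config = config or NomenclatureConfig()
    if not references:
        raise ConfigurationError("reference set is empty")
    if candidate.status != "complete":
        raise ValidationError(
            f"candidate {candidate.protein_id!r} has status {candidate.status!r}; "
            "only complete candidates are classified"
        )
    namer = namer or _Namer(references)
    seq = candidate.protein.sequence
    best_ref = None
    best_identity = -1.0
    for ref in references:
        ident = percent_identity(seq, ref.sequence, config)
        if ident > best_identity:
            best_identity = ident
            best_ref = ref
    novelty = _novelty(best_identity, config)
    if novelty == "known_subfamily":
        family, subfamily = best_ref.family, best_ref.subfamily
    elif novelty == "new_subfamily":
        family = best_ref.family
        subfamily = namer.new_subfamily(family, seq, config)
    else:
        family, subfamily = namer.new_family(seq, config)
    return P450Annotation(
        candidate.protein_id,
        candidate.species_code,
        family,
        subfamily,
        best_ref.ref_id,
        best_identity,
        novelty,
    )


def annotate(
    candidates: Iterable[P450Candidate],
    references: Sequence[ReferenceP450],
    config: NomenclatureConfig | None = None,
) -> list[P450Annotation]:
    """Classify all complete candidates with consistent novel naming."""
    config = config or NomenclatureConfig()
    if not references:
        raise ConfigurationError("reference set is empty")
    namer = _Namer(references)
    return [
        assign(c, references, config, namer)
        for c in candidates
        if c.status == "complete"
    ]


@dataclass(frozen=True)
class FamilyCensus:
    """Family-level counts/percentages plus per-subfamily counts."""

    families: pd.DataFrame  # columns: family, count, percent
    subfamilies: pd.DataFrame  # columns: family, subfamily, count
    total: int


def family_census(annotations: Sequence[P450Annotation]) -> FamilyCensus:
    """Tally families and subfamilies.

    Percentages are of the total P450 count, rounded to the nearest
    integer (ties away from zero); families are sorted by count
    descending, then name.  Counts conserve mass.
    """
    total = len(annotations)
    rows = [(a.family, a.subfamily) for a in annotations]
    df = pd.DataFrame(rows, columns=["family", "subfamily"])
    if total == 0:
        return FamilyCensus(
            pd.DataFrame(columns=["family", "count", "percent"]),
            pd.DataFrame(columns=["family", "subfamily", "count"]),
            0,
        )
    fam = (
        df.groupby("family").size().reset_index(name="count")
        .sort_values(["count", "family"], ascending=[False, True])
        .reset_index(drop=True)
    )
    fam["percent"] = [
        int(round_half_away(100.0 * c / total)) for c in fam["count"]
    ]
    sub = (
        df.groupby(["family", "subfamily"]).size().reset_index(name="count")
        .sort_values(["family", "subfamily"])
        .reset_index(drop=True)
    )
    return FamilyCensus(fam, sub, total)


def annotations_to_frame(annotations: Sequence[P450Annotation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                a.protein_id,
                a.species_code,
                a.family,
                a.subfamily,
                a.best_identity,
                a.best_ref_id,
                a.novelty,
            )
            for a in annotations
        ],
        columns=[
            "protein_id",
            "species_code",
            "family",
            "subfamily",
            "best_identity",
            "best_ref_id",
            "novelty",
        ],
    )
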