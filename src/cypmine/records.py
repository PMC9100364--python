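"""Core record types shared by every mining stage.

A :class:`ProteinRecord` is the atom all miners consume: one amino-acid
sequence tied to the species it came from. :class:`SpeciesRecord` mirrors a
row of the species metadata table (code, name, genus, group label, genome
id), and :class:`ReferenceP450` is one labelled entry of the P450 reference
set used for nomenclature assignment.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import ValidationError

#: The 20 standard amino acids plus X (unknown residue).
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")

_FAMILY_RE = re.compile(r"^CYP(NEW)?\d+$")
_SUBFAMILY_RE = re.compile(r"^[A-Z]+$")


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with species linkage.

    The sequence must be uppercase, whitespace free, and drawn from the
    20 standard residues plus X.  ``length`` is always the residue count.
    """

    protein_id: str
    species_code: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValidationError("protein_id must be non-empty")
        if not self.sequence:
            raise ValidationError(
                f"protein {self.protein_id!r}: sequence must be non-empty"
            )
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise ValidationError(
                f"protein {self.protein_id!r}: invalid residue(s) "
                f"{''.join(sorted(bad))!r} (allowed: 20 standard + X)"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SpeciesRecord:
    """One row of the species metadata table."""

    species_code: str
    species_name: str
    genus: str
    group_label: str
    genome_id: str

    def __post_init__(self) -> None:
        if not self.species_code:
            raise ValidationError("species_code must be non-empty")
        if not self.group_label:
            raise ValidationError(
                f"species {self.species_code!r}: group_label must be non-empty"
            )


@dataclass(frozen=True)
class ReferenceP450:
    """A labelled reference P450: family ``CYP<digits>``, subfamily letters."""

    ref_id: str
    family: str
    subfamily: str
    sequence: str

    def __post_init__(self) -> None:
        if not _FAMILY_RE.match(self.family):
            raise ValidationError(
                f"reference {self.ref_id!r}: family {self.family!r} does not "
                "match CYP<digits>"
            )
        if not _SUBFAMILY_RE.match(self.subfamily):
            raise ValidationError(
                f"reference {self.ref_id!r}: subfamily {self.subfamily!r} must "
                "be one or more uppercase letters"
            )
        if not self.sequence:
            raise ValidationError(f"reference {self.ref_id!r}: empty sequence")
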