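"""Readers and writers for proteome FASTA, species tables and reference sets.

Proteomes are plain FASTA, one file per species; the species metadata table
is a TSV with a header row; the P450 reference set is FASTA with the
family/subfamily labels encoded in the header as ``>ref_id|CYPnnn|SUBFAM``
so the whole reference set travels as a single portable file.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .errors import FastaParseError, SchemaError
from .records import ProteinRecord, ReferenceP450, SpeciesRecord

SPECIES_COLUMNS = ["species_code", "species_name", "genus", "group_label", "genome_id"]


def read_fasta(path: str | Path, species_code: str | None = None) -> list[ProteinRecord]:
    """Read a proteome FASTA file into :class:`ProteinRecord` objects.

    Sequences are uppercased; a trailing ``*`` stop symbol is stripped; an
    internal ``*`` (frameshift/pseudogene artefact) is an error.  When
    ``species_code`` is not given, the file stem is used.

    Raises
    ------
    FastaParseError
        On an empty/missing header, an empty sequence, or residues outside
        the 20 standard letters + X, naming the offending entry.
    """
    path = Path(path)
    code = species_code if species_code is not None else path.stem
    records: list[ProteinRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        if not entry.id:
            raise FastaParseError(f"{path}: entry with empty header")
        seq = str(entry.seq).upper().rstrip("*")
        if not seq:
            raise FastaParseError(f"{path}: entry {entry.id!r} has an empty sequence")
        if "*" in seq:
            raise FastaParseError(
                f"{path}: entry {entry.id!r} has an internal stop symbol '*'"
            )
        try:
            records.append(ProteinRecord(entry.id, code, seq))
        except Exception as exc:  # re-raise with the file context
            raise FastaParseError(f"{path}: entry {entry.id!r}: {exc}") from exc
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA (headers are the protein ids)."""
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.protein_id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_species_table(path: str | Path) -> list[SpeciesRecord]:
    """Read the species metadata TSV.

    Requires the five canonical columns; duplicate species codes are a
    uniqueness error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in SPECIES_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    dupes = df["species_code"][df["species_code"].duplicated()].tolist()
    if dupes:
        raise SchemaError(f"{path}: duplicate species_code(s) {sorted(set(dupes))}")
    return [
        SpeciesRecord(
            row.species_code, row.species_name, row.genus, row.group_label, row.genome_id
        )
        for row in df.itertuples()
    ]


def write_species_table(species: Sequence[SpeciesRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (s.species_code, s.species_name, s.genus, s.group_label, s.genome_id)
            for s in species
        ],
        columns=SPECIES_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_reference_set(path: str | Path) -> list[ReferenceP450]:
    """Read a labelled P450 reference FASTA (``>ref_id|CYPnnn|SUBFAM``).

    Dots inside the subfamily label are dropped (printed labels such as
    ``A.P.`` denote the subfamily ``AP``).
    """
    path = Path(path)
    refs: list[ReferenceP450] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        parts = entry.id.split("|")
        if len(parts) != 3:
            raise FastaParseError(
                f"{path}: header {entry.id!r} is not of the form "
                "'ref_id|CYPnnn|SUBFAM'"
            )
        ref_id, family, subfamily = parts
        subfamily = subfamily.replace(".", "").upper()
        seq = str(entry.seq).upper().rstrip("*")
        if not seq:
            raise FastaParseError(f"{path}: reference {ref_id!r} has an empty sequence")
        try:
            refs.append(ReferenceP450(ref_id, family, subfamily, seq))
        except Exception as exc:
            raise FastaParseError(f"{path}: reference {ref_id!r}: {exc}") from exc
    return refs


def write_reference_set(refs: Sequence[ReferenceP450], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for ref in refs:
            fh.write(f">{ref.ref_id}|{ref.family}|{ref.subfamily}\n")
            for i in range(0, len(ref.sequence), width):
                fh.write(ref.sequence[i : i + width] + "\n")


def check_species_linkage(
    proteins: Iterable[ProteinRecord], species: Sequence[SpeciesRecord]
) -> None:
    """Every protein's species_code must resolve to exactly one species row."""
    codes = {s.species_code for s in species}
    unknown = sorted({p.species_code for p in proteins} - codes)
    if unknown:
        raise SchemaError(f"protein records reference unknown species code(s) {unknown}")
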