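"""P450 candidate mining by diagnostic motifs.

Two motifs are diagnostic of the P450 fold: the K-helix salt bridge EXXR
(realised as the regex ``E..R``) and the heme-binding region around the
absolutely conserved cysteine, labelled CXG here and realised as the
ten-residue consensus ``F..G...C.G`` (reported with its start at the F).
A protein carrying both motifs at adequate length is a complete P450; a
protein carrying only one motif, or both but short, is a fragment and is
flagged rather than silently dropped.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import UndefinedStatisticError
from .records import ProteinRecord, SpeciesRecord
from .rounding import round_half_away

EXXR_PATTERN = r"E..R"
CXG_PATTERN = r"F..G...C.G"


@dataclass(frozen=True)
class MiningConfig:
    """Knobs of the motif screen.

    ``min_length`` (residues) separates complete P450s from fragments;
    complete bacterial P450s run ~400 aa, so 300 sits below essentially all
    of them and above most fragments.  ``require_cxg_after_exxr`` enforces
    the fold topology (heme-binding motif C-terminal of the K-helix).
    """

    min_length: int = 300
    require_cxg_after_exxr: bool = True
    exxr_pattern: str = EXXR_PATTERN
    cxg_pattern: str = CXG_PATTERN


@dataclass(frozen=True)
class MotifHit:
    motif_name: str  # "EXXR" or "CXG"
    start: int  # 0-based residue index
    matched_text: str


@dataclass(frozen=True)
class P450Candidate:
    protein: ProteinRecord
    exxr: MotifHit | None
    cxg: MotifHit | None
    status: str  # complete | fragment | rejected

    @property
    def protein_id(self) -> str:
        return self.protein.protein_id

    @property
    def species_code(self) -> str:
        return self.protein.species_code


def find_motifs(sequence: str, config: MiningConfig | None = None) -> list[MotifHit]:
    """All (possibly overlapping) EXXR and CXG matches, in position order."""
    config = config or MiningConfig()
    hits: list[MotifHit] = []
    for name, pattern in (("EXXR", config.exxr_pattern), ("CXG", config.cxg_pattern)):
        for m in re.finditer(f"(?=({pattern}))", sequence):
            hits.append(MotifHit(name, m.start(), m.group(1)))
    hits.sort(key=lambda h: (h.start, h.motif_name != "EXXR"))
    return hits


def _classify(
    protein: ProteinRecord, hits: Sequence[MotifHit], config: MiningConfig
) -> P450Candidate:
    exxr_hits = [h for h in hits if h.motif_name == "EXXR"]
    cxg_hits = [h for h in hits if h.motif_name == "CXG"]
    exxr = exxr_hits[0] if exxr_hits else None
    cxg = None
    if cxg_hits:
        after = [h for h in cxg_hits if exxr is not None and h.start > exxr.start]
        cxg = after[0] if after else cxg_hits[0]

    if exxr is not None and cxg is not None:
        topology_ok = (not config.require_cxg_after_exxr) or any(
            c.start > e.start for e in exxr_hits for c in cxg_hits
        )
        if protein.length >= config.min_length and topology_ok:
            status = "complete"
        elif protein.length < config.min_length:
            status = "fragment"
        else:
            # both motifs, adequate length, but heme motif precedes the
            # K-helix everywhere: not a plausible P450 fold
            status = "rejected"
    else:
        status = "fragment"
    return P450Candidate(protein, exxr, cxg, status)


def screen_proteome(
    proteins: Iterable[ProteinRecord], config: MiningConfig | None = None
) -> list[P450Candidate]:
    """Screen a proteome; proteins with zero motif hits are excluded.

    Fragments are flagged (status ``fragment``) and kept in the output so
    they can be counted, but downstream classification only consumes
    ``complete`` candidates.
    """
    config = config or MiningConfig()
    out: list[P450Candidate] = []
    for protein in proteins:
        hits = find_motifs(protein.sequence, config)
        if not hits:
            continue
        out.append(_classify(protein, hits, config))
    return out


def count_species_with_p450s(
    candidates: Iterable[P450Candidate], species: Sequence[SpeciesRecord]
) -> tuple[int, int, int]:
    """(n species with >=1 complete P450, n species total, percent).

    Percent is rounded to the nearest integer (ties away from zero).
    """
    n_total = len(species)
    if n_total == 0:
        raise UndefinedStatisticError("no species analysed")
    with_p450 = {c.species_code for c in candidates if c.status == "complete"}
    known = {s.species_code for s in species}
    n_with = len(with_p450 & known)
    percent = int(round_half_away(100.0 * n_with / n_total))
    return n_with, n_total, percent
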