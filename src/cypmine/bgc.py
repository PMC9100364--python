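"""Secondary-metabolite BGC region parsing, tallying and P450 mapping.

Regions arrive in a light dialect emulating anti-SMASH cluster exports:
either JSON (``{"regions": [{species_code, cluster_id, cluster_type,
genes: [{gene_id, start, end, strand, protein}]}]}``) or a flat TSV with
one row per gene.  Coordinates are 1-based inclusive (GenBank convention).
Cluster type labels follow the anti-SMASH vocabulary; hybrid labels such
as ``Nrps-Transatpks-Otherks`` stay verbatim single categories, and
unknown labels pass through with a warning.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import UndefinedStatisticError, ValidationError
from .mining import MiningConfig, screen_proteome
from .nomenclature import NomenclatureConfig, annotate
from .records import ProteinRecord, ReferenceP450, SpeciesRecord
from .rounding import Stat, display

logger = logging.getLogger(__name__)

#: Core anti-SMASH cluster-type vocabulary (not exhaustive; unknown labels warn).
KNOWN_CLUSTER_TYPES = {
    "terpene",
    "T1PKS",
    "T2PKS",
    "T3PKS",
    "NRPS",
    "NRPS-like",
    "lanthipeptide",
    "arylpolyene",
    "bacteriocin",
    "siderophore",
    "resorcinol",
    "Transatpks",
    "Transatpks-Nrps",
    "Nrps-Transatpks-Otherks",
    "other",
}

GENE_COLUMNS = ["species_code", "cluster_id", "cluster_type", "gene_id", "start", "end", "strand", "protein"]


@dataclass(frozen=True)
class ClusterGene:
    gene_id: str
    start: int  # 1-based inclusive
    end: int
    strand: str  # "+" or "-"
    protein: str  # amino-acid sequence of the gene product


@dataclass(frozen=True)
class ClusterRegion:
    species_code: str
    cluster_id: str
    cluster_type: str
    genes: tuple[ClusterGene, ...]
    start: int | None = None  # optional region bounds
    end: int | None = None


@dataclass(frozen=True)
class ClusterP450Link:
    """One P450 found inside one cluster region (Table-4 shape)."""

    species_code: str
    family: str
    cluster_type: str
    cluster_id: str = ""
    gene_id: str = ""


def _validate_region(region: ClusterRegion) -> None:
    for gene in region.genes:
        if gene.end < gene.start:
            raise ValidationError(
                f"region {region.cluster_id!r}: gene {gene.gene_id!r} has end < start"
            )
        if gene.strand not in {"+", "-"}:
            raise ValidationError(
                f"region {region.cluster_id!r}: gene {gene.gene_id!r} has strand "
                f"{gene.strand!r}"
            )
        if region.start is not None and region.end is not None:
            if gene.start < region.start or gene.end > region.end:
                raise ValidationError(
                    f"region {region.cluster_id!r}: gene {gene.gene_id!r} lies "
                    "outside the region bounds"
                )
    if not region.genes:
        logger.info("region %s has zero genes", region.cluster_id)
    if region.cluster_type not in KNOWN_CLUSTER_TYPES:
        logger.warning(
            "region %s: cluster type %r not in the known anti-SMASH vocabulary; "
            "kept verbatim",
            region.cluster_id,
            region.cluster_type,
        )


def read_clusters(path: str | Path) -> list[ClusterRegion]:
    """Read regions from the JSON or TSV dialect (validated)."""
    path = Path(path)
    text_head = path.open().read(1).strip()
    if path.suffix.lower() == ".json" or text_head in "{[":
        payload = json.loads(path.read_text())
        raw_regions = payload["regions"] if isinstance(payload, dict) else payload
        regions = []
        for raw in raw_regions:
            genes = tuple(
                ClusterGene(g["gene_id"], int(g["start"]), int(g["end"]), g["strand"], g["protein"])
                for g in raw.get("genes", [])
            )
            regions.append(
                ClusterRegion(
                    raw["species_code"],
                    raw["cluster_id"],
                    raw["cluster_type"],
                    genes,
                    raw.get("start"),
                    raw.get("end"),
                )
            )
    else:
        df = pd.read_csv(path, sep="\t", dtype={"species_code": str, "cluster_id": str})
        missing = [c for c in GENE_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"{path}: missing column(s) {missing}")
        regions = []
        for (code, cid, ctype), sub in df.groupby(
            ["species_code", "cluster_id", "cluster_type"], sort=False
        ):
            genes = tuple(
                ClusterGene(r.gene_id, int(r.start), int(r.end), r.strand, r.protein)
                for r in sub.itertuples()
            )
            regions.append(ClusterRegion(code, cid, ctype, genes))
    for region in regions:
        _validate_region(region)
    return regions


def write_clusters_json(regions: Sequence[ClusterRegion], path: str | Path) -> None:
    payload = {
        "regions": [
            {
                "species_code": r.species_code,
                "cluster_id": r.cluster_id,
                "cluster_type": r.cluster_type,
                "start": r.start,
                "end": r.end,
                "genes": [
                    {
                        "gene_id": g.gene_id,
                        "start": g.start,
                        "end": g.end,
                        "strand": g.strand,
                        "protein": g.protein,
                    }
                    for g in r.genes
                ],
            }
            for r in regions
        ]
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def smbgc_average(total_regions: int, n_species: int) -> Stat:
    """Regions per species: raw ratio plus the one-decimal display.

    Published tables occasionally print a different rounding for ratios
    near x.x5 (e.g. 126/229 = 0.5502 shown as 0.5); emitting the raw value
    next to the display keeps any such discrepancy visible.
    """
    if n_species == 0:
        return Stat(0.0, display(0.0, 1))
    raw = total_regions / n_species
    return Stat(raw, display(raw, 1))


@dataclass(frozen=True)
class BgcTally:
    per_type: dict[str, int]
    total: int
    n_species_with_regions: int
    average: Stat  # raw ratio + one-decimal display


def tally_cluster_types(
    regions: Sequence[ClusterRegion],
    species_table: Sequence[SpeciesRecord] | None = None,
    group_label: str | None = None,
) -> BgcTally:
    """Per-type counts, total, and the average per region-bearing species.

    The denominator is the number of species with >=1 region.  Both the
    raw ratio and the one-decimal display are emitted, because rounding
    of ratios near x.x5 is a visible reporting choice, never hidden.
    """
    if species_table is not None and group_label is not None:
        keep = {s.species_code for s in species_table if s.group_label == group_label}
        regions = [r for r in regions if r.species_code in keep]
    per_type = Counter(r.cluster_type for r in regions)
    total = len(regions)
    n_species = len({r.species_code for r in regions})
    return BgcTally(dict(per_type), total, n_species, smbgc_average(total, n_species))


def find_p450s_in_clusters(
    regions: Sequence[ClusterRegion],
    references: Sequence[ReferenceP450],
    mining_config: MiningConfig | None = None,
    nomenclature_config: NomenclatureConfig | None = None,
) -> list[ClusterP450Link]:
    """Screen every cluster gene product for complete P450s and classify them.

    Returns one link per (P450, region); a species with P450s in two
    regions of different types yields two links.
    """
    mining_config = mining_config or MiningConfig()
    links: list[ClusterP450Link] = []
    for region in regions:
        proteins = [
            ProteinRecord(g.gene_id, region.species_code, g.protein) for g in region.genes
        ]
        candidates = screen_proteome(proteins, mining_config)
        annotations = annotate(
            [c for c in candidates if c.status == "complete"],
            references,
            nomenclature_config,
        )
        for ann in annotations:
            links.append(
                ClusterP450Link(
                    region.species_code,
                    ann.family,
                    region.cluster_type,
                    region.cluster_id,
                    ann.protein_id,
                )
            )
    return links


def percentage_p450s_in_bgcs(n_in_bgc: int, n_total_p450s: int) -> Stat:
    """Share of a group's P450s sitting inside smBGCs (display: nearest int)."""
    if n_total_p450s == 0:
        raise UndefinedStatisticError("no P450s in the group")
    raw = 100.0 * n_in_bgc / n_total_p450s
    return Stat(raw, display(raw, 0))


def links_to_frame(links: Iterable[ClusterP450Link]) -> pd.DataFrame:
    return pd.DataFrame(
        [(l.species_code, l.family, l.cluster_type, l.cluster_id, l.gene_id) for l in links],
        columns=["species_code", "family", "cluster_type", "cluster_id", "gene_id"],
    )
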