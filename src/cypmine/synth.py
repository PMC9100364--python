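"""Seeded, manifest-backed synthetic cohorts for end-to-end testing.

The generator emulates the world the analysis assumes: per-species
proteome FASTA files containing planted complete P450s (mutated from
built-in reference sequences to a controlled identity band, with both
diagnostic motifs preserved), planted ferredoxins realising exact Fe-S
spacing signatures, motif-free decoy proteins, and BGC region files with
planted P450 genes.  Every planted protein has one row in the truth
manifest, which downstream tests treat as the oracle.  The same spec and
seed always produce byte-identical outputs.

What the defaults emulate: a small bacterial cohort in which P450s are
sparse (a few per carrier species, many species without any), three
planted family situations spanning the nomenclature bands (clearly known
subfamily, clearly new subfamily, clearly new family, each >= 3 points
away from the 40/55 thresholds), the five ferredoxin cluster types the
field reports for such cohorts, and a handful of cluster regions of the
dominant anti-SMASH types with occasional in-cluster P450s.  Real
proteomes add homologous noise, fragments and phylogenetic correlation
that this generator deliberately does not model.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .align import global_identity
from .bgc import ClusterGene, ClusterRegion, write_clusters_json
from .errors import GenerationError
from .ferredoxin import FdxConfig, detect_fes_motifs, parse_signature
from .io import write_fasta, write_reference_set, write_species_table
from .mining import find_motifs
from .records import ProteinRecord, ReferenceP450, SpeciesRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_FLANK = "".join(c for c in AA20 if c not in "CP")  # keeps planted motifs exact

FAMILY_THRESHOLD = 40.0
SUBFAMILY_THRESHOLD = 55.0


# ---------------------------------------------------------------------------
# built-in reference set

def builtin_references() -> list[ReferenceP450]:
    """Four synthetic, real-shaped ~450 aa reference P450s.

    These are not database sequences: they are random proteins with valid
    EXXR and heme-binding motifs planted at realistic offsets, mutually
    unrelated (far below the family threshold), fixed once by an internal
    seed so the reference set is stable across runs.
    """
    rng = np.random.default_rng(1103)
    labels = [
        ("ref1103A", "CYP1103", "A"),
        ("ref236A", "CYP236", "A"),
        ("ref1144A", "CYP1144", "A"),
        ("ref152AP", "CYP152", "AP"),
    ]
    refs = []
    for ref_id, family, subfamily in labels:
        seq = list(_random_seq(rng, 450))
        seq[280], seq[283] = "E", "R"  # K-helix ExxR
        seq[395], seq[398], seq[402], seq[404] = "F", "G", "C", "G"  # heme FxxGxxxCxG
        refs.append(ReferenceP450(ref_id, family, subfamily, "".join(seq)))
    return refs


def _random_seq(rng: np.random.Generator, length: int, alphabet: str = AA20) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=length))


# ---------------------------------------------------------------------------
# controlled mutation

def _motif_windows(sequence: str) -> list[tuple[int, int]]:
    hits = find_motifs(sequence)
    exxr = next((h for h in hits if h.motif_name == "EXXR"), None)
    windows = []
    if exxr is not None:
        windows.append((exxr.start, exxr.start + 4))
        cxg = next(
            (h for h in hits if h.motif_name == "CXG" and h.start > exxr.start), None
        )
        if cxg is None:
            cxg = next((h for h in hits if h.motif_name == "CXG"), None)
        if cxg is not None:
            windows.append((cxg.start, cxg.start + 10))
    return windows


def mutate_to_identity(
    reference: str, lo: float, hi: float, seed: int
) -> tuple[str, float]:
    """Point-mutate ``reference`` until global identity lands in [lo, hi].

    Substitutions are applied one at a time in a seeded shuffled order,
    always outside the EXXR/CXG motif windows, and the realised identity
    is verified with the package's alignment definition.  Deterministic
    given the seed.  Raises :class:`GenerationError` if the band cannot
    be reached while preserving the motifs.
    """
    if not (0 < lo <= hi <= 100):
        raise GenerationError(f"invalid identity band [{lo}, {hi}]")
    if len(reference) < 100:
        raise GenerationError("reference too short (< 100 residues) for controlled mutation")
    if hi >= 100.0:
        return reference, 100.0

    rng = np.random.default_rng(seed)
    protected = np.zeros(len(reference), dtype=bool)
    for a, b in _motif_windows(reference):
        protected[a:b] = True
    free = np.flatnonzero(~protected)
    order = rng.permutation(free)

    seq = list(reference)
    # substitutions-only keeps the alignment near the diagonal, so identity
    # tracks (L - m)/L closely; skip expensive checks until near the band
    check_from = max(0, int(len(reference) * (1.0 - hi / 100.0)) - 8)
    for m, pos in enumerate(order, start=1):
        current = seq[pos]
        choices = [c for c in AA20 if c != current]
        seq[pos] = choices[int(rng.integers(0, len(choices)))]
        if m < check_from:
            continue
        ident = global_identity("".join(seq), reference)
        if ident <= hi:
            if ident >= lo:
                return "".join(seq), ident
            raise GenerationError(
                f"overshot identity band [{lo}, {hi}]: realised {ident:.2f}"
            )
    raise GenerationError(
        f"identity band [{lo}, {hi}] unreachable while preserving motifs"
    )


# ---------------------------------------------------------------------------
# cohort specification

@dataclass(frozen=True)
class FamilyPlan:
    """Plant ``count`` P450s mutated from ``family``'s reference into the band."""

    family: str
    identity_lo: float
    identity_hi: float
    count: int
    adversarial: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.identity_lo <= self.identity_hi <= 100):
            raise GenerationError(f"identity band [{self.identity_lo}, {self.identity_hi}] invalid")
        if not self.adversarial:
            for thr in (FAMILY_THRESHOLD, SUBFAMILY_THRESHOLD):
                if self.identity_lo <= thr <= self.identity_hi:
                    raise GenerationError(
                        f"band [{self.identity_lo}, {self.identity_hi}] straddles the "
                        f"{thr}% threshold; flag adversarial=True if intended"
                    )

    @property
    def expected_novelty(self) -> str | None:
        if self.identity_hi <= FAMILY_THRESHOLD:
            return "new_family"
        if self.identity_lo > SUBFAMILY_THRESHOLD:
            return "known_subfamily"
        if self.identity_lo > FAMILY_THRESHOLD and self.identity_hi <= SUBFAMILY_THRESHOLD:
            return "new_subfamily"
        return None  # adversarial band


@dataclass(frozen=True)
class FerredoxinPlan:
    cluster_type: str
    signature: str
    count: int


@dataclass(frozen=True)
class BgcPlan:
    cluster_type: str
    count: int
    p450_family: str | None = None


_DEFAULT_FAMILY_PLAN = (
    FamilyPlan("CYP1103", 70.0, 90.0, 8),
    FamilyPlan("CYP236", 45.0, 52.0, 6),
    FamilyPlan("CYP1144", 22.0, 32.0, 4),
)
_DEFAULT_FDX_PLAN = (
    FerredoxinPlan("2Fe-2S", "C-x4-C-x2-C-x28-C", 6),
    FerredoxinPlan("4Fe-4S", "C-x2-C-x2-C-x3-C", 4),
    FerredoxinPlan("3Fe-4S", "C-x2-C-x7-C", 3),
    FerredoxinPlan("2[4Fe-4S]", "C-x2-C-x2-C-x3-C-x6-C-x2-C-x2-C-x3-C", 3),
    FerredoxinPlan("2[4Fe-4S]Alv", "C-x2-C-x2-C-x3-C-x30-C-x2-C-x2-C-x3-C", 3),
)
_DEFAULT_BGC_PLAN = (
    BgcPlan("terpene", 4, "CYP1103"),
    BgcPlan("NRPS", 3, None),
    BgcPlan("T1PKS", 2, None),
    BgcPlan("arylpolyene", 2, "CYP236"),
)


@dataclass(frozen=True)
class CohortSpec:
    n_species: int = 24
    group_label: str = "GroupA"
    p450_carrier_fraction: float = 0.5  # most species carry no P450 at all
    p450_max_per_species: int = 3
    decoys_per_species: int = 8
    family_plan: tuple[FamilyPlan, ...] = _DEFAULT_FAMILY_PLAN
    ferredoxin_plan: tuple[FerredoxinPlan, ...] = _DEFAULT_FDX_PLAN
    bgc_plan: tuple[BgcPlan, ...] = _DEFAULT_BGC_PLAN
    seed: int = 20220502

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSpec":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "family_plan" in kwargs:
            kwargs["family_plan"] = tuple(FamilyPlan(**d) for d in kwargs["family_plan"])
        if "ferredoxin_plan" in kwargs:
            kwargs["ferredoxin_plan"] = tuple(
                FerredoxinPlan(**d) for d in kwargs["ferredoxin_plan"]
            )
        if "bgc_plan" in kwargs:
            kwargs["bgc_plan"] = tuple(BgcPlan(**d) for d in kwargs["bgc_plan"])
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# realisation helpers

def _realize_ferredoxin(
    cluster_type: str, signature: str, rng: np.random.Generator
) -> str:
    """Build a small protein realising ``signature`` exactly for its type."""
    gaps = parse_signature(signature)

    def motif(gaps3: Sequence[int], with_p: bool) -> str:
        out = ["C"]
        for g in gaps3:
            out.append(_random_seq(rng, g, _FLANK))
            out.append("C")
        if with_p:
            out.append("P")
        return "".join(out)

    if cluster_type == "2Fe-2S":
        if len(gaps) != 3 or gaps[0] != 4 or gaps[1] != 2 or not (20 <= gaps[2] <= 40):
            raise GenerationError(f"signature {signature!r} invalid for 2Fe-2S")
        core = motif(gaps, with_p=False)
    elif cluster_type == "3Fe-4S":
        if len(gaps) != 2 or gaps[0] != 2 or not (5 <= gaps[1] <= 9):
            raise GenerationError(f"signature {signature!r} invalid for 3Fe-4S")
        core = motif(gaps, with_p=True)
    elif cluster_type == "4Fe-4S":
        if gaps != [2, 2, 3]:
            raise GenerationError(f"signature {signature!r} invalid for 4Fe-4S")
        core = motif(gaps, with_p=True)
    elif cluster_type in ("2[4Fe-4S]", "2[4Fe-4S]Alv"):
        if len(gaps) != 7 or gaps[:3] != [2, 2, 3] or gaps[4:] != [2, 2, 3]:
            raise GenerationError(f"signature {signature!r} invalid for {cluster_type}")
        inter = gaps[3]
        if cluster_type == "2[4Fe-4S]" and not (1 <= inter <= 20):
            raise GenerationError("twin-cluster inter-motif gap must be 1..20")
        if cluster_type == "2[4Fe-4S]Alv" and inter <= 20:
            raise GenerationError("Alvin-type inter-motif gap must exceed 20")
        # the residue right after the first motif's last Cys is its P
        core = (
            motif(gaps[:3], with_p=True)
            + _random_seq(rng, inter - 1, _FLANK)
            + motif(gaps[4:], with_p=True)
        )
    else:
        raise GenerationError(f"cannot realise cluster type {cluster_type!r}")

    n_flank = _random_seq(rng, int(rng.integers(8, 16)), _FLANK)
    c_flank = _random_seq(rng, int(rng.integers(8, 16)), _FLANK)
    seq = n_flank + core + c_flank
    if len(seq) > 200:
        raise GenerationError(f"realised ferredoxin too long ({len(seq)} aa)")
    return seq


def _make_decoy(rng: np.random.Generator, length: int) -> str:
    """A protein with no P450 motif and no Fe-S motif (rejection-sampled)."""
    for _ in range(500):
        seq = _random_seq(rng, length)
        if find_motifs(seq):
            continue
        if detect_fes_motifs(seq, FdxConfig()):
            continue
        return seq
    raise GenerationError(f"could not sample a motif-free decoy of length {length}")


# ---------------------------------------------------------------------------
# cohort generation

@dataclass
class Cohort:
    spec: CohortSpec
    species: list[SpeciesRecord]
    proteomes: dict[str, list[ProteinRecord]]
    clusters: list[ClusterRegion]
    manifest: pd.DataFrame
    references: list[ReferenceP450]

    def all_proteins(self) -> list[ProteinRecord]:
        return [p for code in sorted(self.proteomes) for p in self.proteomes[code]]

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        (out / "proteomes").mkdir(parents=True, exist_ok=True)
        for code in sorted(self.proteomes):
            write_fasta(self.proteomes[code], out / "proteomes" / f"{code}.fasta")
        write_species_table(self.species, out / "species.tsv")
        write_clusters_json(self.clusters, out / "clusters.json")
        write_reference_set(self.references, out / "references.fasta")
        self.manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
        return {
            "proteome_dir": out / "proteomes",
            "species_table": out / "species.tsv",
            "clusters": out / "clusters.json",
            "references": out / "references.fasta",
            "manifest": out / "manifest.tsv",
        }


_MANIFEST_COLUMNS = [
    "species_code",
    "protein_id",
    "kind",
    "family",
    "subfamily",
    "expected_novelty",
    "cluster_type",
    "signature",
    "identity_lo",
    "identity_hi",
    "realized_identity",
    "in_bgc",
    "bgc_cluster_type",
    "bgc_cluster_id",
]


def generate_cohort(spec: CohortSpec | None = None) -> Cohort:
    """Generate one cohort: proteomes, clusters, species table and manifest."""
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    references = builtin_references()
    ref_by_family = {r.family: r for r in references}

    species = [
        SpeciesRecord(
            f"SP{i:03d}",
            f"Synthbacter cohortis {i}",
            "Synthbacter",
            spec.group_label,
            f"T9{i:04d}",
        )
        for i in range(1, spec.n_species + 1)
    ]
    codes = [s.species_code for s in species]
    proteomes: dict[str, list[ProteinRecord]] = {c: [] for c in codes}
    manifest_rows: list[dict] = []
    p450_load = {c: 0 for c in codes}
    serial = {"p450": 0, "fdx": 0, "bgc": 0}

    n_carriers = max(1, int(round(spec.p450_carrier_fraction * spec.n_species)))
    carriers = sorted(rng.choice(codes, size=n_carriers, replace=False).tolist())

    def pick_species() -> str:
        return codes[int(rng.integers(0, len(codes)))]

    def pick_carrier() -> str:
        # least-loaded first: spreads P450s over carriers (1-3 per genome)
        pool = [c for c in carriers if p450_load[c] < spec.p450_max_per_species]
        if not pool:
            raise GenerationError("no carrier species left under the per-species P450 cap")
        low = min(p450_load[c] for c in pool)
        pool = [c for c in pool if p450_load[c] == low]
        return pool[int(rng.integers(0, len(pool)))]

    def add_p450(code: str, plan_family: str, lo: float, hi: float,
                 in_bgc: bool = False, bgc_type: str = "", bgc_id: str = "",
                 pid: str | None = None) -> ProteinRecord:
        serial["p450"] += 1
        pid = pid or f"{code}_P450_{serial['p450']:04d}"
        ref = ref_by_family[plan_family]
        child_seed = int(rng.integers(0, 2**31 - 1))
        seq, realized = mutate_to_identity(ref.sequence, lo, hi, child_seed)
        rec = ProteinRecord(pid, code, seq)
        proteomes[code].append(rec)
        novelty = FamilyPlan(plan_family, lo, hi, 1).expected_novelty
        manifest_rows.append(
            dict(
                species_code=code, protein_id=pid, kind="p450",
                family=plan_family, subfamily=ref.subfamily,
                expected_novelty=novelty or "adversarial",
                cluster_type="", signature="",
                identity_lo=lo, identity_hi=hi, realized_identity=realized,
                in_bgc=in_bgc, bgc_cluster_type=bgc_type, bgc_cluster_id=bgc_id,
            )
        )
        return rec

    # planted P450s
    for plan in spec.family_plan:
        for _ in range(plan.count):
            code = pick_carrier()
            p450_load[code] += 1
            add_p450(code, plan.family, plan.identity_lo, plan.identity_hi)

    # planted ferredoxins
    for plan in spec.ferredoxin_plan:
        for _ in range(plan.count):
            code = pick_species()
            serial["fdx"] += 1
            pid = f"{code}_FDX_{serial['fdx']:04d}"
            seq = _realize_ferredoxin(plan.cluster_type, plan.signature, rng)
            proteomes[code].append(ProteinRecord(pid, code, seq))
            manifest_rows.append(
                dict(
                    species_code=code, protein_id=pid, kind="ferredoxin",
                    family="", subfamily="", expected_novelty="",
                    cluster_type=plan.cluster_type, signature=plan.signature,
                    identity_lo=np.nan, identity_hi=np.nan,
                    realized_identity=np.nan, in_bgc=False,
                    bgc_cluster_type="", bgc_cluster_id="",
                )
            )

    # decoys
    for code in codes:
        for i in range(spec.decoys_per_species):
            pid = f"{code}_DEC_{i + 1:03d}"
            length = int(rng.integers(80, 351))
            seq = _make_decoy(rng, length)
            proteomes[code].append(ProteinRecord(pid, code, seq))
            manifest_rows.append(
                dict(
                    species_code=code, protein_id=pid, kind="decoy",
                    family="", subfamily="", expected_novelty="",
                    cluster_type="", signature="",
                    identity_lo=np.nan, identity_hi=np.nan,
                    realized_identity=np.nan, in_bgc=False,
                    bgc_cluster_type="", bgc_cluster_id="",
                )
            )

    # BGC regions; planted cluster P450s also join the proteome so the
    # standalone and in-cluster pipelines stay consistent
    clusters: list[ClusterRegion] = []
    for plan in spec.bgc_plan:
        for _ in range(plan.count):
            code = pick_carrier() if plan.p450_family is not None else pick_species()
            if plan.p450_family is not None:
                p450_load[code] += 1
            serial["bgc"] += 1
            cid = f"{code}_BGC{serial['bgc']:03d}"
            products: list[tuple[str, str]] = []
            products.append((f"{cid}_g1", _make_decoy(rng, int(rng.integers(120, 251)))))
            if plan.p450_family is not None:
                gene_id = f"{cid}_g2"
                rec = add_p450(
                    code, plan.p450_family, 70.0, 90.0,
                    in_bgc=True, bgc_type=plan.cluster_type, bgc_id=cid, pid=gene_id,
                )
                products.append((gene_id, rec.sequence))
            products.append((f"{cid}_g3", _make_decoy(rng, int(rng.integers(120, 251)))))
            genes = []
            pos = 1
            for gene_id, prot in products:
                glen = 3 * len(prot) + 3
                strand = "+" if rng.integers(0, 2) else "-"
                genes.append(ClusterGene(gene_id, pos, pos + glen - 1, strand, prot))
                pos += glen + 50
            clusters.append(
                ClusterRegion(code, cid, plan.cluster_type, tuple(genes), 1, genes[-1].end)
            )

    manifest = pd.DataFrame(manifest_rows, columns=_MANIFEST_COLUMNS)
    return Cohort(spec, species, proteomes, clusters, manifest, references)


# ---------------------------------------------------------------------------
# recovery scoring against the manifest

def score_recovery(cohort: Cohort, p450_annotations, fdx_annotations) -> dict:
    """Fraction of planted labels the pipeline recovered.

    A planted P450 counts as recovered when its novelty call matches the
    manifest and the family is the planted one (or any CYPNEW placeholder
    for planted new-family proteins).  Ferredoxins count when the cluster
    type matches.
    """
    ann_by_id = {a.protein_id: a for a in p450_annotations}
    fdx_by_id = {a.protein_id: a for a in fdx_annotations}
    p450_rows = cohort.manifest[cohort.manifest["kind"] == "p450"]
    fdx_rows = cohort.manifest[cohort.manifest["kind"] == "ferredoxin"]

    p450_ok = 0
    for row in p450_rows.itertuples():
        ann = ann_by_id.get(row.protein_id)
        if ann is None or ann.novelty != row.expected_novelty:
            continue
        if row.expected_novelty == "new_family":
            if ann.family.startswith("CYPNEW"):
                p450_ok += 1
        elif ann.family == row.family:
            p450_ok += 1
    fdx_ok = sum(
        1
        for row in fdx_rows.itertuples()
        if row.protein_id in fdx_by_id
        and fdx_by_id[row.protein_id].cluster_type == row.cluster_type
    )
    return {
        "n_p450_planted": len(p450_rows),
        "p450_recovery": p450_ok / len(p450_rows) if len(p450_rows) else float("nan"),
        "n_fdx_planted": len(fdx_rows),
        "fdx_recovery": fdx_ok / len(fdx_rows) if len(fdx_rows) else float("nan"),
    }
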