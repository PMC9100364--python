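# Methods

This note documents the models and procedures `cypmine` implements, the
defaults it chooses where the underlying field conventions leave room, and
what its tests do and do not establish.

## P450 mining

P450s are recognised by two diagnostic sequence motifs of the fold:

* **EXXR** — the K-helix Glu-x-x-Arg salt bridge, realised as the regex
  `E..R`;
* **CXG** — the heme-binding region around the absolutely conserved cysteine,
  realised as the ten-residue consensus `F..G...C.G` and reported with its
  start at the F. The short label "CXG" is kept for the motif even though the
  implemented pattern is the full heme-binding consensus containing C-x-G.

`find_motifs` reports *all* (possibly overlapping) matches of both patterns in
position order. `screen_proteome` emits one candidate per protein with at
least one hit and assigns a status:

* **complete** — both motifs present, length ≥ `min_length` (default
  **300 aa**: complete bacterial P450s run ~400 aa, so 300 sits below
  essentially all of them and above most fragments; the cutoff is a package
  decision, not a literature constant), and — by default — at least one CXG
  hit C-terminal of an EXXR hit (the heme motif follows the K-helix in all
  P450 folds; configurable off);
* **fragment** — exactly one motif, or both motifs in a short protein;
* **rejected** — both motifs at adequate length but the heme motif precedes
  the K-helix everywhere (not a plausible P450 topology).

Fragments are flagged, never silently dropped; only complete candidates move
on to classification. Profile/HMM detection is out of scope, so P450 families
genuinely lacking EXXR are a known blind spot of the motif screen.

## Percent identity and nomenclature

Family/subfamily assignment uses the standard committee thresholds with
strict inequalities: identity **> 55%** inherits the best reference's
subfamily, **> 40%** its family (with a new subfamily letter), and **≤ 40%**
founds a new family. Identity exactly 40.0 is therefore a new family and
exactly 55.0 a new subfamily.

Because "percent identity" is not a single number without a convention, the
package fixes one and states it:

* global (end-gap-penalised) alignment, Gotoh affine-gap recurrences;
* BLOSUM62 substitution scores; gap open 10, gap extend 1 (a gap of length L
  costs `10 + (L-1)·1`);
* identity = identical columns / all alignment columns, gaps included;
* among co-optimal alignments the traceback prefers match/mismatch, then a
  gap in the reference, then a gap in the query — two optimal alignments of
  equal score can differ in identity, so the tie-break is part of the
  definition. The test suite checks the implementation against an
  independently written brute-force dynamic program under the same stated
  convention, and checks optimal scores against biopython's PairwiseAligner.

All parameters (thresholds, matrix, penalties) are configurable. Identity is
computed over full-length sequences; terminal trimming is not applied.

Best-reference ties break by reference file order (first wins), for
determinism. New families receive placeholder names `CYPNEW1, CYPNEW2, …` in
query input order — a repository cannot mint official committee names; the
annotation table retains the best-reference id and identity so the
placeholders can be renamed later. By default a post-pass merges novel
queries sharing > 40% mutual identity into one placeholder family (and > 55%
into one subfamily within it), mirroring how several members end up in a
single newly named family; per-query independent assignment is available by
switching the merge off.

## Ferredoxin typing

Ferredoxins are small iron-sulfur electron carriers; candidates are capped at
**200 aa** (default) to keep large Fe-S enzymes out of the screen. The
concrete binding-motif patterns are package decisions (the field typically
defers to curated domain databases, which the offline pipeline does not
call):

| motif | pattern | cysteines |
|---|---|---|
| plant-type 2Fe-2S | `C-x4-C-x2-C-x(20–40)-C` | 4 |
| bacterial 4Fe-4S | `C-x2-C-x2-C-x3-C-P` | 4 |
| bacterial 3Fe-4S | `C-x2-C-x(5–9)-C-P` | 3 |

The scan is left-to-right, greedy and non-overlapping, trying patterns in the
order 4Fe-4S → 3Fe-4S → plant (the 4Fe-4S motif's tail also satisfies the
3Fe-4S pattern, so the more specific pattern must win). Gap bounds are
configuration values.

Cluster type follows from the motif combination: one plant motif ⇒ 2Fe-2S;
one bacterial 3Fe-4S ⇒ 3Fe-4S; one bacterial 4Fe-4S ⇒ 4Fe-4S; two 4Fe-4S
motifs ⇒ the twin cluster 2[4Fe-4S], **promoted to 2[4Fe-4S]Alv when the
insertion between the two motifs exceeds 20 residues** (Alvin-type
ferredoxins carry a characteristic loop/C-terminal extension; the spacing
rule and its threshold are package decisions); a 3Fe-4S plus a 4Fe-4S motif
⇒ 7Fe-8S. No motif raises a not-a-ferredoxin signal; unrecognised
combinations are reported as ambiguous, never silently dropped.

Within a cluster type, the subtype is the exact **spacing signature** over
all motif cysteines, `C-x<g1>-C-x<g2>-…` with `g` the inter-cysteine gaps (for
twin clusters this includes the inter-motif gap, which cleanly separates
Alvin from non-Alvin signatures). Subtype numbers live in a registry with one
namespace per cluster type: an existing signature keeps its number forever, a
new signature takes the next free number. The registry ships empty and can be
seeded from a TSV (`signature, cluster_type, subtype`) to continue published
numbering explicitly — the package does not guess any published
signature↔number mapping.

## smBGC mapping

Cluster regions arrive in a documented JSON (or flat TSV) dialect emulating
anti-SMASH exports: region label, anti-SMASH cluster type, and member genes
with 1-based inclusive coordinates, strand and protein sequence. Hybrid type
labels stay verbatim single categories; unknown labels pass through with a
warning. Running anti-SMASH itself, and similarity of clusters to external
cluster databases, are out of scope.

Tallies conserve mass, and the per-species average divides by the number of
species with at least one region. The average is emitted both raw and at
one-decimal display precision because published tables have printed
inconsistent roundings for ratios near x.x5 (e.g. 126/229 = 0.5502 shown as
0.5 where nearest rounding gives 0.6); the raw value next to the display
keeps any such discrepancy auditable. `smbgc_average` exposes the ratio
directly for denominators that are not derivable from the region list (such
as per-group species counts taken from a published table).

In-cluster P450s are found by running the standard miner and classifier over
every cluster gene product, one link per (P450, region); a species with
P450s in two regions of different types contributes two links.

## Comparative statistics

For a group with `P` P450s, `S` species carrying them and `F` families:

* **average P450s** = `P/S`, displayed as the nearest integer when ≥ 1, else
  to one decimal. The denominator is a caller argument because published
  comparison tables mix denominators (some columns divide by carrier
  species, some by all species analysed).
* **diversity percentage** = `100·F/(P·S)`, displayed to two decimals. The
  denominator is the *product* P×S — the printed values of the comparison
  tables confirm the product reading of the formula (e.g.
  `100·21/(98·77) = 0.28`).
* **percentage of P450s in BGCs** = `100·n_in_BGC/P`, displayed as the
  nearest integer.

All display rounding is nearest with ties away from zero, and every report
carries the raw float next to the display string.

Presence/absence matrices have one row per family (or ferredoxin subtype) and
one column per species with ≥ 1 P450, encoded **3 = present / −3 = absent**
(the MeV heat-map convention) and binarised (multiple members still give one
presence). Hierarchical clustering runs on Euclidean distances of the ±3
vectors via scipy, with **average linkage** by default (the distance metric
is the stated convention; the linkage method is a package choice,
configurable to single/complete). Leaf orders and the scipy merge trees are
returned for both axes; rendering is deliberately minimal. Dominant-family
ties are flagged rather than silently resolved.

## Synthetic cohorts

The generator states a world and sticks to it. Defaults:

* 24 species, with P450s planted into a carrier subset of **half** the
  cohort (carrying no P450 is the norm in the phyla this emulates), at most
  3 per genome, spread least-loaded-first so carriers hold 1–3 each;
* three family plans from four built-in ~450 aa synthetic references:
  8 proteins at 70–90% identity (known subfamily), 6 at 45–52% (new
  subfamily), 4 at 22–32% (new family). Bands keep ≥ 3 points clear of the
  40/55 thresholds; bands straddling a threshold must be explicitly flagged
  adversarial;
* 19 ferredoxins across the five cluster types commonly reported for such
  cohorts (6× 2Fe-2S, 4× 4Fe-4S, 3× 3Fe-4S, 3× twin, 3× Alvin), each
  realising its planted signature exactly;
* 8 motif-free decoy proteins per species (80–350 aa, rejection-sampled until
  they contain no P450 motif and no Fe-S motif);
* 11 cluster regions over four common anti-SMASH types, six of them carrying
  a planted P450 gene (which also joins the species proteome, keeping the
  standalone and in-cluster pipelines consistent).

Controlled mutation applies seeded point substitutions outside the motif
windows one at a time and verifies the realised identity with the package's
aligner once near the band; unreachable bands raise a generation error rather
than bending the target. The same spec and seed produce byte-identical
output files.

What a green end-to-end test establishes: the pipeline recovers planted
family/novelty labels and cluster types under clean conditions — motifs
exact, identity bands clear of thresholds, decoys motif-free. What it does
not establish: behaviour on real proteomes, which add homologous noise near
the thresholds, genuine fragments, non-canonical motif variants and
phylogenetic correlation among species. The generator deliberately does not
model those.

## Numerical and degenerate-input choices

* Zero denominators (no species, no P450s) raise an undefined-statistic
  error instead of returning 0 or NaN.
* FASTA parsing rejects residues outside the 20 standard letters + X, accepts
  `*` only as a trailing stop symbol (internal `*` signals a
  pseudogene/frameshift artefact and is an error), and names the offending
  entry in every parse error.
* A single-row (or single-column) presence matrix returns the identity leaf
  ordering with no merge tree.
* Registry numbers are append-only; re-running a pipeline with the same
  inputs and seed registry reproduces identical subtype assignments.
* Species metadata columns follow the conventional five-field table
  (species_code, species_name, genus, group_label, genome_id); duplicate
  species codes are a uniqueness error.

## Known limitations

* Motif regexes miss P450s without a canonical EXXR and non-canonical Fe-S
  motifs; profile-based detection is a non-goal.
* Placeholder `CYPNEW` names are stable only within a run's input order.
* The Alvin spacing rule is a proxy; homology-based Alvin assignment may
  differ on real sequences.
* The anti-SMASH dialect captures exactly the fields the analysis uses;
  it is not a general GenBank region parser.
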