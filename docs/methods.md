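# Methods

## Scope and data model

`nemadelim` operates on per-locus nucleotide sequence sets (FASTA), an isolate
metadata table (TSV: isolate_id, species, population, locality, optionally
accession), a primer table (TSV: locus, forward, reverse, max_mismatches) and
morphometric measurement tables (TSV, one specimen per row). Coordinates are
1-based closed intervals everywhere, matching the positional style used in
taxonomic reports (`g.1212A>G`). Sequences are uppercased on ingestion and RNA
`U` is normalized to `T`; IUPAC ambiguity codes and gaps are retained in
records and handled downstream.

## Amplicon extraction

The similarity claims of barcode delimitation refer to the region *flanked by*
the amplification primers. The extractor scans every offset for the forward
primer and for the reverse complement of the reverse primer, scoring IUPAC-
compatible matches (a primer position matches a target position when their
code expansions intersect) and allowing at most `max_mismatches` residual
mismatches. The returned region lies strictly between the two primer sites:
primer positions are invariant by construction and would inflate identity, so
trimming them makes similarity scores independent of primer choice. Records in
which either primer is absent (already-trimmed database sequences) are passed
through unchanged and flagged `untrimmed` rather than truncated. Multiple
equally good forward placements raise an ambiguity error listing positions; a
reverse hit upstream of the forward hit raises an orientation error.

## Substitution counting and distances

Counting uses **pairwise deletion**: a column contributes to a pair's
`compared_sites` only when both sequences carry an unambiguous A/C/G/T.
Ambiguity codes are excluded rather than partially matched — ambiguous base
calls are a documented source of erroneous taxonomic affiliation in this
group, so the conservative default is exclusion plus a per-record ambiguity
tally; a strict mode refuses records with more than 2 % ambiguous residues.
Each matrix retains the per-pair `compared_sites` so reports are auditable.

Differences are classified as A↔G transitions (`P₁`), C↔T transitions (`P₂`)
or transversions (`Q`). On top of these counts:

* p-distance `d = diff/n`, and percent similarity `100·(1 − d)` — the two are
  exact complements; similarities are rounded to one decimal only at
  reporting time.
* K2P `d = −½·ln(1−2P−Q) − ¼·ln(1−2Q)` with `P = P₁+P₂`.
* TN93 using the pair's pooled empirical base frequencies
  (`g_R = g_A+g_G`, `g_Y = g_C+g_T`):
  `d = −k₁·ln(w₁) − k₂·ln(w₂) − k₃·ln(w₃)` with
  `k₁ = 2g_Ag_G/g_R`, `k₂ = 2g_Cg_T/g_Y`,
  `k₃ = 2(g_Rg_Y − g_Ag_Gg_Y/g_R − g_Cg_Tg_R/g_Y)`,
  `w₁ = 1 − P₁/k₁ − Q/2g_R`, `w₂ = 1 − P₂/k₂ − Q/2g_Y`,
  `w₃ = 1 − Q/2g_Rg_Y`.

Saturated pairs (any logarithm argument ≤ 0, or a zero base frequency for
TN93) are flagged and stored as infinite; tree building refuses such matrices
explicitly. Gamma and invariant-site rate corrections are deliberately not
implemented — the matrices record the plain estimator in their `model` tag, so
no result can silently claim a correction that was not applied. In the
equal-frequency, `P₁ = P₂` limit TN93 reduces to K2P; the test suite verifies
this to 1e-12 and checks both closed forms against independent literal
transcriptions to 1e-9.

## Diagnostic polymorphism

A site is diagnostic between two groups when every member of one group carries
one unambiguous base and every member of the other a different one — fixity at
100 % frequency, with no frequency-threshold relaxation: the signatures this
mirrors are presented as invariant within species and populations. Columns
containing any gap or ambiguity in either group are skipped for that pair.
Variant names use a designated reference sequence's ungapped coordinates;
columns where the reference is gapped map to the preceding reference position
and are flagged insertions. The reference state (left side of `g.POSREF>ALT`)
is taken from the group containing the reference isolate, falling back to the
alphabetically first group.

## Delimitation

Species hypotheses are connected components of the similarity graph with an
edge for every pair at or above the threshold (ties included; single linkage).
This is the operative logic of barcode thresholds — any pair above the
boundary is conspecific — and it makes the recovery property provable: if the
labeled grouping has a barcode gap (smallest intra-species similarity `s₁`
exceeding the largest inter-species similarity `s₂`), every threshold in
`(s₂, s₁]` returns exactly the labeled partition. Average/complete linkage are
out of scope in this version. The default sweep grid spans 90–100 % in 0.5
steps and always contains 94 % (the literature threshold for the genus) and
the 97 / 98 % boundary values; sweeps report cluster counts and, when labels
are available, an exact-match flag and the pairwise Rand index. Cluster order
is deterministic (by smallest member label).

## Tree building

Neighbor joining minimizes `Q(i,j) = (r−2)·d(i,j) − Σ_k d(i,k) − Σ_k d(j,k)`
with lexicographic tie-breaking on cluster names (a cluster is named by its
smallest leaf), so runs are fully deterministic even on degenerate matrices
with many zero distances. Negative branch-length estimates are clamped to
zero with the deficit moved to the sister branch (the common convention); the
clamp count is recorded on the tree. On additive matrices NJ recovers the
unique generating tree exactly (verified on 200 random trees up to 12 leaves).
Bootstrap resamples alignment columns with replacement, rebuilds the tree per
replicate, and scores each internal edge of the reference tree by the
percentage of replicates containing the same bipartition. Per-replicate RNG
seeds derive from one root seed by a fixed increment of one, so individual
replicates can be replayed; replicates that leave a pair with no comparable
sites (or a saturated distance) are dropped and counted. Newick output writes
branch lengths and integer-percent supports as internal node labels.
Likelihood and Bayesian inference are out of scope: the delimitation claims
rest on distances, and NJ is the distance method the workflow standardizes on.

## Morphometrics

`compute_indices` evaluates the classical ratio indices from raw characters
(micrometers): a = L/BD, b = L/NL, c = L/T, c′ = T/ABD, V = VA/L·100, and the
derived percentages D% = EP/PL·100, E% = EP/T·100, SW% = SL/ABD·100,
GS% = GL/SL·100, H% = H/T·100, NR% = NR/NL·100, EP% = EP/NL·100,
Rectum% = R/ABD·100 and stoma/lip. Values are kept at full precision; rounding
happens at reporting. A zero denominator fails only that index. Two
documented quirks of the source tables are handled explicitly: D% is defined
as EP/PL·100 throughout (one published table labels the row EP/NL·100, but
its printed values are EP/PL — e.g. 101.05 = 96.2/95.2·100), and the printed
ruandica male SW% (242) equals SL/GL·100 rather than SL/ABD·100; the test
suite asserts the inconsistency instead of reproducing it.

The packaged comparative range tables (four stages: males, hermaphrodites,
second-generation females, infective juveniles; 40 published descriptions
each) are shipped as editable TSV fixtures transcribed cell-by-cell from the
published compilation, including single printed values (stored as degenerate
min = max intervals), computed-from-mean markers (`*`/`**`, kept in a note
column) and a handful of typeset intervals printed with min > max, which are
swapped at load time and flagged `printed-interval-inverted`. Range
membership uses closed intervals: printed endpoints are attained values. A
species with several published descriptions is *excluded* only when every
description excludes it, and *consistent* when at least one admits all
measured characters; characters missing on either side are skipped and
listed. The packaged dichotomous key for the closest relatives of the two new
species is a reconstruction compiled from the published diagnoses and range
tables, shipped as JSON data; `run_key` is a generic interpreter in which
every node declares its comparison operator (and therefore which side an
exact tie falls on), so traversal is deterministic and total on complete
records.

## Synthetic data generator

The generator emulates the structure of a recently diverged species complex:
a fast mitochondrial barcode next to nearly invariant nuclear markers.
Species are stars around a random ancestral sequence; each species receives a
configured number of private substitutions at fresh sites (transition vs
transversion drawn at ti/tv = 2 by default), and each population beyond the
first receives additional fixed transitions at fresh sites on the barcode
locus. Isolates within a population are identical by default, matching the
near-absent intraspecific variation of such complexes; an optional noise rate
adds singleton mutations for robustness testing. Substitutions are planted
with exact counts rather than drawn from a continuous-time model because the
downstream tests are about exact signature recovery, not about evolutionary
realism. Default conditions: 3 species × 2 populations × 2 isolates; COI
343 bp with 6–20 substitutions per species; D2D3 500 bp with 0–1; 1–3
population transitions. Generation ends with a self-check that re-derives all
diagnostic sites from the emitted sequences and compares them with the plan.

`bacteriophora_group_config` freezes the study conditions for the
three-species complex: per-species budgets chosen so the type-population
pairwise difference counts reproduce the published per-locus counts
(COI 7/19/20 over 343 bp; ITS 2/6/4 over 667 sites; D2D3 0/1/1 over 500
sites; one Rwandan and three Mexican population transitions). Because species
are additive stars, isolates carrying population-private substitutions sit a
few counts away from these type-pair values; the published bands refer to the
type comparisons, and the tests assert them there.

What passing on synthetic data does *not* show: robustness to alignment
error, indels, heterozygous/ambiguous calls at diagnostic sites, rate
variation across sites, or homoplasy — none of which the generator emulates.
Analyses of real data should inspect the per-pair `compared_sites` and
ambiguity tallies the reports carry.

## Problem sizes and determinism

Test and acceptance runs use 12-isolate, 343–667 bp datasets, 100 bootstrap
replicates, 200 random trees (n ≤ 12) for NJ consistency and 1000 random
parameter draws for the distance oracles — sizes at which every check runs in
seconds while still exercising each code path. All randomness flows from
explicit integer seeds (numpy `default_rng`); reruns with the same seed are
byte-identical, and the pipeline manifest records seeds, thresholds, linkage
and deletion policy for every run.

## Known limitations

* No multiple sequence alignment: inputs must be pre-aligned per locus (or
  equal-length amplicons); no indel model.
* No ML/Bayesian trees, no substitution-model selection, no rate
  heterogeneity corrections (+G/+I).
* Diagnostic sites require 100 % fixity; a single conflicting isolate removes
  a site (by design, but sensitive to sequencing error).
* Single-linkage only; a single aberrant high-similarity pair can chain two
  clusters (the barcode-gap report exposes this).
* Morphometric comparison is range-based; no multivariate or discriminant
  analysis.
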