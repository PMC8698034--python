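# Methods

## Notation and data model

An ORF's domain organization is a string of domain codes: `/` joins
domains within a module, `-` separates modules, `…` (or `...`) at either
end marks a cluster truncated by a contig edge. Extender specificity is
subscripted on AT (`AT_m_` malonyl, `AT_mm_` methylmalonyl) and A-domain
substrates as 3-letter codes (`A_thr_`, including hyphenated codes like
`A_b-ala_`). The parser accepts the subscript dialects that appear in
curated tables (`AT_m_`, `AT_m`, `ATm`) and normalizes them; unknown
domain codes map to `X` with the raw spelling preserved, never dropped.

Module assembly rules (the same rules curated tables use implicitly):

- a segment led by CoL is a **loading** module;
- a segment containing KS or C with at least one partner domain is an
  **extension** module (a new module starts at each KS/C, though tables
  normally pre-split these with `-`);
- a lone KS, C, A, T or carrier domain is a **standalone domain** (a
  discrete protein: trans-acting A, type-II KSα/KSβ/ACP subunits, …);
- a multi-domain segment with neither KS nor C (e.g. `A/T`, `A_glu_/T/TD`)
  is a **standalone unit** — a trans-acting didomain protein;
- a release/tailoring-only segment following a module in the same ORF is
  folded into that module, so `KS/AT_m_/ACP-Te` and `KS/AT_m_/ACP/Te`
  normalize identically (the two spellings both occur for the same
  module in curated tables).

Serialization emits the normalized form; parse∘serialize is the identity
on normalized strings and serialize∘parse is the identity on parsed
structures (property-tested on generated clusters).

**Module counting** counts loading + extension modules; standalone
domains/units are excluded. This reproduces the published total of 33 for
the giant quinolidomicin-type line only if the loading module is counted,
which is therefore the convention throughout.

## Classification

Type-II PKS: a cluster of discrete KSα/KSβ/ACP proteins with no modules.
Type-III PKS: a single ORF that is a single standalone KS. Otherwise the
cluster is typed by module chemistry: KS/AT only → modular (type-I) PKS;
C/A only → NRPS; both → hybrid.

## Product prediction

Walking ORFs and elements in gene order: a CoL loading module emits `st`;
an extension module emits its A-domain substrate (`x` if unannotated), or
`y` if it carries C and T but no A domain, or `pk` if KS-bearing; a
trans-acting standalone A domain or A-containing didomain emits its
residue unit as well, since the A domain activates one residue wherever it
sits. Standalone KS, C, T or carrier proteins emit nothing — they cannot
incorporate a unit without a partner. Length classes use Greek prefixes
(dipeptide … decaketide) and fall back to `<n>-ketide`/`<n>-peptide`.

Clusters containing any trans-acting element are flagged
`colinear=False`: their units are still emitted in gene order but the
assembly order is not gene-encoded. Incomplete (truncation-flagged)
clusters are `unpredictable`.

This uniform rule reproduces the curated product strings of the packaged
tables exactly for colinear clusters and as multisets for trans-acting
ones, with two documented exceptions where the curation itself is
internally inconsistent: one cluster lists five A domains but a
tetrapeptide product, and one ignores a trailing trans-acting A/T
didomain that an identical didomain in another cluster contributes to.
The corresponding strict test expectations are asserted and fail
honestly rather than special-casing those clusters.

## Module alignment and ortholog calls

Two clusters' module sequences (loading + extension, in gene order) are
aligned by Needleman–Wunsch. The match score is the Jaccard index of the
two modules' domain-label sets; when both sides annotate an AT or A
specificity and the annotations disagree, that domain's contribution is
scaled by `specificity_weight` (default 0.0, i.e. a disagreeing extender
counts as a full mismatch — extender choice changes the product, so it is
treated as architecture). Loading modules score 0 against extension
modules. Each unaligned module costs `gap_penalty` (default 0.4).

Traceback is deterministic: the reference-gap move is preferred at
score ties, which places an indel at the *last* of a run of score-tied
positions. This matters because tandem near-identical modules make indel
placement degenerate; reference tables resolve the degeneracy by gene
boundaries, and the last-position convention reproduces the published
placement of the absent module 4 in the quinolidomicin comparison. The
dynamic program is verified against exhaustive enumeration of all
alignments for clusters of ≤ 6 modules.

An **ortholog verdict** requires mean similarity over aligned pairs
≥ `s_min` (default 0.9) and aligned fraction ≥ `c_min` (default 0.85) on
*both* sides. These defaults are calibrated on the packaged tables: the
reference-vs-ortholog alignments score 0.95–0.97 mean at 0.97–1.0
coverage and mutated copies with ≤ 3 module indels stay above 0.9/0.9,
while the best non-orthologous same-type pair (two unrelated modular PKS
lines sharing the generic reduced-polyketide module vocabulary) reaches
only 0.73 mean — generic KS/AT/KR/ACP-style modules make lenient
thresholds (e.g. 0.6/0.8) accept guaranteed-spurious pairs. Thresholds
live in `clusterline.config` and every entry point accepts overrides.

**Inventory comparison** restricts candidates to equal computed types,
keeps ortholog-positive pairs, and matches greedily best-first by mean
similarity, one-to-one, ties resolved by inventory order. Clusters
without modules are handled specially: a single-ORF single-domain cluster
(type-III PKS) is compared by exact architecture identity; multi-protein
iterative systems (type-II PKS) are *excluded* from matching because
their notation (KSα/KSβ/ACP) is invariant within the class — any match
would be vacuous. Distinguishing type-II clusters requires sequence
similarity, which is outside this package's scope.

**Screening** aligns a reference against every same-type cluster of each
strain inventory and reports the best match and its verdict per strain.

## Taxonomy thresholds

`pairwise_identity` globally aligns two nucleotide sequences (Biopython
PairwiseAligner; match 5, mismatch −4, gap −10/−0.5, free terminal gaps)
and reports matches over aligned columns excluding terminal-gap columns,
rounded to one decimal — so marker genes trimmed to different lengths are
compared over their shared span. Note that for *unrelated* sequences
optimal gapping inflates this identity well above the ~25% positionwise
expectation; the measure is meant for homologous markers.

Verdicts are inclusive at the boundary (≥ 98.5% gyrB, ≥ 70% dDDH): the
published correspondences state points, not open intervals. 16S identity
alone always returns `inconclusive` — identical 16S sequences occur
between distinct genomospecies. dDDH values are inputs, never computed;
genome-to-genome distance formulas are out of scope. Species groups are
connected components of the same-species graph, invariant to pair order.

The packaged relatedness panel stores values printed only as bounds or
ranges ("&gt;90", "~90", "74–94", "33.5–33.8") at a representative point
inside the bound, flagged `approximate` in the note column; group
structure does not depend on the exact representative as long as it stays
on the printed side of 70%.

## Synthetic data

The generator emulates the architecture statistics of curated tables:
PKS modules are KS/AT(±DH(±ER))/KR/ACP with the reductive-loop domains
drawn by weight (KR 0.85, DH 0.45, ER 0.2 — reflecting how often they
appear in the packaged tables), methylmalonyl extenders at 0.35, NRPS
modules C/A/T with substrates annotated at 0.7 and occasional MT/E;
modules are packed into ORFs of 1–6 modules like real megasynthase genes,
and a release domain terminates the line. `mutate_cluster` applies seeded
whole-module deletions/insertions (an insertion copies an adjacent module
and may flip its extender, mimicking tandem near-identical modules),
domain swaps and specificity flips, returning an exact edit log; replaying
the log reproduces the mutant, which is what the recovery benchmarks use
as ground truth.

What the generator does **not** emulate: nucleotide/protein sequence
(there is none anywhere in the cluster model), inter-ORF intergenic
structure, trans-AT systems, domain-order rearrangements within modules,
or the non-colinear trans-acting architectures of real hybrid clusters.
Passing synthetic benchmarks therefore demonstrates correct recovery of
module-level edits under this model, not performance on raw genomes —
domain calling from sequence (e.g. antiSMASH/HMM annotation) is upstream
of, and outside, this package.

## Problem sizes and determinism

All packaged-table computations are exact and deterministic; the largest
alignment is 34×33 modules. The benchmark suites use 200 seeded
deletion-recovery trials on 15–25-module synthetic lines, 50-strain
screening panels, and 1000 round-trip architectures; the full test suite
runs in a few seconds on one CPU. Every stochastic entry point takes an
explicit seed; identical seed and configuration give byte-identical
output.

## Known limitations

- No sequence-level evidence: orthology rests on module architecture
  only, so architecture-identical but evolutionarily unrelated clusters
  (common for short NRPS lines and universal for type-II PKS) cannot be
  separated; coverage thresholds, type gating and the type-II abstention
  are mitigations, not solutions.
- Unit order for trans-acting clusters follows gene order, which curated
  tables sometimes override by manual reasoning that is not reproducible
  from the table alone.
- The greedy inventory matcher is not globally optimal (it is exact here
  because accepted pairs are near-unambiguous); a Hungarian assignment
  would be the upgrade path if dense candidate sets appear.
- dDDH and 16S similarities are consumed, not computed.
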