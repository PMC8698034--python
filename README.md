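# clusterline

Assembly-line analysis of modular PKS/NRPS biosynthetic gene clusters
(BGCs) for genome-mining studies of actinomycetes: parse the
domain-organization notation used in curated cluster tables, predict
product skeletons by the co-linearity rule, align module architectures to
call orthologs and whole-module indels between clusters, compare whole
cluster inventories across strains, and apply genomospecies thresholds
(gyrB marker identity, digital DNA–DNA hybridization).

## Who it is for

Natural-product genome miners who annotate type-I polyketide synthase
(PKS), type-II/III PKS, nonribosomal peptide synthetase (NRPS) and hybrid
clusters as domain-organization strings (`KS/AT_m_/DH/KR/ACP-…`,
`C/A_ser_/T-…`) and want those tables to be computable: validated,
round-trippable, and usable for product prediction and cross-strain
comparison without touching raw genome sequence.

## The model

A type-I PKS or NRPS is an assembly line of **modules**; each module is an
ordered run of catalytic domains. By the **co-linearity rule** the order
and number of modules determine the order and number of units in the
product chain:

- an NRPS extension module (C/A/T ± E/MT) contributes the residue
  activated by its adenylation (A) domain — written `x` when the substrate
  is unannotated and `y` when the module lacks an A domain;
- a KS-bearing PKS module contributes one ketide unit (`pk`), with the AT
  domain selecting malonyl (`AT_m_`) or methylmalonyl (`AT_mm_`) extenders;
- a CoA-ligase (CoL) loading module contributes the starter (`st`);
- a thioesterase (Te) or terminal reductase (TD) releases the chain.

Orthologous clusters in related strains keep nearly the same
module-by-module organization; `clusterline` aligns two module sequences
with a Needleman–Wunsch dynamic program (match score = per-module
domain-content Jaccard similarity with extender/substrate specificity
treated as part of the match; gap = one unaligned module) and calls an
ortholog when the mean pairwise similarity and both-side coverage pass
configurable thresholds. Whole-module insertions/deletions between
orthologs predict changed product skeletons.

For taxonomy, two strains are one genomospecies when digital DDH ≥ 70%
(the standard species cut-off) or gyrB identity ≥ 98.5% (the marker-gene
correspondence point for that boundary); species groups are connected
components of the same-species graph.

## Worked example

```python
from clusterline import (align_clusters, compare_inventories,
                         load_qnm_reference, load_tp_a0316, load_tp_a0468)

a, b = load_tp_a0316(), load_tp_a0468()
comparison = compare_inventories(a, b)
for ca, cb, aln in comparison.matched_pairs:
    print(f"conserved  {ca:12s} ~ {cb:12s} mean similarity {aln.mean_similarity:.3f}")
```

prints

```
conserved  t3pks-1      ~ t3pks-1      mean similarity 1.000
conserved  pks/nrps-2   ~ pks/nrps-2   mean similarity 1.000
conserved  pks/nrps-3   ~ pks/nrps-3   mean similarity 1.000
conserved  t1pks-2      ~ t1pks-2      mean similarity 0.967
```

— of 15 clusters per strain only these 4 are architecture-conserved,
consistent with the two strains being different species. Aligning the qnm
reference against its ortholog shows the single module indel:

```python
aln = align_clusters(load_qnm_reference(), a.get("t1pks-2"))
print(aln.ref_gaps)   # ['4']  — reference module 4 is absent in t1pks-2
```

so the ortholog's product is predicted one ketide unit shorter than the
reference macrolide. The `examples/` directory holds one short script per
capability (parsing/counting, product prediction, reference alignment,
inventory comparison, synthetic ortholog screening, species delimitation);
each prints its numbers with a line on what they mean. A thin CLI wraps
the same stages:

```
clusterline parse   --input src/clusterline/data/tp_a0316.tsv
clusterline compare --input-a .../tp_a0316.tsv --input-b .../tp_a0468.tsv
clusterline delimit --panel .../ddh_panel.tsv
```

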