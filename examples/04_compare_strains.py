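"""Find architecture-conserved gene clusters between two strains.

Same-type clusters are aligned module-by-module and matched one-to-one;
only pairs passing the ortholog thresholds (mean similarity and coverage)
count as conserved.  The two packaged strains, though both harboring 15
clusters, share only 4 - consistent with their being different species.
"""

from clusterline import compare_inventories, load_tp_a0316, load_tp_a0468

comparison = compare_inventories(load_tp_a0316(), load_tp_a0468())
print(f"{comparison.strain_a} vs {comparison.strain_b}:")
for a, b, aln in comparison.matched_pairs:
    print(f"  conserved  {a:12s} ~ {b:12s} "
          f"mean similarity {aln.mean_similarity:.3f}")
print(f"  {len(comparison.matched_pairs)} of "
      f"{len(comparison.matched_pairs) + len(comparison.unmatched_a)} "
      "clusters conserved")
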