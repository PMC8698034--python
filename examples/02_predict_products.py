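"""Predict product skeletons by the assembly-line co-linearity rule.

One unit per extension module: the A-domain substrate for peptides (x when
the substrate is unannotated, y when the module lacks an A domain), pk per
KS-bearing module, st for a CoA-ligase starter.  Clusters with trans-acting
standalone A domains are flagged non-colinear: their unit order follows
gene order but is not guaranteed by the assembly line.
"""

from clusterline import load_tp_a0316, predict_product

for cluster in load_tp_a0316():
    p = predict_product(cluster)
    units = p.unit_string or "-"
    print(f"{p.cluster_id:12s} {p.category:18s} {p.length_name:13s} {units}"
          f"{'' if p.colinear else '  [trans-acting]'}")

print("\nnrps-5 reads ser-pro directly off its two modules; incomplete"
      " clusters (t1pks-4, nrps-4) are unpredictable by construction.")
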