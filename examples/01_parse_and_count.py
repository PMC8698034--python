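"""Parse a packaged cluster table and count assembly-line modules.

Each row of the table is one ORF with its domain-organization string;
modules (loading + extension) are the positions of the assembly line, so
their count bounds the size of the product skeleton.
"""

from clusterline import count_modules, load_tp_a0316

inventory = load_tp_a0316()
print(f"{inventory.strain_id}: {len(inventory.clusters)} gene clusters")
for cluster in inventory:
    print(f"  {cluster.cluster_id:12s} {count_modules(cluster):3d} modules"
          f"{'' if cluster.complete else '  (incomplete)'}")

big = inventory.get("t1pks-2")
print(f"\nThe giant macrolide-type line {big.cluster_id} spans "
      f"{len(big.orfs)} megasynthase genes and {count_modules(big)} modules "
      "- one polyketide extender unit per KS-bearing module.")
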