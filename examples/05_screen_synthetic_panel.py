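"""Screen a synthetic strain panel for orthologs of a reference cluster.

Half the synthetic strains carry a mutated copy of the reference (up to 3
module indels plus domain swaps and specificity flips); the screen should
flag exactly those strains as ortholog-positive.
"""

from clusterline import (
    GeneratorConfig, generate_inventory, load_qnm_reference,
    mutate_cluster, screen_for_ortholog,
)

reference = load_qnm_reference()
panel, truth = [], []
for k in range(10):
    strain = generate_inventory(
        GeneratorConfig(seed=300 + k, n_modules=(3, 10)), 3, f"SYN-{k}")
    if k % 2 == 0:
        copy, _ = mutate_cluster(
            reference, GeneratorConfig(seed=k, mutation_rates=(0.06, 0.03, 0.05, 0.05)),
            max_indels=3)
        copy.strain_id = strain.strain_id
        strain.clusters.append(copy)
    panel.append(strain)
    truth.append(k % 2 == 0)

results = screen_for_ortholog(reference, panel)
correct = 0
for r, seeded in zip(results, truth):
    mark = "ok" if r.present == seeded else "MISS"
    correct += r.present == seeded
    print(f"{r.strain_id:8s} seeded={seeded!s:5s} present={r.present!s:5s} "
          f"mean={r.mean_similarity:.3f}  {mark}")
print(f"\n{correct}/{len(results)} strains called correctly")
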