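"""Apply genomospecies thresholds to the packaged relatedness panel.

Pairs at or above 70% digital DDH (or 98.5% gyrB identity) are conspecific;
connected components of the same-species graph form the genomospecies.
"""

from clusterline import load_ddh_panel, panel_verdicts

verdicts, groups = panel_verdicts(load_ddh_panel())
for v in verdicts[:5]:
    print(f"{v.strain_a} | {v.strain_b}: {v.metric}={v.value:.1f}% "
          f"-> {v.verdict}")
print("...")
for i, group in enumerate(g for g in groups if len(g) > 1):
    print(f"genomospecies group {i + 1}: {', '.join(group)}")
singletons = sum(1 for g in groups if len(g) == 1)
print(f"plus {singletons} strains left as independent genomospecies")
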