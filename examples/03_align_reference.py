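"""Align the quinolidomicin reference line against its ortholog.

A module-level global alignment shows the single whole-module deletion that
distinguishes the ortholog: reference module 4 has no counterpart ('-'),
predicting a product one ketide unit shorter than the reference macrolide.
"""

from clusterline import align_clusters, load_qnm_reference, load_tp_a0316, render_alignment

qnm = load_qnm_reference()
query = load_tp_a0316().get("t1pks-2")
alignment = align_clusters(qnm, query)
print(render_alignment(qnm, query, alignment))
print(f"\nreference modules missing from the query: {alignment.ref_gaps}")
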