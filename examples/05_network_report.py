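"""Segment significant links into subnetwork components and hubs.

Builds a small significant-link graph by hand (as the permutation test
would emit it) and derives the network report: connected components ordered
by edge count and nodes with strictly more than 3 disconnections (hubs).
"""

import numpy as np

from disconnectomics import ClsmResult, Parcellation, make_report

labels = np.zeros((10, 2, 2), dtype=int)
names, hemis = {}, {}
for lab, (name, hemi) in enumerate(
    [("SPL_R", "right"), ("INS_R", "right"), ("TP_R", "right"), ("MTG_R", "right"),
     ("FUS_R", "right"), ("IFG_R", "right"), ("OFC_R", "right"), ("OFC_L", "left")],
    start=1,
):
    labels[lab, 0, 0] = lab
    names[lab], hemis[lab] = name, hemi
parcellation = Parcellation(labels, np.eye(4), names, hemis)

# one 7-node component with an SPL-like hub, plus an isolated interhemispheric link
link_index = [(1, 2), (1, 3), (1, 4), (1, 5), (2, 6), (7, 8), (3, 4)]
result = ClsmResult(
    beta=np.array([0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3]),
    p_value=np.full(7, 0.0009),
    significant=np.ones(7, dtype=bool),
    chosen_C=2.0**-16,
    n_permutations=1000,
    alpha=0.05,
    link_index=link_index,
)

report = make_report(result, parcellation, hub_threshold=3)
print("components (node sets, largest subnetwork first):")
for comp in report.components:
    print("  ", sorted(names[n] for n in comp))
print("hubs (degree > 3 within the significant graph):")
for node, degree in report.hubs:
    print(f"   {names[node]}: {degree} disconnections")
inter = report.edge_table[report.edge_table.interhemispheric]
print("interhemispheric links:", [f"{r.name_a}–{r.name_b}" for r in inter.itertuples()])
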