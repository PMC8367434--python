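"""Cross-sample normalization, clustering and the comparison figures.

Within-pathway normalization divides a pathway's abundance in each sample by
its total over samples, putting pathways of very different magnitude on one
0-1 scale; samples are then clustered on Bray-Curtis dissimilarity, and
heatmap + per-cycle sketch figures are written as SVG and PNG.
"""

import pandas as pd

from biogeopath import bubble_transform, cluster_samples, normalize_across_samples, render_cycle_sketch, render_heatmap

table = pd.DataFrame(
    {"vent1": [2.0, 0.0, 10.0], "vent2": [3.0, 0.0, 30.0], "plume": [5.0, 0.0, 60.0]},
    index=["asr", "dnra", "dmsp_cleavage"],
)
normalized = normalize_across_samples(table)
print(normalized.round(3))
# each nonzero row sums to 1; the undetected dnra row stays all-zero

print("bubble-scale of 0.001 and 1:", list(bubble_transform([0.001, 1.0])))
# log10(x * 1000): detection-floor abundances land near 0, unit abundance at 3

order, _, _ = cluster_samples(table)
print("sample order after clustering:", order)

render_heatmap(table, "scratch/heatmap")
geometry = render_cycle_sketch(normalized, "sulfur", "scratch/sketch_sulfur", {"asr": "sulfur"})
print("sketch marker areas (pt^2):", {k: round(v, 1) for k, v in geometry.items()})
# marker area is linear in the normalized fraction, so area ratios between
# samples read directly as abundance ratios
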