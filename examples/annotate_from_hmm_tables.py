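"""Annotate genes from hmmsearch tabular output with per-family thresholds.

KO families are accepted by their own bit-score cutoff (full-sequence or
best-domain, per the threshold table); custom organosulfur families by
per-family E-value ceilings. A gene keeps every accepted family.
"""

from biogeopath import assign_custom_families, assign_kos, dmsp_family_cutoffs, merge_annotations
from biogeopath.model import HmmHit, KoThresholdEntry, ScoreType

ko_hits = [
    HmmHit("g1", "K00392", full_score=210.3, dom_score=209.0, evalue=1e-50),
    HmmHit("g2", "K00392", full_score=120.0, dom_score=118.0, evalue=1e-20),  # too weak
    HmmHit("g1", "K00380", full_score=180.0, dom_score=175.0, evalue=1e-40),
]
thresholds = {
    "K00392": KoThresholdEntry("K00392", 150.0, ScoreType.FULL),
    "K00380": KoThresholdEntry("K00380", 100.0, ScoreType.FULL),
}
ko_ann = assign_kos(ko_hits, thresholds)

dmsp_hits = [
    HmmHit("g3", "DmdA", full_score=460.0, dom_score=455.0, evalue=1e-140),  # passes 1e-130
    HmmHit("g4", "DmdA", full_score=120.0, dom_score=118.0, evalue=1e-90),   # fails
]
custom_ann = assign_custom_families(dmsp_hits, dmsp_family_cutoffs())

merged = merge_annotations(ko_ann, custom_ann)
for gene, ann in sorted(merged.items()):
    print(f"{gene}: {sorted(ann.families)}")
# g1 carries both accepted KOs; g2 and g4 fell below their cutoffs.
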