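"""Length-normalized gene abundance (TPM) and aggregation to gene families.

TPM divides each gene's read rate (reads/length) by the sample total and
scales to one million, so values are comparable across genes and samples.
A gene carrying several functions contributes its full TPM to each.
"""

from biogeopath import aggregate_profile, compute_tpm
from biogeopath.model import CountRecord, GeneAnnotation

records = [
    CountRecord("geneA", length=100, count=10),  # rate 0.10
    CountRecord("geneB", length=400, count=20),  # rate 0.05
    CountRecord("geneC", length=500, count=0),   # undetected
]
tpms = compute_tpm(records)
for t in tpms:
    print(f"{t.gene_id}: TPM = {t.tpm:,.2f}")
# geneA gets 2/3 of the million, geneB 1/3, geneC 0.

annotations = {
    "geneA": GeneAnnotation("geneA", {"K00392"}),
    "geneB": GeneAnnotation("geneB", {"K00380", "K00381"}),  # bifunctional
}
profile = aggregate_profile("demo", tpms, annotations)
for fam, v in sorted(profile.abundance.items()):
    print(f"{fam}: {v:,.2f}")
# K00380 and K00381 each receive geneB's full TPM — no splitting.
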