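"""Evaluate pathway relative abundance from a family-level profile.

A pathway is alternative routes of required components; its abundance is the
mean abundance of each route's components, summed over routes. Undetected
components keep the divisor (a missing subunit dilutes, it does not vanish).
"""

from biogeopath import builtin_definitions, pathway_abundance
from biogeopath.model import AbundanceProfile

profile = AbundanceProfile(
    "vent_sample",
    {
        # sulfite -> sulfide, two routes: Sir (K00392) or CysJI (K00380+K00381)
        "K00392": 4.0, "K00380": 2.0, "K00381": 6.0,
        # nitrite -> ammonia, two routes: NirBD or NrfAH
        "K00362": 1.0, "K00363": 3.0, "K03385": 2.0, "K15876": 4.0,
        # thiosulfate reductase subunits; phsB was not detected
        "phsA": 6.0, "phsC": 3.0,
    },
)

defs = {d.pathway_id: d for d in builtin_definitions()}
for pid in ("asr", "dnra", "thiosulfate_disproportionation"):
    d = defs[pid]
    print(f"{d.display_name}: {pathway_abundance(d, profile):.4f}")

# Assimilatory sulfite reduction = 4 + (2+6)/2         = 8.0
# Nitrite reduction to ammonia   = (1+3)/2 + (2+4)/2   = 5.0
# Thiosulfate disproportionation = (6+0+3)/3           = 3.0  (phsB absent,
#   divisor stays at the 3 essential subunits)
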