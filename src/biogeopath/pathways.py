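"""Evaluate pathway relative abundance from family-level profiles.

A pathway is a set of alternative *routes*; each route is an ordered list of
required *components* (enzymes or subunits), and each component may list
interchangeable gene families. The pathway's relative abundance in a sample is

    A = sum over routes m of  ( a_{m,1} + a_{m,2} + ... + a_{m,n} ) / n

i.e. the mean abundance of a route's n components, summed across routes.
Averaging within a route (rather than summing) makes pathways of different
gene counts comparable within a sample; a component that was not detected
contributes 0 to the numerator while the divisor stays at n, because the
subunit is still required (e.g. thiosulfate reductase phsABC is always
divided by 3 even when phsB is missing from the assembly).

Alternatives *within* a component pool by sum: e.g. the DMSP-cleavage step is
the pooled abundance of all eight lyase families.

Definitions are data, not code — the engine evaluates whatever the definition
schema encodes, and the built-in set can be extended from user TSV files in
the same schema.
"""

from __future__ import annotations

from importlib import resources
from typing import Sequence

import pandas as pd

from . import formats
from .model import AbundanceProfile, Component, PathwayDefinition, Route


def component_abundance(component: Component, profile: AbundanceProfile) -> float:
    """Pooled (summed) abundance of a component's alternative families."""
    return sum(profile.get(f) for f in component.families)


def route_abundance(route: Route, profile: AbundanceProfile) -> float:
    """Mean component abundance over the route's n required components."""
    return sum(component_abundance(c, profile) for c in route.components) / route.n


def pathway_abundance(definition: PathwayDefinition, profile: AbundanceProfile) -> float:
    """Sum of route abundances over the pathway's alternative routes."""
    return sum(route_abundance(r, profile) for r in definition.routes)


def build_pathway_table(
    definitions: Sequence[PathwayDefinition],
    profiles: Sequence[AbundanceProfile],
) -> pd.DataFrame:
    """Evaluate every definition against every profile.

    Rows follow definition order, columns follow input sample order; pathways
    absent everywhere keep their all-zero row.
    """
    if not profiles:
        raise ValueError("at least one profile is required")
    sample_ids = [p.sample_id for p in profiles]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError(f"duplicate sample ids: {sample_ids}")
    data = {
        p.sample_id: [pathway_abundance(d, p) for d in definitions] for p in profiles
    }
    df = pd.DataFrame(data, index=[d.pathway_id for d in definitions])
    df.index.name = "pathway_id"
    return df[sample_ids]


def builtin_definitions() -> list[PathwayDefinition]:
    """The shipped pathway-definition set.

    Includes the worked sulfur/nitrogen examples (assimilatory sulfite
    reduction, dissimilatory nitrite reduction to ammonia, thiosulfate
    disproportionation), the DMSP cycle (synthesis, demethylation, cleavage,
    DMS/DMSO/MeSH interconversions), the three sulfoquinovose degradation
    pathways and isoprene degradation. Further pathways load from user TSV
    files in the same schema via :func:`biogeopath.formats.read_pathway_definitions`.
    """
    ref = resources.files("biogeopath.data").joinpath("pathways_builtin.tsv")
    with resources.as_file(ref) as path:
        return formats.read_pathway_definitions(path)
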