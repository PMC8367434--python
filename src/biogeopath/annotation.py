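"""Threshold-based functional annotation of genes from homology-search hits.

Two databases drive annotation. KEGG Orthology (KO) families each carry their
own adaptive bit-score cutoff and a score type saying whether it applies to
the full-sequence or the best-domain score — this mirrors hmmsearch's
``-T`` / ``--domT`` reporting thresholds, so acceptance is inclusive
(score >= threshold). Custom organosulfur families (DMSP cycling and related
genes) are filtered instead by per-family E-value ceilings (evalue <= cutoff).

A gene keeps *every* family it is accepted against, across both databases:
there is deliberately no best-hit resolution, so multifunctional genes
contribute to all of their functions downstream.
"""

from __future__ import annotations

import logging
from importlib import resources
from typing import Iterable, Mapping

from . import formats
from .model import (
    CustomFamilyCutoff,
    GeneAnnotation,
    HmmHit,
    KoThresholdEntry,
    ScoreType,
)

logger = logging.getLogger(__name__)

#: E-value ceiling used for KO families whose cutoff table row carries no
#: usable bit-score threshold.
DEFAULT_FALLBACK_EVALUE = 1e-5


def assign_kos(
    hits: Iterable[HmmHit],
    thresholds: Mapping[str, KoThresholdEntry],
    fallback_evalue: float = DEFAULT_FALLBACK_EVALUE,
) -> dict[str, GeneAnnotation]:
    """Assign KO families to genes by each KO's own score cutoff.

    A hit is accepted when its score of the KO's score type meets the KO's
    threshold (inclusive). Threshold-less KOs fall back to
    ``evalue <= fallback_evalue``. Hits to families absent from ``thresholds``
    are dropped (their count is logged). Duplicate accepted hits to the same
    (gene, family) pair count once.
    """
    annotations: dict[str, GeneAnnotation] = {}
    n_unknown = 0
    n_fallback = 0
    for hit in hits:
        entry = thresholds.get(hit.family_id)
        if entry is None:
            n_unknown += 1
            continue
        if entry.has_threshold:
            score = (
                hit.full_score if entry.score_type is ScoreType.FULL else hit.dom_score
            )
            accepted = score >= entry.threshold
        else:
            accepted = hit.evalue <= fallback_evalue
            if accepted:
                n_fallback += 1
        if accepted:
            ann = annotations.setdefault(hit.gene_id, GeneAnnotation(hit.gene_id))
            ann.families.add(hit.family_id)
    if n_unknown:
        logger.info("dropped %d hits to families with no threshold entry", n_unknown)
    if n_fallback:
        logger.info(
            "accepted %d hits via the threshold-less E-value fallback (<= %g)",
            n_fallback,
            fallback_evalue,
        )
    return annotations


def assign_custom_families(
    hits: Iterable[HmmHit],
    cutoffs: Iterable[CustomFamilyCutoff],
) -> dict[str, GeneAnnotation]:
    """Assign custom families to genes by per-family E-value ceilings.

    Unlike the KO path, a hit against a family with no configured ceiling is
    a configuration error: a custom database must be fully specified.
    """
    by_family = {c.family_id: c.max_evalue for c in cutoffs}
    annotations: dict[str, GeneAnnotation] = {}
    for hit in hits:
        if hit.family_id not in by_family:
            raise KeyError(
                f"no E-value cutoff configured for custom family {hit.family_id!r}"
            )
        if hit.evalue <= by_family[hit.family_id]:
            ann = annotations.setdefault(hit.gene_id, GeneAnnotation(hit.gene_id))
            ann.families.add(hit.family_id)
    return annotations


def merge_annotations(
    a: Mapping[str, GeneAnnotation], b: Mapping[str, GeneAnnotation]
) -> dict[str, GeneAnnotation]:
    """Per-gene set union of two annotation maps."""
    merged: dict[str, GeneAnnotation] = {}
    for source in (a, b):
        for gene_id, ann in source.items():
            tgt = merged.setdefault(gene_id, GeneAnnotation(gene_id))
            tgt.families |= ann.families
    return merged


def _load_cutoff_data(filename: str) -> list[CustomFamilyCutoff]:
    ref = resources.files("biogeopath.data").joinpath(filename)
    with resources.as_file(ref) as path:
        return formats.read_custom_cutoffs(path)


def dmsp_family_cutoffs() -> list[CustomFamilyCutoff]:
    """The 20 DMSP-cycling gene families and their curated E-value ceilings.

    Covers DMSP synthesis (DSYB, DsyB, MmtN), demethylation (DmdA, DmdB,
    DmdC, DmdD, AcuH), the eight cleavage lyases (DddD/K/L/P/Q/W/Y, Alma1),
    DMS oxidation (DmoA), DMSO reduction (DorA), methanethiol S-methylation
    (MddA) and methanethiol oxidation (MTO).
    """
    return _load_cutoff_data("dmsp_cutoffs.tsv")


def organosulfur_family_cutoffs() -> list[CustomFamilyCutoff]:
    """The DMSP set plus the DMS→DMSO families (DdhA, DdhB, DdhC, Tmm).

    The DMS dehydrogenase subunits and Tmm sit outside the core 20-family
    DMSP database but are needed to evaluate the DMS→DMSO pathway; each uses
    a 1e-30 ceiling. See docs/methods.md for the naming ambiguity around the
    Ddh subunits.
    """
    return dmsp_family_cutoffs() + _load_cutoff_data("organosulfur_extra.tsv")
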