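"""Per-gene TPM and aggregation to per-family relative-abundance profiles.

TPM (transcripts per million) expresses a gene's relative abundance within one
sample as its length-normalized read rate divided by the sample's total rate,
scaled to 10^6:

    TPM_i = 10^6 * (X_i / L_i) / sum_j (X_j / L_j)

where X_i is the number of reads mapped to gene i and L_i its length in
nucleotides. In coverage mode the per-base average coverage stands in for
X_i/L_i directly (coverage = X_i * read_length / L_i, so the constant read
length cancels in the ratio).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd

from .model import AbundanceProfile, CountRecord, GeneAnnotation, GeneTpm

TPM_SCALE = 1e6


def compute_tpm(records: Sequence[CountRecord]) -> list[GeneTpm]:
    """Compute per-gene TPM for one sample.

    If every gene has zero signal, every TPM is zero (empty controls flow
    through rather than erroring). Otherwise the TPMs sum to 10^6.
    """
    rates = [r.rate for r in records]
    total = sum(rates)
    if total == 0.0:
        return [GeneTpm(r.gene_id, 0.0) for r in records]
    return [
        GeneTpm(r.gene_id, TPM_SCALE * rate / total)
        for r, rate in zip(records, rates)
    ]


def aggregate_profile(
    sample_id: str,
    tpms: Iterable[GeneTpm],
    annotations: Mapping[str, GeneAnnotation],
) -> AbundanceProfile:
    """Sum gene TPM into per-family relative abundance.

    A gene annotated with k families contributes its full TPM to each of the
    k families (no splitting). Unannotated genes contribute to no family but
    already diluted the TPM denominator.
    """
    abundance: dict[str, float] = {}
    for gt in tpms:
        ann = annotations.get(gt.gene_id)
        if ann is None:
            continue
        for family in ann.families:
            abundance[family] = abundance.get(family, 0.0) + gt.tpm
    return AbundanceProfile(sample_id=sample_id, abundance=abundance)


def gene_tpm_frame(per_sample: Mapping[str, Sequence[GeneTpm]]) -> pd.DataFrame:
    """Gene × sample TPM matrix (absent genes are 0)."""
    cols = {
        sample: {gt.gene_id: gt.tpm for gt in tpms}
        for sample, tpms in per_sample.items()
    }
    df = pd.DataFrame(cols).fillna(0.0)
    df.index.name = "gene_id"
    return df[list(per_sample)]


def profile_frame(profiles: Sequence[AbundanceProfile]) -> pd.DataFrame:
    """Family × sample relative-abundance matrix from per-sample profiles."""
    ids = [p.sample_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate sample ids: {ids}")
    df = pd.DataFrame({p.sample_id: p.abundance for p in profiles}).fillna(0.0)
    df.index.name = "family_id"
    return df[ids]
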