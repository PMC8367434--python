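"""Readers and writers for every external table the pipeline touches.

HMMER3 tabular output is whitespace-aligned, not TSV, so the hit reader
splits on runs of whitespace at the documented column positions and treats
the remainder of each line as free-text description. Everything that *is*
tab-separated (ko_list thresholds, counts, pathway definitions, abundance
tables) goes through pandas with UTF-8, tab separator and ``.`` decimal.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd

from .model import (
    Component,
    CountMode,
    CountRecord,
    CustomFamilyCutoff,
    Cycle,
    GeneAnnotation,
    HmmHit,
    KoThresholdEntry,
    PathwayDefinition,
    Route,
    ScoreType,
)

PathLike = Union[str, os.PathLike]


class ParseError(ValueError):
    """A malformed row in an input table, reported with its line number."""


class SchemaError(ValueError):
    """An input table whose columns or structure violate the expected schema."""


# ---------------------------------------------------------------------------
# HMMER3 tabular results

# Column positions per the HMMER3 user-guide layout.
_TBLOUT_NCOL = 18
_DOMTBLOUT_NCOL = 22
_TBLOUT_IDX = {"gene": 0, "family": 2, "evalue": 4, "full": 5, "dom": 8}
_DOMTBLOUT_IDX = {"gene": 0, "family": 3, "evalue": 6, "full": 7, "dom": 13}


def read_hmm_table(path: PathLike, dialect: str) -> list[HmmHit]:
    """Parse an hmmsearch ``--tblout`` or ``--domtblout`` file into hits.

    Every data row becomes one :class:`HmmHit`; multiple rows for the same
    (gene, family) pair are all returned — downstream annotation deduplicates.
    ``#`` comment lines are skipped. Malformed rows raise :class:`ParseError`
    naming the 1-based line number.
    """
    if dialect == "tblout":
        idx, ncol = _TBLOUT_IDX, _TBLOUT_NCOL
    elif dialect == "domtblout":
        idx, ncol = _DOMTBLOUT_IDX, _DOMTBLOUT_NCOL
    else:
        raise ValueError(f"unknown HMMER table dialect: {dialect!r}")

    hits: list[HmmHit] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.split(None, ncol)
            if len(fields) < ncol:
                raise ParseError(
                    f"{path}:{lineno}: expected >= {ncol} columns, got {len(fields)}"
                )
            try:
                hit = HmmHit(
                    gene_id=fields[idx["gene"]],
                    family_id=fields[idx["family"]],
                    full_score=float(fields[idx["full"]]),
                    dom_score=float(fields[idx["dom"]]),
                    evalue=float(fields[idx["evalue"]]),
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            hits.append(hit)
    return hits


def write_hmm_table(hits: Iterable[HmmHit], path: PathLike, dialect: str) -> None:
    """Write hits back out in a minimal HMMER3-layout table (round-trip aid)."""
    if dialect == "tblout":
        idx, ncol = _TBLOUT_IDX, _TBLOUT_NCOL
    elif dialect == "domtblout":
        idx, ncol = _DOMTBLOUT_IDX, _DOMTBLOUT_NCOL
    else:
        raise ValueError(f"unknown HMMER table dialect: {dialect!r}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# synthetic HMMER3 %s table\n" % dialect)
        for h in hits:
            fields = ["-"] * ncol
            fields[idx["gene"]] = h.gene_id
            fields[idx["family"]] = h.family_id
            fields[idx["evalue"]] = repr(h.evalue)
            fields[idx["full"]] = repr(h.full_score)
            fields[idx["dom"]] = repr(h.dom_score)
            fh.write(" ".join(fields) + " -\n")


# ---------------------------------------------------------------------------
# KO threshold table (ko_list dialect)

_KO_LIST_REQUIRED = ("knum", "threshold", "score_type")


def read_ko_thresholds(path: PathLike) -> dict[str, KoThresholdEntry]:
    """Read a KO cutoff table in the ko_list dialect.

    Rows whose threshold is non-numeric (upstream marks some KOs ``-``) are
    retained flagged threshold-less; annotation then falls back to an E-value
    ceiling for those families.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _KO_LIST_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required ko_list columns: {missing}")
    out: dict[str, KoThresholdEntry] = {}
    for row in df.itertuples(index=False):
        ko = getattr(row, "knum")
        raw_thr = getattr(row, "threshold")
        raw_type = getattr(row, "score_type")
        definition = getattr(row, "definition", "") if "definition" in df.columns else ""
        try:
            threshold = float(raw_thr)
            score_type = ScoreType(raw_type)
        except ValueError:
            threshold, score_type = None, None
        out[ko] = KoThresholdEntry(
            family_id=ko,
            threshold=threshold,
            score_type=score_type,
            definition=definition if isinstance(definition, str) else "",
        )
    return out


def write_ko_thresholds(entries: Mapping[str, KoThresholdEntry], path: PathLike) -> None:
    rows = []
    for e in entries.values():
        rows.append(
            {
                "knum": e.family_id,
                "threshold": "-" if e.threshold is None else repr(e.threshold),
                "score_type": "-" if e.score_type is None else e.score_type.value,
                "definition": e.definition,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Custom family cutoffs

def read_custom_cutoffs(path: PathLike) -> list[CustomFamilyCutoff]:
    """Read a two-column TSV of custom family E-value ceilings."""
    # parse the ceiling with Python's float() — pandas' fast parser can be
    # one ulp off on extreme exponents like 1e-130
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("family_id", "max_evalue") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns: {missing}")
    return [
        CustomFamilyCutoff(family_id=r.family_id, max_evalue=float(r.max_evalue))
        for r in df.itertuples(index=False)
    ]


def write_custom_cutoffs(cutoffs: Iterable[CustomFamilyCutoff], path: PathLike) -> None:
    pd.DataFrame(
        [{"family_id": c.family_id, "max_evalue": repr(c.max_evalue)} for c in cutoffs]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Counts table

def read_counts_table(path: PathLike) -> list[CountRecord]:
    """Read a per-gene counts/coverage TSV.

    Requires columns ``gene_id``, ``length`` and exactly one of ``reads`` /
    ``avg_coverage``; the present column sets the record mode.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "length"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    has_reads = "reads" in df.columns
    has_cov = "avg_coverage" in df.columns
    if has_reads == has_cov:
        raise SchemaError(
            f"{path}: exactly one of 'reads' / 'avg_coverage' must be present"
        )
    records = []
    for row in df.itertuples(index=False):
        kwargs = (
            {"count": float(row.reads)}
            if has_reads
            else {"coverage": float(row.avg_coverage)}
        )
        records.append(
            CountRecord(gene_id=str(row.gene_id), length=int(row.length), **kwargs)
        )
    return records


def write_counts_table(records: Sequence[CountRecord], path: PathLike) -> None:
    if not records:
        raise ValueError("cannot write an empty counts table")
    modes = {r.mode for r in records}
    if len(modes) != 1:
        raise ValueError("all records in one counts table must share a mode")
    mode = modes.pop()
    col = "reads" if mode is CountMode.READS else "avg_coverage"
    pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "length": r.length,
                col: repr(r.count if mode is CountMode.READS else r.coverage),
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Pathway definition files
#
# One row per component:
#   pathway_id  display_name  cycle  route_index  component_index  fam1[,fam2,...]
# route/component indices are 1-based and consecutive within their parent.

_PATHWAY_COLS = [
    "pathway_id",
    "display_name",
    "cycle",
    "route_index",
    "component_index",
    "families",
]


def read_pathway_definitions(path: PathLike) -> list[PathwayDefinition]:
    """Read a pathway-definition TSV into validated definitions, in file order."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _PATHWAY_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns: {missing}")

    # group contiguous row blocks by pathway id; a block reappearing after a
    # different pathway intervened is a duplicate definition
    order: list[str] = []
    rows_by_pathway: dict[str, list] = {}
    prev: str | None = None
    for row in df.itertuples(index=False):
        pid = row.pathway_id
        if pid != prev and pid in rows_by_pathway:
            raise SchemaError(f"{path}: duplicate pathway id {pid!r}")
        if pid not in rows_by_pathway:
            order.append(pid)
            rows_by_pathway[pid] = []
        rows_by_pathway[pid].append(row)
        prev = pid

    definitions: list[PathwayDefinition] = []
    for pid in order:
        rows = rows_by_pathway[pid]
        display = rows[0].display_name
        try:
            cycle = Cycle(rows[0].cycle)
        except ValueError as exc:
            raise SchemaError(f"{path}: unknown cycle {rows[0].cycle!r}") from exc

        routes_map: dict[int, dict[int, Component]] = {}
        for row in rows:
            try:
                ri = int(row.route_index)
                ci = int(row.component_index)
            except ValueError as exc:
                raise SchemaError(f"{path}: non-integer route/component index") from exc
            fams = [f.strip() for f in str(row.families).split(",") if f.strip()]
            if not fams:
                raise SchemaError(f"{path}: pathway {pid!r} has an empty component")
            routes_map.setdefault(ri, {})
            if ci in routes_map[ri]:
                raise SchemaError(
                    f"{path}: pathway {pid!r} route {ri} repeats component {ci}"
                )
            routes_map[ri][ci] = Component.of(*fams)

        if sorted(routes_map) != list(range(1, len(routes_map) + 1)):
            raise SchemaError(f"{path}: pathway {pid!r} route indices not 1..m")
        routes = []
        for ri in sorted(routes_map):
            comps = routes_map[ri]
            if sorted(comps) != list(range(1, len(comps) + 1)):
                raise SchemaError(
                    f"{path}: pathway {pid!r} route {ri} component indices not 1..n"
                )
            routes.append(Route(tuple(comps[ci] for ci in sorted(comps))))
        definitions.append(
            PathwayDefinition(
                pathway_id=pid,
                display_name=display,
                cycle=cycle,
                routes=tuple(routes),
            )
        )
    return definitions


def write_pathway_definitions(
    definitions: Sequence[PathwayDefinition], path: PathLike
) -> None:
    rows = []
    for d in definitions:
        for ri, route in enumerate(d.routes, start=1):
            for ci, comp in enumerate(route.components, start=1):
                rows.append(
                    {
                        "pathway_id": d.pathway_id,
                        "display_name": d.display_name,
                        "cycle": d.cycle.value,
                        "route_index": ri,
                        "component_index": ci,
                        "families": ",".join(sorted(comp.families)),
                    }
                )
    pd.DataFrame(rows, columns=_PATHWAY_COLS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Annotation and abundance tables

def write_annotation_table(
    annotations: Mapping[str, GeneAnnotation], path: PathLike
) -> None:
    """Write gene → comma-joined family ids, one row per gene."""
    pd.DataFrame(
        [
            {"gene_id": g, "families": ",".join(sorted(a.families))}
            for g, a in sorted(annotations.items())
        ]
    ).to_csv(path, sep="\t", index=False)


def read_annotation_table(path: PathLike) -> dict[str, GeneAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("gene_id", "families"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    out = {}
    for row in df.itertuples(index=False):
        fams = {f for f in row.families.split(",") if f}
        out[row.gene_id] = GeneAnnotation(gene_id=row.gene_id, families=fams)
    return out


def write_matrix(df: pd.DataFrame, path: PathLike) -> None:
    """Write a feature × sample matrix as TSV (UTF-8, '.' decimal)."""
    df.to_csv(path, sep="\t", index=True, index_label=df.index.name or "id")


def read_matrix(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
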