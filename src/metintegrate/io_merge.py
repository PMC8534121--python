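"""Readers/writers for the pipeline's file formats, and cohort merging.

Formats handled:

* expression — GCT 1.2 (``#1.2`` header, dimensions line, Name and
  Description columns) or plain TSV with a header row; sample class and
  cohort labels travel in a small sample-metadata TSV since neither
  format carries them;
* gene sets — GMT (set id, description, members, tab-separated);
* dependency matrices, drug-response vectors, annotation tables and
  simulation truth — plain TSV.

All files are UTF-8 and tab-delimited, genes as row keys.  ``read`` and
``write`` are inverses on valid files; TSV expression round-trips
bit-exactly because floats are serialised with full repr precision.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    AnnotationTables,
    DependencyMatrix,
    ExpressionMatrix,
    GeneSetCollection,
    SimulationTruth,
)
from .errors import FormatError, InvalidInputError, MergeError

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "merge_cohorts",
    "read_dependency",
    "write_dependency",
    "read_response",
    "write_response",
    "read_annotations",
    "write_annotations",
    "write_truth",
]


def _parse_numeric_body(df: pd.DataFrame, path) -> pd.DataFrame:
    out = df.apply(pd.to_numeric, errors="coerce")
    bad = out.isna() & df.notna()
    if bad.to_numpy().any():
        r = bad.any(axis=1).idxmax()
        c = bad.loc[r].idxmax()
        raise FormatError(f"{path}: non-numeric cell at row {r!r}, column {c!r}")
    if out.isna().to_numpy().any():
        r = out.isna().any(axis=1).idxmax()
        raise FormatError(f"{path}: missing value in row {r!r}")
    # astype(float) parses via strtod and round-trips repr() exactly,
    # unlike to_numeric (used above only to locate bad cells)
    return df.astype(float)


def _check_unique(index: pd.Index, what: str, path) -> None:
    if index.has_duplicates:
        dup = index[index.duplicated()][0]
        raise FormatError(f"{path}: duplicate {what} id {dup!r}")


def _read_sample_meta(path) -> tuple[pd.Series, pd.Series]:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample", "class"):
        if col not in meta.columns:
            raise FormatError(f"{path}: sample metadata needs a {col!r} column")
    meta = meta.set_index("sample")
    cohort = meta["cohort"] if "cohort" in meta.columns else None
    return meta["class"], cohort


def read_expression(path, format: str = "tsv", sample_meta=None) -> ExpressionMatrix:
    """Read an expression matrix from GCT 1.2 or TSV.

    ``sample_meta``, when given, is a TSV with columns ``sample``,
    ``class`` and optionally ``cohort``; without it every sample gets
    the class ``unknown``.
    """
    path = Path(path)
    if format == "gct":
        with open(path, encoding="utf-8") as fh:
            version = fh.readline().strip()
            if version != "#1.2":
                raise FormatError(f"{path}: expected '#1.2' header, got {version!r}")
            dims = fh.readline().split()
            if len(dims) != 2:
                raise FormatError(f"{path}: malformed dimensions line")
            n_genes, n_samples = int(dims[0]), int(dims[1])
            body = pd.read_csv(fh, sep="\t", index_col=0, dtype=str)
        if "Description" in body.columns:
            body = body.drop(columns="Description")
        if body.shape != (n_genes, n_samples):
            raise FormatError(
                f"{path}: header declares {n_genes}x{n_samples} "
                f"but body is {body.shape[0]}x{body.shape[1]}"
            )
    elif format == "tsv":
        body = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    else:
        raise FormatError(f"unknown expression format {format!r}")

    body.index.name = None
    body.columns.name = None
    _check_unique(body.index, "gene", path)
    _check_unique(body.columns, "sample", path)
    values = _parse_numeric_body(body, path)

    if sample_meta is not None:
        sample_class, cohort = _read_sample_meta(sample_meta)
    else:
        sample_class, cohort = pd.Series("unknown", index=values.columns), None
    return ExpressionMatrix(values=values, sample_class=sample_class, cohort=cohort)


def write_expression(em: ExpressionMatrix, path, format: str = "tsv",
                     sample_meta=None) -> None:
    """Write expression as GCT 1.2 or TSV, plus optional sample metadata."""
    path = Path(path)
    if format == "gct":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("#1.2\n")
            fh.write(f"{em.n_genes}\t{em.n_samples}\n")
            fh.write("Name\tDescription\t" + "\t".join(em.sample_ids) + "\n")
            for gene, row in zip(em.gene_ids, em.values.to_numpy()):
                fh.write(gene + "\tna\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    elif format == "tsv":
        out = em.values.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t")
    else:
        raise FormatError(f"unknown expression format {format!r}")
    if sample_meta is not None:
        meta = pd.DataFrame(
            {"sample": em.sample_ids,
             "class": em.sample_class.to_numpy(),
             "cohort": em.cohort.to_numpy()}
        )
        meta.to_csv(sample_meta, sep="\t", index=False)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT gene-set file; duplicate members are dropped with a warning."""
    coll = GeneSetCollection()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs id, description "
                                  "and at least one member")
            set_id, desc, members = fields[0], fields[1], fields[2:]
            members = [m for m in members if m]
            if len(set(members)) != len(members):
                logger.warning("%s:%d: duplicate members in set %s dropped",
                               path, lineno, set_id)
            if set_id in coll:
                raise FormatError(f"{path}:{lineno}: duplicate set id {set_id!r}")
            coll.add(set_id, desc, members)
    return coll


def write_gmt(coll: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for set_id, (desc, members) in coll.sets.items():
            fh.write("\t".join([set_id, desc, *members]) + "\n")


def merge_cohorts(matrices, median_center: bool = False) -> ExpressionMatrix:
    """Merge cohorts on the intersection of their genes.

    Genes keep first-cohort order; samples are concatenated with their
    cohort tags preserved.  ``median_center`` subtracts each cohort's
    per-gene median before concatenation — an explicit, optional batch
    adjustment for inputs that were not normalised jointly (off by
    default, which assumes comparably normalised cohorts).
    """
    matrices = list(matrices)
    if not matrices:
        raise MergeError("need at least one cohort")
    genes = list(matrices[0].values.index)
    common = set(genes)
    for m in matrices[1:]:
        common &= set(m.values.index)
    genes = [g for g in genes if g in common]
    if not genes:
        raise MergeError("gene intersection across cohorts is empty")

    seen: set[str] = set()
    parts, classes, cohorts = [], [], []
    for m in matrices:
        overlap = seen.intersection(m.sample_ids)
        if overlap:
            raise MergeError(f"duplicate sample ids across cohorts: {sorted(overlap)[:5]}")
        seen.update(m.sample_ids)
        vals = m.values.loc[genes]
        if median_center:
            vals = vals.sub(vals.median(axis=1), axis=0)
        parts.append(vals)
        classes.append(m.sample_class)
        cohorts.append(m.cohort)
    return ExpressionMatrix(
        values=pd.concat(parts, axis=1),
        sample_class=pd.concat(classes),
        cohort=pd.concat(cohorts),
    )


def write_dependency(dm: DependencyMatrix, matrix_path, meta_path) -> None:
    out = dm.values.copy()
    out.index.name = "gene"
    out.to_csv(matrix_path, sep="\t")
    meta = pd.DataFrame(
        {"cell_line": dm.cellline_ids,
         "origin": dm.origin.to_numpy(),
         "lineage": dm.lineage.to_numpy()}
    )
    meta.to_csv(meta_path, sep="\t", index=False)


def read_dependency(matrix_path, meta_path) -> DependencyMatrix:
    body = pd.read_csv(matrix_path, sep="\t", index_col=0)
    body.index.name = None
    body.columns.name = None
    _check_unique(body.index, "gene", matrix_path)
    _check_unique(body.columns, "cell line", matrix_path)
    meta = pd.read_csv(meta_path, sep="\t", dtype=str).set_index("cell_line")
    missing = set(body.columns) - set(meta.index)
    if missing:
        raise InvalidInputError(f"lines without metadata: {sorted(missing)[:5]}")
    return DependencyMatrix(values=body.astype(float),
                            origin=meta["origin"],
                            lineage=meta.get("lineage"))


def write_response(lfc: pd.Series, path) -> None:
    pd.DataFrame({"cell_line": lfc.index, "lfc": lfc.to_numpy()}).to_csv(
        path, sep="\t", index=False)


def read_response(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if not {"cell_line", "lfc"}.issubset(df.columns):
        raise FormatError(f"{path}: need columns cell_line and lfc")
    _check_unique(pd.Index(df["cell_line"]), "cell line", path)
    s = pd.Series(df["lfc"].to_numpy(dtype=float), index=df["cell_line"], name="lfc")
    if not np.isfinite(s.to_numpy()).all():
        raise FormatError(f"{path}: non-finite LFC values")
    return s


def write_annotations(tables: AnnotationTables, surf_path, secr_path, drug_path) -> None:
    tables.surfaceome.to_csv(surf_path, sep="\t", index=False)
    tables.secretome.to_csv(secr_path, sep="\t", index=False)
    tables.drug_targets.to_csv(drug_path, sep="\t", index=False)


def read_annotations(surf_path, secr_path, drug_path) -> AnnotationTables:
    surf = pd.read_csv(surf_path, sep="\t")
    secr = pd.read_csv(secr_path, sep="\t", keep_default_na=False)
    drug = pd.read_csv(drug_path, sep="\t")
    return AnnotationTables(surfaceome=surf, secretome=secr, drug_targets=drug)


def write_truth(truth: SimulationTruth, path) -> None:
    """Flat TSV of all planted ids: columns kind, id, detail."""
    rows = [("de_gene", g, repr(e)) for g, e in truth.planted_de_genes]
    rows += [("enriched_set", s, d) for s, d in truth.planted_enriched_sets]
    rows += [("essential_gene", g, "") for g in truth.planted_essential_genes]
    rows += [("response_signature_gene", g, "") for g in truth.planted_response_signature]
    pd.DataFrame(rows, columns=["kind", "id", "detail"]).to_csv(
        path, sep="\t", index=False)
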