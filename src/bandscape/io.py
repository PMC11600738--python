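"""Readers, writers and cohort assembly.

All external formats enter through this module: cBioPortal-style
GISTIC-thresholded CN matrices, MAF-lite mutation tables, expression TSVs,
clinical tables, UCSC ``cytoBand.txt``, GMT gene sets and GDSC-like drug
response CSVs.  Readers validate against their declared schemas and raise
:class:`~bandscape.errors.ParseError` rather than silently coercing
out-of-contract values.
"""

from __future__ import annotations

import logging
import re
from collections.abc import Callable
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    CN_CODES,
    CohortBundle,
    CohortTable,
    DrugResponseTable,
    ExpressionMatrix,
    FeatureMatrix,
    GeneCNMatrix,
    GenomeAnnotation,
    MutationTable,
    SignatureMatrix,
)
from .errors import AmbiguityError, ParseError

logger = logging.getLogger("bandscape")

_TCGA_BARCODE_RE = re.compile(r"^TCGA-\w{2}-\w{4}")


# ---------------------------------------------------------------------------
# copy-number matrix


def read_gene_cn_matrix(path: str | Path, dialect: str = "cbioportal_tsv") -> GeneCNMatrix:
    """Read a gene-level GISTIC-thresholded CN matrix.

    The cbioportal_tsv dialect is a TSV whose first column holds gene
    symbols and whose remaining columns are samples; cells are integers in
    {-2..2} or blank (missing).
    """
    if dialect != "cbioportal_tsv":
        raise ParseError(f"unknown CN dialect {dialect!r}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(set(header[1:])) != len(header[1:]):
        dups = sorted({h for h in header[1:] if header[1:].count(h) > 1})
        raise ParseError(f"{path}: duplicated sample headers: {dups}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: CN matrix needs a gene column plus >=1 sample")
    gene_col = df.columns[0]
    genes = df[gene_col]
    if genes.duplicated().any():
        dups = genes[genes.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicated gene rows: {dups}")
    samples = list(df.columns[1:])
    if len(set(samples)) != len(samples):
        raise ParseError(f"{path}: duplicated sample headers")
    out = np.full((len(df), len(samples)), np.nan)
    for j, col in enumerate(samples):
        raw = df[col]
        for i, cell in enumerate(raw):
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
                continue
            try:
                v = int(cell)
            except (TypeError, ValueError):
                raise ParseError(
                    f"{path}: non-integer CN value {cell!r} at "
                    f"(gene {genes.iloc[i]!r}, sample {col!r})"
                ) from None
            if v not in CN_CODES:
                raise ParseError(
                    f"{path}: CN value {v} outside -2..2 at "
                    f"(gene {genes.iloc[i]!r}, sample {col!r})"
                )
            out[i, j] = v
    values = pd.DataFrame(out, index=pd.Index(genes, name="gene_id"), columns=samples)
    logger.info("read CN matrix %s: %d genes x %d samples", path, *values.shape)
    return GeneCNMatrix(values)


def write_gene_cn_matrix(matrix: GeneCNMatrix, path: str | Path) -> None:
    """Write a CN matrix in the cbioportal_tsv dialect (blank = missing)."""
    df = matrix.values.copy()
    txt = df.map(lambda v: "" if pd.isna(v) else str(int(v)))
    txt.index.name = "gene_id"
    txt.to_csv(path, sep="\t", lineterminator="\n")


# ---------------------------------------------------------------------------
# annotation


def read_cytoband_annotation(path: str | Path) -> pd.DataFrame:
    """Read a UCSC ``cytoBand.txt`` file into a band table.

    Rows are ``chrom  start  end  name  stain`` with 0-based half-open
    coordinates, exactly as distributed by UCSC.  The band name is composed
    as chromosome (without the ``chr`` prefix) + arm/band, e.g. "13q14.2".
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 5:
                raise ParseError(f"{path}:{ln}: expected 5 fields, got {len(parts)}")
            chrom, start, end, name, stain = parts
            short = chrom.removeprefix("chr")
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(start),
                    "end": int(end),
                    "band_name": f"{short}{name}",
                    "stain": stain,
                }
            )
    if not rows:
        logger.warning("cytoband file %s is empty", path)
        return pd.DataFrame(columns=["chrom", "start", "end", "band_name", "stain"])
    df = pd.DataFrame(rows).sort_values(["chrom", "start"], kind="stable")
    # overlap check happens again in GenomeAnnotation; report early with names
    for chrom, grp in df.groupby("chrom", sort=False):
        s = grp["start"].to_numpy()
        e = grp["end"].to_numpy()
        bad = np.nonzero(s[1:] < e[:-1])[0]
        if bad.size:
            k = int(bad[0])
            pair = grp.iloc[[k, k + 1]]["band_name"].tolist()
            raise ParseError(f"{path}: overlapping bands {pair[0]} and {pair[1]}")
    return df.reset_index(drop=True)


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    """Read a gene interval TSV declared 1-based inclusive; convert to
    0-based half-open.  Columns: gene_id, chrom, start, end."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["gene_id", "chrom", "start", "end"], path)
    out = df[["gene_id", "chrom", "start", "end"]].copy()
    out["start"] = out["start"].astype(int) - 1
    out["end"] = out["end"].astype(int)
    return out


def build_annotation(genes: pd.DataFrame, bands: pd.DataFrame) -> GenomeAnnotation:
    return GenomeAnnotation(genes=genes.reset_index(drop=True), bands=bands.reset_index(drop=True))


# ---------------------------------------------------------------------------
# simple tables


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing mandatory column(s) {missing}")


def read_mutation_table(path: str | Path) -> MutationTable:
    """Read a MAF-lite TSV: sample_id, gene_id, class, pathogenic."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["sample_id", "gene_id", "class"], path)
    if "pathogenic" in df.columns:
        path_flag = df["pathogenic"].fillna("false").str.lower().map(
            {"true": True, "false": False}
        )
        if path_flag.isna().any():
            bad = df.loc[path_flag.isna(), "pathogenic"].iloc[0]
            raise ParseError(f"{path}: pathogenic flag must be true/false, got {bad!r}")
    else:
        path_flag = pd.Series(False, index=df.index)
    out = pd.DataFrame(
        {
            "sample_id": df["sample_id"],
            "gene_id": df["gene_id"],
            "mutation_class": df["class"],
            "pathogenic": path_flag.astype(bool),
        }
    )
    logger.info("read %d mutation records from %s", len(out), path)
    return MutationTable(out)


def write_mutation_table(table: MutationTable, path: str | Path) -> None:
    df = table.records.rename(columns={"mutation_class": "class"})
    df = df.assign(pathogenic=df["pathogenic"].map({True: "true", False: "false"}))
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_expression_matrix(path: str | Path, scale_tag: str = "raw") -> ExpressionMatrix:
    """Read a gene x sample expression TSV (first column gene_id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.columns.has_duplicates:
        raise ParseError(f"{path}: duplicated sample headers")
    vals = df.astype(float)
    logger.info("read expression %s: %d genes x %d samples", path, *vals.shape)
    return ExpressionMatrix(vals, scale_tag=scale_tag)


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path) -> None:
    df = expr.values.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", lineterminator="\n", float_format="%.10g")


def read_clinical_table(path: str | Path) -> CohortTable:
    """Read a clinical TSV: sample_id, pam50, er, her2, os_months, os_event."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["sample_id", "pam50", "er", "her2", "os_months", "os_event"], path)
    t = pd.to_numeric(df["os_months"], errors="coerce")
    bad = t.notna() & (t < 0)
    if bad.any():
        raise ParseError(
            f"{path}: negative os_months for sample {df.loc[bad, 'sample_id'].iloc[0]!r}"
        )
    out = df[["sample_id", "pam50", "er", "her2"]].copy()
    out["os_months"] = t
    out["os_event"] = pd.to_numeric(df["os_event"], errors="coerce")
    logger.info("read %d clinical rows from %s", len(out), path)
    return CohortTable(out)


def write_clinical_table(table: CohortTable, path: str | Path) -> None:
    table.rows.to_csv(path, sep="\t", index=False, lineterminator="\n", float_format="%.10g")


def read_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{ln}: GMT line needs name, description, >=1 gene")
            name = parts[0]
            if name in sets:
                raise ParseError(f"{path}:{ln}: duplicated gene-set name {name!r}")
            sets[name] = {g for g in parts[2:] if g}
    logger.info("read %d gene sets from %s", len(sets), path)
    return sets


def read_drug_response(path: str | Path) -> tuple[DrugResponseTable, int]:
    """Read a GDSC-like CSV of log10 IC50 values.

    Columns: cell_line, drug, screen, log10_ic50 (optional auc).  Rows with
    an unparsable response are skipped and counted, not fatal; the skip
    count is returned alongside the table.
    """
    df = pd.read_csv(path)
    _require_columns(df, ["cell_line", "drug", "screen", "log10_ic50"], path)
    vals = pd.to_numeric(df["log10_ic50"], errors="coerce")
    keep = vals.notna() & np.isfinite(vals)
    n_skipped = int((~keep).sum())
    if n_skipped:
        logger.warning("%s: skipped %d malformed IC50 rows", path, n_skipped)
    out = pd.DataFrame(
        {
            "cell_line": df.loc[keep, "cell_line"],
            "drug": df.loc[keep, "drug"],
            "screen_id": df.loc[keep, "screen"].astype(str),
            "log10_ic50": vals[keep].astype(float),
        }
    )
    if "auc" in df.columns:
        out["auc"] = pd.to_numeric(df.loc[keep, "auc"], errors="coerce")
    return DrugResponseTable(out.reset_index(drop=True)), n_skipped


def write_drug_response(table: DrugResponseTable, path: str | Path) -> None:
    df = table.records.rename(columns={"screen_id": "screen"})
    df.to_csv(path, index=False, lineterminator="\n", float_format="%.10g")


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    """Read a binary cell-line x feature TSV (first column cell_line)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return FeatureMatrix(df.astype(int))


def write_feature_matrix(fm: FeatureMatrix, path: str | Path) -> None:
    df = fm.values.copy()
    df.index.name = "cell_line"
    df.to_csv(path, sep="\t", lineterminator="\n")


def read_signature_matrix(path: str | Path) -> SignatureMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SignatureMatrix(df.astype(float))


def write_signature_matrix(sm: SignatureMatrix, path: str | Path) -> None:
    df = sm.values.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", lineterminator="\n", float_format="%.10g")


# ---------------------------------------------------------------------------
# cohort assembly and filtering


def exclude_pathogenic_carriers(
    bundle: CohortBundle, genes: list[str]
) -> tuple[CohortBundle, pd.DataFrame]:
    """Remove samples carrying a pathogenic mutation in any listed gene.

    Mirrors the upstream exclusion of pathogenic RB1-mutation carriers
    before copy-number analysis: a sample is dropped from every table in
    the bundle if it has at least one mutation with pathogenic=True in one
    of ``genes``.  Returns the filtered bundle and a report of
    (sample_id, triggering gene) pairs.  Carriers of non-pathogenic
    mutations in the same genes are retained.
    """
    known = set(bundle.annotation.genes["gene_id"])
    unknown = [g for g in genes if g not in known]
    if unknown:
        raise AmbiguityError(f"genes not in annotation: {unknown}")
    rec = bundle.mutations.records
    hit = rec["pathogenic"] & rec["gene_id"].isin(genes)
    report = (
        rec.loc[hit, ["sample_id", "gene_id"]]
        .drop_duplicates()
        .reset_index(drop=True)
    )
    carriers = set(report["sample_id"])
    keep = [s for s in bundle.sample_ids if s not in carriers]
    new = CohortBundle(
        cn=bundle.cn.select_samples(keep),
        mutations=bundle.mutations.select_samples(keep),
        clinical=bundle.clinical.select_samples(keep),
        annotation=bundle.annotation,
        expression=bundle.expression.select_samples(
            [s for s in bundle.expression.sample_ids if s not in carriers]
        )
        if bundle.expression is not None
        else None,
        provenance=list(bundle.provenance),
    )
    new.log(
        f"excluded {len(carriers)} pathogenic carrier(s) of {sorted(genes)}: "
        f"{sorted(carriers)}"
    )
    return new, report


def tcga_patient_normalizer(sample_id: str) -> str:
    """Truncate TCGA-style barcodes to the 12-character patient prefix;
    non-TCGA identifiers pass through unchanged."""
    if _TCGA_BARCODE_RE.match(sample_id):
        return sample_id[:12]
    return sample_id


def match_by_patient_id(
    cn_samples: list[str],
    clinical: CohortTable,
    id_normalizer: Callable[[str], str] = tcga_patient_normalizer,
) -> tuple[dict[str, str], list[str], list[str]]:
    """Match CN sample identifiers to clinical rows by normalized patient ID.

    Returns (mapping cn_sample -> clinical sample_id, unmatched CN samples,
    unmatched clinical samples).  Two CN samples normalizing to the same
    patient is an :class:`AmbiguityError` listing the collisions.
    """
    norm_cn: dict[str, str] = {}
    collisions: dict[str, list[str]] = {}
    for s in cn_samples:
        p = id_normalizer(s)
        if p in norm_cn:
            collisions.setdefault(p, [norm_cn[p]]).append(s)
        else:
            norm_cn[p] = s
    if collisions:
        raise AmbiguityError(f"CN samples collide after normalization: {collisions}")
    clin_ids = list(clinical.rows["sample_id"])
    norm_clin: dict[str, str] = {}
    for s in clin_ids:
        p = id_normalizer(s)
        if p in norm_clin:
            raise AmbiguityError(f"clinical rows collide after normalization: {p!r}")
        norm_clin[p] = s
    mapping = {norm_cn[p]: norm_clin[p] for p in norm_cn if p in norm_clin}
    unmatched_cn = [norm_cn[p] for p in norm_cn if p not in norm_clin]
    unmatched_clin = [norm_clin[p] for p in norm_clin if p not in norm_cn]
    if unmatched_cn or unmatched_clin:
        logger.info(
            "patient matching: %d matched, %d CN-only, %d clinical-only",
            len(mapping),
            len(unmatched_cn),
            len(unmatched_clin),
        )
    return mapping, unmatched_cn, unmatched_clin
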