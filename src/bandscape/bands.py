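"""Cytoband-level copy-number status calling and frequency summaries.

Gene-level GISTIC-thresholded calls (-2..+2) are summarised per sample to a
band status: a band whose non-missing gene values are all equal maps to
deep_loss / loss / neutral / gain / amplification; a band with two or more
distinct values in one sample harbours an intra-band breakpoint and is
called ambiguous; a band with no non-missing values is missing.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CN_CODES, CohortTable, GeneCNMatrix, GenomeAnnotation
from .errors import DegenerateDataError, ValidationError

logger = logging.getLogger("bandscape")

DEEP_LOSS = "deep_loss"
LOSS = "loss"
NEUTRAL = "neutral"
GAIN = "gain"
AMPLIFICATION = "amplification"
AMBIGUOUS = "ambiguous"
MISSING = "missing"

STATUS_OF_CODE = {-2: DEEP_LOSS, -1: LOSS, 0: NEUTRAL, 1: GAIN, 2: AMPLIFICATION}
DEFAULT_LOSS_DEF = frozenset({LOSS, DEEP_LOSS})


def assign_genes_to_bands(
    annotation: GenomeAnnotation,
) -> tuple[dict[str, list[str]], list[str]]:
    """Map each gene to the band containing its interval midpoint.

    Membership uses the 0-based half-open band interval; genes whose
    midpoint falls outside every band on their chromosome are returned in
    the unassigned list rather than raising.
    """
    mapping: dict[str, list[str]] = {b: [] for b in annotation.band_names}
    unassigned: list[str] = []
    bands_by_chrom = {
        chrom: grp.sort_values("start")
        for chrom, grp in annotation.bands.groupby("chrom", sort=False)
    }
    for row in annotation.genes.itertuples(index=False):
        mid = (row.start + row.end) // 2
        grp = bands_by_chrom.get(row.chrom)
        hit = None
        if grp is not None:
            inside = (grp["start"] <= mid) & (mid < grp["end"])
            if inside.any():
                hit = grp.loc[inside, "band_name"].iloc[0]
        if hit is None:
            unassigned.append(row.gene_id)
        else:
            mapping[hit].append(row.gene_id)
    if unassigned:
        logger.info("%d gene(s) unassigned to any band", len(unassigned))
    return {b: genes for b, genes in mapping.items() if genes}, unassigned


def call_band_status(gene_values) -> str:
    """Call one band's status in one sample from its gene-level CN codes.

    All non-missing values equal v -> the status for v; two or more
    distinct non-missing values -> ambiguous (intra-band breakpoint); no
    non-missing values -> missing.
    """
    arr = np.asarray(gene_values, dtype=float)
    obs = arr[~np.isnan(arr)]
    if obs.size == 0:
        return MISSING
    bad = ~np.isin(obs, CN_CODES)
    if bad.any():
        raise ValidationError(f"CN value {obs[bad][0]!r} outside -2..2")
    uniq = np.unique(obs)
    if uniq.size > 1:
        return AMBIGUOUS
    return STATUS_OF_CODE[int(uniq[0])]


def call_bands(cn: GeneCNMatrix, annotation: GenomeAnnotation) -> pd.DataFrame:
    """Band x sample status table (bands in genomic order).

    Bands with zero annotated genes in the CN matrix are absent from the
    result.
    """
    mapping, _ = assign_genes_to_bands(annotation)
    present_genes = set(cn.gene_ids)
    rows = {}
    for band, genes in mapping.items():
        genes = [g for g in genes if g in present_genes]
        if not genes:
            continue
        sub = cn.values.loc[genes].to_numpy(dtype=float)
        n_obs = (~np.isnan(sub)).sum(axis=0)
        with np.errstate(invalid="ignore"):
            lo = np.nanmin(sub, axis=0) if len(sub) else np.array([])
            hi = np.nanmax(sub, axis=0)
        status = np.where(
            n_obs == 0,
            MISSING,
            np.where(
                lo != hi,
                AMBIGUOUS,
                pd.Series(lo).map(lambda v: STATUS_OF_CODE.get(v, MISSING)).to_numpy(),
            ),
        )
        rows[band] = status
    order = [b for b in annotation.band_names if b in rows]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cn.sample_ids).loc[order]


def band_loss_frequencies(
    status_table: pd.DataFrame,
    loss_def: frozenset[str] | set[str] = DEFAULT_LOSS_DEF,
) -> pd.DataFrame:
    """Per-band loss frequency and descending rank.

    Frequency = #samples with status in ``loss_def`` / #callable samples
    (callable = status != missing; ambiguous counts in the denominator but
    never the numerator).  Ties in frequency are broken by genomic order,
    i.e. the table's row order.
    """
    if status_table.empty:
        raise DegenerateDataError("empty band status table")
    is_loss = status_table.isin(loss_def)
    callable_ = status_table != MISSING
    n_callable = callable_.sum(axis=1)
    if (n_callable == 0).any():
        bad = list(status_table.index[n_callable == 0])
        raise DegenerateDataError(f"bands with zero callable samples: {bad}")
    freq = is_loss.sum(axis=1) / n_callable
    out = pd.DataFrame(
        {"frequency": freq, "n_callable": n_callable, "genomic_order": range(len(freq))}
    )
    out = out.sort_values(
        ["frequency", "genomic_order"], ascending=[False, True], kind="stable"
    )
    out["rank"] = range(1, len(out) + 1)
    return out.drop(columns="genomic_order").loc[status_table.index].sort_values("rank")


def compare_band_vs_genome(
    cn: GeneCNMatrix,
    annotation: GenomeAnnotation,
    anchor_band: str,
    mode: str = "loss",
) -> dict:
    """Two-sample t-test of per-gene alteration frequencies, in-band vs
    out-of-band.

    The replicate unit is the gene: for each gene the fraction of samples
    carrying the mode's sign (loss: CN < 0; gain: CN > 0) is computed over
    non-missing cells, then genes inside the anchor band are contrasted
    with all other genes by Welch-free (pooled) Student t.
    """
    if mode not in ("loss", "gain"):
        raise ValidationError(f"mode must be loss or gain, got {mode!r}")
    mapping, _ = assign_genes_to_bands(annotation)
    if anchor_band not in mapping:
        raise DegenerateDataError(f"anchor band {anchor_band!r} has no genes")
    in_genes = [g for g in mapping[anchor_band] if g in set(cn.gene_ids)]
    out_genes = [g for g in cn.gene_ids if g not in set(in_genes)]
    if len(in_genes) < 2 or len(out_genes) < 2:
        raise DegenerateDataError("need >= 2 genes inside and outside the anchor band")
    arr = cn.values.to_numpy(dtype=float)
    altered = (arr < 0) if mode == "loss" else (arr > 0)
    n_obs = (~np.isnan(arr)).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = pd.Series(
            np.where(n_obs > 0, altered.sum(axis=1) / np.maximum(n_obs, 1), np.nan),
            index=cn.values.index,
        )
    f_in = freq.loc[in_genes].dropna()
    f_out = freq.loc[out_genes].dropna()
    if np.ptp(f_in.to_numpy()) == 0 and np.ptp(f_out.to_numpy()) == 0:
        raise DegenerateDataError("constant frequencies in both groups")
    t, p = stats.ttest_ind(f_in, f_out)
    return {
        "t": float(t),
        "p": float(p),
        "mean_in": float(f_in.mean()),
        "mean_out": float(f_out.mean()),
        "n_in": len(f_in),
        "n_out": len(f_out),
    }


def subtype_status_table(
    band_statuses: pd.Series,
    clinical: CohortTable,
    grouping: str = "pam50",
) -> dict:
    """Status-category x subtype contingency with Pearson chi-square.

    ``grouping`` is ``pam50`` or ``er_her2`` (joint ER/HER2 label).  The
    chi-square uses no continuity correction; cells with expected count
    < 5 raise a flag but the statistic is still returned.
    """
    clin = clinical.rows.set_index("sample_id")
    shared = [s for s in band_statuses.index if s in clin.index]
    status = band_statuses.loc[shared]
    if grouping == "pam50":
        group = clin.loc[shared, "pam50"]
    elif grouping == "er_her2":
        group = clin.loc[shared, "er"].astype(str) + "/" + clin.loc[shared, "her2"].astype(str)
    else:
        raise ValidationError(f"unknown grouping {grouping!r}")
    keep = status != MISSING
    table = pd.crosstab(status[keep], group[keep])
    table = table.loc[:, table.sum(axis=0) > 0]
    if table.shape[1] < 2:
        raise DegenerateDataError("need >= 2 subtype levels with samples")
    table = table.loc[table.sum(axis=1) > 0]
    chi2, p, dof, expected = stats.chi2_contingency(table.to_numpy(), correction=False)
    return {
        "table": table,
        "chi2": float(chi2),
        "p": float(p),
        "dof": int(dof),
        "low_expected": bool((expected < 5).any()),
    }
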