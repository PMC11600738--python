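"""Differential expression between anchor-loss and neutral samples.

Genes are standardised to z-scores across samples, contrasted by the
difference of group medians, and tested with a two-sided rank-sum test on
independent groups (exact enumeration for small tie-free groups, tie-
corrected normal approximation otherwise).  Gene-level runs adjust p-values
with Bonferroni; the protein-level variant reuses the identical pipeline
with Benjamini-Hochberg.  Pathway input selection applies the top-k rule
with the exclusion of downregulated genes on the anchor's chromosome arm,
and over-representation is a plain upper-tail hypergeometric test on user
gene sets.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionMatrix, GenomeAnnotation, arm_of_band
from .errors import DegenerateDataError, ValidationError

logger = logging.getLogger("bandscape")


def zscore_by_gene(expr: ExpressionMatrix) -> tuple[ExpressionMatrix, list[str]]:
    """Standardise each gene across samples (sample sd, denominator n-1).

    Zero-variance genes cannot be standardised; they are dropped and
    returned in the report list.  Idempotent on already-standardised input
    (within numerical tolerance).
    """
    df = expr.values
    if df.shape[1] < 2:
        raise DegenerateDataError("z-scoring needs >= 2 samples")
    mu = df.mean(axis=1)
    sd = df.std(axis=1, ddof=1)
    dropped = list(df.index[sd == 0])
    if dropped:
        logger.info("dropped %d zero-variance gene(s) before z-scoring", len(dropped))
    keep = sd > 0
    z = df.loc[keep].sub(mu[keep], axis=0).div(sd[keep], axis=0)
    return ExpressionMatrix(z, scale_tag="zscore"), dropped


def rank_sum_p(x: np.ndarray, y: np.ndarray, alternative: str = "two-sided") -> float:
    """Two-sided (default) independent-samples rank-sum p.

    Exact enumeration when both groups have <= 12 observations and the
    pooled data are tie-free; otherwise the normal approximation with
    mid-ranks and tie-corrected variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    ties = len(np.unique(pooled)) < len(pooled)
    if not ties and max(len(x), len(y)) <= 12:
        method = "exact"
    else:
        method = "asymptotic"
    if np.ptp(pooled) == 0:
        return 1.0
    return float(
        stats.mannwhitneyu(x, y, alternative=alternative, method=method).pvalue
    )


def differential_expression(
    z: ExpressionMatrix,
    anchor: pd.Series,
    adjust: str = "bonferroni",
    annotation: GenomeAnnotation | None = None,
    anchor_band: str | None = None,
) -> pd.DataFrame:
    """Per-gene contrast of anchor-loss vs neutral samples.

    ``anchor`` is the 0/1 loss indicator over the samples entering the
    contrast.  Effect = median(z | loss) - median(z | neutral); p from the
    two-sided rank-sum test; ``adjust`` in {bonferroni, bh} applied over all
    tested genes.  If an annotation and anchor band are given, each gene is
    flagged as lying on the anchor band / the anchor's chromosome arm.
    """
    if adjust not in ("bonferroni", "bh"):
        raise ValidationError(f"adjust must be bonferroni or bh, got {adjust!r}")
    samples = [s for s in anchor.index if s in set(z.sample_ids)]
    a = anchor.loc[samples]
    loss = [s for s in samples if a[s] == 1]
    neutral = [s for s in samples if a[s] == 0]
    if len(loss) < 2 or len(neutral) < 2:
        raise DegenerateDataError("both groups need >= 2 samples")
    lv = z.values[loss].to_numpy(dtype=float)
    nv = z.values[neutral].to_numpy(dtype=float)
    delta = np.median(lv, axis=1) - np.median(nv, axis=1)
    pvals = np.array([rank_sum_p(lv[i], nv[i]) for i in range(lv.shape[0])])
    padj = adjust_pvalues(pvals, method=adjust)
    out = pd.DataFrame(
        {
            "gene_id": z.gene_ids,
            "delta_median_z": delta,
            "p_value": pvals,
            "p_adjusted": padj,
            "adjust_method": adjust,
        }
    )
    if annotation is not None and anchor_band is not None:
        from .bands import assign_genes_to_bands

        mapping, _ = assign_genes_to_bands(annotation)
        band_of = {g: b for b, genes in mapping.items() for g in genes}
        arm = arm_of_band(anchor_band)
        out["on_anchor_band"] = out["gene_id"].map(lambda g: band_of.get(g) == anchor_band)
        out["on_anchor_arm"] = out["gene_id"].map(
            lambda g: g in band_of and arm_of_band(band_of[g]) == arm
        )
    return out


def adjust_pvalues(pvalues, method: str = "bonferroni") -> np.ndarray:
    """Multiple-testing adjustment: Bonferroni min(1, m p) or BH step-up."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in [0, 1]")
    if method == "bonferroni":
        return np.minimum(1.0, p * p.size)
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    raise ValidationError(f"unknown adjustment method {method!r}")


def select_pathway_input(
    results: pd.DataFrame,
    k: int = 50,
    exclude_down_on_anchor_arm: bool = True,
) -> list[str]:
    """Top-k differentially expressed genes for over-representation input.

    Genes are ranked by adjusted p ascending, ties broken by |effect|
    descending.  Downregulated genes (effect < 0) on the anchor's chromosome
    arm are removed before the top-k cut — their deficit is a direct dosage
    consequence of the copy-number loss, not a functional signal.
    Upregulated genes on the arm are retained.
    """
    if k <= 0:
        raise ValidationError("k must be positive")
    df = results.copy()
    if exclude_down_on_anchor_arm:
        if "on_anchor_arm" not in df.columns:
            raise ValidationError("results lack the on_anchor_arm annotation")
        df = df[~((df["delta_median_z"] < 0) & (df["on_anchor_arm"]))]
    df = df.assign(_abs=df["delta_median_z"].abs()).sort_values(
        ["p_adjusted", "_abs"], ascending=[True, False], kind="stable"
    )
    selected = list(df["gene_id"].head(k))
    if len(selected) < k:
        logger.warning("only %d genes survive selection (requested %d)", len(selected), k)
    return selected


def ora_hypergeometric(
    gene_list: list[str],
    gene_sets: dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of a gene list.

    Every set is intersected with the universe first; sets disjoint from
    the universe are skipped (reported via the ``skipped`` attribute of the
    returned frame).  BH correction is applied across tested sets.
    """
    if not universe:
        raise ValidationError("empty universe")
    query = set(gene_list)
    if not query <= universe:
        raise ValidationError(f"gene list not contained in universe: {sorted(query - universe)[:5]}")
    M = len(universe)
    N = len(query)
    rows = []
    skipped = []
    for name, genes in gene_sets.items():
        in_universe = genes & universe
        if not in_universe:
            skipped.append(name)
            continue
        K = len(in_universe)
        overlap = len(in_universe & query)
        p = float(stats.hypergeom.sf(overlap - 1, M, K, N)) if overlap > 0 else 1.0
        rows.append(
            {"set": name, "set_size": K, "overlap": overlap, "p_value": min(p, 1.0)}
        )
    out = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "p_value"])
    if len(out):
        out["q_value"] = adjust_pvalues(out["p_value"].to_numpy(), method="bh")
    else:
        out["q_value"] = []
    if skipped:
        logger.info("skipped %d gene set(s) disjoint from the universe", len(skipped))
    out.attrs["skipped"] = skipped
    return out.sort_values("p_value", kind="stable").reset_index(drop=True)
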