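"""Bulk-expression deconvolution under the linear mixing model.

A bulk profile is modelled as ``P_j = SM . beta_j + eps`` where ``SM`` is a
gene x cell-type signature matrix of mean expression profiles, ``beta_j``
the vector of mixing fractions of sample ``j``, and ``eps`` noise.  The
model is solved per sample by non-negative least squares; fractions are
renormalised to the probability simplex afterwards (a fully constrained
sum-to-one solve is available behind a flag).  Estimates from an ensemble
of signature matrices are averaged element-wise, which reduces the variance
contributed by any single reference.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .datatypes import CellFractions, ExpressionMatrix, SignatureMatrix
from .errors import DegenerateDataError, ValidationError
from .expression import adjust_pvalues, rank_sum_p

logger = logging.getLogger("bandscape")


def prepare_expression(expr: ExpressionMatrix, mode: str = "scale") -> ExpressionMatrix:
    """Input scaling ahead of deconvolution.

    ``log2_scale`` applies log2(1 + x) then per-gene standardisation (the
    RNA-seq route); ``scale`` standardises only (the microarray route).
    """
    df = expr.values
    if mode == "log2_scale":
        df = np.log2(1.0 + df.clip(lower=0))
    elif mode != "scale":
        raise ValidationError(f"unknown preparation mode {mode!r}")
    sd = df.std(axis=1, ddof=1).replace(0, np.nan)
    z = df.sub(df.mean(axis=1), axis=0).div(sd, axis=0).dropna()
    return ExpressionMatrix(z, scale_tag="zscore")


def estimate_fractions(
    bulk: ExpressionMatrix,
    sm: SignatureMatrix,
    sum_to_one: str = "renormalize",
) -> CellFractions:
    """Estimate cell-type fractions for every bulk sample.

    Per sample solves ``argmin ||P_j - SM beta||^2 s.t. beta >= 0`` on the
    genes shared between the bulk matrix and the signature matrix, then
    maps the solution to the simplex.  ``sum_to_one="constrained"`` instead
    augments the system with a heavily weighted sum-to-one row so the
    constraint is honoured inside the solve.  Samples whose raw solution is
    all-zero are flagged and assigned uniform fractions.
    """
    if sum_to_one not in ("renormalize", "constrained"):
        raise ValidationError(f"unknown sum_to_one mode {sum_to_one!r}")
    if len(sm.cell_types) < 2:
        raise DegenerateDataError("need >= 2 cell types")
    shared = [g for g in sm.gene_ids if g in set(bulk.gene_ids)]
    if not shared:
        raise DegenerateDataError("no shared genes between bulk matrix and signature matrix")
    logger.info("deconvolution uses %d shared gene(s)", len(shared))
    A = sm.values.loc[shared].to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        cond = np.linalg.cond(A)
        logger.warning(
            "signature matrix is rank-deficient (rank %d < %d types, cond %.3g); "
            "fractions of collinear types are split arbitrarily",
            rank,
            A.shape[1],
            cond,
        )
    P = bulk.values.loc[shared].to_numpy(dtype=float)
    k = A.shape[1]
    if sum_to_one == "constrained":
        w = 1e6 * max(1.0, float(np.abs(A).max()))
        A_solve = np.vstack([A, w * np.ones((1, k))])
    else:
        A_solve = A
    betas = np.empty((k, P.shape[1]))
    residuals = np.empty(P.shape[1])
    flagged = []
    for j in range(P.shape[1]):
        b = P[:, j]
        if sum_to_one == "constrained":
            beta, _ = nnls(A_solve, np.concatenate([b, [w]]))
        else:
            beta, _ = nnls(A_solve, b)
        total = beta.sum()
        if total <= 0:
            flagged.append(bulk.sample_ids[j])
            beta = np.full(k, 1.0 / k)
        else:
            beta = beta / total
        betas[:, j] = beta
        residuals[j] = float(np.linalg.norm(b - A @ beta))
    fractions = pd.DataFrame(
        betas, index=pd.Index(sm.cell_types, name="cell_type"), columns=bulk.sample_ids
    )
    if flagged:
        logger.warning("%d sample(s) produced an all-zero solution", len(flagged))
    return CellFractions(
        fractions=fractions,
        residual_norm=pd.Series(residuals, index=bulk.sample_ids, name="residual_norm"),
        flagged=tuple(flagged),
    )


def ensemble_fractions(estimates: list[CellFractions]) -> CellFractions:
    """Element-wise mean over an ensemble of fraction estimates.

    Cell types are harmonised by name; mismatched sets are an error listing
    the differences.  The mean is renormalised per sample, and the stored
    residual is the mean of the member residuals.
    """
    if not estimates:
        raise ValidationError("empty ensemble")
    ref_types = set(estimates[0].cell_types)
    ref_samples = list(estimates[0].sample_ids)
    for est in estimates[1:]:
        if set(est.cell_types) != ref_types:
            raise ValidationError(
                "cell-type sets differ across ensemble members: "
                f"{sorted(ref_types ^ set(est.cell_types))}"
            )
        if list(est.sample_ids) != ref_samples:
            raise ValidationError("sample spaces differ across ensemble members")
    order = estimates[0].cell_types
    stack = np.stack([est.fractions.loc[order].to_numpy() for est in estimates])
    mean = stack.mean(axis=0)
    mean = mean / mean.sum(axis=0, keepdims=True)
    res = None
    if all(est.residual_norm is not None for est in estimates):
        res = pd.Series(
            np.mean([est.residual_norm.to_numpy() for est in estimates], axis=0),
            index=ref_samples,
            name="residual_norm",
        )
    fr = pd.DataFrame(mean, index=pd.Index(order, name="cell_type"), columns=ref_samples)
    fr.attrs["ensemble_size"] = len(estimates)
    return CellFractions(fractions=fr, residual_norm=res)


def compare_fractions(
    fractions: CellFractions,
    anchor: pd.Series,
    adjust: str = "bh",
) -> pd.DataFrame:
    """Contrast each cell type's fractions between loss and neutral samples.

    Per cell type: median fraction difference (loss - neutral) and
    two-sided independent rank-sum p, with BH correction across cell types.
    A type constant in both groups gets p = 1 and a flag.
    """
    samples = [s for s in anchor.index if s in set(fractions.sample_ids)]
    a = anchor.loc[samples]
    loss = [s for s in samples if a[s] == 1]
    neutral = [s for s in samples if a[s] == 0]
    if len(loss) < 2 or len(neutral) < 2:
        raise DegenerateDataError("both groups need >= 2 samples")
    rows = []
    for ct in fractions.cell_types:
        x = fractions.fractions.loc[ct, loss].to_numpy(dtype=float)
        y = fractions.fractions.loc[ct, neutral].to_numpy(dtype=float)
        constant = np.ptp(np.concatenate([x, y])) == 0
        p = 1.0 if constant else rank_sum_p(x, y)
        rows.append(
            {
                "cell_type": ct,
                "median_diff": float(np.median(x) - np.median(y)),
                "p_value": p,
                "constant": constant,
            }
        )
    out = pd.DataFrame(rows)
    out["q_value"] = adjust_pvalues(out["p_value"].to_numpy(), method=adjust)
    return out


def consistent_fraction_shifts(
    comparison_a: pd.DataFrame,
    comparison_b: pd.DataFrame,
    q_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Cell types shifted the same way in two cohorts.

    Consistency = same sign of the median difference and q < cutoff in
    both cohorts; types absent from either cohort are excluded and listed
    in the ``excluded`` attribute.
    """
    a = comparison_a.set_index("cell_type")
    b = comparison_b.set_index("cell_type")
    shared = [ct for ct in a.index if ct in b.index]
    excluded = sorted(set(a.index) ^ set(b.index))
    rows = []
    for ct in shared:
        same_sign = np.sign(a.loc[ct, "median_diff"]) == np.sign(b.loc[ct, "median_diff"])
        sig = a.loc[ct, "q_value"] < q_cutoff and b.loc[ct, "q_value"] < q_cutoff
        if same_sign and sig and a.loc[ct, "median_diff"] != 0:
            rows.append(
                {
                    "cell_type": ct,
                    "median_diff_a": float(a.loc[ct, "median_diff"]),
                    "median_diff_b": float(b.loc[ct, "median_diff"]),
                }
            )
    out = pd.DataFrame(rows, columns=["cell_type", "median_diff_a", "median_diff_b"])
    out.attrs["excluded"] = excluded
    return out
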