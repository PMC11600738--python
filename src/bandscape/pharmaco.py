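"""Pharmacogenomic interaction screening.

Binary genomic features (mutations, focal CNAs, band-loss indicators) are
screened against per-drug log10 IC50 vectors.  Each (feature, drug, screen)
combination is summarised by

* the group mean difference of log10 IC50 (feature-positive minus
  feature-negative; negative = sensitivity),
* Glass' delta computed against both group standard deviations, with the
  effect-size cutoff applied to the smaller of the two (conservative),
* a Mann-Whitney U p-value with BH correction per screen,
* the point-biserial correlation r with a Fisher-z 95% CI and the
  negligible/small/medium/large magnitude boundaries at |r| = 0.10, 0.24
  and 0.37,
* optionally an elastic-net coefficient from a cross-validated penalised
  regression over all features (1-SE penalty rule).

The default volcano cutoffs are p < 0.001, FDR < 0.25 and Glass' delta
> 1.4; the anchor-only screen instead gates on adjusted p (q < 0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import ElasticNet
from sklearn.model_selection import KFold

from .datatypes import DrugResponseTable, FeatureMatrix
from .errors import DegenerateDataError, ValidationError
from .expression import adjust_pvalues

logger = logging.getLogger("bandscape")

MAGNITUDE_BOUNDS = (0.10, 0.24, 0.37)
DEFAULT_CUTOFFS = {"p": 0.001, "fdr": 0.25, "delta": 1.4}


@dataclass(frozen=True)
class PharmacoHit:
    feature: str
    drug: str
    screen_id: str
    n_pos: int
    n_neg: int
    mean_diff: float
    glass_delta_pos: float
    glass_delta_neg: float
    mw_p: float
    q: float
    r_pb: float
    r_ci_low: float
    r_ci_high: float
    magnitude: str
    direction: str  # sensitivity | resistance
    passes: bool
    untestable: bool = False
    enet_coef: float = float("nan")


def glass_delta(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float, float]:
    """Group mean difference and Glass' delta against each group's sd.

    Returns (mean_diff, delta_pos, delta_neg) where mean_diff =
    mean(pos) - mean(neg) and delta_k = |mean_diff| / sd_k (sample sd).
    A zero sd in either group makes the pair untestable; the caller flags
    it rather than receiving an exception, so NaN is returned for the
    affected delta.
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if len(pos) < 2 or len(neg) < 2:
        raise DegenerateDataError("glass_delta needs >= 2 values per group")
    mean_diff = float(pos.mean() - neg.mean())
    sd_pos = float(pos.std(ddof=1))
    sd_neg = float(neg.std(ddof=1))
    delta_pos = abs(mean_diff) / sd_pos if sd_pos > 0 else float("nan")
    delta_neg = abs(mean_diff) / sd_neg if sd_neg > 0 else float("nan")
    return mean_diff, delta_pos, delta_neg


def magnitude_of_r(r: float) -> str:
    a = abs(r)
    if a < MAGNITUDE_BOUNDS[0]:
        return "negligible"
    if a < MAGNITUDE_BOUNDS[1]:
        return "small"
    if a < MAGNITUDE_BOUNDS[2]:
        return "medium"
    return "large"


def point_biserial(
    indicator: np.ndarray, values: np.ndarray
) -> tuple[float, tuple[float, float], str]:
    """Point-biserial r with a Fisher-z 95% CI and magnitude label.

    r is the Pearson correlation of the 0/1 indicator with the values; the
    CI uses se = 1/sqrt(n-3) on the z scale and is undefined (NaN bounds)
    for n <= 3, where r is still returned.
    """
    x = np.asarray(indicator, dtype=float)
    y = np.asarray(values, dtype=float)
    n = len(x)
    if n < 4:
        if x.min() == x.max():
            raise DegenerateDataError("indicator has a single class")
        r = float(stats.pearsonr(x, y)[0]) if n >= 3 else float("nan")
        return r, (float("nan"), float("nan")), magnitude_of_r(r) if np.isfinite(r) else "negligible"
    if x.min() == x.max():
        raise DegenerateDataError("indicator has a single class")
    r = float(stats.pearsonr(x, y)[0])
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    se = 1.0 / np.sqrt(n - 3)
    lo, hi = np.tanh(z - 1.959963984540054 * se), np.tanh(z + 1.959963984540054 * se)
    return r, (float(lo), float(hi)), magnitude_of_r(r)


def mw_group_test(pos, neg, alternative: str = "two-sided") -> float:
    """Mann-Whitney U p: exact for combined n <= 20 without ties, else
    tie-corrected normal approximation."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise DegenerateDataError("both groups must be non-empty")
    pooled = np.concatenate([pos, neg])
    if np.ptp(pooled) == 0:
        return 1.0
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 20 and not ties) else "asymptotic"
    alt = {"two_sided": "two-sided"}.get(alternative, alternative)
    return float(stats.mannwhitneyu(pos, neg, alternative=alt, method=method).pvalue)


# ---------------------------------------------------------------------------
# elastic net


def elastic_net_screen(
    response: pd.Series,
    features: FeatureMatrix,
    mixing: float = 0.5,
    folds: int = 10,
    n_alphas: int = 50,
    random_state: int = 0,
) -> pd.Series:
    """Per-feature elastic-net coefficients at the 1-SE cross-validated penalty.

    Features are standardised before fitting; the returned coefficients are
    rescaled back to the raw 0/1 feature scale (log10 IC50 units per
    feature).  The penalty is chosen on a log-spaced grid by ``folds``-fold
    cross-validation, taking the largest penalty whose mean CV error is
    within one standard error of the minimum; nonzero coefficients mark
    candidate interactions.
    """
    lines = [cl for cl in features.cell_lines if cl in response.index]
    y = response.loc[lines].to_numpy(dtype=float)
    X = features.values.loc[lines].to_numpy(dtype=float)
    n, k = X.shape
    if n < 2 * folds:
        raise DegenerateDataError(f"need >= {2 * folds} cell lines with response, got {n}")
    if np.ptp(y) == 0:
        logger.warning("constant response: all elastic-net coefficients set to 0")
        return pd.Series(0.0, index=features.features)
    sd = X.std(axis=0, ddof=0)
    usable = sd > 0
    Xs = np.zeros_like(X)
    Xs[:, usable] = (X[:, usable] - X[:, usable].mean(axis=0)) / sd[usable]
    yc = y - y.mean()

    alpha_max = np.abs(Xs.T @ yc).max() / (n * max(mixing, 1e-3))
    alphas = np.logspace(np.log10(alpha_max), np.log10(alpha_max * 1e-3), n_alphas)

    kf = KFold(n_splits=folds, shuffle=True, random_state=random_state)
    cv_mse = np.zeros((folds, n_alphas))
    for f, (tr, te) in enumerate(kf.split(Xs)):
        for a, alpha in enumerate(alphas):
            model = ElasticNet(alpha=alpha, l1_ratio=mixing, fit_intercept=True, max_iter=5000)
            model.fit(Xs[tr], y[tr])
            cv_mse[f, a] = np.mean((y[te] - model.predict(Xs[te])) ** 2)
    mean_mse = cv_mse.mean(axis=0)
    se_mse = cv_mse.std(axis=0, ddof=1) / np.sqrt(folds)
    best = int(np.argmin(mean_mse))
    threshold = mean_mse[best] + se_mse[best]
    # largest alpha (earliest index: alphas descend) within one SE of the best
    one_se = int(np.nonzero(mean_mse <= threshold)[0][0])
    final = ElasticNet(alpha=alphas[one_se], l1_ratio=mixing, fit_intercept=True, max_iter=10000)
    final.fit(Xs, y)
    coefs = np.zeros(k)
    coefs[usable] = final.coef_[usable] / sd[usable]
    return pd.Series(coefs, index=features.features)


# ---------------------------------------------------------------------------
# screens


def _test_pair(
    feature: str,
    drug: str,
    screen: str,
    pos: np.ndarray,
    neg: np.ndarray,
) -> dict:
    mean_diff, d_pos, d_neg = glass_delta(pos, neg)
    p = mw_group_test(pos, neg)
    indicator = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    values = np.concatenate([pos, neg])
    r, (lo, hi), mag = point_biserial(indicator, values)
    return {
        "feature": feature,
        "drug": drug,
        "screen_id": screen,
        "n_pos": len(pos),
        "n_neg": len(neg),
        "mean_diff": mean_diff,
        "glass_delta_pos": d_pos,
        "glass_delta_neg": d_neg,
        "mw_p": p,
        "r_pb": r,
        "r_ci_low": lo,
        "r_ci_high": hi,
        "magnitude": mag,
        "direction": "sensitivity" if mean_diff < 0 else "resistance",
        "untestable": False,
    }


def interaction_screen(
    responses: DrugResponseTable,
    features: FeatureMatrix,
    min_group: int = 3,
    p_cutoff: float = DEFAULT_CUTOFFS["p"],
    fdr_cutoff: float = DEFAULT_CUTOFFS["fdr"],
    delta_cutoff: float = DEFAULT_CUTOFFS["delta"],
    pooled_bh: bool = False,
    response_col: str = "log10_ic50",
) -> pd.DataFrame:
    """Screen every feature against every (drug, screen) response vector.

    A pair is untestable when either genotype class has fewer than
    ``min_group`` responding lines or zero variance.  BH q-values are
    computed separately per screen by default (IC50 scales differ between
    screens); ``pooled_bh`` pools all tested pairs instead.  A pair passes
    iff mw_p < p_cutoff, q < fdr_cutoff, and min(delta_pos, delta_neg)
    > delta_cutoff.
    """
    if not features.features:
        raise ValidationError("empty feature set")
    rec = responses.records
    rows: list[dict] = []
    fm = features.values
    for (screen, drug), grp in rec.groupby(["screen_id", "drug"], sort=True):
        y = grp.set_index("cell_line")[response_col]
        lines = [cl for cl in fm.index if cl in y.index]
        if not lines:
            continue
        yv = y.loc[lines]
        for feature in fm.columns:
            mask = fm.loc[lines, feature].to_numpy() == 1
            pos = yv.to_numpy()[mask]
            neg = yv.to_numpy()[~mask]
            if len(pos) < min_group or len(neg) < min_group:
                rows.append(
                    {
                        "feature": feature,
                        "drug": drug,
                        "screen_id": screen,
                        "n_pos": len(pos),
                        "n_neg": len(neg),
                        "untestable": True,
                    }
                )
                continue
            row = _test_pair(feature, drug, screen, pos, neg)
            if not (np.isfinite(row["glass_delta_pos"]) and np.isfinite(row["glass_delta_neg"])):
                row["untestable"] = True
            rows.append(row)
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    for col in ("glass_delta_pos", "glass_delta_neg", "mw_p"):
        if col not in out.columns:
            out[col] = np.nan
    out["q"] = np.nan
    testable = ~out["untestable"]
    if pooled_bh:
        out.loc[testable, "q"] = adjust_pvalues(out.loc[testable, "mw_p"].to_numpy(), "bh")
    else:
        for screen in out["screen_id"].unique():
            m = testable & (out["screen_id"] == screen)
            if m.any():
                out.loc[m, "q"] = adjust_pvalues(out.loc[m, "mw_p"].to_numpy(), "bh")
    min_delta = out[["glass_delta_pos", "glass_delta_neg"]].min(axis=1)
    out["passes"] = (
        testable
        & (out["mw_p"] < p_cutoff)
        & (out["q"] < fdr_cutoff)
        & (min_delta > delta_cutoff)
    )
    return out.reset_index(drop=True)


def anchor_screen(
    responses: DrugResponseTable,
    features: FeatureMatrix,
    anchor_feature: str,
    q_cutoff: float = 0.05,
    fdr_cutoff: float = DEFAULT_CUTOFFS["fdr"],
    delta_cutoff: float = DEFAULT_CUTOFFS["delta"],
    min_group: int = 3,
    response_col: str = "log10_ic50",
) -> pd.DataFrame:
    """Anchor-only screen across all drugs and screens.

    Identical statistics restricted to one feature; drugs appearing in
    multiple screens are kept as separate records tagged by screen.  The
    pass rule gates on the BH-adjusted p (q < q_cutoff) in place of the raw
    p cutoff of the genome-wide screen.
    """
    if anchor_feature not in features.features:
        raise ValidationError(f"anchor feature {anchor_feature!r} not in feature matrix")
    single = FeatureMatrix(features.values[[anchor_feature]])
    out = interaction_screen(
        responses,
        single,
        min_group=min_group,
        p_cutoff=1.0,
        fdr_cutoff=fdr_cutoff,
        delta_cutoff=delta_cutoff,
        response_col=response_col,
    )
    if out.empty:
        return out
    testable = ~out["untestable"]
    min_delta = out[["glass_delta_pos", "glass_delta_neg"]].min(axis=1)
    out["passes"] = (
        testable
        & (out["q"] < q_cutoff)
        & (out["q"] < fdr_cutoff)
        & (min_delta > delta_cutoff)
    )
    return out


def pdx_group_comparison(auc_pos, auc_neg) -> dict:
    """Two-group comparison of PDX response AUCs (no curve fitting)."""
    mean_diff, d_pos, d_neg = glass_delta(auc_pos, auc_neg)
    return {
        "mean_diff": mean_diff,
        "glass_delta_pos": d_pos,
        "glass_delta_neg": d_neg,
        "mw_p": mw_group_test(auc_pos, auc_neg),
        "median_pos": float(np.median(auc_pos)),
        "median_neg": float(np.median(auc_neg)),
    }
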