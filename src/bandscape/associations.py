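"""Co-occurrence / mutual-exclusivity screening against a binary anchor.

Each feature is crossed with the anchor event in a 2x2 table and tested
with a two-sided Fisher exact test.  The association is summarised by

* ``odds_ratio`` = (a d)/(b c), with the Haldane-Anscombe +0.5 applied to
  all four cells if and only if any cell is zero (the exact p always uses
  the raw counts),
* ``direction`` = log2(odds ratio),
* ``score`` = -log10(p) x direction, so positive scores mark co-occurrence
  and negative scores mutual exclusivity; p = 1 gives score 0 regardless
  of the odds ratio.

A feature is called co_occurring when p < alpha and direction > 0,
mutually_exclusive when p < alpha and direction < 0, else not_significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CohortTable
from .errors import DegenerateDataError, ValidationError

logger = logging.getLogger("bandscape")

CO_OCCURRING = "co_occurring"
MUTUALLY_EXCLUSIVE = "mutually_exclusive"
NOT_SIGNIFICANT = "not_significant"


@dataclass(frozen=True)
class AssociationResult:
    feature_id: str
    a: int  # anchor+ feature+
    b: int  # anchor+ feature-
    c: int  # anchor- feature+
    d: int  # anchor- feature-
    odds_ratio: float
    p_value: float
    direction: float  # log2(odds ratio)
    score: float  # -log10(p) * direction
    call: str
    flagged_adjacent: bool = False

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def binary_anchor(
    band_statuses: pd.Series,
    loss_def: frozenset[str] | set[str] = frozenset({"loss", "deep_loss"}),
) -> tuple[pd.Series, list[str]]:
    """Per-sample 0/1 anchor vector: 1 = loss (per loss_def), 0 = neutral.

    Samples with gain, amplification, ambiguous or missing status are
    excluded from the contrast and returned in the excluded list.
    """
    is_loss = band_statuses.isin(loss_def)
    is_neutral = band_statuses == "neutral"
    keep = is_loss | is_neutral
    excluded = list(band_statuses.index[~keep])
    anchor = is_loss[keep].astype(int)
    if anchor.empty or anchor.nunique() < 2:
        raise DegenerateDataError(
            "anchor is degenerate: need both loss and neutral samples "
            f"(got {int(anchor.sum()) if not anchor.empty else 0} loss of {len(anchor)})"
        )
    return anchor, excluded


def odds_ratio_haldane(a: int, b: int, c: int, d: int) -> float:
    """Cross-product odds ratio with +0.5 on all cells iff any cell is 0."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def fisher_association(
    anchor: pd.Series | np.ndarray,
    feature: pd.Series | np.ndarray,
    feature_id: str = "",
    alpha: float = 0.05,
) -> AssociationResult:
    """Two-sided Fisher exact association of one feature with the anchor."""
    x = np.asarray(anchor, dtype=int)
    y = np.asarray(feature, dtype=int)
    if x.shape != y.shape:
        raise ValidationError(f"anchor and feature lengths differ: {x.shape} vs {y.shape}")
    a = int(np.sum((x == 1) & (y == 1)))
    b = int(np.sum((x == 1) & (y == 0)))
    c = int(np.sum((x == 0) & (y == 1)))
    d = int(np.sum((x == 0) & (y == 0)))
    return fisher_from_counts(a, b, c, d, feature_id=feature_id, alpha=alpha)


def fisher_from_counts(
    a: int, b: int, c: int, d: int, feature_id: str = "", alpha: float = 0.05
) -> AssociationResult:
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    orr = odds_ratio_haldane(a, b, c, d)
    direction = float(np.log2(orr))
    score = 0.0 if p >= 1.0 else float(-np.log10(p) * direction)
    if p < alpha and direction > 0:
        call = CO_OCCURRING
    elif p < alpha and direction < 0:
        call = MUTUALLY_EXCLUSIVE
    else:
        call = NOT_SIGNIFICANT
    return AssociationResult(
        feature_id=feature_id,
        a=a,
        b=b,
        c=c,
        d=d,
        odds_ratio=float(orr),
        p_value=float(p),
        direction=direction,
        score=score,
        call=call,
    )


def screen_features(
    anchor: pd.Series,
    features: pd.DataFrame,
    min_prevalence: float = 0.02,
    alpha: float = 0.05,
    adjacent_features: set[str] | None = None,
    adjust: str | None = None,
) -> list[AssociationResult]:
    """Screen every binary feature column against the anchor.

    Features with prevalence below ``min_prevalence`` among the anchored
    samples are dropped before testing (mirroring the >2% mutation-frequency
    floor).  Results are sorted by |score| descending.  Band features on the
    anchor's chromosome arm may be passed in ``adjacent_features``; they are
    flagged (adjacency caveat) but not removed.  ``adjust="bh"`` applies a
    Benjamini-Hochberg correction to the p-values used for calls (off by
    default: the screen keeps raw p < alpha).
    """
    if not 0 <= min_prevalence < 1:
        raise ValidationError("min_prevalence must be in [0, 1)")
    feats = features.reindex(index=anchor.index)
    if feats.isna().any().any():
        raise ValidationError("features missing for some anchored samples")
    prevalence = feats.mean(axis=0)
    tested = [f for f in feats.columns if prevalence[f] >= min_prevalence]
    if not tested:
        logger.warning("no features above prevalence %.3f; empty screen", min_prevalence)
        return []
    results = [
        fisher_association(anchor, feats[f], feature_id=f, alpha=alpha) for f in tested
    ]
    if adjust == "bh":
        from .expression import adjust_pvalues

        q = adjust_pvalues([r.p_value for r in results], method="bh")
        redone = []
        for r, qi in zip(results, q):
            if qi < alpha and r.direction > 0:
                call = CO_OCCURRING
            elif qi < alpha and r.direction < 0:
                call = MUTUALLY_EXCLUSIVE
            else:
                call = NOT_SIGNIFICANT
            redone.append(
                AssociationResult(
                    r.feature_id, r.a, r.b, r.c, r.d, r.odds_ratio, qi, r.direction,
                    0.0 if qi >= 1 else float(-np.log10(qi) * r.direction), call,
                )
            )
        results = redone
    if adjacent_features:
        results = [
            AssociationResult(
                r.feature_id, r.a, r.b, r.c, r.d, r.odds_ratio, r.p_value,
                r.direction, r.score, r.call,
                flagged_adjacent=r.feature_id in adjacent_features,
            )
            for r in results
        ]
    return sorted(results, key=lambda r: (-abs(r.score), r.feature_id))


def cross_cohort_consistency(
    results_a: list[AssociationResult],
    results_b: list[AssociationResult],
) -> pd.DataFrame:
    """Features carrying the same significant call in both cohorts.

    A feature is consistent iff its call is co_occurring in both cohorts or
    mutually_exclusive in both; both scores are preserved in the output.
    """
    by_a = {r.feature_id: r for r in results_a}
    by_b = {r.feature_id: r for r in results_b}
    shared = sorted(set(by_a) & set(by_b))
    if not shared:
        logger.warning("no shared features between cohorts")
    rows = []
    for f in shared:
        ra, rb = by_a[f], by_b[f]
        if ra.call == rb.call and ra.call in (CO_OCCURRING, MUTUALLY_EXCLUSIVE):
            rows.append(
                {"feature_id": f, "call": ra.call, "score_a": ra.score, "score_b": rb.score}
            )
    return pd.DataFrame(rows, columns=["feature_id", "call", "score_a", "score_b"])


def stratified_screen(
    anchor: pd.Series,
    features: pd.DataFrame,
    clinical: CohortTable,
    grouping: str = "pam50",
    min_prevalence: float = 0.02,
    alpha: float = 0.05,
) -> tuple[dict[str, list[AssociationResult]], list[str]]:
    """Run the screen independently inside each subtype stratum.

    Strata where the anchor is degenerate (one class only) are reported as
    untestable rather than raising.
    """
    clin = clinical.rows.set_index("sample_id")
    if grouping == "pam50":
        labels = clin["pam50"]
    elif grouping == "er_her2":
        labels = clin["er"].astype(str) + "/" + clin["her2"].astype(str)
    else:
        raise ValidationError(f"unknown grouping {grouping!r}")
    labels = labels.reindex(anchor.index)
    per_stratum: dict[str, list[AssociationResult]] = {}
    untestable: list[str] = []
    for level in sorted(labels.dropna().unique()):
        idx = labels.index[labels == level]
        sub_anchor = anchor.loc[idx]
        try:
            if sub_anchor.nunique() < 2:
                raise DegenerateDataError("single anchor class")
            per_stratum[level] = screen_features(
                sub_anchor, features.loc[idx], min_prevalence=min_prevalence, alpha=alpha
            )
        except DegenerateDataError:
            untestable.append(level)
    return per_stratum, untestable
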