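"""Kaplan-Meier estimation and log-rank comparison.

The product-limit estimator and the two-group log-rank test are implemented
directly (they are the whole of this module's statistical content, and the
exhaustive small-sample oracle tests exercise every censoring pattern).
At tied times, events are processed before censorings: a sample censored at
t is still at risk for an event at t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CohortTable
from .errors import DegenerateDataError

LOSS_DEF = frozenset({"loss", "deep_loss"})


@dataclass(frozen=True)
class SurvivalComparison:
    n_groups: tuple[int, int]
    curves: tuple[pd.DataFrame, pd.DataFrame]
    logrank_chi2: float
    logrank_p: float
    zero_events: bool = False


def km_estimate(times, events) -> pd.DataFrame:
    """Product-limit survival curve with right censoring.

    Returns one row per distinct event time: at_risk, events and the
    survival probability S(t).  Censored observations reduce the risk set
    without contributing events; all-censored input gives S = 1 throughout
    (an empty event-time table).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise DegenerateDataError("empty survival input")
    if (t < 0).any():
        raise DegenerateDataError("negative survival times")
    if not np.isin(e, (0, 1)).all():
        raise DegenerateDataError("events must be 0/1")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    rows = []
    s = 1.0
    for ti in np.unique(t[e == 1]):
        at_risk = int(np.sum(t >= ti))  # censored at ti still at risk
        d = int(np.sum((t == ti) & (e == 1)))
        s *= 1.0 - d / at_risk
        rows.append({"time": float(ti), "at_risk": at_risk, "events": d, "survival": s})
    return pd.DataFrame(rows, columns=["time", "at_risk", "events", "survival"])


def logrank_test(times_a, events_a, times_b, events_b) -> SurvivalComparison:
    """Two-group log-rank test with hypergeometric variance per event time.

    Zero total events gives p = 1 with the ``zero_events`` flag set.
    """
    ta = np.asarray(times_a, dtype=float)
    ea = np.asarray(events_a, dtype=int)
    tb = np.asarray(times_b, dtype=float)
    eb = np.asarray(events_b, dtype=int)
    if ta.size == 0 or tb.size == 0:
        raise DegenerateDataError("both groups must be non-empty")
    curves = (km_estimate(ta, ea), km_estimate(tb, eb))
    all_t = np.concatenate([ta, tb])
    all_e = np.concatenate([ea, eb])
    grp = np.concatenate([np.zeros(ta.size, dtype=int), np.ones(tb.size, dtype=int)])
    event_times = np.unique(all_t[all_e == 1])
    if event_times.size == 0:
        return SurvivalComparison((ta.size, tb.size), curves, 0.0, 1.0, zero_events=True)
    obs_a = 0.0
    exp_a = 0.0
    var = 0.0
    for ti in event_times:
        at_risk = all_t >= ti
        n_tot = int(at_risk.sum())
        n_a = int((at_risk & (grp == 0)).sum())
        d_tot = int(((all_t == ti) & (all_e == 1)).sum())
        d_a = int(((all_t == ti) & (all_e == 1) & (grp == 0)).sum())
        obs_a += d_a
        exp_a += d_tot * n_a / n_tot
        if n_tot > 1:
            var += (
                d_tot
                * (n_a / n_tot)
                * (1 - n_a / n_tot)
                * (n_tot - d_tot)
                / (n_tot - 1)
            )
    if var == 0:
        return SurvivalComparison((ta.size, tb.size), curves, 0.0, 1.0, zero_events=False)
    chi2 = (obs_a - exp_a) ** 2 / var
    p = float(stats.chi2.sf(chi2, df=1))
    return SurvivalComparison((ta.size, tb.size), curves, float(chi2), p)


def survival_by_group(
    clinical: CohortTable,
    band_statuses: pd.Series,
    strata: str = "all",
    loss_def: frozenset[str] = LOSS_DEF,
    min_per_class: int = 5,
) -> tuple[dict[str, SurvivalComparison], list[str]]:
    """Loss-vs-neutral survival comparison, overall or per subtype.

    ``strata`` is ``all``, ``er_her2`` or ``pam50``.  A stratum needs at
    least ``min_per_class`` patients in each anchor class (configurable
    floor); under-sized strata are reported untestable rather than raising.
    Rows lacking survival time or event are dropped.
    """
    clin = clinical.rows.set_index("sample_id")
    shared = [s for s in band_statuses.index if s in clin.index]
    status = band_statuses.loc[shared]
    is_loss = status.isin(loss_def)
    is_neutral = status == "neutral"
    keep = (is_loss | is_neutral) & clin.loc[shared, "os_months"].notna().to_numpy() & clin.loc[
        shared, "os_event"
    ].notna().to_numpy()
    samples = status.index[keep]
    anchor = is_loss.loc[samples].astype(int)

    if strata == "all":
        labels = pd.Series("all", index=samples)
    elif strata == "pam50":
        labels = clin.loc[samples, "pam50"]
    elif strata == "er_her2":
        labels = clin.loc[samples, "er"].astype(str) + "/" + clin.loc[samples, "her2"].astype(str)
    else:
        raise DegenerateDataError(f"unknown strata {strata!r}")

    comparisons: dict[str, SurvivalComparison] = {}
    untestable: list[str] = []
    for level in sorted(labels.dropna().unique()):
        idx = labels.index[labels == level]
        a = anchor.loc[idx]
        loss_idx = a.index[a == 1]
        neut_idx = a.index[a == 0]
        if len(loss_idx) < min_per_class or len(neut_idx) < min_per_class:
            untestable.append(level)
            continue
        comparisons[level] = logrank_test(
            clin.loc[loss_idx, "os_months"],
            clin.loc[loss_idx, "os_event"].astype(int),
            clin.loc[neut_idx, "os_months"],
            clin.loc[neut_idx, "os_event"].astype(int),
        )
    return comparisons, untestable
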