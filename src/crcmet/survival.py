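"""Survival statistics and the survival-predictive CNA selection (SPPS).

Kaplan-Meier estimation, the two-group log-rank test and univariate Cox
proportional-hazards fits (Efron tie handling) are delegated to lifelines;
this module wraps them behind small typed results and implements the SPPS
procedure: for each candidate CNA region, samples carrying a same-direction
call over enough of the region form the In-Group, everyone else the
Out-Group, and disease-free survival is compared by log-rank. "Mean
survival" is reported as the restricted mean survival time (RMST) up to the
last observed time, since a marginal mean is undefined under censoring.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError, ConvergenceWarning
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.utils import restricted_mean_survival_time

log = logging.getLogger(__name__)

CLINICAL_COLUMNS = [
    "sample_id",
    "dfs_time",
    "dfs_event",
    "os_time",
    "os_event",
    "group",
    "msi",
    "stage",
    "grade",
]


@dataclass
class CoxFit:
    coef: float  # log hazard ratio per unit covariate
    se: float
    p: float  # Wald
    n: int
    n_events: int
    converged: bool = True
    separation_flag: bool = False


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and its upper-tail p-value."""
    times_a, times_b = np.asarray(times_a, float), np.asarray(times_b, float)
    events_a, events_b = np.asarray(events_a, int), np.asarray(events_b, int)
    if len(times_a) == 0 or len(times_b) == 0:
        raise ValueError("both groups must be non-empty")
    if events_a.sum() + events_b.sum() == 0:
        raise ValueError("log-rank undefined with zero events")
    res = _ll_logrank(times_a, times_b, event_observed_A=events_a, event_observed_B=events_b)
    return float(res.test_statistic), float(res.p_value)


def cox_fit(covariate, times, events) -> CoxFit:
    """Univariate Cox PH fit on the partial likelihood (Efron ties), Wald p."""
    x = np.asarray(covariate, float)
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    if not np.isfinite(x).all():
        raise ValueError("covariate contains non-finite values")
    if len(np.unique(x[e == 1])) < 2:
        raise ValueError("need >=2 distinct covariate values among event samples")
    df = pd.DataFrame({"x": x, "t": t, "e": e})
    cph = CoxPHFitter()
    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            cph.fit(df, duration_col="t", event_col="e")
        except ConvergenceError as err:
            raise RuntimeError(f"Cox fit did not converge: {err}") from err
        separation = any(issubclass(w.category, ConvergenceWarning) for w in caught)
    return CoxFit(
        coef=float(cph.params_["x"]),
        se=float(cph.standard_errors_["x"]),
        p=float(cph.summary.loc["x", "p"]),
        n=len(df),
        n_events=int(e.sum()),
        converged=True,
        separation_flag=separation,
    )


def kaplan_meier(times, events) -> pd.DataFrame:
    """KM survival curve as a (time, survival) table; S=1 before first event."""
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(times, float), np.asarray(events, int))
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()})


def restricted_mean(times, events, tau: float | None = None) -> float:
    t = np.asarray(times, float)
    kmf = KaplanMeierFitter().fit(t, np.asarray(events, int))
    return float(restricted_mean_survival_time(kmf, t=tau if tau is not None else t.max()))


def _region_coverage(
    region: pd.Series, calls: pd.DataFrame, sample: str
) -> float:
    """Fraction of the region covered by the union of this sample's
    same-direction calls (0-based half-open arithmetic)."""
    sub = calls[
        (calls["sample_id"] == sample)
        & (calls["chrom"] == region["chrom"])
        & (calls["direction"] == region["direction"])
        & (calls["start"] < region["end"])
        & (calls["end"] > region["start"])
    ]
    if sub.empty:
        return 0.0
    ivs = sorted(
        (max(int(s), int(region["start"])), min(int(e), int(region["end"])))
        for s, e in zip(sub["start"], sub["end"])
    )
    covered, cur_s, cur_e = 0, *ivs[0]
    for s, e in ivs[1:]:
        if s > cur_e:
            covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    covered += cur_e - cur_s
    return covered / (int(region["end"]) - int(region["start"]))


def spps_select(
    regions: pd.DataFrame,
    calls: pd.DataFrame,
    clinical: pd.DataFrame,
    min_cover: float = 0.5,
    alpha: float = 0.05,
    endpoint: str = "dfs",
) -> pd.DataFrame:
    """Select regions whose carriers have different (worse) survival.

    For each region the In-Group is the set of samples whose same-direction
    calls cover >= min_cover of the region; log-rank compares the endpoint
    between In- and Out-Group. Regions with an empty In- or Out-Group are
    skipped with a warning. The returned table carries the log-rank
    statistic, p-value, group sizes, per-group RMST, and a ``selected``
    flag (p < alpha).
    """
    tcol, ecol = f"{endpoint}_time", f"{endpoint}_event"
    rows = []
    samples = clinical["sample_id"].tolist()
    for _, region in regions.iterrows():
        cover = np.array([_region_coverage(region, calls, s) for s in samples])
        in_mask = cover >= min_cover
        if in_mask.all() or not in_mask.any():
            log.warning(
                "SPPS skip %s:%s-%s (%s): empty %s-group",
                region["chrom"], region["start"], region["end"],
                region["direction"], "Out" if in_mask.all() else "In",
            )
            continue
        t = clinical[tcol].to_numpy(float)
        e = clinical[ecol].to_numpy(int)
        stat, p = logrank_test(t[in_mask], e[in_mask], t[~in_mask], e[~in_mask])
        row = dict(region)
        row.update(
            n_in=int(in_mask.sum()),
            n_out=int((~in_mask).sum()),
            logrank_stat=stat,
            p_spps=p,
            rmst_in=restricted_mean(t[in_mask], e[in_mask], tau=float(t.max())),
            rmst_out=restricted_mean(t[~in_mask], e[~in_mask], tau=float(t.max())),
            selected=p < alpha,
        )
        rows.append(row)
    return pd.DataFrame(rows)
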