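"""Lifespan-assay statistics: Kaplan–Meier, Mantel–Cox log-rank, Fisher's exact.

Worms are scored alive/dead/censored on an every-other-day grid; censored
animals (bagging, desiccation, contamination, handling error) leave the
risk set at their recorded day without counting as deaths. Group survival
is estimated with the product-limit (Kaplan–Meier) estimator and
summarized by the restricted mean lifespan (area under the survival curve
up to the last observed day) and the 75%-mortality day (first recorded day
with survival <= 0.25). Groups are compared pairwise with the Mantel–Cox
log-rank test, Bonferroni-corrected across comparisons. Marker-penetrance
2x2 tables are scored with Fisher's exact test (two-sided, probability-mass
rule).
"""

from __future__ import annotations

import itertools
import warnings
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .datatypes import (
    ContingencyTable2x2,
    KMCurve,
    LifespanSummary,
    LogRankResult,
    SurvivalRecord,
)
from .exceptions import InvalidConfigError

__all__ = [
    "km_estimate",
    "lifespan_summary",
    "logrank_test",
    "fisher_exact",
    "lifespan_pipeline",
]


def _to_arrays(records: Sequence[SurvivalRecord]) -> Tuple[np.ndarray, np.ndarray]:
    days = np.array([r.event_day for r in records], dtype=float)
    observed = np.array([r.status == "dead" for r in records], dtype=bool)
    return days, observed


def km_estimate(records: Sequence[SurvivalRecord], group: str = "") -> KMCurve:
    """Product-limit survival estimate for one group of worms.

    Ties are handled with the standard simultaneous-death convention, and
    worms censored on a death day are kept at risk for that day's deaths
    (deaths processed before censorings at the same recorded day).
    """
    if len(records) == 0:
        raise InvalidConfigError("cannot estimate survival from an empty group")
    days, observed = _to_arrays(records)
    kmf = KaplanMeierFitter()
    kmf.fit(days, event_observed=observed)
    table = kmf.event_table  # indexed by time, includes t=0 row
    times = table.index.to_numpy(dtype=float)
    keep = times > 0
    times = times[keep]
    surv = kmf.survival_function_at_times(times).to_numpy(dtype=float)
    return KMCurve(
        times=times,
        survival=surv,
        at_risk=table["at_risk"].to_numpy(dtype=int)[keep],
        deaths=table["observed"].to_numpy(dtype=int)[keep],
        censored=table["censored"].to_numpy(dtype=int)[keep],
        group=group,
    )


def lifespan_summary(curve: KMCurve, n: Optional[int] = None,
                     n_censored: Optional[int] = None) -> LifespanSummary:
    """Restricted-mean lifespan and 75%-mortality day from a KM curve.

    The mean is the area under the survival step function from day 0 to
    the largest observed day (the restricted mean survival time). The
    75%-mortality day is the first recorded day on which survival has
    dropped to <= 0.25; if survival never reaches 0.25 (heavy censoring),
    it is undefined and flagged.
    """
    times = np.concatenate([[0.0], curve.times])
    surv = np.concatenate([[1.0], curve.survival])
    # S is right-continuous: on (t_{i-1}, t_i] survival is surv[i-1]
    mean = float(np.sum(np.diff(times) * surv[:-1]))
    below = curve.survival <= 0.25
    if np.any(below):
        day75: Optional[float] = float(curve.times[np.argmax(below)])
        defined = True
    else:
        day75, defined = None, False
    if n is None:
        n = int(curve.deaths.sum() + curve.censored.sum())
    if n_censored is None:
        n_censored = int(curve.censored.sum())
    return LifespanSummary(mean_lifespan=mean, day75=day75, n=n,
                           n_censored=n_censored, group=curve.group,
                           day75_defined=defined)


def logrank_test(records_a: Sequence[SurvivalRecord],
                 records_b: Sequence[SurvivalRecord],
                 n_comparisons: int = 1,
                 groups: Tuple[str, str] = ("A", "B")) -> LogRankResult:
    """Mantel–Cox log-rank comparison of two groups (1 df).

    The Bonferroni-corrected p multiplies p by ``n_comparisons`` and caps
    at 1, matching correction across a family of pairwise strain
    comparisons.
    """
    if len(records_a) == 0 or len(records_b) == 0:
        raise InvalidConfigError("both groups must be nonempty")
    da, oa = _to_arrays(records_a)
    db, ob = _to_arrays(records_b)
    if oa.sum() + ob.sum() == 0:
        warnings.warn("no observed deaths in either group; statistic is 0")
        return LogRankResult(chi_square=0.0, df=1, p=1.0,
                             p_bonferroni=1.0, groups=groups)
    if oa.sum() == 0 or ob.sum() == 0:
        warnings.warn("a group has zero observed deaths")
    res = _ll_logrank(da, db, event_observed_A=oa, event_observed_B=ob)
    chi2 = float(res.test_statistic)
    p = float(res.p_value)
    return LogRankResult(chi_square=chi2, df=1, p=p,
                         p_bonferroni=min(1.0, p * n_comparisons),
                         groups=groups)


def fisher_exact(table: Union[ContingencyTable2x2, Sequence[Sequence[int]]]) -> float:
    """Two-sided Fisher's exact p-value for a 2x2 count table.

    Two-sided by the probability-mass rule: the p-value sums the
    hypergeometric probabilities of all tables with the observed margins
    that are no more probable than the observed one.
    """
    if not isinstance(table, ContingencyTable2x2):
        (a, b), (c, d) = table
        table = ContingencyTable2x2(int(a), int(b), int(c), int(d))
    arr = table.array
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        warnings.warn("a margin of the table is empty; p = 1")
        return 1.0
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


def lifespan_pipeline(
    records: Union[Sequence[SurvivalRecord], pd.DataFrame],
    control: Optional[str] = None,
) -> Dict[str, object]:
    """Per-group KM curves, lifespan summaries, and pairwise log-rank tests.

    Parameters
    ----------
    records : sequence of SurvivalRecord or DataFrame
        A DataFrame must have columns worm_id, group, event_day, status.
    control : str, optional
        When given, each other group is compared against this one;
        otherwise all pairs are compared. Bonferroni correction uses the
        number of comparisons actually performed.

    Returns
    -------
    dict with keys ``curves`` (group -> KMCurve), ``summaries``
    (group -> LifespanSummary) and ``comparisons`` (list of LogRankResult).
    """
    if isinstance(records, pd.DataFrame):
        records = [
            SurvivalRecord(worm_id=str(r.worm_id), group=str(r.group),
                           event_day=float(r.event_day), status=str(r.status))
            for r in records.itertuples(index=False)
        ]
    by_group: Dict[str, List[SurvivalRecord]] = {}
    for r in records:
        by_group.setdefault(r.group, []).append(r)
    if not by_group:
        raise InvalidConfigError("no survival records given")
    for r in records:
        if r.event_day % 2 != 0:
            warnings.warn(
                f"event day {r.event_day} (worm {r.worm_id}) is off the "
                "every-other-day scoring grid"
            )
            break

    curves = {g: km_estimate(rs, group=g) for g, rs in by_group.items()}
    summaries = {}
    for g, rs in by_group.items():
        n_cens = sum(1 for r in rs if r.status == "censored")
        summaries[g] = lifespan_summary(curves[g], n=len(rs), n_censored=n_cens)
        if n_cens == len(rs):
            warnings.warn(f"group {g!r} is fully censored; summaries undefined")

    if control is not None and control not in by_group:
        raise InvalidConfigError(f"control group {control!r} not in data")
    if control is not None:
        pairs = [(control, g) for g in by_group if g != control]
    else:
        pairs = list(itertools.combinations(sorted(by_group), 2))
    comparisons = [
        logrank_test(by_group[a], by_group[b], n_comparisons=max(1, len(pairs)),
                     groups=(a, b))
        for a, b in pairs
    ]
    return {"curves": curves, "summaries": summaries, "comparisons": comparisons}
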