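"""Kaplan-Meier estimation and log-rank comparison of Wnt+ vs Wnt- patients.

The product-limit estimator and its Greenwood variance come from lifelines;
the two-group log-rank test is computed from the combined lifetable (observed
minus expected events under the hypergeometric null at each event time) so
that the per-group O, E and variance the result reports are the actual
accumulated quantities.  Ties follow the standard convention that events
precede censoring at equal times, i.e. a subject censored at t is still at
risk for events at t.

Site-specific metastasis-free survival is cause-specific: metastases at
other sites are converted to censoring at their event time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .io import METASTASIS_SITES, SurvivalRecord


@dataclass
class KMCurve:
    """Product-limit curve: event times, risk sets, events, S(t), Greenwood SE."""

    times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray
    se: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function evaluation; S = 1 before the first event."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def se_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 0.0 if idx < 0 else float(self.se[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "at_risk": self.at_risk,
                             "events": self.events, "survival": self.survival,
                             "se": self.se})


@dataclass
class LogrankResult:
    """Two-group log-rank: per-group O and E, variance, chi-square, p."""

    groups: tuple[str, str]
    observed: dict[str, float]
    expected: dict[str, float]
    variance: float
    statistic: float
    p_value: float


def km_estimate(records: Sequence[SurvivalRecord]) -> KMCurve:
    """Kaplan-Meier curve over one endpoint's records.

    With no events the curve is identically 1 (empty event-time vector).
    """
    if len(records) == 0:
        raise ValueError("no survival records")
    times = np.array([r.time for r in records])
    events = np.array([r.event for r in records])
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    t = ev.index.to_numpy(dtype=float)
    n_j = ev["at_risk"].to_numpy(dtype=float)
    d_j = ev["observed"].to_numpy(dtype=float)
    surv = kmf.survival_function_.loc[t, "KM_estimate"].to_numpy(dtype=float)
    # Greenwood: Var S(t) = S(t)^2 * sum_{t_j <= t} d_j / (n_j (n_j - d_j))
    with np.errstate(divide="ignore"):
        terms = np.where(n_j > d_j, d_j / (n_j * (n_j - d_j)), np.inf)
    cum = np.cumsum(terms)
    se = np.where(surv > 0, surv * np.sqrt(cum), 0.0)
    return KMCurve(times=t, at_risk=n_j, events=d_j, survival=surv, se=se)


def logrank_test(records: Sequence[SurvivalRecord],
                 groups: Mapping[str, str] | pd.Series) -> LogrankResult:
    """Two-group log-rank test from the combined lifetable.

    ``groups`` maps sample id to one of exactly two labels.  Records without
    a group label are dropped.  Errors if a group ends up with no subjects
    or if there are no events at all.
    """
    groups = pd.Series(groups)
    labels = [groups.get(r.sample_id) for r in records]
    kept = [(r, g) for r, g in zip(records, labels) if g is not None and not pd.isna(g)]
    if not kept:
        raise ValueError("no records with a group label")
    names = sorted({g for _, g in kept})
    if len(names) != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, got {names}")
    g0, g1 = names
    time = np.array([r.time for r, _ in kept])
    event = np.array([r.event for r, _ in kept])
    in_g0 = np.array([g == g0 for _, g in kept])
    if in_g0.all() or not in_g0.any():
        raise ValueError(f"group with zero subjects among {names}")
    if event.sum() == 0:
        raise ValueError("no events in either group; log-rank undefined")

    event_times = np.unique(time[event == 1])
    O0 = E0 = V = 0.0
    for t in event_times:
        at_risk = time >= t  # censored-at-t subjects still at risk (ties convention)
        n = at_risk.sum()
        n0 = (at_risk & in_g0).sum()
        d = ((time == t) & (event == 1)).sum()
        d0 = ((time == t) & (event == 1) & in_g0).sum()
        O0 += d0
        E0 += d * n0 / n
        if n > 1:
            V += d * (n0 / n) * (1 - n0 / n) * (n - d) / (n - 1)
    O_total = float(event.sum())
    if V == 0:
        statistic, p = 0.0, 1.0
    else:
        statistic = (O0 - E0) ** 2 / V
        p = float(max(stats.chi2.sf(statistic, df=1), np.finfo(float).tiny))
    return LogrankResult(
        groups=(g0, g1),
        observed={g0: float(O0), g1: O_total - float(O0)},
        expected={g0: float(E0), g1: O_total - float(E0)},
        variance=float(V), statistic=float(statistic), p_value=p,
    )


def site_specific_records(records: Sequence[SurvivalRecord],
                          site: str) -> list[SurvivalRecord]:
    """Cause-specific MFS records for one metastasis site.

    Events at the named site stay events; metastases at other sites become
    censoring at their event time; censored records pass through.  Only MFS
    records are considered; their absence is an error.
    """
    if site not in ("lung", "brain", "bone"):
        raise ValueError(f"site must be lung, brain or bone, got {site!r}")
    mfs = [r for r in records if r.endpoint == "MFS"]
    if not mfs:
        raise ValueError("no MFS records present")
    out = []
    for r in mfs:
        if r.event == 1:
            if r.site is None or r.site not in METASTASIS_SITES:
                raise ValueError(f"MFS event without valid site: {r.sample_id}")
            if r.site == site:
                out.append(r)
            else:
                out.append(SurvivalRecord(r.sample_id, r.time, 0, "MFS", None))
        else:
            out.append(r)
    return out


def endpoint_records(records: Sequence[SurvivalRecord],
                     endpoint: str) -> list[SurvivalRecord]:
    """Subset to one endpoint (OS, RFS or MFS)."""
    out = [r for r in records if r.endpoint == endpoint]
    if not out:
        raise ValueError(f"no records for endpoint {endpoint!r}")
    return out
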