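"""Kaplan-Meier estimation and two-group log-rank testing.

Larval survival is recorded on a fixed observation grid until pupation;
subjects alive at the last observation are right-censored.  The survivor
function is the product-limit estimate S(t) = prod_{t_i <= t} (1 - d_i/n_i)
with subjects censored at an event time still counted at risk for that
time.  Two groups are compared with the log-rank chi-square (df = 1) built
from the observed-minus-expected deaths and hypergeometric variance over
the shared event times.  Estimation and testing are delegated to
``lifelines``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .errors import InputError

logger = logging.getLogger(__name__)


@dataclass
class KmCurve:
    group: str
    event_times: np.ndarray   # ascending distinct event times
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray      # S(t) just after each event time

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    @property
    def final_survival(self) -> float:
        return 1.0 if len(self.survival) == 0 else float(self.survival[-1])


@dataclass(frozen=True)
class LogRankResult:
    chi_square: float
    df: int
    p_value: float


def _group_arrays(data: pd.DataFrame, group: str):
    sub = data[data["group"] == group]
    if sub.empty:
        raise InputError(f"group {group!r} not present in survival data")
    t = sub["time_days"].to_numpy(dtype=float)
    e = sub["event"].to_numpy(dtype=int)
    if (t <= 0).any():
        raise InputError("survival times must be positive")
    if not set(np.unique(e)) <= {0, 1}:
        raise InputError("event must be 0 (censored) or 1 (death)")
    return t, e


def km_estimate(data: pd.DataFrame, group: str) -> KmCurve:
    """Product-limit survivor curve for one group of (time, event) records."""
    t, e = _group_arrays(data, group)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    ev = kmf.event_table
    mask = ev["observed"] > 0
    ev = ev[mask]
    times = ev.index.to_numpy(dtype=float)
    keep = times > 0  # drop the t=0 bookkeeping row if eventless
    return KmCurve(
        group=group,
        event_times=times[keep],
        at_risk=ev["at_risk"].to_numpy(dtype=float)[keep],
        events=ev["observed"].to_numpy(dtype=float)[keep],
        survival=kmf.survival_function_.loc[times[keep]]
        .to_numpy(dtype=float)
        .ravel(),
    )


def km_table(curve: KmCurve) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time_days": curve.event_times,
            "at_risk": curve.at_risk,
            "events": curve.events,
            "survival": curve.survival,
        }
    )


def logrank_test(data: pd.DataFrame, group_a: str, group_b: str) -> LogRankResult:
    """Two-group log-rank chi-square with df = 1.

    When neither group has an event (no information) the test degrades to
    chi-square 0, p = 1 with a warning.
    """
    ta, ea = _group_arrays(data, group_a)
    tb, eb = _group_arrays(data, group_b)
    if ea.sum() + eb.sum() == 0:
        logger.warning("log-rank: no events in either group; p = 1")
        return LogRankResult(0.0, 1, 1.0)
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    chi = float(res.test_statistic)
    p = float(res.p_value)
    if not np.isfinite(chi):
        logger.warning("log-rank: zero total variance; p = 1")
        return LogRankResult(0.0, 1, 1.0)
    return LogRankResult(chi, 1, p)
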