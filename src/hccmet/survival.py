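"""Expression-stratified Kaplan-Meier estimation and the log-rank test.

Both are implemented directly from the textbook formulas: the product-limit
estimator S(t) = prod_{t_i <= t} (1 - d_i / n_i) over distinct event times,
and the Mantel-Cox statistic (sum(O - E))^2 / sum(V) with hypergeometric
expectation and variance at each distinct event time, referred to a
chi-square with one degree of freedom.

Conventions: at a tied event/censoring time, events precede censoring
(censored subjects at time t are still at risk for the event at t); zero
total variance yields statistic 0 and p = 1.  Times beyond the follow-up
horizon should be administratively censored upstream (the synthetic
generator truncates at 60 months).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["KMEstimate", "LogRankResult", "stratify_by_expression",
           "km_estimate", "logrank_test"]


@dataclass
class KMEstimate:
    """Product-limit curve with its risk table."""

    times: np.ndarray      # distinct event times, ascending
    survival: np.ndarray   # S(t) just after each event time
    at_risk: np.ndarray    # n_i at each event time
    events: np.ndarray     # d_i at each event time
    n_subjects: int

    def survival_at(self, t: float) -> float:
        """S(t); right-continuous step function with S(0) = 1."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "at_risk": self.at_risk,
                             "events": self.events, "survival": self.survival})


@dataclass
class LogRankResult:
    statistic: float
    p_value: float
    observed: np.ndarray   # observed events per group
    expected: np.ndarray   # expected events per group


def stratify_by_expression(cohort: pd.DataFrame, mode: str = "median") -> pd.DataFrame:
    """Assign expression strata: two halves ('median') or thirds ('tertile').

    Ties are broken by stable rank order (original row order), so equal
    expression values are assigned deterministically.  Median mode labels the
    lower floor(n/2) subjects 'low' and the rest 'high' (bottom vs top 50%);
    tertile mode labels thirds 'low'/'intermediate'/'high', with remainders
    going to the later strata.
    """
    n = len(cohort)
    if mode not in ("median", "tertile"):
        raise ValueError(f"unknown mode {mode!r}")
    if (mode == "median" and n < 2) or (mode == "tertile" and n < 3):
        raise ValueError(f"too few subjects ({n}) for {mode} stratification")
    x = np.asarray(cohort["expression"], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("degenerate stratification: all expression values identical")
    order = np.argsort(x, kind="stable")
    labels = np.empty(n, dtype=object)
    if mode == "median":
        cut = n // 2
        labels[order[:cut]] = "low"
        labels[order[cut:]] = "high"
    else:
        thirds = np.array_split(order, 3)
        for part, name in zip(thirds, ("low", "intermediate", "high")):
            labels[part] = name
    out = cohort.copy()
    out["stratum"] = labels
    return out


def km_estimate(times, events) -> KMEstimate:
    """Kaplan-Meier product-limit estimate for one stratum.

    ``times`` are positive follow-up times; ``events`` flags (1 = death
    observed, 0 = censored).  Censored subjects leave the risk set after
    their time; subjects censored exactly at an event time count as at risk
    for that event.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("empty stratum")
    if np.any(t <= 0) or not np.all(np.isfinite(t)):
        raise ValueError("times must be finite and positive")
    event_times = np.unique(t[e == 1])
    at_risk = np.array([(t >= u).sum() for u in event_times], dtype=int)
    d = np.array([((t == u) & (e == 1)).sum() for u in event_times], dtype=int)
    with np.errstate(divide="ignore", invalid="ignore"):
        surv = np.cumprod(1.0 - d / at_risk) if len(event_times) else np.array([])
    return KMEstimate(event_times, surv, at_risk, d, n_subjects=t.size)


def logrank_test(times_a, events_a, times_b, events_b) -> LogRankResult:
    """Two-sample log-rank (Mantel-Cox) test.

    At each distinct event time j (pooled): with n_gj at risk and d_j total
    events, E_gj = d_j n_gj / n_j and
    V_j = d_j (n_1j/n_j)(1 - n_1j/n_j)(n_j - d_j)/(n_j - 1).
    Statistic (sum(O_1 - E_1))^2 / sum(V); p from chi2(1).
    """
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, int)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both strata must be non-empty")
    t_all = np.concatenate([ta, tb])
    e_all = np.concatenate([ea, eb])
    if e_all.sum() == 0:
        raise ValueError("need at least one event overall")
    event_times = np.unique(t_all[e_all == 1])
    o_minus_e = 0.0
    var = 0.0
    obs = np.zeros(2)
    exp = np.zeros(2)
    for u in event_times:
        n1 = (ta >= u).sum()
        n2 = (tb >= u).sum()
        nj = n1 + n2
        d1 = ((ta == u) & (ea == 1)).sum()
        d2 = ((tb == u) & (eb == 1)).sum()
        dj = d1 + d2
        e1 = dj * n1 / nj
        obs += (d1, d2)
        exp += (e1, dj - e1)
        o_minus_e += d1 - e1
        if nj > 1:
            var += dj * (n1 / nj) * (1 - n1 / nj) * (nj - dj) / (nj - 1)
    if var == 0.0:
        return LogRankResult(0.0, 1.0, obs, exp)
    stat = o_minus_e ** 2 / var
    return LogRankResult(float(stat), float(stats.chi2.sf(stat, df=1)), obs, exp)
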