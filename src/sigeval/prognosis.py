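"""Survival analysis: Kaplan-Meier at a five-year horizon, log-rank tests,
and the every-fifth-percentile dichotomization scan.

Follow-up is administratively censored at the horizon (60 months by
default).  The scan dichotomizes a per-sample score at each percentile from
the 50th to the 95th in steps of 5 ("high" = score strictly above the
threshold, ties go low), runs a log-rank test at each split, and calls a
percentile significant at p <= 0.005 — the 0.05 family level Bonferroni
corrected for the 10 thresholds tested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .errors import DataError

__all__ = [
    "SurvivalRecord",
    "KMCurve",
    "PercentileRow",
    "PercentileScanResult",
    "km_estimator",
    "logrank_test",
    "percentile_scan",
    "SCAN_PERCENTILES",
]

SCAN_PERCENTILES = tuple(range(50, 100, 5))  # 50, 55, ..., 95
DEFAULT_HORIZON_MONTHS = 60.0


@dataclass(frozen=True)
class SurvivalRecord:
    sample_id: str
    time_months: float
    event: bool

    def __post_init__(self) -> None:
        if not np.isfinite(self.time_months) or self.time_months < 0:
            raise DataError(f"bad survival time for {self.sample_id!r}")


@dataclass
class KMCurve:
    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray


@dataclass
class PercentileRow:
    percentile: int
    threshold: float
    n_high: int
    n_low: int
    logrank_chi2: float
    logrank_p: float
    significant: bool
    defined: bool = True


@dataclass
class PercentileScanResult:
    rows: list[PercentileRow]
    alpha: float
    any_significant: bool = False
    best_percentile: int | None = None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.rows])


def _censor_at_horizon(
    records: Sequence[SurvivalRecord], horizon: float
) -> tuple[np.ndarray, np.ndarray]:
    t = np.array([r.time_months for r in records], dtype=float)
    e = np.array([r.event for r in records], dtype=bool)
    over = t > horizon
    t = np.minimum(t, horizon)
    e = e & ~over  # events past the horizon become administrative censorings
    return t, e


def km_estimator(
    records: Sequence[SurvivalRecord], horizon_months: float = DEFAULT_HORIZON_MONTHS
) -> KMCurve:
    """Product-limit survival estimate, censored at the horizon."""
    if not records:
        raise DataError("no survival records")
    t, e = _censor_at_horizon(records, horizon_months)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    times = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = np.array(
        [int((t >= u).sum()) for u in times], dtype=int
    )
    return KMCurve(event_times=times, survival=surv, at_risk=at_risk)


def logrank_test(
    group_a: Sequence[SurvivalRecord],
    group_b: Sequence[SurvivalRecord],
    horizon_months: float = DEFAULT_HORIZON_MONTHS,
) -> dict:
    """Two-group log-rank test (1 df) on horizon-censored data."""
    if not group_a or not group_b:
        raise DataError("both groups must be non-empty")
    ta, ea = _censor_at_horizon(group_a, horizon_months)
    tb, eb = _censor_at_horizon(group_b, horizon_months)
    if not ea.any() and not eb.any():
        warnings.warn("no events in either group; log-rank undefined, p = 1",
                      stacklevel=2)
        return {"chi2": 0.0, "p": 1.0}
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return {"chi2": float(res.test_statistic), "p": float(res.p_value)}


def percentile_scan(
    scores: pd.Series,
    records: Sequence[SurvivalRecord],
    percentiles: Sequence[int] = SCAN_PERCENTILES,
    alpha: float = 0.005,
    horizon_months: float = DEFAULT_HORIZON_MONTHS,
) -> PercentileScanResult:
    """Dichotomize at every listed score percentile and log-rank each split.

    ``scores`` is indexed by sample id and joined with the records; at the
    80th percentile the high group is the top 20% of the cohort (up to
    ties, which go to the low group).  A split leaving either group empty
    is reported as undefined for that percentile.
    """
    rec_by_id = {r.sample_id: r for r in records}
    common = [sid for sid in scores.index if sid in rec_by_id]
    if not common:
        raise DataError("scores and survival records share no sample ids")
    if len(common) < 20:
        warnings.warn("fewer than 20 joined samples; scan may be unstable",
                      stacklevel=2)
    s = scores.loc[common].to_numpy(dtype=float)
    recs = [rec_by_id[sid] for sid in common]

    rows: list[PercentileRow] = []
    for q in percentiles:
        thr = float(np.quantile(s, q / 100.0))
        high = s > thr
        n_high, n_low = int(high.sum()), int((~high).sum())
        if n_high == 0 or n_low == 0:
            rows.append(PercentileRow(q, thr, n_high, n_low,
                                      np.nan, np.nan, False, defined=False))
            continue
        res = logrank_test(
            [r for r, h in zip(recs, high) if h],
            [r for r, h in zip(recs, high) if not h],
            horizon_months,
        )
        rows.append(
            PercentileRow(q, thr, n_high, n_low, res["chi2"], res["p"],
                          res["p"] <= alpha)
        )
    defined = [r for r in rows if r.defined]
    any_sig = any(r.significant for r in defined)
    best = None
    if defined:
        best = min(defined, key=lambda r: (r.logrank_p, r.percentile)).percentile
    return PercentileScanResult(
        rows=rows, alpha=alpha, any_significant=any_sig, best_percentile=best
    )
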