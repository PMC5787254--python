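"""Survival comparison across frailty bands.

Kaplan–Meier product-limit estimation, the k-sample log-rank test across
the seven frailty categories (df = k - 1, hypergeometric variance for
ties, censoring processed after deaths at tied times), and horizon
mortality tables from grouped alive/deceased counts.  In the validation
design censoring is purely administrative at 24 months — no patient is
lost to follow-up — so horizon mortality is a simple deceased fraction.

Estimation and testing are delegated to ``lifelines``; this module wraps
them with the input validation and tidy containers the pipeline needs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .cohort_io import GroupedOutcomeCounts

__all__ = [
    "SurvivalSample",
    "KMCurve",
    "LogRankResult",
    "HorizonMortality",
    "km_estimate",
    "logrank_test",
    "mortality_at_horizon",
]


@dataclass
class SurvivalSample:
    """Follow-up for one patient: time in months and death indicator."""

    time: float
    event: bool
    band: Optional[str] = None


def _as_arrays(samples) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(samples, tuple) and len(samples) == 2:
        times, events = np.asarray(samples[0], float), np.asarray(samples[1])
    else:
        samples = list(samples)
        if samples and isinstance(samples[0], SurvivalSample):
            times = np.array([s.time for s in samples], dtype=float)
            events = np.array([s.event for s in samples])
        else:
            raise TypeError(
                "expected a sequence of SurvivalSample or a (times, events) pair"
            )
    events = np.asarray(events).astype(bool)
    if times.size == 0:
        raise ValueError("no survival samples")
    if not np.all(times > 0):
        raise ValueError("follow-up times must be strictly positive")
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")
    return times, events


@dataclass
class KMCurve:
    """Kaplan–Meier step function with at-risk and event counts."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t): the step value at the last event time <= t."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "events": self.events,
            }
        )


@dataclass
class LogRankResult:
    chi_square: float
    df: int
    p_value: float


def km_estimate(samples) -> KMCurve:
    """Product-limit survival estimate S(t) = prod(1 - d_i / n_i).

    ``samples`` is either a sequence of :class:`SurvivalSample` or a
    ``(times, events)`` pair of arrays.
    """
    times, events = _as_arrays(samples)
    fitter = KaplanMeierFitter()
    fitter.fit(times, event_observed=events)
    table = fitter.event_table.iloc[1:] if 0.0 in fitter.event_table.index else fitter.event_table
    event_rows = table[table["observed"] > 0]
    grid = event_rows.index.to_numpy(dtype=float)
    surv = fitter.survival_function_at_times(grid).to_numpy(dtype=float)
    return KMCurve(
        times=grid,
        survival=surv,
        at_risk=event_rows["at_risk"].to_numpy(dtype=int),
        events=event_rows["observed"].to_numpy(dtype=int),
    )


def logrank_test(groups: Sequence) -> LogRankResult:
    """k-sample log-rank comparison of survival across groups.

    Observed-minus-expected deaths summed over distinct event times, with
    the hypergeometric variance for ties; the statistic is chi-square
    distributed with k - 1 degrees of freedom under equal hazards.
    """
    if len(groups) < 2:
        raise ValueError("log-rank test needs at least two groups")
    parts = [_as_arrays(group) for group in groups]
    times = np.concatenate([t for t, _ in parts])
    events = np.concatenate([e for _, e in parts])
    labels = np.concatenate(
        [np.full(t.shape[0], i) for i, (t, _) in enumerate(parts)]
    )
    if not events.any():
        raise ValueError("log-rank test undefined: no events in any group")
    result = multivariate_logrank_test(times, labels, events)
    return LogRankResult(
        chi_square=float(result.test_statistic),
        df=len(groups) - 1,
        p_value=float(result.p_value),
    )


@dataclass
class HorizonMortality:
    """Deceased percentages per band and overall at a fixed horizon."""

    horizon_months: int
    bands: tuple
    percent: np.ndarray  # NaN where the band has no patients
    overall_percent: float
    undefined_bands: tuple

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"band": list(self.bands), "deceased_pct": np.round(self.percent, 1)}
        )


def mortality_at_horizon(counts: GroupedOutcomeCounts) -> HorizonMortality:
    """Per-band and overall deceased percentages from grouped counts.

    Bands with zero patients get NaN and are flagged in
    ``undefined_bands`` rather than silently reported as 0%.
    """
    totals = counts.total
    if counts.grand_total == 0:
        raise ValueError("no patients in any band")
    with np.errstate(invalid="ignore"):
        percent = np.where(totals > 0, counts.deceased / np.maximum(totals, 1) * 100.0, np.nan)
    undefined = tuple(b for b, t in zip(counts.bands, totals) if t == 0)
    overall = counts.deceased.sum() / counts.grand_total * 100.0
    return HorizonMortality(
        horizon_months=counts.horizon_months,
        bands=tuple(counts.bands),
        percent=percent,
        overall_percent=float(overall),
        undefined_bands=undefined,
    )
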