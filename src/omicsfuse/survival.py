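"""Kaplan–Meier curves and the k-group log-rank test.

Detected subtypes are validated by how far apart their survival profiles
are: the product-limit estimate per cluster, and a chi-square log-rank
statistic comparing observed with expected event counts across clusters
(hypergeometric null at every distinct event time, k-1 degrees of
freedom). A small p-value indicates prognostically distinct subtypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

__all__ = ["SurvivalCurve", "LogRankResult", "kaplan_meier", "logrank"]


@dataclass
class SurvivalCurve:
    """Product-limit estimate: S(t) = prod over event times (1 - d/n)."""

    event_times: np.ndarray  # distinct times with >= 1 event, ascending
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray  # S just after each event time

    def __post_init__(self) -> None:
        if np.any(np.diff(self.event_times) <= 0):
            raise ValueError("event_times must be strictly increasing")
        if np.any(np.diff(self.survival) > 1e-12) or (
            self.survival.size and self.survival[0] > 1.0 + 1e-12
        ):
            raise ValueError("survival must be non-increasing from 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "at_risk": self.at_risk,
                "events": self.events,
                "survival": self.survival,
            }
        )


@dataclass
class LogRankResult:
    statistic: float
    df: int
    p_value: float

    def __post_init__(self) -> None:
        if self.statistic < 0 or not 0 <= self.p_value <= 1:
            raise ValueError("invalid log-rank result")


def kaplan_meier(times, events) -> SurvivalCurve:
    """Kaplan–Meier estimate from right-censored (time, event) pairs."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty survival input")
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")
    if np.any(times < 0) or not np.isin(events, (0, 1)).all():
        raise ValueError("times must be >= 0 and events binary")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    table = kmf.event_table
    mask = table["observed"].to_numpy() > 0
    event_times = table.index.to_numpy(dtype=float)[mask]
    at_risk = table["at_risk"].to_numpy(dtype=float)[mask]
    observed = table["observed"].to_numpy(dtype=float)[mask]
    survival = np.cumprod(1.0 - observed / at_risk)
    return SurvivalCurve(
        event_times=event_times,
        at_risk=at_risk,
        events=observed,
        survival=survival,
    )


def logrank(times, events, group_labels) -> LogRankResult:
    """k-group log-rank test of equal survival across groups.

    Statistic is (O - E)' V^-1 (O - E) over k-1 groups with the standard
    hypergeometric covariance (simultaneous-event tie convention); p from
    chi-square with k-1 degrees of freedom.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    labels = np.asarray(group_labels)
    if not times.shape == events.shape == labels.shape:
        raise ValueError("times, events and group_labels must align")
    groups = np.unique(labels)
    if groups.size < 2:
        raise ValueError("log-rank test requires at least 2 groups")
    if events.sum() == 0:
        raise ValueError("log-rank test requires at least one event")
    res = multivariate_logrank_test(times, labels, events)
    return LogRankResult(
        statistic=float(res.test_statistic),
        df=int(groups.size - 1),
        p_value=float(res.p_value),
    )
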