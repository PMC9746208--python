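"""Counting-process bookkeeping and Kaplan-Meier estimation.

For each composite endpoint k the cohort yields a counting process
``N̄_k(t) = Σ_i 1{X_ik <= t, delta_ik = 1}`` and an at-risk process
``Ȳ_k(t) = Σ_i 1{X_ik >= t}`` (a subject with an event or censoring
exactly at t is still at risk at t — the standard left-limit
convention, so tied censorings are processed after events).  The
product-limit estimator multiplies ``1 - dN̄_k(u)/Ȳ_k(u)`` over event
times u in (0, t].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .event_model import EndpointRecord

__all__ = ["StepFunction", "EndpointCounting", "CountingData", "build_counting", "km_estimate"]


@dataclass(frozen=True)
class StepFunction:
    """Right-continuous piecewise-constant function on [0, inf).

    ``values[j]`` is the value at and after ``times[j]`` (up to the next
    jump); before the first jump the function equals ``value_at_0``.
    """

    times: np.ndarray
    values: np.ndarray
    value_at_0: float = 1.0

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.shape != t.shape:
            raise ValueError("times and values must be 1-d arrays of equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("jump times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __call__(self, t):
        """Evaluate at scalar or array t (value of the last jump <= t)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right")
        padded = np.concatenate(([self.value_at_0], self.values))
        out = padded[idx]
        return out if out.ndim else float(out)

    def to_frame(self):
        """Two-column (time, value) table including the t=0 anchor."""
        import pandas as pd

        return pd.DataFrame(
            {
                "time": np.concatenate(([0.0], self.times)),
                "value": np.concatenate(([self.value_at_0], self.values)),
            }
        )


@dataclass(frozen=True)
class EndpointCounting:
    """Event times, multiplicities and at-risk counts for one endpoint.

    ``event_times`` are the distinct observed event times (sorted),
    ``n_events[j]`` the number of events at ``event_times[j]`` and
    ``at_risk[j] = Ȳ_k(event_times[j])``.
    """

    event_times: np.ndarray
    n_events: np.ndarray
    at_risk: np.ndarray
    x: np.ndarray  # per-subject observed times for this endpoint
    delta: np.ndarray  # per-subject event indicators

    @property
    def n(self) -> int:
        return self.x.size

    def y_at(self, t):
        """At-risk count Ȳ_k(t) = #{i : X_ik >= t}."""
        xs = np.sort(self.x)
        t = np.asarray(t, dtype=float)
        out = self.n - np.searchsorted(xs, t, side="left")
        return out if out.ndim else int(out)


@dataclass(frozen=True)
class CountingData:
    """Counting-process summaries for all five composite endpoints."""

    endpoints: tuple  # 5 EndpointCounting, index k-1 for endpoint k

    @property
    def n(self) -> int:
        return self.endpoints[0].n


def _counting_one(x: np.ndarray, delta: np.ndarray) -> EndpointCounting:
    order = np.argsort(x, kind="stable")
    xs, ds = x[order], delta[order]
    ev_mask = ds == 1
    times, counts = np.unique(xs[ev_mask], return_counts=True)
    # at risk at u: subjects with X >= u
    at_risk = x.size - np.searchsorted(xs, times, side="left")
    return EndpointCounting(
        event_times=times,
        n_events=counts.astype(np.int64),
        at_risk=at_risk.astype(np.int64),
        x=x.copy(),
        delta=delta.astype(np.int8).copy(),
    )


def build_counting(records: Sequence[EndpointRecord]) -> CountingData:
    """Assemble counting-process data from a cohort's endpoint records."""
    if len(records) == 0:
        raise ValueError("need at least one subject")
    x = np.stack([r.x for r in records])  # (n, 5)
    delta = np.stack([r.delta for r in records])
    return CountingData(endpoints=tuple(_counting_one(x[:, k], delta[:, k]) for k in range(5)))


def km_estimate(counting: EndpointCounting) -> StepFunction:
    """Kaplan-Meier estimator for one composite endpoint.

    Ŝ(t) = Π_{u <= t} (1 - dN̄(u)/Ȳ(u)) over distinct event times u.
    """
    if counting.event_times.size == 0:
        return StepFunction(times=np.empty(0), values=np.empty(0), value_at_0=1.0)
    frac = 1.0 - counting.n_events / counting.at_risk
    surv = np.cumprod(frac)
    return StepFunction(times=counting.event_times, values=surv, value_at_0=1.0)
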