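"""Occupation probabilities for all ten states, and derived functionals.

Two estimation routes are provided.

*KM differences* (model-free): transient-state probabilities are
differences of the composite-endpoint survival curves,

    P(state 0) = Ŝ1,        P(state 2) = Ŝ3 - Ŝ1,
    P(state 4) = Ŝ2 - Ŝ3,   P(state 6) = Ŝ5 - Ŝ2,
    P(state 8) = Ŝ4 - Ŝ5,

which telescope to Ŝ4 (disease-free survival).  Finite-sample values
may dip slightly below zero and are reported raw.

*Aalen-Johansen* (product integral): the empirical transition-intensity
increments are accumulated into factor matrices I + ΔÂ(u) whose ordered
product estimates the full transition-probability matrix; its first row
gives every state's occupation probability, including the absorbing
failure states 1, 3, 5, 7, 9 (cumulative incidences).  The two routes
agree asymptotically but not in finite samples; only
P(state 0) = Ŝ1 = P̂00 is an exact identity.

Derived functionals: the prevalence of chronic GVHD among leukemia-free
patients, (P2 + P6)/DFS, and the failure-odds contrast
P5/P4 - P1/P0 comparing failure odds after resolved GVHD against the
initial remission state.  Both get nonparametric bootstrap percentile
intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .event_model import SubjectHistory, derive_all
from .km import StepFunction, build_counting, km_estimate

__all__ = [
    "OccupancyCurves",
    "UndefinedFunctionalError",
    "occupancy_km",
    "aalen_johansen",
    "cgrfs_aalen_johansen",
    "prevalence_ratio",
    "failure_odds_contrast",
    "bootstrap_ci",
]

#: transient (alive) states and the absorbing failure state entered from each
TRANSIENT = (0, 2, 4, 6, 8)
FAIL_FROM = {0: 1, 2: 3, 4: 5, 6: 7, 8: 9}
#: GVHD path transitions in order: onset 1, resolution 1, onset 2, resolution 2
_PATH_STEPS = (("t_gvhd1", 0, 2), ("t_res1", 2, 4), ("t_gvhd2", 4, 6), ("t_res2", 6, 8))


class UndefinedFunctionalError(ValueError):
    """The functional's denominator vanishes at the requested time."""


@dataclass(frozen=True)
class OccupancyCurves:
    """P(state i at t), i = 0..9, as right-continuous step functions."""

    curves: tuple  # 10 StepFunctions, index = state
    times: np.ndarray
    probs: np.ndarray  # (len(times), 10)
    method: str
    factors: Optional[list] = None  # [(time, 10x10 factor matrix), ...] if retained

    def __getitem__(self, state: int) -> StepFunction:
        return self.curves[state]


def occupancy_km(records) -> dict[int, StepFunction]:
    """Transient-state occupation curves from KM differences.

    Accepts endpoint records (or subject histories, which are derived
    first).  Returns {state: StepFunction} for states 0, 2, 4, 6, 8.
    """
    records = _as_records(records)
    counting = build_counting(records)
    grid = np.unique(np.concatenate([ep.event_times for ep in counting.endpoints]))
    s = [km_estimate(ep)(grid) for ep in counting.endpoints]
    s1, s2, s3, s4, s5 = s
    combos = {0: s1, 2: s3 - s1, 4: s2 - s3, 6: s5 - s2, 8: s4 - s5}
    return {
        state: StepFunction(grid, vals, value_at_0=(1.0 if state == 0 else 0.0))
        for state, vals in combos.items()
    }


def _as_records(data):
    if len(data) and isinstance(data[0], SubjectHistory):
        return derive_all(data)
    return list(data)


def _transitions(histories: Sequence[SubjectHistory]):
    """Per-subject (time, tie_rank, from, to) transition tuples.

    ``tie_rank`` orders simultaneous within-subject transitions (a
    failure tied with a GVHD event is processed after it, so failure
    dominates and the subject lands in the later absorbing state).
    """
    trans = []
    for i, h in enumerate(histories):
        state = 0
        subj = []
        for field, frm, to in _PATH_STEPS:
            t = getattr(h, field)
            if t is None:
                break
            subj.append((float(t), frm, to))
            state = to
        if h.t_fail is not None:
            subj.append((float(h.t_fail), state, FAIL_FROM[state]))
        prev_t, rank = None, 0
        for t, frm, to in subj:
            rank = rank + 1 if t == prev_t else 0
            trans.append((t, rank, frm, to, i))
            prev_t = t
    return trans


def aalen_johansen(
    histories: Sequence[SubjectHistory], store_factors: bool = False
) -> OccupancyCurves:
    """Aalen-Johansen occupation probabilities for all ten states.

    The product integral runs over the ordered distinct transition
    times (simultaneous within-subject transitions are resolved in path
    order by sub-steps); at-risk counts use the left-limit convention
    shared with the KM module, so a subject censored at u is still at
    risk at u.  Every factor matrix is a proper stochastic matrix, so
    the ten probabilities sum to one at every time.
    """
    n = len(histories)
    if n == 0:
        raise ValueError("need at least one subject")
    trans = _transitions(histories)
    censor = np.array(
        [h.t_censor if h.t_censor is not None else np.inf for h in histories], dtype=float
    )
    state = np.zeros(n, dtype=np.int64)

    from collections import defaultdict

    groups: dict[tuple, list] = defaultdict(list)
    for t, rank, frm, to, i in trans:
        groups[(t, rank)].append((frm, to, i))

    p = np.zeros(10)
    p[0] = 1.0
    out_times, out_probs, factors = [], [], []
    for key in sorted(groups):
        t, _rank = key
        moves = groups[key]
        at_risk_mask = censor >= t
        delta = np.zeros((10, 10))
        by_from: dict[int, list] = defaultdict(list)
        for frm, to, i in moves:
            by_from[frm].append(to)
        for frm, tos in by_from.items():
            y = int(np.count_nonzero((state == frm) & at_risk_mask))
            if y == 0:
                raise RuntimeError(f"empty risk set in state {frm} at time {t}")
            for to in tos:
                delta[frm, to] += 1.0 / y
            delta[frm, frm] -= len(tos) / y
        # p <- p @ (I + delta), using only the touched rows
        p = p + p @ delta
        for frm, to, i in moves:
            state[i] = to
        if store_factors:
            factors.append((t, np.eye(10) + delta))
        if out_times and out_times[-1] == t:
            out_probs[-1] = p.copy()
        else:
            out_times.append(t)
            out_probs.append(p.copy())

    times = np.array(out_times)
    probs = np.array(out_probs) if out_times else np.zeros((0, 10))
    curves = tuple(
        StepFunction(times, probs[:, s] if times.size else np.empty(0),
                     value_at_0=(1.0 if s == 0 else 0.0))
        for s in range(10)
    )
    return OccupancyCurves(
        curves=curves,
        times=times,
        probs=probs,
        method="aalen-johansen",
        factors=factors if store_factors else None,
    )


def cgrfs_aalen_johansen(histories: Sequence[SubjectHistory]) -> StepFunction:
    """Product-integral CGRFS estimate: P̂00 + P̂04 + P̂08."""
    occ = aalen_johansen(histories)
    vals = occ.probs[:, [0, 4, 8]].sum(axis=1) if occ.times.size else np.empty(0)
    return StepFunction(occ.times, vals, value_at_0=1.0)


def prevalence_ratio(records, t: float) -> float:
    """Prevalence of chronic GVHD among leukemia-free patients at t.

    (P(state 2) + P(state 6)) / DFS(t), with the transient-state
    probabilities from the KM-difference route and DFS = Ŝ4.
    Undefined where Ŝ4(t) = 0.
    """
    records = _as_records(records)
    counting = build_counting(records)
    s = [km_estimate(ep)(t) for ep in counting.endpoints]
    s1, s2, s3, s4, s5 = (float(v) for v in s)
    if s4 <= 0:
        raise UndefinedFunctionalError(f"DFS is zero at t={t}")
    return ((s3 - s1) + (s5 - s2)) / s4


def failure_odds_contrast(histories: Sequence[SubjectHistory], t: float) -> float:
    """Failure-odds contrast P5/P4 - P1/P0 at time t.

    Compares the odds of having failed after a resolved first GVHD
    episode against failure from the initial remission state; the
    absorbing-state probabilities come from the Aalen-Johansen route.
    Undefined where P(state 4) or P(state 0) vanishes.
    """
    occ = aalen_johansen(histories)
    p0, p1, p4, p5 = (float(occ[s](t)) for s in (0, 1, 4, 5))
    if p4 <= 0 or p0 <= 0:
        raise UndefinedFunctionalError(
            f"denominator zero at t={t}: P(state 4)={p4}, P(state 0)={p0}"
        )
    return p5 / p4 - p1 / p0


def bootstrap_ci(
    functional: Callable,
    data: Sequence,
    t: float,
    alpha: float = 0.05,
    B: int = 500,
    seed: int = 0,
) -> tuple[float, float]:
    """Nonparametric bootstrap percentile interval for ``functional(data, t)``.

    Subjects are resampled with replacement; resamples where the
    functional is undefined are dropped, and more than 50% undefined
    resamples is an error (the functional is not stably estimable at t).
    """
    if B < 1:
        raise ValueError("B must be positive")
    rng = np.random.default_rng(seed)
    n = len(data)
    values = []
    failed = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        sample = [data[j] for j in idx]
        try:
            values.append(functional(sample, t))
        except UndefinedFunctionalError:
            failed += 1
    if failed > B / 2:
        raise RuntimeError(
            f"functional undefined in {failed}/{B} bootstrap resamples at t={t}"
        )
    lo, hi = np.quantile(values, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)
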