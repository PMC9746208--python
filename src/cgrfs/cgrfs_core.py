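"""CGRFS point estimation, influence values, variance and pointwise CIs.

CGRFS — the probability of being alive, in remission and free of
moderate-to-severe chronic GVHD at time t — equals the sum of the
occupation probabilities of states 0, 4 and 8 and admits the model-free
representation

    C(t) = S1(t) + S2(t) - S3(t) + S4(t) - S5(t),

a linear combination of the survival functions of the five composite
endpoints, each estimated by Kaplan-Meier.  Asymptotic inference rests
on the i.i.d. (influence) representation

    sqrt(n) [ Ĉ(t) - C(t) ] ≈ n^{-1/2} Σ_i W_i(t),

with W_i a signed sum of compensated martingale integrals of the five
endpoint counting processes.  Because the five counting processes share
events, their martingales are correlated; the moment estimator
σ̂²(t) = n^{-1} Σ_i Ŵ_i(t)² captures the full covariance.  Pointwise
confidence intervals use either the linear scale or the log-log
transform (which keeps the interval inside (0,1)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .event_model import EndpointRecord
from .km import CountingData, StepFunction, build_counting, km_estimate

__all__ = [
    "CgrfsFit",
    "TransformError",
    "SIGNS",
    "estimate_cgrfs",
    "influence_values",
    "variance",
    "ci_linear",
    "ci_loglog",
]

#: signs of the five KM curves in the CGRFS linear combination
SIGNS = np.array([1.0, 1.0, -1.0, 1.0, -1.0])


class TransformError(ValueError):
    """log-log transform undefined (point estimate at or outside (0,1))."""


@dataclass(frozen=True)
class CgrfsFit:
    """Fitted CGRFS curve with influence values on the pooled event grid.

    ``grid`` holds the pooled distinct event times of all five
    endpoints; Ĉ, σ̂ and the per-subject influence values Ŵ_i change
    value only there.  ``influence`` has shape (n, len(grid)) and
    satisfies ``mean_i Ŵ_i(t)² = σ̂(t)²`` at every grid time.
    """

    n: int
    grid: np.ndarray
    c_hat: StepFunction
    sigma_hat: StepFunction
    influence: np.ndarray
    survival: tuple  # the five KM StepFunctions Ŝ_1..Ŝ_5
    counting: CountingData
    # per endpoint: (subject row, grid column, 1/Ȳ at event) for each
    # observed event — the ingredients of the endpoint-level multiplier.
    endpoint_jumps: tuple = field(repr=False, default=())

    @property
    def sigma2(self) -> np.ndarray:
        return self.sigma_hat.values**2 if self.grid.size else np.empty(0)

    def max_time(self) -> float:
        """Largest observed time (event or censoring) in the sample."""
        return float(max(ep.x.max() for ep in self.counting.endpoints))


def _influence_one_endpoint(
    ep, grid: np.ndarray
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Per-subject compensated integral A_ik(t) = ∫_0^t dM̂_ik(u)/Ȳ_k(u).

    Returns the (n, G) matrix of A values on the grid plus the event
    jump triplet (subject index, grid column, 1/Ȳ) used by the
    multiplier resampler.
    """
    u, d, y = ep.event_times, ep.n_events, ep.at_risk
    n, G = ep.n, grid.size
    if u.size == 0:
        return np.zeros((n, G)), (np.empty(0, int), np.empty(0, int), np.empty(0))
    if np.any(y == 0):
        j = int(np.argmax(y == 0))
        raise ZeroDivisionError(f"degenerate risk set: Ȳ=0 at event time {u[j]}")
    h = d / y.astype(float) ** 2
    H0 = np.concatenate(([0.0], np.cumsum(h)))  # H0[r] = Σ_{j<=r} h_j
    r_subj = np.searchsorted(u, ep.x, side="right")  # events with u <= X_i
    r_grid = np.searchsorted(u, grid, side="right")

    # dN part: delta_i / Ȳ(X_i) once X_i <= t
    ev = ep.delta == 1
    term1 = np.zeros(n)
    term1[ev] = 1.0 / y[r_subj[ev] - 1]
    a = term1[:, None] * (ep.x[:, None] <= grid[None, :])
    # compensator part: Σ_{u_j <= min(t, X_i)} h_j
    a -= H0[np.minimum(r_subj[:, None], r_grid[None, :])]

    subj_idx = np.nonzero(ev)[0]
    col_idx = np.searchsorted(grid, ep.x[subj_idx], side="left")
    inv_risk = 1.0 / y[r_subj[subj_idx] - 1]
    return a, (subj_idx.astype(int), col_idx.astype(int), inv_risk)


def estimate_cgrfs(records: Sequence[EndpointRecord]) -> CgrfsFit:
    """Fit the model-free CGRFS estimator with influence-based variance.

    Ĉ is computed by exact step-function arithmetic on the pooled event
    grid and reported raw — in finite samples it may locally exceed
    [0, 1]; clamp only for display, never before inference.
    """
    counting = build_counting(records)
    n = counting.n
    grid = np.unique(np.concatenate([ep.event_times for ep in counting.endpoints]))
    survival = tuple(km_estimate(ep) for ep in counting.endpoints)

    s_on_grid = np.stack([s(grid) for s in survival]) if grid.size else np.zeros((5, 0))
    c_vals = SIGNS @ s_on_grid

    influence = np.zeros((n, grid.size))
    jumps = []
    for k, ep in enumerate(counting.endpoints):
        a, jump = _influence_one_endpoint(ep, grid)
        # W_i has sign -s_k on each endpoint integral
        influence -= SIGNS[k] * s_on_grid[k][None, :] * a
        jumps.append(jump)
    influence *= n

    sigma = np.sqrt((influence**2).mean(axis=0)) if n else np.zeros(grid.size)
    return CgrfsFit(
        n=n,
        grid=grid,
        c_hat=StepFunction(grid, c_vals, value_at_0=1.0),
        sigma_hat=StepFunction(grid, sigma, value_at_0=0.0),
        influence=influence,
        survival=survival,
        counting=counting,
        endpoint_jumps=tuple(jumps),
    )


def influence_values(records: Sequence[EndpointRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject influence values Ŵ_i on the pooled event grid.

    Returns ``(grid, W)`` with ``W`` of shape (n, len(grid)).  The
    values are exactly centred: Σ_i Ŵ_i(t) = 0 at every grid time.
    """
    if len(records) < 2:
        raise ValueError("influence values need n >= 2")
    fit = estimate_cgrfs(records)
    return fit.grid, fit.influence


def variance(fit: CgrfsFit, t) -> np.ndarray | float:
    """Moment variance estimate σ̂²(t) = n^{-1} Σ_i Ŵ_i(t)²."""
    s = fit.sigma_hat(t)
    return s**2


def ci_linear(fit: CgrfsFit, t, alpha: float = 0.05):
    """Linear (1-alpha) pointwise CI: Ĉ ± z_{1-α/2} σ̂ / sqrt(n)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0,1)")
    z = norm.ppf(1 - alpha / 2)
    c = fit.c_hat(t)
    half = z * fit.sigma_hat(t) / np.sqrt(fit.n)
    return c - half, c + half


def ci_loglog(fit: CgrfsFit, t, alpha: float = 0.05):
    """Log-log transformed (1-alpha) pointwise CI.

    With θ = exp( z_{1-α/2} σ̂(t) / (sqrt(n) Ĉ ln Ĉ) ) the interval is
    [Ĉ^{1/θ}, Ĉ^θ], ordered so lo <= hi; it always lies inside (0,1).
    Undefined when Ĉ(t) is outside (0,1) — callers may fall back to the
    linear CI there.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0,1)")
    c = np.asarray(fit.c_hat(t), dtype=float)
    if np.any(c <= 0.0) or np.any(c >= 1.0):
        raise TransformError("log-log CI undefined: Ĉ(t) outside (0,1)")
    z = norm.ppf(1 - alpha / 2)
    theta = np.exp(z * np.asarray(fit.sigma_hat(t)) / (np.sqrt(fit.n) * c * np.log(c)))
    lo = np.minimum(c ** (1.0 / theta), c**theta)
    hi = np.maximum(c ** (1.0 / theta), c**theta)
    if lo.ndim:
        return lo, hi
    return float(lo), float(hi)
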