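"""Simultaneous confidence bands and the two-sample supremum test.

The law of sqrt(n)(Ĉ - C) is approximated by multiplier resampling:
martingale increments are replaced by standard-normal-weighted jumps of
the observed counting processes, giving realizable Gaussian processes
whose supremum quantiles calibrate simultaneous bands and the
two-sample supremum test.

Two multiplier schemes are provided:

``subject`` (default)
    one draw G_i per subject multiplies the whole influence value
    Ŵ_i(t); the realized process is n^{-1/2} Σ_i G_i Ŵ_i(t), whose
    conditional variance is exactly σ̂²(t) — it inherits the
    cross-endpoint covariance that the moment variance captures.

``endpoint``
    independent draws G_ik per (subject, endpoint) pair weight each
    endpoint's observed jumps separately,

        W̃(t) = sqrt(n) Σ_i Σ_k (-s_k) Ŝ_k(t) Σ_{u<=t} G_ik dN_ik(u)/Ȳ_k(u),

    which treats the five endpoint martingales as orthogonal.

A one-sample (1-α) band on [t1, t2] is Ĉ(t) ± n^{-1/2} q̃_α σ̂(t) with
q̃_α the empirical (1-α) quantile of sup_t |W̃_b(t)/σ̂(t)|.  For two
independent samples the difference band and the supremum test statistic
K̂ = sup |(Ĉ1-Ĉ2)/SE| are standardized by
SE(t) = sqrt(σ̂1²/n1 + σ̂2²/n2) on the probability scale, which reduces
to the equal-n single-sqrt(n) formulas when n1 = n2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .cgrfs_core import SIGNS, CgrfsFit
from .km import StepFunction

__all__ = [
    "BandResult",
    "SupTestResult",
    "DegenerateBandError",
    "realize_processes",
    "confidence_band",
    "difference_band",
    "supremum_test",
    "default_interval",
]


class DegenerateBandError(ValueError):
    """No usable grid point (σ̂ = 0 everywhere) in the requested interval."""


@dataclass(frozen=True)
class BandResult:
    """A simultaneous confidence band on [t1, t2]."""

    interval: tuple
    critical_value: float
    lower: StepFunction
    upper: StepFunction
    B: int
    seed: int
    alpha: float
    scheme: str = "subject"
    times: Optional[np.ndarray] = None
    estimate: Optional[np.ndarray] = None


@dataclass(frozen=True)
class SupTestResult:
    """Two-sample supremum test: K̂ and its resampling p-value."""

    k_hat: float
    p_value: float
    B: int
    interval: tuple
    seed: int
    scheme: str = "subject"


def realize_processes(
    fit: CgrfsFit, B: int, seed: int, scheme: str = "subject", rng: Optional[np.random.Generator] = None
) -> np.ndarray:
    """Draw B multiplier realizations of sqrt(n)(Ĉ - C) on the fit grid.

    Each realization draws one standard-normal variate per subject
    (``subject`` scheme) or per (subject, endpoint) pair (``endpoint``
    scheme) — constant in t — and returns a (B, len(grid)) array.
    Bit-reproducible for a given seed.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n, grid = fit.n, fit.grid
    G = grid.size
    if scheme == "subject":
        g = rng.standard_normal((B, n))
        return (g @ fit.influence) / np.sqrt(n)
    if scheme == "endpoint":
        out = np.zeros((B, G))
        rows = np.arange(B)[:, None]
        for k in range(5):
            subj, col, inv_risk = fit.endpoint_jumps[k]
            if subj.size == 0:
                continue
            g = rng.standard_normal((B, subj.size))
            jumps = np.zeros((B, G))
            np.add.at(jumps, (rows, col[None, :]), g * inv_risk[None, :])
            sk = fit.survival[k](grid)
            out -= SIGNS[k] * sk[None, :] * np.cumsum(jumps, axis=1)
        return np.sqrt(n) * out
    raise ValueError(f"unknown multiplier scheme {scheme!r}")


def _interval_mask(grid: np.ndarray, sigma: np.ndarray, t1: float, t2: float) -> np.ndarray:
    mask = (grid >= t1) & (grid <= t2) & (sigma > 0)
    if not mask.any():
        raise DegenerateBandError(f"σ̂ vanishes on every grid point in [{t1}, {t2}]")
    return mask


def _sup_quantile(sups: np.ndarray, alpha: float) -> float:
    """Smallest q with #{sup_b > q}/B <= alpha (empirical (1-α) percentile)."""
    sups = np.sort(sups)
    B = sups.size
    idx = int(np.ceil((1 - alpha) * B)) - 1
    return float(sups[max(idx, 0)])


def default_interval(fit1: CgrfsFit, fit2: Optional[CgrfsFit] = None) -> tuple[float, float]:
    """Default comparison window [t1, t2].

    t1 is the largest of the per-sample smallest event times (so every
    sample has started accruing events); t2 is the largest event time
    across samples — sensible when many subjects remain under study then.
    """
    fits = [fit1] if fit2 is None else [fit1, fit2]
    mins, maxs = [], []
    for f in fits:
        if f.grid.size == 0:
            raise ValueError("no events in a sample: cannot choose a default interval")
        mins.append(f.grid[0])
        maxs.append(f.grid[-1])
    return float(max(mins)), float(max(maxs))


def confidence_band(
    fit: CgrfsFit,
    t1: Optional[float] = None,
    t2: Optional[float] = None,
    alpha: float = 0.05,
    B: int = 1000,
    seed: int = 0,
    scheme: str = "subject",
) -> BandResult:
    """(1-alpha) simultaneous confidence band for C(t) on [t1, t2]."""
    if t1 is None or t2 is None:
        d1, d2 = default_interval(fit)
        t1 = d1 if t1 is None else t1
        t2 = d2 if t2 is None else t2
    sigma = fit.sigma_hat.values
    mask = _interval_mask(fit.grid, sigma, t1, t2)
    real = realize_processes(fit, B, seed, scheme=scheme)
    sups = np.abs(real[:, mask] / sigma[None, mask]).max(axis=1)
    q = _sup_quantile(sups, alpha)

    times = fit.grid[mask]
    c = fit.c_hat.values[mask]
    half = q * sigma[mask] / np.sqrt(fit.n)
    return BandResult(
        interval=(float(t1), float(t2)),
        critical_value=q,
        lower=StepFunction(times, c - half, value_at_0=c[0] - half[0]),
        upper=StepFunction(times, c + half, value_at_0=c[0] + half[0]),
        B=B,
        seed=seed,
        alpha=alpha,
        scheme=scheme,
        times=times,
        estimate=c,
    )


def _eval_on(times_from: np.ndarray, values: np.ndarray, times_to: np.ndarray, v0: float = 0.0):
    """Evaluate right-continuous step rows (B, len(times_from)) at times_to."""
    idx = np.searchsorted(times_from, times_to, side="right")
    padded = np.concatenate((np.full((values.shape[0], 1), v0), values), axis=1)
    return padded[:, idx]


def _two_sample_machinery(fit1, fit2, t1, t2, alpha, B, seed, scheme):
    if t1 is None or t2 is None:
        d1, d2 = default_interval(fit1, fit2)
        t1 = d1 if t1 is None else t1
        t2 = d2 if t2 is None else t2
    pooled = np.unique(np.concatenate([fit1.grid, fit2.grid]))
    pooled = pooled[(pooled >= t1) & (pooled <= t2)]
    if pooled.size == 0:
        raise DegenerateBandError(f"no event times in [{t1}, {t2}]")
    se = np.sqrt(fit1.sigma_hat(pooled) ** 2 / fit1.n + fit2.sigma_hat(pooled) ** 2 / fit2.n)
    ok = se > 0
    if not ok.any():
        raise DegenerateBandError(f"SE vanishes on every grid point in [{t1}, {t2}]")

    rng = np.random.default_rng(seed)
    r1 = realize_processes(fit1, B, seed, scheme=scheme, rng=rng)
    r2 = realize_processes(fit2, B, seed, scheme=scheme, rng=rng)
    d = _eval_on(fit1.grid, r1, pooled) / np.sqrt(fit1.n) - _eval_on(
        fit2.grid, r2, pooled
    ) / np.sqrt(fit2.n)
    u = np.abs(d[:, ok] / se[None, ok])
    sups = u.max(axis=1)

    diff = fit1.c_hat(pooled) - fit2.c_hat(pooled)
    k_hat = float(np.abs(diff[ok] / se[ok]).max())
    return (float(t1), float(t2)), pooled, ok, se, diff, sups, k_hat


def difference_band(
    fit1: CgrfsFit,
    fit2: CgrfsFit,
    t1: Optional[float] = None,
    t2: Optional[float] = None,
    alpha: float = 0.05,
    B: int = 1000,
    seed: int = 0,
    scheme: str = "subject",
) -> BandResult:
    """(1-alpha) simultaneous band for C1(t) - C2(t) on [t1, t2]."""
    interval, pooled, ok, se, diff, sups, _ = _two_sample_machinery(
        fit1, fit2, t1, t2, alpha, B, seed, scheme
    )
    g = _sup_quantile(sups, alpha)
    times = pooled[ok]
    est = diff[ok]
    half = g * se[ok]
    return BandResult(
        interval=interval,
        critical_value=g,
        lower=StepFunction(times, est - half, value_at_0=est[0] - half[0]),
        upper=StepFunction(times, est + half, value_at_0=est[0] + half[0]),
        B=B,
        seed=seed,
        alpha=alpha,
        scheme=scheme,
        times=times,
        estimate=est,
    )


def supremum_test(
    fit1: CgrfsFit,
    fit2: CgrfsFit,
    t1: Optional[float] = None,
    t2: Optional[float] = None,
    B: int = 1000,
    seed: int = 0,
    scheme: str = "subject",
) -> SupTestResult:
    """Two-sample supremum test of H0: C1(t) = C2(t) on [t1, t2].

    K̂ = sup_t |(Ĉ1 - Ĉ2)/SE| over grid points in the window; the
    p-value is the proportion of resampled suprema >= K̂.
    """
    interval, _, _, _, _, sups, k_hat = _two_sample_machinery(
        fit1, fit2, t1, t2, None, B, seed, scheme
    )
    p = float(np.mean(sups >= k_hat))
    return SupTestResult(k_hat=k_hat, p_value=p, B=B, interval=interval, seed=seed, scheme=scheme)
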