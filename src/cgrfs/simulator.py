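"""Continuous-time Markov simulation of the ten-state model, with oracles.

Cohorts are generated from a time-homogeneous Markov process on the
ten-state diagram: each transient (alive) state 0, 2, 4, 6, 8 has a
failure intensity (into the adjacent absorbing state) and, except the
last, a progression intensity (onset or resolution of a GVHD episode,
into the next transient state).  Sojourn times are exponential with the
total exit rate; the destination is chosen proportionally to the rates.
Right-censoring is independent (exponential, uniform or administrative)
and truncates the observed path.

Because the intensities are constant, the exact occupation
probabilities are available in closed form as the matrix exponential of
the generator, P(0, t) = exp(tQ); this is the truth oracle for every
calibration experiment (estimator consistency, CI and band coverage,
test size and power, variance calibration).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import expm
from scipy.stats import norm

from . import bands_tests, cgrfs_core
from .event_model import SubjectHistory, derive_all
from .state_probs import cgrfs_aalen_johansen

__all__ = [
    "Censoring",
    "IntensitySpec",
    "ALLOWED_TRANSITIONS",
    "DEFAULT_SPEC",
    "simulate_cohort",
    "generator_matrix",
    "true_occupancy",
    "true_cgrfs",
    "run_calibration",
    "EXPERIMENTS",
]

#: the nine allowed transitions of the state diagram
ALLOWED_TRANSITIONS = ((0, 1), (0, 2), (2, 3), (2, 4), (4, 5), (4, 6), (6, 7), (6, 8), (8, 9))
_TRANSIENT = (0, 2, 4, 6, 8)


@dataclass(frozen=True)
class Censoring:
    """Independent right-censoring distribution.

    kind: "exponential" (params: rate), "uniform" (params: low, high) or
    "administrative" (params: tau; tau = inf means no censoring).
    """

    kind: str
    params: tuple

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "exponential":
            (rate,) = self.params
            if rate <= 0:
                raise ValueError("exponential censoring needs rate > 0")
            return rng.exponential(1.0 / rate, size=n)
        if self.kind == "uniform":
            low, high = self.params
            if not 0 <= low < high:
                raise ValueError("uniform censoring needs 0 <= low < high")
            return rng.uniform(low, high, size=n)
        if self.kind == "administrative":
            (tau,) = self.params
            if tau < 0:
                raise ValueError("administrative censoring needs tau >= 0")
            return np.full(n, float(tau))
        raise ValueError(f"unknown censoring kind {self.kind!r}")

    @property
    def proper(self) -> bool:
        return not (self.kind == "administrative" and not np.isfinite(self.params[0]))


@dataclass(frozen=True)
class IntensitySpec:
    """Constant transition intensities plus a censoring distribution."""

    rates: dict  # {(from, to): rate} over ALLOWED_TRANSITIONS
    censoring: Censoring

    def __post_init__(self):
        for key, rate in self.rates.items():
            if tuple(key) not in ALLOWED_TRANSITIONS:
                raise ValueError(f"transition {key} not in the state diagram")
            if rate < 0:
                raise ValueError(f"negative intensity for transition {key}")
        if self.rate(0, 1) + self.rate(0, 2) <= 0:
            raise ValueError("need at least one positive exit rate out of state 0")

    def rate(self, frm: int, to: int) -> float:
        return float(self.rates.get((frm, to), 0.0))

    def proper_followup(self) -> bool:
        """Whether every simulated subject's follow-up terminates a.s."""
        if self.censoring.proper:
            return True
        # improper censoring: every subject must eventually fail, which
        # holds unless some reachable transient state has zero exit rate
        state = 0
        while True:
            lam_fail = self.rate(state, state + 1)
            lam_prog = self.rate(state, state + 2) if state < 8 else 0.0
            if lam_fail + lam_prog <= 0:
                return False
            if lam_prog <= 0 or state == 8:
                return True
            state += 2

    def doubled_failure(self) -> "IntensitySpec":
        """Same spec with every failure intensity doubled (power experiments)."""
        rates = dict(self.rates)
        for k in _TRANSIENT:
            if (k, k + 1) in rates:
                rates[(k, k + 1)] = 2.0 * rates[(k, k + 1)]
        return IntensitySpec(rates=rates, censoring=self.censoring)


#: Benchmark scenario used throughout the calibration experiments: time
#: unit years, substantial first-episode onset and resolution, modest
#: second episodes, staggered-accrual censoring uniform on [2, 6] years.
#: These are illustrative defaults, not estimates of any real cohort.
DEFAULT_SPEC = IntensitySpec(
    rates={
        (0, 1): 0.25,
        (0, 2): 0.35,
        (2, 3): 0.15,
        (2, 4): 0.20,
        (4, 5): 0.08,
        (4, 6): 0.10,
        (6, 7): 0.15,
        (6, 8): 0.25,
        (8, 9): 0.05,
    },
    censoring=Censoring("uniform", (2.0, 6.0)),
)

#: evaluation horizon for calibration experiments (years); the tails of
#: the curves beyond it carry few subjects and high variance
DEFAULT_T_MAX = 4.0
#: interior evaluation time for pointwise experiments
DEFAULT_T_EVAL = 2.0

# fields recording entry into transient states 2, 4, 6, 8
_ENTRY_FIELDS = ("t_gvhd1", "t_res1", "t_gvhd2", "t_res2")


def simulate_cohort(spec: IntensitySpec, n: int, seed: int) -> list[SubjectHistory]:
    """Generate n independent subject histories from the Markov model."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not spec.proper_followup():
        raise ValueError(
            "non-terminating model: no exit out of state 0 and improper censoring"
        )
    rng = np.random.default_rng(seed)
    censor = spec.censoring.draw(n, rng)

    clock = np.zeros(n)
    active = np.ones(n, dtype=bool)
    fail_time = np.full(n, np.inf)
    entries = np.full((4, n), np.inf)  # rows follow _ENTRY_FIELDS

    for stage, state in enumerate(_TRANSIENT):
        lam_fail = spec.rate(state, state + 1)
        lam_prog = spec.rate(state, state + 2) if state < 8 else 0.0
        total = lam_fail + lam_prog
        idx = np.nonzero(active)[0]
        if idx.size == 0 or total <= 0:
            break
        dwell = rng.exponential(1.0 / total, size=idx.size)
        exit_time = clock[idx] + dwell
        to_fail = rng.random(idx.size) < (lam_fail / total)
        fail_time[idx[to_fail]] = exit_time[to_fail]
        active[idx[to_fail]] = False
        move = idx[~to_fail]
        if state < 8:
            entries[stage, move] = exit_time[~to_fail]
            clock[move] = exit_time[~to_fail]
        else:
            active[move] = False  # no progression out of the last recovery state

    histories = []
    for i in range(n):
        failed = fail_time[i] <= censor[i]
        cut = fail_time[i] if failed else censor[i]
        if not failed and not np.isfinite(censor[i]):
            raise ValueError(f"non-terminating follow-up for subject {i}")
        kwargs = {}
        for j, fname in enumerate(_ENTRY_FIELDS):
            t = entries[j, i]
            kwargs[fname] = float(t) if t <= cut else None
        histories.append(
            SubjectHistory(
                subject_id=i,
                t_fail=float(fail_time[i]) if failed else None,
                t_censor=None if failed else float(censor[i]),
                **kwargs,
            )
        )
    return histories


def generator_matrix(spec: IntensitySpec) -> np.ndarray:
    """The 10x10 generator Q of the Markov process (rows sum to zero)."""
    q = np.zeros((10, 10))
    for frm, to in ALLOWED_TRANSITIONS:
        q[frm, to] = spec.rate(frm, to)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def true_occupancy(spec: IntensitySpec, t: float) -> np.ndarray:
    """Exact occupation probabilities P_{0i}(0, t), i = 0..9."""
    return expm(float(t) * generator_matrix(spec))[0]


def true_cgrfs(spec: IntensitySpec, times) -> np.ndarray:
    """Exact C(t) = P00 + P04 + P08 at each requested time."""
    q = generator_matrix(spec)
    out = np.empty(np.size(times))
    for j, t in enumerate(np.atleast_1d(np.asarray(times, dtype=float))):
        row = expm(t * q)[0]
        out[j] = row[0] + row[4] + row[8]
    return out


EXPERIMENTS = (
    "ci-coverage",
    "band-coverage",
    "test-size",
    "test-power",
    "variance-ratio",
    "estimator-agreement",
)


def _fit(histories):
    return cgrfs_core.estimate_cgrfs(derive_all(histories))


def run_calibration(
    spec: IntensitySpec,
    n: int,
    reps: int,
    B: int,
    seed: int,
    experiment: str,
    alpha: float = 0.05,
    t_eval: float = DEFAULT_T_EVAL,
    t_max: float = DEFAULT_T_MAX,
    scheme: str = "subject",
    n_list: Optional[Sequence[int]] = None,
) -> dict:
    """Monte-Carlo calibration experiments against the exact oracle.

    Replication r simulates with seed ``seed + r`` (two-sample
    experiments use ``seed + 2r`` and ``seed + 2r + 1``); resampling in
    replication r uses seed ``seed + r`` as well, so every experiment is
    a pure function of (spec, sizes, seed).  Returns a machine-readable
    dict with the Monte-Carlo estimate and its standard error.
    """
    if experiment not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {experiment!r}; choose from {EXPERIMENTS}")
    spec2 = spec if experiment != "test-power" else spec.doubled_failure()

    if experiment == "ci-coverage":
        truth = true_cgrfs(spec, [t_eval])[0]
        cover_ll, cover_lin = [], []
        for r in range(reps):
            fit = _fit(simulate_cohort(spec, n, seed + r))
            lo, hi = cgrfs_core.ci_linear(fit, t_eval, alpha)
            cover_lin.append(lo <= truth <= hi)
            try:
                lo, hi = cgrfs_core.ci_loglog(fit, t_eval, alpha)
            except cgrfs_core.TransformError:
                pass  # fall back to the linear interval already computed
            cover_ll.append(lo <= truth <= hi)
        out = {}
        for name, cov in (("loglog", cover_ll), ("linear", cover_lin)):
            p = float(np.mean(cov))
            out[f"coverage_{name}"] = p
            out[f"se_{name}"] = float(np.sqrt(p * (1 - p) / reps))
        return {"experiment": experiment, "n": n, "reps": reps, "t_eval": t_eval,
                "alpha": alpha, "truth": float(truth), **out}

    if experiment == "variance-ratio":
        est, avar = [], []
        for r in range(reps):
            fit = _fit(simulate_cohort(spec, n, seed + r))
            est.append(float(fit.c_hat(t_eval)))
            avar.append(float(fit.sigma_hat(t_eval)) ** 2 / n)
        mc_var = float(np.var(est, ddof=1))
        mean_est = float(np.mean(avar))
        return {"experiment": experiment, "n": n, "reps": reps, "t_eval": t_eval,
                "mc_variance": mc_var, "mean_estimated_variance": mean_est,
                "ratio": mean_est / mc_var}

    if experiment == "band-coverage":
        q = generator_matrix(spec)
        covered, q_ge_z = [], []
        z = norm.ppf(1 - alpha / 2)
        for r in range(reps):
            fit = _fit(simulate_cohort(spec, n, seed + r))
            t1, t2 = np.quantile(fit.grid, [0.10, 0.90])  # middle 80% of follow-up
            band = bands_tests.confidence_band(
                fit, t1, t2, alpha=alpha, B=B, seed=seed + r, scheme=scheme
            )
            ts = band.times
            truth = true_cgrfs(spec, ts)
            lo, hi = band.lower.values, band.upper.values
            # each band piece is constant on [t_j, t_{j+1}); by continuity of
            # C it suffices to check the truth at both ends of every piece
            ok = np.all(lo <= truth) and np.all(truth <= hi)
            ok = ok and np.all(lo[:-1] <= truth[1:]) and np.all(truth[1:] <= hi[:-1])
            covered.append(ok)
            q_ge_z.append(band.critical_value >= z)
        p = float(np.mean(covered))
        return {"experiment": experiment, "n": n, "reps": reps, "B": B, "alpha": alpha,
                "scheme": scheme, "coverage": p,
                "se": float(np.sqrt(p * (1 - p) / reps)),
                "frac_critical_ge_z": float(np.mean(q_ge_z))}

    if experiment in ("test-size", "test-power"):
        pvals = []
        for r in range(reps):
            fit1 = _fit(simulate_cohort(spec, n, seed + 2 * r))
            fit2 = _fit(simulate_cohort(spec2, n, seed + 2 * r + 1))
            t1, t2 = bands_tests.default_interval(fit1, fit2)
            res = bands_tests.supremum_test(
                fit1, fit2, t1, min(t2, t_max), B=B, seed=seed + r, scheme=scheme
            )
            pvals.append(res.p_value)
        pvals = np.asarray(pvals)
        rej = float(np.mean(pvals <= alpha))
        # Kolmogorov distance of the p-value sample from Uniform(0,1)
        ps = np.sort(pvals)
        ecdf_hi = np.arange(1, reps + 1) / reps
        ecdf_lo = np.arange(0, reps) / reps
        ks = float(max(np.max(ecdf_hi - ps), np.max(ps - ecdf_lo)))
        return {"experiment": experiment, "n_per_arm": n, "reps": reps, "B": B,
                "alpha": alpha, "scheme": scheme, "rejection_rate": rej,
                "se": float(np.sqrt(rej * (1 - rej) / reps)), "ks_uniform": ks,
                "p_values": pvals.tolist()}

    # estimator-agreement
    sizes = list(n_list) if n_list else [n]
    results = {}
    for size in sizes:
        gaps = []
        for r in range(reps):
            hist = simulate_cohort(spec, size, seed + r)
            fit = _fit(hist)
            aj = cgrfs_aalen_johansen(hist)
            ts = fit.grid[fit.grid <= t_max]
            if ts.size == 0:
                continue
            gaps.append(float(np.max(np.abs(fit.c_hat(ts) - aj(ts)))))
        results[int(size)] = {
            "median_max_gap": float(np.median(gaps)),
            "mean_max_gap": float(np.mean(gaps)),
        }
    return {"experiment": experiment, "reps": reps, "t_max": t_max, "by_n": results}
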