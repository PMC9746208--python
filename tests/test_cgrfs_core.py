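import numpy as np
import pytest

from cgrfs.cgrfs_core import (
    SIGNS,
    TransformError,
    ci_linear,
    ci_loglog,
    estimate_cgrfs,
    influence_values,
    variance,
)
from cgrfs.event_model import SubjectHistory, derive_all
from cgrfs.km import build_counting, km_estimate
from cgrfs.simulator import simulate_cohort
from cgrfs.state_probs import aalen_johansen


def brute_force_influence(records, grid):
    """Independent per-subject loop evaluation of the influence values.

    Ŵ_i(t) = n Σ_k (-s_k) Ŝ_k(t) Σ_{events u<=t} [dN_ik(u) - Y_ik(u) dN̄_k(u)/Ȳ_k(u)] / Ȳ_k(u)
    """
    cd = build_counting(records)
    n = cd.n
    surv = [km_estimate(ep) for ep in cd.endpoints]
    W = np.zeros((n, len(grid)))
    for k, ep in enumerate(cd.endpoints):
        sk = SIGNS[k]
        for gi, t in enumerate(grid):
            s_kt = surv[k](t)
            for i in range(n):
                integral = 0.0
                for u, d, y in zip(ep.event_times, ep.n_events, ep.at_risk):
                    if u > t:
                        break
                    dn_i = 1.0 if (ep.x[i] == u and ep.delta[i] == 1) else 0.0
                    y_i = 1.0 if ep.x[i] >= u else 0.0
                    integral += (dn_i - y_i * d / y) / y
                W[i, gi] += -sk * s_kt * integral
    return n * W


class TestEstimate:
    def test_single_subject_death(self):
        fit = estimate_cgrfs(derive_all([SubjectHistory("a", t_fail=3.0)]))
        assert fit.c_hat(2.999) == 1.0
        assert fit.c_hat(3.0) == 0.0

    def test_two_subject_nonmonotone_recovery(self, two_subject_records):
        fit = estimate_cgrfs(two_subject_records)
        assert fit.c_hat(0.0) == 1.0
        assert fit.c_hat(1.9) == 1.0
        assert fit.c_hat(2.0) == pytest.approx(0.5)
        assert fit.c_hat(3.999) == pytest.approx(0.5)
        assert fit.c_hat(4.0) == pytest.approx(1.0)
        assert fit.c_hat(10.0) == pytest.approx(1.0)

    def test_no_gvhd_reduces_to_dfs(self, no_gvhd_spec):
        hist = simulate_cohort(no_gvhd_spec, 60, seed=5)
        fit = estimate_cgrfs(derive_all(hist))
        s4 = fit.survival[3]
        ts = np.concatenate(([0.0], fit.grid))
        np.testing.assert_allclose(fit.c_hat(ts), s4(ts), atol=1e-14)

    def test_single_episode_reduction(self):
        # with at most one GVHD episode the second-episode endpoints
        # collapse onto failure, so C reduces to S1 - S3 + S4 exactly
        from cgrfs.simulator import Censoring, IntensitySpec, simulate_cohort

        spec = IntensitySpec(
            rates={(0, 1): 0.3, (0, 2): 0.5, (2, 3): 0.2, (2, 4): 0.4, (4, 5): 0.1},
            censoring=Censoring("uniform", (1.0, 5.0)),
        )
        fit = estimate_cgrfs(derive_all(simulate_cohort(spec, 80, seed=12)))
        s1, s2, s3, s4, s5 = fit.survival
        ts = fit.grid
        np.testing.assert_allclose(s2(ts), s4(ts), atol=1e-14)
        np.testing.assert_allclose(s5(ts), s4(ts), atol=1e-14)
        np.testing.assert_allclose(fit.c_hat(ts), s1(ts) - s3(ts) + s4(ts), atol=1e-12)

    def test_s1_equals_aj_p00(self, small_cohort, small_records):
        fit = estimate_cgrfs(small_records)
        occ = aalen_johansen(small_cohort)
        np.testing.assert_allclose(
            fit.survival[0](occ.times), occ.probs[:, 0], atol=1e-12
        )


class TestInfluence:
    def test_zero_before_first_event(self, small_records):
        fit = estimate_cgrfs(small_records)
        t0 = fit.grid[0]
        w = brute_force_influence(small_records[:10], np.array([t0 / 2]))
        assert np.allclose(w, 0.0)

    def test_centering(self, small_records):
        grid, w = influence_values(small_records)
        np.testing.assert_allclose(w.sum(axis=0), 0.0, atol=1e-8)

    def test_matches_brute_force(self, benchmark_spec):
        hist = simulate_cohort(benchmark_spec, 25, seed=77)
        records = derive_all(hist)
        fit = estimate_cgrfs(records)
        probe = fit.grid[:: max(1, fit.grid.size // 8)]
        expected = brute_force_influence(records, probe)
        idx = np.searchsorted(fit.grid, probe)
        np.testing.assert_allclose(fit.influence[:, idx], expected, atol=1e-10)

    def test_no_gvhd_closed_form_variance(self, no_gvhd_spec):
        # with all five endpoints identical, the moment variance collapses to
        # n Ŝ4² Σ (dN̄/Ȳ²)(1 - dN̄/Ȳ): the exact square-sum of KM influence
        # values, whose leading term is the familiar Σ dN̄/Ȳ² form
        hist = simulate_cohort(no_gvhd_spec, 120, seed=6)
        records = derive_all(hist)
        fit = estimate_cgrfs(records)
        ep = fit.counting.endpoints[3]
        d, y = ep.n_events.astype(float), ep.at_risk.astype(float)
        inc = (d / y**2) * (1.0 - d / y)
        closed = fit.n * fit.survival[3](fit.grid) ** 2 * np.cumsum(inc)
        np.testing.assert_allclose(fit.sigma2, closed, atol=1e-10)
        leading = fit.n * fit.survival[3](fit.grid) ** 2 * np.cumsum(d / y**2)
        half = fit.grid.size // 2  # risk sets still large here
        np.testing.assert_allclose(fit.sigma2[:half], leading[:half], rtol=0.05)

    def test_requires_two_subjects(self):
        with pytest.raises(ValueError, match="n >= 2"):
            influence_values(derive_all([SubjectHistory("a", t_fail=1.0)]))


class FakeFit:
    """Minimal stand-in with prescribed Ĉ, σ̂ and n for CI arithmetic."""

    def __init__(self, c, sigma, n):
        self.c_hat = lambda t: np.float64(c)
        self.sigma_hat = lambda t: np.float64(sigma)
        self.n = n


class TestIntervals:
    def test_variance_is_sigma_squared(self, small_records):
        fit = estimate_cgrfs(small_records)
        t = fit.grid[len(fit.grid) // 2]
        assert variance(fit, t) == pytest.approx(float(fit.sigma_hat(t)) ** 2)

    def test_linear_arithmetic(self):
        lo, hi = ci_linear(FakeFit(0.8, 1.0, 100), t=1.0)
        assert lo == pytest.approx(0.8 - 0.19600, abs=1e-4)
        assert hi == pytest.approx(0.8 + 0.19600, abs=1e-4)

    def test_linear_collapses_when_sigma_zero(self):
        lo, hi = ci_linear(FakeFit(0.7, 0.0, 50), t=1.0)
        assert lo == hi == pytest.approx(0.7)

    def test_loglog_worked_example(self):
        # θ = exp(0.196/(0.8 ln 0.8)) ≈ 0.3335 → CI ≈ (0.512, 0.928)
        lo, hi = ci_loglog(FakeFit(0.8, 1.0, 100), t=1.0)
        assert lo == pytest.approx(0.512, abs=0.001)
        assert hi == pytest.approx(0.928, abs=0.001)

    def test_loglog_degenerate_sigma(self):
        lo, hi = ci_loglog(FakeFit(0.8, 0.0, 100), t=1.0)
        assert lo == hi == pytest.approx(0.8)

    @pytest.mark.parametrize("c", [0.0, 1.0, 1.05, -0.01])
    def test_loglog_undefined_outside_unit_interval(self, c):
        with pytest.raises(TransformError):
            ci_loglog(FakeFit(c, 0.5, 100), t=1.0)

    def test_loglog_stays_inside_unit_interval(self, small_records):
        fit = estimate_cgrfs(small_records)
        ts = fit.grid[(fit.c_hat.values > 0) & (fit.c_hat.values < 1)]
        lo, hi = ci_loglog(fit, ts)
        assert np.all(lo > 0) and np.all(hi < 1) and np.all(lo <= hi)

    @pytest.mark.parametrize("alpha", [0, 1, -0.2, 1.3])
    def test_alpha_domain(self, alpha):
        with pytest.raises(ValueError):
            ci_linear(FakeFit(0.5, 1.0, 10), 1.0, alpha)
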