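"""Gauss–Newton and Marquardt solvers: recovery, damping, divergence."""

import math

import numpy as np
import pytest
from scipy.optimize import curve_fit

import sprkin as sk
from sprkin.fitters import assoc_jacobian, dissoc_jacobian


class TestJacobian:
    def test_zero_at_origin(self):
        A, B = assoc_jacobian(3358.0, 0.01, np.array([0.0]))
        assert A[0] == 0.0 and B[0] == 0.0

    def test_saturation_limit(self):
        A, B = assoc_jacobian(3358.0, 1e6, np.array([1.0]))
        assert A[0] == pytest.approx(1.0)
        assert B[0] == pytest.approx(0.0, abs=1e-200)

    def test_analytic_values(self):
        A, B = assoc_jacobian(3358.0, 0.01, np.array([100.0]))
        assert A[0] == pytest.approx(1.0 - math.exp(-1.0), rel=1e-12)
        assert B[0] == pytest.approx(100.0 * 3358.0 * math.exp(-1.0), rel=1e-12)

    def test_matches_finite_differences(self, noisy_assoc):
        t, _ = noisy_assoc
        a, b, h = 3000.0, 0.009, 1e-7
        A, B = assoc_jacobian(a, b, t)
        # y is linear in a, so its finite difference is exact at any step
        ha = 1.0
        fd_a = ((a + ha) * (1 - np.exp(-b * t)) - (a - ha) * (1 - np.exp(-b * t))) / (2 * ha)
        fd_b = (a * (1 - np.exp(-(b + h) * t)) - a * (1 - np.exp(-(b - h) * t))) / (2 * h)
        assert np.allclose(A, fd_a, rtol=1e-9)
        assert np.allclose(B, fd_b, rtol=1e-5, atol=1e-6)
        Ad, Bd = dissoc_jacobian(a, b, t)
        fd_bd = (a * np.exp(-(b + h) * t) - a * np.exp(-(b - h) * t)) / (2 * h)
        assert np.allclose(Ad, np.exp(-b * t), rtol=1e-12)
        assert np.allclose(Bd, fd_bd, rtol=1e-5, atol=1e-6)


class TestGaussNewton:
    def test_recovers_generating_parameters(self, noiseless_assoc, ref_assoc):
        t, y = noiseless_assoc
        cfg = sk.FitConfig(a0=float(np.max(y)), b0=0.0118)
        res = sk.gauss_newton_fit(t, y, "association", cfg)
        assert res.converged
        assert res.params[0] == pytest.approx(ref_assoc.a, rel=1e-6)
        assert res.params[1] == pytest.approx(ref_assoc.b, rel=1e-6)

    def test_fixed_point_at_truth(self, noiseless_assoc, ref_assoc):
        """Init at the exact optimum: residuals orthogonal to the Jacobian."""
        t, y = noiseless_assoc
        cfg = sk.FitConfig(a0=ref_assoc.a, b0=ref_assoc.b)
        res = sk.gauss_newton_fit(t, y, "association", cfg)
        assert res.converged and res.iterations == 1
        rec = res.trace.records[-1]
        assert abs(rec.delta1) <= 1e-6 and abs(rec.delta2) <= 1e-6

    def test_diverges_from_poor_init(self, ref_assoc):
        """Short noisy series with a wildly wrong rate guess blows up."""
        t = np.arange(40.0)
        rng = np.random.default_rng(7)
        y = sk.association_response(ref_assoc, t) + rng.normal(0, 20, len(t))
        res = sk.gauss_newton_fit(
            t, y, "association", sk.FitConfig(a0=float(np.max(y)), b0=1.0)
        )
        assert res.status in ("diverged", "max_iter")

    def test_singular_normal_matrix_flagged(self):
        # all-zero times: both Jacobian columns vanish identically
        t = np.zeros(5)
        y = np.arange(5.0)
        with pytest.raises(ValueError):
            sk.Sensorgram(t, y)  # not even a valid sensorgram
        res = sk.gauss_newton_fit(
            np.array([0.0, 0.0, 0.0]), np.array([1.0, 2.0, 3.0]),
            "association", sk.FitConfig(a0=1.0, b0=0.01),
        )
        assert res.status == "diverged"
        assert "singular" in res.message


class TestMarquardt:
    def test_recovers_from_reference_init(self, noiseless_assoc, ref_assoc):
        t, y = noiseless_assoc
        cfg = sk.FitConfig(a0=float(np.max(y)), b0=0.0095)
        res = sk.marquardt_fit(t, y, "association", cfg)
        assert res.converged
        assert res.params[0] == pytest.approx(ref_assoc.a, rel=1e-6)
        assert res.params[1] == pytest.approx(ref_assoc.b, rel=1e-6)

    def test_dissociation_recovery(self, noiseless_dissoc, ref_dissoc):
        t, y = noiseless_dissoc
        res = sk.marquardt_fit(t, y, "dissociation", sk.FitConfig(b0=0.001))
        assert res.converged
        assert res.params[1] == pytest.approx(ref_dissoc.m, rel=1e-6)

    def test_zero_damping_reproduces_gauss_newton(self, noiseless_assoc):
        """With d = 0 the damped system is the plain normal equations."""
        t, y = noiseless_assoc
        cfg = sk.FitConfig(a0=float(np.max(y)), b0=0.0095, d0=0.0)
        lm = sk.marquardt_fit(t, y, "association", cfg)
        gn = sk.gauss_newton_fit(t, y, "association", cfg)
        assert lm.iterations == gn.iterations
        for r_lm, r_gn in zip(lm.trace.records, gn.trace.records):
            assert r_lm.a == pytest.approx(r_gn.a, rel=1e-15, abs=0)
            assert r_lm.b == pytest.approx(r_gn.b, rel=1e-15, abs=0)
        step_lm = sk.damped_step("association", (3000.0, 0.009), t, y, 0.0)
        gn1 = sk.gauss_newton_fit(
            t, y, "association", sk.FitConfig(a0=3000.0, b0=0.009, max_iter=1)
        ).trace.records[-1]
        assert step_lm[0] == pytest.approx(gn1.delta1, rel=1e-15)
        assert step_lm[1] == pytest.approx(gn1.delta2, rel=1e-15)

    def test_accepted_steps_strictly_decrease_q(self, noisy_assoc):
        t, y = noisy_assoc
        res = sk.marquardt_fit(
            t, y, "association", sk.FitConfig(a0=float(np.max(y)), b0=0.0095)
        )
        assert res.converged
        assert np.all(np.diff(res.trace.q_values()) < 0)

    def test_step_length_vanishes_with_damping(self, noisy_assoc):
        """‖(Δ1, Δ2)‖ → 0 as d → ∞ at a fixed iterate."""
        t, y = noisy_assoc
        p = (3000.0, 0.009)
        norms = [
            np.hypot(*sk.damped_step("association", p, t, y, d))
            for d in (1e4, 1e8, 1e13, 1e16, 1e19)
        ]
        assert norms[-1] < 1e-8
        assert norms[-1] < norms[0] * 1e-6

    def test_rescues_inits_where_gauss_newton_fails(self, noiseless_assoc, ref_assoc):
        """Q stays finite and below Q(init); here it even reaches the optimum."""
        t, y = noiseless_assoc
        for b0 in (1.0, 0.2, 0.05):
            cfg = sk.FitConfig(a0=float(np.max(y)), b0=b0)
            gn = sk.gauss_newton_fit(t, y, "association", cfg)
            assert not (
                gn.converged
                and np.isclose(gn.params[1], ref_assoc.b, rtol=1e-3)
            ), "init should defeat the undamped iteration"
            lm = sk.marquardt_fit(t, y, "association", cfg)
            q_init = float(np.sum((y - np.max(y) * (1 - np.exp(-b0 * t))) ** 2))
            assert np.isfinite(lm.Q) and lm.Q <= q_init
            assert lm.converged
            assert lm.params[1] == pytest.approx(ref_assoc.b, rel=1e-6)

    def test_finite_q_even_on_hopeless_init(self, noisy_assoc):
        t, y = noisy_assoc
        cfg = sk.FitConfig(a0=float(np.max(y)), b0=-0.01, max_iter=200)
        lm = sk.marquardt_fit(t, y, "association", cfg)
        q_init = float(np.sum((y - np.max(y) * (1 - np.exp(0.01 * t))) ** 2))
        assert np.isfinite(lm.Q)
        assert lm.Q <= q_init

    def test_matches_grid_search_minimum(self, noisy_assoc, ref_assoc):
        """Dense 2-D grid search as an independent oracle for the optimum."""
        t, y = noisy_assoc
        res = sk.marquardt_fit(
            t, y, "association", sk.FitConfig(a0=3000.0, b0=0.01)
        )
        a_grid = np.linspace(ref_assoc.a * 0.9, ref_assoc.a * 1.1, 500)
        b_grid = np.linspace(ref_assoc.b * 0.5, ref_assoc.b * 1.5, 500)
        best_q, best = np.inf, None
        for b in b_grid:
            resid = y[None, :] - a_grid[:, None] * (1 - np.exp(-b * t))[None, :]
            q = np.einsum("ij,ij->i", resid, resid)
            i = int(q.argmin())
            if q[i] < best_q:
                best_q, best = float(q[i]), (float(a_grid[i]), float(b))
        assert res.Q <= best_q * (1 + 1e-12)
        assert abs(res.params[0] - best[0]) <= a_grid[1] - a_grid[0]
        assert abs(res.params[1] - best[1]) <= b_grid[1] - b_grid[0]

    def test_agrees_with_scipy_curve_fit(self, noisy_assoc):
        """Independent library fit lands on the same least-squares optimum."""
        t, y = noisy_assoc
        ours = sk.marquardt_fit(
            t, y, "association", sk.FitConfig(a0=3000.0, b0=0.01)
        )
        popt, _ = curve_fit(
            lambda x, a, b: a * (1 - np.exp(-b * x)), t, y, p0=(3000.0, 0.01)
        )
        assert ours.params[0] == pytest.approx(popt[0], rel=1e-6)
        assert ours.params[1] == pytest.approx(popt[1], rel=1e-6)

    def test_parameter_recovery_under_noise(self, ref_assoc, assoc_grid):
        """Median relative error of b over 200 seeded 20 RU replicates < 2%."""
        t = assoc_grid
        clean = sk.association_response(ref_assoc, t)
        errors = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            y = clean + rng.normal(0.0, 20.0, len(t))
            res = sk.marquardt_fit(
                t, y, "association", sk.FitConfig(a0=float(np.max(y)), b0=0.01)
            )
            assert res.converged
            errors.append(abs(res.params[1] - ref_assoc.b) / ref_assoc.b)
        assert np.median(errors) < 0.02


class TestTwoPhaseFit:
    def test_noiseless_reference_sensorgram(self, reference_sensorgram):
        phases = sk.segment_phases(reference_sensorgram, sk.PhaseWindows())
        dissoc_p, assoc_p, *_ = sk.fit_dissociation_then_association(
            phases.association.time, phases.association.response,
            phases.dissociation.time, phases.dissociation.response,
            sk.FitConfig(b0=0.0095),
        )
        assert dissoc_p.m == pytest.approx(0.00073, rel=1e-6)
        assert assoc_p.b == pytest.approx(0.01188, rel=1e-6)

    def test_constant_dissociation_flagged(self, noiseless_assoc):
        t, y = noiseless_assoc
        td = np.arange(39.0)
        yd = np.full_like(td, 3000.0)
        with pytest.raises(sk.PhaseFitError, match="dissociation"):
            sk.fit_dissociation_then_association(t, y, td, yd)

    def test_empty_phase_rejected(self, noiseless_assoc):
        t, y = noiseless_assoc
        with pytest.raises(sk.PhaseFitError, match="dissociation"):
            sk.fit_dissociation_then_association(t, y, np.array([]), np.array([]))

    def test_noisy_recovery_within_sampling_error(self):
        """20 RU noise: association coefficients within 5%; kd within 3 SE.

        Over the 38 s dissociation window the decay removes only ~2.7%
        of the amplitude, so kd's sampling error at 20 RU noise is
        ≈12% relative; a 5% band would reject most realizations of the
        stated conditions.  The association phase is long enough for a
        5% check.
        """
        spec = sk.GeneratorSpec(noise_sd=20.0, seed=3)
        s = sk.generate(spec)
        phases = sk.segment_phases(s, spec.windows)
        dissoc_p, assoc_p, *_ = sk.fit_dissociation_then_association(
            phases.association.time, phases.association.response,
            phases.dissociation.time, phases.dissociation.response,
            sk.FitConfig(b0=0.0095),
        )
        assert assoc_p.a == pytest.approx(spec.a, rel=0.05)
        assert assoc_p.b == pytest.approx(spec.b, rel=0.05)
        assert dissoc_p.m == pytest.approx(spec.m, rel=0.36)


class TestCompareFitters:
    def test_truth_in_grid_converges_immediately(self, noiseless_assoc, ref_assoc):
        t, y = noiseless_assoc
        rep = sk.compare_fitters(t, y, [(ref_assoc.a, ref_assoc.b)])
        assert all(e.status == "converged" and e.iterations <= 2 for e in rep.entries)

    def test_reference_grid_all_marquardt_converge(self, noisy_assoc):
        t, y = noisy_assoc
        a0 = float(np.max(y))
        rep = sk.compare_fitters(t, y, [(a0, 0.0095), (a0, 0.011)])
        lm = [e for e in rep.entries if e.algorithm == "marquardt"]
        assert len(lm) == 2
        assert all(e.status == "converged" for e in lm)

    def test_marquardt_never_diverges_more_than_gauss_newton(self, noisy_assoc):
        t, y = noisy_assoc
        a0 = float(np.max(y))
        grid = [(a0, b0) for b0 in (0.0095, 0.011, 0.05, 0.2, 1.0, -0.01)]
        rep = sk.compare_fitters(t, y, grid, sk.FitConfig(max_iter=200))
        assert rep.divergence_count("marquardt") <= rep.divergence_count("gauss_newton")

    def test_empty_grid_rejected(self, noisy_assoc):
        t, y = noisy_assoc
        with pytest.raises(ValueError):
            sk.compare_fitters(t, y, [])


def test_short_input_rejected():
    with pytest.raises(ValueError):
        sk.marquardt_fit(np.array([0.0, 1.0]), np.array([0.0, 1.0]))
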