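"""Unit tests of the two-tissue compartment model and frame averaging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import petkin as pk
from petkin.compartment import frame_weight_matrix

rates = st.floats(min_value=0.0, max_value=2.0, allow_nan=False)


def ones(t):
    return np.ones_like(np.asarray(t, dtype=float))


def zeros(t):
    return np.zeros_like(np.asarray(t, dtype=float))


class TestAlphas:
    @pytest.mark.parametrize(
        "k2,k3,k4,expected",
        [
            (0.1, 0.05, 0.0, (0.0, 0.15)),  # k4=0 forces alpha1=0, alpha2=k2+k3
            (0.0, 0.0, 0.0, (0.0, 0.0)),
        ],
    )
    def test_examples(self, k2, k3, k4, expected):
        pair = pk.compute_alphas(pk.KineticParams(0.01, k2, k3, k4))
        assert pair.alpha1 == pytest.approx(expected[0], abs=1e-15)
        assert pair.alpha2 == pytest.approx(expected[1], abs=1e-15)

    def test_published_tumor_means(self):
        # subcutaneous-tumor group means; identities checked by arithmetic,
        # roots against numpy's independent quadratic solver
        pair = pk.compute_alphas(pk.KineticParams(0.00229, 0.042, 0.0104, 0.00177))
        assert pair.alpha1 + pair.alpha2 == pytest.approx(0.05417, abs=1e-12)
        assert pair.alpha1 * pair.alpha2 == pytest.approx(7.434e-5, rel=1e-10)
        roots = np.sort(np.roots([1.0, -(0.042 + 0.0104 + 0.00177), 0.042 * 0.00177]))
        assert pair.alpha1 == pytest.approx(roots[0], rel=1e-12)
        assert pair.alpha2 == pytest.approx(roots[1], rel=1e-12)

    @settings(max_examples=300, derandomize=True)
    @given(k2=rates, k3=rates, k4=rates)
    def test_eigenrate_identities(self, k2, k3, k4):
        """Sum and product of the eigenrates match k2+k3+k4 and k2*k4."""
        pair = pk.compute_alphas(pk.KineticParams(0.01, k2, k3, k4))
        s = k2 + k3 + k4
        tol = 1e-12 * max(1.0, s)
        assert 0.0 <= pair.alpha1 <= pair.alpha2
        assert abs(pair.alpha1 + pair.alpha2 - s) < tol
        assert abs(pair.alpha1 * pair.alpha2 - k2 * k4) < tol


class TestInfluxConstant:
    @pytest.mark.parametrize(
        "K1,k2,k3,expected",
        [
            (0.5, 0.1, 0.0, 0.0),  # no trapping
            (0.5, 0.0, 0.1, 0.5),  # everything delivered is trapped
            (0.00229, 0.042, 0.0104, 0.00229 * 0.0104 / 0.0524),
            (0.5, 0.0, 0.0, 0.0),  # k2+k3=0 convention
        ],
    )
    def test_examples(self, K1, k2, k3, expected):
        assert pk.influx_constant(pk.KineticParams(K1, k2, k3, 0.0)) == pytest.approx(
            expected, rel=1e-12
        )

    @settings(max_examples=100, derandomize=True)
    @given(K1=st.floats(1e-4, 1.0), k2=rates, k3=st.floats(1e-6, 2.0), frac=st.floats(0.0, 0.5))
    def test_monotone_in_k3_and_K1(self, K1, k2, k3, frac):
        base = pk.influx_constant(pk.KineticParams(K1, k2, k3, 0.0))
        assert pk.influx_constant(pk.KineticParams(K1, k2, k3 * (1 + frac), 0.0)) >= base - 1e-15
        assert pk.influx_constant(pk.KineticParams(K1 * (1 + frac), k2, k3, 0.0)) >= base - 1e-15


class TestOdeSolver:
    def test_pure_accumulation(self):
        # k2=k3=k4=0: CT(t) = K1*t + VB with a unit plasma input
        params = pk.KineticParams(0.004, 0, 0, 0, 0.2)
        t = np.linspace(0.0, 600.0, 41)
        _, _, ct = pk.solve_tissue_ode(params, ones, t)
        assert np.allclose(ct, 0.004 * t + 0.2, rtol=1e-8, atol=1e-10)

    def test_zero_input(self):
        params = pk.KineticParams(0.01, 0.1, 0.05, 0.01, 0.1)
        t = np.linspace(0.0, 300.0, 31)
        ce, cm, ct = pk.solve_tissue_ode(params, zeros, t)
        assert not ce.any() and not cm.any() and not ct.any()

    def test_single_compartment_closed_form(self):
        # k3=k4=0, VB=0, Cp=1: CT = (K1/k2)(1 - exp(-k2 t))
        K1, k2 = 0.01, 0.04
        params = pk.KineticParams(K1, k2, 0, 0, 0)
        t = np.linspace(0.0, 900.0, 61)
        _, _, ct = pk.solve_tissue_ode(params, ones, t)
        assert np.allclose(ct, K1 / k2 * (1 - np.exp(-k2 * t)), rtol=1e-9, atol=1e-12)

    def test_rejects_non_monotone_grid(self):
        params = pk.KineticParams(0.01, 0.1, 0.05, 0.01)
        with pytest.raises(ValueError):
            pk.solve_tissue_ode(params, ones, np.array([0.0, 10.0, 5.0]))

    def test_mass_sanity_cm_nondecreasing_without_k4(self, bolus):
        # irreversible trapping: the bound pool can only grow
        params = pk.KineticParams(0.01, 0.2, 0.05, 0.0, 0.0)
        t = np.linspace(0.0, 3600.0, 241)
        _, cm, _ = pk.solve_tissue_ode(params, bolus, t)
        assert np.all(np.diff(cm) >= -1e-12)


class TestAnalyticCurve:
    def test_zero_input(self):
        params = pk.KineticParams(0.01, 0.1, 0.05, 0.01, 0.2)
        t = np.linspace(0.0, 100.0, 11)
        assert not pk.analytic_tissue_curve(params, zeros, t).any()

    def test_degenerate_kernel_is_linear_ramp(self):
        # all rates zero (confluent eigenrates): CT = K1*t for unit input
        params = pk.KineticParams(0.003, 0, 0, 0, 0)
        t = np.linspace(0.0, 200.0, 21)
        ct = pk.analytic_tissue_curve(params, ones, t)
        assert np.allclose(ct, 0.003 * t, rtol=1e-9, atol=1e-12)

    def test_matches_ode_oracle(self, bolus, rng):
        """Closed form and RK4 integration agree on random parameter sets."""
        t = np.linspace(0.0, 3600.0, 121)
        for _ in range(10):
            params = pk.KineticParams(*rng.uniform(0.0, 0.5, 4), vb=rng.uniform(0, 0.4))
            ct_a = pk.analytic_tissue_curve(params, bolus, t)
            _, _, ct_o = pk.solve_tissue_ode(params, bolus, t)
            scale = max(ct_o.max(), 1e-12)
            assert np.max(np.abs(ct_a - ct_o)) / scale < 1e-4

    def test_confluent_limit_continuity(self, bolus):
        # k3=0, k2=k4 makes the eigenrates collide; the confluent kernel
        # must join the generic branch continuously
        t = np.linspace(0.0, 600.0, 61)
        conf = pk.analytic_tissue_curve(pk.KineticParams(0.01, 0.05, 0.0, 0.05), bolus, t)
        near = pk.analytic_tissue_curve(pk.KineticParams(0.01, 0.05, 1e-7, 0.05), bolus, t)
        assert np.allclose(conf, near, rtol=1e-4, atol=1e-10)

    def test_linearity_in_input(self, bolus):
        params = pk.KineticParams(0.01, 0.1, 0.02, 0.005, 0.1)
        t = np.linspace(0.0, 1800.0, 61)
        ct = pk.analytic_tissue_curve(params, bolus, t)
        ct2 = pk.analytic_tissue_curve(params, lambda u: 2.0 * bolus(u), t)
        assert np.allclose(ct2, 2.0 * ct, rtol=1e-12)


class TestFrameAverage:
    def test_constant_curve(self, schedule):
        tac = pk.frame_average(lambda t: np.full_like(np.asarray(t, float), 7.0), schedule)
        assert np.allclose(tac.values, 7.0)

    def test_linear_ramp_midpoint(self):
        sched = pk.FrameSchedule(np.array([0.0]), np.array([10.0]))
        tac = pk.frame_average(lambda t: np.asarray(t, dtype=float), sched)
        assert tac.values[0] == pytest.approx(5.0, rel=1e-12)

    def test_exponential_exact_integral(self):
        sched = pk.FrameSchedule(np.array([0.0]), np.array([1.0]))
        tac = pk.frame_average(lambda t: np.exp(-np.asarray(t, dtype=float)), sched)
        assert tac.values[0] == pytest.approx(1.0 - np.exp(-1.0), rel=1e-10)

    def test_rejects_frames_beyond_domain(self, schedule):
        class ShortCurve:
            t_end = 100.0

            def __call__(self, t):
                return np.ones_like(np.asarray(t, dtype=float))

        with pytest.raises(ValueError, match="beyond the curve domain"):
            pk.frame_average(ShortCurve(), schedule)

    def test_weight_matrix_exact_for_piecewise_linear(self, schedule, rng):
        # trapezoid weights must reproduce frame averages of any PWL curve
        t = np.sort(rng.uniform(0.0, schedule.ends[-1], 400))
        t = np.unique(np.concatenate([[0.0], t, [schedule.ends[-1]]]))
        y = rng.uniform(0.0, 5.0, t.size)
        W = frame_weight_matrix(t, schedule)
        got = W @ y
        for f in range(schedule.n_frames):
            s, e = schedule.starts[f], schedule.ends[f]
            tt = np.unique(np.concatenate([[s], t[(t > s) & (t < e)], [e]]))
            yy = np.interp(tt, t, y)
            assert got[f] == pytest.approx(np.trapezoid(yy, tt) / (e - s), rel=1e-9)


class TestKineticParamsValidation:
    @pytest.mark.parametrize("bad", [{"K1": -0.1}, {"k3": -1e-9}, {"vb": 1.0}, {"vb": -0.2}])
    def test_invalid_rejected(self, bad):
        kwargs = {"K1": 0.01, "k2": 0.1, "k3": 0.05, "k4": 0.01, "vb": 0.1}
        kwargs.update(bad)
        with pytest.raises(ValueError):
            pk.KineticParams(**kwargs)
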