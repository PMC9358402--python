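"""Slow-plane reduction: QSS hormones, nullclines, fixed points, the Graves
bifurcation, the TSH(T4) curve, region labels and sweeps."""

import numpy as np
import pytest

from thyraxis import (
    DomainError,
    ScaledParameters,
    default_parameters,
    scale_parameters,
    set_point_state,
)
from thyraxis.axis_analysis import (
    classify_region,
    curve_from_setpoint,
    curve_residual,
    fast_relation_exponent,
    fixed_points,
    graves_threshold,
    nullcline_pituitary,
    nullcline_thyroid,
    qss_hormones,
    steady_state,
    sweep,
    transcritical_ab,
    tsh_of_t4_curve,
)
from thyraxis.simulator import EventSchedule, integrate


class TestQssHormones:
    def test_set_point_masses_give_set_point_hormones(self, default_params):
        h = qss_hormones(1.0, 1.0, default_params)
        assert (h.trh, h.tsh, h.th) == (pytest.approx(1.0), pytest.approx(1.5),
                                        pytest.approx(15.0))

    def test_cubic_closed_form(self, default_params):
        # scaled th = (t p)^(1/3): masses (8, 1) double TH
        h = qss_hormones(8.0, 1.0, default_params)
        assert h.th / 15.0 == pytest.approx(2.0, rel=1e-12)

    def test_external_t4_raises_the_root(self, default_params):
        base = qss_hormones(0.7, 1.3, default_params)
        boosted = qss_hormones(0.7, 1.3, default_params.replace(b_30=1.0))
        assert boosted.th > base.th

    def test_no_thyroid_no_source_is_degenerate(self, default_params):
        h = qss_hormones(0.0, 1.0, default_params)
        assert h.degenerate and h.th == default_params.th_floor

    def test_general_root_matches_closed_form(self, default_params):
        """The numeric 1-D root with a vanishing perturbation reproduces the
        cubic closed form."""
        p = default_params.replace(b_30=1e-12)
        h_num = qss_hormones(2.0, 0.5, p)
        h_closed = qss_hormones(2.0, 0.5, default_params)
        assert h_num.th == pytest.approx(h_closed.th, rel=1e-9)


class TestFastRelation:
    def test_inverse_kernels_give_exactly_two(self, default_params):
        assert fast_relation_exponent(default_params) == 2.0
        assert fast_relation_exponent(default_params,
                                      th_pair=(10.0, 25.0)) == pytest.approx(2.0)

    def test_michaelis_suppression_flattens_below_two(self):
        p = default_parameters(th_suppression="michaelis")
        assert fast_relation_exponent(p) < 2.0
        fd = fast_relation_exponent(p, th_pair=(14.0, 16.0))
        assert fd < 2.0

    def test_degenerate_pair_uses_analytic_derivative(self, default_params):
        assert fast_relation_exponent(default_params, th_pair=(15.0, 15.0)) == 2.0


class TestNullclines:
    def test_thyroid_closed_form_points(self):
        s0 = ScaledParameters()
        assert nullcline_thyroid([1.0], s0).p_values[0] == pytest.approx(1.0)
        assert nullcline_thyroid([2.0], s0).p_values[0] == pytest.approx(4.0)
        s = ScaledParameters(K_T=0.5)
        assert nullcline_thyroid([1.0], s).p_values[0] == pytest.approx(8.0)

    def test_pituitary_closed_form_points(self):
        s0 = ScaledParameters()
        assert nullcline_pituitary([1.0], s0).t_values[0] == pytest.approx(1.0)
        assert nullcline_pituitary([4.0], s0).t_values[0] == pytest.approx(0.25)
        s = ScaledParameters(K_P=0.5)
        assert nullcline_pituitary([1.0], s).t_values[0] == pytest.approx(0.125)

    @pytest.mark.parametrize("K_T,K_P", [(0.0, 0.0), (0.4, 0.0), (0.0, 0.6),
                                         (0.5, 0.3)])
    def test_numeric_route_matches_closed_forms(self, K_T, K_P):
        s = ScaledParameters(K_T=K_T, K_P=K_P)
        t_hi = 0.95 / K_T if K_T else 3.0
        tg = np.linspace(0.02, t_hi, 200)
        num = nullcline_thyroid(tg, s)
        clo = nullcline_thyroid(tg, s, method="closed")
        assert np.max(np.abs(num.p_values / clo.p_values - 1)) < 1e-8
        p_hi = 0.95 / K_P if K_P else 3.0
        pg = np.linspace(0.02, p_hi, 200)
        num = nullcline_pituitary(pg, s)
        clo = nullcline_pituitary(pg, s, method="closed")
        assert np.max(np.abs(num.t_values / clo.t_values - 1)) < 1e-8

    def test_domain_errors(self):
        s = ScaledParameters(K_T=0.5, K_P=0.5)
        with pytest.raises(DomainError):
            nullcline_thyroid([2.5], s)  # beyond 1/K_T
        with pytest.raises(DomainError):
            nullcline_pituitary([0.0], s)  # trivial branch excluded
        with pytest.raises(DomainError):
            nullcline_thyroid([1.0], ScaledParameters(AB=0.5), method="closed")


class TestFixedPoints:
    def test_unperturbed_unique_stable_interior(self):
        fps = fixed_points(ScaledParameters())
        assert len(fps) == 1
        fp = fps[0]
        assert fp.branch == "interior" and fp.stable
        assert (fp.state.t_mass, fp.state.p_mass) == (pytest.approx(1.0),
                                                      pytest.approx(1.0))

    def test_above_threshold_p_zero_branch_is_stable(self):
        s = ScaledParameters(K_T=0.5, AB=2.0)  # threshold 1 + K_T = 1.5
        fps = fixed_points(s)
        branches = {f.branch: f for f in fps}
        assert "p_zero" in branches and branches["p_zero"].stable
        assert not any(f.branch == "interior" and f.stable for f in fps)

    def test_below_threshold_interior_stable_boundary_unstable(self):
        s = ScaledParameters(K_T=0.5, AB=1.2)
        branches = {f.branch: f for f in fixed_points(s)}
        assert branches["interior"].stable
        assert not branches["p_zero"].stable

    def test_transcritical_p_star_vanishes_linearly(self):
        """With K_P = 0 the interior thyrotroph mass is P* = 1 + K_T - AB,
        reaching zero continuously at the threshold."""
        K_T = 0.5
        for ab in (1.1, 1.3, 1.45):
            fps = fixed_points(ScaledParameters(K_T=K_T, AB=ab))
            interior = [f for f in fps if f.branch == "interior"][0]
            assert interior.state.p_mass == pytest.approx(1 + K_T - ab, rel=1e-6)
        assert transcritical_ab(ScaledParameters(K_T=K_T)) == 1.5

    def test_stability_matches_full_5d_jacobian(self, default_params):
        """Timescale separation: the slow 2-D classification agrees with the
        eigenvalues of the full 5-D system at the same point."""
        from thyraxis.hpt_model import jacobian
        p = default_parameters(k_t=0.4)
        fps = fixed_points(scale_parameters(p))
        interior = [f for f in fps if f.branch == "interior"][0]
        assert interior.stable
        eig = np.linalg.eigvals(jacobian(set_point_state(p), p))
        assert np.max(eig.real) < 0


class TestGravesThreshold:
    def test_capacity_free_threshold_is_set_point_tsh(self, default_params):
        assert graves_threshold(default_params) == pytest.approx(1.5)

    def test_scaled_threshold_is_one_plus_kt(self):
        p = default_parameters(k_t=0.5)
        thr = graves_threshold(p)
        assert thr * p.b_t / p.a_t == pytest.approx(
            1 + scale_parameters(p).K_T, rel=1e-12)

    def test_threshold_increases_with_capacity_term(self, default_params):
        # raising k_t at fixed rate constants (no recalibration) raises the
        # threshold through its positive k_t coefficient; recalibrating b_t
        # against the same set point would cancel the shift exactly
        thr = [graves_threshold(default_params.replace(k_t=k))
               for k in (0.0, 0.2, 0.4)]
        assert thr[0] < thr[1] < thr[2]


class TestTshT4Curve:
    def test_zero_at_and_beyond_crossing(self):
        p = default_parameters(k_p=0.2)
        cv = tsh_of_t4_curve(p)
        assert cv(cv.beta_inv) == 0.0
        assert cv(cv.beta_inv * 2) == 0.0
        assert cv(cv.beta_inv * 0.999) > 0.0  # continuous approach to zero

    def test_requires_pituitary_capacity(self, default_params):
        with pytest.raises(DomainError):
            tsh_of_t4_curve(default_params)

    def test_setpoint_form_matches_parameter_form(self):
        """alpha = TSH0*T40^2/(P0*k_p) equals A = bTRH*bTSH*u/(aTRH*aTSH*k_p)
        under the capacity-free steady-state substitution."""
        p = default_parameters(k_p=0.2)
        cv = tsh_of_t4_curve(p)
        fold = 1.0 / (p.k_p * 1.0)  # capacity in units of the healthy mass
        cv2 = curve_from_setpoint(1.5, 15.0, fold)
        assert cv.alpha == pytest.approx(cv2.alpha, rel=1e-12)
        assert cv.beta_inv == pytest.approx(15.0 / (1 - 0.2), rel=1e-12)

    def test_thyroid_side_sweeps_stay_on_curve(self):
        p = default_parameters(k_t=1 / 5.5, k_p=1 / 5.3)
        cv = tsh_of_t4_curve(p)
        tables = [sweep("a_t", [1, 2, 5, 15], p, relative=True),
                  sweep("ab", [0.0, 0.75, 1.8, 3.0], p, relative=False),
                  sweep("b_th", [1, 0.1, 0.04, 0.02], p, relative=True)]
        for tab in tables:
            for th, tsh in zip(tab["th"], tab["tsh"]):
                if tsh > 0:
                    assert curve_residual(cv, th, tsh) < 1e-6
                else:
                    assert cv(th) == 0.0  # clinical-hyper limb, TSH suppressed

    def test_pituitary_side_perturbations_leave_curve(self):
        p = default_parameters(k_t=1 / 5.5, k_p=1 / 5.3)
        cv = tsh_of_t4_curve(p)
        for name in ("u", "b_tsh"):
            tab = sweep(name, [2.0], p, relative=True)
            assert curve_residual(cv, tab["th"][0], tab["tsh"][0]) > 0.1
        # doubling u doubles the curve amplitude
        cv2 = tsh_of_t4_curve(p.replace(u=2 * p.u))
        assert cv2.alpha == pytest.approx(2 * cv.alpha)


class TestRegionsAndSweeps:
    def test_healthy_masses_are_euthyroid(self, default_params):
        assert classify_region(1.0, 1.0, default_params).composite == "euthyroid"

    def test_hashimoto_staging(self):
        p = default_parameters(k_t=1 / 5.5, k_p=1 / 5.3)
        tab = sweep("a_t", [1, 5, 15], p, relative=True)
        assert list(tab["region"]) == ["euthyroid", "subclinical-hypo",
                                       "clinical-hypo"]
        assert np.all(np.diff(tab["tsh"]) > 0)  # TSH non-decreasing in a_t
        assert np.all(np.diff(tab["th"]) < 0)

    def test_graves_p_zero_exactly_beyond_threshold(self):
        p = default_parameters(k_t=1 / 5.5, k_p=1 / 5.3)
        thr = graves_threshold(p)
        tab = sweep("ab", [0.5 * thr, 1.2 * thr], p, relative=False)
        assert tab["p_mass"][0] > 0 and tab["branch"][0] == "interior"
        assert tab["p_mass"][1] == 0.0 and tab["tsh"][1] == 0.0

    def test_identity_sweep_reproduces_set_point(self, default_params):
        tab = sweep("a_t", [1.0], default_params, relative=True)
        assert tab["th"][0] == pytest.approx(15.0, rel=1e-9)
        assert tab["tsh"][0] == pytest.approx(1.5, rel=1e-9)

    def test_steady_state_agrees_with_long_integration(self):
        """Root-found steady states coincide with the simulator's attractor."""
        p = default_parameters(k_t=1 / 5.5, k_p=1 / 5.3).replace(
            a_t=5 / 30)
        ss = steady_state(p)
        traj = integrate(set_point_state(p), p, EventSchedule([], 3000.0),
                         dt_out=5.0)
        term = traj.terminal_state().as_array()
        assert np.max(np.abs(ss.state.as_array() / term - 1)) < 1e-5
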