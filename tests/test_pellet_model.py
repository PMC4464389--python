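"""Steady and transient pellet solvers against analytic oracles."""

import math

import numpy as np
import pytest

from pelletox import (
    DETECTION_LIMIT_MG_L,
    MMKinetics,
    PelletGeometry,
    analytic_reference,
    solve_pellet_profile,
    transient_no_reaction,
)
from pelletox.pellet_model import zero_order_core_radius

from conftest import make_modulus_scenario


class TestGeometry:
    def test_derived_quantities(self):
        g = PelletGeometry(1400.0)
        assert g.radius == 700.0
        assert g.area == pytest.approx(math.pi * 1400.0**2)
        assert g.volume == pytest.approx(math.pi * 1400.0**3 / 6)
        assert g.specific_area == pytest.approx(6.0 / 1400.0)
        assert g.specific_area == pytest.approx(g.area / g.volume)

    @pytest.mark.parametrize("bad", [0.0, -100.0])
    def test_rejects_nonpositive_diameter(self, bad):
        with pytest.raises(ValueError):
            PelletGeometry(bad)


class TestKinetics:
    def test_rate_shape(self, kin_default):
        c = np.linspace(0, 20, 50)
        r = kin_default.rate(c)
        assert (r >= 0).all() and (r <= kin_default.r_max).all()
        assert (np.diff(r) >= 0).all()
        assert kin_default.rate(kin_default.K_M) == pytest.approx(kin_default.r_max / 2)

    def test_validation(self):
        with pytest.raises(ValueError):
            MMKinetics(-1.0, 0.11)
        with pytest.raises(ValueError):
            MMKinetics(0.026, 0.0)


class TestSteadySolvers:
    def test_no_uptake_gives_uniform_field(self, geom_small, kin_default):
        sol = solve_pellet_profile(geom_small, MMKinetics(0.0, 0.11), 1000.0, 7.0)
        assert np.allclose(sol.c, 7.0)
        assert sol.r_obs == 0.0
        assert sol.r_anox == 0.0

    def test_input_validation(self, geom_small, kin_default):
        with pytest.raises(ValueError):
            solve_pellet_profile(geom_small, kin_default, -5.0, 7.0)
        with pytest.raises(ValueError):
            solve_pellet_profile(geom_small, kin_default, 1000.0, -1.0)
        with pytest.raises(ValueError):
            solve_pellet_profile(geom_small, kin_default, 1000.0, 7.0, method="spectral")

    def test_pseudo_first_order_center_value(self):
        # K_M = 110 mg/l >> c: uptake is nearly first order with
        # k1 = r_max/K_M; the center-to-surface ratio approaches
        # phi/sinh(phi).  The saturable correction at c/K_M ~ 6% leaves a
        # ~2e-3 relative gap, which vanishes in the stricter limit below.
        g = PelletGeometry(2000.0)
        sol = solve_pellet_profile(g, MMKinetics(0.026, 110.0), 1000.0, 7.0)
        phi = 1000.0 * math.sqrt(0.026 / 110.0 / 1000.0)
        assert phi == pytest.approx(0.486, abs=5e-4)
        assert sol.c_center / 7.0 == pytest.approx(phi / math.sinh(phi), rel=3e-3)

    def test_first_order_limit_matches_analytic_field(self):
        g = PelletGeometry(2000.0)
        c_s = 7.0
        kin = MMKinetics(0.026, 1e3 * c_s)
        sol = solve_pellet_profile(g, kin, 1000.0, c_s)
        ref = analytic_reference("first", g, 1000.0, c_s, kin.r_max / kin.K_M)
        assert np.max(np.abs(sol.c - ref.c)) / c_s < 1e-4

    def test_zero_order_limit_matches_analytic_field(self):
        # sub-critical pellet, c >> K_M everywhere: genuine zero-order regime
        g = PelletGeometry(1400.0)
        c_s = 7.0
        kin = MMKinetics(0.026, 1e-3 * c_s)
        sol = solve_pellet_profile(g, kin, 1000.0, c_s)
        ref = analytic_reference("zero", g, 1000.0, c_s, kin.r_max)
        assert ref.c.min() > 500 * kin.K_M
        assert np.max(np.abs(sol.c - ref.c)) / c_s < 1e-3

    def test_zero_order_limit_with_anoxic_core(self):
        # With a core the saturable field passes through c ~ K_M, so the
        # agreement outside the core converges linearly in K_M.
        g = PelletGeometry(4000.0)
        c_s = 7.0
        ref = analytic_reference("zero", g, 1000.0, c_s, 0.026)
        outside = ref.c > 0.1 * c_s
        devs = []
        for scale in (1e-3, 1e-4):
            sol = solve_pellet_profile(g, MMKinetics(0.026, scale * c_s), 1000.0, c_s)
            devs.append(np.max(np.abs(sol.c - ref.c)[outside]) / c_s)
        assert devs[0] < 5e-3
        assert devs[1] < 1e-3
        assert devs[1] < 0.2 * devs[0]

    def test_shooting_and_finite_difference_agree(self, kin_default):
        geom = PelletGeometry(1400.0)
        a = solve_pellet_profile(geom, kin_default, 985.0, 7.0, "shooting")
        b = solve_pellet_profile(geom, kin_default, 985.0, 7.0, "finite_difference")
        assert np.max(np.abs(a.c - b.c)) < 1e-3

    def test_oracle_equivalence_random_scenarios(self):
        rng = np.random.default_rng(2024)
        for _ in range(6):
            geom, kin, d_eff, c_s, _ = make_modulus_scenario(rng)
            a = solve_pellet_profile(geom, kin, d_eff, c_s, "shooting")
            b = solve_pellet_profile(geom, kin, d_eff, c_s, "finite_difference")
            assert np.max(np.abs(a.c - b.c)) < 1e-3

    @pytest.mark.parametrize("method", ["shooting", "finite_difference"])
    def test_conservation_and_monotonicity(self, kin_default, method):
        rng = np.random.default_rng(7)
        for _ in range(4):
            geom, kin, d_eff, c_s, _ = make_modulus_scenario(rng, phi_m_range=(0.1, 10.0))
            sol = solve_pellet_profile(geom, kin, d_eff, c_s, method)
            supply = sol.flux_surface * geom.specific_area
            assert supply == pytest.approx(sol.r_obs, rel=5e-3)
            assert (np.diff(sol.c) >= -1e-9).all()
            assert sol.c[-1] == pytest.approx(c_s, rel=1e-6)

    def test_higher_diffusivity_raises_field(self, geom_small, kin_default):
        lo = solve_pellet_profile(geom_small, kin_default, 600.0, 7.0)
        hi = solve_pellet_profile(geom_small, kin_default, 1200.0, 7.0)
        assert (hi.c[:-1] >= lo.c[:-1]).all()
        assert hi.c_center > lo.c_center

    def test_anoxic_core_reported(self):
        # strongly limited pellet: detectable-oxygen shell only
        g = PelletGeometry(6000.0)
        sol = solve_pellet_profile(g, MMKinetics(), 800.0, 5.0)
        assert sol.r_anox > 0
        assert sol.interpolate(sol.r_anox) == pytest.approx(DETECTION_LIMIT_MG_L, abs=2e-3)
        # concentration below the limit inside, above outside
        inside = sol.r < sol.r_anox - 1.0
        outside = sol.r > sol.r_anox + 1.0
        assert (sol.c[inside] <= DETECTION_LIMIT_MG_L + 1e-9).all()
        assert (sol.c[outside] >= DETECTION_LIMIT_MG_L - 1e-9).all()


class TestAnalyticReference:
    def test_invalid_order(self, geom_small):
        with pytest.raises(ValueError):
            analytic_reference("second", geom_small, 1000.0, 7.0, 0.01)

    def test_zero_order_subcritical_full_penetration(self):
        g = PelletGeometry(2000.0)
        # 6 D c_S / (k0 R^2) = 6*1000*7/(0.026*1e6) = 1.615 >= 1
        ref = analytic_reference("zero", g, 1000.0, 7.0, 0.026)
        assert ref.meta["rho"] == 0.0
        assert ref.meta["eta0"] == 1.0
        assert ref.c.min() > 0
        # parabolic: c_S - c(0) = k0 R^2 / (6 D)
        assert ref.c[-1] - ref.c[0] == pytest.approx(0.026 * 1e6 / 6000.0, rel=1e-12)

    def test_zero_order_core_radius_against_bisection(self):
        # independent bisection of 1 + 2 rho^3 - 3 rho^2 = m
        g = PelletGeometry(4000.0)
        m = 6.0 * 1000.0 * 7.0 / (0.026 * 2000.0**2)
        assert m == pytest.approx(0.40385, abs=1e-4)
        lo, hi = 0.0, 1.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if 1 + 2 * mid**3 - 3 * mid**2 > m:
                lo = mid
            else:
                hi = mid
        rho = zero_order_core_radius(g, 1000.0, 7.0, 0.026)
        assert rho == pytest.approx(0.5 * (lo + hi), abs=1e-10)
        assert rho == pytest.approx(0.565, abs=1e-3)

    def test_first_order_center_is_removable(self):
        g = PelletGeometry(2000.0)
        ref = analytic_reference("first", g, 1000.0, 7.0, 2.36e-4)
        phi = 1000.0 * math.sqrt(2.36e-4 / 1000.0)
        assert np.isfinite(ref.c).all()
        assert ref.c[0] == pytest.approx(7.0 * phi / math.sinh(phi), rel=1e-10)
        # series continuation near the centre is smooth
        assert abs(ref.c[1] - ref.c[0]) < 1e-4


class TestTransient:
    def test_initial_condition(self):
        g = PelletGeometry(2000.0)
        sol = transient_no_reaction(g, 1000.0, 7.0, 2.0, [0.0])[0]
        assert np.allclose(sol.c[:-1], 2.0)
        assert sol.c[-1] == 7.0

    def test_long_time_uniform(self):
        g = PelletGeometry(2000.0)
        t_inf = 20.0 * g.radius**2 / 1000.0
        sol = transient_no_reaction(g, 1000.0, 7.0, 0.0, [t_inf])[0]
        assert np.allclose(sol.c, 7.0, atol=1e-8)

    def test_center_value_at_fourier_0p1(self):
        # series oracle: 1 + 2 sum (-1)^n exp(-n^2 pi^2 Fo), Fo = 0.1
        g = PelletGeometry(2000.0)
        t = 0.1 * g.radius**2 / 1000.0
        sol = transient_no_reaction(g, 1000.0, 7.0, 0.0, [t])[0]
        expected = 1.0 + 2.0 * sum(
            (-1.0) ** n * math.exp(-(n**2) * math.pi**2 * 0.1) for n in range(1, 11)
        )
        assert expected == pytest.approx(0.293, abs=5e-4)
        assert sol.c[0] / 7.0 == pytest.approx(expected, abs=1e-6)

    def test_monotone_in_time(self):
        g = PelletGeometry(2000.0)
        times = [10.0, 100.0, 500.0, 2000.0]
        sols = transient_no_reaction(g, 1000.0, 7.0, 0.0, times)
        for earlier, later in zip(sols, sols[1:]):
            assert (later.c - earlier.c >= -1e-9).all()

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            transient_no_reaction(PelletGeometry(2000.0), 1000.0, 7.0, 0.0, [-1.0])
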