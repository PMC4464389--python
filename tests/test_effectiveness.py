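"""Moduli, effectiveness factors, regime bands and film transfer."""

import math

import numpy as np
import pytest

from pelletox import (
    MMKinetics,
    PelletGeometry,
    classify_regime,
    convert_oxygen_units,
    couple_film_pellet,
    exact_internal_effectiveness,
    external_transfer,
    internal_efficiency,
    solve_pellet_profile,
    thiele_modulus_mm,
    weisz_modulus,
)

from conftest import make_modulus_scenario


class TestUnitConversion:
    @pytest.mark.parametrize(
        "um, mg_l",
        [(0.3, 0.0096), (0.0, 0.0), (250.0, 8.0)],
    )
    def test_micromolar_to_mg_per_l(self, um, mg_l):
        assert convert_oxygen_units(um) == pytest.approx(mg_l, abs=1e-12)

    def test_detection_limit_presents_as_0p01(self):
        assert round(convert_oxygen_units(0.3), 2) == 0.01

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            convert_oxygen_units(-1.0)


class TestThieleModulus:
    def test_regression_value_small_pellet(self, geom_small, kin_default):
        # independent direct evaluation of the closed form at
        # R=700, kinetics (0.026, 0.11), D_eff=985, c_S=7
        R, r_max, K_M, D, cS = 700.0, 0.026, 0.11, 985.0, 7.0
        rate = r_max * cS / (cS + K_M)
        expected = (R / 3) * rate / math.sqrt(2 * D * r_max * (cS - K_M * math.log(1 + cS / K_M)))
        assert expected == pytest.approx(0.326304, abs=1e-6)
        assert thiele_modulus_mm(geom_small, kin_default, 985.0, 7.0) == pytest.approx(expected)

    def test_first_order_limit(self, geom_small):
        cS = 7.0
        kin = MMKinetics(0.026, 1e3 * cS)
        phi1 = (700.0 / 3) * math.sqrt(kin.r_max / (kin.K_M * 985.0))
        assert thiele_modulus_mm(geom_small, kin, 985.0, cS) == pytest.approx(phi1, rel=1e-3)

    def test_zero_order_limit_converges(self, geom_small):
        # approach is logarithmic in K_M/c_S (the K_M ln(1+c_S/K_M) term),
        # ~0.25% at K_M = 1e-3 c_S, below 0.1% only by K_M ~ 1e-5 c_S
        cS = 7.0
        phi0 = (700.0 / 3) * math.sqrt(0.026 / (2 * 985.0 * cS))
        errs = []
        for scale in (1e-3, 1e-5):
            kin = MMKinetics(0.026, scale * cS)
            errs.append(abs(thiele_modulus_mm(geom_small, kin, 985.0, cS) - phi0) / phi0)
        assert errs[0] < 5e-3
        assert errs[1] < 1e-3

    def test_zero_surface_concentration_rejected(self, geom_small, kin_default):
        with pytest.raises(ValueError):
            thiele_modulus_mm(geom_small, kin_default, 985.0, 0.0)


class TestInternalEfficiency:
    def test_no_limitation_limit(self, kin_default):
        report = internal_efficiency(PelletGeometry(20.0), kin_default, 2000.0, 7.0)
        assert report.eta_zero == pytest.approx(1.0)
        assert report.eta_first == pytest.approx(1.0, abs=1e-3)
        assert report.eta_internal == pytest.approx(1.0, abs=1e-3)
        assert report.regime == "kinetic"

    def test_first_order_effectiveness_closed_form(self):
        from pelletox import eta_first_order

        assert eta_first_order(1.0) == pytest.approx(1 / math.tanh(3) - 1 / 3, rel=1e-12)
        assert eta_first_order(1.0) == pytest.approx(0.6716, abs=1e-4)
        assert eta_first_order(1e-7) == pytest.approx(1.0)
        # 1/phi asymptote
        assert eta_first_order(50.0) == pytest.approx(1 / 50.0 - 1 / (3 * 50.0**2), rel=1e-6)

    def test_zero_order_effectiveness_curve(self):
        from pelletox import eta_zero_order

        # full penetration up to the critical modulus 1/sqrt(3)
        assert eta_zero_order(0.5) == 1.0
        assert eta_zero_order(1 / math.sqrt(3) - 1e-9) == 1.0
        # beyond it, an anoxic core develops and eta -> 1/phi
        assert eta_zero_order(0.7) < 1.0
        assert eta_zero_order(50.0) == pytest.approx(1 / 50.0, rel=0.02)

    def test_beta_endpoints(self, geom_small):
        # beta -> 0 (c_S >> K_M): eta_im -> eta_i0
        rep = internal_efficiency(geom_small, MMKinetics(0.026, 1e-6), 985.0, 7.0)
        assert rep.eta_internal == pytest.approx(rep.eta_zero, rel=1e-4)
        # beta -> inf (K_M >> c_S): eta_im -> eta_i1
        rep = internal_efficiency(geom_small, MMKinetics(0.026, 1e5), 985.0, 7.0)
        assert rep.eta_internal == pytest.approx(rep.eta_first, rel=1e-4)

    def test_eta_im_between_order_limits_and_in_unit_interval(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            geom, kin, d_eff, c_s, _ = make_modulus_scenario(rng, beta_range=(0.01, 100.0))
            rep = internal_efficiency(geom, kin, d_eff, c_s)
            assert 0 < rep.eta_zero <= 1 and 0 < rep.eta_first <= 1
            assert 0 < rep.eta_internal <= 1
            lo, hi = sorted((rep.eta_zero, rep.eta_first))
            assert lo - 1e-12 <= rep.eta_internal <= hi + 1e-12

    def test_interpolation_tracks_exact_effectiveness(self):
        # Eq-4-style interpolation vs the numeric volume-average ratio
        rng = np.random.default_rng(5)
        for _ in range(8):
            geom, kin, d_eff, c_s, _ = make_modulus_scenario(
                rng, phi_m_range=(0.1, 10.0), beta_range=(0.01, 100.0)
            )
            sol = solve_pellet_profile(geom, kin, d_eff, c_s, "finite_difference")
            eta_exact = exact_internal_effectiveness(sol)
            rep = internal_efficiency(geom, kin, d_eff, c_s)
            assert rep.eta_internal == pytest.approx(eta_exact, rel=0.15)


class TestWeiszModulus:
    def test_beta_identity_certifies_weight(self):
        # (1+b)[1 + b ln(b/(1+b))] == (K+c)(c - K ln(1+c/K))/c^2 with
        # b = K/c; both sides evaluated directly, within the range where
        # double precision keeps the cancellation benign.
        rng = np.random.default_rng(99)
        worst = 0.0
        for _ in range(1000):
            beta = math.exp(rng.uniform(math.log(1e-2), math.log(30.0)))
            c = math.exp(rng.uniform(math.log(0.1), math.log(10.0)))
            K = beta * c
            lhs = (1 + beta) * (1 + beta * math.log(beta / (1 + beta)))
            rhs = (K + c) * (c - K * math.log1p(c / K)) / c**2
            worst = max(worst, abs(lhs - rhs) / abs(rhs))
        assert worst < 1e-12

    def test_large_beta_limit(self):
        # bracket -> 1/(2 beta), so Phi -> phi_m^2 * eta
        phi_m, eta = 1.7, 0.6
        val = weisz_modulus(phi_m, eta, 1e8)
        assert val == pytest.approx(phi_m**2 * eta, rel=1e-6)

    def test_matches_observable_form_from_numeric_solution(self):
        rng = np.random.default_rng(3)
        for _ in range(6):
            geom, kin, d_eff, c_s, _ = make_modulus_scenario(rng, phi_m_range=(0.1, 10.0))
            sol = solve_pellet_profile(geom, kin, d_eff, c_s, "finite_difference")
            eta = exact_internal_effectiveness(sol)
            phi_m = thiele_modulus_mm(geom, kin, d_eff, c_s)
            observable = (geom.radius / 3) ** 2 * sol.r_obs / (d_eff * c_s)
            assert weisz_modulus(phi_m, eta, kin.K_M / c_s) == pytest.approx(observable, rel=0.02)

    def test_invalid_beta(self):
        with pytest.raises(ValueError):
            weisz_modulus(1.0, 0.5, 0.0)
        with pytest.raises(ValueError):
            weisz_modulus(float("nan"), 0.5, 1.0)


class TestRegimeClassification:
    @pytest.mark.parametrize(
        "phi, label",
        [
            (0.1, "kinetic"),
            (0.299999, "kinetic"),
            (0.3, "intermediate"),
            (1.0, "intermediate"),
            (3.0, "intermediate"),
            (3.000001, "diffusion_limited"),
            (5.0, "diffusion_limited"),
        ],
    )
    def test_band_edges(self, phi, label):
        assert classify_regime(phi) == label

    def test_totality_on_positive_axis(self):
        rng = np.random.default_rng(1)
        values = 10 ** rng.uniform(-4, 4, size=500)
        labels = {classify_regime(v) for v in values}
        assert labels <= {"kinetic", "intermediate", "diffusion_limited"}
        for v in values:
            assert classify_regime(v) in labels

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            classify_regime(float("inf"))
        with pytest.raises(ValueError):
            classify_regime(-0.1)


class TestExternalTransfer:
    def test_no_gradient_gives_unit_efficiency(self, geom_small):
        rep = external_transfer(geom_small, 7.0, 7.0, 0.11)
        assert rep.eta_external == pytest.approx(1.0)

    def test_quiescent_film_arithmetic(self):
        rep = external_transfer(PelletGeometry(1400.0), 7.0, 3.5, 0.11)
        assert rep.k_S == pytest.approx(4.0)            # 2 * 2800 / 1400 um/s
        assert rep.a == pytest.approx(6.0 / 1400.0)
        assert rep.kSa == pytest.approx(0.01714, abs=1e-5)
        assert rep.eta_external == pytest.approx(3.5 * 7.11 / (7.0 * 3.61), rel=1e-12)
        assert rep.eta_external == pytest.approx(0.985, abs=1e-3)

    def test_monotone_in_surface_concentration(self, geom_small):
        etas = [
            external_transfer(geom_small, 7.0, cs, 0.11).eta_external
            for cs in np.linspace(0.0, 7.0, 15)
        ]
        assert (np.diff(etas) > 0).all()
        assert etas[-1] == pytest.approx(1.0)

    def test_zero_bulk_rejected(self, geom_small):
        with pytest.raises(ValueError):
            external_transfer(geom_small, 0.0, 0.0, 0.11)


class TestFilmPelletCoupling:
    def test_no_uptake_means_no_gradient(self, kin_default):
        c_s, sol, rep = couple_film_pellet(
            PelletGeometry(2000.0), MMKinetics(0.0, 0.11), 900.0, 7.0
        )
        assert c_s == 7.0
        assert rep.eta_external == pytest.approx(1.0)

    def test_flux_balance_closes(self, kin_default):
        geom = PelletGeometry(2000.0)
        c_s, sol, rep = couple_film_pellet(geom, kin_default, 900.0, 7.0)
        k_S = 2.0 * 2800.0 / 2000.0
        film = k_S * (7.0 - c_s)
        assert 0.0 < c_s < 7.0
        assert sol.flux_surface == pytest.approx(film, rel=5e-3)

    def test_slower_internal_diffusion_relaxes_the_film(self, kin_default):
        # lower D_eff shrinks the oxygen-reached volume, hence the uptake
        # flux the film must deliver, so c_S rises monotonically toward c_B
        geom = PelletGeometry(2000.0)
        cs = [
            couple_film_pellet(geom, kin_default, d, 7.0)[0]
            for d in (2000.0, 900.0, 400.0, 150.0)
        ]
        assert (np.diff(cs) > 0).all()
        assert cs[-1] < 7.0

    def test_stronger_uptake_lowers_surface(self):
        geom = PelletGeometry(2000.0)
        cs = [
            couple_film_pellet(geom, MMKinetics(r, 0.11), 900.0, 7.0)[0]
            for r in (0.005, 0.026, 0.1)
        ]
        assert (np.diff(cs) < 0).all()
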