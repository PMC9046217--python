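"""Tunneling corrections: analytic Eckart/Bell/Wigner against independent
numeric oracles, limits, and monotonicity properties."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from oracles import kappa_kemble_numeric, kappa_numerov, numerov_transmission
from radtunnel.constants import HC_OVER_KB, R_KCAL
from radtunnel.tunneling import (
    BarrierSpec,
    eckart_transmission,
    effective_barrier,
    invert_frequency,
    kappa_bell,
    kappa_eckart,
    kappa_wigner,
    kie,
    reduction_percent,
)

THIH = dict(V=20.0, V_eff=9.6, T=333.15)
NOSL = dict(V=18.3, V_eff=10.7, T=298.15)


def spec_sym(V=20.0, nu=2800.0, T=333.15):
    return BarrierSpec.symmetric(V, nu, T)


class TestEckartTransmission:
    def test_zero_energy_gives_zero_flux(self):
        assert eckart_transmission(0.0, spec_sym()) == 0.0

    def test_classical_limit_is_unity(self):
        s = spec_sym()
        e_high = s.V_forward + 50.0 * s.kT
        assert eckart_transmission(e_high, s) == pytest.approx(1.0, abs=1e-6)

    def test_matches_numerov_at_symmetric_barrier(self):
        s = spec_sym()
        t = eckart_transmission(10.0, s)
        ref = numerov_transmission(10.0, 20.0, 20.0, 2800.0)
        assert t == pytest.approx(ref, rel=0.01)

    def test_matches_numerov_over_random_specs(self, rng):
        """Analytic transmission equals the 1-D Schrodinger (Numerov)
        solution within 1% at 20 random (E, spec) points with u in [2, 20]."""
        checked = 0
        while checked < 20:
            vf = rng.uniform(5, 25)
            vr = vf if rng.random() < 0.5 else rng.uniform(3, vf)
            nu = rng.uniform(1000, 3500)
            T = rng.uniform(280, 360)
            s = BarrierSpec(vf, vr, nu, T)
            if not 2.0 <= s.u <= 20.0:
                continue
            E = rng.uniform(max(0.0, vf - vr) + 0.3, 2.0 * vf)
            ref = numerov_transmission(E, vf, vr, nu)
            assert eckart_transmission(E, s) == pytest.approx(ref, rel=0.01, abs=1e-12)
            checked += 1

    def test_rejects_negative_or_nonfinite_energy(self):
        with pytest.raises(ValueError):
            eckart_transmission(-1.0, spec_sym())
        with pytest.raises(ValueError):
            eckart_transmission(float("nan"), spec_sym())

    def test_below_product_asymptote_is_closed_channel(self):
        s = BarrierSpec(20.0, 10.0, 2500.0, 300.0)
        assert eckart_transmission(5.0, s) == 0.0

    @given(
        vf=st.floats(3.0, 30.0),
        ratio=st.floats(0.3, 1.0),
        nu=st.floats(200.0, 4000.0),
        escale=st.floats(0.01, 3.0),
    )
    def test_transmission_bounded_and_monotone(self, vf, ratio, nu, escale):
        """T(E) stays in [0, 1] and never decreases with E."""
        s = BarrierSpec(vf, vf * ratio, nu, 300.0)
        e1 = escale * vf
        e2 = e1 * 1.3 + 0.1
        t1 = eckart_transmission(e1, s)
        t2 = eckart_transmission(e2, s)
        assert 0.0 <= t1 <= 1.0 and 0.0 <= t2 <= 1.0
        assert t2 >= t1 - 1e-12

    def test_no_overflow_at_extreme_barrier(self):
        s = BarrierSpec.symmetric(150.0, 300.0, 300.0)
        t = eckart_transmission(1.0, s)
        assert math.isfinite(t) and 0.0 <= t <= 1.0


class TestKappaEckart:
    def test_classical_limit(self):
        assert kappa_eckart(spec_sym(nu=0.01, T=300.0)).kappa == pytest.approx(1.0, abs=1e-4)

    def test_small_u_matches_wigner(self):
        k = kappa_eckart(spec_sym(nu=200.0, T=300.0)).kappa
        w = kappa_wigner(200.0, 300.0).kappa
        assert k == pytest.approx(w, rel=0.015)

    def test_deep_tunneling_matches_numeric_oracle(self):
        k = kappa_eckart(spec_sym()).kappa
        ref = kappa_numerov(20.0, 20.0, 2800.0, 333.15)
        assert k == pytest.approx(ref, rel=0.02)

    def test_refuses_outside_validated_domain(self):
        with pytest.raises(ValueError, match="deep-tunneling"):
            kappa_eckart(spec_sym(nu=20000.0, T=300.0))

    def test_kappa_increases_with_frequency(self):
        ks = [kappa_eckart(spec_sym(nu=nu)).kappa for nu in (800.0, 1600.0, 2400.0, 3200.0)]
        assert all(a < b for a, b in zip(ks, ks[1:]))
        effs = [kappa_eckart(spec_sym(nu=nu)).effective_barrier
                for nu in (800.0, 1600.0, 2400.0, 3200.0)]
        assert all(a > b for a, b in zip(effs, effs[1:]))


class TestKappaBell:
    def test_small_u_limit(self):
        assert kappa_bell(20.0, 1.0, 300.0).kappa == pytest.approx(1.0, abs=1e-4)

    def test_u_pi_closed_form(self):
        nu = math.pi * 300.0 / HC_OVER_KB  # u = pi exactly
        k = kappa_bell(20.0, nu, 300.0)    # alpha = 33.5 >= 30
        assert k.kappa == pytest.approx(math.pi / 2.0, abs=1e-3)

    def test_deep_tunneling_matches_kemble_integral(self):
        k = kappa_bell(20.0, 2800.0, 333.15).kappa
        ref = kappa_kemble_numeric(20.0, 2800.0, 333.15)
        assert k == pytest.approx(ref, rel=0.005)

    @pytest.mark.parametrize("u", [0.5, 2.0, 4.0, 2 * math.pi - 0.2, 2 * math.pi + 0.2,
                                   9.0, 12.0, 16.0])
    def test_series_matches_numeric_across_u(self, u):
        """Bell series equals numerical Kemble Boltzmann integration within
        0.5% away from the poles, alpha >= 10."""
        T = 300.0
        nu = u * T / HC_OVER_KB
        V = max(12.0 * R_KCAL * T, 8.0)
        assert kappa_bell(V, nu, T).kappa == pytest.approx(
            kappa_kemble_numeric(V, nu, T), rel=0.005)

    def test_pole_fallback_flagged_and_accurate(self):
        T = 300.0
        nu = (2.0 * math.pi + 0.03) * T / HC_OVER_KB
        k = kappa_bell(15.0, nu, T)
        assert k.warnings and "pole" in k.warnings[0]
        assert k.kappa == pytest.approx(kappa_kemble_numeric(15.0, nu, T), rel=0.005)


class TestWigner:
    def test_limits_and_closed_form(self):
        assert kappa_wigner(1e-9, 300.0).kappa == pytest.approx(1.0, abs=1e-12)
        u1_nu = 300.0 / HC_OVER_KB
        assert kappa_wigner(u1_nu, 300.0).kappa == pytest.approx(1.0 + 1.0 / 24.0, rel=1e-12)
        k = kappa_wigner(2000.0, 333.15).kappa
        assert k == pytest.approx(1.0 + (HC_OVER_KB * 2000.0 / 333.15) ** 2 / 24.0, rel=1e-12)

    def test_small_u_convergence_of_all_models(self):
        """Eckart and Bell both approach 1 + u^2/24 within 2% for u <= 0.5."""
        for u in (0.2, 0.35, 0.5):
            T = 300.0
            nu = u * T / HC_OVER_KB
            w = 1.0 + u * u / 24.0
            assert kappa_eckart(spec_sym(nu=nu, T=T)).kappa == pytest.approx(w, rel=0.02)
            assert kappa_bell(20.0, nu, T).kappa == pytest.approx(w, rel=0.02)


class TestEffectiveBarrierAndInversion:
    def test_identity_at_unit_kappa(self):
        assert effective_barrier(spec_sym(), 1.0) == 20.0

    def test_analytic_log_case(self):
        eff = effective_barrier(spec_sym(T=333.15), math.exp(10.0))
        assert eff == pytest.approx(20.0 - 10.0 * R_KCAL * 333.15, rel=1e-12)

    def test_rejects_nonpositive_kappa(self):
        with pytest.raises(ValueError):
            effective_barrier(spec_sym(), 0.0)

    def test_no_tunneling_required_edge(self):
        nu, warnings = invert_frequency(20.0, 20.0, 333.15)
        assert nu == 50.0 and "no tunneling required" in warnings[0]

    def test_rejects_effective_above_forward(self):
        with pytest.raises(ValueError):
            invert_frequency(20.0, 21.0, 333.15)

    def test_thih_inversion_exceeds_2000(self):
        nu, _ = invert_frequency(THIH["V"], THIH["V_eff"], THIH["T"])
        assert nu >= 2000.0

    @pytest.mark.parametrize("model", ["eckart-symmetric", "bell"])
    def test_round_trip_recovers_frequency(self, model):
        """invert o forward is the identity on nu within 1 cm^-1."""
        nu_true = 2500.0
        T = 333.15
        if model == "bell":
            kap = kappa_bell(20.0, nu_true, T).kappa
        else:
            kap = kappa_eckart(spec_sym(nu=nu_true, T=T)).kappa
        v_eff = effective_barrier(spec_sym(nu=nu_true, T=T), kap)
        nu_back, _ = invert_frequency(20.0, v_eff, T, model=model)
        assert nu_back == pytest.approx(nu_true, abs=1.0)

    def test_round_trip_effective_barrier(self):
        """Feeding the inverted frequency back reproduces the effective
        barrier that defined it."""
        nu, _ = invert_frequency(THIH["V"], THIH["V_eff"], THIH["T"])
        k = kappa_eckart(spec_sym(V=THIH["V"], nu=nu, T=THIH["T"]))
        assert k.effective_barrier == pytest.approx(THIH["V_eff"], abs=0.05)

    @pytest.mark.parametrize("nu_true", [500.0, 1500.0, 3000.0, 4000.0])
    def test_round_trip_across_frequency_range(self, nu_true):
        T = 320.0
        kap = kappa_eckart(spec_sym(nu=nu_true, T=T)).kappa
        v_eff = effective_barrier(spec_sym(nu=nu_true, T=T), kap)
        nu_back, _ = invert_frequency(20.0, v_eff, T)
        assert nu_back == pytest.approx(nu_true, abs=1.0)


class TestKIE:
    def test_classical_limit_is_unity(self):
        assert kie(spec_sym(nu=5.0, T=300.0)) == pytest.approx(1.0, abs=1e-4)

    def test_wigner_closed_form(self):
        T = 300.0
        nu = T / HC_OVER_KB  # u_H = 1; mass ratio 2 halves u^2
        r = kie(BarrierSpec.symmetric(20.0, nu, T, mass=1.0), heavy_mass=2.0, model="wigner")
        assert r == pytest.approx((1.0 + 1.0 / 24.0) / (1.0 + 0.5 / 24.0), rel=1e-9)

    def test_matches_numeric_oracle(self):
        s = spec_sym()
        nu_d = s.nu_imag * math.sqrt(s.mass / 2.0141)
        ref = kappa_numerov(20.0, 20.0, s.nu_imag, s.T) / \
            kappa_numerov(20.0, 20.0, nu_d, s.T, mass_amu=2.0141)
        assert kie(s) == pytest.approx(ref, rel=0.05)
        assert kie(s) >= 1.0

    def test_rejects_lighter_heavy_mass(self):
        with pytest.raises(ValueError):
            kie(spec_sym(), heavy_mass=0.5)


def test_reduction_percent_matches_barrier_pairs():
    assert reduction_percent(20.0, 9.6) == pytest.approx(52.0, abs=1e-9)
    assert reduction_percent(18.3, 10.7) == pytest.approx(41.53, abs=0.01)
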