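"""Tensioned thin-plate waveguide: rigidities, branch roots, limits."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import quartic_roots_oracle
from elastowave import (
    ParameterDomainError,
    PlateSpec,
    dispersion_curve,
    effective_rigidity,
    flexural_rigidities,
    phase_speed,
    wavenumber_branches,
)


class TestFlexuralRigidities:
    def test_cornea_value(self, cornea_plate):
        D, _ = flexural_rigidities(cornea_plate)
        assert D == pytest.approx(1.1985e-6, rel=1e-3)
        assert round(D * 1e6, 1) == 1.2  # the printed 1.2e-6 N*m

    def test_cubic_thickness_scaling(self, cornea_plate):
        D1, _ = flexural_rigidities(cornea_plate)
        D2, _ = flexural_rigidities(replace(cornea_plate, h=2 * cornea_plate.h))
        assert D2 / D1 == pytest.approx(8.0)

    def test_zero_poisson_twisting(self):
        spec = PlateSpec(h=1e-3, rho=1000.0, E_perp=1e4, nu_xy=0.0, mu_perp=5e3)
        D, Dxy = flexural_rigidities(spec)
        assert Dxy == pytest.approx(5e3 * 1e-9 / 12.0)
        assert D == pytest.approx(1e4 * 1e-9 / 12.0)

    def test_lossy_rigidity_sign(self, cornea_plate):
        D, Dxy = flexural_rigidities(replace(cornea_plate, loss_factor=0.15))
        assert D.imag < 0 and Dxy.imag < 0
        assert abs(D.imag) / D.real == pytest.approx(0.15)

    def test_poisson_bound(self):
        with pytest.raises(ParameterDomainError):
            PlateSpec(h=1e-3, rho=1000.0, E_perp=1e4, nu_xy=0.5, mu_perp=5e3)


class TestEffectiveRigidity:
    def test_heading_cases(self):
        D, Dxy = 2.0, 0.8
        assert effective_rigidity(D, Dxy, 0.0) == pytest.approx(D)
        assert effective_rigidity(D, Dxy, math.pi / 2) == pytest.approx(D)
        assert effective_rigidity(D, Dxy, math.pi / 4) == pytest.approx((D + Dxy) / 2)

    def test_isotropic_plate_heading_independent(self):
        for psi in np.linspace(0, math.pi, 7):
            assert effective_rigidity(3.0, 3.0, psi) == pytest.approx(3.0)


class TestWavenumberBranches:
    def test_cornea_zero_tension(self, cornea_plate):
        br = wavenumber_branches(cornea_plate, 2 * math.pi * 1000.0)
        assert br.alpha == pytest.approx(2108.5, rel=1e-3)
        assert br.beta == pytest.approx(br.alpha, rel=1e-12)  # xi = 0

    def test_cornea_with_tension(self, cornea_plate):
        spec = replace(cornea_plate, sigma=20e3)
        br = wavenumber_branches(spec, 2 * math.pi * 1000.0)
        assert br.alpha == pytest.approx(1299.6, rel=1e-3)
        # branch identities pin beta given alpha
        D, _ = flexural_rigidities(spec)
        assert br.beta**2 - br.alpha**2 == pytest.approx(
            spec.sigma * spec.h / D, rel=1e-10
        )

    def test_roots_property(self, cornea_plate):
        br = wavenumber_branches(cornea_plate, 100.0)
        roots = br.roots
        assert roots[0] == -roots[1]
        assert roots[2] == pytest.approx(1j * br.beta)

    def test_rejects_nonpositive_omega(self, cornea_plate):
        with pytest.raises(ParameterDomainError):
            wavenumber_branches(cornea_plate, 0.0)

    @settings(max_examples=200, derandomize=True)
    @given(
        h=st.floats(1e-4, 5e-3),
        E=st.floats(1e3, 1e6),
        nu=st.floats(0.0, 0.4999),
        sigma=st.floats(-5e3, 1e5),
        f=st.floats(10.0, 1e4),
    )
    def test_branch_identities_random(self, h, E, nu, sigma, f):
        spec = PlateSpec(h=h, rho=1000.0, E_perp=E, nu_xy=nu, mu_perp=E / 3)
        spec = replace(spec, sigma=sigma)
        omega = 2 * math.pi * f
        br = wavenumber_branches(spec, omega)
        D, _ = flexural_rigidities(spec)
        # identity difference cannot beat machine precision of the root
        # magnitudes themselves, hence the eps-scaled absolute floor
        floor = 1e-12 * (br.alpha**2 + br.beta**2)
        assert br.beta**2 - br.alpha**2 == pytest.approx(
            sigma * h / D, rel=1e-10, abs=floor
        )
        assert br.alpha**2 * br.beta**2 == pytest.approx(
            omega**2 * 1000.0 * h / D, rel=1e-10
        )

    @settings(max_examples=100, derandomize=True)
    @given(
        h=st.floats(1e-4, 5e-3),
        E=st.floats(1e3, 1e6),
        sigma=st.floats(0.0, 1e5),
        f=st.floats(10.0, 1e4),
    )
    def test_matches_generic_quartic_solver(self, h, E, sigma, f):
        spec = PlateSpec(h=h, rho=1000.0, E_perp=E, nu_xy=0.499, mu_perp=E / 3,
                         sigma=sigma)
        omega = 2 * math.pi * f
        br = wavenumber_branches(spec, omega)
        D, _ = flexural_rigidities(spec)
        a_ref, b_ref = quartic_roots_oracle(D, sigma * h, 1000.0 * h, omega)
        assert br.alpha == pytest.approx(a_ref, rel=1e-8)
        assert br.beta == pytest.approx(b_ref, rel=1e-8)

    def test_compression_keeps_real_roots(self, cornea_plate):
        br = wavenumber_branches(replace(cornea_plate, sigma=-2e3), 2 * math.pi * 500)
        assert isinstance(br.alpha, float) and br.alpha > 0
        assert isinstance(br.beta, float) and 0 < br.beta < br.alpha

    def test_lossy_roots_decay_and_continuity(self, cornea_plate):
        omega = 2 * math.pi * 1000.0
        br0 = wavenumber_branches(replace(cornea_plate, sigma=10e3), omega)
        brl = wavenumber_branches(
            replace(cornea_plate, sigma=10e3, loss_factor=0.1), omega
        )
        assert brl.alpha.real > 0 and brl.alpha.imag > 0  # spatial decay
        assert brl.beta.real > 0
        assert brl.alpha.real == pytest.approx(br0.alpha, rel=0.05)  # continuity


class TestPhaseSpeed:
    def test_cornea_reference_points(self, cornea_plate):
        c0, att0 = phase_speed(cornea_plate, 2 * math.pi * 1000.0)
        assert c0 == pytest.approx(2.980, rel=1e-3)
        assert att0 == 0.0
        c_mem, _ = phase_speed(replace(cornea_plate, sigma=20e3), 2 * math.pi * 100.0)
        assert c_mem == pytest.approx(4.475, rel=1.5e-3)
        assert c_mem == pytest.approx(math.sqrt(20e3 / 1000.0), rel=2e-3)
        c_hi, _ = phase_speed(replace(cornea_plate, sigma=20e3), 2 * math.pi * 1000.0)
        assert c_hi == pytest.approx(4.835, rel=1e-3)

    def test_membrane_limit(self, cornea_plate):
        # xi >= 100*omega/a: pick low frequency, high tension
        spec = replace(cornea_plate, sigma=20e3)
        D, _ = flexural_rigidities(spec)
        xi = spec.sigma * spec.h / (2 * D)
        a = math.sqrt(D / (spec.rho * spec.h))
        omega = xi * a / 100.0
        c, _ = phase_speed(spec, omega)
        assert c == pytest.approx(math.sqrt(spec.sigma / spec.rho), rel=1e-3)

    def test_classical_plate_limit(self, cornea_plate):
        spec = replace(cornea_plate, sigma=1.0)
        D, _ = flexural_rigidities(spec)
        xi = spec.sigma * spec.h / (2 * D)
        a = math.sqrt(D / (spec.rho * spec.h))
        omega = xi * a / 1e-4
        c, _ = phase_speed(spec, omega)
        assert c == pytest.approx(math.sqrt(omega) * (D / (spec.rho * spec.h)) ** 0.25,
                                  rel=1e-3)

    def test_monotone_in_tension_and_stiffness(self, cornea_plate):
        omega = 2 * math.pi * 800.0
        c_sig = [phase_speed(replace(cornea_plate, sigma=s), omega)[0]
                 for s in np.linspace(0, 20e3, 6)]
        assert np.all(np.diff(c_sig) > 0)
        c_E = [phase_speed(replace(cornea_plate, E_perp=E), omega)[0]
               for E in np.linspace(15e3, 75e3, 6)]
        assert np.all(np.diff(c_E) > 0)

    def test_neither_limit_is_the_bulk_speed(self, cornea_plate):
        # the waveguide point: plate speeds never equal the bulk shear formula
        mu_perp, phi, sigma = 10e3, 0.0, 10e3
        c_bulk = math.sqrt((mu_perp * (1 + phi) + sigma / 2) / 1000.0)
        spec = replace(cornea_plate, sigma=sigma)
        for f in (50.0, 500.0, 5000.0):
            c, _ = phase_speed(spec, 2 * math.pi * f)
            assert abs(c - c_bulk) / c_bulk > 0.05


class TestDispersionCurve:
    def test_single_point_equals_phase_speed(self, cornea_plate):
        curve = dispersion_curve(cornea_plate, [750.0])
        c, att = phase_speed(cornea_plate, 2 * math.pi * 750.0)
        assert curve.phase_speed[0] == pytest.approx(c, rel=1e-14)
        assert curve.attenuation[0] == att
        assert curve.metadata["model"] == "plate"

    def test_tension_ordering_of_wavenumber(self, cornea_plate_30k):
        f = np.linspace(200, 5000, 20)
        curves = [dispersion_curve(replace(cornea_plate_30k, sigma=s), f)
                  for s in (0.0, 5.56e3, 11.11e3, 16.67e3, 22.22e3)]
        ks = np.array([np.real(c.wavenumber) for c in curves])
        assert np.all(np.diff(ks, axis=0) < 0)  # k decreases with tension

    def test_stiffness_quarter_power_scaling(self, cornea_plate):
        f = np.array([500.0, 2000.0])
        base = dispersion_curve(replace(cornea_plate, sigma=0.0, E_perp=15e3), f)
        for E in (30e3, 60e3, 75e3):
            c = dispersion_curve(replace(cornea_plate, sigma=0.0, E_perp=E), f)
            np.testing.assert_allclose(
                c.phase_speed / base.phase_speed, (E / 15e3) ** 0.25, rtol=1e-10
            )

    def test_rejects_nonmonotone_grid(self, cornea_plate):
        with pytest.raises(Exception):
            dispersion_curve(cornea_plate, [100.0, 50.0])
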