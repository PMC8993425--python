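"""Transverse waves in a thin NITI plate under in-plane biaxial tension.

The plate lies in the x–y plane with the axis of isotropy along z and
thickness h much smaller than the shear wavelength; the in-plane biaxial
tension σ (σx = σy = σ, σz = 0) models, e.g., the hoop stress a
pressurized cornea carries.  Classical thin-plate kinematics with
rotational inertia neglected reduce transverse motion w(x, t) for a
planar wavefront to

    D w,xxxx + ρh w,tt = σh w,xx

whose harmonic solutions w = W e^{i(γx − ωt)} have the four wavenumber
roots γ = ±α, ±iβ handled by :mod:`elastowave._branches` with rigidity
D = E⊥h³/12(1−νxy²), tension resultant σh and line inertia ρh.  The
propagating phase speed c_ph = ω/Re(α) interpolates between the membrane
limit sqrt(σ/ρ) (σh ≫ 2D) and the classical plate limit
ω^(1/2)(D/ρh)^(1/4) (σh ≪ 2D); neither limit coincides with the bulk
shear speed of the same material, which is the waveguide point of the
model.

External load q is fixed to zero (free waves); no fluid loading or
elastic foundation.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np

from ._branches import WavenumberBranches, branch_roots
from .curves import DispersionCurve
from .errors import ParameterDomainError
from .materials import LOSS_IMAG_SIGN

__all__ = [
    "PlateSpec",
    "flexural_rigidities",
    "effective_rigidity",
    "wavenumber_branches",
    "phase_speed",
    "dispersion_curve",
]

# Poisson ratios at or above this diverge D; the nearly incompressible
# in-plane limit is represented by 0.499.
_NU_MAX = 0.4999


@dataclass(frozen=True)
class PlateSpec:
    """Thin tensioned plate.

    h : thickness, m.
    rho : density, kg/m³.
    E_perp : in-plane Young's modulus E⊥, Pa.
    nu_xy : in-plane Poisson ratio, 0 ≤ ν ≤ 0.4999 (D diverges at 0.5).
    mu_perp : in-plane shear modulus μ⊥, Pa (enters the twisting
        rigidity Dxy only).
    loss_factor : η applied to E⊥ and μ⊥ alike (single loss factor).
    sigma : in-plane biaxial tension σ, Pa (σx = σy = σ, σz = 0);
        negative values (compression) are accepted, with no buckling
        analysis.
    """

    h: float
    rho: float
    E_perp: float
    nu_xy: float
    mu_perp: float
    loss_factor: float = 0.0
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if not self.h > 0:
            raise ParameterDomainError(f"h must be > 0, got {self.h}")
        if not self.rho > 0:
            raise ParameterDomainError(f"rho must be > 0, got {self.rho}")
        if not self.E_perp > 0:
            raise ParameterDomainError(f"E_perp must be > 0, got {self.E_perp}")
        if not (0.0 <= self.nu_xy <= _NU_MAX):
            raise ParameterDomainError(
                f"nu_xy must be in [0, {_NU_MAX}], got {self.nu_xy}"
            )
        if not self.mu_perp > 0:
            raise ParameterDomainError(f"mu_perp must be > 0, got {self.mu_perp}")
        if not self.loss_factor >= 0:
            raise ParameterDomainError(
                f"loss_factor must be >= 0, got {self.loss_factor}"
            )
        if not math.isfinite(self.sigma):
            raise ParameterDomainError(f"sigma must be finite, got {self.sigma}")


def flexural_rigidities(spec: PlateSpec) -> tuple[complex, complex]:
    """Bending rigidity D = E⊥h³/12(1−νxy²) and twisting rigidity
    Dxy = D·νxy + μ⊥h³/12, N·m.  Complex when the spec is lossy (the
    loss factor multiplies E⊥ and μ⊥ alike)."""
    h3 = spec.h**3
    D = spec.E_perp * h3 / (12.0 * (1.0 - spec.nu_xy**2))
    Dxy = D * spec.nu_xy + spec.mu_perp * h3 / 12.0
    if spec.loss_factor > 0:
        fac = 1.0 + LOSS_IMAG_SIGN * 1j * spec.loss_factor
        return D * fac, Dxy * fac
    return D, Dxy


def effective_rigidity(D: complex, Dxy: complex, psi: float):
    """Plane-wave bending rigidity at in-plane heading ψ:
    D cos⁴ψ + 2Dxy cos²ψ sin²ψ + D sin⁴ψ.  Equals D for all ψ when
    Dxy = D (in-plane isotropy)."""
    c2, s2 = math.cos(psi) ** 2, math.sin(psi) ** 2
    return D * c2 * c2 + 2.0 * Dxy * c2 * s2 + D * s2 * s2


def wavenumber_branches(spec: PlateSpec, omega: float) -> WavenumberBranches:
    """Four roots ±α, ±iβ of D γ⁴ + σh γ² − ρh ω² = 0."""
    D, _ = flexural_rigidities(spec)
    return branch_roots(D, spec.sigma * spec.h, spec.rho * spec.h, omega)


def phase_speed(spec: PlateSpec, omega: float) -> tuple[float, float]:
    """(c_ph, attenuation): c_ph = ω/Re(α), attenuation = |Im(α)| Np/m."""
    br = wavenumber_branches(spec, omega)
    return omega / np.real(br.alpha), abs(float(np.imag(br.alpha)))


def dispersion_curve(spec: PlateSpec, f_grid) -> DispersionCurve:
    """Evaluate the propagating branch over a strictly increasing
    frequency grid (Hz)."""
    f = np.asarray(f_grid, dtype=float)
    if f.size and not np.all(f > 0):
        raise ParameterDomainError("frequencies must be positive")
    k = np.empty(f.size, dtype=complex)
    c = np.empty(f.size)
    att = np.empty(f.size)
    for i, fi in enumerate(f):
        br = wavenumber_branches(spec, 2.0 * math.pi * fi)
        k[i] = br.alpha
        c[i] = br.omega / np.real(br.alpha)
        att[i] = abs(float(np.imag(br.alpha)))
    meta = {"model": "plate", **asdict(spec)}
    return DispersionCurve(f, k, c, att, meta)
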