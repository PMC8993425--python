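"""Transverse waves in a thin pre-tensioned beam: the 1-D waveguide model
for slender muscle.

A rod aligned with the fiber axis (z), with cross-section much smaller
than wavelength and uniaxial tension σ along the axis, carries x-polarized
transverse waves governed by the pre-tensioned Euler–Bernoulli equation

    E∥I u,zzzz − σA u,zz + ρA u,tt = 0,

the exact 1-D analogue of the tensioned plate: same quartic, with
rigidity E∥I, tension resultant σA and line inertia ρA (shared core in
:mod:`elastowave._branches`).  The flexural modulus is the fiber-parallel
Young's modulus E∥ = μ⊥(4ζ + 3) when built from a NITI material; only
the fiber-aligned case is modeled.  c_ph runs from the classical beam
value ω^(1/2)(E∥I/ρA)^(1/4) at σA ≪ 2E∥I to the string value sqrt(σ/ρ)
at σA ≫ 2E∥I — the regime in which passively tensioned muscle is
observed to sit, so the measured speed reflects tension, not modulus.
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
    "BeamSpec",
    "circular_section",
    "beam_branches",
    "beam_phase_speed",
    "beam_dispersion_curve",
    "regime_index",
]


@dataclass(frozen=True)
class BeamSpec:
    """Thin tensioned beam.

    area : cross-sectional area A, m² (e.g. muscle PCSA).
    inertia : area moment I, m⁴ (πr⁴/4 for a circular section).
    E_par : fiber-parallel Young's modulus E∥, Pa.
    rho : density, kg/m³.
    sigma : uniaxial tension along the beam axis, Pa.
    loss_factor : η applied to E∥.
    """

    area: float
    inertia: float
    E_par: float
    rho: float
    sigma: float = 0.0
    loss_factor: float = 0.0

    def __post_init__(self) -> None:
        if not self.area > 0:
            raise ParameterDomainError(f"area must be > 0, got {self.area}")
        if not self.inertia > 0:
            raise ParameterDomainError(f"inertia must be > 0, got {self.inertia}")
        if not self.E_par > 0:
            raise ParameterDomainError(f"E_par must be > 0, got {self.E_par}")
        if not self.rho > 0:
            raise ParameterDomainError(f"rho must be > 0, got {self.rho}")
        if not self.loss_factor >= 0:
            raise ParameterDomainError(
                f"loss_factor must be >= 0, got {self.loss_factor}"
            )
        if not math.isfinite(self.sigma):
            raise ParameterDomainError(f"sigma must be finite, got {self.sigma}")


def circular_section(r: float) -> tuple[float, float]:
    """(A, I) for a circular cross section: A = πr², I = πr⁴/4."""
    if not r > 0:
        raise ParameterDomainError(f"radius must be > 0, got {r}")
    return math.pi * r * r, math.pi * r**4 / 4.0


def _rigidity(spec: BeamSpec) -> complex:
    EI = spec.E_par * spec.inertia
    if spec.loss_factor > 0:
        return EI * (1.0 + LOSS_IMAG_SIGN * 1j * spec.loss_factor)
    return EI


def beam_branches(spec: BeamSpec, omega: float) -> WavenumberBranches:
    """Four roots ±α, ±iβ of E∥I γ⁴ + σA γ² − ρA ω² = 0."""
    return branch_roots(_rigidity(spec), spec.sigma * spec.area,
                        spec.rho * spec.area, omega)


def beam_phase_speed(spec: BeamSpec, omega: float) -> tuple[float, float]:
    """(c_ph, attenuation): c_ph = ω/Re(α), attenuation = |Im(α)|."""
    br = beam_branches(spec, omega)
    return omega / np.real(br.alpha), abs(float(np.imag(br.alpha)))


def beam_dispersion_curve(spec: BeamSpec, f_grid) -> DispersionCurve:
    """Propagating-branch dispersion over a frequency grid (Hz)."""
    f = np.asarray(f_grid, dtype=float)
    if f.size and not np.all(f > 0):
        raise ParameterDomainError("frequencies must be positive")
    k = np.empty(f.size, dtype=complex)
    c = np.empty(f.size)
    att = np.empty(f.size)
    for i, fi in enumerate(f):
        br = beam_branches(spec, 2.0 * math.pi * fi)
        k[i] = br.alpha
        c[i] = br.omega / np.real(br.alpha)
        att[i] = abs(float(np.imag(br.alpha)))
    meta = {"model": "beam", **asdict(spec)}
    return DispersionCurve(f, k, c, att, meta)


def regime_index(
    spec: BeamSpec,
    omega: float,
    string_threshold: float = 100.0,
    beam_threshold: float = 0.01,
) -> tuple[float, str]:
    """Dimensionless ratio ξ·a/ω locating the operating regime.

    ξ·a/ω compares the tension term to the bending term at this
    frequency: ≥ ``string_threshold`` means tension dominates (string
    regime, c_ph ≈ sqrt(σ/ρ)), ≤ ``beam_threshold`` means bending
    dominates (Euler–Bernoulli regime); in between both terms matter.
    Thresholds are configurable. Uses storage (real) parts when lossy.
    """
    if not omega > 0:
        raise ParameterDomainError(f"omega must be > 0, got {omega}")
    EI = spec.E_par * spec.inertia
    xi = spec.sigma * spec.area / (2.0 * EI)
    a = math.sqrt(EI / (spec.rho * spec.area))
    ratio = xi * a / omega
    if ratio >= string_threshold:
        label = "string"
    elif ratio <= beam_threshold:
        label = "beam"
    else:
        label = "intermediate"
    return ratio, label
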