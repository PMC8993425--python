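"""Plane waves in an unbounded prestressed NITI medium.

With static normal prestresses (σx, σy, σz) superimposed on the material —
no shear prestress, tension positive — axis-aligned plane waves have
closed-form phase speeds: nine propagation/polarization pairs (three
compression, six shear), where each shear entry picks up half the
difference of the prestresses along propagation and polarization.  For a
uniaxial stress σ along the fiber axis the slow and fast shear branches
generalize to any propagation angle θ from the axis:

    c_s²(θ) = (μ⊥/ρ)(1 + φ cos²θ) + (σ/2ρ) cos²θ
    c_f²(θ) = (μ⊥/ρ)(1 + φ + (ζ − φ) sin²2θ) + (σ/2ρ) cos 2θ

("slow" = polarized in the plane of isotropy, "fast" = polarized toward
the fiber axis; the labels follow the branch formulas, not a magnitude
sort — the curves can cross for exotic (ζ−φ, σ) combinations).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InstabilityError, ParameterDomainError
from .materials import NITIMaterial, complex_shear_moduli

__all__ = [
    "PrestressState",
    "PlaneWaveEntry",
    "phase_speed_table",
    "shear_speed",
    "wavelength_count",
    "phase_speed_from_rho_c2",
]


@dataclass(frozen=True)
class PrestressState:
    """Static normal stresses (Pa, tension positive); shear prestress is
    identically zero in this model."""

    sigma_x: float = 0.0
    sigma_y: float = 0.0
    sigma_z: float = 0.0

    def __post_init__(self) -> None:
        for name in ("sigma_x", "sigma_y", "sigma_z"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ParameterDomainError(f"{name} must be finite, got {v}")


@dataclass(frozen=True)
class PlaneWaveEntry:
    """One propagation/polarization pair of the bulk table."""

    propagation_axis: str
    polarization_axis: str
    rho_c2: complex  # ρc², Pa (complex when lossy)
    phase_speed: float  # m/s, from ω/Re(k)
    mode_label: str  # compression | shear-slow-like | shear-fast-like


def phase_speed_from_rho_c2(rho_c2: complex, rho: float) -> float:
    """Phase speed from (possibly complex) ρc².

    Lossless: sqrt(ρc²/ρ).  Lossy: c = ω/Re(k) with k = ω sqrt(ρ/ρc²)
    taking the root with positive real part; ω cancels, giving
    1 / Re(sqrt(ρ/ρc²)).
    """
    if np.iscomplexobj(rho_c2) and np.imag(rho_c2) != 0.0:
        unit_k = np.sqrt(rho / rho_c2)
        if unit_k.real < 0:
            unit_k = -unit_k
        return float(1.0 / unit_k.real)
    return float(math.sqrt(np.real(rho_c2) / rho))


def phase_speed_table(
    mat: NITIMaterial, stress: PrestressState = PrestressState()
) -> list[PlaneWaveEntry]:
    """The nine axis-aligned plane-wave entries.

    Compression entries depend only on the moduli (κ dominates for soft
    tissue); shear entries shift by half the prestress difference between
    the propagation and polarization axes, so a hydrostatic prestress
    leaves the whole table unchanged.  Lossy materials (η > 0) yield
    complex ρc²; the reported speed is ω/Re(k).

    Raises
    ------
    InstabilityError
        If any entry's Re(ρc²) ≤ 0 (excessive compressive prestress),
        naming the offending propagation/polarization pair.
    """
    mu_perp_c, mu_par_c = complex_shear_moduli(mat)
    lossless = mat.loss_factor == 0.0
    if lossless:
        mu_perp_c, mu_par_c = mu_perp_c.real, mu_par_c.real
    k, z = mat.kappa, mat.zeta
    sx, sy, sz = stress.sigma_x, stress.sigma_y, stress.sigma_z
    comp_xy = k + mat.mu_perp * (4.0 / 3.0 + 4.0 * z / 9.0)
    comp_z = k + mat.mu_perp * (4.0 / 3.0 + 16.0 * z / 9.0)

    raw = [
        ("x", "x", comp_xy, "compression"),
        ("x", "y", mu_perp_c + (sx - sy) / 2.0, "shear-slow-like"),
        ("x", "z", mu_par_c + (sx - sz) / 2.0, "shear-fast-like"),
        ("y", "x", mu_perp_c + (sy - sx) / 2.0, "shear-slow-like"),
        ("y", "y", comp_xy, "compression"),
        ("y", "z", mu_par_c + (sy - sz) / 2.0, "shear-fast-like"),
        ("z", "x", mu_par_c + (sz - sx) / 2.0, "shear-fast-like"),
        ("z", "y", mu_par_c + (sz - sy) / 2.0, "shear-fast-like"),
        ("z", "z", comp_z, "compression"),
    ]
    entries = []
    for prop, pol, rc2, label in raw:
        if np.real(rc2) <= 0:
            raise InstabilityError(
                f"rho*c^2 <= 0 for propagation {prop}, polarization {pol} "
                f"({np.real(rc2):.6g} Pa): compressive prestress exceeds "
                "the stable range (no buckling analysis)"
            )
        entries.append(
            PlaneWaveEntry(prop, pol, rc2, phase_speed_from_rho_c2(rc2, mat.rho), label)
        )
    return entries


def shear_speed(
    mat: NITIMaterial, sigma: float, theta: float, branch: str = "slow"
) -> float:
    """Slow/fast shear phase speed at angle θ from the fiber axis under
    uniaxial stress σ along that axis.

    θ outside [0, π/2] is handled by the formulas' own symmetries
    (cos²θ, sin²2θ, cos 2θ are invariant under θ → −θ and θ → π − θ).
    Lossy materials use the complex μ and report ω/Re(k).
    """
    mu_perp_c, _ = complex_shear_moduli(mat)
    if mat.loss_factor == 0.0:
        mu_perp_c = mu_perp_c.real
    ct2 = math.cos(theta) ** 2
    if branch == "slow":
        rc2 = mu_perp_c * (1.0 + mat.phi * ct2) + (sigma / 2.0) * ct2
    elif branch == "fast":
        s2t2 = math.sin(2.0 * theta) ** 2
        c2t = math.cos(2.0 * theta)
        rc2 = mu_perp_c * (1.0 + mat.phi + (mat.zeta - mat.phi) * s2t2) + (
            sigma / 2.0
        ) * c2t
    else:
        raise ParameterDomainError(f"branch must be 'slow' or 'fast', got {branch!r}")
    if np.real(rc2) <= 0:
        raise InstabilityError(
            f"rho*c^2 <= 0 for {branch} shear at theta={theta:.4g} rad, "
            f"sigma={sigma:.6g} Pa"
        )
    return phase_speed_from_rho_c2(rc2, mat.rho)


def wavelength_count(c: float, f: float, R: float) -> float:
    """Number of wavelengths over a distance R: R·f/c.

    Used to judge whether a finite boundary matters — e.g. whether a
    source-to-boundary path spans enough wavelengths for the unbounded
    plane-wave picture to hold.
    """
    if not c > 0:
        raise ParameterDomainError(f"c must be > 0, got {c}")
    if not f > 0:
        raise ParameterDomainError(f"f must be > 0, got {f}")
    if R < 0:
        raise ParameterDomainError(f"R must be >= 0, got {R}")
    return R * f / c
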