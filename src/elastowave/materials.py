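"""Nearly incompressible, transversely isotropic (NITI) linear elastic material.

A NITI material models soft biological tissue with a single fiber axis
(taken as z, the axis of isotropy): muscle, white matter, or — with the
axis normal to the surface — layered tissue such as the cornea.  It is
described by the bulk modulus κ and three independent small-strain
parameters: the shear storage modulus in the plane of isotropy μ⊥, the
shear anisotropy φ = μ∥/μ⊥ − 1, and the tensile anisotropy
ζ = E∥/E⊥ − 1.  The tensile moduli are then fixed by E∥ = μ⊥(4ζ + 3)
and E⊥ = E∥/(1 + ζ).  Viscoelastic loss is a single frequency-independent
loss factor η applied equally to both shear moduli, μc = μR(1 ∓ iη).

Units are strict SI throughout (Pa, kg/m³).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterDomainError

__all__ = [
    "NITIMaterial",
    "LOSS_IMAG_SIGN",
    "complex_shear_moduli",
    "elasticity_matrix",
    "tensile_moduli",
    "landau_A_small_strain",
    "material_from_dict",
    "material_to_dict",
]

# Sign of the imaginary part of every complex modulus.  The package-wide
# harmonic convention is exp(i(γx − ωt)); with that convention a forward
# propagating root γ = ω·sqrt(ρ/μc) decays in +x only when Im(μc) < 0,
# so loss enters as μc = μR·(1 + LOSS_IMAG_SIGN·i·η).  This constant is
# the single place the sign is chosen.
LOSS_IMAG_SIGN: float = -1.0


@dataclass(frozen=True)
class NITIMaterial:
    """Linear elastic NITI material.

    Parameters
    ----------
    kappa : float
        Bulk modulus κ, Pa.  For soft tissue κ/μ⊥ is typically ~1e6.
    mu_perp : float
        Shear storage modulus in the plane of isotropy, μ⊥R, Pa.
    loss_factor : float
        η = μ⊥I/μ⊥R = μ∥I/μ∥R ≥ 0, dimensionless.
    phi : float
        Shear anisotropy φ = μ∥/μ⊥ − 1; must satisfy 1 + φ > 0.
    zeta : float
        Tensile anisotropy ζ = E∥/E⊥ − 1; must satisfy 4ζ + 3 > 0
        (E∥ > 0) and 1 + ζ > 0 (E⊥ > 0).
    rho : float
        Mass density, kg/m³.
    """

    kappa: float
    mu_perp: float
    loss_factor: float = 0.0
    phi: float = 0.0
    zeta: float = 0.0
    rho: float = 1000.0

    def __post_init__(self) -> None:
        if not (self.kappa > 0):
            raise ParameterDomainError(f"kappa must be > 0, got {self.kappa}")
        if not (self.mu_perp > 0):
            raise ParameterDomainError(f"mu_perp must be > 0, got {self.mu_perp}")
        if not (self.rho > 0):
            raise ParameterDomainError(f"rho must be > 0, got {self.rho}")
        if not (self.loss_factor >= 0):
            raise ParameterDomainError(
                f"loss_factor must be >= 0, got {self.loss_factor}"
            )
        if not (1.0 + self.phi > 0):
            raise ParameterDomainError(
                f"1 + phi must be > 0 (mu_par > 0), got phi={self.phi}"
            )
        if not (4.0 * self.zeta + 3.0 > 0):
            raise ParameterDomainError(
                f"4*zeta + 3 must be > 0 (E_par > 0), got zeta={self.zeta}"
            )
        if not (1.0 + self.zeta > 0):
            raise ParameterDomainError(
                f"1 + zeta must be > 0 (E_perp > 0), got zeta={self.zeta}"
            )

    @property
    def mu_par(self) -> float:
        """Shear storage modulus parallel to fibers, μ∥ = μ⊥(1 + φ), Pa."""
        return self.mu_perp * (1.0 + self.phi)


def complex_shear_moduli(mat: NITIMaterial) -> tuple[complex, complex]:
    """Complex shear moduli (μ⊥c, μ∥c).

    Both moduli share the loss factor η; the imaginary-part sign follows
    :data:`LOSS_IMAG_SIGN` so propagating waves decay spatially under the
    exp(i(γx − ωt)) convention.
    """
    mu_perp_c = mat.mu_perp * (1.0 + LOSS_IMAG_SIGN * 1j * mat.loss_factor)
    return mu_perp_c, mu_perp_c * (1.0 + mat.phi)


def elasticity_matrix(mat: NITIMaterial) -> np.ndarray:
    """6×6 transversely isotropic stiffness matrix, Voigt order
    (xx, yy, zz, yz, xz, xy), z the axis of isotropy.

    Built from the storage moduli (real).  Entries:

    - C11 = C22 = κ + μ⊥(4/3 + 4ζ/9)
    - C12 = κ − μ⊥(2/3 − 4ζ/9)
    - C13 = C23 = κ − μ⊥(2/3 + 8ζ/9)
    - C33 = κ + μ⊥(4/3 + 16ζ/9)
    - C44 = C55 = μ⊥(1 + φ),  C66 = μ⊥

    These satisfy the plane-wave identities C12 + C66 = κ + μ⊥(1/3 + 4ζ/9)
    and C13 + C55 = κ + μ⊥(1/3 + φ − 8ζ/9) used by the governing equations
    of motion, and the diagonal entries are the ρc² of axis-aligned plane
    waves at zero prestress.
    """
    k, mu, z = mat.kappa, mat.mu_perp, mat.zeta
    c11 = k + mu * (4.0 / 3.0 + 4.0 * z / 9.0)
    c12 = k - mu * (2.0 / 3.0 - 4.0 * z / 9.0)
    c13 = k - mu * (2.0 / 3.0 + 8.0 * z / 9.0)
    c33 = k + mu * (4.0 / 3.0 + 16.0 * z / 9.0)
    c44 = mu * (1.0 + mat.phi)
    c66 = mu
    C = np.zeros((6, 6))
    C[0, 0] = C[1, 1] = c11
    C[0, 1] = C[1, 0] = c12
    C[0, 2] = C[2, 0] = C[1, 2] = C[2, 1] = c13
    C[2, 2] = c33
    C[3, 3] = C[4, 4] = c44
    C[5, 5] = c66
    return C


def tensile_moduli(mat: NITIMaterial) -> tuple[float, float]:
    """(E∥, E⊥) in Pa, from E∥ = μ⊥(4ζ + 3) and E⊥ = E∥/(1 + ζ)."""
    e_par = mat.mu_perp * (4.0 * mat.zeta + 3.0)
    return e_par, e_par / (1.0 + mat.zeta)


def landau_A_small_strain(mu: float) -> float:
    """Third-order Landau coefficient A = −6μ, Pa.

    This is the value for which finite-strain isotropic acoustoelastic
    theory reduces to the small-strain prestressed formulation used here;
    it lies within the range reported for agar-gelatin and PVA tissue
    phantoms.
    """
    if not mu > 0:
        raise ParameterDomainError(f"mu must be > 0, got {mu}")
    return -6.0 * mu


# Flat serialization keys mirror the case-study nomenclature.
_DICT_KEYS = {
    "kappa_Pa": "kappa",
    "mu_perp_Pa": "mu_perp",
    "loss_factor": "loss_factor",
    "phi": "phi",
    "zeta": "zeta",
    "rho_kg_m3": "rho",
}


def material_from_dict(d: dict) -> NITIMaterial:
    """Build a material from a flat JSON/TOML block
    (keys kappa_Pa, mu_perp_Pa, loss_factor, phi, zeta, rho_kg_m3)."""
    unknown = set(d) - set(_DICT_KEYS)
    if unknown:
        raise ParameterDomainError(f"unknown material keys: {sorted(unknown)}")
    missing = {"kappa_Pa", "mu_perp_Pa", "rho_kg_m3"} - set(d)
    if missing:
        raise ParameterDomainError(f"missing material keys: {sorted(missing)}")
    kwargs = {_DICT_KEYS[k]: float(v) for k, v in d.items()}
    return NITIMaterial(**kwargs)


def material_to_dict(mat: NITIMaterial) -> dict:
    return {
        "kappa_Pa": mat.kappa,
        "mu_perp_Pa": mat.mu_perp,
        "loss_factor": mat.loss_factor,
        "phi": mat.phi,
        "zeta": mat.zeta,
        "rho_kg_m3": mat.rho,
    }
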