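"""Shared branch algebra for the tensioned thin-plate and thin-beam quartics.

Both waveguides reduce, for a planar wavefront, to the same dispersion
relation in the wavenumber γ:

    R γ⁴ + T γ² − m ω² = 0

with bending rigidity R (D for the plate, E∥I for the beam), tension
resultant T (σh, σA) and line inertia m (ρh, ρA).  Its four roots are
γ = ±α, ±iβ with

    α = (−ξ + s)^(1/2),  β = (ξ + s)^(1/2),  s = (ξ² + ω²/a²)^(1/2),
    ξ = T/(2R),          a = (R/m)^(1/2),

two propagating (±α) and two evanescent (±iβ) branches.  For lossless
inputs α, β are real and satisfy β² − α² = 2ξ and α²β² = ω²/a².

Lossy case: R is complex (loss factor applied to the modulus).  The
principal square roots are the analytic continuation of the lossless
roots — α², β² rotate continuously off the positive real axis as η grows
and stay in the right half-plane for any physical loss factor — so the
closed form itself performs the continuation and no root re-matching is
needed; Re(α) > 0 and, with Im(R) < 0 under the exp(i(γx − ωt))
convention, Im(α) > 0 (spatial decay).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterDomainError

__all__ = ["WavenumberBranches", "branch_roots"]


@dataclass(frozen=True)
class WavenumberBranches:
    """Roots of the tensioned-waveguide dispersion quartic at one ω.

    Attributes
    ----------
    alpha : float | complex
        Propagating wavenumber magnitude (the +α root), rad/m.
    beta : float | complex
        Evanescent decay rate (the root is ±iβ), 1/m.
    xi : float | complex
        Tension parameter ξ = T/(2R), 1/m².
    a : float | complex
        Stiffness parameter a = sqrt(R/m), m²/s.
    omega : float
        Angular frequency, rad/s.
    """

    alpha: complex
    beta: complex
    xi: complex
    a: complex
    omega: float

    @property
    def roots(self) -> tuple[complex, complex, complex, complex]:
        """The four quartic roots (+α, −α, +iβ, −iβ)."""
        return (self.alpha, -self.alpha, 1j * self.beta, -1j * self.beta)


def branch_roots(rigidity: complex, tension: float, line_inertia: float,
                 omega: float) -> WavenumberBranches:
    """Solve R γ⁴ + T γ² − m ω² = 0 in closed form.

    Parameters
    ----------
    rigidity : float or complex
        R: plate D or beam E∥I (complex when lossy), N·m or N·m².
    tension : float
        T: σh (N/m) or σA (N).  May be negative (compression); the model
        contains no buckling analysis, and ω > 0 keeps the roots finite.
    line_inertia : float
        m: ρh (kg/m²) or ρA (kg/m).
    omega : float
        Angular frequency, rad/s; must be > 0.
    """
    if not omega > 0:
        raise ParameterDomainError(f"omega must be > 0, got {omega}")
    if line_inertia <= 0:
        raise ParameterDomainError(f"line inertia must be > 0, got {line_inertia}")
    lossy = bool(np.iscomplexobj(rigidity)) and rigidity.imag != 0.0
    if np.real(rigidity) <= 0:
        raise ParameterDomainError(f"rigidity must have positive real part, got {rigidity}")

    xi = tension / (2.0 * rigidity)
    a = np.sqrt(rigidity / line_inertia) if lossy else np.sqrt(rigidity.real / line_inertia)
    w2a2 = omega * omega * line_inertia / rigidity  # ω²/a², avoids sqrt twice
    s = np.sqrt(xi * xi + w2a2)
    # The smaller radicand s ∓ |ξ| suffers cancellation when ξ² ≫ ω²/a²;
    # rewrite it as (ω²/a²)/(s ± |ξ|), which also makes the identities
    # β²−α² = 2ξ and α²β² = ω²/a² exact in floating point.
    if np.real(xi) >= 0:
        beta2 = s + xi
        alpha2 = w2a2 / beta2
    else:
        alpha2 = s - xi
        beta2 = w2a2 / alpha2
    if lossy:
        alpha = complex(np.sqrt(alpha2))
        beta = complex(np.sqrt(beta2))
        if alpha.real < 0:  # principal sqrt never lands here; keep defensive
            alpha = -alpha
        if beta.real < 0:
            beta = -beta
    else:
        xi = float(np.real(xi))
        alpha = float(np.sqrt(max(np.real(alpha2), 0.0)))
        beta = float(np.sqrt(max(np.real(beta2), 0.0)))
    return WavenumberBranches(alpha=alpha, beta=beta, xi=xi, a=a, omega=float(omega))
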