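import numpy as np
import pytest

from elastowave import BeamSpec, NITIMaterial, PlateSpec


@pytest.fixture
def soft_tissue():
    """The soft-tissue case-study material: kappa=2.6 GPa, mu_perp=2.77 kPa,
    phi=1, zeta=2, rho=1000 (lossless variant)."""
    return NITIMaterial(kappa=2.6e9, mu_perp=2770.0, loss_factor=0.0,
                        phi=1.0, zeta=2.0, rho=1000.0)


@pytest.fixture
def soft_tissue_lossy(soft_tissue):
    from dataclasses import replace
    return replace(soft_tissue, loss_factor=0.15)


@pytest.fixture
def cornea_plate():
    """Cornea-like plate: h=0.6 mm, E_perp=50 kPa, nu=0.499, lossless."""
    return PlateSpec(h=0.6e-3, rho=1000.0, E_perp=50e3, nu_xy=0.499,
                     mu_perp=50e3 / (2 * 1.499))


@pytest.fixture
def cornea_plate_30k(cornea_plate):
    from dataclasses import replace
    return replace(cornea_plate, E_perp=30e3)


@pytest.fixture
def soleus_beam():
    """Cat-soleus-like beam: PCSA 1 cm^2 circular section, E_par=30.47 kPa."""
    return BeamSpec(area=1e-4, inertia=7.958e-10, E_par=30470.0, rho=1000.0)


def quartic_roots_oracle(rigidity, tension, line_inertia, omega):
    """Independent oracle: roots of R*g^4 + T*g^2 - m*w^2 = 0 via a generic
    polynomial root finder.  Returns (alpha, beta) as the positive-real and
    positive-imaginary root magnitudes."""
    roots = np.roots([rigidity, 0.0, tension, 0.0, -line_inertia * omega**2])
    real = sorted(r.real for r in roots if abs(r.imag) < 1e-9 * max(abs(r), 1.0))
    imag = sorted(r.imag for r in roots if abs(r.real) < 1e-9 * max(abs(r), 1.0))
    alpha = real[-1]
    beta = imag[-1]
    return alpha, beta
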