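"""Dispersion-curve container: the exchange format between forward models,
synthesis, and inversion."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError

__all__ = ["DispersionCurve"]


@dataclass
class DispersionCurve:
    """Sampled (frequency, wavenumber, phase speed, attenuation) table.

    frequency : Hz, strictly increasing.
    wavenumber : rad/m; complex-capable (Im = spatial decay rate).
    phase_speed : m/s, ω / Re(k).
    attenuation : Np/m, |Im(k)|; zeros when lossless.
    metadata : generating parameters (flat dict of scalars/strings).
    """

    frequency: np.ndarray
    wavenumber: np.ndarray
    phase_speed: np.ndarray
    attenuation: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frequency = np.asarray(self.frequency, dtype=float)
        self.wavenumber = np.asarray(self.wavenumber)
        self.phase_speed = np.asarray(self.phase_speed, dtype=float)
        self.attenuation = np.asarray(self.attenuation, dtype=float)
        n = self.frequency.size
        for name in ("wavenumber", "phase_speed", "attenuation"):
            if getattr(self, name).size != n:
                raise SchemaError(f"{name} length != frequency length")
        if n > 1 and not np.all(np.diff(self.frequency) > 0):
            raise SchemaError("frequency must be strictly increasing")

    def __len__(self) -> int:
        return int(self.frequency.size)

    def __eq__(self, other) -> bool:
        if not isinstance(other, DispersionCurve):
            return NotImplemented
        return (
            np.array_equal(self.frequency, other.frequency)
            and np.array_equal(self.wavenumber, other.wavenumber)
            and np.array_equal(self.phase_speed, other.phase_speed)
            and np.array_equal(self.attenuation, other.attenuation)
            and self.metadata == other.metadata
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frequency_Hz": self.frequency,
                "k_rad_per_m_re": np.real(self.wavenumber),
                "k_rad_per_m_im": np.imag(self.wavenumber),
                "c_m_per_s": self.phase_speed,
                "attenuation_Np_per_m": self.attenuation,
            }
        )
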