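"""Thermal-noise biophysics of the cell–chip cleft.

An adherent, non-electrogenic cell seals an electrolyte-filled cleft
between its basal membrane and the sensor oxide. The cleft behaves as an
ohmic resistor R_cleft whose Johnson–Nyquist (thermal) voltage noise has
the one-sided PSD 4·k_B·T·R. The measured adhesion noise ΔS_V on the
flat (resistive) plateau therefore converts directly to a cleft
resistance:

    R_cleft = ΔS_V / (4 k_B T)

Both directions are pure, vectorised functions; k_B is the exact 2019 SI
Boltzmann constant and is not configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["K_B", "CleftEstimate", "cleft_resistance", "johnson_psd"]

#: Boltzmann constant, exact SI value (J/K).
K_B = 1.380649e-23


def cleft_resistance(delta_sv: float | np.ndarray, temperature: float) -> float | np.ndarray:
    """Cleft resistance (Ω) from adhesion noise ΔS_V (V²/Hz) at T (K).

    ΔS_V must be non-negative: a negative adhesion noise has no resistive
    interpretation — clamp or reject upstream before calling.
    """
    dsv = np.asarray(delta_sv, dtype=float)
    if np.any(dsv < 0):
        raise ValueError("delta_sv must be >= 0; clamp or reject negative adhesion noise first")
    if temperature <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    r = dsv / (4.0 * K_B * temperature)
    return float(r) if np.isscalar(delta_sv) else r


def johnson_psd(resistance: float | np.ndarray, temperature: float) -> float | np.ndarray:
    """One-sided thermal-noise PSD 4·k_B·T·R (V²/Hz) of a resistance (Ω).

    Exact inverse of :func:`cleft_resistance`.
    """
    r = np.asarray(resistance, dtype=float)
    if np.any(r < 0):
        raise ValueError("resistance must be >= 0")
    if temperature <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    s = 4.0 * K_B * temperature * r
    return float(s) if np.isscalar(resistance) else s


@dataclass(frozen=True)
class CleftEstimate:
    """A ΔS_V measurement and the cleft resistance it implies."""

    delta_sv: float  # V²/Hz
    temperature: float  # K
    r_cleft: float  # Ω

    @classmethod
    def from_delta_sv(cls, delta_sv: float, temperature: float) -> "CleftEstimate":
        return cls(delta_sv, temperature, cleft_resistance(delta_sv, temperature))
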