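"""Unit conversions and physical constants used across the package.

All rate arithmetic is carried out in cm^-1 and seconds; energies cross
module boundaries in eV and are converted here.
"""

from __future__ import annotations

import numpy as np

#: eV -> cm^-1 conversion factor.
EV_TO_CM: float = 8065.544

#: eV * nm product for photon energy/wavelength conversion.
EV_NM: float = 1239.842

#: Speed of light in cm/s.
C_CM_S: float = 2.99792458e10

#: Boltzmann constant in cm^-1 per kelvin.
KB_CM_PER_K: float = 0.695035

#: Hartree in cm^-1 (atomic-unit couplings to spectroscopic units).
HARTREE_CM: float = 219474.63

#: Strickler-Berg constant, cm^-2 s (k_r = nu^2 f / 1.499).
SB_CONSTANT: float = 1.499


def ev_to_wavenumber(e):
    """Convert an energy in eV to wavenumbers (cm^-1). Accepts arrays."""
    return np.multiply(e, EV_TO_CM)


def wavenumber_to_ev(nu):
    """Convert wavenumbers (cm^-1) to eV. Accepts arrays."""
    return np.divide(nu, EV_TO_CM)


def ev_to_nm(e):
    """Convert a photon energy in eV to a wavelength in nm.

    The map ``x -> 1239.842 / x`` is an involution, so the same function
    converts nm back to eV.

    Raises
    ------
    ValueError
        If any input is not strictly positive.
    """
    arr = np.asarray(e, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("photon energy/wavelength must be > 0 for eV<->nm conversion")
    out = EV_NM / arr
    return float(out) if np.isscalar(e) or arr.ndim == 0 else out


nm_to_ev = ev_to_nm  # the conversion is its own inverse


def kbt_cm(temperature: float) -> float:
    """Thermal energy k_B*T in cm^-1 for a temperature in kelvin."""
    if temperature <= 0:
        raise ValueError("temperature must be > 0 K")
    return KB_CM_PER_K * temperature
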