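"""Broadened absorption/emission curves from stick spectra.

TD-DFT yields discrete transitions (energy, oscillator strength); comparison
with measured spectra requires convolving these sticks with a line shape.
Broadening is always performed on the energy (eV) axis; displaying in nm or
cm^-1 relabels the axis pointwise without Jacobian reweighting, the common
convention for TD-DFT overlays.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np

from .units import EV_TO_CM, ev_to_nm

__all__ = ["StickSpectrum", "Spectrum", "broaden", "convert_axis", "normalize"]

AxisUnit = Literal["eV", "nm", "cm^-1"]
Kind = Literal["absorption", "emission"]


@dataclass(frozen=True)
class StickSpectrum:
    """Discrete transitions: (energy eV, weight) pairs plus a kind tag."""

    lines: tuple[tuple[float, float], ...]
    kind: Kind = "absorption"

    def __post_init__(self) -> None:
        lines = tuple((float(e), float(w)) for e, w in self.lines)
        for e, w in lines:
            if e <= 0:
                raise ValueError(f"line energy must be > 0 eV, got {e}")
            if w < 0:
                raise ValueError(f"line weight must be >= 0, got {w}")
        object.__setattr__(self, "lines", lines)

    @property
    def total_weight(self) -> float:
        return sum(w for _, w in self.lines)


@dataclass(frozen=True)
class Spectrum:
    """Intensity sampled on a strictly monotone axis."""

    grid: np.ndarray
    intensity: np.ndarray
    kind: Kind = "absorption"
    axis_unit: AxisUnit = "eV"
    #: fraction of the total stick weight captured inside the grid
    #: (1 for Gaussian up to quadrature error; < 1 for truncated Lorentzian tails)
    weight_captured: Optional[float] = None

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if grid.ndim != 1 or grid.shape != inten.shape:
            raise ValueError("grid and intensity must be matching 1-D arrays")
        d = np.diff(grid)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("grid must be strictly monotone")
        if np.any(inten < 0):
            raise ValueError("intensity must be >= 0 everywhere")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "intensity", inten)

    def argmax_position(self) -> float:
        """Axis position of the intensity maximum."""
        return float(self.grid[int(np.argmax(self.intensity))])

    def integral(self) -> float:
        """Trapezoid integral of intensity over the axis (absolute value,
        so descending axes integrate positively)."""
        return abs(float(np.trapezoid(self.intensity, self.grid)))


_SQRT_8LN2 = np.sqrt(8.0 * np.log(2.0))


def _default_grid(s: StickSpectrum, fwhm: float, n: int = 2000) -> np.ndarray:
    energies = [e for e, _ in s.lines]
    lo = min(energies) - 5.0 * fwhm
    hi = max(energies) + 5.0 * fwhm
    return np.linspace(max(lo, 1e-6), hi, n)


def broaden(
    s: StickSpectrum,
    fwhm: float = 0.15,
    shape: Literal["gaussian", "lorentzian"] = "gaussian",
    grid: Optional[np.ndarray] = None,
) -> Spectrum:
    """Convolve a stick spectrum with unit-area line shapes of the given FWHM
    (eV), returning intensity per eV on the grid.

    The summed curve integrates to the total stick weight (to quadrature
    accuracy for Gaussians; Lorentzian wings lost outside the grid are
    reported via ``Spectrum.weight_captured``).  The default grid spans the
    lines +/- 5 FWHM with 2000 points.

    Raises if the grid does not cover every line by at least 3 FWHM.
    """
    if fwhm <= 0:
        raise ValueError("fwhm must be > 0 eV")
    if grid is None:
        if not s.lines:
            grid = np.linspace(1.0, 2.0, 2000)  # arbitrary axis for an empty spectrum
        else:
            grid = _default_grid(s, fwhm)
    grid = np.asarray(grid, dtype=float)
    for e, _ in s.lines:
        if e - 3.0 * fwhm < grid.min() or e + 3.0 * fwhm > grid.max():
            raise ValueError(
                f"grid [{grid.min():g}, {grid.max():g}] eV does not cover line at "
                f"{e:g} eV by 3*fwhm"
            )
    inten = np.zeros_like(grid)
    if shape == "gaussian":
        sigma = fwhm / _SQRT_8LN2
        norm = 1.0 / (sigma * np.sqrt(2.0 * np.pi))
        for e, w in s.lines:
            inten += w * norm * np.exp(-0.5 * ((grid - e) / sigma) ** 2)
    elif shape == "lorentzian":
        gamma = fwhm / 2.0
        for e, w in s.lines:
            inten += w * (gamma / np.pi) / ((grid - e) ** 2 + gamma**2)
    else:
        raise ValueError(f"unknown line shape {shape!r}")
    sp = Spectrum(grid=grid, intensity=inten, kind=s.kind, axis_unit="eV")
    total = s.total_weight
    captured = sp.integral() / total if total > 0 else 1.0
    return replace(sp, weight_captured=captured)


def convert_axis(sp: Spectrum, to: AxisUnit) -> Spectrum:
    """Relabel the spectral axis (eV <-> nm <-> cm^-1) pointwise.

    Intensities are carried over unchanged (no Jacobian), so peak positions
    map exactly through the unit conversion.  The returned grid is flipped
    where needed to stay monotone increasing.
    """
    if to not in ("eV", "nm", "cm^-1"):
        raise ValueError(f"unknown axis unit {to!r}")
    if to == sp.axis_unit:
        return sp
    # go through eV
    if sp.axis_unit == "eV":
        ev = sp.grid
    elif sp.axis_unit == "cm^-1":
        ev = sp.grid / EV_TO_CM
    else:  # nm
        ev = ev_to_nm(sp.grid)
    if to == "eV":
        new = ev
    elif to == "cm^-1":
        new = ev * EV_TO_CM
    else:
        new = ev_to_nm(ev)
    inten = sp.intensity
    if new[0] > new[-1]:
        new = new[::-1]
        inten = inten[::-1]
    return Spectrum(grid=new, intensity=inten, kind=sp.kind, axis_unit=to,
                    weight_captured=sp.weight_captured)


def normalize(sp: Spectrum, mode: Literal["max", "area"] = "max") -> Spectrum:
    """Scale a spectrum so its peak is 1 (``max``) or its integral is 1
    (``area``).  Idempotent; a zero spectrum cannot be normalized."""
    if mode == "max":
        scale = float(np.max(sp.intensity))
    elif mode == "area":
        scale = sp.integral()
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if scale <= 0:
        raise ValueError("cannot normalize an identically zero spectrum")
    return replace(sp, intensity=sp.intensity / scale)
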