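"""Excited-state rate constants: radiative, intersystem crossing, internal
conversion.

The engine implements the kinetic competition that sets the fluorescence
quantum yield of a molecular emitter whose S1 state decays through three
first-order channels:

* ``k_r`` — spontaneous emission, from the Strickler-Berg relation
  ``k_r = nu^2 f / 1.499`` with ``nu`` the emission energy in cm^-1 and ``f``
  the oscillator strength (vacuum, single-transition form).
* ``k_isc`` — S1 -> T1 intersystem crossing, a Fermi golden-rule rate
  ``4 pi^2 c |SOCME|^2 FCWD(gap)`` driven by the spin-orbit coupling matrix
  element and a Franck-Condon-weighted density of states (FCWD) evaluated at
  the S1-T1 energy gap.  The FCWD is the Marcus-Levich-Jortner form: one
  effective high-frequency accepting mode (Huang-Rhys factor ``S``, quantum
  ``hbar*omega``) dressed by a classical low-frequency/solvent reorganization
  Gaussian.
* ``k_ic`` — S1 -> S0 internal conversion in the X-H promoting-mode
  approximation: the full electronic gap is deposited into overtone quanta of
  anharmonic X-H stretching oscillators (X = C, N, O), the only intramolecular
  modes stiff enough to absorb ~1.5-2.5 eV in a handful of quanta.

Because the ISC/IC golden-rule expressions involve vibrational structure the
package cannot compute ab initio, :func:`calibrate_fcwd` pins the effective
FCWD parameters to observed (SOCME, gap, k_ISC) triples by least squares.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .descriptors import S1_OPT, EmitterDescriptor, RateSet, XHMode
from .units import C_CM_S, HARTREE_CM, SB_CONSTANT, ev_to_wavenumber, kbt_cm

__all__ = [
    "FCWDParams",
    "FCWDFit",
    "XHModeSet",
    "DEFAULT_XH_MODES",
    "strickler_berg_rate",
    "fcwd",
    "isc_rate",
    "calibrate_fcwd",
    "ic_rate_xh",
    "compute_rates",
]

_GOLDEN_PREFACTOR = 4.0 * math.pi**2 * C_CM_S  # cm/s; couplings in cm^-1, FCWD per cm^-1


@dataclass(frozen=True)
class FCWDParams:
    """Effective parameters of the Marcus-Levich-Jortner FCWD.

    mode_energy : cm^-1
        Quantum of the effective high-frequency accepting mode.
    huang_rhys : dimensionless
        Huang-Rhys factor S of that mode (electron-vibration coupling).
    reorg_low : cm^-1
        Classical (low-frequency + solvent) reorganization energy setting the
        Gaussian width of each vibronic line.
    temperature : K
    n_max : int
        Truncation order of the vibronic (Poisson) sum.
    """

    mode_energy: float = 1400.0
    huang_rhys: float = 1.0
    reorg_low: float = 800.0
    temperature: float = 298.15
    n_max: int = 100

    def __post_init__(self) -> None:
        if self.mode_energy <= 0:
            raise ValueError("mode_energy must be > 0 cm^-1")
        if self.huang_rhys < 0:
            raise ValueError("huang_rhys must be >= 0")
        if self.reorg_low <= 0:
            raise ValueError("reorg_low must be > 0 cm^-1")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0 K")
        if self.n_max < 1:
            raise ValueError("n_max must be >= 1")


@dataclass(frozen=True)
class XHModeSet:
    """Inventory of X-H stretching oscillators available as IC acceptors."""

    entries: tuple[XHMode, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))

    @classmethod
    def from_tuples(cls, tuples: Iterable[tuple[int, float, float]]) -> "XHModeSet":
        return cls(tuple(XHMode(count=c, frequency=f, anharmonicity=x) for c, f, x in tuples))

    def __len__(self) -> int:
        return len(self.entries)


#: Generic X-H inventory of a nucleobase shell around a metal cluster:
#: aromatic/methyl C-H, amino/imino N-H and hydration O-H stretches.
DEFAULT_XH_MODES = XHModeSet.from_tuples(
    [(10, 2950.0, 0.018), (4, 3400.0, 0.021), (2, 3550.0, 0.023)]
)


def strickler_berg_rate(e_emit: float, f: float, refractive_index: float = 1.0) -> float:
    """Radiative rate constant (s^-1) from emission energy and oscillator
    strength.

    Parameters
    ----------
    e_emit : float
        Vertical emission energy in eV (S1 at the S1-optimized geometry).
    f : float
        Oscillator strength of the emitting transition.
    refractive_index : float, optional
        Medium refractive index; the default 1.0 gives the vacuum
        single-transition Strickler-Berg form ``k_r = nu^2 f / 1.499``.
    """
    if e_emit <= 0:
        raise ValueError("emission energy must be > 0 eV")
    if f < 0:
        raise ValueError("oscillator strength must be >= 0")
    nu = ev_to_wavenumber(e_emit)
    return refractive_index**2 * nu * nu * f / SB_CONSTANT


def _poisson_weights(s: float, n_max: int) -> np.ndarray:
    n = np.arange(n_max + 1)
    if s == 0.0:
        w = np.zeros(n_max + 1)
        w[0] = 1.0
        return w
    # stable in log space for large S
    logw = -s + n * math.log(s) - np.cumsum(np.concatenate(([0.0], np.log(np.arange(1, n_max + 1)))))
    return np.exp(logw)


def fcwd(gap, p: FCWDParams):
    """Franck-Condon-weighted density of states (per cm^-1) at an electronic
    energy gap (cm^-1, positive = downhill).

    Marcus-Levich-Jortner form: Poisson-weighted vibronic lines at
    ``n * mode_energy``, each a Gaussian of variance ``2 * reorg_low * kT``
    centred at ``gap = reorg_low + n * mode_energy``, carrying the Marcus
    prefactor ``1/sqrt(4 pi reorg_low kT)``.  Normalized to 1 over the gap
    axis.  Negative gaps (inverted regime) are valid inputs.
    """
    garr = np.asarray(gap, dtype=float)
    if not np.all(np.isfinite(garr)):
        raise ValueError("gap must be finite")
    kt = kbt_cm(p.temperature)
    var2 = 4.0 * p.reorg_low * kt  # denominator 4*lambda*kT
    pref = 1.0 / math.sqrt(math.pi * var2)
    w = _poisson_weights(p.huang_rhys, p.n_max)
    tail = 1.0 - w.sum()
    if tail > 1e-12:
        warnings.warn(
            f"vibronic sum truncated at n_max={p.n_max} leaves Poisson tail mass "
            f"{tail:.3e} > 1e-12; increase n_max",
            stacklevel=2,
        )
    n = np.arange(p.n_max + 1)
    centers = p.reorg_low + n * p.mode_energy
    x = garr[..., None] - centers  # broadcast over gaps
    dens = pref * np.exp(-(x**2) / var2)
    out = np.sum(w * dens, axis=-1)
    return float(out) if garr.ndim == 0 else out


def isc_rate(socme: float, gap_s1_t1: float, p: FCWDParams) -> float:
    """Golden-rule intersystem-crossing rate (s^-1).

    ``k_ISC = 4 pi^2 c * socme^2 * FCWD(gap)`` with the spin-orbit coupling
    matrix element in cm^-1 and the S1-T1 gap in eV (positive when T1 lies
    below S1).  Exactly quadratic in the coupling.
    """
    if socme < 0:
        raise ValueError("SOCME magnitude must be >= 0 cm^-1")
    return _GOLDEN_PREFACTOR * socme * socme * fcwd(ev_to_wavenumber(gap_s1_t1), p)


@dataclass(frozen=True)
class FCWDFit:
    """Result of an FCWD calibration."""

    params: FCWDParams
    residuals: np.ndarray  # log-rate residuals, model - observed
    converged: bool
    cost: float
    free: tuple[str, ...]


_FITTABLE = ("mode_energy", "huang_rhys", "reorg_low")
_FIT_BOUNDS = {  # log10-space bounds keeping parameters physical
    "mode_energy": (math.log10(100.0), math.log10(4000.0)),
    "huang_rhys": (math.log10(1e-3), math.log10(30.0)),
    "reorg_low": (math.log10(10.0), math.log10(10000.0)),
}


def calibrate_fcwd(
    points: Sequence[tuple[float, float, float]],
    fixed: Iterable[str] = (),
    initial: Optional[FCWDParams] = None,
) -> FCWDFit:
    """Fit effective FCWD parameters to observed ISC rates.

    Parameters
    ----------
    points : sequence of (socme_cm1, gap_ev, k_isc_s1)
        Observed triples; at least two with distinct gaps.
    fixed : iterable of str
        Names among ``mode_energy``, ``huang_rhys``, ``reorg_low`` to hold at
        their ``initial`` values.  Temperature and ``n_max`` are always fixed.
    initial : FCWDParams, optional
        Starting point (and values of the fixed fields); defaults to
        ``FCWDParams()``.

    Minimizes ``sum (ln k_model - ln k_obs)^2`` over the free parameters in
    log10 space (positivity by construction), deterministically for a fixed
    starting point.  Non-convergence is flagged on the result, never silent.
    """
    pts = [(float(s), float(g), float(k)) for s, g, k in points]
    if any(k <= 0 or s <= 0 for s, _, k in pts):
        raise ValueError("calibration points need socme > 0 and k_isc > 0")
    gaps = {round(g, 12) for _, g, _ in pts}
    if len(pts) < 2 or len(gaps) < 2:
        raise ValueError("need at least two calibration points with distinct gaps")
    fixed = tuple(fixed)
    unknown = set(fixed) - set(_FITTABLE)
    if unknown:
        raise ValueError(f"cannot fix unknown parameters: {sorted(unknown)}")
    free = tuple(f for f in _FITTABLE if f not in fixed)
    if not free:
        raise ValueError("no free parameters to fit")
    if len(free) > len(pts):
        raise ValueError(f"underdetermined fit: {len(free)} free parameters, {len(pts)} points")
    p0 = initial if initial is not None else FCWDParams()

    # order-invariant objective: sort points canonically
    pts_sorted = sorted(pts)
    obs = np.log([k for _, _, k in pts_sorted])

    def unpack(x: np.ndarray) -> FCWDParams:
        vals = {f: 10.0 ** xi for f, xi in zip(free, x)}
        return replace(p0, **vals)

    def resid(x: np.ndarray) -> np.ndarray:
        p = unpack(x)
        model = np.array([isc_rate(s, g, p) for s, g, _ in pts_sorted])
        return np.log(np.maximum(model, 1e-300)) - obs

    x0 = np.array([math.log10(getattr(p0, f)) for f in free])
    lo = np.array([_FIT_BOUNDS[f][0] for f in free])
    hi = np.array([_FIT_BOUNDS[f][1] for f in free])
    x0 = np.clip(x0, lo, hi)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # truncation warnings during line search
        sol = least_squares(resid, x0, bounds=(lo, hi), method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14)
    fit = FCWDFit(
        params=unpack(sol.x),
        residuals=sol.fun.copy(),
        converged=bool(sol.success),
        cost=float(sol.cost),
        free=free,
    )
    if not fit.converged:
        warnings.warn("FCWD calibration did not converge; inspect fit.residuals", stacklevel=2)
    return fit


def _morse_enhancement(n: int, chi: float) -> float:
    """Density-of-states enhancement of an n-quantum overtone of a Morse
    oscillator relative to the harmonic ladder: level spacing compresses as
    ``omega (1 - 2 chi (k + 1/2))``, so high overtones are easier to reach."""
    out = 1.0
    for k in range(1, n + 1):
        denom = 1.0 - k * chi
        if denom <= 0:  # beyond dissociation; no bound level to accept
            return 0.0
        out /= denom
    return out


def _class_weights(n_target: int, count: int, s_xh: float, chi: float) -> float:
    """Franck-Condon weight for depositing ``n_target`` quanta among ``count``
    identical Morse oscillators (per-oscillator Huang-Rhys ``s_xh``),
    by polynomial convolution of single-oscillator weights."""
    single = np.array(
        [math.exp(-s_xh) * s_xh**j / math.factorial(j) * _morse_enhancement(j, chi) for j in range(n_target + 1)]
    )
    conv = np.array([1.0])
    for _ in range(count):
        conv = np.convolve(conv, single)[: n_target + 1]
    return float(conv[n_target]) if n_target < len(conv) else 0.0


def ic_rate_xh(
    gap_s1_s0: float,
    nacme: float,
    modes: XHModeSet,
    temperature: float = 298.15,
    s_xh: float = 0.05,
) -> float:
    """Internal-conversion rate (s^-1) in the X-H promoting-mode model.

    The S1 -> S0 electronic gap is deposited into ``n = round(gap/frequency)``
    stretching quanta of each X-H mode class (n at least 1); the
    Franck-Condon weight of that overtone is the convolution of
    single-oscillator displaced-Morse factors over the class's ``count``
    equivalent bonds.  The electronic matrix element is the nonadiabatic
    coupling; per class the effective coupling is ``nacme * frequency`` so

    ``k_IC = 4 pi^2 c nacme^2 * sum_c frequency_c * F_c(n_c)``.

    In the harmonic limit (anharmonicity -> 0) the class weight reduces to the
    analytic Poisson factor ``exp(-m S) (m S)^n / n!``.  Thermal occupation of
    X-H stretches is negligible below ~1000 K (hbar*omega >> kT) and is not
    modeled; ``temperature`` is validated for interface consistency.

    Monotone non-increasing in the gap at fixed modes (energy-gap law).
    """
    if gap_s1_s0 <= 0:
        raise ValueError("S1-S0 gap must be > 0 eV")
    if nacme < 0:
        raise ValueError("NACME magnitude must be >= 0 a.u.")
    if temperature <= 0:
        raise ValueError("temperature must be > 0 K")
    if not (0 < s_xh < 1):
        raise ValueError("per-bond Huang-Rhys factor s_xh must be in (0, 1)")
    if nacme == 0.0:
        return 0.0
    if len(modes) == 0 or all(m.count == 0 for m in modes.entries):
        raise ValueError("no accepting X-H modes supplied for a nonzero NACME")
    gap_cm = float(ev_to_wavenumber(gap_s1_s0))
    total = 0.0
    for m in modes.entries:
        if m.count == 0:
            continue
        n = max(1, round(gap_cm / m.frequency))
        total += m.frequency * _class_weights(n, m.count, s_xh, m.anharmonicity)
    return _GOLDEN_PREFACTOR * nacme * nacme * total


class MissingDataError(ValueError):
    """A descriptor lacks fields required for a requested rate."""


def compute_rates(
    d: EmitterDescriptor,
    p: Optional[FCWDParams] = None,
    *,
    prefer_supplied: bool = True,
    s_xh: float = 0.05,
) -> RateSet:
    """Assemble the three S1 decay channels for one emitter.

    For each channel, an externally supplied value (typically carried over
    from a higher-level calculation, as in the packaged benchmark emitters)
    is used when present and ``prefer_supplied`` is true, and tagged with
    provenance ``"supplied"``.  Otherwise:

    * ``k_r`` is computed from E(S1) and f at the S1-optimized geometry
      (Strickler-Berg);
    * ``k_isc`` is the golden-rule rate from the descriptor's SOCME and the
      S1-T1 gap at the S1-opt geometry, with FCWD parameters ``p``;
    * ``k_ic`` is computed from NACME and the X-H inventory when both are
      present, else falls back to a supplied value even under
      ``prefer_supplied=False``.  With no source at all, an error — never a
      silent default.
    """
    if p is None:
        p = FCWDParams()
    ctx = d.context(S1_OPT)
    missing = []
    if ctx is None:
        missing.append(f"context {S1_OPT!r}")
        s1 = t1 = None
    else:
        s1 = ctx.state("S1")
        t1 = ctx.state("T1")
        if s1 is None:
            missing.append("S1 energy at S1-opt")
        elif s1.oscillator_strength is None:
            missing.append("S1 oscillator strength at S1-opt")
        if t1 is None:
            missing.append("T1 energy at S1-opt")
    if missing:
        raise MissingDataError(f"{d.name}: cannot compute rates; missing {', '.join(missing)}")

    supplied = d.supplied_rates.present() if d.supplied_rates is not None else {}

    prov = {}
    if prefer_supplied and "k_r" in supplied:
        k_r = supplied["k_r"]
        prov["k_r"] = "supplied"
    else:
        k_r = strickler_berg_rate(s1.energy, s1.oscillator_strength)
        prov["k_r"] = "computed"

    if prefer_supplied and "k_isc" in supplied:
        k_isc = supplied["k_isc"]
        prov["k_isc"] = "supplied"
    else:
        k_isc = isc_rate(d.socme_s1_t1, s1.energy - t1.energy, p)
        prov["k_isc"] = "computed"

    can_compute_ic = d.nacme is not None and d.xh_modes
    if "k_ic" in supplied and (prefer_supplied or not can_compute_ic):
        k_ic = supplied["k_ic"]
        prov["k_ic"] = "supplied"
    elif can_compute_ic:
        k_ic = ic_rate_xh(s1.energy, d.nacme, XHModeSet(d.xh_modes), p.temperature, s_xh=s_xh)
        prov["k_ic"] = "computed"
    else:
        raise MissingDataError(
            f"{d.name}: no source for k_ic (need NACME + X-H modes, or a supplied value)"
        )
    return RateSet(k_r=k_r, k_isc=k_isc, k_ic=k_ic, provenance=prov)
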