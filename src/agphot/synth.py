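"""Deterministic synthetic fixtures: emitter descriptors whose ISC rates are
manufactured from a known FCWD (so calibration can be closed-loop tested) and
toy cluster/ligand structure pairs with controlled per-subset jitter.

Defaults emulate the regime of few-atom silver clusters stabilized by DNA:
S1 emission between ~1.6 and 2.6 eV, S1-T1 gaps of 0.2-0.4 eV, SOCMEs of a
few cm^-1, oscillator strengths near 1.
"""

from __future__ import annotations

import math

from dataclasses import dataclass, field

import numpy as np

from .descriptors import (
    ElectronicState,
    EmitterDescriptor,
    GeometryContext,
    RateSet,
)
from .rates import DEFAULT_XH_MODES, FCWDParams, isc_rate
from .structures import Structure

__all__ = ["GeneratorSpec", "gen_descriptors", "gen_toy_cluster", "DEFAULT_NACME"]

#: Effective S1-S0 nonadiabatic coupling magnitude (a.u.) assigned to
#: generated emitters; with the default X-H inventory it puts k_IC on the
#: 10^5-10^7 s^-1 scale typical when the transition is localized away from
#: the X-H bonds.
DEFAULT_NACME = 5.0e-4


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the descriptor generator (all ranges closed)."""

    seed: int = 17
    n_emitters: int = 8
    gap_range: tuple[float, float] = (0.2, 0.4)  # eV, S1-T1
    socme_range: tuple[float, float] = (2.0, 4.1)  # cm^-1
    f_range: tuple[float, float] = (0.8, 1.35)
    e_s1_range: tuple[float, float] = (1.6, 2.6)  # eV at the S1-opt geometry
    fcwd_truth: FCWDParams = field(default_factory=FCWDParams)

    def __post_init__(self) -> None:
        if self.n_emitters < 1:
            raise ValueError("n_emitters must be >= 1")
        for name in ("gap_range", "socme_range", "f_range", "e_s1_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be a positive non-empty interval")


def gen_descriptors(spec: GeneratorSpec) -> list[EmitterDescriptor]:
    """Generate emitters whose supplied k_ISC values come from
    ``spec.fcwd_truth`` (closed loop: feeding the drawn SOCME and gap back
    through :func:`agphot.rates.isc_rate` with the truth parameters
    reproduces the supplied rate exactly).  Byte-identical under a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    out = []
    for i in range(spec.n_emitters):
        gap = float(rng.uniform(*spec.gap_range))
        socme = float(rng.uniform(*spec.socme_range))
        f = float(rng.uniform(*spec.f_range))
        e_s1 = float(rng.uniform(*spec.e_s1_range))
        e_t1 = e_s1 - gap
        # rate from the gap exactly as a consumer will reconstruct it from the
        # stored energies, so the closed loop is bit-exact
        k_isc = isc_rate(socme, e_s1 - e_t1, spec.fcwd_truth)
        # S0-geometry block: vertical energies sit ~0.5 eV above the relaxed
        # emission values, mirroring a modest excited-state relaxation.
        e_s1_vert = e_s1 + 0.5
        d = EmitterDescriptor(
            name=f"SYN{i:02d}-seed{spec.seed}",
            contexts=(
                GeometryContext(
                    tag="S0-opt",
                    states=(
                        ElectronicState(label="T1", energy=e_s1_vert - gap - 0.1),
                        ElectronicState(
                            label="S1", energy=e_s1_vert, oscillator_strength=round(f * 0.7, 4)
                        ),
                    ),
                ),
                GeometryContext(
                    tag="S1-opt",
                    states=(
                        ElectronicState(label="T1", energy=e_t1),
                        ElectronicState(label="S1", energy=e_s1, oscillator_strength=f),
                    ),
                ),
            ),
            socme_s1_t1=socme,
            nacme=DEFAULT_NACME,
            xh_modes=DEFAULT_XH_MODES.entries,
            supplied_rates=RateSet(k_isc=k_isc, provenance={"k_isc": "supplied"}),
        )
        out.append(d)
    return out


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform proper rotation via QR of a Gaussian matrix."""
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def gen_toy_cluster(
    n_core: int = 16,
    n_ligand: int = 30,
    seed: int = 17,
    sigma_core: float = 0.0,
    sigma_ligand: float = 0.0,
) -> tuple[Structure, Structure]:
    """A reference metal-core/ligand-shell structure and a copy moved by a
    known rigid transform with independent isotropic Gaussian jitter on the
    core (``sigma_core`` Å) and ligand (``sigma_ligand`` Å) subsets.

    Both structures carry ``"core"`` and ``"ligand"`` selections; atoms are
    Ag for the core and C/N/O for the shell.  Deterministic under ``seed``.
    """
    if n_core < 3:
        raise ValueError("n_core must be >= 3 (superposition needs 3 atoms)")
    rng = np.random.default_rng(seed)
    # rejection-sample core positions with a ~2.6 Å minimum separation so
    # nearest-neighbour distances look like metal-metal bonds
    core_pts: list[np.ndarray] = []
    box = 1.2 * (3.0 * n_core) ** (1.0 / 3.0)
    while len(core_pts) < n_core:
        cand = rng.uniform(-box, box, size=3)
        if all(np.linalg.norm(cand - q) >= 2.6 for q in core_pts):
            core_pts.append(cand)
    core = np.array(core_pts)
    shell_dir = rng.standard_normal((n_ligand, 3))
    shell_dir /= np.linalg.norm(shell_dir, axis=1, keepdims=True)
    r_in = math.sqrt(3.0) * box + 2.5  # shell clear of the core's corners
    shell = shell_dir * rng.uniform(r_in, r_in + 3.0, size=(n_ligand, 1))
    coords = np.vstack([core, shell])
    elements = ["Ag"] * n_core + [("C", "N", "O")[i % 3] for i in range(n_ligand)]
    sel = {"core": tuple(range(n_core)), "ligand": tuple(range(n_core, n_core + n_ligand))}
    ref = Structure(elements=list(elements), coords=coords.copy(), name=f"toy-ref-seed{seed}",
                    selections=dict(sel))
    R = _random_rotation(rng)
    t = rng.uniform(-5.0, 5.0, size=3)
    moved = coords @ R.T + t
    moved[: n_core] += sigma_core * rng.standard_normal((n_core, 3))
    moved[n_core:] += sigma_ligand * rng.standard_normal((n_ligand, 3))
    mob = Structure(elements=list(elements), coords=moved, name=f"toy-mobile-seed{seed}",
                    selections=dict(sel))
    return ref, mob
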