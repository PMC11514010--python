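"""Structure comparison and geometry reporting.

Utilities for validating computed cluster geometries against reference
structures: subset RMSD by Kabsch least-squares superposition, metal-metal /
metal-halide bond tables, and donor-acceptor contact (hydrogen-bond)
geometry.  Atom correspondence is always by list order or explicit selection;
no distance-based assignment is attempted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "Structure",
    "SuperpositionResult",
    "read_structure",
    "write_structure",
    "superpose",
    "rmsd_report",
    "bond_table",
    "contact_report",
]

_ELEMENTS = frozenset(
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co Ni Cu Zn "
    "Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te I Xe Cs Ba La "
    "Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re Os Ir Pt Au Hg Tl Pb Bi Po "
    "At Rn Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf Es Fm Md No Lr".split()
)

Selection = Union[str, Sequence[int]]


@dataclass
class Structure:
    """Element-labeled Cartesian coordinates (Å) with named atom subsets.

    ``atom_meta`` optionally carries per-atom PDB metadata (chain, residue
    name/number, atom name, serial) for selection building; selections are
    0-based index tuples.
    """

    elements: list[str]
    coords: np.ndarray
    name: str = ""
    selections: dict[str, tuple[int, ...]] = field(default_factory=dict)
    atom_meta: Optional[list[dict]] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.elements) != len(self.coords):
            raise ValueError("elements and coordinates differ in length")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        bad = sorted({e for e in self.elements if e not in _ELEMENTS})
        if bad:
            raise ValueError(f"unknown element symbols: {bad}")
        for label, idx in self.selections.items():
            self._check_indices(label, idx)
            self.selections[label] = tuple(idx)

    def _check_indices(self, label: str, idx: Sequence[int]) -> None:
        n = len(self.coords)
        if len(set(idx)) != len(idx):
            raise ValueError(f"selection {label!r} repeats atom indices")
        if any(i < 0 or i >= n for i in idx):
            raise ValueError(f"selection {label!r} has indices outside [0, {n})")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def add_selection(self, label: str, indices: Sequence[int]) -> None:
        self._check_indices(label, indices)
        self.selections[label] = tuple(indices)

    def select_element(self, *symbols: str) -> tuple[int, ...]:
        """Indices of all atoms whose element is among ``symbols``."""
        want = set(symbols)
        unknown = want - _ELEMENTS
        if unknown:
            raise ValueError(f"unknown element symbols: {sorted(unknown)}")
        return tuple(i for i, e in enumerate(self.elements) if e in want)

    def resolve(self, selection: Selection) -> tuple[int, ...]:
        """Turn a selection label or an index sequence into index tuple."""
        if isinstance(selection, str):
            if selection not in self.selections:
                raise KeyError(
                    f"structure {self.name!r} has no selection {selection!r}; "
                    f"known: {sorted(self.selections)}"
                )
            return self.selections[selection]
        idx = tuple(int(i) for i in selection)
        self._check_indices("<inline>", idx)
        return idx


def _read_xyz(path: Path) -> Structure:
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty XYZ file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise ValueError(f"{path}:1: expected an atom count") from exc
    if len(lines) < n + 2:
        raise ValueError(f"{path}: header declares {n} atoms but file has {len(lines) - 2} records")
    name = lines[1].strip()
    elements, coords = [], []
    for ln in range(2, 2 + n):
        parts = lines[ln].split()
        if len(parts) < 4:
            raise ValueError(f"{path}:{ln + 1}: malformed XYZ record {lines[ln]!r}")
        sym = parts[0].capitalize()
        try:
            xyz = [float(v) for v in parts[1:4]]
        except ValueError as exc:
            raise ValueError(f"{path}:{ln + 1}: non-numeric coordinate in {lines[ln]!r}") from exc
        elements.append(sym)
        coords.append(xyz)
    return Structure(elements=elements, coords=np.array(coords), name=name or path.stem)


def _read_pdb(path: Path) -> Structure:
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    model = next(parser.get_structure(path.stem, str(path)).get_models())
    elements, coords, meta = [], [], []
    saw_altloc = False
    for chain in model:
        for residue in chain:
            for atom in residue:
                if atom.is_disordered():
                    saw_altloc = True
                    atom = atom.disordered_get_list()[0]  # keep first altloc
                sym = (atom.element or atom.get_name()[:1]).capitalize()
                elements.append(sym)
                coords.append(atom.coord.astype(float))
                het, resseq, icode = residue.id
                meta.append(
                    {
                        "chain": chain.id,
                        "resname": residue.get_resname(),
                        "resseq": resseq,
                        "icode": icode.strip(),
                        "atom_name": atom.get_name(),
                        "serial": atom.get_serial_number(),
                    }
                )
    if saw_altloc:
        warnings.warn(f"{path}: alternate locations present; first altloc kept", stacklevel=3)
    return Structure(elements=elements, coords=np.array(coords), name=path.stem, atom_meta=meta)


def read_structure(path, format: Optional[str] = None) -> Structure:
    """Read an XYZ or PDB file (format inferred from the suffix by default)."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "xyz":
        return _read_xyz(path)
    if fmt == "pdb":
        return _read_pdb(path)
    raise ValueError(f"unsupported structure format {fmt!r} (use 'xyz' or 'pdb')")


def write_structure(s: Structure, path) -> None:
    """Write a structure as XYZ (4 decimals, ~1e-4 Å round-trip precision)."""
    path = Path(path)
    lines = [str(s.n_atoms), s.name]
    for e, (x, y, z) in zip(s.elements, s.coords):
        lines.append(f"{e} {x:.4f} {y:.4f} {z:.4f}")
    path.write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid-body fit of one ordered point set onto another."""

    rotation: np.ndarray  # 3x3, proper orthogonal
    translation: np.ndarray  # applied after rotation
    rmsd: float
    n_atoms: int
    degenerate: bool = False  # near-collinear/planar-rank-deficient input

    def transform(self, coords: np.ndarray) -> np.ndarray:
        """Apply the fitted transform to any coordinate array."""
        return coords @ self.rotation.T + self.translation


def superpose(mobile: Structure, target: Structure, selection: Selection) -> SuperpositionResult:
    """Kabsch superposition of ``mobile`` onto ``target`` over a selection.

    Correspondence is positional: the i-th selected mobile atom maps to the
    i-th selected target atom.  Returns the proper rotation (determinant +1,
    sign-corrected via the SVD), translation and the RMSD over the selection
    after the fit.  Rank-deficient (collinear) selections are solved the same
    way and flagged ``degenerate``.
    """
    mi = mobile.resolve(selection)
    ti = target.resolve(selection)
    if len(mi) != len(ti):
        raise ValueError(f"selection sizes differ: {len(mi)} (mobile) vs {len(ti)} (target)")
    if len(mi) < 3:
        raise ValueError(f"superposition needs >= 3 atoms, got {len(mi)}")
    P = mobile.coords[list(mi)]
    Q = target.coords[list(ti)]
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    degenerate = bool(S[-1] < 1e-8 * max(S[0], 1.0))
    t = qc - R @ pc
    moved = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_atoms=len(mi),
                               degenerate=degenerate)


def rmsd_report(mobile: Structure, target: Structure, selections: Sequence[str]) -> pd.DataFrame:
    """Per-selection RMSD table; each subset is superposed independently
    (subset RMSDs are not derived from a single global fit)."""
    rows = []
    for label in selections:
        res = superpose(mobile, target, label)
        rows.append({"selection": label, "n_atoms": res.n_atoms, "rmsd": res.rmsd})
    return pd.DataFrame(rows, columns=["selection", "n_atoms", "rmsd"])


def bond_table(s: Structure, pair: tuple[str, str], cutoff: float) -> list[tuple[int, int, float]]:
    """All unordered atom pairs of the two elements within ``cutoff`` Å
    (closed boundary), each pair once (i < j), sorted by distance."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0 Å")
    a, b = pair
    ia = s.select_element(a)
    ib = s.select_element(b)
    seen = set()
    out = []
    for i in ia:
        for j in ib:
            if i == j:
                continue
            key = (min(i, j), max(i, j))
            if key in seen:
                continue
            seen.add(key)
            d = float(np.linalg.norm(s.coords[i] - s.coords[j]))
            if d <= cutoff:
                out.append((key[0], key[1], d))
    out.sort(key=lambda r: (r[2], r[0], r[1]))
    return out


def contact_report(
    s: Structure,
    donors: Selection,
    acceptors: Selection,
    d_max: float,
    angle_min: Optional[float] = None,
) -> list[dict]:
    """Donor-acceptor contacts with distance <= d_max Å (closed boundary).

    When ``angle_min`` (degrees) is given, hydrogens covalently attached to
    each donor (within 1.25 Å) must realize a D-H...A angle at the hydrogen of
    at least ``angle_min``; an error is raised if no donor carries a hydrogen.
    Distances are reported to 0.01 Å.
    """
    di = s.resolve(donors)
    ai = s.resolve(acceptors)
    if not di or not ai:
        raise ValueError("donor and acceptor selections must be non-empty")
    if d_max <= 0:
        raise ValueError("d_max must be > 0 Å")
    h_idx = s.select_element("H")
    attached: dict[int, list[int]] = {}
    if angle_min is not None:
        for d in di:
            hs = [h for h in h_idx if np.linalg.norm(s.coords[h] - s.coords[d]) <= 1.25]
            if hs:
                attached[d] = hs
        if not attached:
            raise ValueError("angle criterion requested but no donor carries a hydrogen")
    out = []
    for d in di:
        for a in ai:
            if d == a:
                continue
            dist = float(np.linalg.norm(s.coords[d] - s.coords[a]))
            if dist > d_max:
                continue
            angle = None
            if angle_min is not None:
                best = None
                for h in attached.get(d, []):
                    v1 = s.coords[d] - s.coords[h]
                    v2 = s.coords[a] - s.coords[h]
                    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                    ang = math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))
                    best = ang if best is None else max(best, ang)
                if best is None or best < angle_min:
                    continue
                angle = round(best, 1)
            out.append(
                {"donor": d, "acceptor": a, "distance": round(dist, 2), "angle": angle}
            )
    out.sort(key=lambda r: (r["distance"], r["donor"], r["acceptor"]))
    return out
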