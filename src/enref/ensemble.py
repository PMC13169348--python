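"""Core ensemble data model, multi-structure XYZ I/O, and geometry descriptors.

A :class:`Conformer` is one structure of a flexible molecule; an
:class:`Ensemble` is the ordered collection produced by a conformational
search (CREST, GOAT, ...). Energies are stored in kcal/mol, coordinates in Å,
rotational constants in MHz.

XYZ comment lines that parse as a single real number are interpreted as
electronic energies in Hartree — the convention of the common semiempirical
ensemble generators — and converted to kcal/mol on input.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem
from scipy.spatial.distance import pdist, squareform

from .errors import DataError, StructureError, XYZParseError
from .units import CM1_TO_MHZ, PLANCK, UA2_TO_KGM2, hartree_to_kcal

__all__ = [
    "Conformer",
    "Ensemble",
    "read_xyz_ensemble",
    "write_xyz_ensemble",
    "distance_matrix",
    "rotational_constants",
    "atomic_mass",
]

_PT = Chem.GetPeriodicTable()

#: moments of inertia below this (u·Å²) are treated as zero (linear/atomic tops)
_INERTIA_TOL = 1e-6

# our own writer's comment convention: "E=<v> kcal/mol idx=<n>" / "G=<v> ..."
_COMMENT_RE = re.compile(r"^\s*([EG])=(-?\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)\s+kcal/mol")


def atomic_mass(symbol: str) -> float:
    """Most-common-isotope mass (u) for an element symbol."""
    num = _PT.GetAtomicNumber(symbol)
    if num == 0:
        raise DataError(f"unknown element symbol {symbol!r}")
    return _PT.GetMostCommonIsotopeMass(symbol)


@dataclass
class Conformer:
    """One conformer: geometry plus the per-structure quantities the filters use.

    Attributes
    ----------
    symbols : list of element symbols, length n_atoms
    coords : (n_atoms, 3) Cartesian coordinates, Å
    e_el : electronic energy, kcal/mol (None until a calculator supplies it)
    gibbs : Gibbs free energy, kcal/mol (None unless frequencies were computed)
    frequencies : harmonic wavenumbers, cm⁻¹
    b_norm : scalar norm of the rotational-constant vector, MHz
    degeneracy : Boltzmann degeneracy g_i (≥ 1)
    population : fractional Boltzmann population, in [0, 1]
    active : whether the conformer survives the filters applied so far
    index : original position in the input ensemble (0-based, stable)
    """

    symbols: list[str]
    coords: np.ndarray
    e_el: float | None = None
    gibbs: float | None = None
    frequencies: np.ndarray | None = None
    b_norm: float | None = None
    degeneracy: int = 1
    population: float | None = None
    active: bool = True
    index: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.symbols), 3):
            raise StructureError(
                f"coords shape {self.coords.shape} does not match "
                f"{len(self.symbols)} atom symbols"
            )
        if self.degeneracy < 1:
            raise DataError("degeneracy must be a positive integer")
        if self.b_norm is not None and self.b_norm < 0:
            raise DataError("b_norm must be non-negative")
        if self.population is not None and not (0.0 <= self.population <= 1.0):
            raise DataError("population must lie in [0, 1]")

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    def energy(self, use_gibbs: bool) -> float:
        """The energy the filters compare: G when requested, else E_el."""
        e = self.gibbs if use_gibbs else self.e_el
        if e is None:
            kind = "Gibbs free energy" if use_gibbs else "electronic energy"
            raise DataError(f"conformer {self.index} has no {kind}")
        return e

    def copy(self) -> "Conformer":
        return Conformer(
            symbols=list(self.symbols),
            coords=self.coords.copy(),
            e_el=self.e_el,
            gibbs=self.gibbs,
            frequencies=None if self.frequencies is None else np.array(self.frequencies),
            b_norm=self.b_norm,
            degeneracy=self.degeneracy,
            population=self.population,
            active=self.active,
            index=self.index,
        )


@dataclass
class Ensemble:
    """Ordered conformer collection with a temperature and a provenance log."""

    conformers: list[Conformer]
    temperature: float = 298.15
    step_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.conformers:
            raise StructureError("an ensemble needs at least one conformer")
        ref = self.conformers[0].symbols
        for i, c in enumerate(self.conformers):
            if c.symbols != ref:
                raise StructureError(
                    f"conformer {i} atom sequence differs from conformer 0"
                )

    def __len__(self) -> int:
        return len(self.conformers)

    def __iter__(self):
        return iter(self.conformers)

    @property
    def active(self) -> list[Conformer]:
        return [c for c in self.conformers if c.active]

    @property
    def n_active(self) -> int:
        return sum(1 for c in self.conformers if c.active)

    def log(self, entry: dict) -> None:
        self.step_log.append(entry)


def read_xyz_ensemble(path: str | Path) -> Ensemble:
    """Read a multi-structure XYZ file into an :class:`Ensemble`.

    Each frame is an atom-count line, a free-format comment line, and the
    coordinate block. A comment line that is a single real number is stored as
    the electronic energy in Hartree (converted to kcal/mol); the
    ``E=<v> kcal/mol`` / ``G=<v> kcal/mol`` convention written by
    :func:`write_xyz_ensemble` is also recognised.
    """
    lines = Path(path).read_text().splitlines()
    conformers: list[Conformer] = []
    i, frame = 0, 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise XYZParseError(
                f"frame {frame}: expected atom count, got {lines[i]!r}"
            ) from exc
        if i + 1 + n >= len(lines) + 1:
            raise XYZParseError(f"frame {frame}: truncated (declared {n} atoms)")
        comment = lines[i + 1]
        symbols: list[str] = []
        coords = np.empty((n, 3))
        for j in range(n):
            parts = lines[i + 2 + j].split()
            if len(parts) < 4:
                raise XYZParseError(
                    f"frame {frame}: atom line {j} has {len(parts)} fields, need 4"
                )
            symbols.append(parts[0])
            try:
                coords[j] = [float(p) for p in parts[1:4]]
            except ValueError as exc:
                raise XYZParseError(
                    f"frame {frame}: non-numeric coordinate on atom line {j}"
                ) from exc
        e_el = gibbs = None
        m = _COMMENT_RE.match(comment)
        if m:
            val = float(m.group(2))
            if m.group(1) == "G":
                gibbs = val
            else:
                e_el = val
        else:
            try:
                e_el = hartree_to_kcal(float(comment.strip()))
            except ValueError:
                pass
        conformers.append(
            Conformer(symbols=symbols, coords=coords, e_el=e_el, gibbs=gibbs, index=frame)
        )
        i += 2 + n
        frame += 1
    if not conformers:
        raise XYZParseError(f"{path}: no XYZ frames found")
    return Ensemble(conformers=conformers)


def write_xyz_ensemble(
    ens: Ensemble, path: str | Path, active_only: bool = True
) -> None:
    """Write an ensemble to a multi-structure XYZ file.

    The comment line carries ``G=<v> kcal/mol idx=<n>`` when a Gibbs energy is
    present, ``E=<v> kcal/mol idx=<n>`` when only the electronic energy is, or
    just ``idx=<n>``. Round-trips preserve symbols exactly and coordinates to
    better than 1e-6 Å.
    """
    confs = ens.active if active_only else list(ens.conformers)
    if not confs:
        raise DataError("refusing to write an ensemble with no active conformers")
    out = []
    for c in confs:
        if c.gibbs is not None:
            comment = f"G={c.gibbs:.8f} kcal/mol idx={c.index}"
        elif c.e_el is not None:
            comment = f"E={c.e_el:.8f} kcal/mol idx={c.index}"
        else:
            comment = f"idx={c.index}"
        out.append(str(c.n_atoms))
        out.append(comment)
        for sym, (x, y, z) in zip(c.symbols, c.coords):
            out.append(f"{sym:<3s} {x:18.10f} {y:18.10f} {z:18.10f}")
    Path(path).write_text("\n".join(out) + "\n")


def distance_matrix(conf: Conformer, include_hydrogens: bool = True) -> np.ndarray:
    """Symmetric Euclidean interatomic distance matrix (Å).

    With ``include_hydrogens=False`` hydrogen rows/columns are removed, which
    focuses downstream eigenvalue descriptors on the heavy-atom skeleton. The
    matrix is invariant under rigid translation and rotation.
    """
    coords = conf.coords
    if not include_hydrogens:
        keep = [i for i, s in enumerate(conf.symbols) if s != "H"]
        coords = coords[keep]
    if coords.shape[0] < 2:
        raise StructureError(
            f"conformer {conf.index}: fewer than 2 atoms remain for a distance matrix"
        )
    return squareform(pdist(coords))


def _moments_of_inertia(conf: Conformer) -> np.ndarray:
    """Principal moments of inertia, u·Å², sorted ascending."""
    masses = np.array([atomic_mass(s) for s in conf.symbols])
    coords = conf.coords - np.average(conf.coords, axis=0, weights=masses)
    x, y, z = coords.T
    ixx = np.sum(masses * (y**2 + z**2))
    iyy = np.sum(masses * (x**2 + z**2))
    izz = np.sum(masses * (x**2 + y**2))
    ixy = -np.sum(masses * x * y)
    ixz = -np.sum(masses * x * z)
    iyz = -np.sum(masses * y * z)
    tensor = np.array([[ixx, ixy, ixz], [ixy, iyy, iyz], [ixz, iyz, izz]])
    return np.linalg.eigvalsh(tensor)


def rotational_constants(conf: Conformer) -> tuple[np.ndarray, float]:
    """Rotational constants B_k = h/(8π²I_k) in MHz, plus their scalar norm.

    Linear molecules have one vanishing moment and yield two finite constants;
    the norm is taken over the finite components. A single atom has no
    rotational structure and returns ``B_norm = 0`` by convention.
    """
    if conf.n_atoms < 2:
        return np.zeros(0), 0.0
    moments = _moments_of_inertia(conf)
    finite = moments[moments > _INERTIA_TOL]
    if finite.size == 0:
        return np.zeros(0), 0.0
    b_hz = PLANCK / (8.0 * np.pi**2 * finite * UA2_TO_KGM2)
    b_mhz = b_hz / 1e6
    return b_mhz, float(np.linalg.norm(b_mhz))


def moments_of_inertia(conf: Conformer) -> np.ndarray:
    """Principal moments of inertia (u·Å², ascending); zeros dropped by callers."""
    if conf.n_atoms < 2:
        return np.zeros(0)
    return _moments_of_inertia(conf)


def molecular_mass(conf: Conformer) -> float:
    """Total molecular mass, u (most-common isotopes)."""
    return float(sum(atomic_mass(s) for s in conf.symbols))
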