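"""Molecular structures, atomic property tables and reactivity indices.

A :class:`Molecule` is an ordered, element-labelled 3D point set — the unit
every descriptor in this package consumes.  Structures are read from plain
XYZ files or from the atom block of MOL/SDF V2000 records; coordinates are
always interpreted as angstroms.  Per-element weighting properties (mass,
van der Waals volume, polarizability, electronegativity, logP contribution,
polar surface area, refractivity, hardness and softness) ship as CSV tables
under ``catqspr/data/properties``; Gasteiger–Marsili partial charges are
molecule-dependent and are computed by :func:`gasteiger_charges`.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np

from .errors import (
    DomainError,
    ParameterizationError,
    PropertyLookupError,
    StructureParseError,
)

__all__ = [
    "Atom",
    "Molecule",
    "AtomicPropertyTable",
    "GeometryErrorReport",
    "PROPERTY_IDS",
    "load_property_tables",
    "property_lookup",
    "covalent_radii",
    "read_structure",
    "write_xyz",
    "gasteiger_charges",
    "electrophilicity",
    "geometry_error_metrics",
]

# Elements 1-103; membership defines a "recognized symbol".
ELEMENTS = frozenset(
    """H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co
    Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te
    I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re Os Ir
    Pt Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf Es Fm Md No
    Lr""".split()
)

#: Transition metals appearing in the catalyst dataset.
METALS = frozenset({"Ru", "Rh", "Os", "Ir"})

#: Valid atomic weighting property identifiers.
PROPERTY_IDS = ("m", "v", "p", "e", "a", "c", "psa", "r", "h", "s")


@dataclass(frozen=True)
class Atom:
    """One atom: element symbol, Cartesian position in angstroms, formal charge."""

    element: str
    position: np.ndarray
    formal_charge: int = 0

    def __post_init__(self):
        if self.element not in ELEMENTS:
            raise StructureParseError(f"unknown element symbol {self.element!r}")
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"position must be a finite 3-vector, got {pos!r}")
        object.__setattr__(self, "position", pos)


@dataclass
class Molecule:
    """Element-labelled 3D point set; atom order defines all matrix indexing."""

    id: str
    atoms: list[Atom]
    total_charge: int = 0

    def __post_init__(self):
        if not self.atoms:
            raise ValueError("a Molecule needs at least one atom")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in angstroms."""
        return np.stack([a.position for a in self.atoms])

    def distance_matrix(self) -> np.ndarray:
        xyz = self.coords
        diff = xyz[:, None, :] - xyz[None, :, :]
        return np.sqrt((diff**2).sum(axis=-1))

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None,
                    permutation: Sequence[int] | None = None,
                    id_suffix: str = "_t") -> "Molecule":
        """Rigidly transformed and/or atom-permuted copy (testing invariances)."""
        xyz = self.coords
        if rotation is not None:
            xyz = xyz @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            xyz = xyz + np.asarray(translation, dtype=float)
        order = range(self.n_atoms) if permutation is None else permutation
        atoms = [Atom(self.atoms[i].element, xyz[i], self.atoms[i].formal_charge)
                 for i in order]
        return Molecule(self.id + id_suffix, atoms, self.total_charge)


def canonical_orientation(mol: Molecule) -> Molecule:
    """Center a molecule at its centroid and rotate onto its principal axes.

    Minkowski metrics of order p != 2 (and Chebyshev) depend on the
    coordinate frame, so the descriptor pipeline evaluates them in this
    canonical frame to make every descriptor invariant under rigid motion.
    Axes are the eigenvectors of the coordinate covariance, ordered by
    descending variance; axis signs are irrelevant for metrics built from
    absolute coordinate differences.  Molecules with degenerate principal
    moments (exactly symmetric tops) have an ambiguous frame; random and
    real catalyst geometries are generically non-degenerate.
    """
    xyz = mol.coords - mol.coords.mean(axis=0)
    cov = xyz.T @ xyz
    w, v = np.linalg.eigh(cov)
    axes = v[:, ::-1]  # descending variance
    new = xyz @ axes
    atoms = [Atom(a.element, p, a.formal_charge)
             for a, p in zip(mol.atoms, new)]
    return Molecule(mol.id, atoms, mol.total_charge)


# ---------------------------------------------------------------------------
# Atomic property tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AtomicPropertyTable:
    """Per-element values of one weighting property (units fixed per property)."""

    property_id: str
    values: Mapping[str, float]

    def __post_init__(self):
        if self.property_id not in PROPERTY_IDS:
            raise PropertyLookupError(
                f"unknown property id {self.property_id!r}; "
                f"valid ids: {PROPERTY_IDS}")
        if self.property_id in ("m", "v", "p"):
            bad = {e: v for e, v in self.values.items() if v <= 0}
            if bad:
                raise ValueError(
                    f"property {self.property_id!r} must be strictly positive, "
                    f"got {bad}")


def _data_text(name: str) -> str:
    return resources.files("catqspr.data").joinpath(name).read_text()


def _read_element_csv(text: str) -> dict[str, float]:
    reader = csv.DictReader(io.StringIO(text))
    return {row["element"]: float(row["value"]) for row in reader}


_TABLE_CACHE: dict[str, AtomicPropertyTable] | None = None


def load_property_tables() -> dict[str, AtomicPropertyTable]:
    """Load the packaged per-element tables for every tabulated property.

    Property ``c`` (Gasteiger–Marsili charge) is molecule-dependent and has
    no table; request it through :func:`gasteiger_charges`.
    """
    global _TABLE_CACHE
    if _TABLE_CACHE is None:
        tables = {}
        for pid in PROPERTY_IDS:
            if pid == "c":
                continue
            values = _read_element_csv(_data_text(f"properties/{pid}.csv"))
            tables[pid] = AtomicPropertyTable(pid, values)
        _TABLE_CACHE = tables
    return _TABLE_CACHE


def property_lookup(tables: Mapping[str, AtomicPropertyTable],
                    element: str, property_id: str) -> float:
    """Tabulated value of ``property_id`` for ``element``.

    Raises :class:`PropertyLookupError` identifying both keys when the pair
    is not tabulated, and redirects property ``c`` to the charge routine.
    """
    if property_id == "c":
        raise PropertyLookupError(
            "property 'c' (Gasteiger-Marsili charge) is molecule-dependent; "
            "use gasteiger_charges()")
    if property_id not in PROPERTY_IDS:
        raise PropertyLookupError(
            f"unknown property id {property_id!r} (element {element!r})")
    table = tables[property_id]
    try:
        return table.values[element]
    except KeyError:
        raise PropertyLookupError(
            f"no tabulated value for element {element!r}, "
            f"property {property_id!r}") from None


def covalent_radii() -> dict[str, float]:
    """Packaged single-bond covalent radii in angstroms."""
    return _read_element_csv(_data_text("covalent_radii.csv"))


# ---------------------------------------------------------------------------
# Structure I/O
# ---------------------------------------------------------------------------

def read_structure(source: TextIO | str, format: str, mol_id: str | None = None
                   ) -> Molecule:
    """Parse a 3D structure from an XYZ or SDF/MOL V2000 text stream.

    Atoms keep file order; coordinates are angstroms.  Total charge is taken
    from ``charge=N`` in the XYZ comment line or from ``M  CHG`` entries in a
    molblock, defaulting to 0.  Malformed input raises
    :class:`StructureParseError` naming the offending line.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    fmt = format.lower()
    if fmt == "xyz":
        return _read_xyz(source, mol_id)
    if fmt in ("sdf", "mol"):
        return _read_molblock(source, mol_id)
    raise ValueError(f"unsupported format {format!r}; use 'xyz' or 'sdf'")


def _read_xyz(stream: TextIO, mol_id: str | None) -> Molecule:
    lines = stream.read().splitlines()
    if not lines:
        raise StructureParseError("empty XYZ input", line=1)
    try:
        n_declared = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise StructureParseError(
            f"expected atom count, got {lines[0]!r}", line=1) from None
    comment = lines[1] if len(lines) > 1 else ""
    charge = 0
    for token in comment.split():
        if token.lower().startswith("charge="):
            charge = int(token.split("=", 1)[1])
    atoms = []
    for k, raw in enumerate(lines[2:2 + n_declared], start=3):
        parts = raw.split()
        if len(parts) < 4:
            raise StructureParseError(
                f"expected 'element x y z', got {raw!r}", line=k)
        el = parts[0]
        if el not in ELEMENTS:
            raise StructureParseError(f"unknown element {el!r}", line=k)
        try:
            xyz = [float(p) for p in parts[1:4]]
        except ValueError:
            raise StructureParseError(
                f"non-numeric coordinate in {raw!r}", line=k) from None
        atoms.append(Atom(el, np.array(xyz)))
    if len(atoms) != n_declared:
        raise StructureParseError(
            f"header declares {n_declared} atoms but {len(atoms)} listed",
            line=2 + len(atoms) + 1)
    name = mol_id or (comment.split()[0] if comment.split() else "mol")
    return Molecule(name, atoms, total_charge=charge)


def _read_molblock(stream: TextIO, mol_id: str | None) -> Molecule:
    lines = stream.read().splitlines()
    if len(lines) < 4:
        raise StructureParseError("molblock shorter than 4 header lines", line=1)
    dim_tag = lines[1][20:22].strip() if len(lines[1]) >= 22 else ""
    if dim_tag == "2D":
        raise StructureParseError(
            "molblock is flagged 2D; 3D coordinates are required", line=2)
    counts = lines[3]
    try:
        n_atoms = int(counts[0:3])
        n_bonds = int(counts[3:6])
    except ValueError:
        raise StructureParseError(
            f"malformed counts line {counts!r}", line=4) from None
    if "V2000" not in counts:
        raise StructureParseError("only V2000 molblocks are supported", line=4)
    atoms = []
    for k in range(n_atoms):
        ln = 5 + k
        if ln - 1 >= len(lines):
            raise StructureParseError(
                f"atom block truncated: {n_atoms} declared, {k} present", line=ln)
        raw = lines[ln - 1]
        try:
            x, y, z = float(raw[0:10]), float(raw[10:20]), float(raw[20:30])
            el = raw[31:34].strip()
        except (ValueError, IndexError):
            raise StructureParseError(
                f"malformed atom line {raw!r}", line=ln) from None
        if el not in ELEMENTS:
            raise StructureParseError(f"unknown element {el!r}", line=ln)
        atoms.append(Atom(el, np.array([x, y, z])))
    if not atoms:
        raise StructureParseError("molblock declares zero atoms", line=4)
    # formal charges from M  CHG property lines override the atom block
    charges = {}
    for ln, raw in enumerate(lines[4 + n_atoms + n_bonds:],
                             start=5 + n_atoms + n_bonds):
        if raw.startswith("M  CHG"):
            parts = raw.split()
            n_entries = int(parts[2])
            for i in range(n_entries):
                idx = int(parts[3 + 2 * i]) - 1
                charges[idx] = int(parts[4 + 2 * i])
        if raw.startswith("M  END"):
            break
    if charges:
        atoms = [Atom(a.element, a.position, charges.get(i, 0))
                 for i, a in enumerate(atoms)]
    total = sum(charges.values())
    name = mol_id or (lines[0].strip() or "mol")
    return Molecule(name, atoms, total_charge=total)


def write_xyz(mol: Molecule, stream: TextIO | None = None) -> str:
    """Serialize a Molecule as plain XYZ; returns the text."""
    out = [str(mol.n_atoms), f"{mol.id} charge={mol.total_charge}"]
    for a in mol.atoms:
        x, y, z = a.position
        out.append(f"{a.element} {x:.8f} {y:.8f} {z:.8f}")
    text = "\n".join(out) + "\n"
    if stream is not None:
        stream.write(text)
    return text


# ---------------------------------------------------------------------------
# Gasteiger-Marsili (PEOE) partial charges
# ---------------------------------------------------------------------------

def _peoe_params() -> dict[str, tuple[float, float, float]]:
    reader = csv.DictReader(io.StringIO(_data_text("peoe_params.csv")))
    return {r["element"]: (float(r["a"]), float(r["b"]), float(r["c"]))
            for r in reader}


# cation electronegativity of hydrogen; classic PEOE special case
_H_CHI_PLUS = 20.02


def gasteiger_charges(mol: Molecule, n_iter: int = 6, damping: float = 0.5,
                      bonds: Iterable[tuple[int, int]] | None = None,
                      metal_fallback: bool = True) -> np.ndarray:
    """Gasteiger–Marsili PEOE partial charges in units of e.

    Partial equalization of orbital electronegativity: starting from formal
    charges, each iteration ``k`` transfers charge across every bond from the
    less to the more electronegative atom, proportional to the difference of
    their charge-dependent electronegativities ``chi(q) = a + b q + c q**2``
    and attenuated by ``damping**k``.  Atoms whose element lacks PEOE
    parameters (the transition metals here) keep their formal charge fixed and
    are excluded from transfer when ``metal_fallback`` is true; otherwise a
    :class:`ParameterizationError` is raised.

    The sum of returned charges equals ``mol.total_charge`` exactly up to
    floating point (transfers are antisymmetric; any residual between the
    formal charges and the total is seated on the first fallback atom, else
    spread uniformly).
    """
    if not 0 < damping < 1:
        raise DomainError(f"damping must lie in (0,1), got {damping}")
    params = _peoe_params()
    n = mol.n_atoms
    frozen = np.zeros(n, dtype=bool)
    for i, a in enumerate(mol.atoms):
        if a.element not in params:
            if not metal_fallback:
                raise ParameterizationError(
                    f"no PEOE parameters for element {a.element!r} "
                    "(metal_fallback disabled)")
            frozen[i] = True

    q = np.array([float(a.formal_charge) for a in mol.atoms])
    residual = mol.total_charge - q.sum()
    if abs(residual) > 0:
        targets = np.flatnonzero(frozen)
        if targets.size:
            q[targets[0]] += residual
        else:
            q += residual / n

    if bonds is None:
        from .matrices import bond_graph  # deferred: avoids import cycle
        bonds = bond_graph(mol).edges
    bonds = [(i, j) for (i, j) in bonds if not (frozen[i] or frozen[j])]

    def chi(i: int, qi: float) -> float:
        a, b, c = params[mol.atoms[i].element]
        return a + b * qi + c * qi * qi

    def chi_plus(i: int) -> float:
        if mol.atoms[i].element == "H":
            return _H_CHI_PLUS
        a, b, c = params[mol.atoms[i].element]
        return a + b + c

    for k in range(1, n_iter + 1):
        damp = damping**k
        dq = np.zeros(n)
        for i, j in bonds:
            ci, cj = chi(i, q[i]), chi(j, q[j])
            if cj > ci:
                t = (cj - ci) / chi_plus(i) * damp
                dq[i] += t
                dq[j] -= t
            elif ci > cj:
                t = (ci - cj) / chi_plus(j) * damp
                dq[j] += t
                dq[i] -= t
        q += dq
    return q


# ---------------------------------------------------------------------------
# Conceptual-DFT indices and geometry benchmarking
# ---------------------------------------------------------------------------

def electrophilicity(chi: float, eta: float) -> float:
    """Global electrophilicity index ``chi**2 / (2 eta)`` in eV.

    ``chi`` is the electronegativity (= -mu, the negative chemical
    potential) and ``eta`` the chemical hardness, both in eV.
    """
    if eta <= 0:
        raise DomainError(f"hardness must be positive, got {eta}")
    return chi * chi / (2.0 * eta)


@dataclass(frozen=True)
class GeometryErrorReport:
    """Mean unsigned / signed / percent relative errors of geometry parameters."""

    MUE: float
    MSE: float
    pct_Er: float


def geometry_error_metrics(calc: Sequence[float], ref: Sequence[float]
                           ) -> GeometryErrorReport:
    """MUE, MSE and average percent relative error of calculated vs reference.

    MUE = mean |Pc - Pr|; MSE = mean (Pc - Pr); %Er = mean 100|Pc - Pr|/|Pr|.
    The relative errors are averaged per parameter, not normalized by the
    mean reference.
    """
    c = np.asarray(calc, dtype=float)
    r = np.asarray(ref, dtype=float)
    if c.shape != r.shape or c.ndim != 1 or c.size == 0:
        raise DomainError("calc and ref must be equal-length nonempty vectors")
    if np.any(r == 0):
        raise DomainError("reference values must be nonzero for %Er")
    diff = c - r
    return GeometryErrorReport(
        MUE=float(np.mean(np.abs(diff))),
        MSE=float(np.mean(diff)),
        pct_Er=float(100.0 * np.mean(np.abs(diff) / np.abs(r))),
    )
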