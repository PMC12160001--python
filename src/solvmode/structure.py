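"""Core molecular-structure machinery.

Atomic structures with XYZ I/O, covalent connectivity and molecule
partitioning, principal moments of inertia, and van-der-Waals convex-hull
molecular volumes. Everything downstream (region selection, mode analysis,
thermochemistry, the droplet generator) consumes these types.

Coordinates are Cartesian Angstrom throughout; masses are amu.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import ConvexHull, QhullError

from . import elements

__all__ = [
    "AtomicStructure",
    "MoleculePartition",
    "MolecularSystem",
    "XYZParseError",
    "read_xyz",
    "write_xyz",
    "detect_molecules",
    "assign_solute",
    "principal_moments",
    "molecular_volume",
    "fibonacci_sphere",
]


class XYZParseError(ValueError):
    """Malformed XYZ input; the message names the offending line."""


@dataclass(frozen=True)
class AtomicStructure:
    """A molecular geometry: element symbols plus Cartesian coordinates.

    Parameters
    ----------
    symbols:
        Element symbols, one per atom.
    coordinates:
        N x 3 Cartesian positions in Angstrom.
    masses:
        Atomic masses in amu; derived from the symbols unless overridden.
    charge, multiplicity:
        Total charge and spin multiplicity (bookkeeping only).
    comment:
        Free-text metadata, preserved on XYZ round trips.
    """

    symbols: tuple[str, ...]
    coordinates: np.ndarray
    masses: np.ndarray = None  # type: ignore[assignment]
    charge: int = 0
    multiplicity: int = 1
    comment: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "symbols", tuple(self.symbols))
        coords = np.asarray(self.coordinates, dtype=float).reshape(-1, 3)
        object.__setattr__(self, "coordinates", coords)
        if self.masses is None:
            masses = np.array([elements.atomic_mass(s) for s in self.symbols])
        else:
            masses = np.asarray(self.masses, dtype=float)
        object.__setattr__(self, "masses", masses)
        if len(self.symbols) != len(coords) or len(masses) != len(coords):
            raise ValueError("symbols, coordinates and masses must agree in length")
        if len(coords) and not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        if len(masses) and not np.all(masses > 0):
            raise ValueError("all masses must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    def with_coordinates(self, coordinates: np.ndarray) -> "AtomicStructure":
        return replace(self, coordinates=np.asarray(coordinates, float).reshape(-1, 3))

    def subset(self, atom_ids) -> "AtomicStructure":
        """New structure containing only ``atom_ids`` (sorted ascending)."""
        idx = sorted(int(i) for i in atom_ids)
        return AtomicStructure(
            symbols=tuple(self.symbols[i] for i in idx),
            coordinates=self.coordinates[idx],
            masses=self.masses[idx],
            charge=self.charge,
            multiplicity=self.multiplicity,
            comment=self.comment,
        )

    def center_of_mass(self) -> np.ndarray:
        return self.masses @ self.coordinates / self.masses.sum()


@dataclass(frozen=True)
class MoleculePartition:
    """Disjoint cover of all atoms into covalently bound molecules.

    ``solute_ids`` marks the molecules of the reactive complex; the rest
    are solvent.
    """

    molecules: tuple[frozenset, ...]
    solute_ids: frozenset = frozenset()

    def __post_init__(self) -> None:
        mols = tuple(frozenset(int(i) for i in m) for m in self.molecules)
        object.__setattr__(self, "molecules", mols)
        object.__setattr__(self, "solute_ids", frozenset(int(i) for i in self.solute_ids))
        total = sum(len(m) for m in mols)
        union = set().union(*mols) if mols else set()
        if len(union) != total:
            raise ValueError("molecules must be disjoint")
        if union and union != set(range(max(union) + 1)):
            raise ValueError("molecules must cover atoms 0..N-1")
        if not self.solute_ids <= set(range(len(mols))):
            raise ValueError("solute_ids must index molecules")

    @property
    def solvent_ids(self) -> frozenset:
        return frozenset(range(len(self.molecules))) - self.solute_ids

    @property
    def n_atoms(self) -> int:
        return sum(len(m) for m in self.molecules)

    def solute_atoms(self) -> frozenset:
        return frozenset().union(*(self.molecules[i] for i in self.solute_ids)) \
            if self.solute_ids else frozenset()

    def molecule_of(self) -> dict[int, int]:
        """Map atom index -> molecule index."""
        out: dict[int, int] = {}
        for k, mol in enumerate(self.molecules):
            for i in mol:
                out[i] = k
        return out


@dataclass(frozen=True)
class MolecularSystem:
    """A solute-solvent cluster with its reactive and active atom sets.

    *Reactive atoms* are the atoms assigned to form or break bonds in the
    elementary step; *active atoms* are solute atoms expected to interact
    with the solvent (e.g. hydrogen-bond donors/acceptors).
    """

    structure: AtomicStructure
    partition: MoleculePartition
    reactive_atoms: frozenset = frozenset()
    active_atoms: frozenset = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "reactive_atoms",
                           frozenset(int(i) for i in self.reactive_atoms))
        object.__setattr__(self, "active_atoms",
                           frozenset(int(i) for i in self.active_atoms))
        n = self.structure.n_atoms
        if self.partition.n_atoms != n:
            raise ValueError("partition does not cover the structure")
        all_atoms = set(range(n))
        if not self.reactive_atoms <= all_atoms or not self.active_atoms <= all_atoms:
            raise ValueError("reactive/active atoms must be valid atom indices")
        if not self.reactive_atoms <= self.partition.solute_atoms():
            raise ValueError("reactive atoms must belong to solute molecules")

    @property
    def n_atoms(self) -> int:
        return self.structure.n_atoms

    def solute_atoms(self) -> frozenset:
        return self.partition.solute_atoms()

    def subsystem(self, atom_ids) -> tuple["MolecularSystem", dict[int, int]]:
        """Extract ``atom_ids`` as a standalone system.

        Returns the sub-system and the old->new atom index map. Molecule
        membership, solute flags and reactive/active sets are carried over
        (restricted to the kept atoms).
        """
        idx = sorted(int(i) for i in atom_ids)
        old_to_new = {old: new for new, old in enumerate(idx)}
        kept = set(idx)
        mols, solute = [], set()
        for k, mol in enumerate(self.partition.molecules):
            sub = mol & kept
            if sub:
                if k in self.partition.solute_ids:
                    solute.add(len(mols))
                mols.append(frozenset(old_to_new[i] for i in sub))
        sub_sys = MolecularSystem(
            structure=self.structure.subset(idx),
            partition=MoleculePartition(tuple(mols), frozenset(solute)),
            reactive_atoms=frozenset(old_to_new[i] for i in self.reactive_atoms if i in kept),
            active_atoms=frozenset(old_to_new[i] for i in self.active_atoms if i in kept),
        )
        return sub_sys, old_to_new


def read_xyz(path) -> AtomicStructure:
    """Read a standard XYZ file (count line, comment line, atom lines).

    The comment line may carry ``charge=<int>`` and ``multiplicity=<int>``
    key=value tokens, which populate the corresponding fields.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise XYZParseError(f"{path}: line 1: empty file, expected an atom count")
    try:
        n = int(lines[0].strip())
    except ValueError:
        raise XYZParseError(
            f"{path}: line 1: malformed atom count {lines[0]!r}") from None
    comment = lines[1] if len(lines) > 1 else ""
    atom_lines = lines[2:2 + n]
    if len(atom_lines) < n:
        raise XYZParseError(
            f"{path}: line {2 + len(atom_lines)}: expected {n} atom lines, "
            f"found {len(atom_lines)}")
    symbols, coords = [], []
    for k, line in enumerate(atom_lines):
        parts = line.split()
        if len(parts) < 4:
            raise XYZParseError(f"{path}: line {k + 3}: expected 'symbol x y z'")
        sym = parts[0]
        if sym not in elements.known_elements():
            raise XYZParseError(f"{path}: line {k + 3}: unknown element {sym!r}")
        try:
            xyz = [float(v) for v in parts[1:4]]
        except ValueError:
            raise XYZParseError(
                f"{path}: line {k + 3}: non-numeric coordinate") from None
        symbols.append(sym)
        coords.append(xyz)
    charge, mult = 0, 1
    for token in comment.split():
        if token.startswith("charge="):
            charge = int(token.split("=", 1)[1])
        elif token.startswith("multiplicity="):
            mult = int(token.split("=", 1)[1])
    return AtomicStructure(tuple(symbols), np.array(coords).reshape(-1, 3),
                           charge=charge, multiplicity=mult, comment=comment)


def write_xyz(structure: AtomicStructure, path) -> None:
    """Write a standard XYZ file with 8-decimal coordinates."""
    lines = [str(structure.n_atoms), structure.comment]
    for sym, (x, y, z) in zip(structure.symbols, structure.coordinates):
        lines.append(f"{sym} {x:.8f} {y:.8f} {z:.8f}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def detect_molecules(structure: AtomicStructure,
                     bond_tolerance: float = 1.2) -> MoleculePartition:
    """Partition atoms into covalently bound molecules.

    Atoms i and j are bonded iff ``d_ij <= tolerance * (r_cov_i + r_cov_j)``;
    molecules are the connected components of that bond graph. Isolated
    atoms become single-atom molecules.
    """
    if bond_tolerance <= 0:
        raise ValueError("bond_tolerance must be positive")
    n = structure.n_atoms
    if n == 0:
        return MoleculePartition(())
    r_cov = np.array([elements.covalent_radius(s) for s in structure.symbols])
    diff = structure.coordinates[:, None, :] - structure.coordinates[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    cut = bond_tolerance * (r_cov[:, None] + r_cov[None, :])
    bonded = (dist <= cut) & ~np.eye(n, dtype=bool)
    ii, jj = np.nonzero(bonded)
    graph = coo_matrix((np.ones(len(ii)), (ii, jj)), shape=(n, n))
    n_comp, labels = connected_components(graph, directed=False)
    mols = [frozenset(np.nonzero(labels == c)[0].tolist()) for c in range(n_comp)]
    # stable order: by smallest atom index
    mols.sort(key=min)
    return MoleculePartition(tuple(mols))


def assign_solute(partition: MoleculePartition, solute_atoms) -> MoleculePartition:
    """Mark every molecule containing one of ``solute_atoms`` as solute."""
    solute_atoms = {int(i) for i in solute_atoms}
    ids = frozenset(k for k, mol in enumerate(partition.molecules)
                    if mol & solute_atoms)
    return MoleculePartition(partition.molecules, ids)


def principal_moments(structure: AtomicStructure) -> np.ndarray:
    """Principal moments of inertia about the center of mass, amu*A^2.

    Returned ascending; a single atom yields (0, 0, 0).
    """
    if structure.n_atoms == 0:
        raise ValueError("need at least one atom")
    x = structure.coordinates - structure.center_of_mass()
    m = structure.masses
    r2 = np.sum(x * x, axis=1)
    tensor = np.diag([np.sum(m * (r2 - x[:, k] ** 2)) for k in range(3)])
    for a in range(3):
        for b in range(a + 1, 3):
            val = -np.sum(m * x[:, a] * x[:, b])
            tensor[a, b] = tensor[b, a] = val
    moments = np.linalg.eigvalsh(tensor)
    return np.clip(moments, 0.0, None)


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic Fibonacci-lattice points on the unit sphere (n x 3)."""
    i = np.arange(n)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    y = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.clip(1.0 - y * y, 0.0, None))
    theta = golden * i
    return np.column_stack([np.cos(theta) * r, y, np.sin(theta) * r])


def _molecular_frame(coords: np.ndarray) -> np.ndarray:
    """Rotation-covariant orthonormal frame (columns) from the geometry.

    Principal axes of the centred coordinate covariance, with each axis
    sign fixed against the most distant atom so that rotating the input
    rotates the frame identically.
    """
    centroid = coords.mean(axis=0)
    x = coords - centroid
    if len(coords) < 2 or np.allclose(x, 0.0):
        return np.eye(3)
    cov = x.T @ x
    _, vecs = np.linalg.eigh(cov)
    order = np.argsort(np.linalg.norm(x, axis=1))[::-1]
    for k in range(3):
        for a in order:
            dot = float(x[a] @ vecs[:, k])
            if abs(dot) > 1e-8:
                if dot < 0:
                    vecs[:, k] = -vecs[:, k]
                break
    return vecs


def molecular_volume(structure: AtomicStructure,
                     points_per_atom: int = 256) -> float:
    """Convex-hull van-der-Waals volume in Angstrom^3.

    Points are sampled on every atom's van der Waals sphere with a
    deterministic Fibonacci lattice and the volume of their convex hull is
    returned (the convention used for both solutes and solvents, so that
    cavity radius ratios are consistent). The lattice is oriented in a
    molecule-fixed principal-axes frame, which makes the result exactly
    invariant under rigid rotation (up to symmetric-top frame degeneracy).
    """
    if structure.n_atoms == 0:
        raise ValueError("need at least one atom")
    if points_per_atom < 50:
        raise ValueError("points_per_atom must be >= 50")
    unit = fibonacci_sphere(points_per_atom) @ _molecular_frame(
        structure.coordinates).T
    clouds = []
    for sym, center in zip(structure.symbols, structure.coordinates):
        clouds.append(center + elements.vdw_radius(sym) * unit)
    points = np.vstack(clouds)
    try:
        return float(ConvexHull(points).volume)
    except QhullError as exc:  # pragma: no cover - spheres are never coplanar
        raise RuntimeError(f"convex hull construction failed: {exc}") from exc
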