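"""Transition-state normal-mode analysis and active-solvent identification.

Given the (partial) non-mass-weighted Hessian of a TS (guess) structure,
every eigenvector with a negative eigenvalue is a reaction-coordinate
candidate. Each candidate is mass-weighted, normalized, and scored by

    s_i = 0.5 * w_norm_i + 0.5 * C_i

where w_norm_i = w_i / w_min normalizes the negative eigenvalues by the
most negative one and C_i is the summed squared amplitude of the reactive
atoms in the mass-weighted unit eigenvector. Both terms lie in [0, 1].
The highest-scoring mode defines per-atom contributions c_i; atoms whose
contribution reaches the minimum reactive-atom contribution c_min mark
the *involved atoms*, and any solvent molecule containing an involved
atom is an *active solvent molecule*.

Mass weighting multiplies each atom's three Cartesian components by the
atomic mass m (not sqrt(m)); the conventional sqrt(m) weighting is
available through the ``weighting`` switch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure import MolecularSystem

__all__ = [
    "HessianData",
    "ModeSet",
    "ModeScoreTable",
    "ContributionReport",
    "NoTransitionStateError",
    "read_hessian",
    "write_hessian",
    "diagonalize",
    "mass_weight_and_normalize",
    "reactive_contribution",
    "score_modes",
    "atom_contributions",
    "find_active_solvent",
    "analyze_hessian",
]

DEFAULT_SCORE_WEIGHTS = (0.5, 0.5)


class NoTransitionStateError(ValueError):
    """The Hessian has no negative eigenvalue: no TS character to analyze."""


@dataclass(frozen=True)
class HessianData:
    """A symmetric 3N x 3N second-derivative matrix over ``atom_ids``.

    Partial Hessians span only the unfrozen (QM-region) atoms;
    ``frozen_context=True`` marks that environment atoms were excluded.
    """

    matrix: np.ndarray
    atom_ids: tuple[int, ...]
    frozen_context: bool = False
    units: str = "hartree/bohr^2"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "atom_ids", tuple(int(i) for i in self.atom_ids))
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("Hessian must be square")
        if m.shape[0] != 3 * len(self.atom_ids):
            raise ValueError("Hessian dimension must equal 3 * number of atoms")
        scale = max(1.0, float(np.abs(m).max()) if m.size else 1.0)
        if m.size and np.abs(m - m.T).max() > 1e-8 * scale:
            raise ValueError("Hessian must be symmetric")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_ids)


@dataclass(frozen=True)
class ModeSet:
    """Eigenpairs of a Hessian: ascending eigenvalues, column eigenvectors."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray


@dataclass(frozen=True)
class ModeScoreTable:
    """Scores of all analyzed (negative-eigenvalue) modes.

    ``mode_indices`` are column indices into the ModeSet; ``selected_index``
    is the ModeSet column of the winning mode.
    """

    mode_indices: tuple[int, ...]
    eigenvalues: np.ndarray
    w_norm: np.ndarray
    reactive_C: np.ndarray
    scores: np.ndarray
    selected_index: int


@dataclass(frozen=True)
class ContributionReport:
    """Per-atom contributions of the selected mode and the derived sets.

    ``c`` maps each Hessian atom (global index) to its contribution;
    contributions sum to one. ``involved_atoms`` collects atoms with
    ``c_i >= threshold_factor * c_min``; ``relevant_atoms`` adds the
    system's active atoms; ``active_solvent_molecules`` are the solvent
    molecules containing at least one involved atom.
    """

    c: dict
    c_min: float
    threshold_factor: float
    involved_atoms: frozenset
    relevant_atoms: frozenset
    active_solvent_molecules: tuple[int, ...]

    @property
    def n_active(self) -> int:
        return len(self.active_solvent_molecules)


def read_hessian(path, atom_ids=None, units: str = "hartree/bohr^2",
                 frozen_context: bool = False) -> HessianData:
    """Read a whitespace-delimited 3N x 3N matrix from a text file."""
    raw = np.loadtxt(path)
    m = np.atleast_2d(raw)
    if m.shape[0] != m.shape[1] or m.shape[0] % 3:
        raise ValueError(f"{path}: expected a square 3Nx3N matrix, got {m.shape}")
    if atom_ids is None:
        atom_ids = tuple(range(m.shape[0] // 3))
    return HessianData(m, tuple(atom_ids), frozen_context=frozen_context, units=units)


def write_hessian(hessian: HessianData, path) -> None:
    np.savetxt(path, hessian.matrix, fmt="%.12e")


def diagonalize(hessian: HessianData) -> ModeSet:
    """Eigen-decomposition with ascending eigenvalues (symmetric solver)."""
    w, v = np.linalg.eigh(hessian.matrix)
    return ModeSet(w, v)


def _per_atom_weights(masses, weighting: str) -> np.ndarray:
    masses = np.asarray(masses, float)
    if weighting == "mass":
        return masses
    if weighting == "sqrt_mass":
        return np.sqrt(masses)
    raise ValueError(f"unknown weighting {weighting!r}")


def mass_weight_and_normalize(n: np.ndarray, masses,
                              weighting: str = "mass") -> np.ndarray:
    """Mass-weight an eigenvector elementwise and normalize to unit norm.

    Each atom's three Cartesian components are multiplied by that atom's
    mass (``weighting="mass"``, the default) or sqrt(mass).
    """
    vec = np.asarray(n, float).reshape(-1, 3)
    if len(vec) != len(masses):
        raise ValueError("eigenvector length does not match the mass vector")
    weighted = vec * _per_atom_weights(masses, weighting)[:, None]
    norm = np.linalg.norm(weighted)
    if norm == 0:
        raise ValueError("cannot normalize a zero eigenvector")
    return (weighted / norm).ravel()


def reactive_contribution(n_norm_m: np.ndarray, reactive_local) -> float:
    """Total squared amplitude of the reactive atoms in a unit mode vector."""
    reactive_local = sorted(int(i) for i in reactive_local)
    if not reactive_local:
        raise ValueError("reactive atom set must be nonempty")
    vec = np.asarray(n_norm_m, float).reshape(-1, 3)
    return float(np.sum(vec[reactive_local] ** 2))


def score_modes(modes: ModeSet, masses, reactive_local,
                weights=DEFAULT_SCORE_WEIGHTS,
                weighting: str = "mass") -> ModeScoreTable:
    """Score every negative-eigenvalue mode and select the best.

    The most negative eigenvalue defines w_min; w_norm_i = w_i / w_min.
    Ties in the score go to the more negative eigenvalue (stronger TS
    character).
    """
    neg = np.nonzero(modes.eigenvalues < 0)[0]
    if len(neg) == 0:
        raise NoTransitionStateError(
            "no negative Hessian eigenvalue: structure has no TS character")
    w = modes.eigenvalues[neg]
    w_min = w.min()
    w_norm = w / w_min
    C = np.array([
        reactive_contribution(
            mass_weight_and_normalize(modes.eigenvectors[:, k], masses, weighting),
            reactive_local)
        for k in neg
    ])
    s = weights[0] * w_norm + weights[1] * C
    # argmax with tie-break toward the more negative eigenvalue
    best = min(range(len(neg)), key=lambda i: (-s[i], w[i]))
    return ModeScoreTable(tuple(int(i) for i in neg), w, w_norm, C, s,
                          selected_index=int(neg[best]))


def atom_contributions(selected_norm_m: np.ndarray) -> np.ndarray:
    """Per-atom contributions c_i of a mass-weighted unit mode; sums to 1."""
    vec = np.asarray(selected_norm_m, float).reshape(-1, 3)
    return np.sum(vec * vec, axis=1)


def find_active_solvent(c: np.ndarray, atom_ids, system: MolecularSystem,
                        threshold_factor: float = 1.0) -> ContributionReport:
    """Threshold the contributions and collect involved/relevant/active sets.

    ``c_min`` is the smallest contribution among the reactive atoms; atoms
    with ``c_i >= threshold_factor * c_min`` are involved. A factor below
    one (the analysis variant uses 0.85) admits borderline solvent atoms.
    """
    if threshold_factor <= 0:
        raise ValueError("threshold_factor must be positive")
    if not system.reactive_atoms:
        raise ValueError("system has no reactive atoms")
    atom_ids = tuple(int(i) for i in atom_ids)
    local = {g: l for l, g in enumerate(atom_ids)}
    missing = system.reactive_atoms - set(atom_ids)
    if missing:
        raise ValueError(f"reactive atoms {sorted(missing)} absent from the Hessian")
    c = np.asarray(c, float)
    c_min = min(c[local[g]] for g in system.reactive_atoms)
    involved = frozenset(g for g in atom_ids
                         if c[local[g]] >= threshold_factor * c_min)
    relevant = involved | system.active_atoms
    active_mols = tuple(sorted(
        k for k in system.partition.solvent_ids
        if system.partition.molecules[k] & involved))
    return ContributionReport(
        c={g: float(c[local[g]]) for g in atom_ids},
        c_min=float(c_min),
        threshold_factor=float(threshold_factor),
        involved_atoms=involved,
        relevant_atoms=relevant,
        active_solvent_molecules=active_mols,
    )


def analyze_hessian(hessian: HessianData, system: MolecularSystem,
                    threshold_factor: float = 1.0,
                    weights=DEFAULT_SCORE_WEIGHTS,
                    weighting: str = "mass") -> tuple[ModeScoreTable, ContributionReport]:
    """Full analysis: diagonalize, score, select, threshold.

    The Hessian may be partial; reactive atoms must lie inside its atom
    set (they always do, because every solute atom is in every region).
    """
    local = {g: l for l, g in enumerate(hessian.atom_ids)}
    missing = system.reactive_atoms - set(hessian.atom_ids)
    if missing:
        raise ValueError(f"reactive atoms {sorted(missing)} absent from the Hessian")
    masses = system.structure.masses[list(hessian.atom_ids)]
    reactive_local = [local[g] for g in system.reactive_atoms]
    modes = diagonalize(hessian)
    table = score_modes(modes, masses, reactive_local, weights, weighting)
    selected = mass_weight_and_normalize(
        modes.eigenvectors[:, table.selected_index], masses, weighting)
    c = atom_contributions(selected)
    report = find_active_solvent(c, hessian.atom_ids, system, threshold_factor)
    return table, report
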