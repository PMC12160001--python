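"""Synthetic inputs: seeded microdroplets, prescribed TS Hessians, and an
analytic toy potential implementing the engine contract.

Everything the staged pipeline consumes can be generated offline and
deterministically here:

* :func:`make_droplet` places two shells of solvent molecules around a
  reactive complex by seeded rejection sampling (random positions and
  quaternion orientations, minimum interatomic separation honored).
* :func:`make_ts_hessian` builds a symmetric Hessian whose single
  negative-eigenvalue eigenvector has prescribed per-atom mass-weighted
  contributions - exact ground truth for active-solvent recovery tests.
* :class:`ToyPotential` is an analytic energy/gradient/Hessian engine:
  harmonic intramolecular bonds, one quartic double-well along a chosen
  interatomic distance (guaranteeing a first-order saddle at a known
  location), and a finite-range pairwise repulsion between molecules.

All generators are pure functions of their inputs and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import constants as const
from .cavity import SolventSpec, load_solvent
from .engine import Engine, optimize
from .modes import ContributionReport, HessianData
from .structure import (AtomicStructure, MoleculePartition, MolecularSystem,
                        assign_solute)

__all__ = [
    "DropletConfig",
    "PackingError",
    "make_droplet",
    "SyntheticTSSpec",
    "prescribe_fractions",
    "make_ts_hessian",
    "ReactionParams",
    "ToyPotential",
    "make_reactive_complex",
    "toy_engine_for",
]


class PackingError(RuntimeError):
    """Solvent placement failed within the retry budget."""


@dataclass(frozen=True)
class DropletConfig:
    """Placement parameters for a two-shell solvent microdroplet.

    ``shell_radii`` gives (inner, outer) bounds per shell in Angstrom; if
    omitted both shells are sized from the reactive-complex extent r_max:
    [r_max+2.5, r_max+5.5] and [r_max+5.5, r_max+8.5].
    """

    n_solvent: int = 100
    shell_radii: tuple | None = None
    min_separation: float = 1.8
    seed: int = 0
    solvent: str = "water"
    max_attempts: int = 2000

    def __post_init__(self) -> None:
        if self.n_solvent < 0:
            raise ValueError("n_solvent must be non-negative")
        if self.min_separation <= 0:
            raise ValueError("min_separation must be positive")
        if self.shell_radii is not None:
            for inner, outer in self.shell_radii:
                if not inner < outer:
                    raise ValueError("shell inner radius must be below outer")


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix from a normalized quaternion."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def make_droplet(rc: AtomicStructure, config: DropletConfig,
                 reactive_atoms=(), active_atoms=()) -> MolecularSystem:
    """Surround a reactive complex with two seeded shells of solvent.

    The complex is centred at the origin; solvent template copies are
    placed with random positions (uniform in shell radius and direction)
    and orientations, rejecting any placement that brings an atom within
    ``min_separation`` of an already-placed atom. Deterministic for a
    fixed seed. The returned partition marks the complex's molecules as
    solute.
    """
    solvent = (config.solvent if isinstance(config.solvent, SolventSpec)
               else load_solvent(config.solvent))
    template = solvent.template
    if template is None:
        raise ValueError("solvent spec carries no template geometry")
    rng = np.random.default_rng(config.seed)
    rc_coords = rc.coordinates - rc.coordinates.mean(axis=0)
    r_max = float(np.linalg.norm(rc_coords, axis=1).max()) if rc.n_atoms else 0.0
    shells = config.shell_radii or ((r_max + 2.5, r_max + 5.5),
                                    (r_max + 5.5, r_max + 8.5))
    t_coords = template.coordinates - template.coordinates.mean(axis=0)

    symbols = list(rc.symbols)
    placed = [rc_coords] if rc.n_atoms else []
    molecules = []
    n_inner = config.n_solvent // 2
    for k in range(config.n_solvent):
        inner, outer = shells[0] if k < n_inner else shells[1]
        for _ in range(config.max_attempts):
            radius = rng.uniform(inner, outer)
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            rot = _random_rotation(rng)
            candidate = t_coords @ rot.T + radius * direction
            ok = all(
                np.min(np.linalg.norm(block[:, None, :] - candidate[None, :, :],
                                      axis=-1)) >= config.min_separation
                for block in placed)
            if ok:
                start = sum(len(b) for b in placed)
                placed.append(candidate)
                symbols.extend(template.symbols)
                molecules.append(frozenset(range(start, start + template.n_atoms)))
                break
        else:
            raise PackingError(
                f"could not place solvent molecule {k + 1}/{config.n_solvent}; "
                "enlarge the shells or reduce min_separation")
    coords = np.vstack(placed) if placed else np.zeros((0, 3))
    structure = AtomicStructure(tuple(symbols), coords, charge=rc.charge,
                                multiplicity=rc.multiplicity, comment=rc.comment)
    from .structure import detect_molecules  # late import avoids cycle at init
    rc_part = detect_molecules(rc) if rc.n_atoms else MoleculePartition(())
    all_mols = tuple(rc_part.molecules) + tuple(molecules)
    partition = MoleculePartition(all_mols,
                                  frozenset(range(len(rc_part.molecules))))
    return MolecularSystem(structure, partition,
                           frozenset(int(i) for i in reactive_atoms),
                           frozenset(int(i) for i in active_atoms))


@dataclass(frozen=True)
class SyntheticTSSpec:
    """Prescription for a synthetic TS Hessian.

    ``target_fractions`` maps atom index -> the mass-weighted per-atom
    contribution c_i the lowest mode must carry (fractions sum to 1;
    unlisted atoms get zero). Exactly one negative eigenvalue is placed;
    the rest are drawn uniformly from ``positive_spectrum``.
    """

    system: MolecularSystem
    target_fractions: dict
    negative_eigenvalue: float = -0.05
    positive_spectrum: tuple[float, float] = (0.01, 1.0)
    seed: int = 0
    threshold_factor: float = 1.0

    def __post_init__(self) -> None:
        total = sum(self.target_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"target fractions must sum to 1, got {total}")
        if self.negative_eigenvalue >= 0:
            raise ValueError("the prescribed eigenvalue must be negative")


def prescribe_fractions(system: MolecularSystem, active_molecules,
                        amplitude_ratio: float = 1.5,
                        rng: np.random.Generator | None = None) -> dict:
    """Target fractions giving each reactive atom c_min and one atom of
    each chosen solvent molecule ``amplitude_ratio * c_min``.

    With ratio >= 1 exactly the chosen molecules are recovered as active
    at threshold factor 1.
    """
    reactive = sorted(system.reactive_atoms)
    if not reactive:
        raise ValueError("system has no reactive atoms")
    chosen = []
    for mol_id in sorted(int(m) for m in active_molecules):
        mol = sorted(system.partition.molecules[mol_id])
        pick = mol[0] if rng is None else int(rng.choice(mol))
        chosen.append(pick)
    base = 1.0 / (len(reactive) + amplitude_ratio * len(chosen))
    fractions = {a: base for a in reactive}
    for a in chosen:
        fractions[a] = amplitude_ratio * base
    return fractions


def make_ts_hessian(spec: SyntheticTSSpec) -> tuple[HessianData, ContributionReport]:
    """Assemble H = V diag(w) V^T with a prescribed reaction mode.

    The unit Cartesian eigenvector of the single negative eigenvalue is
    constructed so that after mass weighting and normalization its
    per-atom squared norms equal ``target_fractions`` exactly; the
    orthonormal completion and positive spectrum are seeded. Returns the
    Hessian and the analytically known contribution report.
    """
    system = spec.system
    n = system.n_atoms
    rng = np.random.default_rng(spec.seed)
    masses = system.structure.masses

    mode = np.zeros((n, 3))
    for atom, frac in spec.target_fractions.items():
        if frac < 0:
            raise ValueError("fractions must be non-negative")
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        # mass-weighted amplitude sqrt(frac); Cartesian = mw / m
        mode[int(atom)] = np.sqrt(frac) * direction / masses[int(atom)]
    v = mode.ravel()
    v /= np.linalg.norm(v)

    basis = rng.standard_normal((3 * n, 3 * n))
    basis[:, 0] = v
    q, _ = np.linalg.qr(basis)
    if np.dot(q[:, 0], v) < 0:
        q[:, 0] *= -1.0
    lo, hi = spec.positive_spectrum
    eigenvalues = np.concatenate([[spec.negative_eigenvalue],
                                  np.sort(rng.uniform(lo, hi, 3 * n - 1))])
    h = (q * eigenvalues) @ q.T
    h = 0.5 * (h + h.T)
    hessian = HessianData(h, tuple(range(n)), units="hartree/bohr^2")

    # analytic ground truth, straight from the prescription
    fractions = {int(a): float(f) for a, f in spec.target_fractions.items()}
    c = {i: fractions.get(i, 0.0) for i in range(n)}
    c_min = min(c[i] for i in system.reactive_atoms)
    involved = frozenset(i for i in range(n)
                         if c[i] >= spec.threshold_factor * c_min)
    relevant = involved | system.active_atoms
    active = tuple(sorted(k for k in system.partition.solvent_ids
                          if system.partition.molecules[k] & involved))
    truth = ContributionReport(c=c, c_min=c_min,
                               threshold_factor=spec.threshold_factor,
                               involved_atoms=involved, relevant_atoms=relevant,
                               active_solvent_molecules=active)
    return hessian, truth


@dataclass(frozen=True)
class ReactionParams:
    """Double-well reaction coordinate between two atoms.

    V(d) = barrier * ((u^2 - half_width^2)^2 / half_width^4), u = d - d_ts:
    minima at d_ts -/+ half_width, barrier height ``barrier`` hartree at
    the saddle distance ``d_ts``.
    """

    atom_i: int = 0
    atom_j: int = 1
    barrier: float = 0.02  # hartree
    half_width: float = 0.35  # Angstrom
    d_ts: float = 1.8  # Angstrom


class ToyPotential(Engine):
    """Analytic cluster potential implementing the engine contract.

    Terms (all functions of interatomic distances, hence rigid-motion
    invariant): harmonic bonds for every intramolecular atom pair, a
    quartic double-well along one designated pair, and a finite-range
    polynomial repulsion eps*(1 - d/cutoff)^4 (C2-smooth at the cutoff)
    between atoms of different molecules.
    """

    def __init__(self, system: MolecularSystem,
                 reaction: ReactionParams | None,
                 bond_k: float = 1.0, rep_eps: float = 0.005,
                 rep_cutoff: float = 2.6):
        self.system = system
        self.reaction = reaction
        self.n_atoms = system.n_atoms
        coords0 = system.structure.coordinates
        mol_of = system.partition.molecule_of()
        bonds_i, bonds_j, bonds_r0 = [], [], []
        rep_i, rep_j = [], []
        skip = set()
        if reaction is not None:
            skip = {(reaction.atom_i, reaction.atom_j),
                    (reaction.atom_j, reaction.atom_i)}
        for a in range(self.n_atoms):
            for b in range(a + 1, self.n_atoms):
                if (a, b) in skip:
                    continue
                if mol_of[a] == mol_of[b]:
                    bonds_i.append(a)
                    bonds_j.append(b)
                    bonds_r0.append(np.linalg.norm(coords0[a] - coords0[b]))
                else:
                    rep_i.append(a)
                    rep_j.append(b)
        self._bonds = (np.array(bonds_i, int), np.array(bonds_j, int),
                       float(bond_k), np.array(bonds_r0))
        self._rep = (np.array(rep_i, int), np.array(rep_j, int),
                     float(rep_eps), float(rep_cutoff))

    # -- pair-term values and first/second distance derivatives -----------
    def _terms(self, coords: np.ndarray):
        bi, bj, k, r0 = self._bonds
        ri, rj, eps, cut = self._rep
        p = self.reaction
        pairs, f, fp, fpp = [], [], [], []
        if len(bi):
            d = np.linalg.norm(coords[bi] - coords[bj], axis=1)
            pairs.append((bi, bj, d))
            f.append(0.5 * k * (d - r0) ** 2)
            fp.append(k * (d - r0))
            fpp.append(np.full_like(d, k))
        if len(ri):
            d = np.linalg.norm(coords[ri] - coords[rj], axis=1)
            inside = d < cut
            t = np.where(inside, 1.0 - d / cut, 0.0)
            pairs.append((ri, rj, d))
            f.append(eps * t ** 4)
            fp.append(np.where(inside, -4.0 * eps * t ** 3 / cut, 0.0))
            fpp.append(np.where(inside, 12.0 * eps * t ** 2 / cut ** 2, 0.0))
        if p is not None:
            i, j = np.array([p.atom_i]), np.array([p.atom_j])
            d = np.linalg.norm(coords[i] - coords[j], axis=1)
            u = d - p.d_ts
            w2 = p.half_width ** 2
            scale = p.barrier / p.half_width ** 4
            pairs.append((i, j, d))
            f.append(scale * (u ** 2 - w2) ** 2)
            fp.append(scale * 4.0 * u * (u ** 2 - w2))
            fpp.append(scale * 4.0 * (3.0 * u ** 2 - w2))
        return pairs, f, fp, fpp

    def energy(self, coords: np.ndarray) -> float:
        _, f, _, _ = self._terms(np.asarray(coords, float))
        return float(sum(arr.sum() for arr in f))

    def gradient(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, float)
        pairs, _, fp, _ = self._terms(coords)
        grad = np.zeros_like(coords)
        for (i, j, d), fp_arr in zip(pairs, fp):
            u = (coords[i] - coords[j]) / d[:, None]
            contrib = fp_arr[:, None] * u
            np.add.at(grad, i, contrib)
            np.add.at(grad, j, -contrib)
        return grad

    def hessian(self, coords: np.ndarray, atom_ids=None) -> HessianData:
        coords = np.asarray(coords, float)
        if atom_ids is None:
            atom_ids = range(self.n_atoms)
        atom_ids = tuple(sorted(int(a) for a in atom_ids))
        pos = {a: k for k, a in enumerate(atom_ids)}
        m = len(atom_ids)
        h = np.zeros((3 * m, 3 * m))
        pairs, _, fp, fpp = self._terms(coords)
        eye = np.eye(3)
        for (ii, jj, dd), fp_arr, fpp_arr in zip(pairs, fp, fpp):
            for i, j, d, f1, f2 in zip(ii, jj, dd, fp_arr, fpp_arr):
                pi, pj = pos.get(int(i)), pos.get(int(j))
                if pi is None and pj is None:
                    continue
                u = (coords[i] - coords[j]) / d
                block = f2 * np.outer(u, u) + (f1 / d) * (eye - np.outer(u, u))
                if pi is not None:
                    h[3 * pi:3 * pi + 3, 3 * pi:3 * pi + 3] += block
                if pj is not None:
                    h[3 * pj:3 * pj + 3, 3 * pj:3 * pj + 3] += block
                if pi is not None and pj is not None:
                    h[3 * pi:3 * pi + 3, 3 * pj:3 * pj + 3] -= block
                    h[3 * pj:3 * pj + 3, 3 * pi:3 * pi + 3] -= block
        return HessianData(h, atom_ids, frozen_context=(m != self.n_atoms),
                           units="hartree/angstrom^2")

    # -- reaction-specific hooks -----------------------------------------
    def ts_guess(self, coords: np.ndarray, free_atoms,
                 gtol: float = 1e-4) -> np.ndarray:
        """Single-ended search stand-in: stretch the reaction pair to the
        barrier-top distance, then relax the other free atoms."""
        if self.reaction is None:
            raise ValueError("no reaction coordinate defined for this engine")
        coords = np.array(coords, float)
        p = self.reaction
        axis = coords[p.atom_j] - coords[p.atom_i]
        d = np.linalg.norm(axis)
        axis /= d
        shift = (p.d_ts - d)
        free = {int(a) for a in free_atoms}
        if p.atom_i in free and p.atom_j in free:
            coords[p.atom_i] -= 0.5 * shift * axis
            coords[p.atom_j] += 0.5 * shift * axis
        elif p.atom_j in free:
            coords[p.atom_j] += shift * axis
        elif p.atom_i in free:
            coords[p.atom_i] -= shift * axis
        else:
            raise ValueError("reaction atoms are frozen; cannot search")
        others = free - {p.atom_i, p.atom_j}
        if others:
            coords = optimize(self, coords, others, gtol=gtol)
        return coords

    def subsystem(self, atom_ids) -> tuple["ToyPotential", "MolecularSystem"]:
        """Extract ``atom_ids`` as a standalone cluster with its own engine.

        The double-well term is kept only if both reaction atoms are in
        the subset; all other terms are restricted to internal pairs.
        """
        atom_ids = sorted(int(a) for a in atom_ids)
        sub_sys, old_to_new = self.system.subsystem(atom_ids)
        p = self.reaction
        sub_reaction = None
        if p is not None and p.atom_i in old_to_new and p.atom_j in old_to_new:
            sub_reaction = ReactionParams(old_to_new[p.atom_i],
                                          old_to_new[p.atom_j],
                                          p.barrier, p.half_width, p.d_ts)
        bi, bj, k, br0 = self._bonds
        _, _, eps, cut = self._rep
        sub = ToyPotential(sub_sys, sub_reaction, bond_k=k, rep_eps=eps,
                           rep_cutoff=cut)
        # carry the parent's bond rest lengths over (the sub constructor
        # would otherwise re-derive them from the current coordinates)
        parent_r0 = {(old_to_new[a], old_to_new[b]): r0
                     for a, b, r0 in zip(bi, bj, br0)
                     if a in old_to_new and b in old_to_new}
        sbi, sbj, sk, sr0 = sub._bonds
        new_r0 = np.array([parent_r0.get((a, b), parent_r0.get((b, a), r0))
                           for a, b, r0 in zip(sbi, sbj, sr0)])
        sub._bonds = (sbi, sbj, sk, new_r0)
        return sub, sub_sys


def make_reactive_complex(d: float | None = None) -> AtomicStructure:
    """A minimal two-atom reactive complex (C...O) for the toy reaction.

    Placed at the reactant-side minimum of the default double well unless
    a distance is given.
    """
    p = ReactionParams()
    if d is None:
        d = p.d_ts - p.half_width
    return AtomicStructure(("C", "O"),
                           np.array([[-d / 2, 0.0, 0.0], [d / 2, 0.0, 0.0]]),
                           comment="toy reactive complex")


def toy_engine_for(system: MolecularSystem,
                   reaction: ReactionParams | None = None,
                   **kwargs) -> ToyPotential:
    """Build the default toy engine for a droplet system."""
    return ToyPotential(system, reaction or ReactionParams(), **kwargs)
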