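"""QM-region construction from spheres around reactive/active atoms.

A QM region is the union of spheres centred on a set of atoms, with two
closure rules: every solute (reactive-complex) atom is always included,
and any solvent molecule with at least one atom inside a sphere is
included in full. Sphere radii are either a fixed value (large-region
stage, 4.5 A default) or scale with the covalent radii of the centre atom
and a solvent probe atom, ``r_s = s * (r_cov,center + r_cov,probe)``.

The three staged defaults are lQM (fixed 4.5 A around reactive+active
atoms), mQM (scaled, s = 2.3) and sQM (scaled, s = 2.0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import elements
from .structure import MolecularSystem

__all__ = [
    "RadiusPolicy",
    "RegionSelection",
    "STAGE_POLICIES",
    "sphere_radius",
    "atoms_within",
    "build_region",
    "stage_region",
]


@dataclass(frozen=True)
class RadiusPolicy:
    """How the per-centre sphere radius is chosen.

    mode ``"fixed"`` uses ``r_c`` for every centre; mode ``"scaled"`` uses
    ``s * (r_cov(center) + r_cov(probe_element))``. The probe element
    defaults to hydrogen and can be swapped for a solvent-specific atom
    (e.g. Cl for dichloromethane).
    """

    mode: str = "fixed"
    r_c: float = 4.5
    s: float = 2.3
    probe_element: str = "H"

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "scaled"):
            raise ValueError(f"unknown radius mode {self.mode!r}")
        if self.r_c <= 0:
            raise ValueError("r_c must be positive")
        if self.s < 0:
            raise ValueError("scaling factor must be non-negative")


@dataclass(frozen=True)
class RegionSelection:
    """The atom set of a QM region plus the policy that produced it."""

    atom_ids: frozenset
    center_atoms: frozenset
    per_center_radii: dict = field(default_factory=dict)
    policy: RadiusPolicy = RadiusPolicy()

    def __post_init__(self) -> None:
        object.__setattr__(self, "atom_ids", frozenset(int(i) for i in self.atom_ids))
        object.__setattr__(self, "center_atoms",
                           frozenset(int(i) for i in self.center_atoms))

    @property
    def n_atoms(self) -> int:
        return len(self.atom_ids)


def sphere_radius(center_symbol: str, policy: RadiusPolicy) -> float:
    """Sphere radius in Angstrom for a centre atom under ``policy``."""
    if policy.mode == "fixed":
        return policy.r_c
    return policy.s * (elements.covalent_radius(center_symbol)
                       + elements.covalent_radius(policy.probe_element))


def atoms_within(system: MolecularSystem, center: int, r_s: float) -> frozenset:
    """Atoms within (closed inequality) ``r_s`` of atom ``center``.

    The centre itself is always a member (distance zero).
    """
    if r_s < 0:
        raise ValueError("radius must be non-negative")
    coords = system.structure.coordinates
    if not 0 <= center < len(coords):
        raise IndexError(f"center atom {center} out of range")
    d = np.linalg.norm(coords - coords[center], axis=1)
    return frozenset(np.nonzero(d <= r_s)[0].tolist())


def build_region(system: MolecularSystem, centers, policy: RadiusPolicy) -> RegionSelection:
    """Union of spheres over ``centers`` with solute and whole-molecule closure.

    All solute atoms are added unconditionally; any solvent molecule with
    at least one atom in a sphere contributes all of its atoms.
    """
    centers = sorted(int(i) for i in centers)
    if not centers:
        raise ValueError("centers must be nonempty")
    radii = {c: sphere_radius(system.structure.symbols[c], policy) for c in centers}
    total: set[int] = set()
    for c in centers:
        total |= atoms_within(system, c, radii[c])
    total |= system.solute_atoms()
    for mol_id in system.partition.solvent_ids:
        mol = system.partition.molecules[mol_id]
        if mol & total:
            total |= mol
    return RegionSelection(frozenset(total), frozenset(centers), radii, policy)


STAGE_POLICIES: dict[str, RadiusPolicy] = {
    "lQM": RadiusPolicy(mode="fixed", r_c=4.5),
    "mQM": RadiusPolicy(mode="scaled", s=2.3),
    "sQM": RadiusPolicy(mode="scaled", s=2.0),
}


def stage_region(system: MolecularSystem, stage: str,
                 relevant_atoms=None) -> RegionSelection:
    """Build the region for a named stage with its default policy.

    lQM centres on the union of reactive and active atoms; mQM and sQM
    centre on the ``relevant_atoms`` produced by the mode analysis.
    """
    if stage not in STAGE_POLICIES:
        raise ValueError(f"unknown stage {stage!r}; expected one of "
                         f"{sorted(STAGE_POLICIES)}")
    if stage == "lQM":
        centers = system.reactive_atoms | system.active_atoms
        if relevant_atoms:
            centers |= frozenset(int(i) for i in relevant_atoms)
    else:
        if not relevant_atoms:
            raise ValueError(f"stage {stage} requires a nonempty relevant-atom set")
        centers = frozenset(int(i) for i in relevant_atoms)
    if not centers:
        raise ValueError("no sphere centers: reactive/active atoms are empty")
    return build_region(system, centers, STAGE_POLICIES[stage])
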