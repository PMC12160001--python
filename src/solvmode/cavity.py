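"""Cavity-entropy correction for microsolvated activation free energies.

The RRHO model misses the entropy penalty of assembling a solute-solvent
cluster from isolated species in a continuum. A scaled-particle-theory
style cavity term captures part of it: the solvent's packing fraction is
estimated from its relative permittivity,

    y = (3 / 4 pi) * (eps_r - 1) / (eps_r + 2),

the cavity size enters through the cube-root volume ratio
R_s = (V_solute / V_solvent)^(1/3), and the dimensionless cavity work (in
units of RT) is

    g_c = -ln(1 - y) + R_s * 3y/(1-y)
          + R_s^2 * (3y/(1-y) + (9/2) (y/(1-y))^2).

The cavity free energy is G_c = RT g_c and the cavity entropy
S_c = G_c / T = R g_c. The activation correction compares the TS cavity
with the cavities of the isolated solute fragments and the n explicit
solvent molecules,

    dS_c = S_c(TS) - (sum_i S_c(R'_i) + n S_c(L)),

which is non-positive for volume-additive transition states, and the
corrected barrier is dG_c = dG - T dS_c.

Solvent mixtures use mole-fraction-weighted arithmetic means of eps_r and
the molecular volume (1:1 water/methanol gives eps_r = 56.52 with the
shipped database).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import yaml

from . import constants as const
from .structure import AtomicStructure, molecular_volume, read_xyz

__all__ = [
    "SolventSpec",
    "MixtureSpec",
    "CavityResult",
    "load_solvent",
    "available_solvents",
    "packing_fraction",
    "radius_ratio",
    "cavity_work",
    "cavity_entropy",
    "delta_Sc_activation",
    "corrected_gibbs",
    "mixture_effective",
]

Y_MAX = 3.0 / (4.0 * math.pi)


@dataclass(frozen=True)
class SolventSpec:
    """A solvent: relative permittivity, molecular volume, template geometry."""

    name: str
    relative_permittivity: float
    molecular_volume: float  # A^3
    template: AtomicStructure | None = None

    def __post_init__(self) -> None:
        if self.relative_permittivity < 1:
            raise ValueError("relative permittivity must be >= 1")
        if self.molecular_volume <= 0:
            raise ValueError("molecular volume must be positive")

    @property
    def effective_permittivity(self) -> float:
        return self.relative_permittivity

    @property
    def effective_volume(self) -> float:
        return self.molecular_volume


@dataclass(frozen=True)
class MixtureSpec:
    """A solvent mixture reduced to effective permittivity and volume."""

    components: tuple[tuple[SolventSpec, float], ...]
    effective_permittivity: float
    effective_volume: float

    @property
    def name(self) -> str:
        return "+".join(f"{s.name}:{f:g}" for s, f in self.components)


def _database() -> dict:
    text = resources.files("solvmode.data").joinpath("solvents.yaml").read_text()
    return yaml.safe_load(text)


def available_solvents() -> tuple[str, ...]:
    return tuple(sorted(_database()))


def load_solvent(name: str, points_per_atom: int = 256) -> SolventSpec:
    """Load a shipped solvent; its volume is computed from the template
    geometry with the same convex-hull convention used for solutes."""
    db = _database()
    if name not in db:
        raise KeyError(f"unknown solvent {name!r}; available: {sorted(db)}")
    entry = db[name]
    template_path = resources.files("solvmode.data").joinpath(entry["template"])
    with resources.as_file(template_path) as p:
        template = read_xyz(p)
    volume = molecular_volume(template, points_per_atom)
    return SolventSpec(name=name,
                       relative_permittivity=float(entry["relative_permittivity"]),
                       molecular_volume=volume, template=template)


def packing_fraction(eps_r: float) -> float:
    """Packing fraction y from the relative permittivity; y in [0, 3/4pi)."""
    if eps_r < 1:
        raise ValueError("relative permittivity must be >= 1")
    return Y_MAX * (eps_r - 1.0) / (eps_r + 2.0)


def radius_ratio(v_solute: float, v_solvent: float) -> float:
    """R_s = (V_solute / V_solvent)^(1/3)."""
    if v_solute <= 0 or v_solvent <= 0:
        raise ValueError("volumes must be positive")
    return (v_solute / v_solvent) ** (1.0 / 3.0)


def cavity_work(y: float, r_s: float) -> float:
    """Dimensionless cavity-formation work g_c (units of RT)."""
    if not 0 <= y < 1:
        raise ValueError("packing fraction must lie in [0, 1)")
    if r_s < 0:
        raise ValueError("radius ratio must be non-negative")
    t = y / (1.0 - y)
    return -math.log1p(-y) + r_s * 3.0 * t + r_s ** 2 * (3.0 * t + 4.5 * t * t)


def cavity_entropy(species_volume: float, solvent, T: float = 298.15) -> float:
    """Cavity entropy S_c = R g_c in J/(mol K) for one species.

    ``solvent`` is a SolventSpec or MixtureSpec. The temperature enters
    only through G_c = RT g_c; S_c itself is temperature-independent
    because eps_r is treated as constant.
    """
    y = packing_fraction(solvent.effective_permittivity)
    r_s = radius_ratio(species_volume, solvent.effective_volume)
    return const.GAS_CONSTANT_R * cavity_work(y, r_s)


def cavity_free_energy(species_volume: float, solvent, T: float = 298.15) -> float:
    """Cavity formation free energy G_c = RT g_c in kJ/mol."""
    return T * cavity_entropy(species_volume, solvent, T) / 1000.0


def delta_Sc_activation(ts_volume: float, fragment_volumes, n_solvent: int,
                        solvent, T: float = 298.15) -> float:
    """Change in cavity entropy of activation, J/(mol K).

    ``fragment_volumes`` are the isolated solute species R'_i; the n
    explicit solvent molecules contribute n times the solvent's own
    cavity entropy. Only isolated-species cavities and the TS cavity are
    needed; the reactant-cluster cavity cancels.
    """
    fragment_volumes = list(fragment_volumes)
    if not fragment_volumes:
        raise ValueError("fragment volume list must be nonempty")
    if n_solvent < 0:
        raise ValueError("n_solvent must be non-negative")
    s_ts = cavity_entropy(ts_volume, solvent, T)
    s_frag = sum(cavity_entropy(v, solvent, T) for v in fragment_volumes)
    s_solv = n_solvent * cavity_entropy(solvent.effective_volume, solvent, T)
    return s_ts - (s_frag + s_solv)


def corrected_gibbs(dG_kJ: float, dSc: float, T: float = 298.15) -> float:
    """Cavity-corrected activation free energy dG_c = dG - T dS_c (kJ/mol)."""
    return dG_kJ - T * dSc / 1000.0


def mixture_effective(components) -> MixtureSpec:
    """Mole-fraction-weighted arithmetic means of eps_r and volume.

    ``components`` is an iterable of (SolventSpec, fraction) pairs whose
    fractions sum to one.
    """
    comps = tuple((spec, float(frac)) for spec, frac in components)
    if not comps:
        raise ValueError("mixture needs at least one component")
    total = sum(f for _, f in comps)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"mole fractions must sum to 1, got {total}")
    eps = sum(f * s.relative_permittivity for s, f in comps)
    vol = sum(f * s.molecular_volume for s, f in comps)
    return MixtureSpec(comps, eps, vol)


@dataclass(frozen=True)
class CavityResult:
    """Cavity summary for one activation: per-species entropies and totals."""

    solvent_name: str
    eps_r: float
    y: float
    ts_volume: float
    fragment_volumes: tuple[float, ...]
    n_solvent: int
    S_c_ts: float
    S_c_fragments: tuple[float, ...]
    S_c_solvent: float
    dSc: float  # J/(mol K)
    T: float

    @staticmethod
    def compute(ts_volume: float, fragment_volumes, n_solvent: int, solvent,
                T: float = 298.15) -> "CavityResult":
        fragment_volumes = tuple(float(v) for v in fragment_volumes)
        dSc = delta_Sc_activation(ts_volume, fragment_volumes, n_solvent,
                                  solvent, T)
        return CavityResult(
            solvent_name=getattr(solvent, "name", "custom"),
            eps_r=solvent.effective_permittivity,
            y=packing_fraction(solvent.effective_permittivity),
            ts_volume=float(ts_volume),
            fragment_volumes=fragment_volumes,
            n_solvent=int(n_solvent),
            S_c_ts=cavity_entropy(ts_volume, solvent, T),
            S_c_fragments=tuple(cavity_entropy(v, solvent, T)
                                for v in fragment_volumes),
            S_c_solvent=cavity_entropy(solvent.effective_volume, solvent, T),
            dSc=dSc, T=T)
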