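"""RRHO thermochemistry and Eyring rates.

The standard rigid-rotor/harmonic-oscillator/particle-in-a-box model:
translational, rotational, and vibrational contributions to the internal
energy U and entropy S, assembled into H = U + pV (ideal gas, pV = RT per
mole) and G = H - T*S. Activation quantities between a reactant cluster
and its TS keep only the terms that survive the cancellation for equal
composition: dH = dE_el + dU_vib and dS = dS_rot + dS_vib. Rates follow
Eyring, k = (k_B T / h) exp(-dG / RT).

Units: energies kJ/mol, entropies J/(mol K), frequencies cm^-1,
temperatures K, pressures Pa. Imaginary frequencies are carried as
negative wavenumbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import constants as const
from .modes import HessianData
from .structure import AtomicStructure, principal_moments

__all__ = [
    "ThermoConditions",
    "SpeciesThermo",
    "ActivationResult",
    "translational",
    "rotational",
    "vibrational",
    "frequencies_from_hessian",
    "species_thermo",
    "activation",
    "eyring_rate",
]

NOISE_CUTOFF_CM = 5.0  # |nu| below this is numerical noise and is dropped
_LINEAR_MOMENT_TOL = 1e-3  # amu A^2; smallest moment below -> linear rotor


@dataclass(frozen=True)
class ThermoConditions:
    """Temperature (K), pressure (Pa) and rotational symmetry number."""

    T: float = 298.15
    p: float = const.ATM_PA
    sigma: int = 1

    def __post_init__(self) -> None:
        if self.T <= 0 or self.p <= 0:
            raise ValueError("temperature and pressure must be positive")
        if self.sigma < 1:
            raise ValueError("symmetry number must be >= 1")


@dataclass(frozen=True)
class SpeciesThermo:
    """Thermochemistry of a single structure at fixed conditions."""

    E_el: float  # kJ/mol
    frequencies: tuple[float, ...]  # real modes, cm^-1
    imaginary_count: int
    mass: float  # amu
    moments: tuple[float, float, float]  # amu A^2
    U_tra: float
    U_rot: float
    U_vib: float
    S_tra: float
    S_rot: float
    S_vib: float
    conditions: ThermoConditions

    @property
    def U(self) -> float:
        return self.E_el + self.U_tra + self.U_rot + self.U_vib

    @property
    def H(self) -> float:
        # ideal-gas pV work per mole
        return self.U + const.GAS_CONSTANT_R * self.conditions.T / 1000.0

    @property
    def S(self) -> float:
        return self.S_tra + self.S_rot + self.S_vib

    @property
    def G(self) -> float:
        return self.H - self.conditions.T * self.S / 1000.0


@dataclass(frozen=True)
class ActivationResult:
    """Activation quantities between a reactant and its TS."""

    dE_el: float  # kJ/mol
    dU_vib: float  # kJ/mol
    dH: float  # kJ/mol
    dS_rot: float  # J/(mol K)
    dS_vib: float  # J/(mol K)
    dS: float  # J/(mol K)
    dG: float  # kJ/mol
    rate: float  # 1/s
    T: float


def translational(mass_amu: float, cond: ThermoConditions) -> tuple[float, float]:
    """Particle-in-a-box translational (U, S): (3/2)RT and Sackur-Tetrode.

    Returns U in kJ/mol and S in J/(mol K).
    """
    if mass_amu <= 0:
        raise ValueError("mass must be positive")
    R, T = const.GAS_CONSTANT_R, cond.T
    m = mass_amu * const.AMU_KG
    q = (2.0 * math.pi * m * const.BOLTZMANN_KB * T / const.PLANCK_H ** 2) ** 1.5 \
        * const.BOLTZMANN_KB * T / cond.p
    U = 1.5 * R * T / 1000.0
    S = R * (2.5 + math.log(q))
    return U, S


def rotational(moments, cond: ThermoConditions) -> tuple[float, float]:
    """Rigid-rotor rotational (U, S) for an atom, linear, or nonlinear rotor.

    A single atom (all moments ~ 0) has no rotational degrees of freedom.
    Nonlinear rotors use the C1 nonsymmetric-top expression
    S = R(3/2 + ln[ sqrt(pi)/sigma * (8 pi^2 kB T / h^2)^(3/2)
                    * sqrt(Ia Ib Ic) ]).
    """
    moments = np.sort(np.asarray(moments, float))
    if np.any(moments < -1e-9):
        raise ValueError("moments of inertia must be non-negative")
    moments = np.clip(moments, 0.0, None)
    R, T = const.GAS_CONSTANT_R, cond.T
    amuA2 = const.AMU_KG * 1e-20  # amu A^2 -> kg m^2
    if moments[2] < _LINEAR_MOMENT_TOL:  # single atom
        return 0.0, 0.0
    beta = 8.0 * math.pi ** 2 * const.BOLTZMANN_KB * T / const.PLANCK_H ** 2
    if moments[0] < _LINEAR_MOMENT_TOL:  # linear rotor
        I = moments[2] * amuA2
        q = beta * I / cond.sigma
        return R * T / 1000.0, R * (1.0 + math.log(q))
    Ia, Ib, Ic = moments * amuA2
    q = math.sqrt(math.pi) / cond.sigma * beta ** 1.5 * math.sqrt(Ia * Ib * Ic)
    return 1.5 * R * T / 1000.0, R * (1.5 + math.log(q))


def vibrational(frequencies, cond: ThermoConditions) -> tuple[float, float]:
    """Harmonic-oscillator (U_vib, S_vib) summed over real modes.

    U_vib includes the zero-point energy; an empty list gives (0, 0).
    """
    freqs = np.asarray(list(frequencies), float)
    if freqs.size == 0:
        return 0.0, 0.0
    bad = np.nonzero(freqs <= 0)[0]
    if bad.size:
        raise ValueError(f"non-positive frequency at mode index {bad[0]}")
    T = cond.T
    x = const.PLANCK_H * const.SPEED_OF_LIGHT_CM * freqs / (const.BOLTZMANN_KB * T)
    nu_hz = const.SPEED_OF_LIGHT_CM * freqs
    occupation = 1.0 / np.expm1(x)
    U = const.AVOGADRO_NA * const.PLANCK_H * np.sum(nu_hz * (0.5 + occupation)) / 1000.0
    S = const.GAS_CONSTANT_R * np.sum(x * occupation - np.log1p(-np.exp(-x)))
    return float(U), float(S)


def _rigid_body_basis(coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Orthonormal mass-weighted translation/rotation vectors (columns)."""
    n = len(masses)
    com = masses @ coords / masses.sum()
    x = coords - com
    sqm = np.sqrt(masses)
    vecs = []
    for k in range(3):
        t = np.zeros((n, 3))
        t[:, k] = sqm
        vecs.append(t.ravel())
    for axis in np.eye(3):
        r = np.cross(np.broadcast_to(axis, (n, 3)), x) * sqm[:, None]
        vecs.append(r.ravel())
    basis = np.column_stack(vecs)
    # orthonormalize, dropping null directions (single atoms, linear species)
    q, r = np.linalg.qr(basis)
    keep = np.abs(np.diag(r)) > 1e-8 * max(1.0, np.abs(np.diag(r)).max())
    return q[:, keep]


def frequencies_from_hessian(structure: AtomicStructure, hessian: HessianData,
                             project: bool = True) -> np.ndarray:
    """Harmonic wavenumbers (cm^-1, ascending) from a full Cartesian Hessian.

    The Hessian is mass-weighted, rigid-body translations/rotations are
    projected out (Eckart), and eigenvalues are converted to wavenumbers;
    negative values encode imaginary modes. Rigid-body null modes are not
    returned.
    """
    if hessian.n_atoms != structure.n_atoms:
        raise ValueError("Hessian does not match the structure")
    if hessian.frozen_context:
        raise ValueError("thermochemistry requires a full (unfrozen) Hessian")
    if hessian.units == "hartree/bohr^2":
        h_ang = hessian.matrix / const.BOHR_ANGSTROM ** 2  # -> hartree/A^2
    elif hessian.units == "hartree/angstrom^2":
        h_ang = hessian.matrix
    else:
        raise ValueError(f"unsupported Hessian units {hessian.units!r}")
    sqm = np.repeat(np.sqrt(structure.masses), 3)
    h_mw = h_ang / sqm[:, None] / sqm[None, :]
    n_rigid = 0
    if project:
        basis = _rigid_body_basis(structure.coordinates, structure.masses)
        n_rigid = basis.shape[1]
        proj = np.eye(h_mw.shape[0]) - basis @ basis.T
        h_mw = proj @ h_mw @ proj
        h_mw = 0.5 * (h_mw + h_mw.T)
    w = np.linalg.eigvalsh(h_mw)
    # hartree/(A^2 amu) -> s^-2
    conv = const.HARTREE_J / (const.AMU_KG * 1e-20)
    omega2 = w * conv
    nu = np.sign(omega2) * np.sqrt(np.abs(omega2)) / (2.0 * math.pi * const.SPEED_OF_LIGHT_CM)
    if project:
        # discard the projected rigid-body null modes (smallest magnitudes)
        order = np.argsort(np.abs(nu))
        nu = np.delete(nu, order[:n_rigid])
    return np.sort(nu)


def species_thermo(structure: AtomicStructure, E_el: float, hessian: HessianData,
                   cond: ThermoConditions = ThermoConditions(),
                   is_ts: bool = False,
                   noise_cutoff: float = NOISE_CUTOFF_CM) -> SpeciesThermo:
    """Assemble the full RRHO thermochemistry of one structure.

    ``E_el`` is the electronic energy in kJ/mol. For a TS exactly one
    imaginary mode (beyond the noise cutoff) is expected and excluded from
    the vibrational sums; a minimum must have none.
    """
    nu = frequencies_from_hessian(structure, hessian)
    nu = nu[np.abs(nu) >= noise_cutoff]
    n_imag = int(np.sum(nu < 0))
    if is_ts:
        if n_imag == 0:
            raise ValueError("TS input has no imaginary mode")
        if n_imag > 1:
            raise ValueError(f"higher-order saddle: {n_imag} imaginary modes")
    elif n_imag:
        raise ValueError(f"minimum structure has {n_imag} imaginary mode(s)")
    real = tuple(float(v) for v in nu[nu > 0])
    mass = float(structure.masses.sum())
    moments = principal_moments(structure)
    U_tra, S_tra = translational(mass, cond)
    U_rot, S_rot = rotational(moments, cond)
    U_vib, S_vib = vibrational(real, cond)
    return SpeciesThermo(
        E_el=float(E_el), frequencies=real, imaginary_count=n_imag,
        mass=mass, moments=tuple(float(m) for m in moments),
        U_tra=U_tra, U_rot=U_rot, U_vib=U_vib,
        S_tra=S_tra, S_rot=S_rot, S_vib=S_vib, conditions=cond)


def activation(reactant: SpeciesThermo, ts: SpeciesThermo,
               cond: ThermoConditions | None = None) -> ActivationResult:
    """Activation quantities; translational terms cancel by construction."""
    if cond is None:
        cond = reactant.conditions
    for sp in (reactant, ts):
        if (sp.conditions.T, sp.conditions.p) != (cond.T, cond.p):
            raise ValueError("species evaluated at different conditions")
    dE_el = ts.E_el - reactant.E_el
    dU_vib = ts.U_vib - reactant.U_vib
    dH = dE_el + dU_vib
    dS_rot = ts.S_rot - reactant.S_rot
    dS_vib = ts.S_vib - reactant.S_vib
    dS = dS_rot + dS_vib
    dG = dH - cond.T * dS / 1000.0
    return ActivationResult(dE_el, dU_vib, dH, dS_rot, dS_vib, dS, dG,
                            rate=eyring_rate(dG, cond.T), T=cond.T)


def eyring_rate(dG_kJ: float, T: float) -> float:
    """Eyring rate constant k = (k_B T / h) exp(-dG / RT) in 1/s."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    prefactor = const.BOLTZMANN_KB * T / const.PLANCK_H
    return prefactor * math.exp(-dG_kJ * 1000.0 / (const.GAS_CONSTANT_R * T))
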