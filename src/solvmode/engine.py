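"""Engine contract and generic structure-manipulation routines.

An :class:`Engine` supplies energies, gradients and (partial) Hessians
for a fixed atom topology. On top of that contract this module provides
the structure manipulations the staged pipeline needs: minimization and
transition-state optimization under frozen-atom masks, and steepest-
descent reaction-path (IRC-style) integration. Frozen atoms are
bit-exact invariant under every routine.

Engine units: energies hartree, coordinates Angstrom, gradients
hartree/Angstrom, Hessians hartree/Angstrom^2.
"""

from __future__ import annotations

import abc

import numpy as np
from scipy.optimize import minimize

from .modes import HessianData, ModeSet, NoTransitionStateError, score_modes

__all__ = [
    "Engine",
    "ConvergenceError",
    "optimize",
    "ts_optimize",
    "irc_endpoints",
]


class ConvergenceError(RuntimeError):
    """An optimizer failed to reach the requested gradient norm."""


class Engine(abc.ABC):
    """Energy/gradient/Hessian provider over a fixed set of atoms."""

    @abc.abstractmethod
    def energy(self, coords: np.ndarray) -> float:
        ...

    @abc.abstractmethod
    def gradient(self, coords: np.ndarray) -> np.ndarray:
        """Gradient as an (N, 3) array, hartree/Angstrom."""

    @abc.abstractmethod
    def hessian(self, coords: np.ndarray, atom_ids=None) -> HessianData:
        """Analytic Hessian over ``atom_ids`` (all atoms if None), with the
        remaining atoms frozen (their rows/columns excluded)."""


def _free_index(n_atoms: int, free_atoms) -> np.ndarray:
    idx = np.array(sorted(int(i) for i in free_atoms), dtype=int)
    if len(idx) == 0:
        raise ValueError("no free atoms")
    if idx[0] < 0 or idx[-1] >= n_atoms:
        raise IndexError("free atom index out of range")
    return idx


def optimize(engine: Engine, coords: np.ndarray, free_atoms,
             gtol: float = 1e-5, max_iter: int = 2000) -> np.ndarray:
    """Minimize the energy over the free atoms; frozen atoms untouched.

    ``gtol`` bounds the max-abs gradient component (hartree/Angstrom).
    """
    coords = np.array(coords, float)
    idx = _free_index(len(coords), free_atoms)

    def fun(x):
        c = coords.copy()
        c[idx] = x.reshape(-1, 3)
        g = engine.gradient(c)
        return engine.energy(c), g[idx].ravel()

    res = minimize(fun, coords[idx].ravel(), jac=True, method="L-BFGS-B",
                   options={"maxiter": max_iter, "gtol": gtol, "ftol": 1e-14})
    out = coords.copy()
    out[idx] = res.x.reshape(-1, 3)
    # Newton polish: L-BFGS may stop on ftol slightly above the target
    for _ in range(50):
        g = engine.gradient(out)[idx].ravel()
        if np.abs(g).max() <= gtol:
            return out
        hess = engine.hessian(out, atom_ids=idx).matrix
        w, v = np.linalg.eigh(hess)
        lam = np.where(np.abs(w) < 1e-6, 1e-6, np.abs(w))
        step = -(v @ ((v.T @ g) / lam))
        norm = np.linalg.norm(step)
        if norm > 0.2:
            step *= 0.2 / norm
        out = out.copy()
        out[idx] += step.reshape(-1, 3)
    if np.abs(engine.gradient(out)[idx]).max() > gtol:
        raise ConvergenceError(
            f"minimization stalled above gtol={gtol} after {res.nit} iterations")
    return out


def _select_mode(modeset: ModeSet, masses_free: np.ndarray,
                 reactive_local) -> int:
    """Pick the mode to follow: scored selection if possible, else lowest."""
    if reactive_local and np.any(modeset.eigenvalues < 0):
        try:
            return score_modes(modeset, masses_free, reactive_local).selected_index
        except NoTransitionStateError:  # pragma: no cover
            pass
    return 0  # ascending order: the lowest eigenvalue


def ts_optimize(engine: Engine, coords: np.ndarray, free_atoms, masses,
                reactive_atoms=(), gtol: float = 1e-5, max_iter: int = 200,
                trust_radius: float = 0.3) -> np.ndarray:
    """Eigenvector-following saddle search over the free atoms.

    At each step the partial Hessian over the free atoms is diagonalized,
    the followed mode is chosen by the reactive-contribution score (the
    lowest mode if no negative eigenvalue exists yet), and a partitioned
    Newton step maximizes along that mode while minimizing along all
    others. Adequate for analytic surfaces.
    """
    coords = np.array(coords, float)
    idx = _free_index(len(coords), free_atoms)
    pos = {a: k for k, a in enumerate(idx)}
    reactive_local = [pos[int(a)] for a in reactive_atoms if int(a) in pos]
    masses = np.asarray(masses, float)
    for _ in range(max_iter):
        g = engine.gradient(coords)[idx].ravel()
        if np.abs(g).max() <= gtol:
            hess = engine.hessian(coords, atom_ids=idx)
            if np.linalg.eigvalsh(hess.matrix)[0] < 0:
                return coords
        hess = engine.hessian(coords, atom_ids=idx)
        w, v = np.linalg.eigh(hess.matrix)
        sel = _select_mode(ModeSet(w, v), masses[idx], reactive_local)
        comps = v.T @ g
        lam = np.abs(w)
        lam = np.where(lam < 1e-4, 1e-4, lam)
        lam[sel] = -lam[sel]  # maximize along the followed mode
        step = -(v @ (comps / lam))
        norm = np.linalg.norm(step)
        if norm > trust_radius:
            step *= trust_radius / norm
        coords = coords.copy()
        coords[idx] += step.reshape(-1, 3)
    raise ConvergenceError(f"TS optimization did not converge in {max_iter} steps")


def irc_endpoints(engine: Engine, ts_coords: np.ndarray, free_atoms, masses,
                  mode: np.ndarray, delta: float = 0.1, gtol: float = 1e-5,
                  max_steps: int = 5000, step_size: float = 0.05):
    """Follow the reaction path downhill from a TS in both directions.

    The TS is displaced by ``delta`` (mass-weighted norm, Angstrom) along
    +/- the followed mode (a Cartesian vector over the free atoms); a
    damped steepest descent relaxes each side, and the end points are
    polished with :func:`optimize`. Returns (forward, backward) coordinate
    arrays.
    """
    ts_coords = np.asarray(ts_coords, float)
    idx = _free_index(len(ts_coords), free_atoms)
    masses = np.asarray(masses, float)[idx]
    mode = np.asarray(mode, float).reshape(-1, 3)
    if len(mode) != len(idx):
        raise ValueError("mode vector must span the free atoms")
    mw = mode * np.sqrt(masses)[:, None]
    disp = mode * (delta / np.linalg.norm(mw))

    def descend(sign: float) -> np.ndarray:
        coords = ts_coords.copy()
        coords[idx] += sign * disp
        alpha = step_size
        e_prev = engine.energy(coords)
        for _ in range(max_steps):
            g = engine.gradient(coords)[idx]
            if np.abs(g).max() <= gtol:
                break
            trial = coords.copy()
            gnorm = np.linalg.norm(g)
            trial[idx] -= alpha * g / max(gnorm, 1e-12)
            e_trial = engine.energy(trial)
            if e_trial <= e_prev:
                coords, e_prev = trial, e_trial
                alpha = min(alpha * 1.2, 0.2)
            else:
                alpha *= 0.5
                if alpha < 1e-8:
                    break
        return optimize(engine, coords, idx, gtol=gtol)

    return descend(+1.0), descend(-1.0)
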