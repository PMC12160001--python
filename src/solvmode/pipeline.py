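"""Three-stage region-pruning pipeline over a pluggable engine.

Stage 1 (lQM): relax the solvent droplet with the reactive complex
frozen, build a large QM region from fixed 4.5 A spheres (rebuilt between
two loosened-convergence relaxation passes), search for a TS guess and
compute the partial Hessian of the region with the environment frozen.

Stage 2 (mQM): analyze that Hessian's reaction mode, shrink to a medium
region (scaled radii, s = 2.3) around the relevant atoms, re-relax the
environment, optimize the TS, follow the reaction path to both minima
and disassemble the reactant-side cluster into molecules.

Stage 3 (sQM): analyze the TS mode again, shrink to the small region
(s = 2.0), re-optimize TS and path on the standalone cluster (the
continuum-stage hand-off), and evaluate the activation quantities:
electronic barrier dE_el, RRHO free-energy barrier dG, and the
cavity-entropy-corrected barrier dG_c, together with the number of
active solvent molecules.

Failed trials are data, not exceptions: every failure is recorded with
its stage and cause.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import constants as const
from .cavity import (SolventSpec, corrected_gibbs, delta_Sc_activation,
                     load_solvent)
from .engine import ConvergenceError, irc_endpoints, optimize, ts_optimize
from .modes import (ContributionReport, HessianData, NoTransitionStateError,
                    analyze_hessian, diagonalize)
from .regions import RegionSelection, stage_region
from .structure import (AtomicStructure, MolecularSystem, detect_molecules,
                        molecular_volume)
from .synthetic import (DropletConfig, PackingError, ReactionParams,
                        make_droplet, toy_engine_for)
from .thermo import ThermoConditions, activation, species_thermo

__all__ = [
    "PipelineConfig",
    "StageRecord",
    "TrialResult",
    "run_stage1",
    "run_stage2",
    "run_stage3",
    "run_trial",
    "run_batch",
    "summarize_ensemble",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable knobs of the staged pipeline.

    ``base_gtol`` is the gradient-norm convergence criterion in
    hartree/bohr; the loosened lQM passes multiply it by
    ``loosen_factor`` (ten by default).
    """

    droplet: DropletConfig = field(default_factory=DropletConfig)
    reaction: ReactionParams = field(default_factory=ReactionParams)
    lqm_iterations: int = 2
    loosen_factor: float = 10.0
    base_gtol: float = 3e-4  # hartree/bohr
    endpoint_gtol: float = 1e-6  # hartree/bohr, stationary-point polish
    threshold_factor: float = 1.0
    score_weights: tuple[float, float] = (0.5, 0.5)
    conditions: ThermoConditions = field(default_factory=ThermoConditions)
    solvent: str = "water"
    irc_delta: float = 0.1  # Angstrom, mass-weighted displacement

    @property
    def gtol(self) -> float:  # hartree/Angstrom
        return self.base_gtol / const.BOHR_ANGSTROM

    @property
    def gtol_loose(self) -> float:
        return self.gtol * self.loosen_factor

    @property
    def gtol_tight(self) -> float:
        return self.endpoint_gtol / const.BOHR_ANGSTROM

    def solvent_spec(self) -> SolventSpec:
        if isinstance(self.solvent, SolventSpec):
            return self.solvent
        return load_solvent(self.solvent)


@dataclass
class StageRecord:
    """Artifacts of one pipeline stage."""

    stage: str
    region: RegionSelection
    structures: dict = field(default_factory=dict)  # name -> (N,3) coords
    mode_report: ContributionReport | None = None
    hessian: HessianData | None = None
    energies: dict = field(default_factory=dict)  # hartree
    barriers: dict = field(default_factory=dict)  # stage 3 only


@dataclass
class TrialResult:
    """Outcome of one seeded reaction trial."""

    seed: int
    success: bool
    records: list = field(default_factory=list)
    failure_stage: str | None = None
    failure_reason: str | None = None

    @property
    def n_active(self) -> int | None:
        if not self.success:
            return None
        return self.records[-1].barriers.get("n_active")


def _with_coords(system: MolecularSystem, coords: np.ndarray) -> MolecularSystem:
    return replace(system, structure=system.structure.with_coordinates(coords))


def _maybe_optimize(engine, coords, free_atoms, gtol):
    free_atoms = sorted(free_atoms)
    if not free_atoms:
        return np.array(coords, float)
    return optimize(engine, coords, free_atoms, gtol=gtol)


def run_stage1(system: MolecularSystem, engine, config: PipelineConfig) -> StageRecord:
    """Droplet relaxation, lQM construction, TS-guess search, partial Hessian."""
    coords = system.structure.coordinates
    solvent_atoms = sorted(set(range(system.n_atoms)) - system.solute_atoms())
    coords = _maybe_optimize(engine, coords, solvent_atoms, config.gtol)
    region = stage_region(_with_coords(system, coords), "lQM")
    for _ in range(config.lqm_iterations):
        free = sorted(region.atom_ids - system.solute_atoms())
        coords = _maybe_optimize(engine, coords, free, config.gtol_loose)
        region = stage_region(_with_coords(system, coords), "lQM")
    guess = engine.ts_guess(coords, free_atoms=sorted(region.atom_ids),
                            gtol=config.gtol)
    hessian = engine.hessian(guess, atom_ids=sorted(region.atom_ids))
    record = StageRecord(stage="1-lQM", region=region)
    record.structures["droplet"] = coords
    record.structures["ts_guess"] = guess
    record.hessian = hessian
    record.energies["ts_guess"] = engine.energy(guess)
    return record


def run_stage2(record1: StageRecord, system: MolecularSystem, engine,
               config: PipelineConfig) -> StageRecord:
    """Mode-guided shrink to mQM, TS optimization, reaction path, fragments."""
    guess = record1.structures["ts_guess"]
    sys_at_guess = _with_coords(system, guess)
    _, report = analyze_hessian(record1.hessian, sys_at_guess,
                                threshold_factor=config.threshold_factor,
                                weights=config.score_weights)
    region = stage_region(sys_at_guess, "mQM", report.relevant_atoms)
    mm_atoms = sorted(set(range(system.n_atoms)) - region.atom_ids)
    coords = _maybe_optimize(engine, guess, mm_atoms, config.gtol)
    ts = ts_optimize(engine, coords, sorted(region.atom_ids),
                     system.structure.masses,
                     reactive_atoms=system.reactive_atoms,
                     gtol=config.gtol)
    hessian = engine.hessian(ts, atom_ids=sorted(region.atom_ids))
    table, ts_report = analyze_hessian(hessian, _with_coords(system, ts),
                                       threshold_factor=config.threshold_factor,
                                       weights=config.score_weights)
    mode = diagonalize(hessian).eigenvectors[:, table.selected_index]
    fwd, bwd = irc_endpoints(engine, ts, sorted(region.atom_ids),
                             system.structure.masses, mode,
                             delta=config.irc_delta, gtol=config.gtol_tight)
    # reactant side: the endpoint closer to the pre-search droplet
    ref = record1.structures["droplet"]
    idx = sorted(region.atom_ids)
    rmsd = [float(np.sqrt(np.mean((e[idx] - ref[idx]) ** 2))) for e in (fwd, bwd)]
    reactant, product = (fwd, bwd) if rmsd[0] <= rmsd[1] else (bwd, fwd)
    record = StageRecord(stage="2-mQM", region=region, mode_report=ts_report,
                         hessian=hessian)
    record.structures.update(ts=ts, reactant=reactant, product=product)
    record.energies.update(ts=engine.energy(ts),
                           reactant=engine.energy(reactant),
                           product=engine.energy(product))
    return record


def _fragment_structures(sub_engine, sub_sys: MolecularSystem, coords,
                         gtol: float):
    """Disassemble a cluster into molecules and optimize each separately."""
    partition = detect_molecules(sub_sys.structure.with_coordinates(coords))
    fragments = []
    for mol in partition.molecules:
        idx = sorted(mol)
        frag_engine, frag_sys = sub_engine.subsystem(idx)
        frag_coords = optimize(frag_engine, coords[idx], range(len(idx)),
                               gtol=gtol) if len(idx) > 1 else coords[idx]
        structure = frag_sys.structure.with_coordinates(frag_coords)
        is_solute = bool(mol & sub_sys.solute_atoms())
        fragments.append((structure, is_solute, frag_engine.energy(frag_coords)))
    return fragments


def run_stage3(record2: StageRecord, system: MolecularSystem, engine,
               config: PipelineConfig) -> StageRecord:
    """Shrink to sQM, re-derive the path on the standalone cluster, and
    evaluate dE_el, dG and the cavity-corrected dG_c."""
    ts_full = record2.structures["ts"]
    sys_at_ts = _with_coords(system, ts_full)
    region = stage_region(sys_at_ts, "sQM", record2.mode_report.relevant_atoms)
    idx = sorted(region.atom_ids)
    sub_engine, sub_sys = engine.subsystem(idx)
    sub_sys = _with_coords(sub_sys, ts_full[idx])
    all_free = list(range(sub_sys.n_atoms))
    masses = sub_sys.structure.masses

    ts = ts_optimize(sub_engine, sub_sys.structure.coordinates, all_free,
                     masses, reactive_atoms=sub_sys.reactive_atoms,
                     gtol=config.gtol_tight)
    hessian = sub_engine.hessian(ts)
    table, report = analyze_hessian(hessian, _with_coords(sub_sys, ts),
                                    threshold_factor=config.threshold_factor,
                                    weights=config.score_weights)
    mode = diagonalize(hessian).eigenvectors[:, table.selected_index]
    fwd, bwd = irc_endpoints(sub_engine, ts, all_free, masses, mode,
                             delta=config.irc_delta, gtol=config.gtol_tight)
    old_to_new = {g: l for l, g in enumerate(idx)}
    ref = record2.structures["reactant"][idx]
    rmsd = [float(np.sqrt(np.mean((e - ref) ** 2))) for e in (fwd, bwd)]
    reactant = fwd if rmsd[0] <= rmsd[1] else bwd

    # stationary-point audit
    for name, c in (("ts", ts), ("reactant", reactant)):
        gmax = float(np.abs(sub_engine.gradient(c)).max())
        if gmax > config.gtol:
            raise ConvergenceError(f"sQM {name} not converged (|g|={gmax:.2e})")

    e_ts = sub_engine.energy(ts)
    e_r = sub_engine.energy(reactant)
    cond = config.conditions
    thermo_r = species_thermo(sub_sys.structure.with_coordinates(reactant),
                              e_r * const.HARTREE_KJ_PER_MOL,
                              sub_engine.hessian(reactant), cond)
    thermo_ts = species_thermo(sub_sys.structure.with_coordinates(ts),
                               e_ts * const.HARTREE_KJ_PER_MOL,
                               hessian, cond, is_ts=True)
    act = activation(thermo_r, thermo_ts, cond)

    solvent = config.solvent_spec()
    fragments = _fragment_structures(sub_engine, sub_sys, reactant,
                                     config.gtol_tight)
    solute_volumes = [molecular_volume(s) for s, is_solute, _ in fragments
                      if is_solute]
    n_solvent = sum(1 for _, is_solute, _ in fragments if not is_solute)
    ts_volume = molecular_volume(sub_sys.structure.with_coordinates(ts))
    dSc = delta_Sc_activation(ts_volume, solute_volumes, n_solvent, solvent,
                              cond.T)
    dGc = corrected_gibbs(act.dG, dSc, cond.T)

    record = StageRecord(stage="3-sQM", region=region, mode_report=report,
                         hessian=hessian)
    record.structures.update(ts=ts, reactant=reactant,
                             forward=fwd, backward=bwd)
    record.energies.update(ts=e_ts, reactant=e_r)
    record.barriers.update(
        dE_el=(e_ts - e_r) * const.HARTREE_KJ_PER_MOL,
        dH=act.dH, dS=act.dS, dG=act.dG, dSc=dSc, dGc=dGc,
        rate=act.rate, n_active=report.n_active,
        ts_volume=ts_volume, n_solvent_cluster=n_solvent)
    return record


def run_trial(rc: AtomicStructure, reactive_atoms, active_atoms,
              config: PipelineConfig, seed: int,
              engine_factory=None) -> TrialResult:
    """One seeded end-to-end trial; failures become data."""
    if engine_factory is None:
        engine_factory = lambda system: toy_engine_for(system, config.reaction)
    result = TrialResult(seed=seed, success=False)
    stage = "0-setup"
    try:
        droplet_cfg = replace(config.droplet, seed=seed)
        system = make_droplet(rc, droplet_cfg, reactive_atoms, active_atoms)
        engine = engine_factory(system)
        stage = "1-lQM"
        rec1 = run_stage1(system, engine, config)
        result.records.append(rec1)
        stage = "2-mQM"
        rec2 = run_stage2(rec1, system, engine, config)
        result.records.append(rec2)
        stage = "3-sQM"
        rec3 = run_stage3(rec2, system, engine, config)
        result.records.append(rec3)
        result.success = True
    except (ConvergenceError, NoTransitionStateError, PackingError,
            ValueError) as exc:
        result.failure_stage = stage
        result.failure_reason = f"{type(exc).__name__}: {exc}"
    return result


def run_batch(rc: AtomicStructure, reactive_atoms, active_atoms,
              config: PipelineConfig, n_trials: int, seed_base: int = 1000,
              engine_factory=None) -> list[TrialResult]:
    """Run ``n_trials`` seeded trials (seeds seed_base .. seed_base+n-1)."""
    return [run_trial(rc, reactive_atoms, active_atoms, config,
                      seed_base + k, engine_factory)
            for k in range(n_trials)]


def summarize_ensemble(results, quantity: str = "dGc") -> pd.DataFrame:
    """Five-number summaries of a barrier quantity grouped by n_active.

    Returns a DataFrame indexed by the active-solvent count with columns
    count, min, q1, median, q3, max (the box-plot statistics).
    """
    rows = []
    for r in results:
        if getattr(r, "success", False):
            rec = r.records[-1]
            rows.append((rec.barriers["n_active"], rec.barriers[quantity]))
        elif isinstance(r, StageRecord) and r.barriers:
            rows.append((r.barriers["n_active"], r.barriers[quantity]))
    if not rows:
        raise ValueError("no successful records to summarize")
    df = pd.DataFrame(rows, columns=["n_active", quantity])
    out = df.groupby("n_active")[quantity].agg(
        count="count", min="min",
        q1=lambda s: s.quantile(0.25),
        median="median",
        q3=lambda s: s.quantile(0.75),
        max="max")
    return out
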