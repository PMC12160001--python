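# solvmode

Staged QM-region selection, transition-state normal-mode analysis, and
microsolvated activation free energies for cluster–continuum reaction
modelling.

## The problem

Solvent molecules are often not spectators: in reactions such as the
hydration of a carbonyl group or of CO₂, water molecules shuttle protons
through ring-shaped transition-state motifs. Modelling this requires
*explicit* solvent molecules around the reacting solute — but only a
handful actually participate, and carrying the rest through expensive
electronic-structure calculations is wasteful. `solvmode` implements the
structure-preparation and free-energy machinery for this workflow:

1. **Microdroplet assembly** — seeded placement of two solvent shells
   around a reactive complex (`solvmode.synthetic.make_droplet`).
2. **QM-region selection** — a QM region is the union of spheres around
   the *reactive* atoms (bond-breaking/forming) and *active* atoms
   (solvent-interacting), with two closure rules: all solute atoms are
   always kept, and a solvent molecule with any atom inside a sphere is
   kept whole. Radii are fixed (large region, r_c = 4.5 Å) or scaled,
   r_s = s·(r_cov,center + r_cov,probe), with s = 2.3 for the medium and
   s = 2.0 for the small region (`solvmode.regions`).
3. **Reaction-mode analysis** — every negative-eigenvalue eigenvector
   **n**ᵢ of the (partial, non-mass-weighted) TS Hessian is mass-weighted
   (**n**⊙**m**), normalized, and scored,
   sᵢ = 0.5·w_norm,ᵢ + 0.5·Cᵢ, where w_norm,ᵢ = wᵢ/w_min and Cᵢ is the
   squared amplitude on the reactive atoms. The winning mode's per-atom
   contributions cᵢ (Σcᵢ = 1) are thresholded at the minimum
   reactive-atom contribution c_min: atoms with cᵢ ≥ c_min are
   *involved*, and solvent molecules containing involved atoms are the
   *active solvent molecules* (`solvmode.modes`).
4. **RRHO thermochemistry and Eyring rates** — translational
   (Sackur–Tetrode), rigid-rotor and harmonic-oscillator contributions to
   U and S; ΔH‡ = ΔE_el‡ + ΔU_vib‡, ΔS‡ = ΔS_rot‡ + ΔS_vib‡,
   ΔG‡ = ΔH‡ − TΔS‡, and k = (k_B T/h)·exp(−ΔG‡/RT)
   (`solvmode.thermo`).
5. **Cavity-entropy correction** — the cluster-assembly entropy penalty
   estimated from scaled-particle theory: packing fraction
   y = (3/4π)(ε_r−1)/(ε_r+2), cavity work g_c(y, R_s) with
   R_s = (V_solute/V_solvent)^⅓ from convex-hull van-der-Waals volumes,
   S_c = R·g_c, ΔS_c‡ = S_c^TS − (Σᵢ S_c^{R′ᵢ} + n·S_c^L), and
   ΔG_c‡ = ΔG‡ − TΔS_c‡ (`solvmode.cavity`).
6. **A three-stage pipeline** (`solvmode.pipeline`) that chains these
   over a pluggable engine contract. A fully analytic toy engine
   (harmonic bonds + a double-well reaction coordinate + finite-range
   repulsion) ships with the package, so the entire workflow runs and is
   tested offline, with no quantum-chemistry backend.

## Worked example

```python
import numpy as np
from solvmode import (DropletConfig, PipelineConfig, run_trial,
                      make_reactive_complex)

rc = make_reactive_complex()                 # two-atom toy reactive complex
cfg = PipelineConfig(droplet=DropletConfig(n_solvent=10))
result = run_trial(rc, reactive_atoms={0, 1}, active_atoms={1},
                   config=cfg, seed=1001)
for rec in result.records:
    print(rec.stage, len(rec.region.atom_ids))
print({k: round(v, 2) for k, v in result.records[-1].barriers.items()
       if isinstance(v, float)})
```

prints

```
1-lQM 11
2-mQM 2
3-sQM 2
{'dE_el': 52.51, 'dH': 45.36, 'dS': 3.41, 'dG': 44.35, 'dSc': 1.21,
 'dGc': 43.98, 'rate': 105691.07, 'ts_volume': 31.88}
```

The large region captured three waters (11 atoms); the mode analysis
found none of them participating in the reaction mode, so the medium and
small regions shrink to the two-atom solute. The electronic barrier is
the toy double-well height (0.02 hartree = 52.5 kJ/mol); zero-point and
thermal vibrational energy lower ΔH‡ to 45.4 kJ/mol, and the small
positive ΔS_c‡ (the TS cavity is slightly larger than the reactant
cavity of this unimolecular step) leaves ΔG_c‡ at 44.0 kJ/mol, an Eyring
rate of about 1×10⁵ s⁻¹ at 298.15 K.

A command-line interface mirrors the library
(`solvmode region | modes | thermo | activation | cavity | droplet |
synth-hessian | pipeline | report`); run `solvmode --help`.

## Scope

The package prepares structures and evaluates the free-energy model; it
deliberately contains no electronic-structure methods, force-field
parametrization, continuum solvers, or reaction-network exploration.
Real engines can be plugged in through the `solvmode.engine.Engine`
contract. See `docs/methods.md` for model details and limitations.
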