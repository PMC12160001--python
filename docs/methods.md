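# Methods

This note records the models implemented in `solvmode`, the defaults and
why they were chosen, what the synthetic generators do and do not
emulate, and the numerical conventions a user should know before
trusting a number.

## Region construction

A QM region is the union of closed spheres around a set of centre atoms.
Membership uses the closed inequality `d ≤ r_s`, so an atom exactly on a
sphere boundary is inside. Two closure rules are applied after the
sphere union: every solute (reactive-complex) atom is included
unconditionally, and a solvent molecule with at least one atom inside is
included whole — a region never cuts through a molecule, and because the
clusters dissect only weak intermolecular contacts no covalent boundary
capping is ever needed.

Radii come in two policies. The large-region (lQM) stage uses a fixed
radius, default 4.5 Å, around the union of reactive and active atoms
(both serve as centres; using only reactive atoms would under-solvate
hydrogen-bond acceptors that are active but not bond-breaking). The
medium (mQM) and small (sQM) stages use element-scaled radii
`r_s = s·(r_cov,centre + r_cov,probe)` around the *relevant atoms* from
the mode analysis, with s = 2.3 and s = 2.0 respectively. The probe
element defaults to hydrogen (protic solvents); it is a parameter so
that, e.g., chlorine can be used for dichloromethane. Region size is
monotone in both r_c and s; the suite asserts this over
s ∈ {2.0, 2.3, 2.6, 2.9, 3.2}.

Distances are plain Euclidean in Å: the droplets are finite clusters,
so there is no periodic boundary or minimum-image convention.

Element data (Cordero 2008 covalent radii, Bondi/Mantina van der Waals
radii with Alvarez values for elements missing there, standard atomic
weights) ships as a plain-text table covering H–Rn. These tables are a
pinned choice; any self-consistent alternative would shift scaled radii
and hull volumes slightly but coherently.

## Reaction-mode analysis

The TS optimizers this workflow feeds operate on the non-mass-weighted
Cartesian Hessian, so the analysis does too. Every eigenvector with a
negative eigenvalue is a candidate reaction mode. Each is converted to
mass-weighted form by elementwise multiplication with the atomic masses
(`n ⊙ m`) and renormalized; mass weighting damps the otherwise dominant
amplitudes of hydrogen atoms. Multiplying by m rather than the
conventional √m is a deliberate convention of this scoring scheme — it
damps light atoms more aggressively — and the `weighting="sqrt_mass"`
switch provides the textbook alternative for comparison.

The candidate score is `s_i = 0.5·w_norm,i + 0.5·C_i` with
`w_norm,i = w_i / w_min` (eigenvalues normalized by the most negative
one, so w_norm ∈ [0, 1]) and C_i the summed squared amplitude of the
reactive atoms in the unit mass-weighted mode (also in [0, 1]). The
weights (0.5, 0.5) are configuration keys; equal weighting is the
default and fine-tuning has little effect in practice. Ties in the
argmax go to the more negative eigenvalue (stronger TS character).

The winning mode's per-atom contributions `c_i` sum to one. The
threshold is the minimum contribution among the reactive atoms, c_min:
atoms with `c_i ≥ f·c_min` are *involved* (f = 1 by default; f = 0.85 is
a useful analysis variant that admits borderline atoms), solvent
molecules containing an involved atom are *active*, and the involved
atoms plus the user-declared active atoms form the *relevant atoms* that
seed the next region. Partial Hessians (environment frozen) break
translational invariance, so no rigid-body projection is applied before
scoring; projection happens only in the thermochemistry, which requires
full Hessians. Reactive atoms are always inside every region by
construction, so they can never be missing from a partial Hessian; the
code asserts this rather than handling it.

## RRHO thermochemistry

Standard rigid-rotor/harmonic-oscillator/particle-in-a-box expressions
with CODATA-2018 constants pinned in one module; energies in kJ/mol,
entropies in J/(mol K), frequencies in cm⁻¹. Defaults: T = 298.15 K,
p = 1 atm, σ = 1 (an asymmetric solute–solvent cluster has C₁ symmetry),
singlet states, no electronic degeneracy. The nonsymmetric-rotor entropy
is used for nonlinear species, the linear-rotor formula when the
smallest principal moment vanishes (below 10⁻³ amu Å²), and atoms have
no rotational contribution. H = U + RT (ideal-gas pV per mole);
G = H − TS.

Full Hessians are mass-weighted, Eckart-projected (3 translations plus 3
rotations, 2 for linear species), and diagonalized; eigenvalues convert
to wavenumbers with imaginary modes carried as negative numbers. Modes
with |ν| < 5 cm⁻¹ are discarded as numerical noise — this also removes
the internal rigid-body modes of non-interacting sub-clusters on the toy
surface. A TS must retain exactly one imaginary mode (more is a
higher-order-saddle error, none is a not-a-TS error); a minimum must
retain none.

For activation quantities between species of identical composition the
translational terms cancel exactly, leaving
ΔH‡ = ΔE_el‡ + ΔU_vib‡ and ΔS‡ = ΔS_rot‡ + ΔS_vib‡ with
ΔG‡ = ΔH‡ − TΔS‡; the suite verifies this shortcut against the
brute-force G(TS) − G(R) difference. Rates follow Eyring. Hindered-rotor
or quasi-harmonic low-frequency corrections are out of scope, as is any
conformational/ensemble averaging: all quantities are per-structure.

## Cavity entropy

The RRHO gas-phase model misses the entropy cost of assembling the
solute–solvent cluster from isolated species in solution. The correction
used here routes everything through two observables: the solvent's
relative permittivity, mapped to a packing fraction through the
Clausius–Mossotti-like form `y = (3/4π)(ε_r − 1)/(ε_r + 2)`
(y ∈ [0, 3/4π)), and molecular volumes, entering as the cube-root ratio
R_s. The scaled-particle cavity work

    g_c(y, R_s) = −ln(1−y) + R_s·3y/(1−y)
                  + R_s²·(3y/(1−y) + (9/2)(y/(1−y))²)

is dimensionless and is read as a free energy in units of RT, giving
G_c = RT·g_c and S_c = G_c/T = R·g_c. This reading reproduces correction
magnitudes of tens of J/(mol K) for molecule-sized cavities, the scale
such corrections should have; treating g_c as an absolute energy would
be dimensionally inconsistent. ε_r is treated as
temperature-independent, so S_c carries no ∂ε_r/∂T term.

The activation correction telescopes so that only isolated-species
cavities are needed:
`ΔS_c‡ = S_c^TS − (Σ_i S_c^{R′_i} + n·S_c^L)`, over the isolated solute
fragments R′_i of the reactant cluster and its n explicit solvent
molecules L. For any volume-additive TS (V_TS = ΣV_i + nV_L) this is
provably non-positive — each term of g_c is concave-subadditive in the
fragment volumes — so the correction always raises barriers in the
regime it is meant for; the suite checks this on 1000 random
decompositions. ΔG_c‡ = ΔG‡ − TΔS_c‡.

Volumes are convex hulls of deterministic Fibonacci-lattice samples
(256 points/atom by default) on van-der-Waals spheres, oriented in a
molecule-fixed principal-axes frame so the result is exactly invariant
under rigid motion (up to frame degeneracy for symmetric tops, where
residual orientation dependence is below 10⁻³ relative). Solvent volumes
are computed from the shipped template geometries with the same
convention, which is what makes R_s meaningful. The inscribed hull
underestimates the true union-of-spheres volume by O(1/n_points); since
only volume *ratios* enter, this bias largely cancels.

The shipped database pins water at ε_r = 80.10 and methanol at 32.94
(CRC 20 °C values); their 1:1 arithmetic mean is 56.52. Mixtures use
mole-fraction-weighted arithmetic means for both ε_r and volume — a
deliberate simplicity: real mixture permittivities are not linear in
composition, and the resulting MixtureSpec does not distinguish solvent
types in the analysis.

## Synthetic generators and the toy engine

`make_droplet` places two shells of rigid solvent templates around the
centred reactive complex by seeded rejection sampling: uniform shell
radius and direction, uniform random orientation from a normalized
quaternion, candidates rejected within 1.8 Å of any placed atom. Shells
default to [r_max+2.5, r_max+5.5] and [r_max+5.5, r_max+8.5] Å, which
accommodates on the order of 100 waters around a small solute. The
generator emulates geometry only: there is no energetic bias, hydrogen
bonding, or density equilibration, so droplets are sparser and more
isotropic than relaxed solvation shells. Every generator is a pure
function of (inputs, seed).

`make_ts_hessian` builds ground truth for the mode analysis: a Cartesian
unit vector whose mass-weighted per-atom squared norms equal prescribed
fractions exactly, completed to a seeded orthonormal basis, reassembled
as H = VΛVᵀ with one prescribed negative eigenvalue and a seeded
positive spectrum. Analysis of such a Hessian must reproduce the
fractions to 10⁻⁹ and flag exactly the prescribed molecules — the
suite's central parameter-recovery property.

The toy engine is an analytic cluster potential: stiff harmonic bonds on
all intramolecular pairs (k = 1 hartree/Å², rest lengths from the
template), one quartic double well along a designated interatomic
distance (barrier 0.02 hartree ≈ 52.5 kJ/mol, wells at d_ts ± 0.35 Å),
and a finite-range polynomial repulsion ε(1 − d/d_cut)⁴ between
molecules (ε = 0.005 hartree, d_cut = 2.6 Å, C²-smooth at the cutoff).
All terms depend only on interatomic distances, so energies are
rigid-motion invariant, and the finite range means configurations exist
where the double-well saddle is an exact analytic stationary point.
Because solvent couples to the solute only through weak short-range
repulsion, the toy reaction mode stays localized on the reaction pair
and trials typically report zero active solvent molecules — the toy
surface exercises the machinery and its bookkeeping, not the chemistry
of proton-shuttling networks. Passing tests therefore demonstrate
correctness of the algorithms, not realism of solvation energetics.

## Pipeline conventions

Convergence is a max-abs gradient criterion, base 3·10⁻⁴ hartree/bohr
(a conventional tight-optimization default), multiplied by ten for the
two loosened lQM relaxation passes and tightened to 10⁻⁶ hartree/bohr
for stationary points entering thermochemistry; the lQM region is
rebuilt between the passes. Minimization is L-BFGS on the free
coordinates with a regularized-Newton polish; TS refinement is
eigenvector following (partitioned Newton, the followed mode chosen by
the same reactive-contribution score, trust radius 0.3 Å); reaction
paths are damped steepest descent from the TS displaced ±0.1 Å
(mass-weighted norm) along the followed mode, with both ends polished to
minima. Frozen-atom masks are respected bit-exactly by every routine.
The reactant-side endpoint is identified as the one with smaller RMSD to
the pre-search droplet; the reactant cluster is disassembled into
molecules, each optimized in isolation, to supply the fragment volumes
of the cavity correction. Failed trials (packing, convergence, saddle
order) are recorded with stage and cause rather than raised, since hit
rates are themselves results.

The batch convention is 204 seeded trials. The shipped acceptance run
uses droplets of 10 solvent molecules — the package's choice of toy
problem size, large enough that the lQM region has real solvent content
and small enough that a full batch runs in minutes on one CPU. Per-seed
outputs are bit-reproducible.

## Known limitations

* The mode-based pruning sees only the TS: solvent molecules that
  stabilize reactant or product valleys without participating in the
  decaying mode are discarded.
* Per-structure free energies on a single path ignore conformational
  averaging; barriers from different trials are not samples of one
  thermodynamic state function.
* The cavity term is a heuristic: its RT-units reading and the
  permittivity→packing-fraction map are conventions, exposed as such,
  and mixtures are reduced to two effective scalars.
* The toy engine's solvent is chemically inert (no attractive
  solute–solvent interactions), so ensemble groupings by active-solvent
  count are degenerate on the shipped surface.
* Symmetric-top geometries leave the volume sampling frame
  under-determined; volumes remain deterministic but rotation invariance
  degrades to about 10⁻³ relative there.
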