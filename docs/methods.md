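# Methods

## Scope and model systems

The package implements selective Gaussian-accelerated dynamics as a
desk-scale, fully testable workflow.  The atomistic systems such a method
targets in practice (solvated peptides, glycosylated proteins) are replaced
by two classes of toy systems chosen so that every claim has an exact
reference:

* **Analytic surfaces** (`toy_systems.PotentialSurface`) — 1D/2D periodic
  potentials built from cosine series, Gaussian wells and harmonic terms.
  For one coordinate with a uniform configurational measure the PMF equals
  the potential up to a constant, so reweighting accuracy can be measured
  against a closed form.  The workhorse is `make_double_well(barrier)`,
  minima at ±90°, barrier at 0°/180°.
* **Bead systems** (`toy_systems.BeadSystem`) — small 3D mixtures of a
  bonded solute chain and free solvent beads with harmonic bonds, proper
  3-fold dihedrals, and a 12-6 pair interaction energy-shifted to zero at
  the cutoff (0.9 nm), with minimum-image periodicity.  Directly bonded
  (1-2) pairs are excluded from the nonbonded sum.  These provide the
  many-term energies the selective decomposition is about.

Units: kJ/mol, nm, ps, u, degrees in [−180, 180);
kB = 0.008314463 kJ mol⁻¹ K⁻¹.  Surface coordinates carry an effective
inertia (default 0.005 kJ mol⁻¹ ps² deg⁻²) chosen so well oscillation
periods are a few ps, which keeps decorrelation times short at the 0.1 ps
timestep used throughout the surface runs.

## Dynamics

`md_engine.run` integrates Langevin dynamics with the BAOAB splitting:
velocity half-kicks around a half-drift / Ornstein–Uhlenbeck / half-drift
core.  It samples the canonical ensemble with very small configurational
timestep bias and reduces to velocity Verlet at zero friction.  This
replaces the full production-engine apparatus (constraints, reaction-field
electrostatics, barostat, heat-up schedules) deliberately: the boost
machinery is independent of those details, and Langevin gives rigorous
canonical sampling on toy systems, which is what the correctness tests
need.  One seeded generator per run supplies the initial Maxwell–Boltzmann
velocities and the thermostat noise; bias providers receive no randomness,
which is what makes the selective-vs-monolithic equivalence check bit-exact.
Frames are recorded every `output_stride` steps (initial state included),
carrying per-term energies, per-region boost energies and CV values.

## Energy decomposition and acceleration regions

Groups must partition the beads (solvent is itself a group), so the
catalogue — N bonded, N self, N(N−1)/2 pair terms — is exhaustive and the
conservation property (term energies and forces summing to the
undecomposed totals at machine precision) is testable.  A bonded
interaction whose beads span two groups is an error rather than being
assigned arbitrarily: only nonbonded terms split across groups, and users
must draw group boundaries at nonbonded interfaces.  Under dual boosting
the torsional part of each group's bonded term is carved out into a
`dihedral_i` term; conservation then holds on the refined catalogue.
Terms assigned to no region are propagated unbiased.  Proper-dihedral
gradients are analytic and validated against finite differences of the
angle itself.

## Boost parameters and staging

The lower-bound rule is used exclusively: E = V_max (the maximal observed
region energy) and k = k0/(V_max − V_min) with k0 capped at 1.  The target
boost width σ0 defaults to 10 kJ/mol per region and is a per-region
configuration knob (the appropriate value scales with the region's energy
fluctuation; the bead-system examples use 3 kJ/mol).  The staged protocol
runs (1) an unbiased search accumulating streaming Welford statistics per
region, (2) a boosted search in which statistics keep accumulating —
cumulatively, so V_max/V_min are monotone — and parameters are
re-estimated every update interval (default: search length/50), and (3) a
production run with parameters frozen at the final search values.  The
alternative of re-deriving production parameters from the complete search
statistics would differ only when the last update interval saw a new
extremum; freezing at the final adaptive values was chosen as the simpler
contract.  Dual boosting uses one joint dihedral sub-term per region (not
per group); a dual-boost region without torsions degrades to a zero
dihedral sub-boost with a warning.

## Reweighting and the anharmonicity diagnostic

Both estimators bin samples on the CV grid.  The cumulant expansion uses
the per-bin population mean and variance of ΔV; exponential averaging
subtracts the per-bin maximum before exponentiation.  Empty bins carry
NaN, occupied minima anchor the PMF at zero, and bins with fewer than 10
samples are flagged (not suppressed) via `FreeEnergySurface.reliable`.

Anharmonicity is the entropy deficit γ = S_gauss − S_emp, with S_emp the
differential entropy of a Freedman–Diaconis histogram of the boost
samples; the population value is non-negative, so the estimate is clipped
at zero.  The estimator is deliberately swappable — the quantity is a
convention, and different codes use different entropy estimators.

A structural caveat worth stating: γ < 0.1 is achievable only when the
region energy aggregates many degrees of freedom (central-limit regime).
For a single-coordinate surface the equilibrium energy distribution is
χ²₁-like (density of states ∝ (V−V_min)^{−1/2}), ΔV is a near-affine
function of V, and γ is invariant under affine maps — so the double-well
boost measures γ ≈ 0.4 no matter how the parameters are chosen.  This does
*not* degrade reweighting there: within a narrow CV bin of a 1-dof system
ΔV is nearly deterministic, so the per-bin cumulant expansion is
essentially exact (measured PMF error ≈ 0.06 kBT).  On bead systems, where
region energies sum many terms, γ drops below 0.05 as expected.

## LEUS

The grid bias is B(Q) = c·Σ_k n_k·Π_d g(MI(Q_d − Q*_k,d)) over an
N_l-dimensional periodic grid (N_g cells per dimension, grid points at
cell centers, floor-based cell assignment with boundary ties to the lower
cell).  Defaults follow common dihedral practice: N_g = 36,
σ = 360°/N_g, c = 0.005 kJ/mol per visit.  The kernel g is pluggable; the
default is a finite-support Gaussian with the truncation offset removed,
g(d) = (e^{−d²/2σ²} − e^{−κ²/2})/(1 − e^{−κ²/2}) on |d| ≤ κσ with κ = 2,
so g(0) = 1, g(±2σ) = 0 and — unlike a raw truncated Gaussian, which
jumps by e^{−2} ≈ 0.135 per kernel at its edge — the biased Hamiltonian is
continuous, keeping the umbrella-phase ensemble well defined.  A raw
truncated Gaussian is provided alongside.  LE updates increment the
current cell once per step; freezing makes the Hamiltonian
time-independent and is required before umbrella reweighting
(p ∝ p_biased·⟨e^{+βB}⟩ per bin).  Per-linkage biases built on fragments
and recombined are out of scope: one bias per CV subspace.

## Conformer analytics

Letter regions are axis-aligned boxes on the dihedral torus with half-open,
wrap-aware intervals; region tables are user-editable (the shipped ones are
synthetic fixtures, not literature basin definitions).  Angles falling
outside every region are assigned to the nearest region center by periodic
distance (default) or labeled `X`.  Durations follow the convention that a
frame represents one `frame_dt` of residence: a run of m frames lasts
m·frame_dt, and both the dwell filter (default τ = 10 ps) and the event
detector (e.g. value ≤ 0.3 held ≥ 100 ps) are boundary-inclusive.  The
dwell criterion uses one contiguous run by default, with a cumulative-
occupancy mode available.  Transitions are counted on the recorded-frame
grid with no interpolation, matching per-ns rate reporting.

## Problem sizes and what the tests show

The default verification runs use 10⁴ steps of unbiased search, 3×10⁴ of
adaptive search and 1.5×10⁵ of production on the double well (with 2×10⁵
LE and 1.5×10⁵ US steps for the LEUS reference) — a few seconds each,
chosen as the smallest sizes at which the stochastic checks sit well clear
of their thresholds.  Passing them shows the machinery is correct:
conservation exact to rounding, the boost law and its gradient exact, the
selective path bit-identical to a monolithic reference when M = 1, and
free-energy recovery accurate against closed forms.  What toy systems
cannot show is behavior that depends on atomistic structure — forcefield
accuracy, solvent viscosity effects on barrier crossing, the actual basin
geometry of real glycosidic linkages — so quantitative results on real
systems (boost magnitudes, transition rates, conformer counts) are outside
what these tests certify.

## Known limitations

* Boost thresholds implement the lower-bound rule only (E = V_max); the
  upper-bound variant is not provided.
* LEUS dynamics runs on surface coordinates (the CV is the coordinate);
  grid biases in 1 or 2 dimensions.
* No replica exchange and no sigmoid-shaped acceleration.
* The bead nonbonded interaction is energy- but not force-shifted at the
  cutoff; conservation tests are unaffected, but long microcanonical runs
  would see a small drift at cutoff crossings.
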