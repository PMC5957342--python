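# Methods

`densassign` implements, at desk scale, the three simulation-based lines of
evidence used to decide whether an ambiguous, disconnected electron density in
a protein structure is better modelled as a water molecule or as an ion:
relative binding free energies from alchemical thermodynamic integration,
absolute binding free energies from staged decoupling cycles with an analytic
standard-state restraint correction, and comparative residence-time statistics
from free simulations.  The atomistic system is replaced by a synthetic
single-particle binding-site model whose every ingredient has a closed-form
equilibrium answer, so the entire pipeline can be validated against exact
oracles rather than against other simulation codes.

## The toy model

One tagged particle (a `Species`: charge, LJ ε/σ, mass) moves in a rigid
environment (a `SiteModel`): a handful of fixed interaction centers with
partial charges and LJ parameters, an optional isotropic harmonic cage, and a
reflecting cubic box standing in for bulk.  The potential is

    U(x) = Σ_j [ 4 ε_ij (σ_ij¹²/r¹² − σ_ij⁶/r⁶) + f q_i q_j / (ε_r r) ]
           + k_cage |x − x₀|²/2,

with Lorentz–Berthelot combination rules, f = 138.935458 kJ mol⁻¹ nm e⁻², and
a uniform dielectric ε_r screening the charges (the only nod to solvent
electrostatics).  Units are kJ/mol, nm, ps, K and elementary charges
throughout; masses in g/mol make kJ/mol ≡ amu nm² ps⁻², and
k_B = 0.008314462618 kJ mol⁻¹ K⁻¹ (CODATA).

Solvent is implicit.  What explicit water would contribute is emulated by two
devices: the dielectric screening above, and "bulk shell" environments — small
arrangements of partial charges that give an ion a large, tunable desolvation
penalty when it is decoupled from them.  The packaged defaults
(`data/toy_sites.yaml`) realize the regimes the method is meant to
distinguish: a three-donor pocket with favourable LJ contacts for a neutral
water-sized particle and repulsive partial charges for an anion
("f85_like"), a tetrahedral carbonyl-like cage that coordinates a cation
("tm3_like"), and anion/cation hydration shells for the bulk end states.  The
numbers are illustrative model parameters, chosen once so that the pocket
binds water by roughly 15–18 kJ/mol while expelling the anion; they are not
fitted to any force field, and nothing downstream depends on their exact
values.

What the toy deliberately does not model: explicit solvent structure and
hydrogen-bond networks, multi-atom solutes and their orientational entropy,
membranes, long-range electrostatics (no periodicity, no Ewald), finite-size
and background-charge effects, and protein flexibility.  Passing tests
therefore demonstrate the correctness of the estimators and bookkeeping, not
the fidelity of any particular force field to a real channel.

## Dynamics

Trajectories are generated by underdamped Langevin dynamics with the BAOAB
splitting, chosen for its small configurational sampling bias at moderate
time steps.  Reflecting walls preserve the equilibrium distribution in the
finite box.  Defaults: T = 300 K, dt = 0.002 ps, friction γ = 1 ps⁻¹.  The
friction is the package's own choice for an implicit-solvent model: every
equilibrium observable tested is independent of γ, and γ = 1 ps⁻¹ gives a
free-particle diffusion constant of kBT/(mγ) ≈ 0.14 nm²/ps, which keeps
box-scale relaxation times in the low-picosecond range.  The cycle-closure
test tightens dt to 0.001 ps because the O(dt²) configurational bias of the
integrator, while irrelevant to any single leg, differs slightly between the
two alchemical routes it compares.  Each simulation is reproducible
bit-for-bit from its seed; a global seed is fanned out to stages through a
name-keyed hash, so adding a stage never perturbs the others' random streams.

## Alchemical Hamiltonians

The λ-coupling follows the standard soft-core construction: distances in the
vanishing interaction terms are replaced by

    d(r, w) = (α σ_sc⁶ w^p + r⁶)^(1/6),

with w the "off-ness" of the state (w = λ for the disappearing state A,
1 − λ for the appearing state B) and defaults α = 0.5, σ_sc = 0.3 nm, p = 1 —
one shared parameter set for LJ and Coulomb.  Both the relative
transformation V = (1−λ)V_A(d_A) + λV_B(d_B) and the staged decoupling legs
(restraint on → charges off → LJ off) are supported; in the charge-removal
leg the LJ term stays at full, unsoftened strength, since the repulsive core
is still present to keep the particle off the centers (that leg is
consequently not singularity-free at r = 0, by construction).  ∂V/∂λ is
analytic in every mode and is cross-checked against central finite
differences in the tests.  A `HarmonicSwitchHamiltonian` (linear
interpolation between two harmonic wells, with offsets) provides the exact
Gaussian oracle used throughout: switching K₀ → K₁ in 3-D costs
(3/2)k_BT ln(K₁/K₀).

## Thermodynamic integration

ΔG = ∫₀¹ ⟨∂H/∂λ⟩ dλ over a uniform λ grid (41 points by convention for
LJ/relative legs, 11 for Coulomb/restraint legs; both endpoints always
included).  Each window discards a configurable burn-in (50 ps against the
paper-scale series lengths; scaled down proportionally for the toy's shorter
windows) and carries a standard error from block averaging with 10 blocks,
which absorbs autocorrelation on scales shorter than a block — block lengths
must comfortably exceed the slowest relaxation time (box diffusion, a few ps
here) for the errors to be honest, which sizes the windows used in the
statistical tests.  Quadrature is the trapezoidal rule: minimal assumptions,
exact for profiles linear in λ, O(n⁻²) otherwise; duplicate λ values are
rejected rather than averaged, and a schedule not spanning [0, 1] is
integrated but flagged (never extrapolated).  Windows are treated as
independent simulations, so the integrated error is the quadrature-weighted
root-sum-square of window SEMs.  External two-column (time, ∂H/∂λ) tables
with `#`/`@` comments can be ingested directly.

## Thermodynamic cycles

Relative: ΔΔG_bind = ΔG_site − ΔG_bulk for the same A→B transformation run
in the site and in bulk; negative values favour water.  The occupancy
interpretation P_wat/P_ion = (c_wat/c_ion)·exp(−ΔΔG/k_BT) is provided as a
helper (the concentration bias cancels at ΔΔG = +k_BT ln(c_wat/c_ion)).

Absolute: ΔG_bind = ΔG₂ − ΔG₁ with ΔG₁ the site path (simulated restrain,
charge-off and LJ-off legs, plus the identically-zero translation of the
decoupled particle) and ΔG₂ the bulk path (bulk decoupling legs plus the
analytic restraint term).  Restraining a non-interacting particle with
U = K_x|x−x₀|²/2 confines it to V_eff = (2π k_B T/K_x)^{3/2}; confining an
ideal particle from the standard volume V° into V_eff costs
k_BT ln(V°/V_eff) — +0.774 kJ/mol at K_x = 200 kJ mol⁻¹ nm⁻², 300 K and
V° = 0.02992 nm³ (the molecular volume of pure water, the default standard
state; overridable).  The module applies this term *signed* on the bulk
path: that placement is the one under which the assembly reduces, for a
purely harmonic site of stiffness K_cage and depth E₀, to the closed form
ΔG_bind = −E₀ + k_BT ln(V°/V_eff(K_cage)) independent of the restraint
stiffness K_x — the self-consistency the tests enforce for
K_x ∈ {100, 200, 400}.  (The sign matters: the magnitude alone misassembles
whenever V_eff(K_x) > V°.)  The public `restraint_free_energy` returns the
magnitude, which is how the correction is conventionally quoted.

A numerical check of the restraint term against TI must respect one bit of
physics: switching the restraint on *inside* a box of volume V° truncates
the restrained Gaussian (σ ≈ 0.112 nm against a half-width of 0.155 nm) and
shifts the result by over 1 kJ/mol.  The test therefore runs the switch in a
larger box (half-width 0.4 nm, truncation ~2·10⁻³ kJ/mol) and converts with
the analytic k_BT ln(V°/V_box) — the standard volume enters analytically, as
it does in production workflows.

## Censored lifetimes

Residence times are modelled as exponential.  With M molecules observed for
spans T_s,i and m escape events at times t_i, the maximum-likelihood estimate
is total time at risk over events,

    τ_ml = [ Σ_censored T_s,i + Σ_events t_i ] / m,

verified in the tests against direct numerical maximization of the censored
log-likelihood.  With m = 0 the likelihood is monotone and only a lower
bound exists; the estimator returns the total observation time flagged as a
bound (20 × 80 ns with no escape ⇒ τ ≳ 1600 ns), and downstream logic treats
bounds conservatively.  An optional parametric bootstrap (resampling
exponential escape experiments under the same censoring layout) yields
percentile confidence intervals; the interval is widened if needed to
contain the point estimate, so degenerate small-n_boot cases stay sane.
Escape events are extracted from trajectories by a radial criterion with a
persistence window: the first frame at which |x − x_site| exceeds the escape
radius continuously for ≥ 5 ps (default).  An explicit, testable rule is
used deliberately instead of visual trace inspection; brief boundary
rattling does not count, and a terminal excursion shorter than the
persistence window is censored.

## Disorder

RMSF = √⟨|x − x̄|²⟩ about the retained-frame mean position (not the initial
frame), after an equilibration cut.  In a harmonic cage this equals
√(3k_BT/K) — the 2%-level acceptance check — and in the assignment logic it
serves qualitatively: softer confinement ⇒ larger RMSF ⇒ a bound molecule
too dispersed to produce a resolvable density.

## Assignment logic

Three criteria, combined conjunctively (never averaged):

1. **Relative** — water_favored if ΔΔG < −20 kJ/mol (default threshold) and
   |ΔΔG| > 2σ; symmetric for the ion; otherwise inconclusive.  The 20 kJ/mol
   default sits conservatively between the ~40 kJ/mol scale of known
   force-field bias in ion–aromatic interactions and the hundreds of kJ/mol
   where conclusions are unambiguous; it is configuration, not a claim.
2. **Absolute** — a water assignment is plausible only if ΔG_bind(water) ≤
   +5 kJ/mol ("negative or near zero"); implausibility vetoes a water call
   but does not by itself identify the ion.
3. **Stability** — a species is favoured when its lifetime (or lower bound)
   exceeds the other's *point estimate* by ≥ 10×; a lower bound supports only
   the species it bounds, so two censored lifetimes are always inconclusive.

A verdict is issued only when at least one criterion speaks and none
opposes; any disagreement, or all-inconclusive evidence, is surfaced as
`inconclusive`.  The logic is antisymmetric under relabelling the two
species and monotone in ΔΔG (property-tested).

## Problem sizes and numerical choices

The statistical tests run at sizes chosen so that their Monte-Carlo errors
are honest and small relative to the asserted tolerances: TI oracles use
11–21 windows of 50 000 steps; the cycle-closure comparison uses 31–41
windows of 500 000 steps at dt = 0.001 ps (the restraint-on legs get the
densest grid because their integrand is the most curved); stability runs use
20 replicas of 200 ps; the RMSF check uses a single 4 ns run.  Degenerate
inputs are rejected loudly (empty windows after burn-in, duplicate λ,
schedules not reaching the endpoints, zero axes, singular configurations of
non-soft-core potentials), and a particle entering a singular core during
integration aborts with the offending step.  The Boltzmann-sampling check
folds the double-well histogram onto |x| to remove the one slow antisymmetric
relaxation mode, and subsamples to near-independent frames so the χ²
statistic is calibrated.

## Known limitations

Single-particle, single-topology alchemy only (no multi-atom mappings); no
MBAR/BAR estimators (TI only); exponential residence model only (no
Weibull); uniform λ grids only; no finite-size or background-charge
corrections.  The toy's absolute numbers (well depths, lifetimes, ΔΔG
magnitudes) are properties of the illustrative parameter set, not
predictions for any real system.
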