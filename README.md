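# densassign

Free-energy and stability evidence for assigning ambiguous water/ion
crystallographic densities — exercised on a synthetic binding-site model with
exact ground truths.

## The problem

Disconnected electron densities near proteins (a blob that could be a water,
a halide, or a cation) are among the most error-prone assignments in
structural models: coordination geometry and chemical intuition often cannot
distinguish the candidates. Molecular simulation offers three quantitative
discriminants:

1. **Relative binding free energy** ΔΔG_bind between the two candidate
   species, from thermodynamic integration (TI) over an alchemical
   transformation, ΔG = ∫₀¹ ⟨∂H/∂λ⟩_λ dλ, with soft-core interactions
   d(r) = (α σ⁶ λᵖ + r⁶)^{1/6} keeping the integrand finite as a particle
   vanishes. Negative ΔΔG_bind (our convention) favours water.
2. **Absolute binding free energy** ΔG_bind of water, from a staged
   decoupling cycle (restrain → charges off → LJ off, at the site and in
   bulk) closed by the analytic standard-state restraint correction
   k_BT ln(V°/V_eff), V_eff = (2π k_BT/K_x)^{3/2}. A water assignment is
   plausible only if ΔG_bind ≲ 0.
3. **Residence lifetimes** from free simulations, estimated by the
   censored-exponential MLE τ_ml = m⁻¹[(M−m)T_s + Σᵢ tᵢ]; molecules that
   never escape contribute observation time only, and with zero events only
   a lower bound is reported.

`densassign` implements all three plus the conjunctive decision logic that
combines them, and ships a single-particle toy binding-site model (LJ +
screened Coulomb centers, BAOAB Langevin dynamics, reflecting box) in which
every estimator can be validated against closed-form Gaussian and
exponential oracles. It is a library for studying and teaching the
*method*; it does not read structure factors or density maps.

## Worked example

`examples/assignment_pipeline.py` runs the full workflow on the packaged toy
pocket (favourable water contacts, anion-repelling partial charges, and a
bulk "hydration shell" giving the anion a large desolvation penalty):

```
$ python examples/assignment_pipeline.py
ddG_bind (water vs anion) = -58.7 +- 0.9 kJ/mol  (negative favours water)
dG_bind (water)           = 0.9 +- 1.4 kJ/mol  (restraint term 0.774)
criterion absolute_water : plausible
criterion relative       : water_favored
criterion stability      : water_favored
verdict: water_favored  (all decisive criteria favour water and none opposes)
artifacts in pipeline_out/
```

Reading the numbers: the alchemical ion→water transformation is 58.7 kJ/mol
more favourable at the site than in bulk — dominated by the toy anion's
desolvation penalty, so water wins the site by a wide margin; the absolute
decoupling cycle puts water's binding free energy near zero (plausible
occupancy); and in free simulations the water outlives the anion by more
than the required order of magnitude. All three criteria agree, so the
verdict is `water_favored`. Per-leg TI tables, escape-event CSVs and JSON
results land in `pipeline_out/`.

The other examples are single-capability narratives:
`restraint_correction.py` (the analytic 0.774 kJ/mol standard-state term),
`harmonic_ti.py` (TI against the exact (3/2)k_BT ln(K₁/K₀) oracle),
`lifetimes.py` (censored MLE and its bootstrap interval, including the
20 × 80 ns → τ ≥ 1600 ns bound), `free_simulation_stability.py` (escape
detection, lifetime ratio, RMSF) and `dhdl_tables.py` (ingesting
engine-style ∂H/∂λ text dumps).

```
$ python examples/lifetimes.py
no escapes in 20 x 80 ns:  tau >= 1600 ns (lower bound: True)
synthetic tau=50 ns, M=2000, T_s=40 ns:
  events observed: 1099 (901 censored)
  tau_ml = 50.16 ns, 95% CI [47.32, 53.16] ns
```

See `docs/methods.md` for the model, its assumptions, parameter defaults and
known limitations.

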