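# semiflex

Replica-exchange Monte Carlo and generalized microcanonical
inflection-point analysis for coarse-grained flexible and semiflexible
bead-spring polymers.

`semiflex` is for people studying conformational phase behaviour of
single polymer chains — collapse from random coils to liquid globules,
and freezing from globules into solid (for flexible chains, icosahedral)
structures — and how a bending stiffness changes the character and order
of those transitions. Because a 55-mer is nowhere near the thermodynamic
limit, the analysis works microcanonically, in energy space, where
transitions of finite systems have unambiguous signatures.

## Model and method

A chain of N monomers carries the energy

    E(X) = Σ_{i>j+1} V_NB(r_ij) + Σ_i V_B(r_i,i+1) + Σ_l κ [1 − cos θ_l]

with a truncated-and-shifted 12-6 Lennard-Jones potential between
non-bonded pairs (σ = 2^(−1/6) r0, cutoff 2.5 σ), a FENE + LJ bond
potential (range R = (3/7) r0, strength K = (98/5) r0², finite only for
|r − r0| < R), and a bending penalty on the angle between successive
bonds. Everything is in reduced units (ε_LJ = r0 = kB = 1); κ = 0 is
the flexible chain.

The pipeline is:

1. **Sampling** — parallel tempering across a temperature ladder
   (default 40 geometric temperatures in [0.1, 5.0]) with
   single-monomer displacement moves (step sizes auto-calibrated to
   ~50% acceptance) and rigid pivot rotations, exchanges every 1500
   sweeps; plus simulated annealing for ground-state search.
2. **Density of states** — multiple-histogram reweighting of the
   per-temperature energy histograms, iterated in log space to a fixed
   point g(E); errors from independent runs.
3. **Microcanonical analysis** — entropy S(E) = ln g(E) smoothed by a
   global Bernstein-form Bézier curve with analytic derivatives
   β = dS/dE, γ = dβ/dE, δ = dγ/dE; phase transitions are
   least-sensitive inflection points: a positive-valued minimum of β is
   a first-order transition, a negative-valued peak of γ a second-order
   one, and so on up to third order, with dependent transitions admitted
   as higher-energy companions.
4. **Observables** — canonical ⟨E⟩(T) and C_V(T) from the density of
   states, d⟨R²_gyr⟩/dT from time series, and structural analysis of
   low-energy conformations (pair distributions, contact maps,
   hairpin/helix streak statistics).

## Worked example

Three short independent runs of a flexible 13-mer, combined into one
density of states and classified:

```python
import numpy as np
import semiflex as sf

params = sf.ModelParameters(n_monomers=13, kappa=0.0)
ladder = sf.TemperatureLadder.geometric(0.3, 3.0, 8)
schedule = sf.SweepSchedule(total_sweeps=60_000, thermalization_sweeps=20_000,
                            exchange_period_sweeps=500, timeseries_stride=2)

runs = [sf.run_parallel_tempering(params, ladder, schedule, seed=s)
        for s in (5, 6, 7)]
e_min = min(r.best_energy for r in runs)
print("lowest energy found:", round(e_min, 3))

estimates = [sf.wham_solve(r.histograms, min_count=5)[0] for r in runs]
dos = sf.combine_runs(estimates)
entropy = sf.entropy_from_dos(dos, e_min=e_min)
curves = sf.derivative_curves(entropy, n_grid=1000)
records = sf.find_transitions(curves, entropy, beta_range=(1/3.0, 1/0.3))
print(sf.transition_table(records, kappa=0.0, e_min=e_min)
        .to_string(index=False, float_format=lambda v: f"{v:.3f}"))
```

prints (about a minute on one core):

```
lowest energy found: -41.404
 kappa    E_tr  Delta_E  beta_tr  order  dependence  significance
 0.000 -33.696    7.709    2.891      2 independent        11.668
 0.000 -14.779   26.626    0.962      2 independent       146.882
```

Read: the 13-mer's lowest energy found is −41.40 (the icosahedral
cluster with a threaded chain); the entropy derivative γ has two
significant negative peaks, i.e. two second-order transitions — the
coil–globule collapse at inverse temperature β ≈ 0.96 and the
globule–solid transition at β ≈ 2.89, the latter 7.7 energy units above
the ground state. At this tiny size the freezing is still second order;
for the 55-mer it sharpens into the first-order backbending signature.

The same pipeline is scriptable from a shell:

```
semiflex simulate --preset smoke --seed 5 --out run.h5
semiflex wham --run run.h5 --out dos.txt
semiflex analyze --dos dos.txt --e-min -41.4 --out-prefix analysis
semiflex structures --run run.h5 --out-prefix ground
semiflex anneal --n-monomers 55 --kappa 2 --out best55.xyz
```

The `production` preset (`--preset production`, N = 55, 40 temperatures,
κ ∈ {0, 1, 2}) runs the full study setup; it needs hours to days per
stiffness on one core.

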