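# Methods

## Model

A chain of N identical monomers with three energy terms, all in reduced
units (Lennard-Jones energy scale, reference bond length r0 and the
Boltzmann constant all equal to 1):

* **Non-bonded pairs** (all pairs `i > j + 1`): the 12-6 Lennard-Jones
  potential with sigma = 2^(-1/6) r0 (so the minimum of depth 1 sits at
  r0), truncated at r_c = 2.5 sigma and shifted by V_LJ(r_c) ≈ -0.01632
  so the potential is continuous at the cutoff.
* **Bonds**: a FENE spring combined with the same shifted LJ term,
  V_B(r) = -(1/2) K R² ln[1 - ((r - r0)/R)²] + V_LJ(r) - V_shift with
  R = (3/7) r0 and K = (98/5) r0². Bonds are confined to the open
  interval (r0 - R, r0 + R); the minimum of V_B is at r0. A bond outside
  the range carries an infinite-energy sentinel (not an exception), so
  the Metropolis step can reject such proposals uniformly.
* **Bending**: kappa [1 - cos(theta - theta0)] on each of the N - 2
  angles between successive bond vectors, theta0 = 0 (a straight chain
  pays nothing). The angle convention is the arccosine of the normalized
  dot product of consecutive bond vectors, clamped to [-1, 1]; any other
  convention would penalize straight chains. kappa = 0 is the fully
  flexible chain; kappa = 1 puts bending on par with the pair
  attraction; kappa = 2 makes bending dominant.

Energies are evaluated by a naive O(N²) double loop (numba-compiled);
at N = 55 neighbour lists would not pay for themselves. Incremental
evaluation recomputes only the terms a move touches: for a displacement
of monomer i the non-bonded column of i, its one or two bonds and up to
three angles; for a pivot at i the bend at i and the non-bonded pairs
straddling the pivot (a rigid tail rotation preserves every bond length
and every other angle). Property tests pin the incremental path to the
full-recomputation oracle at 1e-9.

## Sampling

Replica-exchange (parallel tempering) Metropolis Monte Carlo:

* One thread per temperature; the default production ladder is 40
  geometrically spaced temperatures in [0.1, 5.0]. Geometric spacing
  keeps neighbour temperature ratios constant, which roughly evens out
  exchange acceptance across a heat capacity that varies over decades.
* **Displacement sweep** = N attempted single-monomer moves, each a
  uniform shift in a cube of edge r_d centred on the monomer. r_d is
  calibrated per thread to a 45–55% acceptance rate by multiplicative
  (×/÷ 1.1) adjustment rounds of 200 trial sweeps, *after*
  thermalization, and the calibration only terminates when every thread
  measures in-window in the same round.
* **Pivot sweep** = N - 2 attempted pivots (uniform interior monomer,
  uniform random axis through it, angle uniform in [0, 2π), tail rotated
  rigidly). One pivot sweep runs after every d displacement sweeps,
  where d is interpolated linearly per thread from 70 at the coldest
  temperature down to 20 at the hottest: compact low-T states need many
  local moves between the (rarely accepted but cheap) global pivots,
  while high-T coils re-equilibrate instantly under pivots.
* **Exchanges** between neighbouring threads every 1500 sweeps
  (configurable), alternating even/odd neighbour pairs on successive
  exchange epochs, with the standard two-temperature acceptance rule. A
  swap exchanges conformations, cached energies and replica identity
  labels; the RNG stream and step size stay with the thread.
* Every thread starts from a straight chain at bond length r0 (always
  FENE-valid). Measurements (energy histogram; optionally an
  (E, R_gyr²) time series at a configurable stride) are taken once per
  displacement sweep during the measurement phase only. Histogram bins
  are 0.5 energy units wide by default on [-6N, +6N]; out-of-grid
  samples are counted and warned about.
* **RNG**: one numpy PCG64 stream per thread plus one for the exchange
  scheduler, all spawned from a single master seed via SeedSequence.
  All random numbers are drawn in the Python layer and passed to the
  numba kernels in per-segment batches, so runs are bit-reproducible.
  The cached running energy is re-synced against a full evaluation at
  the end of every segment.
* **Simulated annealing** reuses the same kernels under geometric
  cooling, with the step size steered toward 50% acceptance between
  stages; restarts use spawned sub-streams and the best-ever
  conformation is tracked across them, so the best energy is
  non-increasing in the number of restarts. Its role is ground-state
  search and verification/refinement of the parallel-tempering minimum.

## Density of states (multiple-histogram reweighting)

Per-temperature energy histograms are combined by iterating the usual
two reweighting equations to a fixed point, entirely in log space with
log-sum-exp (no bare exponentials of ±E/T appear anywhere). The gauge is
fixed by pinning ln Z of the first thread to zero; convergence is
max_k |Δ ln Z_k| < 1e-8 (configurable, default max_iter 1e5). ln g is
defined up to one additive constant; every downstream observable is
invariant under that constant (property-tested).

Support handling: bins with nonzero total counts form the support;
`min_count` optionally trims bins whose estimates are shot-noise
(support fringes), and `histogram_support_window` reports the energy
window actually constrained by the data — from a low quantile of the
coldest thread's histogram to a high quantile of the hottest thread's.
Outside that window ln g is extrapolation and transition records there
are suppressed by passing the simulated inverse-temperature range to the
detector (`beta_range`).

Statistical errors are estimated exclusively from independent runs:
`combine_runs` aligns replicate ln g tables by a least-squares additive
constant on shared support and reports the per-bin mean and standard
error of the mean. No within-run error propagation is attempted.

## Microcanonical inflection-point analysis

S(E) = ln g(E) on the support. The curve is smoothed by a **single
global Bézier curve in Bernstein form with every data point a control
point** (degree = number of points - 1), evaluated by the de Casteljau
recursion, which is numerically stable at degree ~10³. The first three
derivatives with respect to the curve parameter come from finite
differences of the de Casteljau intermediate points (exact, not
numerical differentiation); derivatives with respect to energy follow by
the chain rule through the parameter-to-energy map, which is itself a
Bézier curve of the energy control points (for a uniform grid this map
is exactly affine). A `decimate` option keeps every m-th point as a
control point, which stiffens the smoother on noisy data.

Transitions are least-sensitive inflection points, operationalized as
interior extrema of prescribed sign in the next-higher derivative:
order 1 independent = positive-valued local minimum of beta; order 2
independent / dependent = negative-valued local maximum / positive-valued
local minimum of gamma; order 3 independent / dependent = positive-valued
local minimum / negative-valued local maximum of delta. Dependent
records are admitted only as higher-energy companions of an independent
record of the next-lower order. Implementation details that matter:

* a margin (default 2% of the grid) is excluded at each end of the
  support to avoid Bézier endpoint artifacts;
* extrema must clear a prominence floor, max(1e-4 × window range,
  50 × median |second difference|); the second-difference term separates
  genuinely flat curves (whose float-rounding wiggle would otherwise
  produce hundreds of fake extrema — the Bernstein curve of a parabola
  has constant curvature to 1e-12) from real structure;
* each record carries beta_tr = beta(E_tr), the reduced energy
  Delta E = E_tr - E_min(kappa) (E_min from the sampler's best
  conformation), the extremal value as signal strength, and a
  significance = |signal| / propagated replicate error; records below
  significance 2 are flagged noisy but still listed;
* replicate errors for all four curves come from redoing the smoothing
  and differentiation per independent run and taking the cross-run
  spread of the mean.

The synthetic test constructions are chosen so each rule has an
independent oracle: a log-concave S (no transitions at all); a
two-Gaussian density of states tuned so beta stays positive through a
clear convex intruder, whose first-order record must sit within 5% of
the Maxwell double-tangent slope computed by an independent concave-hull
construction; and a decreasing beta with a flat inflection
(beta = b - a(E-E*) - c(E-E*)³), whose gamma peaks negatively at E*,
giving exactly one independent second-order record.

## Canonical observables

Mean energy and heat capacity are reweighted from the density of states
at any heat-bath temperature (log-sum-exp; C_V via the fluctuation
identity, cross-checked against finite differences of ⟨E⟩). The
temperature derivative of the squared radius of gyration cannot come
from the energy-only density of states, so it is estimated per thread
from the paired (R_gyr², E) time series via
d⟨O⟩/dT = (⟨OE⟩ - ⟨O⟩⟨E⟩)/kB T². Canonical peak locations are reported
for comparison only; the microcanonical analysis is the transition
criterion.

## Structure analysis

Squared radius of gyration (uniform masses); pair distribution P(r)
over all unordered pairs, binned into disjoint cells of width 2 r_t
(r_t = 0.01) centred on r_t(2m+1) so counts sum to N(N-1)/2 exactly (a
distance exactly on a cell edge goes to the upper cell); contact maps of
non-bonded pairs (j > i + 1) with r < 1.2, strict inequality, 1-based
indices; and maximal anti-diagonal (i+j constant, hairpin-like) and
diagonal (j-i constant, helix-like) runs of contacts with length ≥ 2
reported as streaks. Conformations export to XYZ and minimal PDB.

## Problem sizes used by the test suite and acceptance script

The published study (N = 55, 40–50 threads, up to ten independent runs,
~10⁶ sweeps each) is a multi-day single-CPU computation. The packaged
test suite and the acceptance script run the identical pipeline at
reduced budgets chosen to finish in minutes:

* smoke preset: N = 13, 8 threads in [0.3, 3.0], 20k + 60k sweeps,
  3 replicates;
* reduced N = 55 study: 20 threads in [0.12, 5.0], 6k + 15k sweeps
  (12k in the acceptance script), 2 replicates per stiffness, with the
  putative ground state refined by simulated annealing from the
  parallel-tempering minimum.

What this scale does and does not support: the collapse (Theta)
transition lives at high temperature where autocorrelation times are
short, so its second-order signature and location are resolved (with a
statistical wobble of a few hundredths in beta_tr). The freezing
transition and the true ground states are not: equilibrating the solid
phase of the 55-mer and reaching the icosahedral global minimum require
orders of magnitude more sweeps than a desk-scale run, so at this budget
the backbending region of beta(E) is not resolved and the best energies
found sit several percent above the global minima. The full-scale runs
are available through the `production` preset of the command line
(`semiflex simulate --preset production ...`).

## Known limitations

* Plain displacement + pivot dynamics freeze into glassy low-energy
  states; there is no crankshaft/cluster move or multicanonical option,
  so ground-state search at N ≳ 50 needs long schedules and restarts.
* The global Bernstein smoother couples the whole support: badly
  sampled fringes perturb the curve everywhere, which is why the
  support-window and min-count trims exist. Its smoothing bias scales
  like 1/(number of control points), so very coarse histograms bias
  derivative magnitudes (not usually peak locations).
* WHAM errors come from replicates only; with fewer than two runs all
  error fields are absent (None), never silently zero.
* Dependent transitions (the admissibility-gated positive-minimum /
  negative-maximum rules) are implemented but none are expected in this
  system; orders above 3 are supported generically but untested.
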