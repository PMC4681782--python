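# Model and methods

`recallnet` simulates free recall as stochastic attractor dynamics in a
sparse Hopfield network whose feedback inhibition is periodically modulated.
This note documents the model equations as implemented, the conventions the
package fixes where the formulation is open, the numerical choices, and the
known limitations.

## The network

Each of `P` list items is stored as a random binary ensemble over `N`
rate neurons: membership bits `eta_i^mu ~ Bernoulli(f)` i.i.d. (defaults
`N = 1e5`, `P = 16`, `f = 0.1`). Currents follow

    tau dc_i/dt = -c_i + sum_j J_ij g(c_j) + xi_i(t),      r_i = g(c_i),

with the threshold power-law gain `g(x) = (x + theta)^gamma` for
`x + theta > 0`, else 0 (defaults `gamma = 2/5`, `theta = 0`; the
mean-field analysis uses `gamma = 1/2`, which is solvable in closed form).
The weights combine a covariance ("Hebbian") term with uniform inhibition,

    J_ij = (kappa/N) * (sum_mu (eta_i^mu - f)(eta_j^mu - f) - phi),

plus optional temporal-contiguity terms that couple each item to its list
neighbours,

    dJ_ij = (J+/N) sum_mu eta_i^mu eta_j^(mu+1)
          + (J-/N) sum_mu eta_i^mu eta_j^(mu-1).

Conventions fixed here:

* **Inhibition is subtracted once per weight** (outside the `mu` sum).
  Placing it inside the sum would multiply the inhibitory drive by `P` and
  move the existence boundary to `phi ~ (1-f)^2 Q / P`; only the
  once-subtracted form yields the boundary `phi < (1-f)^2 Q` that the
  inhibition oscillation (between 0.7 and 1.06) is built around.
* **Contiguity carries the same `1/N` as the Hebbian term.**  This makes
  the neuron-level system exactly equivalent to the population-reduced one
  (verified to 1e-10 in the tests) and puts the reference couplings
  `J+ = 1500-2500` on the same intensive scale as the recurrent drive.
* **Direction.**  As written, the `J+` term lets the active item drive the
  populations of the *preceding* list item, so strong-contiguity chains
  traverse the list backwards from the starting item.  Every statistic the
  package reports (distinct-item counts, rank distributions, IRTs) is
  invariant under reversing the chain direction, so the convention is
  recorded rather than "fixed".

## Population reduction

Neurons sharing the membership vector `eta_i = v` receive identical input
and are lumped into one population with empirical weight `S_v = count/N`
(`PopulationPartition`).  The reduced dynamics are

    tau dc_v/dt = -c_v + sum_w Jt_vw S_w g(c_w) + xi_v(t),
    Jt_vw = kappa (sum_mu (v^mu - f)(w^mu - f) - phi)
            + J+ sum_mu v^mu w^(mu+1) + J- sum_mu v^mu w^(mu-1).

At `N = 1e5`, `P = 16`, `f = 0.1` the partition holds roughly 3,900
occupied populations (about 1,800 at `N = 2e4`) — the simulator therefore
integrates thousands of equations instead of `N`.  The simulator never
materialises `Jt`: the drive is evaluated through the overlaps
`m^mu = sum_w (w^mu - f) S_w g(c_w)` and `m0 = sum_w S_w g(c_w)` at
`O(n_pop * P)` per step, which is algebraically identical (the explicit
matrix from `reduced_coupling` is used in the equivalence tests).

For population-constant initial conditions and zero noise the reduction is
*exact*, and the tests hold the two simulators to a 1e-6 sup-norm over the
trajectory of population-mean currents.

## Mean-field fixed points

In the `N -> infinity` limit the fixed points solve

    m^mu = sum_v (v^mu - f) S_v g(c_v),   m0 = sum_v S_v g(c_v),
    c_v  = kappa (sum_nu (v^nu - f) m^nu - phi m0),

with analytic weights `S_v = f^|v| (1-f)^(P-|v|)`; the package evaluates
the map by exact enumeration of all `2^P` membership vectors (Monte-Carlo
weighting for `P > 20`).  Under the symmetric `Q`-intersection ansatz —
`Q` memories share the overlap `m_active`, only populations inside all `Q`
fire — the system collapses to one scalar equation.  For `gamma = 1/2`:

    m0 = ( A f^(2Q) + sqrt(A^2 f^(4Q) + 4 theta f^(2Q)) ) / 2,
    A  = kappa ((1-f)^2 Q - phi),         m_active = (1-f) m0.

This form is derived directly from the scalar self-consistency equation
`m0 = f^Q sqrt(kappa m0 ((1-f)^2 Q - phi) + theta)` and zeroes the
enumerated fixed-point map to ~1e-12 (verified in the tests).
At `theta = 0` the solution exists iff `phi < (1-f)^2 Q`
(0.81 for single memories, 1.62 for pairs at `f = 0.1`), and the ansatz'
current-sign conditions additionally require `phi > (1-f)(1-2f) = 0.72`
for pairs.  The reference oscillation `phi in [0.7, 1.06]` therefore
toggles the network between a phase with single-memory attractors and a
phase with only pair intersections — the engine of retrieval.  For general
`gamma` the same scalar equation is solved with a bracketed root search
(`scipy.optimize.brentq`, tolerance 1e-14); a bracketed scalar root is
more robust than damped fixed-point iteration and needs no damping
schedule.  Stability is probed by simulation (the quiescent state,
persistence below the boundary, collapse above it); no analytic spectra
are computed.

## Noise

`xi_v` is Gaussian white noise integrated by Euler-Maruyama: per step the
current receives `sd_v * sqrt(dt)/tau * z`, `z ~ N(0,1)`.  `xi0` (default
65) is the noise scale (SD).  How `sd_v` should depend on the population a
unit represents is a genuine modelling choice — the reduction lumps many
neurons into one equation, and the lumped noise can be read either as one
process per unit or as the average of the members' noises — so `NoiseSpec`
exposes the rule as a hook with two implementations:

* `uniform_scaling` (default): `sd_v = xi0` for every population — the
  reduced equation read literally, each population unit carrying one noise
  process.  Under this convention the reference value `xi0 = 65` sits at
  the *interior optimum* of recall performance (the desk-scale sweep gives
  ~1.7 items at `xi0 = 0`, ~8.7 at 65, ~5-6.5 at 120-200), strong
  contiguity produces order-following chains, and transitions are rich
  enough to reproduce the accumulation and IRT phenomenology.  This is the
  convention all experiments use.
* `clt_scaling`: `sd_v = xi0 / sqrt(S_v N)` — the exact noise of the
  *average* of the population's neurons, appropriate when moment-matching
  the reduced system against the neuron-level simulator.  As a model of
  the retrieval dynamics it makes the effective noise far too weak at
  reference parameters: pair-state selection becomes winner-take-all and
  chains stall.

## Simulation protocol

Each trial draws a fresh pattern set (a new "word list"), initialises all
populations of one uniformly chosen memory at rate `r_ini = 1` (currents
`g^-1(r_ini)`), and integrates with Euler steps `dt` while
`phi(t) = mean - amplitude * cos(2 pi t / tau_osc)` oscillates between 0.7
and 1.06 with period `tau_osc = 1` (the phase starts at the trough so the
initial memory is inside the single-attractor regime; the phase is
configurable).  A memory is *recalled* whenever the mean rate of its
neurons crosses `r_thresh = 15` upward (crossing times linearly
interpolated; repeated crossings of the same item within one oscillation
cycle are merged; two items above threshold at one sample raise an error,
as the threshold is calibrated to forbid simultaneous recall).

Reference parameters: `N = 1e5`, `P = 16`, `f = 0.1`, `tau = 0.01`,
`kappa = 13000`, `phi in [0.7, 1.06]`, `gamma = 2/5`, `theta = 0`,
`tau_osc = 1`, `T = 450`, `dt = 1e-3`, `J+ = 1500`, `J- = 400`,
`xi0 = 65`, `r_thresh = 15`, `r_ini = 1`, 10,000 trials.

**Desk-scale profile** (used by the test-suite and the acceptance script):
`N = 2e4`, 50 trials, `T = 100` cycles, `dt = 2e-3`; other parameters
unchanged.  These sizes keep a full ensemble in minutes on one core while
leaving every population class well populated.  `dt = tau/5` is the
coarsest step the configuration validator accepts without complaint;
first-order Euler convergence is verified in the tests.

## Recall statistics

From each trajectory the package derives a `RecallLog` (ordered recall
events) and from ensembles of logs:

* accumulation curves (mean distinct items by time; first retrievals only);
* inter-retrieval times between successive *new* items, pooled and
  conditioned on the trial's final recall total;
* recall probability vs representation size (equal-count size bins, since
  the binning is otherwise unspecified);
* transition statistics against an item-similarity matrix (by default the
  intersection-size matrix of the trial's patterns): the rank distribution
  (rank 15 = most similar partner; fractional ranks on ties, mass split
  between adjacent integer ranks) and mean transition IRT vs similarity
  (raw similarity values with configurable binning).

Transitions are item changes between consecutive events; repeats of the
current item are not transitions.  The analysis layer accepts external
recall logs and similarity matrices with the same shapes, so behavioural
tables can be analysed identically.

## What the synthetic conditions do and do not show

All inputs are generated internally (random sparse patterns); there is no
external data path.  Passing tests therefore demonstrate the *mechanism* —
oscillation-gated, noise-selected transitions shaped by representation
overlaps — under the stated statistical assumptions (independent uniform
bits, fixed sparsity, uncorrelated items).  Real lexical representations
are certainly correlated and non-uniform; none of the quantitative values
here should be read as predictions for behavioural data beyond the
qualitative signatures (recall slow-down, IRT variability, similarity
effects).

One scale sensitivity deserves emphasis: the *transition-rank* statistic
(how strongly transitions concentrate on the largest-intersection partner)
depends on the balance between the intersection-size spread (relative
spread ~ 1/sqrt(f^2 N)) and the noise, and is therefore not intensive.  At
the full reference scale with contiguity off, the measured distribution
decays monotonically from rank 15 (top mass ~0.5 at `xi0 = 65`); at the
desk scale the same configuration is winner-take-all (~0.85), while with
the reference contiguity couplings transitions are dominated by
list-neighbour chains and the rank distribution flattens (~0.11 at the
top).  The desk-scale transition-stats test documents this honestly rather
than retuning the model per scale.

## Numerical details

* Integration: explicit Euler / Euler-Maruyama; state checked for
  divergence at every recording sample (error names the step and |c|).
* Determinism: every stochastic component is seeded; per-trial seeds
  derive from the master seed via `numpy.random.SeedSequence` and stay
  below 2^31.  Identical configurations reproduce identical outputs
  byte-for-byte.
* The hot loop is JIT-compiled (numba) and split so the state-update loops
  touch no output buffers — this lets LLVM vectorise them (~3x faster than
  a fused kernel at n_pop ~ 1800).
* Degenerate inputs: all-zero memory columns are redrawn (bounded retries);
  empty partitions, non-square or asymmetric similarity matrices, unordered
  event tables, and `dt >= tau` are rejected with specific exceptions.
* The `gamma = 1/2` gain used for the analytics is an unbounded sublinear
  power law, not a saturating function; no saturation is imposed anywhere.

## Known limitations

* No spiking neurons, explicit interneuron classes, or adaptation/
  synaptic-depression transition mechanisms; inhibition is a single scalar
  modulation.
* Memory loading is low (`P << N`); capacity effects are out of scope.
* Analytic linear-stability spectra are not computed.
* Items are uncorrelated by construction; semantically structured codes
  (and their LSA analogues) are only supported through user-supplied
  similarity matrices in the analysis layer.
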