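# Methods

## The model

`mcmgene` models the promoter of a doxycycline (dox)-inducible reporter
gene as a discrete-time Markov chain.  Three experimental systems are
represented:

* **activator-only** — a 2-state telegraph between *unbound* (basal
  activity 1) and *activator-bound* (activity 10);
* **repressor-only** — a 2-state telegraph between *repressor-bound*
  (activity 0) and *unbound*;
* **competing activator + repressor** — a 3-state chain
  (repressor-bound / unbound / activator-bound) in which the two factors
  compete for the same site and can never be bound simultaneously
  ("binding contingency": the two exit probabilities from the unbound
  state satisfy P_A1 + P_R1 ≤ 1, enforced at construction).

Per time cycle the promoter state updates first, then the expression
level X updates by a noisy birth–death rule

    X' = max(0, X + (α·f + BL − γ·δ·X)·Δt)

with transcription rate α = 2.0 per cycle, degradation rate γ = 0.2 per
cycle, Δt = 1, promoter activity f ∈ {0, 1, 10} by state,
degradation-noise factor δ ~ N(1, 0.5²) and basal (leaky) level
BL = γ·10^z with z ~ N(0, 0.5²).  X is clamped at zero because δ is
occasionally negative (≈ 2.3% of draws).  Populations are 10,000
independent cells run for 200 cycles; the final-cycle values form the
steady-state sample.

### Two-jump updates

For the 3-state chain the default per-cycle update lets a bound state
that unbinds complete a *full* unbound-state update within the same
cycle: it may re-bind the same factor, bind the competitor, or stay
unbound.  The unbound state is treated as a transient waypoint rather
than a state dwelt in, which prevents its over-occupancy; direct
repressor↔activator switching within a single jump never occurs.  A
`single_jump` mode (at most one transition per cycle) is available via
`SimulationConfig.update_mode`; the closed-form stationary law of the
single-jump chain is π_A : π_U : π_R = P_A1/P_A2 : 1 : P_R1/P_R2, and
the two-jump stationary law is computed by power iteration of the
explicit composite kernel (`transition_matrix_3state`).

### Initial conditions

Cells start at X = 0 in the chain's **zero-dox resting state**:
repressor-bound for any chain containing the repressor, unbound for the
activator-only chain.  Cells are grown without inducer before the
experiment, so this is the biologically consistent start; it also makes
the [dox] = 0 row of a dose–response table the basal repressed level.
Starting every chain unbound is not an option in this model family: the
high-dox occupancy ratio caps the repressor-binding probability near
0.006 per cycle for rising Hill functions, so a repressor chain started
unbound provably cannot reach its observed near-total repression at low
dox within 200 cycles.

## Estimation

The four 3-state switching probabilities (and the two of each 2-state
chain) are Hill functions of [dox], h(x) = x^H/(K^H + x^H), giving eight
(respectively four) parameters.  They are estimated from the two
observed single-factor dose–response curves, supplied as reference Hill
fits (defaults H_act = 1.6, H_rep = 1.8, K_act = K_rep = 0.6 µg/ml; the
K values are configurable because the source text does not print them).
Each binding/unbinding pair is read as a 2-state telegraph, whose
probability of attaining the bound state from the unbound state is
p_bind/(p_bind + p_unbind); this is matched in least squares over the
positive doses of a 34-point grid (0 plus 33 log-spaced doses in
[0.01, 10] µg/ml) to the observed activator-bound occupancy (the rising
curve itself) and repressor-bound occupancy (the complement of the
rising repressor-only expression curve).  A penalty constant C = 10,000
is added when binding contingency fails at any grid dose; it dominates
every achievable squared-error term (≤ 2 per dose over ≤ 100 doses).

### What the data do not determine, and how the package decides

Two latitudes remain after the fit above, and both matter enormously
for the simulation:

1. **Switching speed.**  The telegraph occupancy depends only on the
   *ratio* of binding to unbinding probabilities, so rescaling a pair
   leaves the fit unchanged while making the chain arbitrarily slow.  A
   near-frozen representative never leaves its initial state in 200
   cycles and the simulate-then-fit pipeline becomes meaningless.
2. **Occupancy amplitude.**  The observed curves are min–max-normalized
   fluorescence, so they constrain the *shape* of an occupancy curve,
   not its absolute level.

`estimate` therefore runs in two seeded stages.  Stage 1 is a bounded
differential-evolution search (log₁₀ K ∈ [−3, 6], H ∈ [0.1, 10] per
Hill function) of the penalized occupancy objective.  Stage 2 selects a
*representative* of the near-optimal family:

* **2-state chains** minimize the mismatch between the observed
  normalized curve and the chain's exact finite-horizon normalized
  expression curve (the 200-step state law from the resting state,
  computed by matrix powers, mapped through the activity values and
  min–max-normalized).  This is the in-package analogue of calibrating
  the single-factor simulations to reproduce the observed Hill
  coefficients, and it automatically favours responsive, well-mixed
  chains.  The reported `objective_value` is the occupancy objective
  profiled over the undetermined amplitude.
* **The 3-state chain** uses a lexicographic rule.  The activator arm is
  chosen first by a deterministic scan of the exact-fit manifold (swept
  by the unbinding Hill function and the amplitude; the binding function
  is induced by a log-scale Hill fit to ratio × unbinding), scored by
  amplitude-profiled occupancy error, a relaxation-feasibility penalty
  and a responsiveness tie-break.  The repressor arm is then fitted the
  same way *within the binding headroom the activator leaves*
  (P_R1 ≤ 0.95 − P_A1 pointwise), which enforces binding contingency by
  construction.  A final Gauss–Newton touch-up sharpens the occupancy
  shapes; it has no gradient along the scale-degenerate direction, so it
  cannot trade away the selected switching speed.

The relaxation-feasibility term demands at least three relaxation times
of an arm's telegraph within the 200-cycle horizon — a chain compared
with steady-state measurements must actually reach its steady state —
but only at doses where the occupancy must move away from the resting
state (a repressed chain at zero dox has nowhere to go and needs no
relaxation).  The responsiveness tie-break (log-scale, weight 2×10⁻⁴)
prefers the least slow among otherwise equivalent representatives; TF
binding is fast on the cell-cycle scale.

All stages are reproducible bit-exactly for a fixed seed: the
evolutionary searches are seeded and the scans and polish steps are
deterministic.

## Dose–response analysis and prediction

`run_dose_response` simulates one population per grid dose and min–max
normalizes the mean expression across the grid (the source data are
presented as % of maximal GFP).  `predict_hill` fits the two-parameter
Hill function to (dose, normalized mean) by bounded least squares
(start: K = geometric mean of positive doses, H = 1; standard errors
from the Gauss–Newton curvature at the optimum).  `run_prediction` runs
estimate → simulate → fit for all three chains and reports the fitted
Hill coefficients next to the customary "calculated" combinations
1.6 + 1.8 = 3.4 and 1.6 × 1.8 = 2.88 and the observed 3.2.

`mode_count` distinguishes all-or-none from graded population responses:
a Gaussian kernel density (Silverman bandwidth) on log₁₀(X + 0.01),
counting local maxima of at least 5% of the global peak.

## Numerical choices

* Population simulation advances all cells in lock-step with batched
  draws from one generator seeded from (config seed, dose bits); results
  are bit-stable for fixed (seed, dose, n_cells).  The scalar
  `simulate_cell` uses a per-cell child seed instead.
* Switching occurs iff the uniform draw r < p (strict), so p = 0 means
  never and p = 1 always.
* Exits from the unbound state use one partitioned uniform draw, valid
  because binding contingency bounds the two probabilities' sum.
* Stationary laws: closed form where available, otherwise power
  iteration of the lazy kernel (M + M²)/2 to 10⁻¹⁴ from all three pure
  starts; disagreement between starts raises a degenerate-chain error.
* BL is redrawn every cycle; the basal level is a per-cycle random
  effect, not a per-cell trait.
* CSV outputs use the fixed column sets in
  `mcmgene.config.OUTPUT_SCHEMAS` and full double precision.

## What the synthetic conditions do and do not show

The generator reproduces the study conditions exactly (10,000 cells,
200 cycles, 34 doses, the α/γ/noise constants above).  It does not model
protein maturation, cell division or extrinsic noise correlations, and
the "observed" curves are idealized Hill fits rather than raw
flow-cytometry histograms — so passing tests demonstrate internal
consistency of the method under the stated model, not agreement with
new experimental data.

## Known limitations

The estimation problem is deeply underdetermined: the normalized
single-factor curves fix only occupancy shapes and binding/unbinding
ratios.  Across defensible representative-selection rules the simulated
combined Hill coefficient spans roughly 1.2–5.7.  The frozen rule
described above preserves the qualitative structure of the system — the
combined response is steeper than either single-factor response
(≈ 2.1–2.2 vs 1.55–1.63 and 1.81–1.83 across seeds), the baseline is
repressed, and slow-switching competing chains are bimodal — but the
exact steepness of the combined curve, and the speed of repressor escape
at mid doses (which controls how fast the ensemble mean settles there),
remain properties of the selected representative rather than of the
data.  The repressor arm is structurally the slow one in this model
family: a rising Hill binding probability capped by the high-dox
occupancy ratio cannot be large at intermediate doses, which is also
why repressor-containing chains, not the activator chain, produce
all-or-none expression patterns.
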