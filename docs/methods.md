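# Methods

## Master equation and solvers

Both channel architectures are continuous-time Markov models. With
occupancies `p` and generator `Q(V)` (entry `(i, j)` the rate from state
*j* into *i*, columns summing to zero), `dp/dt = Q(V) p`. All protocols
are piecewise-constant in voltage, so within a segment the exact solution
is `p(t) = expm(Q t) p(0)`; the production solver propagates segments with
the matrix exponential (models have ≤ 48 states, so this is both exact and
fast). A fixed-step fourth-order Runge–Kutta integrator is retained as an
independent cross-check route; the two agree to ≤ 1e-6 per state on
randomized models in the test suite. The RK4 step defaults to
`min(segment/50, 0.2/max|Q_ii|)`; a user step with `max|Q_ii|·step > 0.5`
raises a stability error carrying an advisory step. Occupancies more
negative than −1e-9 raise; smaller float noise is clipped and
renormalized. Stationary distributions are computed by an equilibrated
least-squares solve of `Q p = 0, Σp = 1`, which tolerates rate constants
spanning ten orders of magnitude better than an SVD null space; reducible
generators are rejected.

Test pulses are read out as the *peak* summed occupancy of the conducting
state(s), sampled by stepping `expm(Q·Δt)` at Δt = 20 µs — an order of
magnitude below the fastest activation transient in the shipped models.
Once the conducting occupancy has fallen to a quarter of the running
peak the scan finishes the segment in one exact jump; for these models
the post-peak transient is monotone, so the peak is unaffected (verified
against a dense oracle scan in the tests). Driving force and unitary
conductance are constants that cancel under normalization, so currents
are reported as relative conducting occupancy.

## Rate law

Every voltage-dependent rate follows the saturating three-parameter form
`k(V) = A / (1 + exp(∓(V − V½)/r))` — limiting rate `A` (1/s), inflection
`V½` (mV), slope `r` (mV). A two-parameter exponential has no maximum and
makes stiff systems blow up at extreme potentials; the saturating form is
bounded by construction. The sign convention ("sense") states whether the
rate saturates on depolarization or hyperpolarization; opening of the
activation gate saturates depolarized, recovery of the inactivation gates
saturates hyperpolarized.

## Drug algebra (modulated receptor with guarded access)

A drug is `(ka, kd, CA, CF, CS, concentration)`. Binding is allowed in
every gating configuration; a bound copy of each state is added to the
graph. For a configuration whose closed-gate set is G:

* association rate = `ka · c · Π_{g∈G} C_g`; dissociation = `kd`
  everywhere. The equilibrium affinity for a configuration with gate g
  closed is therefore `C_g`-fold the resting affinity, and the extra
  affinity is expressed in the association limb (the binding site of an
  inactivated channel is more accessible, not only stickier).
* bound-layer gating: the rate *away* from the conformation the drug
  stabilizes (gate opening, i.e. recovery, for `C_g > 1`) is divided by
  `C_g`; the rate toward it is unchanged.

Microscopic reversibility fixes only the *ratio* of bound-layer rates,
not the split. The delayed-recovery split used here is the one that
matches how inactivated-state stabilization manifests in voltage-clamp
data: a bound fast-inactivated channel recovers `CF`-fold slower, so it
outlasts the 10 ms hyperpolarizing gap even after the drug's nominal
recovery window. The alternative (multiplying the onset rate instead)
satisfies the same equilibria but lets bound channels recover at control
speed, which erases the characteristic dominance of the fast-binding
fast-state-preferring mechanism in the onset protocol; it can be restored
by editing a single factor assignment in `tetracube.extend_with_drug`
(and its MSA counterpart). With either split, the clockwise and
counter-clockwise rate products agree on all 24 square faces of the
tesseract (and on every cycle-basis loop of the 48-state MSA graph) to
better than 1e-8 at all test voltages — asserted in the suite.

`CA` (open-/activated-state preference) is supported by the cube algebra
but fixed at 1 in every shipped drug; open-channel block is out of scope.

## Protocols

All protocols equilibrate at the holding potential (−150 mV unless
stated) *with the drug present* — continuous exposure — by starting from
the exact stationary distribution, so results cannot depend on an
arbitrary equilibration time (a property test doubles the holding
segment and checks readouts move < 1e-4).

* `FInact_V`: pre-pulse −120…−30 mV in 5 mV steps, 0.1 s (2 s variant),
  then test pulse.
* `SInact_V`: 10 s pre-pulse over the same grid, 10 ms gap at −150 mV,
  test pulse.
* `SInact_t`: pre-pulse at −20 mV of swept duration (1 ms–30 s,
  log-even, 8 points/decade), 10 ms/−150 mV gap (5 ms/−120 mV variant),
  test pulse.
* `Rec_t`: 5 s at −20 mV, gap at −150 mV of swept duration (1 ms–10 s),
  test pulse.
* Concentration–response: single test depolarizations from holdings of
  −150, −90, −60 mV.

The test pulse is 0 mV for 10 ms. Its voltage/duration are not critical:
the readout is the activation peak, and normalization cancels the
remaining dependence. The `SInact_t` conditioning voltage (−20 mV) is
chosen to match the `Rec_t` conditioning step so onset and recovery probe
the same state mixture; the `Rec_t` gap voltage (−150 mV) matches the
other gaps so the recovery time constants anchor one voltage. Control
curves normalize to their own maximum; drug curves normalize to the
*control* maximum (so complete block gives nSOD = 1), except when fitting
a drug curve's midpoint, where it is renormalized to its own maximum to
separate shift from block.

## Metrics

* **Boltzmann fit** `y = bottom + (top − bottom)/(1 + exp((V − V½)/k))`,
  free asymptotes; curves with dynamic range < 0.2 are reported
  fit-undefined rather than given a meaningless midpoint.
* **Biexponential recovery** `y = 1 − a₁e^(−t/τ₁) − a₂e^(−t/τ₂)` with
  shared asymptote 1, multi-start least squares (five deterministic
  log-spaced τ seed pairs); degenerate data (vanishing amplitude or
  coincident τs) are flagged single-exponential. Because availability is
  a *product* of two recovering gate populations, the exact curve has a
  small cross term `a₁a₂e^(−t(1/τ₁+1/τ₂))`; the fitted components
  therefore differ by a few percent from the underlying gate rates.
* **nSOD** `Σ(control − drug)/Σcontrol` on a shared log-even grid
  (proportional to the area between the curves on a semilog plot),
  clipped to [0, 1]; facilitation would otherwise produce negative terms.
* **IC50**: bisection on log concentration to 1% relative tolerance;
  failure to bracket 50% inhibition in [1e-3, 1e5] µM raises.
* **Gap-duration effect**: nSOD of the onset protocol as a function of
  gap duration, minus the gap-independent tonic block `c/(c+Kd)` that
  every drug exerts from the holding potential (clipped at 0), so the
  statistic isolates the component a hyperpolarizing gap can wash out.
* **Effectiveness plane**: each drug is a point
  (nSOD onset, nSOD recovery). Family regions are convex hulls — chosen
  for determinism — of the fast- (`CF>1`) and slow-family (`CS>1`) points
  of a reference drug set: the 100-drug kinetics×factor grid at per-drug
  IC50(−90 mV), the factor series at fixed concentrations (14 µM fast /
  81.75 µM slow family), and a ×0.1/×1/×10 concentration series for the
  factor-10 drugs. Query points classify as fast-only / slow-only /
  overlap / outside (shapely point-in-polygon with a 1e-9 buffer for
  boundary robustness).

## Calibration

The 18 cube parameters are constrained by behavioral targets rather than
current traces (all computed through the protocol engine + metrics):
recovery τ_fast = 2.21 ms and τ_slow = 58.25 ms (±20%); ≈45%/55%
fast/slow-inactivated after 5 s at −20 mV (±10 points); ≥95% recovery
from fast inactivation within the 10 ms/−150 mV gap; slow-inactivated
fraction ≈5% (±2 points) after 0.1 s and ≈40% (±20%) after 2 s at the
depolarized end of the availability protocol; availability-midpoint shift
< 4 mV between 0.1 s and 2 s pre-pulses; and the fast-inactivation
equilibrium midpoint more negative than the slow one. Approximate ("≈")
targets carry the generous tolerances above deliberately — exact equality
would over-claim precision the targets don't have.

Each constraint's residual is a hinge: zero inside the tolerance band,
linear in units of the tolerance outside, so the weighted sum of squares
is zero iff every constraint passes. `calibrate()` returns a seed that
already passes unchanged; otherwise it runs deterministic multi-start
Nelder–Mead in transformed coordinates (log for rates and slopes, linear
for midpoints) inside a bounds box, optionally over a parameter subset,
and flags the best point infeasible if the budget runs out. Gradient-free
local search was chosen over a large evolutionary stage because the
observable map is smooth in the transformed coordinates near feasible
sets and each evaluation runs the full protocol pipeline; the
parameter-recovery test re-derives a feasible set from a corrupted seed
within ~200 evaluations. The calibration map is many-to-one, so recovery
is judged on observables, not parameter identity.

The shipped default (`data/tetracube_calibrated.yaml`) satisfies all
eight constraints with zero objective. Fast-gate recovery: limiting rate
483/s at −150 mV (τ = 2.07 ms at the gate level; the *fitted* fast
component lands on 2.20 ms once the product-of-gates cross term is
absorbed). The slow-gate recovery law has its inflection far below the
physiological range (−230 mV) — at −150 mV the rate is still rising —
which is what lets a single saturating law be both ≈17/s at −150 mV and
shallow enough near −25 mV to keep the slow-inactivated fractions inside
all three targets simultaneously; the parameters are a phenomenological
encoding of the constraint set, not structural claims.

The MSA parameter set (`data/msa_default.yaml`) reuses the same targets
qualitatively: ~95% gap recovery, ~48% slow inactivation after 10 s at
−20 mV, fast-inactivation midpoint left of slow. Because inactivation in
the MSA inherits the cooperativity of four sensors, its availability
transitions are intrinsically steeper than the cube's, and drug-induced
depression converts into smaller midpoint shifts; quantitative identity
with the cube is not claimed (or needed — the MSA's role is robustness of
the qualitative observations).

## Monte Carlo robustness study

All 18 parameters are redrawn uniformly between bounds — linearly for
midpoints, logarithmically for limiting rates and slopes. The shipped
bounds bracket the calibrated set by ±30 mV and ×/÷30; they are a
reconstruction (wide enough that most draws gate abnormally, which is the
point of the study) and adjustable via config. Randomness is the
counter-based Philox generator keyed per record from the study seed, so
any record regenerates in isolation. Two validity flags replace silent
dropping: `gating_ok` (drug-free equilibrium availability at −120 mV
≥ 0.5) and `slow_inactivation_ok` (slow-inactivated fraction after 10 s
at −20 mV ≥ 5%, below which a slow-inactivation midpoint shift is
undefined). Per-record failures (stiff systems, undefined fits) are
flagged, never abort the batch. The study's summary reports *directional*
quantities — which drug wins each protocol, how often the slow-curve
shift exceeds 5 mV — because the original tally numbers depend on the
original (unavailable) constraint table and are not asserted anywhere in
this package.

## What the synthetic conditions do and do not show

All inputs are generated: the four prototypical mechanisms (fast binding
ka = 0.5 /µM/s, kd = 100/s; slow binding ka = 0.005 /µM/s, kd = 1/s;
preferred-state factor 10; 30 µM; resting Kd = 200 µM for all four) and
the 100-drug grid (ka log-spaced 5e-4–15 /µM/s with ka/kd = 5e-3 fixed;
factors 2, 5, 10, 20, 50 as CF or CS). Passing tests show the *model
algebra and protocol logic* reproduce the expected kinetic phenomenology
under these idealized conditions — single homogeneous channel population,
no rundown, no series-resistance or space-clamp artifacts, no
partitioning delays for drug access, binding treated as a single
microscopic step. Conclusions about real recordings inherit none of those
guarantees; in particular, measured "association rates" of lipophilic
drugs fold in membrane partitioning and access steps the model does not
represent.

## Known limitations

* Gates of the cube are independent by construction; coupling between
  activation and inactivation exists only in the MSA architecture.
* No open-channel block (CA ≡ 1 in shipped fixtures), no trapped-drug
  schemes, no multiple activation particles in the cube, no temperature
  dependence, no ramp (time-varying) voltages within a segment, no
  stochastic single-channel simulation.
* Convex hulls over-cover non-convex point clouds; the overlap class is
  correspondingly conservative.
* The MSA opening step is voltage-independent; its availability
  midpoints sit more negative than the cube's and only qualitative
  agreement between architectures is claimed.
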