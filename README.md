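# navgate

Markov-state simulation of voltage-gated sodium-channel (Na<sub>V</sub>)
gating and state-dependent inhibitor binding.

## The problem

Sodium-channel inhibitors — local anesthetics, anticonvulsants,
antiarrhythmics, and many antidepressants — act by binding preferentially
to inactivated channel conformations. Na<sub>V</sub> channels inactivate on
two time scales: *fast* inactivation (milliseconds, recovering within
~10 ms at strong hyperpolarization) and *slow* inactivation (hundreds of
milliseconds to minutes, surviving brief hyperpolarizing gaps). Whether a
drug stabilizes the fast- or the slow-inactivated state is routinely
inferred from voltage-clamp availability protocols: a long depolarizing
pre-pulse, a brief hyperpolarizing gap that lets fast-inactivated channels
recover, then a test pulse. `navgate` exists to ask, *in silico*, whether
that inference is sound: it simulates the standard protocols against
kinetic channel models with explicit drug-bound states and quantifies what
each protocol can and cannot distinguish.

The short answer the simulations give: a slowly binding drug that
stabilizes the **fast**-inactivated state is nearly indistinguishable from
a slow-inactivated-state stabilizer in the conventional "steady-state slow
inactivation" protocol, so these protocols alone cannot certify
slow-state preference. Combining effectiveness in the *onset* and
*recovery* protocols on a single plane separates the mechanisms — but
only partially, because their regions overlap.

## Models

Two architectures, both continuous-time Markov models `dp/dt = Q(V) p`:

* **Gating cube / tetracube** — three independent two-state gates
  (activation *A*, fast inactivation *F*, slow inactivation *S*) give an
  8-state cube; the channel conducts when all three gates are open. Each
  rate constant follows a saturating three-parameter law
  `k(V) = A / (1 + exp(∓(V − V½)/r))` (18 channel parameters total).
  Adding a drug-bound copy of every vertex yields the 16-state tesseract.
* **Multi-step activation (MSA)** — four identical, independent voltage
  sensors (C0…C4), a concerted opening step, and voltage-independent fast
  and slow inactivation tiers that draw voltage dependence allosterically
  from sensor position (on-rates ×`a^n`, off-rates ÷`a^n` after *n* sensor
  steps). 24 states drug-free, 48 with a drug (224 directed transitions).

A drug is five numbers: association/dissociation rate constants to the
resting state (`ka`, `kd`) and three gate-stabilizing factors
(`CA`, `CF`, `CS`). A factor `C > 1` multiplies both the binding affinity
for configurations with that gate shut and the closed/open equilibrium of
that gate in the drug-bound channel — implemented by slowing recovery of
the bound gate — which keeps every reaction cycle microscopically
reversible. Drug-bound channels never conduct.

Effectiveness statistics: Boltzmann availability-midpoint (V½) shifts,
biexponential recovery time constants, IC50 by bisection, and **nSOD** —
the normalized sum of differences between control and drug availability
curves on a log-even grid, 0 (no effect) to 1 (current abolished).

## Worked example

```python
from navgate import (build_free_model, default_channel_params,
                     prototype_drugs, standard_protocol, run_sweep,
                     run_control_and_drug, fit_biexponential, nsod)

model = build_free_model(default_channel_params())   # calibrated cube
drugs = prototype_drugs()                            # four mechanisms, 30 uM

# drug-free recovery from a 5 s depolarization: two components
rec = run_sweep(model, None, standard_protocol("Rec_t"))
fit = fit_biexponential(rec)
print(f"tau_fast = {fit.tau_fast*1e3:.2f} ms, tau_slow = {fit.tau_slow*1e3:.2f} ms")

# drug effectiveness in the slow-inactivation-onset protocol
proto = standard_protocol("SInact_t")
control = run_sweep(model, None, proto)
for name, drug in drugs.items():
    _, d = run_control_and_drug(model, drug, proto, control=control)
    print(f"nSOD(SInact_t, {name}) = {nsod(control, d):.3f}")
```

Output:

```
tau_fast = 2.20 ms, tau_slow = 57.75 ms
nSOD(SInact_t, FI_fb) = 0.361
nSOD(SInact_t, FI_sb) = 0.303
nSOD(SInact_t, SI_fb) = 0.185
nSOD(SInact_t, SI_sb) = 0.181
```

The two recovery components are the fast- and slow-inactivated pools
(≈2.2 and ≈58 ms at −150 mV). In the onset protocol the *fast-binding,
fast-state-preferring* drug (`FI_fb`) is the most effective — more so than
either slow-state-preferring drug — which is exactly why a shift in this
protocol must not be read as evidence of slow-state preference.

The CLI mirrors the library for batch runs, e.g.

```bash
navgate prototypes --out results/prototypes   # all drugs x all protocols
navgate mc --n 100 --seed 1 --out results/mc.csv
navgate plane --out results/plane.csv
```

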