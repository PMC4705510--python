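# Methods

## Model overview

`mucosim` simulates the early mucosal immune response to a mixed bacterial
exposure as a hybrid ABM/ODE/PDE-style system on a discrete cycle clock. One
cycle has three phases:

1. **Movement and diffusion.** Every live agent takes one random-walk step,
   then every cytokine layer performs one diffusion–evaporation step. The
   relative order (movement first by default) is configurable; the two
   operations commute in expectation because agents never read layers during
   movement unless chemotaxis is enabled.
2. **Computing and updating.** Agents are visited in a uniformly re-shuffled
   order. Immature DCs check their grid cell for bacteria; matured DCs
   secrete; naive T cells (when the intracellular scale is due) query the
   differentiation ODE with the concentrations of their grid cell. All layer
   writes are buffered and applied at the end of the phase, so what
   co-located agents sense within a cycle cannot depend on the shuffle.
3. **Reporting.** Callbacks observe the completed state (population census,
   layer statistics, snapshots, dumps).

A consequence of the phase structure worth knowing: a cytokine deposited in
phase 2 of cycle *n* sits undiffused in its grid cell until phase 1 of cycle
*n*+1, and T cells therefore react to stimuli one cycle after they are
deposited.

## Diffusion–evaporation layers

Each layer applies, synchronously from the previous step's field,

    v_n = ce · [ v_{n−1} + cd' · Σ_N (v_{n−1,neighbor} − v_{n−1}) ]

with `ce = 0.98`, `cd = 0.6` per the study conditions. With a 4- or
8-neighborhood and `cd = 0.6`, the literal rule is unstable at sharp peaks
(the center term `1 − |N|·cd` goes negative), so the default mode is
**normalized**: `cd' = cd/|N|`, which makes each new value `ce` times a
convex combination of old values — unconditionally stable and sign
preserving. The literal rule remains available as `mode="raw"` (paired with
non-negativity clamping by default). Boundary handling is `zero_flux`
(out-of-bounds neighbors mirror the center, contributing zero difference) or
`torus`; on a torus the pairwise cancellation of differences gives the exact
identity `Σ after = ce · Σ before`, which the tests exploit. The von Neumann
stencil is the default; Moore is available, both unweighted.

## Agent rules

* Movement: direction ~ U[0, 2π), speed ~ U[0, speed_max] with
  speed_max = 1 cell side; candidate positions reflect off the walls of the
  agent's compartment. Chemotaxis, when enabled per population, mixes the
  random unit vector with the normalized local gradient: `(1−w)·u + w·∇c/|∇c|`,
  renormalized.
* DC maturation is contact-driven with probability 1 by default. The deposit
  value 70 is the study's stated relative concentration; the TGF-β value for
  tolerogenic DCs is not separately specified and defaults to the same 70 by
  symmetry. Matured DCs re-deposit every cycle while alive (configurable to
  once-only); sustained secretion is what maintains the spatial cytokine
  domains that drive regional Th1/Th17/Treg patterning.
* When infectious and tolerogenic bacteria co-occupy a DC's cell, the
  effector (inflammatory) outcome wins by default; the tie-break is
  configurable.
* Death rules are off by default (none are part of the reference scenario);
  an optional per-type death probability per cycle exists. Dead agents are
  retained with `alive=False` and never move, transition or secrete.
* Buffered deposits are applied in sorted `(layer, cell, value)` order, which
  makes the result independent of agent order; among conflicting `set` writes
  to the same cell the largest value wins deterministically.

## The reduced differentiation model

The network has 9 species — three constant inputs (IL-12, TGF-β, IL-6),
three phenotype master activities (A_Th1, A_Th17, A_Treg) and three outputs
(IFN-γ, IL-17, IL-10) — and 9 reactions giving 6 ODEs:

    dA_Th1/dt  = ka1·IL12                    − kd·A_Th1
    dA_Th17/dt = ka2·TGFb·IL6/(K6 + IL6)     − kd·A_Th17
    dA_Treg/dt = ka3·TGFb/(1 + IL6/Ki)       − kd·A_Treg
    dOUT/dt    = ks·A                          (one per branch)

Defaults: ka1 = ka2 = ka3 = 0.01, kd = 0.1, ks1 = ks2 = ks3 = 0.1,
Ki = K6 = 1.0, horizon T = 50, output-positivity threshold θ_out = 1e-3
(all concentrations in the same relative units as the layers). The phenotype
is the argmax of the terminal outputs (naive if all ≤ θ_out), ties broken
Th1 > Th17 > Treg.

**Why the Th17 branch saturates in IL-6.** Only the network topology and the
three qualitative rules are given; the kinetics are this package's design.
A naive bilinear Th17 induction `ka2·TGFb·IL6/s` has a structural flaw under
the study conditions: effector DCs write *identical* deposits to IL-6 and
IL-12, so those two fields are numerically equal everywhere, and a bilinear
law scaled to the deposit concentration can then never exceed the Th1 drive
(TGF-β ≤ 70 with `set` semantics). Th17 cells would never emerge, which
contradicts the intended "TGF-β and IL-6 both positive → Th17" rule in any
mixed region. With saturation constant K6 the drives become, for
IL6 = IL12 = v and TGFb = w (all branch gains equal):

    Th1 ∝ v      Th17 ∝ w·v/(1 + v)      Treg ∝ w/(1 + v)

so Treg wins where IL-6 is effectively absent (v < 1), Th17 wins in mixed
regions (1 < v < w − 1), and Th1 wins where the eDC signal dominates
(v > w − 1). All three phenotypes then arise in distinct, spatially coherent
cytokine regimes, as the simulated tissue maps show. The corner-input rules
(IL-12 → Th1, TGF-β → Treg, TGF-β+IL-6 → Th17, silence → naive) hold exactly
for either choice. Conflicting inputs are deliberately resolved by the ODE
argmax, not by rule precedence.

**Thresholds.** "Positive" cytokine levels are nowhere quantified; θ_out =
1e-3 relative units keeps cells naive under numerical dust while letting
genuine diffusion tails (which reach ≫ 1e-3 within a few cells of a source)
trigger commitment.

## Numerical integration

The default integrator is classical fixed-step RK4 with h = 0.25 over the
horizon T = 50. For these linear-in-state kinetics (decay rate kd = 0.1,
non-stiff) the global relative error is ~1e-10, comfortably below the 1e-6
agreement the tests demand against the Th1-branch closed form
`A(t) = (ka1·c/kd)(1 − e^{−kd·t})`. RK4 was chosen over an adaptive scheme
for a second reason: its arithmetic is columnwise independent, so a batch of
input conditions integrates to *bitwise* the same result as one-at-a-time
calls. That property is what makes the three solver-instance strategies
(singleton, per-cell, pool) exactly interchangeable and lets the engine batch
all due T cell queries per cycle (with exact-duplicate inputs deduplicated)
without affecting any output. An adaptive route (`method="adaptive"`, scipy
LSODA at rtol 1e-10) is kept as an independent cross-check and is compared in
the tests against an RK4 reference at h = 1e-3.

Model **inflation** pads the reduced network with a mass-action chain of
dynamic dummy species (initialized and hence frozen at zero), isolated
zero-derivative dummies and constant dummies until the metadata matches a
target such as (108, 46, 60); the pathway is untouched, so reduced and
inflated outputs agree to machine precision while the per-step cost scales
with the enlarged state.

## Scheduling, strategies and cost accounting

A scale with frequency f executes on cycles divisible by `round(1/f)`
(cycle 0 included), which reproduces "once every 10 cycles" exactly for
f = 0.1; non-reciprocal frequencies are approximated by the rounded period.
When the intracellular scale is not due, naive T cells simply skip
differentiation that cycle — no cached outputs are reused. Execution counts
per scale and per-cell ODE calls are tracked separately: the DF/RM ratio of
*scale executions* is exactly 0.1 by construction, whereas per-cell call
counts depend on how many T cells remain naive.

Costs `c_si` are measured with a monotonic timer and reported in arbitrary
units; absolute wall-clock and memory figures are hardware-dependent and
deliberately out of scope. The estimate `Σ_i f_si·c_si` is recomputable from
the reported components.

Solver strategies only differ in instance bookkeeping: singleton
reinitializes one shared solver per call, per-cell keeps one per querying
agent (2,000 at peak in the MS scenario), pool rotates through a fixed set.
Since every strategy rebuilds the model state from the querying cell's
inputs, outputs are identical by contract, and the tests assert this at the
byte level on full runs.

## Randomness and determinism

One master seed spawns named child streams (placement, movement, shuffle,
rules) via `SeedSequence` spawn keys, so adding a consumer does not perturb
the others. Every artifact (counts TSV, layer dumps, PNGs) is a pure function
of (config, seed); the suite checks byte-for-byte reproducibility.

## What the presets do and do not emulate

The presets reproduce the reference study conditions: grid size, population
sizes, layer constants, the deposit concentration and the four benchmark
variants. They are still an idealization: a single homogeneous compartment
(the compartment machinery supports lumen/epithelium/lamina-propria layouts
but the reference scenario does not exercise boundaries), no cell division,
recruitment, antigen presentation or death, first-order kinetics with
invented rate constants, and relative concentration units throughout.
Passing tests therefore demonstrate the simulator's mechanics and the stated
qualitative immunology — regional Th1/Th17/Treg patterning and its scheduling
/instance-management structure — not a calibrated prediction for real tissue.

## Problem sizes used in the packaged checks

The automated checks run the full 100×100 scenario with 5,000 agents: 100
cycles for scheduling and qualitative dynamics (5 seeds), 60 cycles for the
three-strategy byte-identity comparison, 30 cycles for determinism, and
10-cycle horizons for the four-scenario benchmark table, keeping the whole
suite around a minute of CPU. Diffusion identities use 10×10–12×12 fields
where the brute-force oracle is cheap.

## Known limitations

* The literal (`raw`) update rule with the study's constants is unstable at
  point sources; it is retained for fidelity but the normalized mode is the
  default everywhere.
* `f` values whose reciprocal is far from an integer are honored only
  through the rounded period.
* The pool strategy is a correctness/bookkeeping model of pooling; no actual
  multithreading is performed.
* SBML import/export of the declarative reaction format is not provided; the
  YAML model-definition file is the exchange format.
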