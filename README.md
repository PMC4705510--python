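# mucosim

Multiscale agent-based simulation of gut mucosal immune responses.

`mucosim` couples three spatiotemporal scales of an inflamed gut tissue on a
shared cycle clock:

* **Cellular scale** — bacteria, dendritic cells and CD4+ T cells are agents
  with continuous positions on a 2-D grid of tissue compartments. They move by
  a bounded random walk (direction uniform on the circle, speed uniform on
  `[0, 1]` cell sides per cycle, optional chemotactic bias) and change state
  through stochastic contact and cytokine rules: an immature dendritic cell
  (iDC) co-located with an infectious bacterium matures into an effector DC
  and releases IL-6 and IL-12 (concentration set to 70, relative units, at its
  grid cell); contact with a tolerogenic bacterium produces a tolerogenic DC
  releasing TGF-β.
* **Intercellular scale** — each cytokine is a *value layer*: a per-grid-cell
  concentration field evolved once per cycle by the discrete
  diffusion–evaporation rule
  `v_n = c_e [ v_{n−1} + c_d Σ_N (v_{n−1,neighbor} − v_{n−1}) ]`
  with evaporation constant `c_e = 0.98` and diffusion constant `c_d = 0.6`
  (normalized by the neighborhood size for unconditional stability).
* **Intracellular scale** — each naive CD4+ T cell senses the local
  (IL-12, TGF-β, IL-6) concentrations and feeds them to a reduced kinetic
  model of CD4+ T cell differentiation (9 species, 9 reactions, 6 ODEs). The
  terminal output cytokines decide the phenotype — IL-12 drives Th1 (IFN-γ),
  TGF-β alone drives Treg (IL-10), TGF-β together with IL-6 drives Th17
  (IL-17) — and the committed cell deposits its signature cytokine back into
  the tissue. Differentiation is irreversible.

Three performance-matching techniques from multiscale-simulation practice are
built in and benchmarkable: **hybrid frequencies** (each scale runs with its
own frequency `f_si ∈ (0,1]`; the estimated cycle cost is `Σ_i f_si·c_si`),
**solver-instance strategies** (one shared singleton ODE solver reinitialized
per call, one persistent solver per cell, or a fixed pool) and **model
reduction/inflation** (an inert-padding inflator reproduces the metadata of a
comprehensive 108-species, 46-reaction, 60-ODE network while preserving the
reduced model's input→output mapping, for cost benchmarking).

Four preset scenarios package the reference study conditions — a 100×100
single-compartment square with 1,000 bacteria (half infectious, half
tolerogenic), 2,000 naive T cells and 2,000 immature DCs placed uniformly at
random:

| preset | meaning |
|--------|---------|
| `RM` | reduced ODE model, singleton solver, all frequencies 1 |
| `BM` | RM with the model inflated to comprehensive size (108, 46, 60) |
| `MS` | RM with one solver instance per T cell (peaks at 2,000 instances) |
| `DF` | RM with intracellular frequency 0.1 (ODE once per 10 cycles) |

## Worked example

```sh
mucosim run --preset RM --cycles 20 --seed 42 --out out/
```

prints `wrote out/counts.tsv (20 cycles, seed 42)` and produces a
tab-separated per-cycle census. Pivoting the T cell rows:

```
state   Th1  Th17  Treg  naive
cycle
0         0     0     0   2000
1         0     0     0   2000
2        93     1    73   1833
5       685    25   622    668
10      998    27   969      6
20     1003    27   970      0
```

Cycle 0 is the initial census and nothing differentiates during cycle 1: the
DCs that meet bacteria mature then, but their cytokines only become visible to
T cells after diffusing in the next cycle. From cycle 2 on, T cells caught in
the spreading IL-12/IL-6 plumes of effector DCs commit to Th1, cells in
TGF-β-dominated regions around tolerogenic DCs commit to Treg, and the mixed
fringes (strong TGF-β with moderate IL-6) yield Th17. By cycle 20 every naive
cell has differentiated. The run manifest (`out/manifest.json`) records the
config hash, seed, 9,707 per-cell ODE calls, 20 intracellular executions and a
peak of 1 solver instance (singleton).

Other entry points: `mucosim benchmark` runs all four presets and tabulates
init cost, per-run cost, the `Σ f·c` estimate, peak solver instances and
invocation counts; `mucosim validate` checks a scenario file;
`mucosim render` re-renders PNG snapshots from layer dumps. Everything is also
available as a library (`mucosim.preset`, `mucosim.run`,
`mucosim.build_reduced_model`, …).

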