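"""Simulation engine: scenarios, the three-phase cycle, scheduling.

A scenario couples three scales on a shared clock of discrete cycles:

* **cellular** — agents move (Brownian walk) and apply contact /
  transition rules;
* **intercellular** — cytokine value layers diffuse and evaporate;
* **intracellular** — naive CD4+ T cells query the differentiation ODE
  model with their local cytokine concentrations.

Each cycle runs three phases: (a) movement then layer diffusion,
(b) computing-and-updating in uniformly shuffled agent order with all
cytokine deposits buffered and applied at the end of the phase (so what
co-located agents sense cannot depend on update order), (c) reporting.

Per-scale execution frequencies ``f_si`` in (0, 1] implement hybrid
multiscale coupling: a scale with frequency f executes on cycles that
are multiples of ``round(1/f)``. With the cost ``c_si`` of one sub-model
execution of scale i, the estimated cost of a cycle is ``sum_i f_si *
c_si``.

Four named benchmark scenarios are provided:

* ``RM`` — reduced ODE model, singleton solver, all frequencies 1;
* ``BM`` — RM with the model inflated to comprehensive-model size
  (108 species, 46 reactions, 60 ODEs);
* ``MS`` — RM with one persistent solver instance per T cell;
* ``DF`` — RM with intracellular frequency 0.1 (ODE once per 10 cycles).
"""

from __future__ import annotations

import time
import zlib
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import yaml

from . import agents as ag
from . import intracellular as intra
from .spatial import Compartment, GridSpace, ValueLayer

__all__ = [
    "LayerSpec",
    "PopulationSpec",
    "ScenarioConfig",
    "CostMetrics",
    "SimulationState",
    "preset",
    "PRESET_NAMES",
    "init_scenario",
    "run_cycle",
    "run",
    "is_due",
    "estimate_cycle_cost",
]

SCALES = ("cellular", "intercellular", "intracellular")
DEFAULT_LAYERS = ("IL12", "TGFb", "IL6", "IFNg", "IL17", "IL10")
PRESET_NAMES = ("RM", "BM", "MS", "DF")


@dataclass(frozen=True)
class LayerSpec:
    name: str
    ce: float = 0.98
    cd: float = 0.6
    neighborhood: str = "von_neumann"
    boundary: str = "zero_flux"
    mode: str = "normalized"
    clamp_nonnegative: bool = True


@dataclass(frozen=True)
class PopulationSpec:
    cell_type: str
    state: str
    count: int
    distribution: str = "uniform"  # uniform random placement
    speed_max: float = 1.0
    chemotaxis: tuple[str, float] | None = None

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("population count must be >= 0")


@dataclass
class ScenarioConfig:
    """Complete specification of a simulation run."""

    width: int = 100
    height: int = 100
    compartments: list[Compartment] = field(default_factory=list)
    layers: list[LayerSpec] = field(
        default_factory=lambda: [LayerSpec(n) for n in DEFAULT_LAYERS]
    )
    populations: list[PopulationSpec] = field(default_factory=list)
    ode_params: intra.KineticParams = field(default_factory=intra.KineticParams)
    ode_horizon: float = 50.0
    ode_inflation: tuple[int, int, int] | None = None
    solver_strategy: str = "singleton"
    frequencies: dict = field(
        default_factory=lambda: {s: 1.0 for s in SCALES}
    )
    cycles: int = 100
    seed: int = 0
    deposit_value: float = 70.0
    deposit_semantics: str = "set"
    dc_secrete_every_cycle: bool = True
    mixed_contact_tie_break: str = "effector"
    movement_enabled: bool = True
    diffusion_before_movement: bool = False
    death_probability: dict = field(default_factory=dict)  # cell_type -> p
    generic_rules: list[ag.TransitionRule] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.cycles < 0:
            raise ValueError("cycles must be >= 0")
        for scale, f in self.frequencies.items():
            if scale not in SCALES:
                raise ValueError(f"unknown scale {scale!r}")
            if not (0.0 < f <= 1.0):
                raise ValueError(f"frequency for {scale!r} must be in (0, 1]")
        names = [l.name for l in self.layers]
        if len(set(names)) != len(names):
            raise ValueError("duplicate layer names")
        intra.SolverStrategy.parse(self.solver_strategy)  # validate
        for rule in self.generic_rules:
            if rule.trigger[0] == "local_cytokine" and rule.trigger[1] not in names:
                raise ValueError(
                    f"rule for {rule.agent_type!r} references unknown layer "
                    f"{rule.trigger[1]!r}"
                )
            for layer, _v, _s in rule.secretions:
                if layer not in names:
                    raise ValueError(f"rule secretion to unknown layer {layer!r}")

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "grid": {"width": self.width, "height": self.height},
            "layers": [vars(l).copy() for l in self.layers],
            "populations": [
                {k: v for k, v in vars(p).items() if v is not None}
                for p in self.populations
            ],
            "ode": {
                "params": {
                    k: getattr(self.ode_params, k)
                    for k in (
                        "ka1", "ka2", "ka3", "kd", "ks1", "ks2", "ks3",
                        "Ki", "K6", "theta_out",
                    )
                },
                "horizon": self.ode_horizon,
                "inflation": list(self.ode_inflation) if self.ode_inflation else None,
                "strategy": self.solver_strategy,
            },
            "frequencies": dict(self.frequencies),
            "cycles": self.cycles,
            "seed": self.seed,
            "deposit_value": self.deposit_value,
            "deposit_semantics": self.deposit_semantics,
            "dc_secrete_every_cycle": self.dc_secrete_every_cycle,
            "mixed_contact_tie_break": self.mixed_contact_tie_break,
            "movement_enabled": self.movement_enabled,
            "diffusion_before_movement": self.diffusion_before_movement,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        ode = d.get("ode", {})
        pops = []
        for p in d.get("populations", []):
            p = dict(p)
            if "chemotaxis" in p and p["chemotaxis"] is not None:
                p["chemotaxis"] = tuple(p["chemotaxis"])
            pops.append(PopulationSpec(**p))
        return cls(
            width=d.get("grid", {}).get("width", 100),
            height=d.get("grid", {}).get("height", 100),
            layers=[LayerSpec(**l) for l in d.get("layers", [])]
            or [LayerSpec(n) for n in DEFAULT_LAYERS],
            populations=pops,
            ode_params=intra.KineticParams(**ode.get("params", {})),
            ode_horizon=ode.get("horizon", 50.0),
            ode_inflation=tuple(ode["inflation"]) if ode.get("inflation") else None,
            solver_strategy=ode.get("strategy", "singleton"),
            frequencies=d.get("frequencies", {s: 1.0 for s in SCALES}),
            cycles=d.get("cycles", 100),
            seed=d.get("seed", 0),
            deposit_value=d.get("deposit_value", 70.0),
            deposit_semantics=d.get("deposit_semantics", "set"),
            dc_secrete_every_cycle=d.get("dc_secrete_every_cycle", True),
            mixed_contact_tie_break=d.get("mixed_contact_tie_break", "effector"),
            movement_enabled=d.get("movement_enabled", True),
            diffusion_before_movement=d.get("diffusion_before_movement", False),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def preset(name: str, *, cycles: int = 100, seed: int = 0) -> ScenarioConfig:
    """One of the four benchmark scenarios (RM, BM, MS, DF).

    All share the reference setup: a 100x100 single-compartment square,
    1,000 bacteria (50% infectious, 50% tolerogenic), 2,000 naive T cells
    and 2,000 immature dendritic cells uniformly placed at random, six
    cytokine layers with ce=0.98 and cd=0.6, and unit frequencies.
    """
    if name not in PRESET_NAMES:
        raise ValueError(
            f"unknown preset {name!r}; valid presets: {', '.join(PRESET_NAMES)}"
        )
    cfg = ScenarioConfig(
        width=100,
        height=100,
        populations=[
            PopulationSpec("bacterium", "infectious", 500),
            PopulationSpec("bacterium", "tolerogenic", 500),
            PopulationSpec("t_cell", "naive", 2000),
            PopulationSpec("dendritic_cell", "immature", 2000),
        ],
        cycles=cycles,
        seed=seed,
    )
    if name == "BM":
        cfg.ode_inflation = (108, 46, 60)
    elif name == "MS":
        cfg.solver_strategy = "per_cell"
    elif name == "DF":
        cfg.frequencies = {"cellular": 1.0, "intercellular": 1.0, "intracellular": 0.1}
    return cfg


# -- scheduling and cost accounting ------------------------------------


def is_due(scale: str, cycle: int, f_si: float) -> bool:
    """Whether a scale with frequency f executes on a given cycle.

    The execution period is ``round(1/f)``; the scale runs on cycle 0 of
    each period. ``f = 1`` runs every cycle.
    """
    if not (0.0 < f_si <= 1.0):
        raise ValueError(f"frequency must be in (0, 1], got {f_si}")
    period = int(round(1.0 / f_si))
    return cycle % period == 0


@dataclass
class CostMetrics:
    """Per-scale accounting: execution counts, measured costs, instances.

    ``executions`` counts cycles on which a scale's sub-model ran;
    ``ode_calls`` counts individual per-cell ODE queries; ``cost`` is the
    cumulative measured wall time of each scale in arbitrary units
    (absolute values are hardware-dependent and not reproducible).
    """

    executions: dict = field(default_factory=lambda: {s: 0 for s in SCALES})
    cost: dict = field(default_factory=lambda: {s: 0.0 for s in SCALES})
    ode_calls: int = 0
    peak_solver_instances: int = 0
    init_cost: float = 0.0

    def mean_cost(self, scale: str) -> float:
        n = self.executions[scale]
        return self.cost[scale] / n if n else 0.0


def estimate_cycle_cost(
    metrics: CostMetrics, frequencies: Mapping[str, float]
) -> float:
    """Estimated cost of one cycle, ``sum_i f_si * c_si``.

    ``c_si`` is the measured mean per-execution cost of scale i. Scales
    absent from ``frequencies`` (or with f=0) contribute nothing.
    """
    if not any(metrics.executions.values()):
        raise ValueError("metrics are empty; run at least one cycle first")
    total = 0.0
    for scale, f in frequencies.items():
        if f:
            total += f * metrics.mean_cost(scale)
    return total


# -- simulation state and cycle ----------------------------------------


def _stream(seed: int, name: str) -> np.random.Generator:
    """A named child RNG stream derived from the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(zlib.crc32(name.encode()),))
    )


class SimulationState:
    """Everything the engine evolves: space, layers, agents, counters."""

    def __init__(self, config: ScenarioConfig) -> None:
        self.config = config
        self.space = GridSpace(config.width, config.height, compartments=list(config.compartments))
        self.layers: dict[str, ValueLayer] = {
            spec.name: ValueLayer(
                spec.name,
                config.width,
                config.height,
                ce=spec.ce,
                cd=spec.cd,
                neighborhood=spec.neighborhood,
                boundary=spec.boundary,
                mode=spec.mode,
                clamp_nonnegative=spec.clamp_nonnegative,
            )
            for spec in config.layers
        }
        self.agents: list[ag.CellAgent] = []
        self.cycle = 0
        self.rng = {
            name: _stream(config.seed, name)
            for name in ("placement", "movement", "shuffle", "rules")
        }
        self.metrics = CostMetrics()
        model = intra.build_reduced_model(config.ode_params, config.ode_horizon)
        if config.ode_inflation is not None:
            model = intra.inflate_model(model, config.ode_inflation)
        self.ode_service = intra.OdeService(model, config.solver_strategy)
        self.reporters: list[Callable[["SimulationState"], None]] = []

    # convenience accessors -------------------------------------------

    def counts(self) -> dict[tuple[str, str], int]:
        out: dict[tuple[str, str], int] = {}
        for a in self.agents:
            key = (a.cell_type, a.state)
            out[key] = out.get(key, 0) + 1
        return out

    def agents_of(self, cell_type: str, state: str | None = None) -> list[ag.CellAgent]:
        return [
            a
            for a in self.agents
            if a.cell_type == cell_type and (state is None or a.state == state)
        ]


def init_scenario(config: ScenarioConfig) -> SimulationState:
    """Build the initial state: zero layers, uniformly placed agents."""
    t0 = time.perf_counter()
    state = SimulationState(config)
    rng = state.rng["placement"]
    next_id = 0
    for pop in config.populations:
        if pop.distribution != "uniform":
            raise ValueError(
                f"unknown spatial distribution {pop.distribution!r} "
                f"for population {pop.cell_type}/{pop.state}"
            )
        xs = rng.uniform(0.0, config.width, size=pop.count)
        ys = rng.uniform(0.0, config.height, size=pop.count)
        for x, y in zip(xs, ys):
            comp = state.space.compartment_of(x, y)
            state.agents.append(
                ag.CellAgent(
                    id=next_id,
                    cell_type=pop.cell_type,
                    state=pop.state,
                    x=float(x),
                    y=float(y),
                    compartment=comp.name,
                    speed_max=pop.speed_max,
                    chemotaxis=pop.chemotaxis,
                )
            )
            next_id += 1
    # Touch the solver once so instance accounting starts from a built pool.
    state.metrics.peak_solver_instances = state.ode_service.n_instances
    state.metrics.init_cost = time.perf_counter() - t0
    return state


def _do_movement(state: SimulationState) -> None:
    t0 = time.perf_counter()
    rng = state.rng["movement"]
    for a in state.agents:
        if a.alive:
            ag.move(a, state.space, rng, state.layers)
    state.metrics.cost["cellular"] += time.perf_counter() - t0


def _do_diffusion(state: SimulationState) -> None:
    t0 = time.perf_counter()
    for layer in state.layers.values():
        layer.diffuse()
    state.metrics.cost["intercellular"] += time.perf_counter() - t0


def _apply_deposits(
    state: SimulationState, deposits: list[tuple[str, tuple[int, int], float, str]]
) -> None:
    """Apply buffered deposits in a canonical order.

    Sorting by (layer, cell, value) makes the final field independent of
    the shuffled agent order; among conflicting ``set`` writes to one
    cell the largest value wins.
    """
    for layer, cell, value, sem in sorted(
        deposits, key=lambda d: (d[0], d[1], d[2], d[3])
    ):
        state.layers[layer].deposit(cell, value, sem)


def run_cycle(state: SimulationState) -> SimulationState:
    """Advance the simulation by one cycle (three phases)."""
    cfg = state.config
    cyc = state.cycle
    freqs = cfg.frequencies
    cellular_due = is_due("cellular", cyc, freqs.get("cellular", 1.0))
    intercellular_due = is_due("intercellular", cyc, freqs.get("intercellular", 1.0))
    intracellular_due = is_due("intracellular", cyc, freqs.get("intracellular", 1.0))

    # Phase (a): movement and diffusion (gated by their scale frequencies).
    move_now = cellular_due and cfg.movement_enabled
    if intercellular_due:
        state.metrics.executions["intercellular"] += 1
    if cfg.diffusion_before_movement:
        if intercellular_due:
            _do_diffusion(state)
        if move_now:
            _do_movement(state)
    else:
        if move_now:
            _do_movement(state)
        if intercellular_due:
            _do_diffusion(state)

    # Phase (b): computing and updating, in shuffled order, deposits buffered.
    deposits: list[tuple[str, tuple[int, int], float, str]] = []
    if cellular_due:
        state.metrics.executions["cellular"] += 1
        t0 = time.perf_counter()
        order = state.rng["shuffle"].permutation(len(state.agents))
        by_cell: dict[tuple[int, int], list[ag.CellAgent]] = {}
        for a in state.agents:
            if a.alive:
                by_cell.setdefault(a.cell(), []).append(a)
        rules_rng = state.rng["rules"]
        naive_tcells: list[ag.CellAgent] = []
        for idx in order:
            a = state.agents[idx]
            if not a.alive:
                continue
            if a.cell_type == "dendritic_cell":
                if a.state == "immature":
                    deposits += ag.dc_contact_update(
                        a,
                        by_cell.get(a.cell(), ()),
                        state.layers,
                        rules_rng,
                        deposit_value=cfg.deposit_value,
                        semantics=cfg.deposit_semantics,
                        tie_break=cfg.mixed_contact_tie_break,
                    )
                elif cfg.dc_secrete_every_cycle:
                    deposits += ag.dc_secrete(
                        a,
                        deposit_value=cfg.deposit_value,
                        semantics=cfg.deposit_semantics,
                    )
            elif a.cell_type == "t_cell" and a.state == "naive":
                if intracellular_due:
                    naive_tcells.append(a)
            if cfg.generic_rules:
                deposits += ag.apply_generic_rules(
                    a, cfg.generic_rules, by_cell.get(a.cell(), ()), state.layers, rules_rng
                )
            p_death = cfg.death_probability.get(a.cell_type, 0.0)
            if p_death and a.alive and rules_rng.random() < p_death:
                a.kill()
        state.metrics.cost["cellular"] += time.perf_counter() - t0

        if intracellular_due:
            state.metrics.executions["intracellular"] += 1
            t0 = time.perf_counter()
            if naive_tcells:
                inputs = np.empty((3, len(naive_tcells)))
                cells = [a.cell() for a in naive_tcells]
                for k, name in enumerate(("IL12", "TGFb", "IL6")):
                    layer = state.layers[name]
                    inputs[k] = [layer.value_at(c) for c in cells]
                try:
                    outputs = state.ode_service.query_batch(
                        inputs, [a.id for a in naive_tcells]
                    )
                except Exception as exc:
                    raise RuntimeError(
                        f"intracellular solve failed at cycle {cyc} "
                        f"(agents {[a.id for a in naive_tcells[:3]]}...): {exc}"
                    ) from exc
                theta = state.ode_service.model.params.theta_out
                for j, a in enumerate(naive_tcells):
                    phenotype = intra.classify_outputs(outputs[:, j], theta)
                    if phenotype == "naive":
                        continue
                    a.state = phenotype
                    layer = ag.TCELL_SECRETION[phenotype]
                    row = {"IFNg": 0, "IL17": 1, "IL10": 2}[layer]
                    deposits.append(
                        (layer, cells[j], float(outputs[row, j]), cfg.deposit_semantics)
                    )
            state.metrics.ode_calls = state.ode_service.calls
            state.metrics.cost["intracellular"] += time.perf_counter() - t0

        _apply_deposits(state, deposits)
        state.metrics.peak_solver_instances = max(
            state.metrics.peak_solver_instances, state.ode_service.n_instances
        )

    # Phase (c): reporting callbacks (after the cycle counter advances,
    # so a reporter sees the number of completed cycles).
    state.cycle += 1
    for reporter in state.reporters:
        reporter(state)
    return state


def run(
    config: ScenarioConfig,
    *,
    reporters: Sequence[Callable[[SimulationState], None]] = (),
) -> SimulationState:
    """Initialize a scenario and run it for its configured cycle count.

    Reporters fire once at cycle 0 (initial state) and then at the end of
    every cycle.
    """
    state = init_scenario(config)
    state.reporters = list(reporters)
    for reporter in state.reporters:
        reporter(state)
    for _ in range(config.cycles):
        run_cycle(state)
    return state
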