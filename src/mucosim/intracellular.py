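"""Intracellular CD4+ T cell differentiation model.

A naive CD4+ T cell senses three input cytokines in its micro-environment
(IL-12, TGF-beta, IL-6) and commits to one of three phenotypes, each with
a signature output cytokine:

* IL-12 positive                      -> Th1  (secretes IFN-gamma)
* TGF-beta positive, IL-6 negative    -> Treg (secretes IL-10)
* TGF-beta and IL-6 both positive     -> Th17 (secretes IL-17)

The reduced kinetic network has 9 species (3 inputs, 3 phenotype master
activities, 3 outputs), 9 reactions and 6 ODEs; the inputs are held
constant over a solve. Induction kinetics:

    dA_Th1/dt  = ka1 * IL12                      - kd * A_Th1
    dA_Th17/dt = ka2 * TGFb * IL6 / (K6 + IL6)   - kd * A_Th17
    dA_Treg/dt = ka3 * TGFb / (1 + IL6 / Ki)     - kd * A_Treg
    dOUT/dt    = ks  * A_phenotype               (OUT in IFNg, IL17, IL10)

The Th17 branch saturates in IL-6 so that a strong TGF-beta signal with
clearly positive IL-6 out-competes the Th1 branch at moderate IL-12,
while the ``1/(1 + IL6/Ki)`` term suppresses Treg induction whenever IL-6
is present. Conflicting inputs are resolved quantitatively: the phenotype
whose output cytokine is largest at the end of the time course wins.

Solver-instance management mirrors the scale-coupling techniques of the
surrounding multiscale engine: a ``singleton`` solver reinitialized per
call, a persistent ``per_cell`` solver per agent, or a fixed ``pool``.
All strategies reset the model state from the querying cell's inputs on
every call, so their outputs are identical by construction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import yaml

__all__ = [
    "KineticParams",
    "Species",
    "Reaction",
    "ODEModel",
    "SolverStrategy",
    "OdeSolver",
    "OdeService",
    "build_reduced_model",
    "inflate_model",
    "time_course",
    "time_course_batch",
    "classify_outputs",
    "solve_for_cell",
    "save_model",
    "load_model",
]

INPUT_SPECIES = ("IL12", "TGFb", "IL6")
OUTPUT_SPECIES = ("IFNg", "IL17", "IL10")
PHENOTYPE_BY_OUTPUT = {"IFNg": "Th1", "IL17": "Th17", "IL10": "Treg"}
#: Tie-break priority when two output cytokines are exactly equal.
PHENOTYPE_PRIORITY = ("Th1", "Th17", "Treg")


@dataclass(frozen=True)
class KineticParams:
    """Rate constants of the reduced differentiation network.

    All rates are in reciprocal time-course time units; concentrations are
    relative units. ``Ki`` is the IL-6 inhibition constant of Treg
    induction, ``K6`` the IL-6 half-saturation of Th17 induction,
    ``theta_out`` the output-positivity threshold used by
    :func:`classify_outputs`.
    """

    ka1: float = 0.01  # Th1 induction per unit IL-12
    ka2: float = 0.01  # Th17 induction per unit TGF-beta (IL-6 saturating)
    ka3: float = 0.01  # Treg induction per unit TGF-beta (IL-6 inhibited)
    kd: float = 0.1  # phenotype activity decay
    ks1: float = 0.1  # IFN-gamma secretion per unit A_Th1
    ks2: float = 0.1  # IL-17 secretion per unit A_Th17
    ks3: float = 0.1  # IL-10 secretion per unit A_Treg
    Ki: float = 1.0  # IL-6 inhibition constant (Treg branch)
    K6: float = 1.0  # IL-6 saturation constant (Th17 branch)
    theta_out: float = 1e-3

    def __post_init__(self) -> None:
        for name in ("ka1", "ka2", "ka3", "kd", "ks1", "ks2", "ks3", "Ki", "K6"):
            if getattr(self, name) <= 0:
                raise ValueError(f"kinetic parameter {name} must be > 0")
        if self.theta_out < 0:
            raise ValueError("theta_out must be >= 0")


@dataclass(frozen=True)
class Species:
    name: str
    role: str  # input | state | output | inert
    dynamic: bool  # whether the species carries an ODE


# Rate-law registry. Each law maps (concentration row vectors of the
# reaction's modifier species, parameter dict) -> rate vector.
def _law_mass_action(mods: Sequence[np.ndarray], p: dict) -> np.ndarray:
    return p["k"] * mods[0]


def _law_bilinear_saturating(mods: Sequence[np.ndarray], p: dict) -> np.ndarray:
    a, b = mods
    return p["k"] * a * b / (p["K"] + b)


def _law_inhibited_linear(mods: Sequence[np.ndarray], p: dict) -> np.ndarray:
    a, b = mods
    return p["k"] * a / (1.0 + b / p["K"])


RATE_LAWS: dict[str, Callable] = {
    "mass_action": _law_mass_action,
    "bilinear_saturating": _law_bilinear_saturating,
    "inhibited_linear": _law_inhibited_linear,
}


@dataclass(frozen=True)
class Reaction:
    """A named rate process: rate law over modifier species, applied to
    the ODEs of the stoichiometry map (species -> signed coefficient)."""

    name: str
    rate_law: str
    params: dict
    modifiers: tuple[str, ...]
    stoichiometry: dict

    def __post_init__(self) -> None:
        if self.rate_law not in RATE_LAWS:
            raise ValueError(f"unknown rate law {self.rate_law!r}")
        for key, value in self.params.items():
            if value <= 0:
                raise ValueError(
                    f"reaction {self.name!r}: rate constant {key} must be > 0"
                )


class ODEModel:
    """A declarative reaction-network model with constant-input species."""

    def __init__(
        self,
        species: Sequence[Species],
        reactions: Sequence[Reaction],
        params: KineticParams,
        horizon: float = 50.0,
    ) -> None:
        if horizon <= 0:
            raise ValueError("horizon must be > 0")
        self.species = list(species)
        self.reactions = list(reactions)
        self.params = params
        self.horizon = float(horizon)
        self._index = {s.name: i for i, s in enumerate(self.species)}
        if len(self._index) != len(self.species):
            raise ValueError("duplicate species names")
        for r in self.reactions:
            for name in itertools.chain(r.modifiers, r.stoichiometry):
                if name not in self._index:
                    raise ValueError(
                        f"reaction {r.name!r} references unknown species {name!r}"
                    )
                if name in r.stoichiometry and not self.species[
                    self._index[name]
                ].dynamic:
                    raise ValueError(
                        f"reaction {r.name!r} writes to non-dynamic species {name!r}"
                    )

    # -- metadata ------------------------------------------------------

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def n_odes(self) -> int:
        return sum(s.dynamic for s in self.species)

    @property
    def metadata(self) -> tuple[int, int, int]:
        """(species, reactions, ODEs) counts."""
        return (self.n_species, self.n_reactions, self.n_odes)

    def index_of(self, name: str) -> int:
        return self._index[name]

    # -- right-hand side -----------------------------------------------

    def rhs(self, conc: np.ndarray) -> np.ndarray:
        """Time derivative of the full concentration matrix.

        ``conc`` has shape ``(n_species, n)``; non-dynamic rows (inputs,
        inert constants) always have zero derivative.
        """
        d = np.zeros_like(conc)
        for r in self.reactions:
            mods = [conc[self._index[m]] for m in r.modifiers]
            rate = RATE_LAWS[r.rate_law](mods, r.params)
            for name, coeff in r.stoichiometry.items():
                d[self._index[name]] += coeff * rate
        return d

    # -- (de)serialization ---------------------------------------------

    def to_dict(self) -> dict:
        return {
            "horizon": self.horizon,
            "params": {
                k: getattr(self.params, k)
                for k in (
                    "ka1", "ka2", "ka3", "kd", "ks1", "ks2", "ks3",
                    "Ki", "K6", "theta_out",
                )
            },
            "species": [
                {"name": s.name, "role": s.role, "dynamic": s.dynamic}
                for s in self.species
            ],
            "reactions": [
                {
                    "name": r.name,
                    "rate_law": r.rate_law,
                    "params": dict(r.params),
                    "modifiers": list(r.modifiers),
                    "stoichiometry": dict(r.stoichiometry),
                }
                for r in self.reactions
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ODEModel":
        species = [Species(s["name"], s["role"], bool(s["dynamic"])) for s in d["species"]]
        reactions = [
            Reaction(
                r["name"],
                r["rate_law"],
                dict(r["params"]),
                tuple(r["modifiers"]),
                dict(r["stoichiometry"]),
            )
            for r in d["reactions"]
        ]
        return cls(species, reactions, KineticParams(**d["params"]), d["horizon"])


def save_model(model: ODEModel, path) -> None:
    """Write the declarative model definition as structured text (YAML)."""
    with open(path, "w") as fh:
        yaml.safe_dump(model.to_dict(), fh, sort_keys=False)


def load_model(path) -> ODEModel:
    with open(path) as fh:
        return ODEModel.from_dict(yaml.safe_load(fh))


def build_reduced_model(
    params: KineticParams | None = None, horizon: float = 50.0
) -> ODEModel:
    """The reduced differentiation network: 9 species, 9 reactions, 6 ODEs."""
    p = params or KineticParams()
    species = (
        [Species(n, "input", False) for n in INPUT_SPECIES]
        + [Species(n, "state", True) for n in ("A_Th1", "A_Th17", "A_Treg")]
        + [Species(n, "output", True) for n in OUTPUT_SPECIES]
    )
    reactions = [
        Reaction("th1_induction", "mass_action", {"k": p.ka1}, ("IL12",), {"A_Th1": 1.0}),
        Reaction("th1_decay", "mass_action", {"k": p.kd}, ("A_Th1",), {"A_Th1": -1.0}),
        Reaction(
            "th17_induction",
            "bilinear_saturating",
            {"k": p.ka2, "K": p.K6},
            ("TGFb", "IL6"),
            {"A_Th17": 1.0},
        ),
        Reaction("th17_decay", "mass_action", {"k": p.kd}, ("A_Th17",), {"A_Th17": -1.0}),
        Reaction(
            "treg_induction",
            "inhibited_linear",
            {"k": p.ka3, "K": p.Ki},
            ("TGFb", "IL6"),
            {"A_Treg": 1.0},
        ),
        Reaction("treg_decay", "mass_action", {"k": p.kd}, ("A_Treg",), {"A_Treg": -1.0}),
        Reaction("ifng_secretion", "mass_action", {"k": p.ks1}, ("A_Th1",), {"IFNg": 1.0}),
        Reaction("il17_secretion", "mass_action", {"k": p.ks2}, ("A_Th17",), {"IL17": 1.0}),
        Reaction("il10_secretion", "mass_action", {"k": p.ks3}, ("A_Treg",), {"IL10": 1.0}),
    ]
    return ODEModel(species, reactions, p, horizon)


def inflate_model(
    model: ODEModel, target: tuple[int, int, int]
) -> ODEModel:
    """Pad a model with inert species/reactions/ODEs to match a metadata
    target, leaving the input->output mapping untouched.

    The padding consists of (i) a chain of dynamic dummy species coupled
    by mass-action transfer reactions, all initialized at zero so they
    stay at zero, (ii) isolated dynamic dummies with no reactions
    (identically zero derivative), and (iii) constant dummy species.
    None of them touches the differentiation pathway.
    """
    n_sp, n_rx, n_ode = target
    if n_sp < model.n_species or n_rx < model.n_reactions or n_ode < model.n_odes:
        raise ValueError(
            f"inflation target {target} below current metadata {model.metadata}"
        )
    add_rx = n_rx - model.n_reactions
    add_ode = n_ode - model.n_odes
    add_sp = n_sp - model.n_species
    # A chain of add_rx reactions spans add_rx + 1 dynamic species (when
    # any reactions are added at all).
    chain_len = add_rx + 1 if add_rx > 0 else 0
    isolated = add_ode - chain_len
    constants = add_sp - add_ode
    if isolated < 0 or constants < 0:
        raise ValueError(
            f"infeasible inflation target {target}: needs at least "
            f"{model.n_odes + chain_len} ODEs and ODE count <= species count"
        )
    species = list(model.species)
    reactions = list(model.reactions)
    chain = [Species(f"dummy_chain_{i}", "inert", True) for i in range(chain_len)]
    species += chain
    species += [Species(f"dummy_iso_{i}", "inert", True) for i in range(isolated)]
    species += [Species(f"dummy_const_{i}", "inert", False) for i in range(constants)]
    for i in range(add_rx):
        a, b = chain[i].name, chain[i + 1].name
        reactions.append(
            Reaction(
                f"dummy_transfer_{i}",
                "mass_action",
                {"k": 0.1},
                (a,),
                {a: -1.0, b: 1.0},
            )
        )
    return ODEModel(species, reactions, model.params, model.horizon)


# -- integration -------------------------------------------------------


def _initial_state(model: ODEModel, inputs: np.ndarray) -> np.ndarray:
    """(n_species, n) concentration matrix: inputs set, everything else 0."""
    n = inputs.shape[1]
    conc = np.zeros((model.n_species, n), dtype=np.float64)
    for k, name in enumerate(INPUT_SPECIES):
        conc[model.index_of(name)] = inputs[k]
    return conc


def _integrate_rk4(model: ODEModel, conc: np.ndarray, horizon: float, h: float) -> np.ndarray:
    """Classical fixed-step RK4 on the full concentration matrix.

    Columnwise independent arithmetic: integrating a batch gives bitwise
    the same result per column as integrating each column alone, which is
    what makes solver strategies and batched engine calls exactly
    interchangeable.
    """
    n_steps = int(round(horizon / h))
    if abs(n_steps * h - horizon) > 1e-9 * horizon:
        n_steps += 1
        h = horizon / n_steps
    for _ in range(n_steps):
        k1 = model.rhs(conc)
        k2 = model.rhs(conc + 0.5 * h * k1)
        k3 = model.rhs(conc + 0.5 * h * k2)
        k4 = model.rhs(conc + h * k3)
        conc = conc + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    return conc


def _integrate_adaptive(
    model: ODEModel, conc: np.ndarray, horizon: float, rtol: float, atol: float
) -> np.ndarray:
    from scipy.integrate import solve_ivp

    shape = conc.shape

    def fun(_t, y):
        return model.rhs(y.reshape(shape)).ravel()

    sol = solve_ivp(
        fun,
        (0.0, horizon),
        conc.ravel(),
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return sol.y[:, -1].reshape(shape)


def time_course_batch(
    model: ODEModel,
    inputs: np.ndarray,
    horizon: float | None = None,
    *,
    method: str = "rk4",
    h: float = 0.25,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> np.ndarray:
    """Terminal concentrations for a batch of input conditions.

    Parameters
    ----------
    inputs : array of shape ``(3, n)`` with rows (IL12, TGFb, IL6).

    Returns
    -------
    Full terminal concentration matrix, shape ``(n_species, n)``.
    """
    inputs = np.asarray(inputs, dtype=np.float64)
    if inputs.ndim != 2 or inputs.shape[0] != 3:
        raise ValueError("inputs must have shape (3, n)")
    if not np.isfinite(inputs).all() or (inputs < 0).any():
        raise ValueError("inputs must be finite and >= 0")
    T = model.horizon if horizon is None else float(horizon)
    if T <= 0:
        raise ValueError("horizon must be > 0")
    conc = _initial_state(model, inputs)
    if method == "rk4":
        return _integrate_rk4(model, conc, T, h)
    if method == "adaptive":
        try:
            return _integrate_adaptive(model, conc, T, rtol, atol)
        except RuntimeError as exc:
            raise RuntimeError(
                f"time course failed for inputs {inputs.T.tolist()}: {exc}"
            ) from exc
    raise ValueError(f"unknown integration method {method!r}")


def time_course(
    model: ODEModel,
    inputs: Sequence[float] | dict,
    horizon: float | None = None,
    **kw,
) -> dict[str, float]:
    """Terminal concentrations of all species for one input condition.

    ``inputs`` is either an (IL12, TGFb, IL6) triple or a mapping with
    those keys.
    """
    if isinstance(inputs, dict):
        vec = [float(inputs.get(n, 0.0)) for n in INPUT_SPECIES]
    else:
        vec = [float(v) for v in inputs]
        if len(vec) != 3:
            raise ValueError("inputs must be a triple (IL12, TGFb, IL6)")
    conc = time_course_batch(model, np.array(vec)[:, None], horizon, **kw)
    return {s.name: float(conc[i, 0]) for i, s in enumerate(model.species)}


def classify_outputs(
    outputs: Sequence[float], theta_out: float = 1e-3
) -> str:
    """Phenotype decision from terminal output cytokines (IFNg, IL17, IL10).

    Below-threshold outputs leave the cell naive; otherwise the largest
    output decides, ties broken by the fixed priority Th1 > Th17 > Treg.
    """
    vals = [float(v) for v in outputs]
    if len(vals) != 3:
        raise ValueError("outputs must be a triple (IFNg, IL17, IL10)")
    if any(v < 0 for v in vals):
        raise ValueError("outputs must be >= 0")
    if max(vals) <= theta_out:
        return "naive"
    best = max(range(3), key=lambda i: (vals[i], -i))
    return PHENOTYPE_PRIORITY[best]


# -- solver-instance management ----------------------------------------


@dataclass(frozen=True)
class SolverStrategy:
    """How ODE-solver instances are allocated to querying cells."""

    kind: str = "singleton"  # singleton | per_cell | pool
    pool_size: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("singleton", "per_cell", "pool"):
            raise ValueError(f"unknown solver strategy {self.kind!r}")
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")

    @classmethod
    def parse(cls, text: str) -> "SolverStrategy":
        """Parse ``singleton``, ``per_cell`` or ``pool:N``."""
        if text.startswith("pool:"):
            return cls("pool", int(text.split(":", 1)[1]))
        return cls(text)


class OdeSolver:
    """One solver instance holding a model and a resettable state."""

    def __init__(self, model: ODEModel, method: str = "rk4", h: float = 0.25) -> None:
        self.model = model
        self.method = method
        self.h = h
        self.n_solves = 0

    def reinitialize(self) -> None:
        """Reset internal state; inputs are set fresh on every solve."""
        # State is rebuilt from the cell's inputs inside solve(); nothing
        # persists between calls by design (strategy-invariance contract).

    def solve(self, inputs: np.ndarray) -> np.ndarray:
        self.n_solves += inputs.shape[1]
        return time_course_batch(self.model, inputs, method=self.method, h=self.h)


class OdeService:
    """Dispatches time-course queries through a solver-instance strategy.

    Tracks invocation counts and the peak number of live solver
    instances, the quantities compared across benchmark scenarios.
    A surrogate function ``(3, n) -> (n_species, n)`` may replace the
    integrator (hook for machine-learned stand-ins).
    """

    def __init__(
        self,
        model: ODEModel,
        strategy: SolverStrategy | str = "singleton",
        *,
        method: str = "rk4",
        h: float = 0.25,
        surrogate: Callable[[np.ndarray], np.ndarray] | None = None,
    ) -> None:
        if isinstance(strategy, str):
            strategy = SolverStrategy.parse(strategy)
        self.model = model
        self.strategy = strategy
        self.method = method
        self.h = h
        self.surrogate = surrogate
        self.calls = 0  # per-cell queries answered
        self._solvers: dict = {}
        self._pool: list[OdeSolver] = []
        self._rr = 0  # round-robin pool cursor
        if strategy.kind == "singleton":
            self._solvers["singleton"] = self._new_solver()
        elif strategy.kind == "pool":
            self._pool = [self._new_solver() for _ in range(strategy.pool_size)]

    def _new_solver(self) -> OdeSolver:
        return OdeSolver(self.model, self.method, self.h)

    @property
    def n_instances(self) -> int:
        return len(self._pool) if self.strategy.kind == "pool" else len(self._solvers)

    def _checkout(self, agent_id) -> OdeSolver:
        kind = self.strategy.kind
        if kind == "singleton":
            solver = self._solvers["singleton"]
            solver.reinitialize()  # shared instance: reset on every call
            return solver
        if kind == "per_cell":
            if agent_id not in self._solvers:
                self._solvers[agent_id] = self._new_solver()
            return self._solvers[agent_id]
        solver = self._pool[self._rr % len(self._pool)]
        self._rr += 1
        solver.reinitialize()
        return solver

    def query(self, inputs: Sequence[float], agent_id=None) -> tuple[float, float, float]:
        """Terminal (IFNg, IL17, IL10) for one cell's local cytokines."""
        arr = np.asarray(inputs, dtype=np.float64)[:, None]
        conc = self._solve(arr, [agent_id])
        return self._outputs(conc)[:, 0].tolist()

    def query_batch(self, inputs: np.ndarray, agent_ids: Sequence) -> np.ndarray:
        """Terminal outputs, shape (3, n), for a batch of cells.

        Exactly equivalent to ``n`` single queries: the integrator's
        arithmetic is columnwise independent, and each agent id is run
        through the strategy's instance accounting.
        """
        conc = self._solve(np.asarray(inputs, dtype=np.float64), agent_ids)
        return self._outputs(conc)

    def _solve(self, inputs: np.ndarray, agent_ids: Sequence) -> np.ndarray:
        n = inputs.shape[1]
        if len(agent_ids) != n:
            raise ValueError("one agent id per input column required")
        for aid in agent_ids:
            self._checkout(aid)  # instance accounting per querying cell
        self.calls += n
        if self.surrogate is not None:
            return self.surrogate(inputs)
        # Deduplicate identical input columns: columnwise-independent
        # arithmetic makes this bitwise-transparent.
        uniq, inverse = np.unique(inputs, axis=1, return_inverse=True)
        conc = time_course_batch(self.model, uniq, method=self.method, h=self.h)
        return conc[:, inverse]

    def _outputs(self, conc: np.ndarray) -> np.ndarray:
        rows = [self.model.index_of(n) for n in OUTPUT_SPECIES]
        return conc[rows]


def solve_for_cell(
    strategy: SolverStrategy | str,
    model: ODEModel,
    inputs: Sequence[float],
    service: OdeService | None = None,
    agent_id=None,
) -> tuple[float, float, float]:
    """One-shot dispatch of a time course through an instance strategy."""
    if service is None:
        service = OdeService(model, strategy)
    return tuple(service.query(inputs, agent_id=agent_id))
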