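"""Cell agents: movement, contact rules, cytokine-driven transitions.

Concrete rule sets exist for the three cell types of the gut-inflammation
study — bacteria (infectious/tolerogenic/dead), dendritic cells
(immature/effector/tolerogenic/dead) and CD4+ T cells
(naive/Th1/Th17/Treg/dead). Other mucosal cell types (epithelial cells,
macrophages, neutrophils, B cells) are supported through the generic
declarative :class:`TransitionRule` machinery but ship with no built-in
rules.

Movement is a bounded random walk: direction uniform on the circle,
speed uniform on ``[0, speed_max]`` cell sides per cycle, with optional
chemotaxis (the direction is a convex mix of a random unit vector and
the normalized local gradient of a named cytokine layer). Candidate
positions are reflected off impermeable compartment walls.

State transitions are stochastic: a triggered rule fires with its
configured probability. Dead agents never move, transition or secrete.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .spatial import GridSpace, ValueLayer

__all__ = [
    "CellAgent",
    "TransitionRule",
    "ALLOWED_STATES",
    "move",
    "dc_contact_update",
    "tcell_update",
    "apply_generic_rules",
]

ALLOWED_STATES = {
    "bacterium": {"infectious", "tolerogenic", "dead"},
    "dendritic_cell": {"immature", "effector", "tolerogenic", "dead"},
    "t_cell": {"naive", "Th1", "Th17", "Treg", "dead"},
}

#: Output cytokine deposited when a naive T cell commits to a phenotype.
TCELL_SECRETION = {"Th1": "IFNg", "Th17": "IL17", "Treg": "IL10"}


@dataclass
class CellAgent:
    """A typed cell with a state, a continuous position and motility."""

    id: int
    cell_type: str
    state: str
    x: float
    y: float
    compartment: str = "generic"
    speed_max: float = 1.0
    chemotaxis: tuple[str, float] | None = None  # (layer name, bias w in [0,1])
    alive: bool = True

    def __post_init__(self) -> None:
        allowed = ALLOWED_STATES.get(self.cell_type)
        if allowed is not None and self.state not in allowed:
            raise ValueError(
                f"{self.cell_type} state {self.state!r} not in {sorted(allowed)}"
            )
        if self.speed_max < 0:
            raise ValueError("speed_max must be >= 0")
        if self.chemotaxis is not None and not (0.0 <= self.chemotaxis[1] <= 1.0):
            raise ValueError("chemotaxis bias weight must be in [0, 1]")
        if self.state == "dead":
            self.alive = False

    def cell(self) -> tuple[int, int]:
        return int(math.floor(self.x)), int(math.floor(self.y))

    def kill(self) -> None:
        self.state = "dead"
        self.alive = False


@dataclass(frozen=True)
class TransitionRule:
    """A declarative stochastic state-transition rule.

    trigger kinds:
      ``("contact_with", type, state)``   — a co-located agent matches;
      ``("local_cytokine", layer, theta)``— local concentration > theta;
      ``("always",)``                     — unconditional (e.g. death rate);
      ``("ode_decision",)``               — delegated to the intracellular
                                            service (T cells only).
    ``secretions`` is a list of ``(layer, value, semantics)`` deposited at
    the agent's grid cell when the rule fires.
    """

    agent_type: str
    from_state: str
    trigger: tuple
    to_state: str
    probability: float = 1.0
    secretions: tuple = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.probability <= 1.0):
            raise ValueError("rule probability must be in [0, 1]")
        for _layer, value, _sem in self.secretions:
            if value < 0:
                raise ValueError("secretion values must be >= 0")


def _reflect(value: float, lo: float, hi: float) -> float:
    """Reflect a coordinate into the half-open interval [lo, hi)."""
    span = hi - lo
    if span <= 0:
        raise ValueError("empty interval")
    v = value
    # A few bounces suffice for |displacement| <= span; loop for safety.
    for _ in range(64):
        if lo <= v < hi:
            return v
        if v < lo:
            v = 2 * lo - v
        else:
            v = 2 * hi - v
            if v == hi:  # landed exactly on the open edge
                v = np.nextafter(hi, lo)
    return min(max(v, lo), np.nextafter(hi, lo))


def move(
    agent: CellAgent,
    space: GridSpace,
    rng: np.random.Generator,
    layers: Mapping[str, ValueLayer] | None = None,
) -> CellAgent:
    """Advance one agent by one Brownian (optionally chemotactic) step.

    Draws direction ~ Uniform[0, 2pi) and speed ~ Uniform[0, speed_max];
    the candidate position is reflected off the walls of the agent's
    compartment (or the grid, if the compartment is permeable for this
    agent). Mutates and returns the agent.
    """
    if not agent.alive:
        return agent
    theta = rng.uniform(0.0, 2.0 * math.pi)
    speed = rng.uniform(0.0, agent.speed_max)
    dx, dy = math.cos(theta), math.sin(theta)
    if agent.chemotaxis is not None and layers is not None:
        layer_name, w = agent.chemotaxis
        if layer_name in layers:
            gx, gy = layers[layer_name].gradient_at(agent.cell())
            norm = math.hypot(gx, gy)
            if norm > 0:
                dx = (1.0 - w) * dx + w * gx / norm
                dy = (1.0 - w) * dy + w * gy / norm
                n = math.hypot(dx, dy)
                if n > 0:
                    dx, dy = dx / n, dy / n
    cx, cy = agent.x + speed * dx, agent.y + speed * dy

    comp = space.compartment_of(agent.x, agent.y)
    crossed = space.in_bounds(cx, cy) and not comp.contains(cx, cy)
    if crossed and comp.may_cross(agent.cell_type, agent.state):
        agent.compartment = space.compartment_of(cx, cy).name
        agent.x, agent.y = cx, cy
    else:
        agent.x = _reflect(cx, comp.x0, comp.x1)
        agent.y = _reflect(cy, comp.y0, comp.y1)
    return agent


def dc_contact_update(
    dc: CellAgent,
    cohabitants: Sequence[CellAgent],
    layers: Mapping[str, ValueLayer],
    rng: np.random.Generator,
    *,
    deposit_value: float = 70.0,
    semantics: str = "set",
    probability: float = 1.0,
    tie_break: str = "effector",
) -> list[tuple[str, tuple[int, int], float, str]]:
    """Contact-driven dendritic cell maturation.

    An immature DC co-located with an infectious bacterium becomes an
    effector DC and releases IL-6 and IL-12 (concentration 70, relative
    units, written into its grid cell); co-located with a tolerogenic
    bacterium it becomes tolerogenic and releases TGF-beta. When both
    bacterial subtypes co-occur the ``tie_break`` side wins (inflammation
    dominant by default). Returns the list of layer deposits
    ``(layer, cell, value, semantics)``; the caller applies them (the
    engine buffers them to the end of the update phase).
    """
    if dc.cell_type != "dendritic_cell" or dc.state != "immature" or not dc.alive:
        return []
    infectious = any(
        a.alive and a.cell_type == "bacterium" and a.state == "infectious"
        for a in cohabitants
    )
    tolerogenic = any(
        a.alive and a.cell_type == "bacterium" and a.state == "tolerogenic"
        for a in cohabitants
    )
    if not (infectious or tolerogenic):
        return []
    if probability < 1.0 and rng.random() >= probability:
        return []
    if infectious and tolerogenic:
        infectious = tie_break == "effector"
        tolerogenic = not infectious
    cell = dc.cell()
    if infectious:
        dc.state = "effector"
        return [
            ("IL6", cell, deposit_value, semantics),
            ("IL12", cell, deposit_value, semantics),
        ]
    dc.state = "tolerogenic"
    return [("TGFb", cell, deposit_value, semantics)]


def dc_secrete(
    dc: CellAgent,
    *,
    deposit_value: float = 70.0,
    semantics: str = "set",
) -> list[tuple[str, tuple[int, int], float, str]]:
    """Per-cycle cytokine release of an already-matured dendritic cell.

    Effector DCs keep releasing IL-6/IL-12 and tolerogenic DCs TGF-beta
    at their current grid cell while alive, sustaining the local gradients.
    """
    if dc.cell_type != "dendritic_cell" or not dc.alive:
        return []
    cell = dc.cell()
    if dc.state == "effector":
        return [
            ("IL6", cell, deposit_value, semantics),
            ("IL12", cell, deposit_value, semantics),
        ]
    if dc.state == "tolerogenic":
        return [("TGFb", cell, deposit_value, semantics)]
    return []


def tcell_update(
    t: CellAgent,
    local_concentrations: Mapping[str, float],
    ode_service,
    *,
    semantics: str = "set",
) -> list[tuple[str, tuple[int, int], float, str]]:
    """Cytokine-driven differentiation of one naive CD4+ T cell.

    Sends the local (IL-12, TGF-beta, IL-6) concentrations to the
    intracellular service, classifies the returned (IFNg, IL-17, IL-10)
    outputs, and on commitment deposits the phenotype's signature
    cytokine at the cell's grid position (value = the ODE-predicted
    output concentration). Differentiation is irreversible. Returns the
    deposits for the caller to apply.
    """
    if t.cell_type != "t_cell" or t.state != "naive" or not t.alive:
        return []
    inputs = [
        float(local_concentrations.get("IL12", 0.0)),
        float(local_concentrations.get("TGFb", 0.0)),
        float(local_concentrations.get("IL6", 0.0)),
    ]
    outputs = ode_service.query(inputs, agent_id=t.id)
    from .intracellular import classify_outputs

    phenotype = classify_outputs(outputs, ode_service.model.params.theta_out)
    if phenotype == "naive":
        return []
    t.state = phenotype
    layer = TCELL_SECRETION[phenotype]
    value = dict(zip(("IFNg", "IL17", "IL10"), outputs))[layer]
    return [(layer, t.cell(), float(value), semantics)]


def apply_generic_rules(
    agent: CellAgent,
    rules: Sequence[TransitionRule],
    cohabitants: Sequence[CellAgent],
    layers: Mapping[str, ValueLayer],
    rng: np.random.Generator,
) -> list[tuple[str, tuple[int, int], float, str]]:
    """Evaluate declarative transition rules for one agent.

    Rules are checked in configured order; the first rule whose trigger
    holds gets a chance to fire (with its probability). Returns the
    fired rule's secretions as deposits.
    """
    if not agent.alive:
        return []
    for rule in rules:
        if rule.agent_type != agent.cell_type or rule.from_state != agent.state:
            continue
        kind = rule.trigger[0]
        if kind == "contact_with":
            _, ctype, cstate = rule.trigger
            hit = any(
                a.alive and a.cell_type == ctype and a.state == cstate
                for a in cohabitants
            )
        elif kind == "local_cytokine":
            _, layer_name, theta = rule.trigger
            if layer_name not in layers:
                raise KeyError(f"rule references unknown layer {layer_name!r}")
            hit = layers[layer_name].value_at(agent.cell()) > theta
        elif kind == "always":
            hit = True
        else:
            raise ValueError(f"trigger {kind!r} not handled by generic rules")
        if not hit:
            continue
        if rule.probability < 1.0 and rng.random() >= rule.probability:
            return []  # triggered but did not fire; no further rules
        agent.state = rule.to_state
        if rule.to_state == "dead":
            agent.alive = False
        cell = agent.cell()
        return [(layer, cell, value, sem) for layer, value, sem in rule.secretions]
    return []
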