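"""Outputs: per-cycle population counts, layer dumps, snapshots, benchmarks.

All tabular outputs are tab-separated text with deterministic row order,
so a (config, seed) pair reproduces every artifact byte for byte.
Snapshots are headless PNG renderings: three cytokine layers map to the
three primary color channels of the background (each normalized by its
running maximum) and agents are drawn as colored glyph blocks, dead
cells always black.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from . import engine as eng
from .spatial import dump_layer

__all__ = [
    "CycleReport",
    "ReportCollector",
    "SnapshotSpec",
    "write_counts_tsv",
    "read_counts_tsv",
    "render_snapshot",
    "run_benchmark",
    "write_benchmark_tsv",
]


@dataclass(frozen=True)
class CycleReport:
    """Population counts and bookkeeping for one completed cycle."""

    cycle: int
    counts: Mapping[tuple[str, str], int]
    layer_stats: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    ode_calls: int = 0
    intracellular_executions: int = 0

    @property
    def total_agents(self) -> int:
        return sum(self.counts.values())


class ReportCollector:
    """Engine reporter accumulating one :class:`CycleReport` per cycle."""

    def __init__(self, with_layer_stats: bool = True) -> None:
        self.reports: list[CycleReport] = []
        self.with_layer_stats = with_layer_stats

    def __call__(self, state: "eng.SimulationState") -> None:
        stats = {}
        if self.with_layer_stats:
            stats = {
                name: (layer.total(), float(layer.values.max()))
                for name, layer in state.layers.items()
            }
        self.reports.append(
            CycleReport(
                cycle=state.cycle,
                counts=dict(state.counts()),
                layer_stats=stats,
                ode_calls=state.metrics.ode_calls,
                intracellular_executions=state.metrics.executions["intracellular"],
            )
        )


def write_counts_tsv(reports: Sequence[CycleReport], path) -> None:
    """Serialize per-cycle (type, state) counts.

    Columns: cycle, type, state, count. A (type, state) pair appears for
    every cycle once its population has ever been nonzero, so count
    trajectories are rectangular and plottable directly. Rows are sorted
    by (cycle, type, state).
    """
    if not reports:
        raise ValueError("no reports to write")
    seen = sorted({key for r in reports for key, n in r.counts.items() if n})
    with open(path, "w") as fh:
        fh.write("cycle\ttype\tstate\tcount\n")
        for r in sorted(reports, key=lambda r: r.cycle):
            for ctype, cstate in seen:
                fh.write(
                    f"{r.cycle}\t{ctype}\t{cstate}\t{r.counts.get((ctype, cstate), 0)}\n"
                )


def read_counts_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    expected = ["cycle", "type", "state", "count"]
    if list(df.columns) != expected:
        raise ValueError(f"counts TSV must have columns {expected}")
    return df


def write_layer_dumps(state: "eng.SimulationState", path) -> None:
    """Append dense matrix dumps of every layer at the current cycle."""
    with open(path, "a") as fh:
        for name in sorted(state.layers):
            fh.write(dump_layer(state.layers[name], state.cycle))


@dataclass(frozen=True)
class SnapshotSpec:
    """How a simulation state is rendered to pixels.

    ``channel_map`` assigns exactly three layer names to the red, green
    and blue background channels. The default follows the study's
    phenotype palette: IFN-gamma (Th1) red, IL-10 (Treg) green and IL-17
    (Th17) blue; regions where IFN-gamma and IL-17 co-occur render
    purple. ``state_colors`` maps (type, state) to glyph RGB; dead cells
    are always black regardless of type.
    """

    channel_map: tuple[str, str, str] = ("IFNg", "IL10", "IL17")
    state_colors: Mapping[tuple[str, str], tuple[int, int, int]] = field(
        default_factory=lambda: {
            ("bacterium", "infectious"): (255, 140, 0),
            ("bacterium", "tolerogenic"): (160, 255, 160),
            ("dendritic_cell", "immature"): (200, 200, 200),
            ("dendritic_cell", "effector"): (255, 0, 255),
            ("dendritic_cell", "tolerogenic"): (0, 200, 200),
            ("t_cell", "naive"): (255, 255, 255),
            ("t_cell", "Th1"): (255, 0, 0),
            ("t_cell", "Th17"): (128, 0, 255),
            ("t_cell", "Treg"): (0, 0, 255),
        }
    )
    scale: int = 4  # pixels per grid cell

    def __post_init__(self) -> None:
        if len(self.channel_map) != 3:
            raise ValueError("exactly three layers map to color channels")
        if self.scale < 1:
            raise ValueError("scale must be >= 1")
        colors = list(self.state_colors.values())
        if len(set(colors)) != len(colors):
            raise ValueError("glyph colors must be distinct per state")


def render_snapshot(state: "eng.SimulationState", spec: SnapshotSpec, path) -> None:
    """Render the state to a PNG file.

    Background: each mapped layer, normalized by its own running maximum
    (zero if the layer is empty), fills one primary channel per grid
    cell, expanded to ``scale x scale`` pixel blocks. Agents: a glyph
    block at each agent's grid cell in its state color; dead agents
    black.
    """
    h, w, s = state.space.height, state.space.width, spec.scale
    img = np.zeros((h, w, 3), dtype=np.float64)
    for ch, name in enumerate(spec.channel_map):
        if name not in state.layers:
            raise KeyError(f"snapshot references unknown layer {name!r}")
        v = state.layers[name].values
        vmax = v.max()
        if vmax > 0:
            img[:, :, ch] = v / vmax
    rgb = (np.clip(img, 0.0, 1.0) * 255).astype(np.uint8)
    rgb = np.kron(rgb, np.ones((s, s, 1), dtype=np.uint8))
    for a in state.agents:
        cx, cy = a.cell()
        color = (0, 0, 0) if not a.alive else spec.state_colors.get(
            (a.cell_type, a.state), (255, 255, 0)
        )
        rgb[cy * s : (cy + 1) * s, cx * s : (cx + 1) * s] = color
    Image.fromarray(rgb, mode="RGB").save(path, format="PNG")


# -- benchmark harness -------------------------------------------------


def run_benchmark(
    presets: Sequence[str] = eng.PRESET_NAMES,
    cycles: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the benchmark scenarios and tabulate their cost structure.

    One row per scenario with columns: ``init_cost`` and ``cycle_cost``
    (measured, arbitrary time units — absolute values are
    hardware-dependent), ``est_cycle_cost`` (the sum_i f_si*c_si
    estimate), ``peak_solver_instances``, ``ode_calls``,
    ``intracellular_executions``, and final phenotype counts. Structural
    relations (instance counts, execution ratios) are the reproducible
    quantities; wall-clock columns are not.
    """
    rows = []
    for name in presets:
        cfg = eng.preset(name, cycles=cycles, seed=seed)
        collector = ReportCollector(with_layer_stats=False)
        t0 = time.perf_counter()
        state = eng.run(cfg, reporters=[collector])
        wall = time.perf_counter() - t0
        m = state.metrics
        counts = state.counts()
        rows.append(
            {
                "scenario": name,
                "init_cost": m.init_cost,
                "cycle_cost": wall - m.init_cost,
                "est_cycle_cost": eng.estimate_cycle_cost(m, cfg.frequencies),
                "peak_solver_instances": m.peak_solver_instances,
                "ode_calls": m.ode_calls,
                "intracellular_executions": m.executions["intracellular"],
                "naive": counts.get(("t_cell", "naive"), 0),
                "Th1": counts.get(("t_cell", "Th1"), 0),
                "Th17": counts.get(("t_cell", "Th17"), 0),
                "Treg": counts.get(("t_cell", "Treg"), 0),
            }
        )
    return pd.DataFrame(rows)


def write_benchmark_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")
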