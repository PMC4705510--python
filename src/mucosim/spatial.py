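"""Tissue space and cytokine value layers.

The tissue is a 2-D grid of unit cells. Agents live at continuous
positions inside the half-open box ``[0, width) x [0, height)``; the grid
cell of a position is the floor of its coordinates. Tissue compartments
(lumen, epithelium, lamina propria, lymph node, blood) are axis-aligned
rectangles that partition the grid.

Each cytokine or chemokine is a :class:`ValueLayer`: a per-grid-cell
scalar concentration field evolved once per simulation cycle by a
discrete diffusion-evaporation rule

    v_n = ce * [ v_{n-1} + cd * sum_neighbors (v_{n-1,neighbor} - v_{n-1}) ]

where ``ce`` is the evaporation (retention) constant and ``cd`` the
diffusion constant. In ``normalized`` mode (the default) ``cd`` is divided
by the neighborhood size, which makes every new value a convex combination
of old values scaled by ``ce`` and therefore unconditionally stable; ``raw``
mode applies the update literally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

__all__ = [
    "Compartment",
    "GridSpace",
    "ValueLayer",
    "diffuse_step",
    "gradient_at",
    "deposit",
]

COMPARTMENT_NAMES = {
    "lumen",
    "epithelium",
    "lamina_propria",
    "lymph_node",
    "blood",
    "generic",
}


@dataclass
class Compartment:
    """An axis-aligned rectangular tissue region.

    Bounds are continuous and half-open: a position ``(x, y)`` belongs to
    the compartment iff ``x0 <= x < x1`` and ``y0 <= y < y1``.
    ``permeability`` maps an agent type (or ``(type, state)`` pair) to a
    boolean saying whether such agents may cross out of the compartment;
    agents are contained by default.
    """

    name: str
    x0: float
    x1: float
    y0: float
    y1: float
    permeability: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in COMPARTMENT_NAMES:
            raise ValueError(
                f"unknown compartment name {self.name!r}; "
                f"expected one of {sorted(COMPARTMENT_NAMES)}"
            )
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise ValueError("compartment region must have positive extent")

    def contains(self, x: float, y: float) -> bool:
        return self.x0 <= x < self.x1 and self.y0 <= y < self.y1

    def may_cross(self, cell_type: str, state: str) -> bool:
        if (cell_type, state) in self.permeability:
            return bool(self.permeability[(cell_type, state)])
        return bool(self.permeability.get(cell_type, False))


@dataclass
class GridSpace:
    """The 2-D simulation arena: a grid of unit cells plus compartments."""

    width: int
    height: int
    cell_side: float = 1.0
    compartments: list[Compartment] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("grid must be at least 1x1")
        if not self.compartments:
            self.compartments = [
                Compartment("generic", 0.0, float(self.width), 0.0, float(self.height))
            ]
        self._validate_partition()

    def _validate_partition(self) -> None:
        for c in self.compartments:
            if c.x0 < 0 or c.y0 < 0 or c.x1 > self.width or c.y1 > self.height:
                raise ValueError(f"compartment {c.name!r} exceeds grid bounds")
        for i, a in enumerate(self.compartments):
            for b in self.compartments[i + 1 :]:
                if a.x0 < b.x1 and b.x0 < a.x1 and a.y0 < b.y1 and b.y0 < a.y1:
                    raise ValueError(
                        f"compartments {a.name!r} and {b.name!r} overlap"
                    )
        area = sum((c.x1 - c.x0) * (c.y1 - c.y0) for c in self.compartments)
        if not np.isclose(area, self.width * self.height):
            raise ValueError("compartments must partition the grid (area mismatch)")

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """Grid cell of a continuous position (floor of coordinates)."""
        if not (0 <= x < self.width and 0 <= y < self.height):
            raise ValueError(f"position ({x}, {y}) outside grid")
        return int(np.floor(x)), int(np.floor(y))

    def compartment_of(self, x: float, y: float) -> Compartment:
        for c in self.compartments:
            if c.contains(x, y):
                return c
        raise ValueError(f"position ({x}, {y}) not in any compartment")

    def in_bounds(self, x: float, y: float) -> bool:
        return 0 <= x < self.width and 0 <= y < self.height


class ValueLayer:
    """A per-cytokine concentration field on the grid.

    Values are stored as a ``(height, width)`` float64 array indexed
    ``values[y, x]``; the public API addresses cells as ``(x, y)`` tuples.

    Parameters
    ----------
    name : cytokine identifier, e.g. ``"IL-12"``.
    width, height : grid dimensions in cells.
    ce : evaporation constant in [0, 1]; per-step retention factor.
    cd : diffusion constant in [0, 1]; weight on the neighbor-difference sum.
    neighborhood : ``"von_neumann"`` (4 neighbors, default) or ``"moore"`` (8).
    boundary : ``"zero_flux"`` (default; out-of-bounds neighbors mirror the
        center so they contribute nothing to the difference sum) or
        ``"torus"`` (wrap-around indices).
    mode : ``"normalized"`` (default; cd is divided by the neighborhood
        size, guaranteeing stability) or ``"raw"`` (literal update rule).
    clamp_nonnegative : clip negative post-update values to zero.
    """

    NEIGHBORHOOD_SIZES = {"von_neumann": 4, "moore": 8}

    def __init__(
        self,
        name: str,
        width: int,
        height: int,
        *,
        ce: float = 0.98,
        cd: float = 0.6,
        neighborhood: str = "von_neumann",
        boundary: str = "zero_flux",
        mode: str = "normalized",
        clamp_nonnegative: bool = True,
        values: np.ndarray | None = None,
    ) -> None:
        if not (0.0 <= ce <= 1.0):
            raise ValueError(f"ce must be in [0, 1], got {ce}")
        if not (0.0 <= cd <= 1.0):
            raise ValueError(f"cd must be in [0, 1], got {cd}")
        if neighborhood not in self.NEIGHBORHOOD_SIZES:
            raise ValueError(f"unknown neighborhood {neighborhood!r}")
        if boundary not in ("zero_flux", "torus"):
            raise ValueError(f"unknown boundary mode {boundary!r}")
        if mode not in ("normalized", "raw"):
            raise ValueError(f"unknown mode {mode!r}")
        self.name = name
        self.width = int(width)
        self.height = int(height)
        self.ce = float(ce)
        self.cd = float(cd)
        self.neighborhood = neighborhood
        self.boundary = boundary
        self.mode = mode
        self.clamp_nonnegative = bool(clamp_nonnegative)
        if values is None:
            self.values = np.zeros((self.height, self.width), dtype=np.float64)
        else:
            values = np.asarray(values, dtype=np.float64)
            if values.shape != (self.height, self.width):
                raise ValueError(
                    f"values shape {values.shape} != (height, width) "
                    f"({self.height}, {self.width})"
                )
            self.values = values.copy()

    # -- helpers -------------------------------------------------------

    def copy(self) -> "ValueLayer":
        return ValueLayer(
            self.name,
            self.width,
            self.height,
            ce=self.ce,
            cd=self.cd,
            neighborhood=self.neighborhood,
            boundary=self.boundary,
            mode=self.mode,
            clamp_nonnegative=self.clamp_nonnegative,
            values=self.values,
        )

    def total(self) -> float:
        return float(self.values.sum())

    def value_at(self, cell: tuple[int, int]) -> float:
        x, y = cell
        self._check_cell(x, y)
        return float(self.values[y, x])

    def _check_cell(self, x: int, y: int) -> None:
        if not (0 <= x < self.width and 0 <= y < self.height):
            raise ValueError(
                f"cell ({x}, {y}) outside layer {self.name!r} "
                f"({self.width}x{self.height})"
            )

    def _neighbor_offsets(self) -> list[tuple[int, int]]:
        if self.neighborhood == "von_neumann":
            return [(1, 0), (-1, 0), (0, 1), (0, -1)]
        return [
            (dx, dy)
            for dx in (-1, 0, 1)
            for dy in (-1, 0, 1)
            if (dx, dy) != (0, 0)
        ]

    def _neighbor_sum(self, v: np.ndarray) -> np.ndarray:
        """Sum of neighbor values per cell under the layer's boundary mode.

        Under zero_flux the out-of-bounds neighbor mirrors the center
        (edge replication), so its difference term vanishes.
        """
        offsets = self._neighbor_offsets()
        if self.boundary == "torus":
            padded = np.pad(v, 1, mode="wrap")
            s = np.zeros_like(v)
            for dx, dy in offsets:
                s += padded[1 + dy : 1 + dy + v.shape[0], 1 + dx : 1 + dx + v.shape[1]]
            return s
        # zero_flux: out-of-bounds neighbors mirror the center value, so
        # S = sum(in-bounds neighbors) + (missing count) * center.
        padded = np.pad(v, 1, mode="constant")
        ones = np.pad(np.ones_like(v), 1, mode="constant")
        s = np.zeros_like(v)
        count = np.zeros_like(v)
        for dx, dy in offsets:
            sl = (slice(1 + dy, 1 + dy + v.shape[0]), slice(1 + dx, 1 + dx + v.shape[1]))
            s += padded[sl]
            count += ones[sl]
        return s + (len(offsets) - count) * v

    # -- core operations -----------------------------------------------

    def diffuse(self) -> None:
        """One synchronous diffusion-evaporation step, in place.

        All new values are computed from the previous step's field
        (double-buffered update).
        """
        v = self.values
        if not np.isfinite(v).all():
            raise ValueError(
                f"layer {self.name!r} contains non-finite values; state corrupted"
            )
        k = self.NEIGHBORHOOD_SIZES[self.neighborhood]
        cd = self.cd / k if self.mode == "normalized" else self.cd
        new = self.ce * (v + cd * (self._neighbor_sum(v) - k * v))
        if self.clamp_nonnegative:
            np.maximum(new, 0.0, out=new)
        self.values = new

    def gradient_at(self, cell: tuple[int, int]) -> tuple[float, float]:
        """Central-difference gradient of the field at a grid cell.

        Out-of-bounds samples follow the layer's boundary mode (wrap for
        torus, edge replication for zero_flux).
        """
        x, y = cell
        self._check_cell(x, y)
        v = self.values
        if self.boundary == "torus":
            xm, xp = (x - 1) % self.width, (x + 1) % self.width
            ym, yp = (y - 1) % self.height, (y + 1) % self.height
        else:
            xm, xp = max(x - 1, 0), min(x + 1, self.width - 1)
            ym, yp = max(y - 1, 0), min(y + 1, self.height - 1)
        gx = (v[y, xp] - v[y, xm]) / 2.0
        gy = (v[yp, x] - v[ym, x]) / 2.0
        return float(gx), float(gy)

    def deposit(
        self, cell: tuple[int, int], value: float, semantics: str = "set"
    ) -> None:
        """Write a concentration into one grid cell.

        ``set`` overwrites, ``add`` increments, ``set_max`` keeps the
        maximum of the current and deposited value.
        """
        x, y = cell
        self._check_cell(x, y)
        if value < 0:
            raise ValueError(f"deposit value must be >= 0, got {value}")
        if semantics == "set":
            self.values[y, x] = value
        elif semantics == "add":
            self.values[y, x] += value
        elif semantics == "set_max":
            self.values[y, x] = max(self.values[y, x], value)
        else:
            raise ValueError(f"unknown deposit semantics {semantics!r}")


# -- functional wrappers (pure; return a new layer) ---------------------


def diffuse_step(layer: ValueLayer) -> ValueLayer:
    """Return a new layer advanced by one diffusion-evaporation step."""
    out = layer.copy()
    out.diffuse()
    return out


def gradient_at(layer: ValueLayer, cell: tuple[int, int]) -> tuple[float, float]:
    return layer.gradient_at(cell)


def deposit(
    layer: ValueLayer, cell: tuple[int, int], value: float, semantics: str = "set"
) -> ValueLayer:
    out = layer.copy()
    out.deposit(cell, value, semantics)
    return out


def dump_layer(layer: ValueLayer, cycle: int) -> str:
    """Dense TSV dump of a layer: header line then row-major matrix."""
    lines = [f"# layer={layer.name} cycle={cycle}"]
    for row in layer.values:
        lines.append("\t".join(format(v, ".17g") for v in row))
    return "\n".join(lines) + "\n"
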