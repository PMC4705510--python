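"""Value-layer diffusion, gradients, deposits and the grid space."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mucosim.spatial import Compartment, GridSpace, ValueLayer, diffuse_step


def oracle_diffuse(values, ce, cd, neighborhood, boundary, mode, clamp):
    """Independent per-cell double-loop implementation of the update rule.

    v_n = ce * [v + cd' * sum(neighbor - v)] with cd' = cd/|N| in
    normalized mode; zero-flux boundaries mirror the center value.
    """
    h, w = values.shape
    if neighborhood == "von_neumann":
        offsets = [(1, 0), (-1, 0), (0, 1), (0, -1)]
    else:
        offsets = [(dx, dy) for dx in (-1, 0, 1) for dy in (-1, 0, 1) if (dx, dy) != (0, 0)]
    cdn = cd / len(offsets) if mode == "normalized" else cd
    out = np.empty_like(values)
    for y in range(h):
        for x in range(w):
            acc = 0.0
            for dx, dy in offsets:
                nx, ny = x + dx, y + dy
                if boundary == "torus":
                    nv = values[ny % h, nx % w]
                elif 0 <= nx < w and 0 <= ny < h:
                    nv = values[ny, nx]
                else:
                    nv = values[y, x]  # mirrored: zero difference
                acc += nv - values[y, x]
            v = ce * (values[y, x] + cdn * acc)
            out[y, x] = max(v, 0.0) if clamp else v
    return out


def make_layer(values, **kw):
    values = np.asarray(values, dtype=float)
    h, w = values.shape
    return ValueLayer("test", w, h, values=values, **kw)


class TestDiffusion:
    @pytest.mark.parametrize("mode", ["normalized", "raw"])
    @pytest.mark.parametrize("neighborhood", ["von_neumann", "moore"])
    def test_uniform_field_fixed_point_without_evaporation(self, mode, neighborhood):
        layer = make_layer(np.full((6, 7), 10.0), ce=1.0, cd=0.5,
                           mode=mode, neighborhood=neighborhood)
        layer.diffuse()
        np.testing.assert_allclose(layer.values, 10.0, rtol=1e-14)

    def test_uniform_field_scales_by_evaporation_constant(self):
        layer = make_layer(np.full((5, 5), 10.0), ce=0.98, cd=0.6)
        layer.diffuse()
        np.testing.assert_allclose(layer.values, 9.8, rtol=1e-14)

    def test_point_source_matches_oracle_everywhere(self):
        values = np.zeros((5, 5))
        values[2, 2] = 70.0
        layer = make_layer(values, ce=0.98, cd=0.6, neighborhood="von_neumann",
                           mode="normalized", boundary="torus")
        expected = oracle_diffuse(values, 0.98, 0.6, "von_neumann", "torus",
                                  "normalized", True)
        layer.diffuse()
        np.testing.assert_allclose(layer.values, expected, atol=1e-12)
        # spot-check center and 4-neighborhood against hand-computable values
        assert layer.values[2, 2] == pytest.approx(0.98 * 70 * (1 - 0.6), abs=1e-12)
        assert layer.values[2, 3] == pytest.approx(0.98 * 0.15 * 70, abs=1e-12)

    @pytest.mark.parametrize("neighborhood", ["von_neumann", "moore"])
    @pytest.mark.parametrize("mode", ["normalized", "raw"])
    def test_oracle_agreement_on_random_fields(self, neighborhood, mode):
        """>=100 random 10x10 fields agree with the per-cell loop to 1e-12."""
        rng = np.random.default_rng(7)
        for case in range(30):
            values = rng.uniform(0, 100, size=(10, 10))
            boundary = "torus" if case % 2 else "zero_flux"
            layer = make_layer(values, ce=0.98, cd=0.6, neighborhood=neighborhood,
                               mode=mode, boundary=boundary, clamp_nonnegative=False)
            expected = oracle_diffuse(values, 0.98, 0.6, neighborhood, boundary,
                                      mode, False)
            layer.diffuse()
            np.testing.assert_allclose(layer.values, expected, atol=1e-12)

    @given(
        ce=st.floats(0.0, 1.0),
        cd=st.floats(0.0, 1.0),
        seed=st.integers(0, 2**31 - 1),
        neighborhood=st.sampled_from(["von_neumann", "moore"]),
        mode=st.sampled_from(["normalized", "raw"]),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_torus_mass_scaling(self, ce, cd, seed, neighborhood, mode):
        """On a torus the neighbor differences cancel pairwise, so total
        mass scales exactly by the evaporation constant."""
        values = np.random.default_rng(seed).uniform(0, 50, size=(8, 8))
        layer = make_layer(values, ce=ce, cd=cd, neighborhood=neighborhood,
                           mode=mode, boundary="torus", clamp_nonnegative=False)
        before = layer.total()
        layer.diffuse()
        assert layer.total() == pytest.approx(ce * before, rel=1e-9, abs=1e-9)

    def test_normalized_mode_preserves_nonnegativity_without_clamping(self):
        rng = np.random.default_rng(11)
        values = rng.uniform(0, 100, size=(10, 10))
        values[3, 4] = 1e4  # sharp peak
        layer = make_layer(values, ce=0.98, cd=1.0, mode="normalized",
                           clamp_nonnegative=False)
        for _ in range(5):
            layer.diffuse()
        assert (layer.values >= 0).all()

    def test_raw_mode_point_source_goes_negative_then_clamps(self):
        values = np.zeros((5, 5))
        values[2, 2] = 70.0
        unclamped = make_layer(values, ce=0.98, cd=0.6, mode="raw",
                               clamp_nonnegative=False, boundary="torus")
        unclamped.diffuse()
        assert unclamped.values.min() < 0  # cd=0.6 with 4 neighbors overshoots
        clamped = make_layer(values, ce=0.98, cd=0.6, mode="raw",
                             clamp_nonnegative=True, boundary="torus")
        clamped.diffuse()
        assert clamped.values.min() == 0.0

    def test_zero_flux_conserves_mass_up_to_evaporation(self):
        rng = np.random.default_rng(3)
        values = rng.uniform(0, 10, size=(6, 6))
        layer = make_layer(values, ce=0.98, cd=0.6, boundary="zero_flux",
                           clamp_nonnegative=False)
        before = layer.total()
        layer.diffuse()
        assert layer.total() == pytest.approx(0.98 * before, rel=1e-9)

    def test_functional_wrapper_leaves_input_untouched(self):
        values = np.zeros((4, 4))
        values[1, 1] = 5.0
        layer = make_layer(values)
        out = diffuse_step(layer)
        np.testing.assert_array_equal(layer.values, values)
        assert out.values[1, 1] != 5.0

    def test_non_finite_values_rejected(self):
        layer = make_layer(np.zeros((3, 3)))
        layer.values[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            layer.diffuse()

    def test_invalid_constants_rejected(self):
        with pytest.raises(ValueError):
            ValueLayer("x", 3, 3, ce=1.5)
        with pytest.raises(ValueError):
            ValueLayer("x", 3, 3, cd=-0.1)


class TestGradient:
    def test_flat_field_has_zero_gradient(self):
        layer = make_layer(np.full((5, 5), 3.0))
        assert layer.gradient_at((2, 2)) == (0.0, 0.0)

    def test_linear_ramp_gradient_points_uphill(self):
        values = np.tile(np.arange(8, dtype=float), (8, 1))  # v(x,y) = x
        layer = make_layer(values, boundary="torus")
        gx, gy = layer.gradient_at((3, 4))
        assert gx > 0 and gy == 0.0

    def test_gradient_at_neighbor_points_toward_peak(self):
        values = np.zeros((7, 7))
        values[3, 3] = 50.0
        layer = make_layer(values)
        gx, gy = layer.gradient_at((2, 3))  # west neighbor of the peak
        assert gx > 0 and gy == 0.0
        gx, gy = layer.gradient_at((3, 4))  # south neighbor (y+1)
        assert gy < 0 and gx == 0.0

    def test_out_of_bounds_cell_rejected(self):
        layer = make_layer(np.zeros((4, 4)))
        with pytest.raises(ValueError):
            layer.gradient_at((4, 0))


class TestDeposit:
    def test_set_writes_only_target_cell(self):
        layer = make_layer(np.zeros((7, 7)))
        layer.deposit((3, 3), 70.0, "set")
        assert layer.value_at((3, 3)) == 70.0
        assert layer.total() == 70.0

    def test_set_is_idempotent(self):
        layer = make_layer(np.zeros((5, 5)))
        layer.deposit((1, 2), 70.0, "set")
        layer.deposit((1, 2), 70.0, "set")
        assert layer.value_at((1, 2)) == 70.0

    def test_add_zero_is_identity(self):
        layer = make_layer(np.arange(9.0).reshape(3, 3))
        before = layer.values.copy()
        layer.deposit((1, 1), 0.0, "add")
        np.testing.assert_array_equal(layer.values, before)

    def test_set_max_keeps_maximum_either_order(self):
        for first, second in [(50.0, 70.0), (70.0, 50.0)]:
            layer = make_layer(np.zeros((3, 3)))
            layer.deposit((0, 0), first, "set_max")
            layer.deposit((0, 0), second, "set_max")
            assert layer.value_at((0, 0)) == 70.0

    def test_negative_value_rejected(self):
        layer = make_layer(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            layer.deposit((0, 0), -1.0)


class TestGridSpace:
    def test_position_maps_to_floor_cell(self):
        space = GridSpace(10, 10)
        assert space.cell_of(3.7, 9.01) == (3, 9)
        assert space.cell_of(0.0, 0.0) == (0, 0)

    def test_default_single_compartment_covers_grid(self):
        space = GridSpace(5, 8)
        assert len(space.compartments) == 1
        assert space.compartment_of(4.9, 7.9).name == "generic"

    def test_compartments_must_partition(self):
        with pytest.raises(ValueError, match="area mismatch"):
            GridSpace(10, 10, compartments=[Compartment("lumen", 0, 5, 0, 10)])
        with pytest.raises(ValueError, match="overlap"):
            GridSpace(10, 10, compartments=[
                Compartment("lumen", 0, 6, 0, 10),
                Compartment("lamina_propria", 4, 10, 0, 10),
            ])

    def test_column_compartments_partition(self):
        space = GridSpace(10, 10, compartments=[
            Compartment("lumen", 0, 3, 0, 10),
            Compartment("epithelium", 3, 4, 0, 10),
            Compartment("lamina_propria", 4, 10, 0, 10),
        ])
        assert space.compartment_of(3.5, 5.0).name == "epithelium"
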