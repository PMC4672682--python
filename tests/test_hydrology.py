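"""DEM conditioning and drainage derivation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import accumulation_oracle, make_chain_fd
from fwstream.errors import (
    EmptyInputError,
    FlowError,
    GeometryError,
    InvalidParameterError,
)
from fwstream.grid import SINK, ElevationGrid, default_geometry
from fwstream.hydrology import (
    carve,
    extract_streams,
    fill_depressions,
    flow_accumulation,
    flow_direction,
    smooth_by_order,
    strahler,
)
from fwstream.synth import SyntheticBasinSpec, make_valley_dem


def grid(values, nodata=None):
    values = np.asarray(values, dtype=float)
    return ElevationGrid(values, geometry=default_geometry(*values.shape),
                         nodata=nodata)


class TestCarve:
    def test_stream_cells_lowered_by_depth_others_unchanged(self):
        dem = grid(np.full((3, 3), 100.0))
        streams = np.zeros((3, 3), dtype=bool)
        streams[1, 1] = True
        out = carve(dem, streams, depth=22.0)
        assert out.values[1, 1] == 78.0
        assert (out.values[~streams] == 100.0).all()

    def test_zero_depth_is_identity(self):
        dem = grid(np.arange(9.0).reshape(3, 3))
        out = carve(dem, np.ones((3, 3), dtype=bool), depth=0.0)
        np.testing.assert_array_equal(out.values, dem.values)

    def test_shape_mismatch_raises(self):
        with pytest.raises(GeometryError):
            carve(grid(np.zeros((3, 3))), np.zeros((4, 4), dtype=bool))


class TestSmoothByOrder:
    def test_constant_raster_unchanged(self):
        dem = grid(np.full((5, 5), 3.0))
        order = np.ones((5, 5), dtype=int)
        np.testing.assert_allclose(smooth_by_order(dem, order).values, 3.0)

    def test_straight_reach_mean(self):
        vals = np.zeros((3, 5))
        vals[1, 1:4] = [1.0, 4.0, 7.0]
        order = np.zeros((3, 5), dtype=int)
        order[1, 1:4] = 1
        out = smooth_by_order(grid(vals), order)
        assert out.values[1, 2] == pytest.approx(4.0)
        assert out.values[1, 1] == pytest.approx(2.5)  # only (1,4) in window
        assert (out.values[order == 0] == 0).all()

    def test_orders_do_not_mix(self):
        vals = np.array([[10.0, 10.0, 10.0], [2.0, 2.0, 2.0], [0.0, 0.0, 0.0]])
        order = np.array([[1, 1, 1], [2, 2, 2], [0, 0, 0]])
        out = smooth_by_order(grid(vals), order)
        np.testing.assert_allclose(out.values[0], 10.0)
        np.testing.assert_allclose(out.values[1], 2.0)

    def test_even_window_rejected(self):
        with pytest.raises(InvalidParameterError):
            smooth_by_order(grid(np.zeros((3, 3))), np.ones((3, 3), int), window=4)


class TestFillDepressions:
    def test_draining_plane_unchanged(self):
        dem = grid(np.arange(16.0).reshape(4, 4))
        out = fill_depressions(dem)
        np.testing.assert_array_equal(out.values, dem.values)

    def test_center_pit_raised_to_rim_plus_epsilon(self):
        vals = np.full((3, 3), 10.0)
        vals[1, 1] = 1.0
        out = fill_depressions(grid(vals))
        assert out.values[1, 1] > 10.0
        assert out.values[1, 1] == pytest.approx(10.0, abs=1e-9)

    def test_never_lowers_and_idempotent(self):
        spec = SyntheticBasinSpec(24, 24, relief=100.0, noise_amplitude=3.0, seed=2)
        dem = make_valley_dem(spec)
        once = fill_depressions(dem)
        assert (once.values >= dem.values).all()
        twice = fill_depressions(once)
        np.testing.assert_array_equal(once.values, twice.values)

    def test_every_cell_gains_descending_path_to_edge(self):
        rng = np.random.default_rng(0)
        dem = grid(rng.uniform(0, 50, size=(12, 12)))
        filled = fill_depressions(dem)
        fd = flow_direction(filled)  # would raise on any undrainable flat
        assert (fd.codes[1:-1, 1:-1] != SINK).all()

    def test_all_nodata_raises(self):
        with pytest.raises(EmptyInputError):
            fill_depressions(grid(np.full((3, 3), -9.0), nodata=-9.0))


class TestFlowDirection:
    def test_eastward_plane_routes_east(self):
        dem = grid(np.tile(np.arange(5.0, 0.0, -1.0), (4, 1)))
        fd = flow_direction(dem)
        assert (fd.codes[:, :-1] == 0).all()
        assert (fd.codes[:, -1] == SINK).all()

    def test_tie_between_east_and_south_resolves_east(self):
        # symmetric saddle: equal drop to E and S from the centre
        vals = np.array([[5.0, 5.0, 5.0], [5.0, 5.0, 4.0], [5.0, 4.0, 5.0]])
        fd = flow_direction(grid(vals))
        assert fd.codes[1, 1] == 0  # E before S in scan order

    def test_filled_bowl_routes_acyclically_to_single_sink(self):
        rng = np.random.default_rng(4)
        vals = rng.uniform(10, 20, size=(9, 9))
        vals[3:6, 3:6] = 0.0  # interior bowl
        fd = flow_direction(fill_depressions(grid(vals)))
        acc = flow_accumulation(fd)  # raises FlowError on a cycle
        assert acc.values.max() <= 81

    def test_interior_flat_raises_naming_cell(self):
        vals = np.full((5, 5), 7.0)
        with pytest.raises(FlowError, match=r"\(1, 1\)"):
            flow_direction(grid(vals))

    def test_deterministic(self):
        spec = SyntheticBasinSpec(16, 16, relief=90.0, noise_amplitude=2.0, seed=8)
        dem = fill_depressions(make_valley_dem(spec))
        a = flow_direction(dem)
        b = flow_direction(dem)
        np.testing.assert_array_equal(a.codes, b.codes)


class TestFlowAccumulation:
    def test_straight_chain_counts_1_to_n(self):
        fd = make_chain_fd(6)
        acc = flow_accumulation(fd)
        np.testing.assert_array_equal(acc.values[0], [1, 2, 3, 4, 5, 6])

    def test_defining_recurrence_holds_everywhere(self, basin32):
        fd, acc = basin32["fd"], basin32["acc"]
        down = fd.downstream_index()
        ncols = fd.shape[1]
        donor_sum = np.zeros(fd.shape, dtype=np.int64)
        for i in np.nonzero(fd.valid.ravel())[0]:
            j = down[i]
            if j >= 0:
                donor_sum[j // ncols, j % ncols] += acc.values[i // ncols, i % ncols]
        np.testing.assert_array_equal(acc.values, donor_sum + 1)

    def test_matches_path_counting_oracle(self, basin32):
        np.testing.assert_array_equal(
            basin32["acc"].values, accumulation_oracle(basin32["fd"])
        )


class TestExtractStreams:
    def test_threshold_semantics(self):
        acc = flow_accumulation(make_chain_fd(10))
        assert extract_streams(acc, threshold=5).sum() == 6  # cells 5..10
        assert extract_streams(acc, threshold=1).all()
        assert extract_streams(acc, threshold=11).sum() == 0

    def test_threshold_below_one_rejected(self):
        with pytest.raises(InvalidParameterError):
            extract_streams(flow_accumulation(make_chain_fd(3)), threshold=0)


class TestStrahler:
    def test_two_order1_reaches_merge_to_order2(self):
        from fwstream.synth import make_minimal_order_network

        fd, streams = make_minimal_order_network(2)
        order = strahler(fd, streams)
        assert sorted(order.values[streams]) == [1, 1, 2]

    def test_side_tributary_does_not_promote(self):
        # order-1 joining an order-2 reach keeps it at order 2
        from fwstream.grid import FlowDirectionGrid, default_geometry

        codes = np.full((3, 4), -2, dtype=np.int8)
        codes[0, 0] = 1   # SE -> (1,1)
        codes[2, 0] = 7   # NE -> (1,1)
        codes[1, 1] = 0   # E  -> (1,2)
        codes[0, 2] = 2   # S  -> (1,2)   extra order-1 tributary
        codes[1, 2] = 0   # E  -> (1,3)
        codes[1, 3] = -1  # sink
        fd = FlowDirectionGrid(codes, default_geometry(3, 4))
        streams = codes != -2
        order = strahler(fd, streams)
        assert order.values[1, 1] == 2
        assert order.values[0, 2] == 1
        assert order.values[1, 2] == 2
        assert order.values[1, 3] == 2

    def test_order_never_decreases_downstream(self, basin32):
        fd, streams, order = basin32["fd"], basin32["streams"], basin32["order"]
        down = fd.downstream_index()
        ncols = fd.shape[1]
        for i in np.nonzero(streams.ravel())[0]:
            j = down[i]
            if j >= 0 and streams.ravel()[j]:
                assert (order.values[j // ncols, j % ncols]
                        >= order.values[i // ncols, i % ncols])


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_routing_conserves_mass_on_random_basins(seed):
    """Total accumulation at sinks equals the number of cells (property)."""
    spec = SyntheticBasinSpec(12, 12, relief=60.0, noise_amplitude=2.0, seed=seed)
    fd = flow_direction(fill_depressions(make_valley_dem(spec)))
    acc = flow_accumulation(fd)
    sinks = fd.codes == SINK
    assert acc.values[sinks].sum() == 144
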