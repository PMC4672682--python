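"""Upstream metrics, storage scaling, and the layer catalog."""

import numpy as np
import pytest

from conftest import make_chain_fd
from fwstream.aggregation import MetricSpec, aggregate, build_variable, scale_store
from fwstream.catalog import layer_catalog
from fwstream.errors import InvalidParameterError, RangeError
from fwstream.grid import EnvGrid, default_geometry
from fwstream.subcatchment import iter_subcatchments
from fwstream.synth import make_env_layer, make_minimal_order_network


def env(values, nodata=None):
    values = np.asarray(values, dtype=float)
    return EnvGrid(values, geometry=default_geometry(*values.shape), nodata=nodata)


class TestAggregate:
    def test_constant_field_average_equals_weighted_average(self, basin32):
        layer = make_env_layer((32, 32), "constant", {"value": 5.5})
        for sc in list(iter_subcatchments(basin32["fd"], basin32["streams"]))[:10]:
            for domain in ("catchment", "watercourse"):
                a = aggregate(sc, layer, MetricSpec("average", domain))
                w = aggregate(sc, layer, MetricSpec("weighted_average", domain))
                assert a == pytest.approx(5.5)
                assert w == pytest.approx(5.5)

    def test_hand_computed_weighted_average_on_two_valued_cells(self):
        # 3-cell reach, middle cell NoData: valued cells sit at network
        # distance 1 (outlet, v=10) and 2 (v=4), so the weighted average is
        # (1*10 + 0.5*4) / 1.5 = 8
        fd = make_chain_fd(3)
        streams = np.ones((1, 3), dtype=bool)
        sc = list(iter_subcatchments(fd, streams))[-1]
        assert sc.outlet == (0, 2)
        layer = env([[4.0, -9.0, 10.0]], nodata=-9.0)
        got = aggregate(sc, layer, MetricSpec("weighted_average", "watercourse"))
        assert got == pytest.approx(8.0)

    def test_sum_at_basin_outlet_is_grand_total(self, basin32):
        spec, fd = basin32["spec"], basin32["fd"]
        streams = basin32["streams"]
        layer = make_env_layer((32, 32), "random", seed=12)
        sc = [s for s in iter_subcatchments(fd, streams) if s.outlet == spec.outlet]
        assert len(sc) == 1
        got = aggregate(sc[0], layer, MetricSpec("sum", "catchment"))
        assert got == pytest.approx(layer.values.sum())

    def test_min_max_range_consistency(self, basin32):
        layer = make_env_layer((32, 32), "random", seed=3)
        sc = max(iter_subcatchments(basin32["fd"], basin32["streams"]),
                 key=lambda s: s.n_cells)
        lo = aggregate(sc, layer, MetricSpec("min"))
        hi = aggregate(sc, layer, MetricSpec("max"))
        rng_ = aggregate(sc, layer, MetricSpec("range"))
        assert rng_ == pytest.approx(hi - lo)
        vals = layer.values[sc.cells[:, 0], sc.cells[:, 1]]
        assert lo == vals.min() and hi == vals.max()

    def test_all_nodata_domain_yields_nan_not_exception(self, basin32):
        layer = env(np.full((32, 32), -9.0), nodata=-9.0)
        sc = next(iter_subcatchments(basin32["fd"], basin32["streams"]))
        assert np.isnan(aggregate(sc, layer, MetricSpec("average")))

    def test_weighted_average_discounts_distant_cells(self, basin32):
        """On a field increasing with distance from the outlet the weighted
        average must fall below the plain average."""
        fd, streams = basin32["fd"], basin32["streams"]
        sc = max(iter_subcatchments(fd, streams), key=lambda s: s.n_cells)
        field = np.zeros((32, 32))
        field[sc.cells[:, 0], sc.cells[:, 1]] = sc.d_euclid
        layer = env(field)
        plain = aggregate(sc, layer, MetricSpec("average", "catchment"))
        weighted = aggregate(sc, layer, MetricSpec("weighted_average", "catchment"))
        assert weighted < plain

    def test_binary_layer_weighted_sum_is_sum_of_inverse_distances(self):
        fd = make_chain_fd(5)
        streams = np.ones((1, 5), dtype=bool)
        sc = list(iter_subcatchments(fd, streams))[-1]
        ones = env(np.ones((1, 5)))
        got = aggregate(sc, ones, MetricSpec("weighted_sum", "catchment"))
        assert got == pytest.approx(sum(1.0 / max(1, d) for d in range(5)))


class TestBuildVariable:
    def test_constant_layer_gives_constant_on_streams(self, basin32):
        fd, streams = basin32["fd"], basin32["streams"]
        layer = make_env_layer((32, 32), "constant", {"value": 2.0})
        var = build_variable(fd, streams, layer, MetricSpec("average"))
        assert (var.values[streams] == 2.0).all()
        assert (var.values[~streams] == var.nodata).all()

    def test_minimal_order2_outlet_flow_acc_is_three(self):
        """A 2nd-order confluence collects exactly its two 1st-order donors."""
        fd, streams = make_minimal_order_network(2)
        ones = EnvGrid(np.ones(fd.shape), geometry=fd.geometry)
        var = build_variable(fd, streams, ones, MetricSpec("sum", "catchment"))
        out = tuple(np.argwhere(fd.codes == -1)[0])
        assert var.values[out] == 3.0

    def test_every_stream_cell_matches_definitional_aggregate(self, basin32):
        fd, streams = basin32["fd"], basin32["streams"]
        layer = make_env_layer((32, 32), "random", seed=5)
        spec = MetricSpec("weighted_sum", "catchment")
        var = build_variable(fd, streams, layer, spec)
        for sc in list(iter_subcatchments(fd, streams))[::5]:
            assert var.values[sc.outlet] == pytest.approx(aggregate(sc, layer, spec))

    def test_upstream_sum_never_decreases_downstream(self, basin32):
        fd, streams = basin32["fd"], basin32["streams"]
        layer = make_env_layer((32, 32), "random", {"low": 0.0, "high": 2.0}, seed=9)
        var = build_variable(fd, streams, layer, MetricSpec("sum", "catchment"))
        down = fd.downstream_index()
        ncols = fd.shape[1]
        for i in np.nonzero(streams.ravel())[0]:
            j = down[i]
            if j >= 0 and streams.ravel()[j]:
                assert (var.values[j // ncols, j % ncols]
                        >= var.values[i // ncols, i % ncols] - 1e-9)


class TestScaleStore:
    @pytest.mark.parametrize(
        "value,factor,expected",
        [(21.57, 10, 215), (-3.27, 10, -32), (1.234, 100, 123), (7.0, 1, 7)],
    )
    def test_truncates_toward_zero(self, value, factor, expected):
        assert scale_store(value, factor, "Int32") == expected

    def test_nan_passes_through(self):
        assert np.isnan(scale_store(float("nan"), 10, "Int32"))

    def test_overflow_raises(self):
        with pytest.raises(RangeError):
            scale_store(1e9, 10, "Int32")
        with pytest.raises(RangeError):
            scale_store(200.0, 1, "Byte")

    def test_bad_factor_rejected(self):
        with pytest.raises(InvalidParameterError):
            scale_store(1.0, 0)


class TestCatalog:
    def test_total_layer_count_is_324(self):
        assert len(layer_catalog()) == 324

    def test_family_sizes(self):
        cat = layer_catalog()
        assert sum(1 for e in cat if e.file == "geology_weighted_sum.nc") == 92
        assert sum(1 for e in cat if e.category == "Land cover") == 60
        assert sum(1 for e in cat if e.category == "Soil") == 50
        assert sum(1 for e in cat if e.code.startswith("hydro_")) == 38
        assert sum(1 for e in cat if e.category == "Quality control") == 2

    def test_codes_and_bands_unique(self):
        cat = layer_catalog()
        codes = [e.code for e in cat]
        assert len(set(codes)) == len(codes)
        fb = [(e.file, e.band) for e in cat]
        assert len(set(fb)) == len(fb)

    def test_storage_schema_follows_released_product(self):
        cat = layer_catalog()
        by = {e.code: e for e in cat}
        assert (by["tmin_avg_07"].scale_factor, by["tmin_avg_07"].nodata) == (10, -999)
        assert by["tmin_avg_07"].storage == "Int32"
        assert (by["slope_avg"].scale_factor, by["slope_avg"].nodata) == (100, -999)
        assert by["prec_sum_01"].storage == "Float64"
        assert by["prec_sum_01"].nodata == -9999
        assert by["lc_wavg_12"].storage == "Byte"
        assert by["lc_wavg_12"].nodata == -127
        assert by["geo_wsum_92"].nodata == -9999
        assert by["soil_avg_02"].scale_factor == 10  # pH x10
        assert by["hydro_avg_03"].scale_factor == 100  # isothermality x100
        assert by["missing_cells"].file == "quality_control.nc"

    def test_temperature_domains_are_watercourse(self):
        cat = layer_catalog()
        for e in cat:
            if e.code.startswith(("tmin_", "tmax_")):
                assert e.domain == "watercourse"
            if e.code.startswith(("prec_", "soil_", "lc_", "geo_")):
                assert e.domain == "catchment"
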