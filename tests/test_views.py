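"""Static view renderers: figure files plus JSON sidecars of plotted numbers."""
import json
from pathlib import Path

import numpy as np
import pytest
from matplotlib.path import Path as MplPath

import brnuq as bq
from brnuq.ensembles import TrajectoryEnsemble
from brnuq.views import ColorMapSpec, layout_positions, parameter_stats


def sidecar(path):
    return json.loads(Path(str(path) + ".json").read_text())


@pytest.fixture(scope="module")
def mm_setup(mm_with_data, mm_prior_sample, mm_ensembles):
    graph = bq.build_graph(mm_with_data)
    return {
        "model": mm_with_data,
        "sample": mm_prior_sample,
        "graph": graph,
        "state_stats": bq.summarize(mm_ensembles.states),
        "flux_stats": bq.summarize(mm_ensembles.fluxes),
        "output_stats": bq.summarize(mm_ensembles.outputs),
        "ens": mm_ensembles,
    }


class TestGraphView:
    def test_link_segment_count_equals_rate_law_parameter_count(self, mm_setup, tmp_path):
        p = bq.render_graph(
            mm_setup["graph"], mm_setup["model"], tmp_path / "g.png",
            state_stats=mm_setup["state_stats"],
            param_stats=parameter_stats(mm_setup["sample"]),
        )
        side = sidecar(p)
        assert len(side["segments"]["conversion:X1->X2"]) == 2  # Michaelis-Menten
        assert len(side["segments"]["export:X3->__env__"]) == 1  # mass action
        params = [s["parameter"] for s in side["segments"]["conversion:X1->X2"]]
        assert params == ["vmax2", "km2"]  # first at link start, last at arrowhead

    def test_hull_encloses_exactly_the_member_positions(self, mm_setup, tmp_path):
        p = bq.render_graph(
            mm_setup["graph"], mm_setup["model"], tmp_path / "g.png",
            state_stats=mm_setup["state_stats"],
            param_stats=parameter_stats(mm_setup["sample"]),
            layout_seed=1,
        )
        side = sidecar(p)
        pos = layout_positions(mm_setup["graph"], seed=1)
        poly = MplPath(np.asarray(side["hulls"]["y1"]["polygon"]))
        for sid in ("X1", "X2"):
            assert poly.contains_point(pos[sid])
        for sid in ("X3", "E"):
            assert not poly.contains_point(pos[sid])

    def test_missing_statistic_for_displayed_element_raises(self, mm_setup, tmp_path):
        stats = parameter_stats(mm_setup["sample"]).drop(index="km2")
        with pytest.raises(ValueError, match="km2"):
            bq.render_graph(
                mm_setup["graph"], mm_setup["model"], tmp_path / "g.png",
                state_stats=mm_setup["state_stats"], param_stats=stats,
            )

    def test_svg_renders_are_byte_identical(self, mm_setup, tmp_path):
        kwargs = dict(
            state_stats=mm_setup["state_stats"],
            param_stats=parameter_stats(mm_setup["sample"]),
        )
        p1 = bq.render_graph(mm_setup["graph"], mm_setup["model"], tmp_path / "a.svg", **kwargs)
        p2 = bq.render_graph(mm_setup["graph"], mm_setup["model"], tmp_path / "b.svg", **kwargs)
        assert Path(p1).read_bytes() == Path(p2).read_bytes()


class TestAnimation:
    def test_frame_count_and_single_highlight(self, mm_setup, tmp_path):
        vals = np.zeros((5, 8, 2))
        vals[:, 4:, 0] = 1.0  # one drastic step in element s0
        ens = TrajectoryEnsemble("state", vals, np.arange(8.0), "e1", ("X1", "X2"))
        stats = bq.summarize(ens)
        flags = bq.detect_changes(stats)
        small = bq.BRNModel(
            species=(bq.Species("X1"), bq.Species("X2")),
            reactions=(bq.Reaction("r", {"X1": 1}, {"X2": 1}, bq.MassAction("k")),),
            parameters=("k",),
            experiments=(bq.ExperimentCondition("e1"),),
            name="two",
        )
        frames = bq.render_animation(
            bq.build_graph(small), small, tmp_path / "anim", stats,
            flags=flags, edge_attr="fluxes",
        )
        assert len(frames) == 8
        highlighted = [f for f in frames if sidecar(f)["highlight"]]
        assert len(highlighted) == 1
        assert sidecar(highlighted[0])["highlight"] == ["X1"]


class TestLines:
    def test_constant_ensemble_gives_zero_height_band(self, tmp_path):
        ens = TrajectoryEnsemble("output", np.full((6, 5, 1), 2.0), np.arange(5.0), "e1", ("y",))
        p = bq.render_lines(bq.summarize(ens), tmp_path / "l.png", selection=["y"])
        s = sidecar(p)["series"][0]
        assert s["p_low"] == s["p_high"] == s["median"]

    def test_data_dots_only_at_measurement_times(self, mm_setup, tmp_path):
        ds = mm_setup["model"].experiments[0].dataset
        p = bq.render_lines(
            mm_setup["output_stats"], tmp_path / "l.png", selection=["y1"], data=ds
        )
        s = sidecar(p)["series"][0]
        expected = sorted(ds.table[ds.table["observable"] == "y1"]["time"])
        assert sorted(s["data_t"]) == expected

    def test_between_experiment_plot_has_one_series_per_condition(self, mm_setup, tmp_path):
        stats = [mm_setup["output_stats"]] * 3  # three conditions
        p = bq.render_lines(
            stats, tmp_path / "b.png", mode="between_experiment", selection=["y2"]
        )
        side = sidecar(p)
        assert len(side["series"]) == 3
        assert all("p_low" in s and "p_high" in s for s in side["series"])


class TestScatter:
    def test_identical_columns_lie_on_diagonal(self, mm_setup, tmp_path):
        p = bq.render_scatter(mm_setup["ens"].states, ("X1", "X1"), tmp_path / "s.png", t_k=5.0)
        side = sidecar(p)
        np.testing.assert_array_equal(side["x"], side["y"])
        assert side["n"] == mm_setup["ens"].states.n_s

    def test_nonlinear_pair_deviates_from_any_line(self, tmp_path):
        import pandas as pd

        z = np.linspace(-1, 1, 200)
        s = bq.ParameterSample(pd.DataFrame({"a": z, "b": z**2}), "log10")
        p = bq.render_scatter(s, ("a", "b"), tmp_path / "s.png")
        side = sidecar(p)
        x, y = np.asarray(side["x"]), np.asarray(side["y"])
        slope, icpt = np.polyfit(x, y, 1)
        assert np.max(np.abs(y - (slope * x + icpt))) > 0.1

    def test_dynamic_kind_requires_time_point(self, mm_setup, tmp_path):
        with pytest.raises(ValueError, match="t_k"):
            bq.render_scatter(mm_setup["ens"].states, ("X1", "X2"), tmp_path / "s.png")


class TestMatrixAndTable:
    def test_identity_correlation_prints_unit_diagonal(self, tmp_path):
        rng = np.random.default_rng(0)
        m = bq.pearson_matrix(rng.normal(size=(100, 3)), labels=("a", "b", "c"))
        p = bq.render_matrix(m, tmp_path / "m.png")
        side = sidecar(p)
        for i in range(3):
            assert side["cell_text"][i][i] == "1.00"

    def test_cell_text_is_entry_rounded_to_two_decimals(self, tmp_path):
        rng = np.random.default_rng(1)
        m = bq.pearson_matrix(rng.normal(size=(50, 3)))
        side = sidecar(bq.render_matrix(m, tmp_path / "m.png"))
        for i in range(3):
            for j in range(3):
                assert side["cell_text"][i][j] == f"{m.values[i, j]:.2f}"

    def test_table_csv_equals_sample_statistics_exactly(self, mm_setup, tmp_path):
        import pandas as pd

        fig_path, csv_path = bq.render_table(mm_setup["sample"], tmp_path / "t.png")
        back = pd.read_csv(csv_path, index_col="parameter", float_precision="round_trip")
        expected = parameter_stats(mm_setup["sample"])
        np.testing.assert_array_equal(back.to_numpy(), expected.to_numpy())

    def test_constant_column_has_zero_sd_cell(self, tmp_path):
        import pandas as pd

        df = pd.DataFrame({"a": np.zeros(10), "b": np.arange(10.0)})
        s = bq.ParameterSample(df, "log10")
        _, csv_path = bq.render_table(s, tmp_path / "t.png")
        back = pd.read_csv(csv_path, index_col="parameter")
        assert back.loc["a", "sd"] == 0.0

    def test_extreme_cells_carry_palette_endpoints(self, mm_setup, tmp_path):
        from matplotlib import colormaps

        fig_path, _ = bq.render_table(mm_setup["sample"], tmp_path / "t.png")
        side = sidecar(fig_path)
        means = np.asarray(side["mean"])
        colors = side["cell_colors"]
        lo, hi = int(np.argmin(means)), int(np.argmax(means))
        cmap = colormaps["YlGnBu"]
        assert tuple(colors[lo][0]) == tuple(cmap(0.0))
        assert tuple(colors[hi][0]) == tuple(cmap(1.0))


class TestColorMaps:
    def test_univariate_lookup_monotone_in_statistic(self):
        cm = ColorMapSpec("univariate", ("mean",))
        cm.fit({"mean": np.array([0.0, 10.0])})
        norms = [cm._norm("mean", v) for v in np.linspace(0, 10, 7)]
        assert all(a <= b for a, b in zip(norms, norms[1:]))

    def test_bivariate_requires_two_statistics(self):
        with pytest.raises(ValueError, match="two statistics"):
            ColorMapSpec("bivariate", ("mean",))

    def test_bivariate_color_is_product_of_ramps(self):
        cm = ColorMapSpec("bivariate", ("mean", "sd"))
        cm.fit({"mean": np.array([0.0, 1.0]), "sd": np.array([0.0, 1.0])})
        c_low = cm.color(mean=0.0, sd=0.0)
        c_high = cm.color(mean=1.0, sd=1.0)
        assert all(a >= b for a, b in zip(c_low[:3], c_high[:3]))  # darker when both high
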