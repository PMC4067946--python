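"""Ensemble propagation, summaries, correlations, histograms, change flags."""
import numpy as np
import pandas as pd
import pytest

import brnuq as bq
from brnuq.ensembles import TrajectoryEnsemble


def _ensemble(values, t=None, labels=None, kind="state"):
    values = np.asarray(values, float)
    t = np.arange(values.shape[1], dtype=float) if t is None else np.asarray(t, float)
    labels = labels or tuple(f"s{i}" for i in range(values.shape[2]))
    return TrajectoryEnsemble(kind, values, t, "e1", tuple(labels))


class TestPropagate:
    def test_rows_match_independent_simulation(self, mm_with_data, mm_prior_sample, mm_ensembles):
        lin = mm_prior_sample.linear().draws
        t = mm_ensembles.states.t
        for a in (0, 7, 42):
            theta = lin.iloc[a][list(mm_with_data.parameters)].to_dict()
            st, fl = bq.simulate(mm_with_data, theta, mm_with_data.experiments[0], t)
            np.testing.assert_allclose(mm_ensembles.states.values[a], st.x, rtol=1e-10)
            np.testing.assert_allclose(mm_ensembles.fluxes.values[a], fl.v, rtol=1e-10)
            y = bq.evaluate_outputs(mm_with_data, st, theta)
            np.testing.assert_allclose(mm_ensembles.outputs.values[a], y, rtol=1e-10)

    def test_identical_draws_give_identical_rows(self, mm_with_data, mm_spec):
        theta_log = {k: np.log10(v) for k, v in mm_spec.theta_true.items()}
        df = pd.DataFrame([theta_log, theta_log])
        s = bq.ParameterSample(df, "log10")
        ens = bq.propagate(mm_with_data, s, mm_with_data.experiments[0], np.linspace(0, 5, 10))
        np.testing.assert_array_equal(ens.states.values[0], ens.states.values[1])

    def test_permutation_equivariance(self, mm_with_data, mm_prior_sample):
        t = np.linspace(0.0, 5.0, 6)
        perm = np.random.default_rng(1).permutation(mm_prior_sample.n_s)
        ens = bq.propagate(mm_with_data, mm_prior_sample, mm_with_data.experiments[0], t)
        shuffled = bq.ParameterSample(
            mm_prior_sample.draws.iloc[perm].reset_index(drop=True), "log10"
        )
        ens_p = bq.propagate(mm_with_data, shuffled, mm_with_data.experiments[0], t)
        np.testing.assert_allclose(ens_p.states.values, ens.states.values[perm], rtol=1e-12)

    @staticmethod
    def _explosive_model():
        # autocatalysis x' = k x^2 blows up at t = 1/(k x0): a deterministic
        # way to make individual draws fail
        return bq.BRNModel(
            species=(bq.Species("Z", initial=1.0),),
            reactions=(bq.Reaction("auto", {"Z": 2}, {"Z": 3}, bq.MassAction("k")),),
            parameters=("k",),
            experiments=(bq.ExperimentCondition("e"),),
            name="explosive",
        )

    def test_failed_draws_are_dropped_with_indices(self):
        m = self._explosive_model()
        df = pd.DataFrame({"k": np.log10([0.05, 100.0, 0.05, 0.05])})
        s = bq.ParameterSample(df, "log10")
        ens = bq.propagate(m, s, m.experiments[0], np.linspace(0, 5, 6), max_failure_fraction=0.5)
        assert ens.states.n_s == 3
        np.testing.assert_array_equal(ens.states.draw_indices, [0, 2, 3])

    def test_excess_failures_abort(self):
        m = self._explosive_model()
        df = pd.DataFrame({"k": np.log10([0.05, 100.0, 100.0])})
        s = bq.ParameterSample(df, "log10")
        with pytest.raises(bq.SimulationError, match="failed to simulate"):
            bq.propagate(m, s, m.experiments[0], np.linspace(0, 5, 6), max_failure_fraction=0.05)


class TestSummarize:
    def test_constant_ensemble_collapses(self):
        ens = _ensemble(np.full((8, 4, 2), 3.5))
        st = bq.summarize(ens)
        for arr in (st.mean, st.median, st.p_low, st.p_high):
            assert (arr == 3.5).all()
        assert (st.sd == 0).all()

    def test_percentiles_match_sort_and_interpolate_oracle(self):
        vals = np.arange(1.0, 101.0).reshape(100, 1, 1)
        st = bq.summarize(_ensemble(vals))
        srt = np.sort(vals[:, 0, 0])

        def interp(q):
            pos = q / 100 * (len(srt) - 1)
            lo = int(np.floor(pos))
            return srt[lo] + (pos - lo) * (srt[min(lo + 1, len(srt) - 1)] - srt[lo])

        assert st.p_low[0, 0] == pytest.approx(interp(5))
        assert st.median[0, 0] == pytest.approx(interp(50))
        assert st.p_high[0, 0] == pytest.approx(interp(95))

    def test_band_ordering_and_coverage_on_gaussian_sample(self):
        rng = np.random.default_rng(12)
        ens = _ensemble(rng.normal(size=(1000, 6, 3)))
        st = bq.summarize(ens)
        assert (st.p_low <= st.median).all() and (st.median <= st.p_high).all()
        cov = bq.band_coverage(ens, st)
        assert np.all(np.abs(cov - 0.90) < 2 / np.sqrt(1000))

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError, match="two sample members"):
            bq.summarize(_ensemble(np.ones((1, 3, 1))))


class TestCorrelations:
    def test_self_and_negation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        m = bq.pearson_matrix(np.column_stack([x, x, -x]))
        assert m.values[0, 1] == pytest.approx(1.0)
        assert m.values[0, 2] == pytest.approx(-1.0)

    def test_matches_covariance_formula_oracle(self):
        rng = np.random.default_rng(1)
        cols = rng.normal(size=(200, 4))
        m = bq.pearson_matrix(cols)
        for i in range(4):
            for j in range(4):
                xi, xj = cols[:, i] - cols[:, i].mean(), cols[:, j] - cols[:, j].mean()
                r = (xi * xj).sum() / np.sqrt((xi**2).sum() * (xj**2).sum())
                assert abs(m.values[i, j] - r) < 1e-12

    def test_zero_variance_column_flagged_nan(self):
        cols = np.column_stack([np.ones(50), np.arange(50.0)])
        m = bq.pearson_matrix(cols)
        assert np.isnan(m.values[0, 1]) and np.isnan(m.values[0, 0])
        assert m.values[1, 1] == 1.0

    def test_eigen_ratio_closed_form(self):
        rng = np.random.default_rng(2)
        z = rng.normal(size=(500, 2))
        cols = np.column_stack([z[:, 0], 0.8 * z[:, 0] + 0.6 * z[:, 1], z[:, 1]])
        p = bq.pearson_matrix(cols)
        e = bq.eigen_ratio_matrix(cols)
        for i in range(3):
            assert e.values[i, i] == 0.0
            for j in range(i + 1, 3):
                r = abs(p.values[i, j])
                assert e.values[i, j] == pytest.approx((1 - r) / (1 + r), abs=1e-8)

    def test_collinear_pair_ratio_zero(self):
        x = np.arange(100.0)
        e = bq.eigen_ratio_matrix(np.column_stack([x, 3 * x + 1]))
        assert e.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_independent_pair_ratio_near_one(self):
        rng = np.random.default_rng(3)
        e = bq.eigen_ratio_matrix(rng.normal(size=(100_000, 2)))
        assert e.values[0, 1] > 0.98

    def test_mean_course_of_identical_curves(self):
        base = np.sin(np.linspace(0, 3, 20))
        vals = np.stack([np.column_stack([base, base]) + rng_off for rng_off in np.random.default_rng(4).normal(0, 0.1, (50, 1, 1))])
        m = bq.correlation_contexts(_ensemble(vals), "mean_course")
        assert m.values[0, 1] == pytest.approx(1.0)

    def test_at_time_equals_pushforward_of_linear_map(self):
        """Constant-in-time ensemble y = A z: slice correlation equals the
        correlation of the linearly mapped sample."""
        rng = np.random.default_rng(5)
        z = rng.normal(size=(400, 2))
        A = np.array([[1.0, 0.5], [0.2, 1.0], [1.0, -1.0]])
        mapped = z @ A.T  # (400, 3)
        vals = np.repeat(mapped[:, None, :], 4, axis=1)
        got = bq.correlation_contexts(_ensemble(vals), "at_time", t_k=2.0)
        expected = bq.pearson_matrix(mapped)
        np.testing.assert_allclose(got.values, expected.values, atol=1e-12)

    def test_conserved_fluxes_strongly_correlated(self, conserved_model):
        """Near steady state v_fwd = v_rev across draws, so variations in one
        flux are compensated by the other: |r| close to 1."""
        prior = bq.Prior(
            {
                "k1": bq.PriorComponent("log10_uniform", -0.5, 0.5),
                "k2": bq.PriorComponent("log10_uniform", -0.8, 0.2),
            }
        )
        s = bq.ParameterSample(prior.sample_log10(np.random.default_rng(6), 80), "log10")
        ens = bq.propagate(conserved_model, s, conserved_model.experiments[0], [0.0, 20.0, 40.0])
        m = bq.correlation_contexts(ens.fluxes, "at_time", t_k=40.0)
        assert abs(m.values[0, 1]) > 0.99


class TestHistograms:
    def _sample(self, cols):
        return bq.ParameterSample(pd.DataFrame(cols), "log10")

    def test_counts_sum_to_n_and_shared_width_is_max_fd(self):
        rng = np.random.default_rng(7)
        cols = {"a": rng.normal(0, 1, 500), "b": rng.normal(0, 3, 500)}
        h = bq.common_histograms(self._sample(cols))
        for c in ("a", "b"):
            assert h.counts[c].sum() == 500

        def fd(x):
            q75, q25 = np.percentile(x, [75, 25])
            return 2 * (q75 - q25) / len(x) ** (1 / 3)

        assert h.bin_width == pytest.approx(max(fd(cols["a"]), fd(cols["b"])))

    def test_bimodal_column_shows_two_separated_masses(self):
        rng = np.random.default_rng(8)
        col = np.concatenate([rng.normal(-4, 0.2, 300), rng.normal(4, 0.2, 300)])
        h = bq.common_histograms(self._sample({"p": col}))
        c = h.counts["p"]
        nz = np.flatnonzero(c)
        assert (c[nz[0] : nz[-1] + 1] == 0).any()  # an empty gap between modes

    def test_zero_iqr_fallback(self):
        col = np.zeros(100)
        col[:2] = [0.0, 1.0]  # IQR 0, range 1
        h = bq.common_histograms(self._sample({"p": np.sort(col)}))
        assert h.bin_width == pytest.approx(1.0 / np.ceil(np.sqrt(100)))
        assert h.counts["p"].sum() == 100

    def test_unknown_selection_raises(self):
        with pytest.raises(KeyError):
            bq.common_histograms(self._sample({"a": np.arange(10.0)}), ["zzz"])


class TestChangeFlags:
    def test_constant_series_never_flagged(self):
        st = bq.summarize(_ensemble(np.full((5, 10, 2), 1.0)))
        flags = bq.detect_changes(st)
        assert not flags.flags.any()

    def test_single_full_range_step_flags_exactly_one_frame(self):
        vals = np.zeros((5, 10, 1))
        vals[:, 5:, 0] = 1.0
        flags = bq.detect_changes(bq.summarize(_ensemble(vals)))
        assert flags.flags.sum() == 1
        assert flags.flags[5, 0]

    def test_matches_brute_force_difference_scan(self, mm_ensembles):
        st = bq.summarize(mm_ensembles.states)
        flags = bq.detect_changes(st, "mean", threshold=0.2)
        series = st.mean
        for i in range(series.shape[1]):
            rng_i = series[:, i].max() - series[:, i].min()
            for fr in range(1, series.shape[0]):
                expected = (
                    rng_i > 0 and abs(series[fr, i] - series[fr - 1, i]) > 0.2 * rng_i
                )
                assert flags.flags[fr, i] == expected
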