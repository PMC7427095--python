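"""Global fitting: initialization, recovery, bootstrap, summaries."""

import numpy as np
import pytest

import optobind as ob
from optobind.errors import InputError
from optobind.fit import DEFAULT_BOUNDS, _ParamLayout, _pooled_residuals
from optobind.model import CurveShapeParams, PairShapes, Phase, SensorgramCurve


def flat_dataset(n_pairs=2):
    t = np.arange(0.0, 60.0, 2.0)
    curves = []
    for i in range(n_pairs):
        cid = f"c{i + 1}"
        curves.append(SensorgramCurve(cid, Phase.ASSOCIATION, t, np.zeros(t.size), i + 1.0))
        curves.append(SensorgramCurve(cid, Phase.DISSOCIATION, t, np.zeros(t.size)))
    return ob.BindingDataset(curves)


class TestInitialGuess:
    def test_koff_within_20pct_on_noise_free_data(self, ha4_noise_free):
        truth, dataset = ha4_noise_free
        guess = ob.initial_guess(dataset)
        assert guess.k_off == pytest.approx(truth.k_off, rel=0.20)

    def test_kon_exact_from_two_noise_free_concentrations(self):
        """With no noise and no leak the k_obs decomposition is exact, so the
        slope over two concentrations recovers k_on to 3 significant figures."""
        truth = ob.SimulationTruth(
            k_on=0.0631, k_off=0.0145, k_leak=0.0,
            concentrations=[0.1, 1.0], noise_sd=0.0, seed=0,
        )
        guess = ob.initial_guess(ob.simulate_dataset(truth))
        assert guess.k_on == pytest.approx(0.0631, rel=5e-4)

    def test_flat_zero_signal_degenerates_to_floors(self):
        guess = ob.initial_guess(flat_dataset())
        for shp in guess.per_curve.values():
            assert shp.on.a == 0.0 and shp.on.b == 0.0
            assert shp.off.a == 0.0 and shp.off.b == 0.0
        assert guess.k_off == DEFAULT_BOUNDS["k_off"][0]
        assert guess.k_leak <= 1e-5

    def test_single_concentration_warns(self):
        truth = ob.SimulationTruth(
            k_on=0.0631, k_off=0.0145, k_leak=0.0,
            concentrations=[1.0], noise_sd=0.0, seed=0,
        )
        with pytest.warns(UserWarning, match="fewer than 2 distinct concentrations"):
            ob.initial_guess(ob.simulate_dataset(truth))


class TestFitGlobal:
    def test_noise_free_recovery_to_0p1_percent(self, ha4_noise_free):
        truth, dataset = ha4_noise_free
        result = ob.fit_global(dataset, ob.FitOptions(seed=1))
        assert result.params.k_on == pytest.approx(truth.k_on, rel=1e-3)
        assert result.params.k_off == pytest.approx(truth.k_off, rel=1e-3)
        assert result.params.k_leak == pytest.approx(truth.k_leak, rel=1e-3)
        assert result.kd == pytest.approx(truth.kd, rel=1e-3)

    @pytest.mark.parametrize("n_pairs", [1, 2, 3, 4, 5])
    def test_parameter_count_is_4n_plus_3(self, n_pairs):
        truth = ob.SimulationTruth(
            k_on=0.0631, k_off=0.0145,
            concentrations=list(np.geomspace(0.08, 0.7, n_pairs + 1))[:n_pairs]
            if n_pairs > 1 else [0.23],
            sampling_interval=10.0, noise_sd=0.005, seed=n_pairs,
        )
        result = ob.fit_global(ob.simulate_dataset(truth), ob.FitOptions(seed=1))
        assert result.n_parameters == 4 * n_pairs + 3
        assert result.params.n_parameters == 4 * n_pairs + 3

    def test_zero_signal_flagged_unidentifiable(self):
        result = ob.fit_global(flat_dataset(), ob.FitOptions(seed=1))
        assert not result.rates_identifiable
        for shp in result.params.per_curve.values():
            assert abs(shp.on.a) < 1e-6

    def test_refuses_dataset_without_dissociation(self):
        t = np.arange(0.0, 60.0, 2.0)
        ds = ob.BindingDataset(
            [SensorgramCurve("c1", Phase.ASSOCIATION, t, np.ones(t.size), 1.0)]
        )
        with pytest.raises(InputError, match="dissociation"):
            ob.fit_global(ds)

    def test_scale_equivariance(self, coarse_truth):
        """Scaling every signal by c scales the fitted shape parameters by c
        and leaves the rate constants unchanged."""
        dataset = ob.simulate_dataset(coarse_truth)
        c = 3.7
        scaled = ob.BindingDataset(
            [
                SensorgramCurve(cv.curve_id, cv.phase, cv.times, c * cv.signal,
                                cv.analyte_conc)
                for cv in dataset.curves
            ],
            dataset.condition_label,
        )
        base = ob.fit_global(dataset, ob.FitOptions(seed=1))
        scaled_fit = ob.fit_global(scaled, ob.FitOptions(seed=1))
        assert scaled_fit.params.k_on == pytest.approx(base.params.k_on, rel=1e-3)
        assert scaled_fit.params.k_off == pytest.approx(base.params.k_off, rel=1e-3)
        for cid in base.params.per_curve:
            assert scaled_fit.params.per_curve[cid].on.a == pytest.approx(
                c * base.params.per_curve[cid].on.a, rel=1e-3
            )

    def test_stored_objective_matches_recomputation(self, ha4_noisy_fit):
        _, dataset, result = ha4_noisy_fit
        ssr = 0.0
        for ac, dc in dataset.pairs():
            shp = result.params.per_curve[ac.curve_id]
            model_a = ob.eval_association(
                result.params.k_on, result.params.k_off, result.params.k_leak,
                ac.analyte_conc, shp.on, ac.times,
            )
            model_d = ob.eval_dissociation(
                result.params.k_off, result.params.k_leak, shp.off, dc.times
            )
            ssr += float(np.sum((model_a - ac.signal) ** 2))
            ssr += float(np.sum((model_d - dc.signal) ** 2))
        assert result.sum_squared_residuals == pytest.approx(ssr, rel=1e-10)

    def test_same_seed_reproduces_fit(self, coarse_truth):
        dataset = ob.simulate_dataset(coarse_truth)
        a = ob.fit_global(dataset, ob.FitOptions(seed=5))
        b = ob.fit_global(dataset, ob.FitOptions(seed=5))
        assert a.params.k_on == b.params.k_on
        assert a.sum_squared_residuals == b.sum_squared_residuals
        assert a.best_restart_index == b.best_restart_index

    def test_grid_search_oracle_equivalence(self):
        """On a reduced 2-parameter problem (shapes and leak fixed at truth)
        the optimizer's (k_on, k_off) matches a dense log-grid search to
        within the grid spacing."""
        rng = np.random.default_rng(7)
        k_on, k_off = 0.0631, 0.0145
        t = np.linspace(0.0, 95.0, 20)
        shapes = {"c1": PairShapes(CurveShapeParams(1.0, 0.0), CurveShapeParams(0.9, 0.0))}
        conc = 2.0
        y_a = ob.eval_association(k_on, k_off, 0.0, conc, shapes["c1"].on, t)
        y_d = ob.eval_dissociation(k_off, 0.0, shapes["c1"].off, t)
        noise = 0.01
        dataset = ob.BindingDataset(
            [
                SensorgramCurve("c1", Phase.ASSOCIATION, t,
                                y_a + rng.normal(0, noise, t.size), conc),
                SensorgramCurve("c1", Phase.DISSOCIATION, t,
                                y_d + rng.normal(0, noise, t.size)),
            ]
        )
        options = ob.FitOptions(
            seed=1, fixed_rates={"k_leak": 0.0}, fixed_shapes=shapes
        )
        result = ob.fit_global(dataset, options)
        assert result.n_parameters == 2

        layout = _ParamLayout(["c1"], options)
        pairs = dataset.pairs()
        grid = np.linspace(-0.5, 0.5, 81)  # log10 offsets around truth
        step = grid[1] - grid[0]
        best, best_cost = None, np.inf
        for d_on in grid:
            for d_off in grid:
                theta = np.array([np.log10(k_on) + d_on, np.log10(k_off) + d_off])
                cost = float(np.sum(_pooled_residuals(theta, layout, pairs) ** 2))
                if cost < best_cost:
                    best_cost, best = cost, theta
        assert abs(np.log10(result.params.k_on) - best[0]) <= step
        assert abs(np.log10(result.params.k_off) - best[1]) <= step
        assert result.sum_squared_residuals <= best_cost + 1e-12


class TestBootstrap:
    def test_same_seed_gives_identical_intervals(self, coarse_truth):
        dataset = ob.simulate_dataset(coarse_truth)
        result = ob.fit_global(dataset, ob.FitOptions(seed=1))
        ci1 = ob.bootstrap_ci(dataset, result, n_boot=50, seed=3)
        ci2 = ob.bootstrap_ci(dataset, result, n_boot=50, seed=3)
        assert ci1.intervals == ci2.intervals

    def test_noise_free_intervals_collapse(self, ha4_noise_free):
        _, dataset = ha4_noise_free
        result = ob.fit_global(dataset, ob.FitOptions(seed=1))
        ci = ob.bootstrap_ci(dataset, result, n_boot=50, seed=3)
        for name, (lo, hi) in ci.intervals.items():
            assert hi - lo <= 1e-6 * max(abs(ci.estimates[name]), 1e-12) + 1e-12

    def test_interval_contains_point_estimate(self, coarse_truth):
        dataset = ob.simulate_dataset(coarse_truth)
        result = ob.fit_global(dataset, ob.FitOptions(seed=1))
        ci = ob.bootstrap_ci(dataset, result, n_boot=60, seed=4)
        for name, (lo, hi) in ci.intervals.items():
            assert lo <= ci.estimates[name] <= hi

    def test_rejects_small_n_boot(self, coarse_truth):
        dataset = ob.simulate_dataset(coarse_truth)
        result = ob.fit_global(dataset, ob.FitOptions(seed=1))
        with pytest.raises(InputError, match="n_boot"):
            ob.bootstrap_ci(dataset, result, n_boot=10, seed=3)


class TestSummaries:
    def test_replicate_summary_trivial(self):
        summary = ob.ReplicateSummary("x", [0.19] * 3, 0.19, 0.0, 3)
        assert summary.mean_kd == 0.19

    def test_summary_mean_sd(self, coarse_truth):
        truth = coarse_truth
        truth.n_replicates = 3
        fits = [ob.fit_global(ds, ob.FitOptions(seed=1))
                for ds in ob.simulate_replicates(truth)]
        summary = ob.summarize_replicates(fits, "dark")
        assert summary.n == 3
        assert summary.mean_kd == pytest.approx(np.mean(summary.kds))
        assert summary.sd_kd == pytest.approx(np.std(summary.kds, ddof=1))
        assert summary.mean_kd == pytest.approx(truth.kd, rel=0.15)
        # permutation invariance of the mean
        reordered = ob.summarize_replicates(list(reversed(fits)), "dark")
        assert reordered.mean_kd == summary.mean_kd

    def test_single_replicate_sd_is_undefined(self, ha4_noisy_fit):
        _, _, result = ha4_noisy_fit
        summary = ob.summarize_replicates([result])
        assert np.isnan(summary.sd_kd)

    def test_fold_change(self):
        fold = ob.fold_change(63.0, 0.19)
        assert fold == pytest.approx(331.578947, rel=1e-8)
        assert ob.round_sig(fold, 2) == 330.0
        assert ob.fold_change(1.0, 1.0) == 1.0
        assert ob.fold_change(5.0, 2.0) * ob.fold_change(2.0, 5.0) == pytest.approx(1.0)
        with pytest.raises(InputError):
            ob.fold_change(0.0, 1.0)
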