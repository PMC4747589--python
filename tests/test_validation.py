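import numpy as np
import pandas as pd
import pytest

from mecell.dynamics import ErrorModel
from mecell.population import PopulationModel
from mecell.synthetic import CellTrajectory, StudyDataset, default_population
from mecell.input_model import default_schedule
from mecell.validation import (PopulationEnvelope, envelope_coverage, fit_error,
                               predict_population, simulate_virtual_population,
                               subsample_study, truncate_study)


def toy_dataset(trajs):
    features = pd.DataFrame(index=pd.Index([t.cell_id for t in trajs],
                                           name="cell_id"))
    lineage = pd.DataFrame(columns=["daughter_id", "mother_id", "birth_time_min"])
    return StudyDataset(trajectories=trajs, features=features, lineage=lineage)


class TestPredictPopulation:
    def test_zero_variance_gives_zero_width_band(self):
        pop = default_population()
        clonal = PopulationModel(mu=pop.mu, sigma=np.zeros((4, 4)),
                                 tau_min=pop.tau_min, error=pop.error)
        env = predict_population(clonal, default_schedule(), n=200, rng=0,
                                 with_noise=False)
        np.testing.assert_allclose(env.lower, env.median, atol=1e-9)
        np.testing.assert_allclose(env.upper, env.median, atol=1e-9)

    def test_quantiles_match_full_sort_oracle(self):
        pop = default_population()
        frames, vals = simulate_virtual_population(pop, default_schedule(), 500,
                                                   np.random.default_rng(1))
        env = predict_population(pop, default_schedule(), n=500, rng=1,
                                 with_noise=False)
        lo = np.sort(vals, axis=0)
        np.testing.assert_allclose(env.median,
                                   np.percentile(vals, 50, axis=0), rtol=1e-12)
        np.testing.assert_allclose(env.lower,
                                   np.percentile(vals, 2.5, axis=0), rtol=1e-12)
        assert np.all(env.upper <= lo[-1, :] + 1e-9)

    def test_band_self_coverage_near_nominal(self):
        pop = default_population()
        env = predict_population(pop, default_schedule(), n=4000, rng=2,
                                 with_noise=True)
        frames, vals = simulate_virtual_population(pop, default_schedule(), 2000,
                                                   np.random.default_rng(3),
                                                   with_noise=True)
        inside = np.mean((vals >= env.lower) & (vals <= env.upper))
        assert abs(inside - 0.95) < 0.02

    def test_too_few_virtual_cells_rejected(self):
        with pytest.raises(ValueError):
            predict_population(default_population(), default_schedule(), n=10)


class TestFitError:
    def _study_and_preds(self, values, preds):
        t = np.arange(0.0, 60.0, 6.0)
        trajs = [CellTrajectory(cell_id="a", times=t, values=values,
                                birth_time_min=0.0, end_time_min=60.0)]
        return toy_dataset(trajs), {"a": preds}

    def test_perfect_predictions_give_zero(self):
        v = np.full(10, 100.0)
        study, preds = self._study_and_preds(v, v.copy())
        assert fit_error(study, preds) == 0.0

    def test_constant_relative_offset(self):
        v = np.full(10, 100.0)
        study, preds = self._study_and_preds(v, 1.1 * v)
        assert fit_error(study, preds) == pytest.approx(10.0, rel=1e-12)

    def test_matches_hand_computation(self):
        v = np.array([100.0, 200.0, 100.0, 200.0, 150.0, 150.0, 100.0, 200.0,
                      150.0, 150.0])
        p = v + np.array([10.0, -20.0, 5.0, 0.0, 15.0, -15.0, 10.0, -20.0, 5.0, 0.0])
        study, preds = self._study_and_preds(v, p)
        y_ref = v.mean()  # 150, well above the 5% floor
        expected = 100.0 * np.mean(np.abs(p - v) / y_ref)
        assert fit_error(study, preds) == pytest.approx(expected, rel=1e-12)

    def test_length_mismatch_rejected(self):
        v = np.full(10, 100.0)
        study, _ = self._study_and_preds(v, v)
        with pytest.raises(ValueError):
            fit_error(study, {"a": v[:5]})


class TestEnvelopeCoverage:
    def _env(self, t, lo, md, hi):
        return PopulationEnvelope(times=t, median=md, lower=lo, upper=hi,
                                  n_virtual=100)

    def test_zero_width_band_on_noisy_data(self):
        t = np.arange(0.0, 60.0, 6.0)
        rng = np.random.default_rng(4)
        trajs = [CellTrajectory(cell_id="a", times=t,
                                values=50 + rng.standard_normal(10),
                                birth_time_min=0.0, end_time_min=60.0)]
        env = self._env(t, np.full(10, 50.0), np.full(10, 50.0), np.full(10, 50.0))
        assert envelope_coverage(toy_dataset(trajs), env) < 0.2

    def test_minmax_band_covers_everything(self):
        t = np.arange(0.0, 60.0, 6.0)
        rng = np.random.default_rng(5)
        vals = [50 + 10 * rng.standard_normal(10) for _ in range(3)]
        trajs = [CellTrajectory(cell_id=f"c{i}", times=t, values=v,
                                birth_time_min=0.0, end_time_min=60.0)
                 for i, v in enumerate(vals)]
        V = np.array(vals)
        env = self._env(t, V.min(axis=0), np.median(V, axis=0), V.max(axis=0))
        assert envelope_coverage(toy_dataset(trajs), env) == 1.0

    def test_matches_brute_force_count_on_toy_set(self):
        t = np.arange(0.0, 30.0, 6.0)
        rng = np.random.default_rng(6)
        trajs = [CellTrajectory(cell_id=f"c{i}", times=t,
                                values=50 + 20 * rng.standard_normal(5),
                                birth_time_min=0.0, end_time_min=30.0)
                 for i in range(5)]
        lo, hi = np.full(5, 40.0), np.full(5, 70.0)
        env = self._env(t, lo, np.full(5, 55.0), hi)
        count = sum(bool(40.0 <= v <= 70.0) for tr in trajs for v in tr.values)
        assert envelope_coverage(toy_dataset(trajs), env) == count / 25


class TestStudyTransforms:
    def test_truncation_drops_late_samples(self, small_study):
        _, study = small_study
        out = truncate_study(study, 7 * 60.0)
        for t in out.trajectories:
            assert t.times[-1] <= 7 * 60.0 + 1e-9

    def test_subsample_is_seeded_and_subsets_tables(self, small_study):
        _, study = small_study
        a = subsample_study(study, 10, np.random.default_rng(7))
        b = subsample_study(study, 10, np.random.default_rng(7))
        assert [t.cell_id for t in a.trajectories] == [t.cell_id for t in b.trajectories]
        ids = {t.cell_id for t in a.trajectories}
        assert set(a.features.index) <= ids
        assert set(a.lineage["daughter_id"]) <= ids


class TestRobustnessExperiment:
    def test_smoke_on_tiny_conditions(self, small_study):
        """Each condition refits and returns finite metrics."""
        from mecell.saem import SAEMConfig
        from mecell.validation import robustness_experiment

        cfg, study = small_study
        table = robustness_experiment(
            study, cfg.build_input(),
            SAEMConfig(seed=1, n_burnin=30, n_sa=30, mcmc_steps=2),
            cell_counts=(20,), horizons_h=(6.0,), rng=1, n_envelope=300)
        assert len(table) == 1
        row = table.iloc[0]
        assert np.isfinite(row["mu_error"]) and np.isfinite(row["coverage"])
        assert 0.0 <= row["coverage"] <= 1.0
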