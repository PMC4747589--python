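import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mecell.analysis import (correlate_features, inheritance_test,
                             md_feature_comparison, pca_rank, perceived_shock)
from mecell.input_model import ShockSchedule


class TestPerceivedShock:
    def _schedule(self):
        return ShockSchedule(((60.0, 68.0), (120.0, 128.0), (180.0, 188.0)), 300.0)

    def test_constant_volume_gives_zero(self):
        t = np.arange(0.0, 300.0, 3.0)
        assert perceived_shock(t, np.full(len(t), 40.0), self._schedule()) == 0.0

    def test_uniform_ten_percent_drop(self):
        t = np.arange(0.0, 300.0, 3.0)
        v = np.full(len(t), 100.0)
        for start, _ in self._schedule().intervals:
            v[(t >= start) & (t < start + 12.0)] = 90.0
        assert perceived_shock(t, v, self._schedule()) == pytest.approx(0.10)

    def test_mixed_drops_average(self):
        # drops of 5%, 15%, 10% -> mean 10%
        t = np.arange(0.0, 300.0, 3.0)
        v = np.full(len(t), 100.0)
        for (start, _), drop in zip(self._schedule().intervals, (5.0, 15.0, 10.0)):
            v[(t >= start) & (t < start + 12.0)] = 100.0 - drop
        assert perceived_shock(t, v, self._schedule()) == pytest.approx(0.10)

    def test_no_shock_in_span_gives_nan(self):
        t = np.arange(200.0, 230.0, 3.0)  # covers no shock onset window
        sched = ShockSchedule(((60.0, 68.0),), 300.0)
        assert np.isnan(perceived_shock(t, np.full(len(t), 50.0), sched))


class TestCorrelateFeatures:
    def _tables(self, x, y):
        idx = pd.Index([f"c{i}" for i in range(len(x))], name="cell_id")
        return (pd.DataFrame({"p": x}, index=idx),
                pd.DataFrame({"f": y}, index=idx))

    def test_monotone_map_gives_unit_correlation(self):
        x = np.linspace(-2, 2, 30)
        P, F = self._tables(x, np.exp(x))
        rho, p = correlate_features(P, F)
        assert rho.loc["p", "f"] == 1.0

    def test_reversed_ranks_give_minus_one(self):
        x = np.arange(12.0)
        P, F = self._tables(x, x[::-1])
        rho, _ = correlate_features(P, F)
        assert rho.loc["p", "f"] == -1.0

    def test_tied_ranks_match_midrank_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 4.0, 4.0, 5.0, 6.0, 7.0])
        y = np.array([2.0, 1.0, 3.0, 3.0, 5.0, 4.0, 6.0, 6.0, 7.0, 8.0])
        P, F = self._tables(x, y)
        rho, _ = correlate_features(P, F)
        # exhaustive mid-rank computation: Pearson on mid-ranks
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert rho.loc["p", "f"] == pytest.approx(expected, rel=1e-12)

    def test_constant_column_reported_nan(self):
        P, F = self._tables(np.ones(12), np.arange(12.0))
        rho, p = correlate_features(P, F)
        assert np.isnan(rho.loc["p", "f"])


class TestPcaRank:
    def test_isotropic_variance_fractions_nearly_equal(self):
        rng = np.random.default_rng(1)
        Z = rng.standard_normal((1000, 4))
        lp = pd.DataFrame(Z, columns=list("abcd"),
                          index=pd.Index([f"c{i}" for i in range(1000)],
                                         name="cell_id"))
        summary = pca_rank(lp)
        assert np.all(np.abs(summary.variance_fractions - 0.25) < 0.05)

    def test_two_dim_gaussian_matches_analytic_eigendecomposition(self):
        # cov [[2,1],[1,2]]: eigenvalues 3 and 1 -> fractions 0.75/0.25
        rng = np.random.default_rng(2)
        L = np.linalg.cholesky(np.array([[2.0, 1.0], [1.0, 2.0]]))
        Z = rng.standard_normal((2000, 2)) @ L.T
        lp = pd.DataFrame(Z, columns=["a", "b"],
                          index=pd.Index([f"c{i}" for i in range(2000)],
                                         name="cell_id"))
        summary = pca_rank(lp)
        assert abs(summary.variance_fractions[0] - 0.75) < 0.03
        assert abs(summary.variance_fractions[1] - 0.25) < 0.03

    def test_fractions_sum_to_one_and_ignore_features(self):
        rng = np.random.default_rng(3)
        Z = rng.standard_normal((200, 4))
        idx = pd.Index([f"c{i}" for i in range(200)], name="cell_id")
        lp = pd.DataFrame(Z, columns=list("abcd"), index=idx)
        feats = pd.DataFrame({"f": rng.standard_normal(200)}, index=idx)
        s1 = pca_rank(lp)
        s2 = pca_rank(lp, feats)
        assert s1.variance_fractions.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(s1.variance_fractions, s2.variance_fractions)

    def test_feature_equal_to_pc1_scores_weighted_by_varfrac1(self):
        rng = np.random.default_rng(4)
        L = np.linalg.cholesky(np.array([[2.0, 1.0], [1.0, 2.0]]))
        Z = rng.standard_normal((500, 2)) @ L.T
        idx = pd.Index([f"c{i}" for i in range(500)], name="cell_id")
        lp = pd.DataFrame(Z, columns=["a", "b"], index=idx)
        pre = pca_rank(lp)
        feats = pd.DataFrame({"f": pre.pc_scores["PC1"]}, index=idx)
        summary = pca_rank(lp, feats)
        # |rho(PC1, f)| = 1, |rho(PC2, f)| ~ 0
        assert summary.feature_scores["f"] == pytest.approx(
            summary.variance_fractions[0], abs=0.02)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(5)
        Z = rng.standard_normal((100, 4))
        lp = pd.DataFrame(Z, columns=list("abcd"),
                          index=pd.Index([f"c{i}" for i in range(100)],
                                         name="cell_id"))
        summary = pca_rank(lp)
        np.testing.assert_allclose(summary.loadings.T @ summary.loadings,
                                   np.eye(4), atol=1e-10)


def lineage_tables(rng, n_mothers=50, rho=0.0, sd=0.5):
    """Mothers and daughters with optional log-parameter inheritance."""
    mothers = [f"m{i}" for i in range(n_mothers)]
    daughters = [f"d{i}" for i in range(n_mothers)]
    zm = rng.standard_normal(n_mothers) * sd
    zd = rho * zm + np.sqrt(1 - rho**2) * rng.standard_normal(n_mothers) * sd
    params = pd.DataFrame({"k": np.exp(np.concatenate([zm, zd]))},
                          index=pd.Index(mothers + daughters, name="cell_id"))
    lineage = pd.DataFrame({"daughter_id": daughters, "mother_id": mothers,
                            "birth_time_min": np.zeros(n_mothers)})
    return params, lineage


class TestInheritanceTest:
    def test_perfect_inheritance(self):
        rng = np.random.default_rng(6)
        mothers = [f"m{i}" for i in range(45)]
        daughters = [f"d{i}" for i in range(45)]
        z = rng.standard_normal(45)
        params = pd.DataFrame({"k": np.exp(np.concatenate([z, z]))},
                              index=pd.Index(mothers + daughters, name="cell_id"))
        lineage = pd.DataFrame({"daughter_id": daughters, "mother_id": mothers,
                                "birth_time_min": np.zeros(45)})
        rep = inheritance_test(params, lineage, n_boot=2000, rng=0)
        row = rep.per_parameter.loc["k"]
        assert row["mean_md"] == 0.0
        assert row["closeness_pct"] == pytest.approx(100.0)
        assert row["p_value"] <= 1 / 2000

    def test_pvalue_invariant_to_cell_relabeling(self):
        rng = np.random.default_rng(7)
        params, lineage = lineage_tables(rng, rho=0.4)
        rep1 = inheritance_test(params, lineage, n_boot=2000, rng=11)
        mapping = {cid: f"x{i}" for i, cid in enumerate(params.index)}
        params2 = params.rename(index=mapping)
        lineage2 = lineage.assign(
            daughter_id=lineage["daughter_id"].map(mapping),
            mother_id=lineage["mother_id"].map(mapping))
        rep2 = inheritance_test(params2, lineage2, n_boot=2000, rng=11)
        assert rep1.per_parameter["p_value"].equals(rep2.per_parameter["p_value"])

    def test_insufficient_pairs_rejected(self):
        rng = np.random.default_rng(8)
        params, lineage = lineage_tables(rng, n_mothers=10)
        with pytest.raises(ValueError):
            inheritance_test(params, lineage, n_pairs=40, n_boot=100, rng=0)


class TestMdFeatureComparison:
    def _tables(self, fm, fd):
        n = len(fm)
        mothers = [f"m{i}" for i in range(n)]
        daughters = [f"d{i}" for i in range(n)]
        feats = pd.DataFrame({"f": np.concatenate([fm, fd])},
                             index=pd.Index(mothers + daughters, name="cell_id"))
        lineage = pd.DataFrame({"daughter_id": daughters, "mother_id": mothers,
                                "birth_time_min": np.zeros(n)})
        return feats, lineage

    def test_fourteen_percent_more_sensitive_daughters(self):
        rng = np.random.default_rng(9)
        fm = np.abs(rng.normal(0.3, 0.05, 40))
        feats, lineage = self._tables(fm, 1.14 * fm)
        out = md_feature_comparison(feats, lineage, "f")
        assert out["mean_relative_difference"] == pytest.approx(0.14, rel=1e-12)

    def test_perfect_anti_inheritance(self):
        fm = np.linspace(0.1, 0.9, 30)
        feats, lineage = self._tables(fm, -fm + 1.0)
        out = md_feature_comparison(feats, lineage, "f")
        assert out["spearman_rho"] == -1.0

    def test_independent_features_near_zero_correlation(self):
        rng = np.random.default_rng(10)
        feats, lineage = self._tables(np.abs(rng.normal(1, 0.2, 100)),
                                      np.abs(rng.normal(1, 0.2, 100)))
        out = md_feature_comparison(feats, lineage, "f")
        assert abs(out["spearman_rho"]) < 0.2

    def test_zero_mother_rows_dropped(self):
        fm = np.concatenate([[0.0], np.linspace(0.5, 1.5, 15)])
        feats, lineage = self._tables(fm, 1.1 * fm + 0.1)
        out = md_feature_comparison(feats, lineage, "f")
        assert out["n_dropped_zero_mother"] == 1
        assert out["n_pairs"] == 15
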