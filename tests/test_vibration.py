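"""Electrode-cluster vibration analysis and repeated-measures ANOVA."""

import numpy as np
import pytest
from scipy import stats

from spncat import (
    CatalogueError,
    Catalogue,
    chi_square_independence,
    cross_cluster_correlation,
    recompute_clusters,
    rm_anova_oneway,
    spn_summary,
)
from spncat.simulate import generate_catalogue
from spncat.vibration import DEFAULT_CLUSTERS

from conftest import fast_config


@pytest.fixture(scope="module")
def catalogue(posterior16):
    cfg = fast_config(seed=31, n_experiments=8, n_range=(6, 10), noise_sd=0.5)
    return generate_catalogue(cfg, montage=posterior16)


@pytest.fixture(scope="module")
def report(catalogue):
    return recompute_clusters(catalogue, DEFAULT_CLUSTERS, window=(300.0, 1000.0))


class TestRecompute:
    def test_original_cluster_identity(self, catalogue, report):
        # "Original" column equals a direct spn_summary at each experiment's
        # own cluster and window
        for exp, summary in zip(catalogue.experiments, report.summaries["Original"]):
            direct = spn_summary(
                exp, exp.original_cluster, exp.original_window, catalogue.montage
            )
            assert summary.mean == direct.mean
            assert summary.p_two_tailed == direct.p_two_tailed

    def test_every_experiment_in_every_cluster(self, catalogue, report):
        for rows in report.summaries.values():
            assert [s.experiment_id for s in rows] == [e.id for e in catalogue.experiments]

    def test_counts_match_brute_force_recount(self, report):
        for name, rows in report.summaries.items():
            brute = sum(1 for s in rows if s.p_two_tailed < 0.05)
            assert report.significance_counts[name] == brute

    def test_unknown_electrode_names_cluster_and_label(self, catalogue):
        with pytest.raises(CatalogueError, match="'Bad'.*Cz"):
            recompute_clusters(catalogue, {"Bad": ("PO7", "Cz")})

    def test_uniform_topography_gives_near_perfect_correlations(self, posterior16):
        cfg = fast_config(
            seed=33, n_experiments=8, n_range=(8, 12), noise_sd=0.3,
            topography={lab: 1.0 for lab in posterior16.labels},
        )
        cat = generate_catalogue(cfg, montage=posterior16)
        rep = recompute_clusters(cat, DEFAULT_CLUSTERS)
        corr = rep.correlation_matrix.to_numpy()
        assert corr[~np.eye(len(corr), dtype=bool)].min() >= 0.99

    def test_rank_stability_across_clusters(self, report):
        amp = report.amplitudes()
        cols = list(amp.columns)
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                rho = stats.spearmanr(amp[cols[i]], amp[cols[j]]).statistic
                assert rho >= 0.95


class TestChiSquare:
    def test_identical_rows_independent(self):
        res = chi_square_independence([[20, 10], [20, 10], [20, 10]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_hand_computed_diagonal(self):
        res = chi_square_independence([[10, 0], [0, 10]])
        assert res.statistic == pytest.approx(20.0, abs=1e-9)
        assert res.df == 1

    def test_matches_textbook_formula_on_random_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            obs = rng.integers(1, 40, size=(rng.integers(2, 5), rng.integers(2, 4)))
            res = chi_square_independence(obs)
            expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
            direct = ((obs - expected) ** 2 / expected).sum()
            assert res.statistic == pytest.approx(direct, rel=1e-12)
            assert res.df == (obs.shape[0] - 1) * (obs.shape[1] - 1)

    def test_degenerate_tables_rejected(self):
        with pytest.raises(ValueError):
            chi_square_independence([[1, 2]])
        with pytest.raises(ValueError):
            chi_square_independence([[0, 0], [3, 4]])
        with pytest.raises(ValueError):
            chi_square_independence([[1, -2], [3, 4]])


class TestCrossClusterCorrelation:
    def test_self_correlation_unity(self, report):
        corr = cross_cluster_correlation(report)
        assert np.allclose(np.diag(corr), 1.0)
        assert np.allclose(corr, corr.T)

    def test_five_experiment_fixture_matches_hand_r(self):
        x = np.array([-2.0, -1.5, -0.7, -0.2, -1.1])
        y = np.array([-1.8, -1.6, -0.5, -0.4, -1.0])
        # hand Pearson r via the definitional formula
        xc, yc = x - x.mean(), y - y.mean()
        hand = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
        assert stats.pearsonr(x, y).statistic == pytest.approx(hand, abs=1e-12)
        assert stats.pearsonr(x, 2 * x).statistic == pytest.approx(1.0)


class TestRmAnova:
    def test_two_conditions_equal_squared_paired_t(self):
        rng = np.random.default_rng(8)
        mat = rng.normal(0, 1, size=(14, 2))
        res = rm_anova_oneway(mat)
        t = stats.ttest_rel(mat[:, 0], mat[:, 1])
        assert res.F == pytest.approx(t.statistic**2, rel=1e-9)
        assert res.p == pytest.approx(t.pvalue, rel=1e-9)

    def test_identical_conditions_null(self):
        mat = np.tile(np.array([[1.0], [2.0], [3.0]]), (1, 4))
        res = rm_anova_oneway(mat)
        assert res.F == 0.0
        assert res.p == 1.0

    def test_brute_force_sums_of_squares(self):
        rng = np.random.default_rng(9)
        mat = rng.normal(0, 1, size=(6, 3))
        res = rm_anova_oneway(mat)
        # oracle: explicit loops over the SS decomposition
        grand = mat.mean()
        ss_cond = sum(6 * (mat[:, j].mean() - grand) ** 2 for j in range(3))
        ss_subj = sum(3 * (mat[i, :].mean() - grand) ** 2 for i in range(6))
        ss_tot = sum((mat[i, j] - grand) ** 2 for i in range(6) for j in range(3))
        ss_err = ss_tot - ss_cond - ss_subj
        f = (ss_cond / 2) / (ss_err / 10)
        assert res.F == pytest.approx(f, rel=1e-9)
        assert (res.df1, res.df2) == (2, 10)

    def test_agrees_with_pingouin(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(10)
        mat = rng.normal(0, 1, size=(10, 4)) + rng.normal(0, 1, (10, 1))
        long = pd.DataFrame(
            [
                {"subj": i, "cond": j, "y": mat[i, j]}
                for i in range(10)
                for j in range(4)
            ]
        )
        pg_res = pg.rm_anova(data=long, dv="y", within="cond", subject="subj")
        res = rm_anova_oneway(mat)
        assert res.F == pytest.approx(float(pg_res["F"].iloc[0]), rel=1e-6)
        assert res.p == pytest.approx(float(pg_res["p_unc"].iloc[0]), rel=1e-6)

    def test_observed_power_convention(self):
        rng = np.random.default_rng(12)
        mat = rng.normal(0, 1, size=(12, 3))
        mat[:, 0] += 0.8
        res = rm_anova_oneway(mat)
        fcrit = stats.f.ppf(0.95, res.df1, res.df2)
        expect = stats.ncf.sf(fcrit, res.df1, res.df2, res.F * res.df1)
        assert res.observed_power == pytest.approx(expect, rel=1e-9)
        assert 0.0 < res.observed_power < 1.0

    def test_incomplete_matrix_rejected(self):
        mat = np.ones((4, 3))
        mat[1, 2] = np.nan
        with pytest.raises(ValueError, match="incomplete"):
            rm_anova_oneway(mat)
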