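import numpy as np
import pytest

from daisel import BlupTable, ammi_biplot_coords, ammi_decompose, impute_column_min
from daisel.ammi import GEMatrix
from tests.conftest import make_environments


def gematrix(values, prefix="g"):
    g, e = values.shape
    return GEMatrix(
        genotypes=[f"{prefix}{i}" for i in range(g)],
        environments=[f"E{j}" for j in range(e)],
        values=np.asarray(values, dtype=float),
    )


class TestImputation:
    def test_direct_rule(self):
        envs = make_environments()[:1]
        t = BlupTable(["a", "b", "c"], envs, np.array([[3.0], [np.nan], [5.0]]))
        m = impute_column_min(t)
        assert m.values[:, 0].tolist() == [3.0, 3.0, 5.0]

    def test_complete_matrix_identity(self, random_blups):
        m = impute_column_min(random_blups)
        assert np.array_equal(m.values, random_blups.values)

    def test_matches_brute_force_column_min(self, random_blups, rng):
        vals = random_blups.values.copy()
        holes = rng.random(vals.shape) < 0.15
        vals[holes] = np.nan
        t = BlupTable(random_blups.genotypes, random_blups.environments, vals)
        m = impute_column_min(t)
        for j in range(vals.shape[1]):
            col_min = np.nanmin(vals[:, j])
            assert np.all(m.values[holes[:, j], j] == col_min)

    def test_fully_missing_column_rejected(self):
        envs = make_environments()[:2]
        t = BlupTable(["a", "b"], envs, np.array([[1.0, np.nan], [2.0, np.nan]]))
        with pytest.raises(ValueError, match="no observed"):
            impute_column_min(t)


class TestDecomposition:
    def test_purely_additive_matrix_has_no_interaction(self):
        a = np.array([10.0, 20.0, 35.0, 50.0])
        b = np.array([1.0, 5.0, 9.0])
        m = gematrix(a[:, None] + b[None, :] + 100.0)
        res = ammi_decompose(m, k_max=2)
        assert res.interaction_ss == pytest.approx(0.0, abs=1e-18)
        assert np.allclose(res.singular_values, 0.0, atol=1e-9)

    def test_rank_one_interaction_recovered_exactly(self):
        u = np.array([2.0, -1.0, -1.0, 0.0])
        v = np.array([1.0, 0.0, -1.0])
        a = np.array([100.0, 200.0, 300.0, 400.0])
        b = np.array([0.0, 50.0, 100.0])
        m = gematrix(a[:, None] + b[None, :] + 7.0 * np.outer(u, v))
        res = ammi_decompose(m, k_max=2)
        expected_ss = 49.0 * np.sum(u**2) * np.sum(v**2)
        assert res.interaction_ss == pytest.approx(expected_ss, rel=1e-12)
        assert res.singular_values[0] ** 2 == pytest.approx(expected_ss, rel=1e-12)
        assert res.axis_ss_fraction[0] == pytest.approx(1.0)

    def test_partition_matches_brute_force(self, random_blups):
        m = impute_column_min(random_blups)
        res = ammi_decompose(m, k_max=2)
        y = m.values
        z = y - y.mean(1, keepdims=True) - y.mean(0, keepdims=True) + y.mean()
        assert np.sum(res.singular_values**2) == pytest.approx(np.sum(z**2), rel=1e-8)
        # total corrected SS partition
        total = np.sum((y - y.mean()) ** 2)
        anova = res.anova.set_index("source")
        assert (
            anova.loc["Genotypes", "SS"] + anova.loc["Environments", "SS"]
            + anova.loc["Interactions", "SS"]
        ) == pytest.approx(total, rel=1e-10)

    def test_score_scaling_and_centering(self, random_blups):
        res = ammi_decompose(impute_column_min(random_blups), k_max=2)
        for k, lam in zip((1, 2), res.singular_values[:2]):
            gsc = res.genotype_scores[f"IPCA{k}"].to_numpy()
            esc = res.environment_scores[f"IPCA{k}"].to_numpy()
            assert gsc.sum() == pytest.approx(0.0, abs=1e-8 * lam)
            assert esc.sum() == pytest.approx(0.0, abs=1e-8 * lam)
            assert np.sum(gsc**2) == pytest.approx(lam, rel=1e-10)
            assert np.sum(esc**2) == pytest.approx(lam, rel=1e-10)
        # orthogonality between axes on each side
        g1 = res.genotype_scores["IPCA1"]
        g2 = res.genotype_scores["IPCA2"]
        assert np.dot(g1, g2) == pytest.approx(0.0, abs=1e-6)

    def test_full_reconstruction(self, random_blups):
        m = impute_column_min(random_blups)
        res = ammi_decompose(m, k_max=7)
        y = m.values
        recon = (
            res.grand_mean
            + (m.genotype_means - res.grand_mean)[:, None]
            + (m.environment_means - res.grand_mean)[None, :]
        )
        for k in range(1, 8):
            recon = recon + np.outer(
                res.genotype_scores[f"IPCA{k}"], res.environment_scores[f"IPCA{k}"]
            )
        assert np.allclose(recon, y, atol=1e-8)

    def test_gollob_df_bookkeeping(self, random_blups):
        res = ammi_decompose(impute_column_min(random_blups), k_max=2)
        anova = res.anova.set_index("source")
        # 24 genotypes, 8 environments
        assert anova.loc["Genotypes", "df"] == 23
        assert anova.loc["Environments", "df"] == 7
        assert anova.loc["Interactions", "df"] == 161
        assert anova.loc["IPCA 1", "df"] == 24 + 8 - 1 - 2
        assert anova.loc["IPCA 2", "df"] == 24 + 8 - 1 - 4
        assert anova.loc["Residuals", "df"] == 161 - 29 - 27
        assert 23 + 7 + 161 == 24 * 8 - 1

    def test_k_max_bounds(self, random_blups):
        with pytest.raises(ValueError):
            ammi_decompose(impute_column_min(random_blups), k_max=8)


class TestBiplots:
    def test_mean_view_x_is_marginal_mean(self, random_blups):
        m = impute_column_min(random_blups)
        res = ammi_decompose(m, k_max=2)
        pts = ammi_biplot_coords(res, "mean_vs_ipca1")
        gx = pts[pts.kind == "genotype"].set_index("entity")["x"]
        assert np.allclose(gx[m.genotypes], m.genotype_means)
        ex = pts[pts.kind == "environment"].set_index("entity")["x"]
        assert np.allclose(ex[m.environments], m.environment_means)

    def test_entity_counts(self, random_blups):
        res = ammi_decompose(impute_column_min(random_blups), k_max=2)
        for view in ("mean_vs_ipca1", "ipca1_vs_ipca2", "mean_vs_ipca2"):
            assert len(ammi_biplot_coords(res, view)) == 24 + 8

    def test_missing_axis_rejected(self, random_blups):
        res = ammi_decompose(impute_column_min(random_blups), k_max=1)
        with pytest.raises(ValueError):
            ammi_biplot_coords(res, "ipca1_vs_ipca2")
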