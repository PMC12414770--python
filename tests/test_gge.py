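import numpy as np
import pytest

from daisel import (
    environment_ranking,
    gge_decompose,
    ideal_genotype_ranking,
    impute_column_min,
    mean_vs_stability,
    which_won_where,
)
from daisel.ammi import GEMatrix


def gematrix(values):
    g, e = np.asarray(values).shape
    return GEMatrix(
        genotypes=[f"g{i}" for i in range(g)],
        environments=[f"E{j}" for j in range(e)],
        values=np.asarray(values, dtype=float),
    )


@pytest.fixture
def random_gem(random_blups):
    return impute_column_min(random_blups)


class TestDecomposition:
    def test_no_genotype_signal_rejected(self):
        # every genotype equal within each environment → centred matrix is 0
        row = np.array([1.0, 5.0, 9.0, 2.0])
        with pytest.raises(ValueError, match="zero"):
            gge_decompose(gematrix(np.tile(row[None, :], (4, 1))))

    def test_rank_one_structure_explains_everything(self, rng):
        u = rng.normal(size=10)
        v = rng.uniform(0.5, 2.0, 5)
        m = gematrix(1000.0 + np.outer(u, v))
        res = gge_decompose(m)
        assert res.variance_fraction[0] == pytest.approx(100.0)

    @pytest.mark.parametrize("svp", ["genotype_focused", "environment_focused", "symmetric"])
    def test_reconstruction_any_svp(self, random_gem, svp):
        res = gge_decompose(random_gem, svp=svp)
        recon = res.genotype_scores @ res.environment_scores.T
        assert np.allclose(recon, res.centered, atol=1e-8)

    def test_columns_centered(self, random_gem):
        res = gge_decompose(random_gem)
        assert np.allclose(res.centered.sum(axis=0), 0.0, atol=1e-8)

    def test_variance_fractions_sum_to_100(self, random_gem):
        res = gge_decompose(random_gem)
        assert res.variance_fraction.sum() == pytest.approx(100.0)


class TestWhichWonWhere:
    def test_square_geometry(self):
        # 4 genotype points at the corners of a square, environments in the
        # middle of each sector → winner is the nearest corner by projection
        pts = np.array([[1.0, 1.0], [-1.0, 1.0], [-1.0, -1.0], [1.0, -1.0], [0.0, 0.0]])
        env_dirs = np.array([[2.0, 0.5], [-0.5, 2.0], [-2.0, -0.5], [0.5, -2.0]])
        centered = np.hstack([pts @ d[:, None] for d in env_dirs])
        m = gematrix(1000.0 + centered)
        res = gge_decompose(m)
        www = which_won_where(res)
        gsc, esc = res.scores_2d()
        for j, env in enumerate(res.environments):
            brute = res.genotypes[int(np.argmax(gsc @ esc[j]))]
            assert www["winner_per_environment"][env] == brute
        assert set(www["winner_per_environment"].values()) == {"g0", "g1", "g2", "g3"}

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_winner_equals_argmax_inner_product(self, seed):
        rng = np.random.default_rng(seed)
        m = gematrix(np.abs(rng.normal(2000, 400, (24, 8))) + 50)
        res = gge_decompose(m)
        www = which_won_where(res)
        gsc, esc = res.scores_2d()
        for j, env in enumerate(res.environments):
            brute = res.genotypes[int(np.argmax(gsc @ esc[j]))]
            assert www["winner_per_environment"][env] == brute

    def test_hull_vertices_are_genotypes(self, random_gem):
        www = which_won_where(gge_decompose(random_gem))
        assert set(www["hull_vertices"]) <= set(random_gem.genotypes)


class TestMeanVsStability:
    def test_origin_genotype_has_zero_coordinates(self, rng):
        base = np.abs(rng.normal(2000, 300, (10, 6))) + 50
        m = gematrix(base)
        res = gge_decompose(m, svp="genotype_focused")
        # force one genotype's 2-D scores to the origin by replacing its data
        res.genotype_scores[0, :] = 0.0
        ms = mean_vs_stability(res)
        assert ms.loc[0, "mean_projection"] == pytest.approx(0.0, abs=1e-12)
        assert ms.loc[0, "stability"] == pytest.approx(0.0, abs=1e-12)

    def test_projection_tracks_genotype_means(self, rng):
        from scipy.stats import spearmanr

        geno = rng.normal(0, 300, 30)
        env = rng.normal(0, 150, 6)
        noise = rng.normal(0, 60, (30, 6))
        m = gematrix(2000.0 + geno[:, None] + env[None, :] + noise)
        res = gge_decompose(m, svp="genotype_focused")
        ms = mean_vs_stability(res)
        rho = spearmanr(ms["mean_projection"], m.genotype_means).statistic
        assert rho >= 0.95

    def test_reflection_flips_stability_keeps_projection(self, random_gem):
        res = gge_decompose(random_gem, svp="genotype_focused")
        ms = mean_vs_stability(res)
        aec_ms = ms.copy()
        # reflect genotype 0 across the AEC axis in score space
        from daisel.gge import _aec_direction

        aec = _aec_direction(res)
        perp = np.array([-aec[1], aec[0]])
        g0 = res.genotype_scores[0, :2]
        res.genotype_scores[0, :2] = (g0 @ aec) * aec - (g0 @ perp) * perp
        ms2 = mean_vs_stability(res)
        assert ms2.loc[0, "mean_projection"] == pytest.approx(aec_ms.loc[0, "mean_projection"])
        assert ms2.loc[0, "stability"] == pytest.approx(-aec_ms.loc[0, "stability"])


class TestIdealRanking:
    def test_ideal_defining_genotype_ranks_first(self, random_gem):
        res = gge_decompose(random_gem, svp="genotype_focused")
        ms = mean_vs_stability(res)
        best = ms.loc[ms["mean_projection"].idxmax(), "genotype_id"]
        # zero that genotype's instability so it sits exactly at the ideal point
        i = res.genotypes.index(best)
        from daisel.gge import _aec_direction

        aec = _aec_direction(res)
        proj = res.genotype_scores[i, :2] @ aec
        res.genotype_scores[i, :2] = proj * aec
        ranking = ideal_genotype_ranking(res)
        assert ranking.iloc[0]["genotype_id"] == best
        assert ranking.iloc[0]["distance_to_ideal"] == pytest.approx(0.0, abs=1e-10)

    def test_rotation_invariance(self, random_gem):
        res = gge_decompose(random_gem, svp="genotype_focused")
        base = ideal_genotype_ranking(res)["genotype_id"].tolist()
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        res.genotype_scores = res.genotype_scores[:, :2] @ rot.T
        res.environment_scores = res.environment_scores[:, :2] @ rot.T
        assert ideal_genotype_ranking(res)["genotype_id"].tolist() == base

    def test_distances_match_brute_force(self, random_gem):
        res = gge_decompose(random_gem, svp="genotype_focused")
        ranking = ideal_genotype_ranking(res).set_index("genotype_id")
        ms = mean_vs_stability(res).set_index("genotype_id")
        ideal = ms["mean_projection"].max()
        for gid in res.genotypes:
            d = np.hypot(ms.loc[gid, "mean_projection"] - ideal, ms.loc[gid, "stability"])
            assert ranking.loc[gid, "distance_to_ideal"] == pytest.approx(d)


class TestEnvironmentRanking:
    def test_collinear_environment_fully_representative(self, rng):
        u = rng.normal(size=12)
        # all environment columns proportional to one pattern → every env
        # vector is collinear with the AEC
        scales = np.array([1.0, 2.0, 0.5, 1.5])
        m = gematrix(1500.0 + np.outer(u, scales))
        res = gge_decompose(m, svp="environment_focused")
        er = environment_ranking(res)
        assert np.allclose(np.abs(er["representativeness"]), 1.0, atol=1e-8)

    def test_doubling_column_doubles_vector_length(self, random_gem):
        res = gge_decompose(random_gem, svp="environment_focused")
        vals = random_gem.values.copy()
        centered = vals - vals.mean(axis=0, keepdims=True)
        centered[:, 3] *= 2
        doubled = gematrix(1000.0 + centered)
        res2 = gge_decompose(doubled, svp="environment_focused")
        er1 = environment_ranking(res).set_index("environment")
        er2 = environment_ranking(res2).set_index("environment")
        # environment-focused SVP keeps environment vectors at (approximately,
        # up to 2-axis truncation) the centred-column geometry; compare full space
        full1 = np.linalg.norm(res.centered[:, 3])
        full2 = np.linalg.norm(res2.centered[:, 3])
        assert full2 == pytest.approx(2 * full1, rel=1e-10)
        env1 = res.environments[3]
        env2 = res2.environments[3]
        assert er2.loc[env2, "vector_length"] > er1.loc[env1, "vector_length"]

    def test_angles_match_brute_force(self, random_gem):
        from daisel.gge import _aec_direction

        res = gge_decompose(random_gem, svp="environment_focused")
        er = environment_ranking(res).set_index("environment")
        aec = _aec_direction(res)
        _, esc = res.scores_2d()
        for j, env in enumerate(res.environments):
            cos = float(esc[j] @ aec / np.linalg.norm(esc[j]))
            assert er.loc[env, "representativeness"] == pytest.approx(cos, abs=1e-10)
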