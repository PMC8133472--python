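"""PCoA / dbRDA oracles, environmental distances, turnover regressions."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from mosaicdiv import (
    ComparisonPair,
    dbrda,
    dbrda_marginal,
    env_distance,
    lingoes_correction,
    pcoa,
    survey_turnover_distance,
    turnover_env_regression,
)

from conftest import make_occ

import pandas as pd


class TestPCoA:
    def test_reconstructs_euclidean_distances(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(12, 2))
        dist = squareform(pdist(pts))
        coords = pcoa(dist).coordinates
        assert np.abs(squareform(pdist(coords)) - dist).max() < 1e-8

    def test_collinear_points_have_one_positive_eigenvalue(self):
        pts = np.array([[0.0], [1.0], [3.0]])
        dist = squareform(pdist(pts))
        eig = pcoa(dist).eigenvalues
        assert (eig > 1e-10).sum() == 1

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            pcoa(d)

    def test_matches_skbio_on_random_euclidean_cloud(self):
        skbio_ord = pytest.importorskip("skbio.stats.ordination")
        rng = np.random.default_rng(3)
        dist = squareform(pdist(rng.normal(size=(9, 3))))
        ours = pcoa(dist)
        theirs = skbio_ord.pcoa(dist, method="eigh")
        np.testing.assert_allclose(
            np.sort(ours.eigenvalues)[::-1][:8],
            np.sort(theirs.eigvals.to_numpy())[::-1][:8],
            atol=1e-8,
        )

    def test_jaccard_distances_yield_negative_eigenvalues_lingoes_fixes(self):
        # non-Euclidean configuration from binary data
        occ = make_occ(
            [
                [1, 1, 0, 0, 0],
                [0, 1, 1, 0, 0],
                [0, 0, 1, 1, 0],
                [0, 0, 0, 1, 1],
                [1, 0, 0, 0, 1],
                [1, 0, 1, 0, 1],
            ]
        )
        dist = survey_turnover_distance(occ)
        eig = pcoa(dist).eigenvalues
        assert eig.min() < -1e-8
        corrected, c1 = lingoes_correction(dist)
        assert c1 > 0
        eig2 = pcoa(corrected).eigenvalues
        assert eig2.min() >= -1e-6 * abs(eig2[0])


def _classical_rda_f(coords, x, n_perm=0):
    """Independent oracle: RDA pseudo-F by direct OLS projection."""
    y = coords - coords.mean(axis=0)
    xm = np.column_stack([np.ones(len(x)), x])
    beta, *_ = np.linalg.lstsq(xm, y, rcond=None)
    fitted = xm @ beta - y.mean(axis=0)
    ss_ex = (fitted**2).sum()
    ss_res = (y**2).sum() - ss_ex
    q = np.linalg.matrix_rank(x - x.mean(axis=0) if x.ndim > 1 else (x - x.mean())[:, None])
    df_res = len(y) - 1 - q
    return (ss_ex / q) / (ss_res / df_res), ss_ex / (y**2).sum()


class TestDbRDA:
    def test_fully_explanatory_predictor(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=25)
        dist = squareform(pdist((3 * x)[:, None]))
        res = dbrda(dist, x, n_perm=199, rng_seed=1)
        assert res.r2 >= 0.99
        assert res.perm_p == pytest.approx(1 / 200)

    def test_equals_classical_rda_on_euclidean_response(self):
        rng = np.random.default_rng(7)
        coords = rng.normal(size=(20, 3))
        x = rng.normal(size=(20, 2))
        dist = squareform(pdist(coords))
        res = dbrda(dist, x, n_perm=9, rng_seed=0)
        f_oracle, r2_oracle = _classical_rda_f(coords, x)
        assert res.f_stat == pytest.approx(f_oracle, rel=1e-6)
        assert res.r2 == pytest.approx(r2_oracle, rel=1e-6)

    def test_condition_identical_to_predictor_kills_marginal_share(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        dist = squareform(pdist((x + 0.1 * rng.normal(size=30))[:, None]))
        res = dbrda_marginal(
            dist, {"a": x, "b": x.copy()}, n_perm=49, rng_seed=3
        )
        assert res.marginal["a"]["r2_share"] == pytest.approx(0.0, abs=1e-6)
        assert res.marginal["b"]["r2_share"] == pytest.approx(0.0, abs=1e-6)

    def test_variance_decomposition_additive(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            coords = rng.normal(size=(18, 3))
            x = rng.normal(size=(18, 2))
            z = rng.normal(size=(18, 1))
            dist = squareform(pdist(coords))
            r_joint = dbrda(dist, np.column_stack([x, z]), n_perm=9, rng_seed=0)
            r_z = dbrda(dist, z, n_perm=9, rng_seed=0)
            r_x_given_z = dbrda(dist, x, condition=z, n_perm=9, rng_seed=0)
            assert r_joint.r2 == pytest.approx(
                r_z.r2 + r_x_given_z.r2, abs=1e-8
            )

    def test_more_predictors_than_surveys_rejected(self):
        rng = np.random.default_rng(5)
        dist = squareform(pdist(rng.normal(size=(6, 2))))
        with pytest.raises(ValueError, match="predictors"):
            dbrda(dist, rng.normal(size=(6, 7)), n_perm=9)

    def test_constant_predictor_dropped_with_warning(self, caplog):
        rng = np.random.default_rng(6)
        dist = squareform(pdist(rng.normal(size=(12, 2))))
        x = np.column_stack([np.ones(12), rng.normal(size=12)])
        with caplog.at_level("WARNING"):
            res = dbrda(dist, x, n_perm=9, rng_seed=0)
        assert "constant" in caplog.text
        assert np.isfinite(res.f_stat)

    def test_permutation_p_never_zero(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=15)
        dist = squareform(pdist((2 * x)[:, None]))
        res = dbrda(dist, x, n_perm=49, rng_seed=0)
        assert res.perm_p >= 1 / 50


class TestEnvDistance:
    @staticmethod
    def _pair():
        return ComparisonPair(
            region_id="r",
            high_level="SPA",
            low_level="NPA",
            high_surveys=["h1", "h2"],
            low_surveys=["l1", "l2"],
        )

    def test_identical_environments_give_zero(self):
        env = pd.DataFrame(
            {"t": [1.0, 1.0, 1.0, 1.0], "p": [2.0, 2.0, 2.0, 2.0]},
            index=["h1", "h2", "l1", "l2"],
        )
        res = env_distance(self._pair(), env, n_iter=5, rng_seed=0)
        assert res.env_distance == pytest.approx(0.0)

    def test_single_variable_log_scale_offset(self):
        # one variable differing by delta on the ln(x+1) scale -> distance |delta|
        hi, lo = 3.0, 1.0
        env = pd.DataFrame({"t": [hi, hi, lo, lo]}, index=["h1", "h2", "l1", "l2"])
        res = env_distance(self._pair(), env, n_iter=3, rng_seed=0)
        assert res.env_distance == pytest.approx(abs(np.log1p(hi) - np.log1p(lo)))

    def test_centroid_arithmetic_oracle(self):
        env = pd.DataFrame(
            {"t": [1.0, 3.0, 0.5, 2.5], "p": [4.0, 2.0, 1.0, 5.0]},
            index=["h1", "h2", "l1", "l2"],
        )
        res = env_distance(self._pair(), env, n_iter=4, rng_seed=0)
        logv = np.log1p(env.to_numpy())
        expected = np.linalg.norm(logv[:2].mean(axis=0) - logv[2:].mean(axis=0))
        assert res.env_distance == pytest.approx(expected)

    def test_incomplete_side_skips_pair(self, caplog):
        env = pd.DataFrame(
            {"t": [1.0, np.nan, 1.0, 2.0]}, index=["h1", "h2", "l1", "l2"]
        )
        with caplog.at_level("WARNING"):
            res = env_distance(self._pair(), env, n_iter=3, rng_seed=0)
        assert res is None
        assert "skipped" in caplog.text


class TestTurnoverEnvRegression:
    def test_perfectly_collinear(self):
        pts = [(0.0, 0.1), (1.0, 0.3), (2.0, 0.5), (3.0, 0.7)]
        fit = turnover_env_regression(pts)
        assert fit["r2"] == pytest.approx(1.0)
        assert fit["slope"] == pytest.approx(0.2)

    def test_duplicated_points_leave_fit_unchanged(self):
        pts = [(0.0, 0.1), (1.0, 0.4), (2.0, 0.3)]
        a = turnover_env_regression(pts)
        b = turnover_env_regression(pts + pts)
        assert a["slope"] == pytest.approx(b["slope"])
        assert a["intercept"] == pytest.approx(b["intercept"])

    def test_zero_variance_x_is_an_error(self):
        with pytest.raises(ValueError, match="variance"):
            turnover_env_regression([(1.0, 0.2), (1.0, 0.4), (1.0, 0.6)])

    def test_independent_x_y_slope_p_roughly_uniform(self):
        rng = np.random.default_rng(9)
        ps = []
        for _ in range(200):
            x = rng.normal(size=12)
            y = rng.normal(size=12)
            ps.append(turnover_env_regression(list(zip(x, y)))["p"])
        from scipy import stats

        assert stats.kstest(ps, "uniform").pvalue > 0.01
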