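import numpy as np
import pytest

from metgei import biplot_coords, fit_gge, which_won_where
from metgei.bilinear import BilinearFit

from conftest import make_table

import pandas as pd


class TestFitGge:
    def test_identical_genotypes_zero_gge_ss(self, rng):
        e = rng.normal(0, 3, 5)
        tab = make_table(np.tile(10 + e, (4, 1)))
        fit = fit_gge(tab)
        assert fit.ss_table.loc["GGE", "SS"] == pytest.approx(0.0, abs=1e-10)

    def test_lambda_sq_conservation(self, rng):
        vals = rng.normal(15, 4, (6, 5))
        fit = fit_gge(make_table(vals))
        direct = float(((vals - vals.mean(axis=0)) ** 2).sum())
        assert np.sum(fit.singular_values**2) == pytest.approx(direct, abs=1e-8)

    def test_rank2_g_plus_ge_structure(self, rng):
        # genotype main + rank-1 interaction => GGE is rank 2 exactly
        g = rng.normal(0, 2, 8)
        e = rng.normal(0, 3, 6)
        u = rng.normal(0, 1, 8)
        v = rng.normal(0, 1, 6)
        u -= u.mean()
        v -= v.mean()
        vals = 20 + np.add.outer(g, e) + np.outer(u, v)
        fit = fit_gge(make_table(vals))
        pct2 = fit.ss_table.loc[["IPC1", "IPC2"], "pct_GGE"].sum()
        assert pct2 == pytest.approx(100.0, abs=1e-6)
        # rank-2 reconstruction error equals the trailing lambda^2 sum
        Z = vals - vals.mean(axis=0)
        recon = (fit.genotype_scores.to_numpy()[:, :2]
                 @ np.diag(fit.singular_values[:2])
                 @ fit.env_loadings.to_numpy()[:, :2].T)
        err = float(((Z - recon) ** 2).sum())
        assert err == pytest.approx(float(np.sum(fit.singular_values[2:] ** 2)), abs=1e-8)


class TestBiplotCoords:
    def test_reconstruction_identity(self, rng):
        vals = rng.normal(10, 3, (5, 4))
        fit = fit_gge(make_table(vals))
        F, H = biplot_coords(fit, k=2)
        Z = vals - vals.mean(axis=0)
        rank2 = (fit.genotype_scores.to_numpy()[:, :2]
                 @ np.diag(fit.singular_values[:2])
                 @ fit.env_loadings.to_numpy()[:, :2].T)
        assert np.allclose(F.to_numpy() @ H.to_numpy().T, rank2, atol=1e-10)

    def test_deterministic_sign_convention(self, rng):
        vals = rng.normal(10, 3, (6, 5))
        f1 = fit_gge(make_table(vals))
        f2 = fit_gge(make_table(vals.copy()))
        pd.testing.assert_frame_equal(f1.genotype_scores, f2.genotype_scores)
        # largest-magnitude environment loading on each axis is positive
        V = f1.env_loadings.to_numpy()
        for k in range(V.shape[1]):
            assert V[np.argmax(np.abs(V[:, k])), k] > 0

    def test_three_by_three_svd_hand_check(self):
        vals = np.array([[4.0, 1.0, 0.0], [1.0, 3.0, 1.0], [0.0, 1.0, 5.0]])
        fit = fit_gge(make_table(vals))
        Z = vals - vals.mean(axis=0)
        # independent SVD via eigen-decomposition of Z'Z
        w = np.sqrt(np.maximum(np.linalg.eigvalsh(Z.T @ Z), 0))[::-1]
        assert np.allclose(fit.singular_values, w[: len(fit.singular_values)], atol=1e-10)


def _fit_from_coords(F, H):
    """Minimal BilinearFit carrying prescribed symmetric-scaled coordinates."""
    lam = np.array([1.0, 1.0])  # lambda^0.5 = 1 so coords == raw scores
    return BilinearFit(
        model_kind="GGE", grand_mean=0.0, genotype_main=None,
        env_main=pd.Series(0.0, index=H.index), singular_values=lam,
        genotype_scores=F, env_loadings=H,
        ss_table=pd.DataFrame(), K=2,
    )


class TestWhichWonWhere:
    def test_constructed_winner(self):
        F = pd.DataFrame([[1.0, 0.0], [-1.0, 1.0], [-1.0, -1.0]],
                         index=["A", "B", "C"], columns=["IPC1", "IPC2"])
        H = pd.DataFrame([[2.0, 0.1]], index=["e1"], columns=["IPC1", "IPC2"])
        www = which_won_where(_fit_from_coords(F, H))
        assert www.sector_of_env["e1"] == "A"

    def test_origin_environment_tie_breaks_by_identifier(self):
        F = pd.DataFrame([[1.0, 0.0], [-1.0, 1.0], [-1.0, -1.0]],
                         index=["B", "A", "C"], columns=["IPC1", "IPC2"])
        H = pd.DataFrame([[0.0, 0.0]], index=["e1"], columns=["IPC1", "IPC2"])
        www = which_won_where(_fit_from_coords(F, H))
        assert www.sector_of_env["e1"] == "A"  # all inner products 0 -> first id

    def test_geometry_equals_argmax_over_vertices(self, rng):
        # winner restricted to hull vertices == brute-force inner-product argmax
        for _ in range(25):
            vals = rng.normal(12, 4, (7, 5))
            fit = fit_gge(make_table(vals))
            www = which_won_where(fit)
            F, H = biplot_coords(fit, k=2)
            hull = set(www.hull_vertices)
            for env in H.index:
                scores = {g: float(F.loc[g] @ H.loc[env]) for g in hull}
                best = max(scores.values())
                brute = sorted(g for g, s in scores.items()
                               if np.isclose(s, best, rtol=0, atol=1e-12))[0]
                assert www.sector_of_env[env] == brute

    def test_winner_is_global_argmax_too(self, rng):
        # hull-vertex winner equals argmax over ALL genotypes (hull property)
        vals = rng.normal(12, 4, (9, 6))
        fit = fit_gge(make_table(vals))
        www = which_won_where(fit)
        F, H = biplot_coords(fit, k=2)
        for env in H.index:
            s = F.to_numpy() @ H.loc[env].to_numpy()
            assert www.sector_of_env[env] == F.index[int(np.argmax(s))]

    def test_sectors_partition_environments(self, rng):
        fit = fit_gge(make_table(rng.normal(12, 4, (8, 6))))
        www = which_won_where(fit)
        envs = sorted(e for v in www.sectors.values() for e in v)
        assert envs == sorted(fit.environments)
        assert set(www.sectors) <= set(www.hull_vertices)

    def test_collinear_markers_fall_back_to_extremes(self):
        F = pd.DataFrame([[1.0, 1.0], [2.0, 2.0], [-1.0, -1.0]],
                         index=["A", "B", "C"], columns=["IPC1", "IPC2"])
        H = pd.DataFrame([[1.0, 1.0], [-1.0, -0.5]], index=["e1", "e2"],
                         columns=["IPC1", "IPC2"])
        www = which_won_where(_fit_from_coords(F, H))
        assert set(www.hull_vertices) == {"B", "C"}
        assert www.sector_of_env["e1"] == "B"
        assert www.sector_of_env["e2"] == "C"
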