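import numpy as np
import pandas as pd
import pytest

from metgei import asv, delineate_mega_envs, fit_ammi, gsi, impute_missing_em
from metgei.errors import ValidationError

from conftest import make_table
from oracles import asv_direct, interaction_ss_direct


def _rank2_table(rng, G=10, E=7, lambdas=(6.0, 3.0), noise=0.0):
    def centered_orth(n, k):
        A = rng.standard_normal((n, k))
        A -= A.mean(axis=0)
        Q, _ = np.linalg.qr(A)
        return Q[:, :k]

    a = centered_orth(G, 2)
    c = centered_orth(E, 2)
    g = rng.normal(0, 2, G)
    e = rng.normal(0, 3, E)
    vals = 20 + np.add.outer(g, e) + a @ np.diag(lambdas) @ c.T
    if noise:
        vals = vals + rng.normal(0, noise, (G, E))
    return make_table(vals)


class TestFitAmmi:
    def test_additive_table_zero_lambdas(self, rng):
        tab = make_table(10 + np.add.outer(rng.normal(0, 2, 5), rng.normal(0, 3, 4)))
        fit = fit_ammi(tab)
        assert np.allclose(fit.singular_values, 0.0, atol=1e-10)

    def test_rank2_noiseless_recovery(self, rng):
        tab = _rank2_table(rng)
        fit = fit_ammi(tab, K=2)
        assert np.allclose(fit.singular_values[:2], [6.0, 3.0], atol=1e-8)
        pct = fit.ss_table.loc[["IPC1", "IPC2"], "pct_interaction"].sum()
        assert pct == pytest.approx(100.0, abs=1e-6)

    def test_lambda_sq_equals_interaction_ss_oracle(self, rng):
        for _ in range(5):
            vals = rng.normal(10, 4, (3, 4))
            fit = fit_ammi(make_table(vals))
            assert fit.interaction_ss == pytest.approx(
                interaction_ss_direct(vals), abs=1e-8
            )

    def test_ss_conservation_and_df(self, rng):
        G, E, K = 8, 6, 3
        fit = fit_ammi(make_table(rng.normal(10, 4, (G, E))), K=K)
        ss = fit.ss_table
        per_axis = ss.loc[[f"IPC{k+1}" for k in range(K)], "SS"].sum()
        assert per_axis + ss.loc["interaction_residual", "SS"] == pytest.approx(
            ss.loc["interaction", "SS"], abs=1e-8
        )
        for k in range(K):
            assert ss.loc[f"IPC{k+1}", "df"] == G + E - 1 - 2 * (k + 1)

    def test_missing_cells_rejected(self, rng):
        vals = rng.normal(10, 2, (4, 4))
        vals[1, 2] = np.nan
        with pytest.raises(ValidationError, match="missing"):
            fit_ammi(make_table(vals))

    def test_orthonormal_scores(self, study_table):
        fit = fit_ammi(study_table, K=2)
        U = fit.genotype_scores.to_numpy()
        V = fit.env_loadings.to_numpy()
        assert np.allclose(U.T @ U, np.eye(U.shape[1]), atol=1e-8)
        assert np.allclose(V.T @ V, np.eye(V.shape[1]), atol=1e-8)


class TestAsv:
    def test_zero_scores_zero_asv(self, rng):
        tab = _rank2_table(rng)
        fit = fit_ammi(tab, K=2)
        fit.genotype_scores.iloc[0, :] = 0.0
        vals = asv(fit)
        assert vals.iloc[0] == 0.0

    def test_pythagorean_case(self):
        # equal axis SS and scaled scores (3, 4) -> ASV 5
        assert asv_direct(1.0, 1.0, 3.0, 4.0) == pytest.approx(5.0)

    def test_formula_oracle_random_table(self, rng):
        fit = fit_ammi(make_table(rng.normal(10, 4, (6, 5))), K=2)
        got = asv(fit)
        S = fit.scaled_scores(0.5, k=2).to_numpy()
        l1, l2 = fit.singular_values[:2]
        for i, g in enumerate(fit.genotypes):
            assert got[g] == pytest.approx(asv_direct(l1, l2, S[i, 0], S[i, 1]), abs=1e-10)

    def test_sign_flip_invariance(self, rng):
        fit = fit_ammi(make_table(rng.normal(10, 4, (6, 5))), K=2)
        base = asv(fit)
        fit.genotype_scores.iloc[:, 0] *= -1
        fit.env_loadings.iloc[:, 0] *= -1
        assert np.allclose(asv(fit), base, atol=1e-12)

    def test_degenerate_second_axis(self, rng):
        tab = _rank2_table(rng, lambdas=(5.0, 0.0))
        fit = fit_ammi(tab, K=2)
        with pytest.warns(UserWarning, match="ASV undefined"):
            vals = asv(fit)
        assert vals.isna().all()


class TestGsi:
    def test_double_winner_minimal(self, rng):
        tab = _rank2_table(rng, G=6, E=5)
        fit = fit_ammi(tab, K=2)
        a = asv(fit)
        # force one genotype to be best on both criteria
        fit.genotype_main.iloc[2] = fit.genotype_main.max() + 5
        a.iloc[2] = 0.0
        stab = gsi(fit, a)
        best = stab.table.iloc[0]
        assert best["gsi"] == 2
        assert stab.table["gsi"].min() == 2

    def test_tie_rule_integral_gsi(self):
        fit = fit_ammi(make_table([[10, 12, 8], [11, 10, 9], [9, 11, 13]]), K=2)
        a = asv(fit)
        stab = gsi(fit, a)
        assert stab.table["gsi"].dtype.kind in "iu" or (
            stab.table["gsi"] == stab.table["gsi"].round()).all()
        assert sorted(stab.table["rank_yield"]) == [1, 2, 3]

    def test_rank_and_sum_oracle(self, rng):
        tab = _rank2_table(rng, G=8, E=6)
        fit = fit_ammi(tab, K=2)
        a = asv(fit)
        stab = gsi(fit, a).table
        mean_perf = (fit.grand_mean + fit.genotype_main)
        for g in stab.index:
            ry = 1 + sum(
                (mean_perf[o], o) > (mean_perf[g], g) for o in stab.index if o != g
            )
            rasv = 1 + sum((a[o], o) < (a[g], g) for o in stab.index if o != g)
            assert stab.loc[g, "gsi"] == ry + rasv


class TestMegaEnv:
    def test_additive_single_winner(self, rng):
        tab = make_table(10 + np.add.outer(rng.normal(0, 2, 5), rng.normal(0, 3, 6)))
        fit = fit_ammi(tab, K=2)
        mega = delineate_mega_envs(fit)
        assert mega.n_mega_environments == 1

    def test_constructed_two_groups(self):
        # genotype A wins envs e1-e3, B wins e4-e5 by construction
        vals = np.array([
            [20, 20, 20, 10, 10],   # A
            [10, 10, 10, 20, 20],   # B
            [12, 12, 12, 12, 12],   # C
        ], float)
        fit = fit_ammi(make_table(vals, genotypes=["A", "B", "C"]), K=2)
        mega = delineate_mega_envs(fit)
        assert mega.groups == {"A": ["e1", "e2", "e3"], "B": ["e4", "e5"]}

    def test_group_count_bounded_by_envs(self, rng):
        tab = _rank2_table(rng, G=12, E=6)
        mega = delineate_mega_envs(fit_ammi(tab, K=2))
        assert mega.n_mega_environments <= 6
        # groups form a partition
        envs = sorted(e for grp in mega.groups.values() for e in grp)
        assert envs == sorted(tab.environments)


class TestImputation:
    def test_complete_table_unchanged(self, rng):
        tab = make_table(rng.normal(10, 3, (5, 4)))
        out = impute_missing_em(tab)
        assert np.array_equal(out.means, tab.means)

    def test_rank2_reconstruction(self, rng):
        tab = _rank2_table(rng, G=12, E=9)
        truth = tab.means.copy()
        vals = truth.copy()
        holes = [(1, 2), (4, 7), (9, 0), (6, 4), (11, 8)]  # ~5% of cells
        for i, j in holes:
            vals[i, j] = np.nan
        out = impute_missing_em(make_table(vals), K=2, tol=1e-10, max_iter=2000)
        for i, j in holes:
            assert out.means[i, j] == pytest.approx(truth[i, j], abs=1e-4)

    def test_half_missing_refused(self, rng):
        vals = rng.normal(10, 3, (6, 6))
        vals[np.unravel_index(np.arange(18), vals.shape)] = np.nan
        with pytest.raises(ValidationError, match="ceiling"):
            impute_missing_em(make_table(vals))
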