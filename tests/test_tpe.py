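import numpy as np
import pandas as pd
import pytest

from metgei import (SimulationConfig, accuracy_curve, cluster_environments, cullis_h2,
                    rank_environments, simulate_met)
from metgei.mixed import Factor, MixedModel, design_fixed, mean_pairwise_pev_difference
from metgei.tpe import env_cullis_h2, fit_env_genotype_model

from conftest import BASE_SEED, small_config


class TestCullisH2:
    def test_perfect_replication_limit(self):
        h2, flag = cullis_h2(0.0, 2.0)
        assert h2 == 1.0 and not flag

    def test_zero_when_vbar_is_twice_varg(self):
        h2, flag = cullis_h2(4.0, 2.0)
        assert h2 == 0.0 and not flag

    def test_boundary_varg(self):
        h2, flag = cullis_h2(1.0, 0.0)
        assert h2 == 0.0 and flag

    def test_clipping_flagged(self):
        h2, flag = cullis_h2(5.0, 2.0)
        assert h2 == 0.0 and flag

    def test_balanced_toy_matches_direct_mme(self):
        # 5 genotypes x 3 reps: compare against dense mixed-model equations
        data, _ = simulate_met(SimulationConfig(
            seed=BASE_SEED + 5, n_genotypes=5, trials=[("A", 2019)],
            missing_trials=[], n_two_rep_trials=0, var_env=0, K=0,
            var_ge_noise=0, var_g=3.0, var_error=2.0))
        env = data.environments[0]
        fit = fit_env_genotype_model(data, env, "FYLD")
        h2, _ = env_cullis_h2(fit)
        # direct MME on the same data at the fitted variances
        sub = data.df
        X = design_fixed(sub, "prop_harvested", rep_fixed=True)
        Z = Factor.from_series(sub["genotype"]).dummies()
        s2 = fit.resid_var
        vg = fit.var_components["genotype"]
        W = np.hstack([X, Z])
        C = W.T @ W / s2
        p = X.shape[1]
        C[np.arange(p, p + 5), np.arange(p, p + 5)] += 1.0 / vg
        pev = np.linalg.inv(C)[p:, p:]
        vbar = mean_pairwise_pev_difference(pev)
        assert h2 == pytest.approx(1.0 - vbar / (2 * vg), abs=1e-8)

    def test_close_to_entry_mean_h2_when_balanced(self):
        # balanced, well-replicated: Cullis H2 ~ var_g / (var_g + var_e / r)
        data, _ = simulate_met(SimulationConfig(
            seed=BASE_SEED, n_genotypes=80, trials=[("A", 2019)],
            missing_trials=[], n_two_rep_trials=0, var_env=0, K=0,
            var_ge_noise=0, var_g=4.0, var_error=4.0))
        fit = fit_env_genotype_model(data, data.environments[0], "FYLD")
        h2, _ = env_cullis_h2(fit)
        vg, ve = fit.var_components["genotype"], fit.resid_var
        entry_mean = vg / (vg + ve / 3)
        assert h2 == pytest.approx(entry_mean, rel=0.02)


class TestRankEnvironments:
    def test_row_count_and_rank_sums(self, small_sim):
        data, _ = small_sim
        out = rank_environments(data, "FYLD")
        assert len(out) == len(data.environments)
        assert (out["sum_ranks"] == out["rank_r"] + out["rank_h2"]).all()
        assert sorted(out["rank_r"]) == list(range(1, len(out) + 1))

    def test_noisy_environment_ranks_at_bottom(self):
        # one environment with 4x the error variance drops to the bottom of
        # the representativeness ranking (bottom 3 of 17; strictly last place
        # is not reliable at this variance ratio)
        cfg = SimulationConfig(seed=1)
        envs = cfg.environments()
        het = {e: 4.0 for e in envs}
        het[envs[7]] = 16.0
        hits = 0
        n_seeds = 10
        for k in range(n_seeds):
            data, _ = simulate_met(SimulationConfig(seed=BASE_SEED + k,
                                                    error_heterogeneity=het))
            out = rank_environments(data, "FYLD")
            pos = list(out.index).index(envs[7]) + 1
            hits += pos >= len(out) - 2
        assert hits >= 9


class TestAccuracyCurve:
    def test_small_scale_curve(self, small_sim):
        data, _ = small_sim
        curve = accuracy_curve(data, "FYLD", n_samples=6, seed=11)
        c = curve.curve
        assert list(c.index) == [1, 2, 3, 4, 5]
        # full set reproduces the reference BLUPs exactly
        assert c.loc[5, "mean_r"] == pytest.approx(1.0, abs=1e-6)
        # broadly increasing
        assert c.loc[4, "mean_r"] > c.loc[1, "mean_r"]

    def test_reproducible_from_seed(self, small_sim):
        data, _ = small_sim
        c1 = accuracy_curve(data, "FYLD", n_samples=3, seed=7).curve
        c2 = accuracy_curve(data, "FYLD", n_samples=3, seed=7).curve
        pd.testing.assert_frame_equal(c1, c2)


class TestClusterEnvironments:
    def test_duplicated_environments_merge_first(self, rng):
        # feed a fixed GE BLUP matrix via a stub joint fit
        from metgei.joint import VarianceComponents
        from metgei.mixed import MixedFit

        G, E = 10, 5
        M = rng.normal(0, 1, (G, E))
        M[:, 1] = M[:, 0] + rng.normal(0, 1e-6, G)  # e2 duplicates e1
        labels, values = [], []
        for i in range(G):
            for j in range(E):
                labels.append(f"g{i}:e{j}")
                values.append(M[i, j])
        fit = MixedFit(var_components={}, resid_var=1.0, loglik=0.0,
                       fixed_effects=np.zeros(1), blups={"gei": pd.Series(values, index=labels)},
                       n_obs=G * E, converged=True, boundary={}, n_iter=1)
        vc = VarianceComponents({}, {}, 0.0, fit=fit)
        clus = cluster_environments(None, None, n_clusters=2, joint_vc=vc)
        # first merge joins e0 and e1 at ~0 height
        first = clus.linkage[0]
        merged = {clus.correlation.index[int(first[0])], clus.correlation.index[int(first[1])]}
        assert merged == {"e0", "e1"}
        assert first[2] < 1e-2
        # ultrametric heights non-decreasing
        assert (np.diff(clus.linkage[:, 2]) >= -1e-12).all()

    def test_planted_blocks_recovered(self):
        hits = 0
        for k in range(5):
            cfg = small_config(n_genotypes=15, seed=BASE_SEED + 50 + k)
            envs = cfg.environments()
            rng = np.random.default_rng(BASE_SEED + 900 + k)
            delta = rng.normal(0, 1.5, 15)
            signs = pd.Series([1.0, 1.0, 1.0, -1.0, -1.0], index=envs)
            ge = pd.DataFrame(np.outer(delta, signs),
                              index=[f"G{i+1:03d}" for i in range(15)], columns=envs)
            cfg.ge_matrix = ge
            data, _ = simulate_met(cfg)
            clus = cluster_environments(data, "FYLD", n_clusters=2)
            planted = signs.map({1.0: "a", -1.0: "b"})
            tab = pd.crosstab(clus.labels, planted[clus.labels.index])
            pure = (tab.astype(bool).sum(axis=1) == 1).all()
            hits += bool(pure and len(tab) == 2)
        assert hits >= 4
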