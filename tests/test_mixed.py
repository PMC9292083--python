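"""The REML engine against independent restricted-likelihood oracles."""

import subprocess
import sys

import numpy as np
import pandas as pd
import pytest

from metgei import SimulationConfig, simulate_met
from metgei.mixed import Factor, MixedModel, design_fixed, mean_pairwise_pev_difference

from conftest import BASE_SEED, small_config
from oracles import coordinate_grid_reml, grid_reml_2d, neg2_reml_dense


def _tiny_trial(seed=BASE_SEED, n_g=4, n_rep=3, var_g=3.0, var_e=2.0):
    rng = np.random.default_rng(seed)
    g = rng.normal(0, np.sqrt(var_g), n_g)
    rows = []
    for r in range(n_rep):
        rep_eff = rng.normal(0, 0.5)
        for i in range(n_g):
            rows.append((f"g{i}", r + 1, 10 + rep_eff + g[i] + rng.normal(0, np.sqrt(var_e))))
    return pd.DataFrame(rows, columns=["genotype", "replicate", "y"])


class TestAgainstDenseOracle:
    def test_loglik_identity_homogeneous(self, small_sim):
        data, _ = small_sim
        sub = data.df
        X = design_fixed(sub, "prop_harvested", rep_fixed=False)
        gt = Factor.from_series(sub["genotype"])
        env = Factor.from_series(sub["environment"])
        terms = {"genotype": gt, "environment": env, "gei": Factor.cross(gt, env)}
        fit = MixedModel(sub["FYLD"].to_numpy(), X, terms).fit()
        Zs = [f.dummies() for f in terms.values()]
        vs = [max(fit.var_components[t], 1e-10) for t in terms]
        dense = neg2_reml_dense(sub["FYLD"], X, Zs, vs,
                                np.full(len(sub), fit.resid_var))
        assert -2 * fit.loglik == pytest.approx(dense, abs=1e-7)

    def test_loglik_identity_heterogeneous(self, small_sim):
        data, _ = small_sim
        sub = data.df
        X = design_fixed(sub, "prop_harvested", rep_fixed=False)
        gt = Factor.from_series(sub["genotype"])
        env = Factor.from_series(sub["environment"])
        terms = {"genotype": gt, "environment": env, "gei": Factor.cross(gt, env)}
        fit = MixedModel(sub["FYLD"].to_numpy(), X, terms, resid_factor=env).fit()
        Zs = [f.dummies() for f in terms.values()]
        vs = [max(fit.var_components[t], 1e-10) for t in terms]
        resid = fit.resid_var.loc[sub["environment"]].to_numpy()
        dense = neg2_reml_dense(sub["FYLD"], X, Zs, vs, resid)
        assert -2 * fit.loglik == pytest.approx(dense, abs=1e-7)

    def test_single_factor_matches_zoom_grid(self):
        df = _tiny_trial()
        X = design_fixed(df, None, rep_fixed=True)
        gfac = Factor.from_series(df["genotype"])
        fit = MixedModel(df["y"].to_numpy(), X, {"genotype": gfac}).fit()
        vg, ve, _ = grid_reml_2d(df["y"].to_numpy(), X, gfac.dummies())
        assert fit.var_components["genotype"] == pytest.approx(vg, abs=1e-4)
        assert fit.resid_var == pytest.approx(ve, abs=1e-4)

    def test_joint_toy_matches_coordinate_grid(self):
        # 3 genotypes x 3 environments x 2 reps
        cfg = small_config(
            n_genotypes=3,
            trials=[("A", 2018), ("B", 2018), ("C", 2018)],
            n_two_rep_trials=3, K=1, lambdas=[2.0],
            var_g=2.0, var_env=3.0, var_block=0.3, var_ge_noise=0.2, var_error=1.0,
        )
        data, _ = simulate_met(cfg)
        sub = data.df
        X = design_fixed(sub, "prop_harvested", rep_fixed=False)
        gt = Factor.from_series(sub["genotype"])
        env = Factor.from_series(sub["environment"])
        terms = {
            "genotype": gt,
            "environment": env,
            "block": Factor.from_series(sub["environment"].astype(str) + "/"
                                        + sub["replicate"].astype(str)),
            "gei": Factor.cross(gt, env),
        }
        fit = MixedModel(sub["FYLD"].to_numpy(), X, terms).fit()
        Zs = [f.dummies() for f in terms.values()]
        gvars, gres, gneg2 = coordinate_grid_reml(sub["FYLD"].to_numpy(), X, Zs)
        # the engine should do at least as well as the grid maximizer ...
        assert -2 * fit.loglik <= gneg2 + 1e-6
        # ... and land on the same components
        for (t, v), gv in zip(fit.var_components.items(), gvars):
            assert v == pytest.approx(gv, rel=1e-3, abs=1e-3)
        assert fit.resid_var == pytest.approx(gres, rel=1e-3, abs=1e-3)


class TestAgainstLme4:
    def test_joint_components_match_lme4(self, tmp_path, small_sim):
        data, _ = small_sim
        df = data.df.copy()
        df["p_c"] = df["prop_harvested"] - df["prop_harvested"].mean()
        df["block"] = df["environment"].astype(str) + "/" + df["replicate"].astype(str)
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        out = tmp_path / "vc.csv"
        script = f"""
d <- read.csv("{csv}")
suppressMessages(library(lme4))
m <- lmer(FYLD ~ 1 + p_c + (1|genotype) + (1|environment) + (1|block)
          + (1|genotype:environment), data=d, REML=TRUE)
vc <- as.data.frame(VarCorr(m))
write.csv(vc[,c("grp","vcov")], "{out}", row.names=FALSE)
"""
        rfile = tmp_path / "chk.R"
        rfile.write_text(script)
        proc = subprocess.run(["Rscript", str(rfile)], capture_output=True, text=True)
        if proc.returncode != 0:
            pytest.skip(f"Rscript/lme4 unavailable: {proc.stderr[-200:]}")
        ref = pd.read_csv(out).set_index("grp")["vcov"]
        X = design_fixed(df, "prop_harvested", rep_fixed=False)
        gt = Factor.from_series(df["genotype"])
        env = Factor.from_series(df["environment"])
        terms = {"genotype": gt, "environment": env,
                 "block": Factor.from_series(df["block"]),
                 "gei": Factor.cross(gt, env)}
        fit = MixedModel(df["FYLD"].to_numpy(), X, terms).fit()
        assert fit.var_components["genotype"] == pytest.approx(ref["genotype"], rel=1e-3)
        assert fit.var_components["environment"] == pytest.approx(ref["environment"], rel=1e-3)
        assert fit.var_components["block"] == pytest.approx(ref["block"], rel=1e-2)
        assert fit.var_components["gei"] == pytest.approx(ref["genotype:environment"], rel=1e-3)
        assert fit.resid_var == pytest.approx(ref["Residual"], rel=1e-3)


class TestPev:
    def test_mean_pairwise_pev_matches_brute_force(self, rng):
        P = rng.standard_normal((6, 6))
        P = P @ P.T
        q = P.shape[0]
        acc = [P[i, i] + P[j, j] - 2 * P[i, j] for i in range(q) for j in range(i + 1, q)]
        assert mean_pairwise_pev_difference(P) == pytest.approx(np.mean(acc), abs=1e-12)

    def test_pev_from_dense_inverse(self):
        # PEV block equals the genotype block of C^-1 computed densely
        df = _tiny_trial(n_g=5)
        X = design_fixed(df, None, rep_fixed=True)
        gfac = Factor.from_series(df["genotype"])
        fit = MixedModel(df["y"].to_numpy(), X, {"genotype": gfac}).fit(
            pev_terms=("genotype",)
        )
        Z = gfac.dummies()
        s2, vg = fit.resid_var, max(fit.var_components["genotype"], 1e-12)
        W = np.hstack([X, Z])
        C = W.T @ W / s2
        p = X.shape[1]
        C[np.arange(p, p + 5), np.arange(p, p + 5)] += 1.0 / vg
        Cinv = np.linalg.inv(C)
        assert np.allclose(fit.pev("genotype"), Cinv[p:, p:], atol=1e-8)
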