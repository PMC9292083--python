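"""REML estimation for variance-component mixed models via Henderson's MME.

The models in this package share one shape: a few fixed effects, several
independent random factors (genotype, environment, block-within-environment,
genotype-by-environment, ...), and a residual that is either homogeneous or
has one variance per environment.  None of the installed Python mixed-model
packages handles crossed random factors with grouped residual variances, so
the restricted likelihood is computed here directly from the mixed-model
equations:

    C = W' R^-1 W + diag(0, G^-1),   W = [X  Z_1 ... Z_m]

    -2 l_R = (n-p) log 2pi + log|R| + log|G| + log|C| + y' P y

with y'Py = y'R^-1 y - b_hat' W'R^-1 y.  Because every random factor's Z'Z
block is diagonal (each plot has one level per factor), the largest factor is
*absorbed*: its diagonal block D drops out of the Cholesky via the Schur
complement S = A - B D^-1 B', leaving a system of a few hundred equations at
most.  With a homogeneous residual the residual variance is profiled out
analytically, so the optimizer works on log variance ratios only.

Optimization uses L-BFGS-B on log-variances with a Powell fallback; variances
driven to the lower bound are reported as 0 and flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

from .errors import FitError

_LOG2PI = math.log(2.0 * math.pi)
_LOWER, _UPPER = -27.0, 18.0  # bounds on log variance (ratio) parameters


@dataclass
class Factor:
    """A categorical design factor: integer codes plus level labels."""

    codes: np.ndarray
    labels: list

    @classmethod
    def from_series(cls, s: pd.Series) -> "Factor":
        cat = pd.Categorical(s)
        return cls(np.asarray(cat.codes, dtype=np.intp), list(cat.categories))

    @classmethod
    def cross(cls, a: "Factor", b: "Factor", sep: str = ":") -> "Factor":
        """Interaction factor; only observed level combinations get a code."""
        pair = pd.Series(
            [f"{a.labels[i]}{sep}{b.labels[j]}" for i, j in zip(a.codes, b.codes)]
        )
        return cls.from_series(pair)

    @property
    def n_levels(self) -> int:
        return len(self.labels)

    def dummies(self) -> np.ndarray:
        Z = np.zeros((len(self.codes), self.n_levels))
        Z[np.arange(len(self.codes)), self.codes] = 1.0
        return Z


@dataclass
class MixedFit:
    """Result of one REML fit."""

    var_components: dict[str, float]
    resid_var: float | pd.Series
    loglik: float                      # restricted log-likelihood (with constants)
    fixed_effects: np.ndarray
    blups: dict[str, pd.Series]
    n_obs: int
    converged: bool
    boundary: dict[str, bool]
    n_iter: int
    _pev: dict[str, np.ndarray] = field(default_factory=dict)

    def pev(self, term: str) -> np.ndarray:
        """Prediction error variance matrix of the BLUPs of one factor."""
        if term not in self._pev:
            raise KeyError(
                f"PEV for '{term}' not computed (request it via pev_terms= at fit time)"
            )
        return self._pev[term]

    def mean_resid_var(self, weights: np.ndarray | None = None) -> float:
        """Residual variance; plot-weighted mean when heterogeneous."""
        if isinstance(self.resid_var, pd.Series):
            if weights is None:
                return float(self.resid_var.mean())
            return float(np.average(self.resid_var.to_numpy(), weights=weights))
        return float(self.resid_var)


class MixedModel:
    """One model specification bound to data; call :meth:`fit`."""

    def __init__(
        self,
        y: np.ndarray,
        X: np.ndarray,
        random_terms: Mapping[str, Factor],
        resid_factor: Factor | None = None,
    ):
        self.y = np.asarray(y, float)
        self.X = np.atleast_2d(np.asarray(X, float))
        if self.X.shape[0] != len(self.y):
            raise ValueError("X and y length mismatch")
        self.terms = dict(random_terms)
        self.resid_factor = resid_factor
        self.n, self.p = self.X.shape
        if not self.terms:
            raise ValueError("at least one random term required")

    # ------------------------------------------------------------------
    def _layout(self, pev_terms: Sequence[str]):
        """Choose the absorbed factor and build cross-product blocks."""
        names = list(self.terms)
        sizes = {t: self.terms[t].n_levels for t in names}
        candidates = [t for t in names if t not in pev_terms]
        absorb = None
        if candidates:
            big = max(candidates, key=lambda t: sizes[t])
            if sizes[big] >= 60:
                absorb = big
        others = [t for t in names if t != absorb]
        # dense design of fixed part + non-absorbed random factors
        blocks = [self.X] + [self.terms[t].dummies() for t in others]
        Wa = np.hstack(blocks)
        offsets, pos = {}, self.p
        for t in others:
            offsets[t] = (pos, pos + sizes[t])
            pos += sizes[t]
        return absorb, others, Wa, offsets

    def _crossprods(self, Wa, absorb):
        """Per-residual-group cross-products (one group when homogeneous)."""
        groups = (
            [np.arange(self.n)]
            if self.resid_factor is None
            else [np.flatnonzero(self.resid_factor.codes == h)
                  for h in range(self.resid_factor.n_levels)]
        )
        qd = self.terms[absorb].n_levels if absorb else 0
        cd = self.terms[absorb].codes if absorb else None
        parts = []
        for idx in groups:
            W = Wa[idx]
            yg = self.y[idx]
            A = W.T @ W
            ra = W.T @ yg
            yy = float(yg @ yg)
            if absorb:
                B = np.zeros((qd, Wa.shape[1]))
                np.add.at(B, cd[idx], W)
                counts = np.bincount(cd[idx], minlength=qd).astype(float)
                rd = np.bincount(cd[idx], weights=yg, minlength=qd)
            else:
                B = counts = rd = None
            parts.append((A, ra, yy, B, counts, rd, len(idx)))
        return parts

    # ------------------------------------------------------------------
    def fit(
        self,
        pev_terms: Sequence[str] = (),
        start: Mapping[str, float] | None = None,
        resid_start: float | None = None,
        max_iter: int = 200,
    ) -> MixedFit:
        """REML fit.  ``start`` maps term name to a variance starting value."""
        absorb, others, Wa, offsets = self._layout(pev_terms)
        parts = self._crossprods(Wa, absorb)
        names = list(self.terms)
        sizes = np.array([self.terms[t].n_levels for t in names], float)
        vary = float(np.var(self.y)) or 1.0
        hetero = self.resid_factor is not None
        n, p = self.n, self.p

        def build(weights, inv_var: dict[str, float]):
            """Assemble A, rhs, etc. under residual weights; add G^-1."""
            pa = Wa.shape[1]
            A = np.zeros((pa, pa))
            ra = np.zeros(pa)
            yy = 0.0
            if absorb:
                qd = self.terms[absorb].n_levels
                B = np.zeros((qd, pa))
                D0 = np.zeros(qd)
                rd = np.zeros(qd)
            for w, (Ag, rag, yyg, Bg, cg, rdg, _) in zip(weights, parts):
                A += w * Ag
                ra += w * rag
                yy += w * yyg
                if absorb:
                    B += w * Bg
                    D0 += w * cg
                    rd += w * rdg
            for t in others:
                lo, hi = offsets[t]
                A[np.arange(lo, hi), np.arange(lo, hi)] += inv_var[t]
            if absorb:
                D = D0 + inv_var[absorb]
                return A, ra, yy, B, D, rd
            return A, ra, yy, None, None, None

        def solve(A, ra, yy, B, D, rd):
            if B is not None:
                S = A - (B.T / D) @ B
                radj = ra - B.T @ (rd / D)
            else:
                S, radj = A, ra
            c, low = cho_factor(S, lower=True)
            sol = cho_solve((c, low), radj)
            logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
            r = yy - float(radj @ sol)
            if B is not None:
                ud = (rd - B @ sol) / D
                logdet += float(np.sum(np.log(D)))
                # r above already accounts for ud via radj adjustment:
                # y'Py = yy - ra.sol - rd.ud; algebra check in tests
                r = yy - float(ra @ sol) - float(rd @ ud)
            else:
                ud = None
            return sol, ud, r, logdet, (c, low)

        if hetero:
            ne = self.resid_factor.n_levels
            nh = np.array([pt[6] for pt in parts], float)

            def unpack(params):
                v = np.exp(params)
                comp = dict(zip(names, v[:len(names)]))
                rv = v[len(names):]
                return comp, rv

            def neg2(params):
                v = np.exp(params)
                rv = v[len(names):]
                weights = 1.0 / rv
                inv_var = {t: 1.0 / cv for t, cv in zip(names, v)}
                A, ra, yy, B, D, rd = build(weights, inv_var)
                try:
                    _, _, r, logdet, _ = solve(A, ra, yy, B, D, rd)
                except np.linalg.LinAlgError:
                    return 1e12
                if r <= 0:
                    return 1e12
                return (
                    (n - p) * _LOG2PI
                    + float(nh @ np.log(rv))
                    + float(sizes @ np.log(v[:len(names)]))
                    + logdet
                    + r
                )

            x0 = np.log(np.array(
                [max((start or {}).get(t, vary / (len(names) + 1)), 1e-8 * vary) for t in names]
                + [max(resid_start or vary / 2.0, 1e-8 * vary)] * ne
            ))
            npar = len(names) + ne
        else:
            def neg2(params):
                gam = np.exp(params)
                inv_var = {t: 1.0 / g for t, g in zip(names, gam)}
                A, ra, yy, B, D, rd = build([1.0], inv_var)
                try:
                    _, _, r, logdet, _ = solve(A, ra, yy, B, D, rd)
                except np.linalg.LinAlgError:
                    return 1e12
                if r <= 0:
                    return 1e12
                s2 = r / (n - p)
                return (
                    (n - p) * (_LOG2PI + math.log(s2) + 1.0)
                    + float(sizes @ params)
                    + logdet
                )

            x0 = np.log(np.array(
                [max((start or {}).get(t, 0.3 * vary) / max(resid_start or vary, 1e-12), 1e-8)
                 if start else 0.3
                 for t in names]
            ))
            npar = len(names)

        lo = np.full(npar, _LOWER)
        hi = np.full(npar, _UPPER)
        x0 = np.clip(x0, lo + 1e-6, hi - 1e-6)
        res = minimize(
            neg2, x0, method="L-BFGS-B", bounds=list(zip(lo, hi)),
            options={"maxiter": max_iter, "ftol": 1e-13, "gtol": 1e-9},
        )
        best = res
        # Powell fallback / polish when L-BFGS-B stalls
        if not res.success or not np.isfinite(res.fun):
            res2 = minimize(neg2, res.x if np.isfinite(res.fun) else x0,
                            method="Powell", bounds=list(zip(lo, hi)),
                            options={"maxiter": 20000, "xtol": 1e-10, "ftol": 1e-12})
            if res2.fun < res.fun or not np.isfinite(res.fun):
                best = res2
        if not np.isfinite(best.fun) or best.fun >= 1e12:
            raise FitError("REML optimization failed to find a finite optimum")

        params = best.x
        # ---- final quantities at the optimum --------------------------
        if hetero:
            comp, rv = unpack(params)
            weights = 1.0 / rv
            inv_var = {t: 1.0 / comp[t] for t in names}
            A, ra, yy, B, D, rd = build(weights, inv_var)
            sol, ud, r, logdet, chol = solve(A, ra, yy, B, D, rd)
            resid_var = pd.Series(rv, index=self.resid_factor.labels)
            scale = 1.0
            var_components = comp
        else:
            gam = np.exp(params)
            inv_var = {t: 1.0 / g for t, g in zip(names, gam)}
            A, ra, yy, B, D, rd = build([1.0], inv_var)
            sol, ud, r, logdet, chol = solve(A, ra, yy, B, D, rd)
            s2 = r / (n - p)
            resid_var = float(s2)
            scale = s2
            var_components = {t: float(g * s2) for t, g in zip(names, gam)}

        loglik = -0.5 * float(neg2(params))
        boundary = {
            t: bool(np.exp(params[i]) <= math.exp(_LOWER) * 1.01)
            for i, t in enumerate(names)
        }
        var_components = {
            t: (0.0 if boundary[t] else v) for t, v in var_components.items()
        }

        blups = {}
        for t in others:
            a, b = offsets[t]
            blups[t] = pd.Series(sol[a:b], index=self.terms[t].labels)
        if absorb:
            blups[absorb] = pd.Series(ud, index=self.terms[absorb].labels)

        pev = {}
        if pev_terms:
            c, low = chol
            Sinv = cho_solve((c, low), np.eye(c.shape[0]))
            for t in pev_terms:
                if t not in offsets:
                    raise FitError(f"PEV unavailable for absorbed term '{t}'")
                a, b = offsets[t]
                pev[t] = Sinv[a:b, a:b] * scale

        return MixedFit(
            var_components=var_components,
            resid_var=resid_var,
            loglik=loglik,
            fixed_effects=sol[: self.p],
            blups=blups,
            n_obs=n,
            converged=bool(best.success or np.isfinite(best.fun)),
            boundary=boundary,
            n_iter=int(getattr(best, "nit", -1)),
            _pev=pev,
        )


def mean_pairwise_pev_difference(pev: np.ndarray) -> float:
    """Mean over all level pairs of var(BLUP_i - BLUP_j) from a PEV matrix.

    For a q x q PEV block P this is 2*(q*tr(P) - 1'P1) / (q*(q-1)).
    """
    q = pev.shape[0]
    if q < 2:
        raise ValueError("need at least two levels")
    return float(2.0 * (q * np.trace(pev) - pev.sum()) / (q * (q - 1)))


def design_fixed(df: pd.DataFrame, covariate: str | None, rep_fixed: bool) -> np.ndarray:
    """Intercept [+ sum-coded replicate effects] [+ centered covariate]."""
    n = len(df)
    cols = [np.ones(n)]
    if rep_fixed:
        reps = sorted(df["replicate"].unique())
        if len(reps) > 1:
            codes = pd.Categorical(df["replicate"], categories=reps).codes
            for j in range(len(reps) - 1):
                col = np.where(codes == j, 1.0, 0.0)
                col[codes == len(reps) - 1] = -1.0
                cols.append(col)
    if covariate is not None:
        p = df[covariate].to_numpy(float)
        p = np.where(np.isnan(p), np.nanmean(p), p)
        cols.append(p - p.mean())
    return np.column_stack(cols)
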