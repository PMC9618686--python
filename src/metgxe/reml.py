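"""REML estimation for crossed variance-component models.

Fits the linear mixed model

    y = X b + sum_c Z_c u_c + e,     u_c ~ N(0, sigma_c^2 I),  e ~ N(0, sigma_e^2 I)

by residual maximum likelihood, with every random term having an identity
covariance among its levels (no pedigree/genomic relationship matrices).
This is the model class behind both the random-genotype analysis (variance
components, BLUPs, heritability) and the per-environment fixed-genotype
adjusted-means (BLUE) fits.

Algorithm
---------
All computation runs on Henderson's mixed-model equations (MME).  With
``W = [X, Z]`` and ``C`` the MME coefficient matrix, the REML deviance is

    -2 l_R = n log s2e + sum_c q_c log s2c + log|C| + y' P y   (+ const)

which needs only one Cholesky factorisation of ``C`` per evaluation; its
gradient follows from the inverse-MME diagonal blocks.  The optimiser is a
short boundary-safe EM warm start followed by an L-BFGS-B polish with the
analytic gradient.  Components driven to the boundary are pinned at exactly
zero (an explicit, reportable state) and excluded from the final polish.
Standard errors come from the observed information (numerical Hessian of the
REML log-likelihood at the optimum); z-tests for variance components are
one-sided.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

__all__ = ["VarianceComponentModel", "VCResults", "ConvergenceError", "AliasError"]


class ConvergenceError(RuntimeError):
    """REML failed to converge; carries the iteration trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


class AliasError(ValueError):
    """Singular fixed-effects design; names the aliased columns."""


def _chol_inverse(L):
    """Inverse of A from its lower Cholesky factor (LAPACK dpotri)."""
    inv, info = linalg.lapack.dpotri(L, lower=1)
    if info != 0:  # pragma: no cover - defensive
        raise np.linalg.LinAlgError("dpotri failed")
    # dpotri fills one triangle only
    inv = np.tril(inv) + np.tril(inv, -1).T
    return inv


class VarianceComponentModel:
    """REML model for one response with crossed i.i.d. random terms.

    Parameters
    ----------
    endog : array-like, shape (n,)
        Response vector (no missing values).
    exog : ndarray, shape (n, p)
        Fixed-effects design matrix.  Must be full column rank; aliased
        columns raise :class:`AliasError` naming them.
    vc : dict of str -> ndarray (n, q_c)
        Indicator (or covariate) matrix per random term.
    exog_names, vc_levels : optional
        Column names for ``exog`` and level labels per random term.
    """

    def __init__(self, endog, exog, vc, exog_names=None, vc_levels=None):
        y = np.asarray(endog, dtype=float).ravel()
        if np.isnan(y).any():
            raise ValueError("endog contains missing values; drop them first")
        X = np.atleast_2d(np.asarray(exog, dtype=float))
        if X.shape[0] != y.size:
            raise ValueError("exog and endog lengths differ")
        self.exog_names = list(exog_names) if exog_names is not None else \
            [f"x{j}" for j in range(X.shape[1])]

        # pivoted QR rank check on X
        _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
        rank = int((diag > tol).sum())
        if rank < X.shape[1]:
            aliased = [self.exog_names[j] for j in piv[rank:]]
            raise AliasError(f"fixed-effects design is singular; aliased terms: {aliased}")

        self.y = y
        self.X = X
        self.n, self.p = X.shape
        self.vc_names = list(vc.keys())
        self.Z = {k: np.asarray(v, dtype=float) for k, v in vc.items()}
        for k, Zk in self.Z.items():
            if Zk.shape[0] != self.n:
                raise ValueError(f"random term '{k}' has wrong number of rows")
            if Zk.shape[1] < 2:
                raise ValueError(f"random term '{k}' has < 2 levels")
        self.vc_levels = {
            k: (list(vc_levels[k]) if vc_levels and k in vc_levels
                else [f"{k}[{j}]" for j in range(self.Z[k].shape[1])])
            for k in self.vc_names
        }
        self.q = np.array([self.Z[k].shape[1] for k in self.vc_names], dtype=int)

        # response scaled to unit variance internally for conditioning
        self._scale = float(np.std(y))
        if self._scale == 0:
            self._scale = 1.0
        ys = y / self._scale
        W = np.hstack([X] + [self.Z[k] for k in self.vc_names]) if self.vc_names else X
        self._W = W
        self._WtW = W.T @ W
        self._Wty = W.T @ ys
        self._yty = float(ys @ ys)
        self._ys = ys
        # column slices of W per random term
        self.slices = {}
        off = self.p
        for k, qk in zip(self.vc_names, self.q):
            self.slices[k] = slice(off, off + qk)
            off += qk

    # ------------------------------------------------------------------
    def _factor(self, theta, active):
        """Cholesky of the MME matrix for the active random terms.

        Returns (cols, L, b, quad, logdetC) where cols indexes W's columns.
        """
        s2e = theta[-1]
        cols = list(range(self.p))
        for i, k in enumerate(self.vc_names):
            if active[i]:
                sl = self.slices[k]
                cols.extend(range(sl.start, sl.stop))
        cols = np.asarray(cols, dtype=int)
        C = self._WtW[np.ix_(cols, cols)] / s2e
        off = self.p
        for i, k in enumerate(self.vc_names):
            if active[i]:
                qk = self.q[i]
                idx = np.arange(off, off + qk)
                C[idx, idx] += 1.0 / theta[i]
                off += qk
        L, low = linalg.cho_factor(C, lower=True, check_finite=False)
        rhs = self._Wty[cols] / s2e
        b = linalg.cho_solve((L, low), rhs, check_finite=False)
        quad = (self._yty - float(self._Wty[cols] @ b)) / s2e
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
        return cols, L, b, quad, logdet

    def loglike(self, theta, active=None):
        """REML log-likelihood (scaled response, additive constant dropped)."""
        if active is None:
            active = [theta[i] > 0 for i in range(len(self.vc_names))]
        *_, quad, logdet = self._factor(theta, active)[2:]  # b, quad, logdet
        ll = -0.5 * (self.n * np.log(theta[-1]) + logdet + quad)
        for i, k in enumerate(self.vc_names):
            if active[i]:
                ll -= 0.5 * self.q[i] * np.log(theta[i])
        return ll

    def _nll_grad(self, theta, active):
        """Negative REML log-likelihood and analytic gradient (active terms)."""
        s2e = theta[-1]
        cols, L, b, quad, logdet = self._factor(theta, active)
        nll = 0.5 * (self.n * np.log(s2e) + logdet + quad)
        act_idx = [i for i in range(len(self.vc_names)) if active[i]]
        for i in act_idx:
            nll += 0.5 * self.q[i] * np.log(theta[i])

        Cinv = _chol_inverse(L)
        grad = np.zeros(len(act_idx) + 1)
        off = self.p
        sum_sc2_trT = 0.0
        for j, i in enumerate(act_idx):
            qk = self.q[i]
            s2c = theta[i]
            u = b[off:off + qk]
            tr_cc = float(np.trace(Cinv[off:off + qk, off:off + qk]))
            trT = (qk * s2c - tr_cc) / s2c ** 2
            grad[j] = 0.5 * (trT - float(u @ u) / s2c ** 2)
            sum_sc2_trT += s2c * trT
            off += qk
        resid = self._ys - self._W[:, cols] @ b
        trP = (self.n - self.p - sum_sc2_trT) / s2e
        grad[-1] = 0.5 * (trP - float(resid @ resid) / s2e ** 2)
        return nll, grad, b, Cinv, cols

    # ------------------------------------------------------------------
    def fit(self, start=None, em_iter=15, max_iter=500, tol=1e-8,
            compute_se=True, pin_tol=1e-8) -> "VCResults":
        """Estimate variance components by EM-warm-started REML.

        ``tol`` is the relative-change convergence criterion on the
        components; components shrinking below ``pin_tol`` (relative to the
        phenotypic variance) are pinned at exactly 0.
        """
        m = len(self.vc_names)
        theta = np.asarray(start, dtype=float) / self._scale ** 2 if start is not None \
            else np.r_[np.full(m, 0.5 / max(m, 1)), 0.5]
        if theta.size != m + 1:
            raise ValueError("start must have one entry per random term plus residual")
        active = [theta[i] > 0 for i in range(m)]
        em_trace = []
        n_em = 0

        for it in range(em_iter):
            nll, _, b, Cinv, cols = self._nll_grad(theta, active)
            em_trace.append(-nll)
            new = theta.copy()
            off = self.p
            for i in range(m):
                if not active[i]:
                    continue
                qk = self.q[i]
                u = b[off:off + qk]
                tr_cc = float(np.trace(Cinv[off:off + qk, off:off + qk]))
                new[i] = (float(u @ u) + tr_cc) / qk
                off += qk
            new[-1] = max(
                (self._yty - float(self._Wty[cols] @ b)) / (self.n - self.p),
                1e-12)  # zero-residual data: keep sigma_e^2 at the floor
            rel = np.max(np.abs(new - theta) / np.maximum(np.abs(theta), 1e-12))
            theta = new
            n_em = it + 1
            for i in range(m):  # boundary pinning during EM
                if active[i] and theta[i] < pin_tol:
                    active[i] = False
                    theta[i] = 0.0
            if rel < tol:
                break

        # quasi-Newton polish on active components
        theta, act, opt_ok, n_qn = self._polish(theta, active, max_iter, pin_tol)
        converged = opt_ok
        if not converged:
            raise ConvergenceError(
                f"REML did not converge within {max_iter} iterations",
                trace=em_trace,
            )

        nll, grad, b, Cinv, cols = self._nll_grad(theta, act)
        se = cov = None
        if compute_se:
            se = self._standard_errors(theta, act)
        return VCResults(self, theta, act, -nll, b, Cinv, cols,
                         em_trace=em_trace, n_iter=n_em + n_qn, se=se,
                         converged=converged)

    def _polish(self, theta, active, max_iter, pin_tol):
        """L-BFGS-B with analytic gradient; re-polish after boundary pinning."""
        m = len(self.vc_names)
        floor = 1e-12
        total_iter = 0
        for _pass in range(m + 1):
            act_idx = [i for i in range(m) if active[i]]

            def pack(th):
                return np.r_[[th[i] for i in act_idx], th[-1]]

            def unpack(x):
                th = np.zeros(m + 1)
                for j, i in enumerate(act_idx):
                    th[i] = x[j]
                th[-1] = x[-1]
                return th

            def fun(x):
                th = unpack(x)
                nll, grad, *_ = self._nll_grad(th, active)
                return nll, grad

            x0 = np.maximum(pack(theta), 10 * floor)
            res = optimize.minimize(
                fun, x0, jac=True, method="L-BFGS-B",
                bounds=[(floor, None)] * len(x0),
                options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-10},
            )
            total_iter += res.nit
            if not res.success:  # line-search stalls near optimum: restart once
                res2 = optimize.minimize(
                    fun, res.x, jac=True, method="L-BFGS-B",
                    bounds=[(floor, None)] * len(res.x),
                    options={"maxiter": max_iter, "ftol": 1e-15, "gtol": 1e-12},
                )
                total_iter += res2.nit
                if res2.fun <= res.fun:
                    res = res2
            # Newton refinement: L-BFGS line searches stall once objective
            # changes drop below float resolution, long after the components
            # are converged; a few damped Newton steps with the numerical
            # Hessian of the analytic gradient settle the optimum tightly.
            x, nwt_ok, nit = self._newton(res.x, fun, floor)
            total_iter += nit
            theta = unpack(x)
            newly_pinned = False
            for i in act_idx:
                if theta[i] < pin_tol:
                    active[i] = False
                    theta[i] = 0.0
                    newly_pinned = True
            if not newly_pinned:
                ok = bool(res.success or nwt_ok)
                return theta, active, ok, total_iter
        return theta, active, False, total_iter  # pragma: no cover

    @staticmethod
    def _newton(x, fun, floor, max_steps=10, gtol=1e-5):
        """Damped, bound-projected Newton steps on the packed parameters.

        The gradient of the REML objective bottoms out at a numerical noise
        floor well below any statistically meaningful scale (curvatures here
        are >= O(10^2), so a relative gradient of 1e-5 bounds the parameter
        error by ~1e-7); the acceptance thresholds reflect that.
        """
        f0, g = fun(x)
        k = x.size

        def _relgrad(x, g):
            free = ~((x <= floor * 1.001) & (g > 0))
            if not free.any():
                return 0.0
            return float(np.max(np.abs(g[free]) * np.maximum(x[free], 1e-3)))

        for step in range(max_steps):
            if _relgrad(x, g) < gtol:
                return x, True, step
            H = np.zeros((k, k))
            for j in range(k):
                h = 1e-6 * max(x[j], 1e-6)
                xp = x.copy()
                xp[j] += h
                _, gp = fun(xp)
                H[:, j] = (gp - g) / h
            H = 0.5 * (H + H.T)
            try:
                d = np.linalg.solve(H + 1e-12 * np.eye(k), g)
            except np.linalg.LinAlgError:  # pragma: no cover
                return x, False, step
            lam = 1.0
            for _ in range(12):
                xn = np.maximum(x - lam * d, floor)
                fn, gn = fun(xn)
                if fn <= f0 + 1e-12 * abs(f0):
                    break
                lam *= 0.5
            else:
                return x, True, step  # no descent possible: at optimum
            if np.max(np.abs(xn - x)) < 1e-14:
                return xn, True, step
            x, f0, g = xn, fn, gn
        # plateau at the gradient noise floor still counts as converged
        return x, _relgrad(x, g) < 10 * gtol, max_steps

    def _standard_errors(self, theta, active):
        """Observed-information SEs: numerical Hessian of the analytic gradient."""
        m = len(self.vc_names)
        act_idx = [i for i in range(m) if active[i]] + [m]

        def g(x):
            th = np.zeros(m + 1)
            th[act_idx] = x
            _, grad, *_ = self._nll_grad(th, active)
            return grad

        x = theta[act_idx]
        k = x.size
        H = np.zeros((k, k))
        for j in range(k):
            h = 1e-5 * max(x[j], 1e-3)
            xp, xm = x.copy(), x.copy()
            xp[j] += h
            xm[j] = max(xm[j] - h, 1e-12)
            H[:, j] = (g(xp) - g(xm)) / (xp[j] - xm[j])
        H = 0.5 * (H + H.T)
        se = np.full(m + 1, np.nan)
        try:
            cov = np.linalg.inv(H)
            d = np.diag(cov).copy()
            d[d < 0] = np.nan
            se[act_idx] = np.sqrt(d)
        except np.linalg.LinAlgError:  # pragma: no cover
            pass
        return se


class VCResults:
    """REML fit results: components, BLUPs/PEVs, inverse-MME accessors."""

    def __init__(self, model, theta, active, llf, b, Cinv, cols,
                 em_trace, n_iter, se, converged):
        self.model = model
        s2 = model._scale ** 2
        self._theta = theta  # scaled domain
        self.active = list(active)
        self.params = {k: theta[i] * s2 for i, k in enumerate(model.vc_names)}
        self.params["residual"] = theta[-1] * s2
        self.bse = {}
        if se is not None:
            for i, k in enumerate(model.vc_names):
                self.bse[k] = se[i] * s2
            self.bse["residual"] = se[-1] * s2
        self.llf = llf - (model.n - model.p) * np.log(model._scale)
        self.em_loglik_trace = [v - (model.n - model.p) * np.log(model._scale)
                                for v in em_trace]
        self.n_iter = n_iter
        self.converged = converged

        # fixed effects and random-effect predictions on the original scale
        sc = model._scale
        self.fe_params = pd.Series(b[:model.p] * sc, index=model.exog_names)
        self._fe_cov = Cinv[:model.p, :model.p] * s2
        self._blups = {}
        self._pev_blocks = {}
        off = model.p
        for i, k in enumerate(model.vc_names):
            qk = model.q[i]
            if self.active[i]:
                u = b[off:off + qk] * sc
                block = Cinv[off:off + qk, off:off + qk] * s2
                off += qk
            else:
                u = np.zeros(qk)
                block = np.zeros((qk, qk))
            self._blups[k] = pd.Series(u, index=model.vc_levels[k])
            self._pev_blocks[k] = block

        self.fittedvalues = pd.Series(model._W[:, cols] @ b * sc)
        self.resid = pd.Series(model.y - self.fittedvalues.to_numpy())

    # ------------------------------------------------------------------
    def ranef(self, term) -> pd.DataFrame:
        """BLUPs with prediction-error variances for one random term."""
        pev = np.diag(self._pev_blocks[term])
        return pd.DataFrame({"blup": self._blups[term], "pev": pev})

    def pev_matrix(self, term) -> np.ndarray:
        """Full PEV (inverse-MME) block Var(u - u_hat) for one term."""
        return self._pev_blocks[term].copy()

    def vbar_delta(self, term, method="exact") -> float:
        """Mean variance of pairwise BLUP differences for one term.

        ``exact`` averages Var(u_i - u_j) over all pairs using the full
        inverse-MME block; ``approx`` uses 2 * mean(PEV), which ignores BLUP
        covariances.
        """
        M = self._pev_blocks[term]
        nlev = M.shape[0]
        if method == "approx":
            return float(2.0 * np.mean(np.diag(M)))
        tr = float(np.trace(M))
        s = float(M.sum())
        return 2.0 * (nlev * tr - s) / (nlev * (nlev - 1))

    @property
    def pct_explained(self) -> pd.Series:
        """Percent of phenotypic variance per component, residual included."""
        tot = sum(self.params.values())
        return pd.Series({k: 100.0 * v / tot for k, v in self.params.items()})

    def varcomp_frame(self) -> pd.DataFrame:
        """Variance components with SEs, one-sided z-tests and % explained."""
        rows = []
        for k, est in self.params.items():
            se = self.bse.get(k, np.nan)
            z = est / se if se and np.isfinite(se) and se > 0 else np.nan
            p = stats.norm.sf(z) if np.isfinite(z) else np.nan
            rows.append((k, est, se, z, p, self.pct_explained[k]))
        return pd.DataFrame(rows, columns=["term", "estimate", "se", "z",
                                           "pvalue", "pct_explained"])

    def summary(self) -> str:
        lines = ["Variance components (REML)",
                 "=" * 62,
                 f"{'term':<24}{'estimate':>12}{'se':>10}{'z':>8}{'p':>8}"]
        for _, r in self.varcomp_frame().iterrows():
            se = f"{r.se:.4f}" if np.isfinite(r.se) else "--"
            z = f"{r.z:.2f}" if np.isfinite(r.z) else "--"
            p = f"{r.pvalue:.3f}" if np.isfinite(r.pvalue) else "--"
            lines.append(f"{r.term:<24}{r.estimate:>12.5f}{se:>10}{z:>8}{p:>8}")
        lines.append("-" * 62)
        lines.append(f"REML log-likelihood {self.llf:.4f}   "
                     f"iterations {self.n_iter}   converged {self.converged}")
        return "\n".join(lines)
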