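"""Generalized linear mixed models with crossed random intercepts.

``MixedGLM`` fits Poisson (log link) and binomial (logit link, counts of
successes out of per-row trials) regressions with one or more crossed
random-intercept factors (e.g. mother identity, father identity, year of
breeding).  Estimation maximises the Laplace approximation to the
marginal likelihood: for candidate variance components the joint
penalized likelihood in (beta, u) is maximised by penalized IRLS, and
the marginal log-likelihood

    l(theta) ~= log f(y | eta_hat) - u'D^{-1}u/2 - log|D|/2 - log|H_u|/2

(H_u the negative Hessian in u at the mode) is optimised over the
log-standard-deviations by Nelder-Mead.  With all variance components
pinned to zero the fit reduces exactly to the ordinary GLM.

The design matrices stay small (hundreds of rows, a few hundred random
levels), so all linear algebra is dense; the random-effect cross-product
blocks are accumulated from the factor codes rather than materialising
indicator matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize

__all__ = ["MixedGLM", "MixedGLMResults"]

_SIGMA_FLOOR = 1e-4
_LOG_SIGMA_BOUNDS = (-7.0, 3.0)


def _binom_loglik(y, trials, eta, const):
    p = 1.0 / (1.0 + np.exp(-eta))
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(const + np.sum(y * np.log(p) + (trials - y) * np.log1p(-p)))


def _poisson_loglik(y, eta, const):
    mu = np.exp(eta)
    return float(const + np.sum(y * eta - mu))


class MixedGLM:
    """GLMM with crossed random intercepts, Laplace-approximate likelihood.

    Parameters
    ----------
    endog : response counts (fledged / clutch size).
    exog : fixed-effect design matrix (include the constant explicitly).
    groups : mapping factor name -> integer-coded or labelled series; one
        random intercept per level of each factor.
    family : "binomial" or "poisson".
    trials : binomial trials per row (required for the binomial family).
    """

    def __init__(
        self,
        endog,
        exog,
        groups: dict[str, np.ndarray] | None = None,
        family: str = "binomial",
        trials=None,
        exog_names: list[str] | None = None,
    ):
        if family not in ("binomial", "poisson"):
            raise ValueError(f"unsupported family {family!r}")
        self.family = family
        if isinstance(exog, pd.DataFrame):
            exog_names = list(exog.columns)
            exog = exog.to_numpy(float)
        self.endog = np.asarray(endog, float)
        self.exog = np.asarray(exog, float)
        self.nobs, self.k_exog = self.exog.shape
        self.exog_names = exog_names or [f"x{i}" for i in range(self.k_exog)]
        if family == "binomial":
            if trials is None:
                raise ValueError("binomial family requires trials")
            self.trials = np.asarray(trials, float)
            if np.any(self.endog > self.trials):
                raise ValueError("successes exceed trials")
        else:
            self.trials = None
        groups = groups or {}
        self.group_names = list(groups)
        self.codes, self.n_levels, self.level_offsets = [], [], []
        off = 0
        for name in self.group_names:
            codes, _ = pd.factorize(pd.Series(groups[name]), sort=True)
            self.codes.append(codes.astype(np.int64))
            self.n_levels.append(int(codes.max()) + 1 if len(codes) else 0)
            self.level_offsets.append(off)
            off += self.n_levels[-1]
        self.q = off
        # per-random-column factor index (for the variance map)
        self.col_factor = np.concatenate(
            [np.full(nl, i) for i, nl in enumerate(self.n_levels)]
        ) if self.q else np.zeros(0, int)
        rank = np.linalg.matrix_rank(self.exog)
        if rank < self.k_exog:
            raise ValueError("fixed-effect design is rank deficient")
        from scipy.special import gammaln

        if family == "binomial":
            self._ll_const = float(
                np.sum(
                    gammaln(self.trials + 1)
                    - gammaln(self.endog + 1)
                    - gammaln(self.trials - self.endog + 1)
                )
            )
        else:
            self._ll_const = float(-np.sum(gammaln(self.endog + 1)))

    # -- likelihood internals -------------------------------------------

    def _eta(self, beta, u):
        eta = self.exog @ beta
        for codes, off in zip(self.codes, self.level_offsets):
            eta = eta + u[off + codes]
        return eta

    def _irls_weights(self, eta):
        if self.family == "poisson":
            mu = np.exp(np.clip(eta, -30, 30))
            w = mu
            z = eta + (self.endog - mu) / np.maximum(mu, 1e-10)
        else:
            p = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
            w = np.maximum(self.trials * p * (1 - p), 1e-10)
            z = eta + (self.endog - self.trials * p) / w
        return w, z

    def _loglik_cond(self, eta):
        if self.family == "poisson":
            return _poisson_loglik(self.endog, eta, self._ll_const)
        return _binom_loglik(self.endog, self.trials, eta, self._ll_const)

    def _assemble(self, w, z):
        """Normal equations of the weighted working regression on [X | Z]."""
        p, q = self.k_exog, self.q
        m = np.zeros((p + q, p + q))
        rhs = np.zeros(p + q)
        Xw = self.exog * w[:, None]
        m[:p, :p] = self.exog.T @ Xw
        rhs[:p] = Xw.T @ z
        for i, (codes, off, nl) in enumerate(
            zip(self.codes, self.level_offsets, self.n_levels)
        ):
            # Z_f' W X and Z_f' W z
            blk = np.zeros((nl, p))
            np.add.at(blk, codes, Xw)
            m[p + off : p + off + nl, :p] = blk
            m[:p, p + off : p + off + nl] = blk.T
            rhs[p + off : p + off + nl] = np.bincount(codes, weights=w * z, minlength=nl)
            # within-factor block is diagonal
            diag = np.bincount(codes, weights=w, minlength=nl)
            idx = np.arange(nl)
            m[p + off + idx, p + off + idx] += diag
            # cross-factor blocks
            for j in range(i):
                codes_j, off_j, nl_j = (
                    self.codes[j],
                    self.level_offsets[j],
                    self.n_levels[j],
                )
                cross = np.zeros((nl, nl_j))
                np.add.at(cross, (codes, codes_j), w)
                m[p + off : p + off + nl, p + off_j : p + off_j + nl_j] = cross
                m[p + off_j : p + off_j + nl_j, p + off : p + off + nl] = cross.T
        return m, rhs

    def _pirls(self, sigmas, beta0=None, u0=None, maxiter=60, tol=1e-8):
        p, q = self.k_exog, self.q
        prec = np.zeros(q)
        if q:
            prec = 1.0 / np.maximum(sigmas[self.col_factor], _SIGMA_FLOOR) ** 2
        beta = np.zeros(p) if beta0 is None else beta0.copy()
        u = np.zeros(q) if u0 is None else u0.copy()
        pen_old = -np.inf
        converged = False
        for _ in range(maxiter):
            eta = self._eta(beta, u)
            w, z = self._irls_weights(eta)
            m, rhs = self._assemble(w, z)
            if q:
                m[np.arange(p, p + q), np.arange(p, p + q)] += prec
            try:
                c, low = linalg.cho_factor(m, lower=True, check_finite=False)
            except linalg.LinAlgError:
                m[np.arange(p + q), np.arange(p + q)] += 1e-8
                c, low = linalg.cho_factor(m, lower=True, check_finite=False)
            sol = linalg.cho_solve((c, low), rhs, check_finite=False)
            beta_new, u_new = sol[:p], sol[p:]
            # step-halving on the penalized objective
            step = 1.0
            for _ in range(8):
                b_try = beta + step * (beta_new - beta)
                u_try = u + step * (u_new - u)
                pen = self._loglik_cond(self._eta(b_try, u_try)) - 0.5 * np.sum(
                    prec * u_try**2
                )
                if np.isfinite(pen) and (pen >= pen_old - 1e-10 or step < 0.2):
                    break
                step *= 0.5
            beta, u = b_try, u_try
            if abs(pen - pen_old) < tol * (1 + abs(pen)):
                converged = True
                pen_old = pen
                break
            pen_old = pen
        return beta, u, pen_old, converged

    def _laplace_loglik(self, sigmas, beta, u):
        eta = self._eta(beta, u)
        w, _ = self._irls_weights(eta)
        ll = self._loglik_cond(eta)
        if self.q == 0:
            return ll
        sig = np.maximum(sigmas[self.col_factor], _SIGMA_FLOOR)
        prec = 1.0 / sig**2
        ll -= 0.5 * np.sum(prec * u**2)
        # -1/2 log|D| - 1/2 log|Z'WZ + D^-1|
        m, _ = self._assemble(w, np.zeros(self.nobs))
        h = m[self.k_exog :, self.k_exog :].copy()
        h[np.arange(self.q), np.arange(self.q)] += prec
        try:
            c, _low = linalg.cho_factor(h, lower=True, check_finite=False)
        except linalg.LinAlgError:
            return -np.inf
        logdet_h = 2.0 * float(np.sum(np.log(np.diag(c))))
        ll -= np.sum(np.log(sig))
        ll -= 0.5 * logdet_h
        return ll

    # -- public fitting API ---------------------------------------------

    def fit(
        self,
        start_sigmas: np.ndarray | None = None,
        fix_sigmas: np.ndarray | None = None,
        maxiter: int = 200,
    ) -> "MixedGLMResults":
        """Fit by Laplace ML.

        ``fix_sigmas`` pins the variance components (0 allowed: the
        corresponding random terms drop out and the fit is a plain GLM
        when all are 0); otherwise they are estimated.
        """
        nf = len(self.group_names)
        state: dict = {"beta": None, "u": None}

        def fit_at(sigmas):
            beta, u, _, conv = self._pirls(
                sigmas, beta0=state["beta"], u0=state["u"]
            )
            state["beta"], state["u"] = beta, u
            return beta, u, conv

        if nf == 0 or fix_sigmas is not None:
            sigmas = np.zeros(nf) if nf == 0 else np.asarray(fix_sigmas, float)
            active = sigmas > 0
            if nf and not active.all():
                sub = self._drop_factors(active)
                res = sub.fit(
                    fix_sigmas=sigmas[active] if active.any() else None
                )
                return MixedGLMResults(
                    self, res.params.to_numpy(), res.cov_params_arr,
                    res.llf, np.where(active, sigmas, 0.0), res.converged,
                    res.random_effects, k_var=int(active.sum()),
                )
            beta, u, conv = fit_at(sigmas)
            llf = self._laplace_loglik(sigmas, beta, u)
            cov = self._cov_beta(sigmas, beta, u)
            return MixedGLMResults(self, beta, cov, llf, sigmas, conv, u,
                                   k_var=int((sigmas > 0).sum()))

        warm = start_sigmas is not None
        x0 = np.log(np.full(nf, 0.3) if not warm else
                    np.maximum(start_sigmas, 1e-3))

        def objective(log_sig):
            log_sig = np.clip(log_sig, *_LOG_SIGMA_BOUNDS)
            sig = np.exp(log_sig)
            beta, u, _ = fit_at(sig)
            return -self._laplace_loglik(sig, beta, u)

        step = 0.2 if warm else 0.6
        opt = optimize.minimize(
            objective, x0, method="Nelder-Mead",
            options={"xatol": 3e-2, "fatol": 2e-4, "maxiter": maxiter,
                     "initial_simplex": x0 + np.vstack(
                         [np.zeros(nf), np.eye(nf) * step])},
        )
        sigmas = np.exp(np.clip(opt.x, *_LOG_SIGMA_BOUNDS))
        beta, u, conv = fit_at(sigmas)
        llf = self._laplace_loglik(sigmas, beta, u)
        cov = self._cov_beta(sigmas, beta, u)
        converged = bool(conv and np.isfinite(llf))
        return MixedGLMResults(self, beta, cov, llf, sigmas, converged, u,
                               k_var=nf)

    def _drop_factors(self, active_mask) -> "MixedGLM":
        groups = {
            name: self.codes[i]
            for i, name in enumerate(self.group_names)
            if active_mask[i]
        }
        return MixedGLM(
            self.endog, self.exog, groups=groups, family=self.family,
            trials=self.trials, exog_names=self.exog_names,
        )

    def _cov_beta(self, sigmas, beta, u):
        eta = self._eta(beta, u)
        w, _ = self._irls_weights(eta)
        m, _ = self._assemble(w, np.zeros(self.nobs))
        p, q = self.k_exog, self.q
        if q:
            prec = 1.0 / np.maximum(sigmas[self.col_factor], _SIGMA_FLOOR) ** 2
            m[np.arange(p, p + q), np.arange(p, p + q)] += prec
        try:
            c, low = linalg.cho_factor(m, lower=True, check_finite=False)
            inv = linalg.cho_solve((c, low), np.eye(p + q), check_finite=False)
        except linalg.LinAlgError:
            inv = np.linalg.pinv(m)
        return inv[:p, :p]


@dataclass
class MixedGLMResults:
    """Estimates, Wald uncertainties and Laplace log-likelihood of a fit."""

    model: MixedGLM
    _params: np.ndarray
    cov_params_arr: np.ndarray
    llf: float
    sigmas: np.ndarray
    converged: bool
    random_effects: np.ndarray
    k_var: int = 0

    @property
    def params(self) -> pd.Series:
        return pd.Series(self._params, index=self.model.exog_names)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.maximum(np.diag(self.cov_params_arr), 0.0)),
            index=self.model.exog_names,
        )

    @property
    def pvalues(self) -> pd.Series:
        from scipy.stats import norm

        z = self._params / np.maximum(self.bse.to_numpy(), 1e-300)
        return pd.Series(2 * norm.sf(np.abs(z)), index=self.model.exog_names)

    @property
    def k_params(self) -> int:
        return self.model.k_exog + self.k_var

    @property
    def nobs(self) -> int:
        return self.model.nobs

    def cov_params(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.cov_params_arr,
            index=self.model.exog_names,
            columns=self.model.exog_names,
        )

    @property
    def variance_components(self) -> pd.Series:
        return pd.Series(self.sigmas, index=self.model.group_names, name="sd")

    def summary(self) -> str:
        tab = pd.DataFrame(
            {
                "coef": self.params,
                "std err": self.bse,
                "z": self.params / self.bse.replace(0, np.nan),
                "P>|z|": self.pvalues,
            }
        )
        lines = [
            f"MixedGLM ({self.model.family}, Laplace)  "
            f"nobs={self.nobs}  llf={self.llf:.3f}  k={self.k_params}",
            tab.to_string(float_format=lambda v: f"{v: .4f}"),
        ]
        if len(self.sigmas):
            vc = ", ".join(
                f"{n}={s:.3f}" for n, s in self.variance_components.items()
            )
            lines.append(f"random-intercept SDs: {vc}")
        if not self.converged:
            lines.append("WARNING: fit did not converge")
        return "\n".join(lines)
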