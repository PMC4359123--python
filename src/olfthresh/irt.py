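"""Random-effects 3AFC logistic IRT: marginal ML fit and empirical Bayes.

Model
-----
Subject ``i`` responds to presentation ``j`` at dilution step ``d_ij``::

    P(Y_ij = 1 | alpha_i) = 1/3 + 2/3 * expit(alpha_i - beta * d_ij)
    alpha_i ~ N(mu_alpha, var_alpha)

The fixed 1/3 lower asymptote is the 3AFC guessing floor.  The marginal
likelihood integrates the Bernoulli likelihood over the Normal ability
distribution; the integral is evaluated by Gauss-Hermite quadrature with
per-subject recentering: nodes are first placed at the prior mean/SD,
then re-centered twice at the running posterior mean/SD of each subject
(a derivative-free form of adaptive quadrature).  ``(beta, mu_alpha,
sigma_alpha)`` are estimated by maximizing the marginal log-likelihood
over ``(log beta, mu_alpha, log sigma_alpha)``; standard errors come
from the observed information (numerical Hessian) mapped to the natural
scale by the delta method.

A subject's threshold is the step at which P(correct) = 2/3, i.e.
``alpha_i / beta``.  Individual thresholds are predicted by empirical
Bayes: the posterior mean of ``alpha_i`` given the subject's responses
and the fitted population distribution, divided by ``beta_hat``.  These
predictions are shrunk toward the population mean (posterior SD never
exceeds the prior SD) and are unconditionally unbiased for the
population mean threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize
from scipy.special import expit, logsumexp

__all__ = ["ThresholdIRT", "ThresholdIRTResults", "SubjectFit", "fit_per_subject"]

_LOG3 = math.log(3.0)
_LOG23 = math.log(2.0 / 3.0)

# box bounds for (log beta, mu_alpha, log sigma)
_BOUNDS = [(-4.0, 4.0), (-200.0, 200.0), (-6.0, 6.0)]
_BOUND_TOL = 1e-3


def _record_loglik(alpha, y1, step):
    """Log-likelihood of each record at each ability node.

    alpha : (R, K) ability per record x node
    y1    : (R,) boolean, response correct
    step  : (R,) dilution step
    """
    eta = alpha - step[:, None] if alpha.ndim == 2 else alpha - step
    # log P(correct) = log((1 + 2*expit(eta)) / 3); log P(incorrect) = log(2/3) - log(1+e^eta)
    ll = np.where(y1[:, None] if alpha.ndim == 2 else y1,
                  np.log1p(2.0 * expit(eta)) - _LOG3,
                  _LOG23 - np.logaddexp(0.0, eta))
    return ll


class ThresholdIRT:
    """Random-intercept 3AFC logistic IRT model.

    Parameters
    ----------
    response : array_like of {0, 1}
        Correct/incorrect indicator per presentation (impute don't-know /
        refused codes first; see :mod:`olfthresh.impute`).
    step : array_like
        Dilution step of each presentation.
    subject : array_like
        Subject label per presentation (any hashable dtype).
    n_quadrature : int
        Gauss-Hermite nodes per subject (default 21).
    n_refine : int
        Recentering passes of the quadrature grid (default 3).
    """

    def __init__(self, response, step, subject, n_quadrature: int = 21,
                 n_refine: int = 3):
        response = np.asarray(response)
        if not np.isin(response, (0, 1)).all():
            raise ValueError("responses must be coded 0/1; impute DK/REF first")
        self.step = np.asarray(step, dtype=float)
        if not np.isfinite(self.step).all():
            raise ValueError("all dilution steps must be finite")
        codes, self.subject_ids = pd.factorize(np.asarray(subject), sort=True)
        self.subject_index = codes
        self.y1 = response.astype(bool)
        self.n_subjects = len(self.subject_ids)
        self.nobs = self.y1.size
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects for a random-effects fit")
        if np.unique(self.step).size < 2:
            raise ValueError("need at least 2 distinct dilution steps")
        self.n_quadrature = int(n_quadrature)
        self.n_refine = int(n_refine)
        self._nodes, self._gh_weights = hermgauss(self.n_quadrature)
        # log(w_k) + x_k^2 : node log-weights for integrating f against dx
        self._logw = np.log(self._gh_weights) + self._nodes ** 2
        self._collapse_patterns()

    def _collapse_patterns(self):
        """Group subjects sharing an identical (steps, responses) record.

        Subjects administered the same stimulus sequence contribute
        identical likelihood terms whenever their response patterns
        coincide; with short protocols (6 items -> at most 64 patterns)
        collapsing to weighted unique patterns makes the fit cost
        independent of the number of subjects.
        """
        order = np.lexsort((np.arange(self.nobs), self.subject_index))
        counts = np.bincount(self.subject_index, minlength=self.n_subjects)
        self._group_of_subject = np.arange(self.n_subjects)
        self._group_weights = np.ones(self.n_subjects)
        self._g_step, self._g_y1 = self.step, self.y1
        self._g_index = self.subject_index
        self.n_groups = self.n_subjects
        if np.ptp(counts) != 0 or counts[0] == 0:
            return
        m = int(counts[0])
        steps = self.step[order].reshape(self.n_subjects, m)
        if np.ptp(steps, axis=0).any():
            return  # subjects saw different stimulus sequences
        ys = self.y1[order].reshape(self.n_subjects, m)
        uniq, gidx = np.unique(ys, axis=0, return_inverse=True)
        self.n_groups = uniq.shape[0]
        self._group_of_subject = gidx
        self._group_weights = np.bincount(gidx, minlength=self.n_groups).astype(float)
        self._g_step = np.tile(steps[0], self.n_groups)
        self._g_y1 = uniq.ravel()
        self._g_index = np.repeat(np.arange(self.n_groups), m)

    # ------------------------------------------------------------------
    def _group_logints(self, beta, mu, sigma, centers, scales):
        """Per-group log-integrand on the recentered node grid.

        Returns (alpha_nodes (G,K), logint (G,K)) where
        logint[g,k] = loglik_g(alpha_gk) + log phi(alpha_gk; mu, sigma^2).
        """
        sqrt2 = math.sqrt(2.0)
        alpha = centers[:, None] + sqrt2 * scales[:, None] * self._nodes[None, :]
        rec = _record_loglik(alpha[self._g_index], self._g_y1, self._g_step * beta)
        ll = np.empty((self.n_groups, self.n_quadrature))
        for k in range(self.n_quadrature):
            ll[:, k] = np.bincount(self._g_index, weights=rec[:, k],
                                   minlength=self.n_groups)
        logprior = (-0.5 * ((alpha - mu) / sigma) ** 2
                    - math.log(sigma) - 0.5 * math.log(2.0 * math.pi))
        return alpha, ll + logprior

    def _quadrature(self, beta, mu, sigma):
        """Adaptive pass: per-group (loglik, posterior mean, posterior sd)."""
        centers = np.full(self.n_groups, mu)
        scales = np.full(self.n_groups, sigma)
        for _ in range(self.n_refine + 1):
            alpha, logint = self._group_logints(beta, mu, sigma, centers, scales)
            g = self._logw[None, :] + logint
            logL = np.log(math.sqrt(2.0) * scales) + logsumexp(g, axis=1)
            p = np.exp(g - logsumexp(g, axis=1, keepdims=True))
            m = np.sum(p * alpha, axis=1)
            v = np.sum(p * (alpha - m[:, None]) ** 2, axis=1)
            centers = m
            scales = np.clip(np.sqrt(np.maximum(v, 0.0)), 1e-4, 1e4)
        return logL, centers, scales

    def loglike(self, params):
        """Marginal log-likelihood at natural-scale ``(beta, mu_alpha, sigma_alpha)``."""
        beta, mu, sigma = (float(p) for p in params)
        if beta <= 0 or sigma <= 0:
            raise ValueError("beta and sigma_alpha must be positive")
        logL, _, _ = self._quadrature(beta, mu, sigma)
        return float(np.dot(self._group_weights, logL))

    def _negll(self, theta):
        beta, mu, sigma = math.exp(theta[0]), theta[1], math.exp(theta[2])
        logL, _, _ = self._quadrature(beta, mu, sigma)
        val = -float(np.dot(self._group_weights, logL))
        return val if np.isfinite(val) else 1e12

    def _negll_and_grad(self, theta):
        """Objective and its gradient on the (log beta, mu, log sigma) scale.

        The gradient uses the Fisher identity: the score of the marginal
        log-likelihood is the posterior expectation of the complete-data
        score, evaluated on the recentered quadrature grid.
        """
        beta, mu, sigma = math.exp(theta[0]), theta[1], math.exp(theta[2])
        centers = np.full(self.n_groups, mu)
        scales = np.full(self.n_groups, sigma)
        for _ in range(self.n_refine + 1):
            alpha, logint = self._group_logints(beta, mu, sigma, centers, scales)
            g = self._logw[None, :] + logint
            norm = logsumexp(g, axis=1)
            logL = np.log(math.sqrt(2.0) * scales) + norm
            p = np.exp(g - norm[:, None])
            m = np.sum(p * alpha, axis=1)
            v = np.sum(p * (alpha - m[:, None]) ** 2, axis=1)
            centers = m
            scales = np.clip(np.sqrt(np.maximum(v, 0.0)), 1e-4, 1e4)
        w = self._group_weights
        val = -float(np.dot(w, logL))
        if not np.isfinite(val):
            return 1e12, np.zeros(3)

        # complete-data score per record x node, summed to group x node
        eta = alpha[self._g_index] - (beta * self._g_step)[:, None]
        s = expit(eta)
        dll_deta = np.where(self._g_y1[:, None],
                            2.0 * s * (1.0 - s) / (1.0 + 2.0 * s), -s)
        rec_dbeta = dll_deta * (-self._g_step)[:, None]
        dbeta_gn = np.empty((self.n_groups, self.n_quadrature))
        for k in range(self.n_quadrature):
            dbeta_gn[:, k] = np.bincount(self._g_index, weights=rec_dbeta[:, k],
                                         minlength=self.n_groups)
        pw = p * w[:, None]
        z = alpha - mu
        g_beta = float(np.sum(pw * dbeta_gn))
        g_mu = float(np.sum(pw * z) / sigma ** 2)
        g_sigma = float(np.sum(pw * (z ** 2 / sigma ** 3 - 1.0 / sigma)))
        grad = -np.array([beta * g_beta, g_mu, sigma * g_sigma])
        return val, grad

    def start_params(self):
        """Method-of-moments starting values on the natural scale.

        Guess-corrected per-step accuracies ``q_d = (3 p_d - 1) / 2`` are
        regressed on step after a logit transform; the slope starts
        ``beta`` and the intercept ``mu_alpha`` (attenuated by the
        ability spread, which is fine for a start).
        """
        steps, inv = np.unique(self.step, return_inverse=True)
        p_d = np.bincount(inv, weights=self.y1) / np.bincount(inv)
        q = np.clip((3.0 * p_d - 1.0) / 2.0, 0.02, 0.98)
        z = np.log(q / (1.0 - q))
        slope, intercept = np.polyfit(steps, z, 1)
        beta0 = float(np.clip(-slope, 0.1, 5.0))
        return np.array([beta0, float(intercept), 1.0])

    def fit(self, start_params=None, maxiter: int = 300) -> "ThresholdIRTResults":
        """Maximize the marginal likelihood; never raises on non-convergence.

        A small ladder of method-of-moments starting values is tried
        until one attempt converges (sparse designs far from the
        population's thresholds occasionally send the first attempt to a
        degenerate boundary).  Returns a :class:`ThresholdIRTResults`
        whose ``converged`` flag is False when the optimizer fails, a
        parameter sits on its box bound, or the observed information is
        not positive definite.
        """
        mom = self.start_params()
        ladder = [mom, np.array([mom[0], mom[1], 2.0]),
                  np.array([1.0, mom[1], 1.0]),
                  np.array([0.5, 0.5 * mom[1], 2.0])]
        if start_params is not None:
            ladder = [np.asarray(start_params, dtype=float)]
        best = None
        for beta0, mu0, sigma0 in ladder:
            theta0 = np.array([math.log(beta0), mu0, math.log(sigma0)])
            res = optimize.minimize(
                self._negll_and_grad, theta0, jac=True, method="L-BFGS-B",
                bounds=_BOUNDS,
                options={"maxiter": maxiter, "ftol": 1e-13, "gtol": 5e-3})
            at_bound = any(
                th - lo < _BOUND_TOL or hi - th < _BOUND_TOL
                for th, (lo, hi) in zip(res.x, _BOUNDS))
            if best is None or res.fun < best[0].fun - 1e-9:
                best = (res, at_bound)
            if res.success and not at_bound:
                best = (res, at_bound)
                break
        res, at_bound = best
        theta = res.x
        hess = self._numerical_hessian(theta)
        cov_theta, pd_ok = _safe_inverse(hess)
        beta, mu, sigma = math.exp(theta[0]), theta[1], math.exp(theta[2])
        # delta method to (beta, mu_alpha, var_alpha)
        if cov_theta is not None:
            jac = np.diag([beta, 1.0, 2.0 * sigma ** 2])
            cov = jac @ cov_theta @ jac.T
            bse = np.sqrt(np.maximum(np.diag(cov), 0.0))
        else:
            cov = None
            bse = np.full(3, np.nan)

        converged = bool(res.success) and not at_bound and pd_ok
        names = ["beta", "mu_alpha", "var_alpha"]
        return ThresholdIRTResults(
            model=self,
            params=pd.Series([beta, mu, sigma ** 2], index=names),
            bse=pd.Series(bse, index=names),
            cov_params=cov,
            llf=-float(res.fun),
            converged=converged,
            optimizer_message=str(res.message),
            n_quadrature=self.n_quadrature,
        )

    def _numerical_hessian(self, theta, eps: float = 1e-4):
        n = len(theta)
        h = eps * np.maximum(1.0, np.abs(theta))
        f0 = self._negll(theta)
        hess = np.empty((n, n))
        for i in range(n):
            for j in range(i, n):
                ei = np.zeros(n); ei[i] = h[i]
                ej = np.zeros(n); ej[j] = h[j]
                if i == j:
                    val = (self._negll(theta + ei) - 2 * f0
                           + self._negll(theta - ei)) / h[i] ** 2
                else:
                    val = (self._negll(theta + ei + ej) - self._negll(theta + ei - ej)
                           - self._negll(theta - ei + ej) + self._negll(theta - ei - ej)
                           ) / (4 * h[i] * h[j])
                hess[i, j] = hess[j, i] = val
        return hess

    def posterior_abilities(self, beta, mu, sigma):
        """Posterior mean and SD of alpha_i at the given parameters.

        Estimates depend on the data only through each subject's
        response pattern; pattern-level posteriors are expanded back to
        subjects.
        """
        _, post_mean, post_sd = self._quadrature(float(beta), float(mu), float(sigma))
        counts = np.bincount(self._g_index, minlength=self.n_groups)
        # groups with no informative records sit at the prior
        post_mean = np.where(counts == 0, mu, post_mean)
        post_sd = np.where(counts == 0, sigma, post_sd)
        return (post_mean[self._group_of_subject],
                post_sd[self._group_of_subject])

    # ------------------------------------------------------------------
    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response_col: str = "response",
                       step_col: str = "dilution_step",
                       subject_col: str = "subject_id", **kwargs) -> "ThresholdIRT":
        """Build the model from a long-format response table."""
        return cls(data[response_col].to_numpy(), data[step_col].to_numpy(),
                   data[subject_col].to_numpy(), **kwargs)


def _safe_inverse(hess):
    try:
        np.linalg.cholesky(hess)
        return np.linalg.inv(hess), True
    except np.linalg.LinAlgError:
        try:
            return np.linalg.pinv(hess), False
        except np.linalg.LinAlgError:
            return None, False


@dataclass
class ThresholdIRTResults:
    """Fit results: estimates of (beta, mu_alpha, var_alpha) and diagnostics."""

    model: ThresholdIRT
    params: pd.Series
    bse: pd.Series
    cov_params: np.ndarray | None
    llf: float
    converged: bool
    optimizer_message: str
    n_quadrature: int

    @property
    def beta(self) -> float:
        return float(self.params["beta"])

    @property
    def mu_alpha(self) -> float:
        return float(self.params["mu_alpha"])

    @property
    def var_alpha(self) -> float:
        return float(self.params["var_alpha"])

    @property
    def sigma_alpha(self) -> float:
        return math.sqrt(self.var_alpha)

    @property
    def mean_threshold(self) -> float:
        """Population mean threshold, ``mu_alpha / beta`` (step units)."""
        return self.mu_alpha / self.beta

    def empirical_bayes(self) -> pd.DataFrame:
        """Per-subject empirical-Bayes ability and threshold predictions.

        Returns a DataFrame with columns ``subject_id``, ``alpha_eb``,
        ``alpha_eb_sd`` and ``threshold_eb`` (= alpha_eb / beta_hat).
        """
        m, s = self.model.posterior_abilities(self.beta, self.mu_alpha,
                                              self.sigma_alpha)
        return pd.DataFrame({
            "subject_id": self.model.subject_ids,
            "alpha_eb": m,
            "alpha_eb_sd": s,
            "threshold_eb": m / self.beta,
        })

    def summary(self) -> str:
        """Plain-text summary table in the spirit of statsmodels."""
        lines = [
            "Random-effects 3AFC logistic IRT (marginal ML)",
            "=" * 58,
            f"Subjects: {self.model.n_subjects:>6d}    "
            f"Presentations: {self.model.nobs:>7d}",
            f"Quadrature nodes: {self.n_quadrature:<4d} "
            f"Log-likelihood: {self.llf:.3f}",
            f"Converged: {self.converged}",
            "-" * 58,
            f"{'':12s}{'estimate':>12s}{'std err':>12s}",
        ]
        for name in self.params.index:
            lines.append(f"{name:12s}{self.params[name]:12.4f}{self.bse[name]:12.4f}")
        lines += [
            "-" * 58,
            f"mean threshold (mu_alpha/beta): {self.mean_threshold:.3f} steps",
            f"threshold SD  (sigma/beta):     {self.sigma_alpha / self.beta:.3f} steps",
            "=" * 58,
        ]
        return "\n".join(lines)


@dataclass
class SubjectFit:
    """Per-subject ML fit of the response curve (fixed-effects, one subject)."""

    alpha: float
    beta: float | None
    estimable: bool
    message: str = ""

    @property
    def threshold(self) -> float:
        b = self.beta
        return self.alpha / b if (self.estimable and b) else math.nan


def fit_per_subject(response, step, beta: float | None = None) -> SubjectFit:
    """Maximum-likelihood fit of one subject's dilution-response curve.

    With ``beta`` given, only the ability ``alpha`` is estimated;
    otherwise ``(alpha, beta)`` are fit jointly.  All-correct or
    all-incorrect response vectors are separated and flagged
    non-estimable rather than fitted.
    """
    y = np.asarray(response).astype(bool)
    step = np.asarray(step, dtype=float)
    if y.all() or (~y).all():
        return SubjectFit(math.nan, beta, False, "complete separation")

    if beta is not None:
        if beta <= 0:
            raise ValueError("beta must be positive")

        def nll(a):
            return -float(_record_loglik(np.full_like(step, a), y, step * beta).sum())

        res = optimize.minimize_scalar(nll, bounds=(-100, 100), method="bounded",
                                       options={"xatol": 1e-8})
        return SubjectFit(float(res.x), float(beta), True)

    def nll2(th):
        a, logb = th
        return -float(_record_loglik(np.full_like(step, a), y,
                                     step * math.exp(logb)).sum())

    res = optimize.minimize(nll2, np.array([np.median(step), 0.0]),
                            method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
    a, logb = res.x
    ok = bool(res.success) and abs(logb) < 6
    return SubjectFit(float(a), float(math.exp(logb)), ok,
                      "" if ok else "slope not identified")
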