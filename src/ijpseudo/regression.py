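"""Weighted estimating-equation regression for pseudo-observations.

The mean model is E(V | Z) = mu(beta' x) for an invertible link, and
beta^ solves the (weighted) generalized estimating equation

    sum_i  A(beta; Z_i) w_i { theta^_i - mu(beta; Z_i) } = 0 ,

with the quasi-score choice A = d mu / d beta (so the identity link
reduces to weighted least squares, solved in closed form).  Three
variance estimators are provided:

* Huber--White sandwich M^{-1} (sum U_i U_i') M^{-1} -- ignores the
  correlation between pseudo-observations induced by the second-order
  influence function; known to be conservative (biased upwards) for
  Kaplan--Meier / Aalen--Johansen functionals;
* the asymptotic variance M^{-1} Var{h0 + h1} M^{-1}, where the h1 term
  is built from a numerical second-order influence function of the
  Aalen--Johansen functional (mixed central differences on a
  two-parameter weight perturbation);
* a nonparametric subject-level bootstrap that recomputes the
  pseudo-observations (and, for truncated data, the sampling weights)
  inside every replicate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Sample
from .pseudo import (
    PseudoSet,
    aalen_johansen_weighted,
    ij_pseudo,
    ij_pseudo_truncated,
    ipcw_pseudo,
    jackknife_pseudo,
)

__all__ = [
    "LINKS",
    "ModelSpec",
    "Fit",
    "fit_pseudo_glm",
    "sandwich_variance",
    "second_order_influence",
    "asymptotic_variance",
    "bootstrap_variance",
    "PseudoRegression",
]


class _Link:
    """Inverse link mu(eta), its derivative, the link g(mu), and mu-domain."""

    def __init__(self, name, mu, dmu, g, lo, hi):
        self.name, self.mu, self.dmu, self.g = name, mu, dmu, g
        self.lo, self.hi = lo, hi

    def in_domain(self, mu):
        return np.all(mu > self.lo) and np.all(mu < self.hi)


def _expit(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


LINKS = {
    "identity": _Link("identity", lambda e: e, lambda e: np.ones_like(e),
                      lambda m: m, -np.inf, np.inf),
    "log": _Link("log", np.exp, np.exp, np.log, 0.0, np.inf),
    "logit": _Link("logit", _expit, lambda e: _expit(e) * (1 - _expit(e)),
                   lambda m: np.log(m / (1 - m)), 0.0, 1.0),
    "cloglog": _Link("cloglog", lambda e: 1 - np.exp(-np.exp(e)),
                     lambda e: np.exp(e - np.exp(e)),
                     lambda m: np.log(-np.log(1 - m)), 0.0, 1.0),
}


@dataclass
class ModelSpec:
    """Mean-model configuration: link, intercept handling, A-function."""

    link: str = "identity"
    intercept: bool = True
    A_choice: str = "quasi-score"      # A = d mu / d beta (default)


@dataclass
class Fit:
    """Regression estimate with convergence info and variance estimates."""

    beta: np.ndarray
    iterations: int
    converged: bool
    vcov_hw: np.ndarray = None
    vcov_sigma: np.ndarray = None
    vcov_boot: np.ndarray = None
    n: int = 0
    link: str = "identity"
    ee_norm: float = np.nan

    def se(self, which: str = "hw") -> np.ndarray:
        v = {"hw": self.vcov_hw, "sigma": self.vcov_sigma,
             "boot": self.vcov_boot}[which]
        if v is None:
            raise ValueError(f"{which} variance was not computed")
        return np.sqrt(np.diag(v))


def _design(Z, intercept: bool) -> np.ndarray:
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[0] == 1 and Z.shape[1] > 1:
        Z = Z.T
    return np.column_stack([np.ones(Z.shape[0]), Z]) if intercept else Z


def _ee(beta, X, y, w, link):
    eta = X @ beta
    mu = link.mu(eta)
    dmu = link.dmu(eta)
    U = X * (w * dmu * (y - mu))[:, None]
    J = -(X * (w * dmu * dmu)[:, None]).T @ X     # Fisher-scoring Jacobian
    return U.sum(axis=0), J, mu


def fit_pseudo_glm(pseudos, Z, spec: ModelSpec = None, weights=None,
                   tol: float = 1e-10, max_iter: int = 100) -> Fit:
    """Solve the weighted estimating equation for the mean model.

    ``pseudos`` may be a :class:`~ijpseudo.pseudo.PseudoSet` (its
    sampling weights are used unless ``weights`` overrides them) or a
    plain response vector.  The identity link with the quasi-score A is
    solved in closed form (weighted least squares); other links use
    Fisher scoring with step-halving on domain violations, declaring
    convergence when the estimating-equation norm drops below ``tol``
    or the relative change in beta is below 1e-12.
    """
    spec = spec or ModelSpec()
    if isinstance(pseudos, PseudoSet):
        y = pseudos.values
        if weights is None:
            weights = pseudos.weights
    else:
        y = np.asarray(pseudos, dtype=float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    X = _design(Z, spec.intercept)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    link = LINKS[spec.link]

    if spec.link == "identity":
        XtW = (X * w[:, None]).T
        beta = np.linalg.solve(XtW @ X, XtW @ y)
        U, _, _ = _ee(beta, X, y, w, link)
        return Fit(beta=beta, iterations=1, converged=True, n=n,
                   link=spec.link, ee_norm=float(np.linalg.norm(U)))

    # initialisation: link(mean pseudo) for the intercept, 0 elsewhere
    ybar = float(np.clip(np.average(y, weights=w), 0.001, 0.999))
    beta = np.zeros(p)
    beta[0 if spec.intercept else 0] = link.g(ybar) if spec.intercept else 0.0
    U, J, mu = _ee(beta, X, y, w, link)
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(J, -U)
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError("singular Jacobian in Fisher scoring")
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            mu_c = link.mu(X @ cand)
            if link.in_domain(mu_c) and np.all(np.isfinite(mu_c)):
                break
            scale *= 0.5
        else:
            raise FloatingPointError(
                f"{spec.link} link: mean left its domain and step-halving "
                "did not recover"
            )
        rel = np.max(np.abs(scale * step) / np.maximum(np.abs(beta), 1e-12))
        beta = cand
        U, J, mu = _ee(beta, X, y, w, link)
        if np.linalg.norm(U) < tol or rel < 1e-12:
            return Fit(beta=beta, iterations=it, converged=True, n=n,
                       link=spec.link, ee_norm=float(np.linalg.norm(U)))
    return Fit(beta=beta, iterations=max_iter, converged=False, n=n,
               link=spec.link, ee_norm=float(np.linalg.norm(U)))


def sandwich_variance(fit: Fit, pseudos, Z, spec: ModelSpec = None,
                      weights=None) -> np.ndarray:
    """Huber--White robust covariance M^{-1}(sum_i U_i U_i')M^{-T} at beta^."""
    spec = spec or ModelSpec(link=fit.link)
    if isinstance(pseudos, PseudoSet):
        y = pseudos.values
        if weights is None:
            weights = pseudos.weights
    else:
        y = np.asarray(pseudos, dtype=float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    X = _design(Z, spec.intercept)
    link = LINKS[spec.link]
    eta = X @ fit.beta
    mu, dmu = link.mu(eta), link.dmu(eta)
    M = (X * (w * dmu * dmu)[:, None]).T @ X
    U = X * (w * dmu * (y - mu))[:, None]
    Minv = np.linalg.inv(M)
    vcov = Minv @ (U.T @ U) @ Minv.T
    fit.vcov_hw = vcov
    return vcov


def second_order_influence(sample: Sample, t: float, cause: int,
                           i1: int, i2: int, step: float = 1e-4) -> float:
    """Numerical second-order influence phiddot(X_i1, X_i2) of the AJ functional.

    Mixed second directional derivative of the Aalen--Johansen
    functional at F_n in directions (delta_{X_i1} - F_n) and
    (delta_{X_i2} - F_n), by 4-point central differences on a
    two-parameter reweighting of the sample.  ``step`` is the
    perturbation in direction space; keep it below 1/n so all weights
    stay positive.
    """
    n = sample.n
    base = np.full(n, 1.0 / n)
    e1 = np.zeros(n); e1[i1] = 1.0
    e2 = np.zeros(n); e2[i2] = 1.0
    v1, v2 = e1 - base, e2 - base

    def phi(s1, s2):
        w = base + s1 * v1 + s2 * v2
        if np.any(w < 0):
            raise ValueError("perturbed weights negative; reduce step")
        return aalen_johansen_weighted(sample, t, cause, w)

    h = step
    return (phi(h, h) - phi(h, -h) - phi(-h, h) + phi(-h, -h)) / (4.0 * h * h)


def asymptotic_variance(fit: Fit, sample: Sample, pseudos, Z,
                        spec: ModelSpec = None, step: float = 1e-4,
                        subsample: int = None, rng=None) -> np.ndarray:
    """Plug-in estimate of M^{-1} Var{h0 + h1} M^{-T} (untruncated path).

    h0_i is the per-subject estimating function at beta^ (the IJ
    decomposition term); h1_i = (1/n) sum_k A(beta^; Z_k)
    phiddot(X_k, X_i) adds the second-order influence correction that the
    Huber--White estimate ignores.  The full h1 computation costs
    O(n^2) functional evaluations; ``subsample`` draws that many k-terms
    per subject instead.
    """
    if sample.truncated:
        raise ValueError("asymptotic variance is implemented for untruncated samples")
    spec = spec or ModelSpec(link=fit.link)
    y = pseudos.values if isinstance(pseudos, PseudoSet) else np.asarray(pseudos)
    t = pseudos.t if isinstance(pseudos, PseudoSet) else None
    cause = pseudos.cause if isinstance(pseudos, PseudoSet) else 1
    X = _design(Z, spec.intercept)
    n, p = X.shape
    link = LINKS[spec.link]
    eta = X @ fit.beta
    mu, dmu = link.mu(eta), link.dmu(eta)
    A = X * dmu[:, None]                       # quasi-score rows
    h0 = A * (y - mu)[:, None]

    ks = np.arange(n)
    if subsample is not None and subsample < n:
        rng = np.random.default_rng(rng)
        ks = rng.choice(n, size=subsample, replace=False)
    # phiddot(X_k, X_i) for k in ks, all i
    h1 = np.zeros((n, p))
    for k in ks:
        row = np.array([second_order_influence(sample, t, cause, k, i, step)
                        for i in range(n)])
        h1 += row[:, None] * A[k][None, :]
    h1 /= len(ks)

    g = h0 + h1
    # uncentered sum of outer products: the estimating function has mean
    # zero at beta^, and this keeps the no-censoring case (h1 = 0) equal
    # to the sandwich exactly
    Sigma = g.T @ g
    M = (X * (dmu * dmu)[:, None]).T @ X
    Minv = np.linalg.inv(M)
    vcov = Minv @ np.atleast_2d(Sigma) @ Minv.T
    fit.vcov_sigma = vcov
    return vcov


def _pseudo_by_method(sample: Sample, t, cause, method, algorithm="efficient"):
    if method == "ij":
        return ij_pseudo(sample, t, cause)
    if method == "ij_truncated":
        return ij_pseudo_truncated(sample, t, cause)
    if method == "jackknife":
        return jackknife_pseudo(sample, t, cause, algorithm)
    if method == "ipcw":
        return ipcw_pseudo(sample, t, cause)
    raise ValueError(f"unknown pseudo-observation method {method!r}")


def bootstrap_variance(sample: Sample, t: float, cause: int,
                       spec: ModelSpec = None, B: int = 200, seed=None,
                       method: str = "ij", max_failures: float = 0.1) -> np.ndarray:
    """Nonparametric bootstrap covariance of beta^.

    Subjects (entry, time, status, Z) are resampled with replacement;
    pseudo-observations and, for truncated data, sampling weights are
    recomputed inside every replicate before refitting.  Replicate
    failures (degenerate resamples) are skipped and counted; more than
    ``max_failures`` of B is an error.  A fixed seed reproduces the
    matrix bit for bit.
    """
    if B < 2:
        raise ValueError("bootstrap needs B >= 2")
    spec = spec or ModelSpec()
    rng = np.random.default_rng(seed)
    betas, failures = [], 0
    for _ in range(B):
        idx = rng.integers(0, sample.n, sample.n)
        try:
            bs = sample.subset(idx)
            ps = _pseudo_by_method(bs, t, cause, method)
            f = fit_pseudo_glm(ps, bs.covariates, spec)
            if not f.converged:
                raise RuntimeError("non-convergence")
            betas.append(f.beta)
        except (ZeroDivisionError, FloatingPointError, RuntimeError,
                np.linalg.LinAlgError, ValueError):
            failures += 1
    if failures > max_failures * B:
        raise RuntimeError(f"{failures}/{B} bootstrap replicates failed")
    betas = np.asarray(betas)
    return np.atleast_2d(np.cov(betas, rowvar=False, bias=False))


# ---------------------------------------------------------------------------
# sklearn-style regressor
# ---------------------------------------------------------------------------

from sklearn.base import BaseEstimator, RegressorMixin  # noqa: E402

from .io import frame_to_sample  # noqa: E402


class PseudoRegression(BaseEstimator, RegressorMixin):
    """Pseudo-observation regression of a cumulative incidence at time t.

    Accepts a records DataFrame (columns ``entry`` (optional), ``time``,
    ``status``, plus covariates) or a :class:`~ijpseudo.core.Sample`.
    Computes pseudo-observations by the requested method, solves the
    (weighted) estimating equation for the chosen link, and exposes the
    requested variance estimates.

    Parameters
    ----------
    t, cause : analysis time and event type (or ``cause="survival"``).
    link : {"identity", "log", "logit", "cloglog"}.
    method : {"ij", "jackknife", "ij_truncated", "ipcw"}; "ij_truncated"
        applies inverse sampling weights to the estimating equation.
    variance : iterable of {"hw", "sigma", "boot"}.
    bootstrap_reps, random_state : bootstrap configuration.

    Fitted attributes: ``coef_``, ``vcov_hw_``, ``vcov_sigma_``,
    ``vcov_boot_``, ``pseudo_values_``, ``sample_weights_``,
    ``converged_``, ``n_iter_``, ``feature_names_in_``.
    """

    def __init__(self, t: float = 1.0, cause=1, link: str = "identity",
                 method: str = "ij", intercept: bool = True,
                 variance=("hw",), bootstrap_reps: int = 200,
                 random_state=None, covariates=None):
        self.t = t
        self.cause = cause
        self.link = link
        self.method = method
        self.intercept = intercept
        self.variance = variance
        self.bootstrap_reps = bootstrap_reps
        self.random_state = random_state
        self.covariates = covariates

    def _as_sample(self, X):
        if isinstance(X, Sample):
            self.feature_names_in_ = np.array(
                [f"z{j + 1}" for j in range(X.covariates.shape[1])])
            return X
        sample = frame_to_sample(X, covariates=self.covariates)
        names = (self.covariates if self.covariates is not None else
                 [c for c in X.columns
                  if c.lower() not in ("id", "entry", "time", "status",
                                       "pseudo", "weight")])
        self.feature_names_in_ = np.asarray(names)
        return sample

    def fit(self, X, y=None):
        sample = self._as_sample(X)
        method = self.method
        if method == "ij" and sample.truncated:
            method = "ij_truncated"
        from .pseudo import PseudoObservations, ij_pseudo_survival

        if self.cause == "survival":
            ps = ij_pseudo_survival(sample, self.t)
        else:
            ps = PseudoObservations(self.t, self.cause, method).fit(sample).pseudo_set_
        spec = ModelSpec(link=self.link, intercept=self.intercept)
        fit = fit_pseudo_glm(ps, sample.covariates, spec)
        self.sample_ = sample
        self.pseudo_set_ = ps
        self.pseudo_values_ = ps.values
        self.sample_weights_ = ps.weights
        self.coef_ = fit.beta
        self.converged_ = fit.converged
        self.n_iter_ = fit.iterations
        self.fit_ = fit
        if "hw" in self.variance:
            self.vcov_hw_ = sandwich_variance(fit, ps, sample.covariates, spec)
        if "sigma" in self.variance:
            self.vcov_sigma_ = asymptotic_variance(fit, sample, ps,
                                                   sample.covariates, spec)
        if "boot" in self.variance:
            self.vcov_boot_ = bootstrap_variance(
                sample, self.t, self.cause, spec, B=self.bootstrap_reps,
                seed=self.random_state, method=method)
            fit.vcov_boot = self.vcov_boot_
        return self

    def predict(self, X):
        """Predicted mean mu(beta^' x) for new covariate rows."""
        if isinstance(X, Sample):
            Z = X.covariates
        elif hasattr(X, "columns"):
            Z = X[list(self.feature_names_in_)].to_numpy(float)
        else:
            Z = np.atleast_2d(np.asarray(X, dtype=float))
        Xd = _design(Z, self.intercept)
        return LINKS[self.link].mu(Xd @ self.coef_)

    def summary(self, alpha: float = 0.05):
        """Term/estimate/SE/CI/p table using the Huber--White variance."""
        import pandas as pd
        from scipy.stats import norm  # scipy ships with sklearn's stack

        se = np.sqrt(np.diag(self.vcov_hw_))
        zq = norm.ppf(1 - alpha / 2)
        zval = self.coef_ / se
        terms = (["(Intercept)"] if self.intercept else []) + list(
            self.feature_names_in_)
        return pd.DataFrame({
            "term": terms,
            "estimate": self.coef_,
            "se_hw": se,
            "ci_low": self.coef_ - zq * se,
            "ci_high": self.coef_ + zq * se,
            "p": 2 * norm.sf(np.abs(zval)),
        })
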