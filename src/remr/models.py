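"""Subject-level mixed-effects models for clustered longitudinal data.

Implements the linear mixed model (ML or REML, random intercept or random
intercept+slope) and the logistic mixed model with a subject random intercept
(maximum likelihood via adaptive Gauss-Hermite quadrature), both in
unweighted and survey-weighted pseudo-likelihood form.  Sampling weights are
constant within subject and enter each subject's marginal log-likelihood
contribution as frequency-style multipliers, so an integer weight of w is
exactly equivalent to replicating the subject w times.

The Gaussian likelihood is the usual marginal normal form with
``Sigma_i = Z_i G Z_i' + sigma2_e I``; it is evaluated through the Woodbury
identity so the cost per objective evaluation is linear in the number of
rows.  Variance components are optimized on an unconstrained scale (log
variance ratio for a scalar random intercept, log-Cholesky for the 2x2
intercept+slope covariance) with the residual variance profiled out.
Boundary estimates below 1e-8 are reported as exact zeros and flagged.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logsumexp

from .data import LongitudinalDataset
from .design import build_design, check_full_rank

logger = logging.getLogger(__name__)

BOUNDARY_TOL = 1e-8
_LOG_GAMMA_BOUNDS = (-16.0, 23.0)


# --------------------------------------------------------------------------
# result containers
# --------------------------------------------------------------------------
@dataclass
class ModelSpec:
    """Declaration of a mixed model.

    ``fixed_terms`` is an ordered list of covariate names or
    :class:`~remr.design.Term` declarations; the intercept is implicit.
    ``random_structure`` is ``"intercept"`` (q=1) or ``"intercept+slope"``
    (q=2, the slope is on ``time``).  ``estimation`` is ``"REML"`` (gaussian
    default), ``"ML"`` or ``"pseudo-likelihood"`` (weighted fits).
    """

    family: str = "gaussian"  # "gaussian" | "binomial"
    fixed_terms: Sequence = field(default_factory=list)
    random_structure: str = "intercept"
    estimation: str = "REML"
    quadrature_points: int = 15
    robust_se: bool = False

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "binomial"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.random_structure not in ("intercept", "intercept+slope"):
            raise ValueError(f"unknown random structure {self.random_structure!r}")
        if self.estimation not in ("ML", "REML", "pseudo-likelihood"):
            raise ValueError(f"unknown estimation {self.estimation!r}")
        if self.quadrature_points < 1:
            raise ValueError("quadrature_points must be >= 1")
        if self.family == "binomial" and self.random_structure != "intercept":
            raise ValueError(
                "binomial family supports only a random intercept"
            )
        if self.random_structure == "intercept+slope":
            names = [t if isinstance(t, str) else t.name for t in self.fixed_terms]
            if "time" not in names:
                raise ValueError(
                    "intercept+slope random structure requires 'time' as a model term"
                )

    @property
    def q(self) -> int:
        return 1 if self.random_structure == "intercept" else 2


@dataclass
class VarianceComponents:
    """Random-effect covariance G (q x q) plus gaussian residual variance."""

    G: np.ndarray
    sigma2_e: float | None = None
    boundary: bool = False

    def __post_init__(self) -> None:
        self.G = np.atleast_2d(np.asarray(self.G, dtype=float))
        eig = np.linalg.eigvalsh((self.G + self.G.T) / 2.0)
        if eig.min() < -1e-8 * max(1.0, abs(eig).max()):
            raise ValueError("G must be positive semidefinite")
        if self.sigma2_e is not None and self.sigma2_e < 0:
            raise ValueError("sigma2_e must be non-negative")

    @property
    def q(self) -> int:
        return self.G.shape[0]

    def n_parameters(self) -> int:
        q = self.q
        n = q * (q + 1) // 2
        if self.sigma2_e is not None:
            n += 1
        return n

    def to_dict(self) -> dict:
        return {
            "G": self.G.tolist(),
            "sigma2_e": self.sigma2_e,
            "boundary": self.boundary,
        }


@dataclass
class FitResult:
    beta: pd.Series
    beta_cov: pd.DataFrame
    variance_components: VarianceComponents
    loglik: float
    aic: float
    bic: float
    n_subjects: int
    n_obs: int
    converged: bool
    n_iterations: int
    method: str
    spec: ModelSpec | None = None
    robust_cov: pd.DataFrame | None = None
    ic_comparable: bool = True
    dropped_terms: list = field(default_factory=list)
    k_params: int = 0

    @property
    def se(self) -> pd.Series:
        cov = self.robust_cov if (
            self.spec is not None and self.spec.robust_se and self.robust_cov is not None
        ) else self.beta_cov
        return pd.Series(np.sqrt(np.diag(cov.to_numpy())), index=self.beta.index)

    def coef_frame(self, alpha: float = 0.05) -> pd.DataFrame:
        from scipy.stats import norm

        se = self.se
        z = norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {
                "term": self.beta.index,
                "estimate": self.beta.to_numpy(),
                "se": se.to_numpy(),
                "ci_low": self.beta.to_numpy() - z * se.to_numpy(),
                "ci_high": self.beta.to_numpy() + z * se.to_numpy(),
            }
        )

    def to_dict(self) -> dict:
        return {
            "beta": self.beta.to_dict(),
            "se": self.se.to_dict(),
            "variance_components": self.variance_components.to_dict(),
            "loglik": self.loglik,
            "aic": self.aic,
            "bic": self.bic,
            "n_subjects": self.n_subjects,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "method": self.method,
            "ic_comparable": self.ic_comparable,
            "dropped_terms": list(self.dropped_terms),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def information_criteria(fit: FitResult) -> tuple[float, float]:
    """(AIC, BIC) with AIC = -2l + 2k and BIC = -2l + k log(m).

    k counts fixed effects plus distinct variance components; m is the number
    of subjects -- the independent sampling units of the marginal likelihood.
    For pseudo-likelihood fits the values are flagged as non-comparable
    across differing pseudo-data (see :attr:`FitResult.ic_comparable`).
    """
    if not fit.converged:
        logger.warning("information criteria requested for a non-converged fit")
    k = fit.k_params
    aic = -2.0 * fit.loglik + 2.0 * k
    bic = -2.0 * fit.loglik + k * math.log(fit.n_subjects)
    return aic, bic


# --------------------------------------------------------------------------
# data preparation
# --------------------------------------------------------------------------
class _Prepared:
    """Per-subject aggregated arrays shared by the gaussian and logit paths."""

    def __init__(self, data: LongitudinalDataset, spec: ModelSpec,
                 drop_constant_columns: bool = False):
        df = data.df
        X, names, dropped = build_design(
            df, spec.fixed_terms, drop_constant=drop_constant_columns
        )
        check_full_rank(X, names)
        y = df["outcome"].to_numpy(dtype=float)
        if spec.family == "binomial" and not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("binomial family requires outcomes in {0,1}")
        subj_codes, starts = np.unique(
            df["subject_id"].to_numpy(), return_index=True
        )
        # subjects are contiguous because LongitudinalDataset sorts rows
        starts = np.sort(starts)
        counts = np.diff(np.append(starts, len(df)))
        w = (
            df["weight"].to_numpy(dtype=float)[starts]
            if data.has_weights
            else np.ones(len(starts))
        )
        if np.any(w <= 0):
            raise ValueError("weights must be strictly positive")
        self.X, self.names, self.dropped = X, names, dropped
        self.y = y
        self.t = df["time"].to_numpy(dtype=float)
        self.starts, self.counts = starts, counts
        self.subj_idx = np.repeat(np.arange(len(starts)), counts)
        self.w = w
        self.wr = w[self.subj_idx]  # row-expanded subject weights
        self.n_subjects = len(starts)
        self.n_obs = len(df)
        self.p = X.shape[1]

    def rescale_weights(self) -> None:
        """Rescale subject weights to sum to the number of subjects."""
        total = self.w.sum()
        self.w = self.w * (self.n_subjects / total)
        self.wr = self.w[self.subj_idx]


def _reduceat(a: np.ndarray, starts: np.ndarray) -> np.ndarray:
    return np.add.reduceat(a, starts, axis=0)


# --------------------------------------------------------------------------
# gaussian family
# --------------------------------------------------------------------------
class _GaussianProfile:
    """Profiled (over beta and sigma2_e) gaussian objective.

    The marginal covariance is written sigma2_e * Lambda_i with
    Lambda_i = I + Z_i Gamma Z_i' and Gamma = G / sigma2_e, so the residual
    variance has a closed-form update and the optimization runs over the
    q(q+1)/2 free parameters of Gamma only.
    """

    def __init__(self, prep: _Prepared, reml: bool):
        self.prep = prep
        self.reml = reml
        X, y, wr = prep.X, prep.y, prep.wr
        self.XtWX = (X * wr[:, None]).T @ X
        self.XtWy = (X * wr[:, None]).T @ y
        self.ytWy = float(y @ (wr * y))
        self.sx = _reduceat(X, prep.starts)  # N x p
        self.sy = _reduceat(y, prep.starts)
        t = prep.t
        self.stx = _reduceat(X * t[:, None], prep.starts)
        self.sty = _reduceat(y * t, prep.starts)
        self.st = _reduceat(t, prep.starts)
        self.stt = _reduceat(t * t, prep.starts)
        self.n_w = float(prep.w @ prep.counts)

    # -- q = 1 ---------------------------------------------------------------
    def _moments_q1(self, gamma: float):
        prep = self.prep
        c = gamma / (1.0 + gamma * prep.counts)  # N
        wc = prep.w * c
        A = self.XtWX - (self.sx * wc[:, None]).T @ self.sx
        b = self.XtWy - self.sx.T @ (wc * self.sy)
        qyy = self.ytWy - float(wc @ (self.sy**2))
        logdet_lam = float(prep.w @ np.log1p(gamma * prep.counts))
        return A, b, qyy, logdet_lam

    # -- q = 2 (random intercept + slope on time) -----------------------------
    def _moments_q2(self, Gamma: np.ndarray):
        prep = self.prep
        N = prep.n_subjects
        S = np.empty((N, 2, 2))
        S[:, 0, 0] = prep.counts
        S[:, 0, 1] = S[:, 1, 0] = self.st
        S[:, 1, 1] = self.stt
        M = np.eye(2)[None, :, :] + S @ Gamma  # N x 2 x 2
        det = M[:, 0, 0] * M[:, 1, 1] - M[:, 0, 1] * M[:, 1, 0]
        Minv = np.empty_like(M)
        Minv[:, 0, 0] = M[:, 1, 1]
        Minv[:, 1, 1] = M[:, 0, 0]
        Minv[:, 0, 1] = -M[:, 0, 1]
        Minv[:, 1, 0] = -M[:, 1, 0]
        Minv /= det[:, None, None]
        C = np.broadcast_to(Gamma, (N, 2, 2)) @ Minv  # Gamma (I + S Gamma)^-1
        Cw = C * prep.w[:, None, None]
        U = np.stack([self.sx, self.stx], axis=1)  # N x 2 x p
        V = np.stack([self.sy, self.sty], axis=1)  # N x 2
        A = self.XtWX - np.einsum("nip,nij,njq->pq", U, Cw, U)
        b = self.XtWy - np.einsum("nip,nij,nj->p", U, Cw, V)
        qyy = self.ytWy - float(np.einsum("ni,nij,nj->", V, Cw, V))
        logdet_lam = float(self.prep.w @ np.log(det))
        return A, b, qyy, logdet_lam

    def solve(self, A, b, qyy, logdet_lam):
        p, n_w = self.prep.p, self.n_w
        beta = np.linalg.solve(A, b)
        rss = max(qyy - float(beta @ b), 1e-300)
        if self.reml:
            sigma2 = rss / (n_w - p)
            sign, logdet_a = np.linalg.slogdet(A)
            loglik = -0.5 * (
                (n_w - p) * (math.log(2 * math.pi) + math.log(sigma2) + 1.0)
                + logdet_lam
                + logdet_a
            )
        else:
            sigma2 = rss / n_w
            loglik = -0.5 * (
                n_w * (math.log(2 * math.pi) + math.log(sigma2) + 1.0) + logdet_lam
            )
        return beta, sigma2, loglik, A

    def objective_q1(self, log_gamma: float) -> float:
        gamma = math.exp(log_gamma)
        _, _, loglik, _ = self.solve(*self._moments_q1(gamma))
        return -loglik

    def objective_q2(self, theta: np.ndarray) -> float:
        Gamma = _gamma_from_logchol(theta)
        _, _, loglik, _ = self.solve(*self._moments_q2(Gamma))
        return -loglik

    def subject_scores(self, beta: np.ndarray, gamma_or_Gamma) -> np.ndarray:
        """Per-subject weighted score of beta at the solution, for the
        subject-level sandwich covariance.  Scores are on the Lambda scale;
        the common 1/sigma2 factor cancels between bread and meat."""
        prep = self.prep
        r = prep.y - prep.X @ beta
        Xr = _reduceat(prep.X * r[:, None], prep.starts)  # N x p
        sr = _reduceat(r, prep.starts)
        if np.isscalar(gamma_or_Gamma):
            c = gamma_or_Gamma / (1.0 + gamma_or_Gamma * prep.counts)
            S = Xr - self.sx * (c * sr)[:, None]
        else:
            Gamma = gamma_or_Gamma
            str_ = _reduceat(r * prep.t, prep.starts)
            V = np.stack([sr, str_], axis=1)
            N = prep.n_subjects
            S2 = np.empty((N, 2, 2))
            S2[:, 0, 0] = prep.counts
            S2[:, 0, 1] = S2[:, 1, 0] = self.st
            S2[:, 1, 1] = self.stt
            M = np.eye(2)[None, :, :] + S2 @ Gamma
            det = M[:, 0, 0] * M[:, 1, 1] - M[:, 0, 1] * M[:, 1, 0]
            Minv = np.empty_like(M)
            Minv[:, 0, 0] = M[:, 1, 1]
            Minv[:, 1, 1] = M[:, 0, 0]
            Minv[:, 0, 1] = -M[:, 0, 1]
            Minv[:, 1, 0] = -M[:, 1, 0]
            Minv /= det[:, None, None]
            C = np.broadcast_to(Gamma, (N, 2, 2)) @ Minv
            U = np.stack([self.sx, self.stx], axis=1)
            S = Xr - np.einsum("nip,nij,nj->np", U, C, V)
        return S * prep.w[:, None]


def _gamma_from_logchol(theta: np.ndarray) -> np.ndarray:
    """2x2 PSD matrix from its log-Cholesky parameters (a, b, c)."""
    L = np.array([[math.exp(theta[0]), 0.0], [theta[1], math.exp(theta[2])]])
    return L @ L.T


def marginal_loglik_gaussian(
    data: LongitudinalDataset,
    spec: ModelSpec,
    beta: np.ndarray,
    vc: VarianceComponents,
) -> float:
    """ML marginal log-likelihood at an arbitrary parameter point.

    Direct evaluation of the gaussian quadratic form through the same
    Woodbury factorization used by the fitter; serves as the hook for
    checking the fitter's objective against a dense-matrix computation.
    """
    prep = _Prepared(data, spec)
    sigma2 = float(vc.sigma2_e)
    r = prep.y - prep.X @ np.asarray(beta, dtype=float)
    total = 0.0
    for i, (s, c) in enumerate(zip(prep.starts, prep.counts)):
        ri = r[s : s + c]
        Z = (
            np.ones((c, 1))
            if spec.q == 1
            else np.column_stack([np.ones(c), prep.t[s : s + c]])
        )
        Sig = Z @ vc.G @ Z.T + sigma2 * np.eye(c)
        sign, logdet = np.linalg.slogdet(Sig)
        quad = float(ri @ np.linalg.solve(Sig, ri))
        total += prep.w[i] * (
            -0.5 * (c * math.log(2 * math.pi) + logdet + quad)
        )
    return total


def fit_lmm(
    data: LongitudinalDataset,
    spec: ModelSpec,
    gamma_fixed: float | np.ndarray | None = None,
    drop_constant_columns: bool = False,
    _prep: _Prepared | None = None,
) -> FitResult:
    """Fit a gaussian linear mixed model by ML or REML.

    ``gamma_fixed`` pins the variance ratio G/sigma2_e instead of estimating
    it (0 gives the generalized-least-squares/OLS reduction); the residual
    variance is still profiled.
    """
    if spec.family != "gaussian":
        raise ValueError("fit_lmm requires the gaussian family")
    estimation = spec.estimation
    if estimation == "pseudo-likelihood":
        estimation = "REML"  # weighted gaussian pseudo-likelihood is REML-form
    reml = estimation == "REML"
    prep = _prep if _prep is not None else _Prepared(
        data, spec, drop_constant_columns
    )
    prof = _GaussianProfile(prep, reml=reml)

    n_iter = 0
    converged = True
    if spec.q == 1:
        if gamma_fixed is not None:
            gamma = float(gamma_fixed)
        else:
            res = optimize.minimize_scalar(
                prof.objective_q1,
                bounds=_LOG_GAMMA_BOUNDS,
                method="bounded",
                options={"xatol": 1e-10, "maxiter": 500},
            )
            n_iter = int(res.nfev)
            converged = bool(res.success)
            gamma = math.exp(float(res.x))
            # the unconstrained scale cannot reach zero; take the boundary
            # when it beats the interior solution
            if prof.objective_q1(_LOG_GAMMA_BOUNDS[0]) <= res.fun:
                gamma = math.exp(_LOG_GAMMA_BOUNDS[0])
        A, b, qyy, logdet_lam = prof._moments_q1(gamma)
        beta, sigma2, loglik, A = prof.solve(A, b, qyy, logdet_lam)
        G = np.array([[gamma * sigma2]])
        gamma_repr: float | np.ndarray = gamma
    else:
        if gamma_fixed is not None:
            Gamma = np.atleast_2d(np.asarray(gamma_fixed, dtype=float))
        else:
            x0 = _q2_start(prof)
            res = optimize.minimize(
                prof.objective_q2,
                x0,
                method="L-BFGS-B",
                bounds=[(-10.0, 10.0), (-30.0, 30.0), (-10.0, 10.0)],
                options={"ftol": 1e-12, "gtol": 1e-7, "maxiter": 500},
            )
            n_iter = int(res.nit)
            converged = bool(res.success)
            Gamma = _gamma_from_logchol(res.x)
        A, b, qyy, logdet_lam = prof._moments_q2(Gamma)
        beta, sigma2, loglik, A = prof.solve(A, b, qyy, logdet_lam)
        G = Gamma * sigma2
        gamma_repr = Gamma

    boundary = False
    if sigma2 < BOUNDARY_TOL:
        sigma2 = 0.0
        boundary = True
    Gd = np.diag(G).copy()
    if np.any(Gd < BOUNDARY_TOL):
        boundary = True
        for j in np.where(Gd < BOUNDARY_TOL)[0]:
            G[j, :] = 0.0
            G[:, j] = 0.0
    vc = VarianceComponents(G=G, sigma2_e=sigma2, boundary=boundary)

    beta_cov = sigma2 * np.linalg.inv(A) if sigma2 > 0 else 0.0 * np.linalg.inv(A)
    if not converged:
        warnings.warn("LMM optimizer did not converge", RuntimeWarning)

    fit = _assemble_result(
        prep, spec, beta, beta_cov, vc, loglik,
        method=estimation if spec.estimation != "pseudo-likelihood" else "pseudo-likelihood",
        converged=converged, n_iterations=n_iter,
    )
    if spec.robust_se or spec.estimation == "pseudo-likelihood":
        S = prof.subject_scores(beta, gamma_repr)
        bread = np.linalg.inv(A)  # (X' Lambda^-1 X)^-1; sigma2 cancels
        meat = S.T @ S
        rob = bread @ meat @ bread
        fit.robust_cov = pd.DataFrame(rob, index=prep.names, columns=prep.names)
    return fit


def _q2_start(prof: _GaussianProfile) -> np.ndarray:
    """Start the 2x2 search from the fitted random-intercept ratio."""
    res = optimize.minimize_scalar(
        prof.objective_q1, bounds=_LOG_GAMMA_BOUNDS, method="bounded",
        options={"xatol": 1e-6, "maxiter": 200},
    )
    a0 = 0.5 * math.log(max(math.exp(res.x), 1e-4))
    return np.array([a0, 0.0, -2.0])


def _assemble_result(
    prep: _Prepared,
    spec: ModelSpec,
    beta: np.ndarray,
    beta_cov: np.ndarray,
    vc: VarianceComponents,
    loglik: float,
    method: str,
    converged: bool,
    n_iterations: int,
) -> FitResult:
    names = prep.names
    k = prep.p + vc.n_parameters()
    fit = FitResult(
        beta=pd.Series(beta, index=names),
        beta_cov=pd.DataFrame(beta_cov, index=names, columns=names),
        variance_components=vc,
        loglik=float(loglik),
        aic=math.nan,
        bic=math.nan,
        n_subjects=prep.n_subjects,
        n_obs=prep.n_obs,
        converged=converged,
        n_iterations=n_iterations,
        method=method,
        spec=spec,
        ic_comparable=method != "pseudo-likelihood",
        dropped_terms=list(prep.dropped),
        k_params=k,
    )
    fit.aic, fit.bic = information_criteria(fit)
    return fit


# --------------------------------------------------------------------------
# binomial family (logit link, random intercept)
# --------------------------------------------------------------------------
def _row_bernoulli_loglik(y: np.ndarray, eta: np.ndarray) -> np.ndarray:
    return y * eta - np.logaddexp(0.0, eta)


def _logistic_irls(X, y, wr, max_iter=100, tol=1e-10):
    """Plain weighted logistic regression MLE (Newton / IRLS)."""
    p = X.shape[1]
    beta = np.zeros(p)
    for it in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        Wd = wr * np.clip(mu * (1 - mu), 1e-10, None)
        g = X.T @ (wr * (y - mu))
        H = (X * Wd[:, None]).T @ X
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            return beta, H, it + 1, True
    return beta, H, max_iter, False


class _LogitMarginal:
    """Vectorized adaptive Gauss-Hermite marginal log-likelihood."""

    def __init__(self, prep: _Prepared, n_points: int):
        self.prep = prep
        nodes, weights = np.polynomial.hermite.hermgauss(n_points)
        self.nodes = nodes
        self.logw_plus_t2 = np.log(weights) + nodes**2

    def _find_modes(self, eta: np.ndarray, sigma2_b: float):
        """Per-subject mode and curvature of the integrand (Newton)."""
        prep = self.prep
        b = np.zeros(prep.n_subjects)
        for _ in range(50):
            mu = expit(eta + b[prep.subj_idx])
            g = _reduceat(prep.y - mu, prep.starts) - b / sigma2_b
            h = -_reduceat(mu * (1 - mu), prep.starts) - 1.0 / sigma2_b
            step = g / h
            b = b - step
            if np.max(np.abs(step)) < 1e-11:
                break
        mu = expit(eta + b[prep.subj_idx])
        h = -_reduceat(mu * (1 - mu), prep.starts) - 1.0 / sigma2_b
        return b, 1.0 / np.sqrt(-h)

    def subject_logliks(self, beta: np.ndarray, sigma_b: float) -> np.ndarray:
        prep = self.prep
        eta = prep.X @ beta
        if sigma_b < 1e-8:
            return _reduceat(_row_bernoulli_loglik(prep.y, eta), prep.starts)
        sigma2_b = sigma_b * sigma_b
        bhat, shat = self._find_modes(eta, sigma2_b)
        bk = bhat[:, None] + math.sqrt(2.0) * shat[:, None] * self.nodes[None, :]
        eta_k = eta[:, None] + bk[prep.subj_idx, :]
        H = _reduceat(
            _row_bernoulli_loglik(prep.y[:, None], eta_k), prep.starts
        )  # N x K
        H = H - bk**2 / (2 * sigma2_b) - 0.5 * math.log(
            2 * math.pi * sigma2_b
        )
        return logsumexp(self.logw_plus_t2[None, :] + H, axis=1) + np.log(
            math.sqrt(2.0) * shat
        )

    def total(self, x: np.ndarray) -> float:
        beta, sigma_b = x[:-1], math.exp(x[-1])
        return float(self.prep.w @ self.subject_logliks(beta, sigma_b))


def fit_glmm_logit(
    data: LongitudinalDataset,
    spec: ModelSpec,
    re_variance_fixed: float | None = None,
    drop_constant_columns: bool = False,
    compute_se: bool = True,
    _prep: _Prepared | None = None,
) -> FitResult:
    """Fit a logistic mixed model (random intercept) by ML.

    The marginal likelihood integral is approximated by adaptive
    Gauss-Hermite quadrature with ``spec.quadrature_points`` nodes, centered
    and scaled at each subject's empirical-Bayes mode.  Apparent separation
    (diverging coefficients) is reported as non-convergence, never silently.
    """
    if spec.family != "binomial":
        raise ValueError("fit_glmm_logit requires the binomial family")
    prep = _prep if _prep is not None else _Prepared(
        data, spec, drop_constant_columns
    )
    beta0, H0, n0, ok0 = _logistic_irls(prep.X, prep.y, prep.wr)

    if re_variance_fixed is not None:
        if re_variance_fixed != 0.0:
            raise ValueError("only re_variance_fixed=0 is supported")
        loglik = float(
            prep.w
            @ _reduceat(_row_bernoulli_loglik(prep.y, prep.X @ beta0), prep.starts)
        )
        vc = VarianceComponents(G=np.array([[0.0]]), sigma2_e=None, boundary=True)
        cov = np.linalg.inv(H0)
        fit = _assemble_result(
            prep, spec, beta0, cov, vc, loglik,
            method="ML", converged=ok0, n_iterations=n0,
        )
        fit.k_params = prep.p  # no free variance component
        fit.aic, fit.bic = information_criteria(fit)
        return fit

    marg = _LogitMarginal(prep, spec.quadrature_points)
    n_w = float(prep.w @ prep.counts)

    def neg(x: np.ndarray) -> float:
        return -marg.total(x) / n_w

    x0 = np.append(beta0, 0.0)  # log sigma_b = 0
    res = optimize.minimize(
        neg, x0, method="BFGS",
        options={"gtol": 1e-7, "maxiter": 300},
    )
    x = res.x
    converged = bool(res.success) or float(
        np.max(np.abs(res.jac))
    ) < 1e-5
    if np.max(np.abs(x[:-1])) > 30.0:
        warnings.warn(
            "coefficients diverging; possible (quasi-)complete separation",
            RuntimeWarning,
        )
        converged = False
    if not converged and res.success is False and np.max(np.abs(res.jac)) >= 1e-5:
        warnings.warn("GLMM optimizer did not converge", RuntimeWarning)

    beta, sigma_b = x[:-1], math.exp(x[-1])
    loglik = marg.total(x)
    sigma2_b = sigma_b * sigma_b
    boundary = sigma2_b < BOUNDARY_TOL
    vc = VarianceComponents(
        G=np.array([[0.0 if boundary else sigma2_b]]),
        sigma2_e=None,
        boundary=boundary,
    )
    if compute_se:
        Hn = _numeric_hessian(neg, x) * n_w  # observed information
        cov_all = _robust_psd_inv(Hn)
        cov = cov_all[: prep.p, : prep.p]
    else:
        cov = np.full((prep.p, prep.p), np.nan)
    fit = _assemble_result(
        prep, spec, beta, cov, vc, loglik,
        method="ML" if spec.estimation != "pseudo-likelihood" else "pseudo-likelihood",
        converged=converged, n_iterations=int(res.nit),
    )
    if spec.robust_se and compute_se:
        S = _subject_scores_numeric(marg, x)  # N x (p+1), weighted
        bread = cov_all
        meat = S.T @ S
        rob = (bread @ meat @ bread)[: prep.p, : prep.p]
        fit.robust_cov = pd.DataFrame(rob, index=prep.names, columns=prep.names)
    return fit


def _numeric_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of a scalar function."""
    m = len(x)
    H = np.empty((m, m))
    f0 = f(x)
    for j in range(m):
        ej = np.zeros(m)
        ej[j] = h
        H[j, j] = (f(x + ej) - 2 * f0 + f(x - ej)) / h**2
    for j in range(m):
        for k in range(j + 1, m):
            ej = np.zeros(m)
            ek = np.zeros(m)
            ej[j] = h
            ek[k] = h
            H[j, k] = H[k, j] = (
                f(x + ej + ek) - f(x + ej - ek) - f(x - ej + ek) + f(x - ej - ek)
            ) / (4 * h**2)
    return H


def _robust_psd_inv(H: np.ndarray) -> np.ndarray:
    """Inverse of a (numerically) PSD information matrix via eigen clipping."""
    vals, vecs = np.linalg.eigh((H + H.T) / 2.0)
    vals = np.clip(vals, 1e-12 * max(vals.max(), 1.0), None)
    return (vecs / vals) @ vecs.T


def _subject_scores_numeric(
    marg: _LogitMarginal, x: np.ndarray, h: float = 1e-5
) -> np.ndarray:
    """Per-subject weighted score vectors by central differences."""
    prep = marg.prep
    m = len(x)
    S = np.empty((prep.n_subjects, m))
    for j in range(m):
        ej = np.zeros(m)
        ej[j] = h
        lp = marg.subject_logliks(
            (x + ej)[:-1], math.exp((x + ej)[-1])
        )
        lm = marg.subject_logliks(
            (x - ej)[:-1], math.exp((x - ej)[-1])
        )
        S[:, j] = (lp - lm) / (2 * h)
    return S * prep.w[:, None]


def brute_force_marginal_loglik(
    data: LongitudinalDataset,
    beta: np.ndarray,
    vc: VarianceComponents,
    spec: ModelSpec | None = None,
    n_grid: int = 4001,
) -> float:
    """Dense deterministic 1-D integration of the logit marginal likelihood.

    Test-scale oracle for the quadrature path: trapezoid rule over a grid
    spanning +-8 SD of the random intercept.  Refuses the gaussian family
    (the marginal likelihood there has a closed form) and datasets with more
    than 50 subjects.
    """
    spec = spec or ModelSpec(family="binomial", fixed_terms=[])
    if spec.family != "binomial":
        raise ValueError(
            "brute-force integration is for the binomial family only; "
            "the gaussian marginal likelihood has a closed form"
        )
    if data.n_subjects > 50:
        raise ValueError("oracle is test-scale only (<= 50 subjects)")
    prep = _Prepared(data, spec)
    eta = prep.X @ np.asarray(beta, dtype=float)
    sigma2_b = float(vc.G[0, 0])
    base = _reduceat(_row_bernoulli_loglik(prep.y, eta), prep.starts)
    if sigma2_b == 0.0:
        return float(prep.w @ base)
    sigma_b = math.sqrt(sigma2_b)
    grid = np.linspace(-8 * sigma_b, 8 * sigma_b, n_grid)
    total = 0.0
    for i, (s, c) in enumerate(zip(prep.starts, prep.counts)):
        yi = prep.y[s : s + c, None]
        ei = eta[s : s + c, None]
        logf = _row_bernoulli_loglik(yi, ei + grid[None, :]).sum(axis=0)
        logf = logf - grid**2 / (2 * sigma2_b) - 0.5 * math.log(
            2 * math.pi * sigma2_b
        )
        m = logf.max()
        integral = np.trapezoid(np.exp(logf - m), grid)
        total += prep.w[i] * (m + math.log(integral))
    return float(total)


def quadrature_objective(
    data: LongitudinalDataset,
    spec: ModelSpec,
    beta: np.ndarray,
    vc: VarianceComponents,
) -> float:
    """The fitter's internal AGQ marginal log-likelihood at a parameter point."""
    prep = _Prepared(data, spec)
    marg = _LogitMarginal(prep, spec.quadrature_points)
    sigma_b = math.sqrt(float(vc.G[0, 0]))
    return float(prep.w @ marg.subject_logliks(np.asarray(beta, float), sigma_b))


# --------------------------------------------------------------------------
# weighted pseudo-likelihood front end
# --------------------------------------------------------------------------
def fit_weighted(
    data: LongitudinalDataset,
    spec: ModelSpec,
    normalize_weights: bool = True,
    drop_constant_columns: bool = False,
) -> FitResult:
    """Survey-weighted pseudo-likelihood fit (gaussian or binomial).

    Subject-level weights multiply each subject's marginal log-likelihood
    contribution.  By default weights are rescaled to sum to the number of
    analyzed subjects, which leaves point estimates unchanged (a common
    rescaling of the whole objective) but keeps pseudo-likelihood magnitudes
    on the unweighted scale; pass ``normalize_weights=False`` for raw
    weights.  With ``spec.robust_se`` the reported covariance is the
    subject-level sandwich estimator.
    """
    if not data.has_weights:
        raise ValueError("fit_weighted requires a 'weight' column")
    if spec.estimation != "pseudo-likelihood":
        raise ValueError("fit_weighted requires estimation='pseudo-likelihood'")
    prep = _Prepared(data, spec, drop_constant_columns)
    if normalize_weights:
        prep.rescale_weights()
    if spec.family == "gaussian":
        fit = fit_lmm(data, spec, _prep=prep)
    else:
        fit = fit_glmm_logit(data, spec, _prep=prep)
    fit.ic_comparable = False
    fit.method = "pseudo-likelihood"
    return fit
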