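"""Pooling of per-cluster coefficient estimates by meta-regression.

A large clustered cohort is partitioned by cluster (e.g. administrative
region), the subject-level mixed model is fitted independently within each
cluster, and each coefficient's cluster estimates ``phi_i`` with standard
errors ``sigma_i`` are pooled into a national estimate:

* fixed-effects meta-regression (FEMR): inverse-variance weighted least
  squares ``phi_i = tau + gamma1*z_i + gamma2*x_i + eps_i``,
  ``eps_i ~ N(0, sigma_i^2)``;
* random-effects meta-regression (REMR): adds a between-cluster component
  ``nu_i ~ N(0, sigma_v^2)`` estimated by the one-step DerSimonian-Laird
  moment estimator (default) or restricted maximum likelihood.

Pooling assumes homogeneity of cluster-level effects; Cochran's Q, I² and an
iterative leave-one-out outlier screen are provided to check and restore it.
Each coefficient is pooled separately with its own sigma_v^2.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data import LongitudinalDataset
from .models import FitResult, ModelSpec, fit_glmm_logit, fit_lmm

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------
@dataclass
class ClusterEstimate:
    """One cluster's estimate of one coefficient."""

    cluster_id: object
    phi: float
    sigma: float
    n_cluster: int = 0
    z: np.ndarray | None = None  # cluster-level covariates
    x: np.ndarray | None = None  # aggregates of subject-level covariates

    def __post_init__(self) -> None:
        if not np.isfinite(self.phi):
            raise ValueError("phi must be finite")
        if not (np.isfinite(self.sigma) and self.sigma > 0):
            raise ValueError("sigma must be strictly positive and finite")
        if self.z is not None:
            self.z = np.atleast_1d(np.asarray(self.z, dtype=float))
        if self.x is not None:
            self.x = np.atleast_1d(np.asarray(self.x, dtype=float))


@dataclass
class HomogeneityResult:
    Q: float
    df: int
    p_value: float
    I2: float


@dataclass
class PooledResult:
    tau: float
    se_tau: float
    ci: tuple[float, float]
    sigma2_v: float
    method: str  # FEMR | REMR-DL | REMR-REML
    homogeneity: HomogeneityResult | None = None
    gamma: np.ndarray | None = None
    excluded_clusters: list = field(default_factory=list)
    k: int = 0

    def to_dict(self) -> dict:
        return {
            "tau": self.tau,
            "se_tau": self.se_tau,
            "ci_low": self.ci[0],
            "ci_high": self.ci[1],
            "sigma2_v": self.sigma2_v,
            "method": self.method,
            "k": self.k,
            "Q": None if self.homogeneity is None else self.homogeneity.Q,
            "Q_df": None if self.homogeneity is None else self.homogeneity.df,
            "Q_p_value": None
            if self.homogeneity is None
            else self.homogeneity.p_value,
            "I2": None if self.homogeneity is None else self.homogeneity.I2,
            "gamma": None if self.gamma is None else list(self.gamma),
            "excluded_clusters": list(self.excluded_clusters),
        }


# --------------------------------------------------------------------------
# helpers
# --------------------------------------------------------------------------
def _meta_design(estimates: list[ClusterEstimate]) -> np.ndarray:
    """Intercept plus any cluster-level (z) and aggregate (x) covariates."""
    k = len(estimates)
    cols = [np.ones(k)]
    if estimates[0].z is not None:
        cols.append(np.vstack([e.z for e in estimates]))
    if estimates[0].x is not None:
        cols.append(np.vstack([e.x for e in estimates]))
    return np.column_stack(cols)


def _wls(phi, D, w):
    """Weighted least squares; returns (coef, cov, Q residual statistic)."""
    Dw = D * w[:, None]
    M = Dw.T @ D
    try:
        cov = np.linalg.inv(M)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular meta-regression design") from exc
    if np.linalg.cond(M) > 1e12:
        raise ValueError("singular meta-regression design")
    coef = cov @ (Dw.T @ phi)
    resid = phi - D @ coef
    Q = float(w @ resid**2)
    return coef, cov, Q


def _dl_denominator(D: np.ndarray, w: np.ndarray) -> float:
    """tr(P) for the method-of-moments estimator: sum(w) - tr((D'WD)^-1 D'W²D).

    Reduces to sum(w) - sum(w²)/sum(w) for an intercept-only design.
    """
    M = np.linalg.inv((D * w[:, None]).T @ D)
    return float(w.sum() - np.trace(M @ ((D * (w**2)[:, None]).T @ D)))


def _finish(tau, se, sigma2_v, method, hom, gamma, k, alpha=0.05) -> PooledResult:
    zcrit = stats.norm.ppf(1 - alpha / 2)
    return PooledResult(
        tau=float(tau),
        se_tau=float(se),
        ci=(float(tau - zcrit * se), float(tau + zcrit * se)),
        sigma2_v=float(sigma2_v),
        method=method,
        homogeneity=hom,
        gamma=gamma,
        k=k,
    )


def _single_passthrough(e: ClusterEstimate, method: str) -> PooledResult:
    warnings.warn(
        "pooling a single cluster estimate: pass-through", RuntimeWarning
    )
    return _finish(e.phi, e.sigma, 0.0, method, None, None, k=1)


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------
def homogeneity_test(estimates: list[ClusterEstimate]) -> HomogeneityResult:
    """Cochran's Q against the fixed-effects fit, with I² = max(0,(Q-df)/Q).

    When meta-covariates are attached the test is for residual heterogeneity
    (df reduced by the number of covariates).
    """
    k = len(estimates)
    if k < 2:
        raise ValueError("homogeneity test requires at least 2 clusters")
    phi = np.array([e.phi for e in estimates])
    w = np.array([1.0 / e.sigma**2 for e in estimates])
    D = _meta_design(estimates)
    _, _, Q = _wls(phi, D, w)
    df = k - D.shape[1]
    p = float(stats.chi2.sf(Q, df)) if df > 0 else math.nan
    I2 = max(0.0, (Q - df) / Q) if Q > 0 else 0.0
    return HomogeneityResult(Q=float(Q), df=df, p_value=p, I2=float(I2))


def pool_femr(estimates: list[ClusterEstimate]) -> PooledResult:
    """Fixed-effects meta-regression: inverse-variance WLS of phi on
    (1, z, x).  With no covariates this is the classical inverse-variance
    pooled mean."""
    k = len(estimates)
    if k < 1:
        raise ValueError("no estimates to pool")
    if k == 1:
        return _single_passthrough(estimates[0], "FEMR")
    phi = np.array([e.phi for e in estimates])
    w = np.array([1.0 / e.sigma**2 for e in estimates])
    D = _meta_design(estimates)
    if k <= D.shape[1]:
        raise ValueError(
            f"need more clusters ({k}) than meta-regression parameters "
            f"({D.shape[1]})"
        )
    coef, cov, _ = _wls(phi, D, w)
    hom = homogeneity_test(estimates)
    gamma = coef[1:] if D.shape[1] > 1 else None
    return _finish(coef[0], math.sqrt(cov[0, 0]), 0.0, "FEMR", hom, gamma, k)


def pool_remr(
    estimates: list[ClusterEstimate],
    method: str = "DL",
    knapp_hartung: bool = False,
) -> PooledResult:
    """Random-effects meta-regression pooled estimate.

    ``method="DL"``: one-step DerSimonian-Laird; the between-cluster variance
    is the truncated moment estimator from Cochran's Q, after which clusters
    are re-weighted by 1/(sigma_i^2 + sigma_v^2).  ``method="REML"``:
    restricted maximum likelihood by bounded 1-D search over sigma_v^2 with
    (tau, gamma) profiled out.  The confidence interval uses normal quantiles
    (classic one-step form) unless ``knapp_hartung`` is set.
    """
    if method not in ("DL", "REML"):
        raise ValueError(f"unknown REMR method {method!r}")
    k = len(estimates)
    if k < 1:
        raise ValueError("no estimates to pool")
    if k == 1:
        return _single_passthrough(estimates[0], f"REMR-{method}")
    phi = np.array([e.phi for e in estimates])
    s2 = np.array([e.sigma**2 for e in estimates])
    D = _meta_design(estimates)
    if k <= D.shape[1]:
        raise ValueError(
            f"need more clusters ({k}) than meta-regression parameters "
            f"({D.shape[1]})"
        )
    hom = homogeneity_test(estimates)

    if method == "DL":
        w = 1.0 / s2
        sigma2_v = max(0.0, (hom.Q - hom.df) / _dl_denominator(D, w))
    else:
        sigma2_v = _reml_sigma2_v(phi, D, s2)

    w_star = 1.0 / (s2 + sigma2_v)
    coef, cov, _ = _wls(phi, D, w_star)
    tau = coef[0]
    se = math.sqrt(cov[0, 0])
    gamma = coef[1:] if D.shape[1] > 1 else None
    if knapp_hartung:
        resid = phi - D @ coef
        q_kh = float(w_star @ resid**2) / (k - D.shape[1])
        se = se * math.sqrt(max(q_kh, 1.0))
        zcrit = stats.t.ppf(0.975, k - D.shape[1])
        return PooledResult(
            tau=float(tau),
            se_tau=float(se),
            ci=(float(tau - zcrit * se), float(tau + zcrit * se)),
            sigma2_v=float(sigma2_v),
            method=f"REMR-{method}",
            homogeneity=hom,
            gamma=gamma,
            k=k,
        )
    return _finish(tau, se, sigma2_v, f"REMR-{method}", hom, gamma, k)


def _reml_sigma2_v(phi: np.ndarray, D: np.ndarray, s2: np.ndarray) -> float:
    """Profiled restricted likelihood over the between-cluster variance."""

    def neg_restricted(sv2: float) -> float:
        w = 1.0 / (s2 + sv2)
        coef, _, _ = _wls(phi, D, w)
        resid = phi - D @ coef
        sign, logdet = np.linalg.slogdet((D * w[:, None]).T @ D)
        return 0.5 * (
            float(np.log(s2 + sv2).sum()) + logdet + float(w @ resid**2)
        )

    upper = max(float(np.var(phi) * 10.0), float(s2.max()) * 10.0, 1e-8)
    res = optimize.minimize_scalar(
        neg_restricted, bounds=(0.0, upper), method="bounded",
        options={"xatol": 1e-10},
    )
    sv2 = float(res.x)
    # accept the boundary when it is at least as good
    if neg_restricted(0.0) <= res.fun:
        sv2 = 0.0
    return sv2


def screen_outliers(
    estimates: list[ClusterEstimate],
    threshold: float = 3.0,
) -> tuple[list[ClusterEstimate], list[ClusterEstimate], pd.DataFrame]:
    """Iterative leave-one-out outlier screen on cluster estimates.

    For each cluster the externally standardized residual
    ``(phi_i - tau_(-i)) / sqrt(sigma_i^2 + sigma_v(-i)^2 + se^2(tau_(-i)))``
    is computed from a DerSimonian-Laird fit on the remaining clusters; the
    cluster with the largest absolute residual exceeding ``threshold`` is
    excluded and the screen repeats, never reducing the kept set below 3
    clusters.  Ties break deterministically by cluster_id order.  The
    operational rule (leave-one-out studentization, default threshold 3.0)
    is this package's own choice and is recorded in the report.
    """
    if len(estimates) < 3:
        raise ValueError("outlier screening requires at least 3 clusters")
    kept = sorted(estimates, key=lambda e: str(e.cluster_id))
    excluded: list[ClusterEstimate] = []
    rows = []
    iteration = 0
    while True:
        iteration += 1
        if len(kept) <= 3:
            if excluded:
                warnings.warn(
                    "outlier screen stopped at the 3-cluster floor",
                    RuntimeWarning,
                )
            break
        resids = np.empty(len(kept))
        for i in range(len(kept)):
            rest = kept[:i] + kept[i + 1 :]
            loo = pool_remr(rest, method="DL")
            e = kept[i]
            denom = math.sqrt(e.sigma**2 + loo.sigma2_v + loo.se_tau**2)
            resids[i] = (e.phi - loo.tau) / denom
        j = int(np.argmax(np.abs(resids)))
        if abs(resids[j]) <= threshold:
            break
        out = kept.pop(j)
        excluded.append(out)
        rows.append(
            {
                "iteration": iteration,
                "cluster_id": out.cluster_id,
                "residual": float(resids[j]),
                "threshold": threshold,
            }
        )
        logger.info(
            "excluded cluster %s (studentized residual %.2f)",
            out.cluster_id,
            resids[j],
        )
    report = pd.DataFrame(
        rows, columns=["iteration", "cluster_id", "residual", "threshold"]
    )
    return kept, excluded, report


# --------------------------------------------------------------------------
# cluster-wise fitting
# --------------------------------------------------------------------------
@dataclass
class ClusterFitSet:
    """Per-coefficient cluster estimates plus the underlying fits."""

    estimates: dict[str, list[ClusterEstimate]]
    fits: dict[object, FitResult]
    exclusions: pd.DataFrame  # cluster_id, coefficient/None, reason


def fit_by_cluster(
    data: LongitudinalDataset,
    spec: ModelSpec,
    coefficient_names: list[str] | None = None,
    aggregate_covariates: list[str] | None = None,
) -> ClusterFitSet:
    """Fit the subject-level mixed model independently within each cluster.

    Fits are order-independent (clusters are processed in sorted cluster_id
    order and share no state), so the operation parallelizes by contract.
    Clusters where a named coefficient is inestimable (for instance an empty
    covariate category) are excluded from that coefficient's estimate set
    only; clusters whose fit fails or does not converge are excluded
    entirely, with the reason recorded.

    ``aggregate_covariates`` names subject-level columns whose cluster means
    are attached to each estimate as the ``x`` meta-regression covariates.
    """
    cluster_ids = sorted(data.df["cluster_id"].unique(), key=str)
    if len(cluster_ids) < 2:
        raise ValueError("cluster-wise fitting requires at least 2 clusters")
    estimates: dict[str, list[ClusterEstimate]] = {}
    fits: dict[object, FitResult] = {}
    exclusions = []
    for cid in cluster_ids:
        sub = data.subset_cluster(cid)
        try:
            if spec.family == "gaussian":
                fit = fit_lmm(sub, spec, drop_constant_columns=True)
            else:
                fit = fit_glmm_logit(sub, spec, drop_constant_columns=True)
        except Exception as exc:  # rank-deficiency etc.
            exclusions.append(
                {"cluster_id": cid, "coefficient": None, "reason": str(exc)}
            )
            logger.warning("cluster %s excluded: %s", cid, exc)
            continue
        if not fit.converged:
            exclusions.append(
                {
                    "cluster_id": cid,
                    "coefficient": None,
                    "reason": "fit did not converge",
                }
            )
            logger.warning("cluster %s excluded: non-convergence", cid)
            continue
        fits[cid] = fit
        x = None
        if aggregate_covariates:
            sdf = sub.df.drop_duplicates("subject_id")
            x = np.array(
                [float(sdf[c].mean()) for c in aggregate_covariates]
            )
        wanted = coefficient_names or list(fit.beta.index)
        se = fit.se
        for name in wanted:
            if name not in fit.beta.index:
                exclusions.append(
                    {
                        "cluster_id": cid,
                        "coefficient": name,
                        "reason": "coefficient inestimable in cluster",
                    }
                )
                continue
            sigma = float(se[name])
            if not (np.isfinite(sigma) and sigma > 0):
                exclusions.append(
                    {
                        "cluster_id": cid,
                        "coefficient": name,
                        "reason": "non-finite standard error",
                    }
                )
                continue
            estimates.setdefault(name, []).append(
                ClusterEstimate(
                    cluster_id=cid,
                    phi=float(fit.beta[name]),
                    sigma=sigma,
                    n_cluster=fit.n_subjects,
                    x=x,
                )
            )
    if len(fits) < 2:
        raise ValueError("fewer than 2 clusters produced usable fits")
    return ClusterFitSet(
        estimates=estimates,
        fits=fits,
        exclusions=pd.DataFrame(
            exclusions, columns=["cluster_id", "coefficient", "reason"]
        ),
    )


@dataclass
class PooledIC:
    aic_sum: float
    bic_sum: float
    aic_weighted_mean: float
    bic_weighted_mean: float
    comparable_with_full_data: bool = False


def pooled_information_criteria(cluster_fits: list[FitResult]) -> PooledIC:
    """Sum and subject-weighted mean of per-cluster information criteria.

    The result is flagged non-comparable with full-data criteria: the
    partitioned likelihood omits any cross-cluster structure and
    pseudo-criteria depend on the pseudo-data.
    """
    if not cluster_fits:
        raise ValueError("no cluster fits supplied")
    specs = {id(f.spec) if f.spec is None else _spec_key(f.spec) for f in cluster_fits}
    if len(specs) > 1:
        raise ValueError("cluster fits do not share a common model spec")
    if not all(f.converged for f in cluster_fits):
        raise ValueError("all cluster fits must have converged")
    aic = np.array([f.aic for f in cluster_fits])
    bic = np.array([f.bic for f in cluster_fits])
    n = np.array([f.n_subjects for f in cluster_fits], dtype=float)
    return PooledIC(
        aic_sum=float(aic.sum()),
        bic_sum=float(bic.sum()),
        aic_weighted_mean=float((aic * n).sum() / n.sum()),
        bic_weighted_mean=float((bic * n).sum() / n.sum()),
    )


def _spec_key(spec: ModelSpec) -> tuple:
    terms = tuple(t if isinstance(t, str) else t.name for t in spec.fixed_terms)
    return (spec.family, terms, spec.random_structure, spec.estimation)


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------
def estimates_to_frame(estimates: dict[str, list[ClusterEstimate]]) -> pd.DataFrame:
    rows = []
    for coef, ests in estimates.items():
        for e in ests:
            row = {
                "cluster_id": e.cluster_id,
                "coefficient": coef,
                "phi": e.phi,
                "sigma": e.sigma,
                "n": e.n_cluster,
            }
            if e.z is not None:
                row.update({f"z{j}": v for j, v in enumerate(e.z)})
            if e.x is not None:
                row.update({f"x{j}": v for j, v in enumerate(e.x)})
            rows.append(row)
    return pd.DataFrame(rows)


def estimates_from_frame(df: pd.DataFrame) -> dict[str, list[ClusterEstimate]]:
    zcols = sorted(c for c in df.columns if c.startswith("z") and c[1:].isdigit())
    xcols = sorted(c for c in df.columns if c.startswith("x") and c[1:].isdigit())
    out: dict[str, list[ClusterEstimate]] = {}
    if "coefficient" not in df.columns:
        df = df.assign(coefficient="effect")
    for coef, g in df.groupby("coefficient", sort=True):
        seen = set()
        ests = []
        for _, row in g.iterrows():
            if row["cluster_id"] in seen:
                raise ValueError(
                    f"duplicate estimate for cluster {row['cluster_id']!r}, "
                    f"coefficient {coef!r}"
                )
            seen.add(row["cluster_id"])
            ests.append(
                ClusterEstimate(
                    cluster_id=row["cluster_id"],
                    phi=float(row["phi"]),
                    sigma=float(row["sigma"]),
                    n_cluster=int(row["n"]) if "n" in row and pd.notna(row.get("n")) else 0,
                    z=row[zcols].to_numpy(dtype=float) if zcols else None,
                    x=row[xcols].to_numpy(dtype=float) if xcols else None,
                )
            )
        out[coef] = ests
    return out


def forest_frame(
    estimates: list[ClusterEstimate], pooled: PooledResult
) -> pd.DataFrame:
    """Per-cluster estimates with 95% bounds plus the pooled row, in the
    layout of a forest plot."""
    rows = [
        {
            "label": str(e.cluster_id),
            "estimate": e.phi,
            "ci_low": e.phi - 1.96 * e.sigma,
            "ci_high": e.phi + 1.96 * e.sigma,
            "pooled": False,
        }
        for e in estimates
    ]
    rows.append(
        {
            "label": pooled.method,
            "estimate": pooled.tau,
            "ci_low": pooled.ci[0],
            "ci_high": pooled.ci[1],
            "pooled": True,
        }
    )
    return pd.DataFrame(rows)
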