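"""Subject-level resampling strategies and the benchmarking study engine.

Comparator strategies for fitting mixed models to data too large to fit
whole: analyze a simple random subsample (SRS), a cluster-stratified
subsample with inverse-probability weights and a pseudo-likelihood fit
(StRS), or partition-and-pool meta-regression (REMR).  The study engine
refits a chosen strategy set over many replicate draws and benchmarks the
replicate estimates — mean, percentile "simulated" 95% interval, empirical
SE, bias and coverage — against the full-data fit, mirroring a bootstrap
design in which the study subject is the sampling unit.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import LongitudinalDataset
from .meta import fit_by_cluster, pool_remr, screen_outliers
from .models import FitResult, ModelSpec, fit_glmm_logit, fit_lmm, fit_weighted

logger = logging.getLogger(__name__)

STRATEGIES = ("full", "SRS", "StRS", "REMR")


@dataclass
class SamplingPlan:
    design: str = "SRS"  # SRS | StRS | bootstrap
    fraction: float = 1.0
    strata_var: str = "cluster_id"
    n_replicates: int = 1
    seed: int = 0
    with_replacement: bool | None = None  # default: True only for bootstrap

    def __post_init__(self) -> None:
        if self.design not in ("SRS", "StRS", "bootstrap"):
            raise ValueError(f"unknown sampling design {self.design!r}")
        if not (0 < self.fraction <= 1):
            raise ValueError("fraction must be in (0, 1]")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.with_replacement is None:
            self.with_replacement = self.design == "bootstrap"


def _round_half_even(x: float) -> int:
    """Banker's rounding of fractional sample sizes (documented rule)."""
    return int(round(x))


# --------------------------------------------------------------------------
# draws
# --------------------------------------------------------------------------
def draw_srs(
    data: LongitudinalDataset, fraction: float, rng: np.random.Generator
) -> LongitudinalDataset:
    """Simple random sample of subjects without replacement.

    All visits of a sampled subject are retained; every subject receives
    weight 1/fraction (the inverse selection probability).
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    subjects = data.df["subject_id"].unique()
    n = _round_half_even(fraction * len(subjects))
    if n == 0:
        raise ValueError(
            f"fraction {fraction} yields zero subjects from {len(subjects)}"
        )
    chosen = rng.choice(subjects, size=n, replace=False)
    return data.subset_subjects(chosen).with_weights(1.0 / fraction)


def draw_strs(
    data: LongitudinalDataset,
    fraction: float,
    strata_var: str,
    rng: np.random.Generator,
) -> LongitudinalDataset:
    """Stratified random sample: round(fraction * N_h) subjects independently
    within each stratum (minimum 1, logged), weight N_h / n_h."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    if strata_var not in data.df.columns:
        raise ValueError(f"stratum column {strata_var!r} not in data")
    per = data.df.drop_duplicates("subject_id")[["subject_id", strata_var]]
    chosen: list[np.ndarray] = []
    weights: dict = {}
    for stratum in sorted(per[strata_var].unique(), key=str):
        ids = per.loc[per[strata_var] == stratum, "subject_id"].to_numpy()
        n_h = _round_half_even(fraction * len(ids))
        if n_h == 0:
            n_h = 1
            logger.warning(
                "stratum %r rounded to zero subjects; drawing 1", stratum
            )
        take = rng.choice(ids, size=n_h, replace=False)
        chosen.append(take)
        w = len(ids) / n_h
        weights.update({sid: w for sid in take})
    sample = data.subset_subjects(np.concatenate(chosen))
    return sample.with_weights(pd.Series(weights))


def bootstrap_resample(
    data: LongitudinalDataset, rng: np.random.Generator
) -> LongitudinalDataset:
    """Nonparametric bootstrap of subjects (with replacement, original size).

    Subjects drawn more than once get distinct synthetic subject ids so the
    fitter treats the copies as independent; provenance is kept in a
    ``source_subject_id`` column and cluster labels are preserved.
    """
    subjects = data.df["subject_id"].unique()
    if len(subjects) < 2:
        raise ValueError("bootstrap requires at least 2 subjects")
    draw = rng.choice(subjects, size=len(subjects), replace=True)
    blocks = []
    counts: dict = {}
    indexed = data.df.set_index("subject_id")
    for sid in draw:
        copy = counts.get(sid, 0)
        counts[sid] = copy + 1
        block = indexed.loc[[sid]].reset_index()
        block["source_subject_id"] = block["subject_id"]
        if copy:
            block["subject_id"] = block["subject_id"].astype(str) + f":{copy}"
        blocks.append(block)
    return LongitudinalDataset(pd.concat(blocks, ignore_index=True))


# --------------------------------------------------------------------------
# study engine
# --------------------------------------------------------------------------
@dataclass
class SimulationSummary:
    """Tidy per-(strategy, coefficient) benchmarking table."""

    table: pd.DataFrame
    benchmark: pd.Series
    n_replicates: int
    nonconverged: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _strategy_fit(sample: LongitudinalDataset, spec: ModelSpec, weighted: bool):
    if not weighted and sample.has_weights:
        # equal selection probabilities: the unweighted fit is the analysis
        sample = LongitudinalDataset(
            sample.df.drop(columns=["weight"]), validate=False
        )
    if weighted:
        wspec = ModelSpec(
            family=spec.family,
            fixed_terms=spec.fixed_terms,
            random_structure=spec.random_structure,
            estimation="pseudo-likelihood",
            quadrature_points=spec.quadrature_points,
            robust_se=True,
        )
        return fit_weighted(sample, wspec, drop_constant_columns=True)
    if spec.family == "gaussian":
        return fit_lmm(sample, spec, drop_constant_columns=True)
    return fit_glmm_logit(sample, spec, drop_constant_columns=True)


def run_resampling_study(
    data: LongitudinalDataset,
    plan: SamplingPlan,
    spec: ModelSpec,
    strategies: list[str],
    coefficient_names: list[str] | None = None,
    pool_method: str = "DL",
    screen: bool = False,
    screen_threshold: float = 3.0,
    benchmark_fit: FitResult | None = None,
) -> SimulationSummary:
    """Benchmark sampling strategies against the full-data fit.

    The full-data model is fitted once as the benchmark ("true values" for
    judging bias).  ``SRS`` refits the model on an unweighted subject
    subsample per replicate; ``StRS`` draws within strata and refits by
    weighted pseudo-likelihood with sandwich standard errors; ``REMR`` is
    deterministic given the data (per-cluster fits pooled by random-effects
    meta-regression, optionally after outlier screening) and is computed
    once.  Replicate seeds derive deterministically from ``plan.seed``, so
    identical inputs reproduce the summary exactly; replicates are
    independent and order-invariant by construction.
    """
    unknown = set(strategies) - set(STRATEGIES)
    if unknown:
        raise ValueError(f"unknown strategies: {sorted(unknown)}")
    bench = benchmark_fit if benchmark_fit is not None else _strategy_fit(
        data, spec, weighted=False
    )
    coef_names = coefficient_names or list(bench.beta.index)
    benchmark = bench.beta.reindex(coef_names)

    replicate_rngs = [
        np.random.default_rng(s)
        for s in np.random.SeedSequence(plan.seed).spawn(plan.n_replicates)
    ]
    rows = []
    nonconv: dict[str, int] = {}
    for strategy in strategies:
        if strategy == "REMR":
            fitset = fit_by_cluster(data, spec, coefficient_names=coef_names)
            for name in coef_names:
                ests = fitset.estimates.get(name, [])
                excluded: list = []
                if screen and len(ests) >= 3:
                    ests, exc, _ = screen_outliers(ests, screen_threshold)
                    excluded = [e.cluster_id for e in exc]
                pooled = pool_remr(ests, method=pool_method)
                rows.append(
                    {
                        "strategy": "REMR",
                        "coefficient": name,
                        "mean": pooled.tau,
                        "ci_low": pooled.ci[0],
                        "ci_high": pooled.ci[1],
                        "ci_low_normal": pooled.ci[0],
                        "ci_high_normal": pooled.ci[1],
                        "emp_se": pooled.se_tau,
                        "bias": pooled.tau - benchmark[name],
                        "coverage": float(
                            pooled.ci[0] <= benchmark[name] <= pooled.ci[1]
                        ),
                        "n_replicates_converged": 1,
                        "excluded_clusters": ";".join(map(str, excluded)),
                    }
                )
            continue

        if strategy == "full" and plan.fraction == 1.0 and not plan.with_replacement:
            # resampling all subjects without replacement is the identity
            est = np.tile(benchmark.to_numpy(), (plan.n_replicates, 1))
            ses = np.tile(
                bench.se.reindex(coef_names).to_numpy(), (plan.n_replicates, 1)
            )
            _summarize(rows, "full", coef_names, est, ses, benchmark)
            continue

        est = np.full((plan.n_replicates, len(coef_names)), np.nan)
        ses = np.full_like(est, np.nan)
        for r, rng in enumerate(replicate_rngs):
            if strategy == "full":
                sample = (
                    bootstrap_resample(data, rng)
                    if plan.with_replacement
                    else data
                )
                weighted = False
            elif strategy == "SRS":
                if plan.with_replacement:
                    sample = _srs_with_replacement(data, plan.fraction, rng)
                else:
                    sample = draw_srs(data, plan.fraction, rng)
                weighted = False
            else:  # StRS
                sample = draw_strs(data, plan.fraction, plan.strata_var, rng)
                weighted = True
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    fit = _strategy_fit(sample, spec, weighted)
            except Exception as exc:
                logger.warning(
                    "replicate %d (%s) failed: %s", r, strategy, exc
                )
                continue
            if not fit.converged:
                continue
            b = fit.beta.reindex(coef_names)
            s = fit.se.reindex(coef_names)
            est[r] = b.to_numpy()
            ses[r] = s.to_numpy()
        bad = int(np.isnan(est[:, 0]).sum())
        nonconv[strategy] = bad
        if bad > 0.2 * plan.n_replicates:
            warnings.warn(
                f"{strategy}: {bad}/{plan.n_replicates} replicates failed to "
                "converge; summary is based on the remainder",
                RuntimeWarning,
            )
        _summarize(rows, strategy, coef_names, est, ses, benchmark)

    table = pd.DataFrame(rows)
    return SimulationSummary(
        table=table,
        benchmark=benchmark,
        n_replicates=plan.n_replicates,
        nonconverged=nonconv,
    )


def _srs_with_replacement(data, fraction, rng):
    boot = bootstrap_resample(data, rng)
    return draw_srs(boot, fraction, rng)


def _summarize(rows, strategy, coef_names, est, ses, benchmark) -> None:
    ok = ~np.isnan(est[:, 0])
    e = est[ok]
    s = ses[ok]
    for j, name in enumerate(coef_names):
        col = e[:, j]
        if len(col) == 0:
            continue
        mean = float(col.mean())
        emp_se = float(col.std(ddof=1)) if len(col) > 1 else 0.0
        lo, hi = (
            (float(np.percentile(col, 2.5)), float(np.percentile(col, 97.5)))
            if len(col) > 1
            else (mean, mean)
        )
        # Wald coverage of the benchmark by replicate-level intervals
        if np.all(np.isfinite(s[:, j])):
            cov = float(
                np.mean(
                    (col - 1.96 * s[:, j] <= benchmark[name])
                    & (benchmark[name] <= col + 1.96 * s[:, j])
                )
            )
        else:
            cov = math.nan
        rows.append(
            {
                "strategy": strategy,
                "coefficient": name,
                "mean": mean,
                "ci_low": lo,
                "ci_high": hi,
                "ci_low_normal": mean - 1.96 * emp_se,
                "ci_high_normal": mean + 1.96 * emp_se,
                "emp_se": emp_se,
                "bias": mean - float(benchmark[name]),
                "coverage": cov,
                "n_replicates_converged": int(len(col)),
                "excluded_clusters": "",
            }
        )
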