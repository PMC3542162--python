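"""Synthetic VA-like longitudinal diabetes cohorts with known ground truth.

Emulates the structure of a national clustered cohort: ~23 regional clusters,
up to 5 annual visits per subject, a continuous glycemic-control outcome
(HbA1c, %) or its dichotomization (poor control, HbA1c >= 8), and the
standard covariate mix (4-level race/ethnicity, 4-level comorbidity count,
sex, marital status, urban residence, service-connected disability, region).
Default covariate margins match the published full-cohort profile
(race 62/12/14/12; comorbidity 57/28/11/4; 98% male; 65% married; 62% urban)
and the default coefficients put the mean continuous outcome near 7.4.

Per-cluster true coefficient vectors are ``beta + nu_v`` with
``nu_v ~ N(0, sigma_v^2)`` per coefficient, plus optional injected outlier
shifts that mimic a pair of extreme clusters.  The gaussian outcome is
``x'beta_v + b_i + e_ij`` with a subject random intercept; the binary outcome
is generated from its own logistic mechanism with the same linear-predictor
structure (so the logistic mixed model is correctly specified), with a
threshold-of-gaussian mode available to mimic dichotomizing an observed
continuous measure.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import LongitudinalDataset
from .design import Term, build_design

RACE_LEVELS = ("NHW", "NHB", "Hispanic", "Other")
COMORBIDITY_LEVELS = ("0", "1", "2", "3+")
REGION_LEVELS = ("South", "Northeast", "MidAtlantic", "Midwest", "West")

#: model terms in declaration order; references: NHW race, zero
#: comorbidities, female sex (male indicator), single (married indicator),
#: rural (urban indicator), South region; time enters linearly.
DEFAULT_TERMS = (
    "time",
    Term("race", categorical=True, levels=RACE_LEVELS, reference="NHW"),
    "male",
    "married",
    "urban",
    "disability",
    Term("region", categorical=True, levels=REGION_LEVELS, reference="South"),
    Term(
        "comorbidities",
        categorical=True,
        levels=COMORBIDITY_LEVELS,
        reference="0",
    ),
)

DEFAULT_BETA_GAUSSIAN = {
    "Intercept": 7.54,
    "time": -0.05,
    "race[NHB]": 0.46,
    "race[Hispanic]": 0.29,
    "race[Other]": 0.25,
    "male": -0.15,
    "married": -0.02,
    "urban": -0.01,
    "disability": 0.001,
    "region[Northeast]": 0.0,
    "region[MidAtlantic]": 0.0,
    "region[Midwest]": 0.0,
    "region[West]": 0.0,
    "comorbidities[1]": 0.01,
    "comorbidities[2]": 0.04,
    "comorbidities[3+]": 0.11,
}

DEFAULT_BETA_BINOMIAL = {
    "Intercept": -0.94,
    "time": -0.02,
    "race[NHB]": 0.62,
    "race[Hispanic]": 0.45,
    "race[Other]": 0.36,
    "male": -0.10,
    "married": 0.0,
    "urban": 0.0,
    "disability": 0.001,
    "region[Northeast]": 0.0,
    "region[MidAtlantic]": 0.0,
    "region[Midwest]": 0.0,
    "region[West]": 0.0,
    "comorbidities[1]": 0.07,
    "comorbidities[2]": 0.15,
    "comorbidities[3+]": 0.27,
}


def _default_region_map(n_clusters: int) -> dict[int, str]:
    """Assign clusters to regions in blocks sized to the published regional
    shares (South 30%, Mid-Atlantic 23%, Midwest 21%, West 15%, NE 12%)."""
    shares = {
        "South": 0.30,
        "MidAtlantic": 0.23,
        "Midwest": 0.21,
        "West": 0.15,
        "Northeast": 0.12,
    }
    counts = {r: max(1, round(s * n_clusters)) for r, s in shares.items()}
    while sum(counts.values()) > n_clusters:
        counts[max(counts, key=counts.get)] -= 1
    while sum(counts.values()) < n_clusters:
        counts[min(counts, key=counts.get)] += 1
    mapping = {}
    cid = 0
    for region, c in counts.items():
        for _ in range(c):
            mapping[cid] = region
            cid += 1
    return mapping


@dataclass
class CohortConfig:
    n_subjects: int = 2000
    n_clusters: int = 23
    visits: int = 5
    race_probs: dict = field(
        default_factory=lambda: dict(zip(RACE_LEVELS, (0.62, 0.12, 0.14, 0.12)))
    )
    comorbidity_probs: dict = field(
        default_factory=lambda: dict(
            zip(COMORBIDITY_LEVELS, (0.57, 0.28, 0.11, 0.04))
        )
    )
    p_male: float = 0.98
    p_married: float = 0.65
    p_urban: float = 0.62
    disability_mean: float = 12.0
    disability_sd: float = 10.0
    beta: dict | None = None  # defaults depend on family
    sigma_b: float = 1.0  # person random-intercept SD (gaussian)
    sigma_e: float = 0.7  # residual SD (gaussian)
    sigma_b_binomial: float = 1.0  # person random-intercept SD (logit scale)
    sigma_v: dict = field(default_factory=dict)  # per-coefficient SD of beta_v
    outlier_clusters: list = field(default_factory=list)  # (cid, coef, shift)
    retention: float = 0.95  # per-visit retention probability
    family: str = "gaussian"  # "gaussian" | "binomial"
    binary_mode: str = "logistic"  # "logistic" | "threshold"
    threshold: float = 8.0
    cluster_sizes: list | None = None  # optional unequal-size profile
    seed: int = 0

    def resolved_beta(self) -> dict:
        if self.beta is not None:
            return dict(self.beta)
        # threshold mode dichotomizes a latent continuous outcome, so its
        # coefficients live on the continuous scale
        if self.family == "binomial" and self.binary_mode == "logistic":
            return dict(DEFAULT_BETA_BINOMIAL)
        return dict(DEFAULT_BETA_GAUSSIAN)

    def validate(self) -> None:
        for name, probs in (
            ("race_probs", self.race_probs),
            ("comorbidity_probs", self.comorbidity_probs),
        ):
            if abs(sum(probs.values()) - 1.0) > 1e-8:
                raise ValueError(f"{name} must sum to 1")
        if self.family not in ("gaussian", "binomial"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.binary_mode not in ("logistic", "threshold"):
            raise ValueError(f"unknown binary_mode {self.binary_mode!r}")
        if not (0 < self.retention <= 1):
            raise ValueError("retention must be in (0, 1]")
        if min(self.sigma_b, self.sigma_e, self.sigma_b_binomial) < 0:
            raise ValueError("variance components must be non-negative")
        if any(sd < 0 or not np.isfinite(sd) for sd in self.sigma_v.values()):
            raise ValueError("sigma_v entries must be finite and non-negative")
        beta = self.resolved_beta()
        seen = set()
        for cid, coef, shift in self.outlier_clusters:
            if not (0 <= cid < self.n_clusters):
                raise ValueError(
                    f"outlier cluster id {cid} outside 0..{self.n_clusters - 1}"
                )
            if coef not in beta:
                raise ValueError(f"outlier coefficient {coef!r} not in the model")
            if not np.isfinite(shift):
                raise ValueError("outlier shift must be finite")
            if (cid, coef) in seen:
                raise ValueError(f"duplicate outlier entry for ({cid}, {coef!r})")
            seen.add((cid, coef))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)

    @classmethod
    def from_json(cls, path) -> "CohortConfig":
        with open(path) as fh:
            raw = json.load(fh)
        raw["outlier_clusters"] = [tuple(t) for t in raw.get("outlier_clusters", [])]
        return cls(**raw)


@dataclass
class TrueParameters:
    """Ground truth used to generate a cohort, for recovery testing."""

    beta: pd.Series
    per_cluster: pd.DataFrame  # n_clusters x p realized coefficient vectors
    sigma_b: float
    sigma_e: float | None
    sigma_v: dict
    outliers: list
    family: str

    def to_json(self, path) -> None:
        payload = {
            "beta": self.beta.to_dict(),
            "per_cluster": self.per_cluster.to_dict(orient="index"),
            "sigma_b": self.sigma_b,
            "sigma_e": self.sigma_e,
            "sigma_v": self.sigma_v,
            "outliers": [list(o) for o in self.outliers],
            "family": self.family,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=str)


def inject_outliers(
    config: CohortConfig,
    clusters: list[int],
    coefficient: str,
    shift,
) -> CohortConfig:
    """Return a config with outlier shifts added for the given clusters.

    ``shift`` may be a scalar (applied to every listed cluster) or a sequence
    matched to ``clusters`` — an opposite-direction pair is
    ``inject_outliers(cfg, [a, b], coef, (+s, -s))``.
    """
    if np.isscalar(shift):
        shifts = [float(shift)] * len(clusters)
    else:
        shifts = [float(s) for s in shift]
        if len(shifts) != len(clusters):
            raise ValueError("shift sequence length must match clusters")
    new = dataclasses.replace(
        config,
        outlier_clusters=list(config.outlier_clusters)
        + [(int(c), coefficient, s) for c, s in zip(clusters, shifts)],
    )
    new.validate()
    return new


def generate_cohort(
    config: CohortConfig,
) -> tuple[LongitudinalDataset, TrueParameters]:
    """Draw one synthetic cohort; fully reproducible from ``config.seed``.

    A single seed sequence feeds four named substreams (covariates, cluster
    effects, outcome noise, dropout) so that, e.g., changing the retention
    rate does not perturb the covariate draws.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_cov, rng_eff, rng_noise, rng_drop = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    n, K, v = config.n_subjects, config.n_clusters, config.visits

    # -- subjects ------------------------------------------------------------
    if config.cluster_sizes is not None:
        sizes = np.asarray(config.cluster_sizes, dtype=float)
        cluster = rng_cov.choice(K, size=n, p=sizes / sizes.sum())
    else:
        cluster = rng_cov.integers(0, K, size=n)  # multinomial-uniform
    region_map = _default_region_map(K)
    race = rng_cov.choice(
        list(config.race_probs), size=n, p=list(config.race_probs.values())
    )
    comorb = rng_cov.choice(
        list(config.comorbidity_probs),
        size=n,
        p=list(config.comorbidity_probs.values()),
    )
    male = (rng_cov.random(n) < config.p_male).astype(float)
    married = (rng_cov.random(n) < config.p_married).astype(float)
    urban = (rng_cov.random(n) < config.p_urban).astype(float)
    disability = np.clip(
        rng_cov.normal(config.disability_mean, config.disability_sd, n), 0.0, 100.0
    )

    # -- per-cluster realized coefficients ------------------------------------
    beta = config.resolved_beta()
    coef_names = list(beta)
    B = np.tile(np.array([beta[c] for c in coef_names]), (K, 1))
    for j, cname in enumerate(coef_names):
        sd = float(config.sigma_v.get(cname, 0.0))
        if sd > 0:
            B[:, j] += rng_eff.normal(0.0, sd, size=K)
    for cid, coef, shift in config.outlier_clusters:
        B[cid, coef_names.index(coef)] += shift

    # -- long format ----------------------------------------------------------
    subj = pd.DataFrame(
        {
            "subject_id": np.arange(n),
            "cluster_id": cluster,
            "race": race,
            "comorbidities": comorb,
            "male": male,
            "married": married,
            "urban": urban,
            "disability": disability,
        }
    )
    subj["region"] = subj["cluster_id"].map(region_map)
    df = subj.loc[subj.index.repeat(v)].reset_index(drop=True)
    df["time"] = np.tile(np.arange(v, dtype=float), n)

    # monotone dropout: once gone, gone
    if config.retention < 1.0:
        stay = rng_drop.random((n, v)) < config.retention
        stay[:, 0] = True
        present = np.cumprod(stay, axis=1).astype(bool).ravel()
    else:
        present = np.ones(n * v, dtype=bool)

    X, names, _ = build_design(df, list(DEFAULT_TERMS))
    if names != coef_names:
        # coefficient dict must cover exactly the design columns
        raise ValueError(
            "beta names do not match design columns: "
            f"{sorted(set(coef_names) ^ set(names))}"
        )
    lp = np.einsum("ij,ij->i", X, B[df["cluster_id"].to_numpy()])

    if config.family == "gaussian":
        b_i = rng_noise.normal(0.0, config.sigma_b, n)
        e = rng_noise.normal(0.0, config.sigma_e, n * v)
        df["outcome"] = lp + b_i[df["subject_id"].to_numpy()] + e
        sigma_b, sigma_e = config.sigma_b, config.sigma_e
    elif config.binary_mode == "threshold":
        b_i = rng_noise.normal(0.0, config.sigma_b, n)
        e = rng_noise.normal(0.0, config.sigma_e, n * v)
        cont = lp + b_i[df["subject_id"].to_numpy()] + e
        df["outcome"] = (cont >= config.threshold).astype(float)
        sigma_b, sigma_e = config.sigma_b, config.sigma_e
    else:
        b_i = rng_noise.normal(0.0, config.sigma_b_binomial, n)
        eta = lp + b_i[df["subject_id"].to_numpy()]
        p1 = 1.0 / (1.0 + np.exp(-eta))
        df["outcome"] = (rng_noise.random(n * v) < p1).astype(float)
        sigma_b, sigma_e = config.sigma_b_binomial, None

    df = df.loc[present].reset_index(drop=True)
    cols = ["subject_id", "cluster_id", "time", "outcome"] + [
        c for c in df.columns
        if c not in ("subject_id", "cluster_id", "time", "outcome")
    ]
    dataset = LongitudinalDataset(df[cols])
    truth = TrueParameters(
        beta=pd.Series(beta),
        per_cluster=pd.DataFrame(B, columns=coef_names),
        sigma_b=sigma_b,
        sigma_e=sigma_e,
        sigma_v=dict(config.sigma_v),
        outliers=list(config.outlier_clusters),
        family=config.family,
    )
    return dataset, truth
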