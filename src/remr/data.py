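"""Long-format longitudinal data container.

One row per subject-visit.  Required columns: ``subject_id``, ``cluster_id``,
``time`` and ``outcome``; any remaining columns are treated as model
covariates, except an optional per-subject ``weight`` column (sampling
weights, strictly positive and constant within subject).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("subject_id", "cluster_id", "time", "outcome")
WEIGHT_COLUMN = "weight"


@dataclass
class LongitudinalDataset:
    """Clustered longitudinal table with validation of its structural invariants.

    Parameters
    ----------
    df
        Long-format frame.  Rows are sorted by (subject, time) on
        construction so that downstream per-subject aggregation is
        deterministic regardless of input order.
    validate
        Check invariants on construction (default).  Disable only for
        internal round-trips of already-validated frames.
    """

    df: pd.DataFrame
    validate: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"missing required column(s): {', '.join(missing)}")
        df = self.df.sort_values(["subject_id", "time"], kind="mergesort")
        self.df = df.reset_index(drop=True)
        if self.validate:
            self._check_invariants()

    # -- invariants ---------------------------------------------------------
    def _check_invariants(self) -> None:
        df = self.df
        t = np.asarray(df["time"], dtype=float)
        if not np.all(np.isfinite(t)) or np.any(t < 0):
            raise ValueError("visit times must be non-negative and finite")
        n_clusters_per_subject = df.groupby("subject_id", sort=False)[
            "cluster_id"
        ].nunique()
        if (n_clusters_per_subject > 1).any():
            bad = n_clusters_per_subject[n_clusters_per_subject > 1].index[:5]
            raise ValueError(
                f"subjects belong to more than one cluster: {list(bad)}"
            )
        if WEIGHT_COLUMN in df.columns:
            w = np.asarray(df[WEIGHT_COLUMN], dtype=float)
            if np.any(~np.isfinite(w)) or np.any(w <= 0):
                raise ValueError("weights must be strictly positive and finite")
            per_subj = df.groupby("subject_id", sort=False)[WEIGHT_COLUMN].nunique()
            if (per_subj > 1).any():
                raise ValueError("weights must be constant within subject")

    # -- basic accessors ----------------------------------------------------
    @property
    def n_obs(self) -> int:
        return len(self.df)

    @property
    def n_subjects(self) -> int:
        return self.df["subject_id"].nunique()

    @property
    def n_clusters(self) -> int:
        return self.df["cluster_id"].nunique()

    @property
    def covariate_columns(self) -> list[str]:
        skip = set(REQUIRED_COLUMNS) | {WEIGHT_COLUMN}
        return [c for c in self.df.columns if c not in skip]

    @property
    def has_weights(self) -> bool:
        return WEIGHT_COLUMN in self.df.columns

    def subject_weights(self) -> pd.Series:
        """One weight per subject (1.0 when no weight column is present)."""
        if not self.has_weights:
            ids = self.df["subject_id"].drop_duplicates()
            return pd.Series(1.0, index=ids.to_numpy(), name=WEIGHT_COLUMN)
        g = self.df.groupby("subject_id", sort=False)[WEIGHT_COLUMN].first()
        return g

    def is_binary_outcome(self) -> bool:
        y = np.asarray(self.df["outcome"], dtype=float)
        return bool(np.isin(y, (0.0, 1.0)).all())

    # -- subsetting ---------------------------------------------------------
    def subset_subjects(self, subject_ids) -> "LongitudinalDataset":
        mask = self.df["subject_id"].isin(set(subject_ids))
        return LongitudinalDataset(self.df.loc[mask].copy(), validate=False)

    def subset_cluster(self, cluster_id) -> "LongitudinalDataset":
        mask = self.df["cluster_id"] == cluster_id
        return LongitudinalDataset(self.df.loc[mask].copy(), validate=False)

    def with_weights(self, weights: pd.Series | float) -> "LongitudinalDataset":
        """Return a copy with per-subject weights attached (scalar or Series
        indexed by subject_id)."""
        df = self.df.copy()
        if np.isscalar(weights):
            df[WEIGHT_COLUMN] = float(weights)
        else:
            df[WEIGHT_COLUMN] = df["subject_id"].map(weights).astype(float)
        w = df[WEIGHT_COLUMN].to_numpy()
        if np.any(~np.isfinite(w)) or np.any(w <= 0):
            raise ValueError("weights must be strictly positive and finite")
        return LongitudinalDataset(df, validate=False)

    # -- I/O -----------------------------------------------------------------
    @classmethod
    def from_csv(cls, path, model_columns: list[str] | None = None) -> "LongitudinalDataset":
        """Read a long-format CSV.

        Rows with missing values in required columns (or in ``model_columns``
        when given) are dropped with a logged count; empty fields are the
        missing-value convention.
        """
        df = pd.read_csv(path)
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(
                f"input CSV is missing required column(s): {', '.join(missing)}"
            )
        check = list(REQUIRED_COLUMNS) + [
            c for c in (model_columns or []) if c in df.columns
        ]
        before = len(df)
        df = df.dropna(subset=check)
        dropped = before - len(df)
        if dropped:
            logger.warning("dropped %d row(s) with missing model variables", dropped)
        return cls(df)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)
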