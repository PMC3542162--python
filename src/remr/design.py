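"""Fixed-effect design matrices with deterministic reference coding.

Categorical covariates expand to indicator columns named ``term[level]`` in
declaration order, with an explicit reference level that is dropped.  The
deterministic naming keeps coefficient indices stable across per-cluster fits
and simulation replicates, which the pooling step relies on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

INTERCEPT = "Intercept"


@dataclass(frozen=True)
class Term:
    """One model term.

    ``levels``/``reference`` apply to categorical terms only; when ``levels``
    is None they are taken (sorted) from the data and the first level is the
    reference.
    """

    name: str
    categorical: bool | None = None  # None = infer from dtype
    levels: tuple | None = None
    reference: object | None = None


def as_term(t) -> Term:
    if isinstance(t, Term):
        return t
    if isinstance(t, str):
        return Term(t)
    raise TypeError(f"cannot interpret model term {t!r}")


def _is_categorical(series: pd.Series, term: Term) -> bool:
    if term.categorical is not None:
        return term.categorical
    if term.levels is not None:
        return True
    return series.dtype == object or isinstance(
        series.dtype, pd.CategoricalDtype
    ) or series.dtype == bool


def build_design(
    df: pd.DataFrame,
    terms: Sequence,
    drop_constant: bool = False,
):
    """Build (X, column_names, dropped) for the declared fixed terms.

    ``drop_constant=True`` removes indicator columns that are constant in
    this particular frame (e.g. an empty race category inside one cluster),
    returning their names in ``dropped`` so callers can record which
    coefficients are inestimable there.  The intercept is always kept.
    """
    cols: list[np.ndarray] = [np.ones(len(df))]
    names: list[str] = [INTERCEPT]
    for raw in terms:
        term = as_term(raw)
        if term.name not in df.columns:
            raise ValueError(f"model term '{term.name}' not found in data")
        s = df[term.name]
        if _is_categorical(s, term):
            levels = list(term.levels) if term.levels is not None else sorted(
                s.dropna().unique().tolist()
            )
            ref = term.reference if term.reference is not None else levels[0]
            if ref not in levels:
                raise ValueError(
                    f"reference level {ref!r} not among levels of '{term.name}'"
                )
            for lev in levels:
                if lev == ref:
                    continue
                cols.append((s == lev).to_numpy(dtype=float))
                names.append(f"{term.name}[{lev}]")
        else:
            cols.append(s.to_numpy(dtype=float))
            names.append(term.name)
    X = np.column_stack(cols)
    dropped: list[str] = []
    if drop_constant:
        keep = [0]
        for j in range(1, X.shape[1]):
            col = X[:, j]
            if np.ptp(col) == 0.0:
                dropped.append(names[j])
            else:
                keep.append(j)
        X = X[:, keep]
        names = [names[j] for j in keep]
    return X, names, dropped


def check_full_rank(X: np.ndarray, names: Sequence[str]) -> None:
    """Raise naming the collinear columns if X is rank deficient."""
    if X.shape[0] < X.shape[1]:
        raise ValueError(
            f"design has more columns ({X.shape[1]}) than rows ({X.shape[0]})"
        )
    if np.linalg.matrix_rank(X) == X.shape[1]:
        return
    # name offenders in declaration order: a column is collinear if it does
    # not increase the rank of the columns declared before it
    bad = []
    rank = 0
    for j in range(X.shape[1]):
        new_rank = np.linalg.matrix_rank(X[:, : j + 1])
        if new_rank == rank:
            bad.append(names[j])
        rank = new_rank
    raise ValueError(
        "rank-deficient design; collinear term(s): " + ", ".join(bad)
    )
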