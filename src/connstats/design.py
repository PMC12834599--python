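"""Design-matrix construction from a cohort table."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DesignMatrix", "RankDeficiencyError", "build_design"]


class RankDeficiencyError(Exception):
    """The design matrix does not have full column rank."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; collinear columns: "
            + ", ".join(self.columns)
        )


@dataclass
class DesignMatrix:
    """Numeric design with coefficient names, interest column, and cluster ids."""

    X: np.ndarray
    coef_names: list[str]
    interest_index: int
    cluster_ids: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.cluster_ids = np.asarray(self.cluster_ids)
        n, p = self.X.shape
        if len(self.coef_names) != p:
            raise ValueError("coef_names length must match design columns")
        if not 0 <= self.interest_index < p:
            raise ValueError("interest_index out of range")
        if len(self.cluster_ids) != n:
            raise ValueError("one cluster id per subject required")
        if len(self.cluster_ids) == 0:
            raise ValueError("cluster_ids must be non-empty")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Names of columns that add no rank when appended left to right."""
    bad = []
    rank = 0
    kept: list[int] = []
    for k in range(X.shape[1]):
        cand = X[:, kept + [k]]
        r = np.linalg.matrix_rank(cand)
        if r > rank:
            rank = r
            kept.append(k)
        else:
            bad.append(names[k])
    return bad


def build_design(
    cohort: pd.DataFrame,
    formula_terms: list[str],
    interest_term: str | None,
    cluster: str = "site_id",
) -> DesignMatrix:
    """Assemble an OLS design from cohort columns.

    An intercept is always included first.  Categorical (object/category)
    columns are expanded to treatment-coded indicators.  The cluster label is
    taken from ``cluster`` (``site_id`` by default; ``family_id`` or a
    composite column are the alternatives).  ``interest_term=None`` yields an
    intercept-anchored design (the intercept is the coefficient of interest).
    Rank deficiency raises :class:`RankDeficiencyError` naming the offending
    columns.
    """
    if interest_term is not None and interest_term not in formula_terms:
        formula_terms = [interest_term] + list(formula_terms)
    for term in formula_terms:
        if term not in cohort.columns:
            raise ValueError(f"term {term!r} not found in cohort")
    if cluster not in cohort.columns:
        raise ValueError(f"cluster column {cluster!r} not found in cohort")

    cols: list[np.ndarray] = [np.ones(len(cohort))]
    names: list[str] = ["intercept"]
    interest_index: int | None = None
    for term in formula_terms:
        col = cohort[term]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=term, drop_first=True)
            for c in dummies.columns:
                cols.append(dummies[c].to_numpy(float))
                names.append(str(c))
                if term == interest_term and interest_index is None:
                    interest_index = len(names) - 1
        else:
            cols.append(col.to_numpy(float))
            names.append(term)
            if term == interest_term:
                interest_index = len(names) - 1
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficiencyError(_collinear_columns(X, names))
    if interest_term is None:
        interest_index = 0
    return DesignMatrix(
        X=X,
        coef_names=names,
        interest_index=interest_index,
        cluster_ids=cohort[cluster].to_numpy(),
    )
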