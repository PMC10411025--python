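"""GLM on ranking-difference groups, and the two-way disease classification.

The stability question — does the relation between the two rankings drift
over time? — is posed as a Gaussian identity-link GLM on the numeric RDG
code of every disease-year:

    RDG ~ C(year) + C(disease_group)

where the disease grouping collapses the disease factor to the three RDG
levels each disease occupied in a baseline year.  Factors use sum-to-zero
(effects) coding, so each level's coefficient is its deviation from the
grand mean and every level carries a reportable coefficient (the omitted
contrast is reconstructed as minus the sum of the others, with its
standard error from the coefficient covariance).  Small year coefficients
relative to disease-group coefficients indicate a time-stable relation.

Classification: a disease whose collapsed RDG code is 0 (ranked much
higher in search than in the registry — publicity inflation and/or
under-diagnosis suspected) is category 2; all other diseases, where the
registry is considered relatively comprehensive, are category 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import FitError, ValidationError
from .ranking import DiffTable

__all__ = [
    "Design",
    "GLMFit",
    "Classification",
    "build_design",
    "fit_glm",
    "classify_diseases",
]


@dataclass
class Design:
    """Long-form observations plus factor levels and coding metadata."""

    frame: pd.DataFrame  # disease_id, year, rdg, disease_group
    baseline_year: int
    year_levels: tuple[int, ...]
    group_levels: tuple[int, ...]
    encoding: str = "sum-to-zero (effects) coding"

    @property
    def n_obs(self) -> int:
        return len(self.frame)


def build_design(
    diffs: DiffTable,
    baseline_year: Optional[int] = None,
    groups: Optional[pd.Series] = None,
) -> Design:
    """Expand a :class:`DiffTable` into GLM observations (disease-years).

    Each disease is assigned to the disease-group given by its RDG code in
    ``baseline_year`` (default: the earliest year); ``groups`` overrides
    the assignment, e.g. with a known ground truth.  Group levels with no
    members are dropped from the coding with a warning.
    """
    years = list(diffs.years)
    if len(years) < 2:
        raise ValidationError("build_design: need at least 2 years")
    if baseline_year is None:
        baseline_year = years[0]
    if baseline_year not in years:
        raise ValidationError(f"baseline_year {baseline_year} not among {years}")
    if groups is None:
        groups = diffs.rdg[baseline_year]
    groups = groups.reindex(diffs.rdg.index)
    if groups.isna().any():
        missing = list(groups.index[groups.isna()])
        raise ValidationError(f"groups: missing assignment for {missing[:5]}")
    present = tuple(sorted(int(g) for g in groups.unique()))
    absent = [g for g in (0, 1, 2) if g not in present]
    if absent:
        warnings.warn(
            f"disease-group level(s) {absent} have no members and are dropped "
            "from the coding",
            stacklevel=2,
        )
    long = diffs.rdg.stack().reset_index()
    long.columns = ["disease_id", "year", "rdg"]
    long["disease_group"] = long["disease_id"].map(groups).astype(int)
    long = long.sort_values(["disease_id", "year"], ignore_index=True)
    return Design(
        frame=long,
        baseline_year=int(baseline_year),
        year_levels=tuple(int(y) for y in years),
        group_levels=present,
    )


@dataclass
class GLMFit:
    """Per-term coefficients of the fitted GLM, effects-coded.

    ``coefficients`` maps term names (``year[2016]``,
    ``disease_group[0]``, ...) to deviations from the grand mean;
    ``intercept`` is the grand mean of the response under balance.
    z = beta / SE and p is the two-sided normal tail probability.
    """

    coefficients: dict
    std_errors: dict
    z_values: dict
    p_values: dict
    intercept: float
    intercept_se: float
    encoding: str
    n_obs: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for term in self.coefficients:
            rows.append(
                {
                    "term": term,
                    "coefficient": self.coefficients[term],
                    "std_error": self.std_errors[term],
                    "z": self.z_values[term],
                    "p": self.p_values[term],
                }
            )
        iz = self.intercept / self.intercept_se if self.intercept_se > 0 else np.nan
        rows.append(
            {
                "term": "intercept",
                "coefficient": self.intercept,
                "std_error": self.intercept_se,
                "z": iz,
                "p": float(2 * stats.norm.sf(abs(iz))) if np.isfinite(iz) else np.nan,
            }
        )
        return pd.DataFrame(rows)


def _sum_coded(labels: pd.Series, levels: tuple) -> np.ndarray:
    """Sum-to-zero contrast columns: one per level except the last.

    Rows at level j get 1 in column j, rows at the last level get -1 in
    every column.
    """
    k = len(levels)
    cols = np.zeros((len(labels), k - 1))
    last = levels[-1]
    arr = labels.to_numpy()
    for j, lvl in enumerate(levels[:-1]):
        cols[arr == lvl, j] = 1.0
    cols[arr == last, :] = -1.0
    return cols


def fit_glm(design: Design) -> GLMFit:
    """Fit the Gaussian identity-link GLM on the effects-coded design.

    Equivalent to ordinary least squares; the coefficient covariance is
    the usual normal-equations estimator, and the omitted contrast of each
    factor is reconstructed so every level is reported.
    """
    frame = design.frame
    y = frame["rdg"].to_numpy(dtype=float)
    blocks = [np.ones((len(frame), 1))]
    names = ["intercept"]
    factors = []  # (factor name, levels, column slice)
    col = 1
    for fac, levels in (
        ("year", design.year_levels),
        ("disease_group", design.group_levels),
    ):
        if len(levels) < 2:
            continue  # a single-level factor carries no contrast
        cols = _sum_coded(frame[fac], levels)
        blocks.append(cols)
        names.extend(f"{fac}[{lvl}]" for lvl in levels[:-1])
        factors.append((fac, levels, slice(col, col + cols.shape[1])))
        col += cols.shape[1]
    X = np.hstack(blocks)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise FitError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]} "
            f"columns: {names}); collinear factor levels"
        )
    # Gaussian family with identity link is exactly least squares; OLS gives
    # the same estimates and normal-equations covariance and stays finite
    # when the response is constant (zero residual variance)
    res = sm.OLS(y, X).fit()
    beta = res.params
    cov = np.asarray(res.cov_params())

    coefs: dict = {}
    ses: dict = {}
    for name, b, v in zip(names[1:], beta[1:], np.diag(cov)[1:]):
        coefs[name] = float(b)
        ses[name] = float(np.sqrt(v))
    # reconstruct the omitted (last) level of each factor: -sum of the others
    for fac, levels, sl in factors:
        idx = np.arange(sl.start, sl.stop)
        b_last = -float(beta[idx].sum())
        v_last = float(np.ones(len(idx)) @ cov[np.ix_(idx, idx)] @ np.ones(len(idx)))
        coefs[f"{fac}[{levels[-1]}]"] = b_last
        ses[f"{fac}[{levels[-1]}]"] = float(np.sqrt(v_last))
    # order terms: all year levels, then all group levels
    ordered = [
        f"{fac}[{lvl}]"
        for fac, levels, _ in factors
        for lvl in levels
    ]
    coefs = {t: coefs[t] for t in ordered}
    ses = {t: ses[t] for t in ordered}
    zs = {
        t: (coefs[t] / ses[t] if ses[t] > 0 else np.nan) for t in ordered
    }
    ps = {
        t: (float(2 * stats.norm.sf(abs(zs[t]))) if np.isfinite(zs[t]) else np.nan)
        for t in ordered
    }
    return GLMFit(
        coefficients=coefs,
        std_errors=ses,
        z_values=zs,
        p_values=ps,
        intercept=float(beta[0]),
        intercept_se=float(np.sqrt(cov[0, 0])),
        encoding=design.encoding,
        n_obs=len(frame),
    )


@dataclass
class Classification:
    """Two-way disease classification derived from per-year RDG codes."""

    category: pd.Series  # disease_id -> 1 or 2
    collapsed_rdg: pd.Series  # disease_id -> the single code the policy chose
    policy: str
    cutoff: int

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {"collapsed_rdg": self.collapsed_rdg, "category": self.category}
        ).reset_index()
        out.columns = ["disease_id", "collapsed_rdg", "category"]
        return out.sort_values("disease_id", ignore_index=True)


def _collapse_majority(codes: pd.Series) -> int:
    """Most frequent code across years; ties go to the most recent tied year."""
    counts = codes.value_counts()
    top = counts.max()
    tied = set(counts.index[counts == top])
    if len(tied) == 1:
        return int(next(iter(tied)))
    for y in sorted(codes.index, reverse=True):
        if codes.loc[y] in tied:
            return int(codes.loc[y])
    raise AssertionError("unreachable: tie set is non-empty")


def classify_diseases(diffs: DiffTable, policy: str = "majority") -> Classification:
    """Collapse per-year RDG codes to one per disease, then map to categories.

    ``policy='majority'`` takes the most frequent code across years (ties
    broken by the most recent tied year); ``policy='baseline-year'`` takes
    the earliest year's code.  Category 2 iff the collapsed code is 0 —
    the disease ranks much higher in search than in the registry; codes 1
    and 2 map to category 1, where the registry is considered relatively
    comprehensive.
    """
    if policy not in ("majority", "baseline-year"):
        raise ValidationError(f"unknown classification policy {policy!r}")
    years = list(diffs.years)
    if policy == "baseline-year":
        collapsed = diffs.rdg[years[0]].astype(int)
    else:
        collapsed = diffs.rdg.apply(_collapse_majority, axis=1).astype(int)
    category = pd.Series(
        np.where(collapsed == 0, 2, 1), index=collapsed.index, dtype=int
    )
    collapsed.name = "collapsed_rdg"
    category.name = "category"
    return Classification(
        category=category,
        collapsed_rdg=collapsed,
        policy=policy,
        cutoff=diffs.cutoff,
    )
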