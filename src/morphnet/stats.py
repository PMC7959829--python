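"""Age x efficiency interaction model, FDR correction, LOO reproducibility.

The behavioral model is an ordinary least squares fit of

    beh = a1*age + a2*E + a3*sex + a4*edu + a5*ICV + a6*morph_global
          + beta*(age x E) + intercept

where E is a network efficiency value (global, or one parcel's nodal or
local efficiency) and morph_global is the whole-cortex covariate matched
to the network's measure (total volume / total area / mean thickness).
The coefficient of interest is beta, the age x efficiency interaction:
does the efficiency-behavior association change with age?

By default all continuous variables (including the behavior) are z-scored
before fitting and the interaction is the product of standardized age and
standardized E, so reported betas are standardized coefficients; raw-scale
fitting is available via ``standardize=False``.  Sex enters as a binary
code and is not scaled.

Multiple testing across parcels is controlled by Benjamini-Hochberg FDR;
reproducibility is the percentage of leave-one-out refits in which beta
stays significant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm_api
from statsmodels.stats.multitest import multipletests

from morphnet.errors import ModelSpecificationError

COVARIATES = ("age", "sex", "edu", "icv", "morph_global")
CONTINUOUS_COVARIATES = ("age", "edu", "icv", "morph_global")


@dataclass
class InteractionFit:
    """One fitted interaction model for (behavior, efficiency column)."""

    behavior: str
    efficiency_column: str
    coefficients: dict[str, float]
    beta: float  # age x E interaction coefficient
    t_stat: float
    p_value: float
    n: int
    standardized: bool = True


@dataclass
class FdrResult:
    """BH-adjusted q-values for one family of tests."""

    family: str
    p_values: np.ndarray
    q_values: np.ndarray
    q_threshold: float = 0.05

    @property
    def significant(self) -> np.ndarray:
        return self.q_values < self.q_threshold


@dataclass
class LooResult:
    """Leave-one-out reproducibility of the interaction term."""

    behavior: str
    efficiency_column: str
    n_folds: int
    n_significant: int
    n_skipped: int = 0
    fold_betas: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def reproducibility_pct(self) -> float:
        usable = self.n_folds - self.n_skipped
        if usable == 0:
            return float("nan")
        return 100.0 * self.n_significant / usable


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=1)


def _design_matrix(
    cohort: pd.DataFrame, behavior: str, efficiency_column: str, standardize: bool
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    cols = list(CONTINUOUS_COVARIATES) + [efficiency_column, behavior]
    missing = [c for c in cols + ["sex"] if c not in cohort.columns]
    if missing:
        raise ModelSpecificationError(f"cohort table lacks column(s) {missing}")
    sub = cohort[cols + ["sex"]]
    if sub.isna().any().any():
        bad = sub.columns[sub.isna().any()].tolist()
        raise ModelSpecificationError(f"missing values in model column(s) {bad}")

    for c in cols:
        if np.asarray(sub[c], dtype=float).std() == 0:
            raise ModelSpecificationError(f"zero-variance column {c!r}")

    def prep(c: str) -> np.ndarray:
        v = np.asarray(sub[c], dtype=float)
        return _zscore(v) if standardize else v

    age = prep("age")
    eff = prep(efficiency_column)
    names = ["age", efficiency_column, "sex", "edu", "icv", "morph_global",
             f"age_x_{efficiency_column}", "intercept"]
    x = np.column_stack(
        [
            age,
            eff,
            np.asarray(sub["sex"], dtype=float),
            prep("edu"),
            prep("icv"),
            prep("morph_global"),
            age * eff,
            np.ones(len(sub)),
        ]
    )
    y = prep(behavior)
    return x, y, names


def fit_interaction_glm(
    cohort: pd.DataFrame,
    behavior: str,
    efficiency_column: str,
    standardize: bool = True,
) -> InteractionFit:
    """OLS fit of the interaction model; beta's two-sided t test.

    Raises :class:`ModelSpecificationError` on missing/constant columns or
    a rank-deficient design (the offending columns are named).
    """
    x, y, names = _design_matrix(cohort, behavior, efficiency_column, standardize)
    n, k = x.shape
    if n < k + 2:
        raise ModelSpecificationError(
            f"n = {n} too small for {k} model terms (need >= {k + 2})"
        )
    rank = np.linalg.matrix_rank(x)
    if rank < k:
        # identify collinear columns by checking rank drop on removal
        collinear = [
            names[j]
            for j in range(k - 1)  # intercept excluded from blame
            if np.linalg.matrix_rank(np.delete(x, j, axis=1)) == rank
        ]
        raise ModelSpecificationError(
            f"design matrix is rank deficient; collinear column(s): {collinear}"
        )
    fit = sm_api.OLS(y, x).fit()
    beta_idx = names.index(f"age_x_{efficiency_column}")
    return InteractionFit(
        behavior=behavior,
        efficiency_column=efficiency_column,
        coefficients=dict(zip(names, map(float, fit.params))),
        beta=float(fit.params[beta_idx]),
        t_stat=float(fit.tvalues[beta_idx]),
        p_value=float(fit.pvalues[beta_idx]),
        n=n,
        standardized=standardize,
    )


def fdr_bh(
    p_values, q_threshold: float = 0.05, family: str = ""
) -> FdrResult:
    """Benjamini-Hochberg step-up adjusted q-values.

    q_i = min over j >= rank(i) of m * p_(j) / j, clipped at 1; the
    significant set is {q < q_threshold}.  An empty family yields an
    empty result.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return FdrResult(family, p, np.array([]), q_threshold)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    _rej, q, _a, _b = multipletests(p, alpha=q_threshold, method="fdr_bh")
    return FdrResult(family=family, p_values=p, q_values=q, q_threshold=q_threshold)


def loo_reproducibility(
    cohort: pd.DataFrame,
    behavior: str,
    efficiency_column: str,
    alpha: float = 0.05,
    standardize: bool = True,
) -> LooResult:
    """Refit the model n times, each time deleting one subject.

    Reproducibility is 100 x (folds with beta's p < alpha) / usable folds.
    A fold whose design is rank deficient is flagged and excluded from both
    numerator and denominator with a warning.
    """
    n = len(cohort)
    betas = np.full(n, np.nan)
    n_sig = 0
    n_skipped = 0
    for i in range(n):
        fold = cohort.drop(cohort.index[i])
        try:
            fit = fit_interaction_glm(
                fold, behavior, efficiency_column, standardize=standardize
            )
        except ModelSpecificationError as exc:
            warnings.warn(f"LOO fold {i} skipped: {exc}", stacklevel=2)
            n_skipped += 1
            continue
        betas[i] = fit.beta
        if fit.p_value < alpha:
            n_sig += 1
    return LooResult(
        behavior=behavior,
        efficiency_column=efficiency_column,
        n_folds=n,
        n_significant=n_sig,
        n_skipped=n_skipped,
        fold_betas=betas,
    )


def interaction_family(
    cohort: pd.DataFrame,
    behavior: str,
    efficiency_columns: list[str],
    q_threshold: float = 0.05,
    standardize: bool = True,
) -> pd.DataFrame:
    """Fit one behavior against a family of efficiency columns and FDR-correct.

    For nodal/local efficiency the family is the set of parcels (one test
    per parcel); BH runs across that family.  Returns a tidy frame with
    beta, t, p, q and the significance flag per column.
    """
    fits = [
        fit_interaction_glm(cohort, behavior, col, standardize=standardize)
        for col in efficiency_columns
    ]
    fdr = fdr_bh([f.p_value for f in fits], q_threshold, family=behavior)
    return pd.DataFrame(
        {
            "behavior": behavior,
            "efficiency_column": efficiency_columns,
            "beta": [f.beta for f in fits],
            "t": [f.t_stat for f in fits],
            "p": [f.p_value for f in fits],
            "q": fdr.q_values,
            "significant": fdr.significant,
            "n": [f.n for f in fits],
        }
    )
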