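"""Covariate adjustment and rank-based inverse normal transformation.

Each raw trait is adjusted for age, age^2, sex and their interactions in an
ordinary least-squares regression; the residuals are then mapped to normal
quantiles through Blom rank fractions, giving a trait on a dimensionless
normalized scale suitable for the Gaussian variance-components likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

#: Design columns, in order, for the full covariate model.
FULL_DESIGN = ("sex", "age", "age2", "age_sex", "age2_sex")


@dataclass
class AdjustedTrait:
    """Normalized residual scores for one trait.

    ``scores`` is indexed by individual id; rows with missing trait or
    covariates were excluded and are listed in ``excluded``.
    """

    trait: str
    scores: pd.Series
    model: dict
    n: int
    excluded: list = field(default_factory=list)

    @property
    def ids(self) -> list[str]:
        return [str(i) for i in self.scores.index]

    def values(self) -> np.ndarray:
        return self.scores.to_numpy(dtype=float)


def _design_matrix(df: pd.DataFrame, terms) -> pd.DataFrame:
    sex = df["sex"].map({"male": 0.0, "female": 1.0, 1: 0.0, 2: 1.0})
    if sex.isna().any():
        sex = pd.to_numeric(df["sex"], errors="coerce") - 1.0
    age = pd.to_numeric(df["age"], errors="coerce")
    cols = {
        "sex": sex,
        "age": age,
        "age2": age**2,
        "age_sex": age * sex,
        "age2_sex": age**2 * sex,
    }
    X = pd.DataFrame({t: cols[t] for t in terms}, index=df.index)
    return sm.add_constant(X, has_constant="add")


def adjust_covariates(
    table: pd.DataFrame,
    trait: str,
    terms=FULL_DESIGN,
    id_column: str = "individual_id",
) -> tuple[pd.Series, dict]:
    """OLS residuals of ``trait`` on {1, sex, age, age^2, age*sex, age^2*sex}.

    Rows with a missing trait value or missing covariates are dropped
    (listwise per trait) and reported in the model record.  Returns the
    residual series (indexed by individual id) and a description of the
    fitted covariate model.
    """
    df = table.set_index(id_column) if id_column in table.columns else table
    y = pd.to_numeric(df[trait], errors="coerce")
    X = _design_matrix(df, terms)
    keep = y.notna() & X.notna().all(axis=1)
    excluded = [str(i) for i in df.index[~keep]]
    y, X = y[keep], X[keep]
    p = X.shape[1]
    if len(y) < p + 2:
        raise ValueError(
            f"trait {trait!r}: only {len(y)} complete cases for {p} design terms"
        )
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < p:
        # identify collinear columns by QR pivoting on the correlation structure
        _, R = np.linalg.qr(X.to_numpy())
        bad = [X.columns[k] for k in range(p) if abs(R[k, k]) < 1e-8 * abs(R[0, 0])]
        raise ValueError(
            f"trait {trait!r}: rank-deficient covariate design; "
            f"collinear columns: {bad or list(X.columns)}"
        )
    fit = sm.OLS(y, X).fit()
    model = {
        "trait": trait,
        "terms": list(X.columns),
        "coef": {c: float(b) for c, b in fit.params.items()},
        "n": int(len(y)),
        "r_squared": float(fit.rsquared),
        "excluded": excluded,
    }
    resid = pd.Series(fit.resid, index=y.index, name=trait)
    return resid, model


def inverse_normal(residuals, offset: float = 0.375) -> np.ndarray:
    """Rank-based inverse normal transformation with Blom fractions.

    score_i = Probit((rank_i - offset) / (n + 1 - 2*offset)); ties get the
    average of their ranks.  The default offset 3/8 gives the Blom variant;
    0.5 gives van der Waerden-like (r - 1/2)/n and 0 gives r/(n+1).
    """
    x = np.asarray(residuals, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("inverse normal transformation needs n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("all residuals equal: no ordering information")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - offset) / (n + 1.0 - 2.0 * offset))


def adjust_and_normalize(
    table: pd.DataFrame,
    trait: str,
    terms=FULL_DESIGN,
    offset: float = 0.375,
    id_column: str = "individual_id",
) -> AdjustedTrait:
    """Covariate adjustment followed by inverse normal transformation."""
    resid, model = adjust_covariates(table, trait, terms=terms, id_column=id_column)
    scores = pd.Series(
        inverse_normal(resid.to_numpy(), offset=offset),
        index=resid.index,
        name=trait,
    )
    model["inverse_normal_offset"] = offset
    return AdjustedTrait(
        trait=trait,
        scores=scores,
        model=model,
        n=len(scores),
        excluded=model["excluded"],
    )
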