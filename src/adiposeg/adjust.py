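"""Gender and age-tertile covariate adjustment.

Traits are adjusted by taking residuals from the additive two-way linear
model ``trait ~ gender + age_tertile`` (no interaction).  Residuals are
invariant to the factor coding, so the choice of treatment coding here is
cosmetic.  Tertiles are computed on the pooled sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = ["AdjustedTrait", "age_tertiles", "adjust", "anova_table"]


def age_tertiles(ages) -> np.ndarray:
    """Assign age tertiles 1..3 cut at the 33.3%/66.7% sample quantiles.

    Intervals are lower-closed; values tied with a cut point go to the lower
    tertile.
    """
    a = np.asarray(ages, dtype=float)
    if a.size < 3:
        raise ValueError(f"need at least 3 ages, got {a.size}")
    if np.ptp(a) == 0:
        raise ValueError("all ages identical; tertiles undefined")
    q1, q2 = np.quantile(a, [1 / 3, 2 / 3])
    return 1 + (a > q1).astype(int) + (a > q2).astype(int)


@dataclass
class AdjustedTrait:
    """Residuals from the additive gender + age-tertile model."""

    residuals: pd.Series
    cell_means: pd.DataFrame
    r_squared: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError(f"R^2 out of range: {self.r_squared}")


def adjust(trait, gender, tertile) -> AdjustedTrait:
    """Residuals of ``trait ~ C(gender) + C(tertile)`` (additive, OLS)."""
    df = pd.DataFrame(
        {
            "trait": np.asarray(trait, dtype=float),
            "gender": pd.Categorical(gender),
            "tertile": pd.Categorical(tertile),
        }
    )
    if len({len(np.asarray(trait)), len(df)}) != 1:
        raise ValueError("trait and covariates must have equal lengths")
    for col in ("gender", "tertile"):
        unused = set(df[col].cat.categories) - set(df[col].unique())
        if unused:
            warnings.warn(f"dropping empty {col} level(s): {sorted(map(str, unused))}")
            df[col] = df[col].cat.remove_unused_categories()
    fit = smf.ols("trait ~ C(gender) + C(tertile)", data=df).fit()
    cell_means = (
        df.groupby(["gender", "tertile"], observed=True)["trait"]
        .mean()
        .unstack("tertile")
    )
    # a (near-)constant trait has no variance to explain; tiny negatives are
    # numerical noise
    n = len(df)
    tss_floor = 1e-12 * n * (1.0 + float(df["trait"].mean()) ** 2)
    r2 = float(fit.rsquared) if fit.centered_tss > tss_floor else 0.0
    r2 = float(np.clip(r2, 0.0, 1.0))
    resid = pd.Series(np.asarray(fit.resid), index=df.index, name="residual")
    return AdjustedTrait(residuals=resid, cell_means=cell_means, r_squared=r2)


def anova_table(trait, gender, tertile) -> pd.DataFrame:
    """Two-way additive ANOVA (type II) summary used for descriptive tables."""
    df = pd.DataFrame(
        {
            "trait": np.asarray(trait, dtype=float),
            "gender": pd.Categorical(gender),
            "tertile": pd.Categorical(tertile),
        }
    )
    fit = smf.ols("trait ~ C(gender) + C(tertile)", data=df).fit()
    return sm.stats.anova_lm(fit, typ=2)
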