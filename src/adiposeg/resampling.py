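"""Stratified bootstrap over individuals.

Each draw resamples individuals with replacement within family-history
stratum at the original stratum sizes and re-runs an arbitrary
parameter-producing pipeline; percentile confidence intervals and medians
summarize the draws.  Draws whose pipeline raises or returns non-finite
values are dropped and counted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

__all__ = ["BootstrapSummary", "bootstrap"]

#: Fraction of failed draws above which the summary is flagged unreliable.
FAILURE_THRESHOLD = 0.20


@dataclass
class ParameterSummary:
    point: float
    median: float
    ci_lo: float
    ci_hi: float


@dataclass
class BootstrapSummary:
    """Percentile bootstrap summary keyed by parameter name."""

    parameters: dict[str, ParameterSummary]
    n_draws: int
    n_failed: int
    seed: int
    unreliable: bool = field(default=False)

    def to_dict(self) -> dict:
        return {
            "parameters": {
                k: {
                    "point": v.point,
                    "median": v.median,
                    "ci_lo": v.ci_lo,
                    "ci_hi": v.ci_hi,
                }
                for k, v in self.parameters.items()
            },
            "n_draws": self.n_draws,
            "n_failed": self.n_failed,
            "seed": self.seed,
            "unreliable": self.unreliable,
        }


def bootstrap(
    cohort: pd.DataFrame,
    pipeline: Callable[[pd.DataFrame], dict[str, float]],
    n_draws: int = 1000,
    seed: int = 0,
    stratum_col: str = "fh",
) -> BootstrapSummary:
    """Stratified percentile bootstrap of ``pipeline(cohort)``.

    ``pipeline`` maps a cohort table to a flat dict of finite parameters.
    Resampling is within ``stratum_col`` levels at the original sizes, so
    the FH+/FH- design is preserved in every draw.  Deterministic given
    ``seed``.
    """
    if stratum_col not in cohort.columns:
        raise ValueError(f"stratum column {stratum_col!r} not in cohort")
    point = pipeline(cohort)
    names = list(point)

    strata = [np.flatnonzero((cohort[stratum_col] == lev).to_numpy())
              for lev in pd.unique(cohort[stratum_col])]
    rng = np.random.default_rng(seed)
    draws: list[list[float]] = []
    n_failed = 0
    for _ in range(n_draws):
        idx = np.concatenate([rng.choice(s, size=s.size, replace=True) for s in strata])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est = pipeline(cohort.iloc[idx].reset_index(drop=True))
            row = [float(est[k]) for k in names]
        except Exception:
            n_failed += 1
            continue
        if not np.all(np.isfinite(row)):
            n_failed += 1
            continue
        draws.append(row)

    unreliable = n_failed > FAILURE_THRESHOLD * n_draws
    if unreliable:
        warnings.warn(
            f"{n_failed}/{n_draws} bootstrap draws failed; summary unreliable"
        )
    arr = np.array(draws) if draws else np.empty((0, len(names)))
    params = {}
    for j, k in enumerate(names):
        col = arr[:, j] if arr.size else np.array([np.nan])
        params[k] = ParameterSummary(
            point=float(point[k]),
            median=float(np.median(col)),
            ci_lo=float(np.percentile(col, 2.5)),
            ci_hi=float(np.percentile(col, 97.5)),
        )
    return BootstrapSummary(
        parameters=params,
        n_draws=n_draws,
        n_failed=n_failed,
        seed=seed,
        unreliable=unreliable,
    )
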