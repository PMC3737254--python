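"""End-to-end analysis: cohort table in, full segregation report out.

Chains the stages: standardize/log -> ML factor fit -> varimax -> Bartlett
scores -> Frame/Adiposity labelling -> gender/age-tertile adjustment ->
pooled-decile relative risks -> bimodal fit of the FH+ Adiposity densities
-> heritability -> Hardy-Weinberg allele-frequency chain -> stratified
bootstrap confidence intervals.
"""

from __future__ import annotations

import hashlib
import json
from contextlib import contextmanager
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import __version__
from .adjust import adjust, age_tertiles
from .factors import (
    FactorModel,
    bartlett_scores,
    label_and_sign,
    ml_factor_fit,
    standardize_log,
    varimax_rotate,
)
from .hwe import allele_estimates
from .resampling import BootstrapSummary, bootstrap
from .segregation import (
    BimodalFit,
    DecileProfile,
    decile_relative_risk,
    fit_bimodal,
    heritability,
)

__all__ = [
    "AnalysisReport",
    "fit_factor_scores",
    "segregation_parameters",
    "full_pipeline",
]


@contextmanager
def _stage(name: str):
    try:
        yield
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {name!r}: {exc}") from exc


def fit_factor_scores(cohort: pd.DataFrame):
    """Factor stages only: returns the labelled model and (frame, adiposity) scores."""
    with _stage("standardize_log"):
        z = standardize_log(cohort)
    with _stage("ml_factor_fit"):
        model = ml_factor_fit(z, k=2)
    with _stage("varimax_rotate"):
        model = varimax_rotate(model)
    with _stage("bartlett_scores"):
        scores = bartlett_scores(z, model)
    with _stage("label_and_sign"):
        model, scores = label_and_sign(model, scores)
    return model, scores


def _segregation_from_scores(adiposity: pd.Series, cohort: pd.DataFrame):
    """Adjustment, decile profile, bimodal fit and allele chain for one cohort."""
    with _stage("age_tertiles"):
        tert = age_tertiles(cohort["age"].to_numpy())
    with _stage("adjust"):
        adj = adjust(adiposity.to_numpy(), cohort["gender"].to_numpy(), tert)
    resid = adj.residuals.to_numpy()
    is_plus = (cohort["fh"] == "FH+").to_numpy()
    with _stage("decile_relative_risk"):
        profile = decile_relative_risk(resid[is_plus], resid[~is_plus])
    with _stage("fit_bimodal"):
        fit = fit_bimodal(profile.midpoints, profile.density_fh_plus, profile.widths)
    with _stage("heritability"):
        her = heritability(fit, adj.r_squared)
    with _stage("hwe_chain"):
        alleles = allele_estimates(fit.alpha, profile.rr_8)
    return adj, profile, fit, her, alleles


def segregation_parameters(
    cohort: pd.DataFrame, precomputed_adiposity: pd.Series | None = None
) -> dict[str, float]:
    """Scalar parameter vector of the full analysis (bootstrap workhorse).

    With ``precomputed_adiposity`` the factor stages are skipped and the
    supplied scores (aligned with ``cohort``) are used directly.
    """
    if precomputed_adiposity is None:
        _, scores = fit_factor_scores(cohort)
        adiposity = scores["adiposity"]
    else:
        adiposity = precomputed_adiposity
    _, profile, fit, her, alleles = _segregation_from_scores(adiposity, cohort)
    return {
        "m1": fit.m1,
        "d2": fit.d2,
        "s": fit.s,
        "alpha_fh_plus": fit.alpha,
        "rr_8": profile.rr_8,
        "h2_adjusted": her.h2_adjusted,
        "h2_unadjusted": her.h2_unadjusted,
        "alpha_fh_minus": alleles.alpha_fh_minus,
        "alpha_t2dm": alleles.alpha_t2dm,
        "q_fh_minus": alleles.q_fh_minus,
        "q_fh_plus": alleles.q_fh_plus,
        "q_t2dm": alleles.q_t2dm,
    }


@dataclass
class AnalysisReport:
    """Serializable summary of every pipeline stage."""

    factor_summary: dict
    group_table: dict
    decile_table: dict
    bimodal: dict
    heritability: dict
    alleles: dict
    bootstrap_summary: dict
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "factor_summary": self.factor_summary,
            "group_table": self.group_table,
            "decile_table": self.decile_table,
            "bimodal": self.bimodal,
            "heritability": self.heritability,
            "alleles": self.alleles,
            "bootstrap": self.bootstrap_summary,
            "provenance": self.provenance,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)


def _factor_summary(model: FactorModel) -> dict:
    return {
        "variables": list(model.variable_names),
        "factor_labels": list(model.factor_labels or ()),
        "loadings": [[round(v, 6) for v in row] for row in model.loadings.tolist()],
        "uniquenesses": [round(v, 6) for v in model.uniquenesses.tolist()],
        "var_explained": [round(v, 6) for v in model.var_explained.tolist()],
        "var_explained_total": round(model.var_explained_total, 6),
        "cov_explained": round(model.cov_explained, 6),
    }


def _group_table(cohort: pd.DataFrame, scores: pd.DataFrame) -> dict:
    table: dict[str, dict] = {}
    traits = pd.concat([cohort[["age"]].copy(), scores], axis=1)
    from .simulate import MEASURE_COLUMNS

    for col in MEASURE_COLUMNS:
        traits[col] = cohort[col]
    for col in traits.columns:
        by = traits.groupby(cohort["fh"].to_numpy())[col]
        table[col] = {
            grp: {"mean": round(float(v.mean()), 4), "sd": round(float(v.std(ddof=1)), 4)}
            for grp, v in by
        }
    return table


def _decile_table(profile: DecileProfile) -> dict:
    def lst(a):
        return [None if not np.isfinite(v) else round(float(v), 6) for v in a]

    return {
        "edges": lst(profile.edges),
        "midpoints": lst(profile.midpoints),
        "counts_fh_plus": profile.counts_fh_plus.tolist(),
        "counts_fh_minus": profile.counts_fh_minus.tolist(),
        "density_fh_plus": lst(profile.density_fh_plus),
        "density_fh_minus": lst(profile.density_fh_minus),
        "rr": lst(profile.rr),
        "rr_lo": lst(profile.rr_lo),
        "rr_hi": lst(profile.rr_hi),
        "corrected": profile.corrected.tolist(),
        "undefined": profile.undefined.tolist(),
    }


def full_pipeline(
    cohort: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    freeze_factors: bool = False,
) -> AnalysisReport:
    """Run the complete analysis and bootstrap on a cohort table.

    ``freeze_factors`` resamples precomputed factor scores in the bootstrap
    instead of re-running the factor extraction per draw (faster; the
    default propagates factor-model uncertainty honestly).  ``n_boot=0``
    skips the bootstrap.
    """
    model, scores = fit_factor_scores(cohort)
    adj, profile, fit, her, alleles = _segregation_from_scores(
        scores["adiposity"], cohort
    )

    if n_boot > 0:
        if freeze_factors:
            boot_cohort = cohort.copy()
            boot_cohort["_adiposity"] = scores["adiposity"].to_numpy()

            def draw_pipeline(df):
                return segregation_parameters(
                    df, precomputed_adiposity=df["_adiposity"]
                )

        else:
            boot_cohort = cohort

            def draw_pipeline(df):
                return segregation_parameters(df)

        with _stage("bootstrap"):
            boot = bootstrap(boot_cohort, draw_pipeline, n_draws=n_boot, seed=seed)
        boot_dict = boot.to_dict()
    else:
        boot_dict = {"n_draws": 0}

    options = {"n_boot": n_boot, "seed": seed, "freeze_factors": freeze_factors}
    config_hash = hashlib.sha256(
        json.dumps(options, sort_keys=True).encode()
    ).hexdigest()[:16]
    return AnalysisReport(
        factor_summary=_factor_summary(model),
        group_table=_group_table(cohort, scores),
        decile_table=_decile_table(profile),
        bimodal={
            "m1": round(fit.m1, 6),
            "d2": round(fit.d2, 6),
            "s": round(fit.s, 6),
            "alpha": round(fit.alpha, 6),
            "sse": round(fit.sse, 8),
            "converged": fit.converged,
            "n_starts": fit.n_starts,
            "degenerate": fit.degenerate,
        },
        heritability={
            "h2_adjusted": round(her.h2_adjusted, 6),
            "h2_unadjusted": round(her.h2_unadjusted, 6),
            "e2": round(her.e2, 6),
            "r2_covariates": round(her.r2_covariates, 6),
        },
        alleles=alleles.to_dict(),
        bootstrap_summary=boot_dict,
        provenance={"version": __version__, "seed": seed, "config_hash": config_hash},
    )
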