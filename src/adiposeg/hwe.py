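"""Dominant bi-allelic Hardy-Weinberg inversion of phenotypic fractions.

Under Hardy-Weinberg equilibrium with risk-allele frequency ``q`` (and
``p = 1 - q``), genotype frequencies are ``AA = p**2``, ``Aa = 2*p*q``,
``aa = q**2``.  With dominant expression of the risk allele the fraction of
the population showing the high-adiposity phenotype is

    alpha = 2*p*q + q**2 = 1 - (1 - q)**2

which inverts to ``q = 1 - sqrt(1 - alpha)``.  This module provides that
inversion, the spouse-pool inference for the allele frequency in unobserved
T2DM-affected relatives, the relative-risk route to the fraction of the
family-history-negative (FH-) group under the upper mode, and the downstream
risk arithmetic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

__all__ = [
    "AlleleEstimates",
    "q_from_alpha",
    "alpha_from_q",
    "genotype_freqs",
    "fh_minus_upper_fraction",
    "t2dm_allele_freq",
    "t2dm_risk_bounds",
    "allele_estimates",
    "sensitivity_substitute_alpha",
]


def _check_unit_interval(x: float, name: str) -> None:
    if not (0.0 <= x <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {x!r}")


def q_from_alpha(alpha: float) -> float:
    """Risk-allele frequency from the dominant phenotype fraction.

    Inverts ``alpha = 2*p*q + q**2`` under HWE with ``p = 1 - q``:
    ``q = 1 - sqrt(1 - alpha)``.
    """
    _check_unit_interval(alpha, "alpha")
    return 1.0 - math.sqrt(1.0 - alpha)


def alpha_from_q(q: float) -> float:
    """Dominant phenotype fraction ``2*p*q + q**2`` from allele frequency."""
    _check_unit_interval(q, "q")
    p = 1.0 - q
    return 2.0 * p * q + q * q


def genotype_freqs(q: float) -> tuple[float, float, float]:
    """HWE genotype frequencies ``(AA, Aa, aa)`` for risk-allele frequency q."""
    _check_unit_interval(q, "q")
    p = 1.0 - q
    return (p * p, 2.0 * p * q, q * q)


def _clamp_unit(x: float, name: str) -> float:
    if x < 0.0 or x > 1.0:
        clamped = min(max(x, 0.0), 1.0)
        warnings.warn(
            f"{name} = {x:.4f} outside [0, 1]; clamped to {clamped:.1f}",
            stacklevel=3,
        )
        return clamped
    return x


def fh_minus_upper_fraction(alpha_fh_plus: float, rr_8: float) -> float:
    """Upper-mode fraction in FH- inferred from the 8th-decile relative risk.

    The FH+ excess in the 8th decile of the pooled trait distribution is read
    as the ratio of upper-mode occupancy between the groups, so
    ``alpha_FH- = alpha_FH+ / RR_8``, clamped to [0, 1] with a warning.
    """
    _check_unit_interval(alpha_fh_plus, "alpha_fh_plus")
    if not rr_8 > 0:
        raise ValueError(f"rr_8 must be positive, got {rr_8!r}")
    return _clamp_unit(alpha_fh_plus / rr_8, "alpha_fh_minus")


def t2dm_allele_freq(q_fh_minus: float, q_fh_plus: float) -> float:
    """Allele frequency in unobserved T2DM-affected relatives.

    Treats the FH- group as the pool of spouses in the parental generation:
    offspring (FH+) allele frequency is the mean of the affected-parent and
    spouse pools, so ``q_T2DM = 2*q_FH+ - q_FH-`` (clamped to [0, 1] with a
    warning, since bootstrap draws can cross the boundary).
    """
    _check_unit_interval(q_fh_minus, "q_fh_minus")
    _check_unit_interval(q_fh_plus, "q_fh_plus")
    return _clamp_unit(2.0 * q_fh_plus - q_fh_minus, "q_t2dm")


def t2dm_risk_bounds(alpha_fh_plus: float) -> tuple[float, float]:
    """T2DM-risk range for FH+ carriers of the high-adiposity phenotype.

    Returns ``(alpha * 0.5, alpha)``: the lower figure assumes adiposity and
    T2DM susceptibilities are inherited independently (half of sibships carry
    the T2DM side), the upper assumes full pleiotropy.
    """
    _check_unit_interval(alpha_fh_plus, "alpha_fh_plus")
    return (0.5 * alpha_fh_plus, alpha_fh_plus)


@dataclass
class AlleleEstimates:
    """Phenotypic fractions and risk-allele frequencies for the three groups."""

    alpha_fh_minus: float
    alpha_fh_plus: float
    alpha_t2dm: float
    q_fh_minus: float
    q_fh_plus: float
    q_t2dm: float
    genotypes: dict[str, tuple[float, float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.genotypes:
            self.genotypes = {
                "FH-": genotype_freqs(self.q_fh_minus),
                "FH+": genotype_freqs(self.q_fh_plus),
                "T2DM": genotype_freqs(self.q_t2dm),
            }

    def to_dict(self) -> dict:
        return {
            "alpha": {
                "FH-": self.alpha_fh_minus,
                "FH+": self.alpha_fh_plus,
                "T2DM": self.alpha_t2dm,
            },
            "q": {
                "FH-": self.q_fh_minus,
                "FH+": self.q_fh_plus,
                "T2DM": self.q_t2dm,
            },
            "genotypes": {g: list(v) for g, v in self.genotypes.items()},
        }


def allele_estimates(alpha_fh_plus: float, rr_8: float) -> AlleleEstimates:
    """Full deterministic chain from (alpha_FH+, RR_8) to all three groups.

    alpha_FH+ and RR_8 come from the bimodal fit and the decile relative-risk
    profile; everything else follows by closed form.
    """
    alpha_minus = fh_minus_upper_fraction(alpha_fh_plus, rr_8)
    q_minus = q_from_alpha(alpha_minus)
    q_plus = q_from_alpha(alpha_fh_plus)
    q_t2dm = t2dm_allele_freq(q_minus, q_plus)
    return AlleleEstimates(
        alpha_fh_minus=alpha_minus,
        alpha_fh_plus=alpha_fh_plus,
        alpha_t2dm=alpha_from_q(q_t2dm),
        q_fh_minus=q_minus,
        q_fh_plus=q_plus,
        q_t2dm=q_t2dm,
    )


def sensitivity_substitute_alpha(
    alpha_fh_minus_new: float, baseline: AlleleEstimates
) -> AlleleEstimates:
    """Recompute the chain with a substituted FH- phenotype fraction.

    Holds ``q_FH+`` fixed, recomputes ``q_FH-`` from the substituted fraction
    (e.g. a population obesity prevalence used in place of the in-sample
    estimate) and propagates through the spouse-pool relation.
    """
    _check_unit_interval(alpha_fh_minus_new, "alpha_fh_minus_new")
    q_minus = q_from_alpha(alpha_fh_minus_new)
    q_t2dm = t2dm_allele_freq(q_minus, baseline.q_fh_plus)
    return AlleleEstimates(
        alpha_fh_minus=alpha_fh_minus_new,
        alpha_fh_plus=baseline.alpha_fh_plus,
        alpha_t2dm=alpha_from_q(q_t2dm),
        q_fh_minus=q_minus,
        q_fh_plus=baseline.q_fh_plus,
        q_t2dm=q_t2dm,
    )
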