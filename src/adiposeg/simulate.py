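"""Synthetic two-group cohort generator.

Forward model of the structure the downstream analysis assumes: a dominantly
expressed bi-allelic genotype under Hardy-Weinberg equilibrium shifts a
latent *Adiposity* trait in carriers, a gendered latent *Frame* trait drives
the skeletal measures, and six observed body measurements arise from a
two-factor linear model on the log scale.

The generator emits the genotype of every simulated individual, but the
analysis pipeline never reads it: the column exists purely so that tests can
compare recovered quantities against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .hwe import alpha_from_q
from .adjust import age_tertiles

__all__ = [
    "MEASURE_COLUMNS",
    "SimulationConfig",
    "draw_genotypes",
    "simulate_cohort",
    "write_config",
    "read_config",
]

#: Cohort measurement columns, in loading-matrix row order.
MEASURE_COLUMNS = ("height_m", "waist_cm", "hip_cm", "lean_kg", "bone_kg", "fat_kg")

# Target loading pattern: Frame carries the skeletal measures, Adiposity the
# fat stores, waist/hip sit mostly on Adiposity and lean/bone lean slightly
# into it (muscle and bone scale with total mass).
_DEFAULT_LOADINGS = (
    (0.90, 0.00),  # height
    (0.30, 0.85),  # waist
    (0.10, 0.85),  # hip
    (0.90, 0.35),  # lean mass
    (0.90, 0.35),  # bone mass
    (0.00, 0.95),  # fat mass
)

# Log-scale location and scale constants giving adult-range natural units
# (height ~1.7 m, waist ~87 cm, hip ~102 cm, lean ~47 kg, bone ~2.8 kg,
# fat ~25 kg with realistic coefficients of variation).
_DEFAULT_MEANS = (0.527, 4.466, 4.625, 3.850, 1.030, 3.240)
_DEFAULT_SCALES = (0.060, 0.160, 0.100, 0.230, 0.180, 0.450)


def _default_uniquenesses() -> tuple[float, ...]:
    return tuple(1.0 - (a * a + b * b) for a, b in _DEFAULT_LOADINGS)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Latent-trait parameters (``m1``, ``d2``, ``s``, the gender and age
    effects) are in SD units of the adjusted trait scale used throughout the
    analysis.  ``m1=None`` resolves to ``-d2 * alpha_pooled`` so that the
    pooled latent *Adiposity* mean is zero in expectation.
    """

    n_fh_minus: int = 122
    n_fh_plus: int = 80
    q_fh_minus: float = 0.09
    q_fh_plus: float = 0.36
    m1: float | None = None
    d2: float = 0.93
    s: float = 0.30
    frame_gender_effect: float = 1.8
    frame_sd: float = 0.5
    adiposity_age_slope: float = 0.22
    female_fraction: float = 0.6
    age_range: tuple[float, float] = (20.0, 70.0)
    loading_matrix: tuple = _DEFAULT_LOADINGS
    uniquenesses: tuple = field(default_factory=_default_uniquenesses)
    measure_means: tuple = _DEFAULT_MEANS
    measure_scales: tuple = _DEFAULT_SCALES
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("q_fh_minus", "q_fh_plus", "female_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
        if self.d2 < 0:
            raise ValueError(f"d2 must be >= 0, got {self.d2!r}")
        if not self.s > 0:
            raise ValueError(f"s must be positive, got {self.s!r}")
        if not self.frame_sd > 0:
            raise ValueError(f"frame_sd must be positive, got {self.frame_sd!r}")
        if self.n_fh_minus < 1 or self.n_fh_plus < 1:
            raise ValueError("group sizes must be >= 1")
        lo, hi = self.age_range
        if not hi > lo:
            raise ValueError(f"age_range must be increasing, got {self.age_range!r}")
        lam = np.asarray(self.loading_matrix, dtype=float)
        psi = np.asarray(self.uniquenesses, dtype=float)
        if lam.shape != (6, 2) or psi.shape != (6,):
            raise ValueError("loading_matrix must be 6x2 and uniquenesses length 6")
        comm = (lam**2).sum(axis=1)
        if np.any(comm > 1.0 + 1e-9):
            raise ValueError("squared loadings in a row must sum to <= 1")
        if np.any(psi <= 0):
            raise ValueError("uniquenesses must be positive")
        if np.max(np.abs(psi - (1.0 - comm))) > 1e-6:
            raise ValueError("uniquenesses must equal 1 - communality per row")
        if np.any(np.asarray(self.measure_scales, dtype=float) <= 0):
            raise ValueError("measure_scales must be positive")

    @property
    def resolved_m1(self) -> float:
        """Lower-mode mean; defaults so the pooled latent mean is zero."""
        if self.m1 is not None:
            return float(self.m1)
        n = self.n_fh_minus + self.n_fh_plus
        alpha_pooled = (
            self.n_fh_minus * alpha_from_q(self.q_fh_minus)
            + self.n_fh_plus * alpha_from_q(self.q_fh_plus)
        ) / n
        return -self.d2 * alpha_pooled


def draw_genotypes(q: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n genotypes i.i.d. from HWE proportions (p^2, 2pq, q^2)."""
    if not (0.0 <= q <= 1.0):
        raise ValueError(f"q must lie in [0, 1], got {q!r}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n!r}")
    p = 1.0 - q
    return rng.choice(
        np.array(["AA", "Aa", "aa"]), size=n, p=[p * p, 2 * p * q, q * q]
    )


def simulate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Simulate a two-group cohort table; deterministic given ``config.seed``.

    Draw order from the single generator stream: gender, age, genotype
    (FH- then FH+ throughout), Frame noise, Adiposity noise, measurement
    noise.  Latents:

    * Frame  = gender_effect * (male - E[male]) + N(0, frame_sd)
    * Adiposity = m1 + d2 * 1[carrier] + slope * (age_tertile - 2) + N(0, s)

    Log-measures are ``mean_j + scale_j * (l_j1*Frame + l_j2*Adiposity +
    sqrt(psi_j)*eps_j)`` and are exponentiated to natural units.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_minus, n_plus = config.n_fh_minus, config.n_fh_plus
    n = n_minus + n_plus

    gender = np.where(rng.random(n) < config.female_fraction, "F", "M")
    age = rng.uniform(*config.age_range, size=n)
    genotype = np.concatenate(
        [
            draw_genotypes(config.q_fh_minus, n_minus, rng),
            draw_genotypes(config.q_fh_plus, n_plus, rng),
        ]
    )
    frame_noise = rng.normal(0.0, config.frame_sd, size=n)
    adip_noise = rng.normal(0.0, config.s, size=n)
    eps = rng.standard_normal((n, 6))

    male = (gender == "M").astype(float)
    frame = config.frame_gender_effect * (male - (1.0 - config.female_fraction))
    frame += frame_noise

    carrier = (genotype != "AA").astype(float)
    tert = age_tertiles(age)
    adiposity = (
        config.resolved_m1
        + config.d2 * carrier
        + config.adiposity_age_slope * (tert - 2.0)
        + adip_noise
    )

    lam = np.asarray(config.loading_matrix, dtype=float)
    psi = np.asarray(config.uniquenesses, dtype=float)
    means = np.asarray(config.measure_means, dtype=float)
    scales = np.asarray(config.measure_scales, dtype=float)
    latent = np.column_stack([frame, adiposity])
    log_measures = means + scales * (latent @ lam.T + np.sqrt(psi) * eps)
    measures = np.exp(log_measures)

    fh = np.array(["FH-"] * n_minus + ["FH+"] * n_plus)
    out = pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "gender": gender,
            "age": age,
            "fh": fh,
            "genotype": genotype,
        }
    )
    for j, col in enumerate(MEASURE_COLUMNS):
        out[col] = measures[:, j]
    return out


def write_config(config: SimulationConfig, path: str | Path) -> None:
    """Serialize a SimulationConfig as YAML."""
    d = asdict(config)
    d["age_range"] = list(d["age_range"])
    d["loading_matrix"] = [list(r) for r in d["loading_matrix"]]
    for k in ("uniquenesses", "measure_means", "measure_scales"):
        d[k] = list(d[k])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def read_config(path: str | Path) -> SimulationConfig:
    """Read a SimulationConfig from YAML."""
    d = yaml.safe_load(Path(path).read_text())
    d["age_range"] = tuple(d["age_range"])
    d["loading_matrix"] = tuple(tuple(r) for r in d["loading_matrix"])
    for k in ("uniquenesses", "measure_means", "measure_scales"):
        d[k] = tuple(d[k])
    return SimulationConfig(**d)
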