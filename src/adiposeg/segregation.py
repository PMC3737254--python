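"""Decile density profiles, relative risks, and the bimodal-normal fit.

The adjusted trait is binned by deciles of the pooled sample; per-decile
relative risks (FH+/FH-) get log-normal confidence intervals; the FH+
empirical bin densities are fitted by least squares to an equal-variance
two-mode normal density

    y(x) = (1 - alpha) * phi(x; m1, s) + alpha * phi(x; m1 + d2, s)

with alpha in [0, 1] and d2 >= 0 enforced by bounded quasi-Newton (L-BFGS-B)
from multiple starts.  Heritability follows from the within-mode SD as
``h2 = 1 - s**2`` on the adjusted SD scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "DecileProfile",
    "BimodalFit",
    "HeritabilityEstimate",
    "pooled_deciles",
    "assign_bins",
    "decile_relative_risk",
    "fit_bimodal",
    "heritability",
]

_SQRT2PI = np.sqrt(2.0 * np.pi)
#: z-quantile for the 95% relative-risk intervals.
_Z95 = 1.959963984540054


def _npdf(x, m, s):
    z = (x - m) / s
    return np.exp(-0.5 * z * z) / (s * _SQRT2PI)


def pooled_deciles(values) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Decile bin edges, midpoints and widths of the pooled sample.

    Edges are the 0, 10, ..., 100% quantiles.  Bins are lower-closed
    half-open, last bin closed.  Tied quantiles make bins degenerate and are
    rejected.
    """
    x = np.asarray(values, dtype=float)
    if np.unique(x).size < 20:
        raise ValueError("need at least 20 distinct values for decile binning")
    edges = np.quantile(x, np.linspace(0.0, 1.0, 11))
    dup = np.flatnonzero(np.diff(edges) <= 0)
    if dup.size:
        raise ValueError(
            f"duplicate decile edge at the {10 * (dup[0] + 1)}% quantile"
        )
    midpoints = 0.5 * (edges[:-1] + edges[1:])
    widths = np.diff(edges)
    return edges, midpoints, widths


def assign_bins(values, edges: np.ndarray) -> np.ndarray:
    """Bin indices 0..9 for values under the half-open decile convention."""
    x = np.asarray(values, dtype=float)
    return np.clip(np.searchsorted(edges[1:-1], x, side="right"), 0, 9)


@dataclass
class DecileProfile:
    """Per-decile densities and FH+/FH- relative risks with 95% CIs."""

    edges: np.ndarray
    midpoints: np.ndarray
    widths: np.ndarray
    counts_fh_plus: np.ndarray
    counts_fh_minus: np.ndarray
    n_fh_plus: int
    n_fh_minus: int
    density_fh_plus: np.ndarray
    density_fh_minus: np.ndarray
    rr: np.ndarray
    rr_lo: np.ndarray
    rr_hi: np.ndarray
    corrected: np.ndarray  # deciles where the 0.5 continuity correction applied
    undefined: np.ndarray  # deciles empty in both groups

    @property
    def rr_8(self) -> float:
        """Relative risk in the 8th decile (index 7)."""
        return float(self.rr[7])


def decile_relative_risk(values_fh_plus, values_fh_minus, edges=None) -> DecileProfile:
    """Decile profile of two groups on pooled-sample bins.

    ``RR_i = (n_i+/N+) / (n_i-/N-)`` with
    ``SE(log RR) = sqrt(1/n+ - 1/N+ + 1/n- - 1/N-)`` and normal 95% limits on
    the log scale.  Deciles with a zero count in either group get the
    Haldane-Anscombe 0.5 continuity correction applied to all four counts of
    that decile only (flagged in ``corrected``); deciles empty in both groups
    are flagged undefined with RR = NaN.
    """
    xp = np.asarray(values_fh_plus, dtype=float)
    xm = np.asarray(values_fh_minus, dtype=float)
    if xp.size == 0 or xm.size == 0:
        raise ValueError("both groups must be non-empty")
    if edges is None:
        edges, midpoints, widths = pooled_deciles(np.concatenate([xp, xm]))
    else:
        edges = np.asarray(edges, dtype=float)
        midpoints = 0.5 * (edges[:-1] + edges[1:])
        widths = np.diff(edges)
    np_, nm_ = xp.size, xm.size
    cp = np.bincount(assign_bins(xp, edges), minlength=10).astype(float)
    cm = np.bincount(assign_bins(xm, edges), minlength=10).astype(float)

    undefined = (cp == 0) & (cm == 0)
    corrected = ((cp == 0) | (cm == 0)) & ~undefined
    a_p, a_m = cp.copy(), cm.copy()
    tot_p = np.full(10, float(np_))
    tot_m = np.full(10, float(nm_))
    a_p[corrected] += 0.5
    a_m[corrected] += 0.5
    tot_p[corrected] += 1.0
    tot_m[corrected] += 1.0

    with np.errstate(divide="ignore", invalid="ignore"):
        rr = (a_p / tot_p) / (a_m / tot_m)
        se = np.sqrt(1.0 / a_p - 1.0 / tot_p + 1.0 / a_m - 1.0 / tot_m)
        lo = rr * np.exp(-_Z95 * se)
        hi = rr * np.exp(_Z95 * se)
    rr[undefined] = np.nan
    lo[undefined] = np.nan
    hi[undefined] = np.nan

    return DecileProfile(
        edges=edges,
        midpoints=midpoints,
        widths=widths,
        counts_fh_plus=cp.astype(int),
        counts_fh_minus=cm.astype(int),
        n_fh_plus=np_,
        n_fh_minus=nm_,
        density_fh_plus=cp / np_ / widths,
        density_fh_minus=cm / nm_ / widths,
        rr=rr,
        rr_lo=lo,
        rr_hi=hi,
        corrected=corrected,
        undefined=undefined,
    )


@dataclass
class BimodalFit:
    """Least-squares fit of the equal-variance two-mode normal density."""

    m1: float
    d2: float
    s: float
    alpha: float
    sse: float
    converged: bool
    n_starts: int

    @property
    def degenerate(self) -> bool:
        """True when the fitted density is effectively unimodal.

        An equal-variance two-component normal mixture is unimodal whenever
        the mode separation is at most 2s (for any mixing fraction); fits
        with essentially all mass in one component are likewise one-mode.
        """
        return self.d2 <= 2.0 * self.s or self.alpha < 0.05 or self.alpha > 0.95

    def density(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return (1.0 - self.alpha) * _npdf(x, self.m1, self.s) + self.alpha * _npdf(
            x, self.m1 + self.d2, self.s
        )


def _objective(params, x, dens):
    m1, d2, s, a = params
    m2 = m1 + d2
    f1 = _npdf(x, m1, s)
    f2 = _npdf(x, m2, s)
    r = dens - ((1.0 - a) * f1 + a * f2)
    z1 = (x - m1) / s
    z2 = (x - m2) / s
    dy_dm1 = ((1.0 - a) * f1 * z1 + a * f2 * z2) / s
    dy_dd2 = a * f2 * z2 / s
    dy_ds = ((1.0 - a) * f1 * (z1 * z1 - 1.0) + a * f2 * (z2 * z2 - 1.0)) / s
    dy_da = f2 - f1
    grad = -2.0 * np.array([r @ dy_dm1, r @ dy_dd2, r @ dy_ds, r @ dy_da])
    return float(r @ r), grad


def default_starts(midpoints, densities, widths) -> list[tuple[float, float, float, float]]:
    """Multistart grid: alpha x d2 lattice with moment-matched (m1, s)."""
    mu = float(np.sum(densities * widths * midpoints))
    var = float(np.sum(densities * widths * (midpoints - mu) ** 2))
    sd = np.sqrt(max(var, 1e-8))
    starts = []
    for a0 in (0.2, 0.5, 0.8):
        for d0 in (0.3, 0.9, 1.5):
            s0 = np.sqrt(max(var - a0 * (1.0 - a0) * d0 * d0, 1e-4))
            starts.append((mu - a0 * d0, d0, s0, a0))
            starts.append((mu - d0 / 2.0, d0, sd / 2.0, a0))
    starts.append((mu, 0.05, sd, 0.5))
    starts.append((mu - sd, 2.0 * sd, sd / 2.0, 0.5))
    return starts


def fit_bimodal(midpoints, densities, widths, starts=None) -> BimodalFit:
    """Fit (m1, d2, s, alpha) to empirical decile densities.

    Unweighted least squares on the 10 (midpoint, density) pairs; L-BFGS-B
    with analytic gradient under the constraints alpha in [0, 1], d2 >= 0,
    s >= 0.01, from 20 default starts.  Returns the best feasible solution;
    ``converged`` is False if no start reported convergence.
    """
    x = np.asarray(midpoints, dtype=float)
    dens = np.asarray(densities, dtype=float)
    w = np.asarray(widths, dtype=float)
    if x.shape != dens.shape or x.shape != w.shape:
        raise ValueError("midpoints, densities and widths must have equal length")
    if starts is None:
        starts = default_starts(x, dens, w)
    bounds = [(None, None), (0.0, None), (0.01, None), (0.0, 1.0)]
    best = None
    any_converged = False
    for st in starts:
        res = minimize(
            _objective, st, args=(x, dens), jac=True, method="L-BFGS-B",
            bounds=bounds,
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    m1, d2, s, alpha = best.x
    return BimodalFit(
        m1=float(m1),
        d2=float(d2),
        s=float(s),
        alpha=float(alpha),
        sse=float(best.fun),
        converged=any_converged,
        n_starts=len(starts),
    )


@dataclass
class HeritabilityEstimate:
    """Variance-component heritability from the within-mode SD."""

    h2_adjusted: float
    h2_unadjusted: float
    e2: float
    r2_covariates: float


def heritability(fit: BimodalFit | float, r2_covariates: float) -> HeritabilityEstimate:
    """``h2 = 1 - s**2`` on the adjusted scale, rescaled to the raw trait.

    ``s`` is the within-mode SD in adjusted-trait SD units, so ``e2 = s**2``
    is the error-variance proportion.  On the unadjusted scale the gender-
    and age-explained variance share ``r2_covariates`` dilutes the genetic
    proportion: ``h2_unadjusted = (1 - s**2) * (1 - r2)``.
    """
    s = fit.s if isinstance(fit, BimodalFit) else float(fit)
    if not s > 0:
        raise ValueError(f"s must be positive, got {s!r}")
    if not (0.0 <= r2_covariates < 1.0):
        raise ValueError(f"r2_covariates must lie in [0, 1), got {r2_covariates!r}")
    e2 = s * s
    if e2 > 1.0:
        warnings.warn(
            f"s = {s:.3f} > 1 on the adjusted SD scale; heritability clamped to 0"
        )
        e2 = 1.0
    h2 = 1.0 - e2
    return HeritabilityEstimate(
        h2_adjusted=h2,
        h2_unadjusted=h2 * (1.0 - r2_covariates),
        e2=e2,
        r2_covariates=r2_covariates,
    )
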