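"""Two-factor measurement model of the six body measures.

Maximum-likelihood factor analysis of the standardized log-measurements,
varimax rotation, Bartlett (weighted-least-squares) factor scores, and the
Frame/Adiposity labelling and sign conventions.

The ML fit profiles the likelihood over the uniquenesses (the classic
Lawley-Maxwell reduction): for fixed uniquenesses ``psi`` the optimal
loadings come from the top eigenvectors of ``diag(psi)^-1/2 R diag(psi)^-1/2``
and the remaining objective depends only on the discarded eigenvalues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar

__all__ = [
    "FactorModel",
    "standardize_log",
    "ml_factor_fit",
    "varimax_rotate",
    "varimax_criterion",
    "bartlett_scores",
    "label_and_sign",
]

#: Floor on uniquenesses; hitting it marks a Heywood case.
UNIQUENESS_FLOOR = 0.005


@dataclass
class FactorModel:
    """Rotated or unrotated orthogonal factor model for standardized data.

    ``loadings`` are correlations of the variables with the factors;
    ``rotation`` accumulates the orthogonal transform applied since the
    canonical ML solution.
    """

    loadings: np.ndarray  # (p, k)
    uniquenesses: np.ndarray  # (p,)
    rotation: np.ndarray  # (k, k)
    var_explained: np.ndarray  # (k,) proportion of standardized variance
    cov_explained: float
    variable_names: tuple[str, ...]
    factor_labels: tuple[str, ...] | None = None

    @property
    def communalities(self) -> np.ndarray:
        return (self.loadings**2).sum(axis=1)

    @property
    def var_explained_total(self) -> float:
        return float(self.var_explained.sum())


def standardize_log(cohort: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Log-transform the measurement columns and scale to mean 0, SD 1.

    Sample-SD (n-1) convention.  Raises on non-positive measurements (naming
    row and column) and on zero-variance columns.
    """
    from .simulate import MEASURE_COLUMNS

    cols = list(columns) if columns is not None else list(MEASURE_COLUMNS)
    missing = [c for c in cols if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort is missing measurement column(s): {missing}")
    x = cohort[cols].astype(float)
    bad = (x <= 0) | ~np.isfinite(x)
    if bad.any().any():
        col = bad.any(axis=0).idxmax()
        row = bad[col].idxmax()
        raise ValueError(
            f"non-positive or non-finite measurement in column {col!r}, row {row!r}"
        )
    logged = np.log(x)
    sd = logged.std(ddof=1)
    degenerate = sd <= 1e-10 * logged.abs().mean().clip(lower=1.0)
    if degenerate.any():
        col = degenerate.idxmax()
        raise ValueError(f"column {col!r} has zero variance after log-transform")
    return (logged - logged.mean()) / sd


def _profile_objective(psi, eigvals_fn, k):
    theta = eigvals_fn(psi)
    tail = theta[k:]
    f = float(np.sum(tail - np.log(tail) - 1.0))
    return f, theta


def ml_factor_fit(z: pd.DataFrame | np.ndarray, k: int = 2) -> FactorModel:
    """Fit the k-factor Gaussian model to the sample correlation matrix.

    Minimizes the ML discrepancy profiled over uniquenesses with L-BFGS-B
    (analytic gradient), uniquenesses bounded in [0.005, 1].  A bound hit is
    a Heywood case and is reported with a warning.
    """
    if k < 1:
        raise ValueError(f"number of factors must be >= 1, got {k}")
    if isinstance(z, pd.DataFrame):
        names = tuple(z.columns)
        zm = z.to_numpy(dtype=float)
    else:
        zm = np.asarray(z, dtype=float)
        names = tuple(f"v{j}" for j in range(zm.shape[1]))
    n, p = zm.shape
    if n <= p:
        raise ValueError(f"need more observations ({n}) than variables ({p})")
    if k >= p:
        raise ValueError("more factors than variables")
    r = np.corrcoef(zm, rowvar=False)
    if np.linalg.eigvalsh(r).min() <= 1e-10:
        raise ValueError("sample correlation matrix is not positive definite")

    def objective(psi):
        d = 1.0 / np.sqrt(psi)
        rstar = r * np.outer(d, d)
        theta, vecs = np.linalg.eigh(rstar)
        theta, vecs = theta[::-1], vecs[:, ::-1]
        tail, vtail = theta[k:], vecs[:, k:]
        f = float(np.sum(tail - np.log(tail) - 1.0))
        grad = -np.sum((tail - 1.0) * vtail**2, axis=1) / psi
        return f, grad

    psi0 = np.clip((1.0 - 0.5 * k / p) / np.diag(np.linalg.inv(r)), 0.05, 0.95)
    res = minimize(
        objective,
        psi0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(UNIQUENESS_FLOOR, 1.0)] * p,
        options={"maxiter": 1000, "ftol": 1e-12, "gtol": 1e-10},
    )
    psi = res.x
    if np.any(psi <= UNIQUENESS_FLOOR + 1e-9):
        warnings.warn(
            "Heywood case: uniqueness clamped at floor "
            f"{UNIQUENESS_FLOOR} for variable(s) "
            f"{[names[i] for i in np.flatnonzero(psi <= UNIQUENESS_FLOOR + 1e-9)]}"
        )
    d = 1.0 / np.sqrt(psi)
    theta, vecs = np.linalg.eigh(r * np.outer(d, d))
    theta, vecs = theta[::-1], vecs[:, ::-1]
    lam = np.sqrt(psi)[:, None] * vecs[:, :k] * np.sqrt(
        np.clip(theta[:k] - 1.0, 0.0, None)
    )
    # canonical column signs: largest-|loading| entry positive
    for j in range(k):
        if lam[np.argmax(np.abs(lam[:, j])), j] < 0:
            lam[:, j] = -lam[:, j]

    off = ~np.eye(p, dtype=bool)
    fitted_off = (lam @ lam.T)[off]
    cov_explained = float(1.0 - np.sum((r[off] - fitted_off) ** 2) / np.sum(r[off] ** 2))
    return FactorModel(
        loadings=lam,
        uniquenesses=psi,
        rotation=np.eye(k),
        var_explained=(lam**2).sum(axis=0) / p,
        cov_explained=cov_explained,
        variable_names=names,
    )


def varimax_criterion(loadings: np.ndarray, normalize: bool = True) -> float:
    """Varimax objective: summed variance of squared (Kaiser-normalized) loadings."""
    lam = np.asarray(loadings, dtype=float)
    if normalize:
        h = np.sqrt((lam**2).sum(axis=1))
        lam = lam / h[:, None]
    sq = lam**2
    return float(np.sum(sq.var(axis=0)))


def _rot2(phi: float) -> np.ndarray:
    c, s = np.cos(phi), np.sin(phi)
    return np.array([[c, -s], [s, c]])


def varimax_rotate(model: FactorModel) -> FactorModel:
    """Varimax rotation of a two-factor model (Kaiser row-normalization).

    For k=2 the rotation reduces to a single angle with a closed-form
    stationary point; a grid search plus bounded refinement guards against
    picking a minimum of the criterion.
    """
    lam = model.loadings
    if lam.shape[1] != 2:
        raise ValueError("varimax_rotate supports exactly 2 factors")
    h = np.sqrt((lam**2).sum(axis=1))
    if np.any(h == 0):
        raise ValueError("zero-communality row; cannot Kaiser-normalize")
    w = lam / h[:, None]
    p = w.shape[0]

    u = w[:, 0] ** 2 - w[:, 1] ** 2
    v = 2.0 * w[:, 0] * w[:, 1]
    a, b = u.sum(), v.sum()
    c = np.sum(u**2 - v**2)
    d = np.sum(2.0 * u * v)
    phi_closed = np.arctan2(d - 2.0 * a * b / p, c - (a**2 - b**2) / p) / 4.0

    def neg_crit(phi):
        return -varimax_criterion(lam @ _rot2(phi), normalize=True)

    grid = np.linspace(-np.pi / 4, np.pi / 4, 181)
    candidates = np.append(grid, phi_closed)
    best = candidates[np.argmin([neg_crit(t) for t in candidates])]
    span = np.pi / 180
    res = minimize_scalar(
        neg_crit, bounds=(best - span, best + span), method="bounded",
        options={"xatol": 1e-10},
    )
    phi = res.x if res.fun < neg_crit(best) else best
    rot = _rot2(phi)
    return replace(
        model,
        loadings=lam @ rot,
        rotation=model.rotation @ rot,
        var_explained=((lam @ rot) ** 2).sum(axis=0) / p,
    )


def bartlett_scores(z: pd.DataFrame | np.ndarray, model: FactorModel) -> pd.DataFrame:
    """Bartlett weighted-least-squares factor scores.

    ``F = (L' Psi^-1 L)^-1 L' Psi^-1 z'`` — conditionally unbiased for the
    latent factors under the fitted model.
    """
    zm = z.to_numpy(dtype=float) if isinstance(z, pd.DataFrame) else np.asarray(z, float)
    index = z.index if isinstance(z, pd.DataFrame) else pd.RangeIndex(len(zm))
    lam, psi = model.loadings, model.uniquenesses
    if zm.shape[1] != lam.shape[0]:
        raise ValueError("z and model have incompatible variable counts")
    lp = lam.T / psi  # (k, p)
    gram = lp @ lam
    if np.linalg.cond(gram) > 1e12:
        raise ValueError("L' Psi^-1 L is singular; cannot compute Bartlett scores")
    scores = zm @ lp.T @ np.linalg.inv(gram).T
    labels = model.factor_labels or tuple(
        f"factor{j + 1}" for j in range(lam.shape[1])
    )
    return pd.DataFrame(scores, index=index, columns=[s.lower() for s in labels])


def label_and_sign(
    model: FactorModel, scores: pd.DataFrame
) -> tuple[FactorModel, pd.DataFrame]:
    """Fix factor order and signs to the Frame/Adiposity convention.

    The factor loading height more strongly (in absolute value) is Frame and
    is listed first; signs are flipped so height loads positively on Frame
    and fat mass positively on Adiposity.
    """
    lam = model.loadings
    if lam.shape[1] != 2:
        raise ValueError("labelling requires a 2-factor model")
    names = model.variable_names

    def _find(key, default):
        hits = [i for i, nm in enumerate(names) if key in nm.lower()]
        return hits[0] if hits else default

    i_height = _find("height", 0)
    i_fat = _find("fat", len(names) - 1)

    h_abs = np.abs(lam[i_height])
    if abs(h_abs[0] - h_abs[1]) < 0.05:
        warnings.warn(
            "ambiguous loading pattern: both factors load height within 0.05; "
            "keeping fit order"
        )
        order = [0, 1]
    else:
        frame_col = int(np.argmax(h_abs))
        order = [frame_col, 1 - frame_col]

    lam = lam[:, order]
    signs = np.array(
        [1.0 if lam[i_height, 0] >= 0 else -1.0, 1.0 if lam[i_fat, 1] >= 0 else -1.0]
    )
    lam = lam * signs
    new_model = replace(
        model,
        loadings=lam,
        rotation=model.rotation[:, order] * signs,
        var_explained=model.var_explained[order],
        factor_labels=("Frame", "Adiposity"),
    )
    new_scores = scores.iloc[:, order] * signs
    new_scores.columns = ["frame", "adiposity"]
    return new_model, new_scores
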