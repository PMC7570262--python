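"""Quasibinomial logit regression with Type III analysis-of-deviance tests.

Retention proportions from merged packet locations are overdispersed
binomial data, so the regression model is a binomial GLM with logit link
whose standard errors are inflated by an estimated dispersion
(Pearson chi-squared over residual degrees of freedom).  Fitting is
iteratively reweighted least squares on the proportion response with
prior weights equal to the number of seeds behind each proportion
(unweighted Bernoulli rows for the seed-level staining model are the
weight-1 special case).

Type III tests drop one term at a time from the full model while keeping
every other term, which is only well defined under non-treatment
contrasts; factor coding is therefore fixed to sum-to-zero.  Each term's
"sum of squares" is the scaled deviance difference and

    F = (delta_deviance / df_term) / dispersion_full

is referred to F(df_term, df_residual).  When dispersion exceeds 2 the
table carries an overdispersion caveat: the quasi-likelihood correction
absorbs, but does not remove, extra-binomial variation, so p-values are
approximate.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

MAX_ITER = 100
DEVIANCE_RTOL = 1e-10
OVERDISPERSION_CAVEAT = 2.0


class ConvergenceError(RuntimeError):
    """IRLS failed to converge; carries the deviance trace."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


@dataclass
class GLMFit:
    """A converged quasibinomial logit fit."""

    coefficients: np.ndarray
    column_names: list[str]
    deviance: float
    pearson_chi2: float
    dispersion: float
    df_residual: int
    df_model: int
    n_obs: int
    fitted: np.ndarray
    deviance_trace: list[float]
    separation_flag: bool = False


@dataclass
class DevianceTable:
    """Type III analysis-of-deviance table plus model metadata."""

    table: pd.DataFrame
    family: str
    link: str
    dispersion: float
    weights: str
    contrasts: str
    df_residual: int
    overdispersed: bool
    notes: list[str] = field(default_factory=list)


def sum_contrast(series: pd.Series, name: str) -> tuple[np.ndarray, list[str]]:
    """Sum-to-zero coding: k-1 columns, last level carries -1 in each."""
    levels = sorted(pd.unique(series.astype(str)))
    if len(levels) < 2:
        raise ValueError(f"factor {name!r} needs >= 2 levels, has {levels}")
    values = series.astype(str).to_numpy()
    cols = np.zeros((len(values), len(levels) - 1))
    for j, level in enumerate(levels[:-1]):
        cols[:, j] = np.where(values == level, 1.0, np.where(values == levels[-1], -1.0, 0.0))
    names = [f"{name}[S.{level}]" for level in levels[:-1]]
    return cols, names


def full_factorial(factors: list[str], max_order: int | None = None) -> list[tuple[str, ...]]:
    """All main effects and interactions of the named factors, by order."""
    max_order = max_order or len(factors)
    terms = []
    for order in range(1, max_order + 1):
        terms.extend(itertools.combinations(factors, order))
    return terms


def build_design(
    data: pd.DataFrame, terms: list[tuple[str, ...]]
) -> tuple[np.ndarray, list[str], dict[tuple[str, ...], slice]]:
    """Model matrix with intercept and sum-to-zero factor columns."""
    blocks = [np.ones((len(data), 1))]
    names = ["(Intercept)"]
    spans: dict[tuple[str, ...], slice] = {}
    base = {f: sum_contrast(data[f], f) for f in sorted({f for t in terms for f in t})}
    col = 1
    for term in terms:
        cols, cnames = base[term[0]]
        for factor in term[1:]:
            fcols, fnames = base[factor]
            cols = np.einsum("ij,ik->ijk", cols, fcols).reshape(len(data), -1)
            cnames = [f"{a}:{b}" for a in cnames for b in fnames]
        blocks.append(cols)
        names.extend(cnames)
        spans[term] = slice(col, col + cols.shape[1])
        col += cols.shape[1]
    return np.hstack(blocks), names, spans


def _binomial_deviance(y: np.ndarray, mu: np.ndarray, w: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        term0 = np.where(y < 1, (1 - y) * np.log((1 - y) / (1 - mu)), 0.0)
    return float(2.0 * np.sum(w * (term1 + term0)))


def fit_irls(
    y: np.ndarray, X: np.ndarray, w: np.ndarray, column_names: list[str] | None = None
) -> GLMFit:
    """Binomial-logit IRLS on proportions with prior weights.

    Converges when the relative deviance change falls below 1e-10
    (or raises :class:`ConvergenceError` after 100 iterations, attaching
    the deviance trace).  Quasi-separation is flagged, not fatal.
    """
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("response proportions must lie in [0, 1]")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    n, p = X.shape
    mu = (w * y + 0.5) / (w + 1.0)
    eta = np.log(mu / (1 - mu))
    deviance = _binomial_deviance(y, mu, w)
    trace = [deviance]
    for _ in range(MAX_ITER):
        variance = mu * (1 - mu)
        z = eta + (y - mu) / variance
        wls = w * variance
        sqw = np.sqrt(wls)
        beta, *_ = np.linalg.lstsq(X * sqw[:, None], z * sqw, rcond=None)
        eta = np.clip(X @ beta, -30.0, 30.0)
        mu = 1.0 / (1.0 + np.exp(-eta))
        new_deviance = _binomial_deviance(y, mu, w)
        trace.append(new_deviance)
        if abs(new_deviance - deviance) <= DEVIANCE_RTOL * (abs(deviance) + 0.1):
            deviance = new_deviance
            break
        deviance = new_deviance
    else:
        raise ConvergenceError(
            f"IRLS did not converge in {MAX_ITER} iterations", trace
        )
    rank = int(np.linalg.matrix_rank(X))
    df_residual = n - rank
    if df_residual <= 0:
        raise ValueError("model is saturated: residual df must be positive")
    pearson = float(np.sum(w * (y - mu) ** 2 / (mu * (1 - mu))))
    separated = bool(np.any(np.abs(eta) >= 29.0))
    if separated:
        warnings.warn(
            "quasi-separation detected: some fitted logits at the clip "
            "boundary; coefficients unreliable",
            stacklevel=2,
        )
    return GLMFit(
        coefficients=beta,
        column_names=column_names or [f"x{i}" for i in range(p)],
        deviance=deviance,
        pearson_chi2=pearson,
        dispersion=pearson / df_residual,
        df_residual=df_residual,
        df_model=rank,
        n_obs=n,
        fitted=mu,
        deviance_trace=trace,
        separation_flag=separated,
    )


def fit_quasibinomial_glm(
    data: pd.DataFrame,
    response: str,
    factors: list[str],
    weights: str | None = None,
    max_order: int | None = None,
) -> DevianceTable:
    """Fit the factorial quasibinomial logit model and its Type III table.

    ``response`` is a proportion column; ``weights`` names the trials
    column (seeds recovered behind each proportion) or is None for
    Bernoulli rows.  ``factors`` are categorical columns entering as a
    full factorial up to ``max_order`` (default: all interactions).
    Table rows follow the term order of the model and end with a
    residual row.
    """
    terms = full_factorial(factors, max_order)
    X, names, spans = build_design(data, terms)
    y = data[response].to_numpy(dtype=float)
    w = data[weights].to_numpy(dtype=float) if weights else np.ones(len(data))
    full = fit_irls(y, X, w, names)
    phi = full.dispersion

    rows = []
    for term in terms:
        keep = np.ones(X.shape[1], dtype=bool)
        keep[spans[term]] = False
        reduced = fit_irls(y, X[:, keep], w)
        delta_dev = reduced.deviance - full.deviance
        df_term = spans[term].stop - spans[term].start
        f_stat = (delta_dev / df_term) / phi
        p = float(stats.f.sf(f_stat, df_term, full.df_residual)) if f_stat >= 0 else np.nan
        rows.append(
            {
                "term": " x ".join(term),
                "sum_sq": delta_dev,
                "df": df_term,
                "f_value": f_stat,
                "p_value": p,
            }
        )
    rows.append(
        {
            "term": "residuals",
            "sum_sq": full.deviance,
            "df": full.df_residual,
            "f_value": np.nan,
            "p_value": np.nan,
        }
    )
    notes = []
    overdispersed = phi > OVERDISPERSION_CAVEAT
    if overdispersed:
        notes.append(
            f"dispersion {phi:.2f} > {OVERDISPERSION_CAVEAT:g}: quasi-likelihood "
            "scaling did not eliminate overdispersion; p-values approximate"
        )
    if full.separation_flag:
        notes.append("quasi-separation flagged during fitting")
    return DevianceTable(
        table=pd.DataFrame(rows),
        family="quasibinomial",
        link="logit",
        dispersion=phi,
        weights=weights or "unweighted (Bernoulli rows)",
        contrasts="sum-to-zero",
        df_residual=full.df_residual,
        overdispersed=overdispersed,
        notes=notes,
    )
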