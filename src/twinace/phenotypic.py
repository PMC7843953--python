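"""Phenotypic-level analyses: transforms, tetrachoric correlation/PCA,
composite outcome coding, and cluster-robust logistic regression.

These are the individual-level analyses that precede the twin modelling:
positively skewed questionnaire totals are ln(x+1)-transformed and
z-scored; binary suicidality items are OR-combined into a composite;
binary symptom items are summarized by their tetrachoric correlation
matrix and its principal components; and odds ratios for suicidality
outcomes come from logistic regressions with sandwich variance clustered
on family, since co-twins are not independent observations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize
from scipy.stats import norm

from ._bvn import bvn_cdf

__all__ = [
    "log_standardize",
    "composite_suicidality",
    "tetrachoric",
    "tetrachoric_matrix",
    "pca_tetrachoric",
    "polyserial",
    "cluster_robust_logistic",
    "RegressionResult",
    "format_or_table",
]


def log_standardize(values) -> np.ndarray:
    """ln(x+1) transform followed by z-scoring on the non-missing entries.

    Intended for non-negative, positively skewed questionnaire totals.
    Missing values propagate.  Raises on zero variance (a constant score
    carries no information to standardize).
    """
    x = np.asarray(values, float)
    mask = ~np.isnan(x)
    if np.any(x[mask] < 0):
        raise ValueError("log_standardize expects non-negative scores")
    out = np.full_like(x, np.nan)
    logged = np.log1p(x[mask])
    sd = logged.std()
    if sd == 0 or not mask.any():
        raise ValueError("zero variance after transform; cannot standardize")
    out[mask] = (logged - logged.mean()) / sd
    return out


def composite_suicidality(ideation, attempt):
    """OR-combination of two binary items into one binary outcome.

    Positive if either item is endorsed; negative only when both are
    observed 0; missing when one item is missing and the other is 0 (an
    endorsement cannot be ruled out).
    """
    i = np.asarray(ideation, float)
    a = np.asarray(attempt, float)
    out = np.full(np.broadcast(i, a).shape, np.nan)
    i, a = np.broadcast_arrays(i, a)
    pos = (i == 1) | (a == 1)
    neg = (i == 0) & (a == 0)
    out[pos] = 1.0
    out[neg] = 0.0
    return out


@dataclass
class TetrachoricResult:
    rho: float
    thresholds: tuple[float, float]
    n: int
    at_bound: bool = False


def tetrachoric(table: np.ndarray, tol: float = 1e-8) -> TetrachoricResult:
    """Tetrachoric correlation from a 2x2 contingency table.

    Two-step maximum likelihood: thresholds from the margins, then a
    1-D Brent search on the latent bivariate-normal correlation.  Rows
    index the first item (0, 1), columns the second.  An empty cell pins
    the estimate at the +/-1 bound, returned with ``at_bound=True``.
    """
    t = np.asarray(table, float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("need a 2x2 table of non-negative counts")
    n = t.sum()
    row1 = t[1].sum() / n
    col1 = t[:, 1].sum() / n
    if min(row1, col1) <= 0 or max(row1, col1) >= 1:
        raise ValueError("a margin of the 2x2 table is empty")
    tau1 = norm.isf(row1)  # threshold of item 1
    tau2 = norm.isf(col1)

    def loglik(rho):
        p11 = _bvn_upper(tau1, tau2, rho)
        p10 = (1.0 - norm.cdf(tau1)) - p11
        p01 = (1.0 - norm.cdf(tau2)) - p11
        p00 = 1.0 - p11 - p10 - p01
        probs = np.clip([p00, p01, p10, p11], 1e-12, 1)
        counts = np.array([t[0, 0], t[0, 1], t[1, 0], t[1, 1]])
        return float((counts * np.log(probs)).sum())

    at_bound = (t == 0).any()
    res = optimize.minimize_scalar(
        lambda r: -loglik(np.tanh(r)),
        bounds=(-7.0, 7.0),
        method="bounded",
        options={"xatol": tol},
    )
    rho = float(np.tanh(res.x))
    if at_bound and abs(rho) > 0.99:
        rho = float(np.sign(rho))
    return TetrachoricResult(rho, (float(tau1), float(tau2)), int(n), at_bound)


def _bvn_upper(h, k, rho):
    """P(X > h, Y > k) via the lower CDF."""
    return float(1.0 - norm.cdf(h) - norm.cdf(k) + bvn_cdf(h, k, rho))


def polyserial(x, y, tol: float = 1e-8) -> float:
    """Two-step ML polyserial correlation: continuous ``x``, binary/ordinal ``y``.

    Thresholds from the marginal category frequencies of ``y``; ``x`` is
    z-scored; the latent correlation maximizes the conditional likelihood
    of the observed categories given ``x``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    if x.std() == 0:
        raise ValueError("x is constant")
    z = (x - x.mean()) / x.std()
    cats = np.unique(y)
    cum = np.cumsum([np.mean(y == c) for c in cats])[:-1]
    tau = norm.ppf(np.clip(cum, 1e-10, 1 - 1e-10))
    tau_pad = np.concatenate([[-np.inf], tau, [np.inf]])
    codes = np.searchsorted(cats, y)
    lo, hi = tau_pad[codes], tau_pad[codes + 1]

    def negll(zr):
        r = np.tanh(zr)
        s = np.sqrt(1.0 - r * r)
        p = norm.cdf((hi - r * z) / s) - norm.cdf((lo - r * z) / s)
        return -np.log(np.clip(p, 1e-300, 1)).sum()

    res = optimize.minimize_scalar(
        negll, bounds=(-7.0, 7.0), method="bounded", options={"xatol": tol}
    )
    return float(np.tanh(res.x))


def tetrachoric_matrix(items: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise tetrachoric correlations over binary item columns.

    Returns (matrix, pairwise n).  Items with zero variance are dropped
    with a warning before computing the matrix.
    """
    keep = []
    for c in items.columns:
        col = items[c].dropna()
        if col.nunique() < 2:
            warnings.warn(f"item {c!r} has zero variance; dropped", UserWarning)
        else:
            keep.append(c)
    items = items[keep]
    k = len(keep)
    R = np.eye(k)
    N = np.zeros((k, k), int)
    for i in range(k):
        N[i, i] = items[keep[i]].notna().sum()
        for j in range(i + 1, k):
            sub = items[[keep[i], keep[j]]].dropna()
            tab = np.zeros((2, 2))
            for a in (0, 1):
                for b in (0, 1):
                    tab[a, b] = ((sub.iloc[:, 0] == a) & (sub.iloc[:, 1] == b)).sum()
            res = tetrachoric(tab)
            R[i, j] = R[j, i] = res.rho
            N[i, j] = N[j, i] = res.n
    return R, N


def _nearest_psd(R: np.ndarray) -> tuple[np.ndarray, bool]:
    vals, vecs = np.linalg.eigh(R)
    if vals.min() >= -1e-10:
        return R, False
    vals = np.clip(vals, 1e-8, None)
    fixed = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    return fixed / np.outer(d, d), True


def _varimax(loadings: np.ndarray, max_iter: int = 200, tol: float = 1e-8):
    p, k = loadings.shape
    rot = np.eye(k)
    var = 0.0
    for _ in range(max_iter):
        L = loadings @ rot
        u, s, vt = np.linalg.svd(
            loadings.T @ (L**3 - (L * (L**2).sum(axis=0)) / p)
        )
        rot = u @ vt
        new = s.sum()
        if new < var * (1 + tol):
            break
        var = new
    return loadings @ rot


@dataclass
class PCAResult:
    eigenvalues: np.ndarray
    loadings: np.ndarray  # unrotated component loadings (items x n_factors)
    rotated_loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    psd_repaired: bool
    items: list[str]


def pca_tetrachoric(items: pd.DataFrame, n_factors: int = 4) -> PCAResult:
    """Principal components of the tetrachoric correlation matrix.

    Eigendecomposition of the (nearest-PSD-repaired, if needed) tetrachoric
    matrix; loadings are eigenvectors scaled by sqrt(eigenvalue), plus a
    varimax rotation of the retained components for interpretation.
    """
    if items.shape[1] < 2:
        raise ValueError("need at least two items")
    R, _ = tetrachoric_matrix(items)
    R, repaired = _nearest_psd(R)
    vals, vecs = np.linalg.eigh(R)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    k = min(n_factors, len(vals))
    load = vecs[:, :k] * np.sqrt(np.maximum(vals[:k], 0))
    # sign convention: dominant direction positive
    signs = np.sign(load.sum(axis=0))
    signs[signs == 0] = 1.0
    load = load * signs
    return PCAResult(
        eigenvalues=vals,
        loadings=load,
        rotated_loadings=_varimax(load),
        explained_variance_ratio=vals / vals.sum(),
        psd_repaired=repaired,
        items=list(items.columns),
    )


@dataclass
class RegressionResult:
    """Odds ratios with cluster-robust 95% Wald confidence intervals."""

    terms: list[str]
    odds_ratios: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    p_values: np.ndarray
    n_obs: int
    n_clusters: int
    adjustment: str = ""
    separation_flag: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "odds_ratio": self.odds_ratios,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "p_value": self.p_values,
                "n": self.n_obs,
                "adjustment": self.adjustment,
            }
        )


def cluster_robust_logistic(
    data: pd.DataFrame,
    outcome: str,
    predictors: list[str],
    cluster: str = "family_id",
    covariates: list[str] | None = None,
    adjustment_label: str = "",
) -> RegressionResult:
    """Logistic regression with sandwich variance clustered on families.

    Missing values are handled by listwise deletion over the model's
    columns; the n actually used is reported.  Complete or quasi-complete
    separation is flagged and the affected CIs marked unreliable via
    ``separation_flag``.
    """
    covariates = covariates or []
    cols = [outcome] + list(predictors) + list(covariates)
    sub = data[cols + [cluster]].dropna()
    y = sub[outcome].to_numpy()
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError(f"outcome {outcome!r} is not binary 0/1")
    X = sm.add_constant(sub[list(predictors) + list(covariates)].to_numpy())
    terms = ["intercept"] + list(predictors) + list(covariates)
    groups = sub[cluster].to_numpy()

    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(tol=1e-12)
        except (sm.tools.sm_exceptions.PerfectSeparationWarning, Exception) as exc:
            if "eparation" not in str(type(exc).__name__) + str(exc):
                raise
            separation = True
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(y, X, family=sm.families.Binomial()).fit(
                    maxiter=25, tol=1e-12
                )
    if np.abs(res.params).max() > 15:
        separation = True

    # plain cluster sandwich H^-1 (sum_c s_c s_c') H^-1, no small-sample
    # factor: invariant under within-cluster duplication
    scores = pd.DataFrame(res.model.score_obs(res.params), index=groups)
    s_c = scores.groupby(level=0).sum().to_numpy()
    bread = res.cov_params()
    vcov = bread @ (s_c.T @ s_c) @ bread
    coefs = res.params
    se = np.sqrt(np.diag(vcov))
    z = norm.ppf(0.975)
    return RegressionResult(
        terms=terms,
        odds_ratios=np.exp(coefs),
        ci_lower=np.exp(coefs - z * se),
        ci_upper=np.exp(coefs + z * se),
        p_values=2.0 * norm.sf(np.abs(coefs / se)),
        n_obs=int(len(sub)),
        n_clusters=int(pd.unique(groups).size),
        adjustment=adjustment_label,
        separation_flag=separation,
    )


def _stars(p: float) -> str:
    return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""


def format_or_table(results: list[RegressionResult]) -> str:
    """Plain-text odds-ratio table: OR (CI lower - upper) with stars."""
    lines = []
    for res in results:
        lines.append(f"[{res.adjustment or 'unadjusted'}]  n = {res.n_obs}")
        for i, term in enumerate(res.terms):
            if term == "intercept":
                continue
            lines.append(
                f"  {term:<28s} {res.odds_ratios[i]:.2f} "
                f"({res.ci_lower[i]:.2f} - {res.ci_upper[i]:.2f})"
                f"{_stars(res.p_values[i])}"
            )
    return "\n".join(lines)
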