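"""Maximum-likelihood fitting of ACE liability models to twin pair data.

Free parameters are mapped to a valid :class:`~twinace.structure.PathModel`
through smooth unconstrained transforms:

* variance shares per trait via normalized squares ``a2 = xa^2 / (1 + xa^2
  [+ xc^2])`` with the E raw coordinate pinned at 1, so the boundary
  ``c2 -> 0`` is reached smoothly and ``a2 + c2 + e2 = 1`` holds by
  construction;
* aetiological correlations via ``tanh``;
* thresholds as a free first cut point plus log-increments;
* (non-standardized) continuous means and log-SDs.

Model fit is summarized by -2LL and AIC = -2LL + 2k.  Confidence intervals
are profile-likelihood intervals: the bound is where the profiled -2LL
rises 3.841 (chi-square(1), 95%) above the minimum, computed for any smooth
scalar function of the parameters (a variance share, rA, a percentage of
the phenotypic correlation) by penalized refitting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from types import SimpleNamespace

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2, norm

from .likelihood import PairData, build_pair_table, fiml_loglik
from .structure import PathModel, TraitDef

__all__ = [
    "FitOptions",
    "FitResult",
    "ProfileCI",
    "CovarianceDecomposition",
    "CorrelatedFactorsParam",
    "CholeskyParam",
    "fit_model",
    "profile_ci",
    "compare_models",
    "decompose_correlation",
    "fit_trivariate_prospective",
    "path_variance_pct",
]

_CHI2_95_1DF = float(chi2.ppf(0.95, 1))  # 3.841
_R_CAP = 1.0 - 1e-9


def path_variance_pct(path: float) -> float:
    """Variance percentage carried by a standardized path: 100 * path**2."""
    return 100.0 * float(path) ** 2


# ---------------------------------------------------------------------------
# parameterizations


class CorrelatedFactorsParam:
    """Correlated-factors ACE/AE model for one or two traits."""

    def __init__(
        self,
        traits: list[TraitDef],
        components: str = "ACE",
        standardized: bool = True,
        threshold_covariates: bool = False,
    ):
        if len(traits) > 2:
            raise ValueError(
                "correlated-factors fitting supports 1 or 2 traits; "
                "use CholeskyParam for more"
            )
        if components not in ("ACE", "AE"):
            raise ValueError("components must be 'ACE' or 'AE'")
        self.traits = traits
        self.components = components
        self.standardized = standardized
        self.threshold_covariates = threshold_covariates
        self.labels: list[str] = []
        for t in traits:
            self.labels.append(f"xa:{t.name}")
            if components == "ACE":
                self.labels.append(f"xc:{t.name}")
        if len(traits) == 2:
            for comp in components:
                self.labels.append(f"z{comp}")
        for t in traits:
            if t.kind == "ordinal":
                self.labels.append(f"tau:{t.name}:0")
                for k in range(1, t.n_categories - 1):
                    self.labels.append(f"dtau:{t.name}:{k}")
                if threshold_covariates:
                    self.labels.append(f"bage:{t.name}")
                    self.labels.append(f"bsex:{t.name}")
            elif not standardized:
                self.labels.append(f"mean:{t.name}")
                self.labels.append(f"logsd:{t.name}")

    @property
    def k(self) -> int:
        return len(self.labels)

    def _get(self, theta, label):
        return theta[self.labels.index(label)]

    def model(self, theta: np.ndarray) -> PathModel:
        p = len(self.traits)
        shares = np.zeros((p, 3))  # a2, c2, e2
        for i, t in enumerate(self.traits):
            xa = self._get(theta, f"xa:{t.name}")
            xc = self._get(theta, f"xc:{t.name}") if self.components == "ACE" else 0.0
            denom = 1.0 + xa * xa + xc * xc
            shares[i] = [xa * xa / denom, xc * xc / denom, 1.0 / denom]
        paths = {
            "A": np.sqrt(shares[:, 0]),
            "E": np.sqrt(shares[:, 2]),
        }
        corr = {}
        if self.components == "ACE":
            paths["C"] = np.sqrt(shares[:, 1])
        if p == 2:
            for comp in self.components:
                r = np.clip(np.tanh(self._get(theta, f"z{comp}")), -_R_CAP, _R_CAP)
                corr[comp] = np.array([[1.0, r], [r, 1.0]])
        thresholds, betas, means, sds = {}, {}, {}, {}
        for t in self.traits:
            if t.kind == "ordinal":
                tau0 = self._get(theta, f"tau:{t.name}:0")
                taus = [tau0]
                for k in range(1, t.n_categories - 1):
                    taus.append(taus[-1] + np.exp(self._get(theta, f"dtau:{t.name}:{k}")))
                thresholds[t.name] = np.array(taus)
                if self.threshold_covariates:
                    betas[t.name] = {
                        "age": self._get(theta, f"bage:{t.name}"),
                        "sex": self._get(theta, f"bsex:{t.name}"),
                    }
            elif not self.standardized:
                means[t.name] = self._get(theta, f"mean:{t.name}")
                sds[t.name] = float(np.exp(self._get(theta, f"logsd:{t.name}")))
        return PathModel(
            traits=self.traits,
            form="correlated_factors",
            components=self.components,
            paths=paths,
            corr=corr,
            thresholds=thresholds,
            threshold_betas=betas,
            means=means,
            sds=sds,
            standardized=self.standardized,
        )

    def start(self, pairs: PairData, jitter: np.ndarray | None = None) -> np.ndarray:
        p = len(self.traits)
        theta = np.zeros(self.k)
        for i, label in enumerate(self.labels):
            kind = label.split(":")[0]
            if kind in ("xa", "xc"):
                theta[i] = 0.8  # shares ~ (0.3, 0.3, 0.4)
            elif kind == "tau":
                name = label.split(":")[1]
                j = [t.name for t in self.traits].index(name)
                vals = pairs.y[:, [j, j + p]]
                vals = vals[~np.isnan(vals)]
                p0 = max(min((vals == 0).mean(), 0.999), 0.001) if vals.size else 0.5
                theta[i] = norm.ppf(p0)
            elif kind == "dtau":
                name = label.split(":")[1]
                j = [t.name for t in self.traits].index(name)
                kcat = int(label.split(":")[2])
                vals = pairs.y[:, [j, j + p]]
                vals = vals[~np.isnan(vals)]
                if vals.size:
                    lo = max(min((vals <= kcat - 1).mean(), 0.998), 0.001)
                    hi = max(min((vals <= kcat).mean(), 0.999), lo + 1e-3)
                    theta[i] = np.log(max(norm.ppf(hi) - norm.ppf(lo), 1e-2))
            elif kind == "mean":
                name = label.split(":")[1]
                j = [t.name for t in self.traits].index(name)
                vals = pairs.y[:, [j, j + p]]
                theta[i] = np.nanmean(vals)
            elif kind == "logsd":
                name = label.split(":")[1]
                j = [t.name for t in self.traits].index(name)
                vals = pairs.y[:, [j, j + p]]
                theta[i] = np.log(max(np.nanstd(vals), 1e-3))
        if jitter is not None:
            theta = theta + jitter
        return theta

    def quantity(self, theta: np.ndarray, name: str) -> float:
        """Derived scalar estimates by label.

        Supported: ``a2:<trait>`` (likewise c2/e2), ``a:<trait>``, ``rA``,
        ``rC``, ``rE``, ``rPh``, ``covA``/``covC``/``covE`` (cross-trait
        covariance channels), ``pctA``/``pctC``/``pctE``,
        ``tau:<trait>:<k>``, ``mean:<trait>``, ``sd:<trait>``.
        """
        model = self.model(theta)
        shares = model.trait_variance_shares()
        parts = name.split(":")
        if parts[0] in ("a2", "c2", "e2"):
            return shares[parts[1]][parts[0]]
        if parts[0] in ("a", "c", "e"):
            return float(np.sqrt(shares[parts[1]][parts[0] + "2"]))
        if name in ("rA", "rC", "rE"):
            comp = name[1]
            if comp not in model.corr:
                return 0.0
            return float(model.corr[comp][0, 1])
        if name in ("covA", "covC", "covE", "rPh") or parts[0].startswith("pct"):
            covs = {
                comp: float(model.component_covariance(comp)[0, 1])
                for comp in model.component_list
            }
            rph = sum(covs.values())
            if name == "rPh":
                return rph
            if name.startswith("cov"):
                return covs.get(name[3], 0.0)
            if abs(rph) < 1e-8:
                raise ZeroDivisionError(
                    "phenotypic correlation is ~0; component percentages undefined"
                )
            return 100.0 * covs.get(name[3], 0.0) / rph
        if parts[0] == "tau":
            return float(model.thresholds[parts[1]][int(parts[2])])
        if parts[0] == "mean":
            return float(model.means[parts[1]])
        if parts[0] == "sd":
            return float(model.sds[parts[1]])
        raise KeyError(f"unknown quantity {name!r}")

    def report_quantities(self) -> list[str]:
        names = []
        for t in self.traits:
            for comp in self.components:
                names.append(f"{comp.lower()}2:{t.name}")
        if len(self.traits) == 2:
            names += [f"r{comp}" for comp in self.components]
            names += ["rPh"] + [f"pct{comp}" for comp in self.components]
        for t in self.traits:
            if t.kind == "ordinal":
                names += [f"tau:{t.name}:{k}" for k in range(t.n_categories - 1)]
        return names


class CholeskyParam:
    """Lower-triangular Cholesky ACE/AE model (typically trivariate).

    Raw lower-triangular entries for each component (the E diagonal is
    pinned at 1 as the scale gauge); each trait's row is normalized across
    components so standardized liability variances equal 1.
    """

    def __init__(self, traits: list[TraitDef], components: str = "AE"):
        if components not in ("ACE", "AE"):
            raise ValueError("components must be 'ACE' or 'AE'")
        self.traits = traits
        self.components = components
        self.labels = []
        p = len(traits)
        for comp in components:
            for i in range(p):
                for j in range(i + 1):
                    if comp == "E" and i == j:
                        continue  # gauge: raw E diagonal = 1
                    self.labels.append(f"{comp}:{i}:{j}")
        for t in traits:
            if t.kind == "ordinal":
                self.labels.append(f"tau:{t.name}:0")
                for k in range(1, t.n_categories - 1):
                    self.labels.append(f"dtau:{t.name}:{k}")

    @property
    def k(self) -> int:
        return len(self.labels)

    def _matrices(self, theta):
        p = len(self.traits)
        mats = {comp: np.zeros((p, p)) for comp in self.components}
        for comp in self.components:
            for i in range(p):
                for j in range(i + 1):
                    if comp == "E" and i == j:
                        mats[comp][i, j] = 1.0
                    else:
                        mats[comp][i, j] = theta[self.labels.index(f"{comp}:{i}:{j}")]
        # normalize rows so total liability variance is 1 per trait
        total = sum((m**2).sum(axis=1) for m in mats.values())
        scale = 1.0 / np.sqrt(total)
        for comp in self.components:
            mats[comp] = mats[comp] * scale[:, None]
        return mats

    def model(self, theta: np.ndarray) -> PathModel:
        mats = self._matrices(theta)
        thresholds = {}
        for t in self.traits:
            if t.kind == "ordinal":
                tau0 = theta[self.labels.index(f"tau:{t.name}:0")]
                taus = [tau0]
                for k in range(1, t.n_categories - 1):
                    taus.append(
                        taus[-1]
                        + np.exp(theta[self.labels.index(f"dtau:{t.name}:{k}")])
                    )
                thresholds[t.name] = np.array(taus)
        return PathModel(
            traits=self.traits,
            form="cholesky",
            components=self.components,
            paths=mats,
            thresholds=thresholds,
            standardized=True,
        )

    def start(self, pairs: PairData, jitter: np.ndarray | None = None) -> np.ndarray:
        p = len(self.traits)
        theta = np.zeros(self.k)
        for i, label in enumerate(self.labels):
            parts = label.split(":")
            if parts[0] in self.components:
                theta[i] = 0.7 if parts[1] == parts[2] else 0.1
            elif parts[0] == "tau":
                name = parts[1]
                j = [t.name for t in self.traits].index(name)
                vals = pairs.y[:, [j, j + p]]
                vals = vals[~np.isnan(vals)]
                p0 = max(min((vals == 0).mean(), 0.999), 0.001) if vals.size else 0.5
                theta[i] = norm.ppf(p0)
            elif parts[0] == "dtau":
                theta[i] = 0.0
        if jitter is not None:
            theta = theta + jitter
        return theta

    def quantity(self, theta: np.ndarray, name: str) -> float:
        """Cholesky-specific quantities.

        ``path:<comp>:<i>:<j>`` (normalized path), ``a2:<trait>`` etc.
        (total shares), ``r<comp>:<i>:<j>`` (correlated-factors
        aetiological correlation), ``cov<comp>_unique`` and
        ``pct<comp>_unique`` (the trait-2 -> trait-3 covariance channel not
        routed through trait 1's factors).
        """
        mats = self._matrices(theta)
        model = self.model(theta)
        parts = name.split(":")
        if parts[0] == "path":
            return float(mats[parts[1]][int(parts[2]), int(parts[3])])
        if parts[0] in ("a2", "c2", "e2"):
            return model.trait_variance_shares()[parts[1]][parts[0]]
        if parts[0] == "tau":
            return float(model.thresholds[parts[1]][int(parts[2])])
        if parts[0][0] == "r" and len(parts) == 3:
            comp = parts[0][1]
            cov = model.component_covariance(comp)
            i, j = int(parts[1]), int(parts[2])
            denom = np.sqrt(cov[i, i] * cov[j, j])
            return float(cov[i, j] / denom) if denom > 0 else 0.0
        if name.endswith("_unique"):
            comp_covs = {
                comp: float(mats[comp][1, 1] * mats[comp][2, 1])
                for comp in self.components
            }
            total = sum(comp_covs.values())
            comp = name[3] if name.startswith("cov") else name[3]
            if name.startswith("cov"):
                return comp_covs[comp]
            if abs(total) < 1e-12:
                raise ZeroDivisionError("unique association is ~0; shares undefined")
            return 100.0 * comp_covs[comp] / total
        raise KeyError(f"unknown quantity {name!r}")

    def report_quantities(self) -> list[str]:
        p = len(self.traits)
        names = []
        for comp in self.components:
            for i in range(p):
                for j in range(i + 1):
                    names.append(f"path:{comp}:{i}:{j}")
        for t in self.traits:
            for comp in self.components:
                names.append(f"{comp.lower()}2:{t.name}")
        for comp in self.components:
            names.append(f"r{comp}:0:1")
        if p >= 3:
            for comp in self.components:
                names.append(f"cov{comp}_unique")
        return names


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitOptions:
    n_starts: int = 5
    start_seed: int = 1234
    jitter_sd: float = 0.3
    maxiter: int = 500
    gtol: float = 1e-5
    min_pairs_per_zygosity: int = 20


@dataclass
class ProfileCI:
    lower: float
    upper: float
    truncated_lower: bool = False
    truncated_upper: bool = False

    def contains(self, value: float) -> bool:
        return self.lower - 1e-12 <= value <= self.upper + 1e-12


@dataclass
class FitResult:
    param: object
    theta: np.ndarray
    minus2LL: float
    converged: bool
    n_pairs: dict
    pairs: PairData | None = None
    estimates: dict = field(default_factory=dict)
    cis: dict = field(default_factory=dict)
    n_starts_used: int = 1

    @property
    def k(self) -> int:
        return self.param.k

    @property
    def aic(self) -> float:
        return self.minus2LL + 2.0 * self.k

    def quantity(self, name: str) -> float:
        return self.param.quantity(self.theta, name)

    @property
    def model(self) -> PathModel:
        return self.param.model(self.theta)

    def to_json(self, path=None) -> str:
        doc = {
            "parameterization": type(self.param).__name__,
            "components": self.param.components,
            "traits": [
                {"name": t.name, "kind": t.kind, "n_categories": t.n_categories}
                for t in self.param.traits
            ],
            "minus2LL": self.minus2LL,
            "AIC": self.aic,
            "k_free_parameters": self.k,
            "converged": bool(self.converged),
            "n_pairs": self.n_pairs,
            "theta": {l: float(v) for l, v in zip(self.param.labels, self.theta)},
            "estimates": {k: float(v) for k, v in self.estimates.items()},
            "estimates_2dp": {k: round(float(v), 2) for k, v in self.estimates.items()},
            "profile_ci": {
                k: {
                    "lower": ci.lower,
                    "upper": ci.upper,
                    "truncated_lower": ci.truncated_lower,
                    "truncated_upper": ci.truncated_upper,
                }
                for k, ci in self.cis.items()
            },
        }
        text = json.dumps(doc, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _objective(param, pairs):
    def m2ll(theta):
        try:
            return -2.0 * fiml_loglik(param.model(theta), pairs)
        except (np.linalg.LinAlgError, ValueError):
            return 1e12

    return m2ll


def fit_model(
    param,
    data: pd.DataFrame | PairData,
    options: FitOptions | None = None,
) -> FitResult:
    """Fit a parameterized ACE model by FIML with deterministic multi-start.

    ``data`` may be a long-format cohort (pivoted internally) or a
    pre-built :class:`PairData`.  The best of ``options.n_starts`` jittered
    starts is reported; failure to converge from every start yields
    ``converged=False``, never a silent partial result.
    """
    options = options or FitOptions()
    if isinstance(data, PairData):
        pairs = data
    else:
        pairs = build_pair_table(data, SimpleNamespace(traits=param.traits))
    counts = pairs.counts()
    for zyg, cnt in counts.items():
        if cnt < options.min_pairs_per_zygosity:
            raise ValueError(
                f"only {cnt} {zyg} pairs available "
                f"(minimum {options.min_pairs_per_zygosity})"
            )

    m2ll = _objective(param, pairs)
    rng = np.random.default_rng(options.start_seed)
    best = None
    any_converged = False
    n_used = 0
    for s in range(options.n_starts):
        jitter = None if s == 0 else rng.normal(0.0, options.jitter_sd, param.k)
        theta0 = param.start(pairs, jitter=jitter)
        res = optimize.minimize(
            m2ll,
            theta0,
            method="L-BFGS-B",
            options={"maxiter": options.maxiter, "gtol": options.gtol},
        )
        n_used = s + 1
        if best is None or res.fun < best.fun - 1e-9:
            best = res
        if res.success:
            any_converged = True
            if s >= 1 and best.fun <= res.fun + 1e-6:
                break  # converged start agreeing with the incumbent

    fit = FitResult(
        param=param,
        theta=np.asarray(best.x, float),
        minus2LL=float(best.fun),
        converged=bool(any_converged),
        n_pairs=counts,
        pairs=pairs,
        n_starts_used=n_used,
    )
    fit.estimates = {
        name: fit.quantity(name) for name in param.report_quantities()
    }
    return fit


# ---------------------------------------------------------------------------
# profile confidence intervals


_QUANTITY_BOUNDS = {
    "a2": (0.0, 1.0),
    "c2": (0.0, 1.0),
    "e2": (0.0, 1.0),
    "a": (0.0, 1.0),
    "c": (0.0, 1.0),
    "e": (0.0, 1.0),
    "rA": (-1.0, 1.0),
    "rC": (-1.0, 1.0),
    "rE": (-1.0, 1.0),
    "rPh": (-1.0, 1.0),
}


def _bounds_for(name: str):
    key = name.split(":")[0]
    if key in _QUANTITY_BOUNDS:
        return _QUANTITY_BOUNDS[key]
    if key.startswith("r") and len(key) == 2:
        return (-1.0, 1.0)
    if key.startswith("pct"):
        return (-np.inf, np.inf)
    return (-np.inf, np.inf)


def profile_ci(
    fit: FitResult,
    name: str,
    level: float = 0.95,
    max_halfwidth: float | None = None,
) -> ProfileCI:
    """Profile-likelihood CI for any smooth scalar quantity of the fit.

    The quantity is pinned at trial values with a quadratic penalty while
    all other parameters are re-optimized; the bound solves
    ``profiled -2LL = min -2LL + chi2_{1,level}``.  Bounds hitting the
    natural box of the quantity (0, +/-1) are truncated and flagged.
    """
    if not fit.converged:
        raise ValueError("profile CI requires a converged fit")
    if fit.pairs is None:
        raise ValueError("fit carries no data; refit before profiling")
    qhat = fit.quantity(name)
    crit = float(chi2.ppf(level, 1))
    target = fit.minus2LL + crit
    lo_bound, hi_bound = _bounds_for(name)
    scale = max(abs(qhat), 100.0 if name.startswith("pct") else 0.25)
    if max_halfwidth is None:
        max_halfwidth = 8.0 * scale
    weight = 1e6 / scale**2
    m2ll = _objective(fit.param, fit.pairs)
    warm = {"theta": fit.theta.copy()}

    def profiled(v):
        def pen(theta):
            q = fit.param.quantity(theta, name)
            return m2ll(theta) + weight * (q - v) ** 2

        res = optimize.minimize(
            pen, warm["theta"], method="L-BFGS-B", options={"maxiter": 300}
        )
        warm["theta"] = res.x
        return m2ll(res.x)

    def bound(direction):
        step = 0.05 * scale
        prev_v, prev_h = qhat, -crit
        truncated = False
        v = qhat
        while True:
            v = v + direction * step
            clipped = min(max(v, lo_bound), hi_bound)
            at_edge = clipped != v
            v = clipped
            h = profiled(v) - target
            if h >= 0.0:
                break
            prev_v, prev_h = v, h
            if at_edge or abs(v - qhat) >= max_halfwidth:
                truncated = True
                break
            step *= 1.8
        if truncated:
            return v, True
        if prev_v == v:
            return v, False
        root = optimize.brentq(
            lambda u: profiled(u) - target, min(prev_v, v), max(prev_v, v),
            xtol=1e-4 * scale,
        )
        return root, False

    lower, tl = bound(-1.0)
    upper, tu = bound(+1.0)
    warm["theta"] = fit.theta.copy()
    ci = ProfileCI(float(lower), float(upper), tl, tu)
    fit.cis[name] = ci
    return ci


# ---------------------------------------------------------------------------
# model comparison and decomposition


@dataclass
class ModelComparison:
    delta_minus2LL: float
    delta_df: int
    p_value: float
    delta_aic: float
    preferred: str  # "full" | "nested"

    def as_dict(self):
        return {
            "delta_minus2LL": self.delta_minus2LL,
            "delta_df": self.delta_df,
            "p_value": self.p_value,
            "delta_AIC": self.delta_aic,
            "preferred": self.preferred,
        }


def compare_models(full: FitResult, nested: FitResult) -> ModelComparison:
    """Likelihood-ratio and AIC comparison of nested model fits.

    The simpler model is preferred when the -2LL difference is
    non-significant (chi-square test), or when its AIC is lower by >= 3.
    """
    full_labels, nested_labels = set(full.param.labels), set(nested.param.labels)
    if not nested_labels <= full_labels:
        raise ValueError(
            "models are not nested: nested model has parameters "
            f"{sorted(nested_labels - full_labels)} absent from the full model"
        )
    ddf = full.k - nested.k
    dll = nested.minus2LL - full.minus2LL
    p = float(chi2.sf(max(dll, 0.0), ddf)) if ddf > 0 else 1.0
    daic = nested.aic - full.aic
    if ddf == 0:
        preferred = "nested"
    elif p > 0.05 or daic <= -3.0:
        preferred = "nested"
    else:
        preferred = "full"
    return ModelComparison(float(dll), int(ddf), p, float(daic), preferred)


@dataclass
class CovarianceDecomposition:
    """Decomposition of a bivariate phenotypic correlation into A/C/E channels."""

    rPh: float
    rA: float
    rC: float
    rE: float
    pctA: float
    pctC: float
    pctE: float
    cis: dict = field(default_factory=dict)

    def as_dict(self):
        d = {
            "rPh": self.rPh,
            "rA": self.rA,
            "rC": self.rC,
            "rE": self.rE,
            "pctA": self.pctA,
            "pctC": self.pctC,
            "pctE": self.pctE,
        }
        if self.cis:
            d["ci"] = {
                k: {"lower": v.lower, "upper": v.upper} for k, v in self.cis.items()
            }
        return d


def decompose_correlation(
    fit: FitResult, with_ci: bool = False, level: float = 0.95
) -> CovarianceDecomposition:
    """Split the model-implied phenotypic correlation into component shares.

    ``pctX = 100 * rX * x1 * x2 / rPh``; the shares sum to 100 by
    construction.  Raises if the phenotypic correlation is numerically 0.
    """
    if not fit.converged:
        raise ValueError("decomposition requires a converged fit")
    if len(fit.param.traits) != 2:
        raise ValueError("decomposition is defined for bivariate fits")
    rph = fit.quantity("rPh")
    if abs(rph) < 1e-8:
        raise ZeroDivisionError(
            "phenotypic correlation is ~0; component percentages undefined"
        )
    comps = fit.param.components
    out = CovarianceDecomposition(
        rPh=rph,
        rA=fit.quantity("rA"),
        rC=fit.quantity("rC") if "C" in comps else 0.0,
        rE=fit.quantity("rE"),
        pctA=fit.quantity("pctA"),
        pctC=fit.quantity("pctC") if "C" in comps else 0.0,
        pctE=fit.quantity("pctE"),
    )
    if with_ci:
        for q in ["pct" + c for c in comps] + ["rA", "rE", "rPh"]:
            out.cis[q] = profile_ci(fit, q, level=level)
    return out


def fit_with_ae_reduction(
    traits: list[TraitDef],
    data: pd.DataFrame | PairData,
    options: FitOptions | None = None,
    c_share_cutoff: float = 0.05,
):
    """Fit the full ACE model, then test the AE reduction.

    When every fitted C share is below ``c_share_cutoff`` the AE model is
    fitted and accepted if the likelihood-ratio test shows no significant
    loss of fit (the usual reporting convention: boundary-pinned C both
    biases A downward and costs a parameter).  Returns
    ``(chosen_fit, ace_fit, comparison_or_None)``.
    """
    ace = fit_model(CorrelatedFactorsParam(traits, "ACE"), data, options)
    shares = [ace.quantity(f"c2:{t.name}") for t in traits]
    if max(shares) >= c_share_cutoff:
        return ace, ace, None
    ae = fit_model(CorrelatedFactorsParam(traits, "AE"), data, options)
    comparison = compare_models(ace, ae)
    chosen = ae if comparison.preferred == "nested" else ace
    return chosen, ace, comparison


def fit_trivariate_prospective(
    data: pd.DataFrame | PairData,
    traits: list[TraitDef],
    components: str = "AE",
    options: FitOptions | None = None,
    min_complete_followup: int = 50,
) -> tuple[FitResult, dict]:
    """Trivariate Cholesky model for a prospective association.

    Traits must be ordered (baseline suicidality, baseline OCS, follow-up
    suicidality).  The concurrent baseline block is reported in
    correlated-factors form; directed Cholesky paths carry both baseline
    factor sets onto the follow-up trait.  The returned decomposition gives
    the %A/%E split of the *unique* baseline-OCS -> follow-up channel (the
    covariance not routed through baseline suicidality's factors).
    """
    if len(traits) != 3:
        raise ValueError("the prospective model takes exactly three traits")
    param = CholeskyParam(traits, components=components)
    if isinstance(data, PairData):
        pairs = data
    else:
        pairs = build_pair_table(data, SimpleNamespace(traits=param.traits))
    p = 3
    follow = pairs.y[:, [2, 2 + p]]
    n_complete = int((~np.isnan(follow)).any(axis=1).sum())
    if n_complete < min_complete_followup:
        raise ValueError(
            f"only {n_complete} pairs have follow-up data "
            f"(minimum {min_complete_followup})"
        )
    fit = fit_model(param, pairs, options=options)
    covs = {c: fit.quantity(f"cov{c}_unique") for c in components}
    total = sum(covs.values())
    decomp = {"cov_unique_total": total}
    for c in components:
        decomp[f"cov{c}_unique"] = covs[c]
        decomp[f"pct{c}_unique"] = (
            100.0 * covs[c] / total if abs(total) > 1e-12 else np.nan
        )
    decomp["paths_to_followup"] = {
        f"{c}:{j}": fit.quantity(f"path:{c}:2:{j}")
        for c in components
        for j in range(3)
    }
    decomp["n_pairs_with_followup"] = n_complete
    return fit, decomp
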