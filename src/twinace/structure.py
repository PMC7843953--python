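"""ACE path models and their model-implied twin covariance structure.

Two equivalent parameterizations of the multivariate ACE model are
supported:

* ``correlated_factors`` — per-trait standardized paths ``a_i, c_i, e_i``
  plus aetiological correlation matrices ``rA, rC, rE`` between traits'
  component factors (the reporting form for concurrent associations);
* ``cholesky`` — lower-triangular path matrices ``A, C, E`` letting earlier
  traits' factors load on later traits (the directed form used for
  prospective decompositions).

Either way, the model implies a ``2p x 2p`` covariance over (twin-1 traits,
twin-2 traits): within-person blocks are the summed component covariances,
and cross-twin blocks scale the A contribution by 1.0 (MZ) or 0.5 (DZ) and
the C contribution by 1.0, with E uncorrelated across co-twins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TraitDef", "PathModel", "implied_structure", "A_SCALE"]

#: cross-twin scaling of the additive-genetic covariance
A_SCALE = {"MZ": 1.0, "DZ": 0.5}
_C_SCALE = {"MZ": 1.0, "DZ": 1.0}


@dataclass(frozen=True)
class TraitDef:
    """Analysis-side trait: a column name plus its measurement scale."""

    name: str
    kind: str = "continuous"  # continuous | ordinal
    n_categories: int = 2  # ordinal only

    def __post_init__(self):
        if self.kind not in ("continuous", "ordinal"):
            raise ValueError(f"unknown trait kind {self.kind!r}")
        if self.kind == "ordinal" and self.n_categories < 2:
            raise ValueError("ordinal traits need >= 2 categories")


@dataclass
class PathModel:
    """A fully specified ACE structural model (point in parameter space).

    ``paths`` holds, per component, either a length-p vector of standardized
    paths (correlated-factors form, with ``corr`` the component correlation
    matrices) or a p x p lower-triangular matrix (Cholesky form).
    Ordinal traits carry free ``thresholds`` (strictly increasing liability
    cut points, shared across co-twins) and optional linear age/sex effects
    on those thresholds.  Continuous traits carry a mean and SD unless
    ``standardized`` is set.
    """

    traits: list[TraitDef]
    form: str = "correlated_factors"  # correlated_factors | cholesky
    components: str = "ACE"  # ACE | AE
    paths: dict = field(default_factory=dict)  # comp -> vector or lower-tri matrix
    corr: dict = field(default_factory=dict)  # comp -> (p, p) correlation matrix
    thresholds: dict = field(default_factory=dict)  # trait name -> array
    threshold_betas: dict = field(default_factory=dict)  # trait -> {"age","sex"}
    means: dict = field(default_factory=dict)  # continuous trait -> mean
    sds: dict = field(default_factory=dict)  # continuous trait -> sd
    standardized: bool = True

    @property
    def p(self) -> int:
        return len(self.traits)

    @property
    def component_list(self) -> list[str]:
        return list(self.components)

    def validate(self) -> None:
        p = self.p
        for comp in self.component_list:
            if comp == "E" and comp not in self.paths:
                raise ValueError("E paths are required")
            m = np.asarray(self.paths.get(comp, np.zeros(p)), float)
            if self.form == "cholesky":
                if m.shape != (p, p) or not np.allclose(m, np.tril(m)):
                    raise ValueError(f"{comp} must be a {p}x{p} lower-triangular matrix")
            else:
                if m.shape != (p,):
                    raise ValueError(f"{comp} paths must be a length-{p} vector")
                r = self.corr.get(comp, np.eye(p))
                if np.abs(np.asarray(r)).max() > 1 + 1e-12:
                    raise ValueError(f"r{comp} outside [-1, 1]")
        if self.form == "correlated_factors":
            for i, t in enumerate(self.traits):
                total = sum(
                    float(np.asarray(self.paths.get(comp, np.zeros(p)))[i]) ** 2
                    for comp in self.component_list
                )
                if t.kind == "ordinal" and not np.isclose(total, 1.0, atol=1e-8):
                    raise ValueError(
                        f"liability variance of ordinal trait {t.name!r} is "
                        f"{total:.6f}, must be 1"
                    )
        for t in self.traits:
            if t.kind == "ordinal":
                tau = np.asarray(self.thresholds.get(t.name, ()), float)
                if tau.size != t.n_categories - 1:
                    raise ValueError(f"trait {t.name!r} needs {t.n_categories - 1} thresholds")
                if np.any(np.diff(tau) <= 0):
                    raise ValueError(f"thresholds of {t.name!r} not increasing")

    def component_covariance(self, comp: str) -> np.ndarray:
        """Within-person covariance contributed by one component."""
        p = self.p
        if comp not in self.paths:
            return np.zeros((p, p))
        m = np.asarray(self.paths[comp], float)
        if self.form == "cholesky":
            return m @ m.T
        r = np.asarray(self.corr.get(comp, np.eye(p)), float)
        return r * np.outer(m, m)

    def trait_variance_shares(self) -> dict[str, dict[str, float]]:
        """Per-trait standardized variance shares (a2/c2/e2)."""
        out = {}
        total = sum(
            np.diag(self.component_covariance(c)) for c in self.component_list
        )
        for i, t in enumerate(self.traits):
            out[t.name] = {
                comp.lower() + "2": float(
                    np.diag(self.component_covariance(comp))[i] / total[i]
                )
                for comp in self.component_list
            }
        return out


def implied_structure(model: PathModel, zygosity: str) -> np.ndarray:
    """Model-implied 2p x 2p covariance over (twin-1 traits, twin-2 traits).

    Within-person cross-trait entries are ``rA a_i a_j + rC c_i c_j +
    rE e_i e_j`` (or the matching Cholesky products); cross-twin entries
    scale the A contribution by 1.0 (MZ) / 0.5 (DZ), C by 1.0, E by 0.
    """
    if zygosity not in A_SCALE:
        raise ValueError(f"zygosity must be MZ or DZ, got {zygosity!r}")
    p = model.p
    within = np.zeros((p, p))
    cross = np.zeros((p, p))
    for comp in model.component_list:
        cov = model.component_covariance(comp)
        within += cov
        scale = A_SCALE[zygosity] if comp == "A" else (_C_SCALE[zygosity] if comp == "C" else 0.0)
        cross += scale * cov
    full = np.block([[within, cross], [cross.T, within]])
    eig = np.linalg.eigvalsh(full)
    if eig.min() < -1e-8:
        sub = "cross-twin" if np.linalg.eigvalsh(within).min() >= -1e-8 else "within-person"
        raise ValueError(
            f"implied {zygosity} structure not PSD (min eigenvalue {eig.min():.3g}; "
            f"{sub} block at fault)"
        )
    return full
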