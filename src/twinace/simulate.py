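"""Synthetic twin-cohort generation.

Generates long-format twin data (one row per individual per wave) whose
statistical structure follows a multivariate ACE liability model: each
trait's liability is the sum of additive-genetic (A), shared-environment (C)
and non-shared-environment (E) standard-normal factors with variance shares
``a2 + c2 + e2 = 1``.  Across co-twins the A factors correlate 1.0 in
monozygotic (MZ) and 0.5 in dizygotic (DZ) pairs, C correlates 1.0 in both,
and E is uncorrelated.  Between traits, the component factors correlate
``rA``/``rC``/``rE``, so the within-person cross-trait correlation is
``rA*a1*a2 + rC*c1*c2 + rE*e1*e2``.

Binary/ordinal traits are produced by cutting the liability at fixed
thresholds; continuous traits may be skew-transformed to emulate the
positively skewed observed scales common to symptom questionnaires.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

__all__ = [
    "TraitSpec",
    "SimConfig",
    "simulate_twin_cohort",
    "apply_attrition",
    "write_cohort",
    "read_cohort",
    "load_config",
    "save_config",
    "default_cohort_config",
    "COHORT_COLUMNS",
]

#: fixed column order and coding of the cohort CSV
BASE_COLUMNS = ["family_id", "twin_index", "zygosity", "sex", "age", "wave"]
COHORT_COLUMNS = BASE_COLUMNS  # trait columns appended in config order
ZYGOSITY_CODES = ("MZ", "DZ", "unknown")


@dataclass(frozen=True)
class TraitSpec:
    """One simulated phenotype on the liability scale.

    Parameters
    ----------
    name
        Column name in the output cohort.
    kind
        ``"continuous"``, ``"binary"`` or ``"ordinal"``.
    a2, c2, e2
        Liability variance shares; must sum to 1.
    thresholds
        Strictly increasing liability cut points (binary/ordinal only).
        A binary trait has one threshold; ``norm.isf(prevalence)`` places it.
    wave
        Measurement wave tag (e.g. 18 or 24).
    skew
        If nonzero, the observed continuous score is ``exp(skew * liability)``
        rescaled to ``score_mean``/``score_sd`` — a log-normal-shaped score so
        a downstream ln(x+1) transform is exercised round-trip.
    score_mean, score_sd
        Target observed mean/SD for skewed continuous traits.
    sex_effect, age_effect
        Linear effects of (sex - mean sex) and (age - mean age) added to the
        liability before thresholding / transformation.
    """

    name: str
    kind: str = "continuous"
    a2: float = 0.0
    c2: float = 0.0
    e2: float = 1.0
    thresholds: tuple[float, ...] = ()
    wave: int = 18
    skew: float = 0.0
    score_mean: float = 1.0
    score_sd: float = 1.0
    sex_effect: float = 0.0
    age_effect: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary", "ordinal"):
            raise ValueError(f"unknown trait kind {self.kind!r}")
        total = self.a2 + self.c2 + self.e2
        if not np.isclose(total, 1.0, atol=1e-10):
            raise ValueError(
                f"variance shares of {self.name!r} sum to {total}, expected 1"
            )
        if min(self.a2, self.c2, self.e2) < 0:
            raise ValueError(f"negative variance share in {self.name!r}")
        th = np.asarray(self.thresholds, float)
        if self.kind == "continuous":
            if th.size:
                raise ValueError(f"continuous trait {self.name!r} has thresholds")
        else:
            if self.kind == "binary" and th.size != 1:
                raise ValueError(f"binary trait {self.name!r} needs one threshold")
            if th.size < 1:
                raise ValueError(f"ordinal trait {self.name!r} needs thresholds")
            if np.any(np.diff(th) <= 0):
                raise ValueError(f"thresholds of {self.name!r} not increasing")

    @property
    def paths(self) -> np.ndarray:
        """Standardized path coefficients (a, c, e)."""
        return np.sqrt([self.a2, self.c2, self.e2])

    @classmethod
    def binary_from_prevalence(cls, name, prevalence, **kw) -> "TraitSpec":
        """Binary trait with its threshold set at the given tail prevalence."""
        return cls(name, kind="binary", thresholds=(float(norm.isf(prevalence)),), **kw)


def _as_corr(mat, p, label) -> np.ndarray:
    m = np.asarray(mat, float)
    if m.shape != (p, p):
        raise ValueError(f"{label} must be {p}x{p}, got {m.shape}")
    if not np.allclose(m, m.T, atol=1e-12):
        raise ValueError(f"{label} not symmetric")
    if not np.allclose(np.diag(m), 1.0, atol=1e-12):
        raise ValueError(f"{label} diagonal must be 1")
    if np.abs(m).max() > 1 + 1e-12:
        raise ValueError(f"{label} has entries outside [-1, 1]")
    if np.linalg.eigvalsh(m).min() < -1e-8:
        raise ValueError(f"{label} is not positive semi-definite")
    return m


@dataclass
class SimConfig:
    """Full specification of a simulated twin cohort."""

    n_mz_pairs: int
    n_dz_pairs: int
    traits: list[TraitSpec]
    rA: np.ndarray | None = None
    rC: np.ndarray | None = None
    rE: np.ndarray | None = None
    seed: int = 0
    wave_retention: float = 1.0
    sex_ratio: float = 0.5  # probability of sex code 1 (female)
    age_mean: float = 18.0
    age_sd: float = 0.3
    unknown_zygosity_rate: float = 0.0
    item_missingness: float = 0.0

    def __post_init__(self) -> None:
        p = len(self.traits)
        names = [t.name for t in self.traits]
        if len(set(names)) != p:
            raise ValueError("duplicate trait names")
        for attr in ("rA", "rC", "rE"):
            m = getattr(self, attr)
            if m is None:
                m = np.eye(p)
            setattr(self, attr, _as_corr(m, p, attr))
        if not (0.0 < self.wave_retention <= 1.0):
            raise ValueError("wave_retention must be in (0, 1]")
        if not (0.0 <= self.unknown_zygosity_rate < 1.0):
            raise ValueError("unknown_zygosity_rate must be in [0, 1)")

    @property
    def trait_names(self) -> list[str]:
        return [t.name for t in self.traits]


def implied_pair_correlation(config: SimConfig, zygosity: str) -> np.ndarray:
    """Generating 2p x 2p liability correlation over (twin1 traits, twin2 traits)."""
    p = len(config.traits)
    paths = np.array([t.paths for t in config.traits])  # (p, 3) columns a, c, e
    a, c, e = paths[:, 0], paths[:, 1], paths[:, 2]
    k_a = 1.0 if zygosity == "MZ" else 0.5
    within = (
        config.rA * np.outer(a, a)
        + config.rC * np.outer(c, c)
        + config.rE * np.outer(e, e)
    )
    cross = k_a * config.rA * np.outer(a, a) + config.rC * np.outer(c, c)
    full = np.block([[within, cross], [cross.T, within]])
    eig = np.linalg.eigvalsh(full)
    if eig.min() < -1e-8:
        raise ValueError(
            f"implied {zygosity} liability correlation matrix is not PSD "
            f"(min eigenvalue {eig.min():.3g}); check rA/rC/rE and variance shares"
        )
    return full


def _observed_from_liability(
    liab: np.ndarray, trait: TraitSpec
) -> np.ndarray:
    if trait.kind == "continuous":
        if trait.skew:
            # affine rescale of exp(s*L) uses the theoretical log-normal
            # moments so the map is fixed, not re-estimated per batch
            s2 = trait.skew**2
            mu = np.exp(s2 / 2.0)
            sd = mu * np.sqrt(np.expm1(s2))
            raw = np.exp(trait.skew * liab)
            return np.maximum((raw - mu) / sd * trait.score_sd + trait.score_mean, 0.0)
        return liab
    th = np.asarray(trait.thresholds, float)
    return np.searchsorted(th, liab, side="left").astype(float)


def simulate_twin_cohort(config: SimConfig) -> pd.DataFrame:
    """Draw a twin cohort from the liability ACE model in ``config``.

    Returns a long-format DataFrame: one row per individual per wave, with
    the wave's trait columns filled and the other wave's traits missing.
    Reproducible for a fixed ``config.seed``.
    """
    ss = np.random.SeedSequence(config.seed)
    s_liab, s_cov, s_zyg, s_miss = [np.random.default_rng(c) for c in ss.spawn(4)]

    p = len(config.traits)
    blocks = []
    fam_offset = 0
    for zyg, n in (("MZ", config.n_mz_pairs), ("DZ", config.n_dz_pairs)):
        if n == 0:
            continue
        corr = implied_pair_correlation(config, zyg)
        # eigh tolerates the PSD-singular structures (e.g. rA = 1) that
        # cholesky would reject
        liab = s_liab.multivariate_normal(
            np.zeros(2 * p), corr, size=n, method="eigh"
        )
        fam = np.arange(fam_offset, fam_offset + n)
        fam_offset += n
        blocks.append((zyg, fam, liab))

    n_pairs = fam_offset
    sex_pair = (s_cov.random(n_pairs) < config.sex_ratio).astype(int)
    age_pair = s_cov.normal(config.age_mean, config.age_sd, size=n_pairs)
    relabel = s_zyg.random(n_pairs) < config.unknown_zygosity_rate

    waves = sorted({t.wave for t in config.traits})
    rows = []
    for zyg, fam, liab in blocks:
        sex = sex_pair[fam]
        age0 = age_pair[fam]
        zyg_lab = np.where(relabel[fam], "unknown", zyg)
        for twin in (1, 2):
            for wi, wave in enumerate(waves):
                rec = {
                    "family_id": fam,
                    "twin_index": twin,
                    "zygosity": zyg_lab,
                    "sex": sex,
                    "age": age0 + (wave - waves[0]),
                    "wave": wave,
                }
                for j, trait in enumerate(config.traits):
                    col = liab[:, (twin - 1) * p + j].copy()
                    col += trait.sex_effect * (sex - config.sex_ratio)
                    col += trait.age_effect * (age0 - config.age_mean)
                    obs = _observed_from_liability(col, trait)
                    rec[trait.name] = np.where(trait.wave == wave, obs, np.nan)
                rows.append(pd.DataFrame(rec))
    data = pd.concat(rows, ignore_index=True)
    data = data.sort_values(["family_id", "wave", "twin_index"]).reset_index(drop=True)

    if config.item_missingness > 0:
        for trait in config.traits:
            drop = s_miss.random(len(data)) < config.item_missingness
            data.loc[drop, trait.name] = np.nan

    if config.wave_retention < 1.0 and len(waves) > 1:
        data = apply_attrition(
            data,
            config.wave_retention,
            seed=ss.spawn(1)[0].generate_state(1)[0] % (2**31),
            followup_wave=waves[-1],
        )
    return data


def apply_attrition(
    data: pd.DataFrame,
    retention: float,
    seed: int,
    followup_wave: int = 24,
) -> pd.DataFrame:
    """Drop follow-up-wave rows pairwise (both co-twins together).

    Each family keeps its follow-up rows with probability ``retention``;
    baseline rows are never touched.  Attrition is pairwise: the registry
    follow-up questionnaire is assumed mailed per household.
    """
    if not (0.0 < retention <= 1.0):
        raise ValueError("retention must be in (0, 1]")
    if retention == 1.0:
        return data.copy()
    rng = np.random.default_rng(seed)
    fams = np.sort(data["family_id"].unique())
    keep = pd.Series(rng.random(fams.size) < retention, index=fams)
    is_follow = data["wave"] == followup_wave
    mask = ~is_follow | data["family_id"].map(keep).to_numpy()
    return data.loc[mask].reset_index(drop=True)


# ---------------------------------------------------------------------------
# I/O

def write_cohort(data: pd.DataFrame, path) -> None:
    """Write the cohort CSV with the fixed header and MZ/DZ/unknown coding."""
    traits = [c for c in data.columns if c not in BASE_COLUMNS]
    data[BASE_COLUMNS + traits].to_csv(path, index=False, float_format="%.10g")


def read_cohort(path) -> pd.DataFrame:
    data = pd.read_csv(path)
    missing = [c for c in BASE_COLUMNS if c not in data.columns]
    if missing:
        raise ValueError(f"cohort file lacks required columns: {missing}")
    bad = set(data["zygosity"].unique()) - set(ZYGOSITY_CODES)
    if bad:
        raise ValueError(f"unknown zygosity codes: {sorted(bad)}")
    return data


def save_config(config: SimConfig, path) -> None:
    d = dataclasses.asdict(config)
    d["traits"] = [dataclasses.asdict(t) for t in config.traits]
    for t in d["traits"]:
        t["thresholds"] = [float(x) for x in t["thresholds"]]
    for key in ("rA", "rC", "rE"):
        d[key] = np.asarray(d[key]).tolist()
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def load_config(path) -> SimConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    d["traits"] = [
        TraitSpec(**{**t, "thresholds": tuple(t.get("thresholds", ()))})
        for t in d["traits"]
    ]
    return SimConfig(**d)


def default_cohort_config(
    n_mz_pairs: int = 1350,
    n_dz_pairs: int = 3100,
    seed: int = 0,
) -> SimConfig:
    """Cohort emulating the study population this package targets.

    Two waves (ages 18 and 24).  At 18: a skewed continuous total OCS score
    (heritability 37%), a binary suicide-attempt item at 6% prevalence
    (heritability 61%), and continuous depression/anxiety scores.  At 24: a
    skewed continuous OCS score (38%), binary suicidal ideation (24.2%) and
    attempt (5.3%) items, and a continuous depression score.  Aetiological
    correlations follow the reported bivariate estimates (rA = .42 / rE = .13
    between OCS and attempts at 18; rA = .37 / rE = .29 between OCS and
    suicidality at 24) with plausible within-construct stability values
    elsewhere.  ~30% of pairs are MZ, ~3% relabelled unknown, and pairwise
    follow-up retention is 25%.
    """
    traits = [
        TraitSpec("ocs_total_18", a2=0.37, e2=0.63, wave=18, skew=0.8,
                  score_mean=1.82, score_sd=2.24),
        TraitSpec.binary_from_prevalence("suicide_attempt_18", 0.06,
                                         a2=0.61, e2=0.39, wave=18),
        TraitSpec("depression_18", a2=0.40, e2=0.60, wave=18, skew=0.6,
                  score_mean=8.46, score_sd=6.02),
        TraitSpec("anxiety_18", a2=0.40, e2=0.60, wave=18, skew=0.6,
                  score_mean=15.93, score_sd=11.45),
        TraitSpec("ocs_total_24", a2=0.38, e2=0.62, wave=24, skew=0.8,
                  score_mean=8.01, score_sd=6.99),
        TraitSpec.binary_from_prevalence("ideation_24", 0.242,
                                         a2=0.49, e2=0.51, wave=24),
        TraitSpec.binary_from_prevalence("attempt_24", 0.053,
                                         a2=0.49, e2=0.51, wave=24),
        TraitSpec("depression_24", a2=0.40, e2=0.60, wave=24, skew=0.6,
                  score_mean=5.26, score_sd=3.57),
    ]
    #           ocs18 att18 dep18 anx18 ocs24 ide24 att24 dep24
    rA = np.array([
        [1.00, 0.42, 0.45, 0.45, 0.60, 0.35, 0.35, 0.40],  # ocs18
        [0.42, 1.00, 0.50, 0.40, 0.40, 0.60, 0.60, 0.45],  # att18
        [0.45, 0.50, 1.00, 0.60, 0.40, 0.50, 0.50, 0.65],  # dep18
        [0.45, 0.40, 0.60, 1.00, 0.40, 0.40, 0.40, 0.55],  # anx18
        [0.60, 0.40, 0.40, 0.40, 1.00, 0.37, 0.37, 0.45],  # ocs24
        [0.35, 0.60, 0.50, 0.40, 0.37, 1.00, 0.75, 0.55],  # ide24
        [0.35, 0.60, 0.50, 0.40, 0.37, 0.75, 1.00, 0.55],  # att24
        [0.40, 0.45, 0.65, 0.55, 0.45, 0.55, 0.55, 1.00],  # dep24
    ])
    rE = np.array([
        [1.00, 0.13, 0.25, 0.25, 0.35, 0.10, 0.10, 0.20],
        [0.13, 1.00, 0.25, 0.20, 0.10, 0.25, 0.25, 0.20],
        [0.25, 0.25, 1.00, 0.40, 0.20, 0.25, 0.25, 0.35],
        [0.25, 0.20, 0.40, 1.00, 0.20, 0.20, 0.20, 0.30],
        [0.35, 0.10, 0.20, 0.20, 1.00, 0.29, 0.29, 0.25],
        [0.10, 0.25, 0.25, 0.20, 0.29, 1.00, 0.45, 0.30],
        [0.10, 0.25, 0.25, 0.20, 0.29, 0.45, 1.00, 0.30],
        [0.20, 0.20, 0.35, 0.30, 0.25, 0.30, 0.30, 1.00],
    ])
    return SimConfig(
        n_mz_pairs=n_mz_pairs,
        n_dz_pairs=n_dz_pairs,
        traits=traits,
        rA=rA,
        rE=rE,
        seed=seed,
        wave_retention=0.25,
        sex_ratio=0.588,
        unknown_zygosity_rate=0.03,
    )
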