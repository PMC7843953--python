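"""End-to-end analysis pipeline on a twin cohort.

Runs the full analysis sequence: schema validation, score transforms and
composite coding, tiered cluster-robust logistic regressions
(cross-sectional at each wave, then prospective), latent-scale correlation
screening, and — for trait pairs passing the correlation gate — bivariate
twin-model decomposition with the ACE -> AE reduction rule, plus an
optional trivariate prospective model.  Output is a ReportBundle of
regression tables, decomposition tables and a run log, serializable to a
deterministic JSON document.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import phenotypic as ph
from .fitting import (
    FitOptions,
    decompose_correlation,
    fit_trivariate_prospective,
    fit_with_ae_reduction,
)
from .structure import TraitDef

__all__ = ["AnalysisPlan", "ReportBundle", "validate_schema", "run_pipeline"]


@dataclass
class AnalysisPlan:
    """Which stages to run, on which columns, with which adjustment tiers."""

    outcome_18: str = "suicide_attempt_18"
    ocs_18: str = "ocs_total_18"
    ideation_24: str = "ideation_24"
    attempt_24: str = "attempt_24"
    ocs_24: str = "ocs_total_24"
    depression_18: str = "depression_18"
    anxiety_18: str = "anxiety_18"
    depression_24: str = "depression_24"
    anxiety_24: str | None = None
    subscales_18: tuple = ()
    subscales_24: tuple = ()
    stages: tuple = (
        "cross_sectional_18",
        "cross_sectional_24",
        "prospective",
        "bivariate_twin",
        "trivariate",
    )
    gate_threshold: float = 0.2
    prevalence_18: float | None = None  # binary outcome threshold placement
    with_ci: bool = False
    n_starts: int = 2
    seed: int = 0

    def fit_options(self) -> FitOptions:
        return FitOptions(n_starts=self.n_starts, start_seed=1234 + self.seed)


@dataclass
class ReportBundle:
    tables: dict = field(default_factory=dict)  # name -> DataFrame
    twin_models: dict = field(default_factory=dict)  # name -> dict
    log: list = field(default_factory=list)
    issues: list = field(default_factory=list)
    seed: int = 0

    def to_json(self) -> str:
        doc = {
            "seed": self.seed,
            "log": self.log,
            "issues": self.issues,
            "tables": {
                k: json.loads(v.to_json(orient="records", double_precision=15))
                for k, v in self.tables.items()
            },
            "twin_models": self.twin_models,
        }
        return json.dumps(doc, indent=1, sort_keys=True)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, tab in self.tables.items():
            tab.to_csv(out / f"{name}.csv", index=False)
        (out / "bundle.json").write_text(self.to_json())
        (out / "run.log").write_text("\n".join(self.log) + "\n")


def validate_schema(data: pd.DataFrame) -> list[dict]:
    """Machine-readable structural checks on a cohort table (report-only)."""
    issues = []
    required = ["family_id", "twin_index", "zygosity", "sex", "age", "wave"]
    for col in required:
        if col not in data.columns:
            issues.append({"issue": "missing_column", "column": col})
    if issues:
        return issues
    bad_zyg = set(data["zygosity"].unique()) - {"MZ", "DZ", "unknown"}
    if bad_zyg:
        issues.append({"issue": "bad_zygosity_codes", "values": sorted(bad_zyg)})
    bad_twin = set(data["twin_index"].unique()) - {1, 2}
    if bad_twin:
        issues.append({"issue": "bad_twin_index", "values": sorted(bad_twin)})
    sizes = data.groupby(["family_id", "wave"]).size()
    over = sizes[sizes > 2]
    for (fam, wave), cnt in over.items():
        issues.append(
            {"issue": "family_exceeds_two_rows", "family_id": int(fam),
             "wave": int(wave), "rows": int(cnt)}
        )
    dup = data.duplicated(["family_id", "twin_index", "wave"])
    if dup.any():
        issues.append(
            {"issue": "duplicated_individual_wave",
             "count": int(dup.sum())}
        )
    zyg_n = data.groupby("family_id")["zygosity"].nunique()
    for fam in zyg_n[zyg_n > 1].index:
        issues.append({"issue": "zygosity_mismatch_within_family", "family_id": int(fam)})
    return issues


def _tiered_regressions(data, outcome, predictors, tiers, bundle, table_name):
    rows = []
    results = []
    for label, covs in tiers:
        covs = [c for c in covs if c is not None and c in data.columns]
        try:
            res = ph.cluster_robust_logistic(
                data, outcome, predictors, covariates=covs, adjustment_label=label
            )
        except Exception as exc:  # stage failure: record, keep going
            bundle.log.append(f"{table_name} [{label}] failed: {exc}")
            continue
        results.append(res)
        frame = res.to_frame()
        frame = frame[~frame["term"].isin(["intercept", "age_z", "sex"])]
        rows.append(frame)
    if rows:
        bundle.tables[table_name] = pd.concat(rows, ignore_index=True)
        bundle.log.append(
            f"{table_name}: {len(rows)} adjustment tiers "
            f"(n = {', '.join(str(r.n_obs) for r in results)})"
        )


def _prep_wave(data, wave, plan, bundle):
    """One row per individual at the given wave, with derived columns."""
    sub = data[data["wave"] == wave].copy()
    for col in sub.columns:
        if col in (plan.ocs_18, plan.ocs_24, plan.depression_18, plan.anxiety_18,
                   plan.depression_24, plan.anxiety_24) and col in sub.columns:
            try:
                sub[col + "_z"] = ph.log_standardize(sub[col])
            except ValueError as exc:
                bundle.log.append(f"transform of {col} failed: {exc}")
    sub["age_z"] = sub["age"] - sub["age"].mean()
    return sub


def run_pipeline(data: pd.DataFrame, plan: AnalysisPlan | None = None) -> ReportBundle:
    """Execute the analysis plan; independent stages survive each other's
    failures.  Deterministic given the plan's seed."""
    plan = plan or AnalysisPlan()
    bundle = ReportBundle(seed=plan.seed)
    bundle.issues = validate_schema(data)
    if any(i["issue"] == "missing_column" for i in bundle.issues):
        bundle.log.append("schema validation failed; aborting")
        return bundle
    bundle.log.append(f"schema validation: {len(bundle.issues)} issue(s)")

    n_unknown = (data["zygosity"] == "unknown").sum()
    bundle.log.append(
        f"rows: {len(data)}; unknown-zygosity rows excluded from twin models: {n_unknown}"
    )

    d18 = _prep_wave(data, 18, plan, bundle)
    d24 = _prep_wave(data, 24, plan, bundle) if (data["wave"] == 24).any() else None

    if d24 is not None and plan.ideation_24 in d24.columns:
        d24["suicidality_24"] = ph.composite_suicidality(
            d24[plan.ideation_24], d24.get(plan.attempt_24, np.nan)
        )

    base = ["age_z", "sex"]

    def _stage(name, fn):
        try:
            fn()
        except Exception as exc:
            bundle.log.append(f"{name} stage failed: {exc}")

    # -- cross-sectional, age 18
    if "cross_sectional_18" in plan.stages and plan.outcome_18 in d18.columns:
        tiers = [
            ("unadjusted", base),
            ("adj_depression", base + [plan.depression_18 + "_z"]),
            ("adj_depression_anxiety",
             base + [plan.depression_18 + "_z", plan.anxiety_18 + "_z"]),
        ]
        _tiered_regressions(
            d18, plan.outcome_18, [plan.ocs_18 + "_z"], tiers, bundle,
            "cross_sectional_18",
        )
        if plan.subscales_18:
            _tiered_regressions(
                d18, plan.outcome_18, list(plan.subscales_18), tiers, bundle,
                "subscales_18",
            )

    # -- cross-sectional, age 24
    if (
        "cross_sectional_24" in plan.stages
        and d24 is not None
        and "suicidality_24" in d24.columns
        and plan.ocs_24 + "_z" in d24.columns
    ):
        dep24 = plan.depression_24 + "_z" if plan.depression_24 else None
        anx24 = plan.anxiety_24 + "_z" if plan.anxiety_24 else None
        tiers = [("unadjusted", base), ("adj_depression", base + [dep24])]
        if anx24:
            tiers.append(("adj_depression_anxiety", base + [dep24, anx24]))
        _tiered_regressions(
            d24, "suicidality_24", [plan.ocs_24 + "_z"], tiers, bundle,
            "cross_sectional_24",
        )
        if plan.subscales_24:
            _tiered_regressions(
                d24, "suicidality_24", list(plan.subscales_24), tiers, bundle,
                "subscales_24",
            )

    # -- prospective: OCS 18 -> suicidality 24, only pairs retained at 24
    def _prospective():
        pred18 = d18.set_index(["family_id", "twin_index"])
        keep = [c for c in [plan.ocs_18 + "_z", plan.outcome_18,
                            plan.depression_18 + "_z", plan.anxiety_18 + "_z"]
                if c in pred18.columns]
        base24 = d24.drop(columns=[c for c in keep if c in d24.columns])
        merged = base24.join(pred18[keep], on=["family_id", "twin_index"])
        tiers = [
            ("unadjusted", base),
            ("adj_baseline_attempts", base + [plan.outcome_18]),
            ("adj_attempts_depression",
             base + [plan.outcome_18, plan.depression_18 + "_z"]),
            ("adj_attempts_depression_anxiety",
             base + [plan.outcome_18, plan.depression_18 + "_z",
                     plan.anxiety_18 + "_z"]),
        ]
        _tiered_regressions(
            merged, "suicidality_24", [plan.ocs_18 + "_z"], tiers, bundle,
            "prospective",
        )

    if "prospective" in plan.stages and d24 is not None and "suicidality_24" in d24.columns:
        _stage("prospective", _prospective)

    # -- twin models behind the latent correlation gate
    if "bivariate_twin" in plan.stages:
        _bivariate_stage(data, d18, plan, bundle)
    if "trivariate" in plan.stages and d24 is not None:
        _trivariate_stage(data, plan, bundle)
    return bundle


def _latent_gate_corr(d18, cont_col, bin_col, bundle):
    try:
        return ph.polyserial(d18[cont_col], d18[bin_col])
    except Exception as exc:
        bundle.log.append(f"gate correlation {cont_col}~{bin_col} failed: {exc}")
        return 0.0


def _binary_traitdef(name):
    return TraitDef(name, "ordinal", 2)


def _ace_reduction(traits, pairs_or_data, options, bundle, label):
    """ACE fit with the AE reduction rule, logged."""
    chosen, fit_ace, comparison = fit_with_ae_reduction(
        traits, pairs_or_data, options
    )
    shares = [fit_ace.quantity(f"c2:{t.name}") for t in traits]
    bundle.log.append(
        f"{label}: ACE -2LL={fit_ace.minus2LL:.2f}; "
        f"max C share={max(shares):.3f}; final={chosen.param.components}"
    )
    return chosen, fit_ace, comparison


def _bivariate_stage(data, d18, plan, bundle):
    cont, binary = plan.ocs_18, plan.outcome_18
    if cont not in data.columns or binary not in data.columns:
        return
    try:
        zcol = cont + "_z"
        r_gate = _latent_gate_corr(d18, zcol if zcol in d18.columns else cont,
                                   binary, bundle)
        bundle.log.append(
            f"bivariate gate: polyserial({cont}, {binary}) = {r_gate:.3f} "
            f"(threshold {plan.gate_threshold})"
        )
        if abs(r_gate) <= plan.gate_threshold:
            bundle.twin_models["bivariate_18"] = {
                "gate_correlation": r_gate,
                "triggered": False,
            }
            return
        work = data.copy()
        work[cont] = _log_std_within_wave(work, cont)
        traits = [TraitDef(cont, "continuous"), _binary_traitdef(binary)]
        options = plan.fit_options()
        chosen, fit_ace, comparison = _ace_reduction(
            traits, work, options, bundle, "bivariate_18"
        )
        dec = decompose_correlation(chosen, with_ci=plan.with_ci)
        bundle.twin_models["bivariate_18"] = {
            "gate_correlation": r_gate,
            "triggered": True,
            "final_components": chosen.param.components,
            "minus2LL": chosen.minus2LL,
            "AIC": chosen.aic,
            "n_pairs": chosen.n_pairs,
            "estimates": {k: float(v) for k, v in chosen.estimates.items()},
            "decomposition": dec.as_dict(),
            "comparison": comparison.as_dict() if comparison else None,
        }
    except Exception as exc:
        bundle.log.append(f"bivariate_twin stage failed: {exc}")


def _trivariate_stage(data, plan, bundle):
    cols = (plan.outcome_18, plan.ocs_18, plan.ideation_24)
    if not all(c in data.columns for c in cols):
        return
    try:
        work = data.copy()
        work[plan.ocs_18] = _log_std_within_wave(work, plan.ocs_18)
        d24 = work[work["wave"] == 24].copy()
        d24["suicidality_24"] = ph.composite_suicidality(
            d24[plan.ideation_24], d24.get(plan.attempt_24, np.nan)
        )
        work = pd.concat([work[work["wave"] == 18], d24], ignore_index=True)
        traits = [
            _binary_traitdef(plan.outcome_18),
            TraitDef(plan.ocs_18, "continuous"),
            _binary_traitdef("suicidality_24"),
        ]
        fit, dec = fit_trivariate_prospective(
            work, traits, components="AE", options=plan.fit_options()
        )
        bundle.twin_models["trivariate_prospective"] = {
            "minus2LL": fit.minus2LL,
            "AIC": fit.aic,
            "converged": fit.converged,
            "estimates": {k: float(v) for k, v in fit.estimates.items()},
            "unique_association": {
                k: (v if not isinstance(v, dict) else v)
                for k, v in dec.items()
            },
        }
        bundle.log.append(
            f"trivariate: unique %A = {dec.get('pctA_unique', float('nan')):.1f}"
        )
    except Exception as exc:
        bundle.log.append(f"trivariate stage failed: {exc}")


def _log_std_within_wave(data, col):
    out = np.full(len(data), np.nan)
    for wave, idx in data.groupby("wave").groups.items():
        vals = data.loc[idx, col]
        if vals.notna().any():
            out[data.index.get_indexer(idx)] = ph.log_standardize(vals)
    return out
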