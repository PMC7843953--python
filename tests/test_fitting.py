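"""Model fitting, comparison, profile CIs and decomposition."""

import numpy as np
import pytest
from scipy.stats import chi2

from twinace.fitting import (
    CholeskyParam,
    CorrelatedFactorsParam,
    FitOptions,
    compare_models,
    decompose_correlation,
    fit_model,
    fit_trivariate_prospective,
    path_variance_pct,
    profile_ci,
)
from twinace.likelihood import fiml_loglik
from twinace.simulate import SimConfig, TraitSpec, simulate_twin_cohort
from twinace.structure import TraitDef

from conftest import bivariate_config, BIV_TRAITS

FAST = FitOptions(n_starts=2)


def test_path_variance_rule():
    # squaring a standardized path gives its variance percentage
    assert round(path_variance_pct(0.61)) == 37


def test_null_recovery_e_only_data():
    tr = [TraitSpec("x", e2=1.0)]
    data = simulate_twin_cohort(SimConfig(800, 800, tr, seed=42))
    param = CorrelatedFactorsParam([TraitDef("x")], "ACE")
    fit = fit_model(param, data, FAST)
    assert fit.converged
    assert fit.quantity("a2:x") < 0.05
    assert fit.quantity("c2:x") < 0.05
    ci = profile_ci(fit, "a2:x")
    assert ci.contains(0.0) and ci.truncated_lower and ci.lower == 0.0


def test_continuous_bivariate_minus2ll_matches_gaussian_oracle():
    """For all-continuous data the fitted -2LL equals the closed-form
    multivariate-normal value at the same parameters."""
    from scipy.stats import multivariate_normal as mvn
    from twinace.structure import implied_structure

    tr = [TraitSpec("x", a2=0.4, e2=0.6), TraitSpec("y", a2=0.5, e2=0.5)]
    rA = np.array([[1, 0.6], [0.6, 1]])
    data = simulate_twin_cohort(SimConfig(500, 500, tr, rA=rA, seed=3))
    param = CorrelatedFactorsParam(
        [TraitDef("x"), TraitDef("y")], "AE"
    )
    fit = fit_model(param, data, FAST)
    model = fit.model
    ref = 0.0
    for zyg in ("MZ", "DZ"):
        S = implied_structure(model, zyg)
        ref += mvn(np.zeros(4), S).logpdf(
            fit.pairs.y[fit.pairs.zygosity == zyg]
        ).sum()
    assert fit.minus2LL == pytest.approx(-2 * ref, abs=1e-6)
    # optimizer sanity: fitted -2LL no worse than at the generating values
    gen = param.model(fit.theta)  # structure only; rebuild at generating values
    gen.paths = {"A": np.sqrt([0.4, 0.5]), "E": np.sqrt([0.6, 0.5])}
    gen.corr = {"A": rA, "E": np.eye(2)}
    assert fit.minus2LL <= -2 * fiml_loglik(gen, fit.pairs) + 1e-6


def test_bivariate_recovery_and_decomposition(big_bivariate_fit):
    """The 20k+20k-pair fit at the generating values recovers rA ~ 0.42 and
    the genetic share of the phenotypic correlation ~ 74.6%."""
    fit = big_bivariate_fit
    assert fit.quantity("rA") == pytest.approx(0.42, abs=0.05)
    assert fit.quantity("a2:ocs") == pytest.approx(0.37, abs=0.03)
    assert fit.quantity("a2:att") == pytest.approx(0.61, abs=0.05)
    dec = decompose_correlation(fit)
    assert dec.pctA == pytest.approx(74.6, abs=8.0)
    assert dec.pctA + dec.pctC + dec.pctE == pytest.approx(100.0, abs=1e-6)
    assert dec.rPh == pytest.approx(0.26, abs=0.02)


def test_decomposition_single_component_is_100_percent():
    param = CorrelatedFactorsParam(BIV_TRAITS, "AE")
    data = simulate_twin_cohort(bivariate_config(400, 400, seed=77))
    fit = fit_model(param, data, FAST)
    # force rE to zero by zeroing its unconstrained coordinate
    fit.theta[param.labels.index("zE")] = 0.0
    dec = decompose_correlation(fit)
    assert dec.pctA == pytest.approx(100.0, abs=1e-9)


def test_decomposition_shares_sum_to_100_for_random_fits():
    rng = np.random.default_rng(0)
    param = CorrelatedFactorsParam(BIV_TRAITS, "ACE")
    data = simulate_twin_cohort(bivariate_config(300, 300, seed=5))
    fit = fit_model(param, data, FitOptions(n_starts=1))
    for _ in range(20):
        fit.theta = rng.normal(0, 0.8, param.k)
        try:
            dec = decompose_correlation(fit)
        except ZeroDivisionError:
            continue
        assert dec.pctA + dec.pctC + dec.pctE == pytest.approx(100.0, abs=1e-6)


def test_zero_phenotypic_correlation_decomposition_errors():
    param = CorrelatedFactorsParam(BIV_TRAITS, "AE")
    data = simulate_twin_cohort(bivariate_config(300, 300, seed=6))
    fit = fit_model(param, data, FitOptions(n_starts=1))
    fit.theta[param.labels.index("zA")] = 0.0
    fit.theta[param.labels.index("zE")] = 0.0
    with pytest.raises(ZeroDivisionError):
        decompose_correlation(fit)


def test_compare_models_chi_square_and_rules():
    param_full = CorrelatedFactorsParam([TraitDef("x")], "ACE")
    param_nested = CorrelatedFactorsParam([TraitDef("x")], "AE")
    mk = lambda p, m2ll: type(
        "F", (), {"param": p, "minus2LL": m2ll, "k": p.k, "aic": m2ll + 2 * p.k}
    )()
    full, nested = mk(param_full, 100.0), mk(param_nested, 105.0)
    cmp = compare_models(full, nested)
    assert cmp.delta_df == 1
    assert cmp.p_value == pytest.approx(0.0253, abs=5e-4)  # chi2(1) tail at 5.0
    assert cmp.p_value == pytest.approx(float(chi2.sf(5.0, 1)), abs=1e-12)

    same = compare_models(mk(param_full, 100.0), mk(param_full, 100.0))
    assert same.delta_minus2LL == 0.0 and same.preferred == "nested"

    with pytest.raises(ValueError, match="not nested"):
        compare_models(nested, full)


def test_ae_preferred_when_no_shared_environment():
    """On data generated without C, the AE reduction is accepted in a
    majority of replicates."""
    wins = 0
    seeds = range(20)
    for s in seeds:
        tr = [TraitSpec("x", a2=0.5, e2=0.5)]
        data = simulate_twin_cohort(SimConfig(250, 250, tr, seed=1000 + s))
        ace = fit_model(CorrelatedFactorsParam([TraitDef("x")], "ACE"), data,
                        FitOptions(n_starts=1))
        ae = fit_model(CorrelatedFactorsParam([TraitDef("x")], "AE"), data,
                       FitOptions(n_starts=1))
        if compare_models(ace, ae).preferred == "nested":
            wins += 1
    assert wins > len(seeds) / 2


def test_profile_ci_quadratic_limit():
    """For a Gaussian mean the likelihood is exactly quadratic, so the
    profile CI must match the Wald interval from the numerical Hessian."""
    from statsmodels.tools.numdiff import approx_hess1

    tr = [TraitSpec("x", a2=0.4, e2=0.6)]
    data = simulate_twin_cohort(SimConfig(200, 200, tr, seed=21))
    data["x"] = data["x"] + 3.0  # non-trivial mean
    param = CorrelatedFactorsParam([TraitDef("x")], "AE", standardized=False)
    fit = fit_model(param, data, FAST)
    ci = profile_ci(fit, "mean:x")

    idx = param.labels.index("mean:x")
    obj = lambda th: -2 * fiml_loglik(param.model(th), fit.pairs)
    H = approx_hess1(fit.theta, obj)
    se = np.sqrt(2.0 * np.linalg.inv(H)[idx, idx])
    mu = fit.quantity("mean:x")
    assert ci.lower == pytest.approx(mu - 1.96 * se, abs=2e-3)
    assert ci.upper == pytest.approx(mu + 1.96 * se, abs=2e-3)


def test_profile_ci_coverage_scaled_replicates():
    """~95% profile CIs for the heritability cover the generating value in
    at least 90% of scaled-down replicates (deterministic seed set)."""
    hits, total = 0, 24
    for s in range(total):
        tr = [TraitSpec("x", a2=0.4, e2=0.6)]
        data = simulate_twin_cohort(SimConfig(150, 150, tr, seed=3000 + s))
        fit = fit_model(CorrelatedFactorsParam([TraitDef("x")], "AE"), data,
                        FitOptions(n_starts=1))
        if not fit.converged:
            continue
        ci = profile_ci(fit, "a2:x")
        hits += ci.contains(0.4)
    assert hits / total >= 0.9


def test_trivariate_null_unique_path_and_normalization():
    """With no unique OCS->follow-up channel in the generating model, the
    fitted unique covariance is near zero; %A + %E of the unique channel
    always normalizes to 100."""
    # generating model: trait 3 depends on trait 1's factors only
    a2 = [0.6, 0.4, 0.5]
    e2 = [1 - v for v in a2]
    rA = np.array([[1, 0.45, 0.70], [0.45, 1, 0.45 * 0.70], [0.70, 0.315, 1]])
    rE = np.array([[1, 0.25, 0.40], [0.25, 1, 0.25 * 0.40], [0.40, 0.10, 1]])
    # rA[1,2] = rA[0,1]*rA[0,2]: trait-2/trait-3 genetic overlap runs
    # entirely through trait 1, so the unique channel is null
    tr = [
        TraitSpec.binary_from_prevalence("s18", 0.10, a2=a2[0], e2=e2[0], wave=18),
        TraitSpec.binary_from_prevalence("ocs", 0.30, a2=a2[1], e2=e2[1], wave=18),
        TraitSpec.binary_from_prevalence("s24", 0.25, a2=a2[2], e2=e2[2], wave=24),
    ]
    data = simulate_twin_cohort(SimConfig(1500, 1500, tr, rA=rA, rE=rE, seed=17))
    traits = [TraitDef(n, "ordinal") for n in ("s18", "ocs", "s24")]
    fit, dec = fit_trivariate_prospective(
        data, traits, options=FitOptions(n_starts=1)
    )
    assert fit.converged
    assert abs(dec["cov_unique_total"]) < 0.08
    assert dec["pctA_unique"] + dec["pctE_unique"] == pytest.approx(100.0, abs=1e-6)
    # follow-up paths from trait 1's factors are substantial by contrast
    assert abs(fit.quantity("path:A:2:0")) > abs(fit.quantity("path:A:2:1"))


def test_fit_refuses_insufficient_pairs():
    tr = [TraitSpec("x", e2=1.0)]
    data = simulate_twin_cohort(SimConfig(5, 30, tr, seed=1))
    with pytest.raises(ValueError, match="pairs"):
        fit_model(CorrelatedFactorsParam([TraitDef("x")], "AE"), data, FAST)


def test_fit_result_json_roundtrip(tmp_path):
    tr = [TraitSpec("x", a2=0.4, e2=0.6)]
    data = simulate_twin_cohort(SimConfig(150, 150, tr, seed=9))
    fit = fit_model(CorrelatedFactorsParam([TraitDef("x")], "AE"), data,
                    FitOptions(n_starts=1))
    import json

    doc = json.loads(fit.to_json(tmp_path / "fit.json"))
    assert doc["AIC"] == pytest.approx(fit.minus2LL + 2 * fit.k)
    assert doc["estimates"]["a2:x"] == pytest.approx(fit.quantity("a2:x"))
    assert (tmp_path / "fit.json").exists()
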