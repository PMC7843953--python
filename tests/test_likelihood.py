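"""FIML likelihood against closed-form and Monte-Carlo oracles."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal as mvn

from twinace.likelihood import build_pair_table, fiml_loglik
from twinace.simulate import SimConfig, TraitSpec, simulate_twin_cohort
from twinace.structure import PathModel, TraitDef, implied_structure

from conftest import bivariate_config, BIV_TRAITS


def _pairs_for(data, traits):
    from types import SimpleNamespace

    return build_pair_table(data, SimpleNamespace(traits=traits))


def test_symmetric_threshold_binary_loglik():
    """A 50%-prevalence binary trait with no twin correlation contributes
    exactly ln(1/2) per individual."""
    tr = [TraitSpec.binary_from_prevalence("b", 0.5, a2=0, c2=0, e2=1)]
    data = simulate_twin_cohort(SimConfig(60, 60, tr, seed=2))
    model = PathModel(
        traits=[TraitDef("b", "ordinal")], components="AE",
        paths={"A": np.array([0.0]), "E": np.array([1.0])},
        thresholds={"b": [0.0]},
    )
    pairs = _pairs_for(data, model.traits)
    n_obs = int((~np.isnan(pairs.y)).sum())
    assert fiml_loglik(model, pairs) == pytest.approx(n_obs * np.log(0.5), abs=1e-9)


def test_independent_bivariate_binary_factorizes():
    """With all cross correlations zero, the joint ordinal likelihood equals
    the sum of the two independent univariate likelihoods."""
    tr = [
        TraitSpec.binary_from_prevalence("u", 0.3, e2=1.0),
        TraitSpec.binary_from_prevalence("v", 0.2, e2=1.0),
    ]
    data = simulate_twin_cohort(SimConfig(150, 150, tr, seed=8))

    def uni(name, tau):
        return PathModel(
            traits=[TraitDef(name, "ordinal")], components="AE",
            paths={"A": np.array([0.0]), "E": np.array([1.0])},
            thresholds={name: [tau]},
        )

    tau_u, tau_v = tr[0].thresholds[0], tr[1].thresholds[0]
    joint = PathModel(
        traits=[TraitDef("u", "ordinal"), TraitDef("v", "ordinal")],
        components="AE",
        paths={"A": np.zeros(2), "E": np.ones(2)},
        thresholds={"u": [tau_u], "v": [tau_v]},
    )
    ll_joint = fiml_loglik(joint, _pairs_for(data, joint.traits))
    ll_u = fiml_loglik(uni("u", tau_u), _pairs_for(data, [TraitDef("u", "ordinal")]))
    ll_v = fiml_loglik(uni("v", tau_v), _pairs_for(data, [TraitDef("v", "ordinal")]))
    assert ll_joint == pytest.approx(ll_u + ll_v, abs=1e-8)


def test_continuous_fiml_matches_closed_form_gaussian():
    tr = [TraitSpec("x", a2=0.4, e2=0.6), TraitSpec("y", a2=0.3, c2=0.2, e2=0.5)]
    rA = np.array([[1, 0.5], [0.5, 1]])
    rE = np.array([[1, 0.2], [0.2, 1]])
    data = simulate_twin_cohort(SimConfig(250, 250, tr, rA=rA, rE=rE, seed=5))
    model = PathModel(
        traits=[TraitDef("x"), TraitDef("y")], components="ACE",
        paths={"A": np.sqrt([0.4, 0.3]), "C": np.sqrt([0.0, 0.2]),
               "E": np.sqrt([0.6, 0.5])},
        corr={"A": rA, "C": np.eye(2), "E": rE},
    )
    pairs = _pairs_for(data, model.traits)
    got = fiml_loglik(model, pairs)
    ref = 0.0
    for zyg in ("MZ", "DZ"):
        S = implied_structure(model, zyg)
        ref += mvn(np.zeros(4), S).logpdf(pairs.y[pairs.zygosity == zyg]).sum()
    assert got == pytest.approx(ref, abs=1e-6)


def test_mixed_pair_block_matches_monte_carlo_oracle():
    """Conditional ordinal rectangles agree with brute-force MC integration
    of the joint liability distribution (10^6 draws, 3 MC SEs)."""
    data = simulate_twin_cohort(bivariate_config(4, 4, seed=7))
    model = PathModel(
        traits=BIV_TRAITS, components="AE",
        paths={"A": np.sqrt([0.37, 0.61]), "E": np.sqrt([0.63, 0.39])},
        corr={"A": np.array([[1, 0.42], [0.42, 1]]),
              "E": np.array([[1, 0.13], [0.13, 1]])},
        thresholds={"att": [1.5548]},
    )
    pairs = _pairs_for(data, model.traits)
    got = fiml_loglik(model, pairs)

    rng = np.random.default_rng(11)
    ref, var = 0.0, 0.0
    n_draw = 1_000_000
    for i in range(pairs.n_pairs):
        S = implied_structure(model, pairs.zygosity[i])
        y = pairs.y[i]
        ci, oi = [0, 2], [1, 3]
        xc = y[ci]
        llg = mvn(np.zeros(2), S[np.ix_(ci, ci)]).logpdf(xc)
        K = S[np.ix_(oi, ci)] @ np.linalg.inv(S[np.ix_(ci, ci)])
        cm = K @ xc
        cc = S[np.ix_(oi, oi)] - K @ S[np.ix_(ci, oi)]
        draws = rng.multivariate_normal(cm, cc, size=n_draw)
        inb = np.ones(n_draw, bool)
        for jj, o in enumerate(oi):
            if int(y[o]) == 0:
                inb &= draws[:, jj] <= 1.5548
            else:
                inb &= draws[:, jj] > 1.5548
        phat = inb.mean()
        ref += llg + np.log(phat)
        var += (1 - phat) / (phat * n_draw)  # delta-method var of log(phat)
    assert got == pytest.approx(ref, abs=max(3 * np.sqrt(var), 1e-3))


def test_high_dimensional_rectangles_match_seeded_scipy():
    """All-ordinal trivariate pairs (6-D rectangles) agree with scipy's
    integrator to its tolerance."""
    tr = [
        TraitSpec.binary_from_prevalence("a", 0.3, a2=0.5, e2=0.5, wave=18),
        TraitSpec.binary_from_prevalence("b", 0.4, a2=0.4, e2=0.6, wave=18),
        TraitSpec.binary_from_prevalence("c", 0.25, a2=0.45, e2=0.55, wave=24),
    ]
    rA = np.array([[1, 0.5, 0.6], [0.5, 1, 0.4], [0.6, 0.4, 1]])
    data = simulate_twin_cohort(SimConfig(40, 40, tr, rA=rA, seed=4))
    model = PathModel(
        traits=[TraitDef(t.name, "ordinal") for t in tr], components="AE",
        paths={"A": np.sqrt([0.5, 0.4, 0.45]), "E": np.sqrt([0.5, 0.6, 0.55])},
        corr={"A": rA, "E": np.eye(3)},
        thresholds={t.name: list(t.thresholds) for t in tr},
    )
    pairs = _pairs_for(data, model.traits)
    got = fiml_loglik(model, pairs)

    ref = 0.0
    for i in range(pairs.n_pairs):
        S = implied_structure(model, pairs.zygosity[i])
        y = pairs.y[i]
        lo, hi = [], []
        for j, v in enumerate(y):
            tau = model.thresholds[model.traits[j % 3].name][0]
            (lo.append(-np.inf), hi.append(tau)) if int(v) == 0 else (
                lo.append(tau), hi.append(np.inf))
        p = mvn.cdf(np.array(hi), mean=np.zeros(6), cov=S,
                    lower_limit=np.array(lo),
                    rng=np.random.default_rng(5), abseps=1e-8, maxpts=2_000_000)
        ref += np.log(p)
    assert got == pytest.approx(ref, abs=0.05)


def test_missing_dimensions_are_marginalized():
    """Dropping one twin's values changes the contribution to exactly the
    marginal likelihood of the remaining twin."""
    tr = [TraitSpec("x", a2=0.5, e2=0.5)]
    data = simulate_twin_cohort(SimConfig(30, 30, tr, seed=6))
    model = PathModel(
        traits=[TraitDef("x")], components="AE",
        paths={"A": np.array([np.sqrt(0.5)]), "E": np.array([np.sqrt(0.5)])},
    )
    pairs = _pairs_for(data, model.traits)
    pairs.y[:, 1] = np.nan  # lose twin 2 everywhere
    got = fiml_loglik(model, pairs)
    ref = mvn(0.0, 1.0).logpdf(pairs.y[:, 0]).sum()
    assert got == pytest.approx(ref, abs=1e-9)


def test_twin_order_exchangeability():
    data = simulate_twin_cohort(bivariate_config(300, 300, seed=13))
    model = PathModel(
        traits=BIV_TRAITS, components="AE",
        paths={"A": np.sqrt([0.37, 0.61]), "E": np.sqrt([0.63, 0.39])},
        corr={"A": np.array([[1, 0.42], [0.42, 1]]),
              "E": np.array([[1, 0.13], [0.13, 1]])},
        thresholds={"att": [1.5548]},
    )
    pairs = _pairs_for(data, model.traits)
    ll = fiml_loglik(model, pairs)
    swapped = pairs.y[:, [2, 3, 0, 1]].copy()
    pairs.y = swapped
    assert fiml_loglik(model, pairs) == pytest.approx(ll, abs=1e-8)


def test_inconsistent_category_floors_with_warning():
    tr = [TraitSpec.binary_from_prevalence("b", 0.5, e2=1.0)]
    data = simulate_twin_cohort(SimConfig(30, 30, tr, seed=2))
    model = PathModel(
        traits=[TraitDef("b", "ordinal")], components="AE",
        paths={"A": np.array([0.0]), "E": np.array([1.0])},
        thresholds={"b": [9.0]},  # category 1 nearly impossible
    )
    pairs = _pairs_for(data, model.traits)
    with pytest.warns(RuntimeWarning, match="near-zero"):
        ll = fiml_loglik(model, pairs)
    assert np.isfinite(ll)
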