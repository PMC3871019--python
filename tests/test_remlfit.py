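"""Design construction and restricted-likelihood correctness."""

import numpy as np
import pandas as pd
import pytest

from maternorm import (
    DesignConfig,
    DesignError,
    FitOptions,
    ModelSpec,
    SingularModelError,
    TrueParameters,
    VarianceComponents,
    build_design,
    extend_blups,
    fit_reml,
    intercept_truth,
    restricted_loglik,
    simulate_experiment,
)
from maternorm.pedigree import Pedigree
from maternorm.remlfit import REMLEngine, encode_fixed_effects, theta_from_vc

from oracles import dense_reml_m2ll, dense_single_trait_m2ll

VC_INTERCEPT = VarianceComponents(
    sigma2_e1=18.0, sigma2_e2=824.0, sigma2_int=789.0, sigma2_v=35.0,
    cov_int_v=78.1, sigma_e12=4.0,
)
VC_RN = VarianceComponents(
    sigma2_e1=18.0, sigma2_e2=818.0, sigma2_int=768.0, sigma2_v=35.0,
    sigma2_slope=2.5, cov_int_v=70.0, cov_int_slope=-8.0, cov_slope_v=-3.0,
    sigma_e12=3.0,
)


# -------------------------------------------------------------- design matrices

def test_hand_built_fixed_effect_matrix():
    df = pd.DataFrame({"f": ["a", "b", "b", "a", "c", "c"],
                       "g": [1, 1, 2, 2, 1, 2]})
    X, labels = encode_fixed_effects(df, (("f",), ("g",), ("f", "g")))
    assert labels[0].endswith("(intercept)")
    expected = {
        "f[b]": [0, 1, 1, 0, 0, 0],
        "f[c]": [0, 0, 0, 0, 1, 1],
        "g[2]": [0, 0, 1, 1, 0, 1],
        "f[b]:g[2]": [0, 0, 1, 0, 0, 0],
        "f[c]:g[2]": [0, 0, 0, 0, 0, 1],
    }
    for name, col in expected.items():
        j = labels.index(name)
        np.testing.assert_array_equal(X[:, j], col)
    assert np.linalg.matrix_rank(X) == X.shape[1]


def test_single_level_factor_dropped():
    df = pd.DataFrame({"only": ["x"] * 4, "two": ["a", "b", "a", "b"]})
    X, labels = encode_fixed_effects(df, (("only",), ("two",)))
    assert not any("only" in lab for lab in labels)
    assert any("two[b]" in lab for lab in labels)


def test_twins_share_milk_covariate(tiny_bundles):
    b = tiny_bundles["reaction_norm"]
    for row in b.patterns["mgg"]:
        milk_value = b.y[row[0]]
        np.testing.assert_allclose(b.covariate[row[1:]], milk_value)
    # lsb has a single level (twins) and must be dropped from the design
    assert not any("lsb" in lab for lab in b.x_labels)


def test_unmatched_growth_record_rejected(tiny_dataset):
    design, _, milk, growth = tiny_dataset
    bad = growth.copy()
    bad.loc[bad.index[0], "milk_id"] = "nonexistent:1:1"
    with pytest.raises(DesignError, match="no matching"):
        build_design(milk, bad, design.pedigree, ModelSpec(kind="intercept"))


def test_animal_missing_from_pedigree_rejected(tiny_dataset):
    design, _, milk, growth = tiny_dataset
    bad = milk.copy()
    bad.loc[bad.index[0], "ewe"] = "GHOST"
    with pytest.raises(DesignError, match="pedigree"):
        build_design(bad, growth, design.pedigree, ModelSpec(kind="intercept"))


# ------------------------------------------------------------- oracle agreement

@pytest.mark.parametrize("kind,vc", [
    ("intercept", VC_INTERCEPT),
    ("reaction_norm", VC_RN),
    ("milk_only", VarianceComponents(sigma2_e1=18.0, sigma2_e2=0.0, sigma2_v=35.0)),
])
def test_reml_matches_dense_oracle(tiny_bundles, kind, vc):
    bundle = tiny_bundles[kind]
    mme = -2.0 * restricted_loglik(vc, bundle)
    dense = dense_reml_m2ll(bundle, vc)
    assert abs(mme - dense) <= 1e-8


def test_factorisation_limit_beta_zero_covariances_zero(tiny_dataset):
    """With sigma_e12 = cov_int_v = 0 the bivariate REML logL equals the sum
    of the two single-trait REML logLs."""
    design, _, milk, growth = tiny_dataset
    spec = ModelSpec(kind="intercept")
    b = build_design(milk, growth, design.pedigree, spec)
    vc = VarianceComponents(sigma2_e1=18.0, sigma2_e2=824.0, sigma2_int=789.0,
                            sigma2_v=35.0)
    joint = -2.0 * restricted_loglik(vc, b)

    W = b.build_W().toarray()
    z = {e: W[:, b.p + i * b.q: b.p + (i + 1) * b.q] for i, e in enumerate(b.effects)}
    rm, rg = b.rows_milk, b.rows_growth
    xm_cols = [j for j in range(b.p) if np.any(b.X[rm, j] != 0)]
    xg_cols = [j for j in range(b.p) if j not in xm_cols]
    milk_part = dense_single_trait_m2ll(
        b.X[np.ix_(rm, xm_cols)], z["v"][rm], b.A, b.y[rm], 35.0, 18.0)
    growth_part = dense_single_trait_m2ll(
        b.X[np.ix_(rg, xg_cols)], z["int"][rg], b.A, b.y[rg], 789.0, 824.0)
    assert joint == pytest.approx(milk_part + growth_part, abs=1e-8)


def test_scaling_identity_on_oracle(tiny_bundles):
    """Scaling every variance by c shifts -2logL by (n-p) log c + (1/c - 1) * yPy."""
    b = tiny_bundles["intercept"]
    vc = VC_INTERCEPT
    c = 2.0
    scaled = VarianceComponents(
        sigma2_e1=c * vc.sigma2_e1, sigma2_e2=c * vc.sigma2_e2,
        sigma2_int=c * vc.sigma2_int, sigma2_v=c * vc.sigma2_v,
        cov_int_v=c * vc.cov_int_v, sigma_e12=c * vc.sigma_e12,
    )
    f1 = dense_reml_m2ll(b, vc)
    f2 = dense_reml_m2ll(b, scaled)
    # recover yPy from the engine's assembly at vc
    eng = REMLEngine(b)
    smalls = eng._smalls(theta_from_vc(vc, b.spec))
    _, aux = eng._assemble(smalls)
    ypy = aux["yRy"] - float(aux["r"] @ aux["sol"])
    expected = f1 + (b.n - b.p) * np.log(c) + (1.0 / c - 1.0) * ypy
    assert f2 == pytest.approx(expected, abs=1e-7)
    assert -2.0 * restricted_loglik(scaled, b) == pytest.approx(f2, abs=1e-8)


def test_ml_profile_likelihood_matches_oracle(tiny_bundles):
    from maternorm.remlfit import _residual_block

    b = tiny_bundles["intercept"]
    vc = VC_INTERCEPT
    ml = -2.0 * restricted_loglik(vc, b, method="ml")
    W = b.build_W().toarray()
    X, Z = b.X, W[:, b.p:]
    G = np.kron(vc.genetic_matrix(b.effects), b.A)
    R = np.zeros((b.n, b.n))
    Sig = vc.residual_matrix(2)
    for name, members in b.patterns.items():
        B = _residual_block(Sig, members.shape[1] - 1)
        for row in members:
            R[np.ix_(row, row)] = B
    V = Z @ G @ Z.T + R
    Vi = np.linalg.inv(V)
    bhat = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ b.y)
    resid = b.y - X @ bhat
    _, ldV = np.linalg.slogdet(V)
    oracle = ldV + resid @ Vi @ resid + b.n * np.log(2 * np.pi)
    assert ml == pytest.approx(oracle, abs=1e-8)


def test_non_psd_input_is_signalled(tiny_bundles):
    vc = VarianceComponents(sigma2_e1=18.0, sigma2_e2=824.0, sigma2_int=10.0,
                            sigma2_v=10.0, cov_int_v=50.0)  # |cov| > sqrt(product)
    with pytest.raises(SingularModelError):
        restricted_loglik(vc, tiny_bundles["intercept"])


# ------------------------------------------------------------------ invariances

def test_record_order_invariance(tiny_dataset):
    design, _, milk, growth = tiny_dataset
    spec = ModelSpec(kind="intercept")
    b1 = build_design(milk, growth, design.pedigree, spec)
    rng = np.random.default_rng(0)
    milk2 = milk.sample(frac=1.0, random_state=1).reset_index(drop=True)
    growth2 = growth.sample(frac=1.0, random_state=2).reset_index(drop=True)
    b2 = build_design(milk2, growth2, design.pedigree, spec)
    l1 = restricted_loglik(VC_INTERCEPT, b1)
    l2 = restricted_loglik(VC_INTERCEPT, b2)
    assert l1 == pytest.approx(l2, abs=1e-8)


def test_reference_level_relabel_invariance(tiny_dataset):
    design, _, milk, growth = tiny_dataset
    spec = ModelSpec(kind="intercept")
    b1 = build_design(milk, growth, design.pedigree, spec)
    relabel = {"F": "ZF", "M": "AM"}  # flips which level sorts first
    growth2 = growth.assign(sex=growth["sex"].map(relabel))
    b2 = build_design(milk, growth2, design.pedigree, spec)
    assert restricted_loglik(VC_INTERCEPT, b1) == pytest.approx(
        restricted_loglik(VC_INTERCEPT, b2), abs=1e-7)


def test_nesting_reaction_norm_logl_at_least_intercept(reduced_dataset):
    design, _, milk, growth = reduced_dataset
    b0 = build_design(milk, growth, design.pedigree, ModelSpec(kind="intercept"))
    b1 = build_design(milk, growth, design.pedigree, ModelSpec(kind="reaction_norm"))
    f0 = fit_reml(b0, options=FitOptions(n_starts=1, seed=0))
    f1 = fit_reml(b1, options=FitOptions(n_starts=1, seed=0))
    # tolerance reflects the optimizer's practical |delta logL| precision
    assert f1.loglik >= f0.loglik - 1e-3


# ------------------------------------------------------------------- estimation

def test_reported_loglik_reproducible_from_estimates(tiny_bundles):
    b = tiny_bundles["intercept"]
    fit = fit_reml(b, options=FitOptions(n_starts=1, seed=0))
    again = restricted_loglik(fit.vc, b)
    assert fit.loglik == pytest.approx(again, abs=1e-6)


def test_multistart_reaches_consistent_optimum(tiny_bundles):
    fit = fit_reml(tiny_bundles["intercept"], options=FitOptions(n_starts=3, seed=4))
    assert len(fit.start_values) == 3
    assert np.ptp(fit.start_values) < 1e-3 * max(1.0, abs(fit.start_values[0]))


def test_null_genetic_truth_recovered_small():
    """Data generated without genetic effects: estimates pile near zero."""
    cfg = DesignConfig(n_ewes_per_maternal_group=6, n_rams_per_direct_group=2)
    params = TrueParameters(beta=3.9, residual=((18.0, 0.0), (0.0, 824.0)))
    design, _, milk, growth = simulate_experiment(cfg, params, seed=21, group_shifts=False)
    b = build_design(milk, growth, design.pedigree, ModelSpec(kind="intercept"))
    fit = fit_reml(b, options=FitOptions(n_starts=1, seed=0))
    assert fit.converged
    # tolerances ~ 3 sampling SEs of a variance at this design size
    assert fit.vc.sigma2_int <= 0.4 * fit.vc.sigma2_e2
    assert fit.vc.sigma2_v <= 0.6 * fit.vc.sigma2_e1
    assert np.abs(fit.blups.to_numpy()).max() <= 30.0


def test_blup_calibration_and_parent_average():
    cfg = DesignConfig(n_ewes_per_maternal_group=8, n_rams_per_direct_group=2)
    truth = intercept_truth()
    design, bv, milk, growth = simulate_experiment(cfg, truth, seed=31, group_shifts=False)
    b = build_design(milk, growth, design.pedigree, ModelSpec(kind="intercept"))
    fit = fit_reml(b, options=FitOptions(n_starts=1, seed=0))
    assert fit.converged
    lambs = sorted(set(growth["lamb"]))
    pred = fit.blups.loc[lambs, "u_int"].to_numpy()
    true = bv.loc[lambs, "u_int"].to_numpy()
    r = np.corrcoef(pred, true)[0, 1]
    assert r > 0.2
    slope = np.polyfit(pred, true, 1)[0]  # regression of true on predicted ~ 1
    assert 0.5 < slope < 1.5
    # an unrecorded, uninformative descendant gets the parent average
    sire, dam = lambs[0], None
    parents = design.pedigree.parents_of(sire)
    extended_ped = Pedigree.from_records(
        [(a, *design.pedigree.parents_of(a)) for a in design.pedigree.ids]
        + [("NEWBORN", parents[0], parents[1])]
    )
    ext = extend_blups(fit, extended_ped)
    expected = 0.5 * (fit.blups.loc[parents[0]] + fit.blups.loc[parents[1]])
    np.testing.assert_allclose(ext.loc["NEWBORN"], expected, atol=1e-10)
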