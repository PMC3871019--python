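"""Interaction RLRT, heritabilities and the nested-LRT selection utility."""

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from maternorm import (
    FitOptions,
    ModelSpec,
    VarianceComponents,
    build_design,
    fit_reml,
    heritabilities,
    nested_lrt,
    phenotypic_variance,
    phenotypic_variance_report,
    rlrt,
    rlrt_statistic,
    select_fixed_effects,
)
from maternorm.gxetest import ols_ml_fit

TABLE3_INTERCEPT = VarianceComponents(
    sigma2_e1=18.0, sigma2_e2=824.0, sigma2_int=789.0, sigma2_v=35.0,
    cov_int_v=0.47 * np.sqrt(789.0 * 35.0), beta=3.9,
)


# ------------------------------------------------------------------------ RLRT

def test_rlrt_statistic_arithmetic():
    f0 = SimpleNamespace(loglik=-100.0)
    f1 = SimpleNamespace(loglik=-99.21)
    assert rlrt_statistic(f0, f1) == pytest.approx(-2 * -100.0 + 2 * -99.21)
    assert rlrt_statistic(f0, f0) == 0.0
    # small negative differences are clipped to zero
    assert rlrt_statistic(SimpleNamespace(loglik=-99.0), f1) == 0.0


def test_rlrt_requires_same_fixed_effects(tiny_dataset):
    design, _, milk, growth = tiny_dataset
    opts = FitOptions(n_starts=1, seed=0)
    b0 = build_design(milk, growth, design.pedigree, ModelSpec(kind="intercept"))
    spec_other = ModelSpec(kind="reaction_norm", adg_fixed=(("sex",),))
    b1 = build_design(milk, growth, design.pedigree, spec_other)
    f0 = fit_reml(b0, options=opts)
    f1 = fit_reml(b1, options=opts)
    with pytest.raises(ValueError, match="fixed-effect"):
        rlrt(f0, f1, calibration="chi2_mixture")


def test_rlrt_chi2_calibrations(tiny_dataset):
    design, _, milk, growth = tiny_dataset
    opts = FitOptions(n_starts=1, seed=0)
    b0 = build_design(milk, growth, design.pedigree, ModelSpec(kind="intercept"))
    b1 = build_design(milk, growth, design.pedigree, ModelSpec(kind="reaction_norm"))
    f0 = fit_reml(b0, options=opts)
    f1 = fit_reml(b1, options=opts)
    res = rlrt(f0, f1, calibration="chi2_mixture")
    s = res.statistic
    expected = 0.5 * stats.chi2.sf(s, 1) + (0.5 if s <= 0 else 0.0)
    assert res.p_value == pytest.approx(expected)
    res3 = rlrt(f0, f1, calibration="chi2_3")
    assert res3.p_value == pytest.approx(stats.chi2.sf(s, 3))
    assert res.n_boundary_parameters == 3  # slope variance + two covariances


def test_rlrt_parametric_bootstrap_runs(tiny_dataset):
    design, _, milk, growth = tiny_dataset
    opts = FitOptions(n_starts=1, seed=0)
    b0 = build_design(milk, growth, design.pedigree, ModelSpec(kind="intercept"))
    b1 = build_design(milk, growth, design.pedigree, ModelSpec(kind="reaction_norm"))
    f0 = fit_reml(b0, options=opts)
    f1 = fit_reml(b1, options=opts)
    res = rlrt(f0, f1, calibration="parametric_bootstrap", bundle_intercept=b0,
               bundle_rn=b1, n_boot=9, seed=1,
               fit_options=FitOptions(n_starts=1, seed=0, gtol=1e-4, maxiter=100))
    assert res.n_bootstrap == 9
    assert 0.0 < res.p_value <= 1.0
    assert np.all(res.bootstrap_statistics >= 0.0)


# --------------------------------------------------------------- heritabilities

def test_h2_milk_from_fitted_components():
    h = heritabilities(TABLE3_INTERCEPT)
    assert h.h2_milk == pytest.approx(35.0 / 53.0)
    assert round(h.h2_milk, 2) == 0.66


def test_h2_zero_dam_variance():
    vc = VarianceComponents(sigma2_e1=18.0, sigma2_e2=824.0, sigma2_int=789.0,
                            sigma2_v=0.0, beta=3.9)
    h = heritabilities(vc)
    assert h.h2_milk == 0.0
    assert h.h2_mat == 0.0


@pytest.mark.parametrize("variant,s2p,h2d,h2m", [
    # frozen values from an independent spreadsheet-style recomputation
    ("as_printed", 2515.233479435938, 0.3136885726318098, 0.21165033161032187),
    ("conventional", 3028.3371396003176, 0.26053902311026467, 0.17578954239892194),
])
def test_sigma2p_variants_against_arithmetic_oracle(variant, s2p, h2d, h2m):
    assert phenotypic_variance(TABLE3_INTERCEPT, variant) == pytest.approx(s2p, rel=1e-9)
    h = heritabilities(TABLE3_INTERCEPT, variant)
    assert h.h2_direct == pytest.approx(h2d, rel=1e-9)
    assert h.h2_mat == pytest.approx(h2m, rel=1e-9)


def test_neither_variant_matches_published_reference():
    """Fidelity over silent correction: the report must flag that no variant
    reproduces the previously published 0.34 / 0.23 / 2887."""
    report = phenotypic_variance_report(
        TABLE3_INTERCEPT,
        reference={"h2_direct": 0.34, "h2_mat": 0.23, "sigma2_p": 2887.0},
    )
    assert report["any_variant_matches_reference"] is False
    assert "discrepancy_flag" in report


# ------------------------------------------------------------------- nested LRT

def test_nested_lrt_identities():
    full = SimpleNamespace(loglik=-50.0, method="ml", terms=(("a",), ("b",)))
    same = SimpleNamespace(loglik=-50.0, method="ml", terms=(("a",), ("b",)))
    stat, p = nested_lrt(full, same, df=0)
    assert (stat, p) == (0.0, 1.0)
    reduced = SimpleNamespace(loglik=-50.0 - 3.84 / 2, method="ml", terms=(("a",),))
    stat, p = nested_lrt(full, reduced, df=1)
    assert stat == pytest.approx(3.84)
    assert p == pytest.approx(0.0500, abs=5e-4)


def test_nested_lrt_rejects_reml_fits():
    full = SimpleNamespace(loglik=-50.0, method="reml", terms=())
    with pytest.raises(ValueError, match="ML"):
        nested_lrt(full, full, df=1)


def test_nested_lrt_rejects_non_nested_terms():
    full = SimpleNamespace(loglik=-50.0, method="ml", terms=(("a",),))
    other = SimpleNamespace(loglik=-51.0, method="ml", terms=(("b",),))
    with pytest.raises(ValueError, match="subset"):
        nested_lrt(full, other, df=1)


def test_nested_lrt_null_calibration(rng):
    """A null factor tested at 5% rejects ~5% of the time."""
    n, reps, df = 60, 500, 2
    rejections = 0
    for _ in range(reps):
        df_data = pd.DataFrame({
            "y": rng.normal(size=n),
            "f": rng.choice(["a", "b", "c"], size=n),
        })
        full = ols_ml_fit(df_data, "y", (("f",),))
        reduced = ols_ml_fit(df_data, "y", ())
        stat, p = nested_lrt(full, reduced, df=df)
        rejections += p <= 0.05
    ci = stats.binomtest(rejections, reps, 0.05)
    assert ci.pvalue > 0.005  # consistent with nominal level


# ---------------------------------------------------------- stepwise selection

def test_select_no_candidates_returns_intercept_only(rng):
    df = pd.DataFrame({"y": rng.normal(size=10)})
    retained, log = select_fixed_effects(df, "y", [])
    assert retained == []


def test_select_alpha_one_keeps_everything(rng):
    df = pd.DataFrame({
        "y": rng.normal(size=40),
        "f": rng.choice(["a", "b"], size=40),
        "g": rng.choice(["u", "v"], size=40),
    })
    retained, _ = select_fixed_effects(df, "y", [("f",), ("g",)], alpha=1.0)
    assert set(retained) == {("f",), ("g",)}


def test_select_respects_hierarchy(rng):
    df = pd.DataFrame({
        "y": rng.normal(size=80),
        "f": rng.choice(["a", "b"], size=80),
        "g": rng.choice(["u", "v"], size=80),
    })
    df["y"] += 3.0 * ((df["f"] == "b") & (df["g"] == "v"))
    retained, _ = select_fixed_effects(df, "y", [("f",), ("g",), ("f", "g")])
    if ("f", "g") in retained:  # interaction kept => main effects kept too
        assert ("f",) in retained and ("g",) in retained


def test_select_drops_null_factor_in_majority(rng):
    reps, dropped_null, dropped_active = 200, 0, 0
    for _ in range(reps):
        n = 60
        df = pd.DataFrame({
            "active": rng.choice(["a", "b"], size=n),
            "null": rng.choice(["u", "v"], size=n),
        })
        df["y"] = 2.0 * (df["active"] == "b") + rng.normal(size=n)
        retained, _ = select_fixed_effects(df, "y", [("active",), ("null",)])
        dropped_null += ("null",) not in retained
        dropped_active += ("active",) not in retained
    assert dropped_null > reps / 2
    assert dropped_active < reps / 10
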