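"""Synthetic experiment generator: design arithmetic, model equations, moments."""

import numpy as np
import pandas as pd
import pytest

from maternorm import (
    AttritionConfig,
    DesignConfig,
    TrueParameters,
    compute_fce,
    compute_tms,
    intercept_truth,
    study_design,
    simulate_breeding_values,
    simulate_design,
    simulate_experiment,
    simulate_records,
)
from maternorm.simulate import apply_attrition, group_mean_shifts, wb_class


# ---------------------------------------------------------------------- design

def test_design_counting_small():
    cfg = DesignConfig(n_ewes_per_maternal_group=1, n_rams_per_direct_group=1)
    design = simulate_design(cfg, seed=0)
    assert len(design.lambs) == 3 * 2 * 2  # 3 ewes x 2 matings x 2 lambs
    assert len(design.matings) == 6


def test_design_counting_full_scale():
    design = simulate_design(DesignConfig(), seed=0)
    assert len(design.lambs) == 960  # 240 ewes x 2 matings x twins
    assert design.animals["role"].value_counts()["ram"] == 12
    assert design.animals["role"].value_counts()["ewe"] == 240


def test_ram_group_alternates_between_matings():
    design = simulate_design(DesignConfig(n_ewes_per_maternal_group=5,
                                          n_rams_per_direct_group=2), seed=1)
    ram_group = design.animals.set_index("animal")["direct_group"]
    for _, per_ewe in design.matings.groupby("ewe"):
        groups = [ram_group[r] for r in per_ewe.sort_values("parity")["ram"]]
        assert set(groups) == {"low", "high"}


def test_same_seed_identical_different_seed_same_structure():
    cfg = DesignConfig(n_ewes_per_maternal_group=2, n_rams_per_direct_group=1)
    truth = intercept_truth()
    a = simulate_experiment(cfg, truth, seed=3)
    b = simulate_experiment(cfg, truth, seed=3)
    pd.testing.assert_frame_equal(a[2], b[2])
    pd.testing.assert_frame_equal(a[3], b[3])
    c = simulate_experiment(cfg, truth, seed=4)
    assert list(c[2]["milk_id"]) == list(a[2]["milk_id"])  # identical design
    assert not np.allclose(c[2]["my_dl"], a[2]["my_dl"])   # different noise


def test_growth_links_and_twin_sharing():
    _, _, milk, growth = simulate_experiment(
        DesignConfig(n_ewes_per_maternal_group=2, n_rams_per_direct_group=1),
        intercept_truth(), seed=9)
    assert set(growth["milk_id"]) <= set(milk["milk_id"])
    # twins share their dam's milk record
    assert (growth.groupby("milk_id")["lamb"].nunique() == 2).all()
    # TMS consistency: (MF+MP) x MY with MY in L/day
    np.testing.assert_allclose(
        milk["tms"], (milk["mf"] + milk["mp"]) * milk["my_dl"] / 10.0
    )


# ------------------------------------------------------------------ phenotypes

@pytest.mark.parametrize(
    "mf,mp,my,expected",
    [(60, 50, 2.3, 253.0), (0, 0, 2.3, 0.0), (40, 50, 3.3, 297.0)],
)
def test_compute_tms(mf, mp, my, expected):
    assert compute_tms(mf, mp, my) == pytest.approx(expected)


def test_compute_tms_rejects_negative():
    with pytest.raises(ValueError):
        compute_tms(-1, 50, 2.0)


@pytest.mark.parametrize(
    "milk,adg,expected",
    [(2.3, 230, 0.01), (0.0, 200, 0.0), (2.4, 207, 2.4 / 207)],
)
def test_compute_fce(milk, adg, expected):
    assert compute_fce(milk, adg) == pytest.approx(expected)


def test_compute_fce_zero_adg_error():
    with pytest.raises(ValueError):
        compute_fce(2.0, 0.0)


def test_wb_classes():
    assert [wb_class(w) for w in (2.0, 2.5, 3.4, 3.5, 4.4, 4.5, 6.0)] == \
        [1, 2, 2, 3, 3, 4, 4]


# -------------------------------------------------------------- model equations

def test_zero_variance_records_equal_fixed_sums():
    cfg = DesignConfig(n_ewes_per_maternal_group=1, n_rams_per_direct_group=1)
    params = TrueParameters(beta=0.0, residual=((0.0, 0.0), (0.0, 0.0)))
    _, _, milk, growth = simulate_experiment(cfg, params, seed=2, group_shifts=False)
    np.testing.assert_allclose(milk["my_dl"], params.milk_mean)
    np.testing.assert_allclose(growth["adg"], params.adg_mean)


def test_beta_linearity_common_random_numbers():
    """Raising one dam's milk by 1 dL (all noise held fixed) raises each of her
    lambs' ADG by beta + u_slope."""
    cfg = DesignConfig(n_ewes_per_maternal_group=1, n_rams_per_direct_group=1)
    params = intercept_truth()
    design = simulate_design(cfg, seed=6)
    bv = simulate_breeding_values(design.pedigree, params, seed=6)
    milk0, growth0 = simulate_records(design, bv, params, seed=6)
    bumped = bv.copy()
    dam = milk0["ewe"].iloc[0]
    bumped.loc[dam, "v"] += 1.0
    milk1, growth1 = simulate_records(design, bumped, params, seed=6)
    d_milk = milk1["my_dl"] - milk0["my_dl"]
    assert np.allclose(d_milk[milk0["ewe"] == dam], 1.0)
    assert np.allclose(d_milk[milk0["ewe"] != dam], 0.0)
    d_adg = growth1["adg"] - growth0["adg"]
    own = growth0["dam"] == dam
    slopes = bv.loc[growth0.loc[own, "lamb"], "u_slope"].to_numpy()
    np.testing.assert_allclose(d_adg[own], params.beta + slopes)
    assert np.allclose(d_adg[~own], 0.0)


def test_milk_variance_matches_components():
    """Under intercept-model truth the ewe-day MY variance is s2_v + s2_e1 = 53."""
    _, _, milk, _ = simulate_experiment(
        study_design(), intercept_truth(), seed=12, group_shifts=False)
    var = milk.groupby(["ewe"])["my_dl"].transform("size")  # noqa: F841 (structure check)
    v = float(np.var(milk["my_dl"], ddof=1))
    # sampling error: ~sqrt(2/n_ewes) relative for the between-ewe part
    assert v == pytest.approx(53.0, rel=0.20)


def test_founder_breeding_value_covariance(rng):
    """Founders-only: empirical covariance over 10k animals matches G3."""
    from maternorm.pedigree import Pedigree

    params = intercept_truth()
    records = [(f"F{k}", None, None) for k in range(10_000)]
    ped = Pedigree.from_records(records)
    bv = simulate_breeding_values(ped, params, seed=42)
    emp = np.cov(bv[["u_int", "u_slope", "v"]].to_numpy().T)
    g3 = params.g3_matrix
    se = np.sqrt((np.outer(np.diag(g3), np.diag(g3)) + g3 ** 2) / 10_000)
    assert np.all(np.abs(emp - g3) <= 3 * np.maximum(se, 1e-9))


def test_gene_dropped_values_match_kronecker_covariance():
    """Across replicate drops, cov(bv_i[e], bv_j[f]) = A_ij * G3[e,f]."""
    from maternorm.pedigree import Pedigree, additive_relationship

    params = intercept_truth()
    ped = Pedigree.from_records(
        [("S", None, None), ("D", None, None), ("O1", "S", "D"),
         ("O2", "S", "D"), ("G", "S", "O1")]
    )
    A = additive_relationship(ped).matrix
    g3 = params.g3_matrix
    n_rep = 4000
    draws = np.stack([
        simulate_breeding_values(ped, params, seed=s).to_numpy()
        for s in range(n_rep)
    ])  # (rep, animal, effect)
    flat = draws.reshape(n_rep, -1)  # animal-major, 3 effects per animal
    emp = np.cov(flat.T)
    target = np.kron(A, g3)
    scale = np.sqrt(np.outer(np.diag(target), np.diag(target)) + target ** 2)
    se = scale / np.sqrt(n_rep)
    assert np.all(np.abs(emp - target) <= 4 * np.maximum(se, 1e-9))


def test_zero_g3_gives_zero_breeding_values():
    from maternorm.pedigree import Pedigree

    ped = Pedigree.from_records([("S", None, None), ("D", None, None), ("O", "S", "D")])
    bv = simulate_breeding_values(ped, TrueParameters(), seed=1)
    assert np.all(bv.to_numpy() == 0.0)


def test_group_shifts_move_group_means():
    cfg = DesignConfig()
    params = intercept_truth()
    design = simulate_design(cfg, seed=8)
    shifts = group_mean_shifts(design, params)
    bv = simulate_breeding_values(design.pedigree, params, shifts=shifts, seed=8)
    ewes = design.animals[design.animals["role"] == "ewe"]
    v_by_group = bv.loc[ewes["animal"], "v"].groupby(
        ewes.set_index("animal")["maternal_group"]
    ).mean()
    assert v_by_group["high"] > v_by_group["medium"] > v_by_group["low"]


# -------------------------------------------------------------------- attrition

def test_attrition_reaches_experiment_vicinity():
    """Full design thinned by the default attrition lands near 1284 records /
    442 lambs / 166 ewes."""
    _, _, milk, growth = simulate_experiment(
        DesignConfig(), intercept_truth(), seed=12, group_shifts=False)
    counts = []
    for seed in (1, 2, 3):
        m, g = apply_attrition(milk, growth, AttritionConfig(), seed=seed)
        counts.append((len(g), g["lamb"].nunique(), m["ewe"].nunique()))
    mean = np.mean(counts, axis=0)
    for got, want in zip(mean, (1284, 442, 166)):
        assert abs(got - want) / want < 0.25
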