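"""Synthetic data generator for the twin-rearing 3x2 factorial milk/growth experiment.

Emulates an experiment in which multiparous ewes from three maternal-genetic-merit
groups are each mated twice (to rams of opposite direct-genetic-merit groups, two
rams groups in total), rear twin litters, and have milk yield (MY, internally in
dL/day), fat (MF, g/L) and protein (MP, g/L) measured at days 15, 21 and 35 after
lambing, while the lambs' average daily gain (ADG, g/day) is recorded over the
periods 0-15, 15-21 and 21-35 days.

Phenotypes are generated under the recursive reaction-norm model

    MILK = mu_milk + fixed + v + eps1
    ADG  = mu_adg  + fixed + beta*MILK + u_int + u_slope*MILK + eps2

with (u_int, u_slope, v) jointly Gaussian over the pedigree with covariance
A (x) G3 (gene dropping with Mendelian-sampling variance, including the standard
inbreeding adjustment) and residuals (eps1, eps2) with a 2x2 covariance in which
the milk residual eps1 is shared by the twin pair and each twin's eps2 is
conditionally independent given eps1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import Pedigree, additive_relationship

logger = logging.getLogger(__name__)

PERIODS = ("0-15", "15-21", "21-35")
PERIOD_DAY = {"0-15": 15, "15-21": 21, "21-35": 35}
PERIOD_LENGTH = {"0-15": 15, "15-21": 6, "21-35": 14}
MATERNAL_GROUPS = ("low", "medium", "high")
DIRECT_GROUPS = ("low", "high")
WB_EDGES = (2.5, 3.5, 4.5)  # birth-weight class boundaries, kg


def wb_class(birth_weight_kg: float) -> int:
    """Birth-weight class: 1 (<2.5), 2 ([2.5,3.5)), 3 ([3.5,4.5)), 4 (>=4.5 kg)."""
    return 1 + int(np.searchsorted(WB_EDGES, birth_weight_kg, side="right"))


def compute_tms(mf_g_per_l: float, mp_g_per_l: float, my_l_per_day: float):
    """Total milk solids, g/day: TMS = (MF + MP) * MY with MY in L/day."""
    mf = np.asarray(mf_g_per_l, dtype=float)
    mp = np.asarray(mp_g_per_l, dtype=float)
    my = np.asarray(my_l_per_day, dtype=float)
    if np.any(mf < 0) or np.any(mp < 0) or np.any(my < 0):
        raise ValueError("TMS inputs must be non-negative")
    out = (mf + mp) * my
    return float(out) if out.ndim == 0 else out


def compute_fce(milk_consumed_l_per_day: float, adg_g_per_day: float):
    """Feed conversion efficiency: milk consumed per day / average daily gain."""
    milk = np.asarray(milk_consumed_l_per_day, dtype=float)
    adg = np.asarray(adg_g_per_day, dtype=float)
    if np.any(adg == 0):
        raise ValueError("FCE undefined for zero ADG")
    out = milk / adg
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class AttritionConfig:
    """Post-hoc exclusions applied to the full factorial design.

    ``ewe_retention`` thins the ewe panel (non-participation across the whole
    experiment), ``litter_retention`` keeps a mating's litter in the
    maternally-reared twin group (fertility failures and allocation to
    artificial rearing), ``lamb_mortality`` removes a whole litter when either
    twin dies (single-suckled survivors are not representative), and
    ``record_failure`` drops individual suckling growth records.
    """

    ewe_retention: float = 166 / 240
    litter_retention: float = 0.70
    lamb_mortality: float = 0.025
    record_failure: float = 0.02


@dataclass(frozen=True)
class DesignConfig:
    """Structure of the 3x2 factorial mating design."""

    n_ewes_per_maternal_group: int = 80
    n_rams_per_direct_group: int = 6
    n_matings_per_ewe: int = 2
    litter_size: int = 2
    measurement_days: tuple = (15, 21, 35)
    maternal_group_ebv: tuple = (-9.7, 4.0, 16.6)  # g/day, low/medium/high
    direct_group_ebv: tuple = (-14.1, 29.1)  # g/day, low/high
    ebv_shift_scale: float = 0.5
    years: tuple = (2009, 2010, 2011)
    attrition: AttritionConfig | None = None

    def __post_init__(self):
        if min(self.n_ewes_per_maternal_group, self.n_rams_per_direct_group,
               self.n_matings_per_ewe, self.litter_size) < 1:
            raise ValueError("design counts must be >= 1")
        if len(self.maternal_group_ebv) != 3 or len(self.direct_group_ebv) != 2:
            raise ValueError("expect three maternal and two direct groups")


def study_design() -> DesignConfig:
    """Full-scale design with attrition tuned to yield ~1284 records on ~442 lambs."""
    return DesignConfig(attrition=AttritionConfig())


def reduced_design(n_ewes_per_maternal_group: int = 3,
                   n_rams_per_direct_group: int = 2) -> DesignConfig:
    """A small design for calibration simulations (no attrition)."""
    return DesignConfig(
        n_ewes_per_maternal_group=n_ewes_per_maternal_group,
        n_rams_per_direct_group=n_rams_per_direct_group,
    )


@dataclass(frozen=True)
class TrueParameters:
    """Generating parameters of the recursive reaction-norm model.

    Genetic covariance ``g3`` is 3x3 over (u_int, u_slope, v) on the scale of
    ADG in g/day with milk in dL/day; ``residual`` is 2x2 over (eps1, eps2).
    ``milk_mean`` (dL/day) and ``adg_mean`` (g/day, before the beta*MILK term)
    are the overall trait means; all other fixed-effect levels default to zero
    and can be supplied per trait/factor/level via ``fixed_effects``.
    """

    beta: float = 3.9
    g3: tuple = ((0.0,) * 3,) * 3
    residual: tuple = ((18.0, 0.0), (0.0, 824.0))
    milk_mean: float = 23.0
    adg_mean: float = 117.0
    mf_mean: float = 60.0
    mf_sd: float = 18.0
    mp_mean: float = 50.0
    mp_sd: float = 4.0
    birth_weight_mean: float = 3.5
    birth_weight_sd: float = 0.6
    fixed_effects: dict = field(default_factory=dict)

    @property
    def g3_matrix(self) -> np.ndarray:
        return np.asarray(self.g3, dtype=float)

    @property
    def residual_matrix(self) -> np.ndarray:
        return np.asarray(self.residual, dtype=float)

    def fixed_value(self, trait: str, factor: str, level) -> float:
        return float(self.fixed_effects.get(trait, {}).get(factor, {}).get(level, 0.0))


def _g3(s2_int, s2_slope, s2_v, c_is=0.0, c_iv=0.0, c_sv=0.0):
    return (
        (s2_int, c_is, c_iv),
        (c_is, s2_slope, c_sv),
        (c_iv, c_sv, s2_v),
    )


def intercept_truth() -> TrueParameters:
    """Fitted intercept-model components of the source experiment (no slope)."""
    rho_iv = 0.47
    c_iv = rho_iv * np.sqrt(789.0 * 35.0)
    return TrueParameters(
        beta=3.9,
        g3=_g3(789.0, 0.0, 35.0, c_iv=c_iv),
        residual=((18.0, 0.0), (0.0, 824.0)),
    )


def reaction_norm_truth(s2_slope: float = 126.0) -> TrueParameters:
    """Fitted reaction-norm components; slope variance is overridable."""
    s2_int, s2_v = 768.0, 35.0
    c_is = -0.23 * np.sqrt(s2_int * s2_slope) if s2_slope > 0 else 0.0
    c_iv = 0.46 * np.sqrt(s2_int * s2_v)
    c_sv = -0.59 * np.sqrt(s2_slope * s2_v) if s2_slope > 0 else 0.0
    return TrueParameters(
        beta=3.9,
        g3=_g3(s2_int, s2_slope, s2_v, c_is=c_is, c_iv=c_iv, c_sv=c_sv),
        residual=((18.0, 0.0), (0.0, 818.0)),
    )


@dataclass
class SimulatedDesign:
    """Pedigree plus mating plan and group assignments of one simulated experiment."""

    pedigree: Pedigree
    animals: pd.DataFrame  # animal, role, direct_group, maternal_group, cohort, sex
    matings: pd.DataFrame  # litter, ewe, ram, parity, year, dam_age
    lambs: pd.DataFrame    # lamb, litter, ewe, ram, sex, birth_weight, wb, year, ...
    config: DesignConfig


def _ids(prefix: str, n: int, width: int) -> list:
    return [f"{prefix}{k + 1:0{width}d}" for k in range(n)]


def simulate_design(config: DesignConfig, seed: int = 0) -> SimulatedDesign:
    """Lay out the factorial mating plan and pedigree (deterministic given seed).

    Every ewe is mated ``n_matings_per_ewe`` times, alternating the direct
    group of the service ram between consecutive matings; each mating yields a
    litter of ``litter_size`` lambs.  Rams and ewes are founders.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 101]))
    n_rams = 2 * config.n_rams_per_direct_group
    n_ewes = 3 * config.n_ewes_per_maternal_group
    rams = _ids("R", n_rams, 3)
    ewes = _ids("E", n_ewes, 4)
    ram_group = {r: DIRECT_GROUPS[k // config.n_rams_per_direct_group]
                 for k, r in enumerate(rams)}
    ewe_group = {e: MATERNAL_GROUPS[k // config.n_ewes_per_maternal_group]
                 for k, e in enumerate(ewes)}
    # two cohorts, balanced within each maternal group
    cohort = {e: ("A" if (k % config.n_ewes_per_maternal_group)
                  < (config.n_ewes_per_maternal_group + 1) // 2 else "B")
              for k, e in enumerate(ewes)}
    years = config.years
    cohort_years = {"A": (years[0], years[1]), "B": (years[1], years[2])}
    dam_age0 = {e: int(rng.integers(2, 4)) for e in ewes}  # 2 or 3 years old at entry

    ram_cursor = {g: 0 for g in DIRECT_GROUPS}
    rams_by_group = {g: [r for r in rams if ram_group[r] == g] for g in DIRECT_GROUPS}
    matings = []
    lambs = []
    lamb_counter = 0
    for k, e in enumerate(ewes):
        first_group = DIRECT_GROUPS[k % 2]
        for parity in range(config.n_matings_per_ewe):
            g = DIRECT_GROUPS[(DIRECT_GROUPS.index(first_group) + parity) % 2]
            ram = rams_by_group[g][ram_cursor[g] % len(rams_by_group[g])]
            ram_cursor[g] += 1
            year = cohort_years[cohort[e]][min(parity, 1)]
            litter = f"{e}.{parity + 1}"
            dam_age = min(dam_age0[e] + parity, 4)
            matings.append((litter, e, ram, parity + 1, year, dam_age))
            sexes = rng.choice(["F", "M"], size=config.litter_size)
            for j in range(config.litter_size):
                lamb_counter += 1
                lambs.append((f"L{lamb_counter:05d}", litter, e, ram, sexes[j], year))
    matings_df = pd.DataFrame(
        matings, columns=["litter", "ewe", "ram", "parity", "year", "dam_age"]
    )
    lambs_df = pd.DataFrame(
        lambs, columns=["lamb", "litter", "ewe", "ram", "sex", "year"]
    )
    # litter "sex": 1 = two females, 2 = mixed, 3 = two males
    n_males = lambs_df.groupby("litter")["sex"].apply(lambda s: (s == "M").sum())
    frac = n_males / lambs_df.groupby("litter")["sex"].size()
    totsex = (1 + np.where(frac == 0, 0, np.where(frac == 1, 2, 1))).astype(int)
    totsex_map = dict(zip(n_males.index, totsex))
    matings_df["totsex"] = matings_df["litter"].map(totsex_map)
    lambs_df["totsex"] = lambs_df["litter"].map(totsex_map)
    lambs_df["dam_age"] = lambs_df["litter"].map(
        dict(zip(matings_df["litter"], matings_df["dam_age"]))
    )

    records = [(r, None, None) for r in rams] + [(e, None, None) for e in ewes]
    records += [(row.lamb, row.ram, row.ewe) for row in lambs_df.itertuples()]
    ped = Pedigree.from_records(records)

    animals = pd.DataFrame(
        {
            "animal": rams + ewes + list(lambs_df["lamb"]),
            "role": ["ram"] * n_rams + ["ewe"] * n_ewes + ["lamb"] * len(lambs_df),
        }
    )
    direct = {**ram_group, **{row.lamb: ram_group[row.ram] for row in lambs_df.itertuples()}}
    maternal = {**ewe_group, **{row.lamb: ewe_group[row.ewe] for row in lambs_df.itertuples()}}
    animals["direct_group"] = animals["animal"].map(direct)
    animals["maternal_group"] = animals["animal"].map(maternal)
    animals["cohort"] = animals["animal"].map(
        {**cohort, **{row.lamb: cohort[row.ewe] for row in lambs_df.itertuples()}}
    )
    return SimulatedDesign(
        pedigree=ped, animals=animals, matings=matings_df, lambs=lambs_df, config=config
    )


def _psd_sqrt(mat: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Symmetric PSD square root; raises on clearly indefinite input."""
    mat = np.asarray(mat, dtype=float)
    w, v = np.linalg.eigh((mat + mat.T) / 2)
    floor = -tol * max(1.0, float(np.max(np.abs(w))))
    if np.min(w) < floor:
        raise ValueError(f"covariance matrix is not positive semi-definite: eig={w}")
    w = np.clip(w, 0.0, None)
    return v @ np.diag(np.sqrt(w)) @ v.T


def group_mean_shifts(design: SimulatedDesign, params: TrueParameters) -> dict:
    """Founder mean shifts emulating parent selection on estimated breeding values.

    Ram groups are shifted on u_int by the group-mean direct EBV, ewe groups on
    v by the group-mean maternal EBV divided by beta (a maternal EBV acts on
    lamb growth through beta*v).  Both are damped by ``ebv_shift_scale``.
    """
    cfg = design.config
    scale = cfg.ebv_shift_scale
    shifts = {}
    for row in design.animals.itertuples():
        mu = np.zeros(3)
        if row.role == "ram":
            mu[0] = scale * cfg.direct_group_ebv[DIRECT_GROUPS.index(row.direct_group)]
        elif row.role == "ewe":
            if params.beta != 0:
                mu[2] = (scale / params.beta) * cfg.maternal_group_ebv[
                    MATERNAL_GROUPS.index(row.maternal_group)
                ]
        shifts[row.animal] = mu
    return shifts


def simulate_breeding_values(
    ped: Pedigree,
    params: TrueParameters,
    shifts: dict | None = None,
    seed: int = 0,
    inbreeding: np.ndarray | None = None,
) -> pd.DataFrame:
    """Gene-drop (u_int, u_slope, v) breeding values down the pedigree.

    Founders are drawn from N(shift, G3); non-founders are the parental mean
    plus a Mendelian-sampling deviation with covariance
    ``0.5 * (1 - (F_s + F_d)/2) * G3`` (unknown parents contribute founder
    variance: one parent known gives ``(3/4 - F_known/4) * G3``).
    """
    g3 = params.g3_matrix
    root = _psd_sqrt(g3)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 202]))
    n = len(ped)
    if inbreeding is None:
        if np.all(ped.generation <= 1):
            inbreeding = np.zeros(n)  # founders and their direct offspring: F = 0
        else:
            inbreeding = additive_relationship(ped).matrix.diagonal() - 1.0
    bv = np.zeros((n, 3))
    z = rng.standard_normal((n, 3))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s < 0 and d < 0:
            mean = np.zeros(3)
            factor = 1.0
        elif s >= 0 and d >= 0:
            mean = 0.5 * (bv[s] + bv[d])
            factor = 0.5 * (1.0 - 0.5 * (inbreeding[s] + inbreeding[d]))
        else:
            p = s if s >= 0 else d
            mean = 0.5 * bv[p]
            factor = 0.75 - 0.25 * inbreeding[p]
        bv[i] = mean + np.sqrt(factor) * (root @ z[i])
        if shifts is not None and ped.ids[i] in shifts:
            bv[i] = bv[i] + np.asarray(shifts[ped.ids[i]], dtype=float)
    return pd.DataFrame(bv, columns=["u_int", "u_slope", "v"], index=list(ped.ids))


def simulate_records(
    design: SimulatedDesign,
    breeding_values: pd.DataFrame,
    params: TrueParameters,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate milk and growth records under the recursive model equations.

    Returns ``(milk, growth)`` data frames.  Milk yield is in dL/day
    internally; TMS is computed with MY converted to L/day.  One eps1 is drawn
    per ewe-day and shared by the twin pair; each twin's eps2 is drawn
    conditionally on it.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 303]))
    sig = params.residual_matrix
    s11, s12, s22 = sig[0, 0], sig[0, 1], sig[1, 1]
    if s11 < 0 or s22 < 0 or (s11 * s22 - s12 ** 2) < -1e-9 * max(1.0, s11 * s22):
        raise ValueError("residual covariance matrix is not PSD")
    if s11 == 0 and s12 != 0:
        raise ValueError("sigma_e12 must be 0 when sigma2_e1 is 0")
    cond_var = s22 - (s12 ** 2 / s11 if s11 > 0 else 0.0)

    bv = breeding_values
    milk_rows = []
    growth_rows = []
    lambs_by_litter = {
        lit: grp.sort_values("lamb") for lit, grp in design.lambs.groupby("litter")
    }
    bw = {
        row.lamb: row.birth_weight
        for row in design.lambs.assign(
            birth_weight=rng.normal(
                params.birth_weight_mean, params.birth_weight_sd, len(design.lambs)
            )
        ).itertuples()
    }
    for m in design.matings.sort_values("litter").itertuples():
        litter_lambs = lambs_by_litter.get(m.litter)
        if litter_lambs is None:
            continue
        for day in design.config.measurement_days:
            age = int(day)
            lag = int(rng.integers(-4, 5))
            fx_milk = (
                params.fixed_value("milk", "age", age)
                + params.fixed_value("milk", "year", m.year)
                + params.fixed_value("milk", "totsex", m.totsex)
                + params.fixed_value("milk", "dam_age", m.dam_age)
            )
            eps1 = rng.normal(0.0, np.sqrt(s11)) if s11 > 0 else 0.0
            my = params.milk_mean + fx_milk + bv.at[m.ewe, "v"] + eps1
            if my <= 0:
                logger.warning("non-positive milk yield simulated (%.2f dL); clipped", my)
                my = 0.1
            mf = max(rng.normal(params.mf_mean, params.mf_sd), 0.0)
            mp = max(rng.normal(params.mp_mean, params.mp_sd), 0.0)
            milk_id = f"{m.ewe}:{m.year}:{day}"
            milk_rows.append(
                (milk_id, m.ewe, m.year, day, my, mf, mp,
                 compute_tms(mf, mp, my / 10.0), lag, m.totsex, m.dam_age)
            )
            period = PERIODS[design.config.measurement_days.index(day)]
            for lamb_row in litter_lambs.itertuples():
                fx_adg = (
                    params.fixed_value("adg", "age", age)
                    + params.fixed_value("adg", "year", m.year)
                    + params.fixed_value("adg", "sex", lamb_row.sex)
                    + params.fixed_value("adg", "dam_age", m.dam_age)
                    + params.fixed_value("adg", "wb", wb_class(bw[lamb_row.lamb]))
                    + params.fixed_value("adg", "lw", lag)
                    + params.fixed_value("adg", "lsb", len(litter_lambs))
                    + params.fixed_value("adg", "lw*age", (lag, age))
                )
                mean2 = (s12 / s11) * eps1 if s11 > 0 else 0.0
                eps2 = mean2 + (rng.normal(0.0, np.sqrt(cond_var)) if cond_var > 0 else 0.0)
                adg = (
                    params.adg_mean
                    + fx_adg
                    + params.beta * my
                    + bv.at[lamb_row.lamb, "u_int"]
                    + bv.at[lamb_row.lamb, "u_slope"] * my
                    + eps2
                )
                growth_rows.append(
                    (lamb_row.lamb, m.ewe, m.year, period, age, adg, lamb_row.sex,
                     wb_class(bw[lamb_row.lamb]), len(litter_lambs), m.totsex,
                     m.dam_age, lag, milk_id)
                )
    milk = pd.DataFrame(
        milk_rows,
        columns=["milk_id", "ewe", "year", "day", "my_dl", "mf", "mp", "tms",
                 "lag", "totsex", "dam_age"],
    )
    growth = pd.DataFrame(
        growth_rows,
        columns=["lamb", "dam", "year", "period", "age", "adg", "sex", "wb",
                 "lsb", "totsex", "dam_age", "lw", "milk_id"],
    )
    return milk, growth


def apply_attrition(
    milk: pd.DataFrame,
    growth: pd.DataFrame,
    attrition: AttritionConfig,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Thin a full factorial dataset down to realistic experiment sizes.

    Removes whole ewes, whole litters (fertility / artificial rearing), whole
    litters in which a lamb died (the surviving single-suckled twin is not
    representative), and a small fraction of individual growth records (failed
    suckling tests).  Milk records without any surviving litter are dropped.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 404]))
    ewes = sorted(milk["ewe"].unique())
    keep_ewes = {e for e in ewes if rng.random() < attrition.ewe_retention}
    litters = sorted(set(zip(growth["dam"], growth["year"])))
    keep_litters = set()
    for dam, year in litters:
        if dam not in keep_ewes:
            continue
        if rng.random() >= attrition.litter_retention:
            continue
        lambs = growth.loc[(growth["dam"] == dam) & (growth["year"] == year), "lamb"].unique()
        if any(rng.random() < attrition.lamb_mortality for _ in lambs):
            continue  # a death leaves a single-suckled twin: litter excluded
        keep_litters.add((dam, year))
    g = growth[[ (d, y) in keep_litters for d, y in zip(growth["dam"], growth["year"]) ]]
    g = g[rng.random(len(g)) >= attrition.record_failure].reset_index(drop=True)
    m = milk[milk["milk_id"].isin(set(g["milk_id"]))].reset_index(drop=True)
    return m, g


def simulate_experiment(
    config: DesignConfig,
    params: TrueParameters,
    seed: int = 0,
    group_shifts: bool = True,
):
    """Full generator: design, breeding values, records, optional attrition.

    Returns ``(design, breeding_values, milk, growth)``.  With
    ``group_shifts=False`` founders are drawn from the zero-mean model, which
    is the appropriate setting for variance-component recovery studies.
    """
    design = simulate_design(config, seed=seed)
    shifts = group_mean_shifts(design, params) if group_shifts else None
    bv = simulate_breeding_values(design.pedigree, params, shifts=shifts, seed=seed)
    milk, growth = simulate_records(design, bv, params, seed=seed)
    if config.attrition is not None:
        milk, growth = apply_attrition(milk, growth, config.attrition, seed=seed)
    return design, bv, milk, growth


# ---------------------------------------------------------------------------
# CSV interfaces (files store MY in L/day; in-memory frames use dL/day)

def write_milk_csv(milk: pd.DataFrame, path, seed: int | None = None) -> None:
    out = milk.copy()
    out["MY_L_per_day"] = out.pop("my_dl") / 10.0
    out = out.rename(columns={"mf": "MF", "mp": "MP"})
    cols = ["ewe", "year", "day", "MY_L_per_day", "MF", "MP", "lag",
            "totsex", "dam_age"]
    with open(path, "w", encoding="utf-8") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        out[cols].to_csv(fh, index=False)


def read_milk_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    df["my_dl"] = df.pop("MY_L_per_day") * 10.0
    df = df.rename(columns={"MF": "mf", "MP": "mp"})
    df["tms"] = compute_tms(df["mf"], df["mp"], df["my_dl"] / 10.0)
    df["milk_id"] = (
        df["ewe"].astype(str) + ":" + df["year"].astype(str) + ":" + df["day"].astype(str)
    )
    return df


def write_growth_csv(growth: pd.DataFrame, path, seed: int | None = None) -> None:
    cols = ["lamb", "dam", "year", "period", "age", "adg", "sex", "wb", "lsb",
            "totsex", "dam_age", "lw"]
    with open(path, "w", encoding="utf-8") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        growth[cols].to_csv(fh, index=False)


def read_growth_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    if "age" not in df.columns:
        df["age"] = df["period"].map(PERIOD_DAY)
    df["milk_id"] = (
        df["dam"].astype(str) + ":" + df["year"].astype(str) + ":" + df["age"].astype(str)
    )
    return df
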