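"""Descriptive summaries of milk and growth records.

Covers the group-contrast table of 0-35 day average daily gain by direct and
maternal genetic-merit group, the per-measurement-day trait summary (ADG in
g/day, milk yield reported in mL/day, total milk solids in g/day), phenotypic
correlations between the maternal phenotypes and growth, and a minimal feed
conversion efficiency (FCE = milk consumed per day / ADG) scatter export.

The 0-35 day ADG of a lamb is the day-length-weighted mean of its period
gains, (15*ADG[0-15] + 6*ADG[15-21] + 14*ADG[21-35]) / 35, algebraically the
same as (weight at 35 d - birth weight) / 35 when all three periods are
present; with missing periods the weights renormalise over observed periods.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import PERIOD_LENGTH, compute_fce

logger = logging.getLogger(__name__)

DL_PER_L = 10.0
ML_PER_DL = 100.0


def dl_to_ml(my_dl: float):
    return np.asarray(my_dl, dtype=float) * ML_PER_DL


def dl_to_l(my_dl: float):
    return np.asarray(my_dl, dtype=float) / DL_PER_L


def l_to_dl(my_l: float):
    return np.asarray(my_l, dtype=float) * DL_PER_L


def adg_0_35(growth: pd.DataFrame) -> pd.Series:
    """Day-length-weighted 0-35 d ADG per lamb from period ADGs."""
    g = growth.assign(w=growth["period"].map(PERIOD_LENGTH))
    if g["w"].isna().any():
        bad = sorted(g.loc[g["w"].isna(), "period"].unique())
        raise ValueError(f"unknown growth periods: {bad}")
    num = (g["adg"] * g["w"]).groupby(g["lamb"]).sum()
    den = g.groupby("lamb")["w"].sum()
    return (num / den).rename("adg_0_35")


@dataclass
class GroupSummaryTable:
    """Cell and marginal mean (SD) of 0-35 d ADG over the 3x2 factorial."""

    cells: pd.DataFrame          # rows: direct group, cols: maternal group
    cell_sd: pd.DataFrame
    cell_n: pd.DataFrame
    marginal_direct: pd.DataFrame   # mean, sd, n per direct group
    marginal_maternal: pd.DataFrame
    overall_mean: float
    overall_sd: float
    differences: dict

    def to_frame(self) -> pd.DataFrame:
        out = self.cells.copy()
        out["Total"] = self.marginal_direct["mean"]
        total_row = self.marginal_maternal["mean"].copy()
        total_row["Total"] = self.overall_mean
        out.loc["Total"] = total_row
        return out


def group_summary(growth: pd.DataFrame, assignments: pd.DataFrame) -> GroupSummaryTable:
    """0-35 d ADG means and SDs per direct x maternal group cell with marginals.

    ``assignments`` maps each lamb to its direct and maternal group (columns
    ``animal``, ``direct_group``, ``maternal_group``).  Marginal means are
    record-count-weighted averages of cell means (i.e. plain means over
    lambs).  Empty cells are reported as missing, not raised.
    """
    per_lamb = adg_0_35(growth).reset_index()
    merged = per_lamb.merge(
        assignments[["animal", "direct_group", "maternal_group"]],
        left_on="lamb", right_on="animal", how="left",
    )
    if merged["direct_group"].isna().any():
        missing = merged.loc[merged["direct_group"].isna(), "lamb"].tolist()
        raise ValueError(f"lambs without group assignment: {missing[:10]}")

    d_order = [g for g in ("low", "high") if g in set(merged["direct_group"])]
    m_order = [g for g in ("low", "medium", "high") if g in set(merged["maternal_group"])]
    cells = merged.pivot_table(
        index="direct_group", columns="maternal_group", values="adg_0_35",
        aggfunc="mean",
    ).reindex(index=d_order, columns=m_order)
    cell_sd = merged.pivot_table(
        index="direct_group", columns="maternal_group", values="adg_0_35",
        aggfunc=lambda s: s.std(ddof=1),
    ).reindex(index=d_order, columns=m_order)
    cell_n = merged.pivot_table(
        index="direct_group", columns="maternal_group", values="adg_0_35",
        aggfunc="count",
    ).reindex(index=d_order, columns=m_order).fillna(0).astype(int)

    def _marginal(by):
        grp = merged.groupby(by)["adg_0_35"]
        return pd.DataFrame(
            {"mean": grp.mean(), "sd": grp.std(ddof=1), "n": grp.count()}
        ).reindex(d_order if by == "direct_group" else m_order)

    md = _marginal("direct_group")
    mm = _marginal("maternal_group")
    differences = {}
    if {"low", "high"} <= set(md.index):
        differences["direct_high_minus_low"] = float(
            md.at["high", "mean"] - md.at["low", "mean"]
        )
    if {"low", "high"} <= set(mm.index):
        differences["maternal_high_minus_low"] = float(
            mm.at["high", "mean"] - mm.at["low", "mean"]
        )
    if {"medium", "high"} <= set(mm.index):
        differences["maternal_high_minus_medium"] = float(
            mm.at["high", "mean"] - mm.at["medium", "mean"]
        )
    return GroupSummaryTable(
        cells=cells,
        cell_sd=cell_sd,
        cell_n=cell_n,
        marginal_direct=md,
        marginal_maternal=mm,
        overall_mean=float(merged["adg_0_35"].mean()),
        overall_sd=float(merged["adg_0_35"].std(ddof=1)),
        differences=differences,
    )


def age_summary(milk: pd.DataFrame, growth: pd.DataFrame, days=None) -> pd.DataFrame:
    """Per-measurement-day mean (SD) of ADG (g/day), MY (mL/day) and TMS (g/day).

    ``days`` defaults to the standard measurement days (15, 21, 35) plus any
    observed day; days with no records appear as missing rows (n = 0).
    A single record yields SD 0.
    """
    if days is None:
        days = sorted({15, 21, 35} | set(milk["day"]) | set(growth["age"]))

    def _sd(series):
        return float(series.std(ddof=1)) if len(series) > 1 else (0.0 if len(series) else np.nan)

    rows = []
    for day in days:
        m = milk.loc[milk["day"] == day]
        g = growth.loc[growth["age"] == day]
        rows.append(
            {
                "day": day,
                "adg_mean": g["adg"].mean() if len(g) else np.nan,
                "adg_sd": _sd(g["adg"]),
                "n_adg": len(g),
                "my_ml_mean": float(dl_to_ml(m["my_dl"]).mean()) if len(m) else np.nan,
                "my_ml_sd": _sd(pd.Series(dl_to_ml(m["my_dl"]))),
                "tms_mean": m["tms"].mean() if len(m) else np.nan,
                "tms_sd": _sd(m["tms"]),
                "n_milk": len(m),
            }
        )
        if not len(m) and not len(g):
            logger.warning("day %s has no records; row flagged missing", day)
    return pd.DataFrame(rows).set_index("day")


def phenotypic_correlations(milk: pd.DataFrame, growth: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations of (MY, ADG), (TMS, ADG) and (MY, TMS) on matched
    dam-day / lamb-period pairs, per day and pooled."""
    pairs = growth.merge(
        milk[["milk_id", "my_dl", "tms"]], on="milk_id", how="inner"
    )
    if len(pairs) < 3:
        raise ValueError("fewer than 3 matched milk-growth pairs")

    def _cors(df_sub, label):
        return {
            "scope": label,
            "n": len(df_sub),
            "my_adg": _pearson(df_sub["my_dl"], df_sub["adg"]),
            "tms_adg": _pearson(df_sub["tms"], df_sub["adg"]),
            "my_tms": _pearson(df_sub["my_dl"], df_sub["tms"]),
        }

    rows = [_cors(pairs, "pooled")]
    for day in sorted(pairs["age"].unique()):
        sub = pairs.loc[pairs["age"] == day]
        if len(sub) >= 3:
            rows.append(_cors(sub, f"day{day}"))
    return pd.DataFrame(rows).set_index("scope")


def _pearson(a: pd.Series, b: pd.Series) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def fce_table(milk: pd.DataFrame, growth: pd.DataFrame) -> pd.DataFrame:
    """Per matched record: milk consumed (L/day), ADG (g/day) and FCE."""
    pairs = growth.merge(milk[["milk_id", "my_dl"]], on="milk_id", how="inner")
    pairs = pairs.loc[pairs["adg"] != 0].copy()
    pairs["milk_l"] = dl_to_l(pairs["my_dl"])
    pairs["fce"] = compute_fce(pairs["milk_l"].to_numpy(), pairs["adg"].to_numpy())
    return pairs[["lamb", "age", "milk_l", "adg", "fce"]]


def plot_fce(milk: pd.DataFrame, growth: pd.DataFrame, path) -> None:
    """Minimal FCE-vs-MY and FCE-vs-ADG scatter export."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tab = fce_table(milk, growth)
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    axes[0].scatter(tab["milk_l"], tab["fce"], s=8, alpha=0.5)
    axes[0].set_xlabel("milk yield (L/day)")
    axes[0].set_ylabel("FCE (L milk per g gain)")
    axes[1].scatter(tab["adg"], tab["fce"], s=8, alpha=0.5)
    axes[1].set_xlabel("ADG (g/day)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
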