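"""Interaction testing and heritability computation.

The genotype-by-maternal-environment interaction is tested with the restricted
likelihood ratio test comparing the recursive intercept model (no u_slope
term) to the recursive linear reaction-norm model:

    RLRT = -2 logL(intercept) + 2 logL(reaction norm).

Because the null value of the slope variance sits on the boundary of the
parameter space (and two covariances vanish with it), the RLRT null
distribution is not a simple chi-square.  The default calibration is a
parametric bootstrap from the fitted intercept model; a 50:50 chi2(0):chi2(1)
mixture and a naive chi2(3) are offered as fast, labelled approximations.

Heritabilities follow the source formulas: h2_MILK = s2_v / (s2_v + s2_e1);
for ADG, h2_direct = s2_int / s2_P and h2_mat = beta^2 s2_v / s2_P, where the
phenotypic variance s2_P is computed under two declared variants (the
"as-printed" literal term list is ambiguous in its source; see
``phenotypic_variance_report``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .remlfit import (
    DesignBundle,
    FitOptions,
    FitResult,
    VarianceComponents,
    fit_reml,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# RLRT

@dataclass
class RLRTResult:
    """Restricted likelihood ratio test of the reaction-norm slope terms."""

    statistic: float
    calibration: str
    p_value: float | None
    n_boundary_parameters: int
    n_bootstrap: int = 0
    bootstrap_statistics: np.ndarray | None = field(default=None, repr=False)

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_value is not None and self.p_value <= alpha


def rlrt_statistic(fit_intercept: FitResult, fit_rn: FitResult, tol: float = 1e-6) -> float:
    """-2 logL(intercept) + 2 logL(reaction norm), clipped to zero at -tol."""
    stat = -2.0 * fit_intercept.loglik + 2.0 * fit_rn.loglik
    if stat < -tol:
        logger.warning(
            "reaction-norm logL below intercept logL by %.3g; clipping RLRT to 0",
            -stat,
        )
    return max(stat, 0.0)


def _check_comparable(fit_intercept: FitResult, fit_rn: FitResult) -> None:
    if fit_intercept.x_labels != fit_rn.x_labels:
        raise ValueError(
            "REML likelihood ratio test requires identical fixed-effect structures"
        )
    if not (fit_intercept.converged and fit_rn.converged):
        raise ValueError("both fits must have converged for the RLRT")
    if fit_intercept.spec.kind != "intercept" or fit_rn.spec.kind != "reaction_norm":
        raise ValueError("expected an intercept fit and a reaction-norm fit")


def simulate_from_fit(
    bundle: DesignBundle, fit: FitResult, rng: np.random.Generator
) -> DesignBundle:
    """Parametric draw of new (milk, growth) responses from a fitted model.

    The recursive structure is respected: milk responses are simulated first,
    then each growth response uses its dam's *simulated* milk value as the
    structural covariate (and, for a reaction-norm fit, as the slope
    covariate).  Returns a new bundle sharing the design.
    """
    b = bundle
    vc = fit.vc
    effects = b.effects
    Gk = vc.genetic_matrix(effects)
    # genetic draw with covariance Gk (x) A: columns are effects
    Lg = _psd_chol(Gk)
    gmat = b.chol_A() @ rng.standard_normal((b.q, len(effects))) @ Lg.T
    gval = {e: gmat[:, i] for i, e in enumerate(effects)}

    bhat = fit.fixed_effects["estimate"].to_numpy()
    mean_all = b.X @ bhat
    beta_hat = bhat[b.x_cov_col] if b.x_cov_col is not None else 0.0
    if b.x_cov_col is not None:
        mean_all = mean_all - beta_hat * b.X[:, b.x_cov_col]

    s11, s12, s22 = vc.sigma2_e1, vc.sigma_e12, vc.sigma2_e2
    cond = s22 - (s12 ** 2 / s11 if s11 > 0 else 0.0)
    n_milk = len(b.rows_milk)
    eps1 = math.sqrt(max(s11, 0.0)) * rng.standard_normal(n_milk)
    milk_y = mean_all[b.rows_milk] + gval["v"][b.z_cols["v"]] + eps1

    growth_y = None
    if len(b.rows_growth):
        milk_pos = {r: i for i, r in enumerate(b.rows_milk)}
        eps1_of_growth = eps1[[milk_pos[r] for r in b.milk_row_of_growth]]
        eps2 = (s12 / s11 if s11 > 0 else 0.0) * eps1_of_growth
        eps2 = eps2 + math.sqrt(max(cond, 0.0)) * rng.standard_normal(len(b.rows_growth))
        cov_new = milk_y[[milk_pos[r] for r in b.milk_row_of_growth]] - b.center
        growth_y = mean_all[b.rows_growth] + beta_hat * cov_new + eps2
        growth_y = growth_y + gval["int"][b.z_cols["int"]]
        if "slope" in effects:
            growth_y = growth_y + gval["slope"][b.z_cols["slope"]] * cov_new
    return b.with_response(milk_y, growth_y)


def _psd_chol(mat: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh((mat + mat.T) / 2)
    w = np.clip(w, 0.0, None)
    return v @ np.diag(np.sqrt(w))


def fit_interaction_models(
    bundle_intercept: DesignBundle,
    bundle_rn: DesignBundle,
    options: FitOptions | None = None,
    cold_start: bool = True,
) -> tuple[FitResult, FitResult]:
    """Fit the intercept and reaction-norm models for an RLRT comparison.

    The reaction-norm model is warm-started at the intercept solution with a
    likelihood-neutral slope seed, which makes the nesting inequality
    logL(reaction norm) >= logL(intercept) hold up to optimizer tolerance by
    construction (a single arbitrary start does not guarantee it).  With
    ``cold_start`` the default moment start is also tried and the better
    optimum kept; calibration loops may disable it for speed since the warm
    start alone preserves nesting and the bootstrap uses the same regime.
    """
    from dataclasses import replace as _replace

    opts = options or FitOptions()
    fit0 = fit_reml(bundle_intercept, options=opts)
    # the slope seed must be likelihood-neutral: on a dL-scale covariate even
    # 1e-2 of slope variance shifts logL by ~0.2 and strands the optimizer
    warm = _replace(
        fit0.vc, sigma2_slope=1e-6, cov_int_slope=0.0, cov_slope_v=0.0, beta=None
    )
    fit1 = fit_reml(bundle_rn, init=warm, options=opts)
    if cold_start:
        fit1_cold = fit_reml(bundle_rn, options=opts)
        if fit1_cold.loglik > fit1.loglik:
            fit1 = fit1_cold
    return fit0, fit1


def rlrt(
    fit_intercept: FitResult,
    fit_rn: FitResult,
    calibration: str = "parametric_bootstrap",
    bundle_intercept: DesignBundle | None = None,
    bundle_rn: DesignBundle | None = None,
    n_boot: int = 99,
    seed: int = 0,
    fit_options: FitOptions | None = None,
) -> RLRTResult:
    """Restricted likelihood ratio test for the reaction-norm slope terms.

    ``calibration`` is one of ``parametric_bootstrap`` (default; simulates
    from the fitted intercept model and refits both models to each draw),
    ``chi2_mixture`` (50:50 chi2(0):chi2(1)) or ``chi2_3`` (slope variance
    plus its two covariances counted as three free parameters).
    """
    _check_comparable(fit_intercept, fit_rn)
    stat = rlrt_statistic(fit_intercept, fit_rn)
    n_boundary = len(fit_rn.spec.effects) * (len(fit_rn.spec.effects) + 1) // 2 - \
        len(fit_intercept.spec.effects) * (len(fit_intercept.spec.effects) + 1) // 2

    if calibration == "chi2_mixture":
        p = 0.5 * float(stats.chi2.sf(stat, 1)) + (0.5 if stat <= 0 else 0.0)
        return RLRTResult(stat, calibration, p, n_boundary)
    if calibration == "chi2_3":
        p = float(stats.chi2.sf(stat, 3))
        return RLRTResult(stat, calibration, p, n_boundary)
    if calibration != "parametric_bootstrap":
        raise ValueError(f"unknown calibration {calibration!r}")
    if bundle_intercept is None or bundle_rn is None:
        raise ValueError("parametric bootstrap needs the intercept and RN bundles")

    opts = fit_options or FitOptions(n_starts=1)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 808]))
    boot = np.empty(n_boot)
    for bdx in range(n_boot):
        sim0 = simulate_from_fit(bundle_intercept, fit_intercept, rng)
        sim1 = bundle_rn.with_response(
            sim0.y[sim0.rows_milk], sim0.y[sim0.rows_growth] if len(sim0.rows_growth) else None
        )
        # warm starts at the parent estimates speed up the refits materially
        f0 = fit_reml(sim0, init=fit_intercept.vc, options=opts)
        f1 = fit_reml(sim1, init=fit_rn.vc, options=opts)
        boot[bdx] = rlrt_statistic(f0, f1)
    p = (1.0 + float(np.sum(boot >= stat))) / (n_boot + 1.0)
    return RLRTResult(stat, calibration, p, n_boundary, n_boot, boot)


# ---------------------------------------------------------------------------
# heritabilities

@dataclass
class HeritabilitySet:
    """Milk, direct and maternal heritabilities with the s2_P variant used."""

    h2_milk: float
    h2_direct: float
    h2_mat: float
    sigma2_p: float
    variant: str
    se_h2_milk: float | None = None


def phenotypic_variance(vc: VarianceComponents, variant: str = "as_printed") -> float:
    """ADG phenotypic variance under one of two declared term lists.

    ``as_printed`` reads the source's term list literally:
    s2_int + s2_e2 + beta^2 s2_e1 + cov_int_v + beta^2 s2_v + s2_e1.
    ``conventional`` is the variance implied by the recursive model:
    s2_int + s2_e2 + beta^2 (s2_v + s2_e1) + 2 beta cov_int_v.
    """
    beta = vc.beta if vc.beta is not None else 0.0
    if variant == "as_printed":
        return (
            vc.sigma2_int + vc.sigma2_e2 + beta ** 2 * vc.sigma2_e1
            + vc.cov_int_v + beta ** 2 * vc.sigma2_v + vc.sigma2_e1
        )
    if variant == "conventional":
        return (
            vc.sigma2_int + vc.sigma2_e2
            + beta ** 2 * (vc.sigma2_v + vc.sigma2_e1)
            + 2.0 * beta * vc.cov_int_v
        )
    raise ValueError(f"unknown sigma2_P variant {variant!r}")


def heritabilities(vc: VarianceComponents, variant: str = "as_printed") -> HeritabilitySet:
    """Heritabilities from variance components.

    h2_MILK is variant-free; the direct and maternal heritabilities divide by
    the requested s2_P variant.
    """
    denom_milk = vc.sigma2_v + vc.sigma2_e1
    if denom_milk <= 0:
        if vc.sigma2_v == 0:
            return HeritabilitySet(0.0, 0.0, 0.0, phenotypic_variance(vc, variant), variant)
        raise ZeroDivisionError("milk phenotypic variance is zero")
    h2_milk = vc.sigma2_v / denom_milk
    s2p = phenotypic_variance(vc, variant)
    if s2p <= 0:
        raise ZeroDivisionError("ADG phenotypic variance is not positive")
    beta = vc.beta if vc.beta is not None else 0.0
    return HeritabilitySet(
        h2_milk=float(h2_milk),
        h2_direct=float(vc.sigma2_int / s2p),
        h2_mat=float(beta ** 2 * vc.sigma2_v / s2p),
        sigma2_p=float(s2p),
        variant=variant,
    )


def phenotypic_variance_report(
    vc: VarianceComponents, reference: dict | None = None, tol: float = 0.005
) -> dict:
    """Both s2_P variants side by side, with agreement flags against a reference.

    ``reference`` may contain ``h2_direct``, ``h2_mat`` and ``sigma2_p``
    values to compare against (e.g. previously published estimates).  The
    report never silently corrects a variant towards the reference: if neither
    variant matches, ``any_variant_matches_reference`` is False and the
    discrepancy is flagged.
    """
    report: dict = {"variants": {}}
    for variant in ("as_printed", "conventional"):
        h = heritabilities(vc, variant)
        entry = {
            "sigma2_p": h.sigma2_p,
            "h2_direct": h.h2_direct,
            "h2_mat": h.h2_mat,
            "h2_milk": h.h2_milk,
        }
        if reference:
            matches = {}
            for key in ("h2_direct", "h2_mat", "sigma2_p"):
                if key in reference:
                    ref = float(reference[key])
                    scale = max(abs(ref), 1e-12)
                    rtol = tol if abs(ref) <= 1 else 0.01
                    matches[key] = abs(entry[key] - ref) / scale <= rtol
            entry["matches_reference"] = matches
            entry["variant_matches_reference"] = all(matches.values()) if matches else True
        report["variants"][variant] = entry
    if reference:
        report["reference"] = dict(reference)
        report["any_variant_matches_reference"] = any(
            v["variant_matches_reference"] for v in report["variants"].values()
        )
        if not report["any_variant_matches_reference"]:
            report["discrepancy_flag"] = (
                "neither sigma2_P variant reproduces the reference heritabilities/"
                "phenotypic variance; values are reported as computed"
            )
            logger.warning(report["discrepancy_flag"])
    return report


# ---------------------------------------------------------------------------
# nested LRT and step-down fixed-effect selection (single-trait ML fits)

@dataclass
class OLSFit:
    """Maximum-likelihood ordinary linear model fit (no relationships)."""

    terms: tuple
    loglik: float
    n_params: int
    method: str = "ml"
    x_labels: list = field(default_factory=list)


def nested_lrt(fit_full, fit_reduced, df: int) -> tuple[float, float]:
    """Chi-square LRT of nested fixed-effect structures fitted by ML.

    Returns ``(statistic, p_value)``.  Raises if either fit is not an ML fit
    or if the reduced model is not nested in the full one.
    """
    for f in (fit_full, fit_reduced):
        if getattr(f, "method", None) != "ml":
            raise ValueError("nested_lrt requires ML fits (REML logLs are not comparable)")
    full_terms = getattr(fit_full, "terms", None)
    red_terms = getattr(fit_reduced, "terms", None)
    if full_terms is not None and red_terms is not None:
        if not set(red_terms) <= set(full_terms):
            raise ValueError("reduced model terms are not a subset of the full model")
    if df < 0:
        raise ValueError("degrees of freedom must be >= 0")
    stat = max(2.0 * (fit_full.loglik - fit_reduced.loglik), 0.0)
    p = 1.0 if df == 0 else float(stats.chi2.sf(stat, df))
    return stat, p


def ols_ml_fit(df: pd.DataFrame, response: str, terms, covariates=()) -> OLSFit:
    """Profile-ML Gaussian linear model fit used by the selection driver."""
    from .remlfit import encode_fixed_effects

    X, labels = encode_fixed_effects(df, terms)
    for cov in covariates:
        X = np.column_stack([X, df[cov].to_numpy(dtype=float)])
        labels = labels + [cov]
    beta, *_ = np.linalg.lstsq(X, df[response].to_numpy(dtype=float), rcond=None)
    resid = df[response].to_numpy(dtype=float) - X @ beta
    n = len(df)
    s2 = float(resid @ resid) / n
    loglik = -0.5 * n * (math.log(2 * math.pi * max(s2, 1e-300)) + 1.0)
    return OLSFit(terms=tuple(terms), loglik=loglik, n_params=X.shape[1], x_labels=labels)


def select_fixed_effects(
    df: pd.DataFrame,
    response: str,
    candidate_terms,
    alpha: float = 0.05,
    covariates=(),
) -> tuple[list, list]:
    """Step-down elimination of fixed-effect terms by nested ML likelihood-ratio
    tests at level ``alpha`` (hierarchy respected: a main effect is not tested
    while one of its interactions remains).

    Returns ``(retained_terms, elimination_log)``; the log records each tested
    term with its statistic and p-value in elimination order.
    """
    current = [tuple(t) for t in candidate_terms]
    log: list = []
    while True:
        full = ols_ml_fit(df, response, current, covariates)
        droppable = [
            t for t in current
            if len(t) == 2
            or not any(len(u) == 2 and t[0] in u for u in current)
        ]
        if not droppable:
            break
        results = []
        for t in droppable:
            reduced_terms = [u for u in current if u != t]
            reduced = ols_ml_fit(df, response, reduced_terms, covariates)
            df_diff = max(full.n_params - reduced.n_params, 0)
            stat, p = nested_lrt(full, reduced, df_diff)
            results.append((t, stat, p, df_diff))
        results.sort(key=lambda r: (-r[2], r[0]))
        worst = results[0]
        if worst[2] > alpha:
            current = [u for u in current if u != worst[0]]
            log.append(
                {"term": worst[0], "statistic": worst[1], "p_value": worst[2],
                 "df": worst[3], "action": "dropped"}
            )
        else:
            for t, stat, p, dfd in results:
                log.append(
                    {"term": t, "statistic": stat, "p_value": p, "df": dfd,
                     "action": "retained"}
                )
            break
    return current, log
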