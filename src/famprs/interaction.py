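"""Attributable fractions, joint effects, and interaction on two scales.

For a binary exposure with adjusted odds ratio OR (rare-disease /
case-control setting), the attributable fraction in the exposed is
AF_exposed = (OR - 1)/OR and the population attributable fraction uses
Miettinen's case-based form AF_population = p_c * (OR - 1)/OR, with p_c the
exposure prevalence among cases.

Interaction between family history (FH) and the PRS is assessed on the
multiplicative scale (Wald test of the FH x PRS product term, with a
likelihood-ratio cross-check) and on the additive scale via the relative
excess risk due to interaction,

    RERI = OR11 - OR10 - OR01 + 1,

computed from a single covariate-adjusted logistic fit of the four-level
joint exposure (FH x dichotomized PRS), with a delta-method
(Hosmer-Lemeshow) confidence interval from the coefficient covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from famprs.regression import FitResult, ModelSpec, build_design, logistic_fit


@dataclass
class AFResult:
    af_exposed: float
    af_population: float | None
    odds_ratio: float
    p_cases: float | None  # exposure prevalence among cases
    method: str = "miettinen_case_based"


@dataclass
class RERIResult:
    reri: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    sided: str = "two_sided"


@dataclass
class InteractionResult:
    joint_or: pd.DataFrame  # rows (fh, prs_top): or, ci, p; reference == 1
    reri: RERIResult
    fit: FitResult
    gamma: float | None = None  # multiplicative product-term estimate
    gamma_se: float | None = None
    gamma_p: float | None = None
    gamma_p_lrt: float | None = None
    stratified: pd.DataFrame | None = None
    notes: list[str] = field(default_factory=list)


def attributable_fractions(
    or_adjusted: float, p_c: float | None = None, ndigits: int | None = None
) -> AFResult:
    """Attributable fractions from an adjusted odds ratio.

    ``p_c`` is the exposure prevalence among cases; when omitted only
    AF_exposed is returned. ``ndigits`` applies reporting rounding.
    """
    if or_adjusted <= 0:
        raise ValueError("odds ratio must be positive")
    if p_c is not None and not 0 <= p_c <= 1:
        raise ValueError("p_c must lie in [0, 1]")
    af_e = (or_adjusted - 1.0) / or_adjusted
    af_p = None if p_c is None else p_c * af_e
    if ndigits is not None:
        af_e = round(af_e, ndigits)
        af_p = None if af_p is None else round(af_p, ndigits)
    return AFResult(af_exposed=af_e, af_population=af_p,
                    odds_ratio=or_adjusted, p_cases=p_c)


JOINT_TERMS = ("fh1_prs0", "fh0_prs1", "fh1_prs1")


def _joint_design(df: pd.DataFrame, covariates, outcome, n_pcs, include_pcs):
    spec = ModelSpec(outcome=outcome, predictor_set="fh_plus_prs",
                     prs_form="top_tertile", covariates=tuple(covariates),
                     extra_covariates=(), n_pcs=n_pcs if include_pcs else 0)
    need = [outcome, "family_history", "prs_top_tertile", *covariates]
    if include_pcs:
        need += [f"pc{j+1}" for j in range(n_pcs) if f"pc{j+1}" in df.columns]
    sub = df[need].dropna()
    fh = sub["family_history"].astype(bool).to_numpy()
    top = sub["prs_top_tertile"].astype(bool).to_numpy()
    for cell, mask in (("fh=1,prs=0", fh & ~top), ("fh=0,prs=1", ~fh & top),
                       ("fh=1,prs=1", fh & top), ("fh=0,prs=0", ~fh & ~top)):
        if not mask.any():
            raise ValueError(f"empty joint-exposure cell: {cell}")
    y, X = build_design(sub, spec)
    # replace the two main-effect columns with the 4-level factor coding
    X = X.drop(columns=["family_history", "prs_top_tertile"])
    X.insert(1, "fh1_prs0", (fh & ~top).astype(float))
    X.insert(2, "fh0_prs1", (~fh & top).astype(float))
    X.insert(3, "fh1_prs1", (fh & top).astype(float))
    return y, X


def joint_effects(
    df: pd.DataFrame,
    covariates=("age", "sex", "pack_years"),
    outcome: str = "copd_case",
    n_pcs: int = 5,
    include_pcs: bool = True,
    sided: str = "two_sided",
) -> InteractionResult:
    """Joint effects of FH and the dichotomized PRS, plus RERI.

    Fits one logistic model with a four-level joint-exposure factor
    (reference: no family history, bottom two PRS tertiles) and the usual
    covariates; odds ratios are against the double-negative reference, and
    RERI comes from the same fit.
    """
    y, X = _joint_design(df, covariates, outcome, n_pcs, include_pcs)
    fit = logistic_fit(X, y)
    zc = stats.norm.ppf(0.975)
    rows = [{"fh": 0, "prs_top": 0, "term": "reference", "or": 1.0,
             "ci_low": 1.0, "ci_high": 1.0, "p_value": np.nan}]
    for term, (fh_v, prs_v) in zip(JOINT_TERMS, ((1, 0), (0, 1), (1, 1))):
        b, s = fit.params[term], fit.bse[term]
        rows.append({
            "fh": fh_v, "prs_top": prs_v, "term": term,
            "or": float(np.exp(b)),
            "ci_low": float(np.exp(b - zc * s)),
            "ci_high": float(np.exp(b + zc * s)),
            "p_value": float(fit.pvalues[term]),
        })
    reri = reri_from_joint(fit, sided=sided)
    return InteractionResult(joint_or=pd.DataFrame(rows), reri=reri, fit=fit)


def _reri_delta(or10, or01, or11, grad_terms, cov):
    """Delta-method RERI inference from log-OR gradient contributions."""
    reri = or11 - or10 - or01 + 1.0
    g = np.zeros(cov.shape[0])
    for idx, val in grad_terms:
        g[idx] += val
    var = float(g @ cov @ g)
    se = float(np.sqrt(max(var, 0.0)))
    return reri, se


def _finish_reri(reri, se, sided):
    zc = stats.norm.ppf(0.975)
    if se == 0:
        p = np.nan
    else:
        z = reri / se
        p = stats.norm.sf(abs(z)) * (2 if sided == "two_sided" else 1)
    return RERIResult(reri=float(reri), se=se, ci_low=float(reri - zc * se),
                      ci_high=float(reri + zc * se), p_value=float(p),
                      sided=sided)


def reri_from_joint(fit: FitResult, sided: str = "two_sided") -> RERIResult:
    """RERI from a four-level joint-exposure fit (terms fh1_prs0 etc.)."""
    names = list(fit.params.index)
    try:
        i10, i01, i11 = (names.index(t) for t in JOINT_TERMS)
    except ValueError as e:
        raise ValueError(f"fit lacks joint-exposure terms {JOINT_TERMS}: {e}")
    b = fit.params.to_numpy()
    cov = fit.cov_params.to_numpy()
    or10, or01, or11 = np.exp(b[i10]), np.exp(b[i01]), np.exp(b[i11])
    reri, se = _reri_delta(
        or10, or01, or11,
        [(i10, -or10), (i01, -or01), (i11, or11)], cov)
    return _finish_reri(reri, se, sided)


def reri_from_product_term(
    fit: FitResult,
    fh_term: str = "family_history",
    prs_term: str = "prs_top_tertile",
    product_term: str = "fh_x_prs",
    sided: str = "two_sided",
) -> RERIResult:
    """RERI from a main-effects + product-term parameterization.

    OR10 = exp(b_fh), OR01 = exp(b_prs), OR11 = exp(b_fh + b_prs + g);
    identical to the four-level coding on the same data (the two designs
    span the same space). With a continuous PRS the ORs are evaluated at a
    +1 SD contrast of the named PRS column.
    """
    names = list(fit.params.index)
    i_f, i_p, i_x = (names.index(t) for t in (fh_term, prs_term, product_term))
    b = fit.params.to_numpy()
    cov = fit.cov_params.to_numpy()
    or10 = np.exp(b[i_f])
    or01 = np.exp(b[i_p])
    or11 = np.exp(b[i_f] + b[i_p] + b[i_x])
    reri, se = _reri_delta(
        or10, or01, or11,
        [(i_f, -or10 + or11), (i_p, -or01 + or11), (i_x, or11)], cov)
    return _finish_reri(reri, se, sided)


def multiplicative_interaction_test(
    df: pd.DataFrame,
    covariates=("age", "sex", "pack_years"),
    outcome: str = "copd_case",
    prs_col: str = "prs_z",
    n_pcs: int = 5,
    include_pcs: bool = True,
) -> dict:
    """Wald (and LRT) test of the FH x PRS product term.

    Returns the full product-term fit plus {gamma, se, p_wald, p_lrt}.
    """
    spec = ModelSpec(outcome=outcome, predictor_set="fh_plus_prs",
                     prs_form="continuous_z" if prs_col == "prs_z" else "top_tertile",
                     covariates=tuple(covariates), extra_covariates=(),
                     n_pcs=n_pcs if include_pcs else 0)
    y, X = build_design(df, spec)
    X["fh_x_prs"] = X["family_history"] * X[prs_col]
    full = logistic_fit(X, y)
    reduced = logistic_fit(X.drop(columns="fh_x_prs"), y)
    lrt = 2 * (full.loglik - reduced.loglik)
    p_lrt = stats.chi2.sf(max(lrt, 0.0), df=1)
    return {
        "gamma": float(full.params["fh_x_prs"]),
        "se": float(full.bse["fh_x_prs"]),
        "p_wald": float(full.pvalues["fh_x_prs"]),
        "p_lrt": float(p_lrt),
        "fit": full,
        "fit_reduced": reduced,
    }


def stratified_estimates(
    df: pd.DataFrame,
    stratum: str = "family_history",
    covariates=("age", "sex", "pack_years"),
    outcome: str = "copd_case",
    prs_col: str = "prs_z",
    n_pcs: int = 5,
) -> pd.DataFrame:
    """PRS odds ratios within exposure strata (model-2-style fits)."""
    rows = []
    strata = df[stratum].dropna().unique()
    if len(strata) < 2:
        raise ValueError(f"need both strata of {stratum!r} non-empty")
    for level in sorted(strata, key=bool):
        sub = df[df[stratum] == level]
        spec = ModelSpec(outcome=outcome, predictor_set="prs_only",
                         prs_form="continuous_z" if prs_col == "prs_z" else "top_tertile",
                         covariates=tuple(covariates), extra_covariates=(),
                         n_pcs=n_pcs)
        y, X = build_design(sub, spec)
        fit = logistic_fit(X, y)
        b, s = fit.params[prs_col], fit.bse[prs_col]
        zc = stats.norm.ppf(0.975)
        rows.append({
            "stratum": f"{stratum}={level}", "n": fit.n_used,
            "or": float(np.exp(b)),
            "ci_low": float(np.exp(b - zc * s)),
            "ci_high": float(np.exp(b + zc * s)),
            "p_value": float(fit.pvalues[prs_col]),
        })
    return pd.DataFrame(rows)
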