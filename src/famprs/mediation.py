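"""Exposure-mediator correlation and natural-effects mediation.

Biserial correlation treats the binary exposure (family history) as a
dichotomized latent standard normal and estimates its correlation with the
observed continuous mediator (the PRS). Two estimators are provided:

* ``closed_form``: r_b = r_pb * sqrt(p*(1-p)) / phi(Phi^-1(p)), converting
  the Pearson point-biserial r_pb (p = positive-class fraction);
* ``binned_ml``: a two-step latent-bivariate-normal ML estimator with the
  continuous variable cut into 10 equal-count bins (the polyserial-style
  procedure applied to a decile-binned score).

Mediation uses the imputation-based natural-effects model: the outcome
model logit P(Y=1 | x, m, c) is fitted, each record is expanded into
counterfactual rows over hypothetical exposure levels with the observed
mediator held fixed, imputed outcome expectations are attached, and the
natural-effects logistic model logit E[Y(x0, M(x1))] ~ x0 + x1 + c is
fitted on the expanded data. The coefficient on x0 is the natural direct
effect (NDE), on x1 the natural indirect effect through the mediator
(NIE), both on the log-odds scale; proportion mediated = NIE/(NDE+NIE).
Inference is by nonparametric bootstrap over subjects. Validity assumes no
unmeasured exposure-outcome, mediator-outcome or exposure-mediator
confounding beyond the supplied covariates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from famprs.regression import logistic_fit

logger = logging.getLogger(__name__)


@dataclass
class CorrelationResult:
    r_biserial: float
    r_point_biserial: float
    p_positive: float  # prevalence of the binary variable
    p_value: float  # from the point-biserial t test
    method: str
    n: int


@dataclass
class MediationResult:
    nde: float
    nie: float
    total: float
    proportion_mediated: float
    nde_ci: tuple[float, float] | None
    nie_ci: tuple[float, float] | None
    total_ci: tuple[float, float] | None
    proportion_mediated_ci: tuple[float, float] | None
    nde_p: float | None
    nie_p: float | None
    proportion_stable: bool
    n_used: int
    n_boot: int
    seed: int | None


# ------------------------------------------------------------- correlation

def _closed_form_biserial(d: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    r_pb, p_val = stats.pearsonr(d, x)
    p = d.mean()
    z = stats.norm.ppf(p)
    r_b = r_pb * np.sqrt(p * (1 - p)) / stats.norm.pdf(z)
    return float(r_b), float(r_pb)


def _binned_ml_biserial(d: np.ndarray, x: np.ndarray, bins: int = 10) -> float:
    """Two-step latent-normal estimate from a 2 x ``bins`` contingency table.

    Thresholds are fixed at the normal quantiles of the empirical margins
    (equal-count bins for the continuous variable; the observed prevalence
    for the binary one); the latent correlation rho maximizes the
    multinomial likelihood of the table under a bivariate normal.
    """
    n = len(d)
    qs = np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1])
    cat = np.searchsorted(qs, x, side="right")  # 0..bins-1
    counts = np.zeros((2, bins))
    for di, ci in zip(d.astype(int), cat):
        counts[di, ci] += 1
    cum = np.concatenate([[0.0], np.searchsorted(np.sort(x), qs, side="right") / n,
                          [1.0]])
    a = stats.norm.ppf(np.clip(cum, 1e-10, 1 - 1e-10))  # bin edges, latent scale
    a[0], a[-1] = -np.inf, np.inf
    tau = stats.norm.ppf(1 - d.mean())  # binary threshold: D=1 iff latent > tau

    def bvn_cdf(h, k, rho):
        if np.isinf(h) and h > 0:
            return stats.norm.cdf(k)
        if np.isinf(k) and k > 0:
            return stats.norm.cdf(h)
        if np.isinf(h) or np.isinf(k):
            return 0.0
        return stats.multivariate_normal(
            mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]).cdf([h, k])

    def negll(rho):
        ll = 0.0
        for j in range(bins):
            lo, hi = a[j], a[j + 1]
            # P(lo < U <= hi, V <= tau) for D=0 row
            p_low = bvn_cdf(hi, tau, rho) - bvn_cdf(lo, tau, rho)
            p_col = stats.norm.cdf(hi) - stats.norm.cdf(lo)
            p_high = p_col - p_low
            for row, pr in ((0, p_low), (1, p_high)):
                if counts[row, j] > 0:
                    ll += counts[row, j] * np.log(max(pr, 1e-300))
        return -ll

    res = optimize.minimize_scalar(negll, bounds=(-0.999, 0.999), method="bounded")
    return float(res.x)


def biserial_correlation(
    fh, prs, method: str = "closed_form", bins: int = 10
) -> CorrelationResult:
    """Biserial correlation between a binary exposure and a continuous score."""
    d = np.asarray(fh, dtype=float)
    x = np.asarray(prs, dtype=float)
    keep = np.isfinite(d) & np.isfinite(x)
    d, x = d[keep], x[keep]
    if len(np.unique(d)) < 2:
        raise ValueError("binary variable has a single class")
    if len(np.unique(x)) < 3:
        raise ValueError("need >=3 distinct continuous values")
    r_closed, r_pb = _closed_form_biserial(d, x)
    _, p_val = stats.pearsonr(d, x)
    if method == "closed_form":
        r = r_closed
    elif method == "binned_ml":
        r = _binned_ml_biserial(d, x, bins=bins)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(
        r_biserial=float(np.clip(r, -1.0, 1.0)), r_point_biserial=r_pb,
        p_positive=float(d.mean()), p_value=float(p_val), method=method,
        n=len(d),
    )


# --------------------------------------------------------------- mediation

def _ne_point(
    y: np.ndarray, x: np.ndarray, m: np.ndarray, C: np.ndarray,
    interaction: bool,
) -> tuple[float, float]:
    """One natural-effects point estimate (NDE, NIE) on the log-odds scale."""
    cols = [np.ones_like(x), x, m]
    if interaction:
        cols.append(x * m)
    Xout = np.column_stack(cols + [C])
    out_fit = logistic_fit(Xout, y)
    b = out_fit.params.to_numpy()

    def predict(x0):
        cols = [np.ones_like(x), x0, m]
        if interaction:
            cols.append(x0 * m)
        return np.column_stack(cols + [C]) @ b

    n = len(y)
    eta0 = predict(np.zeros(n))
    eta1 = predict(np.ones(n))
    from scipy.special import expit

    ytilde = np.concatenate([expit(eta0), expit(eta1)])
    x0 = np.concatenate([np.zeros(n), np.ones(n)])  # hypothetical exposure
    x1 = np.concatenate([x, x])  # exposure that set the observed mediator
    Xne = np.column_stack([np.ones(2 * n), x0, x1, np.vstack([C, C])])
    ne_fit = logistic_fit(Xne, ytilde, allow_nonbinary=True)
    beta = ne_fit.params.to_numpy()
    return float(beta[1]), float(beta[2])  # NDE, NIE


def natural_effects_mediation(
    df: pd.DataFrame,
    exposure: str = "family_history",
    mediator: str = "prs_z",
    outcome: str = "copd_case",
    covariates=("age", "sex", "pack_years"),
    interaction: bool = False,
    B: int = 1000,
    seed: int | None = 0,
    alpha: float = 0.05,
) -> MediationResult:
    """Decompose the exposure's effect into natural direct/indirect parts.

    ``B`` bootstrap resamples of subjects give percentile CIs and p-values
    (``B=0`` returns point estimates only). The proportion-mediated CI is
    reported as stable only when the bootstrapped total effect excludes 0
    in at least 97.5% of replicates.
    """
    cols = [outcome, exposure, mediator, *covariates]
    sub = df[list(cols)].dropna()
    y = sub[outcome].astype(float).to_numpy()
    x = sub[exposure].astype(float).to_numpy()
    m = pd.to_numeric(sub[mediator]).to_numpy()
    Cparts = []
    for c in covariates:
        s = sub[c]
        if c == "sex":
            Cparts.append((s == "male").astype(float).to_numpy())
        else:
            Cparts.append(pd.to_numeric(s).to_numpy())
    C = np.column_stack(Cparts) if Cparts else np.empty((len(y), 0))
    n = len(y)
    for level in (0, 1):
        if (x == level).sum() < 10:
            raise ValueError(f"non-overlap: exposure level {level} has <10 subjects")

    nde, nie = _ne_point(y, x, m, C, interaction)
    total = nde + nie
    pm = nie / total if total != 0 else np.nan

    if B <= 0:
        return MediationResult(nde, nie, total, pm, None, None, None, None,
                               None, None, proportion_stable=False,
                               n_used=n, n_boot=0, seed=seed)

    rng = np.random.default_rng(seed)
    draws = np.empty((B, 2))
    kept = 0
    for b in range(B):
        idx = rng.integers(0, n, n)
        try:
            draws[kept] = _ne_point(y[idx], x[idx], m[idx], C[idx], interaction)
            kept += 1
        except (ValueError, RuntimeError):  # degenerate resample: skip
            continue
    draws = draws[:kept]
    if kept < B:
        logger.info("mediation bootstrap: %d of %d replicates degenerate",
                    B - kept, B)
    nde_b, nie_b = draws[:, 0], draws[:, 1]
    tot_b = nde_b + nie_b
    lo, hi = 100 * alpha / 2, 100 * (1 - alpha / 2)

    def ci(a):
        return (float(np.percentile(a, lo)), float(np.percentile(a, hi)))

    def boot_p(a):
        frac = min((a <= 0).mean(), (a >= 0).mean())
        return float(min(1.0, max(2 * frac, 1.0 / kept)))

    stable = (np.sign(tot_b) == np.sign(np.median(tot_b))).mean() >= 0.975 \
        and not np.any(tot_b == 0)
    pm_b = np.divide(nie_b, tot_b, out=np.full_like(nie_b, np.nan),
                     where=tot_b != 0)
    pm_ci = ci(pm_b[np.isfinite(pm_b)]) if stable else None
    if not stable:
        logger.info("mediation: total effect unstable across bootstrap; "
                    "proportion-mediated CI withheld")
    return MediationResult(
        nde=nde, nie=nie, total=total, proportion_mediated=pm,
        nde_ci=ci(nde_b), nie_ci=ci(nie_b), total_ci=ci(tot_b),
        proportion_mediated_ci=pm_ci,
        nde_p=boot_p(nde_b), nie_p=boot_p(nie_b),
        proportion_stable=bool(stable), n_used=n, n_boot=kept, seed=seed,
    )
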