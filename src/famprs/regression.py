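"""Nested risk-model fitting: logistic MLE, Firth-penalized logistic, OLS.

Three model specifications are used throughout:

* model 1 — ``outcome ~ family_history + covariates``
* model 2 — ``outcome ~ PRS + covariates + genetic PCs``
* model 3 — ``outcome ~ family_history + PRS + covariates + genetic PCs``

All models adjust for age, sex (female reference) and pack-years of
smoking; certain outcomes take extra covariates (exacerbation outcomes:
baseline FEV1 % predicted and current smoking; 6-minute walk: height and
weight; death: BODE; CT traits: CT scanner).

Logistic models are fitted by Newton/IRLS with step-halving, a fixed start
at beta=0 and convergence when the max-abs score drops below 1e-8, so the
fit is deterministic. The Firth variant maximizes the Jeffreys-prior
penalized log-likelihood l(b) + 0.5*log det I(b) using the hat-value
adjusted score U_j = sum_i (y_i - p_i + h_i(1/2 - p_i)) x_ij, which keeps
estimates finite under separation and reduces small-sample / rare-event
bias — the standard remedy for heavily imbalanced case:control samples.
Linear models go through ordinary least squares (statsmodels).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit

MAX_ITER = 50
SCORE_TOL = 1e-8

#: outcome -> additional covariates beyond (age, sex, pack_years)
OUTCOME_EXTRA_COVARIATES: dict[str, tuple[str, ...]] = {
    "frequent_exacerbations": ("fev1_pp", "current_smoker"),
    "severe_exacerbation": ("fev1_pp", "current_smoker"),
    "sixmwd": ("height", "weight"),
    "dead": ("bode",),
    "pct_laa950": ("ct_scanner",),
    "perc15": ("ct_scanner",),
    "pi10": ("ct_scanner",),
    "wa_pct": ("ct_scanner",),
}

_BINARY_OUTCOMES = {
    "copd_case", "frequent_exacerbations", "severe_exacerbation", "dead",
}


class ConvergenceError(RuntimeError):
    pass


class SeparationError(ConvergenceError):
    pass


class RankError(ValueError):
    pass


@dataclass
class ModelSpec:
    """Declarative model definition; see module docstring for the three sets."""

    outcome: str
    predictor_set: str  # fh_only | prs_only | fh_plus_prs
    family: str | None = None  # binary | continuous (inferred if None)
    prs_form: str = "continuous_z"  # or top_tertile
    estimator: str | None = None  # mle | firth | ols (inferred if None)
    n_pcs: int = 5
    covariates: tuple[str, ...] = ("age", "sex", "pack_years")
    extra_covariates: tuple[str, ...] | None = None  # None -> by outcome

    def __post_init__(self):
        if self.predictor_set not in ("fh_only", "prs_only", "fh_plus_prs"):
            raise ValueError(f"unknown predictor_set {self.predictor_set!r}")
        if self.prs_form not in ("continuous_z", "top_tertile"):
            raise ValueError(f"unknown prs_form {self.prs_form!r}")
        if self.family is None:
            self.family = "binary" if self.outcome in _BINARY_OUTCOMES else "continuous"
        if self.estimator is None:
            self.estimator = "ols" if self.family == "continuous" else "mle"

    @property
    def prs_column(self) -> str:
        return "prs_z" if self.prs_form == "continuous_z" else "prs_top_tertile"

    def resolved_extra(self) -> tuple[str, ...]:
        if self.extra_covariates is not None:
            return tuple(self.extra_covariates)
        return OUTCOME_EXTRA_COVARIATES.get(self.outcome, ())

    def predictor_columns(self) -> list[str]:
        cols = []
        if self.predictor_set in ("fh_only", "fh_plus_prs"):
            cols.append("family_history")
        if self.predictor_set in ("prs_only", "fh_plus_prs"):
            cols.append(self.prs_column)
        return cols


@dataclass
class FitResult:
    """Fitted coefficients with Wald inference and model diagnostics."""

    params: pd.Series
    bse: pd.Series
    zvalues: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame  # columns: lower, upper
    cov_params: pd.DataFrame
    n_used: int
    loglik: float
    family: str
    estimator: str
    converged: bool
    n_iter: int
    fitted: np.ndarray
    loglik_path: list[float] = field(default_factory=list)
    r_squared: float | None = None
    r_squared_adj: float | None = None
    mse: float | None = None
    spec: ModelSpec | None = None

    @property
    def odds_ratios(self) -> pd.Series:
        if self.family != "binary":
            raise ValueError("odds ratios only defined for binary outcomes")
        return np.exp(self.params)

    def to_frame(self) -> pd.DataFrame:
        """Tidy coefficient table (term, estimate, SE, CI, OR, p)."""
        out = pd.DataFrame({
            "term": self.params.index,
            "estimate": self.params.to_numpy(),
            "se": self.bse.to_numpy(),
            "z": self.zvalues.to_numpy(),
            "ci_low": self.conf_int["lower"].to_numpy(),
            "ci_high": self.conf_int["upper"].to_numpy(),
            "p_value": self.pvalues.to_numpy(),
        })
        if self.family == "binary":
            out["or"] = np.exp(out["estimate"])
            out["or_ci_low"] = np.exp(out["ci_low"])
            out["or_ci_high"] = np.exp(out["ci_high"])
        out["n_used"] = self.n_used
        out["estimator"] = self.estimator
        return out


# ------------------------------------------------------------- design matrix

def build_design(
    df: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, pd.DataFrame]:
    """Assemble (y, X) for a spec; complete-case on all model variables.

    Sex is coded male=1 (female reference); CT scanner expands to dummies
    against the first level; genetic PCs enter only when the PRS does
    (models 2 and 3).
    """
    cols = [spec.outcome] + spec.predictor_columns() + list(spec.covariates)
    cols += list(spec.resolved_extra())
    pcs = []
    if spec.predictor_set != "fh_only":
        pcs = [f"pc{j + 1}" for j in range(spec.n_pcs) if f"pc{j + 1}" in df.columns]
        cols += pcs
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise KeyError(f"model variables absent from table: {missing}")
    sub = df[cols].copy()
    for c in cols:
        if sub[c].dtype == object and c not in ("sex", "ct_scanner", "visual_ct_subtype"):
            sub[c] = pd.to_numeric(sub[c], errors="coerce")
    sub = sub.dropna()
    y = sub.pop(spec.outcome).astype(float).to_numpy()

    parts = [pd.Series(1.0, index=sub.index, name="intercept")]
    for c in sub.columns:
        s = sub[c]
        if c == "sex":
            parts.append((s == "male").astype(float).rename("sex_male"))
        elif s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(s, prefix=c, drop_first=True, dtype=float)
            parts.extend(dummies[c2] for c2 in dummies.columns)
        else:
            parts.append(s.astype(float).rename(c))
    X = pd.concat(parts, axis=1)
    return y, X


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy()
    s = np.linalg.svd(arr, compute_uv=False)
    rank = int((s > s[0] * max(arr.shape) * np.finfo(float).eps).sum())
    if rank < arr.shape[1]:
        # name offending columns via pivoted QR
        from scipy.linalg import qr

        _, _, piv = qr(arr, mode="economic", pivoting=True)
        bad = [X.columns[j] for j in piv[rank:]]
        raise RankError(f"design matrix rank deficient; collinear column(s): {bad}")


# ----------------------------------------------------------------- logistic

def _loglik(y, p):
    eps = 1e-12
    return float(np.sum(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))


def _penalized_loglik(X, y, beta):
    p = expit(X @ beta)
    w = p * (1 - p)
    info = (X * w[:, None]).T @ X
    sign, logdet = np.linalg.slogdet(info)
    return _loglik(y, p) + 0.5 * logdet


def logistic_fit(
    X,
    y,
    firth: bool = False,
    max_iter: int = MAX_ITER,
    tol: float = SCORE_TOL,
    allow_nonbinary: bool = False,
) -> FitResult:
    """Core Newton/IRLS logistic fit on an explicit design matrix.

    ``X`` may be a DataFrame (column names kept) or array. With
    ``firth=True`` maximizes the Jeffreys-penalized likelihood; otherwise
    plain ML. ``allow_nonbinary`` admits fractional responses in [0,1]
    (quasi-likelihood), used by the natural-effects mediation step.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        names = [f"x{j}" for j in range(Xa.shape[1])]
    y = np.asarray(y, dtype=float)
    if not allow_nonbinary:
        uniq = np.unique(y)
        if not np.all(np.isin(uniq, (0.0, 1.0))):
            raise ValueError("binary outcome must be coded 0/1")
        if len(uniq) < 2:
            raise ValueError("outcome has a single class; cannot fit")
    _check_rank(pd.DataFrame(Xa, columns=names))

    beta = np.zeros(Xa.shape[1])
    objective = (lambda b: _penalized_loglik(Xa, y, b)) if firth else (
        lambda b: _loglik(y, expit(Xa @ b)))
    path = [objective(beta)]
    converged = False
    it = 0
    score = np.full_like(beta, np.inf)
    for it in range(1, max_iter + 1):
        p = expit(Xa @ beta)
        w = np.clip(p * (1 - p), 1e-12, None)
        info = (Xa * w[:, None]).T @ Xa
        if firth:
            # hat values of the weighted design
            try:
                Wh = np.sqrt(w)
                Q, _ = np.linalg.qr(Xa * Wh[:, None])
                h = np.einsum("ij,ij->i", Q, Q)
            except np.linalg.LinAlgError as e:  # pragma: no cover
                raise ConvergenceError(f"information matrix singular: {e}")
            resid = y - p + h * (0.5 - p)
        else:
            resid = y - p
        score = Xa.T @ resid
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as e:
            raise ConvergenceError(f"information matrix singular: {e}")
        # step-halving: never decrease the (penalized) log-likelihood
        cur = path[-1]
        lam = 1.0
        for _ in range(30):
            cand = beta + lam * step
            val = objective(cand)
            if np.isfinite(val) and val >= cur - 1e-10:
                break
            lam *= 0.5
        beta = beta + lam * step
        path.append(objective(beta))
    else:
        it = max_iter

    p = expit(Xa @ beta)
    if not converged:
        gnorm = float(np.max(np.abs(score)))
        if not firth and (np.max(np.abs(beta)) > 15 or np.min(p * (1 - p)) < 1e-10):
            raise SeparationError(
                "apparent (quasi-)separation: MLE diverges; refit with "
                "estimator='firth'"
            )
        raise ConvergenceError(
            f"no convergence after {max_iter} iterations (max|score|={gnorm:.3g})"
        )
    if not firth and not allow_nonbinary and np.max(np.abs(y - p)) < 1e-4:
        # score -> 0 as |beta| -> inf: convergence is illusory
        raise SeparationError(
            "apparent (quasi-)separation: MLE diverges; refit with "
            "estimator='firth'"
        )
    w = np.clip(p * (1 - p), 1e-12, None)
    info = (Xa * w[:, None]).T @ Xa
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2 * stats.norm.sf(np.abs(z))
    zc = stats.norm.ppf(0.975)
    idx = pd.Index(names, name="term")
    return FitResult(
        params=pd.Series(beta, index=idx),
        bse=pd.Series(se, index=idx),
        zvalues=pd.Series(z, index=idx),
        pvalues=pd.Series(pvals, index=idx),
        conf_int=pd.DataFrame(
            {"lower": beta - zc * se, "upper": beta + zc * se}, index=idx),
        cov_params=pd.DataFrame(cov, index=idx, columns=idx),
        n_used=len(y),
        loglik=_loglik(y, p),
        family="binary",
        estimator="firth" if firth else "mle",
        converged=converged,
        n_iter=it,
        fitted=p,
        loglik_path=path,
    )


def fit_logistic_mle(df: pd.DataFrame, spec: ModelSpec,
                     drop: Sequence[str] = ()) -> FitResult:
    """Maximum-likelihood logistic fit of a model spec on a cohort table.

    ``drop`` removes named design columns (used to test nested-model
    consistency by constraining coefficients to zero).
    """
    y, X = build_design(df, spec)
    if len(np.unique(y)) < 2:
        raise ValueError(f"outcome {spec.outcome!r} has a single class")
    if drop:
        X = X.drop(columns=list(drop))
    res = logistic_fit(X, y)
    res.spec = spec
    return res


def fit_logistic_firth(df: pd.DataFrame, spec: ModelSpec,
                       drop: Sequence[str] = ()) -> FitResult:
    """Firth-penalized logistic fit (bias-reduced; finite under separation)."""
    y, X = build_design(df, spec)
    if y.sum() == 0:
        raise ValueError("no events; Firth fit requires at least one case")
    if drop:
        X = X.drop(columns=list(drop))
    res = logistic_fit(X, y, firth=True)
    res.spec = spec
    return res


def fit_linear(df: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """OLS fit with classical SEs; stores adjusted R^2 and MSE = RSS/n."""
    y, X = build_design(df, spec)
    _check_rank(X)
    if X.shape[0] <= X.shape[1]:
        raise ValueError("fewer observations than parameters")
    ols = sm.OLS(y, X).fit()
    ci = ols.conf_int()
    ci.columns = ["lower", "upper"]
    idx = pd.Index(X.columns, name="term")
    rss = float(np.sum(ols.resid ** 2))
    res = FitResult(
        params=pd.Series(ols.params.to_numpy(), index=idx),
        bse=pd.Series(ols.bse.to_numpy(), index=idx),
        zvalues=pd.Series(ols.tvalues.to_numpy(), index=idx),
        pvalues=pd.Series(ols.pvalues.to_numpy(), index=idx),
        conf_int=ci.set_index(idx),
        cov_params=pd.DataFrame(ols.cov_params().to_numpy(), index=idx, columns=idx),
        n_used=int(ols.nobs),
        loglik=float(ols.llf),
        family="continuous",
        estimator="ols",
        converged=True,
        n_iter=0,
        fitted=np.asarray(ols.fittedvalues),
        r_squared=float(ols.rsquared),
        r_squared_adj=float(ols.rsquared_adj),
        mse=rss / int(ols.nobs),
        spec=spec,
    )
    return res


def fit_model(df: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Dispatch on the spec's family/estimator."""
    if spec.family == "continuous":
        return fit_linear(df, spec)
    if spec.estimator == "firth":
        return fit_logistic_firth(df, spec)
    return fit_logistic_mle(df, spec)


def fit_three_models(
    df: pd.DataFrame,
    outcome: str,
    estimator: str | None = None,
    prs_form: str = "continuous_z",
    n_pcs: int = 5,
) -> Mapping[int, FitResult]:
    """Fit the nested model-1/2/3 triple for one outcome."""
    out = {}
    for k, pset in ((1, "fh_only"), (2, "prs_only"), (3, "fh_plus_prs")):
        spec = ModelSpec(outcome=outcome, predictor_set=pset,
                         prs_form=prs_form, estimator=estimator, n_pcs=n_pcs)
        out[k] = fit_model(df, spec)
    return out
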