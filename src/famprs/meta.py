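"""Inverse-variance fixed-effect meta-analysis with Cochran heterogeneity.

Per-study effects are pooled on the log scale (log odds ratios, or raw
betas for continuous outcomes) with weights w_i = 1/SE_i^2:

    pooled = sum(w_i * theta_i) / sum(w_i),   SE = 1/sqrt(sum(w_i))
    Q = sum(w_i * (theta_i - pooled)^2),      I^2 = max(0, (Q - df)/Q) * 100

When only a printed 95% CI is available, the SE is recovered as
(ln U - ln L)/3.92 on the odds-ratio scale ((U - L)/3.92 for betas);
rounding of printed CIs makes such SEs approximate. A DerSimonian-Laird
random-effects variant is available behind a flag for completeness; the
pipeline reports fixed effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class StudyEstimate:
    label: str
    effect: float  # on the log scale for ORs
    se: float
    n: int | None = None

    def __post_init__(self):
        if self.se <= 0:
            raise ValueError(f"study {self.label!r}: SE must be positive")

    @classmethod
    def from_or_ci(cls, label: str, or_: float, ci_low: float, ci_high: float,
                   n: int | None = None) -> "StudyEstimate":
        """Build from a printed OR with 95% CI; SE = (ln U - ln L)/3.92."""
        if not 0 < ci_low <= or_ <= ci_high:
            raise ValueError("CI must bracket the OR and be positive")
        return cls(label=label, effect=float(np.log(or_)),
                   se=float((np.log(ci_high) - np.log(ci_low)) / 3.92), n=n)

    @classmethod
    def from_beta_ci(cls, label: str, beta: float, ci_low: float,
                     ci_high: float, n: int | None = None) -> "StudyEstimate":
        if not ci_low <= beta <= ci_high:
            raise ValueError("CI must bracket the estimate")
        return cls(label=label, effect=float(beta),
                   se=float((ci_high - ci_low) / 3.92), n=n)


@dataclass
class MetaResult:
    pooled: float
    se: float
    ci_low: float
    ci_high: float
    weights: np.ndarray  # normalized, sum to 1
    q: float
    df: int
    i_squared: float  # percent in [0, 100]
    labels: list[str] = field(default_factory=list)
    model: str = "fixed"
    tau_squared: float = 0.0

    @property
    def pooled_or(self) -> float:
        return float(np.exp(self.pooled))

    @property
    def or_ci(self) -> tuple[float, float]:
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))


def fixed_effect_meta(
    estimates: list[StudyEstimate], alpha: float = 0.05,
    random_effects: bool = False,
) -> MetaResult:
    """Pool per-study log-scale effects; fixed effect unless flagged.

    ``random_effects=True`` applies a DerSimonian-Laird between-study
    variance (non-default; the primary analysis is fixed-effect).
    """
    if len(estimates) < 2:
        raise ValueError("meta-analysis requires at least 2 studies")
    theta = np.array([e.effect for e in estimates], dtype=float)
    se = np.array([e.se for e in estimates], dtype=float)
    if np.any(se <= 0):
        raise ValueError("all study SEs must be positive")
    w = 1.0 / se**2
    pooled_fe = float(np.sum(w * theta) / np.sum(w))
    q = float(np.sum(w * (theta - pooled_fe) ** 2))
    df = len(estimates) - 1
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    tau2 = 0.0
    if random_effects:
        cc = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (q - df) / cc) if cc > 0 else 0.0
        w = 1.0 / (se**2 + tau2)
    pooled = float(np.sum(w * theta) / np.sum(w))
    se_pooled = float(1.0 / np.sqrt(np.sum(w)))
    zc = stats.norm.ppf(1 - alpha / 2)
    return MetaResult(
        pooled=pooled, se=se_pooled,
        ci_low=pooled - zc * se_pooled, ci_high=pooled + zc * se_pooled,
        weights=w / w.sum(), q=q, df=df, i_squared=float(i2),
        labels=[e.label for e in estimates],
        model="random" if random_effects else "fixed", tau_squared=tau2,
    )
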