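"""Synthetic smoker-cohort generator.

Emulates the joint structure the downstream analyses assume, following the
exposure -> mediator -> outcome graph: family history FH ~
Bernoulli(fh_prevalence); the polygenic risk score PRS_raw ~
Normal(a*FH, 1), where `a` (``mediation_shift``) is a mean shift in SD
units that induces a weak biserial FH-PRS correlation; and moderate-to-severe
COPD drawn from a logistic model

    logit P(case) = b0 + b_FH*FH + b_PRS*PRS + g*FH*PRS
                    + b_age*(age - mean) + b_sex*male + b_py*(py - mean)

Age and pack-years enter centered so ``beta0`` sets the case fraction at
covariate means. Spirometry is then back-filled consistently with assigned
status from truncated normals on the correct side of the diagnostic
thresholds (cases: FEV1pp < 80 and FEV1/FVC < 0.7; controls the reverse),
and secondary outcomes (exacerbations, SGRQ, 6-minute walk, BODE, death,
quantitative CT traits) are generated from simple stated models so every
pipeline stage has data. An optional case:control resampling step emulates
heavily imbalanced replication cohorts (e.g. 1713 cases : 147 controls).

Default effect sizes are the study conditions the generator emulates:
FH prevalence 0.33, OR 1.67 per positive family history, OR 2.11 per SD of
PRS, mediator shift a=0.153 (closed form: biserial correlation 0.093 at
33% prevalence; the point-biserial is then ~0.072), no interaction.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit
from scipy.stats import truncnorm


def _trunc(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


@dataclass
class SimulationConfig:
    """Generator parameters (all effects on the logit scale unless noted)."""

    n: int = 5000
    seed: int = 0
    cohort_label: str = "SYNTH"
    # exposure and mediator
    fh_prevalence: float = 0.33
    mediation_shift: float = 0.153  # a: PRS mean shift (SD units) given FH=1
    # outcome model
    beta0: float = 0.0
    beta_fh: float = float(np.log(1.67))
    beta_prs: float = float(np.log(2.11))
    gamma: float = 0.0  # FH x PRS interaction
    beta_age: float = 0.06  # per year, centered
    beta_sex_male: float = -0.2
    beta_packyears: float = 0.02  # per pack-year, centered
    # covariate distributions
    age_mean: float = 62.0
    age_sd: float = 8.5
    male_fraction: float = 0.46
    packyears_mean: float = 45.0
    packyears_sd: float = 25.0
    current_smoker_fraction: float = 0.38
    n_pcs: int = 5
    # optional case-control imbalance (n_cases, n_controls), e.g. (1713, 147)
    case_control_sampling: Optional[tuple[int, int]] = None
    # secondary-outcome blocks: linear coefficients + noise SDs
    sgrq: dict = field(default_factory=lambda: dict(
        b0=17.0, b_case=24.0, b_fh=0.3, b_prs=1.5, sd=15.0))
    sixmwd: dict = field(default_factory=lambda: dict(
        b0=1550.0, b_case=-350.0, b_fh=-27.0, b_prs=-33.0,
        b_height=5.0, b_weight=-2.0, sd=300.0))
    bode: dict = field(default_factory=lambda: dict(
        b0=0.5, b_case=2.9, b_fh=0.4, b_prs=0.35, sd=1.2))
    ct: dict = field(default_factory=lambda: dict(
        laa_b0=2.0, laa_b_case=8.0, laa_b_fh=0.37, laa_b_prs=0.19, laa_sd=4.0,
        perc15_b0=-910.0, perc15_b_case=-30.0, perc15_b_fh=-6.1,
        perc15_b_prs=-3.4, perc15_sd=20.0,
        pi10_b0=3.68, pi10_b_case=0.05, pi10_b_fh=0.009, pi10_b_prs=0.013,
        pi10_sd=0.10,
        wa_b0=60.0, wa_b_case=2.0, wa_b_fh=0.35, wa_b_prs=0.75, wa_sd=3.0))
    exacerbation: dict = field(default_factory=lambda: dict(
        b0=-3.0, b_fh=0.5, b_prs=0.0, b_fev1pp=-0.03, b_smoker=0.3))
    death: dict = field(default_factory=lambda: dict(
        b0=-4.0, b_bode=0.35, b_fh=0.13, b_prs=0.13))

    def __post_init__(self):
        if not 0 < self.fh_prevalence < 1:
            raise ValueError("fh_prevalence must lie in (0, 1)")
        for name in ("age_sd", "packyears_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n < 1:
            raise ValueError("n must be positive")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        if d["case_control_sampling"] is not None:
            d["case_control_sampling"] = list(d["case_control_sampling"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if d.get("case_control_sampling") is not None:
            d["case_control_sampling"] = tuple(d["case_control_sampling"])
        return cls(**d)

    def replace(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


def generate_synthetic_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Draw one synthetic cohort table.

    Deterministic for a fixed config: a master ``SeedSequence`` is spawned
    into independent child streams per generation block, so e.g. adding PCs
    does not perturb the outcome draw. The spawn layout and seed are echoed
    in ``df.attrs``.
    """
    c = config
    ss = np.random.SeedSequence(c.seed)
    streams = {name: np.random.default_rng(child) for name, child in zip(
        ("covariates", "fh", "prs", "outcome", "spirometry", "secondary",
         "sampling", "pcs"),
        ss.spawn(8),
    )}
    n = c.n
    rng = streams["covariates"]
    age = rng.normal(c.age_mean, c.age_sd, n).clip(45, 90)
    male = rng.random(n) < c.male_fraction
    pack_years = _trunc(rng, c.packyears_mean, c.packyears_sd, 10, 200, n)
    current_smoker = rng.random(n) < c.current_smoker_fraction
    height = np.where(male, rng.normal(176, 7, n), rng.normal(163, 6, n))
    weight = rng.normal(82, 18, n).clip(40, 200)
    bmi = weight / (height / 100.0) ** 2

    fh = streams["fh"].random(n) < c.fh_prevalence
    prs = streams["prs"].normal(0.0, 1.0, n) + c.mediation_shift * fh

    eta = (c.beta0
           + c.beta_fh * fh
           + c.beta_prs * prs
           + c.gamma * fh * prs
           + c.beta_age * (age - c.age_mean)
           + c.beta_sex_male * male
           + c.beta_packyears * (pack_years - c.packyears_mean))
    case = streams["outcome"].random(n) < expit(eta)

    rng = streams["spirometry"]
    fev1_pp = np.where(
        case,
        _trunc(rng, 49.0, 18.0, 10.0, 79.999, n),
        _trunc(rng, 95.0, 13.0, 80.0, 150.0, n),
    )
    fev1_fvc = np.where(
        case,
        _trunc(rng, 0.48, 0.13, 0.10, 0.6999, n),
        _trunc(rng, 0.77, 0.06, 0.70, 0.95, n),
    )

    rng = streams["secondary"]
    s = c.sgrq
    sgrq = (s["b0"] + s["b_case"] * case + s["b_fh"] * fh + s["b_prs"] * prs
            + rng.normal(0, s["sd"], n)).clip(0, 100)
    s = c.sixmwd
    sixmwd = (s["b0"] + s["b_case"] * case + s["b_fh"] * fh + s["b_prs"] * prs
              + s["b_height"] * (height - 170.0) + s["b_weight"] * (weight - 82.0)
              + rng.normal(0, s["sd"], n)).clip(0, None)
    s = c.bode
    bode = np.round(
        s["b0"] + s["b_case"] * case + s["b_fh"] * fh + s["b_prs"] * prs
        + rng.normal(0, s["sd"], n)
    ).clip(0, 10)
    s = c.ct
    pct_laa950 = (s["laa_b0"] + s["laa_b_case"] * case + s["laa_b_fh"] * fh
                  + s["laa_b_prs"] * prs + rng.normal(0, s["laa_sd"], n)).clip(0, 100)
    perc15 = (s["perc15_b0"] + s["perc15_b_case"] * case + s["perc15_b_fh"] * fh
              + s["perc15_b_prs"] * prs + rng.normal(0, s["perc15_sd"], n))
    pi10 = (s["pi10_b0"] + s["pi10_b_case"] * case + s["pi10_b_fh"] * fh
            + s["pi10_b_prs"] * prs + rng.normal(0, s["pi10_sd"], n)).clip(0.5, None)
    wa_pct = (s["wa_b0"] + s["wa_b_case"] * case + s["wa_b_fh"] * fh
              + s["wa_b_prs"] * prs + rng.normal(0, s["wa_sd"], n)).clip(0, 100)
    s = c.exacerbation
    p_freq = expit(s["b0"] + s["b_fh"] * fh + s["b_prs"] * prs
                   + s["b_fev1pp"] * (fev1_pp - 90.0) + s["b_smoker"] * current_smoker)
    frequent = rng.random(n) < p_freq
    exac = np.where(frequent, 2 + rng.poisson(0.8, n),
                    (rng.random(n) < 0.15).astype(int))
    severe = rng.random(n) < expit(-3.0 + 0.8 * case + 0.15 * fh)
    s = c.death
    dead = rng.random(n) < expit(s["b0"] + s["b_bode"] * bode + s["b_fh"] * fh
                                 + s["b_prs"] * prs)
    subtype_p = np.where(case, 0.45, 0.08)
    has_emph = rng.random(n) < subtype_p
    subtype_labels = np.array(
        ["none", "paraseptal", "mild_cle", "upper_lobe_cle", "diffuse_cle"])
    subtype_idx = rng.integers(1, len(subtype_labels), n)
    visual_ct_subtype = np.where(has_emph, subtype_labels[subtype_idx], "none")
    ct_scanner = np.where(rng.random(n) < 0.5, "scannerA", "scannerB")

    pcs = streams["pcs"].normal(0.0, 1.0, (n, c.n_pcs))

    # yes/no/unknown questionnaire fields consistent with the composite FH:
    # positives get at least one "yes"; negatives are "no" with an occasional
    # "unknown" (coded to "no" downstream, exercising the sensitivity mode).
    rng = streams["fh"]
    which = rng.integers(0, 3, n)
    unknown_mask = (~fh) & (rng.random(n) < 0.05)
    fh_fields = {}
    for j, name in enumerate(("fh_copd", "fh_chronic_bronchitis", "fh_emphysema")):
        col = np.where(fh & (which == j), "yes", "no")
        col = np.where(unknown_mask, "unknown", col)
        fh_fields[name] = col

    df = pd.DataFrame({
        "subject_id": [f"S{i:06d}" for i in range(n)],
        "cohort": c.cohort_label,
        "age": age,
        "sex": np.where(male, "male", "female"),
        "pack_years": pack_years,
        "current_smoker": current_smoker,
        "height": height,
        "weight": weight,
        "bmi": bmi,
        "fev1_pp": fev1_pp,
        "fev1_fvc": fev1_fvc,
        **fh_fields,
        "prs_raw": prs,
        "exacerbations_12mo": exac,
        "severe_exacerbation": severe,
        "dead": dead,
        "bode": bode,
        "sgrq_total": sgrq,
        "sixmwd": sixmwd,
        "pct_laa950": pct_laa950,
        "perc15": perc15,
        "pi10": pi10,
        "wa_pct": wa_pct,
        "visual_ct_subtype": visual_ct_subtype,
        "ct_scanner": ct_scanner,
        **{f"pc{j + 1}": pcs[:, j] for j in range(c.n_pcs)},
    })

    if c.case_control_sampling is not None:
        n_cases, n_controls = c.case_control_sampling
        case_idx = np.flatnonzero(case)
        ctrl_idx = np.flatnonzero(~case)
        if len(case_idx) < n_cases or len(ctrl_idx) < n_controls:
            raise ValueError(
                f"target counts unreachable (have {len(case_idx)} cases / "
                f"{len(ctrl_idx)} controls, need {n_cases}/{n_controls}); "
                "increase n"
            )
        rng = streams["sampling"]
        keep = np.concatenate([
            rng.choice(case_idx, n_cases, replace=False),
            rng.choice(ctrl_idx, n_controls, replace=False),
        ])
        keep.sort()
        df = df.iloc[keep].reset_index(drop=True)

    df.attrs["simulation"] = {"config": asdict(c), "seed": c.seed,
                              "streams": list(streams)}
    return df
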