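"""End-to-end orchestration: cohorts -> models -> metrics -> meta-analysis.

``run_full_pipeline`` executes, per cohort: derivation of outcomes and
predictors, the nested model-1/2/3 triple for each requested outcome,
discrimination/calibration metrics, attributable fractions, joint-effect /
RERI interaction, biserial correlation and natural-effects mediation, then
pools the per-cohort model-3 estimates by fixed-effect meta-analysis. All
results are tidy CSV tables plus a JSON run manifest and a JSON-lines log.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import famprs
from famprs import cohort as cohort_mod
from famprs.interaction import (
    attributable_fractions,
    joint_effects,
    multiplicative_interaction_test,
    stratified_estimates,
)
from famprs.mediation import biserial_correlation, natural_effects_mediation
from famprs.meta import StudyEstimate, fixed_effect_meta
from famprs.performance import auc_with_ci, compare_auc_delong, scaled_brier
from famprs.regression import fit_three_models
from famprs.simulate import SimulationConfig, generate_synthetic_cohort

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class CohortSource:
    """One cohort: either a file to load or a simulation to run."""

    label: str
    path: str | None = None
    column_map: dict | None = None
    simulate: dict | None = None  # SimulationConfig kwargs
    estimator: str | None = None  # force 'firth' for imbalanced cohorts


@dataclass
class PipelineConfig:
    cohorts: list[CohortSource]
    outcomes: list[str] = field(default_factory=lambda: ["copd_case"])
    fh_mode: str = "copdgene_full"
    n_pcs: int = 5
    seed: int = 0
    mediation_B: int = 200
    run_interaction: bool = True
    run_mediation: bool = True
    out_dir: str = "famprs_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["cohorts"] = [CohortSource(**c) for c in d["cohorts"]]
        return cls(**d)


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except PipelineError:
                raise
            except Exception as e:
                raise PipelineError(name, e) from e
        return wrapped
    return deco


@_stage("cohort")
def _get_cohort(src: CohortSource, cfg: PipelineConfig, seed: int) -> pd.DataFrame:
    if src.simulate is not None:
        sim = SimulationConfig(**{"seed": seed, **src.simulate,
                                  "cohort_label": src.label})
        df = generate_synthetic_cohort(sim)
    elif src.path is not None:
        df = cohort_mod.load_cohort(src.path, column_map=src.column_map,
                                    require=("fev1_pp", "fev1_fvc", "prs_raw"))
        df["cohort"] = src.label
    else:
        raise ValueError(f"cohort {src.label!r}: neither path nor simulate given")
    return cohort_mod.derive_cohort(df, fh_mode=cfg.fh_mode)


@_stage("models")
def _fit_models(df, outcome, estimator, n_pcs):
    for col in ("family_history", "prs_z"):
        if col not in df.columns:
            raise KeyError(f"derived column {col!r} absent")
    if outcome not in df.columns:
        raise KeyError(f"outcome column {outcome!r} absent from cohort table")
    return fit_three_models(df, outcome, estimator=estimator, n_pcs=n_pcs)


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Run every analysis stage and write the report bundle.

    Returns a dict of the main tables; writes CSVs, ``manifest.json`` and
    ``log.jsonl`` under ``config.out_dir``. Raises :class:`PipelineError`
    naming the failing stage (partial outputs retained with a FAILED
    marker).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "log.jsonl"
    t0 = time.time()

    def log(event, **kw):
        rec = {"t": round(time.time() - t0, 3), "event": event, **kw}
        with open(log_path, "a") as fh:
            fh.write(json.dumps(rec, default=str) + "\n")
        logger.info("%s %s", event, kw)

    results: dict = {}
    model_rows, perf_rows, af_rows, inter_rows, med_rows = [], [], [], [], []
    meta_inputs: dict[str, list] = {}
    try:
        log("start", config=asdict(config))
        ss = np.random.SeedSequence(config.seed)
        cohort_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                        ss.spawn(len(config.cohorts))]
        for src, cseed in zip(config.cohorts, cohort_seeds):
            df = _get_cohort(src, config, cseed)
            log("cohort", label=src.label, n=len(df))
            cohort_mod.write_cohort(df, out / f"cohort_{src.label}.csv")
            table1 = cohort_mod.summarize_cohort(df)
            table1.insert(0, "cohort", src.label)
            results.setdefault("table1", []).append(table1)

            for outcome in config.outcomes:
                fits = _fit_models(df, outcome, src.estimator, config.n_pcs)
                binary = fits[3].family == "binary"
                for k, fit in fits.items():
                    tidy = fit.to_frame()
                    tidy.insert(0, "model", k)
                    tidy.insert(0, "outcome", outcome)
                    tidy.insert(0, "cohort", src.label)
                    model_rows.append(tidy)
                    row = {"cohort": src.label, "outcome": outcome, "model": k,
                           "n": fit.n_used}
                    if binary:
                        y, p = None, fit.fitted
                        # reconstruct outcome vector aligned with fit
                        from famprs.regression import ModelSpec, build_design
                        y, _ = build_design(df, fit.spec)
                        perf = auc_with_ci(p, y, model=f"model{k}")
                        row.update(auc=perf.auc, auc_ci_low=perf.ci_low,
                                   auc_ci_high=perf.ci_high,
                                   scaled_brier=scaled_brier(p, y))
                    else:
                        row.update(adjusted_r2=fit.r_squared_adj, mse=fit.mse)
                    perf_rows.append(row)
                if binary:
                    from famprs.regression import build_design
                    y3, _ = build_design(df, fits[3].spec)
                    y1, _ = build_design(df, fits[1].spec)
                    if len(y3) == len(y1):
                        for ka, kb in ((1, 3), (2, 3)):
                            cmp_res = compare_auc_delong(
                                fits[ka].fitted, fits[kb].fitted, y3)
                            perf_rows.append({
                                "cohort": src.label, "outcome": outcome,
                                "model": f"{ka}v{kb}",
                                "delta_auc": cmp_res.delta,
                                "p_delong": cmp_res.p_value})
                # meta-analysis inputs: model-3 FH and PRS terms
                for term in ("family_history", "prs_z"):
                    if term in fits[3].params.index:
                        est = StudyEstimate(label=src.label,
                                            effect=float(fits[3].params[term]),
                                            se=float(fits[3].bse[term]),
                                            n=fits[3].n_used)
                        meta_inputs.setdefault(
                            (outcome, term, binary), []).append(est)
                if binary and outcome == "copd_case":
                    # attributable fractions from the dichotomized-PRS model 3
                    fits_t = fit_three_models(df, outcome, estimator=src.estimator,
                                              prs_form="top_tertile",
                                              n_pcs=config.n_pcs)
                    cases = df[df[outcome] == 1]
                    for term, prev_col in (("family_history", "family_history"),
                                           ("prs_top_tertile", "prs_top_tertile")):
                        or_ = float(np.exp(fits_t[3].params[term]))
                        p_c = float(cases[prev_col].dropna().astype(bool).mean())
                        af = attributable_fractions(or_, p_c)
                        af_rows.append({
                            "cohort": src.label, "exposure": term,
                            "or": or_, "p_cases": p_c,
                            "af_exposed": af.af_exposed,
                            "af_population": af.af_population,
                            "method": af.method})

            if config.run_interaction and "copd_case" in config.outcomes:
                try:
                    ir = joint_effects(df, n_pcs=config.n_pcs)
                    mult = multiplicative_interaction_test(df, n_pcs=config.n_pcs)
                    strat = stratified_estimates(df, n_pcs=config.n_pcs)
                    jr = ir.joint_or.copy()
                    jr.insert(0, "cohort", src.label)
                    inter_rows.append({
                        "cohort": src.label,
                        "reri": ir.reri.reri, "reri_ci_low": ir.reri.ci_low,
                        "reri_ci_high": ir.reri.ci_high, "reri_p": ir.reri.p_value,
                        "gamma": mult["gamma"], "gamma_se": mult["se"],
                        "gamma_p_wald": mult["p_wald"], "gamma_p_lrt": mult["p_lrt"],
                    })
                    results.setdefault("joint_effects", []).append(jr)
                    strat.insert(0, "cohort", src.label)
                    results.setdefault("stratified", []).append(strat)
                except (ValueError, RuntimeError) as e:
                    log("interaction_skipped", cohort=src.label, reason=str(e))

            if config.run_mediation and "copd_case" in config.outcomes:
                corr = biserial_correlation(
                    df["family_history"].astype("float"), df["prs_z"])
                med = natural_effects_mediation(
                    df, B=config.mediation_B, seed=cseed)
                log("mediation_dag",
                    assumption="no unmeasured exposure-outcome, "
                               "mediator-outcome or exposure-mediator "
                               "confounding beyond adjusted covariates")
                med_rows.append({
                    "cohort": src.label,
                    "biserial_r": corr.r_biserial, "biserial_p": corr.p_value,
                    "nde": med.nde, "nie": med.nie, "total": med.total,
                    "proportion_mediated": med.proportion_mediated,
                    "pm_ci_low": med.proportion_mediated_ci[0] if med.proportion_mediated_ci else np.nan,
                    "pm_ci_high": med.proportion_mediated_ci[1] if med.proportion_mediated_ci else np.nan,
                    "pm_stable": med.proportion_stable,
                    "B": med.n_boot, "seed": med.seed, "n_used": med.n_used,
                })

        meta_rows = []
        for (outcome, term, binary), ests in meta_inputs.items():
            if len(ests) >= 2:
                mr = fixed_effect_meta(ests)
                row = {"outcome": outcome, "term": term,
                       "pooled_effect": mr.pooled,
                       "effect_scale": "log_or" if binary else "beta",
                       "q": mr.q, "df": mr.df, "i_squared": mr.i_squared,
                       "studies": ";".join(mr.labels), "model": mr.model}
                if binary:
                    row.update(pooled_or=mr.pooled_or,
                               or_ci_low=mr.or_ci[0], or_ci_high=mr.or_ci[1])
                else:
                    row.update(ci_low=mr.ci_low, ci_high=mr.ci_high)
                meta_rows.append(row)

        tables = {
            "table1": pd.concat(results.get("table1", []), ignore_index=True)
            if results.get("table1") else pd.DataFrame(),
            "models": pd.concat(model_rows, ignore_index=True)
            if model_rows else pd.DataFrame(),
            "performance": pd.DataFrame(perf_rows),
            "attributable_fractions": pd.DataFrame(af_rows),
            "interaction": pd.DataFrame(inter_rows),
            "joint_effects": pd.concat(results.get("joint_effects", []),
                                       ignore_index=True)
            if results.get("joint_effects") else pd.DataFrame(),
            "stratified": pd.concat(results.get("stratified", []),
                                    ignore_index=True)
            if results.get("stratified") else pd.DataFrame(),
            "mediation": pd.DataFrame(med_rows),
            "meta": pd.DataFrame(meta_rows),
        }
        # annotation, not a filter: multiple-testing thresholds for readers
        if not tables["models"].empty:
            tables["models"]["bonferroni_alpha"] = 0.05 / 3
        for name, tab in tables.items():
            tab.to_csv(out / f"{name}.csv", index=False)
        cfg_json = json.dumps(asdict(config), sort_keys=True, default=str)
        manifest = {
            "package": "famprs", "version": famprs.__version__,
            "seed": config.seed,
            "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
            "tables": sorted(tables),
            "elapsed_s": round(time.time() - t0, 2),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        log("done", elapsed=manifest["elapsed_s"])
        return tables
    except PipelineError as e:
        (out / "FAILED").write_text(f"stage={e.stage}\ncause={e.cause}\n")
        log("failed", stage=e.stage, cause=str(e.cause))
        raise
    except Exception as e:
        (out / "FAILED").write_text(f"stage=unknown\ncause={e}\n")
        log("failed", stage="unknown", cause=str(e))
        raise PipelineError("unknown", e) from e
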