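"""End-to-end audit: generate/load -> cohort -> models -> performance ->
fairness -> hospital stratification, as one seeded, logged, reproducible run.

A single audit seed fans out to per-stage child seeds by a fixed rule
(``SeedSequence([seed, k])`` with k = 0 generator, 1 retraining split,
2 as-is coefficient noise), so any stage can be rerun in isolation.  Rerun
with an identical config produces byte-identical outputs; no timestamps are
written.

The point-score models (LACE, modified HOSPITAL) are evaluated on the full
eligible cohort; the CMS-style models are restricted to the medicine cohort,
with the retrained variant scored on the held-out testing half.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import fairness, performance, riskmodels, stratify, synthgen
from .cohort import AXIS_COLUMNS, apply_exclusions, label_readmissions, observed_rates

__all__ = ["AuditConfig", "AuditReport", "run_audit", "summarize_cohort"]

logger = logging.getLogger(__name__)

ALL_MODELS = ("lace", "hospital_mod", "cms_asis", "cms_retrained")
#: protected vs reference group per grouping axis
AXIS_CONTRASTS = {
    "race": ("black", "white"),
    "income": ("low", "other"),
    "payer": ("medicaid", "private"),
}


def _stage_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))


@dataclass
class AuditConfig:
    generator: synthgen.GeneratorConfig | str = field(
        default_factory=synthgen.GeneratorConfig)
    models: tuple = ALL_MODELS
    grouping_axes: tuple = ("race", "income")
    window_days: int = 30
    anchor: str = "discharge"
    min_gap: int = 1
    brier_mode: str = "binary"
    gei_alpha: float = 2.0
    bin_thresholds: tuple = stratify.DEFAULT_BIN_THRESHOLDS
    outdir: str | None = None
    seed: int = 0
    cms_asis_noise: float = 0.2
    cms_asis_coefficients: dict | None = None  # {"intercept":, "age_decade":, "conditions": []}
    retrain_fraction: float = 0.5
    ci_method: str = "wald"

    def validate(self) -> None:
        if not self.models:
            raise ValueError("config must list at least one model")
        unknown = set(self.models) - set(ALL_MODELS)
        if unknown:
            raise ValueError(f"unknown models: {sorted(unknown)}")
        if not self.grouping_axes:
            raise ValueError("config must list at least one grouping axis")
        unknown = set(self.grouping_axes) - set(AXIS_CONTRASTS)
        if unknown:
            raise ValueError(f"unknown grouping axes: {sorted(unknown)}")
        if isinstance(self.generator, synthgen.GeneratorConfig):
            self.generator.validate()
        elif not Path(self.generator).exists():
            raise ValueError(f"discharge CSV not found: {self.generator}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if isinstance(self.generator, synthgen.GeneratorConfig):
            d["generator"] = self.generator.to_dict()
        for key in ("models", "grouping_axes", "bin_thresholds"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AuditConfig":
        d = dict(d)
        gen = d.get("generator")
        if isinstance(gen, dict):
            d["generator"] = synthgen.GeneratorConfig.from_dict(gen)
        for key in ("models", "grouping_axes", "bin_thresholds"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "AuditConfig":
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("outdir", None)  # run location is not part of the analysis identity
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class AuditReport:
    metadata: dict
    records: pd.DataFrame
    labels: pd.DataFrame
    cohort_summary: dict
    observed: pd.DataFrame
    performance: pd.DataFrame
    bias: pd.DataFrame
    predictions: dict
    per_hospital: dict
    bins: dict
    hospitals: pd.DataFrame | None = None
    truth: pd.DataFrame | None = None


def summarize_cohort(records: pd.DataFrame, labels: pd.DataFrame,
                     axes=("race", "income")) -> dict:
    """Group descriptives (n, %, means with SD) and group-comparison p-values.

    Means are compared between the axis' protected and reference groups with
    a Welch t test, proportions with a chi-square test.
    """
    merged = labels.merge(records, on="record_id", how="left", validate="1:1")
    sub = merged.loc[merged["eligible_index"]]
    mean_vars = ("age_years", "los_days", "charlson", "n_diagnoses")
    prop_vars = {"female_pct": sub["sex"] == "female",
                 "procedure_pct": sub["any_procedure"].astype(bool)}
    desc_rows, p_rows = [], []
    for axis in axes:
        col = AXIS_COLUMNS[axis]
        total = len(sub)
        for group, frame in sub.groupby(col, sort=True):
            row = {"axis": axis, "group": group, "n": len(frame),
                   "pct": 100.0 * len(frame) / total}
            for v in mean_vars:
                row[f"{v}_mean"] = float(frame[v].mean())
                row[f"{v}_sd"] = float(frame[v].std())
            for name, ind in prop_vars.items():
                row[name] = 100.0 * float(ind.loc[frame.index].mean())
            desc_rows.append(row)
        prot, ref = AXIS_CONTRASTS[axis]
        a = sub.loc[sub[col] == prot]
        b = sub.loc[sub[col] == ref]
        if len(a) < 2 or len(b) < 2:
            continue
        for v in mean_vars:
            p = float(stats.ttest_ind(a[v], b[v], equal_var=False).pvalue)
            p_rows.append({"axis": axis, "characteristic": v, "p_value": p})
        for name, ind in prop_vars.items():
            tab = np.array([[ind.loc[a.index].sum(), (~ind.loc[a.index]).sum()],
                            [ind.loc[b.index].sum(), (~ind.loc[b.index]).sum()]])
            if (tab.sum(axis=1) > 0).all() and (tab.sum(axis=0) > 0).all():
                p = float(stats.chi2_contingency(tab).pvalue)
            else:
                p = float("nan")
            p_rows.append({"axis": axis, "characteristic": name, "p_value": p})
    return {"descriptives": pd.DataFrame(desc_rows), "pvalues": pd.DataFrame(p_rows)}


def _model_runs(config: AuditConfig, eligible: pd.DataFrame,
                gen_config: synthgen.GeneratorConfig | None) -> list[dict]:
    """Score, threshold and classify each configured model on its cohort."""
    runs = []
    outcome = "readmit_30d_unplanned"
    medicine = eligible.loc[eligible["cohort_label"] == "medicine"]

    if "lace" in config.models:
        scores = riskmodels.lace_score(eligible)
        preds = riskmodels.classify(scores, 10, model_id="lace")
        runs.append({"model_id": "lace", "kind": "points", "frame": eligible,
                     "predictions": preds, "threshold": 10})
    if "hospital_mod" in config.models:
        scores = riskmodels.hospital_mod_score(eligible)
        preds = riskmodels.classify(scores, 5, model_id="hospital_mod")
        runs.append({"model_id": "hospital_mod", "kind": "points", "frame": eligible,
                     "predictions": preds, "threshold": 5})

    n_cond = None
    if gen_config is not None:
        n_cond = gen_config.n_condition_vars
    else:
        n_cond = sum(c.startswith("cond_") for c in eligible.columns)

    if "cms_asis" in config.models:
        if config.cms_asis_coefficients is not None:
            cc = config.cms_asis_coefficients
            spec = riskmodels.RiskModelSpec(
                model_id="cms_asis", kind="logistic", intercept=cc["intercept"],
                coefficients={"age_decade": cc.get("age_decade", 0.0),
                              "conditions": list(cc["conditions"])},
                threshold=None, threshold_rule="youden", cohort_restriction="medicine")
        elif gen_config is not None:
            spec = riskmodels.make_asis_spec_from_truth(
                gen_config, noise_scale=config.cms_asis_noise,
                seed=_stage_seed(config.seed, 2))
        else:
            logger.warning("cms_asis skipped: no coefficients supplied and no generator truth")
            spec = None
        if spec is not None and len(medicine) > 0:
            scores = riskmodels.cms_linear_predictor(medicine, spec)
            spec.threshold = riskmodels.youden_threshold(scores, medicine[outcome])
            preds = riskmodels.classify(scores, spec)
            runs.append({"model_id": "cms_asis", "kind": "logistic", "frame": medicine,
                         "predictions": preds, "threshold": spec.threshold, "spec": spec})

    if "cms_retrained" in config.models and len(medicine) >= 2:
        part = riskmodels.split_retrain_test(medicine, config.retrain_fraction,
                                             seed=_stage_seed(config.seed, 1))
        train = medicine.loc[part == "train"]
        test = medicine.loc[part == "test"]
        spec = riskmodels.retrain_cms(train, train[outcome], n_cond,
                                      seed=_stage_seed(config.seed, 1))
        train_scores = riskmodels.cms_linear_predictor(train, spec)
        spec.threshold = riskmodels.youden_threshold(train_scores, train[outcome])
        scores = riskmodels.cms_linear_predictor(test, spec)
        preds = riskmodels.classify(scores, spec)
        runs.append({"model_id": "cms_retrained", "kind": "logistic", "frame": test,
                     "predictions": preds, "threshold": spec.threshold, "spec": spec})
    return runs


def run_audit(config: AuditConfig) -> AuditReport:
    """Execute the full audit; write the report bundle when outdir is set."""
    config.validate()

    # --- data ------------------------------------------------------------
    if isinstance(config.generator, synthgen.GeneratorConfig):
        gen_config = dataclasses.replace(config.generator, seed=_stage_seed(config.seed, 0))
        hospitals = synthgen.generate_hospitals(gen_config)
        records, truth = synthgen.generate_discharges(gen_config, hospitals)
        study_end = gen_config.study_days
    else:
        gen_config, hospitals, truth = None, None, None
        records = synthgen.read_discharges(config.generator)
        study_end = None
    logger.info("stage data: %d records", len(records))

    # --- cohort ------------------------------------------------------------
    labels = apply_exclusions(records)
    labels = label_readmissions(records, labels, window_days=config.window_days,
                                anchor=config.anchor, min_gap=config.min_gap,
                                study_end=study_end)
    eligible = labels.merge(records, on="record_id", how="left", validate="1:1")
    eligible = eligible.loc[eligible["eligible_index"]].reset_index(drop=True)
    logger.info("stage cohort: %d eligible of %d", len(eligible), len(records))

    observed = pd.concat(
        [observed_rates(labels, records, axis).assign(grouping_axis=axis)
         for axis in config.grouping_axes], ignore_index=True).drop_duplicates(
        subset=["grouping_axis", "group"])

    # --- models, performance, fairness -------------------------------------
    runs = _model_runs(config, eligible, gen_config)
    perf_rows, bias_rows = [], []
    per_hospital, bins, predictions = {}, {}, {}
    for run in runs:
        frame = run["frame"].copy()
        frame["score"] = run["predictions"]["score"].to_numpy()
        frame["predicted_high_risk"] = run["predictions"]["predicted_high_risk"].to_numpy()
        predictions[run["model_id"]] = pd.DataFrame({
            "record_id": frame["record_id"], "model_id": run["model_id"],
            "score": frame["score"], "predicted_high_risk": frame["predicted_high_risk"],
            "threshold": run["threshold"]})
        for axis in config.grouping_axes:
            col = AXIS_COLUMNS[axis]
            perf_rows.append(performance.performance_table(
                frame, run["model_id"], run["kind"], axis, col,
                brier_mode=config.brier_mode))
            prot, ref = AXIS_CONTRASTS[axis]
            g = frame[col].to_numpy()
            if (g == prot).any() and (g == ref).any():
                bias_rows.append(fairness.bias_table(
                    frame["predicted_high_risk"], frame["readmit_30d_unplanned"],
                    g, prot, ref, model_id=run["model_id"], axis=axis,
                    alpha=config.gei_alpha))
        hb = stratify.per_hospital_bias(frame)
        per_hospital[run["model_id"]] = hb
        bins[run["model_id"]] = stratify.composition_bins(
            frame, hb, thresholds=config.bin_thresholds, model_id=run["model_id"],
            ci_method=config.ci_method)
        logger.info("stage model %s: n=%d threshold=%s", run["model_id"], len(frame),
                    run["threshold"])

    perf = (pd.concat(perf_rows, ignore_index=True)
            .drop_duplicates(subset=["model_id", "grouping_axis", "group"])
            if perf_rows else pd.DataFrame())
    bias = pd.DataFrame(bias_rows)
    summary = summarize_cohort(records, labels, config.grouping_axes)

    reasons = labels.loc[labels["excluded"], "exclusion_reason"].value_counts().to_dict()
    metadata = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_records": int(len(records)),
        "n_excluded": int(labels["excluded"].sum()),
        "exclusions_by_reason": {k: int(v) for k, v in sorted(reasons.items())},
        "n_eligible": int(len(eligible)),
        "models_run": [r["model_id"] for r in runs],
        "thresholds": {r["model_id"]: float(r["threshold"]) for r in runs},
    }
    report = AuditReport(metadata=metadata, records=records, labels=labels,
                         cohort_summary=summary, observed=observed, performance=perf,
                         bias=bias, predictions=predictions, per_hospital=per_hospital,
                         bins=bins, hospitals=hospitals, truth=truth)
    if config.outdir is not None:
        _write_report(config, report)
    return report


def _write_report(config: AuditConfig, report: AuditReport) -> None:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    try:
        def w(df: pd.DataFrame, name: str):
            path = out / name
            df.to_csv(path, index=False)
            written.append(path)

        w(report.records, "records.csv")
        if report.hospitals is not None:
            w(report.hospitals, "hospitals.csv")
        w(report.labels, "labels.csv")
        w(report.observed, "observed_rates.csv")
        w(report.performance, "performance.csv")
        w(report.bias, "bias.csv")
        w(report.cohort_summary["descriptives"], "cohort_descriptives.csv")
        w(report.cohort_summary["pvalues"], "cohort_pvalues.csv")
        for mid, df in report.predictions.items():
            w(df, f"predictions_{mid}.csv")
        for mid, df in report.per_hospital.items():
            w(df, f"per_hospital_{mid}.csv")
        for mid, df in report.bins.items():
            w(df, f"composition_bins_{mid}.csv")
        path = out / "report.json"
        cfg = config.to_dict()
        cfg.pop("outdir", None)
        with open(path, "w") as fh:
            json.dump({"metadata": report.metadata, "config": cfg},
                      fh, indent=2, sort_keys=True, default=str)
        written.append(path)
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise
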