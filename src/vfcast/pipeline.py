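"""End-to-end orchestration: simulate → prepare → stage 1 → FPCA → predict → evaluate.

Training-time stratification uses the measured progressor labels (full-series
slopes); at inference each test-set eye is routed to a stratum FPCA model by
its Stage-1 *predicted* label, the deployment scenario. Only the eye's
baseline-window (first-year) observations feed its score prediction; later
tests are held out as evaluation targets. Nothing downstream of the training
split — imputation means, bandwidths, model coefficients, the decision
threshold, Tukey fences — sees validation or test data.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort, evaluate, fpca, stage1
from .cohort import BASELINE_WINDOW_DAYS, EYE_KEY, FilterCriteria
from .errors import ConfigError, DataError
from .evaluate import _r2_stat, _rmse_stat
from .simulate import FAST, SLOW, SimConfig, simulate_cohort


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run (one global seed expands into
    per-stage seeds deterministically)."""

    sim: SimConfig = field(default_factory=SimConfig)
    filters: FilterCriteria = field(default_factory=FilterCriteria)
    fpca: fpca.FPCAOptions = field(default_factory=fpca.FPCAOptions)
    classifier_C: float = 1.0
    min_tests: int = 3
    split_ratios: tuple = (0.8, 0.1, 0.1)
    bootstrap_B: int = 1000
    seed: int = 0

    def validate(self) -> None:
        self.sim.validate()
        self.fpca.validate()
        if self.classifier_C <= 0:
            raise ConfigError("classifier_C must be positive")
        if self.bootstrap_B < 1:
            raise ConfigError("bootstrap_B must be at least 1")

    def stage_seed(self, k: int) -> int:
        return int(np.random.SeedSequence(self.seed).generate_state(k + 1)[k] % (2**31))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        required = {"sim", "fpca"}
        missing = required - set(raw)
        if missing:
            raise ConfigError(f"config missing block(s): {sorted(missing)}")
        kwargs: dict = {}
        kwargs["sim"] = SimConfig(**raw["sim"])
        kwargs["fpca"] = fpca.FPCAOptions(**_tupled(raw["fpca"], "domain"))
        if "filters" in raw:
            kwargs["filters"] = FilterCriteria(**_tupled(raw["filters"], "excluded_patterns"))
        for key in ("classifier_C", "min_tests", "bootstrap_B", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        if "split_ratios" in raw:
            kwargs["split_ratios"] = tuple(raw["split_ratios"])
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        d = {
            "sim": asdict(self.sim),
            "filters": asdict(self.filters),
            "fpca": vars(self.fpca) | {"domain": list(self.fpca.domain)},
            "classifier_C": self.classifier_C,
            "min_tests": self.min_tests,
            "split_ratios": list(self.split_ratios),
            "bootstrap_B": self.bootstrap_B,
            "seed": self.seed,
        }
        d["filters"]["excluded_patterns"] = list(self.filters.excluded_patterns)
        Path(path).write_text(yaml.safe_dump(d))


def _tupled(d: dict, key: str) -> dict:
    d = dict(d)
    if key in d:
        d[key] = tuple(d[key])
    return d


def prepare(vf: pd.DataFrame, config: PipelineConfig):
    """Filters → strategy resolution → min-test rule → split → slopes/labels.

    Tukey fences are computed on training-split slopes and applied to all
    splits. Returns ``(series, labels, split, audit)`` where `labels` carries
    slope/label/split per retained eye.
    """
    series, audit = cohort.prepare_cohort(vf, config.filters, config.min_tests)
    labels = cohort.label_table(series)
    split = cohort.split_by_patient(
        series["patient_id"], config.split_ratios, seed=config.stage_seed(1)
    )
    labels = labels.merge(split, on="patient_id", how="left")
    slopes = labels.set_index(["patient_id", "eye"])["slope"]
    train_slopes = labels.loc[labels["split"] == "train"].set_index(["patient_id", "eye"])["slope"]
    kept, removed = cohort.tukey_outlier_filter(slopes, fences_from=train_slopes)
    audit["tukey_outliers"] = int(len(removed))
    labels = labels.set_index(["patient_id", "eye"]).loc[kept.index].reset_index()
    series = series.merge(labels[EYE_KEY], on=EYE_KEY, how="inner")
    return series, labels, split, audit


def _series_list(series: pd.DataFrame, keys: pd.DataFrame):
    grouped = dict(tuple(series.groupby(EYE_KEY, sort=False)))
    out = []
    for pid, eye in keys[EYE_KEY].itertuples(index=False):
        g = grouped[(pid, eye)]
        out.append((g["t"].to_numpy(float), g["md_db"].to_numpy(float)))
    return out


def _stratum_rows(pairs: pd.DataFrame, B: int, seed: int) -> list:
    """Table-3-style rows: per-bin and overall RMSE/R² with bootstrap CIs."""
    report, _ = evaluate.horizon_stratified_metrics(pairs)
    bins = pairs["t"].map(evaluate.horizon_bin)
    rows = []
    for rec in report.to_dict("records"):
        label = rec["interval"]
        sub = pairs if label == evaluate.OVERALL_LABEL else pairs.loc[(bins == label).to_numpy()]
        if len(sub):
            try:
                bs_rmse = evaluate.bootstrap_ci(sub, _rmse_stat, B=B, seed=seed)
                rec.update(
                    rmse_median=bs_rmse.median, rmse_lower=bs_rmse.lower, rmse_upper=bs_rmse.upper
                )
                bs_r2 = evaluate.bootstrap_ci(sub, _r2_stat, B=B, seed=seed)
                rec.update(r2_median=bs_r2.median, r2_lower=bs_r2.lower, r2_upper=bs_r2.upper)
            except Exception:
                pass
        rows.append(rec)
    return rows


def run_pipeline(
    config: PipelineConfig,
    vf: pd.DataFrame | None = None,
    ehr: pd.DataFrame | None = None,
    out_dir=None,
) -> dict:
    """Run the full two-stage pipeline and return the machine-readable report.

    When `vf`/`ehr` are omitted a synthetic cohort is generated from
    ``config.sim``. Artifacts (cohort tables, models, predictions, report)
    are written under `out_dir` when given.
    """
    config.validate()
    timings: dict = {}
    report: dict = {"timings": timings}
    t0 = time.perf_counter()

    if vf is None or ehr is None:
        vf, ehr, _truth = simulate_cohort(config.sim)
    timings["simulate_s"] = round(time.perf_counter() - t0, 3)

    # --- cohort preparation -----------------------------------------------
    t0 = time.perf_counter()
    series, labels, split, audit = prepare(vf, config)
    report["filter_audit"] = audit
    report["counts"] = {
        "vf_rows_in": int(len(vf)),
        "vf_rows_retained": int(len(series)),
        "eyes": int(len(labels)),
        "patients": int(labels["patient_id"].nunique()),
        "fast_eyes": int((labels["label"] == FAST).sum()),
        "split": labels.groupby("split")["patient_id"].nunique().to_dict(),
    }
    timings["prepare_s"] = round(time.perf_counter() - t0, 3)

    # --- stage-1 features and classifier ----------------------------------
    t0 = time.perf_counter()
    base_feats = cohort.baseline_vf_features(series)
    base_feats = base_feats.merge(labels[EYE_KEY + ["label", "split"]], on=EYE_KEY, how="inner")
    train_mask = (base_feats["split"] == "train").to_numpy()
    fm = cohort.build_feature_matrix(
        ehr, base_feats.drop(columns=["label", "split"]), train_mask
    )
    y_all = (base_feats["label"] == FAST).astype(int).to_numpy()
    sp = base_feats["split"].to_numpy()
    w = stage1.compute_class_weight(y_all[sp == "train"])
    clf = stage1.fit_weighted_logistic(
        fm.X.loc[sp == "train"], y_all[sp == "train"], w=w, C=config.classifier_C
    )
    val_probs = clf.predict_proba(fm.X.loc[sp == "validation"])
    try:
        clf.threshold = stage1.select_threshold(val_probs, y_all[sp == "validation"])
    except DataError:
        warnings.warn(
            "validation split has no fast eyes: decision threshold defaults to 0.5",
            stacklevel=2,
        )
        clf.threshold = 0.5
    test_probs = clf.predict_proba(fm.X.loc[sp == "test"])
    report["stage1"] = {
        "class_weight": w,
        "threshold": clf.threshold,
        "test_metrics": evaluate.classification_metrics(
            test_probs, y_all[sp == "test"], clf.threshold
        ),
    }
    timings["stage1_s"] = round(time.perf_counter() - t0, 3)

    # --- stratified FPCA on training eyes ----------------------------------
    t0 = time.perf_counter()
    models: dict = {}
    report["fpca"] = {}
    train_labels = base_feats.loc[sp == "train"]
    for stratum in (FAST, SLOW):
        keys = train_labels.loc[train_labels["label"] == stratum, EYE_KEY]
        sample = _series_list(series, keys)
        models[stratum] = fpca.fit_fpca(sample, config.fpca, stratum=stratum)
        mdl = models[stratum]
        report["fpca"][stratum] = {
            "n_subjects": mdl.report["n_subjects"],
            "lam": list(map(float, mdl.lam)),
            "sigma2": mdl.sigma2,
            "fve": list(map(float, mdl.fve)),
            "bandwidths": mdl.bandwidths,
        }
    timings["fpca_s"] = round(time.perf_counter() - t0, 3)

    # --- routed prediction on the test split -------------------------------
    t0 = time.perf_counter()
    test_feats = base_feats.loc[sp == "test"].reset_index(drop=True)
    routed = np.where(test_probs >= clf.threshold, FAST, SLOW)
    pair_rows = []
    grouped = dict(tuple(series.groupby(EYE_KEY, sort=False)))
    for i, (pid, eye) in enumerate(test_feats[EYE_KEY].itertuples(index=False)):
        g = grouped[(pid, eye)]
        t = g["t"].to_numpy(float)
        md = g["md_db"].to_numpy(float)
        base = t <= BASELINE_WINDOW_DAYS
        mdl = models[routed[i]]
        scores = fpca.compute_scores_pace((t[base], md[base]), mdl)
        pred = fpca.predict_trajectory(scores, mdl)
        held = ~base & (t <= mdl.grid[-1])
        if not held.any():
            continue
        pred_md = fpca.interpolate_md(pred, t[held])
        for tt, act, pv in zip(t[held], md[held], np.atleast_1d(pred_md)):
            pair_rows.append(
                {
                    "patient_id": pid,
                    "eye": eye,
                    "t": float(tt),
                    "actual": float(act),
                    "predicted": float(pv),
                    "true_label": test_feats["label"].iloc[i],
                    "predicted_label": routed[i],
                }
            )
    pairs = pd.DataFrame(pair_rows)
    timings["predict_s"] = round(time.perf_counter() - t0, 3)

    # --- evaluation ---------------------------------------------------------
    t0 = time.perf_counter()
    bseed = config.stage_seed(2)
    report["trajectory"] = {}
    for strat_col, key in (("true_label", "by_true_label"), ("predicted_label", "by_predicted_label")):
        report["trajectory"][key] = {}
        for stratum in (FAST, SLOW):
            sub = pairs.loc[pairs[strat_col] == stratum] if len(pairs) else pairs
            report["trajectory"][key][stratum] = (
                _stratum_rows(sub, config.bootstrap_B, bseed) if len(sub) else []
            )
    timings["evaluate_s"] = round(time.perf_counter() - t0, 3)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        series.to_csv(out / "retained_vf.csv", index=False)
        labels.to_csv(out / "labels.csv", index=False)
        split.to_csv(out / "split.csv", index=False)
        pairs.to_csv(out / "predictions.csv", index=False)
        clf.save(out / "stage1_model.json")
        for stratum, mdl in models.items():
            mdl.save(out / f"fpca_{stratum}")
        (out / "run_report.json").write_text(json.dumps(report, indent=2, default=float))

    report["_artifacts"] = {
        "models": models,
        "classifier": clf,
        "pairs": pairs,
        "labels": labels,
        "features": fm,
    }
    return report
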