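"""Cohort construction: inclusion filters, slope labeling, splits, features.

Implements the study's eligibility rules for visual-field tests (reliability
indices below 33%, white background, no 10-2 pattern, adults, no prior
glaucoma surgery), per-eye majority-strategy resolution, the minimum-3-test
rule, OLS mean-deviation slopes, Tukey-fence outlier removal, strict
fast/slow labeling at −1 dB/year, patient-level 80:10:10 splitting, and the
Stage-1 feature matrix with training-only imputation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError
from .simulate import FAST, SLOW

EYE_KEY = ["patient_id", "eye"]

#: Days in the baseline window, inclusive: "up to one year of baseline VF".
BASELINE_WINDOW_DAYS = 365


@dataclass
class FilterCriteria:
    """Record-level inclusion rules for visual-field tests."""

    max_fixation_loss: float = 0.33  # strict upper bound
    max_false_neg: float = 0.33
    required_background: str = "white"
    excluded_patterns: tuple = ("10-2",)
    min_age: float = 18.0
    exclude_post_surgery: bool = True


def filter_vf_tests(records: pd.DataFrame, criteria: FilterCriteria | None = None):
    """Apply record-level inclusion rules.

    Returns ``(retained, audit)`` where `audit` maps each rule name to the
    number of records it excluded (a record failing several rules counts
    toward each).
    """
    criteria = criteria or FilterCriteria()
    for col in ("fixation_loss", "false_neg", "age"):
        vals = pd.to_numeric(records[col], errors="coerce")
        if vals.isna().any():
            idx = int(np.flatnonzero(vals.isna().to_numpy())[0])
            raise DataError(f"unparseable {col} at row index {records.index[idx]}")
        records = records.assign(**{col: vals})

    fails = {
        "fixation_loss": records["fixation_loss"] >= criteria.max_fixation_loss,
        "false_neg": records["false_neg"] >= criteria.max_false_neg,
        "background": records["background"] != criteria.required_background,
        "pattern": records["pattern"].isin(criteria.excluded_patterns),
        "age": records["age"] < criteria.min_age,
    }
    if criteria.exclude_post_surgery:
        fails["post_surgery"] = records["post_surgery"].astype(bool)
    audit = {rule: int(mask.sum()) for rule, mask in fails.items()}
    any_fail = np.logical_or.reduce([m.to_numpy() for m in fails.values()])
    return records.loc[~any_fail].copy(), audit


def resolve_test_strategy(eye_records: pd.DataFrame) -> pd.DataFrame:
    """Keep only the modal (strategy, stimulus) combination of one eye.

    Ties are broken in favor of the combination of the chronologically first
    test of the eye.
    """
    if eye_records.empty:
        return eye_records
    combos = list(zip(eye_records["strategy"], eye_records["stimulus"]))
    counts: dict = {}
    for c in combos:
        counts[c] = counts.get(c, 0) + 1
    best_n = max(counts.values())
    tied = [c for c, n in counts.items() if n == best_n]
    if len(tied) > 1:
        order = np.argsort(eye_records["test_date"].to_numpy(), kind="stable")
        first = combos[order[0]]
        winner = first if first in tied else tied[0]
    else:
        winner = tied[0]
    keep = [c == winner for c in combos]
    return eye_records.loc[keep].copy()


def resolve_strategies(records: pd.DataFrame) -> pd.DataFrame:
    """Apply majority-strategy resolution per eye across a whole table."""
    parts = [resolve_test_strategy(g) for _, g in records.groupby(EYE_KEY, sort=False)]
    return pd.concat(parts, ignore_index=False) if parts else records


def apply_min_test_filter(records: pd.DataFrame, min_tests: int = 3) -> pd.DataFrame:
    """Keep eyes with at least `min_tests` retained tests."""
    counts = records.groupby(EYE_KEY)["test_date"].transform("count")
    return records.loc[counts >= min_tests].copy()


def compute_md_slope(t_days, md) -> float:
    """OLS slope of MD against time in years (days / 365)."""
    t = np.asarray(t_days, dtype=float) / 365.0
    y = np.asarray(md, dtype=float)
    if len(t) < 2 or np.ptp(t) == 0:
        raise DataError("slope undefined: need >=2 tests with distinct dates")
    tc = t - t.mean()
    return float(np.dot(tc, y - y.mean()) / np.dot(tc, tc))


def tukey_outlier_filter(slopes: pd.Series, fences_from: pd.Series | None = None):
    """Split eyes into retained/removed by Tukey fences on the slope distribution.

    Quantiles use linear interpolation of order statistics (position
    (n−1)p + 1). With fewer than 4 values the filter is a no-op with a
    warning. `fences_from` optionally supplies the values the fences are
    computed on (e.g. training-split slopes) while the filter is applied to
    all of `slopes`.
    """
    ref = slopes if fences_from is None else fences_from
    ref = ref.dropna()
    if len(ref) < 4:
        import warnings

        warnings.warn("fewer than 4 slopes: Tukey filter skipped", stacklevel=2)
        return slopes, slopes.iloc[0:0]
    q1, q3 = np.quantile(ref.to_numpy(), [0.25, 0.75], method="linear")
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    out = (slopes < lo) | (slopes > hi)
    return slopes.loc[~out], slopes.loc[out]


def label_progressor(slope: float) -> str:
    """Fast iff the MD slope is strictly worse than −1 dB/year."""
    if not np.isfinite(slope):
        raise DataError("cannot label a non-finite slope")
    return FAST if slope < -1.0 else SLOW


def eye_series_table(records: pd.DataFrame) -> pd.DataFrame:
    """Normalize a retained VF table into per-eye series with t = days since
    the eye's first retained test, sorted and strictly increasing."""
    recs = records.sort_values(EYE_KEY + ["test_date"]).copy()
    recs["t"] = recs.groupby(EYE_KEY)["test_date"].transform(lambda s: s - s.min())
    return recs


def label_table(series: pd.DataFrame) -> pd.DataFrame:
    """Per-eye slope / label / test-count table from normalized series."""
    rows = []
    for (pid, eye), g in series.groupby(EYE_KEY, sort=False):
        slope = compute_md_slope(g["t"], g["md_db"])
        rows.append(
            {
                "patient_id": pid,
                "eye": eye,
                "slope": slope,
                "label": label_progressor(slope),
                "n_tests": len(g),
            }
        )
    return pd.DataFrame(rows)


def split_by_patient(patient_ids, ratios=(0.8, 0.1, 0.1), seed: int = 0) -> pd.DataFrame:
    """Assign whole patients to train/validation/test by seeded permutation."""
    ratios = np.asarray(ratios, dtype=float)
    if np.any(ratios <= 0) or not np.isclose(ratios.sum(), 1.0):
        raise DataError("ratios must be positive and sum to 1")
    pids = pd.unique(pd.Series(patient_ids))
    n = len(pids)
    if n < len(ratios):
        raise DataError("fewer patients than splits")
    perm = np.random.default_rng(seed).permutation(n)
    bounds = np.floor(np.cumsum(ratios) * n + 1e-9).astype(int)
    names = ["train", "validation", "test"]
    assign = np.empty(n, dtype=object)
    start = 0
    for name, stop in zip(names, bounds):
        assign[perm[start:stop]] = name
        start = stop
    assign[perm[start:]] = names[-1]
    return pd.DataFrame({"patient_id": pids, "split": assign})


# ---------------------------------------------------------------------------
# Stage-1 feature matrix

_NUMERIC_EHR = ["va_logmar", "iop_max", "cdr", "cct", "sph_eq", "age_baseline"]
_CATEGORICAL = ["race", "sex"]


@dataclass
class FeatureMatrix:
    """Per-eye design matrix plus the column/imputation metadata used to build it."""

    X: pd.DataFrame
    keys: pd.DataFrame  # patient_id, eye per row of X
    imputation: dict = field(default_factory=dict)
    categories: dict = field(default_factory=dict)


def baseline_vf_features(series: pd.DataFrame) -> pd.DataFrame:
    """Per-eye features from the baseline window (t <= 365 days): earliest-test
    MD/PSD, test count, and the within-baseline OLS slope when >=2 tests."""
    rows = []
    for (pid, eye), g in series.groupby(EYE_KEY, sort=False):
        base = g.loc[g["t"] <= BASELINE_WINDOW_DAYS].sort_values("t")
        if base.empty:
            continue
        row = {
            "patient_id": pid,
            "eye": eye,
            "baseline_md": float(base["md_db"].iloc[0]),
            "baseline_psd": float(base["psd_db"].iloc[0]),
            "n_baseline_tests": int(len(base)),
        }
        if len(base) >= 2 and np.ptp(base["t"].to_numpy()) > 0:
            row["baseline_slope"] = compute_md_slope(base["t"], base["md_db"])
            row["baseline_slope_defined"] = 1
        else:
            row["baseline_slope"] = np.nan  # imputed 0 with indicator
            row["baseline_slope_defined"] = 0
        rows.append(row)
    return pd.DataFrame(rows)


def build_feature_matrix(
    ehr: pd.DataFrame, baseline_vf: pd.DataFrame, train_mask
) -> FeatureMatrix:
    """Join patient EHR rows onto per-eye baseline VF features and encode.

    Numeric missing values are imputed with the training-row mean; missing race
    becomes the "Other" level; categoricals are one-hot encoded with explicit
    `column=level` names; the within-baseline slope is imputed 0 when undefined
    (its companion indicator column carries the distinction). Categorical
    levels present only outside the training rows raise an error naming the
    column.
    """
    df = baseline_vf.merge(ehr, on="patient_id", how="left", validate="many_to_one")
    train_mask = np.asarray(train_mask, dtype=bool)
    if train_mask.shape[0] != len(df):
        raise DataError("train mask length does not match feature rows")

    keys = df[EYE_KEY].reset_index(drop=True)
    numeric_cols = [c for c in _NUMERIC_EHR if c in df.columns] + [
        "baseline_md",
        "baseline_psd",
        "n_baseline_tests",
    ]
    indicator_cols = sorted(
        c for c in df.columns if c.startswith("dx_") or c.startswith("med_")
    )
    imputation: dict = {}
    out = {}
    for col in numeric_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        mean = float(vals[train_mask].mean())
        imputation[col] = mean
        out[col] = vals.fillna(mean).to_numpy(dtype=float)
    # within-baseline slope: undefined -> 0, flagged by the indicator column
    slope = pd.to_numeric(df["baseline_slope"], errors="coerce")
    out["baseline_slope"] = slope.fillna(0.0).to_numpy(dtype=float)
    imputation["baseline_slope"] = 0.0
    out["baseline_slope_defined"] = df["baseline_slope_defined"].to_numpy(dtype=float)
    for col in indicator_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        mean = float(vals[train_mask].mean())
        imputation[col] = mean
        out[col] = vals.fillna(mean).to_numpy(dtype=float)

    categories: dict = {}
    for col in _CATEGORICAL:
        if col not in df.columns:
            continue
        vals = df[col].astype(object).where(df[col].notna(), None)
        vals = ["" if v is None else str(v) for v in vals]
        if col == "race":
            vals = ["Other" if v == "" else v for v in vals]
        levels = sorted({v for v, m in zip(vals, train_mask) if m})
        unseen = {v for v in vals if v not in levels}
        if unseen:
            raise DataError(
                f"column {col!r}: level(s) {sorted(unseen)} never observed in training rows"
            )
        categories[col] = levels
        for lev in levels:
            out[f"{col}={lev}"] = np.array([1.0 if v == lev else 0.0 for v in vals])

    X = pd.DataFrame(out)
    if X.isna().any().any():
        raise DataError("feature matrix contains missing cells after imputation")
    return FeatureMatrix(X=X, keys=keys, imputation=imputation, categories=categories)


def prepare_cohort(
    vf: pd.DataFrame,
    criteria: FilterCriteria | None = None,
    min_tests: int = 3,
):
    """Record filters → strategy resolution → min-test rule → normalized series.

    Returns ``(series, audit)``; slope labeling and the Tukey filter are left
    to the caller because the fences may be restricted to training slopes.
    """
    retained, audit = filter_vf_tests(vf, criteria)
    n_after_record_filters = len(retained)
    retained = resolve_strategies(retained)
    audit["minority_strategy"] = int(n_after_record_filters - len(retained))
    n_before = len(retained)
    retained = apply_min_test_filter(retained, min_tests)
    audit["min_tests"] = int(n_before - len(retained))
    return eye_series_table(retained), audit
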