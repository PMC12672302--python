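"""Evaluation: trajectory RMSE/R² by prediction horizon with bootstrap CIs,
and the binary-classification metric panel.

Horizons are measured from the end of the one-year baseline window (day 365):
bin k covers held-out tests with k*365 < t − 365 <= ... (index floor((t−365)/365)),
bins 0-5 are labeled "Year 0-1" .. "Year 5-6", everything at or beyond six
post-baseline years lands in "Year >6", and "Overall (all years)" pools all
evaluated pairs. The bootstrap resamples eyes (not individual pairs) with
replacement, preserving within-eye correlation, and reports the replicate
median with a 95% percentile interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .errors import DataError

EYE_KEY = ["patient_id", "eye"]
BASELINE_END_DAY = 365.0
BIN_LABELS = [
    "Year 0-1",
    "Year 1-2",
    "Year 2-3",
    "Year 3-4",
    "Year 4-5",
    "Year 5-6",
    "Year >6",
]
OVERALL_LABEL = "Overall (all years)"


def trajectory_metrics(actual, predicted) -> tuple[float, float]:
    """RMSE and R² of predicted vs actual MD values.

    R² = 1 − SS_res/SS_tot with SS_tot taken about the mean of the actual
    values within the evaluated set.
    """
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if len(a) == 0:
        raise DataError("no prediction pairs to evaluate")
    rmse = float(np.sqrt(np.mean((a - p) ** 2)))
    ss_tot = float(np.sum((a - a.mean()) ** 2))
    if len(a) < 2 or ss_tot == 0.0:
        raise DataError("R² undefined: need >=2 pairs with nonconstant actuals")
    r2 = 1.0 - float(np.sum((a - p) ** 2)) / ss_tot
    return rmse, r2


def horizon_bin(t_days: float) -> str | None:
    """Bin label for a held-out test at day `t_days`; None inside baseline."""
    h = t_days - BASELINE_END_DAY
    if h <= 0:
        return None
    idx = int(np.floor(h / 365.0))
    return BIN_LABELS[idx] if idx < 6 else BIN_LABELS[6]


def horizon_stratified_metrics(pairs: pd.DataFrame):
    """Per-horizon-bin and overall RMSE/R² rows.

    `pairs` needs columns patient_id, eye, t, actual, predicted. Pairs with
    t <= 365 are excluded and counted. R² is NaN where undefined (fewer than
    2 pairs or constant actuals in a bin). Returns ``(report, n_excluded)``.
    """
    pairs = pairs.copy()
    bins = pairs["t"].map(horizon_bin)
    n_excluded = int(bins.isna().sum())
    pairs = pairs.loc[bins.notna()]
    bins = bins.dropna()
    rows = []
    for label in BIN_LABELS + [OVERALL_LABEL]:
        sub = pairs if label == OVERALL_LABEL else pairs.loc[bins == label]
        row = {"interval": label, "n": int(len(sub))}
        if len(sub):
            a = sub["actual"].to_numpy(float)
            p = sub["predicted"].to_numpy(float)
            row["rmse"] = float(np.sqrt(np.mean((a - p) ** 2)))
            ss_tot = float(np.sum((a - a.mean()) ** 2))
            row["r2"] = (
                1.0 - float(np.sum((a - p) ** 2)) / ss_tot if len(a) >= 2 and ss_tot > 0 else np.nan
            )
        else:
            row["rmse"] = np.nan
            row["r2"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows), n_excluded


@dataclass
class BootstrapResult:
    median: float
    lower: float
    upper: float
    n_dropped: int = 0


def bootstrap_ci(
    pairs: pd.DataFrame,
    statistic,
    B: int = 1000,
    seed: int = 0,
    indices=None,
) -> BootstrapResult:
    """Eye-level nonparametric bootstrap of a statistic of prediction pairs.

    Eyes are resampled with replacement and all pairs of a resampled eye enter
    the replicate (repeated eyes repeat their pairs). `statistic` maps arrays
    ``(actual, predicted)`` to a float; replicates where it raises or returns
    NaN are dropped and counted. `indices` optionally supplies the resample
    index arrays (shape (B, n_eyes)) for index-level cross-checks.
    """
    if B < 1:
        raise DataError("B must be at least 1")
    groups = [g[["actual", "predicted"]].to_numpy(float) for _, g in pairs.groupby(EYE_KEY, sort=True)]
    n = len(groups)
    if n == 0:
        raise DataError("no prediction pairs to bootstrap")
    if indices is None:
        rng = np.random.default_rng(seed)
        indices = rng.integers(0, n, size=(B, n))
    else:
        indices = np.asarray(indices)
        B = indices.shape[0]
    stats = []
    n_dropped = 0
    for b in range(B):
        arr = np.concatenate([groups[i] for i in indices[b]], axis=0)
        try:
            val = statistic(arr[:, 0], arr[:, 1])
        except DataError:
            val = np.nan
        if np.isnan(val):
            n_dropped += 1
        else:
            stats.append(val)
    if not stats:
        raise DataError("statistic undefined in every bootstrap replicate")
    stats = np.asarray(stats)
    return BootstrapResult(
        median=float(np.percentile(stats, 50)),
        lower=float(np.percentile(stats, 2.5)),
        upper=float(np.percentile(stats, 97.5)),
        n_dropped=n_dropped,
    )


def classification_metrics(probs, labels, tau: float) -> dict:
    """Confusion panel at threshold tau plus AUROC (trapezoid over the ROC)
    and AUPRC (step interpolation). One-class labels leave AUROC/AUPRC NaN
    with a warning while the threshold metrics are still computed."""
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=int)
    if np.any((p < 0) | (p > 1)):
        raise DataError("probabilities must lie in [0, 1]")
    pred = (p >= tau).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))

    def _div(a, b):
        return a / b if b else np.nan

    sens = _div(tp, tp + fn)
    spec = _div(tn, tn + fp)
    panel = {
        "threshold": float(tau),
        "accuracy": _div(tp + tn, tp + tn + fp + fn),
        "balanced_accuracy": (sens + spec) / 2.0,
        "sensitivity": sens,
        "specificity": spec,
        "ppv": _div(tp, tp + fp),
        "npv": _div(tn, tn + fn),
        "f1": _div(2 * tp, 2 * tp + fp + fn),
        "confusion": {"tp": tp, "fp": fp, "fn": fn, "tn": tn},
    }
    if len(np.unique(y)) < 2:
        warnings.warn("one-class labels: AUROC/AUPRC undefined", stacklevel=2)
        panel["auroc"] = np.nan
        panel["auprc"] = np.nan
    else:
        panel["auroc"] = float(roc_auc_score(y, p))
        panel["auprc"] = float(average_precision_score(y, p))
    return panel


def subgroup_metrics(
    pairs: pd.DataFrame,
    group_col: str,
    known_groups=None,
    min_eyes: int = 5,
    B: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Overall trajectory metrics with bootstrap CIs per subgroup.

    Groups with fewer than `min_eyes` eyes are flagged insufficient; values
    outside `known_groups` (when given) are pooled under "Other" with a
    warning.
    """
    pairs = pairs.copy()
    groups = pairs[group_col].astype(str)
    if known_groups is not None:
        unknown = ~groups.isin(list(known_groups))
        if unknown.any():
            warnings.warn(
                f"{int(unknown.sum())} pairs with unknown {group_col} grouped under 'Other'",
                stacklevel=2,
            )
            groups = groups.where(~unknown, "Other")
    pairs[group_col] = groups
    rows = []
    for name, sub in pairs.groupby(group_col, sort=True):
        n_eyes = sub[EYE_KEY].drop_duplicates().shape[0]
        row = {"group": name, "n_eyes": n_eyes, "n_pairs": len(sub)}
        if n_eyes < min_eyes:
            row["status"] = "insufficient"
            rows.append(row)
            continue
        row["status"] = "ok"
        rmse, r2 = trajectory_metrics(sub["actual"], sub["predicted"])
        row["rmse"], row["r2"] = rmse, r2
        bs_rmse = bootstrap_ci(
            sub, lambda a, p: float(np.sqrt(np.mean((a - p) ** 2))), B=B, seed=seed
        )
        bs_r2 = bootstrap_ci(sub, _r2_stat, B=B, seed=seed)
        row.update(
            rmse_median=bs_rmse.median,
            rmse_lower=bs_rmse.lower,
            rmse_upper=bs_rmse.upper,
            r2_median=bs_r2.median,
            r2_lower=bs_r2.lower,
            r2_upper=bs_r2.upper,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def _rmse_stat(a, p) -> float:
    return float(np.sqrt(np.mean((a - p) ** 2)))


def _r2_stat(a, p) -> float:
    ss_tot = float(np.sum((a - np.mean(a)) ** 2))
    if len(a) < 2 or ss_tot == 0.0:
        return np.nan
    return 1.0 - float(np.sum((a - p) ** 2)) / ss_tot
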