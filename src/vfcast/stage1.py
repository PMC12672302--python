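"""Stage-1 progressor classifier: class-weighted L2 logistic regression.

The fast class is rare (~9%), so the fast-class log-likelihood terms are
weighted by w = N_slow / N_fast computed on the training split. Features are
standardized internally from training statistics; the decision threshold is
tuned on the validation split to maximize fast-class F1. Feature importance is
ranked both by coefficient magnitude and by effect size (beta / SE), with SEs
from the weighted, penalty-free observed information at the fitted optimum.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .errors import DataError, FitError

THRESHOLD_GRID = np.round(np.arange(1, 100) * 0.01, 2)


@dataclass
class ClassifierModel:
    feature_names: list
    mean: np.ndarray  # training standardization means
    sd: np.ndarray  # training standardization SDs (zero-variance -> 1)
    coef: np.ndarray  # on the standardized scale
    intercept: float
    C: float = 1.0
    class_weight: float = 1.0
    threshold: float = 0.5

    def standardize(self, X: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.feature_names if f not in X.columns]
        if missing:
            raise DataError(f"missing feature(s): {missing}")
        arr = X[self.feature_names].to_numpy(dtype=float)
        return (arr - self.mean) / self.sd

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        z = self.standardize(X) @ self.coef + self.intercept
        return 1.0 / (1.0 + np.exp(-z))

    def save(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = {
            "feature_names": list(self.feature_names),
            "mean": list(map(float, self.mean)),
            "sd": list(map(float, self.sd)),
            "coef": list(map(float, self.coef)),
            "intercept": float(self.intercept),
            "C": float(self.C),
            "class_weight": float(self.class_weight),
            "threshold": float(self.threshold),
        }
        path.write_text(json.dumps(payload, indent=2))

    @classmethod
    def load(cls, path) -> "ClassifierModel":
        d = json.loads(Path(path).read_text())
        return cls(
            feature_names=d["feature_names"],
            mean=np.asarray(d["mean"]),
            sd=np.asarray(d["sd"]),
            coef=np.asarray(d["coef"]),
            intercept=d["intercept"],
            C=d["C"],
            class_weight=d["class_weight"],
            threshold=d["threshold"],
        )


def compute_class_weight(labels) -> float:
    """w = N_slow / N_fast on the training labels (1 = fast)."""
    y = np.asarray(labels)
    n_fast = int(np.sum(y == 1))
    n_slow = int(np.sum(y == 0))
    if n_fast == 0 or n_slow == 0:
        raise DataError("both classes must be present to compute a class weight")
    return n_slow / n_fast


def fit_weighted_logistic(
    X: pd.DataFrame, y, w: float, C: float = 1.0, threshold: float = 0.5
) -> ClassifierModel:
    """Maximize the weighted log-likelihood minus ||beta||²/(2C), intercept
    unpenalized; deterministic for fixed data (convex, tight tolerance)."""
    y = np.asarray(y, dtype=int)
    arr = X.to_numpy(dtype=float)
    if not np.all(np.isfinite(arr)):
        raise DataError("feature matrix contains non-finite values")
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (arr - mean) / sd
    clf = LogisticRegression(
        C=C, class_weight={0: 1.0, 1: float(w)}, solver="lbfgs", tol=1e-12, max_iter=20000
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(Z, y)
    if clf.n_iter_[0] >= 20000:
        grad = _penalized_gradient_norm(Z, y, w, C, clf.coef_[0], clf.intercept_[0])
        raise FitError(f"logistic fit did not converge (gradient norm {grad:.3e})")
    return ClassifierModel(
        feature_names=list(X.columns),
        mean=mean,
        sd=sd,
        coef=clf.coef_[0].copy(),
        intercept=float(clf.intercept_[0]),
        C=float(C),
        class_weight=float(w),
        threshold=float(threshold),
    )


def _penalized_gradient_norm(Z, y, w, C, beta, b):
    p = 1.0 / (1.0 + np.exp(-(Z @ beta + b)))
    s = np.where(y == 1, w, 1.0)
    g_beta = Z.T @ (s * (p - y)) + beta / C
    g_b = np.sum(s * (p - y))
    return float(np.sqrt(np.sum(g_beta**2) + g_b**2))


def _f1(y_true, y_pred) -> float:
    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    fp = int(np.sum((y_pred == 1) & (y_true == 0)))
    fn = int(np.sum((y_pred == 0) & (y_true == 1)))
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def select_threshold(probs, labels) -> float:
    """Scan tau over {0.01, ..., 0.99}; return the smallest tau maximizing the
    fast-class F1 on the validation set (smallest favors sensitivity)."""
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=int)
    if np.sum(y == 1) == 0:
        raise DataError("no positive labels in validation set")
    if np.any((probs < 0) | (probs > 1)):
        raise DataError("probabilities must lie in [0, 1]")
    best_tau, best_f1 = None, -1.0
    for tau in THRESHOLD_GRID:
        f1 = _f1(y, (probs >= tau).astype(int))
        if f1 > best_f1 + 1e-12:
            best_f1, best_tau = f1, float(tau)
    return best_tau


def predict_class(model: ClassifierModel, row) -> tuple[float, str]:
    """Probability and routed label for one feature row (fast iff p >= tau)."""
    if isinstance(row, dict):
        row = pd.Series(row)
    missing = [f for f in model.feature_names if f not in row.index]
    if missing:
        raise DataError(f"missing feature(s): {missing}")
    x = row[model.feature_names].to_numpy(dtype=float)
    z = float((x - model.mean) / model.sd @ model.coef + model.intercept)
    p = 1.0 / (1.0 + np.exp(-z))
    return p, ("fast" if p >= model.threshold else "slow")


def feature_importance(model: ClassifierModel, X: pd.DataFrame, y) -> pd.DataFrame:
    """Rank features by |beta| and by effect size beta/SE.

    SEs come from the inverse of the weighted, penalty-free observed
    information at the fitted coefficients. A singular information matrix
    (e.g. perfectly collinear columns) leaves SEs undefined with a warning,
    and those features are excluded from the effect-size ranking.
    """
    y = np.asarray(y, dtype=int)
    Z = model.standardize(X)
    Zb = np.column_stack([np.ones(len(Z)), Z])
    p = 1.0 / (1.0 + np.exp(-(Zb @ np.concatenate([[model.intercept], model.coef]))))
    s = np.where(y == 1, model.class_weight, 1.0)
    W = s * p * (1.0 - p)
    H = Zb.T @ (Zb * W[:, None])
    se = np.full(len(model.coef), np.nan)
    cond = np.linalg.cond(H)
    if not np.isfinite(cond) or cond > 1e12:
        warnings.warn("singular information matrix: standard errors undefined", stacklevel=2)
    else:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.diag(cov))[1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        effect = model.coef / se
    out = pd.DataFrame(
        {
            "feature": model.feature_names,
            "beta": model.coef,
            "abs_beta": np.abs(model.coef),
            "se": se,
            "effect_size": effect,
        }
    )
    out["rank_magnitude"] = out["abs_beta"].rank(ascending=False, method="min").astype(int)
    eff = out["effect_size"].abs()
    out["rank_effect"] = eff.rank(ascending=False, method="min")
    return out.sort_values("rank_magnitude").reset_index(drop=True)
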