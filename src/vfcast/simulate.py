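"""Seeded synthetic glaucoma cohort generator.

Produces visual-field (VF) test tables and baseline EHR feature tables with the
statistical structure the two-stage pipeline assumes, together with the latent
truth (classes, scores, mean functions, eigenfunctions) for recovery tests.

The trajectory model is a two-component Karhunen–Loève expansion per latent
progression class:

    Y_ij = mu_class(t_ij) + xi_i1 * phi1(t_ij) + xi_i2 * phi2(t_ij) + eps_ij

with phi1 a flat (constant) mode — persistent eye-to-eye offsets in MD — and
phi2 a one-cycle cosine — slow oscillation around the class mean; eps_ij is
i.i.d. Gaussian measurement noise. Visit schedules are sparse and irregular:
each eye starts at day 0, has a lognormal follow-up span, and lognormal
inter-test gaps calibrated so the median retained test count is 4.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

FAST = "fast"
SLOW = "slow"

#: Lognormal gap-scale constant: gap median = _GAP_SCALE * span_median / (visit_rate - 1),
#: calibrated once by simulation so the median visit count equals the configured target
#: (4) under the default follow-up-span distribution.
_GAP_SCALE = 0.70

#: Per-class (slow, fast) means and SDs of the continuous baseline features.
_CONTINUOUS = {
    "va_logmar": ((0.13, 0.33), (0.12, 0.30)),
    "iop_max": ((21.57, 7.36), (21.58, 7.16)),
    "cdr": ((0.62, 0.08), (0.62, 0.09)),
    "cct": ((558.95, 15.99), (558.37, 13.93)),
    "sph_eq": ((-2.36, 3.24), (-2.35, 3.51)),
    "age_baseline": ((60.64, 14.86), (56.69, 16.62)),
}

#: Race/ethnicity category probabilities per class (slow, fast).
_RACE_LEVELS = ["White", "Black", "Hispanic", "Asian", "Other", "NotGiven"]
_RACE_PROBS = {
    SLOW: [0.3684, 0.0262, 0.0858, 0.3963, 0.1090, 0.0143],
    FAST: [0.2825, 0.0332, 0.1108, 0.4377, 0.1302, 0.0056],
}
_FEMALE_PROB = {SLOW: 0.5074, FAST: 0.5247}

#: Baseline prevalence of the binary diagnosis/medication indicators.
_INDICATOR_BASE = {
    "med_pga": 0.45,
    "med_beta_blocker": 0.30,
    "dx_systemic_htn": 0.35,
    "dx_diabetes": 0.20,
}

#: Default additive log-odds on indicator prevalence for fast-class patients,
#: calibrated once so Stage-1 AUROC on synthetic cohorts lands near 0.77.
_DEFAULT_EFFECTS = {
    "med_pga": 2.0,
    "med_beta_blocker": 1.3,
    "dx_systemic_htn": 0.9,
    "dx_diabetes": 0.7,
}

_DEFAULT_MISSINGNESS = {
    "va_logmar": 0.005,
    "iop_max": 0.005,
    "cdr": 0.005,
    "cct": 0.005,
    "sph_eq": 0.27,
    "race": 0.013,
}

_DEFAULT_EXCLUSION_RATES = {
    "unreliable": 0.03,
    "pattern_10_2": 0.01,
    "post_surgery": 0.01,
    "minority_strategy": 0.02,
}

VF_COLUMNS = [
    "patient_id",
    "eye",
    "test_date",
    "md_db",
    "psd_db",
    "fixation_loss",
    "false_neg",
    "strategy",
    "pattern",
    "stimulus",
    "background",
    "age",
    "post_surgery",
]


@dataclass
class SimConfig:
    """Generative parameters of a synthetic cohort.

    Defaults emulate the published cohort composition: ~8.92% fast progressors,
    class mean slopes −2.51 / +0.20 dB/year, baseline MD −5.11 ± 6.33 dB,
    median 4 tests per eye over a 10-year window, median follow-up span 1651
    days. Inter-eye score correlation (0.5) and the visit-interval model are
    stand-ins: neither is reported for the source cohort.
    """

    n_eyes: int = 2000
    frac_fast: float = 0.0892
    followup_days: int = 3650
    visit_rate: float = 4.0  # target median visit count per eye
    span_median_days: float = 1651.0
    span_log_sd: float = 0.715  # matches Q3 = 2674 d for the lognormal span
    gap_log_sd: float = 0.75
    mean_slope_fast: float = -2.51
    mean_slope_slow: float = 0.20
    baseline_md_mean: float = -5.11
    baseline_md_sd: float = 6.33
    lambda1: float | None = None  # dB²·days; default derived from baseline_md_sd
    lambda2: float | None = 6000.0  # dB²·days
    sigma2: float = 1.0  # dB² measurement noise
    inter_eye_corr: float = 0.5
    two_eye_prob: float = 0.72
    covariate_effect_sizes: dict = field(default_factory=lambda: dict(_DEFAULT_EFFECTS))
    missingness: dict = field(default_factory=lambda: dict(_DEFAULT_MISSINGNESS))
    exclusion_rates: dict = field(default_factory=lambda: dict(_DEFAULT_EXCLUSION_RATES))
    seed: int = 0

    def validate(self) -> None:
        if not (isinstance(self.n_eyes, (int, np.integer)) and self.n_eyes > 0):
            raise ConfigError("n_eyes must be a positive integer")
        if not 0.0 <= self.frac_fast <= 1.0:
            raise ConfigError("frac_fast must lie in [0, 1]")
        if self.followup_days <= 365:
            raise ConfigError("followup_days must exceed 365")
        if self.visit_rate < 1:
            raise ConfigError("visit_rate must be at least 1")
        l1, l2 = self.resolved_lambdas()
        if not (l1 >= l2 > 0):
            raise ConfigError("lambda1/lambda2 must satisfy lambda1 >= lambda2 > 0")
        if self.sigma2 < 0:
            raise ConfigError("sigma2 must be nonnegative")
        if not 0.0 <= self.inter_eye_corr <= 1.0:
            raise ConfigError("inter_eye_corr must lie in [0, 1]")
        if not 0.0 <= self.two_eye_prob <= 1.0:
            raise ConfigError("two_eye_prob must lie in [0, 1]")
        for name, rate in self.missingness.items():
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"missingness rate for {name!r} must lie in [0, 1]")

    def resolved_lambdas(self) -> tuple[float, float]:
        """Score variances, filling derived defaults.

        lambda1 defaults to (baseline_md_sd² − sigma2)·followup_days so the flat
        first mode alone reproduces the configured cross-eye baseline-MD spread.
        """
        l1 = self.lambda1
        if l1 is None:
            l1 = max(self.baseline_md_sd**2 - self.sigma2, 1.0) * self.followup_days
        l2 = self.lambda2 if self.lambda2 is not None else 0.042 * l1
        return float(l1), float(l2)


class SimTruth:
    """Latent truth of a simulated cohort: generative parameters and scores."""

    def __init__(self, config: SimConfig, eyes: pd.DataFrame):
        self.config = config
        self.eyes = eyes  # patient_id, eye, true_class, xi1, xi2
        self.T = float(config.followup_days)
        self.lam1, self.lam2 = config.resolved_lambdas()
        self.sigma2 = float(config.sigma2)
        self.grid = np.linspace(0.0, self.T, 101)

    # -- model functions ---------------------------------------------------
    def mu(self, label: str, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if label == FAST:
            slope = self.config.mean_slope_fast
        elif label == SLOW:
            slope = self.config.mean_slope_slow
        else:
            raise DataError(f"unknown class label {label!r}")
        return self.config.baseline_md_mean + slope * t / 365.0

    def phi(self, k: int, t) -> np.ndarray:
        """Unit-norm eigenfunctions on [0, T]: flat mode, then one-cycle cosine."""
        t = np.asarray(t, dtype=float)
        if k == 1:
            return np.full_like(t, 1.0 / math.sqrt(self.T))
        if k == 2:
            return math.sqrt(2.0 / self.T) * np.cos(2.0 * math.pi * t / self.T)
        raise DataError(f"eigenfunction index {k} out of range (1 or 2)")

    def latent_curve(self, label: str, xi1: float, xi2: float, t) -> np.ndarray:
        return self.mu(label, t) + xi1 * self.phi(1, t) + xi2 * self.phi(2, t)

    def sample_dense(self, label: str, tgrid, n: int, rng, noiseless: bool = True):
        """Draw `n` trajectories observed on a common grid (for covariance checks)."""
        tgrid = np.asarray(tgrid, dtype=float)
        xi1 = rng.normal(0.0, math.sqrt(self.lam1), size=n)
        xi2 = rng.normal(0.0, math.sqrt(self.lam2), size=n)
        curves = (
            self.mu(label, tgrid)[None, :]
            + xi1[:, None] * self.phi(1, tgrid)[None, :]
            + xi2[:, None] * self.phi(2, tgrid)[None, :]
        )
        if not noiseless and self.sigma2 > 0:
            curves = curves + rng.normal(0.0, math.sqrt(self.sigma2), size=curves.shape)
        return curves

    def covariance_surface(self, tgrid) -> np.ndarray:
        """True covariance lam1·phi1⊗phi1 + lam2·phi2⊗phi2 on a grid."""
        p1 = self.phi(1, tgrid)
        p2 = self.phi(2, tgrid)
        return self.lam1 * np.outer(p1, p1) + self.lam2 * np.outer(p2, p2)

    # -- serialization -----------------------------------------------------
    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        header = {
            "config": asdict(self.config),
            "lambda": [self.lam1, self.lam2],
            "sigma2": self.sigma2,
            "domain": [0.0, self.T],
        }
        (out / "truth.json").write_text(json.dumps(header, indent=2))
        tab = pd.DataFrame(
            {
                "t_days": self.grid,
                "mu_fast": self.mu(FAST, self.grid),
                "mu_slow": self.mu(SLOW, self.grid),
                "phi1": self.phi(1, self.grid),
                "phi2": self.phi(2, self.grid),
            }
        )
        tab.to_csv(out / "truth_functions.csv", index=False, float_format="%.17g")
        self.eyes.to_csv(out / "truth_eyes.csv", index=False, float_format="%.17g")


def sample_visit_times(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw one eye's visit schedule: integer days, strictly increasing, first = 0.

    The follow-up span is lognormal (capped at the domain end); inter-test gaps
    are lognormal with median calibrated so the cohort median visit count hits
    the configured target. A visit_rate of 1 forces the degenerate single-visit
    schedule [0].
    """
    if config.visit_rate <= 1:
        return np.array([0.0])
    span = rng.lognormal(math.log(config.span_median_days), config.span_log_sd)
    span = min(span, float(config.followup_days))
    gap_median = _GAP_SCALE * config.span_median_days / (config.visit_rate - 1.0)
    times = [0.0]
    t = 0.0
    while True:
        t += rng.lognormal(math.log(gap_median), config.gap_log_sd)
        if t > span:
            break
        day = round(t)
        if day > times[-1]:
            times.append(float(day))
    return np.asarray(times)


def simulate_eye_trajectory(
    class_label: str,
    config: SimConfig,
    rng: np.random.Generator,
    times: np.ndarray | None = None,
    xi: tuple[float, float] | None = None,
    truth: SimTruth | None = None,
):
    """Simulate one eye's sparse MD series under the Karhunen–Loève model.

    Returns ``(times, md_values, xi1, xi2)``. `times` and `xi` may be forced
    for deterministic checks; otherwise they are drawn from the configured
    schedule and score distributions.
    """
    if class_label not in (FAST, SLOW):
        raise DataError(f"unknown class label {class_label!r}")
    if truth is None:
        truth = SimTruth(config, pd.DataFrame())
    if times is None:
        times = sample_visit_times(config, rng)
    times = np.asarray(times, dtype=float)
    if xi is None:
        xi1 = rng.normal(0.0, math.sqrt(truth.lam1))
        xi2 = rng.normal(0.0, math.sqrt(truth.lam2))
    else:
        xi1, xi2 = float(xi[0]), float(xi[1])
    md = truth.latent_curve(class_label, xi1, xi2, times)
    if config.sigma2 > 0:
        md = md + rng.normal(0.0, math.sqrt(config.sigma2), size=times.shape)
    return times, md, xi1, xi2


def simulate_baseline_features(
    class_label: str, config: SimConfig, rng: np.random.Generator
) -> dict:
    """Draw one patient's baseline EHR feature row, linked to progression class.

    Continuous features use per-class means/SDs (fast eyes are younger on
    average); race/sex use per-class category probabilities; binary
    diagnosis/medication indicators get an additive log-odds shift for
    fast-class patients per ``covariate_effect_sizes``. Configured missingness
    is applied last.
    """
    if class_label not in (FAST, SLOW):
        raise DataError(f"unknown class label {class_label!r}")
    ci = 1 if class_label == FAST else 0
    row: dict = {}
    for name, (slow_ms, fast_ms) in _CONTINUOUS.items():
        mean, sd = (fast_ms if ci else slow_ms)
        row[name] = rng.normal(mean, sd)
    row["cdr"] = float(np.clip(row["cdr"], 0.05, 0.99))
    row["cct"] = float(np.clip(row["cct"], 400.0, 700.0))
    row["age_baseline"] = float(np.clip(row["age_baseline"], 18.0, 100.0))
    row["va_logmar"] = float(np.clip(row["va_logmar"], -0.3, 3.0))
    row["iop_max"] = float(np.clip(row["iop_max"], 5.0, 60.0))
    probs = _RACE_PROBS[class_label]
    row["race"] = _RACE_LEVELS[rng.choice(len(_RACE_LEVELS), p=np.asarray(probs) / sum(probs))]
    row["sex"] = "F" if rng.random() < _FEMALE_PROB[class_label] else "M"
    for name, base in _INDICATOR_BASE.items():
        logit = math.log(base / (1.0 - base))
        if ci:
            logit += config.covariate_effect_sizes.get(name, 0.0)
        p = 1.0 / (1.0 + math.exp(-logit))
        row[name] = int(rng.random() < p)
    for name, rate in config.missingness.items():
        if name in row and rate > 0 and rng.random() < rate:
            row[name] = np.nan if name != "race" else ""
    return row


def _psd_from_md(md: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Pattern standard deviation as a noisy function of global damage."""
    psd = 1.8 + 0.25 * np.minimum(np.abs(md), 20.0) + rng.normal(0.0, 0.5, size=np.shape(md))
    return np.clip(psd, 0.5, 18.0)


def _reliable_rate(rng: np.random.Generator, size) -> np.ndarray:
    # fixation-loss / false-negative rates of retained-quality tests: < 0.33
    return 0.32 * rng.beta(1.2, 8.0, size=size)


def simulate_cohort(config: SimConfig):
    """Generate a full cohort: VF table, EHR table, and the latent truth.

    Byte-identical outputs for identical configs (single seeded generator,
    fixed construction order). Rows that violate the inclusion filters
    (unreliable, 10-2 pattern, post-surgery, minority strategy) are injected as
    extra records at configured rates so the cohort pipeline has real work to do.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    excl = config.exclusion_rates

    eye_rows = []
    vf_parts = []
    ehr_rows = []
    truth = SimTruth(config, pd.DataFrame())
    n_emitted = 0
    pidx = 0
    while n_emitted < config.n_eyes:
        pidx += 1
        pid = f"P{pidx:05d}"
        n_eyes_p = 2 if rng.random() < config.two_eye_prob else 1
        n_eyes_p = min(n_eyes_p, config.n_eyes - n_emitted)
        labels = [FAST if rng.random() < config.frac_fast else SLOW for _ in range(n_eyes_p)]
        # shared patient effect on scores (inter-eye correlation)
        rho = config.inter_eye_corr
        zp = rng.normal(size=2)
        patient_label = FAST if FAST in labels else SLOW
        feats = simulate_baseline_features(patient_label, config, rng)
        age0 = feats["age_baseline"] if np.isfinite(feats.get("age_baseline", np.nan)) else 60.0
        ehr_rows.append({"patient_id": pid, **feats})
        for ei in range(n_eyes_p):
            eye = "OD" if ei == 0 else "OS"
            label = labels[ei]
            ze = rng.normal(size=2)
            xi1 = math.sqrt(truth.lam1) * (math.sqrt(rho) * zp[0] + math.sqrt(1 - rho) * ze[0])
            xi2 = math.sqrt(truth.lam2) * (math.sqrt(rho) * zp[1] + math.sqrt(1 - rho) * ze[1])
            times, md, _, _ = simulate_eye_trajectory(
                label, config, rng, xi=(xi1, xi2), truth=truth
            )
            n = len(times)
            part = pd.DataFrame(
                {
                    "patient_id": pid,
                    "eye": eye,
                    "test_date": times.astype(int),
                    "md_db": md,
                    "psd_db": _psd_from_md(md, rng),
                    "fixation_loss": _reliable_rate(rng, n),
                    "false_neg": _reliable_rate(rng, n),
                    "strategy": "SITA-Standard",
                    "pattern": "24-2",
                    "stimulus": "III",
                    "background": "white",
                    "age": age0 + times / 365.0,
                    "post_surgery": False,
                }
            )
            vf_parts.append(part)
            vf_parts.extend(
                _injected_exclusions(pid, eye, label, age0, times, config, truth, rng, excl)
            )
            eye_rows.append(
                {
                    "patient_id": pid,
                    "eye": eye,
                    "true_class": label,
                    "xi1": xi1,
                    "xi2": xi2,
                }
            )
            n_emitted += 1

    vf = pd.concat(vf_parts, ignore_index=True)[VF_COLUMNS]
    ehr = pd.DataFrame(ehr_rows)
    truth.eyes = pd.DataFrame(eye_rows)
    return vf, ehr, truth


def _injected_exclusions(pid, eye, label, age0, times, config, truth, rng, rates):
    """Extra VF rows that the inclusion filters must remove."""
    parts = []
    t_max = float(times.max()) if len(times) else 0.0

    def _row(day, **overrides):
        md = float(
            truth.latent_curve(label, 0.0, 0.0, np.array([day]))[0]
            + rng.normal(0.0, max(config.sigma2, 0.25) ** 0.5)
        )
        base = {
            "patient_id": pid,
            "eye": eye,
            "test_date": int(day),
            "md_db": md,
            "psd_db": float(_psd_from_md(np.array([md]), rng)[0]),
            "fixation_loss": float(_reliable_rate(rng, ())),
            "false_neg": float(_reliable_rate(rng, ())),
            "strategy": "SITA-Standard",
            "pattern": "24-2",
            "stimulus": "III",
            "background": "white",
            "age": age0 + day / 365.0,
            "post_surgery": False,
        }
        base.update(overrides)
        return pd.DataFrame([base])

    if rng.random() < rates.get("unreliable", 0.0):
        day = rng.uniform(30, max(t_max, 60))
        which = "fixation_loss" if rng.random() < 0.5 else "false_neg"
        parts.append(_row(day, **{which: float(rng.uniform(0.34, 0.9))}))
    if rng.random() < rates.get("pattern_10_2", 0.0):
        parts.append(_row(rng.uniform(30, max(t_max, 60)), pattern="10-2"))
    if rng.random() < rates.get("post_surgery", 0.0):
        parts.append(_row(t_max + rng.uniform(60, 365), post_surgery=True))
    if rng.random() < rates.get("minority_strategy", 0.0):
        parts.append(_row(rng.uniform(30, max(t_max, 60)), strategy="SITA-Fast"))
    return parts
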