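"""Shared test utilities: truth-model construction and error measures."""

import numpy as np
import pandas as pd

from vfcast.fpca import FPCAModel, FPCAOptions, _trapz_weights
from vfcast.simulate import SimConfig, SimTruth, sample_visit_times, simulate_eye_trajectory


def default_truth(**overrides) -> SimTruth:
    cfg = SimConfig(n_eyes=1, **overrides)
    return SimTruth(cfg, pd.DataFrame())


def sparse_sample(truth: SimTruth, label: str, n: int, rng: np.random.Generator):
    """Draw n eyes' sparse series from the generative model; returns
    (list of (t, y), xi array of shape (n, 2))."""
    sample, xis = [], []
    for _ in range(n):
        t, y, x1, x2 = simulate_eye_trajectory(label, truth.config, rng, truth=truth)
        sample.append((t, y))
        xis.append((x1, x2))
    return sample, np.asarray(xis)


def truth_fpca_model(truth: SimTruth, label: str, n_grid: int = 100) -> FPCAModel:
    """FPCAModel populated with the exact generative quantities (no fitting)."""
    grid = np.linspace(0.0, truth.T, n_grid)
    phi = np.vstack([truth.phi(1, grid), truth.phi(2, grid)])
    lam = np.array([truth.lam1, truth.lam2])
    total = lam.sum()
    return FPCAModel(
        grid=grid,
        mu=truth.mu(label, grid),
        phi=phi,
        lam=lam,
        sigma2=truth.sigma2,
        fve=np.cumsum(lam) / total,
        options=FPCAOptions(),
        stratum=label,
    )


def sign_aligned_ise(phi_est: np.ndarray, phi_true: np.ndarray, grid: np.ndarray) -> float:
    w = _trapz_weights(grid)
    return float(
        min(np.sum(w * (phi_est - phi_true) ** 2), np.sum(w * (phi_est + phi_true) ** 2))
    )


def visit_counts(config: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    return np.array([len(sample_visit_times(config, rng)) for _ in range(n)])
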