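"""Sparse functional principal component analysis with conditional-expectation scores.

Estimates, from sparse irregular longitudinal observations pooled across
subjects, a mean function (local-linear kernel smoother), a smoothed
covariance surface with measurement-error variance split off the diagonal,
and its quadrature eigendecomposition; subject scores are best linear
predictions given the subject's own observations (the conditional-expectation
/ PACE estimator), which makes trajectory prediction possible from as little
as a single observation.

All smoothing uses the Epanechnikov kernel. Raw covariance cross-products are
binned onto the covariance grid before surface smoothing. Bandwidths marked
"auto" are selected over a geometric candidate grid spanning 5%-50% of the
domain: GCV for the mean, subject-level cross-validation for the covariance
surface (whose raw cross-products are correlated within an eye, which breaks
GCV's independence assumption). A reduced-rank maximum-likelihood refinement
(EM) polishes the kernel estimates by default; see FPCAOptions.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, FitError

_WIDEN_FACTOR = 1.5
_MAX_WIDEN = 40


def _epan(u: np.ndarray) -> np.ndarray:
    out = 1.0 - u * u
    out[out < 0.0] = 0.0
    return 0.75 * out


@dataclass
class FPCAOptions:
    """Tuning knobs for sparse FPCA.

    The output grid has 100 equispaced points over the 10-year domain (days);
    the covariance surface is smoothed on a coarser 51-point grid and
    interpolated. K=2 components by default; set ``fve_target`` (and K=None)
    to select K by fraction of variance explained instead.
    """

    n_grid_out: int = 100
    n_grid_cov: int = 51
    K: int | None = 2
    fve_target: float | None = None
    bandwidth_mean: float | str = "auto"
    bandwidth_cov: float | str = "auto"
    domain: tuple[float, float] = (0.0, 3650.0)
    n_gcv_bins: int = 101
    n_gcv_candidates: int = 6
    #: refit eigenvalues by least squares of the raw off-diagonal
    #: cross-products on the fitted eigenfunction products; this removes both
    #: the smoothing attenuation and the noise-eigenvalue inflation that the
    #: surface eigenvalues inherit (used when em_iterations == 0)
    reestimate_lambda: bool = True
    #: reduced-rank maximum-likelihood refinement: EM iterations over the
    #: K-component random-effects model, initialized from the kernel fit.
    #: The kernel eigendecomposition is consistent but statistically
    #: inefficient for weak components under sparse designs; the ML refinement
    #: recovers them markedly better. 0 disables.
    em_iterations: int = 300
    #: EM stops early when the relative change of (lam, sigma2) drops below this
    em_tol: float = 1e-5
    #: knots of the piecewise-linear basis the refined eigenfunctions live on
    em_basis_knots: int = 13

    def validate(self) -> None:
        if self.n_grid_out < 2:
            raise ConfigError("n_grid_out must be at least 2")
        if self.n_grid_cov < 4:
            raise ConfigError("n_grid_cov must be at least 4")
        if self.K is None and self.fve_target is None:
            raise ConfigError("either K or fve_target must be set")
        if self.K is not None and self.K < 1:
            raise ConfigError("K must be at least 1")
        if not self.domain[0] < self.domain[1]:
            raise ConfigError("domain start must precede domain end")


@dataclass
class SubjectScores:
    """Conditional-expectation FPC scores for one subject."""

    xi: np.ndarray
    n_obs: int


@dataclass
class TrajectoryPrediction:
    """Predicted MD trajectory on the model grid."""

    grid: np.ndarray
    values: np.ndarray
    stratum: str | None = None


@dataclass
class FPCAModel:
    """Fitted sparse-FPCA model for one stratum."""

    grid: np.ndarray  # output grid, days
    mu: np.ndarray  # mean MD on grid, dB
    phi: np.ndarray  # (K, len(grid)) eigenfunctions, unit norm
    lam: np.ndarray  # (K,) eigenvalues, dB²·days
    sigma2: float  # measurement-error variance, dB²
    fve: np.ndarray  # cumulative FVE at k = 1..K
    bandwidths: dict = field(default_factory=dict)
    options: FPCAOptions | None = None
    stratum: str | None = None
    report: dict = field(default_factory=dict)

    @property
    def K(self) -> int:
        return self.phi.shape[0]

    def validate(self) -> None:
        w = _trapz_weights(self.grid)
        gram = (self.phi * w) @ self.phi.T
        if np.max(np.abs(gram - np.eye(self.K))) >= 1e-6:
            raise FitError("eigenfunctions are not orthonormal under trapezoid quadrature")
        if np.any(np.diff(self.lam) > 1e-9 * max(self.lam[0], 1.0)):
            raise FitError("eigenvalues are not sorted in decreasing order")
        if self.sigma2 < 0:
            raise FitError("negative noise variance")
        if np.any(np.diff(self.fve) < -1e-12) or np.any(self.fve > 1 + 1e-12):
            raise FitError("FVE must be nondecreasing and at most 1")

    # -- serialization: JSON header + delimited numeric table ---------------
    def save(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        header = {
            "stratum": self.stratum,
            "sigma2": self.sigma2,
            "lam": list(map(float, self.lam)),
            "fve": list(map(float, self.fve)),
            "bandwidths": self.bandwidths,
            "options": None if self.options is None else vars(self.options) | {
                "domain": list(self.options.domain)
            },
            "report": self.report,
        }
        path.with_suffix(".json").write_text(json.dumps(header, indent=2))
        tab = pd.DataFrame({"grid": self.grid, "mu": self.mu})
        for k in range(self.K):
            tab[f"phi{k + 1}"] = self.phi[k]
        tab.to_csv(path.with_suffix(".csv"), index=False, float_format="%.17g")

    @classmethod
    def load(cls, path) -> "FPCAModel":
        path = Path(path)
        header = json.loads(path.with_suffix(".json").read_text())
        tab = pd.read_csv(path.with_suffix(".csv"))
        phi_cols = sorted(c for c in tab.columns if c.startswith("phi"))
        opts = None
        if header.get("options"):
            o = dict(header["options"])
            o["domain"] = tuple(o["domain"])
            opts = FPCAOptions(**o)
        return cls(
            grid=tab["grid"].to_numpy(),
            mu=tab["mu"].to_numpy(),
            phi=np.vstack([tab[c].to_numpy() for c in phi_cols]),
            lam=np.asarray(header["lam"], dtype=float),
            sigma2=float(header["sigma2"]),
            fve=np.asarray(header["fve"], dtype=float),
            bandwidths=header.get("bandwidths", {}),
            options=opts,
            stratum=header.get("stratum"),
            report=header.get("report", {}),
        )


def _trapz_weights(grid: np.ndarray) -> np.ndarray:
    w = np.empty_like(grid, dtype=float)
    w[1:-1] = (grid[2:] - grid[:-2]) / 2.0
    w[0] = (grid[1] - grid[0]) / 2.0
    w[-1] = (grid[-1] - grid[-2]) / 2.0
    return w


# ---------------------------------------------------------------------------
# 1-D local-linear smoothing

def _llin_1d_pass(x, y, w, xout, bw, chunk=512):
    """One smoothing pass; NaN where the window holds no data."""
    est = np.empty(len(xout))
    for lo in range(0, len(xout), chunk):
        xo = xout[lo : lo + chunk]
        d = x[None, :] - xo[:, None]
        K = _epan(d / bw) * w
        S0 = K.sum(axis=1)
        S1 = (K * d).sum(axis=1)
        Kd = K * d
        S2 = (Kd * d).sum(axis=1)
        T0 = (K * y).sum(axis=1)
        T1 = (Kd * y).sum(axis=1)
        denom = S0 * S2 - S1 * S1
        scale = S0 * S2 + S1 * S1
        good = denom > 1e-10 * np.maximum(scale, 1e-300)
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = (S2 * T0 - S1 * T1) / denom
            lc = T0 / S0
        e = np.where(good, ll, lc)
        e[S0 <= 0.0] = np.nan
        est[lo : lo + chunk] = e
    return est


def _llin_1d(x, y, w, xout, bw):
    """Local-linear estimate with per-point bandwidth widening where the
    window is empty (falls back to a local-constant fit where the local-linear
    system is degenerate, e.g. all data at one location)."""
    est = _llin_1d_pass(x, y, w, xout, bw)
    remaining = np.flatnonzero(~np.isfinite(est))
    if len(remaining):
        warnings.warn(
            "mean/variance smoother: bandwidth widened locally to cover data gaps",
            stacklevel=2,
        )
    cur = bw
    for _ in range(_MAX_WIDEN):
        if not len(remaining):
            break
        cur *= _WIDEN_FACTOR
        e = _llin_1d_pass(x, y, w, xout[remaining], cur)
        ok = np.isfinite(e)
        est[remaining[ok]] = e[ok]
        remaining = remaining[~ok]
    if len(remaining):
        raise FitError("smoother found no data within any candidate bandwidth")
    return est


def _bin_1d(x, y, n_bins, lo, hi):
    """Bin scatter data; returns centers, bin means, counts, and the within-bin
    sum of squares (constant across bandwidths but needed for honest GCV)."""
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(x, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    sums = np.bincount(idx, weights=y, minlength=n_bins)
    sq = np.bincount(idx, weights=y * y, minlength=n_bins)
    keep = counts > 0
    means = sums[keep] / counts[keep]
    within_ss = float(np.sum(sq[keep] - counts[keep] * means**2))
    centers = (edges[:-1] + edges[1:]) / 2.0
    return centers[keep], means, counts[keep], within_ss


def _gcv_1d(x, y, lo, hi, options: FPCAOptions):
    """GCV bandwidth selection on binned data; returns the chosen bandwidth.

    The raw-data residual sum of squares decomposes into the between-bin RSS
    plus the (bandwidth-independent) within-bin SS; the latter must stay in
    the GCV numerator or the trace penalty carries no weight.
    """
    rng_len = hi - lo
    cands = np.geomspace(0.05 * rng_len, 0.5 * rng_len, options.n_gcv_candidates)
    cx, cm, cn, within_ss = _bin_1d(
        np.asarray(x, float), np.asarray(y, float), options.n_gcv_bins, lo, hi
    )
    n_eff = cn.sum()
    best_bw, best_score = cands[-1], np.inf
    for bw in cands:
        d = cx[None, :] - cx[:, None]
        K = _epan(d / bw) * cn
        S0 = K.sum(axis=1)
        S1 = (K * d).sum(axis=1)
        S2 = (K * d * d).sum(axis=1)
        T0 = (K * cm).sum(axis=1)
        T1 = (K * d * cm).sum(axis=1)
        denom = S0 * S2 - S1 * S1
        good = denom > 1e-10 * np.maximum(S0 * S2 + S1 * S1, 1e-300)
        with np.errstate(divide="ignore", invalid="ignore"):
            fit = np.where(good, (S2 * T0 - S1 * T1) / denom, T0 / np.maximum(S0, 1e-300))
            self_w = np.where(good, 0.75 * cn * S2 / denom, 0.75 * cn / np.maximum(S0, 1e-300))
        if not np.all(np.isfinite(fit)):
            continue
        tr = self_w.sum()
        if tr >= 0.9 * n_eff:
            continue
        rss = float(np.sum(cn * (cm - fit) ** 2)) + within_ss
        score = rss / (1.0 - tr / n_eff) ** 2
        if score < best_score:
            best_score, best_bw = score, bw
    return float(best_bw)


# ---------------------------------------------------------------------------
# 2-D local-plane smoothing for the covariance surface

#: Monomial exponents of the local 2-D polynomial bases, by degree.
_BASIS_2D = {
    1: [(0, 0), (1, 0), (0, 1)],
    2: [(0, 0), (1, 0), (0, 1), (2, 0), (1, 1), (0, 2)],
}


def _l2d_moments(sx, tx, y, w, so, to, bw, degree):
    """Kernel-weighted moment matrices M and right-hand sides for a chunk."""
    basis = _BASIS_2D[degree]
    ds = sx[None, :] - so
    dt = tx[None, :] - to
    K = _epan(ds / bw) * _epan(dt / bw) * w
    max_p = 2 * degree
    pow_s = [np.ones_like(ds)]
    pow_t = [np.ones_like(dt)]
    for _ in range(max_p):
        pow_s.append(pow_s[-1] * ds)
        pow_t.append(pow_t[-1] * dt)
    m = ds.shape[0]
    q = len(basis)
    M = np.empty((m, q, q))
    rhs = np.empty((m, q))
    for a, (pa, qa) in enumerate(basis):
        rhs[:, a] = (K * pow_s[pa] * pow_t[qa] * y).sum(axis=1)
        for b in range(a, q):
            pb, qb = basis[b]
            M[:, a, b] = M[:, b, a] = (K * pow_s[pa + pb] * pow_t[qa + qb]).sum(axis=1)
    return M, rhs, K.sum(axis=1), (K * y).sum(axis=1)


def _l2d_pass(sx, tx, y, w, s_out, t_out, bw, degree=2):
    """Local polynomial surface fit at each output point; NaN on empty windows.

    Falls back degree 2 → 1 → 0 where the local system is ill-conditioned
    (e.g. all data concentrated on a lower-dimensional set).
    """
    n_out = len(s_out)
    est = np.empty(n_out)
    chunk = max(1, int(2e6 // max(len(sx), 1)))
    for lo in range(0, n_out, chunk):
        so = s_out[lo : lo + chunk, None]
        to = t_out[lo : lo + chunk, None]
        m = so.shape[0]
        out = np.full(m, np.nan)
        unresolved = np.ones(m, dtype=bool)
        S00 = T00 = None
        for deg in range(degree, 0, -1):
            M, rhs, S00, T00 = _l2d_moments(sx, tx, y, w, so, to, bw, deg)
            with np.errstate(all="ignore"):
                cond = np.linalg.cond(M)
            good = unresolved & np.isfinite(cond) & (cond < 1e10)
            if good.any():
                sol = np.linalg.solve(M[good], rhs[good][:, :, None])
                out[good] = sol[:, 0, 0]
                unresolved &= ~good
            if not unresolved.any():
                break
        rest = unresolved & (S00 > 0)
        out[rest] = T00[rest] / S00[rest]
        est[lo : lo + chunk] = out
    return est


def _llin_2d(sx, tx, y, w, s_out, t_out, bw, degree=2):
    est = _l2d_pass(sx, tx, y, w, s_out, t_out, bw, degree)
    remaining = np.flatnonzero(~np.isfinite(est))
    if len(remaining):
        warnings.warn(
            "covariance smoother: bandwidth widened locally to cover data gaps",
            stacklevel=2,
        )
    cur = bw
    for _ in range(_MAX_WIDEN):
        if not len(remaining):
            break
        cur *= _WIDEN_FACTOR
        e = _l2d_pass(sx, tx, y, w, s_out[remaining], t_out[remaining], cur, degree)
        ok = np.isfinite(e)
        est[remaining[ok]] = e[ok]
        remaining = remaining[~ok]
    if len(remaining):
        raise FitError("covariance smoother found no data within any candidate bandwidth")
    return est


# ---------------------------------------------------------------------------
# Estimation operations

def _pool(sample, domain):
    """Pooled (t, y) arrays and the per-subject list, truncated to the domain."""
    per_subject = []
    for entry in sample:
        t, y = entry
        t = np.asarray(t, dtype=float)
        y = np.asarray(y, dtype=float)
        keep = (t >= domain[0]) & (t <= domain[1])
        if keep.any():
            per_subject.append((t[keep], y[keep]))
    if not per_subject:
        raise DataError("empty sample: no observations inside the domain")
    pooled_t = np.concatenate([t for t, _ in per_subject])
    pooled_y = np.concatenate([y for _, y in per_subject])
    return per_subject, pooled_t, pooled_y


def estimate_mean(sample, options: FPCAOptions | None = None):
    """Local-linear mean function on the output grid.

    Returns ``(grid, mu, bandwidth)``.
    """
    options = options or FPCAOptions()
    options.validate()
    _, t, y = _pool(sample, options.domain)
    if len(sample) < 1:
        raise DataError("empty sample")
    grid = np.linspace(options.domain[0], options.domain[1], options.n_grid_out)
    bw = options.bandwidth_mean
    if bw == "auto":
        bw = _gcv_1d(t, y, options.domain[0], options.domain[1], options)
    mu = _llin_1d(t, y, np.ones_like(t), grid, float(bw))
    return grid, mu, float(bw)


def _mean_at(sample, options, bw, xout):
    _, t, y = _pool(sample, options.domain)
    return _llin_1d(t, y, np.ones_like(t), np.asarray(xout, float), float(bw))


def _offdiag_pairs(per_subject, mu_at):
    """Raw residual cross-products: off-diagonal pairs (with subject index)
    plus diagonal squared residuals."""
    s_list, t_list, c_list, id_list = [], [], [], []
    diag_t, diag_r2 = [], []
    for i, (t, y) in enumerate(per_subject):
        r = y - mu_at(t)
        diag_t.append(t)
        diag_r2.append(r * r)
        n = len(t)
        if n < 2:
            continue
        ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        off = ii != jj
        s_list.append(t[ii[off]])
        t_list.append(t[jj[off]])
        c_list.append(r[ii[off]] * r[jj[off]])
        id_list.append(np.full(int(off.sum()), i))
    if not s_list:
        raise FitError("noise variance not identifiable: no subject has >=2 observations")
    return (
        np.concatenate(s_list),
        np.concatenate(t_list),
        np.concatenate(c_list),
        np.concatenate(id_list),
        np.concatenate(diag_t),
        np.concatenate(diag_r2),
    )


def _bin_pairs(sx, tx, cx, cov_grid):
    """Average raw cross-products within covariance-grid cells."""
    m = len(cov_grid)
    half = (cov_grid[1] - cov_grid[0]) / 2.0
    edges = np.concatenate([[cov_grid[0] - half], cov_grid + half])
    si = np.clip(np.digitize(sx, edges) - 1, 0, m - 1)
    ti = np.clip(np.digitize(tx, edges) - 1, 0, m - 1)
    flat = si * m + ti
    counts = np.bincount(flat, minlength=m * m).astype(float)
    sums = np.bincount(flat, weights=cx, minlength=m * m)
    sq = np.bincount(flat, weights=cx * cx, minlength=m * m)
    keep = counts > 0
    cell_s = np.repeat(cov_grid, m)[keep]
    cell_t = np.tile(cov_grid, m)[keep]
    cell_v = sums[keep] / counts[keep]
    cell_n = counts[keep]
    within_ss = float(np.sum(sq[keep] - cell_n * cell_v**2))
    return cell_s, cell_t, cell_v, cell_n, within_ss


def _cv_2d_subject(sx, tx, cx, pair_subj, cov_grid, options: FPCAOptions, degree=1, n_folds=3):
    """Surface bandwidth by subject-level K-fold cross-validation.

    Cross-products from the same eye share its scores, so their errors are
    correlated; GCV (which assumes independent errors) systematically
    undersmooths here, while holding out whole subjects gives an honest
    out-of-sample error. Fold assignment is deterministic (subject index
    round-robin).
    """
    lo, hi = cov_grid[0], cov_grid[-1]
    cands = np.geomspace(0.05 * (hi - lo), 0.5 * (hi - lo), options.n_gcv_candidates)
    folds = pair_subj % n_folds
    parts = []
    for f in range(n_folds):
        test = folds == f
        if not test.any() or test.all():
            continue
        train_cells = _bin_pairs(sx[~test], tx[~test], cx[~test], cov_grid)
        test_cells = _bin_pairs(sx[test], tx[test], cx[test], cov_grid)
        parts.append((train_cells, test_cells))
    if not parts:
        return float(cands[-1])
    scores = np.zeros(len(cands))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for ci, bw in enumerate(cands):
            err = 0.0
            for (trs, trt, trv, trn, _), (tes, tet, tev, ten, _) in parts:
                fit = _llin_2d(trs, trt, trv, trn, tes, tet, float(bw), degree)
                err += float(np.sum(ten * (tev - fit) ** 2))
            scores[ci] = err
    return float(cands[int(np.argmin(scores))])


def estimate_covariance(sample, mu_at, options: FPCAOptions | None = None):
    """Smoothed covariance surface on the covariance grid plus noise variance.

    `mu_at` is a callable evaluating the estimated mean at arbitrary times.
    Off-diagonal raw cross-products of residuals are binned onto the grid and
    smoothed with a local quadratic surface; the noise variance is the
    average, over the central 50% of the domain, of the positive part of the
    difference between the smoothed diagonal (which includes noise) and the
    surface diagonal.

    Returns ``(cov_grid, G, sigma2, bandwidth)``.
    """
    options = options or FPCAOptions()
    options.validate()
    per_subject, _, _ = _pool(sample, options.domain)
    lo, hi = options.domain
    m = options.n_grid_cov
    cov_grid = np.linspace(lo, hi, m)

    sx, tx, cx, pair_subj, dt_all, dr2_all = _offdiag_pairs(per_subject, mu_at)
    cell_s, cell_t, cell_v, cell_n, _within = _bin_pairs(sx, tx, cx, cov_grid)

    bw = options.bandwidth_cov
    if bw == "auto":
        bw = _cv_2d_subject(sx, tx, cx, pair_subj, cov_grid, options)
    S, T = np.meshgrid(cov_grid, cov_grid, indexing="ij")
    G = _llin_2d(cell_s, cell_t, cell_v, cell_n, S.ravel(), T.ravel(), float(bw))
    G = G.reshape(m, m)
    G = (G + G.T) / 2.0

    # diagonal including noise, from smoothed squared residuals
    V = _llin_1d(dt_all, dr2_all, np.ones_like(dt_all), cov_grid, float(bw))
    central = (cov_grid >= lo + 0.25 * (hi - lo)) & (cov_grid <= lo + 0.75 * (hi - lo))
    sigma2 = float(np.mean(np.clip(V[central] - np.diag(G)[central], 0.0, None)))
    return cov_grid, G, sigma2, float(bw)


def eigendecompose(G, grid, K=None, fve_target=None):
    """Quadrature-weighted eigendecomposition of a covariance surface.

    Negative eigenvalues are truncated to zero and excluded from the FVE.
    Eigenfunctions are unit-norm under trapezoid quadrature on `grid` and
    sign-fixed so their integral is nonnegative (first nonzero value positive
    on a zero integral). Returns ``(phi, lam, fve)`` with `fve` the cumulative
    fraction of variance explained over all positive eigenvalues.
    """
    G = np.asarray(G, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if G.shape[0] != G.shape[1] or G.shape[0] != len(grid):
        raise DataError("covariance surface and grid sizes disagree")
    w = _trapz_weights(grid)
    sw = np.sqrt(w)
    A = sw[:, None] * G * sw[None, :]
    A = (A + A.T) / 2.0
    evals, evecs = np.linalg.eigh(A)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    tol = max(evals[0], 0.0) * 1e-12
    pos = evals > tol
    n_pos = int(pos.sum())
    if n_pos == 0:
        raise FitError("covariance surface has no positive eigenvalues")
    lam_pos = evals[:n_pos]
    fve = np.cumsum(lam_pos) / lam_pos.sum()
    if K is None:
        if fve_target is None:
            raise ConfigError("either K or fve_target must be given")
        K = int(np.searchsorted(fve, fve_target) + 1)
        K = min(K, n_pos)
    if K > n_pos:
        raise FitError(f"requested K={K} exceeds the {n_pos} positive eigenvalues")
    phi = np.empty((K, len(grid)))
    for k in range(K):
        v = evecs[:, k] / sw
        integral = float(np.sum(w * v))
        if abs(integral) > 1e-12 * math.sqrt(grid[-1] - grid[0]):
            sign = 1.0 if integral >= 0 else -1.0
        else:
            nz = np.flatnonzero(np.abs(v) > 1e-12 * np.max(np.abs(v)))
            sign = 1.0 if v[nz[0]] >= 0 else -1.0
        phi[k] = sign * v
    return phi, lam_pos[:K].copy(), fve


def _orthonormalize(phi, w):
    """Gram-Schmidt under the quadrature inner product, preserving signs."""
    out = phi.copy()
    for k in range(out.shape[0]):
        for j in range(k):
            out[k] -= np.sum(w * out[k] * out[j]) * out[j]
        nrm = math.sqrt(float(np.sum(w * out[k] ** 2)))
        if nrm <= 0:
            raise FitError("degenerate eigenfunction after interpolation")
        out[k] /= nrm
    return out


def fit_fpca(sample, options: FPCAOptions | None = None, stratum: str | None = None) -> FPCAModel:
    """Fit the full sparse-FPCA model for one stratum.

    Orchestrates mean estimation, covariance smoothing, eigendecomposition on
    the covariance grid, interpolation of eigenfunctions to the output grid
    (re-orthonormalized under the output quadrature), and noise-variance
    estimation. The fitted model satisfies the orthonormality/ordering
    invariants by construction and is re-validated before being returned.
    """
    options = options or FPCAOptions()
    options.validate()
    per_subject, pooled_t, pooled_y = _pool(sample, options.domain)
    grid, mu, bw_mean = estimate_mean(per_subject, options)

    def mu_at(tq):
        return _llin_1d(
            pooled_t, pooled_y, np.ones_like(pooled_t), np.asarray(tq, float), bw_mean
        )

    cov_grid, G, sigma2, bw_cov = estimate_covariance(per_subject, mu_at, options)
    phi_cov, lam, fve = eigendecompose(G, cov_grid, K=options.K, fve_target=options.fve_target)
    K = phi_cov.shape[0]
    phi = np.vstack([np.interp(grid, cov_grid, phi_cov[k]) for k in range(K)])
    phi = _orthonormalize(phi, _trapz_weights(grid))
    if options.em_iterations > 0:
        kernel_est = (mu.copy(), phi.copy(), lam.copy(), sigma2)
        mu, phi, lam, sigma2 = _em_refine(
            per_subject, mu_at, grid, _trapz_weights(grid), phi, lam, sigma2, options
        )
        phi = _orthonormalize(phi, _trapz_weights(grid))
        # Sanity guard: by orthonormality, sum(lam)/|domain| is the model's
        # domain-averaged trajectory variance and cannot legitimately exceed
        # the observed mean squared residual. Heterogeneous small strata can
        # drive the ML refinement to a degenerate high-variance ramp mode
        # whose PACE predictions explode; fall back to the kernel estimates.
        mu_chk = np.interp(pooled_t, grid, mu)
        mean_sq_resid = float(np.mean((pooled_y - mu_chk) ** 2))
        implied = float(lam.sum()) / (grid[-1] - grid[0])
        if implied > 2.0 * mean_sq_resid:
            warnings.warn(
                "ML refinement produced an implausible variance profile; "
                "keeping the kernel-smoothing estimates",
                stacklevel=2,
            )
            mu, phi, lam, sigma2 = kernel_est
    elif options.reestimate_lambda:
        lam = _reestimate_lambda(per_subject, mu_at, grid, phi, lam)
        order = np.argsort(lam)[::-1]
        lam = lam[order]
        phi = phi[order]
    model = FPCAModel(
        grid=grid,
        mu=mu,
        phi=phi,
        lam=lam,
        sigma2=sigma2,
        fve=fve[:K].copy(),
        bandwidths={"mean": bw_mean, "cov": bw_cov},
        options=options,
        stratum=stratum,
        report={
            "n_subjects": len(per_subject),
            "n_points": int(len(pooled_t)),
            "fve_table": list(map(float, fve)),
        },
    )
    model.validate()
    return model


def _hat_basis(t, knots):
    """Piecewise-linear (hat-function) basis matrix evaluated at times t."""
    t = np.asarray(t, dtype=float)
    p = len(knots)
    B = np.zeros((len(t), p))
    idx = np.clip(np.searchsorted(knots, t, side="right") - 1, 0, p - 2)
    left = knots[idx]
    width = knots[idx + 1] - left
    frac = (t - left) / width
    rows = np.arange(len(t))
    B[rows, idx] = 1.0 - frac
    B[rows, idx + 1] = frac
    return B


def _em_refine(per_subject, mu_at, grid, w, phi, lam, sigma2, options):
    """Reduced-rank ML refinement of (mu, phi, lam, sigma2) by EM.

    The mean and the K eigenfunctions are parameterized on a coarse
    piecewise-linear basis and the Karhunen–Loève model
    y_i = mu(t_i) + Phi_i xi_i + eps is treated as a random-effects model: the
    E-step computes each subject's posterior score moments, the M-step solves
    one joint linear system for the mean and eigenfunction coefficients, then
    the component representation is re-canonicalized (orthonormal under
    quadrature, decreasing variances). Initialization comes from the
    kernel-smoothing estimates, which are consistent but statistically
    inefficient at sparse designs — in particular near the domain boundary
    for the mean and for weak components of the covariance.

    Returns ``(mu, phi, lam, sigma2)`` on `grid`.
    """
    K = phi.shape[0]
    # fewer knots for small strata: ~one knot per five subjects caps the
    # effective parameter count, and the roughness ridge below keeps knots
    # without local data on the linear continuation of their neighbors
    p = int(min(options.em_basis_knots, max(4, len(per_subject) // 5)))
    knots = np.linspace(grid[0], grid[-1], p)
    Bg = _hat_basis(grid, knots)
    C, *_ = np.linalg.lstsq(Bg, phi.T, rcond=None)  # p x K
    a, *_ = np.linalg.lstsq(Bg, mu_at(grid), rcond=None)  # p mean coefficients
    lam = np.maximum(np.asarray(lam, dtype=float).copy(), 1e-8)
    sig2 = max(float(sigma2), 1e-8)

    subj = [(_hat_basis(t, knots), np.asarray(y, dtype=float)) for t, y in per_subject]
    n_subj = len(subj)
    n_obs_total = sum(len(y) for _, y in subj)

    # second-difference roughness ridge per coefficient block
    D2 = np.zeros((max(p - 2, 0), p))
    for i in range(p - 2):
        D2[i, i : i + 3] = (1.0, -2.0, 1.0)
    rough = D2.T @ D2

    for _ in range(options.em_iterations):
        q = p * (K + 1)
        S1 = np.zeros((q, q))
        S2 = np.zeros(q)
        Exx_sum = np.zeros((K, K))
        rss = 0.0
        for B_i, y_i in subj:
            Phi_i = B_i @ C
            r_i = y_i - B_i @ a
            A = np.diag(1.0 / lam) + Phi_i.T @ Phi_i / sig2
            Sx = np.linalg.inv(A)
            m = Sx @ (Phi_i.T @ r_i) / sig2
            Exx = np.outer(m, m) + Sx
            BtB = B_i.T @ B_i
            # joint normal equations for [a, vec_F(C)]
            S1[:p, :p] += BtB
            cross = np.kron(m[None, :], BtB).reshape(p, K * p)
            S1[:p, p:] += cross
            S1[p:, :p] += cross.T
            S1[p:, p:] += np.kron(Exx, BtB)
            S2[:p] += B_i.T @ y_i
            S2[p:] += (B_i.T @ np.outer(y_i, m)).reshape(-1, order="F")
            Exx_sum += Exx
            resid = r_i - Phi_i @ m
            rss += float(resid @ resid) + float(np.einsum("ij,jk,ik->", Phi_i, Sx, Phi_i))
        ridge = 1e-3 * np.mean(np.diag(S1)[:p])
        for b in range(K + 1):
            S1[b * p : (b + 1) * p, b * p : (b + 1) * p] += ridge * rough
        try:
            sol = np.linalg.solve(S1, S2)
        except np.linalg.LinAlgError:
            break
        a = sol[:p]
        C = sol[p:].reshape((p, K), order="F")
        sig2_prev = sig2
        sig2 = max(rss / n_obs_total, 1e-8)
        Lam_full = Exx_sum / n_subj

        # canonicalize: orthonormal components with decreasing variances
        Phi_g = Bg @ C
        T = Phi_g.T @ (w[:, None] * Phi_g)
        d, U = np.linalg.eigh(T)
        if np.any(d <= 1e-12 * d.max()):
            break
        Dh = U @ np.diag(np.sqrt(d)) @ U.T
        Dhi = U @ np.diag(1.0 / np.sqrt(d)) @ U.T
        M = Dh @ Lam_full @ Dh
        L, V = np.linalg.eigh((M + M.T) / 2.0)
        order = np.argsort(L)[::-1]
        L, V = L[order], V[:, order]
        R = Dhi @ V
        Phi_new = Phi_g @ R
        for k in range(K):
            s = float(np.sum(w * Phi_new[:, k]))
            if abs(s) < 1e-12 * math.sqrt(grid[-1] - grid[0]):
                nz = np.flatnonzero(np.abs(Phi_new[:, k]) > 0)
                s = Phi_new[nz[0], k] if len(nz) else 1.0
            if s < 0:
                Phi_new[:, k] *= -1.0
                R[:, k] *= -1.0
        C = C @ R
        lam_new = np.maximum(L, 1e-8)
        delta = max(
            float(np.max(np.abs(lam_new - lam) / np.maximum(lam, 1e-8))),
            abs(sig2 - sig2_prev) / max(sig2_prev, 1e-8),
        )
        lam = lam_new
        if delta < options.em_tol:
            break
    return Bg @ a, (Bg @ C).T, lam, sig2


def _reestimate_lambda(per_subject, mu_at, grid, phi, lam_init):
    """Refit eigenvalues by least squares of raw off-diagonal cross-products
    on the eigenfunction products phi_k(s) phi_k(t).

    The surface eigenvalues inherit both downward smoothing attenuation and
    upward noise-eigenvalue inflation; regressing the raw products on the
    fitted modes removes both to first order. Non-positive solutions fall
    back to the surface eigenvalues.
    """
    sx, tx, cx, _, _, _ = _offdiag_pairs(per_subject, mu_at)
    K = phi.shape[0]
    A = np.empty((len(cx), K))
    for k in range(K):
        A[:, k] = np.interp(sx, grid, phi[k]) * np.interp(tx, grid, phi[k])
    lam, *_ = np.linalg.lstsq(A, cx, rcond=None)
    lam = np.asarray(lam, dtype=float)
    bad = ~np.isfinite(lam) | (lam <= 0)
    lam[bad] = lam_init[bad]
    return lam


# ---------------------------------------------------------------------------
# Prediction operations

def compute_scores_pace(series, model: FPCAModel) -> SubjectScores:
    """Best linear prediction of a subject's FPC scores from its observations.

    xi_hat = Lam Phi_i' (Phi_i Lam Phi_i' + sigma2 I)^{-1} (y_i - mu_i), with
    model quantities linearly interpolated to the observation times. Works
    from a single observation. A jitter of 1e-8 stabilizes the inversion when
    sigma2 = 0.
    """
    t, y = series
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    g0, g1 = model.grid[0], model.grid[-1]
    if np.any(t < g0 - 1e-9) or np.any(t > g1 + 1e-9):
        raise DataError("observation outside the model domain")
    if len(t) == 0:
        raise DataError("need at least one observation to compute scores")
    mu_i = np.interp(t, model.grid, model.mu)
    Phi = np.vstack([np.interp(t, model.grid, model.phi[k]) for k in range(model.K)]).T
    Sigma = (Phi * model.lam) @ Phi.T + model.sigma2 * np.eye(len(t))
    if model.sigma2 <= 0:
        Sigma = Sigma + 1e-8 * np.eye(len(t))
    try:
        sol = np.linalg.solve(Sigma, y - mu_i)
    except np.linalg.LinAlgError as exc:
        raise FitError("singular score system after jitter") from exc
    xi = model.lam * (Phi.T @ sol)
    if not np.all(np.isfinite(xi)):
        raise FitError("non-finite scores")
    return SubjectScores(xi=xi, n_obs=len(t))


def predict_trajectory(scores, model: FPCAModel, stratum: str | None = None) -> TrajectoryPrediction:
    """Reconstruct the trajectory mu + sum_k xi_k phi_k on the model grid."""
    xi = scores.xi if isinstance(scores, SubjectScores) else np.asarray(scores, dtype=float)
    if len(xi) != model.K:
        raise DataError(f"expected {model.K} scores, got {len(xi)}")
    values = model.mu + xi @ model.phi
    return TrajectoryPrediction(grid=model.grid, values=values, stratum=stratum or model.stratum)


def interpolate_md(prediction: TrajectoryPrediction, t) -> np.ndarray | float:
    """Piecewise-linear MD at arbitrary days within the domain (no extrapolation)."""
    t_arr = np.asarray(t, dtype=float)
    g = prediction.grid
    if np.any(t_arr < g[0] - 1e-9) or np.any(t_arr > g[-1] + 1e-9):
        raise DataError("time outside the prediction domain")
    out = np.interp(t_arr, g, prediction.values)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out
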