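"""Negative-binomial GLM differential expression for the two-factor
(individual + stage) design.

The model is a log-link NB GLM fitted per feature by IRLS with library
size x TMM-factor offsets and a single common dispersion estimated by
maximizing the Cox-Reid adjusted profile likelihood on a coarse grid.
Each non-baseline stage is tested by a likelihood-ratio test against the
design with that stage's column removed (chi-square, 1 df), and p-values
are adjusted per contrast by Benjamini-Hochberg.

NB parameterization: Var(Y) = mu + dispersion * mu^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

from .core_io import STAGES, ExpressionMatrix, SampleDesign

__all__ = [
    "CONTRASTS",
    "build_design_matrix",
    "tmm_factors",
    "estimate_common_dispersion",
    "fit_nb_glm_lrt",
    "bh_adjust",
    "run_de_contrasts",
]

BASELINE_STAGE = "-14"
CONTRASTS = tuple(f"{s}vs{BASELINE_STAGE}" for s in STAGES if s != BASELINE_STAGE)

_MAX_ITER = 50
_TOL = 1e-8


# ---------------------------------------------------------------------------
# Design


def build_design_matrix(samples: list[SampleDesign]) -> tuple[np.ndarray, list[str]]:
    """Intercept + individual indicators + stage indicators; baseline stage
    (-14) and the lexicographically first individual carry no column."""
    stages_present = {s.stage for s in samples}
    if BASELINE_STAGE not in stages_present:
        raise ValueError(f"baseline stage {BASELINE_STAGE} absent from design")
    individuals = sorted({s.individual for s in samples})
    stage_levels = [s for s in STAGES if s in stages_present and s != BASELINE_STAGE]
    cols = ["intercept"] + [f"ind_{i}" for i in individuals[1:]] + [
        f"stage_{s}" for s in stage_levels
    ]
    X = np.zeros((len(samples), len(cols)))
    X[:, 0] = 1.0
    for r, smp in enumerate(samples):
        if smp.individual != individuals[0]:
            X[r, 1 + individuals[1:].index(smp.individual)] = 1.0
        if smp.stage != BASELINE_STAGE:
            X[r, 1 + len(individuals) - 1 + stage_levels.index(smp.stage)] = 1.0
    if np.linalg.matrix_rank(X) != X.shape[1]:
        raise ValueError("design matrix is rank-deficient")
    return X, cols


# ---------------------------------------------------------------------------
# TMM normalization


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              trim_m: float = 0.30, trim_a: float = 0.05) -> float:
    """Weighted trimmed mean of M-values of one column against the reference,
    returned as a log2 factor."""
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep].astype(float), ref[keep].astype(float)
    if obs.size == 0:
        return 0.0
    p_obs, p_ref = obs / n_obs, ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    if np.max(np.abs(m)) < 1e-6:          # identical profiles; avoid rank noise
        return 0.0
    n = m.size
    lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep2.any() or w[keep2].sum() == 0:
        return 0.0
    with np.errstate(divide="ignore"):
        f = np.sum(m[keep2] / w[keep2]) / np.sum(1.0 / w[keep2])
    return float(f) if np.isfinite(f) else 0.0


def tmm_factors(counts: np.ndarray) -> np.ndarray:
    """Trimmed-mean-of-M-values normalization factors (geometric mean 1).

    Reference column = column whose count total is closest to the median
    total.  30% of M values and 5% of A values are trimmed from each tail.
    """
    counts = np.asarray(counts)
    if counts.ndim != 2 or counts.shape[1] < 2:
        raise ValueError("need a features x samples matrix with >= 2 samples")
    totals = counts.sum(axis=0).astype(float)
    if np.any(totals == 0):
        raise ValueError("sample with all-zero counts")
    ref_idx = int(np.argmin(np.abs(totals - np.median(totals))))
    log_f = np.array(
        [
            _tmm_pair(counts[:, k], counts[:, ref_idx], totals[k], totals[ref_idx])
            for k in range(counts.shape[1])
        ]
    )
    factors = 2.0 ** log_f
    return factors / np.exp(np.mean(np.log(factors)))


# ---------------------------------------------------------------------------
# NB likelihood / IRLS


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> float:
    mu = np.maximum(mu, 1e-10)
    if phi < 1e-8:
        return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1)))
    r = 1.0 / phi
    return float(
        np.sum(
            gammaln(y + r) - gammaln(r) - gammaln(y + 1)
            + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu))
        )
    )


def _irls_fit(
    y: np.ndarray, X: np.ndarray, offset: np.ndarray, phi: float
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Fit the NB log-link GLM; returns (beta, mu, converged)."""
    beta = np.zeros(X.shape[1])
    mean_rate = max(np.mean(y / np.exp(offset)), 1e-8)
    beta[0] = np.log(mean_rate)
    eta = X @ beta + offset
    mu = np.exp(eta)
    ll_old = _nb_loglik(y, mu, phi)
    converged = False
    for _ in range(_MAX_ITER):
        w = mu / (1.0 + phi * mu)
        z = (eta - offset) + (y - mu) / np.maximum(mu, 1e-10)
        sw = np.sqrt(np.maximum(w, 1e-12))
        beta_new, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
        eta_new = np.clip(X @ beta_new + offset, -30, 30)
        mu_new = np.exp(eta_new)
        ll_new = _nb_loglik(y, mu_new, phi)
        # step-halving if the likelihood worsened
        step = 1.0
        while ll_new < ll_old - 1e-10 and step > 1e-4:
            step /= 2.0
            beta_try = beta + step * (beta_new - beta)
            eta_new = np.clip(X @ beta_try + offset, -30, 30)
            mu_new = np.exp(eta_new)
            ll_new = _nb_loglik(y, mu_new, phi)
            beta_new = beta_try
        if abs(ll_new - ll_old) < _TOL * (abs(ll_old) + 1.0):
            beta, eta, mu = beta_new, eta_new, mu_new
            converged = True
            break
        beta, eta, mu, ll_old = beta_new, eta_new, mu_new, ll_new
    return beta, mu, converged


def _cox_reid_apl(y: np.ndarray, X: np.ndarray, offset: np.ndarray, phi: float) -> float:
    """Cox-Reid adjusted profile log-likelihood at dispersion phi."""
    _, mu, _ = _irls_fit(y, X, offset, phi)
    w = mu / (1.0 + phi * mu)
    info = X.T @ (X * w[:, None])
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        return -np.inf
    return _nb_loglik(y, mu, phi) - 0.5 * logdet


def estimate_common_dispersion(
    counts: np.ndarray,
    X: np.ndarray,
    offsets: np.ndarray,
    grid: np.ndarray | None = None,
    max_features: int = 500,
) -> float:
    """Single dispersion maximizing the summed Cox-Reid APL: coarse
    log-spaced grid (1e-4 ... 10) followed by a bounded 1-d optimization
    of log-dispersion within the bracketing grid interval.

    At most ``max_features`` evenly strided non-degenerate rows are used.
    """
    from scipy.optimize import minimize_scalar

    if grid is None:
        grid = np.logspace(-4, 1, 16)
    counts = np.asarray(counts)
    usable = np.flatnonzero(counts.sum(axis=1) > 0)
    if usable.size == 0:
        raise ValueError("no nonzero features for dispersion estimation")
    if usable.size > max_features:
        usable = usable[np.linspace(0, usable.size - 1, max_features).astype(int)]
    rows = counts[usable].astype(float)

    def neg_total_apl(log_phi: float) -> float:
        return -sum(_cox_reid_apl(y, X, offsets, float(np.exp(log_phi)), ) for y in rows)

    scores = np.array([-neg_total_apl(np.log(p)) for p in grid])
    i = int(np.argmax(scores))
    lo = np.log(grid[max(i - 1, 0)])
    hi = np.log(grid[min(i + 1, len(grid) - 1)])
    if lo == hi:
        return float(grid[i])
    res = minimize_scalar(
        neg_total_apl, bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-3},
    )
    return float(np.exp(res.x))


def fit_nb_glm_lrt(
    y: np.ndarray,
    X: np.ndarray,
    colnames: list[str],
    offsets: np.ndarray,
    dispersion: float,
) -> dict[str, tuple[float, float, float]]:
    """Fit the full model and LRT each stage column.

    Returns {stage column name: (log2fc, lrt_stat, p)}; all-NaN values for
    an all-zero row or non-convergence.
    """
    y = np.asarray(y, dtype=float)
    stage_cols = [c for c in colnames if c.startswith("stage_")]
    if np.all(y == 0):
        return {c: (np.nan, np.nan, np.nan) for c in stage_cols}
    beta_full, mu_full, conv = _irls_fit(y, X, offsets, dispersion)
    if not conv:
        return {c: (np.nan, np.nan, np.nan) for c in stage_cols}
    ll_full = _nb_loglik(y, mu_full, dispersion)
    # log2fc reported from a 0.5-stabilized refit; testing uses raw counts
    beta_rep, _, _ = _irls_fit(y + 0.5, X, offsets, dispersion)
    out = {}
    for col in stage_cols:
        j = colnames.index(col)
        X_red = np.delete(X, j, axis=1)
        _, mu_red, conv_red = _irls_fit(y, X_red, offsets, dispersion)
        if not conv_red:
            out[col] = (np.nan, np.nan, np.nan)
            continue
        stat = max(2.0 * (ll_full - _nb_loglik(y, mu_red, dispersion)), 0.0)
        out[col] = (
            float(beta_rep[j] / np.log(2.0)),
            float(stat),
            float(chi2.sf(stat, df=1)),
        )
    return out


# ---------------------------------------------------------------------------
# Multiple testing


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values; NaNs are ignored for
    ranking and propagated to the output."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values outside [0, 1]")
    pv = p[ok]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    adj = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[ok] = res
    return out


# ---------------------------------------------------------------------------
# Full contrast table


@dataclass(frozen=True)
class DEOptions:
    alpha: float = 0.05
    dispersion: float | None = None    # estimated from the data when None


def run_de_contrasts(
    expr: ExpressionMatrix, options: DEOptions | None = None
) -> pd.DataFrame:
    """DE table over the four stage-vs-baseline contrasts.

    Columns: feature_id, contrast, log2fc, lrt_stat, p, p_adj, direction,
    significant.  BH adjustment is applied within each contrast.
    """
    options = options or DEOptions()
    X, cols = build_design_matrix(expr.samples)
    counts = expr.counts
    factors = tmm_factors(counts)
    lib = counts.sum(axis=0).astype(float)
    offsets = np.log(lib * factors)
    phi = (
        options.dispersion
        if options.dispersion is not None
        else estimate_common_dispersion(counts, X, offsets)
    )
    stage_cols = [c for c in cols if c.startswith("stage_")]
    records: dict[str, list] = {c: [] for c in stage_cols}
    for i, fid in enumerate(expr.feature_ids):
        res = fit_nb_glm_lrt(counts[i], X, cols, offsets, phi)
        for col, (lfc, stat, p) in res.items():
            records[col].append((fid, lfc, stat, p))
    frames = []
    for col in stage_cols:
        stage = col.removeprefix("stage_")
        df = pd.DataFrame(records[col], columns=["feature_id", "log2fc", "lrt_stat", "p"])
        df["contrast"] = f"{stage}vs{BASELINE_STAGE}"
        df["p_adj"] = bh_adjust(df["p"].to_numpy())
        df["direction"] = np.where(df["log2fc"] >= 0, "up", "down")
        df["significant"] = df["p_adj"] < options.alpha
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.attrs["dispersion"] = phi
    return out[
        ["feature_id", "contrast", "log2fc", "lrt_stat", "p", "p_adj",
         "direction", "significant"]
    ]
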