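"""k-means clustering of stage expression profiles with gap-statistic
selection of the number of clusters."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .core_io import STAGES, ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "stage_profiles",
    "within_cluster_ss",
    "gap_statistic_select_k",
    "cluster_patterns",
    "ClusterAssignment",
]


def stage_profiles(expr: ExpressionMatrix, feature_ids: list[str]) -> pd.DataFrame:
    """Per-feature z-standardized vector of the 5 stage mean FPKMs.

    Constant-profile features are dropped (cannot be standardized).
    """
    stages = [s for s in STAGES if any(smp.stage == s for smp in expr.samples)]
    cols = {s: [i for i, smp in enumerate(expr.samples) if smp.stage == s] for s in stages}
    rows, kept = [], []
    for fid in feature_ids:
        v = expr.row(fid, "fpkm")
        means = np.array([v[cols[s]].mean() for s in stages])
        sd = means.std(ddof=0)
        if sd == 0:
            logger.warning("feature %s has a constant stage profile; dropped", fid)
            continue
        rows.append((means - means.mean()) / sd)
        kept.append(fid)
    return pd.DataFrame(rows, index=kept, columns=stages)


def within_cluster_ss(x: np.ndarray, labels: np.ndarray) -> float:
    """Total within-cluster sum of squared distances to cluster centroids."""
    wss = 0.0
    for lab in np.unique(labels):
        pts = x[labels == lab]
        wss += float(np.sum((pts - pts.mean(axis=0)) ** 2))
    return wss


def _kmeans(x: np.ndarray, k: int, seed: int, n_init: int) -> tuple[np.ndarray, float]:
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed, algorithm="lloyd")
    labels = km.fit_predict(x)
    return labels, float(km.inertia_)


def gap_statistic_select_k(
    profiles: np.ndarray,
    k_range: range | None = None,
    B: int = 50,
    seed: int = 0,
    n_init: int = 10,
) -> tuple[int, pd.DataFrame]:
    """Tibshirani gap statistic with a uniform reference over each
    dimension's observed range.

    gap(k) = mean_b log W*_kb - log W_k;  s(k) = sd_b(log W*) * sqrt(1+1/B).
    k* is the smallest k with gap(k) >= gap(k+1) - s(k+1) (1-SE rule); if no
    k satisfies the rule, the k maximizing gap is returned.
    """
    x = np.asarray(profiles, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need >= 2 profiles")
    if np.allclose(x, x[0]):
        logger.warning("all profiles identical; k* = 1")
        curve = pd.DataFrame({"k": [1], "gap": [0.0], "s": [0.0], "log_wk": [0.0]})
        return 1, curve
    if k_range is None:
        k_range = range(1, min(11, x.shape[0]))
    ks = [k for k in k_range if 1 <= k <= x.shape[0]]
    rng = np.random.default_rng(seed)
    lo, hi = x.min(axis=0), x.max(axis=0)
    refs = [rng.uniform(lo, hi, size=x.shape) for _ in range(B)]

    rows = []
    for k in ks:
        if k == 1:
            log_wk = np.log(within_cluster_ss(x, np.zeros(x.shape[0], dtype=int)))
            log_wkb = np.array(
                [np.log(within_cluster_ss(r, np.zeros(r.shape[0], dtype=int))) for r in refs]
            )
        else:
            _, inertia = _kmeans(x, k, seed, n_init)
            log_wk = np.log(max(inertia, 1e-300))
            log_wkb = np.array(
                [np.log(max(_kmeans(r, k, seed, n_init)[1], 1e-300)) for r in refs]
            )
        gap = float(np.mean(log_wkb) - log_wk)
        s = float(np.std(log_wkb, ddof=0) * np.sqrt(1.0 + 1.0 / B))
        rows.append({"k": k, "gap": gap, "s": s, "log_wk": float(log_wk)})
    curve = pd.DataFrame(rows)

    k_star = None
    for i in range(len(ks) - 1):
        if curve.gap[i] >= curve.gap[i + 1] - curve.s[i + 1]:
            k_star = ks[i]
            break
    if k_star is None:
        k_star = ks[int(curve.gap.idxmax())]
    return k_star, curve


@dataclass
class ClusterAssignment:
    labels: dict[str, int]
    k: int
    gap_curve: pd.DataFrame | None = None
    wss: float = field(default=np.nan)


def cluster_patterns(
    profiles: pd.DataFrame, k: int, seed: int = 0, n_init: int = 25
) -> ClusterAssignment:
    """Lloyd k-means with random restarts; labels renumbered 1..k by
    descending cluster size (ties broken by first occurrence) so that the
    labeling is deterministic."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > profiles.shape[0]:
        raise ValueError(f"k={k} exceeds number of features {profiles.shape[0]}")
    x = profiles.to_numpy(dtype=float)
    raw, wss = _kmeans(x, k, seed, n_init)
    sizes = pd.Series(raw).value_counts()
    # order: size desc, then first appearance
    first_seen = {lab: int(np.argmax(raw == lab)) for lab in sizes.index}
    ordered = sorted(sizes.index, key=lambda lab: (-sizes[lab], first_seen[lab]))
    remap = {old: new + 1 for new, old in enumerate(ordered)}
    labels = {fid: remap[lab] for fid, lab in zip(profiles.index, raw)}
    return ClusterAssignment(labels=labels, k=k, wss=wss)
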