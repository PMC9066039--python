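"""Weighted co-expression modules from scratch: unsigned correlation
network raised to a soft power, topological-overlap similarity,
average-linkage tree with a static size-maximizing cut, module eigengenes
and their association with stage indicators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import t as t_dist

from .core_io import STAGES, ExpressionMatrix, SampleDesign

logger = logging.getLogger(__name__)

__all__ = [
    "pick_soft_power",
    "adjacency_matrix",
    "scale_free_fit",
    "tom_from_expression",
    "detect_modules",
    "module_eigengene",
    "module_trait_association",
    "ModuleResult",
]

DEFAULT_POWER_FALLBACK = 6


def _drop_constant(expr: np.ndarray, feature_ids: list[str]) -> tuple[np.ndarray, list[str]]:
    sd = expr.std(axis=1)
    keep = sd > 0
    if not keep.all():
        dropped = [f for f, k in zip(feature_ids, keep) if not k]
        logger.warning("excluding %d constant features: %s...", len(dropped), dropped[:3])
    return expr[keep], [f for f, k in zip(feature_ids, keep) if k]


def adjacency_matrix(expr: np.ndarray, power: int) -> np.ndarray:
    """Unsigned adjacency a_ij = |cor(x_i, x_j)|^power with unit diagonal."""
    if power < 1:
        raise ValueError("power must be >= 1")
    c = np.corrcoef(expr)
    a = np.abs(np.clip(c, -1, 1)) ** power
    np.fill_diagonal(a, 1.0)
    return a


def scale_free_fit(adj: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of the log10(freq) ~ log10(k) regression over connectivity bins.

    k_i = sum_j!=i a_ij; connectivity values are binned into equal-width
    bins, empty bins dropped.
    """
    k = adj.sum(axis=1) - np.diag(adj)
    if np.allclose(k.max(), k.min()):
        return 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        members = k[which == b]
        if members.size == 0 or members.mean() <= 0:
            continue
        xs.append(np.log10(members.mean()))
        ys.append(np.log10(members.size / k.size))
    if len(xs) < 3:
        return 0.0
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r) if np.isfinite(r) else 0.0


def pick_soft_power(
    expr: np.ndarray,
    powers: range = range(1, 21),
    r2_min: float = 0.8,
) -> tuple[int, pd.DataFrame]:
    """Smallest power whose adjacency gives scale-free fit R^2 >= r2_min;
    falls back to 6 with a warning when none does (e.g. pure noise)."""
    expr = np.asarray(expr, dtype=float)
    if expr.shape[0] < 3:
        raise ValueError("need >= 3 features")
    rows = []
    chosen = None
    for p in powers:
        r2 = scale_free_fit(adjacency_matrix(expr, p))
        rows.append({"power": p, "r2": r2})
        if chosen is None and r2 >= r2_min:
            chosen = p
    stats = pd.DataFrame(rows)
    if chosen is None:
        logger.warning(
            "no power in %s reached scale-free R^2 >= %.2f; using fallback %d",
            list(powers), r2_min, DEFAULT_POWER_FALLBACK,
        )
        chosen = DEFAULT_POWER_FALLBACK
    return chosen, stats


def tom_from_expression(expr: np.ndarray, power: int) -> np.ndarray:
    """Topological overlap similarity of the unsigned adjacency.

    TOM_ij = (sum_u a_iu a_uj - 2 a_ij^... ) per the standard formula
    (shared-neighbor sum excludes i and j themselves):
        l_ij  = sum_{u != i,j} a_iu a_uj
        TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),  TOM_ii = 1
    where k_i = sum_{u != i} a_iu.
    """
    expr = np.asarray(expr, dtype=float)
    if np.any(expr.std(axis=1) == 0):
        raise ValueError("constant feature in expression; exclude before TOM")
    a = adjacency_matrix(expr, power)
    k = a.sum(axis=1) - 1.0                       # exclude self (a_ii = 1)
    prod = a @ a
    # remove u == i and u == j contributions from the shared-neighbor sum
    l = prod - a * 2.0
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (l + a) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return tom


def detect_modules(
    tom: np.ndarray,
    min_module_size: int = 5,
    n_heights: int = 40,
    max_module_frac: float = 0.8,
) -> np.ndarray:
    """Average-linkage clustering of 1 - TOM with a static cut.

    Candidate cut heights form an evenly spaced grid over the dendrogram
    height range.  A branch counts as a module when its size is >=
    min_module_size and <= max_module_frac of all features (a near-global
    cluster is no module structure).  The module count kept is the one
    stable over the longest run of consecutive grid heights (ties -> more
    modules); within that run the cut assigning the most features wins.
    Unassigned features get label 0; labels 1.. are ordered by descending
    module size.
    """
    n = tom.shape[0]
    dist = 1.0 - tom
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    heights = np.linspace(z[:, 2].min(), z[:, 2].max(), n_heights, endpoint=False)
    cuts = []
    for h in heights:
        raw = fcluster(z, t=h, criterion="distance")
        sizes = pd.Series(raw).value_counts()
        big = sizes[(sizes >= min_module_size) & (sizes <= max_module_frac * n)]
        cuts.append((int(len(big)), int(big.sum()), raw))
    # longest run of a constant positive module count
    runs: list[tuple[int, int, int]] = []   # (length, n_big, start index)
    i = 0
    while i < len(cuts):
        j = i
        while j < len(cuts) and cuts[j][0] == cuts[i][0]:
            j += 1
        if cuts[i][0] > 0:
            runs.append((j - i, cuts[i][0], i))
        i = j
    if not runs:
        logger.warning("no branch reached min_module_size; all features unassigned")
        return np.zeros(n, dtype=int)
    length, best_count, start = max(runs, key=lambda r: (r[0], r[1], -r[2]))
    best = max(cuts[start : start + length], key=lambda c: c[1])
    best_labels = best[2]
    sizes = pd.Series(best_labels).value_counts()
    big = [lab for lab in sizes.index
           if min_module_size <= sizes[lab] <= max_module_frac * n]
    first_seen = {lab: int(np.argmax(best_labels == lab)) for lab in big}
    ordered = sorted(big, key=lambda lab: (-sizes[lab], first_seen[lab]))
    remap = {lab: i + 1 for i, lab in enumerate(ordered)}
    return np.array([remap.get(lab, 0) for lab in best_labels], dtype=int)


def module_eigengene(sub: np.ndarray) -> np.ndarray:
    """First principal component across samples of a standardized
    (features x samples) submatrix, unit norm, sign-oriented so the mean
    correlation with member profiles is positive."""
    sd = sub.std(axis=1, ddof=0)
    if np.all(sd == 0):
        raise ValueError("module of constant features")
    z = (sub - sub.mean(axis=1, keepdims=True)) / np.where(sd == 0, 1.0, sd)[:, None]
    _u, _s, vt = np.linalg.svd(z, full_matrices=False)
    eig = vt[0]
    cors = [np.corrcoef(eig, row)[0, 1] for row in z if row.std() > 0]
    if np.nanmean(cors) < 0:
        eig = -eig
    return eig / np.linalg.norm(eig)


@dataclass
class ModuleResult:
    feature_ids: list[str]
    labels: np.ndarray
    power: int
    eigengenes: pd.DataFrame              # modules x samples
    associations: pd.DataFrame            # rows (module, stage) with r, p


def module_trait_association(
    labels: np.ndarray,
    expr: np.ndarray,
    samples: list[SampleDesign],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlate each module eigengene with each stage's 0/1 indicator.

    Returns (eigengene matrix [modules x samples], long-format association
    table with Pearson r and Student-t p, n-2 df).
    """
    n_samples = len(samples)
    if expr.shape[1] != n_samples:
        raise ValueError("expression / design sample mismatch")
    modules = sorted(set(labels) - {0})
    if not modules:
        raise ValueError("no modules to associate")
    stages = [s for s in STAGES if any(smp.stage == s for smp in samples)]
    eig_rows, assoc = {}, []
    for mod in modules:
        sub = expr[labels == mod]
        try:
            eig = module_eigengene(sub)
        except ValueError:
            eig_rows[f"M{mod}"] = np.full(n_samples, np.nan)
            for s in stages:
                assoc.append({"module": mod, "stage": s, "r": np.nan, "p": np.nan})
            continue
        eig_rows[f"M{mod}"] = eig
        for s in stages:
            indicator = np.array([1.0 if smp.stage == s else 0.0 for smp in samples])
            r = float(np.corrcoef(eig, indicator)[0, 1])
            if abs(r) >= 1.0:
                p = float(np.finfo(float).tiny)
            else:
                t_stat = r * np.sqrt((n_samples - 2) / (1.0 - r * r))
                p = 2.0 * float(t_dist.sf(abs(t_stat), df=n_samples - 2))
            assoc.append({"module": mod, "stage": s, "r": r, "p": p})
    eig_df = pd.DataFrame(eig_rows, index=[s.sample_id for s in samples]).T
    return eig_df, pd.DataFrame(assoc)


def run_coexpression(
    expr: ExpressionMatrix,
    feature_ids: list[str] | None = None,
    min_module_size: int = 5,
    power: int | None = None,
) -> ModuleResult:
    """End-to-end: pick power, TOM, modules, stage associations (on log1p
    FPKM)."""
    ids = feature_ids or expr.feature_ids
    mat = np.log1p(np.vstack([expr.row(f, "fpkm") for f in ids]))
    mat, ids = _drop_constant(mat, ids)
    if power is None:
        power, _ = pick_soft_power(mat)
    tom = tom_from_expression(mat, power)
    labels = detect_modules(tom, min_module_size=min_module_size)
    if set(labels) == {0}:
        eig_df = pd.DataFrame()
        assoc = pd.DataFrame(columns=["module", "stage", "r", "p"])
    else:
        eig_df, assoc = module_trait_association(labels, mat, expr.samples)
    return ModuleResult(ids, labels, power, eig_df, assoc)
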