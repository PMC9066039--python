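"""Cis-target prediction: protein-coding genes within a genomic window of a
lncRNA whose expression correlates by Spearman's rank test."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata, t as t_dist

from .core_io import ExpressionMatrix, GenomicInterval
from .diff_expression import bh_adjust

logger = logging.getLogger(__name__)

__all__ = ["TargetPair", "cis_candidates", "spearman_correlation", "predict_targets"]

DEFAULT_WINDOW = 100_000


@dataclass(frozen=True)
class TargetPair:
    lncrna_id: str
    gene_id: str
    distance: int
    rho: float
    p: float
    significant: bool


def cis_candidates(
    lncs: list[tuple[str, GenomicInterval]],
    genes: list[tuple[str, GenomicInterval]],
    window: int = DEFAULT_WINDOW,
) -> list[tuple[str, str, int]]:
    """All (lncRNA, gene, gap) pairs on the same chromosome whose interval
    gap is <= window nt; overlap counts as distance 0; strand ignored."""
    if window < 0:
        raise ValueError("window must be >= 0")
    genes_by_chrom: dict[str, list[tuple[str, GenomicInterval]]] = {}
    for gid, iv in genes:
        genes_by_chrom.setdefault(iv.chrom, []).append((gid, iv))
    for chrom in genes_by_chrom:
        genes_by_chrom[chrom].sort(key=lambda g: g[1].start)
    out = []
    for lid, liv in lncs:
        for gid, giv in genes_by_chrom.get(liv.chrom, []):
            if giv.start > liv.end + window + 1:
                break
            d = liv.distance(giv)
            if d is not None and d <= window:
                out.append((lid, gid, d))
    return out


def spearman_correlation(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho with mid-ranks and a two-sided t-approximation p-value.

    |rho| = 1 maps to the smallest positive float rather than p = 0.
    Zero variance in either vector returns (nan, nan) with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    n = x.size
    if n < 4:
        raise ValueError("need n >= 4 observations")
    rx, ry = rankdata(x), rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        logger.warning("zero variance in correlation input; returning NA")
        return np.nan, np.nan
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = max(min(rho, 1.0), -1.0)
    if 1.0 - abs(rho) < 1e-12:          # rank-identical up to fp rounding
        rho = float(np.sign(rho))
    if abs(rho) == 1.0:
        return rho, float(np.finfo(float).tiny)
    t_stat = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * float(t_dist.sf(abs(t_stat), df=n - 2))
    return rho, min(p, 1.0)


def predict_targets(
    candidates: list[tuple[str, str, int]],
    expr: ExpressionMatrix,
    alpha: float = 0.05,
    adjust: bool = False,
) -> list[TargetPair]:
    """Correlate each candidate pair's expression across samples.

    The significance flag uses the unadjusted p < alpha rule by default; the
    optional BH mode flags on adjusted p instead.  Candidates missing from
    the matrix are skipped with a warning.
    """
    rows = []
    for lid, gid, dist in candidates:
        if lid not in expr or gid not in expr:
            logger.warning("candidate pair (%s, %s) missing from matrix; skipped", lid, gid)
            continue
        rho, p = spearman_correlation(expr.row(lid, "fpkm"), expr.row(gid, "fpkm"))
        rows.append([lid, gid, dist, rho, p])
    if not rows:
        return []
    df = pd.DataFrame(rows, columns=["lncrna_id", "gene_id", "distance", "rho", "p"])
    pcol = bh_adjust(df["p"].to_numpy()) if adjust else df["p"].to_numpy()
    sig = (pcol < alpha) & ~np.isnan(pcol)
    return [
        TargetPair(r.lncrna_id, r.gene_id, int(r.distance), float(r.rho),
                   float(r.p), bool(s))
        for r, s in zip(df.itertuples(index=False), sig)
    ]
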