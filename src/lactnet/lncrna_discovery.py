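"""Multi-step filtering cascade that reduces assembled transcripts to a
candidate lncRNA set.

Order of filters (first failure recorded as the removal reason):

0. support        — kept if seen in >= 2 samples OR assembled by >= 2 tools
1. class_code     — "=" exits as *known*; only "u" (intergenic) and "i"
                    (intronic) continue; anything else is removed
2. length/exons   — length >= 200 nt and >= 2 exons
3. expression     — FPKM aggregate (max over samples by default) >= 0.3
4. orf            — longest ATG-initiated forward-frame ORF < 360 nt
                    (length includes the stop codon: 360 nt ~ 120 aa)
5. coding_potential — removed if the configured combination of the three
                    coding-potential scores is > 0 (mode "any" by default)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix, TranscriptModel

__all__ = [
    "DiscoveryParams",
    "DiscoveryReport",
    "find_max_orf",
    "run_discovery_cascade",
]

_STOPS = {"TAA", "TAG", "TGA"}
_VALID = set("ACGTN")

REMOVAL_REASONS = (
    "support",
    "class_code",
    "length",
    "exon_count",
    "expression",
    "orf",
    "coding_potential",
)


@dataclass
class DiscoveryParams:
    min_len: int = 200
    min_exons: int = 2
    min_fpkm: float = 0.3
    max_orf: int = 360
    min_support: int = 2
    fpkm_agg: str = "max"          # {"max", "mean"}
    coding_mode: str = "any"       # {"any", "all"}
    novel_class_codes: tuple[str, ...] = ("u", "i")

    def __post_init__(self) -> None:
        if self.fpkm_agg not in ("max", "mean"):
            raise ValueError("fpkm_agg must be 'max' or 'mean'")
        if self.coding_mode not in ("any", "all"):
            raise ValueError("coding_mode must be 'any' or 'all'")


@dataclass
class DiscoveryReport:
    """Per-transcript outcome of the cascade plus per-step removal counts."""

    status: dict[str, str] = field(default_factory=dict)   # known/retained_lncRNA/removed
    removal_reason: dict[str, str] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "transcript_id": tid,
                "status": st,
                "removal_reason": self.removal_reason.get(tid, ""),
            }
            for tid, st in self.status.items()
        ]
        return pd.DataFrame(rows)

    def validate(self) -> None:
        n = len(self.status)
        total = sum(
            self.counts.get(k, 0)
            for k in ("known", "retained_lncRNA", *REMOVAL_REASONS)
        )
        if total != n:
            raise AssertionError(f"report counts {total} != input size {n}")


def find_max_orf(sequence: str) -> int:
    """Length in nt (stop codon included) of the longest ATG-initiated ORF
    closed by TAA/TAG/TGA in any forward frame; 0 if none.

    Codons containing ``N`` match neither start nor stop.  Raises on
    characters outside A/C/G/T/N.
    """
    seq = sequence.upper()
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"non-IUPAC nucleotide characters: {sorted(bad)}")
    best = 0
    n = len(seq)
    for frame in range(3):
        open_start: int | None = None
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if open_start is None:
                if codon == "ATG":
                    open_start = i
            elif codon in _STOPS:
                best = max(best, i + 3 - open_start)
                open_start = None
    return best


def _fpkm_aggregate(expr: ExpressionMatrix, tid: str, agg: str) -> float:
    row = expr.row(tid, "fpkm")
    return float(np.max(row) if agg == "max" else np.mean(row))


def _is_coding(scores: pd.Series, mode: str) -> bool:
    flags = [scores["cpc_score"] > 0, scores["plek_score"] > 0, scores["cnci_score"] > 0]
    return any(flags) if mode == "any" else all(flags)


def run_discovery_cascade(
    transcripts: list[TranscriptModel],
    fpkm: ExpressionMatrix,
    scores: pd.DataFrame,
    params: DiscoveryParams | None = None,
) -> tuple[list[str], DiscoveryReport]:
    """Apply the filter cascade; returns (retained lncRNA ids, report).

    ``scores`` is indexed by transcript_id with cpc/plek/cnci columns and
    only needs rows for transcripts that reach the coding-potential step;
    likewise ``sequence`` is only required at the ORF step.
    """
    params = params or DiscoveryParams()
    report = DiscoveryReport()
    retained: list[str] = []

    def remove(tid: str, reason: str) -> None:
        report.status[tid] = "removed"
        report.removal_reason[tid] = reason
        report.counts[reason] = report.counts.get(reason, 0) + 1

    for t in sorted(transcripts, key=lambda t: t.transcript_id):
        tid = t.transcript_id
        if max(t.sample_occurrence, t.assembler_support) < params.min_support:
            remove(tid, "support")
            continue
        if t.class_code == "=":
            report.status[tid] = "known"
            report.counts["known"] = report.counts.get("known", 0) + 1
            continue
        if t.class_code not in params.novel_class_codes:
            remove(tid, "class_code")
            continue
        if t.length < params.min_len:
            remove(tid, "length")
            continue
        if t.n_exons < params.min_exons:
            remove(tid, "exon_count")
            continue
        if tid not in fpkm:
            raise KeyError(f"transcript {tid} missing from expression matrix")
        if _fpkm_aggregate(fpkm, tid, params.fpkm_agg) < params.min_fpkm:
            remove(tid, "expression")
            continue
        if t.sequence is None:
            raise ValueError(f"transcript {tid} reached ORF step without sequence")
        if find_max_orf(t.sequence) >= params.max_orf:
            remove(tid, "orf")
            continue
        if tid not in scores.index:
            raise KeyError(f"transcript {tid} missing from coding-potential scores")
        if _is_coding(scores.loc[tid], params.coding_mode):
            remove(tid, "coding_potential")
            continue
        report.status[tid] = "retained_lncRNA"
        report.counts["retained_lncRNA"] = report.counts.get("retained_lncRNA", 0) + 1
        retained.append(tid)

    report.validate()
    return retained, report
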