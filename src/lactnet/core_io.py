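"""Canonical in-memory data model and text-format readers/writers.

Coordinate convention: all in-memory coordinates are 1-based inclusive
(GTF-native).  The single conversion point to 0-based half-open is the
BED writer/reader.  All tabular files are tab-delimited UTF-8; lines
starting with ``#`` are ignored.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STAGES = ("-14", "-10", "-6", "-2", "+1")

__all__ = [
    "STAGES",
    "GenomicInterval",
    "TranscriptModel",
    "SampleDesign",
    "ExpressionMatrix",
    "SnpRecord",
    "GtfParseError",
    "read_gtf",
    "write_gtf",
    "read_fasta",
    "write_fasta",
    "read_design",
    "read_expression_matrix",
    "read_snp_effects",
    "write_snp_effects",
    "read_coding_scores",
    "write_bed",
    "read_bed",
]


class GtfParseError(ValueError):
    """Raised for malformed GTF input, carrying the offending line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """Closed genomic interval, 1-based inclusive on both ends."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"end < start ({self.end} < {self.start}) on {self.chrom}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def distance(self, other: "GenomicInterval") -> int | None:
        """Gap in nt between two intervals; 0 if overlapping, None if on
        different chromosomes."""
        if self.chrom != other.chrom:
            return None
        if self.start <= other.end and other.start <= self.end:
            return 0
        if self.end < other.start:
            return other.start - self.end - 1
        return self.start - other.end - 1


@dataclass
class TranscriptModel:
    """Assembled transcript with exon structure and assembly metadata."""

    transcript_id: str
    gene_id: str
    interval: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)
    class_code: str = "="
    assembler_support: int = 0
    sample_occurrence: int = 0
    sequence: str | None = None

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"{self.transcript_id}: overlapping exons "
                    f"[{a.start},{a.end}] and [{b.start},{b.end}]"
                )
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"{self.transcript_id}: sequence length {len(self.sequence)} "
                f"!= exonic length {self.length}"
            )

    @property
    def length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)


@dataclass(frozen=True)
class SampleDesign:
    """One sample of the 3-individual x 5-stage design."""

    sample_id: str
    individual: str
    stage: str

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(
                f"unknown stage {self.stage!r}; expected one of {STAGES}"
            )


class ExpressionMatrix:
    """Features x samples expression with parallel counts and FPKM layers.

    Columns of both layers are aligned to the order of ``samples``.
    """

    def __init__(
        self,
        feature_ids: Sequence[str],
        samples: Sequence[SampleDesign],
        counts: np.ndarray,
        fpkm: np.ndarray,
    ) -> None:
        self.feature_ids = list(feature_ids)
        self.samples = list(samples)
        counts = np.asarray(counts)
        fpkm = np.asarray(fpkm, dtype=float)
        shape = (len(self.feature_ids), len(self.samples))
        if counts.shape != shape or fpkm.shape != shape:
            raise ValueError(
                f"matrix shape mismatch: counts {counts.shape}, fpkm "
                f"{fpkm.shape}, expected {shape}"
            )
        if np.any(counts < 0):
            raise ValueError("negative counts")
        if not np.all(np.isfinite(fpkm)) or np.any(fpkm < 0):
            raise ValueError("FPKM must be finite and non-negative")
        pairs = [(s.individual, s.stage) for s in self.samples]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate (individual, stage) pairs in design")
        self.counts = counts.astype(np.int64)
        self.fpkm = fpkm
        self._index = {f: i for i, f in enumerate(self.feature_ids)}

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def row(self, feature_id: str, layer: str = "fpkm") -> np.ndarray:
        i = self._index[feature_id]
        return (self.fpkm if layer == "fpkm" else self.counts)[i]

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self._index

    def subset(self, feature_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self._index[f] for f in feature_ids]
        return ExpressionMatrix(
            [self.feature_ids[i] for i in idx],
            self.samples,
            self.counts[idx],
            self.fpkm[idx],
        )


@dataclass(frozen=True)
class SnpRecord:
    """GWAS marker with its estimated effect on the trait."""

    id: str
    chrom: str
    pos: int
    beta: float
    genotype_counts: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.id}: pos must be >= 1")
        if not np.isfinite(self.beta):
            raise ValueError(f"{self.id}: beta not finite")


# ---------------------------------------------------------------------------
# GTF

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Parse a (gffcompare-annotated) GTF into transcript models.

    Exon lines are aggregated per ``transcript_id``; ``class_code``,
    ``assembler_support`` and ``sample_occurrence`` attributes are read
    when present.  A transcript without a class_code attribute defaults
    to ``"="`` with a warning.
    """
    path = Path(path)
    exons: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, dict] = {}
    order: list[str] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{path}:{lineno}: expected 9 tab-delimited columns, "
                    f"got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs_s = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise GtfParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if end < start:
                raise ValueError(f"{path}:{lineno}: end < start")
            attrs = _parse_attributes(attrs_s)
            tid = attrs.get("transcript_id")
            if tid is None:
                raise GtfParseError(
                    f"{path}:{lineno}: missing transcript_id attribute"
                )
            if tid not in meta:
                order.append(tid)
                meta[tid] = {
                    "gene_id": attrs.get("gene_id", tid),
                    "strand": strand,
                    "chrom": chrom,
                    "class_code": None,
                    "assembler_support": 0,
                    "sample_occurrence": 0,
                }
                exons[tid] = []
            if "class_code" in attrs:
                meta[tid]["class_code"] = attrs["class_code"]
            for key in ("assembler_support", "sample_occurrence"):
                if key in attrs:
                    meta[tid][key] = int(attrs[key])
            if feature == "exon":
                exons[tid].append(GenomicInterval(chrom, start, end, strand))

    models = []
    for tid in order:
        m = meta[tid]
        ex = exons[tid]
        if not ex:
            raise GtfParseError(f"{path}: transcript {tid} has no exon lines")
        cc = m["class_code"]
        if cc is None:
            logger.warning("transcript %s has no class_code; defaulting to '='", tid)
            cc = "="
        iv = GenomicInterval(
            m["chrom"], min(e.start for e in ex), max(e.end for e in ex), m["strand"]
        )
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=m["gene_id"],
                interval=iv,
                exons=ex,
                class_code=cc,
                assembler_support=m["assembler_support"],
                sample_occurrence=m["sample_occurrence"],
            )
        )
    return models


def write_gtf(transcripts: Iterable[TranscriptModel], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for t in transcripts:
            attrs = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'class_code "{t.class_code}"; '
                f'assembler_support "{t.assembler_support}"; '
                f'sample_occurrence "{t.sample_occurrence}";'
            )
            iv = t.interval
            fh.write(
                "\t".join(
                    [iv.chrom, "lactnet", "transcript", str(iv.start), str(iv.end),
                     ".", iv.strand, ".", attrs]
                )
                + "\n"
            )
            for e in t.exons:
                fh.write(
                    "\t".join(
                        [e.chrom, "lactnet", "exon", str(e.start), str(e.end),
                         ".", e.strand, ".", attrs]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, list[str]] = {}
    name = None
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                if name in seqs:
                    raise ValueError(f"duplicate FASTA record {name}")
                seqs[name] = []
            else:
                if name is None:
                    raise ValueError("FASTA sequence before header")
                seqs[name].append(line.upper())
    return {k: "".join(v) for k, v in seqs.items()}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 60) -> None:
    with Path(path).open("w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Expression matrix + design


def _read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kw)


def read_design(path: str | Path) -> list[SampleDesign]:
    df = _read_tsv(path, dtype=str)
    required = {"sample_id", "individual", "stage"}
    if not required.issubset(df.columns):
        raise ValueError(f"design table missing columns {required - set(df.columns)}")
    return [
        SampleDesign(r.sample_id, r.individual, r.stage)
        for r in df.itertuples(index=False)
    ]


def read_expression_matrix(
    counts_path: str | Path,
    fpkm_path: str | Path,
    design_path: str | Path,
) -> ExpressionMatrix:
    """Load counts + FPKM TSVs and align their columns to the design order.

    Both matrices must have a ``feature_id`` first column and one column
    per sample; the sample sets of both matrices must equal the design's.
    """
    design = read_design(design_path)
    want = [s.sample_id for s in design]
    counts_df = _read_tsv(counts_path, index_col=0)
    fpkm_df = _read_tsv(fpkm_path, index_col=0)
    for name, df in (("counts", counts_df), ("fpkm", fpkm_df)):
        missing = set(want) - set(df.columns)
        extra = set(df.columns) - set(want)
        if missing or extra:
            raise ValueError(
                f"{name} matrix sample mismatch: missing {sorted(missing)}, "
                f"unexpected {sorted(extra)}"
            )
    if list(counts_df.index) != list(fpkm_df.index):
        raise ValueError("counts and fpkm feature ids differ")
    counts = counts_df[want].to_numpy()
    if np.any(counts < 0):
        raise ValueError("negative count encountered")
    if not np.allclose(counts, np.round(counts)):
        raise ValueError("non-integer counts")
    return ExpressionMatrix(
        list(counts_df.index), design, np.round(counts).astype(np.int64),
        fpkm_df[want].to_numpy(),
    )


def write_expression_matrix(
    expr: ExpressionMatrix,
    counts_path: str | Path,
    fpkm_path: str | Path,
    design_path: str | Path,
) -> None:
    ids = expr.sample_ids
    pd.DataFrame(expr.counts, index=expr.feature_ids, columns=ids).rename_axis(
        "feature_id"
    ).to_csv(counts_path, sep="\t")
    pd.DataFrame(expr.fpkm, index=expr.feature_ids, columns=ids).rename_axis(
        "feature_id"
    ).to_csv(fpkm_path, sep="\t", float_format="%.6g")
    pd.DataFrame(
        {
            "sample_id": ids,
            "individual": [s.individual for s in expr.samples],
            "stage": [s.stage for s in expr.samples],
        }
    ).to_csv(design_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# SNP effects


def read_snp_effects(path: str | Path) -> list[SnpRecord]:
    """Read the SNP effect table, sorted by (chrom, pos); duplicate ids and
    non-numeric betas are rejected."""
    df = _read_tsv(path, dtype={"id": str, "chrom": str})
    required = {"id", "chrom", "pos", "beta"}
    if not required.issubset(df.columns):
        raise ValueError(f"SNP table missing columns {required - set(df.columns)}")
    if df["id"].duplicated().any():
        dups = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate SNP ids: {dups[:5]}")
    betas = pd.to_numeric(df["beta"], errors="coerce")
    bad = df.loc[betas.isna() | ~np.isfinite(betas)]
    if len(bad):
        raise ValueError(
            f"non-numeric beta at rows {list(bad.index[:5])} (ids {list(bad['id'][:5])})"
        )
    has_geno = {"n_AA", "n_Aa", "n_aa"}.issubset(df.columns)
    records = []
    for i, r in df.iterrows():
        gc = None
        if has_geno and not pd.isna(r["n_AA"]):
            gc = (int(r["n_AA"]), int(r["n_Aa"]), int(r["n_aa"]))
        records.append(
            SnpRecord(str(r["id"]), str(r["chrom"]), int(r["pos"]),
                      float(betas[i]), gc)
        )
    records.sort(key=lambda s: (s.chrom, s.pos, s.id))
    return records


def write_snp_effects(snps: Iterable[SnpRecord], path: str | Path) -> None:
    rows = []
    for s in snps:
        row = {"id": s.id, "chrom": s.chrom, "pos": s.pos, "beta": f"{s.beta:.8g}"}
        if s.genotype_counts is not None:
            row["n_AA"], row["n_Aa"], row["n_aa"] = s.genotype_counts
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_coding_scores(path: str | Path) -> pd.DataFrame:
    """Coding-potential score table: transcript_id, cpc_score, plek_score,
    cnci_score."""
    df = _read_tsv(path, dtype={"transcript_id": str})
    required = {"transcript_id", "cpc_score", "plek_score", "cnci_score"}
    if not required.issubset(df.columns):
        raise ValueError(f"score table missing columns {required - set(df.columns)}")
    return df.set_index("transcript_id")


# ---------------------------------------------------------------------------
# BED


def write_bed(features: Iterable[tuple[str, GenomicInterval]], path: str | Path) -> None:
    """Write BED6; internal 1-based inclusive -> 0-based half-open here and
    only here.  Rows sorted by (chrom, start, name)."""
    rows = sorted(features, key=lambda f: (f[1].chrom, f[1].start, f[0]))
    with Path(path).open("w") as fh:
        for name, iv in rows:
            fh.write(
                f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{name}\t0\t{iv.strand}\n"
            )


def read_bed(path: str | Path) -> list[tuple[str, GenomicInterval]]:
    out = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ValueError(f"{path}:{lineno}: BED needs >= 4 columns")
            strand = f[5] if len(f) >= 6 else "."
            out.append((f[3], GenomicInterval(f[0], int(f[1]) + 1, int(f[2]), strand)))
    return out
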