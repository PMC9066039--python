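"""Self-consistent synthetic study generator with known ground truth.

Emits every input the analysis stages consume — transcript models (GTF),
transcript sequences (FASTA), coding-potential scores (TSV), counts/FPKM
matrices with a 3-individual x 5-stage design (TSV) and a SNP effect
table (TSV) — together with a truth object recording planted lncRNAs,
differential features, cis pairs, co-expression modules and the
GWAS-enriched feature set.

Counts are NB-distributed (Var = mu + dispersion * mu^2) with log-link
individual effects; FPKM is derived from the simulated counts so the two
layers are mutually consistent.  A configurable set of decoy transcripts
each violates exactly one discovery filter.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core_io import (
    STAGES,
    ExpressionMatrix,
    GenomicInterval,
    SampleDesign,
    SnpRecord,
    TranscriptModel,
    write_expression_matrix,
    write_fasta,
    write_gtf,
    write_snp_effects,
)

__all__ = ["SimulationConfig", "SimulationTruth", "simulate_dataset", "simulate_null_gwas"]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_STOPS = ("TAA", "TAG", "TGA")

DECOY_KINDS = (
    "support", "class_code", "length", "exon_count", "expression", "orf",
    "coding_potential",
)


@dataclass
class SimulationConfig:
    seed: int = 0
    n_transcripts: int = 200
    frac_known: float = 0.4
    frac_novel_u: float = 0.4
    frac_novel_i: float = 0.2
    n_genes: int = 80
    n_de_lnc: int = 10
    de_log2fc: float = 2.0
    nb_dispersion: float = 0.1
    base_mean: float = 100.0
    n_cis_pairs: int = 5
    cis_rho: float = 0.9
    n_snps: int = 2000
    n_enriched_snps: int = 100
    beta_sd_background: float = 0.1
    beta_sd_enriched: float = 0.3
    snp_flank: int = 10_000
    genome: tuple[tuple[str, int], ...] = (("chr1", 50_000_000), ("chr2", 50_000_000))
    decoys_per_kind: int = 2
    n_modules: int = 3
    module_size: int = 15
    module_effect: float = 2.0

    def validate(self) -> None:
        fracs = self.frac_known + self.frac_novel_u + self.frac_novel_i
        if abs(fracs - 1.0) > 1e-9:
            raise ValueError(f"class-code fractions sum to {fracs}, expected 1")
        if self.n_enriched_snps > self.n_snps:
            raise ValueError("n_enriched_snps exceeds n_snps")
        if not -1.0 <= self.cis_rho <= 1.0:
            raise ValueError("cis_rho outside [-1, 1]")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        n_novel = self.n_transcripts - round(self.frac_known * self.n_transcripts)
        n_clean = n_novel - self.decoys_per_kind * len(DECOY_KINDS)
        if n_clean < self.n_de_lnc:
            raise ValueError("more planted DE lncRNAs than clean novel transcripts")
        if n_clean < self.n_cis_pairs:
            raise ValueError("more cis pairs than clean novel transcripts")
        if self.n_modules * self.module_size > round(self.frac_known * self.n_transcripts):
            raise ValueError("planted modules exceed the number of coding genes")


@dataclass
class SimulationTruth:
    true_lncrna_ids: list[str] = field(default_factory=list)
    true_de_ids: dict[str, list[str]] = field(default_factory=dict)
    true_cis_pairs: list[tuple[str, str]] = field(default_factory=list)
    enriched_feature_set: str = ""
    enriched_snp_ids: list[str] = field(default_factory=list)
    module_membership: dict[str, int] = field(default_factory=dict)
    decoys: dict[str, str] = field(default_factory=dict)   # transcript -> violated filter
    coding_gene_ids: list[str] = field(default_factory=list)
    exchangeable_null: bool = False

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationTruth":
        d = json.loads(Path(path).read_text())
        d["true_cis_pairs"] = [tuple(p) for p in d["true_cis_pairs"]]
        return cls(**d)


# ---------------------------------------------------------------------------
# Sequence construction


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _max_orf(seq: str) -> int:
    # local copy of the forward-frame scan to keep the generator
    # independent of the module it feeds
    best = 0
    for frame in range(3):
        start = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in _STOPS:
                best = max(best, i + 3 - start)
                start = None
    return best


def _noncoding_seq(rng: np.random.Generator, n: int, max_orf: int = 360) -> str:
    """Random sequence whose longest ORF is < max_orf (rejection sampled)."""
    for _ in range(200):
        seq = _random_seq(rng, n)
        if _max_orf(seq) < max_orf:
            return seq
    raise RuntimeError("could not sample an ORF-free sequence")


def _coding_seq(rng: np.random.Generator, n: int, orf_nt: int = 450) -> str:
    """Sequence of length n embedding an ORF of >= orf_nt nt."""
    n_codons = orf_nt // 3 - 2
    codons = []
    while len(codons) < n_codons:
        c = _random_seq(rng, 3)
        if c not in _STOPS and c != "ATG":
            codons.append(c)
    orf = "ATG" + "".join(codons) + "TAA"
    if len(orf) > n:
        raise ValueError(f"transcript length {n} too short for a {orf_nt} nt ORF")
    pad = n - len(orf)
    left = int(rng.integers(0, pad + 1))
    # pad with C runs: cannot create ATG/stop codons across junctions
    return "C" * left + orf + "C" * (pad - left)


# ---------------------------------------------------------------------------
# Locus layout


def _make_exons(
    rng: np.random.Generator, chrom: str, start: int, total_len: int, n_exons: int,
    strand: str,
) -> list[GenomicInterval]:
    cuts = np.sort(rng.choice(np.arange(1, total_len), size=n_exons - 1, replace=False)) \
        if n_exons > 1 else np.array([], dtype=int)
    lengths = np.diff(np.concatenate([[0], cuts, [total_len]])).astype(int)
    exons, pos = [], start
    for L in lengths:
        exons.append(GenomicInterval(chrom, pos, pos + int(L) - 1, strand))
        pos += int(L) + int(rng.integers(100, 2000))   # intron
    return exons


def _place_transcript(
    rng: np.random.Generator, cfg: SimulationConfig, tid: str, gene_id: str,
    class_code: str, length: int, n_exons: int, *, start: int | None = None,
    chrom: str | None = None, support: tuple[int, int] = (2, 3),
) -> TranscriptModel:
    if chrom is None:
        ci = int(rng.integers(0, len(cfg.genome)))
        chrom, clen = cfg.genome[ci]
    else:
        clen = dict(cfg.genome)[chrom]
    if start is None:
        start = int(rng.integers(1, max(clen - length * 3 - 20_000, 2)))
    strand = "+" if rng.random() < 0.5 else "-"
    exons = _make_exons(rng, chrom, start, length, n_exons, strand)
    iv = GenomicInterval(chrom, exons[0].start, exons[-1].end, strand)
    return TranscriptModel(
        transcript_id=tid, gene_id=gene_id, interval=iv, exons=exons,
        class_code=class_code, assembler_support=support[0],
        sample_occurrence=support[1],
    )


# ---------------------------------------------------------------------------
# Main generator


def _build_design() -> list[SampleDesign]:
    return [
        SampleDesign(f"I{ind}_S{stage}", f"I{ind}", stage)
        for ind in (1, 2, 3)
        for stage in STAGES
    ]


def simulate_dataset(
    config: SimulationConfig, out_dir: str | Path
) -> tuple[dict[str, Path], SimulationTruth]:
    """Generate the full synthetic study under ``out_dir``.

    Returns ({file role: path}, truth).  Byte-identical output for a fixed
    config (including seed).
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    truth = SimulationTruth()

    n_known = round(config.frac_known * config.n_transcripts)
    n_u = round(config.frac_novel_u * config.n_transcripts)
    n_i = config.n_transcripts - n_known - n_u

    transcripts: list[TranscriptModel] = []
    seqs: dict[str, str] = {}
    scores: dict[str, tuple[float, float, float]] = {}

    # --- known coding genes ("=" transcripts, one gene each) ----------------
    gene_ids = []
    for g in range(n_known):
        gid = f"GENE{g:05d}"
        gene_ids.append(gid)
        length = int(rng.integers(800, 3000))
        t = _place_transcript(rng, config, gid, gid, "=", length,
                              int(rng.integers(2, 8)))
        t.sequence = _coding_seq(rng, length)
        transcripts.append(t)
        seqs[gid] = t.sequence
        scores[gid] = tuple(rng.uniform(0.5, 3.0, size=3))
    truth.coding_gene_ids = gene_ids

    # --- novel transcripts --------------------------------------------------
    novel_specs = [("u", f"LNC{j:05d}") for j in range(n_u)] + [
        ("i", f"LNCI{j:05d}") for j in range(n_i)
    ]
    n_decoys = config.decoys_per_kind * len(DECOY_KINDS)
    decoy_slots = {}
    for d, kind in enumerate(np.repeat(DECOY_KINDS, config.decoys_per_kind)):
        decoy_slots[len(novel_specs) - n_decoys + d] = str(kind)

    low_expr_ids: set[str] = set()
    for j, (code, tid) in enumerate(novel_specs):
        kind = decoy_slots.get(j)
        length = int(rng.integers(300, 1500))
        n_exons = int(rng.integers(2, 5))
        support = (2, 3)
        cc = code
        if kind == "support":
            support = (1, 1)
        elif kind == "class_code":
            cc = "j"
        elif kind == "length":
            length = int(rng.integers(60, 200))
        elif kind == "exon_count":
            n_exons = 1
        elif kind == "orf":
            length = max(length, 500)
        t = _place_transcript(rng, config, tid, f"XLOC_{tid}", cc, length,
                              n_exons, support=support)
        if kind == "orf":
            t.sequence = _coding_seq(rng, t.length, orf_nt=420)
        else:
            t.sequence = _noncoding_seq(rng, t.length)
        sc = tuple(-rng.uniform(0.5, 3.0, size=3))
        if kind == "coding_potential":
            sc = (float(rng.uniform(0.5, 2.0)), sc[1], sc[2])
        if kind == "expression":
            low_expr_ids.add(tid)
        transcripts.append(t)
        seqs[tid] = t.sequence
        scores[tid] = sc
        if kind is not None:
            truth.decoys[tid] = kind
        elif code in ("u", "i"):
            truth.true_lncrna_ids.append(tid)

    # --- planted structure selections --------------------------------------
    clean = list(truth.true_lncrna_ids)
    de_ids = clean[: config.n_de_lnc]
    truth.true_de_ids = {"-2vs-14": list(de_ids), "+1vs-14": list(de_ids)}
    cis_lncs = clean[config.n_de_lnc : config.n_de_lnc + config.n_cis_pairs]

    # cis partner genes are relocated next to their lncRNA (within 100 kb)
    by_id = {t.transcript_id: t for t in transcripts}
    cis_gene_pool = [g for g in gene_ids[config.n_modules * config.module_size :]]
    if len(cis_gene_pool) < len(cis_lncs):
        cis_gene_pool = gene_ids[-len(cis_lncs):]
    for lnc_id, gid in zip(cis_lncs, cis_gene_pool):
        lnc = by_id[lnc_id]
        gene = by_id[gid]
        offset = int(rng.integers(5_000, 80_000))
        start = lnc.interval.end + offset
        moved = _place_transcript(
            rng, config, gid, gid, "=", gene.length, gene.n_exons,
            start=start, chrom=lnc.interval.chrom,
        )
        moved.sequence = gene.sequence
        transcripts[transcripts.index(gene)] = moved
        by_id[gid] = moved
        truth.true_cis_pairs.append((lnc_id, gid))

    for m in range(config.n_modules):
        for gid in gene_ids[m * config.module_size : (m + 1) * config.module_size]:
            truth.module_membership[gid] = m + 1

    # --- expression ---------------------------------------------------------
    samples = _build_design()
    feature_ids = [t.transcript_id for t in transcripts]
    expr = _simulate_expression(
        rng, config, feature_ids, samples, by_id, truth, low_expr_ids
    )

    # --- SNPs ---------------------------------------------------------------
    truth.enriched_feature_set = "true_lncRNAs"
    lnc_ivs = [(tid, by_id[tid].interval) for tid in truth.true_lncrna_ids]
    snps = _simulate_snps(rng, config, lnc_ivs, truth)

    # --- write --------------------------------------------------------------
    paths = {
        "gtf": out_dir / "transcripts.gtf",
        "fasta": out_dir / "transcripts.fa",
        "scores": out_dir / "coding_scores.tsv",
        "counts": out_dir / "counts.tsv",
        "fpkm": out_dir / "fpkm.tsv",
        "design": out_dir / "design.tsv",
        "snps": out_dir / "snps.tsv",
        "truth": out_dir / "truth.json",
    }
    write_gtf(transcripts, paths["gtf"])
    write_fasta(seqs, paths["fasta"])
    with paths["scores"].open("w") as fh:
        fh.write("transcript_id\tcpc_score\tplek_score\tcnci_score\n")
        for tid in feature_ids:
            c, p, n = scores[tid]
            fh.write(f"{tid}\t{c:.4f}\t{p:.4f}\t{n:.4f}\n")
    write_expression_matrix(expr, paths["counts"], paths["fpkm"], paths["design"])
    write_snp_effects(snps, paths["snps"])
    truth.to_json(paths["truth"])
    return paths, truth


def _simulate_expression(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    feature_ids: list[str],
    samples: list[SampleDesign],
    by_id: dict[str, TranscriptModel],
    truth: SimulationTruth,
    low_expr_ids: set[str],
) -> ExpressionMatrix:
    n_f, n_s = len(feature_ids), len(samples)
    stage_idx = {s: i for i, s in enumerate(STAGES)}
    ind_effect = {f"I{k}": e for k, e in zip((1, 2, 3), (0.0, 0.15, -0.15))}
    ln2 = np.log(2.0)

    base = np.exp(rng.normal(np.log(cfg.base_mean), 0.5, size=n_f))
    log_mu = np.log(base)[:, None] + np.array(
        [ind_effect[s.individual] for s in samples]
    )[None, :]

    de_set = set(truth.true_de_ids.get("+1vs-14", []))
    for i, fid in enumerate(feature_ids):
        if fid in de_set:
            for s_i, smp in enumerate(samples):
                if smp.stage in ("-2", "+1"):
                    log_mu[i, s_i] += cfg.de_log2fc * ln2
        if fid in low_expr_ids:
            log_mu[i, :] = np.log(1e-4)

    # planted co-expression modules: a stage-tracking latent shared by the
    # block plus a per-sample shared wiggle
    module_profiles = {}
    for m in range(1, cfg.n_modules + 1):
        prof = np.zeros(len(STAGES))
        prof[(m - 1) % len(STAGES)] = cfg.module_effect
        wiggle = rng.normal(0.0, 0.3, size=n_s)
        module_profiles[m] = (prof, wiggle)
    for i, fid in enumerate(feature_ids):
        m = truth.module_membership.get(fid)
        if m is not None:
            prof, wiggle = module_profiles[m]
            for s_i, smp in enumerate(samples):
                log_mu[i, s_i] += prof[stage_idx[smp.stage]] + wiggle[s_i]

    # planted cis pairs: correlated per-sample latents on the log scale
    for lnc_id, gid in truth.true_cis_pairs:
        z = rng.normal(0.0, 1.0, size=n_s)
        w = rng.normal(0.0, 1.0, size=n_s)
        z_gene = cfg.cis_rho * z + np.sqrt(max(1.0 - cfg.cis_rho**2, 0.0)) * w
        log_mu[feature_ids.index(lnc_id)] += z
        log_mu[feature_ids.index(gid)] += z_gene

    mu = np.exp(log_mu)
    if cfg.nb_dispersion > 0:
        r = 1.0 / cfg.nb_dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    else:
        counts = rng.poisson(mu)
    # expression decoys must fail the FPKM filter and nothing else: at the
    # simulated library depths any stray count yields a sizeable FPKM, so
    # their rows are clamped to zero
    for i, fid in enumerate(feature_ids):
        if fid in low_expr_ids:
            counts[i, :] = 0

    kb = np.array([by_id[f].length for f in feature_ids]) / 1000.0
    totals = counts.sum(axis=0).astype(float)
    fpkm = counts / (kb[:, None] * (totals[None, :] / 1e6))
    return ExpressionMatrix(feature_ids, samples, counts, fpkm)


def _simulate_snps(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    feature_ivs: list[tuple[str, GenomicInterval]],
    truth: SimulationTruth,
    exchangeable: bool = False,
) -> list[SnpRecord]:
    chroms = [c for c, _l in cfg.genome]
    lengths = np.array([l for _c, l in cfg.genome], dtype=float)
    probs = lengths / lengths.sum()

    records = []
    n_bg = cfg.n_snps - (0 if exchangeable else cfg.n_enriched_snps)
    windows = [
        (iv.chrom, max(iv.start - cfg.snp_flank, 1), iv.end + cfg.snp_flank)
        for _f, iv in feature_ivs
    ]

    def in_any_window(chrom: str, pos: int) -> bool:
        return any(c == chrom and lo <= pos <= hi for c, lo, hi in windows)

    i = 0
    while len(records) < n_bg:
        ci = int(rng.choice(len(chroms), p=probs))
        pos = int(rng.integers(1, int(lengths[ci])))
        if not exchangeable and in_any_window(chroms[ci], pos):
            continue   # keep background strictly outside the enriched windows
        beta = float(rng.normal(0.0, cfg.beta_sd_background))
        maf = float(rng.uniform(0.05, 0.5))
        geno = rng.multinomial(985, [(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2])
        records.append(
            SnpRecord(f"SNP{i:06d}", chroms[ci], pos, beta, tuple(int(x) for x in geno))
        )
        i += 1

    if not exchangeable and cfg.n_enriched_snps > 0:
        if not windows:
            raise ValueError("cannot plant enriched SNPs without feature intervals")
        for _ in range(cfg.n_enriched_snps):
            c, lo, hi = windows[int(rng.integers(0, len(windows)))]
            pos = int(rng.integers(lo, hi + 1))
            beta = float(rng.normal(0.0, cfg.beta_sd_enriched))
            maf = float(rng.uniform(0.05, 0.5))
            geno = rng.multinomial(985, [(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2])
            records.append(
                SnpRecord(f"SNP{i:06d}", c, pos, beta, tuple(int(x) for x in geno))
            )
            truth.enriched_snp_ids.append(f"SNP{i:06d}")
            i += 1
    return records


def simulate_null_gwas(
    config: SimulationConfig,
    feature_ivs: list[tuple[str, GenomicInterval]],
    out_path: str | Path,
) -> tuple[Path, SimulationTruth]:
    """SNP table under the exchangeable null: every beta — inside or
    outside the feature set — drawn from Normal(0, beta_sd_background)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = SimulationTruth(exchangeable_null=True)
    snps = _simulate_snps(rng, config, feature_ivs, truth, exchangeable=True)
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    write_snp_effects(snps, out_path)
    return out_path, truth
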