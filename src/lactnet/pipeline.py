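"""Orchestration of the full analysis chain with one config and one seed.

Stage order: simulate -> discover -> de -> cluster -> enrich -> targets ->
modules.  A single global seed is split deterministically into per-stage
seeds (so toggling one stage never perturbs another's randomness), every
stage writes a manifest with the SHA-256 of each input it consumed, and a
failed stage aborts everything downstream while keeping partial outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import coexpression as coex
from . import core_io, synthetic_data
from .diff_expression import DEOptions, run_de_contrasts
from .gwas_enrichment import FeatureSet, permutation_enrichment, snp_qc
from .lncrna_discovery import DiscoveryParams, run_discovery_cascade
from .pattern_clustering import cluster_patterns, gap_statistic_select_k, stage_profiles
from .target_prediction import cis_candidates, predict_targets

logger = logging.getLogger(__name__)

STAGE_ORDER = ("simulate", "discover", "de", "cluster", "enrich", "targets", "modules")


class PipelineError(RuntimeError):
    """A stage failed; downstream stages were not run."""

    def __init__(self, stage: str, cause: BaseException) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seeds(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(STAGE_ORDER))
    return {
        stage: int(child.generate_state(1)[0])
        for stage, child in zip(STAGE_ORDER, children)
    }


def _write_manifest(stage_dir: Path, inputs: dict[str, Path], params: dict, seed: int) -> None:
    manifest = {
        "stage": stage_dir.name,
        "seed": seed,
        "params": params,
        "inputs": {k: {"path": str(p), "sha256": _sha256(Path(p))} for k, p in inputs.items()},
    }
    (stage_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))


def default_config() -> dict:
    return {
        "stages": list(STAGE_ORDER),
        "inputs": {},
        "simulate": dataclasses.asdict(synthetic_data.SimulationConfig()),
        "discover": {},
        "de": {"alpha": 0.05},
        "cluster": {"k": None, "k_max": 8, "B": 20},
        "enrich": {"flank": 10_000, "n_perm": 1000, "p_mode": "ge", "qc": True},
        "targets": {"window": 100_000, "alpha": 0.05},
        "modules": {"min_module_size": 5, "power": None, "max_features": 150},
    }


def run_pipeline(config: dict, out_dir: str | Path, seed: int) -> dict:
    """Run the enabled stages in dependency order under ``out_dir``.

    Returns a summary dict (also written to ``summary.json``).
    """
    cfg = default_config()
    for key, val in (config or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(seed)
    enabled = [s for s in STAGE_ORDER if s in cfg["stages"]]
    state: dict = {"paths": dict(cfg.get("inputs", {})), "summary": {"seed": seed}}

    runners = {
        "simulate": _stage_simulate,
        "discover": _stage_discover,
        "de": _stage_de,
        "cluster": _stage_cluster,
        "enrich": _stage_enrich,
        "targets": _stage_targets,
        "modules": _stage_modules,
    }
    for stage in enabled:
        stage_dir = out_dir / stage
        stage_dir.mkdir(exist_ok=True)
        logger.info("running stage %s", stage)
        try:
            runners[stage](cfg[stage], stage_dir, seeds[stage], state)
        except Exception as exc:   # noqa: BLE001 - re-raised with stage context
            raise PipelineError(stage, exc) from exc
    (out_dir / "summary.json").write_text(
        json.dumps(state["summary"], indent=1, sort_keys=True, default=str)
    )
    return state["summary"]


# ---------------------------------------------------------------------------
# stage implementations


def _load_expression(paths: dict) -> core_io.ExpressionMatrix:
    return core_io.read_expression_matrix(paths["counts"], paths["fpkm"], paths["design"])


def _stage_simulate(params: dict, stage_dir: Path, seed: int, state: dict) -> None:
    sim_cfg = synthetic_data.SimulationConfig(**{**params, "seed": seed})
    paths, truth = synthetic_data.simulate_dataset(sim_cfg, stage_dir)
    state["paths"].update({k: str(p) for k, p in paths.items()})
    state["truth"] = truth
    state["summary"]["simulate"] = {
        "n_transcripts": sim_cfg.n_transcripts,
        "n_true_lncrnas": len(truth.true_lncrna_ids),
        "n_snps": sim_cfg.n_snps,
    }
    _write_manifest(stage_dir, {}, dataclasses.asdict(sim_cfg), seed)


def _stage_discover(params: dict, stage_dir: Path, seed: int, state: dict) -> None:
    paths = state["paths"]
    transcripts = core_io.read_gtf(paths["gtf"])
    seqs = core_io.read_fasta(paths["fasta"])
    for t in transcripts:
        t.sequence = seqs.get(t.transcript_id)
    expr = _load_expression(paths)
    scores = core_io.read_coding_scores(paths["scores"])
    retained, report = run_discovery_cascade(
        transcripts, expr, scores, DiscoveryParams(**params)
    )
    by_id = {t.transcript_id: t for t in transcripts}
    bed = stage_dir / "lncrnas.bed"
    core_io.write_bed([(tid, by_id[tid].interval) for tid in retained], bed)
    report.to_frame().to_csv(stage_dir / "report.tsv", sep="\t", index=False)
    known = [tid for tid, st in report.status.items() if st == "known"]
    core_io.write_bed(
        [(tid, by_id[tid].interval) for tid in known], stage_dir / "known_genes.bed"
    )
    state["paths"]["lncrna_bed"] = str(bed)
    state["paths"]["known_bed"] = str(stage_dir / "known_genes.bed")
    state["lncrna_ids"] = retained
    state["summary"]["discover"] = {"n_retained": len(retained), "counts": report.counts}
    _write_manifest(
        stage_dir,
        {k: Path(paths[k]) for k in ("gtf", "fasta", "scores", "counts", "fpkm", "design")},
        params, seed,
    )


def _stage_de(params: dict, stage_dir: Path, seed: int, state: dict) -> None:
    paths = state["paths"]
    expr = _load_expression(paths)
    if "lncrna_ids" in state:
        ids = state["lncrna_ids"]
    elif "lncrna_list" in paths:
        ids = [l.strip() for l in Path(paths["lncrna_list"]).read_text().splitlines() if l.strip()]
    else:
        ids = expr.feature_ids
    sub = expr.subset([f for f in ids if f in expr])
    table = run_de_contrasts(sub, DEOptions(alpha=params.get("alpha", 0.05)))
    table.to_csv(stage_dir / "de_results.tsv", sep="\t", index=False, float_format="%.6g")
    summary = (
        table[table.significant]
        .groupby(["contrast", "direction"], observed=True)
        .size()
        .unstack(fill_value=0)
    )
    summary.to_csv(stage_dir / "summary.tsv", sep="\t")
    de_ids = sorted(table.loc[table.significant, "feature_id"].unique())
    (stage_dir / "de_ids.txt").write_text("".join(f"{i}\n" for i in de_ids))
    state["de_table"] = table
    state["de_ids"] = de_ids
    state["paths"]["de_ids"] = str(stage_dir / "de_ids.txt")
    state["summary"]["de"] = {
        "n_de_features": len(de_ids),
        "dispersion": table.attrs.get("dispersion"),
    }
    _write_manifest(
        stage_dir, {k: Path(paths[k]) for k in ("counts", "fpkm", "design")}, params, seed
    )


def _stage_cluster(params: dict, stage_dir: Path, seed: int, state: dict) -> None:
    paths = state["paths"]
    expr = _load_expression(paths)
    ids = state.get("de_ids") or state.get("lncrna_ids") or expr.feature_ids
    ids = [f for f in ids if f in expr]
    profiles = stage_profiles(expr, ids)
    if profiles.shape[0] < 3:
        state["summary"]["cluster"] = {"skipped": "fewer than 3 usable profiles"}
        _write_manifest(stage_dir, {k: Path(paths[k]) for k in ("fpkm", "design")}, params, seed)
        return
    k = params.get("k")
    if k is None:
        k_max = min(params.get("k_max", 8), profiles.shape[0] - 1)
        k, curve = gap_statistic_select_k(
            profiles.to_numpy(), range(1, k_max + 1), B=params.get("B", 20), seed=seed
        )
        curve.to_csv(stage_dir / "gap_curve.tsv", sep="\t", index=False, float_format="%.6g")
    assignment = cluster_patterns(profiles, k, seed=seed)
    pd.DataFrame(
        {"feature_id": list(assignment.labels), "cluster": list(assignment.labels.values())}
    ).to_csv(stage_dir / "clusters.tsv", sep="\t", index=False)
    state["summary"]["cluster"] = {"k": k, "n_features": profiles.shape[0]}
    _write_manifest(stage_dir, {k2: Path(paths[k2]) for k2 in ("fpkm", "design")}, params, seed)


def _stage_enrich(params: dict, stage_dir: Path, seed: int, state: dict) -> None:
    paths = state["paths"]
    snps = core_io.read_snp_effects(paths["snps"])
    if params.get("qc", True) and all(s.genotype_counts is not None for s in snps):
        snps, _qc = snp_qc(snps)
    features = core_io.read_bed(paths["lncrna_bed"])
    fs = FeatureSet("lncRNAs", tuple(features), flank=params.get("flank", 10_000))
    res = permutation_enrichment(
        snps, fs, n_perm=params.get("n_perm", 1000), seed=seed,
        p_mode=params.get("p_mode", "ge"),
    )
    pd.DataFrame(
        [{
            "feature_set": res.feature_set, "m_g": res.m_g, "t_obs": res.t_obs,
            "p_emp": res.p_emp, "fold": res.fold, "n_perm": res.n_perm, "seed": res.seed,
        }]
    ).to_csv(stage_dir / "enrichment.tsv", sep="\t", index=False, float_format="%.6g")
    pd.DataFrame({"null_sum": res.null_sums}).to_csv(
        stage_dir / "null_sums.tsv", sep="\t", index=False, float_format="%.6g"
    )
    state["summary"]["enrich"] = {"m_g": res.m_g, "p_emp": res.p_emp, "fold": res.fold}
    _write_manifest(
        stage_dir, {"snps": Path(paths["snps"]), "lncrna_bed": Path(paths["lncrna_bed"])},
        params, seed,
    )


def _stage_targets(params: dict, stage_dir: Path, seed: int, state: dict) -> None:
    paths = state["paths"]
    expr = _load_expression(paths)
    lncs = core_io.read_bed(paths["lncrna_bed"])
    genes = core_io.read_bed(paths["known_bed"])
    cands = cis_candidates(lncs, genes, window=params.get("window", 100_000))
    pairs = predict_targets(cands, expr, alpha=params.get("alpha", 0.05))
    pd.DataFrame([dataclasses.asdict(p) for p in pairs]).to_csv(
        stage_dir / "targets.tsv", sep="\t", index=False, float_format="%.6g"
    )
    n_sig = sum(p.significant for p in pairs)
    state["summary"]["targets"] = {"n_candidates": len(cands), "n_significant": n_sig}
    _write_manifest(
        stage_dir,
        {"lncrna_bed": Path(paths["lncrna_bed"]), "known_bed": Path(paths["known_bed"]),
         "fpkm": Path(paths["fpkm"])},
        params, seed,
    )


def _stage_modules(params: dict, stage_dir: Path, seed: int, state: dict) -> None:
    paths = state["paths"]
    expr = _load_expression(paths)
    genes = [g for g, _iv in core_io.read_bed(paths["known_bed"])] if "known_bed" in paths \
        else expr.feature_ids
    genes = [g for g in genes if g in expr]
    max_features = params.get("max_features", 150)
    if len(genes) > max_features:
        genes = genes[:max_features]
    result = coex.run_coexpression(
        expr, genes, min_module_size=params.get("min_module_size", 5),
        power=params.get("power"),
    )
    pd.DataFrame({"feature_id": result.feature_ids, "module": result.labels}).to_csv(
        stage_dir / "modules.tsv", sep="\t", index=False
    )
    result.eigengenes.rename_axis("module").to_csv(
        stage_dir / "eigengenes.tsv", sep="\t", float_format="%.6g"
    )
    result.associations.to_csv(
        stage_dir / "associations.tsv", sep="\t", index=False, float_format="%.6g"
    )
    n_modules = len(set(result.labels) - {0})
    sig = result.associations[result.associations.p < 0.05] if len(result.associations) else []
    state["summary"]["modules"] = {
        "power": result.power, "n_modules": n_modules,
        "n_significant_associations": len(sig),
    }
    _write_manifest(
        stage_dir, {k: Path(paths[k]) for k in ("fpkm", "design")}, params, seed
    )
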