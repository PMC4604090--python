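"""End-to-end orchestration: sim -> pileup -> quant -> snp -> ase
(-> linkage placement), with assembly statistics, a run manifest and the
stage-by-stage filter funnel.

The YAML config is the single source of truth; CLI flags override it and
the effective config is embedded in the manifest so a run can be reproduced
exactly. Every filter logs its in/out counts so the SNP funnel
(stage-1 diagnostic SNPs -> stage-2 hybrid-informative SNPs) is always
inspectable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import ase as ase_mod
from . import linkmap as linkmap_mod
from . import pileup as pileup_mod
from . import quant as quant_mod
from . import sim as sim_mod
from . import snp as snp_mod
from .sim import SimConfig
from .snp import PipelineThresholds

logger = logging.getLogger(__name__)


class WorkflowError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class AssemblyStats:
    n_contigs: int
    min_length: int
    max_length: int
    mean_length: float
    total_length: int
    n50: int


def assembly_stats(contigs: Mapping[str, str] | list[int]) -> AssemblyStats:
    """Descriptive assembly statistics including N50.

    N50 is the largest length L such that contigs of length >= L together
    cover at least half of the total assembly length (descending-length
    cumulative sum).
    """
    lengths = ([len(s) for s in contigs.values()]
               if isinstance(contigs, Mapping) else list(contigs))
    if not lengths:
        raise ValueError("assembly_stats requires at least one contig")
    arr = np.sort(np.asarray(lengths))[::-1]
    total = int(arr.sum())
    cum = np.cumsum(arr)
    n50 = int(arr[np.searchsorted(cum, total / 2)])
    return AssemblyStats(len(arr), int(arr.min()), int(arr.max()),
                         float(arr.mean()), total, n50)


@dataclass
class RunManifest:
    config: dict[str, Any]
    inputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    outputs: dict[str, str] = field(default_factory=dict)
    summary: dict[str, Any] = field(default_factory=dict)
    seed: int | None = None
    version: str = ""
    started: str = ""
    finished: str = ""

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                         sort_keys=True) + "\n")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str):
    """Wrap a stage so failures carry the stage name."""
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except WorkflowError:
                raise
            except Exception as exc:
                raise WorkflowError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


DEFAULT_CONFIG: dict[str, Any] = {
    "sim": None,          # SimConfig fields, or None to use existing inputs
    "inputs": {           # used when sim is None
        "reference": None,
        "samples": {},    # role -> SAM path
    },
    "thresholds": {},     # PipelineThresholds overrides
    "linkmap": None,      # {marker_map, genotypes, candidates} TSV paths
    "outdir": "cavecall_out",
    "seed": 0,
}


def load_config(path: str | Path | None,
                overrides: Mapping[str, Any] | None = None) -> dict[str, Any]:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        for k, v in user.items():
            if isinstance(v, dict) and isinstance(cfg.get(k), dict):
                cfg[k].update(v)
            else:
                cfg[k] = v
    for k, v in (overrides or {}).items():
        if v is not None:
            cfg[k] = v
    return cfg


def run_pipeline(config: Mapping[str, Any]) -> RunManifest:
    """Execute every configured stage and write all artifacts.

    Returns the manifest; its ``summary`` carries the funnel counts
    (stage-1/stage-2 SNP and contig totals, means, ASE verdict counts) and
    the assembly statistics.
    """
    cfg = dict(config)
    outdir = Path(cfg.get("outdir", "cavecall_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg, seed=cfg.get("seed"),
                           version=_package_version(),
                           started=time.strftime("%Y-%m-%dT%H:%M:%S"))
    summary: dict[str, Any] = {}

    # --- sim (optional) ----------------------------------------------------
    if cfg.get("sim") is not None:
        sim_cfg = SimConfig(**{**cfg["sim"], "seed": cfg.get("seed", 0)})
        truth, paths = _run_sim(sim_cfg, outdir / "sim")
        reference = truth.reference
        sample_paths = {s: paths[f"{s}_sam"] for s in sim_mod.SAMPLES
                        if f"{s}_sam" in paths}
        manifest.outputs.update({k: str(v) for k, v in paths.items()})
    else:
        inputs = cfg.get("inputs") or {}
        ref_path = inputs.get("reference")
        if not ref_path:
            raise WorkflowError("stage 'inputs' failed: no reference FASTA "
                                "configured and sim disabled")
        reference = pileup_mod.read_reference_fasta(ref_path)
        sample_paths = dict(inputs.get("samples") or {})
        manifest.inputs[str(ref_path)] = _sha256(ref_path)
        for p in sample_paths.values():
            manifest.inputs[str(p)] = _sha256(p)

    stats = assembly_stats(reference)
    summary["assembly"] = dataclasses.asdict(stats)

    thresholds = PipelineThresholds(**(cfg.get("thresholds") or {}))

    # --- pileup ------------------------------------------------------------
    pile = _run_pileup(sample_paths, reference)

    # --- quant -------------------------------------------------------------
    quant_table = _run_quant(sample_paths, reference)
    quant_path = outdir / "quant.tsv"
    quant_mod.write_quant_tsv(quant_table, quant_path)
    manifest.outputs["quant"] = str(quant_path)

    # --- snp ---------------------------------------------------------------
    stage1 = _run_snp(pile, thresholds)
    s1 = snp_mod.summarize_snps(stage1)
    summary["snps_stage1"] = {"n_snps": s1.n_snps, "n_contigs": s1.n_contigs,
                              "mean_snps_per_contig": s1.mean_snps_per_contig}
    hybrid_present = "hybrid" in sample_paths
    if hybrid_present:
        stage2 = snp_mod.filter_hybrid_informative(stage1, thresholds)
    else:
        logger.warning("no hybrid sample configured: hybrid-informative "
                       "filter and ASE skipped")
        stage2 = []
    s2 = snp_mod.summarize_snps(stage2)
    summary["snps_stage2"] = {"n_snps": s2.n_snps, "n_contigs": s2.n_contigs,
                              "mean_snps_per_contig": s2.mean_snps_per_contig}

    vcf_path = outdir / "diagnostic_snps.vcf"
    informative_ids = {(s.contig_id, s.pos) for s in stage2}
    merged = [dataclasses.replace(
        s, hybrid_informative=(s.contig_id, s.pos) in informative_ids)
        for s in stage1]
    snp_mod.write_vcf(merged, reference, vcf_path)
    snp_mod.write_summary_tsv(s1, s2, outdir / "snp_summary.tsv")
    manifest.outputs["vcf"] = str(vcf_path)
    manifest.outputs["snp_summary"] = str(outdir / "snp_summary.tsv")

    # --- ase ---------------------------------------------------------------
    if hybrid_present:
        calls = _run_ase(merged, reference, thresholds)
        ase_path = outdir / "ase_calls.tsv"
        ase_mod.write_ase_tsv(calls, ase_path)
        manifest.outputs["ase"] = str(ase_path)
        verdicts: dict[str, int] = {}
        for c in calls:
            verdicts[c.verdict] = verdicts.get(c.verdict, 0) + 1
        summary["ase_verdicts"] = verdicts

    # --- linkmap (optional) ------------------------------------------------
    lm = cfg.get("linkmap")
    if lm:
        results = _run_linkmap(lm)
        place_path = outdir / "placement.tsv"
        linkmap_mod.write_placement_tsv(results, place_path)
        manifest.outputs["placement"] = str(place_path)
        summary["placements"] = {
            r.candidate_id: (r.assigned_linkage_group or
                             ("ambiguous" if r.ambiguous else "unplaced"))
            for r in results}

    manifest.summary = summary
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    summary_path = outdir / "summary.json"
    Path(summary_path).write_text(json.dumps(summary, indent=2,
                                             sort_keys=True) + "\n")
    manifest.outputs["summary"] = str(summary_path)
    manifest.write(outdir / "manifest.json")
    return manifest


@_stage("sim")
def _run_sim(sim_cfg: SimConfig, outdir: Path):
    return sim_mod.simulate_experiment(sim_cfg, outdir)


@_stage("pileup")
def _run_pileup(sample_paths, reference):
    return pileup_mod.build_pileup(sample_paths, reference)


@_stage("quant")
def _run_quant(sample_paths, reference):
    return quant_mod.quantify(sample_paths, reference)


@_stage("snp")
def _run_snp(pile, thresholds):
    return snp_mod.discover_diagnostic_snps(pile, thresholds)


@_stage("ase")
def _run_ase(snps, reference, thresholds):
    unique_ids = ase_mod.uniqueness_filter(reference, thresholds)
    return ase_mod.call_ase(snps, unique_ids, thresholds)


@_stage("linkmap")
def _run_linkmap(lm_cfg: Mapping[str, str]):
    mmap = linkmap_mod.read_marker_map(lm_cfg["marker_map"])
    matrix = linkmap_mod.read_genotype_matrix(lm_cfg["genotypes"], mmap)
    candidates = linkmap_mod.read_candidate_genotypes(lm_cfg["candidates"])
    results = []
    for cid, series in candidates.items():
        scores = linkmap_mod.score_concordance(series, matrix)
        n_geno = int((series.isin(linkmap_mod.CODES)).sum())
        results.append(linkmap_mod.place_candidate(
            cid, scores, mmap, n_genotyped=n_geno))
    return results


def _package_version() -> str:
    try:
        from importlib.metadata import version

        return version("cavecall")
    except Exception:
        return "unknown"
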