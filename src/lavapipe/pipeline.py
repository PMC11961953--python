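"""End-to-end orchestration: simulate -> build-track -> quantify ->
harmonize -> de -> signatures, with a JSON manifest of seeds, file checksums,
and per-stage feature/sample counts.

Re-running with the same config and seed reproduces byte-identical outputs
(the manifest records no timestamps)."""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .matrix import CountMatrix
from .quantify import (
    assign_multimappers,
    count_genes,
    count_te,
    dedup_alignments,
    read_alignment_tsv,
    read_exon_bed,
    rpm,
    tpm,
    write_alignment_tsv,
    write_exon_bed,
)
from .repeats import (
    integrate_copies,
    parse_repeatmasker_out,
    select_full_length,
    write_repeatmasker_out,
)
from .signatures import loading_set_union, pca, top_loading_features
from .simulate import (
    SimulationConfig,
    generate_toy_genome,
    simulate_alignments,
    simulate_count_matrix,
    simulate_ortholog_map,
    write_fasta,
)
from .xspecies import (
    clade_specific_de,
    detect_outliers,
    filter_batch_genes,
    intersect_orthologs,
    merge_individuals,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)

STAGES = ["simulate", "build_track", "quantify", "harmonize", "de", "signatures"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    """Declarative pipeline configuration (YAML-loadable).

    Thresholds default to the study's: full-length selection at
    repStart < 100 / repEnd > 1200, DE at FDR < 0.05 and |log2FC| > 1,
    outlier cut at dendrogram height 0.8, top-10 signed loadings on two
    components."""

    out_dir: str = "pipeline_out"
    seed: int = 0
    simulation: dict = field(default_factory=dict)
    max_rep_start: int = 100
    min_rep_end: int = 1200
    fdr: float = 0.05
    lfc: float = 1.0
    height: float = 0.8
    top_k: int = 10
    n_components: int = 2
    strandedness: str = "reverse"
    target_clade: str = "small_ape"
    stages: dict = field(default_factory=dict)  # stage name -> bool toggle
    batch_filter: bool = True

    def validate(self) -> None:
        if not 0 < self.fdr < 1:
            raise ValueError(f"fdr must lie in (0, 1), got {self.fdr}")
        if self.lfc < 0 or self.height < 0 or self.top_k < 1 or self.n_components < 1:
            raise ValueError("thresholds out of range")
        if self.max_rep_start < 0 or self.min_rep_end < 0:
            raise ValueError("consensus thresholds must be >= 0")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage toggles: {sorted(unknown)}")

    def enabled(self, stage: str) -> bool:
        return bool(self.stages.get(stage, True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def sim_config(self) -> SimulationConfig:
        sim = dict(self.simulation)
        sim.setdefault("seed", self.seed)
        sim.setdefault("strandedness", self.strandedness)
        sim.setdefault("target_clade", self.target_clade)
        return SimulationConfig.from_dict(sim)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order and return the run manifest.

    Outputs land under ``out_dir/<stage>/``; the manifest (also written to
    ``out_dir/manifest.json``) records the package version, seed, per-stage
    record counts, and a sha256 checksum for every file produced.  A failing
    stage moves its partial outputs under ``out_dir/failed/`` and raises
    :class:`PipelineError`.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "lavapipe",
        "version": __version__,
        "seed": config.seed,
        "stages": {},
    }

    def run_stage(name, fn):
        if not config.enabled(name):
            manifest["stages"][name] = {"enabled": False}
            return
        stage_dir = out / name
        stage_dir.mkdir(exist_ok=True)
        try:
            info = fn(stage_dir)
        except Exception as exc:
            failed = out / "failed"
            failed.mkdir(exist_ok=True)
            target = failed / name
            if target.exists():
                shutil.rmtree(target)
            shutil.move(str(stage_dir), str(target))
            raise PipelineError(name, exc) from exc
        info["enabled"] = True
        info["files"] = {
            str(p.relative_to(out)): _sha256(p) for p in sorted(stage_dir.glob("*"))
        }
        manifest["stages"][name] = info
        logger.info("stage %s: %s", name, {k: v for k, v in info.items() if k != "files"})

    def stage_simulate(d: Path) -> dict:
        sim = config.sim_config()
        toy = generate_toy_genome(sim)
        write_fasta(toy.genome, d / "genome.fa")
        write_exon_bed(toy.exons, d / "exons.bed")
        write_repeatmasker_out(toy.base_track, d / "base_repeats.out")
        write_repeatmasker_out(toy.consensus_hits, d / "consensus_hits.out")
        records, aln_truth = simulate_alignments(toy, sim)
        write_alignment_tsv(records, d / "alignments.tsv")
        cm, meta, truth = simulate_count_matrix(sim)
        cm.to_tsv(d / "xspecies_counts.tsv")
        meta.to_csv(d / "metadata.tsv", sep="\t", index=False)
        orth = simulate_ortholog_map(sim, list(cm.features), truth)
        orth.to_csv(d / "orthologs.tsv", sep="\t", index=False)
        return {
            "genes_annotated": int(toy.exons["gene"].nunique()),
            "te_copies_planted": len(toy.consensus_hits),
            "alignment_records": int(len(records)),
            "xspecies_genes": int(cm.shape[0]),
            "xspecies_samples": int(cm.shape[1]),
        }

    def stage_build_track(d: Path) -> dict:
        sim_dir = out / "simulate"
        base = parse_repeatmasker_out(sim_dir / "base_repeats.out")
        hits = parse_repeatmasker_out(sim_dir / "consensus_hits.out")
        selected = select_full_length(hits, config.max_rep_start, config.min_rep_end)
        merged = integrate_copies(base, selected)
        write_repeatmasker_out(merged, d / "merged_track.out")
        merged.to_bed(d / "merged_track.bed")
        return {
            "consensus_hits": len(hits),
            "full_length_selected": len(selected),
            "base_copies": len(base),
            "merged_copies": len(merged),
        }

    def stage_quantify(d: Path) -> dict:
        sim_dir = out / "simulate"
        records = read_alignment_tsv(sim_dir / "alignments.tsv")
        n_in = len(records)
        records = dedup_alignments(records)
        n_dedup = len(records)
        records = assign_multimappers(records, seed=config.seed)
        write_alignment_tsv(records, d / "alignments.dedup.tsv")
        exons = read_exon_bed(sim_dir / "exons.bed")
        gene_cm = count_genes(records, exons)
        gene_cm.to_tsv(d / "gene_counts.tsv")
        tpm(gene_cm).to_csv(d / "gene_tpm.tsv", sep="\t", index_label="feature")
        track = parse_repeatmasker_out(out / "build_track" / "merged_track.out")
        te_cm = count_te(records, track, library_strandedness=config.strandedness)
        te_cm.to_tsv(d / "te_counts.tsv")
        rpm(te_cm).to_csv(d / "te_rpm.tsv", sep="\t", index_label="feature")
        return {
            "records_in": n_in,
            "records_after_dedup": n_dedup,
            "gene_features": int(gene_cm.shape[0]),
            "te_families": int(te_cm.shape[0]),
        }

    def stage_harmonize(d: Path) -> dict:
        sim_dir = out / "simulate"
        cm = CountMatrix.from_tsv(sim_dir / "xspecies_counts.tsv")
        meta = pd.read_csv(sim_dir / "metadata.tsv", sep="\t")
        orth = pd.read_csv(sim_dir / "orthologs.tsv", sep="\t")
        genomes = sorted(orth["genome"].unique())
        kept = intersect_orthologs(orth, genomes, require_coding=True)
        cm = cm.subset_features(kept)
        n_ortholog = cm.shape[0]
        cm, meta = merge_individuals(cm, meta)
        expr = cm.counts.div(cm.counts.sum(axis=0), axis=1) * 1e6
        outliers = detect_outliers(expr, height_max=config.height)
        kept_samples = [s for s in cm.samples if s not in outliers]
        cm = cm.subset_samples(kept_samples)
        meta = meta[meta["sample"].isin(kept_samples)]
        removed: set = set()
        if config.batch_filter:
            removed, cm = filter_batch_genes(cm, meta, fdr_max=config.fdr)
        cm.to_tsv(d / "harmonized_counts.tsv")
        meta.to_csv(d / "harmonized_metadata.tsv", sep="\t", index=False)
        pd.Series(sorted(removed), name="feature").to_csv(
            d / "batch_genes_removed.tsv", sep="\t", index=False
        )
        return {
            "genes_after_ortholog_intersection": int(n_ortholog),
            "outlier_samples": sorted(outliers),
            "batch_genes_removed": len(removed),
            "genes_final": int(cm.shape[0]),
            "individuals_final": int(cm.shape[1]),
        }

    def stage_de(d: Path) -> dict:
        cm = CountMatrix.from_tsv(out / "harmonize" / "harmonized_counts.tsv")
        meta = pd.read_csv(out / "harmonize" / "harmonized_metadata.tsv", sep="\t")
        table = clade_specific_de(
            cm, meta, config.target_clade, fdr_max=config.fdr, lfc_min=config.lfc
        )
        table.to_csv(d / "clade_de.tsv", sep="\t", index=False, float_format="%.6g")
        calls = table["call"].value_counts()
        return {
            "genes_tested": int(len(table)),
            "up": int(calls.get("up", 0)),
            "down": int(calls.get("down", 0)),
        }

    def stage_signatures(d: Path) -> dict:
        cm = CountMatrix.from_tsv(out / "harmonize" / "harmonized_counts.tsv")
        expr = cm.counts.div(cm.counts.sum(axis=0), axis=1) * 1e6
        res = pca(expr, transform="log2p1")
        res.scores.iloc[:, : config.n_components].to_csv(
            d / "gene_pca_scores.tsv", sep="\t", index_label="sample", float_format="%.6g"
        )
        res.loadings.iloc[:, : config.n_components].to_csv(
            d / "gene_pca_loadings.tsv", sep="\t", index_label="feature", float_format="%.6g"
        )
        te_rpm = pd.read_csv(out / "quantify" / "te_rpm.tsv", sep="\t", index_col="feature")
        info: dict = {
            "gene_pc1_variance_ratio": float(res.explained_variance_ratio[0]),
        }
        lists = []
        n_te_comp = min(config.n_components, min(te_rpm.shape) - 1)
        if te_rpm.shape[0] >= 2 and n_te_comp >= 1:
            te_res = pca(te_rpm, transform="log2p1")
            k = min(config.top_k, te_rpm.shape[0])
            for comp in range(1, n_te_comp + 1):
                for mode in ("signed_top", "signed_bottom"):
                    lists.append(top_loading_features(te_res, comp, k, mode))
            union, overlap = loading_set_union(lists)
            info["te_signature_size"] = len(union)
            info["te_signature_overlap"] = overlap
            payload = {
                "lists": lists,
                "union": sorted(union),
                "overlap": overlap,
            }
            with open(d / "te_signatures.json", "w") as fh:
                json.dump(payload, fh, indent=2, sort_keys=True)
        return info

    fns = {
        "simulate": stage_simulate,
        "build_track": stage_build_track,
        "quantify": stage_quantify,
        "harmonize": stage_harmonize,
        "de": stage_de,
        "signatures": stage_signatures,
    }
    for name in STAGES:
        run_stage(name, fns[name])

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
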