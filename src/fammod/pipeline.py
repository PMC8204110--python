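"""End-to-end pipeline: QC -> presence matrix -> modules -> breadth.

Each stage writes its tables atomically (``.partial`` then rename) and the
run closes with a manifest recording the config hash, input checksums and
per-stage counts.  The analysis path is fully deterministic, so two runs on
identical inputs produce byte-identical tables and manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from pathlib import Path

import pandas as pd

from .breadth import BreadthScorer
from .config import PipelineConfig
from .io import read_alignment, read_tsv, sha256_file, write_text, write_tsv
from .matrix import PresenceMatrix, build_matrix
from .modules import (
    FamilyModuleDetector,
    cluster_genomes,
    modules_table,
    summarize_modules,
)
from .qc import run_qc

logger = logging.getLogger("fammod")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name in its message."""


def _require(path: str, what: str, stage: str) -> Path:
    p = Path(path)
    if not path or not p.exists():
        raise PipelineError(f"stage {stage}: missing {what} file: {path!r}")
    return p


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute qc -> matrix -> modules -> breadth; returns the manifest dict.

    Per-stage outputs land in ``config.out_dir``:
    qc_report.tsv, matrix.tsv, modules.tsv, family_modules.tsv,
    residual_clusters.tsv, genome_dendrogram.nwk, matrix_ordered.tsv,
    breadth.tsv (when bacterial inputs are configured) and manifest.json.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_text(),
        "config_sha256": hashlib.sha256(config.to_text().encode()).hexdigest(),
        "inputs": {},
        "counts": {},
    }

    # ---- stage: qc --------------------------------------------------------
    stage = "qc"
    logger.info("stage %s", stage)
    scg_p = _require(config.scg_counts, "SCG table", stage)
    ani_p = _require(config.ani, "ANI table", stage)
    aln_p = _require(config.alignment, "alignment", stage)
    rp_p = _require(config.rp_scaffolds, "RP scaffold table", stage)
    meta_p = _require(config.meta, "genome metadata", stage)
    for name, p in [
        ("scg_counts", scg_p), ("ani", ani_p), ("alignment", aln_p),
        ("rp_scaffolds", rp_p), ("meta", meta_p),
    ]:
        manifest["inputs"][name] = sha256_file(p)

    meta = read_tsv(meta_p)
    try:
        scg = read_tsv(scg_p)
        ani = read_tsv(ani_p, index_col=0)
        alignment = read_alignment(aln_p)
        rp = read_tsv(rp_p)
        qc_report = run_qc(
            scg, ani, alignment, rp,
            thresholds={
                "min_scgs": config.min_scgs,
                "max_duplicated": config.max_scg_duplicated,
                "min_completeness": config.min_completeness,
                "max_contamination": config.max_contamination,
                "min_aln_coverage": config.min_aln_coverage,
                "ani": config.ani_threshold,
            },
        )
    except PipelineError:
        raise
    except Exception as exc:  # annotate with the failing stage
        raise PipelineError(f"stage {stage} failed: {exc}") from exc
    write_tsv(qc_report, out / "qc_report.tsv", index=True)
    survivors = list(qc_report.index[qc_report["qc_pass"]])
    representatives = sorted(qc_report.index[qc_report["is_representative"]])
    manifest["counts"]["genomes_in"] = int(len(qc_report))
    manifest["counts"]["genomes_pass_qc"] = int(len(survivors))
    manifest["counts"]["ani_clusters"] = int(qc_report["cluster_id"].dropna().nunique())
    manifest["counts"]["representatives"] = int(len(representatives))

    # ---- stage: matrix ----------------------------------------------------
    stage = "matrix"
    logger.info("stage %s", stage)
    hits_p = _require(config.hits, "hit table", stage)
    manifest["inputs"]["hits"] = sha256_file(hits_p)
    try:
        hits = read_tsv(hits_p)
        sub_map = None
        if config.subfamily_map:
            sub_p = _require(config.subfamily_map, "subfamily map", stage)
            manifest["inputs"]["subfamily_map"] = sha256_file(sub_p)
            sub_map = read_tsv(sub_p)
        pm = build_matrix(
            hits,
            representatives,
            threshold=config.evalue,
            subfamily_map=sub_map,
            on_unknown_genome="drop",
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage} failed: {exc}") from exc
    pm.to_tsv(out / "matrix.tsv")
    manifest["counts"]["families"] = int(pm.shape[0])
    manifest["counts"]["matrix_genomes"] = int(pm.shape[1])

    # ---- stage: modules ---------------------------------------------------
    stage = "modules"
    logger.info("stage %s", stage)
    try:
        det = FamilyModuleDetector(
            cutoff=config.cutoff,
            min_size=config.min_module_size,
            linkage=config.linkage,
            purity=config.purity,
        ).fit(pm, meta)
        newick, ordered = cluster_genomes(pm, linkage=config.linkage)
    except Exception as exc:
        raise PipelineError(f"stage {stage} failed: {exc}") from exc
    mtable = modules_table(det.modules_)
    write_tsv(mtable, out / "modules.tsv")
    fam_map = det.labels_.rename_axis("family_id").reset_index()
    write_tsv(fam_map, out / "family_modules.tsv")
    write_tsv(det.residuals_, out / "residual_clusters.tsv")
    write_text(newick + "\n", out / "genome_dendrogram.nwk")
    ordered.index.name = "family_id"
    write_tsv(ordered, out / "matrix_ordered.tsv", index=True)
    summary = summarize_modules(det.modules_)
    manifest["counts"]["modules"] = int(len(det.modules_))
    manifest["counts"].update({k: int(v) for k, v in summary.items()})

    # ---- stage: breadth ---------------------------------------------------
    if config.bacterial_hits or config.bacterial_meta:
        stage = "breadth"
        logger.info("stage %s", stage)
        bh_p = _require(config.bacterial_hits, "bacterial hit table", stage)
        bm_p = _require(config.bacterial_meta, "bacterial metadata", stage)
        manifest["inputs"]["bacterial_hits"] = sha256_file(bh_p)
        manifest["inputs"]["bacterial_meta"] = sha256_file(bm_p)
        try:
            bhits = read_tsv(bh_p)
            bmeta = read_tsv(bm_p)
            scorer = BreadthScorer(
                threshold=config.evalue, min_fraction=config.breadth_min_fraction
            ).fit(bhits, bmeta)
            fam_sizes = pm.data.sum(axis=1)
            report = scorer.report(fam_sizes)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage {stage} failed: {exc}") from exc
        write_tsv(report, out / "breadth.tsv")
        manifest["counts"]["families_with_bacterial_hit"] = int(
            scorer.profiles_["has_bacterial_hit"].sum()
        )
        manifest["counts"]["bacterial_phyla"] = int(scorer.n_phyla_)

    text = json.dumps(manifest, indent=2, sort_keys=True)
    write_text(text + "\n", out / "manifest.json")
    logger.info("pipeline complete: %s", out / "manifest.json")
    return manifest
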