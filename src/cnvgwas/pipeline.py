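"""End-to-end orchestration: simulate/preprocess -> segment -> callset ->
assoc -> annotate, from a single config.

Stages communicate only through files (TSV/BED/GFF3/JSON) so any stage can
be re-run from its on-disk inputs.  A JSON manifest records versions,
seeds, input checksums and per-stage record counts; a plain-text summary
reports events retained, significant associations per trait and overlap
counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import annotate, assoc, cnvset, intensity, segmentation, synthio

log = logging.getLogger(__name__)

STAGES = ["preprocess", "segment", "callset", "assoc", "annotate"]


@dataclass
class PipelineConfig:
    """Every threshold of the pipeline, with the published defaults."""

    seed: int = 0
    allowed_chromosomes: list = field(default_factory=list)  # empty: all in map
    # input paths (ignored when `simulate` is set)
    marker_map: str | None = None
    lrr_matrix: str | None = None
    lrr_dialect: str = "matrix"
    traits: str | None = None
    genes: str | None = None
    qtls: str | None = None
    # simulation block (dict) or None to use the paths above
    simulate: dict | None = None
    # segmentation
    segmentation: dict = field(default_factory=dict)
    # event filters
    min_carrier_samples: int = 10
    max_length_bp: int = 5_000_000
    # association
    assoc_traits: list | None = None  # None: every trait in the table
    min_accuracy: float = 0.5
    k_pcs: int = 10
    n_permutations: int = 10_000
    alpha: float = 0.05
    # annotation
    upstream_bp: int = 2000
    max_ci_bp: int = 30_000_000
    min_coverage: float = 0.5

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        for name in ("min_carrier_samples", "max_length_bp",
                     "n_permutations", "upstream_bp", "max_ci_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.k_pcs < 0:
            raise ValueError("k_pcs must be >= 0 (0 disables PC correction)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def segmentation_params(self) -> segmentation.SegmentationParams:
        return segmentation.SegmentationParams(**self.segmentation)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _simulate_inputs(config: PipelineConfig, indir: Path) -> dict:
    sim = dict(config.simulate or {})
    seed = int(sim.get("seed", config.seed))
    marker_map = synthio.generate_marker_map(
        n_chromosomes=sim.get("n_chromosomes", 2),
        markers_per_chromosome=sim.get("markers_per_chromosome", 300),
        mean_spacing_bp=sim.get("mean_spacing_bp", 10_000),
        gc_wave_period_bp=sim.get("gc_wave_period_bp", 2_000_000),
        seed=seed,
    )
    planted = [synthio.PlantedCnv(**p) for p in sim.get("planted", [])]
    matrix, truth = synthio.generate_lrr(
        marker_map, n_samples=sim.get("n_samples", 100), planted=planted,
        noise_sd=sim.get("noise_sd", 0.15),
        gc_wave_amplitude=sim.get("gc_wave_amplitude", 0.2),
        seed=seed + 1,
    )
    trait_names = sim.get("trait_names", synthio.DEFAULT_TRAITS[:3])
    effects = {(e["cnv_index"], e["trait"]): e["beta"]
               for e in sim.get("effects", [])}
    traits = synthio.generate_traits(
        truth, truth.genotypes(), trait_names,
        trait_corr_target=sim.get("trait_corr_target", 0.3),
        effect_map=effects,
        accuracy_range=tuple(sim.get("accuracy_range", (0.5, 0.99))),
        seed=seed + 2,
    )
    genes, qtls = synthio.generate_annotations(
        marker_map, n_genes=sim.get("n_genes", 30), n_qtls=sim.get("n_qtls", 15),
        qtl_span_range_bp=tuple(sim.get("qtl_span_range_bp", (50_000, 40_000_000))),
        seed=seed + 3,
    )
    indir.mkdir(parents=True, exist_ok=True)
    paths = {
        "marker_map": indir / "marker_map.tsv",
        "lrr_matrix": indir / "lrr_matrix.tsv",
        "traits": indir / "traits.tsv",
        "genes": indir / "genes.genepred.tsv",
        "qtls": indir / "qtls.gff3",
        "truth": indir / "truth.json",
    }
    intensity.write_marker_map(marker_map, paths["marker_map"])
    intensity.write_lrr_matrix(matrix, paths["lrr_matrix"])
    traits.write(paths["traits"])
    annotate.write_genepred(genes, paths["genes"])
    annotate.write_qtl_gff3(qtls, paths["qtls"])
    truth.to_json(paths["truth"])
    return {k: str(v) for k, v in paths.items()}


def run_all(config: PipelineConfig, outdir) -> Path:
    """Execute every stage; return the run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "stages": [],
        "inputs": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    summary_lines = []

    if config.simulate is not None:
        paths = _simulate_inputs(config, outdir / "inputs")
        log.info("stage simulate: wrote synthetic inputs to %s", outdir / "inputs")
    else:
        paths = {"marker_map": config.marker_map, "lrr_matrix": config.lrr_matrix,
                 "traits": config.traits, "genes": config.genes,
                 "qtls": config.qtls}
    for key, p in paths.items():
        if p is not None:
            manifest["inputs"][key] = {"path": str(p), "sha256": _sha256(Path(p))}

    def fail(stage, exc):
        raise RuntimeError(
            f"stage {stage!r} failed ({exc}); partial outputs in {outdir}") from exc

    # --- preprocess -------------------------------------------------------
    try:
        marker_map = intensity.read_marker_map(paths["marker_map"])
        matrix = intensity.read_lrr_matrix(paths["lrr_matrix"], marker_map,
                                           dialect=config.lrr_dialect)
        allowed = (config.allowed_chromosomes
                   or sorted(marker_map["chromosome"].unique(),
                             key=intensity.chromosome_sort_key))
        matrix, retention = intensity.restrict_to_autosomes(matrix, allowed)
        matrix = intensity.impute_missing(matrix)
        matrix = intensity.gc_correct(matrix)
        intensity.write_lrr_matrix(matrix, outdir / "lrr_corrected.tsv")
        intensity.write_marker_map(matrix.marker_map, outdir / "marker_map_used.tsv")
    except Exception as exc:  # noqa: BLE001 - stage boundary
        fail("preprocess", exc)
    manifest["stages"].append({"name": "preprocess", "markers": matrix.n_markers,
                               "samples": matrix.n_samples,
                               "retention": retention})
    log.info("stage preprocess: %d samples x %d markers", matrix.n_samples,
             matrix.n_markers)

    # --- segment ----------------------------------------------------------
    try:
        params = config.segmentation_params()
        segments = segmentation.segment_multivariate(matrix, params)
        calls = segmentation.call_states(segments, matrix, params.state_threshold)
        segmentation.segments_to_frame(segments).to_csv(
            outdir / "segments.tsv", sep="\t", index=False)
        calls.to_frame().to_csv(outdir / "state_calls.tsv", sep="\t", index=False)
    except Exception as exc:
        fail("segment", exc)
    manifest["stages"].append({"name": "segment", "segments": len(segments)})

    # --- callset ----------------------------------------------------------
    try:
        events = cnvset.merge_events(calls)
        retained, filter_report = cnvset.filter_events(
            events, config.min_carrier_samples, config.max_length_bp)
        retained = cnvset.name_by_loss_frequency(retained)
        if not retained:
            raise ValueError("no events survive the frequency/length filters")
        genotypes = cnvset.build_genotypes(retained)
        cnvset.events_to_frame(retained).to_csv(outdir / "events.tsv",
                                                sep="\t", index=False)
        cnvset.write_events_bed(retained, outdir / "events.bed")
        genotypes.to_csv(outdir / "genotypes.tsv", sep="\t")
    except Exception as exc:
        fail("callset", exc)
    manifest["stages"].append({"name": "callset", **filter_report,
                               "retained_events": len(retained)})
    summary_lines.append(f"events merged: {filter_report['input_events']}, "
                         f"retained after filters: {len(retained)}")

    # --- assoc ------------------------------------------------------------
    try:
        traits = assoc.TraitTable.read(paths["traits"])
        trait_list = config.assoc_traits or traits.trait_names
        k = min(config.k_pcs, genotypes.shape[0] - 2, genotypes.shape[1] - 1)
        if k < config.k_pcs:
            log.warning("k_pcs clamped from %d to %d", config.k_pcs, k)
        pcs = assoc.compute_pcs(genotypes, k) if k >= 1 else None
        n_sig = {}
        for ti, trait in enumerate(trait_list):
            res = assoc.associate(genotypes, traits, trait, pcs,
                                  n_permutations=config.n_permutations,
                                  seed=config.seed + 1000 + ti,
                                  alpha=config.alpha,
                                  min_accuracy=config.min_accuracy)
            res.write(outdir / f"assoc_{trait}.tsv")
            assoc.manhattan_table(res, retained).to_csv(
                outdir / f"manhattan_{trait}.tsv", sep="\t", index=False)
            n_sig[trait] = len(res.significant_cnvs())
            summary_lines.append(
                f"trait {trait}: {n_sig[trait]} significant CNVs "
                f"(q < {config.alpha}): {', '.join(res.significant_cnvs()) or '-'}")
    except Exception as exc:
        fail("assoc", exc)
    manifest["stages"].append({"name": "assoc", "traits": trait_list,
                               "significant_per_trait": n_sig})

    # --- annotate ---------------------------------------------------------
    try:
        genes = annotate.read_genepred(paths["genes"]) if paths.get("genes") else []
        qtls = annotate.read_qtl_gff3(paths["qtls"]) if paths.get("qtls") else []
        gene_hits = annotate.overlap_genes(retained, genes)
        promoter_hits = annotate.overlap_promoters(retained, genes,
                                                   config.upstream_bp)
        qtl_hits = annotate.overlap_qtls(retained, qtls, config.max_ci_bp,
                                         config.min_coverage)
        gene_hits.to_csv(outdir / "overlaps_genes.tsv", sep="\t", index=False)
        promoter_hits.to_csv(outdir / "overlaps_promoters.tsv", sep="\t",
                             index=False)
        qtl_hits.to_csv(outdir / "overlaps_qtls.tsv", sep="\t", index=False)
    except Exception as exc:
        fail("annotate", exc)
    manifest["stages"].append({"name": "annotate", "gene_overlaps": len(gene_hits),
                               "promoter_overlaps": len(promoter_hits),
                               "qtl_overlaps": len(qtl_hits)})
    summary_lines.append(f"overlaps: {len(gene_hits)} gene, "
                         f"{len(promoter_hits)} promoter, {len(qtl_hits)} QTL")

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    (outdir / "summary.txt").write_text("\n".join(summary_lines) + "\n")
    log.info("run complete: %s", outdir)
    return outdir
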