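"""Full-scan orchestration: scan -> candidates -> annotate -> enrich -> cross-pop.

``run_full`` executes every stage the inputs support, writes all tabular
outputs into the output directory, and records a manifest (package
version, parameters, per-stage seeds, input checksums, row counts).  A
single global seed is expanded into per-stage child seeds by hashing the
stage name, so rerunning a stage in isolation reproduces its output
regardless of execution order.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

import sweepscan
from sweepscan import annotation, crosspop, differentiation, enrichment
from sweepscan import genotype_io, outliers, sweep_stats
from sweepscan.differentiation import window_fst_to_tracks

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All inputs and parameters of one pipeline run."""

    vcf_a: str
    output_dir: str
    vcf_b: str | None = None
    genes: str | None = None
    categories: str | None = None
    reference_fasta: str | None = None
    window_snps: int = 201
    fst_window_bp: int = 10_000
    fst_step_bp: int = 1_000
    fst_min_snps: int = 5
    top_k: int = 100
    mask_radius_bp: int = 100_000
    max_gene_distance: int = 20_000
    r_max: int = 50
    min_genes: int = 3
    mask_kb: int = 30
    n_permutations: int = 100
    alpha: float = 0.05
    max_missing_fraction: float = 0.10
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (stable across stage order)."""
    return (global_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


def _checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_full(config: PipelineConfig) -> dict:
    """Run every supported stage; returns the manifest dict.

    Stages without their inputs (no second VCF, no annotation, no
    category map) are skipped and logged.  A stage failure raises with
    the stage name; outputs of completed stages are retained.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    manifest: dict = {
        "package_version": sweepscan.__version__,
        "parameters": dataclasses.asdict(config),
        "inputs": {},
        "stages": [],
    }
    for name in ("vcf_a", "vcf_b", "genes", "categories", "reference_fasta"):
        p = getattr(config, name)
        if p:
            exists = Path(p).exists()
            manifest["inputs"][name] = {
                "path": str(p),
                "sha256": _checksum(p) if exists else "MISSING",
            }

    def record(stage: str, **info) -> None:
        manifest["stages"].append({"stage": stage, **info})
        logger.info("stage %s: %s", stage, info)

    filters = genotype_io.SiteFilterConfig(
        max_missing_fraction=config.max_missing_fraction
    )

    def run_stage(stage: str, fn):
        try:
            return fn()
        except Exception as exc:
            _write_manifest(manifest, out)
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # -- load ---------------------------------------------------------------
    matrix_a = run_stage("load", lambda: genotype_io.read_vcf(config.vcf_a, filters=filters))
    record("load", samples=matrix_a.n_samples, sites=matrix_a.n_sites)

    # -- homogeneity scans --------------------------------------------------
    def _scan_g12():
        tracks = sweep_stats.g12_scan(matrix_a, window_snps=config.window_snps)
        sweep_stats.write_tracks_tsv(tracks, out / "g12_track.tsv")
        return tracks

    g12_tracks = run_stage("scan_g12", _scan_g12)
    record("scan_g12", positions=sum(len(t) for t in g12_tracks))

    def _scan_h():
        tracks = sweep_stats.h_scan(matrix_a)
        sweep_stats.write_tracks_tsv(tracks, out / "h_track.tsv")
        return tracks

    h_tracks = run_stage("scan_h", _scan_h)
    record("scan_h", positions=sum(len(t) for t in h_tracks))

    # -- differentiation ----------------------------------------------------
    fst_tracks = None
    matrix_b = None
    if config.vcf_b:
        matrix_b = run_stage(
            "load_b", lambda: genotype_io.read_vcf(config.vcf_b, filters=filters)
        )
        record("load_b", samples=matrix_b.n_samples, sites=matrix_b.n_sites)

        def _fst():
            per_snp = differentiation.wc_fst_per_snp(matrix_a, matrix_b)
            per_snp.to_csv(out / "fst_per_snp.tsv", sep="\t", index=False)
            windows = differentiation.fst_windows(
                per_snp,
                window_bp=config.fst_window_bp,
                step_bp=config.fst_step_bp,
                min_snps=config.fst_min_snps,
            )
            differentiation.windows_to_bed(windows, out / "fst_windows.bed")
            return window_fst_to_tracks(windows)

        fst_tracks = run_stage("fst", _fst)
        record("fst", windows=sum(len(t) for t in fst_tracks))
    else:
        record("fst", skipped="no second VCF")

    # -- candidates ---------------------------------------------------------
    track_sets = {"G12": g12_tracks, "H": h_tracks}
    if fst_tracks:
        track_sets["Fst"] = fst_tracks
    candidates: dict[str, list] = {}
    for stat, tracks in track_sets.items():
        def _call(tracks=tracks):
            cands = outliers.call_top_loci(
                tracks, k=config.top_k, mask_radius_bp=config.mask_radius_bp
            )
            outliers.candidates_to_tsv(cands, out / f"candidates_{stat.lower()}.tsv")
            outliers.candidates_to_bed(cands, out / f"candidates_{stat.lower()}.bed")
            return cands
        candidates[stat] = run_stage(f"candidates_{stat}", _call)
        record(f"candidates_{stat}", n=len(candidates[stat]))
    rho, p = outliers.track_correlation(g12_tracks, h_tracks)
    record("track_correlation", spearman_rho=round(rho, 4), p_value=p)

    # -- annotation ---------------------------------------------------------
    gene_list = None
    scores = None
    if config.genes:
        gene_list = run_stage("read_genes", lambda: annotation.read_genes(config.genes))
        record("read_genes", n=len(gene_list))
        for stat, cands in candidates.items():
            def _annot(cands=cands, stat=stat):
                near = annotation.filter_by_gene_distance(
                    cands, gene_list, max_distance=config.max_gene_distance
                )
                outliers.candidates_to_tsv(
                    near, out / f"candidates_{stat.lower()}_near_genes.tsv"
                )
                return near
            near = run_stage(f"annotate_{stat}", _annot)
            record(f"annotate_{stat}", n_within_distance=len(near))
        def _null():
            return annotation.distance_null_test(
                candidates["G12"], gene_list, g12_tracks,
                n_permutations=max(100, config.n_permutations),
                seed=stage_seed(config.seed, "distance_null"),
                mask_radius_bp=config.mask_radius_bp,
            )
        null = run_stage("distance_null", _null)
        record(
            "distance_null",
            p_value=null["p_value"],
            observed_median=null["observed_median"],
            null_median=null["null_median"],
        )

        def _scores():
            s = annotation.gene_scores(g12_tracks, gene_list)
            annotation.gene_scores_to_tsv(s, out / "gene_scores_g12.tsv")
            return s

        scores = run_stage("gene_scores", _scores)
        record("gene_scores", n_scored=len(scores))
    else:
        record("annotation", skipped="no gene annotation supplied")

    # -- enrichment ---------------------------------------------------------
    if config.categories and scores and gene_list:
        def _enrich():
            cats = enrichment.CategoryMap.from_tsv(config.categories)
            curve = enrichment.go_enrichment(
                scores, cats, gene_list, r_max=config.r_max,
                min_genes=config.min_genes, mask_kb=config.mask_kb,
            )
            curve.expected_false_discoveries = enrichment.enrichment_fdr(
                scores, cats, gene_list, r_max=config.r_max,
                min_genes=config.min_genes, mask_kb=config.mask_kb,
                n_permutations=config.n_permutations,
                seed=stage_seed(config.seed, "enrichment_fdr"),
            )
            curve.to_tsv(out / "enrichment_curve.tsv")
            with open(out / "enrichment_discoveries.tsv", "w") as fh:
                fh.write("category\trank\tcontributing_genes\n")
                for d in curve.discoveries:
                    fh.write(
                        f"{d.category_id}\t{d.rank}\t{','.join(d.contributing_genes)}\n"
                    )
            return curve
        curve = run_stage("enrichment", _enrich)
        record("enrichment", discoveries=len(curve.discoveries))
    else:
        record("enrichment", skipped="no category map or gene scores")

    # -- cross-population ---------------------------------------------------
    if matrix_b is not None:
        def _crosspop():
            tracks_b = sweep_stats.h_scan(matrix_b)
            comps, summary = crosspop.compare_candidates(
                candidates["H"], tracks_b, alpha=config.alpha
            )
            crosspop.comparisons_to_tsv(comps, out / "crosspop_h.tsv")
            return summary
        summary = run_stage("crosspop", _crosspop)
        record("crosspop", **{k: v for k, v in summary.items() if k != "threshold"})
    else:
        record("crosspop", skipped="no second VCF")

    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
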