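"""End-to-end orchestration: simulate/ingest -> preprocess -> scan ->
postprocess -> enrich, with a YAML config and an auditable run directory.

Each stage reads and writes plain-text TSV interfaces, so stages can be
run independently (see :mod:`veqtl.cli`) and their composition equals a
monolithic :func:`run`.  Identical config + seed produces byte-identical
outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, io as vio, postprocess as post
from .datatypes import ResidualExpressionMatrix
from .enrichment import overrepresentation
from .scan import eqtl_scan, veqtl_scan
from .simulate import SimulationSpec, simulate_dataset, write_fixture

log = logging.getLogger("veqtl")

__all__ = ["PipelineConfig", "run", "stage_simulate", "stage_preprocess",
           "stage_scan", "stage_postprocess", "stage_enrich"]

_TSV_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """Run configuration.

    ``tissues`` maps tissue label -> fixture directory (existing data) or
    -> a SimulationSpec dict (generated under the output directory by the
    simulate stage).  Thresholds default to the standard analysis
    settings: genome-wide significance 5e-8, genotype-class floor 10,
    expression floor RPKM > 0.1 in >= 10 samples, 1 Mb cis window,
    dispersion-class tolerance 0.25.
    """

    tissues: dict
    focal_tissue: str
    output_dir: str
    gene_sets: str | None = None
    significance: float = post.GENOME_WIDE_P
    min_group: int = 10
    expr_min_value: float = 0.1
    expr_min_samples: int = 10
    cis_window: int = post.CIS_WINDOW
    class_tolerance: float = 0.25
    seed: int = 0
    log2_offset: float | None = None

    def __post_init__(self) -> None:
        if not self.tissues:
            raise ValueError("config must declare at least one tissue")
        if self.focal_tissue not in self.tissues:
            raise ValueError(
                f"focal tissue {self.focal_tissue!r} not among tissues "
                f"{sorted(self.tissues)}"
            )
        for name, value in (
            ("significance", self.significance),
            ("min_group", self.min_group),
            ("expr_min_value", self.expr_min_value),
            ("expr_min_samples", self.expr_min_samples),
            ("cis_window", self.cis_window),
            ("class_tolerance", self.class_tolerance),
        ):
            if value <= 0:
                raise ValueError(f"threshold {name} must be positive, got {value}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_dict(self) -> dict:
        return {
            "tissues": self.tissues,
            "focal_tissue": self.focal_tissue,
            "output_dir": str(self.output_dir),
            "gene_sets": self.gene_sets,
            "significance": self.significance,
            "min_group": self.min_group,
            "expr_min_value": self.expr_min_value,
            "expr_min_samples": self.expr_min_samples,
            "cis_window": self.cis_window,
            "class_tolerance": self.class_tolerance,
            "seed": self.seed,
            "log2_offset": self.log2_offset,
        }


def _tissue_dir(cfg: PipelineConfig, tissue: str) -> Path:
    return Path(cfg.output_dir) / tissue


def stage_simulate(cfg: PipelineConfig, tissue: str) -> Path:
    """Materialize the tissue's fixture directory.

    Existing fixture paths are passed through; SimulationSpec dicts are
    simulated (seed offset deterministically per tissue) and written
    under the run directory.
    """
    source = cfg.tissues[tissue]
    if isinstance(source, (str, Path)):
        return Path(source)
    spec_dict = dict(source)
    spec_dict.setdefault(
        "seed", cfg.seed + sorted(cfg.tissues).index(tissue)
    )
    spec = SimulationSpec(**spec_dict)
    out = _tissue_dir(cfg, tissue) / "fixture"
    write_fixture(simulate_dataset(spec), out)
    log.info("simulate[%s]: wrote fixture to %s", tissue, out)
    return out


def stage_preprocess(cfg: PipelineConfig, tissue: str, fixture_dir) -> Path:
    """Filter, collapse, residualize and align one tissue's data."""
    genotypes, expression, covariates, _ = vio.read_fixture(fixture_dir)
    n_var0, n_gene0 = genotypes.n_variants, expression.n_genes
    genotypes = vio.filter_genotypes(genotypes, min_group=cfg.min_group)
    expression = vio.filter_expression(
        expression, min_value=cfg.expr_min_value, min_samples=cfg.expr_min_samples
    )
    collapsed = vio.collapse_replicates(expression)
    residuals = vio.residualize(collapsed, covariates, log2_offset=cfg.log2_offset)
    genotypes, residuals = vio.align(genotypes, residuals, min_group=cfg.min_group)
    out = _tissue_dir(cfg, tissue) / "preprocessed"
    out.mkdir(parents=True, exist_ok=True)
    vio.write_genotype_tsv(genotypes, out / "genotypes.tsv")
    vio.write_variant_annotation(genotypes.variant_meta, out / "variants.tsv")
    res_df = residuals.values.copy()
    res_df.index.name = "gene_id"
    res_df.to_csv(out / "residuals.tsv", sep="\t", float_format=_TSV_FMT)
    vio.write_gene_annotation(residuals.gene_meta, out / "genes.tsv")
    counts = {
        "variants_in": n_var0, "variants_out": genotypes.n_variants,
        "genes_in": n_gene0, "genes_out": len(residuals.gene_ids),
        "subjects": len(residuals.subject_ids),
    }
    with open(out / "counts.yaml", "w") as fh:
        yaml.safe_dump(counts, fh)
    log.info("preprocess[%s]: %s", tissue, counts)
    return out


def _load_preprocessed(pre_dir):
    pre_dir = Path(pre_dir)
    genotypes = vio.read_genotype_tsv(pre_dir / "genotypes.tsv", pre_dir / "variants.tsv")
    res = pd.read_csv(pre_dir / "residuals.tsv", sep="\t", index_col=0)
    residuals = ResidualExpressionMatrix(
        res, gene_meta=vio.read_gene_annotation(pre_dir / "genes.tsv")
    )
    return genotypes, residuals


def stage_scan(cfg: PipelineConfig, tissue: str, pre_dir) -> Path:
    """Run both scans on preprocessed matrices; write the record table."""
    genotypes, residuals = _load_preprocessed(pre_dir)
    records = pd.concat(
        [
            veqtl_scan(genotypes, residuals, min_group=cfg.min_group),
            eqtl_scan(genotypes, residuals),
        ],
        ignore_index=True,
    )
    records.insert(0, "tissue", tissue)
    out = _tissue_dir(cfg, tissue) / "scan.tsv"
    out.parent.mkdir(parents=True, exist_ok=True)
    records.to_csv(out, sep="\t", index=False, float_format=_TSV_FMT)
    log.info("scan[%s]: %d records", tissue, len(records))
    return out


def stage_postprocess(cfg: PipelineConfig, scan_paths: dict) -> Path:
    """Significance calls, cis/trans labels, classes, diagnostics, candidates."""
    out = Path(cfg.output_dir) / "postprocess"
    out.mkdir(parents=True, exist_ok=True)
    annotated = {}
    summaries = []
    for tissue, path in scan_paths.items():
        rec = pd.read_csv(path, sep="\t")
        pre = _tissue_dir(cfg, tissue) / "preprocessed"
        vmeta = vio.read_variant_annotation(pre / "variants.tsv")
        gmeta = vio.read_gene_annotation(pre / "genes.tsv")
        rec = post.call_significant(rec, cfg.significance)
        rec = post.annotate_cis_trans(rec, vmeta, gmeta, cfg.cis_window)
        rec = post.classify_records(rec, tolerance=cfg.class_tolerance)
        rec.to_csv(out / f"records_{tissue}.tsv", sep="\t", index=False,
                   float_format=_TSV_FMT)
        annotated[tissue] = rec
        for test in ("veQTL", "eQTL"):
            sub = rec[(rec["test"] == test) & ~rec["degenerate"]].dropna(subset=["p"])
            if len(sub) == 0:
                continue
            rep = post.genomic_inflation(sub["p"], tissue=tissue, test=test)
            rep.qq_frame().to_csv(out / f"qq_{tissue}_{test}.tsv", sep="\t",
                                  index=False, float_format=_TSV_FMT)
            sig = sub[sub["significant"]]
            summaries.append({
                "tissue": tissue, "test": test,
                "n_pairs": len(sub), "n_significant": len(sig),
                "n_variants": sig["variant_id"].nunique(),
                "n_genes": sig["gene_id"].nunique(),
                "n_cis": int((sig["cis_trans"] == "cis").sum()),
                "lambda": rep.lam,
                "rank_correlation": post.rank_correlation(
                    rec[rec["test"] == "veQTL"], rec[rec["test"] == "eQTL"]
                ),
            })
    pd.DataFrame(summaries).to_csv(out / "summary.tsv", sep="\t", index=False,
                                   float_format="%.6g")
    ve_by_tissue = {t: r[r["test"] == "veQTL"] for t, r in annotated.items()}
    eq_focal = annotated[cfg.focal_tissue]
    candidates = post.candidate_gene_filter(
        ve_by_tissue, eq_focal[eq_focal["test"] == "eQTL"],
        cfg.focal_tissue, cfg.significance,
    )
    candidates.to_csv(out / "candidates.tsv", sep="\t", index=False)
    log.info("postprocess: %d candidate pairs", len(candidates))
    return out


def stage_enrich(cfg: PipelineConfig, post_dir) -> Path | None:
    """Over-representation of candidate genes vs the focal background."""
    if cfg.gene_sets is None:
        log.info("enrich: no gene sets supplied; skipped")
        return None
    post_dir = Path(post_dir)
    cand_path = post_dir / "candidates.tsv"
    if not cand_path.exists():
        raise FileNotFoundError(
            f"{cand_path} missing: run the postprocess stage (candidate_gene_filter) first"
        )
    candidates = pd.read_csv(cand_path, sep="\t")
    if len(candidates) == 0:
        raise ValueError(
            "candidate table is empty (candidate_gene_filter produced no pairs); "
            "nothing to enrich"
        )
    background = vio.read_gene_annotation(
        _tissue_dir(cfg, cfg.focal_tissue) / "preprocessed" / "genes.tsv"
    ).index
    sets = vio.read_gmt(cfg.gene_sets)
    table = overrepresentation(candidates["gene_id"].unique(), background, sets)
    out = Path(cfg.output_dir) / "enrichment.tsv"
    table.to_csv(out, sep="\t", index=False, float_format=_TSV_FMT)
    log.info("enrich: %d gene sets scored", len(table))
    return out


def run(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns a manifest dict (also written as YAML).

    Any stage failure propagates with the stage name prefixed so callers
    (and the CLI) can report where the pipeline stopped.
    """
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": cfg.to_dict(), "version": __version__, "stages": {}}
    scan_paths: dict = {}
    try:
        for tissue in sorted(cfg.tissues):
            stage = f"simulate[{tissue}]"
            fixture = stage_simulate(cfg, tissue)
            stage = f"preprocess[{tissue}]"
            pre = stage_preprocess(cfg, tissue, fixture)
            with open(Path(pre) / "counts.yaml") as fh:
                manifest["stages"][f"preprocess_{tissue}"] = yaml.safe_load(fh)
            stage = f"scan[{tissue}]"
            scan_paths[tissue] = stage_scan(cfg, tissue, pre)
            manifest["stages"][f"scan_{tissue}"] = {
                "records": int(sum(1 for _ in open(scan_paths[tissue])) - 1)
            }
        stage = "postprocess"
        post_dir = stage_postprocess(cfg, scan_paths)
        n_cand = len(pd.read_csv(post_dir / "candidates.tsv", sep="\t"))
        manifest["stages"]["postprocess"] = {"candidate_pairs": n_cand}
        stage = "enrich"
        enr = stage_enrich(cfg, post_dir)
        if enr is not None:
            manifest["stages"]["enrich"] = {
                "gene_sets": int(sum(1 for _ in open(enr)) - 1)
            }
    except Exception as exc:  # annotate with the failing stage, then re-raise
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    with open(outdir / "run_manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest
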