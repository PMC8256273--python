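"""Configuration and orchestration of the full scan-to-candidates run.

``run_pipeline`` executes genotype loading -> AFD scan -> variant-effect
classification -> DEG calling -> integration (and phenotype summaries when
tables are provided), writing TSV outputs plus a JSON manifest with input
checksums, the parameters used, and the count funnel at each filtering
step (total SNPs -> retained -> outliers -> exon/UTR -> candidate genes).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import afd_scan, expression, genotypes, integration, phenotype, variant_effects

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run.

    Defaults follow the standard design: frequency estimation requires at
    least five called individuals per population, outliers are the top 5%
    of the AFD distribution, a DEG needs |log2Ratio| >= 1 at BY FDR < 0.001,
    and "pre-germination" means stages 1 and 2 (4 days after imbibition and
    the day just before radicle emergence).
    """

    vcf: str
    pop_map: str
    out_dir: str
    focal: str
    ref_weedy: str
    ref_cultivated: str
    gff: str | None = None
    fasta: str | None = None
    counts: str | None = None
    sample_sheet: str | None = None
    germination: str | None = None
    qpcr: str | None = None
    qpcr_calibrator: str | None = None
    e_region: str = "E"
    trace_panels: dict | None = None
    min_called: int = 5
    quantile: float = 0.95
    margin: float = 0.0
    log2_cut: float = 1.0
    fdr_cut: float = 0.001
    pre_germination_stages: tuple = (1, 2)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.quantile < 1:
            raise ValueError("quantile must be in (0, 1)")
        if self.min_called < 1:
            raise ValueError("min_called must be >= 1")
        if self.fdr_cut <= 0 or self.fdr_cut >= 1:
            raise ValueError("fdr_cut must be in (0, 1)")
        if self.log2_cut < 0:
            raise ValueError("log2_cut must be >= 0")
        self.pre_germination_stages = tuple(self.pre_germination_stages)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "feralscan_version": __version__,
        "parameters": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
        "inputs": {},
        "counts": {},
        "outputs": {},
    }
    for name in ("vcf", "pop_map", "gff", "fasta", "counts", "sample_sheet",
                 "germination", "qpcr"):
        p = getattr(config, name)
        if p:
            manifest["inputs"][name] = {"path": str(p), "sha256": _sha256(p)}

    def _stage(name):
        logger.info("pipeline stage: %s", name)

    try:
        _stage("genotypes")
        gm = genotypes.read_vcf(config.vcf, config.pop_map)
        manifest["counts"]["total_snps"] = gm.n_sites
        pops = [config.focal, config.ref_weedy, config.ref_cultivated]
        freqs_all = genotypes.allele_frequencies(
            gm, populations=gm.populations, min_called=config.min_called
        )
        scan_freqs = genotypes.allele_frequencies(
            gm, populations=pops, min_called=config.min_called
        )
        manifest["counts"]["retained_snps"] = int(scan_freqs.retained.sum())
        scan_freqs.to_tsv(out / "allele_frequencies.tsv")
        manifest["outputs"]["allele_frequencies"] = "allele_frequencies.tsv"

        _stage("afd_scan")
        scan = afd_scan.scan(
            scan_freqs, config.focal, config.ref_weedy, config.ref_cultivated,
            quantile=config.quantile, margin=config.margin,
        )
        scan.to_tsv(out / "afd_scan.tsv")
        scan.write_metadata(out / "afd_scan_metadata.json")
        manifest["counts"]["outlier_candidate_snps"] = scan.n_candidates
        manifest["outputs"]["afd_scan"] = "afd_scan.tsv"
    except Exception as err:  # noqa: BLE001
        raise RuntimeError(f"pipeline failed at stage genotypes/afd_scan: {err}") from err

    effect_set: set[tuple] = set()
    if config.gff and config.fasta:
        try:
            _stage("variant_effects")
            models, reference = variant_effects.load_gene_models(
                config.gff, config.fasta
            )
            cand_mask = gm.sites["site_id"].isin(scan.candidate_sites)
            effects = variant_effects.classify_variants(
                gm.sites[cand_mask], models, reference
            )
            effects.to_csv(out / "effects.tsv", sep="\t", index=False)
            manifest["outputs"]["effects"] = "effects.tsv"
            effect_set = variant_effects.exon_utr_filter(effects)
            manifest["counts"]["exon_utr_candidate_snps"] = len(
                {s for s, _ in effect_set}
            )
        except Exception as err:  # noqa: BLE001
            raise RuntimeError(f"pipeline failed at stage variant_effects: {err}") from err

    region_sets = None
    if config.counts and config.sample_sheet:
        try:
            _stage("expression")
            cm = expression.read_counts(config.counts, config.sample_sheet)
            deg = expression.call_degs(
                cm, e_region=config.e_region,
                log2_cut=config.log2_cut, fdr_cut=config.fdr_cut,
            )
            deg.to_csv(out / "deg_table.tsv", sep="\t", index=False)
            manifest["outputs"]["deg_table"] = "deg_table.tsv"
            region_sets = expression.region_specific_degs(deg)
            manifest["counts"]["region_specific_degs_per_stage"] = {
                str(s): region_sets.n_common(s) for s in region_sets.common_up
            }
            manifest["counts"]["constant_up"] = len(region_sets.constant_up)
            manifest["counts"]["constant_down"] = len(region_sets.constant_down)
        except Exception as err:  # noqa: BLE001
            raise RuntimeError(f"pipeline failed at stage expression: {err}") from err

    if effect_set and region_sets is not None:
        try:
            _stage("integration")
            cands = integration.candidate_genes(
                scan, effect_set, region_sets, config.pre_germination_stages
            )
            integration.candidate_gene_table(cands).to_csv(
                out / "candidate_genes.tsv", sep="\t", index=False
            )
            manifest["counts"]["candidate_genes"] = len(cands)
            manifest["outputs"]["candidate_genes"] = "candidate_genes.tsv"

            trace_map = config.trace_panels
            if trace_map is None:
                trace_map = {
                    p: p for p in integration.TRACE_PANELS
                    if p in freqs_all.populations
                }
            if not trace_map:
                # synthetic panel labels: map them onto the field names
                from .synthetic_data import PANEL_ALIASES

                trace_map = {
                    alias: pop for pop, alias in PANEL_ALIASES.items()
                    if pop in freqs_all.populations
                }
            cand_snps = sorted({s for c in cands for s in c.snp_ids})
            if trace_map and cand_snps:
                trace = integration.trace_alleles(
                    scan, freqs_all, panel_names=trace_map, site_ids=cand_snps
                )
                trace.to_csv(out / "allele_trace.tsv", sep="\t", index=False)
                manifest["outputs"]["allele_trace"] = "allele_trace.tsv"
                manifest["counts"]["traced_snps"] = len(trace)
        except Exception as err:  # noqa: BLE001
            raise RuntimeError(f"pipeline failed at stage integration: {err}") from err

    if config.germination:
        _stage("phenotype")
        recs = phenotype.read_germination(config.germination)
        phenotype.summarize_germination(recs).to_csv(
            out / "germination_summary.tsv", sep="\t", index=False
        )
        manifest["outputs"]["germination_summary"] = "germination_summary.tsv"
    if config.qpcr and config.qpcr_calibrator:
        _stage("phenotype_qpcr")
        qtab = pd.read_csv(config.qpcr, sep="\t")
        phenotype.relative_expression(qtab, config.qpcr_calibrator).to_csv(
            out / "relative_expression.tsv", sep="\t", index=False
        )
        manifest["outputs"]["relative_expression"] = "relative_expression.tsv"

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
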