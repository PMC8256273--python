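"""SNP-by-expression integration, allele-origin tracing and concordance.

A candidate adaptive gene must (a) carry at least one directional AFD
outlier SNP that survives the exon/UTR effect filter and (b) be
region-specifically up-regulated at at least one pre-germination stage.
Each candidate SNP's elevated allele is then traced across five panels
(wild, japonica, focal NE weedy, reference JS weedy, indica) and classed
by where it pre-exists: standing variation in wild rice, cultivation-
associated (absent from wild but present in a cultivated panel), or private
to the focal weedy populations. Presence means frequency > 0; a panel with
no data at a site is reported as absent data, never as frequency zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .afd_scan import AfdScanResult
from .expression import RegionDegSets
from .genotypes import AlleleFreqTable

logger = logging.getLogger(__name__)

TRACE_PANELS = ("Wild", "JAP", "NE_W", "JS_W", "IND")

ORIGIN_CLASSES = ("standing_in_wild", "cultivation_associated", "weedy_private")


@dataclass
class CandidateGene:
    gene_id: str
    n_outlier_snps: int
    snp_ids: tuple
    up_stages: tuple

    def __post_init__(self) -> None:
        if self.n_outlier_snps < 1 or not self.up_stages:
            raise ValueError("candidate gene requires >=1 SNP and >=1 up stage")


def candidate_genes(
    scan: AfdScanResult,
    exon_utr_set: set[tuple],
    region_sets: RegionDegSets,
    pre_germination_stages: tuple = (1, 2),
) -> list[CandidateGene]:
    """Join the scan, the effect filter, and the up-regulation evidence.

    A gene qualifies iff it contains >= 1 candidate SNP in the exon/UTR
    filter set and is in ``common_up`` at >= 1 pre-germination stage.
    Output sorted by descending SNP count, then gene id.
    """
    cand_sites = set(scan.candidate_sites)
    if not cand_sites:
        logger.warning("empty candidate SNP set; no candidate genes")
        return []
    up_evidence: dict[str, tuple] = {}
    for stage in pre_germination_stages:
        for gid in region_sets.common_up.get(stage, ()):
            up_evidence[gid] = up_evidence.get(gid, ()) + (stage,)
    if not up_evidence:
        logger.warning("no region-specific up-regulated genes; no candidates")
        return []

    per_gene: dict[str, list] = {}
    for site_id, gene_id in exon_utr_set:
        if site_id in cand_sites and gene_id in up_evidence:
            per_gene.setdefault(gene_id, []).append(site_id)
    out = [
        CandidateGene(
            gene_id=gid,
            n_outlier_snps=len(snps),
            snp_ids=tuple(sorted(snps)),
            up_stages=tuple(sorted(up_evidence[gid])),
        )
        for gid, snps in per_gene.items()
    ]
    return sorted(out, key=lambda c: (-c.n_outlier_snps, c.gene_id))


def candidate_gene_table(cands: list[CandidateGene]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in cands],
            "n_outlier_snps": [c.n_outlier_snps for c in cands],
            "snp_ids": [",".join(map(str, c.snp_ids)) for c in cands],
            "up_stages": [",".join(map(str, c.up_stages)) for c in cands],
        }
    )


def _elevated_freq(p_alt: float, elevated: str) -> float:
    return p_alt if elevated == "alt" else 1.0 - p_alt


def trace_alleles(
    scan: AfdScanResult,
    freqs: AlleleFreqTable,
    panel_names: dict[str, str] | None = None,
    site_ids: list | None = None,
    presence_min_count: int = 1,
) -> pd.DataFrame:
    """Frequency of each candidate site's elevated allele across panels.

    ``panel_names`` maps the field panel names (Wild, JAP, NE_W, JS_W, IND)
    to the population labels of ``freqs``; panels without data at a site
    (zero called individuals) get NaN there. Presence for origin
    classification means an elevated-allele count of at least
    ``presence_min_count`` (count = 2 * n_called * frequency, rounded).

    origin_class: ``standing_in_wild`` if present in wild;
    ``cultivation_associated`` if absent from wild but present in japonica
    or indica; ``weedy_private`` otherwise. Sites with no wild data are
    ``unclassifiable`` (absence of data is not absence of the allele).
    """
    if panel_names is None:
        panel_names = {p: p for p in TRACE_PANELS}
    if site_ids is None:
        site_ids = scan.candidate_sites
    rows = []
    for sid in site_ids:
        elevated = scan.table.loc[sid, "elevated_allele"]
        row: dict = {"site_id": sid, "elevated_allele": elevated}
        counts: dict[str, float] = {}
        for panel, pop in panel_names.items():
            if pop in freqs.populations and freqs.n_called.loc[sid, pop] > 0:
                f = _elevated_freq(float(freqs.freq.loc[sid, pop]), elevated)
                row[f"freq_{panel}"] = f
                counts[panel] = round(2 * int(freqs.n_called.loc[sid, pop]) * f)
            else:
                row[f"freq_{panel}"] = np.nan
        present = {p: c >= presence_min_count for p, c in counts.items()}
        if not counts:
            row["origin_class"] = "unclassifiable"
        elif "Wild" not in counts:
            row["origin_class"] = "unclassifiable"
        elif present["Wild"]:
            row["origin_class"] = "standing_in_wild"
        elif present.get("JAP", False) or present.get("IND", False):
            row["origin_class"] = "cultivation_associated"
        else:
            row["origin_class"] = "weedy_private"
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ConcordanceReport:
    """Paired-t comparison of two per-site frequency estimates."""

    n_pairs: int
    t_statistic: float
    df: int
    p_value: float
    mean_difference: float

    def to_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "t_statistic": self.t_statistic,
            "df": self.df,
            "p_value": self.p_value,
            "mean_difference": self.mean_difference,
        }


def concordance_test(est_a, est_b) -> ConcordanceReport:
    """Classical paired t-test on per-site frequency differences.

    Used to check that frequencies estimated by whole-genome sequencing
    agree with targeted genotyping of the same sites. Degenerate inputs:
    all differences zero -> t = 0, p = 1; zero variance with nonzero mean
    -> p = 0 (reported, not raised).
    """
    a = np.asarray(est_a, dtype=float)
    b = np.asarray(est_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired estimates must be equal-length 1-D arrays")
    if len(a) < 2:
        raise ValueError("need at least two pairs")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite estimate")
    diff = a - b
    n = len(diff)
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff.mean(), 0.0):
            return ConcordanceReport(n, 0.0, n - 1, 1.0, 0.0)
        return ConcordanceReport(n, np.inf, n - 1, 0.0, float(diff.mean()))
    t, p = stats.ttest_rel(a, b)
    return ConcordanceReport(n, float(t), n - 1, float(p), float(diff.mean()))
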