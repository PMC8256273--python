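"""RPKM normalization and region-specific differential expression.

Differential expression between two single libraries is tested with the
exact binomial random-sampling model: conditional on the total ``c1 + c2``,
the count in library 1 is Binomial(c1 + c2, n1 / (n1 + n2)) under the null
of equal relative expression, where ``n1``/``n2`` are library sizes. Raw
p-values are corrected per comparison with the Benjamini-Yekutieli step-up
(valid under arbitrary dependence) and a gene is called differentially
expressed when |log2Ratio| >= 1 and q < 0.001 — the dual threshold is the
scientific content here and is preserved exactly.

A DEG is "region-specific" when it is called in the same direction in BOTH
north-eastern populations against the eastern one at the same germination
stage; "stage-persistent" genes are region-specific in the same direction
at every stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class CountMatrix:
    """Gene x sample read counts with gene lengths and sample labels.

    ``counts``: (genes x samples) integer frame. ``lengths``: bp per gene.
    ``sample_sheet``: columns sample, region, stage. ``library_size``
    defaults to column sums; an override must be >= the column sum.
    """

    counts: pd.DataFrame
    lengths: pd.Series
    sample_sheet: pd.DataFrame
    library_size: pd.Series | None = None
    enforce_library_floor: bool = True

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.lengths <= 0).any():
            raise ValueError("gene lengths must be positive")
        self.lengths = self.lengths.reindex(self.counts.index)
        colsum = self.counts.sum(axis=0)
        if self.library_size is None:
            self.library_size = colsum.astype(float)
        else:
            self.library_size = self.library_size.reindex(self.counts.columns).astype(float)
            if self.enforce_library_floor and (self.library_size < colsum - 1e-9).any():
                raise ValueError("library_size below column sum; override requires "
                                 "enforce_library_floor=False")
        sheet = self.sample_sheet.set_index("sample").loc[self.counts.columns]
        sheet.index.name = "sample"
        self.sample_sheet = sheet.reset_index()

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def sample_for(self, region: str, stage) -> str:
        hit = self.sample_sheet[
            (self.sample_sheet["region"] == region)
            & (self.sample_sheet["stage"] == stage)
        ]["sample"]
        if len(hit) != 1:
            raise ValueError(
                f"expected exactly one library for region={region!r} "
                f"stage={stage!r}, found {len(hit)}"
            )
        return hit.iloc[0]

    def to_tsv(self, counts_path: str | Path, sheet_path: str | Path) -> None:
        out = self.counts.copy()
        out.insert(0, "length_bp", self.lengths)
        out.to_csv(counts_path, sep="\t", index_label="gene_id")
        self.sample_sheet.to_csv(sheet_path, sep="\t", index=False)


def read_counts(
    counts_path: str | Path, sheet_path: str | Path, **kwargs
) -> CountMatrix:
    """Read a counts TSV (gene_id, length_bp, one column per sample) plus a
    sample sheet TSV (sample, region, stage)."""
    df = pd.read_csv(counts_path, sep="\t", index_col="gene_id")
    lengths = df.pop("length_bp")
    sheet = pd.read_csv(sheet_path, sep="\t")
    sheet["stage"] = sheet["stage"].astype(int)
    return CountMatrix(df, lengths, sheet, **kwargs)


def rpkm(cm: CountMatrix) -> pd.DataFrame:
    """Reads per kilobase per million mapped reads:
    ``counts * 1e9 / (library_size * gene_length_bp)``."""
    lib = cm.library_size
    if (lib <= 0).any():
        raise ValueError("zero library size")
    return cm.counts * 1e9 / np.outer(cm.lengths.to_numpy(), lib.to_numpy())


def deg_test(c1, c2, n1: float, n2: float):
    """Exact binomial test of equal relative expression in two libraries.

    Returns ``(p, log2_ratio)`` (vectorized over genes). Two-sided p-value
    by tail doubling with the observed point mass included:
    ``p = min(1, 2 * min(P(X <= c1), P(X >= c1)))`` with
    ``X ~ Binomial(c1 + c2, n1/(n1+n2))``. The log2 ratio of normalized
    expression uses a 0.5 pseudocount on both counts only when one of them
    is zero; genes with ``c1 + c2 = 0`` get p = 1 and ratio 0.
    """
    c1 = np.atleast_1d(np.asarray(c1, dtype=np.int64))
    c2 = np.atleast_1d(np.asarray(c2, dtype=np.int64))
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    n = c1 + c2
    pnull = n1 / (n1 + n2)
    lower = stats.binom.cdf(c1, n, pnull)
    upper = stats.binom.sf(c1 - 1, n, pnull)
    p = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    p = np.where(n == 0, 1.0, p)

    pc = np.where((c1 * c2 == 0) & (n > 0), 0.5, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.log2(((c1 + pc) / n1) / ((c2 + pc) / n2))
    ratio = np.where(n == 0, 0.0, ratio)
    return p, ratio


def by_fdr(pvals) -> np.ndarray:
    """Benjamini-Yekutieli adjusted q-values, in input order.

    Step-up with the harmonic-sum inflation c(m) = sum_{k<=m} 1/k, so the
    control holds under arbitrary dependence among tests.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise ValueError("NaN p-value")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_by")[1]


def call_degs(
    cm: CountMatrix,
    e_region: str = "E",
    ne_regions: tuple[str, ...] | None = None,
    stages: tuple | None = None,
    log2_cut: float = 1.0,
    fdr_cut: float = 0.001,
) -> pd.DataFrame:
    """Call DEGs for every (NE region vs E region) pair at each stage.

    BY correction is applied within each comparison across genes. Returns a
    long frame: gene_id, region, stage, rpkm_ne, rpkm_e, log2_ratio, p, q,
    call in {up, down, ns}.
    """
    regions = list(dict.fromkeys(cm.sample_sheet["region"]))
    if e_region not in regions:
        raise ValueError(f"reference region {e_region!r} absent")
    if ne_regions is None:
        ne_regions = tuple(r for r in regions if r != e_region)
    if stages is None:
        stages = tuple(sorted(set(cm.sample_sheet["stage"])))
    norm = rpkm(cm)
    frames = []
    for stage in stages:
        s_e = cm.sample_for(e_region, stage)
        for region in ne_regions:
            s_ne = cm.sample_for(region, stage)
            c1 = cm.counts[s_ne].to_numpy()
            c2 = cm.counts[s_e].to_numpy()
            p, ratio = deg_test(c1, c2, cm.library_size[s_ne], cm.library_size[s_e])
            q = by_fdr(p)
            call = np.where(
                (q < fdr_cut) & (ratio >= log2_cut),
                "up",
                np.where((q < fdr_cut) & (ratio <= -log2_cut), "down", "ns"),
            )
            frames.append(
                pd.DataFrame(
                    {
                        "gene_id": cm.genes,
                        "region": region,
                        "stage": stage,
                        "rpkm_ne": norm[s_ne].to_numpy(),
                        "rpkm_e": norm[s_e].to_numpy(),
                        "log2_ratio": ratio,
                        "p": p,
                        "q": q,
                        "call": call,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


@dataclass
class RegionDegSets:
    """Region-specific DEG sets per stage and their cross-stage cores."""

    common_up: dict = field(default_factory=dict)
    common_down: dict = field(default_factory=dict)
    constant_up: set = field(default_factory=set)
    constant_down: set = field(default_factory=set)

    def n_common(self, stage) -> int:
        return len(self.common_up[stage]) + len(self.common_down[stage])


def region_specific_degs(
    deg: pd.DataFrame, ne_regions: tuple[str, ...] | None = None
) -> RegionDegSets:
    """Genes called in the same direction in every NE comparison per stage;
    the constant sets intersect those across all stages."""
    if ne_regions is None:
        ne_regions = tuple(dict.fromkeys(deg["region"]))
    stages = sorted(set(deg["stage"]))
    sets = RegionDegSets()
    for stage in stages:
        up_sets, down_sets = [], []
        for region in ne_regions:
            sub = deg[(deg["stage"] == stage) & (deg["region"] == region)]
            if sub.empty:
                raise ValueError(f"missing comparison region={region} stage={stage}")
            up_sets.append(set(sub.loc[sub["call"] == "up", "gene_id"]))
            down_sets.append(set(sub.loc[sub["call"] == "down", "gene_id"]))
        sets.common_up[stage] = set.intersection(*up_sets)
        sets.common_down[stage] = set.intersection(*down_sets)
    sets.constant_up = set.intersection(*(sets.common_up[s] for s in stages))
    sets.constant_down = set.intersection(*(sets.common_down[s] for s in stages))
    return sets
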