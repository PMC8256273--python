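"""Genotype panels and per-population allele / genotype frequencies.

The central container is :class:`GenotypeMatrix`: diploid alt-allele dosages
for biallelic SNPs across samples, with a population label per sample.
Frequencies are computed from called genotypes only, and a site is retained
for downstream differentiation scans only if every population of interest has
at least ``min_called`` non-missing individuals at that site — the standard
guard against allele-frequency estimates driven by a handful of calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

SITE_COLUMNS = ["site_id", "chrom", "pos", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """Diploid alt-allele dosages for biallelic SNPs.

    Parameters
    ----------
    calls
        ``(n_samples, n_sites)`` int8 array; entries in {0, 1, 2} or
        ``MISSING`` (-1).
    samples
        Ordered sample identifiers (rows of ``calls``).
    sites
        Frame with columns ``site_id, chrom, pos, ref, alt`` (``pos`` is
        1-based, VCF convention), one row per column of ``calls``.
    pop_map
        Mapping sample id -> population label; every sample must be present.
    """

    calls: np.ndarray
    samples: list[str]
    sites: pd.DataFrame
    pop_map: dict[str, str]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D (samples x sites) array")
        if self.calls.shape[0] != len(self.samples):
            raise ValueError("calls row count does not match samples")
        if self.calls.shape[1] != len(self.sites):
            raise ValueError("calls column count does not match sites")
        bad = set(np.unique(self.calls)) - {0, 1, 2, MISSING}
        if bad:
            raise ValueError(f"invalid dosage values: {sorted(bad)}")
        missing_labels = [s for s in self.samples if s not in self.pop_map]
        if missing_labels:
            raise KeyError(
                f"samples absent from population map: {missing_labels[:5]}"
            )
        self.sites = self.sites.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_sites(self) -> int:
        return self.calls.shape[1]

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.pop_map[s], None)
        return list(seen)

    def sample_indices(self, population: str) -> np.ndarray:
        idx = [i for i, s in enumerate(self.samples) if self.pop_map[s] == population]
        if not idx:
            raise ValueError(f"population {population!r} has no samples")
        return np.asarray(idx, dtype=int)

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            self.calls[:, mask],
            list(self.samples),
            self.sites.loc[mask].reset_index(drop=True),
            dict(self.pop_map),
        )


@dataclass
class AlleleFreqTable:
    """Per (population, site) alternate-allele frequencies.

    ``freq`` and ``n_called`` are (site x population) frames indexed by
    ``site_id``; ``retained`` marks sites with ``n_called >= min_called`` in
    every population the table was built for.
    """

    freq: pd.DataFrame
    n_called: pd.DataFrame
    retained: pd.Series
    min_called: int
    sites: pd.DataFrame

    @property
    def populations(self) -> list[str]:
        return list(self.freq.columns)

    def to_tsv(self, path: str | Path) -> None:
        out = self.sites.set_index("site_id").copy()
        for pop in self.populations:
            out[f"freq_{pop}"] = self.freq[pop]
            out[f"n_called_{pop}"] = self.n_called[pop]
        out["retained"] = self.retained
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, min_called: int = 5) -> "AlleleFreqTable":
        df = pd.read_csv(path, sep="\t", index_col="site_id")
        pops = [c[len("freq_"):] for c in df.columns if c.startswith("freq_")]
        freq = df[[f"freq_{p}" for p in pops]].copy()
        freq.columns = pops
        n_called = df[[f"n_called_{p}" for p in pops]].copy()
        n_called.columns = pops
        sites = df[["chrom", "pos", "ref", "alt"]].reset_index()
        return cls(freq, n_called, df["retained"].astype(bool), min_called, sites)


def read_pop_map(path: str | Path) -> dict[str, str]:
    """Read a two-column (sample_id, population) TSV, with optional header."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample_id", "population"]:
        df = pd.read_csv(path, sep="\t", dtype=str, header=None,
                         names=["sample_id", "population"])
    return dict(zip(df["sample_id"], df["population"]))


def write_pop_map(pop_map: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": list(pop_map), "population": list(pop_map.values())}
    ).to_csv(path, sep="\t", index=False)


def read_vcf(path: str | Path, pop_map_path: str | Path) -> GenotypeMatrix:
    """Load biallelic SNPs from a VCF into a :class:`GenotypeMatrix`.

    Multiallelic and non-SNP records are skipped (count logged). Phase is
    ignored; a half-missing genotype counts as missing. Every VCF sample must
    appear in the population map, otherwise a ``KeyError`` is raised.
    """
    from cyvcf2 import VCF

    pop_map = read_pop_map(pop_map_path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    absent = [s for s in samples if s not in pop_map]
    if absent:
        raise KeyError(f"VCF samples absent from population map: {absent[:5]}")

    rows: list[tuple] = []
    dosage_cols: list[np.ndarray] = []
    n_skipped = 0
    for i, rec in enumerate(vcf):
        alts = rec.ALT
        if len(alts) != 1 or len(rec.REF) != 1 or len(alts[0]) != 1:
            n_skipped += 1
            continue
        # per-allele codes; -1 encodes a missing allele, so half-missing
        # calls (e.g. "./1") become missing as a whole
        alleles = np.array([g[:2] for g in rec.genotypes], dtype=np.int16)
        dos = alleles.sum(axis=1).astype(np.int8)
        dos[(alleles < 0).any(axis=1)] = MISSING
        site_id = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        rows.append((site_id, rec.CHROM, rec.POS, rec.REF, alts[0]))
        dosage_cols.append(dos)
    if n_skipped:
        logger.info("read_vcf: skipped %d multiallelic/non-SNP records", n_skipped)
    calls = (
        np.stack(dosage_cols, axis=1)
        if dosage_cols
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    return GenotypeMatrix(calls, samples, sites, pop_map)


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal GT-only VCF v4.2 (``./.`` for missing calls)."""
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    contigs: dict[str, int] = {}
    for chrom, pos in zip(gm.sites["chrom"], gm.sites["pos"]):
        contigs[chrom] = max(contigs.get(chrom, 0), int(pos))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=feralscan\n")
        for chrom, length in contigs.items():
            fh.write(f"##contig=<ID={chrom},length={length + 1000}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        for j, row in gm.sites.iterrows():
            gts = "\t".join(gt_str[int(d)] for d in gm.calls[:, j])
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.site_id}\t{row.ref}\t{row.alt}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


def allele_frequencies(
    gm: GenotypeMatrix,
    populations: list[str] | None = None,
    min_called: int = 5,
) -> AlleleFreqTable:
    """Alternate-allele frequency per population per site.

    ``p = alt_allele_count / (2 * n_called)`` over non-missing diploid calls.
    Sites where any listed population has fewer than ``min_called`` called
    individuals are flagged ``retained = False`` and excluded downstream.
    """
    if populations is None:
        populations = gm.populations
    freq: dict[str, np.ndarray] = {}
    ncall: dict[str, np.ndarray] = {}
    for pop in populations:
        idx = gm.sample_indices(pop)
        sub = gm.calls[idx]
        called = sub != MISSING
        n = called.sum(axis=0)
        alt = np.where(called, sub, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, alt / (2.0 * np.maximum(n, 1)), np.nan)
        freq[pop] = p
        ncall[pop] = n
    site_ids = gm.sites["site_id"]
    freq_df = pd.DataFrame(freq, index=site_ids)
    n_df = pd.DataFrame(ncall, index=site_ids)
    retained = pd.Series((n_df >= min_called).all(axis=1), index=site_ids)
    return AlleleFreqTable(freq_df, n_df, retained, min_called, gm.sites.copy())


def genotype_frequencies(
    gm: GenotypeMatrix, populations: list[str] | None = None
) -> pd.DataFrame:
    """Fractions of Ref-homozygote / heterozygote / Var-homozygote per site.

    Returns a long frame (population, site_id, ref_hom, het, var_hom,
    n_called); fractions are NaN where no individual is called.
    """
    if populations is None:
        populations = gm.populations
    frames = []
    for pop in populations:
        idx = gm.sample_indices(pop)
        sub = gm.calls[idx]
        called = sub != MISSING
        n = called.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            ref_hom = (sub == 0).sum(axis=0) / n
            het = (sub == 1).sum(axis=0) / n
            var_hom = (sub == 2).sum(axis=0) / n
        frames.append(
            pd.DataFrame(
                {
                    "population": pop,
                    "site_id": gm.sites["site_id"].to_numpy(),
                    "ref_hom": ref_hom,
                    "het": het,
                    "var_hom": var_hom,
                    "n_called": n.astype(int),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
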