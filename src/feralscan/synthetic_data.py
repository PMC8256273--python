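"""Seeded synthetic data with planted truth for pipeline testing.

Generates (i) allele-frequency panels for five populations — a focal weedy
panel, a reference weedy panel, two cultivated panels and a wild panel —
scattered Balding-Nichols-style around shared ancestral frequencies, with a
set of planted near-fixed focal alleles; (ii) diploid genotypes under high
selfing (heterozygote deficit via an inbreeding coefficient F) with
independent site-by-sample missingness; (iii) stage-by-region RNA-seq count
matrices with planted fold-change genes; and (iv) a toy annotated genome so
planted SNPs can be placed in exons and UTRs of planted genes.

Everything is driven by a single integer seed and is deterministic; sites
are independent (no linkage) and no demography is simulated — the point is
a tunable genome-wide differentiation background, not realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .expression import CountMatrix
from .genotypes import MISSING, SITE_COLUMNS, GenotypeMatrix, write_pop_map, write_vcf
from .variant_effects import GeneModel, _revcomp

PANELS = ("focal_weedy", "ref_weedy", "cultivated_A", "cultivated_B", "wild")

# canonical mapping of synthetic panels onto the five field panels used in
# allele tracing: NE weedy, JS weedy, japonica, indica, wild rice
PANEL_ALIASES = {
    "focal_weedy": "NE_W",
    "ref_weedy": "JS_W",
    "cultivated_A": "JAP",
    "cultivated_B": "IND",
    "wild": "Wild",
}

_BASES = np.array(list("ACGT"))


@dataclass
class PopulationModel:
    """Sampling design for the genotype panels.

    ``background_divergence`` is the Balding-Nichols dispersion (an
    Fst-like quantity in (0, 1)); 0 means every panel shares the ancestral
    frequency exactly. ``selfing_F`` is the inbreeding coefficient (1 =
    complete selfing, no heterozygotes). 20 diploids per panel and strong
    selfing mirror a paddy-weed resequencing design.
    """

    panels: tuple[str, ...] = PANELS
    n_samples: int | dict = 20
    n_sites: int = 10_000
    background_divergence: float = 0.05
    selfing_F: float = 0.95
    missing_rate: float = 0.05
    seed: int = 0
    ancestral_beta: float = 0.8

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if not 0 <= self.background_divergence < 1:
            raise ValueError("background_divergence must be in [0, 1)")
        if not 0 <= self.selfing_F <= 1:
            raise ValueError("selfing_F must be in [0, 1]")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        for panel in self.panels:
            if self.samples_in(panel) < 1:
                raise ValueError(f"panel {panel} needs >= 1 sample")

    def samples_in(self, panel: str) -> int:
        if isinstance(self.n_samples, dict):
            return int(self.n_samples[panel])
        return int(self.n_samples)


@dataclass
class PlantedSignal:
    """Planted adaptive loci: near-fixed in the focal panel, rare elsewhere.

    ``focal_freq`` is the alt-allele frequency planted in the focal weedy
    panel; the same allele stays below ``ref_freq_max`` in the reference
    weedy and cultivated_A panels. ``standing_freq_wild`` /
    ``standing_freq_cultivated`` plant the standing-variation pattern (the
    allele pre-exists at low frequency in wild and cultivated genomes).
    """

    site_ids: tuple[int, ...] = ()
    focal_freq: float = 0.97
    ref_freq_max: float = 0.2
    standing_freq_wild: float = 0.05
    standing_freq_cultivated: float = 0.08

    def __post_init__(self) -> None:
        for name in ("focal_freq", "ref_freq_max", "standing_freq_wild",
                     "standing_freq_cultivated"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} outside [0, 1]")
        if self.focal_freq - self.ref_freq_max <= 0:
            raise ValueError("focal_freq must exceed ref_freq_max")
        self.site_ids = tuple(int(s) for s in self.site_ids)


def simulate_panel_frequencies(
    model: PopulationModel, signal: PlantedSignal | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw per-panel per-site allele frequencies plus a planted-truth table.

    Non-planted sites: ancestral frequency ~ symmetric Beta, each panel's
    frequency ~ Beta(p(1-d)/d, (1-p)(1-d)/d) with d = background
    divergence (all panels identical when d = 0). Planted sites override
    panel frequencies per the signal; the truth table records the planted
    site ids and the intended elevated allele (always 'alt').
    """
    rng = np.random.default_rng([model.seed, 0])
    a = model.ancestral_beta
    anc = rng.beta(a, a, size=model.n_sites)
    # keep Beta parameters strictly positive for the panel scatter
    anc = np.clip(anc, 1e-6, 1 - 1e-6)
    d = model.background_divergence
    freqs = pd.DataFrame(index=pd.RangeIndex(model.n_sites, name="site"))
    for panel in model.panels:
        if d == 0:
            freqs[panel] = anc
        else:
            freqs[panel] = rng.beta(anc * (1 - d) / d, (1 - anc) * (1 - d) / d)

    truth = pd.DataFrame(
        columns=["site", "elevated_allele", *model.panels]
    )
    if signal is not None and signal.site_ids:
        ids = np.asarray(signal.site_ids)
        if ids.min() < 0 or ids.max() >= model.n_sites:
            raise IndexError("planted site id out of range")
        k = len(ids)
        planted = {
            "focal_weedy": np.full(k, signal.focal_freq),
            "ref_weedy": rng.uniform(0.0, signal.ref_freq_max, size=k),
            "cultivated_A": np.minimum(
                np.full(k, signal.standing_freq_cultivated), signal.ref_freq_max
            ),
            "cultivated_B": np.full(k, signal.standing_freq_cultivated),
            "wild": np.full(k, signal.standing_freq_wild),
        }
        for panel in model.panels:
            if panel in planted:
                freqs.loc[ids, panel] = planted[panel]
        truth = pd.DataFrame({"site": ids, "elevated_allele": "alt"})
        for panel in model.panels:
            truth[panel] = freqs.loc[ids, panel].to_numpy()
    return freqs, truth


def default_sites(n_sites: int, seed: int, chrom: str = "chr1") -> pd.DataFrame:
    """Site frame with evenly spaced positions and random ref/alt bases."""
    rng = np.random.default_rng([seed, 7])
    ref_i = rng.integers(0, 4, size=n_sites)
    alt_i = (ref_i + rng.integers(1, 4, size=n_sites)) % 4
    pos = np.arange(1, n_sites + 1) * 10
    return pd.DataFrame(
        {
            "site_id": [f"{chrom}:{p}" for p in pos],
            "chrom": chrom,
            "pos": pos,
            "ref": _BASES[ref_i],
            "alt": _BASES[alt_i],
        }
    )


def sample_genotypes(
    freqs: pd.DataFrame,
    model: PopulationModel,
    sites: pd.DataFrame | None = None,
) -> GenotypeMatrix:
    """Draw diploid genotypes with a heterozygote deficit.

    P(het) = 2p(1-p)(1-F); the homozygote classes absorb the remainder
    (P(alt hom) = p^2 + F p(1-p)). Missing calls are inserted independently
    at ``missing_rate``.
    """
    fv = freqs.to_numpy() if isinstance(freqs, pd.DataFrame) else np.asarray(freqs)
    if np.any((fv < 0) | (fv > 1)):
        raise ValueError("frequencies outside [0, 1]")
    rng = np.random.default_rng([model.seed, 1])
    F = model.selfing_F
    n_sites = len(freqs)
    if sites is None:
        sites = default_sites(n_sites, model.seed)

    calls_blocks, samples, pop_map = [], [], {}
    for panel in model.panels:
        p = np.asarray(freqs[panel], dtype=float)
        n = model.samples_in(panel)
        hom_alt = p**2 + F * p * (1 - p)
        het = 2 * p * (1 - p) * (1 - F)
        u = rng.random((n, n_sites))
        g = np.where(u < hom_alt, 2, np.where(u < hom_alt + het, 1, 0)).astype(np.int8)
        if model.missing_rate > 0:
            g[rng.random((n, n_sites)) < model.missing_rate] = MISSING
        calls_blocks.append(g)
        ids = [f"{panel}_{i:03d}" for i in range(n)]
        samples.extend(ids)
        pop_map.update({s: panel for s in ids})
    return GenotypeMatrix(np.vstack(calls_blocks), samples, sites, pop_map)


@dataclass
class ExpressionDesign:
    """Design of the synthetic germination RNA-seq experiment.

    One library per region x stage (two north-eastern regions and one
    eastern region, three germination stages), as in a single-library-per-
    condition sequencing design. ``planted_degs`` lists (gene_id, stage,
    fold) rows; the fold multiplies the mean of BOTH NE libraries relative
    to the E library at that stage (fold > 1 = up-regulated in NE).
    ``overdispersion`` is the negative-binomial dispersion (variance =
    mu + phi mu^2); 0 gives Poisson counts.
    """

    n_genes: int = 2000
    regions: tuple[str, ...] = ("NE_a", "NE_b", "E")
    e_region: str = "E"
    stages: tuple[int, ...] = (1, 2, 3)
    library_size: float | dict = 2_000_000.0
    gene_lengths: np.ndarray | None = None
    planted_degs: pd.DataFrame | None = None
    overdispersion: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.overdispersion < 0:
            raise ValueError("overdispersion must be >= 0")
        libs = (self.library_size.values() if isinstance(self.library_size, dict)
                else [self.library_size])
        if any(l <= 0 for l in libs):
            raise ValueError("library sizes must be positive")
        if self.gene_lengths is not None and np.any(np.asarray(self.gene_lengths) <= 0):
            raise ValueError("gene lengths must be positive")
        if self.planted_degs is not None and (self.planted_degs["fold"] <= 0).any():
            raise ValueError("fold changes must be positive")

    def lib_for(self, sample: str) -> float:
        if isinstance(self.library_size, dict):
            return float(self.library_size[sample])
        return float(self.library_size)


def simulate_counts(
    design: ExpressionDesign, gene_ids: list[str] | None = None
) -> tuple[CountMatrix, pd.DataFrame]:
    """Draw the count matrix and return it with the planted-DEG truth table.

    Gene means are library_size x expression-weight x fold; weights are
    log-normal and sum to one at baseline, so expected counts sum roughly
    to the library size.
    """
    rng = np.random.default_rng([design.seed, 2])
    g = design.n_genes
    if gene_ids is None:
        gene_ids = [f"gene{i:05d}" for i in range(g)]
    if len(gene_ids) != g:
        raise ValueError("gene_ids length mismatch")
    lengths = (
        np.asarray(design.gene_lengths)
        if design.gene_lengths is not None
        else rng.integers(300, 5000, size=g)
    )
    w = rng.lognormal(mean=0.0, sigma=1.0, size=g)
    w = w / w.sum()

    fold = {}  # (stage -> per-gene fold vector for NE libraries)
    for stage in design.stages:
        fold[stage] = np.ones(g)
    truth_rows = []
    if design.planted_degs is not None:
        gene_pos = {gid: i for i, gid in enumerate(gene_ids)}
        for row in design.planted_degs.itertuples(index=False):
            fold[row.stage][gene_pos[row.gene_id]] = row.fold
            truth_rows.append(
                (row.gene_id, row.stage, row.fold, "up" if row.fold > 1 else "down")
            )
    truth = pd.DataFrame(
        truth_rows, columns=["gene_id", "stage", "fold", "direction"]
    )

    counts = {}
    sheet_rows = []
    phi = design.overdispersion
    for stage in design.stages:
        for region in design.regions:
            sample = f"{region}_s{stage}"
            lib = design.lib_for(sample)
            f = fold[stage] if region != design.e_region else np.ones(g)
            mu = lib * w * f
            if phi == 0:
                c = rng.poisson(mu)
            else:
                shape = 1.0 / phi
                c = rng.poisson(rng.gamma(shape, mu / shape))
            counts[sample] = c
            sheet_rows.append((sample, region, stage))
    cm = CountMatrix(
        pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id")),
        pd.Series(lengths, index=gene_ids, name="length_bp"),
        pd.DataFrame(sheet_rows, columns=["sample", "region", "stage"]),
    )
    return cm, truth


def write_fixture_bundle(
    gm: GenotypeMatrix,
    out_dir: str | Path,
    counts: CountMatrix | None = None,
    truth: dict[str, pd.DataFrame] | None = None,
) -> dict[str, Path]:
    """Write VCF + population map (+ counts, sample sheet, truth tables).

    Round-trips through :func:`feralscan.genotypes.read_vcf` and
    :func:`feralscan.expression.read_counts`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "genotypes.vcf",
        "pop_map": out / "pop_map.tsv",
    }
    write_vcf(gm, paths["vcf"])
    write_pop_map(gm.pop_map, paths["pop_map"])
    if counts is not None:
        paths["counts"] = out / "counts.tsv"
        paths["sample_sheet"] = out / "sample_sheet.tsv"
        counts.to_tsv(paths["counts"], paths["sample_sheet"])
    for name, table in (truth or {}).items():
        paths[f"truth_{name}"] = out / f"truth_{name}.tsv"
        table.to_csv(paths[f"truth_{name}"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# toy annotated genome


def simulate_annotated_genome(
    n_genes: int = 20,
    seed: int = 0,
    chrom: str = "chr1",
    codons_range: tuple[int, int] = (20, 80),
    max_cds_exons: int = 3,
) -> tuple[dict[str, str], list[GeneModel]]:
    """Random toy genome: one chromosome of spaced genes on both strands.

    Each gene has a 5' UTR, 1..max_cds_exons CDS exons (total length a
    multiple of 3) separated by introns, and a 3' UTR. Returns the sequence
    dict and gene models (genomic-coordinate intervals, 0-based half-open).
    """
    rng = np.random.default_rng([seed, 3])
    seq_parts: list[str] = []
    genes: list[GeneModel] = []
    cursor = 0
    for i in range(n_genes):
        gap = int(rng.integers(100, 301))
        cursor += gap
        strand = "+" if rng.random() < 0.5 else "-"
        utr_a = int(rng.integers(30, 91))
        utr_b = int(rng.integers(30, 91))
        n_codons = int(rng.integers(*codons_range))
        n_ex = int(rng.integers(1, max_cds_exons + 1))
        cds_total = 3 * n_codons
        cuts = np.sort(rng.choice(np.arange(1, cds_total), size=n_ex - 1,
                                  replace=False)) if n_ex > 1 else np.array([], int)
        exon_lens = np.diff(np.concatenate([[0], cuts, [cds_total]]))
        intron_lens = rng.integers(50, 151, size=n_ex - 1)

        left_utr = (cursor, cursor + utr_a)
        pos = left_utr[1]
        cds = []
        for j, el in enumerate(exon_lens):
            cds.append((pos, pos + int(el)))
            pos += int(el)
            if j < n_ex - 1:
                pos += int(intron_lens[j])
        right_utr = (pos, pos + utr_b)
        cursor = right_utr[1]
        utr5, utr3 = (
            ([left_utr], [right_utr]) if strand == "+" else ([right_utr], [left_utr])
        )
        genes.append(
            GeneModel(f"g{i:03d}", chrom, strand, cds, utr5=utr5, utr3=utr3)
        )
    total_len = cursor + 200
    seq = "".join(rng.choice(_BASES, size=total_len))
    return {chrom: seq}, genes


def write_genome(
    seqs: dict[str, str],
    genes: list[GeneModel],
    fasta_path: str | Path,
    gff_path: str | Path,
) -> None:
    """Write the toy genome as FASTA + GFF3 (gene/mRNA/UTR/CDS features)."""
    with open(fasta_path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, seq in seqs.items():
            fh.write(f"##sequence-region {name} 1 {len(seq)}\n")
        for m in genes:
            s, e = m.span
            fh.write(
                f"{m.chrom}\tsynthetic\tgene\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id}\n"
            )
            tid = f"{m.gene_id}.1"
            fh.write(
                f"{m.chrom}\tsynthetic\tmRNA\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                f"ID={tid};Parent={m.gene_id}\n"
            )
            for us, ue in m.utr5:
                fh.write(
                    f"{m.chrom}\tsynthetic\tfive_prime_UTR\t{us + 1}\t{ue}\t.\t"
                    f"{m.strand}\t.\tParent={tid}\n"
                )
            cds_tx = m.cds if m.strand == "+" else list(reversed(m.cds))
            phase, rows = 0, []
            for cs, ce in cds_tx:
                rows.append((cs, ce, phase))
                phase = (3 - ((ce - cs) - phase) % 3) % 3
            for cs, ce, ph in sorted(rows):
                fh.write(
                    f"{m.chrom}\tsynthetic\tCDS\t{cs + 1}\t{ce}\t.\t"
                    f"{m.strand}\t{ph}\tParent={tid}\n"
                )
            for us, ue in m.utr3:
                fh.write(
                    f"{m.chrom}\tsynthetic\tthree_prime_UTR\t{us + 1}\t{ue}\t.\t"
                    f"{m.strand}\t.\tParent={tid}\n"
                )


def _codon_change(seq: str, m: GeneModel, pos0: int, alt: str) -> tuple[str, str]:
    """Generator-side codon walk (kept independent of the classifier):
    amino acid before/after substituting ``alt`` at genomic ``pos0``."""
    parts = "".join(seq[s:e] for s, e in m.cds)
    offs = [i for s, e in m.cds for i in range(s, e)]
    if m.strand == "-":
        parts = _revcomp(parts)
        offs = offs[::-1]
    k = offs.index(pos0)
    base = alt if m.strand == "+" else _revcomp(alt)
    mutated = parts[:k] + base + parts[k + 1 :]
    ci = k // 3
    return (
        str(Seq(parts[ci * 3 : ci * 3 + 3]).translate()),
        str(Seq(mutated[ci * 3 : ci * 3 + 3]).translate()),
    )


def place_coding_snp(
    seqs: dict[str, str],
    m: GeneModel,
    rng: np.random.Generator,
    want: str = "nonsynonymous",
) -> tuple[int, str, str]:
    """Pick a CDS position and alt allele with the requested coding effect
    ('nonsynonymous' or 'synonymous'). Returns (pos0, ref, alt)."""
    seq = seqs[m.chrom]
    cds_positions = [i for s, e in m.cds for i in range(s, e)]
    for _ in range(500):
        pos0 = int(rng.choice(cds_positions))
        ref = seq[pos0]
        for alt in rng.permutation([b for b in "ACGT" if b != ref]):
            aa_b, aa_a = _codon_change(seq, m, pos0, alt)
            if aa_b == "*":
                continue
            if want == "nonsynonymous" and aa_a not in (aa_b, "*"):
                return pos0, ref, alt
            if want == "synonymous" and aa_a == aa_b:
                return pos0, ref, alt
    raise RuntimeError(f"could not place a {want} SNP in {m.gene_id}")


def place_utr_snp(
    seqs: dict[str, str], m: GeneModel, rng: np.random.Generator
) -> tuple[int, str, str]:
    """Pick a UTR position and any alternate base. Returns (pos0, ref, alt)."""
    utr_positions = [i for s, e in m.utr5 + m.utr3 for i in range(s, e)]
    pos0 = int(rng.choice(utr_positions))
    ref = seqs[m.chrom][pos0]
    alt = str(rng.choice([b for b in "ACGT" if b != ref]))
    return pos0, ref, alt


# ---------------------------------------------------------------------------
# end-to-end joint fixture


@dataclass
class JointFixture:
    """File paths and planted truth for the end-to-end fixture."""

    paths: dict[str, Path]
    joint_genes: list[str]
    planted_sites: pd.DataFrame  # site_id, gene_id, placement, role
    deg_truth: pd.DataFrame
    freq_truth: pd.DataFrame


def simulate_joint_fixture(
    out_dir: str | Path,
    seed: int = 0,
    n_genes: int = 200,
    n_joint: int = 12,
    n_background_sites: int = 600,
    n_samples: int = 20,
    selfing_F: float = 0.95,
    missing_rate: float = 0.03,
    background_divergence: float = 0.02,
    library_size: float = 500_000.0,
    fold: float = 4.0,
) -> JointFixture:
    """Write a complete fixture where ``n_joint`` genes carry BOTH a planted
    exon/UTR adaptive SNP and planted pre-germination up-regulation.

    Decoys are included deliberately: genes with a planted adaptive SNP but
    no expression change, genes up-regulated but without any adaptive SNP,
    and one up-regulated gene whose only adaptive SNP is synonymous (it must
    be excluded by the exon/UTR filter). Background differentiation sites
    are intergenic, so the gene-level ground truth is exactly the planted
    one. The joint genes are the ground truth for candidate-gene recovery.
    """
    rng = np.random.default_rng([seed, 4])
    seqs, genes = simulate_annotated_genome(n_genes=n_genes, seed=seed)
    gene_ids = [m.gene_id for m in genes]
    by_id = {m.gene_id: m for m in genes}

    order = list(rng.permutation(gene_ids))
    joint = sorted(order[:n_joint])
    snp_only = sorted(order[n_joint : n_joint + 3])
    deg_only = sorted(order[n_joint + 3 : n_joint + 6])
    syn_decoy = order[n_joint + 6]

    # --- genotype side: planted SNPs in joint/decoy genes + background sites
    planted_rows = []
    for gid in joint:
        placement = "utr" if rng.random() < 0.5 else "cds"
        if placement == "utr":
            pos0, ref, alt = place_utr_snp(seqs, by_id[gid], rng)
        else:
            pos0, ref, alt = place_coding_snp(seqs, by_id[gid], rng, "nonsynonymous")
        planted_rows.append((gid, pos0, ref, alt, placement, "joint"))
    for gid in snp_only:
        pos0, ref, alt = place_utr_snp(seqs, by_id[gid], rng)
        planted_rows.append((gid, pos0, ref, alt, "utr", "snp_only"))
    pos0, ref, alt = place_coding_snp(seqs, by_id[syn_decoy], rng, "synonymous")
    planted_rows.append((syn_decoy, pos0, ref, alt, "cds_synonymous", "syn_decoy"))

    chrom = genes[0].chrom
    genome_len = len(seqs[chrom])
    genic = np.zeros(genome_len, dtype=bool)
    for m in genes:
        s, e = m.span
        genic[s:e] = True
    intergenic = np.flatnonzero(~genic)
    used = {r[1] for r in planted_rows}
    bg_pos0: list[int] = []
    while len(bg_pos0) < n_background_sites:
        cand = int(rng.choice(intergenic))
        if cand not in used:
            used.add(cand)
            bg_pos0.append(cand)
    site_rows = []
    for gid, p0, ref, alt, placement, role in planted_rows:
        site_rows.append((f"{chrom}:{p0 + 1}", chrom, p0 + 1, ref, alt, True, gid, placement, role))
    for p0 in bg_pos0:
        ref = seqs[chrom][p0]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        site_rows.append((f"{chrom}:{p0 + 1}", chrom, p0 + 1, ref, alt, False, None, None, "background"))
    site_df = pd.DataFrame(
        site_rows,
        columns=SITE_COLUMNS + ["planted", "gene_id", "placement", "role"],
    ).sort_values("pos", kind="stable").reset_index(drop=True)

    model = PopulationModel(
        n_samples=n_samples,
        n_sites=len(site_df),
        background_divergence=background_divergence,
        selfing_F=selfing_F,
        missing_rate=missing_rate,
        seed=seed,
    )
    signal = PlantedSignal(site_ids=tuple(site_df.index[site_df["planted"]]))
    freqs, freq_truth = simulate_panel_frequencies(model, signal)
    freq_truth = freq_truth.merge(
        site_df[["site_id", "gene_id", "role"]],
        left_on="site", right_index=True, how="left",
    )
    gm = sample_genotypes(freqs, model, sites=site_df[SITE_COLUMNS])

    # --- expression side: up-regulation at pre-germination stages (1, 2)
    deg_rows = []
    for gid in joint + deg_only + [syn_decoy]:
        for stage in (1, 2):
            deg_rows.append((gid, stage, fold))
    design = ExpressionDesign(
        n_genes=len(gene_ids),
        library_size=library_size,
        gene_lengths=np.array([m.cds_length for m in genes]),
        planted_degs=pd.DataFrame(deg_rows, columns=["gene_id", "stage", "fold"]),
        overdispersion=0.0,
        seed=seed,
    )
    cm, deg_truth = simulate_counts(design, gene_ids=gene_ids)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fasta, gff = out / "genome.fa", out / "genes.gff3"
    write_genome(seqs, genes, fasta, gff)
    paths = write_fixture_bundle(
        gm,
        out,
        counts=cm,
        truth={
            "planted_sites": site_df[site_df["planted"]][
                ["site_id", "gene_id", "placement", "role"]
            ],
            "deg": deg_truth,
        },
    )
    paths["fasta"] = fasta
    paths["gff"] = gff
    return JointFixture(
        paths=paths,
        joint_genes=joint,
        planted_sites=site_df[site_df["planted"]][
            ["site_id", "gene_id", "placement", "role"]
        ].reset_index(drop=True),
        deg_truth=deg_truth,
        freq_truth=freq_truth,
    )
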