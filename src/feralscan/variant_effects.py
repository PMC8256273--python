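"""SNP effect classification against gene models.

A lightweight annotator for the exon/UTR filter: each biallelic SNP is
classified as nonsynonymous / synonymous / stop_gain / stop_loss (coding),
utr5 / utr3, intronic, or intergenic, from GFF3 gene models and a FASTA
reference. One representative transcript per gene (the one with the longest
total CDS) is used, so gene-level rollups are well defined.

Coordinates are converted from GFF 1-based inclusive to 0-based half-open
exactly once, at parse time; everything internal is half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

CODING_EFFECTS = {"nonsynonymous", "synonymous", "stop_gain", "stop_loss"}
EXON_UTR_EFFECTS = {"nonsynonymous", "stop_gain", "stop_loss", "utr5", "utr3"}

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


@dataclass
class GeneModel:
    """One gene with a representative transcript's CDS and UTR intervals.

    Intervals are 0-based half-open ``(start, end)`` tuples in genomic
    coordinates, sorted by start. ``usable`` is False when the spliced CDS
    length is not a multiple of 3 (coding classification is then refused
    for this gene, but UTR/intron membership still applies).
    """

    gene_id: str
    chrom: str
    strand: str
    cds: list[tuple[int, int]]
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)
    usable: bool = True

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        self.cds = sorted(self.cds)
        self.utr5 = sorted(self.utr5)
        self.utr3 = sorted(self.utr3)
        if self.cds_length % 3 != 0:
            self.usable = False

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def span(self) -> tuple[int, int]:
        ivs = self.cds + self.utr5 + self.utr3
        return (min(s for s, _ in ivs), max(e for _, e in ivs))

    def spliced_cds(self, reference) -> str:
        """Coding sequence 5'->3' (reverse-complemented on minus strand)."""
        parts = [_fetch(reference, self.chrom, s, e) for s, e in self.cds]
        seq = "".join(parts)
        return _revcomp(seq) if self.strand == "-" else seq

    def cds_offset(self, pos0: int) -> int | None:
        """0-based offset of genomic position ``pos0`` within the spliced
        CDS (transcription order), or None if not in the CDS."""
        off = 0
        for s, e in self.cds:
            if s <= pos0 < e:
                plus_off = off + (pos0 - s)
                if self.strand == "+":
                    return plus_off
                return self.cds_length - 1 - plus_off
            off += e - s
        return None


def _fetch(reference, chrom: str, start: int, end: int) -> str:
    """Slice ``reference[chrom][start:end]`` for pyfaidx Fasta or plain
    dict-of-strings references."""
    seg = reference[chrom][start:end]
    return str(getattr(seg, "seq", seg)).upper()


def load_gene_models(
    gff_path: str | Path, fasta_path: str | Path
) -> tuple[list[GeneModel], object]:
    """Parse GFF3 gene models and open the reference FASTA.

    One representative transcript per gene (longest total CDS). Genes whose
    CDS extends beyond the contig end, or whose CDS length is not a multiple
    of 3, are flagged unusable for coding classification.
    """
    import gffutils
    from pyfaidx import Fasta

    db = gffutils.create_db(
        str(gff_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    reference = Fasta(str(fasta_path), as_raw=False)
    contig_len = {name: len(reference[name]) for name in reference.keys()}

    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        best: tuple[int, object] | None = None
        for mrna in db.children(gene, featuretype="mRNA"):
            cds_len = sum(
                c.end - c.start + 1 for c in db.children(mrna, featuretype="CDS")
            )
            if best is None or cds_len > best[0]:
                best = (cds_len, mrna)
        if best is None or best[0] == 0:
            continue
        mrna = best[1]
        cds = [(c.start - 1, c.end) for c in db.children(mrna, featuretype="CDS")]
        utr5 = [
            (u.start - 1, u.end)
            for u in db.children(mrna, featuretype="five_prime_UTR")
        ]
        utr3 = [
            (u.start - 1, u.end)
            for u in db.children(mrna, featuretype="three_prime_UTR")
        ]
        model = GeneModel(gene.id, gene.seqid, gene.strand, cds, utr5, utr3)
        if model.span[1] > contig_len.get(gene.seqid, 0):
            model.usable = False
            logger.warning("gene %s extends past contig end; flagged", gene.id)
        if not model.usable:
            logger.warning(
                "gene %s unusable for coding classification", gene.id
            )
        models.append(model)
    return models, reference


def _gene_trees(models: list[GeneModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for m in models:
        s, e = m.span
        trees.setdefault(m.chrom, IntervalTree()).addi(s, e, m)
    return trees


def classify_snp(
    site, models: list[GeneModel] | dict[str, IntervalTree], reference
) -> list[dict]:
    """Classify one SNP; one record per overlapping gene.

    ``site`` needs attributes/keys chrom, pos (1-based), ref, alt, site_id.
    If the stated ref allele does not match the reference base the record
    carries effect ``ref_mismatch`` (never silently reinterpreted).
    """
    trees = models if isinstance(models, dict) else _gene_trees(models)
    get = site.get if isinstance(site, dict) else lambda k: getattr(site, k)
    chrom, pos, ref, alt = get("chrom"), int(get("pos")), get("ref"), get("alt")
    site_id = get("site_id")
    pos0 = pos - 1

    base = _fetch(reference, chrom, pos0, pos0 + 1)
    if base != ref.upper():
        return [
            {
                "site_id": site_id,
                "gene_id": None,
                "effect": "ref_mismatch",
                "codon_before": None,
                "codon_after": None,
            }
        ]

    hits = sorted(trees.get(chrom, IntervalTree())[pos0], key=lambda iv: iv.data.gene_id)
    if not hits:
        return [
            {
                "site_id": site_id,
                "gene_id": None,
                "effect": "intergenic",
                "codon_before": None,
                "codon_after": None,
            }
        ]

    records = []
    for iv in hits:
        m: GeneModel = iv.data
        effect, cod_b, cod_a = _classify_in_gene(m, pos0, alt, reference)
        records.append(
            {
                "site_id": site_id,
                "gene_id": m.gene_id,
                "effect": effect,
                "codon_before": cod_b,
                "codon_after": cod_a,
            }
        )
    return records


def _classify_in_gene(m: GeneModel, pos0: int, alt: str, reference):
    off = m.cds_offset(pos0)
    if off is not None:
        if not m.usable:
            return "unusable_gene", None, None
        cds = m.spliced_cds(reference)
        codon_i = off // 3
        within = off % 3
        before = cds[codon_i * 3 : codon_i * 3 + 3]
        alt_sense = _revcomp(alt).upper() if m.strand == "-" else alt.upper()
        after = before[:within] + alt_sense + before[within + 1 :]
        aa_b = str(Seq(before).translate())
        aa_a = str(Seq(after).translate())
        if aa_b == aa_a:
            effect = "synonymous"
        elif aa_a == "*":
            effect = "stop_gain"
        elif aa_b == "*":
            effect = "stop_loss"
        else:
            effect = "nonsynonymous"
        return effect, before, after
    for s, e in m.utr5:
        if s <= pos0 < e:
            return "utr5", None, None
    for s, e in m.utr3:
        if s <= pos0 < e:
            return "utr3", None, None
    return "intronic", None, None


def classify_variants(
    sites: pd.DataFrame, models: list[GeneModel], reference
) -> pd.DataFrame:
    """Vector convenience: classify every row of a sites frame
    (site_id, chrom, pos, ref, alt); returns the effect table."""
    trees = _gene_trees(models)
    records: list[dict] = []
    for site in sites.itertuples(index=False):
        records.extend(classify_snp(site, trees, reference))
    return pd.DataFrame(
        records,
        columns=["site_id", "gene_id", "effect", "codon_before", "codon_after"],
    )


def exon_utr_filter(effects: pd.DataFrame) -> set[tuple]:
    """Keep (site_id, gene_id) pairs whose effect is amino-acid-changing or
    in a UTR; synonymous, intronic and intergenic records are dropped."""
    keep = effects["effect"].isin(EXON_UTR_EFFECTS)
    return set(
        zip(effects.loc[keep, "site_id"], effects.loc[keep, "gene_id"])
    )
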