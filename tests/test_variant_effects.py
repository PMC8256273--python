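import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from feralscan import synthetic_data as sd
from feralscan.variant_effects import (
    GeneModel,
    classify_snp,
    classify_variants,
    exon_utr_filter,
    load_gene_models,
)

COMP = str.maketrans("ACGT", "TGCA")


def revcomp(s):
    return s.translate(COMP)[::-1]


def oracle_coding_effect(seq, gene, pos0, alt):
    """Brute-force codon walk, independent of the classifier: concatenate
    CDS bases in transcription order, substitute, translate both codons."""
    cds_bases = [(i, seq[i]) for s, e in gene.cds for i in range(s, e)]
    if gene.strand == "-":
        cds_bases = [(i, b.translate(COMP)) for i, b in reversed(cds_bases)]
        alt = alt.translate(COMP)
    positions = [i for i, _ in cds_bases]
    bases = "".join(b for _, b in cds_bases)
    k = positions.index(pos0)
    mutated = bases[:k] + alt + bases[k + 1 :]
    ci = k // 3
    aa_before = str(Seq(bases[ci * 3 : ci * 3 + 3]).translate())
    aa_after = str(Seq(mutated[ci * 3 : ci * 3 + 3]).translate())
    if aa_before == aa_after:
        return "synonymous"
    if aa_after == "*":
        return "stop_gain"
    if aa_before == "*":
        return "stop_loss"
    return "nonsynonymous"


def flip_genome(seqs, genes):
    """Reverse-complement every chromosome and mirror all annotations."""
    flipped_seqs = {c: revcomp(s) for c, s in seqs.items()}
    flipped_genes = []
    for g in genes:
        L = len(seqs[g.chrom])
        mirror = lambda iv: (L - iv[1], L - iv[0])
        flipped_genes.append(
            GeneModel(
                g.gene_id,
                g.chrom,
                "-" if g.strand == "+" else "+",
                [mirror(iv) for iv in g.cds],
                utr5=[mirror(iv) for iv in g.utr5],
                utr3=[mirror(iv) for iv in g.utr3],
            )
        )
    return flipped_seqs, flipped_genes


def _site(chrom, pos, ref, alt):
    return {"site_id": f"{chrom}:{pos}", "chrom": chrom, "pos": pos,
            "ref": ref, "alt": alt}


class TestLoadGeneModels:
    def test_roundtrip_preserves_intervals(self, toy_genome):
        models, _ = load_gene_models(toy_genome["gff"], toy_genome["fasta"])
        by_id = {m.gene_id: m for m in models}
        assert len(models) == len(toy_genome["genes"])
        for g in toy_genome["genes"]:
            m = by_id[g.gene_id]
            assert (m.strand, m.cds, m.utr5, m.utr3) == (
                g.strand, g.cds, g.utr5, g.utr3
            )

    def test_spliced_cds_length_sums_exons(self, toy_genome):
        models, ref = load_gene_models(toy_genome["gff"], toy_genome["fasta"])
        for m in models:
            assert len(m.spliced_cds(ref)) == sum(e - s for s, e in m.cds)
            assert m.cds_length % 3 == 0

    def test_minus_strand_is_reverse_complement(self, toy_genome):
        models, ref = load_gene_models(toy_genome["gff"], toy_genome["fasta"])
        seq = toy_genome["seqs"]["chr1"]
        for m in models:
            plus = "".join(seq[s:e] for s, e in m.cds)
            expected = revcomp(plus) if m.strand == "-" else plus
            assert m.spliced_cds(ref) == expected

    def test_cds_not_multiple_of_three_flagged(self):
        m = GeneModel("bad", "chr1", "+", [(10, 14)])
        assert not m.usable


class TestClassifySnp:
    def test_intergenic(self, toy_genome):
        models, ref = load_gene_models(toy_genome["gff"], toy_genome["fasta"])
        # genome starts with a 100+ bp intergenic gap
        base = toy_genome["seqs"]["chr1"][0]
        alt = "A" if base != "A" else "C"
        recs = classify_snp(_site("chr1", 1, base, alt), models, ref)
        assert len(recs) == 1 and recs[0]["effect"] == "intergenic"

    def test_handcrafted_synonymous_third_position(self, tmp_path):
        # + strand gene, CDS = GGA GGA GGA; A->G at a codon third position
        # keeps glycine
        seq = "T" * 10 + "GGAGGAGGA" + "T" * 10
        gene = GeneModel("g1", "chr1", "+", [(10, 19)],
                         utr5=[(5, 10)], utr3=[(19, 24)])
        recs = classify_snp(
            _site("chr1", 13, "A", "G"), [gene], {"chr1": seq}
        )
        assert recs[0]["effect"] == "synonymous"
        assert recs[0]["codon_before"] == "GGA"
        assert recs[0]["codon_after"] == "GGG"

    def test_utr_and_intron_membership(self, tmp_path):
        seq = "T" * 10 + "GGAGGAGGA" + "T" * 10
        gene = GeneModel("g1", "chr1", "+", [(10, 19)],
                         utr5=[(5, 10)], utr3=[(19, 24)])
        for pos, effect in ((6, "utr5"), (20, "utr3")):
            recs = classify_snp(_site("chr1", pos, "T", "A"), [gene], {"chr1": seq})
            assert recs[0]["effect"] == effect

    def test_ref_mismatch_reported_not_silent(self, toy_genome):
        models, ref = load_gene_models(toy_genome["gff"], toy_genome["fasta"])
        seq = toy_genome["seqs"]["chr1"]
        base = seq[50]
        wrong = "A" if base != "A" else "C"
        recs = classify_snp(_site("chr1", 51, wrong, base), models, ref)
        assert recs[0]["effect"] == "ref_mismatch"

    def test_coding_classification_matches_translation_oracle(self, toy_genome):
        models, ref = load_gene_models(toy_genome["gff"], toy_genome["fasta"])
        seq = toy_genome["seqs"]["chr1"]
        rng = np.random.default_rng(6)
        for m in models:
            cds_positions = [i for s, e in m.cds for i in range(s, e)]
            for pos0 in rng.choice(cds_positions, 5, replace=False):
                pos0 = int(pos0)
                refb = seq[pos0]
                alt = str(rng.choice([b for b in "ACGT" if b != refb]))
                recs = classify_snp(
                    _site("chr1", pos0 + 1, refb, alt), [m], ref
                )
                assert recs[0]["effect"] == oracle_coding_effect(seq, m, pos0, alt)

    def test_strand_flip_invariance(self):
        seqs, genes = sd.simulate_annotated_genome(n_genes=8, seed=13)
        seq = seqs["chr1"]
        L = len(seq)
        fseqs, fgenes = flip_genome(seqs, genes)
        rng = np.random.default_rng(14)
        for g, fg in zip(genes, fgenes):
            span = range(g.span[0], g.span[1])
            for pos0 in rng.choice(list(span), 8, replace=False):
                pos0 = int(pos0)
                refb = seq[pos0]
                alt = str(rng.choice([b for b in "ACGT" if b != refb]))
                fwd = classify_snp(_site("chr1", pos0 + 1, refb, alt), [g], seqs)
                fpos0 = L - 1 - pos0
                rev = classify_snp(
                    _site("chr1", fpos0 + 1, refb.translate(COMP),
                          alt.translate(COMP)),
                    [fg], fseqs,
                )
                assert fwd[0]["effect"] == rev[0]["effect"]

    def test_every_cds_snp_gets_exactly_one_coding_class(self, toy_genome):
        models, ref = load_gene_models(toy_genome["gff"], toy_genome["fasta"])
        seq = toy_genome["seqs"]["chr1"]
        m = models[0]
        coding = {"synonymous", "nonsynonymous", "stop_gain", "stop_loss"}
        for pos0 in [i for s, e in m.cds for i in range(s, e)][:30]:
            refb = seq[pos0]
            alt = "A" if refb != "A" else "G"
            recs = [
                r for r in classify_snp(_site("chr1", pos0 + 1, refb, alt), [m], ref)
                if r["gene_id"] == m.gene_id
            ]
            assert len(recs) == 1 and recs[0]["effect"] in coding


class TestExonUtrFilter:
    def test_all_intergenic_empty(self):
        eff = pd.DataFrame(
            {"site_id": ["a", "b"], "gene_id": [None, None],
             "effect": ["intergenic", "intergenic"],
             "codon_before": None, "codon_after": None}
        )
        assert exon_utr_filter(eff) == set()

    def test_mixed_set_hand_enumeration(self):
        eff = pd.DataFrame(
            {
                "site_id": ["s1", "s2", "s3", "s4", "s5", "s6", "s7"],
                "gene_id": ["g1", "g1", "g2", "g2", "g3", None, "g4"],
                "effect": [
                    "nonsynonymous", "synonymous", "utr5", "intronic",
                    "utr3", "intergenic", "stop_gain",
                ],
            }
        )
        assert exon_utr_filter(eff) == {
            ("s1", "g1"), ("s3", "g2"), ("s5", "g3"), ("s7", "g4")
        }

    def test_overlapping_genes_keep_utr_copy_only(self):
        # one SNP annotated in two overlapping genes: in the UTR of one,
        # in an intron of the other -> retained once, for the UTR gene
        eff = pd.DataFrame(
            {
                "site_id": ["s1", "s1"],
                "gene_id": ["gA", "gB"],
                "effect": ["utr3", "intronic"],
            }
        )
        assert exon_utr_filter(eff) == {("s1", "gA")}

    def test_overlapping_genes_both_records_emitted(self):
        seq = "T" * 10 + "GGAGGAGGA" + "T" * 30
        gA = GeneModel("gA", "chr1", "+", [(10, 19)], utr3=[(19, 30)])
        gB = GeneModel("gB", "chr1", "+", [(15, 18), (33, 39)])
        recs = classify_snp(_site("chr1", 21, "T", "A"), [gA, gB], {"chr1": seq})
        by_gene = {r["gene_id"]: r["effect"] for r in recs}
        assert by_gene == {"gA": "utr3", "gB": "intronic"}
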