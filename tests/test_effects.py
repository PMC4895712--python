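"""Codon-level effect annotation, including the whole-CDS re-translation
oracle and strand-mirror symmetry."""

import numpy as np
import pytest
from Bio.Seq import Seq

from panelvar.effects import (
    Effect,
    GeneIndex,
    ReferenceMismatchError,
    Region,
    annotate_indel,
    annotate_snp,
    annotate_variant,
    locate,
    summarize_effects,
)
from panelvar.filtering import Genotype, VariantRecord
from panelvar.genome import GeneModel, GenomeReference, compute_phases, reverse_complement

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def make_gene(cds_seq, strand="+", intergenic=200, intron=100, chrom="Ca1"):
    """Two-exon gene carrying the given coding sequence, embedded in a small
    random-free chromosome so tests control every base."""
    half = (len(cds_seq) // 2) // 3 * 3
    pieces = [cds_seq[:half], cds_seq[half:]]
    genomic = cds_seq if strand == "+" else reverse_complement(cds_seq)
    g1 = genomic[: half] if strand == "+" else genomic[: len(cds_seq) - half]
    g2 = genomic[len(g1):]
    seq = "T" * intergenic + g1 + "A" * intron + g2 + "T" * intergenic
    s1 = intergenic + 1
    e1 = s1 + len(g1) - 1
    s2 = e1 + intron + 1
    e2 = s2 + len(g2) - 1
    gene = GeneModel(
        gene_id="g1", chromosome=chrom, strand=strand,
        exons=[(s1, e1), (s2, e2)],
        cds=compute_phases([(s1, e1), (s2, e2)], strand),
    )
    reference = GenomeReference({chrom: seq})
    gene.validate(reference)
    return gene, reference


def snp(chrom, pos, ref, alt):
    return VariantRecord(chrom, pos, ref, alt, 50.0, 10, Genotype.HOM_ALT, "S")


CDS = "ATG" + "GAA" + "TGG" + "CTT" + "GGA" + "CCA" + "TAA"  # M E W L G P *


class TestLocate:
    def test_regions(self):
        gene, reference = make_gene(CDS)
        index = GeneIndex([gene])
        exon_pos = gene.exons[0][0]
        intron_pos = gene.exons[0][1] + 1
        assert locate("Ca1", exon_pos, index)[0] is Region.EXON
        assert locate("Ca1", intron_pos, index)[0] is Region.INTRON
        assert locate("Ca1", 5, index)[0] is Region.INTERGENIC

    def test_position_beyond_chromosome(self):
        gene, reference = make_gene(CDS)
        with pytest.raises(ValueError):
            locate("Ca1", 10**6, GeneIndex([gene]), reference)


def coding_pos(gene, offset):
    return gene.coding_to_genomic(offset)


class TestSnpEffects:
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_synonymous_third_position(self, strand):
        gene, reference = make_gene(CDS, strand)
        pos = coding_pos(gene, 5)  # GAA -> GAG, still Glu
        ref = reference.base("Ca1", pos)
        alt = "G" if strand == "+" else "C"
        call = annotate_snp(snp("Ca1", pos, ref, alt), gene, reference)
        assert call.effect is Effect.SYNONYMOUS_CODING

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_stop_gained(self, strand):
        gene, reference = make_gene(CDS, strand)
        pos = coding_pos(gene, 8)  # TGG -> TGA
        ref = reference.base("Ca1", pos)
        alt = "A" if strand == "+" else "T"
        call = annotate_snp(snp("Ca1", pos, ref, alt), gene, reference)
        assert call.effect is Effect.STOP_GAINED

    def test_start_lost(self):
        gene, reference = make_gene(CDS)
        pos = coding_pos(gene, 2)  # ATG -> ATA
        call = annotate_snp(snp("Ca1", pos, "G", "A"), gene, reference)
        assert call.effect is Effect.START_LOST

    def test_alternative_start_is_start_change(self):
        gene, reference = make_gene(CDS)
        pos = coding_pos(gene, 0)  # ATG -> GTG
        call = annotate_snp(snp("Ca1", pos, "A", "G"), gene, reference)
        assert call.effect is Effect.NON_SYNONYMOUS_START

    def test_stop_lost_and_synonymous_stop(self):
        gene, reference = make_gene(CDS)
        pos = coding_pos(gene, len(CDS) - 2)  # TAA middle base
        assert (
            annotate_snp(snp("Ca1", pos, "A", "G"), gene, reference).effect
            is Effect.SYNONYMOUS_STOP  # TAA -> TGA
        )
        pos0 = coding_pos(gene, len(CDS) - 3)
        assert (
            annotate_snp(snp("Ca1", pos0, "T", "C"), gene, reference).effect
            is Effect.STOP_LOST  # TAA -> CAA (Gln)
        )

    def test_missense(self):
        gene, reference = make_gene(CDS)
        pos = coding_pos(gene, 3)  # GAA -> AAA (Glu -> Lys)
        call = annotate_snp(snp("Ca1", pos, "G", "A"), gene, reference)
        assert call.effect is Effect.NON_SYNONYMOUS_CODING

    def test_reference_mismatch_rejected(self):
        gene, reference = make_gene(CDS)
        pos = coding_pos(gene, 3)
        with pytest.raises(ReferenceMismatchError):
            annotate_snp(snp("Ca1", pos, "C", "A"), gene, reference)


class TestIndelEffects:
    @pytest.mark.parametrize(
        "ref,alt,effect",
        [
            ("GAA", "G", Effect.FRAME_SHIFT),         # 2 bp deletion
            ("G", "GTTT", Effect.CODON_INSERTION),     # 3 bp insertion
            ("GAATGGC", "G", Effect.CODON_DELETION),   # 6 bp deletion
            ("G", "GT", Effect.FRAME_SHIFT),           # 1 bp insertion
        ],
    )
    def test_length_rule(self, ref, alt, effect):
        gene, _ = make_gene(CDS)
        pos = coding_pos(gene, 3)
        record = VariantRecord("Ca1", pos, ref, alt, 50.0, 10, Genotype.HOM_ALT, "S")
        assert annotate_indel(record, gene).effect is effect


def retranslation_oracle(cds, offset, alt_coding_base):
    """Independent classification by re-translating the whole mutated CDS and
    diffing the proteins (valid for every codon except the initiator)."""
    alt_cds = cds[:offset] + alt_coding_base + cds[offset + 1 :]
    ref_prot = str(Seq(cds).translate())
    alt_prot = str(Seq(alt_cds).translate())
    codon = offset // 3
    last = len(cds) // 3 - 1
    if ref_prot == alt_prot:
        return Effect.SYNONYMOUS_STOP if codon == last else Effect.SYNONYMOUS_CODING
    if codon == last:
        return Effect.STOP_LOST
    if alt_prot[codon] == "*":
        return Effect.STOP_GAINED
    return Effect.NON_SYNONYMOUS_CODING


class TestOracleEquivalence:
    def test_random_snps_match_retranslation(self, genome20):
        reference, genes = genome20
        index = GeneIndex(genes)
        rng = np.random.default_rng(123)
        n_checked = 0
        while n_checked < 500:
            gene = genes[rng.integers(0, len(genes))]
            cds = gene.cds_sequence(reference)
            n_codons = len(cds) // 3
            codon = int(rng.integers(1, n_codons))  # everything but initiator
            within = int(rng.integers(0, 3))
            offset = codon * 3 + within
            ref_coding = cds[offset]
            alt_coding = "ACGT"[rng.integers(0, 4)]
            if alt_coding == ref_coding:
                continue
            pos = gene.coding_to_genomic(offset)
            ref = reference.base(gene.chromosome, pos)
            alt = alt_coding if gene.strand == "+" else COMPLEMENT[alt_coding]
            record = snp(gene.chromosome, pos, ref, alt)
            call = annotate_variant(record, index, reference)
            assert call.region is Region.EXON
            assert call.effect is retranslation_oracle(cds, offset, alt_coding)
            n_checked += 1

    def test_strand_mirror_symmetry(self, genome20):
        reference, genes = genome20
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 60:
            gene = genes[rng.integers(0, len(genes))]
            cds = gene.cds_sequence(reference)
            codon = int(rng.integers(0, len(cds) // 3))
            within = int(rng.integers(0, 3))
            offset = codon * 3 + within
            alt_coding = "ACGT"[rng.integers(0, 4)]
            if alt_coding == cds[offset]:
                continue
            pos = gene.coding_to_genomic(offset)
            chrom_seq = reference.sequences[gene.chromosome]
            length = len(chrom_seq)
            # mirrored genome: reverse-complement chromosome, flipped gene
            mirror_seq = reverse_complement(chrom_seq)
            mirror_exons = sorted(
                (length - e + 1, length - s + 1) for s, e in gene.exons
            )
            mirror_strand = "-" if gene.strand == "+" else "+"
            mirror_gene = GeneModel(
                gene_id=gene.gene_id, chromosome=gene.chromosome,
                strand=mirror_strand, exons=mirror_exons,
                cds=compute_phases(mirror_exons, mirror_strand),
            )
            mirror_ref = GenomeReference({gene.chromosome: mirror_seq})
            mirror_gene.validate(mirror_ref)

            ref_base = reference.base(gene.chromosome, pos)
            alt_base = alt_coding if gene.strand == "+" else COMPLEMENT[alt_coding]
            call = annotate_snp(snp(gene.chromosome, pos, ref_base, alt_base),
                                gene, reference)
            m_pos = length - pos + 1
            m_call = annotate_snp(
                snp(gene.chromosome, m_pos, COMPLEMENT[ref_base], COMPLEMENT[alt_base]),
                mirror_gene, mirror_ref,
            )
            assert call.effect is m_call.effect
            checked += 1


class TestSummaries:
    def test_region_partition_conserved(self, genome20):
        reference, genes = genome20
        index = GeneIndex(genes)
        rng = np.random.default_rng(2)
        calls = {}
        for i, pos in enumerate(rng.integers(1, reference.lengths["Ca1"], 400)):
            pos = int(pos)
            ref = reference.base("Ca1", pos)
            alt = "ACGT"[(("ACGT".index(ref)) + 1) % 4]
            record = snp("Ca1", pos, ref, alt)
            calls[("Ca1", pos, ref, alt, i)] = annotate_variant(record, index, reference)
        summary = summarize_effects(calls)
        assert (
            summary["intergenic"] + summary["intron"] + summary["exon"] + summary["other"]
            == summary["total"] == len(calls)
        )

    def test_single_nonsense(self):
        gene, reference = make_gene(CDS)
        pos = coding_pos(gene, 8)
        call = annotate_snp(snp("Ca1", pos, "G", "A"), gene, reference)
        summary = summarize_effects({"x": call})
        assert summary["non_sense"] == 1 and summary["mis_sense"] == 0
        assert summary["silent"] == 0
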