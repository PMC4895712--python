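"""Codon-level variant effect annotation against single-transcript gene models.

Classifies each variant as intergenic / intronic / exonic and, for coding
positions, assigns one effect from the synonymous / non-synonymous taxonomy
(start-lost, stop-gained, stop-lost, frameshift, codon insertion/deletion
included). The classifier rebuilds only the affected codon on the coding
strand and translates it with the standard genetic code; tests cross-check it
against a whole-CDS re-translation oracle.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from intervaltree import IntervalTree

from .filtering import Genotype, VariantRecord, classify_variant, VariantKind
from .genome import (
    GeneModel,
    GenomeReference,
    STOP_CODONS,
    START_CODON,
    reverse_complement,
    translate_codon,
)

# initiator codons treated as viable alternative starts: a SNP turning ATG
# into one of these is a start-codon change, not a start loss
ALTERNATIVE_START_CODONS = frozenset({"GTG", "TTG"})


class Region(enum.Enum):
    INTERGENIC = "INTERGENIC"
    INTRON = "INTRON"
    EXON = "EXON"
    OTHER = "OTHER"  # exonic but untranslated, or exon-boundary-spanning


class Effect(enum.Enum):
    SYNONYMOUS_CODING = "SYNONYMOUS_CODING"
    SYNONYMOUS_STOP = "SYNONYMOUS_STOP"
    NON_SYNONYMOUS_CODING = "NON_SYNONYMOUS_CODING"
    NON_SYNONYMOUS_START = "NON_SYNONYMOUS_START"
    START_LOST = "START_LOST"
    STOP_GAINED = "STOP_GAINED"
    STOP_LOST = "STOP_LOST"
    FRAME_SHIFT = "FRAME_SHIFT"
    CODON_INSERTION = "CODON_INSERTION"
    CODON_DELETION = "CODON_DELETION"
    NONE = "NONE"


MISSENSE_EFFECTS = {Effect.NON_SYNONYMOUS_CODING, Effect.NON_SYNONYMOUS_START}
NONSENSE_EFFECTS = {Effect.STOP_GAINED}
SILENT_EFFECTS = {Effect.SYNONYMOUS_CODING, Effect.SYNONYMOUS_STOP}


@dataclass(frozen=True)
class EffectCall:
    region: Region
    effect: Effect
    gene_id: str | None = None


class ReferenceMismatchError(ValueError):
    """The variant's REF allele disagrees with the reference sequence."""


class GeneIndex:
    """Interval lookup of gene models by chromosome span."""

    def __init__(self, genes: list[GeneModel]):
        self._trees: dict[str, IntervalTree] = {}
        self.genes = {g.gene_id: g for g in genes}
        for g in genes:
            self._trees.setdefault(g.chromosome, IntervalTree()).addi(
                g.start, g.end + 1, g
            )

    def overlapping(self, chromosome: str, position: int) -> list[GeneModel]:
        tree = self._trees.get(chromosome)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree[position]), key=lambda g: g.gene_id)


def locate(
    chromosome: str,
    position: int,
    gene_index: GeneIndex,
    reference: GenomeReference | None = None,
) -> tuple[Region, str | None]:
    """Region of a variant anchor: EXON (translated), OTHER (exonic but
    untranslated), INTRON, or INTERGENIC, plus the gene hit (first by id)."""
    if reference is not None and position > reference.lengths[chromosome]:
        raise ValueError(f"position {position} beyond end of {chromosome}")
    hits = gene_index.overlapping(chromosome, position)
    if not hits:
        return Region.INTERGENIC, None
    for gene in hits:
        if gene.in_cds(position):
            return Region.EXON, gene.gene_id
    for gene in hits:
        if gene.in_exon(position):
            return Region.OTHER, gene.gene_id
    return Region.INTRON, hits[0].gene_id


def annotate_snp(
    record: VariantRecord, gene: GeneModel, reference: GenomeReference
) -> EffectCall:
    """Effect of a coding SNP.

    The affected codon is rebuilt on the coding strand (reverse-complemented
    alleles for '-' genes) and the reference and alternate codons are
    translated with the standard genetic code.
    """
    if reference.base(record.chromosome, record.position) != record.ref_allele:
        raise ReferenceMismatchError(
            f"REF {record.ref_allele} != reference at "
            f"{record.chromosome}:{record.position}"
        )
    offset = gene.cds_offset(record.position)
    codon_index, within = divmod(offset, 3)
    cds = gene.cds_sequence(reference)
    ref_codon = cds[codon_index * 3 : codon_index * 3 + 3]
    if gene.strand == "+":
        ref_base, alt_base = record.ref_allele, record.alt_allele
    else:
        ref_base = reverse_complement(record.ref_allele)
        alt_base = reverse_complement(record.alt_allele)
    if ref_codon[within] != ref_base:
        raise ReferenceMismatchError(
            f"codon/reference inconsistency in {gene.gene_id} at offset {offset}"
        )
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
    n_codons = len(cds) // 3

    if codon_index == 0:
        # initiator codon: loss of a usable start unless the alternate codon
        # is itself a viable start
        if alt_codon == START_CODON:
            effect = Effect.SYNONYMOUS_CODING
        elif alt_codon in ALTERNATIVE_START_CODONS:
            effect = Effect.NON_SYNONYMOUS_START
        else:
            effect = Effect.START_LOST
    elif ref_codon in STOP_CODONS:
        effect = (
            Effect.SYNONYMOUS_STOP if alt_codon in STOP_CODONS else Effect.STOP_LOST
        )
    elif alt_codon in STOP_CODONS:
        effect = Effect.STOP_GAINED
    else:
        same = translate_codon(ref_codon) == translate_codon(alt_codon)
        effect = Effect.SYNONYMOUS_CODING if same else Effect.NON_SYNONYMOUS_CODING
    assert codon_index < n_codons
    return EffectCall(Region.EXON, effect, gene.gene_id)


def annotate_indel(record: VariantRecord, gene: GeneModel) -> EffectCall:
    """Effect of a coding Indel: frameshift unless the length change is a
    whole number of codons."""
    vc = classify_variant(record)
    if vc.kind not in (VariantKind.INSERTION, VariantKind.DELETION):
        raise ValueError("annotate_indel requires an insertion or deletion")
    if vc.length % 3 != 0:
        effect = Effect.FRAME_SHIFT
    elif vc.kind is VariantKind.INSERTION:
        effect = Effect.CODON_INSERTION
    else:
        effect = Effect.CODON_DELETION
    return EffectCall(Region.EXON, effect, gene.gene_id)


def annotate_variant(
    record: VariantRecord,
    gene_index: GeneIndex,
    reference: GenomeReference,
) -> EffectCall:
    """Full locate-then-classify annotation of one variant.

    Coding variants whose allele span crosses an exon boundary are routed to
    the OTHER audit stream (behaviour for such events is deliberately
    conservative).
    """
    region, gene_id = locate(record.chromosome, record.position, gene_index, reference)
    if region is not Region.EXON:
        return EffectCall(region, Effect.NONE, gene_id)
    gene = gene_index.genes[gene_id]
    vc = classify_variant(record)
    if vc.kind is VariantKind.OTHER:
        return EffectCall(Region.OTHER, Effect.NONE, gene_id)
    # allele span must stay inside one CDS interval
    span_end = record.position + max(len(record.ref_allele), 1) - 1
    if not any(s <= record.position and span_end <= e for s, e, _ in gene.cds):
        return EffectCall(Region.OTHER, Effect.NONE, gene_id)
    if vc.kind is VariantKind.SNP:
        return annotate_snp(record, gene, reference)
    return annotate_indel(record, gene)


def annotate_sites(panel_sites, gene_index: GeneIndex, reference: GenomeReference):
    """Annotate every union site of a panel; returns {site.key: EffectCall}."""
    out = {}
    for site in panel_sites:
        rec = VariantRecord(
            chromosome=site.chromosome,
            position=site.position,
            ref_allele=site.ref_allele,
            alt_allele=site.alt_allele,
            quality=99.0,
            sample_depth=99,
            genotype=Genotype.HOM_ALT,
            sample="__panel__",
        )
        out[site.key] = annotate_variant(rec, gene_index, reference)
    return out


def summarize_effects(effect_calls: dict) -> dict[str, int]:
    """Genome-level tallies of an annotation run.

    Returns region counts plus the mis-sense / non-sense / silent split
    (mis-sense = non-synonymous coding + non-synonymous start; non-sense =
    stop gained; silent = synonymous coding + synonymous stop).
    """
    counts = {
        "intergenic": 0,
        "intron": 0,
        "exon": 0,
        "other": 0,
        "mis_sense": 0,
        "non_sense": 0,
        "silent": 0,
        "start_lost": 0,
        "stop_lost": 0,
        "frame_shift": 0,
        "codon_insertion": 0,
        "codon_deletion": 0,
        "total": 0,
    }
    region_key = {
        Region.INTERGENIC: "intergenic",
        Region.INTRON: "intron",
        Region.EXON: "exon",
        Region.OTHER: "other",
    }
    for call in effect_calls.values():
        counts[region_key[call.region]] += 1
        counts["total"] += 1
        if call.effect in MISSENSE_EFFECTS:
            counts["mis_sense"] += 1
        elif call.effect in NONSENSE_EFFECTS:
            counts["non_sense"] += 1
        elif call.effect in SILENT_EFFECTS:
            counts["silent"] += 1
        elif call.effect is Effect.START_LOST:
            counts["start_lost"] += 1
        elif call.effect is Effect.STOP_LOST:
            counts["stop_lost"] += 1
        elif call.effect is Effect.FRAME_SHIFT:
            counts["frame_shift"] += 1
        elif call.effect is Effect.CODON_INSERTION:
            counts["codon_insertion"] += 1
        elif call.effect is Effect.CODON_DELETION:
            counts["codon_deletion"] += 1
    return counts
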