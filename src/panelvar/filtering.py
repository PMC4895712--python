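"""Variant retention filters and SNP/Indel classification.

A called position is retained when its phred quality is strictly greater than
30 and its read depth is at least 5; variants with less than 5 bp flanking
distance to their nearest same-chromosome neighbour are removed (both members
of a too-close pair). Retained records are classed as SNP, insertion or
deletion; insertions/deletions of 1-58 bp count as Indels, anything longer
(or a multi-base substitution) is routed to the OTHER audit class.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

_VALID_BASES = frozenset("ACGT")

DEFAULT_MIN_QUALITY = 30.0
DEFAULT_MIN_DEPTH = 5
DEFAULT_MIN_FLANK = 5
MAX_INDEL_LENGTH = 58


class Genotype(enum.Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"


class VariantKind(enum.Enum):
    SNP = "SNP"
    INSERTION = "INSERTION"
    DELETION = "DELETION"
    OTHER = "OTHER"


@dataclass(frozen=True)
class VariantRecord:
    """One called variant for one sample (alleles follow VCF anchoring)."""

    chromosome: str
    position: int  # 1-based
    ref_allele: str
    alt_allele: str
    quality: float
    sample_depth: int
    genotype: Genotype
    sample: str
    multiallelic: bool = False  # first ALT of a multi-allelic record

    def __post_init__(self):
        for allele in (self.ref_allele, self.alt_allele):
            if not allele or not set(allele) <= _VALID_BASES:
                raise ValueError(f"invalid allele {allele!r}")
        if self.position < 1:
            raise ValueError(f"invalid position {self.position}")

    @property
    def site(self) -> tuple[str, int, str, str]:
        return (self.chromosome, self.position, self.ref_allele, self.alt_allele)


@dataclass(frozen=True)
class VariantClass:
    kind: VariantKind
    length: int  # 0 for SNP, |len(alt) - len(ref)| otherwise


def classify_variant(record_or_alleles) -> VariantClass:
    """Classify a variant by its REF/ALT alleles.

    Accepts a :class:`VariantRecord` or a ``(ref, alt)`` pair. SNP means both
    alleles are single bases; insertions/deletions are Indels only when the
    length difference is 1-58 bp; equal-length multi-base substitutions (MNPs)
    and >58 bp events are OTHER.
    """
    if isinstance(record_or_alleles, VariantRecord):
        ref, alt = record_or_alleles.ref_allele, record_or_alleles.alt_allele
    else:
        ref, alt = record_or_alleles
    diff = abs(len(alt) - len(ref))
    if len(ref) == 1 and len(alt) == 1:
        return VariantClass(VariantKind.SNP, 0)
    if diff == 0 or diff > MAX_INDEL_LENGTH:
        return VariantClass(VariantKind.OTHER, diff)
    if len(alt) > len(ref):
        return VariantClass(VariantKind.INSERTION, diff)
    return VariantClass(VariantKind.DELETION, diff)


def filter_quality_depth(
    records: list[VariantRecord],
    min_quality: float = DEFAULT_MIN_QUALITY,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Retain records with quality > min_quality and depth >= min_depth.

    Quality is compared strictly, depth non-strictly. Returns
    ``(kept, removed)`` with input order preserved in both streams.
    """
    if min_quality < 0 or min_depth < 0:
        raise ValueError("thresholds must be non-negative")
    kept, removed = [], []
    for rec in records:
        if rec.quality > min_quality and rec.sample_depth >= min_depth:
            kept.append(rec)
        else:
            removed.append(rec)
    return kept, removed


def filter_flank_distance(
    records: list[VariantRecord], min_flank: int = DEFAULT_MIN_FLANK
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Remove every record whose nearest same-chromosome neighbour is closer
    than ``min_flank`` (by anchor-position distance); both members of a close
    pair are removed.

    Input must be sorted by (chromosome, position); returns ``(kept, removed)``.
    """
    if min_flank < 0:
        raise ValueError("min_flank must be non-negative")
    key = [(r.chromosome, r.position) for r in records]
    if key != sorted(key):
        raise ValueError("records must be sorted by (chromosome, position)")
    kept, removed = [], []
    n = len(records)
    for i, rec in enumerate(records):
        too_close = False
        if i > 0 and records[i - 1].chromosome == rec.chromosome:
            if rec.position - records[i - 1].position < min_flank:
                too_close = True
        if i < n - 1 and records[i + 1].chromosome == rec.chromosome:
            if records[i + 1].position - rec.position < min_flank:
                too_close = True
        (removed if too_close else kept).append(rec)
    return kept, removed


def apply_filters(
    records: list[VariantRecord],
    min_quality: float = DEFAULT_MIN_QUALITY,
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_flank: int = DEFAULT_MIN_FLANK,
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Quality/depth filter followed by the flank-distance filter.

    Records are sorted by (chromosome, position) between the two stages, so
    the flank rule sees only quality-passing neighbours. Returns
    ``(kept, removed)``; ``|kept| + |removed| == |records|``.
    """
    by_qd, removed = filter_quality_depth(records, min_quality, min_depth)
    by_qd = sorted(by_qd, key=lambda r: (r.chromosome, r.position))
    kept, removed_flank = filter_flank_distance(by_qd, min_flank)
    return kept, removed + removed_flank
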