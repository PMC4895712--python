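"""Reference genome and gene-model containers.

`GenomeReference` holds named pseudomolecule sequences and is the coordinate
frame for every other object in the package. `GeneModel` is a single-transcript
gene (strand, exons, CDS with phase) used by the effect annotator and the
per-gene CNV/PAV caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str:
    """One codon -> one amino acid, '*' for stop (standard genetic code)."""
    if len(codon) != 3:
        raise ValueError(f"not a codon: {codon!r}")
    return str(Seq(codon).translate())


@dataclass(frozen=True)
class GenomeReference:
    """Named pseudomolecule sequences (uppercase A/C/G/T)."""

    sequences: dict[str, str]

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    @property
    def names(self) -> list[str]:
        return list(self.sequences)

    @property
    def genome_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def fetch(self, chromosome: str, start: int, end: int) -> str:
        """Sequence of the 1-based inclusive interval [start, end]."""
        seq = self.sequences[chromosome]
        if start < 1 or end > len(seq) or start > end:
            raise ValueError(
                f"interval {chromosome}:{start}-{end} outside chromosome bounds"
            )
        return seq[start - 1 : end]

    def base(self, chromosome: str, position: int) -> str:
        return self.fetch(chromosome, position, position)


@dataclass
class GeneModel:
    """Single-transcript gene model.

    ``exons`` and ``cds`` are sorted lists of 1-based inclusive intervals on the
    forward genomic strand; ``cds`` intervals additionally carry the GFF3 phase
    of their first translated base. Translation order follows ``strand``.
    """

    gene_id: str
    chromosome: str
    strand: str  # '+' or '-'
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int, int]] = field(default_factory=list)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def length(self) -> int:
        """Genomic span length (bases) including introns."""
        return self.end - self.start + 1

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e, _ in self.cds)

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end

    def in_exon(self, position: int) -> bool:
        return any(s <= position <= e for s, e in self.exons)

    def in_cds(self, position: int) -> bool:
        return any(s <= position <= e for s, e, _ in self.cds)

    def cds_sequence(self, reference: GenomeReference) -> str:
        """Coding-strand CDS sequence (reverse-complemented for '-' genes)."""
        parts = [reference.fetch(self.chromosome, s, e) for s, e, _ in self.cds]
        seq = "".join(parts)
        return reverse_complement(seq) if self.strand == "-" else seq

    def cds_offset(self, position: int) -> int:
        """0-based offset of a genomic position within the coding sequence.

        Raises ValueError if the position is not in the CDS.
        """
        if not self.in_cds(position):
            raise ValueError(f"position {position} not in CDS of {self.gene_id}")
        if self.strand == "+":
            off = 0
            for s, e, _ in self.cds:
                if position > e:
                    off += e - s + 1
                else:
                    return off + (position - s)
        else:
            off = 0
            for s, e, _ in reversed(self.cds):
                if position < s:
                    off += e - s + 1
                else:
                    return off + (e - position)
        raise AssertionError("unreachable")

    def coding_to_genomic(self, offset: int) -> int:
        """Inverse of :meth:`cds_offset`."""
        if not 0 <= offset < self.cds_length:
            raise ValueError(f"CDS offset {offset} out of range for {self.gene_id}")
        if self.strand == "+":
            for s, e, _ in self.cds:
                n = e - s + 1
                if offset < n:
                    return s + offset
                offset -= n
        else:
            for s, e, _ in reversed(self.cds):
                n = e - s + 1
                if offset < n:
                    return e - offset
                offset -= n
        raise AssertionError("unreachable")

    def validate(self, reference: GenomeReference | None = None) -> None:
        """Check structural invariants; raise ValueError on violation."""
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        for ivals in (self.exons, [(s, e) for s, e, _ in self.cds]):
            prev_end = 0
            for s, e in ivals:
                if s > e or s <= prev_end:
                    raise ValueError(f"{self.gene_id}: unsorted/overlapping intervals")
                prev_end = e
        for s, e, _ in self.cds:
            if not any(xs <= s and e <= xe for xs, xe in self.exons):
                raise ValueError(f"{self.gene_id}: CDS interval outside exons")
        if self.cds and self.cds_length % 3 != 0:
            raise ValueError(f"{self.gene_id}: CDS length not divisible by 3")
        if reference is not None and self.cds:
            seq = self.cds_sequence(reference)
            if not seq.startswith(START_CODON):
                raise ValueError(f"{self.gene_id}: CDS does not start with ATG")
            if seq[-3:] not in STOP_CODONS:
                raise ValueError(f"{self.gene_id}: CDS does not end with a stop codon")


def compute_phases(
    cds_intervals: list[tuple[int, int]], strand: str
) -> list[tuple[int, int, int]]:
    """Attach GFF3 phase to CDS intervals given the translation order."""
    order = cds_intervals if strand == "+" else list(reversed(cds_intervals))
    phased = []
    cum = 0
    for s, e in order:
        phase = (3 - (cum % 3)) % 3
        phased.append((s, e, phase))
        cum += e - s + 1
    return sorted(phased)
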