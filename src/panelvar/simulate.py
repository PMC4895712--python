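"""Synthetic resequencing-panel generator with machine-readable ground truth.

Emulates the post-alignment evidence of a small multi-genotype resequencing
panel: a multi-pseudomolecule reference with protein-coding gene models,
per-genotype SNP/Indel calls (with quality, depth and zygosity), per-base
depth profiles carrying planted gene deletions and duplications, and
discordant mate-pair tables carrying planted CTX/ITX/INV events — plus a
truth set recording every planted feature so downstream callers can be scored
exactly.

Key modelling choices (see the methods note for rationale):

* background variants are planted at sites shared by at least two genotypes,
  so the planted line-specific flag coincides exactly with the analytical
  definition (non-reference in exactly one genotype);
* all planted positions of one genotype keep a minimum spacing wider than the
  flank-distance filter, so every truth variant survives filtering;
* depth noise is piecewise-constant over short tiles (coverage is locally
  autocorrelated and the bedGraph output stays compact);
* deleted genes retain a small residual covered fraction (mapping-noise
  analog) so the <10 % absence rule is exercised away from the zero case.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .cnv_pav import DepthProfile, MIN_GENE_LENGTH
from .filtering import Genotype, VariantRecord, DEFAULT_MIN_FLANK
from .genome import (
    GeneModel,
    GenomeReference,
    STOP_CODONS,
    START_CODON,
    compute_phases,
    reverse_complement,
    translate_codon,
)
from .sv import DiscordantPair, SVType

_BASES = "ACGT"
_ALL_CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES]
SENSE_CODONS = [c for c in _ALL_CODONS if c not in STOP_CODONS]
ALT_START_CODONS = ("GTG", "TTG")


class SimulationError(ValueError):
    """Requested regime cannot be realized (packing/spacing infeasible)."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic panel.

    Defaults describe a 5-genotype panel over two 1-Mb pseudomolecules with
    20 genes, ~2,000 SNPs and ~200 Indels per genotype (rates 1e-3 and 1e-4
    per base), 30 % heterozygous calls, 25 line-specific variants, 3 gene
    deletions, 3 duplications and 3 structural variants per type per
    genotype at ~10x coverage with a 400 +/- 40 bp insert model.
    """

    n_chromosomes: int = 2
    chromosome_length: int = 1_000_000
    n_genes: int = 20
    gene_length_range: tuple[int, int] = (1200, 2400)
    n_samples: int = 5
    snp_rate: float = 1e-3
    indel_rate: float = 1e-4
    indel_length_max: int = 58
    het_fraction: float = 0.3
    n_line_specific: int = 25
    n_gene_deletions: int = 3
    n_gene_duplications: int = 3
    n_sv_per_type: int = 3
    base_depth: float = 10.0
    depth_noise_sd: float = 1.0
    read_length: int = 100
    insert_size_mean: int = 400
    insert_size_sd: int = 40
    seed: int = 0
    # secondary knobs
    n_effect_forced_per_category: int = 1
    n_lowqual_noise: int = 20
    n_close_pairs: int = 5
    n_noise_pairs: int = 30
    sv_support: int = 6
    depth_tile: int = 100
    residual_coverage_fraction: float = 0.03

    @property
    def min_spacing(self) -> int:
        """Minimum distance between planted positions of one genotype; wider
        than the flank filter plus the longest possible REF span."""
        return self.indel_length_max + DEFAULT_MIN_FLANK + 1

    @property
    def sample_names(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_samples)]

    def validate(self) -> None:
        counts = (
            self.n_chromosomes, self.n_genes, self.n_samples,
            self.n_line_specific, self.n_gene_deletions,
            self.n_gene_duplications, self.n_sv_per_type,
            self.n_effect_forced_per_category, self.n_lowqual_noise,
            self.n_close_pairs, self.n_noise_pairs,
        )
        if any(c < 0 for c in counts):
            raise SimulationError("all counts must be >= 0")
        if self.n_chromosomes < 1 or self.n_samples < 1:
            raise SimulationError("need at least one chromosome and one sample")
        lo, hi = self.gene_length_range
        if not 300 <= lo <= hi:
            raise SimulationError("gene_length_range must satisfy 300 <= min <= max")
        if self.chromosome_length < 10 * hi:
            raise SimulationError("chromosome_length must be >= 10x max gene length")
        if not 1 <= self.indel_length_max:
            raise SimulationError("indel_length_max must be >= 1")
        if not 0.0 <= self.het_fraction <= 1.0:
            raise SimulationError("het_fraction must be in [0, 1]")
        if self.snp_rate < 0 or self.indel_rate < 0:
            raise SimulationError("rates must be >= 0")
        if self.n_sv_per_type > 0 and self.n_chromosomes < 2:
            raise SimulationError("CTX events require at least two chromosomes")
        if self.sv_support < 2:
            raise SimulationError("sv_support must be >= 2")

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        """Load from a flat key = value text file (comments with '#')."""
        values: dict = {}
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, raw = line.partition("=")
                key, raw = key.strip(), raw.strip()
                if key == "gene_length_range":
                    lo, hi = raw.split(",")
                    values[key] = (int(lo), int(hi))
                elif key in ("snp_rate", "indel_rate", "het_fraction", "base_depth",
                             "depth_noise_sd", "residual_coverage_fraction"):
                    values[key] = float(raw)
                else:
                    values[key] = int(raw)
        return cls(**values)


@dataclass
class TruthSet:
    """Planted ground truth.

    ``variants``: one row per (sample, site) with zygosity, the forced effect
    category (empty for background variants) and the line-specific flag;
    ``gene_events``: planted gene deletions/duplications;
    ``sv_events``: planted CTX/ITX/INV breakpoints (1-based).
    """

    variants: pd.DataFrame
    gene_events: pd.DataFrame
    sv_events: pd.DataFrame

    def line_specific(self) -> pd.DataFrame:
        return self.variants[self.variants["line_specific"]]

    def validate(self, reference: GenomeReference, genes: list[GeneModel]) -> None:
        ls = self.line_specific()
        per_site = ls.groupby(["chromosome", "position", "ref", "alt"])["sample"].nunique()
        if (per_site != 1).any():
            raise AssertionError("line-specific truth variant in more than one sample")
        by_id = {g.gene_id: g for g in genes}
        for gene_id in self.gene_events["gene_id"]:
            if by_id[gene_id].length < MIN_GENE_LENGTH:
                raise AssertionError(f"gene event on short gene {gene_id}")
        lengths = reference.lengths
        for _, row in self.sv_events.iterrows():
            for chrom, pos in ((row.chrom_a, row.pos_a), (row.chrom_b, row.pos_b)):
                if not 1 <= pos <= lengths[chrom]:
                    raise AssertionError("SV breakpoint outside chromosome bounds")


@dataclass
class SimulatedPanel:
    """All outputs of one simulation run."""

    config: SimulationConfig
    reference: GenomeReference
    genes: list[GeneModel]
    records: dict[str, list[VariantRecord]]
    truth: TruthSet
    depths: dict[str, DepthProfile]  # includes the 'control' sample
    pairs: dict[str, list[DiscordantPair]]  # includes the 'control' sample


# ---------------------------------------------------------------------------
# reference + gene models


def _random_sequence(rng: np.random.Generator, length: int) -> bytearray:
    codes = np.frombuffer(b"ACGT", dtype=np.uint8)
    return bytearray(codes[rng.integers(0, 4, size=length)].tobytes())


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    body = rng.choice(len(SENSE_CODONS), size=n_codons - 2)
    stop = sorted(STOP_CODONS)[rng.integers(0, len(STOP_CODONS))]
    return START_CODON + "".join(SENSE_CODONS[i] for i in body) + stop


def generate_reference(
    config: SimulationConfig,
) -> tuple[GenomeReference, list[GeneModel]]:
    """Random uppercase A/C/G/T pseudomolecules with non-overlapping,
    both-strand protein-coding genes (ATG ... stop, CDS length % 3 == 0)."""
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    chrom_names = [f"Ca{i + 1}" for i in range(config.n_chromosomes)]
    raw = {name: _random_sequence(rng, config.chromosome_length) for name in chrom_names}

    genes: list[GeneModel] = []
    lo, hi = config.gene_length_range
    margin = 2000
    per_chrom = [config.n_genes // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_genes % config.n_chromosomes):
        per_chrom[i] += 1
    gene_index = 0
    for chrom, k in zip(chrom_names, per_chrom):
        if k == 0:
            continue
        usable = config.chromosome_length - 2 * margin
        slot = usable // k
        if slot < hi + 400:
            raise SimulationError(
                f"cannot pack {k} genes of up to {hi} bp on one chromosome"
            )
        for j in range(k):
            span = int(rng.integers(lo, hi + 1))
            start = margin + j * slot + int(rng.integers(0, slot - span - 200))
            strand = "+" if gene_index % 2 == 0 else "-"
            gene = _build_gene(
                rng, f"g{gene_index + 1:04d}", chrom, strand, start + 1, span, raw[chrom]
            )
            genes.append(gene)
            gene_index += 1

    reference = GenomeReference(
        {name: bytes(seq).decode("ascii") for name, seq in raw.items()}
    )
    for gene in genes:
        gene.validate(reference)
    return reference, genes


def _build_gene(
    rng: np.random.Generator,
    gene_id: str,
    chrom: str,
    strand: str,
    start: int,  # 1-based
    span: int,
    raw: bytearray,
) -> GeneModel:
    """Carve a gene of the given span into exons/introns and write its CDS
    into the raw chromosome sequence."""
    cds_len = 3 * (int(span * 0.5) // 3)
    intron_total = span - cds_len
    n_exons = int(rng.integers(2, 5))
    n_exons = min(n_exons, 1 + intron_total // 60)
    n_exons = max(n_exons, 2)
    # exon length composition
    base = cds_len // n_exons
    exon_lens = [base] * n_exons
    exon_lens[-1] += cds_len - base * n_exons
    for i in range(n_exons - 1):
        delta = int(rng.integers(-base // 3, base // 3 + 1))
        if exon_lens[i] + delta >= 30 and exon_lens[i + 1] - delta >= 30:
            exon_lens[i] += delta
            exon_lens[i + 1] -= delta
    ibase = intron_total // (n_exons - 1)
    intron_lens = [ibase] * (n_exons - 1)
    intron_lens[-1] += intron_total - ibase * (n_exons - 1)

    intervals = []
    pos = start
    for i, el in enumerate(exon_lens):
        intervals.append((pos, pos + el - 1))
        pos += el
        if i < n_exons - 1:
            pos += intron_lens[i]

    cds_seq = _random_cds(rng, cds_len // 3)
    pasted = cds_seq if strand == "+" else reverse_complement(cds_seq)
    cursor = 0
    for s, e in intervals:
        piece = pasted[cursor : cursor + (e - s + 1)]
        raw[s - 1 : e] = piece.encode("ascii")
        cursor += e - s + 1
    return GeneModel(
        gene_id=gene_id,
        chromosome=chrom,
        strand=strand,
        exons=intervals,
        cds=compute_phases(intervals, strand),
    )


# ---------------------------------------------------------------------------
# variant planting


def _spaced_positions(
    rng: np.random.Generator,
    length: int,
    k: int,
    gap: int,
    blocked: IntervalTree | None,
    margin: int,
) -> np.ndarray:
    """k positions in [margin, length - margin], pairwise spacing >= gap,
    none inside a blocked interval."""
    if k == 0:
        return np.array([], dtype=int)
    lo, hi = margin, length - margin
    for attempt in range(8):
        want = int(k * 1.3) + 20
        room = hi - lo - (want - 1) * gap
        while room <= want and want > k:
            want = max(k, want - max(1, (want - k) // 2))
            room = hi - lo - (want - 1) * gap
        if room <= want:
            raise SimulationError(
                "variant rate too high for the requested spacing guarantees"
            )
        u = np.sort(rng.choice(room, size=want, replace=False))
        pos = lo + u + np.arange(want) * gap
        if blocked is not None:
            pos = np.array([p for p in pos if not blocked[p]], dtype=int)
        if len(pos) >= k:
            take = np.sort(rng.choice(len(pos), size=k, replace=False))
            return pos[take]
    raise SimulationError("could not place variants outside blocked regions")


def _draw_pool(
    rng: np.random.Generator,
    reference: GenomeReference,
    total: int,
    gap: int,
    blocked: dict[str, IntervalTree],
    margin: int,
) -> list[tuple[str, int]]:
    """Draw a genome-wide pool of spaced positions, allocated to chromosomes
    proportionally to length, shuffled."""
    lengths = reference.lengths
    genome = sum(lengths.values())
    pool: list[tuple[str, int]] = []
    names = list(lengths)
    alloc = {n: int(round(total * lengths[n] / genome)) for n in names}
    short = total - sum(alloc.values())
    alloc[names[0]] += short
    for name in names:
        for p in _spaced_positions(
            rng, lengths[name], alloc[name], gap, blocked.get(name), margin
        ):
            pool.append((name, int(p)))
    order = rng.permutation(len(pool))
    return [pool[i] for i in order]


def _draw_zygosity(rng: np.random.Generator, het_fraction: float) -> Genotype:
    return Genotype.HET if rng.random() < het_fraction else Genotype.HOM_ALT


def _passing_qual_depth(rng: np.random.Generator, base_depth: float) -> tuple[float, int]:
    qual = round(float(rng.uniform(35.0, 95.0)), 1)
    depth = max(5, int(rng.poisson(base_depth)))
    return qual, depth


_FORCED_PLAN = (
    ("SYNONYMOUS_CODING", "internal"),
    ("NON_SYNONYMOUS_CODING", "internal"),
    ("STOP_GAINED", "internal"),
    ("FRAME_SHIFT", "indel"),
    ("CODON_INSERTION", "indel"),
    ("CODON_DELETION", "indel"),
    ("START_LOST", "initiator"),
    ("NON_SYNONYMOUS_START", "initiator"),
    ("STOP_LOST", "terminator"),
    ("SYNONYMOUS_STOP", "terminator"),
)


def _snp_for_category(
    rng: np.random.Generator, cds: str, category: str, used: list[int]
) -> tuple[int, int, str]:
    """(codon_index, within, alt_coding_base) realizing the category, at
    least 3 codons away from previously used codons of this gene/sample."""
    n_codons = len(cds) // 3

    def ok_codon(ci):
        return all(abs(ci - u) >= 3 for u in used)

    if category in ("START_LOST", "NON_SYNONYMOUS_START"):
        codon = cds[:3]
        assert codon == START_CODON
        choices = []
        for within in range(3):
            for alt in _BASES:
                if alt == codon[within]:
                    continue
                alt_codon = codon[:within] + alt + codon[within + 1 :]
                is_alt_start = alt_codon in ALT_START_CODONS
                if (category == "NON_SYNONYMOUS_START") == is_alt_start:
                    choices.append((0, within, alt))
        return choices[rng.integers(0, len(choices))]
    if category in ("STOP_LOST", "SYNONYMOUS_STOP"):
        ci = n_codons - 1
        codon = cds[ci * 3 : ci * 3 + 3]
        choices = []
        for within in range(3):
            for alt in _BASES:
                if alt == codon[within]:
                    continue
                alt_codon = codon[:within] + alt + codon[within + 1 :]
                is_stop = alt_codon in STOP_CODONS
                if (category == "SYNONYMOUS_STOP") == is_stop:
                    choices.append((ci, within, alt))
        return choices[rng.integers(0, len(choices))]

    # stay clear of the initiator and terminator codons so categories that
    # target them can share a gene without violating the flank spacing
    for ci in rng.permutation(np.arange(4, n_codons - 4)):
        ci = int(ci)
        if not ok_codon(ci):
            continue
        codon = cds[ci * 3 : ci * 3 + 3]
        options = []
        for within in range(3):
            for alt in _BASES:
                if alt == codon[within]:
                    continue
                alt_codon = codon[:within] + alt + codon[within + 1 :]
                if category == "STOP_GAINED":
                    if alt_codon in STOP_CODONS:
                        options.append((ci, within, alt))
                elif alt_codon in STOP_CODONS:
                    continue
                elif category == "SYNONYMOUS_CODING":
                    if translate_codon(alt_codon) == translate_codon(codon):
                        options.append((ci, within, alt))
                elif category == "NON_SYNONYMOUS_CODING":
                    if translate_codon(alt_codon) != translate_codon(codon):
                        options.append((ci, within, alt))
        if options:
            return options[rng.integers(0, len(options))]
    raise SimulationError(f"no codon available for forced category {category}")


def _indel_site_for_category(
    rng: np.random.Generator,
    gene: GeneModel,
    reference: GenomeReference,
    category: str,
    used: list[int],
) -> tuple[int, int]:
    """(anchor_position, signed_length) for a forced coding Indel; positive
    length = insertion, negative = deletion. The affected span stays inside a
    single CDS interval, >= 3 codons from used codons."""
    length = {"FRAME_SHIFT": -2, "CODON_INSERTION": 3, "CODON_DELETION": -3}[category]
    span = abs(length) if length < 0 else 0
    intervals = sorted(gene.cds, key=lambda t: t[1] - t[0], reverse=True)
    for s, e, _ in intervals:
        if e - s + 1 < span + 40:
            continue
        n_codons = gene.cds_length // 3
        for _attempt in range(50):
            p = int(rng.integers(s + 10, e - span - 10))
            ci = gene.cds_offset(p) // 3
            if not 4 <= ci <= n_codons - 5:
                continue
            if all(abs(ci - u) >= 3 for u in used):
                return p, length
    raise SimulationError(f"no CDS room for forced category {category}")


def simulate_panel_variants(
    reference: GenomeReference,
    genes: list[GeneModel],
    config: SimulationConfig,
) -> tuple[dict[str, list[VariantRecord]], TruthSet]:
    """Plant per-genotype variants and decide gene/SV events.

    Returns per-sample VCF-style records (including filter-failing noise
    records that are absent from the truth set) and the full TruthSet.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 2])
    samples = config.sample_names
    genome_len = reference.genome_length
    eligible = [g for g in genes if g.length >= MIN_GENE_LENGTH]

    # --- gene events -------------------------------------------------------
    n_event = config.n_gene_deletions + config.n_gene_duplications
    gene_event_rows = []
    if n_event > 0:
        if len(eligible) < n_event:
            raise SimulationError("not enough >=1 kb genes for the requested events")
        shuffled = [eligible[i] for i in rng.permutation(len(eligible))]
        forced_need = 5 if config.n_effect_forced_per_category > 0 else 0
        pool_size = min(max(n_event, (len(eligible) + 1) // 2), len(eligible) - forced_need)
        if pool_size < n_event:
            raise SimulationError(
                "not enough >=1 kb genes for gene events plus forced effect categories"
            )
        event_pool = shuffled[:pool_size]
        forced_pool = shuffled[pool_size:]
        for sample in samples:
            pick = rng.choice(len(event_pool), size=n_event, replace=False)
            for idx in pick[: config.n_gene_deletions]:
                gene_event_rows.append(
                    {"sample": sample, "gene_id": event_pool[idx].gene_id, "event": "deletion"}
                )
            for idx in pick[config.n_gene_deletions :]:
                gene_event_rows.append(
                    {"sample": sample, "gene_id": event_pool[idx].gene_id, "event": "duplication"}
                )
    else:
        forced_pool = list(eligible)
    gene_events = pd.DataFrame(
        gene_event_rows, columns=["sample", "gene_id", "event"]
    )

    by_id = {g.gene_id: g for g in genes}
    deleted_gene_ids = set(gene_events.loc[gene_events["event"] == "deletion", "gene_id"])
    forced_pool = [g for g in forced_pool if g.gene_id not in deleted_gene_ids]
    deletion_spans = {
        sample: [
            (by_id[gid].chromosome, by_id[gid].start, by_id[gid].end)
            for gid in gene_events.loc[
                (gene_events["sample"] == sample) & (gene_events["event"] == "deletion"),
                "gene_id",
            ]
        ]
        for sample in samples
    }

    # --- SV events ---------------------------------------------------------
    sv_events = _place_sv_events(rng, reference, config)

    # --- blocked regions: any genotype's deleted gene span ------------------
    spacing = config.min_spacing
    blocked: dict[str, IntervalTree] = {name: IntervalTree() for name in reference.names}
    for gid in deleted_gene_ids:
        g = by_id[gid]
        blocked[g.chromosome].addi(g.start - spacing, g.end + spacing + 1)

    # --- forced-effect variants --------------------------------------------
    truth_rows: list[dict] = []
    per_sample: dict[str, list[VariantRecord]] = {s: [] for s in samples}
    cds_cache = {g.gene_id: g.cds_sequence(reference) for g in forced_pool}
    if config.n_effect_forced_per_category > 0:
        if len(forced_pool) < 5:
            raise SimulationError(
                "not enough event-free genes to plant forced effect categories"
            )
        _plant_forced(
            rng, config, reference, forced_pool, cds_cache,
            per_sample, truth_rows, blocked, spacing,
        )

    # --- global spaced position pool ---------------------------------------
    n_snps = int(round(config.snp_rate * genome_len))
    n_indels = int(round(config.indel_rate * genome_len))
    total_background = n_snps + n_indels
    mean_carriers = (2 + config.n_samples) / 2 if config.n_samples > 1 else 1.0
    m_background = int(round(config.n_samples * total_background / mean_carriers))
    n_ls_total = config.n_samples * config.n_line_specific
    n_noise_total = config.n_samples * (config.n_lowqual_noise + config.n_close_pairs)
    margin = config.indel_length_max + 10
    pool = _draw_pool(
        rng, reference, m_background + n_ls_total + n_noise_total,
        spacing, blocked, margin,
    )
    cursor = 0

    def take(n):
        nonlocal cursor
        chunk = pool[cursor : cursor + n]
        cursor += n
        return chunk

    snp_share = n_snps / total_background if total_background else 0.0

    def make_alleles(chrom: str, pos: int, is_snp: bool) -> tuple[str, str]:
        ref_base = reference.base(chrom, pos)
        if is_snp:
            alt = _BASES[rng.integers(0, 4)]
            while alt == ref_base:
                alt = _BASES[rng.integers(0, 4)]
            return ref_base, alt
        length = int(rng.integers(1, config.indel_length_max + 1))
        if rng.random() < 0.5:  # insertion
            ins = "".join(_BASES[i] for i in rng.integers(0, 4, size=length))
            return ref_base, ref_base + ins
        return reference.fetch(chrom, pos, pos + length), ref_base

    # --- background shared variants ----------------------------------------
    for chrom, pos in take(m_background):
        is_snp = rng.random() < snp_share
        ref, alt = make_alleles(chrom, pos, is_snp)
        if config.n_samples > 1:
            k = int(rng.integers(2, config.n_samples + 1))
            carriers = [samples[i] for i in rng.choice(config.n_samples, size=k, replace=False)]
        else:
            carriers = [samples[0]]
        for sample in carriers:
            zyg = _draw_zygosity(rng, config.het_fraction)
            qual, depth = _passing_qual_depth(rng, config.base_depth)
            per_sample[sample].append(
                VariantRecord(chrom, pos, ref, alt, qual, depth, zyg, sample)
            )
            truth_rows.append(
                {
                    "sample": sample, "chromosome": chrom, "position": pos,
                    "ref": ref, "alt": alt, "zygosity": zyg.value, "effect": "",
                }
            )

    # --- line-specific variants --------------------------------------------
    ls_positions = take(n_ls_total)
    for i, sample in enumerate(samples):
        for chrom, pos in ls_positions[
            i * config.n_line_specific : (i + 1) * config.n_line_specific
        ]:
            is_snp = rng.random() < (snp_share if total_background else 0.9)
            ref, alt = make_alleles(chrom, pos, is_snp)
            zyg = _draw_zygosity(rng, config.het_fraction)
            qual, depth = _passing_qual_depth(rng, config.base_depth)
            per_sample[sample].append(
                VariantRecord(chrom, pos, ref, alt, qual, depth, zyg, sample)
            )
            truth_rows.append(
                {
                    "sample": sample, "chromosome": chrom, "position": pos,
                    "ref": ref, "alt": alt, "zygosity": zyg.value, "effect": "",
                }
            )

    # --- filter-failing noise (absent from truth) ---------------------------
    for sample in samples:
        for chrom, pos in take(config.n_lowqual_noise):
            ref, alt = make_alleles(chrom, pos, True)
            if rng.random() < 0.5:
                qual = round(float(rng.uniform(5.0, 29.5)), 1)
                depth = max(5, int(rng.poisson(config.base_depth)))
            else:
                qual = round(float(rng.uniform(35.0, 95.0)), 1)
                depth = int(rng.integers(0, 5))
            per_sample[sample].append(
                VariantRecord(chrom, pos, ref, alt, qual,
                              depth, _draw_zygosity(rng, config.het_fraction), sample)
            )
        for chrom, pos in take(config.n_close_pairs):
            for p in (pos, pos + 3):
                ref, alt = make_alleles(chrom, p, True)
                qual, depth = _passing_qual_depth(rng, config.base_depth)
                per_sample[sample].append(
                    VariantRecord(chrom, p, ref, alt, qual, depth,
                                  _draw_zygosity(rng, config.het_fraction), sample)
                )

    for sample in samples:
        per_sample[sample].sort(key=lambda r: (r.chromosome, r.position, r.alt_allele))

    variants = pd.DataFrame(
        truth_rows,
        columns=["sample", "chromosome", "position", "ref", "alt", "zygosity", "effect"],
    )
    if len(variants):
        carrier_counts = variants.groupby(
            ["chromosome", "position", "ref", "alt"]
        )["sample"].transform("nunique")
        variants["line_specific"] = carrier_counts == 1
    else:
        variants["line_specific"] = pd.Series(dtype=bool)
    truth = TruthSet(variants=variants, gene_events=gene_events, sv_events=sv_events)
    truth.validate(reference, genes)
    return per_sample, truth


def _plant_forced(
    rng, config, reference, forced_pool, cds_cache, per_sample, truth_rows,
    blocked, spacing,
) -> None:
    samples = config.sample_names
    complement = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for sample in samples:
        order = rng.permutation(len(forced_pool))
        shuffled = [forced_pool[i] for i in order]
        used: dict[str, list[int]] = {}
        special = {"initiator": 0, "terminator": 2}
        internal_cursor = 4 % len(shuffled)
        for repeat in range(config.n_effect_forced_per_category):
            for category, mode in _FORCED_PLAN:
                if mode in special:
                    gi = (special[mode] + repeat * 4) % len(shuffled)
                    special[mode] += 1
                    gene = shuffled[gi]
                else:
                    gene = shuffled[internal_cursor]
                    internal_cursor = (internal_cursor + 1) % len(shuffled)
                    if internal_cursor in (0, 1, 2, 3):
                        internal_cursor = 4 % len(shuffled)
                cds = cds_cache[gene.gene_id]
                used_codons = used.setdefault(gene.gene_id, [])
                if mode == "indel":
                    anchor, signed_len = _indel_site_for_category(
                        rng, gene, reference, category, used_codons
                    )
                    used_codons.append(gene.cds_offset(anchor) // 3)
                    ref_base = reference.base(gene.chromosome, anchor)
                    if signed_len > 0:
                        ins = "".join(_BASES[i] for i in rng.integers(0, 4, size=signed_len))
                        ref, alt = ref_base, ref_base + ins
                    else:
                        ref = reference.fetch(gene.chromosome, anchor, anchor - signed_len)
                        alt = ref_base
                    chrom, pos = gene.chromosome, anchor
                else:
                    ci, within, alt_coding = _snp_for_category(rng, cds, category, used_codons)
                    used_codons.append(ci)
                    offset = ci * 3 + within
                    pos = gene.coding_to_genomic(offset)
                    chrom = gene.chromosome
                    ref = reference.base(chrom, pos)
                    alt = alt_coding if gene.strand == "+" else complement[alt_coding]
                    expected = cds[offset] if gene.strand == "+" else complement[cds[offset]]
                    assert ref == expected, "coding/genomic frame mismatch"
                zyg = _draw_zygosity(rng, config.het_fraction)
                qual, depth = _passing_qual_depth(rng, config.base_depth)
                per_sample[sample].append(
                    VariantRecord(chrom, pos, ref, alt, qual, depth, zyg, sample)
                )
                truth_rows.append(
                    {
                        "sample": sample, "chromosome": chrom, "position": pos,
                        "ref": ref, "alt": alt, "zygosity": zyg.value,
                        "effect": category,
                    }
                )
                span_end = pos + max(len(ref), 1)
                blocked[chrom].addi(pos - spacing, span_end + spacing)


def _place_sv_events(
    rng: np.random.Generator, reference: GenomeReference, config: SimulationConfig
) -> pd.DataFrame:
    """Assign well-separated breakpoint territories to planted SV events."""
    rows = []
    if config.n_sv_per_type == 0:
        return pd.DataFrame(
            rows, columns=["sample", "sv_type", "chrom_a", "pos_a", "chrom_b", "pos_b"]
        )
    names = reference.names
    events = [
        (sample, sv_type)
        for sample in config.sample_names
        for sv_type in (SVType.CTX, SVType.ITX, SVType.INV)
        for _ in range(config.n_sv_per_type)
    ]
    # first pass: chromosome demand
    demand: list[tuple[int, str, SVType, list[str]]] = []
    cycle = 0
    counts = {n: 0 for n in names}
    for i, (sample, sv_type) in enumerate(events):
        if sv_type is SVType.CTX:
            ca, cb = names[cycle % len(names)], names[(cycle + 1) % len(names)]
            cycle += 2
            counts[ca] += 1
            counts[cb] += 1
            demand.append((i, sample, sv_type, [ca, cb]))
        else:
            c = names[cycle % len(names)]
            cycle += 1
            counts[c] += 1
            demand.append((i, sample, sv_type, [c]))
    margin = config.insert_size_mean + 5 * config.insert_size_sd + config.read_length
    widths = {}
    for name in names:
        if counts[name] == 0:
            continue
        w = (reference.lengths[name] - 2 * margin) // counts[name]
        if w < max(8 * (config.insert_size_mean + 3 * config.insert_size_sd), 4000):
            raise SimulationError("too many SV events for the genome size")
        widths[name] = w
    next_territory = {n: 0 for n in names}

    def territory(chrom):
        k = next_territory[chrom]
        next_territory[chrom] += 1
        start = margin + k * widths[chrom]
        return start, widths[chrom]

    for i, sample, sv_type, chroms in demand:
        if sv_type is SVType.CTX:
            (t0a, wa), (t0b, wb) = territory(chroms[0]), territory(chroms[1])
            pos_a = t0a + wa // 2 + int(rng.integers(-wa // 8, wa // 8))
            pos_b = t0b + wb // 2 + int(rng.integers(-wb // 8, wb // 8))
            rows.append(
                {"sample": sample, "sv_type": "CTX", "chrom_a": chroms[0],
                 "pos_a": pos_a, "chrom_b": chroms[1], "pos_b": pos_b}
            )
        else:
            t0, w = territory(chroms[0])
            if sv_type is SVType.ITX:
                pos_a = t0 + int(rng.integers(0, w // 8))
                sep = int(rng.integers(w // 2, int(w * 0.8)))
            else:
                pos_a = t0 + int(rng.integers(0, w // 4))
                sep = int(rng.integers(max(1000, w // 8), w // 3))
            if sep <= config.read_length:
                raise SimulationError("SV breakpoints closer than one read length")
            rows.append(
                {"sample": sample, "sv_type": sv_type.value, "chrom_a": chroms[0],
                 "pos_a": pos_a, "chrom_b": chroms[0], "pos_b": pos_a + sep}
            )
    return pd.DataFrame(rows, columns=["sample", "sv_type", "chrom_a", "pos_a", "chrom_b", "pos_b"])


# ---------------------------------------------------------------------------
# depth profiles

CONTROL_SAMPLE = "control"


def simulate_depth_profiles(
    reference: GenomeReference,
    genes: list[GeneModel],
    truth: TruthSet,
    config: SimulationConfig,
) -> dict[str, DepthProfile]:
    """Per-base depth per genotype plus the reference-vs-self control.

    Baseline depth is Normal(base_depth, depth_noise_sd) truncated at zero,
    piecewise-constant over ``depth_tile``-bp tiles. Deleted genes drop to
    zero except for a small residual covered fraction; duplicated genes double.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 3])
    by_id = {g.gene_id: g for g in genes}
    profiles: dict[str, DepthProfile] = {}
    tile = config.depth_tile
    for sample in config.sample_names + [CONTROL_SAMPLE]:
        depth: dict[str, np.ndarray] = {}
        for name, length in reference.lengths.items():
            n_tiles = -(-length // tile)
            tiles = np.clip(
                np.round(rng.normal(config.base_depth, config.depth_noise_sd, n_tiles)),
                0, None,
            ).astype(np.int32)
            depth[name] = np.repeat(tiles, tile)[:length].copy()
        if sample != CONTROL_SAMPLE:
            ev = truth.gene_events[truth.gene_events["sample"] == sample]
            for _, row in ev.iterrows():
                gene = by_id[row.gene_id]
                arr = depth[gene.chromosome]
                lo, hi = gene.start - 1, gene.end
                if row.event == "duplication":
                    arr[lo:hi] *= 2
                else:
                    original = arr[lo:hi].copy()
                    arr[lo:hi] = 0
                    # small residual covered stretch: mapping-noise analog
                    n_resid = int((hi - lo) * config.residual_coverage_fraction)
                    if n_resid:
                        off = int(rng.integers(0, hi - lo - n_resid))
                        arr[lo + off : lo + off + n_resid] = original[off : off + n_resid]
        profiles[sample] = DepthProfile(sample=sample, depth=depth)
    return profiles


# ---------------------------------------------------------------------------
# discordant pairs


def simulate_discordant_pairs(
    reference: GenomeReference,
    truth: TruthSet,
    config: SimulationConfig,
) -> dict[str, list[DiscordantPair]]:
    """Mate-pair evidence for every planted SV plus background noise.

    Each event is supported by ``sv_support`` pairs whose inner edges jitter
    within one insert-size SD of the true breakpoints; CTX/ITX pairs use
    opposite mate orientations, INV pairs share a common orientation.
    The control emits only noise pairs.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 4])
    rl = config.read_length
    sd = max(1, config.insert_size_sd)
    out: dict[str, list[DiscordantPair]] = {}
    for sample in config.sample_names + [CONTROL_SAMPLE]:
        pairs: list[DiscordantPair] = []
        if sample != CONTROL_SAMPLE:
            ev = truth.sv_events[truth.sv_events["sample"] == sample]
            for k, (_, row) in enumerate(ev.iterrows()):
                inv_orient = "+" if rng.random() < 0.5 else "-"
                for i in range(config.sv_support):
                    j1 = int(rng.integers(0, sd))
                    j2 = int(rng.integers(0, sd))
                    rid = f"{sample}_sv{k}_p{i}"
                    if row.sv_type == "INV":
                        s1, s2 = inv_orient, inv_orient
                    else:
                        s1, s2 = "+", "-"
                    if s1 == "+":
                        end1 = row.pos_a - 1 - j1
                        start1 = end1 - rl
                    else:
                        start1 = row.pos_a - 1 + j1
                        end1 = start1 + rl
                    if s2 == "-":
                        start2 = row.pos_b - 1 + j2
                        end2 = start2 + rl
                    else:
                        end2 = row.pos_b - 1 - j2
                        start2 = end2 - rl
                    pairs.append(
                        DiscordantPair(
                            chrom1=row.chrom_a, start1=start1, end1=end1,
                            chrom2=row.chrom_b, start2=start2, end2=end2,
                            strand1=s1, strand2=s2, mapq=60,
                            sample=sample, read_id=rid,
                        )
                    )
        names = reference.names
        lengths = reference.lengths
        for i in range(config.n_noise_pairs):
            chrom = names[rng.integers(0, len(names))]
            start1 = int(rng.integers(rl, lengths[chrom] - config.insert_size_mean - 4 * sd - rl))
            outer = config.insert_size_mean + int(rng.integers(-2 * sd, 2 * sd))
            pairs.append(
                DiscordantPair(
                    chrom1=chrom, start1=start1, end1=start1 + rl,
                    chrom2=chrom, start2=start1 + outer - rl, end2=start1 + outer,
                    strand1="+", strand2="-", mapq=60,
                    sample=sample, read_id=f"{sample}_noise{i}",
                )
            )
        if len(names) > 1:
            for i in range(10):
                ca, cb = names[0], names[-1]
                p1 = int(rng.integers(rl, lengths[ca] - rl))
                p2 = int(rng.integers(rl, lengths[cb] - rl))
                pairs.append(
                    DiscordantPair(
                        chrom1=ca, start1=p1, end1=p1 + rl,
                        chrom2=cb, start2=p2, end2=p2 + rl,
                        strand1="+", strand2="-", mapq=int(rng.integers(0, 30)),
                        sample=sample, read_id=f"{sample}_lowq{i}",
                    )
                )
        out[sample] = pairs
    return out


def simulate_panel(config: SimulationConfig) -> SimulatedPanel:
    """Run all four generators with one seed; identical seed + config give
    byte-identical outputs."""
    reference, genes = generate_reference(config)
    records, truth = simulate_panel_variants(reference, genes, config)
    depths = simulate_depth_profiles(reference, genes, truth, config)
    pairs = simulate_discordant_pairs(reference, truth, config)
    return SimulatedPanel(
        config=config, reference=reference, genes=genes,
        records=records, truth=truth, depths=depths, pairs=pairs,
    )
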