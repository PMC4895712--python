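"""Paper-schema reports: per-sample effect tables, the SV type-by-chromosome
matrix, named-region reports and plain-text variant tracks."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .effects import (
    Effect,
    EffectCall,
    MISSENSE_EFFECTS,
    NONSENSE_EFFECTS,
    Region,
)
from .panel import HET, HOM_ALT, PanelMatrix


@dataclass(frozen=True)
class RegionQuery:
    """A named 1-based inclusive genomic interval (e.g. a QTL hotspot)."""

    name: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end or self.start < 1:
            raise ValueError(f"invalid region {self.name}: {self.start}-{self.end}")

    @classmethod
    def parse(cls, text: str) -> "RegionQuery":
        """Parse 'name:chrom:start-end'."""
        name, chrom, span = text.split(":")
        start, end = span.split("-")
        return cls(name, chrom, int(start), int(end))


_EFFECT_COLUMNS = [
    ("non_synonymous_coding", Effect.NON_SYNONYMOUS_CODING),
    ("non_synonymous_start", Effect.NON_SYNONYMOUS_START),
    ("start_lost", Effect.START_LOST),
    ("stop_gained", Effect.STOP_GAINED),
    ("stop_lost", Effect.STOP_LOST),
    ("synonymous_coding", Effect.SYNONYMOUS_CODING),
    ("synonymous_stop", Effect.SYNONYMOUS_STOP),
    ("frame_shift", Effect.FRAME_SHIFT),
    ("codon_insertion", Effect.CODON_INSERTION),
    ("codon_deletion", Effect.CODON_DELETION),
]


def table1_report(
    panel: PanelMatrix, effects: dict[tuple, EffectCall]
) -> pd.DataFrame:
    """Per-sample counts of intergenic / intronic / exonic variants with the
    exon effect subclasses, an ``others`` column, a row total, and a genome
    totals row. A variant counts for a sample when that sample carries the
    alternate allele."""
    rows = []
    for sample in panel.samples:
        col = panel.sample_column(sample)
        counts = {key: 0 for key, _ in _EFFECT_COLUMNS}
        counts.update({"intergenic": 0, "intron": 0, "exon": 0, "others": 0})
        for i, site in enumerate(panel.sites):
            if col[i] not in (HET, HOM_ALT):
                continue
            call = effects[site.key]
            if call.region is Region.INTERGENIC:
                counts["intergenic"] += 1
            elif call.region is Region.INTRON:
                counts["intron"] += 1
            elif call.region is Region.EXON:
                counts["exon"] += 1
                for key, effect in _EFFECT_COLUMNS:
                    if call.effect is effect:
                        counts[key] += 1
            else:
                counts["others"] += 1
        counts["total"] = (
            counts["intergenic"] + counts["intron"] + counts["exon"] + counts["others"]
        )
        rows.append({"sample": sample, **counts})
    table = pd.DataFrame(rows).set_index("sample")
    table.loc["Total"] = table.sum(axis=0)
    return table


def region_report(
    query: RegionQuery,
    panel: PanelMatrix,
    effects: dict[tuple, EffectCall],
) -> dict:
    """Variants inside a named region, their effect breakdown, and the
    distinct genes hit by non-synonymous classes."""
    chroms = {s.chromosome for s in panel.sites}
    if panel.sites and query.chromosome not in chroms:
        raise KeyError(f"unknown chromosome {query.chromosome!r}")
    hits = [
        s
        for s in panel.sites
        if s.chromosome == query.chromosome and query.start <= s.position <= query.end
    ]
    breakdown: dict[str, int] = {}
    affected_genes: set[str] = set()
    for site in hits:
        call = effects[site.key]
        label = call.effect.value if call.effect is not Effect.NONE else call.region.value
        breakdown[label] = breakdown.get(label, 0) + 1
        if call.effect in (MISSENSE_EFFECTS | NONSENSE_EFFECTS) and call.gene_id:
            affected_genes.add(call.gene_id)
    return {
        "region": query,
        "n_variants": len(hits),
        "variants": hits,
        "effect_breakdown": breakdown,
        "affected_genes": sorted(affected_genes),
    }


def export_tracks(
    panel: PanelMatrix,
    line_specific: dict[str, dict[str, list]],
    gene_events: dict[str, list],
    genes_by_id: dict,
    directory,
) -> list[Path]:
    """Per-sample BED tracks of line-specific SNPs, line-specific Indels,
    gene deletions and gene duplications (one file per ring of a circos-style
    figure). Empty but valid files are written when a sample has no entries."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for sample in panel.samples:
        ls = line_specific.get(sample, {"snps": [], "indels": []})
        for ring, sites in (("snps", ls["snps"]), ("indels", ls["indels"])):
            path = directory / f"{sample}.line_specific_{ring}.bed"
            with open(path, "w") as fh:
                for site in sites:
                    span = max(len(site.ref_allele), 1)
                    fh.write(
                        f"{site.chromosome}\t{site.position - 1}"
                        f"\t{site.position - 1 + span}\t{site.alt_allele}\n"
                    )
            written.append(path)
        events = gene_events.get(sample, [])
        for ring, wanted in (("deletions", "ABSENT"), ("duplications", "DUPLICATED")):
            path = directory / f"{sample}.gene_{ring}.bed"
            with open(path, "w") as fh:
                for call in events:
                    if call.event.value != wanted:
                        continue
                    gene = genes_by_id[call.gene_id]
                    fh.write(
                        f"{gene.chromosome}\t{gene.start - 1}\t{gene.end}\t{gene.gene_id}\n"
                    )
            written.append(path)
    return written


def write_window_tracks(window_densities, directory) -> tuple[Path, Path]:
    """Window counts as BED (per-kind counts) and bedGraph (total density)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    bed = directory / "windows.bed"
    bedgraph = directory / "windows.density.bedgraph"
    with open(bed, "w") as fb, open(bedgraph, "w") as fg:
        for w in window_densities:
            fb.write(
                f"{w.chromosome}\t{w.window_start}\t{w.window_end}"
                f"\t{w.n_snps};{w.n_insertions};{w.n_deletions}\n"
            )
            fg.write(
                f"{w.chromosome}\t{w.window_start}\t{w.window_end}\t{w.density:.4f}\n"
            )
    return bed, bedgraph
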