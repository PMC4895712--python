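"""Readers and writers for the panel's on-disk formats.

FASTA and VCF v4.2 go through Biopython and pysam; GFF3 is written as plain
text and read back with gffutils; bedGraph, the BEDPE-like pair table and the
truth tables are TSV handled with pandas. VCF and GFF3 are 1-based inclusive,
bedGraph and BEDPE 0-based half-open (see :mod:`panelvar.coords`).
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
import gffutils

from .cnv_pav import DepthProfile
from .filtering import Genotype, VariantRecord
from .genome import GeneModel, GenomeReference, compute_phases
from .simulate import SimulatedPanel, TruthSet
from .sv import DiscordantPair

BEDPE_COLUMNS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2",
    "name", "mapq", "strand1", "strand2",
]


# --- FASTA ------------------------------------------------------------------


def write_fasta(reference: GenomeReference, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in reference.sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> GenomeReference:
    seqs = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }
    return GenomeReference(seqs)


# --- GFF3 -------------------------------------------------------------------


def write_gff3(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in genes:
            base = (gene.chromosome, "panelvar")
            fh.write(
                "\t".join(
                    map(str, [*base, "gene", gene.start, gene.end, ".",
                              gene.strand, ".", f"ID={gene.gene_id}"])
                ) + "\n"
            )
            mrna_id = f"{gene.gene_id}.t1"
            fh.write(
                "\t".join(
                    map(str, [*base, "mRNA", gene.start, gene.end, ".",
                              gene.strand, ".", f"ID={mrna_id};Parent={gene.gene_id}"])
                ) + "\n"
            )
            for i, (s, e) in enumerate(gene.exons, 1):
                fh.write(
                    "\t".join(
                        map(str, [*base, "exon", s, e, ".", gene.strand, ".",
                                  f"ID={mrna_id}.exon{i};Parent={mrna_id}"])
                    ) + "\n"
                )
            for i, (s, e, phase) in enumerate(gene.cds, 1):
                fh.write(
                    "\t".join(
                        map(str, [*base, "CDS", s, e, ".", gene.strand, phase,
                                  f"ID={mrna_id}.cds{i};Parent={mrna_id}"])
                    ) + "\n"
                )


def read_gff3(path) -> list[GeneModel]:
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        exons = sorted(
            (f.start, f.end) for f in db.children(g, featuretype="exon")
        )
        cds = sorted(
            (f.start, f.end) for f in db.children(g, featuretype="CDS")
        )
        genes.append(
            GeneModel(
                gene_id=g.id,
                chromosome=g.seqid,
                strand=g.strand,
                exons=exons,
                cds=compute_phases(cds, g.strand),
            )
        )
    return genes


# --- VCF --------------------------------------------------------------------

_GT_FIELD = {
    Genotype.HOM_REF: (0, 0),
    Genotype.HET: (0, 1),
    Genotype.HOM_ALT: (1, 1),
    Genotype.MISSING: (None, None),
}


def _vcf_header(sample: str, reference: GenomeReference) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in reference.lengths.items():
        header.contigs.add(name, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.filters.add("LowQualDepth", None, None, "Quality/depth filter failed")
    header.filters.add("FlankDistance", None, None, "Neighbour closer than minimum flank")
    header.add_sample(sample)
    return header


def write_vcf(
    records: list[VariantRecord],
    sample: str,
    reference: GenomeReference,
    path,
    filter_tags: dict | None = None,
) -> None:
    """Write one sample's records as VCF v4.2 (QUAL, GT and DP populated).

    ``filter_tags`` optionally maps a record's site key to a FILTER label for
    writing a rejects file.
    """
    header = _vcf_header(sample, reference)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in sorted(records, key=lambda r: (r.chromosome, r.position, r.alt_allele)):
            row = out.new_record(
                contig=rec.chromosome,
                start=rec.position - 1,
                alleles=(rec.ref_allele, rec.alt_allele),
            )
            row.qual = rec.quality
            tag = (filter_tags or {}).get(rec.site)
            if tag:
                row.filter.add(tag)
            row.samples[sample]["GT"] = _GT_FIELD[rec.genotype]
            row.samples[sample]["DP"] = rec.sample_depth
            out.write(row)


def read_vcf(path, sample: str | None = None) -> list[VariantRecord]:
    """Read one-sample VCF into VariantRecords (first ALT; multi-allelic
    records are flagged)."""
    out = []
    with pysam.VariantFile(str(path)) as vcf:
        names = list(vcf.header.samples)
        sample = sample or names[0]
        for row in vcf:
            alts = row.alts or ()
            if not alts:
                continue
            call = row.samples[sample]
            gt = call.get("GT")
            if gt is None or any(a is None for a in gt):
                genotype = Genotype.MISSING
            elif all(a == 0 for a in gt):
                genotype = Genotype.HOM_REF
            elif all(a >= 1 for a in gt):
                genotype = Genotype.HOM_ALT
            else:
                genotype = Genotype.HET
            out.append(
                VariantRecord(
                    chromosome=row.contig,
                    position=row.pos,
                    ref_allele=row.ref,
                    alt_allele=alts[0],
                    quality=float(row.qual) if row.qual is not None else 0.0,
                    sample_depth=int(call.get("DP") or 0),
                    genotype=genotype,
                    sample=sample,
                    multiallelic=len(alts) > 1,
                )
            )
    return out


# --- bedGraph ---------------------------------------------------------------


def write_bedgraph(profile: DepthProfile, path) -> None:
    """Run-length-encoded per-base depth; intervals tile each chromosome."""
    with open(path, "w") as fh:
        for name, arr in profile.depth.items():
            if len(arr) == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(arr)]))
            for s, e in zip(starts, ends):
                fh.write(f"{name}\t{s}\t{e}\t{int(arr[s])}\n")


def read_bedgraph(path, sample: str, lengths: dict[str, int]) -> DepthProfile:
    depth = {name: np.zeros(length, dtype=np.int32) for name, length in lengths.items()}
    table = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"]
    )
    for row in table.itertuples(index=False):
        depth[row.chrom][row.start : row.end] = row.value
    return DepthProfile(sample=sample, depth=depth)


# --- BEDPE-like pair table --------------------------------------------------


def write_bedpe(pairs: list[DiscordantPair], path) -> None:
    rows = [
        {
            "chrom1": p.chrom1, "start1": p.start1, "end1": p.end1,
            "chrom2": p.chrom2, "start2": p.start2, "end2": p.end2,
            "name": p.read_id, "mapq": p.mapq,
            "strand1": p.strand1, "strand2": p.strand2,
        }
        for p in pairs
    ]
    pd.DataFrame(rows, columns=BEDPE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_bedpe(path, sample: str) -> list[DiscordantPair]:
    table = pd.read_csv(path, sep="\t")
    return [
        DiscordantPair(
            chrom1=row.chrom1, start1=int(row.start1), end1=int(row.end1),
            chrom2=row.chrom2, start2=int(row.start2), end2=int(row.end2),
            strand1=row.strand1, strand2=row.strand2,
            mapq=int(row.mapq), sample=sample, read_id=str(row.name_),
        )
        for row in table.rename(columns={"name": "name_"}).itertuples(index=False)
    ]


# --- truth tables -----------------------------------------------------------


def write_truth(truth: TruthSet, directory) -> None:
    directory = Path(directory)
    truth.variants.to_csv(directory / "truth_variants.tsv", sep="\t", index=False)
    truth.gene_events.to_csv(directory / "truth_gene_events.tsv", sep="\t", index=False)
    truth.sv_events.to_csv(directory / "truth_sv_events.tsv", sep="\t", index=False)


def read_truth(directory) -> TruthSet:
    directory = Path(directory)
    variants = pd.read_csv(
        directory / "truth_variants.tsv", sep="\t",
        dtype={"effect": str}, keep_default_na=False,
    )
    if len(variants):
        variants["line_specific"] = variants["line_specific"].astype(str).isin(
            ["True", "true", "1"]
        )
    gene_events = pd.read_csv(directory / "truth_gene_events.tsv", sep="\t")
    sv_events = pd.read_csv(directory / "truth_sv_events.tsv", sep="\t")
    return TruthSet(variants=variants, gene_events=gene_events, sv_events=sv_events)


# --- whole panel ------------------------------------------------------------


def write_panel(panel: SimulatedPanel, directory) -> None:
    """Write every component of a simulated panel under one directory."""
    directory = Path(directory)
    os.makedirs(directory, exist_ok=True)
    write_fasta(panel.reference, directory / "reference.fa")
    write_gff3(panel.genes, directory / "genes.gff3")
    for sample, records in panel.records.items():
        write_vcf(records, sample, panel.reference, directory / f"{sample}.vcf")
    for sample, profile in panel.depths.items():
        write_bedgraph(profile, directory / f"{sample}.depth.bedgraph")
    for sample, pairs in panel.pairs.items():
        write_bedpe(pairs, directory / f"{sample}.pairs.tsv")
    write_truth(panel.truth, directory)


def read_panel(directory, config=None) -> SimulatedPanel:
    """Read a panel directory back into memory (inverse of write_panel)."""
    directory = Path(directory)
    reference = read_fasta(directory / "reference.fa")
    genes = read_gff3(directory / "genes.gff3")
    truth = read_truth(directory)
    records, depths, pairs = {}, {}, {}
    samples = sorted(
        p.name[: -len(".vcf")] for p in directory.glob("*.vcf")
    )
    for sample in samples:
        records[sample] = read_vcf(directory / f"{sample}.vcf", sample)
    for path in sorted(directory.glob("*.depth.bedgraph")):
        sample = path.name[: -len(".depth.bedgraph")]
        depths[sample] = read_bedgraph(path, sample, reference.lengths)
    for path in sorted(directory.glob("*.pairs.tsv")):
        sample = path.name[: -len(".pairs.tsv")]
        pairs[sample] = read_bedpe(path, sample)
    return SimulatedPanel(
        config=config, reference=reference, genes=genes,
        records=records, truth=truth, depths=depths, pairs=pairs,
    )
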