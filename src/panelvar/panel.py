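"""Variants x samples panel matrix and panel-level statistics.

Merges filtered per-sample calls into a union-of-sites genotype matrix and
computes zygosity classes, the per-sample heterozygosity rate, pairwise SNP
counts, line-specific variants (non-reference in exactly one genotype, the
reference allele confidently present in all others), and the
insertion/deletion ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .filtering import Genotype, VariantClass, VariantKind, VariantRecord, classify_variant

if TYPE_CHECKING:  # pragma: no cover
    from .cnv_pav import DepthProfile

# integer codes used in the calls matrix
CODE = {
    Genotype.HOM_REF: 0,
    Genotype.HET: 1,
    Genotype.HOM_ALT: 2,
    Genotype.MISSING: -1,
}
HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1


@dataclass(frozen=True)
class Site:
    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str
    variant_class: VariantClass

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chromosome, self.position, self.ref_allele, self.alt_allele)


@dataclass
class PanelMatrix:
    """Union sites x ordered samples genotype table.

    ``calls[i, j]`` is the genotype code of sample ``j`` at site ``i``.
    """

    sites: list[Site]
    calls: np.ndarray  # int8, shape (n_sites, n_samples)
    samples: list[str]
    _sample_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self):
        self._sample_index = {s: j for j, s in enumerate(self.samples)}
        if self.calls.shape != (len(self.sites), len(self.samples)):
            raise ValueError("calls shape does not match sites x samples")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_column(self, sample: str) -> np.ndarray:
        try:
            return self.calls[:, self._sample_index[sample]]
        except KeyError:
            raise KeyError(f"unknown sample {sample!r}") from None

    def kind_mask(self, kind: VariantKind) -> np.ndarray:
        return np.array([s.variant_class.kind is kind for s in self.sites], dtype=bool)


@dataclass
class SampleSummary:
    sample: str
    n_snps: int
    n_insertions: int
    n_deletions: int
    n_hom: int
    n_het: int
    heterozygosity_rate: float
    indel_ratio: float | None


def build_panel(
    per_sample_records: dict[str, list[VariantRecord]],
    depth_profiles: dict[str, "DepthProfile"] | None = None,
    min_depth: int = 5,
) -> PanelMatrix:
    """Merge filtered per-sample calls into a :class:`PanelMatrix`.

    Sites are the union across samples, ordered by (chromosome, position,
    ref, alt). A sample without a record at a union site is called ``hom_ref``
    when its depth profile covers the site at >= ``min_depth`` reads (or when
    no profiles are supplied), else ``missing``. Two records at one position
    whose REF alleles disagree on the anchor base indicate inconsistent
    reference frames and raise ValueError.
    """
    samples = sorted(per_sample_records)
    site_map: dict[tuple, VariantClass] = {}
    anchor: dict[tuple[str, int], str] = {}
    for recs in per_sample_records.values():
        for rec in recs:
            pos_key = (rec.chromosome, rec.position)
            first = anchor.setdefault(pos_key, rec.ref_allele[0])
            if rec.ref_allele[0] != first:
                raise ValueError(
                    f"conflicting REF alleles at {rec.chromosome}:{rec.position}"
                )
            site_map.setdefault(rec.site, classify_variant(rec))
    keys = sorted(site_map)
    sites = [Site(*k, site_map[k]) for k in keys]
    index = {k: i for i, k in enumerate(keys)}

    calls = np.empty((len(sites), len(samples)), dtype=np.int8)
    for j, sample in enumerate(samples):
        if depth_profiles is None:
            column = np.full(len(sites), HOM_REF, dtype=np.int8)
        else:
            profile = depth_profiles[sample]
            column = np.array(
                [
                    HOM_REF
                    if profile.depth_at(s.chromosome, s.position) >= min_depth
                    else MISSING
                    for s in sites
                ],
                dtype=np.int8,
            )
        for rec in per_sample_records[sample]:
            column[index[rec.site]] = CODE[rec.genotype]
        calls[:, j] = column
    return PanelMatrix(sites, calls, samples)


def zygosity_counts(panel: PanelMatrix, sample: str) -> tuple[int, int, float]:
    """(n_hom, n_het, heterozygosity_rate) over the sample's SNP calls.

    ``n_hom`` counts hom-alt SNP calls, ``n_het`` heterozygous SNP calls;
    rate = het / (het + hom), defined as 0 when the sample has no SNP calls.
    """
    col = panel.sample_column(sample)
    snp = panel.kind_mask(VariantKind.SNP)
    n_hom = int(np.sum((col == HOM_ALT) & snp))
    n_het = int(np.sum((col == HET) & snp))
    denom = n_hom + n_het
    return n_hom, n_het, (n_het / denom if denom else 0.0)


def pairwise_snp_count(panel: PanelMatrix, a: str, b: str) -> int:
    """SNP sites where the called genotypes of two samples differ.

    Sites where either sample is missing are excluded.
    """
    if a == b:
        raise ValueError("pairwise count requires two distinct samples")
    ca, cb = panel.sample_column(a), panel.sample_column(b)
    snp = panel.kind_mask(VariantKind.SNP)
    ok = (ca != MISSING) & (cb != MISSING)
    return int(np.sum(snp & ok & (ca != cb)))


def pairwise_snp_matrix(panel: PanelMatrix) -> pd.DataFrame:
    """Symmetric samples x samples matrix of pairwise SNP counts."""
    n = len(panel.samples)
    out = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            c = pairwise_snp_count(panel, panel.samples[i], panel.samples[j])
            out[i, j] = out[j, i] = c
    return pd.DataFrame(out, index=panel.samples, columns=panel.samples)


def line_specific_variants(panel: PanelMatrix) -> dict[str, dict[str, list[Site]]]:
    """Per-sample line-specific variants, SNPs and Indels separately.

    A site is line-specific for sample ``s`` iff ``s`` carries the alternate
    allele (het or hom-alt) and every other sample is confidently hom-ref; a
    missing call in any other sample disqualifies the site.
    """
    out: dict[str, dict[str, list[Site]]] = {
        s: {"snps": [], "indels": []} for s in panel.samples
    }
    calls = panel.calls
    nonref = (calls == HET) | (calls == HOM_ALT)
    homref = calls == HOM_REF
    for i, site in enumerate(panel.sites):
        row_nonref = nonref[i]
        if row_nonref.sum() != 1:
            continue
        j = int(np.argmax(row_nonref))
        others = np.ones(len(panel.samples), dtype=bool)
        others[j] = False
        if not homref[i][others].all():
            continue
        kind = site.variant_class.kind
        if kind is VariantKind.SNP:
            out[panel.samples[j]]["snps"].append(site)
        elif kind in (VariantKind.INSERTION, VariantKind.DELETION):
            out[panel.samples[j]]["indels"].append(site)
    return out


def indel_ratio(panel: PanelMatrix, sample: str) -> float | None:
    """Insertions / deletions among the sample's non-reference calls.

    ``None`` (absent) when the sample carries no deletions.
    """
    col = panel.sample_column(sample)
    nonref = (col == HET) | (col == HOM_ALT)
    ins = int(np.sum(panel.kind_mask(VariantKind.INSERTION) & nonref))
    dele = int(np.sum(panel.kind_mask(VariantKind.DELETION) & nonref))
    if dele == 0:
        return None
    return ins / dele


def sample_summary(panel: PanelMatrix, sample: str) -> SampleSummary:
    col = panel.sample_column(sample)
    nonref = (col == HET) | (col == HOM_ALT)
    n_snps = int(np.sum(panel.kind_mask(VariantKind.SNP) & nonref))
    n_ins = int(np.sum(panel.kind_mask(VariantKind.INSERTION) & nonref))
    n_del = int(np.sum(panel.kind_mask(VariantKind.DELETION) & nonref))
    n_hom, n_het, rate = zygosity_counts(panel, sample)
    return SampleSummary(
        sample=sample,
        n_snps=n_snps,
        n_insertions=n_ins,
        n_deletions=n_del,
        n_hom=n_hom,
        n_het=n_het,
        heterozygosity_rate=rate,
        indel_ratio=indel_ratio(panel, sample),
    )


def summary_table(panel: PanelMatrix) -> pd.DataFrame:
    """Per-sample summary with line-specific counts (one row per sample)."""
    ls = line_specific_variants(panel)
    rows = []
    for sample in panel.samples:
        s = sample_summary(panel, sample)
        ls_snps = len(ls[sample]["snps"])
        ls_indel_sites = ls[sample]["indels"]
        ls_del = sum(
            1 for x in ls_indel_sites if x.variant_class.kind is VariantKind.DELETION
        )
        ls_ins = len(ls_indel_sites) - ls_del
        rows.append(
            {
                "sample": sample,
                "total_snps": s.n_snps,
                "line_specific_snps": ls_snps,
                "total_deletions": s.n_deletions,
                "line_specific_deletions": ls_del,
                "total_insertions": s.n_insertions,
                "line_specific_insertions": ls_ins,
                "n_hom": s.n_hom,
                "n_het": s.n_het,
                "heterozygosity_rate": s.heterozygosity_rate,
                "indel_ratio": s.indel_ratio,
            }
        )
    return pd.DataFrame(rows).set_index("sample")
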