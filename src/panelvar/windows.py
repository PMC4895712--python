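"""Distribution statistics: 100-kb window counts, per-pseudomolecule densities
and the Indel length spectrum.

Windows are fixed (non-sliding) tiles anchored at coordinate 0; the last
window of a chromosome may be short. Densities are per kb. All statistics are
computed over union sites of the panel, so they are invariant to sample order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .filtering import VariantKind, MAX_INDEL_LENGTH
from .genome import GenomeReference
from .panel import PanelMatrix

DEFAULT_WINDOW = 100_000


@dataclass(frozen=True)
class WindowDensity:
    chromosome: str
    window_start: int  # 0-based
    window_end: int  # exclusive; min(start + window, chromosome length)
    n_snps: int
    n_insertions: int
    n_deletions: int

    @property
    def density(self) -> float:
        """All counted variants per kb of actual window span."""
        span_kb = (self.window_end - self.window_start) / 1000.0
        return (self.n_snps + self.n_insertions + self.n_deletions) / span_kb


def window_counts(
    panel: PanelMatrix, reference: GenomeReference, window: int = DEFAULT_WINDOW
) -> list[WindowDensity]:
    """Count union sites per fixed window of each chromosome.

    Every site is assigned to exactly one window by its (1-based) anchor
    position; window counts sum to chromosome totals.
    """
    if window <= 0:
        raise ValueError("window size must be >= 1")
    counters: dict[str, np.ndarray] = {}
    for name, length in reference.lengths.items():
        n_windows = max(1, -(-length // window))
        counters[name] = np.zeros((n_windows, 3), dtype=int)
    col = {VariantKind.SNP: 0, VariantKind.INSERTION: 1, VariantKind.DELETION: 2}
    for site in panel.sites:
        kind = site.variant_class.kind
        if kind not in col:
            continue
        widx = (site.position - 1) // window
        counters[site.chromosome][widx, col[kind]] += 1
    out = []
    for name, length in reference.lengths.items():
        for w, (n_snp, n_ins, n_del) in enumerate(counters[name]):
            start = w * window
            out.append(
                WindowDensity(
                    name, start, min(start + window, length),
                    int(n_snp), int(n_ins), int(n_del),
                )
            )
    return out


def chromosome_density(
    panel: PanelMatrix,
    reference: GenomeReference,
    exonic_sites: set[tuple[str, int, str, str]] | None = None,
) -> pd.DataFrame:
    """Per-chromosome SNP density, polymorphism rate and exonic variant
    density, all per kb.

    ``snp_density`` counts SNP union sites; ``polymorphism_rate`` counts SNP
    plus Indel union sites; ``exon_variant_density`` counts sites in
    ``exonic_sites`` (site keys from the effect annotator) and is NaN when no
    annotation is supplied.
    """
    rows = []
    for name, length in reference.lengths.items():
        if length == 0:
            raise ValueError(f"zero-length chromosome {name}")
        kb = length / 1000.0
        n_snp = n_indel = n_exon = 0
        for site in panel.sites:
            if site.chromosome != name:
                continue
            kind = site.variant_class.kind
            if kind is VariantKind.SNP:
                n_snp += 1
            elif kind in (VariantKind.INSERTION, VariantKind.DELETION):
                n_indel += 1
            else:
                continue
            if exonic_sites is not None and site.key in exonic_sites:
                n_exon += 1
        rows.append(
            {
                "chromosome": name,
                "length": length,
                "n_snps": n_snp,
                "n_indels": n_indel,
                "snp_density": n_snp / kb,
                "polymorphism_rate": (n_snp + n_indel) / kb,
                "exon_variant_density": (n_exon / kb) if exonic_sites is not None else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("chromosome")


def indel_spectrum(panel: PanelMatrix) -> pd.DataFrame:
    """Length histogram (1..58) of insertion and deletion union sites."""
    lengths = np.arange(1, MAX_INDEL_LENGTH + 1)
    ins = np.zeros(MAX_INDEL_LENGTH, dtype=int)
    dels = np.zeros(MAX_INDEL_LENGTH, dtype=int)
    for site in panel.sites:
        vc = site.variant_class
        if vc.kind is VariantKind.INSERTION:
            ins[vc.length - 1] += 1
        elif vc.kind is VariantKind.DELETION:
            dels[vc.length - 1] += 1
    return pd.DataFrame(
        {"length": lengths, "n_insertions": ins, "n_deletions": dels}
    ).set_index("length")
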