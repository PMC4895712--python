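"""Per-gene presence/absence and duplication calling from read depth.

A gene (only genes >= 1,000 bp are considered) is called ABSENT in a genotype
when less than 10 % of its bases are covered, PRESENT when more than 50 % are
covered, and AMBIGUOUS in between; duplication is called when its mean depth,
normalized by the sample's genome-wide median depth, reaches a two-copy-like
ratio (default threshold 1.75). Events also observed in the reference-vs-self
control sample are excluded as false positives.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GeneModel

MIN_GENE_LENGTH = 1000
ABSENT_BREADTH = 0.10
PRESENT_BREADTH = 0.50
DEFAULT_DUP_THRESHOLD = 1.75


class GeneEvent(enum.Enum):
    ABSENT = "ABSENT"
    PRESENT = "PRESENT"
    AMBIGUOUS = "AMBIGUOUS"
    DUPLICATED = "DUPLICATED"
    NORMAL = "NORMAL"


@dataclass
class DepthProfile:
    """Per-base read depth for one sample, one array per chromosome."""

    sample: str
    depth: dict[str, np.ndarray]
    _median: float | None = field(default=None, repr=False)

    def __post_init__(self):
        for name, arr in self.depth.items():
            if (arr < 0).any():
                raise ValueError(f"negative depth on {name}")

    @property
    def genome_median_depth(self) -> float:
        if self._median is None:
            self._median = float(
                np.median(np.concatenate([a for a in self.depth.values()]))
            )
        return self._median

    def depth_at(self, chromosome: str, position: int) -> int:
        """Depth at a 1-based position."""
        return int(self.depth[chromosome][position - 1])

    def gene_slice(self, gene: GeneModel) -> np.ndarray:
        return self.depth[gene.chromosome][gene.start - 1 : gene.end]


@dataclass(frozen=True)
class GeneEventCall:
    gene_id: str
    sample: str
    event: GeneEvent
    breadth: float
    depth_ratio: float


class GeneTooShortError(ValueError):
    """Gene below the minimum length considered for CNV/PAV calling."""


def gene_coverage_stats(
    profile: DepthProfile, gene: GeneModel, min_covered_depth: int = 1
) -> tuple[float, float]:
    """(breadth, depth_ratio) of a gene span in one sample.

    breadth is the fraction of gene-span bases with depth >=
    ``min_covered_depth``; depth_ratio is the mean gene depth divided by the
    sample's genome-wide median depth.
    """
    if gene.length < MIN_GENE_LENGTH:
        raise GeneTooShortError(
            f"{gene.gene_id}: {gene.length} bp < {MIN_GENE_LENGTH} bp minimum"
        )
    d = profile.gene_slice(gene)
    breadth = float(np.mean(d >= min_covered_depth))
    median = profile.genome_median_depth
    ratio = float(np.mean(d) / median) if median > 0 else 0.0
    return breadth, ratio


def call_pav(breadth: float) -> GeneEvent:
    """ABSENT below 10 % breadth, PRESENT above 50 %, AMBIGUOUS between."""
    if not 0.0 <= breadth <= 1.0:
        raise ValueError("breadth must be within [0, 1]")
    if breadth < ABSENT_BREADTH:
        return GeneEvent.ABSENT
    if breadth > PRESENT_BREADTH:
        return GeneEvent.PRESENT
    return GeneEvent.AMBIGUOUS


def call_duplication(
    depth_ratio: float, threshold: float = DEFAULT_DUP_THRESHOLD
) -> GeneEvent:
    """DUPLICATED when normalized mean depth reaches the two-copy threshold."""
    if depth_ratio < 0:
        raise ValueError("depth_ratio must be >= 0")
    return GeneEvent.DUPLICATED if depth_ratio >= threshold else GeneEvent.NORMAL


def call_sample(
    profile: DepthProfile,
    genes: list[GeneModel],
    min_covered_depth: int = 1,
    dup_threshold: float = DEFAULT_DUP_THRESHOLD,
) -> list[GeneEventCall]:
    """PAV and duplication calls for every eligible gene in one sample.

    Emits one PAV call per gene (ABSENT/PRESENT/AMBIGUOUS) and additionally a
    DUPLICATED call when the normalized depth crosses the duplication
    threshold. Genes shorter than 1 kb are skipped.
    """
    calls = []
    for gene in genes:
        if gene.length < MIN_GENE_LENGTH:
            continue
        breadth, ratio = gene_coverage_stats(profile, gene, min_covered_depth)
        calls.append(
            GeneEventCall(gene.gene_id, profile.sample, call_pav(breadth), breadth, ratio)
        )
        if call_duplication(ratio, dup_threshold) is GeneEvent.DUPLICATED:
            calls.append(
                GeneEventCall(gene.gene_id, profile.sample, GeneEvent.DUPLICATED, breadth, ratio)
            )
    return calls


def exclude_control(
    calls: list[GeneEventCall], control_calls: list[GeneEventCall] | None
) -> list[GeneEventCall]:
    """Drop any (gene, event) pair also called in the control sample.

    The control is the reference genotype re-processed identically; events it
    shows are mapping artefacts, not variation. Idempotent.
    """
    if control_calls is None:
        raise ValueError("control calls are required for false-positive exclusion")
    control = {(c.gene_id, c.event) for c in control_calls}
    return [c for c in calls if (c.gene_id, c.event) not in control]


def event_calls_only(calls: list[GeneEventCall]) -> list[GeneEventCall]:
    """Keep the reportable events: ABSENT (gene deletion) and DUPLICATED."""
    return [c for c in calls if c.event in (GeneEvent.ABSENT, GeneEvent.DUPLICATED)]


def gene_event_sets(panel_calls: dict[str, list[GeneEventCall]]):
    """Panel-level event sets from per-sample calls.

    Returns ``(non_redundant_duplicated, non_redundant_absent,
    line_specific_events, per_gene_sample_counts)`` where the non-redundant
    sets are unions over samples, line-specific events occur in exactly one
    sample, and per_gene_sample_counts maps (gene, event) to the number of
    carrier samples.
    """
    carriers: dict[tuple[str, GeneEvent], list[str]] = {}
    for sample, calls in panel_calls.items():
        for c in event_calls_only(calls):
            carriers.setdefault((c.gene_id, c.event), []).append(sample)
    non_redundant_dup = {g for (g, e) in carriers if e is GeneEvent.DUPLICATED}
    non_redundant_abs = {g for (g, e) in carriers if e is GeneEvent.ABSENT}
    line_specific: dict[str, list[tuple[str, GeneEvent]]] = {
        s: [] for s in panel_calls
    }
    for (gene_id, event), samples in carriers.items():
        if len(samples) == 1:
            line_specific[samples[0]].append((gene_id, event))
    counts = {key: len(samples) for key, samples in carriers.items()}
    return non_redundant_dup, non_redundant_abs, line_specific, counts


def event_matrix(panel_calls: dict[str, list[GeneEventCall]]) -> pd.DataFrame:
    """Genes x samples matrix of event labels ('' where no event)."""
    samples = sorted(panel_calls)
    genes = sorted(
        {c.gene_id for calls in panel_calls.values() for c in event_calls_only(calls)}
    )
    mat = pd.DataFrame("", index=genes, columns=samples)
    for sample, calls in panel_calls.items():
        for c in event_calls_only(calls):
            prev = mat.at[c.gene_id, sample]
            mat.at[c.gene_id, sample] = (
                f"{prev}+{c.event.value}" if prev else c.event.value
            )
    return mat
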