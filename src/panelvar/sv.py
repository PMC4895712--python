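"""Discordant-pair structural-variant typing and breakpoint refinement.

Discordant mate pairs (mapping quality >= 30) are clustered by single linkage
on both mate spans, clusters are typed as inter-chromosomal translocation
(CTX), intra-chromosomal translocation (ITX) or inversion (INV) from their
mate geometry, scored on a 0-99 scale capped at 99, filtered at the
saturated-confidence cutoff of 99, cross-checked against a reference-vs-self
control, and refined to exact breakpoints from the inner edges of the
supporting mate spans.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

DEFAULT_MIN_MAPQ = 30
DEFAULT_MIN_SUPPORT = 2
DEFAULT_MIN_SCORE = 99
SCORE_CAP = 99
SCORE_PER_PAIR = 20


class SVType(enum.Enum):
    CTX = "CTX"
    ITX = "ITX"
    INV = "INV"


@dataclass(frozen=True)
class DiscordantPair:
    """One discordant mate pair; spans are 0-based half-open."""

    chrom1: str
    start1: int
    end1: int
    chrom2: str
    start2: int
    end2: int
    strand1: str
    strand2: str
    mapq: int
    sample: str
    read_id: str

    def __post_init__(self):
        if self.mapq < 0:
            raise ValueError("mapq must be >= 0")
        if self.start1 >= self.end1 or self.start2 >= self.end2:
            raise ValueError("empty mate span")

    def canonical(self) -> "DiscordantPair":
        """Order mates by (chromosome, start) so clustering and refinement do
        not depend on which mate was written first."""
        if (self.chrom1, self.start1) <= (self.chrom2, self.start2):
            return self
        return replace(
            self,
            chrom1=self.chrom2,
            start1=self.start2,
            end1=self.end2,
            chrom2=self.chrom1,
            start2=self.start1,
            end2=self.end1,
            strand1=self.strand2,
            strand2=self.strand1,
        )


@dataclass
class SVCall:
    sv_type: SVType
    chrom_a: str
    pos_a: int  # 1-based refined (or raw) breakpoint
    chrom_b: str
    pos_b: int
    size: int
    score: int
    n_supporting: int
    supporting_ids: list[str]
    sample: str
    refined: bool = False

    def __post_init__(self):
        if self.sv_type is SVType.CTX and self.chrom_a == self.chrom_b:
            raise ValueError("CTX requires two different chromosomes")
        if self.sv_type is not SVType.CTX and self.chrom_a != self.chrom_b:
            raise ValueError(f"{self.sv_type.value} requires one chromosome")


def _span_gap(a_start, a_end, b_start, b_end) -> int:
    """Gap between two half-open intervals (0 when they overlap/touch)."""
    return max(a_start, b_start) - min(a_end, b_end) if (
        a_end <= b_start or b_end <= a_start
    ) else 0


def cluster_pairs(
    pairs: list[DiscordantPair],
    max_gap: float,
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> list[list[DiscordantPair]]:
    """Single-linkage clustering of discordant pairs.

    Pairs below ``min_mapq`` are discarded. Two pairs link when they share the
    canonical chromosome pair and each of their two mate spans lies within
    ``max_gap`` of the other's corresponding span. Clusters and their members
    are returned in deterministic coordinate order.
    """
    kept = sorted(
        (p.canonical() for p in pairs if p.mapq >= min_mapq),
        key=lambda p: (p.chrom1, p.start1, p.chrom2, p.start2, p.read_id),
    )
    # union-find within chromosome-pair groups
    parent = list(range(len(kept)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    groups: dict[tuple[str, str], list[int]] = {}
    for i, p in enumerate(kept):
        groups.setdefault((p.chrom1, p.chrom2), []).append(i)
    for idxs in groups.values():
        # indices are sorted by start1; only a bounded look-back is needed
        for a_pos, i in enumerate(idxs):
            pi = kept[i]
            for j in idxs[a_pos + 1 :]:
                pj = kept[j]
                if pj.start1 - pi.end1 > max_gap:
                    break
                if (
                    _span_gap(pi.start1, pi.end1, pj.start1, pj.end1) <= max_gap
                    and _span_gap(pi.start2, pi.end2, pj.start2, pj.end2) <= max_gap
                ):
                    union(i, j)
    clusters: dict[int, list[DiscordantPair]] = {}
    for i, p in enumerate(kept):
        clusters.setdefault(find(i), []).append(p)
    return [clusters[r] for r in sorted(clusters)]


def classify_cluster(
    cluster: list[DiscordantPair],
    insert_size_mean: float,
    insert_size_sd: float,
) -> SVType | None:
    """Type a cluster from its mate geometry, or None when unclassifiable.

    CTX: mates on different chromosomes. INV: same chromosome with
    same-orientation mates (+/+ or -/-) in the majority of pairs. ITX: same
    chromosome, opposite orientations, but mate separation beyond the
    concordant insert-size model (mean + 3 SD) or reversed mate order.
    Clusters that look concordant are dropped.
    """
    if len(cluster) < DEFAULT_MIN_SUPPORT:
        return None
    if cluster[0].chrom1 != cluster[0].chrom2:
        return SVType.CTX
    same_orientation = sum(1 for p in cluster if p.strand1 == p.strand2)
    if same_orientation * 2 > len(cluster):
        return SVType.INV
    limit = insert_size_mean + 3 * insert_size_sd
    outer_spans = [p.end2 - p.start1 for p in cluster]
    reversed_order = any(p.start2 < p.start1 for p in cluster)
    if float(np.median(outer_spans)) > limit or reversed_order:
        return SVType.ITX
    return None


def score_cluster(cluster: list[DiscordantPair]) -> int:
    """Capped-linear confidence: min(99, 20 x supporting pairs).

    Saturates at 99 from five coherent pairs upward, matching the
    highly-confident-set cutoff used downstream.
    """
    return min(SCORE_CAP, SCORE_PER_PAIR * len(cluster))


def _refine_side(spans: list[tuple[int, int]], strands: list[str]) -> int:
    """Refined 1-based breakpoint of one side from its mate spans.

    A '+' mate reads toward the breakpoint, so its inner edge is its end; a
    '-' mate reads away from it, so its inner edge is its start. The side's
    majority strand selects the rule.
    """
    plus = sum(1 for s in strands if s == "+")
    if plus * 2 >= len(strands):
        return max(end for _, end in spans) + 1
    return min(start for start, _ in spans) + 1


def refine_breakpoints(call: SVCall, pairs: list[DiscordantPair]) -> SVCall:
    """Refine a call's breakpoints from the inner edges of its supporting
    mate spans.

    When the supporting reads cannot be resolved in the pair table the call is
    returned with its raw coordinates and ``refined`` stays False.
    """
    by_id = {p.read_id: p.canonical() for p in pairs}
    support = [by_id[r] for r in call.supporting_ids if r in by_id]
    if len(support) < len(call.supporting_ids) or not support:
        return call
    pos_a = _refine_side(
        [(p.start1, p.end1) for p in support], [p.strand1 for p in support]
    )
    pos_b = _refine_side(
        [(p.start2, p.end2) for p in support], [p.strand2 for p in support]
    )
    if call.sv_type is SVType.CTX:
        size = (
            max(p.end1 for p in support) - min(p.start1 for p in support)
        ) + (max(p.end2 for p in support) - min(p.start2 for p in support))
    else:
        pos_a, pos_b = min(pos_a, pos_b), max(pos_a, pos_b)
        size = pos_b - pos_a
    return replace(call, pos_a=pos_a, pos_b=pos_b, size=size, refined=True)


def calls_from_clusters(
    clusters: list[list[DiscordantPair]],
    insert_size_mean: float,
    insert_size_sd: float,
    sample: str,
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> list[SVCall]:
    """Classify, score and coordinate each cluster into a raw SVCall."""
    calls = []
    for cluster in clusters:
        if len(cluster) < min_support:
            continue
        sv_type = classify_cluster(cluster, insert_size_mean, insert_size_sd)
        if sv_type is None:
            continue
        pos_a = max(p.end1 for p in cluster) + 1
        pos_b = min(p.start2 for p in cluster) + 1
        chrom_a, chrom_b = cluster[0].chrom1, cluster[0].chrom2
        if sv_type is SVType.CTX:
            size = (
                max(p.end1 for p in cluster) - min(p.start1 for p in cluster)
            ) + (max(p.end2 for p in cluster) - min(p.start2 for p in cluster))
        else:
            pos_a, pos_b = min(pos_a, pos_b), max(pos_a, pos_b)
            size = pos_b - pos_a
        calls.append(
            SVCall(
                sv_type=sv_type,
                chrom_a=chrom_a,
                pos_a=pos_a,
                chrom_b=chrom_b,
                pos_b=pos_b,
                size=size,
                score=score_cluster(cluster),
                n_supporting=len(cluster),
                supporting_ids=[p.read_id for p in cluster],
                sample=sample,
            )
        )
    return calls


def filter_and_exclude(
    calls: list[SVCall],
    control_calls: list[SVCall] | None,
    min_score: int = DEFAULT_MIN_SCORE,
    slop: int = 1000,
) -> list[SVCall]:
    """Keep saturated-confidence calls absent from the control.

    Calls below ``min_score`` are dropped; a call is also dropped when either
    refined breakpoint lies within ``slop`` of a control cluster breakpoint on
    the same chromosome (reads from the control at a locus mark it as a
    mapping artefact).
    """
    control_calls = control_calls or []
    control_points = [
        (c.chrom_a, c.pos_a) for c in control_calls
    ] + [(c.chrom_b, c.pos_b) for c in control_calls]

    def near_control(call: SVCall) -> bool:
        for chrom, pos in ((call.chrom_a, call.pos_a), (call.chrom_b, call.pos_b)):
            for c_chrom, c_pos in control_points:
                if chrom == c_chrom and abs(pos - c_pos) <= slop:
                    return True
        return False

    return [c for c in calls if c.score >= min_score and not near_control(c)]


def call_svs(
    pairs: list[DiscordantPair],
    insert_size_mean: float,
    insert_size_sd: float,
    sample: str,
    control_pairs: list[DiscordantPair] | None = None,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    min_support: int = DEFAULT_MIN_SUPPORT,
    min_score: int = DEFAULT_MIN_SCORE,
) -> list[SVCall]:
    """End-to-end SV calling for one sample's discordant-pair table."""
    max_gap = insert_size_mean + 3 * insert_size_sd
    clusters = cluster_pairs(pairs, max_gap, min_mapq)
    calls = calls_from_clusters(
        clusters, insert_size_mean, insert_size_sd, sample, min_support
    )
    control_calls = None
    if control_pairs is not None:
        control_clusters = cluster_pairs(control_pairs, max_gap, min_mapq)
        control_calls = calls_from_clusters(
            control_clusters, insert_size_mean, insert_size_sd, "control", min_support
        )
    calls = filter_and_exclude(calls, control_calls, min_score)
    canonical = [p.canonical() for p in pairs]
    return [refine_breakpoints(c, canonical) for c in calls]


def summarize_sv(calls: list[SVCall], chromosomes: list[str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Type x chromosome count matrix (with totals) and per-type size ranges.

    A CTX call is tallied on its first (canonical) chromosome.
    """
    types = [t.value for t in SVType]
    mat = pd.DataFrame(0, index=types, columns=chromosomes)
    sizes: dict[str, list[int]] = {t: [] for t in types}
    for c in calls:
        mat.at[c.sv_type.value, c.chrom_a] += 1
        sizes[c.sv_type.value].append(c.size)
    mat["Total"] = mat.sum(axis=1)
    mat.loc["Total"] = mat.sum(axis=0)
    ranges = pd.DataFrame(
        {
            "sv_type": types,
            "n": [len(sizes[t]) for t in types],
            "min_size": [min(sizes[t]) if sizes[t] else 0 for t in types],
            "max_size": [max(sizes[t]) if sizes[t] else 0 for t in types],
        }
    ).set_index("sv_type")
    return mat, ranges
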