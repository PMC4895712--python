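"""End-to-end driver: simulate (or load) a panel, run every analysis stage,
and score the results against the planted truth."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cnv_pav, effects, filtering, panel as panel_mod, sv, windows
from .cnv_pav import GeneEvent, GeneEventCall
from .simulate import (
    CONTROL_SAMPLE,
    SimulatedPanel,
    SimulationConfig,
    TruthSet,
    simulate_panel,
)
from .sv import SVCall, SVType


@dataclass
class AnalysisResult:
    panel: panel_mod.PanelMatrix
    removed: dict[str, list]
    summary: pd.DataFrame
    pairwise: pd.DataFrame
    window_densities: list
    chrom_density: pd.DataFrame
    indel_spectrum: pd.DataFrame
    effect_calls: dict
    line_specific: dict
    gene_calls: dict[str, list[GeneEventCall]]
    sv_calls: dict[str, list[SVCall]]
    gene_index: effects.GeneIndex = field(repr=False, default=None)


def analyze_panel(sim: SimulatedPanel) -> AnalysisResult:
    """Run filtering, merging, distribution statistics, effect annotation,
    CNV/PAV calling and SV typing over a simulated (or loaded) panel."""
    config = sim.config
    kept: dict[str, list] = {}
    removed: dict[str, list] = {}
    for sample, records in sim.records.items():
        if sample == CONTROL_SAMPLE:
            continue
        k, r = filtering.apply_filters(records)
        kept[sample], removed[sample] = k, r

    pm = panel_mod.build_panel(kept, depth_profiles=sim.depths, min_depth=5)
    summary = panel_mod.summary_table(pm)
    pairwise = panel_mod.pairwise_snp_matrix(pm)

    gene_index = effects.GeneIndex(sim.genes)
    effect_calls = effects.annotate_sites(pm.sites, gene_index, sim.reference)
    exonic = {
        key for key, call in effect_calls.items() if call.region is effects.Region.EXON
    }
    wd = windows.window_counts(pm, sim.reference)
    cd = windows.chromosome_density(pm, sim.reference, exonic)
    spectrum = windows.indel_spectrum(pm)
    ls = panel_mod.line_specific_variants(pm)

    control_gene_calls = cnv_pav.call_sample(sim.depths[CONTROL_SAMPLE], sim.genes)
    gene_calls = {}
    for sample in pm.samples:
        calls = cnv_pav.call_sample(sim.depths[sample], sim.genes)
        calls = cnv_pav.exclude_control(calls, control_gene_calls)
        gene_calls[sample] = cnv_pav.event_calls_only(calls)

    insert_mean = config.insert_size_mean if config else 400
    insert_sd = config.insert_size_sd if config else 40
    control_pairs = sim.pairs.get(CONTROL_SAMPLE)
    sv_calls = {
        sample: sv.call_svs(
            sim.pairs[sample], insert_mean, insert_sd, sample,
            control_pairs=control_pairs,
        )
        for sample in pm.samples
        if sample in sim.pairs
    }
    return AnalysisResult(
        panel=pm, removed=removed, summary=summary, pairwise=pairwise,
        window_densities=wd, chrom_density=cd, indel_spectrum=spectrum,
        effect_calls=effect_calls, line_specific=ls,
        gene_calls=gene_calls, sv_calls=sv_calls, gene_index=gene_index,
    )


def run_end_to_end(config: SimulationConfig) -> tuple[SimulatedPanel, AnalysisResult]:
    sim = simulate_panel(config)
    return sim, analyze_panel(sim)


# ---------------------------------------------------------------------------
# truth scoring


def _precision_recall(predicted: set, truth: set) -> tuple[float, float]:
    tp = len(predicted & truth)
    precision = tp / len(predicted) if predicted else 1.0
    recall = tp / len(truth) if truth else 1.0
    return precision, recall


def score_line_specific(result: AnalysisResult, truth: TruthSet) -> dict:
    """Precision/recall of recovered line-specific variants vs planted."""
    predicted = {
        (sample, *site.key)
        for sample, groups in result.line_specific.items()
        for sites in groups.values()
        for site in sites
    }
    truth_set = {
        (row.sample, row.chromosome, row.position, row.ref, row.alt)
        for row in truth.line_specific().itertuples(index=False)
    }
    precision, recall = _precision_recall(predicted, truth_set)
    return {
        "precision": precision,
        "recall": recall,
        "n_predicted": len(predicted),
        "n_truth": len(truth_set),
    }


def score_gene_events(result: AnalysisResult, truth: TruthSet) -> dict:
    """Precision/recall of PAV (gene absence) and duplication calls."""
    pred_del = {
        (s, c.gene_id)
        for s, calls in result.gene_calls.items()
        for c in calls
        if c.event is GeneEvent.ABSENT
    }
    pred_dup = {
        (s, c.gene_id)
        for s, calls in result.gene_calls.items()
        for c in calls
        if c.event is GeneEvent.DUPLICATED
    }
    ev = truth.gene_events
    truth_del = {
        (r.sample, r.gene_id)
        for r in ev[ev["event"] == "deletion"].itertuples(index=False)
    }
    truth_dup = {
        (r.sample, r.gene_id)
        for r in ev[ev["event"] == "duplication"].itertuples(index=False)
    }
    del_p, del_r = _precision_recall(pred_del, truth_del)
    dup_p, dup_r = _precision_recall(pred_dup, truth_dup)
    return {
        "deletion_precision": del_p, "deletion_recall": del_r,
        "duplication_precision": dup_p, "duplication_recall": dup_r,
        "n_truth_deletions": len(truth_del), "n_truth_duplications": len(truth_dup),
    }


def score_svs(result: AnalysisResult, truth: TruthSet, insert_sd: float) -> dict:
    """Type confusion matrix and breakpoint accuracy of SV calls.

    A call matches a truth event of its sample when both breakpoints land on
    the right chromosomes within 10 insert-size SDs; the confusion matrix is
    then tallied over matched (truth type, called type) pairs.
    """
    types = [t.value for t in SVType]
    confusion = pd.DataFrame(0, index=types, columns=types)
    bp_errors: list[float] = []
    n_truth = len(truth.sv_events)
    n_matched = 0
    window = 10 * insert_sd
    unmatched_calls = sum(len(v) for v in result.sv_calls.values())
    for row in truth.sv_events.itertuples(index=False):
        best = None
        for call in result.sv_calls.get(row.sample, []):
            ends = [
                (call.chrom_a, call.pos_a, row.chrom_a, row.pos_a,
                 call.chrom_b, call.pos_b, row.chrom_b, row.pos_b),
                (call.chrom_a, call.pos_a, row.chrom_b, row.pos_b,
                 call.chrom_b, call.pos_b, row.chrom_a, row.pos_a),
            ]
            for ca, pa, tca, tpa, cb, pb, tcb, tpb in ends:
                if ca == tca and cb == tcb and abs(pa - tpa) <= window and abs(pb - tpb) <= window:
                    err = max(abs(pa - tpa), abs(pb - tpb))
                    if best is None or err < best[1]:
                        best = (call, err)
        if best is not None:
            call, err = best
            confusion.at[row.sv_type, call.sv_type.value] += 1
            bp_errors.append(err)
            n_matched += 1
            unmatched_calls -= 1
    diagonal = sum(confusion.at[t, t] for t in types)
    return {
        "confusion": confusion,
        "n_truth": n_truth,
        "n_matched": n_matched,
        "n_unmatched_calls": unmatched_calls,
        "type_accuracy": diagonal / n_truth if n_truth else 1.0,
        "max_breakpoint_error": max(bp_errors) if bp_errors else 0.0,
        "mean_breakpoint_error": float(np.mean(bp_errors)) if bp_errors else 0.0,
    }


def score_variant_recovery(result: AnalysisResult, truth: TruthSet) -> dict:
    """Fraction of planted (sample, site, zygosity) calls recovered in the
    filtered panel, and the fraction of panel calls that were planted."""
    code_for = {"het": panel_mod.HET, "hom_alt": panel_mod.HOM_ALT}
    truth_calls = {
        (r.sample, r.chromosome, r.position, r.ref, r.alt, code_for[r.zygosity])
        for r in truth.variants.itertuples(index=False)
    }
    pm = result.panel
    observed = set()
    for j, sample in enumerate(pm.samples):
        col = pm.calls[:, j]
        for i, site in enumerate(pm.sites):
            if col[i] in (panel_mod.HET, panel_mod.HOM_ALT):
                observed.add((sample, *site.key, int(col[i])))
    precision, recall = _precision_recall(observed, truth_calls)
    return {"precision": precision, "recall": recall, "n_truth": len(truth_calls)}
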