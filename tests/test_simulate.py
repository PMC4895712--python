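"""Simulator contracts: gene structure, planted counts, depth and pair
geometry, determinism."""

import numpy as np
import pytest

from panelvar.cnv_pav import MIN_GENE_LENGTH
from panelvar.filtering import Genotype
from panelvar.genome import STOP_CODONS
from panelvar.simulate import (
    CONTROL_SAMPLE,
    SimulationConfig,
    SimulationError,
    generate_reference,
    simulate_discordant_pairs,
    simulate_depth_profiles,
    simulate_panel,
    simulate_panel_variants,
)


def cfg(**kw):
    base = dict(
        seed=9, n_samples=2, n_chromosomes=2, chromosome_length=120_000,
        n_genes=8, gene_length_range=(1200, 1600), snp_rate=3e-4,
        indel_rate=5e-5, n_line_specific=3, n_gene_deletions=1,
        n_gene_duplications=1, n_sv_per_type=1, n_lowqual_noise=3,
        n_close_pairs=1, n_noise_pairs=5,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestReference:
    def test_empty_gene_set(self):
        ref, genes = generate_reference(cfg(n_genes=0))
        assert len(ref.sequences) == 2 and genes == []

    def test_sequences_uppercase_acgt(self):
        ref, _ = generate_reference(cfg())
        for seq in ref.sequences.values():
            assert set(seq) <= set("ACGT")

    def test_gene_structure(self, genome20):
        reference, genes = genome20
        assert len(genes) == 20
        assert {g.strand for g in genes} == {"+", "-"}
        for gene in genes:
            assert gene.cds_length % 3 == 0
            cds = gene.cds_sequence(reference)
            assert cds.startswith("ATG") and cds[-3:] in STOP_CODONS
            # no internal stop codon
            internal = [cds[i : i + 3] for i in range(3, len(cds) - 3, 3)]
            assert not any(c in STOP_CODONS for c in internal)

    def test_genes_do_not_overlap(self, genome20):
        _, genes = genome20
        by_chrom = {}
        for g in genes:
            by_chrom.setdefault(g.chromosome, []).append((g.start, g.end))
        for spans in by_chrom.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 < s2

    def test_same_seed_identical(self):
        r1, g1 = generate_reference(cfg())
        r2, g2 = generate_reference(cfg())
        assert r1.sequences == r2.sequences
        assert [(g.gene_id, g.exons, g.cds) for g in g1] == [
            (g.gene_id, g.exons, g.cds) for g in g2
        ]

    def test_infeasible_packing_rejected(self):
        with pytest.raises(SimulationError):
            generate_reference(
                cfg(n_genes=60, chromosome_length=20_000, gene_length_range=(1500, 2000))
            )


class TestPlantedVariants:
    def test_zero_rates_give_empty_truth(self):
        config = cfg(
            snp_rate=0.0, indel_rate=0.0, n_line_specific=0,
            n_effect_forced_per_category=0, n_lowqual_noise=0, n_close_pairs=0,
            n_gene_deletions=0, n_gene_duplications=0,
        )
        ref, genes = generate_reference(config)
        records, truth = simulate_panel_variants(ref, genes, config)
        assert len(truth.variants) == 0
        assert all(len(v) == 0 for v in records.values())

    def test_line_specific_bookkeeping(self):
        config = cfg(n_samples=3, n_line_specific=5, snp_rate=0.0, indel_rate=0.0,
                     n_effect_forced_per_category=0, n_lowqual_noise=0, n_close_pairs=0)
        ref, genes = generate_reference(config)
        _, truth = simulate_panel_variants(ref, genes, config)
        assert truth.line_specific().shape[0] == 15
        assert truth.variants.groupby("sample").size().eq(5).all()

    def test_per_sample_positions_unique_and_spaced(self, small_sim):
        for sample, records in small_sim.records.items():
            by_chrom = {}
            for r in records:
                by_chrom.setdefault(r.chromosome, []).append(r.position)
            for positions in by_chrom.values():
                assert len(positions) == len(set(positions))

    def test_het_fraction_calibration(self):
        config = cfg(
            n_samples=1, chromosome_length=1_000_000, snp_rate=0.01,
            indel_rate=0.0, n_line_specific=0, n_gene_deletions=0,
            n_gene_duplications=0, n_sv_per_type=0,
            n_effect_forced_per_category=0, n_lowqual_noise=0, n_close_pairs=0,
            het_fraction=0.3,
        )
        ref, genes = generate_reference(config)
        _, truth = simulate_panel_variants(ref, genes, config)
        n = len(truth.variants)
        assert n >= 10_000
        het = (truth.variants["zygosity"] == Genotype.HET.value).mean()
        sd = np.sqrt(0.3 * 0.7 / n)
        assert abs(het - 0.3) <= 3 * sd

    def test_truth_matches_vcf_records(self, small_sim):
        truth_keys = {
            (r.sample, r.chromosome, r.position, r.ref, r.alt)
            for r in small_sim.truth.variants.itertuples(index=False)
        }
        record_keys = {
            (r.sample, r.chromosome, r.position, r.ref_allele, r.alt_allele)
            for recs in small_sim.records.values()
            for r in recs
        }
        assert truth_keys <= record_keys  # noise records are extra

    def test_too_dense_rates_rejected(self):
        config = cfg(snp_rate=0.05)  # 64 bp spacing cannot host 1/20 bp
        ref, genes = generate_reference(config)
        with pytest.raises(SimulationError):
            simulate_panel_variants(ref, genes, config)


class TestDepthProfiles:
    def test_deleted_gene_nearly_uncovered(self, small_sim):
        truth, genes = small_sim.truth, {g.gene_id: g for g in small_sim.genes}
        dels = truth.gene_events[truth.gene_events["event"] == "deletion"]
        assert len(dels) > 0
        for row in dels.itertuples(index=False):
            gene = genes[row.gene_id]
            d = small_sim.depths[row.sample].gene_slice(gene)
            assert np.mean(d >= 1) < 0.10
            assert np.mean(d == 0) >= 0.95

    def test_duplicated_gene_depth_ratio(self, small_sim):
        truth, genes = small_sim.truth, {g.gene_id: g for g in small_sim.genes}
        dups = truth.gene_events[truth.gene_events["event"] == "duplication"]
        assert len(dups) > 0
        for row in dups.itertuples(index=False):
            gene = genes[row.gene_id]
            profile = small_sim.depths[row.sample]
            ratio = np.mean(profile.gene_slice(gene)) / profile.genome_median_depth
            assert ratio >= 1.9

    def test_control_has_no_events(self, small_sim):
        truth = small_sim.truth
        assert CONTROL_SAMPLE not in set(truth.gene_events["sample"])
        assert CONTROL_SAMPLE not in set(truth.sv_events["sample"])
        control = small_sim.depths[CONTROL_SAMPLE]
        assert abs(control.genome_median_depth - small_sim.config.base_depth) <= 1


class TestDiscordantPairs:
    def test_ctx_pairs_cross_chromosomes(self, small_sim):
        truth = small_sim.truth
        ctx = truth.sv_events[truth.sv_events["sv_type"] == "CTX"]
        for row in ctx.itertuples(index=False):
            support = [
                p for p in small_sim.pairs[row.sample]
                if p.read_id.startswith(f"{row.sample}_sv")
                and {p.chrom1, p.chrom2} == {row.chrom_a, row.chrom_b}
                and p.chrom1 != p.chrom2
            ]
            assert len(support) >= 5

    def test_inv_pairs_share_orientation(self, small_sim):
        truth = small_sim.truth
        inv = truth.sv_events[truth.sv_events["sv_type"] == "INV"].iloc[0]
        support = [
            p for p in small_sim.pairs[inv["sample"]]
            if p.chrom1 == p.chrom2 == inv["chrom_a"]
            and abs(p.start1 - inv["pos_a"]) < 2000
        ]
        assert len(support) >= 5
        assert len({(p.strand1, p.strand2) for p in support}) == 1
        assert all(p.strand1 == p.strand2 for p in support)

    def test_no_events_only_noise(self):
        config = cfg(n_sv_per_type=0)
        ref, genes = generate_reference(config)
        _, truth = simulate_panel_variants(ref, genes, config)
        pairs = simulate_discordant_pairs(ref, truth, config)
        for sample_pairs in pairs.values():
            assert all("_sv" not in p.read_id for p in sample_pairs)

    def test_control_emits_no_sv_support(self, small_sim):
        assert all(
            "_sv" not in p.read_id for p in small_sim.pairs[CONTROL_SAMPLE]
        )


class TestDeterminism:
    def test_whole_panel_reproducible(self):
        config = cfg()
        p1, p2 = simulate_panel(config), simulate_panel(config)
        assert p1.reference.sequences == p2.reference.sequences
        assert p1.truth.variants.equals(p2.truth.variants)
        assert p1.truth.gene_events.equals(p2.truth.gene_events)
        assert p1.truth.sv_events.equals(p2.truth.sv_events)
        for s in p1.records:
            assert p1.records[s] == p2.records[s]
        for s in p1.depths:
            for c in p1.depths[s].depth:
                assert np.array_equal(p1.depths[s].depth[c], p2.depths[s].depth[c])
        for s in p1.pairs:
            assert p1.pairs[s] == p2.pairs[s]

    def test_truthset_invariants(self, small_sim):
        small_sim.truth.validate(small_sim.reference, small_sim.genes)
        # every gene event references a gene long enough to call
        by_id = {g.gene_id: g for g in small_sim.genes}
        for gid in small_sim.truth.gene_events["gene_id"]:
            assert by_id[gid].length >= MIN_GENE_LENGTH
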