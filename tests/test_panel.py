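"""Panel matrix construction and panel-level statistics."""

import numpy as np
import pytest

from panelvar.cnv_pav import DepthProfile
from panelvar.filtering import Genotype, VariantRecord
from panelvar.panel import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    build_panel,
    indel_ratio,
    line_specific_variants,
    pairwise_snp_count,
    pairwise_snp_matrix,
    sample_summary,
    summary_table,
    zygosity_counts,
)

CHROM_LEN = 10_000


def rec(sample, pos, ref="A", alt="T", gt=Genotype.HOM_ALT, chrom="Ca1"):
    return VariantRecord(chrom, pos, ref, alt, 50.0, 10, gt, sample)


def profile(sample, depth_value=10, zero_at=()):
    d = np.full(CHROM_LEN, depth_value, dtype=np.int32)
    for pos in zero_at:
        d[pos - 1] = 0
    return DepthProfile(sample=sample, depth={"Ca1": d})


class TestBuildPanel:
    def test_union_of_disjoint_sites(self):
        panel = build_panel(
            {"A": [rec("A", p) for p in (10, 20, 30)],
             "B": [rec("B", p) for p in (40, 50, 60)]}
        )
        assert panel.n_sites == 6

    def test_shared_variant_one_site(self):
        panel = build_panel({"A": [rec("A", 10)], "B": [rec("B", 10)]})
        assert panel.n_sites == 1
        assert (panel.calls == HOM_ALT).all()

    def test_absent_sample_hom_ref_when_covered(self):
        depths = {"A": profile("A"), "B": profile("B")}
        panel = build_panel({"A": [rec("A", 10)], "B": []}, depths, min_depth=5)
        assert panel.sample_column("B")[0] == HOM_REF

    def test_absent_sample_missing_when_uncovered(self):
        depths = {"A": profile("A"), "B": profile("B", zero_at=(10,))}
        panel = build_panel({"A": [rec("A", 10)], "B": []}, depths, min_depth=5)
        assert panel.sample_column("B")[0] == MISSING

    def test_conflicting_ref_alleles_rejected(self):
        with pytest.raises(ValueError):
            build_panel(
                {"A": [rec("A", 10, ref="A", alt="T")],
                 "B": [rec("B", 10, ref="C", alt="G")]}
            )

    def test_unknown_sample_rejected(self):
        panel = build_panel({"A": [rec("A", 10)]})
        with pytest.raises(KeyError):
            panel.sample_column("nope")


class TestZygosity:
    def test_rate_quarter(self):
        records = [rec("A", 10, gt=Genotype.HET)] + [
            rec("A", p) for p in (20, 30, 40)
        ]
        panel = build_panel({"A": records})
        n_hom, n_het, rate = zygosity_counts(panel, "A")
        assert (n_hom, n_het, rate) == (3, 1, 0.25)

    def test_all_hom_rate_zero(self):
        panel = build_panel({"A": [rec("A", p) for p in (10, 20)]})
        assert zygosity_counts(panel, "A")[2] == 0.0

    def test_empty_denominator(self):
        panel = build_panel({"A": [rec("A", 10, ref="AT", alt="A")]})
        assert zygosity_counts(panel, "A") == (0, 0, 0.0)


class TestPairwise:
    def test_clone_zero(self):
        records = {s: [rec(s, p) for p in range(10, 100, 10)] for s in "AB"}
        assert pairwise_snp_count(build_panel(records), "A", "B") == 0

    def test_fully_discordant(self):
        panel = build_panel({"A": [rec("A", p) for p in range(10, 1010, 10)], "B": []})
        assert pairwise_snp_count(panel, "A", "B") == 100

    def test_symmetry_and_bruteforce(self):
        rng = np.random.default_rng(4)
        samples = ["A", "B", "C"]
        records = {s: [] for s in samples}
        positions = np.sort(rng.choice(np.arange(10, 9000, 9), 300, replace=False))
        gts = [Genotype.HOM_ALT, Genotype.HET]
        for pos in positions:
            for s in samples:
                if rng.random() < 0.5:
                    records[s].append(rec(s, int(pos), gt=gts[rng.integers(0, 2)]))
        panel = build_panel(records)
        mat = pairwise_snp_matrix(panel)
        for a in samples:
            for b in samples:
                if a == b:
                    continue
                # brute-force per-site comparison
                ca, cb = panel.sample_column(a), panel.sample_column(b)
                expected = sum(
                    1 for i in range(panel.n_sites)
                    if ca[i] != MISSING and cb[i] != MISSING and ca[i] != cb[i]
                )
                assert mat.at[a, b] == expected == mat.at[b, a]

    def test_same_sample_rejected(self):
        panel = build_panel({"A": [rec("A", 10)]})
        with pytest.raises(ValueError):
            pairwise_snp_count(panel, "A", "A")


class TestLineSpecific:
    def test_single_carrier_detected(self):
        records = {"A": [rec("A", 10)], "B": [], "C": [], "D": [], "E": []}
        panel = build_panel(records)
        ls = line_specific_variants(panel)
        assert len(ls["A"]["snps"]) == 1
        assert all(not ls[s]["snps"] for s in "BCDE")

    def test_two_carriers_not_line_specific(self):
        panel = build_panel({"A": [rec("A", 10)], "B": [rec("B", 10)], "C": []})
        ls = line_specific_variants(panel)
        assert all(not v["snps"] and not v["indels"] for v in ls.values())

    def test_missing_call_disqualifies(self):
        depths = {
            "A": profile("A"),
            "B": profile("B"),
            "C": profile("C", zero_at=(10,)),
        }
        panel = build_panel(
            {"A": [rec("A", 10)], "B": [], "C": []}, depths, min_depth=5
        )
        ls = line_specific_variants(panel)
        assert not ls["A"]["snps"]

    def test_het_counts_as_carrier(self):
        panel = build_panel({"A": [rec("A", 10, gt=Genotype.HET)], "B": []})
        assert len(line_specific_variants(panel)["A"]["snps"]) == 1

    def test_indels_reported_separately(self):
        panel = build_panel({"A": [rec("A", 10, ref="AT", alt="A")], "B": []})
        ls = line_specific_variants(panel)
        assert len(ls["A"]["indels"]) == 1 and not ls["A"]["snps"]

    def test_planted_truth_recovered_exactly(self, small_sim):
        from panelvar.pipeline import analyze_panel, score_line_specific

        result = analyze_panel(small_sim)
        score = score_line_specific(result, small_sim.truth)
        assert score["precision"] == 1.0 and score["recall"] == 1.0


class TestIndelRatio:
    def make(self, n_ins, n_del):
        records = []
        pos = 10
        for _ in range(n_ins):
            records.append(rec("A", pos, ref="A", alt="AG"))
            pos += 10
        for _ in range(n_del):
            records.append(rec("A", pos, ref="AG", alt="A"))
            pos += 10
        return build_panel({"A": records})

    @pytest.mark.parametrize("n_ins,n_del,expected", [
        (50, 50, 1.0), (103, 100, 1.03), (0, 10, 0.0),
    ])
    def test_ratio(self, n_ins, n_del, expected):
        assert indel_ratio(self.make(n_ins, n_del), "A") == pytest.approx(expected)

    def test_zero_deletions_absent(self):
        assert indel_ratio(self.make(5, 0), "A") is None


class TestSummaries:
    def test_counts_conserved_through_merging(self, small_sim):
        from panelvar import filtering

        kept = {
            s: filtering.apply_filters(r)[0]
            for s, r in small_sim.records.items()
        }
        panel = build_panel(kept, small_sim.depths, min_depth=5)
        for sample, records in kept.items():
            s = sample_summary(panel, sample)
            n_nonref = s.n_snps + s.n_insertions + s.n_deletions
            assert n_nonref == len(records)

    def test_summary_table_schema(self, small_sim):
        from panelvar import filtering

        kept = {s: filtering.apply_filters(r)[0] for s, r in small_sim.records.items()}
        table = summary_table(build_panel(kept, small_sim.depths))
        assert {"total_snps", "line_specific_snps", "total_deletions",
                "line_specific_deletions", "total_insertions",
                "line_specific_insertions"} <= set(table.columns)
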