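"""Annotation reconciliation: filters, classification, and the funnel."""

import numpy as np
import pytest

from vinekit.io_formats import GenomeSequence, Interval, CountsTable
from vinekit.reconcile import (MappingStats, ReconcileConfig,
                               acceptance_filter, cds_has_stop,
                               classify_genes, exonic_overlap_fraction,
                               expression_support_filter, nmd_flag,
                               pseudogene_filter, reconcile_pipeline,
                               rtswitch_flag)
from vinekit.simulate import SimulationConfig, simulate_annotation_pair
from conftest import make_gene, oracle_classify, random_genes

CFG = ReconcileConfig()


class TestAcceptanceFilter:
    @pytest.mark.parametrize("cov,ident,expected", [
        (0.85, 0.92, "accepted"),
        (0.79, 0.99, "rejected"),
        (0.80, 0.80, "accepted"),   # closed boundary
        (0.99, 0.79, "rejected"),
    ])
    def test_80_80_rule(self, cov, ident, expected):
        part = acceptance_filter([MappingStats("g", cov, ident)], CFG)
        assert part[expected] == ["g"]
        other = "rejected" if expected == "accepted" else "accepted"
        assert part[other] == []

    def test_fraction_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            MappingStats("g", 1.2, 0.5)

    def test_raising_min_coverage_never_adds_acceptances(self, rng):
        stats = [MappingStats(f"g{i}", float(c), float(i_))
                 for i, (c, i_) in enumerate(rng.uniform(0, 1, size=(50, 2)))]
        prev = None
        for mc in (0.5, 0.7, 0.9):
            cfg = ReconcileConfig(min_coverage=mc)
            acc = set(acceptance_filter(stats, cfg)["accepted"])
            if prev is not None:
                assert acc <= prev
            prev = acc


class TestExonicOverlap:
    def test_identical_genes_fully_overlap(self):
        a = make_gene("a", "c", [(0, 100)])
        b = make_gene("b", "c", [(0, 100)])
        assert exonic_overlap_fraction(a, b) == (1.0, 1.0)

    def test_disjoint_genes(self):
        a = make_gene("a", "c", [(0, 100)])
        b = make_gene("b", "c", [(200, 300)])
        assert exonic_overlap_fraction(a, b) == (0.0, 0.0)

    def test_half_overlap(self):
        a = make_gene("a", "c", [(0, 100)])
        b = make_gene("b", "c", [(50, 150)])
        assert exonic_overlap_fraction(a, b) == (0.5, 0.5)

    def test_opposite_strands_never_overlap(self):
        a = make_gene("a", "c", [(0, 100)], "+")
        b = make_gene("b", "c", [(0, 100)], "-")
        assert exonic_overlap_fraction(a, b) == (0.0, 0.0)


class TestClassify:
    def test_gene_without_reference_overlap_is_novel(self):
        q = [make_gene("q1", "c", [(0, 100)])]
        r = [make_gene("r1", "c", [(500, 600)])]
        rep = classify_genes(q, r, CFG)
        assert rep.classes == {"q1": "novel"}

    def test_query_spanning_two_references_is_fused(self):
        q = [make_gene("q1", "c", [(0, 100), (200, 300)])]
        r = [make_gene("r1", "c", [(0, 100)]), make_gene("r2", "c", [(200, 300)])]
        rep = classify_genes(q, r, CFG)
        assert rep.classes["q1"] == "fused"
        assert rep.counterparts["q1"] == ["r1", "r2"]

    def test_two_half_covering_queries_mark_reference_split(self):
        r = [make_gene("r1", "c", [(0, 100), (200, 300)])]
        q = [make_gene("q1", "c", [(0, 100)]), make_gene("q2", "c", [(200, 300)])]
        rep = classify_genes(q, r, CFG)
        assert rep.split_reference == {"r1": ["q1", "q2"]}
        assert rep.classes == {"q1": "split_member", "q2": "split_member"}

    def test_self_classification_is_all_covered(self):
        sim = simulate_annotation_pair(SimulationConfig(seed=5))
        rep = classify_genes(sim.reference, sim.reference, CFG)
        assert set(rep.classes.values()) == {"covered"}
        assert rep.split_reference == {}

    def test_duplicate_ids_rejected(self):
        q = [make_gene("q1", "c", [(0, 100)]), make_gene("q1", "c", [(500, 600)])]
        with pytest.raises(ValueError, match="duplicate"):
            classify_genes(q, [], CFG)

    def test_matches_brute_force_oracle_on_random_pairs(self):
        for seed in range(6):
            rng = np.random.default_rng(seed)
            q = random_genes(rng, "c", 40, 20_000, "Q")
            r = random_genes(rng, "c", 40, 20_000, "R")
            rep = classify_genes(q, r, CFG)
            oracle_classes, oracle_split = oracle_classify(q, r, CFG)
            assert rep.classes == oracle_classes
            assert rep.split_reference == oracle_split

    def test_raising_reciprocal_fraction_never_adds_covered(self, rng):
        q = random_genes(rng, "c", 40, 15_000, "Q")
        r = random_genes(rng, "c", 40, 15_000, "R")
        prev = None
        for frac in (0.5, 0.7, 0.9):
            cfg = ReconcileConfig(covered_reciprocal_fraction=frac)
            cov = {g for g, c in classify_genes(q, r, cfg).classes.items()
                   if c == "covered"}
            if prev is not None:
                assert cov <= prev
            prev = cov


class TestExpressionSupport:
    def _table(self, rows):
        genes = [f"g{i}" for i in range(len(rows))]
        return CountsTable(genes, [f"s{j}" for j in range(len(rows[0]))],
                           np.array(rows, dtype=np.int64),
                           np.full(len(rows), 1000, dtype=np.int64))

    def test_default_rule(self):
        counts = self._table([[0, 0, 0, 0], [7, 9, 0, 0], [100, 0, 0, 0]])
        part = expression_support_filter(["g0", "g1", "g2"], counts, CFG)
        assert part["supported"] == ["g1"]
        assert part["unsupported"] == ["g0", "g2"]

    def test_gene_without_counts_row_is_unsupported(self):
        counts = self._table([[9, 9]])
        part = expression_support_filter(["g0", "missing"], counts, CFG)
        assert part["unsupported"] == ["missing"]


def _nmd_fixture():
    """Two-exon transcript; CDS of 138 nt ending with TAA inside exon 1,
    62 spliced nt upstream of the single junction."""
    genome = GenomeSequence("c", "A" * 135 + "TAA" + "A" * 262)
    tx = make_gene("g", "c", [(0, 200), (300, 400)],
                   cds_pairs=[(0, 138)]).transcripts[0]
    return tx, genome


class TestTranscriptFlags:
    def test_stop_far_upstream_of_last_junction_is_nmd(self):
        tx, genome = _nmd_fixture()
        assert nmd_flag(tx, genome, CFG) is True

    def test_stop_in_last_exon_is_not_nmd(self):
        genome = GenomeSequence("c", "A" * 334 + "TGA" + "A" * 63)
        tx = make_gene("g", "c", [(0, 200), (300, 400)],
                       cds_pairs=[(0, 200), (300, 337)]).transcripts[0]
        assert nmd_flag(tx, genome, CFG) is False

    def test_single_exon_transcript_never_flagged(self):
        genome = GenomeSequence("c", "A" * 135 + "TAA" + "A" * 62)
        tx = make_gene("g", "c", [(0, 200)],
                       cds_pairs=[(0, 138)]).transcripts[0]
        assert nmd_flag(tx, genome, CFG) is False

    def test_cds_not_multiple_of_three_errors(self):
        genome = GenomeSequence("c", "A" * 400)
        tx = make_gene("g", "c", [(0, 200), (300, 400)],
                       cds_pairs=[(0, 100)]).transcripts[0]
        with pytest.raises(ValueError, match="multiple of 3"):
            nmd_flag(tx, genome, CFG)

    def test_cds_without_stop_is_invalid_not_nmd(self):
        genome = GenomeSequence("c", "A" * 400)  # no stop codon anywhere
        tx = make_gene("g", "c", [(0, 200), (300, 400)],
                       cds_pairs=[(0, 138)]).transcripts[0]
        assert cds_has_stop(tx, genome) is False
        assert nmd_flag(tx, genome, CFG) is False

    def _rt_genome(self, repeat_exonic, repeat_intronic):
        seq = (["A"] * 92 + list(repeat_exonic) + ["C"] * 92
               + list(repeat_intronic) + ["G"] * 100)
        return GenomeSequence("c", "".join(seq))

    def test_planted_boundary_repeat_flags_rtswitch(self):
        genome = self._rt_genome("ACGTACGT", "ACGTACGT")
        tx = make_gene("g", "c", [(0, 100), (200, 300)]).transcripts[0]
        assert rtswitch_flag(tx, genome, CFG) is True

    def test_repeat_free_intron_not_flagged(self):
        genome = self._rt_genome("ACGTACGT", "TGCATGCA")
        tx = make_gene("g", "c", [(0, 100), (200, 300)]).transcripts[0]
        assert rtswitch_flag(tx, genome, CFG) is False

    def test_longer_repeat_requirement_unflags_8bp_repeat(self):
        genome = self._rt_genome("ACGTACGT", "ACGTACGT")
        tx = make_gene("g", "c", [(0, 100), (200, 300)]).transcripts[0]
        cfg9 = ReconcileConfig(rtswitch_repeat_len=9)
        assert rtswitch_flag(tx, genome, cfg9) is False

    def test_rtswitch_is_strand_aware(self):
        # repeat planted on the reverse complement strand only
        from vinekit.io_formats import revcomp
        fwd = self._rt_genome("ACGTACGT", "ACGTACGT").sequence
        genome = GenomeSequence("c", revcomp(fwd))
        n = len(fwd)
        tx = make_gene("g", "c", [(n - 300, n - 200), (n - 100, n)],
                       strand="-").transcripts[0]
        assert rtswitch_flag(tx, genome, CFG) is True


class TestPseudogeneFilter:
    def test_hit_table_partition(self):
        part = pseudogene_filter(["g1", "g2"], {"g1": True, "g2": False})
        assert part == {"coding": ["g1"], "discarded": ["g2"]}

    def test_absent_gene_is_discarded(self):
        assert pseudogene_filter(["gx"], {})["discarded"] == ["gx"]


class TestPipeline:
    def test_planted_truth_recovered_with_filters_off(self):
        sim = simulate_annotation_pair(SimulationConfig(seed=1))
        rep = reconcile_pipeline(sim.query, sim.reference)
        s = rep.summary
        truth = sim.truth["kind"].value_counts().to_dict()
        assert s["novel"] == truth["novel"] == 5
        assert s["fused"] == truth["fused"] == 2
        assert s["split"] == truth["split"] == 1
        assert s["covered"] == truth["covered"]
        # classification partitions the retained set
        assert (s["novel"] + s["covered"] + s["fused"] + s["split_member"]
                + s["ambiguous"]) == s["total"] == len(sim.query)

    def test_no_expression_support_empties_the_funnel(self):
        sim = simulate_annotation_pair(SimulationConfig(seed=2))
        gene_ids = [g.gene_id for g in sim.query]
        zero = CountsTable(gene_ids, ["s1", "s2"],
                           np.zeros((len(gene_ids), 2), dtype=np.int64),
                           np.full(len(gene_ids), 1000, dtype=np.int64))
        rep = reconcile_pipeline(sim.query, sim.reference, counts=zero)
        assert rep.funnel["retained"] == 0
        assert rep.classes == {}

    def test_identity_reconciliation_is_all_covered(self):
        sim = simulate_annotation_pair(SimulationConfig(seed=3))
        rep = reconcile_pipeline(sim.reference, sim.reference)
        assert set(rep.classes.values()) == {"covered"}

    def test_liftover_rejection_drops_genes(self):
        sim = simulate_annotation_pair(
            SimulationConfig(seed=4, n_planted_novel=0, n_planted_fused=0,
                             n_planted_split=0))
        stats = [MappingStats(g.gene_id, 0.99, 0.99) for g in sim.query[:-1]]
        stats.append(MappingStats(sim.query[-1].gene_id, 0.5, 0.99))
        rep = reconcile_pipeline(sim.query, sim.reference, stats=stats)
        assert rep.funnel["liftover_accepted"] == len(sim.query) - 1
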