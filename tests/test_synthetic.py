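from collections import Counter

import numpy as np
import pytest

from asmarbiter.config import EvalConfig
from asmarbiter.error_model import adjudicate_chimera
from asmarbiter.pipeline import evaluate_assembly
from asmarbiter.synthetic import (
    SimulationPlan,
    corrupt_assembly,
    derive_truth_alignments,
    distribute_fragments,
    make_error_plan,
    simulate_expression,
    simulate_reference,
    subsample_reads,
)
from asmarbiter.types import adjacent


class TestSimulateReference:
    def test_counts_and_paralog_bookkeeping(self):
        plan = SimulationPlan(n_genes=100, paralog_fraction=0.2, seed=4)
        ref, loci, chroms, pairs = simulate_reference(plan)
        assert len(ref) == 100 and len(loci) == 100
        assert len(pairs) == 10
        ids = {t.gene_id for t in ref}
        assert all(a in ids and b in ids for a, b in pairs)

    def test_deterministic_per_seed(self):
        plan = SimulationPlan(n_genes=60, seed=9)
        r1 = simulate_reference(plan)
        r2 = simulate_reference(plan)
        assert [t.sequence for t in r1[0]] == [t.sequence for t in r2[0]]
        assert r1[2] == r2[2]  # chromosome sequences byte-identical

    def test_zero_divergence_gives_identical_paralogs(self):
        plan = SimulationPlan(n_genes=40, paralog_fraction=0.5, paralog_divergence=0.0, seed=2)
        ref, _, _, pairs = simulate_reference(plan)
        by_id = {t.gene_id: t.sequence for t in ref}
        assert pairs and all(by_id[a] == by_id[b] for a, b in pairs)

    def test_loci_consistent_with_genome(self):
        plan = SimulationPlan(n_genes=50, seed=6)
        ref, loci, chroms, _ = simulate_reference(plan)
        by_id = {t.gene_id: t.sequence for t in ref}
        for l in loci:
            assert chroms[l.chrom][l.start : l.end] == by_id[l.gene_id]
        # order_index tracks coordinate order per chromosome
        for chrom in chroms:
            ordered = sorted(
                (l for l in loci if l.chrom == chrom), key=lambda l: l.start
            )
            assert [l.order_index for l in ordered] == list(range(1, len(ordered) + 1))

    def test_infeasible_plan_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            SimulationPlan(length_min=10000, length_mean=500, length_sd=100)


class TestSimulateExpression:
    def test_deterministic_and_zero_fraction(self):
        plan = SimulationPlan(n_genes=200, zero_fraction=0.1, seed=3)
        ref, *_ = simulate_reference(plan)
        c1 = simulate_expression(plan, ref)
        c2 = simulate_expression(plan, ref)
        assert c1 == c2
        zeros = sum(1 for v in c1.values() if v == 0)
        assert 5 <= zeros <= 40  # binomial(200, 0.1)

    def test_degenerate_distribution(self):
        plan = SimulationPlan(n_genes=50, expression_log_sd=0.0, zero_fraction=0.0, seed=1)
        ref, *_ = simulate_reference(plan)
        counts = simulate_expression(plan, ref)
        assert len(set(counts.values())) == 1

    def test_dynamic_range_spans_orders_of_magnitude(self):
        plan = SimulationPlan(n_genes=500, zero_fraction=0.0, seed=8)
        ref, *_ = simulate_reference(plan)
        counts = np.array(list(simulate_expression(plan, ref).values()))
        assert counts.max() / max(counts.min(), 1) > 100


class TestCorruptAssembly:
    def test_no_directives_reproduces_reference(self, cfg):
        plan = SimulationPlan(n_genes=20, seed=5)
        ref, loci, chroms, _ = simulate_reference(plan)
        from asmarbiter.synthetic import ErrorPlan

        unigenes, truth = corrupt_assembly(ref, loci, chroms, ErrorPlan(31, ()), seed=5)
        assert len(unigenes) == len(ref)
        assert truth.events == []
        assert sorted(u.sequence for u in unigenes) == sorted(t.sequence for t in ref)

    def test_chimera_directive_must_not_name_adjacent_genes(self):
        plan = SimulationPlan(n_genes=20, seed=5)
        ref, loci, chroms, _ = simulate_reference(plan)
        from asmarbiter.synthetic import ErrorDirective, ErrorPlan

        chrom1 = sorted((l for l in loci if l.chrom == "chr1"), key=lambda l: l.order_index)
        a, b = chrom1[0].gene_id, chrom1[1].gene_id
        bad = ErrorPlan(31, (ErrorDirective("chimera", (a, b)),))
        with pytest.raises(ValueError, match="adjacent"):
            corrupt_assembly(ref, loci, chroms, bad, seed=1)

    def test_truth_labels_cover_every_unigene(self, fixture_bundle):
        fb = fixture_bundle
        assert set(fb["truth"].source_genes) == {
            u.unigene_id for u in fb["unigenes"]
        }

    def test_deterministic_per_seed(self, fixture_bundle):
        fb = fixture_bundle
        uni2, truth2 = corrupt_assembly(
            fb["reference"], fb["loci"], fb["chroms"], fb["error_plan"], seed=11
        )
        assert [u.sequence for u in uni2] == [u.sequence for u in fb["unigenes"]]
        assert truth2.events == fb["truth"].events


class TestDeriveTruthAlignments:
    def test_perfect_unigene_scores_2_bits_per_base(self, fixture_bundle):
        fb = fixture_bundle
        cdna, _ = derive_truth_alignments(fb["truth"])
        # a non-corrupted gene: exactly one full-length record at 2 bits/base
        clean = [
            h
            for h in cdna
            if h.pct_identity == 100.0 and h.q_start == 1 and h.s_start == 1
        ]
        assert clean
        h = clean[0]
        assert h.bit_score == 2 * h.aln_length

    def test_chimeric_unigenes_have_disjoint_query_segments(self, fixture_bundle):
        fb = fixture_bundle
        cdna, _ = derive_truth_alignments(fb["truth"])
        by_query = {}
        for h in cdna:
            by_query.setdefault(h.query_id, []).append(h)
        chimeras = [u for u, v in fb["truth"].verdicts.items() if v == "chimera"]
        assert chimeras
        for uid in chimeras:
            segs = sorted((h.q_start, h.q_end) for h in by_query[uid])
            assert len(segs) == 2
            assert segs[0][1] < segs[1][0]  # disjoint

    def test_co_assembly_has_one_contiguous_genome_window(self, fixture_bundle):
        fb = fixture_bundle
        _, genome = derive_truth_alignments(fb["truth"])
        by_query = {}
        for h in genome:
            by_query.setdefault(h.query_id, []).append(h)
        cos = [u for u, v in fb["truth"].verdicts.items() if v == "co_assembly"]
        assert cos
        for uid in cos:
            assert len(by_query[uid]) == 1


class TestRoundTripRecovery:
    """The module-pair integration check: corrupt -> derive alignments ->
    classify must recover every injected label exactly."""

    def test_error_events_recovered_exactly(self, fixture_bundle, cfg):
        fb = fixture_bundle
        bundle = evaluate_assembly(
            fb["reference"],
            fb["unigenes"],
            fb["cdna_hits"],
            fb["fragment_counts"],
            fb["loci"],
            cfg,
        )
        found = {
            (e.kind, tuple(sorted(e.unigene_ids)), tuple(sorted(e.gene_ids)))
            for e in bundle.events
        }
        want = {
            (k, tuple(sorted(u)), tuple(sorted(g)))
            for k, u, g in fb["truth"].events
        }
        assert found == want
        kinds = Counter(k for k, _, _ in fb["truth"].events)
        assert len(kinds) == 8 and sum(kinds.values()) >= 200

    def test_chimera_verdicts_recovered_exactly(self, fixture_bundle, cfg):
        fb = fixture_bundle
        loc = {l.gene_id: l for l in fb["loci"]}
        lens = {u.unigene_id: u.length for u in fb["unigenes"]}
        by_q = {}
        for h in fb["genome_hits"]:
            by_q.setdefault(h.query_id, []).append(h)
        for uid, want in fb["truth"].verdicts.items():
            got = adjudicate_chimera(
                uid, by_q.get(uid, []), loc, cfg, unigene_length=lens[uid]
            )
            assert got.verdict == want, uid

    def test_no_type2_event_for_adjacent_pairs(self, fixture_bundle, cfg):
        fb = fixture_bundle
        loc = {l.gene_id: l for l in fb["loci"]}
        bundle = evaluate_assembly(
            fb["reference"],
            fb["unigenes"],
            fb["cdna_hits"],
            fb["fragment_counts"],
            fb["loci"],
            cfg,
        )
        for e in bundle.events:
            if e.is_type2 and all(g in loc for g in e.gene_ids):
                a, b = (loc[g] for g in e.gene_ids)
                assert not adjacent(a, b)


class TestSubsample:
    def test_target_at_or_above_total_keeps_all(self):
        assert subsample_reads([152] * 10, 10_000) == list(range(10))

    def test_deterministic_and_overshoot_by_at_most_one_pair(self):
        bases = [152] * 1000
        kept1 = subsample_reads(bases, 15_200, seed=5)
        kept2 = subsample_reads(bases, 15_200, seed=5)
        assert kept1 == kept2
        assert len(kept1) == 100  # 15200 / 152 exactly
        kept = subsample_reads(bases, 15_300, seed=5)
        assert len(kept) == 101  # last accepted pair overshoots

    def test_replicate_subsamples_share_detected_genes(self, fixture_bundle):
        """Equal-size replicate subsamples of the fragment pool detect a
        highly overlapping gene set (the replicate-consistency check)."""
        fb = fixture_bundle
        counts = fb["fragment_counts"]
        reads = [u for u, c in counts.items() for _ in range(min(c, 50))]
        bases = [152] * len(reads)
        target = 152 * len(reads) // 3
        detected = []
        for seed in (1, 2, 3):
            kept = subsample_reads(bases, target, seed=seed)
            detected.append({reads[i] for i in kept})
        for a, b in ((0, 1), (1, 2), (0, 2)):
            inter = len(detected[a] & detected[b])
            union = len(detected[a] | detected[b])
            assert inter / union > 0.5
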