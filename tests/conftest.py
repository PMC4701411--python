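import pytest

from asmarbiter.config import EvalConfig
from asmarbiter.synthetic import (
    SimulationPlan,
    corrupt_assembly,
    derive_truth_alignments,
    distribute_fragments,
    make_error_plan,
    simulate_expression,
    simulate_reference,
)


@pytest.fixture(scope="session")
def cfg():
    return EvalConfig()


@pytest.fixture(scope="session")
def fixture_bundle():
    """A 500-gene synthetic transcriptome with 200 injected errors
    spanning all eight Type I / Type II kinds plus co-assemblies."""
    plan = SimulationPlan(n_genes=500, seed=11)
    reference, loci, chroms, paralog_pairs = simulate_reference(plan)
    error_plan = make_error_plan(reference, loci, k=31, n_per_kind=25, seed=11)
    unigenes, truth = corrupt_assembly(reference, loci, chroms, error_plan, seed=11)
    cdna_hits, genome_hits = derive_truth_alignments(truth)
    gene_counts = simulate_expression(plan, reference)
    fragment_counts = distribute_fragments(gene_counts, truth, seed=11)
    return dict(
        plan=plan,
        reference=reference,
        loci=loci,
        chroms=chroms,
        paralog_pairs=paralog_pairs,
        error_plan=error_plan,
        unigenes=unigenes,
        truth=truth,
        cdna_hits=cdna_hits,
        genome_hits=genome_hits,
        gene_counts=gene_counts,
        fragment_counts=fragment_counts,
    )
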