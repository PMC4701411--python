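# Methods

## Scope and data model

`asmarbiter` evaluates an already-computed *de novo* transcriptome
assembly; it never runs an assembler or an aligner itself. Its inputs
are the field's plain-text interchange formats: FASTA for unigenes and
reference cDNAs, 12-column BLAST-style tabular TSV for unigene→cDNA and
unigene→genome alignments, a two-column fragment-count TSV (one best
alignment per sequenced fragment — a read pair or an orphan counts
once), a BED-like or GFF3 gene table, and plain-text gene lists.
Alignment coordinates are 1-based inclusive on disk (the BLAST
convention, with `s_start > s_end` encoding minus strand) and are
converted to 0-based half-open intervals for all internal arithmetic,
which removes every ±1 ambiguity from gap/overlap computation.
Minus-strand records are canonicalized downstream of parsing so raw
tables round-trip byte-for-byte.

## Locus assignment and coverage

Each unigene is assigned to its most significant reference locus:
highest bit score, ties broken by lower e-value, then by
lexicographically smaller gene id (the final key exists purely for
determinism). Ambiguity classification additionally records the best
*distinct* second locus. Coverage breadth is cumulative: the fraction
of reference bases covered by ≥1 aligned segment from *any* unigene,
not just the best one — breadth measures how much of the transcript the
assembly collectively recovered, while the normalized bit score (below)
measures how well a *single* unigene reconstructs it. Hits are not
identity-filtered for coverage; the e-value threshold (1e-10) is
assumed applied by the aligner that produced the table. Coverage
histograms use (lo,hi] bins of 5% or 10% plus `no_hit`; the `>90` and
`>99` entries are cumulative tail counts that intentionally overlap the
top bins (the convention used when the two lightest bars of a coverage
histogram show high-coverage genes); output metadata flags this
convention.

## Error taxonomy

**Type I (fragmentation).** Per locus, each unigene contributes its
single best alignment; intervals are sorted by subject start and every
consecutive distinct-unigene pair yields one event: a subject-coordinate
gap > 0 is Case I; an overlap of 0..k−1 bases is Case II (a De Bruijn
assembler with word size k cannot join sequences sharing fewer than k
bases, so these are expected failures — abutting intervals count as
overlap 0); an overlap > k−1 is Case III (the assembler had the overlap
it needed and still failed, indicating graph conflict). The boundary is
exact and frozen in tests: overlap = k−1 → Case II, overlap = k →
Case III. Where the field's two common phrasings of this boundary
disagree, the ≤ k−1 / > k−1 convention is adopted and k is
configurable.

**Type II (ambiguity).** Only hits at ≥99% identity participate, and
only the two highest-bit-score loci are considered. Pairs of *adjacent*
genes (|Δ order rank| = 1 on one chromosome) are excluded: with
unstranded libraries, overlapping or colinear neighbouring transcripts
are legitimately co-assembled into one unigene and are not errors.
The surviving two-locus geometry is classified on the unigene's query
segments with precedence I > II > III > IV > V, so the
chimera-indicative case is never masked:

- **Case I** — segments overlap ≤ 10 bp (configurable; "disjoint" with
  a small tolerance for alignment end jitter, since exact zero overlap
  is brittle against real aligner output);
- **Case II** — exactly equal bit scores and segment endpoints within
  the same 10 bp jitter ("aligns equally to two genes"; exact bit-score
  equality is used deliberately and noted as a strict reading);
- **Case III** — one segment properly contained in the other;
- **Case IV / V** — segments overlapping more than / at most 80% of
  the unigene length (configurable fraction).

If a hit's locus is missing from the annotation the event is still
emitted with adjacency marked unknown rather than silently dropped.

**Chimera adjudication.** Ambiguous unigenes are re-examined against
genome alignments. Hits below 90% identity or above 1e-10 e-value are
discarded (no survivors → `unresolved`). Same-chromosome, same-strand
hits separated by ≤ 10 kb are merged into one genomic window — the
intron-scale gap absorbs spliced alignments; the threshold is
configurable because no universal value exists. One window covering
≥90% of the unigene means the unigene is one contiguous genomic
stretch: `co_assembly`. Two or more such windows mean a duplicated or
closely related locus explains the whole unigene: `ambiguous_duplicate`
(ambiguity, not mis-assembly). Unigenes named in an explicit
trans-splice candidate list are set aside as `trans_spliced_candidate` —
there is no robust algorithmic signature separating trans-spliced
transcripts from chimeras, so the verdict requires the flag rather than
guessing. Everything else — query halves explained only by distant
windows — is a `chimera`. The reported Type II *rate* is ambiguously
aligned unigenes over all reference-aligned unigenes.

## Quality versus depth

BS = (bit score of the gene's single best unigene alignment) / (cDNA
length). Under idealized scoring (+2 bits per matched base, −2 per
mismatch, −5 per gap opening, clamped at ≥0) a perfect full-length
alignment scores exactly 2.0 bits/base and an error-free 75%-length
reconstruction exactly 1.5 — the default "long and accurate" threshold.
The +2 match reward is forced by the 2.0 ideal once the −2/−5 penalties
are fixed. Real aligner bit scores run slightly below 2 bits/base
(composition-dependent); they are accepted as an override
(`external_bits`) so real BLAST tables can be scored directly.
BS deliberately uses one best alignment per gene — it asks "did any
single unigene reconstruct this transcript?" — whereas coverage breadth
is its cumulative counterpart.

SFB = (fragments summed over all unigenes assigned to the gene) /
(cDNA length); fragment counts are attributed via the best-hit
assignment, and SFB is invariant to how fragments split among a gene's
unigenes. Fragments (pairs or orphans) are the counted unit throughout;
a phrasing that counts individual reads would double SFB for fully
paired data, and the fragment definition is used consistently.
Genes with no alignment are reported with BS 0 and no best unigene so
threshold counts need no special case. The quality-depth table carries
the tail count n(BS > threshold), the headline number of the analysis.

Conserved-ortholog recovery reports, over a user-supplied gene list,
the fractions with BS above threshold and with coverage >90% / >99%.
Paralog pairs are reciprocal best non-self hits; each pair is classed
by expression (both/one/neither mate at SFB ≥ 0.1) and by assembly
(both/one mate above BS 1.5, present-but-low, or missing). The
closely-related subset keeps expressed pairs with Ks < 0.2, capped at
the 300 lowest-Ks pairs; Ks values are consumed from a precomputed pair
table — estimating Ks is out of scope.

## Reference-free metrics

N50 follows the cumulative-from-longest convention: the length at which
the descending cumulative sum first reaches half the total assembled
bases (ties resolved by that first-reach rule). Sequences under 100 bp
(configurable) are removed first; the cutoff sweep repeats the
computation at 100..600 bp minima. The mappable fraction tolerates
mapped > total with a warning because denominator conventions
legitimately differ (e.g. normalizing by reads that map to a reference
cDNA set rather than all raw reads); the convention belongs in output
metadata.

The titration (gene accumulation) curve samples mapped fragments
without replacement in one seeded random permutation, recording
distinct unigenes every 1000 reads (configurable) plus the exact
endpoint (all mapped reads, all unigenes with ≥1 read). Its analytic
companion is the exact expectation
E[U(m)] = Σᵢ (1 − C(T−cᵢ, m)/C(T, m)), computed via log-gamma for
stability; the Monte-Carlo and analytic curves agreeing within
sampling error is a standing cross-check between two independent
routes. Count correlations (Spearman and Pearson) operate on
log2(x+1)-transformed per-gene counts over the union gene universe with
absent genes imputed as zero.

The four-point checklist passes an assembly that has (1) mappable reads
> 65%, (2) unigene count ≥ 150% of the expected transcript count —
superior assemblers genuinely produce *more* unigenes than transcripts,
because fragmentation at both expression extremes is unavoidable —
(3) N50 ≥ 1200 bp, and (4) conserved-ortholog recovery (fraction
covered >90%) ≥ 0.70. The ortholog threshold is the one the checklist's
source analysis leaves implicit; 0.70 (the leading-assembler ~75%
benchmark rounded down) is the default and all four cuts are
configurable.

## Synthetic fixtures

The generator's role is to make every classifier testable with no
external data, not to simulate sequencing physics. A plan draws gene
lengths from a clipped normal (default mean 1200 bp, sd 400, min 300 —
typical plant cDNA scale), creates a fraction of genes (default 20%,
i.e. 10% of genes as pair partners) by copy-and-mutate at a stated
per-base divergence, and lays genes on chromosomes with exponential
intergenic spacers (mean 2 kb) so gene adjacency and genomic windows
are well defined. Expression is log-normal (defaults: log-mean 4,
log-sd 1.5, spanning roughly three orders of magnitude — transcript
abundance in real tissues varies at least that much) with a stated
fraction of genes zeroed as undetected.

The corruptor realizes an error plan *exactly*: fragmentation
directives split genes so the reference projections produce the planned
gap or overlap (the plan always includes the boundary overlaps k−1 and
k); chimera directives concatenate segments of two genes on different
chromosomes (never adjacent, and their genomic windows can never merge);
co-assembly directives emit the true genomic stretch spanning two
adjacent genes including the intergenic spacer, so exactly one
contiguous genome window explains them; duplicate directives plant
equal full-length two-locus alignments. Alignment tables are then
*emitted from the recorded construction geometry* with idealized
scoring rather than computed by an aligner — this keeps tests
desk-scale and dependency-free, and is honest for what it tests: the
classifiers' decision rules, not an aligner's behaviour. Fragmentation,
chimera and co-assembly fixtures are sequence-consistent by
construction; the Type II overlap cases (III–V) record their intended
two-locus geometry without planting literal homology between the loci.
Consequently passing tests demonstrate correct classification of
well-formed alignment evidence; they do not exercise aligner artifacts
(split HSPs, end trimming, repeat-induced spurious hits), which is what
the configurable jitter/merge tolerances exist to absorb on real data.
A documented escape hatch accepts real BLAST tables end to end.

The fragment-pool subsampler keeps read pairs atomically, sampling
without replacement until the cumulative base count reaches the target;
the last accepted pair may overshoot (the boundary behaviour is
unspecified in common practice, so the overshoot-by-one-pair convention
is chosen and frozen here). All generators are pure functions of
(plan, seed).

## Numerical and testing choices

Problem sizes are chosen for interactive turnaround: the standard test
fixture is a 500-gene transcriptome carrying 200 planted error events
(25 per kind across all eight Type I/II cases, plus 25 chimeras, 25
duplicates and 25 co-assemblies), on which classification is asserted
to be exact — 100% precision and recall, including the k−1/k boundary.
N50 and coverage are validated against brute-force oracles (candidate
enumeration; boolean base masks) on 1000 randomized instances each.
The titration Monte-Carlo (100 seeds) is compared to the closed-form
expectation within 3 standard errors at every recorded point on a
canonical toy table (20 unigenes, counts 1..20); a per-point 3σ rule
across correlated points is expected to fail by chance a few percent of
the time on arbitrary random tables, so the table is fixed rather than
rng-drawn. Every stochastic operation is byte-identical across runs at
a fixed seed, and all randomness flows through
`numpy.random.default_rng`.

## Known limitations

- Read-level coverage (as opposed to unigene-level) is out of scope;
  the fixture generator does not model base-by-base read placement.
- The synthetic corruptor does not simulate splice isoforms,
  strand-specific libraries, quality strings, or realistic read error
  profiles.
- Type II Case II's exact bit-score equality will under-count "aligns
  equally" on real data where scores differ in the last digit; widen
  the jitter or pre-round scores if that matters.
- The trans-splice verdict is flag-driven, never inferred.
- Running assemblers, BLAST/Bowtie, Ks estimation and taxonomic
  classification of unassigned unigenes are all deliberately outside
  the package; their outputs are inputs here.
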