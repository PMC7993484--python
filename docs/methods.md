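# Methods

## The design problem

K-seq amplifies genomic fragments flanked by convergent binding sites of
short (8–9 nt) oligonucleotides, using Klenow polymerase at 37 °C for the
first two extension rounds and standard PCR afterwards. A good oligo set
maximizes the number of sequenceable fragments in single-copy, gene-rich
sequence while avoiding oligos that dimerize or fold. This package
implements that selection, the prediction of the amplified fragment set, the
statistics used to judge a prediction against sequencing data, and a
protocol simulator that provides exact ground truth.

## Coordinate and masking conventions

All internal coordinates are 0-based half-open; GFF3 (1-based inclusive) is
converted on ingest. A single convention eliminates off-by-one drift, and
round-trips (GFF3 → internal → BED) preserve covered base sets exactly.
Chromosome names are matched by exact string equality; no "chr"-prefix
normalization is attempted.

"Nonrepetitive" means a window with zero masked bases, where the mask is the
union of two evidence sources: soft-masked (lower-case) bases in the source
FASTA and bases covered by repeat-type annotation features. Annotations vary
in whether repeats are encoded in case, features, or both, so the union is
the conservative reading; when reproducing a published design this is a
known divergence risk because the original mask definition is rarely stated.
N bases are never part of a k-mer or of a binding site.

## k-mer census

Every ACGT-only window of length k is counted once per position; windows
containing N are dropped; a window counts as nonrepetitive only if *fully*
unmasked (the stricter of the plausible readings — a window merely starting
in unmasked sequence does not qualify). Default strand mode is `both`: a
primer anneals to either strand, so a k-mer's count includes its reverse
complement's occurrences. K-mers are *not* canonicalized — primers are
synthesized as written, so a k-mer and its reverse complement stay distinct
entries; only the counts are strand-folded. `plus_only` mode is retained for
oracle tests. Counting is vectorized (2-bit packing + `np.unique`), which
keeps desk-scale genomes (≤ tens of Mb) in memory comfortably; disk-backed
streaming for multi-gigabase genomes is future work.

## Candidate selection and set assembly

GC bounds (default 0.35–0.75) are inclusive and compared as exact rationals
(`Fraction`), so for k = 8 the window admits exactly 3–6 G/C bases and
boundary k-mers are never lost to float rounding. Ranking is by
nonrepetitive count descending with lexicographic tie-break, making the
candidate pool invariant to input ordering and byte-identical across runs.

Set assembly is greedy in rank order: an oligo joins the growing set only if
its self checks and all pairwise checks against current members pass.
Greedy construction favors abundant k-mers — i.e. more predicted fragments —
and is reproducible; the three sets are disjoint so they offer genuinely
alternative reagents. After a set reaches 10 members, the first 5 by rank
become forward primers. The F/R split is labeling only: both orientation
arrangements of a genomic site pair (F left / R right and R left / F right)
produce sequenceable fragments, so the split does not change which products
exist.

Compatibility is screened with contiguous complementarity runs rather than a
thermodynamic alignment: `longest_any_run` is the longest Watson–Crick run
between one oligo and the reverse of the other over all offsets,
`longest_3prime_run` the longest run touching either oligo's 3′-terminal
base, and the hairpin check the longest self-folding stem with a loop of
≥ 3 unpaired bases. Defaults (any ≤ 5, 3′ ≤ 3, stem ≤ 3) are declared
thresholds appropriate for 8–9-mers, not inferred from any published
parameter set; for oligos this short a run-length screen is deterministic,
dependency-free and fully testable against an exhaustive enumeration
oracle. A `pair_check` hook allows swapping in a thermodynamic scorer.

## Virtual PCR

Binding sites are all windows on either strand within Hamming distance
`max_mismatches` (default 0) of the primer; the scan is a vectorized
per-offset mismatch count. Minus-strand sites are windows matching the
primer's reverse complement, reported in plus-strand coordinates with
mismatch positions mapped back into primer coordinates. A mismatch at the
primer's 3′-terminal base can optionally be disallowed
(`allow_3prime_mismatch=False`); by default it is tolerated since Klenow's
3′-mismatch extension tolerance is not well characterized.

Products are *all* convergent opposite-role site pairs with span in
[`min_product_len`, `max_product_len`] (defaults 50–2000 bp): no
competition, interference or nearest-site suppression is modeled, matching
the combinatorial "number of products expected per primer pair" that the
per-pair report tabulates. Overlapping and nested products are retained;
deduplication is only on identical (chrom, start, end, primer pair). The
50 bp minimum guards against primer-dimer-scale artifacts. The default
`max_mismatches=0` reflects design-time prediction; allowing 1–2 mismatches
shows how much larger the realized library will be, since mismatch priming
is the dominant source of unpredicted fragments in practice.

"Repetitive" classification uses the masked-base fraction of the product
span with threshold 0.5. The alternative definition — multiplicity of the
product sequence elsewhere in the genome — is combinatorially expensive and
was rejected; the threshold is configurable.

## Evaluation statistics

Overlap fractions are computed on merged interval sets; a region counts as
"predicted" on any overlap by default (`min_overlap_fraction` exposes a
stricter criterion, since published overlap figures rarely state one).
The empty observed set is an explicit error rather than a silent NaN.

`end_mismatch_rate` assigns each fragment-end sequence to the primer (both
orientations) with minimal Hamming distance over the primer-length prefix,
ties broken by primer list order with the as-written orientation first.
Ends worse than `max_mm` (default 3) stay unassigned and are excluded. The
rate is reported per fragment end, and additionally per unique priming site
when site keys are supplied, because the two can differ when coverage is
uneven.

## Simulator

`make_genome` draws an i.i.d. background at the requested GC content, places
tandem-repeat blocks (soft-masked and annotated), annotates genes
(length ~ Normal(mean, mean/4), placement uniform non-overlapping), and
plants forward/reverse site pairs at uniformly random unmasked, mutually
non-overlapping loci using a sorted-gap construction that stays O(n log n)
even for 10,000 planted sites. The planted truth records exact fragment
coordinates. Everything derives from one `numpy` generator, so a seed fixes
the genome byte-for-byte.

`simulate_kseq` abstracts enzyme chemistry into survival rules, which is
exactly what the protocol's selection logic amounts to: a fragment survives
to sequencing iff a forward-role and a reverse-role site form a convergent
pair within the maximal extension span (default 2000 bp, mirroring the
virtual-PCR maximum since the true Klenow extension limit is not
characterized) and both priming events succeeded (per-site Bernoulli,
default 1.0). Single-primed, F–F and R–R molecules carry at most one
adapter and are discarded — the Exonuclease I / adapter logic. PCR
duplication draws a geometric copy number (mean configurable, default 1);
the cycle count is recorded but only duplicate multiplicity matters to any
statistic. Optional size selection keeps 300–700 bp fragments. R1 reads
start at the forward-primed end, R2 at the reverse-complemented other end.

Mismatch priming is modeled at read emission: with probability `p_mismatch`
per fragment end, the primer-span prefix of that end acquires exactly one
substitution at a uniform position, shared by all PCR duplicates of the
fragment (it is a priming-event property, not a sequencing error). Fragment
coordinates are unchanged. This is deliberately minimal — it makes
`end_mismatch_rate` an unbiased estimator of `p_mismatch` and keeps the
p = 0 fragment set exactly equal to the virtual-PCR product set — but it
means simulated mismatch fragments do not occupy *new* genomic loci, so the
simulator cannot by itself reproduce the observed-vs-predicted overlap gap
caused by real mismatch priming; that effect is instead explored by raising
`max_mismatches` in the virtual PCR. Base-call errors and quality models
are off by default and out of scope.

## What the synthetic data does and does not show

The generator emulates the features the pipeline is sensitive to: repeat
masking, gene annotation, planted primer sites with known truth, and
mismatch-primed ends. It does not emulate real genome composition
(isochores, repeat families, segmental duplications), chance k-mer abundance
structure at gigabase scale, enzyme kinetics, or read-count imbalance
between pooled samples. Passing tests therefore demonstrate algorithmic
correctness (against brute-force oracles) and internal consistency
(simulator ≡ prediction at p = 0), not that a specific published species
design is reproduced — published product counts additionally depend on the
reference assembly, the original tool's undisclosed compatibility settings
and its mask definition.

## Problem sizes and numerical choices

The test suite exercises: 20 random 100 kb genomes (10 primers, 0–1
mismatches) against a regex-enumeration site oracle and an all-pairs pairing
oracle; 50 random 20 kb genomes against a naive census scan; 5,000-k-mer
randomized tables for selection; and 6 Mb genomes with 10,000 planted sites
for parameter recovery (tolerance 3 binomial SE + 0.005). These sizes give
tight statistical power while keeping the whole suite around a minute.
Degenerate inputs are defined errors, not silent results: empty observed
sets, zero-length targets, empty primer lists, no GC-passing k-mer (which
reports a diagnostic GC histogram), and an unbuildable primer set (which
reports the most frequently failing check).
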