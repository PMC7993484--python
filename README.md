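# kseq

Primer-set design, virtual PCR and protocol simulation for **K-seq**, a
reduced-representation genotyping method that amplifies thousands of genomic
fragments with two rounds of Klenow-polymerase extension from short (8–9 nt)
adapter-tailed oligonucleotides, followed by standard PCR and Illumina
sequencing. Because Klenow extends at 37 °C, oligos this short anneal
reliably — unlike Taq-based RAPD — and a well-chosen oligo set reproducibly
samples the same easily-mappable, gene-rich fraction of the genome in every
sample.

The package is for anyone setting up K-seq (or a similar Klenow/short-primer
protocol) on a new species: it turns a reference genome into candidate primer
sets, predicts what they will amplify, and lets you rehearse the entire
experiment in silico before ordering oligos.

## What it computes

**Oligo selection.** All k-mers (k = 8 for sub-gigabase genomes, 9 for
larger ones) are censused genome-wide and within *nonrepetitive* regions —
windows containing no soft-masked or repeat-annotated base. K-mers with GC
content in [35%, 75%] (inclusive, exact rational comparison) are ranked by
nonrepetitive abundance; the top 1000 form the candidate pool. Greedy
assembly in rank order produces up to three disjoint 10-oligo sets whose
members pass pairwise compatibility screens (contiguous complementarity
runs: cross/self dimer ≤ 5 bp, 3′-anchored run ≤ 3 bp, hairpin stem ≤ 3 bp
with loop ≥ 3). Each set is split into 5 forward and 5 reverse primers —
the role decides which Illumina adapter tail an oligo carries.

**Virtual PCR.** Every genomic window on either strand within a configurable
Hamming distance of a primer (default 0) is a binding site. Every convergent
site pair — plus-strand site left of a minus-strand site, one forward-role
and one reverse-role primer, span within [50, 2000] bp — yields a predicted
product; F–F and R–R pairs carry only one adapter and are never
sequenceable. Products are flagged for the 300–700 bp size-selection window
and classified *single* vs *repetitive* (> 50% repeat-masked bases). The
per-primer-pair report of single/repetitive product counts is the basis for
choosing the final oligo combination (`subset_report` evaluates any subset,
e.g. a 3-oligo reagent).

**Evaluation.** Given observed high-coverage regions (BED) and/or fragment
end reads: region- and base-level observed-vs-predicted overlap fractions;
gene-base fractions of the genome, the prediction and the observation; and
the fraction of fragment ends primed with ≥ 1 mismatch — the mechanism that
makes real K-seq libraries much larger than the exact-match prediction.

**Simulator.** A synthetic-genome generator (repeats, genes, planted
primer-site pairs with exact ground truth) and a stage-faithful protocol
simulator (Klenow round 1, Exonuclease I survival, Klenow round 2, adapter
logic, PCR duplication, size selection, paired reads) for end-to-end testing.

## Worked example

```python
from kseq import (SyntheticGenomeSpec, make_genome, count_kmers,
                  select_candidates, build_primer_sets, run_virtual_pcr,
                  simulate_kseq, overlap_stats, products_to_regions,
                  SimConfig)

genome, features, _ = make_genome(SyntheticGenomeSpec(
    chrom_length=100_000, repeat_fraction=0.1, gene_fraction=0.3, seed=1))
table = count_kmers(genome, k=8)                  # 57,136 distinct 8-mers
candidates = select_candidates(table)             # top 1000 after GC filter
sets = build_primer_sets(candidates)              # 3 compatible 10-oligo sets
products, report = run_virtual_pcr(genome, sets[0])
print(report.totals)
# {'n_products': 22, 'n_single': 18, 'n_repetitive': 4,
#  'n_in_size_window': 4, 'n_nonrepetitive_region': 14}
library = simulate_kseq(genome, sets[0], SimConfig(), seed=2)
ov = overlap_stats(library.truth_regions(), products_to_regions(products))
print(ov.fraction_observed_bases_predicted)       # 1.0
```

On this 100 kb toy genome the first primer set predicts 22 products (18 in
single-copy sequence, 4 falling in the 300–700 bp sequencing window), and —
with perfect priming and no mismatches — the simulated library covers
exactly the predicted fragment set, so the observed-vs-predicted base
overlap is 1.0. Raising `SimConfig(p_mismatch=...)` reproduces the
real-world effect of mismatch priming: the library grows past the prediction
and `end_mismatch_rate` quantifies it.

The same workflow is available from the shell:

```bash
kseq design   --genome genome.fa --k 8 --out design/
kseq vpcr     --genome genome.fa --primers design/primer_set_1.tsv --out vpcr/
kseq simulate --genome genome.fa --primers design/primer_set_1.tsv --seed 5 --out sim/
kseq evaluate overlap --observed sim/truth.bed --predicted vpcr/products.bed
```

Every run writes a `manifest.json` (parameters, tool version, input
checksums) next to its outputs.

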