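"""Prediction-quality statistics.

Three questions about a designed primer set, once real (or simulated)
sequencing data exist:

* how much of what was actually sequenced did the virtual PCR predict
  (:func:`overlap_stats`) — in practice this fraction is small because short
  primers also prime at mismatched genomic sites the exact-match prediction
  does not see;
* how gene-rich are the whole genome, the predicted fragments, and the
  observed regions (:func:`gene_fraction`);
* what fraction of fragment ends were primed with one or more mismatches
  (:func:`end_mismatch_rate`).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .io_formats import FeatureSet, GenomeSequence, RegionSet, reverse_complement


@dataclass
class OverlapReport:
    n_observed_regions: int
    n_observed_bases: int
    fraction_observed_regions_predicted: float
    fraction_observed_bases_predicted: float
    n_predicted_regions: int
    n_predicted_bases: int
    fraction_predicted_regions_observed: float
    fraction_predicted_bases_observed: float


def _region_fraction(a: RegionSet, b_trees, min_overlap_fraction: float) -> float:
    hit = 0
    regions = a.merged().regions
    for chrom, start, end in regions:
        tree = b_trees.get(chrom)
        if tree is None:
            continue
        ov = sum(min(end, iv.end) - max(start, iv.begin)
                 for iv in tree.overlap(start, end))
        if min_overlap_fraction <= 0:
            if ov > 0:
                hit += 1
        elif ov >= min_overlap_fraction * (end - start):
            hit += 1
    return hit / len(regions)


def overlap_stats(observed: RegionSet, predicted: RegionSet,
                  min_overlap_fraction: float = 0.0) -> OverlapReport:
    """Region- and base-level overlap between observed and predicted sets.

    All quantities are computed on merged interval sets.  An observed region
    counts as predicted when any base overlaps the predicted set (default),
    or when at least *min_overlap_fraction* of it does.
    """
    if len(observed) == 0:
        raise ValueError("observed region set is empty")
    obs_m, pred_m = observed.merged(), predicted.merged()
    obs_bases = obs_m.total_bases()
    pred_bases = pred_m.total_bases()
    inter = obs_m.intersect_bases(pred_m)
    pred_trees = pred_m.trees()
    obs_trees = obs_m.trees()
    return OverlapReport(
        n_observed_regions=len(obs_m),
        n_observed_bases=obs_bases,
        fraction_observed_regions_predicted=_region_fraction(
            obs_m, pred_trees, min_overlap_fraction),
        fraction_observed_bases_predicted=inter / obs_bases,
        n_predicted_regions=len(pred_m),
        n_predicted_bases=pred_bases,
        fraction_predicted_regions_observed=(
            _region_fraction(pred_m, obs_trees, min_overlap_fraction)
            if len(pred_m) else 0.0),
        fraction_predicted_bases_observed=(inter / pred_bases
                                           if pred_bases else 0.0),
    )


def gene_fraction(target: RegionSet | GenomeSequence,
                  genes: FeatureSet) -> float:
    """Fraction of the target's bases covered by (merged) gene annotation.

    Pass the genome itself to get the whole-genome baseline, or a region set
    of predicted fragments / observed regions.
    """
    if isinstance(target, GenomeSequence):
        target = RegionSet([(name, 0, genome_len)
                            for name, genome_len in
                            ((n, len(s)) for n, s in target.sequences.items())
                            if genome_len > 0])
    total = target.total_bases()
    if total == 0:
        raise ValueError("zero-length target")
    gene_regions = RegionSet([(f.chrom, f.start, f.end)
                              for f in genes.by_type("gene")])
    if len(gene_regions) == 0:
        return 0.0
    return target.intersect_bases(gene_regions) / total


@dataclass
class MismatchReport:
    n_ends_examined: int
    n_ends_assigned: int
    fraction_with_ge1_mismatch: float
    histogram: dict[int, int]            # mismatch count -> ends
    per_primer: pd.DataFrame             # primer_id, n_assigned, n_mismatched
    fraction_with_ge1_mismatch_dedup: float | None = None


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def end_mismatch_rate(fragment_end_sequences, primers,
                      max_mm: int = 3,
                      site_keys=None) -> MismatchReport:
    """Assign each fragment end to its best-matching primer; count mismatches.

    Each end is compared, over its first ``len(primer)`` bases, against every
    primer in both orientations (as written, then reverse-complemented); the
    minimal Hamming distance wins, ties broken by primer list order with the
    as-written orientation first.  Ends whose best distance exceeds *max_mm*
    are left unassigned and excluded from the rate.

    *primers* is a mapping id -> sequence (or an iterable of (id, sequence)).
    When *site_keys* (one hashable per end, e.g. the priming coordinate) is
    given, a per-unique-site rate is also reported.
    """
    if isinstance(primers, dict):
        primer_items = list(primers.items())
    else:
        primer_items = list(primers)
    if not primer_items:
        raise ValueError("empty primer list")
    variants = []
    for pid, seq in primer_items:
        variants.append((pid, seq))
        variants.append((pid, reverse_complement(seq)))

    hist: Counter[int] = Counter()
    per_primer: dict[str, Counter] = {pid: Counter() for pid, _ in primer_items}
    n_examined = 0
    assigned: list[tuple[str, int]] = []
    site_best: dict = {}
    for idx, end_seq in enumerate(fragment_end_sequences):
        n_examined += 1
        best_pid, best_d = None, None
        for pid, var in variants:
            if len(end_seq) < len(var):
                raise ValueError("fragment end shorter than primer")
            d = _hamming(end_seq[:len(var)], var)
            if best_d is None or d < best_d:
                best_pid, best_d = pid, d
        if best_d > max_mm:
            continue
        assigned.append((best_pid, best_d))
        hist[best_d] += 1
        per_primer[best_pid]["n_assigned"] += 1
        if best_d >= 1:
            per_primer[best_pid]["n_mismatched"] += 1
        if site_keys is not None:
            key = site_keys[idx]
            if key not in site_best:
                site_best[key] = best_d

    n_assigned = len(assigned)
    frac = (sum(1 for _, d in assigned if d >= 1) / n_assigned
            if n_assigned else 0.0)
    dedup = None
    if site_keys is not None and site_best:
        dedup = sum(1 for d in site_best.values() if d >= 1) / len(site_best)
    per_primer_df = pd.DataFrame(
        [(pid, c["n_assigned"], c["n_mismatched"])
         for pid, c in per_primer.items()],
        columns=["primer_id", "n_assigned", "n_mismatched"])
    return MismatchReport(n_examined, n_assigned, frac, dict(hist),
                          per_primer_df, dedup)
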