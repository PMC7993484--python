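"""Virtual PCR: binding-site search, product enumeration and reporting.

A primer binds a genomic window on the plus strand (extension rightward) or
the minus strand (window matches the primer's reverse complement on plus
coordinates; extension leftward).  A product is any convergent pair of
non-overlapping sites — one plus, one minus — on the same chromosome whose
span falls in the configured length window, with exactly one forward-role and
one reverse-role primer (only such fragments carry both adapter tails and are
sequenceable; forward–forward and reverse–reverse pairs are not).  All
qualifying pairs are emitted; there is no competition or nearest-site
suppression.

Products are classified *repetitive* when more than a configurable fraction
of their span is repeat-masked, otherwise *single*.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GenomeSequence, RegionSet, reverse_complement, write_tsv
from .kmer_census import _rolling_nonzero, encode

logger = logging.getLogger("kseq")


@dataclass
class VpcrConfig:
    max_mismatches: int = 0
    min_product_len: int = 50
    max_product_len: int = 2000
    size_min: int = 300
    size_max: int = 700
    repetitive_mask_fraction: float = 0.5
    allow_3prime_mismatch: bool = True

    def __post_init__(self) -> None:
        if not (self.min_product_len < self.size_min <= self.size_max
                <= self.max_product_len):
            raise ValueError("require min_product_len < size_min <= size_max "
                             "<= max_product_len")


@dataclass(frozen=True)
class BindingSite:
    chrom: str
    start: int          # plus-strand coordinate of the matched window
    strand: str         # '+' or '-'
    primer_id: str
    length: int
    mismatch_count: int = 0
    mismatch_positions: tuple[int, ...] = ()  # indices within the primer

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass
class PredictedProduct:
    chrom: str
    start: int
    end: int
    left_id: str
    left_role: str
    right_id: str
    right_role: str
    in_size_window: bool
    classification: str | None = None
    masked_base_fraction: float | None = None

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def pair(self) -> tuple[str, str]:
        """(forward id, reverse id) irrespective of which side is left."""
        if self.left_role == "forward":
            return (self.left_id, self.right_id)
        return (self.right_id, self.left_id)


def find_binding_sites(genome: GenomeSequence, primer: str, primer_id: str,
                       max_mismatches: int = 0,
                       allow_3prime_mismatch: bool = True) -> list[BindingSite]:
    """All windows on either strand within Hamming distance of the primer.

    Windows containing N are never binding sites.  With
    ``allow_3prime_mismatch`` off, a
    mismatch at the primer's 3'-terminal base disqualifies the site.
    """
    if set(primer) - set("ACGT") or not 4 <= len(primer) <= 16:
        raise ValueError(f"primer must be ACGT of length 4..16, got {primer!r}")
    L = len(primer)
    sites: list[BindingSite] = []
    targets = {"+": encode(primer), "-": encode(reverse_complement(primer))}
    for chrom, seq in genome.sequences.items():
        n = len(seq)
        if n < L:
            continue
        codes = encode(seq)
        w = n - L + 1
        has_n = _rolling_nonzero(codes == 4, L)  # N never part of a site
        for strand, target in targets.items():
            dist = np.zeros(w, dtype=np.int16)
            for j in range(L):
                dist += codes[j:j + w] != target[j]
            for pos in np.nonzero((dist <= max_mismatches) & ~has_n)[0].tolist():
                window = codes[pos:pos + L]
                diff = np.nonzero(window != target)[0]
                if strand == "+":
                    mm = tuple(int(d) for d in diff)
                else:  # window position p pairs primer index L-1-p
                    mm = tuple(sorted(L - 1 - int(d) for d in diff))
                if not allow_3prime_mismatch and (L - 1) in mm:
                    continue
                sites.append(BindingSite(chrom, int(pos), strand, primer_id,
                                         L, len(mm), mm))
    return sites


def enumerate_products(sites: list[BindingSite], roles: dict[str, str],
                       config: VpcrConfig | None = None) -> list[PredictedProduct]:
    """Emit every convergent opposite-role site pair within the length window."""
    if config is None:
        config = VpcrConfig()
    by_chrom: dict[str, tuple[list[BindingSite], list[BindingSite]]] = {}
    for s in sites:
        plus, minus = by_chrom.setdefault(s.chrom, ([], []))
        (plus if s.strand == "+" else minus).append(s)

    products: list[PredictedProduct] = []
    seen: set[tuple] = set()
    for chrom, (plus, minus) in by_chrom.items():
        minus.sort(key=lambda s: s.start)
        m_starts = [s.start for s in minus]
        for left in plus:
            lo = bisect_left(m_starts, left.end)
            for right in minus[lo:]:
                span = right.end - left.start
                if right.start - left.start > config.max_product_len:
                    break
                if span > config.max_product_len or span < config.min_product_len:
                    continue
                if roles[left.primer_id] == roles[right.primer_id]:
                    continue  # F-F / R-R molecules are not sequenceable
                key = (chrom, left.start, right.end,
                       left.primer_id, right.primer_id)
                if key in seen:
                    continue
                seen.add(key)
                products.append(PredictedProduct(
                    chrom, left.start, right.end,
                    left.primer_id, roles[left.primer_id],
                    right.primer_id, roles[right.primer_id],
                    in_size_window=(config.size_min <= span <= config.size_max),
                ))
    products.sort(key=lambda p: (p.chrom, p.start, p.end, p.left_id, p.right_id))
    return products


def classify_products(products: list[PredictedProduct],
                      genome: GenomeSequence,
                      config: VpcrConfig | None = None) -> list[PredictedProduct]:
    """Set masked_base_fraction and the single/repetitive classification."""
    if config is None:
        config = VpcrConfig()
    for p in products:
        mask = genome.masks[p.chrom]
        frac = float(mask[p.start:p.end].mean()) if p.end > p.start else 0.0
        p.masked_base_fraction = frac
        p.classification = ("repetitive"
                            if frac > config.repetitive_mask_fraction
                            else "single")
    return products


@dataclass
class VpcrReport:
    """Per-primer-pair product counts plus totals."""

    per_pair: pd.DataFrame  # forward_id, reverse_id, n_single, n_repetitive,
                            # n_products, n_in_size_window
    totals: dict[str, int] = field(default_factory=dict)

    def to_tsv(self, path, config=None) -> None:
        write_tsv(self.per_pair, path, config)


def summarize(products: list[PredictedProduct],
              roles: dict[str, str]) -> VpcrReport:
    """The per-pair report: predicted single and repetitive product counts."""
    per_pair: dict[tuple[str, str], Counter] = {}
    totals = Counter(n_products=0, n_single=0, n_repetitive=0,
                     n_in_size_window=0, n_nonrepetitive_region=0)
    for p in products:
        c = per_pair.setdefault(p.pair, Counter())
        c["n_products"] += 1
        totals["n_products"] += 1
        if p.classification == "repetitive":
            c["n_repetitive"] += 1
            totals["n_repetitive"] += 1
        else:
            c["n_single"] += 1
            totals["n_single"] += 1
        if p.in_size_window:
            c["n_in_size_window"] += 1
            totals["n_in_size_window"] += 1
        if p.masked_base_fraction == 0.0:
            totals["n_nonrepetitive_region"] += 1
    rows = [(f, r, c["n_single"], c["n_repetitive"], c["n_products"],
             c["n_in_size_window"])
            for (f, r), c in sorted(per_pair.items())]
    df = pd.DataFrame(rows, columns=["forward_id", "reverse_id", "n_single",
                                     "n_repetitive", "n_products",
                                     "n_in_size_window"])
    return VpcrReport(df, dict(totals))


def subset_report(products: list[PredictedProduct], roles: dict[str, str],
                  chosen_primer_ids: set[str]) -> VpcrReport:
    """Report restricted to products whose both primers are in the subset.

    This is how a final reagent (e.g. a 3-oligo combination) is evaluated
    against the full prediction.
    """
    chosen_roles = {roles[pid] for pid in chosen_primer_ids}
    if chosen_roles < {"forward", "reverse"}:
        logger.warning("chosen subset lacks a %s primer; empty report",
                       ({"forward", "reverse"} - chosen_roles).pop())
        empty = pd.DataFrame(columns=["forward_id", "reverse_id", "n_single",
                                      "n_repetitive", "n_products",
                                      "n_in_size_window"])
        return VpcrReport(empty, {"n_products": 0, "n_single": 0,
                                  "n_repetitive": 0, "n_in_size_window": 0,
                                  "n_nonrepetitive_region": 0})
    sel = [p for p in products
           if p.left_id in chosen_primer_ids and p.right_id in chosen_primer_ids]
    return summarize(sel, roles)


def run_virtual_pcr(genome: GenomeSequence, primer_set, config=None):
    """find -> enumerate -> classify -> summarize for one primer set.

    Returns (products, report).
    """
    if config is None:
        config = VpcrConfig()
    roles = primer_set.roles()
    sites: list[BindingSite] = []
    for pid, seq in primer_set.primers().items():
        sites.extend(find_binding_sites(genome, seq, pid,
                                        config.max_mismatches,
                                        config.allow_3prime_mismatch))
    products = enumerate_products(sites, roles, config)
    classify_products(products, genome, config)
    return products, summarize(products, roles)


def products_to_regions(products: list[PredictedProduct]) -> RegionSet:
    regions = [(p.chrom, p.start, p.end) for p in products]
    return RegionSet(regions, [float(p.length) for p in products])


def products_to_bed(products: list[PredictedProduct], path) -> None:
    """BED6 export: name = F|R|classification, score = length."""
    with open(path, "w") as fh:
        for p in products:
            f_id, r_id = p.pair
            name = f"{f_id}|{r_id}|{p.classification or 'NA'}"
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{name}\t{p.length}\t+\n")
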