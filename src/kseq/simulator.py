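"""Synthetic genomes and an in-silico K-seq protocol.

The simulator plays the wet protocol forward on a genome: forward primers
anneal at their genomic sites and are extended by Klenow polymerase; material
that was never extended is destroyed (Exonuclease I); reverse primers anneal
within the round-1 molecules and define the fragment's other end; molecules
that do not carry both adapter tails — forward-forward, reverse-reverse or
single-primed — never become sequenceable; PCR multiplies each surviving
fragment; an optional size selection keeps 300–700 bp; finally paired reads
are emitted from the fragment ends.

Enzyme chemistry is abstracted into survival rules: a fragment exists exactly
when a convergent forward/reverse site pair lies within the maximal extension
span and both priming events succeeded.  Mismatch priming is modeled at read
emission: with probability ``p_mismatch`` a fragment end's primer-span prefix
acquires exactly one substitution at a uniform position, shared by all PCR
duplicates of that fragment (a priming-event property, not a sequencing
error).

The genome generator plants known forward/reverse site pairs at random
unmasked loci, soft-masks tandem repeats, and annotates genes, giving exact
ground truth for end-to-end tests.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_formats import (Feature, FeatureSet, GenomeSequence, ReadPair,
                         RegionSet, reverse_complement)
from .primer_design import PrimerSet
from .virtual_pcr import BindingSite, find_binding_sites

logger = logging.getLogger("kseq")

_BASES = "ACGT"


@dataclass
class SyntheticGenomeSpec:
    n_chromosomes: int = 1
    chrom_length: int = 100_000
    gc_content: float = 0.4
    repeat_fraction: float = 0.0
    repeat_unit_length: int = 200
    repeat_copies: int = 3          # tandem copies per repeat block
    gene_fraction: float = 0.0
    mean_gene_length: int = 1000
    #: (forward primer, reverse primer, spacing) — spacing is the gap between
    #: the two primer windows, so the amplicon length is 2*len + spacing.
    planted_sites: Sequence[tuple[str, str, int]] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for frac in (self.gc_content, self.repeat_fraction, self.gene_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")


@dataclass(frozen=True)
class PlantedSite:
    chrom: str
    start: int
    end: int
    f_primer: str
    r_primer: str


@dataclass
class SimConfig:
    priming_success: float = 1.0
    p_mismatch: float = 0.0
    size_selection: bool = False
    size_min: int = 300
    size_max: int = 700
    pcr_cycles: int = 15            # recorded; duplicates below model its effect
    pcr_mean_duplicates: float = 1.0
    read_length: int = 100
    min_fragment_len: int = 50
    max_fragment_len: int = 2000    # maximal Klenow extension span

    def __post_init__(self) -> None:
        for p in (self.priming_success, self.p_mismatch):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class SimulatedFragment:
    chrom: str
    start: int
    end: int
    f_id: str
    r_id: str
    f_is_left: bool
    f_mismatch_pos: int | None = None
    r_mismatch_pos: int | None = None
    n_duplicates: int = 1


@dataclass
class SimulatedLibrary:
    fragments: list[SimulatedFragment] = field(default_factory=list)
    read_pairs: list[ReadPair] = field(default_factory=list)

    def truth_regions(self) -> RegionSet:
        uniq = sorted({(f.chrom, f.start, f.end) for f in self.fragments})
        return RegionSet(list(uniq))

    def fragment_intervals(self) -> set[tuple[str, int, int]]:
        return {(f.chrom, f.start, f.end) for f in self.fragments}


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return rng.choice(4, size=length, p=probs).astype(np.uint8)


def _codes_to_str(codes: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


def _place_nonoverlapping(rng: np.random.Generator, lengths: list[int],
                          span: int) -> list[int]:
    """Uniform random non-overlapping placement of blocks inside [0, span)."""
    total = sum(lengths)
    free = span - total
    if free < 0:
        raise ValueError("planted blocks do not fit in the chromosome")
    gaps = np.sort(rng.integers(0, free + 1, size=len(lengths)))
    starts, acc = [], 0
    for g, length in zip(gaps.tolist(), lengths):
        starts.append(g + acc)
        acc += length
    return starts


def make_genome(spec: SyntheticGenomeSpec
                ) -> tuple[GenomeSequence, FeatureSet, list[PlantedSite]]:
    """Deterministically build a genome with repeats, genes and planted sites."""
    rng = np.random.default_rng(spec.seed)
    sequences: dict[str, str] = {}
    masks: dict[str, np.ndarray] = {}
    feats: list[Feature] = []
    planted: list[PlantedSite] = []

    # distribute planted sites over chromosomes
    per_chrom_sites: list[list[tuple[str, str, int]]] = [
        [] for _ in range(spec.n_chromosomes)]
    for site in spec.planted_sites:
        per_chrom_sites[rng.integers(spec.n_chromosomes)].append(site)

    block_len = spec.repeat_unit_length * spec.repeat_copies
    for ci in range(spec.n_chromosomes):
        name = f"chr{ci + 1}"
        codes = _random_seq(rng, spec.chrom_length, spec.gc_content)
        mask = np.zeros(spec.chrom_length, dtype=bool)

        n_repeat_blocks = int(round(spec.repeat_fraction * spec.chrom_length
                                    / block_len)) if spec.repeat_fraction else 0
        items: list[tuple[str, object]] = [("repeat", None)] * n_repeat_blocks
        items += [("site", s) for s in per_chrom_sites[ci]]
        order = rng.permutation(len(items)) if items else []
        items = [items[i] for i in order]
        lengths = [block_len if kind == "repeat"
                   else len(s[0]) + s[2] + len(s[1])
                   for kind, s in items]
        starts = _place_nonoverlapping(rng, lengths, spec.chrom_length)

        for (kind, payload), start, length in zip(items, starts, lengths):
            if kind == "repeat":
                unit = _random_seq(rng, spec.repeat_unit_length, spec.gc_content)
                codes[start:start + length] = np.tile(unit, spec.repeat_copies)
                mask[start:start + length] = True
                feats.append(Feature(name, start, start + length, "repeat"))
            else:
                f_primer, r_primer, _ = payload
                f_codes = np.frombuffer(f_primer.encode(), np.uint8)
                r_codes = np.frombuffer(
                    reverse_complement(r_primer).encode(), np.uint8)
                from .kmer_census import _CODE
                codes[start:start + len(f_primer)] = _CODE[f_codes]
                end = start + length
                codes[end - len(r_primer):end] = _CODE[r_codes]
                planted.append(PlantedSite(name, start, end,
                                           f_primer, r_primer))

        if spec.gene_fraction > 0:
            target = spec.gene_fraction * spec.chrom_length
            gene_lengths, acc = [], 0.0
            while acc < target:
                glen = max(50, int(round(rng.normal(spec.mean_gene_length,
                                                    spec.mean_gene_length / 4))))
                gene_lengths.append(glen)
                acc += glen
            gstarts = _place_nonoverlapping(rng, gene_lengths,
                                            spec.chrom_length)
            for gs, gl in zip(gstarts, gene_lengths):
                strand = "+" if rng.random() < 0.5 else "-"
                feats.append(Feature(name, gs, gs + gl, "gene", strand))

        sequences[name] = _codes_to_str(codes)
        masks[name] = mask

    return GenomeSequence(sequences, masks), FeatureSet(feats), planted


# ---------------------------------------------------------------------------
# Protocol simulation
# ---------------------------------------------------------------------------

def _mutate_prefix(read: str, pos: int, rng: np.random.Generator) -> str:
    alternatives = [b for b in _BASES if b != read[pos]]
    return read[:pos] + alternatives[rng.integers(3)] + read[pos + 1:]


def simulate_kseq(genome: GenomeSequence, primer_set: PrimerSet,
                  sim_config: SimConfig | None = None,
                  seed: int = 0) -> SimulatedLibrary:
    """Run the in-silico protocol; returns fragments, reads and ground truth."""
    if sim_config is None:
        sim_config = SimConfig()
    cfg = sim_config
    rng = np.random.default_rng(seed)
    primers = primer_set.primers()
    roles = primer_set.roles()

    all_sites: list[BindingSite] = []
    for pid, seq in primers.items():
        all_sites.extend(find_binding_sites(genome, seq, pid, 0))

    # round-1 / round-2 priming success, decided once per genomic site
    survived = {id(s): (cfg.priming_success >= 1.0
                        or rng.random() < cfg.priming_success)
                for s in all_sites}

    by_chrom: dict[str, tuple[list[BindingSite], list[BindingSite]]] = {}
    for s in all_sites:
        plus, minus = by_chrom.setdefault(s.chrom, ([], []))
        (plus if s.strand == "+" else minus).append(s)

    fragments: list[SimulatedFragment] = []
    seen: set[tuple] = set()
    for chrom, (plus, minus) in sorted(by_chrom.items()):
        minus.sort(key=lambda s: s.start)
        m_starts = [s.start for s in minus]
        for left in sorted(plus, key=lambda s: s.start):
            if not survived[id(left)]:
                continue  # exonuclease destroys the unprimed template
            lo = bisect_left(m_starts, left.end)
            for right in minus[lo:]:
                if right.start - left.start > cfg.max_fragment_len:
                    break  # beyond Klenow extension reach
                span = right.end - left.start
                if not cfg.min_fragment_len <= span <= cfg.max_fragment_len:
                    continue
                if roles[left.primer_id] == roles[right.primer_id]:
                    continue  # F-F / R-R molecules carry one adapter; dropped
                if not survived[id(right)]:
                    continue
                f_is_left = roles[left.primer_id] == "forward"
                f_id = left.primer_id if f_is_left else right.primer_id
                r_id = right.primer_id if f_is_left else left.primer_id
                key = (chrom, left.start, right.end, f_id, r_id)
                if key in seen:
                    continue
                seen.add(key)

                f_mm = (int(rng.integers(len(primers[f_id])))
                        if cfg.p_mismatch and rng.random() < cfg.p_mismatch
                        else None)
                r_mm = (int(rng.integers(len(primers[r_id])))
                        if cfg.p_mismatch and rng.random() < cfg.p_mismatch
                        else None)
                ndup = (1 if cfg.pcr_mean_duplicates <= 1.0
                        else int(rng.geometric(1.0 / cfg.pcr_mean_duplicates)))
                fragments.append(SimulatedFragment(
                    chrom, left.start, right.end, f_id, r_id, f_is_left,
                    f_mm, r_mm, ndup))

    if cfg.size_selection:
        fragments = [f for f in fragments
                     if cfg.size_min <= f.end - f.start <= cfg.size_max]

    lib = SimulatedLibrary(fragments=fragments)
    for frag in fragments:
        frag_seq = genome.sequences[frag.chrom][frag.start:frag.end]
        if frag.f_is_left:
            r1, r2 = frag_seq, reverse_complement(frag_seq)
        else:
            r1, r2 = reverse_complement(frag_seq), frag_seq
        r1, r2 = r1[:cfg.read_length], r2[:cfg.read_length]
        if frag.f_mismatch_pos is not None:
            r1 = _mutate_prefix(r1, frag.f_mismatch_pos, rng)
        if frag.r_mismatch_pos is not None:
            r2 = _mutate_prefix(r2, frag.r_mismatch_pos, rng)
        base = (f"{frag.chrom}:{frag.start}-{frag.end}|{frag.f_id}|{frag.r_id}"
                f"|mmF={-1 if frag.f_mismatch_pos is None else frag.f_mismatch_pos}"
                f"|mmR={-1 if frag.r_mismatch_pos is None else frag.r_mismatch_pos}")
        for d in range(frag.n_duplicates):
            lib.read_pairs.append(ReadPair(f"{base}|d{d}", r1, r2))

    if not fragments:
        logger.warning("simulation produced no surviving fragments")
    return lib


def forward_end_sequences(library: SimulatedLibrary
                          ) -> tuple[list[str], list[tuple]]:
    """R1 sequences (one per fragment) and their priming-site keys.

    Ready to feed :func:`kseq.evaluation.end_mismatch_rate`.
    """
    ends, keys = [], []
    seen_names = set()
    for rp in library.read_pairs:
        frag_key = rp.name.rsplit("|d", 1)[0]
        if frag_key in seen_names:
            continue  # PCR duplicates share the priming event
        seen_names.add(frag_key)
        ends.append(rp.r1)
        keys.append(frag_key.split("|mmF")[0])
    return ends, keys
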