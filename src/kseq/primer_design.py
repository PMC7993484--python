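"""Candidate selection and primer-set assembly for Klenow priming.

The design recipe: keep k-mers with GC content between 35% and 75%
(inclusive, compared as exact rationals), rank by abundance in nonrepetitive
regions, take the top 1000, then greedily assemble 10-oligo sets whose
members are mutually compatible in a PCR.  Each set is split into forward
and reverse roles (the role decides which adapter tail an oligo carries;
only fragments primed by one of each are sequenceable).

Compatibility screening uses alignment-free contiguous complementarity runs
(cross-dimer, self-dimer, 3'-anchored run, hairpin stem) rather than a
thermodynamic model: for 8–9-mers run-length screening is deterministic and
dependency-free.  A custom scorer can be swapped in via the ``pair_check``
hook of :func:`build_primer_sets`.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .io_formats import write_tsv
from .kmer_census import KmerTable

_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def _is_pair(a: str, b: str) -> bool:
    return (a, b) in _PAIRS


@dataclass
class DesignConfig:
    """Tunable knobs of the selection/assembly step (defaults per protocol)."""

    gc_min: float = 0.35
    gc_max: float = 0.75
    top_n: int = 1000
    set_size: int = 10
    n_sets: int = 3
    forward_count: int = 5
    max_any_run: int = 5          # longest tolerated cross/self dimer run
    max_3prime_run: int = 3       # longest run anchored at a 3' terminus
    max_hairpin_stem: int = 3
    hairpin_loop_min: int = 3

    def __post_init__(self) -> None:
        if not 0 <= self.gc_min <= self.gc_max <= 1:
            raise ValueError("require 0 <= gc_min <= gc_max <= 1")
        if self.set_size < 2:
            raise ValueError("set_size must be >= 2")
        if not 1 <= self.forward_count < self.set_size:
            raise ValueError("require 1 <= forward_count < set_size")


@dataclass(frozen=True)
class PrimerCandidate:
    sequence: str
    nonrepetitive_count: int
    gc_fraction: float
    rank: int


@dataclass(frozen=True)
class ComplementarityScores:
    longest_any_run: int
    longest_3prime_run: int


@dataclass
class PrimerSet:
    """Forward/reverse oligo lists with their pairwise compatibility scores.

    Primer ids are F1..Fn / R1..Rm in rank order.
    """

    forward: list[str]
    reverse: list[str]
    scores: dict[tuple[str, str], ComplementarityScores] = field(default_factory=dict)
    hairpin_stems: dict[str, int] = field(default_factory=dict)
    compatible: bool = True

    def __post_init__(self) -> None:
        seqs = self.forward + self.reverse
        if len(set(seqs)) != len(seqs):
            raise ValueError("duplicate oligo sequences within a primer set")

    def primers(self) -> dict[str, str]:
        out = {f"F{i + 1}": s for i, s in enumerate(self.forward)}
        out.update({f"R{i + 1}": s for i, s in enumerate(self.reverse)})
        return out

    def roles(self) -> dict[str, str]:
        return {pid: ("forward" if pid.startswith("F") else "reverse")
                for pid in self.primers()}

    def to_tsv(self, path, config=None) -> None:
        rows = [(pid, role, self.primers()[pid])
                for pid, role in self.roles().items()]
        write_tsv(pd.DataFrame(rows, columns=["id", "role", "sequence"]),
                  path, config)

    @classmethod
    def from_tsv(cls, path) -> "PrimerSet":
        df = pd.read_csv(path, sep="\t", comment="#")
        fwd = df.loc[df.role == "forward", "sequence"].tolist()
        rev = df.loc[df.role == "reverse", "sequence"].tolist()
        return cls(fwd, rev)


def _exact_fraction(x: float) -> Fraction:
    # str() round-trips the decimal the user wrote (0.35 -> 7/20 exactly)
    return Fraction(str(x))


def select_candidates(table: KmerTable,
                      config: DesignConfig | None = None) -> list[PrimerCandidate]:
    """GC-filter and rank the k-mer table; return the top candidates.

    Ordered by nonrepetitive abundance descending, ties broken
    lexicographically (deterministic across runs).  GC bounds are inclusive
    and compared as exact rationals, so for k=8 the 35–75% window admits
    3–6 G/C bases.
    """
    if config is None:
        config = DesignConfig()
    if len(table) == 0:
        raise ValueError("empty k-mer table")
    gc_lo, gc_hi = _exact_fraction(config.gc_min), _exact_fraction(config.gc_max)
    k = table.k
    passing = []
    gc_hist: Counter[int] = Counter()
    for row in table.df.itertuples(index=False):
        gc_count = row.kmer.count("G") + row.kmer.count("C")
        gc_hist[gc_count] += 1
        if gc_lo <= Fraction(gc_count, k) <= gc_hi:
            passing.append((row.kmer, int(row.nonrepetitive_count),
                            float(row.gc_fraction)))
    if not passing:
        raise ValueError(
            "no k-mer passes the GC filter; GC-count histogram: "
            + ", ".join(f"{g}/{k}: {n}" for g, n in sorted(gc_hist.items()))
        )
    passing.sort(key=lambda t: (-t[1], t[0]))
    return [PrimerCandidate(seq, count, gc, rank)
            for rank, (seq, count, gc) in
            enumerate(passing[:config.top_n], start=1)]


def complementarity_checks(oligo_a: str, oligo_b: str) -> ComplementarityScores:
    """Longest contiguous Watson–Crick run between *a* and reverse(*b*).

    Slides reverse(b) across a over every offset.  The 3'-anchored score is
    the longest run that includes the 3'-terminal base of either oligo.
    Self-dimer: call with ``a == b``.
    """
    for o in (oligo_a, oligo_b):
        if len(o) < 4 or set(o) - set("ACGT"):
            raise ValueError(f"oligo must be ACGT of length >= 4, got {o!r}")
    a, br = oligo_a, oligo_b[::-1]
    la, lb = len(a), len(br)
    best = best3 = 0
    for offset in range(-(lb - 1), la):
        i0, i1 = max(0, offset), min(la, offset + lb)
        run_start = None
        i = i0
        while i <= i1:
            paired = i < i1 and _is_pair(a[i], br[i - offset])
            if paired and run_start is None:
                run_start = i
            if not paired and run_start is not None:
                length = i - run_start
                best = max(best, length)
                # run touches a's 3' end (i == la) or b's 3' end (br index 0)
                if i == la or run_start - offset == 0:
                    best3 = max(best3, length)
                run_start = None
            i += 1
    return ComplementarityScores(best, best3)


def hairpin_stem(oligo: str, loop_min: int = 3) -> int:
    """Longest self-folding stem with an unpaired loop of >= *loop_min* bases."""
    n = len(oligo)
    best = 0
    for i in range(n):
        for j in range(n - 1, i, -1):
            s = 0
            while (i + s < j - s and _is_pair(oligo[i + s], oligo[j - s])
                   and (j - s) - (i + s) - 1 >= loop_min):
                s += 1
            best = max(best, s)
    return best


def _pair_ok(a: str, b: str, config: DesignConfig) -> tuple[bool, str]:
    sc = complementarity_checks(a, b)
    if sc.longest_any_run > config.max_any_run:
        return False, "any_run"
    if sc.longest_3prime_run > config.max_3prime_run:
        return False, "3prime_run"
    return True, ""


def _self_ok(a: str, config: DesignConfig) -> tuple[bool, str]:
    ok, why = _pair_ok(a, a, config)
    if not ok:
        return False, "self_" + why
    if hairpin_stem(a, config.hairpin_loop_min) > config.max_hairpin_stem:
        return False, "hairpin"
    return True, ""


def build_primer_sets(candidates: Sequence[PrimerCandidate],
                      config: DesignConfig | None = None,
                      seed: int | None = None,
                      pair_check: Callable[[str, str, DesignConfig],
                                           tuple[bool, str]] | None = None,
                      ) -> list[PrimerSet]:
    """Greedily assemble up to ``n_sets`` mutually compatible, disjoint sets.

    Oligos are taken in rank order (or seed-shuffled order when *seed* is
    given); one joins the growing set only if its self checks and all
    pairwise checks against current members pass.  Once a set reaches
    ``set_size``, the first ``forward_count`` members by rank become forward
    primers, the rest reverse.
    """
    if config is None:
        config = DesignConfig()
    if pair_check is None:
        pair_check = _pair_ok
    if len(candidates) < config.set_size:
        raise ValueError(
            f"need >= {config.set_size} candidates, got {len(candidates)}")
    pool = sorted(candidates, key=lambda c: c.rank)
    if seed is not None:
        rng = np.random.default_rng(seed)
        pool = [pool[i] for i in rng.permutation(len(pool))]

    fail_counts: Counter[str] = Counter()
    sets: list[PrimerSet] = []
    remaining = list(pool)
    while len(sets) < config.n_sets:
        members: list[PrimerCandidate] = []
        used: set[str] = set()
        for cand in remaining:
            ok, why = _self_ok(cand.sequence, config)
            if not ok:
                fail_counts[why] += 1
                continue
            verdicts = [pair_check(cand.sequence, m.sequence, config)
                        for m in members]
            if all(v[0] for v in verdicts):
                members.append(cand)
                used.add(cand.sequence)
                if len(members) == config.set_size:
                    break
            else:
                fail_counts[next(v[1] for v in verdicts if not v[0])] += 1
        if len(members) < config.set_size:
            break
        members.sort(key=lambda c: c.rank)
        fwd = [c.sequence for c in members[:config.forward_count]]
        rev = [c.sequence for c in members[config.forward_count:]]
        pset = PrimerSet(fwd, rev)
        verify_set(pset, config)  # fills scores + verdict
        sets.append(pset)
        remaining = [c for c in remaining if c.sequence not in used]
    if not sets:
        worst = fail_counts.most_common(1)
        detail = f"; most frequent failing check: {worst[0][0]}" if worst else ""
        raise ValueError("could not assemble any compatible primer set" + detail)
    return sets


def verify_set(primer_set: PrimerSet,
               config: DesignConfig | None = None) -> bool:
    """Recompute all self/cross checks; store scores and return the verdict."""
    if config is None:
        config = DesignConfig()
    primers = primer_set.primers()
    ids = list(primers)
    scores: dict[tuple[str, str], ComplementarityScores] = {}
    hairpins: dict[str, int] = {}
    ok = True
    for idx, pa in enumerate(ids):
        hairpins[pa] = hairpin_stem(primers[pa], config.hairpin_loop_min)
        if hairpins[pa] > config.max_hairpin_stem:
            ok = False
        for pb in ids[idx:]:
            sc = complementarity_checks(primers[pa], primers[pb])
            scores[(pa, pb)] = sc
            if (sc.longest_any_run > config.max_any_run
                    or sc.longest_3prime_run > config.max_3prime_run):
                ok = False
    primer_set.scores = scores
    primer_set.hairpin_stems = hairpins
    primer_set.compatible = ok
    return ok


def candidates_to_tsv(candidates: Sequence[PrimerCandidate], path,
                      config=None) -> None:
    df = pd.DataFrame(
        [(c.rank, c.sequence, c.nonrepetitive_count, c.gc_fraction)
         for c in candidates],
        columns=["rank", "sequence", "nonrepetitive_count", "gc_fraction"])
    write_tsv(df, path, config)
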