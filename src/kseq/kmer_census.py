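"""Genome-wide k-mer census.

Counts every ACGT-only window of length k once per position.  Windows
containing N are excluded entirely; windows overlapping any masked base are
excluded from the nonrepetitive count (a window must be *fully* unmasked to
count as nonrepetitive).  In ``both`` strand mode each k-mer's count also
includes the occurrences of its reverse complement, because an oligo this
short anneals to either strand; k-mers are never canonicalized — a k-mer and
its reverse complement remain distinct table entries since primers are
synthesized as written.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GenomeSequence, write_tsv

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Map bases to codes 0..3; anything else (N) becomes 4."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _decode(code: int, k: int) -> str:
    out = bytearray(k)
    for i in range(k - 1, -1, -1):
        out[i] = _BASES[code & 3]
        code >>= 2
    return out.decode("ascii")


def _rc_code(code: int, k: int) -> int:
    rc = 0
    for _ in range(k):
        rc = (rc << 2) | (3 - (code & 3))
        code >>= 2
    return rc


def gc_fraction(kmer: str) -> float:
    """Exact (#G + #C) / len for an ACGT-only oligo."""
    if not kmer or set(kmer) - set("ACGT"):
        raise ValueError(f"gc_fraction requires a non-empty ACGT string, got {kmer!r}")
    return (kmer.count("G") + kmer.count("C")) / len(kmer)


@dataclass
class KmerTable:
    """Per-k-mer occurrence counts for a fixed k.

    ``df`` columns: kmer, total_count, nonrepetitive_count, gc_fraction —
    sorted by nonrepetitive_count descending, then lexicographically.
    """

    k: int
    df: pd.DataFrame

    def __len__(self) -> int:
        return len(self.df)

    def counts(self) -> dict[str, tuple[int, int]]:
        return {
            row.kmer: (int(row.total_count), int(row.nonrepetitive_count))
            for row in self.df.itertuples(index=False)
        }

    def to_tsv(self, path, config=None) -> None:
        write_tsv(self.df, path, config)

    @classmethod
    def from_tsv(cls, path) -> "KmerTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        if len(df) == 0:
            raise ValueError("empty k-mer table")
        return cls(len(df.iloc[0].kmer), df)


def _rolling_nonzero(flags: np.ndarray, k: int) -> np.ndarray:
    """True where the length-k window starting at i contains any set flag."""
    csum = np.concatenate(([0], np.cumsum(flags, dtype=np.int64)))
    return (csum[k:] - csum[:-k]) > 0


def count_kmers(genome: GenomeSequence, k: int,
                count_strands: str = "both") -> KmerTable:
    """Census all length-k windows of the genome.

    Parameters
    ----------
    count_strands:
        ``plus_only`` counts each plus-strand window once; ``both`` adds each
        k-mer's reverse-complement occurrences (mask is strand-agnostic).
    """
    if not 4 <= k <= 16:
        raise ValueError(f"k must be in [4, 16], got {k}")
    if count_strands not in ("plus_only", "both"):
        raise ValueError(f"unknown strand mode {count_strands!r}")

    totals: dict[int, int] = {}
    nonrep: dict[int, int] = {}
    for name, seq in genome.sequences.items():
        n = len(seq)
        if n < k:
            continue
        codes = encode(seq)
        w = n - k + 1
        acc = np.zeros(w, dtype=np.int64)
        for j in range(k):
            acc = (acc << 2) | codes[j:j + w]
        has_n = _rolling_nonzero(codes == 4, k)
        has_mask = _rolling_nonzero(genome.masks[name].astype(np.int8), k)
        valid = ~has_n
        for target, sel in ((totals, valid), (nonrep, valid & ~has_mask)):
            codes_u, counts_u = np.unique(acc[sel], return_counts=True)
            for c, cnt in zip(codes_u.tolist(), counts_u.tolist()):
                target[c] = target.get(c, 0) + cnt

    if count_strands == "both":
        keys = set(totals)
        both_tot, both_nr = {}, {}
        for code in keys:
            rc = _rc_code(code, k)
            both_tot[code] = totals[code] + totals.get(rc, 0)
            both_nr[code] = nonrep.get(code, 0) + nonrep.get(rc, 0)
            if rc not in keys:  # rc k-mer observed only via this orientation
                both_tot[rc] = both_tot[code]
                both_nr[rc] = both_nr[code]
        totals, nonrep = both_tot, both_nr

    rows = []
    for code, tot in totals.items():
        kmer = _decode(code, k)
        rows.append((kmer, tot, nonrep.get(code, 0), gc_fraction(kmer)))
    df = pd.DataFrame(rows, columns=["kmer", "total_count",
                                     "nonrepetitive_count", "gc_fraction"])
    df = df.sort_values(["nonrepetitive_count", "kmer"],
                        ascending=[False, True], ignore_index=True)
    return KmerTable(k, df)
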