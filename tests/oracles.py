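"""Independent brute-force reference implementations used only by tests.

Each oracle takes a deliberately different route from the package code:
pattern enumeration + regex scans instead of vectorized mismatch counting,
per-base boolean arrays instead of interval arithmetic, pure-Python prefix
sums instead of numpy slicing.
"""

import itertools
import re
from collections import defaultdict
from itertools import accumulate

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq):
    return "".join(COMP[c] for c in reversed(seq))


def is_pair(a, b):
    return COMP.get(a) == b and a != "N"


# -- k-mer census ------------------------------------------------------------

def naive_kmer_scan(genome, k, strand_mode="plus_only"):
    """Position-by-position scan; returns (totals, nonrepetitive) dicts."""
    totals, nonrep = defaultdict(int), defaultdict(int)
    for name, seq in genome.sequences.items():
        mask = [bool(x) for x in genome.masks[name]]
        views = [(seq, mask)]
        if strand_mode == "both":
            views.append((rc(seq), mask[::-1]))
        for s, m in views:
            prefix = [0] + list(accumulate(int(x) for x in m))
            for i in range(len(s) - k + 1):
                w = s[i:i + k]
                if "N" in w:
                    continue
                totals[w] += 1
                if prefix[i + k] - prefix[i] == 0:
                    nonrep[w] += 1
    return dict(totals), dict(nonrep)


# -- complementarity ---------------------------------------------------------

def brute_complementarity(a, b):
    """All-offsets, all-runs enumeration of complementary runs of a vs rev(b)."""
    br = b[::-1]
    la, lb = len(a), len(br)
    best = best3 = 0
    for offset in range(-(lb - 1), la):
        for start in range(max(0, offset), min(la, offset + lb)):
            for end in range(start + 1, min(la, offset + lb) + 1):
                if all(is_pair(a[i], br[i - offset]) for i in range(start, end)):
                    length = end - start
                    best = max(best, length)
                    if end == la or start - offset == 0:
                        best3 = max(best3, length)
    return best, best3


def brute_hairpin(a, loop_min=3):
    n = len(a)
    best = 0
    for i in range(n):
        for j in range(i + 1, n):
            for s in range(1, n):
                pairs_ok = all(i + t < j - t and is_pair(a[i + t], a[j - t])
                               for t in range(s))
                loop_ok = (j - (s - 1)) - (i + (s - 1)) - 1 >= loop_min
                if pairs_ok and loop_ok:
                    best = max(best, s)
    return best


# -- binding sites / products ------------------------------------------------

def hamming_variants(primer, max_mm):
    """Every ACGT string within Hamming distance max_mm of the primer."""
    out = {primer}
    for r in range(1, max_mm + 1):
        for positions in itertools.combinations(range(len(primer)), r):
            for subs in itertools.product("ACGT", repeat=r):
                if any(primer[p] == s for p, s in zip(positions, subs)):
                    continue
                v = list(primer)
                for p, s in zip(positions, subs):
                    v[p] = s
                out.add("".join(v))
    return out


def regex_binding_sites(genome, primer, primer_id, max_mm,
                        allow_3prime_mismatch=True):
    """Locate sites by exact regex search for every Hamming-ball variant."""
    sites = set()
    L = len(primer)
    for chrom, seq in genome.sequences.items():
        for strand, oriented in (("+", primer), ("-", rc(primer))):
            for var in hamming_variants(oriented, max_mm):
                for m in re.finditer(f"(?={re.escape(var)})", seq):
                    pos = m.start()
                    window = seq[pos:pos + L]
                    if window != var:
                        continue  # same position found via another variant
                    in_primer = window if strand == "+" else rc(window)
                    mm_pos = tuple(i for i in range(L)
                                   if in_primer[i] != primer[i])
                    if not allow_3prime_mismatch and (L - 1) in mm_pos:
                        continue
                    sites.add((chrom, pos, strand, primer_id,
                               len(mm_pos), mm_pos))
    return sites


def brute_products(sites, roles, min_len, max_len):
    """All-pairs convergent pairing with explicit role/size checks."""
    by_chrom = defaultdict(lambda: ([], []))
    for s in sites:
        plus, minus = by_chrom[s.chrom]
        (plus if s.strand == "+" else minus).append(s)
    out = set()
    for chrom, (plus, minus) in by_chrom.items():
        for left in plus:
            for right in minus:
                if left.start + left.length > right.start:
                    continue
                span = right.start + right.length - left.start
                if not min_len <= span <= max_len:
                    continue
                if roles[left.primer_id] == roles[right.primer_id]:
                    continue
                out.add((chrom, left.start, right.start + right.length,
                         left.primer_id, right.primer_id))
    return out


def masked_count_prefix(genome):
    """Pure-Python per-chromosome prefix sums of the repeat mask."""
    return {name: [0] + list(accumulate(int(x) for x in mask))
            for name, mask in genome.masks.items()}


# -- interval statistics -----------------------------------------------------

def bitvector_fractions(observed, predicted, chrom_lengths):
    """Per-base boolean-array overlap fractions between two region sets."""
    import numpy as np

    obs = {c: np.zeros(n, bool) for c, n in chrom_lengths.items()}
    pred = {c: np.zeros(n, bool) for c, n in chrom_lengths.items()}
    for chrom, start, end in observed:
        obs[chrom][start:end] = True
    for chrom, start, end in predicted:
        pred[chrom][start:end] = True
    n_obs = sum(int(a.sum()) for a in obs.values())
    n_pred = sum(int(a.sum()) for a in pred.values())
    inter = sum(int((obs[c] & pred[c]).sum()) for c in chrom_lengths)
    return (inter / n_obs if n_obs else 0.0,
            inter / n_pred if n_pred else 0.0)
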