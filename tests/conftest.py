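import numpy as np
import pytest

from kseq import GenomeSequence, PrimerSet


def random_genome(seed, length=10_000, n_chrom=1, n_frac=0.0,
                  mask_frac=0.0, block=200):
    """Random ACGT(N) genome with optional random repeat-mask blocks."""
    rng = np.random.default_rng(seed)
    seqs, masks = {}, {}
    alphabet = np.array(list("ACGT"))
    for c in range(n_chrom):
        chars = alphabet[rng.integers(0, 4, size=length)]
        if n_frac:
            chars[rng.random(length) < n_frac] = "N"
        mask = np.zeros(length, bool)
        if mask_frac:
            for _ in range(max(1, int(mask_frac * length / block))):
                s = int(rng.integers(0, max(1, length - block)))
                mask[s:s + block] = True
        seqs[f"chr{c + 1}"] = "".join(chars)
        masks[f"chr{c + 1}"] = mask
    return GenomeSequence(seqs, masks)


def primers_from_genome(genome, seed, n_primers=10, k=8):
    """Sample distinct k-mers that occur in the genome; alternate F/R roles."""
    rng = np.random.default_rng(seed)
    chroms = list(genome.sequences)
    chosen: list[str] = []
    while len(chosen) < n_primers:
        chrom = chroms[rng.integers(len(chroms))]
        seq = genome.sequences[chrom]
        pos = int(rng.integers(0, len(seq) - k))
        kmer = seq[pos:pos + k]
        if "N" in kmer or kmer in chosen:
            continue
        chosen.append(kmer)
    half = n_primers // 2
    return PrimerSet(chosen[:half], chosen[half:])


@pytest.fixture
def toy_genome():
    return random_genome(seed=11, length=5_000, mask_frac=0.1, n_frac=0.002)
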