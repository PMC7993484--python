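"""Genome, annotation and region I/O.

All coordinates are 0-based half-open internally.  GFF3 input (1-based,
inclusive) is converted on ingest; BED is taken as-is.  Chromosome names are
matched by exact string equality.

A genome carries a per-base boolean *repeat mask*: a base is masked if it was
soft-masked (lower-case) in the source FASTA or is covered by a repeat-type
annotation feature.  "Nonrepetitive" everywhere in this package means a window
containing zero masked bases.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from intervaltree import IntervalTree

logger = logging.getLogger("kseq")

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

@dataclass
class GenomeSequence:
    """Named chromosomes (upper-case A/C/G/T/N) with per-base repeat masks."""

    sequences: dict[str, str]
    masks: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if set(self.sequences) != set(self.masks):
            raise ValueError("sequences and masks must cover the same chromosomes")
        for name, seq in self.sequences.items():
            if len(self.masks[name]) != len(seq):
                raise ValueError(f"mask length != sequence length for {name!r}")

    @property
    def names(self) -> list[str]:
        return list(self.sequences)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def chrom_length(self, name: str) -> int:
        return len(self.sequences[name])

    def masked_bases(self) -> int:
        return int(sum(m.sum() for m in self.masks.values()))


def read_fasta(path, mask_softmasked: bool = True) -> GenomeSequence:
    """Read a (possibly soft-masked) FASTA file into a :class:`GenomeSequence`.

    Lower-case source bases set the repeat mask when *mask_softmasked* is on.
    Duplicate record names and non-ACGTN characters are errors.
    """
    sequences: dict[str, str] = {}
    masks: dict[str, np.ndarray] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"duplicate FASTA record name: {record.id!r}")
        raw = str(record.seq)
        arr = np.frombuffer(raw.encode("ascii"), dtype=np.uint8)
        lower = (arr >= ord("a")) & (arr <= ord("z"))
        seq = raw.upper()
        bad = set(seq) - VALID_BASES
        if bad:
            pos = next(i for i, c in enumerate(seq) if c in bad)
            raise ValueError(
                f"invalid base {seq[pos]!r} at {record.id}:{pos} (0-based)"
            )
        sequences[record.id] = seq
        masks[record.id] = lower if mask_softmasked else np.zeros(len(seq), bool)
    return GenomeSequence(sequences, masks)


def write_fasta(genome: GenomeSequence, path, soft_mask: bool = True,
                width: int = 70) -> None:
    """Write a genome to FASTA, lower-casing masked bases when *soft_mask*."""
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            if soft_mask:
                chars = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
                mask = genome.masks[name]
                chars[mask] += ord("a") - ord("A")
                seq = chars.tobytes().decode("ascii")
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Features (genes / repeats) and plain regions
# ---------------------------------------------------------------------------

#: GFF3 feature types mapped onto the three classes the tool cares about.
DEFAULT_TYPE_MAP = {
    "gene": "gene",
    "mRNA": "gene",
    "repeat_region": "repeat",
    "dispersed_repeat": "repeat",
    "tandem_repeat": "repeat",
}


@dataclass(frozen=True)
class Feature:
    chrom: str
    start: int  # 0-based
    end: int    # half-open
    ftype: str  # gene | repeat | other
    strand: str = "."


@dataclass
class FeatureSet:
    """Annotation intervals classed as gene / repeat / other."""

    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        for f in self.features:
            if f.start >= f.end:
                raise ValueError(f"empty/inverted interval {f}")

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self) -> Iterator[Feature]:
        return iter(self.features)

    def by_type(self, ftype: str) -> list[Feature]:
        """Coordinate-sorted view of one feature class."""
        sel = [f for f in self.features if f.ftype == ftype]
        return sorted(sel, key=lambda f: (f.chrom, f.start, f.end))


def read_features(path, dialect: str, type_map: dict[str, str] | None = None,
                  genome: GenomeSequence | None = None) -> FeatureSet:
    """Read GFF3 or BED annotation into a :class:`FeatureSet`.

    GFF3 coordinates are converted to 0-based half-open.  Feature types are
    mapped to gene/repeat/other through *type_map* (default
    :data:`DEFAULT_TYPE_MAP`).  When a *genome* is given, features on unknown
    chromosomes are skipped with a logged warning.
    """
    if type_map is None:
        type_map = DEFAULT_TYPE_MAP
    feats: list[Feature] = []
    skipped = 0
    if dialect == "gff3":
        import gffutils

        db = gffutils.create_db(str(path), ":memory:", keep_order=True,
                                merge_strategy="create_unique")
        for f in db.all_features():
            start, end = f.start - 1, f.end  # 1-based inclusive -> half-open
            if start >= end:
                raise ValueError(f"empty interval after conversion: {f}")
            if genome is not None and f.seqid not in genome.sequences:
                skipped += 1
                continue
            ftype = type_map.get(f.featuretype, "other")
            feats.append(Feature(f.seqid, start, end, ftype, f.strand or "."))
    elif dialect == "bed":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         dtype={0: str})
        for row in df.itertuples(index=False):
            chrom, start, end = str(row[0]), int(row[1]), int(row[2])
            if start >= end:
                raise ValueError(f"empty interval in BED: {chrom}:{start}-{end}")
            if genome is not None and chrom not in genome.sequences:
                skipped += 1
                continue
            name = str(row[3]) if len(row) > 3 else "repeat"
            ftype = type_map.get(name, "repeat")
            strand = str(row[5]) if len(row) > 5 else "."
            feats.append(Feature(chrom, start, end, ftype, strand))
    else:
        raise ValueError(f"unknown dialect {dialect!r} (expected gff3 or bed)")
    if skipped:
        logger.warning("skipped %d features on unknown chromosomes", skipped)
    return FeatureSet(feats)


def apply_repeat_features(genome: GenomeSequence,
                          features: FeatureSet) -> GenomeSequence:
    """Union repeat-type features into the genome's repeat mask."""
    masks = {name: mask.copy() for name, mask in genome.masks.items()}
    skipped = 0
    for f in features.by_type("repeat"):
        if f.chrom not in masks:
            skipped += 1
            continue
        masks[f.chrom][f.start:min(f.end, len(masks[f.chrom]))] = True
    if skipped:
        logger.warning("skipped %d repeat features on unknown chromosomes",
                       skipped)
    return GenomeSequence(genome.sequences, masks)


@dataclass
class RegionSet:
    """Plain intervals with optional scores (observed regions, predictions)."""

    regions: list[tuple[str, int, int]] = field(default_factory=list)
    scores: list[float] | None = None

    def __post_init__(self) -> None:
        for chrom, start, end in self.regions:
            if start >= end:
                raise ValueError(f"empty interval {chrom}:{start}-{end}")

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def sorted(self) -> "RegionSet":
        return RegionSet(sorted(self.regions))

    def merged(self) -> "RegionSet":
        """Merge overlapping/abutting intervals; covered base set unchanged."""
        trees: dict[str, IntervalTree] = {}
        for chrom, start, end in self.regions:
            trees.setdefault(chrom, IntervalTree())[start:end] = None
        out = []
        for chrom, tree in trees.items():
            tree.merge_overlaps(strict=False)
            out.extend((chrom, iv.begin, iv.end) for iv in tree)
        return RegionSet(sorted(out))

    def total_bases(self) -> int:
        return sum(e - s for _, s, e in self.merged().regions)

    def trees(self) -> dict[str, IntervalTree]:
        trees: dict[str, IntervalTree] = {}
        for chrom, start, end in self.merged().regions:
            trees.setdefault(chrom, IntervalTree())[start:end] = None
        return trees

    def intersect_bases(self, other: "RegionSet") -> int:
        """Number of bases covered by both sets (computed on merged sets)."""
        trees = other.trees()
        total = 0
        for chrom, start, end in self.merged().regions:
            tree = trees.get(chrom)
            if tree is None:
                continue
            for iv in tree.overlap(start, end):
                total += min(end, iv.end) - max(start, iv.begin)
        return total


def read_bed(path) -> RegionSet:
    regions, scores = [], []
    have_scores = False
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            regions.append((cols[0], int(cols[1]), int(cols[2])))
            if len(cols) > 4:
                scores.append(float(cols[4]))
                have_scores = True
            else:
                scores.append(0.0)
    return RegionSet(regions, scores if have_scores else None)


def write_bed(regions: RegionSet, path) -> None:
    """Write BED3 (or BED5 when scores are present); round-trip safe."""
    with open(path, "w") as fh:
        for i, (chrom, start, end) in enumerate(regions.regions):
            if regions.scores is not None:
                fh.write(f"{chrom}\t{start}\t{end}\t.\t{regions.scores[i]:g}\n")
            else:
                fh.write(f"{chrom}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# Reads and reports
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReadPair:
    name: str
    r1: str
    r2: str


def write_fastq(read_pairs: Sequence[ReadPair], path_r1, path_r2,
                quality_char: str = "I") -> None:
    """Write paired reads as two 4-line-per-record FASTQ files."""
    with open(path_r1, "w") as f1, open(path_r2, "w") as f2:
        for rp in read_pairs:
            f1.write(f"@{rp.name}/1\n{rp.r1}\n+\n{quality_char * len(rp.r1)}\n")
            f2.write(f"@{rp.name}/2\n{rp.r2}\n+\n{quality_char * len(rp.r2)}\n")


def config_hash(config) -> str:
    """Short stable hash of a config object's public fields."""
    items = sorted(vars(config).items()) if hasattr(config, "__dict__") else \
        sorted(config.items())
    blob = repr(items).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_tsv(report: pd.DataFrame, path, config=None) -> None:
    """Write a TSV report with a commented provenance header line."""
    from . import __version__

    with open(path, "w") as fh:
        chash = config_hash(config) if config is not None else "none"
        fh.write(f"# kseq v{__version__} config_hash={chash}\n")
        report.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
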