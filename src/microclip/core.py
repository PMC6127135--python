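"""Core genomic domain types shared across the pipeline.

Coordinates are 0-based half-open everywhere; the only 1-based positions in
the package are miRNA positions (seed = positions 2-8), which is the standard
nomenclature of the miRNA-targeting field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Tuple

COMPLEMENT = str.maketrans("ACGTUacgtu", "TGCAAtgcaa")

STRANDS = ("+", "-")


def revcomp(seq: str) -> str:
    """Reverse complement in DNA alphabet (U treated as T)."""
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class AlignedRead:
    """A primary mapped read with its reference-orientation substitutions.

    ``substitutions`` holds ``(offset, ref_base, alt_base)`` triples, with
    offsets relative to ``interval.start`` and bases in reference-forward
    orientation (a sense-strand T>C conversion on a minus-strand feature
    therefore appears here as A>G).
    """

    read_id: str
    interval: GenomicInterval
    query_sequence: str
    substitutions: list = field(default_factory=list)

    def __post_init__(self):
        n = self.interval.length()
        for off, ref, alt in self.substitutions:
            if not 0 <= off < n:
                raise ValueError(f"substitution offset {off} outside read span")
            if ref == alt:
                raise ValueError("substitution ref_base == alt_base")


@dataclass
class TranscriptModel:
    gene_id: str
    transcript_id: str
    exons: list  # list[GenomicInterval], sorted, non-overlapping
    cds: list = field(default_factory=list)
    utr3: list = field(default_factory=list)

    def __post_init__(self):
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript with zero exons")
        self.exons = sorted(self.exons, key=lambda iv: iv.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        chroms = {iv.chrom for iv in self.exons}
        strands = {iv.strand for iv in self.exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError(f"{self.transcript_id}: mixed chrom/strand")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    def utr3_length(self) -> int:
        return sum(iv.length() for iv in self.utr3)


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA. ``sequence`` is stored T-normalized for genome
    matching; ``seed`` is positions 2-8 (1-based, inclusive)."""

    name: str
    sequence: str

    def __post_init__(self):
        seq = self.sequence.upper().replace("U", "T")
        object.__setattr__(self, "sequence", seq)
        if not 16 <= len(seq) <= 28:
            raise ValueError(
                f"{self.name}: mature miRNA length {len(seq)} outside [16, 28]"
            )
        if set(seq) - set("ACGT"):
            raise ValueError(f"{self.name}: non-ACGU characters in sequence")

    @property
    def seed(self) -> str:
        return self.sequence[1:8]

    def __len__(self) -> int:
        return len(self.sequence)


class ConservationTrack:
    """Per-base conservation scores in [0, 1], e.g. phastCons.

    Backed either by an in-memory mapping ``{(chrom, pos0): score}`` or a
    bigWig file (via pyBigWig). ``score`` returns None for missing values.
    """

    def __init__(self, mapping: Optional[Mapping[Tuple[str, int], float]] = None):
        self._map = dict(mapping or {})
        for v in self._map.values():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"conservation score {v} outside [0, 1]")

    def score(self, chrom: str, pos: int) -> Optional[float]:
        return self._map.get((chrom, pos))

    def mean(self, interval: GenomicInterval) -> Tuple[float, float]:
        """Mean score over the interval and the fraction of missing bases.

        Missing bases are imputed as 0 in the mean.
        """
        vals = [self.score(interval.chrom, p) for p in range(interval.start, interval.end)]
        present = [v for v in vals if v is not None]
        n = len(vals)
        missing_frac = 1.0 - len(present) / n if n else 1.0
        mean = sum(present) / n if n else 0.0
        return mean, missing_frac


class BigWigConservationTrack(ConservationTrack):
    """bigWig-backed conservation accessor (requires pyBigWig)."""

    def __init__(self, path: str):
        import pyBigWig  # deferred: optional dependency

        self._bw = pyBigWig.open(path)
        self._map = {}

    def score(self, chrom: str, pos: int) -> Optional[float]:
        if chrom not in self._bw.chroms():
            return None
        v = self._bw.values(chrom, pos, pos + 1)[0]
        import math

        if v is None or math.isnan(v):
            return None
        return min(1.0, max(0.0, v))


@dataclass
class LibraryStats:
    """Mapped-read totals used as RPKM denominators."""

    per_chrom: dict = field(default_factory=dict)

    @property
    def total_mapped_reads(self) -> int:
        return sum(self.per_chrom.values())


def merge_intervals(ivs: Iterable[GenomicInterval]) -> list:
    """Merge overlapping/adjacent same-strand intervals (chrom+strand aware)."""
    out: list = []
    for iv in sorted(ivs, key=lambda i: (i.chrom, i.strand, i.start, i.end)):
        if (
            out
            and out[-1].chrom == iv.chrom
            and out[-1].strand == iv.strand
            and iv.start <= out[-1].end
        ):
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end, iv.strand)
        else:
            out.append(iv)
    return out
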