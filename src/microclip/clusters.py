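"""AGO-enriched cluster calling and T-to-C classification.

Clusters are maximal read-coverage islands called per (chrom, strand);
a cluster is a T-to-C cluster when at least one sense-strand T position has
>= ``ratio_threshold`` (default 20%) of its covering reads carrying the
T>C transition, supported by >= ``min_conversion_reads`` converted reads.
On minus-strand clusters the sense T>C transition appears as A>G in
reference orientation, which is the 4SU chemistry on the transcribed strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
from intervaltree import IntervalTree

from .core import AlignedRead, GenomicInterval, LibraryStats

T2C = "T2C"
NON_T2C = "NON_T2C"

DEFAULT_RATIO_THRESHOLD = 0.20
DEFAULT_MIN_CONVERSION_READS = 2
DEFAULT_MIN_READS = 5
DEFAULT_MAX_GAP = 0


@dataclass
class Cluster:
    interval: GenomicInterval
    read_count: int
    coverage: np.ndarray
    sub_counts: List[Dict[Tuple[str, str], int]]
    t2c_ratio: float = 0.0
    t2c_class: str = NON_T2C
    rpkm: float = 0.0
    background_overlap: bool = False
    reads: list = field(default_factory=list, repr=False)

    def __post_init__(self):
        if len(self.coverage) != self.interval.length():
            raise ValueError("coverage length != interval length")


def pileup(reads: Iterable[AlignedRead], region: GenomicInterval):
    """Per-base coverage vector and substitution counts over ``region``.

    Returns ``(coverage, sub_counts)`` where ``sub_counts[i]`` maps
    ``(ref, alt)`` to the number of reads substituting at base ``i``.
    """
    n = region.length()
    coverage = np.zeros(n, dtype=int)
    sub_counts: List[Dict[Tuple[str, str], int]] = [dict() for _ in range(n)]
    for read in reads:
        iv = read.interval
        if iv.chrom != region.chrom:
            continue
        lo = max(iv.start, region.start) - region.start
        hi = min(iv.end, region.end) - region.start
        if hi <= lo:
            continue
        coverage[lo:hi] += 1
        for off, ref, alt in read.substitutions:
            pos = iv.start + off - region.start
            if 0 <= pos < n:
                key = (ref, alt)
                sub_counts[pos][key] = sub_counts[pos].get(key, 0) + 1
    return coverage, sub_counts


def call_clusters(
    reads: Iterable[AlignedRead],
    min_reads: int = DEFAULT_MIN_READS,
    max_gap: int = DEFAULT_MAX_GAP,
) -> List[Cluster]:
    """Call read-overlap islands per (chrom, strand).

    An island is a maximal run of covered bases allowing up to ``max_gap``
    zero-coverage bases inside; islands supported by >= ``min_reads`` reads
    become clusters with their pileup attached.
    """
    by_key: Dict[Tuple[str, str], List[AlignedRead]] = {}
    for r in reads:
        by_key.setdefault((r.interval.chrom, r.interval.strand), []).append(r)
    clusters: List[Cluster] = []
    for (chrom, strand), group in sorted(by_key.items()):
        group.sort(key=lambda r: (r.interval.start, r.interval.end))
        island: List[AlignedRead] = []
        island_end = -1
        for r in group:
            if island and r.interval.start > island_end + max_gap:
                clusters.extend(
                    _finish_island(island, chrom, strand, min_reads)
                )
                island = []
                island_end = -1
            island.append(r)
            island_end = max(island_end, r.interval.end)
        if island:
            clusters.extend(_finish_island(island, chrom, strand, min_reads))
    return clusters


def _finish_island(island, chrom, strand, min_reads):
    if len(island) < min_reads:
        return []
    start = min(r.interval.start for r in island)
    end = max(r.interval.end for r in island)
    region = GenomicInterval(chrom, start, end, strand)
    coverage, sub_counts = pileup(island, region)
    return [
        Cluster(
            interval=region,
            read_count=len(island),
            coverage=coverage,
            sub_counts=sub_counts,
            reads=list(island),
        )
    ]


def _conversion_key(strand: str) -> Tuple[str, str]:
    # sense-strand T>C; reference-forward orientation flips on minus strand
    return ("T", "C") if strand == "+" else ("A", "G")


def t2c_profile(cluster: Cluster) -> np.ndarray:
    """Per-base sense-strand T>C conversion read counts."""
    key = _conversion_key(cluster.interval.strand)
    return np.array([sc.get(key, 0) for sc in cluster.sub_counts], dtype=int)


def classify_t2c(
    cluster: Cluster,
    ratio_threshold: float = DEFAULT_RATIO_THRESHOLD,
    min_conversion_reads: int = DEFAULT_MIN_CONVERSION_READS,
) -> str:
    """Classify a cluster as T2C or NON_T2C and set its ``t2c_ratio``.

    ``t2c_ratio`` is the maximum per-position fraction of covering reads with
    the sense T>C transition; the T2C call additionally requires the
    ``min_conversion_reads`` guard at some position reaching the threshold.
    """
    cov = cluster.coverage
    if not np.any(cov):
        raise ValueError("cannot classify a zero-coverage cluster")
    conv = t2c_profile(cluster)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(cov > 0, conv / np.maximum(cov, 1), 0.0)
    cluster.t2c_ratio = float(frac.max()) if len(frac) else 0.0
    qualifying = (frac >= ratio_threshold) & (conv >= min_conversion_reads)
    cluster.t2c_class = T2C if bool(qualifying.any()) else NON_T2C
    return cluster.t2c_class


def cluster_rpkm(cluster: Cluster, stats: LibraryStats) -> float:
    """Reads per kilobase of cluster per million mapped reads."""
    total = stats.total_mapped_reads
    if total <= 0:
        raise ValueError("library has zero mapped reads")
    rpkm = cluster.read_count / (
        (cluster.interval.length() / 1000.0) * (total / 1e6)
    )
    cluster.rpkm = float(rpkm)
    return cluster.rpkm


def region_rpkm(read_count: int, length: int, stats: LibraryStats) -> float:
    total = stats.total_mapped_reads
    if total <= 0:
        raise ValueError("library has zero mapped reads")
    return read_count / ((length / 1000.0) * (total / 1e6))


def subtract_background(
    clusters: Iterable[Cluster], background: Iterable[GenomicInterval]
) -> List[Cluster]:
    """Flag clusters overlapping any background (non-RBP control) interval
    by >= 1 bp. Flagging is non-destructive; downstream filtering is the
    caller's choice."""
    trees: Dict[str, IntervalTree] = {}
    for iv in background:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    out = []
    for c in clusters:
        tree = trees.get(c.interval.chrom)
        c.background_overlap = bool(tree.overlap(c.interval.start, c.interval.end)) if tree else False
        out.append(c)
    return out


def clusters_to_bed(clusters: Iterable[Cluster], path) -> None:
    """BED6+3 dump: read_count, t2c_ratio, t2c_class as extra columns."""
    with open(str(path), "w") as fh:
        for i, c in enumerate(
            sorted(clusters, key=lambda c: (c.interval.chrom, c.interval.start))
        ):
            iv = c.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\tcluster_{i}\t"
                f"{c.read_count}\t{iv.strand}\t{c.read_count}\t"
                f"{c.t2c_ratio:.4f}\t{c.t2c_class}\n"
            )
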