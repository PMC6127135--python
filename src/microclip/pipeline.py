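"""End-to-end discovery: aligned reads to scored miRNA-binding sites.

The minimum pipeline input is a SAM/BAM alignment, a reference FASTA and a
miRNA list; annotation adds gene assignment (CDS/3'UTR), a conservation
track adds evolutionary-rate features, and a trained super learner turns
feature vectors into site probabilities.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

from .clusters import (
    Cluster,
    call_clusters,
    classify_t2c,
    cluster_rpkm,
    subtract_background,
)
from .core import ConservationTrack, GenomicInterval, LibraryStats, MatureMiRNA, revcomp
from .duplex import Duplex, dedupe_candidates, fold_duplex, scan_mres, BINDING_TYPES
from .features import (
    DEFAULT_FLANK,
    assemble,
    clip_features,
    conservation_features,
    duplex_features,
    mre_general_features,
    sequence_features,
)
from .genomic_io import SequenceStore, read_alignments, library_stats


def cluster_sense_sequence(cluster: Cluster, ref: SequenceStore) -> str:
    iv = cluster.interval
    seq = ref.fetch(iv.chrom, iv.start, iv.end)
    return seq if iv.strand == "+" else revcomp(seq)


def sense_to_genomic(cluster: Cluster, lo: int, hi: int) -> GenomicInterval:
    """Map sense-relative [lo, hi) within the cluster to genome coordinates."""
    iv = cluster.interval
    if iv.strand == "+":
        return GenomicInterval(iv.chrom, iv.start + lo, iv.start + hi, "+")
    return GenomicInterval(iv.chrom, iv.end - hi, iv.end - lo, "-")


def _sense_flanks(
    cluster: Cluster, lo: int, hi: int, ref: SequenceStore, flank: int
) -> Tuple[str, str, Optional[GenomicInterval], Optional[GenomicInterval]]:
    """Sense-oriented up/down flanks of a sense-relative window, clipped to
    the chromosome."""
    iv = cluster.interval
    site = sense_to_genomic(cluster, lo, hi)
    L = ref.length(iv.chrom)
    if iv.strand == "+":
        up = (max(0, site.start - flank), site.start)
        down = (site.end, min(L, site.end + flank))
        up_seq = ref.fetch(iv.chrom, *up)
        down_seq = ref.fetch(iv.chrom, *down)
    else:
        up = (site.end, min(L, site.end + flank))
        down = (max(0, site.start - flank), site.start)
        up_seq = revcomp(ref.fetch(iv.chrom, *up))
        down_seq = revcomp(ref.fetch(iv.chrom, *down))
    up_iv = GenomicInterval(iv.chrom, *up, iv.strand) if up[1] > up[0] else None
    down_iv = GenomicInterval(iv.chrom, *down, iv.strand) if down[1] > down[0] else None
    return up_seq, down_seq, up_iv, down_iv


def featurize_cluster(
    cluster: Cluster,
    ref: SequenceStore,
    mirnas: Iterable[MatureMiRNA],
    stats: Optional[LibraryStats] = None,
    track: Optional[ConservationTrack] = None,
    flank: int = DEFAULT_FLANK,
) -> pd.DataFrame:
    """Scan one cluster, fold candidates and compute the 131 descriptors.

    Returns a table with one row per retained duplex: metadata columns
    (mirna, chrom, start, end, strand, binding_type_code, binding_type,
    duplex_energy, region_id) plus the full feature set.
    """
    seq = cluster_sense_sequence(cluster, ref)
    candidates = scan_mres(seq, mirnas)
    duplexes: List[Duplex] = []
    for c in candidates:
        local_pairs = [(i - c.start, j) for i, j in c.seed_pairs]
        dup = fold_duplex(
            c.mirna, seq[c.start : c.end], c.register - c.start, local_pairs
        )
        if dup is None:
            continue
        dup.site_start = c.start
        duplexes.append(dup)
    duplexes = dedupe_candidates(duplexes)
    rows = []
    for dup in duplexes:
        lo = dup.site_start
        hi = lo + len(dup.site_sequence)
        mre_iv = sense_to_genomic(cluster, lo, hi)
        up_seq, down_seq, up_iv, down_iv = _sense_flanks(cluster, lo, hi, ref, flank)
        seed_lo = max(lo, dup.site_start + dup.register - 7)
        seed_hi = min(hi, dup.site_start + dup.register)
        seed_iv = (
            sense_to_genomic(cluster, seed_lo, seed_hi) if seed_hi > seed_lo else None
        )
        cons, flags = conservation_features(mre_iv, up_iv, down_iv, seed_iv, track)
        fv = assemble(
            [
                clip_features(cluster, mre_iv, stats),
                sequence_features(dup.site_sequence, up_seq, down_seq),
                cons,
                duplex_features(dup, up_seq, down_seq),
                mre_general_features(mre_iv, cluster, dup),
            ],
            flags,
        )
        row = dict(fv.values)
        row.update(
            {
                "mirna": dup.mirna.name,
                "chrom": mre_iv.chrom,
                "start": mre_iv.start,
                "end": mre_iv.end,
                "strand": mre_iv.strand,
                "binding_type": BINDING_TYPES[dup.binding_type_code],
                "region_id": f"{mre_iv.chrom}:{mre_iv.start}-{mre_iv.end}({mre_iv.strand})",
                "origin_cluster_class": cluster.t2c_class,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)


def assign_genes(sites: pd.DataFrame, transcripts) -> pd.DataFrame:
    """Annotate each site with the gene and region (CDS/UTR3/other) of the
    first overlapping transcript."""
    sites = sites.copy()
    genes, regions = [], []
    for r in sites.itertuples():
        iv = GenomicInterval(r.chrom, int(r.start), int(r.end), r.strand)
        gene, region = "", "other"
        for t in transcripts:
            if t.chrom != iv.chrom or t.strand != iv.strand:
                continue
            if any(iv.overlaps(e) for e in t.exons):
                gene = t.gene_id
                if any(iv.overlaps(u) for u in t.utr3):
                    region = "UTR3"
                elif any(iv.overlaps(c) for c in t.cds):
                    region = "CDS"
                break
        genes.append(gene)
        regions.append(region)
    sites["gene"] = genes
    sites["region"] = regions
    return sites


def discover_sites(
    sam_path,
    fasta,
    mirnas: Iterable[MatureMiRNA],
    transcripts=None,
    model=None,
    track: Optional[ConservationTrack] = None,
    background=None,
    min_reads: int = 5,
    max_gap: int = 0,
    t2c_threshold: float = 0.20,
    exclude_background: bool = True,
) -> Tuple[pd.DataFrame, List[Cluster]]:
    """Full discovery from an alignment file.

    Returns ``(site table, clusters)``; the site table carries a ``score``
    column when a trained model is supplied.
    """
    ref = fasta if isinstance(fasta, SequenceStore) else SequenceStore(fasta)
    reads = list(read_alignments(sam_path, ref))
    stats = library_stats(reads)
    clusters = call_clusters(reads, min_reads=min_reads, max_gap=max_gap)
    for c in clusters:
        classify_t2c(c, t2c_threshold)
        cluster_rpkm(c, stats)
    if background is not None:
        clusters = subtract_background(clusters, background)
        if exclude_background:
            clusters = [c for c in clusters if not c.background_overlap]
    frames = []
    for ci, c in enumerate(clusters):
        df = featurize_cluster(c, ref, mirnas, stats, track)
        if len(df):
            df["cluster_id"] = ci
            frames.append(df)
    if not frames:
        return pd.DataFrame(), clusters
    sites = pd.concat(frames, ignore_index=True)
    if transcripts is not None:
        sites = assign_genes(sites, transcripts)
    if model is not None:
        sites["score"] = model.predict(sites)
    return sites, clusters
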