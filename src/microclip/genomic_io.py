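"""Readers/writers for the standard formats the pipeline touches.

SAM/BAM goes through pysam, FASTA through pyfaidx, miRNA lists accept FASTA
(Biopython) or 2-column TSV, annotation accepts GTF (gene_id/transcript_id
attributes required) or BED12 (thickStart/thickEnd define the CDS).
Scored-site output is BED6 plus a TSV sidecar carrying full feature
provenance; the pair round-trips losslessly.
"""

from __future__ import annotations

import logging
import math
import os
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

import pandas as pd
import pysam
from Bio import SeqIO

from .core import (
    AlignedRead,
    ConservationTrack,
    GenomicInterval,
    LibraryStats,
    MatureMiRNA,
    TranscriptModel,
)

log = logging.getLogger(__name__)


class SequenceStore:
    """Reference sequences, from a FASTA path or an in-memory dict."""

    def __init__(self, source):
        if isinstance(source, dict):
            self._seqs = {k: v.upper() for k, v in source.items()}
            self._fasta = None
        else:
            import pyfaidx

            self._fasta = pyfaidx.Fasta(str(source))
            self._seqs = None

    def __contains__(self, chrom: str) -> bool:
        if self._seqs is not None:
            return chrom in self._seqs
        return chrom in self._fasta

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if self._seqs is not None:
            return self._seqs[chrom][start:end]
        return str(self._fasta[chrom][start:end]).upper()

    def length(self, chrom: str) -> int:
        if self._seqs is not None:
            return len(self._seqs[chrom])
        return len(self._fasta[chrom])

    def chroms(self) -> List[str]:
        if self._seqs is not None:
            return list(self._seqs)
        return list(self._fasta.keys())


@dataclass
class SkipReport:
    unmapped: int = 0
    secondary: int = 0
    supplementary: int = 0
    missing_chrom: int = 0
    kept: int = 0


def _substitutions_from_alignment(aln, reference: SequenceStore):
    """Derive (offset, ref, alt) triples. Uses the MD tag when present,
    otherwise compares the query against the reference store."""
    subs = []
    try:
        pairs = aln.get_aligned_pairs(matches_only=True, with_seq=True)
        have_md = aln.has_tag("MD")
    except ValueError:
        pairs, have_md = None, False
    if have_md and pairs is not None:
        for qpos, rpos, ref_base in pairs:
            ref_base = ref_base.upper()
            alt = aln.query_sequence[qpos].upper()
            if ref_base != alt and ref_base in "ACGT" and alt in "ACGT":
                subs.append((rpos - aln.reference_start, ref_base, alt))
        return subs
    for qpos, rpos in aln.get_aligned_pairs(matches_only=True):
        ref_base = reference.fetch(aln.reference_name, rpos, rpos + 1)
        alt = aln.query_sequence[qpos].upper()
        if ref_base != alt and ref_base in "ACGT" and alt in "ACGT":
            subs.append((rpos - aln.reference_start, ref_base, alt))
    return subs


def read_alignments(
    path, reference, skip_report: Optional[SkipReport] = None
) -> Iterator[AlignedRead]:
    """Stream primary mapped alignments from a SAM/BAM file.

    Unmapped, secondary and supplementary records are skipped and counted in
    ``skip_report``; records on chromosomes absent from ``reference`` are
    skipped with a warning.
    """
    if not isinstance(reference, SequenceStore):
        reference = SequenceStore(reference)
    report = skip_report if skip_report is not None else SkipReport()
    mode = "rb" if str(path).endswith(".bam") else "r"
    try:
        af = pysam.AlignmentFile(str(path), mode, check_sq=False)
    except (OSError, ValueError) as exc:
        raise ValueError(f"unreadable alignment file {path}: {exc}") from exc
    with af:
        for aln in af:
            if aln.is_unmapped:
                report.unmapped += 1
                continue
            if aln.is_secondary:
                report.secondary += 1
                continue
            if aln.is_supplementary:
                report.supplementary += 1
                continue
            if aln.reference_name not in reference:
                report.missing_chrom += 1
                warnings.warn(
                    f"chromosome {aln.reference_name} absent from reference; "
                    f"skipping {aln.query_name}"
                )
                continue
            strand = "-" if aln.is_reverse else "+"
            interval = GenomicInterval(
                aln.reference_name, aln.reference_start, aln.reference_end, strand
            )
            subs = _substitutions_from_alignment(aln, reference)
            report.kept += 1
            yield AlignedRead(aln.query_name, interval, aln.query_sequence.upper(), subs)


def library_stats(reads: Iterable[AlignedRead]) -> LibraryStats:
    stats = LibraryStats()
    for r in reads:
        stats.per_chrom[r.interval.chrom] = stats.per_chrom.get(r.interval.chrom, 0) + 1
    return stats


# ---------------------------------------------------------------------------
# annotation


def _parse_gtf_attributes(attr: str) -> Dict[str, str]:
    out = {}
    for part in attr.strip().strip(";").split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, val = part.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def _subtract(intervals: List[GenomicInterval], minus: List[GenomicInterval]):
    """Exonic intervals minus CDS intervals (same chrom/strand)."""
    out = []
    for iv in intervals:
        segments = [(iv.start, iv.end)]
        for m in minus:
            nxt = []
            for s, e in segments:
                if m.end <= s or m.start >= e:
                    nxt.append((s, e))
                    continue
                if s < m.start:
                    nxt.append((s, m.start))
                if m.end < e:
                    nxt.append((m.end, e))
            segments = nxt
        out.extend(
            GenomicInterval(iv.chrom, s, e, iv.strand) for s, e in segments if e > s
        )
    return out


def _derive_utr3(exons, cds):
    """3'UTR = exonic sequence strand-downstream of the CDS."""
    if not cds:
        return []
    strand = exons[0].strand
    noncds = _subtract(exons, cds)
    if strand == "+":
        cds_end = max(iv.end for iv in cds)
        return [iv for iv in noncds if iv.start >= cds_end]
    cds_start = min(iv.start for iv in cds)
    return [iv for iv in noncds if iv.end <= cds_start]


def load_annotation(path) -> List[TranscriptModel]:
    """Load transcript models from GTF or BED12 (by extension)."""
    path = str(path)
    if path.endswith((".bed", ".bed12")):
        return _load_bed12(path)
    return _load_gtf(path)


def _load_gtf(path) -> List[TranscriptModel]:
    exons: Dict[str, List[GenomicInterval]] = {}
    cds: Dict[str, List[GenomicInterval]] = {}
    genes: Dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"malformed GTF line: {line!r}")
            chrom, _, ftype, start, end, _, strand, _, attr = fields[:9]
            if ftype not in ("exon", "CDS"):
                continue
            attrs = _parse_gtf_attributes(attr)
            if "gene_id" not in attrs or "transcript_id" not in attrs:
                raise ValueError("GTF requires gene_id and transcript_id attributes")
            tid = attrs["transcript_id"]
            genes[tid] = attrs["gene_id"]
            iv = GenomicInterval(chrom, int(start) - 1, int(end), strand)
            (exons if ftype == "exon" else cds).setdefault(tid, []).append(iv)
    models = []
    for tid, gene in sorted(genes.items()):
        if tid not in exons:
            warnings.warn(f"transcript {tid} has zero exons; rejected")
            continue
        exs = sorted(exons[tid], key=lambda iv: iv.start)
        cd = sorted(cds.get(tid, []), key=lambda iv: iv.start)
        models.append(
            TranscriptModel(gene, tid, exs, cd, _derive_utr3(exs, cd))
        )
    return models


def _load_bed12(path) -> List[TranscriptModel]:
    models = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ValueError("BED12 requires 12 columns")
            chrom, start, end, name, _, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            thick_s, thick_e = int(f[6]), int(f[7])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offs = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [
                GenomicInterval(chrom, start + o, start + o + s, strand)
                for o, s in zip(offs, sizes)
            ]
            gene_id, _, tid = name.partition("|")
            tid = tid or name
            cds = []
            if thick_e > thick_s:
                for iv in exons:
                    s, e = max(iv.start, thick_s), min(iv.end, thick_e)
                    if e > s:
                        cds.append(GenomicInterval(chrom, s, e, strand))
            models.append(
                TranscriptModel(gene_id, tid, exons, cds, _derive_utr3(exons, cds))
            )
    return models


def representative_transcripts(models: Iterable[TranscriptModel]) -> Dict[str, TranscriptModel]:
    """Per gene, the transcript with the longest total 3'UTR; ties broken
    lexicographically by transcript_id."""
    best: Dict[str, TranscriptModel] = {}
    for m in models:
        cur = best.get(m.gene_id)
        if (
            cur is None
            or m.utr3_length() > cur.utr3_length()
            or (m.utr3_length() == cur.utr3_length() and m.transcript_id < cur.transcript_id)
        ):
            best[m.gene_id] = m
    return best


# ---------------------------------------------------------------------------
# miRNAs


def load_mirnas(path) -> List[MatureMiRNA]:
    """Load mature miRNAs from FASTA or a 2-column (name, sequence) TSV."""
    path = str(path)
    entries: List[Tuple[str, str]] = []
    if path.endswith((".fa", ".fasta", ".fna")):
        for rec in SeqIO.parse(path, "fasta"):
            entries.append((rec.id, str(rec.seq)))
    else:
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) < 2:
                    raise ValueError(f"malformed miRNA TSV line: {line!r}")
                entries.append((parts[0], parts[1]))
    if not entries:
        warnings.warn(f"no miRNA entries in {path}")
        return []
    seen = set()
    out = []
    for name, seq in entries:
        if name in seen:
            raise ValueError(f"duplicate miRNA name {name}")
        seen.add(name)
        if len(seq) < 16:
            warnings.warn(f"{name}: sequence shorter than 16 nt; rejected")
            continue
        out.append(MatureMiRNA(name, seq))
    return out


# ---------------------------------------------------------------------------
# conservation


def load_conservation(path) -> ConservationTrack:
    """Load a conservation track from bigWig or a 3-column TSV
    (chrom, pos0, score)."""
    path = str(path)
    if path.endswith((".bw", ".bigwig", ".bigWig")):
        from .core import BigWigConservationTrack

        return BigWigConservationTrack(path)
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "pos", "score"])
    return ConservationTrack(
        {(r.chrom, int(r.pos)): float(r.score) for r in df.itertuples()}
    )


# ---------------------------------------------------------------------------
# scored-site output

SITE_COLUMNS = [
    "chrom",
    "start",
    "end",
    "strand",
    "mirna",
    "gene",
    "binding_type",
    "score",
]


def write_sites(sites: pd.DataFrame, path) -> None:
    """Write scored MRE records as BED6 plus a full TSV sidecar.

    BED name = miRNA|gene|binding_type; BED score = probability scaled to
    [0, 1000]. The sidecar (``<path>.tsv``) keeps every input column so that
    ``read_sites`` round-trips losslessly.
    """
    path = str(path)
    df = sites.copy()
    missing = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"site table missing columns: {missing}")
    df = df.sort_values(["chrom", "start", "end", "mirna"], kind="mergesort")
    try:
        with open(path, "w") as bed:
            for r in df.itertuples():
                name = f"{r.mirna}|{r.gene}|{r.binding_type}"
                bed.write(
                    f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t"
                    f"{int(round(float(r.score) * 1000))}\t{r.strand}\n"
                )
        df.to_csv(path + ".tsv", sep="\t", index=False)
    except OSError as exc:
        raise OSError(f"cannot write sites to {path}: {exc}") from exc


def read_sites(path) -> pd.DataFrame:
    return pd.read_csv(str(path) + ".tsv", sep="\t")
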