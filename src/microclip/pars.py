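"""PARS structural-accessibility scoring and site meta-profiles.

PARS couples S1 (single-strand cutting) and V1 (double-strand cutting)
nuclease digestion with sequencing; the per-base structure score is

    score_i = log2((v1_i + c) / (s1_i + c))

on depth-normalized (per-million) tag-start intensities with pseudocount
``c`` (default 5, the Wan et al. convention). Negative scores indicate
single-stranded (accessible) RNA, positive scores double-stranded RNA.

Meta-profiles average scores across miRNA-binding sites after aligning each
site to a common anchor: profile position 0 is the 3' end of the mRNA site,
placed 2 nt downstream (3'-ward) of the initiation of direct seed pairing
by default (configurable to 1 nt); positive profile positions run 5'-ward
into the site body, so the base opposite miRNA seed position j sits at
profile position j + offset - 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

DEFAULT_PSEUDOCOUNT = 5.0
DEFAULT_WINDOW = (-10, 30)
DEFAULT_ANCHOR_OFFSET = 2  # nt downstream of seed-pairing initiation


@dataclass
class NucleaseCounts:
    """Per-base S1/V1 tag-start counts for one chromosome/transcriptome
    coordinate system, plus library depths."""

    s1: Dict[str, np.ndarray]
    v1: Dict[str, np.ndarray]
    s1_depth: int
    v1_depth: int

    def __post_init__(self):
        for chrom in self.s1:
            if (self.s1[chrom] < 0).any() or (self.v1[chrom] < 0).any():
                raise ValueError("negative nuclease counts")
        for depth, counts in (
            (self.s1_depth, self.s1),
            (self.v1_depth, self.v1),
        ):
            total = sum(int(v.sum()) for v in counts.values())
            if depth < total:
                raise ValueError("library depth smaller than column sums")

    @classmethod
    def from_tsv(cls, path) -> "NucleaseCounts":
        """chrom, pos0, s1, v1 TSV; depths = column sums."""
        df = pd.read_csv(
            path, sep="\t", header=None, names=["chrom", "pos", "s1", "v1"]
        )
        s1, v1 = {}, {}
        for chrom, g in df.groupby("chrom"):
            n = int(g["pos"].max()) + 1
            a = np.zeros(n, dtype=int)
            b = np.zeros(n, dtype=int)
            a[g["pos"].to_numpy()] = g["s1"].to_numpy()
            b[g["pos"].to_numpy()] = g["v1"].to_numpy()
            s1[chrom], v1[chrom] = a, b
        return cls(
            s1, v1,
            sum(int(v.sum()) for v in s1.values()),
            sum(int(v.sum()) for v in v1.values()),
        )


def pars_score(
    counts: NucleaseCounts,
    chrom: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> np.ndarray:
    """Per-base PARS score vector for one chromosome."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if counts.s1_depth <= 0 or counts.v1_depth <= 0:
        raise ValueError("zero library depth")
    s1 = counts.s1[chrom] * 1e6 / counts.s1_depth
    v1 = counts.v1[chrom] * 1e6 / counts.v1_depth
    return np.log2((v1 + pseudocount) / (s1 + pseudocount))


def pars_scores(counts: NucleaseCounts, pseudocount: float = DEFAULT_PSEUDOCOUNT):
    return {c: pars_score(counts, c, pseudocount) for c in counts.s1}


def site_signal_filter(
    site_start: int, site_end: int, chrom: str, counts: NucleaseCounts
) -> bool:
    """True iff both S1 and V1 have nonzero counts on at least half
    (ceil(L/2)) of the site's bases."""
    L = site_end - site_start
    need = -(-L // 2)
    s1 = counts.s1[chrom][site_start:site_end]
    v1 = counts.v1[chrom][site_start:site_end]
    return int((s1 > 0).sum()) >= need and int((v1 > 0).sum()) >= need


@dataclass
class PARSProfile:
    group: str
    positions: np.ndarray
    mean: np.ndarray
    n: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"position": self.positions, "group": self.group, "mean": self.mean, "n": self.n}
        )


def _site_profile_positions(row, window, anchor_offset):
    """Genomic coordinate of each profile position for one site.

    ``seed_start`` is the genomic coordinate of the mRNA base opposite
    miRNA position 1. Position 0 = that base shifted ``anchor_offset`` nt
    downstream (3'-ward on the mRNA); positive positions run 5'-ward.
    """
    lo, hi = window
    p = np.arange(lo, hi + 1)
    if row.strand == "+":
        anchor = row.seed_start + anchor_offset
        return p, anchor - p
    anchor = row.seed_start - anchor_offset
    return p, anchor + p


def meta_profile(
    sites: pd.DataFrame,
    scores: Mapping[str, np.ndarray],
    window: Tuple[int, int] = DEFAULT_WINDOW,
    negative_group: str = "negative",
    anchor_offset: int = DEFAULT_ANCHOR_OFFSET,
):
    """Group-wise mean PARS profiles around site starts plus per-position
    two-sided rank-sum p-values versus the negative group.

    ``sites`` columns: chrom, strand, seed_start, group. Returns
    ``(profiles: {group: PARSProfile}, pvalues: DataFrame)``.
    """
    lo, hi = window
    width = hi - lo + 1
    per_group: Dict[str, List[np.ndarray]] = {}
    for row in sites.itertuples():
        vec = scores.get(row.chrom)
        if vec is None:
            continue
        p, coords = _site_profile_positions(row, window, anchor_offset)
        vals = np.full(width, np.nan)
        ok = (coords >= 0) & (coords < len(vec))
        vals[ok] = vec[coords[ok]]
        per_group.setdefault(row.group, []).append(vals)
    profiles: Dict[str, PARSProfile] = {}
    for group, rows in per_group.items():
        if not rows:
            warnings.warn(f"group {group} is empty; omitted")
            continue
        M = np.vstack(rows)
        n = np.sum(~np.isnan(M), axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(M, axis=0)
        mean[n == 0] = np.nan
        profiles[group] = PARSProfile(group, np.arange(lo, hi + 1), mean, n)
    pvals = []
    neg = per_group.get(negative_group)
    if neg is not None:
        N = np.vstack(neg)
        for group, rows in per_group.items():
            if group == negative_group:
                continue
            M = np.vstack(rows)
            for k in range(width):
                a = M[:, k][~np.isnan(M[:, k])]
                b = N[:, k][~np.isnan(N[:, k])]
                if len(a) >= 2 and len(b) >= 2:
                    p = float(sps.ranksums(a, b).pvalue)
                else:
                    p = np.nan
                pvals.append(
                    {"position": lo + k, "group": group, "p_value": p}
                )
    return profiles, pd.DataFrame(pvals)


def seed_profile_position(
    mirna_position: int, anchor_offset: int = DEFAULT_ANCHOR_OFFSET
) -> int:
    """Profile position of the mRNA base opposite a 1-based miRNA position."""
    return mirna_position + anchor_offset - 1
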