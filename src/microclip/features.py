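"""The 131-descriptor feature catalogue and its producers.

Features are grouped into the 9 base-node subsets of the two-layer
classifier. Nodes 1-6 partition the 131 descriptors (region/CLIP, binding
vectors, matches per domain, duplex, base-pairing composition, MRE general);
nodes 7-9 are three fixed, non-overlapping recombinations of node 1-6
features. The shipped catalogue file
(``data/feature_catalog.tsv``: name, node ids, family) is the single source
of truth for names, order and node membership.

Sequence conventions: all sequences are sense-oriented 5'->3'; flanks default
to 30 nt each side. Shannon entropy is in bits; skews follow
(G-C)/(G+C)-style definitions; the DUST score is the standard triplet
statistic normalized to [0, 1] (1 = homopolymer regime). Nearest-neighbor
dH/dS/dG and Tm come from Biopython's published RNA parameter set
(Tm at 50 mM Na+, 0.25 uM strand).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd
from Bio.SeqUtils import MeltingTemp as mt

from .clusters import Cluster, t2c_profile, region_rpkm
from .core import ConservationTrack, GenomicInterval, LibraryStats
from .duplex import Duplex, binding_vector, domain_matches

DEFAULT_FLANK = 30
DUST_WINDOW = 64
_NN_TABLE = mt.RNA_NN2
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def load_catalog() -> pd.DataFrame:
    with resources.files("microclip").joinpath("data/feature_catalog.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df["node_ids"] = df["nodes"].map(lambda s: tuple(int(x) for x in str(s).split(",")))
    return df


CATALOG = load_catalog()
FEATURE_NAMES: List[str] = list(CATALOG["name"])
N_FEATURES = len(FEATURE_NAMES)


def node_features(node_id: int) -> List[str]:
    """Feature names belonging to one base node (1..9)."""
    return [
        n for n, ids in zip(CATALOG["name"], CATALOG["node_ids"]) if node_id in ids
    ]


NODE_FEATURES: Dict[int, List[str]] = {i: node_features(i) for i in range(1, 10)}


@dataclass
class FeatureVector:
    """131 named descriptors plus provenance flags for imputed values."""

    values: pd.Series
    imputed: Dict[str, bool] = field(default_factory=dict)

    def __post_init__(self):
        if list(self.values.index) != FEATURE_NAMES:
            missing = set(FEATURE_NAMES) - set(self.values.index)
            raise ValueError(f"feature vector mismatch; missing: {sorted(missing)[:5]}")
        if self.values.isna().any():
            bad = list(self.values.index[self.values.isna()])
            raise ValueError(f"NaN features after imputation: {bad[:5]}")


# ---------------------------------------------------------------------------
# sequence descriptors


def shannon_index(seq: str) -> float:
    """Shannon-Wiener index over base frequencies, in bits."""
    if not seq:
        return 0.0
    h = 0.0
    n = len(seq)
    for b in "ACGT":
        p = seq.count(b) / n
        if p > 0:
            h -= p * math.log2(p)
    return h


def dust_score(seq: str, window: int = DUST_WINDOW) -> float:
    """Triplet-based low-complexity score, max over windows, in [0, 1]."""
    if len(seq) < 3:
        return 0.0
    best = 0.0
    step = max(1, window // 2)
    starts = range(0, max(1, len(seq) - 2), step)
    for s in starts:
        w = seq[s : s + window]
        k = len(w) - 2
        if k < 1:
            continue
        counts: Dict[str, int] = {}
        for i in range(k):
            t = w[i : i + 3]
            counts[t] = counts.get(t, 0) + 1
        raw = sum(c * (c - 1) / 2 for c in counts.values())
        if k > 1:
            best = max(best, (raw / (k - 1)) / (k / 2))
        elif raw > 0:
            best = max(best, 1.0)
    return min(1.0, best)


def skews(seq: str) -> Tuple[float, float, float, float]:
    """(GC, AT, purine, keto) skews; 0 with implicit imputation when a
    denominator vanishes."""
    n = len(seq) or 1
    a, c, g, t = (seq.count(b) for b in "ACGT")
    gc = (g - c) / (g + c) if (g + c) else 0.0
    at = (a - t) / (a + t) if (a + t) else 0.0
    purine = (a + g - c - t) / n
    keto = (g + t - a - c) / n
    return gc, at, purine, keto


def codon_usage_bias(seq: str) -> float:
    """Frame-agnostic triplet-usage bias: max over the 3 frames of
    1 - H(triplets)/log2(64)."""
    best = 0.0
    for frame in range(3):
        triplets = [seq[i : i + 3] for i in range(frame, len(seq) - 2, 3)]
        triplets = [t for t in triplets if len(t) == 3]
        if not triplets:
            continue
        counts: Dict[str, int] = {}
        for t in triplets:
            counts[t] = counts.get(t, 0) + 1
        n = len(triplets)
        h = -sum((c / n) * math.log2(c / n) for c in counts.values())
        best = max(best, 1.0 - h / 6.0)
    return best


def nn_thermo(seq: str) -> Tuple[float, float, float, float]:
    """(dH kcal/mol, dS cal/mol/K, dG37 kcal/mol, Tm degC) of the sequence
    paired with its perfect complement, nearest-neighbor model."""
    if len(seq) < 2:
        return 0.0, 0.0, 0.0, 0.0
    dh, ds = _NN_TABLE["init"]
    for end in (seq[0], seq[-1]):
        if end in "AT":
            h, s = _NN_TABLE["init_A/T"]
        else:
            h, s = _NN_TABLE["init_G/C"]
        dh += h
        ds += s
    for i in range(len(seq) - 1):
        step = seq[i : i + 2]
        key = f"{step}/{_COMP[step[0]]}{_COMP[step[1]]}"
        if key not in _NN_TABLE:
            rc = _COMP[step[1]] + _COMP[step[0]]
            key = f"{rc}/{_COMP[rc[0]]}{_COMP[rc[1]]}"
        h, s = _NN_TABLE[key]
        dh += h
        ds += s
    dg37 = dh - 310.15 * ds / 1000.0
    tm = float(mt.Tm_NN(seq, nn_table=_NN_TABLE, Na=50, dnac1=250, dnac2=0))
    return dh, ds, dg37, tm


def sequence_features(seq: str, upflank: str, downflank: str) -> Dict[str, float]:
    """43 sequence-derived descriptors of the MRE and its flanks."""
    seq = seq.upper().replace("U", "T")
    upflank = upflank.upper().replace("U", "T")
    downflank = downflank.upper().replace("U", "T")
    out: Dict[str, float] = {}
    for region, s in (("mre", seq), ("upflank", upflank), ("downflank", downflank)):
        n = len(s) or 1
        for b in "ACGT":
            out[f"freq_{b}_{region}"] = s.count(b) / n
        out[f"dust_{region}"] = dust_score(s)
        out[f"shannon_{region}"] = shannon_index(s)
    n2 = max(1, len(seq) - 1)
    for a in "ACGT":
        for b in "ACGT":
            out[f"freq_{a}{b}_mre"] = sum(
                1 for i in range(len(seq) - 1) if seq[i] == a and seq[i + 1] == b
            ) / n2
    gc, at, purine, keto = skews(seq)
    out["gc_skew_mre"] = gc
    out["at_skew_mre"] = at
    out["purine_skew_mre"] = purine
    out["keto_skew_mre"] = keto
    out["codon_usage_bias_mre"] = codon_usage_bias(seq)
    dh, ds, dg, tm = nn_thermo(seq)
    out["nn_dh_mre"] = dh
    out["nn_ds_mre"] = ds
    out["nn_dg_mre"] = dg
    out["tm_mre"] = tm
    return out


# ---------------------------------------------------------------------------
# CLIP descriptors


def clip_features(
    cluster: Cluster,
    mre_interval: GenomicInterval,
    stats: Optional[LibraryStats] = None,
) -> Dict[str, float]:
    """PAR-CLIP signal descriptors of an MRE within its cluster.

    Distances are signed in sense orientation: negative = conversion
    upstream (5') of the MRE start.
    """
    iv = cluster.interval
    cov = cluster.coverage
    conv = t2c_profile(cluster)
    agg = np.array(
        [sum(sc.values()) for sc in cluster.sub_counts], dtype=int
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        conv_frac = np.where(cov > 0, conv / np.maximum(cov, 1), 0.0)
        agg_frac = np.where(cov > 0, agg / np.maximum(cov, 1), 0.0)

    # sense-oriented positions within the cluster
    def to_sense(pos: int) -> int:
        return pos if iv.strand == "+" else iv.length() - 1 - pos

    mre_lo = max(iv.start, mre_interval.start) - iv.start
    mre_hi = min(iv.end, mre_interval.end) - iv.start
    mre_slice = slice(max(0, mre_lo), max(0, mre_hi))
    if iv.strand == "+":
        mre_start_sense = mre_lo
    else:
        mre_start_sense = iv.length() - mre_hi

    def dist_feature(frac: np.ndarray) -> float:
        if frac.max() <= 0:
            return 0.0
        pos = int(frac.argmax())
        return float(to_sense(pos) - mre_start_sense)

    out: Dict[str, float] = {}
    out["t2c_ratio_cluster"] = float(conv_frac.max()) if len(conv_frac) else 0.0
    out["t2c_ratio_mre"] = (
        float(conv_frac[mre_slice].max()) if mre_hi > mre_lo else 0.0
    )
    out["aggregate_sub_ratio"] = float(agg_frac.max()) if len(agg_frac) else 0.0
    out["sub_rel_position"] = (
        to_sense(int(agg_frac.argmax())) / max(1, iv.length() - 1)
        if agg_frac.max() > 0
        else 0.0
    )
    out["t2c_dist_mre_start"] = dist_feature(conv_frac)
    out["sub_dist_mre_start"] = dist_feature(agg_frac)
    if stats is not None and stats.total_mapped_reads > 0:
        out["cluster_rpkm"] = region_rpkm(
            cluster.read_count, iv.length(), stats
        )
        mre_reads = sum(
            1 for r in cluster.reads if r.interval.overlaps(mre_interval)
        )
        out["mre_rpkm"] = region_rpkm(mre_reads, mre_interval.length(), stats)
    else:
        out["cluster_rpkm"] = 0.0
        out["mre_rpkm"] = 0.0
    mean_cluster = float(cov.mean()) if len(cov) else 0.0
    mean_mre = float(cov[mre_slice].mean()) if mre_hi > mre_lo else 0.0
    out["mre_cluster_coverage_ratio"] = (
        mean_mre / mean_cluster if mean_cluster > 0 else 0.0
    )
    return out


# ---------------------------------------------------------------------------
# conservation descriptors


def conservation_features(
    mre_interval: GenomicInterval,
    upflank: Optional[GenomicInterval],
    downflank: Optional[GenomicInterval],
    seed_bind: Optional[GenomicInterval],
    track: Optional[ConservationTrack],
) -> Tuple[Dict[str, float], Dict[str, bool]]:
    """Mean conservation over the MRE, both flanks, and the seed-bound
    bases (opposite miRNA positions 2-8). A null track imputes 0 with
    per-feature flags."""
    out: Dict[str, float] = {}
    flags: Dict[str, bool] = {}
    regions = {
        "cons_mre": mre_interval,
        "cons_upflank": upflank,
        "cons_downflank": downflank,
        "cons_seed_bind": seed_bind,
    }
    for name, region in regions.items():
        if track is None or region is None:
            out[name] = 0.0
            flags[name] = True
            continue
        mean, missing = track.mean(region)
        out[name] = mean
        flags[name] = missing == 1.0
    return out, flags


# ---------------------------------------------------------------------------
# duplex descriptors


def _au_pair_count(dup: Duplex, positions: Iterable[int]) -> int:
    n = 0
    for j in positions:
        i = dup.pair_map.get(j)
        if i is None:
            continue
        pair = {dup.site_sequence[i], dup.mirna.sequence[j - 1]}
        if pair == {"A", "T"}:
            n += 1
    return n


def _seed_substructure_energy(dup: Duplex) -> float:
    """Energy of the structure restricted to seed-domain (2-8) pairs."""
    from .duplex import eval_structure_energy

    seed = {j: i for j, i in dup.pair_map.items() if 2 <= j <= 8}
    if not seed:
        return 0.0
    n1 = len(dup.site_sequence)
    L = len(dup.mirna)
    chars = ["."] * (n1 + L)
    for j, i in seed.items():
        chars[i] = "("
        chars[n1 + j - 1] = ")"
    e = eval_structure_energy(dup.site_sequence, dup.mirna.sequence, "".join(chars))
    return min(e, 0.0)


def duplex_features(
    dup: Duplex, upflank: str, downflank: str
) -> Dict[str, float]:
    """Node 2 (binding vectors), 3 (domain matches), 4 (duplex) and
    5 (pairing composition) descriptors."""
    out: Dict[str, float] = {}
    mvec, _svec = binding_vector(dup)
    for i, v in enumerate(mvec, start=1):
        out[f"bv_mirna_{i:02d}"] = float(v)
    out.update({k: float(v) for k, v in domain_matches(dup).as_dict().items()})
    L = len(dup.mirna)
    out["duplex_energy"] = dup.duplex_energy
    out["seed_duplex_energy"] = _seed_substructure_energy(dup)
    out["bulge_count"] = float(dup.bulges)
    out["longest_bulge"] = float(dup.longest_bulge)
    out["internal_loop_count"] = float(dup.internal_loops)
    out["longest_internal_loop"] = float(dup.longest_internal_loop)
    out["gu_wobble_count"] = float(dup.gu_wobbles)
    out["dangling_end_len"] = float(dup.dangling_end_len)
    out["au_pairs_seed"] = float(_au_pair_count(dup, range(2, 9)))
    out["au_pairs_supplementary"] = float(_au_pair_count(dup, range(13, min(16, L) + 1)))
    out["au_pairs_total"] = float(_au_pair_count(dup, range(1, L + 1)))
    for name, fl in (("au_content_upflank", upflank), ("au_content_downflank", downflank)):
        fl = fl.upper().replace("U", "T")
        out[name] = (
            sum(1 for b in fl if b in "AT") / len(fl) if fl else 0.0
        )
    # pairing composition: base fractions within each (side, paired) class
    site_paired = [dup.site_sequence[i] for i in dup.pair_map.values()]
    site_unpaired = [
        b
        for i, b in enumerate(dup.site_sequence)
        if i not in set(dup.pair_map.values())
    ]
    mir_paired = [dup.mirna.sequence[j - 1] for j in dup.pair_map]
    mir_unpaired = [
        dup.mirna.sequence[j - 1] for j in range(1, L + 1) if j not in dup.pair_map
    ]
    for cls, bases in (
        ("site_paired", site_paired),
        ("site_unpaired", site_unpaired),
        ("mirna_paired", mir_paired),
        ("mirna_unpaired", mir_unpaired),
    ):
        n = len(bases)
        for b in "ACGT":
            out[f"comp_{b}_{cls}"] = bases.count(b) / n if n else 0.0
    return out


def mre_general_features(
    mre_interval: GenomicInterval, cluster: Cluster, dup: Duplex
) -> Dict[str, float]:
    """Geometry of the MRE within its cluster plus duplex-level skews."""
    iv = cluster.interval
    out: Dict[str, float] = {}
    out["mre_cluster_overlap"] = (
        mre_interval.overlap_len(iv) / mre_interval.length()
    )
    mid = (mre_interval.start + mre_interval.end) / 2.0
    rel = (mid - iv.start) / iv.length()
    out["mre_rel_location"] = float(min(1.0, max(0.0, rel)))
    out["binding_type_code"] = float(dup.binding_type_code)
    paired = "".join(dup.site_sequence[i] for i in dup.pair_map.values())
    gc, at, purine, _ = skews(paired)
    out["paired_gc_skew"] = gc
    out["paired_at_skew"] = at
    out["paired_purine_skew"] = purine
    L = len(dup.mirna)
    out["mirna_paired_ratio"] = len(dup.pair_map) / L
    out["site_paired_ratio"] = len(dup.pair_map) / len(dup.site_sequence)
    return out


# ---------------------------------------------------------------------------
# assembly


def assemble(
    sub_vectors: Iterable[Dict[str, float]],
    imputed: Optional[Dict[str, bool]] = None,
) -> FeatureVector:
    """Merge producer outputs into the canonical 131-feature vector.

    Order-independent: features are re-ordered to the catalogue order; a
    missing producer fails with the absent feature names.
    """
    merged: Dict[str, float] = {}
    for sub in sub_vectors:
        merged.update(sub)
    missing = [n for n in FEATURE_NAMES if n not in merged]
    if missing:
        raise ValueError(f"missing features: {missing[:8]}")
    extra = set(merged) - set(FEATURE_NAMES)
    if extra:
        raise ValueError(f"unknown features: {sorted(extra)[:8]}")
    values = pd.Series([float(merged[n]) for n in FEATURE_NAMES], index=FEATURE_NAMES)
    return FeatureVector(values, dict(imputed or {}))
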