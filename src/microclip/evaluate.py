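"""Functional-evaluation statistics for predicted miRNA targets.

Implements the downstream readouts used to judge CLIP-guided predictions
against miRNA perturbation experiments: gene-level collapsing (max site
score per miRNA-gene pair), median fold-change versus top-N curves with
random-gene resampling bands, cumulative-distribution group comparisons
(two-sided rank-sum and one-sided Kolmogorov-Smirnov), precision versus
total-prediction curves against a validated-interaction set, and
fold-change-based labeling of perturbation responses.
"""

from __future__ import annotations

import warnings
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

PLATFORMS = ("microarray", "psilac", "rnaseq", "rpf")


def load_fold_changes(path, drop_zero: bool = True) -> pd.Series:
    """gene_id -> log2FC from a 2-column TSV; zero-FC genes droppable."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "log2fc"], comment="#")
    s = df.set_index("gene")["log2fc"].astype(float)
    if s.index.duplicated().any():
        raise ValueError("duplicate gene ids in fold-change table")
    if drop_zero:
        s = s[s != 0.0]
    return s


def collapse_to_genes(predictions: pd.DataFrame) -> pd.DataFrame:
    """One row per (miRNA, gene): the max site score and its argmax site.

    Ties broken deterministically by genomic position (chrom, start, end).
    """
    df = predictions.sort_values(
        ["mirna", "gene", "score", "chrom", "start", "end"],
        ascending=[True, True, False, True, True, True],
        kind="mergesort",
    )
    return df.groupby(["mirna", "gene"], as_index=False).first()


def median_fc_curve(
    gene_predictions: pd.DataFrame,
    fc: pd.Series,
    steps: Sequence[int],
) -> pd.DataFrame:
    """Median log2FC of the top-N predicted genes for each step N.

    Predictions are ranked by descending score; genes absent from the
    fold-change table are skipped without consuming rank slots.
    """
    ranked = gene_predictions.sort_values(
        ["score", "gene"], ascending=[False, True], kind="mergesort"
    )
    fcs = [fc[g] for g in ranked["gene"] if g in fc.index]
    rows = []
    for n in steps:
        if n <= 0:
            continue
        if n > len(fcs):
            warnings.warn(f"top-{n} exceeds available genes ({len(fcs)}); curve truncated")
            break
        rows.append({"top_n": n, "median_log2fc": float(np.median(fcs[:n]))})
    return pd.DataFrame(rows)


def random_gene_band(
    fc: pd.Series,
    steps: Sequence[int],
    n_genes: int = 1000,
    resamples: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Random-gene reference: per step, the median and min..max envelope of
    per-resample mean log2FC over ``n_genes`` genes drawn without
    replacement (zero-FC genes excluded before sampling)."""
    pool = fc[fc != 0.0].to_numpy(float)
    if len(pool) < n_genes:
        raise ValueError(f"fold-change table has {len(pool)} nonzero genes < {n_genes}")
    rng = np.random.default_rng(seed)
    draws = np.vstack(
        [rng.choice(pool, size=n_genes, replace=False) for _ in range(resamples)]
    )
    rows = []
    for n in steps:
        if n <= 0 or n > n_genes:
            continue
        means = draws[:, :n].mean(axis=1)
        rows.append(
            {
                "top_n": n,
                "median": float(np.median(means)),
                "lo": float(means.min()),
                "hi": float(means.max()),
            }
        )
    return pd.DataFrame(rows)


def cdf_compare(
    groups: Mapping[str, Sequence[float]],
    reference: str = "no_site",
    alternative: str = "less",
) -> pd.DataFrame:
    """Each group versus the reference (no-site) group: two-sided
    Wilcoxon rank-sum and one-sided Kolmogorov-Smirnov p-values.

    ``alternative='less'`` tests whether the group's fold changes are
    stochastically smaller (stronger repression) than the reference. The
    rank-sum test uses the exact null distribution at small sample sizes.
    """
    if alternative not in ("less", "greater"):
        raise ValueError("alternative must be 'less' or 'greater'")
    clean = {}
    for label, vals in groups.items():
        vals = np.asarray(list(vals), float)
        if len(vals) == 0:
            warnings.warn(f"group {label} is empty; omitted")
            continue
        clean[label] = vals
    if reference not in clean:
        raise ValueError(f"reference group {reference!r} missing or empty")
    ref = clean[reference]
    rows = []
    for label, vals in clean.items():
        if label == reference:
            continue
        if len(vals) < 3 or len(ref) < 3:
            warnings.warn(f"group {label}: n < 3; statistics skipped")
            continue
        rs = sps.mannwhitneyu(vals, ref, alternative="two-sided", method="auto")
        # scipy's KS `alternative` is phrased on CDFs: stochastically
        # smaller values mean a *larger* empirical CDF, hence 'greater'
        ks_alt = "greater" if alternative == "less" else "less"
        ks = sps.ks_2samp(vals, ref, alternative=ks_alt)
        rows.append(
            {
                "group": label,
                "n": len(vals),
                "n_ref": len(ref),
                "ranksum_p": float(rs.pvalue),
                "ks_stat": float(ks.statistic),
                "ks_p": float(ks.pvalue),
            }
        )
    return pd.DataFrame(rows)


def precision_curve(
    predictions: pd.DataFrame,
    truth: pd.DataFrame,
    thresholds: Sequence[float],
    mode: str = "all_sites",
    min_overlap: int = 1,
) -> pd.DataFrame:
    """(total, correct) prediction counts per score threshold.

    Site-level match: same miRNA and >= ``min_overlap`` bp overlap with a
    validated site; gene-level match: same (miRNA, gene).
    ``mode='top_per_cluster'`` keeps only the top-scored site per cluster
    (requires a ``cluster_id`` column) before thresholding.
    """
    df = predictions.copy()
    if mode == "top_per_cluster":
        df = (
            df.sort_values(["cluster_id", "score"], ascending=[True, False], kind="mergesort")
            .groupby("cluster_id", as_index=False)
            .first()
        )
    if mode == "gene_level":
        df = collapse_to_genes(df)
        truth_pairs = set(zip(truth["mirna"], truth["gene"]))
        df["correct"] = [
            (m, g) in truth_pairs for m, g in zip(df["mirna"], df["gene"])
        ]
    else:
        by_mirna: Dict[str, List[Tuple[str, int, int]]] = {}
        for r in truth.itertuples():
            by_mirna.setdefault(r.mirna, []).append((r.chrom, int(r.start), int(r.end)))
        correct = []
        for r in df.itertuples():
            hits = by_mirna.get(r.mirna, ())
            correct.append(
                any(
                    c == r.chrom
                    and min(int(r.end), e) - max(int(r.start), s) >= min_overlap
                    for c, s, e in hits
                )
            )
        df["correct"] = correct
    rows = []
    for t in sorted(thresholds, reverse=True):
        sel = df[df["score"] >= t]
        rows.append(
            {
                "threshold": float(t),
                "total": int(len(sel)),
                "correct": int(sel["correct"].sum()),
            }
        )
    return pd.DataFrame(rows)


def label_from_perturbation(
    fc: pd.Series,
    platform: str,
    perturbation: str = "transfection",
    expression: Optional[pd.Series] = None,
) -> pd.Series:
    """Per-gene {positive, negative, unlabeled} from log2 fold changes.

    microarray/pSILAC use a strict |log2FC| > 1 cutoff; RNA-Seq and
    ribosome profiling use |log2FC| > 0.5 restricted to genes with
    > 10 RPKM expression. Direction follows the perturbation: repression
    after transfection (or induction after knockdown) is positive target
    evidence; the opposite tail is negative; boundary values are unlabeled.
    """
    if platform not in PLATFORMS:
        raise ValueError(f"platform must be one of {PLATFORMS}")
    if platform in ("rnaseq", "rpf"):
        if expression is None:
            raise ValueError(f"{platform} labeling requires an expression table")
        cutoff = 0.5
    else:
        cutoff = 1.0
    sign = -1.0 if perturbation == "transfection" else 1.0
    labels = {}
    for gene, v in fc.items():
        if platform in ("rnaseq", "rpf") and expression.get(gene, 0.0) <= 10.0:
            labels[gene] = "unlabeled"
            continue
        if sign * v > cutoff:
            labels[gene] = "positive"
        elif sign * v < -cutoff:
            labels[gene] = "negative"
        else:
            labels[gene] = "unlabeled"
    return pd.Series(labels)
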