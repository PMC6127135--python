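"""End-to-end synthetic study workflows.

These orchestrate the full pipeline on generated data with known truth:
simulate an aligned PAR-CLIP-like library, call and classify clusters,
scan/fold/featurize candidate sites, train the super learner on
truth-labeled instances, score everything, and measure the functional
shift of predicted targets in a simulated miRNA perturbation.
"""

from __future__ import annotations

import warnings
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .clusters import call_clusters, classify_t2c, cluster_rpkm
from .evaluate import cdf_compare, collapse_to_genes
from .genomic_io import SequenceStore
from .learner import LearnerConfig, train_super_learner
from .pipeline import assign_genes, featurize_cluster
from .simulate import SimulationConfig, simulate_library, simulate_perturbation


def discover_labeled_sites(sim, t2c_threshold: float = 0.20) -> pd.DataFrame:
    """Featurize all clusters of a simulated library and label candidates
    against the planted truth (same miRNA, >= 1 bp overlap)."""
    ref = SequenceStore(sim.genome)
    clusters = call_clusters(sim.reads)
    frames = []
    for ci, c in enumerate(clusters):
        classify_t2c(c, t2c_threshold)
        cluster_rpkm(c, sim.stats)
        df = featurize_cluster(c, ref, sim.mirnas, sim.stats)
        if len(df):
            df["cluster_id"] = ci
            frames.append(df)
    sites = pd.concat(frames, ignore_index=True)
    sites = assign_genes(sites, sim.transcripts)
    planted = sim.truth[sim.truth.has_mre]
    by_mirna: Dict[str, list] = {}
    for r in planted.itertuples():
        by_mirna.setdefault(r.mirna, []).append((r.chrom, r.mre_start, r.mre_end))
    labels = []
    for r in sites.itertuples():
        hits = by_mirna.get(r.mirna, ())
        labels.append(
            int(
                any(
                    c == r.chrom and r.start < e and r.end > s
                    for c, s, e in hits
                )
            )
        )
    sites["label"] = labels
    return sites


def partition_sites(sites: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Assign base/meta/test partitions by MRE region, label-stratified
    (50/25/25)."""
    rng = np.random.default_rng(seed + 101)
    sites = sites.copy()
    parts = pd.Series(index=sites.index, dtype=object)
    for cls in (0, 1):
        regions = sites.loc[sites.label == cls, "region_id"].unique()
        regions = rng.permutation(regions)
        n1 = int(round(len(regions) * 0.5))
        n2 = int(round(len(regions) * 0.75))
        lookup = {}
        for r in regions[:n1]:
            lookup[r] = "base_train"
        for r in regions[n1:n2]:
            lookup[r] = "meta_train"
        for r in regions[n2:]:
            lookup[r] = "test"
        sel = sites.label == cls
        parts[sel] = sites.loc[sel, "region_id"].map(lookup)
    sites["partition"] = parts
    return sites


def end_to_end_functional_shift(
    seed: int,
    n_clusters: int = 200,
    n_mirnas: int = 15,
    cluster_span: int = 61,
    planted_mre_fraction: float = 0.5,
    score_threshold: float = 0.5,
    n_extra_genes: int = 450,
    cv_folds: int = 5,
    min_train: int = 20,
    learner_config: Optional[LearnerConfig] = None,
) -> Dict:
    """Simulated library -> train -> predict -> simulated transfection.

    Returns the one-sided KS statistics comparing the fold-change CDF of
    predicted-target genes against genes with no predicted site, plus the
    intermediates (sites table, model, fold changes).
    """
    cfg = SimulationConfig(
        seed=seed,
        n_clusters=n_clusters,
        n_mirnas=n_mirnas,
        cluster_span=cluster_span,
        planted_mre_fraction=planted_mre_fraction,
    )
    sim = simulate_library(cfg)
    sites = discover_labeled_sites(sim)
    sites = partition_sites(sites, seed)
    lcfg = learner_config or LearnerConfig(
        seed=seed, cv_folds=cv_folds, min_train=min_train
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = train_super_learner(sites, lcfg)
    sites["score"] = model.predict(sites)

    gene_view = collapse_to_genes(sites[sites.gene != ""])
    best = gene_view.groupby("gene")["score"].max()
    predicted = set(best[best >= score_threshold].index)

    transcript_genes = [t.gene_id for t in sim.transcripts]
    extra = [f"null{i:04d}" for i in range(n_extra_genes)]
    all_genes = transcript_genes + extra
    true_targets = set(sim.truth.loc[sim.truth.has_mre, "gene_id"])
    fc = simulate_perturbation(cfg, true_targets, all_genes)
    fc = fc[fc != 0.0]

    no_site = [g for g in all_genes if g not in predicted and g in fc.index]
    pred_in_fc = [g for g in predicted if g in fc.index]
    stats = cdf_compare(
        {"predicted": fc[pred_in_fc], "no_site": fc[no_site]},
        reference="no_site",
        alternative="less",
    )
    return {
        "sites": sites,
        "model": model,
        "fold_changes": fc,
        "predicted_genes": sorted(predicted),
        "true_targets": sorted(true_targets),
        "ks_p": float(stats.loc[0, "ks_p"]),
        "ranksum_p": float(stats.loc[0, "ranksum_p"]),
        "n_predicted": len(pred_in_fc),
        "n_no_site": len(no_site),
    }
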