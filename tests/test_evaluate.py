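import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from microclip.evaluate import (
    cdf_compare,
    collapse_to_genes,
    label_from_perturbation,
    load_fold_changes,
    median_fc_curve,
    precision_curve,
    random_gene_band,
)
from microclip.simulate import SimulationConfig, simulate_perturbation


def pred_frame(rows):
    return pd.DataFrame(
        rows, columns=["mirna", "gene", "chrom", "start", "end", "strand", "score"]
    )


def test_gene_collapsing_keeps_the_best_site():
    df = pred_frame(
        [
            ("m1", "g1", "chr1", 100, 120, "+", 0.3),
            ("m1", "g1", "chr1", 300, 320, "+", 0.9),
            ("m1", "g2", "chr1", 500, 520, "+", 0.5),
        ]
    )
    out = collapse_to_genes(df)
    assert len(out) == 2
    assert out.set_index("gene").loc["g1", "score"] == 0.9
    assert out.set_index("gene").loc["g1", "start"] == 300


def test_gene_collapsing_ties_break_by_genomic_position():
    df = pred_frame(
        [
            ("m1", "g1", "chr1", 300, 320, "+", 0.7),
            ("m1", "g1", "chr1", 100, 120, "+", 0.7),
        ]
    )
    out = collapse_to_genes(df)
    assert out.loc[0, "start"] == 100


def test_gene_collapsing_matches_groupby_max_on_random_sets():
    rng = np.random.default_rng(4)
    rows = [
        (
            f"m{rng.integers(3)}",
            f"g{rng.integers(20)}",
            "chr1",
            int(s),
            int(s) + 20,
            "+",
            float(rng.random()),
        )
        for s in rng.integers(0, 10000, 200)
    ]
    df = pred_frame(rows)
    out = collapse_to_genes(df)
    want = df.groupby(["mirna", "gene"])["score"].max()
    for r in out.itertuples():
        assert r.score == want[(r.mirna, r.gene)]


def test_median_fc_curve_on_small_example():
    preds = pd.DataFrame(
        {"mirna": "m", "gene": ["a", "b", "c"], "score": [0.9, 0.8, 0.7]}
    )
    fc = pd.Series({"a": -1.0, "b": -2.0, "c": -3.0})
    curve = median_fc_curve(preds, fc, steps=[1, 2, 3])
    assert list(curve.median_log2fc) == [-1.0, -1.5, -2.0]


def test_constant_fold_changes_give_flat_curve():
    preds = pd.DataFrame(
        {"mirna": "m", "gene": [f"g{i}" for i in range(20)], "score": np.linspace(1, 0, 20)}
    )
    fc = pd.Series({f"g{i}": 0.7 for i in range(20)})
    curve = median_fc_curve(preds, fc, steps=[5, 10, 20])
    assert (curve.median_log2fc == 0.7).all()


def test_median_curve_matches_resort_oracle_and_skips_missing_genes():
    rng = np.random.default_rng(6)
    genes = [f"g{i}" for i in range(60)]
    preds = pd.DataFrame(
        {"mirna": "m", "gene": genes, "score": rng.random(60)}
    )
    fc = pd.Series(rng.normal(size=40), index=genes[:40])
    curve = median_fc_curve(preds, fc, steps=[5, 10, 20, 40])
    ranked = preds.sort_values(["score", "gene"], ascending=[False, True], kind="mergesort")
    avail = [fc[g] for g in ranked.gene if g in fc.index]
    for r in curve.itertuples():
        assert r.median_log2fc == pytest.approx(np.median(avail[: r.top_n]))
    with pytest.warns(UserWarning):
        truncated = median_fc_curve(preds, fc, steps=[30, 50])
    assert list(truncated.top_n) == [30]


def test_random_band_collapses_on_constant_fold_changes():
    fc = pd.Series(0.5, index=[f"g{i}" for i in range(1500)])
    band = random_gene_band(fc, steps=[100, 1000], seed=5)
    assert (band["lo"] == 0.5).all() and (band["hi"] == 0.5).all()


def test_random_band_is_deterministic_and_centered():
    rng = np.random.default_rng(7)
    fc = pd.Series(rng.normal(size=3000), index=[f"g{i}" for i in range(3000)])
    a = random_gene_band(fc, steps=[1000], seed=3)
    b = random_gene_band(fc, steps=[1000], seed=3)
    pd.testing.assert_frame_equal(a, b)
    assert abs(a.loc[0, "median"]) < 0.1  # CLT at n=1000


def test_random_band_requires_enough_genes():
    fc = pd.Series(np.ones(100), index=[f"g{i}" for i in range(100)])
    with pytest.raises(ValueError):
        random_gene_band(fc, steps=[10], n_genes=1000)


def test_identical_groups_have_null_ks_statistic():
    vals = list(np.random.default_rng(8).normal(size=50))
    out = cdf_compare({"a": vals, "no_site": vals})
    assert out.loc[0, "ks_stat"] == pytest.approx(0.0, abs=1e-12)
    assert out.loc[0, "ks_p"] > 0.9


def test_shifted_group_is_detected_by_one_sided_ks():
    rng = np.random.default_rng(9)
    null = rng.normal(size=200)
    shifted = rng.normal(-1.0, 1.0, size=200)
    out = cdf_compare({"target": shifted, "no_site": null}, alternative="less")
    assert out.loc[0, "ks_p"] < 1e-6
    assert out.loc[0, "ranksum_p"] < 1e-6


def test_ranksum_matches_exact_enumeration_for_tiny_groups():
    a = [1.2, -0.3, 0.8, 2.0, -1.5]
    b = [0.1, 0.4, -0.9, 1.1, 0.6]
    got = cdf_compare({"a": a, "no_site": b}).loc[0, "ranksum_p"]
    # exact two-sided rank-sum by full enumeration of 10 choose 5 labelings
    pooled = a + b
    ranks = sps.rankdata(pooled)
    w_obs = ranks[:5].sum()
    n = 0
    extreme = 0
    mu = 5 * 11 / 2
    for idx in itertools.combinations(range(10), 5):
        w = ranks[list(idx)].sum()
        n += 1
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            extreme += 1
    assert got == pytest.approx(extreme / n, abs=0.02)


def test_precision_curve_is_exact_for_identical_sets():
    truth = pd.DataFrame(
        {
            "mirna": ["m1", "m2"],
            "gene": ["g1", "g2"],
            "chrom": ["chr1", "chr1"],
            "start": [100, 500],
            "end": [120, 520],
        }
    )
    preds = pred_frame(
        [
            ("m1", "g1", "chr1", 100, 120, "+", 0.9),
            ("m2", "g2", "chr1", 500, 520, "+", 0.4),
        ]
    )
    out = precision_curve(preds, truth, thresholds=[0.1, 0.5, 0.95])
    for r in out.itertuples():
        assert r.correct == r.total


def test_precision_curve_zero_for_disjoint_sets():
    truth = pd.DataFrame(
        {"mirna": ["mX"], "gene": ["gX"], "chrom": ["chr9"], "start": [0], "end": [10]}
    )
    preds = pred_frame([("m1", "g1", "chr1", 100, 120, "+", 0.9)])
    out = precision_curve(preds, truth, thresholds=[0.1, 0.5])
    assert (out.correct == 0).all()


def test_precision_curve_monotone_and_matches_allpairs_matching():
    rng = np.random.default_rng(10)
    truth = pd.DataFrame(
        {
            "mirna": [f"m{rng.integers(3)}" for _ in range(30)],
            "gene": [f"g{i}" for i in range(30)],
            "chrom": "chr1",
            "start": rng.integers(0, 5000, 30),
        }
    ).assign(end=lambda d: d.start + 20)
    preds = pred_frame(
        [
            (
                f"m{rng.integers(3)}",
                f"g{rng.integers(40)}",
                "chr1",
                int(s),
                int(s) + 20,
                "+",
                float(rng.random()),
            )
            for s in rng.integers(0, 5000, 100)
        ]
    )
    thresholds = [0.0, 0.2, 0.4, 0.6, 0.8]
    out = precision_curve(preds, truth, thresholds)
    assert list(out.total) == sorted(out.total)  # loosening only adds
    assert (out.correct <= out.total).all()
    # brute-force per-threshold matching
    for r in out.itertuples():
        sel = preds[preds.score >= r.threshold]
        n_correct = 0
        for p in sel.itertuples():
            ok = any(
                t.mirna == p.mirna
                and t.chrom == p.chrom
                and min(t.end, p.end) - max(t.start, p.start) >= 1
                for t in truth.itertuples()
            )
            n_correct += ok
        assert r.correct == n_correct


def test_perturbation_labels_follow_platform_thresholds():
    fc = pd.Series({"a": -1.2, "b": -0.6, "c": 1.5, "d": -1.0})
    labels = label_from_perturbation(fc, "microarray", "transfection")
    assert labels["a"] == "positive"
    assert labels["b"] == "unlabeled"
    assert labels["c"] == "negative"
    assert labels["d"] == "unlabeled"  # boundary is strict


def test_rnaseq_labels_gate_on_expression():
    fc = pd.Series({"a": -0.6, "b": -0.6})
    expr = pd.Series({"a": 5.0, "b": 50.0})
    labels = label_from_perturbation(fc, "rnaseq", "transfection", expr)
    assert labels["a"] == "unlabeled"
    assert labels["b"] == "positive"
    with pytest.raises(ValueError):
        label_from_perturbation(fc, "rnaseq", "transfection")


def test_knockdown_flips_the_positive_direction():
    fc = pd.Series({"a": 1.5, "b": -1.5})
    labels = label_from_perturbation(fc, "psilac", "knockdown")
    assert labels["a"] == "positive" and labels["b"] == "negative"


def test_simulated_knockdown_mirrors_transfection():
    cfg = SimulationConfig(seed=5, effect_size=2.0, zero_fc_fraction=0.0)
    genes = [f"g{i}" for i in range(500)]
    targets = genes[:50]
    up = simulate_perturbation(cfg, targets, genes, "knockdown")
    down = simulate_perturbation(cfg, targets, genes, "transfection")
    shift = up[targets] - down[targets]
    np.testing.assert_allclose(shift, 4.0, atol=1e-9)


def test_strong_transfection_effect_labels_most_targets_positive():
    cfg = SimulationConfig(seed=6, effect_size=2.0, fc_sigma=0.3, zero_fc_fraction=0.0)
    genes = [f"g{i}" for i in range(2000)]
    targets = genes[:200]
    fc = simulate_perturbation(cfg, targets, genes)
    labels = label_from_perturbation(fc, "microarray", "transfection")
    frac = (labels[targets] == "positive").mean()
    assert frac >= 0.95  # P(N(-2, 0.3) < -1) ~ 0.9996


def test_null_effect_yields_only_false_positive_rate_labels():
    cfg = SimulationConfig(seed=7, effect_size=0.0, fc_sigma=0.4, zero_fc_fraction=0.0)
    genes = [f"g{i}" for i in range(2000)]
    fc = simulate_perturbation(cfg, genes[:200], genes)
    labels = label_from_perturbation(fc, "microarray", "transfection")
    assert (labels == "positive").mean() < 0.02


def test_fold_change_loader_drops_zero_fc_genes(tmp_path):
    p = tmp_path / "fc.tsv"
    p.write_text("g1\t-1.5\ng2\t0.0\ng3\t0.8\n")
    fc = load_fold_changes(p)
    assert list(fc.index) == ["g1", "g3"]
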