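"""Two-layer stacked super learner for MRE scoring.

Layer 1 holds nine base nodes, each specialized on one feature subset of the
131-descriptor catalogue. Node 1 ("region features") is a single random
forest; nodes 2-9 each stack seven internal members (2 random forests,
2 gradient-boosting models, 2 feed-forward networks, 1 generalized linear
model) whose out-of-fold probabilities are weighed by a small feed-forward
combiner. Layer 2 is a gradient-boosting meta-learner over the nine node
scores, trained on an instance set disjoint (by MRE region) from the base
training set. A T-to-C-only variant retrains the identical architecture on
instances originating from T-to-C clusters.

The feed-forward members use three hidden layers with rectifier activations
and a log-loss objective; regularization is L2 (``alpha``). Hidden widths
(64/32/16 and 32/16/8) and the 8-unit combiner width are package defaults.
One master seed fans out deterministically to every member.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import joblib
import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import (
    GradientBoostingClassifier,
    HistGradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .features import FEATURE_NAMES, NODE_FEATURES

LABEL_COL = "label"
REGION_COL = "region_id"
ORIGIN_COL = "origin_cluster_class"
PARTITION_COL = "partition"

PARTITIONS = ("base_train", "meta_train", "test")

MEMBER_ORDER = ["rf_a", "rf_b", "gbm_a", "gbm_b", "dl_a", "dl_b", "glm"]


@dataclass
class LearnerConfig:
    seed: int = 0
    cv_folds: int = 10
    min_train: int = 200
    ensembler_width: int = 8
    # small documented grids; a single point by default so training stays
    # within minutes at fixture scale
    grids: Dict[str, List[dict]] = field(default_factory=dict)

    def architecture_hash(self) -> str:
        payload = json.dumps(
            {
                "members": MEMBER_ORDER,
                "cv_folds": self.cv_folds,
                "ensembler_width": self.ensembler_width,
                "grids": {k: sorted(map(str, v)) for k, v in self.grids.items()},
                "nodes": {k: v for k, v in sorted(NODE_FEATURES.items())},
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _member_estimators(seed: int) -> Dict[str, object]:
    rng = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in rng.spawn(7)]

    def mlp(hidden, alpha, s):
        return Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "mlp",
                    MLPClassifier(
                        hidden_layer_sizes=hidden,
                        activation="relu",
                        alpha=alpha,
                        max_iter=300,
                        random_state=s,
                    ),
                ),
            ]
        )

    return {
        "rf_a": RandomForestClassifier(
            n_estimators=80, max_features="sqrt", random_state=seeds[0], n_jobs=1
        ),
        "rf_b": RandomForestClassifier(
            n_estimators=120,
            max_features="log2",
            min_samples_leaf=2,
            random_state=seeds[1],
            n_jobs=1,
        ),
        "gbm_a": HistGradientBoostingClassifier(
            max_iter=100, max_depth=3, learning_rate=0.1, random_state=seeds[2]
        ),
        "gbm_b": HistGradientBoostingClassifier(
            max_iter=150, max_depth=2, learning_rate=0.05, random_state=seeds[3]
        ),
        "dl_a": mlp((64, 32, 16), 1e-3, seeds[4]),
        "dl_b": mlp((32, 16, 8), 1e-2, seeds[5]),
        "glm": Pipeline(
            [
                ("scale", StandardScaler()),
                ("glm", LogisticRegression(max_iter=1000, random_state=seeds[6])),
            ]
        ),
    }


def _region_rf(seed: int):
    return RandomForestClassifier(
        n_estimators=200, max_features="sqrt", random_state=seed, n_jobs=1
    )


def _oof_probabilities(est, X, y, folds, seed):
    """Out-of-fold positive-class probabilities plus a full-data fit."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    oof = np.zeros(len(y))
    for tr, te in skf.split(X, y):
        m = clone(est)
        m.fit(X[tr], y[tr])
        oof[te] = m.predict_proba(X[te])[:, 1]
    final = clone(est)
    final.fit(X, y)
    return oof, final


def _grid_select(name, base_est, grid, X, y, seed):
    """Pick the grid point with the best small internal CV AUC."""
    if not grid or len(grid) <= 1:
        if grid:
            base_est = clone(base_est).set_params(**grid[0])
        return base_est
    best, best_auc = None, -np.inf
    skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
    for params in grid:
        est = clone(base_est).set_params(**params)
        aucs = []
        for tr, te in skf.split(X, y):
            m = clone(est)
            m.fit(X[tr], y[tr])
            aucs.append(roc_auc_score(y[te], m.predict_proba(X[te])[:, 1]))
        mean = float(np.mean(aucs))
        if mean > best_auc:
            best, best_auc = est, mean
    return best


@dataclass
class BaseNodeModel:
    node_id: int
    feature_names: List[str]
    members: Dict[str, object]  # fitted members (node 1: single 'rf')
    ensembler: Optional[object]  # fitted combiner, None for node 1
    cv_auc: float
    member_cv_auc: Dict[str, float] = field(default_factory=dict)

    def member_matrix(self, X: np.ndarray) -> np.ndarray:
        return np.column_stack(
            [self.members[m].predict_proba(X)[:, 1] for m in MEMBER_ORDER]
        )

    def score(self, fv: pd.DataFrame) -> np.ndarray:
        X = fv[self.feature_names].to_numpy(float)
        if self.ensembler is None:
            return self.members["rf"].predict_proba(X)[:, 1]
        return self.ensembler.predict_proba(self.member_matrix(X))[:, 1]


def _check_partitions(df: pd.DataFrame) -> None:
    by_part = {
        p: set(df.loc[df[PARTITION_COL] == p, REGION_COL]) for p in PARTITIONS
    }
    for a in PARTITIONS:
        for b in PARTITIONS:
            if a < b and by_part[a] & by_part[b]:
                raise ValueError(
                    f"MRE-region leakage between partitions {a} and {b}: "
                    f"{sorted(by_part[a] & by_part[b])[:3]}"
                )


def _validate_features(df: pd.DataFrame) -> None:
    missing = [c for c in FEATURE_NAMES if c not in df.columns]
    if missing:
        raise ValueError(f"missing feature columns: {missing[:8]}")


def train_base_nodes(
    instances: pd.DataFrame, config: Optional[LearnerConfig] = None
) -> Dict[int, BaseNodeModel]:
    """Train the nine base nodes on the base_train partition.

    Each node sees only its feature subset; member out-of-fold predictions
    train the node's combiner (standard stacking hygiene) and provide the
    recorded cross-validation metrics.
    """
    config = config or LearnerConfig()
    _validate_features(instances)
    df = instances[instances[PARTITION_COL] == "base_train"]
    y = df[LABEL_COL].to_numpy(int)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("single-class training data")
    for cls in classes:
        if (y == cls).sum() < config.min_train:
            raise ValueError(
                f"class {cls}: {(y == cls).sum()} instances < min_train={config.min_train}"
            )
    master = np.random.SeedSequence(config.seed)
    node_seeds = [
        int(s.generate_state(1)[0] % (2**31 - 1)) for s in master.spawn(9)
    ]
    nodes: Dict[int, BaseNodeModel] = {}
    for node_id in range(1, 10):
        feats = NODE_FEATURES[node_id]
        X = df[feats].to_numpy(float)
        seed = node_seeds[node_id - 1]
        if node_id == 1:
            rf = _region_rf(seed)
            oof, fitted = _oof_probabilities(rf, X, y, config.cv_folds, seed)
            nodes[node_id] = BaseNodeModel(
                node_id, feats, {"rf": fitted}, None, float(roc_auc_score(y, oof))
            )
            continue
        estimators = _member_estimators(seed)
        oof_cols, fitted_members, member_auc = [], {}, {}
        for name in MEMBER_ORDER:
            est = _grid_select(
                name, estimators[name], config.grids.get(name, []), X, y, seed
            )
            oof, fitted = _oof_probabilities(est, X, y, config.cv_folds, seed)
            oof_cols.append(oof)
            fitted_members[name] = fitted
            member_auc[name] = float(roc_auc_score(y, oof))
        M = np.column_stack(oof_cols)
        ens = Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "mlp",
                    MLPClassifier(
                        hidden_layer_sizes=(config.ensembler_width,),
                        activation="relu",
                        max_iter=800,
                        random_state=seed,
                    ),
                ),
            ]
        )
        ens_oof, ens_fitted = _oof_probabilities(
            ens, M, y, config.cv_folds, seed
        )
        nodes[node_id] = BaseNodeModel(
            node_id,
            feats,
            fitted_members,
            ens_fitted,
            float(roc_auc_score(y, ens_oof)),
            member_auc,
        )
    return nodes


@dataclass
class SuperLearnerModel:
    nodes: Dict[int, BaseNodeModel]
    meta: object
    config: LearnerConfig
    variant: str = "full"  # or "t2c_only"
    report: Dict = field(default_factory=dict)

    def node_scores(self, fv: pd.DataFrame) -> np.ndarray:
        missing = [c for c in FEATURE_NAMES if c not in fv.columns]
        if missing:
            raise ValueError(f"missing features at predict time: {missing[:8]}")
        return np.column_stack(
            [self.nodes[i].score(fv) for i in range(1, 10)]
        )

    def predict(self, fv: pd.DataFrame, return_nodes: bool = False):
        """Final super-learner probability per row (and optionally the
        nine per-node scores)."""
        S = self.node_scores(fv)
        p = self.meta.predict_proba(S)[:, 1]
        if return_nodes:
            return p, S
        return p

    def save(self, path) -> None:
        """Versioned model archive directory."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        meta_info = {
            "variant": self.variant,
            "seed": self.config.seed,
            "architecture_hash": self.config.architecture_hash(),
            "n_features": len(FEATURE_NAMES),
        }
        (path / "config.json").write_text(json.dumps(meta_info, indent=1))
        (path / "report.json").write_text(json.dumps(self.report, indent=1))
        joblib.dump(
            {"nodes": self.nodes, "meta": self.meta, "config": self.config,
             "variant": self.variant, "report": self.report},
            path / "model.joblib",
        )

    @classmethod
    def load(cls, path) -> "SuperLearnerModel":
        payload = joblib.load(Path(path) / "model.joblib")
        return cls(
            payload["nodes"], payload["meta"], payload["config"],
            payload["variant"], payload["report"],
        )


def train_meta(
    instances: pd.DataFrame,
    base_models: Dict[int, BaseNodeModel],
    config: Optional[LearnerConfig] = None,
    variant: str = "full",
) -> SuperLearnerModel:
    """Fit the gradient-boosting meta-learner on the meta_train partition."""
    config = config or LearnerConfig()
    _check_partitions(instances)
    df = instances[instances[PARTITION_COL] == "meta_train"]
    y = df[LABEL_COL].to_numpy(int)
    if len(np.unique(y)) < 2:
        raise ValueError("single-class meta training data")
    S = np.column_stack(
        [base_models[i].score(df) for i in range(1, 10)]
    )
    if float(S.std(axis=0).max()) < 1e-9:
        warnings.warn("degenerate meta input: constant node scores")
    meta = GradientBoostingClassifier(
        n_estimators=150,
        max_depth=2,
        learning_rate=0.1,
        random_state=config.seed % (2**31 - 1),
    )
    meta.fit(S, y)
    report = {
        "node_cv_auc": {i: base_models[i].cv_auc for i in base_models},
        "member_cv_auc": {
            i: base_models[i].member_cv_auc for i in base_models
        },
        "meta_train_auc": float(roc_auc_score(y, meta.predict_proba(S)[:, 1])),
    }
    return SuperLearnerModel(base_models, meta, config, variant, report)


def train_super_learner(
    instances: pd.DataFrame, config: Optional[LearnerConfig] = None
) -> SuperLearnerModel:
    """Train base nodes and meta-learner from a partitioned instance table."""
    config = config or LearnerConfig()
    _check_partitions(instances)
    nodes = train_base_nodes(instances, config)
    return train_meta(instances, nodes, config)


def train_t2c_variant(
    instances: pd.DataFrame, config: Optional[LearnerConfig] = None
) -> SuperLearnerModel:
    """Retrain the identical architecture on T-to-C-origin instances only."""
    config = config or LearnerConfig()
    if ORIGIN_COL not in instances.columns:
        raise ValueError(f"instances lack {ORIGIN_COL}")
    sub = instances[instances[ORIGIN_COL] == "T2C"]
    model = train_super_learner(sub, config)
    model.variant = "t2c_only"
    return model
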