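"""Cluster feature vectors and the one-vs-one multiclass SVM.

Each cluster is summarized by 16 features: the 4 per-kind SASA burial
ratios (peptide, drug, Zn2+, NO3-, in %) and the 12 canonical mediated-
triplet probabilities.  A multiclass support-vector machine built from
binary (one-vs-one) linear learners separates cluster classes — in the
intended use, clusters formed with nitrate-coordinating drugs (class 1),
a zinc-coordinating drug (class 2), and weakly encapsulating drugs
(class 3).  Features are standardized with training-set statistics only;
prediction is by majority vote with ties broken toward the lowest class
index.  Models serialize to JSON (weights, means, sds, classes).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .interactions import TRIPLET_PATTERNS
from .topology import Kind

SASA_FEATURE_KINDS = (Kind.PEPTIDE, Kind.DRUG, Kind.ZN, Kind.NO3)
FEATURE_NAMES = tuple(
    f"sasa_{k.value.lower()}" for k in SASA_FEATURE_KINDS
) + tuple(f"tri_{p}" for p in TRIPLET_PATTERNS)
N_FEATURES = len(FEATURE_NAMES)  # 16


def assemble_features(stats_list, triplet_profiles, labels=None) -> pd.DataFrame:
    """One 16-feature row per cluster.

    Parameters
    ----------
    stats_list : list of ClusterStats
        Per-cluster metrics (source of the 4 SASA-ratio features).
    triplet_profiles : list of dict
        Per-cluster triplet probability tables, aligned with
        ``stats_list``; missing patterns are imputed as 0, and a kind
        absent from a cluster contributes SASA 0 (fully absent, not
        exposed).
    labels : sequence, optional
        Class label per cluster; attached as a ``label`` column.
    """
    stats_list = list(stats_list)
    triplet_profiles = list(triplet_profiles)
    if len(stats_list) != len(triplet_profiles):
        raise ValueError("stats and triplet profiles are misaligned")
    if labels is not None and len(labels) != len(stats_list):
        raise ValueError("labels are misaligned with clusters")
    rows = []
    for idx, (s, tp) in enumerate(zip(stats_list, triplet_profiles)):
        row = {}
        for k in SASA_FEATURE_KINDS:
            v = s.sasa_ratio.get(k, math.nan)
            row[f"sasa_{k.value.lower()}"] = 0.0 if (v is None or math.isnan(v)) else v
        for p in TRIPLET_PATTERNS:
            row[f"tri_{p}"] = float(tp.get(p, 0.0))
        if labels is not None:
            row["label"] = labels[idx]
        rows.append(row)
    cols = list(FEATURE_NAMES) + (["label"] if labels is not None else [])
    return pd.DataFrame(rows, columns=cols)


@dataclass
class TrainedClassifier:
    """One-vs-one linear SVM with train-set standardization."""

    classes: list
    mean: np.ndarray
    sd: np.ndarray
    learners: dict          # (class_a, class_b) -> fitted SVC (or weight dict)
    seed: int
    feature_names: tuple = FEATURE_NAMES

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd

    def decision_values(self, X) -> dict:
        """Per-binary-learner signed decision values (positive -> class_a)."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != len(self.mean):
            raise ValueError(
                f"feature dimension {X.shape[1]} does not match model "
                f"({len(self.mean)})"
            )
        Z = self._standardize(X)
        out = {}
        for (a, b), learner in self.learners.items():
            raw = Z @ np.asarray(learner["w"]) + learner["b"]
            # sklearn's positive side corresponds to the second class in
            # its sorted class_ array; orient so positive means class `a`
            out[(a, b)] = raw if learner["pos"] == a else -raw
        return out

    def predict(self, X) -> list:
        """Majority vote over binary learners; ties -> lowest class index."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        dec = self.decision_values(X)
        votes = np.zeros((X.shape[0], len(self.classes)), dtype=int)
        cindex = {c: i for i, c in enumerate(self.classes)}
        for (a, b), vals in dec.items():
            winner_a = vals > 0
            votes[winner_a, cindex[a]] += 1
            votes[~winner_a, cindex[b]] += 1
        # argmax returns the first (lowest-index) maximum: deterministic tie-break
        return [self.classes[i] for i in votes.argmax(axis=1)]

    def feature_weight_report(self) -> pd.DataFrame:
        """Standardized weights of every binary learner, by feature."""
        rows = []
        for (a, b), learner in self.learners.items():
            w = np.asarray(learner["w"])
            for name, wi in zip(self.feature_names, w):
                rows.append(
                    {"pair": f"{a}_vs_{b}", "feature": name, "weight": float(wi)}
                )
        return pd.DataFrame(rows)

    def to_json(self, path=None) -> str:
        payload = {
            "classes": list(self.classes),
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "seed": self.seed,
            "feature_names": list(self.feature_names),
            "learners": [
                {
                    "class_a": a,
                    "class_b": b,
                    "w": list(map(float, learner["w"])),
                    "b": float(learner["b"]),
                    "pos": learner["pos"],
                }
                for (a, b), learner in self.learners.items()
            ],
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "TrainedClassifier":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        data = json.loads(text)
        learners = {
            (e["class_a"], e["class_b"]): {
                "w": np.array(e["w"]),
                "b": e["b"],
                "pos": e["pos"],
            }
            for e in data["learners"]
        }
        return cls(
            classes=data["classes"],
            mean=np.array(data["mean"]),
            sd=np.array(data["sd"]),
            learners=learners,
            seed=data["seed"],
            feature_names=tuple(data["feature_names"]),
        )


def train_multiclass_svm(
    features, labels, seed: int = 0, C: float = 1.0
) -> TrainedClassifier:
    """Fit one linear SVC per class pair on standardized features.

    Requires at least two classes with >= 5 rows each.  Identical
    ``(features, labels, seed)`` give identical models.
    """
    if isinstance(features, pd.DataFrame):
        X = features[list(FEATURE_NAMES)].to_numpy(dtype=float) \
            if set(FEATURE_NAMES) <= set(features.columns) \
            else features.drop(columns=["label"], errors="ignore").to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    classes = sorted(set(y.tolist()))
    if len(classes) < 2:
        raise ValueError("training requires at least two classes")
    for c in classes:
        if (y == c).sum() < 5:
            raise ValueError(f"class {c!r} has fewer than 5 training rows")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)  # constant features pass through unscaled
    Z = (X - mean) / sd
    learners = {}
    for a, b in combinations(classes, 2):
        mask = (y == a) | (y == b)
        svc = SVC(kernel="linear", C=C, random_state=seed)
        svc.fit(Z[mask], y[mask])
        # sklearn decision_function is positive for svc.classes_[1]
        learners[(a, b)] = {
            "w": svc.coef_[0].copy(),
            "b": float(svc.intercept_[0]),
            "pos": svc.classes_[1],
        }
    return TrainedClassifier(
        classes=classes, mean=mean, sd=sd, learners=learners, seed=seed
    )


def classify(model: TrainedClassifier, features):
    """Predicted labels plus per-pair decision values."""
    if isinstance(features, pd.DataFrame):
        X = features[list(model.feature_names)].to_numpy(dtype=float) \
            if set(model.feature_names) <= set(features.columns) \
            else features.drop(columns=["label"], errors="ignore").to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
    labels = model.predict(X)
    decisions = model.decision_values(X)
    return labels, decisions
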