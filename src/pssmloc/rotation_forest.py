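"""Rotation Forest ensemble classifier.

Each ensemble member trains a decision tree on a rotated copy of the data:
the feature set is randomly partitioned into small subsets, PCA is fitted to
a class-and-bootstrap-subsampled view of each subset, and the per-subset
loadings are assembled into one block-sparse rotation matrix. Because every
block is orthonormal, the rotation preserves within-subset geometry while
giving each tree a different coordinate system — the source of ensemble
diversity. Predictions are combined by majority vote.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
from sklearn.tree import DecisionTreeClassifier

#: Eigenvalues at or below this are treated as zero, so the corresponding
#: principal components are dropped (making M < N for rank-deficient subsets).
_EIG_TOL = 1e-12


@dataclass(frozen=True)
class RotationForestConfig:
    """Ensemble settings.

    ``ensemble_size``
        number of (rotation, tree) members; 100 by default.
    ``subset_size``
        features per random subset fed to one PCA; 3 by default.
    ``class_sample_fraction``
        bootstrap fraction of the rows of a random class subset used to fit
        each subset's PCA; 0.75 by default.
    ``split_criterion``
        impurity measure of the CART base trees; ``entropy`` approximates the
        information-gain splitting of C4.5-style learners.
    """

    ensemble_size: int = 100
    subset_size: int = 3
    class_sample_fraction: float = 0.75
    base_learner: str = "decision_tree"
    split_criterion: str = "gini"
    max_depth: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ensemble_size < 1:
            raise ValueError("ensemble_size must be >= 1")
        if self.subset_size < 1:
            raise ValueError("subset_size must be >= 1")
        if not 0 < self.class_sample_fraction <= 1:
            raise ValueError("class_sample_fraction must be in (0, 1]")
        if self.base_learner != "decision_tree":
            raise ValueError(f"unsupported base learner {self.base_learner!r}")
        if self.split_criterion not in ("gini", "entropy"):
            raise ValueError(f"unsupported split criterion {self.split_criterion!r}")


@dataclass
class RotationForestModel:
    """Trained ensemble: (rotation matrix, tree) pairs plus the class list."""

    members: list[tuple[np.ndarray, DecisionTreeClassifier]]
    classes: np.ndarray
    feature_count: int
    config: RotationForestConfig

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict(self, X)

    def save(self, path: str | Path) -> None:
        """Serialize to a single self-describing archive."""
        joblib.dump({"schema_version": 1, "model": self}, path)

    @staticmethod
    def load(path: str | Path) -> "RotationForestModel":
        payload = joblib.load(path)
        if payload.get("schema_version") != 1:
            raise ValueError("unrecognized model archive schema")
        return payload["model"]


def build_rotation(
    X: np.ndarray,
    y: np.ndarray,
    cfg: RotationForestConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Build one member's N x M rotation matrix.

    Features are randomly partitioned into ceil(N / subset_size) disjoint
    subsets. For each subset a random non-empty set of classes is drawn, a
    ``class_sample_fraction`` bootstrap of their rows is taken, and the PCA
    loadings of that sub-matrix (every component with nonzero eigenvalue)
    become the subset's column block, placed at the subset's original feature
    rows. A zero-variance subset falls back to an identity block.
    """
    n_samples, n_features = X.shape
    classes = np.unique(y)
    order = rng.permutation(n_features)
    subsets = [order[i : i + cfg.subset_size] for i in range(0, n_features, cfg.subset_size)]

    blocks: list[tuple[np.ndarray, np.ndarray]] = []  # (feature rows, loadings)
    total_cols = 0
    for subset in subsets:
        n_cls = int(rng.integers(1, classes.size + 1))
        chosen = rng.choice(classes, size=n_cls, replace=False)
        rows = np.flatnonzero(np.isin(y, chosen))
        n_boot = max(2, int(round(cfg.class_sample_fraction * rows.size)))
        boot = rng.choice(rows, size=n_boot, replace=True)
        sub = X[np.ix_(boot, subset)]
        centered = sub - sub.mean(axis=0, keepdims=True)
        cov = centered.T @ centered / max(1, centered.shape[0] - 1)
        eigvals, eigvecs = np.linalg.eigh(cov)
        keep = eigvals > _EIG_TOL
        if not np.any(keep):
            loadings = np.eye(subset.size)
        else:
            # descending eigenvalue order
            loadings = eigvecs[:, keep][:, ::-1]
        blocks.append((subset, loadings))
        total_cols += loadings.shape[1]

    rotation = np.zeros((n_features, total_cols))
    col = 0
    for subset, loadings in blocks:
        rotation[subset, col : col + loadings.shape[1]] = loadings
        col += loadings.shape[1]
    return rotation


def fit(X: np.ndarray, y: np.ndarray, cfg: RotationForestConfig | None = None) -> RotationForestModel:
    """Train a Rotation Forest. Deterministic given (X, y, cfg) including seed."""
    cfg = cfg or RotationForestConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be samples x features with one label per row")
    if X.shape[0] < 2:
        raise ValueError("at least 2 samples are required")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite entries")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("at least 2 classes are required")

    members: list[tuple[np.ndarray, DecisionTreeClassifier]] = []
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.ensemble_size)
    for t in range(cfg.ensemble_size):
        rng = np.random.default_rng(streams[t])
        rotation = build_rotation(X, y, cfg, rng)
        tree = DecisionTreeClassifier(
            criterion=cfg.split_criterion,
            max_depth=cfg.max_depth,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X @ rotation, y)
        members.append((rotation, tree))
    return RotationForestModel(
        members=members, classes=classes, feature_count=X.shape[1], config=cfg
    )


def predict(model: RotationForestModel, X: np.ndarray) -> np.ndarray:
    """Majority vote over the ensemble; ties go to the lowest class index."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.feature_count:
        raise ValueError(
            f"X has {X.shape[1] if X.ndim == 2 else '?'} columns, "
            f"model expects {model.feature_count}"
        )
    class_index = {c: i for i, c in enumerate(model.classes)}
    votes = np.zeros((X.shape[0], model.classes.size), dtype=int)
    for rotation, tree in model.members:
        pred = tree.predict(X @ rotation)
        for s, label in enumerate(pred):
            votes[s, class_index[label]] += 1
    # argmax returns the first maximum: lowest class index wins ties
    return model.classes[np.argmax(votes, axis=1)]
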