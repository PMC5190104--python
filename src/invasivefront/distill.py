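"""Data distillation: PCA overview, iterative random-forest Gini elimination,
and CART cut-off modelling.

The chain reduces the 123-parameter multi-parametric feature-set against a
binary outcome (disease-specific death):

* :func:`pca_overview` — a 2-component PCA scatter with a two-group
  clustering and its sensitivity/specificity/AUC against the outcome, used
  as a visual sanity check that the feature-set separates outcome groups.
* :func:`rf_iterative_reduce` — fit a random forest (5000 trees by default),
  rank features by Gini importance, drop the least important, refit, and
  repeat until the out-of-bag predictive value (OOB AUC) falls more than a
  tolerance below the best observed; returns the surviving set at the best
  observed OOB AUC.
* :func:`cart_fit` — a single Gini CART on the surviving features, pruned by
  cost-complexity with a cross-validated 1-SE rule; its root split is the
  headline "optimal parameter and cut-off". Scikit-learn places every split
  threshold at the midpoint between adjacent sorted feature values, the
  convention adopted here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier, export_text

logger = logging.getLogger(__name__)


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    return pd.DataFrame(np.asarray(X, dtype=float))


def _check_binary(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    return y


# ---------------------------------------------------------------------------
# PCA overview
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    scores: np.ndarray                 # n_patients x 2 component scores
    explained_variance: np.ndarray     # fractions, non-increasing
    clusters: np.ndarray               # 0/1 cluster per patient
    sensitivity: float
    specificity: float
    auc: float
    dropped_constant: list[str]

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "value": [
                    self.explained_variance[0],
                    self.explained_variance[1],
                    float(self.explained_variance[:2].sum()),
                    self.sensitivity,
                    self.specificity,
                    self.auc,
                ]
            },
            index=["pc1_var_fraction", "pc2_var_fraction", "total_var_fraction",
                   "sensitivity", "specificity", "auc"],
        )


def pca_overview(X, y, n_clusters: int = 2, seed: int = 0) -> PCAResult:
    """Two-component PCA of the z-scored feature table with a 2-group clustering.

    Clusters are mapped to the outcome by majority vote; the AUC is computed
    from each patient's continuous position along the inter-cluster-centroid
    axis (the clustering's natural score).
    """
    X = _as_frame(X)
    y = _check_binary(y)
    if len(X) < 3:
        raise ValueError("PCA overview needs at least 3 patients")

    variances = X.var(axis=0).to_numpy()
    keep = variances > 0
    dropped = [str(c) for c, k in zip(X.columns, keep) if not k]
    if dropped:
        warnings.warn(f"dropping {len(dropped)} constant feature(s)", stacklevel=2)
    Xs = StandardScaler().fit_transform(X.loc[:, X.columns[keep]])

    pca = PCA(n_components=2, random_state=seed)
    scores = pca.fit_transform(Xs)
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
    clusters = km.fit_predict(scores)

    # orient cluster 1 toward the event-rich cluster
    rate = [y[clusters == k].mean() if (clusters == k).any() else 0.0
            for k in range(n_clusters)]
    pos = int(np.argmax(rate))
    pred = (clusters == pos).astype(int)

    axis = km.cluster_centers_[pos] - km.cluster_centers_[1 - pos]
    denom = np.linalg.norm(axis)
    score = scores @ axis / denom if denom > 0 else np.zeros(len(scores))

    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    sens = tp / (tp + fn) if (tp + fn) else np.nan
    spec = tn / (tn + fp) if (tn + fp) else np.nan
    auc = float(roc_auc_score(y, score))

    return PCAResult(
        scores=scores,
        explained_variance=pca.explained_variance_ratio_,
        clusters=pred,
        sensitivity=float(sens),
        specificity=float(spec),
        auc=auc,
        dropped_constant=dropped,
    )


# ---------------------------------------------------------------------------
# iterative random-forest elimination
# ---------------------------------------------------------------------------

@dataclass
class EliminationStep:
    features: list[str]
    importances: dict[str, float]
    oob_auc: float
    removed: str | None


@dataclass
class FeatureRanking:
    """Trace of the iterative Gini elimination plus the selected subset."""

    steps: list[EliminationStep]
    selected: list[str]
    best_oob_auc: float
    tolerance: float

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_features": [len(s.features) for s in self.steps],
                "oob_auc": [s.oob_auc for s in self.steps],
                "removed_next": [s.removed for s in self.steps],
            }
        )


def rf_iterative_reduce(
    X,
    y,
    n_trees: int = 5000,
    tolerance: float = 0.005,
    seed: int = 0,
    min_features: int = 1,
) -> FeatureRanking:
    """Iteratively drop the lowest-Gini feature until OOB AUC degrades.

    Each iteration refits the forest on the surviving features, records the
    out-of-bag AUC, and removes the single feature with the smallest Gini
    importance. The loop stops once the OOB AUC falls more than ``tolerance``
    below the best value observed; the selected subset is the surviving set
    at the best observed OOB AUC (earliest such iteration — removing a
    redundant feature never justifies losing an informative one).
    """
    X = _as_frame(X)
    y = _check_binary(y)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features to reduce")

    rng = np.random.default_rng(seed)
    surviving = [str(c) for c in X.columns]
    X = X.copy()
    X.columns = surviving
    steps: list[EliminationStep] = []
    best = -np.inf

    while True:
        rf = RandomForestClassifier(
            n_estimators=n_trees,
            oob_score=True,
            random_state=int(rng.integers(0, 2**31 - 1)),
            n_jobs=1,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # few-tree OOB coverage warnings
            rf.fit(X[surviving].to_numpy(), y)
        oob = rf.oob_decision_function_[:, 1]
        valid = np.isfinite(oob)
        oob_auc = float(roc_auc_score(y[valid], oob[valid]))
        importances = dict(zip(surviving, rf.feature_importances_.astype(float)))

        stop = oob_auc < best - tolerance or len(surviving) <= min_features
        removed = None
        if not stop:
            removed = min(surviving, key=lambda f: importances[f])
        steps.append(EliminationStep(list(surviving), importances, oob_auc, removed))
        best = max(best, oob_auc)
        if stop:
            break
        surviving.remove(removed)

    chosen = steps[int(np.argmax([s.oob_auc for s in steps]))]
    return FeatureRanking(
        steps=steps,
        selected=list(chosen.features),
        best_oob_auc=best,
        tolerance=tolerance,
    )


# ---------------------------------------------------------------------------
# CART
# ---------------------------------------------------------------------------

@dataclass
class CartModel:
    """A pruned single decision tree with its self-test metrics."""

    tree: DecisionTreeClassifier = dc_field(repr=False)
    feature_names: list[str] = dc_field(default_factory=list)
    root_feature: str | None = None
    root_threshold: float | None = None
    ccp_alpha: float = 0.0
    folds: int = 10
    sensitivity: float = np.nan
    specificity: float = np.nan
    auc: float = np.nan
    seed: int = 0

    @property
    def n_leaves(self) -> int:
        return int(self.tree.get_n_leaves())

    def to_dict(self) -> dict:
        t = self.tree.tree_

        def node(i: int) -> dict:
            if t.children_left[i] == -1:
                counts = t.value[i][0]
                return {
                    "leaf": True,
                    "class": int(np.argmax(counts)),
                    "proportions": (counts / counts.sum()).tolist(),
                }
            return {
                "leaf": False,
                "feature": self.feature_names[t.feature[i]],
                "threshold": float(t.threshold[i]),
                "left": node(t.children_left[i]),
                "right": node(t.children_right[i]),
            }

        return {
            "root": node(0),
            "ccp_alpha": self.ccp_alpha,
            "folds": self.folds,
            "metrics": {
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "auc": self.auc,
            },
            "seed": self.seed,
        }

    def pretty(self) -> str:
        if self.n_leaves <= 1:
            return "single leaf (no informative split)"
        return export_text(self.tree, feature_names=self.feature_names)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "value": [
                    self.root_feature,
                    self.root_threshold,
                    self.n_leaves,
                    self.sensitivity,
                    self.specificity,
                    self.auc,
                ]
            },
            index=["root_feature", "root_threshold", "n_leaves",
                   "sensitivity", "specificity", "auc"],
        )


def cart_fit(
    X,
    y,
    folds: int = 10,
    min_leaf: int = 5,
    seed: int = 0,
    se_factor: float = 1.5,
) -> CartModel:
    """Fit a Gini CART with cost-complexity pruning selected by k-fold CV.

    The pruning strength is the largest ccp-alpha whose cross-validated
    misclassification risk stays within ``se_factor`` standard errors of the
    minimum (a c*SE rule; c=1.5 keeps strong splits while reliably pruning
    chance structure in noise-only data to a single leaf).
    Self-test sensitivity/specificity/AUC come from
    out-of-fold predictions of the same k folds. Unsplittable or pure-noise
    data prunes to a single leaf (with a warning).
    """
    X = _as_frame(X)
    y = _check_binary(y)
    names = [str(c) for c in X.columns]
    Xv = X.to_numpy(dtype=float)
    if min(np.bincount(y)) < 2:
        raise ValueError("need at least 2 patients per outcome class")

    base = DecisionTreeClassifier(
        criterion="gini", min_samples_leaf=min_leaf, random_state=seed
    )
    path = base.cost_complexity_pruning_path(Xv, y)
    alphas = np.unique(np.clip(path.ccp_alphas, 0.0, None))

    n_splits = min(folds, int(min(np.bincount(y))))
    if n_splits >= 2 and len(alphas) > 1:
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        fold_risk = np.zeros((n_splits, len(alphas)))
        for k, (tr, te) in enumerate(skf.split(Xv, y)):
            for a, alpha in enumerate(alphas):
                t = DecisionTreeClassifier(
                    criterion="gini", min_samples_leaf=min_leaf,
                    random_state=seed, ccp_alpha=alpha,
                ).fit(Xv[tr], y[tr])
                fold_risk[k, a] = np.mean(t.predict(Xv[te]) != y[te])
        mean_risk = fold_risk.mean(axis=0)
        se = fold_risk.std(axis=0, ddof=1) / np.sqrt(n_splits)
        best_idx = int(np.argmin(mean_risk))
        limit = mean_risk[best_idx] + se_factor * se[best_idx]
        chosen_alpha = float(alphas[np.flatnonzero(mean_risk <= limit).max()])
    else:
        chosen_alpha = 0.0

    tree = DecisionTreeClassifier(
        criterion="gini", min_samples_leaf=min_leaf,
        random_state=seed, ccp_alpha=chosen_alpha,
    ).fit(Xv, y)

    if tree.get_n_leaves() <= 1:
        warnings.warn("CART pruned to a single leaf: no informative split", stacklevel=2)
        root_feature = None
        root_threshold = None
    else:
        root_feature = names[tree.tree_.feature[0]]
        root_threshold = float(tree.tree_.threshold[0])

    # self-test: out-of-fold predictions with the chosen pruning
    sens = spec = auc = np.nan
    if n_splits >= 2:
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        proba = np.zeros(len(y))
        for tr, te in skf.split(Xv, y):
            t = DecisionTreeClassifier(
                criterion="gini", min_samples_leaf=min_leaf,
                random_state=seed, ccp_alpha=chosen_alpha,
            ).fit(Xv[tr], y[tr])
            proba[te] = t.predict_proba(Xv[te])[:, 1]
        pred = (proba >= 0.5).astype(int)
        tp = int(((pred == 1) & (y == 1)).sum())
        tn = int(((pred == 0) & (y == 0)).sum())
        fp = int(((pred == 1) & (y == 0)).sum())
        fn = int(((pred == 0) & (y == 1)).sum())
        sens = tp / (tp + fn) if (tp + fn) else np.nan
        spec = tn / (tn + fp) if (tn + fp) else np.nan
        if len(np.unique(proba)) > 1:
            auc = float(roc_auc_score(y, proba))

    return CartModel(
        tree=tree,
        feature_names=names,
        root_feature=root_feature,
        root_threshold=root_threshold,
        ccp_alpha=chosen_alpha,
        folds=n_splits,
        sensitivity=float(sens),
        specificity=float(spec),
        auc=float(auc) if np.isfinite(auc) else np.nan,
        seed=seed,
    )
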