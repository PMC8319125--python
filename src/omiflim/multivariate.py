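"""Condition-level and single-cell multivariate analysis of OMI features.

Covers the downstream analytics of the differentiation-efficiency study:
z-score heatmap tables with hierarchical (average-linkage, Euclidean)
dendrograms over conditions, seeded UMAP embeddings of the 13-variable
single-cell space, chi-squared variable ranking with accuracy-vs-k curves,
and binary low/high-efficiency classification (logistic regression by
default; SVM and random-forest families available) evaluated by ROC/AUC on
an independent replicate dataset.

The classifier is an sklearn-compatible estimator
(:class:`EfficiencyClassifier`) so it composes with sklearn pipelines and
model selection; :func:`train_classifier` is a thin report-producing
wrapper that also enforces the replicate-level leakage guard.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import chi2 as sklearn_chi2
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler, StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .cells import OMI_VARIABLES, VARIABLE_SUBSETS

__all__ = [
    "ZScoreTable", "SplitSpec", "ClassifierReport", "EfficiencyClassifier",
    "zscore_conditions", "cluster_dendrogram", "umap_embed",
    "chi2_scores", "chi2_rank", "train_classifier",
]

CLASS_ORDER = ["low", "high"]  # "high" is the positive class throughout


@dataclass
class ZScoreTable:
    """Variables × conditions matrix of condition-mean z-scores."""

    values: pd.DataFrame  # rows = variables, columns = conditions

    def __post_init__(self) -> None:
        mu = self.values.mean(axis=1)
        sd = self.values.std(axis=1, ddof=1)
        if not (np.allclose(mu, 0, atol=1e-9)
                and np.allclose(sd, 1, atol=1e-9)):
            raise ValueError("z-score rows must have mean 0 and SD 1")


def zscore_conditions(records: pd.DataFrame,
                      variables: list[str] | None = None) -> ZScoreTable:
    """Z-score each variable's condition means across conditions.

    For each variable, μ_observed is its mean over the cells of one
    condition; the z-score is (μ_observed − μ_row) / σ_row, where μ_row and
    σ_row are the mean and sample SD (ddof = 1) of the condition means
    across all conditions.
    """
    variables = variables or OMI_VARIABLES
    if records["condition"].nunique() < 2:
        raise ValueError("z-scoring needs at least 2 conditions")
    means = records.groupby("condition", sort=True)[variables].mean().T
    sd = means.std(axis=1, ddof=1)
    constant = sd.index[sd == 0].tolist()
    if constant:
        raise ValueError(
            f"variable(s) {constant} are constant across conditions; "
            "z-score undefined (zero row SD)")
    z = means.sub(means.mean(axis=1), axis=0).div(sd, axis=0)
    return ZScoreTable(z)


@dataclass
class DendrogramResult:
    condition_linkage: np.ndarray
    variable_linkage: np.ndarray
    condition_labels: list[str]
    variable_labels: list[str]


def cluster_dendrogram(z: ZScoreTable) -> DendrogramResult:
    """Average-linkage Euclidean hierarchical clustering of a z-score table.

    Clusters both the conditions (columns, points in 13-variable z-space)
    and the variables (rows). Deterministic given input order; SciPy breaks
    distance ties by the lowest original cluster index.
    """
    cond = z.values.T.to_numpy()
    var = z.values.to_numpy()
    return DendrogramResult(
        condition_linkage=linkage(cond, method="average", metric="euclidean"),
        variable_linkage=linkage(var, method="average", metric="euclidean"),
        condition_labels=list(z.values.columns),
        variable_labels=list(z.values.index),
    )


def umap_embed(records: pd.DataFrame, seed: int = 0,
               n_neighbors: int = 10, min_dist: float = 0.3,
               metric: Literal["euclidean", "cosine"] = "euclidean",
               variables: list[str] | None = None) -> np.ndarray:
    """Seeded 2D UMAP embedding of the standardized OMI feature space.

    Defaults follow the visualization convention of the study design:
    ``n_neighbors=10``, ``min_dist=0.3``, Euclidean or cosine metric,
    two output components. Import of the backend is deferred because its
    JIT warm-up is slow.
    """
    import umap  # deferred: numba compilation on import

    variables = variables or OMI_VARIABLES
    x = records[variables].to_numpy(dtype=float)
    if len(x) < n_neighbors + 1:
        raise ValueError(
            f"need at least n_neighbors+1={n_neighbors + 1} cells, "
            f"got {len(x)}")
    x = StandardScaler().fit_transform(x)
    reducer = umap.UMAP(n_neighbors=n_neighbors, min_dist=min_dist,
                        metric=metric, n_components=2, random_state=seed)
    return reducer.fit_transform(x)


# ---------------------------------------------------------------------------
# Classification


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation split of dataset 1 plus the evaluation dataset id."""

    train_fraction: float = 0.80
    train_dataset: int = 1
    eval_dataset: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.train_dataset == self.eval_dataset:
            raise ValueError("evaluation dataset must differ from the "
                             "training dataset (leakage guard)")


def _make_model(family: str, seed: int):
    if family == "logistic":
        # L2 regularization (the sklearn default) at unit strength
        return LogisticRegression(C=1.0, max_iter=2000)
    if family == "svm":
        return SVC(kernel="rbf", random_state=seed)
    if family == "random_forest":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    raise ValueError(f"unknown model family {family!r}")


class EfficiencyClassifier(BaseEstimator, ClassifierMixin):
    """Binary low/high differentiation-efficiency classifier.

    A standardize-then-fit pipeline over a chosen model family. Features
    are standardized on the training statistics so logistic weights are
    comparable across variables.

    Parameters
    ----------
    family : {"logistic", "svm", "random_forest"}
    random_state : int
        Seed for the stochastic families.
    """

    def __init__(self, family: str = "logistic", random_state: int = 0):
        self.family = family
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2D with one label per row")
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        self.pipeline_ = Pipeline([
            ("scale", StandardScaler()),
            ("model", _make_model(self.family, self.random_state)),
        ])
        self.pipeline_.fit(X, y)
        self.classes_ = self.pipeline_.named_steps["model"].classes_
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "pipeline_")
        return self.pipeline_.predict(np.asarray(X, dtype=float))

    def decision_scores(self, X):
        """Continuous score for the positive ("high") class."""
        check_is_fitted(self, "pipeline_")
        X = np.asarray(X, dtype=float)
        model = self.pipeline_.named_steps["model"]
        pos = list(self.classes_).index("high") if "high" in self.classes_ \
            else 1
        if hasattr(model, "decision_function"):
            s = self.pipeline_.decision_function(X)
            return s if pos == 1 else -s
        return self.pipeline_.predict_proba(X)[:, pos]

    @property
    def weights_(self) -> np.ndarray | None:
        """Standardized-feature weights (logistic family only)."""
        check_is_fitted(self, "pipeline_")
        model = self.pipeline_.named_steps["model"]
        if hasattr(model, "coef_"):
            return model.coef_.ravel()
        return None


@dataclass
class ClassifierReport:
    """Everything a trained classifier run reports."""

    family: str
    subset: str
    variables: list[str]
    weights: dict[str, float] | None
    validation_accuracy: float
    evaluation_accuracy: float
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    auc: float
    condition_auc: float
    n_train: int
    n_validation: int
    n_eval: int
    seed: int
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("AUC outside [0, 1]")
        if np.any(np.diff(self.roc_tpr) < 0) or np.any(np.diff(self.roc_fpr) < 0):
            raise ValueError("ROC curve must be monotone nondecreasing")
        if self.weights is not None and len(self.weights) != len(self.variables):
            raise ValueError("one weight per variable required")

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()
             if k not in ("roc_fpr", "roc_tpr")}
        d["roc_fpr"] = np.asarray(self.roc_fpr).tolist()
        d["roc_tpr"] = np.asarray(self.roc_tpr).tolist()
        return d


def _resolve_subset(subset: str | list[str]) -> tuple[str, list[str]]:
    if isinstance(subset, str):
        if subset not in VARIABLE_SUBSETS:
            raise ValueError(f"unknown subset {subset!r}; known: "
                             f"{sorted(VARIABLE_SUBSETS)}")
        return subset, list(VARIABLE_SUBSETS[subset])
    unknown = [v for v in subset if v not in OMI_VARIABLES]
    if unknown:
        raise ValueError(f"unknown variables {unknown}")
    return "custom", list(subset)


def chi2_scores(records: pd.DataFrame,
                variables: list[str] | None = None) -> pd.Series:
    """Chi-squared relevance score of each variable for the binary class.

    Features are min–max scaled to [0, 1] (the statistic requires
    non-negative values) and scored by the one-way chi-squared statistic
    between per-class feature sums. Ties keep the fixed column order.
    """
    variables = variables or OMI_VARIABLES
    y = records["efficiency_class"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("chi-squared ranking needs both classes present")
    x = MinMaxScaler().fit_transform(records[variables].to_numpy(dtype=float))
    scores, _ = sklearn_chi2(x, y)
    return pd.Series(scores, index=variables)


def chi2_rank(records: pd.DataFrame, variables: list[str] | None = None,
              n_resamples: int = 10, train_fraction: float = 0.8,
              family: str = "logistic", seed: int = 0
              ) -> tuple[list[str], pd.DataFrame]:
    """Rank variables by chi-squared score; accuracy as a function of k.

    For k = 1..len(variables) a classifier is retrained on the top-k
    variables over ``n_resamples`` random train/validation re-splits and
    the validation accuracy is summarized as mean ± SD.
    """
    variables = variables or OMI_VARIABLES
    scores = chi2_scores(records, variables)
    order = np.argsort(-scores.to_numpy(), kind="stable")
    ranked = [variables[i] for i in order]

    y = records["efficiency_class"].to_numpy()
    rows = []
    for k in range(1, len(ranked) + 1):
        x = records[ranked[:k]].to_numpy(dtype=float)
        accs = []
        for r in range(n_resamples):
            xtr, xva, ytr, yva = train_test_split(
                x, y, train_size=train_fraction, random_state=seed + r,
                stratify=y)
            clf = EfficiencyClassifier(family=family, random_state=seed + r)
            clf.fit(xtr, ytr)
            accs.append(float((clf.predict(xva) == yva).mean()))
        rows.append({"k": k, "variables": ranked[:k],
                     "accuracy_mean": float(np.mean(accs)),
                     "accuracy_sd": float(np.std(accs, ddof=1))})
    return ranked, pd.DataFrame(rows)


def train_classifier(records: pd.DataFrame,
                     family: str = "logistic",
                     subset: str | list[str] = "all",
                     split: SplitSpec | None = None) -> ClassifierReport:
    """Train on dataset 1 (80/20 train/validation), evaluate on dataset 2.

    Features are standardized on the training fold; validation accuracy is
    reported on the held-out 20 % of dataset 1 and the ROC/AUC on
    cell-level scores from the independent evaluation dataset. A
    condition-level AUC over per-condition mean scores is reported as a
    secondary summary (NaN when a class has fewer than one condition).
    Refuses to run if any cell id appears in both datasets.
    """
    split = split or SplitSpec()
    subset_name, variables = _resolve_subset(subset)

    ds = records["dataset"]
    train_df = records[ds == split.train_dataset]
    eval_df = records[ds == split.eval_dataset]
    if train_df.empty or eval_df.empty:
        raise ValueError("both the training and evaluation datasets must "
                         "contain cells")
    overlap = set(train_df["cell_id"]) & set(eval_df["cell_id"])
    if overlap:
        raise ValueError(
            f"leakage guard: {len(overlap)} cell id(s) appear in both "
            "dataset 1 and dataset 2")

    x = train_df[variables].to_numpy(dtype=float)
    y = train_df["efficiency_class"].to_numpy()
    xtr, xva, ytr, yva = train_test_split(
        x, y, train_size=split.train_fraction, random_state=split.seed,
        stratify=y)
    clf = EfficiencyClassifier(family=family, random_state=split.seed)
    clf.fit(xtr, ytr)
    val_acc = float((clf.predict(xva) == yva).mean())

    xe = eval_df[variables].to_numpy(dtype=float)
    ye = eval_df["efficiency_class"].to_numpy()
    eval_acc = float((clf.predict(xe) == ye).mean())
    scores = clf.decision_scores(xe)
    fpr, tpr, _ = roc_curve(ye, scores, pos_label="high")
    roc_auc = float(sk_auc(fpr, tpr))

    cond = eval_df.assign(_score=scores).groupby("condition").agg(
        _score=("_score", "mean"),
        efficiency_class=("efficiency_class", "first"))
    if cond["efficiency_class"].nunique() == 2:
        cf, ct, _ = roc_curve(cond["efficiency_class"], cond["_score"],
                              pos_label="high")
        condition_auc = float(sk_auc(cf, ct))
    else:
        condition_auc = float("nan")

    w = clf.weights_
    weights = dict(zip(variables, map(float, w))) if w is not None else None
    return ClassifierReport(
        family=family, subset=subset_name, variables=variables,
        weights=weights, validation_accuracy=val_acc,
        evaluation_accuracy=eval_acc, roc_fpr=fpr, roc_tpr=tpr, auc=roc_auc,
        condition_auc=condition_auc, n_train=len(xtr), n_validation=len(xva),
        n_eval=len(xe), seed=split.seed,
        extras={"eval_scores": np.asarray(scores).tolist(),
                "eval_labels": list(map(str, ye))})
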