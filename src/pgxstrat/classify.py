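"""Group-label prediction from principal-component features.

Three classifier families (k-nearest neighbors, random forest, RBF
support-vector machine) predict each sample's self-identified group from
its top PC scores. Accuracy is measured with stratified 5-fold
cross-validation; hyperparameters are chosen by randomized search nested
inside each training fold, so the test fold never influences model
selection. Accuracy is the plain percentage of correct predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy.stats import loguniform, randint
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import RandomizedSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .containers import GroupLabelSet

METHODS = ("knn", "random_forest", "svm")

# Search neighborhoods around hyperparameter values that perform well for
# cohort-scale group prediction from PC features.
_DEFAULT_SPACES: dict[str, dict[str, Any]] = {
    "knn": {"n_neighbors": randint(3, 51)},
    "random_forest": {
        "n_estimators": randint(100, 801),
        "max_depth": randint(10, 151),
        "min_samples_leaf": randint(1, 9),
        "min_samples_split": randint(2, 11),
    },
    # RBF-SVM features are standardized inside the estimator pipeline,
    # hence the svc__ parameter prefix.
    "svm": {"svc__C": loguniform(1, 1e5), "svc__gamma": loguniform(1e-3, 1e2)},
}


@dataclass
class ClassifierSpec:
    method: str = "random_forest"
    search_space: dict[str, Any] | None = None
    n_search_draws: int = 10
    cv_folds: int = 5
    inner_folds: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.n_search_draws < 1:
            raise ValueError("n_search_draws must be >= 1")
        if self.search_space is None:
            self.search_space = dict(_DEFAULT_SPACES[self.method])

    def make_estimator(self, seed: int):
        if self.method == "knn":
            return KNeighborsClassifier()
        if self.method == "random_forest":
            return RandomForestClassifier(random_state=seed)
        return Pipeline(
            [("scale", StandardScaler()), ("svc", SVC(kernel="rbf", random_state=seed))]
        )


@dataclass
class ClassificationReport:
    method: str
    n_pcs: int
    fold_accuracies: list[float]
    best_params: dict[str, Any]
    groups: list[str]
    confusion: pd.DataFrame            # counts, true groups as rows
    misclassified_samples: list[str]
    per_fold_params: list[dict[str, Any]] = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=1)) if len(
            self.fold_accuracies
        ) > 1 else 0.0

    def row_percentages(self) -> pd.DataFrame:
        counts = self.confusion.to_numpy(dtype=float)
        totals = counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            pct = 100.0 * counts / totals
        return pd.DataFrame(pct, index=self.confusion.index,
                            columns=self.confusion.columns)


def train_eval(
    scores: np.ndarray,
    sample_ids: list[str],
    labels: GroupLabelSet,
    spec: ClassifierSpec,
    n_pcs: int,
) -> ClassificationReport:
    """Nested cross-validated accuracy of group prediction from PC scores.

    ``scores`` is the (n_samples, >= n_pcs) PC-score matrix aligned to
    ``sample_ids``; the first ``n_pcs`` columns form the feature vector.
    Every sample is tested exactly once across the outer folds, so the
    confusion matrix aggregates the full cohort.
    """
    if n_pcs < 1 or n_pcs > scores.shape[1]:
        raise ValueError(f"n_pcs must lie in 1..{scores.shape[1]}")
    X = np.asarray(scores[:, :n_pcs], dtype=float)
    y = labels.for_samples(sample_ids)
    groups = sorted(set(y))
    counts = {g: int((y == g).sum()) for g in groups}
    small = [g for g, c in counts.items() if c < spec.cv_folds]
    if small:
        raise ValueError(
            f"groups smaller than cv_folds={spec.cv_folds}: {small}"
        )

    if len(groups) == 1:
        # Degenerate vocabulary: nothing to learn, every prediction correct.
        confusion = pd.DataFrame(
            [[len(y)]], index=pd.Index(groups, name="true"),
            columns=pd.Index(groups, name="predicted"),
        )
        return ClassificationReport(
            method=spec.method, n_pcs=n_pcs,
            fold_accuracies=[1.0] * spec.cv_folds,
            best_params={}, groups=groups, confusion=confusion,
            misclassified_samples=[],
        )

    outer = StratifiedKFold(
        n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed
    )
    predictions = np.empty_like(y)
    fold_accuracies: list[float] = []
    per_fold_params: list[dict[str, Any]] = []
    for fold, (train_idx, test_idx) in enumerate(outer.split(X, y)):
        inner = StratifiedKFold(
            n_splits=spec.inner_folds, shuffle=True,
            random_state=spec.seed + 1000 + fold,
        )
        search = RandomizedSearchCV(
            spec.make_estimator(spec.seed + fold),
            spec.search_space,
            n_iter=spec.n_search_draws,
            cv=inner,
            scoring="accuracy",
            random_state=spec.seed + fold,
            n_jobs=1,
        )
        search.fit(X[train_idx], y[train_idx])
        pred = search.best_estimator_.predict(X[test_idx])
        predictions[test_idx] = pred
        fold_accuracies.append(float(np.mean(pred == y[test_idx])))
        per_fold_params.append(dict(search.best_params_))

    best_fold = int(np.argmax(fold_accuracies))
    confusion = pd.crosstab(
        pd.Series(y, name="true"), pd.Series(predictions, name="predicted")
    ).reindex(index=groups, columns=groups, fill_value=0)
    misclassified = [s for s, t, p in zip(sample_ids, y, predictions) if t != p]
    return ClassificationReport(
        method=spec.method, n_pcs=n_pcs, fold_accuracies=fold_accuracies,
        best_params=per_fold_params[best_fold], groups=groups,
        confusion=confusion, misclassified_samples=misclassified,
        per_fold_params=per_fold_params,
    )


def sweep_pcs(
    scores: np.ndarray,
    sample_ids: list[str],
    labels: GroupLabelSet,
    spec: ClassifierSpec,
    pc_range: range | tuple[int, int],
) -> list[ClassificationReport]:
    """One cross-validated report per PC count over a contiguous range."""
    if isinstance(pc_range, tuple):
        pc_range = range(pc_range[0], pc_range[1] + 1)
    counts = list(pc_range)
    if not counts:
        raise ValueError("empty PC range")
    return [
        train_eval(scores, sample_ids, labels, spec, n_pcs=k) for k in counts
    ]


def best_report(reports: list[ClassificationReport]) -> ClassificationReport:
    """Highest mean accuracy; ties broken by the smallest PC count."""
    return max(reports, key=lambda r: (r.mean_accuracy, -r.n_pcs))


def confusion_analysis(report: ClassificationReport) -> pd.DataFrame:
    """Per-group accuracy and misclassification destinations.

    Returns one row per true group with its test count, percentage
    correctly predicted (the confusion diagonal), and the distribution of
    predicted groups for its misclassified members.
    """
    pct = report.row_percentages()
    rows = []
    for g in report.groups:
        counts = report.confusion.loc[g]
        destinations = {
            dest: float(pct.loc[g, dest])
            for dest in report.groups
            if dest != g and counts[dest] > 0
        }
        rows.append(
            {
                "group": g,
                "n": int(counts.sum()),
                "accuracy_pct": float(pct.loc[g, g]),
                "destinations": dict(
                    sorted(destinations.items(), key=lambda kv: -kv[1])
                ),
            }
        )
    return pd.DataFrame(rows)


def downsample_group(
    labels: GroupLabelSet, group: str, n: int, seed: int
) -> GroupLabelSet:
    """Randomly down-sample one group to ``n`` members (balance option)."""
    members = labels.members(group)
    if n >= len(members):
        return labels
    rng = np.random.default_rng(seed)
    keep = set(rng.choice(members, size=n, replace=False))
    kept = {
        s: g for s, g in labels.labels.items() if g != group or s in keep
    }
    return GroupLabelSet(labels=kept, vocabulary=labels.vocabulary)
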