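"""Classifier training and ROC evaluation over sequences and classifiers.

The evaluation grid is 5 x 4: four sequences plus the combined model
(concatenation of every sequence's selected features) crossed with four
classifiers (decision tree, random forest, K nearest neighbours, logistic
regression).  Splits are subject-grouped and class-stratified by default
so no patient contributes lesions to both sides; a lesion-level split
mode is available behind ``grouping="lesion"``.  Feature selection and
classifier fitting only ever see training rows.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .io import SEQUENCE_TAGS, FeatureTable
from .selection import SelectionResult, select_pipeline

CLASSIFIER_KINDS = ("decision_tree", "random_forest", "knn", "logistic_regression")
MODEL_SEQUENCES = SEQUENCE_TAGS + ("combined",)


@dataclasses.dataclass
class SplitPlan:
    """Disjoint train/test lesion ids; no subject spans both sides."""

    train_lesions: list[str]
    test_lesions: list[str]
    seed: int
    grouping: str = "subject"

    def __post_init__(self) -> None:
        if set(self.train_lesions) & set(self.test_lesions):
            raise ValueError("train and test lesions overlap")

    @property
    def split_hash(self) -> str:
        payload = json.dumps([sorted(self.train_lesions), sorted(self.test_lesions)])
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def split_cohort(table: FeatureTable, test_fraction: float = 0.2,
                 seed: int = 0, grouping: str = "subject") -> SplitPlan:
    """Class-stratified random split, grouped by subject by default."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    frame = table.frame
    rng = np.random.default_rng(seed)
    if grouping == "lesion":
        test_ids: list[str] = []
        for label in (0, 1):
            ids = frame.loc[frame["label"] == label, "lesion_id"].tolist()
            if len(ids) < 2:
                raise ValueError(f"need >= 2 lesions of class {label} to stratify")
            n_test = max(1, round(test_fraction * len(ids)))
            test_ids.extend(rng.permutation(ids)[:n_test].tolist())
        test_set = set(test_ids)
    elif grouping == "subject":
        # a subject's class is the class of its lesions (shared by design)
        subj_label = frame.groupby("subject_id")["label"].first()
        test_subjects: list[str] = []
        for label in (0, 1):
            subs = subj_label.index[subj_label == label].tolist()
            if len(subs) < 2:
                raise ValueError(
                    f"impossible stratification: need >= 2 subjects of class {label}")
            n_test = max(1, round(test_fraction * len(subs)))
            test_subjects.extend(rng.permutation(subs)[:n_test].tolist())
        test_set = set(frame.loc[frame["subject_id"].isin(test_subjects),
                                 "lesion_id"])
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    all_ids = frame["lesion_id"].tolist()
    train = [i for i in all_ids if i not in test_set]
    test = [i for i in all_ids if i in test_set]
    return SplitPlan(train, test, seed, grouping)


class FittedModel:
    """A classifier plus the training-set scaler and feature list."""

    def __init__(self, kind: str, estimator, scaler: StandardScaler,
                 feature_names: list[str]):
        self.kind = kind
        self.estimator = estimator
        self.scaler = scaler
        self.feature_names = feature_names


def train_classifier(kind: str, X: np.ndarray, labels: np.ndarray,
                     feature_names: list[str], seed: int = 0) -> FittedModel:
    """Fit one of the four classifiers with fixed hyperparameters.

    Features are standardized using training-set statistics only.
    """
    if kind not in CLASSIFIER_KINDS:
        raise ValueError(f"unknown classifier kind {kind!r}")
    if X.shape[1] == 0 or not feature_names:
        raise ValueError("no features selected: cannot train a classifier")
    labels = np.asarray(labels, dtype=int)
    if len(set(labels)) < 2:
        raise ValueError("both classes must be present in training data")
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    if kind == "decision_tree":
        est = DecisionTreeClassifier(criterion="gini", max_depth=5,
                                     random_state=seed)
    elif kind == "random_forest":
        est = RandomForestClassifier(n_estimators=100, random_state=seed)
    elif kind == "knn":
        est = KNeighborsClassifier(n_neighbors=min(5, len(labels)))
    else:
        est = LogisticRegression(penalty="l2", C=1.0, max_iter=2000,
                                 random_state=seed)
    est.fit(Xs, labels)
    return FittedModel(kind, est, scaler, list(feature_names))


def predict_scores(model: FittedModel, table: FeatureTable) -> np.ndarray:
    """Continuous class-1 scores in [0, 1] for each lesion."""
    missing = [n for n in model.feature_names if n not in table.feature_names]
    if missing:
        raise ValueError(f"table is missing model features: {missing[:5]}")
    X = model.scaler.transform(table.values(model.feature_names))
    proba = model.estimator.predict_proba(X)
    class_index = list(model.estimator.classes_).index(1)
    return proba[:, class_index]


def roc_auc(scores: np.ndarray, labels: np.ndarray
            ) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """ROC curve and AUC (Mann-Whitney statistic; ties count one half).

    Returns (fpr, tpr, thresholds, auc) with one curve vertex per distinct
    score threshold plus the (0,0) origin.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present for ROC analysis")
    ranks = stats.rankdata(scores)
    auc = (ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)

    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    distinct = np.where(np.diff(sorted_scores))[0]
    idx = np.r_[distinct, len(sorted_scores) - 1]
    tps = np.cumsum(sorted_labels)[idx]
    fps = (idx + 1) - tps
    fpr = np.r_[0.0, fps / n0]
    tpr = np.r_[0.0, tps / n1]
    thresholds = np.r_[np.inf, sorted_scores[idx]]
    return fpr, tpr, thresholds, float(auc)


def operating_point(fpr: np.ndarray, tpr: np.ndarray, thresholds: np.ndarray
                    ) -> tuple[float, float, float]:
    """Youden-index maximizer; ties broken toward higher sensitivity.

    Returns (threshold, sensitivity, specificity) in score units.
    """
    youden = tpr - fpr
    best = np.flatnonzero(youden == youden.max())
    # among ties, prefer the highest sensitivity (largest tpr)
    best_idx = best[np.argmax(tpr[best])]
    return (float(thresholds[best_idx]), float(tpr[best_idx]),
            float(1.0 - fpr[best_idx]))


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def delong_variance(scores: np.ndarray, labels: np.ndarray
                    ) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus the DeLong structural components V10, V01."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    all_ranks = _midrank(np.r_[pos, neg])
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    return float(auc), v10, v01


def compare_auc(scores_a: np.ndarray, scores_b: np.ndarray,
                labels: np.ndarray) -> float:
    """DeLong test for two correlated ROC curves; two-sided p-value.

    Degenerate variance of the AUC difference yields p = 1.
    """
    scores_a = np.asarray(scores_a, dtype=np.float64)
    scores_b = np.asarray(scores_b, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValueError("paired scores and labels must share a common length")
    auc_a, v10_a, v01_a = delong_variance(scores_a, labels)
    auc_b, v10_b, v01_b = delong_variance(scores_b, labels)
    m, n = len(v10_a), len(v01_a)
    with warnings.catch_warnings(), np.errstate(divide="ignore", invalid="ignore"):
        warnings.simplefilter("ignore", RuntimeWarning)
        s10 = np.cov(np.stack([v10_a, v10_b]), bias=False)
        s01 = np.cov(np.stack([v01_a, v01_b]), bias=False)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    # a single case in either class leaves the variance undefined (NaN)
    if not np.isfinite(var) or var <= 0:
        return 1.0
    z = (auc_a - auc_b) / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


@dataclasses.dataclass
class EvaluationReport:
    """The 5 x 4 grid of model results plus AUC-comparison p-values."""

    cells: dict[str, dict]
    selection: dict[str, dict]
    auc_comparisons: dict[str, dict[str, float]]
    split: dict
    provenance: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def table_text(self) -> str:
        """Human-readable grid: rows = images, columns per classifier."""
        lines = []
        for clf in CLASSIFIER_KINDS:
            lines.append(clf.replace("_", " ").title())
            lines.append(f"{'Images':<10} {'AUC':>6} {'Sens':>6} {'Spec':>6}")
            for seq in MODEL_SEQUENCES:
                cell = self.cells.get(f"{seq}::{clf}", {})
                if cell.get("available"):
                    lines.append(f"{seq:<10} {cell['auc']:>6.3f} "
                                 f"{cell['sensitivity']:>6.3f} "
                                 f"{cell['specificity']:>6.3f}")
                else:
                    lines.append(f"{seq:<10} {'--':>6} {'--':>6} {'--':>6}")
            lines.append("")
        return "\n".join(lines)


def evaluate_all(table: FeatureTable,
                 test_fraction: float = 0.2,
                 seed: int = 0,
                 grouping: str = "subject",
                 variance_threshold: float = 0.8,
                 univariate_alpha: float = 0.05,
                 alpha_grid=None,
                 cv_folds: int = 5,
                 sequences: tuple[str, ...] = SEQUENCE_TAGS,
                 provenance: dict | None = None,
                 split_plan: SplitPlan | None = None) -> EvaluationReport:
    """Full split -> per-sequence selection -> 20-cell model evaluation.

    Selection is fitted on training rows only; the combined model
    concatenates each sequence's selected features.  Unavailable cells
    (empty selection) are recorded explicitly, never silently dropped.
    A precomputed ``split_plan`` may be supplied (e.g. to hold the split
    fixed while probing test-label independence).
    """
    plan = split_plan if split_plan is not None \
        else split_cohort(table, test_fraction, seed, grouping)
    is_test = table.frame["lesion_id"].isin(set(plan.test_lesions)).to_numpy()
    train = table.subset_rows(np.flatnonzero(~is_test))
    test = table.subset_rows(np.flatnonzero(is_test))

    selections: dict[str, SelectionResult] = {}
    selected_by_seq: dict[str, list[str]] = {}
    for seq in sequences:
        sel = select_pipeline(train, seq,
                              variance_threshold=variance_threshold,
                              univariate_alpha=univariate_alpha,
                              alpha_grid=alpha_grid, cv_folds=cv_folds,
                              seed=seed)
        selections[seq] = sel
        selected_by_seq[seq] = sel.selected_names

    combined = [n for seq in sequences for n in selected_by_seq[seq]]
    feature_sets = dict(selected_by_seq)
    feature_sets["combined"] = combined

    test_labels = test.labels
    cells: dict[str, dict] = {}
    scores_by_model: dict[str, np.ndarray] = {}
    for seq, names in feature_sets.items():
        for clf in CLASSIFIER_KINDS:
            key = f"{seq}::{clf}"
            if not names:
                cells[key] = {"available": False,
                              "reason": "no features selected",
                              "n_train": train.n_lesions,
                              "n_test": test.n_lesions}
                continue
            model = train_classifier(clf, train.values(names), train.labels,
                                     names, seed=seed)
            scores = predict_scores(model, test)
            fpr, tpr, thr, auc = roc_auc(scores, test_labels)
            threshold, sens, spec = operating_point(fpr, tpr, thr)
            scores_by_model[key] = scores
            cells[key] = {
                "available": True,
                "auc": auc,
                "sensitivity": sens,
                "specificity": spec,
                "threshold": threshold,
                "n_features": len(names),
                "n_train": train.n_lesions,
                "n_test": test.n_lesions,
            }

    comparisons: dict[str, dict[str, float]] = {}
    for clf in CLASSIFIER_KINDS:
        pairs: dict[str, float] = {}
        avail = [seq for seq in feature_sets
                 if f"{seq}::{clf}" in scores_by_model]
        for i, seq_a in enumerate(avail):
            for seq_b in avail[i + 1:]:
                p = compare_auc(scores_by_model[f"{seq_a}::{clf}"],
                                scores_by_model[f"{seq_b}::{clf}"],
                                test_labels)
                pairs[f"{seq_a}_vs_{seq_b}"] = p
        comparisons[clf] = pairs

    return EvaluationReport(
        cells=cells,
        selection={seq: sel.to_dict() for seq, sel in selections.items()},
        auc_comparisons=comparisons,
        split={"train_lesions": plan.train_lesions,
               "test_lesions": plan.test_lesions,
               "seed": seed, "grouping": grouping,
               "hash": plan.split_hash},
        provenance=provenance or {},
    )
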