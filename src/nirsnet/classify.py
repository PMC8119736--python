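"""Linear-SVM group classification on the 20-dimensional feature table.

Repeated stratified 10:3 train/test splits per group, feature
standardization fit on the training split only, fivefold cross-validated
grid search over the SVM penalty C on the training split, and rank-based
ROC/AUC per feature family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .groupstats import FEATURE_METRICS, FEATURE_THRESHOLDS, FeatureTable

POSITIVE_GROUP = "patient"


class ClassifyError(ValueError):
    pass


@dataclass(frozen=True)
class ClassificationConfig:
    kernel: str = "linear"
    c_grid: tuple = (0.01, 0.1, 1.0, 10.0, 100.0)
    g_grid: tuple = ()  # accepted for config compatibility; inert for linear kernel
    n_folds: int = 5
    n_train_per_group: int = 10
    n_test_per_group: int = 3
    n_repeats: int = 24
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ClassifyError("n_folds must be >= 2")
        if not self.c_grid:
            raise ClassifyError("c_grid must be nonempty")
        if self.n_train_per_group < self.n_folds:
            raise ClassifyError("training group smaller than the fold count")
        if self.n_test_per_group < 1 or self.n_repeats < 1:
            raise ClassifyError("n_test_per_group and n_repeats must be >= 1")


@dataclass
class RocCurve:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray


@dataclass
class ClassificationResult:
    accuracies: np.ndarray  # per-repeat test accuracy
    chosen_c: list[float]
    family_roc: dict[str, RocCurve] = field(default_factory=dict)

    @property
    def best_accuracy(self) -> float:
        return float(self.accuracies.max())

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def sd_accuracy(self) -> float:
        return float(self.accuracies.std(ddof=1)) if self.accuracies.size > 1 else 0.0


def split_cohort(
    table: FeatureTable, cfg: ClassificationConfig
) -> list[tuple[list[str], list[str]]]:
    """Seeded stratified splits: per repeat, 10 train / 3 test per group."""
    rng = np.random.default_rng(cfg.seed)
    need = cfg.n_train_per_group + cfg.n_test_per_group
    by_group: dict[str, list[str]] = {}
    for subj, group in table.labels.items():
        by_group.setdefault(group, []).append(subj)
    for group, members in by_group.items():
        if len(members) < need:
            raise ClassifyError(
                f"group {group!r} has {len(members)} subjects; "
                f"{need} needed for a {cfg.n_train_per_group}:{cfg.n_test_per_group} split"
            )
    splits = []
    for _ in range(cfg.n_repeats):
        train: list[str] = []
        test: list[str] = []
        for members in by_group.values():
            order = rng.permutation(len(members))
            chosen = [members[i] for i in order[:need]]
            train.extend(chosen[: cfg.n_train_per_group])
            test.extend(chosen[cfg.n_train_per_group :])
        splits.append((train, test))
    return splits


def train_eval(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_test: np.ndarray,
    y_test: np.ndarray,
    cfg: ClassificationConfig,
) -> tuple[float, float]:
    """Grid-searched linear SVM; returns (test accuracy, chosen C).

    Standardization statistics come from the training split only, inside
    the pipeline, so neither the CV folds nor the test set leak into them.
    """
    if len(set(y_train)) < 2:
        raise ClassifyError("training split contains a single class")
    pipe = Pipeline([("scale", StandardScaler()), ("svm", SVC(kernel=cfg.kernel))])
    cv = StratifiedKFold(n_splits=cfg.n_folds, shuffle=False)
    search = GridSearchCV(pipe, {"svm__C": list(cfg.c_grid)}, cv=cv, scoring="accuracy")
    search.fit(x_train, y_train)
    accuracy = float(search.score(x_test, y_test))
    return accuracy, float(search.best_params_["svm__C"])


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> RocCurve:
    """AUC by the rank (Mann–Whitney) formulation; ties contribute 1/2."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if y.dtype != bool:
        y = y == POSITIVE_GROUP
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ClassifyError("both classes must be present")
    ranks = rankdata(scores)
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    fpr, tpr, _ = roc_curve(y, scores)
    return RocCurve(auc=float(auc), fpr=fpr, tpr=tpr)


def family_rocs(table: FeatureTable) -> dict[str, RocCurve]:
    """ROC/AUC per feature family (metric), scoring each subject by the mean
    of that metric's five standardized threshold columns."""
    out = {}
    y = (table.labels == POSITIVE_GROUP).to_numpy()
    for metric in FEATURE_METRICS:
        cols = [f"{metric}@{s:.2f}" for s in FEATURE_THRESHOLDS]
        x = table.features[cols].to_numpy()
        z = (x - x.mean(axis=0)) / np.where(x.std(axis=0) > 0, x.std(axis=0), 1.0)
        out[metric] = roc_auc(z.mean(axis=1), y)
    return out


def classify_cohort(
    table: FeatureTable,
    cfg: ClassificationConfig | None = None,
    permute_labels: bool = False,
) -> ClassificationResult:
    """Full repeated-split evaluation of the linear-SVM classifier.

    ``permute_labels`` shuffles the group labels once (seeded) before
    splitting — the chance baseline against which real accuracy is judged.
    """
    cfg = cfg or ClassificationConfig()
    labels = table.labels.copy()
    if permute_labels:
        rng = np.random.default_rng(cfg.seed + 1)
        labels = labels.sample(frac=1.0, random_state=int(rng.integers(2**31)))
        labels.index = table.labels.index
    work = FeatureTable(features=table.features, labels=labels)
    x = work.features.to_numpy()
    y = (work.labels == POSITIVE_GROUP).to_numpy().astype(int)
    idx = {subj: i for i, subj in enumerate(work.features.index)}
    accuracies = []
    chosen = []
    for train_ids, test_ids in split_cohort(work, cfg):
        tr = [idx[s] for s in train_ids]
        te = [idx[s] for s in test_ids]
        acc, c = train_eval(x[tr], y[tr], x[te], y[te], cfg)
        accuracies.append(acc)
        chosen.append(c)
    rocs = {} if permute_labels else family_rocs(table)
    return ClassificationResult(
        accuracies=np.array(accuracies), chosen_c=chosen, family_roc=rocs
    )
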