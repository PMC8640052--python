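"""Task comparison and decoding from gaze features.

Two questions about the nine per-trial gaze features: (1) do their
participant-level means differ between the speed and the TTA task
(repeated-measures MANOVA, i.e. a one-sample Hotelling T^2 on the paired
task differences, reported as Wilks's Lambda and its exact F transform);
(2) can the task, or the observer, be decoded from single trials (RBF-kernel
SVM with leave-one-subject-out or tenfold cross-validation, judged against
the no-information rate with binomial and permutation tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold, LeaveOneGroupOut
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .metrics import FEATURE_COLUMNS

__all__ = [
    "TaskComparisonReport",
    "ClassifierReport",
    "manova_compare",
    "train_classifier",
    "loso_cv",
    "kfold_cv",
    "permutation_test",
]


@dataclass
class TaskComparisonReport:
    wilks_lambda: float
    f_stat: float
    df: tuple[int, int]
    p_value: float
    univariate: pd.DataFrame  # per-feature F(1, n-1), p


@dataclass
class ClassifierReport:
    accuracy: float
    ci: tuple[float, float]
    nir: float
    binomial_p: float
    confusion_matrix: pd.DataFrame
    support_vector_fraction: float
    n_test: int
    per_fold_accuracy: list = field(default_factory=list)
    permutation_p: float = float("nan")
    n_permutations: int = 0

    def format_permutation_p(self) -> str:
        if self.n_permutations and self.permutation_p < 1.0 / self.n_permutations:
            return f"< {1.0 / self.n_permutations:.3g}"
        return f"{self.permutation_p:.3f}"


def wilks_from_t2(t2: float, n: int, p: int) -> tuple[float, float, tuple[int, int]]:
    """One-sample transform: Lambda = 1/(1 + T^2/(n-1)), exact F on (p, n-p)."""
    lam = 1.0 / (1.0 + t2 / (n - 1))
    f = ((1.0 - lam) / lam) * ((n - p) / p)
    return float(lam), float(f), (p, n - p)


def manova_compare(task_means: pd.DataFrame,
                   features: list[str] | None = None) -> TaskComparisonReport:
    """Repeated-measures MANOVA over paired per-participant task means.

    ``task_means`` has one row per participant-task with the feature columns;
    the test is a one-sample Hotelling T^2 on the speed-minus-TTA differences.
    """
    features = features or [c for c in FEATURE_COLUMNS if c in task_means.columns]
    wide = task_means.pivot_table(index="participant_id", columns="task",
                                  values=features)
    diffs = np.column_stack([
        wide[(f, "speed")].to_numpy() - wide[(f, "tta")].to_numpy()
        for f in features])
    diffs = diffs[~np.isnan(diffs).any(axis=1)]
    n, p = diffs.shape
    if n - p < 1:
        raise ValueError("need more participants than features for the F transform")
    S = np.cov(diffs, rowvar=False, ddof=1)
    dbar = diffs.mean(axis=0)
    if np.allclose(diffs, 0.0):
        t2 = 0.0  # identical task means: no multivariate effect at all
    else:
        try:
            sol = np.linalg.solve(S, dbar)
        except np.linalg.LinAlgError:
            with np.errstate(invalid="ignore", divide="ignore"):
                corr = np.corrcoef(diffs, rowvar=False)
            bad = [features[i] for i, j in zip(*np.where(np.abs(corr) > 0.999))
                   if i < j]
            raise ValueError(
                f"singular covariance; collinear features: {bad or features}")
        t2 = float(n * dbar @ sol)
    lam, f, df = wilks_from_t2(t2, n, p)
    p_value = float(stats.f.sf(f, *df))
    rows = []
    for i, feat in enumerate(features):
        t, pu = stats.ttest_1samp(diffs[:, i], 0.0)
        rows.append({"feature": feat, "F": float(t**2), "df": (1, n - 1),
                     "p": float(pu)})
    return TaskComparisonReport(wilks_lambda=lam, f_stat=f, df=df,
                                p_value=p_value,
                                univariate=pd.DataFrame(rows))


def _make_svm(c: float = 1.0, gamma="scale"):
    # features z-scored with training-fold statistics only
    return make_pipeline(StandardScaler(), SVC(C=c, gamma=gamma, kernel="rbf"))


def train_classifier(features: np.ndarray, labels: np.ndarray,
                     c: float = 1.0, gamma="scale"):
    """Fit the RBF-kernel maximum-margin classifier.

    Returns the fitted pipeline; ``support_vector_fraction`` is the share of
    training points retained as support vectors.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("training set contains a single class")
    clf = _make_svm(c, gamma)
    clf.fit(features, labels)
    svc = clf.named_steps["svc"]
    clf.support_vector_fraction = float(svc.n_support_.sum() / len(labels))
    return clf


def _evaluate_folds(X, y, splits, c=1.0, gamma="scale"):
    """Run CV folds; returns per-fold accuracy/NIR and pooled predictions."""
    accs, nirs, sv_fracs = [], [], []
    y_true_all, y_pred_all = [], []
    for train_idx, test_idx in splits:
        clf = train_classifier(X[train_idx], y[train_idx], c, gamma)
        pred = clf.predict(X[test_idx])
        truth = y[test_idx]
        accs.append(float(np.mean(pred == truth)))
        # NIR: always predict the test set's modal class
        _, counts = np.unique(truth, return_counts=True)
        nirs.append(float(counts.max() / counts.sum()))
        sv_fracs.append(clf.support_vector_fraction)
        y_true_all.append(truth)
        y_pred_all.append(pred)
    return accs, nirs, sv_fracs, np.concatenate(y_true_all), np.concatenate(y_pred_all)


def _report(accs, nirs, sv_fracs, y_true, y_pred) -> ClassifierReport:
    acc = float(np.mean(accs))
    nir = float(np.mean(nirs))
    n = len(y_true)
    k = int(np.sum(y_true == y_pred))
    binom = stats.binomtest(k, n, p=min(nir, 1 - 1e-12), alternative="greater")
    se = np.std(accs, ddof=1) / np.sqrt(len(accs)) if len(accs) > 1 else 0.0
    labels = np.unique(np.concatenate([y_true, y_pred]))
    cm = pd.DataFrame(0, index=labels, columns=labels)
    for t, p_ in zip(y_true, y_pred):
        cm.loc[t, p_] += 1
    return ClassifierReport(
        accuracy=acc, ci=(acc - 1.96 * se, acc + 1.96 * se), nir=nir,
        binomial_p=float(binom.pvalue), confusion_matrix=cm,
        support_vector_fraction=float(np.mean(sv_fracs)), n_test=n,
        per_fold_accuracy=list(accs))


def loso_cv(features: pd.DataFrame, label: str = "task",
            feature_cols: list[str] | None = None,
            c: float = 1.0, gamma="scale") -> ClassifierReport:
    """Leave-one-subject-out CV: each participant in turn is the test set."""
    cols = feature_cols or [f for f in FEATURE_COLUMNS if f in features.columns]
    df = features.dropna(subset=cols)
    groups = df["participant_id"].to_numpy()
    if len(np.unique(groups)) < 3:
        raise ValueError("need at least 3 participants for LOSO CV")
    X = df[cols].to_numpy(dtype=float)
    y = df[label].to_numpy()
    splits = LeaveOneGroupOut().split(X, y, groups)
    return _report(*_evaluate_folds(X, y, list(splits), c, gamma))


def kfold_cv(features: pd.DataFrame, label: str = "participant_id", k: int = 10,
             seed: int = 0, feature_cols: list[str] | None = None,
             c: float = 1.0, gamma="scale") -> ClassifierReport:
    """Tenfold CV with seeded random (unstratified) folds."""
    cols = feature_cols or [f for f in FEATURE_COLUMNS if f in features.columns]
    df = features.dropna(subset=cols)
    X = df[cols].to_numpy(dtype=float)
    y = df[label].to_numpy()
    if len(y) < k * len(np.unique(y)):
        raise ValueError("too few observations for the requested fold count")
    splits = KFold(n_splits=k, shuffle=True, random_state=seed).split(X)
    return _report(*_evaluate_folds(X, y, list(splits), c, gamma))


def permutation_test(features: pd.DataFrame, label: str,
                     scheme: str = "loso", k: int = 10, n_perm: int = 1000,
                     seed: int = 0, within_participant: bool | None = None,
                     feature_cols: list[str] | None = None,
                     c: float = 1.0, gamma="scale") -> ClassifierReport:
    """Permutation p for the CV accuracy under label-feature independence.

    Task labels are permuted within participant (respecting exchangeability
    of trials inside a session pair); observer labels globally.  One-sided:
    p = (number of permuted accuracies >= observed) / n_perm.
    """
    if within_participant is None:
        within_participant = label == "task"
    rng = np.random.default_rng(seed)
    runner = (lambda d: loso_cv(d, label, feature_cols, c, gamma)) \
        if scheme == "loso" else \
        (lambda d: kfold_cv(d, label, k, seed, feature_cols, c, gamma))
    observed = runner(features)
    count = 0
    df = features.copy()
    for _ in range(n_perm):
        if within_participant:
            perm = df[label].to_numpy().copy()
            for _pid, idx in df.groupby("participant_id", sort=False).groups.items():
                pos = df.index.get_indexer(idx)
                perm[pos] = perm[pos][rng.permutation(len(pos))]
            df[label] = perm
        else:
            df[label] = df[label].to_numpy()[rng.permutation(len(df))]
        if runner(df).accuracy >= observed.accuracy - 1e-12:
            count += 1
    observed.permutation_p = count / n_perm
    observed.n_permutations = n_perm
    return observed
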