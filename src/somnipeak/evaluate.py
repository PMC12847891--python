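"""Reliability and classification analyses on component scores.

Split-half reliability: subjects are divided into two group-balanced halves,
PCA is fit on each half and on the full sample, components are matched
across fits by greedy maximum-|Spearman| assignment of their loading
vectors (PCA order and sign are arbitrary across subsets), and the matched
absolute correlations are reported. |r| > 0.75 is labelled highly reliable,
|r| > 0.5 moderately reliable.

Classification: one-vs-all ridge-penalized logistic regression on component
scores with stratified 5-fold cross-validation; each subject is validated
exactly once; fold-wise ROC-AUCs are averaged. Significance comes from a
label-shuffle permutation test (default 1000 shuffles, full CV re-run per
shuffle) with the smoothed estimator p = (1 + #{null >= observed}) /
(1 + n_perm), which avoids reporting an exact zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import spearmanr
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .decompose import FeatureMatrix, fit_pca

__all__ = [
    "ReliabilityReport",
    "ClassifierReport",
    "split_half",
    "match_components",
    "reliability",
    "one_vs_all_classify",
    "permutation_test",
]


@dataclass
class ReliabilityReport:
    """Matched half-vs-full loading correlations per component index."""

    r_half_a: np.ndarray
    r_half_b: np.ndarray
    labels: list[str]                # 'high' / 'moderate' / 'low' per index
    seed: int
    flagged: bool = False

    @staticmethod
    def label(r: float) -> str:
        return "high" if r > 0.75 else ("moderate" if r > 0.5 else "low")


@dataclass
class ClassifierReport:
    """One-vs-all classification outcome for one target group."""

    target: str
    fold_aucs: np.ndarray
    mean_auc: float
    null_aucs: np.ndarray
    p_perm: float
    seed: int
    n_perm: int


def split_half(group_labels: list[str], seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Randomly split subjects into two group-balanced halves.

    Each group is split as evenly as possible (half sizes differ by at most
    one within a group); the halves are disjoint and exhaustive. A singleton
    group goes wholly to one half, with a warning.
    """
    labels = np.asarray(group_labels)
    rng = np.random.default_rng(seed)
    a, b = [], []
    for g in dict.fromkeys(group_labels):
        idx = np.flatnonzero(labels == g)
        if len(idx) == 1:
            warnings.warn(f"group {g!r} has one subject; assigned to one half")
        perm = rng.permutation(idx)
        half = len(perm) // 2 + (len(perm) % 2 and rng.random() < 0.5)
        a.extend(perm[:int(half)])
        b.extend(perm[int(half):])
    return np.sort(np.array(a, dtype=int)), np.sort(np.array(b, dtype=int))


def match_components(loadings_a: np.ndarray, loadings_b: np.ndarray,
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Greedy maximum-|Spearman| bipartite matching of loading rows.

    Returns (pairing, signs, r): ``pairing[i]`` is the row of B matched to
    row i of A, ``signs[i]`` the sign of that correlation, ``r[i]`` its
    absolute value. Each B row is used at most once.
    """
    na, nb = loadings_a.shape[0], loadings_b.shape[0]
    C = np.zeros((na, nb))
    for i in range(na):
        for j in range(nb):
            C[i, j] = spearmanr(loadings_a[i], loadings_b[j]).statistic
    C = np.nan_to_num(C)
    pairing = np.full(na, -1)
    signs = np.zeros(na)
    rabs = np.zeros(na)
    absC = np.abs(C).copy()
    for _ in range(min(na, nb)):
        i, j = np.unravel_index(np.argmax(absC), absC.shape)
        if absC[i, j] < 0:
            break
        pairing[i] = j
        signs[i] = np.sign(C[i, j]) or 1.0
        rabs[i] = abs(C[i, j])
        absC[i, :] = -1.0
        absC[:, j] = -1.0
    return pairing, signs, rabs


def reliability(fm: FeatureMatrix, group_labels: list[str], seed: int,
                n_top: int = 5) -> ReliabilityReport:
    """Split-half eigenvector reliability of the first ``n_top`` components.

    PCA is fit on each half and on all subjects; each half's loadings are
    matched to the full-sample loadings and the matched |Spearman r| of the
    first ``n_top`` full-sample components is reported for both halves.
    """
    if fm.data.shape[0] < 6:
        raise ValueError("need >= 6 subjects for split-half reliability")
    from dataclasses import replace

    idx_a, idx_b = split_half(group_labels, seed)
    full = fit_pca(fm, n_components=min(n_top, fm.data.shape[0] - 1))
    flagged = False
    rs = []
    for idx in (idx_a, idx_b):
        sub = replace(fm, data=fm.data[idx],
                      subjects=[fm.subjects[i] for i in idx])
        try:
            half = fit_pca(sub, n_components=min(n_top, len(idx) - 1))
        except Exception:
            flagged = True
            rs.append(np.full(full.n_components, np.nan))
            continue
        _, _, r = match_components(full.loadings, half.loadings)
        rs.append(r)
    r_a, r_b = rs
    labels = [ReliabilityReport.label(min(ra, rb)) if np.isfinite(ra) and np.isfinite(rb)
              else "low" for ra, rb in zip(r_a, r_b)]
    return ReliabilityReport(r_a, r_b, labels, seed, flagged)


def _cv_mean_auc(X: np.ndarray, y: np.ndarray, n_folds: int, seed: int,
                 C: float = 1.0) -> tuple[float, np.ndarray]:
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    aucs = []
    for train, test in skf.split(X, y):
        if len(np.unique(y[train])) < 2 or len(np.unique(y[test])) < 2:
            raise ValueError("a fold lost one of the classes; too few subjects")
        model = LogisticRegression(C=C, max_iter=1000)   # ridge (L2) penalty
        model.fit(X[train], y[train])
        prob = model.predict_proba(X[test])[:, 1]
        aucs.append(roc_auc_score(y[test], prob))
    aucs = np.asarray(aucs)
    return float(aucs.mean()), aucs


def one_vs_all_classify(scores: np.ndarray, group_labels: list[str],
                        target: str, n_folds: int = 5, seed: int = 0,
                        ridge_c: float = 1.0) -> tuple[float, np.ndarray]:
    """Stratified k-fold one-vs-all logistic regression; fold AUCs + mean.

    The binary labels are target group vs pooled remainder; AUC is computed
    from the held-out predicted probabilities in each fold, then averaged.
    """
    labels = np.asarray(group_labels)
    if target not in labels:
        raise ValueError(f"target group {target!r} absent")
    y = (labels == target).astype(int)
    if y.sum() < n_folds:
        raise ValueError("target group smaller than the number of folds")
    mean_auc, fold_aucs = _cv_mean_auc(np.asarray(scores, dtype=float), y,
                                       n_folds, seed, ridge_c)
    return mean_auc, fold_aucs


def permutation_test(scores: np.ndarray, group_labels: list[str], target: str,
                     n_perm: int = 1000, n_folds: int = 5, seed: int = 0,
                     ridge_c: float = 1.0, smoothed: bool = True,
                     ) -> ClassifierReport:
    """Label-shuffle permutation test of the one-vs-all mean ROC-AUC.

    Each permutation shuffles subjects' group labels, re-runs the full
    cross-validation and records the mean AUC. The smoothed p-value
    (1 + #{null >= observed}) / (1 + n_perm) is reported by default; the
    plain proportion is available with ``smoothed=False``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    X = np.asarray(scores, dtype=float)
    labels = np.asarray(group_labels)
    y = (labels == target).astype(int)
    mean_auc, fold_aucs = _cv_mean_auc(X, y, n_folds, seed, ridge_c)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        y_perm = rng.permutation(y)
        null[b], _ = _cv_mean_auc(X, y_perm, n_folds, seed, ridge_c)
    k = int((null >= mean_auc).sum())
    p = (1 + k) / (1 + n_perm) if smoothed else k / n_perm
    return ClassifierReport(target, fold_aucs, mean_auc, null, float(p),
                            seed, n_perm)
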