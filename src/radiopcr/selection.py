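"""Stability-based univariate feature selection.

The procedure is deliberately simple and ad hoc: the merged cohort is split
into 8 stratified folds; for each of the 8 leave-one-fold-out subsets every
feature is tested for a class difference (Welch t-test when both classes
pass Shapiro–Wilk normality at alpha = 0.05, Wilcoxon–Mann–Whitney
otherwise) and earns a vote when p < 0.05. Features voted significant in at
least 5 of the 8 subsets form the stable set, which is then greedily pruned
so that no surviving pair has |Pearson r| >= 0.6.

Selection runs once on the full merged table, before model cross-validation;
the optimistic bias this induces on downstream CV estimates is a property of
the reproduced protocol and is flagged in the selection report rather than
silently corrected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .table import FeatureTable

__all__ = [
    "SelectionReport",
    "make_folds",
    "univariate_p",
    "stability_votes",
    "select_stable",
    "prune_correlated",
    "select_features",
]

SHAPIRO_ALPHA = 0.05


@dataclass
class SelectionReport:
    """Everything the selection stage decided, reproducible from ``seed``."""

    fold_assignment: np.ndarray  # fold index per case, 0..k-1
    votes: dict[str, int]
    median_p: dict[str, float]
    stable_set: list[str]
    pruned_set: list[str]
    alpha: float
    min_votes: int
    r_max: float
    seed: int
    notes: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "fold_assignment": self.fold_assignment.tolist(),
            "votes": self.votes,
            "median_p": self.median_p,
            "stable_set": self.stable_set,
            "pruned_set": self.pruned_set,
            "alpha": self.alpha,
            "min_votes": self.min_votes,
            "r_max": self.r_max,
            "seed": self.seed,
            "notes": self.notes,
        }


def make_folds(labels: np.ndarray, k: int = 8, seed: int = 0) -> np.ndarray:
    """Stratified fold assignment (fold index per case), deterministic under seed.

    Fold sizes differ by at most one case, and so do per-class counts across
    folds.
    """
    labels = np.asarray(labels, dtype=int)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both label classes must be present")
    if counts.min() < k:
        raise ValueError(f"each class needs at least k={k} members to stratify")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(labels), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros((len(labels), 1)), labels)):
        assignment[test_idx] = fold
    return assignment


def _is_normal(x: np.ndarray) -> bool:
    # Shapiro-Wilk has essentially no power below ~8 observations; tiny
    # classes fall through to the rank test
    if len(np.unique(x)) < 3 or len(x) < 8:
        return False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return stats.shapiro(x).pvalue > SHAPIRO_ALPHA


def univariate_p(values: np.ndarray, labels: np.ndarray) -> float:
    """Two-sided p-value for a class difference in one feature.

    Welch t-test when both classes pass Shapiro–Wilk normality, otherwise
    Wilcoxon–Mann–Whitney (exact for small tie-free samples, tie-corrected
    normal approximation otherwise). Constant values in both classes give
    p = 1 by convention.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    x0, x1 = values[labels == 0], values[labels == 1]
    if x0.size == 0 or x1.size == 0:
        raise ValueError("both classes must be non-empty")
    if np.unique(values).size < 2:
        return 1.0
    if _is_normal(x0) and _is_normal(x1):
        p = stats.ttest_ind(x0, x1, equal_var=False).pvalue
    else:
        p = stats.mannwhitneyu(x0, x1, alternative="two-sided", method="auto").pvalue
    if not np.isfinite(p):
        return 1.0
    return float(min(max(p, np.nextafter(0, 1)), 1.0))


def _pvals_matrix(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Column-wise p-values; vectorises the rank tests, loops the normality gate."""
    x0, x1 = X[labels == 0], X[labels == 1]
    n_feat = X.shape[1]
    normal = np.zeros(n_feat, dtype=bool)
    const = np.zeros(n_feat, dtype=bool)
    for j in range(n_feat):
        col = X[:, j]
        if np.unique(col).size < 2:
            const[j] = True
            continue
        normal[j] = _is_normal(x0[:, j]) and _is_normal(x1[:, j])
    p = np.ones(n_feat)
    t_cols = normal & ~const
    w_cols = ~normal & ~const
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if t_cols.any():
            p[t_cols] = stats.ttest_ind(
                x0[:, t_cols], x1[:, t_cols], equal_var=False, axis=0
            ).pvalue
        if w_cols.any():
            p[w_cols] = stats.mannwhitneyu(
                x0[:, w_cols], x1[:, w_cols], alternative="two-sided", axis=0
            ).pvalue
    p[~np.isfinite(p)] = 1.0
    return np.clip(p, np.nextafter(0, 1), 1.0)


def stability_votes(
    table: FeatureTable, folds: np.ndarray, alpha: float = 0.05
) -> tuple[dict[str, int], np.ndarray]:
    """Significance votes over the k leave-one-fold-out subsets.

    Returns the per-feature vote counts (0..k) and the full k x n_features
    p-value matrix (rows = left-out fold).
    """
    folds = np.asarray(folds, dtype=int)
    k = int(folds.max()) + 1
    pmat = np.empty((k, table.n_features))
    for left_out in range(k):
        keep = folds != left_out
        pmat[left_out] = _pvals_matrix(table.values[keep], table.labels[keep])
    counts = (pmat < alpha).sum(axis=0)
    votes = {f: int(c) for f, c in zip(table.feature_ids, counts)}
    return votes, pmat


def select_stable(votes: dict[str, int], min_votes: int = 5) -> list[str]:
    """Features voted significant at least ``min_votes`` times, order-preserving."""
    return [f for f, v in votes.items() if v >= min_votes]


def prune_correlated(
    table: FeatureTable,
    stable_set: list[str],
    r_max: float = 0.6,
    priority: dict[str, float] | None = None,
    votes: dict[str, int] | None = None,
) -> list[str]:
    """Greedy redundancy pruning of the stable set.

    Candidates are visited by ascending priority (median p-value across the
    leave-one-fold-out subsets; ties broken by descending vote count, then
    feature id), and accepted iff |Pearson r| < ``r_max`` against every
    already-accepted feature.
    """
    if not stable_set:
        return []
    priority = priority or {}
    votes = votes or {}
    order = sorted(
        stable_set,
        key=lambda f: (priority.get(f, 1.0), -votes.get(f, 0), f),
    )
    cols = {f: table.values[:, table.feature_ids.index(f)] for f in order}
    accepted: list[str] = []
    for f in order:
        x = cols[f]
        ok = True
        for g in accepted:
            r = np.corrcoef(x, cols[g])[0, 1]
            if not np.isfinite(r):
                r = 1.0  # constant column: treat as redundant
            if abs(r) >= r_max:
                ok = False
                break
        if ok:
            accepted.append(f)
    return accepted


def select_features(
    table: FeatureTable,
    k: int = 8,
    alpha: float = 0.05,
    min_votes: int = 5,
    r_max: float = 0.6,
    seed: int = 0,
) -> SelectionReport:
    """Run the full selection stage and return its report."""
    folds = make_folds(table.labels, k=k, seed=seed)
    votes, pmat = stability_votes(table, folds, alpha=alpha)
    median_p = {
        f: float(np.median(pmat[:, j])) for j, f in enumerate(table.feature_ids)
    }
    stable = select_stable(votes, min_votes=min_votes)
    pruned = prune_correlated(table, stable, r_max=r_max, priority=median_p, votes=votes)
    return SelectionReport(
        fold_assignment=folds,
        votes=votes,
        median_p=median_p,
        stable_set=stable,
        pruned_set=pruned,
        alpha=alpha,
        min_votes=min_votes,
        r_max=r_max,
        seed=seed,
        notes={
            "bias_note": (
                "selection runs once on the full merged table before model CV; "
                "downstream CV AUCs inherit the optimistic bias of this protocol"
            )
        },
    )
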