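"""Significance machinery: permutation tests, DeLong ROC comparison, and
demographics statistics.

The permutation test for accuracy refits the entire classification pipeline
under randomly permuted group labels and reports the fraction of
permutations at least as accurate as the observed run (the plain count/n
estimator; an optional (count+1)/(n+1) variant is available). The DeLong
test compares two correlated AUCs computed on the same subjects via
placement-value covariances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


@dataclass
class PermutationResult:
    observed: float
    permuted: np.ndarray
    p_value: float
    n_perm: int
    seed: int
    statistic: str = "accuracy"


@dataclass
class RocComparison:
    auc1: float
    auc2: float
    z: float
    p_value: float
    n: int


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve, Mann-Whitney formulation.

    Mean over all (positive, negative) pairs of 1[s_pos > s_neg] + 0.5 on
    ties; computed via midranks so it is exact under ties.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = labels == 1
    m = int(pos.sum())
    n = int((~pos).sum())
    if m == 0 or n == 0:
        raise ValueError("roc_auc requires both classes present")
    ranks = sps.rankdata(scores)
    return float((ranks[pos].sum() - m * (m + 1) / 2) / (m * n))


def _perm_p(observed: float, permuted: np.ndarray, tail: str,
            estimator: str) -> float:
    if tail == "ge":
        count = int((permuted >= observed).sum())
    elif tail == "gt":
        count = int((permuted > observed).sum())
    else:
        raise ValueError("tail must be 'ge' or 'gt'")
    if estimator == "count":
        return count / len(permuted)
    if estimator == "count_plus_one":
        return (count + 1) / (len(permuted) + 1)
    raise ValueError("estimator must be 'count' or 'count_plus_one'")


def permutation_test_accuracy(
    table,
    p_threshold: float | None = None,
    grid=None,
    n_perm: int = 1000,
    seed: int = 0,
    tail: str = "ge",
    estimator: str = "count",
) -> PermutationResult:
    """Label-shuffling permutation test of LOOCV classification accuracy.

    Each permutation reassigns the existing label multiset to subjects at
    random ("without replacement") and reruns the full pipeline — scaling,
    t-test selection and base-classifier fitting inside every fold. With a
    fixed p_threshold only that threshold is evaluated; with grid the whole
    grid search is repeated per permutation (much slower).
    """
    from .pipeline import UntrainableError, grid_search_threshold, loocv_evaluate

    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")

    def run(tbl) -> float:
        try:
            if grid is not None:
                summary, _, _ = grid_search_threshold(tbl, grid)
                return summary.accuracy
            _, summary = loocv_evaluate(tbl, p_threshold)
            return summary.accuracy
        except UntrainableError:
            # every fold abstained: the zero vote score predicts HC throughout
            return float((np.asarray(tbl.labels) == 0).mean())

    if grid is not None and n_perm > 50:
        import warnings

        warnings.warn(
            "full grid search inside a large permutation test is slow; "
            "consider fixed-threshold mode",
            RuntimeWarning,
            stacklevel=2,
        )
    observed = run(table)
    rng = np.random.default_rng(seed)
    permuted = np.empty(n_perm)
    for i in range(n_perm):
        shuffled = replace_labels(table, rng.permutation(table.labels))
        permuted[i] = run(shuffled)
    return PermutationResult(
        observed, permuted, _perm_p(observed, permuted, tail, estimator),
        n_perm, seed, "accuracy",
    )


def replace_labels(table, new_labels):
    from .feature_extraction import FeatureTable

    return FeatureTable(
        table.matrix, table.feature_index, np.asarray(new_labels),
        table.subject_ids,
    )


def permutation_test_auc(
    scores,
    labels,
    n_perm: int = 1000,
    seed: int = 0,
    tail: str = "ge",
    estimator: str = "count",
) -> PermutationResult:
    """Permutation test of the AUC of a continuous score vector.

    Permutes the score vector against the fixed labels and recomputes the
    AUC each time.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    observed = roc_auc(scores, labels)
    rng = np.random.default_rng(seed)
    permuted = np.empty(n_perm)
    for i in range(n_perm):
        permuted[i] = roc_auc(rng.permutation(scores), labels)
    return PermutationResult(
        observed, permuted, _perm_p(observed, permuted, tail, estimator),
        n_perm, seed, "auc",
    )


def _placements(scores: np.ndarray, pos: np.ndarray):
    """DeLong placement values (V10 for positives, V01 for negatives)."""
    x = scores[pos]
    y = scores[~pos]
    m, n = len(x), len(y)
    tx = sps.rankdata(x)
    ty = sps.rankdata(y)
    tz = sps.rankdata(np.concatenate([x, y]))
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    auc = float(v10.mean())
    return auc, v10, v01


def delong_test(scores1, scores2, labels) -> RocComparison:
    """DeLong comparison of two correlated AUCs on the same subjects.

    Uses placement values per class; the variance of the AUC difference is
    S10/m + S01/n with S the 2x2 covariance matrices of paired placements.
    Identical scores (zero variance of the difference) give z = 0, p = 1.
    """
    scores1 = np.asarray(scores1, dtype=float)
    scores2 = np.asarray(scores2, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not (scores1.shape == scores2.shape == labels.shape):
        raise ValueError("scores1, scores2 and labels must align")
    pos = labels == 1
    m = int(pos.sum())
    n = int((~pos).sum())
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    auc1, v10_1, v01_1 = _placements(scores1, pos)
    auc2, v10_2, v01_2 = _placements(scores2, pos)
    s10 = np.cov(np.vstack([v10_1, v10_2]))
    s01 = np.cov(np.vstack([v01_1, v01_2]))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= 1e-16:
        return RocComparison(auc1, auc2, 0.0, 1.0, len(labels))
    z = (auc1 - auc2) / np.sqrt(var_diff)
    p = 2 * sps.norm.sf(abs(z))
    return RocComparison(auc1, auc2, float(z), float(p), len(labels))


def chi_square_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on a 2x2 table, 1 d.f."""
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("counts must be nonnegative")
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero margin in 2x2 table")
    res = sps.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)


def t_from_summary(
    m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int
) -> tuple[float, int, float]:
    """Pooled-variance two-sample t from group summaries.

    Returns (t, df, two-sided p) with df = n1 + n2 - 2.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be >= 2")
    t, p = sps.ttest_ind_from_stats(m1, sd1, n1, m2, sd2, n2, equal_var=True)
    return float(t), n1 + n2 - 2, float(p)
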