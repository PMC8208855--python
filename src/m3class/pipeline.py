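"""The M3 discriminative procedure.

Five per-modality base classifiers (maximum-uncertainty LDA on the features
surviving a two-sample t-test at a P threshold) are fused into one
classifier by weighted voting; performance is estimated by leave-one-out
cross-validation (LOOCV), the selection P threshold is tuned by a 50-point
grid search on the LOOCV accuracy, and fold-aggregated feature weights rank
the discriminative regions.

Everything fit-like — the z-score scaler, the t-test selection, the MLDA
models and the voting weights — is a function of the training rows of each
fold only (default protocol), so the held-out subject never leaks into the
model that classifies it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .feature_extraction import FeatureTable
from .mlda import MldaModel, fit_mlda, predict_mlda
from .stats import roc_auc

logger = logging.getLogger(__name__)


class UntrainableError(ValueError):
    """No modality retains any feature at the requested threshold."""


def default_grid() -> np.ndarray:
    """The canonical selection-threshold grid: 0.001 to 0.050, step 0.001."""
    return np.round(np.arange(1, 51) * 0.001, 3)


# ---------------------------------------------------------------------------
# z-score standardization


@dataclass
class Scaler:
    """Per-feature training mean and SD; zero-variance features are dropped.

    kept holds the original column indices that survive; apply() returns
    only those columns, standardized with the training parameters.
    """

    mean: np.ndarray
    sd: np.ndarray
    kept: np.ndarray
    n_original: int

    def apply(self, rows: np.ndarray) -> np.ndarray:
        rows = np.atleast_2d(np.asarray(rows, dtype=float))
        if rows.shape[1] != self.n_original:
            raise ValueError(
                f"expected {self.n_original} features, got {rows.shape[1]}"
            )
        return (rows[:, self.kept] - self.mean) / self.sd


def zscore_fit(train: np.ndarray) -> Scaler:
    """Fit a z-score scaler on training rows (sample SD, ddof=1)."""
    train = np.asarray(train, dtype=float)
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=1)
    keep = sd > 1e-12
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("zscore_fit: dropped %d zero-variance features", n_dropped)
    kept = np.flatnonzero(keep)
    return Scaler(mean[kept], sd[kept], kept, train.shape[1])


def zscore_apply(scaler: Scaler, rows: np.ndarray) -> np.ndarray:
    return scaler.apply(rows)


# ---------------------------------------------------------------------------
# t-test feature selection


@dataclass
class SelectionResult:
    """Per-feature two-sample t statistics and the per-modality survivors.

    Arrays are aligned to the scaler's kept columns; selected maps each
    modality to positions into that kept-column array, selected_original to
    the original feature-table column indices.
    """

    p_threshold: float
    t_stats: np.ndarray
    p_values: np.ndarray
    selected: dict[str, np.ndarray]
    selected_original: dict[str, np.ndarray]


def feature_t_tests(xs: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Equal-variance two-sample two-tailed t per feature column (SZ - HC)."""
    t, p = sps.ttest_ind(xs[y == 1], xs[y == 0], axis=0, equal_var=True)
    return np.asarray(t), np.asarray(p)


def select_features_ttest(
    xs: np.ndarray,
    y: np.ndarray,
    p_threshold: float,
    blocks: dict[str, np.ndarray],
    kept: np.ndarray | None = None,
) -> SelectionResult:
    """Keep, per modality block independently, the features with P <= threshold.

    blocks maps modality name to kept-column positions; kept (original column
    indices per position) is used to report original indices.
    """
    if not 0 < p_threshold < 1:
        raise ValueError("p_threshold must be in (0, 1)")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required for selection")
    t, p = feature_t_tests(xs, y)
    selected = {}
    selected_orig = {}
    for mod, positions in blocks.items():
        sel = positions[p[positions] <= p_threshold]
        selected[mod] = sel
        selected_orig[mod] = kept[sel] if kept is not None else sel
        if sel.size == 0:
            logger.info(
                "selection: modality %s empty at P <= %g (abstains)",
                mod, p_threshold,
            )
    return SelectionResult(p_threshold, t, p, selected, selected_orig)


# ---------------------------------------------------------------------------
# the fused model


@dataclass
class M3Model:
    """Five per-modality MLDA base classifiers fused by weighted voting."""

    scaler: Scaler
    selection: SelectionResult
    base_models: dict[str, MldaModel | None]
    voting_weights: dict[str, float]
    modalities: list[str]
    p_threshold: float

    def __post_init__(self) -> None:
        total = sum(self.voting_weights.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError("voting weights must sum to 1")


def _kept_blocks(blocks: dict[str, np.ndarray], kept: np.ndarray
                 ) -> dict[str, np.ndarray]:
    """Map original-column modality blocks to kept-column positions."""
    if kept.size == 0:
        return {mod: np.empty(0, dtype=int) for mod in blocks}
    pos_of = -np.ones(int(kept.max()) + 1, dtype=int)
    pos_of[kept] = np.arange(kept.size)
    out = {}
    for mod, cols in blocks.items():
        cols = np.asarray(cols)
        inside = cols[cols < pos_of.shape[0]] if pos_of.size else cols[:0]
        positions = pos_of[inside]
        out[mod] = positions[positions >= 0]
    return out


def _fit_bases(
    xs: np.ndarray,
    y: np.ndarray,
    selection: SelectionResult,
    cache: dict | None = None,
) -> tuple[dict[str, MldaModel | None], dict[str, float]]:
    """Fit one MLDA per non-empty modality; weights = training accuracy,
    normalized to sum 1 over the non-abstaining modalities."""
    models: dict[str, MldaModel | None] = {}
    raw: dict[str, float] = {}
    for mod, sel in selection.selected.items():
        if sel.size == 0:
            models[mod] = None
            raw[mod] = 0.0
            continue
        key = (mod, sel.tobytes())
        hit = cache.get(key) if cache is not None else None
        if hit is None:
            model = fit_mlda(xs[:, sel], y)
            train_pred, _ = predict_mlda(model, xs[:, sel])
            acc = float((train_pred == y).mean())
            hit = (model, acc)
            if cache is not None:
                cache[key] = hit
        models[mod], raw[mod] = hit
    total = sum(raw.values())
    if total == 0:
        if all(m is None for m in models.values()):
            raise UntrainableError(
                f"every modality selection empty at P <= {selection.p_threshold}"
            )
        active = [m for m, model in models.items() if model is not None]
        weights = {m: (1.0 / len(active) if m in active else 0.0) for m in models}
    else:
        weights = {m: raw[m] / total for m in models}
    return models, weights


def fit_m3(
    x: np.ndarray,
    y: np.ndarray,
    p_threshold: float,
    blocks: dict[str, np.ndarray],
) -> M3Model:
    """Fit the full fused model on a training set.

    blocks maps each modality to its original column indices. The scaler,
    selection and every base classifier are fit on (x, y) only.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    scaler = zscore_fit(x)
    xs = scaler.apply(x)
    kb = _kept_blocks(blocks, scaler.kept)
    selection = select_features_ttest(xs, y, p_threshold, kb, kept=scaler.kept)
    models, weights = _fit_bases(xs, y, selection)
    return M3Model(scaler, selection, models, weights, list(blocks), p_threshold)


def fit_m3_table(table: FeatureTable, p_threshold: float) -> M3Model:
    return fit_m3(table.matrix, table.labels, p_threshold,
                  table.modality_blocks())


def predict_m3(model: M3Model, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Weighted-vote fusion of the base classifiers.

    Each base classifier votes +1 (SZ) or -1 (HC); the vote score is the
    weighted sum in [-1, 1] and the fused label is SZ when the score is
    strictly positive (ties go to HC).
    """
    xs = model.scaler.apply(x)
    score = np.zeros(xs.shape[0])
    for mod in model.modalities:
        base = model.base_models.get(mod)
        w = model.voting_weights.get(mod, 0.0)
        if base is None or w == 0.0:
            continue
        sel = model.selection.selected[mod]
        pred, _ = predict_mlda(base, xs[:, sel])
        score += w * (2 * pred - 1)
    labels = (score > 0).astype(int)
    return labels, score


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class FoldModality:
    """What one base classifier looked like inside one LOOCV fold."""

    selected: np.ndarray  # original column indices
    coef: np.ndarray
    voting_weight: float


@dataclass
class CvResult:
    """Per-fold predictions and fitted-model snapshots from a LOOCV run."""

    y_true: np.ndarray
    y_pred: np.ndarray
    vote_scores: np.ndarray
    folds: list[dict[str, FoldModality]]
    p_threshold: float
    feature_index: list[tuple[str, int, str]]
    modalities: list[str]
    subject_ids: list[str] = field(default_factory=list)

    @property
    def n_folds(self) -> int:
        return len(self.folds)


@dataclass
class PerformanceSummary:
    """Accuracy/sensitivity/specificity (SZ positive) and vote-score AUC."""

    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    n_pos: int
    n_neg: int
    optimal_p_threshold: float | None = None

    @classmethod
    def from_cv(cls, cv: CvResult,
                optimal_p_threshold: float | None = None) -> "PerformanceSummary":
        y, yhat = cv.y_true, cv.y_pred
        pos = y == 1
        tp = int((yhat[pos] == 1).sum())
        tn = int((yhat[~pos] == 0).sum())
        n_pos = int(pos.sum())
        n_neg = int((~pos).sum())
        return cls(
            accuracy=(tp + tn) / len(y),
            sensitivity=tp / n_pos if n_pos else float("nan"),
            specificity=tn / n_neg if n_neg else float("nan"),
            auc=roc_auc(cv.vote_scores, y),
            n_pos=n_pos,
            n_neg=n_neg,
            optimal_p_threshold=optimal_p_threshold,
        )


def _loocv_scan(
    table: FeatureTable,
    thresholds,
    scaling: str = "train",
) -> list[CvResult | None]:
    """One LOOCV pass evaluated at every threshold simultaneously.

    Scaling and t statistics are computed once per fold and reused across
    thresholds; MLDA fits are cached per distinct selection set. Returns one
    CvResult per threshold, or None where every fold was untrainable.
    """
    thresholds = [float(t) for t in thresholds]
    y = table.labels
    n = table.n_subjects
    if n < 4:
        raise ValueError("LOOCV needs at least 4 subjects")
    if min(int((y == 1).sum()), int((y == 0).sum())) < 2:
        raise ValueError("each class needs at least 2 subjects")
    if scaling not in ("train", "pooled"):
        raise ValueError("scaling must be 'train' or 'pooled'")
    blocks = table.modality_blocks()
    pooled_scaler = zscore_fit(table.matrix) if scaling == "pooled" else None

    n_thr = len(thresholds)
    preds = np.zeros((n_thr, n), dtype=int)
    scores = np.zeros((n_thr, n))
    folds: list[list[dict[str, FoldModality] | None]] = [
        [None] * n for _ in range(n_thr)
    ]
    abstain_counts = [0] * n_thr

    for i in range(n):
        train_mask = np.ones(n, dtype=bool)
        train_mask[i] = False
        x_train = table.matrix[train_mask]
        y_train = y[train_mask]
        scaler = pooled_scaler if pooled_scaler is not None else zscore_fit(x_train)
        xs_train = scaler.apply(x_train)
        xs_test = scaler.apply(table.matrix[i:i + 1])
        kb = _kept_blocks(blocks, scaler.kept)
        t_stats, p_vals = feature_t_tests(xs_train, y_train)
        cache: dict = {}
        for k, thr in enumerate(thresholds):
            selected = {m: pos[p_vals[pos] <= thr] for m, pos in kb.items()}
            selection = SelectionResult(
                thr, t_stats, p_vals, selected,
                {m: scaler.kept[s] for m, s in selected.items()},
            )
            try:
                models, weights = _fit_bases(xs_train, y_train, selection, cache)
            except UntrainableError:
                # every modality abstains: the fused vote score is 0, which
                # the tie rule maps to HC
                abstain_counts[k] += 1
                preds[k, i] = 0
                scores[k, i] = 0.0
                folds[k][i] = {
                    mod: FoldModality(np.empty(0, dtype=int), np.empty(0), 0.0)
                    for mod in blocks
                }
                continue
            score = 0.0
            fold_record: dict[str, FoldModality] = {}
            for mod in blocks:
                base = models.get(mod)
                w = weights.get(mod, 0.0)
                if base is None:
                    fold_record[mod] = FoldModality(
                        np.empty(0, dtype=int), np.empty(0), 0.0
                    )
                    continue
                sel = selection.selected[mod]
                pred, _ = predict_mlda(base, xs_test[:, sel])
                score += w * (2 * int(pred[0]) - 1)
                fold_record[mod] = FoldModality(
                    selection.selected_original[mod], base.weights.copy(), w
                )
            preds[k, i] = 1 if score > 0 else 0
            scores[k, i] = score
            folds[k][i] = fold_record

    results: list[CvResult | None] = []
    for k, thr in enumerate(thresholds):
        if abstain_counts[k] == n:
            results.append(None)
            continue
        if abstain_counts[k]:
            logger.info(
                "LOOCV at P <= %g: %d of %d folds had all modalities abstain",
                thr, abstain_counts[k], n,
            )
        results.append(
            CvResult(
                y_true=y.copy(),
                y_pred=preds[k],
                vote_scores=scores[k],
                folds=[f for f in folds[k]],  # type: ignore[misc]
                p_threshold=thr,
                feature_index=list(table.feature_index),
                modalities=list(blocks),
                subject_ids=list(table.subject_ids),
            )
        )
    return results


def loocv_evaluate(
    table: FeatureTable, p_threshold: float, scaling: str = "train"
) -> tuple[CvResult, PerformanceSummary]:
    """Leave-one-out cross-validation of the fused classifier at one threshold."""
    (cv,) = _loocv_scan(table, [p_threshold], scaling)
    if cv is None:
        raise UntrainableError(
            f"every modality selection empty at P <= {p_threshold} in every fold"
        )
    return cv, PerformanceSummary.from_cv(cv)


def grid_search_threshold(
    table: FeatureTable,
    grid=None,
    scaling: str = "train",
) -> tuple[PerformanceSummary, pd.DataFrame, CvResult]:
    """Pick the selection threshold with the highest LOOCV accuracy.

    Runs LOOCV at every grid value (default 0.001..0.050, step 0.001) and
    returns the summary at the argmax-accuracy threshold (ties broken toward
    the smallest threshold), the full accuracy-vs-threshold curve, and the
    winning CvResult.
    """
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("threshold grid is empty")
    if np.any((grid <= 0) | (grid >= 1)):
        raise ValueError("grid values must lie in (0, 1)")
    order = np.argsort(grid, kind="stable")
    sorted_grid = grid[order]
    results = _loocv_scan(table, sorted_grid, scaling)
    rows = []
    best_idx = None
    best_acc = -np.inf
    for k, (thr, cv) in enumerate(zip(sorted_grid, results)):
        acc = np.nan
        if cv is not None:
            acc = float((cv.y_pred == cv.y_true).mean())
            if acc > best_acc:  # ties keep the earlier (smaller) threshold
                best_acc = acc
                best_idx = k
        rows.append({"p_threshold": float(thr), "accuracy": acc})
    if best_idx is None:
        raise UntrainableError("no threshold in the grid was trainable")
    curve = pd.DataFrame(rows)
    best_cv = results[best_idx]
    assert best_cv is not None
    summary = PerformanceSummary.from_cv(
        best_cv, optimal_p_threshold=float(sorted_grid[best_idx])
    )
    return summary, curve, best_cv


# ---------------------------------------------------------------------------
# feature weights


@dataclass
class FeatureWeightReport:
    """Fold-aggregated discriminative weight per region.

    region_weights covers every region; table is restricted to regions whose
    feature was selected in every LOOCV fold for at least one modality (the
    "most discriminative" set), sorted by descending weight, with the
    full-sample t and P per modality alongside.
    """

    region_weights: pd.Series
    per_modality_weights: pd.DataFrame
    table: pd.DataFrame
    p_threshold: float


def compute_feature_weights(
    cv: CvResult, table: FeatureTable | None = None
) -> FeatureWeightReport:
    """Aggregate base-classifier coefficients into region-level weights.

    Per base classifier and fold, coefficients are normalized by the maximum
    absolute coefficient, taken in absolute value, and multiplied by that
    fold's voting weight (unselected features contribute 0); the per-fold
    values are averaged over all folds, and the five per-modality weights
    are summed per region. The reported set is restricted to regions that
    appeared in each fold for at least one modality.
    """
    if cv.n_folds == 0:
        raise ValueError("empty CvResult")
    n_feat = len(cv.feature_index)
    acc = {mod: np.zeros(n_feat) for mod in cv.modalities}
    in_all = {mod: np.ones(n_feat, dtype=bool) for mod in cv.modalities}
    for fold in cv.folds:
        for mod in cv.modalities:
            fm = fold[mod]
            mask = np.zeros(n_feat, dtype=bool)
            if fm.selected.size:
                mask[fm.selected] = True
                norm = np.abs(fm.coef).max()
                if norm > 0:
                    acc[mod][fm.selected] += (
                        np.abs(fm.coef) / norm * fm.voting_weight
                    )
            in_all[mod] &= mask
    for mod in cv.modalities:
        acc[mod] /= cv.n_folds

    regions = sorted({lab for _, lab, _ in cv.feature_index})
    names = {lab: name for _, lab, name in cv.feature_index}
    col_of = {(mod, lab): j for j, (mod, lab, _) in enumerate(cv.feature_index)}
    per_mod = pd.DataFrame(
        {
            mod: [acc[mod][col_of[(mod, lab)]] if (mod, lab) in col_of else 0.0
                  for lab in regions]
            for mod in cv.modalities
        },
        index=[names[lab] for lab in regions],
    )
    region_weights = per_mod.sum(axis=1)

    qualifying = []
    for lab in regions:
        if any(
            (mod, lab) in col_of and in_all[mod][col_of[(mod, lab)]]
            for mod in cv.modalities
        ):
            qualifying.append(lab)

    t_full = p_full = None
    if table is not None:
        t_full, p_full = feature_t_tests(table.matrix, table.labels)
    rows = []
    for lab in qualifying:
        row: dict = {"region": names[lab], "weight": region_weights[names[lab]]}
        for mod in cv.modalities:
            j = col_of.get((mod, lab))
            if t_full is not None and j is not None:
                row[f"{mod}_t"] = t_full[j]
                row[f"{mod}_p"] = p_full[j]
            row[f"{mod}_in_every_fold"] = bool(
                j is not None and in_all[mod][j]
            )
        rows.append(row)
    tab = pd.DataFrame(rows)
    if not tab.empty:
        tab = tab.sort_values("weight", ascending=False).reset_index(drop=True)
    return FeatureWeightReport(
        region_weights.sort_values(ascending=False),
        per_mod,
        tab,
        cv.p_threshold,
    )
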