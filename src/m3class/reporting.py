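"""Experiment orchestration and paper-shaped outputs.

An experiment arm is one (atlas, GSR on/off) preprocessing variant with its
own feature table; run_experiment grid-searches each arm, optionally runs
the accuracy permutation test, and compares arms pairwise with the DeLong
test on their LOOCV vote scores. Output shapes follow the conventional
summary tables of this literature: one performance row per arm (optimal P
threshold, AUC, accuracy/sensitivity/specificity in percent) and a
top-k discriminative-region table with per-modality t (P) entries.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .feature_extraction import FeatureTable
from .pipeline import (
    CvResult,
    FeatureWeightReport,
    PerformanceSummary,
    compute_feature_weights,
    grid_search_threshold,
)
from .stats import delong_test, permutation_test_accuracy

logger = logging.getLogger(__name__)


@dataclass
class ExperimentArm:
    """One preprocessing variant: a parcellation plus the GSR flag."""

    atlas_id: str
    gsr: bool

    @property
    def label(self) -> str:
        return f"{self.atlas_id}_{'GSR' if self.gsr else 'noGSR'}"


@dataclass
class ArmResult:
    arm: ExperimentArm
    summary: PerformanceSummary
    curve: pd.DataFrame
    cv: CvResult
    weights: FeatureWeightReport
    permutation_p: float | None = None


@dataclass
class RunManifest:
    """Everything needed to rerun an experiment to identical outputs."""

    seed: int
    grid: list[float]
    n_perm: int | None
    arms: list[str]
    started: float = field(default_factory=time.time)
    outputs: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        from . import __version__

        return json.dumps(
            {
                "version": __version__,
                "seed": self.seed,
                "grid": self.grid,
                "n_perm": self.n_perm,
                "arms": self.arms,
                "started": self.started,
                "outputs": self.outputs,
            },
            indent=2,
        )


def run_experiment(
    arms: list[ExperimentArm],
    tables: dict[str, FeatureTable],
    grid=None,
    n_perm: int | None = None,
    seed: int = 0,
) -> tuple[list[ArmResult], pd.DataFrame, pd.DataFrame, RunManifest]:
    """Grid-search every arm and compare arms pairwise with the DeLong test.

    tables maps arm label to its feature table; paired arms must share the
    same subjects (ids and order). Randomness (the permutation test) derives
    per-arm seeds deterministically from the root seed. Returns the per-arm
    results, a performance table, a pairwise DeLong table, and the manifest.
    """
    if not arms:
        raise ValueError("need at least one arm")
    results: list[ArmResult] = []
    for k, arm in enumerate(arms):
        table = tables[arm.label]
        summary, curve, cv = grid_search_threshold(table, grid)
        weights = compute_feature_weights(cv, table)
        perm_p = None
        if n_perm:
            perm = permutation_test_accuracy(
                table,
                p_threshold=summary.optimal_p_threshold,
                n_perm=n_perm,
                seed=seed * 1000 + k,
            )
            perm_p = perm.p_value
        results.append(ArmResult(arm, summary, curve, cv, weights, perm_p))
        logger.info("arm %s: accuracy %.4f at P <= %g", arm.label,
                    summary.accuracy, summary.optimal_p_threshold)

    perf = performance_table(results)

    pairs = []
    for i in range(len(results)):
        for j in range(i + 1, len(results)):
            a, b = results[i], results[j]
            if a.cv.subject_ids != b.cv.subject_ids:
                raise ValueError(
                    f"arms {a.arm.label} and {b.arm.label} have different "
                    "subjects; DeLong comparison requires paired scores"
                )
            cmp = delong_test(a.cv.vote_scores, b.cv.vote_scores, a.cv.y_true)
            pairs.append(
                {
                    "arm1": a.arm.label,
                    "arm2": b.arm.label,
                    "auc1": cmp.auc1,
                    "auc2": cmp.auc2,
                    "z": cmp.z,
                    "p_value": cmp.p_value,
                }
            )
    delong = pd.DataFrame(pairs)
    manifest = RunManifest(
        seed=seed,
        grid=[float(g) for g in (grid if grid is not None else
                                 np.round(np.arange(1, 51) * 0.001, 3))],
        n_perm=n_perm,
        arms=[a.label for a in arms],
    )
    return results, perf, delong, manifest


def performance_table(results: list[ArmResult]) -> pd.DataFrame:
    """One row per arm: optimal P threshold, AUC, accuracy/sens/spec in %."""
    rows = []
    for r in results:
        row = {
            "arm": r.arm.label,
            "optimal_p_threshold": r.summary.optimal_p_threshold,
            "auc": r.summary.auc,
            "accuracy_pct": 100 * r.summary.accuracy,
            "sensitivity_pct": 100 * r.summary.sensitivity,
            "specificity_pct": 100 * r.summary.specificity,
        }
        if r.permutation_p is not None:
            row["permutation_p"] = r.permutation_p
        rows.append(row)
    return pd.DataFrame(rows)


def report_discriminative_regions(
    report: FeatureWeightReport, top_k: int = 15
) -> pd.DataFrame:
    """Top-k regions by weight with per-modality "t (P)" cells.

    A modality whose full-sample P exceeds the optimal selection threshold
    shows "NS"; rows are sorted by descending weight.
    """
    if report.table.empty:
        raise ValueError("feature-weight report is empty")
    tab = report.table
    if top_k > len(tab):
        logger.warning("top_k=%d exceeds %d available regions", top_k, len(tab))
        top_k = len(tab)
    mods = [c[:-2] for c in tab.columns if c.endswith("_t")]
    rows = []
    for _, r in tab.head(top_k).iterrows():
        row = {"region": r["region"]}
        for mod in mods:
            t, p = r.get(f"{mod}_t"), r.get(f"{mod}_p")
            if t is None or p is None or p > report.p_threshold:
                row[mod] = "NS"
            else:
                row[mod] = f"t = {t:.2f} (P = {p:.4f})"
        row["weight"] = round(float(r["weight"]), 4)
        rows.append(row)
    return pd.DataFrame(rows)


def write_arm_outputs(result: ArmResult, out_dir: str | Path) -> dict[str, str]:
    """Write the performance JSON, accuracy curve, feature weights, and
    per-subject ROC points for one arm."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    label = result.arm.label
    paths = {}

    perf_path = out / f"{label}_performance.json"
    perf_path.write_text(
        json.dumps(
            {
                "arm": label,
                "optimal_p_threshold": result.summary.optimal_p_threshold,
                "auc": result.summary.auc,
                "accuracy_pct": 100 * result.summary.accuracy,
                "sensitivity_pct": 100 * result.summary.sensitivity,
                "specificity_pct": 100 * result.summary.specificity,
                "permutation_p": result.permutation_p,
            },
            indent=2,
        )
    )
    paths["performance"] = str(perf_path)

    curve_path = out / f"{label}_accuracy_curve.tsv"
    result.curve.to_csv(curve_path, sep="\t", index=False)
    paths["accuracy_curve"] = str(curve_path)

    weights_path = out / f"{label}_feature_weights.tsv"
    result.weights.table.to_csv(weights_path, sep="\t", index=False,
                                float_format="%.6g")
    paths["feature_weights"] = str(weights_path)

    roc_path = out / f"{label}_roc_points.tsv"
    pd.DataFrame(
        {
            "subject_id": result.cv.subject_ids,
            "vote_score": result.cv.vote_scores,
            "label": result.cv.y_true,
        }
    ).to_csv(roc_path, sep="\t", index=False)
    paths["roc_points"] = str(roc_path)
    return paths
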