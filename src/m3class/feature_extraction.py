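"""Atlas ROI feature extraction and the subject x (region, modality) table.

Voxelwise metric maps are reduced to one value per (modality, region) by
averaging over the voxels carrying each atlas label; per-subject vectors are
stacked into a FeatureTable, the unit the whole classification pipeline
operates on. Feature ordering is modality-major with regions in ascending
label order, so column identity is stable across subjects and runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .fmri_metrics import MetricMap


@dataclass
class Atlas:
    """Integer-label parcellation volume plus a label -> region-name table."""

    labels: np.ndarray
    names: dict[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integers")
        if self.labels.min() < 0:
            raise ValueError("atlas labels must be nonnegative")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.names)
        if missing:
            raise ValueError(f"labels without names: {sorted(missing)}")

    @property
    def region_labels(self) -> list[int]:
        return sorted(set(np.unique(self.labels)) - {0})

    @property
    def n_regions(self) -> int:
        return len(self.region_labels)

    @classmethod
    def from_files(cls, label_path: str | Path, lut_path: str | Path) -> "Atlas":
        """Load from a NIfTI label image and a two-column TSV (label, name)."""
        img = nib.load(str(label_path))
        labels = np.asarray(img.dataobj).round().astype(int)
        lut = pd.read_csv(lut_path, sep="\t")
        names = dict(zip(lut.iloc[:, 0].astype(int), lut.iloc[:, 1].astype(str)))
        return cls(labels, names)

    def to_files(self, label_path: str | Path, lut_path: str | Path,
                 affine: np.ndarray | None = None) -> None:
        if affine is None:
            affine = np.eye(4)
        nib.save(nib.Nifti1Image(self.labels.astype(np.int16), affine),
                 str(label_path))
        pd.DataFrame(
            {"label": self.region_labels,
             "name": [self.names[l] for l in self.region_labels]}
        ).to_csv(lut_path, sep="\t", index=False)


@dataclass
class FeatureTable:
    """Subjects x (modality, region) matrix with binary group labels (SZ=1)."""

    matrix: np.ndarray
    feature_index: list[tuple[str, int, str]]  # (modality, region_label, name)
    labels: np.ndarray
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2D")
        if self.matrix.shape != (len(self.subject_ids), len(self.feature_index)):
            raise ValueError("matrix shape inconsistent with ids/feature index")
        if np.isnan(self.matrix).any():
            raise ValueError("feature table contains missing values")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be coded SZ=1 / HC=0")

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    @property
    def modalities(self) -> list[str]:
        seen: list[str] = []
        for mod, _, _ in self.feature_index:
            if mod not in seen:
                seen.append(mod)
        return seen

    def modality_blocks(self) -> dict[str, np.ndarray]:
        """Column indices of each modality block."""
        blocks: dict[str, list[int]] = {}
        for j, (mod, _, _) in enumerate(self.feature_index):
            blocks.setdefault(mod, []).append(j)
        return {m: np.asarray(ix) for m, ix in blocks.items()}

    def column_names(self) -> list[str]:
        return [f"{mod}__{name}" for mod, _, name in self.feature_index]

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.matrix, columns=self.column_names())
        df.insert(0, "group", self.labels)
        df.insert(0, "subject_id", self.subject_ids)
        df.to_csv(path, sep="\t", index=False, float_format="%.12g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureTable":
        df = pd.read_csv(path, sep="\t")
        ids = df["subject_id"].astype(str).tolist()
        labels = df["group"].to_numpy()
        feat_cols = [c for c in df.columns if c not in ("subject_id", "group")]
        index: list[tuple[str, int, str]] = []
        counters: dict[str, int] = {}
        for col in feat_cols:
            mod, _, name = col.partition("__")
            counters[mod] = counters.get(mod, 0) + 1
            index.append((mod, counters[mod], name))
        return cls(df[feat_cols].to_numpy(float), index, labels, ids)


def extract_roi_features(
    maps: list[MetricMap], atlas: Atlas, mask: np.ndarray | None = None
) -> tuple[np.ndarray, list[tuple[str, int, str]]]:
    """Mean map value per (modality, region): one subject's feature vector.

    Voxels with label > 0 but outside the analysis mask are excluded from the
    mean. A region with no contributing voxels in any map is an error (no
    silent fill).
    """
    region_labels = atlas.region_labels
    if mask is None:
        mask = np.ones(atlas.labels.shape, dtype=bool)
    eff_labels = np.where(mask, atlas.labels, 0)
    counts = np.bincount(eff_labels.ravel(), minlength=max(region_labels) + 1)
    empty = [l for l in region_labels if counts[l] == 0]
    if empty:
        names = [atlas.names[l] for l in empty]
        raise ValueError(f"regions with no in-mask voxels: {names}")
    values: list[float] = []
    index: list[tuple[str, int, str]] = []
    flat_labels = eff_labels.ravel()
    for m in maps:
        if m.values.shape != atlas.labels.shape:
            raise ValueError(
                f"map {m.metric_name} shape {m.values.shape} does not match "
                f"atlas shape {atlas.labels.shape}"
            )
        sums = np.bincount(flat_labels, weights=m.values.ravel(),
                           minlength=max(region_labels) + 1)
        for l in region_labels:
            values.append(sums[l] / counts[l])
            index.append((m.metric_name, l, atlas.names[l]))
    return np.asarray(values), index


def assemble_feature_table(
    vectors: list[tuple[np.ndarray, list[tuple[str, int, str]]]],
    labels,
    subject_ids: list[str],
) -> FeatureTable:
    """Stack per-subject (vector, feature_index) pairs into a FeatureTable.

    All subjects must share an identical feature index; the first divergent
    feature is named in the error.
    """
    if not vectors:
        raise ValueError("no subjects given")
    _, ref_index = vectors[0]
    for sid, (_, index) in zip(subject_ids, vectors):
        if index != ref_index:
            for a, b in zip(index, ref_index):
                if a != b:
                    raise ValueError(
                        f"feature index mismatch for subject {sid}: "
                        f"{a} vs {b}"
                    )
            raise ValueError(f"feature index length mismatch for subject {sid}")
    matrix = np.vstack([v for v, _ in vectors])
    return FeatureTable(matrix, list(ref_index), np.asarray(labels), subject_ids)
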