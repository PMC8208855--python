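"""Synthetic cohorts, images and demographics for the M3 pipeline.

Everything the pipeline consumes can be generated here with a known ground
truth: feature tables with planted group effects (two-group cohorts such as
45 patients / 64 controls over five modality blocks), small 4D time-series
volumes with a toy atlas, motion covariates and known spectral content for
the voxelwise metric module, and demographics tables whose summary
statistics are moment-matched exactly.

Features are multivariate normal per modality with exchangeable correlation;
group effects are mean shifts on standardized columns, so Cohen's d is the
single effect parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .feature_extraction import Atlas, FeatureTable
from .fmri_metrics import TimeSeriesImage

MODALITIES = ("ALFF", "ReHo", "DC", "VMHC", "GMD")


class ConfigurationError(ValueError):
    """An invalid generator configuration; the message names the field."""


@dataclass(frozen=True)
class CohortConfig:
    """Two-group cohort layout with planted per-(region, modality) effects.

    effect_map triples are (region_label, modality, cohens_d) with region
    labels 1-based; within_modality_corr is the exchangeable correlation of
    features inside one modality block; noise_sd scales every column's
    marginal SD.
    """

    n_patients: int = 45
    n_controls: int = 64
    n_regions: int = 246
    modalities: tuple[str, ...] = MODALITIES
    effect_map: tuple[tuple[int, str, float], ...] = ()
    within_modality_corr: float = 0.2
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ConfigurationError("n_patients must be >= 2")
        if self.n_controls < 2:
            raise ConfigurationError("n_controls must be >= 2")
        if self.n_regions < 1:
            raise ConfigurationError("n_regions must be >= 1")
        if not self.modalities:
            raise ConfigurationError("modalities must be nonempty")
        if not 0 <= self.within_modality_corr < 1:
            raise ConfigurationError("within_modality_corr must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        for region, mod, d in self.effect_map:
            if not 1 <= region <= self.n_regions:
                raise ConfigurationError(
                    f"effect_map region {region} outside 1..{self.n_regions}"
                )
            if mod not in self.modalities:
                raise ConfigurationError(f"effect_map modality {mod!r} unknown")
            if not np.isfinite(d):
                raise ConfigurationError("effect_map cohens_d must be finite")


@dataclass(frozen=True)
class ImageSimConfig:
    """Small 4D volume with a toy atlas and per-tissue-class sinusoidal signal.

    signal_bands assigns (freq_hz, amplitude) pairs to atlas labels in
    cycling order; symmetric=True builds the atlas and noise-free signal
    mirror-symmetric across the x axis (x-extent must be even).
    """

    grid_shape: tuple[int, int, int] = (16, 16, 10)
    n_volumes: int = 60
    tr_seconds: float = 2.0
    n_atlas_labels: int = 10
    signal_bands: tuple[tuple[float, float], ...] = ((0.05, 1.0), (0.03, 1.0))
    motion_amplitude: float = 0.5
    symmetric: bool = True
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if len(self.grid_shape) != 3 or min(self.grid_shape) < 3:
            raise ConfigurationError("grid_shape must be 3 extents >= 3")
        if self.symmetric and self.grid_shape[0] % 2 != 0:
            raise ConfigurationError(
                "grid_shape x-extent must be even when symmetric=True"
            )
        if self.n_volumes <= 10:
            raise ConfigurationError("n_volumes must be > 10")
        if self.tr_seconds <= 0:
            raise ConfigurationError("tr_seconds must be positive")
        if self.n_atlas_labels < 1:
            raise ConfigurationError("n_atlas_labels must be >= 1")
        if not self.signal_bands:
            raise ConfigurationError("signal_bands must be nonempty")
        nyq = 1.0 / (2.0 * self.tr_seconds)
        for f, _ in self.signal_bands:
            if not 0 < f <= nyq:
                raise ConfigurationError(
                    f"signal_bands frequency {f} outside (0, Nyquist={nyq:.4g}]"
                )
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")


@dataclass
class GroundTruth:
    """Planted effects and the feature columns they occupy."""

    effect_map: tuple[tuple[int, str, float], ...]
    effect_columns: dict[tuple[int, str], int] = field(default_factory=dict)

    @property
    def signal_regions(self) -> list[int]:
        return sorted({region for region, _, _ in self.effect_map})


def region_name(label: int) -> str:
    return f"R{label:03d}"


def gen_feature_table(config: CohortConfig) -> tuple[FeatureTable, GroundTruth]:
    """Generate a cohort feature table with planted group mean shifts.

    Each modality block is multivariate normal with exchangeable correlation
    rho (one shared latent factor per subject per modality); a planted
    (region, modality, d) triple shifts the patient group by d marginal SDs
    on that column. Identical config (including seed) gives an identical
    table.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients + config.n_controls
    r = config.n_regions
    rho = config.within_modality_corr
    is_patient = np.zeros(n, dtype=bool)
    is_patient[: config.n_patients] = True

    blocks = []
    index: list[tuple[str, int, str]] = []
    for mod in config.modalities:
        shared = rng.standard_normal((n, 1))
        eps = rng.standard_normal((n, r))
        block = (np.sqrt(rho) * shared + np.sqrt(1 - rho) * eps) * config.noise_sd
        blocks.append(block)
        index.extend((mod, lab, region_name(lab)) for lab in range(1, r + 1))
    matrix = np.hstack(blocks)

    truth = GroundTruth(tuple(config.effect_map))
    col_of = {(mod, lab): j for j, (mod, lab, _) in enumerate(index)}
    for region, mod, d in config.effect_map:
        j = col_of[(mod, region)]
        matrix[is_patient, j] += d * config.noise_sd
        truth.effect_columns[(region, mod)] = j

    ids = [f"SZ{i + 1:03d}" for i in range(config.n_patients)] + [
        f"HC{i + 1:03d}" for i in range(config.n_controls)
    ]
    labels = is_patient.astype(int)
    return FeatureTable(matrix, index, labels, ids), truth


def random_effect_map(
    n_signal_regions: int,
    d_range: tuple[float, float],
    n_regions: int = 246,
    modalities: tuple[str, ...] = MODALITIES,
    modalities_per_region: tuple[int, int] = (2, 4),
    seed: int = 0,
) -> tuple[tuple[int, str, float], ...]:
    """Draw a plausible effect map: a few regions, each hit in 2-4 modalities."""
    rng = np.random.default_rng(seed)
    regions = rng.choice(np.arange(1, n_regions + 1), size=n_signal_regions,
                         replace=False)
    triples = []
    lo, hi = modalities_per_region
    for region in sorted(int(r) for r in regions):
        k = int(rng.integers(lo, hi + 1))
        mods = rng.choice(len(modalities), size=k, replace=False)
        for m in sorted(mods):
            d = float(rng.uniform(*d_range)) * (1 if rng.random() < 0.5 else -1)
            triples.append((region, modalities[m], d))
    return tuple(triples)


def _toy_atlas(config: ImageSimConfig, mask: np.ndarray) -> Atlas:
    """Tile the mask with n_atlas_labels labels, mirror-symmetric in x."""
    nx = config.grid_shape[0]
    xs, ys, zs = np.nonzero(mask)
    # mirror pairs share a key so they always share a label
    keys = np.stack([np.minimum(xs, nx - 1 - xs), ys, zs], axis=1)
    order = np.lexsort((keys[:, 0], keys[:, 1], keys[:, 2]))
    labels = np.zeros(config.grid_shape, dtype=np.int16)
    chunks = np.array_split(order, config.n_atlas_labels)
    for lab, chunk in enumerate(chunks, start=1):
        labels[xs[chunk], ys[chunk], zs[chunk]] = lab
    names = {lab: region_name(lab) for lab in range(1, config.n_atlas_labels + 1)}
    return Atlas(labels, names)


def gen_timeseries_image(
    config: ImageSimConfig,
) -> tuple[TimeSeriesImage, Atlas, np.ndarray]:
    """Generate a 4D series with known spectral content, a toy atlas, and
    motion parameters.

    Every atlas label carries a sinusoid at one of the configured
    (freq_hz, amplitude) bands (cycling); mirror-paired voxels share a label
    and hence an identical noise-free signal when symmetric=True. Motion
    parameters are smooth random walks rescaled to motion_amplitude.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    shape = config.grid_shape
    mask = np.zeros(shape, dtype=bool)
    mask[1:-1, 1:-1, 1:-1] = True

    atlas = _toy_atlas(config, mask)
    t = np.arange(config.n_volumes) * config.tr_seconds
    data = np.zeros(shape + (config.n_volumes,))
    for lab in atlas.region_labels:
        freq, amp = config.signal_bands[(lab - 1) % len(config.signal_bands)]
        phase = rng.uniform(0, 2 * np.pi)
        sig = amp * np.sin(2 * np.pi * freq * t + phase)
        data[atlas.labels == lab] = sig
    if config.noise_sd > 0:
        data[mask] += config.noise_sd * rng.standard_normal(
            (int(mask.sum()), config.n_volumes)
        )
    img = TimeSeriesImage(data, config.tr_seconds, mask)

    walk = np.cumsum(rng.standard_normal((config.n_volumes, 6)), axis=0)
    walk -= walk.mean(axis=0)
    peak = np.abs(walk).max(axis=0)
    peak[peak == 0] = 1.0
    motion = walk / peak * config.motion_amplitude
    return img, atlas, motion


def gen_demographics(
    n1: int,
    n2: int,
    sex_split: tuple[tuple[int, int], tuple[int, int]] = ((36, 9), (44, 20)),
    age_params: tuple[tuple[float, float], tuple[float, float]] = (
        (37.42, 13.55),
        (35.22, 11.40),
    ),
    seed: int = 0,
) -> pd.DataFrame:
    """Per-subject demographics with exactly moment-matched group ages.

    sex_split gives (male, female) counts per group; ages are drawn normal
    then affinely rescaled so each group's sample mean and SD (ddof=1) equal
    the requested (mean, sd) exactly, which makes summary statistics such as
    the two-sample t reproducible deterministically.
    """
    for n, (m, f), which in ((n1, sex_split[0], "group 1"),
                             (n2, sex_split[1], "group 2")):
        if m < 0 or f < 0 or m + f != n:
            raise ConfigurationError(
                f"sex_split for {which} ({m}/{f}) inconsistent with n={n}"
            )
    rng = np.random.default_rng(seed)
    rows = []
    for group, n, (males, _), (mean, sd), prefix in (
        (1, n1, sex_split[0], age_params[0], "SZ"),
        (0, n2, sex_split[1], age_params[1], "HC"),
    ):
        ages = rng.standard_normal(n)
        ages = (ages - ages.mean()) / ages.std(ddof=1) * sd + mean
        for i in range(n):
            rows.append(
                {
                    "subject_id": f"{prefix}{i + 1:03d}",
                    "group": group,
                    "sex": "M" if i < males else "F",
                    "age": ages[i],
                }
            )
    return pd.DataFrame(rows)
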