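"""Voxelwise resting-state functional metrics.

Implements the standard per-voxel maps used in resting-state discriminative
studies: nuisance regression (24-parameter motion expansion, WM/CSF signals,
linear drift, optional global signal regression), ideal band-pass filtering,
ALFF (amplitude of low-frequency fluctuations), ReHo (Kendall's coefficient
of concordance over a voxel neighborhood), degree centrality with an r
threshold, and voxel-mirrored homotopic connectivity, plus map
standardization and Gaussian smoothing.

The intended order of operations mirrors common preprocessing pipelines:
nuisance regression first, then band-pass filtering; ALFF is computed from
the *unfiltered* (but nuisance-regressed) series, while ReHo and DC consume
the band-passed series; ReHo is computed before any smoothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, stats

logger = logging.getLogger(__name__)

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class TimeSeriesImage:
    """A 4D voxel time-series volume with its repetition time and brain mask.

    data has shape (x, y, z, t); mask is a 3D boolean array over (x, y, z).
    """

    data: np.ndarray
    tr_seconds: float
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 4:
            raise ValueError("data must be 4D (x, y, z, t)")
        if self.data.shape[3] < 2:
            raise ValueError("need at least 2 time points")
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape must equal spatial shape of data")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if not np.all(np.isfinite(self.data[self.mask])):
            raise ValueError("non-finite values inside mask")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def nyquist_hz(self) -> float:
        return 1.0 / (2.0 * self.tr_seconds)


@dataclass
class MetricMap:
    """A 3D voxelwise metric map (ALFF, ReHo, DC, VMHC or GMD)."""

    values: np.ndarray
    metric_name: str
    standardized: bool = False
    smoothing_fwhm_mm: float = 0.0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("metric map must be 3D")


@dataclass
class NuisanceSet:
    """Per-volume nuisance covariates.

    motion is the 24-column Friston expansion [p, p^2, p_{t-1}, p_{t-1}^2]
    of the six rigid-body parameters; wm/csf are tissue mean signals;
    linear_drift is a ramp; global_signal is optional (GSR).
    """

    motion: np.ndarray | None = None
    wm_signal: np.ndarray | None = None
    csf_signal: np.ndarray | None = None
    linear_drift: np.ndarray | None = None
    global_signal: np.ndarray | None = None

    def design_columns(self, include_gsr: bool) -> np.ndarray | None:
        cols = []
        if self.motion is not None:
            cols.append(np.atleast_2d(np.asarray(self.motion, dtype=float)))
        for sig in (self.wm_signal, self.csf_signal, self.linear_drift):
            if sig is not None:
                cols.append(np.asarray(sig, dtype=float).reshape(-1, 1))
        if include_gsr and self.global_signal is not None:
            cols.append(np.asarray(self.global_signal, dtype=float).reshape(-1, 1))
        if not cols:
            return None
        n_t = {c.shape[0] for c in cols}
        if len(n_t) != 1:
            raise ValueError("nuisance covariates have mismatched lengths")
        return np.hstack(cols)


def friston24(motion6: np.ndarray) -> np.ndarray:
    """Expand 6 rigid-body motion parameters to the 24-column Friston set.

    Columns are [p, p^2, p_{t-1}, p_{t-1}^2]; the lagged terms use zero for
    the first volume.
    """
    motion6 = np.asarray(motion6, dtype=float)
    if motion6.ndim != 2 or motion6.shape[1] != 6:
        raise ValueError("expected a (t, 6) motion-parameter array")
    lagged = np.vstack([np.zeros((1, 6)), motion6[:-1]])
    return np.hstack([motion6, motion6**2, lagged, lagged**2])


def make_nuisance_set(
    motion6: np.ndarray | None = None,
    wm_signal: np.ndarray | None = None,
    csf_signal: np.ndarray | None = None,
    n_timepoints: int | None = None,
    img: TimeSeriesImage | None = None,
) -> NuisanceSet:
    """Assemble a NuisanceSet, deriving the drift ramp and global signal.

    The linear drift covariate is a centered ramp over volumes. If img is
    given, the global signal is the mean in-mask time series.
    """
    if n_timepoints is None:
        if img is None:
            raise ValueError("need n_timepoints or img")
        n_timepoints = img.n_volumes
    drift = np.linspace(-1.0, 1.0, n_timepoints)
    gs = None
    if img is not None:
        gs = img.data[img.mask].mean(axis=0)
    motion = friston24(motion6) if motion6 is not None else None
    return NuisanceSet(
        motion=motion,
        wm_signal=wm_signal,
        csf_signal=csf_signal,
        linear_drift=drift,
        global_signal=gs,
    )


def regress_nuisance(
    img: TimeSeriesImage, nuis: NuisanceSet, include_gsr: bool = False
) -> TimeSeriesImage:
    """Remove nuisance covariates by voxelwise multiple linear regression.

    Returns the least-squares residuals of each in-mask voxel series against
    [intercept | covariates]. With include_gsr=True the global signal column
    (computed from img if the set carries none) joins the design.
    """
    if include_gsr and nuis.global_signal is None:
        nuis = replace(nuis, global_signal=img.data[img.mask].mean(axis=0))
    cov = nuis.design_columns(include_gsr)
    n_t = img.n_volumes
    design = np.ones((n_t, 1))
    if cov is not None:
        if cov.shape[0] != n_t:
            raise ValueError(
                f"covariate length {cov.shape[0]} does not match {n_t} volumes"
            )
        design = np.hstack([design, cov])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        logger.warning(
            "rank-deficient nuisance design (rank %d < %d columns); "
            "using pseudoinverse solution",
            rank,
            design.shape[1],
        )
    y = img.data[img.mask].T  # (t, voxels)
    beta = np.linalg.lstsq(design, y, rcond=None)[0]
    resid = y - design @ beta
    out = np.zeros_like(img.data)
    out[img.mask] = resid.T
    return TimeSeriesImage(out, img.tr_seconds, img.mask)


def bandpass(img: TimeSeriesImage, low_hz: float, high_hz: float) -> TimeSeriesImage:
    """Ideal (rectangular FFT) band-pass filter along the time axis.

    Frequency bins with low_hz <= f <= high_hz are retained exactly; all
    other bins (including DC when low_hz > 0) are zeroed.
    """
    if not (0 <= low_hz < high_hz <= img.nyquist_hz + 1e-12):
        raise ValueError(
            f"band [{low_hz}, {high_hz}] outside [0, Nyquist={img.nyquist_hz:.4g}]"
        )
    n_t = img.n_volumes
    freqs = np.fft.rfftfreq(n_t, d=img.tr_seconds)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    spec = np.fft.rfft(img.data, axis=3)
    spec[..., ~keep] = 0.0
    data = np.fft.irfft(spec, n=n_t, axis=3)
    data[~img.mask] = 0.0
    return TimeSeriesImage(data, img.tr_seconds, img.mask)


def compute_alff(
    img: TimeSeriesImage, low_hz: float = 0.01, high_hz: float = 0.1
) -> MetricMap:
    """Amplitude of low-frequency fluctuations.

    Per voxel, the mean of the square-rooted power (amplitude) spectrum over
    [low_hz, high_hz]. Expects the unfiltered, nuisance-regressed series; a
    constant series yields 0 because the DC bin lies outside the band.
    """
    n_t = img.n_volumes
    freqs = np.fft.rfftfreq(n_t, d=img.tr_seconds)
    band = (freqs >= low_hz) & (freqs <= high_hz)
    if not band.any():
        raise ValueError("no frequency bins inside the requested band")
    spec = np.fft.rfft(img.data[img.mask], axis=-1)
    amp = 2.0 * np.abs(spec[:, band]) / n_t
    values = np.zeros(img.mask.shape)
    values[img.mask] = amp.mean(axis=-1)
    return MetricMap(values, "ALFF", params={"low_hz": low_hz, "high_hz": high_hz})


_NEIGHBORHOOD_OFFSETS = {
    7: [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if abs(dx) + abs(dy) + abs(dz) <= 1
    ],
    19: [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if abs(dx) + abs(dy) + abs(dz) <= 2
    ],
    27: [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
    ],
}


def _shift_sum(arr: np.ndarray, offsets, out_dtype=float) -> np.ndarray:
    """Sum arr over the given integer 3D offsets, zero-padding at edges.

    arr may be 3D or 4D (trailing time axis is carried along).
    """
    total = np.zeros(arr.shape, dtype=out_dtype)
    shape = arr.shape[:3]
    for dx, dy, dz in offsets:
        src = []
        dst = []
        for dim, d in zip(shape, (dx, dy, dz)):
            if d >= 0:
                src.append(slice(0, dim - d))
                dst.append(slice(d, dim))
            else:
                src.append(slice(-d, dim))
                dst.append(slice(0, dim + d))
        total[tuple(dst)] += arr[tuple(src)]
    return total


def compute_reho(img: TimeSeriesImage, neighborhood: int = 27) -> MetricMap:
    """Regional homogeneity: Kendall's coefficient of concordance W.

    For each in-mask voxel, W = 12 S / (K^2 (n^3 - n)) over the ranked time
    series of the K in-mask voxels of its neighborhood (the voxel itself
    included), with S the sum of squared deviations of per-timepoint rank
    sums from their mean and n the number of time points. Expects the
    band-passed series. Voxels with fewer than 2 in-mask neighbors get 0.
    """
    if neighborhood not in _NEIGHBORHOOD_OFFSETS:
        raise ValueError("neighborhood must be one of 7, 19, 27")
    offsets = _NEIGHBORHOOD_OFFSETS[neighborhood]
    n_t = img.n_volumes
    ranks = np.zeros_like(img.data)
    ranks[img.mask] = stats.rankdata(img.data[img.mask], axis=-1)
    maskf = img.mask.astype(float)
    rank_sums = _shift_sum(ranks * maskf[..., None], offsets)
    counts = _shift_sum(maskf, offsets)
    k = counts
    mean_rank_sum = k[..., None] * (n_t + 1) / 2.0
    s = ((rank_sums - mean_rank_sum) ** 2).sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = 12.0 * s / (k**2 * (n_t**3 - n_t))
    valid = img.mask & (k >= 2)
    n_degenerate = int((img.mask & ~valid).sum())
    if n_degenerate:
        logger.info("ReHo: %d in-mask voxels with < 2 in-mask neighbors set to 0",
                    n_degenerate)
    values = np.zeros(img.mask.shape)
    values[valid] = np.clip(w[valid], 0.0, 1.0)
    return MetricMap(values, "ReHo", params={"neighborhood": neighborhood})


def compute_dc(
    img: TimeSeriesImage, r_threshold: float = 0.25, weighted: bool = False
) -> MetricMap:
    """Degree centrality: suprathreshold connection count (or strength).

    Per in-mask voxel, the number of other in-mask voxels whose Pearson
    correlation with it exceeds r_threshold (strictly, one-sided); with
    weighted=True, the sum of those correlation values. Expects the
    band-passed series. Zero-variance voxels contribute r = 0.
    """
    x = img.data[img.mask]
    n_vox = x.shape[0]
    if n_vox < 2:
        raise ValueError("need at least 2 in-mask voxels for DC")
    xc = x - x.mean(axis=-1, keepdims=True)
    norm = np.sqrt((xc**2).sum(axis=-1))
    degenerate = norm <= 0
    if degenerate.any():
        logger.info("DC: %d zero-variance voxels treated as r=0",
                    int(degenerate.sum()))
        norm[degenerate] = 1.0
    xn = xc / norm[:, None]
    corr = xn @ xn.T
    corr[degenerate, :] = 0.0
    corr[:, degenerate] = 0.0
    np.fill_diagonal(corr, 0.0)
    above = corr > r_threshold
    dc = (corr * above).sum(axis=1) if weighted else above.sum(axis=1).astype(float)
    values = np.zeros(img.mask.shape)
    values[img.mask] = dc
    return MetricMap(
        values, "DC", params={"r_threshold": r_threshold, "weighted": weighted}
    )


def compute_vmhc(img: TimeSeriesImage) -> MetricMap:
    """Voxel-mirrored homotopic connectivity.

    Per voxel, the Pearson correlation of its time series with the series of
    its partner mirrored across the first spatial axis (x -> X-1-x on a
    0-based grid). The map is symmetric under the mirror by construction.
    Voxels whose partner falls outside the mask are excluded (value 0).
    """
    if img.data.shape[0] % 2 != 0:
        raise ValueError("VMHC requires an even extent along the mirror (x) axis")
    flipped = img.data[::-1]
    valid = img.mask & img.mask[::-1]
    n_excluded = int((img.mask & ~valid).sum())
    if n_excluded:
        logger.info("VMHC: %d voxels with out-of-mask mirror partner excluded",
                    n_excluded)
    a = img.data[valid]
    b = flipped[valid]
    ac = a - a.mean(axis=-1, keepdims=True)
    bc = b - b.mean(axis=-1, keepdims=True)
    denom = np.sqrt((ac**2).sum(axis=-1) * (bc**2).sum(axis=-1))
    zero = denom <= 0
    denom[zero] = 1.0
    r = (ac * bc).sum(axis=-1) / denom
    r[zero] = 0.0
    values = np.zeros(img.mask.shape)
    values[valid] = r
    return MetricMap(values, "VMHC")


def standardize_map(
    m: MetricMap, method: str, mask: np.ndarray | None = None
) -> MetricMap:
    """Standardize a metric map.

    method="fisher_z": atanh(r) for correlation-valued maps (VMHC), with |r|
    clamped to 1 - 1e-7. method="mean_sd_z": (x - mean)/SD computed within
    mask (the whole volume if mask is None) — the "zMap" convention for
    maps whose values are not correlations (ALFF, ReHo, DC).
    """
    values = m.values.copy()
    if mask is None:
        mask = np.ones(values.shape, dtype=bool)
    if method == "fisher_z":
        inside = values[mask]
        if np.any(np.abs(inside) > 1.0 + 1e-6):
            raise ValueError("fisher_z requires correlation values in [-1, 1]")
        clamped = np.clip(inside, -1.0 + 1e-7, 1.0 - 1e-7)
        values[mask] = np.arctanh(clamped)
    elif method == "mean_sd_z":
        inside = values[mask]
        sd = inside.std()
        if sd <= 0:
            raise ValueError("mean_sd_z undefined for a constant map")
        values[mask] = (inside - inside.mean()) / sd
    else:
        raise ValueError(f"unknown standardization method {method!r}")
    return MetricMap(
        values,
        m.metric_name,
        standardized=True,
        smoothing_fwhm_mm=m.smoothing_fwhm_mm,
        params={**m.params, "standardization": method},
    )


def smooth_gaussian(
    m: MetricMap, fwhm_mm: float, voxel_size_mm=(3.0, 3.0, 3.0)
) -> MetricMap:
    """Separable Gaussian smoothing with a kernel given as FWHM in mm.

    sigma per axis = fwhm / (2 sqrt(2 ln 2)) divided by that axis's voxel
    size; fwhm=0 returns the map unchanged.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be nonnegative")
    if fwhm_mm == 0:
        return MetricMap(
            m.values.copy(), m.metric_name, m.standardized, 0.0, dict(m.params)
        )
    sigma = [fwhm_mm * FWHM_TO_SIGMA / v for v in voxel_size_mm]
    # nearest-edge padding keeps constant maps exactly constant
    values = ndimage.gaussian_filter(m.values, sigma=sigma, mode="nearest")
    return MetricMap(values, m.metric_name, m.standardized, fwhm_mm, dict(m.params))
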