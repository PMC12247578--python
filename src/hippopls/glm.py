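"""First-level analysis: volume exclusion, smoothing, motion QC,
design-matrix construction, voxelwise OLS, T-contrasts, and tSNR.

The design follows the mini-block convention: one boxcar per condition over
the 8 s elaboration windows, convolved with the canonical HRF, plus six
motion covariates, a discrete-cosine drift set realizing the 128 s
high-pass filter inside the model, and an intercept.  Fitting is ordinary
least squares (no autocorrelation whitening).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage, stats

from .hrf import condition_regressor, dct_drift_basis
from .types import BoldRun, MotionTrace, TrialSchedule

log = logging.getLogger(__name__)

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # 1/2.3548


@dataclass
class DesignMatrix:
    matrix: np.ndarray
    names: list[str]
    effect_columns: list[int]
    nuisance_columns: list[int]

    def __post_init__(self) -> None:
        if self.matrix.shape[1] != len(self.names):
            raise ValueError("column names do not match the matrix")
        if set(self.effect_columns) & set(self.nuisance_columns):
            raise ValueError("effect and nuisance columns must be disjoint")


@dataclass
class QcReport:
    global_mean: np.ndarray
    outlier_volumes: np.ndarray
    outlier_fraction: float
    excluded: bool


@dataclass
class ContrastMap:
    """A contrast-estimate (and T-statistic) map on the source grid."""

    beta: np.ndarray
    t: np.ndarray
    contrast_name: str
    kind: str = "beta_contrast"  # or "t_stat"
    space: str = "native"

    @property
    def values(self) -> np.ndarray:
        return self.beta if self.kind == "beta_contrast" else self.t


@dataclass
class GlmFit:
    beta: np.ndarray  # (n_regressors, n_masked_voxels)
    resid_var: np.ndarray  # (n_masked_voxels,)
    xtx_inv: np.ndarray
    design: DesignMatrix
    mask_flat: np.ndarray  # flat voxel indices into the grid
    grid_shape: tuple[int, int, int]
    df: int

    def coefficient_map(self, name: str) -> np.ndarray:
        out = np.zeros(self.grid_shape)
        out.reshape(-1)[self.mask_flat] = self.beta[self.design.names.index(name)]
        return out


def discard_leading_volumes(run: BoldRun, n: int) -> BoldRun:
    """Drop the first ``n`` volumes (non-steady-state waiting period)."""
    if n < 0 or n >= run.n_volumes:
        raise ValueError("n must satisfy 0 <= n < run length")
    if n == 0:
        return run
    return replace(
        run,
        data=run.data[..., n:],
        n_discarded_leading_volumes=run.n_discarded_leading_volumes + n,
    )


def smooth_gaussian(run: BoldRun, fwhm_mm: float) -> BoldRun:
    """Spatially smooth each volume with an isotropic Gaussian kernel.

    ``sigma = FWHM / 2.3548`` per axis, expressed in voxel units via the
    voxel size; boundaries use reflect padding so the per-volume mean is
    preserved up to edge effects.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be non-negative")
    if fwhm_mm == 0:
        return run
    sigma = tuple(fwhm_mm * FWHM_TO_SIGMA / v for v in run.voxel_size_mm) + (0.0,)
    return replace(run, data=ndimage.gaussian_filter(run.data, sigma=sigma, mode="reflect"))


def detect_motion_outliers(
    run: BoldRun,
    motion: MotionTrace,
    intensity_band: float = 0.97,
    translation_thresh_mm: float = 1.0,
    rotation_thresh_rad: float = 0.02,
    exclusion_fraction: float = 0.10,
) -> QcReport:
    """Flag artifact volumes and decide run exclusion.

    A volume is an outlier if its standardized global mean intensity falls
    outside the central ``intensity_band`` (default 97%) two-sided normal
    band — the global signal is first detrended with the low-frequency
    discrete-cosine set (so scanner drift is not mistaken for artifact) and
    standardized by the residual SD — OR if any motion parameter jumps by
    more than the
    translation/rotation threshold relative to the previous volume.  The
    run is excluded when the outlier fraction exceeds
    ``exclusion_fraction`` of retained volumes.
    """
    if run.n_volumes == 0:
        raise ValueError("empty run")
    if len(motion) != run.n_volumes:
        raise ValueError("motion trace length does not match the run")

    g = run.data.reshape(-1, run.n_volumes).mean(axis=0)
    X = np.column_stack(
        [np.ones(run.n_volumes), dct_drift_basis(run.n_volumes, run.tr_s)]
    )
    resid = g - X @ np.linalg.lstsq(X, g, rcond=None)[0]
    scale = resid.std()
    z_crit = stats.norm.ppf(0.5 + intensity_band / 2.0)
    intensity_out = (
        np.abs(resid) > z_crit * scale if scale > 0 else np.zeros_like(g, bool)
    )

    d = np.abs(np.diff(motion.params, axis=0))
    motion_out = np.zeros(run.n_volumes, bool)
    motion_out[1:] = (d[:, :3] > translation_thresh_mm).any(axis=1) | (
        d[:, 3:] > rotation_thresh_rad
    ).any(axis=1)

    outliers = np.flatnonzero(intensity_out | motion_out)
    fraction = len(outliers) / run.n_volumes
    return QcReport(
        global_mean=g,
        outlier_volumes=outliers,
        outlier_fraction=fraction,
        excluded=fraction > exclusion_fraction,
    )


def build_design(
    schedule: TrialSchedule,
    motion: MotionTrace,
    tr_s: float,
    n_volumes: int | None = None,
    t0_s: float = 0.0,
    highpass_s: float = 128.0,
) -> DesignMatrix:
    """Mini-block design: AM/MA elaboration regressors + nuisance terms.

    ``t0_s`` is the scanner time of the first retained volume (e.g.
    ``5 * TR`` after discarding five leading volumes); schedule onsets are
    in scanner time.
    """
    if n_volumes is None:
        n_volumes = len(motion)
    if len(motion) != n_volumes:
        raise ValueError("motion trace length does not match n_volumes")
    if schedule.trials["elaboration_end_s"].max() > t0_s + n_volumes * tr_s:
        raise ValueError("schedule extends beyond the run duration")

    cols, names = [], []
    trials = schedule.trials
    for cond in ("AM", "MA"):
        sel = trials["condition"] == cond
        onsets = trials.loc[sel, "elaboration_onset_s"].to_numpy(float)
        durations = (
            trials.loc[sel, "elaboration_end_s"] - trials.loc[sel, "elaboration_onset_s"]
        ).to_numpy(float)
        cols.append(condition_regressor(onsets, durations, n_volumes, tr_s, t0_s=t0_s))
        names.append(cond)
    effect_columns = [0, 1]

    motion_cols = motion.params - motion.params.mean(axis=0)
    for i in range(6):
        cols.append(motion_cols[:, i])
        names.append(f"motion_{i}")
    drift = dct_drift_basis(n_volumes, tr_s, highpass_s)
    for j in range(drift.shape[1]):
        cols.append(drift[:, j])
        names.append(f"dct_{j + 1}")
    cols.append(np.ones(n_volumes))
    names.append("constant")

    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]} columns)"
        )
    return DesignMatrix(
        matrix=X,
        names=names,
        effect_columns=effect_columns,
        nuisance_columns=list(range(2, X.shape[1])),
    )


def fit_glm(run: BoldRun, design: DesignMatrix, mask: np.ndarray | None = None) -> GlmFit:
    """Voxelwise ordinary least squares."""
    X = design.matrix
    if X.shape[0] != run.n_volumes:
        raise ValueError("design rows do not match run volumes")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError("design matrix is rank deficient")

    if mask is None:
        mask_flat = np.arange(int(np.prod(run.grid_shape)))
    else:
        mask_flat = np.flatnonzero(np.asarray(mask).reshape(-1))
    Y = run.data.reshape(-1, run.n_volumes)[mask_flat].T  # (T, V)

    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y
    resid = Y - X @ beta
    df = run.n_volumes - rank
    resid_var = (resid**2).sum(axis=0) / df
    return GlmFit(
        beta=beta,
        resid_var=resid_var,
        xtx_inv=xtx_inv,
        design=design,
        mask_flat=mask_flat,
        grid_shape=run.grid_shape,
        df=df,
    )


def t_contrast(fit: GlmFit, weights: np.ndarray, name: str = "contrast") -> ContrastMap:
    """T-statistic and contrast-estimate maps for ``c' beta``.

    Voxels with zero residual variance keep their beta contrast but have an
    undefined (NaN) T value.
    """
    c = np.asarray(weights, float)
    if c.shape != (fit.beta.shape[0],):
        raise ValueError("weight length must equal the regressor count")
    beta_c = c @ fit.beta
    var_c = fit.resid_var * float(c @ fit.xtx_inv @ c)
    # variance indistinguishable from rounding error (exact interpolation)
    # leaves t undefined rather than astronomically large
    denom = np.sqrt(var_c)
    defined = denom > 1e-10 * (1.0 + np.abs(beta_c))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(defined, beta_c / denom, np.nan)
    if np.any(~defined):
        log.info("zero residual variance at %d voxels; t masked", int((~defined).sum()))

    def to3d(v, fill=0.0):
        out = np.full(fit.grid_shape, fill)
        out.reshape(-1)[fit.mask_flat] = v
        return out

    return ContrastMap(beta=to3d(beta_c), t=to3d(t, np.nan), contrast_name=name)


def percent_signal_change(fit: GlmFit, condition: str) -> np.ndarray:
    """Condition beta scaled to percent of the voxel baseline (intercept)."""
    b = fit.beta[fit.design.names.index(condition)]
    b0 = fit.beta[fit.design.names.index("constant")]
    with np.errstate(divide="ignore", invalid="ignore"):
        psc = np.where(b0 != 0, 100.0 * b / b0, np.nan)
    out = np.zeros(fit.grid_shape)
    out.reshape(-1)[fit.mask_flat] = psc
    return out


def compute_tsnr(
    run: BoldRun, mask: np.ndarray, highpass_s: float = 128.0
) -> tuple[float, np.ndarray]:
    """Mean temporal SNR over a ROI after drift removal.

    tSNR per voxel is the raw temporal mean divided by the residual SD
    after projecting out the intercept and the discrete-cosine drift set;
    zero-variance voxels are excluded from the ROI mean and logged.
    Returns ``(roi_mean, voxel_values)``.
    """
    if run.n_volumes < 2:
        raise ValueError("need at least two volumes for tSNR")
    mask_flat = np.flatnonzero(np.asarray(mask).reshape(-1))
    if mask_flat.size == 0:
        raise ValueError("empty mask")
    Y = run.data.reshape(-1, run.n_volumes)[mask_flat].T
    drift = dct_drift_basis(run.n_volumes, run.tr_s, highpass_s)
    X = np.column_stack([np.ones(run.n_volumes), drift])
    resid = Y - X @ np.linalg.lstsq(X, Y, rcond=None)[0]
    df = run.n_volumes - X.shape[1]
    sd = np.sqrt((resid**2).sum(axis=0) / df)
    mean = Y.mean(axis=0)
    ok = sd > 0
    if not ok.all():
        log.warning("excluding %d zero-variance voxels from tSNR", int((~ok).sum()))
    if not ok.any():
        raise ValueError("all ROI voxels have zero temporal variance")
    tsnr = np.full(mask_flat.shape, np.nan)
    tsnr[ok] = mean[ok] / sd[ok]
    return float(np.nanmean(tsnr)), tsnr
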