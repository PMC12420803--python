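"""Local synchronization (LCOR) of resting-state time series.

LCOR of a voxel is the Gaussian-distance-weighted average Pearson
correlation between its time series and those of the surrounding voxels:

    LCOR(v) = sum_u w(d(v,u)) * corr(x_v, x_u) / sum_u w(d(v,u))

with ``w`` a Gaussian of stated FWHM in mm (sigma = FWHM / 2.3548), the sum
running over in-mask voxels ``u != v`` within a truncation radius.  It is a
local-synchronization analogue of regional homogeneity: high where a voxel's
neighbourhood fluctuates coherently, near zero where it does not.

The standard order of operations is confound regression -> LCOR -> Gaussian
smoothing of the LCOR map; robustness toggles (skip smoothing, drop leading
volumes, omit a regressor) are handled by the caller simply by changing the
inputs to these three functions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from scipy import ndimage

from .types import FunctionalImage, StatMap
from .volume_io import voxel_coords_mm, voxel_sizes_mm

__all__ = ["ConfoundSet", "LcorParams", "regress_confounds", "compute_lcor", "gaussian_smooth"]

logger = logging.getLogger(__name__)

FWHM_TO_SIGMA = 1.0 / 2.3548200450309493  # = 1 / (2 sqrt(2 ln 2))


@dataclass
class ConfoundSet:
    """Nuisance regressors (t x k): tissue mean signals, motion expansions..."""

    regressors: np.ndarray
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.regressors = np.atleast_2d(np.asarray(self.regressors, dtype=float))
        if self.regressors.size and not np.all(np.isfinite(self.regressors)):
            raise ValueError("confound regressors must be finite")
        if not self.names:
            self.names = [f"confound_{i}" for i in range(self.regressors.shape[1])]
        if len(self.names) != self.regressors.shape[1]:
            raise ValueError("one name per regressor column required")

    @classmethod
    def empty(cls, n_timepoints: int) -> "ConfoundSet":
        return cls(regressors=np.empty((n_timepoints, 0)), names=[])


@dataclass
class LcorParams:
    """Kernel and smoothing settings, in mm.

    ``kernel_fwhm_mm`` is the FWHM of the distance weighting (default 25 mm);
    ``smooth_fwhm_mm`` the post-hoc smoothing of the LCOR map (default 6 mm,
    0 disables).  The kernel is truncated at ``truncation_radius_mm``
    (default 2 x FWHM, where weights have fallen below 1e-5 of the peak).
    """

    kernel_fwhm_mm: float = 25.0
    smooth_fwhm_mm: float = 6.0
    truncation_radius_mm: float | None = None
    mask: np.ndarray | None = None
    include_self: bool = False

    def __post_init__(self) -> None:
        if self.kernel_fwhm_mm <= 0:
            raise ValueError("kernel_fwhm_mm must be positive")
        if self.smooth_fwhm_mm < 0:
            raise ValueError("smooth_fwhm_mm must be nonnegative")
        if self.truncation_radius_mm is None:
            self.truncation_radius_mm = 2.0 * self.kernel_fwhm_mm
        if self.truncation_radius_mm < self.kernel_fwhm_mm / 2:
            raise ValueError("truncation radius must be at least FWHM/2")


def regress_confounds(img: FunctionalImage, confounds: ConfoundSet) -> FunctionalImage:
    """Replace every voxel series by its OLS residual against [1 | confounds].

    Collinear confound columns are dropped with a warning (pivoted-QR rank
    detection); the intercept is always kept, so the output is mean-centred
    in time.
    """
    t = img.n_timepoints
    reg = confounds.regressors
    if reg.shape[0] != t:
        raise ValueError(f"confound rows ({reg.shape[0]}) must equal timepoints ({t})")
    X = np.column_stack([np.ones(t), reg])
    if t < X.shape[1] + 2:
        raise ValueError("need at least k+2 timepoints for confound regression")
    # drop collinear columns, keeping the intercept
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, _, piv = sla.qr(X, pivoting=True, mode="economic")
        keep = np.sort(piv[:rank])
        dropped = [(["intercept"] + confounds.names)[i] for i in piv[rank:]]
        logger.warning("dropping collinear confound columns: %s", dropped)
        warnings.warn(f"dropping collinear confound columns: {dropped}", stacklevel=2)
        X = X[:, keep]
    Y = img.data.reshape(-1, t).T  # (t, V)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return FunctionalImage(
        data=resid.T.reshape(img.data.shape), affine=img.affine, tr_seconds=img.tr_seconds
    )


def compute_lcor(img: FunctionalImage, params: LcorParams) -> StatMap:
    """Voxel-wise LCOR within the analysis mask.

    Zero-variance voxels are missing in the output and excluded from every
    neighbourhood average; weights are renormalized over the remaining
    in-mask neighbours.  Output values lie in [-1, 1].
    """
    shape = img.shape3d
    mask = params.mask if params.mask is not None else np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != shape:
        raise ValueError("mask shape must match image grid")
    if mask.sum() < 2:
        raise ValueError("mask must contain at least 2 voxels")

    flat_idx = np.flatnonzero(mask.ravel())
    series = img.data.reshape(-1, img.n_timepoints)[flat_idx]  # (V, t)
    sd = series.std(axis=1)
    valid = sd > 0
    n_invalid = int((~valid).sum())
    if n_invalid:
        logger.warning("%d zero-variance voxels set to missing", n_invalid)
    z = np.zeros_like(series)
    z[valid] = (series[valid] - series[valid].mean(axis=1, keepdims=True)) / (
        sd[valid, None] * np.sqrt(series.shape[1])
    )  # rows unit-norm => z @ z.T is the Pearson correlation matrix

    coords = voxel_coords_mm(shape, img.affine)[flat_idx]
    sigma = params.kernel_fwhm_mm * FWHM_TO_SIGMA
    trunc2 = params.truncation_radius_mm**2

    V = len(flat_idx)
    out = np.full(V, np.nan)
    chunk = max(1, int(4e7 // max(V, 1)))
    for start in range(0, V, chunk):
        stop = min(start + chunk, V)
        d2 = ((coords[start:stop, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
        w = np.exp(-d2 / (2.0 * sigma**2))
        w[d2 > trunc2] = 0.0
        if not params.include_self:
            w[np.arange(stop - start), np.arange(start, stop)] = 0.0
        w[:, ~valid] = 0.0
        c = z[start:stop] @ z.T
        wsum = w.sum(axis=1)
        rows_ok = valid[start:stop] & (wsum > 0)
        vals = np.full(stop - start, np.nan)
        vals[rows_ok] = (w * c).sum(axis=1)[rows_ok] / wsum[rows_ok]
        out[start:stop] = vals

    full = np.full(np.prod(shape), np.nan)
    full[flat_idx] = np.clip(out, -1.0, 1.0)
    return StatMap(data=full.reshape(shape), affine=img.affine, label="LCOR")


def gaussian_smooth(stat: StatMap, fwhm_mm: float) -> StatMap:
    """Mask-aware separable Gaussian smoothing in mm units.

    Non-finite voxels define the mask; the convolution is renormalized by
    the smoothed mask so values do not bleed toward zero at mask edges.
    ``fwhm_mm = 0`` is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be nonnegative")
    if fwhm_mm == 0:
        return StatMap(data=stat.data.copy(), affine=stat.affine, label=stat.label, df=stat.df)
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / voxel_sizes_mm(stat.affine)
    finite = np.isfinite(stat.data)
    filled = np.where(finite, stat.data, 0.0)
    num = ndimage.gaussian_filter(filled, sigma=sigma_vox, mode="constant")
    den = ndimage.gaussian_filter(finite.astype(float), sigma=sigma_vox, mode="constant")
    out = np.full_like(filled, np.nan)
    out[finite] = num[finite] / den[finite]
    return StatMap(data=out, affine=stat.affine, label=stat.label, df=stat.df)
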