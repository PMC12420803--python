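"""Voxel-wise group GLM with permutation-based FWE and TFCE inference.

The model is ordinary least squares per voxel, ``y = X b + e``, with a
single contrast vector ``c``; inference uses Freedman–Lane permutation of
reduced-model residuals (optionally restricted within exchangeability
blocks such as acquisition site), building max-|t| and max-TFCE null
distributions.  Significance requires BOTH the voxel-level FWE p and the
TFCE FWE p to fall below alpha, split by contrast sign.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .types import StatMap

__all__ = [
    "DesignMatrix",
    "InferenceResult",
    "design_from_covariates",
    "fit_voxelwise_glm",
    "tfce_transform",
    "permutation_inference",
]

logger = logging.getLogger(__name__)


@dataclass
class DesignMatrix:
    """Subject x p design with column names and one contrast vector."""

    matrix: np.ndarray
    names: list[str]
    contrast: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        self.contrast = np.asarray(self.contrast, dtype=float)
        if self.matrix.shape[1] != len(self.names):
            raise ValueError("one name per design column required")
        if self.contrast.shape != (self.matrix.shape[1],):
            raise ValueError("contrast length must equal number of columns")
        rank = np.linalg.matrix_rank(self.matrix)
        if rank < self.matrix.shape[1]:
            corr = np.corrcoef(self.matrix, rowvar=False)
            np.fill_diagonal(corr, 0.0)
            i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
            raise ValueError(
                f"design matrix is rank deficient (rank {rank} < {self.matrix.shape[1]}); "
                f"most collinear pair: {self.names[i]!r} / {self.names[j]!r}"
            )

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]


def design_from_covariates(
    covariates: pd.DataFrame,
    group_col: str = "group",
    case_label: str = "case",
    numeric_cols: tuple[str, ...] = ("age", "sex", "fiq", "motion_translation", "motion_rotation"),
    site_col: str | None = "site",
) -> DesignMatrix:
    """Build [intercept | group | covariates | site dummies] with a group contrast.

    The group column is coded case=1 / control=0; the contrast tests
    case - control adjusted for the remaining columns.  Site enters as
    dummy-coded fixed effects (first site is the reference).  A covariate
    with zero variance in the sample is skipped with a warning.
    """
    n = len(covariates)
    group = (covariates[group_col] == case_label).astype(float).to_numpy()
    if group.min() == group.max():
        raise ValueError("both groups must be present")
    cols = [np.ones(n), group]
    names = ["intercept", "group"]
    for c in numeric_cols:
        if c in covariates:
            vals = covariates[c].astype(float).to_numpy()
            if np.ptp(vals) == 0:
                logger.warning("covariate %r is constant in this sample; skipped", c)
                continue
            cols.append(vals)
            names.append(c)
    if site_col is not None and site_col in covariates:
        sites = sorted(covariates[site_col].unique().tolist())
        for s in sites[1:]:
            cols.append((covariates[site_col] == s).astype(float).to_numpy())
            names.append(f"site_{s}")
    X = np.column_stack(cols)
    contrast = np.zeros(X.shape[1])
    contrast[1] = 1.0
    return DesignMatrix(matrix=X, names=names, contrast=contrast)


# ---------------------------------------------------------------------------
# OLS t-maps


def _stack(maps: "list[StatMap] | np.ndarray") -> tuple[np.ndarray, tuple[int, ...], np.ndarray]:
    if isinstance(maps, np.ndarray):
        raise TypeError("pass a list of StatMap")
    shape = maps[0].data.shape
    affine = maps[0].affine
    for m in maps[1:]:
        if m.data.shape != shape or not np.allclose(m.affine, affine, atol=1e-5):
            raise ValueError("subject maps are not co-registered")
    Y = np.stack([m.data.ravel() for m in maps])  # (n, V)
    return Y, shape, affine


def _t_from_Y(Y: np.ndarray, pinvX: np.ndarray, X: np.ndarray, c: np.ndarray, dof: int, cxxc: float) -> np.ndarray:
    beta = pinvX @ Y
    resid = Y - X @ beta
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.maximum(sigma2 * cxxc, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(se > 0, (c @ beta) / se, 0.0)


def fit_voxelwise_glm(maps: list[StatMap], design: DesignMatrix) -> StatMap:
    """Per-voxel OLS t-map for the design's contrast; df = n - rank(X)."""
    Y, shape, affine = _stack(maps)
    X, c = design.matrix, design.contrast
    n, p = X.shape
    if n < p + 2:
        raise ValueError("need at least p+2 subjects")
    if Y.shape[0] != n:
        raise ValueError("number of maps must match design rows")
    dof = n - p
    xtx_inv = np.linalg.inv(X.T @ X)
    pinvX = xtx_inv @ X.T
    cxxc = float(c @ xtx_inv @ c)
    bad = ~np.all(np.isfinite(Y), axis=0)
    Yc = np.where(bad[None, :], 0.0, Y)
    t = _t_from_Y(Yc, pinvX, X, c, dof, cxxc)
    t[bad] = np.nan
    return StatMap(data=t.reshape(shape), affine=affine, label="t_contrast", df=dof)


# ---------------------------------------------------------------------------
# TFCE


def _tfce_one_sided(pos: np.ndarray, heights: np.ndarray, dh: float, E: float, H: float, structure: np.ndarray) -> np.ndarray:
    out = np.zeros_like(pos)
    tol = 1e-9 * float(pos.max())  # guard against arange float accumulation
    for h in heights:
        sup = pos >= h - tol
        if not sup.any():
            break
        lab, n = ndimage.label(sup, structure=structure)
        if n == 0:
            break
        sizes = np.bincount(lab.ravel())
        out[sup] += (sizes[lab[sup]].astype(float) ** E) * (h**H) * dh
    return out


def tfce_transform(
    t_map: StatMap, E: float = 0.5, H: float = 2.0, dh: float | None = None, n_steps: int = 100
) -> StatMap:
    """Threshold-free cluster enhancement with 26-connectivity.

    TFCE(v) = sum_h extent(cluster_h(v))^E * h^H * dh over heights from dh
    to the map maximum; the negative tail is the same transform applied to
    the negated map and re-negated, so the output is signed.  By default
    ``dh = max|t| / n_steps``.
    """
    data = np.nan_to_num(t_map.data, nan=0.0)
    peak = float(np.abs(data).max())
    if peak == 0:
        return StatMap(data=np.zeros_like(data), affine=t_map.affine, label="tfce", df=t_map.df)
    if dh is None:
        dh = peak / n_steps
    structure = np.ones((3, 3, 3), dtype=bool)
    out = np.zeros_like(data)
    for sign in (1.0, -1.0):
        side = np.maximum(sign * data, 0.0)
        mx = side.max()
        if mx <= 0:
            continue
        heights = np.arange(dh, mx + dh / 2, dh)
        out += sign * _tfce_one_sided(side, heights, dh, E, H, structure)
    return StatMap(data=out, affine=t_map.affine, label="tfce", df=t_map.df)


# ---------------------------------------------------------------------------
# Permutation inference


@dataclass
class InferenceResult:
    t_map: StatMap
    tfce_map: StatMap
    fwe_p_voxel: StatMap
    fwe_p_tfce: StatMap
    sig_mask_pos: np.ndarray
    sig_mask_neg: np.ndarray
    n_permutations: int
    seed: int
    alpha: float = 0.05
    exhaustive: bool = False


def _block_permutations(blocks: np.ndarray, n_perm: int, rng: np.random.Generator) -> tuple[np.ndarray, bool]:
    """Row permutations respecting exchangeability blocks.

    Returns (n_perm, n) index array (first row NOT included; the identity is
    handled by the caller as the observed statistic) and whether enumeration
    was exhaustive.
    """
    n = len(blocks)
    uniq = np.unique(blocks)
    n_distinct = 1.0
    for b in uniq:
        n_distinct *= math.factorial(int((blocks == b).sum()))
        if n_distinct > 1e7:
            break
    if n_distinct <= n_perm:
        logger.info("only %d distinct permutations; enumerating exhaustively", int(n_distinct))
        per_block = [list(itertools.permutations(np.flatnonzero(blocks == b))) for b in uniq]
        perms = []
        for combo in itertools.product(*per_block):
            idx = np.empty(n, dtype=int)
            for b, order in zip(uniq, combo):
                idx[np.flatnonzero(blocks == b)] = order
            perms.append(idx)
        return np.array(perms), True
    out = np.tile(np.arange(n), (n_perm, 1))
    for b in uniq:
        pos = np.flatnonzero(blocks == b)
        for i in range(n_perm):
            out[i, pos] = rng.permutation(pos)
    return out, False


def permutation_inference(
    maps: list[StatMap],
    design: DesignMatrix,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    blocks: np.ndarray | None = None,
    tfce_E: float = 0.5,
    tfce_H: float = 2.0,
    tfce_steps: int = 100,
) -> InferenceResult:
    """Freedman–Lane permutation test of the design's contrast.

    The reduced model contains every column with zero contrast weight; its
    residuals are permuted (within ``blocks`` when given), added back to the
    reduced fit and re-analysed under the full model.  Voxel-level FWE
    p-values come from the max-|t| distribution, cluster-level from the
    max-|TFCE| distribution; both use (1 + #{perm >= obs}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    Y, shape, affine = _stack(maps)
    X, c = design.matrix, design.contrast
    n, p = X.shape
    dof = n - p
    rng = np.random.default_rng(seed)
    if blocks is None:
        blocks = np.zeros(n, dtype=int)
    blocks = np.asarray(blocks)

    nuisance = np.abs(c) < 1e-12
    Z = X[:, nuisance]
    if Z.shape[1] == 0:
        Z = np.zeros((n, 0))
    # reduced-model fit and residuals (Freedman-Lane)
    if Z.shape[1]:
        Hz = Z @ np.linalg.pinv(Z)
        fitted_red = Hz @ Y
    else:
        fitted_red = np.zeros_like(Y)
    resid_red = Y - fitted_red

    xtx_inv = np.linalg.inv(X.T @ X)
    pinvX = xtx_inv @ X.T
    cxxc = float(c @ xtx_inv @ c)

    bad = ~np.all(np.isfinite(Y), axis=0)
    Yobs = np.where(bad[None, :], 0.0, Y)
    t_obs = _t_from_Y(Yobs, pinvX, X, c, dof, cxxc)
    t_obs[bad] = 0.0
    t_map = StatMap(data=t_obs.reshape(shape), affine=affine, label="t_contrast", df=dof)
    tfce_map = tfce_transform(t_map, E=tfce_E, H=tfce_H, n_steps=tfce_steps)

    perms, exhaustive = _block_permutations(blocks, n_perm, rng)
    n_eff = len(perms)
    max_t = np.empty(n_eff)
    max_tfce = np.empty(n_eff)
    resid_clean = np.where(bad[None, :], 0.0, resid_red)
    fitted_clean = np.where(bad[None, :], 0.0, fitted_red)
    for i, idx in enumerate(perms):
        Yp = fitted_clean + resid_clean[idx]
        t_p = _t_from_Y(Yp, pinvX, X, c, dof, cxxc)
        t_p[bad] = 0.0
        max_t[i] = np.abs(t_p).max()
        tf = tfce_transform(
            StatMap(data=t_p.reshape(shape), affine=affine), E=tfce_E, H=tfce_H, n_steps=tfce_steps
        )
        max_tfce[i] = np.abs(tf.data).max()

    denom = n_eff + 1
    abs_t = np.abs(t_obs)
    p_vox = (1 + (max_t[None, :] >= abs_t[:, None]).sum(axis=1)) / denom
    abs_tf = np.abs(tfce_map.data.ravel())
    p_tfce = (1 + (max_tfce[None, :] >= abs_tf[:, None]).sum(axis=1)) / denom
    p_vox[bad] = 1.0
    p_tfce[bad] = 1.0

    sig = (p_vox < alpha) & (p_tfce < alpha)
    sig_pos = (sig & (t_obs > 0)).reshape(shape)
    sig_neg = (sig & (t_obs < 0)).reshape(shape)
    return InferenceResult(
        t_map=t_map,
        tfce_map=tfce_map,
        fwe_p_voxel=StatMap(data=p_vox.reshape(shape), affine=affine, label="fwe_p_voxel"),
        fwe_p_tfce=StatMap(data=p_tfce.reshape(shape), affine=affine, label="fwe_p_tfce"),
        sig_mask_pos=sig_pos,
        sig_mask_neg=sig_neg,
        n_permutations=n_eff,
        seed=seed,
        alpha=alpha,
        exhaustive=exhaustive,
    )
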