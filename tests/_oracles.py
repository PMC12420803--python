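"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (double loops, explicit normal
equations) kept separate from the package so each test compares two
independent routes to the same quantity.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def lcor_bruteforce(
    series: np.ndarray,
    coords_mm: np.ndarray,
    fwhm_mm: float,
    truncation_mm: float,
    include_self: bool = False,
) -> np.ndarray:
    """Double-loop weighted-correlation LCOR over an explicit voxel list."""
    sigma = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    V = len(series)
    sd = series.std(axis=1)
    out = np.full(V, np.nan)
    for v in range(V):
        if sd[v] == 0:
            continue
        num = den = 0.0
        for u in range(V):
            if sd[u] == 0 or (u == v and not include_self):
                continue
            d = np.linalg.norm(coords_mm[v] - coords_mm[u])
            if d > truncation_mm:
                continue
            w = np.exp(-(d**2) / (2 * sigma**2))
            r = np.corrcoef(series[v], series[u])[0, 1]
            num += w * r
            den += w
        if den > 0:
            out[v] = num / den
    return out


def partial_spearman_normal_equations(x: np.ndarray, y: np.ndarray, cov: np.ndarray) -> float:
    """Residual-on-ranks partial correlation via explicit normal equations."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rc = stats.rankdata(cov)
    A = np.column_stack([np.ones(len(rc)), rc])
    AtA = A.T @ A
    bx = np.linalg.pinv(AtA) @ A.T @ rx
    by = np.linalg.pinv(AtA) @ A.T @ ry
    ex = rx - A @ bx
    ey = ry - A @ by
    return float(ex @ ey / np.sqrt((ex @ ex) * (ey @ ey)))


def tfce_single_voxel_sum(height: float, E: float, H: float, dh: float) -> float:
    """Discrete-sum closed form for one isolated suprathreshold voxel."""
    heights = np.arange(dh, height + dh / 2, dh)
    return float(np.sum((1.0**E) * heights**H * dh))


def smooth3d_direct(data: np.ndarray, sigma_vox: float) -> np.ndarray:
    """Direct separable discrete-Gaussian convolution (constant padding)."""
    radius = int(4.0 * sigma_vox + 0.5)
    offs = np.arange(-radius, radius + 1)
    k = np.exp(-(offs**2) / (2 * sigma_vox**2))
    k /= k.sum()
    out = data.astype(float)
    for axis in range(3):
        moved = np.moveaxis(out, axis, -1)
        res = np.zeros_like(moved)
        n = moved.shape[-1]
        for j, o in enumerate(offs):
            lo, hi = max(0, -o), min(n, n - o)
            res[..., lo:hi] += k[j] * moved[..., lo + o : hi + o]
        out = np.moveaxis(res, -1, axis)
    return out
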