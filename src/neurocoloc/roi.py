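"""Region-of-interest drug effects: mask means and paired delta-score tests.

Within masks of case-control significance, each subject contributes one
mean LCOR value per pharmacological condition; the delta-score is drug
minus placebo, tested against zero with a directional one-sample t-test
(df = n - 1), Cohen's d = |mean delta| / sd(delta), and a one-sided 90%
confidence interval open toward the hypothesized tail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .types import StatMap

__all__ = ["DeltaResult", "extract_mask_means", "delta_test"]


@dataclass
class DeltaResult:
    t: float
    df: int
    p_one_sided: float
    cohen_d: float
    ci_one_sided: tuple[float, float]
    direction: str
    mask_label: str = ""

    def __post_init__(self) -> None:
        if self.direction not in ("less", "greater"):
            raise ValueError("direction must be 'less' or 'greater'")
        if not (0 < self.p_one_sided < 1):
            raise ValueError("p must lie in (0, 1)")


def extract_mask_means(maps: dict[str, list[StatMap]], mask: np.ndarray) -> dict[str, np.ndarray]:
    """Mean over masked finite voxels, per subject and condition.

    ``maps`` maps condition name -> per-subject StatMaps; returns condition
    name -> vector of subject means.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    out: dict[str, np.ndarray] = {}
    for cond, subject_maps in maps.items():
        means = []
        for m in subject_maps:
            vals = m.data[mask]
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                raise ValueError(f"mask contains no finite voxels for condition {cond!r}")
            means.append(vals.mean())
        out[cond] = np.array(means)
    return out


def delta_test(
    drug_means: np.ndarray,
    placebo_means: np.ndarray,
    direction: str,
    mask_label: str = "",
    ci_level: float = 0.90,
) -> DeltaResult:
    """Directional one-sample t-test on delta = drug - placebo.

    direction='less' tests mean(delta) < 0 (p is the lower tail),
    'greater' the upper tail.  The one-sided CI at ``ci_level`` is
    (-inf, mean + t_level * se] for 'less' and [mean - t_level * se, inf)
    for 'greater'.  Note |t| = cohen_d * sqrt(n) under the d = |mean|/sd
    definition.
    """
    drug_means = np.asarray(drug_means, dtype=float)
    placebo_means = np.asarray(placebo_means, dtype=float)
    if drug_means.shape != placebo_means.shape:
        raise ValueError("paired vectors must have equal length")
    n = len(drug_means)
    if n < 3:
        raise ValueError("need at least 3 paired subjects")
    delta = drug_means - placebo_means
    sd = delta.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance delta: t undefined")
    mean = delta.mean()
    se = sd / np.sqrt(n)
    t = mean / se
    df = n - 1
    p = stats.t.cdf(t, df) if direction == "less" else stats.t.sf(t, df)
    tq = stats.t.ppf(ci_level, df)
    if direction == "less":
        ci = (-np.inf, float(mean + tq * se))
    else:
        ci = (float(mean - tq * se), np.inf)
    return DeltaResult(
        t=float(t),
        df=df,
        p_one_sided=float(p),
        cohen_d=float(abs(mean) / sd),
        ci_one_sided=ci,
        direction=direction,
        mask_label=mask_label,
    )
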