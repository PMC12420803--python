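"""Neurochemical co-localization profiles and individual-level analyses.

A profile is the 16-vector of Fisher-z co-localization strengths of one
contrast with the canonical receptor/transporter template set; profiles of
different contrasts (e.g. case-control vs drug-placebo) are compared by
Pearson correlation over the 16 systems (df = 14).  Individual analyses
standardize each case subject's regional values against the control group
(z-maps), co-localize them with a template, and correlate the resulting
per-subject Fisher z with symptom scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .coloc import ATANH_CLIP, ColocResult, partial_spearman
from .types import CANONICAL_TEMPLATES

__all__ = [
    "NeurochemProfile",
    "SubjectColoc",
    "build_profile",
    "profile_correlation",
    "subject_zmaps",
    "subject_coloc",
    "symptom_correlation",
]

logger = logging.getLogger(__name__)


@dataclass
class NeurochemProfile:
    """Fisher-z co-localization strengths in canonical template order."""

    z: np.ndarray
    template_names: tuple[str, ...]
    contrast_label: str = ""

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.template_names = tuple(self.template_names)
        if len(self.template_names) != len(set(self.template_names)):
            raise ValueError("template names must be unique")
        if self.z.shape != (len(self.template_names),):
            raise ValueError("one z per template required")


@dataclass
class SubjectColoc:
    """Per-subject co-localization strengths and (optional) symptom scores."""

    subject_id: str
    fisher_z_by_template: dict[str, float]
    scores: dict[str, float] = field(default_factory=dict)


def build_profile(
    results: dict[str, ColocResult] | list[ColocResult],
    label: str = "",
    template_order: tuple[str, ...] = CANONICAL_TEMPLATES,
) -> NeurochemProfile:
    """Collect one Fisher z per canonical template, in canonical order.

    Input order is irrelevant; a missing or duplicated template is an error.
    """
    if not isinstance(results, dict):
        by_name: dict[str, ColocResult] = {}
        for r in results:
            if r.template_name in by_name:
                raise ValueError(f"duplicate template {r.template_name!r}")
            by_name[r.template_name] = r
        results = by_name
    missing = set(template_order) - set(results)
    if missing:
        raise ValueError(f"missing templates: {sorted(missing)}")
    z = np.array([results[name].fisher_z for name in template_order])
    return NeurochemProfile(z=z, template_names=template_order, contrast_label=label)


def _pearson_with_ci(x: np.ndarray, y: np.ndarray) -> tuple[float, float, tuple[float, float], int]:
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance vector: correlation undefined")
    r, p = stats.pearsonr(x, y)
    z = np.arctanh(np.clip(r, -ATANH_CLIP, ATANH_CLIP))
    half = stats.norm.ppf(0.975) / np.sqrt(n - 3)
    return float(r), float(p), (float(np.tanh(z - half)), float(np.tanh(z + half))), n - 2


def profile_correlation(a: NeurochemProfile, b: NeurochemProfile):
    """Pearson correlation between two neurochemical profiles.

    Returns (r, p, ci95, df); with the 16 canonical systems df = 14.
    """
    if a.template_names != b.template_names:
        raise ValueError("profiles use different template orders")
    return _pearson_with_ci(a.z, b.z)


def subject_zmaps(case_regions: np.ndarray, control_regions: np.ndarray) -> np.ndarray:
    """Regional z-scores of each case subject relative to the control group.

    z[s, r] = (case[s, r] - mean_controls(r)) / sd_controls(r), with the
    n-1 standard deviation.  Regions with zero control variance are missing.
    """
    case_regions = np.atleast_2d(np.asarray(case_regions, dtype=float))
    control_regions = np.atleast_2d(np.asarray(control_regions, dtype=float))
    if control_regions.shape[0] < 3:
        raise ValueError("need at least 3 controls")
    if case_regions.shape[1] != control_regions.shape[1]:
        raise ValueError("case and control region counts differ")
    mu = control_regions.mean(axis=0)
    sd = control_regions.std(axis=0, ddof=1)
    bad = sd == 0
    if bad.any():
        logger.warning("%d regions with zero control sd set to missing", int(bad.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (case_regions - mu) / sd
    z[:, bad] = np.nan
    return z


def subject_coloc(zmap, template, gm) -> float:
    """Fisher z of the partial Spearman between one subject z-map and a template.

    Saturated correlations (|rho| = 1) are clipped just below 1 before the
    atanh transform so the result stays finite.
    """
    rho = partial_spearman(zmap, template, gm)
    if abs(rho) >= 1.0:
        logger.warning("saturated correlation |rho|=1 clipped before atanh")
    return float(np.arctanh(np.clip(rho, -ATANH_CLIP, ATANH_CLIP)))


def symptom_correlation(subjects: list[SubjectColoc], template: str, score: str):
    """Pearson correlation between per-subject co-localization z and a score.

    Subjects missing either value are dropped; returns (r, p, ci95, df)
    with df = n_complete - 2.
    """
    pairs = [
        (s.fisher_z_by_template[template], s.scores[score])
        for s in subjects
        if template in s.fisher_z_by_template
        and score in s.scores
        and np.isfinite(s.fisher_z_by_template[template])
        and np.isfinite(s.scores[score])
    ]
    if len(pairs) == 0:
        raise ValueError(f"no subject has both {template!r} and {score!r}")
    if len(pairs) < 4:
        raise ValueError("need at least 4 complete subjects")
    x, y = np.array(pairs).T
    return _pearson_with_ci(x, y)


def symptom_correlation_table(
    subjects: list[SubjectColoc], templates: list[str], scores: list[str]
) -> pd.DataFrame:
    """All template x score correlations, raw and BH-adjusted."""
    from .coloc import bh_fdr

    rows = []
    for t in templates:
        for s in scores:
            r, p, ci, df = symptom_correlation(subjects, t, s)
            rows.append(dict(template=t, score=s, r=r, p=p, ci_low=ci[0], ci_high=ci[1], df=df))
    table = pd.DataFrame(rows)
    table["p_bh"] = bh_fdr(table["p"].to_numpy())
    return table
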