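"""Reusable simulation experiments: calibration and recovery studies.

These functions implement the package's standard validation experiments on
synthetic data with known ground truth — null calibration of the surrogate
permutation test (against a naive value permutation), family-wise error
calibration of the permutation GLM, and end-to-end recovery of a
template-shaped group effect through the two-cohort exploration /
replication / meta-combination protocol.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from . import coloc as cl
from . import glm, lcor, synthetic, volume_io
from .seeds import child_seed, substream
from .types import LabelAtlas, StatMap

__all__ = [
    "lcor_maps_for_cohort",
    "group_contrast_vector",
    "two_cohort_replication",
    "surrogate_calibration_replicate",
    "glm_null_replicate",
]


def lcor_maps_for_cohort(cohort: synthetic.Cohort, atlas: LabelAtlas,
                         params: lcor.LcorParams | None = None) -> list[StatMap]:
    """Confound regression (intercept-only) + LCOR + smoothing per subject."""
    if params is None:
        params = lcor.LcorParams(mask=atlas.mask)
    maps = []
    for img in cohort.images:
        resid = lcor.regress_confounds(img, lcor.ConfoundSet.empty(img.n_timepoints))
        m = lcor.compute_lcor(resid, params)
        if params.smooth_fwhm_mm > 0:
            m = lcor.gaussian_smooth(m, params.smooth_fwhm_mm)
        maps.append(m)
    return maps


def group_contrast_vector(cohort: synthetic.Cohort, atlas: LabelAtlas,
                          params: lcor.LcorParams | None = None):
    """Case-control covariate-adjusted t-map, parcellated to region level."""
    maps = lcor_maps_for_cohort(cohort, atlas, params)
    design = glm.design_from_covariates(cohort.covariates)
    tmap = glm.fit_voxelwise_glm(maps, design)
    return volume_io.parcellate(tmap, atlas)


def two_cohort_replication(
    seed: int,
    effect_size: float,
    effect_map_name: str = "NMDA",
    n_surr: int = 200,
    n_templates: int = 16,
    spec_kwargs: dict | None = None,
) -> pd.DataFrame:
    """One two-cohort exploration/replication/meta run on synthetic data.

    Generates an atlas, template set and two independent cohorts (same
    injected effect, different subjects), runs the LCOR -> GLM -> coloc
    chain in both, and returns the replication-protocol table.
    """
    base = dict(effect_map_name=effect_map_name if effect_size != 0.0 else None,
                effect_size=effect_size)
    base.update(spec_kwargs or {})
    geometry = {k: v for k, v in base.items() if k not in ("effect_map_name", "effect_size")}
    atlas = synthetic.make_atlas(
        synthetic.SyntheticSpec(seed=child_seed(seed, "atlas"), **geometry)
    )
    spec_a = synthetic.SyntheticSpec(seed=child_seed(seed, "cohortA"), **base)
    spec_b = synthetic.SyntheticSpec(seed=child_seed(seed, "cohortB"), **base)
    templates = synthetic.make_template_maps(
        atlas, n_templates, seed=child_seed(seed, "templates")
    )
    results = {}
    for label, spec in (("A", spec_a), ("B", spec_b)):
        cohort = synthetic.make_cohort(spec, atlas, templates)
        contrast = group_contrast_vector(cohort, atlas)
        res = {}
        for name, tmpl in templates.maps.items():
            surr = cl.generate_surrogates(
                tmpl, atlas.centroids_mm, n_surr,
                seed=child_seed(seed, f"surr-{label}-{name}"),
            )
            res[name] = cl.coloc_test(contrast, tmpl, templates.gm, surr)
        results[label] = res
    return cl.replication_protocol(results["A"], results["B"])


def surrogate_calibration_replicate(
    seed: int,
    centroids: np.ndarray,
    n_surr: int = 500,
    smoothness_mm: float = 10.0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Null p-values for one smooth map pair: (surrogate p, naive p).

    Contrast, template and gray-matter covariate are independent smooth
    Gaussian random fields, so any rejection is a false positive.  The
    naive p permutes template values without preserving autocorrelation.
    """
    rng = substream(seed, "calibration")
    contrast, template, gm = synthetic._grf(centroids, smoothness_mm, rng, 3)
    rho = cl.partial_spearman(contrast, template, gm)
    surr = cl.generate_surrogates(template, centroids, n_surr, seed=child_seed(seed, "surr"))
    rho_s = cl._partial_spearman_many(contrast, surr.maps, gm)
    rho_s = rho_s[np.isfinite(rho_s)]
    p_surr = (1 + np.sum(np.abs(rho_s) >= abs(rho))) / (len(rho_s) + 1)
    perm = np.array([rng.permutation(template) for _ in range(n_surr)])
    rho_n = cl._partial_spearman_many(contrast, perm, gm)
    rho_n = rho_n[np.isfinite(rho_n)]
    p_naive = (1 + np.sum(np.abs(rho_n) >= abs(rho))) / (len(rho_n) + 1)
    return float(p_surr), float(p_naive)


def glm_null_replicate(
    seed: int,
    shape: tuple[int, int, int] = (6, 6, 6),
    n_subjects: int = 16,
    n_perm: int = 100,
    alpha: float = 0.05,
    smooth_vox: float = 1.0,
) -> bool:
    """One global-null permutation-GLM run; True if anything was rejected.

    Subject maps are spatially smoothed white noise; the binary group label
    carries no effect, so the family-wise rejection indicator should be 1
    with probability at most alpha.
    """
    rng = substream(seed, "glm-null")
    affine = np.eye(4)
    maps = [
        StatMap(data=ndimage.gaussian_filter(rng.standard_normal(shape), smooth_vox), affine=affine)
        for _ in range(n_subjects)
    ]
    covariates = pd.DataFrame(
        dict(
            group=["case"] * (n_subjects // 2) + ["control"] * (n_subjects - n_subjects // 2),
            age=rng.normal(16, 5, n_subjects),
            site=rng.integers(0, 2, n_subjects),
        )
    )
    design = glm.design_from_covariates(covariates, numeric_cols=("age",))
    res = glm.permutation_inference(
        maps, design, n_perm=n_perm, seed=child_seed(seed, "perm"), alpha=alpha,
        blocks=covariates["site"].to_numpy(),
    )
    return bool(res.sig_mask_pos.any() or res.sig_mask_neg.any())
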