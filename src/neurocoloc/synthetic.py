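"""Synthetic study generator with known ground truth.

Emulates the structure of a two-cohort case-control resting-state study
plus a within-subject three-condition pharmacological crossover, at desk
scale: contiguous random parcellations, spatially smooth regional template
maps (squared-exponential Gaussian random fields at region centroids),
multi-subject 4D volumes whose true local synchronization is an explicit
per-voxel mixing weight, group effects whose regional magnitude is
proportional to a chosen template (known co-localization ground truth),
and symptom scores coupled to individual co-localization strength.

Signal model: each voxel's series is ``w * s_r(t) + (1 - w) * sd * e_v(t)``
with ``s_r`` a shared low-pass-filtered regional signal and ``e_v`` i.i.d.
voxel noise.  Two same-region voxels then correlate at
``w^2 / (w^2 + (1 - w)^2 sd^2)``, so true LCOR is monotone in the mixing
weight w — the ground-truth synchronization dial.  Case subjects' w is
shifted region-wise by ``effect_size * zscore(template)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.spatial.distance import pdist, squareform

from .seeds import substream
from .types import CANONICAL_TEMPLATES, FunctionalImage, LabelAtlas, RegionVector

__all__ = [
    "SyntheticSpec",
    "TemplateMapSet",
    "Cohort",
    "DrugDataset",
    "make_atlas",
    "make_template_maps",
    "make_cohort",
    "make_drug_sessions",
    "make_clinical_scores",
]

_NEIGHBOR_SHIFTS = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


@dataclass(frozen=True)
class SyntheticSpec:
    """Study-condition parameters for the synthetic generators.

    Defaults define the desk-scale study used throughout the test suite:
    a 12x12x12 grid of 3 mm voxels, 40 contiguous regions, 20 subjects per
    group, 60 timepoints, 2 acquisition sites, and no injected effect.
    ``effect_size`` is the shift of the synchronization weight w per unit
    of z-scored template value (negative = case reduction where the
    template is dense); ``noise_sd`` scales the unshared voxel noise.
    """

    grid_shape: tuple[int, int, int] = (12, 12, 12)
    voxel_size_mm: float = 3.0
    n_regions: int = 40
    n_per_group: int = 20
    n_timepoints: int = 60
    effect_map_name: str | None = None
    effect_size: float = 0.0
    noise_sd: float = 1.0
    n_sites: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(s < 2 for s in self.grid_shape):
            raise ValueError("grid_shape must be a triple of dimensions >= 2")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if self.n_regions < 2:
            raise ValueError("n_regions must be >= 2")
        if self.n_regions > int(np.prod(self.grid_shape)):
            raise ValueError("n_regions exceeds the number of voxels")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.n_timepoints < 20:
            raise ValueError("n_timepoints must be >= 20")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")


@dataclass
class TemplateMapSet:
    """Named regional template maps plus a gray-matter-probability vector."""

    maps: dict[str, RegionVector]
    gm: RegionVector
    smoothness_mm: float
    seed: int

    @property
    def names(self) -> list[str]:
        return list(self.maps)


@dataclass
class Cohort:
    """Multi-subject synthetic cohort with ground-truth mixing weights."""

    images: list[FunctionalImage]
    covariates: pd.DataFrame
    w_true: np.ndarray  # (n_subjects, n_regions)
    spec: SyntheticSpec


@dataclass
class DrugDataset:
    """Within-subject three-condition crossover dataset."""

    images: dict[str, list[FunctionalImage]]  # condition -> per-subject 4D
    masks: dict[str, np.ndarray]
    condition_effects: dict[str, tuple[float, float]]
    n_subjects: int


# ---------------------------------------------------------------------------
# Atlas


def _grid_affine(spec: SyntheticSpec) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] *= spec.voxel_size_mm
    aff[:3, 3] = -0.5 * (np.array(spec.grid_shape) - 1) * spec.voxel_size_mm
    return aff


def _brain_mask(shape: tuple[int, int, int]) -> np.ndarray:
    """Inscribed ellipsoid covering most of the grid."""
    idx = np.indices(shape, dtype=float)
    center = (np.array(shape, dtype=float) - 1) / 2
    semi = np.maximum(np.array(shape, dtype=float) / 2, 1.0)
    r2 = sum(((idx[i] - center[i]) / semi[i]) ** 2 for i in range(3))
    return r2 <= 1.0


def make_atlas(spec: SyntheticSpec) -> LabelAtlas:
    """Contiguous random parcellation grown from seed voxels.

    Regions grow by iterative 6-connected dilation from randomly placed
    seeds with random tie-breaking, so every region is spatially contiguous
    and the regions exactly tile the brain mask (0 = background).
    """
    rng = substream(spec.seed, "atlas")
    mask = _brain_mask(spec.grid_shape)
    voxels = np.flatnonzero(mask.ravel())
    if spec.n_regions > len(voxels):
        raise ValueError("invalid spec: n_regions exceeds mask voxel count")
    labels = np.zeros(spec.grid_shape, dtype=np.int32)
    seed_flat = rng.choice(voxels, size=spec.n_regions, replace=False)
    labels.ravel()[seed_flat] = np.arange(1, spec.n_regions + 1)

    while True:
        unassigned = mask & (labels == 0)
        if not unassigned.any():
            break
        cand = np.zeros((len(_NEIGHBOR_SHIFTS), *spec.grid_shape), dtype=np.int32)
        for k, (dx, dy, dz) in enumerate(_NEIGHBOR_SHIFTS):
            shifted = np.zeros_like(labels)
            src = [slice(None)] * 3
            dst = [slice(None)] * 3
            for ax, d in enumerate((dx, dy, dz)):
                if d == 1:
                    src[ax], dst[ax] = slice(0, -1), slice(1, None)
                elif d == -1:
                    src[ax], dst[ax] = slice(1, None), slice(0, -1)
            shifted[tuple(dst)] = labels[tuple(src)]
            cand[k] = shifted
        has_lab = cand > 0
        growable = unassigned & has_lab.any(axis=0)
        if not growable.any():
            # disconnected mask pocket: attach to nearest seed by flat index
            rem = np.argwhere(mask & (labels == 0))
            seeds = np.argwhere(labels > 0)
            d2 = ((rem[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
            labels[tuple(rem.T)] = labels[tuple(seeds[d2.argmin(axis=1)].T)]
            break
        # random tie-break among labelled neighbours
        priority = rng.random(cand.shape)
        priority[~has_lab] = -1.0
        choice = np.take_along_axis(cand, priority.argmax(axis=0)[None], axis=0)[0]
        labels[growable] = choice[growable]

    aff = _grid_affine(spec)
    rows = []
    for rid in range(1, spec.n_regions + 1):
        vox = np.argwhere(labels == rid)
        cen = aff[:3, :3] @ vox.mean(axis=0) + aff[:3, 3]
        rows.append(dict(id=rid, name=f"region_{rid:03d}", x=cen[0], y=cen[1], z=cen[2]))
    return LabelAtlas(labels=labels, affine=aff, regions=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Template maps


def _grf(centroids: np.ndarray, length_scale_mm: float, rng: np.random.Generator, n_draws: int) -> np.ndarray:
    """Squared-exponential Gaussian random field draws at region centroids."""
    d = squareform(pdist(centroids))
    K = np.exp(-(d**2) / (2.0 * max(length_scale_mm, 1e-6) ** 2))
    L = np.linalg.cholesky(K + 1e-8 * np.eye(len(centroids)))
    return (L @ rng.standard_normal((len(centroids), n_draws))).T  # (n_draws, R)


def _minmax(v: np.ndarray, lo: float, hi: float) -> np.ndarray:
    span = v.max() - v.min()
    if span == 0:
        return np.full_like(v, (lo + hi) / 2)
    return lo + (hi - lo) * (v - v.min()) / span


def make_template_maps(
    atlas: LabelAtlas, n_maps: int, smoothness_mm: float = 10.0, seed: int = 0
) -> TemplateMapSet:
    """Spatially smooth regional template maps rescaled to [0, 100].

    Each map is an independent squared-exponential GRF sampled at the
    atlas region centroids (length scale ``smoothness_mm``) and min-max
    rescaled to [0, 100]; an extra smooth gray-matter-probability vector in
    [0, 1] is generated alongside.  With ``n_maps = 16`` the maps carry the
    canonical receptor/transporter names.
    """
    if n_maps < 1:
        raise ValueError("n_maps must be >= 1")
    rng = substream(seed, "templates")
    draws = _grf(atlas.centroids_mm, smoothness_mm, rng, n_maps + 1)
    if n_maps == len(CANONICAL_TEMPLATES):
        names = list(CANONICAL_TEMPLATES)
    else:
        names = [f"template_{i:02d}" for i in range(1, n_maps + 1)]
    ids = atlas.region_ids
    maps = {
        name: RegionVector(values=_minmax(draws[i], 0.0, 100.0), region_ids=ids, name=name)
        for i, name in enumerate(names)
    }
    gm = RegionVector(values=_minmax(draws[n_maps], 0.2, 0.95), region_ids=ids, name="gm_probability")
    return TemplateMapSet(maps=maps, gm=gm, smoothness_mm=smoothness_mm, seed=seed)


# ---------------------------------------------------------------------------
# Cohorts


def _subject_volume(
    w_vox: np.ndarray,
    region_of_voxel: np.ndarray,
    n_regions: int,
    spec: SyntheticSpec,
    rng: np.random.Generator,
    mask_flat: np.ndarray,
) -> np.ndarray:
    """One 4D volume from per-voxel mixing weights (flat in-mask arrays)."""
    t = spec.n_timepoints
    s = gaussian_filter1d(rng.standard_normal((n_regions, t)), sigma=2.0, axis=1, mode="wrap")
    s = (s - s.mean(axis=1, keepdims=True)) / s.std(axis=1, keepdims=True)
    eps = rng.standard_normal((len(region_of_voxel), t))
    series = w_vox[:, None] * s[region_of_voxel] + (1.0 - w_vox[:, None]) * spec.noise_sd * eps
    vol = np.zeros((*spec.grid_shape, t))
    vol.reshape(-1, t)[mask_flat] = series
    return vol


def _normalized_template(templates: TemplateMapSet, name: str) -> np.ndarray:
    v = templates.maps[name].values
    return (v - v.mean()) / v.std()


def make_cohort(spec: SyntheticSpec, atlas: LabelAtlas, templates: TemplateMapSet) -> Cohort:
    """Case-control cohort with a template-shaped group effect on w.

    Controls share a smooth regional baseline w around 0.5; case subjects'
    w is shifted by ``effect_size * zscore(template)`` region-wise.  Site
    membership adds a small zero-mean region-level offset to w, emulating
    scanner effects that a site fixed effect removes.  Covariates (age,
    sex, FIQ, motion, site) are drawn from documented distributions.
    """
    if spec.effect_map_name is not None and spec.effect_map_name not in templates.maps:
        raise ValueError(f"effect_map_name {spec.effect_map_name!r} not in templates")
    rng_base = substream(spec.seed, "cohort-baseline")
    rng_cov = substream(spec.seed, "cohort-covariates")

    mask = atlas.mask
    mask_flat = np.flatnonzero(mask.ravel())
    region_of_voxel = atlas.labels.ravel()[mask_flat] - 1
    R = atlas.n_regions

    baseline_w = 0.5 + 0.08 * _grf(atlas.centroids_mm, 12.0, rng_base, 1)[0]
    site_offsets = 0.03 * rng_base.standard_normal((spec.n_sites, R))
    shift = np.zeros(R)
    if spec.effect_map_name is not None and spec.effect_size != 0.0:
        shift = spec.effect_size * _normalized_template(templates, spec.effect_map_name)

    n_total = 2 * spec.n_per_group
    groups = ["control"] * spec.n_per_group + ["case"] * spec.n_per_group
    sites = rng_cov.integers(0, spec.n_sites, size=n_total)
    age = np.exp(rng_cov.normal(np.log(16.0), 0.35, size=n_total))
    sex = np.array(
        [rng_cov.random() < (0.15 if g == "case" else 0.25) for g in groups], dtype=float
    )
    fiq = rng_cov.normal(108.0, 15.0, size=n_total)
    motion_t = np.abs(rng_cov.normal(0.9, 0.6, size=n_total))
    motion_r = np.abs(rng_cov.normal(0.9, 0.6, size=n_total))

    images: list[FunctionalImage] = []
    w_true = np.empty((n_total, R))
    aff = atlas.affine
    for i, g in enumerate(groups):
        rng_s = substream(spec.seed, f"cohort-subject-{i}")
        w = baseline_w + site_offsets[sites[i]]
        if g == "case":
            w = w + shift
        w = np.clip(w, 0.02, 0.98)
        w_true[i] = w
        vol = _subject_volume(w[region_of_voxel], region_of_voxel, R, spec, rng_s, mask_flat)
        images.append(FunctionalImage(data=vol, affine=aff, tr_seconds=2.0))

    covariates = pd.DataFrame(
        dict(
            subject_id=[f"sub-{i + 1:03d}" for i in range(n_total)],
            group=groups,
            age=age,
            sex=sex,
            fiq=fiq,
            motion_translation=motion_t,
            motion_rotation=motion_r,
            site=sites,
        )
    )
    return Cohort(images=images, covariates=covariates, w_true=w_true, spec=spec)


# ---------------------------------------------------------------------------
# Drug sessions


def make_drug_sessions(
    n_subjects: int,
    atlas: LabelAtlas,
    masks: dict[str, np.ndarray],
    condition_effects: dict[str, tuple[float, float]],
    spec: SyntheticSpec,
) -> DrugDataset:
    """Three-condition (two drugs + placebo) within-subject crossover.

    Each subject owns a baseline synchronization field shared across the
    three sessions; condition c shifts w inside the two masks by
    ``condition_effects[c] = (shift in first mask, shift in second mask)``.
    Sessions differ in their realization of signals and noise.
    """
    if n_subjects < 3:
        raise ValueError("need at least 3 subjects")
    if len(masks) != 2:
        raise ValueError("exactly two masks required")
    mask_names = list(masks)
    m1, m2 = (np.asarray(masks[k], dtype=bool) for k in mask_names)
    if (m1 & m2).any():
        raise ValueError("masks overlap")

    mask = atlas.mask
    mask_flat = np.flatnonzero(mask.ravel())
    region_of_voxel = atlas.labels.ravel()[mask_flat] - 1
    R = atlas.n_regions
    rng_base = substream(spec.seed, "drug-baseline")
    baseline_w = 0.5 + 0.08 * _grf(atlas.centroids_mm, 12.0, rng_base, 1)[0]

    m1_flat = m1.ravel()[mask_flat]
    m2_flat = m2.ravel()[mask_flat]

    conditions = list(condition_effects) + ["placebo"]
    images: dict[str, list[FunctionalImage]] = {c: [] for c in conditions}
    for i in range(n_subjects):
        rng_subj = substream(spec.seed, f"drug-subject-{i}")
        w_subj = np.clip(baseline_w + 0.05 * rng_subj.standard_normal(R), 0.05, 0.95)
        for c in conditions:
            w_vox = w_subj[region_of_voxel].copy()
            if c != "placebo":
                e1, e2 = condition_effects[c]
                w_vox[m1_flat] += e1
                w_vox[m2_flat] += e2
            w_vox = np.clip(w_vox, 0.02, 0.98)
            rng_sess = substream(spec.seed, f"drug-session-{i}-{c}")
            vol = _subject_volume(w_vox, region_of_voxel, R, spec, rng_sess, mask_flat)
            images[c].append(FunctionalImage(data=vol, affine=atlas.affine, tr_seconds=2.0))
    return DrugDataset(
        images=images,
        masks={k: m for k, m in zip(mask_names, (m1, m2))},
        condition_effects=dict(condition_effects),
        n_subjects=n_subjects,
    )


# ---------------------------------------------------------------------------
# Clinical scores


_SCORE_SCALES = {
    "ados_total": (12.0, 4.0),
    "communication": (4.0, 2.5),
    "rsi": (8.0, 3.0),
    "sbri": (2.0, 1.5),
}


def make_clinical_scores(
    subject_ids: "list[str] | Cohort",
    subject_coloc_strength: np.ndarray,
    coupling: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Symptom scores coupled to individual co-localization strength.

    Each score is ``coupling * zscore(strength) + sqrt(1 - coupling^2) * noise``
    affinely mapped to a plausible range (total and three subdomain scores);
    ``coupling = 0`` gives scores independent of strength.
    """
    if not -1.0 <= coupling <= 1.0:
        raise ValueError("coupling must lie in [-1, 1]")
    if isinstance(subject_ids, Cohort):
        cov = subject_ids.covariates
        subject_ids = cov.loc[cov["group"] == "case", "subject_id"].tolist()
    strength = np.asarray(subject_coloc_strength, dtype=float)
    if len(strength) != len(subject_ids):
        raise ValueError("one strength value per case subject required")
    rng = substream(seed, "clinical-scores")
    sd = strength.std()
    x = (strength - strength.mean()) / sd if sd > 0 else np.zeros_like(strength)
    out = {"subject_id": list(subject_ids)}
    for name, (mu, scale) in _SCORE_SCALES.items():
        raw = coupling * x + np.sqrt(1.0 - coupling**2) * rng.standard_normal(len(x))
        out[name] = mu + scale * raw
    return pd.DataFrame(out)
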