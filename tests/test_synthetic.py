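import numpy as np
import pytest
from scipy import ndimage, stats

from neurocoloc.lcor import LcorParams, compute_lcor
from neurocoloc.synthetic import (
    SyntheticSpec,
    make_atlas,
    make_clinical_scores,
    make_cohort,
    make_drug_sessions,
    make_template_maps,
)
from neurocoloc.types import CANONICAL_TEMPLATES
from neurocoloc.volume_io import parcellate

TINY = dict(grid_shape=(6, 6, 6), n_regions=8, n_per_group=8, n_timepoints=20, n_sites=1)


class TestMakeAtlas:
    def test_two_regions_tile_the_mask(self):
        atlas = make_atlas(SyntheticSpec(grid_shape=(4, 4, 4), n_regions=2, n_per_group=2, seed=1))
        labels = atlas.labels
        mask = labels > 0
        assert set(np.unique(labels[mask])) == {1, 2}
        assert mask.sum() == (labels == 1).sum() + (labels == 2).sum()

    def test_same_seed_reproduces_labels(self):
        spec = SyntheticSpec(seed=9)
        assert np.array_equal(make_atlas(spec).labels, make_atlas(spec).labels)

    def test_119_regions_nonempty_with_bruteforce_centroids(self, atlas119):
        labels = atlas119.labels
        aff = atlas119.affine
        for _, row in atlas119.regions.iterrows():
            vox = np.argwhere(labels == row["id"])
            assert len(vox) > 0
            expected = aff[:3, :3] @ vox.mean(axis=0) + aff[:3, 3]
            assert np.allclose([row["x"], row["y"], row["z"]], expected, atol=1e-9)

    def test_regions_are_contiguous(self, atlas40):
        structure = ndimage.generate_binary_structure(3, 1)
        for rid in atlas40.region_ids:
            _, n = ndimage.label(atlas40.labels == rid, structure=structure)
            assert n == 1

    def test_too_many_regions_rejected(self):
        with pytest.raises(ValueError):
            SyntheticSpec(grid_shape=(2, 2, 2), n_regions=100)


class TestMakeTemplateMaps:
    def test_sixteen_canonical_maps_in_range(self, atlas40, templates16):
        assert tuple(templates16.maps) == CANONICAL_TEMPLATES
        for vec in templates16.maps.values():
            assert len(vec) == atlas40.n_regions
            assert vec.values.min() == pytest.approx(0.0)
            assert vec.values.max() == pytest.approx(100.0)
        assert templates16.gm.values.min() >= 0.0 and templates16.gm.values.max() <= 1.0

    def test_zero_smoothness_limit_is_spatially_uncorrelated(self, atlas40, rng):
        # Moran-type lag-1 neighbour correlation across 150 seeds, compared
        # with a Monte-Carlo iid oracle (which carries a small -1/(R-1) bias)
        cent = atlas40.centroids_mm
        d = np.linalg.norm(cent[:, None] - cent[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        neigh = d.argmin(axis=1)
        rs = []
        for seed in range(150):
            tset = make_template_maps(atlas40, 1, smoothness_mm=1e-6, seed=seed)
            v = tset.maps["template_01"].values
            rs.append(np.corrcoef(v, v[neigh])[0, 1])
        iid = [np.corrcoef(x, x[neigh])[0, 1] for x in rng.standard_normal((2000, len(cent)))]
        assert abs(np.mean(rs) - np.mean(iid)) < 0.05

    def test_independent_seeds_uncorrelated(self, atlas40):
        rhos = []
        for seed in range(200):
            a = make_template_maps(atlas40, 1, seed=2 * seed).maps["template_01"].values
            b = make_template_maps(atlas40, 1, seed=2 * seed + 1).maps["template_01"].values
            rhos.append(stats.spearmanr(a, b).statistic)
        assert abs(np.mean(rhos)) < 0.05


class TestMakeCohort:
    def test_fixed_seed_bit_identical(self, templates16):
        spec = SyntheticSpec(**TINY, seed=4)
        atlas = make_atlas(spec)
        tset = make_template_maps(atlas, 4, seed=4)
        a = make_cohort(spec, atlas, tset)
        b = make_cohort(spec, atlas, tset)
        for ia, ib in zip(a.images, b.images):
            assert np.array_equal(ia.data, ib.data)
        assert a.covariates.equals(b.covariates)

    def test_null_effect_rejection_rate_at_alpha(self):
        """With no injected effect the groups are exchangeable, so a
        two-sample t on any per-subject regional summary rejects at ~alpha."""
        n_rep, alpha = 250, 0.05
        spec0 = SyntheticSpec(**TINY, seed=0)
        atlas = make_atlas(spec0)
        tset = make_template_maps(atlas, 2, seed=0)
        rejections = 0
        for rep in range(n_rep):
            spec = SyntheticSpec(**TINY, seed=1000 + rep)
            cohort = make_cohort(spec, atlas, tset)
            grp = (cohort.covariates["group"] == "case").to_numpy()
            region1 = atlas.labels == 1
            stat = np.array([img.data[region1].std(axis=0).mean() for img in cohort.images])
            p = stats.ttest_ind(stat[grp], stat[~grp]).pvalue
            rejections += p < alpha
        lo, hi = stats.binom.interval(0.95, n_rep, alpha)
        assert lo <= rejections <= hi

    def test_negative_effect_recovers_template_sign(self):
        """A negative NMDA-shaped effect must make the case-control LCOR
        difference negatively rank-correlated with the template."""
        small = dict(grid_shape=(8, 8, 8), n_regions=16, n_per_group=10,
                     n_timepoints=40, n_sites=1)
        spec0 = SyntheticSpec(**small, seed=0)
        atlas = make_atlas(spec0)
        tset = make_template_maps(atlas, 16, seed=0)
        tmpl = tset.maps["NMDA"].values
        params = LcorParams(mask=atlas.mask, smooth_fwhm_mm=0.0)
        hits = 0
        n_rep = 100
        for rep in range(n_rep):
            spec = SyntheticSpec(**small, seed=500 + rep,
                                 effect_map_name="NMDA", effect_size=-0.35)
            cohort = make_cohort(spec, atlas, tset)
            grp = (cohort.covariates["group"] == "case").to_numpy()
            regions = np.stack([parcellate(compute_lcor(img, params), atlas).values
                                for img in cohort.images])
            diff = regions[grp].mean(axis=0) - regions[~grp].mean(axis=0)
            hits += stats.spearmanr(diff, tmpl).statistic < 0
        assert hits >= 0.9 * n_rep

    def test_lcor_monotone_in_mixing_weight(self):
        """Holding geometry fixed, mean LCOR increases with the mixing
        weight w: subjects with spatially constant w spanning [0.15, 0.85]
        must order exactly by their mean LCOR at t=200."""
        from neurocoloc.synthetic import _subject_volume
        from neurocoloc.types import FunctionalImage

        spec = SyntheticSpec(grid_shape=(8, 8, 8), n_regions=4, n_per_group=2,
                             n_timepoints=200, n_sites=1, seed=12)
        atlas = make_atlas(spec)
        mask_flat = np.flatnonzero(atlas.mask.ravel())
        region_of_voxel = atlas.labels.ravel()[mask_flat] - 1
        params = LcorParams(mask=atlas.mask, smooth_fwhm_mm=0.0)
        ws = np.linspace(0.15, 0.85, 20)
        means = []
        for i, w in enumerate(ws):
            rng_s = np.random.default_rng(100 + i)
            vol = _subject_volume(np.full(len(region_of_voxel), w), region_of_voxel,
                                  atlas.n_regions, spec, rng_s, mask_flat)
            img = FunctionalImage(data=vol, affine=atlas.affine)
            means.append(np.nanmean(compute_lcor(img, params).data))
        rho = stats.spearmanr(ws, means).statistic
        assert rho > 0.95


class TestMakeDrugSessions:
    @staticmethod
    def _setup(seed):
        spec = SyntheticSpec(grid_shape=(6, 6, 6), n_regions=8, n_per_group=2,
                             n_timepoints=30, n_sites=1, seed=seed)
        atlas = make_atlas(spec)
        m1 = atlas.labels <= 3
        m1 &= atlas.labels > 0
        m2 = atlas.labels >= 6
        return spec, atlas, {"decrease": m1, "increase": m2}

    def _delta(self, drug, masks, atlas, which="decrease"):
        # local kernel so mask-mean LCOR tracks the within-region weight shift
        params = LcorParams(kernel_fwhm_mm=4.0, mask=atlas.mask, smooth_fwhm_mm=0.0)
        means = {}
        for cond, imgs in drug.images.items():
            means[cond] = np.array([
                np.nanmean(compute_lcor(img, params).data[masks[which]]) for img in imgs
            ])
        return means

    def test_null_condition_effects_delta_near_zero(self):
        deltas = []
        for rep in range(30):
            spec, atlas, masks = self._setup(rep)
            drug = make_drug_sessions(6, atlas, masks, {"ketamine": (0.0, 0.0)}, spec)
            m = self._delta(drug, masks, atlas)
            deltas.append((m["ketamine"] - m["placebo"]).mean())
        deltas = np.array(deltas)
        assert abs(deltas.mean()) < 3 * deltas.std() / np.sqrt(len(deltas))

    def test_power_for_ketamine_like_effect(self):
        """One-sided t on delta-scores at a -0.15 synchronization shift in the
        decrease mask should be significant in >= 80% of replicates."""
        hits, n_rep = 0, 100
        for rep in range(n_rep):
            spec, atlas, masks = self._setup(10_000 + rep)
            drug = make_drug_sessions(6, atlas, masks, {"ketamine": (-0.15, 0.0)}, spec)
            m = self._delta(drug, masks, atlas)
            from neurocoloc.roi import delta_test
            res = delta_test(m["ketamine"], m["placebo"], direction="less")
            hits += res.p_one_sided < 0.05
        assert hits >= 0.8 * n_rep

    def test_overlapping_masks_rejected(self):
        spec, atlas, masks = self._setup(0)
        bad = {"a": masks["decrease"], "b": masks["decrease"]}
        with pytest.raises(ValueError, match="overlap"):
            make_drug_sessions(4, atlas, bad, {"ketamine": (0.0, 0.0)}, spec)


class TestMakeClinicalScores:
    def test_zero_coupling_independent(self, rng):
        rs = []
        for rep in range(200):
            strength = np.random.default_rng(rep).standard_normal(40)
            scores = make_clinical_scores([f"s{i}" for i in range(40)], strength, 0.0, seed=rep)
            rs.append(stats.pearsonr(scores["ados_total"], strength).statistic)
        assert abs(np.mean(rs)) < 0.05

    def test_strong_coupling_recovered(self, rng):
        strength = rng.standard_normal(200)
        scores = make_clinical_scores([f"s{i}" for i in range(200)], strength, 0.9, seed=1)
        r = stats.pearsonr(scores["ados_total"], strength).statistic
        assert abs(r - 0.9) < 0.1

    def test_fixed_seed_identical(self, rng):
        strength = rng.standard_normal(10)
        ids = [f"s{i}" for i in range(10)]
        assert make_clinical_scores(ids, strength, 0.5, seed=3).equals(
            make_clinical_scores(ids, strength, 0.5, seed=3)
        )

    def test_mismatched_strength_length_rejected(self):
        with pytest.raises(ValueError):
            make_clinical_scores(["a", "b"], np.zeros(3), 0.5)
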