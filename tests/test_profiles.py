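import numpy as np
import pytest

from neurocoloc.coloc import ColocResult
from neurocoloc.profiles import (
    NeurochemProfile,
    SubjectColoc,
    build_profile,
    profile_correlation,
    subject_coloc,
    subject_zmaps,
    symptom_correlation,
)
from neurocoloc.types import CANONICAL_TEMPLATES


def _result(rho, name):
    return ColocResult(
        rho=rho, p_perm=0.5, fisher_z=float(np.arctanh(np.clip(rho, -1 + 1e-15, 1 - 1e-15))),
        ci95=(-1.0, 1.0), df_report=38, n_regions_used=40, template_name=name,
    )


class TestBuildProfile:
    def test_zero_rhos_give_zero_profile(self):
        prof = build_profile([_result(0.0, n) for n in CANONICAL_TEMPLATES])
        assert np.all(prof.z == 0)

    def test_fisher_z_of_half(self):
        results = [_result(0.5 if n == "NMDA" else 0.0, n) for n in CANONICAL_TEMPLATES]
        prof = build_profile(results)
        idx = CANONICAL_TEMPLATES.index("NMDA")
        assert prof.z[idx] == pytest.approx(np.arctanh(0.5), abs=1e-12)
        assert prof.z[idx] == pytest.approx(0.5493, abs=1e-4)

    def test_input_order_irrelevant(self, rng):
        results = [_result(r, n) for r, n in zip(rng.uniform(-0.8, 0.8, 16), CANONICAL_TEMPLATES)]
        a = build_profile(results)
        b = build_profile(list(reversed(results)))
        assert np.array_equal(a.z, b.z)

    def test_missing_template_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            build_profile([_result(0.1, n) for n in CANONICAL_TEMPLATES[:-1]])


class TestProfileCorrelation:
    def test_self_correlation_is_one_with_df_14(self, rng):
        prof = NeurochemProfile(z=rng.standard_normal(16), template_names=CANONICAL_TEMPLATES)
        r, p, ci, df = profile_correlation(prof, prof)
        assert r == pytest.approx(1.0)
        assert df == 14

    def test_matches_covariance_formula_oracle(self, rng):
        za, zb = rng.standard_normal((2, 16))
        a = NeurochemProfile(z=za, template_names=CANONICAL_TEMPLATES)
        b = NeurochemProfile(z=zb, template_names=CANONICAL_TEMPLATES)
        r, *_ = profile_correlation(a, b)
        xa, xb = za - za.mean(), zb - zb.mean()
        expected = (xa @ xb) / np.sqrt((xa @ xa) * (xb @ xb))
        assert r == pytest.approx(expected, abs=1e-12)

    def test_constant_profile_rejected(self):
        a = NeurochemProfile(z=np.zeros(16), template_names=CANONICAL_TEMPLATES)
        b = NeurochemProfile(z=np.arange(16.0), template_names=CANONICAL_TEMPLATES)
        with pytest.raises(ValueError, match="zero-variance"):
            profile_correlation(a, b)


class TestSubjectZmaps:
    def test_case_at_control_mean_gives_zero(self, rng):
        controls = rng.standard_normal((10, 8))
        case = controls.mean(axis=0, keepdims=True)
        assert np.allclose(subject_zmaps(case, controls), 0.0, atol=1e-12)

    def test_hand_computation(self):
        controls = np.array([[0.0], [1.0], [2.0]])
        z = subject_zmaps(np.array([[3.0]]), controls)
        assert z[0, 0] == pytest.approx(2.0)  # (3 - 1) / 1

    def test_control_self_standardization(self, rng):
        controls = rng.standard_normal((200, 50))
        z = subject_zmaps(controls, controls)
        assert abs(z.mean()) < 0.02
        assert abs(z.std() - 1.0) < 0.02

    def test_zero_control_sd_region_missing(self, rng):
        controls = rng.standard_normal((5, 3))
        controls[:, 1] = 7.0
        z = subject_zmaps(rng.standard_normal((2, 3)), controls)
        assert np.isnan(z[:, 1]).all() and np.isfinite(z[:, [0, 2]]).all()


class TestSubjectColoc:
    def test_saturation_clipped_finite(self):
        v = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0])
        gm = np.full(6, 0.5)
        z = subject_coloc(v, v, gm)
        assert np.isfinite(z) and z > 15  # atanh(1 - 1e-15)

    def test_sign_flip_negates(self, rng):
        zmap = rng.standard_normal(20)
        tmpl = rng.standard_normal(20)
        gm = rng.standard_normal(20)
        assert subject_coloc(zmap, tmpl, gm) == pytest.approx(-subject_coloc(-zmap, tmpl, gm), abs=1e-10)

    def test_null_zmap_near_zero_on_average(self, rng):
        tmpl = rng.standard_normal(30)
        gm = rng.standard_normal(30)
        zs = [subject_coloc(rng.standard_normal(30), tmpl, gm) for _ in range(200)]
        assert abs(np.mean(zs)) < 0.05


class TestSymptomCorrelation:
    @staticmethod
    def _subjects(strength, scores):
        return [
            SubjectColoc(subject_id=str(i), fisher_z_by_template={"NMDA": s}, scores={"ados_total": a})
            for i, (s, a) in enumerate(zip(strength, scores))
        ]

    def test_df_convention_238_subjects(self, rng):
        strength = rng.standard_normal(238)
        scores = strength + rng.standard_normal(238)
        r, p, ci, df = symptom_correlation(self._subjects(strength, scores), "NMDA", "ados_total")
        assert df == 236

    def test_recovers_strong_coupling(self, rng):
        n, target = 200, 0.9
        x = rng.standard_normal(n)
        y = target * x + np.sqrt(1 - target**2) * rng.standard_normal(n)
        r, *_ = symptom_correlation(self._subjects(x, y), "NMDA", "ados_total")
        assert abs(r - target) < 0.1

    def test_missing_scores_dropped(self, rng):
        subs = self._subjects(rng.standard_normal(10), rng.standard_normal(10))
        subs[0].scores["ados_total"] = np.nan
        r, p, ci, df = symptom_correlation(subs, "NMDA", "ados_total")
        assert df == 7  # 9 complete - 2

    def test_constant_score_rejected(self):
        subs = self._subjects(np.arange(6.0), np.full(6, 3.0))
        with pytest.raises(ValueError, match="zero-variance"):
            symptom_correlation(subs, "NMDA", "ados_total")


class TestPipelineConsistency:
    def test_mean_subject_zmap_tracks_group_tmap(self):
        """The mean of case-subject z-maps and the covariate-adjusted group
        t-map are two routes to the same regional effect pattern and must
        rank-correlate strongly at n=50 per group."""
        from scipy import stats as sps

        from neurocoloc.experiments import group_contrast_vector, lcor_maps_for_cohort
        from neurocoloc.lcor import LcorParams
        from neurocoloc.synthetic import SyntheticSpec, make_atlas, make_cohort, make_template_maps
        from neurocoloc.volume_io import parcellate

        spec = SyntheticSpec(grid_shape=(8, 8, 8), n_regions=20, n_per_group=50,
                             n_timepoints=40, n_sites=1, seed=31,
                             effect_map_name="NMDA", effect_size=-0.3)
        atlas = make_atlas(spec)
        tset = make_template_maps(atlas, 16, seed=31)
        cohort = make_cohort(spec, atlas, tset)
        params = LcorParams(mask=atlas.mask, smooth_fwhm_mm=0.0)
        maps = lcor_maps_for_cohort(cohort, atlas, params)
        region_mat = np.stack([parcellate(m, atlas).values for m in maps])
        is_case = (cohort.covariates["group"] == "case").to_numpy()
        zmean = subject_zmaps(region_mat[is_case], region_mat[~is_case]).mean(axis=0)
        tvec = group_contrast_vector(cohort, atlas, params)
        rho = sps.spearmanr(zmean, tvec.values).statistic
        assert rho > 0.8

    def test_case_and_drug_profiles_correlate_when_effects_share_shape(self):
        """When the drug shifts synchronization in the regions carrying the
        case-group effect, the two neurochemical profiles must correlate
        positively in >= 90% of replicates."""
        from scipy import stats as sps

        from neurocoloc.coloc import generate_surrogates, coloc_test
        from neurocoloc.experiments import group_contrast_vector, lcor_maps_for_cohort
        from neurocoloc.glm import DesignMatrix, fit_voxelwise_glm
        from neurocoloc.lcor import LcorParams
        from neurocoloc.synthetic import (
            SyntheticSpec, make_atlas, make_cohort, make_drug_sessions, make_template_maps,
        )
        from neurocoloc.types import StatMap
        from neurocoloc.volume_io import parcellate

        base = dict(grid_shape=(10, 10, 10), n_regions=20, n_per_group=10,
                    n_timepoints=40, n_sites=1)
        hits, n_rep = 0, 10
        for rep in range(n_rep):
            spec = SyntheticSpec(**base, seed=600 + rep,
                                 effect_map_name="NMDA", effect_size=-0.3)
            atlas = make_atlas(spec)
            tset = make_template_maps(atlas, 16, seed=600 + rep)
            cohort = make_cohort(spec, atlas, tset)
            contrast_case = group_contrast_vector(cohort, atlas)
            tmpl = tset.maps["NMDA"].values
            eff = -0.3 * (tmpl - tmpl.mean()) / tmpl.std()
            order = np.argsort(eff)
            dec = np.isin(atlas.labels, atlas.region_ids[order[:5]])
            inc = np.isin(atlas.labels, atlas.region_ids[order[-5:]])
            drug = make_drug_sessions(6, atlas, {"dec": dec, "inc": inc},
                                      {"ketamine": (-0.25, 0.0)}, spec)
            from neurocoloc.lcor import ConfoundSet, compute_lcor, gaussian_smooth, regress_confounds

            params = LcorParams(mask=atlas.mask)
            lcor_by_cond = {}
            for c, imgs in drug.images.items():
                maps_c = []
                for img in imgs:
                    resid = regress_confounds(img, ConfoundSet.empty(img.n_timepoints))
                    maps_c.append(gaussian_smooth(compute_lcor(resid, params), params.smooth_fwhm_mm))
                lcor_by_cond[c] = maps_c
            diffs = [StatMap(data=a.data - b.data, affine=a.affine)
                     for a, b in zip(lcor_by_cond["ketamine"], lcor_by_cond["placebo"])]
            design = DesignMatrix(matrix=np.ones((len(diffs), 1)), names=["i"],
                                  contrast=np.array([1.0]))
            contrast_drug = parcellate(fit_voxelwise_glm(diffs, design), atlas)
            z_case, z_drug = [], []
            for ti, (name, t) in enumerate(tset.maps.items()):
                surr = generate_surrogates(t, atlas.centroids_mm, 100, seed=rep * 37 + ti)
                z_case.append(coloc_test(contrast_case, t, tset.gm, surr).fisher_z)
                z_drug.append(coloc_test(contrast_drug, t, tset.gm, surr).fisher_z)
            hits += sps.pearsonr(z_case, z_drug).statistic > 0
        assert hits >= 0.9 * n_rep
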