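"""Study orchestration: exploration cohort -> replication cohort -> meta
combination -> pharmacological comparison -> individual symptom analysis.

``synthesize_study`` materializes a complete synthetic study on disk
(NIfTI volumes, TSV tables, YAML provenance echo); ``run_study`` executes
the full analysis from a :class:`StudyConfig` and writes versioned TSV/JSON
outputs per stage.  All randomness flows from one root seed through named
substreams, so two runs with the same config are byte-identical on every
TSV/JSON output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coloc as cl
from . import glm, lcor, profiles, roi, synthetic, volume_io
from .seeds import child_seed
from .types import RegionVector, StatMap

__all__ = [
    "StudyConfig",
    "exclude_by_motion",
    "synthesize_study",
    "run_study",
]

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"


@dataclass
class RobustnessFlags:
    drop_first_4_volumes: bool = False
    no_smoothing: bool = False
    no_gm_regression: bool = False
    alternate_atlas: bool = False


@dataclass
class StudyConfig:
    """Paths and parameters for one full study run."""

    data_dir: str
    out_dir: str
    alpha: float = 0.05
    n_perm: int = 1000
    n_surr: int = 1000
    seed: int = 0
    kernel_fwhm_mm: float = 25.0
    smooth_fwhm_mm: float = 6.0
    motion_translation_mm: float = 3.0
    motion_rotation_deg: float = 3.0
    robustness: RobustnessFlags = field(default_factory=RobustnessFlags)

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        flags = RobustnessFlags(**raw.pop("robustness", {}))
        return cls(robustness=flags, **raw)


def exclude_by_motion(
    covariates: pd.DataFrame,
    translation_mm: float = 3.0,
    rotation_deg: float = 3.0,
) -> pd.DataFrame:
    """Drop subjects whose head motion strictly exceeds either threshold.

    A subject at exactly the threshold is kept (strict-inequality reading
    of 'translation > 3 mm or rotation > 3 degrees').
    """
    for col in ("motion_translation", "motion_rotation"):
        if col not in covariates:
            raise ValueError(f"missing motion column {col!r}")
    keep = ~(
        (covariates["motion_translation"] > translation_mm)
        | (covariates["motion_rotation"] > rotation_deg)
    )
    kept = covariates[keep].reset_index(drop=True)
    logger.info("motion exclusion: kept %d of %d subjects", len(kept), len(covariates))
    if len(kept) == 0:
        raise ValueError("no subjects left after motion exclusion")
    return kept


# ---------------------------------------------------------------------------
# Synthetic study materialization


DEFAULT_SYNTH = dict(
    grid_shape=[12, 12, 12],
    voxel_size_mm=3.0,
    n_regions=40,
    n_per_group=20,
    n_timepoints=60,
    n_templates=16,
    template_smoothness_mm=10.0,
    effect_map_name="NMDA",
    effect_size=-0.25,
    noise_sd=1.0,
    n_sites=2,
    n_drug_subjects=12,
    drug_effects={"ketamine": [-0.2, 0.0], "midazolam": [0.0, 0.2]},
    score_coupling=0.3,
    seed=0,
)


def _spec_from_cfg(cfg: dict, seed: int) -> synthetic.SyntheticSpec:
    return synthetic.SyntheticSpec(
        grid_shape=tuple(cfg["grid_shape"]),
        voxel_size_mm=cfg["voxel_size_mm"],
        n_regions=cfg["n_regions"],
        n_per_group=cfg["n_per_group"],
        n_timepoints=cfg["n_timepoints"],
        effect_map_name=cfg["effect_map_name"],
        effect_size=cfg["effect_size"],
        noise_sd=cfg["noise_sd"],
        n_sites=cfg["n_sites"],
        seed=seed,
    )


def _write_templates_tsv(templates: synthetic.TemplateMapSet, path: Path) -> None:
    table = pd.DataFrame({"id": templates.gm.region_ids})
    for name, vec in templates.maps.items():
        table[name] = vec.values
    table["gm_probability"] = templates.gm.values
    table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def _read_templates_tsv(path: Path) -> tuple[dict[str, RegionVector], RegionVector]:
    table = pd.read_csv(path, sep="\t")
    ids = table["id"].to_numpy(dtype=int)
    maps = {
        c: RegionVector(values=table[c].to_numpy(float), region_ids=ids, name=c)
        for c in table.columns
        if c not in ("id", "gm_probability")
    }
    gm = RegionVector(values=table["gm_probability"].to_numpy(float), region_ids=ids, name="gm_probability")
    return maps, gm


def synthesize_study(cfg: dict | None, out_dir: str | Path) -> Path:
    """Generate a complete synthetic study (two cohorts + drug crossover).

    Writes the atlas (NIfTI + region TSV), region-level template maps
    (TSV), per-subject 4D volumes, covariate and clinical-score tables, and
    a YAML echo of the generating parameters for provenance.
    """
    cfg = {**DEFAULT_SYNTH, **(cfg or {})}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])

    spec_a = _spec_from_cfg(cfg, child_seed(seed, "cohortA"))
    atlas = synthetic.make_atlas(dataclasses.replace(spec_a, seed=child_seed(seed, "atlas")))
    templates = synthetic.make_template_maps(
        atlas, cfg["n_templates"], cfg["template_smoothness_mm"], seed=child_seed(seed, "templates")
    )
    volume_io.save_atlas(atlas, out / "atlas.nii.gz", out / "regions.tsv")
    _write_templates_tsv(templates, out / "templates.tsv")

    norm_template = None
    if cfg["effect_map_name"] is not None:
        if cfg["effect_map_name"] not in templates.maps:
            raise ValueError(
                f"effect_map_name {cfg['effect_map_name']!r} not among the "
                f"{len(templates.maps)} generated templates"
            )
        v = templates.maps[cfg["effect_map_name"]].values
        norm_template = (v - v.mean()) / v.std()

    for label in ("cohortA", "cohortB"):
        spec = _spec_from_cfg(cfg, child_seed(seed, label))
        cohort = synthetic.make_cohort(spec, atlas, templates)
        cdir = out / label
        cdir.mkdir(exist_ok=True)
        for sid, img in zip(cohort.covariates["subject_id"], cohort.images):
            volume_io.save_functional(img, cdir / f"{sid}_bold.nii.gz")
        cohort.covariates.to_csv(cdir / "covariates.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
        # per-subject true effect loading: projection of w onto the template shape
        case = cohort.covariates["group"] == "case"
        w_case = cohort.w_true[case.to_numpy()]
        if norm_template is not None:
            strength = w_case @ norm_template / len(norm_template)
        else:
            strength = np.zeros(case.sum())
        scores = synthetic.make_clinical_scores(
            cohort.covariates.loc[case, "subject_id"].tolist(),
            strength,
            coupling=float(cfg["score_coupling"]),
            seed=child_seed(seed, f"{label}-scores"),
        )
        scores.to_csv(cdir / "clinical_scores.tsv", sep="\t", index=False, float_format=FLOAT_FMT)

    # drug crossover: masks from the template's extreme regions
    ddir = out / "drug"
    ddir.mkdir(exist_ok=True)
    # regions ordered by the injected case-group effect: the "decrease" mask
    # covers regions where case LCOR is shifted down the most
    if norm_template is not None:
        ref = float(cfg["effect_size"]) * norm_template
    else:
        ref = np.linspace(-1, 1, atlas.n_regions)
    order = np.argsort(ref)
    ids = atlas.region_ids
    low_ids = ids[order[: max(2, atlas.n_regions // 5)]]
    high_ids = ids[order[-max(2, atlas.n_regions // 5):]]
    mask_dec = np.isin(atlas.labels, low_ids)
    mask_inc = np.isin(atlas.labels, high_ids)
    spec_d = _spec_from_cfg(cfg, child_seed(seed, "drug"))
    drug = synthetic.make_drug_sessions(
        int(cfg["n_drug_subjects"]),
        atlas,
        {"decrease": mask_dec, "increase": mask_inc},
        {k: tuple(v) for k, v in cfg["drug_effects"].items()},
        spec_d,
    )
    for cond, imgs in drug.images.items():
        for i, img in enumerate(imgs):
            volume_io.save_functional(img, ddir / f"sub-{i + 1:03d}_{cond}_bold.nii.gz")
    for name, m in drug.masks.items():
        volume_io.save_stat_map(StatMap(data=m.astype(float), affine=atlas.affine, label=name),
                                ddir / f"mask_{name}.nii.gz")

    with open(out / "synth_spec.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return out


# ---------------------------------------------------------------------------
# Analysis stages


def _lcor_params(config: StudyConfig, mask: np.ndarray) -> lcor.LcorParams:
    smooth = 0.0 if config.robustness.no_smoothing else config.smooth_fwhm_mm
    return lcor.LcorParams(
        kernel_fwhm_mm=config.kernel_fwhm_mm, smooth_fwhm_mm=smooth, mask=mask
    )


def _subject_lcor(img, params: lcor.LcorParams, drop_first_4: bool = False) -> StatMap:
    data = img.data[..., 4:] if drop_first_4 else img.data
    from .types import FunctionalImage

    fi = FunctionalImage(data=data, affine=img.affine, tr_seconds=img.tr_seconds)
    fi = lcor.regress_confounds(fi, lcor.ConfoundSet.empty(fi.n_timepoints))
    m = lcor.compute_lcor(fi, params)
    if params.smooth_fwhm_mm > 0:
        m = lcor.gaussian_smooth(m, params.smooth_fwhm_mm)
    return m


def _load_cohort(cdir: Path) -> tuple[pd.DataFrame, dict[str, Path]]:
    covariates = pd.read_csv(cdir / "covariates.tsv", sep="\t")
    paths = {sid: cdir / f"{sid}_bold.nii.gz" for sid in covariates["subject_id"]}
    return covariates, paths


def coloc_all_templates(
    contrast: RegionVector,
    templates: dict[str, RegionVector],
    gm: RegionVector,
    centroids: np.ndarray,
    n_surr: int,
    seed: int,
) -> dict[str, cl.ColocResult]:
    """Co-localization of one contrast with every template map."""
    out: dict[str, cl.ColocResult] = {}
    for name, tmpl in templates.items():
        surr = cl.generate_surrogates(tmpl, centroids, n_surr, seed=child_seed(seed, f"surr-{name}"))
        out[name] = cl.coloc_test(contrast, tmpl, gm, surr)
    return out


def _coloc_table(results: dict[str, cl.ColocResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                template=name, rho=r.rho, p_perm=r.p_perm, fisher_z=r.fisher_z,
                ci_low=r.ci95[0], ci_high=r.ci95[1], df=r.df_report, n_regions=r.n_regions_used,
            )
            for name, r in results.items()
        ]
    )


def _paired_t_map(a: list[StatMap], b: list[StatMap]) -> StatMap:
    """One-sample t on per-subject difference maps (a - b)."""
    diffs = [
        StatMap(data=x.data - y.data, affine=x.affine, label="diff") for x, y in zip(a, b)
    ]
    design = glm.DesignMatrix(matrix=np.ones((len(diffs), 1)), names=["intercept"], contrast=np.array([1.0]))
    return glm.fit_voxelwise_glm(diffs, design)


def _save_tsv(table: pd.DataFrame, path: Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def run_study(config: StudyConfig) -> dict:
    """Execute the full study workflow; returns the report dictionary.

    Stages: motion exclusion -> per-subject LCOR -> cohort GLM + permutation
    inference -> co-localization (exploration, replication, Fisher+BH) ->
    cross-cohort map similarity -> drug delta-tests in cohort-A masks ->
    drug co-localization + neurochemical profile correlations -> individual
    z-maps, subject co-localization and symptom correlations.  Each stage
    writes TSV/JSON outputs under ``config.out_dir``; any failure aborts
    with the stage name (partial outputs are preserved).
    """
    data = Path(config.data_dir)
    out = Path(config.out_dir)
    stage = "setup"
    t_start = time.time()
    try:
        report: dict = {"seed": config.seed, "stages": {}}
        out.mkdir(parents=True, exist_ok=True)
        atlas = volume_io.load_atlas(data / "atlas.nii.gz", data / "regions.tsv")
        templates, gm = _read_templates_tsv(data / "templates.tsv")
        centroids = atlas.centroids_mm
        params = _lcor_params(config, atlas.mask)
        drop4 = config.robustness.drop_first_4_volumes

        # --- cohorts: LCOR, GLM, inference, parcellation -------------------
        infer: dict[str, glm.InferenceResult] = {}
        contrast_vec: dict[str, RegionVector] = {}
        lcor_by_cohort: dict[str, tuple[pd.DataFrame, list[StatMap]]] = {}
        for label in ("cohortA", "cohortB"):
            stage = f"{label}-lcor"
            (out / label).mkdir(exist_ok=True)
            covariates, paths = _load_cohort(data / label)
            covariates = exclude_by_motion(
                covariates, config.motion_translation_mm, config.motion_rotation_deg
            )
            maps = [
                _subject_lcor(volume_io.load_functional(paths[sid]), params, drop4)
                for sid in covariates["subject_id"]
            ]
            lcor_by_cohort[label] = (covariates, maps)

            stage = f"{label}-glm"
            design = glm.design_from_covariates(covariates)
            res = glm.permutation_inference(
                maps,
                design,
                n_perm=config.n_perm,
                seed=child_seed(config.seed, f"{label}-perm"),
                alpha=config.alpha,
                blocks=covariates["site"].to_numpy(),
            )
            infer[label] = res
            volume_io.save_stat_map(res.t_map, out / label / "t_map.nii.gz")
            volume_io.save_stat_map(res.tfce_map, out / label / "tfce_map.nii.gz")
            volume_io.save_stat_map(res.fwe_p_voxel, out / label / "fwe_p_voxel.nii.gz")
            volume_io.save_stat_map(res.fwe_p_tfce, out / label / "fwe_p_tfce.nii.gz")
            for nm, m in (("sig_mask_pos", res.sig_mask_pos), ("sig_mask_neg", res.sig_mask_neg)):
                volume_io.save_stat_map(
                    StatMap(data=m.astype(float), affine=atlas.affine, label=nm),
                    out / label / f"{nm}.nii.gz",
                )
            contrast_vec[label] = volume_io.parcellate(res.t_map, atlas)
            report["stages"][label] = dict(
                n_subjects=int(len(covariates)),
                n_sig_pos=int(res.sig_mask_pos.sum()),
                n_sig_neg=int(res.sig_mask_neg.sum()),
                n_permutations=res.n_permutations,
            )

        # --- co-localization: exploration / replication / meta -------------
        stage = "coloc"
        (out / "coloc").mkdir(exist_ok=True)
        results_ab: dict[str, dict[str, cl.ColocResult]] = {}
        for label in ("cohortA", "cohortB"):
            results_ab[label] = coloc_all_templates(
                contrast_vec[label], templates, gm, centroids, config.n_surr,
                seed=child_seed(config.seed, f"{label}-surr"),
            )
            _save_tsv(_coloc_table(results_ab[label]), out / "coloc" / f"{label}.tsv")
        protocol = cl.replication_protocol(results_ab["cohortA"], results_ab["cohortB"], config.alpha)
        _save_tsv(protocol, out / "coloc" / "replication.tsv")
        replicated = protocol.loc[protocol["replicated_significant"], "template"].tolist()
        report["stages"]["coloc"] = dict(replicated_significant=replicated)

        # --- cross-cohort map similarity ------------------------------------
        stage = "similarity"
        surr_b = cl.generate_surrogates(
            contrast_vec["cohortB"], centroids, config.n_surr,
            seed=child_seed(config.seed, "similarity-surr"),
        )
        sim = cl.map_similarity(contrast_vec["cohortA"], contrast_vec["cohortB"], gm, surr_b)
        report["stages"]["similarity"] = dict(rho=sim.rho, p_perm=sim.p_perm, df=sim.df_report)

        # --- drug dataset ----------------------------------------------------
        stage = "drug"
        (out / "drug").mkdir(exist_ok=True)
        drug_lcor: dict[str, list[StatMap]] = {}
        conds = ["ketamine", "midazolam", "placebo"]
        n_drug = len(list((data / "drug").glob("sub-*_placebo_bold.nii.gz")))
        for cond in conds:
            drug_lcor[cond] = [
                _subject_lcor(
                    volume_io.load_functional(data / "drug" / f"sub-{i + 1:03d}_{cond}_bold.nii.gz"),
                    params,
                    drop4,
                )
                for i in range(n_drug)
            ]
        delta_rows = []
        for mask_name, mask, direction_map in (
            ("autism_decrease", infer["cohortA"].sig_mask_neg, {"ketamine": "less", "midazolam": "less"}),
            ("autism_increase", infer["cohortA"].sig_mask_pos, {"ketamine": "greater", "midazolam": "greater"}),
        ):
            if not mask.any():
                logger.warning("empty %s mask; skipping delta tests there", mask_name)
                continue
            means = roi.extract_mask_means({c: drug_lcor[c] for c in conds}, mask)
            for drugname in ("ketamine", "midazolam"):
                dres = roi.delta_test(
                    means[drugname], means["placebo"], direction_map[drugname], mask_label=mask_name
                )
                delta_rows.append(
                    dict(
                        mask=mask_name, drug=drugname, t=dres.t, df=dres.df,
                        p_one_sided=dres.p_one_sided, cohen_d=dres.cohen_d,
                        ci_low=dres.ci_one_sided[0], ci_high=dres.ci_one_sided[1],
                        direction=dres.direction,
                    )
                )
        if delta_rows:
            _save_tsv(pd.DataFrame(delta_rows), out / "drug" / "delta_tests.tsv")
        report["stages"]["drug"] = dict(n_subjects=n_drug, n_delta_tests=len(delta_rows))

        # --- profiles --------------------------------------------------------
        stage = "profiles"
        (out / "profiles").mkdir(exist_ok=True)
        drug_results: dict[str, dict[str, cl.ColocResult]] = {}
        drug_vec: dict[str, RegionVector] = {}
        for drugname in ("ketamine", "midazolam"):
            tmap = _paired_t_map(drug_lcor[drugname], drug_lcor["placebo"])
            drug_vec[drugname] = volume_io.parcellate(tmap, atlas)
            drug_results[drugname] = coloc_all_templates(
                drug_vec[drugname], templates, gm, centroids, config.n_surr,
                seed=child_seed(config.seed, f"{drugname}-surr"),
            )
            table = _coloc_table(drug_results[drugname])
            table["p_bh"] = cl.bh_fdr(table["p_perm"].to_numpy())
            _save_tsv(table, out / "profiles" / f"coloc_{drugname}.tsv")

        order = tuple(templates)
        prof = {
            "autism_A": profiles.build_profile(results_ab["cohortA"], "autism_A", order),
            "autism_B": profiles.build_profile(results_ab["cohortB"], "autism_B", order),
            "ketamine": profiles.build_profile(drug_results["ketamine"], "ketamine", order),
            "midazolam": profiles.build_profile(drug_results["midazolam"], "midazolam", order),
        }
        prof_table = pd.DataFrame({k: p.z for k, p in prof.items()}, index=list(order))
        prof_table.insert(0, "template", prof_table.index)
        _save_tsv(prof_table.reset_index(drop=True), out / "profiles" / "profiles.tsv")
        pairs = [
            ("autism_A", "ketamine"), ("autism_B", "ketamine"),
            ("autism_A", "midazolam"), ("autism_B", "midazolam"),
            ("autism_A", "autism_B"), ("ketamine", "midazolam"),
        ]
        rows = []
        for a, b in pairs:
            r, p, ci, df = profiles.profile_correlation(prof[a], prof[b])
            rows.append(dict(profile_a=a, profile_b=b, r=r, p=p, ci_low=ci[0], ci_high=ci[1], df=df))
        _save_tsv(pd.DataFrame(rows), out / "profiles" / "profile_correlations.tsv")
        report["stages"]["profiles"] = {f"{a}_vs_{b}": rows[i]["r"] for i, (a, b) in enumerate(pairs)}

        # --- individual-level symptom analysis -------------------------------
        stage = "individual"
        (out / "individual").mkdir(exist_ok=True)
        indiv_templates = replicated if replicated else list(order)[:1]
        symptom_tables = []
        for label in ("cohortA", "cohortB"):
            covariates, maps = lcor_by_cohort[label]
            region_mat = np.stack([volume_io.parcellate(m, atlas).values for m in maps])
            is_case = (covariates["group"] == "case").to_numpy()
            zmat = profiles.subject_zmaps(region_mat[is_case], region_mat[~is_case])
            scores = pd.read_csv(data / label / "clinical_scores.tsv", sep="\t").set_index("subject_id")
            case_ids = covariates.loc[is_case, "subject_id"].tolist()
            subjects = []
            for si, sid in enumerate(case_ids):
                zmap = RegionVector(values=zmat[si], region_ids=atlas.region_ids, name=sid)
                zs = {
                    t: profiles.subject_coloc(zmap, templates[t], gm) for t in indiv_templates
                }
                sc = scores.loc[sid].to_dict() if sid in scores.index else {}
                subjects.append(profiles.SubjectColoc(subject_id=sid, fisher_z_by_template=zs, scores=sc))
            subj_table = pd.DataFrame(
                [dict(subject_id=s.subject_id, **s.fisher_z_by_template, **s.scores) for s in subjects]
            )
            _save_tsv(subj_table, out / "individual" / f"{label}_subject_coloc.tsv")
            score_names = [c for c in scores.columns]
            table = profiles.symptom_correlation_table(subjects, indiv_templates, score_names)
            table.insert(0, "cohort", label)
            symptom_tables.append(table)
        symptom = pd.concat(symptom_tables, ignore_index=True)
        _save_tsv(symptom, out / "individual" / "symptom_correlations.tsv")
        report["stages"]["individual"] = dict(
            templates=indiv_templates,
            n_tests=int(len(symptom)),
            min_p=float(symptom["p"].min()),
        )

        stage = "report"
        with open(out / "study_report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        logger.info("study complete in %.1f s", time.time() - t_start)
        return report
    except Exception as err:
        raise RuntimeError(f"study failed at stage {stage!r}: {err}") from err
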