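"""End-to-end orchestration: phantom cohorts -> preprocessing -> segmentation ->
regional quantification -> group report.

Every subject is brought onto the adult-protocol sampling grid
(0.98 x 0.98 x 3 mm), which doubles as the template grid for frequency maps
(phantoms are generated in a shared space, so the stereotaxic transform is
the identity).  Ratio-based thresholds (T1 black holes at a fraction of the
NAWM mean; the infratentorial T2 threshold) are applied to the bias-corrected
images: a relative threshold is invariant under a global intensity gain, but
not under the two-piece normalization map, so applying it before
normalization keeps it exactly protocol-relative.  The Bayesian multispectral
classifier runs on the normalized images.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io, phantom, preprocess, quantify, segment, stats
from .config import ConfigurationError, PipelineConfig
from .preprocess import GridGeometry, adult_target_geometry
from .types import SubjectScan

logger = logging.getLogger(__name__)


@dataclass
class PreprocessedSubject:
    """One subject after resampling, bias correction, registration and
    normalization, with its analytic atlas and (when synthetic) ground truth
    resampled onto the working grid."""

    scan_norm: SubjectScan       # normalized intensities, for the Bayesian step
    scan_corrected: SubjectScan  # bias-corrected raw intensities, for ratio thresholds
    atlas: phantom.RegionAtlas
    norm_maps: dict
    truth_t2: np.ndarray | None = None
    truth_t1: np.ndarray | None = None


def preprocess_subject(scan: SubjectScan, config: PipelineConfig,
                       truth: phantom.GroundTruth | None = None) -> PreprocessedSubject:
    pp = config.preprocess
    source = GridGeometry(shape=scan.shape, voxel_size=scan.voxel_size)
    target = adult_target_geometry(source)
    logger.info("preprocess subject=%s protocol=%s source=%s target=%s",
                scan.subject_id, scan.protocol, source.shape, target.shape)

    def regrid(vol, order=1):
        return preprocess.resample_to_grid(vol, source, target, order=order)

    resampled = {c: regrid(v) for c, v in scan.contrasts().items()}
    brain = preprocess.resample_mask(scan.brain_mask, source, target)
    atlas = phantom.build_region_atlas(
        target.shape, target.voxel_size,
        periventricular_distance_mm=config.quantify.periventricular_distance_mm)
    # keep the analytic atlas and the resampled head consistent at the margin
    brain &= atlas.brain_mask

    corrected = {}
    for c, vol in resampled.items():
        vol = np.where(brain, np.maximum(vol, 1e-3), vol)
        corrected[c], _ = preprocess.correct_bias(
            vol, brain, smoothness_mm=pp.bias_smoothness_mm,
            voxel_size=target.voxel_size, n_iter=pp.bias_iterations)
        logger.info("bias-corrected subject=%s contrast=%s", scan.subject_id, c)

    if pp.register:
        for c in ("pd", "t1"):
            tr, warped = preprocess.rigid_register(
                corrected[c], corrected["t2"], brain, target.voxel_size,
                coarse_factor=pp.registration_coarse_factor,
                fine=pp.registration_fine)
            corrected[c] = warped
            logger.info("registered subject=%s contrast=%s rot=%s trans=%s",
                        scan.subject_id, c, np.round(tr.rotation, 4),
                        np.round(tr.translation, 3))

    normalized, maps = {}, {}
    for c, vol in corrected.items():
        normalized[c], maps[c] = preprocess.normalize_intensity(
            vol, brain, percentiles=pp.landmark_percentiles,
            targets=pp.standard_scale)

    mk = lambda vols, normed: SubjectScan(
        subject_id=scan.subject_id, pd=vols["pd"], t2=vols["t2"], t1=vols["t1"],
        brain_mask=brain, voxel_size=target.voxel_size, protocol=scan.protocol,
        normalized=normed)
    out = PreprocessedSubject(scan_norm=mk(normalized, True),
                              scan_corrected=mk(corrected, False),
                              atlas=atlas, norm_maps=maps)
    if truth is not None:
        out.truth_t2 = preprocess.resample_mask(truth.t2_lesion_mask, source, target)
        out.truth_t1 = preprocess.resample_mask(truth.t1_lesion_mask, source, target)
    return out


def derive_tissue_model(pre: PreprocessedSubject, config: PipelineConfig,
                        max_per_class: int = 20000, seed: int = 0) -> segment.TissueModel:
    """Fit the WM/GM/CSF classes from the subject's atlas tissue labels on the
    normalized images, then synthesize the lesion class from the WM statistics:
    its raw-scale mean is the WM mean times the configured contrast multipliers,
    mapped through each contrast's normalization map; its covariance is the WM
    covariance inflated to absorb lesion heterogeneity.

    WM training samples are trimmed of their brightest-T2 tail so implanted or
    real lesions do not contaminate the WM class.
    """
    sg = config.segment
    rng = np.random.default_rng(seed)
    feats = pre.scan_norm.stack()
    tissue = pre.atlas.tissue.ravel()
    brain = pre.scan_norm.brain_mask.ravel()

    samples = {}
    for code, name in ((phantom.TISSUE_WM, "WM"), (phantom.TISSUE_GM, "GM"),
                       (phantom.TISSUE_CSF, "CSF")):
        idx = np.nonzero((tissue == code) & brain)[0]
        if name == "WM":
            t2 = feats[idx, 1]
            idx = idx[t2 <= np.percentile(t2, 90.0)]
        if len(idx) > max_per_class:
            idx = rng.choice(idx, size=max_per_class, replace=False)
        samples[name] = feats[idx]
    model3 = segment.fit_tissue_model(samples)

    wm_raw = pre.scan_corrected
    wm_mask = pre.atlas.wm_mask & wm_raw.brain_mask
    raw_means = [float(v[wm_mask].mean()) for v in
                 (wm_raw.pd, wm_raw.t2, wm_raw.t1)]
    lesion_mean = np.array([
        pre.norm_maps[c](m * k)
        for c, m, k in zip(("pd", "t2", "t1"), raw_means, sg.lesion_contrast_multipliers)
    ], dtype=float)
    lesion_cov = np.asarray(model3.covariances["WM"]) * sg.lesion_covariance_inflation

    scale = 1.0 - sg.lesion_prior
    priors = {c: p * scale for c, p in model3.priors.items()}
    priors["lesion"] = sg.lesion_prior
    means = dict(model3.means)
    means["lesion"] = lesion_mean
    covs = dict(model3.covariances)
    covs["lesion"] = lesion_cov
    return segment.TissueModel(means=means, covariances=covs, priors=priors)


@dataclass
class SegmentedSubject:
    t2_mask: np.ndarray
    t1_mask: np.ndarray
    model: segment.TissueModel


def segment_subject(pre: PreprocessedSubject, config: PipelineConfig) -> SegmentedSubject:
    sg = config.segment
    model = derive_tissue_model(pre, config)
    supra = segment.segment_t2_lesions(
        pre.scan_norm, model, pre.atlas.supratentorial_mask,
        posterior_threshold=sg.posterior_threshold)
    infra = segment.segment_infratentorial_t2(
        pre.scan_corrected, pre.atlas.infratentorial_mask, pre.atlas.wm_mask,
        threshold_multiple=sg.infratentorial_threshold_multiple)
    t2_mask = segment.apply_manual_edits(
        supra | infra, np.zeros(pre.scan_norm.shape, dtype=np.uint8))

    fraction = (sg.t1_fraction_pediatric if pre.scan_norm.protocol == "pediatric"
                else sg.t1_fraction_adult)
    t1_cfg = segment.T1ThresholdConfig(fraction=fraction, nawm_ring_mm=sg.nawm_ring_mm)
    t1_mask = segment.segment_t1_hypointense(
        pre.scan_corrected.t1, t2_mask, pre.atlas.wm_mask, t1_cfg,
        voxel_size=pre.scan_corrected.voxel_size)
    logger.info("segmented subject=%s t2_voxels=%d t1_voxels=%d fraction=%.2f",
                pre.scan_norm.subject_id, int(t2_mask.sum()), int(t1_mask.sum()),
                fraction)
    return SegmentedSubject(t2_mask=t2_mask, t1_mask=t1_mask, model=model)


def process_subject(scan: SubjectScan, config: PipelineConfig,
                    truth: phantom.GroundTruth | None = None):
    """Preprocess, segment and quantify one subject; returns
    (PreprocessedSubject, SegmentedSubject, LesionInventory)."""
    pre = preprocess_subject(scan, config, truth=truth)
    seg = segment_subject(pre, config)
    inv = quantify.regional_inventory(
        scan.subject_id, seg.t2_mask, seg.t1_mask, pre.atlas,
        pre.scan_norm.voxel_volume_mm3,
        connectivity=config.quantify.connectivity,
        min_voxels_t2=config.quantify.min_voxels_t2,
        min_voxels_t1=config.quantify.min_voxels_t1)
    return pre, seg, inv


def run_pipeline(config: PipelineConfig) -> stats.GroupReport:
    """Run the full two-cohort analysis and write every artifact under
    ``config.out_dir``.  Deterministic given ``config.seed``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.save(out / "config.yaml")

    master = np.random.default_rng(config.seed)
    seeds = {"pediatric": int(master.integers(0, 2**31 - 1)),
             "adult": int(master.integers(0, 2**31 - 1))}

    ped_grid = tuple(config.cohort.grid_shape)
    adult_grid = adult_target_geometry(
        GridGeometry(shape=ped_grid, voxel_size=(0.98, 0.98, 2.0))).shape

    samplers = {
        "pediatric": phantom.pediatric_cohort_sampler(
            grid_shape=ped_grid, bias_field_amplitude=config.cohort.bias_field_amplitude,
            protocol=phantom.pediatric_protocol(noise_sigma=config.cohort.noise_sigma)),
        "adult": phantom.adult_cohort_sampler(
            grid_shape=adult_grid, bias_field_amplitude=config.cohort.bias_field_amplitude,
            protocol=phantom.adult_protocol(noise_sigma=config.cohort.noise_sigma)),
    }
    n_by_group = {"pediatric": config.cohort.n_pediatric,
                  "adult": config.cohort.n_adult}

    inventories: dict = {}
    for group in ("pediatric", "adult"):
        inventories[group] = []
        cohort = phantom.generate_cohort(n_by_group[group], samplers[group],
                                         seeds[group])
        template_masks, template_t2 = [], []
        compartments = None
        for scan, truth in cohort:
            pre, seg, inv = process_subject(scan, config, truth=truth)
            inventories[group].append(inv)
            tf = truth.template_transform
            template_masks.append(quantify.to_template(seg.t2_mask, tf, is_mask=True))
            template_t2.append(quantify.to_template(pre.scan_norm.t2, tf))
            compartments = pre.atlas
        for comp in ("supratentorial", "infratentorial"):
            fmap = quantify.lesion_frequency_map(
                template_masks, compartments.region_mask(comp), compartment=comp)
            io.save_nifti(out / group / f"frequency_{comp}.nii.gz", fmap.values,
                          compartments.voxel_size)
        io.save_nifti(out / group / "average_t2.nii.gz",
                      quantify.average_anatomy(template_t2), compartments.voxel_size)

    inv_frame = quantify.inventories_to_frame(
        inventories["pediatric"] + inventories["adult"])
    inv_frame.to_csv(out / "inventories.csv", index=False)

    report = stats.group_report(
        inventories["pediatric"], inventories["adult"],
        config=stats.ReportConfig(log_constant_cm3=config.stats.log_constant_cm3,
                                  equal_variance=config.stats.equal_variance,
                                  alpha=config.stats.alpha))
    frame = report.to_frame()
    frame.to_csv(out / "group_report.csv", index=False)
    io.save_json(out / "group_report.json", frame.to_dict(orient="records"))
    logger.info("pipeline complete: %d + %d subjects, report at %s",
                report.n1, report.n2, out / "group_report.csv")
    return report
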