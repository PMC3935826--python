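"""Segmentation: Gaussian tissue model, Bayesian T2 lesion masks, the
infratentorial threshold stand-in, T1 black-hole thresholding and the
cross-protocol threshold calibration."""

import math

import numpy as np
import pytest

from lesionquant import phantom, segment
from lesionquant.config import PipelineConfig
from lesionquant.pipeline import preprocess_subject, derive_tissue_model
from lesionquant.segment import (CalibrationError, SegmentationError,
                                 T1ThresholdConfig, TissueModel,
                                 apply_manual_edits, calibrate_t1_threshold,
                                 fit_tissue_model, nawm_reference_intensity,
                                 segment_infratentorial_t2, segment_t1_hypointense,
                                 segment_t2_lesions)

from conftest import ADULT_GRID


def _gaussian_samples(rng, n=10_000):
    params = {
        "WM": ([120.0, 136.0, 100.0], np.diag([16.0, 16.0, 16.0])),
        "GM": ([125.0, 100.0, 85.0], np.diag([16.0, 16.0, 16.0])),
        "CSF": ([90.0, 180.0, 40.0], np.diag([25.0, 25.0, 25.0])),
        "lesion": ([160.0, 204.0, 80.0], np.diag([36.0, 36.0, 36.0])),
    }
    return {c: rng.multivariate_normal(mu, cov, size=n)
            for c, (mu, cov) in params.items()}, params


class TestTissueModel:
    def test_known_gaussians_recovered_within_3_se(self, rng):
        samples, params = _gaussian_samples(rng)
        model = fit_tissue_model(samples)
        for c, (mu, cov) in params.items():
            se = np.sqrt(np.diag(cov) / len(samples[c]))
            assert np.all(np.abs(model.means[c] - mu) <= 3 * se)
            assert model.priors[c] == pytest.approx(0.25)

    def test_duplicating_samples_leaves_model_unchanged(self, rng):
        samples, _ = _gaussian_samples(rng, n=500)
        doubled = {c: np.concatenate([x, x]) for c, x in samples.items()}
        m1 = fit_tissue_model(samples)
        m2 = fit_tissue_model(doubled)
        for c in samples:
            assert np.allclose(m1.means[c], m2.means[c])
            assert np.allclose(m1.covariances[c], m2.covariances[c])
            assert m1.priors[c] == pytest.approx(m2.priors[c])

    def test_degenerate_covariance_gets_ridge(self, rng):
        x = rng.normal(size=(200, 1)) @ np.ones((1, 3))  # rank-1 features
        model = fit_tissue_model({"WM": x + [120, 136, 100], "GM": x + [125, 100, 85]})
        assert np.all(np.linalg.eigvalsh(model.covariances["WM"]) > 0)

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(SegmentationError):
            fit_tissue_model({"WM": rng.normal(size=(3, 3))})

    def test_priors_must_sum_to_one(self):
        with pytest.raises(SegmentationError):
            TissueModel(means={"WM": np.zeros(3)},
                        covariances={"WM": np.eye(3)}, priors={"WM": 0.5})

    def test_serialization_roundtrip(self, rng):
        samples, _ = _gaussian_samples(rng, n=200)
        m1 = fit_tissue_model(samples)
        m2 = TissueModel.from_dict(m1.to_dict())
        x = rng.normal(size=(50, 3)) * 10 + [120, 140, 90]
        assert np.allclose(m1.posterior(x), m2.posterior(x))


def _brute_force_posterior(x, model, cls="lesion"):
    """Straight-line per-voxel posterior: explicit Gaussian densities and the
    mixture rule, no shared code with the vectorized implementation."""
    out = np.empty(len(x))
    names = list(model.means)
    for i, row in enumerate(x):
        dens = {}
        for c in names:
            mu = np.asarray(model.means[c], float)
            cov = np.asarray(model.covariances[c], float)
            diff = row - mu
            quad = float(diff @ np.linalg.inv(cov) @ diff)
            norm = math.sqrt(((2 * math.pi) ** 3) * np.linalg.det(cov))
            dens[c] = model.priors[c] * math.exp(-0.5 * quad) / norm
        out[i] = dens[cls] / sum(dens.values())
    return out


class TestBayesianSegmentation:
    @pytest.fixture(scope="class")
    def fitted(self, rng):
        samples, _ = _gaussian_samples(np.random.default_rng(5))
        return fit_tissue_model(samples)

    def test_posterior_matches_brute_force_on_subvolume(self, fitted, rng):
        x = rng.normal(size=(20**3 // 100, 3)) * 30 + [130, 150, 90]
        vec = fitted.posterior(x, "lesion")
        ref = _brute_force_posterior(x, fitted, "lesion")
        assert np.allclose(vec, ref, rtol=1e-10, atol=1e-12)

    def test_high_cnr_phantom_dice(self, lesioned_subject, atlas_adult):
        """At the default contrast (lesion/WM separation well beyond 5 sigma)
        the supratentorial Bayesian mask must overlap ground truth at
        Dice >= 0.90."""
        scan, truth = lesioned_subject
        cfg = PipelineConfig()
        pre = preprocess_subject(scan, cfg, truth=truth)
        model = derive_tissue_model(pre, cfg)
        mask = segment_t2_lesions(pre.scan_norm, model,
                                  pre.atlas.supratentorial_mask)
        gt = pre.truth_t2 & pre.atlas.supratentorial_mask
        from lesionquant.quantify import dice_coefficient
        assert dice_coefficient(mask, gt) >= 0.90

    def test_lesion_free_phantom_low_false_positives(self, noiseless_subject):
        spec = phantom.PhantomSpec(
            grid_shape=ADULT_GRID, protocol=phantom.adult_protocol(),
            n_lesions_by_region={}, seed=31)
        scan, truth = phantom.generate_subject(spec)
        cfg = PipelineConfig()
        pre = preprocess_subject(scan, cfg, truth=truth)
        model = derive_tissue_model(pre, cfg)
        mask = segment_t2_lesions(pre.scan_norm, model,
                                  pre.atlas.supratentorial_mask)
        assert mask.sum() <= 0.001 * pre.scan_norm.brain_mask.sum()

    def test_threshold_one_gives_empty_mask(self, fitted, lesioned_subject):
        scan, _ = lesioned_subject
        cfg = PipelineConfig()
        pre = preprocess_subject(scan, cfg)
        mask = segment_t2_lesions(pre.scan_norm, fitted,
                                  pre.atlas.supratentorial_mask,
                                  posterior_threshold=1.0)
        assert not mask.any()

    def test_unnormalized_scan_rejected(self, lesioned_subject, fitted, atlas_adult):
        scan, _ = lesioned_subject  # raw intensities: landmark check must fail
        with pytest.raises(SegmentationError):
            segment_t2_lesions(scan, fitted, atlas_adult.supratentorial_mask)


class TestManualEdits:
    def test_empty_edits_keep_mask(self, rng):
        mask = rng.uniform(size=(10, 10, 5)) < 0.2
        out = apply_manual_edits(mask, np.zeros(mask.shape, dtype=np.uint8))
        assert np.array_equal(out, mask)

    def test_remove_everything(self, rng):
        mask = rng.uniform(size=(10, 10, 5)) < 0.2
        out = apply_manual_edits(mask, np.full(mask.shape, 2, dtype=np.uint8))
        assert not out.any()

    def test_add_and_remove_arithmetic(self):
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask.ravel()[:100] = True
        edits = np.zeros(mask.shape, dtype=np.uint8)
        edits.ravel()[200:205] = 1   # add 5 outside the mask
        edits.ravel()[0:3] = 2       # remove 3 inside
        out = apply_manual_edits(mask, edits)
        assert out.sum() == 102

    def test_grid_mismatch_rejected(self):
        with pytest.raises(SegmentationError):
            apply_manual_edits(np.zeros((5, 5, 5), bool), np.zeros((5, 5, 4), np.uint8))


class TestInfratentorialThreshold:
    def test_pontine_lesion_fully_detected(self, atlas_adult):
        spec = phantom.PhantomSpec(
            grid_shape=ADULT_GRID, protocol=phantom.adult_protocol(),
            n_lesions_by_region={"pons": 1},
            infra_lesion_radius_range_mm=(3.5, 4.0), bias_field_amplitude=0.0,
            seed=13)
        scan, truth = phantom.generate_subject(spec)
        mask = segment_infratentorial_t2(scan, atlas_adult.infratentorial_mask,
                                         atlas_adult.wm_mask)
        from lesionquant.quantify import dice_coefficient
        assert dice_coefficient(mask, truth.t2_lesion_mask) >= 0.9

    def test_lesion_free_noiseless_is_empty(self, noiseless_subject, atlas_adult):
        scan, _ = noiseless_subject
        mask = segment_infratentorial_t2(scan, atlas_adult.infratentorial_mask,
                                         atlas_adult.wm_mask)
        assert not mask.any()

    def test_threshold_above_maximum_is_empty(self, lesioned_subject, atlas_adult):
        scan, _ = lesioned_subject
        mask = segment_infratentorial_t2(scan, atlas_adult.infratentorial_mask,
                                         atlas_adult.wm_mask,
                                         threshold_multiple=10.0)
        assert not mask.any()

    def test_empty_mask_rejected(self, lesioned_subject, atlas_adult):
        scan, _ = lesioned_subject
        with pytest.raises(SegmentationError):
            segment_infratentorial_t2(scan, np.zeros(scan.shape, bool),
                                      atlas_adult.wm_mask)


class TestNawmReference:
    def test_noiseless_reference_is_wm_mean(self, atlas_adult):
        spec = phantom.PhantomSpec(
            grid_shape=ADULT_GRID, protocol=phantom.adult_protocol(noise_sigma=0.0),
            n_lesions_by_region={"supratentorial": 2}, bias_field_amplitude=0.0,
            seed=2)
        scan, truth = phantom.generate_subject(spec)
        ref = nawm_reference_intensity(scan.t1, atlas_adult.wm_mask,
                                       truth.t2_lesion_mask, ring_mm=5.0,
                                       voxel_size=scan.voxel_size)
        assert ref == pytest.approx(100.0)

    def test_noisy_reference_within_3_se(self, atlas_adult):
        spec = phantom.PhantomSpec(
            grid_shape=ADULT_GRID, protocol=phantom.adult_protocol(),
            n_lesions_by_region={"supratentorial": 3}, bias_field_amplitude=0.0,
            seed=19)
        scan, truth = phantom.generate_subject(spec)
        ref = nawm_reference_intensity(scan.t1, atlas_adult.wm_mask,
                                       truth.t2_lesion_mask, ring_mm=5.0,
                                       voxel_size=scan.voxel_size)
        # ring size: bound SE generously by sigma / sqrt(1000)
        assert abs(ref - 100.0) <= 3 * 4.0 / np.sqrt(1000)

    def test_empty_ring_falls_back_with_warning(self, caplog):
        t1 = np.full((20, 20, 10), 100.0)
        lesion = np.zeros(t1.shape, bool)
        lesion[5:8, 5:8, 4:6] = True
        wm = np.zeros(t1.shape, bool)
        wm[18:20, 18:20, 8:10] = True  # all WM far beyond the ring
        t1[wm] = 90.0
        with caplog.at_level("WARNING"):
            ref = nawm_reference_intensity(t1, wm, lesion, ring_mm=2.0)
        assert ref == pytest.approx(90.0)
        assert any("fall" in r.message for r in caplog.records)

    def test_no_nawm_at_all_rejected(self):
        lesion = np.ones((5, 5, 5), bool)
        with pytest.raises(SegmentationError):
            nawm_reference_intensity(np.ones((5, 5, 5)), lesion, lesion, 3.0)


class TestT1Hypointense:
    def _tiny_case(self, voxel_ratio):
        """One lesion voxel at ``voxel_ratio`` x the NAWM mean of 100."""
        t1 = np.full((12, 12, 6), 100.0)
        wm = np.ones(t1.shape, bool)
        t2 = np.zeros(t1.shape, bool)
        t2[6, 6, 3] = True
        t1[6, 6, 3] = voxel_ratio * 100.0
        return t1, t2, wm

    def test_084_included_pediatric_excluded_adult(self):
        t1, t2, wm = self._tiny_case(0.84)
        ped = segment_t1_hypointense(t1, t2, wm, T1ThresholdConfig(fraction=0.85))
        adult = segment_t1_hypointense(t1, t2, wm, T1ThresholdConfig(fraction=0.83))
        assert ped[6, 6, 3] and ped.sum() == 1
        assert not adult.any()

    def test_tiny_fraction_gives_empty_mask(self):
        t1, t2, wm = self._tiny_case(0.5)
        out = segment_t1_hypointense(t1, t2, wm, T1ThresholdConfig(fraction=0.01))
        assert not out.any()

    def test_invalid_fraction_rejected(self):
        with pytest.raises(SegmentationError):
            T1ThresholdConfig(fraction=1.2)

    def test_output_subset_of_t2_mask(self, lesioned_subject, atlas_adult):
        scan, truth = lesioned_subject
        out = segment_t1_hypointense(scan.t1, truth.t2_lesion_mask,
                                     atlas_adult.wm_mask,
                                     T1ThresholdConfig(fraction=0.83),
                                     voxel_size=scan.voxel_size)
        assert not np.any(out & ~truth.t2_lesion_mask)

    def test_t1lv_recovered_within_10pct(self, atlas_adult):
        """Core fraction 0.4 with core multiplier 0.7: thresholding at the
        protocol fraction must recover the ground-truth black-hole volume."""
        spec = phantom.PhantomSpec(
            grid_shape=ADULT_GRID, protocol=phantom.adult_protocol(),
            n_lesions_by_region={"pons": 1}, target_t2lv_cm3=10.0,
            t1_core_fraction=0.4, seed=5)
        scan, truth = phantom.generate_subject(spec)
        out = segment_t1_hypointense(scan.t1, truth.t2_lesion_mask,
                                     atlas_adult.wm_mask,
                                     T1ThresholdConfig(fraction=0.83),
                                     voxel_size=scan.voxel_size)
        assert out.sum() == pytest.approx(truth.t1_voxel_count, rel=0.10)

    def test_t1lv_monotone_in_fraction(self, lesioned_subject, atlas_adult):
        scan, truth = lesioned_subject
        vols = []
        for f in (0.6, 0.7, 0.8, 0.85, 0.9):
            out = segment_t1_hypointense(scan.t1, truth.t2_lesion_mask,
                                         atlas_adult.wm_mask,
                                         T1ThresholdConfig(fraction=f),
                                         voxel_size=scan.voxel_size)
            vols.append(int(out.sum()))
        assert vols == sorted(vols)


class TestCalibration:
    @pytest.fixture(scope="class")
    def paired(self):
        pairs_raw = phantom.generate_paired_calibration_subjects(10, seed=42)
        pairs = []
        for a, b, truth in pairs_raw:
            atlas = phantom.build_region_atlas(a.shape, a.voxel_size)
            wm = atlas.wm_mask
            pairs.append(((a.t1, truth.t2_lesion_mask, wm, a.voxel_size),
                          (b.t1, truth.t2_lesion_mask, wm, b.voxel_size)))
        return pairs

    def test_self_calibration_returns_reference(self, paired):
        res = calibrate_t1_threshold([(a, a) for a, _ in paired],
                                     reference_fraction=0.85)
        assert res.fraction == pytest.approx(0.85, abs=0.005)

    def test_constructed_protocol_pair_recovers_083(self, paired):
        """Ten synthetic paired subjects whose adult-protocol T1 contrast makes
        83% equivalent to the pediatric 85% by construction."""
        res = calibrate_t1_threshold(paired, reference_fraction=0.85)
        assert res.fraction == pytest.approx(0.83, abs=0.005)
        assert res.achieved_discrepancy_cm3 <= 0.05

    def test_volume_curve_monotone_per_subject(self, paired):
        for _, (t1, t2_mask, wm, voxel) in paired[:3]:
            vols = [segment.t1_lesion_volume_cm3(t1, t2_mask, wm, f, voxel)
                    for f in (0.6, 0.75, 0.85, 0.95)]
            assert vols == sorted(vols)

    def test_nonoverlapping_curves_raise_with_diagnostics(self):
        rng = np.random.default_rng(0)
        shape = (16, 16, 8)
        wm = np.ones(shape, bool)
        t2 = np.zeros(shape, bool)
        t2[4:8, 4:8, 2:5] = True
        t1_a = np.full(shape, 100.0)
        t1_a[t2] = 50.0   # protocol A: large black-hole volume at 0.85
        t1_b = np.full(shape, 100.0)  # protocol B: lesion isointense, volume 0
        pairs = [((t1_a, t2, wm, (1, 1, 1)), (t1_b, t2, wm, (1, 1, 1)))
                 for _ in range(3)]
        with pytest.raises(CalibrationError) as exc:
            calibrate_t1_threshold(pairs, reference_fraction=0.85)
        assert exc.value.curve is not None

    def test_too_few_pairs_rejected(self, paired):
        with pytest.raises(CalibrationError):
            calibrate_t1_threshold(paired[:1])
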