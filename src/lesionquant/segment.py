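"""Lesion segmentation.

Supratentorial T2-hyperintense lesions are segmented with a multispectral
Bayesian classifier: a four-class (WM, GM, CSF, lesion) Gaussian model over
the (PD, T2, T1) feature vector, with a voxel included when the lesion
posterior exceeds a threshold.  Infratentorial T2 lesions — unreliable for
the multispectral classifier in the source protocol — use a relative
intensity threshold against infratentorial white matter, with a
manual-edit importer standing in for interactive review.

T1-hypointense ("black hole") segmentation first requires a voxel to be
bright on T2 (containment in the final T2 lesion mask), then thresholds the
T1 intensity at a protocol-specific fraction of the mean intensity of
surrounding normal-appearing white matter (NAWM): 85% under the pediatric
protocol, 83% under the adult protocol.  ``calibrate_t1_threshold``
reproduces the cross-protocol calibration that makes those two fractions
equivalent: given subjects scanned under both protocols, it finds the
fraction for protocol B whose median T1 lesion volume matches protocol A's
at the reference fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .preprocess import is_normalized

logger = logging.getLogger(__name__)

CLASSES = ("WM", "GM", "CSF", "lesion")


class SegmentationError(Exception):
    pass


class CalibrationError(SegmentationError):
    def __init__(self, msg, curve=None):
        super().__init__(msg)
        self.curve = curve  # list of (fraction, median volume difference)


@dataclass
class TissueModel:
    """Per-class Gaussian model over (PD, T2, T1): means, covariances, priors."""

    means: dict
    covariances: dict
    priors: dict

    def __post_init__(self):
        total = sum(self.priors.values())
        if not np.isclose(total, 1.0):
            raise SegmentationError(f"class priors sum to {total}, expected 1")
        for c, cov in self.covariances.items():
            cov = np.asarray(cov)
            if not np.allclose(cov, cov.T):
                raise SegmentationError(f"covariance of {c} is not symmetric")
            if np.any(np.linalg.eigvalsh(cov) <= 0):
                raise SegmentationError(f"covariance of {c} is not positive definite")

    def log_likelihoods(self, x: np.ndarray) -> dict:
        """Per-class Gaussian log density at feature rows ``x`` (n, 3)."""
        out = {}
        for c in self.means:
            mu = np.asarray(self.means[c], dtype=float)
            cov = np.asarray(self.covariances[c], dtype=float)
            L = np.linalg.cholesky(cov)
            d = np.linalg.solve(L, (x - mu).T)
            maha = np.sum(d * d, axis=0)
            logdet = 2.0 * np.sum(np.log(np.diag(L)))
            k = x.shape[1]
            out[c] = -0.5 * (maha + logdet + k * np.log(2.0 * np.pi))
        return out

    def posterior(self, x: np.ndarray, cls: str = "lesion") -> np.ndarray:
        """P(cls | x) under the Gaussian mixture, computed stably in log space."""
        ll = self.log_likelihoods(x)
        logp = np.stack([ll[c] + np.log(self.priors[c]) for c in self.means], axis=0)
        logp -= logp.max(axis=0, keepdims=True)
        p = np.exp(logp)
        p /= p.sum(axis=0, keepdims=True)
        names = list(self.means)
        return p[names.index(cls)]

    def to_dict(self) -> dict:
        return {
            "means": {c: list(map(float, m)) for c, m in self.means.items()},
            "covariances": {c: np.asarray(v).tolist() for c, v in self.covariances.items()},
            "priors": {c: float(p) for c, p in self.priors.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TissueModel":
        return cls(means={c: np.asarray(m, float) for c, m in d["means"].items()},
                   covariances={c: np.asarray(v, float) for c, v in d["covariances"].items()},
                   priors=dict(d["priors"]))


def fit_tissue_model(samples: dict, min_samples: int = 10, ridge: float = 1e-6) -> TissueModel:
    """Maximum-likelihood Gaussian per class from labeled (n_c, 3) feature arrays;
    priors are the class sample fractions.  Singular covariances get a ridge on
    the diagonal; if still singular, a model error is raised."""
    means, covs, priors = {}, {}, {}
    n_total = sum(len(v) for v in samples.values())
    for c, x in samples.items():
        x = np.asarray(x, dtype=np.float64)
        if len(x) < min_samples:
            raise SegmentationError(f"class {c!r} has {len(x)} samples; need >= {min_samples}")
        means[c] = x.mean(axis=0)
        # MLE covariance (1/n), so duplicating every sample leaves the model unchanged
        cov = np.cov(x, rowvar=False, bias=True)
        if np.any(np.linalg.eigvalsh(cov) <= 0):
            cov = cov + ridge * np.trace(cov) / cov.shape[0] * np.eye(cov.shape[0])
        if np.any(np.linalg.eigvalsh(cov) <= 0):
            cov = cov + ridge * np.eye(cov.shape[0])
            if np.any(np.linalg.eigvalsh(cov) <= 0):
                raise SegmentationError(f"covariance of class {c!r} is singular")
        covs[c] = cov
        priors[c] = len(x) / n_total
    return TissueModel(means=means, covariances=covs, priors=priors)


def segment_t2_lesions(scan, model: TissueModel, region_mask: np.ndarray,
                       posterior_threshold: float = 0.5,
                       check_normalization: bool = True) -> np.ndarray:
    """Bayesian multispectral T2 lesion mask: voxels inside ``region_mask`` whose
    lesion posterior exceeds the threshold."""
    if check_normalization and not (scan.normalized or
                                    is_normalized(scan.t2, scan.brain_mask)):
        raise SegmentationError(
            "scan intensities are not on the standard scale (landmark check failed); "
            "run normalize_intensity first")
    region = region_mask.astype(bool) & scan.brain_mask.astype(bool)
    out = np.zeros(scan.shape, dtype=bool)
    if posterior_threshold >= 1.0 or not region.any():
        return out
    x = np.stack([scan.pd[region], scan.t2[region], scan.t1[region]], axis=1)
    post = model.posterior(x, "lesion")
    out[region] = post > posterior_threshold
    return out


def apply_manual_edits(auto_mask: np.ndarray, edits: np.ndarray) -> np.ndarray:
    """Apply an edited-label volume: 0 keeps the automatic decision, 1 adds the
    voxel, 2 removes it."""
    if edits.shape != auto_mask.shape:
        raise SegmentationError("edit volume grid does not match the mask grid")
    out = auto_mask.astype(bool).copy()
    out[edits == 1] = True
    out[edits == 2] = False
    return out


def segment_infratentorial_t2(scan, infratentorial_mask: np.ndarray,
                              wm_mask: np.ndarray,
                              threshold_multiple: float = 1.3) -> np.ndarray:
    """Relative-threshold T2 lesion mask for the infratentorium: voxels brighter
    than ``threshold_multiple`` x the infratentorial WM mean, within the mask.
    Intended to be reviewed through :func:`apply_manual_edits`."""
    infra = infratentorial_mask.astype(bool)
    if not infra.any():
        raise SegmentationError("infratentorial mask is empty")
    ref_mask = infra & wm_mask.astype(bool)
    if not ref_mask.any():
        raise SegmentationError("no infratentorial white matter to reference")
    ref = float(scan.t2[ref_mask].mean())
    return infra & (scan.t2 > threshold_multiple * ref)


@dataclass(frozen=True)
class T1ThresholdConfig:
    """T1 black-hole thresholding: include a voxel when its T1 intensity falls
    below ``fraction`` of the mean NAWM intensity within ``nawm_ring_mm`` of the
    lesion surface; ``require_t2_bright`` restricts to the final T2 mask."""

    fraction: float = 0.85
    nawm_ring_mm: float = 5.0
    require_t2_bright: bool = True

    def __post_init__(self):
        if not (0.0 < self.fraction < 1.0):
            raise SegmentationError("T1 threshold fraction must lie strictly in (0,1)")
        if self.nawm_ring_mm <= 0:
            raise SegmentationError("nawm_ring_mm must be positive")


def nawm_reference_intensity(t1: np.ndarray, wm_mask: np.ndarray,
                             t2_lesion_mask: np.ndarray, ring_mm: float,
                             voxel_size=(1.0, 1.0, 1.0)) -> float:
    """Mean T1 intensity of normal-appearing WM within ``ring_mm`` of the lesion
    surface (lesion voxels excluded).  Falls back to the global NAWM mean with a
    logged warning when the ring holds no NAWM voxel."""
    wm = wm_mask.astype(bool)
    lesions = t2_lesion_mask.astype(bool)
    nawm = wm & ~lesions
    if not nawm.any():
        raise SegmentationError("no normal-appearing white matter available")
    if lesions.any():
        dist = ndimage.distance_transform_edt(~lesions, sampling=voxel_size)
        ring = nawm & (dist <= ring_mm)
    else:
        ring = np.zeros_like(nawm)
    if ring.any():
        return float(t1[ring].mean())
    logger.warning("NAWM ring empty within %.1f mm of lesions; "
                   "falling back to global NAWM mean", ring_mm)
    return float(t1[nawm].mean())


def segment_t1_hypointense(t1: np.ndarray, t2_lesion_mask: np.ndarray,
                           wm_mask: np.ndarray, config: T1ThresholdConfig,
                           voxel_size=(1.0, 1.0, 1.0)) -> np.ndarray:
    """T1 black-hole mask: voxels confirmed bright on T2 (inside the final T2
    lesion mask, when ``require_t2_bright``) with T1 intensity below
    ``config.fraction`` x the surrounding-NAWM reference.  The output is a
    subset of the T2 mask whenever ``require_t2_bright`` is on."""
    t2_mask = t2_lesion_mask.astype(bool)
    ref = nawm_reference_intensity(t1, wm_mask, t2_mask, config.nawm_ring_mm,
                                   voxel_size=voxel_size)
    hypo = t1 < config.fraction * ref
    if config.require_t2_bright:
        return hypo & t2_mask
    return hypo & (wm_mask.astype(bool) | t2_mask)


def t1_lesion_volume_cm3(t1, t2_mask, wm_mask, fraction, voxel_size,
                         nawm_ring_mm: float = 5.0) -> float:
    cfg = T1ThresholdConfig(fraction=fraction, nawm_ring_mm=nawm_ring_mm)
    mask = segment_t1_hypointense(t1, t2_mask, wm_mask, cfg, voxel_size=voxel_size)
    return float(mask.sum()) * float(np.prod(voxel_size)) / 1000.0


@dataclass
class CalibrationResult:
    fraction: float
    achieved_discrepancy_cm3: float
    curve: list  # (fraction, median volume difference) pairs

    def curve_records(self) -> list:
        return [{"fraction": f, "median_volume_diff_cm3": d} for f, d in self.curve]


def calibrate_t1_threshold(pairs: list, reference_fraction: float = 0.85,
                           grid_step: float = 0.005, grid_lo: float = 0.5,
                           grid_hi: float = 0.995, refine_tol: float = 1e-4,
                           nawm_ring_mm: float = 5.0,
                           rel_discrepancy: float = 0.05) -> CalibrationResult:
    """Cross-protocol T1 threshold calibration.

    ``pairs`` is a list of per-subject tuples
    ``((t1_A, t2_mask, wm_mask, voxel_A), (t1_B, t2_mask_B, wm_mask_B, voxel_B))``
    for the same subject scanned under protocol A and protocol B.  Finds the
    protocol-B fraction minimizing the absolute median (over subjects) of
    T1LV_B(f) - T1LV_A(reference_fraction): a coarse grid (default step 0.005)
    followed by bisection on the signed median difference, which is monotone
    because per-subject thresholded volumes are non-decreasing in f.
    """
    if len(pairs) < 2:
        raise CalibrationError("calibration needs at least 2 paired subjects")
    if not (0.0 < reference_fraction < 1.0):
        raise CalibrationError("reference fraction must lie in (0,1)")

    # the NAWM reference does not depend on the fraction: precompute it and the
    # candidate (T2-bright) lesion T1 intensities once per subject and side
    def prepare(side):
        t1, t2_mask, wm_mask, voxel = side
        ref = nawm_reference_intensity(t1, wm_mask, t2_mask, nawm_ring_mm,
                                       voxel_size=voxel)
        vals = t1[t2_mask.astype(bool)]
        return vals, ref, float(np.prod(voxel)) / 1000.0

    prep_a = [prepare(a) for a, _ in pairs]
    prep_b = [prepare(b) for _, b in pairs]
    ref_vols = np.array([np.count_nonzero(v < reference_fraction * r) * vv
                         for v, r, vv in prep_a])

    def median_diff(f: float) -> float:
        vols = np.array([np.count_nonzero(v < f * r) * vv for v, r, vv in prep_b])
        return float(np.median(vols - ref_vols))

    grid = np.arange(grid_lo, grid_hi + 1e-12, grid_step)
    diffs = np.array([median_diff(f) for f in grid])
    curve = list(zip(grid.tolist(), diffs.tolist()))

    sign_change = np.nonzero(np.diff(np.sign(diffs)) != 0)[0]
    zeros = np.nonzero(diffs == 0)[0]
    if len(zeros):
        best = float(grid[zeros].mean())  # middle of an exact-match plateau
        achieved = 0.0
    elif len(sign_change):
        lo, hi = grid[sign_change[0]], grid[sign_change[0] + 1]
        dlo = diffs[sign_change[0]]
        while hi - lo > refine_tol:
            mid = (lo + hi) / 2.0
            dm = median_diff(mid)
            if dm == 0:
                lo = hi = mid
                break
            if np.sign(dm) == np.sign(dlo):
                lo, dlo = mid, dm
            else:
                hi = mid
        best = (lo + hi) / 2.0
        achieved = abs(median_diff(best))
    else:
        k = int(np.argmin(np.abs(diffs)))
        best, achieved = float(grid[k]), float(abs(diffs[k]))
        # the volume curves never cross: non-overlapping beyond a relative slack
        if achieved > rel_discrepancy * max(float(np.median(ref_vols)), 1e-9):
            raise CalibrationError(
                f"no protocol-B fraction equates T1 lesion volumes "
                f"(best discrepancy {achieved:.3f} cm^3)", curve=curve)
    logger.info("calibrated T1 fraction %.4f (discrepancy %.4f cm^3)", best, achieved)
    return CalibrationResult(fraction=float(best),
                             achieved_discrepancy_cm3=float(achieved), curve=curve)
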