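"""Synthetic multi-contrast brain phantoms with regional atlas and lesion ground truth.

The phantom emulates the two acquisition protocols of a pediatric/adult RRMS
imaging comparison: axial PD/T2-weighted images plus a T1-weighted volume, on
2 mm (pediatric) or 3 mm (adult) contiguous slices with 0.98 mm in-plane
sampling.  Anatomy is a nested-ellipsoid head: a supratentorial ellipsoid with
a white-matter core, grey-matter shell and paired lateral-ventricle CSF
compartments, and an infratentorial compartment made of a stacked
midbrain/pons/medulla brainstem column plus a cerebellum.  Lesions are
spheres implanted in white matter, PD/T2-hyperintense, with a controllable
fraction of each lesion's voxels rendered T1-hypointense (the chronic
"black hole" core).

Intensities are piecewise constant tissue means, modulated by a smooth
multiplicative bias field (exponentiated sum of broad Gaussian bumps) and
additive Gaussian noise.  Everything is generated from a single integer seed
and is bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

# region label codes
BACKGROUND = 0
SUPRATENTORIAL = 1
CEREBELLUM = 2
MIDBRAIN = 3
PONS = 4
MEDULLA = 5
VENTRICLES = 6

REGION_NAMES = {
    SUPRATENTORIAL: "supratentorial",
    CEREBELLUM: "cerebellum",
    MIDBRAIN: "midbrain",
    PONS: "pons",
    MEDULLA: "medulla",
    VENTRICLES: "ventricles",
}
REGION_CODES = {v: k for k, v in REGION_NAMES.items()}

# tissue label codes
TISSUE_BG = 0
TISSUE_WM = 1
TISSUE_GM = 2
TISSUE_CSF = 3

# reference fraction the T1 lesion intensity profile is anchored to: under the
# pediatric protocol the hypointense core is exactly the voxels whose T1
# intensity falls below this fraction of the WM mean.
T1_PROFILE_REFERENCE_FRACTION = 0.85

# minimal physical extent (mm) that holds every compartment of the geometry
_MIN_FOV_MM = (82.0, 92.0, 104.0)


class PhantomError(Exception):
    """Base class for phantom generation failures."""


class GridSizeError(PhantomError):
    """Grid too small to hold the compartment geometry."""


class PlacementError(PhantomError):
    """A requested lesion could not be placed after bounded retries."""


@dataclass(frozen=True)
class ProtocolSpec:
    """Acquisition protocol: sampling geometry, tissue contrast and T1 threshold.

    ``tissue_means`` maps tissue/lesion class name to (PD, T2, T1) mean
    intensities.  ``t1_lesion_scale`` rescales the T1 lesion intensity profile
    relative to the pediatric reference so that this protocol's
    ``t1_threshold_fraction`` selects the same hypointense core: the adult
    protocol's slightly different T1 contrast makes an 83% threshold
    equivalent to the pediatric 85%.
    """

    name: str
    slice_thickness_mm: float
    inplane_mm: float = 0.98
    tissue_means: dict = field(default_factory=dict)
    noise_sigma: float = 4.0
    t1_lesion_core_multiplier: float = 0.70
    t1_threshold_fraction: float = 0.85

    def __post_init__(self):
        if self.slice_thickness_mm <= 0 or self.inplane_mm <= 0:
            raise ValueError("voxel dimensions must be strictly positive")
        if not (0.0 < self.t1_lesion_core_multiplier < 1.0):
            raise ValueError("t1_lesion_core_multiplier must lie in (0,1)")
        if not (0.0 < self.t1_threshold_fraction < 1.0):
            raise ValueError("t1_threshold_fraction must lie in (0,1)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")

    @property
    def voxel_size(self) -> tuple:
        return (self.inplane_mm, self.inplane_mm, self.slice_thickness_mm)

    @property
    def t1_lesion_scale(self) -> float:
        return self.t1_threshold_fraction / T1_PROFILE_REFERENCE_FRACTION

    def contrast_ratio_t2(self) -> float:
        wm = self.tissue_means["WM"][1]
        gm = self.tissue_means["GM"][1]
        return wm / gm


def _default_tissue_means(wm_gm_t2_ratio: float = 1.36) -> dict:
    """Tissue class (PD, T2, T1) means.

    Absolute intensities are free parameters of the phantom; only contrast
    relationships matter: lesions bright on PD/T2, WM:GM T2 ratio near the
    configured value, CSF bright on T2 / dark on T1.
    """
    gm_t2 = 100.0
    wm_t2 = wm_gm_t2_ratio * gm_t2
    return {
        "WM": (120.0, wm_t2, 100.0),
        "GM": (125.0, gm_t2, 85.0),
        "CSF": (90.0, 180.0, 40.0),
        # lesion T1 entry is the rim value; the core follows the radial profile
        "lesion": (160.0, 1.5 * wm_t2, 100.0),
    }


def pediatric_protocol(**overrides) -> ProtocolSpec:
    kw = dict(
        name="pediatric",
        slice_thickness_mm=2.0,
        tissue_means=_default_tissue_means(1.36),
        t1_threshold_fraction=0.85,
    )
    kw.update(overrides)
    return ProtocolSpec(**kw)


def adult_protocol(**overrides) -> ProtocolSpec:
    kw = dict(
        name="adult",
        slice_thickness_mm=3.0,
        tissue_means=_default_tissue_means(1.38),
        t1_threshold_fraction=0.83,
    )
    kw.update(overrides)
    return ProtocolSpec(**kw)


def get_protocol(name: str, **overrides) -> ProtocolSpec:
    if name == "pediatric":
        return pediatric_protocol(**overrides)
    if name == "adult":
        return adult_protocol(**overrides)
    raise ValueError(f"unknown protocol {name!r}")


@dataclass(frozen=True)
class PhantomSpec:
    """Full recipe for one synthetic subject."""

    grid_shape: tuple = (96, 96, 60)
    protocol: ProtocolSpec = field(default_factory=pediatric_protocol)
    n_lesions_by_region: dict = field(default_factory=dict)
    lesion_radius_range_mm: tuple = (2.5, 6.0)
    # smaller radii for the narrow infratentorial compartments; defaults to
    # lesion_radius_range_mm when None
    infra_lesion_radius_range_mm: tuple | None = (1.8, 4.0)
    t1_core_fraction: float = 0.6
    bias_field_amplitude: float = 0.2
    seed: int = 0
    # optional: keep adding supratentorial lesions until the ground-truth T2
    # lesion volume reaches this target (cm^3)
    target_t2lv_cm3: float | None = None

    def __post_init__(self):
        if not (0.0 <= self.t1_core_fraction <= 1.0):
            raise ValueError("t1_core_fraction must lie in [0,1]")
        lo, hi = self.lesion_radius_range_mm
        if lo <= 0 or hi < lo:
            raise ValueError("lesion_radius_range_mm must be a positive interval")
        if self.bias_field_amplitude < 0:
            raise ValueError("bias_field_amplitude must be nonnegative")


@dataclass
class LesionRecord:
    lesion_id: int
    region: str
    center_voxel: tuple
    n_voxels: int
    volume_mm3: float
    n_t1_voxels: int


@dataclass
class GroundTruth:
    t2_lesion_mask: np.ndarray
    t1_lesion_mask: np.ndarray
    lesions: list
    true_bias_field: np.ndarray
    template_transform: np.ndarray  # 4x4 voxel-to-template affine

    @property
    def t2_voxel_count(self) -> int:
        return int(self.t2_lesion_mask.sum())

    @property
    def t1_voxel_count(self) -> int:
        return int(self.t1_lesion_mask.sum())


@dataclass
class RegionAtlas:
    """Voxelwise region labels plus tissue classes and derived masks."""

    labels: np.ndarray  # region codes, int16
    tissue: np.ndarray  # WM/GM/CSF codes, int16
    voxel_size: tuple
    periventricular_distance_mm: float = 3.0

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels != BACKGROUND

    @property
    def supratentorial_mask(self) -> np.ndarray:
        return self.labels == SUPRATENTORIAL

    @property
    def ventricle_mask(self) -> np.ndarray:
        return self.labels == VENTRICLES

    @property
    def brainstem_mask(self) -> np.ndarray:
        return np.isin(self.labels, (MIDBRAIN, PONS, MEDULLA))

    @property
    def infratentorial_mask(self) -> np.ndarray:
        return np.isin(self.labels, (CEREBELLUM, MIDBRAIN, PONS, MEDULLA))

    @property
    def wm_mask(self) -> np.ndarray:
        return self.tissue == TISSUE_WM

    @property
    def gm_mask(self) -> np.ndarray:
        return self.tissue == TISSUE_GM

    def region_mask(self, name: str) -> np.ndarray:
        if name == "whole_brain":
            return self.supratentorial_mask | self.infratentorial_mask
        if name == "supratentorial":
            return self.supratentorial_mask
        if name == "infratentorial":
            return self.infratentorial_mask
        if name == "brainstem":
            return self.brainstem_mask
        if name == "periventricular":
            return self.periventricular_mask()
        if name == "non_periventricular":
            pv = self.periventricular_mask()
            return (self.supratentorial_mask | self.infratentorial_mask) & ~pv
        if name in REGION_CODES:
            return self.labels == REGION_CODES[name]
        raise KeyError(f"unknown region {name!r}")

    def periventricular_mask(self, distance_mm: float | None = None) -> np.ndarray:
        """Brain voxels within ``distance_mm`` of the ventricles (dilation by
        Euclidean distance with anisotropic voxel sampling), ventricles included,
        restricted to the lesion-bearing brain (supra+infra compartments)."""
        d = self.periventricular_distance_mm if distance_mm is None else distance_mm
        if not hasattr(self, "_pv_cache"):
            object.__setattr__(self, "_pv_cache", {})
        if d in self._pv_cache:
            return self._pv_cache[d]
        vent = self.ventricle_mask
        if d <= 0:
            return vent
        dist = ndimage.distance_transform_edt(~vent, sampling=self.voxel_size)
        near = dist <= d
        out = (near & (self.supratentorial_mask | self.infratentorial_mask)) | vent
        self._pv_cache[d] = out
        return out


def _ellipsoid(coords, center, semi) -> np.ndarray:
    x, y, z = coords
    cx, cy, cz = center
    ax, ay, az = semi
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2


def build_region_atlas(grid_shape, voxel_size, periventricular_distance_mm: float = 3.0) -> RegionAtlas:
    """Construct the nested-ellipsoid region atlas on a voxel grid.

    Coordinates are physical mm, origin at the grid center.  The tentorium is
    the axial plane z = -14 mm: the supratentorial ellipsoid sits above it,
    the brainstem column and cerebellum below.
    """
    grid_shape = tuple(int(s) for s in grid_shape)
    voxel_size = tuple(float(v) for v in voxel_size)
    fov = tuple(s * v for s, v in zip(grid_shape, voxel_size))
    if any(f < m for f, m in zip(fov, _MIN_FOV_MM)):
        raise GridSizeError(
            f"field of view {fov} mm is below the minimal compartment geometry {_MIN_FOV_MM} mm"
        )

    idx = np.indices(grid_shape, dtype=np.float64)
    coords = [(idx[a] - (grid_shape[a] - 1) / 2.0) * voxel_size[a] for a in range(3)]
    z = coords[2]

    labels = np.zeros(grid_shape, dtype=np.int16)
    tissue = np.zeros(grid_shape, dtype=np.int16)

    tent_z = -14.0

    # supratentorial ellipsoid with GM shell and WM core
    rho2 = _ellipsoid(coords, (0.0, 0.0, 18.0), (38.0, 44.0, 32.0))
    supra = (rho2 <= 1.0) & (z >= tent_z)
    labels[supra] = SUPRATENTORIAL
    tissue[supra & (rho2 > 0.82**2)] = TISSUE_GM
    tissue[supra & (rho2 <= 0.82**2)] = TISSUE_WM

    # paired lateral ventricles (CSF) inside the supratentorial WM
    for sx in (-10.0, 10.0):
        v2 = _ellipsoid(coords, (sx, 6.0, 16.0), (5.0, 16.0, 7.0))
        vent = (v2 <= 1.0) & supra
        labels[vent] = VENTRICLES
        tissue[vent] = TISSUE_CSF

    # brainstem column: midbrain / pons / medulla slabs of a vertical cylinder
    x, y = coords[0], coords[1]
    col = ((x / 7.5) ** 2 + ((y + 6.0) / 7.5) ** 2 <= 1.0) & (z < tent_z) & (z >= -48.0)
    for code, zlo, zhi in ((MIDBRAIN, -24.0, tent_z), (PONS, -36.0, -24.0), (MEDULLA, -48.0, -36.0)):
        slab = col & (z >= zlo) & (z < zhi)
        labels[slab] = code
        tissue[slab] = TISSUE_WM

    # cerebellum: posterior-inferior ellipsoid around the column, GM shell + WM core
    c2 = _ellipsoid(coords, (0.0, -20.0, -30.0), (28.0, 20.0, 15.0))
    cereb = (c2 <= 1.0) & (z < tent_z) & ~col
    labels[cereb] = CEREBELLUM
    tissue[cereb & (c2 > 0.7**2)] = TISSUE_GM
    tissue[cereb & (c2 <= 0.7**2)] = TISSUE_WM

    atlas = RegionAtlas(labels=labels, tissue=tissue, voxel_size=voxel_size,
                        periventricular_distance_mm=periventricular_distance_mm)
    for name in ("supratentorial", "cerebellum", "midbrain", "pons", "medulla"):
        if not np.any(atlas.region_mask(name) & atlas.wm_mask):
            raise GridSizeError(f"region {name} has no white matter at this grid size")
    return atlas


def _sphere_offsets(radius_mm: float, voxel_size) -> np.ndarray:
    """Integer voxel offsets covered by a sphere of the given physical radius."""
    half = [int(np.floor(radius_mm / v)) for v in voxel_size]
    rng = [np.arange(-h, h + 1) for h in half]
    dx, dy, dz = np.meshgrid(*rng, indexing="ij")
    d2 = (dx * voxel_size[0]) ** 2 + (dy * voxel_size[1]) ** 2 + (dz * voxel_size[2]) ** 2
    keep = d2 <= radius_mm**2
    offs = np.stack([dx[keep], dy[keep], dz[keep]], axis=1)
    dist = np.sqrt(d2[keep])
    return offs, dist


class _LesionPlacer:
    """Places non-touching spheres inside region white matter."""

    MAX_TRIES = 200

    def __init__(self, atlas: RegionAtlas, rng: np.random.Generator):
        self.atlas = atlas
        self.rng = rng
        self.occupied = np.zeros(atlas.labels.shape, dtype=bool)  # lesions + 1-voxel margin
        self.t2_mask = np.zeros(atlas.labels.shape, dtype=bool)
        # distance (mm) from each WM voxel of a region to the region-WM boundary
        self._depth = {}

    def _region_depth(self, region: str) -> np.ndarray:
        if region not in self._depth:
            wm = self.atlas.region_mask(region) & self.atlas.wm_mask
            self._depth[region] = ndimage.distance_transform_edt(wm, sampling=self.atlas.voxel_size)
        return self._depth[region]

    def place(self, region: str, radius_range) -> tuple:
        """Place one sphere fully inside the region's WM, not touching (26-adjacent
        to) any existing lesion.  Returns (voxel index array, center, radius,
        center distances)."""
        depth = self._region_depth(region)
        lo, hi = radius_range
        # small compartments (pons, medulla, ...) cannot host the largest radii:
        # never draw beyond what fits in the empty region, and shrink the cap
        # toward the minimum as tries fail so crowded regions still fill up
        hi = min(hi, float(depth.max()))
        if hi < lo:
            raise PlacementError(
                f"no sphere of radius >= {lo} mm fits inside {region} WM")
        for attempt in range(self.MAX_TRIES):
            if attempt and attempt % 20 == 0:
                hi = max(lo, 0.8 * hi)
            r = float(self.rng.uniform(lo, hi))
            candidates = np.argwhere((depth >= r + 1e-9) & ~self.occupied)
            if candidates.size == 0:
                continue
            center = candidates[self.rng.integers(len(candidates))]
            offs, dist = _sphere_offsets(r, self.atlas.voxel_size)
            vox = center[None, :] + offs
            ix, iy, iz = vox[:, 0], vox[:, 1], vox[:, 2]
            if np.any(self.occupied[ix, iy, iz]):
                continue
            self.t2_mask[ix, iy, iz] = True
            # 1-voxel 26-connected margin keeps distinct lesions separated;
            # dilate only within the lesion's bounding box
            sl = tuple(slice(max(0, vox[:, a].min() - 2),
                             min(self.occupied.shape[a], vox[:, a].max() + 3))
                       for a in range(3))
            local = np.zeros(tuple(s.stop - s.start for s in sl), dtype=bool)
            local[ix - sl[0].start, iy - sl[1].start, iz - sl[2].start] = True
            local = ndimage.binary_dilation(local, structure=np.ones((3, 3, 3), bool))
            self.occupied[sl] |= local
            return vox, tuple(int(c) for c in center), r, dist
        raise PlacementError(
            f"could not place a lesion of radius in {radius_range} mm inside {region} WM "
            f"after {self.MAX_TRIES} tries"
        )


def _t1_profile_exponent(core_mult: float, core_fraction: float) -> tuple:
    """Exponent gamma of the radial T1 multiplier m(d) = core + (1-core) * d**gamma
    such that the fraction of sphere volume with m below the reference threshold
    equals ``core_fraction`` (d = r/R)."""
    f = T1_PROFILE_REFERENCE_FRACTION
    q = core_fraction ** (1.0 / 3.0)  # radius fraction enclosing the volume fraction
    if q <= 0.0 or q >= 1.0:
        return None, q
    gamma = np.log((f - core_mult) / (1.0 - core_mult)) / np.log(q)
    return gamma, q


def _lesion_t1_multiplier(dist: np.ndarray, radius: float, core_mult: float,
                          core_fraction: float) -> np.ndarray:
    """Radial T1 intensity multiplier (relative to WM mean, pediatric reference
    contrast) for each lesion voxel; strictly increasing from the center."""
    f = T1_PROFILE_REFERENCE_FRACTION
    d = np.clip(dist / max(radius, 1e-9), 0.0, 1.0)
    gamma, q = _t1_profile_exponent(core_mult, core_fraction)
    if q <= 0.0:
        # no hypointense core: keep every voxel at or above the reference fraction
        return f + (1.0 - f) * d
    if q >= 1.0:
        # fully hypointense: ramp from the core multiplier up to just under f
        return core_mult + (f - 1e-6 - core_mult) * d
    return core_mult + (1.0 - core_mult) * d**gamma


def _bias_log_field(shape, voxel_size, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Sum of 2-3 broad 3-D Gaussian bumps, scaled so the log-field peak-to-peak
    range is about ``amplitude``; smooth and (after exp) strictly positive."""
    if amplitude <= 0:
        return np.zeros(shape)
    idx = np.indices(shape, dtype=np.float64)
    coords = [idx[a] * voxel_size[a] for a in range(3)]
    fov = [s * v for s, v in zip(shape, voxel_size)]
    n_bumps = int(rng.integers(2, 4))
    logf = np.zeros(shape)
    for _ in range(n_bumps):
        center = [rng.uniform(0.2 * f, 0.8 * f) for f in fov]
        width = [rng.uniform(30.0, 60.0) for _ in range(3)]
        sign = rng.choice([-1.0, 1.0])
        bump = np.exp(-sum(((c - mu) / w) ** 2 for c, mu, w in zip(coords, center, width)))
        logf += sign * bump
    span = logf.max() - logf.min()
    if span > 0:
        logf *= amplitude / span
    return logf - logf.mean()


def generate_subject(spec: PhantomSpec) -> tuple:
    """Generate one subject's co-registered PD/T2/T1 volumes and ground truth.

    Deterministic in ``spec.seed``: the same spec yields bit-identical volumes.
    """
    from .types import SubjectScan  # local import to avoid a cycle

    rng = np.random.default_rng(spec.seed)
    proto = spec.protocol
    atlas = build_region_atlas(spec.grid_shape, proto.voxel_size)
    voxel_vol = float(np.prod(proto.voxel_size))

    placer = _LesionPlacer(atlas, rng)
    lesion_voxels = []  # (vox, center, radius, dist, region)
    infra_range = spec.infra_lesion_radius_range_mm or spec.lesion_radius_range_mm
    for region, n in sorted(spec.n_lesions_by_region.items()):
        if region not in ("supratentorial", "cerebellum", "midbrain", "pons", "medulla"):
            raise PhantomError(f"cannot place lesions in region {region!r}")
        rng_mm = spec.lesion_radius_range_mm if region == "supratentorial" else infra_range
        for _ in range(int(n)):
            vox, center, r, dist = placer.place(region, rng_mm)
            lesion_voxels.append((vox, center, r, dist, region))

    if spec.target_t2lv_cm3 is not None:
        target_vox = spec.target_t2lv_cm3 * 1000.0 / voxel_vol
        while placer.t2_mask.sum() < target_vox:
            remaining_mm3 = (target_vox - placer.t2_mask.sum()) * voxel_vol
            lo, hi = spec.lesion_radius_range_mm
            # shrink the radius cap near the target to land close to it
            r_cap = min(hi, max(lo, (3.0 * remaining_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)))
            vox, center, r, dist = placer.place("supratentorial", (lo, r_cap))
            lesion_voxels.append((vox, center, r, dist, "supratentorial"))

    shape = spec.grid_shape
    pd_w = np.zeros(shape)
    t2_w = np.zeros(shape)
    t1_w = np.zeros(shape)
    means = proto.tissue_means
    for code, cls in ((TISSUE_WM, "WM"), (TISSUE_GM, "GM"), (TISSUE_CSF, "CSF")):
        m = atlas.tissue == code
        pd_w[m], t2_w[m], t1_w[m] = means[cls]

    wm_t1 = means["WM"][2]
    t1_mask = np.zeros(shape, dtype=bool)
    records = []
    for i, (vox, center, r, dist, region) in enumerate(lesion_voxels):
        ix, iy, iz = vox[:, 0], vox[:, 1], vox[:, 2]
        pd_w[ix, iy, iz] = means["lesion"][0]
        t2_w[ix, iy, iz] = means["lesion"][1]
        mult = _lesion_t1_multiplier(dist, r, proto.t1_lesion_core_multiplier,
                                     spec.t1_core_fraction)
        t1_w[ix, iy, iz] = wm_t1 * proto.t1_lesion_scale * mult
        core = mult < T1_PROFILE_REFERENCE_FRACTION
        t1_mask[ix[core], iy[core], iz[core]] = True
        records.append(LesionRecord(
            lesion_id=i + 1, region=region, center_voxel=center,
            n_voxels=len(vox), volume_mm3=len(vox) * voxel_vol,
            n_t1_voxels=int(core.sum()),
        ))

    logf = _bias_log_field(shape, proto.voxel_size, spec.bias_field_amplitude, rng)
    bias = np.exp(logf)
    brain = atlas.brain_mask
    bias /= bias[brain].mean()

    noise = proto.noise_sigma
    for vol in (pd_w, t2_w, t1_w):
        vol *= bias
        if noise > 0:
            vol += rng.normal(0.0, noise, size=shape)
        np.copyto(vol, 0.0, where=~brain)

    scan = SubjectScan(
        subject_id=f"{proto.name}-{spec.seed}",
        pd=pd_w, t2=t2_w, t1=t1_w,
        brain_mask=brain.copy(),
        voxel_size=proto.voxel_size,
        protocol=proto.name,
    )
    truth = GroundTruth(
        t2_lesion_mask=placer.t2_mask,
        t1_lesion_mask=t1_mask,
        lesions=records,
        true_bias_field=bias,
        template_transform=np.eye(4),
    )
    logger.info("phantom subject=%s protocol=%s lesions=%d t2_voxels=%d",
                scan.subject_id, proto.name, len(records), truth.t2_voxel_count)
    return scan, truth


@dataclass(frozen=True)
class CohortSampler:
    """Distribution over PhantomSpec emulating one study arm.

    Defaults for each arm follow the study conditions: per-subject total T2
    lesion volume drawn from a normal with the arm's reported mean/SD (cm^3),
    infratentorial lesions present with the arm's reported incidence, and—
    when present—a count near the arm's reported infratentorial mean, split
    among pons, midbrain, medulla and cerebellum.
    """

    protocol: ProtocolSpec
    t2lv_mean_cm3: float
    t2lv_sd_cm3: float
    infratentorial_probability: float
    mean_infratentorial_lesions: float = 2.0
    infratentorial_region_probs: dict = field(default_factory=lambda: {
        "pons": 0.45, "midbrain": 0.125, "medulla": 0.125, "cerebellum": 0.3})
    t1_core_fraction: float = 0.6
    grid_shape: tuple = (96, 96, 60)
    bias_field_amplitude: float = 0.2
    lesion_radius_range_mm: tuple = (2.5, 6.0)

    def __post_init__(self):
        if not (0.0 <= self.infratentorial_probability <= 1.0):
            raise PhantomError("infratentorial_probability must lie in [0,1]")
        if self.t2lv_sd_cm3 < 0 or self.t2lv_mean_cm3 <= 0:
            raise PhantomError("t2lv mean must be positive and sd nonnegative")
        if self.mean_infratentorial_lesions < 1.0:
            raise PhantomError("mean_infratentorial_lesions must be >= 1")

    def sample_spec(self, rng: np.random.Generator, seed: int) -> PhantomSpec:
        target = max(1.0, rng.normal(self.t2lv_mean_cm3, self.t2lv_sd_cm3))
        n_by_region: dict = {}
        if rng.uniform() < self.infratentorial_probability:
            # cap totals and per-compartment counts so the narrow brainstem
            # segments can host their share; overflow goes to the cerebellum
            n_infra = min(6, 1 + rng.poisson(self.mean_infratentorial_lesions - 1.0))
            regions = list(self.infratentorial_region_probs)
            probs = np.array([self.infratentorial_region_probs[r] for r in regions])
            probs = probs / probs.sum()
            for r in rng.choice(regions, size=n_infra, p=probs):
                if r != "cerebellum" and n_by_region.get(r, 0) >= 3:
                    r = "cerebellum"
                n_by_region[r] = n_by_region.get(r, 0) + 1
        return PhantomSpec(
            grid_shape=self.grid_shape,
            protocol=self.protocol,
            n_lesions_by_region=n_by_region,
            lesion_radius_range_mm=self.lesion_radius_range_mm,
            t1_core_fraction=self.t1_core_fraction,
            bias_field_amplitude=self.bias_field_amplitude,
            seed=seed,
            target_t2lv_cm3=target,
        )


def pediatric_cohort_sampler(**overrides) -> CohortSampler:
    """Pediatric RRMS arm: T2LV 12.76 (2.7) cm^3, infratentorial incidence 75.9%,
    mean infratentorial count 4.1."""
    kw = dict(protocol=pediatric_protocol(), t2lv_mean_cm3=12.76, t2lv_sd_cm3=2.7,
              infratentorial_probability=0.759, mean_infratentorial_lesions=4.1,
              t1_core_fraction=0.70)
    kw.update(overrides)
    return CohortSampler(**kw)


def adult_cohort_sampler(**overrides) -> CohortSampler:
    """Adult RRMS arm: T2LV 10.03 (3.4) cm^3, infratentorial incidence 43.4%,
    mean infratentorial count 1.45."""
    kw = dict(protocol=adult_protocol(), t2lv_mean_cm3=10.03, t2lv_sd_cm3=3.4,
              infratentorial_probability=0.434, mean_infratentorial_lesions=1.45,
              t1_core_fraction=0.62, grid_shape=(96, 96, 40))
    kw.update(overrides)
    return CohortSampler(**kw)


def generate_cohort(n_subjects: int, sampler: CohortSampler, seed: int) -> list:
    """Generate a cohort; per-subject seeds derive deterministically from ``seed``."""
    if n_subjects < 1:
        raise PhantomError("n_subjects must be >= 1")
    master = np.random.default_rng(seed)
    subject_seeds = master.integers(0, 2**31 - 1, size=n_subjects)
    out = []
    for i, s in enumerate(subject_seeds):
        spec = sampler.sample_spec(np.random.default_rng(int(s)), seed=int(s))
        scan, truth = generate_subject(spec)
        scan.subject_id = f"{sampler.protocol.name}-{seed}-{i:03d}"
        out.append((scan, truth))
    return out


def generate_paired_calibration_subjects(n: int, seed: int,
                                         grid_shape=(96, 96, 40),
                                         t2lv_cm3: float = 10.0,
                                         t1_core_fraction: float = 0.6) -> list:
    """Same-anatomy subject pairs under the pediatric and adult T1 contrasts,
    both sampled on the adult slice geometry (the calibration scans of the
    source study were acquired back-to-back on one scanner).

    Returns a list of (scan_pediatric_contrast, scan_adult_contrast, truth)
    triples; lesion geometry and ground truth are identical within a pair, so
    an adult-protocol threshold of 0.83 reproduces the pediatric 0.85 core by
    construction.
    """
    master = np.random.default_rng(seed)
    pairs = []
    proto_a = pediatric_protocol(slice_thickness_mm=3.0)  # pediatric contrast, adult sampling
    proto_b = adult_protocol()
    for i in range(n):
        s = int(master.integers(0, 2**31 - 1))
        spec_a = PhantomSpec(grid_shape=grid_shape, protocol=proto_a,
                             n_lesions_by_region={"pons": 1},
                             t1_core_fraction=t1_core_fraction, seed=s,
                             target_t2lv_cm3=t2lv_cm3)
        spec_b = replace(spec_a, protocol=proto_b)
        scan_a, truth = generate_subject(spec_a)
        scan_b, _ = generate_subject(spec_b)
        scan_a.subject_id = f"calib-{i:02d}-pediatric"
        scan_b.subject_id = f"calib-{i:02d}-adult"
        pairs.append((scan_a, scan_b, truth))
    return pairs
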