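"""Shared in-memory containers passed between pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SubjectScan:
    """Co-registered PD/T2/T1 volumes, brain mask and protocol tag for one subject.

    Volumes share one grid; ``voxel_size`` is (x, y, z) in mm with z the slice
    axis.  ``normalized`` flags whether intensities are on the standard scale.
    """

    subject_id: str
    pd: np.ndarray
    t2: np.ndarray
    t1: np.ndarray
    brain_mask: np.ndarray
    voxel_size: tuple
    protocol: str
    normalized: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        shapes = {self.pd.shape, self.t2.shape, self.t1.shape, self.brain_mask.shape}
        if len(shapes) != 1:
            raise ValueError(f"contrast volumes disagree in shape: {shapes}")

    @property
    def shape(self) -> tuple:
        return self.t2.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))

    def contrasts(self) -> dict:
        return {"pd": self.pd, "t2": self.t2, "t1": self.t1}

    def stack(self) -> np.ndarray:
        """(n_voxels, 3) feature matrix over the whole grid in (PD, T2, T1) order."""
        return np.stack([self.pd.ravel(), self.t2.ravel(), self.t1.ravel()], axis=1)
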