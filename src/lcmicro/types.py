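"""Core containers shared by all pipeline stages.

Axis convention: arrays are indexed ``(fast, slow, axial)``.  The fast and
slow axes are the two lateral (en-face) scan directions; the axial axis is
depth.  A C-mode slice is ``data[:, :, k]``.  Voxel spacing is anisotropic:
the default scan geometry (3.5 x 3.5 x 3.64 mm over 400 x 400 x 896 voxels)
gives 8.75 um laterally and 4.0625 um axially.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Segmentation label values (also the pixel values written to TIFF stacks).
OUTSIDE = 0
PORE = 1
BEAM = 2

LABEL_NAMES = {OUTSIDE: "outside", PORE: "pore", BEAM: "beam"}

#: Lateral spacing (um/voxel) of the nominal ONH cube scan: 3500 um / 400 px.
DEFAULT_LATERAL_SPACING = 3500.0 / 400.0
#: Axial spacing (um/voxel): 3640 um / 896 px.
DEFAULT_AXIAL_SPACING = 3640.0 / 896.0


@dataclass(frozen=True)
class VoxelGrid:
    """Shape and physical spacing of a scan volume.

    Parameters
    ----------
    shape
        Voxel counts ``(n_fast, n_slow, n_axial)``.
    spacing
        Voxel edge lengths ``(dx, dy, dz)`` in micrometres.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (
        DEFAULT_LATERAL_SPACING,
        DEFAULT_LATERAL_SPACING,
        DEFAULT_AXIAL_SPACING,
    )

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or len(self.spacing) != 3:
            raise ValueError("VoxelGrid is three-dimensional")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        if any(n < 1 for n in self.shape):
            raise ValueError(f"voxel counts must be >= 1, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacings must be > 0, got {self.spacing}")

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical size (um) along each axis."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    def to_dict(self) -> dict:
        return {"shape": list(self.shape), "spacing": list(self.spacing)}

    @classmethod
    def from_dict(cls, d: dict) -> "VoxelGrid":
        return cls(shape=tuple(d["shape"]), spacing=tuple(d["spacing"]))


@dataclass
class Volume:
    """A 3D scalar intensity volume on a :class:`VoxelGrid`."""

    data: np.ndarray
    grid: VoxelGrid

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.shape != self.grid.shape:
            raise ValueError(
                f"data shape {self.data.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume intensities must be finite")
        if self.data.min() < 0:
            raise ValueError("volume intensities must be >= 0")

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.grid)


@dataclass
class Segmentation:
    """Three-label voxel classification: OUTSIDE (0), PORE (1), BEAM (2).

    BEAM | PORE together form the analyzable-LC mask; everything the
    quality mask rejected is OUTSIDE.
    """

    labels: np.ndarray
    grid: VoxelGrid

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.shape != self.grid.shape:
            raise ValueError(
                f"labels shape {self.labels.shape} != grid shape {self.grid.shape}"
            )
        bad = set(np.unique(self.labels)) - {OUTSIDE, PORE, BEAM}
        if bad:
            raise ValueError(f"unexpected label values: {sorted(bad)}")

    @property
    def mask(self) -> np.ndarray:
        """Boolean analyzable-LC mask (BEAM or PORE)."""
        return self.labels != OUTSIDE

    def phase_mask(self, phase: int) -> np.ndarray:
        if phase not in (PORE, BEAM):
            raise ValueError(f"phase must be PORE ({PORE}) or BEAM ({BEAM})")
        return self.labels == phase

    def copy(self) -> "Segmentation":
        return Segmentation(self.labels.copy(), self.grid)


@dataclass
class ThicknessMap:
    """Per-voxel local thickness (um) of one phase.

    ``values[p]`` is the diameter of the largest sphere that contains voxel
    ``p`` and fits entirely within the phase; zero outside the phase.
    """

    values: np.ndarray
    grid: VoxelGrid
    phase: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise ValueError("thickness map shape mismatch with grid")
        if self.values.min() < 0:
            raise ValueError("thickness values must be >= 0")


@dataclass(frozen=True)
class LCParams:
    """The per-scan microarchitecture parameter set.

    The seven headline parameters (pore diameter and SD, beam thickness and
    SD, beam-to-pore ratio, pore area, pore aspect ratio) plus the slice and
    pore-count bookkeeping quantities.  Pore counts depend on how much LC is
    visible in a particular scan, so they are reported for inspection but
    excluded from repeatability statistics by default.
    """

    pore_diameter_mean: float
    pore_diameter_sd: float
    beam_thickness_mean: float
    beam_thickness_sd: float
    beam_pore_ratio: float
    pore_area_mean: float
    pore_aspect_ratio_mean: float
    n_slices_with_pores: int
    pore_count_top_half: int
    pore_count_bottom_half: int

    #: names of the parameters fed to imprecision statistics by default
    REPEATABILITY_PARAMS = (
        "pore_diameter_mean",
        "pore_diameter_sd",
        "beam_thickness_mean",
        "beam_thickness_sd",
        "beam_pore_ratio",
        "pore_area_mean",
        "pore_aspect_ratio_mean",
    )

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.REPEATABILITY_PARAMS}
        d["n_slices_with_pores"] = self.n_slices_with_pores
        d["pore_count_top_half"] = self.pore_count_top_half
        d["pore_count_bottom_half"] = self.pore_count_bottom_half
        return d
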