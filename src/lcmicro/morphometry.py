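"""Microarchitecture morphometry of a segmented lamina cribrosa.

Two families of parameters are computed from a :class:`~lcmicro.types.Segmentation`:

* 3D sphere-fitting statistics — pore diameter and beam thickness are the
  local thickness (diameter of the largest inscribed sphere through each
  voxel) of the pore and beam phases, averaged voxel-wise over the phase.
* Per-C-mode-slice pore morphometry — 8-connected pore components on each
  en-face slice yield pore area and the aspect ratio of the
  moment-equivalent ellipse.

Spheres are physical (micrometre) spheres: with 8.75 um lateral and
4.0625 um axial voxels, a sphere that is round in voxel units would be more
than twice too tall, so every distance here carries the grid spacing.
The OUTSIDE label is treated as background for both phases, i.e. inscribed
spheres may not cross the analyzable-LC mask boundary; thickness is
therefore biased low at the mask edge, which is the expected edge effect of
a conservatively masked scan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from ._thickness import _paint_spheres, _ridge_mask
from .types import BEAM, OUTSIDE, PORE, LCParams, Segmentation, ThicknessMap

__all__ = [
    "PoreComponent",
    "local_thickness",
    "thickness_stats",
    "slice_pores",
    "compute_params",
]


@dataclass(frozen=True)
class PoreComponent:
    """One 8-connected pore cross-section on a single C-mode slice."""

    slice_index: int
    area: float  # um^2
    major_axis: float  # um
    minor_axis: float  # um
    centroid: tuple[float, float]  # (fast, slow) um

    def __post_init__(self) -> None:
        if not (self.major_axis >= self.minor_axis > 0):
            raise ValueError("require major_axis >= minor_axis > 0")
        if self.area <= 0:
            raise ValueError("area must be positive")

    @property
    def aspect_ratio(self) -> float:
        return self.major_axis / self.minor_axis


def _phase_radii(seg: Segmentation, phase: int):
    """Squared inscribed-sphere radius at every phase voxel.

    The Euclidean distance transform (with per-axis spacing) gives the
    nearest background voxel; the squared radius is recomputed from the
    index offset so it is exact in float arithmetic.
    """
    inphase = seg.phase_mask(phase)
    spacing = np.asarray(seg.grid.spacing, dtype=np.float64)
    _, idx = ndimage.distance_transform_edt(
        inphase, sampling=spacing, return_indices=True, return_distances=True
    )
    ii, jj, kk = np.indices(seg.labels.shape)
    r2 = (
        ((idx[0] - ii) * spacing[0]) ** 2
        + ((idx[1] - jj) * spacing[1]) ** 2
        + ((idx[2] - kk) * spacing[2]) ** 2
    )
    r2[~inphase] = 0.0
    return inphase, r2, spacing


def local_thickness(seg: Segmentation, phase: int) -> ThicknessMap:
    """Local thickness transform of one phase (maximal inscribed spheres).

    For every voxel ``p`` of the phase the value is the diameter (um) of the
    largest sphere that both contains ``p`` and fits entirely inside the
    phase.  Background (the other phase and OUTSIDE) limits the spheres; the
    array boundary does not, so structures touching the volume edge are not
    artificially thinned there.

    Returns an all-zero map with a warning if the phase is empty.
    """
    inphase, r2, spacing = _phase_radii(seg, phase)
    tmap = np.zeros(seg.labels.shape, dtype=np.float64)
    if not inphase.any():
        warnings.warn(f"empty {('', 'pore', 'beam')[phase]} phase; thickness map is all zero")
        return ThicknessMap(tmap, seg.grid, phase)

    keep = _ridge_mask(r2, inphase, spacing)
    centers = np.argwhere(keep)
    r2s = r2[keep]
    order = np.argsort(-r2s, kind="stable")
    _paint_spheres(
        np.ascontiguousarray(centers[order]),
        np.ascontiguousarray(r2s[order]),
        tmap,
        spacing,
    )
    return ThicknessMap(tmap, seg.grid, phase)


def thickness_stats(tmap: ThicknessMap) -> tuple[float, float]:
    """Voxel-weighted mean and population SD (um) over the measured phase."""
    vals = tmap.values[tmap.values > 0]
    if vals.size == 0:
        raise ValueError("thickness map has no positive voxels")
    return float(vals.mean()), float(vals.std())


def slice_pores(seg: Segmentation, min_pixels: int = 4) -> list[PoreComponent]:
    """Per-C-mode-slice pore components with moment-ellipse morphometry.

    On each en-face slice, 8-connected PORE components are extracted;
    components touching the analyzable mask boundary (adjacent to OUTSIDE or
    the image edge) are excluded because their shape is truncated, and
    components below ``min_pixels`` are discarded as segmentation specks.
    Major/minor axes come from the second central moments
    (moment-equivalent ellipse), in physical units.
    """
    dx, dy = seg.grid.spacing[0], seg.grid.spacing[1]
    out: list[PoreComponent] = []
    eight = np.ones((3, 3), dtype=bool)
    for k in range(seg.grid.shape[2]):
        sl = seg.labels[:, :, k]
        pores = sl == PORE
        if not pores.any():
            continue
        lab, _ = ndimage.label(pores, structure=eight)
        # components whose 8-dilation touches OUTSIDE or the image border
        outside = sl == OUTSIDE
        border = np.zeros_like(outside)
        border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
        touch_zone = ndimage.binary_dilation(outside | border, structure=eight)
        excluded = set(np.unique(lab[touch_zone & pores]))
        for rp in measure.regionprops(lab, spacing=(dx, dy)):
            if rp.label in excluded or rp.num_pixels < min_pixels:
                continue
            major, minor = rp.axis_major_length, rp.axis_minor_length
            if minor <= 0:  # degenerate (collinear pixels)
                continue
            out.append(
                PoreComponent(
                    slice_index=k,
                    area=float(rp.area),
                    major_axis=float(major),
                    minor_axis=float(minor),
                    centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
                )
            )
    return out


def compute_params(
    seg: Segmentation,
    pore_area_per_slice: bool = False,
    boundary_smooth: float = 0.0,
) -> LCParams:
    """All Table-style microarchitecture parameters for one scan.

    Parameters
    ----------
    seg
        Segmentation with non-empty beam and pore phases.
    pore_area_per_slice
        If True, pore area (and aspect ratio) are first averaged within each
        slice and then across slices; default pools every component in the
        scan volume.
    boundary_smooth
        Physical radius (um) of a majority-vote regularization of the
        beam/pore interface applied before measuring.  Sphere fitting is
        very sensitive to boundary roughness left by image noise — a single
        mislabelled protrusion caps every inscribed sphere it pierces — so
        the pipeline passes a radius scaled to the measured noise level;
        0 (default) measures the labels as given.

    Notes
    -----
    ``beam_pore_ratio`` is beam_thickness_mean / pore_diameter_mean by
    construction, so the invariant holds bit-exactly.  The top/bottom pore
    count split is at the axial midpoint of the mask's occupied slice range;
    a component exactly on the midpoint counts as top.
    """
    if boundary_smooth > 0:
        from .segmentation import smooth_labels

        seg = smooth_labels(seg, boundary_smooth)
    if not (seg.labels == PORE).any():
        raise ValueError("empty pore phase")
    if not (seg.labels == BEAM).any():
        raise ValueError("empty beam phase")

    pore_mean, pore_sd = thickness_stats(local_thickness(seg, PORE))
    beam_mean, beam_sd = thickness_stats(local_thickness(seg, BEAM))

    comps = slice_pores(seg)
    if comps:
        if pore_area_per_slice:
            by_slice: dict[int, list[PoreComponent]] = {}
            for c in comps:
                by_slice.setdefault(c.slice_index, []).append(c)
            area = float(
                np.mean([np.mean([c.area for c in v]) for v in by_slice.values()])
            )
            aspect = float(
                np.mean([np.mean([c.aspect_ratio for c in v]) for v in by_slice.values()])
            )
        else:
            area = float(np.mean([c.area for c in comps]))
            aspect = float(np.mean([c.aspect_ratio for c in comps]))
        slices = sorted({c.slice_index for c in comps})
        n_slices = len(slices)
        occupied = np.nonzero(seg.mask.any(axis=(0, 1)))[0]
        mid = 0.5 * (occupied[0] + occupied[-1])
        top = sum(1 for c in comps if c.slice_index <= mid)
        bottom = len(comps) - top
    else:
        area = float("nan")
        aspect = float("nan")
        n_slices = top = bottom = 0

    return LCParams(
        pore_diameter_mean=pore_mean,
        pore_diameter_sd=pore_sd,
        beam_thickness_mean=beam_mean,
        beam_thickness_sd=beam_sd,
        beam_pore_ratio=beam_mean / pore_mean,
        pore_area_mean=area,
        pore_aspect_ratio_mean=aspect,
        n_slices_with_pores=n_slices,
        pore_count_top_half=top,
        pore_count_bottom_half=bottom,
    )
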