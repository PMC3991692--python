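"""Independent brute-force oracle for the local thickness transform.

Evaluates the maximal-inscribed-sphere definition directly, with no shared
code with the implementation: every phase voxel is a candidate sphere
centre whose radius is the minimum physical distance to any background
voxel; a voxel's thickness is the largest diameter over all spheres that
strictly contain it.  O(n^2) in the number of voxels — only usable on tiny
volumes, which is the point.
"""

from __future__ import annotations

import numpy as np


def brute_force_local_thickness(
    phase_mask: np.ndarray, spacing: tuple[float, float, float]
) -> np.ndarray:
    sp = np.asarray(spacing, dtype=np.float64)
    inph = np.asarray(phase_mask, dtype=bool)
    out = np.zeros(inph.shape, dtype=np.float64)
    centers = np.argwhere(inph)
    background = np.argwhere(~inph)
    if centers.size == 0 or background.size == 0:
        return out
    # squared radius of the inscribed sphere at each candidate centre
    d2_cb = (((centers[:, None, :] - background[None, :, :]) * sp) ** 2).sum(-1)
    r2 = d2_cb.min(axis=1)
    # pairwise squared distances between phase voxels
    d2_pc = (((centers[:, None, :] - centers[None, :, :]) * sp) ** 2).sum(-1)
    for i, p in enumerate(centers):
        covering = d2_pc[i] < r2
        if covering.any():
            out[tuple(p)] = 2.0 * np.sqrt(r2[covering].max())
    return out
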