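"""Numba kernels for the maximal-inscribed-sphere local thickness transform.

The transform follows the classic three-step scheme used for trabecular
morphometry: (1) exact Euclidean distance transform of the phase with
physical (anisotropic) voxel spacing, (2) reduction to a distance ridge by
discarding spheres wholly contained in a 26-neighbour's sphere, and
(3) sphere painting — each ridge sphere writes its diameter into every voxel
it covers, keeping the maximum.

A voxel ``p`` is covered by the sphere centred at ``c`` with radius ``r``
iff ``dist(p, c) < r`` (strict: the voxel at exactly ``r`` is the nearest
background voxel).  All distances are squared physical distances computed as
``(di*dx)**2 + (dj*dy)**2 + (dk*dz)**2`` so that results agree bit-for-bit
with a brute-force evaluation of the same definition.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=True)
def _ridge_mask(r2: np.ndarray, inphase: np.ndarray, spacing: np.ndarray) -> np.ndarray:
    """Mark phase voxels whose sphere is NOT contained in a neighbour's.

    Sphere at c is contained in the sphere at neighbour q when
    ``r_q >= d(c, q) + r_c``; removing such centres cannot change the
    painted maximum because q's sphere covers every voxel c's does, with a
    larger diameter.  A small tolerance keeps the removal conservative
    against float rounding.
    """
    nx, ny, nz = r2.shape
    dx, dy, dz = spacing[0], spacing[1], spacing[2]
    keep = np.zeros(r2.shape, dtype=np.bool_)
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if not inphase[i, j, k]:
                    continue
                rc = math.sqrt(r2[i, j, k])
                contained = False
                for di in range(-1, 2):
                    ii = i + di
                    if ii < 0 or ii >= nx:
                        continue
                    for dj in range(-1, 2):
                        jj = j + dj
                        if jj < 0 or jj >= ny:
                            continue
                        for dk in range(-1, 2):
                            kk = k + dk
                            if kk < 0 or kk >= nz:
                                continue
                            if di == 0 and dj == 0 and dk == 0:
                                continue
                            if not inphase[ii, jj, kk]:
                                continue
                            d = math.sqrt(
                                (di * dx) ** 2 + (dj * dy) ** 2 + (dk * dz) ** 2
                            )
                            if math.sqrt(r2[ii, jj, kk]) >= d + rc + 1e-9:
                                contained = True
                                break
                        if contained:
                            break
                    if contained:
                        break
                if not contained:
                    keep[i, j, k] = True
    return keep


@njit(cache=True)
def _paint_spheres(
    centers: np.ndarray,
    r2s: np.ndarray,
    tmap: np.ndarray,
    spacing: np.ndarray,
) -> None:
    """Write each sphere's diameter into the voxels it covers (max-combine).

    ``centers`` must be sorted by decreasing radius so large spheres paint
    first; this does not change the result, only memory-write locality.
    """
    nx, ny, nz = tmap.shape
    dx, dy, dz = spacing[0], spacing[1], spacing[2]
    for n in range(centers.shape[0]):
        ci, cj, ck = centers[n, 0], centers[n, 1], centers[n, 2]
        r2 = r2s[n]
        r = math.sqrt(r2)
        diam = 2.0 * r
        ei = int(r / dx)
        ej = int(r / dy)
        ek = int(r / dz)
        i0 = max(0, ci - ei)
        i1 = min(nx - 1, ci + ei)
        j0 = max(0, cj - ej)
        j1 = min(ny - 1, cj + ej)
        k0 = max(0, ck - ek)
        k1 = min(nz - 1, ck + ek)
        for i in range(i0, i1 + 1):
            di2 = ((i - ci) * dx) ** 2
            for j in range(j0, j1 + 1):
                dj2 = ((j - cj) * dy) ** 2
                for k in range(k0, k1 + 1):
                    d2 = di2 + dj2 + ((k - ck) * dz) ** 2
                    if d2 < r2 and tmap[i, j, k] < diam:
                        tmap[i, j, k] = diam
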