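"""Seeded region growing with a running-mean acceptance criterion.

Growth proceeds in breadth-first waves over the 6-connected lattice; a
candidate voxel is accepted when its intensity lies within ``tol`` of the
mean intensity of the region accepted so far.  Voxels rejected in one wave
may be reconsidered later if the running mean drifts toward them, so the
result depends only on the seed set, not on traversal order within a wave.
"""

from __future__ import annotations

import numpy as np


def region_grow(
    data: np.ndarray,
    seeds: list[tuple[int, int, int]],
    tol: float,
    allowed: np.ndarray | None = None,
) -> np.ndarray:
    """Grow a 6-connected region from ``seeds`` under a running-mean rule.

    Parameters
    ----------
    data : 3D float array of intensities.
    seeds : list of (z, y, x) voxel indices; all must be in bounds.
    tol : acceptance tolerance, same units as ``data``.
    allowed : optional boolean mask confining growth.

    Returns
    -------
    Boolean mask of the grown region (always contains the seeds).
    """
    nz, ny, nx = data.shape
    flat = data.ravel()
    sz, sy, sx = ny * nx, nx, 1

    seed_idx = []
    for z, y, x in seeds:
        if not (0 <= z < nz and 0 <= y < ny and 0 <= x < nx):
            raise IndexError(f"seed {(z, y, x)} outside volume of shape {data.shape}")
        seed_idx.append(z * sz + y * sy + x * sx)
    seed_idx = np.unique(np.asarray(seed_idx, dtype=np.int64))

    allowed_flat = None if allowed is None else allowed.ravel()
    accepted = np.zeros(flat.shape, dtype=bool)
    accepted[seed_idx] = True
    total = float(flat[seed_idx].sum())
    count = int(seed_idx.size)
    frontier = seed_idx

    while frontier.size:
        z = frontier // sz
        rem = frontier - z * sz
        y = rem // sy
        x = rem - y * sy
        nbrs = []
        for dz, dy, dx, off in (
            (-1, 0, 0, -sz), (1, 0, 0, sz),
            (0, -1, 0, -sy), (0, 1, 0, sy),
            (0, 0, -1, -sx), (0, 0, 1, sx),
        ):
            ok = np.ones(frontier.shape, dtype=bool)
            if dz:
                ok = (z + dz >= 0) & (z + dz < nz)
            elif dy:
                ok = (y + dy >= 0) & (y + dy < ny)
            else:
                ok = (x + dx >= 0) & (x + dx < nx)
            nbrs.append(frontier[ok] + off)
        cand = np.unique(np.concatenate(nbrs))
        cand = cand[~accepted[cand]]
        if allowed_flat is not None:
            cand = cand[allowed_flat[cand]]
        if cand.size == 0:
            break
        mean = total / count
        new = cand[np.abs(flat[cand] - mean) <= tol]
        if new.size == 0:
            break
        accepted[new] = True
        total += float(flat[new].sum())
        count += int(new.size)
        frontier = new

    return accepted.reshape(data.shape)
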