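"""Low-level geometry kernels shared across the package.

Everything here operates on plain numpy arrays in internal units (micrometres)
so that the numba-compiled hot loops in :mod:`gluspill._kernels` and the
environment validation code use one single implementation of

* the uniform spatial hash over spheroids,
* point classification (extracellular / neuronal / astroglial / cleft
  obstacle) with the deepest-containment ownership rule, and
* elastic mirror reflection of a step segment off spheres, the two
  hemispheric cleft obstacles and the arena walls.

Labels: 0 extracellular, 1 neuronal, 2 astroglial, 3 cleft obstacle.
"""

from __future__ import annotations

import numpy as np
from numba import njit

EXTRACELLULAR = 0
NEURONAL = 1
ASTROGLIAL = 2
CLEFT_OBSTACLE = 3

# Default spatial-hash margin (um): must cover the neighbour-list reach plus
# the largest credible single Brownian step, so a cell query from any point in
# the cell never misses a relevant sphere.
GRID_MARGIN = 0.09


@njit(cache=True)
def _count_and_fill(cx, cy, cz, r, ncell, csize, half, margin, counts, items, starts, fill):
    n = cx.shape[0]
    for i in range(n):
        reach = r[i] + margin
        ix0 = int(np.floor((cx[i] - reach + half) / csize))
        ix1 = int(np.floor((cx[i] + reach + half) / csize))
        iy0 = int(np.floor((cy[i] - reach + half) / csize))
        iy1 = int(np.floor((cy[i] + reach + half) / csize))
        iz0 = int(np.floor((cz[i] - reach + half) / csize))
        iz1 = int(np.floor((cz[i] + reach + half) / csize))
        if ix0 < 0:
            ix0 = 0
        if iy0 < 0:
            iy0 = 0
        if iz0 < 0:
            iz0 = 0
        if ix1 >= ncell:
            ix1 = ncell - 1
        if iy1 >= ncell:
            iy1 = ncell - 1
        if iz1 >= ncell:
            iz1 = ncell - 1
        for ax in range(ix0, ix1 + 1):
            # closest point of the cell slab to the centre, per axis
            lox = -half + ax * csize
            hix = lox + csize
            dx = 0.0
            if cx[i] < lox:
                dx = lox - cx[i]
            elif cx[i] > hix:
                dx = cx[i] - hix
            for ay in range(iy0, iy1 + 1):
                loy = -half + ay * csize
                hiy = loy + csize
                dy = 0.0
                if cy[i] < loy:
                    dy = loy - cy[i]
                elif cy[i] > hiy:
                    dy = cy[i] - hiy
                for az in range(iz0, iz1 + 1):
                    loz = -half + az * csize
                    hiz = loz + csize
                    dz = 0.0
                    if cz[i] < loz:
                        dz = loz - cz[i]
                    elif cz[i] > hiz:
                        dz = cz[i] - hiz
                    if dx * dx + dy * dy + dz * dz <= reach * reach:
                        cell = (ax * ncell + ay) * ncell + az
                        if fill:
                            items[starts[cell] + counts[cell]] = i
                        counts[cell] += 1


class SphereGrid:
    """Uniform spatial hash mapping arena cells to overlapping spheroid ids.

    Each sphere is registered in every cell whose box lies within
    ``radius + margin`` of the sphere centre, so a single-cell query returns a
    superset of all spheres relevant to any point in that cell (no false
    negatives within ``margin`` of a surface).
    """

    def __init__(self, centres: np.ndarray, radii: np.ndarray, edge: float,
                 cell_size: float = 0.25, margin: float = GRID_MARGIN):
        centres = np.ascontiguousarray(centres, dtype=np.float64).reshape(-1, 3)
        radii = np.ascontiguousarray(radii, dtype=np.float64)
        self.edge = float(edge)
        self.half = self.edge / 2.0
        self.ncell = max(1, int(np.ceil(self.edge / cell_size)))
        self.csize = self.edge / self.ncell
        self.margin = float(margin)
        ncells = self.ncell ** 3
        counts = np.zeros(ncells, dtype=np.int64)
        dummy_items = np.zeros(1, dtype=np.int32)
        dummy_starts = np.zeros(ncells + 1, dtype=np.int64)
        _count_and_fill(centres[:, 0], centres[:, 1], centres[:, 2], radii,
                        self.ncell, self.csize, self.half, self.margin,
                        counts, dummy_items, dummy_starts, False)
        starts = np.zeros(ncells + 1, dtype=np.int64)
        np.cumsum(counts, out=starts[1:])
        items = np.zeros(max(1, int(starts[-1])), dtype=np.int32)
        counts[:] = 0
        _count_and_fill(centres[:, 0], centres[:, 1], centres[:, 2], radii,
                        self.ncell, self.csize, self.half, self.margin,
                        counts, items, starts, True)
        self.cell_start = starts
        self.cell_items = items


@njit(inline="always")
def _cell_of(x, y, z, half, csize, ncell):
    ix = int(np.floor((x + half) / csize))
    iy = int(np.floor((y + half) / csize))
    iz = int(np.floor((z + half) / csize))
    if ix < 0:
        ix = 0
    elif ix >= ncell:
        ix = ncell - 1
    if iy < 0:
        iy = 0
    elif iy >= ncell:
        iy = ncell - 1
    if iz < 0:
        iz = 0
    elif iz >= ncell:
        iz = ncell - 1
    return (ix * ncell + iy) * ncell + iz


@njit(cache=True)
def classify_kernel(px, py, pz, sx, sy, sz, sr, astro,
                    cell_start, cell_items, csize, ncell, half,
                    z0, rap2, labels, owners):
    """Deepest-containment classification of points.

    A point inside several spheres belongs to the sphere whose surface is
    farthest away inside (maximum ``r - dist``); ties go to the lowest sphere
    index (cell item lists are ordered by sphere index). Points inside a
    hemispheric cleft obstacle are labelled 3; spheres are excluded from the
    cleft neighbourhood by construction so the two tests never compete.
    """
    n = px.shape[0]
    for k in range(n):
        x = px[k]
        y = py[k]
        z = pz[k]
        if rap2 > 0.0:
            if z > z0:
                d2 = x * x + y * y + (z - z0) * (z - z0)
                if d2 < rap2:
                    labels[k] = 3
                    owners[k] = -1
                    continue
            elif z < -z0:
                d2 = x * x + y * y + (z + z0) * (z + z0)
                if d2 < rap2:
                    labels[k] = 3
                    owners[k] = -1
                    continue
        cell = _cell_of(x, y, z, half, csize, ncell)
        best = 0.0
        owner = -1
        for j in range(cell_start[cell], cell_start[cell + 1]):
            i = cell_items[j]
            dx = x - sx[i]
            dy = y - sy[i]
            dz = z - sz[i]
            d = np.sqrt(dx * dx + dy * dy + dz * dz)
            depth = sr[i] - d
            if depth > best:
                best = depth
                owner = i
        owners[k] = owner
        if owner < 0:
            labels[k] = 0
        elif astro[owner]:
            labels[k] = 2
        else:
            labels[k] = 1


@njit(inline="always")
def _reflect_sphere(px, py, pz, qx, qy, qz, cx, cy, cz, r):
    """Mirror-reflect segment p->q (q inside the sphere) off the sphere.

    Returns the entry point (new segment origin) and the reflected endpoint.
    Falls back to a radial push-out of q when the segment geometry is
    degenerate (p already on/inside the surface numerically).
    """
    dx = qx - px
    dy = qy - py
    dz = qz - pz
    a = dx * dx + dy * dy + dz * dz
    ox = px - cx
    oy = py - cy
    oz = pz - cz
    b = 2.0 * (ox * dx + oy * dy + oz * dz)
    c0 = ox * ox + oy * oy + oz * oz - r * r
    disc = b * b - 4.0 * a * c0
    ok = a > 1e-30 and disc > 0.0
    t = 0.0
    if ok:
        t = (-b - np.sqrt(disc)) / (2.0 * a)
        if t < 0.0:
            t = 0.0
        if t > 1.0:
            ok = False
    if not ok:
        # radial push-out: mirror q about the surface along the radial line
        ex = qx - cx
        ey = qy - cy
        ez = qz - cz
        d = np.sqrt(ex * ex + ey * ey + ez * ez)
        if d < 1e-12:
            ex = 1.0
            ey = 0.0
            ez = 0.0
            d = 1.0
        s = (2.0 * r - d) / d
        gx = cx + ex / d * r
        gy = cy + ey / d * r
        gz = cz + ez / d * r
        return gx, gy, gz, cx + ex * s, cy + ey * s, cz + ez * s
    gx = px + t * dx
    gy = py + t * dy
    gz = pz + t * dz
    nx = (gx - cx) / r
    ny = (gy - cy) / r
    nz = (gz - cz) / r
    rx = qx - gx
    ry = qy - gy
    rz = qz - gz
    dot = rx * nx + ry * ny + rz * nz
    return gx, gy, gz, gx + rx - 2.0 * dot * nx, gy + ry - 2.0 * dot * ny, gz + rz - 2.0 * dot * nz


@njit(inline="always")
def _reflect_hemisphere(px, py, pz, qx, qy, qz, sgn, z0, rap):
    """Reflect off one hemispheric cleft obstacle.

    The solid is ``{sgn*z >= z0} ∩ ball((0,0,sgn*z0), rap)``: a dome sitting on
    the cleft face with its flat disc facing the cleft. A segment entering
    through the flat face reflects off the plane ``z = sgn*z0``; otherwise it
    reflects off the spherical surface.
    """
    pzs = sgn * pz
    qzs = sgn * qz
    if pzs <= z0 and qzs > pzs:
        t = (z0 - pzs) / (qzs - pzs)
        if 0.0 <= t <= 1.0:
            hx = px + t * (qx - px)
            hy = py + t * (qy - py)
            if hx * hx + hy * hy <= rap * rap:
                # plane reflection
                hz = sgn * z0
                nqz = sgn * (2.0 * z0 - qzs)
                return hx, hy, hz, qx, qy, nqz
    return _reflect_sphere(px, py, pz, qx, qy, qz, 0.0, 0.0, sgn * z0, rap)


@njit(inline="always")
def _resolve_move(px, py, pz, qx, qy, qz,
                  cand, ncand, sx, sy, sz, sr, sr2,
                  z0, rap, rap2, half, reflective, max_iter):
    """Resolve one proposed step against walls, cleft obstacles and spheres.

    Iterates mirror reflections until the endpoint is valid. Returns
    ``(x, y, z, code)`` with code 0 = resolved, 1 = escaped through an open
    wall, 2 = iteration cap hit. In narrow wedges between overlapping spheres
    the reflection sequence may not settle within the cap; the step is then
    rejected (endpoint returned to the original, valid, origin).
    """
    x0 = px
    y0 = py
    z0_orig = pz
    for _ in range(max_iter):
        moved = False
        # arena walls
        if qx > half or qx < -half or qy > half or qy < -half or qz > half or qz < -half:
            if not reflective:
                return qx, qy, qz, 1
            if qx > half:
                qx = 2.0 * half - qx
            elif qx < -half:
                qx = -2.0 * half - qx
            if qy > half:
                qy = 2.0 * half - qy
            elif qy < -half:
                qy = -2.0 * half - qy
            if qz > half:
                qz = 2.0 * half - qz
            elif qz < -half:
                qz = -2.0 * half - qz
            moved = True
        # hemispheric cleft obstacles
        if rap2 > 0.0:
            if qz > z0:
                d2 = qx * qx + qy * qy + (qz - z0) * (qz - z0)
                if d2 < rap2:
                    px, py, pz, qx, qy, qz = _reflect_hemisphere(px, py, pz, qx, qy, qz, 1.0, z0, rap)
                    moved = True
            elif qz < -z0:
                d2 = qx * qx + qy * qy + (qz + z0) * (qz + z0)
                if d2 < rap2:
                    px, py, pz, qx, qy, qz = _reflect_hemisphere(px, py, pz, qx, qy, qz, -1.0, z0, rap)
                    moved = True
        # spheroids
        for k in range(ncand):
            i = cand[k]
            dx = qx - sx[i]
            dy = qy - sy[i]
            dz = qz - sz[i]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 < sr2[i]:
                px, py, pz, qx, qy, qz = _reflect_sphere(px, py, pz, qx, qy, qz,
                                                         sx[i], sy[i], sz[i], sr[i])
                moved = True
                break
        if not moved:
            return qx, qy, qz, 0
    return x0, y0, z0_orig, 2
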