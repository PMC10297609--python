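"""Fused numba kernel advancing the particle ensemble through time.

One call advances all particles by ``nsteps`` Brownian steps, resolving
mirror reflections off neuronal/astroglial spheroids, the hemispheric cleft
obstacles and the arena walls, and running the transporter hazard model
(contact clocks, binding, fate assignment, scheduled unbinding release).

Brownian increments are NOT drawn inside the kernel: they arrive as a
pre-generated ``(nsteps, N, 3)`` array indexed by (step, particle) so that
paired simulation arms (unbinding on/off) consume bit-identical diffusion
noise even after their particle states diverge. The kernel's internal RNG
(seeded per call) is used only for binding/fate draws, which stay aligned
across arms until the first actual unbinding release; the fate delay is drawn
even for translocation fates to keep those streams aligned.

Per-particle neighbour lists (anchor + sphere ids whose surface lies within
``reach`` of the anchor) amortise the spatial-hash query over the many small
steps a particle spends near one anchor point; the list is rebuilt from the
hash whenever the particle moves beyond ``trigger`` of its anchor. The hash
margin exceeds ``reach`` plus any credible single step, so the lists have no
false negatives for either collision or 5 nm proximity tests.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from ._geom import _cell_of, _resolve_move

# status codes (mirror gluspill.transporters)
FREE = 0
BOUND = 1
RETAINED = 2
ESCAPED = 3

FATE_NONE = 0
FATE_UNBIND = 1
FATE_TRANSLOCATE = 2

TRIGGER = 0.030   # um moved from anchor before a neighbour-list rebuild
REACH = 0.060     # um: list holds spheres with surface within REACH of anchor

# counter slots
C_BIND = 0
C_RELEASE = 1
C_CLAMP = 2
C_ESCAPE = 3


@njit(cache=True)
def seed_kernel_rng(seed):
    np.random.seed(seed)


@njit(inline="always")
def _rebuild_list(i, x, y, z, neigh, nblock, nn, anchor, budget,
                  sx, sy, sz, sr, sr2, rc2, astro, cutoff,
                  cell_start, cell_items, csize, ncell, half,
                  z0, rap, rap2):
    """Refresh particle i's packed neighbour data and safe-distance budget.

    ``nblock[i, k] = (cx, cy, cz, r2_tol, rc2_or_-1)`` for each sphere whose
    surface lies within REACH of the anchor; ``budget[i]`` is a certified
    lower bound on (distance to the nearest solid surface or wall) minus the
    proximity cutoff, so steps whose cumulative L1 length stays below it can
    skip all collision and contact tests.
    """
    cell = _cell_of(x, y, z, half, csize, ncell)
    cap = neigh.shape[1]
    cnt = 0
    overflow = False
    dmin = REACH
    for j in range(cell_start[cell], cell_start[cell + 1]):
        s = cell_items[j]
        dx = x - sx[s]
        dy = y - sy[s]
        dz = z - sz[s]
        d = np.sqrt(dx * dx + dy * dy + dz * dz) - sr[s]
        if d < dmin:
            dmin = d
        if d < REACH:
            if cnt < cap:
                neigh[i, cnt] = s
                nblock[i, cnt, 0] = sx[s]
                nblock[i, cnt, 1] = sy[s]
                nblock[i, cnt, 2] = sz[s]
                nblock[i, cnt, 3] = sr2[s]
                nblock[i, cnt, 4] = rc2[s] if astro[s] else -1.0
                cnt += 1
            else:
                overflow = True
    nn[i] = -1 if overflow else cnt
    anchor[i, 0] = x
    anchor[i, 1] = y
    anchor[i, 2] = z
    # hemispheric obstacles: distance to the bounding ball is a lower bound
    if rap2 > 0.0:
        dz_t = z - z0
        dh = np.sqrt(x * x + y * y + dz_t * dz_t) - rap
        if dh < dmin:
            dmin = dh
        dz_b = z + z0
        dh = np.sqrt(x * x + y * y + dz_b * dz_b) - rap
        if dh < dmin:
            dmin = dh
    # arena walls bound the budget in both wall modes
    ax = half - abs(x)
    ay = half - abs(y)
    az = half - abs(z)
    dw = ax if ax < ay else ay
    if az < dw:
        dw = az
    if dw < dmin:
        dmin = dw
    budget[i] = dmin - cutoff - 1e-6


@njit(cache=True, fastmath=True)
def run_steps(pos, status, clock, bind_t, rel_t, fate, nbind,
              t0, nsteps, dt, sig, gauss,
              sx, sy, sz, sr, sr2, rc2, astro,
              cell_start, cell_items, csize, ncell, half,
              z0, rap, rap2, cutoff,
              hazard, p_unbind, mu, sigma, transporters_on,
              reflective,
              neigh, nblock, nn, anchor, budget, counters):
    n = pos.shape[0]
    trig2 = TRIGGER * TRIGGER
    for s in range(nsteps):
        t = t0 + (s + 1) * dt
        for i in range(n):
            st = status[i]
            if st == BOUND:
                if rel_t[i] <= t:
                    status[i] = FREE
                    clock[i] = 0.0
                    counters[C_RELEASE] += 1
                continue
            if st >= RETAINED:
                continue
            gx = sig * gauss[s, i, 0]
            gy = sig * gauss[s, i, 1]
            gz = sig * gauss[s, i, 2]
            px = pos[i, 0]
            py = pos[i, 1]
            pz = pos[i, 2]
            # fast path: the L1 step length never exceeds the certified
            # distance to the nearest surface, so no test can be missed
            l1 = abs(gx) + abs(gy) + abs(gz)
            if l1 < budget[i]:
                budget[i] -= l1
                pos[i, 0] = px + gx
                pos[i, 1] = py + gy
                pos[i, 2] = pz + gz
                clock[i] = 0.0
                continue
            qx = px + gx
            qy = py + gy
            qz = pz + gz
            # neighbour-list upkeep
            dax = qx - anchor[i, 0]
            day = qy - anchor[i, 1]
            daz = qz - anchor[i, 2]
            if dax * dax + day * day + daz * daz > trig2:
                _rebuild_list(i, px, py, pz, neigh, nblock, nn, anchor, budget,
                              sx, sy, sz, sr, sr2, rc2, astro, cutoff,
                              cell_start, cell_items, csize, ncell, half,
                              z0, rap, rap2)
                if l1 < budget[i]:
                    budget[i] -= l1
                    pos[i, 0] = qx
                    pos[i, 1] = qy
                    pos[i, 2] = qz
                    clock[i] = 0.0
                    continue
            ncand = nn[i]
            if ncand >= 0:
                # merged single scan: containment + astroglial contact at q
                hit = -1
                contact = False
                blk = nblock[i]
                for k in range(ncand):
                    dx = qx - blk[k, 0]
                    dy = qy - blk[k, 1]
                    dz = qz - blk[k, 2]
                    d2 = dx * dx + dy * dy + dz * dz
                    if d2 < blk[k, 3]:
                        hit = k
                        break
                    if d2 < blk[k, 4]:
                        contact = True
                wall = (qx > half or qx < -half or qy > half or qy < -half
                        or qz > half or qz < -half)
                hemi = False
                if rap2 > 0.0:
                    if qz > z0:
                        dzt = qz - z0
                        hemi = qx * qx + qy * qy + dzt * dzt < rap2
                    elif qz < -z0:
                        dzb = qz + z0
                        hemi = qx * qx + qy * qy + dzb * dzb < rap2
                if hit >= 0 or wall or hemi:
                    cand = neigh[i]
                    x, y, z, code = _resolve_move(px, py, pz, qx, qy, qz,
                                                  cand, ncand, sx, sy, sz,
                                                  sr, sr2, z0, rap, rap2,
                                                  half, reflective, 8)
                    if code == 1:
                        status[i] = ESCAPED
                        counters[C_ESCAPE] += 1
                        continue
                    if code == 2:
                        counters[C_CLAMP] += 1
                    qx = x
                    qy = y
                    qz = z
                    # re-evaluate contact at the corrected position
                    contact = False
                    if transporters_on:
                        for k in range(ncand):
                            if blk[k, 4] > 0.0:
                                dx = qx - blk[k, 0]
                                dy = qy - blk[k, 1]
                                dz = qz - blk[k, 2]
                                if dx * dx + dy * dy + dz * dz < blk[k, 4]:
                                    contact = True
                                    break
            else:
                # neighbour capacity overflow: fall back to the raw cell list
                cell = _cell_of(px, py, pz, half, csize, ncell)
                cand = cell_items[cell_start[cell]:cell_start[cell + 1]]
                x, y, z, code = _resolve_move(px, py, pz, qx, qy, qz,
                                              cand, cand.shape[0],
                                              sx, sy, sz, sr, sr2,
                                              z0, rap, rap2, half,
                                              reflective, 8)
                if code == 1:
                    status[i] = ESCAPED
                    counters[C_ESCAPE] += 1
                    continue
                if code == 2:
                    counters[C_CLAMP] += 1
                qx = x
                qy = y
                qz = z
                contact = False
                if transporters_on:
                    for k in range(cand.shape[0]):
                        j = cand[k]
                        if astro[j]:
                            dx = qx - sx[j]
                            dy = qy - sy[j]
                            dz = qz - sz[j]
                            if dx * dx + dy * dy + dz * dz < rc2[j]:
                                contact = True
                                break
            pos[i, 0] = qx
            pos[i, 1] = qy
            pos[i, 2] = qz
            # near-path moves consume budget too (L1 <= sqrt(3) * L2 of the
            # reflected displacement, itself bounded by the step length)
            budget[i] -= 1.7320508075688772 * l1
            if transporters_on and contact:
                clock[i] += dt
                if np.random.random() < hazard:
                    counters[C_BIND] += 1
                    nbind[i] += 1
                    bind_t[i] = t
                    u = np.random.random()
                    # draw the delay unconditionally: keeps the RNG stream
                    # aligned between paired unbinding-on/off arms
                    d = mu + sigma * np.random.normal()
                    while d <= 0.0:
                        d = mu + sigma * np.random.normal()
                    if u < p_unbind:
                        status[i] = BOUND
                        fate[i] = FATE_UNBIND
                        rel_t[i] = t + d
                    else:
                        status[i] = RETAINED
                        fate[i] = FATE_TRANSLOCATE
                        rel_t[i] = np.inf
            else:
                clock[i] = 0.0


@njit(cache=True)
def resolve_many(old, prop, out, codes,
                 sx, sy, sz, sr, sr2,
                 cell_start, cell_items, csize, ncell, half,
                 z0, rap, rap2, reflective):
    for i in range(old.shape[0]):
        cell = _cell_of(old[i, 0], old[i, 1], old[i, 2], half, csize, ncell)
        cand = cell_items[cell_start[cell]:cell_start[cell + 1]]
        x, y, z, code = _resolve_move(old[i, 0], old[i, 1], old[i, 2],
                                      prop[i, 0], prop[i, 1], prop[i, 2],
                                      cand, cand.shape[0],
                                      sx, sy, sz, sr, sr2,
                                      z0, rap, rap2, half, reflective, 12)
        out[i, 0] = x
        out[i, 1] = y
        out[i, 2] = z
        codes[i] = code


@njit(cache=True)
def astro_distance_many(pts, dist,
                        sx, sy, sz, sr, astro,
                        cell_start, cell_items, csize, ncell, half):
    """Distance from each point to the nearest astroglial surface, capped at
    the spatial-hash margin (points farther than every listed sphere get inf)."""
    for i in range(pts.shape[0]):
        cell = _cell_of(pts[i, 0], pts[i, 1], pts[i, 2], half, csize, ncell)
        best = np.inf
        for j in range(cell_start[cell], cell_start[cell + 1]):
            s = cell_items[j]
            if not astro[s]:
                continue
            dx = pts[i, 0] - sx[s]
            dy = pts[i, 1] - sy[s]
            dz = pts[i, 2] - sz[s]
            d = np.sqrt(dx * dx + dy * dy + dz * dz) - sr[s]
            if d < best:
                best = d
        dist[i] = best
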