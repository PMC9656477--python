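"""Numba kernels for hard-sphere Brownian dynamics with a linked-cell grid.

All kernels operate on plain arrays owned by :class:`nanorelease.engine.
BrownianEngine`.  The cell grid is a doubly linked list (head / nxt / prv /
cellof) over a cubic grid of ``nc**3`` cells spanning [gmin, gmin+nc*edge)
in each direction; a per-bead integer scan radius ``scanr`` guarantees that
every potentially contacting pair is found even when the cell edge is
smaller than the largest contact distance.

The random stream is numba's internal generator, seeded once per run via
:func:`seed_rng`; with a fixed seed the trajectory is reproducible on a
given platform.
"""

import math

import numpy as np
from numba import njit

# status codes returned by run_steps
OK = 0
GRID_OVERFLOW = 1
COINCIDENT_BOND = 2


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True, inline="always")
def _cell_coord(x, gmin, edge, nc):
    i = int((x - gmin) / edge)
    if i < 0:
        i = 0
    elif i >= nc:
        i = nc - 1
    return i


@njit(cache=True, inline="always")
def _cell_index(x, y, z, gmin, edge, nc):
    ix = _cell_coord(x, gmin, edge, nc)
    iy = _cell_coord(y, gmin, edge, nc)
    iz = _cell_coord(z, gmin, edge, nc)
    return (ix * nc + iy) * nc + iz


@njit(cache=True)
def build_cells(pos, gmin, edge, nc, head, nxt, prv, cellof):
    head[:] = -1
    for i in range(pos.shape[0]):
        c = _cell_index(pos[i, 0], pos[i, 1], pos[i, 2], gmin, edge, nc)
        old = head[c]
        head[c] = i
        nxt[i] = old
        prv[i] = -1
        if old != -1:
            prv[old] = i
        cellof[i] = c


@njit(cache=True, inline="always")
def _unlink(i, head, nxt, prv, cellof):
    p = prv[i]
    nx = nxt[i]
    if p == -1:
        head[cellof[i]] = nx
    else:
        nxt[p] = nx
    if nx != -1:
        prv[nx] = p


@njit(cache=True, inline="always")
def _link(i, c, head, nxt, prv, cellof):
    old = head[c]
    head[c] = i
    nxt[i] = old
    prv[i] = -1
    if old != -1:
        prv[old] = i
    cellof[i] = c


@njit(cache=True)
def trial_overlaps(
    i, x, y, z, pos, radii, scanr_i, gmin, edge, nc, head, nxt, pptr, pidx
):
    """True iff bead i at (x, y, z) overlaps any non-bonded bead."""
    ri = radii[i]
    cx = _cell_coord(x, gmin, edge, nc)
    cy = _cell_coord(y, gmin, edge, nc)
    cz = _cell_coord(z, gmin, edge, nc)
    ax0 = cx - scanr_i
    if ax0 < 0:
        ax0 = 0
    ax1 = cx + scanr_i + 1
    if ax1 > nc:
        ax1 = nc
    ay0 = cy - scanr_i
    if ay0 < 0:
        ay0 = 0
    ay1 = cy + scanr_i + 1
    if ay1 > nc:
        ay1 = nc
    az0 = cz - scanr_i
    if az0 < 0:
        az0 = 0
    az1 = cz + scanr_i + 1
    if az1 > nc:
        az1 = nc
    p0 = pptr[i]
    p1 = pptr[i + 1]
    for ax in range(ax0, ax1):
        for ay in range(ay0, ay1):
            base = (ax * nc + ay) * nc
            for az in range(az0, az1):
                j = head[base + az]
                while j != -1:
                    if j != i:
                        dx = x - pos[j, 0]
                        dy = y - pos[j, 1]
                        dz = z - pos[j, 2]
                        s = ri + radii[j]
                        if dx * dx + dy * dy + dz * dz < s * s:
                            bonded = False
                            for q in range(p0, p1):
                                if pidx[q] == j:
                                    bonded = True
                                    break
                            if not bonded:
                                return True
                    j = nxt[j]
    return False


@njit(cache=True)
def trial_overlaps_fast(
    i, x, y, z, pos, radii, offs27, gmin, edge, nc, head, nxt, pptr, pidx
):
    """Scan-radius-1 overlap test with precomputed neighbour-cell offsets.

    Valid only for beads whose contact search fits in the 27 surrounding
    cells and whose coordinates are at least one cell away from the grid
    rim (which run_steps guarantees via its overflow check).
    """
    ri = radii[i]
    base = _cell_index(x, y, z, gmin, edge, nc)
    p0 = pptr[i]
    p1 = pptr[i + 1]
    for q in range(27):
        j = head[base + offs27[q]]
        while j != -1:
            if j != i:
                dx = x - pos[j, 0]
                dy = y - pos[j, 1]
                dz = z - pos[j, 2]
                s = ri + radii[j]
                if dx * dx + dy * dy + dz * dz < s * s:
                    bonded = False
                    for w in range(p0, p1):
                        if pidx[w] == j:
                            bonded = True
                            break
                    if not bonded:
                        return True
            j = nxt[j]
    return False


@njit(cache=True)
def count_nonbonded_overlaps(pos, radii, pptr, pidx, tol):
    """All-pairs count of non-bonded overlaps (distance < ri + rj - tol)."""
    n = pos.shape[0]
    cnt = 0
    for i in range(n):
        p0 = pptr[i]
        p1 = pptr[i + 1]
        for j in range(i + 1, n):
            bonded = False
            for q in range(p0, p1):
                if pidx[q] == j:
                    bonded = True
                    break
            if bonded:
                continue
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            s = radii[i] + radii[j] - tol
            if s > 0.0 and dx * dx + dy * dy + dz * dz < s * s:
                cnt += 1
    return cnt


@njit(cache=True)
def run_steps(
    pos,
    radii,
    d0,
    mobile,
    scanr,
    sqrtcoef,
    bonds,
    ke,
    r0,
    flexible,
    pptr,
    pidx,
    cptr,
    cidx,
    dt,
    n_steps,
    gmin,
    edge,
    nc,
    head,
    nxt,
    prv,
    cellof,
    box_half,
    forces,
    perm,
    offs27,
    normals,
    check_every,
    check_tol,
):
    """Propagate ``n_steps`` hard-sphere Brownian-dynamics steps in place.

    Per step: bond forces are evaluated once from the start-of-step
    configuration (flexible mode only), then every mobile bead is visited
    in a fresh random permutation; each receives a Gaussian trial
    displacement (plus the deterministic drift D0 F dt in flexible mode)
    which is accepted iff it creates no overlap with any non-bonded bead in
    the current, partially updated configuration.  Box walls reflect.

    Returns (accepted, attempted, overlap_violations, steps_done, status).
    ``status`` is GRID_OVERFLOW if a bead left the cell grid (the caller
    rebuilds a larger grid and resumes), COINCIDENT_BOND if two bonded
    beads coincide (undefined force direction).
    """
    nm = mobile.shape[0]
    nb = bonds.shape[0]
    acc = 0
    att = 0
    violations = 0
    glo = gmin + edge  # one-cell safety margin
    ghi = gmin + edge * (nc - 1)
    for s in range(n_steps):
        if flexible:
            for q in range(forces.shape[0]):
                forces[q, 0] = 0.0
                forces[q, 1] = 0.0
                forces[q, 2] = 0.0
            for b in range(nb):
                ii = bonds[b, 0]
                jj = bonds[b, 1]
                dx = pos[jj, 0] - pos[ii, 0]
                dy = pos[jj, 1] - pos[ii, 1]
                dz = pos[jj, 2] - pos[ii, 2]
                r = math.sqrt(dx * dx + dy * dy + dz * dz)
                if r < 1e-10:
                    return acc, att, violations, s, COINCIDENT_BOND
                fmag = -ke * (r - r0) / r
                fx = fmag * dx
                fy = fmag * dy
                fz = fmag * dz
                forces[jj, 0] += fx
                forces[jj, 1] += fy
                forces[jj, 2] += fz
                forces[ii, 0] -= fx
                forces[ii, 1] -= fy
                forces[ii, 2] -= fz
        for q in range(nm):
            perm[q] = mobile[q]
        for q in range(nm - 1, 0, -1):
            w = np.random.randint(0, q + 1)
            tmp = perm[q]
            perm[q] = perm[w]
            perm[w] = tmp
        for q in range(nm):
            i = perm[q]
            att += 1
            x = pos[i, 0] + sqrtcoef[i] * normals[s, q, 0]
            y = pos[i, 1] + sqrtcoef[i] * normals[s, q, 1]
            z = pos[i, 2] + sqrtcoef[i] * normals[s, q, 2]
            if flexible:
                x += d0[i] * forces[i, 0] * dt
                y += d0[i] * forces[i, 1] * dt
                z += d0[i] * forces[i, 2] * dt
            if x > box_half:
                x = 2.0 * box_half - x
            elif x < -box_half:
                x = -2.0 * box_half - x
            if y > box_half:
                y = 2.0 * box_half - y
            elif y < -box_half:
                y = -2.0 * box_half - y
            if z > box_half:
                z = 2.0 * box_half - z
            elif z < -box_half:
                z = -2.0 * box_half - z
            if (
                x < glo
                or x > ghi
                or y < glo
                or y > ghi
                or z < glo
                or z > ghi
            ):
                return acc, att, violations, s, GRID_OVERFLOW
            if scanr[i] == 1:
                hit = trial_overlaps_fast(
                    i, x, y, z, pos, radii, offs27, gmin, edge, nc, head,
                    nxt, pptr, pidx,
                )
            else:
                hit = trial_overlaps(
                    i, x, y, z, pos, radii, scanr[i], gmin, edge, nc, head,
                    nxt, pptr, pidx,
                )
            if not hit:
                pos[i, 0] = x
                pos[i, 1] = y
                pos[i, 2] = z
                c = _cell_index(x, y, z, gmin, edge, nc)
                if c != cellof[i]:
                    _unlink(i, head, nxt, prv, cellof)
                    _link(i, c, head, nxt, prv, cellof)
                acc += 1
        if check_every > 0 and (s + 1) % check_every == 0:
            violations += count_nonbonded_overlaps(
                pos, radii, cptr, cidx, check_tol
            )
    return acc, att, violations, n_steps, OK


@njit(cache=True)
def place_solutes(
    pos,
    radii,
    n_existing,
    n_drug,
    com,
    r_max,
    max_attempts,
    scanr_s,
    gmin,
    edge,
    nc,
    head,
    nxt,
    prv,
    cellof,
    pptr,
    pidx,
):
    """Rejection-sample ``n_drug`` solute centres uniformly in a sphere.

    Centres are drawn uniformly in the sphere of radius ``r_max`` about
    ``com`` and accepted iff they create no overlap with network beads or
    previously placed solutes.  ``pos`` and ``radii`` must already hold the
    solute rows (positions are overwritten); accepted solutes are linked
    into the cell grid.  Returns the number successfully placed.
    """
    for kk in range(n_drug):
        i = n_existing + kk
        placed = False
        for _ in range(max_attempts):
            while True:
                ux = 2.0 * np.random.random() - 1.0
                uy = 2.0 * np.random.random() - 1.0
                uz = 2.0 * np.random.random() - 1.0
                if ux * ux + uy * uy + uz * uz <= 1.0:
                    break
            x = com[0] + r_max * ux
            y = com[1] + r_max * uy
            z = com[2] + r_max * uz
            if not trial_overlaps(
                i, x, y, z, pos, radii, scanr_s, gmin, edge, nc, head, nxt,
                pptr, pidx,
            ):
                pos[i, 0] = x
                pos[i, 1] = y
                pos[i, 2] = z
                c = _cell_index(x, y, z, gmin, edge, nc)
                _link(i, c, head, nxt, prv, cellof)
                placed = True
                break
        if not placed:
            return kk
    return n_drug
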