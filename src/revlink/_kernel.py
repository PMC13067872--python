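"""Numba-compiled Langevin dynamics kernel.

Layout conventions (enforced by :mod:`revlink.simulate`):

* monomers are numbered consecutively within each chain, so two monomers are
  directly bonded iff they share a chain id and their indices differ by 1;
* ``link_type`` is 0 for neutral monomers, 1 for crosslinkable A-monomers,
  2 for crosslinkable B-monomers;
* ``partner[i]`` is the index of the monomer i is crosslinked to, or -1.

Interaction rules per non-bonded pair (minimum-image convention):

* crosslinkable A-B pair with both members free, or the registered pair
  itself: cosine binding attraction, no WCA;
* crosslinkable A-B pair where at least one member is bound to a third
  party: WCA;
* every other pair (including directly bonded neighbours unless
  ``wca_bonded`` is 0): WCA.

Integration is the BAOAB splitting of Langevin dynamics; with gamma=0 it
reduces to velocity Verlet (NVE).  The binding registry is updated once per
step after the position update: registered pairs beyond ``r_bind`` break,
then all free A/free B crosslinker pairs closer than ``r_bind`` are accepted
greedily in ascending distance order (exact ties broken by lowest id pair)
subject to one-to-one saturation.

Non-bonded pairs are iterated through a half Verlet list (cutoff + 0.4 sigma
skin) rebuilt from a cell grid whenever any particle has moved more than
half the skin since the last build.
"""

from __future__ import annotations

import numpy as np
from numba import njit

WCA_CUTOFF = 2.0 ** (1.0 / 6.0)
SKIN = 0.4
MAX_NEIGH = 96

# The Ornstein-Uhlenbeck (thermostat) substep runs every NOISE_STRIDE-th
# step with decay constants compensated for the longer interval; between
# kicks the integrator is plain velocity Verlet.  The noise stays exactly
# Gaussian while its generation cost drops by the stride factor.  The
# lumped friction interval (stride * dt = 0.02 t0 by default) remains an
# order of magnitude below the stiffest oscillation period of the model
# (~0.3 t0 for the binding well).
NOISE_STRIDE = 4

# status codes returned by run_segment
STATUS_OK = 0
STATUS_NONFINITE = 1
STATUS_BLOWUP = 2
STATUS_NLIST_OVERFLOW = 3

# Cap on the magnitude of any pair force [kBT/sigma].  The model switches a
# crosslinkable A-B pair from the binding attraction to WCA the moment one
# member registers with a third party, so a monomer can transiently find
# itself inside the WCA core where forces reach ~1e5 kBT/sigma.  The cap
# bounds the resulting energy injection; it only modifies the force where
# U_WCA > ~30 kBT (r < 0.82 sigma), a region with Boltzmann weight < 1e-13,
# so equilibrium properties are unaffected while the integrator stays stable.
_FORCE_CAP = 500.0

# half stencil: the cell itself plus 13 forward neighbour cells
_STENCIL = np.array(
    [[0, 0, 0]]
    + [[1, oy, oz] for oy in (-1, 0, 1) for oz in (-1, 0, 1)]
    + [[0, 1, oz] for oz in (-1, 0, 1)]
    + [[0, 0, 1]],
    dtype=np.int64,
)


@njit(cache=True, inline="always")
def _min_image(dx, L):
    # wrapped coordinates differ by less than one box length, so a single
    # conditional shift is cheaper than rint and equivalent
    if dx > 0.5 * L:
        return dx - L
    if dx < -0.5 * L:
        return dx + L
    return dx


@njit(cache=True)
def _cell_grid(box, rc):
    """Number of cells per dimension; (1,1,1) signals the O(N^2) fallback."""
    ncx = int(box[0] / rc)
    ncy = int(box[1] / rc)
    ncz = int(box[2] / rc)
    if ncx < 3 or ncy < 3 or ncz < 3:
        return 1, 1, 1
    while ncx * ncy * ncz > 500000:
        ncx = max(3, ncx // 2)
        ncy = max(3, ncy // 2)
        ncz = max(3, ncz // 2)
    return ncx, ncy, ncz


@njit(cache=True, fastmath=True)
def _build_nlist(pos, box, rlist, nlist, ncount, ref_pos):
    """Half neighbour list within ``rlist``; returns True on overflow.

    Cell binning by counting sort, then a half stencil (13 forward neighbour
    cells + same cell with i < j) so each pair is visited exactly once.
    """
    n = pos.shape[0]
    rl2 = rlist * rlist
    for i in range(n):
        ncount[i] = 0
        for d in range(3):
            ref_pos[i, d] = pos[i, d]
    ncx, ncy, ncz = _cell_grid(box, rlist)
    if n < 250 or ncx == 1:
        for i in range(n):
            for j in range(i + 1, n):
                dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
                dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
                dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
                if dx * dx + dy * dy + dz * dz < rl2:
                    if ncount[i] >= MAX_NEIGH:
                        return True
                    nlist[i, ncount[i]] = j
                    ncount[i] += 1
        return False
    ncell = ncx * ncy * ncz
    # counting-sort binning: cell_start[c]..cell_start[c+1] indexes members
    cell_of = np.empty(n, dtype=np.int64)
    counts = np.zeros(ncell + 1, dtype=np.int64)
    for i in range(n):
        cx = int(pos[i, 0] / box[0] * ncx)
        cy = int(pos[i, 1] / box[1] * ncy)
        cz = int(pos[i, 2] / box[2] * ncz)
        if cx >= ncx:
            cx = ncx - 1
        if cy >= ncy:
            cy = ncy - 1
        if cz >= ncz:
            cz = ncz - 1
        c = (cx * ncy + cy) * ncz + cz
        cell_of[i] = c
        counts[c + 1] += 1
    for c in range(ncell):
        counts[c + 1] += counts[c]
    members = np.empty(n, dtype=np.int64)
    fill = counts[:ncell].copy()
    for i in range(n):
        c = cell_of[i]
        members[fill[c]] = i
        fill[c] += 1
    # half stencil: same cell + 13 forward neighbours
    for cx in range(ncx):
        for cy in range(ncy):
            for cz in range(ncz):
                c = (cx * ncy + cy) * ncz + cz
                s0 = counts[c]
                e0 = counts[c + 1]
                if s0 == e0:
                    continue
                for st in range(14):
                    ox = _STENCIL[st, 0]
                    oy = _STENCIL[st, 1]
                    oz = _STENCIL[st, 2]
                    c2x = cx + ox
                    c2y = cy + oy
                    c2z = cz + oz
                    if c2x >= ncx:
                        c2x -= ncx
                    elif c2x < 0:
                        c2x += ncx
                    if c2y >= ncy:
                        c2y -= ncy
                    elif c2y < 0:
                        c2y += ncy
                    if c2z >= ncz:
                        c2z -= ncz
                    elif c2z < 0:
                        c2z += ncz
                    c2 = (c2x * ncy + c2y) * ncz + c2z
                    s1 = counts[c2]
                    e1 = counts[c2 + 1]
                    same = c2 == c
                    for p in range(s0, e0):
                        i = members[p]
                        q0 = p + 1 if same else s1
                        for q in range(q0, e1):
                            j = members[q]
                            dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
                            dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
                            dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
                            if dx * dx + dy * dy + dz * dz < rl2:
                                ii = i if i < j else j
                                jj = j if i < j else i
                                if ncount[ii] >= MAX_NEIGH:
                                    return True
                                nlist[ii, ncount[ii]] = jj
                                ncount[ii] += 1
    return False


@njit(cache=True, inline="always")
def _pair_coef(r2, is_bind, eps, eps_sp):
    """Force coefficient c with F_i = c * (r_i - r_j), plus pair energy."""
    if is_bind:
        if r2 >= 0.25:
            return 0.0, 0.0
        r = np.sqrt(r2)
        u = -eps_sp * (np.cos(2.0 * np.pi * r) + 1.0)
        if r < 1.0e-9:
            return 0.0, u
        coef = -eps_sp * 2.0 * np.pi * np.sin(2.0 * np.pi * r) / r
        return coef, u
    if r2 >= WCA_CUTOFF * WCA_CUTOFF:
        return 0.0, 0.0
    if r2 < 1.0e-18:
        return _FORCE_CAP, 4.0 * eps * 1.0e12
    inv2 = 1.0 / r2
    inv6 = inv2 * inv2 * inv2
    coef = 24.0 * eps * inv2 * inv6 * (2.0 * inv6 - 1.0)
    if coef > _FORCE_CAP:
        coef = _FORCE_CAP
    u = 4.0 * eps * (inv6 * inv6 - inv6 + 0.25)
    return coef, u


@njit(cache=True, inline="always")
def _is_bind_pair(i, j, link_type, partner):
    ti = link_type[i]
    tj = link_type[j]
    if (ti == 1 and tj == 2) or (ti == 2 and tj == 1):
        if partner[i] == j:
            return True
        if partner[i] < 0 and partner[j] < 0:
            return True
    return False


@njit(cache=True, fastmath=True)
def _nonbonded_from_list(pos, box, link_type, chain_id, partner,
                         eps, eps_sp, wca_bonded, nlist, ncount, forces):
    n = pos.shape[0]
    pe = 0.0
    for i in range(n):
        for k in range(ncount[i]):
            j = nlist[i, k]
            dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
            dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
            dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= WCA_CUTOFF * WCA_CUTOFF:
                continue
            if wca_bonded == 0 and chain_id[i] == chain_id[j] and abs(i - j) == 1:
                continue
            coef, u = _pair_coef(r2, _is_bind_pair(i, j, link_type, partner),
                                 eps, eps_sp)
            pe += u
            forces[i, 0] += coef * dx
            forces[i, 1] += coef * dy
            forces[i, 2] += coef * dz
            forces[j, 0] -= coef * dx
            forces[j, 1] -= coef * dy
            forces[j, 2] -= coef * dz
    return pe


@njit(cache=True, fastmath=True)
def _bonded_forces(pos, box, bonds, angles, kb, r0, ka, forces):
    """Harmonic bonds + harmonic bending; returns bonded potential energy."""
    pe = 0.0
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
        dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
        dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        pe += 0.5 * kb * (r - r0) ** 2
        if r > 1.0e-12:
            coef = -kb * (r - r0) / r
            forces[i, 0] += coef * dx
            forces[i, 1] += coef * dy
            forces[i, 2] += coef * dz
            forces[j, 0] -= coef * dx
            forces[j, 1] -= coef * dy
            forces[j, 2] -= coef * dz
    for a in range(angles.shape[0]):
        i = angles[a, 0]
        j = angles[a, 1]
        k = angles[a, 2]
        ax = _min_image(pos[i, 0] - pos[j, 0], box[0])
        ay = _min_image(pos[i, 1] - pos[j, 1], box[1])
        az = _min_image(pos[i, 2] - pos[j, 2], box[2])
        bx = _min_image(pos[k, 0] - pos[j, 0], box[0])
        by = _min_image(pos[k, 1] - pos[j, 1], box[1])
        bz = _min_image(pos[k, 2] - pos[j, 2], box[2])
        la = np.sqrt(ax * ax + ay * ay + az * az)
        lb = np.sqrt(bx * bx + by * by + bz * bz)
        if la < 1.0e-12 or lb < 1.0e-12:
            continue
        ct = (ax * bx + ay * by + az * bz) / (la * lb)
        if ct > 1.0:
            ct = 1.0
        elif ct < -1.0:
            ct = -1.0
        theta = np.arccos(ct)
        pe += 0.5 * ka * (theta - np.pi) ** 2
        st = np.sqrt(1.0 - ct * ct)
        if st > 1.0e-8:
            g = ka * (theta - np.pi) / st
        else:
            g = -ka  # limit of (theta - pi)/sin(theta) as theta -> pi
        ahx, ahy, ahz = ax / la, ay / la, az / la
        bhx, bhy, bhz = bx / lb, by / lb, bz / lb
        fix = g * (bhx - ct * ahx) / la
        fiy = g * (bhy - ct * ahy) / la
        fiz = g * (bhz - ct * ahz) / la
        fkx = g * (ahx - ct * bhx) / lb
        fky = g * (ahy - ct * bhy) / lb
        fkz = g * (ahz - ct * bhz) / lb
        forces[i, 0] += fix
        forces[i, 1] += fiy
        forces[i, 2] += fiz
        forces[k, 0] += fkx
        forces[k, 1] += fky
        forces[k, 2] += fkz
        forces[j, 0] -= fix + fkx
        forces[j, 1] -= fiy + fky
        forces[j, 2] -= fiz + fkz
    return pe


@njit(cache=True)
def compute_forces_energy(pos, box, bonds, angles, link_type, chain_id, partner,
                          kb, r0, ka, eps, eps_sp, wca_bonded):
    """One-shot force evaluation (fresh neighbour list); returns (forces, pe)."""
    n = pos.shape[0]
    forces = np.zeros((n, 3))
    if n == 0:
        return forces, 0.0
    nlist = np.empty((n, MAX_NEIGH), dtype=np.int64)
    ncount = np.zeros(n, dtype=np.int64)
    ref = np.empty((n, 3))
    if _build_nlist(pos, box, WCA_CUTOFF + SKIN, nlist, ncount, ref):
        raise RuntimeError("neighbour list overflow")
    pe = _nonbonded_from_list(pos, box, link_type, chain_id, partner,
                              eps, eps_sp, wca_bonded, nlist, ncount, forces)
    pe += _bonded_forces(pos, box, bonds, angles, kb, r0, ka, forces)
    return forces, pe


@njit(cache=True, fastmath=True)
def _collect_candidates(pos, box, link_type, partner, r_bind,
                        nlist, ncount, cand, dist):
    """Free-A/free-B crosslinker pairs within r_bind from the half list."""
    n = pos.shape[0]
    m = 0
    cap = cand.shape[0]
    rb2 = r_bind * r_bind
    for i in range(n):
        ti = link_type[i]
        if ti == 0:
            continue
        for k in range(ncount[i]):
            j = nlist[i, k]
            tj = link_type[j]
            if ti + tj != 3:  # need one type-1 and one type-2 member
                continue
            if partner[i] >= 0 or partner[j] >= 0:
                continue
            dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
            dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
            dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < rb2 and m < cap:
                if ti == 1:
                    cand[m, 0] = i
                    cand[m, 1] = j
                else:
                    cand[m, 0] = j
                    cand[m, 1] = i
                dist[m] = np.sqrt(r2)
                m += 1
    return m


@njit(cache=True, fastmath=True)
def _update_bindings_from_list(pos, box, link_type, partner, r_bind,
                               nlist, ncount, cand, dist):
    """One registry update: break stretched pairs, then greedy re-pairing."""
    n = pos.shape[0]
    for i in range(n):
        j = partner[i]
        if j > i:
            dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
            dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
            dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
            if dx * dx + dy * dy + dz * dz >= r_bind * r_bind:
                partner[i] = -1
                partner[j] = -1
    m = _collect_candidates(pos, box, link_type, partner, r_bind,
                            nlist, ncount, cand, dist)
    if m == 0:
        return 0
    order = np.argsort(dist[:m])
    # stabilise exact distance ties by lowest (a, b) id pair
    s = 0
    while s < m - 1:
        e = s
        while e + 1 < m and dist[order[e + 1]] == dist[order[s]]:
            e += 1
        if e > s:
            for p in range(s + 1, e + 1):  # insertion sort of the tie group
                o = order[p]
                a_ = cand[o, 0]
                b_ = cand[o, 1]
                q = p - 1
                while q >= s and (cand[order[q], 0] > a_ or
                                  (cand[order[q], 0] == a_ and cand[order[q], 1] > b_)):
                    order[q + 1] = order[q]
                    q -= 1
                order[q + 1] = o
        s = e + 1
    formed = 0
    for p in range(m):
        o = order[p]
        a = cand[o, 0]
        b = cand[o, 1]
        if partner[a] < 0 and partner[b] < 0:
            partner[a] = b
            partner[b] = a
            formed += 1
    return formed


@njit(cache=True)
def update_bindings(pos, box, link_type, partner, r_bind):
    """Standalone registry update (fresh neighbour list); returns pairs formed."""
    n = pos.shape[0]
    if n == 0:
        return 0
    nlist = np.empty((n, MAX_NEIGH), dtype=np.int64)
    ncount = np.zeros(n, dtype=np.int64)
    ref = np.empty((n, 3))
    if _build_nlist(pos, box, max(WCA_CUTOFF, r_bind) + SKIN, nlist, ncount, ref):
        raise RuntimeError("neighbour list overflow")
    cand = np.empty((16 * n + 64, 2), dtype=np.int64)
    dist = np.empty(16 * n + 64)
    return _update_bindings_from_list(pos, box, link_type, partner, r_bind,
                                      nlist, ncount, cand, dist)


@njit(cache=True, fastmath=True)
def run_chunk(pos, img, vel, box, bonds, angles, link_type, chain_id, partner,
              kb, r0, ka, eps, eps_sp, r_bind, wca_bonded,
              dt, gamma, mass, kBT, step0, n_steps, save_every, noise,
              nlist, ncount, ref_pos, forces, rebuild,
              tp, ti, tpart, tt, tke, tpe, isave0):
    """Integrate ``n_steps`` BAOAB steps (global step index starts at step0+1).

    ``noise`` holds pre-generated standard normals, one row of 3n per step
    (ignored when gamma == 0).  Saved frames go into the caller-allocated
    arrays tp/ti/tpart/tt/tke/tpe starting at slot ``isave0``; a frame is
    recorded whenever the global step index is a multiple of ``save_every``.
    ``rebuild`` is a length-1 flag array: set it nonzero to force a neighbour
    list rebuild on entry (first call, or positions changed externally).
    Returns (next_save_slot, status).
    """
    n = pos.shape[0]
    if n == 0:
        return isave0, STATUS_OK
    nsave_cap = tp.shape[0]
    rlist = WCA_CUTOFF + SKIN
    cap = cand_capacity(n)
    cand = np.empty((cap, 2), dtype=np.int64)
    cdist = np.empty(cap)

    c1 = np.exp(-gamma * NOISE_STRIDE * dt / mass)
    c2 = np.sqrt(kBT / mass * (1.0 - c1 * c1))
    half = 0.5 * dt / mass
    noise_row = 0
    lmin = min(box[0], min(box[1], box[2]))
    skin_half2 = (0.5 * SKIN) * (0.5 * SKIN)
    binding_on = eps_sp > 0.0

    if rebuild[0] != 0:
        if _build_nlist(pos, box, rlist, nlist, ncount, ref_pos):
            return isave0, STATUS_NLIST_OVERFLOW
        rebuild[0] = 0
    for i in range(n):
        for d in range(3):
            forces[i, d] = 0.0
    pe = _nonbonded_from_list(pos, box, link_type, chain_id, partner,
                              eps, eps_sp, wca_bonded, nlist, ncount, forces)
    pe += _bonded_forces(pos, box, bonds, angles, kb, r0, ka, forces)

    isave = isave0
    status = STATUS_OK
    for k in range(n_steps):
        gstep = step0 + k + 1
        # B (half kick) + A (half drift)
        for i in range(n):
            for d in range(3):
                vel[i, d] += half * forces[i, d]
                pos[i, d] += 0.5 * dt * vel[i, d]
        # O (friction + noise), every NOISE_STRIDE-th step
        if gamma > 0.0 and gstep % NOISE_STRIDE == 0:
            for i in range(n):
                for d in range(3):
                    vel[i, d] = c1 * vel[i, d] + c2 * noise[noise_row, 3 * i + d]
            noise_row += 1
        # A (half drift)
        maxdisp2 = 0.0
        for i in range(n):
            dsp2 = 0.0
            for d in range(3):
                pos[i, d] += 0.5 * dt * vel[i, d]
                step_d = dt * vel[i, d]
                dsp2 += step_d * step_d
            if dsp2 > maxdisp2:
                maxdisp2 = dsp2
        if not np.isfinite(maxdisp2):
            status = STATUS_NONFINITE
            break
        if maxdisp2 > 0.25 * lmin * lmin:
            status = STATUS_BLOWUP
            break
        # wrap into the box, updating image counters
        for i in range(n):
            for d in range(3):
                sh = np.floor(pos[i, d] / box[d])
                if sh != 0.0:
                    pos[i, d] -= sh * box[d]
                    img[i, d] += np.int64(sh)
        # rebuild the neighbour list if any particle moved > skin/2
        need = False
        for i in range(n):
            dx = _min_image(pos[i, 0] - ref_pos[i, 0], box[0])
            dy = _min_image(pos[i, 1] - ref_pos[i, 1], box[1])
            dz = _min_image(pos[i, 2] - ref_pos[i, 2], box[2])
            if dx * dx + dy * dy + dz * dz > skin_half2:
                need = True
                break
        if need:
            if _build_nlist(pos, box, rlist, nlist, ncount, ref_pos):
                status = STATUS_NLIST_OVERFLOW
                break
        if binding_on:
            _update_bindings_from_list(pos, box, link_type, partner, r_bind,
                                       nlist, ncount, cand, cdist)
        for i in range(n):
            for d in range(3):
                forces[i, d] = 0.0
        pe = _nonbonded_from_list(pos, box, link_type, chain_id, partner,
                                  eps, eps_sp, wca_bonded, nlist, ncount, forces)
        pe += _bonded_forces(pos, box, bonds, angles, kb, r0, ka, forces)
        # B (half kick)
        ke = 0.0
        for i in range(n):
            for d in range(3):
                vel[i, d] += half * forces[i, d]
                ke += 0.5 * mass * vel[i, d] * vel[i, d]
        if save_every > 0 and gstep % save_every == 0 and isave < nsave_cap:
            for i in range(n):
                tpart[isave, i] = partner[i]
                for d in range(3):
                    tp[isave, i, d] = pos[i, d]
                    ti[isave, i, d] = img[i, d]
            tt[isave] = gstep * dt
            tke[isave] = ke
            tpe[isave] = pe
            isave += 1
    return isave, status


@njit(cache=True, inline="always")
def cand_capacity(n):
    return 16 * n + 64
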