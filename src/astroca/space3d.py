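"""Voxel-based 3D reaction-diffusion engine for the astrocyte-process
geometry (reaction-diffusion master equation with diffusion as first-order
inter-voxel hops).

The cytosol is the shell between a plasma-membrane cylinder (length 1 um,
radius 0.1 um) and a shorter coaxial ER cylinder (0.75 um, 0.03 um).  It is
discretized into a structured mesh of axial slices x radial rings x angular
sectors whose volumes are analytically exact; both membranes are reflective
and IP3R channels sit in cytosolic voxels touching the ER surface.  Three
model variants are supported: "No-GCaMP" (raw signal = free Ca), "GCaMP"
(GCaMP6s or 6f indicator; raw signal = Ca-bound indicator) and "GC+Buf"
(additional endogenous buffers).

Sampling uses a fixed-step tau-leap with the step chosen so the largest
per-molecule event probability stays near 5%, which at the copy numbers of
this system (a few hundred molecules) is statistically indistinguishable
from exact event sampling (verified against the Gillespie engine on a
degenerate single-voxel mesh).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .core import (AVOGADRO, BufferSpec, ConfigurationError, GECIParams,
                   Geometry3DParams, KineticParams, SimulationTrace,
                   TABLE2_COUNTS)
from .ip3r import OPEN_STATE


# ---------------------------------------------------------------------------
# mesh construction
# ---------------------------------------------------------------------------

@dataclass
class ProcessMesh:
    """Structured cylindrical-shell discretization of the cytosol."""

    centers: np.ndarray          # (n_vox, 3) m, for reporting/classification
    volumes: np.ndarray          # (n_vox,) liters
    nbr_start: np.ndarray        # CSR over voxels
    nbr_idx: np.ndarray
    nbr_k: np.ndarray            # A_ij/(V_i*d_ij) in 1/m^2 (V_i in m^3)
    er_surface: np.ndarray       # voxel ids touching the ER lateral surface
    plasma_surface: np.ndarray   # voxel ids touching the plasma membrane
    geometry: Geometry3DParams | None = None

    @property
    def n_voxels(self) -> int:
        return len(self.volumes)

    @property
    def total_volume(self) -> float:
        """Mesh cytosolic volume in liters."""
        return float(self.volumes.sum())


def build_mesh(geom: Geometry3DParams, ntheta: int = 8) -> ProcessMesh:
    """Build the structured mesh at ``geom.voxel_scale`` resolution.

    Rings touching the axis (in the ER-free end caps) are kept as single
    central voxels rather than split into slivers, which keeps the maximal
    hop rate — and hence the time step — well behaved.
    """
    h = geom.voxel_scale
    if round((geom.R_astro - geom.R_ER) / h) < 1:
        raise ConfigurationError(
            "voxel_scale too coarse to separate the ER from the plasma "
            "membrane; reduce it below ~1.5x the membrane gap")
    nx = max(1, round(geom.L_astro / h))
    dx = geom.L_astro / nx
    er_lo = 0.5 * (geom.L_astro - geom.L_ER)
    er_hi = geom.L_astro - er_lo

    def ring_edges(has_er: bool) -> np.ndarray:
        if has_er:
            nr = max(1, round((geom.R_astro - geom.R_ER) / h))
            return np.linspace(geom.R_ER, geom.R_astro, nr + 1)
        nr = max(1, round(geom.R_astro / h))
        return np.linspace(0.0, geom.R_astro, nr + 1)

    def nsec(edges, r) -> int:
        return 1 if edges[r] == 0.0 else ntheta

    # enumerate voxels slice by slice
    slice_has_er = []
    slice_rings = []
    vox_of = {}
    centers = []
    volumes_m3 = []
    for i in range(nx):
        xc = (i + 0.5) * dx
        has_er = er_lo < xc < er_hi
        edges = ring_edges(has_er)
        slice_has_er.append(has_er)
        slice_rings.append(edges)
        for r in range(len(edges) - 1):
            ns = nsec(edges, r)
            for s in range(ns):
                vox_of[(i, r, s)] = len(centers)
                r_mid = 0.5 * (edges[r] + edges[r + 1])
                th = (s + 0.5) * 2 * math.pi / ns
                centers.append((xc, r_mid * math.cos(th), r_mid * math.sin(th)))
                volumes_m3.append(math.pi * (edges[r + 1] ** 2 - edges[r] ** 2)
                                  * dx / ns)

    n_vox = len(centers)
    volumes_m3 = np.asarray(volumes_m3)
    centers = np.asarray(centers)

    pairs: list[tuple[int, int, float, float]] = []  # (i, j, area, dist)

    def add(i, j, area, dist):
        pairs.append((i, j, area, dist))
        pairs.append((j, i, area, dist))

    for i in range(nx):
        edges = slice_rings[i]
        nr = len(edges) - 1
        for r in range(nr):
            r_mid = 0.5 * (edges[r] + edges[r + 1])
            ns = nsec(edges, r)
            # radial neighbours (outward)
            if r + 1 < nr:
                ns2 = nsec(edges, r + 1)
                r_mid2 = 0.5 * (edges[r + 1] + edges[r + 2])
                if ns == 1 and ns2 == ntheta:
                    for s2 in range(ns2):
                        add(vox_of[(i, r, 0)], vox_of[(i, r + 1, s2)],
                            2 * math.pi * edges[r + 1] * dx / ns2,
                            r_mid2 - r_mid)
                else:
                    for s in range(ns):
                        add(vox_of[(i, r, s)], vox_of[(i, r + 1, s)],
                            2 * math.pi * edges[r + 1] * dx / ns,
                            r_mid2 - r_mid)
            # angular neighbours within a sector-split ring
            if ns > 2:
                for s in range(ns):
                    w = vox_of[(i, r, (s + 1) % ns)]
                    v = vox_of[(i, r, s)]
                    if w > v:
                        add(v, w, (edges[r + 1] - edges[r]) * dx,
                            r_mid * 2 * math.pi / ns)
            elif ns == 2:
                add(vox_of[(i, r, 0)], vox_of[(i, r, 1)],
                    (edges[r + 1] - edges[r]) * dx, r_mid * math.pi)
        # axial neighbours to slice i+1 (rings may differ across slices)
        if i + 1 < nx:
            edges2 = slice_rings[i + 1]
            nr2 = len(edges2) - 1
            for r in range(nr):
                ns = nsec(edges, r)
                for r2 in range(nr2):
                    ns2 = nsec(edges2, r2)
                    lo = max(edges[r], edges2[r2])
                    hi = min(edges[r + 1], edges2[r2 + 1])
                    if hi <= lo:
                        continue
                    area = math.pi * (hi ** 2 - lo ** 2)
                    if ns == ns2 == ntheta:
                        for s in range(ntheta):
                            add(vox_of[(i, r, s)], vox_of[(i + 1, r2, s)],
                                area / ntheta, dx)
                    elif ns == 1 and ns2 == ntheta:
                        for s2 in range(ns2):
                            add(vox_of[(i, r, 0)], vox_of[(i + 1, r2, s2)],
                                area / ns2, dx)
                    elif ns == ntheta and ns2 == 1:
                        for s in range(ns):
                            add(vox_of[(i, r, s)], vox_of[(i + 1, r2, 0)],
                                area / ns, dx)
                    else:
                        add(vox_of[(i, r, 0)], vox_of[(i + 1, r2, 0)],
                            area, dx)

    # CSR with hop-rate geometric factors
    nbr_start = np.zeros(n_vox + 1, dtype=np.int64)
    for i, _, _, _ in pairs:
        nbr_start[i + 1] += 1
    nbr_start = np.cumsum(nbr_start)
    nbr_idx = np.zeros(len(pairs), dtype=np.int64)
    nbr_k = np.zeros(len(pairs))
    fill = nbr_start[:-1].copy()
    for i, j, area, dist in pairs:
        nbr_idx[fill[i]] = j
        nbr_k[fill[i]] = area / (volumes_m3[i] * dist)
        fill[i] += 1

    er_surface = []
    plasma_surface = []
    for (i, r, _s), v in vox_of.items():
        edges = slice_rings[i]
        if slice_has_er[i] and r == 0:
            er_surface.append(v)
        if r == len(edges) - 2:
            plasma_surface.append(v)

    return ProcessMesh(centers, volumes_m3 * 1e3, nbr_start, nbr_idx, nbr_k,
                       np.asarray(sorted(er_surface), dtype=np.int64),
                       np.asarray(sorted(plasma_surface), dtype=np.int64),
                       geom)


def single_voxel_mesh(volume_liters: float) -> ProcessMesh:
    """Degenerate well-mixed mesh (one voxel, no diffusion) for testing."""
    return ProcessMesh(
        centers=np.zeros((1, 3)),
        volumes=np.array([volume_liters]),
        nbr_start=np.array([0, 0], dtype=np.int64),
        nbr_idx=np.empty(0, dtype=np.int64),
        nbr_k=np.empty(0),
        er_surface=np.array([0], dtype=np.int64),
        plasma_surface=np.array([0], dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# tau-leap kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _find_remove(vox_of, n, v):
    """Remove (swap-delete) one molecule located in voxel v; return new n."""
    for i in range(n):
        if vox_of[i] == v:
            vox_of[i] = vox_of[n - 1]
            return n - 1
    return n  # should not happen if counts are consistent


@njit(cache=True)
def _hop(v, nbr_start, nbr_idx, nbr_k, K, u):
    """Choose a hop destination from voxel v; u ~ U(0,1)."""
    acc = 0.0
    target = u * K[v]
    for q in range(nbr_start[v], nbr_start[v + 1]):
        acc += nbr_k[q]
        if target < acc:
            return nbr_idx[q]
    return nbr_idx[nbr_start[v + 1] - 1]


@njit(cache=True)
def _run3d_kernel(n_vox, vol_L, nbr_start, nbr_idx, nbr_k, K, cumvol,
                  plc_cnt, rec_vox, rec_at,
                  D_s, n_species, n_buf,
                  a1, a2, a3, b1, b2, b3, delta, beta, alpha,
                  gamma_ions, mu,
                  kon_g, koff_g, kon_buf, koff_buf,
                  init_counts, init_vox_ca, init_vox_ip3, init_vox_g,
                  tau, n_steps, sample_every, seed, cap,
                  log_transitions, log_cap,
                  bolus_step, bolus_count, bolus_vox):
    np.random.seed(seed)

    NA_V = AVOGADRO_ * vol_L  # molecules per molar, per voxel
    n_rec = rec_vox.shape[0]
    rstate = np.zeros(n_rec, dtype=np.int64)

    mob = np.full((n_species, cap), -1, dtype=np.int64)
    n_mob = np.zeros(n_species, dtype=np.int64)
    cnt = np.zeros((n_species, n_vox), dtype=np.int64)

    # initial placement
    for i in range(init_counts[0]):
        v = init_vox_ca[i]
        mob[0, i] = v
        cnt[0, v] += 1
    n_mob[0] = init_counts[0]
    for i in range(init_counts[1]):
        v = init_vox_ip3[i]
        mob[1, i] = v
        cnt[1, v] += 1
    n_mob[1] = init_counts[1]
    for i in range(init_counts[2]):
        v = init_vox_g[i]
        mob[2, i] = v
        cnt[2, v] += 1
    n_mob[2] = init_counts[2]
    for b in range(n_buf):
        s = 4 + 2 * b
        for i in range(init_counts[s]):
            u = np.random.random()
            v = 0
            for q in range(n_vox):
                if u < cumvol[q]:
                    v = q
                    break
            mob[s, i] = v
            cnt[s, v] += 1
        n_mob[s] = init_counts[s]

    n_samples = n_steps // sample_every + 1
    tr_ca = np.empty(n_samples, dtype=np.int64)
    tr_ip = np.empty(n_samples, dtype=np.int64)
    tr_open = np.empty(n_samples, dtype=np.int64)
    tr_gb = np.empty(n_samples, dtype=np.int64)
    isample = 0

    log = np.empty((log_cap if log_transitions else 1, 4))
    n_log = 0
    overflow = False

    n_open = 0

    for step in range(n_steps + 1):
        if step % sample_every == 0 and isample < n_samples:
            tr_ca[isample] = n_mob[0]
            tr_ip[isample] = n_mob[1]
            tr_open[isample] = n_open
            tr_gb[isample] = n_mob[3]
            isample += 1
        if step == n_steps:
            break
        t_now = (step + 1) * tau

        if step == bolus_step:
            for _ in range(bolus_count):
                if n_mob[0] < cap:
                    mob[0, n_mob[0]] = bolus_vox
                    n_mob[0] += 1
                    cnt[0, bolus_vox] += 1

        # --- Ca pass: removal / indicator / buffer / receptor binding,
        #     PLC-catalysed IP3 production, hop --------------------------
        i = 0
        while i < n_mob[0]:
            v = mob[0, i]
            lam = D_s[0] * K[v] * tau
            did_multihop_ca = lam > 0.25
            if did_multihop_ca:
                for _ in range(np.random.poisson(lam)):
                    w = _hop(v, nbr_start, nbr_idx, nbr_k, K,
                             np.random.random())
                    cnt[0, v] -= 1
                    cnt[0, w] += 1
                    v = w
                mob[0, i] = v
            inv_nav = 1.0 / NA_V[v]
            # independent (non-consuming) PLC production
            if plc_cnt[v] > 0 and delta > 0.0:
                if np.random.random() < delta * plc_cnt[v] * inv_nav * tau:
                    if n_mob[1] < cap:
                        mob[1, n_mob[1]] = v
                        n_mob[1] += 1
                        cnt[1, v] += 1
                    else:
                        overflow = True
            u = np.random.random()
            acc = alpha * tau
            consumed = False
            if u < acc:
                mob[0, i] = mob[0, n_mob[0] - 1]
                n_mob[0] -= 1
                cnt[0, v] -= 1
                consumed = True
            if not consumed and kon_g > 0.0 and cnt[2, v] > 0:
                acc += kon_g * cnt[2, v] * inv_nav * tau
                if u < acc:
                    n_mob[2] = _find_remove(mob[2], n_mob[2], v)
                    cnt[2, v] -= 1
                    if n_mob[3] < cap:
                        mob[3, n_mob[3]] = v
                        n_mob[3] += 1
                        cnt[3, v] += 1
                    mob[0, i] = mob[0, n_mob[0] - 1]
                    n_mob[0] -= 1
                    cnt[0, v] -= 1
                    consumed = True
            if not consumed:
                for b in range(n_buf):
                    sf = 4 + 2 * b
                    if cnt[sf, v] > 0 and kon_buf[b] > 0.0:
                        acc += kon_buf[b] * cnt[sf, v] * inv_nav * tau
                        if u < acc:
                            n_mob[sf] = _find_remove(mob[sf], n_mob[sf], v)
                            cnt[sf, v] -= 1
                            sb = sf + 1
                            if n_mob[sb] < cap:
                                mob[sb, n_mob[sb]] = v
                                n_mob[sb] += 1
                                cnt[sb, v] += 1
                            mob[0, i] = mob[0, n_mob[0] - 1]
                            n_mob[0] -= 1
                            cnt[0, v] -= 1
                            consumed = True
                            break
            if not consumed and rec_at[v] >= 0:
                r = rec_at[v]
                s = rstate[r]
                if (s >> 2) & 1 == 0:
                    acc += a1 * inv_nav * tau
                    if u < acc:
                        old = s
                        rstate[r] = s | 4
                        mob[0, i] = mob[0, n_mob[0] - 1]
                        n_mob[0] -= 1
                        cnt[0, v] -= 1
                        consumed = True
                        if rstate[r] == OPEN_STATE:
                            n_open += 1
                        if log_transitions and (old == OPEN_STATE or rstate[r] == OPEN_STATE):
                            if n_log < log_cap:
                                log[n_log, 0] = t_now
                                log[n_log, 1] = r
                                log[n_log, 2] = old
                                log[n_log, 3] = rstate[r]
                                n_log += 1
                if not consumed and (s >> 0) & 1 == 0:
                    acc += a3 * inv_nav * tau
                    if u < acc:
                        old = rstate[r]
                        rstate[r] = old | 1
                        mob[0, i] = mob[0, n_mob[0] - 1]
                        n_mob[0] -= 1
                        cnt[0, v] -= 1
                        consumed = True
                        if old == OPEN_STATE:
                            n_open -= 1
                            if log_transitions and n_log < log_cap:
                                log[n_log, 0] = t_now
                                log[n_log, 1] = r
                                log[n_log, 2] = old
                                log[n_log, 3] = rstate[r]
                                n_log += 1
            if not consumed:
                if not did_multihop_ca:
                    p_hop = D_s[0] * K[v] * tau
                    acc += p_hop
                    if u < acc:
                        w = _hop(v, nbr_start, nbr_idx, nbr_k, K,
                                 (u - (acc - p_hop)) / p_hop)
                        mob[0, i] = w
                        cnt[0, v] -= 1
                        cnt[0, w] += 1
                i += 1
            # if consumed, the swapped-in molecule is processed next loop

        # --- IP3 pass (fast diffuser: Poisson multi-hop, then reactions) --
        i = 0
        while i < n_mob[1]:
            v = mob[1, i]
            lam = D_s[1] * K[v] * tau
            did_multihop = lam > 0.25
            if did_multihop:
                for _ in range(np.random.poisson(lam)):
                    w = _hop(v, nbr_start, nbr_idx, nbr_k, K,
                             np.random.random())
                    cnt[1, v] -= 1
                    cnt[1, w] += 1
                    v = w
                mob[1, i] = v
            inv_nav = 1.0 / NA_V[v]
            u = np.random.random()
            acc = beta * tau
            consumed = False
            if u < acc:
                mob[1, i] = mob[1, n_mob[1] - 1]
                n_mob[1] -= 1
                cnt[1, v] -= 1
                consumed = True
            if not consumed and rec_at[v] >= 0:
                r = rec_at[v]
                s = rstate[r]
                if (s >> 1) & 1 == 0:
                    acc += a2 * inv_nav * tau
                    if u < acc:
                        old = s
                        rstate[r] = s | 2
                        mob[1, i] = mob[1, n_mob[1] - 1]
                        n_mob[1] -= 1
                        cnt[1, v] -= 1
                        consumed = True
                        if rstate[r] == OPEN_STATE:
                            n_open += 1
                            if log_transitions and n_log < log_cap:
                                log[n_log, 0] = t_now
                                log[n_log, 1] = r
                                log[n_log, 2] = old
                                log[n_log, 3] = rstate[r]
                                n_log += 1
            if not consumed:
                if not did_multihop:
                    acc += D_s[1] * K[v] * tau
                    if u < acc:
                        w = _hop(v, nbr_start, nbr_idx, nbr_k, K,
                                 np.random.random())
                        mob[1, i] = w
                        cnt[1, v] -= 1
                        cnt[1, w] += 1
                i += 1

        # --- GCaMP free: diffusion only (Poisson multi-hop) ---------------
        for i in range(n_mob[2]):
            v = mob[2, i]
            lam = D_s[2] * K[v] * tau
            if lam > 0.25:
                for _ in range(np.random.poisson(lam)):
                    w = _hop(v, nbr_start, nbr_idx, nbr_k, K,
                             np.random.random())
                    cnt[2, v] -= 1
                    cnt[2, w] += 1
                    v = w
                mob[2, i] = v
            elif np.random.random() < lam:
                w = _hop(v, nbr_start, nbr_idx, nbr_k, K, np.random.random())
                mob[2, i] = w
                cnt[2, v] -= 1
                cnt[2, w] += 1

        # --- GCaMP-Ca: dissociation or hop ------------------------------
        i = 0
        while i < n_mob[3]:
            v = mob[3, i]
            lam = D_s[3] * K[v] * tau
            if lam > 0.25:
                for _ in range(np.random.poisson(lam)):
                    w = _hop(v, nbr_start, nbr_idx, nbr_k, K,
                             np.random.random())
                    cnt[3, v] -= 1
                    cnt[3, w] += 1
                    v = w
                mob[3, i] = v
                lam = 0.0
            u = np.random.random()
            if u < koff_g * tau:
                mob[3, i] = mob[3, n_mob[3] - 1]
                n_mob[3] -= 1
                cnt[3, v] -= 1
                if n_mob[2] < cap:
                    mob[2, n_mob[2]] = v
                    n_mob[2] += 1
                    cnt[2, v] += 1
                if n_mob[0] < cap:
                    mob[0, n_mob[0]] = v
                    n_mob[0] += 1
                    cnt[0, v] += 1
                else:
                    overflow = True
            else:
                if lam > 0.0 and u < koff_g * tau + lam:
                    w = _hop(v, nbr_start, nbr_idx, nbr_k, K,
                             np.random.random())
                    mob[3, i] = w
                    cnt[3, v] -= 1
                    cnt[3, w] += 1
                i += 1

        # --- buffers ----------------------------------------------------
        for b in range(n_buf):
            sf = 4 + 2 * b
            sb = sf + 1
            for i in range(n_mob[sf]):
                v = mob[sf, i]
                lam = D_s[sf] * K[v] * tau
                if lam > 0.25:
                    for _ in range(np.random.poisson(lam)):
                        w = _hop(v, nbr_start, nbr_idx, nbr_k, K,
                                 np.random.random())
                        cnt[sf, v] -= 1
                        cnt[sf, w] += 1
                        v = w
                    mob[sf, i] = v
                elif np.random.random() < lam:
                    w = _hop(v, nbr_start, nbr_idx, nbr_k, K,
                             np.random.random())
                    mob[sf, i] = w
                    cnt[sf, v] -= 1
                    cnt[sf, w] += 1
            i = 0
            while i < n_mob[sb]:
                v = mob[sb, i]
                lam = D_s[sb] * K[v] * tau
                if lam > 0.25:
                    for _ in range(np.random.poisson(lam)):
                        w = _hop(v, nbr_start, nbr_idx, nbr_k, K,
                                 np.random.random())
                        cnt[sb, v] -= 1
                        cnt[sb, w] += 1
                        v = w
                    mob[sb, i] = v
                    lam = 0.0
                u = np.random.random()
                if u < koff_buf[b] * tau:
                    mob[sb, i] = mob[sb, n_mob[sb] - 1]
                    n_mob[sb] -= 1
                    cnt[sb, v] -= 1
                    mob[sf, n_mob[sf]] = v
                    n_mob[sf] += 1
                    cnt[sf, v] += 1
                    if n_mob[0] < cap:
                        mob[0, n_mob[0]] = v
                        n_mob[0] += 1
                        cnt[0, v] += 1
                    else:
                        overflow = True
                else:
                    if lam > 0.0 and u < koff_buf[b] * tau + lam:
                        w = _hop(v, nbr_start, nbr_idx, nbr_k, K,
                                 np.random.random())
                        mob[sb, i] = w
                        cnt[sb, v] -= 1
                        cnt[sb, w] += 1
                    i += 1

        # --- receptor unbinding and channel influx ----------------------
        for r in range(n_rec):
            s = rstate[r]
            if s == 0:
                continue
            v = rec_vox[r]
            for site in range(3):
                bit = 2 - site
                if (s >> bit) & 1 == 1:
                    b_rate = b1 if site == 0 else (b2 if site == 1 else b3)
                    if np.random.random() < b_rate * tau:
                        old = rstate[r]
                        rstate[r] = old & ~(1 << bit)
                        s = rstate[r]
                        sp = 1 if site == 1 else 0
                        if n_mob[sp] < cap:
                            mob[sp, n_mob[sp]] = v
                            n_mob[sp] += 1
                            cnt[sp, v] += 1
                        else:
                            overflow = True
                        if old == OPEN_STATE or rstate[r] == OPEN_STATE:
                            if rstate[r] == OPEN_STATE:
                                n_open += 1
                            else:
                                n_open -= 1
                            if log_transitions and n_log < log_cap:
                                log[n_log, 0] = t_now
                                log[n_log, 1] = r
                                log[n_log, 2] = old
                                log[n_log, 3] = rstate[r]
                                n_log += 1
            if rstate[r] == OPEN_STATE:
                for _ in range(np.random.poisson(mu * tau)):
                    if n_mob[0] < cap:
                        mob[0, n_mob[0]] = v
                        n_mob[0] += 1
                        cnt[0, v] += 1
                    else:
                        overflow = True

        # --- IP3R-independent influx (uniform over the cytosol) ---------
        if np.random.random() < gamma_ions * tau:
            u = np.random.random()
            v = n_vox - 1
            for q in range(n_vox):
                if u < cumvol[q]:
                    v = q
                    break
            if n_mob[0] < cap:
                mob[0, n_mob[0]] = v
                n_mob[0] += 1
                cnt[0, v] += 1
            else:
                overflow = True

    return (tr_ca[:isample], tr_ip[:isample], tr_open[:isample],
            tr_gb[:isample], log[:n_log], overflow)


AVOGADRO_ = AVOGADRO  # module-level constant visible to the jitted kernel


# ---------------------------------------------------------------------------
# public driver
# ---------------------------------------------------------------------------

def run_3d(mesh: ProcessMesh, kinetics: KineticParams,
           geci: GECIParams | None = None,
           buffers: tuple[BufferSpec, ...] = (),
           T: float = 10.0, seed: int = 1, sample_dt: float = 0.05,
           counts: dict | None = None,
           tau: float | None = None, tau_safety: float = 0.05,
           capacity: int = 100_000, record_transitions: bool = False,
           log_capacity: int = 1_000_000,
           canonical_volume: float | None = None,
           ca_bolus: tuple[float, int] | None = None) -> SimulationTrace:
    """Simulate the 3D model for ``T`` seconds of biological time.

    ``kinetics`` must be in SI units; ``gamma`` is a volumetric influx in
    M/s over the canonical volume.  ``counts`` may override the default
    initial copy numbers (keys ``Ca0, IP0, N_plc, N_IP3R, N_GCaMP``).
    Concentration columns are reported through the canonical volume.
    """
    if kinetics.unit_system != "si":
        raise ConfigurationError("the 3D engine requires SI-unit kinetics")
    if T <= 0:
        raise ValueError("T must be positive")
    geci = geci or GECIParams()
    c = dict(TABLE2_COUNTS)
    c.update(counts or {})
    V_can = canonical_volume or (mesh.geometry.V_cyt_canonical
                                 if mesh.geometry else mesh.total_volume)
    n_gcamp = (c["N_GCaMP"] if geci.variant != "none" else 0)
    if geci.variant != "none" and geci.C_total > 0:
        n_gcamp = int(round(geci.C_total * AVOGADRO * V_can))

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 91]))
    n_vox = mesh.n_voxels
    vols = mesh.volumes
    probs = vols / vols.sum()
    cumvol = np.cumsum(probs)

    plc_cnt = rng.multinomial(c["N_plc"], probs).astype(np.int64)

    n_rec = c["N_IP3R"]
    if n_rec > len(mesh.er_surface):
        raise ConfigurationError(
            f"cannot place {n_rec} receptors in {len(mesh.er_surface)} "
            "distinct ER-surface voxels; refine the mesh")
    rec_vox = rng.choice(mesh.er_surface, size=n_rec,
                         replace=False).astype(np.int64)
    rec_at = np.full(n_vox, -1, dtype=np.int64)
    rec_at[rec_vox] = np.arange(n_rec)

    n_buf = len(buffers)
    n_species = 4 + 2 * n_buf
    D_s = np.zeros(n_species)
    D_s[0] = kinetics_D(kinetics, "D_Ca")
    D_s[1] = kinetics_D(kinetics, "D_IP3")
    D_s[2] = D_s[3] = geci.D_GCaMP
    kon_buf = np.zeros(max(n_buf, 1))
    koff_buf = np.zeros(max(n_buf, 1))
    init_counts = np.zeros(n_species, dtype=np.int64)
    init_counts[0] = c["Ca0"]
    init_counts[1] = c["IP0"]
    init_counts[2] = n_gcamp
    for b, spec in enumerate(buffers):
        D_s[4 + 2 * b] = spec.D_free
        D_s[5 + 2 * b] = spec.D_bound
        kon_buf[b] = spec.k_on
        koff_buf[b] = spec.k_off
        init_counts[4 + 2 * b] = int(round(spec.total * AVOGADRO * V_can))

    init_vox_ca = rng.choice(n_vox, size=max(c["Ca0"], 1), p=probs).astype(np.int64)
    init_vox_ip3 = rng.choice(n_vox, size=max(c["IP0"], 1), p=probs).astype(np.int64)
    init_vox_g = rng.choice(n_vox, size=max(n_gcamp, 1), p=probs).astype(np.int64)

    K = np.zeros(n_vox)
    for v in range(n_vox):
        K[v] = mesh.nbr_k[mesh.nbr_start[v]:mesh.nbr_start[v + 1]].sum()

    gamma_ions = kinetics.gamma * AVOGADRO * V_can  # M/s -> ions/s

    if tau is None:
        # Fast diffusers take Poisson multi-hop counts within a step, so
        # hop rates do not bound the step stiffly; the step is chosen to
        # resolve (i) Ca hops at a fraction of a hop per step, preserving
        # the near-channel spatial correlations the model is about, and
        # (ii) every reaction at <= tau_safety probability per step
        # (channel influx uses Poisson counts and needs no bound).
        Kmax = K.max() if n_vox > 1 else 0.0
        max_rate = max(kinetics.b1, kinetics.b2, kinetics.b3,
                       kinetics.alpha, kinetics.beta, geci.k_off,
                       max((b.k_off for b in buffers), default=0.0), 1.0)
        tau = tau_safety / max_rate
        if Kmax > 0.0:
            tau = min(tau, 0.3 / (D_s[0] * Kmax))

    n_steps = int(round(T / tau))
    sample_every = max(1, int(round(sample_dt / tau)))

    # optional Ca bolus at an ER-surface voxel (mimics a channel burst)
    bolus_step, bolus_count, bolus_vox = -1, 0, 0
    if ca_bolus is not None:
        bolus_step = int(round(ca_bolus[0] / tau))
        bolus_count = int(ca_bolus[1])
        bolus_vox = int(rng.choice(mesh.er_surface))

    (ca, ip3, op, gb, log, overflow) = _run3d_kernel(
        n_vox, vols, mesh.nbr_start, mesh.nbr_idx, mesh.nbr_k, K, cumvol,
        plc_cnt, rec_vox, rec_at, D_s, n_species, n_buf,
        kinetics.a1, kinetics.a2, kinetics.a3,
        kinetics.b1, kinetics.b2, kinetics.b3,
        kinetics.delta, kinetics.beta, kinetics.alpha,
        gamma_ions, kinetics.mu,
        geci.k_on, geci.k_off, kon_buf, koff_buf,
        init_counts, init_vox_ca, init_vox_ip3, init_vox_g,
        tau, n_steps, sample_every, int(seed) % (2**32), int(capacity),
        record_transitions, int(log_capacity),
        bolus_step, bolus_count, bolus_vox)
    if overflow:
        raise RuntimeError("3D engine molecule capacity exceeded")

    time = np.arange(len(ca), dtype=float) * (sample_every * tau)
    to_nM = 1e9 / (AVOGADRO * V_can)
    meta = {
        "engine": "space3d",
        "unit_system": "si",
        "variant": ("No-GCaMP" if geci.variant == "none"
                    else ("GC+Buf" if buffers else geci.variant)),
        "V": V_can,
        "mesh_volume": mesh.total_volume,
        "seed": int(seed),
        "sample_dt": sample_every * tau,
        "tau": tau,
        "mode": "tau-leap",
        "n_voxels": n_vox,
    }
    trace = SimulationTrace(time=time, ca=ca.astype(float),
                            ip3=ip3.astype(float),
                            open_count=op.astype(float), meta=meta,
                            transitions=log if record_transitions else None,
                            receptor_positions=mesh.centers[rec_vox])
    trace.extra["ca_nM"] = ca * to_nM
    trace.extra["gcamp_ca"] = gb.astype(float)
    trace.extra["gcamp_ca_nM"] = gb * to_nM
    return trace


def kinetics_D(kinetics: KineticParams, name: str) -> float:
    """Diffusion defaults of the 3D parameter set (m^2/s)."""
    defaults = {"D_Ca": 13.0e-12, "D_IP3": 280.0e-12}
    return defaults[name]


def sample_fluorescence(trace: SimulationTrace, rate: float) -> SimulationTrace:
    """Point-sample the indicator signal at an imaging frame rate (Hz)."""
    if rate <= 0:
        raise ValueError("sampling rate must be positive")
    native_dt = float(trace.time[1] - trace.time[0]) if len(trace) > 1 else 0.0
    period = 1.0 / rate
    if native_dt > 0 and period < native_dt * (1 - 1e-9):
        raise ValueError("cannot sample faster than the native trace rate")
    idx = []
    t = trace.time[0]
    while t <= trace.time[-1] + 1e-12:
        idx.append(int(np.searchsorted(trace.time, t - 1e-12)))
        t += period
    idx = np.asarray(idx)
    out = SimulationTrace(
        time=trace.time[idx], ca=np.asarray(trace.ca)[idx],
        ip3=np.asarray(trace.ip3)[idx],
        open_count=np.asarray(trace.open_count)[idx],
        meta=dict(trace.meta, sample_dt=period, resampled_hz=rate),
        transitions=trace.transitions,
        receptor_positions=trace.receptor_positions,
    )
    for k, v in trace.extra.items():
        arr = np.asarray(v)
        if arr.ndim >= 1 and arr.shape[-1] == len(trace.time):
            out.extra[k] = arr[..., idx]
    return out
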