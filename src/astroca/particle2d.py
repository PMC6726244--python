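"""Lattice-free 2D Brownian-dynamics Monte-Carlo engine.

Every molecule carries an explicit position in a rectangular domain with
reflective boundaries.  PLCdelta and IP3R are immobile; Ca, IP3 (and the
optional explicit buffer particles) diffuse.  Each step of duration ``dt``
(0.01 MC time units) applies, in order: diffusion, binding, unbinding,
removal, influx.  Setting a diffusion coefficient to ``inf`` selects the
perfectly mixed mode in which positions are redrawn uniformly each step.

Contact reactions fire when a ligand lies within the interaction distance
of a receptor (or PLCdelta); the acceptance probability per candidate pair
and step is ``a_i*dt/(pi*d^2)``, so that the perfectly mixed limit
reproduces the mass-action propensity ``a_i/V`` used by the SSA and
mean-field models.  IP3R receptors are placed in clusters of ``eta``
channels drawn uniformly within a disk of radius
``R_c = d_IP3R*sqrt(eta/0.91)`` around uniformly placed centers, which
keeps the in-cluster areal density independent of ``eta``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .core import (BufferSpec, ConfigurationError, KineticParams,
                   SimulationTrace, SpatialParams2D, check_step_probabilities)
from .ip3r import OPEN_STATE


# ---------------------------------------------------------------------------
# receptor cluster placement
# ---------------------------------------------------------------------------

@dataclass
class ClusterLayout:
    """Positions of the IP3R channels and their cluster assignment."""

    positions: np.ndarray  # (N, 2)
    cluster_id: np.ndarray  # (N,)
    centers: np.ndarray  # (Nc, 2)
    radius: float  # R_c

    @property
    def n_receptors(self) -> int:
        return len(self.positions)


def cluster_radius(d_IP3R: float, eta: int) -> float:
    """R_c = d_IP3R * sqrt(eta / 0.91): constant areal density in clusters."""
    return d_IP3R * math.sqrt(eta / 0.91)


def place_receptor_clusters(N_IP3R: int, eta: int, d_IP3R: float,
                            extent: tuple[float, float],
                            seed) -> ClusterLayout:
    """Draw cluster centers uniformly and members uniformly within R_c.

    If ``eta`` does not divide ``N_IP3R`` the last cluster absorbs the
    remainder, preserving the total receptor count.
    """
    if N_IP3R < 1 or eta < 1:
        raise ConfigurationError("N_IP3R and eta must be >= 1")
    if eta > N_IP3R:
        raise ConfigurationError("eta cannot exceed N_IP3R")
    rng = np.random.default_rng(seed)
    Lx, Ly = extent
    n_clusters = N_IP3R // eta
    sizes = [eta] * n_clusters
    sizes[-1] += N_IP3R % eta
    rc = cluster_radius(d_IP3R, eta)
    centers = rng.uniform((0.0, 0.0), (Lx, Ly), size=(n_clusters, 2))
    pos = np.empty((N_IP3R, 2))
    cid = np.empty(N_IP3R, dtype=np.int64)
    k = 0
    for c, size in enumerate(sizes):
        r = rc * np.sqrt(rng.uniform(size=size))
        th = rng.uniform(0.0, 2 * math.pi, size=size)
        pos[k:k + size, 0] = centers[c, 0] + r * np.cos(th)
        pos[k:k + size, 1] = centers[c, 1] + r * np.sin(th)
        cid[k:k + size] = c
        k += size
    # reflect stray members into the domain
    pos[:, 0] = _reflect_np(pos[:, 0], Lx)
    pos[:, 1] = _reflect_np(pos[:, 1], Ly)
    return ClusterLayout(pos, cid, centers, rc)


def _reflect_np(x, L):
    x = np.mod(x, 2 * L)
    return np.where(x > L, 2 * L - x, x)


# ---------------------------------------------------------------------------
# static neighbour grids (immobile species)
# ---------------------------------------------------------------------------

def _build_grid(pos: np.ndarray, cell: float, Lx: float, Ly: float):
    nx = max(1, int(Lx / cell))
    ny = max(1, int(Ly / cell))
    ix = np.minimum((pos[:, 0] / (Lx / nx)).astype(np.int64), nx - 1)
    iy = np.minimum((pos[:, 1] / (Ly / ny)).astype(np.int64), ny - 1)
    flat = ix * ny + iy
    order = np.argsort(flat, kind="stable")
    sorted_flat = flat[order]
    start = np.searchsorted(sorted_flat, np.arange(nx * ny + 1))
    return nx, ny, start.astype(np.int64), order.astype(np.int64)


# ---------------------------------------------------------------------------
# the Monte-Carlo kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _reflect(x, L):
    while x < 0.0 or x > L:
        if x < 0.0:
            x = -x
        if x > L:
            x = 2.0 * L - x
    return x


@njit(cache=True)
def _grid_query(x, y, nx, ny, Lx, Ly, start, order, out):
    """Collect indices of immobile particles in the 3x3 cells around (x,y)."""
    cx = Lx / nx
    cy = Ly / ny
    ix = min(int(x / cx), nx - 1)
    iy = min(int(y / cy), ny - 1)
    n = 0
    for dx in range(-1, 2):
        jx = ix + dx
        if jx < 0 or jx >= nx:
            continue
        for dy in range(-1, 2):
            jy = iy + dy
            if jy < 0 or jy >= ny:
                continue
            flat = jx * ny + jy
            for p in range(start[flat], start[flat + 1]):
                if n < out.shape[0]:
                    out[n] = order[p]
                    n += 1
    return n


@njit(cache=True)
def _sim2d(rx, ry, plc_x, plc_y,
           rnx, rny, rstart, rorder,
           pnx, pny, pstart, porder,
           Lx, Ly, d_ip3r, d_plc,
           n_ca0, n_ip0, n_buf0,
           D_ca, D_ip, D_buf_free, D_buf_bound, inf_ca, inf_ip,
           a1, a2, a3, b1, b2, b3, delta, beta, alpha, gamma, mu,
           buf_on, buf_off,
           R_gamma, dt, n_steps, sample_every, seed,
           cap, log_transitions, log_cap):
    np.random.seed(seed)

    n_rec = rx.shape[0]
    rstate = np.zeros(n_rec, dtype=np.int64)
    site_bound_step = np.full((n_rec, 3), -1, dtype=np.int64)

    # mobile species arrays
    ca_x = np.empty(cap)
    ca_y = np.empty(cap)
    ca_fresh = np.full(cap, -1, dtype=np.int64)
    ip_x = np.empty(cap)
    ip_y = np.empty(cap)
    ip_fresh = np.full(cap, -1, dtype=np.int64)
    n_ca = n_ca0
    n_ip = n_ip0
    for i in range(n_ca0):
        ca_x[i] = np.random.random() * Lx
        ca_y[i] = np.random.random() * Ly
    for i in range(n_ip0):
        ip_x[i] = np.random.random() * Lx
        ip_y[i] = np.random.random() * Ly

    # explicit buffers: free and Ca-bound particles
    bcap = max(2 * n_buf0, 1)
    bf_x = np.empty(bcap)
    bf_y = np.empty(bcap)
    bb_x = np.empty(bcap)
    bb_y = np.empty(bcap)
    n_bf = n_buf0
    n_bb = 0
    for i in range(n_buf0):
        bf_x[i] = np.random.random() * Lx
        bf_y[i] = np.random.random() * Ly
    # hash grid for Ca-buffer contact detection (rebuilt each step)
    HSIZE = 8192
    bh_head = np.full(HSIZE, -1, dtype=np.int64)
    bh_stamp = np.full(HSIZE, -1, dtype=np.int64)
    bh_next = np.empty(bcap, dtype=np.int64)
    bf_taken = np.full(bcap, False)
    bcell = max(d_ip3r, 1e-12)

    # active receptors (any bound site); lazily compacted each step
    active = np.empty(n_rec, dtype=np.int64)
    n_active = 0

    sig_ca = math.sqrt(2.0 * D_ca * dt) if not inf_ca else 0.0
    sig_ip = math.sqrt(2.0 * D_ip * dt) if not inf_ip else 0.0
    sig_bf = math.sqrt(2.0 * D_buf_free * dt)
    sig_bb = math.sqrt(2.0 * D_buf_bound * dt)

    pi_d2_r = math.pi * d_ip3r * d_ip3r
    pi_d2_p = math.pi * d_plc * d_plc
    p_a1 = a1 * dt / pi_d2_r
    p_a2 = a2 * dt / pi_d2_r
    p_a3 = a3 * dt / pi_d2_r
    p_delta = delta * dt / pi_d2_p
    p_buf_on = buf_on * dt / pi_d2_r

    n_samples = n_steps // sample_every + 1
    tr_ca = np.empty(n_samples, dtype=np.int64)
    tr_ip = np.empty(n_samples, dtype=np.int64)
    tr_open = np.empty(n_samples, dtype=np.int64)
    tr_bb = np.empty(n_samples, dtype=np.int64)
    isample = 0

    log = np.empty((log_cap if log_transitions else 1, 4))
    n_log = 0
    log_overflow = False
    overflow = False

    neigh = np.empty(128, dtype=np.int64)
    cand_cap = 65536
    cand_type = np.empty(cand_cap, dtype=np.int64)
    cand_lig = np.empty(cand_cap, dtype=np.int64)
    cand_rec = np.empty(cand_cap, dtype=np.int64)
    ca_remove = np.full(cap, False)
    ip_remove = np.full(cap, False)

    n_open = 0

    for step in range(n_steps + 1):
        if step % sample_every == 0 and isample < n_samples:
            tr_ca[isample] = n_ca
            tr_ip[isample] = n_ip
            tr_open[isample] = n_open
            tr_bb[isample] = n_bb
            isample += 1
        if step == n_steps:
            break

        # --- 1. diffusion -------------------------------------------------
        if inf_ca:
            for i in range(n_ca):
                ca_x[i] = np.random.random() * Lx
                ca_y[i] = np.random.random() * Ly
        elif sig_ca > 0.0:
            for i in range(n_ca):
                ca_x[i] = _reflect(ca_x[i] + sig_ca * np.random.normal(0.0, 1.0), Lx)
                ca_y[i] = _reflect(ca_y[i] + sig_ca * np.random.normal(0.0, 1.0), Ly)
        if inf_ip:
            for i in range(n_ip):
                ip_x[i] = np.random.random() * Lx
                ip_y[i] = np.random.random() * Ly
        elif sig_ip > 0.0:
            for i in range(n_ip):
                ip_x[i] = _reflect(ip_x[i] + sig_ip * np.random.normal(0.0, 1.0), Lx)
                ip_y[i] = _reflect(ip_y[i] + sig_ip * np.random.normal(0.0, 1.0), Ly)
        if sig_bf > 0.0:
            for i in range(n_bf):
                bf_x[i] = _reflect(bf_x[i] + sig_bf * np.random.normal(0.0, 1.0), Lx)
                bf_y[i] = _reflect(bf_y[i] + sig_bf * np.random.normal(0.0, 1.0), Ly)
        if sig_bb > 0.0:
            for i in range(n_bb):
                bb_x[i] = _reflect(bb_x[i] + sig_bb * np.random.normal(0.0, 1.0), Lx)
                bb_y[i] = _reflect(bb_y[i] + sig_bb * np.random.normal(0.0, 1.0), Ly)

        # --- 2a. PLC-catalysed IP3 production (Ca not consumed) -----------
        for i in range(n_ca):
            nn = _grid_query(ca_x[i], ca_y[i], pnx, pny, Lx, Ly,
                             pstart, porder, neigh)
            for q in range(nn):
                p = neigh[q]
                dx = ca_x[i] - plc_x[p]
                dy = ca_y[i] - plc_y[p]
                if dx * dx + dy * dy <= d_plc * d_plc:
                    if np.random.random() < p_delta:
                        if n_ip < cap:
                            ip_x[n_ip] = plc_x[p]
                            ip_y[n_ip] = plc_y[p]
                            ip_fresh[n_ip] = -1
                            n_ip += 1
                        else:
                            overflow = True
                        break  # one IP3 per Ca per step at most

        # --- 2b. receptor binding (shuffled candidate pairs) --------------
        n_cand = 0
        for i in range(n_ca):
            nn = _grid_query(ca_x[i], ca_y[i], rnx, rny, Lx, Ly,
                             rstart, rorder, neigh)
            for q in range(nn):
                r = neigh[q]
                dx = ca_x[i] - rx[r]
                dy = ca_y[i] - ry[r]
                if dx * dx + dy * dy <= d_ip3r * d_ip3r:
                    if n_cand < cand_type.shape[0]:
                        cand_type[n_cand] = 0
                        cand_lig[n_cand] = i
                        cand_rec[n_cand] = r
                        n_cand += 1
        for i in range(n_ip):
            nn = _grid_query(ip_x[i], ip_y[i], rnx, rny, Lx, Ly,
                             rstart, rorder, neigh)
            for q in range(nn):
                r = neigh[q]
                dx = ip_x[i] - rx[r]
                dy = ip_y[i] - ry[r]
                if dx * dx + dy * dy <= d_ip3r * d_ip3r:
                    if n_cand < cand_type.shape[0]:
                        cand_type[n_cand] = 1
                        cand_lig[n_cand] = i
                        cand_rec[n_cand] = r
                        n_cand += 1
        # Fisher-Yates shuffle of the candidate list
        for i in range(n_cand - 1, 0, -1):
            j = np.random.randint(0, i + 1)
            cand_type[i], cand_type[j] = cand_type[j], cand_type[i]
            cand_lig[i], cand_lig[j] = cand_lig[j], cand_lig[i]
            cand_rec[i], cand_rec[j] = cand_rec[j], cand_rec[i]

        for i in range(n_ca):
            ca_remove[i] = False
        for i in range(n_ip):
            ip_remove[i] = False
        for c in range(n_cand):
            r = cand_rec[c]
            lig = cand_lig[c]
            s = rstate[r]
            if cand_type[c] == 0:
                if ca_remove[lig]:
                    continue
                ca1_free = (s >> 2) & 1 == 0 and site_bound_step[r, 0] != step
                ca2_free = (s >> 0) & 1 == 0 and site_bound_step[r, 2] != step
                site = -1
                if ca1_free and ca2_free:
                    if np.random.random() < p_a1:
                        site = 0
                    elif np.random.random() < p_a3:
                        site = 2
                elif ca1_free:
                    if np.random.random() < p_a1:
                        site = 0
                elif ca2_free:
                    if np.random.random() < p_a3:
                        site = 2
                if site >= 0:
                    bit = 2 if site == 0 else 0
                    old = rstate[r]
                    rstate[r] = old | (1 << bit)
                    site_bound_step[r, site] = step
                    ca_remove[lig] = True
                    if old == 0:
                        active[n_active] = r
                        n_active += 1
                    if old == OPEN_STATE or rstate[r] == OPEN_STATE:
                        if rstate[r] == OPEN_STATE:
                            n_open += 1
                        else:
                            n_open -= 1
                        if log_transitions:
                            if n_log < log_cap:
                                log[n_log, 0] = (step + 1) * dt
                                log[n_log, 1] = r
                                log[n_log, 2] = old
                                log[n_log, 3] = rstate[r]
                                n_log += 1
                            else:
                                log_overflow = True
            else:
                if ip_remove[lig]:
                    continue
                if (s >> 1) & 1 == 0 and site_bound_step[r, 1] != step:
                    if np.random.random() < p_a2:
                        old = rstate[r]
                        rstate[r] = old | 2
                        site_bound_step[r, 1] = step
                        ip_remove[lig] = True
                        if old == 0:
                            active[n_active] = r
                            n_active += 1
                        if old == OPEN_STATE or rstate[r] == OPEN_STATE:
                            if rstate[r] == OPEN_STATE:
                                n_open += 1
                            else:
                                n_open -= 1
                            if log_transitions:
                                if n_log < log_cap:
                                    log[n_log, 0] = (step + 1) * dt
                                    log[n_log, 1] = r
                                    log[n_log, 2] = old
                                    log[n_log, 3] = rstate[r]
                                    n_log += 1
                                else:
                                    log_overflow = True

        # --- 2c. buffer binding of remaining free Ca ----------------------
        if n_bf > 0 and p_buf_on > 0.0:
            for b in range(n_bf):
                bf_taken[b] = False
                hx = np.int64(bf_x[b] / bcell)
                hy = np.int64(bf_y[b] / bcell)
                h = ((hx * 73856093) ^ (hy * 19349663)) & (HSIZE - 1)
                if bh_stamp[h] != step:
                    bh_head[h] = -1
                    bh_stamp[h] = step
                bh_next[b] = bh_head[h]
                bh_head[h] = b
            for i in range(n_ca):
                if ca_remove[i]:
                    continue
                cx0 = np.int64(ca_x[i] / bcell)
                cy0 = np.int64(ca_y[i] / bcell)
                done = False
                for ddx in range(-1, 2):
                    if done:
                        break
                    for ddy in range(-1, 2):
                        if done:
                            break
                        h = (((cx0 + ddx) * 73856093)
                             ^ ((cy0 + ddy) * 19349663)) & (HSIZE - 1)
                        if bh_stamp[h] != step:
                            continue
                        b = bh_head[h]
                        while b >= 0:
                            if not bf_taken[b]:
                                dx = ca_x[i] - bf_x[b]
                                dy = ca_y[i] - bf_y[b]
                                if dx * dx + dy * dy <= d_ip3r * d_ip3r:
                                    if np.random.random() < p_buf_on:
                                        bb_x[n_bb] = bf_x[b]
                                        bb_y[n_bb] = bf_y[b]
                                        n_bb += 1
                                        bf_taken[b] = True
                                        ca_remove[i] = True
                                        done = True
                                        break
                            b = bh_next[b]
            # drop the buffers that captured a Ca this step
            w = 0
            for b in range(n_bf):
                if not bf_taken[b]:
                    bf_x[w] = bf_x[b]
                    bf_y[w] = bf_y[b]
                    w += 1
            n_bf = w

        # compact the Ca/IP3 arrays after binding
        w = 0
        for i in range(n_ca):
            if not ca_remove[i]:
                ca_x[w] = ca_x[i]
                ca_y[w] = ca_y[i]
                ca_fresh[w] = ca_fresh[i]
                w += 1
        n_ca = w
        w = 0
        for i in range(n_ip):
            if not ip_remove[i]:
                ip_x[w] = ip_x[i]
                ip_y[w] = ip_y[i]
                ip_fresh[w] = ip_fresh[i]
                w += 1
        n_ip = w

        # --- 3. unbinding (same-step bindings exempt) ---------------------
        w = 0
        for ia in range(n_active):
            r = active[ia]
            s = rstate[r]
            if s == 0:
                continue  # lazily dropped from the active list
            for site in range(3):
                bit = 2 - site  # site bits: activating Ca 2, IP3 1, inact. Ca 0
                if (s >> bit) & 1 == 1 and site_bound_step[r, site] != step:
                    b_rate = b1 if site == 0 else (b2 if site == 1 else b3)
                    if np.random.random() < b_rate * dt:
                        old = rstate[r]
                        rstate[r] = old & ~(1 << bit)
                        s = rstate[r]
                        if site == 1:
                            if n_ip < cap:
                                ip_x[n_ip] = rx[r]
                                ip_y[n_ip] = ry[r]
                                ip_fresh[n_ip] = step
                                n_ip += 1
                            else:
                                overflow = True
                        else:
                            if n_ca < cap:
                                ca_x[n_ca] = rx[r]
                                ca_y[n_ca] = ry[r]
                                ca_fresh[n_ca] = step
                                n_ca += 1
                            else:
                                overflow = True
                        if old == OPEN_STATE or rstate[r] == OPEN_STATE:
                            if rstate[r] == OPEN_STATE:
                                n_open += 1
                            else:
                                n_open -= 1
                            if log_transitions:
                                if n_log < log_cap:
                                    log[n_log, 0] = (step + 1) * dt
                                    log[n_log, 1] = r
                                    log[n_log, 2] = old
                                    log[n_log, 3] = rstate[r]
                                    n_log += 1
                                else:
                                    log_overflow = True
            if rstate[r] != 0:
                active[w] = r
                w += 1
        n_active = w

        # buffer release: bound buffer frees its Ca at the buffer position
        if n_bb > 0 and buf_off > 0.0:
            b = 0
            while b < n_bb:
                if np.random.random() < buf_off * dt:
                    if n_ca < cap:
                        ca_x[n_ca] = bb_x[b]
                        ca_y[n_ca] = bb_y[b]
                        ca_fresh[n_ca] = step
                        n_ca += 1
                    else:
                        overflow = True
                    bf_x[n_bf] = bb_x[b]
                    bf_y[n_bf] = bb_y[b]
                    n_bf += 1
                    bb_x[b] = bb_x[n_bb - 1]
                    bb_y[b] = bb_y[n_bb - 1]
                    n_bb -= 1
                else:
                    b += 1

        # --- 4. removal (same-step unbindings exempt) ---------------------
        i = 0
        while i < n_ca:
            if ca_fresh[i] != step and np.random.random() < alpha * dt:
                ca_x[i] = ca_x[n_ca - 1]
                ca_y[i] = ca_y[n_ca - 1]
                ca_fresh[i] = ca_fresh[n_ca - 1]
                n_ca -= 1
            else:
                i += 1
        i = 0
        while i < n_ip:
            if ip_fresh[i] != step and np.random.random() < beta * dt:
                ip_x[i] = ip_x[n_ip - 1]
                ip_y[i] = ip_y[n_ip - 1]
                ip_fresh[i] = ip_fresh[n_ip - 1]
                n_ip -= 1
            else:
                i += 1

        # --- 5. influx ----------------------------------------------------
        for ia in range(n_active):
            r = active[ia]
            if rstate[r] == OPEN_STATE and np.random.random() < mu * dt:
                if n_ca < cap:
                    ca_x[n_ca] = rx[r]
                    ca_y[n_ca] = ry[r]
                    ca_fresh[n_ca] = -1
                    n_ca += 1
                else:
                    overflow = True
        if np.random.random() < gamma * dt:
            r = np.random.randint(0, n_rec)
            rad = R_gamma * math.sqrt(np.random.random())
            th = 2.0 * math.pi * np.random.random()
            if n_ca < cap:
                ca_x[n_ca] = _reflect(rx[r] + rad * math.cos(th), Lx)
                ca_y[n_ca] = _reflect(ry[r] + rad * math.sin(th), Ly)
                ca_fresh[n_ca] = -1
                n_ca += 1
            else:
                overflow = True

    return (tr_ca[:isample], tr_ip[:isample], tr_open[:isample],
            tr_bb[:isample], rstate, log[:n_log], log_overflow, overflow,
            ca_x[:n_ca].copy(), ca_y[:n_ca].copy())


# ---------------------------------------------------------------------------
# public driver
# ---------------------------------------------------------------------------

def run_2d(kinetics: KineticParams, space: SpatialParams2D, T: float,
           seed: int, buffers: BufferSpec | None = None,
           record_transitions: bool = False, layout: ClusterLayout = None,
           capacity: int = 200_000,
           log_capacity: int = 2_000_000) -> SimulationTrace:
    """Run the 2D particle-based model for ``T`` MC time units.

    The trace is sampled once per MC time unit.  ``buffers`` adds explicit
    mobile Ca buffers (the trace still reports *free* Ca).  The receptor
    layout is drawn from ``seed`` unless one is supplied.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    check_step_probabilities(kinetics, space,
                             (buffers,) if buffers else ())
    k = kinetics
    if layout is None:
        layout = place_receptor_clusters(space.N_IP3R, space.eta,
                                         space.d_IP3R, (space.Lx, space.Ly),
                                         np.random.SeedSequence([int(seed), 77]))
    cell = max(space.d_IP3R, space.d_PLC)
    rnx, rny, rstart, rorder = _build_grid(layout.positions, cell,
                                           space.Lx, space.Ly)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 78]))
    plc = rng.uniform((0.0, 0.0), (space.Lx, space.Ly), size=(space.N_plc, 2))
    pnx, pny, pstart, porder = _build_grid(plc, cell, space.Lx, space.Ly)

    buf = buffers or BufferSpec(total=0)
    n_steps = int(round(T / space.dt))
    sample_every = int(round(1.0 / space.dt))

    (ca, ip3, op, bb, rstate, log, log_ovf, ovf, ca_fx, ca_fy) = _sim2d(
        layout.positions[:, 0].copy(), layout.positions[:, 1].copy(),
        plc[:, 0].copy(), plc[:, 1].copy(),
        rnx, rny, rstart, rorder, pnx, pny, pstart, porder,
        space.Lx, space.Ly, space.d_IP3R, space.d_PLC,
        space.Ca0, space.IP0, int(buf.total),
        0.0 if math.isinf(space.D_Ca) else space.D_Ca,
        0.0 if math.isinf(space.D_IP3) else space.D_IP3,
        buf.D_free, buf.D_bound,
        math.isinf(space.D_Ca), math.isinf(space.D_IP3),
        k.a1, k.a2, k.a3, k.b1, k.b2, k.b3, k.delta, k.beta, k.alpha,
        k.gamma, k.mu, buf.k_on, buf.k_off,
        space.R_gamma, space.dt, n_steps, sample_every,
        int(seed) % (2**32), int(capacity),
        record_transitions, int(log_capacity))
    if ovf:
        raise RuntimeError(
            "particle capacity exceeded; the run left the intended copy-"
            "number regime (increase `capacity` to simulate it anyway)")
    time = np.arange(len(ca), dtype=float) * (sample_every * space.dt)
    meta = {
        "engine": "particle2d",
        "unit_system": k.unit_system,
        "V": space.area,
        "seed": int(seed),
        "sample_dt": sample_every * space.dt,
        "dt": space.dt,
        "eta": space.eta,
        "R_gamma": space.R_gamma,
        "D_Ca": space.D_Ca,
        "D_IP3": space.D_IP3,
        "n_buffers": int(buf.total),
        "transition_log_overflow": bool(log_ovf),
    }
    trace = SimulationTrace(time=time, ca=ca.astype(float),
                            ip3=ip3.astype(float),
                            open_count=op.astype(float), meta=meta,
                            transitions=log if record_transitions else None,
                            receptor_positions=layout.positions)
    if buf.total:
        trace.extra["buffer_bound"] = bb.astype(float)
    trace.extra["ca_final_positions"] = np.column_stack([ca_fx, ca_fy])
    return trace


def run_2d_with_buffers(kinetics: KineticParams, space: SpatialParams2D,
                        buffer: BufferSpec, T: float, seed: int,
                        **kwargs) -> SimulationTrace:
    """Convenience wrapper: explicit-buffer run (S1-style protocol)."""
    return run_2d(kinetics, space, T, seed, buffers=buffer, **kwargs)
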