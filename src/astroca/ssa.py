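"""Exact well-mixed stochastic simulation (Gillespie) of the CICR network.

Every IP3R is represented individually (one-hot over the 8 monomer states),
so the engine can produce per-receptor transition logs for closure-path
statistics and matches the particle engine channel-for-channel.  Bimolecular
propensities carry the 1/V volume factor: e.g. Ca binding to the activating
site of one receptor in state {001} has propensity ``a1/V * N_Ca``.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .core import KineticParams, SimulationTrace, SpatialParams2D
from .ip3r import OPEN_STATE

# site bit positions in the packed state (activating Ca, IP3, inactivating Ca)
_BITS = np.array([2, 1, 0], dtype=np.int64)


@njit(cache=True)
def _ssa_kernel(n_receptors, n_ca0, n_ip30, n_plc, V,
                a1, a2, a3, b1, b2, b3, delta, beta, alpha, gamma, mu,
                T, sample_dt, seed, log_transitions, log_cap):
    np.random.seed(seed)

    state_of = np.zeros(n_receptors, dtype=np.int64)
    # per-state receptor lists for O(1) uniform selection
    state_lists = np.zeros((8, n_receptors), dtype=np.int64)
    pos_in_state = np.zeros(n_receptors, dtype=np.int64)
    state_counts = np.zeros(8, dtype=np.int64)
    for r in range(n_receptors):
        state_lists[0, r] = r
        pos_in_state[r] = r
    state_counts[0] = n_receptors

    n_ca = n_ca0
    n_ip3 = n_ip30

    n_samples = int(T / sample_dt) + 1
    ts = np.empty(n_samples)
    ca_tr = np.empty(n_samples, dtype=np.int64)
    ip3_tr = np.empty(n_samples, dtype=np.int64)
    open_tr = np.empty(n_samples, dtype=np.int64)

    log = np.empty((log_cap if log_transitions else 1, 4))
    n_log = 0
    log_overflow = False

    on_bit = np.array([2, 1, 0], dtype=np.int64)
    a_rates = np.array([a1, a2, a3])
    b_rates = np.array([b1, b2, b3])

    t = 0.0
    isample = 0
    next_sample = 0.0
    halted = False

    while isample < n_samples:
        # record any sample points passed
        while isample < n_samples and next_sample <= t:
            ts[isample] = next_sample
            ca_tr[isample] = n_ca
            ip3_tr[isample] = n_ip3
            open_tr[isample] = state_counts[OPEN_STATE]
            isample += 1
            next_sample += sample_dt
        if isample >= n_samples:
            break
        if halted:
            # propensity vanished earlier: trace stays flat
            t = next_sample
            continue

        ca_conc = n_ca / V
        ip3_conc = n_ip3 / V

        # channels: per (state, site) aggregated receptor transitions,
        # then gamma influx, alpha removal, beta removal, PLC production,
        # mu influx through open channels
        props = np.zeros(8 * 3 + 5)
        for s in range(8):
            cnt = state_counts[s]
            if cnt == 0:
                continue
            for site in range(3):
                occ = (s >> on_bit[site]) & 1
                if occ:
                    rate = b_rates[site]
                else:
                    lig = ip3_conc if site == 1 else ca_conc
                    rate = a_rates[site] * lig
                props[s * 3 + site] = cnt * rate
        props[24] = gamma
        props[25] = alpha * n_ca
        props[26] = beta * n_ip3
        props[27] = delta * n_plc * ca_conc
        props[28] = mu * state_counts[OPEN_STATE]

        r_total = props.sum()
        if r_total <= 0.0:
            halted = True
            continue

        t += np.random.exponential(1.0 / r_total)
        u = np.random.random() * r_total
        acc = 0.0
        chan = 28
        for i in range(29):
            acc += props[i]
            if u < acc:
                chan = i
                break

        if chan < 24:
            s = chan // 3
            site = chan % 3
            # uniform receptor in state s
            idx = np.random.randint(0, state_counts[s])
            rec = state_lists[s, idx]
            new_s = s ^ (1 << on_bit[site])
            occ = (s >> on_bit[site]) & 1
            if occ:
                # unbinding releases the ligand
                if site == 1:
                    n_ip3 += 1
                else:
                    n_ca += 1
            else:
                if site == 1:
                    n_ip3 -= 1
                else:
                    n_ca -= 1
            # move receptor between state lists (swap-remove)
            last = state_lists[s, state_counts[s] - 1]
            state_lists[s, idx] = last
            pos_in_state[last] = idx
            state_counts[s] -= 1
            state_lists[new_s, state_counts[new_s]] = rec
            pos_in_state[rec] = state_counts[new_s]
            state_counts[new_s] += 1
            state_of[rec] = new_s
            if log_transitions and (s == OPEN_STATE or new_s == OPEN_STATE):
                if n_log < log_cap:
                    log[n_log, 0] = t
                    log[n_log, 1] = rec
                    log[n_log, 2] = s
                    log[n_log, 3] = new_s
                    n_log += 1
                else:
                    log_overflow = True
        elif chan == 24:
            n_ca += 1
        elif chan == 25:
            n_ca -= 1
        elif chan == 26:
            n_ip3 -= 1
        elif chan == 27:
            n_ip3 += 1
        else:
            n_ca += 1

    return ts, ca_tr, ip3_tr, open_tr, log[:n_log], log_overflow, halted


def run_ssa(kinetics: KineticParams, space: SpatialParams2D, T: float,
            seed: int, sample_dt: float = 1.0,
            record_transitions: bool = False,
            log_capacity: int = 2_000_000) -> SimulationTrace:
    """Simulate the well-mixed network exactly for ``T`` MC time units.

    The trace is sampled on a uniform grid of spacing ``sample_dt``.  If the
    total propensity ever vanishes the simulation halts and the trace stays
    flat (documented behaviour, not an error).
    """
    if T <= 0:
        raise ValueError("T must be positive")
    k = kinetics
    V = space.area
    ts, ca, ip3, op, log, overflow, halted = _ssa_kernel(
        space.N_IP3R, space.Ca0, space.IP0, space.N_plc, V,
        k.a1, k.a2, k.a3, k.b1, k.b2, k.b3, k.delta, k.beta, k.alpha,
        k.gamma, k.mu,
        float(T), float(sample_dt), int(seed) % (2**32),
        record_transitions, int(log_capacity))
    meta = {
        "engine": "ssa",
        "unit_system": k.unit_system,
        "V": V,
        "seed": int(seed),
        "sample_dt": sample_dt,
        "halted": bool(halted),
        "transition_log_overflow": bool(overflow),
    }
    return SimulationTrace(time=ts, ca=ca.astype(float), ip3=ip3.astype(float),
                           open_count=op.astype(float), meta=meta,
                           transitions=log if record_transitions else None)


def propensities(n_ca: int, n_ip3: int, state_counts: np.ndarray,
                 kinetics: KineticParams, space: SpatialParams2D) -> dict:
    """Reference (pure python) propensity map, keyed by channel name.

    Used in tests as an independent check of the kernel's rate arithmetic.
    """
    if n_ca < 0 or n_ip3 < 0:
        raise ValueError("counts must be >= 0")
    k = kinetics
    V = space.area
    ca_c, ip3_c = n_ca / V, n_ip3 / V
    out = {}
    a = (k.a1, k.a2, k.a3)
    b = (k.b1, k.b2, k.b3)
    for s in range(8):
        cnt = int(state_counts[s])
        if cnt == 0:
            continue
        for site, bit in enumerate((2, 1, 0)):
            occ = (s >> bit) & 1
            if occ:
                rate = b[site]
            else:
                rate = a[site] * (ip3_c if site == 1 else ca_c)
            if rate > 0:
                out[f"state{s}_site{site}"] = cnt * rate
    out["gamma"] = k.gamma
    out["alpha"] = k.alpha * n_ca
    out["beta"] = k.beta * n_ip3
    out["plc"] = k.delta * space.N_plc * ca_c
    out["mu"] = k.mu * int(state_counts[OPEN_STATE])
    return out
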