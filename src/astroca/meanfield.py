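"""Deterministic well-mixed (mean-field) model.

Concentration dynamics of the seven independent receptor states, IP3 and
free Ca under mass-action kinetics; the eighth receptor state {111} follows
from receptor conservation.  Activated PLCdelta produces IP3 at rate
``delta*[PLC][Ca]`` without consuming Ca, IP3 decays at ``beta``, free Ca is
cleared at ``alpha`` and fed by a constant influx ``gamma`` plus ``mu`` per
open channel.  With the default 2D parameter set the model has a single
stable fixed point (no limit cycle); transient excitability appears for
large values of the activating-site binding constant ``a1``.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .core import KineticParams, SimulationTrace, SpatialParams2D
from .ip3r import N_STATES, OPEN_STATE, build_generator, unpack_state

# state vector layout: y[0:7] = [000],[001],[010],[011],[100],[101],[110],
# y[7] = [IP3], y[8] = [Ca]; all concentrations (counts per volume).
_IDX_IP3 = 7
_IDX_CA = 8


def _site_masks():
    """Index sets used by the ligand balance terms of the Ca and IP3 ODEs."""
    free_ca1, bound_ca1 = [], []   # activating Ca site
    free_ip3, bound_ip3 = [], []   # IP3 site
    free_ca2, bound_ca2 = [], []   # inactivating Ca site
    for s in range(N_STATES):
        i, j, k = unpack_state(s)
        (bound_ca1 if i else free_ca1).append(s)
        (bound_ip3 if j else free_ip3).append(s)
        (bound_ca2 if k else free_ca2).append(s)
    return (np.array(free_ca1), np.array(bound_ca1), np.array(free_ip3),
            np.array(bound_ip3), np.array(free_ca2), np.array(bound_ca2))


_F1, _B1, _F2, _B2, _F3, _B3 = _site_masks()


def receptor_total(space: SpatialParams2D) -> float:
    return space.N_IP3R / space.area


def rhs(y: np.ndarray, kinetics: KineticParams, space: SpatialParams2D) -> np.ndarray:
    """Time derivative of the mean-field state (concentration units)."""
    V = space.area
    r_tot = space.N_IP3R / V
    plc = space.N_plc / V
    ip3 = y[_IDX_IP3]
    ca = y[_IDX_CA]

    states = np.empty(N_STATES)
    states[:7] = y[:7]
    states[7] = r_tot - y[:7].sum()

    Q = build_generator(max(ca, 0.0), max(ip3, 0.0), kinetics)
    dstates = Q.T @ states

    dip3 = (-kinetics.a2 * ip3 * states[_F2].sum()
            + kinetics.b2 * states[_B2].sum()
            + kinetics.delta * plc * ca
            - kinetics.beta * ip3)
    dca = (-(kinetics.a1 * states[_F1].sum() + kinetics.a3 * states[_F3].sum()) * ca
           + kinetics.b1 * states[_B1].sum()
           + kinetics.b3 * states[_B3].sum()
           - kinetics.alpha * ca
           + kinetics.gamma / V
           + kinetics.mu * states[OPEN_STATE])

    out = np.empty(9)
    out[:7] = dstates[:7]
    out[_IDX_IP3] = dip3
    out[_IDX_CA] = dca
    return out


def initial_state(kinetics: KineticParams, space: SpatialParams2D) -> np.ndarray:
    """All receptors unbound, initial Ca/IP3 from the spatial parameters."""
    V = space.area
    y0 = np.zeros(9)
    y0[0] = space.N_IP3R / V
    y0[_IDX_IP3] = space.IP0 / V
    y0[_IDX_CA] = space.Ca0 / V
    return y0


def simulate_mf(kinetics: KineticParams, space: SpatialParams2D, T: float,
                y0: np.ndarray | None = None, sample_dt: float = 1.0,
                rtol: float = 1e-8) -> SimulationTrace:
    """Integrate the ODE system over ``[0, T]`` (MC time units).

    Uses an adaptive stiff-capable integrator (LSODA); the trace reports
    counts (concentration times the reaction volume) on a uniform grid.
    """
    if y0 is None:
        y0 = initial_state(kinetics, space)
    t_eval = np.arange(0.0, T + 0.5 * sample_dt, sample_dt)
    sol = solve_ivp(lambda t, y: rhs(y, kinetics, space), (0.0, T), y0,
                    method="LSODA", t_eval=t_eval, rtol=rtol, atol=1e-12)
    if not sol.success:
        raise RuntimeError(f"mean-field integration failed: {sol.message}")
    V = space.area
    trace = SimulationTrace(
        time=sol.t,
        ca=sol.y[_IDX_CA] * V,
        ip3=sol.y[_IDX_IP3] * V,
        open_count=sol.y[OPEN_STATE] * V,
        meta={"engine": "meanfield", "unit_system": kinetics.unit_system,
              "V": V, "rtol": rtol},
    )
    trace.extra["state"] = sol.y
    return trace


class SteadyStateError(RuntimeError):
    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


def steady_state(kinetics: KineticParams, space: SpatialParams2D,
                 tol: float = 1e-8) -> dict:
    """Fixed point of the mean-field model.

    Integrates to near-stationarity, then polishes with a root finder and
    verifies ``max |rhs| < tol`` in count units.  Returns both concentration
    and count representations.
    """
    y0 = initial_state(kinetics, space)
    sol = solve_ivp(lambda t, y: rhs(y, kinetics, space), (0.0, 5000.0), y0,
                    method="LSODA", rtol=1e-10, atol=1e-14)
    y_guess = sol.y[:, -1]
    res = root(lambda y: rhs(y, kinetics, space), y_guess, method="hybr",
               tol=tol * 1e-3)
    y_star = res.x
    V = space.area
    resid = np.max(np.abs(rhs(y_star, kinetics, space))) * V
    if resid >= tol:
        raise SteadyStateError(
            f"steady state residual {resid:.3g} exceeds tolerance {tol:.3g}",
            last_iterate=y_star)
    states = np.empty(N_STATES)
    states[:7] = y_star[:7]
    states[7] = space.N_IP3R / V - y_star[:7].sum()
    return {
        "y": y_star,
        "ca_conc": y_star[_IDX_CA],
        "ip3_conc": y_star[_IDX_IP3],
        "ca_count": y_star[_IDX_CA] * V,
        "ip3_count": y_star[_IDX_IP3] * V,
        "receptor_counts": states * V,
        "open_count": states[OPEN_STATE] * V,
        "residual": resid,
    }


def ip3_injection_response(kinetics: KineticParams, space: SpatialParams2D,
                           n_inject: float, t_inject: float = 0.2,
                           T_post: float = 2000.0,
                           sample_dt: float = 0.5,
                           equilibration: str | float = "initial") -> dict:
    """Excitability probe: instantaneous injection of ``n_inject`` IP3.

    ``equilibration`` selects the pre-injection state: ``"initial"`` starts
    from the standard initial condition and injects at ``t_inject`` (the
    published figure protocol, injection at t = 20 dt); ``"steady"`` injects
    onto the exact fixed point.  The two differ materially at large ``a1``,
    where the system is bistable and an exactly equilibrated state can be
    kicked across the separatrix into the high-activity state (see the
    methods note).  Amplitude is the post-injection maximum of Ca above its
    pre-injection level, in count units.
    """
    if n_inject < 0:
        raise ValueError("n_inject must be >= 0")
    V = space.area
    if equilibration == "steady":
        y_pre = steady_state(kinetics, space)["y"]
        pre_t = np.empty(0)
        pre_ca = np.empty(0)
    else:
        t_eq = t_inject if equilibration == "initial" else float(equilibration)
        pre = simulate_mf(kinetics, space, max(t_eq, 1e-6),
                          sample_dt=max(t_eq, 1e-6) / 4)
        y_pre = pre.extra["state"][:, -1]
        pre_t, pre_ca = pre.time, pre.ca
    ca_pre = float(y_pre[_IDX_CA] * V)

    y_kick = y_pre.copy()
    y_kick[_IDX_IP3] += n_inject / V
    post = simulate_mf(kinetics, space, T_post, y0=y_kick, sample_dt=sample_dt)
    # response amplitude = maximal Ca excess over the unperturbed trajectory,
    # so relaxation of the pre-injection state cancels out exactly
    ref = simulate_mf(kinetics, space, T_post, y0=y_pre.copy(),
                      sample_dt=sample_dt)
    amplitude = float(np.max(post.ca - ref.ca))
    return {
        "amplitude": max(amplitude, 0.0),
        "ca_pre_count": ca_pre,
        "time": np.concatenate([pre_t, post.time + (pre_t[-1] if len(pre_t) else 0.0)]),
        "ca_count": np.concatenate([pre_ca, post.ca]),
        "ca_reference": ref.ca,
    }
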