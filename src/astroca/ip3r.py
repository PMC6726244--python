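"""The 8-state IP3R monomer Markov model shared by every engine.

A receptor monomer carries three independent binding sites: an activating
Ca site (``i``), an IP3 site (``j``) and an inactivating Ca site (``k``).
Occupancy triplets {i, j, k} are packed into integers ``s = 4i + 2j + k``;
the channel is open iff the triplet is {1, 1, 0}.  Binding rates are
``a1*[Ca]``, ``a2*[IP3]``, ``a3*[Ca]`` and unbinding rates ``b1``, ``b2``,
``b3``; none of them depends on the occupancy of the other two sites
(no intra-channel cooperativity), so the stationary distribution of the
monomer at fixed ligand levels factorizes over sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import KineticParams

N_STATES = 8
OPEN_STATE = 6  # {110}

# site index -> bit position in the packed state
_SITE_BIT = (2, 1, 0)  # site 0: activating Ca, 1: IP3, 2: inactivating Ca


def pack_state(i: int, j: int, k: int) -> int:
    """Pack an occupancy triplet {i, j, k} into an integer state."""
    for v in (i, j, k):
        if v not in (0, 1):
            raise ValueError("site occupancies must be 0 or 1")
    return (i << 2) | (j << 1) | k


def unpack_state(state: int) -> tuple[int, int, int]:
    """Unpack an integer state into the occupancy triplet {i, j, k}."""
    if not 0 <= state < N_STATES:
        raise ValueError(f"invalid receptor state {state}")
    return (state >> 2) & 1, (state >> 1) & 1, state & 1


def is_open(state: int) -> bool:
    """True iff the state is the conducting state {110}."""
    if not 0 <= state < N_STATES:
        raise ValueError(f"invalid receptor state {state}")
    return state == OPEN_STATE


def state_label(state: int) -> str:
    i, j, k = unpack_state(state)
    return f"{i}{j}{k}"


def transition_rates(state: int, ca_avail: float, ip3_avail: float,
                     kinetics: KineticParams) -> dict[int, float]:
    """Per-site transition rates out of ``state``.

    ``ca_avail`` / ``ip3_avail`` are ligand availabilities: bulk
    concentrations for the well-mixed engines, or contact indicators (0/1)
    for the particle engine.  Returns a map successor-state -> rate with
    zero-rate transitions omitted.
    """
    if ca_avail < 0 or ip3_avail < 0:
        raise ValueError("ligand availability must be >= 0")
    i, j, k = unpack_state(state)
    on = (kinetics.a1 * ca_avail, kinetics.a2 * ip3_avail, kinetics.a3 * ca_avail)
    off = (kinetics.b1, kinetics.b2, kinetics.b3)
    rates: dict[int, float] = {}
    for site, occ in enumerate((i, j, k)):
        rate = off[site] if occ else on[site]
        if rate > 0:
            rates[state ^ (1 << _SITE_BIT[site])] = rate
    return rates


def build_generator(ca: float, ip3: float, kinetics: KineticParams) -> np.ndarray:
    """8x8 CTMC generator matrix at fixed ligand concentrations."""
    Q = np.zeros((N_STATES, N_STATES))
    for s in range(N_STATES):
        for t, rate in transition_rates(s, ca, ip3, kinetics).items():
            Q[s, t] = rate
        Q[s, s] = -Q[s].sum()
    return Q


def stationary_distribution(ca: float, ip3: float,
                            kinetics: KineticParams) -> np.ndarray:
    """Stationary law of the monomer CTMC, solved from the generator."""
    Q = build_generator(ca, ip3, kinetics)
    A = np.vstack([Q.T, np.ones(N_STATES)])
    b = np.zeros(N_STATES + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    return pi


def site_occupancy_product(ca: float, ip3: float,
                           kinetics: KineticParams) -> np.ndarray:
    """Product-form stationary law from the three independent sites."""
    on = (kinetics.a1 * ca, kinetics.a2 * ip3, kinetics.a3 * ca)
    off = (kinetics.b1, kinetics.b2, kinetics.b3)
    p_bound = [o / (o + f) if (o + f) > 0 else 0.0 for o, f in zip(on, off)]
    pi = np.empty(N_STATES)
    for s in range(N_STATES):
        i, j, k = unpack_state(s)
        pi[s] = np.prod([p if occ else 1 - p
                         for p, occ in zip(p_bound, (i, j, k))])
    return pi


# ---------------------------------------------------------------------------
# closure-path statistics
# ---------------------------------------------------------------------------

# closure targets, in the reporting order ({111}, {100}, {010})
CLOSURE_TARGETS = (7, 4, 2)


@dataclass(frozen=True)
class ClosureStats:
    """Empirical distribution of the three exits from the open state.

    ``p_110_111`` is the probability that closure resulted from Ca binding
    the inactivating site, ``p_110_100`` from IP3 unbinding and
    ``p_110_010`` from Ca unbinding from the activating site; the three sum
    to one whenever at least one closure was observed.
    """

    p_110_111: float
    p_110_100: float
    p_110_010: float
    counts: tuple[int, int, int]

    @property
    def n_closures(self) -> int:
        return int(sum(self.counts))


class NoClosuresError(RuntimeError):
    """Signals that closure statistics are undefined (no exits observed)."""


def closure_paths(transitions) -> ClosureStats:
    """Closure-path statistics from a transition log.

    Parameters
    ----------
    transitions : array-like
        Rows ``(time, receptor_id, from_state, to_state)`` (extra leading
        columns are tolerated as long as the last two are from/to states).
    """
    log = np.asarray(transitions)
    if log.size == 0:
        raise NoClosuresError("transition log contains no events")
    frm = log[:, -2].astype(int)
    to = log[:, -1].astype(int)
    exits = to[frm == OPEN_STATE]
    if exits.size == 0:
        raise NoClosuresError("no exit from the open state in the log")
    counts = tuple(int(np.sum(exits == t)) for t in CLOSURE_TARGETS)
    total = sum(counts)
    p = tuple(c / total for c in counts)
    return ClosureStats(p[0], p[1], p[2], counts)
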