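"""Parameter containers, unit systems and configuration handling.

Two unit systems coexist in the package:

``mc``
    Arbitrary Monte-Carlo units used by the 2D engines.  Times are measured
    in *MC time units* (one MC time unit = 100 simulation steps of length
    ``dt = 0.01``), lengths in *MC space units* (set by the IP3R interaction
    distance, ``d_IP3R = 1``).  First-order rate constants (``b1..b3``,
    ``beta``, ``alpha``, ``mu``) are in (MC time unit)^-1; the bimolecular
    constants (``a1..a3``, ``delta``) are 2D rate-areas in
    (MC space unit)^2 (MC time unit)^-1, so that the well-mixed mass-action
    rate of e.g. Ca binding to a single free activating site is
    ``a1 * N_Ca / V`` with ``V`` the domain area.  ``gamma`` is a zeroth
    order influx in ions per MC time unit for the whole domain.

``si``
    SI units used by the 3D engine: rates in s^-1 or M^-1 s^-1, lengths in
    meters, diffusion coefficients in m^2 s^-1.  ``gamma`` is a volumetric
    influx in M s^-1 over the canonical cytosolic volume and ``mu`` is an
    ion flux in s^-1 per open channel.

Counts and molar concentrations are interconverted through the canonical
cytosolic volume of the modelled astrocytic process (2.81e-17 L), which is
the value that makes the printed count/concentration pairs of the 3D
parameter set mutually consistent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np

AVOGADRO = 6.02214076e23

#: Canonical cytosolic volume (liters) of the 3D process geometry used for
#: every count <-> concentration conversion.  The analytic cylinder-shell
#: volume of the same geometry is ~2.93e-17 L; the canonical value is the one
#: consistent with the published count/concentration pairs.
V_CYT_CANONICAL = 2.81e-17

MC_TIME_UNIT_STEPS = 100  # one MC time unit = 100 dt
DEFAULT_DT_2D = 0.01  # MC time units


class ConfigurationError(ValueError):
    """Raised when a parameter set fails validation."""


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticParams:
    """Rate constants of the CICR reaction scheme.

    Attributes
    ----------
    a1, a2, a3 : float
        Binding rate constants for the activating Ca site, the IP3 site and
        the inactivating Ca site of the IP3R (rate-areas in ``mc`` units,
        M^-1 s^-1 in ``si`` units).
    b1, b2, b3 : float
        The corresponding unbinding rates (time^-1).
    delta : float
        PLCdelta maximal IP3 production rate constant (bimolecular: active
        PLCdelta x Ca -> IP3 production).
    beta : float
        First-order IP3 degradation rate.
    alpha : float
        First-order free-Ca clearance rate, lumping ER and plasma-membrane
        pumps.
    gamma : float
        IP3R-independent Ca influx (ions per time in ``mc`` units, M/s in
        ``si`` units).
    mu : float
        Ca influx rate through one open IP3R channel (time^-1).
    unit_system : str
        ``"mc"`` or ``"si"``.
    """

    a1: float = 1.0
    a2: float = 1.0
    a3: float = 0.1
    b1: float = 0.1
    b2: float = 0.1
    b3: float = 0.1
    delta: float = 0.1
    beta: float = 0.01
    alpha: float = 1.0
    gamma: float = 50.0
    mu: float = 50.0
    unit_system: str = "mc"

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "unit_system":
                continue
            v = getattr(self, f.name)
            if not (isinstance(v, (int, float)) and v >= 0 and math.isfinite(v)):
                raise ConfigurationError(
                    f"kinetic parameter {f.name} must be finite and >= 0, got {v!r}"
                )
        if self.unit_system not in ("mc", "si"):
            raise ConfigurationError(f"unknown unit system {self.unit_system!r}")


@dataclass(frozen=True)
class SpatialParams2D:
    """Geometry, copy numbers and discretization of the 2D particle model.

    ``D_Ca``/``D_IP3`` may be ``math.inf``, selecting the perfectly mixed
    mode in which mobile molecules are redrawn uniformly each step.
    """

    Lx: float = 200.0
    Ly: float = 200.0
    D_Ca: float = math.inf
    D_IP3: float = math.inf
    d_IP3R: float = 1.0
    d_PLC: float = 1.0
    eta: int = 1
    R_gamma: float = 200.0
    N_IP3R: int = 1000
    N_plc: int = 1000
    Ca0: int = 50
    IP0: int = 15
    dt: float = DEFAULT_DT_2D

    def __post_init__(self) -> None:
        if self.Lx <= 0 or self.Ly <= 0:
            raise ConfigurationError("domain extent must be positive")
        if self.eta < 1 or self.eta != int(self.eta):
            raise ConfigurationError("eta must be an integer >= 1")
        if self.eta > self.N_IP3R:
            raise ConfigurationError("eta cannot exceed N_IP3R")
        if self.R_gamma < 0:
            raise ConfigurationError("R_gamma must be >= 0")
        for name in ("D_Ca", "D_IP3"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0 (or inf)")
        if not (0 < self.dt <= 1):
            raise ConfigurationError("dt must lie in (0, 1] MC time units")
        for name in ("N_IP3R", "N_plc", "Ca0", "IP0"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")

    @property
    def area(self) -> float:
        return self.Lx * self.Ly


@dataclass(frozen=True)
class Geometry3DParams:
    """Cylindrical process geometry: outer (plasma) cylinder with a shorter,
    thinner ER cylinder inside, both coaxial and centered."""

    L_astro: float = 1.0e-6
    R_astro: float = 0.1e-6
    L_ER: float = 0.75e-6
    R_ER: float = 0.03e-6
    V_cyt_canonical: float = V_CYT_CANONICAL
    voxel_scale: float = 25.0e-9

    def __post_init__(self) -> None:
        if not (0 < self.L_ER < self.L_astro and 0 < self.R_ER < self.R_astro):
            raise ConfigurationError("ER cylinder must lie strictly inside the process")
        if self.V_cyt_canonical <= 0:
            raise ConfigurationError("V_cyt_canonical must be positive")
        if self.voxel_scale <= 0:
            raise ConfigurationError("voxel_scale must be positive")

    @property
    def analytic_volume_liters(self) -> float:
        """Exact cylinder-shell cytosolic volume in liters."""
        v_m3 = math.pi * (
            self.R_astro**2 * self.L_astro - self.R_ER**2 * self.L_ER
        )
        return v_m3 * 1e3


@dataclass(frozen=True)
class GECIParams:
    """Genetically encoded calcium indicator (GCaMP) description."""

    variant: str = "none"  # "GCaMP6s" | "GCaMP6f" | "none"
    C_total: float = 0.0  # M
    D_GCaMP: float = 50.0e-12  # m^2/s (calmodulin-like mobility)
    k_on: float = 0.0  # M^-1 s^-1
    k_off: float = 0.0  # s^-1

    def __post_init__(self) -> None:
        if self.variant not in ("GCaMP6s", "GCaMP6f", "none"):
            raise ConfigurationError(f"unknown GECI variant {self.variant!r}")
        if self.k_on < 0 or self.k_off < 0 or self.C_total < 0 or self.D_GCaMP < 0:
            raise ConfigurationError("GECI parameters must be >= 0")
        if self.variant == "none" and self.C_total != 0:
            raise ConfigurationError("variant 'none' requires C_total = 0")


def gcamp6s(C_total: float = 10e-6) -> GECIParams:
    """GCaMP6s kinetics (k_on 7.78e6 /M/s, k_off 1.12 /s)."""
    return GECIParams("GCaMP6s", C_total, 50.0e-12, 7.78e6, 1.12)


def gcamp6f(C_total: float = 10e-6) -> GECIParams:
    """GCaMP6f kinetics (k_on 1.05e7 /M/s, k_off 3.93 /s)."""
    return GECIParams("GCaMP6f", C_total, 50.0e-12, 1.05e7, 3.93)


@dataclass(frozen=True)
class BufferSpec:
    """A calcium buffer species (endogenous buffer or explicit 2D 'Buf').

    In ``mc`` units ``total`` is a copy number, ``k_on`` a rate-area and the
    diffusion coefficients are in MC units; in ``si`` units ``total`` is a
    molar concentration and ``k_on`` is in M^-1 s^-1.
    """

    name: str = "Buf"
    total: float = 0.0
    k_on: float = 300.0
    k_off: float = 0.5
    D_free: float = 0.1
    D_bound: float = 0.1

    def __post_init__(self) -> None:
        for name in ("total", "k_on", "k_off", "D_free", "D_bound"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"buffer {name} must be >= 0")


# Endogenous-buffer defaults for the 3D "GC+Buf" variant: literature-typical
# calbindin (slow/fast site) and parvalbumin kinetics, with totals two orders
# of magnitude below whole-dendrite models, as appropriate for a fine process.
# These are synthetic defaults (the exact published set is not reproduced
# here) and are fully config-overridable.
ENDOGENOUS_BUFFERS_3D = (
    BufferSpec("CBs", 1.6e-6, 5.5e6, 2.6, 28.0e-12, 28.0e-12),
    BufferSpec("CBf", 1.6e-6, 8.7e7, 35.8, 28.0e-12, 28.0e-12),
    BufferSpec("PV", 0.4e-6, 1.07e8, 0.95, 43.0e-12, 43.0e-12),
)


def table1_kinetics(**overrides) -> KineticParams:
    """Default 2D kinetic parameter set (arbitrary MC units)."""
    return replace(KineticParams(unit_system="mc"), **overrides)


def table1_space(**overrides) -> SpatialParams2D:
    """Default 2D spatial parameter set."""
    return replace(SpatialParams2D(), **overrides)


def table2_kinetics(**overrides) -> KineticParams:
    """Default 3D kinetic parameter set (SI units).

    ``gamma`` is interpreted as a volumetric influx of 1.5e-7 M/s over the
    canonical volume (~2.5 ions/s); as a bare per-second ion rate the printed
    figure would provide essentially no influx and the basal state would
    collapse.  ``delta`` is bimolecular (M^-1 s^-1).
    """
    kw = dict(
        a1=1.2e6, a2=4.1e7, a3=1.6e4,
        b1=50.0, b2=400.0, b3=100.0,
        delta=1.0, beta=1.2e-4,
        alpha=30.0, gamma=1.5e-7, mu=6.0e3,
        unit_system="si",
    )
    kw.update(overrides)
    return KineticParams(**kw)


#: Initial copy numbers of the 3D model (canonical volume).
TABLE2_COUNTS = {"Ca0": 5, "IP0": 3, "N_plc": 1696, "N_IP3R": 50, "N_GCaMP": 169}


# ---------------------------------------------------------------------------
# count <-> concentration conversion
# ---------------------------------------------------------------------------

def concentration_from_count(count: float, volume: float = V_CYT_CANONICAL) -> float:
    """Molar concentration of ``count`` molecules in ``volume`` liters."""
    if volume <= 0:
        raise ConfigurationError("volume must be positive")
    if count < 0:
        raise ConfigurationError("count must be >= 0")
    return count / (AVOGADRO * volume)


def count_from_concentration(conc: float, volume: float = V_CYT_CANONICAL) -> int:
    """Nearest integer copy number for a molar concentration."""
    if volume <= 0:
        raise ConfigurationError("volume must be positive")
    if conc < 0:
        raise ConfigurationError("concentration must be >= 0")
    return int(round(conc * AVOGADRO * volume))


# ---------------------------------------------------------------------------
# configuration files
# ---------------------------------------------------------------------------

# ---------------------------------------------------------------------------
# simulation traces
# ---------------------------------------------------------------------------

@dataclass
class SimulationTrace:
    """Uniformly sampled time series produced by any engine.

    ``ca``/``ip3`` hold copy numbers (2D engines) or copy numbers alongside
    molar columns in ``extra`` (3D engine); ``open_count`` is the number of
    simultaneously open IP3R at each sample.  ``transitions`` is an optional
    receptor transition log with rows (time, receptor_id, from, to), and
    ``receptor_positions`` an optional (N, ndim) array of channel positions.
    """

    time: "np.ndarray"
    ca: "np.ndarray"
    ip3: "np.ndarray"
    open_count: "np.ndarray"
    meta: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)
    transitions: "np.ndarray | None" = None
    receptor_positions: "np.ndarray | None" = None

    def __len__(self) -> int:
        return len(self.time)

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0]) if len(self.time) > 1 else 0.0

    def to_frame(self):
        import pandas as pd

        data = {"time": self.time, "ca": self.ca, "ip3": self.ip3,
                "open_count": self.open_count}
        data.update(self.extra)
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# configuration files
# ---------------------------------------------------------------------------

_SECTIONS = ("kinetics", "space2d", "geometry3d", "geci", "buffers", "protocol")


@dataclass
class SimulationConfig:
    """Validated, fully defaulted configuration."""

    kinetics: KineticParams = field(default_factory=table1_kinetics)
    space2d: SpatialParams2D = field(default_factory=table1_space)
    geometry3d: Geometry3DParams = field(default_factory=Geometry3DParams)
    geci: GECIParams = field(default_factory=GECIParams)
    buffers: tuple = ()
    protocol: dict = field(default_factory=dict)


def _build(cls, section: dict, section_name: str, defaults=None):
    known = {f.name for f in fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) {sorted(unknown)} in section [{section_name}]"
        )
    if defaults is not None:
        return replace(defaults, **section)
    return cls(**section)


def validate_config(raw: dict | None) -> SimulationConfig:
    """Normalize a raw (parsed) configuration mapping.

    Unknown sections or keys are rejected; omitted keys take the default 2D
    values unless ``kinetics.unit_system`` is ``"si"``, in which case the 3D
    defaults apply.  Per-step probabilities implied by the 2D time step are
    verified to be < 1 (the offending rate is named on failure).
    """
    raw = dict(raw or {})
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ConfigurationError(f"unknown configuration section(s) {sorted(unknown)}")

    kin_raw = dict(raw.get("kinetics") or {})
    system = kin_raw.get("unit_system", "mc")
    kin_defaults = table2_kinetics() if system == "si" else table1_kinetics()
    kinetics = _build(KineticParams, kin_raw, "kinetics", kin_defaults)

    space2d = _build(SpatialParams2D, dict(raw.get("space2d") or {}), "space2d",
                     SpatialParams2D())
    geometry3d = _build(Geometry3DParams, dict(raw.get("geometry3d") or {}),
                        "geometry3d", Geometry3DParams())

    geci_raw = dict(raw.get("geci") or {})
    variant = geci_raw.get("variant", "none")
    if variant == "GCaMP6s":
        geci_defaults = gcamp6s()
    elif variant == "GCaMP6f":
        geci_defaults = gcamp6f()
    else:
        geci_defaults = GECIParams()
    geci = _build(GECIParams, geci_raw, "geci", geci_defaults)

    buffers = []
    for i, buf in enumerate(raw.get("buffers") or []):
        buffers.append(_build(BufferSpec, dict(buf), f"buffers[{i}]", BufferSpec()))

    protocol = dict(raw.get("protocol") or {})

    cfg = SimulationConfig(kinetics, space2d, geometry3d, geci, tuple(buffers),
                           protocol)
    if kinetics.unit_system == "mc":
        check_step_probabilities(kinetics, space2d, cfg.buffers)
    return cfg


def check_step_probabilities(kinetics: KineticParams, space: SpatialParams2D,
                             buffers: tuple = ()) -> None:
    """Verify every per-step probability of the 2D MC scheme is < 1."""
    dt = space.dt
    contact_ip3r = math.pi * space.d_IP3R**2
    contact_plc = math.pi * space.d_PLC**2
    probs = {
        "b1": kinetics.b1 * dt,
        "b2": kinetics.b2 * dt,
        "b3": kinetics.b3 * dt,
        "beta": kinetics.beta * dt,
        "alpha": kinetics.alpha * dt,
        "mu": kinetics.mu * dt,
        "gamma": kinetics.gamma * dt,
        "a1": kinetics.a1 * dt / contact_ip3r,
        "a2": kinetics.a2 * dt / contact_ip3r,
        "a3": kinetics.a3 * dt / contact_ip3r,
        "delta": kinetics.delta * dt / contact_plc,
    }
    for i, buf in enumerate(buffers):
        probs[f"buffers[{i}].k_on"] = buf.k_on * dt / contact_ip3r
        probs[f"buffers[{i}].k_off"] = buf.k_off * dt
    for name, p in probs.items():
        if p >= 1.0:
            raise ConfigurationError(
                f"rate {name} yields per-step probability {p:.3g} >= 1 "
                f"at dt={dt}; reduce the rate or the time step"
            )


def load_config(path) -> SimulationConfig:
    """Load and validate a YAML configuration file."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError("configuration root must be a mapping")
    return validate_config(raw)


def config_digest(cfg: SimulationConfig) -> str:
    """Short stable digest of a configuration, for trace headers."""
    import hashlib

    text = repr(cfg).encode()
    return hashlib.sha1(text).hexdigest()[:12]
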