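"""Trace and peak-table files, plus the synthetic fixture generator.

Traces are plain columnar text with a structured ``# key: value`` header
carrying the engine name, unit system, sampling step, seed and a digest of
the configuration, so a trace can always be matched to the run that made
it.  Peak tables are tab-separated with one row per detected event.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import SimulationTrace
from .peaks import PeakRecord

_META_KEYS = ("engine", "unit_system", "V", "seed", "sample_dt", "dt",
              "variant", "digest", "mode", "tau", "eta", "R_gamma", "D_Ca",
              "D_IP3", "n_voxels", "mesh_volume", "resampled_hz")


def write_trace(trace: SimulationTrace, path) -> None:
    cols = {"time": trace.time, "ca": trace.ca, "ip3": trace.ip3,
            "open_count": trace.open_count}
    for k, v in trace.extra.items():
        arr = np.asarray(v)
        if arr.ndim == 1 and arr.shape[0] == len(trace.time):
            cols[k] = arr
    with open(path, "w") as fh:
        for k in _META_KEYS:
            if k in trace.meta:
                v = trace.meta[k]
                if isinstance(v, np.generic):
                    v = v.item()
                fh.write(f"# {k}: {v!r}\n")
        fh.write("\t".join(cols) + "\n")
        mat = np.column_stack(list(cols.values()))
        for row in mat:
            fh.write("\t".join(f"{x:.10g}" for x in row) + "\n")


def read_trace(path) -> SimulationTrace:
    meta = {}
    header = None
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                k, _, v = line[1:].partition(":")
                import ast
                meta[k.strip()] = ast.literal_eval(v.strip())
            elif header is None:
                header = line.split("\t")
            elif line:
                rows.append([float(x) for x in line.split("\t")])
    if header is None:
        raise ValueError(f"{path}: not a trace file")
    mat = np.asarray(rows, dtype=float)
    cols = {h: mat[:, i] for i, h in enumerate(header)}
    trace = SimulationTrace(time=cols.pop("time"), ca=cols.pop("ca"),
                            ip3=cols.pop("ip3"),
                            open_count=cols.pop("open_count"), meta=meta)
    trace.extra.update(cols)
    return trace


def write_transitions(transitions, path) -> None:
    """Columnar receptor transition log (time, receptor, from, to)."""
    with open(path, "w") as fh:
        fh.write("time\treceptor_id\tfrom_state\tto_state\n")
        for row in np.asarray(transitions):
            fh.write(f"{row[0]:.10g}\t{int(row[1])}\t{int(row[2])}"
                     f"\t{int(row[3])}\n")


def read_transitions(path) -> np.ndarray:
    return np.loadtxt(path, skiprows=1)


def write_layout(layout, path) -> None:
    """Receptor cluster layout (receptor_id, cluster_id, x, y)."""
    with open(path, "w") as fh:
        fh.write("receptor_id\tcluster_id\tx\ty\n")
        for i, (cid, (x, y)) in enumerate(zip(layout.cluster_id,
                                              layout.positions)):
            fh.write(f"{i}\t{int(cid)}\t{x:.10g}\t{y:.10g}\n")


def write_peaks(peaks: list[PeakRecord], path, trace_id: str = "trace") -> None:
    with open(path, "w") as fh:
        fh.write("trace_id\tt_start\tt_end\tamplitude\tfwhm\tdff"
                 "\tmax_open\tclass\n")
        for p in peaks:
            fh.write(f"{trace_id}\t{p.t_start:.10g}\t{p.t_end:.10g}"
                     f"\t{p.amplitude:.10g}\t{p.fwhm:.10g}\t{p.dff:.10g}"
                     f"\t{p.max_open}\t{p.klass or 'NA'}\n")


def read_peaks(path) -> list[PeakRecord]:
    out = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append(PeakRecord(
                t_start=float(f[1]), t_end=float(f[2]), amplitude=float(f[3]),
                fwhm=float(f[4]), dff=float(f[5]), max_open=int(f[6]),
                klass=None if f[7] == "NA" else f[7]))
    return out


# ---------------------------------------------------------------------------
# synthetic fixtures for the analysis layer
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixtureSpec:
    """Synthetic trace with planted peaks for detector testing."""

    baseline: float = 50.0
    noise_sd: float = 2.0
    peak_times: tuple = (200.0, 500.0, 800.0)
    peak_amplitudes: tuple = (150.0, 120.0, 180.0)  # absolute peak heights
    peak_fwhms: tuple = (10.0, 8.0, 15.0)
    shape: str = "gaussian"  # or "rectangular"
    duration: float = 1000.0
    sample_dt: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not (len(self.peak_times) == len(self.peak_amplitudes)
                == len(self.peak_fwhms)):
            raise ValueError("peak arrays must have equal length")
        for t in self.peak_times:
            if not 0 <= t <= self.duration:
                raise ValueError("planted peak outside trace duration")
        for a in self.peak_amplitudes:
            if a <= self.baseline:
                raise ValueError("peak amplitude must exceed baseline")
        if self.shape not in ("gaussian", "rectangular"):
            raise ValueError("shape must be gaussian or rectangular")


def make_fixture(spec: FixtureSpec) -> tuple[SimulationTrace, list[PeakRecord]]:
    """Build the synthetic trace and its ground-truth peak table."""
    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, spec.duration + 0.5 * spec.sample_dt, spec.sample_dt)
    v = np.full_like(t, spec.baseline)
    truth = []
    for t0, amp, fwhm in zip(spec.peak_times, spec.peak_amplitudes,
                             spec.peak_fwhms):
        h = amp - spec.baseline
        if spec.shape == "gaussian":
            sd = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
            v += h * np.exp(-0.5 * ((t - t0) / sd) ** 2)
        else:
            v += np.where(np.abs(t - t0) <= fwhm / 2.0, h, 0.0)
        truth.append(PeakRecord(t_start=t0 - fwhm, t_end=t0 + fwhm,
                                amplitude=amp, fwhm=fwhm,
                                dff=h / spec.baseline))
    if spec.noise_sd > 0:
        v = v + rng.normal(0.0, spec.noise_sd, size=v.size)
    trace = SimulationTrace(
        time=t, ca=v, ip3=np.zeros_like(v), open_count=np.zeros_like(v),
        meta={"engine": "fixture", "unit_system": "mc",
              "sample_dt": spec.sample_dt, "seed": spec.seed})
    return trace, truth
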