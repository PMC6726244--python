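"""Replicate orchestration and the in-silico experiments.

Stochastic quantities are reported as mean +/- SD over replicates (default
20, seeds ``base_seed + 0..n-1``).  Two-group comparisons use an unpaired
t-test when both samples pass a Shapiro normality pre-test at alpha = 0.05
and a Mann-Whitney U test otherwise, with the usual star codes; parameter
sweeps support a one-way ANOVA across levels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

from .core import KineticParams, SimulationTrace, SpatialParams2D
from .ip3r import ClosureStats, NoClosuresError, closure_paths
from . import meanfield, particle2d, peaks, ssa

DEFAULT_N_REPLICATES = 20

_STAT_KEYS = ("frequency", "mean_amplitude", "mean_fwhm", "mean_dff",
              "puff_ratio", "baseline", "max_open", "n_peaks",
              "max_amplitude_above_baseline")


def _run_engine(engine: str, kinetics: KineticParams, space: SpatialParams2D,
                T: float, seed: int, **kwargs) -> SimulationTrace:
    if engine == "ssa":
        return ssa.run_ssa(kinetics, space, T, seed, **kwargs)
    if engine == "particle2d":
        return particle2d.run_2d(kinetics, space, T, seed, **kwargs)
    if engine == "meanfield":
        return meanfield.simulate_mf(kinetics, space, T, **kwargs)
    raise ValueError(f"unknown engine {engine!r}")


@dataclass
class ReplicateResult:
    """Per-statistic replicate vectors with mean +/- SD summaries."""

    engine: str
    n_replicates: int
    seeds: list[int]
    raw: dict[str, np.ndarray]
    failures: list[tuple[int, str]] = field(default_factory=list)

    def mean(self, key: str) -> float:
        return float(np.nanmean(self.raw[key]))

    def sd(self, key: str) -> float:
        return float(np.nanstd(self.raw[key], ddof=1))

    def summary(self) -> dict:
        return {k: (self.mean(k), self.sd(k)) for k in self.raw}


def replicate_run(engine: str, kinetics: KineticParams,
                  space: SpatialParams2D, T: float,
                  n: int = DEFAULT_N_REPLICATES, base_seed: int = 1,
                  peak_n: float | None = None,
                  **engine_kwargs) -> ReplicateResult:
    """Run ``n`` replicates and summarize their peak statistics."""
    if n < 2:
        raise ValueError("need at least 2 replicates")
    seeds = [base_seed + i for i in range(n)]
    raw = {k: np.full(n, np.nan) for k in _STAT_KEYS}
    failures = []
    for i, seed in enumerate(seeds):
        try:
            trace = _run_engine(engine, kinetics, space, T, seed,
                                **engine_kwargs)
            est, found = peaks.analyze_trace(trace, n=peak_n)
            st = peaks.peak_statistics(found, trace.duration)
        except Exception as exc:  # pragma: no cover - engine failure path
            failures.append((seed, repr(exc)))
            continue
        for k in _STAT_KEYS:
            if k == "baseline":
                raw[k][i] = est.baseline
            elif k == "max_amplitude_above_baseline":
                raw[k][i] = (max(p.amplitude for p in found) - est.baseline
                             if found else np.nan)
            else:
                raw[k][i] = st.get(k, np.nan)
    return ReplicateResult(engine, n, seeds, raw, failures)


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------

def star_code(p: float) -> str:
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def compare_groups(sample_a, sample_b, alpha_normality: float = 0.05) -> dict:
    """Two-group comparison with normality-dependent test choice."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each sample needs at least 3 values")
    normal = True
    for s in (a, b):
        if np.ptp(s) == 0:
            continue  # constant sample: Shapiro undefined, treat as normal
        if sstats.shapiro(s).pvalue < alpha_normality:
            normal = False
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return {"test": "t", "statistic": 0.0, "pvalue": 1.0, "stars": "ns"}
    if normal:
        res = sstats.ttest_ind(a, b)
        name = "t"
    else:
        res = sstats.mannwhitneyu(a, b, alternative="two-sided")
        name = "mannwhitney"
    p = float(res.pvalue)
    return {"test": name, "statistic": float(res.statistic), "pvalue": p,
            "stars": star_code(p)}


def anova_oneway(*groups) -> dict:
    """One-way ANOVA across sweep levels."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    res = sstats.f_oneway(*[np.asarray(g, dtype=float) for g in groups])
    return {"test": "anova", "statistic": float(res.statistic),
            "pvalue": float(res.pvalue), "stars": star_code(float(res.pvalue))}


# ---------------------------------------------------------------------------
# regime map (frequency / max-open over a mu x a1 grid)
# ---------------------------------------------------------------------------

@dataclass
class RegimeMap:
    mu_values: list[float]
    a1_values: list[float]
    frequency: np.ndarray  # (n_mu, n_a1) mean peak frequency
    max_open: np.ndarray  # (n_mu, n_a1) max simultaneously open per peak
    labels: np.ndarray  # (n_mu, n_a1) object array of regime names
    results: dict = field(default_factory=dict)


def _label_cell(all_peaks: list) -> str:
    """stationary: no peaks; blips: >=90% of peaks single-channel; else puffs."""
    if not all_peaks:
        return "stationary"
    single = sum(1 for p in all_peaks if p.max_open <= 1)
    return "blips" if single / len(all_peaks) >= 0.9 else "puffs"


def regime_map(mu_values, a1_values, kinetics: KineticParams,
               space: SpatialParams2D, T: float = 150.0,
               n: int = DEFAULT_N_REPLICATES, base_seed: int = 1,
               engine: str = "particle2d") -> RegimeMap:
    """Explore the (mu, a1) plane and label each cell's activity regime.

    Arbitrary (irregular) grids are supported.  The default per-replicate
    duration is short because the high-excitability corner of the plane is
    only metastable: beyond a few hundred MC time units the PLC feedback
    escalates it out of the puff regime (see the methods note).
    """
    mu_values = list(mu_values)
    a1_values = list(a1_values)
    freq = np.zeros((len(mu_values), len(a1_values)))
    mo = np.zeros_like(freq)
    labels = np.empty(freq.shape, dtype=object)
    results = {}
    for i, mu in enumerate(mu_values):
        for j, a1 in enumerate(a1_values):
            from dataclasses import replace
            kin = replace(kinetics, mu=float(mu), a1=float(a1))
            cell_peaks = []
            freqs = []
            for rep in range(n):
                trace = _run_engine(engine, kin, space, T,
                                    base_seed + rep)
                est, found = peaks.analyze_trace(trace)
                cell_peaks.extend(found)
                freqs.append(len(found) / trace.duration)
            freq[i, j] = float(np.mean(freqs))
            mo[i, j] = max((p.max_open for p in cell_peaks), default=0)
            labels[i, j] = _label_cell(cell_peaks)
            results[(mu, a1)] = {"frequency": freqs,
                                 "n_peaks": len(cell_peaks)}
    return RegimeMap(mu_values, a1_values, freq, mo, labels, results)


# ---------------------------------------------------------------------------
# closure-path experiment (Fig 4E/F protocol)
# ---------------------------------------------------------------------------

def closure_experiment(D_Ca_values, R_gamma_values, kinetics: KineticParams,
                       space: SpatialParams2D, T: float = 2000.0,
                       n: int = DEFAULT_N_REPLICATES,
                       base_seed: int = 1) -> dict:
    """Closure-path probabilities of open receptors over a (D_Ca, R_gamma)
    grid, from particle-engine transition logs.

    Returns ``{(D, R): ClosureStats | None}`` (None flags a cell without
    any observed closure).
    """
    from dataclasses import replace

    out = {}
    for D in D_Ca_values:
        for R in R_gamma_values:
            sp = replace(space, D_Ca=float(D), R_gamma=float(R))
            logs = []
            for rep in range(n):
                trace = particle2d.run_2d(kinetics, sp, T,
                                          base_seed + rep,
                                          record_transitions=True)
                if trace.transitions is not None and len(trace.transitions):
                    logs.append(trace.transitions)
            try:
                stats = closure_paths(np.vstack(logs) if logs else np.empty((0, 4)))
            except NoClosuresError:
                stats = None
            out[(D, R)] = stats
    return out
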