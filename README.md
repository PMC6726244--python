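# astroca

Stochastic, spatially explicit simulation of IP3R-mediated calcium
signaling in fine astrocytic processes.

Most astrocyte calcium activity happens in processes too thin for
conventional light microscopy, where copy numbers are tiny (a handful of
calcium ions in ~0.03 fL) and deterministic, well-mixed models are the
wrong tool.  `astroca` implements a calcium-induced calcium-release
(CICR) model built around the classical 8-state IP3 receptor monomer —
occupancy triplets {i, j, k} for the activating Ca site, the IP3 site and
the inactivating Ca site, conducting iff the state is {110}, with no
intra-channel cooperativity — embedded in a reaction scheme with
first-order Ca clearance (`alpha`), IP3R-independent influx (`gamma`),
per-open-channel influx (`mu`), calcium-activated IP3 production by
PLCdelta (`delta`) and IP3 decay (`beta`).

Four interoperable engines:

| engine | description |
|---|---|
| `meanfield` | deterministic mass-action ODEs (perfect mixing) |
| `ssa` | exact Gillespie simulation, every receptor individual |
| `particle2d` | lattice-free 2D Brownian dynamics: explicit positions, receptor clusters (`eta` channels within radius `d*sqrt(eta/0.91)`), co-localized influx (within `R_gamma` of a receptor), optional explicit buffers, `D = inf` perfect-mixing mode |
| `space3d` | voxel-based reaction-diffusion (RDME) in a 1 um x 0.1 um cylindrical process with internal ER, IP3R on the ER surface, optional GCaMP6s/6f indicator and endogenous buffers |

plus a shared analysis layer (histogram-mode baseline, n-sigma threshold
peak detection, FWHM, dF/F, blip/puff classification by diffusion length
vs open-channel separation) and replicate/sweep protocols with the usual
t-test / Mann-Whitney / ANOVA statistics.

## A worked example

```python
import numpy as np
from astroca import (table1_kinetics, table1_space, run_ssa, run_2d,
                     steady_state, analyze_trace, peak_statistics)

kin, sp = table1_kinetics(), table1_space()   # default 2D parameter set

ss = steady_state(kin, sp)
print(f"mean-field basal Ca: {ss['ca_count']:.1f} ions")

tr = run_2d(kin, sp, T=10_000.0, seed=1)      # D = inf, eta = 1
est, found = analyze_trace(tr)
stats = peak_statistics(found, tr.duration)
print(f"baseline mode: {est.baseline:.1f} ions (sigma {est.sigma:.1f}, "
      f"n = {est.n:.0f})")
print(f"{stats['n_peaks']} spontaneous peaks, "
      f"frequency {stats['frequency']:.4f} per MC time unit, "
      f"mean amplitude {stats['mean_amplitude']:.1f} ions")
```

prints

```
mean-field basal Ca: 52.1 ions
baseline mode: 49.1 ions (sigma 5.3, n = 4)
79 spontaneous peaks, frequency 0.0079 per MC time unit, mean amplitude 97.8 ions
```

The deterministic model sits at a stationary basal level of ~52 ions; the
stochastic engines fluctuate around the same baseline (histogram mode
49–50 ions) but additionally fire spontaneous calcium peaks tens of ions
above it — stochasticity, acting on an excitable system, creates the
signals that the mean-field description misses entirely.

The same machinery runs the 3D process model:

```python
from astroca import (Geometry3DParams, build_mesh, table2_kinetics,
                     gcamp6s, run_3d, sample_fluorescence)

mesh = build_mesh(Geometry3DParams(voxel_scale=50e-9))
tr = run_3d(mesh, table2_kinetics(), gcamp6s(), T=60.0, seed=1)
fl = sample_fluorescence(tr, rate=2.0)        # 2 Hz, like the microscope
```

giving a Ca-bound GCaMP6s trace with a basal level around 300 nM and
second-scale spontaneous transients.

There is also a command line (`astroca simulate-2d / simulate-ssa /
simulate-mf / simulate-3d / detect-peaks / sweep / make-fixture`) writing
plain-text traces and peak tables with config digests in their headers.

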