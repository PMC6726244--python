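# Methods

## The model

`astroca` simulates calcium-induced calcium release (CICR) through IP3
receptor channels (IP3R) in the small, low-copy-number volumes typical of
fine astrocytic processes.  The reaction scheme has five elements:

* free cytosolic Ca2+ is cleared at a first-order rate `alpha` (lumping ER
  and plasma-membrane pumps) and replenished by an IP3R-independent influx
  `gamma`;
* each open IP3R injects Ca2+ at rate `mu`;
* PLCdelta, activated by Ca2+ (which it does not consume), produces IP3 at
  rate `delta`; IP3 decays at rate `beta`;
* each IP3R monomer carries three binding sites — an activating Ca site
  (`a1`/`b1`), an IP3 site (`a2`/`b2`) and an inactivating Ca site
  (`a3`/`b3`) — giving an 8-state Markov chain with occupancy triplets
  {i, j, k}; the channel conducts iff the state is {110};
* there is no intra-channel cooperativity: every site binds and unbinds
  independently of the other two, so the monomer's stationary law
  factorizes over sites (a tested invariant).

Four engines share this scheme:

1. **meanfield** — mass-action ODEs for the seven independent receptor-state
   concentrations (the eighth follows from receptor conservation), IP3 and
   Ca.  Integrated with LSODA at rtol 1e-8 (excitable systems amplify
   integrator error); steady states are root-polished and verified to
   |rhs| < 1e-8 in count units.
2. **ssa** — exact Gillespie simulation with every receptor represented
   individually; bimolecular propensities carry 1/V (e.g. the activating
   site of a receptor binds Ca with propensity `a1/V * N_Ca`).
3. **particle2d** — a lattice-free Brownian-dynamics Monte Carlo model in a
   200 x 200 domain (arbitrary units, reflective boundaries).  Each step
   (dt = 0.01 MC time units; one MC time unit = 100 steps) applies, in
   order: diffusion (Gaussian displacements of s.d. sqrt(2 D dt) per axis,
   or a uniform redraw in the perfectly mixed `D = inf` mode), binding,
   unbinding, removal, influx.  Receptors are placed in clusters of `eta`
   channels inside disks of radius `R_c = d * sqrt(eta/0.91)` (constant
   in-cluster areal density); the IP3R-independent influx lands uniformly
   within `R_gamma` of a uniformly chosen receptor, so small `R_gamma`
   co-localizes both calcium sources.
4. **space3d** — a reaction–diffusion master equation (RDME) model of a
   cylindrical process (length 1 um, radius 0.1 um) containing a coaxial
   ER cylinder (0.75 um, 0.03 um), with 50 IP3R placed in distinct
   ER-surface voxels, SI kinetics, and optional GCaMP6s/6f indicator and
   endogenous buffers.  The raw signal is free Ca for the indicator-free
   variant and Ca-bound indicator otherwise.

## Unit conventions

In the 2D engines, first-order constants are per MC time unit and the
bimolecular constants `a1, a2, a3, delta` are *rate-areas*
((space unit)^2 per time unit).  In the particle engine a candidate
ligand–receptor contact (distance below `d_IP3R` = 1 space unit) is
accepted with probability `a_i * dt / (pi d^2)`, whose perfectly mixed
limit is exactly the mass-action propensity `a_i/V` used by the SSA and
mean-field engines.  This is the only convention under which the three
engines agree quantitatively — the property the model's own baseline
comparisons assert — and it is consistent with the area units attached to
those constants in the 2D parameter table.  Treating `a_i * dt` as a bare
contact probability instead would scale every contact reaction by
`pi d^2` and destabilize the default parameter set.

In the 3D engine all kinetics are SI.  Two printed values require
interpretation: `gamma` (1.5e-7) is read as a volumetric influx in M/s
(~2.5 ions/s in the canonical volume); as a bare per-second ion rate the
cytosol would have essentially no Ca source and the basal state would
collapse.  `delta` (printed as 1 "s^-1") multiplies [PLC][Ca] and is
therefore bimolecular, 1 M^-1 s^-1; with `beta` = 1.2e-4 s^-1 both IP3
fluxes are negligible over simulated timescales, so IP3 stays near its
initial 3 copies (~177 nM), as intended.

Counts and concentrations are interconverted through the canonical
cytosolic volume 2.81e-17 L.  The analytic shell volume of the stated
geometry is ~2.93e-17 L (4.3% larger); the canonical value is the one
that makes the published count/concentration pairs mutually consistent,
so it is used for every conversion while the mesh keeps its exact
analytic volume.

## The 3D discretization

Instead of an unstructured tetrahedral mesh, the cytosol is divided into
axial slices x radial rings x angular sectors whose volumes are
analytically exact.  Rings touching the axis are kept as single central
voxels (splitting them into slivers would blow up the maximal hop rate).
Diffusion is a first-order hop with rate `D * A / (V_i * h)` per molecule
across each shared face (area A, centroid distance h); the hop network
satisfies detailed balance, so a diffusion-only run relaxes to uniform
occupancy (tested).  Both membranes are reflective and ER luminal calcium
is not modelled (the ER is an infinite reservoir entering only through
`mu`).

Sampling is a fixed-step tau-leap: the step is chosen so that every
reaction has probability at most ~5% per step and a Ca molecule makes at
most ~0.3 hops per step (preserving near-channel spatial correlations,
which the 3D model exists to resolve); faster diffusers (IP3 at
280 um^2/s, GCaMP at 50 um^2/s) take Poisson-distributed multi-hop counts
within a step, and channel influx (`mu` = 6000/s) uses Poisson counts.
At the copy numbers of this system (~200 mobile molecules) the scheme is
statistically indistinguishable from exact event sampling; the test suite
verifies the engine against the exact Gillespie simulator on a degenerate
single-voxel mesh and against closed-form binding isotherms.  An exact
next-subvolume scheme was considered and dropped: with fewer than ~10^3
molecules the tau-leap is both simpler and accurate, and it keeps long 3D
traces cheap.

Default voxel scales: 25 nm for geometry work, 50 nm for production runs
(165 voxels), 100 nm (66 voxels) for long directional protocols; all are
configurable and the mesh volume is always within 5% of the canonical
volume.

## Peak detection

The detector follows the histogram procedure: baseline = mode of the
trace histogram (bin 0.25 ions, or its concentration equivalent
14.8 nM in the canonical volume); threshold = baseline + n*sigma with n
in {2, 3, 4}; a peak is a maximal contiguous excursion above threshold
(overlapping events merge); amplitude is the in-peak maximum; duration is
the full width at half maximum measured from baseline; dFF =
(A - baseline)/baseline.  Two points were genuinely open:

* **sigma.**  The noise scale is the rms deviation from the mode of the
  samples *at or below* the mode (the mirrored lower half-distribution).
  Release events only add probability mass above the mode, so this
  estimator is immune to event contamination; estimating sigma from all
  sub-threshold samples instead inflates it roughly twofold on
  event-dense traces (slow diffusion, co-localized influx) and erases the
  mobility dependence of the detected peak frequency.
* **n.**  Chosen per trace as the smallest value in {2, 3, 4} for which
  the expected number of Gaussian noise crossings over the whole trace
  stays below 0.5 — a reproducible, length-adaptive stand-in for
  per-trace hand tuning (10^4-sample count traces get n = 4, 2-Hz
  fluorescence traces n = 3); overridable everywhere.  No minimum peak
  width is imposed: on slow-diffusion traces nearly half of the genuine
  release events span a single sample at the default cadence.

A peak is a **blip** when at most one channel was open during it.  With
several open channels it is a **puff** when the rms diffusion length
`sqrt(2 * ndim * D_Ca * FWHM)` exceeds the mean pairwise distance between
the channels that opened during the peak (perfect mixing always
qualifies).  Open-channel identities come from the receptor transition
log (transitions into and out of {110}), so openings shorter than the
trace sampling interval are still attributed correctly.

## Protocols and problem sizes

Stochastic results are mean +/- SD over replicates with seeds
`base_seed + 0..n-1` (default n = 20).  Two-sample comparisons use an
unpaired t-test when both samples pass Shapiro normality at alpha = 0.05,
otherwise Mann-Whitney; sweeps support one-way ANOVA.  Default 2D run
length is 10,000 MC time units.

**Metastability of the puff regime.**  With the default 2D parameter set
the PLCdelta feedback (IP3 production proportional to [Ca]) makes the
high-excitability corner of the (mu, a1) plane only metastable: at
mu = 75, a1 = 7 the deterministic model leaves the low-activity state at
t ~ 500–800 time units and saturates at ~27,000 ions with hundreds of
open channels, and the stochastic engines follow (escape onset can occur
below 300 time units in a 20-replicate batch).  Within the metastable
window the regime shows exactly the expected phenomenology — frequent
peaks with 2–12 simultaneously open channels.  Puff-regime protocols
therefore use 150 time units per replicate, which 60 test replicates
place safely inside the window; the regime-map default duration is the
same.  The default condition (mu = 50, a1 = 1) is stable for at least
10,000 time units.

Relatedly, the mean-field model is bistable at large `a1`: at a1 = 5 a
second stable state exists at ~17,400 ions and the separatrix sits
between 90 and 95 injected IP3 molecules when starting from the exact
fixed point.  The IP3-injection protocol therefore follows the published
figure protocol — start from the standard initial conditions, inject at
t = 20 dt — under which responses relax back to baseline; the response
amplitude is measured against the unperturbed reference trajectory so
that pre-equilibration drift cancels exactly.  Doubling the injection
from 50 to 100 molecules at a1 = 5 amplifies the response 4.1-fold
(vs 2.0-fold in the linear regime at a1 = 0.5).

**Explicit 2D buffers.**  The buffer-equivalence protocol uses mobile
buffer particles (D_buf = 0.1, free Ca at D_Ca = 0.8) against the
reference model with effective D_Ca = 0.1.  The buffer kinetics are not
part of the published parameter set.  For explicit buffers to emulate a
reduced effective diffusion coefficient at all, the exchange must be in
the classical rapid-buffering regime — capture and release both fast
compared with the free-Ca clearance (alpha = 1/time unit) and with peak
durations; slow capture is simply outrun by clearance and does nothing.
The defaults are therefore `buf_f = 300` (rate-area; the largest value
compatible with the per-step probability bound at dt = 0.01) and
`buf_b = 0.5` per time unit, giving a buffering capacity
kappa = capture/release of ~7.5 at 500 buffers (effective mobility
~0.18) and ~30 at 2000 (~0.12).  At 500 buffers the equivalence holds
in full — the attenuation of free-Ca transients by buffering is
compensated by the stronger local CICR recruitment that slow effective
diffusion produces.  At 2000 buffers the frequency still matches but the
basal level and peak amplitude shift upward by ~20%: very strong
buffering capacity enhances near-channel recruitment beyond what a plain
slow-diffusion model shows, a genuine limitation of the
effective-diffusion picture documented here rather than hidden.

**3D protocols.**  The GCaMP basal concentration is reported as the
histogram-mode baseline of the bound-indicator trace (this is what
"measured basal" means under the detection procedure; the raw time mean
is roughly double because large transients are frequent).  Peak-duration
statistics are computed on traces point-sampled at 2 Hz, mirroring
confocal acquisition.  Production acceptance runs use a 50-nm mesh and
90–120 s of biological time; directional indicator comparisons (6f vs 6s)
use a controlled protocol in which a 25-ion Ca bolus is released at an
ER-surface voxel of an equilibrated process and the bound-indicator
transient is measured — the spontaneous-event rate is too low to compare
indicators reliably in short runs.  Endogenous-buffer defaults for the
"GC+Buf" variant are literature-typical calbindin/parvalbumin kinetics
with totals two orders of magnitude below whole-dendrite models; they are
synthetic defaults, clearly overridable in configuration.

## What the synthetic fixtures do and do not show

The analysis layer is validated on generated traces (Gaussian or
rectangular peaks of known amplitude and FWHM on a noisy baseline).
These fixtures establish detector correctness (recall/precision >= 0.95
at SNR >= 5, exact FWHM and dFF recovery on clean shapes) but not
biological realism: real traces have skewed noise, slow baseline drifts
and overlapping events, which is why every engine-level criterion is also
checked on actual simulations.

## Known limitations

* The 2D model's arbitrary units have no mapping to SI; only the 3D model
  is quantitative in concentrations.
* No receptor clustering parameter in 3D (channels are uniform over the
  ER surface) and no ER luminal depletion.
* The puff-regime corner of parameter space is metastable (above); results
  there are conditional on sampling the metastable window.
* The tau-leap accelerator trades exactness for speed; its error is
  controlled by the 5%-per-step bound and validated against the exact
  engine only in well-mixed reductions.
* A single 2D peak-amplitude extreme over 20 x 10,000 time units can reach
  ~150 ions above baseline, slightly beyond the 20–120 band typical of
  individual traces.
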