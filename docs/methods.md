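# Methods

## Scientific framing

The broadband, `1/f`-like background of an EEG power spectrum can be
produced by two very different mechanisms: the *kinetics of postsynaptic
currents* (exponentially decaying conductances produce Lorentzian spectra
regardless of input dynamics) and *temporally correlated network
activity* (propagating spikes near avalanche criticality put power at low
frequencies).  The two mechanisms confound each other: a drug that slows
inhibitory synaptic decay multiplies the spectral trend and masquerades
as a change in brain dynamics.  This package implements both mechanisms
as simulations, the arithmetic that connects single neurons to the scalp
ensemble, and the detrending analysis that separates them in recordings.

## Spectral trend models (`aperspectra.spectral`)

Three aperiodic closed forms are supported; all derive from the Fourier
transform of exponential synaptic kernels:

* `two_lorentzian`: `A1/(1+(2πτ1 f)²) + A2/(1+(2πτ2 f)²)` — slow
  (inhibitory, τ1) plus fast (excitatory, τ2) components;
* `lorentzian_plus_const`: `A1 τ1/(1+(2πτ1 f)²) + λ` — the fast component
  replaced by a flat floor λ (spikes, EMG, amplifier noise), appropriate
  for scalp data whose high-frequency end plateaus;
* `diff_exp_plus_const`: `A1(τr−τ1)²/[(1+(2πτr f)²)(1+(2πτ1 f)²)] + λ` —
  the exact spectrum of a difference-of-exponentials synaptic response
  with rise τr, fixed at 4 ms; the default form for anesthesia data,
  where fits constrain τ1 to [10, 75] ms.

The amplitude conventions differ between forms (A1 vs A1τ1 vs
A1(τr−τ1)²); A1 is treated as a free fit amplitude per form, since no
absolute unit convention is imposed by the data.

**Fitting.**  The combined trend+peaks fit works in log10-power space
(the dynamic range spans ≥4 decades): a robust initial trend fit that
drops high-residual (putative peak) bins, Gaussian peaks fitted
largest-first on the residual, then trend refits on the peak-subtracted
spectrum, iterated to a relative parameter tolerance of 1e−4 (cap 50
iterations; non-convergence is flagged, not raised).  Numerical choices
that matter:

* amplitudes and timescales are fitted as log10 quantities with bounds;
* the trend fit is multi-started over τ1 — the landscape has a local
  optimum in which τ2 degenerates into a floor and τ1 absorbs all
  curvature;
* peak detection threshold: residual > 2 SD *and* > 0.05 log10 units
  (so numerically exact spectra do not sprout peaks); at most 6 peaks;
* peak widths are capped (default 3 Hz SD): without the cap a broad
  pseudo-peak can absorb the trend entirely;
* 0 Hz bins are excluded (log undefined);
* optionally the trend model is convolved with the spectral window of the
  estimator that produced the data (`kernel=`): a 2-s, NW=2 multitaper
  estimate smooths ±1 Hz and otherwise biases fitted knees upward.

Divisive detrending (ratio to the fitted trend, optionally in dB) is the
correct correction for multiplicative postsynaptic changes; subtractive
detrending (difference, clipped at zero) for additive independent
sources.  The spectral exponent β is an ordinary least-squares fit of
`10^α/f^β` to log-log coordinates over 1–40 Hz.

## Point-dipole neuron (`aperspectra.neuron`)

The morphologically detailed neuron is reduced to one compartment with
*direction-tagged* synapses (soma at the origin, one unit vector per
synapse), licensed by the near-linear relation between synapse location
and evoked dipole orientation.  Membrane dynamics:

`Cm dV/dt = −gL(V−EL) − Σ_E gE sE(t)(V−EE) − Σ_I gI sI(t)(V−EI)`

with difference-of-exponentials gates (E: 0.3 ms rise, τE decay; I: 2 ms
rise, τI decay; unit peak), integrated by exponential Euler at dt = 0.1 ms
(gates are exact discrete filters of the spike impulse trains).  Membrane
area is 1e−4 cm², so gL in mS/cm² gives a 1 ms membrane time constant at
gL = 1.  The dipole is `Q(t) = Σ g_x s(t)(E_x − V) d_syn`; a clamped-
voltage mode makes Q exactly linear in the input for superposition and
scaling tests.  Reference parameters: gL = 1 mS/cm², EL = −58 mV,
τE = 1.8 ms, gE = 0.7 nS, τI = 10 ms, gI = 0.7 nS, reversals 0/−80 mV.

Sampling distributions for the population analyses: log-uniform for
conductances (0.2–2 nS), leak (0.01–5 mS/cm²) and rates, uniform for
timescales (τE 1–3.5 ms, τI 5–20 ms) and EL (−75 to −45 mV).  Per-synapse
input rates are not pinned by any stated value; we use log-uniform
λE ∈ [0.1, 5] Hz and λI ∈ [0.5, 25] Hz (reference 1 and 5 Hz), typical
cortical per-synapse rates.

**Layouts.**  Default layouts draw directions uniformly but
*antithetically* (+d/−d pairs per kind, so Σd = 0 exactly).  A dendritic
arbor surrounds its soma; an unbalanced random sample instead leaks
network-wide rate fluctuations into the dipole through its O(√n)
direction-sum residual, which contaminates dipole-correlation null
controls.  Inhibitory:excitatory synapse count ratio 0.15.

**Unitary spectra** average, over trials, the Welch spectrum (2-s
segments, 50% overlap) of `g·(u·Q)` with a log-normal scalar gain g
(σ_log = 0.5) and uniformly random projection direction u per trial —
a scalar stand-in for averaging source locations through a head model.
Absolute amplitudes are therefore calibrated, not predicted; shapes and
parameter dependencies are the object of study.

**Sensitivity.**  Variance-based indices of β use a Saltelli radial
design (A, B, AB_i, BA_i: n(2k+2) evaluations), the Saltelli-2010
first-order and Jansen total-order estimators, and closed second-order
indices for requested pairs.  The default simulator uses common random
numbers (one fixed simulation seed), making β a deterministic function of
the parameters so that simulation noise cannot masquerade as sensitivity;
a `dummy` parameter then scores exactly zero.

The leak/E:I interaction deserves a caveat: in this proxy the correlation
between β and log(λE:λI) is clearly negative when the leak is strong
(V pinned near EL: more excitation adds fast power and flattens the
spectrum) and approximately zero when the leak is weak (driving-force
compensation: excitation depolarises V, which amplifies inhibitory
currents and cancels the rate effect).  The interaction — β is not a
single-valued readout of E:I balance — is robust; the per-stratum signs
are morphology-dependent and not asserted.

## Branching network (`aperspectra.branching`)

Binary neurons on the unit torus; each projects to exactly d_out = 10
targets sampled without replacement with probability ∝ exp(−d/0.05).
Each bin (1 ms), a neuron fires from baseline Poisson drive at rate
λ0(1−m) or from a pending propagated spike; each spike schedules, per
out-neighbour, an independent Bernoulli(m/d_out) spike uniformly within
the following 4 ms; a neuron fires at most once per bin.  The branching
identity keeps the stationary rate at λ0 for every m < 1 — but note that
near m = 0.98 the total spike count of a single 40-s run is dominated by
the few largest avalanches: the run-mean rate is unbiased yet heavy-
tailed (median ≈ 15% below the mean at N = 2000, λ0 = 1 Hz), so rate
checks average replicate runs.  At small N (≈500) with high rates,
same-bin spike merging genuinely saturates the cascade; at N = 2000,
λ0 = 1 Hz merging losses are <0.5%.

Inhibitory units (15% of the network) are not wired into the graph (their
influence is implicit in m): each pools its 20 nearest excitatory units'
spikes thinned to contribute a fraction m of its rate λI, plus
independent Poisson spikes for the remaining 1−m.

STTC follows the published definition; the matrix path uses a compiled
two-pointer kernel that agrees with the scalar implementation to
float precision and with an independent interval-sweep oracle to 1e−12.
The coincidence window Δt defaults to 10 ms.

## Dipole coherence (`aperspectra.mapping`)

The embedding contract — Spearman rank correlation between pairwise
source correlation and angular distance below −0.3 — is met with a
deterministic spectral embedding (top-3 eigenvectors of the correlation
matrix, rows normalised to the sphere).  Any manifold embedding passing
the contract is admissible; this one is dependency-light and exactly
reproducible.

Optimality perturbation displaces each point along a uniformly random
great-circle bearing by θ = arccos(1 − 2α(1−X)), α ~ U[0,1].  X = 1 is
the identity; X = 0 makes cos θ uniform on [−1, 1], i.e. a uniform
re-scatter.  (The source text prints a π prefactor on this distance,
which exceeds the arccos range for most α and contradicts the X = 0
uniformity property; the implementation omits it.)

Synapse assignment visits synapses in area-weighted random order and
connects each to the closest embedded unit (kind-matched); since units
are never consumed, the outcome is simply nearest-unit per synapse, ties
to the lowest index.  `dyad_from_raster` additionally restricts each
postsynaptic neuron to a random half of the presynaptic units ("axonal
reach"): without this, two neurons sampling nearest units from the same
embedding share most inputs, and shared wiring alone manufactures dipole
correlation even from an asynchronous (m = 0) source.

The minimal correlated-synapse model generates binary spike trains per
1 ms bin with pairwise count correlations R_max e^(−θij) and no temporal
structure, via a dichotomised Gaussian: the target binary correlation is
converted pairwise through the bivariate-normal orthant probability
(tabulated and interpolated per rate pair), the latent matrix is repaired
to the nearest PSD matrix by eigenvalue clipping, and thresholded
correlated Gaussian draws produce the spikes.

**Dyad correlation** is the Pearson correlation of the two neurons'
dipole projections on a *common* z axis (dt = 0.2 ms suffices for 40-s
correlations).  The dyad stands for neighbouring cortical neurons, whose
apical axes are aligned — projecting each neuron on its own mean-synapse
axis would be noise for isotropic layouts.  The shuffle control permutes
each neuron's synapse directions, preserving every train.  For balanced
layouts the shuffle-ensemble mean is zero by construction; a single
shuffled dyad at m = 0.98 still scatters with sd ≈ 0.18 because a few
large avalanches dominate 40 s of activity, so null checks average
hundreds of shuffle draws.

## Ensemble fields (`aperspectra.ensemble`)

Meshes are `trimesh` surfaces (shipped constructors: flat square and
icosphere; any OFF/PLY surface loads, including anatomical templates)
with neuron surface density μ = 100,000 mm⁻².  The signed neuron count
ν(r) sums μ·A_j·f_j(r)·(N_j·N_i) with the ball-intersection fraction f_j
computed by recursive 4-way triangle subdivision, deepened until ν
changes by <1e−3 (cap: depth 8).  The mean pairwise correlation ρ̄
Monte-Carlo averages ν over k area-weighted surface points (k = 2000 by
default) onto an r-grid out to 5σ and integrates ρ_max e^(−r²/σ²) against
dν̄ by the midpoint Stieltjes rule; distances are Euclidean 3D and the
cos θ alignment factor uses face normals.  On a flat patch this
reproduces ρ̄ = ρ_max μπσ²/(N−1) to 0.04% when sampling away from the
patch boundary (an open boundary truncates ν̄, so the closed-form check
samples the interior).  Ensemble power is σ_N² = Nσ0²(1 + (N−1)ρ̄).

## Anesthesia pipeline (`aperspectra.pipeline`)

Multitaper spectrograms use 3 DPSS tapers (NW = 2) on 2-s windows with
1.9-s overlap, one-sided PSD in μV²/Hz; Parseval holds to <5% against
pure tones, and single-window PSDs agree with an independent multitaper
implementation to a few percent (taper weighting differs).  The 60 Hz
line band is filled by log-linear interpolation before fitting.

τ1 tracking fits the difference-of-exponentials trend (τr fixed at 4 ms,
τ1 ∈ [10, 75] ms) over 3–55 Hz — below ~3 Hz the trend is coloured by
slow dynamics (delta rhythms, near-critical network activity), not
synaptic kinetics.  Estimator structure, chosen for the very low dof of
2-s windows (~6 per bin):

1. spectra are locally averaged over ±1 s of the heavily overlapping
   windows (negligible against the ~30 s pharmacokinetic drift of τ1) and
   the taper spectral window is convolved into the trend model;
2. free per-window fits (every `stride`-th window) give a τ1 series;
3. the series is smoothed by a 15-s running median and per-window trend
   amplitudes are refitted with τ1 fixed (a one-sided loss down-weights
   bins above the trend, where oscillatory peaks live);
4. the baseline τ1 is a single fit to the average of all pre-infusion
   windows — far tighter than averaging noisy per-window fits.

Effect-site concentration integrates the three-compartment plasma model
(rate constants shipped as configuration citing Marsh et al. 1991,
V1 = 0.228 L/kg) under the recorded constant-rate infusion, then
dCe/dt = keo(Cp − Ce) with keo = 1.21 min⁻¹; output in μM
(molar mass 178.27 g/mol).  Hill fits minimise least squares of
`b + span·C^n/(EC50^n + C^n)`; for fold-change data the baseline is
fixed at 1.

Band powers (delta 0.5–3, alpha 8–15, beta 15–30 Hz) are trapezoid
integrals per window; the detrended variant divides each window by its
fitted trend *evaluated over the band*, i.e. extrapolated below the fit
range, then normalises to the pre-infusion mean.  Group statistics: per
0.05-wide rescaled-time segment (infusion ↦ −1, LOC ↦ 0), an exact
right-tailed sign test of positive subject-median change, ties excluded;
no multiple-testing correction by default (a Benjamini–Hochberg option
exists).

## Synthetic cohort (`aperspectra.cohort`)

Each subject sums six independent components at 1024 Hz:

* aperiodic: white noise through a *peak-normalised* time-varying
  difference-of-exponentials filter (decay τ1(t), rise 4 ms).  Peak
  normalisation mimics a fixed peak conductance, so lengthening τ1
  injects more charge and low-frequency power grows as (τ1−τr)² — the
  multiplicative confound under study.  τ1(t) = τ1_base × the Hill fold
  change (EC50 3.7 μM, n 1.6, span 1.6) of the Marsh effect-site
  concentration; baseline rms 15 μV;
* low-frequency excess: the population rate of a 200-unit m = 0.98
  branching network, low-passed at 2.5 Hz (4 μV rms) — the dynamic
  colour below the fit range;
* alpha (10 Hz, 5 μV) and beta (20 Hz, 2.5 μV): 1-Hz-wide filtered noise
  ramping from infusion onset to a plateau at half the latency (an
  optional rise-then-fall beta template exists);
* delta (1.5 Hz, 20 μV): steps on at LOC with a 2-s ramp.  Anesthetic
  delta dominates the post-LOC EEG; smaller values make the detrended
  step physically implausible;
* floor: white noise, 2 μV rms.

Cohorts (default n = 14) draw latencies uniformly from 95–285 s and apply
10% log-normal subject jitter to amplitudes and baseline τ1 (clipped to
the [10, 75] ms fit bounds); 60 s of pre-infusion baseline and 30 s
post-LOC are recorded; weight 70 kg, infusion 1 mg·kg⁻¹·min⁻¹ until LOC.

**What the generator does and does not emulate.**  It reproduces the
statistical structure the analysis assumes — an exactly
Lorentzian-family trend, independent narrowband rhythms with the stated
timing, pharmacokinetic τ1 drift — so passing recovery tests shows the
*pipeline* is unbiased and correctly localises dynamics, not that real
EEG obeys the model.  It omits electrode montages, artifacts,
volume-conduction channel correlations, non-Gaussian rhythm waveforms
and any coupling between components.

## Problem sizes and checks

The test suite runs everything at desk scale chosen once: unitary-spectrum
sweeps use 4-s simulations with heavy trial averaging (the
timescale-identity check uses 1024 draws per τI point, matching the
order of the study's 1000-simulation averages; fewer draws leave the
5 ms fit degenerate); branching rate checks average 40 replicate 40-s
runs at N = 2000; dyad monotonicity uses 16 dyads per condition and the
shuffle null 500 draws; the cohort recovery runs all 14 subjects with a
2-s tracking stride.  End-to-end, the synthetic cohort recovers the mean
baseline τ1 to ~1%, the pooled binned Hill fit to EC50 ≈ 3.7 μM and
n ≈ 1.4, raw delta power rises long before LOC while the first
significant detrended delta segment sits at rescaled time 0.025 — the
numbers printed by `tests/test_acceptance.py` and
`scripts/acceptance.py`.

## Known limitations

* The point-dipole proxy cannot predict absolute EEG amplitudes (no
  morphology, no head model); amplitude-dependent published values
  (single-neuron power distributions, the ρ_max requirement band, the
  absolute dyad correlation 0.18) are out of scope, covered by
  monotonicity and closed-form properties instead.
* τ1 estimates from single 2-s windows are noise-limited once the knee
  (1/2πτ1) approaches the 3 Hz fit edge (τ1 ≳ 40 ms): per-window values
  scatter ±30% and occasionally saturate the [10, 75] ms bounds; group
  and dose–response conclusions rest on pooling, exactly as in cohort
  analyses of real data.
* Single near-critical branching runs and single shuffled dyads are
  avalanche-dominated; every null or conservation statement is about
  ensemble means, estimated by replication.
* The dichotomised Gaussian can require PSD repair for dense high-R_max
  targets; repaired correlations deviate slightly from the nominal
  kernel (a warning is emitted).
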