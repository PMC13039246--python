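# Methods

## The circuit model

`mbcircuit` implements a firing-rate model of the *Drosophila* mushroom body:
M = 2000 Kenyon cells (KCs) receive excitation from 24 olfactory projection
neurons (PNs) and feedback inhibition from the single anterior paired lateral
(APL) neuron. APL inhibition is driven by the combined PN input to all KCs,
independent of KC output (dendro-dendritic feedback), so the response of KC j
to stimulus k is

    y_jk = Relu( Σ_i w_ij x_ik − α Σ_j Σ_i w_ij x_ik − C_θ θ_j )

where `w_ij ≥ 0` are PN→KC synaptic weights (nonzero only on a KC's claws),
`θ_j > 0` are per-KC threshold factors, and α (inhibitory gain) and C_θ
(global threshold scale) are the two tunables. The total input
T_k = Σ_j Σ_i w_ij x_ik is also the APL activity read-out: calcium responses
reflect APL's inputs, whereas α conflates input and output strength.

PN activity derives from olfactory receptor-neuron (ORN) firing rates through
a saturating transfer function with antennal-lobe lateral suppression:

    x_ik = R_max · ORN_ik^1.5 / (ORN_ik^1.5 + s_k^1.5 + σ^1.5),
    s_k  = m · Σ_i ORN_ik / 190

with defaults R_max = 165 Hz, m = 10.63, σ = 12 Hz and exponent 1.5. The
divisor 190 is kept verbatim as a configurable parameter (`norm_const`).

Connectivity is sampled per instance: claw counts per KC are
normal(μ = 6, σ = 1.7), rounded and truncated to [2, 11]; claw PNs are
distinct, uniform without replacement; nonzero weights are
log-normal(μ = −0.0507, σ = 0.3527); thresholds θ_j are normal with
coefficient of variation 0.26, redrawn to be positive. The θ mean is
normalised to 1 so that C_θ alone carries the threshold scale — only the CV
of the threshold distribution is constrained by physiology.

### PN noise

For tuning, 30 noisy trials of each odour's PN vector are generated as
x + N(0, CV(x)·x), clipped at 0. The firing-rate-dependent CV curve is a
package choice (the physiological curve is not published in closed form):
CV(x) = 0.1 + 0.9·exp(−x/30 Hz), i.e. high relative variability at low rates
decaying to ~10% at saturation. The function is injectable everywhere it is
used.

### Weight equalisation and tuning

Two constraints calibrate each instance:

1. **Sparse coding**: on average 10% of KCs respond per odour, rising to 20%
   when inhibition is blocked (α = 0). Because the blocked coding level is
   independent of α, the system is triangular: C_θ is bisected first at
   α = 0 to the 20% target, then α is bisected at fixed C_θ to the 10%
   target (tolerance 0.002 absolute on the coding level, measured on the
   noisy trials).
2. **Equal mean activity**: each KC's input weights are rescaled
   multiplicatively so that all KCs have the same mean response across the
   odour panel.

These constraints are coupled: rescaling weights shifts the coding level,
and retuning C_θ re-spreads the per-KC activities. Alternating
equalise-to-convergence with retuning does not settle — the pair of
operations forms a self-similar treadmill in which C_θ and the weights of
high-threshold KCs grow geometrically while the relative activity spread is
invariant. The package therefore solves the joint fixed point: single damped
equalisation steps (the per-KC scale solving the piecewise-linear
mean-activity equation exactly, applied with damping ½ in log space) are
interleaved with exact empirical retuning of (α, C_θ), with the weight scale
gauge-fixed to geometric mean 1 at every step so that C_θ carries the
overall scale. This converges in 10–40 steps to a maximum per-KC activity
deviation below 2% with both coding targets met; a final two-stage bisection
on the noisy trials sets the released (α, C_θ). KCs with zero excitatory
drive to every panel odour cannot be equalised by rescaling; they are
excluded and reported via a warning.

The standalone `equalise_weights` operation performs the same damped solve
at a fixed operating point and errors (naming the worst KC deviation) if the
tolerance is not met within `max_iter`.

### Plasticity scalings

After tuning, whole-population proportional scalings model adaptation:
w → g_w·w, α → g_α·α, C_θ → g_θ·C_θ. Grid searches cover g_w, g_α ∈ [0, 1.2]
and g_θ ∈ [0.8, 2.0] (step 0.05 by default; probes outside the ranges warn
rather than error). The read-out is the mean total KC activity over the 30
noisy trials of the designated read-out odour, averaged over independently
sampled and tuned instances (20 by default; 5 in the heavier grid checks to
keep runtimes modest). Blocking APL is α = 0. "Plasticity arrows" return the
four read-outs (adapted and base, each ± block) needed to compare adapted
states against the unperturbed circuit.

## Synthetic data

The generators stand in for the study's recordings:

* **ORN panel** (110 odours × 24 classes): i.i.d. gamma-distributed rates
  (mean 30 Hz, shape 0.7) with a 20% zero-response fraction, clipped at 0 —
  the saturating transfer function requires non-negative input, and real
  panels contain inhibitory responses that are clipped the same way. One
  odour is flagged as the read-out ("isoamyl acetate analogue"): the odour
  whose summed ORN drive sits at the 80th percentile, i.e. strong but not
  extreme. The panel deliberately reproduces only marginal rate statistics,
  not receptor identities, odour–odour correlations or dilution series.
* **Paired KC/APL tables** (220 samples × 7 odours): KC responses are a
  per-sample log-normal gain (σ = 0.4) times a fixed 7-odour intensity
  profile (1.5 … 0.05 ΔF/F) plus small jitter (SD 0.05); APL responses are
  the KC responses plus Gaussian noise whose per-sample SD is
  exp(N(μ_n, σ_n)). 220 samples is the default; 222 (the other count used in
  the study) is equally supported.
* **Traces**: square odour pulses on a constant baseline with optional white
  noise. Indicator kinetics, bleaching and motion are out of scope, so
  passing trace tests says nothing about those artefacts.

All generators draw from named sub-streams of a single root seed
(connectivity, weights, thresholds, PN noise, synthetic data, statistics),
so toggling one source of randomness never perturbs another, and every
output is bit-reproducible given the seed.

## Statistics

* **Per-sample correlation / origin slope**: Pearson r of the 7 paired
  responses per sample; the APL-sensitivity slope is the least-squares fit of
  APL = k·KC constrained through the origin (k = Σ kc·apl / Σ kc²),
  reflecting that APL does not respond to odours when KCs are silenced.
  Zero-variance samples yield a flagged NaN, never a silent drop.
* **Noise-model fit**: (μ_n, σ_n) are found by a sign-driven search: per
  iteration, 10 simulated APL datasets are drawn at the current parameters;
  if the simulated correlations' mean is higher (lower) than the real mean,
  μ_n increases (decreases); if their variance is higher (lower), σ_n
  decreases (increases). Steps start at 0.1, halve on every sign flip with a
  floor of 0.02, and the search stops after 5 consecutive flips on both
  parameters plus a 30-step dither phase whose time-average is the returned
  estimate (stochastic-approximation averaging); μ_n is floored at −10
  (fits driven there are flagged degenerate) and σ_n's internal chain may
  wander slightly negative (simulating with max(σ, 0)) so the clipped
  average is unbiased near the boundary. Known limitation: because the fit
  matches the *observed* variance of ~220 correlations, the σ_n estimate
  inherits that statistic's large sampling error and a positive residual
  bias near σ_n = 0 (up to ~0.1 when the noise SD is comparable to the
  signal); exp(μ_n) is recovered to a few per cent.
* **Monte-Carlo two-sample K-S test**: the fitted model is simulated 1000
  times (200 in calibration checks); D_n (sup distance between empirical
  CDFs, computed on raw unbinned values) is evaluated for every
  simulation-vs-simulation and simulation-vs-data pair; each simulation's
  mean D_n against the other simulations forms the null distribution, and
  the p-value is the fraction of those means exceeding the mean
  simulation-vs-data D_n. The pairwise computation stores each dataset's
  ECDF as rank counts (uint8/uint16) at all pooled observations, making the
  1000×1000 pair matrix a few vectorised passes. Under the null (data drawn
  from the fitted model) the p-value is calibrated: the rejection rate at
  0.05 is 0.050 over 200 repeats.
* **NLI**: (nuclear − cytoplasmic)/(nuclear + cytoplasmic) on
  background-subtracted signals; KC hemisphere values average 20 cells.
* **ΔF/F quantification**: ΔF/F = (F − F0)/F0 with F0 the baseline-window
  mean; 0.2 s boxcar smoothing; linear interpolation onto a 0.018 s frame
  grid (endpoints clamped); mean over the 5 s odour window (equivalent to
  the integral for a fixed-length pulse).

## Numerical choices

* Coding-level bisection tolerance 0.002; equalisation tolerance 0.02 (max
  relative deviation); "active" means y > 0 exactly (the model is noiseless
  after the Relu; the epsilon is configurable).
* Tuning computations use float32 drive matrices (≈7 significant digits on
  quantities compared at 10⁻³ tolerance) for memory locality.
* Degenerate inputs error loudly: empty panels, zero baselines, all-zero KC
  vectors, silent PN input during tuning, single-odour correlation requests.
* Grid cells at scale 1 reproduce the base model exactly; activity is
  monotone non-decreasing in g_w and non-increasing in g_α and g_θ cell by
  cell.

## Problem sizes

Unit tests run reduced models (150–400 KCs, 30–40 odours, 5–10 trials); the
scientific checks use the full configuration (20 instances × 2000 KCs, 110
odours × 30 trials), 200×200 Monte-Carlo calibration repeats, and 16
replicate tables per ground-truth point for noise-model recovery. The
acceptance script reproduces the headline numbers at the full sizes in
roughly 20 seconds on one core.

## Known limitations

* With the i.i.d.-gamma synthetic panel, each KC's drive is strongly
  odour-specific (claws sample 6 of 24 channels whose rates are independent
  across odours). Even with per-KC mean activity perfectly equalised, the
  distribution of drive/threshold margins for any single odour retains a
  tail of 2.5–3× the threshold scale. Proportional weight reductions
  therefore silence the read-out odour completely only below ≈0.5 of the
  base excitation (thresholds: above ≈2× base), with activity at a 25%
  weight reduction already down to ~20% of base. A panel with strong shared
  odour-strength structure (as in real receptor data, where divisive
  normalisation makes total PN drive similar across odours) would compress
  those margins and move the silent region to milder scalings; the generator
  exposes its parameters for such experiments but defaults to the simple
  marginal model.
* The noise-model σ_n estimate is variance-limited at 220 samples (see
  above); comparisons should rely on exp(μ_n) where possible.
* The model is a rate model: no spike timing, no conductances, no KC-subtype
  parameters (subtype differences are interpreted through the plasticity
  scalings), no synapse-level plasticity rules.
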