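# Methods

This note documents the models, procedures and numerical choices behind
`fusiform`: a pipeline for deciding which noise-exposed mice show behavioral
evidence of tinnitus from gap-prepulse-inhibition startle testing, and a
conductance-based model of dorsal cochlear nucleus (DCN) fusiform cells used
to generate and analyze the patch-clamp measurements that distinguish
tinnitus-vulnerable from tinnitus-resilient animals.

## Behavioral assay and classification

**Assay.** A silent gap in a narrow-band background sound (centered at 10,
12, 16, 20, 24 or 32 kHz) presented shortly before a loud startle stimulus
suppresses the startle reflex in normal-hearing mice. The *gap startle
ratio* — peak-to-peak (p2p) startle force in gap trials divided by p2p in
paired no-gap trials — quantifies gap detection; ratios near 1 mean the gap
was not detected. Prepulse inhibition (PPI), the converse paradigm, controls
for general startle-circuit changes. A session comprises three rounds, each
with 72 gap/no-gap pairs (12 per frequency) and 30 prepulse/startle-only
pairs (5 per frequency), trials alternating within a pair.

**Trial QC** (`fusiform.behavior.qc`), in order:

1. *Baseline filter*: per mouse × phase × round, the RMS of baseline
   movement preceding the startle (100 ms window by default; the window
   length is configurable since no standard exists) is pooled over all four
   trial types; trials outside mean ± 2.5 SD are eliminated together with
   their paired trial, so elimination counts are always even.
2. *Pair ratios*: p2p(gap)/p2p(no-gap), resp. prepulse/startle-only. Pairs
   with a non-positive denominator are flagged invalid and dropped.
   Maximum absolute amplitude is stored for provenance but ratios use p2p.
3. *Jump filter* (gap ratios only; applying it to PPI is a config switch,
   off by default): within one frequency and round, ratios sorted ascending
   are truncated at the first consecutive increase exceeding 0.5; if more
   than 5 ratios fall after the cut, that frequency is dropped for the
   round. The first offending jump governs — the tail is already gone.
4. *Averaging*: mean of retained ratios within each round, then mean across
   rounds.
5. *Final exclusions*: gap ratios > 0.9 pre-exposure or > 1.1 post-exposure,
   and PPI ratios > 1 in either phase, mark the frequency absent. Absence is
   a recorded outcome (`drop_reason`), never a silent drop.

**Classification** (`fusiform.behavior.classify`). The per-frequency change
Δ = post − pre of the final gap ratio is the classification statistic. The
sign convention is chosen so that the gap-detection deficit of tinnitus mice
(gap ratios *rise* after exposure) is positive, which is the only convention
consistent with a positive threshold. The null distribution of Δ is
estimated from sham-exposed controls by a maximum-likelihood Gaussian fit
(sample mean and SD; moment fitting is bin-free and robust, unlike fitting a
histogram). The decision threshold is μ + 2σ; with the canonical control fit
(μ = −0.02, σ = 0.15) it is 0.28, and by construction Φ(2) ≈ 97.7% of the
fitted null lies below it. A mouse is *tinnitus* if Δ strictly exceeds the
threshold at ≥ 1 usable frequency, *non-tinnitus* if not, and
*unclassifiable* (reported separately) if no frequency survived QC.
`TinnitusClassifier` wraps this as a scikit-learn estimator
(`fit` on control deltas; `predict` on a mouse × frequency matrix).

Incidences between groups are compared with Fisher's exact test by default:
a one-sample binomial test between two observed proportions is
underdetermined, so the conditional-binomial reading (k₁ of n₁ against rate
k₂/n₂) is available as an option and both are reported as percentages
rounded half-up to one decimal. Two Δ distributions can also be compared by
a threshold sweep (fractions above t for t from 1 to −1 in 0.02 steps)
against the diagonal.

## Synthetic behavior generator

The generator (`fusiform.behavior.synth`) defines the study conditions under
which the pipeline is validated:

* Each mouse carries latent per-frequency gap and PPI ratios. Pre-exposure
  gap latents are Normal(0.67, 0.06) — the center of the published
  per-frequency group means — clipped to (0.05, 1.2] so the final exclusion
  rules are occasionally exercised. Phase-to-phase changes are drawn from
  the control Δ distribution Normal(−0.02, 0.15) for control and
  non-tinnitus mice; tinnitus mice additionally receive effects
  {20 kHz: +0.18, 24 kHz: +0.18, 32 kHz: +0.27} (the published tinnitus-group
  Δ magnitudes) at high frequencies only, with rejection sampling enforcing
  that at least one high-frequency latent Δ exceeds μ + 2σ.
* Trial amplitudes are the latent expectation times multiplicative
  log-normal noise with mean exactly 1 and CV 0.15. The source assay does
  not report within-mouse startle variability; CV 0.15 is typical of rodent
  startle amplitudes and is the single free calibration knob.
* Baseline RMS is drawn as the RMS of a finite Gaussian window
  (b·√(χ²₁₀₀/100)); artifact trials (probability 0.02) have a 10× inflated
  baseline SD, which the ±2.5 SD filter catches.
* Waveforms, when materialized, are a damped 40 Hz sinusoid (τ = 30 ms) on a
  Gaussian baseline at 1 kHz sampling, 500 ms per trial with startle onset
  at 250 ms — only p2p and baseline RMS matter downstream, and the
  materialized waveform reproduces the drawn summary values exactly, so
  summary-mode and waveform-mode sessions are statistically identical.
  Monte-Carlo studies use summary mode.

What this emulates — and what it does not: the generator reproduces the
session structure, amplitude statistics, QC-relevant artifacts and the
latent Δ structure of the three cohorts. It does not model startle
habituation across trials, frequency-correlated deficits within mouse, or
hearing-threshold shifts, so passing tests demonstrate correctness of the
analysis rules and calibration of the decision procedure, not robustness to
those real-data features.

Through the full pipeline the measured Δ acquires a small measurement
variance on top of the latent σ = 0.15 (≈ 0.036 at the default noise level,
giving fitted σ ≈ 0.154), so recovered thresholds average ≈ 0.287 rather
than exactly 0.28 — the expected behavior of the paradigm, not an estimator
bias; noise-free runs recover latents exactly.

## Fusiform-cell model

`fusiform.ephys.model` integrates a single compartment (units mV, ms, pA,
nS, pF):

C_m dV/dt = −[g_leak(V−E_leak) + g_kleak(V−E_K) + G_kcnq·m·(V−E_K)
            + G_hcn·h·(V−E_h) + I_spike] + I_inj + I_drive + I_noise

with first-order Boltzmann gates: m∞(V) = 1/(1+exp(−(V−V½)/k)) for the
KCNQ2/3 (M-type, E_K = −85.5 mV) conductance and a mirrored sigmoid for HCN
(E_h = −30 mV, activating with hyperpolarization). KCNQ slope and kinetics
are not published for this preparation; defaults k = 6 mV, τ = 130 ms give
the slow deactivation visible in a 1-s tail step. HCN defaults
V½ = −90 mV, slope 8 mV, τ = 400 ms. Passive scaffold: C_m = 65 pF,
g_leak = 10 nS (onset input resistance ≈ 98 MΩ at rest).

**Spikes.** An exponential integrate-and-fire term (soft threshold −50 mV,
slope 2 mV) launches the upstroke; at the +8 mV cutoff the waveform is
completed by a 0.5 ms linear repolarization to −65 mV and a 1.5 ms
refractory hold, yielding spikes with a defined peak, downstroke and fast
AHP so the spike-parameter extractor has a genuine waveform to measure. A
constant pacemaker drive (persistent-Na-like, hence removed by TTX together
with the spike mechanism) sustains spontaneous firing; KCNQ's slow gate
provides spike-frequency adaptation that linearizes the rate-vs-drive
relation. Full Na/K channel kinetics are deliberately out of scope: the
measurements reproduced here depend on spike timing and coarse shape, not
on sodium-channel biophysics.

**Drugs** are parameter switches: XE991 → G_kcnq = 0; ZD7288 → G_hcn = 0;
TTX → spikes and drive off; retigabine → KCNQ V½ shifted −10 mV
(configurable).

**Integration.** Fixed-step exponential-Euler for the gates and forward
Euler for V, step ≤ 0.025 ms (JIT-compiled when numba is importable, with
an identical pure-Python fallback). Accuracy contract: halving the step
changes reported features by < 0.5% (tested). Voltage-clamp mode evaluates
the gates along the command with the exact exponential update and reports
total plus channel-resolved currents; series-resistance and capacitive
artifacts are not modeled (experimentally compensated). The optional
Ornstein–Uhlenbeck current noise is off by default so analyses are
deterministic.

**Presets** (`fusiform.ephys.presets`) are calibrated per experimental
group; the calibration inverse problems (`fusiform.ephys.calibrate`) are:
leak reversal in closed form from the target RMP; background K leak in
closed form for hyperpolarized-RMP groups; HCN conductance by bisection on
the simulated ZD7288-sensitive sag (sag is strictly increasing in G_hcn);
pacemaker drive by bisection on the simulated 10-s spontaneous rate.
Within this model the resting HCN contribution is small, so group RMP
differences are carried by the background K leak rather than by HCN; the
ZD7288 effect on RMP is therefore reproduced in direction but not in
magnitude. The sham sag targets differ between published step conventions
(15.5% vs 27.2%); presets are calibrated to the 15.5/14.1/8.3% family and
the two are not reconciled. The published tail-current amplitude (73.8 pA)
and ramp-derived G_max (39.1 nS) are mutually inconsistent under a single
Boltzmann conductance, so the tail check uses a dedicated variant
(`control_tail`) whose G_kcnq is scaled to the tail amplitude (the tail is
exactly proportional to G_kcnq, so one simulation calibrates it); the
noise-vs-sham tail *direction* holds for the G–V presets as well.

## Feature extraction

`fusiform.ephys.features` implements the measurement battery; all
extractors are deterministic given a trace.

* *Drug subtraction*: pointwise pre − post on identical protocols; in
  voltage clamp this isolates the blocked channel exactly.
* *Tail current*: step −30 → −50 mV; amplitude = median over a post-settle
  window (20–60 ms after onset) minus the mean over the final 100 ms.
  Window lengths are unpublished, hence configurable and logged; the
  peak-minus-steady alternative is computed as `tail_current_peak`.
* *Ramp → G–V*: G = I/(V − V_r) with V_r = −85.5 mV, points within 5 mV of
  V_r or outside [−80, 0] mV dropped and counted. Because a 10 mV/s ramp on
  a τ = 130 ms gate lags the quasi-static curve by τ·dV/dt ≈ 1.3 mV, the
  converter offers exact kinetics compensation: from dm/dt = (m∞ − m)/τ it
  follows that G_qs = G + τ·dG/dt pointwise, which removes the lag entirely
  (first-order axis shifts leave a skew bias of ~0.1 mV). Used when τ is
  known, as in simulator-based validation.
* *Boltzmann fit*: least squares with multi-start initialization over a
  V½ × k grid, bounds G_max > 0, k > 0; flat curves are flagged
  unconverged rather than silently fitted; parameter standard errors come
  from the fit covariance.
* *Sag*: from the −75 mV bias, V_peak is the largest deflection during the
  −550 pA step and V_ss the mean deflection over the final 100 ms (window
  choice documented, not published); sag ratio = (V_peak − V_ss)/V_peak ×
  100, invariant to vertical offsets. ZD-sensitive sag is the pre/post-ZD
  difference.
* *Input resistance*: −60…+60 pA family; per step, onset voltage is the
  mean over 100 ms from the response peak and steady-state over the final
  250 ms; R_in is the least-squares I–V slope (MΩ). The flat 0-pA sweep is
  handled by a mid-trace window.
* *RMP*: mean of a gap-free trace under TTX after a 500 ms settle; detecting
  any spike raises an error (precondition violated).
* *Spikes*: upward crossings of −20 mV with 2 ms refractory merging (the
  detector is not specified in the source assay; these defaults are logged).
  Averaged spikes align 20 consecutive spikes at the post-spike negative
  peak. Threshold is the first upstroke voltage where dV/dt > 10 V/s, with
  dV/dt from central differences after zero-phase 1 kHz low-pass smoothing
  — the 10 V/s rule is noise-sensitive, so the smoothing is part of the
  definition here. Amplitude = peak − threshold; fAHP = threshold − trough;
  half-height width at threshold + amplitude/2.

## Statistics

`fusiform.stats` implements the analysis decision tree. Normality is gated
by a Lilliefors test whose null is generated by Monte Carlo (parameters
re-estimated per replicate; add-one p-value), which is exact for any n
instead of relying on tabulated critical values; a precomputed null can be
shared across same-size samples. The gate is applied per group (pooled
residual gating is a config option; the source procedure does not say
which). Branches: t-test / one-way ANOVA with Tukey HSD post-hoc when all
groups pass at α, Wilcoxon rank-sum / Kruskal–Wallis otherwise; all tests
two-sided. "Tukey's least significant test" is read as Tukey's HSD. The
type-I error of the gate is calibrated to 0.05 ± 0.02 (tested at
n ∈ {10, 20, 50}, and at the cohort size n = 21 in the acceptance run); its power against the uniform at n = 100 is ≈ 50–60%
(matching the statsmodels reference implementation), so tests assert high
power only against skewed alternatives.

## Problem sizes and determinism

Validation studies use the sizes of the emulated experiments: control
cohorts of 21 mice × 6 frequencies (126 deltas), 200-replicate Monte-Carlo
studies for threshold recovery and gate calibration, 10-s gap-free traces
for rates, and the published clamp protocols for everything else. Every
stochastic step takes an explicit seed (numpy `SeedSequence` spawning);
identical configuration and seed give byte-identical outputs.

## Known limitations

* The behavioral generator omits habituation, within-mouse frequency
  correlations and hearing-threshold dynamics (above).
* The cell model is a single compartment without synaptic conductances
  (recordings block synaptic transmission) or temperature dependence; the
  4-day noise preset is silent at rest rather than slow-firing, so
  noise-exposure effects on rate are validated directionally.
* Auditory brainstem responses, in-vivo pharmacokinetics and slice
  procedures are out of scope; drug effects exist only as parameter
  switches.
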