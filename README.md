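# fusiform

Quantitative workflow for noise-induced tinnitus studies in mice: decide,
from gap-prepulse-inhibition startle testing, which noise-exposed animals
show behavioral evidence of tinnitus, and extract the dorsal cochlear
nucleus (DCN) fusiform-cell biophysics — KCNQ2/3 (M-current) and HCN
conductances, input resistance, resting potential, spike parameters — that
distinguish tinnitus-vulnerable from tinnitus-resilient animals. Because no
raw data are deposited for this kind of experiment, the package includes
first-class synthetic generators for both the behavioral sessions and the
patch-clamp traces, so every analysis rule is testable end to end.

Intended users: auditory/behavioral neuroscientists running gap-detection
tinnitus screens, and cellular electrophysiologists analyzing fusiform-cell
recordings or modeling their excitability.

## The statistics and models at the core

**Behavioral screen.** Gap detection is quantified by the gap startle ratio
r = p2p(gap)/p2p(no-gap) per background frequency (10–32 kHz); sessions are
three rounds of 72 gap/no-gap + 30 prepulse/startle-only pairs. After trial
QC (baseline-RMS ±2.5 SD filter with paired removal; sorted-ratio jump
filter; per-round then across-round averaging; final exclusion rules), the
classification statistic is Δ = r_post − r_pre per frequency. The control
null Δ ~ N(μ, σ²) is fitted by maximum likelihood on sham-exposed mice and
a mouse is called *tinnitus* when Δ > μ + 2σ at one or more frequencies —
with the canonical control fit (μ = −0.02, σ = 0.15) the threshold is 0.28.
`TinnitusClassifier` exposes this as a scikit-learn estimator; incidences
are compared by exact tests, distributions by a threshold sweep against the
diagonal.

**Cell model.** A single-compartment conductance model,

C dV/dt = −[g_L(V−E_L) + g_KL(V−E_K) + G_KCNQ·m·(V−E_K) + G_HCN·h·(V−E_h)]
          − I_spike + I_inj,

with Boltzmann-gated KCNQ (m∞ = 1/(1+e^{−(V−V½)/k}), E_K = −85.5 mV, slow
τ = 130 ms) and HCN (hyperpolarization-activated, E_h = −30 mV), an
exponential integrate-and-fire spike mechanism with a shaped reset, and
drug switches (XE991, ZD7288, TTX, retigabine). Calibrated presets
reproduce the published group biophysics (sham: V½ = −28.3 mV,
G_max = 39.1 nS, ZD-sensitive sag 15.5%, RMP −64.2 mV, ~14 Hz spontaneous;
4-day noise-exposed: V½ = −20.3 mV, RMP −67.7 mV; resilient: sag 8.3%,
RMP −67.5 mV). Feature extractors recover tail currents, Boltzmann G–V
parameters (with exact gating-lag compensation for ramp protocols), sag
ratio (V_peak−V_ss)/V_peak·100%, onset/steady-state R_in, RMP, firing rate
and averaged-spike parameters. A Monte-Carlo Lilliefors test gates all
group comparisons between parametric and rank-based branches.

See `docs/methods.md` for assumptions, parameter tables and limitations.

## Worked example

Simulate a full study (21 sham + 21 noise-exposed mice), run QC, fit the
control null and classify:

```python
from fusiform.behavior import (CohortConfig, generate_cohort,
                               StartleRatioPipeline, TinnitusClassifier,
                               delta_ratios, delta_matrix)

cfg = CohortConfig(n_control=21, n_tinnitus=11, n_non_tinnitus=10, seed=42)
trials, profiles = generate_cohort(cfg)          # 51,408 trials
deltas = delta_ratios(StartleRatioPipeline().transform(trials))

controls = delta_matrix(deltas).filter(like="control", axis=0)
clf = TinnitusClassifier().fit(controls.to_numpy())
labels = clf.classify_table(deltas)

print(f"control null: mu={clf.mu_:.3f} sigma={clf.sigma_:.3f} "
      f"threshold={clf.threshold_:.3f} (n={clf.n_} deltas, "
      f"Lilliefors p={clf.lilliefors_p_:.2f})")
exposed = labels[~labels.mouse_id.str.startswith("control")]
k = (exposed.label == "tinnitus").sum()
print(f"tinnitus incidence among noise-exposed: {k}/{len(exposed)} "
      f"= {100 * k / len(exposed):.1f}%")
```

This prints (seed 42):

```
control null: mu=-0.018 sigma=0.146 threshold=0.273 (n=126 deltas, Lilliefors p=0.87)
tinnitus incidence among noise-exposed: 13/21 = 61.9%
```

The fitted null recovers the generating parameters (−0.02, 0.15) within
sampling error, the threshold lands near 0.28, and the 21 noise-exposed
mice split into tinnitus/non-tinnitus with the occasional false positive a
2.3%-per-frequency tail predicts. On the ephys side:

```python
from fusiform.ephys import preset_states, protocol_library, simulate, DrugState
from fusiform.ephys.features import subtract_traces, ramp_to_gv, fit_boltzmann

cell = preset_states()["noise_4d"]
lib = protocol_library()
pre, post = (simulate(cell, lib["gv_ramp"], d)
             for d in (None, DrugState(xe991=True)))
fit = fit_boltzmann(ramp_to_gv(subtract_traces(pre, post), tau_lag_ms=cell.tau))
print(f"KCNQ G-V (4-day noise-exposed): G_max={fit.g_max:.1f} nS, "
      f"V_half={fit.v_half:.1f} mV, k={fit.k:.1f} mV")
```

```
KCNQ G-V (4-day noise-exposed): G_max=37.7 nS, V_half=-20.3 mV, k=6.0 mV
```

i.e. the XE991-subtracted 10 mV/s ramp inverts the model's conductance
exactly, recovering the depolarized half-activation that characterizes
noise-exposed cells.

A `fusiform` command-line group wraps the same steps
(`simulate-behavior`, `behavior-qc`, `classify`, `simulate-ephys`,
`ephys-features`, `stats-compare`); run `fusiform --help`.

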