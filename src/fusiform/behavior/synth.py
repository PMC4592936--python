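"""Synthetic gap/PPI startle sessions.

Generates seeded, statistically realistic acoustic-startle test sessions for
three cohorts of mice (sham-exposed controls, noise-exposed mice that develop
tinnitus, and noise-exposed resilient mice), so the behavioral QC and
classification pipeline can be exercised end to end without animal data.

The session layout mirrors the standard gap-detection / prepulse-inhibition
(PPI) paradigm: three rounds of testing, each containing 72 gap/no-gap trial
pairs (12 per background frequency, 6 frequencies) and 30 prepulse/startle-only
pairs (5 per frequency), trials alternating within a pair.  Startle responses
are summarized by the peak-to-peak (p2p) force amplitude of the startle
waveform and the RMS of pre-stimulus baseline movement — the only two
quantities the downstream QC consumes — so sessions can be generated either as
summary tables (fast, used for Monte-Carlo work) or with fully materialized
force waveforms.

Cohort structure: each mouse carries latent per-frequency gap and PPI ratios.
Control and non-tinnitus mice change between phases by a draw from the control
delta distribution Normal(mu, sigma) (defaults -0.02, 0.15); tinnitus mice
additionally receive a positive post-exposure shift of their gap ratio at the
high frequencies (20-32 kHz) only, and are guaranteed to exceed the mu + 2*sigma
threshold at at least one high frequency.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FREQUENCIES_KHZ = (10, 12, 16, 20, 24, 32)
HIGH_FREQUENCIES_KHZ = (20, 24, 32)
GAP_PAIRS_PER_FREQ = 12
PPI_PAIRS_PER_FREQ = 5
N_ROUNDS = 3

TRIAL_TYPES = ("gap", "no_gap", "prepulse", "startle_only")
#: trial types whose p2p is scaled by the latent ratio (numerator of each pair)
_MODULATED = {"gap": "gap", "prepulse": "ppi"}
#: reference trial of each pair (denominator)
_REFERENCE = {"no_gap": "gap", "startle_only": "ppi"}

SAMPLE_RATE_KHZ = 1.0          # 1 kHz sampling; only relative timing matters
TRIAL_LENGTH_MS = 500.0
STARTLE_ONSET_MS = 250.0
BASELINE_WINDOW_MS = 100.0     # window immediately preceding startle onset


class ConfigurationError(ValueError):
    """Raised for invalid generator configuration (e.g. unknown frequency)."""


@dataclass(frozen=True)
class TrialSpec:
    """Metadata identifying a single startle trial."""

    trial_type: str
    frequency_khz: int
    phase: str                  # 'pre' or 'post' exposure
    round_index: int            # 1..3
    pair_index: int = 0

    def __post_init__(self):
        if self.trial_type not in TRIAL_TYPES:
            raise ConfigurationError(f"unknown trial type {self.trial_type!r}")
        if self.frequency_khz not in FREQUENCIES_KHZ:
            raise ConfigurationError(
                f"unknown background frequency {self.frequency_khz} kHz; "
                f"expected one of {FREQUENCIES_KHZ}")
        if self.phase not in ("pre", "post"):
            raise ConfigurationError(f"phase must be 'pre' or 'post', got {self.phase!r}")
        if not 1 <= self.round_index <= N_ROUNDS:
            raise ConfigurationError(f"round_index must be 1..{N_ROUNDS}")

    @property
    def measure(self) -> str:
        """'gap' for gap/no-gap trials, 'ppi' for prepulse/startle-only."""
        return _MODULATED.get(self.trial_type) or _REFERENCE[self.trial_type]


@dataclass
class StartleTrial:
    """One force waveform with its spec.

    ``force_au`` holds the downward pressing force (arbitrary units) sampled at
    ``sample_rate_khz``; ``baseline_window`` is the index range (start, stop)
    preceding startle onset used for baseline-RMS QC.
    """

    spec: TrialSpec
    time_ms: np.ndarray
    force_au: np.ndarray
    baseline_window: tuple[int, int]
    sample_rate_khz: float = SAMPLE_RATE_KHZ
    startle_onset_index: int = 0

    def __post_init__(self):
        if not np.all(np.isfinite(self.force_au)):
            raise ValueError("waveform contains non-finite samples")
        b0, b1 = self.baseline_window
        if b1 <= b0:
            raise ValueError("baseline window is empty")
        if b1 > self.startle_onset_index:
            raise ValueError("baseline window must precede startle onset")


@dataclass
class MouseProfile:
    """Latent behavioral parameters for one simulated mouse."""

    mouse_id: str
    cohort: str                                   # control | tinnitus | non_tinnitus
    latent_gap_ratio: dict                        # (frequency_khz, phase) -> ratio
    latent_ppi_ratio: dict
    startle_scale: float = 100.0                  # expected no-gap p2p, AU
    trial_noise_sd: float = 0.15                  # CV of multiplicative log-normal noise
    baseline_artifact_rate: float = 0.02
    baseline_rms_scale: float = 2.0               # typical baseline movement RMS, AU

    def ratio_for(self, spec: TrialSpec) -> float:
        table = self.latent_gap_ratio if spec.measure == "gap" else self.latent_ppi_ratio
        key = (spec.frequency_khz, spec.phase)
        if key not in table:
            raise ConfigurationError(
                f"profile {self.mouse_id} has no latent ratio for {key}")
        return table[key]


@dataclass
class CohortConfig:
    """Study-design parameters for a synthetic cohort dataset.

    ``control_delta_mu`` / ``control_delta_sigma`` parameterize the Gaussian
    distribution of phase-to-phase changes in gap startle ratio for mice
    without tinnitus. ``tinnitus_effect`` is the additional post-exposure gap
    ratio increase of tinnitus mice per high frequency.
    """

    n_control: int = 21
    n_tinnitus: int = 11
    n_non_tinnitus: int = 10
    control_delta_mu: float = -0.02
    control_delta_sigma: float = 0.15
    tinnitus_effect: dict = field(
        default_factory=lambda: {20: 0.18, 24: 0.18, 32: 0.27})
    gap_pre_mean: float = 0.67
    gap_pre_sd: float = 0.06
    ppi_pre_mean: float = 0.60
    ppi_pre_sd: float = 0.06
    startle_scale: float = 100.0
    trial_noise_sd: float = 0.15
    baseline_artifact_rate: float = 0.02
    baseline_rms_scale: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.control_delta_sigma <= 0:
            raise ConfigurationError("control_delta_sigma must be > 0")
        for n in (self.n_control, self.n_tinnitus, self.n_non_tinnitus):
            if n < 0:
                raise ConfigurationError("cohort sizes must be >= 0")
        for f in self.tinnitus_effect:
            if f not in HIGH_FREQUENCIES_KHZ:
                raise ConfigurationError(
                    f"tinnitus effect specified at {f} kHz; tinnitus deficits "
                    f"are restricted to {HIGH_FREQUENCIES_KHZ}")


# ---------------------------------------------------------------------------
# waveform construction
# ---------------------------------------------------------------------------

def _startle_shape(t_ms: np.ndarray, freq_hz: float = 40.0,
                   decay_ms: float = 30.0) -> np.ndarray:
    """Damped-sinusoid startle transient, unit-free template."""
    return np.exp(-t_ms / decay_ms) * np.sin(2 * np.pi * freq_hz * t_ms / 1000.0)


def materialize_waveform(spec: TrialSpec, p2p_au: float, baseline_rms_au: float,
                         rng: np.random.Generator) -> StartleTrial:
    """Build a force waveform with exactly the requested p2p and baseline RMS.

    The startle response is a damped sinusoid starting at startle onset and
    scaled so its peak-to-peak amplitude equals ``p2p_au``; samples before
    onset are Gaussian baseline movement rescaled to ``baseline_rms_au``.
    """
    n = int(round(TRIAL_LENGTH_MS * SAMPLE_RATE_KHZ))
    t = np.arange(n) / SAMPLE_RATE_KHZ
    onset = int(round(STARTLE_ONSET_MS * SAMPLE_RATE_KHZ))
    force = np.zeros(n)

    noise = rng.standard_normal(onset)
    b1 = onset
    b0 = onset - int(round(BASELINE_WINDOW_MS * SAMPLE_RATE_KHZ))
    rms = np.sqrt(np.mean(noise[b0:b1] ** 2))
    if rms > 0 and baseline_rms_au > 0:
        force[:onset] = noise * (baseline_rms_au / rms)

    shape = _startle_shape(t[onset:] - t[onset])
    span = shape.max() - shape.min()
    force[onset:] = shape * (p2p_au / span)
    return StartleTrial(spec=spec, time_ms=t, force_au=force,
                        baseline_window=(b0, b1), startle_onset_index=onset)


def _draw_amplitude(expected_p2p: float, noise_sd: float,
                    rng: np.random.Generator) -> float:
    return expected_p2p * _lognormal_factors(noise_sd, 1, rng)[0]


def _lognormal_factors(cv: float, size, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative noise factors with mean exactly 1 and CV ``cv``."""
    if cv <= 0:
        return np.ones(size)
    s2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-s2 / 2, sigma=np.sqrt(s2), size=size)


def _draw_baseline_rms(scale: float, artifact: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
    """Baseline RMS as observed over a finite window of Gaussian movement.

    RMS of k Gaussian samples with SD b is b*sqrt(chi2_k / k); artifact trials
    have their baseline SD inflated 10-fold.
    """
    k = int(round(BASELINE_WINDOW_MS * SAMPLE_RATE_KHZ))
    sd = np.where(artifact, 10.0 * scale, scale)
    return sd * np.sqrt(rng.chisquare(k, size=len(sd)) / k)


def generate_startle_waveform(spec: TrialSpec, profile: MouseProfile,
                              rng_seed) -> StartleTrial:
    """Generate one trial: draw a noisy amplitude and materialize the waveform.

    The expected p2p amplitude is ``startle_scale`` for reference trials
    (no-gap / startle-only) and ``startle_scale * latent_ratio`` for gap and
    prepulse trials, with multiplicative log-normal trial noise (mean 1).
    """
    rng = np.random.default_rng(rng_seed)
    ratio = profile.ratio_for(spec) if spec.trial_type in _MODULATED else 1.0
    p2p = _draw_amplitude(profile.startle_scale * ratio, profile.trial_noise_sd, rng)
    artifact = rng.random() < profile.baseline_artifact_rate
    rms = _draw_baseline_rms(profile.baseline_rms_scale,
                             np.array([artifact]), rng)[0]
    return materialize_waveform(spec, p2p, rms, rng)


# ---------------------------------------------------------------------------
# session / cohort generation (summary-table form)
# ---------------------------------------------------------------------------

def generate_session(profile: MouseProfile, phase: str, seed) -> pd.DataFrame:
    """Generate a full 3-round session for one mouse and phase.

    Returns a tidy table with one row per trial, columns::

        mouse_id, cohort, phase, round_index, measure, frequency_khz,
        pair_index, trial_type, p2p_au, baseline_rms_au, is_artifact

    Each round holds exactly 72 gap/no-gap pairs (12 per frequency) and 30
    prepulse/startle-only pairs (5 per frequency); the two trials of a pair
    are adjacent rows (alternating presentation).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for rnd in range(1, N_ROUNDS + 1):
        for freq in FREQUENCIES_KHZ:
            for measure, n_pairs, mod, ref in (
                    ("gap", GAP_PAIRS_PER_FREQ, "gap", "no_gap"),
                    ("ppi", PPI_PAIRS_PER_FREQ, "prepulse", "startle_only")):
                table = (profile.latent_gap_ratio if measure == "gap"
                         else profile.latent_ppi_ratio)
                ratio = table[(freq, phase)]
                for pair in range(n_pairs):
                    for ttype, r in ((mod, ratio), (ref, 1.0)):
                        rows.append((profile.mouse_id, profile.cohort, phase,
                                     rnd, measure, freq, pair, ttype,
                                     profile.startle_scale * r))
    df = pd.DataFrame(rows, columns=[
        "mouse_id", "cohort", "phase", "round_index", "measure",
        "frequency_khz", "pair_index", "trial_type", "expected_p2p"])
    n = len(df)
    df["p2p_au"] = df["expected_p2p"].to_numpy() * _lognormal_factors(
        profile.trial_noise_sd, n, rng)
    df["is_artifact"] = rng.random(n) < profile.baseline_artifact_rate
    df["baseline_rms_au"] = _draw_baseline_rms(
        profile.baseline_rms_scale, df["is_artifact"].to_numpy(), rng)
    return df.drop(columns="expected_p2p")


def _clip_ratio(x):
    return float(np.clip(x, 0.05, 1.2))


def generate_profiles(config: CohortConfig, rng: np.random.Generator
                      ) -> list[MouseProfile]:
    """Draw latent per-mouse ratio tables for all three cohorts."""
    profiles = []
    threshold = config.control_delta_mu + 2 * config.control_delta_sigma
    cohorts = (("control", config.n_control),
               ("tinnitus", config.n_tinnitus),
               ("non_tinnitus", config.n_non_tinnitus))
    for cohort, n in cohorts:
        for i in range(n):
            gap, ppi = {}, {}
            for freq in FREQUENCIES_KHZ:
                pre = rng.normal(config.gap_pre_mean, config.gap_pre_sd)
                gap[(freq, "pre")] = _clip_ratio(pre)
                ppi_pre = rng.normal(config.ppi_pre_mean, config.ppi_pre_sd)
                ppi[(freq, "pre")] = _clip_ratio(ppi_pre)
                ppi[(freq, "post")] = _clip_ratio(
                    ppi_pre + rng.normal(config.control_delta_mu,
                                         config.control_delta_sigma))
            for _ in range(1000):
                deltas = {f: rng.normal(config.control_delta_mu,
                                        config.control_delta_sigma)
                          for f in FREQUENCIES_KHZ}
                if cohort == "tinnitus":
                    for f, eff in config.tinnitus_effect.items():
                        deltas[f] += eff
                    if not any(deltas[f] > threshold
                               for f in config.tinnitus_effect):
                        continue       # tinnitus mice must exceed threshold
                break
            for freq in FREQUENCIES_KHZ:
                gap[(freq, "post")] = _clip_ratio(gap[(freq, "pre")] + deltas[freq])
            profiles.append(MouseProfile(
                mouse_id=f"{cohort}_{i:03d}", cohort=cohort,
                latent_gap_ratio=gap, latent_ppi_ratio=ppi,
                startle_scale=config.startle_scale,
                trial_noise_sd=config.trial_noise_sd,
                baseline_artifact_rate=config.baseline_artifact_rate,
                baseline_rms_scale=config.baseline_rms_scale))
    return profiles


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, list[MouseProfile]]:
    """Generate pre- and post-exposure sessions for every mouse in the config.

    Deterministic given ``config.seed``. Returns the concatenated trial table
    and the latent profiles (ground truth for end-to-end tests).
    """
    root = np.random.SeedSequence(config.seed)
    profile_rng = np.random.default_rng(root.spawn(1)[0])
    profiles = generate_profiles(config, profile_rng)
    frames = []
    session_seeds = root.spawn(len(profiles) * 2)
    k = 0
    for profile in profiles:
        for phase in ("pre", "post"):
            frames.append(generate_session(profile, phase, session_seeds[k]))
            k += 1
    trials = pd.concat(frames, ignore_index=True)
    return trials, profiles


def latent_deltas(profiles: list[MouseProfile]) -> pd.DataFrame:
    """Ground-truth latent gap-ratio changes (post - pre) per mouse x frequency.

    This is what the behavioral pipeline estimates; noise-free sessions
    reproduce it exactly, so classification against the true threshold
    agrees with labels derived from this table.
    """
    rows = [(p.mouse_id, f,
             p.latent_gap_ratio[(f, "post")] - p.latent_gap_ratio[(f, "pre")])
            for p in profiles for f in FREQUENCIES_KHZ]
    return pd.DataFrame(rows, columns=["mouse_id", "frequency_khz", "delta"])
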