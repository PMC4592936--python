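"""Extraction of biophysical features from clamp traces.

Implements every trace-derived quantity of the recording battery:
drug-subtracted currents, KCNQ tail-current amplitude, ramp-derived G-V
curves with Boltzmann fits, HCN sag ratio (with the ZD7288-sensitive
component), onset and steady-state input resistance, resting membrane
potential, spontaneous spike detection/rate, and averaged-spike parameters.
All extractors are deterministic given a trace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import butter, filtfilt
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .model import Trace

V_REV_K = -85.5     # K+ reversal used for G = I/(V - V_r), mV


class FeatureError(ValueError):
    pass


def _require_same_grid(a: Trace, b: Trace):
    if a.mode != b.mode or a.dt_ms != b.dt_ms or a.signal.size != b.signal.size:
        raise FeatureError("traces differ in mode, sampling or length")
    if not np.allclose(a.command, b.command):
        raise FeatureError("traces were recorded under different protocols")


def subtract_traces(pre_drug: Trace, post_drug: Trace) -> Trace:
    """Pointwise pre - post; isolates the drug-sensitive current component."""
    _require_same_grid(pre_drug, post_drug)
    return Trace(time_ms=pre_drug.time_ms,
                 signal=pre_drug.signal - post_drug.signal,
                 command=pre_drug.command, mode=pre_drug.mode,
                 dt_ms=pre_drug.dt_ms,
                 meta={"derived": "pre_minus_post"})


# ---------------------------------------------------------------------------
# KCNQ tail current
# ---------------------------------------------------------------------------

def _step_onset_index(command: np.ndarray) -> int:
    jumps = np.nonzero(np.abs(np.diff(command)) > 1e-9)[0]
    if jumps.size == 0:
        raise FeatureError("no voltage step found in command")
    return int(jumps[0] + 1)


def tail_current_amplitude(diff: Trace, settle_ms: tuple = (20.0, 60.0),
                           steady_ms: float = 100.0) -> float:
    """KCNQ tail amplitude (pA) from the deactivation-step difference trace.

    Amplitude = median current over the post-settle window after step onset
    minus the steady current over the final ``steady_ms`` of the step. The
    alternative peak-minus-baseline reading is available via
    :func:`tail_current_peak`.
    """
    onset = _step_onset_index(diff.command)
    dt = diff.dt_ms
    i0 = onset + int(round(settle_ms[0] / dt))
    i1 = onset + int(round(settle_ms[1] / dt))
    if i1 > diff.signal.size:
        raise FeatureError("deactivation segment shorter than settle window")
    instantaneous = float(np.median(diff.signal[i0:i1]))
    n_steady = int(round(steady_ms / dt))
    steady = float(np.mean(diff.signal[-n_steady:]))
    return instantaneous - steady


def tail_current_peak(diff: Trace, steady_ms: float = 100.0) -> float:
    """Peak-minus-steady reading of the tail (no settle window)."""
    onset = _step_onset_index(diff.command)
    n_steady = int(round(steady_ms / diff.dt_ms))
    steady = float(np.mean(diff.signal[-n_steady:]))
    return float(np.max(diff.signal[onset:]) - steady)


# ---------------------------------------------------------------------------
# ramp -> G-V -> Boltzmann
# ---------------------------------------------------------------------------

def ramp_to_gv(diff: Trace, v_rev: float = V_REV_K, guard_mv: float = 5.0,
               v_span: tuple = (-80.0, 0.0), tau_lag_ms: float | None = None
               ) -> pd.DataFrame:
    """Convert a ramp-evoked difference current to a conductance-voltage curve.

    G(V) = I/(V - V_r) in nS for I in pA, V in mV. Points within ``guard_mv``
    of the reversal potential or outside ``v_span`` are dropped (the count is
    recorded in ``attrs['n_dropped']``).

    ``tau_lag_ms`` compensates the gating lag of a first-order channel with
    known time constant tau: since dm/dt = (m_inf - m)/tau holds identically,
    the quasi-static conductance is recovered exactly as
    G_qs = G + tau * dG/dt, with dG/dt taken numerically along the ramp.
    Without it, a 10 mV/s ramp on a tau = 130 ms channel reads ~1.3 mV
    depolarized of the true activation curve.
    """
    v = diff.command.astype(float)
    i = diff.signal.astype(float)
    dvdt = np.gradient(v, diff.dt_ms)
    ramp = np.abs(dvdt) > 1e-6
    if not ramp.any():
        raise FeatureError("no ramp segment found in command")
    v, i = v[ramp], i[ramp]
    with np.errstate(divide="ignore", invalid="ignore"):
        g = i / (v - v_rev)
    if tau_lag_ms is not None:
        g = g + tau_lag_ms * np.gradient(g, diff.dt_ms)
    keep = (np.abs(v - v_rev) >= guard_mv) & (v >= v_span[0]) & (v <= v_span[1])
    keep &= np.isfinite(g)
    out = pd.DataFrame({"v_mv": v[keep], "g_ns": g[keep]})
    out.attrs["n_dropped"] = int(np.count_nonzero(~keep))
    return out


def _boltzmann(v, g_max, v_half, k):
    return g_max / (1.0 + np.exp(-(v - v_half) / k))


@dataclass
class BoltzmannFit:
    g_max: float
    v_half: float
    k: float
    residual_norm: float
    converged: bool
    stderr: tuple = (np.nan, np.nan, np.nan)

    def __post_init__(self):
        if self.converged and (self.g_max <= 0 or self.k <= 0):
            raise ValueError("converged fit must have g_max > 0 and k > 0")


class BoltzmannModel(RegressorMixin, BaseEstimator):
    """Least-squares Boltzmann fit G(V) = G_max / (1 + exp(-(V - V_half)/k)).

    Multi-start initialization over a V_half/k grid; fitted attributes are
    ``g_max_``, ``v_half_``, ``k_``, ``converged_``, ``residual_norm_`` and
    ``stderr_`` (from the covariance of the best fit). Degenerate (flat)
    curves are flagged unconverged rather than silently fitted.
    """

    def __init__(self, v_half_starts=(-60, -45, -30, -15, 0),
                 k_starts=(4.0, 8.0), min_points: int = 8):
        self.v_half_starts = v_half_starts
        self.k_starts = k_starts
        self.min_points = min_points

    def fit(self, X, y):
        v = np.asarray(X, dtype=float).ravel()
        g = np.asarray(y, dtype=float).ravel()
        ok = np.isfinite(v) & np.isfinite(g)
        v, g = v[ok], g[ok]
        if v.size < self.min_points:
            raise FeatureError(
                f"need >= {self.min_points} G-V points, got {v.size}")
        span = g.max() - g.min()
        self.converged_ = False
        self.g_max_ = self.v_half_ = self.k_ = np.nan
        self.residual_norm_ = np.nan
        self.stderr_ = (np.nan,) * 3
        if span <= 1e-12 * max(1.0, abs(g.max())):
            return self                      # flat curve: flagged, no fit
        best = None
        for vh0 in self.v_half_starts:
            for k0 in self.k_starts:
                try:
                    popt, pcov = curve_fit(
                        _boltzmann, v, g, p0=(max(g.max(), 1e-6), vh0, k0),
                        bounds=([1e-9, -150.0, 1e-3], [np.inf, 50.0, 100.0]),
                        maxfev=20000)
                except (RuntimeError, ValueError):
                    continue
                rss = float(np.linalg.norm(g - _boltzmann(v, *popt)))
                if best is None or rss < best[0]:
                    best = (rss, popt, pcov)
        if best is None:
            return self
        rss, popt, pcov = best
        self.g_max_, self.v_half_, self.k_ = map(float, popt)
        self.residual_norm_ = rss
        with np.errstate(invalid="ignore"):
            self.stderr_ = tuple(np.sqrt(np.diag(pcov)))
        self.converged_ = True
        return self

    def predict(self, X):
        check_is_fitted(self, "g_max_")
        return _boltzmann(np.asarray(X, dtype=float), self.g_max_,
                          self.v_half_, self.k_)

    def result(self) -> BoltzmannFit:
        check_is_fitted(self, "converged_")
        return BoltzmannFit(self.g_max_, self.v_half_, self.k_,
                            self.residual_norm_, self.converged_, self.stderr_)


def fit_boltzmann(gv: pd.DataFrame, **kwargs) -> BoltzmannFit:
    """Fit a G-V curve (columns ``v_mv``, ``g_ns``); see :class:`BoltzmannModel`."""
    return BoltzmannModel(**kwargs).fit(gv["v_mv"], gv["g_ns"]).result()


# ---------------------------------------------------------------------------
# sag ratio
# ---------------------------------------------------------------------------

@dataclass
class SagMeasurement:
    v_peak: float          # largest deflection from baseline, mV (positive down)
    v_ss: float            # deflection at end of step, mV
    sag_ratio: float       # (v_peak - v_ss)/v_peak * 100, %
    baseline_mv: float


def _step_window(trace: Trace):
    """Start/stop indices of the (single) current step in a CC trace."""
    jumps = np.nonzero(np.abs(np.diff(trace.command)) > 1e-9)[0]
    if jumps.size < 2:
        raise FeatureError("no complete current step found")
    return int(jumps[0] + 1), int(jumps[1] + 1)


def sag_ratio(trace: Trace, ss_window_ms: float = 100.0,
              baseline_ms: float = 100.0) -> SagMeasurement:
    """Sag from a hyperpolarizing step: (V_peak - V_ss)/V_peak x 100%.

    V_peak is the largest membrane-potential change from the pre-step
    baseline during the step; V_ss the mean change over the final
    ``ss_window_ms`` of the step. Depends only on deflections, so it is
    invariant to a vertical offset of the whole trace.
    """
    i0, i1 = _step_window(trace)
    dt = trace.dt_ms
    nb = int(round(baseline_ms / dt))
    baseline = float(np.mean(trace.signal[max(0, i0 - nb):i0]))
    defl = baseline - trace.signal[i0:i1]          # positive = hyperpolarizing
    v_peak = float(defl.max())
    if v_peak <= 0:
        raise FeatureError("no hyperpolarizing deflection during the step")
    nss = int(round(ss_window_ms / dt))
    v_ss = float(np.mean(defl[-nss:]))
    return SagMeasurement(v_peak=v_peak, v_ss=v_ss,
                          sag_ratio=(v_peak - v_ss) / v_peak * 100.0,
                          baseline_mv=baseline)


def zd_sensitive_sag(pre: Trace, post_zd: Trace, **kwargs) -> float:
    """ZD7288-sensitive sag: sag ratio before minus after HCN block (%)."""
    return sag_ratio(pre, **kwargs).sag_ratio - sag_ratio(post_zd, **kwargs).sag_ratio


# ---------------------------------------------------------------------------
# input resistance
# ---------------------------------------------------------------------------

@dataclass
class RinMeasurement:
    onset_mohm: float
    steady_state_mohm: float
    currents_pa: np.ndarray
    onset_mv: np.ndarray
    steady_mv: np.ndarray


def input_resistance(traces: list[Trace], onset_ms: float = 100.0,
                     steady_ms: float = 250.0, expected_steps=range(-60, 61, 20)
                     ) -> RinMeasurement:
    """Onset and steady-state input resistance from the step family.

    Per step: onset voltage = mean over ``onset_ms`` starting at the peak of
    the voltage response; steady voltage = mean over the final ``steady_ms``
    of the step. R_in (MOhm) is the least-squares slope of V (mV) against
    I (pA), x1000. Scale-invariant: doubling all currents and responses
    leaves both resistances unchanged.
    """
    found = {}
    for tr in traces:
        try:
            i0, i1 = _step_window(tr)
        except FeatureError:
            # the 0-pA sweep has a flat command; use the middle of the trace
            i0, i1 = tr.signal.size // 5, 4 * tr.signal.size // 5
        amp = float(np.round(tr.command[i0]))
        dt = tr.dt_ms
        nb = int(round(100.0 / dt))
        baseline = float(np.mean(tr.signal[max(0, i0 - nb):i0]))
        resp = tr.signal[i0:i1] - baseline
        if amp == 0:
            peak_idx = 0
        else:
            peak_idx = int(np.argmax(resp) if amp > 0 else np.argmin(resp))
        n_on = int(round(onset_ms / dt))
        onset_v = float(np.mean(resp[peak_idx:peak_idx + n_on]))
        n_ss = int(round(steady_ms / dt))
        steady_v = float(np.mean(resp[-n_ss:]))
        found[amp] = (onset_v, steady_v)
    missing = [i for i in expected_steps if float(i) not in found]
    if missing:
        raise FeatureError(
            f"missing current steps {missing}; found {sorted(found)}")
    currents = np.array(sorted(found))
    onset = np.array([found[c][0] for c in currents])
    steady = np.array([found[c][1] for c in currents])
    slope_on = np.polyfit(currents, onset, 1)[0] * 1000.0     # mV/pA -> MOhm
    slope_ss = np.polyfit(currents, steady, 1)[0] * 1000.0
    return RinMeasurement(onset_mohm=float(slope_on),
                          steady_state_mohm=float(slope_ss),
                          currents_pa=currents, onset_mv=onset, steady_mv=steady)


# ---------------------------------------------------------------------------
# resting potential, spikes
# ---------------------------------------------------------------------------

def detect_spikes(trace: Trace, level_mv: float = -20.0,
                  refractory_ms: float = 2.0) -> np.ndarray:
    """Spike times (ms) by upward level crossing with refractory merging."""
    v = trace.signal
    up = np.nonzero((v[1:] >= level_mv) & (v[:-1] < level_mv))[0] + 1
    if up.size == 0:
        return np.array([])
    times = trace.time_ms[up]
    keep = [times[0]]
    for t in times[1:]:
        if t - keep[-1] >= refractory_ms:
            keep.append(t)
    return np.asarray(keep)


def firing_rate(trace: Trace, **kwargs) -> float:
    """Mean spontaneous firing rate (Hz) over the whole trace."""
    spikes = detect_spikes(trace, **kwargs)
    duration_s = (trace.time_ms[-1] - trace.time_ms[0]) / 1000.0
    return spikes.size / duration_s


def resting_potential(trace: Trace, discard_ms: float = 500.0,
                      spike_level_mv: float = -20.0) -> float:
    """RMP (mV): mean voltage of a gap-free trace recorded under TTX.

    Raises if spikes are detected (the TTX precondition is violated). The
    initial ``discard_ms`` are dropped to let the state equilibrate.
    """
    if detect_spikes(trace, level_mv=spike_level_mv).size:
        raise FeatureError("spikes detected; RMP requires TTX (no spiking)")
    n0 = int(round(discard_ms / trace.dt_ms))
    return float(np.mean(trace.signal[n0:]))


# ---------------------------------------------------------------------------
# averaged spike waveform and parameters
# ---------------------------------------------------------------------------

@dataclass
class SpikeParams:
    threshold_mv: float
    amplitude_mv: float
    half_height_width_ms: float
    fahp_mv: float
    max_depol_slope_vps: float
    min_hyperpol_slope_vps: float

    def __post_init__(self):
        if self.amplitude_mv <= 0 or self.half_height_width_ms <= 0:
            raise ValueError("spike amplitude and width must be > 0")


def average_spike(trace: Trace, n: int = 20, window_ms: tuple = (8.0, 8.0),
                  level_mv: float = -20.0) -> tuple[np.ndarray, np.ndarray]:
    """Average ``n`` consecutive spontaneous spikes aligned at the negative peak.

    The negative peak (fAHP trough) is located within 6 ms after each
    detected spike; windows of ``window_ms`` (before, after) around it are
    averaged. Returns (time_ms relative to trough, averaged voltage). Raises
    if fewer than ``n`` alignable spikes exist.
    """
    spikes = detect_spikes(trace, level_mv=level_mv)
    dt = trace.dt_ms
    nb, na = (int(round(w / dt)) for w in window_ms)
    segments = []
    for t_spk in spikes:
        i = int(round(t_spk / dt))
        trough = i + int(np.argmin(trace.signal[i:i + int(round(6.0 / dt))]))
        if trough - nb < 0 or trough + na > trace.signal.size:
            continue
        segments.append(trace.signal[trough - nb:trough + na])
        if len(segments) == n:
            break
    if len(segments) < n:
        raise FeatureError(
            f"need {n} alignable spikes, found {len(segments)}")
    avg = np.mean(segments, axis=0)
    t = (np.arange(avg.size) - nb) * dt
    return t, avg


def _smoothed_dvdt(v: np.ndarray, dt_ms: float, cutoff_hz: float = 1000.0
                   ) -> np.ndarray:
    """Central-difference dV/dt (V/s) after low-pass smoothing.

    The 10 V/s threshold rule is noise-sensitive, so the waveform is low-pass
    filtered (4th-order Butterworth, zero-phase) before differentiation.
    """
    fs = 1000.0 / dt_ms
    if cutoff_hz < fs / 2:
        b, a = butter(4, cutoff_hz / (fs / 2))
        v = filtfilt(b, a, v)
    return np.gradient(v, dt_ms)          # mV/ms == V/s


def spike_parameters(time_ms: np.ndarray, v: np.ndarray,
                     dvdt_threshold_vps: float = 10.0,
                     smooth_cutoff_hz: float = 1000.0) -> SpikeParams:
    """Parameters of an averaged spike waveform.

    Threshold: first voltage on the upstroke where dV/dt exceeds 10 V/s.
    Amplitude: peak minus threshold. fAHP: threshold minus the post-spike
    negative peak. Half-height width: width at threshold + amplitude/2.
    """
    dt = float(time_ms[1] - time_ms[0])
    dvdt = _smoothed_dvdt(v, dt, smooth_cutoff_hz)
    peak_idx = int(np.argmax(v))
    upstroke = np.nonzero(dvdt[:peak_idx + 1] > dvdt_threshold_vps)[0]
    if upstroke.size == 0:
        raise FeatureError("no dV/dt threshold crossing on the upstroke")
    thr_idx = int(upstroke[0])
    threshold = float(v[thr_idx])
    peak = float(v[peak_idx])
    amplitude = peak - threshold
    trough_idx = peak_idx + int(np.argmin(v[peak_idx:]))
    fahp = threshold - float(v[trough_idx])
    half = threshold + amplitude / 2.0
    above = np.nonzero(v >= half)[0]
    above = above[(above >= thr_idx) & (above <= trough_idx)]
    width = (above[-1] - above[0] + 1) * dt if above.size else np.nan
    return SpikeParams(
        threshold_mv=threshold, amplitude_mv=amplitude,
        half_height_width_ms=float(width), fahp_mv=fahp,
        max_depol_slope_vps=float(dvdt[:peak_idx + 1].max()),
        min_hyperpol_slope_vps=float(dvdt[peak_idx:trough_idx + 1].min()
                                     if trough_idx > peak_idx else dvdt.min()))
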