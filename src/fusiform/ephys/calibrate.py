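"""Preset calibration: solve model parameters for measured targets.

These routines back out the free parameters of a :class:`CellParams` set from
the summary measurements a preset should reproduce: leak reversal from the
resting potential, background K leak from a hyperpolarized resting potential,
HCN conductance from the ZD7288-sensitive sag ratio (bisection over
simulated sag protocols), pacemaker drive from the spontaneous firing rate,
and KCNQ conductance from the deactivation tail amplitude. They are used to
derive the frozen constants in :mod:`fusiform.ephys.presets` and can
regenerate them.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .features import (firing_rate, sag_ratio, subtract_traces,
                       tail_current_amplitude, zd_sensitive_sag)
from .model import CellParams, DrugState, Protocol, Segment, protocol_library, simulate


def e_leak_for_rmp(cell: CellParams, rmp_mv: float) -> float:
    """Leak reversal putting the TTX steady state exactly at ``rmp_mv``."""
    other = (cell.g_kleak * (rmp_mv - cell.e_k)
             + cell.g_kcnq * float(cell.m_inf(rmp_mv)) * (rmp_mv - cell.e_k)
             + cell.g_hcn * float(cell.h_inf(rmp_mv)) * (rmp_mv - cell.e_h))
    return rmp_mv + other / cell.g_leak


def g_kleak_for_rmp(cell: CellParams, rmp_mv: float) -> float:
    """Background K leak putting the TTX steady state at ``rmp_mv``.

    Keeps e_leak fixed; used for presets whose resting potential is
    hyperpolarized relative to their parent preset.
    """
    other = (cell.g_leak * (rmp_mv - cell.e_leak)
             + cell.g_kcnq * float(cell.m_inf(rmp_mv)) * (rmp_mv - cell.e_k)
             + cell.g_hcn * float(cell.h_inf(rmp_mv)) * (rmp_mv - cell.e_h))
    g = -other / (rmp_mv - cell.e_k)
    if g < 0:
        raise ValueError("target RMP is depolarized relative to this cell; "
                         "a K leak cannot reach it")
    return g


def measured_zd_sag(cell: CellParams, dt_ms: float = 0.025) -> float:
    """ZD7288-sensitive sag ratio (%) of a cell, from simulated sag steps."""
    sag = protocol_library(dt_ms=dt_ms)["sag_step"]
    pre = simulate(cell, sag, DrugState(ttx=True))
    post = simulate(cell, sag, DrugState(ttx=True, zd7288=True))
    return zd_sensitive_sag(pre, post)


def g_hcn_for_sag(cell: CellParams, target_pct: float, lo: float = 0.01,
                  hi: float = 30.0, tol: float = 0.01, dt_ms: float = 0.025
                  ) -> float:
    """Bisection over the HCN conductance for a ZD-sensitive sag target.

    Sag ratio is strictly increasing in g_hcn (the depolarizing rebound grows
    with the conductance), so bisection is exact.
    """
    def eval_g(g):
        return measured_zd_sag(dataclasses.replace(cell, g_hcn=g), dt_ms)

    f_lo, f_hi = eval_g(lo) - target_pct, eval_g(hi) - target_pct
    if f_lo > 0 or f_hi < 0:
        raise ValueError(f"sag target {target_pct}% not bracketed by "
                         f"g_hcn in [{lo}, {hi}] nS")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if abs(hi - lo) < 1e-4:
            break
        if eval_g(mid) - target_pct > 0:
            hi = mid
        else:
            lo = mid
    g = 0.5 * (lo + hi)
    if abs(eval_g(g) - target_pct) > tol:
        raise ValueError("sag calibration did not converge")
    return g


def measured_rate(cell: CellParams, duration_s: float = 10.0,
                  dt_ms: float = 0.025) -> float:
    gap_free = protocol_library(dt_ms=dt_ms, gap_free_s=duration_s)["gap_free"]
    return firing_rate(simulate(cell, gap_free))


def i_drive_for_rate(cell: CellParams, target_hz: float, lo: float = 0.0,
                     hi: float = 400.0, tol_hz: float = 0.1,
                     duration_s: float = 10.0, dt_ms: float = 0.025) -> float:
    """Bisection over the pacemaker drive for a spontaneous-rate target."""
    def eval_i(i):
        return measured_rate(dataclasses.replace(cell, i_drive=i),
                             duration_s, dt_ms)

    if eval_i(lo) - target_hz > 0 or eval_i(hi) - target_hz < 0:
        raise ValueError(f"rate target {target_hz} Hz not bracketed by "
                         f"i_drive in [{lo}, {hi}] pA")
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if eval_i(mid) > target_hz:
            hi = mid
        else:
            lo = mid
        if hi - lo < 0.05:
            break
    i = 0.5 * (lo + hi)
    if abs(eval_i(i) - target_hz) > tol_hz:
        raise ValueError("firing-rate calibration did not converge")
    return i


def measured_tail(cell: CellParams, dt_ms: float = 0.025) -> float:
    """XE991-sensitive tail amplitude (pA) from the deactivation protocol."""
    prot = protocol_library(dt_ms=dt_ms)["kcnq_deactivation"]
    pre = simulate(cell, prot)
    post = simulate(cell, prot, DrugState(xe991=True))
    return tail_current_amplitude(subtract_traces(pre, post))


def g_kcnq_for_tail(cell: CellParams, target_pa: float) -> float:
    """KCNQ conductance matching a tail-current amplitude target.

    The tail amplitude is exactly proportional to g_kcnq (everything else
    subtracts out), so one simulation suffices.
    """
    ref = dataclasses.replace(cell, g_kcnq=1.0)
    return target_pa / measured_tail(ref)
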