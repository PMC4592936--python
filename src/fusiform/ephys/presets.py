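"""Calibrated cohort parameter sets for the fusiform-cell model.

Each preset reproduces the summary biophysics of one experimental group:

* ``control``          — sham-exposed: KCNQ V_half -28.3 mV, G_max 39.1 nS;
  HCN level giving a ZD7288-sensitive sag ratio of 15.5%; RMP -64.2 mV;
  spontaneous rate ~14.3 Hz.
* ``noise_4d``         — 4 days after noise exposure: KCNQ V_half -20.3 mV,
  G_max 37.7 nS; control-level HCN; RMP hyperpolarized to -67.7 mV via a
  raised background K leak.
* ``tinnitus_7d``      — tinnitus at day 7: depolarized KCNQ V_half
  (-20.3 mV), near-control HCN (ZD-sensitive sag 14.1%), control RMP.
* ``non_tinnitus_7d``  — resilient at day 7: control KCNQ, HCN reduced to a
  ZD-sensitive sag of 8.3%, RMP -67.5 mV.
* ``control_tail``     — control kinetics with the KCNQ conductance scaled to
  the deactivation-tail amplitude (73.8 pA) instead of the ramp-derived
  G_max; the two published measurements are mutually inconsistent under a
  single Boltzmann conductance, so the tail check uses this variant.

The numeric constants below were derived with :mod:`fusiform.ephys.calibrate`
(closed-form leak balance; bisection over g_hcn / i_drive on simulated
protocols) and are frozen here; ``recalibrate()`` regenerates them.
"""

from __future__ import annotations

import dataclasses

from .model import CellParams

#: measured targets each preset is calibrated to (units: %, mV, Hz, pA)
PRESET_TARGETS = {
    "control": {"zd_sag_pct": 15.5, "rmp_mv": -64.2, "rate_hz": 14.3},
    "noise_4d": {"rmp_mv": -67.7},
    "tinnitus_7d": {"zd_sag_pct": 14.1, "rmp_mv": -64.2},
    "non_tinnitus_7d": {"zd_sag_pct": 8.3, "rmp_mv": -67.5},
    "control_tail": {"tail_pa": 73.8},
}

#: shared passive/kinetic scaffold (see methods note for rationale)
_BASE = dict(c_m=65.0, g_leak=10.0, k=6.0, tau=130.0,
             v_half_h=-90.0, k_h=8.0, tau_h=400.0)

#: frozen calibration output (regenerate with `recalibrate()`)
_CALIBRATED = {
    "control": dict(g_kcnq=39.1, v_half=-28.3, g_hcn=1.2327,
                    e_leak=-64.1518, g_kleak=0.0, i_drive=162.4268),
    "noise_4d": dict(g_kcnq=37.7, v_half=-20.3, g_hcn=1.2327,
                     e_leak=-64.1518, g_kleak=2.1308, i_drive=162.4268),
    "tinnitus_7d": dict(g_kcnq=37.7, v_half=-20.3, g_hcn=1.1054,
                        e_leak=-64.2912, g_kleak=0.0, i_drive=162.4268),
    "non_tinnitus_7d": dict(g_kcnq=39.1, v_half=-28.3, g_hcn=0.6961,
                            e_leak=-64.1518, g_kleak=1.8855, i_drive=162.4268),
    "control_tail": dict(g_kcnq=7.0161, v_half=-28.3, g_hcn=1.2327,
                         e_leak=-64.1518, g_kleak=0.0, i_drive=162.4268),
}


def preset_states() -> dict:
    """Calibrated :class:`CellParams` per experimental group."""
    return {name: CellParams(**_BASE, **params)
            for name, params in _CALIBRATED.items()}


def recalibrate(verbose: bool = False) -> dict:
    """Re-derive the frozen constants from the targets (slow; dev tool)."""
    from . import calibrate as cal

    out = {}
    control = CellParams(**_BASE, g_kcnq=39.1, v_half=-28.3, g_hcn=1.0,
                         e_leak=-64.0, i_drive=0.0)
    # control: iterate sag / RMP (weakly coupled), then firing rate
    for _ in range(3):
        control = dataclasses.replace(
            control, g_hcn=cal.g_hcn_for_sag(
                control, PRESET_TARGETS["control"]["zd_sag_pct"]))
        control = dataclasses.replace(
            control, e_leak=cal.e_leak_for_rmp(
                control, PRESET_TARGETS["control"]["rmp_mv"]))
    control = dataclasses.replace(
        control, i_drive=cal.i_drive_for_rate(
            control, PRESET_TARGETS["control"]["rate_hz"]))
    out["control"] = control

    noise4 = dataclasses.replace(control, g_kcnq=37.7, v_half=-20.3)
    noise4 = dataclasses.replace(
        noise4, g_kleak=cal.g_kleak_for_rmp(
            noise4, PRESET_TARGETS["noise_4d"]["rmp_mv"]))
    out["noise_4d"] = noise4

    tin = dataclasses.replace(control, g_kcnq=37.7, v_half=-20.3)
    for _ in range(3):
        tin = dataclasses.replace(tin, g_hcn=cal.g_hcn_for_sag(
            tin, PRESET_TARGETS["tinnitus_7d"]["zd_sag_pct"]))
        tin = dataclasses.replace(tin, e_leak=cal.e_leak_for_rmp(
            tin, PRESET_TARGETS["tinnitus_7d"]["rmp_mv"]))
    out["tinnitus_7d"] = tin

    nt = dataclasses.replace(control)
    for _ in range(3):
        nt = dataclasses.replace(nt, g_hcn=cal.g_hcn_for_sag(
            nt, PRESET_TARGETS["non_tinnitus_7d"]["zd_sag_pct"]))
        nt = dataclasses.replace(nt, g_kleak=cal.g_kleak_for_rmp(
            nt, PRESET_TARGETS["non_tinnitus_7d"]["rmp_mv"]))
    out["non_tinnitus_7d"] = nt

    out["control_tail"] = dataclasses.replace(
        control, g_kcnq=cal.g_kcnq_for_tail(
            control, PRESET_TARGETS["control_tail"]["tail_pa"]))

    if verbose:
        for name, cell in out.items():
            print(name, {k: round(getattr(cell, k), 4)
                         for k in ("g_kcnq", "v_half", "g_hcn", "e_leak",
                                   "g_kleak", "i_drive")})
    return out
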