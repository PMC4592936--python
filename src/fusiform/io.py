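"""Plain-text readers and writers for the pipeline's interchange formats.

Schemas (version 1):

* trial tables — tidy CSV, one row per startle trial with columns
  ``mouse_id, cohort, phase, round_index, measure, frequency_khz, pair_index,
  trial_type, p2p_au, baseline_rms_au, is_artifact``.
* ratio tables — tidy CSV, one row per mouse x phase x measure x frequency.
* classifications — CSV plus a JSON fit report (mu, sigma, threshold, n,
  Lilliefors p).
* traces — CSV (``time_ms, signal, command``) with a JSON sidecar carrying
  protocol, drug state and cell parameters.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .ephys.model import Trace

SCHEMA_VERSION = 1


def write_trials(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"mouse_id", "phase", "round_index", "measure",
                "frequency_khz", "pair_index", "trial_type", "p2p_au",
                "baseline_rms_au"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    return df


def write_ratios(ratios: pd.DataFrame, path) -> None:
    ratios.to_csv(path, index=False)


def read_ratios(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_classification_report(classifications: pd.DataFrame, null_dist,
                                out_dir) -> None:
    """Write classifications.csv plus the Gaussian-null fit report JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    classifications.to_csv(out / "classifications.csv", index=False)
    report = {
        "schema_version": SCHEMA_VERSION,
        "mu": null_dist.mu, "sigma": null_dist.sigma,
        "threshold": null_dist.threshold, "n": null_dist.n,
        "lilliefors_p": null_dist.lilliefors_p,
        "fraction_below_threshold": null_dist.fraction_below_threshold(),
    }
    (out / "fit_report.json").write_text(json.dumps(report, indent=2))


def write_trace(trace: Trace, path) -> None:
    """Trace CSV plus a ``<path>.json`` sidecar with full provenance."""
    path = Path(path)
    trace.to_frame().to_csv(path, index=False)
    sidecar = {"schema_version": SCHEMA_VERSION, "mode": trace.mode,
               "dt_ms": trace.dt_ms, "meta": trace.meta}
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, default=str))


def read_trace(path) -> Trace:
    path = Path(path)
    df = pd.read_csv(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    mode, dt, meta = "current_clamp", None, {}
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        mode = sidecar.get("mode", mode)
        dt = sidecar.get("dt_ms")
        meta = sidecar.get("meta", {})
    t = df["time_ms"].to_numpy()
    if dt is None:
        dt = float(np.median(np.diff(t)))
    return Trace(time_ms=t, signal=df["signal"].to_numpy(),
                 command=df["command"].to_numpy(), mode=mode, dt_ms=dt,
                 meta=meta)
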