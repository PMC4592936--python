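"""Startle-trial quality control and ratio averaging.

Turns raw gap/no-gap and prepulse/startle-only trial pairs into one final gap
startle ratio and one PPI ratio per mouse x frequency x phase, applying the
standard elimination rules of the gap-detection paradigm:

1. Baseline-movement filter: within each session round, trials whose baseline
   RMS falls outside mean +/- 2.5 SD of the pooled RMS distribution (all four
   trial types pooled) are eliminated, together with their paired trial.
2. Pair ratios: p2p(gap) / p2p(no-gap), resp. p2p(prepulse) / p2p(startle-only).
3. Jump filter (gap ratios only): within one frequency and round, ratios are
   sorted ascending; at the first increase of more than 0.5 over the preceding
   value that ratio and all larger ones are excluded. If more than 5 ratios are
   excluded the frequency is dropped for that round.
4. Averaging: mean of retained ratios within each round, then mean across the
   three rounds.
5. Final exclusions: gap ratios > 0.9 pre-exposure or > 1.1 post-exposure, and
   PPI ratios > 1 in either phase, mark the frequency absent.

The main entry point is :class:`StartleRatioPipeline`, a stateless
scikit-learn transformer (``transform`` maps a tidy trial table to a tidy
ratio table); the individual rules are exposed as functions for testing and
reuse.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .synth import StartleTrial, _MODULATED, _REFERENCE

_SESSION_KEYS = ["mouse_id", "phase", "round_index"]
_PAIR_KEYS = _SESSION_KEYS + ["measure", "frequency_khz", "pair_index"]
_FREQ_KEYS = _SESSION_KEYS + ["measure", "frequency_khz"]


# ---------------------------------------------------------------------------
# waveform-level measurements
# ---------------------------------------------------------------------------

def peak_to_peak(trial: StartleTrial) -> float:
    """Peak-to-peak startle amplitude (AU) over the response region."""
    resp = trial.force_au[trial.startle_onset_index:]
    if resp.size == 0:
        raise ValueError("trial has no response region")
    return float(resp.max() - resp.min())


def max_abs_amplitude(trial: StartleTrial) -> float:
    """Maximum absolute response amplitude; stored for provenance only."""
    resp = trial.force_au[trial.startle_onset_index:]
    return float(np.abs(resp).max())


def rms_baseline(trial: StartleTrial) -> float:
    """Root mean square of baseline movement preceding the startle response."""
    b0, b1 = trial.baseline_window
    window = trial.force_au[b0:b1]
    if window.size == 0:
        raise ValueError("baseline window is empty")
    return float(np.sqrt(np.mean(window ** 2)))


def summarize_trials(trials: list[StartleTrial], mouse_id: str,
                     cohort: str = "") -> pd.DataFrame:
    """Reduce waveform trials to the tidy summary table the QC consumes."""
    rows = []
    for t in trials:
        s = t.spec
        rows.append((mouse_id, cohort, s.phase, s.round_index, s.measure,
                     s.frequency_khz, s.pair_index, s.trial_type,
                     peak_to_peak(t), rms_baseline(t), max_abs_amplitude(t)))
    return pd.DataFrame(rows, columns=[
        "mouse_id", "cohort", "phase", "round_index", "measure",
        "frequency_khz", "pair_index", "trial_type", "p2p_au",
        "baseline_rms_au", "max_abs_au"])


# ---------------------------------------------------------------------------
# rule 1: baseline-RMS filter with paired removal
# ---------------------------------------------------------------------------

def filter_trials_by_baseline(trials: pd.DataFrame, n_sd: float = 2.5
                              ) -> pd.DataFrame:
    """Eliminate trials with outlying baseline RMS, plus their paired trials.

    Mean and SD are pooled per mouse x phase x round over all trial types.
    Returns the table with boolean columns ``baseline_outlier`` (this trial
    outlying) and ``eliminated`` (this trial or its partner outlying). Groups
    with fewer than 2 trials are left unfiltered.
    """
    df = trials.copy()
    grp = df.groupby(_SESSION_KEYS)["baseline_rms_au"]
    mean = grp.transform("mean")
    sd = grp.transform("std")        # ddof=1 sample SD
    count = grp.transform("size")
    sd = sd.fillna(0.0)
    lo, hi = mean - n_sd * sd, mean + n_sd * sd
    df["baseline_outlier"] = ((df["baseline_rms_au"] < lo)
                              | (df["baseline_rms_au"] > hi)) & (count >= 2)
    # paired removal: if either member of a pair is out, both are
    df["eliminated"] = df.groupby(_PAIR_KEYS)["baseline_outlier"].transform("max")
    return df


# ---------------------------------------------------------------------------
# rule 2: pair ratios
# ---------------------------------------------------------------------------

def compute_pair_ratios(trials: pd.DataFrame) -> pd.DataFrame:
    """Compute one ratio per retained pair: modulated p2p / reference p2p.

    Pairs whose reference p2p is not > 0 are flagged invalid and dropped.
    Expects the ``eliminated`` column from :func:`filter_trials_by_baseline`
    (absent -> nothing eliminated).
    """
    df = trials if "eliminated" in trials.columns else trials.assign(eliminated=False)
    df = df[~df["eliminated"]]
    num = df[df["trial_type"].isin(_MODULATED)]
    den = df[df["trial_type"].isin(_REFERENCE)]
    merged = num.merge(den[_PAIR_KEYS + ["p2p_au"]], on=_PAIR_KEYS,
                       suffixes=("", "_ref"))
    merged = merged[merged["p2p_au_ref"] > 0]
    out = merged[_PAIR_KEYS].copy()
    out["ratio"] = merged["p2p_au"].to_numpy() / merged["p2p_au_ref"].to_numpy()
    return out


def compute_pair_ratio(modulated: StartleTrial, reference: StartleTrial) -> float:
    """Ratio of one waveform pair (gap/no-gap or prepulse/startle-only)."""
    den = peak_to_peak(reference)
    if den <= 0:
        raise ValueError("reference trial has non-positive peak-to-peak amplitude")
    return peak_to_peak(modulated) / den


# ---------------------------------------------------------------------------
# rule 3: sorted-ratio jump filter
# ---------------------------------------------------------------------------

def filter_sorted_ratios(ratios, jump: float = 0.5, max_excluded: int = 5):
    """Apply the ascending-sort jump filter to one frequency/round of ratios.

    Returns ``(retained_sorted, n_excluded, dropped)``: ratios are sorted
    ascending and truncated at the first consecutive increase larger than
    ``jump``; if more than ``max_excluded`` ratios fall after the truncation
    point (or the input is empty) the frequency is dropped for this round.
    """
    arr = np.sort(np.asarray(ratios, dtype=float))
    if arr.size == 0:
        return arr, 0, True
    gaps = np.diff(arr)
    idx = np.nonzero(gaps > jump)[0]
    cut = idx[0] + 1 if idx.size else arr.size
    n_excluded = arr.size - cut
    return arr[:cut], n_excluded, n_excluded > max_excluded


def _jump_filter_table(ratios: pd.DataFrame, jump: float, max_excluded: int
                       ) -> pd.DataFrame:
    """Vectorized jump filter over all (mouse, phase, round, frequency) groups."""
    df = ratios.sort_values(_FREQ_KEYS + ["ratio"], kind="mergesort").copy()
    g = df.groupby(_FREQ_KEYS, sort=False)
    diff = g["ratio"].diff().fillna(0.0)
    df["jump_excluded"] = (diff > jump).groupby(
        [df[k] for k in _FREQ_KEYS], sort=False).cummax()
    n_exc = df.groupby(_FREQ_KEYS, sort=False)["jump_excluded"].transform("sum")
    df["freq_round_dropped"] = n_exc > max_excluded
    return df


# ---------------------------------------------------------------------------
# rules 4-5: averaging and final exclusions
# ---------------------------------------------------------------------------

def finalize_ratios(pair_ratios: pd.DataFrame, jump: float = 0.5,
                    max_excluded: int = 5, gap_pre_max: float = 0.9,
                    gap_post_max: float = 1.1, ppi_max: float = 1.0,
                    jump_filter_ppi: bool = False) -> pd.DataFrame:
    """Average QC-filtered pair ratios into the final per-frequency table.

    Per frequency: mean of retained ratios within each round, then mean across
    rounds; rounds dropped by the jump filter do not contribute. Frequencies
    whose final gap ratio exceeds 0.9 (pre) / 1.1 (post), or PPI ratio exceeds
    1 (either phase), are marked absent with ``drop_reason='ratio_exclusion'``.
    """
    gap = pair_ratios[pair_ratios["measure"] == "gap"]
    ppi = pair_ratios[pair_ratios["measure"] == "ppi"]
    parts = [_jump_filter_table(gap, jump, max_excluded)]
    if jump_filter_ppi:
        parts.append(_jump_filter_table(ppi, jump, max_excluded))
    else:
        parts.append(ppi.assign(jump_excluded=False, freq_round_dropped=False))
    df = pd.concat(parts, ignore_index=True)

    n_jump = (df.groupby(_FREQ_KEYS[:-1] + ["frequency_khz"])["jump_excluded"]
              .sum().groupby(["mouse_id", "phase", "measure", "frequency_khz"]).sum())
    kept = df[~df["jump_excluded"] & ~df["freq_round_dropped"]]
    round_means = kept.groupby(_FREQ_KEYS, as_index=False).agg(
        round_mean=("ratio", "mean"), n_pairs=("ratio", "size"))
    final = round_means.groupby(
        ["mouse_id", "phase", "measure", "frequency_khz"], as_index=False).agg(
        ratio=("round_mean", "mean"), n_pairs_used=("n_pairs", "sum"),
        n_rounds_used=("round_mean", "size"))
    final = final.merge(
        n_jump.rename("n_jump_excluded").reset_index(),
        on=["mouse_id", "phase", "measure", "frequency_khz"], how="left")
    final["n_jump_excluded"] = final["n_jump_excluded"].fillna(0).astype(int)

    is_gap = final["measure"] == "gap"
    is_pre = final["phase"] == "pre"
    excl = np.where(
        is_gap,
        np.where(is_pre, final["ratio"] > gap_pre_max,
                 final["ratio"] > gap_post_max),
        final["ratio"] > ppi_max)
    final["drop_reason"] = np.where(excl, "ratio_exclusion", "")
    final.loc[excl, "ratio"] = np.nan

    # frequencies dropped in *all* rounds never reach `final`; reinstate them
    # as absent rows so absence is a recorded outcome
    all_freqs = df.groupby(["mouse_id", "phase", "measure", "frequency_khz"],
                           as_index=False).size().drop(columns="size")
    final = all_freqs.merge(final, how="left",
                            on=["mouse_id", "phase", "measure", "frequency_khz"])
    missing = final["drop_reason"].isna()
    final.loc[missing, "drop_reason"] = "jump_filter_dropped"
    for col, fill in (("n_pairs_used", 0), ("n_rounds_used", 0),
                      ("n_jump_excluded", 0)):
        final[col] = final[col].fillna(fill).astype(int)
    return final


class StartleRatioPipeline(TransformerMixin, BaseEstimator):
    """Stateless transformer: tidy trial table -> tidy per-frequency ratio table.

    Parameters mirror the QC rules; defaults are the paradigm's published
    values. ``transform`` expects the schema produced by
    :func:`fusiform.behavior.synth.generate_session` /
    :func:`~fusiform.behavior.qc.summarize_trials` and returns one row per
    mouse x phase x measure x frequency with columns ``ratio`` (NaN when the
    frequency is absent), ``n_pairs_used``, ``n_rounds_used``,
    ``n_jump_excluded``, ``n_baseline_eliminated`` and ``drop_reason``.
    """

    def __init__(self, baseline_n_sd: float = 2.5, jump: float = 0.5,
                 max_excluded: int = 5, gap_pre_max: float = 0.9,
                 gap_post_max: float = 1.1, ppi_max: float = 1.0,
                 jump_filter_ppi: bool = False):
        self.baseline_n_sd = baseline_n_sd
        self.jump = jump
        self.max_excluded = max_excluded
        self.gap_pre_max = gap_pre_max
        self.gap_post_max = gap_post_max
        self.ppi_max = ppi_max
        self.jump_filter_ppi = jump_filter_ppi

    def fit(self, X=None, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        filtered = filter_trials_by_baseline(X, n_sd=self.baseline_n_sd)
        n_elim = (filtered.groupby(["mouse_id", "phase", "measure",
                                    "frequency_khz"])["eliminated"]
                  .sum().rename("n_baseline_eliminated"))
        ratios = compute_pair_ratios(filtered)
        final = finalize_ratios(
            ratios, jump=self.jump, max_excluded=self.max_excluded,
            gap_pre_max=self.gap_pre_max, gap_post_max=self.gap_post_max,
            ppi_max=self.ppi_max, jump_filter_ppi=self.jump_filter_ppi)
        final = final.merge(n_elim.reset_index(), how="left",
                            on=["mouse_id", "phase", "measure", "frequency_khz"])
        final["n_baseline_eliminated"] = (
            final["n_baseline_eliminated"].fillna(0).astype(int))
        return final
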