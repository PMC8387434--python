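"""Unit-level spike-train analytics.

Covers waveform-based classification of units into putative excitatory /
inhibitory classes, rate- and session-based unit filtering, valid-trial
extraction from behavioral event logs, high-frequency (ISI < 12 ms) burst
detection with the change-from-rest measure, a spike-count-preserving shuffle
control, the d-prime discrimination index, and opto-tag identification of
light-responsive units.

Spike times are in seconds throughout this module; ISI thresholds are in
milliseconds (the field's conventional units for each).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "UnitWaveformFeatures",
    "SpikeTrain",
    "BurstSummary",
    "classify_unit",
    "filter_units",
    "extract_valid_trials",
    "detect_bursts",
    "burst_spike_proportion",
    "delta_burst",
    "shuffle_null",
    "d_prime",
    "opto_tag_test",
]

#: waveform classification boundaries (peak-to-valley ratio, half-valley
#: width in microseconds)
RATIO_BOUNDARY = 1.5
WIDTH_BOUNDARY_US = 250.0


@dataclass(frozen=True)
class UnitWaveformFeatures:
    peak_to_valley_ratio: float
    half_valley_width_us: float
    mean_rate_hz: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.peak_to_valley_ratio)
                and np.isfinite(self.half_valley_width_us)):
            raise ValueError("waveform features must be finite")
        if self.half_valley_width_us <= 0 or self.mean_rate_hz < 0:
            raise ValueError("width must be positive and rate non-negative")


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times (seconds) for one unit."""

    unit_id: str
    times: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or (t.size > 1 and np.any(np.diff(t) <= 0)):
            raise ValueError("spike times must be strictly increasing 1-D")
        object.__setattr__(self, "times", t)


@dataclass
class BurstSummary:
    """Burst groups (as index runs) and the burst-spike proportion."""

    burst_groups: list[np.ndarray]
    burst_spike_proportion: float
    n_spikes: int
    isi_threshold_ms: float
    degenerate: bool = False


def classify_unit(features: UnitWaveformFeatures) -> str:
    """Classify a unit as ``pExc`` / ``pInh`` / ``unclassified`` from its
    extracellular waveform: broad, peaky waveforms (ratio > 1.5 and
    half-valley width > 250 us) are putative excitatory; narrow waveforms
    (ratio < 1.5 and width < 250 us) putative inhibitory."""
    r, w = features.peak_to_valley_ratio, features.half_valley_width_us
    if r > RATIO_BOUNDARY and w > WIDTH_BOUNDARY_US:
        return "pExc"
    if r < RATIO_BOUNDARY and w < WIDTH_BOUNDARY_US:
        return "pInh"
    return "unclassified"


def filter_units(spikes: pd.DataFrame, sessions: pd.DataFrame,
                 rate_threshold_hz: float = 0.5,
                 required_sessions: list[str] | None = None) -> list[str]:
    """Retain units with overall firing rate above ``rate_threshold_hz`` and
    at least one spike in every required session.

    ``spikes`` has columns (unit_id, time_s); ``sessions`` has columns
    (session, start_s, end_s) giving the extent of each recording session.
    ``required_sessions`` defaults to every session present.
    """
    if spikes.empty:
        return []
    if required_sessions is None:
        required_sessions = list(sessions["session"].unique())
    span = sessions["end_s"].max() - sessions["start_s"].min()
    kept = []
    for unit_id, grp in spikes.groupby("unit_id", sort=True):
        t = grp["time_s"].to_numpy()
        if t.size / span <= rate_threshold_hz:
            continue
        ok = True
        for name in required_sessions:
            rows = sessions[sessions["session"] == name]
            active = any(((t >= r.start_s) & (t < r.end_s)).any()
                         for r in rows.itertuples())
            if not active:
                ok = False
                break
        if ok:
            kept.append(unit_id)
    return kept


def extract_valid_trials(events: pd.DataFrame) -> pd.DataFrame:
    """Filter raw interaction events to valid trials.

    A trial is valid when its onset follows the previous interaction's end by
    more than 2 s and it lasts more than 1 s.  ``events`` has columns
    (session, target, side, start_s, end_s), time-ordered; overlapping events
    are rejected.
    """
    ev = events.sort_values("start_s").reset_index(drop=True)
    if (ev["end_s"] <= ev["start_s"]).any():
        raise ValueError("events must have end_s > start_s")
    if (ev["start_s"].to_numpy()[1:] < ev["end_s"].to_numpy()[:-1]).any():
        raise ValueError("overlapping interaction events")
    prev_end = np.concatenate([[-np.inf], ev["end_s"].to_numpy()[:-1]])
    gap_ok = (ev["start_s"].to_numpy() - prev_end) > 2.0
    dur_ok = (ev["end_s"] - ev["start_s"]).to_numpy() > 1.0
    return ev[gap_ok & dur_ok].reset_index(drop=True)


def detect_bursts(train: SpikeTrain | np.ndarray,
                  isi_threshold_ms: float = 12.0,
                  max_isi_considered_ms: float = 200.0,
                  min_spikes: int = 2) -> BurstSummary:
    """Group spikes into high-frequency bursts.

    A burst is a maximal run of >= ``min_spikes`` consecutive spikes with
    every internal inter-spike interval below ``isi_threshold_ms``.  The
    burst-spike proportion is the fraction of all spikes that belong to a
    burst (0 for an empty train).  ``max_isi_considered_ms`` caps the ISIs
    entering ISI histograms; it does not alter grouping.
    """
    if isi_threshold_ms >= max_isi_considered_ms:
        raise ValueError("isi_threshold must be below max_isi_considered")
    t = train.times if isinstance(train, SpikeTrain) else np.asarray(train,
                                                                     float)
    n = t.size
    if n == 0:
        return BurstSummary([], 0.0, 0, isi_threshold_ms, degenerate=True)
    isi_ms = np.diff(t) * 1000.0
    groups: list[np.ndarray] = []
    start = 0
    for k in range(isi_ms.size + 1):
        if k < isi_ms.size and isi_ms[k] < isi_threshold_ms:
            continue
        run = np.arange(start, k + 1)
        if run.size >= min_spikes:
            groups.append(run)
        start = k + 1
    in_burst = sum(g.size for g in groups)
    return BurstSummary(groups, in_burst / n, n, isi_threshold_ms)


def burst_spike_proportion(times: np.ndarray,
                           windows: list[tuple[float, float]],
                           isi_threshold_ms: float = 12.0,
                           min_spikes: int = 2) -> tuple[float, int]:
    """Burst-spike proportion of a train restricted to a set of windows.

    Bursts are detected within each window independently, so spikes in
    different windows never form a spurious burst.  Returns (proportion,
    total spike count); proportion is 0 when no spikes fall in the windows.
    """
    times = np.asarray(times, float)
    in_burst = 0
    total = 0
    for (a, b) in windows:
        t = times[(times >= a) & (times < b)]
        if t.size == 0:
            continue
        s = detect_bursts(t, isi_threshold_ms, min_spikes=min_spikes)
        in_burst += sum(g.size for g in s.burst_groups)
        total += t.size
    return (in_burst / total if total else 0.0), total


def delta_burst(train: SpikeTrain, trials: pd.DataFrame,
                rest_windows: list[tuple[float, float]],
                isi_threshold_ms: float = 12.0) -> pd.DataFrame:
    """Change in burst-spike proportion during target encounters vs rest.

    For each target present in ``trials`` (columns target, start_s, end_s),
    pools that target's trial windows, computes the burst-spike proportion,
    and subtracts the proportion over the rest windows.  Returns a table
    (target, delta_burst, target_proportion, rest_proportion, degenerate);
    ``degenerate`` flags targets where rest (or the target itself) had no
    spikes so the difference is computed against 0.
    """
    rest_prop, rest_n = burst_spike_proportion(train.times, rest_windows,
                                               isi_threshold_ms)
    rows = []
    for target, grp in trials.groupby("target", sort=True):
        wins = list(zip(grp["start_s"], grp["end_s"]))
        prop, n = burst_spike_proportion(train.times, wins, isi_threshold_ms)
        rows.append({
            "target": target,
            "delta_burst": prop - rest_prop,
            "target_proportion": prop,
            "rest_proportion": rest_prop,
            "degenerate": bool(rest_n == 0 or n == 0),
        })
    return pd.DataFrame(rows)


def shuffle_null(train: SpikeTrain, trials: pd.DataFrame | list,
                 n_perm: int, seed: int,
                 isi_threshold_ms: float = 12.0) -> np.ndarray:
    """Spike-count-preserving shuffle null for the burst-spike proportion.

    Within each interaction window the same number of spike times is
    redrawn uniformly over the window, and the pooled burst-spike proportion
    is recomputed; this controls for firing-rate differences between
    conditions.  Returns the ``n_perm`` null proportions.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if isinstance(trials, pd.DataFrame):
        windows = list(zip(trials["start_s"], trials["end_s"]))
    else:
        windows = list(trials)
    rng = np.random.default_rng(seed)
    counts = [int(((train.times >= a) & (train.times < b)).sum())
              for (a, b) in windows]
    out = np.empty(n_perm)
    for p in range(n_perm):
        in_burst = 0
        total = 0
        for t in _resample_windows(windows, counts, rng):
            s = detect_bursts(t, isi_threshold_ms)
            in_burst += sum(g.size for g in s.burst_groups)
            total += t.size
        out[p] = in_burst / total if total else 0.0
    return out


def _resample_windows(windows, counts, rng) -> list[np.ndarray]:
    """One shuffle draw: per window, the same number of spike times redrawn
    uniformly over the window (spike counts conserved exactly)."""
    out = []
    for (a, b), c in zip(windows, counts):
        if c:
            out.append(np.sort(rng.uniform(a, b, c)))
    return out


def d_prime(mu1: float, sigma1: float, mu2: float, sigma2: float) -> float:
    """Discrimination index d' = (mu1 - mu2) / sqrt((sigma1^2 + sigma2^2)/2)."""
    pooled = 0.5 * (sigma1**2 + sigma2**2)
    if pooled == 0:
        raise ValueError("d' undefined when both standard deviations are 0")
    return (mu1 - mu2) / np.sqrt(pooled)


def opto_tag_test(train: SpikeTrain, pulse_onsets_s: np.ndarray,
                  alpha: float = 0.05, min_pulses: int = 10) -> str:
    """Opto-tag a unit from its light-locked response.

    Per light pulse, spikes are counted in the first 20 ms and the last 20 ms
    of the 100-ms inter-pulse interval; the unit is ``tagged`` when the early
    counts exceed the late counts by a one-sided paired t-test at ``alpha``.
    A zero-variance difference is tagged only when every pulse shows a
    strictly positive difference and at least ``min_pulses`` pulses exist.
    """
    onsets = np.asarray(pulse_onsets_s, float)
    if onsets.size < 2:
        raise ValueError("need at least two pulses")
    t = train.times
    early = np.array([((t >= o) & (t < o + 0.020)).sum() for o in onsets])
    late = np.array([((t >= o + 0.080) & (t < o + 0.100)).sum()
                     for o in onsets])
    diff = early - late
    if diff.std(ddof=1) == 0:
        if np.all(diff > 0) and onsets.size >= min_pulses:
            return "tagged"
        return "untagged"
    res = stats.ttest_rel(early, late, alternative="greater")
    return "tagged" if (res.pvalue < alpha and diff.mean() > 0) else "untagged"
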