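"""Synthetic recording sessions with known ground truth.

Emulates the statistical structure of tetrode recording sessions from a
social linear-chamber task: a rest period followed by three exploration
sessions (E-E, S-O, O-S) with nose-poke interaction trials; units split
into two waveform-feature clusters (narrow/broad) with condition-dependent
firing rates, injected high-frequency doublets, optional von Mises phase
coupling to a band-limited LFP oscillation, and event-locked LFP band-power
modulation.  Every generated feature is parameterized by a
:class:`GroundTruth` so each analysis stage can be validated against the
planted values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import special

from .lfp import BandDefinition, LfpTrace, bandpass_fir, instantaneous_phase
from .lif import SimResult
from .spikes import SpikeTrain, extract_valid_trials

__all__ = [
    "GroundTruth",
    "SessionData",
    "PulseSession",
    "generate_session",
    "generate_pulse_session",
    "expected_burst_proportion",
]

SESSION_ORDER = ("E-E", "S-O", "O-S")
#: target by (session, side)
SESSION_TARGETS = {
    ("E-E", "L"): "E", ("E-E", "R"): "E",
    ("S-O", "L"): "S", ("S-O", "R"): "O",
    ("O-S", "L"): "O", ("O-S", "R"): "S",
}


@dataclass(frozen=True)
class GroundTruth:
    """Planted parameters of a synthetic recording session.

    Rates in Hz, durations in seconds.  ``burst_prob`` gives the doublet
    (injected second spike) probability per parent spike by condition
    (R = rest).  ``frac_s_specific`` units (drawn from both classes) fire at
    ``selective_gain`` times their base rate during social-target trials.
    ``coupling_kappa`` > 0 phase-couples inhibitory-class units to the
    ``coupling_band`` oscillation via von Mises thinning.
    """

    n_units: int = 40
    frac_inhibitory: float = 0.15
    rest_rate_exc: float = 2.0
    rest_rate_inh: float = 8.0
    target_rate_gain_exc: float = 1.5
    target_rate_gain_inh: float = 1.0
    burst_prob: Mapping[str, float] = field(default_factory=lambda: {
        "R": 0.05, "E": 0.05, "O": 0.05, "S": 0.15})
    frac_s_specific: float = 0.2
    selective_gain: float = 3.0
    rest_duration_s: float = 300.0
    session_duration_s: float = 600.0
    mean_trial_gap_s: float = 6.0
    mean_trial_duration_s: float = 2.0
    invalid_trial_frac: float = 0.2
    lfp_fs: float = 1000.0
    band_amplitudes: Mapping[str, float] = field(default_factory=lambda: {
        "theta": 1.0, "gamma": 0.5})
    modulated_band: str = "gamma"
    post_event_gain: float = 0.5
    coupling_band: str = "theta"
    coupling_kappa: float = 2.0
    coupling_mu: float = 0.0
    pulse_response: tuple[float, float, float] = (0.2, 0.5, 0.3)
    pulse_background_rate_hz: float = 2.0
    pulse_early_elevation: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for p in list(self.burst_prob.values()) + list(self.pulse_response):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.coupling_kappa < 0:
            raise ValueError("kappa must be non-negative")
        if abs(sum(self.pulse_response) - 1.0) > 1e-9:
            raise ValueError("pulse response probabilities must sum to 1")


#: bands the generator can synthesize carriers for
_GEN_BANDS = {
    "delta": BandDefinition("delta", 1.0, 4.0),
    "theta": BandDefinition("theta", 5.0, 11.0),
    "beta": BandDefinition("beta", 13.0, 30.0),
    "gamma": BandDefinition("gamma", 30.0, 150.0),
    "slow_gamma": BandDefinition("slow_gamma", 30.0, 55.0),
    "fast_gamma": BandDefinition("fast_gamma", 80.0, 110.0),
}


@dataclass
class SessionData:
    spikes: pd.DataFrame          # unit_id, time_s
    events: pd.DataFrame          # session, target, side, start_s, end_s
    sessions: pd.DataFrame        # session, start_s, end_s
    lfp: LfpTrace
    features: pd.DataFrame        # unit_id, ratio, width_us, rate_hz
    units: pd.DataFrame           # per-unit planted ground truth
    truth: GroundTruth

    def spike_train(self, unit_id: str) -> SpikeTrain:
        t = self.spikes.loc[self.spikes["unit_id"] == unit_id,
                            "time_s"].to_numpy()
        return SpikeTrain(unit_id, np.sort(t))

    @property
    def rest_windows(self) -> list[tuple[float, float]]:
        rest = self.sessions[self.sessions["session"] == "rest"]
        return list(zip(rest["start_s"], rest["end_s"]))


def expected_burst_proportion(rate_hz: float, doublet_prob: float,
                              isi_threshold_ms: float = 12.0) -> float:
    """Approximate expected burst-spike proportion of the generator output.

    Parents are Poisson at ``rate_hz``; each parent spawns a doublet partner
    (<12 ms away) with probability p.  Both doublet members are burst spikes;
    a non-doublet parent still joins a burst when a neighboring parent falls
    within the threshold (Poisson chance 1 - exp(-2 r theta)).
    """
    theta = isi_threshold_ms / 1000.0
    p_chance = 1.0 - np.exp(-2.0 * rate_hz * theta)
    return (2.0 * doublet_prob
            + (1.0 - doublet_prob) * p_chance) / (1.0 + doublet_prob)


def _draw_trials(rng: np.random.Generator, truth: GroundTruth,
                 session: str, start: float, end: float) -> list[dict]:
    rows = []
    t = start + rng.exponential(truth.mean_trial_gap_s)
    side = rng.choice(["L", "R"])
    prev_end = start
    while True:
        dur = 1.05 + rng.exponential(truth.mean_trial_duration_s - 1.0)
        if rng.random() < truth.invalid_trial_frac:
            # plant an invalid trial: too short, or too close to predecessor
            if rng.random() < 0.5:
                dur = rng.uniform(0.3, 0.95)
            else:
                t = prev_end + rng.uniform(0.3, 1.8)
        if t <= prev_end:
            t = prev_end + 0.1
        if t + dur >= end:
            break
        rows.append({"session": session,
                     "target": SESSION_TARGETS[(session, side)],
                     "side": side, "start_s": t, "end_s": t + dur})
        prev_end = t + dur
        side = "R" if side == "L" else "L"
        t = prev_end + 2.05 + rng.exponential(truth.mean_trial_gap_s)
    return rows


def _condition_timeline(valid: pd.DataFrame, total: float
                        ) -> tuple[np.ndarray, list[str]]:
    """Breakpoints and per-segment condition labels (R outside valid trials)."""
    pts = [0.0]
    labels = []
    cursor = 0.0
    for r in valid.sort_values("start_s").itertuples():
        if r.start_s > cursor:
            labels.append("R")
            pts.append(r.start_s)
        labels.append(r.target)
        pts.append(r.end_s)
        cursor = r.end_s
    if cursor < total:
        labels.append("R")
        pts.append(total)
    return np.asarray(pts), labels


def _poisson_times(rng: np.random.Generator, rate: float,
                   a: float, b: float) -> np.ndarray:
    n = rng.poisson(rate * (b - a))
    return np.sort(rng.uniform(a, b, n))


def _synth_band_noise(rng: np.random.Generator, band: BandDefinition,
                      n: int, fs: float, amplitude: float) -> np.ndarray:
    white = rng.normal(0.0, 1.0, n)
    y = bandpass_fir(LfpTrace(white, fs), band).samples
    sd = y.std()
    return amplitude * y / sd if sd > 0 else y


def generate_session(truth: GroundTruth) -> SessionData:
    """Generate one full synthetic recording session.

    Deterministic given ``truth.seed``: identical truths yield identical
    outputs.
    """
    rng = np.random.default_rng(truth.seed)

    # --- session structure and behavioral events -------------------------
    sess_rows = [{"session": "rest", "start_s": 0.0,
                  "end_s": truth.rest_duration_s}]
    cursor = truth.rest_duration_s
    ev_rows: list[dict] = []
    for name in SESSION_ORDER:
        end = cursor + truth.session_duration_s
        sess_rows.append({"session": name, "start_s": cursor, "end_s": end})
        ev_rows.extend(_draw_trials(rng, truth, name, cursor, end))
        cursor = end
    sessions = pd.DataFrame(sess_rows)
    events = pd.DataFrame(ev_rows)
    total = cursor
    valid_trials = extract_valid_trials(events)

    # --- LFP --------------------------------------------------------------
    fs = truth.lfp_fs
    n_samp = int(round(total * fs))
    lfp_sig = 0.05 * rng.normal(0.0, 1.0, n_samp)
    carriers: dict[str, np.ndarray] = {}
    for name, amp in truth.band_amplitudes.items():
        carriers[name] = _synth_band_noise(rng, _GEN_BANDS[name], n_samp,
                                           fs, amp)
    if truth.modulated_band in carriers and truth.post_event_gain != 1.0:
        gain = np.ones(n_samp)
        tvec_edges = valid_trials["start_s"].to_numpy()
        for e in tvec_edges:
            i0 = int((e + 0.5) * fs)
            i1 = min(int((e + 1.5) * fs), n_samp)
            if i0 < n_samp:
                gain[i0:i1] = truth.post_event_gain
        carriers[truth.modulated_band] = carriers[truth.modulated_band] * gain
    for c in carriers.values():
        lfp_sig = lfp_sig + c
    lfp = LfpTrace(lfp_sig, fs, 0.0)

    coupling_phase = None
    if truth.coupling_kappa > 0 and truth.coupling_band in carriers:
        coupling_phase = instantaneous_phase(carriers[truth.coupling_band])

    # --- per-unit ground truth -------------------------------------------
    n = truth.n_units
    is_inh = rng.random(n) < truth.frac_inhibitory
    is_s_spec = rng.random(n) < truth.frac_s_specific
    unit_rows = []
    feat_rows = []
    spike_frames = []
    pts, labels = _condition_timeline(valid_trials, total)
    acc_mean = float(special.i0(truth.coupling_kappa)
                     * np.exp(-truth.coupling_kappa))

    for u in range(n):
        uid = f"u{u:03d}"
        inh = bool(is_inh[u])
        base = truth.rest_rate_inh if inh else truth.rest_rate_exc
        gain = truth.target_rate_gain_inh if inh else truth.target_rate_gain_exc
        rates = {"R": base, "E": base * gain, "O": base * gain,
                 "S": base * gain}
        if is_s_spec[u]:
            rates["S"] = base * truth.selective_gain
        coupled = inh and coupling_phase is not None

        times = []
        for (a, b), lab in zip(zip(pts[:-1], pts[1:]), labels):
            r = rates[lab]
            if coupled:
                cand = _poisson_times(rng, r / acc_mean, a, b)
                if cand.size:
                    idx = np.clip((cand * fs).astype(int), 0, n_samp - 1)
                    ph = coupling_phase[idx]
                    acc = np.exp(truth.coupling_kappa
                                 * (np.cos(ph - truth.coupling_mu) - 1.0))
                    cand = cand[rng.random(cand.size) < acc]
                parents = cand
            else:
                parents = _poisson_times(rng, r, a, b)
            p_doublet = truth.burst_prob.get(lab, 0.0)
            if p_doublet > 0 and parents.size:
                mask = rng.random(parents.size) < p_doublet
                extra = parents[mask] + rng.uniform(0.004, 0.010,
                                                    int(mask.sum()))
                parents = np.concatenate([parents, extra])
            times.append(parents)
        t = np.sort(np.concatenate(times)) if times else np.empty(0)
        if t.size > 1:  # enforce a 1.5-ms refractory floor
            keep = np.concatenate([[True], np.diff(t) >= 0.0015])
            t = t[keep]
        spike_frames.append(pd.DataFrame({"unit_id": uid, "time_s": t}))

        # truncated draws: the planted class must stay recoverable from the
        # waveform, so neither cluster may cross the (1.5, 250 us) boundary
        if inh:
            ratio = min(rng.normal(1.1, 0.12), 1.35)
            width = min(rng.normal(185.0, 22.0), 230.0)
        else:
            ratio = max(rng.normal(2.2, 0.25), 1.7)
            width = max(rng.normal(330.0, 30.0), 270.0)
        feat_rows.append({"unit_id": uid, "ratio": ratio,
                          "width_us": max(width, 1.0),
                          "rate_hz": t.size / total})
        unit_rows.append({"unit_id": uid,
                          "is_inhibitory": inh,
                          "s_specific": bool(is_s_spec[u]),
                          "coupled": coupled,
                          "rate_R": rates["R"], "rate_E": rates["E"],
                          "rate_O": rates["O"], "rate_S": rates["S"]})

    return SessionData(spikes=pd.concat(spike_frames, ignore_index=True),
                       events=events, sessions=sessions, lfp=lfp,
                       features=pd.DataFrame(feat_rows),
                       units=pd.DataFrame(unit_rows), truth=truth)


@dataclass
class PulseSession:
    """Pulse-aligned spike trains with known per-epoch response classes."""

    onsets_s: np.ndarray
    train: SpikeTrain
    frequency: float
    epoch_classes: np.ndarray  # 0 no-fire, 1 tonic, 2 burst

    @property
    def sim_result(self) -> SimResult:
        """View as a single-neuron simulation result (times in ms)."""
        period = 1000.0 / self.frequency
        n_ep = self.onsets_s.size
        return SimResult(
            spike_times=[self.train.times * 1000.0],
            epoch_windows=[(k * period, (k + 1) * period)
                           for k in range(n_ep)],
            stimulated_ids=np.array([0]),
            gap_neighbor_ids=np.array([], dtype=int),
            duration=n_ep * period, dt=np.nan)


def generate_pulse_session(truth: GroundTruth, frequency: float,
                           n_epochs: int = 200) -> PulseSession:
    """Pulse-aligned spike train with planted epoch response classes.

    Each inter-pulse epoch is independently classed no-fire / tonic / burst
    with probabilities ``truth.pulse_response``.  With
    ``pulse_early_elevation`` the evoked spikes land in the first 20 ms after
    pulse onset (an opto-tagged unit); background spiking at
    ``pulse_background_rate_hz`` is uniform over the epoch.
    """
    if frequency not in (10.0, 40.0, 80.0, 10, 40, 80):
        raise ValueError("frequency must be one of 10, 40, 80 Hz")
    rng = np.random.default_rng(truth.seed)
    period = 1.0 / frequency
    onsets = np.arange(n_epochs) * period
    classes = rng.choice(3, size=n_epochs, p=list(truth.pulse_response))
    times = []
    for k, cls in enumerate(classes):
        o = onsets[k]
        hi = min(0.018, period - 0.002)
        if cls == 1:
            start = (rng.uniform(0.002, hi) if truth.pulse_early_elevation
                     else rng.uniform(0.0, period))
            times.append([o + start])
        elif cls == 2:
            n_sp = 2 + rng.geometric(0.6) - 1
            start = (rng.uniform(0.002, hi * 0.5)
                     if truth.pulse_early_elevation
                     else rng.uniform(0.0, period * 0.5))
            isis = rng.uniform(0.004, 0.010, n_sp - 1)
            burst = o + start + np.concatenate([[0.0], np.cumsum(isis)])
            times.append(list(burst[burst < o + period]))
        if truth.pulse_background_rate_hz > 0:
            nb = rng.poisson(truth.pulse_background_rate_hz * period)
            times.append(list(o + rng.uniform(0.0, period, nb)))
    t = np.sort(np.concatenate([np.asarray(x) for x in times])
                if times else np.empty(0))
    if t.size > 1:
        t = t[np.concatenate([[True], np.diff(t) > 1e-4])]
    return PulseSession(onsets_s=onsets, train=SpikeTrain("pulse-unit", t),
                        frequency=float(frequency), epoch_classes=classes)
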