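"""Gap-junction-coupled inhibitory LIF network: construction, simulation,
and per-epoch response classification.

The model is a randomly connected network of leaky integrate-and-fire
interneurons with exponentially decaying inhibitory conductance synapses,
bidirectional electrical (gap-junction) coupling, and pulsed external drive
mimicking optogenetic stimulation.  Subthreshold dynamics:

    tau dV_i/dt = g_L (V_rest - V_i) + I_inh,i + I_gap,i + I_ext,i(t) + I_noise,i

with I_inh,i = g_inh,i(t) (V_inh - V_i), g_inh incremented by g_max on each
presynaptic spike and decaying with time constant tau_syn, and

    I_gap,i = - sum_j J_ij F(V_i - V_j)

where J_ij is g_gap on gap edges and F is a causal 10th-order low-pass
(<30 Hz) filter, giving the electrical coupling its characteristic low-pass
behaviour.  When V crosses v_th a spike is recorded and V is clamped at
v_reset for the refractory period.

Conductances and currents are dimensionless model units chosen so the
published parameter values are used verbatim; voltages are in mV and times
in ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from ._integrator import run_lif

__all__ = [
    "LifParams",
    "NetworkModel",
    "StimProtocol",
    "SimResult",
    "EpochResponseSummary",
    "NumericalBlowupError",
    "build_network",
    "design_gap_filter",
    "simulate",
    "classify_epochs",
    "sweep_gap_parameters",
    "DEFAULT_PULSE_WIDTHS",
]

#: stimulation pulse widths (ms) by pulse frequency (Hz), matching the
#: optogenetic protocols (5-ms pulses at 10 Hz; 2-ms pulses at 40/80 Hz)
DEFAULT_PULSE_WIDTHS = {10.0: 5.0, 40.0: 2.0, 80.0: 2.0}


class NumericalBlowupError(RuntimeError):
    """Raised when a membrane voltage leaves the sanity bound."""


@dataclass(frozen=True)
class LifParams:
    """Single-neuron and synapse parameters.

    Voltages in mV, times in ms; conductances/currents in dimensionless
    model units.  ``sigma_noise`` is the SD of the per-step Gaussian noise
    current (per integration step, so results are tied to ``dt``).

    ``v_floor`` is a hard lower bound on the membrane voltage, analogous to
    the hard upper bound that the spike/reset rule provides.  The filtered
    diffusive gap coupling carries a phase lag, so at high gap strength times
    degree the linearized network admits growing oscillatory modes; without a
    floor these drive unbounded hyperpolarizing excursions that no biophysical
    membrane would show.  The default (-80 mV, below the inhibitory reversal)
    leaves ordinary dynamics untouched and only truncates those artifacts.
    Set it to ``-np.inf`` to disable.
    """

    tau: float = 1.0
    v_rest: float = -65.0
    g_leak: float = 0.4
    sigma_noise: float = 0.2
    g_max: float = 0.03
    tau_syn: float = 10.0
    v_inh: float = -75.0
    v_th: float = -64.0
    v_reset: float = -65.0
    v_floor: float = -80.0
    t_refrac: float = 1.5
    dt: float = 0.1

    def __post_init__(self) -> None:
        if self.tau <= 0 or self.tau_syn <= 0:
            raise ValueError("time constants must be positive")
        if self.dt <= 0 or self.dt > self.t_refrac:
            raise ValueError("require 0 < dt <= t_refrac")
        if self.v_reset >= self.v_th:
            raise ValueError("require v_reset < v_th")
        if self.v_floor > self.v_reset:
            raise ValueError("require v_floor <= v_reset")


@dataclass(frozen=True)
class NetworkModel:
    """Connectivity of the inhibitory network.

    ``syn_adjacency[j, i]`` is True when neuron j makes an inhibitory synapse
    onto neuron i (directed, zero diagonal).  ``gap_links`` is the symmetric
    boolean edge structure; ``gap_adjacency`` is the weighted matrix
    J = gap_links * g_gap with entries in {0, g_gap}.  Keeping the structure
    separate lets g_gap = 0 serve as an uncoupled control with the neighbor
    population still defined.
    """

    n_neurons: int
    syn_adjacency: np.ndarray
    gap_links: np.ndarray
    g_gap: float
    gap_mean_degree: float
    rng_seed: int

    def __post_init__(self) -> None:
        L = self.gap_links
        if L.shape != (self.n_neurons, self.n_neurons):
            raise ValueError("gap link matrix shape mismatch")
        if not np.array_equal(L, L.T):
            raise ValueError("gap links must be symmetric")
        if np.any(np.diag(L)) or np.any(np.diag(self.syn_adjacency)):
            raise ValueError("adjacency diagonals must be zero")
        if self.g_gap < 0:
            raise ValueError("g_gap must be non-negative")

    @property
    def gap_adjacency(self) -> np.ndarray:
        """Symmetric weighted matrix J_ij in {0, g_gap}, zero diagonal."""
        return self.gap_links * self.g_gap

    @property
    def gap_edges(self) -> tuple[np.ndarray, np.ndarray]:
        """Undirected gap edges as (a, b) index arrays with a < b."""
        a, b = np.nonzero(np.triu(self.gap_links, 1))
        return a.astype(np.int64), b.astype(np.int64)

    def gap_neighbors(self, targets: Sequence[int]) -> np.ndarray:
        """Neurons gap-linked to any of ``targets`` (targets excluded)."""
        mask = np.zeros(self.n_neurons, dtype=bool)
        for t in targets:
            mask |= self.gap_links[t]
        mask[list(targets)] = False
        return np.nonzero(mask)[0]


@dataclass(frozen=True)
class StimProtocol:
    """Pulsed external drive mimicking laser stimulation."""

    mode: Literal["single-neuron", "all-neurons"] = "single-neuron"
    target_ids: tuple[int, ...] = (0,)
    frequency: float = 10.0
    pulse_width: float | None = None
    amplitude: float = 0.7
    duration: float = 2000.0

    def __post_init__(self) -> None:
        pw = self.resolved_pulse_width
        if pw >= 1000.0 / self.frequency:
            raise ValueError("pulse width must be shorter than the period")
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    @property
    def resolved_pulse_width(self) -> float:
        if self.pulse_width is not None:
            return self.pulse_width
        return DEFAULT_PULSE_WIDTHS.get(self.frequency, 5.0)

    @property
    def period(self) -> float:
        return 1000.0 / self.frequency


@dataclass
class SimResult:
    """Spike output of one network simulation."""

    spike_times: list[np.ndarray]
    epoch_windows: list[tuple[float, float]]
    stimulated_ids: np.ndarray
    gap_neighbor_ids: np.ndarray
    duration: float
    dt: float
    voltage_traces: np.ndarray | None = None

    @property
    def n_neurons(self) -> int:
        return len(self.spike_times)


@dataclass(frozen=True)
class EpochResponseSummary:
    """Per-epoch response-class probabilities for a neuron population.

    Each (neuron, epoch) pair is classed by its spike count within the
    stimulation-pulse period: 0 -> no-fire, 1 -> tonic, >=2 -> burst.
    """

    p_no_fire: float
    p_tonic: float
    p_burst: float
    mean_rate: float
    population: str
    n_pairs: int


def build_network(n_neurons: int, syn_prob: float, gap_mean_degree: float,
                  g_gap: float, seed: int) -> NetworkModel:
    """Draw a random network: directed synapses with probability ``syn_prob``
    and symmetric gap edges approximating per-neuron target degrees drawn
    from a Gaussian with mean M and SD M/3 (rounded, clipped to [0, n-1]).

    Edges are placed greedily: neurons are visited in random order and matched
    with the partners that have the largest unmet residual degree, ties broken
    by a seed-controlled shuffle.
    """
    if n_neurons < 2:
        raise ValueError("need at least 2 neurons")
    if not 0.0 <= syn_prob <= 1.0:
        raise ValueError("syn_prob must be in [0, 1]")
    if gap_mean_degree < 0 or g_gap < 0:
        raise ValueError("degrees and strengths must be non-negative")

    rng = np.random.default_rng(seed)
    syn = rng.random((n_neurons, n_neurons)) < syn_prob
    np.fill_diagonal(syn, False)

    linked = np.zeros((n_neurons, n_neurons), dtype=bool)
    if gap_mean_degree > 0:
        target = np.clip(
            np.round(rng.normal(gap_mean_degree, gap_mean_degree / 3.0,
                                n_neurons)),
            0, n_neurons - 1).astype(np.int64)
        need = target.copy()
        for i in rng.permutation(n_neurons):
            if need[i] <= 0:
                continue
            cand = np.array([j for j in range(n_neurons)
                             if j != i and not linked[i, j] and need[j] > 0],
                            dtype=np.int64)
            rng.shuffle(cand)
            cand = cand[np.argsort(-need[cand], kind="stable")]
            k = min(int(need[i]), cand.size)
            for j in cand[:k]:
                linked[i, j] = linked[j, i] = True
                need[i] -= 1
                need[j] -= 1
    return NetworkModel(n_neurons=n_neurons, syn_adjacency=syn,
                        gap_links=linked, g_gap=g_gap,
                        gap_mean_degree=gap_mean_degree, rng_seed=seed)


def design_gap_filter(order: int = 10, cutoff_hz: float = 30.0,
                      fs: float = 10_000.0) -> np.ndarray:
    """Design the gap-junction low-pass filter as second-order sections.

    Butterworth family by default; the cascade is applied causally
    sample-by-sample inside the integrator.
    """
    if not 0 < cutoff_hz < fs / 2:
        raise ValueError("cutoff must lie below the Nyquist frequency")
    return signal.butter(order, cutoff_hz, btype="low", fs=fs, output="sos")


def _child_seed(seed_seq: np.random.SeedSequence) -> int:
    return int(seed_seq.generate_state(1)[0] % (2**31 - 1))


def simulate(model: NetworkModel, params: LifParams, stim: StimProtocol,
             duration: float | None = None, seed: int = 0,
             record_voltage: bool = False,
             init: Literal["uniform", "rest"] = "uniform",
             gap_filter_order: int = 10,
             gap_filter_cutoff_hz: float = 30.0) -> SimResult:
    """Forward-Euler integration of the network under pulsed stimulation.

    Deterministic given ``seed`` (noise and initial voltages).  With
    ``init='uniform'`` initial voltages are drawn uniformly in
    [v_reset, v_th) to avoid artificial synchrony; ``init='rest'`` starts
    every neuron exactly at v_rest.
    """
    duration = stim.duration if duration is None else duration
    if duration < stim.period:
        raise ValueError("duration must cover at least one stimulation period")
    n = model.n_neurons
    dt = params.dt
    n_steps = int(round(duration / dt))
    fs = 1000.0 / dt
    sos = design_gap_filter(gap_filter_order, gap_filter_cutoff_hz, fs)

    rng = np.random.default_rng(seed)
    if init == "uniform":
        v0 = rng.uniform(params.v_reset, params.v_th, n)
    elif init == "rest":
        v0 = np.full(n, params.v_rest)
        rng.uniform(params.v_reset, params.v_th, n)  # keep stream aligned
    else:
        raise ValueError(f"unknown init {init!r}")
    noise = (rng.normal(0.0, params.sigma_noise, (n_steps, n))
             if params.sigma_noise > 0 else np.zeros((n_steps, n)))

    # CSR of postsynaptic targets
    post = [np.nonzero(model.syn_adjacency[j])[0] for j in range(n)]
    ptr = np.zeros(n + 1, dtype=np.int64)
    for j in range(n):
        ptr[j + 1] = ptr[j] + post[j].size
    idx = (np.concatenate(post).astype(np.int64) if ptr[-1] > 0
           else np.zeros(0, dtype=np.int64))

    edge_a, edge_b = model.gap_edges
    stim_mask = np.zeros(n, dtype=np.bool_)
    if stim.mode == "single-neuron":
        stim_mask[list(stim.target_ids)] = True
    else:
        stim_mask[:] = True
    targets = np.nonzero(stim_mask)[0]

    period_steps = int(round(stim.period / dt))
    pulse_steps = int(round(stim.resolved_pulse_width / dt))
    refrac_steps = int(math.ceil(params.t_refrac / dt))
    v_out = (np.empty((n_steps, n)) if record_voltage
             else np.empty((0, 0)))

    st, si, n_sp, blowup = run_lif(
        v0, n_steps, dt, params.tau, params.g_leak, params.v_rest,
        params.v_th, params.v_reset, refrac_steps, params.g_max,
        params.tau_syn, params.v_inh, params.v_floor, idx, ptr, edge_a, edge_b,
        model.g_gap, sos, stim_mask, stim.amplitude, period_steps,
        pulse_steps, noise, v_out)
    if blowup:
        raise NumericalBlowupError(
            "membrane voltage left the sanity bound; check parameters")

    spikes = [np.sort(st[si == i]) for i in range(n)]
    n_epochs = int(duration // stim.period)
    windows = [(k * stim.period, (k + 1) * stim.period)
               for k in range(n_epochs)]
    return SimResult(spike_times=spikes, epoch_windows=windows,
                     stimulated_ids=targets,
                     gap_neighbor_ids=model.gap_neighbors(targets),
                     duration=duration, dt=dt,
                     voltage_traces=v_out if record_voltage else None)


def classify_epochs(result: SimResult,
                    population: Literal["stimulated", "gap-neighbors",
                                        "all"] = "stimulated"
                    ) -> EpochResponseSummary:
    """Class each (neuron, epoch) pair as no-fire / tonic / burst by its
    spike count in the stimulation-pulse period and report the fractions
    over the selected population."""
    if population == "stimulated":
        ids = result.stimulated_ids
    elif population == "gap-neighbors":
        ids = result.gap_neighbor_ids
    elif population == "all":
        ids = np.arange(result.n_neurons)
    else:
        raise ValueError(f"unknown population {population!r}")
    if len(ids) == 0:
        raise ValueError(f"population {population!r} is empty")

    edges = np.array([w[0] for w in result.epoch_windows]
                     + [result.epoch_windows[-1][1]])
    counts = []
    total_spikes = 0
    for i in ids:
        t = result.spike_times[i]
        t = t[(t >= edges[0]) & (t < edges[-1])]
        counts.append(np.histogram(t, bins=edges)[0])
        total_spikes += t.size
    c = np.concatenate(counts)
    span_s = (edges[-1] - edges[0]) / 1000.0
    return EpochResponseSummary(
        p_no_fire=float(np.mean(c == 0)),
        p_tonic=float(np.mean(c == 1)),
        p_burst=float(np.mean(c >= 2)),
        mean_rate=total_spikes / (span_s * len(ids)),
        population=population,
        n_pairs=int(c.size))


def sweep_gap_parameters(M_values: Sequence[float],
                         g_gap_values: Sequence[float],
                         repeats: int,
                         stim_frequencies: Sequence[float],
                         seed: int,
                         n_neurons: int = 100,
                         syn_prob: float = 0.5,
                         params: LifParams | None = None,
                         conditions: Sequence[str] = ("single-neuron",
                                                      "all-neurons"),
                         duration: float = 2000.0) -> pd.DataFrame:
    """Grid sweep over gap degree M, gap strength, and stimulation frequency.

    For every (M, g_gap, frequency, condition) cell, ``repeats`` independent
    networks are simulated and the per-epoch response summaries averaged.
    Returns a long-format table with one row per cell and population.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    params = params or LifParams()
    root = np.random.SeedSequence(seed)
    rows = []
    for M in M_values:
        for g in g_gap_values:
            for freq in stim_frequencies:
                for cond in conditions:
                    pops = (["stimulated", "gap-neighbors"]
                            if cond == "single-neuron" else ["all"])
                    acc: dict[str, list[EpochResponseSummary]] = {
                        p: [] for p in pops}
                    for _ in range(repeats):
                        s_net, s_sim = root.spawn(2)
                        try:
                            net = build_network(n_neurons, syn_prob, M, g,
                                                _child_seed(s_net))
                            stim = StimProtocol(mode=cond, target_ids=(0,),
                                                frequency=freq,
                                                duration=duration)
                            res = simulate(net, params, stim,
                                           seed=_child_seed(s_sim))
                        except NumericalBlowupError as err:
                            raise NumericalBlowupError(
                                f"blow-up at M={M}, g_gap={g}, "
                                f"freq={freq}, condition={cond}") from err
                        for p in pops:
                            if p == "gap-neighbors" and \
                                    len(res.gap_neighbor_ids) == 0:
                                continue
                            acc[p].append(classify_epochs(res, p))
                    for p, summaries in acc.items():
                        if not summaries:
                            continue
                        rows.append({
                            "M": M, "g_gap": g, "freq": freq,
                            "condition": cond, "population": p,
                            "p_no_fire": np.mean(
                                [s.p_no_fire for s in summaries]),
                            "p_tonic": np.mean(
                                [s.p_tonic for s in summaries]),
                            "p_burst": np.mean(
                                [s.p_burst for s in summaries]),
                            "mean_rate": np.mean(
                                [s.mean_rate for s in summaries]),
                            "repeats": len(summaries),
                        })
    return pd.DataFrame(rows)
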