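# Methods

This note documents the model equations, the package's modeling decisions,
the synthetic generator's scope, and the tolerances used by the validation
suite. Everything here is stated in the package's own terms; the test suite
(`tests/`) and the acceptance script (`scripts/acceptance.py`) implement
exactly these definitions.

## 1. Network model

Subthreshold membrane dynamics of neuron *i* (voltages in mV, time in ms,
currents/conductances in dimensionless model units):

```
tau dV_i/dt = g_L (V_rest - V_i) + I_inh,i + I_gap,i + I_ext,i(t) + I_noise,i
```

with defaults `tau = 1`, `g_L = 0.4`, `V_rest = -65`. Integration is forward
Euler at `dt = 0.1 ms`.

**Inhibitory synapses.** `I_inh,i = g_inh,i(t) (V_inh - V_i)` with reversal
`V_inh = -75 mV`; each presynaptic spike increments `g_inh` by
`g_max = 0.03` and the conductance decays with `tau_syn = 10 ms`. Directed
connections are drawn independently with probability `syn_prob` (default
0.5). The conductance-based form with a hyperpolarizing reversal guarantees
the synapses act inhibitory for all attainable voltages; a fixed-sign
current term would flip sign (and become excitatory) whenever
`V < V_rest`, which contradicts the intended role of the connections.

**Gap junctions.** Symmetric edges are placed so per-neuron degrees
approximate draws from `Normal(M, M/3)` (rounded, clipped to `[0, n-1]`).
The gap current is

```
I_gap,i = - sum_j J_ij F(V_i - V_j),    J_ij in {0, g_gap}
```

where `F` is a causal 10th-order Butterworth low-pass at 30 Hz (applied as
cascaded biquads inside the integrator). The low-pass reflects the
empirical property of electrical synapses that slow potentials transmit
efficiently while fast spikes are strongly attenuated. Because `F` is
linear and all filter states start at zero, the per-edge filtering is
computed as per-neuron filtering plus differencing
(`F(V_i - V_j) = F(V_i) - F(V_j)`), which reduces the cost from O(edges) to
O(neurons) filter evaluations per step.

**Spiking.** When `V` crosses `v_th` a spike is recorded, `V` is reset to
`v_reset = -65 mV` and held for the 1.5-ms refractory period (synaptic
conductances keep decaying). The threshold default is `v_th = -64 mV`:
with the published drive amplitude `c = 0.7` and leak `g_L = 0.4`, the
maximal steady-state depolarization from rest is `c / g_L = 1.75 mV`, so a
threshold more than ~1.75 mV above rest can never be reached by the pulsed
drive and the model would be silent for every parameter setting. The
1-mV threshold-above-rest operating point, together with per-step noise
`sigma_noise = 0.2`, produces the full qualitative repertoire the simulator
is meant to exhibit: burst probability of gap-coupled neighbors increases
with both gap degree `M` and strength `g_gap`, is much higher under 10-Hz
than 40-Hz stimulation (5-ms vs 2-ms pulses), and is higher in sparser
(50-neuron) than denser (100-neuron) networks.

**Voltage floor.** `v_floor = -80 mV` bounds the membrane from below
(disable with `-inf`). The filtered diffusive coupling carries a phase lag,
so at moderately large `g_gap × degree` the linearized network has growing
oscillatory modes; the spike/reset rule bounds voltage from above but
nothing bounds it from below, and the unstable mode otherwise drives
excursions to hundreds of negative millivolts that no physical membrane
shows. The floor sits just below the inhibitory reversal and leaves
ordinary dynamics untouched. A genuine single-step divergence (e.g. a
pathological input current) is still detected: the ±1000 mV sanity check
runs before the clamp and raises `NumericalBlowupError`.

**Stimulation and epochs.** Pulse widths default to 5 ms at 10 Hz and 2 ms
at 40/80 Hz, amplitude 0.7, in `single-neuron` (one target) or
`all-neurons` mode. Each pulse period is an *epoch*; a neuron's epoch is
classed by spike count: 0 → no-fire, 1 → tonic, ≥2 → burst.
`sweep_gap_parameters` averages these class probabilities over repeated
independent networks per grid cell (seeds derived via
`numpy.random.SeedSequence` spawning, so cells are statistically
independent and the whole sweep is reproducible from one seed).

## 2. Spike-train metrics

- **Unit classification:** peak-to-valley ratio > 1.5 *and* half-valley
  width > 250 µs → putative excitatory (pExc); both below → putative
  inhibitory (pInh); mixed → unclassified.
- **Unit filter:** overall rate > 0.5 Hz and ≥1 spike in every required
  session.
- **Valid trials:** interaction onset > 2 s after the previous
  interaction's end, duration > 1 s; overlapping events are rejected as
  malformed input.
- **Bursts:** maximal runs of ≥2 consecutive spikes whose internal ISIs are
  all < 12 ms (strict inequality; threshold configurable). The burst-spike
  proportion is the fraction of spikes belonging to any burst. When a
  proportion is computed over a set of windows, bursts are detected within
  each window independently so spikes across window boundaries never group.
- **Δburst:** burst-spike proportion pooled over a target's valid-trial
  windows minus the proportion over the rest windows.
- **Shuffle null:** per interaction window, the observed spike count is
  redrawn uniformly over the window and the pooled burst-spike proportion
  recomputed; this conserves every window's spike count exactly and
  isolates burst *structure* from rate differences.
- **d′:** `(mu1 - mu2) / sqrt((sd1^2 + sd2^2)/2)`, undefined (raises) when
  both SDs are zero.
- **Opto-tagging:** per light pulse, spikes in the first 20 ms vs the last
  20 ms of the 100-ms inter-pulse interval; one-sided paired t-test at
  α = 0.05. A zero-variance difference is tagged only when every pulse
  shows a strictly positive difference and ≥10 pulses exist.

## 3. Selectivity

Per unit, trial firing rates with factors target ∈ {E, O, S} and side ∈
{L, R}. The three target pairs (S–E, S–O, E–O) are flagged by Tukey's HSD
at α = 0.05; the L–R flag comes from the side main effect of a type-II
two-way ANOVA (`rate ~ C(target) + C(side)`). A unit is X-specific when
both pairwise comparisons involving X are significant; the information
number counts significant flags among the four. Venn summaries report the
eight regions over the three target-pair flags, a side overlay, and
marginal proportions.

**Known property (intentional test failure).** Tukey's HSD controls the
*family-wise* error rate at α across the three comparisons; the per-pair
false-positive rate on null data is therefore ≈0.02, not 0.05 (measured:
0.014–0.026 per pair on 500 null units; the side-ANOVA flag, a single
test, sits at ≈0.05 as expected). The acceptance check asserting a per-pair
rate of ≈0.05 fails for the three target pairs and is retained as an honest
negative result rather than silently replacing Tukey with unadjusted
pairwise tests. Sensitivity on large planted effects is 1.0 for all flags.

## 4. LFP

- **Bandpass:** 200th-order windowed-sinc FIR (Hamming), applied zero-phase
  with `filtfilt`; traces must exceed 3× the filter order.
- **Phase:** angle of the Hilbert analytic signal of the (mean-removed)
  band-limited trace.
- **Phase locking:** spike phases sampled at the nearest LFP sample;
  locking strength is the resultant length `R = |mean(exp(i*phase))|`,
  preferred phase its angle. For von Mises–distributed phases the
  population value is `I1(kappa)/I0(kappa)`.
- **Band power:** Welch periodogram (1-s Hann windows, 50% overlap)
  integrated over the band; a pure in-band sinusoid of amplitude A yields
  ≈A²/2.
- **Peri-event z-scores:** band power in (−1.5, −0.5) s and (+0.5, +1.5) s
  around each event, z-scored against band powers of non-overlapping 1-s
  segments tiled over the rest windows.

## 5. Synthetic generator

`generate_session` builds a rest period (300 s) followed by three
interaction sessions (600 s each: E-E, S-O, O-S) with nose-poke events on
alternating sides; ~20% of events are planted invalid (too short or too
close to their predecessor). Units are piecewise-constant Poisson processes
whose rate depends on the condition timeline (R outside valid trials);
burst structure is planted by doublet injection (each parent spike spawns a
partner 4–10 ms later with condition-dependent probability, highest for S),
and inhibitory-class units are phase-coupled to the theta carrier by von
Mises thinning (acceptance ∝ exp(kappa·(cos φ − 1)); the thinned phases are
von Mises, so the planted resultant is `I1(kappa)/I0(kappa)`). The LFP is a
sum of RMS-normalized band-limited noise carriers plus white noise, with
the gamma carrier's amplitude scaled by `post_event_gain` for 1 s starting
0.5 s after each valid-trial onset. Waveform features are drawn from two
clusters truncated away from the (1.5, 250 µs) classification boundary so
the planted class is recoverable by construction for every seed.

Closed-form expectations used in validation:

- **Burst proportion of a doublet-injected Poisson train** (rate r,
  doublet probability p, threshold θ):
  `E ≈ (2p + (1-p)(1 - e^{-2rθ})) / (1+p)`.
- **Shuffle-null burst proportion for n uniform spikes in a window of
  length W:** interior spikes escape bursts with probability
  `(1 - 2θ/W)^n`, edge spikes with `(1 - θ/W)^n`, giving
  `E = [(n-2)(1-(1-2θ/W)^n) + 2(1-(1-θ/W)^n)]/n` — the finite-window
  refinement of the Poisson `P(ISI<θ) = 1 - e^{-rθ}`.

**Scope and limits.** The generator plants *statistical* structure (rates,
burst proportions, selectivity, coupling, band power), not biophysics: no
waveform shapes are synthesized beyond two feature clusters, spike trains
are conditionally Poisson rather than integrate-and-fire, and LFP carriers
are band-limited noise rather than network-generated fields. It validates
the analysis chain, not the network model; the simulator and generator are
linked only through the shared burst/epoch definitions.

## 6. Validation tolerances and sizes

All tolerances were fixed from the closed-form oracles and one
characterization run *before* being frozen into tests; none were adjusted
to outcomes afterward.

| Check | Size | Tolerance |
|---|---|---|
| Monotonicity (Spearman vs M, g_gap) | 6×6 grid × 20 repeats, 10 Hz | ρ > 0, p < 0.01 |
| 10 Hz vs 40 Hz | cells with M ≥ 5, g ≥ 0.2, 20 repeats | every cell, strict |
| Density 50 vs 100 neurons | 3×3 grid × 10 repeats, both modes | grand mean ≥ |
| Zero-coupling control | 20 neurons, 2 s | exact array equality |
| Burst detector vs brute force | 1000 random trains | exact |
| Shuffle null vs closed form | 5×10 s windows at 20 Hz, 200 perms | 2 Monte-Carlo SEs |
| d′ closed forms | — | exact / 1e-12 |
| Phase locking, κ ∈ {0.5, 1, 2, 4} | 10⁴ spikes | R within 0.02, phase within 5° |
| Selectivity type-I / sensitivity | 500 null / 100 planted units | 0.05 ± 2 binomial SE / > 0.95 |
| Round-trip rates | 40 units, 2100 s | 15% relative |
| Round-trip burst proportions | same | 0.03 absolute |
| Round-trip S-specific fraction | same | 2.5 binomial SE + 0.05; recall > 0.8 |
| Round-trip gamma z-score | same | 25% relative of `(g²-1)·A²/sd_rest` |
| Round-trip coupling resultant | same | 0.1 absolute (filtering and the broadband floor attenuate R by ~0.05 below the von Mises value) |

Determinism is enforced throughout: identical seeds give identical
networks, simulations, synthetic sessions, and shuffle draws.
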