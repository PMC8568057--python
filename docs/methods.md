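# Methods

## Modulation formalism

A neuromodulator is identified by a short key (`DA`, `ACh`, ...).  Each
modulated target — an ion-channel conductance, a synaptic amplitude
(`g_max`), or a release probability (`U`) — carries one parameter triplet per
modulator:

| parameter | meaning | range |
|---|---|---|
| `maxMod` | modulation degree at full activation | ≥ 0, finite |
| `mod` | activation flag | {0, 1} |
| `level` | instantaneous modulation level | [0, 1] |

The factor applied to the target is `f = 1 + mod·level·(maxMod − 1)`.  This
is the simplest form that (a) multiplies the target, (b) reaches `maxMod`
exactly at full modulation, and (c) interpolates linearly in the transient
level; `maxMod = 0.6` therefore produces a 40 % reduction at `level = 1` and
a 20 % reduction at `level = 0.5`.  Assumptions worth noting:

- **Linearity in level** is a modeling choice, not a biophysical claim; any
  monotone map of receptor occupancy to effect is compatible with the same
  interface by reshaping the level trace.
- **Several modulators combine multiplicatively** (independent fractional
  effects).  Combination is commutative and associative, so modulator order
  never matters.
- Levels outside [0, 1] are clipped with a logged warning rather than
  raised: transient superposition can legitimately overshoot.  `maxMod < 0`
  is rejected at load, which makes a negative effective conductance
  impossible by construction.
- Modulated `U` is clipped to (0, 1] with a tiny positive floor (1e−6), so
  release-probability modulation can silence but never invert a synapse.

## Surrogate neurons

Three cell types stand in for detailed striatal models on a shared
ball-and-stick morphology (soma 18 µm; two basal dendritic compartments
120 × 2 µm; one axonal compartment 60 × 1 µm; Ra = 150 Ω·cm, Cm = 1 µF/cm²).

Channels are ohmic with Boltzmann gates
`x∞(V) = 1/(1 + exp(−(V − v½)/k))` and first-order kinetics; time constants
are constant or carry a Gaussian bell in V.  The SPN complement (shared by
dSPN and iSPN; the types differ only in their receptor maps):

| channel | gates | role |
|---|---|---|
| `naf` (0.25 S/cm², soma+axon) | m³ (v½ −38, k 6, τ 0.1 ms), h (v½ −52, k −6, τ 0.3 + bell 5 ms) | spike generation |
| `kdr` (0.04, soma+axon) | n² (v½ −25, k 12, τ 3 ms) | repolarization |
| `kas` (0.008, soma+dendrite) | a² (v½ −42, k 8, τ 0.5 ms), b (v½ −60, k −10, τ 250 ms) | slow A-type: near-threshold brake, postpones and spaces spikes |
| `kir` (3e−4, everywhere) | k (v½ −85, k −12, τ 1 ms) | inward rectifier: sets the ~−80 mV down-state rest |
| `leak` (1e−4, E −70 mV) | — | passive |

The FS surrogate carries faster `naf`/`kdr` kinetics (sustaining several
hundred Hz), a weak `kir` (1.5e−4, v½ −75, k −16) and a leak at −60 mV,
resting near −72 mV.  The inward rectifier was added to the FS complement
deliberately: the D1-like dopamine effect on FS interneurons is a
depolarization, and with only `naf` + `kdr` + leak no conductance exists
whose reduction depolarizes the cell at rest.

Behavior (verified by the test suite): SPN surrogates rest in [−85, −75] mV,
are silent without input, and fire regularly above a rheobase of roughly
200 pA; the FS surrogate rests in [−75, −65] mV and out-paces the SPN at
twice rheobase.  The f–I curves are steeper than in real SPNs (the surrogate
lacks the slow AHP/calcium-dependent currents that linearize rates), so
spike-count features behave more switch-like than experiment; population
metrics (percent spiking, mean rate) remain graded because synaptic drive
varies across neurons.

**Default modulation maps** (shipping surrogates for cell-type receptor
tables; directions follow striatal physiology, magnitudes chosen for robust,
clearly visible effects): D1-like on dSPN (kir ×0.7, kas ×0.7, naf ×1.25,
AMPA amplitude ×1.2, release ×1.1) and on FS (kir ×0.4, naf ×1.2) increase
excitability / depolarize; D2-like on iSPN (kir ×1.3, kas ×1.3, naf ×0.8,
AMPA ×0.9) decreases excitability; muscarinic on both SPN types (kir ×0.8,
kas ×0.8) increases excitability.

## Numerics

- **Voltage**: backward (implicit) Euler on the compartment tree, with ionic
  conductances frozen at the current gate state; the linear system is solved
  exactly by Hines elimination (parents precede children).  Unconditionally
  stable.
- **Gates**: exponential Euler — exact for the gate ODE at frozen voltage,
  confined to [0, 1].
- **Units**: mV, ms, nF, µS, nA internally; conductance densities in S/cm²
  are folded into per-compartment µS via the compartment areas.  Currents in
  protocols are pA; synaptic conductances nS.
- **Time step**: 0.025 ms default for single-cell protocols (the
  dt-convergence test shows early spike times shift < 0.5 ms under halving);
  network-scale studies in the test suite use 0.05 ms as their problem size.
- **Resting state**: each cell type is relaxed for 2 s at coarse dt once and
  cached; all runs start from that settled state, so unstimulated traces are
  stationary from t = 0.
- **Spike detection**: upward crossing of −10 mV with a 1 ms dead time,
  online during integration and identically in the offline
  `detect_spikes`.  Surrogate spikes overshoot 0 mV while subthreshold
  events stay below −30 mV, so the threshold is uncritical.
- **Divergence**: a non-finite voltage aborts single runs with the
  compartment and time; in population evaluation the affected candidate is
  flagged and parked while the batch continues, and flagged candidates never
  pass selection.
- **Determinism**: every stochastic stage (placement, wiring, input
  generation, modulatory sources) draws from separately spawned generators
  under one seed; identical inputs give bit-identical traces.  Population
  candidates are integrated side by side as one batch, so results are
  independent of any worker scheduling by construction.

## Synapses and external drive

Synapses are conductance-based double exponentials (AMPA: τ 0.3/3 ms,
E 0 mV; GABA: τ 0.5/8 ms, E −72 mV), normalized so an event of weight w
peaks at w.  Release follows Tsodyks–Markram dynamics: resources `R` recover
toward 1 with `τ_rec`, utilization jumps by `U(1−u)` per spike and decays
with `τ_fac` (`τ_fac = 0` disables facilitation).  Modulation scales
`g_max` (amplitude) and `U` (release probability) through the same triplet
formalism, re-read at every delivery.

External cortical-like drive gives each target neuron `n_synapses`
independent Poisson trains (default 150 at 1 Hz background, raised to 12 Hz
inside the activation window, 2 nS each through its own TM synapse).  Many
weak independent inputs rather than one strong aggregate train keeps
short-term depression in its physiological, mild regime.

## Transients and replay

A transient is a tonic level plus burst (+) / pause (−) events with kernel
`(1 − e^(−t/τ_rise))·e^(−t/τ_decay)`, renormalized to unit peak so the event
amplitude is exactly the peak deviation; the sum is clipped to [0, 1].
Defaults τ_rise = 50 ms, τ_decay = 300 ms are placeholders of the right
order for striatal DA/ACh transients; the cholinergic convention is tonic
0.5 with burst/pause deviations of 0.5.  Replay arrays are resampled to the
simulation grid by zero-order hold and applied to every registered target of
the (cell type, modulator) pair each time step.  A timing-sweep helper
shifts one transient by {−500, −300, −100, +100, +300, +500} ms relative to
a stimulus; the network size for such sweeps is configurable (the examples
use a few tens of dSPNs).

## Adaptive mode

Modulatory neurons are spike sources, not biophysical models.  Each source
spike increments the target's concentration state: `conc ← conc·e^(−dt/τ) +
A·(spikes)`, i.e. an exponential kernel of integral `A·τ` per spike, so an
unsaturated regular train at rate f settles at time-average `A·f·τ` (the
test suite checks 2 %).  The level map is `min(1, conc)` by default; a
saturating `conc/(conc + K)` is available by config.  The exponential kernel
and the hard-min map are the package's own choices among the plausible
options; both are isolated behind `ConcState` so alternatives are local
changes.  Recorded level traces from an adaptive run, replayed through the
replay engine, reproduce the adaptive spikes — the two engines share every
downstream code path.

## Population search

Candidates are sampled independently and uniformly per interval (no
correlation structure and no genetic refinement; the population/selection
loop is deliberately simple).  The control run is computed once and shared —
control features cannot depend on the candidate.  Features are extracted
over the clamp stimulus window only; the registry ships
`spike_count_change`, `mean_rate_change` and `depolarization_mV` and accepts
custom callables.  Acceptance bands are closed intervals, typically mean ±
SD of experimental data; widening a band can only grow the passing set.
Passing sets are kept unranked and serialized to the modulation-file schema:

```json
{"DA": {"ion_channels": {"soma": [{"channel": "kir", "maxMod": 0.7}]},
        "receptors": {"AMPA": {"maxMod": 1.2, "release_mod": 1.1}}}}
```

(one object per set; several sets form a JSON array; loaders tolerate absent
sections and report schema violations with a JSON pointer).

## Networks

Placement draws positions i.i.d. uniform in a cube; fractional compositions
resolve to exact integer counts by largest remainder with declaration-order
tie-break (49.5/49.5/1 % at N = 10,000 gives exactly 4950/4950/100).
Connectivity is Bernoulli(p) per ordered pair within a Euclidean cutoff —
the defaults (SPN→SPN p 0.2 within 100 µm, 0.5 nS GABA; FS→SPN p 0.6 within
150 µm, 2 nS perisomatic GABA) are plausible-order placeholders and fully
config-overridable.  Synaptic delay is 1 ms.  The desk-scale default is 400
neurons in a 300 µm cube with full-scale proportions; the 10,000-neuron
recipe ships as configuration.

## What the surrogates do and do not show

The synthetic study conditions emulate: hyperpolarized SPN down-states,
cortical activation windows, D1/D2-direction dopamine effects, tonic
acetylcholine with burst/pause transients, and spike-driven dopamine in a
small dSPN network.  They do **not** emulate the published, optimized
striatal models (no reconstructed morphologies, no calcium or
calcium-dependent channels, no touch-detection connectivity, no LTS/ChIN
interneurons, no presynaptic nicotinic effects, no plasticity).  Passing
tests therefore demonstrate that the machinery — formalism, search loop,
engines, metrics — behaves correctly and that effect *directions* follow
receptor physiology at desk scale; they make no claim that quantitative
percentages transfer to the full-scale published models.  Problem sizes
used by the direction-of-effect checks: 400-neuron mixed network (DA burst),
30-neuron dSPN network (adaptive), 60-neuron SPN network (ACh pause), five
seeds each, 0.05 ms steps.

## Known limitations

- The SPN surrogate's f–I curve is steep; near-rheobase spike counts jump
  rather than grow smoothly, which makes single-cell spike-count features
  nearly binary.  Criteria on rate or depolarization behave more smoothly.
- The first-spike delay of the SPN surrogate (slow A-type mechanism) is
  milliseconds, not the hundreds of milliseconds seen in large
  reconstructed models, because the electrotonically compact surrogate
  charges quickly.
- Percent-spiking values depend on the input-drive working point; the
  defaults are tuned so the unmodulated network sits mid-range (~30 %),
  leaving headroom in both directions.
- Receptor (synaptic) modulation entries are inert in single-cell clamp
  protocols — there are no synapses to modulate; they take effect in
  network simulations.
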