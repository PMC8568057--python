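# neuromodnet

Phenomenological neuromodulation of conductance-based neuron models and
microcircuits, from single-cell parameter search to network simulation.

Neuromodulators such as dopamine (DA) and acetylcholine (ACh) reshape circuit
dynamics by scaling ion-channel conductances and synaptic parameters through
metabotropic receptors.  `neuromodnet` is for computational neuroscientists
who want to (i) find modulation parameters that reproduce measured single-cell
effects of a neuromodulator, and (ii) play those parameters through a network
simulation — either as predefined modulator transients or driven by the spikes
of modulatory neurons.  It ships with surrogate striatal-like neurons (dSPN,
iSPN and FS interneuron models built on simple ball-and-stick morphologies),
so everything runs out of the box with no external model files.

## The formalism

Every modulated target (a channel conductance `g`, a synaptic amplitude
`g_max`, or a release probability `U`) carries, per modulator `*`, the triplet
`maxMod*`, `mod*`, `level*`.  The applied factor is linear in the
instantaneous level,

```
f = 1 + mod · level · (maxMod − 1),        g_eff = f · g
```

so `f = maxMod` at full modulation (`mod = 1`, `level = 1`), `f = 1` whenever
modulation is inactive, and e.g. `maxMod = 0.6` is a 40 % reduction.  Several
modulators acting on one target combine multiplicatively.  The level can be
set as a constant (*bath application*), follow a precomputed transient per
cell type (*replay* mode: tonic + burst/pause double-exponential kernels), or
be driven by presynaptic spikes through a concentration-like integrator
(*adaptive* mode: `conc ← conc·e^(−dt/τ) + A` per spike, `level = min(1,
conc)`).

The single-cell search (`ModulationSearch`) samples a population of candidate
`maxMod` sets uniformly from user intervals, simulates each under a clamp
protocol with the modulator bath-applied, extracts features of the change
(spike count, firing rate, subthreshold depolarization), and keeps the
candidates inside experimental acceptance bands (typically mean ± SD).

## Worked example

Search for dopaminergic modulation of the dSPN surrogate that raises the
spike count at a near-rheobase current step into a target band:

```python
from neuromodnet import (ModulationSearch, SearchSpace, SearchEntry,
                         SelectionCriterion, ClampProtocol)

space = SearchSpace([
    SearchEntry("kir", "soma", "DA", 0.5, 1.0),      # inward rectifier down
    SearchEntry("kir", "dendrite", "DA", 0.5, 1.0),
    SearchEntry("naf", "soma", "DA", 1.0, 1.3),      # fast sodium up
])
protocol = ClampProtocol.current_step(start_ms=200.0, duration_ms=500.0,
                                      amplitude_pa=220.0)
criteria = [SelectionCriterion.from_mean_sd("spike_count_change",
                                            mean=40.0, sd=8.0)]
search = ModulationSearch("dSPN", space, protocol, criteria,
                          population=20, duration_ms=800.0, dt_ms=0.05)
results = search.fit(seed=42)
print(results.summary())
results.save("modulation.json")   # passing sets, ready for network replay
```

which prints

```
Modulation population search
============================================================
cell type:            dSPN
modulators:           DA
population sampled:   20 (seed 42)
bath level:           1
control spike count:  1 (stimulus window)
passing sets:         16 (80.0 %)
------------------------------------------------------------
    spike_count_change in [  32.000,   48.000]  pass  80.0 %  (population mean   36.050, sd   18.509)
------------------------------------------------------------
    spike_count_change of passing sets:   45.062 +/-    0.854
```

The control run fires a single spike in the stimulus window; 16 of the 20
sampled candidate sets add 32–48 spikes under bath-applied dopamine and pass
the acceptance band, and their parameters are written to `modulation.json`.

At network scale the same modulation file drives cell-type-specific effects.
With the built-in desk-scale striatal recipe (400 neurons, 49.5 % dSPN /
49.5 % iSPN / 1 % FS) and a dopamine burst timed to a cortical activation, the
fraction of spiking dSPNs rises, the fraction of spiking iSPNs falls, and FS
interneurons depolarize — mirroring D1/D2-type receptor physiology:

```python
from neuromodnet import build_network, simulate_replay, SpikeRaster, percent_spiking
from neuromodnet.presets import desk_recipe, replay_da_burst

net = build_network(desk_recipe(400), seed=1)
ctrl = simulate_replay(net, None, 1000.0, dt_ms=0.05, seed=101)
da = simulate_replay(net, replay_da_burst(1000.0, 0.05), 1000.0, dt_ms=0.05, seed=101)
```

The same command surface is available from a shell: `nmn modcell run`,
`nmn network build`, `nmn simulate replay|adaptive`, `nmn analyze` (see
`nmn --help`).

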