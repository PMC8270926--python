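# dexat

Spiking neurons whose firing threshold decays with **two** exponentials —
a fast one and a slow one — and the recurrent spiking networks (LSNNs)
built from them.

## The problem

Recurrent spiking networks acquire a working memory when their neurons
adapt: each output spike raises the firing threshold, which then relaxes
back to baseline, leaving a decaying imprint of recent activity.  With a
single decay time constant (the ALIF neuron), the imprint only survives as
long as `tau_a`, so storing a bit for 1200 ms effectively requires
`tau_a >= 1200 ms` — a hard ask for analog hardware, where the time
constant comes from a physical relaxation process.

The **DEXAT** (double-exponential adaptive threshold) neuron splits the
threshold deviation into two components updated by the same spike train
but decaying independently:

    B_j(t)      = b_j0 + beta_1 b_j1(t) + beta_2 b_j2(t)
    b_ji(t+dt)  = rho_i b_ji(t) + (1 - rho_i) z_j(t),   rho_i = exp(-dt/tau_ai)

A fast component (`tau_a1` ~ 30 ms) gives prompt spike-frequency
adaptation; a slow one (`tau_a2` ~ 200-600 ms) carries memory far beyond
itself: trained with surrogate-gradient BPTT, LSNNs of 10 LIF + 10 DEXAT
neurons hold a bit over delays up to ten times `tau_a2`.  The same
double-exponential arises naturally as the RESET-decay of non-filamentary
oxide memristors, so the package also provides the pipeline that turns a
measured conductance-depression curve into neuron parameters, plus a
model of the device variability such hardware injects.

## What's in the box

| module | contents |
| --- | --- |
| `dexat.neurons` | LIF / ALIF / DEXAT step dynamics, parameter sets, YAML round-trip |
| `dexat.network` | vectorized LSNN simulator (compiled inner loop), weight init, traces |
| `dexat.training` | hand-written surrogate-gradient BPTT, Adam, decision error, design-space sweeps |
| `dexat.tasks` | STORE-RECALL working-memory generator, sequential-image encoder, synthetic digits |
| `dexat.device` | LTD-curve preprocessing and DEXAT fitting, asymmetric nonlinearity, variability extraction/injection, behavioral threshold-modulator and endurance models |

`examples/` holds one short narrative script per capability; a thin
`dexat` CLI (`train`, `generate`, `fit-device`, `variability`) wraps the
same functions.

## Worked example

Train the working-memory network at a desk-scale setting
(`examples/store_recall_training.py`):

```bash
$ python examples/store_recall_training.py
iteration  loss    decision_error
        1  0.6943  0.5156
       10  0.6551  0.4453
       19  0.5558  0.5000
       28  0.4581  0.5000
       31  0.4153  0.3828
       34  0.3306  0.1484
       36  0.2266  0.0469

converged: decision error < 0.05 at iteration 36
```

The network sees a stream of 200 ms characters (random bits encoded by
50 Hz Poisson channel groups), a STORE command marking one of them, and a
RECALL command 600 ms after the STORE; the decision error is the fraction
of held-out trials whose recalled bit is wrong.  Dropping below 0.05
means the bit survives the delay — and the distractor characters filling
it — in the neurons' slow threshold components, not in ongoing activity.

And the device pipeline (`examples/device_fit.py`):

```bash
$ python examples/device_fit.py
parameter   true    fitted
tau_a1      30.00    30.251
tau_a2     300.00   298.651
beta1        0.50     0.527
beta2        0.50     0.501
residual 2-norm: 0.0575
```

A synthetic depression curve with known double-exponential shape is
upsampled, normalized, and fitted with the neuron's free-decay solution;
the recovered time constants (here within ~1% despite 3% multiplicative
noise) become simulator-ready `DEXATParams` via
`DEXATFit.to_neuron_params`.

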