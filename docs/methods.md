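# Methods

## Neuron models

All neurons are discrete-time leaky integrate-and-fire units with step
`delta_t` (default 1 ms).  The membrane follows

    v(t+dt) = alpha * v(t) + I(t),        alpha = exp(-dt/tau_m),

with delta synapses (a presynaptic spike adds its weight to the input
current of the *next* step), reset-by-subtraction (`v -= B` at a spike),
and an absolute refractory period (default 2 ms).  The source experiments
never state the membrane equation, reset rule, `tau_m`, or refractory
period; these follow the standard recurrent-spiking-network lineage the
model builds on (`tau_m` = 20 ms) and are configurable.

Adaptive thresholds low-pass filter the spike train `z` (value `1/dt` at
a spike):

    ALIF:   b(t+dt)  = rho  b(t)  + (1-rho)  z(t),   B = b0 + beta * b
    DEXAT:  b1, b2 updated independently with rho1, rho2,
            B = b0 + beta1 * b1 + beta2 * b2,

`rho_i = exp(-dt/tau_ai)`, `tau_a1 <= tau_a2`.  One spike therefore raises
the threshold by `beta_i (1-rho_i)/dt ~ beta_i / tau_ai`.  Thresholds and
potentials are dimensionless with baseline `b0 = 1`; the device module
maps volts onto this scale by min-max normalization.

**Adaptation strength.** The experiments report time constants but never
the `beta` values.  We parameterize defaults by the per-spike threshold
jump in units of `b0`: 0.1 (fast) + 0.4 (slow) for DEXAT and the matching
total of 0.5 for ALIF.  These were fixed once during pilot training runs
of the working-memory task: jumps of order `b0` suppress firing too
strongly, jumps far below 0.1 leave no usable memory imprint, and
weighting the slow component (which carries the memory) clearly
outperformed an even split.  Helpers (`*_from_spike_jump`) expose the
parameterization.

## Network

Hidden layer = LIF block followed by an adaptive block (ALIF or DEXAT);
dense input, recurrent (zero diagonal, one-step delay), and linear readout
weights, all drawn zero-mean Gaussian scaled by 1/sqrt(fan-in).  The
readout is a leaky integrator of hidden spikes, `y(t+dt) = kappa y(t) +
W_out z(t)`, `kappa = exp(-dt/tau_out)`, `tau_out` = 20 ms (not stated in
the source; configurable).  Class scores are the softmax of the readout
averaged over the decision window.

The vectorized engine and the BPTT reverse pass have compiled (numba)
inner loops; a pure-NumPy loop remains the reference path (used for the
smooth-spike gradient check and threshold-noise injection) and the test
suite pins the two paths to bit-identical outputs.

## Training

Backpropagation-through-time is written out by hand in reverse mode over
the unrolled dynamics.  Gradients flow through the membrane leak, the
reset, the recurrent synapses, both threshold filters, and the readout
leak; the spike derivative is replaced by the pseudo-derivative

    psi = gamma * max(0, 1 - |v - B| / B),      gamma = dampening = 0.3.

Correctness is guarded by a finite-difference check with the hard spike
replaced by a sigmoid (exact derivative, tolerance 1e-5 relative).
Optimization uses Adam at learning rate 0.01 with multiplicative decay
0.8; the decay interval is not stated in the source and is applied every
50 iterations, which consolidated the late phase of working-memory
training in pilots.  Loss is cross-entropy on the window-averaged softmax
readout (two-way for STORE-RECALL, over the RECALL window only).  An
optional quadratic firing-rate penalty and optional global gradient-norm
clipping are available but off by default — in pilot runs neither changed
working-memory convergence rates.
"Convergence" means the decision error on one fixed held-out batch (128
cases, evaluated every iteration) drops below 0.05; training stops there.

## The STORE-RECALL task

A trial is a stream of 200 ms character slots (a random bit per slot,
encoded by one of two 10-channel value groups firing Poisson at 50 Hz),
followed by a 200 ms RECALL command; a 10-channel STORE group fires
concurrently with the character to be remembered.  Working memory is the
STORE-onset to RECALL-onset interval.  The decision window is the RECALL
segment; the target is the stored bit.

Three content decisions matter and were fixed after pilot runs:

* **Distractors.**  The character stream continues through the delay.
  With a silent delay, trained networks solved the task by sparse
  recurrent reverberation (~1-5 Hz delay activity) at *any* adaptation
  time constant, erasing the dependence of performance on `tau_a` that is
  the model's point.  Distractor bits overwrite reverberating activity
  and force threshold-based memory.
* **Concurrent STORE.**  The STORE command overlaps the character it
  marks.  A sequential value-then-STORE layout requires the network to
  buffer every character before knowing whether it matters, and did not
  train within the iteration budget.
* **Randomized STORE position (training only).**  Training batches draw
  the STORE slot uniformly, so delays range from 0 up to the full
  working-memory requirement; evaluation always uses the full delay.
  This is the natural curriculum — short delays are learnable early and
  bootstrap the long ones — and with a fixed full-length delay no run
  converged within 200 iterations.

Batch sizes: 256 for training batches, 128 for the evaluation batch the
decision error is computed on (the source states both numbers in
different sentences; we use each where stated).  Trial length and slot
structure are configurable (`SequenceLayout`); `distractors` and the
curriculum can be switched off.

What the generator does *not* emulate: real sensory noise statistics,
trial-to-trial rate drift, or correlated channel noise — passing the
convergence checks shows the architecture can learn and retain a bit
over seconds under Poisson input, not that it handles natural stimuli.

## Sequential images

28x28 grey images are streamed one pixel per step in row-major order (784
steps).  Input neuron k fires when the grey level crosses its threshold
(80 levels evenly spaced in (0,1)) between consecutive pixels, in either
direction; a cue neuron fires for 56 steps after the image (840 steps
total), marking the readout window.  A deterministic synthetic-digit
generator (class-keyed smooth random-field prototypes plus shift/noise/
contrast jitter) exercises the full pipeline without the external
dataset; an IDX reader is provided for the real one.  The synthetic
classes are linearly well separated and smooth — results on them say the
pipeline is wired correctly, not that the network reaches handwritten-
digit accuracy.

## Device module

`preprocess_ltd` maps a depression curve onto a uniform `delta_t` grid by
linear interpolation and min-max normalizes it; `fit_dexat` fits

    b(t) = baseline + a1 exp(-t/tau_a1) + a2 exp(-t/tau_a2)

(the single-spike free-decay solution of the threshold equations) by
trust-region least squares with 8 log-spaced multi-starts for the time
constants over [dt/10, 100 x span], tau ordering enforced by sorting, and
a flagged result if every start fails.  `DEXATFit.to_neuron_params`
converts curve amplitudes to neuron scaling factors exactly
(`beta_i = a_i dt / (1 - rho_i)`), so a single spike reproduces the
fitted transient.

The asymmetric nonlinearity is implemented as the mean absolute
difference between the depression curve and the mirrored potentiation
curve on a shared normalized abscissa — zero for a symmetric pair,
bounded by 1.  This is one realization of the measure (the source defers
its formula to prior literature) and is isolated behind one function.

Variability: for repeated threshold traces, `eta_i = sigma_i / mu_i` per
timestep and `eta_r = median(eta_i)`; synthesis draws each point from
`N(mu_i, (eta_r mu_i)^2)`; injection perturbs each adaptive neuron's
threshold multiplicatively per step with coefficient of variation
`eta_r`, clipped below at `0.01 b0` to avoid non-physical values.

The behavioral threshold-modulator simulator is event-driven: between
spikes the device conductance relaxes double-exponentially toward its
floor; each spike applies a SET whose outcome is a logistic, increasing
function of the pre-SET conductance (weaker high-resistance state gives a
stronger SET — the coupling that makes consecutive spikes adapt); the
threshold is read through a resistive divider, with defaults calibrated
to a 5x peak-to-floor ratio.  Endurance is modelled as a resistance-
window scale in (0,1], linear or exponential in cycle count, applied to
the adaptation betas.  Both are behavioral stand-ins for circuit-level
simulation, not device physics.

## Numerical choices and problem sizes

Decay factors are precomputed once per parameter set; simulations are
float64 throughout; recurrent diagonals are re-zeroed after each
optimizer step; thresholds are validated positive; non-finite states and
losses raise immediately.  The packaged experiments run the convergence
studies at a 2 ms step (1 ms where stated for the headline working-memory
run), 3 seeds with majority voting and medians — individual surrogate-
gradient runs are stochastic, and roughly two of three seeds converge in
the hardest settings.  Design-space checks use one seed per cell and the
pass/fail pattern, matching how the original sweeps are read.

## Known limitations

* Convergence of the hardest settings (working memory >= 4x the slow time
  constant) is seed-dependent; medians and majorities are the stable
  quantities, single runs are not.
* The STORE-RECALL content decisions above are reconstructions; the
  original task timing is not published in the text.
* The speech-recognition pipeline (MFCC frontend) is out of scope; the
  working-memory and sequential-image paths exercise every model
  component it would use.
* Full-dataset digit classification requires the external MNIST data and
  GPU-scale budgets; the package tests the pipeline on synthetic digits
  at desk scale instead.
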