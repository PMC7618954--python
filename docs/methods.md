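# Methods

`mapspread` models how the neuromodulatory state during learning controls
the *spread of association* across a relational memory map, and provides
the behavioural and pupillometric statistics used to measure that spread
in a two-arm (drug vs placebo) cohort. This note documents the model, the
numerical choices behind it, and what the synthetic-data studies do and do
not establish.

## 1. Spiking network model

### Neurons and synapses

Point leaky integrate-and-fire neurons (1000 excitatory, 250 inhibitory)
with an after-hyperpolarisation (AHP) conductance and conductance-based
AMPA, GABA and NMDA channels:

    tau_m dV/dt = (V_rest - V) + sum_X g_X (V_X - V)

with tau_m = 30 ms, V_rest = -65 mV, threshold -50 mV, reversals 0 mV
(AMPA/NMDA) and -80 mV (GABA/AHP), refractory 5 ms (E) / 2.5 ms (I).
Channel kinetics are first-order with tau_AMPA = 5 ms, tau_GABA = 10 ms,
tau_NMDA = 150 ms, tau_AHP = 100 ms, and the AHP increments by
A_AHP = 5 nS per spike. Connectivity is Bernoulli(5%) between and across
all groups; initial weights w_EE = 0.25, w_EI = 0.35, w_IE = w_II =
0.31 nS; a 100-neuron, 1 Hz Poisson background projects to every E neuron
at 0.1 nS.

The conductances in the membrane equation are dimensionless multiples of
a leak conductance `g_leak` (default 1 nS), so synaptic "currents"
g·(V - V_rev) used by the plasticity rules carry units of nS·mV.

Two structural choices required calibration because the published
parameter set does not jointly fix them:

* **NMDA coupling.** External (sensory and background) synapses drive the
  NMDA channel at full weight, which is what lets a 0.5 nS probe drive
  its assembly to ~30 Hz against the AHP. Recurrent synapses use an
  attenuated NMDA coupling (`nmda_mix = 0.1`): at full recurrent coupling
  the 150 ms channel carries ~30x the AMPA charge and the recurrent loop
  has no balanced regime at the printed weights (it is bistable between
  silence and refractory-limited saturation).
* **Adaptation.** The AHP current is restricted to excitatory neurons.
  With adapting interneurons the network locks into AHP-paced global
  population bursts (population Fano factor ~700 at 5 ms resolution);
  with excitatory-only adaptation — the physiological pattern for
  fast-spiking interneurons — the same network is asynchronous
  (Fano ~4) at a few Hz.

### Integration

The engine integrates the membrane with **exponential Euler** (the exact
update for conductances frozen within a step) at dt = 0.1 ms. Forward
Euler is available as an option but is unstable in the model's operating
regime: the balanced network is a high-conductance state (total
conductance 10-1000x leak), where the forward-Euler step factor
g_tot·dt/tau_m exceeds the stability limit and produces an artifact
oscillation that locks every neuron at its refractory-limited rate.
Synaptic propagation uses a one-step (0.1 ms) delay; Poisson inputs are
Bernoulli per bin. A compiled (numba) kernel performs the full update;
the test suite pins it, spike-for-spike, to a plain-NumPy reference
implementation built from the documented unit operations.

### Co-dependent plasticity

E->E and I->E synapses are plastic; E->I and I->I are static. Weight
changes depend jointly on spike timing (exponential traces; unit
increment per spike) and on low-pass-filtered local synaptic currents:
E(t) filters the magnitude of the NMDA current (tau = 10 ms), I(t) the
GABA current (tau = 100 ms), per postsynaptic neuron.

Excitatory rule, per synapse j -> post, event-driven at spike bins:

    dw = [ A_LTP x+_j S_post E  -  A_LTD y-_post S_j w  -
           A_het yE_post S_post E^2 ] · exp[-(I/I*)^gamma]

with A_LTP = 3e-4, A_LTD = 3e-5, A_het = 1.5e-8, I* = 200, gamma = 3;
trace constants tau_+ = 16.8 ms, tau_- = 33.7 ms, tau_yE = 100 ms.
Traces are read before their increment for the current step's spikes, so
a spike never pairs with itself. The printed trace equations attach the
postsynaptic spike train to the presynaptic trace and vice versa; the
implementation follows the accompanying prose (presynaptic traces driven
by presynaptic spikes), with `as_printed=True` reproducing the literal
pairing, which simply swaps whose trace each term reads.

Inhibitory rule, per synapse j -> post:

    dw = A_ISP (E/I*) ((E - alpha I)/I*) (x_j S_post + y_post S_j)

with A_ISP = 1e-3 and tau_STDP = 20 ms. The current factors are
expressed in units of I*; with raw nS·mV currents the printed learning
rate produces per-event steps of tens of nS on 0.3-0.9 nS weights.

**Units and the operating point.** The learning rates fix a stationary
excitatory-trace level E* = A_LTP·tau_+ / (A_het·tau_yE) = 3360, where
potentiation and heterosynaptic depression cancel for equal pre/post
rates, independent of the gate. The one-shot calibration (run once per
network, after inhibitory balancing) therefore sets two current scales so
that the balanced baseline sits exactly at (E, I) = (E*, I*): excitatory
weights are then stationary, the gate is half-engaged (e^-1) and closes
steeply when local inhibition rises, and with alpha = E*/I* = 16.8 the
same point is the inhibitory rule's fixed point. A naive balance point
of alpha = 1 would pin the baseline inhibitory trace at 3360 = 16.8·I*
(gate e^-4745, permanently shut) and is unusable.

### Embedding protocol

1. **Warm-up** (2 s, plasticity off) from membrane potentials drawn
   uniformly in [V_rest, V_th), avoiding a cold-start synchronous burst.
2. **Assemblies**: six 100-neuron Poisson groups at 2.5 Hz project
   (p = 1) onto six disjoint 100-neuron E subgroups at 0.1 ± 0.01 nS
   (Gaussian, 3-sigma truncation, clipped at 0); intra-assembly I->E
   weights from the six 25-neuron I subgroups are set to 0.9 ± 0.05 nS.
3. **Balancing** (~40 s): the inhibitory rule alone, at a boosted
   learning rate on raw current traces with balance point 0.8, grows
   I->E weights until each neuron's inhibitory current matches its
   excitatory current. Because the rule's updates are spike-gated it can
   overshoot into silence and then generate no corrective events; a
   supervisory step deflates all I->E weights uniformly whenever the
   excitatory rate collapses. Calibration (above) then pins the scales,
   and each neuron's unchanged inhibitory total is re-concentrated onto
   its assembly's designated I subgroup at the printed 0.9 : 0.31 ratio.
4. **Settling** (20 s) with every rule active.
5. **Ring embedding**: E->E weights between ring-adjacent assemblies set
   to (0.43/0.25)x the current mean E-E weight (the printed ratio,
   re-anchored because absolute values are meaningless after the network
   has found its own balance scale); a brief boosted-inhibitory
   rebalance cancels the added excitation; then a bisection search finds
   the minimum inter-nodal I->E scaling that keeps a plasticity-on test
   probe selective (state fully restored after each test). The
   reduced-inhibition condition ("atx") takes exactly that minimum — the
   minimum strengthening that prevents runaway — and settles for 2 s
   with all E->I weights at 97% (restored afterwards); the placebo takes
   9/7 of it (the printed 0.9 : 0.7 ratio) and settles normally.
6. **Probe**: the target assembly's Poisson weights are raised to
   0.5 nS for 3.3 s (2 s baseline recorded first), plasticity on.

Stage durations are chosen so each balancing loop converges while the
post-calibration stages stay near the calibrated operating point (the
open-gate state drifts on a ~10 s timescale through causal-correlation-
boosted potentiation).

### Readouts

Per-assembly rates (100 ms bins), the 6x6 mean weight-change table, and
the **functional overlap**: the percentage of an assembly's neurons whose
mean stimulus-window rate exceeds their own baseline mean + 2 SD (SD over
the baseline's 100 ms bins). A structural variant (fraction of neurons
whose summed incoming weight from the probed assembly grew) is available.
The spread gradient statistic averages stimulus rates over symmetric ring
distances (d = 1: assemblies 2, 6; d = 2: 3, 5; d = 3: 4) and reports the
Spearman correlation with distance plus a strict-ordering flag.

### What the model does and does not reproduce

Reproduced robustly: a stable asynchronous few-Hz baseline; probing the
pre-learning network activates exclusively the driven assembly (~30 Hz vs
~5 Hz baseline); after ring learning, co-activation and probe-induced
weight changes are skewed toward ring-adjacent assemblies, and the
seed-averaged overlap ordering (2,6) > (3,5) > (4) holds. Not reproduced
robustly: the dissociation between the two conditions is weak — the 22%
inter-nodal inhibition difference lies within run-to-run variability at
this network size, and overlap magnitudes are several-fold smaller than
the original report. The published parameter set does not pin down a
unique dynamical regime (units, integrator, NMDA routing and adaptation
assignments are all unstated degrees of freedom); the operating point
used here was selected for the qualitative pre-learning phenomena and
stability, and every downstream number is reported as measured.

## 2. Behavioural statistics

The task is an 11-node ring: each of 11 birds belongs to two contexts,
and the designated correct context of a bird is the room shared with its
clockwise neighbour. For the 6-alternative implicit test:

* **Overgeneralisation errors** — per error trial, a proximal choice
  (link distance 1 from the correct context, either direction)
  contributes +1/N_proximal and a distal choice -1/N_distal, where the
  normalisers count such cues in that trial's option set; the sum is
  divided by the number of *opportunity* trials (error trials offering
  at least one proximal and one distal cue) and scaled to percent.
  Uniform errors give 0 in expectation; an always-proximal policy gives
  +100 only when a single proximal cue is offered (ceiling
  100·E[1/N_prox] ~ 86 under random 6-option sets), and the most
  negative attainable score is -100/N_distal per trial.
* **Mean rank proximity** — mean over error trials of
  link_distance(correct, chosen) + 1; chance under uniform errors is
  exactly 4.0 on an 11-ring (enumeration over the 10 incorrect contexts).
* **Topological distance** — mean rank score of a reconstructed ring
  (bird-bird adjacencies score their true link distance; a bird-scene
  placement scores the distance between the placed and true scene + 1).
* **Bang's blinding index** — 2·(proportion correct guesses) - 1 per
  arm; |BI| <= 0.2 is classified as successful blinding.

Inference: two-sided label-permutation tests on group mean differences
(default 10,000 permutations, add-one p-value estimator) and
bias-corrected (BC) percentile bootstrap of the mean (default 10,000
resamples; z0 from the fraction of resamples below the estimate).

## 3. Pupillometry pipeline

500 Hz recordings; missing (blink) samples are linearly interpolated
before smoothing with a 120 ms Gaussian kernel (interpreted as the SD; an
FWHM reading is available — the original convention is not stated).
Epochs of -0.25 to 10 s around stimulus onsets; trials with > 1000 ms of
interpolated-missing data are dropped; subjects with > 50% of trials
dropped are flagged excluded; normalisation is the percentage difference
from the scan-block mean, baseline correction subtracts the 250 ms
pre-stimulus mean. The oddball-minus-regular contrast per subject feeds a
cluster-based permutation test: pointwise Welch t, two-sided p < 0.05
cluster-forming threshold (critical values interpolated over a Welch-df
grid for speed), cluster mass = sum of |t|, null distribution of the
maximum cluster mass over subject-label permutations. Statistics run on a
downsampled epoch grid (default factor 25, i.e. 20 Hz) after smoothing.

## 4. Synthetic data

The behavioural generator emulates the implicit test: per trial, the
correct response occurs with probability `p_correct` (default 0.25, the
near-chance regime); otherwise an incorrect option is drawn with
probability proportional to exp(-lambda·(d-1)) over link distance d
(lambda = 0: uniform; the proximal bias grows monotonically with lambda;
lambda = 0.2 puts the expected overgeneralisation score near +10).
Option sets are the correct context plus 5 of the remaining 10, sampled
uniformly. The generator does **not** model learning curves, memory
consolidation, option-set structure of the human test (unreported), or
subject-level trait correlations, so passing recovery tests shows the
statistics behave correctly on data with known ground truth — not that
the human effects are reproduced.

The pupil generator produces 500 Hz traces as baseline + slow sinusoidal
drift + AR(1) noise + a gamma-shaped phasic response to every stimulus
(larger for oddballs, ~9% of trials) + an oddball-only tonic plateau over
6-10 s whose amplitude is the group manipulation + Poisson blink
dropouts. Events are spaced 11.5 s so epochs do not overlap, unlike the
real task's ~2.3 s inter-trial intervals; overlap-corrected deconvolution
is out of scope.

Study sizes used by the test suite: group-difference recovery uses 22
subjects x 66 trials per group and 100 replicate experiments;
family-wise-error simulation uses 6 subjects x 8 trials per group and
500 replicates at 300 permutations; effect recovery uses 8 x 16 with a
5%-amplitude tonic plateau (SNR ~3 against the between-subject contrast
noise). All generators are pure functions of their spec and seed.

## 5. Known limitations

* The network-condition contrast (placebo vs reduced inhibition) is not
  statistically separable at n = 1000/250 with the chosen operating
  point; see section 1.
* The assembly-overlap sweep inherits the same fragility: its threshold
  depends on network size, as the original exploration itself notes.
* Eq.-level ambiguities (trace drive terms, current units, kernel width
  convention, option-set composition) are resolved by documented
  defaults with the alternatives exposed as flags.
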