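# Methods

## Network model

The core object is a continuous-time rate network of N = 40 units
(32 excitatory, 8 inhibitory; the 80/20 split is a default, not a
constraint of the code) with subthreshold dynamics

    τ dx/dt = −x + W_rec r + W_in u + noise,     r_i = 1 / (1 + exp(−g_i x_i))

and τ = 100 ms. Dale's law is enforced structurally: the recurrent matrix
is parametrised as `|W_plastic| ⊙ mask`, where the mask has zeros on the
diagonal (no autapses) and carries each *presynaptic* unit's sign in its
column (+1 for the first 32 units, −1 for the last 8) — a neuron's outgoing
synapses share one sign no matter what the optimiser does. Input and
readout weights are constrained nonnegative by taking absolute values, and
only excitatory rates reach the readout `z = W_out r_E`. The readout
weight matrix is stored as (2 × N_E) so that `z = W_out r_E` is
dimensionally consistent.

Simulation uses Euler–Maruyama at dt = 1 ms:

    x(t+Δt) = (1−α) x(t) + α (W_rec r + W_in u) + σ_rec √Δt · N(0,1),  α = Δt/τ

with σ_rec = 0.01 per unit and the Wiener increment scaled by √Δt in
milliseconds. Seeds are explicit arguments everywhere; no global RNG is
consulted. A non-finite state raises an error naming the offending step.

### Dynamic gain

Gain follows a linear ODE forced by the Shannon entropy of the softmaxed
readout (inverse temperature ω = 0.25):

    τ dg/dt = g_tonic − g + γ H(z),     H(z) = −Σ_i p_i ln p_i ∈ [0, ln 2]

Entropy is implemented with the conventional negative sign so the forcing
is nonnegative and gain *rises* with uncertainty, decaying exponentially to
its tonic value (1) when the readout is confident. Gain is a per-unit
vector in the state but is updated uniformly (one scalar broadcast to all
units), modelling a diffuse neuromodulatory broadcast. With γ ≥ 0 and
g(0) = g_tonic, gain never falls below tonic. A static-gain mode freezes g
for a whole trial (used by the gain-sweep and regime analyses).

## Task and training

The change-detection task ramps two evidence channels linearly and
complementarily (u1 + u2 = 1) over a 1 s trial, from [1, 0] to [0, 1] or
mirrored. The target is category 1 while u1 > 0.5 and category 2 while
u1 < 0.5; the single exactly-balanced midpoint step satisfies neither rule
and is excluded from the loss and from accuracy.

Training minimises the per-time-step two-class cross-entropy of
softmax(z) (unit inverse temperature; the ω = 0.25 softmax belongs to the
uncertainty mechanism, not the loss) by backprop-through-time with Adam,
1000 iterations, one trial per batch with direction alternating by
iteration parity, and gain fixed at 1. The recurrence is unrolled at a
coarse step, default dt_train = 100 ms (α = 1). Coarser steps with α > 1
are accepted and applied exactly as written but emit a warning: the
one-step map `x ← (1−α)x + α(...)` is then non-contractive, and in our
experiments networks trained at α = 2 fail to transfer to the 1 ms
dynamics (they latch onto one category, switch in only one direction, and
show inverted gain effects), whereas any α ≤ 1 yields ensembles with
held-out accuracy 0.97 ± 0.02 at dt = 1 ms and all the qualitative gain
effects. Held-out accuracy is always evaluated at the fine simulation
step, over both directions, with fresh noise.

Two training hyperparameters are not part of the published contract and
are exposed with the following defaults: learning rate 1e-2 (reaches
criterion within the 1000 iterations) and initial plastic weights
N(0, 0.1/√N). The small initialisation matters: with O(1/√N) dense
positive initial recurrence, training can lean on the random recurrent
scaffold and produce direction-biased solutions; starting small forces it
to build the task circuitry — two stimulus-selective excitatory clusters,
selectively inhibited, with weak cross-cluster excitation — which is the
solution class all downstream analyses probe.

## Circuit analyses

Because input and readout weights are nonnegative, normalised weights act
as selectivity indices: an excitatory unit's input selectivity is
`W_in[i,0] / (W_in[i,0] + W_in[i,1])`, and an inhibitory unit inherits the
readout selectivity of the excitatory units it inhibits, weighted by
inhibition strength (weighted mean; units with no outgoing weight default
to 0.5 with a warning).

**Switch time** is the first *sustained* departure of argmax(z) from the
initially dominant category (the channel with maximal evidence at t = 0).
The sustained rule is robust to noise flickers; referencing the input
rather than the network's t = 0 choice matters because at the reset state
x = 0 the readout reflects only a trained bias. Trials that never leave
the initial category return no switch; sweep summaries count them as the
full trial duration plus one step. Gain-sweep summaries average switch
times over both directions; the static-gain sweep is run noise-free, since
it probes deterministic attractor structure and noise flicker at high gain
only jitters the sustained-switch estimate.

**Lesions** zero the outgoing recurrent weights of inhibitory units
selected by selectivity threshold (default 0.5) — "dominant" lesions
those targeting the initially dominant excitatory cluster, "competing"
the other side — returning a modified copy and leaving the input network
untouched.

**Oscillation delay.** With balanced input u = [0.5, 0.5] and static gain
1.5, each network starts with the dominant-channel excitatory units and
their like-selective inhibitory partners at rate 0.999 and everything else
at 0.001 (subthreshold states via the inverse sigmoid at the applied
gain). The resulting out-of-phase oscillation silences the dominant
population and then boosts the competing one; the delay is measured
between the dominant population's mean rate first falling below 0.5 and
the competing population's mean rate first exceeding 0.5 *after* that
silencing. Repetitions that do not instantiate this sequence (no
silencing, no boost, or the competing population already above threshold
at the silencing moment) are excluded and counted: they reflect a
different phase relationship, not the silencing-then-boost phenomenon this
measure quantifies. Runs are noise-free, so each network × direction pair
is one deterministic repetition.

## Regime mapping

For each (static gain, Δinput) cell, many noise-free runs start from
uniform-random rates and are classified by whether the summed absolute
rate change per step, Δr = Σ_i |r_i(t) − r_i(t−Δt)|, falls below 1e-2 and
stays there for a 100 ms dwell window within the horizon (defaults: 100
initialisations, 10 s horizon). The absolute sum is essential — a signed
sum cancels to zero at every oscillation reversal — and the dwell window
rejects spurious zero-crossings. Cells report the converged proportion,
the mean time to convergence (converged runs only, with an all-runs
variant), and an oscillation amplitude: the temporal rate variance over
the final window computed only over never-converged runs, so slow
sub-tolerance drift of late-converging runs is not mistaken for
oscillation. All runs in a cell integrate together as one batched matrix
recurrence and stop early once everything has converged.

## Energy landscapes

Probability and energy are linked by the Boltzmann relation; with the
density estimated by a normalised Gaussian KDE (Silverman bandwidth,
exposed in config) the partition function is 1 and, with β = 1,
E = ln(1/p̂). Grid points where the density underflows are capped at a
configurable maximum (default 50; figure-style clipping at 6 is a display
choice and never alters stored values).

The **allocentric** landscape bins PC1 positions (PCA fit on concatenated
γ = 0 firing rates, both directions) into 250 ms windows, pooling samples
across trials within each window. **Neural work** per window is
W_t = −(dE/dx)·s_t with s_t the absolute PC1 displacement across the
window and the gradient the finite difference of that window's energy
between the start and end positions (zero displacement ⇒ zero work).

The **egocentric** landscape applies the same energy construction to
mean-squared displacements MSD(τ0, τ) = ⟨|r(τ0+τ) − r(τ0)|²⟩ over units,
with reference times and lags advancing in 250 ms steps. The printed
protocol (reference times from 1 s, lags to 5 s) is served by extending
simulations to 6 s with the input held at its final value; because the
1 s trial contains the entire morph, analyses of the switch sample
displacements from t = 0 so the transition itself contributes (the
post-switch tail alone is quiescent and carries no gamma ordering).
Energies for different γ conditions are evaluated on one common grid
spanning the union of their supports, and the landscape's area under the
curve (trapezoidal) summarises flattening: conditions that make large
displacements likely have lower energy at large MSD.

Velocity comparisons across γ are made on ensemble-average velocity
curves of the PC1 trajectory (noise-free, both directions), with the
first 300 ms excluded: trials start from the reset state x = 0 and its
~3τ relaxation is not task dynamics.

## BOLD pipeline

Parcel time series (default geometry 375 regions, TR = 2 s) are z-scored
per region within subject (the standardisation is optional), concatenated
across subjects, and decomposed by PCA; subjects' PC time courses are
projections onto the group loadings. Nine event regressors — first two
images of each picture set, the seven images centred on the reported
switch (Δ = −3…+3), and the last two — are built as impulse trains
convolved with a canonical double-gamma HRF (peak delay 6 s, undershoot
delay 16 s, ratio 6, unit peak; all exposed). Each PC time series is fit
by OLS with intercept; an image belonging to several event types
contributes to each of them.

The **block-resampling null** treats the picture set as the exchangeable
unit: each permutation reassigns the sets' switch indices by a random
permutation across sets, rebuilds the seven switch regressors, and refits;
the 95th percentile of the null |β| is the significance threshold. The
permutation loop re-convolves only the switch trains, so thousands of
permutations cost seconds.

**MBD.** The main BOLD displacement of a regressor is its absolute evoked
β; its energy is the surprisal of the probability that the evoked value
differs from zero (at the group level, the complement of a one-sample
t-test p-value across subjects), and the landscape "depth" is energy per
unit displacement, E/|β| — minimal where large displacements are
unsurprising, i.e. at the switch. The reciprocal convention is available
to callers by inverting the ratio.

**Topology.** Signed modularity Q_T rewards within-module positive weight
against a degree-based null (scaled by a resolution parameter) and
penalises within-module negative weight with the standard asymmetric
normalisation (1/v⁺ vs 1/(v⁺+v⁻)). Community detection is a hand-rolled
two-phase Louvain on the (W⁺, W⁻) pair — no installed package provides
signed-resolution Louvain — run repeatedly across a resolution range
(default 0.5–2.0 in steps of 0.1, 500 runs) and collapsed by an
agreement-matrix consensus: the co-assignment probability minus τ = 0.5
is re-clustered (agreement above chance attracts, below repels) until all
runs agree; partitions are compared after first-occurrence relabelling so
label names never matter. A second level re-runs the procedure inside
each first-level module and accepts a sub-split only if it does not lower
global Q_T at resolution 1, so flat structure stays flat. Cartography
(participation coefficient and module-degree z-score) uses positive
weights only, since both definitions assume nonnegative strengths; the
joint 101 × 101 histogram over [0,1] × [−1,1] is correlated bin-wise
across subjects with per-subject combined switch βs, with significance by
subject-label permutation and bins occupied by fewer than 3 subjects
excluded.

## Pupillometry

Traces (1 kHz) are cleaned by masking explicit flags, non-positive
samples (blink dropouts) and velocity spikes, then linearly interpolated;
a trial with more than 40% masked is flagged invalid. Filtering is a
second-order 2.5 Hz Butterworth applied forward-backward so switch-locked
peaks are not delayed; normalisation is a z-score within each 15-image
set, which removes slow baseline drift without touching within-set
structure. Per-image responses summarise a window of 750 ms presentation
plus 500 ms (configurable) from image onset.

The **pre-switch test** contrasts each subject's mean response at
Δ = −3…−1 against their first-image baseline with a one-tailed one-sample
t-test (degenerate all-zero input yields t = 0, p = 0.5 by convention).
The **latency model** keeps trials within ±2 images of the grand median
switch index, fits a per-subject OLS slope of evoked peak on switch index
(subjects need ≥3 qualifying trials and ≥2 distinct indices), and tests
the mean slope < 0 one-tailed at the group level.

## Synthetic cohorts

The pupil generator builds each set as baseline + slow sinusoidal drift +
a switch-locked dilation complex + white noise + blink dropouts. The
dilation kernel is gamma-shaped (peak latency ~900 ms, rising over the
three images before the switch via an envelope peaked at Δ = 0), and the
trial amplitude follows a = a0 + b·(switch_index − 9) with b = −0.2 by
default, mimicking larger dilations for earlier switches. Planted
amplitudes are stated in units of the pipeline's evoked-peak measure: an
internal injection gain (0.70) compensates for the per-set z-scoring and
the overlap of neighbouring dilations under the default drift/noise
levels, so the planted slope is recovered ≈1:1 by the latency model.

The BOLD generator plants three orthonormal spatial maps carrying a
smooth background fluctuation, an HRF-convolved switch-locked component
(event amplitudes [0, .2, .5, 1, .5, .2, 0] over Δ = −3…+3) and a
set-onset component, with near-orthogonal time courses so PCA can
identify them; component amplitudes are solved from target variance
shares (defaults 12/8/5%). The residual is modular noise — three planted
modules with shared AR(1) signals — plus independent AR(1) noise
(φ = 0.3; white-noise mode for calibration). Event schedules mirror the
task: 20 sets of 15 two-second images with eight jittered fixation gaps
(2/4/6/8 s) per set, switch indices ~N(9, 1.5²) clipped to [4, 14]. Both
generators are pure functions of (spec, seed).

What the synthetic cohorts do *not* emulate: pupil foreshortening and
gaze artefacts, luminance coupling, scanner drift and motion, spatial
autocorrelation of parcels, and any nonlinearity of the haemodynamic
response. Passing recoveries therefore certify the pipelines' statistical
machinery — not robustness to those real-data nuisances.

## Numerical notes

- Euler at dt = 1 ms with τ = 100 ms carries an intrinsic first-order
  error of order dt/2τ of the dynamic range: even a pure leak deviates by
  ~1.8e-3 (closed form) from the exact trajectory over 1 s, and trained
  networks add a stiff transient at the switch. Integration accuracy is
  therefore validated on the firing-rate trajectory (sup-norm ≤ 1e-3
  against a 10×-finer RK4 reference with the same zero-order-hold input)
  together with a first-order convergence check (a 10× finer Euler step
  shrinks the subthreshold error ~10×).
- Zero-phase IIR filtering is not exactly idempotent (in-band
  re-attenuation and boundary transients); re-preprocessing agrees in the
  trace interior for deep-passband signals.
- Degenerate statistics (zero-variance samples, constant fits, empty
  lesion sets, isolated graph nodes) resolve by documented conventions
  rather than NaNs, each with a warning where information is lost.

## Problem sizes

Default analysis sizes used by the test suite and the reproduction
script: ensembles of 12–25 trained networks; regime grids of 5 × 9 cells
× 30 initialisations at a 3 s horizon; landscape analyses on 4 networks ×
3 γ conditions with 6 s extended simulations; synthetic cohorts of 6–30
subjects; 200–500 permutations/replicates for calibration checks. All
scale up by argument.
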