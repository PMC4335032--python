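# Methods

## Model

The circuit is an all-to-all network of leaky integrate-and-fire neurons.
Below threshold, τ_m V̇ᵢ = −Vᵢ + Iᵢ with Iᵢ in mV (currents are expressed as
the membrane potential they would sustain); crossing θ emits a spike, resets
V to V_R and silences integration of V (not of the synaptic currents) for
τ_arp. Membrane constants are τ_E = 20 ms and τ_I = 10 ms.

The recurrent current is carried by three channels,
I^rec = I^N + I^A − I^G, each first-order:

    τ_N İ^N = −I^N + X τ_m Σ J δ(t − t_spk)     (NMDA-like, τ_N = 50 ms)
    τ_A İ^A = −I^A + (1−X) τ_m Σ J δ(t − t_spk) (AMPA-like, τ_A = 5 ms)
    τ_G İ^G = −I^G + τ_m Σ J δ(t − t_spk)       (GABA, τ_G = 5 ms)

so one pre-synaptic spike of efficacy J deposits an instantaneous kick
X τ_m J/τ_N on the NMDA channel and (1−X) τ_m J/τ_A on the AMPA channel
(τ_m J/τ_G for inhibitory afferents); each channel then integrates to
exactly its charge share of τ_m J. X depends on the *target*: X_E = 0.7 on
excitatory, X_I = 0.002 on inhibitory neurons, i.e. excitatory cells feel
mostly slow recurrent excitation, inhibitory cells almost only fast. X_I is
part of the canonical parameter set and is used as given.

**Connectivity.** The excitatory sub-network contains p = 6 disjoint memory
representations of f·N_E = 80 cells each (480 selective cells) plus 1120
non-selective cells. Efficacies are block-structured: a selective target
receives J₊ = 0.156 mV from its own representation and J₋ from every other
excitatory source; non-selective targets receive the baseline J_EE = 0.025
from all excitatory sources; E→I, I→E, I→I are uniform (2.5, 3, 4 × J_EE).
J₋ is derived from the balance constraint f J₊ + (1−f) J₋ = J_EE, which
makes the spontaneous state — and the calibration below — independent of
J₊. There are no self-connections: the model is defined all-to-all, but
self-coupling is biologically meaningless and at these sizes its effect is
O(1/N); the block-summed implementation subtracts the would-be self-kick of
any neuron that fired.

**External input.** Every neuron receives a quenched mean current drawn once
from N(μ̄_ext^{E,I}, σ_BG²), σ_BG = 1 mV, plus white noise of amplitude
σ = 0.75 mV (the same σ enters the mean-field transfer function; the model
uses a single fast-noise parameter). A stimulus adds frozen per-neuron
currents to the selective cells only: N(α+β, σ_S²) in its own
representation, N(β, σ_S²) elsewhere; non-selective and inhibitory cells
receive nothing stimulus-specific. Standard experiments use α = 1.5,
β = 1.8, σ_S = 2 mV; the distractor protocols use the weaker α = 0.84,
β = 1.7 regime in which persistent activity usually — but not always —
survives a distractor. Draws are untruncated (negative selective currents
are allowed) and are frozen across trials and epochs, so a given stimulus
always injects the same current into a given neuron; only the fast noise
differs between trials. Quenched draws and fast noise use independent seed
streams.

## Mean-field theory

The stationary rate of a white-noise-driven LIF neuron is

    Φ(μ, σ) = [ τ_arp + τ_m √π ∫_b^a erfcx(−u) du ]⁻¹,
    a = (θ−μ)/σ, b = (V_R−μ)/σ,

evaluated with the scaled complementary error function so the integrand
stays finite deep into the subthreshold regime (where the integral overflows
to infinity the rate correctly underflows to zero). The integral uses
fixed-order Gauss–Legendre quadrature (96 nodes; at machine precision
against adaptive quadrature). Quenched averaging over the external current
uses Gauss–Hermite quadrature with 201 nodes, which agrees with adaptive
integration to better than 1e-10 Hz; σ_BG = 0 degenerates to a plain Φ
evaluation.

Self-consistency is solved with a damped Newton–Raphson iteration
(finite-difference Jacobian, step halving, tolerance 1e-10 Hz on the rate
residuals, 200 iterations max) in two parameterizations: the symmetric
spontaneous state (p+2 populations) and the delay state (selective
foreground, selective background, non-selective, inhibitory; γ foreground
representations, γ = 1 throughout). The external means μ̄_ext^{E,I} are not
free parameters: they are calibrated so the spontaneous state sits at
0.75 Hz (excitatory) and 5 Hz (inhibitory); with the rates pinned the two
inversions decouple and a coarse bracketing scan seeds the Newton iteration.

Fixed-point stability is classified by the eigenvalues of the
finite-difference Jacobian of the surrogate dynamics ν̇ = Φ̄(μ(ν)) − ν: all
real parts negative ⇒ stable. The unstable (saddle) solution between the
spontaneous and memory branches is found by Newton from their midpoint. The
continuation over J₊ reuses the previous memory solution as the next guess
and refines the critical J₊ (memory-branch onset, ≈ 0.142 mV at canonical
parameters) by bisection. The noise entering Φ is the external σ only;
recurrent spiking fluctuations are neglected, which is why the spiking
network reproduces the calibrated rates only to ~10–20%.

## Spiking simulation

Euler integration at dt = 0.1 ms. Per step: synaptic currents decay,
non-refractory membranes advance by dt/τ_m (I_tot − V) plus a Gaussian
increment of SD σ√(dt/τ_m), threshold crossings reset and start the
refractory clock, and the spikes emitted this step kick their targets at the
end of the step (one-step transmission delay; the model itself specifies
none, so the convention is fixed and documented here). Because efficacies
are block-structured, the recurrent input of every neuron depends on
pre-synaptic spikes only through per-population counts, giving O(N) cost per
step; a unit test verifies spike-for-spike agreement with a naive
per-synapse dense-matrix simulation on a 30-neuron network. A numba-compiled
kernel and a vectorized numpy path consume the same pre-generated noise
stream and agree to floating-point reordering; both paths are tested.

Trials start from V uniform in [V_R, θ) with zero synaptic currents; the 1 s
pre-stimulus interval washes out the initialization. Population rate traces
are binned at 10 ms for reporting only — no statistic is computed from the
binned traces except the delay-survival flag (below).

## Simplified rate dynamics

The rate model evolves the three current channels of each population with
the same kinetics, driving them with the mean recurrent currents implied by
the instantaneous population rates, and reads rates through the
quenched-averaged transfer function ν_K = Φ̄(I^N + I^A − I^G + μ̄_ext +
stimulus). Stimuli enter as population-mean steps (α+β / β); the σ_S spread
is deliberately not represented here — per-neuron heterogeneity lives in the
spiking model, and the rate model operates on population means. All p
selective representations are integrated individually (p+2 populations, 3
currents each): the four-population foreground/background description is
the special case where the non-cued representations share a rate, and
integrating them separately removes any bookkeeping ambiguity when a
nonmatch stimulus must activate a new representation while the old one is
still active. Euler at dt = 1 ms; halving dt changes 200 ms responses by
< 1%. Because the fixed points of the Euler map are exactly the fixed points
of the ODE, long integrations reproduce the Newton solutions to < 1e-6 Hz
(tested from perturbed initializations under random parameter
perturbations).

The inner loop evaluates Φ̄ through a cubic-spline table (grid step 0.04 mV
over [−40, 90] mV, interpolation error < 1e-7 Hz, direct quadrature outside
the range); the Newton solvers always use the full quadrature.

## Protocols and statistics

All trials: pre 1 s, stimulus 0.5 s, delay 0.7 s, repeated as needed; the
test presentation is 0.5 s. ABBA is sample A, distractor B, repeated
distractor B, match A, with 0.7 s delays throughout; distractor protocols
insert 1–2 distinct non-sample stimuli before a match or nonmatch test.
Distractor identities are sampled without replacement with a seeded RNG.
Each trial restarts from fresh initial conditions.

Responses are spike counts of the 480 selective neurons in the first 200 ms
of a presentation (reported in Hz); delay activity is the rate over the last
200 ms of the delay, chosen symmetric with the response window. A delay
"survives" if the sample representation's mean rate over the last 100 ms of
the delay exceeds 5× the calibrated spontaneous rate; the factor is a
configurable reporting threshold, not part of the dynamics.

Indices are ratios of population-averaged responses: enhancement = M/S over
foreground pairs (neuron in the tested stimulus's representation),
suppression = M/S over background pairs, match–nonmatch = M/NM per group.
Background nonmatch averages *include* the cells of the representation that
is persistently active during the trial: their strong transient response to
the nonmatch is precisely what drives the background M/NM index below one,
matching the single-unit analyses these statistics mirror.

**Suppressed-fraction convention.** A cell/stimulus combination is
suppressed when its trial-averaged match count is strictly below its sample
count, enhanced when strictly above, tied when equal. Ties are almost
exclusively combinations that emitted no spike in either 200 ms window at
realistic trial counts — the quenched Gaussian input puts a substantial mass
of cells far below threshold, and such combinations cannot exhibit either
effect. The headline fraction therefore uses the classified (non-tied)
combinations as denominator, the convention of the experimental literature
in which only measurably responsive cell/stimulus combinations are
classified; the all-pairs fraction and the tie fraction are always reported
alongside. With 20 trials per stimulus the classified fraction is ≈ 0.74
suppressed and the tie fraction ≈ 0.36.

Pearson sample–delay (and match–delay) correlations are computed per neuron
across the stimulus set and averaged over selective neurons; neurons with
fewer than 3 jointly observed stimuli or zero variance are excluded and
counted.

## Problem sizes

The test suite runs the full N = 2000 network: a 10 s spontaneous run, 60
match trials (10 noise seeds × 6 stimuli) for the suppression statistics,
24 ABBA trials and 24 trials per distractor condition in the weak-input
regime, and 12 match trials per σ_S ∈ {2, 3, 4} mV for the heterogeneity
correlations; the acceptance script uses 20 noise seeds per stimulus for the
suppression fraction. Monte-Carlo validation of Φ uses 300 independent
neurons for 7 s at two Euler steps with Richardson extrapolation in √dt,
because the Euler first-passage rate has an O(√dt) bias. A fixture-scaling
helper shrinks N_E, N_I by an integer factor while multiplying all
efficacies by it, preserving every N·J product and hence all mean-field
rates; finite-size fluctuations grow ≈ √factor, so fixture networks are used
only where that is acceptable (CLI round-trip tests and quick protocol
checks).

## What the simulations do and do not show

All inputs are generated by the model itself; there is no external data.
Passing tests show that the implementation is internally consistent (spiking
↔ mean-field ↔ rate dynamics) and that the mechanism produces the
qualitative phenomenology of DMS recordings: coexisting enhancement and
suppression, suppression dominance, repeated-distractor asymmetry, decay of
suppression with intervening stimuli, and decorrelation of sensory from
mnemonic tuning under input heterogeneity. They do not show that the
quantitative values transfer to cortex: persistent-activity rates are high
and homogeneous, spiking is more regular than in vivo, and the proportion of
cells showing match effects is larger than in recordings — known properties
of this model class without short-term plasticity or adaptation, which are
out of scope here.

## Known limitations

* The mean-field noise term ignores recurrent fluctuations, so spiking
  spontaneous rates deviate ~10% from the calibration targets.
* γ > 1 delay states (multiple co-active representations) are not solved.
* The rate model has no trial-to-trial variability; stochastic distractor
  survival exists only in the spiking engine.
* Overlapping or correlated memory representations are not supported.
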