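# Model and methods

## Overview

`inexa` simulates a mixed neuron–astrocyte culture as four coupled layers
advanced synchronously on a 5 ms grid:

1. **Spatial topology.** Neurons (250 by default, 80 % excitatory) and
   astrocytes (0/28/63/107) are placed uniformly in a 750 × 750 × 10 µm
   box with minimum inter-soma distances (10 µm neurons, 30 µm
   astrocytes) enforced by rejection sampling (capped at 10⁵ redraws).
   Directed neuron pairs connect independently with probability
   `exp(−d²/2σ_N²)`, σ_N = 200 µm. Each excitatory synapse tries
   astrocytes in increasing distance order with success probability
   `exp(−d²/2σ_A²)·H(d_A−d)` (σ_A = 150 µm, hard cutoff d_A = 70 µm,
   H(0) = 0); failures at every eligible astrocyte leave the synapse
   "naked". Astrocytes closer than 100 µm are gap-junction coupled.
2. **Neuronal spiking.** Per bin, the rectified propensity λ (noise +
   synaptic input − adenosine depression) yields at most one spike with
   the single-event Poisson probability λe^(−λ).
3. **Synapses.** Discretized Tsodyks–Markram dynamics with recovery rate
   Ω_d = 4.0405 s⁻¹ and facilitation decay Ω_f = 2 s⁻¹; weights are
   Y_max·RR with Y_max = ±0.7 and basal weights drawn from a symmetric
   triangular distribution on [0, 0.7]. Gliotransmitter bound at the
   presynapse interpolates the release increment U* between
   y_base/Y_max and α = 0.7.
4. **Astrocytes.** Per-synapse local areas integrate released resources
   into IP₃ (degradation Ω_IP₃ = 152.3 s⁻¹) and Ca²⁺ (per-bin
   accumulation gain Ω_acc = 0.05); an upward calcium crossing of
   Ca_th = 0.1 binds a fraction g_r = 0.3 of free receptors, recovering
   at Ω_g = 0.077 s⁻¹. Whole cells follow U/A/R state dynamics with
   activation propensity γ = θ·Σβ + M·⟨Ca⟩ (M = 5), threshold
   θ = 0.02·n + 0.205, and memoryless transitions (Δt/τ with
   τ_A = 1.5 s, τ_R = 7 s, τ_U = 5 s). Active astrocytes clamp their
   local IP₃ to 1 and depress every enwrapped synapse by y_Astro = 0.01.

Within a bin the order is: propensities from the previous bin's spikes,
weights and astrocyte states → spike draws → TM update and weights (U*
from the previous bin's g) → local IP₃/Ca/g updates (with clamping) →
UAR propagation and transitions. All one-bin delays follow the t_{k−1}
indices of the update rules; everything else couples within the bin.

## Units of the drive terms

C_max, the synaptic weights and y_Astro are dimensionless. They are
treated as **per-bin spike expectations**: the rectified sum λ enters the
spike probability as λe^(−λ), i.e. the instantaneous rate in s⁻¹ is λ/Δt.
Reading the same numbers as rates in s⁻¹ (so that λΔt ≤ 0.004) makes the
per-spike branching factor of the recurrent network ≈ 0.08 — a silent,
never-bursting culture in which local calcium cannot approach Ca_th and
the entire astrocytic machinery is unreachable. The per-bin reading is
the only one under which the network is active and the astrocyte layer
can engage, and it is consistent with the parameter table listing these
quantities without units.

## Dynamic regimes and the astrocyte initial state

With the default parameters the coupled system is **bistable**:

* an *inert* branch — the recurrent network sits in a stable asynchronous
  high-rate state (~59 Hz/neuron) in which short-term depression holds
  the released fraction so low that local calcium saturates near 0.036
  and every astrocyte propensity stays below threshold; the astrocyte
  layer is permanently dormant;
* an *engaged* branch — a large astrocyte fraction (~40 %) cycles
  U→A→R collectively, sustained by gap-junction propagation, with
  gliotransmission events occurring on forced calcium rises and
  adenosine depression reducing the neuronal rate by roughly a third.

The engaged branch is the regime in which the astrocytic network actually
regulates the neurons; it does not nucleate spontaneously from an
all-dormant start (verified over 300 s). Simulations therefore start the
astrocytes in the active state by default (`astro_init="active"`),
relaxing into the engaged attractor within a few seconds;
`astro_init="dormant"` selects the inert branch explicitly.

Two related consequences of the printed parameters are worth knowing:

* Sustained presynaptic drive alone, at any rate, saturates a local
  area's calcium near 0.077 < Ca_th; per-synapse gliotransmission events
  are triggered through whole-cell activation (IP₃ clamping), not by
  synaptic drive in isolation.
* Because the high-rate neuronal state is insensitive to the noise level
  (it is saturation- rather than noise-limited), the published
  network-level contrasts that presuppose a noise-sensitive uncoupled
  regime — homeostatic range compression relative to the
  process-only model, a noise-dependent sign flip of the astrocyte
  effect, and the ±5/±10 s cross-correlation lag structure of burst
  cycles — do not emerge at these parameter values. The corresponding
  acceptance tests encode those claims faithfully and fail; the
  update-rule, reproducibility and sweep-trend checks pass, as do the
  network-statistics checks except the count-scale cells (synapses per
  astrocyte) whose published comparison band excludes the dominant
  network-draw variance.

## Scenarios

`noise_only` (unconnected neurons), `nn_only` (recurrent network, no
astrocytes), `nn_psa` (astrocyte processes enwrap excitatory presynapses,
no gap-junction propagation β ≡ 0, no adenosine y_Astro = 0) and `nn_a`
(full model, 28/63/107 astrocytes). Three noise levels × (noise_only,
nn_only, nn_psa, three nn_a densities) enumerate the 18 standard
scenarios. TM dynamics are active in every connected scenario; in
`nn_only` U* is the constant y_base/|Y_max|.

## Randomness and reproducibility

All randomness derives from one master seed through named `SeedSequence`
spawn keys: neuron topology (placement, connectivity, base weights),
per-neuron noise, and per-run streams for astrocyte placement/assignment,
spike draws and UAR transitions. Experiments share the neuronal network
across runs and resample the astrocyte network per run. Identical seeds
give bit-identical rasters. Per-neuron noise is a unit triangular draw
scaled by C_max, so the same neurons keep the same relative noise across
noise levels.

## Analysis choices

* **CMA burst detection.** ISI histogram (5 ms bins); the threshold is
  the upper edge of the first bin past the maximum of the cumulative
  moving average curve where it falls below α₁·max, with α₁ chosen from
  the skewness of the CMA curve (<1 → 1.0, 1–4 → 0.7, 4–9 → 0.5,
  >9 → 0.3; table and bin width configurable). Bursts need ≥ 3 spikes.
* **Smoothing.** Normalized (border-corrected) Gaussian convolution: the
  kernel mass is renormalised to the observed grid, so constants are
  preserved exactly at the borders. Spectra use σ = 0.025 Hz on
  run-averaged DFT moduli of mean-centred pooled counts; activity series
  use ρ = 3 s.
* **Cross-correlation.** Normalized estimator r(k) = corr(x_t, y_{t+k})
  with full-sample standard deviations (|r| ≤ 1); positive lag means the
  astrocytic series follows the neuronal one.
* **Activation ratio.** AR = (⟨B⟩/n_A)·(τ_A+τ_R+τ_U)/τ_R. The dwell
  time in the active state is τ_R (the A→R transition fires with
  probability Δt/τ_R), so continuous cycling yields an active fraction
  τ_R/(τ_A+τ_R+τ_U) and AR = 1.

## Problem sizes used in the test suite

Network-statistics checks use the full 250-neuron/107-astrocyte
geometry (10 network seeds, 5 astrocyte resamplings). Dynamical
properties run the full culture at 60 s × 2 runs per scenario and 30 s
per parameter-sweep cell; module-level dynamics tests use reduced
cultures (40–60 neurons). These sizes give sampling errors well below
the effect sizes being asserted while keeping the suite fast.

## Known limitations

* The published figure-level regimes (sparse synchronized bursting with
  noise-dependent rates) are not reproduced by the printed equations and
  parameters under any unit reading we examined; see "Dynamic regimes"
  above for what the model does instead and which tests encode the gap.
* The synapse's spatial location for astrocyte assignment is taken as
  the postsynaptic soma (configurable: pre soma or midpoint); the choice
  shifts naked-synapse fractions by well under the resampling spread.
* No membrane potentials, conduction delays, receptor kinetics,
  extracellular diffusion, or long-term plasticity; astrocyte calcium is
  amplitude-coded only.
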