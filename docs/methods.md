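# Methods

This note records the model, the numerical choices, and the design
decisions behind `cabletune`, and states what the synthetic substrate
does and does not emulate.

## The substrate model

The virtual substrate is a linear chain of `n_compartments = 5` passive
leaky-integrator compartments,

    C_m,i dU_i/dt = -g_l,i (U_i - E_l,i) + Σ_j g_ic,i↔j (U_j - U_i) + I_i^ext,

i.e. the second-order central-difference discretization of the passive
cable equation. All quantities are in dimensionless model units; no
attempt is made to reproduce any hardware's absolute time base or
voltage scale. Synaptic input is current-based with an exponential
kernel `I(t) = A exp(-(t - t_spike)/τ_syn)`; this keeps the system
linear, which both matches the sub-threshold operating regime of the
experiment and makes an exact solution available.

**Integration.** Because the model is linear and time-invariant and all
inputs are exponentials or constants, the dynamics are solved in closed
form instead of stepped: the coupling operator `A = -C⁻¹G` is
diagonalized once per chain (it is similar to a symmetric matrix, so the
eigendecomposition is real and stable) and the response to the initial
deviation, a constant bias current, and each synaptic kernel is
evaluated analytically at every sample time. Synaptic kernels are
truncated once all modes have decayed below ~1e-17 of their peak
(40 max(τ_slow, τ_syn)), which is far below quantizer resolution. The
sampling interval `dt = 0.01` therefore carries no stability constraint;
it only sets the recording resolution (≥ 20 samples per synaptic time
constant). Near-resonant modes (|μ + 1/τ_syn| ≈ 0) use the limiting
`t·exp(μt)` form. A fixed-step exponential-Euler scheme was considered
and rejected: the exact propagator costs the same, is error-free, and
vectorizes over samples, which the genetic-algorithm workloads need.

**DAC → conductance.** Integer codes in [0, 1022] map affinely onto
a conductance range, code 0 → range minimum, 1022 → maximum. The code
range [0, 1022] (not [0, 1023]) follows the convention of the bias-current
DACs being emulated. Calibration constants (documented defaults, chosen
once):

| parameter | default | rationale |
|---|---|---|
| `g_l_range` | (0.8, 1.8) | mid-DAC λ_emp ≈ 0.95 compartments; see below |
| `g_ic_range` | (0.5, 4.2) | idem |
| `syn_amplitude` | 3.5 | h⁰ well clear of quantization (≈ 270 bits) without ADC clipping |
| `τ_syn` | 0.2 | fast synapse relative to membrane (τ_m ≈ 0.2–0.8) |
| `c_m`, `e_l` | 1.0, 0.25 | unit capacitance; rest well inside the ADC span |
| `adc_range`, `adc_bits` | (0, 1.2), 10 | 10-bit clip-and-round quantizer |

The conductance ranges keep the whole DAC plane **leak-dominated**. At
very small leak with strong coupling, an injected charge packet
equalizes across the chain and decays only slowly; the fitted offset *c*
absorbs that plateau and the fitted λ_emp stops responding monotonically
to the leak DAC. Real bias-current DACs cannot reach a near-leakless
membrane either, so the restriction also keeps the emulation inside the
physically meaningful regime. Within these ranges the noiseless λ and h⁰
maps are strictly monotone in both DACs, with margins larger than the
ADC-quantization jitter of the fit (which is why `syn_amplitude` is set
so amplitudes are a few hundred bits: relative quantization error of the
small far-compartment amplitudes scales inversely with the drive).

**Noise.** Trial-to-trial variation is modeled as an
Ornstein–Uhlenbeck (membrane-filtered) Gaussian process per compartment,
stationary SD `noise_sigma = 5.5e-3` (≈ 4.7 ADC steps), correlation time
`0.4` (membrane-time-constant scale), added at the recording stage and
then quantized. Two calibration anchors fixed these jointly: the
STA-mode trial-to-trial SD of λ_emp is ≈ 0.02 (≈ 2% — the run-to-run
error reported for analog multi-compartment measurements), and the
single-shot/STA SD ratio of h⁰ reflects the √10 averaging law. White
(iid per-sample) noise is available via `noise_correlation_time = 0`;
note that under white noise the max-over-window amplitude estimator
compresses the single/STA SD ratio to ≈ 2.9 through extreme-value
statistics of the near-peak plateau, which is why the low-pass model —
also the physically correct description of membrane noise — is the
default. Fixed-pattern mismatch (static log-normal factors per circuit,
`mismatch_sigma`, drawn once per chain instantiation) is off by default,
matching experiments run on one fixed circuit set.

**What the substrate does not emulate:** spiking/threshold dynamics and
adaptation (the protocol is sub-threshold), membrane-shorting switch
topologies, absolute hardware scales (a mid-range length constant of
1.07 compartments and h⁰ = 147 bits are chip-specific; this substrate
sits at ≈ 0.95 compartments and ≈ 270 bits), cross-talk, drift, and
temperature effects. Passing tests therefore validate the *procedure*
and its statistical behavior, not any particular chip's numbers.

## Measurement protocol

Ten spikes (`n_spikes = 10`) are injected into the input compartment
with an inter-spike interval of 10× the slowest relaxation time of the
chain under test (residual deflection < 0.005%, so windows are
independent). The baseline window is the 20% of the interval ending one
sample before the spike; the response window is 75% of the interval
after it. Per window and compartment the pre-spike mean is subtracted
(resting potential at zero), windows are averaged across spikes, and the
amplitude is the maximum of the averaged trace over the response window
— no smoothing. The exponential fit `a·exp(-x/λ)+c` uses nonlinear least
squares over x = 0..4 (all five compartments), initialized at
`a = amp[0]−amp[4], λ = 1, c = amp[4]`, with λ constrained positive.
Exactly flat profiles raise a degenerate-fit error (λ unidentifiable);
the GA maps degenerate measurements to a sentinel fitness of 1e6 rather
than crashing. The multisite protocol concatenates one 10-spike block
per input compartment into a single emulation run and reads the STA
amplitude matrix h[i, j] blockwise.

## Genetic algorithm

The loop per generation: evaluate unevaluated individuals → record →
copy the `n_elites` fittest unchanged (ties broken by population order)
→ tournament-select `n_individuals − n_elites` (k drawn without
replacement within a tournament, with replacement across tournaments) →
one-point crossover of consecutive selected pairs with `p_cx` (offspring
1 takes parent 2's leading segment; orientation locked by test) →
mutate individuals with `p_mut`, genes within a mutated individual with
`p_gen`, step ±2^x with x uniform on 0..9, both sign and x redrawn while
the result leaves [0, 1022]. Defaults: 50 individuals, 5 elites, 30
generations, p_cx 0.5, p_mut 0.1, p_gen 0.5, k 3. Elites keep their
cached fitness by default; `reevaluate_elites` re-measures them each
generation, which on a noisy substrate makes the recorded best fitness
fluctuate despite elitism — the behavior observed on analog hardware.
An optional `stop_fitness` ends the run early once the best individual
reaches it (used for convergence-speed measurements); otherwise exactly
`n_generations` generations run.

Two consequences of the bounded power-of-two mutation worth knowing:
from mid-range genes the ±512 step always leaves the bounds, so the
nine reachable magnitudes renormalize to 2/18 each (exact uniformity
holds only at the boundaries, where one sign direction is always
valid); and fine-tuning to an exact integer optimum requires rare
magnitude-1 mutations (rate ≈ p_mut·p_gen/18 per gene per offspring),
so a deterministic toy objective reaches its exact optimum in roughly
20–60 generations even though it is within a few codes by generation 10.

All randomness — mismatch, trial noise, GA initialization, selection,
variation, and the fresh measurement seed drawn per evaluation —
derives from one master seed through named CRC-keyed `SeedSequence`
streams; equal configurations reproduce bit-identically.

## Grid search and landscape

The grid sweep runs the attenuation protocol at every (g_l, g_ic) DAC
pair with one fresh measurement seed per cell (independent runs, as on
hardware); degenerate fits are flagged as failed cells, never silently
filled. The f₂ landscape applies the two-observable fitness cellwise
(failed cells carry the sentinel), and iso-λ contours use marching
squares on the λ map, returned in DAC coordinates. Default production
resolution is 32×32; tests and the acceptance script use a documented
5×5 grid (codes 0, 255, 511, 766, 1022) for exact monotonicity checks
at desk-scale runtime.

## Problem sizes used in tests and the acceptance script

Trial-to-trial statistics use 1000 repeats (200 for GA targets);
GA convergence and recovery use 10 seeded runs of the Table-default
configuration; the 9-D multisite search is scaled down to 30 individuals
(3 elites) and 12 generations with 3 seeded runs and a 50-repeat target
— sizes chosen so the whole suite reproduces the qualitative findings
(mean-fitness decrease, slower convergence than 2-D) in minutes on one
core. The 9-D search does not reach its measurement noise floor within
12 generations; the generation-to-floor comparison treats such runs as
censored at 13 generations, which still bounds them above the 2-D
search's one-to-two generations.

## Known limitations

- The exact propagator relies on linearity; adding conductance-based
  synapses or active currents would require a stepping integrator.
- The noise model is stationary and additive; real analog noise can be
  state-dependent and include burst/popcorn components.
- The affine DAC transfer is a placeholder for a hardware-specific,
  monotone but nonlinear bias-current characteristic; conclusions that
  depend only on monotonicity transfer, absolute DAC positions do not.
- With `reevaluate_elites` off and a noisy evaluator, a lucky
  measurement can pin an overrated individual in the elite set; the
  two-observable acceptance check therefore re-measures final winners
  independently.
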