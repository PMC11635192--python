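# cabletune

Genetic-algorithm parameterization of passive multi-compartment neuron
chains on a virtual analog substrate.

## The problem

Structured (multi-compartment) neuron models need parameters — leak
conductances, axial/inter-compartment conductances — that are not
directly observable but determine high-level behavior such as how far a
synaptic potential spreads along a dendrite. On analog neuromorphic
systems these parameters are set indirectly through integer DAC codes
for bias currents, the mapping from code to conductance is nonlinear and
circuit-specific, and every read-out is corrupted by analog noise and
ADC quantization. `cabletune` reproduces this whole parameterization
workflow on a desktop: a **virtual analog substrate** emulates a linear
chain of passive compartments with DAC-controlled conductances, noisy
quantized voltage recording, and optional fixed-pattern mismatch, and a
**genetic algorithm** searches the integer DAC space so the chain
reproduces a target observation. The package is for computational
neuroscientists and neuromorphic engineers who want to study or extend
black-box parameter-search strategies for analog substrates without
hardware access.

## The model

Each compartment *i* is a leaky integrator coupled to its chain
neighbours:

    C_m,i dU_i/dt = -g_l,i (U_i - E_l,i) + Σ_j g_ic,i↔j (U_j - U_i) + I_i^ext

the spatial discretization of the passive cable equation. A synaptic
event injects a current kernel `A·exp(-(t-t_spike)/τ_syn)`, producing an
EPSP that attenuates along the chain. The measurement protocol injects
`N_spikes = 10` spikes, computes the **spike-triggered average** (STA)
of the baseline-subtracted windows — suppressing trial-to-trial noise by
≈ 1/√N — extracts the per-compartment peak amplitudes `U_max(x)` in ADC
bits, and fits

    U_max(x) = a · exp(-x / λ_emp) + c

over the compartment index *x* to obtain the empirical length constant
λ_emp (in compartments) and the first-compartment amplitude h⁰.

The genetic algorithm evolves integer genomes (2 DAC genes for a
homogeneous chain, 9 for per-circuit conductances of a 5-compartment
chain) with elitism (5 of 50), tournament selection (k = 3), one-point
crossover (p = 0.5), and a power-of-two mutation (±2^x, x uniform on
0..9, resampled while out of bounds), minimizing one of

    f  = |λ_emp − λ̂_emp|
    f₂ = ((λ̂_emp − λ_emp)/λ̂_emp)² + ((ĥ⁰ − h⁰)/ĥ⁰)²
    f₃ = Σ_ij (ĥ_ij − h_ij)²

where hats mark the target observation and `h_ij` is the EPSP amplitude
recorded in compartment *i* for an input in compartment *j*. A 2-D grid
search over both DACs provides the validation landscape: λ_emp falls
with the leak DAC and rises with the coupling DAC, h⁰ falls with both,
so a λ-only target is degenerate along an iso-λ valley while f₂ pins a
point.

## Worked example

```sh
$ cabletune --seed 1 --out out simulate
lambda_emp = 0.9403 compartments, h0 = 268.8 bits
```

One noisy emulation at mid-range genes (511, 511): the EPSP decays with
a length constant of about 0.94 compartments and peaks at ~269 ADC bits
in the stimulated compartment. Trial-to-trial statistics over 200
repeats per recording mode:

```sh
$ cabletune --seed 1 --out out t2t --repeats 200
       lambda_emp                    h0
             mean       std        mean       std
mode
single   0.916990  0.057808  269.320195  4.471884
sta      0.935027  0.021720  268.713740  1.584956
```

The STA over 10 spikes cuts the spread of both observables roughly
threefold (√10 ≈ 3.16 for ideal averaging), and the single-shot
amplitude is biased slightly high because a max over a noisier trace
overshoots. Finally, a two-observable search against a target recorded
at genes (511, 511):

```sh
$ cabletune --seed 1 --out out evolve --fitness lambda_and_h0
best genes [532, 513] fitness 4.93312e-07 after 30 generations
```

The GA recovers the target's DAC setting to within a few codes — the
residual fitness is far below the trial-to-trial noise floor, i.e. the
solution is indistinguishable from the target within measurement error.

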