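"""Virtual analog substrate: a DAC-controlled chain of passive compartments.

The substrate emulates the measurement conditions of an analog
neuromorphic chip without requiring one: a linear chain of passive
leaky-integrator compartments (the spatial discretization of the cable
equation), whose leak conductance ``g_l`` and inter-compartment
conductance ``g_ic`` are set through integer DAC codes, and whose
membrane voltages are read back through a 10-bit ADC with additive
per-sample Gaussian noise.  The compartment dynamics are

    C_m,i dU_i/dt = -g_l,i (U_i - E_l,i)
                    + sum_j g_ic,i<->j (U_j - U_i) + I_i^ext

with the sum running over the chain neighbours of compartment ``i``.
Synaptic events inject a current-based exponential kernel
``I(t) = A exp(-(t - t_spike)/tau_syn)``, which keeps the system linear.

Because the system is linear and time-invariant, `simulate` integrates it
exactly: the coupling matrix is diagonalized once per chain and the
response to every input (initial deviation, constant bias current,
exponential synaptic kernels) is evaluated in closed form at each sample
time.  ``dt`` is purely a sampling interval; there is no stability limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg

__all__ = [
    "DAC_MAX",
    "SubstrateConfig",
    "ChainModel",
    "StimulusProgram",
    "RecordingSet",
    "SubstrateError",
    "dac_to_conductance",
    "make_chain",
    "simulate",
    "steady_state",
    "slowest_time_constant",
    "draw_noise",
    "quantize",
]

#: Both conductance DACs accept integer codes in [0, DAC_MAX].
DAC_MAX = 1022


class SubstrateError(ValueError):
    """Invalid substrate configuration or stimulus."""


# --------------------------------------------------------------------------
# configuration and domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SubstrateConfig:
    """Constants of the virtual substrate, in dimensionless model units.

    The default conductance ranges and synaptic amplitude are documented
    calibration constants: they place the mid-range DAC setting
    (511, 511) at an EPSP length constant of roughly one compartment
    (the operating regime the measurement protocol is designed for) and
    keep the whole DAC plane inside the leak-dominated regime, where the
    fitted length constant responds monotonically to both DACs.  A
    nearly leakless chain — which a real bias-current DAC cannot reach
    either — would instead let the slow charge-equalization plateau leak
    into the fit offset and fold the length-constant map over.

    Parameters
    ----------
    n_compartments
        Chain length (>= 2).
    c_m
        Membrane capacitance per compartment.
    e_l
        Leak (resting) potential, model volts.
    g_l_range, g_ic_range
        (min, max) conductances reached by DAC codes 0 and 1022.
    syn_amplitude
        Peak synaptic current of one input event.
    tau_syn
        Decay time of the exponential synaptic current kernel.
    dt
        Sampling interval of the recorded traces.
    adc_range
        (v_lo, v_hi) span of the voltage quantizer.
    adc_bits
        Quantizer resolution; traces are integer codes in [0, 2**bits - 1].
    noise_sigma
        Stationary SD of the Gaussian trial-to-trial membrane noise
        added to every recorded sample (model volts).  The default
        (~4.7 ADC steps) is calibrated so the STA-mode trial-to-trial
        SD of the fitted length constant is about 2% — the relative
        run-to-run error reported for analog multi-compartment
        measurements.
    noise_correlation_time
        Correlation time of the membrane noise (an Ornstein-Uhlenbeck
        process per compartment), default of the order of the membrane
        time constant.  Analog membrane noise is low-pass filtered by
        the membrane itself, so correlated noise is the faithful
        default; 0 gives white (iid per-sample) noise.
    mismatch_sigma
        Relative SD of the static per-circuit fixed-pattern factors
        applied to each realized conductance (0 disables mismatch).
    """

    n_compartments: int = 5
    c_m: float = 1.0
    e_l: float = 0.25
    g_l_range: tuple[float, float] = (0.8, 1.8)
    g_ic_range: tuple[float, float] = (0.5, 4.2)
    syn_amplitude: float = 3.5
    tau_syn: float = 0.2
    dt: float = 0.01
    adc_range: tuple[float, float] = (0.0, 1.2)
    adc_bits: int = 10
    noise_sigma: float = 5.5e-3
    noise_correlation_time: float = 0.4
    mismatch_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.n_compartments < 2:
            raise SubstrateError("n_compartments must be >= 2")
        for name in ("g_l_range", "g_ic_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo < hi):
                raise SubstrateError(f"{name} must satisfy 0 < min < max")
        if self.c_m <= 0:
            raise SubstrateError("c_m must be positive")
        if self.tau_syn <= 0:
            raise SubstrateError("tau_syn must be positive")
        if self.dt <= 0:
            raise SubstrateError("dt must be positive")
        if self.adc_bits < 1:
            raise SubstrateError("adc_bits must be >= 1")
        v_lo, v_hi = self.adc_range
        if not v_lo < v_hi:
            raise SubstrateError("adc_range must satisfy v_lo < v_hi")
        if self.noise_sigma < 0 or self.mismatch_sigma < 0:
            raise SubstrateError("noise/mismatch SDs must be non-negative")
        if self.noise_correlation_time < 0:
            raise SubstrateError("noise_correlation_time must be non-negative")

    @property
    def adc_codes(self) -> int:
        return 2**self.adc_bits

    @property
    def adc_step(self) -> float:
        """Volts per ADC code ("one bit")."""
        v_lo, v_hi = self.adc_range
        return (v_hi - v_lo) / (self.adc_codes - 1)


@dataclass(frozen=True)
class ChainModel:
    """A realized compartment chain: one concrete set of circuit values.

    ``g_l = 0`` is tolerated (leakless chains conserve total charge and
    are useful as a diagnostic limit); inter-compartment conductances and
    capacitances must be strictly positive.
    """

    g_l: np.ndarray
    g_ic: np.ndarray
    c_m: np.ndarray
    e_l: np.ndarray
    mismatch_factors: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("g_l", "g_ic", "c_m", "e_l"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.g_l.size
        if n < 1:
            raise SubstrateError("chain needs at least one compartment")
        if self.g_ic.size != n - 1:
            raise SubstrateError("g_ic must have one entry per edge (n - 1)")
        if self.c_m.size != n or self.e_l.size != n:
            raise SubstrateError("c_m and e_l must have one entry per compartment")
        if np.any(self.g_l < 0):
            raise SubstrateError("leak conductances must be non-negative")
        if self.g_ic.size and np.any(self.g_ic <= 0):
            raise SubstrateError("inter-compartment conductances must be positive")
        if np.any(self.c_m <= 0):
            raise SubstrateError("capacitances must be positive")

    @property
    def n_compartments(self) -> int:
        return self.g_l.size

    def conductance_matrix(self) -> np.ndarray:
        """Dense symmetric conductance matrix G with G @ U the total
        passive current out of each compartment (leak + coupling)."""
        n = self.n_compartments
        G = np.zeros((n, n))
        np.fill_diagonal(G, self.g_l)
        for i, g in enumerate(self.g_ic):
            G[i, i] += g
            G[i + 1, i + 1] += g
            G[i, i + 1] -= g
            G[i + 1, i] -= g
        return G


@dataclass(frozen=True)
class StimulusProgram:
    """Synaptic events plus an optional constant bias current.

    ``events`` is a sequence of (spike_time, target_compartment) pairs in
    ascending time order; each triggers the exponential synaptic kernel
    on its target.  ``bias_current`` (one entry per compartment) models a
    constant current injection, used e.g. for steady-state checks.
    """

    events: tuple[tuple[float, int], ...]
    total_duration: float
    bias_current: np.ndarray | None = None

    def __post_init__(self) -> None:
        events = tuple((float(t), int(c)) for t, c in self.events)
        object.__setattr__(self, "events", events)
        if self.total_duration <= 0:
            raise SubstrateError("total_duration must be positive")
        times = [t for t, _ in events]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise SubstrateError("spike times must be sorted ascending")
        if any(not (0 <= t < self.total_duration) for t in times):
            raise SubstrateError("spike times must lie in [0, total_duration)")
        if self.bias_current is not None:
            object.__setattr__(
                self, "bias_current", np.asarray(self.bias_current, dtype=float)
            )


@dataclass
class RecordingSet:
    """Quantized multi-compartment voltage traces from one emulation run.

    ``traces`` has shape (n_compartments, n_samples) and holds integer
    ADC codes in [0, 2**adc_bits - 1]; amplitudes derived from them are
    reported in "bits" (code differences).
    """

    traces: np.ndarray
    dt: float
    meta: dict = field(default_factory=dict)

    @property
    def n_compartments(self) -> int:
        return self.traces.shape[0]

    @property
    def n_samples(self) -> int:
        return self.traces.shape[1]


# --------------------------------------------------------------------------
# DAC transfer and chain realization
# --------------------------------------------------------------------------


def dac_to_conductance(dac: int, value_range: tuple[float, float]) -> float:
    """Map an integer DAC code to a conductance, affinely and monotonically.

    ``g = min + (dac / 1022) * (max - min)``; code 0 gives the range
    minimum and code 1022 the maximum.
    """
    lo, hi = value_range
    if not lo < hi:
        raise SubstrateError("conductance range must satisfy min < max")
    d = int(dac)
    if not 0 <= d <= DAC_MAX:
        raise SubstrateError(f"DAC code {d} outside [0, {DAC_MAX}]")
    return lo + (d / DAC_MAX) * (hi - lo)


def make_chain(
    genes: Sequence[int],
    config: SubstrateConfig,
    mismatch_seed: int | np.random.Generator | None = None,
) -> ChainModel:
    """Realize a chain from integer DAC genes.

    Two genes set one (g_l, g_ic) pair broadcast over the whole chain;
    ``2 n - 1`` genes set the n leak conductances followed by the n - 1
    inter-compartment conductances individually.  With
    ``config.mismatch_sigma > 0`` every realized conductance is
    additionally multiplied by a static log-normal fixed-pattern factor
    drawn once from ``mismatch_seed``.
    """
    genes = [int(g) for g in genes]
    n = config.n_compartments
    if len(genes) == 2:
        gl_genes = [genes[0]] * n
        gic_genes = [genes[1]] * (n - 1)
    elif len(genes) == 2 * n - 1:
        gl_genes = genes[:n]
        gic_genes = genes[n:]
    else:
        raise SubstrateError(
            f"expected 2 or {2 * n - 1} genes for {n} compartments, got {len(genes)}"
        )

    g_l = np.array([dac_to_conductance(g, config.g_l_range) for g in gl_genes])
    g_ic = np.array([dac_to_conductance(g, config.g_ic_range) for g in gic_genes])

    factors = np.ones(2 * n - 1)
    if config.mismatch_sigma > 0:
        if isinstance(mismatch_seed, np.random.Generator):
            rng = mismatch_seed
        else:
            rng = np.random.default_rng(mismatch_seed)
        sigma = np.sqrt(np.log1p(config.mismatch_sigma**2))
        factors = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=2 * n - 1)
    g_l = g_l * factors[:n]
    g_ic = g_ic * factors[n:]

    return ChainModel(
        g_l=g_l,
        g_ic=g_ic,
        c_m=np.full(n, config.c_m),
        e_l=np.full(n, config.e_l),
        mismatch_factors=factors,
    )


# --------------------------------------------------------------------------
# linear algebra core
# --------------------------------------------------------------------------


def _eigenmodes(chain: ChainModel):
    """Eigendecomposition of the relaxation operator A = -C^-1 G.

    G is symmetric, so A is similar to the symmetric matrix
    ``-C^-1/2 G C^-1/2`` and has real, non-positive eigenvalues.
    Returns (mu, to_modes, from_modes) with U = from_modes @ w and
    w' = mu * w + to_modes @ (I / C).
    """
    G = chain.conductance_matrix()
    c_sqrt = np.sqrt(chain.c_m)
    S = -(G / c_sqrt[:, None]) / c_sqrt[None, :]
    mu, W = scipy.linalg.eigh(S)
    from_modes = W / c_sqrt[:, None]
    to_modes = W.T * c_sqrt[None, :]
    return mu, to_modes, from_modes


def steady_state(chain: ChainModel, currents: Sequence[float] | None = None) -> np.ndarray:
    """Stationary voltages under a constant current: solve G U = g_l E_l + I.

    The system is tridiagonal and is solved with a banded direct solver.
    """
    n = chain.n_compartments
    I = np.zeros(n) if currents is None else np.asarray(currents, dtype=float)
    if I.size != n:
        raise SubstrateError("currents must have one entry per compartment")
    if np.all(chain.g_l == 0) :
        raise SubstrateError("steady state undefined for a leakless chain")
    rhs = chain.g_l * chain.e_l + I
    if n == 1:
        return rhs / chain.g_l
    G = chain.conductance_matrix()
    ab = np.zeros((3, n))
    ab[0, 1:] = np.diag(G, 1)
    ab[1] = np.diag(G)
    ab[2, :-1] = np.diag(G, -1)
    return scipy.linalg.solve_banded((1, 1), ab, rhs)


def slowest_time_constant(chain: ChainModel) -> float:
    """Relaxation time of the slowest eigenmode (inf for a leakless chain)."""
    mu, _, _ = _eigenmodes(chain)
    rates = np.abs(mu)
    if rates.min() <= rates.max() * 1e-12:  # numerically-zero mode
        return np.inf
    return 1.0 / rates.min()


def draw_noise(
    rng: np.random.Generator,
    shape: tuple[int, int],
    config: SubstrateConfig,
    sigma: float | None = None,
) -> np.ndarray:
    """Trial-to-trial voltage noise for a recording of the given shape.

    Stationary Gaussian noise of SD ``sigma`` per compartment.  With
    ``noise_correlation_time > 0`` it is an Ornstein-Uhlenbeck process
    (membrane-filtered noise: exponential autocorrelation); with 0 it is
    white, iid per sample.
    """
    import scipy.signal

    sigma = config.noise_sigma if sigma is None else float(sigma)
    if sigma == 0:
        return np.zeros(shape)
    white = rng.normal(0.0, 1.0, size=shape)
    tau = config.noise_correlation_time
    if tau > 0:
        a = np.exp(-config.dt / tau)
        x0 = rng.normal(0.0, 1.0, size=(shape[0], 1))
        out, _ = scipy.signal.lfilter(
            [np.sqrt(1.0 - a**2)], [1.0, -a], white, axis=1, zi=a * x0
        )
        return sigma * out
    return sigma * white


def quantize(voltages: np.ndarray, config: SubstrateConfig) -> np.ndarray:
    """Clip-and-round voltages to integer ADC codes (mid-tread uniform)."""
    v_lo, v_hi = config.adc_range
    codes = np.rint((voltages - v_lo) / config.adc_step)
    return np.clip(codes, 0, config.adc_codes - 1).astype(np.int32)


# --------------------------------------------------------------------------
# emulation
# --------------------------------------------------------------------------


def _clean_traces(
    chain: ChainModel,
    stim: StimulusProgram,
    config: SubstrateConfig,
    initial_state: np.ndarray | None = None,
) -> np.ndarray:
    """Noise-free voltage traces, evaluated in closed form per eigenmode."""
    n = chain.n_compartments
    dt = config.dt
    n_samples = int(round(stim.total_duration / dt)) + 1
    t = np.arange(n_samples) * dt

    mu, to_modes, from_modes = _eigenmodes(chain)
    rates = np.abs(mu)
    zero_mode = rates <= rates.max() * 1e-12
    leakless = bool(np.all(chain.g_l == 0))

    bias = stim.bias_current
    if bias is not None and bias.size != n:
        raise SubstrateError("bias_current must have one entry per compartment")

    # particular (stationary) solution and initial deviation
    if leakless:
        if bias is not None and np.any(bias != 0):
            raise SubstrateError("constant bias has no steady state without leak")
        u_ss = np.zeros(n)
        u0 = chain.e_l.copy() if initial_state is None else np.asarray(initial_state, float)
    else:
        u_ss = steady_state(chain, bias)
        if initial_state is None:
            # start from the quiescent rest (no external current)
            u0 = steady_state(chain, None)
        else:
            u0 = np.asarray(initial_state, float)

    traces = np.tile(u_ss[:, None], (1, n_samples))

    dev = u0 - u_ss
    if np.any(dev != 0):
        w0 = to_modes @ dev
        decay = np.exp(np.outer(mu, t))
        if leakless:
            decay[zero_mode] = 1.0
        traces += from_modes @ (w0[:, None] * decay)

    if not stim.events:
        return traces

    # synaptic kernels: group events by target compartment, compute the
    # unit response once per target over a truncated window, superpose.
    tau = config.tau_syn
    inv_tau = 1.0 / tau
    if not zero_mode.any():
        tau_slow = 1.0 / rates.min()
        horizon = 40.0 * max(tau_slow, tau)
        window = min(n_samples, int(np.ceil(horizon / dt)) + 1)
    else:
        window = n_samples
    tw = np.arange(window) * dt

    denom = mu + inv_tau
    resonant = np.abs(denom) < 1e-9 * inv_tau
    kernels: dict[int, np.ndarray] = {}
    for t_spike, target in stim.events:
        if not 0 <= target < n:
            raise SubstrateError(f"stimulus target {target} out of range")
        if target not in kernels:
            drive = to_modes[:, target] / chain.c_m[target] * config.syn_amplitude
            safe = np.where(resonant, 1.0, denom)
            phi = (np.exp(np.outer(mu, tw)) - np.exp(-tw * inv_tau)[None, :]) / safe[:, None]
            if resonant.any():
                phi[resonant] = tw * np.exp(np.outer(mu[resonant], tw))
            kernels[target] = from_modes @ (drive[:, None] * phi)
        k = kernels[target]
        start = int(round(t_spike / dt))
        stop = min(n_samples, start + window)
        traces[:, start:stop] += k[:, : stop - start]
    return traces


def simulate(
    chain: ChainModel,
    stim: StimulusProgram,
    config: SubstrateConfig,
    *,
    noise_sigma: float | None = None,
    seed: int | np.random.Generator | None = None,
    initial_state: np.ndarray | None = None,
    meta: dict | None = None,
) -> RecordingSet:
    """Emulate one run: exact linear dynamics + read-out noise + ADC.

    Gaussian noise of SD ``noise_sigma`` (default: the config value) is
    added independently to every recorded sample, after which the traces
    are clipped and rounded to integer ADC codes.  Identical inputs and
    seed give bitwise-identical recordings.
    """
    sigma = config.noise_sigma if noise_sigma is None else float(noise_sigma)
    if sigma < 0:
        raise SubstrateError("noise_sigma must be non-negative")
    clean = _clean_traces(chain, stim, config, initial_state=initial_state)
    if sigma > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        noisy = clean + draw_noise(rng, clean.shape, config, sigma)
    else:
        noisy = clean
    info = {"noise_sigma": sigma, "seed": None if isinstance(seed, np.random.Generator) else seed}
    if meta:
        info.update(meta)
    return RecordingSet(traces=quantize(noisy, config), dt=config.dt, meta=info)
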