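"""Measurement protocol: EPSP attenuation, spike-triggered averaging, fits.

The protocol mirrors how the attenuation of an excitatory postsynaptic
potential (EPSP) along a compartment chain is quantified on an analog
substrate: several input spikes are injected into one compartment of the
chain with enough spacing for the membrane to relax in between, the
recorded voltage windows are aligned on the spike times, baseline
subtracted and averaged (spike-triggered average, STA), the peak
amplitude per compartment is extracted, and an exponential

    U_max(x) = a * exp(-x / lambda_emp) + c

is fitted over the compartment index x to obtain the empirical length
constant ``lambda_emp`` (in units of compartments).  Amplitudes are in
ADC bits.  The STA over N spikes suppresses the iid read-out noise by
about 1/sqrt(N) and is the default recording mode.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.optimize

from . import substrate as sub
from .rng import stream
from .substrate import ChainModel, RecordingSet, StimulusProgram, SubstrateConfig

__all__ = [
    "ProtocolConfig",
    "AttenuationFit",
    "Observation",
    "AmplitudeMatrix",
    "TargetObservation",
    "STAResult",
    "ProtocolError",
    "FitError",
    "DegenerateFitError",
    "sta",
    "extract_amplitudes",
    "fit_attenuation",
    "build_stimulus",
    "run_attenuation_experiment",
    "run_multisite_experiment",
    "trial_to_trial",
    "measure_target",
]


class ProtocolError(ValueError):
    """Protocol windows inconsistent with the recording."""


class FitError(RuntimeError):
    """Exponential attenuation fit failed."""

    def __init__(self, message: str, amplitudes: np.ndarray | None = None):
        super().__init__(message)
        self.amplitudes = amplitudes


class DegenerateFitError(FitError):
    """Flat amplitude profile: the length constant is unidentifiable."""


@dataclass(frozen=True)
class ProtocolConfig:
    """Stimulation and analysis windows.

    ``inter_spike_interval``, ``pre_window`` and ``post_window`` default
    to values derived from the chain under test: the interval is ten
    times the slowest membrane relaxation time (residual deflection
    < 0.005%), the baseline window is the 20% of the interval ending one
    sample before the spike, and the response window is 75% of the
    interval after the spike.
    """

    n_spikes: int = 10
    inter_spike_interval: float | None = None
    pre_window: float | None = None
    post_window: float | None = None
    input_compartment: int = 0

    def __post_init__(self) -> None:
        if self.n_spikes < 1:
            raise ProtocolError("n_spikes must be >= 1")
        isi, pre, post = self.inter_spike_interval, self.pre_window, self.post_window
        if isi is not None and isi <= 0:
            raise ProtocolError("inter_spike_interval must be positive")
        if None not in (isi, pre, post) and isi < pre + post:
            raise ProtocolError("inter_spike_interval must cover pre + post windows")

    def resolve(self, chain: ChainModel, config: SubstrateConfig) -> "ProtocolConfig":
        """Fill derived windows for a concrete chain."""
        isi = self.inter_spike_interval
        if isi is None:
            tau = sub.slowest_time_constant(chain)
            if not np.isfinite(tau):
                raise ProtocolError("cannot derive spike interval for a leakless chain")
            isi = 10.0 * max(tau, config.tau_syn)
        pre = 0.2 * isi if self.pre_window is None else self.pre_window
        post = 0.75 * isi if self.post_window is None else self.post_window
        if isi < pre + post:
            raise ProtocolError("inter_spike_interval must cover pre + post windows")
        return replace(
            self, inter_spike_interval=isi, pre_window=pre, post_window=post
        )


@dataclass(frozen=True)
class STAResult:
    """Spike-triggered average: baseline-subtracted mean window, in bits.

    ``traces`` has shape (n_compartments, window_samples); the spike sits
    at sample index ``spike_index``.
    """

    traces: np.ndarray
    dt: float
    spike_index: int
    n_spikes: int


@dataclass(frozen=True)
class AttenuationFit:
    """Parameters of the exponential a*exp(-x/lambda) + c through the
    per-compartment EPSP amplitudes."""

    a: float
    lambda_emp: float
    c: float
    residual: float


@dataclass(frozen=True)
class Observation:
    """One measurement of the chain: amplitudes, length constant, fit."""

    amplitudes: np.ndarray
    lambda_emp: float
    fit: AttenuationFit

    @property
    def h0(self) -> float:
        """EPSP amplitude in the first compartment, bits."""
        return float(self.amplitudes[0])


@dataclass(frozen=True)
class AmplitudeMatrix:
    """EPSP amplitudes h[i, j]: response in compartment i to an input
    spike in compartment j, in bits."""

    h: np.ndarray

    def __post_init__(self) -> None:
        h = np.asarray(self.h, dtype=float)
        if h.ndim != 2 or h.shape[0] != h.shape[1]:
            raise ProtocolError("amplitude matrix must be square")
        object.__setattr__(self, "h", h)


@dataclass(frozen=True)
class TargetObservation:
    """The observation a parameter search should reproduce."""

    lambda_hat: float | None = None
    h0_hat: float | None = None
    h_hat: AmplitudeMatrix | None = None

    def __post_init__(self) -> None:
        if self.lambda_hat is not None and self.lambda_hat <= 0:
            raise ProtocolError("lambda_hat must be positive")
        if self.h0_hat is not None and self.h0_hat <= 0:
            raise ProtocolError("h0_hat must be positive")


# --------------------------------------------------------------------------
# analysis primitives
# --------------------------------------------------------------------------


def sta(
    rec: RecordingSet,
    spike_times: Sequence[float],
    pre_window: float,
    post_window: float,
) -> STAResult:
    """Average baseline-subtracted windows aligned on the spike times.

    For each spike and compartment the window covers
    [t - pre_window, t + post_window]; the mean over the pre-spike part
    is subtracted per window (so the resting potential sits at zero)
    before averaging across spikes.
    """
    dt = rec.dt
    pre_s = int(round(pre_window / dt))
    post_s = int(round(post_window / dt))
    if pre_s < 1:
        raise ProtocolError("pre_window must span at least one sample")
    windows = []
    for t in spike_times:
        s = int(round(t / dt))
        if s - pre_s < 0 or s + post_s >= rec.n_samples:
            raise ProtocolError(
                f"window around spike at t={t} extends past the recording"
            )
        w = rec.traces[:, s - pre_s : s + post_s + 1].astype(float)
        baseline = w[:, :pre_s].mean(axis=1, keepdims=True)
        windows.append(w - baseline)
    avg = np.mean(windows, axis=0)
    return STAResult(traces=avg, dt=dt, spike_index=pre_s, n_spikes=len(windows))


def extract_amplitudes(avg: STAResult) -> np.ndarray:
    """EPSP peak per compartment: max of the STA over the post-spike window."""
    return avg.traces[:, avg.spike_index :].max(axis=1)


def _attenuation_model(x, a, lam, c):
    return a * np.exp(-x / lam) + c


def fit_attenuation(amplitudes: Sequence[float]) -> AttenuationFit:
    """Nonlinear least-squares fit of a*exp(-x/lambda)+c over compartment
    index x = 0..n-1, with lambda constrained positive.

    Raises :class:`DegenerateFitError` for flat profiles (lambda is then
    unidentifiable) and :class:`FitError` on non-finite input or
    non-convergence.
    """
    amps = np.asarray(amplitudes, dtype=float)
    if amps.size < 4:
        raise FitError("need at least 4 amplitudes for a 3-parameter fit", amps)
    if not np.all(np.isfinite(amps)):
        raise FitError("non-finite amplitudes", amps)
    if np.ptp(amps) < 1e-12:
        raise DegenerateFitError("flat amplitude profile", amps)
    x = np.arange(amps.size, dtype=float)
    p0 = (amps[0] - amps[-1], 1.0, amps[-1])
    if p0[0] == 0:
        p0 = (np.ptp(amps), 1.0, amps.min())
    try:
        popt, _ = scipy.optimize.curve_fit(
            _attenuation_model,
            x,
            amps,
            p0=p0,
            bounds=([-np.inf, 1e-6, -np.inf], [np.inf, 1e6, np.inf]),
            maxfev=10000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"attenuation fit did not converge: {exc}", amps) from exc
    resid = amps - _attenuation_model(x, *popt)
    return AttenuationFit(
        a=float(popt[0]),
        lambda_emp=float(popt[1]),
        c=float(popt[2]),
        residual=float(np.sqrt(np.mean(resid**2))),
    )


# --------------------------------------------------------------------------
# protocols
# --------------------------------------------------------------------------


def build_stimulus(
    protocol: ProtocolConfig,
    input_compartments: Sequence[int] | None = None,
) -> tuple[StimulusProgram, list[float]]:
    """Spike schedule for a resolved protocol.

    One block of ``n_spikes`` equally spaced spikes per entry of
    ``input_compartments`` (default: the protocol's input compartment),
    blocks concatenated back to back.  Returns the stimulus and the flat
    list of spike times.
    """
    if protocol.inter_spike_interval is None:
        raise ProtocolError("protocol must be resolved before building a stimulus")
    isi = protocol.inter_spike_interval
    pre = protocol.pre_window
    post = protocol.post_window
    sites = (
        [protocol.input_compartment]
        if input_compartments is None
        else list(input_compartments)
    )
    events = []
    t = pre + 0.05 * isi  # leave room for the first baseline window
    for site in sites:
        for _ in range(protocol.n_spikes):
            events.append((t, site))
            t += isi
    duration = events[-1][0] - isi + max(post + isi * 0.05, isi)
    duration = max(duration, events[-1][0] + post + isi * 0.05)
    stim = StimulusProgram(events=tuple(events), total_duration=duration)
    return stim, [t for t, _ in events]


def run_attenuation_experiment(
    genes: Sequence[int],
    substrate_cfg: SubstrateConfig,
    protocol_cfg: ProtocolConfig,
    seed: int | None = None,
    *,
    noise_sigma: float | None = None,
) -> Observation:
    """Full single-site pipeline: emulate, STA, amplitudes, exponential fit.

    ``seed`` feeds two named streams: "mismatch" (fixed-pattern factors,
    used only when the substrate's mismatch_sigma > 0) and "noise"
    (per-sample read-out noise).  Identical genes, configs and seed give
    an identical Observation.
    """
    master = 0 if seed is None else int(seed)
    chain = sub.make_chain(genes, substrate_cfg, mismatch_seed=stream(master, "mismatch"))
    proto = protocol_cfg.resolve(chain, substrate_cfg)
    stim, spike_times = build_stimulus(proto)
    rec = sub.simulate(
        chain,
        stim,
        substrate_cfg,
        noise_sigma=noise_sigma,
        seed=stream(master, "noise"),
        meta={"genes": list(int(g) for g in genes), "master_seed": master},
    )
    avg = sta(rec, spike_times, proto.pre_window, proto.post_window)
    amps = extract_amplitudes(avg)
    fit = fit_attenuation(amps)
    return Observation(amplitudes=amps, lambda_emp=fit.lambda_emp, fit=fit)


def run_multisite_experiment(
    genes: Sequence[int],
    substrate_cfg: SubstrateConfig,
    protocol_cfg: ProtocolConfig,
    seed: int | None = None,
    *,
    noise_sigma: float | None = None,
) -> AmplitudeMatrix:
    """Amplitude matrix h[i, j]: inject spikes into one compartment after
    another within a single emulation run and read the STA amplitude in
    every compartment for every input site."""
    master = 0 if seed is None else int(seed)
    n = substrate_cfg.n_compartments
    chain = sub.make_chain(genes, substrate_cfg, mismatch_seed=stream(master, "mismatch"))
    proto = protocol_cfg.resolve(chain, substrate_cfg)
    stim, spike_times = build_stimulus(proto, input_compartments=range(n))
    rec = sub.simulate(
        chain,
        stim,
        substrate_cfg,
        noise_sigma=noise_sigma,
        seed=stream(master, "noise"),
        meta={"genes": list(int(g) for g in genes), "master_seed": master},
    )
    h = np.empty((n, n))
    for j in range(n):
        block = spike_times[j * proto.n_spikes : (j + 1) * proto.n_spikes]
        avg = sta(rec, block, proto.pre_window, proto.post_window)
        h[:, j] = extract_amplitudes(avg)
    return AmplitudeMatrix(h=h)


# --------------------------------------------------------------------------
# trial-to-trial statistics
# --------------------------------------------------------------------------


def trial_to_trial(
    genes: Sequence[int],
    substrate_cfg: SubstrateConfig,
    protocol_cfg: ProtocolConfig,
    n_repeats: int,
    seed: int | None = None,
    *,
    sta_spikes: int = 10,
) -> pd.DataFrame:
    """Repeat the attenuation measurement with independent noise draws.

    Runs both recording modes — single shot (one spike per run) and STA
    over ``sta_spikes`` spikes — ``n_repeats`` times each on the same
    chain, and returns a tidy frame with one row per repeat per mode and
    columns (repeat, mode, lambda_emp, h0).  The noise-free dynamics are
    identical across repeats and are computed once per mode; only the
    read-out noise, quantization and analysis are redone per repeat,
    which is exactly equivalent to repeating the full experiment.
    """
    if n_repeats < 1:
        raise ProtocolError("n_repeats must be >= 1")
    master = 0 if seed is None else int(seed)
    chain = sub.make_chain(genes, substrate_cfg, mismatch_seed=stream(master, "mismatch"))
    rows = []
    for mode, n_spikes in (("single", 1), ("sta", sta_spikes)):
        proto = replace(protocol_cfg, n_spikes=n_spikes).resolve(chain, substrate_cfg)
        stim, spike_times = build_stimulus(proto)
        clean = sub._clean_traces(chain, stim, substrate_cfg)
        rng = stream(master, "noise", mode)
        sigma = substrate_cfg.noise_sigma
        for r in range(n_repeats):
            noisy = (
                clean + sub.draw_noise(rng, clean.shape, substrate_cfg)
                if sigma > 0
                else clean
            )
            rec = RecordingSet(
                traces=sub.quantize(noisy, substrate_cfg), dt=substrate_cfg.dt
            )
            avg = sta(rec, spike_times, proto.pre_window, proto.post_window)
            amps = extract_amplitudes(avg)
            try:
                lam = fit_attenuation(amps).lambda_emp
            except FitError:
                lam = np.nan
            rows.append(
                {"repeat": r, "mode": mode, "lambda_emp": lam, "h0": float(amps[0])}
            )
    return pd.DataFrame(rows)


def summarize_trials(frame: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of lambda_emp and h0 per recording mode."""
    return frame.groupby("mode")[["lambda_emp", "h0"]].agg(["mean", "std"])


def measure_target(
    genes: Sequence[int],
    substrate_cfg: SubstrateConfig,
    protocol_cfg: ProtocolConfig,
    n_repeats: int,
    seed: int | None = None,
    *,
    multisite: bool = False,
) -> tuple[TargetObservation, dict]:
    """Record a target observation at fixed genes, as the mean over
    repeated noisy measurements, together with trial-to-trial SDs.

    Returns (target, stats) where stats holds 'lambda_sd', 'h0_sd' and,
    for multisite targets, 'h_sd' (per-entry SDs) and 'f3_floor' (mean
    sum of squared deviations of a single measurement from the target
    matrix — the noise floor of the multisite fitness).
    """
    master = 0 if seed is None else int(seed)
    if multisite:
        mats = [
            run_multisite_experiment(
                genes, substrate_cfg, protocol_cfg, seed=stream_seed_int(master, r)
            ).h
            for r in range(n_repeats)
        ]
        mats = np.stack(mats)
        h_hat = AmplitudeMatrix(h=mats.mean(axis=0))
        f3_floor = float(np.mean([np.sum((m - h_hat.h) ** 2) for m in mats]))
        stats = {"h_sd": mats.std(axis=0), "f3_floor": f3_floor}
        return TargetObservation(h_hat=h_hat), stats
    frame = trial_to_trial(
        genes, substrate_cfg, protocol_cfg, n_repeats, seed=master
    )
    sta_rows = frame[frame["mode"] == "sta"]
    target = TargetObservation(
        lambda_hat=float(sta_rows["lambda_emp"].mean()),
        h0_hat=float(sta_rows["h0"].mean()),
    )
    stats = {
        "lambda_sd": float(sta_rows["lambda_emp"].std(ddof=1)),
        "h0_sd": float(sta_rows["h0"].std(ddof=1)),
        "lambda_sd_single": float(
            frame[frame["mode"] == "single"]["lambda_emp"].std(ddof=1)
        ),
        "h0_sd_single": float(frame[frame["mode"] == "single"]["h0"].std(ddof=1)),
    }
    return target, stats


def stream_seed_int(master: int, repeat: int) -> int:
    """Per-repeat master seed for independent multisite measurements."""
    return int(
        np.random.SeedSequence(entropy=master, spawn_key=(repeat,)).generate_state(1)[0]
        & 0x7FFFFFFF
    )
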