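"""Synthetic intracellular voltage traces with known ground truth.

Emulates the subthreshold activity seen in inferior-olive whole-cell
recordings: slow spikelets (~1.2 mV, 2.5 ms rise, 12.7 ms half-width)
transmitted through gap junctions, fast intrinsic events (4.5-15.3 mV,
1.4 ms rise, 4.2 ms half-width), Gaussian membrane noise, truncatable
action potentials and, optionally, ~5 Hz subthreshold oscillations with
spikelets confined to the oscillation peaks.

Event waveforms use a gamma-family kernel ``g(t) = (t/t_p)^m exp(m (1 - t/t_p))``
(peak 1 at ``t_p = m tau``). Its 10-90% rise to half-width ratio is a
monotone function of the shape parameter ``m`` spanning ~0 to ~0.7, which
covers both the slow and the fast event classes; the shape and time scale
are solved numerically so that the measured indices of the synthesized
kernel match the requested ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "EventWaveformParams", "GroundTruthEvent", "VoltageTrace",
    "SLOW_EVENT_STATS", "FAST_EVENT_STATS",
    "draw_slow_params", "draw_fast_params",
    "event_kernel", "synth_trace", "synth_pair_traces", "synth_oscillating_trace",
]

# Population statistics of the two event classes (mV, ms): mean/sd for the
# slow (gap-junction spikelet) class, amplitude range + mean/sd kinetics for
# the fast (intrinsic regenerative) class.
SLOW_EVENT_STATS = {
    "amplitude": (1.2, 0.3), "rise_time": (2.5, 0.6), "half_width": (12.7, 3.9),
}
FAST_EVENT_STATS = {
    "amplitude_range": (4.5, 15.3), "rise_time": (1.4, 0.4), "half_width": (4.2, 1.3),
}

# Action-potential rendering defaults (mV, ms): large fast deflection,
# truncated in plots only, never in the data.
SPIKE_AMPLITUDE_MV = 60.0
_SPIKE_RISE_MS = 0.5
_SPIKE_HALF_WIDTH_MS = 1.5


@dataclass(frozen=True)
class EventWaveformParams:
    """Target shape indices for one synthesized event."""

    amplitude: float        # mV, baseline to peak
    rise_time: float        # ms, 10-90% of amplitude
    half_width: float       # ms, full width at half amplitude
    event_class: str = "slow"   # "fast" | "slow" | "spike"

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError(f"amplitude must be positive, got {self.amplitude}")
        if self.rise_time <= 0 or self.half_width <= 0:
            raise ValueError("rise_time and half_width must be positive")
        if self.half_width < self.rise_time:
            raise ValueError(
                f"infeasible shape: half_width {self.half_width} < rise_time {self.rise_time}")


@dataclass(frozen=True)
class GroundTruthEvent:
    """One true event in a synthesized trace (times are peak times, ms)."""

    peak_time: float
    amplitude: float
    params: EventWaveformParams
    source: int | None = None   # presynaptic neuron id for pair recordings


@dataclass
class VoltageTrace:
    """Uniformly sampled membrane-potential record (mV vs ms)."""

    samples: np.ndarray
    sampling_rate_khz: float
    baseline: float = 0.0
    ground_truth: list[GroundTruthEvent] = field(default_factory=list)
    own_spike_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (1.0 <= self.sampling_rate_khz <= 100.0):
            raise ValueError(
                f"sampling rate {self.sampling_rate_khz} kHz outside supported range")

    @property
    def duration_ms(self) -> float:
        return self.samples.size / self.sampling_rate_khz

    @property
    def dt_ms(self) -> float:
        return 1.0 / self.sampling_rate_khz

    def time_ms(self) -> np.ndarray:
        return np.arange(self.samples.size) * self.dt_ms


def draw_slow_params(rng: np.random.Generator,
                     amplitude: float | None = None) -> EventWaveformParams:
    """Draw slow-event (spikelet) shape parameters from the population stats."""
    amp = amplitude if amplitude is not None else _pos_normal(
        rng, *SLOW_EVENT_STATS["amplitude"])
    rise = _pos_normal(rng, *SLOW_EVENT_STATS["rise_time"])
    hw = max(_pos_normal(rng, *SLOW_EVENT_STATS["half_width"]), rise * 1.6)
    return EventWaveformParams(amp, rise, hw, "slow")


def draw_fast_params(rng: np.random.Generator) -> EventWaveformParams:
    """Draw fast-event shape parameters (uniform amplitude, normal kinetics)."""
    amp = rng.uniform(*FAST_EVENT_STATS["amplitude_range"])
    rise = _pos_normal(rng, *FAST_EVENT_STATS["rise_time"])
    hw = max(_pos_normal(rng, *FAST_EVENT_STATS["half_width"]), rise * 1.6)
    return EventWaveformParams(amp, rise, hw, "fast")


def _pos_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal draw truncated at zero by redrawing."""
    while True:
        x = rng.normal(mean, sd)
        if x > 0:
            return x


# ---------------------------------------------------------------------------
# Kernel synthesis
# ---------------------------------------------------------------------------

# rise/half-width ratio achievable by the gamma kernel over m in [_M_LO, _M_HI]
_M_LO, _M_HI = 0.02, 400.0


def _gamma_shape_indices(m: float) -> tuple[float, float]:
    """(rise_10_90, half_width) of the normalized gamma kernel with tau=1."""
    t_peak = m
    t_end = m + 12.0 * np.sqrt(m) + 12.0
    t = np.linspace(1e-9, t_end, 40001)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.exp(m * (np.log(t / t_peak) + 1.0 - t / t_peak))
    ip = int(np.argmax(g))

    def crossing(level: float, rising: bool) -> float:
        if rising:
            idx = np.searchsorted(g[:ip + 1] >= level, True)
            if idx == 0:   # crossing below grid resolution: effectively at t=0
                return float(t[0])
            x0, x1, y0, y1 = t[idx - 1], t[idx], g[idx - 1], g[idx]
        else:
            seg = g[ip:]
            idx = ip + int(np.argmax(seg <= level))
            x0, x1, y0, y1 = t[idx - 1], t[idx], g[idx - 1], g[idx]
        return x0 + (level - y0) * (x1 - x0) / (y1 - y0)

    rise = crossing(0.9, True) - crossing(0.1, True)
    hw = crossing(0.5, False) - crossing(0.5, True)
    return rise, hw


def _solve_gamma_kernel(rise_time: float, half_width: float) -> tuple[float, float]:
    """Solve (m, t_peak_ms) so the gamma kernel hits the requested indices."""
    target = rise_time / half_width
    lo = _gamma_shape_indices(_M_LO)
    hi = _gamma_shape_indices(_M_HI)
    if not (lo[0] / lo[1] < target < hi[0] / hi[1]):
        raise ValueError(
            f"infeasible shape: rise/half-width ratio {target:.3f} outside "
            f"({lo[0] / lo[1]:.3f}, {hi[0] / hi[1]:.3f})")
    m = brentq(lambda mm: (lambda r, h: r / h - target)(*_gamma_shape_indices(mm)),
               _M_LO, _M_HI, xtol=1e-10, rtol=1e-12)
    _, hw_unit = _gamma_shape_indices(m)
    tau = half_width / hw_unit          # time scale, ms
    return m, m * tau


def event_kernel(params: EventWaveformParams, sampling_rate_khz: float,
                 tail_fraction: float = 1e-3) -> tuple[np.ndarray, int]:
    """Sampled event waveform whose measured shape indices match ``params``.

    Returns ``(samples, peak_index)``: the waveform sampled at the trace rate,
    from onset until the decay falls below ``tail_fraction`` of the peak, with
    the index of the peak sample (events are placed by their peak time).
    """
    m, t_peak = _solve_gamma_kernel(params.rise_time, params.half_width)
    tau = t_peak / m
    # decay end: solve g(t) = tail_fraction on the falling side
    t_end = brentq(
        lambda tt: m * (np.log(tt / t_peak) + 1.0 - tt / t_peak) - np.log(tail_fraction),
        t_peak, t_peak + 200.0 * tau * (1 + np.sqrt(m)))
    dt = 1.0 / sampling_rate_khz
    t = np.arange(0.0, t_end + dt, dt)
    with np.errstate(divide="ignore"):
        g = np.exp(m * (np.log(np.maximum(t, 1e-12) / t_peak) + 1.0 - t / t_peak))
    g[0] = 0.0
    return params.amplitude * g, int(round(t_peak / dt))


def _add_event(samples: np.ndarray, kernel: np.ndarray, peak_index_in_kernel: int,
               peak_time: float, rate_khz: float) -> None:
    """Superpose a kernel into the trace so its peak lands at ``peak_time``."""
    start = int(round(peak_time * rate_khz)) - peak_index_in_kernel
    k0 = max(0, -start)
    k1 = min(kernel.size, samples.size - start)
    if k1 > k0:
        samples[start + k0:start + k1] += kernel[k0:k1]


def synth_trace(events: list[tuple[float, EventWaveformParams]],
                noise_sd: float = 0.1, baseline: float = 0.0,
                duration_ms: float = 10_000.0, sampling_rate_khz: float = 10.0,
                seed: int = 0,
                sources: list[int | None] | None = None) -> VoltageTrace:
    """Linear superposition of event kernels plus Gaussian noise.

    ``events`` is a list of ``(peak_time_ms, EventWaveformParams)``; the
    ground-truth event list (peak time, amplitude, params, optional source id)
    is stored on the returned trace.
    """
    n = int(round(duration_ms * sampling_rate_khz))
    rng = np.random.default_rng(seed)
    samples = np.full(n, float(baseline))
    if noise_sd > 0:
        samples += rng.normal(0.0, noise_sd, size=n)
    truth: list[GroundTruthEvent] = []
    kernels: dict[EventWaveformParams, tuple[np.ndarray, int]] = {}
    if sources is None:
        sources = [None] * len(events)
    for (peak_time, params), src in zip(events, sources):
        if not 0.0 <= peak_time < duration_ms:
            raise ValueError(f"event time {peak_time} outside [0, {duration_ms}) ms")
        if params not in kernels:
            kernels[params] = event_kernel(params, sampling_rate_khz)
        kernel, ip = kernels[params]
        _add_event(samples, kernel, ip, peak_time, sampling_rate_khz)
        truth.append(GroundTruthEvent(peak_time, params.amplitude, params, src))
    truth.sort(key=lambda e: e.peak_time)
    return VoltageTrace(samples, sampling_rate_khz, baseline, truth)


def synth_pair_traces(pair_events, noise_sd: float = 0.1,
                      sampling_rate_khz: float = 10.0, seed: int = 0,
                      baseline: float = 0.0) -> tuple[VoltageTrace, VoltageTrace]:
    """Render a simulated paired recording as two voltage traces.

    ``pair_events`` is a :class:`olivenet.net_sim.PairRecordingEvents`. All
    spikelets from one source neuron into one recorded cell share a single
    waveform (amplitude fixed by the coupling map, kinetics drawn once per
    source-recorder edge from the slow-event population), so that downstream
    amplitude grouping can attribute them to a common source. Own action
    potentials are rendered as large fast deflections.
    """
    rng = np.random.default_rng(seed)
    spike_params = EventWaveformParams(
        SPIKE_AMPLITUDE_MV, _SPIKE_RISE_MS, _SPIKE_HALF_WIDTH_MS, "spike")
    duration = pair_events.duration_ms
    traces = []
    for rec in (pair_events.cell_a, pair_events.cell_b):
        shape_by_source: dict[int, EventWaveformParams] = {}
        events: list[tuple[float, EventWaveformParams]] = []
        sources: list[int | None] = []
        for t, amp, src in zip(rec.spikelet_times, rec.spikelet_amplitudes,
                               rec.spikelet_sources):
            src = int(src)
            if src not in shape_by_source:
                shape_by_source[src] = draw_slow_params(rng, amplitude=float(amp))
            events.append((float(t), shape_by_source[src]))
            sources.append(src)
        for t in rec.own_spikes:
            events.append((float(t), spike_params))
            sources.append(None)
        trace = synth_trace(events, noise_sd=noise_sd, baseline=baseline,
                            duration_ms=duration, sampling_rate_khz=sampling_rate_khz,
                            seed=int(rng.integers(2 ** 31)), sources=sources)
        trace.own_spike_times = np.asarray(rec.own_spikes, dtype=float)
        traces.append(trace)
    return traces[0], traces[1]


def synth_oscillating_trace(period_ms: float = 200.0, sto_amplitude: float = 2.0,
                            spikelet_rate_at_peak: float = 10.0,
                            duration_ms: float = 60_000.0,
                            sampling_rate_khz: float = 10.0,
                            noise_sd: float = 0.1, baseline: float = 0.0,
                            peak_window_ms: float = 50.0,
                            seed: int = 0) -> VoltageTrace:
    """Sinusoidal subthreshold oscillation with spikelets confined to its peaks.

    Spikelets occur as a Poisson process at ``spikelet_rate_at_peak`` (Hz)
    restricted to +-``peak_window_ms``/2 around each oscillation peak, the
    pattern seen in oscillating olivary neurons where spikelets crown the
    depolarized phase.
    """
    if period_ms <= 50.0:
        raise ValueError(f"period must exceed 50 ms, got {period_ms}")
    rng = np.random.default_rng(seed)
    half_win = peak_window_ms / 2.0
    # peaks of sin(2 pi t / T) at T/4 + k T
    peak_times = np.arange(period_ms / 4.0, duration_ms, period_ms)
    events: list[tuple[float, EventWaveformParams]] = []
    for pk in peak_times:
        n_ev = rng.poisson(spikelet_rate_at_peak * peak_window_ms / 1000.0)
        for t in np.sort(rng.uniform(pk - half_win, pk + half_win, size=n_ev)):
            if 0.0 <= t < duration_ms - 100.0:
                events.append((float(t), draw_slow_params(rng)))
    trace = synth_trace(events, noise_sd=noise_sd, baseline=baseline,
                        duration_ms=duration_ms, sampling_rate_khz=sampling_rate_khz,
                        seed=int(rng.integers(2 ** 31)))
    t = trace.time_ms()
    trace.samples += sto_amplitude * np.sin(2.0 * np.pi * t / period_ms)
    return trace
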