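"""Detection and classification of subthreshold unitary events in voltage traces.

Depolarizing events are found as peaks of the smoothed, locally
baseline-subtracted trace exceeding a noise-scaled threshold. Each event
gets the standard shape indices — amplitude (local baseline to peak),
10-90% rise time, full width at half amplitude and width at 20% amplitude,
all timed by linear interpolation between samples — and events are
classified into the two populations seen in olivary recordings (fast
high-amplitude intrinsic events vs slow low-amplitude spikelets) by
k-means over standardized shape indices with silhouette-based model
selection. ISLI (inter-spikelet-interval) histograms and detrended
autocorrelations diagnose oscillation-locked spikelet timing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import butter, filtfilt, find_peaks
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

__all__ = [
    "UnitaryEvent", "EventCatalog", "DetectorConfig",
    "detect_events", "shape_indices", "classify_events",
    "isli_histogram", "detrended_autocorrelation", "estimate_noise_sd",
]

INCLUSION_RATE_HZ = 0.02   # minimum event rate for a neuron to enter analysis


@dataclass(frozen=True)
class VoltageTraceView:
    """Lightweight samples + rate wrapper for internally transformed traces."""

    samples: np.ndarray
    sampling_rate_khz: float


@dataclass(frozen=True)
class UnitaryEvent:
    """One detected subthreshold event with its shape indices (ms, mV)."""

    peak_time: float
    amplitude: float
    rise_time_10_90: float
    half_width: float
    width_at_20pct: float
    label: str = "unassigned"   # "fast" | "slow" | "unassigned"
    clipped: bool = False


@dataclass
class EventCatalog:
    """Events detected in one trace, with the rate-based inclusion flag."""

    events: list[UnitaryEvent]
    duration_ms: float
    n_waveform_clusters: int = 0   # k chosen during classification (0 = not run)

    def __len__(self) -> int:
        return len(self.events)

    @property
    def peak_times(self) -> np.ndarray:
        return np.array([e.peak_time for e in self.events])

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([e.amplitude for e in self.events])

    @property
    def labels(self) -> list[str]:
        return [e.label for e in self.events]

    @property
    def frequency_hz(self) -> float:
        return len(self.events) / (self.duration_ms / 1000.0)

    @property
    def included(self) -> bool:
        return self.frequency_hz > INCLUSION_RATE_HZ

    def feature_matrix(self) -> np.ndarray:
        """(n, 3) matrix of (amplitude, rise_time, half_width) for clustering."""
        return np.array([[e.amplitude, e.rise_time_10_90, e.half_width]
                         for e in self.events])

    def subset(self, mask) -> "EventCatalog":
        ev = [e for e, m in zip(self.events, mask) if m]
        return EventCatalog(ev, self.duration_ms, self.n_waveform_clusters)


@dataclass(frozen=True)
class DetectorConfig:
    """All detector thresholds in one place (times ms, voltages mV)."""

    threshold_sd: float = 5.0        # peak threshold, multiples of noise SD
    min_separation_ms: float = 5.0   # minimum spacing between accepted peaks
    smooth_ms: float = 0.5           # Gaussian pre-smoothing SD
    baseline_window_ms: float = 50.0     # span of the running-baseline estimate
    baseline_step_ms: float = 5.0        # grid step of the running baseline
    baseline_quantile: float = 0.50      # running median: unbiased under noise
    shape_baseline_window: tuple[float, float] = (15.0, 60.0)  # pre-peak, (near, far)
    shape_search_ms: float = 200.0   # how far around a peak crossings are sought


def estimate_noise_sd(samples: np.ndarray) -> float:
    """Robust noise SD from the median absolute deviation of first differences.

    Differencing removes baseline and slow event waveforms; the MAD makes the
    estimate insensitive to the sparse fast transients.
    """
    d = np.diff(samples)
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / math.sqrt(2.0))


def _running_baseline(samples: np.ndarray, rate_khz: float,
                      config: DetectorConfig) -> np.ndarray:
    """Running median baseline via median-of-block-medians on a coarse grid."""
    from scipy.ndimage import median_filter

    step = max(1, int(round(config.baseline_step_ms * rate_khz)))
    n_blocks = int(np.ceil(samples.size / step))
    padded = np.pad(samples, (0, n_blocks * step - samples.size), mode="edge")
    block_med = np.quantile(padded.reshape(n_blocks, step),
                            config.baseline_quantile, axis=1)
    w = max(1, int(round(config.baseline_window_ms / config.baseline_step_ms)))
    levels = median_filter(block_med, size=w, mode="nearest")
    centers = np.arange(n_blocks) * step + step // 2
    return np.interp(np.arange(samples.size), centers, levels)


def detect_events(trace, threshold_sd: float | None = None,
                  min_separation_ms: float | None = None,
                  config: DetectorConfig = DetectorConfig(),
                  classify: bool = False,
                  detrend_lowpass_hz: float | None = None) -> EventCatalog:
    """Detect depolarizing unitary events in a voltage trace.

    ``trace`` is a :class:`olivenet.trace_synth.VoltageTrace` (or anything
    with ``samples`` and ``sampling_rate_khz``). Candidate peaks of the
    smoothed, baseline-subtracted trace must exceed ``threshold_sd`` times
    the estimated noise SD — in height and in prominence, so noise riding on
    a slow event's plateau does not split it — and be separated by
    ``min_separation_ms``. For traces dominated by subthreshold
    oscillations, pass ``detrend_lowpass_hz`` (e.g. 20): a low-pass filtered
    copy is subtracted first so the oscillation itself is not detected.
    A flat trace yields an empty catalog; a trace shorter than 1 s is an error.
    """
    samples = np.asarray(trace.samples, dtype=float)
    rate = float(trace.sampling_rate_khz)
    if samples.size == 0:
        raise ValueError("empty trace")
    duration_ms = samples.size / rate
    if duration_ms < 1000.0:
        raise ValueError(f"trace too short for detection: {duration_ms:.0f} ms < 1 s")
    if threshold_sd is not None:
        config = replace(config, threshold_sd=threshold_sd)
    if min_separation_ms is not None:
        config = replace(config, min_separation_ms=min_separation_ms)

    noise_sd = estimate_noise_sd(samples)
    if noise_sd == 0 and np.ptp(samples) == 0:
        return EventCatalog([], duration_ms)
    work = samples
    if detrend_lowpass_hz is not None:
        nyq_hz = rate * 1000.0 / 2.0
        b, a = butter(2, detrend_lowpass_hz / nyq_hz, btype="low")
        work = samples - filtfilt(b, a, samples)
    smoothed = gaussian_filter1d(work, sigma=max(config.smooth_ms * rate, 1e-9))
    detection = smoothed - _running_baseline(smoothed, rate, config)
    # smoothing attenuates white noise; threshold against the *smoothed* noise
    # level, estimated by the MAD of the detection signal (events are sparse)
    smoothed_noise_sd = 1.4826 * float(
        np.median(np.abs(detection - np.median(detection))))
    height = config.threshold_sd * max(smoothed_noise_sd, 1e-12)
    peaks, _ = find_peaks(detection, height=height, prominence=height,
                          distance=max(1, int(round(config.min_separation_ms * rate))))
    shape_trace = trace if detrend_lowpass_hz is None else VoltageTraceView(work, rate)
    events = []
    for p in peaks:
        ev = shape_indices(shape_trace, p / rate, config=config)
        events.append(ev)
    catalog = EventCatalog(events, duration_ms)
    if classify and len(catalog) > 0:
        catalog = classify_events(catalog)
    return catalog


def shape_indices(trace, peak_time: float,
                  config: DetectorConfig = DetectorConfig()) -> UnitaryEvent:
    """Shape indices of the event peaking at ``peak_time`` (ms).

    Amplitude is measured from a local pre-event baseline (a robust quantile
    of the window ``shape_baseline_window`` before the peak) to the peak
    sample; the 10/20/50/90% crossing times use linear interpolation between
    samples. Events whose crossings run off the trace are flagged ``clipped``.
    """
    samples = np.asarray(trace.samples, dtype=float)
    rate = float(trace.sampling_rate_khz)
    ip = int(round(peak_time * rate))
    if not (0 <= ip < samples.size):
        raise ValueError(f"peak time {peak_time} ms outside trace")
    # snap to the local maximum within +-1 ms
    w = int(round(rate))
    lo = max(0, ip - w)
    ip = lo + int(np.argmax(samples[lo:min(samples.size, ip + w + 1)]))

    near, far = config.shape_baseline_window
    b0, b1 = ip - int(round(far * rate)), ip - int(round(near * rate))
    clipped = b0 < 0
    b0 = max(0, b0)
    if b1 <= b0:
        baseline = samples[max(0, ip - 1)]
        clipped = True
    else:
        baseline = float(np.quantile(samples[b0:b1], config.baseline_quantile))
    peak_v = samples[ip]
    amplitude = peak_v - baseline

    span = int(round(config.shape_search_ms * rate))

    def cross_time(level: float, rising: bool) -> float:
        v = baseline + level * amplitude
        if rising:
            seg = samples[max(0, ip - span):ip + 1]
            below = np.where(seg < v)[0]
            if below.size == 0 or ip - span < 0 and below.size == 0:
                return math.nan
            i1 = below[-1] + 1
            if i1 >= seg.size:
                return float(ip) / rate
            base = max(0, ip - span)
            y0, y1 = seg[i1 - 1], seg[i1]
            frac = 0.0 if y1 == y0 else (v - y0) / (y1 - y0)
            return (base + i1 - 1 + frac) / rate
        seg = samples[ip:min(samples.size, ip + span)]
        below = np.where(seg < v)[0]
        if below.size == 0:
            return math.nan
        i1 = below[0]
        if i1 == 0:
            return float(ip) / rate
        y0, y1 = seg[i1 - 1], seg[i1]
        frac = 0.0 if y1 == y0 else (y0 - v) / (y0 - y1)
        return (ip + i1 - 1 + frac) / rate

    t10, t90 = cross_time(0.10, True), cross_time(0.90, True)
    t50r, t50f = cross_time(0.50, True), cross_time(0.50, False)
    t20r, t20f = cross_time(0.20, True), cross_time(0.20, False)
    rise = t90 - t10
    half_width = t50f - t50r
    width20 = t20f - t20r
    if any(math.isnan(x) for x in (rise, half_width, width20)):
        clipped = True
    return UnitaryEvent(peak_time=ip / rate, amplitude=float(amplitude),
                        rise_time_10_90=float(rise), half_width=float(half_width),
                        width_at_20pct=float(width20), clipped=clipped)


def classify_events(catalog: EventCatalog, max_k: int = 6,
                    silhouette_threshold: float = 0.5,
                    seed: int = 0) -> EventCatalog:
    """Split events into fast and slow classes via shape-index clustering.

    K-means runs on standardized (amplitude, rise time, half width) with k
    chosen by the best silhouette over 2..``max_k``. If the best silhouette
    falls below ``silhouette_threshold`` the events are treated as a single
    population and all receive the class of their joint centroid (slow when
    kinetics are slow). Otherwise clusters are merged into two classes by
    2-means over their (rise, half-width) centroids — the slow class is the
    one with the longer kinetics, mirroring the two populations of olivary
    subthreshold events.
    """
    valid = [not e.clipped for e in catalog.events]
    usable = catalog.subset(valid)
    if len(usable) < 2 * max_k:
        events = [replace(e, label="unassigned") for e in catalog.events]
        return EventCatalog(events, catalog.duration_ms, 0)

    X = usable.feature_matrix()
    Xz = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    best_k, best_score, best_labels = 0, -np.inf, None
    for k in range(2, min(max_k, len(usable) - 1) + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        lab = km.fit_predict(Xz)
        if len(np.unique(lab)) < 2:
            continue
        score = silhouette_score(Xz, lab)
        if score > best_score:
            best_k, best_score, best_labels = k, score, lab

    def slowness(rise: float, hw: float) -> bool:
        # boundary midway (in log space) between the two population means
        slow_r, fast_r = 2.5, 1.4
        slow_h, fast_h = 12.7, 4.2
        s = (math.log(rise / math.sqrt(slow_r * fast_r)) +
             math.log(hw / math.sqrt(slow_h * fast_h)))
        return s > 0

    if best_labels is None or best_score < silhouette_threshold:
        # single population: one class, assigned by its joint kinetics
        rise_med = float(np.median(X[:, 1]))
        hw_med = float(np.median(X[:, 2]))
        label = "slow" if slowness(rise_med, hw_med) else "fast"
        events = [replace(e, label=label if not e.clipped else "unassigned")
                  for e in catalog.events]
        return EventCatalog(events, catalog.duration_ms, 1)

    # merge the k waveform clusters into two classes by their kinetics centroids
    cents = np.array([Xz[best_labels == c][:, 1:].mean(axis=0)
                      for c in range(best_k)])
    if best_k == 2:
        meta = np.arange(2)
    else:
        meta = KMeans(n_clusters=2, n_init=10, random_state=seed).fit_predict(cents)
    mean_kin = [cents[meta == g].mean() for g in (0, 1)]
    slow_group = int(np.argmax(mean_kin))
    class_of_cluster = {c: ("slow" if meta[c] == slow_group else "fast")
                        for c in range(best_k)}

    labels_iter = iter(best_labels)
    events = []
    for e, ok in zip(catalog.events, valid):
        if not ok:
            events.append(replace(e, label="unassigned"))
        else:
            events.append(replace(e, label=class_of_cluster[int(next(labels_iter))]))
    return EventCatalog(events, catalog.duration_ms, best_k)


def isli_histogram(events, bin_ms: float = 4.0) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of consecutive inter-event intervals.

    ``events`` is an :class:`EventCatalog`, a list of events, or an array of
    peak times (ms). Returns ``(counts, bin_edges)``; empty arrays for fewer
    than two events.
    """
    if isinstance(events, EventCatalog):
        times = events.peak_times
    elif len(events) and isinstance(events[0], UnitaryEvent):
        times = np.array([e.peak_time for e in events])
    else:
        times = np.asarray(events, dtype=float)
    if times.size < 2:
        return np.array([], dtype=int), np.array([])
    intervals = np.diff(np.sort(times))
    n_bins = int(math.ceil(intervals.max() / bin_ms)) + 1
    edges = np.arange(0.0, (n_bins + 1) * bin_ms, bin_ms)
    counts, _ = np.histogram(intervals, bins=edges)
    return counts, edges


def detrended_autocorrelation(trace, lag_step_ms: float = 1.0,
                              lowpass_cutoff_hz: float | None = 2.0,
                              max_lag_ms: float = 1000.0) -> tuple[np.ndarray, np.ndarray]:
    """Normalized autocorrelation of the (optionally detrended) trace.

    When ``lowpass_cutoff_hz`` is given, a low-pass filtered copy of the
    trace is subtracted first, removing slow drift so the oscillatory
    component dominates. Returns ``(lags_ms, acf)`` with acf[0] = 1.
    """
    samples = np.asarray(trace.samples, dtype=float)
    rate = float(trace.sampling_rate_khz)
    x = samples - samples.mean()
    if lowpass_cutoff_hz is not None:
        nyq_hz = rate * 1000.0 / 2.0
        b, a = butter(2, lowpass_cutoff_hz / nyq_hz, btype="low")
        x = x - filtfilt(b, a, x)
        x = x - x.mean()
    n = x.size
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acf_full = np.fft.irfft(f * np.conj(f))[:n]
    acf_full /= acf_full[0]
    step = max(1, int(round(lag_step_ms * rate)))
    max_idx = min(n - 1, int(round(max_lag_ms * rate)))
    idx = np.arange(0, max_idx + 1, step)
    return idx / rate, acf_full[idx]
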