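"""Event-based simulation of spiking in an electrically coupled network.

Each neuron fires independently (Poisson by default) at a rate drawn from a
truncated normal population distribution. An action potential in a neuron
appears instantaneously in every coupled neighbor as a spikelet whose
amplitude is the edge's coupling coefficient times the nominal spike
amplitude; no membrane dynamics or spike interactions are modeled, which is
all the connection-estimation logic requires (event times, amplitudes and
source identities). On top of this, the module replays the validation of
the connections-per-cell estimator: record a pair of neurons, group their
common spikelets (by ground-truth source or by amplitude clustering), apply
the estimator, and compare estimated to real degrees as a function of
recording duration and firing-rate variability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network_gen import Connectome
from .pair_analysis import estimate_connections, group_common_spikelets

__all__ = [
    "SpikeTable", "CouplingMap", "CellRecording", "PairRecordingEvents",
    "sample_rates", "simulate_spikes", "build_coupling_map", "record_pair",
    "estimation_experiment", "error_vs_duration",
    "DEFAULT_RATE_MEAN_HZ", "DEFAULT_RATE_STD_HZ",
    "DEFAULT_CC_MEAN", "DEFAULT_CC_STD", "DEFAULT_DURATION_MS",
]

# Study conditions: population firing rate 0.058 +- 0.04 Hz, coupling
# coefficient 0.03 +- 0.019, 15 min recordings, 60 mV nominal spikes.
DEFAULT_RATE_MEAN_HZ = 0.058
DEFAULT_RATE_STD_HZ = 0.04
DEFAULT_CC_MEAN = 0.03
DEFAULT_CC_STD = 0.019
DEFAULT_CC_FLOOR = 0.001
DEFAULT_DURATION_MS = 15 * 60 * 1000.0
DEFAULT_SPIKE_AMPLITUDE_MV = 60.0


@dataclass
class SpikeTable:
    """Per-neuron ordered spike times (ms) over a fixed duration."""

    spikes: list[np.ndarray]
    duration_ms: float
    rate_mean_hz: float
    rate_std_hz: float
    seed: int

    @property
    def n(self) -> int:
        return len(self.spikes)

    def counts(self) -> np.ndarray:
        return np.array([s.size for s in self.spikes])


@dataclass
class CouplingMap:
    """Symmetric per-edge coupling coefficients and the nominal spike amplitude."""

    cc: dict[tuple[int, int], float]
    spike_amplitude_mv: float = DEFAULT_SPIKE_AMPLITUDE_MV

    def get(self, i: int, j: int) -> float:
        key = (i, j) if i < j else (j, i)
        return self.cc[key]

    def spikelet_amplitude(self, i: int, j: int) -> float:
        """Amplitude (mV) of the spikelet transmitted across edge (i, j)."""
        return self.get(i, j) * self.spike_amplitude_mv


@dataclass
class CellRecording:
    """Events seen by one recorded cell: incoming spikelets plus own spikes."""

    spikelet_times: np.ndarray
    spikelet_amplitudes: np.ndarray
    spikelet_sources: np.ndarray
    own_spikes: np.ndarray


@dataclass
class PairRecordingEvents:
    """Ground-truth event streams for a simulated paired recording."""

    cell_a: CellRecording
    cell_b: CellRecording
    id_a: int
    id_b: int
    coupled: bool
    duration_ms: float


def sample_rates(n: int, rate_mean: float = DEFAULT_RATE_MEAN_HZ,
                 rate_std: float = DEFAULT_RATE_STD_HZ, seed: int = 0) -> np.ndarray:
    """Per-neuron firing rates: normal(mean, std) truncated at 0 by redrawing."""
    if rate_mean <= 0:
        raise ValueError(f"rate_mean must be positive, got {rate_mean}")
    if rate_std < 0:
        raise ValueError(f"rate_std must be non-negative, got {rate_std}")
    if rate_std == 0:
        return np.full(n, float(rate_mean))
    rng = np.random.default_rng(seed)
    rates = rng.normal(rate_mean, rate_std, size=n)
    bad = rates <= 0
    while np.any(bad):
        rates[bad] = rng.normal(rate_mean, rate_std, size=int(bad.sum()))
        bad = rates <= 0
    return rates


def simulate_spikes(rates: np.ndarray, duration_ms: float, seed: int = 0,
                    firing: str = "poisson") -> SpikeTable:
    """Independent spike trains per neuron.

    ``firing="poisson"`` (the default): homogeneous Poisson process per
    neuron, so spike counts are Poisson(rate * duration).
    ``firing="uniform_count"``: exactly round(rate * duration) spikes at
    uniform random times — the equal-count regime in which the
    connections-per-cell estimator is exact.
    """
    if duration_ms <= 0:
        raise ValueError(f"duration must be positive, got {duration_ms}")
    rates = np.asarray(rates, dtype=float)
    rng = np.random.default_rng(seed)
    duration_s = duration_ms / 1000.0
    spikes = []
    for r in rates:
        if firing == "poisson":
            k = rng.poisson(r * duration_s)
        elif firing == "uniform_count":
            k = int(round(r * duration_s))
        else:
            raise ValueError(f"unknown firing mode {firing!r}")
        spikes.append(np.sort(rng.uniform(0.0, duration_ms, size=k)))
    return SpikeTable(spikes=spikes, duration_ms=float(duration_ms),
                      rate_mean_hz=float(rates.mean()) if rates.size else 0.0,
                      rate_std_hz=float(rates.std()) if rates.size else 0.0,
                      seed=seed)


def build_coupling_map(connectome: Connectome, cc_mean: float = DEFAULT_CC_MEAN,
                       cc_std: float = DEFAULT_CC_STD,
                       cc_floor: float = DEFAULT_CC_FLOOR, seed: int = 0,
                       spike_amplitude_mv: float = DEFAULT_SPIKE_AMPLITUDE_MV,
                       ) -> CouplingMap:
    """One symmetric coupling coefficient per edge, normal truncated at a floor."""
    rng = np.random.default_rng(seed)
    cc: dict[tuple[int, int], float] = {}
    for i, j in connectome.edge_list():
        v = rng.normal(cc_mean, cc_std)
        while v < cc_floor:
            v = rng.normal(cc_mean, cc_std)
        cc[(int(i), int(j))] = float(v)
    return CouplingMap(cc=cc, spike_amplitude_mv=spike_amplitude_mv)


def record_pair(spikes: SpikeTable, connectome: Connectome, coupling: CouplingMap,
                cell_a: int, cell_b: int) -> PairRecordingEvents:
    """Ground-truth event streams a dual intracellular recording would see.

    Every spike of every neighbor of a recorded cell lands in its record as
    a spikelet (amplitude = edge coupling coefficient x spike amplitude) at
    the spike time. Spikelets sourced from the partner cell are excluded
    from the spikelet table — the direct connection is carried by the
    ``coupled`` flag and enters the estimate only through the +1 rule.
    """
    n = connectome.n
    if not (0 <= cell_a < n and 0 <= cell_b < n) or cell_a == cell_b:
        raise ValueError(f"invalid recorded pair ({cell_a}, {cell_b}) for n={n}")

    def one_cell(rec: int, partner: int) -> CellRecording:
        times, amps, sources = [], [], []
        for nb in np.where(connectome.adjacency[rec])[0]:
            if nb == partner:
                continue
            t = spikes.spikes[nb]
            if t.size == 0:
                continue
            times.append(t)
            amps.append(np.full(t.size, coupling.spikelet_amplitude(rec, int(nb))))
            sources.append(np.full(t.size, nb, dtype=int))
        if times:
            t = np.concatenate(times)
            order = np.argsort(t, kind="stable")
            return CellRecording(t[order], np.concatenate(amps)[order],
                                 np.concatenate(sources)[order],
                                 spikes.spikes[rec].copy())
        return CellRecording(np.array([]), np.array([]), np.array([], dtype=int),
                             spikes.spikes[rec].copy())

    return PairRecordingEvents(
        cell_a=one_cell(cell_a, cell_b), cell_b=one_cell(cell_b, cell_a),
        id_a=cell_a, id_b=cell_b,
        coupled=bool(connectome.adjacency[cell_a, cell_b]),
        duration_ms=spikes.duration_ms)


def _estimate_from_recording(pair: PairRecordingEvents, grouping: str,
                             amplitude_noise_sd: float, rng: np.random.Generator,
                             dbscan_eps: float | None,
                             min_group_size: int) -> tuple[float, float]:
    """Estimates for the two cells of a recorded pair; NaN when undefined (C=0)."""
    rec_a, rec_b = pair.cell_a, pair.cell_b
    t_a, t_b = rec_a.spikelet_times.size, rec_b.spikelet_times.size

    if grouping == "ideal":
        common = np.intersect1d(np.unique(rec_a.spikelet_sources),
                                np.unique(rec_b.spikelet_sources))
        if common.size == 0:
            return np.nan, np.nan
        c = int(np.isin(rec_a.spikelet_sources, common).sum())
        n_g = int(common.size)
    elif grouping == "amplitude":
        amp_a = rec_a.spikelet_amplitudes + (
            rng.normal(0.0, amplitude_noise_sd, t_a) if amplitude_noise_sd else 0.0)
        amp_b = rec_b.spikelet_amplitudes + (
            rng.normal(0.0, amplitude_noise_sd, t_b) if amplitude_noise_sd else 0.0)
        from .pair_analysis import filter_groups, match_common_spikelets
        matches = match_common_spikelets((rec_a.spikelet_times, np.abs(amp_a)),
                                         (rec_b.spikelet_times, np.abs(amp_b)))
        if not matches:
            return np.nan, np.nan
        eps = dbscan_eps if dbscan_eps is not None else max(
            4.0 * amplitude_noise_sd, 1e-4)
        groups = filter_groups(
            group_common_spikelets(matches, method="dbscan", dbscan_eps=eps),
            min_group_size=min_group_size)
        c = sum(g.n for g in groups)
        n_g = len(groups)
        if c == 0:
            return np.nan, np.nan
    else:
        raise ValueError(f"unknown grouping mode {grouping!r}")

    est_a = estimate_connections(t_a, n_g, c, pair.coupled).reported
    est_b = estimate_connections(t_b, n_g, c, pair.coupled).reported
    return float(est_a), float(est_b)


def estimation_experiment(connectome: Connectome, coupling: CouplingMap,
                          duration_ms: float = DEFAULT_DURATION_MS,
                          rate_mean: float = DEFAULT_RATE_MEAN_HZ,
                          rate_std: float = DEFAULT_RATE_STD_HZ,
                          n_pairs: int = 20, seed: int = 0,
                          grouping: str = "ideal",
                          amplitude_noise_sd: float = 0.0,
                          dbscan_eps: float | None = None,
                          min_group_size: int | None = None,
                          firing: str = "poisson") -> pd.DataFrame:
    """Estimated vs real connections per cell over randomly sampled pairs.

    Simulates the whole network once, records ``n_pairs`` random pairs, and
    applies the estimator with either ground-truth source grouping
    (``grouping="ideal"``) or amplitude-based clustering with optional
    measurement noise (``grouping="amplitude"``). Pairs with no common
    spikelets have undefined estimates: they appear with NaN estimates and
    ``defined=False``, matching the convention of averaging only over pairs
    with common neighbors.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if min_group_size is None:
        # a real shared source contributes ~rate*duration common spikelets;
        # accept groups holding at least 10% of that (chance coincidences
        # almost never stack that high in one amplitude neighborhood)
        min_group_size = max(2, int(np.ceil(0.1 * rate_mean * duration_ms / 1000.0)))
    rng = np.random.default_rng(seed)
    rates = sample_rates(connectome.n, rate_mean, rate_std,
                         seed=int(rng.integers(2 ** 31)))
    spikes = simulate_spikes(rates, duration_ms, seed=int(rng.integers(2 ** 31)),
                             firing=firing)
    degrees = connectome.degrees()
    rows = []
    for _ in range(n_pairs):
        a, b = rng.choice(connectome.n, size=2, replace=False)
        pair = record_pair(spikes, connectome, coupling, int(a), int(b))
        est_a, est_b = _estimate_from_recording(pair, grouping, amplitude_noise_sd,
                                                rng, dbscan_eps, min_group_size)
        rows.append({
            "cell_a": int(a), "cell_b": int(b),
            "estimated_a": est_a, "real_a": int(degrees[a]),
            "estimated_b": est_b, "real_b": int(degrees[b]),
            "defined": not (np.isnan(est_a) or np.isnan(est_b)),
        })
    return pd.DataFrame(rows)


def error_vs_duration(connectome: Connectome, coupling: CouplingMap,
                      durations: list[float],
                      rate_stds: list[float],
                      n_seeds: int = 10, n_pairs: int = 20,
                      rate_mean: float = DEFAULT_RATE_MEAN_HZ,
                      grouping: str = "ideal", seed: int = 0,
                      firing: str = "poisson") -> pd.DataFrame:
    """Estimation error vs recording duration and firing-rate variability.

    For every (duration, rate_std) cell of the grid, runs
    :func:`estimation_experiment` over ``n_seeds`` seeds and reports the
    mean per-pair absolute error |estimated - real| and the error of the
    network-mean estimate |mean(estimated) - mean(real)|, both averaged over
    seeds and over defined pairs only.
    """
    if not durations or not rate_stds:
        raise ValueError("durations and rate_stds must be non-empty")
    rows = []
    for rate_std in rate_stds:
        for duration in durations:
            per_pair, mean_est = [], []
            for s in range(n_seeds):
                df = estimation_experiment(
                    connectome, coupling, duration_ms=duration,
                    rate_mean=rate_mean, rate_std=rate_std, n_pairs=n_pairs,
                    seed=seed + 1000 * s, grouping=grouping, firing=firing)
                d = df[df["defined"]]
                if len(d) == 0:
                    continue
                est = np.concatenate([d["estimated_a"], d["estimated_b"]])
                real = np.concatenate([d["real_a"], d["real_b"]])
                per_pair.append(np.abs(est - real).mean())
                mean_est.append(abs(est.mean() - real.mean()))
            rows.append({
                "duration_ms": duration, "rate_std_hz": rate_std,
                "n_defined_runs": len(per_pair),
                "per_pair_error": float(np.mean(per_pair)) if per_pair else np.nan,
                "mean_estimate_error": float(np.mean(mean_est)) if mean_est else np.nan,
            })
    return pd.DataFrame(rows)
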