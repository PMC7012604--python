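import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from olivenet import event_detect as ed
from olivenet import net_sim as ns
from olivenet import network_gen as ng
from olivenet import pair_analysis as pa
from olivenet import stats as ost
from olivenet import trace_synth as ts


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------


def test_match_within_window_only():
    matches = pa.match_common_spikelets(([100.0, 500.0], [1.0, 1.0]),
                                        ([104.0, 900.0], [1.0, 1.0]))
    assert len(matches) == 1
    assert (matches[0].time_a, matches[0].time_b) == (100.0, 104.0)


def test_match_prefers_nearest_peak():
    matches = pa.match_common_spikelets(([100.0], [1.0]),
                                        ([100.0, 106.0], [2.0, 3.0]))
    assert len(matches) == 1
    assert matches[0].time_b == 100.0
    assert matches[0].amplitude_b == 2.0


def test_match_one_to_one():
    # two A events compete for one B event; the closer pair wins, the other
    # A event falls back to the remaining B event
    matches = pa.match_common_spikelets(([100.0, 103.0], [1.0, 1.0]),
                                        ([102.0, 107.0], [1.0, 1.0]))
    assert len(matches) == 2
    pairs = {(m.time_a, m.time_b) for m in matches}
    assert pairs == {(103.0, 102.0), (100.0, 107.0)}


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_match_symmetric_in_the_two_cells(seed):
    rng = np.random.default_rng(seed)
    ta = np.sort(rng.uniform(0, 5000, rng.integers(0, 40)))
    tb = np.sort(rng.uniform(0, 5000, rng.integers(0, 40)))
    aa, ab = rng.uniform(0.5, 3, ta.size), rng.uniform(0.5, 3, tb.size)
    fwd = pa.match_common_spikelets((ta, aa), (tb, ab))
    rev = pa.match_common_spikelets((tb, ab), (ta, aa))
    assert {(m.time_a, m.time_b) for m in fwd} == {
        (m.time_b, m.time_a) for m in rev}
    assert all(m.dpeak <= pa.MATCH_WINDOW_MS for m in fwd)


# ---------------------------------------------------------------------------
# Grouping
# ---------------------------------------------------------------------------


def _matches_from_sources(specs, jitter=0.02, seed=0):
    """specs: list of (amp_a, amp_b, n_repeats)."""
    rng = np.random.default_rng(seed)
    matches, t = [], 100.0
    for amp_a, amp_b, n in specs:
        for _ in range(n):
            matches.append(pa.CommonSpikeletMatch(
                0, 0, t, t, amp_a + rng.normal(0, jitter),
                amp_b + rng.normal(0, jitter)))
            t += 100.0
    return matches


def test_grouping_two_separated_sources():
    matches = _matches_from_sources([(0.5, 2.0, 6), (2.5, 0.8, 6)])
    groups = pa.group_common_spikelets(matches)
    assert len(groups) == 2
    assert sorted(g.n for g in groups) == [6, 6]


def test_grouping_single_source_with_jitter():
    matches = _matches_from_sources([(1.0, 1.5, 5)])
    groups = pa.group_common_spikelets(matches)
    assert len(groups) == 1
    assert groups[0].n == 5


def test_grouping_four_source_paired_recording():
    """Sixteen common spikelets from four sources with 2-7 repeats each split
    into exactly four groups (the worked paired-recording example)."""
    specs = [(0.6, 1.8, 7), (1.4, 0.7, 4), (2.4, 2.6, 3), (3.2, 1.1, 2)]
    matches = _matches_from_sources(specs, seed=1)
    assert len(matches) == 16
    groups = pa.group_common_spikelets(matches)
    assert len(groups) == 4
    assert sorted(g.n for g in groups) == [2, 3, 4, 7]
    # groups partition the matches
    members = sorted(i for g in groups for i in g.member_indices)
    assert members == list(range(16))


def test_grouping_dbscan_mode_and_filtering():
    specs = [(0.6, 1.8, 5), (2.4, 0.9, 4), (1.5, 2.9, 1)]
    matches = _matches_from_sources(specs, seed=2)
    groups = pa.group_common_spikelets(matches, method="dbscan", dbscan_eps=0.2)
    assert sorted(g.n for g in groups) == [1, 4, 5]
    kept = pa.filter_groups(groups, min_group_size=2)
    assert sorted(g.n for g in kept) == [4, 5]
    with pytest.raises(ValueError):
        pa.group_common_spikelets(matches, method="spectral")


def test_grouping_merges_oversplit_ratio():
    """Amplitude clusters with indistinguishable cross-cell ratios merge."""
    matches = _matches_from_sources([(1.0, 2.0, 5), (1.002, 2.004, 5)],
                                    jitter=0.001, seed=3)
    groups = pa.group_common_spikelets(matches)
    assert len(groups) == 1


# ---------------------------------------------------------------------------
# The estimator
# ---------------------------------------------------------------------------


def test_estimate_connections_worked_examples():
    """The two printed worked examples: 25*4/16 + 1 = 7.25 -> 7 and
    48*4/16 + 1 = 13.0 -> 13."""
    black = pa.estimate_connections(25, 4, 16, coupled=True)
    assert black.raw == pytest.approx(7.25)
    assert black.reported == 7
    red = pa.estimate_connections(48, 4, 16, coupled=True)
    assert red.raw == pytest.approx(13.0)
    assert red.reported == 13


def test_estimate_connections_all_common():
    est = pa.estimate_connections(16, 4, 16, coupled=False)
    assert est.reported == 4


def test_estimate_connections_errors():
    with pytest.raises(pa.UndefinedEstimateError):
        pa.estimate_connections(10, 1, 0, coupled=False)
    with pytest.raises(ValueError):
        pa.estimate_connections(10, 0, 5, coupled=False)
    with pytest.raises(ValueError):
        pa.estimate_connections(4, 2, 5, coupled=False)


# ---------------------------------------------------------------------------
# Coupling coefficients
# ---------------------------------------------------------------------------


def _pulse_trace(delta, rate=10.0, onset=100.0, offset=350.0, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    samples = rng.normal(0, noise, 5000) if noise else np.zeros(5000)
    samples[int(onset * rate):int(offset * rate)] += delta
    return ts.VoltageTrace(samples, rate)


def test_dc_coupling_coefficient_identity_and_arithmetic():
    pre = _pulse_trace(-10.0)
    assert pa.dc_coupling_coefficient(pre, pre, (100.0, 350.0)) == pytest.approx(1.0)
    post = _pulse_trace(-0.3)
    cc = pa.dc_coupling_coefficient(pre, post, (100.0, 350.0))
    assert cc == pytest.approx(0.03, rel=1e-9)


def test_dc_coupling_coefficient_recovered_under_noise():
    pre = _pulse_trace(-10.0, noise=0.05, seed=1)
    post = _pulse_trace(-10.0 * 0.039, noise=0.05, seed=2)
    cc = pa.dc_coupling_coefficient(pre, post, (100.0, 350.0))
    assert cc == pytest.approx(0.039, rel=0.05)


def test_dc_coupling_coefficient_requires_deflection():
    flat = ts.VoltageTrace(np.zeros(5000), 10.0)
    pre = _pulse_trace(-10.0)
    with pytest.raises(ValueError):
        pa.dc_coupling_coefficient(flat, pre, (100.0, 350.0))


def test_spike_coupling_coefficient():
    assert pa.spike_coupling_coefficient(60.0, 1.2) == pytest.approx(0.02)
    with pytest.raises(ValueError):
        pa.spike_coupling_coefficient(0.0, 1.2)
    with pytest.raises(ValueError):
        pa.spike_coupling_coefficient(60.0, 0.0)


def test_spike_cc_tracks_dc_cc_linearly():
    """Spikelet/spike amplitude ratios regress linearly on the DC coupling
    coefficients that generated them."""
    rng = np.random.default_rng(4)
    dc_cc = rng.uniform(0.005, 0.08, 25)
    spike_amp = 60.0
    spikelet = dc_cc * spike_amp * (1 + rng.normal(0, 0.03, dc_cc.size))
    spike_cc = [pa.spike_coupling_coefficient(spike_amp, s) for s in spikelet]
    slope, intercept, r2, p = ost.linear_fit(dc_cc, spike_cc)
    assert slope > 0
    assert slope == pytest.approx(1.0, rel=0.1)
    assert r2 > 0.9
    assert p < 1e-6


# ---------------------------------------------------------------------------
# End-to-end on rendered traces
# ---------------------------------------------------------------------------


def test_pipeline_recovers_degrees_from_traces():
    """Simulate a network, render two paired recordings as voltage traces,
    detect, match, group and estimate: the mean estimate over recorded cells
    lands within 30% of the mean true degree (and matching hits the
    ground-truth common events at >= 95% precision and recall)."""
    geom = ng.cluster_neurons(ng.place_neurons(180, (125.0, 250.0, 100.0), 7),
                              40, seed=7)
    conn = ng.build_connectome(
        geom, ng.ConnectivityProfile(77, 45, 15, 20, 40), seed=7)
    coupling = ns.build_coupling_map(conn, seed=7)
    spikes = ns.simulate_spikes(
        ns.sample_rates(conn.n, 0.058, 0.0, seed=3), 900_000.0, seed=3)
    adj = conn.adjacency
    # two recorded pairs that share at least three neighbors
    pairs, a = [], 0
    for a in range(conn.n):
        for b in range(a + 1, conn.n):
            if (adj[a] & adj[b]).sum() >= 3:
                pairs.append((a, b))
                break
        if len(pairs) == 2:
            break
    est, real = [], []
    degrees = conn.degrees()
    for k, (a, b) in enumerate(pairs):
        rec = ns.record_pair(spikes, conn, coupling, a, b)
        trace_a, trace_b = ts.synth_pair_traces(rec, noise_sd=0.02, seed=50 + k)
        cat_a = ed.detect_events(trace_a)
        cat_b = ed.detect_events(trace_b)
        result = pa.analyze_pair(cat_a, cat_b,
                                 spikes_a=rec.cell_a.own_spikes,
                                 spikes_b=rec.cell_b.own_spikes,
                                 coupled=rec.coupled, grouping_method="dbscan",
                                 dbscan_eps=0.08, min_group_size=5)
        est += [result.estimate_a.reported, result.estimate_b.reported]
        real += [degrees[a], degrees[b]]
        # matching quality against ground-truth common events, before the
        # group-level chance filtering: exclude own spikes and partner-locked
        # events, then match
        def _clean(cat, own, partner):
            t, amp = cat.peak_times, cat.amplitudes
            keep = np.ones(t.size, bool)
            for s in own:
                keep &= np.abs(t - s) > 4.0
            for s in partner:
                keep &= np.abs(t - s) > 8.0
            return t[keep], amp[keep]

        raw = pa.match_common_spikelets(
            _clean(cat_a, rec.cell_a.own_spikes, rec.cell_b.own_spikes),
            _clean(cat_b, rec.cell_b.own_spikes, rec.cell_a.own_spikes))
        common_sources = set(rec.cell_a.spikelet_sources) & set(
            rec.cell_b.spikelet_sources)
        true_common = np.isin(rec.cell_a.spikelet_sources,
                              sorted(common_sources)).sum()
        assert len(raw) >= 0.95 * true_common        # recall
        assert len(raw) <= 1.05 * true_common        # precision (few spurious)
    assert abs(np.mean(est) - np.mean(real)) <= 0.3 * np.mean(real)


def test_analyze_pair_no_common_spikelets_flagged():
    with pytest.raises(pa.UndefinedEstimateError):
        pa.analyze_pair(([100.0, 300.0], [1.0, 1.0]),
                        ([5000.0], [1.0]))
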