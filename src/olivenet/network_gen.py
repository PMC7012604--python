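"""Clustered, distance-dependent connectivity models for electrically coupled networks.

Neurons are placed uniformly at random in a 3D box, grouped into spatial
clusters with k-means, and connected pairwise with a Gaussian
distance-dependent probability

    P(x) = (Sigma / 100) * exp(-x^2 / (2 * sigma^2))

where ``Sigma`` is the maximal connection probability in percent (the value
at zero inter-somatic distance) and ``sigma`` (um) sets the spatial decay.
A clustered network uses one (Sigma, sigma) pair for neuron pairs inside the
same cluster and another for pairs in different clusters; a distance-only
network uses a single profile for all pairs.

Everything downstream (common-neighbor distributions, connection probability
vs distance, Gaussian profile fits) operates on the resulting symmetric
boolean adjacency matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import curve_fit
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans


class FitFailureError(RuntimeError):
    """Raised when a Gaussian profile fit does not converge."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NetworkGeometry:
    """Positions (um) of point somata in a box, with optional cluster labels.

    Attributes
    ----------
    positions : (n, 3) float array
        Coordinates in um, inside ``volume``.
    volume : tuple of float
        Box dimensions (x, y, z) in um.
    cluster_label : (n,) int array or None
        Spatial cluster index per neuron, contiguous from 0; None until
        :func:`cluster_neurons` has been applied.
    seed : int
        Seed used for placement.
    """

    positions: np.ndarray
    volume: tuple[float, float, float]
    seed: int
    cluster_label: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    @property
    def n_clusters(self) -> int:
        if self.cluster_label is None:
            return 0
        return int(self.cluster_label.max()) + 1

    def density_per_10um_cube(self) -> float:
        """Neuron density in units of neurons per (10 um)^3, truncated to 3 decimals."""
        vol_units = math.prod(self.volume) / 1000.0  # (10 um)^3 = 1000 um^3
        return math.floor(self.n / vol_units * 1000.0) / 1000.0

    def pairwise_distances(self) -> np.ndarray:
        """Condensed Euclidean distance matrix (um), ``scipy.spatial.distance.pdist`` order."""
        return pdist(self.positions)


@dataclass(frozen=True)
class ConnectivityProfile:
    """Gaussian connection-probability profiles for a (possibly clustered) network.

    ``sigma_max_*`` are the maximal probabilities in percent (value at zero
    distance); ``sigma_decay_*`` are the Gaussian decay constants in um.
    For a distance-only (non-clustered) network set the between-cluster
    parameters equal to the within-cluster ones.
    """

    sigma_max_within: float
    sigma_decay_within: float
    sigma_max_between: float
    sigma_decay_between: float
    cluster_size: int = 40

    def __post_init__(self) -> None:
        for s in (self.sigma_max_within, self.sigma_max_between):
            if not 0.0 <= s <= 100.0:
                raise ValueError(f"sigma_max must be in [0, 100] percent, got {s}")
        for s in (self.sigma_decay_within, self.sigma_decay_between):
            if s <= 0:
                raise ValueError(f"sigma_decay must be positive, got {s}")
        if self.cluster_size < 1:
            raise ValueError("cluster_size must be >= 1")

    @classmethod
    def distance_only(cls, sigma_max: float, sigma_decay: float,
                      cluster_size: int = 40) -> "ConnectivityProfile":
        """A single-profile (non-clustered) network parameterization."""
        return cls(sigma_max, sigma_decay, sigma_max, sigma_decay, cluster_size)


@dataclass(frozen=True)
class Connectome:
    """Symmetric boolean adjacency over a :class:`NetworkGeometry`."""

    adjacency: np.ndarray
    geometry: NetworkGeometry
    profile: ConnectivityProfile
    seed: int

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    def mean_degree(self) -> float:
        return float(self.degrees().mean())

    def edge_list(self) -> np.ndarray:
        """(m, 2) array of edges with i < j."""
        iu, ju = np.triu_indices(self.n, k=1)
        mask = self.adjacency[iu, ju]
        return np.column_stack([iu[mask], ju[mask]])


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------


def place_neurons(n: int, volume: tuple[float, float, float], seed: int) -> NetworkGeometry:
    """Place ``n`` somata i.i.d. uniformly in a box of ``volume`` (um)."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    volume = tuple(float(v) for v in volume)
    if len(volume) != 3 or any(v <= 0 for v in volume):
        raise ValueError(f"volume must be three positive dimensions, got {volume}")
    rng = np.random.default_rng(seed)
    positions = rng.uniform(0.0, 1.0, size=(n, 3)) * np.asarray(volume)
    return NetworkGeometry(positions=positions, volume=volume, seed=seed)


def cluster_neurons(geometry: NetworkGeometry, cluster_size: int, seed: int) -> NetworkGeometry:
    """Label neurons by spatial k-means with k = round(n / cluster_size) (min 1).

    Uses k-means++ seeding with 10 restarts, keeping the lowest-inertia
    solution; labels are relabelled contiguously from 0.
    """
    if cluster_size < 1 or cluster_size > geometry.n:
        raise ValueError(
            f"cluster_size must be in [1, n={geometry.n}], got {cluster_size}")
    k = max(1, int(np.round(geometry.n / cluster_size)))
    if k == 1:
        labels = np.zeros(geometry.n, dtype=int)
    else:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = km.fit_predict(geometry.positions)
    # contiguous relabel (KMeans labels already 0..k-1, but guard anyway)
    _, labels = np.unique(labels, return_inverse=True)
    return replace(geometry, cluster_label=labels.astype(int))


def connection_probability(distance, sigma_max: float, sigma_decay: float):
    """Gaussian connection probability P = Sigma * exp(-x^2/(2 sigma^2)) / 100.

    ``distance`` may be a scalar or array (um); ``sigma_max`` is in percent.
    """
    if sigma_decay <= 0:
        raise ValueError(f"sigma_decay must be positive, got {sigma_decay}")
    distance = np.asarray(distance, dtype=float)
    if np.any(distance < 0):
        raise ValueError("distances must be non-negative")
    p = sigma_max * np.exp(-(distance ** 2) / (2.0 * sigma_decay ** 2)) / 100.0
    return p if p.ndim else float(p)


def build_connectome(geometry: NetworkGeometry, profile: ConnectivityProfile,
                     seed: int) -> Connectome:
    """Draw a symmetric adjacency: each unordered pair is connected independently.

    The within-cluster (Sigma_w, sigma_w) profile applies to pairs with equal
    cluster labels, the between-cluster profile to all other pairs.
    """
    if geometry.cluster_label is None:
        raise ValueError("geometry must be clustered first (run cluster_neurons)")
    n = geometry.n
    dist = geometry.pairwise_distances()  # condensed
    labels = geometry.cluster_label
    iu, ju = np.triu_indices(n, k=1)
    same = labels[iu] == labels[ju]
    p = np.where(
        same,
        connection_probability(dist, profile.sigma_max_within, profile.sigma_decay_within),
        connection_probability(dist, profile.sigma_max_between, profile.sigma_decay_between),
    )
    rng = np.random.default_rng(seed)
    connected = rng.random(p.shape) < p
    adjacency = np.zeros((n, n), dtype=bool)
    adjacency[iu, ju] = connected
    adjacency |= adjacency.T
    return Connectome(adjacency=adjacency, geometry=geometry, profile=profile, seed=seed)


def expected_mean_degree(geometry: NetworkGeometry, profile: ConnectivityProfile) -> float:
    """Analytic expected mean degree, Sum over pairs of P(d_ij) * 2 / n."""
    if geometry.cluster_label is None:
        raise ValueError("geometry must be clustered first")
    dist = geometry.pairwise_distances()
    labels = geometry.cluster_label
    iu, ju = np.triu_indices(geometry.n, k=1)
    same = labels[iu] == labels[ju]
    p = np.where(
        same,
        connection_probability(dist, profile.sigma_max_within, profile.sigma_decay_within),
        connection_probability(dist, profile.sigma_max_between, profile.sigma_decay_between),
    )
    return float(2.0 * p.sum() / geometry.n)


def matched_distance_only_profile(geometry: NetworkGeometry, target_mean_degree: float,
                                  sigma_decay: float) -> ConnectivityProfile:
    """Distance-only profile whose expected mean degree matches a target.

    The expected degree is linear in Sigma, so Sigma is solved in closed
    form from the sampled positions. Raises if the required Sigma exceeds
    100% (target unreachable at this decay length).
    """
    dist = geometry.pairwise_distances()
    per_percent = 2.0 * np.exp(-(dist ** 2) / (2.0 * sigma_decay ** 2)).sum() / (
        100.0 * geometry.n)
    sigma_max = target_mean_degree / per_percent
    if sigma_max > 100.0:
        raise ValueError(
            f"target mean degree {target_mean_degree:.2f} needs Sigma={sigma_max:.1f}% "
            f"> 100% at sigma_decay={sigma_decay} um")
    return ConnectivityProfile.distance_only(sigma_max, sigma_decay)


# ---------------------------------------------------------------------------
# Interrogation
# ---------------------------------------------------------------------------


def common_neighbor_count(connectome: Connectome, i: int, j: int) -> int:
    """Number of neurons adjacent to both i and j (i, j themselves excluded)."""
    n = connectome.n
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError(f"indices ({i}, {j}) out of range for n={n}")
    if i == j:
        raise ValueError("common neighbors are defined for distinct neurons")
    # the zero diagonal guarantees i and j are never counted
    return int(np.count_nonzero(connectome.adjacency[i] & connectome.adjacency[j]))


def _eligible_pairs(connectome: Connectome, max_distance: float) -> np.ndarray:
    dist = squareform(connectome.geometry.pairwise_distances())
    iu, ju = np.triu_indices(connectome.n, k=1)
    mask = dist[iu, ju] <= max_distance
    return np.column_stack([iu[mask], ju[mask]])


def _sample_rows(rows: np.ndarray, n_pairs: int | None, seed: int) -> np.ndarray:
    if n_pairs is None or n_pairs >= len(rows):
        return rows
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(rows), size=n_pairs, replace=False)
    return rows[idx]


def common_neighbor_distribution(connectome: Connectome, max_distance: float = 40.0,
                                 n_pairs: int | None = None, seed: int = 0,
                                 max_count: int = 7) -> np.ndarray:
    """Histogram of common-neighbor counts over nearby pairs.

    Pairs with inter-somatic distance <= ``max_distance`` (um) are sampled
    without replacement (all of them when ``n_pairs`` is None or exceeds the
    number available). Returns a length ``max_count + 2`` histogram over
    counts 0..max_count with the last bin collecting counts > max_count,
    mirroring the 0..7+ categories used for common spikelet groups.
    """
    pairs = _eligible_pairs(connectome, max_distance)
    if len(pairs) == 0:
        raise ValueError(f"no pairs within {max_distance} um")
    pairs = _sample_rows(pairs, n_pairs, seed)
    adj = connectome.adjacency
    counts = (adj[pairs[:, 0]] & adj[pairs[:, 1]]).sum(axis=1)
    hist = np.bincount(np.minimum(counts, max_count + 1), minlength=max_count + 2)
    return hist


def connectivity_by_distance(connectome: Connectome, bin_width: float = 10.0,
                             max_distance: float = 100.0, n_pairs: int | None = None,
                             seed: int = 0) -> "pd.DataFrame":
    """Connection counts per distance bin over sampled pairs.

    Returns a DataFrame with columns ``bin_low``, ``bin_high``, ``tested``,
    ``connected``, ``probability`` (NaN for empty bins).
    """
    import pandas as pd

    pairs = _eligible_pairs(connectome, max_distance)
    if len(pairs) == 0:
        raise ValueError(f"no pairs within {max_distance} um")
    pairs = _sample_rows(pairs, n_pairs, seed)
    dist = squareform(connectome.geometry.pairwise_distances())
    d = dist[pairs[:, 0], pairs[:, 1]]
    conn = connectome.adjacency[pairs[:, 0], pairs[:, 1]]
    edges = np.arange(0.0, max_distance + bin_width / 2, bin_width)
    which = np.clip(np.digitize(d, edges) - 1, 0, len(edges) - 2)
    tested = np.bincount(which, minlength=len(edges) - 1)
    connected = np.bincount(which, weights=conn.astype(float),
                            minlength=len(edges) - 1).astype(int)
    with np.errstate(invalid="ignore"):
        prob = np.where(tested > 0, connected / np.maximum(tested, 1), np.nan)
    return pd.DataFrame({
        "bin_low": edges[:-1], "bin_high": edges[1:],
        "tested": tested, "connected": connected, "probability": prob,
    })


def fit_gaussian_profile(distances, probabilities) -> tuple[float, float]:
    """Least-squares fit of P(x) = Sigma exp(-x^2 / 2 sigma^2) / 100.

    Returns ``(sigma_max, sigma_decay)`` with ``sigma_max`` in percent.
    Raises :class:`FitFailureError` on non-convergence or when the profile
    is identically zero (sigma unidentifiable).
    """
    distances = np.asarray(distances, dtype=float)
    probabilities = np.asarray(probabilities, dtype=float)
    if distances.size < 3:
        raise ValueError("need at least 3 points to fit a profile")
    if np.any((probabilities < 0) | (probabilities > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if np.all(probabilities == 0):
        raise FitFailureError("all probabilities are zero: Sigma=0, sigma unidentifiable")

    def model(x, sigma_max, sigma_decay):
        return sigma_max * np.exp(-(x ** 2) / (2.0 * sigma_decay ** 2)) / 100.0

    p0 = (float(probabilities.max() * 100.0),
          float(max(distances[np.argmax(distances * (probabilities > 0))], 1.0)))
    try:
        popt, _ = curve_fit(model, distances, probabilities, p0=p0,
                            bounds=([0.0, 1e-9], [100.0, np.inf]), maxfev=10000)
    except RuntimeError as exc:  # pragma: no cover - scipy message passthrough
        raise FitFailureError(f"Gaussian profile fit did not converge: {exc}") from exc
    return float(popt[0]), float(popt[1])
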