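"""Statistical comparison of model-predicted and observed distributions.

Implements the tests used to compare network-model predictions with
experimental observations: a Monte Carlo Fisher's exact test for R x C
contingency tables (100,000 replicates by default), per-distance-bin 2 x 2
Fisher tests merged with Fisher's combined probability method, a chi-square
goodness-of-fit with an expected-count-driven bin-merging rule, and a small
OLS helper for the linear relations (e.g. spike coupling coefficient vs DC
coupling coefficient).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats
from scipy.special import gammaln

__all__ = [
    "ContingencyTable", "fisher_exact_mc", "distance_fisher_combined",
    "distance_chisquare_merged", "compare_common_group_distributions",
    "linear_fit", "DEFAULT_MC_REPLICATES",
]

DEFAULT_MC_REPLICATES = 100_000


@dataclass(frozen=True)
class ContingencyTable:
    """Non-negative integer matrix with optional row/column labels."""

    counts: np.ndarray
    row_labels: tuple[str, ...] | None = None
    col_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] < 2 or c.shape[1] < 2:
            raise ValueError("contingency table must be at least 2 x 2")
        if np.any(c < 0) or not np.issubdtype(c.dtype, np.integer):
            raise ValueError("contingency table entries must be non-negative integers")


def _validate_table(table) -> np.ndarray:
    if isinstance(table, ContingencyTable):
        t = table.counts
    else:
        t = np.asarray(table)
    if not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)):
            raise ValueError("table entries must be integers")
        t = np.round(t).astype(np.int64)
    t = t.astype(np.int64)
    if t.ndim != 2 or min(t.shape) < 2:
        raise ValueError("table must be at least 2 x 2")
    if np.any(t < 0):
        raise ValueError("table entries must be non-negative")
    if np.any(t.sum(axis=1) == 0) or np.any(t.sum(axis=0) == 0):
        raise ValueError("degenerate table: zero row or column margin")
    return t


def _log_table_prob_terms(counts: np.ndarray) -> np.ndarray:
    """-sum log(n_ij!) over cells: the margin-conditional probability up to a constant."""
    return -gammaln(counts + 1.0).sum(axis=-1)


def fisher_exact_mc(table, replicates: int = DEFAULT_MC_REPLICATES,
                    seed: int = 0) -> float:
    """Monte Carlo Fisher's exact test for an R x C contingency table.

    Samples ``replicates`` tables uniformly from the margin-conditional
    (multivariate hypergeometric) null and counts those whose probability is
    at most that of the observed table (ties included). The observed table
    itself is added to the replicate pool, so the returned p-value is
    (1 + #more-extreme) / (replicates + 1) and never zero.
    """
    t = _validate_table(table)
    rng = np.random.default_rng(seed)
    row_sums = t.sum(axis=1)
    col_sums = t.sum(axis=0)
    obs_stat = _log_table_prob_terms(t.reshape(-1))

    if t.shape[0] == 2:
        # first row of a 2 x C table is multivariate hypergeometric
        top = rng.multivariate_hypergeometric(col_sums, int(row_sums[0]),
                                              size=replicates)
        bottom = col_sums[None, :] - top
        sim_stat = (_log_table_prob_terms(top) + _log_table_prob_terms(bottom))
    else:
        # general R x C: sample by shuffling column labels over row labels
        rows = np.repeat(np.arange(t.shape[0]), row_sums)
        cols = np.repeat(np.arange(t.shape[1]), col_sums)
        sim_stat = np.empty(replicates)
        for r in range(replicates):
            rng.shuffle(cols)
            sim = np.zeros_like(t)
            np.add.at(sim, (rows, cols), 1)
            sim_stat[r] = _log_table_prob_terms(sim.reshape(-1))

    extreme = int(np.count_nonzero(sim_stat <= obs_stat + 1e-9))
    return (1 + extreme) / (replicates + 1)


def distance_fisher_combined(model_connected, model_tested,
                             experimental_connected, experimental_tested,
                             ) -> tuple[float, list[float]]:
    """Per-distance-bin 2 x 2 Fisher tests merged by Fisher's combined method.

    Inputs are per-bin counts of connected pairs and of tested pairs for the
    model and the experiment (default layout: 10 bins of 10 um covering
    0-100 um). Each non-empty bin yields a 2 x 2 exact test on
    (connected, non-connected) x (model, experiment); empty bins are skipped
    with a warning and the degrees of freedom adjusted. Returns
    ``(combined_p, per_bin_p)``.
    """
    mc = np.asarray(model_connected, dtype=np.int64)
    mt = np.asarray(model_tested, dtype=np.int64)
    ec = np.asarray(experimental_connected, dtype=np.int64)
    et = np.asarray(experimental_tested, dtype=np.int64)
    if not (mc.shape == mt.shape == ec.shape == et.shape):
        raise ValueError("per-bin count vectors must share a shape")
    if np.any(mc > mt) or np.any(ec > et):
        raise ValueError("connected counts cannot exceed tested counts")
    p_values = []
    for k in range(mc.size):
        if mt[k] == 0 or et[k] == 0:
            warnings.warn(f"distance bin {k} has no tested pairs; skipped",
                          stacklevel=2)
            continue
        table = np.array([[mc[k], mt[k] - mc[k]], [ec[k], et[k] - ec[k]]])
        _, p = sstats.fisher_exact(table)
        p_values.append(float(p))
    if not p_values:
        raise ValueError("no non-empty distance bins")
    stat = -2.0 * float(np.sum(np.log(p_values)))
    combined_p = float(sstats.chi2.sf(stat, 2 * len(p_values)))
    return combined_p, p_values


# Merge rule used for the goodness-of-fit chi-square: per column, lists of
# distance-bin index groups (10 um bins over 0-100 um) collapsed so that
# every expected cell reaches ~5 counts. The connected column merges the
# 60-100 um bins; the non-connected column merges the 80-100 um bins.
DEFAULT_MERGE_RULE = {
    "connected": [[6, 7, 8, 9]],
    "non_connected": [[8, 9]],
}


def _apply_merges(vec: np.ndarray, merges: list[list[int]]) -> np.ndarray:
    merged_idx = sorted({i for grp in merges for i in grp})
    keep = [i for i in range(vec.size) if i not in merged_idx]
    out = [vec[i] for i in keep] + [vec[grp].sum() for grp in merges]
    return np.asarray(out, dtype=float)


def distance_chisquare_merged(model_expected, observed,
                              merge_rule: dict | None = None,
                              ) -> tuple[float, float, int]:
    """Chi-square goodness-of-fit of observed vs model-expected counts.

    ``model_expected`` and ``observed`` are dicts with keys ``connected``
    and ``non_connected``, each a length-10 per-distance-bin count vector.
    Expected counts are normalized per column and rescaled to the observed
    column totals; the merge rule then collapses the sparse far-distance
    bins. Returns ``(statistic, p_value, dof)`` and warns if any expected
    cell stays below 5 after merging.
    """
    rule = DEFAULT_MERGE_RULE if merge_rule is None else merge_rule
    obs_cells, exp_cells = [], []
    for col in ("connected", "non_connected"):
        obs = np.asarray(observed[col], dtype=float)
        exp = np.asarray(model_expected[col], dtype=float)
        if obs.shape != exp.shape:
            raise ValueError(f"column {col}: shape mismatch")
        if exp.sum() <= 0:
            raise ValueError(f"column {col}: expected counts sum to zero")
        exp = exp / exp.sum() * obs.sum()
        obs_cells.append(_apply_merges(obs, rule.get(col, [])))
        exp_cells.append(_apply_merges(exp, rule.get(col, [])))
    o = np.concatenate(obs_cells)
    e = np.concatenate(exp_cells)
    if np.any(e < 5):
        warnings.warn(
            f"{int((e < 5).sum())} expected cells below 5 after merging",
            stacklevel=2)
    stat = float(((o - e) ** 2 / e).sum())
    dof = o.size - 1
    p = float(sstats.chi2.sf(stat, dof))
    return stat, p, dof


def compare_common_group_distributions(model_hist, experimental_hist,
                                       replicates: int = DEFAULT_MC_REPLICATES,
                                       seed: int = 0) -> float:
    """MC Fisher's exact p-value for two common-group-count histograms.

    The histograms (counts over the number-of-common-groups categories,
    0..7+) become the two rows of a contingency table; categories empty in
    both are dropped.
    """
    m = np.asarray(model_hist, dtype=np.int64)
    e = np.asarray(experimental_hist, dtype=np.int64)
    if m.shape != e.shape:
        raise ValueError("histograms must share categories")
    keep = (m + e) > 0
    table = np.vstack([m[keep], e[keep]])
    if table.shape[1] < 2:
        raise ValueError("need at least two non-empty categories")
    return fisher_exact_mc(table, replicates=replicates, seed=seed)


def linear_fit(x, y) -> tuple[float, float, float, float]:
    """Ordinary least squares y = slope * x + intercept.

    Returns ``(slope, intercept, r_squared, p_value)`` with the Pearson
    p-value of the slope.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")
    res = sstats.linregress(x, y)
    return (float(res.slope), float(res.intercept),
            float(res.rvalue ** 2), float(res.pvalue))
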