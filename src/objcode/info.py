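"""Bias-corrected mutual information and its decompositions.

Spike counts are discretized into equi-populated bins (3 by default,
computed on a neuron's pooled responses).  Plug-in Shannon information
is corrected for limited sampling with the asymptotic (Panzeri-Treves)
term

    BIAS = 1 / (2 N ln 2) * [ sum_s (R_s - 1) - (R - 1) ]

where N is the total trial count and R_s / R are the numbers of response
bins with nonzero conditional / unconditional probability.  Two
decompositions of the total stimulus information I(R;S) are provided:

* energy decomposition   I(R;S) = I(R;L) + I(R;S'|L)   (L = RF luminance)
* invariance decomposition I(R;S) = I(R;O) + I(R;T|O)  (O = object id)

Both identities are exact for the plug-in estimator, because the
conditioning variable is a deterministic function of the stimulus
condition.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "BinnedResponse",
    "InfoDecomposition",
    "equipopulated_bins",
    "plugin_mi",
    "pt_bias",
    "support_size",
    "corrected_mi",
    "joint_counts",
    "energy_decomposition",
    "invariance_decomposition",
    "luminance_object_info",
    "permutation_significance",
    "sparseness",
    "luminance_sensitivity_curve",
]

LN2 = np.log(2.0)


@dataclass
class BinnedResponse:
    """Discretized responses: a bin index per trial."""

    bin_index: np.ndarray
    n_bins: int
    bin_edges: np.ndarray

    def counts(self) -> np.ndarray:
        return np.bincount(self.bin_index.ravel(), minlength=self.n_bins)


def equipopulated_bins(values: np.ndarray, n_bins: int = 3) -> BinnedResponse:
    """Discretize pooled responses into equi-populated bins.

    Edges are the k/n_bins quantiles of the pooled values; values equal
    to an edge go to the lower bin.  With heavy ties the bins cannot be
    exactly equi-populated; the realized counts are attached to the
    returned object and a warning is emitted.  If fewer distinct values
    than bins exist, the binning collapses (with a warning).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("values must be non-empty")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    distinct = np.unique(values)
    if n_bins > distinct.size:
        warnings.warn(
            f"n_bins={n_bins} exceeds {distinct.size} distinct values; "
            "binning collapses",
            stacklevel=2,
        )
    qs = np.arange(1, n_bins) / n_bins
    edges = np.quantile(values, qs) if n_bins > 1 else np.array([])
    idx = np.digitize(values, edges, right=True)
    binned = BinnedResponse(bin_index=idx, n_bins=n_bins, bin_edges=edges)
    counts = binned.counts()
    if n_bins > 1 and counts.size and (counts.max() - counts.min()) > np.ceil(
        values.size / n_bins
    ):
        # routine for integer spike counts: ties at the quantile edges
        # go to the lower bin, so bins deviate from equipopulation
        logger.debug("tied edges: bin counts %s", counts.tolist())
    return binned


def plugin_mi(table: np.ndarray) -> float:
    """Plug-in Shannon mutual information (bits) of a contingency table
    of nonnegative counts (rows: stimuli, columns: response bins)."""
    table = np.asarray(table, dtype=float)
    if np.any(table < 0):
        raise ValueError("counts must be nonnegative")
    total = table.sum()
    if total == 0:
        raise ValueError("all-zero contingency table")
    p = table / total
    ps = p.sum(axis=1, keepdims=True)
    pr = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (ps * pr))
    return float(np.nansum(terms))


def support_size(counts: np.ndarray, method: str = "naive") -> int:
    """Estimate the number of response bins with nonzero probability.

    ``naive``: count of occupied bins.  ``bayes``: occupancy inversion -
    the smallest support R such that the expected number of occupied
    bins after N uniform draws, R (1 - (1 - 1/R)^N), reaches the
    observed occupancy (capped at the table width).  The two agree
    whenever sampling is dense.
    """
    counts = np.asarray(counts, dtype=float)
    occupied = int(np.count_nonzero(counts))
    if method == "naive" or occupied == 0:
        return occupied
    if method != "bayes":
        raise ValueError(f"unknown support method {method!r}")
    n = counts.sum()
    max_r = counts.size
    if occupied >= max_r:
        return max_r
    for r in range(occupied, max_r + 1):
        expected = r * (1.0 - (1.0 - 1.0 / r) ** n)
        if expected >= occupied:
            return r
    return max_r


def pt_bias(
    rs_bins: np.ndarray | list[int], r_bins: int, n_total: int
) -> float:
    """Asymptotic limited-sampling bias (bits) of plug-in MI."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    rs = np.asarray(rs_bins, dtype=float)
    return float((np.sum(rs - 1) - (r_bins - 1)) / (2.0 * n_total * LN2))


def _table_bias(table: np.ndarray, support_method: str = "naive") -> float:
    table = np.asarray(table, dtype=float)
    rows = table[table.sum(axis=1) > 0]
    rs = [support_size(row, support_method) for row in rows]
    r = support_size(table.sum(axis=0), support_method)
    return pt_bias(rs, r, int(table.sum()))


def corrected_mi(table: np.ndarray, support_method: str = "naive") -> float:
    """Plug-in MI minus the asymptotic sampling bias."""
    return plugin_mi(table) - _table_bias(table, support_method)


def joint_counts(
    stimulus_index: np.ndarray, bin_index: np.ndarray, n_stimuli: int, n_bins: int
) -> np.ndarray:
    """Stimulus x response-bin contingency table from per-trial labels."""
    table = np.zeros((n_stimuli, n_bins))
    np.add.at(table, (np.asarray(stimulus_index), np.asarray(bin_index)), 1.0)
    return table


def _counts_to_trials(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(n_cond, n_trials) count array -> per-trial (stim_idx, response)."""
    counts = np.asarray(counts, dtype=float)
    n_cond, n_trials = counts.shape
    stim = np.repeat(np.arange(n_cond), n_trials)
    return stim, counts.ravel()


@dataclass
class InfoDecomposition:
    """Information terms for one neuron (bits, bias-corrected unless
    suffixed ``_plugin``)."""

    I_RS: float
    I_RL: float = float("nan")
    I_RSprime_given_L: float = float("nan")
    f_high: float = float("nan")
    I_RO: float = float("nan")
    I_RT_given_O: float = float("nan")
    I_LO: float = float("nan")
    p_value: float = float("nan")
    I_RS_plugin: float = float("nan")
    identity_gap_plugin: float = float("nan")

    def summary(self) -> str:
        rows = [
            ("I(R;S)", self.I_RS),
            ("I(R;L)", self.I_RL),
            ("I(R;S'|L)", self.I_RSprime_given_L),
            ("f_high", self.f_high),
            ("I(R;O)", self.I_RO),
            ("I(R;T|O)", self.I_RT_given_O),
            ("I(L;O)", self.I_LO),
            ("permutation p", self.p_value),
        ]
        width = max(len(k) for k, _ in rows)
        lines = ["Information decomposition", "-" * 25]
        lines += [
            f"{k.ljust(width)} : {v:.4f}" for k, v in rows if np.isfinite(v)
        ]
        return "\n".join(lines)


def _bin_condition_counts(
    counts: np.ndarray, n_bins: int, bin_edges: np.ndarray | None = None
) -> np.ndarray:
    """Per-trial counts (n_cond, n_trials) -> per-condition response-bin
    tables (n_cond, n_bins), pooled-equipopulated binning."""
    stim, resp = _counts_to_trials(counts)
    if bin_edges is None:
        binned = equipopulated_bins(resp, n_bins)
        idx = binned.bin_index
    else:
        idx = np.digitize(resp, bin_edges, right=True)
    return joint_counts(stim, idx, counts.shape[0], n_bins)


def _conditional_terms(
    table: np.ndarray, groups: np.ndarray, support_method: str
) -> tuple[float, float]:
    """(plug-in, corrected) conditional information
    sum_g P(g) I(R; S | G=g) from a stimulus x bin table whose rows are
    labelled by the conditioning variable ``groups``."""
    total = table.sum()
    plug = 0.0
    corr = 0.0
    for g in np.unique(groups):
        sub = table[groups == g]
        w = sub.sum() / total
        if sub.sum() == 0:
            continue
        plug_g = plugin_mi(sub)
        plug += w * plug_g
        corr += w * (plug_g - _table_bias(sub, support_method))
    return plug, corr


def energy_decomposition(
    counts: np.ndarray,
    L_values: np.ndarray,
    n_response_bins: int = 3,
    n_L_bins: int = 23,
    support_method: str = "naive",
    bin_edges: np.ndarray | None = None,
) -> InfoDecomposition:
    """Decompose total stimulus information into the RF-luminance part
    and the luminance-independent part.

    Parameters
    ----------
    counts : (n_conditions, n_trials) spike counts (230 conditions in
        the standard battery subset).
    L_values : RF luminance of each condition.
    n_L_bins : L is discretized into this many equi-populated bins over
        the conditions (23 bins of 10 stimuli for the standard subset).

    Returns an :class:`InfoDecomposition` with I(R;S), I(R;L),
    I(R;S'|L) (computed directly as the conditional plug-in term, bias
    corrected term-wise) and f_high = I(R;S'|L) / I(R;S).  The plug-in
    chain-rule identity is recorded in ``identity_gap_plugin``.
    """
    counts = np.asarray(counts, dtype=float)
    L_values = np.asarray(L_values, dtype=float)
    n_cond = counts.shape[0]
    if L_values.shape[0] != n_cond:
        raise ValueError("L_values must have one entry per condition")
    if n_L_bins > n_cond:
        raise ValueError("fewer conditions than luminance bins")
    table = _bin_condition_counts(counts, n_response_bins, bin_edges)

    # condition -> L-bin assignment (equi-populated over conditions)
    order = np.argsort(L_values, kind="stable")
    l_bin = np.empty(n_cond, dtype=int)
    l_bin[order] = (np.arange(n_cond) * n_L_bins) // n_cond

    I_RS_plug = plugin_mi(table)
    I_RS = I_RS_plug - _table_bias(table, support_method)

    l_table = np.zeros((n_L_bins, table.shape[1]))
    np.add.at(l_table, l_bin, table)
    I_RL_plug = plugin_mi(l_table)
    I_RL = I_RL_plug - _table_bias(l_table, support_method)

    I_cond_plug, I_cond = _conditional_terms(table, l_bin, support_method)
    gap = I_RS_plug - (I_RL_plug + I_cond_plug)
    f_high = I_cond / I_RS if I_RS > 0 else float("nan")
    return InfoDecomposition(
        I_RS=I_RS,
        I_RL=I_RL,
        I_RSprime_given_L=I_cond,
        f_high=f_high,
        I_RS_plugin=I_RS_plug,
        identity_gap_plugin=float(gap),
    )


def invariance_decomposition(
    counts_i: np.ndarray,
    counts_j: np.ndarray,
    n_response_bins: int = 3,
    support_method: str = "naive",
    bin_edges: np.ndarray | None = None,
) -> InfoDecomposition:
    """Decompose pairwise stimulus information into view-invariant
    object information and within-object view information.

    ``counts_i`` / ``counts_j`` are (n_views, n_trials) spike counts for
    the two objects with matched view sets.  I(R;O) merges the views of
    each object into a single response distribution; I(R;T|O) is the
    view information within each object.
    """
    counts_i = np.asarray(counts_i, dtype=float)
    counts_j = np.asarray(counts_j, dtype=float)
    if counts_i.shape[0] != counts_j.shape[0]:
        raise ValueError("objects must have matched view sets")
    counts = np.vstack([counts_i, counts_j])
    table = _bin_condition_counts(counts, n_response_bins, bin_edges)
    n_views = counts_i.shape[0]
    obj = np.repeat([0, 1], n_views)

    I_RS_plug = plugin_mi(table)
    I_RS = I_RS_plug - _table_bias(table, support_method)

    o_table = np.vstack([table[:n_views].sum(axis=0), table[n_views:].sum(axis=0)])
    I_RO_plug = plugin_mi(o_table)
    I_RO = I_RO_plug - _table_bias(o_table, support_method)

    I_cond_plug, I_cond = _conditional_terms(table, obj, support_method)
    gap = I_RS_plug - (I_RO_plug + I_cond_plug)
    return InfoDecomposition(
        I_RS=I_RS,
        I_RO=I_RO,
        I_RT_given_O=I_cond,
        I_RS_plugin=I_RS_plug,
        identity_gap_plugin=float(gap),
    )


def luminance_object_info(
    L_i: np.ndarray,
    L_j: np.ndarray,
    n_L_bins: int = 23,
    support_method: str = "naive",
    n_trials_per_view: int = 26,
) -> float:
    """I(L;O): view-invariant object information carried by RF luminance
    alone, over the pooled views of an object pair (bias-corrected).

    L is deterministic given the view, so each view contributes its
    trial count to the joint (object, L-bin) table; the sampling unit
    for the bias term is the stimulus presentation, which keeps the
    correction within its validity regime.
    """
    L_i = np.asarray(L_i, dtype=float)
    L_j = np.asarray(L_j, dtype=float)
    values = np.concatenate([L_i, L_j])
    n_bins = min(n_L_bins, values.size)
    binned = equipopulated_bins(values, n_bins)
    obj = np.repeat([0, 1], [L_i.size, L_j.size])
    table = joint_counts(obj, binned.bin_index, 2, n_bins)
    return corrected_mi(table * n_trials_per_view, support_method)


def permutation_significance(
    counts: np.ndarray,
    n_perm: int = 100,
    seed: int | np.random.Generator = 0,
    n_response_bins: int = 3,
    support_method: str = "naive",
) -> tuple[float, float]:
    """Permutation test of I(R;S) against the no-association null.

    Shuffles condition labels across trials ``n_perm`` times; returns
    ``(observed_corrected_mi, p_value)`` with the smoothed estimate
    p = (k + 1) / (n_perm + 1), k = number of null values >= observed.
    """
    rng = np.random.default_rng(seed)
    counts = np.asarray(counts, dtype=float)
    n_cond, n_trials = counts.shape
    stim, resp = _counts_to_trials(counts)
    binned = equipopulated_bins(resp, n_response_bins)
    table = joint_counts(stim, binned.bin_index, n_cond, n_response_bins)
    observed = corrected_mi(table, support_method)
    k = 0
    for _ in range(n_perm):
        perm = rng.permutation(binned.bin_index)
        null_table = joint_counts(stim, perm, n_cond, n_response_bins)
        if corrected_mi(null_table, support_method) >= observed:
            k += 1
    return observed, (k + 1) / (n_perm + 1)


def sparseness(responses: np.ndarray) -> float:
    """Response sparseness S = (1 - (mean r)^2 / mean(r^2)) / (1 - 1/n).

    0 for a constant profile, 1 when a single condition drives the
    neuron.  NaN for an all-zero vector.
    """
    r = np.asarray(responses, dtype=float)
    if r.size < 2:
        raise ValueError("need at least two responses")
    if np.any(r < 0):
        raise ValueError("responses must be nonnegative")
    mean_sq = np.mean(r**2)
    if mean_sq == 0:
        return float("nan")
    n = r.size
    return float((1.0 - np.mean(r) ** 2 / mean_sq) / (1.0 - 1.0 / n))


def luminance_sensitivity_curve(
    responses_by_level: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Luminance-sensitivity curve and its sparseness.

    ``responses_by_level`` is (n_objects, n_levels) mean responses at
    the tested luminance levels (ascending: 0.125, 0.25, 0.5, 1).
    Responses are averaged across objects and max-normalized; the
    sharpness of luminance sensitivity is the sparseness of that curve.
    """
    arr = np.asarray(responses_by_level, dtype=float)
    if arr.ndim != 2:
        raise ValueError("responses_by_level must be 2-D (objects x levels)")
    curve = arr.mean(axis=0)
    peak = curve.max()
    if peak <= 0:
        return np.full(curve.shape, np.nan), float("nan")
    curve = curve / peak
    return curve, sparseness(curve)
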