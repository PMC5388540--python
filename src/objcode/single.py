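"""Single-neuron binary decoders.

A neuron's spike count discriminates two objects through a scalar
threshold r_th placed where the log-ratio of Gaussian posteriors
(means/SDs estimated from training responses, equal priors) crosses
zero - the 1-D quadratic-discriminant boundary.  Counts above the
threshold are labelled as the higher-mean object.

Analyses: linear separability (5-fold cross-validation over all views
of both objects), generalization to untrained views (train on one view
per object), parametric position- and size-generalization, and matched
chance controls in which object labels are shuffled within each
transformation so that only the identity signal is destroyed.
Performance is reported as the mutual information between actual and
predicted labels (with the matched chance information subtracted) and
as percent accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .info import plugin_mi

__all__ = [
    "DecodingResult",
    "qda_threshold",
    "luminosity_ratio",
    "separability",
    "generalization",
    "position_generalization_curve",
    "size_generalization",
    "chance_performance",
    "neuron_summary",
    "POSITION_DISTANCES_DEG",
]

POSITION_DISTANCES_DEG = (7.5, 15.0, 22.5, 30.0)


@dataclass
class DecodingResult:
    """Outcome of one binary decoding analysis."""

    confusion: np.ndarray  # rows: actual (i, j); cols: predicted
    info_bits: float
    accuracy_pct: float
    chance_info_bits: float = float("nan")
    chance_accuracy_pct: float = float("nan")
    flags: list[str] = field(default_factory=list)

    @property
    def net_info_bits(self) -> float:
        if np.isnan(self.chance_info_bits):
            return self.info_bits
        return self.info_bits - self.chance_info_bits

    def summary(self) -> str:
        lines = [
            "Binary decoding result",
            "----------------------",
            f"info          : {self.info_bits:.4f} bits",
            f"chance info   : {self.chance_info_bits:.4f} bits",
            f"net info      : {self.net_info_bits:.4f} bits",
            f"accuracy      : {self.accuracy_pct:.2f} %",
            f"confusion     : {self.confusion.tolist()}",
        ]
        if self.flags:
            lines.append(f"flags         : {sorted(set(self.flags))}")
        return "\n".join(lines)


def qda_threshold(
    mu_i: float, sigma_i: float, mu_j: float, sigma_j: float
) -> tuple[float, str]:
    """Threshold where the Gaussian log-posterior ratio (equal priors)
    is zero.

    Classes are relabelled internally so the first has the larger mean.
    Returns ``(r_th, flag)``; flags: ``'ok'``, ``'equal-variance'``
    (closed-form midpoint), ``'midpoint-fallback'`` (degenerate
    variances or no real root) or ``'undecidable'`` (identical
    distributions with zero variance; r_th is NaN).
    """
    if mu_i < mu_j:
        mu_i, mu_j = mu_j, mu_i
        sigma_i, sigma_j = sigma_j, sigma_i
    if sigma_i == sigma_j:
        if sigma_i == 0 and mu_i == mu_j:
            return float("nan"), "undecidable"
        return 0.5 * (mu_i + mu_j), "equal-variance"
    if sigma_i == 0 or sigma_j == 0:
        return 0.5 * (mu_i + mu_j), "midpoint-fallback"
    a = 0.5 / sigma_j**2 - 0.5 / sigma_i**2
    b = mu_i / sigma_i**2 - mu_j / sigma_j**2
    c = (
        0.5 * mu_j**2 / sigma_j**2
        - 0.5 * mu_i**2 / sigma_i**2
        + np.log(sigma_j / sigma_i)
    )
    roots = np.roots([a, b, c])
    real = roots[np.abs(roots.imag) < 1e-9].real
    if real.size == 0:
        return 0.5 * (mu_i + mu_j), "midpoint-fallback"
    inside = real[(real >= mu_j) & (real <= mu_i)]
    if inside.size:
        return float(inside[0]), "ok"
    # no between-means root: nearest real root to the mean interval
    mid = 0.5 * (mu_i + mu_j)
    return float(real[np.argmin(np.abs(real - mid))]), "ok"


def _classify(counts: np.ndarray, r_th: float) -> tuple[float, float]:
    """Fractional (n_above, n_below) with ties split half/half."""
    counts = np.asarray(counts, dtype=float).ravel()
    above = float(np.sum(counts > r_th))
    below = float(np.sum(counts < r_th))
    ties = counts.size - above - below
    return above + 0.5 * ties, below + 0.5 * ties


def _train_boundary(train_i: np.ndarray, train_j: np.ndarray) -> tuple[float, bool, str]:
    """Boundary from training counts.  Returns (r_th, i_is_high, flag)."""
    mu_i, mu_j = float(np.mean(train_i)), float(np.mean(train_j))
    sd_i = float(np.std(train_i, ddof=1)) if train_i.size > 1 else 0.0
    sd_j = float(np.std(train_j, ddof=1)) if train_j.size > 1 else 0.0
    r_th, flag = qda_threshold(mu_i, sd_i, mu_j, sd_j)
    return r_th, mu_i >= mu_j, flag


def _accumulate(
    confusion: np.ndarray, r_th: float, i_is_high: bool, test_i: np.ndarray, test_j: np.ndarray
) -> None:
    if np.isnan(r_th):
        # undecidable boundary: split every trial half/half
        confusion += 0.5 * np.array(
            [[test_i.size, test_i.size], [test_j.size, test_j.size]], dtype=float
        )
        return
    hi_i, lo_i = _classify(test_i, r_th)
    hi_j, lo_j = _classify(test_j, r_th)
    if i_is_high:
        confusion += np.array([[hi_i, lo_i], [hi_j, lo_j]])
    else:
        confusion += np.array([[lo_i, hi_i], [lo_j, hi_j]])


def _performance(confusion: np.ndarray) -> tuple[float, float]:
    total = confusion.sum()
    if total == 0:
        return 0.0, float("nan")
    row_ok = confusion.sum(axis=1) > 0
    info = plugin_mi(confusion[row_ok]) if confusion[row_ok].sum() > 0 else 0.0
    acc = 100.0 * np.trace(confusion) / total
    return info, acc


def shuffle_within_views(
    counts_i: np.ndarray, counts_j: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Shuffle object labels separately within each matched view,
    preserving per-view trial counts exactly."""
    counts_i = np.asarray(counts_i, dtype=float)
    counts_j = np.asarray(counts_j, dtype=float)
    out_i = np.empty_like(counts_i)
    out_j = np.empty_like(counts_j)
    for t in range(counts_i.shape[0]):
        pool = np.concatenate([counts_i[t], counts_j[t]])
        pool = pool[rng.permutation(pool.size)]
        out_i[t] = pool[: counts_i.shape[1]]
        out_j[t] = pool[counts_i.shape[1] :]
    return out_i, out_j


def _fold_assignments(
    n_views: int, n_trials: int, k_folds: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-(view, trial) fold labels, stratified within each view."""
    folds = np.empty((n_views, n_trials), dtype=int)
    base = np.arange(n_trials) % k_folds
    for t in range(n_views):
        folds[t] = base[rng.permutation(n_trials)]
    return folds


def _separability_confusion(
    counts_i: np.ndarray,
    counts_j: np.ndarray,
    k_folds: int,
    rng: np.random.Generator,
    flags: list[str],
) -> np.ndarray:
    n_views, n_trials = counts_i.shape
    if n_trials < k_folds:
        raise ValueError("insufficient trials per condition for k folds")
    folds_i = _fold_assignments(n_views, n_trials, k_folds, rng)
    folds_j = _fold_assignments(n_views, n_trials, k_folds, rng)
    confusion = np.zeros((2, 2))
    for f in range(k_folds):
        train_i = counts_i[folds_i != f]
        train_j = counts_j[folds_j != f]
        r_th, i_hi, flag = _train_boundary(train_i, train_j)
        if flag != "ok":
            flags.append(flag)
        _accumulate(confusion, r_th, i_hi, counts_i[folds_i == f], counts_j[folds_j == f])
    return confusion


def separability(
    counts_i: np.ndarray,
    counts_j: np.ndarray,
    k_folds: int = 5,
    seed: int | np.random.Generator = 0,
    compute_chance: bool = True,
) -> DecodingResult:
    """Linear separability of an object pair from one neuron's counts.

    ``counts_i``/``counts_j``: (n_views, n_trials) spike counts, views
    aligned between objects.  Five stratified folds; training folds are
    pooled over all views per object to parameterize the boundary.
    """
    rng = np.random.default_rng(seed)
    counts_i = np.asarray(counts_i, dtype=float)
    counts_j = np.asarray(counts_j, dtype=float)
    flags: list[str] = []
    confusion = _separability_confusion(counts_i, counts_j, k_folds, rng, flags)
    info, acc = _performance(confusion)
    result = DecodingResult(confusion, info, acc, flags=flags)
    if compute_chance:
        sh_i, sh_j = shuffle_within_views(counts_i, counts_j, rng)
        ch_conf = _separability_confusion(sh_i, sh_j, k_folds, rng, [])
        result.chance_info_bits, result.chance_accuracy_pct = _performance(ch_conf)
    return result


def _generalization_run(
    counts_i: np.ndarray,
    counts_j: np.ndarray,
    views: np.ndarray,
    n_iter: int,
    rng: np.random.Generator,
    flags: list[str],
) -> tuple[np.ndarray, float, float]:
    infos = np.empty(n_iter)
    accs = np.empty(n_iter)
    total_conf = np.zeros((2, 2))
    for it in range(n_iter):
        x = views[rng.integers(views.size)]
        y = views[rng.integers(views.size)]
        r_th, i_hi, flag = _train_boundary(counts_i[x], counts_j[y])
        if flag != "ok":
            flags.append(flag)
        test_views_i = views[views != x]
        test_views_j = views[views != y]
        confusion = np.zeros((2, 2))
        _accumulate(
            confusion, r_th, i_hi,
            counts_i[test_views_i].ravel(), counts_j[test_views_j].ravel(),
        )
        infos[it], accs[it] = _performance(confusion)
        total_conf += confusion
    return total_conf, float(infos.mean()), float(accs.mean())


def generalization(
    counts_i: np.ndarray,
    counts_j: np.ndarray,
    views: np.ndarray | None = None,
    n_iter: int = 1000,
    seed: int | np.random.Generator = 0,
    compute_chance: bool = True,
) -> DecodingResult:
    """Generalization to untrained views.

    Each iteration trains the boundary on one randomly sampled view per
    object (sampled independently) and tests it on the remaining views
    of ``views`` (all views by default; pass an index list to restrict
    to one variation axis).  Performances are averaged over iterations.
    """
    rng = np.random.default_rng(seed)
    counts_i = np.asarray(counts_i, dtype=float)
    counts_j = np.asarray(counts_j, dtype=float)
    if views is None:
        views = np.arange(counts_i.shape[0])
    views = np.asarray(views, dtype=int)
    if views.size < 2:
        raise ValueError("need at least two views on the chosen axis")
    flags: list[str] = []
    conf, info, acc = _generalization_run(counts_i, counts_j, views, n_iter, rng, flags)
    result = DecodingResult(conf, info, acc, flags=flags)
    if compute_chance:
        sh_i, sh_j = shuffle_within_views(counts_i, counts_j, rng)
        _, ch_info, ch_acc = _generalization_run(sh_i, sh_j, views, n_iter, rng, [])
        result.chance_info_bits, result.chance_accuracy_pct = ch_info, ch_acc
    return result


def position_generalization_curve(
    counts_i: np.ndarray,
    counts_j: np.ndarray,
    seed: int | np.random.Generator = 0,
    compute_chance: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Net generalization vs. distance from the training position.

    ``counts_i``/``counts_j``: (8, n_trials) counts at the eight azimuth
    positions, ascending.  For each training position both objects are
    trained at that same position; the four testing positions step away
    rightward for training positions in [-22.5, 0] deg and leftward for
    [+7.5, +30] deg, at distances 7.5/15/22.5/30 deg.  Returns
    ``(net_info_bits, accuracy_pct)`` arrays of length 4, averaged over
    the eight training positions.
    """
    rng = np.random.default_rng(seed)
    counts_i = np.asarray(counts_i, dtype=float)
    counts_j = np.asarray(counts_j, dtype=float)
    if counts_i.shape[0] != 8:
        raise ValueError("expected counts at the 8 azimuth positions")
    infos = np.zeros(4)
    accs = np.zeros(4)
    chance_infos = np.zeros(4)
    for p in range(8):
        direction = 1 if p <= 3 else -1
        r_th, i_hi, _ = _train_boundary(counts_i[p], counts_j[p])
        if compute_chance:
            sh_i, sh_j = shuffle_within_views(counts_i, counts_j, rng)
            r_th_c, i_hi_c, _ = _train_boundary(sh_i[p], sh_j[p])
        for d in range(1, 5):
            q = p + direction * d
            confusion = np.zeros((2, 2))
            _accumulate(confusion, r_th, i_hi, counts_i[q], counts_j[q])
            info, acc = _performance(confusion)
            infos[d - 1] += info / 8.0
            accs[d - 1] += acc / 8.0
            if compute_chance:
                ch_conf = np.zeros((2, 2))
                _accumulate(ch_conf, r_th_c, i_hi_c, sh_i[q], sh_j[q])
                chance_infos[d - 1] += _performance(ch_conf)[0] / 8.0
    return infos - chance_infos, accs


def size_generalization(
    counts_i: np.ndarray,
    counts_j: np.ndarray,
    seed: int | np.random.Generator = 0,
    compute_chance: bool = True,
) -> tuple[float, float]:
    """Directed size generalization, averaged into two groups.

    ``counts_i``/``counts_j``: (5, n_trials) counts at sizes
    15/25/35/45/55 deg (ascending; 35 deg is the default size).  Eight
    directed train->test evaluations are grouped as: large-to-small
    (35->15, 35->25, 45->35, 55->35) and small-to-large (35->45,
    35->55, 15->35, 25->35).  Returns the two net-information group
    means.
    """
    rng = np.random.default_rng(seed)
    counts_i = np.asarray(counts_i, dtype=float)
    counts_j = np.asarray(counts_j, dtype=float)
    if counts_i.shape[0] != 5:
        raise ValueError("expected counts at the five sizes")
    default = 2
    large_to_small = [(default, 0), (default, 1), (3, default), (4, default)]
    small_to_large = [(default, 3), (default, 4), (0, default), (1, default)]

    def directed(train: int, test: int, ci: np.ndarray, cj: np.ndarray) -> float:
        r_th, i_hi, _ = _train_boundary(ci[train], cj[train])
        confusion = np.zeros((2, 2))
        _accumulate(confusion, r_th, i_hi, ci[test], cj[test])
        return _performance(confusion)[0]

    def group_mean(pairs: list[tuple[int, int]]) -> float:
        vals = [directed(tr, te, counts_i, counts_j) for tr, te in pairs]
        if compute_chance:
            sh_i, sh_j = shuffle_within_views(counts_i, counts_j, rng)
            chance = [directed(tr, te, sh_i, sh_j) for tr, te in pairs]
            return float(np.mean(vals) - np.mean(chance))
        return float(np.mean(vals))

    return group_mean(large_to_small), group_mean(small_to_large)


def chance_performance(
    counts_i: np.ndarray,
    counts_j: np.ndarray,
    mode: str = "separability",
    seed: int | np.random.Generator = 0,
    **kwargs,
) -> DecodingResult:
    """Run a decoding analysis on within-transformation label-shuffled
    data (the matched chance control)."""
    rng = np.random.default_rng(seed)
    sh_i, sh_j = shuffle_within_views(
        np.asarray(counts_i, dtype=float), np.asarray(counts_j, dtype=float), rng
    )
    if mode == "separability":
        return separability(sh_i, sh_j, seed=rng, compute_chance=False, **kwargs)
    if mode == "generalization":
        return generalization(sh_i, sh_j, seed=rng, compute_chance=False, **kwargs)
    raise ValueError("mode must be 'separability' or 'generalization'")


def luminosity_ratio(L_i: np.ndarray, L_j: np.ndarray) -> float:
    """Mean RF luminance of the dimmer object over the brighter one,
    across the matched views of a pair (in [0, 1])."""
    m_i, m_j = float(np.mean(L_i)), float(np.mean(L_j))
    hi = max(m_i, m_j)
    if hi == 0:
        return 1.0
    return min(m_i, m_j) / hi


def neuron_summary(
    pair_metrics: dict[tuple[int, int], dict[str, float]],
    pair_lum_ratios: dict[tuple[int, int], float],
    th_lum_ratio: float = 0.9,
) -> dict[str, float] | None:
    """Unweighted mean of each metric over the pairs whose luminosity
    ratio exceeds ``th_lum_ratio``.  Returns None (with no summary) if
    no pair qualifies."""
    qualifying = [
        pair for pair, ratio in pair_lum_ratios.items() if ratio > th_lum_ratio
    ]
    if not qualifying:
        return None
    keys = pair_metrics[qualifying[0]].keys()
    out = {
        k: float(np.mean([pair_metrics[p][k] for p in qualifying])) for k in keys
    }
    out["n_pairs"] = len(qualifying)
    return out
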