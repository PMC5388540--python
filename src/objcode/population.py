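"""Pseudo-population construction and linear-SVM population decoding.

Units recorded in different sessions are combined into pseudo-population
response vectors: for every stimulus condition, each vector component is
the spike count of one unit on an independently sampled trial of that
condition (sampled without replacement, M vectors per condition).
Binary linear support-vector machines (C = 1) read object identity out
of these vectors: 5-fold cross-validated separability over the 19
aligned views per object, exhaustive 19 x 19 train-view generalization,
an arbitrary-group control (mixed 9+10 view groups), and matched chance
controls with object labels shuffled within each transformation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import RidgeClassifier
from sklearn.svm import LinearSVC
from statsmodels.stats.multitest import multipletests

from .info import plugin_mi
from .single import DecodingResult

__all__ = [
    "PseudoPopulation",
    "build_pseudopopulation",
    "pop_separability",
    "pop_generalization",
    "arbitrary_group_separability",
    "run_population_suite",
    "N_UNITS_DEFAULT",
]

N_UNITS_DEFAULT = (6, 12, 24, 48, 96)


@dataclass
class PseudoPopulation:
    """M pseudo-population vectors of length N per condition.

    ``vectors`` has shape (n_conditions, M, N); conditions follow the
    aligned 19-view-per-object ordering shared by all units.
    """

    vectors: np.ndarray
    unit_ids: np.ndarray
    resample_seed: int | None = None

    @property
    def n_conditions(self) -> int:
        return self.vectors.shape[0]

    @property
    def n_vectors(self) -> int:
        return self.vectors.shape[1]

    @property
    def n_units(self) -> int:
        return self.vectors.shape[2]


def build_pseudopopulation(
    unit_counts: np.ndarray,
    n_units: int,
    n_vectors: int,
    seed: int | np.random.Generator = 0,
    unit_ids: np.ndarray | None = None,
) -> PseudoPopulation:
    """Assemble a pseudo-population from per-unit trial counts.

    ``unit_counts``: (n_available_units, n_conditions, n_trials) spike
    counts on the shared aligned condition set.  ``n_units`` units are
    sampled without replacement; per unit and condition, ``n_vectors``
    trials are sampled without replacement and permuted independently,
    which destroys any cross-unit trial pairing (the units were not
    recorded simultaneously anyway).
    """
    rng = np.random.default_rng(seed)
    unit_counts = np.asarray(unit_counts, dtype=float)
    n_avail, n_cond, n_trials = unit_counts.shape
    if n_units > n_avail:
        raise ValueError(f"requested {n_units} units, only {n_avail} available")
    if n_vectors > n_trials:
        raise ValueError("n_vectors exceeds available trials")
    chosen = rng.choice(n_avail, size=n_units, replace=False)
    vectors = np.empty((n_cond, n_vectors, n_units))
    for k, u in enumerate(chosen):
        for c in range(n_cond):
            picks = rng.choice(n_trials, size=n_vectors, replace=False)
            vectors[c, :, k] = unit_counts[u, c, picks]
    ids = (unit_ids[chosen] if unit_ids is not None else chosen).copy()
    seed_val = seed if isinstance(seed, (int, np.integer)) else None
    return PseudoPopulation(vectors=vectors, unit_ids=ids, resample_seed=seed_val)


def _fit_svm(X: np.ndarray, y: np.ndarray):
    """Linear soft-margin SVM, C = 1 (liblinear).  If the iteration cap
    is hit, fall back to a least-squares linear classifier (flagged)."""
    clf = LinearSVC(C=1.0, max_iter=5000)
    fallback = False
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            clf.fit(X, y)
        except ConvergenceWarning:
            fallback = True
            clf = RidgeClassifier(alpha=1.0)
            clf.fit(X, y)
    return clf, fallback


def _performance(confusion: np.ndarray) -> tuple[float, float]:
    total = confusion.sum()
    info = plugin_mi(confusion) if total > 0 and confusion.min() >= 0 else 0.0
    acc = 100.0 * np.trace(confusion) / total if total else float("nan")
    return info, acc


def _shuffle_vectors_within_views(
    vec_i: np.ndarray, vec_j: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Shuffle object labels within each matched view (vectors keep
    their transformation label)."""
    out_i = np.empty_like(vec_i)
    out_j = np.empty_like(vec_j)
    m = vec_i.shape[1]
    for t in range(vec_i.shape[0]):
        pool = np.concatenate([vec_i[t], vec_j[t]], axis=0)
        perm = rng.permutation(pool.shape[0])
        pool = pool[perm]
        out_i[t] = pool[:m]
        out_j[t] = pool[m:]
    return out_i, out_j


def _separability_confusion(
    vec_i: np.ndarray,
    vec_j: np.ndarray,
    k_folds: int,
    rng: np.random.Generator,
    flags: list[str],
) -> np.ndarray:
    n_views, m, n_units = vec_i.shape
    folds_i = np.stack(
        [(np.arange(m) % k_folds)[rng.permutation(m)] for _ in range(n_views)]
    )
    folds_j = np.stack(
        [(np.arange(m) % k_folds)[rng.permutation(m)] for _ in range(n_views)]
    )
    confusion = np.zeros((2, 2))
    for f in range(k_folds):
        Xtr = np.concatenate([vec_i[folds_i != f], vec_j[folds_j != f]])
        ytr = np.concatenate(
            [np.zeros((folds_i != f).sum()), np.ones((folds_j != f).sum())]
        )
        if len(np.unique(ytr)) < 2:
            raise ValueError("degenerate single-class training fold")
        clf, fb = _fit_svm(Xtr, ytr)
        if fb:
            flags.append("svm-iteration-cap")
        for label, vec, folds in ((0, vec_i, folds_i), (1, vec_j, folds_j)):
            Xte = vec[folds == f]
            if Xte.size == 0:
                continue
            pred = clf.predict(Xte)
            confusion[label, 0] += np.sum(pred == 0)
            confusion[label, 1] += np.sum(pred == 1)
    return confusion


def _pair_vectors(
    pop: PseudoPopulation, pair_slices: tuple[slice, slice] | None
) -> tuple[np.ndarray, np.ndarray]:
    """Split the condition axis into the two objects' view sets."""
    n = pop.n_conditions
    if pair_slices is None:
        half = n // 2
        pair_slices = (slice(0, half), slice(half, n))
    return pop.vectors[pair_slices[0]], pop.vectors[pair_slices[1]]


def pop_separability(
    pop: PseudoPopulation,
    pair_slices: tuple[slice, slice] | None = None,
    k_folds: int = 5,
    seed: int | np.random.Generator = 0,
    compute_chance: bool = True,
) -> DecodingResult:
    """Cross-validated linear separability of an object pair from
    pseudo-population vectors (5 stratified folds, linear SVM, C=1).
    The matched within-transformation chance information is subtracted
    from the information metric only, never from accuracy."""
    rng = np.random.default_rng(seed)
    vec_i, vec_j = _pair_vectors(pop, pair_slices)
    flags: list[str] = []
    confusion = _separability_confusion(vec_i, vec_j, k_folds, rng, flags)
    info, acc = _performance(confusion)
    result = DecodingResult(confusion, info, acc, flags=flags)
    if compute_chance:
        sh_i, sh_j = _shuffle_vectors_within_views(vec_i, vec_j, rng)
        ch_conf = _separability_confusion(sh_i, sh_j, k_folds, rng, [])
        result.chance_info_bits, result.chance_accuracy_pct = _performance(ch_conf)
    return result


def _generalization_confusion(
    vec_i: np.ndarray, vec_j: np.ndarray, flags: list[str]
) -> np.ndarray:
    """Exhaustive train-view combinations: one classifier per (tx, ty),
    tested on the remaining views; confusions merged globally."""
    n_views, m, _ = vec_i.shape
    confusion = np.zeros((2, 2))
    y_train = np.concatenate([np.zeros(m), np.ones(m)])
    for tx, ty in itertools.product(range(n_views), range(n_views)):
        Xtr = np.concatenate([vec_i[tx], vec_j[ty]])
        clf, fb = _fit_svm(Xtr, y_train)
        if fb:
            flags.append("svm-iteration-cap")
        keep_i = np.arange(n_views) != tx
        keep_j = np.arange(n_views) != ty
        Xte_i = vec_i[keep_i].reshape(-1, vec_i.shape[2])
        Xte_j = vec_j[keep_j].reshape(-1, vec_j.shape[2])
        pred_i = clf.predict(Xte_i)
        pred_j = clf.predict(Xte_j)
        confusion[0, 0] += np.sum(pred_i == 0)
        confusion[0, 1] += np.sum(pred_i == 1)
        confusion[1, 0] += np.sum(pred_j == 0)
        confusion[1, 1] += np.sum(pred_j == 1)
    return confusion


def pop_generalization(
    pop: PseudoPopulation,
    pair_slices: tuple[slice, slice] | None = None,
    seed: int | np.random.Generator = 0,
    compute_chance: bool = True,
) -> DecodingResult:
    """Generalization to untrained views at the population level.

    Trains one linear SVM per combination of train views (tx, ty) - all
    19^2 = 361 combinations for the aligned view set - and tests each on
    the vectors of the remaining 18 + 18 views; the 361 confusion
    matrices are merged before computing information and accuracy.
    """
    rng = np.random.default_rng(seed)
    vec_i, vec_j = _pair_vectors(pop, pair_slices)
    flags: list[str] = []
    confusion = _generalization_confusion(vec_i, vec_j, flags)
    info, acc = _performance(confusion)
    result = DecodingResult(confusion, info, acc, flags=flags)
    if compute_chance:
        sh_i, sh_j = _shuffle_vectors_within_views(vec_i, vec_j, rng)
        ch_conf = _generalization_confusion(sh_i, sh_j, [])
        result.chance_info_bits, result.chance_accuracy_pct = _performance(ch_conf)
    return result


def arbitrary_group_separability(
    pop: PseudoPopulation,
    pair_slices: tuple[slice, slice] | None = None,
    k_folds: int = 5,
    n_resamples: int = 50,
    seed: int | np.random.Generator = 0,
) -> DecodingResult:
    """Separability of two arbitrary groups of object views.

    Each resample assigns 9 random views of the first object plus 10 of
    the second to group A and the complementary 10 + 9 views to group B
    (groups of 19 mixed views each), then runs the standard 5-fold
    linear-SVM pipeline; performances are averaged over resamples.  A
    representation that only codes object identity invariantly scores
    near chance here.
    """
    rng = np.random.default_rng(seed)
    vec_i, vec_j = _pair_vectors(pop, pair_slices)
    n_views = vec_i.shape[0]
    n_a_from_i = (n_views - 1) // 2  # 9 for the 19-view set
    infos, accs = [], []
    confusion = np.zeros((2, 2))
    for _ in range(n_resamples):
        pick_i = rng.permutation(n_views)
        pick_j = rng.permutation(n_views)
        group_a = np.concatenate(
            [vec_i[pick_i[:n_a_from_i]], vec_j[pick_j[: n_views - n_a_from_i]]]
        )
        group_b = np.concatenate(
            [vec_i[pick_i[n_a_from_i:]], vec_j[pick_j[n_views - n_a_from_i :]]]
        )
        conf = _separability_confusion(group_a, group_b, k_folds, rng, [])
        confusion += conf
        info, acc = _performance(conf)
        infos.append(info)
        accs.append(acc)
    return DecodingResult(confusion, float(np.mean(infos)), float(np.mean(accs)))


def run_population_suite(
    area_unit_counts: dict[str, np.ndarray],
    pair_slices: dict[tuple[int, int], tuple[slice, slice]],
    n_units_list: tuple[int, ...] = N_UNITS_DEFAULT,
    n_vectors: int = 25,
    n_resamples: int = 50,
    seed: int = 0,
    k_folds: int = 5,
    include_generalization: bool = True,
    area_order: tuple[str, ...] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Population decoding across areas, subpopulation sizes and pairs.

    ``area_unit_counts`` maps area -> (n_units, n_conditions, n_trials)
    counts on the aligned condition set, restricted beforehand to units
    whose qualifying pairs satisfy the active luminosity-ratio
    threshold.  Returns ``(results, comparisons)``: a tidy per-resample
    results table and pairwise 1-tailed Mann-Whitney area comparisons
    (per pair and N, Holm-Bonferroni corrected within each family).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for area, counts in area_unit_counts.items():
        m = min(n_vectors, counts.shape[2])
        for n_units in n_units_list:
            if n_units > counts.shape[0]:
                continue
            for r in range(n_resamples):
                pop = build_pseudopopulation(
                    counts, n_units, m, seed=rng, unit_ids=None
                )
                for pair, slices in pair_slices.items():
                    sep = pop_separability(
                        pop, slices, k_folds=k_folds, seed=rng
                    )
                    row = {
                        "area": area,
                        "n_units": n_units,
                        "pair": str(pair),
                        "resample": r,
                        "separability_net_info": sep.net_info_bits,
                        "separability_accuracy": sep.accuracy_pct,
                    }
                    if include_generalization:
                        gen = pop_generalization(pop, slices, seed=rng)
                        row["generalization_net_info"] = gen.net_info_bits
                        row["generalization_accuracy"] = gen.accuracy_pct
                    rows.append(row)
    results = pd.DataFrame(rows)
    comparisons = _pairwise_area_tests(results, area_order)
    return results, comparisons


def _pairwise_area_tests(
    results: pd.DataFrame, area_order: tuple[str, ...] | None
) -> pd.DataFrame:
    metrics = [c for c in results.columns if c.endswith("_net_info")]
    areas = list(area_order) if area_order else sorted(results["area"].unique())
    rows = []
    for (pair, n_units), grp in results.groupby(["pair", "n_units"]):
        for metric in metrics:
            tests = []
            for a, b in itertools.combinations(areas, 2):
                x = grp.loc[grp["area"] == b, metric]
                y = grp.loc[grp["area"] == a, metric]
                if x.empty or y.empty:
                    continue
                # 1-tailed: later area in the order > earlier area
                p = mannwhitneyu(x, y, alternative="greater").pvalue
                tests.append((a, b, metric, p))
            if not tests:
                continue
            corrected = multipletests([t[3] for t in tests], method="holm")[1]
            for (a, b, metric_name, p_raw), p_corr in zip(tests, corrected):
                rows.append(
                    {
                        "pair": pair,
                        "n_units": n_units,
                        "metric": metric_name,
                        "lower_area": a,
                        "higher_area": b,
                        "p_raw": p_raw,
                        "p_holm": p_corr,
                    }
                )
    return pd.DataFrame(rows)
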