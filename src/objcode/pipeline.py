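"""Neuron screening, latency, quality subsetting, area statistics and
end-to-end analysis over a stimulus battery.

Bridges recordings (real-format or simulated) to the per-neuron
condition subsets used by the information and decoding analyses, and
implements the population-level statistics: bootstrap SEs of medians
and 1-tailed Mann-Whitney area comparisons with Holm-Bonferroni
correction along the hypothesized V1 -> LM -> LI -> LL progression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.stats import mannwhitneyu, ttest_ind
from statsmodels.stats.multitest import multipletests

from .info import (
    energy_decomposition,
    invariance_decomposition,
    luminance_object_info,
    permutation_significance,
)
from .recording import NeuronRecording
from .single import (
    generalization,
    luminosity_ratio,
    neuron_summary,
    separability,
)
from .stimuli import (
    StimulusSet,
    canonical_view_order,
    select_conditions_for_neuron,
    select_population_views,
)

__all__ = [
    "NeuronConditionTable",
    "neuron_condition_table",
    "screen_neurons",
    "estimate_latency",
    "quality_subsets",
    "AreaComparison",
    "compare_areas",
    "single_cell_metrics",
    "aligned_population_counts",
    "DEFAULT_AREA_ORDER",
]

DEFAULT_AREA_ORDER = ("V1like", "LMlike", "LIlike", "LLlike")

N_VIEWS_PER_OBJECT = 23
N_POSITIONS = 8


@dataclass
class NeuronConditionTable:
    """A neuron's 230-condition subset in canonical view order.

    ``counts``: (10 objects, 23 views, n_trials); ``L``: (10, 23) RF
    luminances.  View order: 8 positions (azimuth ascending), 4 sizes
    (15/25/45/55), 4 in-plane then 4 in-depth rotations, 3 luminance
    levels (0.5/0.25/0.125).  ``default_view`` is the position view at
    the neuron's chosen default azimuth (the default pose/size/
    luminance condition, shared by the non-position axes).
    """

    counts: np.ndarray
    L: np.ndarray
    chosen_azimuth: float
    condition_ids: np.ndarray  # (10, 23)
    object_ids: np.ndarray  # (10,)

    @property
    def default_view(self) -> int:
        return 1 if self.chosen_azimuth == -15.0 else 5

    def axis_views(self, axis: str) -> np.ndarray:
        d = self.default_view
        if axis == "all":
            return np.arange(N_VIEWS_PER_OBJECT)
        if axis == "position":
            return np.arange(8)
        if axis == "size":
            return np.array([8, 9, d, 10, 11])  # sizes 15,25,35,45,55
        if axis == "rotation":
            return np.array([12, 13, 14, 15, 16, 17, 18, 19, d])
        if axis == "luminance":
            return np.array([22, 21, 20, d])  # levels 0.125,0.25,0.5,1
        raise ValueError(f"unknown axis {axis!r}")

    def pair(self, i: int, j: int) -> tuple[np.ndarray, np.ndarray]:
        """Counts of the two objects (0-based object indices)."""
        return self.counts[i], self.counts[j]

    def pair_lum_ratio(self, i: int, j: int) -> float:
        return luminosity_ratio(self.L[i], self.L[j])


def neuron_condition_table(
    recording: NeuronRecording, stimset: StimulusSet
) -> NeuronConditionTable:
    """Extract a neuron's per-object view-aligned count table."""
    subset = select_conditions_for_neuron(stimset, recording.rf_center_azimuth)
    chosen = next(c.azimuth_deg for c in subset if c.axis != "position")
    object_ids = sorted({c.object_id for c in subset})
    n_obj = len(object_ids)
    cond_ids = np.empty((n_obj, N_VIEWS_PER_OBJECT), dtype=int)
    for oi, obj in enumerate(object_ids):
        views = canonical_view_order([c for c in subset if c.object_id == obj])
        if len(views) != N_VIEWS_PER_OBJECT:
            raise ValueError("expected 23 views per object")
        cond_ids[oi] = [c.condition_id for c in views]
    counts = recording.spike_counts[cond_ids]
    if recording.rf_luminance is None:
        raise ValueError("recording lacks per-condition RF luminance")
    L = recording.rf_luminance[cond_ids]
    return NeuronConditionTable(
        counts=counts,
        L=L,
        chosen_azimuth=chosen,
        condition_ids=cond_ids,
        object_ids=np.asarray(object_ids),
    )


def screen_neurons(
    recordings: list[NeuronRecording],
    stimset: StimulusSet,
    alpha: float = 0.05,
    n_perm: int = 100,
    seed: int = 0,
) -> tuple[list[NeuronRecording], pd.DataFrame]:
    """Keep units that are (1) visually driven and (2) stimulus
    informative.

    Driven: at least one of the battery conditions whose counts differ
    from background (2-tailed t-test, p < alpha Bonferroni-corrected
    for the number of conditions).  Informative: bias-corrected
    I(R;S) over the neuron's 230-condition subset significant at
    p < alpha by permutation.
    """
    rng = np.random.default_rng(seed)
    kept = []
    log_rows = []
    for rec in recordings:
        if rec.background_counts is None or len(rec.background_counts) == 0:
            raise ValueError(f"{rec.neuron_id}: missing background trials")
        n_cond = rec.n_conditions
        pvals = ttest_ind(
            rec.spike_counts,
            np.asarray(rec.background_counts, dtype=float)[None, :],
            axis=1,
            equal_var=False,
        ).pvalue
        driven = bool(np.nanmin(pvals) < alpha / n_cond)
        informative = False
        mi = np.nan
        p_mi = np.nan
        if driven:
            table = neuron_condition_table(rec, stimset)
            flat = table.counts.reshape(-1, table.counts.shape[-1])
            mi, p_mi = permutation_significance(
                flat, n_perm=n_perm, seed=rng
            )
            informative = p_mi < alpha
        if driven and informative:
            kept.append(rec)
        else:
            reason = "not visually driven" if not driven else "not stimulus informative"
            log_rows.append(
                {
                    "neuron_id": rec.neuron_id,
                    "area": rec.area,
                    "reason": reason,
                    "min_driven_p": float(np.nanmin(pvals)),
                    "I_RS": mi,
                    "perm_p": p_mi,
                }
            )
    return kept, pd.DataFrame(log_rows)


def estimate_latency(
    psth: np.ndarray,
    bin_ms: float = 10.0,
    smooth_sd_ms: float = 5.0,
    onset_index: int = 0,
    baseline: float | None = None,
) -> float:
    """Response latency: first time after onset at which the smoothed
    PSTH reaches baseline + 20% of (peak - baseline).

    Returns NaN when the response never crosses the criterion.
    """
    psth = np.asarray(psth, dtype=float)
    smoothed = gaussian_filter1d(psth, smooth_sd_ms / bin_ms)
    post = smoothed[onset_index:]
    if baseline is None:
        baseline = smoothed[:onset_index].mean() if onset_index > 0 else post.min()
    peak = post.max()
    if peak <= baseline:
        return float("nan")
    criterion = baseline + 0.2 * (peak - baseline)
    above = np.nonzero(post >= criterion)[0]
    if above.size == 0:
        return float("nan")
    return float(above[0] * bin_ms)


def quality_subsets(recordings: list[NeuronRecording]) -> pd.DataFrame:
    """Pooled-across-area spike-isolation tertiles and the
    good-isolation subset (SNR > 10 and RV < 2%)."""
    df = pd.DataFrame(
        {
            "neuron_id": [r.neuron_id for r in recordings],
            "area": [r.area for r in recordings],
            "snr": [r.snr for r in recordings],
            "rv": [r.rv for r in recordings],
        }
    )
    for col in ("snr", "rv"):
        edges = np.quantile(df[col], [1 / 3, 2 / 3])
        df[f"{col}_tertile"] = np.digitize(df[col], edges, right=True)
    df["good_isolation"] = (df["snr"] > 10.0) & (df["rv"] < 2.0)
    return df


@dataclass
class AreaComparison:
    """Per-area medians with bootstrap SEs and pairwise 1-tailed
    Mann-Whitney tests (Holm-Bonferroni corrected)."""

    metric: str
    medians: pd.DataFrame
    tests: pd.DataFrame

    def summary(self) -> str:
        lines = [f"Area comparison: {self.metric}", "-" * 40]
        for _, row in self.medians.iterrows():
            lines.append(
                f"{row['area']:>8}: median {row['median']:.4f} "
                f"+/- {row['se_median']:.4f} (n={int(row['n'])})"
            )
        for _, row in self.tests.iterrows():
            star = "*" if row["p_holm"] < 0.05 else " "
            lines.append(
                f"{row['higher_area']} > {row['lower_area']}: "
                f"p = {row['p_holm']:.4g} {star}"
            )
        return "\n".join(lines)


def _bootstrap_se_median(
    values: np.ndarray, n_boot: int, rng: np.random.Generator
) -> float:
    values = np.asarray(values, dtype=float)
    meds = np.median(
        values[rng.integers(0, values.size, size=(n_boot, values.size))], axis=1
    )
    return float(meds.std(ddof=1))


def compare_areas(
    df: pd.DataFrame,
    metric: str,
    area_order: tuple[str, ...] = DEFAULT_AREA_ORDER,
    n_boot: int = 1000,
    seed: int = 0,
    area_col: str = "area",
) -> AreaComparison:
    """Compare a per-neuron metric across areas.

    1-tailed alternative: the later area in ``area_order`` exceeds the
    earlier one.  All pairwise tests of one metric form the
    Holm-Bonferroni family.
    """
    rng = np.random.default_rng(seed)
    present = [a for a in area_order if a in set(df[area_col])]
    if len(present) < 2:
        raise ValueError("need at least two areas with data")
    med_rows = []
    for a in present:
        vals = df.loc[df[area_col] == a, metric].dropna().to_numpy()
        if vals.size < 2:
            raise ValueError(f"area {a} has fewer than two units")
        med_rows.append(
            {
                "area": a,
                "median": float(np.median(vals)),
                "se_median": _bootstrap_se_median(vals, n_boot, rng),
                "n": vals.size,
            }
        )
    tests = []
    for ia in range(len(present)):
        for ib in range(ia + 1, len(present)):
            lo, hi = present[ia], present[ib]
            x = df.loc[df[area_col] == hi, metric].dropna()
            y = df.loc[df[area_col] == lo, metric].dropna()
            p = mannwhitneyu(x, y, alternative="greater").pvalue
            tests.append({"lower_area": lo, "higher_area": hi, "p_raw": p})
    p_holm = multipletests([t["p_raw"] for t in tests], method="holm")[1]
    for t, p in zip(tests, p_holm):
        t["p_holm"] = float(p)
    return AreaComparison(
        metric=metric, medians=pd.DataFrame(med_rows), tests=pd.DataFrame(tests)
    )


def single_cell_metrics(
    recording: NeuronRecording,
    stimset: StimulusSet,
    th_lum_ratio: float = 0.9,
    n_iter_generalization: int = 100,
    seed: int = 0,
    pairs: list[tuple[int, int]] | None = None,
    include_decoding: bool = True,
) -> dict[str, float]:
    """Per-neuron information and decoding metrics.

    Information terms (I(R;S), I(R;L), I(R;S'|L), f_high) use the full
    230-condition subset; the pairwise terms (I(R;O), separability and
    generalization net information) are averaged over the object pairs
    whose luminosity ratio exceeds ``th_lum_ratio``.
    """
    rng = np.random.default_rng(seed)
    table = neuron_condition_table(recording, stimset)
    flat = table.counts.reshape(-1, table.counts.shape[-1])
    decomp = energy_decomposition(flat, table.L.ravel())
    out = {
        "neuron_id": recording.neuron_id,
        "area": recording.area,
        "I_RS": decomp.I_RS,
        "I_RL": decomp.I_RL,
        "I_RSprime_given_L": decomp.I_RSprime_given_L,
        "f_high": decomp.f_high,
    }
    n_obj = table.counts.shape[0]
    if pairs is None:
        pairs = [(i, j) for i in range(n_obj) for j in range(i + 1, n_obj)]
    pair_metrics: dict[tuple[int, int], dict[str, float]] = {}
    lum_ratios: dict[tuple[int, int], float] = {}
    for i, j in pairs:
        lum_ratios[(i, j)] = table.pair_lum_ratio(i, j)
        if lum_ratios[(i, j)] <= th_lum_ratio:
            continue
        ci, cj = table.pair(i, j)
        inv = invariance_decomposition(ci, cj)
        metrics = {
            "I_RO": inv.I_RO,
            "I_RT_given_O": inv.I_RT_given_O,
            "I_LO": luminance_object_info(table.L[i], table.L[j]),
        }
        if include_decoding:
            sep = separability(ci, cj, seed=rng)
            gen = generalization(
                ci, cj, n_iter=n_iter_generalization, seed=rng
            )
            metrics["separability_net_info"] = sep.net_info_bits
            metrics["generalization_net_info"] = gen.net_info_bits
        pair_metrics[(i, j)] = metrics
    summary = neuron_summary(pair_metrics, lum_ratios, th_lum_ratio)
    if summary is not None:
        out.update(summary)
    else:
        out["n_pairs"] = 0
    return out


def select_population_pairs(
    recordings_by_area: dict[str, list[NeuronRecording]],
    stimset: StimulusSet,
    th_lum_ratio: float = 0.8,
    n_pairs: int = 3,
) -> list[tuple[int, int]]:
    """Choose object pairs for the population analyses.

    Ranks all 45 pairs by the smallest per-area count of units whose
    luminosity ratio for the pair exceeds ``th_lum_ratio`` (the pair
    constraint must hold for every unit entering a subpopulation, in
    every area) and returns the best ``n_pairs``.
    """
    n_obj = 10
    pairs = [(i, j) for i in range(n_obj) for j in range(i + 1, n_obj)]
    min_counts = {}
    for pair in pairs:
        counts = []
        for recs in recordings_by_area.values():
            n_ok = 0
            for rec in recs:
                table = neuron_condition_table(rec, stimset)
                if table.pair_lum_ratio(*pair) > th_lum_ratio:
                    n_ok += 1
            counts.append(n_ok)
        min_counts[pair] = min(counts)
    ranked = sorted(pairs, key=lambda p: -min_counts[p])
    return ranked[:n_pairs]


def aligned_population_counts(
    recordings: list[NeuronRecording],
    stimset: StimulusSet,
    th_lum_ratio: float = 0.8,
    pairs: list[tuple[int, int]] | None = None,
) -> tuple[np.ndarray, dict[tuple[int, int], tuple[slice, slice]], list[str]]:
    """Aligned 19-view count array for the population analyses.

    Each unit keeps the 19 views near its RF side (positions on that
    side plus the non-position views); the two RF groups are aligned
    position-by-position so all units share one 190-condition axis
    (10 objects x 19 view slots).  Units for which any requested pair
    fails the luminosity-ratio threshold are dropped.

    Returns ``(unit_counts, pair_slices, unit_ids)`` with
    ``unit_counts`` of shape (n_units, 190, n_trials).
    """
    if pairs is None:
        pairs = [(0, 1)]
    unit_blocks = []
    unit_ids = []
    for rec in recordings:
        table = neuron_condition_table(rec, stimset)
        ok = all(table.pair_lum_ratio(i, j) > th_lum_ratio for i, j in pairs)
        if not ok:
            continue
        # aligned view slots: 4 same-side positions then the 15
        # non-position views (indices 8..22 of the canonical order)
        if table.chosen_azimuth == -15.0:
            pos_slots = [0, 1, 2, 3]
        else:
            pos_slots = [4, 5, 6, 7]
        view_idx = np.array(pos_slots + list(range(8, 23)))
        unit_blocks.append(
            table.counts[:, view_idx, :].reshape(-1, table.counts.shape[-1])
        )
        unit_ids.append(rec.neuron_id)
    if not unit_blocks:
        raise ValueError("no unit satisfies the luminosity-ratio threshold")
    n_trials = min(b.shape[1] for b in unit_blocks)
    unit_counts = np.stack([b[:, :n_trials] for b in unit_blocks])
    pair_slices = {
        (i, j): (slice(i * 19, (i + 1) * 19), slice(j * 19, (j + 1) * 19))
        for i, j in pairs
    }
    return unit_counts, pair_slices, unit_ids
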