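"""Synthetic spiking data with area-graded object coding.

The generator emulates the statistical structure the analyses assume:
Poisson spike counts in 150 ms windows over the 380-condition battery
(~26 trials per condition), Gaussian receptive fields on the 6 x 11
mapping grid, and a graded functional profile across four areas - from
V1-like units dominated by the luminous energy falling in their RF to
LL-like units with transformation-tolerant object-identity tuning.

A unit's firing rate for condition S = (O, T) is

    rate = rectify( baseline
                    + luminance_gain * L(S)
                    + identity_gain[O] * (tol + (1 - tol) * m(T)) )

where L(S) is the RF luminance of the stimulus, ``tol`` in [0, 1] is
the fraction of identity drive preserved across views, and m(T) is a
frozen per-(unit, view) modulation: the unit's spatial RF gate
evaluated at the view's azimuth times a lognormal jitter.  tol = 1
gives fully view-invariant identity tuning; tol = 0 ties the identity
signal entirely to specific views.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .recording import NeuronRecording
from .rf import GRID_COLS, GRID_ROWS, RFMap, compute_rf_map, default_grid_coords, \
    resample_image_to_grid, rf_luminance
from .stimuli import StimulusSet, render_condition

__all__ = [
    "SyntheticNeuronParams",
    "AreaProfile",
    "DEFAULT_AREA_PROFILES",
    "make_area_population",
    "simulate_bar_mapping",
    "simulate_session",
    "condition_cell_luminance",
    "simulate_scenario",
]


@dataclass(frozen=True)
class SyntheticNeuronParams:
    """Generative parameters of one synthetic unit."""

    neuron_id: str = "unit"
    baseline_rate: float = 2.0  # spikes/s
    luminance_gain: float = 10.0  # spikes/s per unit RF luminance
    identity_gains: tuple[float, ...] = tuple([4.0] * 10)  # per object
    tolerance: float = 0.5
    view_jitter_sd: float = 0.6
    rf_center_azimuth: float = -15.0
    rf_center_elevation: float = 0.0
    rf_sigma_x: float = 10.0
    rf_sigma_y: float = 10.0
    rf_amplitude: float = 20.0  # spikes/s at RF center in bar mapping
    latency_ms: float = 60.0
    snr: float = 10.0
    rv: float = 1.0  # percent
    view_mod_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.tolerance <= 1.0:
            raise ValueError("tolerance must lie in [0, 1]")

    def rf_grid(self) -> RFMap:
        """Noise-free Gaussian RF evaluated on the 6 x 11 grid."""
        az, el = default_grid_coords()
        AZ, EL = np.meshgrid(az, el)
        g = self.rf_amplitude * np.exp(
            -0.5 * (
                ((AZ - self.rf_center_azimuth) / self.rf_sigma_x) ** 2
                + ((EL - self.rf_center_elevation) / self.rf_sigma_y) ** 2
            )
        )
        return RFMap(grid=g)


@dataclass(frozen=True)
class AreaProfile:
    """Parameter distributions for one simulated area.

    The four shipped profiles implement the qualitative functional
    gradient: luminance gain decreases, identity gain / tolerance /
    RF size increase along the V1like -> LLlike progression.
    """

    name: str
    baseline_range: tuple[float, float] = (1.0, 4.0)
    luminance_gain_range: tuple[float, float] = (20.0, 40.0)
    identity_gain_scale: float = 3.0
    identity_selectivity_sd: float = 0.9
    tolerance_beta: tuple[float, float] = (2.0, 8.0)
    view_jitter_sd: float = 0.6
    rf_sigma_range: tuple[float, float] = (4.0, 8.0)
    rf_amplitude_range: tuple[float, float] = (10.0, 30.0)
    latency_range: tuple[float, float] = (40.0, 70.0)
    snr_lognorm: tuple[float, float] = (2.2, 0.5)  # (mu, sigma) of ln SNR
    rv_scale: float = 1.5  # exponential mean, percent

    def draw(self, rng: np.random.Generator, neuron_id: str) -> SyntheticNeuronParams:
        az_side = rng.choice([-15.0, 15.0])
        gains = self.identity_gain_scale * rng.lognormal(
            -0.5 * self.identity_selectivity_sd**2,
            self.identity_selectivity_sd,
            size=10,
        )
        return SyntheticNeuronParams(
            neuron_id=neuron_id,
            baseline_rate=rng.uniform(*self.baseline_range),
            luminance_gain=rng.uniform(*self.luminance_gain_range),
            identity_gains=tuple(gains),
            tolerance=float(rng.beta(*self.tolerance_beta)),
            view_jitter_sd=self.view_jitter_sd,
            rf_center_azimuth=az_side + rng.uniform(-5.0, 5.0),
            rf_center_elevation=rng.uniform(-5.0, 5.0),
            rf_sigma_x=rng.uniform(*self.rf_sigma_range),
            rf_sigma_y=rng.uniform(*self.rf_sigma_range),
            rf_amplitude=rng.uniform(*self.rf_amplitude_range),
            latency_ms=rng.uniform(*self.latency_range),
            snr=float(rng.lognormal(*self.snr_lognorm)),
            rv=float(rng.exponential(self.rv_scale)),
            view_mod_seed=int(rng.integers(2**31 - 1)),
        )


DEFAULT_AREA_PROFILES: dict[str, AreaProfile] = {
    "V1like": AreaProfile(
        name="V1like",
        luminance_gain_range=(20.0, 40.0),
        identity_gain_scale=3.0,
        tolerance_beta=(2.0, 8.0),
        rf_sigma_range=(4.0, 8.0),
    ),
    "LMlike": AreaProfile(
        name="LMlike",
        luminance_gain_range=(14.0, 28.0),
        identity_gain_scale=4.0,
        tolerance_beta=(3.0, 7.0),
        rf_sigma_range=(6.0, 12.0),
    ),
    "LIlike": AreaProfile(
        name="LIlike",
        luminance_gain_range=(7.0, 14.0),
        identity_gain_scale=6.0,
        tolerance_beta=(5.0, 5.0),
        rf_sigma_range=(8.0, 16.0),
    ),
    "LLlike": AreaProfile(
        name="LLlike",
        luminance_gain_range=(1.5, 5.0),
        identity_gain_scale=9.0,
        tolerance_beta=(8.0, 2.0),
        rf_sigma_range=(12.0, 20.0),
    ),
}


def make_area_population(
    profile: AreaProfile, n_units: int, seed: int | np.random.Generator = 0
) -> list[SyntheticNeuronParams]:
    """Draw ``n_units`` i.i.d. parameter sets from an area profile."""
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    rng = np.random.default_rng(seed)
    return [
        profile.draw(rng, neuron_id=f"{profile.name}-{i:03d}")
        for i in range(n_units)
    ]


def simulate_bar_mapping(
    params: SyntheticNeuronParams,
    seed: int | np.random.Generator = 0,
    integration_s: float = 2.0,
    orientation_jitter_sd: float = 0.1,
    noiseless: bool = False,
) -> np.ndarray:
    """Drifting-bar responses per grid cell and orientation.

    Returns (6, 11, 4) mean firing rates: the Gaussian RF evaluated at
    each cell center, with a mild lognormal orientation gain jitter and
    Poisson count noise over ``integration_s`` of accumulated sweeps.
    """
    rng = np.random.default_rng(seed)
    base_rate = params.baseline_rate * 0.1 + params.rf_grid().grid
    ori_gain = (
        np.ones(4)
        if noiseless
        else rng.lognormal(-0.5 * orientation_jitter_sd**2, orientation_jitter_sd, 4)
    )
    rates = base_rate[:, :, None] * ori_gain[None, None, :]
    if noiseless:
        return rates
    counts = rng.poisson(rates * integration_s)
    return counts / integration_s


def condition_cell_luminance(
    stimset: StimulusSet, pixels_per_degree: float = 2.0
) -> np.ndarray:
    """Mean luminance of every condition in each 10-deg RF grid cell.

    Renders each condition on the display raster (at a resolution that
    is ample for 10-deg pooling) and mean-pools it onto the 6 x 11
    grid.  Shape: (n_conditions, 6, 11).
    """
    geometry = replace(stimset.geometry, pixels_per_degree=pixels_per_degree)
    out = np.empty((len(stimset.conditions), GRID_ROWS, GRID_COLS))
    for k, cond in enumerate(stimset.conditions):
        image, az, el = render_condition(cond, stimset.library, geometry)
        out[k] = resample_image_to_grid(image, az, el)
    return out


def _view_modulation(
    params: SyntheticNeuronParams, stimset: StimulusSet
) -> np.ndarray:
    """Frozen per-condition modulation of the identity drive.

    The modulation is keyed by the transformation label T (shared
    across objects): an RF-position gate - the unit's spatial Gaussian
    evaluated at the view's azimuth - times a lognormal draw frozen by
    the unit's private seed.
    """
    rng = np.random.default_rng(params.view_mod_seed)
    labels = sorted({c.view_label for c in stimset.conditions})
    jitter = {
        lab: rng.lognormal(-0.5 * params.view_jitter_sd**2, params.view_jitter_sd)
        for lab in labels
    }
    sigma_gate = max(params.rf_sigma_x, 5.0)
    mods = np.empty(len(stimset.conditions))
    for k, cond in enumerate(stimset.conditions):
        gate = np.exp(
            -0.5 * ((cond.azimuth_deg - params.rf_center_azimuth) / sigma_gate) ** 2
        )
        mods[k] = gate * jitter[cond.view_label]
    return mods


def condition_rates(
    params: SyntheticNeuronParams,
    stimset: StimulusSet,
    cell_luminance: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """(rates, L): firing rate (spikes/s) and RF luminance per condition."""
    rf = params.rf_grid()
    L = np.array([rf_luminance(rf, cell_luminance[k]) for k in range(len(stimset))])
    mods = _view_modulation(params, stimset)
    obj_gain = np.array(
        [params.identity_gains[c.object_id - 1] for c in stimset.conditions]
    )
    drive = (
        params.baseline_rate
        + params.luminance_gain * L
        + obj_gain * (params.tolerance + (1.0 - params.tolerance) * mods)
    )
    return np.maximum(drive, 0.0), L


def simulate_session(
    stimset: StimulusSet,
    neuron_params: list[SyntheticNeuronParams],
    n_trials: int = 26,
    window_ms: float = 150.0,
    seed: int | np.random.Generator = 0,
    cell_luminance: np.ndarray | None = None,
    area: str = "synthetic",
    n_background_trials: int = 100,
    fit_rf: bool = False,
) -> list[NeuronRecording]:
    """Simulate a recording session over the full battery.

    Counts are Poisson with mean rate x window; each unit also gets a
    noisy drifting-bar RF map and matched background-window counts.
    """
    if window_ms <= 0:
        raise ValueError("window must be positive")
    rng = np.random.default_rng(seed)
    if cell_luminance is None:
        cell_luminance = condition_cell_luminance(stimset)
    window_s = window_ms / 1000.0
    recordings = []
    for params in neuron_params:
        rates, L = condition_rates(params, stimset, cell_luminance)
        counts = rng.poisson(rates[:, None] * window_s, size=(len(stimset), n_trials))
        background = rng.poisson(
            params.baseline_rate * window_s, size=n_background_trials
        )
        bar = simulate_bar_mapping(params, seed=rng)
        rf_map = compute_rf_map(bar)
        rf_fit = None
        if fit_rf:
            from .rf import RFGaussianModel

            try:
                rf_fit = RFGaussianModel(rf_map).fit()
            except ValueError:
                rf_fit = None
        recordings.append(
            NeuronRecording(
                neuron_id=params.neuron_id,
                area=area,
                spike_counts=counts,
                background_counts=background,
                window_ms=window_ms,
                latency_ms=params.latency_ms,
                rf_map=rf_map,
                rf_fit=rf_fit,
                snr=params.snr,
                rv=params.rv,
                rf_luminance=L,
                extras={"params": params},
            )
        )
    return recordings


def simulate_scenario(
    stimset: StimulusSet,
    n_units_per_area: int = 100,
    n_trials: int = 26,
    seed: int = 0,
    profiles: dict[str, AreaProfile] | None = None,
    fit_rf: bool = False,
) -> dict[str, list[NeuronRecording]]:
    """The shipped four-area scenario: V1like / LMlike / LIlike /
    LLlike populations simulated over the standard battery."""
    profiles = profiles or DEFAULT_AREA_PROFILES
    rng = np.random.default_rng(seed)
    cell_lum = condition_cell_luminance(stimset)
    out: dict[str, list[NeuronRecording]] = {}
    for name, profile in profiles.items():
        params = make_area_population(profile, n_units_per_area, rng)
        out[name] = simulate_session(
            stimset,
            params,
            n_trials=n_trials,
            seed=rng,
            cell_luminance=cell_lum,
            area=name,
            fit_rf=fit_rf,
        )
    return out
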