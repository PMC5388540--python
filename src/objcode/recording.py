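"""Per-neuron recording container shared by the simulator and the
analysis pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rf import RFFitResults, RFMap

__all__ = ["NeuronRecording"]


@dataclass
class NeuronRecording:
    """Spike counts and metadata for one unit.

    ``spike_counts`` is (n_conditions, n_trials), aligned to the
    condition ids of the stimulus battery; ``background_counts`` are
    counts in matched windows with no stimulus.  ``snr`` (peak-to-peak
    signal over noise) and ``rv`` (% of inter-spike intervals < 2 ms)
    are spike-isolation quality metrics consumed as given attributes.
    """

    neuron_id: str
    area: str
    spike_counts: np.ndarray
    background_counts: np.ndarray
    window_ms: float = 150.0
    latency_ms: float = float("nan")
    layer: str = "unknown"
    rf_map: RFMap | None = None
    rf_fit: RFFitResults | None = None
    snr: float = float("nan")
    rv: float = float("nan")
    rf_luminance: np.ndarray | None = None  # per-condition L
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.spike_counts = np.asarray(self.spike_counts)
        if np.any(self.spike_counts < 0):
            raise ValueError("spike counts must be nonnegative")
        if self.window_ms <= 0:
            raise ValueError("window must be positive")

    @property
    def n_conditions(self) -> int:
        return self.spike_counts.shape[0]

    @property
    def n_trials(self) -> int:
        return self.spike_counts.shape[1]

    @property
    def rf_center_azimuth(self) -> float:
        if self.rf_fit is not None and self.rf_fit.acceptable:
            return self.rf_fit.center_azimuth_deg
        if self.rf_map is not None:
            i, j = np.unravel_index(np.argmax(self.rf_map.grid), self.rf_map.grid.shape)
            return float(self.rf_map.azimuth_deg[j])
        return 0.0

    def mean_rates(self) -> np.ndarray:
        """Mean evoked firing rate per condition (spikes/s)."""
        return self.spike_counts.mean(axis=1) / (self.window_ms / 1000.0)
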