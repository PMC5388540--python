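"""Receptive-field maps, 2-D Gaussian fits, RF luminance and RF contrast.

RFs are summarized on a 6 x 11 grid of 10 deg-wide cells covering the
display.  A raw firing-intensity map is fitted with a two-dimensional
Gaussian with independent widths; RF size is the mean of the two SDs.
Per-stimulus RF luminance (L) weights the stimulus image by the raw map
normalized to its maximum, then normalizes by the full-field maximum, so
L is 1 for a full-field bright stimulus and 0 for a blank screen.  RF
contrast (C) is the SD of the RF-weighted luminances inside the RF
boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "RFMap",
    "RFFitResults",
    "RFGaussianModel",
    "compute_rf_map",
    "default_grid_coords",
    "resample_image_to_grid",
    "rf_luminance",
    "rf_contrast",
    "rf_coverage",
    "rf_inside_mask",
]

GRID_ROWS = 6
GRID_COLS = 11
CELL_DEG = 10.0


def default_grid_coords() -> tuple[np.ndarray, np.ndarray]:
    """(azimuth, elevation) centers (deg) of the 6 x 11 grid cells."""
    az = (np.arange(GRID_COLS) - (GRID_COLS - 1) / 2.0) * CELL_DEG
    el = (np.arange(GRID_ROWS) - (GRID_ROWS - 1) / 2.0) * CELL_DEG
    return az, el


@dataclass
class RFMap:
    """Raw RF map: mean firing intensity per 10-deg grid cell."""

    grid: np.ndarray  # (6, 11), spikes/s
    azimuth_deg: np.ndarray = field(default_factory=lambda: default_grid_coords()[0])
    elevation_deg: np.ndarray = field(default_factory=lambda: default_grid_coords()[1])

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.shape != (GRID_ROWS, GRID_COLS):
            raise ValueError(f"RF grid must be {GRID_ROWS}x{GRID_COLS}")
        if np.any(self.grid < 0):
            raise ValueError("RF map values must be nonnegative")

    def normalized(self) -> np.ndarray:
        m = self.grid.max()
        if m == 0:
            raise ValueError("all-zero RF map cannot be normalized")
        return self.grid / m


def compute_rf_map(bar_responses: np.ndarray) -> RFMap:
    """Average drifting-bar responses over the 4 orientations per cell.

    ``bar_responses`` has shape (6, 11, 4): mean spike rate per grid
    cell for bar orientations 0/45/90/135 deg.
    """
    bar_responses = np.asarray(bar_responses, dtype=float)
    if bar_responses.shape != (GRID_ROWS, GRID_COLS, 4):
        raise ValueError("bar_responses must have shape (6, 11, 4)")
    return RFMap(grid=bar_responses.mean(axis=2))


@dataclass
class RFFitResults:
    """Results of a 2-D Gaussian RF fit.

    Attributes mirror the fitted parameterization
    ``baseline + amplitude * exp(-dx^2/(2 sx^2) - dy^2/(2 sy^2))``.
    """

    center_azimuth_deg: float
    center_elevation_deg: float
    sigma_x_deg: float
    sigma_y_deg: float
    amplitude: float
    baseline: float
    r_squared: float
    converged: bool
    rfmap: RFMap | None = None

    @property
    def acceptable(self) -> bool:
        """Fit quality criterion: R^2 > 0.5 and convergence."""
        return bool(self.converged and self.r_squared > 0.5)

    @property
    def rf_size_deg(self) -> float:
        """RF diameter: mean of the two Gaussian SDs (NaN if the fit is
        not acceptable)."""
        if not self.acceptable:
            return float("nan")
        return 0.5 * (self.sigma_x_deg + self.sigma_y_deg)

    def predict(self, az: np.ndarray, el: np.ndarray) -> np.ndarray:
        dx = (np.asarray(az) - self.center_azimuth_deg) / self.sigma_x_deg
        dy = (np.asarray(el) - self.center_elevation_deg) / self.sigma_y_deg
        return self.baseline + self.amplitude * np.exp(-0.5 * (dx**2 + dy**2))

    def summary(self) -> str:
        lines = [
            "2-D Gaussian receptive-field fit",
            "--------------------------------",
            f"center      : ({self.center_azimuth_deg:+.2f}, "
            f"{self.center_elevation_deg:+.2f}) deg",
            f"sigma (x, y): ({self.sigma_x_deg:.2f}, {self.sigma_y_deg:.2f}) deg",
            f"amplitude   : {self.amplitude:.2f} spikes/s",
            f"baseline    : {self.baseline:.2f} spikes/s",
            f"R^2         : {self.r_squared:.4f}",
            f"RF size     : {self.rf_size_deg:.2f} deg"
            if self.acceptable
            else "RF size     : undefined (fit not acceptable)",
            f"acceptable  : {self.acceptable}",
        ]
        return "\n".join(lines)


class RFGaussianModel:
    """Least-squares 2-D Gaussian model of a raw RF map.

    Parameters
    ----------
    rfmap : RFMap
        Raw 6 x 11 firing-intensity grid.

    ``fit()`` returns :class:`RFFitResults`; non-convergence is flagged
    (``converged=False``), never raised.
    """

    def __init__(self, rfmap: RFMap):
        self.rfmap = rfmap
        if np.ptp(rfmap.grid) == 0:
            raise ValueError("RF map is constant; nothing to fit")

    def _initial_guess(self) -> np.ndarray:
        g = self.rfmap.grid
        az, el = self.rfmap.azimuth_deg, self.rfmap.elevation_deg
        baseline = g.min()
        w = g - baseline
        total = w.sum()
        if total <= 0:
            cx, cy = 0.0, 0.0
            sx = sy = CELL_DEG
        else:
            AZ, EL = np.meshgrid(az, el)
            cx = (w * AZ).sum() / total
            cy = (w * EL).sum() / total
            sx = np.sqrt(max((w * (AZ - cx) ** 2).sum() / total, 1.0))
            sy = np.sqrt(max((w * (EL - cy) ** 2).sum() / total, 1.0))
        return np.array([g.max() - baseline, cx, cy, sx, sy, baseline])

    def fit(self) -> RFFitResults:
        g = self.rfmap.grid
        az, el = self.rfmap.azimuth_deg, self.rfmap.elevation_deg
        AZ, EL = np.meshgrid(az, el)

        def residuals(p: np.ndarray) -> np.ndarray:
            amp, cx, cy, sx, sy, base = p
            model = base + amp * np.exp(
                -0.5 * (((AZ - cx) / sx) ** 2 + ((EL - cy) / sy) ** 2)
            )
            return (model - g).ravel()

        p0 = self._initial_guess()
        lo = [0.0, az[0] - CELL_DEG, el[0] - CELL_DEG, 0.5, 0.5, 0.0]
        hi = [
            np.inf,
            az[-1] + CELL_DEG,
            el[-1] + CELL_DEG,
            10 * CELL_DEG,
            10 * CELL_DEG,
            np.inf,
        ]
        p0 = np.clip(p0, lo, hi)
        converged = True
        try:
            sol = least_squares(residuals, p0, bounds=(lo, hi), max_nfev=2000)
            converged = bool(sol.success)
            p = sol.x
        except Exception:  # pragma: no cover - optimizer pathologies
            converged = False
            p = p0
        ss_resid = float(np.sum(residuals(p) ** 2))
        ss_total = float(np.sum((g - g.mean()) ** 2))
        r2 = 1.0 - ss_resid / ss_total if ss_total > 0 else float("nan")
        amp, cx, cy, sx, sy, base = p
        return RFFitResults(
            center_azimuth_deg=float(cx),
            center_elevation_deg=float(cy),
            sigma_x_deg=float(sx),
            sigma_y_deg=float(sy),
            amplitude=float(amp),
            baseline=float(base),
            r_squared=float(r2),
            converged=converged,
            rfmap=self.rfmap,
        )


def resample_image_to_grid(
    image: np.ndarray,
    azimuth_axis_deg: np.ndarray,
    elevation_axis_deg: np.ndarray,
    grid_azimuth_deg: np.ndarray | None = None,
    grid_elevation_deg: np.ndarray | None = None,
) -> np.ndarray:
    """Mean-pool a display image into the 10-deg RF grid cells."""
    if grid_azimuth_deg is None or grid_elevation_deg is None:
        grid_azimuth_deg, grid_elevation_deg = default_grid_coords()
    out = np.zeros((len(grid_elevation_deg), len(grid_azimuth_deg)))
    half = CELL_DEG / 2.0
    for i, ec in enumerate(grid_elevation_deg):
        rows = (elevation_axis_deg >= ec - half) & (elevation_axis_deg < ec + half)
        for j, ac in enumerate(grid_azimuth_deg):
            cols = (azimuth_axis_deg >= ac - half) & (azimuth_axis_deg < ac + half)
            cell = image[np.ix_(rows, cols)]
            out[i, j] = cell.mean() if cell.size else 0.0
    return out


def rf_luminance(rfmap: RFMap, cell_luminance: np.ndarray) -> float:
    """RF luminance L of a stimulus, as a fraction of the full-field
    maximum.

    ``cell_luminance`` is the stimulus image mean-pooled onto the RF
    grid (values in [0, 1]).  L = sum(w * lum) / sum(w) with w the raw
    map normalized to its maximum; the denominator is the response to a
    hypothetical full-field stimulus at maximal brightness.
    """
    w = rfmap.normalized()
    cell_luminance = np.asarray(cell_luminance, dtype=float)
    if cell_luminance.shape != w.shape:
        raise ValueError("cell_luminance must match the RF grid shape")
    return float((w * cell_luminance).sum() / w.sum())


def rf_inside_mask(rfmap: RFMap, fit: RFFitResults | None = None) -> np.ndarray:
    """Boolean mask of grid cells 'inside the RF'.

    Cells whose centers fall within the 1-SD ellipse of an acceptable
    Gaussian fit; if no acceptable fit is available, cells whose
    normalized raw weight is >= 0.5.
    """
    if fit is not None and fit.acceptable:
        AZ, EL = np.meshgrid(rfmap.azimuth_deg, rfmap.elevation_deg)
        q = ((AZ - fit.center_azimuth_deg) / fit.sigma_x_deg) ** 2 + (
            (EL - fit.center_elevation_deg) / fit.sigma_y_deg
        ) ** 2
        mask = q <= 1.0
        if mask.any():
            return mask
        # RF smaller than one grid cell: fall back to the weight rule
    return rfmap.normalized() >= 0.5


def rf_contrast(
    rfmap: RFMap,
    cell_luminance: np.ndarray,
    inside: np.ndarray | None = None,
    fit: RFFitResults | None = None,
    ddof: int = 0,
) -> float:
    """RF contrast C: SD of the RF-weighted luminances inside the RF.

    ``ddof=0`` (population SD) by default.
    """
    if inside is None:
        inside = rf_inside_mask(rfmap, fit)
    if not np.any(inside):
        raise ValueError("empty RF boundary")
    w = rfmap.normalized()
    vals = (w * np.asarray(cell_luminance, dtype=float))[inside]
    if vals.size <= ddof:
        return float("nan")
    return float(np.std(vals, ddof=ddof))


def rf_coverage(
    rfmap: RFMap,
    cell_luminance: np.ndarray,
    inside: np.ndarray | None = None,
    fit: RFFitResults | None = None,
) -> float:
    """Fraction of within-boundary RF weight overlapped by nonzero
    object pixels (used with the >= 10% coverage criterion)."""
    if inside is None:
        inside = rf_inside_mask(rfmap, fit)
    if not np.any(inside):
        raise ValueError("empty RF boundary")
    w = rfmap.normalized()
    lum = np.asarray(cell_luminance, dtype=float)
    covered = (lum > 0) & inside
    return float(w[covered].sum() / w[inside].sum())


def check_contrast_condition_count(n_qualifying: int, minimum: int = 23) -> bool:
    """A neuron enters the contrast-information analysis only when at
    least ``minimum`` conditions cover >= 10% of its RF."""
    ok = n_qualifying >= minimum
    if not ok:
        warnings.warn(
            f"neuron excluded from contrast analysis: only {n_qualifying} "
            f"conditions cover the RF (need >= {minimum})",
            stacklevel=2,
        )
    return ok
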