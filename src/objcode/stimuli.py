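"""Stimulus battery generation and tangent-screen geometry.

The battery comprises 10 objects x 38 views (380 conditions): 8 azimuth
positions, plus size, in-plane rotation, in-depth rotation and luminance
changes applied at the two default azimuths (-15 deg and +15 deg).  The
display sits close to the eye, so stimuli are drawn under a tangent-screen
projection: each view is rendered as it would appear on a virtual screen
tangent to the viewing circle, which keeps the retinal shape, size and
aspect ratio of an object constant across azimuth positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .shapes import ShapeLibrary, default_library

logger = logging.getLogger(__name__)

__all__ = [
    "DisplayGeometry",
    "StimulusCondition",
    "StimulusSet",
    "tangent_project",
    "tangent_back_project",
    "build_stimulus_set",
    "render_condition",
    "retinal_image",
    "back_project_image",
    "select_conditions_for_neuron",
    "select_population_views",
    "POSITION_AZIMUTHS",
    "DEFAULT_AZIMUTHS",
    "SIZES",
    "INPLANE_ANGLES",
    "INDEPTH_ANGLES",
    "LUMINANCE_LEVELS",
]

POSITION_AZIMUTHS = (-22.5, -15.0, -7.5, 0.0, 7.5, 15.0, 22.5, 30.0)
DEFAULT_AZIMUTHS = (-15.0, 15.0)
DEFAULT_SIZE = 35.0
SIZES = (15.0, 25.0, 35.0, 45.0, 55.0)
INPLANE_ANGLES = (-40.0, -20.0, 0.0, 20.0, 40.0)
INDEPTH_ANGLES = (-60.0, -40.0, 0.0, 40.0, 60.0)
LUMINANCE_LEVELS = (1.0, 0.5, 0.25, 0.125)

AXES = ("position", "size", "inplane_rotation", "indepth_rotation", "luminance")


@dataclass(frozen=True)
class DisplayGeometry:
    """Viewing geometry of the stimulus display.

    Parameters
    ----------
    distance_cm : eye-to-screen distance R (cm).
    azimuth_span_deg, elevation_span_deg : angular extent of the display.
    pixels_per_degree : raster resolution (pixel centers are uniform in
        azimuth/elevation degrees; cm coordinates follow x = R tan a).
    indepth_asymmetry : shear coefficient of the 2-D stand-in for
        in-depth rotation (0 = pure horizontal foreshortening).
    """

    distance_cm: float = 30.0
    azimuth_span_deg: float = 120.0
    elevation_span_deg: float = 90.0
    pixels_per_degree: float = 4.0
    indepth_asymmetry: float = 0.2

    def __post_init__(self) -> None:
        if self.distance_cm <= 0:
            raise ValueError("distance_cm must be positive")
        if self.azimuth_span_deg <= 0 or self.elevation_span_deg <= 0:
            raise ValueError("display spans must be positive")

    def pixel_axes(self) -> tuple[np.ndarray, np.ndarray]:
        """(azimuth, elevation) pixel-center coordinates in degrees."""
        step = 1.0 / self.pixels_per_degree
        n_az = int(round(self.azimuth_span_deg * self.pixels_per_degree))
        n_el = int(round(self.elevation_span_deg * self.pixels_per_degree))
        az = (np.arange(n_az) - (n_az - 1) / 2.0) * step
        el = (np.arange(n_el) - (n_el - 1) / 2.0) * step
        return az, el


def tangent_project(
    x2: np.ndarray, y2: np.ndarray, theta_deg: float, distance_cm: float = 30.0
) -> tuple[np.ndarray, np.ndarray]:
    """Project tangent-screen coordinates onto the flat display.

    A point (x2, y2) (cm, relative to the object center) on the virtual
    screen tangent at azimuth ``theta_deg`` maps to display coordinates
    (x1, y1) (cm, relative to the projected object center x0 = R tan
    theta)::

        x1 = R tan(theta + phi) - x0,   phi = atan(x2 / R)
        y1 = y2 cos(phi) / cos(phi + theta)

    Raises ``ValueError`` when the combined azimuth |theta + phi|
    reaches 90 deg (projection runs off the display plane).
    """
    x2 = np.asarray(x2, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    R = float(distance_cm)
    theta = np.deg2rad(theta_deg)
    phi = np.arctan2(x2, R)
    total = theta + phi
    if np.any(np.abs(total) >= np.pi / 2):
        raise ValueError("projection beyond +/-90 deg combined azimuth")
    x0 = R * np.tan(theta)
    x1 = R * np.tan(total) - x0
    y1 = y2 * np.cos(phi) / np.cos(total)
    return x1, y1


def tangent_back_project(
    x1: np.ndarray, y1: np.ndarray, theta_deg: float, distance_cm: float = 30.0
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`tangent_project` (display -> tangent screen)."""
    x1 = np.asarray(x1, dtype=float)
    y1 = np.asarray(y1, dtype=float)
    R = float(distance_cm)
    theta = np.deg2rad(theta_deg)
    x0 = R * np.tan(theta)
    total = np.arctan2(x1 + x0, R)
    phi = total - theta
    x2 = R * np.tan(phi)
    y2 = y1 * np.cos(total) / np.cos(phi)
    return x2, y2


@dataclass(frozen=True)
class StimulusCondition:
    """One object view S = (O, T)."""

    condition_id: int
    object_id: int
    axis: str
    azimuth_deg: float
    elevation_deg: float = 0.0
    size_deg: float = DEFAULT_SIZE
    inplane_deg: float = 0.0
    indepth_deg: float = 0.0
    luminance_level: float = 1.0

    def __post_init__(self) -> None:
        if self.axis not in AXES:
            raise ValueError(f"unknown axis {self.axis!r}")
        if self.azimuth_deg not in POSITION_AZIMUTHS:
            raise ValueError(f"azimuth {self.azimuth_deg} not in the battery")
        if self.size_deg not in SIZES:
            raise ValueError(f"size {self.size_deg} not in the battery")
        if self.axis != "position" and self.azimuth_deg not in DEFAULT_AZIMUTHS:
            raise ValueError("non-position views only at -15/+15 deg azimuth")

    @property
    def view_label(self) -> str:
        if self.axis == "position":
            return f"pos{self.azimuth_deg:+g}"
        if self.axis == "size":
            return f"size{self.size_deg:g}"
        if self.axis == "inplane_rotation":
            return f"ip{self.inplane_deg:+g}"
        if self.axis == "indepth_rotation":
            return f"id{self.indepth_deg:+g}"
        return f"lum{self.luminance_level:g}"


@dataclass
class StimulusSet:
    """The full battery (or a subset) plus its display geometry."""

    conditions: list[StimulusCondition]
    geometry: DisplayGeometry
    library: ShapeLibrary = field(default_factory=default_library)

    def __len__(self) -> int:
        return len(self.conditions)

    def manifest(self) -> pd.DataFrame:
        rows = [
            {
                "condition_id": c.condition_id,
                "object_id": c.object_id,
                "axis": c.axis,
                "azimuth_deg": c.azimuth_deg,
                "elevation_deg": c.elevation_deg,
                "size_deg": c.size_deg,
                "inplane_deg": c.inplane_deg,
                "indepth_deg": c.indepth_deg,
                "luminance_level": c.luminance_level,
            }
            for c in self.conditions
        ]
        return pd.DataFrame(rows)

    def for_object(self, object_id: int) -> list[StimulusCondition]:
        return [c for c in self.conditions if c.object_id == object_id]


def _object_views(object_id: int) -> list[dict]:
    """The 38 views of one object, in deterministic order."""
    views: list[dict] = []
    for az in POSITION_AZIMUTHS:
        views.append(dict(axis="position", azimuth_deg=az))
    for az in DEFAULT_AZIMUTHS:
        for s in SIZES:
            if s != DEFAULT_SIZE:
                views.append(dict(axis="size", azimuth_deg=az, size_deg=s))
        for a in INPLANE_ANGLES:
            if a != 0.0:
                views.append(
                    dict(axis="inplane_rotation", azimuth_deg=az, inplane_deg=a)
                )
        for a in INDEPTH_ANGLES:
            if a != 0.0:
                views.append(
                    dict(axis="indepth_rotation", azimuth_deg=az, indepth_deg=a)
                )
        for lv in LUMINANCE_LEVELS:
            if lv != 1.0:
                views.append(
                    dict(axis="luminance", azimuth_deg=az, luminance_level=lv)
                )
    return views


def build_stimulus_set(
    library: ShapeLibrary | None = None,
    geometry: DisplayGeometry | None = None,
    allow_any_object_count: bool = False,
) -> StimulusSet:
    """Build the full 380-condition battery (38 views per object)."""
    library = library if library is not None else default_library()
    geometry = geometry if geometry is not None else DisplayGeometry()
    if len(library) != 10 and not allow_any_object_count:
        raise ValueError(
            f"library holds {len(library)} objects; the standard battery "
            "requires 10 (pass allow_any_object_count=True to override)"
        )
    conditions: list[StimulusCondition] = []
    cid = 0
    for object_id in library.object_ids():
        for view in _object_views(object_id):
            conditions.append(
                StimulusCondition(condition_id=cid, object_id=object_id, **view)
            )
            cid += 1
    return StimulusSet(conditions=conditions, geometry=geometry, library=library)


def _shape_coords(
    x2: np.ndarray, y2: np.ndarray, condition: StimulusCondition, geometry: DisplayGeometry
) -> tuple[np.ndarray, np.ndarray]:
    """Tangent-screen cm -> object-local bounding-radius coordinates."""
    R = geometry.distance_cm
    radius_cm = R * np.tan(np.deg2rad(condition.size_deg / 2.0))
    u = x2 / radius_cm
    v = y2 / radius_cm
    if condition.inplane_deg:
        a = np.deg2rad(condition.inplane_deg)
        u, v = np.cos(a) * u + np.sin(a) * v, -np.sin(a) * u + np.cos(a) * v
    if condition.indepth_deg:
        # 2-D stand-in for out-of-plane rotation: horizontal
        # foreshortening by cos(angle) plus a mild shear asymmetry.
        a = np.deg2rad(condition.indepth_deg)
        u = u / np.cos(a)
        v = v + geometry.indepth_asymmetry * np.sin(a) * u * np.cos(a)
    return u, v


def render_condition(
    condition: StimulusCondition,
    library: ShapeLibrary | None = None,
    geometry: DisplayGeometry | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render one condition on the display raster.

    Returns ``(image, azimuth_deg, elevation_deg)`` where ``image`` has
    shape ``(n_elevation, n_azimuth)``, values in [0, 1] (background 0),
    and the axis arrays give pixel-center coordinates in degrees.  Each
    display pixel is back-projected through the inverse tangent map and
    the object is evaluated in tangent-screen coordinates, so the
    retinal image is azimuth-independent by construction.
    """
    library = library if library is not None else default_library()
    geometry = geometry if geometry is not None else DisplayGeometry()
    if condition.object_id not in library:
        raise KeyError(f"unknown object_id {condition.object_id}")
    az, el = geometry.pixel_axes()
    R = geometry.distance_cm
    x1_abs = R * np.tan(np.deg2rad(az))[None, :]
    y1_abs = R * np.tan(np.deg2rad(el))[:, None]
    x0 = R * np.tan(np.deg2rad(condition.azimuth_deg))
    x2, y2 = tangent_back_project(
        x1_abs - x0, np.broadcast_to(y1_abs, (el.size, az.size)),
        condition.azimuth_deg, R,
    )
    u, v = _shape_coords(x2, y2, condition, geometry)
    image = condition.luminance_level * library.evaluate(condition.object_id, u, v)
    return image, az, el


def retinal_image(
    condition: StimulusCondition,
    library: ShapeLibrary | None = None,
    geometry: DisplayGeometry | None = None,
    half_span_deg: float = 40.0,
    pixels_per_degree: float | None = None,
) -> np.ndarray:
    """Object-centered retinal image, exact by construction.

    Samples the object on a grid of tangent-screen coordinates centred
    on the object (x2 = R tan(phi) for retinal azimuth phi relative to
    the object center).  Identical for all display azimuths of the same
    view, since the display render pre-compensates the perspective
    distortion.
    """
    library = library if library is not None else default_library()
    geometry = geometry if geometry is not None else DisplayGeometry()
    ppd = pixels_per_degree or geometry.pixels_per_degree
    n = int(round(2 * half_span_deg * ppd))
    ang = (np.arange(n) - (n - 1) / 2.0) / ppd
    R = geometry.distance_cm
    coords = R * np.tan(np.deg2rad(ang))
    x2 = coords[None, :]
    y2 = coords[:, None]
    u, v = _shape_coords(
        np.broadcast_to(x2, (n, n)), np.broadcast_to(y2, (n, n)), condition, geometry
    )
    return condition.luminance_level * library.evaluate(condition.object_id, u, v)


def back_project_image(
    image: np.ndarray,
    azimuth_axis_deg: np.ndarray,
    elevation_axis_deg: np.ndarray,
    theta_deg: float,
    geometry: DisplayGeometry,
    half_span_deg: float = 40.0,
    pixels_per_degree: float | None = None,
    order: int = 3,
) -> np.ndarray:
    """Numerically resample a rendered display image into retinal
    (object-centered tangent-screen) coordinates.

    Interpolation-limited: agreement with :func:`retinal_image` is at
    the resampling tolerance of the raster, not machine precision.
    """
    ppd = pixels_per_degree or geometry.pixels_per_degree
    n = int(round(2 * half_span_deg * ppd))
    ang = (np.arange(n) - (n - 1) / 2.0) / ppd
    R = geometry.distance_cm
    coords = R * np.tan(np.deg2rad(ang))
    x2 = np.broadcast_to(coords[None, :], (n, n))
    y2 = np.broadcast_to(coords[:, None], (n, n))
    x1, y1 = tangent_project(x2, y2, theta_deg, R)
    x0 = R * np.tan(np.deg2rad(theta_deg))
    a = np.rad2deg(np.arctan2(x1 + x0, R))
    e = np.rad2deg(np.arctan2(y1, R))
    # degree coordinates -> fractional pixel indices (axes are uniform)
    az_step = azimuth_axis_deg[1] - azimuth_axis_deg[0]
    el_step = elevation_axis_deg[1] - elevation_axis_deg[0]
    col = (a - azimuth_axis_deg[0]) / az_step
    row = (e - elevation_axis_deg[0]) / el_step
    return map_coordinates(image, [row, col], order=order, mode="constant", cval=0.0)


def select_conditions_for_neuron(
    stimset: StimulusSet, rf_center_azimuth_deg: float
) -> list[StimulusCondition]:
    """Per-neuron condition subset: 23 views per object, 230 total.

    All 8 positions are kept; the non-position transformations are taken
    at whichever default azimuth (-15/+15 deg) is nearer the neuron's RF
    center (ties resolve to -15 deg).
    """
    if not np.isfinite(rf_center_azimuth_deg):
        raise ValueError("rf_center_azimuth_deg must be finite")
    d_minus = abs(rf_center_azimuth_deg - (-15.0))
    d_plus = abs(rf_center_azimuth_deg - 15.0)
    chosen = -15.0 if d_minus <= d_plus else 15.0
    if d_minus == d_plus:
        logger.info("RF center equidistant from -15/+15 deg; tie -> -15 deg")
    subset = [
        c
        for c in stimset.conditions
        if c.axis == "position" or c.azimuth_deg == chosen
    ]
    return subset


def select_population_views(
    subset: list[StimulusCondition], rf_group: str
) -> tuple[list[StimulusCondition], dict[float, float]]:
    """19-view-per-object subset for the population analyses.

    The four positions far from the neuron group's RF side are dropped:
    the ``minus15`` group keeps positions [-22.5, 0] deg, the ``plus15``
    group keeps [+7.5, +30] deg.  The returned alignment map pairs the
    retained positions of the two groups (-22.5 <-> +7.5, -15 <-> +15,
    -7.5 <-> +22.5, 0 <-> +30) so both groups share one aligned view set.
    """
    if rf_group not in ("minus15", "plus15"):
        raise ValueError("rf_group must be 'minus15' or 'plus15'")
    if rf_group == "minus15":
        keep = {-22.5, -15.0, -7.5, 0.0}
        alignment = {-22.5: 7.5, -15.0: 15.0, -7.5: 22.5, 0.0: 30.0}
    else:
        keep = {7.5, 15.0, 22.5, 30.0}
        alignment = {7.5: -22.5, 15.0: -15.0, 22.5: -7.5, 30.0: 0.0}
    views = [
        c for c in subset if c.axis != "position" or c.azimuth_deg in keep
    ]
    return views, alignment


def canonical_view_order(subset_for_object: list[StimulusCondition]) -> list[StimulusCondition]:
    """Order a per-object view list canonically so view index t aligns
    across objects (positions ascending, then sizes, rotations,
    luminances in battery order)."""
    axis_rank = {a: i for i, a in enumerate(AXES)}

    def key(c: StimulusCondition):
        return (
            axis_rank[c.axis],
            c.azimuth_deg if c.axis == "position" else 0.0,
            c.size_deg,
            c.inplane_deg,
            c.indepth_deg,
            -c.luminance_level,
        )

    return sorted(subset_for_object, key=key)
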