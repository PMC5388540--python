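"""Procedural grayscale object library.

Ten smooth 2-D shapes, each built as a mixture of soft-edged elliptical
lobes, standing in for rendered 3-D objects.  Shapes are defined over a
unit bounding circle (coordinates in units of the bounding radius) and
vary in silhouette, internal luminance structure and overall brightness,
so that object pairs span a wide range of mean-luminance ratios.

Each lobe is ``amp * exp(-q**edge_power)`` where ``q`` is the squared
elliptical radius of the lobe; ``edge_power`` controls how crisp the
silhouette edge is while keeping the profile smooth enough for accurate
image resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Lobe", "Shape", "ShapeLibrary", "default_library"]


@dataclass(frozen=True)
class Lobe:
    """One elliptical luminance lobe in bounding-radius units."""

    cx: float
    cy: float
    rx: float
    ry: float
    angle_deg: float = 0.0
    amp: float = 1.0
    edge_power: float = 3.0

    def evaluate(self, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        a = np.deg2rad(self.angle_deg)
        du, dv = u - self.cx, v - self.cy
        x = np.cos(a) * du + np.sin(a) * dv
        y = -np.sin(a) * du + np.cos(a) * dv
        q = (x / self.rx) ** 2 + (y / self.ry) ** 2
        return self.amp * np.exp(-(q**self.edge_power))


@dataclass(frozen=True)
class Shape:
    """A visual object: a clipped sum of lobes, max luminance 1."""

    object_id: int
    lobes: tuple[Lobe, ...]
    gain: float = 1.0  # scales overall brightness before clipping

    def evaluate(self, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        out = np.zeros(np.broadcast(u, v).shape)
        for lobe in self.lobes:
            out += lobe.evaluate(u, v)
        return np.clip(self.gain * out, 0.0, 1.0)


@dataclass
class ShapeLibrary:
    """Pluggable collection of objects keyed by 1-based object id."""

    shapes: dict[int, Shape] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.shapes)

    def __contains__(self, object_id: int) -> bool:
        return object_id in self.shapes

    def object_ids(self) -> list[int]:
        return sorted(self.shapes)

    def evaluate(self, object_id: int, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        if object_id not in self.shapes:
            raise KeyError(f"unknown object_id {object_id}")
        return self.shapes[object_id].evaluate(u, v)


def _shape_specs() -> list[tuple[float, list[Lobe]]]:
    # Hand-designed lobe mixtures: silhouettes range from compact blobs
    # to elongated, multi-part figures; gains spread the mean luminances
    # so some pairs are luminance-matched and others are not.
    L = Lobe
    return [
        # 1: bright filled disk with a dark notch (high luminance)
        (1.4, [L(0.0, 0.0, 0.72, 0.72), L(0.45, 0.45, 0.28, 0.28, amp=-0.9)]),
        # 2: horizontal dumbbell
        (1.2, [L(-0.52, 0.0, 0.40, 0.34), L(0.52, 0.0, 0.40, 0.34),
               L(0.0, 0.0, 0.55, 0.14)]),
        # 3: thin oblique bar (low luminance)
        (1.0, [L(0.0, 0.0, 0.85, 0.20, angle_deg=35.0)]),
        # 4: tripod of small blobs
        (1.1, [L(0.0, 0.55, 0.30, 0.30), L(-0.50, -0.35, 0.30, 0.30),
               L(0.50, -0.35, 0.30, 0.30)]),
        # 5: crescent
        (1.3, [L(0.0, 0.0, 0.70, 0.70), L(0.32, 0.0, 0.52, 0.52, amp=-1.2)]),
        # 6: vertical lens with bright core
        (1.0, [L(0.0, 0.0, 0.34, 0.80), L(0.0, 0.15, 0.16, 0.30, amp=0.8)]),
        # 7: broad soft blob, slightly elliptical
        (0.9, [L(0.0, 0.0, 0.80, 0.62, angle_deg=-20.0)]),
        # 8: cross of two bars
        (1.1, [L(0.0, 0.0, 0.80, 0.20), L(0.0, 0.0, 0.20, 0.80)]),
        # 9: asymmetric two-lobe figure
        (1.2, [L(-0.35, 0.20, 0.45, 0.40, angle_deg=15.0),
               L(0.40, -0.30, 0.32, 0.28)]),
        # 10: ring
        (1.5, [L(0.0, 0.0, 0.74, 0.74), L(0.0, 0.0, 0.42, 0.42, amp=-1.0)]),
    ]


def default_library() -> ShapeLibrary:
    """The ten-object library shipped with the package."""
    shapes = {
        i + 1: Shape(object_id=i + 1, lobes=tuple(lobes), gain=gain)
        for i, (gain, lobes) in enumerate(_shape_specs())
    }
    return ShapeLibrary(shapes=shapes)
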