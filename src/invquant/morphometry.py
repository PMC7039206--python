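"""Vesicle-capture morphometry from segmented EM contours.

Three per-scene statistics: vesicle diameter (twice the mean
centroid-to-contour-point distance, in nm), vesicle abundance per micron
of mitochondrial perimeter, and the fraction of mitochondrial perimeter
lying within a fixed outward dilation (default 15 nm) of the vesicle
outlines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import LineString, Polygon
from shapely.ops import unary_union

from invquant.io import ContourScene

__all__ = [
    "VesicleMeasure",
    "DecorationMeasure",
    "vesicle_diameter",
    "mito_perimeter",
    "vesicles_per_micron",
    "decorated_fraction",
    "measure_scene",
]


@dataclass
class VesicleMeasure:
    vesicle_id: int
    center: tuple[float, float]  # nm
    diameter: float              # nm
    n_points: int

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")
        if self.n_points < 3:
            raise ValueError("need >= 3 contour points")


@dataclass
class DecorationMeasure:
    micrograph_id: str
    perimeter: float = np.nan           # um
    vesicles_per_micron: float = np.nan
    decorated_fraction: float = np.nan


def _contour_xy_nm(contour: np.ndarray, scale: float) -> np.ndarray:
    return np.asarray(contour, dtype=float)[:, :2] * scale


def vesicle_diameter(contour: np.ndarray, scale: float, vesicle_id: int = 0) -> VesicleMeasure:
    """Mean polar radius about the point centroid, doubled and scaled to nm."""
    xy = _contour_xy_nm(contour, scale)
    if len(xy) < 3:
        raise ValueError("need >= 3 contour points")
    center = xy.mean(axis=0)
    radii = np.linalg.norm(xy - center, axis=1)
    if np.max(radii) < 1e-12 or _collinear(xy):
        raise ValueError("contour points are collinear or degenerate")
    return VesicleMeasure(
        vesicle_id=vesicle_id,
        center=(float(center[0]), float(center[1])),
        diameter=float(2.0 * radii.mean()),
        n_points=len(xy),
    )


def _collinear(xy: np.ndarray) -> bool:
    centered = xy - xy.mean(axis=0)
    return np.linalg.matrix_rank(centered, tol=1e-9) < 2


def _closed_ring(xy: np.ndarray) -> LineString:
    if not np.allclose(xy[0], xy[-1]):
        xy = np.vstack([xy, xy[:1]])
    return LineString(xy)


def mito_perimeter(contours: list[np.ndarray], scale: float) -> float:
    """Total closed-polyline length of mitochondrial contours, in um."""
    total_nm = 0.0
    for contour in contours:
        xy = _contour_xy_nm(contour, scale)
        if len(xy) < 3:
            raise ValueError("mitochondrial contour must have >= 3 points")
        total_nm += _closed_ring(xy).length
    return total_nm / 1000.0


def vesicles_per_micron(scene: ContourScene) -> DecorationMeasure:
    """Vesicle contour count per micron of mitochondrial perimeter."""
    mito = scene.mito_contours
    if not mito:
        raise ValueError("scene has no mitochondrial contour")
    perim = mito_perimeter(mito, scene.scale)
    if perim <= 0:
        raise ValueError("zero mitochondrial perimeter")
    return DecorationMeasure(
        micrograph_id=scene.source,
        perimeter=perim,
        vesicles_per_micron=len(scene.vesicle_contours) / perim,
    )


def decorated_fraction(scene: ContourScene, dilation: float = 15.0) -> DecorationMeasure:
    """Fraction of mitochondrial perimeter within ``dilation`` nm of vesicles.

    Each vesicle polygon is offset outward by ``dilation`` (nm); the
    length of the mitochondrial boundary inside the union of the offsets,
    divided by the total boundary length, is the decorated fraction.
    """
    if dilation < 0:
        raise ValueError("dilation must be >= 0")
    mito = scene.mito_contours
    if not mito:
        raise ValueError("scene has no mitochondrial contour")
    rings = [_closed_ring(_contour_xy_nm(c, scene.scale)) for c in mito]
    total = sum(r.length for r in rings)
    if total <= 0:
        raise ValueError("zero mitochondrial perimeter")

    vesicles = scene.vesicle_contours
    measure = DecorationMeasure(
        micrograph_id=scene.source, perimeter=total / 1000.0
    )
    if not vesicles:
        measure.decorated_fraction = 0.0
        return measure

    dilated = []
    for i, contour in enumerate(vesicles):
        xy = _contour_xy_nm(contour, scene.scale)
        poly = Polygon(xy)
        if not poly.is_valid:
            poly = shapely.make_valid(poly)
        buffered = poly.buffer(dilation, quad_segs=32)
        if buffered.is_empty or not buffered.is_valid:
            raise ValueError(f"unresolvable geometry for vesicle {i}")
        dilated.append(buffered)
    union = unary_union(dilated)

    covered = sum(r.intersection(union).length for r in rings)
    measure.decorated_fraction = min(covered / total, 1.0)
    return measure


def measure_scene(
    scene: ContourScene, dilation: float = 15.0
) -> tuple[list[VesicleMeasure], DecorationMeasure]:
    """Per-vesicle diameters plus the per-micrograph decoration statistics."""
    vesicles = [
        vesicle_diameter(c, scene.scale, vesicle_id=i)
        for i, c in enumerate(scene.vesicle_contours)
    ]
    abundance = vesicles_per_micron(scene)
    decoration = decorated_fraction(scene, dilation=dilation)
    abundance.decorated_fraction = decoration.decorated_fraction
    return vesicles, abundance
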