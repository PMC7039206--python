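"""Standalone image statistics: flicker variance and convex-hull dispersal.

Flicker: each frame of a small excerpt is normalized to its own mean and
the per-pixel temporal variance is averaged over the patch — a gain-free
measure of subresolution intensity fluctuation.

Dispersal: the convex-hull area of thresholded marker signal as a
fraction of the cell-mask area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "FlickerResult",
    "DispersalResult",
    "flicker_variance",
    "golgi_dispersal",
    "threshold_signal_points",
]


@dataclass
class FlickerResult:
    variance_map: np.ndarray
    mean_variance: float


@dataclass
class DispersalResult:
    hull_area: float  # um^2
    cell_area: float  # um^2
    dispersal: float
    flags: dict = field(default_factory=dict)


def flicker_variance(stack: np.ndarray, expected_shape: tuple[int, int] | None = (50, 50)) -> FlickerResult:
    """Mean per-pixel temporal variance of mean-normalized frames.

    ``stack`` is (frames, y, x); each frame is divided by its own mean
    before the per-pixel sample variance (ddof=1) is taken over time.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("stack must be (frames>=2, y, x)")
    if expected_shape is not None and stack.shape[1:] != tuple(expected_shape):
        raise ValueError(
            f"patch shape {stack.shape[1:]} != configured {expected_shape}"
        )
    means = stack.mean(axis=(1, 2))
    bad = np.flatnonzero(means <= 0)
    if bad.size:
        raise ValueError(f"frame {bad[0]} has non-positive mean")
    normalized = stack / means[:, None, None]
    variance_map = normalized.var(axis=0, ddof=1)
    return FlickerResult(
        variance_map=variance_map, mean_variance=float(variance_map.mean())
    )


def threshold_signal_points(
    image: np.ndarray, percentile: float = 95.0
) -> np.ndarray:
    """(x, y) pixel coordinates above an intensity percentile."""
    image = np.asarray(image, dtype=float)
    level = np.percentile(image, percentile)
    ys, xs = np.nonzero(image > level)
    return np.column_stack([xs, ys]).astype(float)


def golgi_dispersal(
    signal_points: np.ndarray,
    cell_mask: np.ndarray,
    pixel_size: float = 1.0,
) -> DispersalResult:
    """Convex-hull area of signal points over the cell-mask area.

    ``signal_points`` are (x, y) in pixels, ``cell_mask`` a binary image,
    ``pixel_size`` in um.  Fewer than 3 non-collinear points define a
    dispersal of 0 with a flag.
    """
    cell_mask = np.asarray(cell_mask).astype(bool)
    n_mask = int(cell_mask.sum())
    if n_mask == 0:
        raise ValueError("cell mask is empty")
    cell_area = n_mask * pixel_size**2

    pts = np.asarray(signal_points, dtype=float).reshape(-1, 2)
    try:
        if len(pts) < 3:
            raise QhullError("fewer than 3 points")
        hull = ConvexHull(pts)
        hull_area = hull.volume * pixel_size**2  # 2-D "volume" is area
        flags = {}
    except QhullError:
        hull_area = 0.0
        flags = {"degenerate": "fewer than 3 non-collinear signal points"}
    return DispersalResult(
        hull_area=float(hull_area),
        cell_area=float(cell_area),
        dispersal=float(hull_area / cell_area),
        flags=flags,
    )
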