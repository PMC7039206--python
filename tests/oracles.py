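"""Independent reference implementations used only by the test suite.

These deliberately avoid the package's own code paths: the raster oracle
replaces exact polygon offsetting with dense boundary sampling, and the
prominence oracle replaces the union-find pass with superlevel-set
labeling.
"""

import numpy as np
import shapely
from shapely.geometry import LineString
from skimage.measure import label as cc_label


def raster_decorated_fraction(scene, dilation=15.0, step_nm=0.5):
    """Dense-sampling oracle for the decorated perimeter fraction.

    A perimeter point is decorated when its distance to any (undilated)
    vesicle polygon is <= dilation — the rasterized equivalent of
    intersecting the perimeter with the union of dilated vesicle areas.
    """
    vesicles = [
        shapely.Polygon(c[:, :2] * scene.scale) for c in scene.vesicle_contours
    ]
    covered = 0
    total = 0
    for contour in scene.mito_contours:
        xy = contour[:, :2] * scene.scale
        ring = LineString(np.vstack([xy, xy[:1]]))
        n = max(int(np.ceil(ring.length / step_nm)), 2)
        s = (np.arange(n) + 0.5) / n * ring.length
        pts = shapely.line_interpolate_point(ring, s)
        total += n
        if vesicles:
            dmin = np.min(
                np.stack([shapely.distance(pts, v) for v in vesicles]), axis=0
            )
            covered += int(np.sum(dmin <= dilation))
    return covered / total


def brute_force_maxima(img, prominence):
    """Exhaustive prominence computation on a small distinct-valued image.

    Every strict local maximum's prominence is its height minus the
    highest threshold at which its superlevel component contains a
    strictly higher pixel (the border connects to nothing; the global
    maximum has infinite prominence).  The threshold search exploits
    monotonicity: once the component reaches higher ground it stays
    there, so a binary search over levels suffices.
    """
    img = np.asarray(img, dtype=float)
    assert len(np.unique(img)) == img.size, "oracle needs distinct values"
    h, w = img.shape
    vmax = img.max()
    maxima = []
    for r in range(h):
        for c in range(w):
            value = img[r, c]
            ring = img[max(r - 1, 0):r + 2, max(c - 1, 0):c + 2]
            if ring.max() > value:
                continue  # not a local maximum
            if value == vmax:
                maxima.append((c, r, value, np.inf))
                continue
            levels = np.sort(np.unique(img[img <= value]))  # ascending

            def connects_higher(t):
                comp = cc_label(img >= t, connectivity=2)
                return img[comp == comp[r, c]].max() > value

            if not connects_higher(levels[0]):
                maxima.append((c, r, value, np.inf))
                continue
            lo, hi = 0, len(levels) - 1  # connects at lo, not at hi (= value)
            while hi - lo > 1:
                mid = (lo + hi) // 2
                if connects_higher(levels[mid]):
                    lo = mid
                else:
                    hi = mid
            maxima.append((c, r, value, value - levels[lo]))
    return [(c, r) for c, r, v, p in sorted(maxima, key=lambda x: -x[2])
            if p > prominence]
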