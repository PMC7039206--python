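"""Synthetic-data generators for every input class the pipeline consumes.

Each generator is a pure function of its parameters and a
:class:`SynthConfig` seed, and attaches the ground truth it drew so that
downstream parameter-recovery tests never re-run the generator.

Noise models: additive Gaussian for intensity traces, Poisson for count
images (shot noise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

from invquant.io import (
    MITOCHONDRION,
    VESICLE,
    ContourScene,
    LocalizationImage,
    SceneObject,
    TimedTrace,
)

__all__ = [
    "SynthConfig",
    "gen_rush_trace",
    "gen_exponential_trace",
    "gen_em_scene",
    "gen_localization_image",
    "spots_for_density",
    "gen_flicker_stack",
    "gen_screen_table",
    "ellipse_contour",
]


@dataclass(frozen=True)
class SynthConfig:
    """Shared generator configuration.

    noise_sd is the SD of additive Gaussian noise in the units of the
    generated values (traces are fractions or a.u.); frame_interval is in
    the trace's own time unit (minutes for secretory traces, seconds
    otherwise).
    """

    seed: int = 0
    noise_sd: float = 0.0
    frame_interval: float = 1.0
    n_samples: int = 30

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _logistic(t, y0, ymax, x_half, n):
    t = np.asarray(t, dtype=float)
    out = np.full_like(t, y0, dtype=float)
    pos = t > 0
    out[pos] = y0 + (ymax - y0) / (1.0 + (x_half / t[pos]) ** n)
    return out


def gen_rush_trace(
    y0: float,
    ymax: float,
    x_half: float,
    n: float,
    decay_slope: float,
    cfg: SynthConfig,
) -> TimedTrace:
    """Logistic organelle-fill rise followed by a linear decline.

    The rise follows ``y0 + (ymax-y0)/(1+(x_half/t)^n)`` until the curve
    reaches 0.99*ymax; from that time on the trace declines linearly with
    ``decay_slope`` (fraction/minute, <= 0).  Times are minutes.
    """
    if x_half <= 0 or n <= 0:
        raise ValueError("x_half and n must be positive")
    if not ymax > y0 >= 0:
        raise ValueError("require ymax > y0 >= 0")
    if decay_slope > 0:
        raise ValueError("decay_slope must be <= 0")

    # time at which the logistic reaches 0.99*ymax (requires 0.99*ymax > y0)
    target = 0.99 * ymax
    if target <= y0:
        raise ValueError("0.99*ymax must exceed y0")
    ratio = (ymax - y0) / (target - y0) - 1.0
    t_peak = x_half / ratio ** (1.0 / n)
    y_peak = _logistic(np.array([t_peak]), y0, ymax, x_half, n)[0]

    times = np.arange(cfg.n_samples) * cfg.frame_interval
    values = _logistic(times, y0, ymax, x_half, n)
    after = times > t_peak
    values[after] = y_peak + decay_slope * (times[after] - t_peak)

    rng = cfg.rng()
    noisy = values + rng.normal(0.0, cfg.noise_sd, size=values.shape)

    y_half = 0.5 * (y0 + ymax)
    if decay_slope < 0:
        t_er_pm = t_peak + (y_peak - y_half) / (-decay_slope)
    else:
        t_er_pm = np.nan
    gt = {
        "y0": y0,
        "ymax": ymax,
        "x_half": x_half,
        "n": n,
        "decay_slope": decay_slope,
        "t_peak": t_peak,
        "t_half_er_golgi": x_half,
        "t_half_er_pm": t_er_pm,
        "golgi_transit": t_er_pm - x_half,
        "noiseless": values,
    }
    return TimedTrace(
        times=times, values=noisy, unit="min", meta={"ground_truth": gt}
    )


def gen_exponential_trace(
    baseline: float,
    amplitude: float,
    taus: list[float],
    fractions: list[float],
    bleach_tau: float | None,
    cfg: SynthConfig,
) -> TimedTrace:
    """Mono- or multi-exponential approach to ``baseline + amplitude``.

    ``y(t) = baseline + amplitude * sum_i f_i (1 - exp(-t/tau_i))``; an
    optional photobleaching envelope ``exp(-t/bleach_tau)`` multiplies the
    signal and is emitted as the ``reference`` series.  Times are seconds.
    """
    taus = [float(t) for t in taus]
    fractions = [float(f) for f in fractions]
    if len(taus) != len(fractions):
        raise ValueError("taus and fractions must have equal length")
    if any(t <= 0 for t in taus):
        raise ValueError("all taus must be positive")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")

    times = np.arange(cfg.n_samples) * cfg.frame_interval
    clean = baseline + amplitude * sum(
        f * (1.0 - np.exp(-times / tau)) for f, tau in zip(fractions, taus)
    )
    if bleach_tau is not None:
        if bleach_tau <= 0:
            raise ValueError("bleach_tau must be positive")
        envelope = np.exp(-times / bleach_tau)
    else:
        envelope = np.ones_like(times)

    rng = cfg.rng()
    signal = clean * envelope + rng.normal(0.0, cfg.noise_sd, size=times.shape)
    reference = envelope * (
        1.0 + rng.normal(0.0, cfg.noise_sd, size=times.shape)
    )
    gt = {
        "baseline": baseline,
        "amplitude": amplitude,
        "taus": taus,
        "fractions": fractions,
        "bleach_tau": bleach_tau,
        "noiseless": clean,
    }
    return TimedTrace(
        times=times,
        values=signal,
        unit="s",
        reference=reference,
        meta={"ground_truth": gt},
    )


# ---------------------------------------------------------------------------
# EM scenes
# ---------------------------------------------------------------------------


def ellipse_contour(
    a_nm: float,
    b_nm: float,
    center_nm: tuple[float, float],
    scale: float,
    n_points: int = 200,
    z: float = 0.0,
) -> np.ndarray:
    """Closed elliptical contour in pixel coordinates ((n, 3), z constant)."""
    theta = np.linspace(0.0, 2 * np.pi, n_points, endpoint=False)
    x = (center_nm[0] + a_nm * np.cos(theta)) / scale
    y = (center_nm[1] + b_nm * np.sin(theta)) / scale
    return np.column_stack([x, y, np.full_like(x, z)])


def _circle_contour(center_nm, radius_nm, scale, n_points=24, z=0.0):
    theta = np.linspace(0.0, 2 * np.pi, n_points, endpoint=False)
    x = (center_nm[0] + radius_nm * np.cos(theta)) / scale
    y = (center_nm[1] + radius_nm * np.sin(theta)) / scale
    return np.column_stack([x, y, np.full_like(x, z)])


def gen_em_scene(
    n_vesicles: int,
    diameter_mean: float,
    diameter_sd: float,
    mito_shape: np.ndarray | None,
    capture_fraction: float,
    scale: float,
    cfg: SynthConfig,
    capture_gap: float = 15.0,
    far_gap: float = 100.0,
    max_retries: int = 500,
) -> ContourScene:
    """A 2-D section: one mitochondrial profile decorated with vesicles.

    A ``capture_fraction`` of vesicles is placed with its boundary within
    ``capture_gap`` (15 nm) of the mitochondrial contour; the rest sit at
    least ``far_gap`` (100 nm) away.  Diameters are Normal(mean, sd)
    truncated below at ``2*scale`` nm.  Coordinates are pixels.
    """
    from shapely.geometry import LineString, Point, Polygon

    if diameter_mean <= 0:
        raise ValueError("diameter_mean must be positive")
    if not 0.0 <= capture_fraction <= 1.0:
        raise ValueError("capture_fraction must be in [0, 1]")
    if scale <= 0:
        raise ValueError("scale must be positive")

    if mito_shape is None:
        mito_shape = ellipse_contour(400.0, 200.0, (0.0, 0.0), scale)
    mito_shape = np.asarray(mito_shape, dtype=float)
    mito_nm = mito_shape[:, :2] * scale
    mito_ring = LineString(np.vstack([mito_nm, mito_nm[:1]]))
    mito_poly = Polygon(mito_nm)

    rng = cfg.rng()
    diameters = rng.normal(diameter_mean, diameter_sd, size=n_vesicles)
    diameters = np.maximum(diameters, 2.0 * scale)
    n_captured = int(round(capture_fraction * n_vesicles))

    placed_centers: list[tuple[float, float]] = []
    placed_radii: list[float] = []
    truth_rows = []
    perim = mito_ring.length

    bbox = mito_nm.min(axis=0) - 600.0, mito_nm.max(axis=0) + 600.0

    for i in range(n_vesicles):
        radius = diameters[i] / 2.0
        captured = i < n_captured
        for attempt in range(max_retries):
            if captured:
                # walk out along the local normal from a random perimeter point
                s = rng.uniform(0.0, perim)
                p0 = mito_ring.interpolate(s)
                p1 = mito_ring.interpolate((s + 1.0) % perim)
                tx, ty = p1.x - p0.x, p1.y - p0.y
                norm = np.hypot(tx, ty)
                nx, ny = ty / norm, -tx / norm
                if mito_poly.contains(Point(p0.x + 5.0 * nx, p0.y + 5.0 * ny)):
                    nx, ny = -nx, -ny  # flip to the outward side
                gap = rng.uniform(0.0, capture_gap)
                cx = p0.x + (radius + gap) * nx
                cy = p0.y + (radius + gap) * ny
                center = Point(cx, cy)
                boundary_dist = mito_ring.distance(center) - radius
                if not (-0.5 <= boundary_dist <= capture_gap):
                    continue
                if mito_poly.contains(center):
                    continue
            else:
                cx = rng.uniform(bbox[0][0], bbox[1][0])
                cy = rng.uniform(bbox[0][1], bbox[1][1])
                center = Point(cx, cy)
                if mito_ring.distance(center) - radius < far_gap:
                    continue
                if mito_poly.contains(center):
                    continue
            ok = all(
                np.hypot(cx - px, cy - py) > radius + pr + 2.0
                for (px, py), pr in zip(placed_centers, placed_radii)
            )
            if ok:
                placed_centers.append((cx, cy))
                placed_radii.append(radius)
                truth_rows.append(
                    {
                        "center_nm": (cx, cy),
                        "diameter_nm": diameters[i],
                        "captured": bool(captured),
                    }
                )
                break
        else:
            raise RuntimeError(
                f"vesicle placement failed after {max_retries} retries "
                f"(seed={cfg.seed}, vesicle {i})"
            )

    vesicle_contours = [
        _circle_contour(c, r, scale)
        for c, r in zip(placed_centers, placed_radii)
    ]
    objects = [SceneObject(label=MITOCHONDRION, contours=[mito_shape])]
    if vesicle_contours:
        objects.append(SceneObject(label=VESICLE, contours=vesicle_contours))
    gt = {
        "n_vesicles": n_vesicles,
        "diameter_mean": diameter_mean,
        "diameter_sd": diameter_sd,
        "capture_fraction": capture_fraction,
        "capture_gap_nm": capture_gap,
        "vesicles": truth_rows,
        "diameters_nm": [row["diameter_nm"] for row in truth_rows],
        "mito_perimeter_nm": perim,
    }
    return ContourScene(
        objects=objects, scale=scale, source="synthetic", ground_truth=gt
    )


# ---------------------------------------------------------------------------
# localization images
# ---------------------------------------------------------------------------


def spots_for_density(density_per_10um2: float, field_um: tuple[float, float]) -> int:
    """Number of spots realizing a density given in spots per 10 um^2."""
    area = field_um[0] * field_um[1]
    return int(round(density_per_10um2 * area / 10.0))


def _pixel_integrated_gaussian(shape, center_px, sigma_px, total):
    """Gaussian integrated over pixel areas, summing to ``total``."""
    h, w = shape
    xs = np.arange(w)
    ys = np.arange(h)
    # integral over [i-0.5, i+0.5] of the 1-D normal pdf
    def cell(edges_lo, mu):
        a = (edges_lo - mu) / (np.sqrt(2.0) * sigma_px)
        b = (edges_lo + 1.0 - mu) / (np.sqrt(2.0) * sigma_px)
        return 0.5 * (special.erf(b) - special.erf(a))

    gx = cell(xs - 0.5, center_px[0])
    gy = cell(ys - 0.5, center_px[1])
    return total * np.outer(gy, gx)


def gen_localization_image(
    n_spots: int,
    sigma: float,
    pixel_size: float,
    field: tuple[float, float],
    counts_per_spot: float,
    cfg: SynthConfig,
    poisson_noise: bool = True,
    min_separation_sigmas: float = 6.0,
    max_retries: int = 10000,
) -> LocalizationImage:
    """Field of isolated Gaussian spots as a localization-count image.

    ``sigma`` and ``pixel_size`` are nm, ``field`` is (width, height) um.
    Each spot integrates to ``counts_per_spot`` before optional Poisson
    pixel noise.  Spots are separated by >= 6 sigma (center to center).
    """
    if sigma <= 0 or pixel_size <= 0:
        raise ValueError("sigma and pixel_size must be positive")
    w_px = int(round(field[0] * 1000.0 / pixel_size))
    h_px = int(round(field[1] * 1000.0 / pixel_size))
    min_sep = min_separation_sigmas * sigma  # nm
    margin = 4.0 * sigma  # keep spots clear of the border

    if field[0] * 1000.0 <= 2 * margin or field[1] * 1000.0 <= 2 * margin:
        raise ValueError("field too small for requested sigma")

    rng = cfg.rng()
    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < n_spots:
        if tries > max_retries:
            raise RuntimeError(
                f"field too small to place {n_spots} spots at "
                f"separation {min_sep:.0f} nm (seed={cfg.seed})"
            )
        tries += 1
        cx = rng.uniform(margin, field[0] * 1000.0 - margin)
        cy = rng.uniform(margin, field[1] * 1000.0 - margin)
        if all(np.hypot(cx - px, cy - py) >= min_sep for px, py in centers):
            centers.append((cx, cy))

    image = np.zeros((h_px, w_px), dtype=float)
    sigma_px = sigma / pixel_size
    for cx, cy in centers:
        image += _pixel_integrated_gaussian(
            (h_px, w_px), (cx / pixel_size, cy / pixel_size), sigma_px,
            counts_per_spot,
        )
    if poisson_noise:
        image = rng.poisson(image).astype(float)

    gt = {
        "n_spots": n_spots,
        "sigma_nm": sigma,
        "centers_nm": centers,
        "centers_px": [(cx / pixel_size, cy / pixel_size) for cx, cy in centers],
        "counts_per_spot": counts_per_spot,
        "fwhm_nm": 2.0 * np.sqrt(2.0 * np.log(2.0)) * sigma,
    }
    return LocalizationImage(pixels=image, pixel_size=pixel_size, meta={"ground_truth": gt})


# ---------------------------------------------------------------------------
# flicker stacks
# ---------------------------------------------------------------------------


def gen_flicker_stack(
    mode: str,
    n_frames: int,
    patch: int,
    vesicle_density: float,
    cfg: SynthConfig,
    mean_intensity: float = 200.0,
    pixel_size_um: float = 0.1,
    spot_sigma_px: float = 1.3,
    step_px: float = 1.5,
    shot_noise: bool = True,
) -> tuple[np.ndarray, dict]:
    """A small live-imaging excerpt: uniform field or diffusing dim spots.

    ``"uniform"`` is a constant field; ``"vesicles"`` adds subresolution
    Gaussian spots (``vesicle_density`` per um^2) performing a random walk,
    with the background lowered so the stack mean matches the uniform mode.
    Poisson shot noise applies to both when ``shot_noise``.
    """
    if mode not in ("uniform", "vesicles"):
        raise ValueError(f"unknown mode {mode!r}")
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")

    rng = cfg.rng()
    if mode == "uniform":
        clean = np.full((n_frames, patch, patch), mean_intensity, dtype=float)
        gt = {"mode": mode, "mean_intensity": mean_intensity}
    else:
        area_um2 = (patch * pixel_size_um) ** 2
        n_spots = max(1, int(round(vesicle_density * area_um2)))
        # split the photon budget: half background, half in moving spots
        spot_total = 0.5 * mean_intensity * patch * patch / n_spots
        background = mean_intensity - 0.5 * mean_intensity
        pos = rng.uniform(0, patch, size=(n_spots, 2))
        clean = np.empty((n_frames, patch, patch), dtype=float)
        for f in range(n_frames):
            frame = np.full((patch, patch), background, dtype=float)
            for sx, sy in pos:
                frame += _pixel_integrated_gaussian(
                    (patch, patch), (sx, sy), spot_sigma_px, spot_total
                )
            clean[f] = frame
            pos = pos + rng.normal(0.0, step_px, size=pos.shape)
            pos %= patch  # periodic wrap keeps density constant
        gt = {
            "mode": mode,
            "mean_intensity": mean_intensity,
            "n_spots": n_spots,
            "spot_sigma_px": spot_sigma_px,
            "step_px": step_px,
        }
    stack = rng.poisson(clean).astype(float) if shot_noise else clean
    return stack, gt


# ---------------------------------------------------------------------------
# screen tables
# ---------------------------------------------------------------------------


def gen_screen_table(
    constructs: dict[str, float],
    n_cells: int,
    trials: int,
    cell_sd: float,
    cfg: SynthConfig,
    baseline_mean: float = 100.0,
    baseline_sd: float = 0.3,
):
    """Per-cell pre/post intensity table with group-level fold changes.

    ``constructs`` maps construct name to its true post/pre fold change.
    Each construct gets ``n_cells`` cells split evenly over ``trials``
    trials; ``F_pre`` is lognormal around ``baseline_mean`` and
    ``F_post = F_pre * fold * lognormal(0, cell_sd)``.
    """
    import pandas as pd

    if any(f <= 0 for f in constructs.values()):
        raise ValueError("fold changes must be positive")
    if n_cells < 3:
        raise ValueError("n_cells must be >= 3")
    if trials < 1:
        raise ValueError("trials must be >= 1")

    rng = cfg.rng()
    rows = []
    for construct, fold in constructs.items():
        for i in range(n_cells):
            trial = i % trials + 1
            f_pre = baseline_mean * rng.lognormal(0.0, baseline_sd)
            f_post = f_pre * fold * rng.lognormal(0.0, cell_sd)
            rows.append(
                {
                    "cell_id": f"{construct}_{i}",
                    "construct": construct,
                    "trial": trial,
                    "F_pre": f_pre,
                    "F_post": f_post,
                }
            )
    table = pd.DataFrame(rows)
    gt = {"constructs": dict(constructs), "n_cells": n_cells,
          "trials": trials, "cell_sd": cell_sd}
    table.attrs["ground_truth"] = gt
    return table
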