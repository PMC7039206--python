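"""Rerouting and photobleaching-recovery trace analysis.

ROI aggregation over image stacks, the simple-ratio photobleach
correction, recovery-curve normalization, and single/double exponential
fitting.  The double-exponential model is

    y(t) = M * [f * (1 - exp(-t/tau_fast)) + (1 - f) * (1 - exp(-t/tau_slow))]

with the mobile fraction M and fraction_slow = 1 - f; tau_fast <= tau_slow
is enforced by reordering after the fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, curve_fit

from invquant.io import TimedTrace
from invquant.rush import FitError

__all__ = [
    "ExpFitResult",
    "roi_mean_traces",
    "bleach_correct_simple_ratio",
    "fit_single_exponential",
    "normalize_frap",
    "fit_double_exponential",
]


@dataclass
class ExpFitResult:
    """Exponential fit parameters for a rerouting or recovery trace."""

    baseline: float = np.nan
    amplitude: float = np.nan
    tau: float = np.nan              # single-exponential time constant
    tau_fast: float = np.nan         # double-exponential components
    tau_slow: float = np.nan
    fraction_slow: float = np.nan
    mobile_fraction: float = np.nan  # recovery traces only
    t_half: float = np.nan           # recovery traces only
    chi2: float = np.nan             # RSS / (N - k)
    converged: bool = False
    flags: dict = field(default_factory=dict)


def roi_mean_traces(
    stack: np.ndarray,
    mito_rois: list[tuple[int, int, int, int]],
    cyto_rois: list[tuple[int, int, int, int]],
    times: np.ndarray | None = None,
    unit: str = "s",
) -> tuple[TimedTrace, TimedTrace]:
    """Per-frame mean intensity over two ROI sets.

    ROIs are (x, y, width, height) boxes in pixels; each must lie within
    the frame.  Returns (mitochondrial trace, cytoplasmic trace).
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("stack must be (frames, y, x)")
    n_frames, h, w = stack.shape
    if times is None:
        times = np.arange(n_frames, dtype=float)

    def roi_means(rois, name):
        if not rois:
            raise ValueError(f"need at least one {name} ROI")
        per_roi = []
        for i, (x, y, rw, rh) in enumerate(rois):
            if x < 0 or y < 0 or x + rw > w or y + rh > h or rw <= 0 or rh <= 0:
                raise ValueError(f"{name} ROI {i} out of bounds: {(x, y, rw, rh)}")
            per_roi.append(stack[:, y:y + rh, x:x + rw].mean(axis=(1, 2)))
        return np.mean(per_roi, axis=0)

    mito = TimedTrace(times=times, values=roi_means(mito_rois, "mito"), unit=unit)
    cyto = TimedTrace(times=times, values=roi_means(cyto_rois, "cyto"), unit=unit)
    return mito, cyto


def bleach_correct_simple_ratio(trace: TimedTrace, reference: TimedTrace) -> TimedTrace:
    """Simple-ratio photobleach correction anchored at the first frame.

    corrected(t) = trace(t) * reference(t0) / reference(t).
    """
    if len(trace) != len(reference):
        raise ValueError("trace and reference must have equal length")
    ref = reference.values
    if np.any(ref <= 0):
        raise ValueError("reference must be positive everywhere")
    corrected = trace.values * ref[0] / ref
    return TimedTrace(times=trace.times, values=corrected, unit=trace.unit,
                      meta=dict(trace.meta))


def _single_model(t, baseline, amplitude, tau):
    return baseline + amplitude * (1.0 - np.exp(-t / tau))


def fit_single_exponential(trace: TimedTrace, t_event: float = 0.0) -> ExpFitResult:
    """Fit ``baseline + amplitude * (1 - exp(-(t - t_event)/tau))``.

    The amplitude sign is free, so decaying traces fit too.  Only samples
    at t >= t_event enter the fit.  chi2 is RSS / (N - 3).
    """
    mask = trace.times >= t_event
    t = trace.times[mask] - t_event
    y = trace.values[mask]
    if len(t) < 6:
        raise ValueError("need >= 6 samples after t_event")

    amp0 = float(y[-1] - y[0])
    result = ExpFitResult()
    if abs(amp0) < 1e-12 and np.ptp(y) < 1e-12:
        result.flags["degenerate"] = "zero amplitude; tau unidentifiable"
        result.baseline = float(y[0])
        result.amplitude = 0.0
        return result

    span = t[-1] - t[0]
    p0 = [float(y[0]), amp0, max(span / 5.0, 1e-3)]
    try:
        popt, _ = curve_fit(
            _single_model, t, y, p0=p0,
            bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"single-exponential fit failed: {exc}")
    resid = y - _single_model(t, *popt)
    result.baseline, result.amplitude, result.tau = map(float, popt)
    result.chi2 = float(resid @ resid) / max(len(t) - 3, 1)
    result.converged = True
    return result


def normalize_frap(
    frap_roi: TimedTrace,
    whole_cell: TimedTrace,
    background: TimedTrace,
    bleach_index: int,
) -> TimedTrace:
    """Background-subtract, ratio to the whole cell, and rescale to [0, 1].

    r(t) = (frap - background) / (whole_cell - background), then scaled so
    r(bleach_index) = 0 and the mean of the first five frames = 1.
    """
    n = len(frap_roi)
    if len(whole_cell) != n or len(background) != n:
        raise ValueError("series must be aligned and of equal length")
    if not 5 <= bleach_index < n:
        raise ValueError("need >= 5 pre-bleach frames")
    denom = whole_cell.values - background.values
    bad = np.flatnonzero(denom <= 0)
    if bad.size:
        raise ValueError(f"whole_cell <= background at frame {bad[0]}")
    r = (frap_roi.values - background.values) / denom

    pre = r[:5].mean()
    post = r[bleach_index]
    if abs(pre - post) < 1e-12:
        raise ValueError(
            "degenerate scaling: pre-bleach mean equals bleach value "
            "(no bleach event?)"
        )
    scaled = (r - post) / (pre - post)
    meta = dict(frap_roi.meta)
    meta["bleach_index"] = bleach_index
    return TimedTrace(times=frap_roi.times, values=scaled,
                      unit=frap_roi.unit, meta=meta)


def _double_model(t, mobile, f_fast, tau_fast, tau_slow):
    return mobile * (
        f_fast * (1.0 - np.exp(-t / tau_fast))
        + (1.0 - f_fast) * (1.0 - np.exp(-t / tau_slow))
    )


def fit_double_exponential(trace: TimedTrace) -> ExpFitResult:
    """Two-process recovery fit of a normalized trace starting at 0.

    Times are measured from the first sample (the bleach frame of the
    normalized recovery segment).  On non-convergence, falls back to a
    single exponential with an explicit flag.  t_half solves
    y(t) = mobile/2 numerically.
    """
    t = trace.times - trace.times[0]
    y = trace.values
    if len(t) < 8:
        raise ValueError("need >= 8 samples for a double-exponential fit")

    plateau = float(np.mean(y[-max(3, len(y) // 10):]))
    span = float(t[-1] - t[0])
    p0 = [max(min(plateau, 1.0), 0.1), 0.3, span / 50.0, span / 3.0]
    bounds = ([0.0, 0.0, 1e-9, 1e-9], [1.05, 1.0, np.inf, np.inf])
    result = ExpFitResult()
    try:
        popt, _ = curve_fit(_double_model, t, y, p0=p0, bounds=bounds,
                            maxfev=50000)
        mobile, f_fast, tau_a, tau_b = map(float, popt)
        if tau_a > tau_b:  # enforce tau_fast <= tau_slow
            tau_a, tau_b = tau_b, tau_a
            f_fast = 1.0 - f_fast
        resid = y - _double_model(t, popt[0], popt[1], popt[2], popt[3])
        result.mobile_fraction = mobile
        result.tau_fast = tau_a
        result.tau_slow = tau_b
        result.fraction_slow = 1.0 - f_fast
        result.chi2 = float(resid @ resid) / max(len(t) - 4, 1)
        result.converged = True

        def half_eq(tt):
            return _double_model(tt, mobile, f_fast, tau_a, tau_b) - mobile / 2.0

        try:
            result.t_half = float(brentq(half_eq, 1e-12, 100.0 * tau_b))
        except ValueError:
            result.flags["t_half"] = "no half-recovery crossing found"
        return result
    except (RuntimeError, ValueError):
        single = fit_single_exponential(trace)
        single.flags["fallback"] = "double-exponential fit did not converge"
        single.mobile_fraction = single.baseline + single.amplitude
        single.tau_fast = single.tau_slow = single.tau
        single.fraction_slow = 1.0
        single.t_half = single.tau * np.log(2.0)
        return single
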