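"""Secretory-transport kinetics from organelle-fill traces.

The Golgi fraction trace is fit in two pieces: a logistic rise
``f(x) = y0 + (ymax - y0) / (1 + (x_half / x)^n)`` over the window from the
start of the trace to two frames past the maximum, and an ordinary
least-squares line ``f(x) = a + b x`` over the declining tail.  Three
half-times follow: t1/2(ER->Golgi) = x_half; t1/2(ER->PM) = the time where
the tail line crosses the logistic half-maximum value (y0+ymax)/2; Golgi
transit = their difference.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from invquant.io import TimedTrace

logger = logging.getLogger("invquant")

__all__ = ["RushFitResult", "golgi_fraction", "fit_logistic", "fit_tail_line",
           "transport_halftimes", "analyze_rush_trace", "logistic_model"]


@dataclass
class RushFitResult:
    """Logistic + tail-line parameters and derived transport half-times."""

    y0: float = np.nan
    ymax: float = np.nan
    x_half: float = np.nan
    n: float = np.nan
    a: float = np.nan
    b: float = np.nan
    t_half_er_golgi: float = np.nan
    t_half_er_pm: float = np.nan
    golgi_transit: float = np.nan
    pm_halftime_defined: bool = False
    fit_diagnostics: dict = field(default_factory=dict)


class FitError(RuntimeError):
    """A least-squares fit failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


def logistic_model(x, y0, ymax, x_half, n):
    x = np.asarray(x, dtype=float)
    return y0 + (ymax - y0) / (1.0 + (x_half / x) ** n)


def golgi_fraction(
    golgi_integrated: np.ndarray,
    cell_integrated: np.ndarray,
    times: np.ndarray,
    unit: str = "min",
) -> TimedTrace:
    """Per-frame ratio of organelle to whole-cell integrated intensity.

    Negative ratios are clipped to 0 with a warning; a zero whole-cell
    intensity is an error naming the frame.
    """
    golgi = np.asarray(golgi_integrated, dtype=float)
    cell = np.asarray(cell_integrated, dtype=float)
    if golgi.shape != cell.shape:
        raise ValueError("golgi and cell series must have equal length")
    bad = np.flatnonzero(cell <= 0)
    if bad.size:
        raise ValueError(f"non-positive cell intensity at frame {bad[0]}")
    frac = golgi / cell
    neg = frac < 0
    if np.any(neg):
        warnings.warn(f"clipped {int(neg.sum())} negative fraction(s) to 0")
        frac = np.where(neg, 0.0, frac)
    return TimedTrace(times=np.asarray(times, dtype=float), values=frac, unit=unit)


def _fit_window(trace: TimedTrace) -> np.ndarray:
    """Indices from the start of the trace to two frames past the maximum."""
    i_max = int(np.argmax(trace.values))
    stop = min(i_max + 2, len(trace) - 1)
    return np.arange(0, stop + 1)


def fit_logistic(trace: TimedTrace, max_restarts: int = 5) -> RushFitResult:
    """Least-squares logistic fit over [start, argmax + 2 frames].

    Samples at t = 0 are excluded (the model is undefined there) and
    logged.  Non-convergence after bounded restarts raises :class:`FitError`.
    """
    idx = _fit_window(trace)
    t = trace.times[idx]
    y = trace.values[idx]
    keep = t > 0
    if not np.all(keep):
        logger.info("excluding %d sample(s) at t<=0 from logistic fit",
                    int((~keep).sum()))
    t, y = t[keep], y[keep]
    if len(t) < 6:
        raise ValueError("need >= 6 samples with t > 0 inside the fit window")

    y0_init = float(y[0])
    ymax_init = float(y.max())
    span = ymax_init - y0_init
    half_level = y0_init + 0.5 * span
    above = np.flatnonzero(y >= half_level)
    x_half_init = float(t[above[0]]) if above.size else float(np.median(t))

    lower = [-np.inf, -np.inf, 1e-9, 1e-6]
    upper = [np.inf, np.inf, np.inf, 50.0]
    last_err: Exception | None = None
    rng = np.random.default_rng(0)
    for restart in range(max_restarts):
        if restart == 0:
            p0 = [y0_init, ymax_init, x_half_init, 4.0]
        else:
            p0 = [
                y0_init,
                ymax_init * rng.uniform(0.8, 1.2),
                x_half_init * rng.uniform(0.5, 2.0),
                rng.uniform(1.0, 10.0),
            ]
        try:
            popt, pcov = curve_fit(
                logistic_model, t, y, p0=p0, bounds=(lower, upper),
                maxfev=20000,
            )
        except (RuntimeError, ValueError) as exc:
            last_err = exc
            continue
        resid = y - logistic_model(t, *popt)
        result = RushFitResult(
            y0=popt[0], ymax=popt[1], x_half=popt[2], n=popt[3],
            fit_diagnostics={
                "rss": float(resid @ resid),
                "converged": True,
                "restarts": restart,
                "n_points": len(t),
            },
        )
        if result.ymax <= result.y0:
            last_err = RuntimeError("degenerate fit: ymax <= y0")
            continue
        return result
    raise FitError(
        f"logistic fit failed after {max_restarts} restarts: {last_err}",
        diagnostics={"n_points": len(t)},
    )


def fit_tail_line(trace: TimedTrace, fit: RushFitResult) -> RushFitResult:
    """OLS line over [argmax frame, last frame]; fills the line block."""
    i_max = int(np.argmax(trace.values))
    t = trace.times[i_max:]
    y = trace.values[i_max:]
    if len(t) < 3:
        raise ValueError("need >= 3 samples after the trace maximum")
    b, a = np.polyfit(t, y, 1)
    fit.a = float(a)
    fit.b = float(b)
    fit.fit_diagnostics["tail_n_points"] = len(t)
    return fit


def transport_halftimes(fit: RushFitResult) -> RushFitResult:
    """Derive the three transport half-times from the two fits.

    t1/2(ER->PM) solves ``a + b t = (y0 + ymax) / 2`` on the declining
    tail; a non-declining tail or a crossing before x_half leaves it
    flagged undefined rather than fabricated.
    """
    if not np.isfinite(fit.x_half) or not np.isfinite(fit.a):
        raise ValueError("logistic and line blocks must both be present")
    fit.t_half_er_golgi = fit.x_half
    y_half = 0.5 * (fit.y0 + fit.ymax)
    if fit.b >= 0:
        fit.pm_halftime_defined = False
        fit.t_half_er_pm = np.nan
        fit.golgi_transit = np.nan
        return fit
    t_pm = (y_half - fit.a) / fit.b
    if t_pm <= fit.x_half:
        fit.pm_halftime_defined = False
        fit.t_half_er_pm = np.nan
        fit.golgi_transit = np.nan
        return fit
    fit.pm_halftime_defined = True
    fit.t_half_er_pm = float(t_pm)
    fit.golgi_transit = float(t_pm - fit.x_half)
    return fit


def analyze_rush_trace(trace: TimedTrace) -> RushFitResult:
    """Full per-cell analysis: logistic fit, tail line, half-times."""
    fit = fit_logistic(trace)
    fit = fit_tail_line(trace, fit)
    return transport_halftimes(fit)
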