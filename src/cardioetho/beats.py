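"""Beat-series extraction from pulsatile arterial pressure.

Systolic peaks are located with a refractory period derived from the maximum
plausible heart rate and a minimum prominence; peak times and values are
refined by parabolic interpolation, so beat timing is sub-sample accurate.
The diastolic minimum is taken between consecutive systoles, and the mean
arterial pressure of a beat is the time-average of the waveform over the
beat's cycle (diastolic onset to next diastolic onset) — not the
DABP + PP/3 estimator.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .core import BeatSeries, InsufficientDataError, Trace

__all__ = ["detect_beats", "artifact_filter", "resample_even"]


def _parabolic_refine(y: np.ndarray, i: int):
    """Vertex of the parabola through samples (i-1, i, i+1); returns
    (fractional index, value).  Falls back to the sample itself at edges."""
    if i <= 0 or i >= y.size - 1:
        return float(i), float(y[i])
    a, b, c = y[i - 1], y[i], y[i + 1]
    denom = a - 2 * b + c
    if denom == 0:
        return float(i), float(b)
    delta = 0.5 * (a - c) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    val = b - 0.25 * (a - c) * delta
    return i + delta, float(val)


def detect_beats(trace: Trace, min_hr_bpm: float = 150.0,
                 max_hr_bpm: float = 600.0,
                 prominence_mmHg: float = 10.0) -> BeatSeries:
    """Extract SABP/DABP/MABP/PI/HR beat-by-beat from an arterial trace.

    Parameters
    ----------
    min_hr_bpm, max_hr_bpm : float
        Plausible heart-rate range; ``max_hr_bpm`` sets the refractory
        period between systolic peaks (60000/max_hr ms).
    prominence_mmHg : float
        Minimum peak prominence, rejects dicrotic notches and noise.
    """
    if trace.duration_s < 2.0:
        raise InsufficientDataError("need at least 2 s of signal")
    x = trace.values
    distance = max(1, int(round(trace.fs_hz * 60.0 / max_hr_bpm)))
    peaks, _ = sps.find_peaks(x, distance=distance, prominence=prominence_mmHg)
    if peaks.size < 2:
        raise InsufficientDataError(
            f"insufficient beats: {peaks.size} systolic peaks found")

    refined = np.array([_parabolic_refine(x, p) for p in peaks])
    beat_times = trace.t0_s + refined[:, 0] / trace.fs_hz
    sabp = refined[:, 1]

    n = peaks.size
    # diastolic onset b[k]: argmin between systole k-1 and systole k;
    # b[0]/b[n] fall back to the trace edges so every beat has a cycle window
    bounds = np.empty(n + 1, dtype=int)
    bounds[0] = 0 if peaks[0] > 0 else peaks[0]
    bounds[n] = x.size
    for k in range(1, n):
        lo, hi = peaks[k - 1] + 1, peaks[k]
        bounds[k] = lo + int(np.argmin(x[lo:hi])) if hi > lo else lo

    dabp = np.empty(n)
    mabp = np.empty(n)
    for k in range(n):
        seg = x[bounds[k]:bounds[k + 1]]
        dabp[k] = seg.min()
        mabp[k] = seg.mean()
    # parabolic value can sit a hair above the cycle max; keep ordering exact
    sabp = np.maximum(sabp, mabp)

    return BeatSeries(beat_times, sabp, dabp, mabp)


def artifact_filter(series: BeatSeries, max_step_pct: float = 50.0,
                    window_beats: int = 11):
    """Remove beats whose PI or SABP deviates more than ``max_step_pct`` %
    from a running median of ``window_beats`` beats.

    Returns ``(filtered, n_removed)``.  Never reorders; the surviving beats
    are a subsequence of the input.
    """
    if series.n == 0:
        raise InsufficientDataError("empty beat series")
    keep = np.ones(series.n, dtype=bool)
    for values, skip_first in ((series.pi_ms, True), (series.sabp_mmHg, False)):
        v = np.asarray(values, float)
        med = _running_median(v, window_beats)
        with np.errstate(invalid="ignore", divide="ignore"):
            dev = np.abs(v - med) / np.abs(med) * 100.0
        bad = dev > max_step_pct
        if skip_first:
            bad[0] = False  # first PI is NaN by convention
        keep &= ~np.nan_to_num(bad, nan=0).astype(bool)
    n_removed = int((~keep).sum())
    return series.take(np.flatnonzero(keep)), n_removed


def _running_median(v: np.ndarray, window: int) -> np.ndarray:
    half = window // 2
    out = np.empty_like(v)
    for i in range(v.size):
        lo, hi = max(0, i - half), min(v.size, i + half + 1)
        seg = v[lo:hi]
        seg = seg[np.isfinite(seg)]
        out[i] = np.median(seg) if seg.size else np.nan
    return out


def resample_even(beat_times_s: np.ndarray, values: np.ndarray,
                  target_hz: float = 10.0, method: str = "cubic"):
    """Interpolate (beat time, value) pairs onto a uniform grid.

    Cubic-spline interpolation by default: with rat heart rates the
    respiratory band reaches a sizable fraction of the beat-sampling
    Nyquist, where linear interpolation attenuates power (sinc^2 roll-off);
    the spline keeps high-band power essentially unbiased.  ``method=
    "linear"`` selects plain linear interpolation (also the fallback below
    4 beats).  Returns ``(grid_times_s, grid_values)``; mean removal is
    left to the spectral stage.
    """
    t = np.asarray(beat_times_s, float)
    v = np.asarray(values, float)
    ok = np.isfinite(t) & np.isfinite(v)
    t, v = t[ok], v[ok]
    if t.size < 2:
        raise InsufficientDataError("need at least 2 beats to resample")
    n = int(np.floor((t[-1] - t[0]) * target_hz)) + 1
    grid = t[0] + np.arange(n) / target_hz
    if method == "linear" or t.size < 4:
        return grid, np.interp(grid, t, v)
    if method != "cubic":
        raise ValueError(f"unknown interpolation method {method!r}")
    from scipy.interpolate import CubicSpline
    return grid, CubicSpline(t, v)(grid)
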