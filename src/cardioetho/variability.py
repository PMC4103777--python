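"""Variance and LF/HF band powers of beat-derived series (SABP, PI).

Spectra come from a Welch-averaged periodogram of the beat series resampled
to a uniform grid (10 Hz default), with per-segment linear detrending and a
Hann taper; the density is scaled so its integral over [0, Nyquist] matches
the series variance (Parseval, within taper bias).  Band edges default to
rat conventions: LF 0.20-0.75 Hz (Mayer-wave/vasomotor), HF 0.75-3.0 Hz
(respiratory); both are configurable and echoed in every summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .beats import resample_even
from .core import BeatSeries, InsufficientDataError, ParameterError

__all__ = ["Band", "SpectralSummary", "DEFAULT_BANDS", "compute_psd",
           "band_power", "variability_summary"]


@dataclass(frozen=True)
class Band:
    name: str
    lo_hz: float
    hi_hz: float

    def __post_init__(self) -> None:
        if not 0 <= self.lo_hz < self.hi_hz:
            raise ParameterError(
                f"band {self.name}: need 0 <= lo < hi, got [{self.lo_hz}, {self.hi_hz}]")


DEFAULT_BANDS = (Band("LF", 0.20, 0.75), Band("HF", 0.75, 3.0))


@dataclass
class SpectralSummary:
    variance: float
    band_powers: dict
    total_power: float
    band_edges: dict
    segment_info: dict = field(default_factory=dict)

    @property
    def lf_power(self) -> float:
        return self.band_powers.get("LF", np.nan)

    @property
    def hf_power(self) -> float:
        return self.band_powers.get("HF", np.nan)


def compute_psd(series: np.ndarray, fs: float, nperseg: int = 512,
                min_duration_s: float = 60.0):
    """One-sided Welch PSD (power density per Hz) of an evenly sampled series.

    The series is mean-removed and each 50%-overlapping Hann-tapered segment
    is linearly detrended.  Returns ``(freqs, psd)``.
    """
    x = np.asarray(series, float)
    if x.size / fs < min_duration_s:
        raise InsufficientDataError(
            f"need >= {min_duration_s:.0f} s of data for spectral analysis, "
            f"got {x.size / fs:.1f} s")
    x = x - x.mean()
    nper = min(nperseg, x.size)
    freqs, psd = sps.welch(x, fs=fs, window="hann", nperseg=nper,
                           noverlap=nper // 2, detrend="linear",
                           scaling="density")
    return freqs, psd


def band_power(freqs: np.ndarray, psd: np.ndarray, band: Band) -> float:
    """Trapezoidal integral of the density over [lo, hi), with linear
    interpolation at the band edges so disjoint bands tile exactly."""
    nyq = freqs[-1]
    if band.hi_hz > nyq + 1e-9 and band.lo_hz > nyq:
        raise ParameterError(f"band {band.name} lies above Nyquist ({nyq} Hz)")
    lo, hi = band.lo_hz, min(band.hi_hz, nyq)
    if hi <= lo:
        return 0.0
    # clip the PSD grid to [lo, hi] with interpolated edge points
    inner = (freqs > lo) & (freqs < hi)
    f_clip = np.concatenate(([lo], freqs[inner], [hi]))
    p_clip = np.interp(f_clip, freqs, psd)
    return float(np.trapezoid(p_clip, f_clip))


def total_power(freqs: np.ndarray, psd: np.ndarray) -> float:
    return float(np.trapezoid(psd, freqs))


def variability_summary(beats: BeatSeries, which: str = "SABP",
                        bands=DEFAULT_BANDS, resample_hz: float = 10.0,
                        nperseg: int = 512,
                        min_duration_s: float = 60.0) -> SpectralSummary:
    """Variance plus band-integrated powers for one beat-derived series.

    ``which`` selects SABP (mmHg^2) or PI (ms^2).  The variance is the
    time-domain sample variance of the resampled series, so it is directly
    comparable with the integrated spectrum.
    """
    key = which.upper()
    if key == "SABP":
        values = beats.sabp_mmHg
    elif key == "PI":
        values = beats.pi_ms
    else:
        raise ParameterError(f"unknown series {which!r}; use 'SABP' or 'PI'")
    grid_t, grid_v = resample_even(beats.beat_times_s, values, resample_hz)
    if grid_v.size / resample_hz < min_duration_s:
        raise InsufficientDataError(
            f"need >= {min_duration_s:.0f} s of beats, have "
            f"{grid_v.size / resample_hz:.1f} s")
    freqs, psd = compute_psd(grid_v, resample_hz, nperseg=nperseg,
                             min_duration_s=min_duration_s)
    powers = {b.name: band_power(freqs, psd, b) for b in bands}
    return SpectralSummary(
        variance=float(np.var(grid_v, ddof=1)),
        band_powers=powers,
        total_power=total_power(freqs, psd),
        band_edges={b.name: (b.lo_hz, b.hi_hz) for b in bands},
        segment_info={"resample_hz": resample_hz, "nperseg": min(nperseg, grid_v.size),
                      "n_samples": int(grid_v.size), "series": key},
    )
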