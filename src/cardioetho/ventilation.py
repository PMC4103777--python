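"""Whole-body barometric plethysmography: f_R, V_T and V_E.

Tidal volume is inferred from chamber-pressure oscillations by the barometric
(Bartlett–Tenney) method: a calibration injection of known volume ``V_K``
produces a pressure deflection ``P_K``; a breath producing deflection ``P_T``
then corresponds to

    V_T = V_K * (P_T / P_K) * F,
    F   = T_A (P_B - P_C) / [ T_A (P_B - P_C) - T_C (P_B - P_A) ]

where ``T_A`` is the animal's body temperature, ``T_C`` the chamber air
temperature (both Kelvin), ``P_B`` barometric pressure, ``P_A`` water-vapor
pressure at body temperature and ``P_C`` at chamber temperature (all mmHg).
Respiratory oscillations during movement/grooming epochs are excluded from
analysis, and the breathing rate is computed on the retained time only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .core import InsufficientDataError, ParameterError, Trace

__all__ = [
    "CalibRecord", "ChamberConditions", "VentilationResult",
    "saturation_vp_mmHg", "correction_factor", "detect_breaths",
    "tidal_volume", "ventilation_summary",
]


def saturation_vp_mmHg(T_K: float, rh: float = 1.0) -> float:
    """Saturated water-vapor pressure (mmHg) at temperature ``T_K`` (Kelvin),
    scaled by relative humidity ``rh`` (0-1).  Magnus approximation."""
    t_c = T_K - 273.15
    e_hpa = 6.1094 * np.exp(17.625 * t_c / (t_c + 243.04))
    return float(rh * e_hpa * 0.750062)


@dataclass
class CalibRecord:
    """Known-volume calibration injection and the deflection it produced."""

    V_K_mL: float
    P_K: float          # chamber-pressure deflection, same units as the trace
    time_s: float = 0.0

    def __post_init__(self) -> None:
        if self.V_K_mL <= 0 or self.P_K <= 0:
            raise ParameterError("calibration volume and deflection must be > 0")


@dataclass
class ChamberConditions:
    """Temperatures, pressures and body mass entering the barometric formula."""

    T_A_K: float = 310.15          # rat body temperature
    T_C_K: float = 298.15          # chamber air temperature
    P_B_mmHg: float = 760.0        # barometric pressure
    P_A_mmHg: float = None         # type: ignore[assignment]
    P_C_mmHg: float = None         # type: ignore[assignment]
    body_mass_kg: float = 0.3
    chamber_rh: float = 0.5        # used only when P_C is derived

    def __post_init__(self) -> None:
        if self.T_A_K <= 273 or self.T_C_K <= 273:
            raise ParameterError("temperatures must be above 273 K")
        if self.body_mass_kg <= 0:
            raise ParameterError("body mass must be positive")
        if self.P_A_mmHg is None:
            self.P_A_mmHg = saturation_vp_mmHg(self.T_A_K)  # airways saturated
        if self.P_C_mmHg is None:
            self.P_C_mmHg = saturation_vp_mmHg(self.T_C_K, rh=self.chamber_rh)
        if self.P_B_mmHg <= max(self.P_A_mmHg, self.P_C_mmHg):
            raise ParameterError("barometric pressure must exceed vapor pressures")


@dataclass
class VentilationResult:
    fR_cpm: float
    V_T_mL_per_kg: float
    V_E_mL_per_kg_min: float
    n_breaths: int
    excluded_time_s: float
    mean_deflection: float = np.nan
    correction_factor: float = np.nan


def correction_factor(cond: ChamberConditions) -> float:
    """Barometric correction factor F; raises if chamber conditions make the
    denominator non-positive (no thermal contrast between animal and chamber)."""
    num = cond.T_A_K * (cond.P_B_mmHg - cond.P_C_mmHg)
    den = num - cond.T_C_K * (cond.P_B_mmHg - cond.P_A_mmHg)
    if den <= 0:
        raise ParameterError("non-physical chamber conditions: F denominator <= 0")
    return num / den


def tidal_volume(mean_deflection: float, calib: CalibRecord,
                 cond: ChamberConditions, per_kg: bool = True) -> float:
    """V_T from a mean per-breath deflection P_T.  Linear in both P_T and V_K.

    Returns mL/kg by default (``per_kg=False`` for absolute mL).
    """
    if mean_deflection < 0:
        raise ParameterError("deflection must be non-negative")
    F = correction_factor(cond)
    v_t_mL = calib.V_K_mL * (mean_deflection / calib.P_K) * F
    return v_t_mL / cond.body_mass_kg if per_kg else v_t_mL


def _merge_epochs(epochs: Sequence[tuple]) -> list:
    if not epochs:
        return []
    eps = sorted((float(a), float(b)) for a, b in epochs)
    merged = [list(eps[0])]
    for a, b in eps[1:]:
        if a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [tuple(m) for m in merged]


def detect_breaths(trace: Trace, exclusion_epochs: Sequence[tuple] = (),
                   band_hz: tuple = (0.5, 15.0)):
    """Breath cycles from a chamber-pressure trace.

    The mean-removed trace is band-limited to ``band_hz`` and cycles are
    delimited by rising zero-crossings.  Cycles overlapping any exclusion
    epoch (absolute times, half-open) are dropped.  Returns
    ``(onset_times_s, deflections)`` where deflection is the per-cycle
    peak-to-trough excursion of the filtered signal.
    """
    epochs = _merge_epochs(exclusion_epochs)
    excluded = sum(min(b, trace.t0_s + trace.duration_s) - max(a, trace.t0_s)
                   for a, b in epochs
                   if b > trace.t0_s and a < trace.t0_s + trace.duration_s)
    if trace.duration_s - excluded < 10.0:
        raise InsufficientDataError(
            "fewer than 10 s of signal remain after exclusions")

    x = trace.values - trace.values.mean()
    nyq = trace.fs_hz / 2.0
    hi = min(band_hz[1], 0.9 * nyq)
    sos = sps.butter(4, [band_hz[0] / nyq, hi / nyq], btype="band", output="sos")
    xf = sps.sosfiltfilt(sos, x)

    rising = np.flatnonzero((xf[:-1] < 0) & (xf[1:] >= 0)) + 1
    if rising.size < 2:
        raise InsufficientDataError("no respiratory cycles detected")

    t = trace.times()
    onsets, durations, deflections = [], [], []
    for i0, i1 in zip(rising[:-1], rising[1:]):
        c0, c1 = t[i0], t[i1]
        if any(c0 < b and c1 > a for a, b in epochs):
            continue
        seg = xf[i0:i1]
        onsets.append(c0)
        durations.append(c1 - c0)
        deflections.append(float(seg.max() - seg.min()))
    if not onsets:
        raise InsufficientDataError("all respiratory cycles excluded")
    return np.asarray(onsets), np.asarray(deflections), np.asarray(durations)


def ventilation_summary(trace: Trace, calib: CalibRecord,
                        cond: ChamberConditions,
                        exclusion_epochs: Sequence[tuple] = (),
                        statistic: str = "mean") -> VentilationResult:
    """f_R, V_T and V_E for one analysis window.

    f_R is breaths per minute of *retained* time — the summed duration of
    the analyzed (non-excluded, complete) cycles, so partial cycles at the
    window edges do not bias the rate; V_T comes from the mean (or median)
    per-cycle deflection; V_E = f_R x V_T exactly.
    """
    epochs = _merge_epochs(exclusion_epochs)
    onsets, deflections, durations = detect_breaths(trace, epochs)
    retained = float(durations.sum())
    fr = 60.0 * onsets.size / retained
    agg = np.median if statistic == "median" else np.mean
    p_t = float(agg(deflections))
    v_t = tidal_volume(p_t, calib, cond)
    return VentilationResult(
        fR_cpm=fr,
        V_T_mL_per_kg=v_t,
        V_E_mL_per_kg_min=fr * v_t,
        n_breaths=int(onsets.size),
        excluded_time_s=trace.duration_s - retained,
        mean_deflection=p_t,
        correction_factor=correction_factor(cond),
    )
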