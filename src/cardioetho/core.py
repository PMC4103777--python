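"""Core containers shared across the pipeline.

Units are fixed repository-wide: pressure in mmHg, intervals in ms, time in
seconds.  A :class:`Trace` is any uniformly sampled physiological signal
(pulsatile arterial pressure, plethysmograph chamber pressure); a
:class:`BeatSeries` is the beat-domain view derived from an arterial pressure
trace (systolic/diastolic/mean pressures, pulse interval, heart rate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ParameterError(ValueError):
    """Invalid simulation or analysis parameters."""


class InsufficientDataError(ValueError):
    """Not enough signal or beats to run the requested analysis."""


@dataclass
class Trace:
    """A uniformly sampled signal.

    Parameters
    ----------
    values : ndarray
        Samples, finite floats (mmHg for pressure signals).
    fs_hz : float
        Sampling rate in Hz.
    t0_s : float
        Time of the first sample, in seconds.
    units : str
        Free-text unit label carried through to outputs.
    """

    values: np.ndarray
    fs_hz: float
    t0_s: float = 0.0
    units: str = "mmHg"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.fs_hz <= 0:
            raise ParameterError("fs_hz must be positive")
        if self.values.ndim != 1:
            raise ParameterError("Trace values must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("Trace values must be finite")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return self.n / self.fs_hz

    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n) / self.fs_hz

    def segment(self, start_s: float, end_s: float) -> "Trace":
        """Half-open time slice [start_s, end_s) as a new Trace."""
        i0 = max(0, int(np.ceil((start_s - self.t0_s) * self.fs_hz)))
        i1 = min(self.n, int(np.ceil((end_s - self.t0_s) * self.fs_hz)))
        if i1 <= i0:
            raise InsufficientDataError(
                f"empty segment [{start_s}, {end_s}) for trace starting at "
                f"{self.t0_s} s with duration {self.duration_s:.1f} s"
            )
        return Trace(self.values[i0:i1], self.fs_hz,
                     t0_s=self.t0_s + i0 / self.fs_hz, units=self.units)

    def to_csv(self, path) -> None:
        df = pd.DataFrame({"time_s": self.times(), "value": self.values})
        df.to_csv(path, index=False, float_format="%.4f")

    @classmethod
    def from_csv(cls, path, units: str = "mmHg") -> "Trace":
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy(float)
        if t.size < 2:
            raise InsufficientDataError(f"trace {path} has fewer than 2 samples")
        dt = np.diff(t)
        fs = 1.0 / np.median(dt)
        return cls(df["value"].to_numpy(float), fs_hz=fs, t0_s=float(t[0]),
                   units=units)


@dataclass
class BeatSeries:
    """Per-beat systolic/diastolic/mean pressure and pulse interval.

    Conventions
    -----------
    * ``pi_ms[n]`` is the interval *ending* at beat n (systole-to-systole);
      the first beat has no preceding systole and carries NaN.
    * ``hr_bpm = 60000 / pi_ms`` beat-by-beat.
    """

    beat_times_s: np.ndarray
    sabp_mmHg: np.ndarray
    dabp_mmHg: np.ndarray
    mabp_mmHg: np.ndarray
    pi_ms: np.ndarray = field(default=None)  # type: ignore[assignment]
    hr_bpm: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.beat_times_s = np.asarray(self.beat_times_s, dtype=float)
        self.sabp_mmHg = np.asarray(self.sabp_mmHg, dtype=float)
        self.dabp_mmHg = np.asarray(self.dabp_mmHg, dtype=float)
        self.mabp_mmHg = np.asarray(self.mabp_mmHg, dtype=float)
        if self.pi_ms is None:
            pi = np.full(self.beat_times_s.size, np.nan)
            pi[1:] = np.diff(self.beat_times_s) * 1000.0
            self.pi_ms = pi
        else:
            self.pi_ms = np.asarray(self.pi_ms, dtype=float)
        if self.hr_bpm is None:
            with np.errstate(divide="ignore", invalid="ignore"):
                self.hr_bpm = 60000.0 / self.pi_ms
        else:
            self.hr_bpm = np.asarray(self.hr_bpm, dtype=float)
        if np.any(np.diff(self.beat_times_s) <= 0):
            raise ParameterError("beat times must be strictly increasing")

    @property
    def n(self) -> int:
        return self.beat_times_s.size

    def __len__(self) -> int:
        return self.n

    def take(self, idx: np.ndarray) -> "BeatSeries":
        """Subset by index without recomputing intervals (gaps keep their PI)."""
        return BeatSeries(self.beat_times_s[idx], self.sabp_mmHg[idx],
                          self.dabp_mmHg[idx], self.mabp_mmHg[idx],
                          self.pi_ms[idx], self.hr_bpm[idx])

    def window(self, start_s: float, end_s: float) -> "BeatSeries":
        mask = (self.beat_times_s >= start_s) & (self.beat_times_s < end_s)
        if not mask.any():
            raise InsufficientDataError(
                f"no beats in window [{start_s}, {end_s})")
        return self.take(np.flatnonzero(mask))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "beat_time_s": self.beat_times_s,
            "sabp": self.sabp_mmHg,
            "dabp": self.dabp_mmHg,
            "mabp": self.mabp_mmHg,
            "pi_ms": self.pi_ms,
            "hr_bpm": self.hr_bpm,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.4f")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BeatSeries":
        return cls(df["beat_time_s"].to_numpy(float),
                   df["sabp"].to_numpy(float),
                   df["dabp"].to_numpy(float),
                   df["mabp"].to_numpy(float),
                   df["pi_ms"].to_numpy(float),
                   df["hr_bpm"].to_numpy(float))

    @classmethod
    def from_csv(cls, path) -> "BeatSeries":
        return cls.from_frame(pd.read_csv(path))


@dataclass
class Ethogram:
    """Ordered, time-stamped behavioral events for one observation session."""

    events: pd.DataFrame  # columns: behavior_code, onset_s, duration_s
    session_s: float
    animal_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        ev = self.events
        required = {"behavior_code", "onset_s", "duration_s"}
        if not required.issubset(ev.columns):
            raise ParameterError(f"ethogram needs columns {sorted(required)}")
        onsets = ev["onset_s"].to_numpy(float)
        if onsets.size and np.any(np.diff(onsets) < 0):
            raise ParameterError("ethogram onsets must be nondecreasing")

    @property
    def n_events(self) -> int:
        return len(self.events)

    def to_csv(self, path) -> None:
        self.events.to_csv(path, index=False, float_format="%.3f")

    @classmethod
    def from_csv(cls, path, session_s: float = 3600.0,
                 animal_id: str = "", group: str = "") -> "Ethogram":
        return cls(pd.read_csv(path), session_s=session_s,
                   animal_id=animal_id, group=group)
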