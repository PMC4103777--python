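"""Spontaneous baroreflex sensitivity by the sequence method.

The sequence method scans the beat series for runs of >= ``min_len``
consecutive beats in which systolic pressure and pulse interval change
concordantly beat-to-beat (both rising = UP sequence, both falling = DOWN),
each step exceeding the thresholds ``d_sabp`` (mmHg) and ``d_pi`` (ms).
Within each accepted run, the slope of the PI-vs-SABP regression (ms/mmHg)
estimates baroreflex gain; a run is accepted only if its Pearson correlation
reaches ``r_min``.  A lag of 1 beat (PI of beat n+1 paired with SABP of
beat n) is the rat default.  Counts are reported per 10,000 analyzed beats.

Defaults (d_sabp = 1 mmHg, d_pi = 1 ms, min_len = 3 beats, lag = 1,
r_min = 0.85) follow common sequence-method practice and are echoed in
every report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as spstats

from .core import BeatSeries, InsufficientDataError

__all__ = ["BaroSequence", "BaroReport", "detect_sequences", "compute_brs",
           "brs_report"]


@dataclass
class BaroSequence:
    start_index: int            # index of the first beat (SABP side)
    length: int                 # number of beats in the run
    direction: str              # "UP" | "DOWN"
    slope_ms_per_mmHg: float
    r: float


@dataclass
class BaroReport:
    n_up_per_10k: float
    n_down_per_10k: float
    mean_slope_up: float
    mean_slope_down: float
    brs_all: float
    n_beats_analyzed: int
    n_up: int = 0
    n_down: int = 0
    no_sequences: bool = False
    params: dict = field(default_factory=dict)


def _paired(beats: BeatSeries, lag_beats: int):
    """SABP paired with PI shifted by ``lag_beats``.  A NaN PI (the first
    beat, by convention) yields NaN differences, which cannot join a run."""
    s = beats.sabp_mmHg
    p = beats.pi_ms
    n = s.size
    if lag_beats > 0:
        return s[:n - lag_beats], p[lag_beats:], 0
    return s, p, 0


def detect_sequences(beats: BeatSeries, d_sabp_mmHg: float = 1.0,
                     d_pi_ms: float = 1.0, min_len: int = 3,
                     lag_beats: int = 1, r_min: float = 0.85):
    """Find all maximal UP/DOWN baroreflex sequences in a beat series."""
    if beats.n < min_len + lag_beats + 1:
        raise InsufficientDataError(
            f"need at least {min_len + lag_beats + 1} beats, have {beats.n}")
    sp, pp, offset = _paired(beats, lag_beats)
    ds = np.diff(sp)
    dp = np.diff(pp)
    with np.errstate(invalid="ignore"):
        up = (ds >= d_sabp_mmHg) & (dp >= d_pi_ms)
        down = (ds <= -d_sabp_mmHg) & (dp <= -d_pi_ms)

    sequences = []
    for mask, direction in ((up, "UP"), (down, "DOWN")):
        for i0, i1 in _maximal_runs(mask, min_len - 1):
            # run of diffs [i0, i1) -> beats i0 .. i1 in the paired arrays
            xs = sp[i0:i1 + 1]
            ys = pp[i0:i1 + 1]
            slope, _, r, _, _ = spstats.linregress(xs, ys)
            if r >= r_min:
                sequences.append(BaroSequence(
                    start_index=i0 + offset, length=i1 - i0 + 1,
                    direction=direction, slope_ms_per_mmHg=float(slope),
                    r=float(r)))
    sequences.sort(key=lambda s: s.start_index)
    return sequences


def _maximal_runs(mask: np.ndarray, min_run: int):
    """(start, end) index pairs of maximal True runs of length >= min_run."""
    runs = []
    i = 0
    n = mask.size
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            if j - i + 1 >= min_run:
                runs.append((i, j + 1))  # diffs i..j -> beats i..j+1
            i = j + 1
        else:
            i += 1
    return runs


def compute_brs(sequences, n_beats: int, params: dict | None = None) -> BaroReport:
    """Summarize sequences into counts per 10,000 beats and mean slopes.

    With no accepted sequences the slope fields are NaN and the report is
    flagged ``no_sequences`` rather than raising.
    """
    if n_beats <= 0:
        raise InsufficientDataError("n_beats must be positive")
    ups = [s.slope_ms_per_mmHg for s in sequences if s.direction == "UP"]
    downs = [s.slope_ms_per_mmHg for s in sequences if s.direction == "DOWN"]
    alls = ups + downs
    scale = 10000.0 / n_beats
    return BaroReport(
        n_up_per_10k=len(ups) * scale,
        n_down_per_10k=len(downs) * scale,
        mean_slope_up=float(np.mean(ups)) if ups else np.nan,
        mean_slope_down=float(np.mean(downs)) if downs else np.nan,
        brs_all=float(np.mean(alls)) if alls else np.nan,
        n_beats_analyzed=int(n_beats),
        n_up=len(ups), n_down=len(downs),
        no_sequences=not alls,
        params=dict(params or {}),
    )


def brs_report(beats: BeatSeries, **kwargs) -> BaroReport:
    """Convenience: detect sequences and summarize in one call."""
    seqs = detect_sequences(beats, **kwargs)
    return compute_brs(seqs, beats.n, params=kwargs)
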