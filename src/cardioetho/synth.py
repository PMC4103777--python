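"""Synthetic cardiorespiratory and behavioral recordings with known truth.

Every generator is a pure function of its parameters and seed, and returns
ground truth alongside the rendered signal, so each downstream stage
(beat detection, spectral analysis, sequence-method baroreflex, barometric
ventilation, grooming scoring) can be verified by construction.

The arterial-pressure model is beat-domain: systolic pressure of beat n is

    S_n = SABP + offset(t_n) + A_LF sin(2 pi f_LF t_n)
                             + A_resp sin(2 pi f_resp t_n) + eps_n

(Mayer-wave and respiratory modulation plus white per-beat noise), and the
pulse interval obeys a lagged linear baroreflex feed-forward

    PI_{n+1} = PI_mean(t) + G (S_{n+1-lag} - SABP_ref(t)) + eta_n

with gain G in ms/mmHg.  Each cycle is rendered as an exponential decay from
systole to diastole (70% of PI) followed by a raised-cosine upstroke (30%)
peaking exactly at the next beat time.

Baseline levels default to rat-typical values (HR 360 bpm, SABP 125 /
DABP 85 mmHg, f_R 100 cpm); these are modelling assumptions, not reported
measurements.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import Ethogram, ParameterError, Trace
from .ethology import GROOMING_CODES, REPERTOIRE
from .ventilation import CalibRecord, ChamberConditions

__all__ = [
    "CardioSimParams", "PlethSimParams", "EthoSimParams", "AnimalRecord",
    "generate_pap", "generate_pleth", "generate_ethogram", "generate_cohort",
    "default_transition_matrix", "apply_grooming_multiplier",
    "stationary_occupancy", "DEFAULT_GROUP_EFFECTS", "STUDY_DESIGN",
]

Profile = Sequence[tuple]  # [(time_s, offset)] piecewise-linear breakpoints


def _profile_fn(profile: Profile | None):
    if not profile:
        return lambda t: 0.0
    pts = sorted((float(a), float(b)) for a, b in profile)
    xs = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])
    return lambda t: float(np.interp(t, xs, ys))


def _profile_array(profile: Profile | None, ts: np.ndarray) -> np.ndarray:
    if not profile:
        return np.zeros_like(ts)
    pts = sorted((float(a), float(b)) for a, b in profile)
    return np.interp(ts, [p[0] for p in pts], [p[1] for p in pts])


# --------------------------------------------------------------------------
# arterial pressure
# --------------------------------------------------------------------------

@dataclass
class CardioSimParams:
    duration_s: float = 600.0
    fs_hz: float = 250.0
    hr_bpm: float = 360.0
    sabp_mmHg: float = 125.0
    dabp_mmHg: float = 85.0
    lf_hz: float = 0.4
    lf_amp_mmHg: float = 3.0
    resp_hz: float = 1.5
    resp_amp_mmHg: float = 2.0
    baro_gain_ms_per_mmHg: float = 1.5
    baro_lag_beats: int = 1
    noise_sd_mmHg: float = 1.0
    noise_sd_ms: float = 1.0
    seed: int = 0
    t0_s: float = 0.0
    map_offset_profile: Profile | None = None   # added to S and D (ramps MABP)
    hr_offset_profile: Profile | None = None    # added to hr_bpm (bpm)

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ParameterError("duration_s must be positive")
        if self.fs_hz < 100:
            raise ParameterError("fs_hz must be >= 100 Hz for beat rendering")
        if self.sabp_mmHg <= self.dabp_mmHg:
            raise ParameterError("systolic must exceed diastolic pressure")
        if self.hr_bpm <= 0:
            raise ParameterError("hr_bpm must be positive")
        if self.baro_gain_ms_per_mmHg < 0:
            raise ParameterError("baroreflex gain must be >= 0")
        if self.baro_lag_beats < 0:
            raise ParameterError("baro_lag_beats must be >= 0")


def generate_pap(params: CardioSimParams):
    """Simulate a pulsatile arterial pressure trace.

    Returns ``(trace, truth)`` where ``truth`` is the per-beat ground-truth
    table (beat_time_s, sabp, dabp, pi_ms) the waveform was rendered from.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    map_off = _profile_fn(p.map_offset_profile)
    hr_off = _profile_fn(p.hr_offset_profile)

    t_end = p.t0_s + p.duration_s
    two_pi = 2 * np.pi
    times, sabp, dabp, pi_ms = [], [], [], []
    t = p.t0_s
    lag = p.baro_lag_beats
    n = 0
    while t < t_end + 1.0:
        off = map_off(t)
        eps = rng.normal(0.0, p.noise_sd_mmHg) if p.noise_sd_mmHg > 0 else 0.0
        s = (p.sabp_mmHg + off
             + p.lf_amp_mmHg * np.sin(two_pi * p.lf_hz * t)
             + p.resp_amp_mmHg * np.sin(two_pi * p.resp_hz * t) + eps)
        d = p.dabp_mmHg + off
        times.append(t)
        sabp.append(s)
        dabp.append(d)
        # interval to the next beat: baroreflex feed-forward of a past systole
        j = min(n + 1 - lag, n)
        s_dev = sabp[j] - (p.sabp_mmHg + map_off(times[j])) if j >= 0 else 0.0
        pi_mean = 60000.0 / (p.hr_bpm + hr_off(t))
        pi_next = (pi_mean + p.baro_gain_ms_per_mmHg * s_dev
                   + (rng.normal(0.0, p.noise_sd_ms) if p.noise_sd_ms > 0 else 0.0))
        pi_next = max(pi_next, 0.3 * pi_mean)   # keep intervals physiological
        pi_ms.append(pi_next)
        t = t + pi_next / 1000.0
        n += 1

    bt = np.asarray(times)
    s_arr = np.asarray(sabp)
    d_arr = np.asarray(dabp)

    # render: cycle [t_n, t_{n+1}) = decay S_n -> D_n (70%), raised-cosine
    # upstroke D_n -> S_{n+1} (30%), peak exactly at t_{n+1}
    n_samp = int(round(p.duration_s * p.fs_hz))
    ts = p.t0_s + np.arange(n_samp) / p.fs_hz
    idx = np.clip(np.searchsorted(bt, ts, side="right") - 1, 0, bt.size - 2)
    phi = (ts - bt[idx]) / (bt[idx + 1] - bt[idx])
    tau = 3.0
    # exponential-family runoff with zero slope at the systolic peak, so the
    # rendered maximum is smooth and sits exactly on the beat time
    u_d = np.clip(phi / 0.7, 0, 1)
    decay_shape = (np.exp(-tau * u_d ** 2) - np.exp(-tau)) / (1.0 - np.exp(-tau))
    decay = d_arr[idx] + (s_arr[idx] - d_arr[idx]) * decay_shape
    u = np.clip((phi - 0.7) / 0.3, 0, 1)
    rise = d_arr[idx] + (s_arr[idx + 1] - d_arr[idx]) * 0.5 * (1 - np.cos(np.pi * u))
    values = np.where(phi < 0.7, decay, rise)

    keep = bt <= t_end
    truth = pd.DataFrame({
        "beat_time_s": bt[keep],
        "sabp": s_arr[keep],
        "dabp": d_arr[keep],
        "pi_ms": np.concatenate([[np.nan], np.diff(bt[keep]) * 1000.0]),
    })
    return Trace(values, p.fs_hz, t0_s=p.t0_s), truth


# --------------------------------------------------------------------------
# plethysmography
# --------------------------------------------------------------------------

@dataclass
class PlethSimParams:
    duration_s: float = 180.0
    fs_hz: float = 100.0
    fR_cpm: float = 100.0
    deflection: float = 0.5            # peak-to-trough per breath, trace units
    calib: CalibRecord = None          # type: ignore[assignment]
    calib_duration_s: float = 1.0
    movement_epochs: Sequence[tuple] = field(default_factory=list)
    movement_noise_scale: float = 3.0  # artifact SD as multiple of deflection
    noise_sd: float = 0.0
    seed: int = 0
    t0_s: float = 0.0
    fr_offset_profile: Profile | None = None        # cpm
    deflection_offset_profile: Profile | None = None

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.fs_hz <= 0:
            raise ParameterError("duration and sampling rate must be positive")
        if self.fR_cpm <= 0:
            raise ParameterError("fR_cpm must be positive")
        if self.calib is None:
            self.calib = CalibRecord(V_K_mL=1.0, P_K=1.0, time_s=self.t0_s + 2.0)
        t_end = self.t0_s + self.duration_s
        for a, b in self.movement_epochs:
            if not (self.t0_s <= a < b <= t_end):
                raise ParameterError(
                    f"movement epoch ({a}, {b}) outside trace extent")
            c0, c1 = self.calib.time_s, self.calib.time_s + self.calib_duration_s
            if a < c1 and b > c0:
                raise ParameterError(
                    "calibration pulse overlaps a movement epoch")


def generate_pleth(params: PlethSimParams):
    """Simulate a plethysmograph chamber-pressure trace.

    Sinusoidal breathing at the requested rate and peak-to-trough deflection,
    a square calibration pulse of known injected volume, and broadband
    artifact inside movement epochs.  Returns ``(trace, truth)`` with truth
    holding the per-sample instantaneous rate and deflection.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    n = int(round(p.duration_s * p.fs_hz))
    ts = p.t0_s + np.arange(n) / p.fs_hz
    fr_cpm = p.fR_cpm + _profile_array(p.fr_offset_profile, ts)
    defl = p.deflection + _profile_array(p.deflection_offset_profile, ts)
    phase = 2 * np.pi * np.cumsum(fr_cpm / 60.0) / p.fs_hz
    values = 0.5 * defl * np.sin(phase)

    c0, c1 = p.calib.time_s, p.calib.time_s + p.calib_duration_s
    values = values + np.where((ts >= c0) & (ts < c1), p.calib.P_K, 0.0)

    if p.noise_sd > 0:
        values = values + rng.normal(0.0, p.noise_sd, n)
    for a, b in p.movement_epochs:
        mask = (ts >= a) & (ts < b)
        values = values + np.where(
            mask, rng.normal(0.0, p.movement_noise_scale * p.deflection, n), 0.0)

    truth = pd.DataFrame({"time_s": ts, "fr_cpm": fr_cpm, "deflection": defl})
    return Trace(values, p.fs_hz, t0_s=p.t0_s, units="a.u."), truth


# --------------------------------------------------------------------------
# ethograms
# --------------------------------------------------------------------------

def default_transition_matrix(repertoire: Sequence[str] = REPERTOIRE,
                              groom_stay: float = 0.6,
                              groom_enter: float = 0.08) -> np.ndarray:
    """Block-structured row-stochastic matrix: grooming behaviors chain with
    probability ``groom_stay``; non-grooming states enter the grooming
    cluster with probability ``groom_enter``.  No self-transitions."""
    codes = list(repertoire)
    gset = set(GROOMING_CODES) & set(codes)
    n = len(codes)
    P = np.zeros((n, n))
    for i, a in enumerate(codes):
        g_targets = [j for j, c in enumerate(codes) if c in gset and j != i]
        o_targets = [j for j, c in enumerate(codes) if c not in gset and j != i]
        pg = groom_stay if a in gset else groom_enter
        if not g_targets:
            pg = 0.0
        if not o_targets:
            pg = 1.0
        for j in g_targets:
            P[i, j] = pg / len(g_targets)
        for j in o_targets:
            P[i, j] = (1 - pg) / len(o_targets)
    return P


@dataclass
class EthoSimParams:
    repertoire: Sequence[str] = tuple(REPERTOIRE)
    transition_matrix: np.ndarray | None = None
    # default dwell: short grooming bouts (3 s), longer other behaviors (8 s)
    dwell_mean_s: float | Sequence[float] | None = None
    grooming_rate_multiplier: float = 1.0
    session_s: float = 3600.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.repertoire) == 0:
            raise ParameterError("repertoire must not be empty")
        if self.transition_matrix is None:
            self.transition_matrix = default_transition_matrix(self.repertoire)
        if self.dwell_mean_s is None:
            self.dwell_mean_s = [3.0 if c in GROOMING_CODES else 8.0
                                 for c in self.repertoire]
        P = np.asarray(self.transition_matrix, float)
        if P.shape != (len(self.repertoire),) * 2:
            raise ParameterError("transition matrix shape mismatch")
        if not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
            raise ParameterError("transition matrix rows must sum to 1")
        self.transition_matrix = P
        dw = np.broadcast_to(np.asarray(self.dwell_mean_s, float),
                             (len(self.repertoire),)).copy()
        if np.any(dw <= 0):
            raise ParameterError("dwell_mean_s must be positive")
        self.dwell_mean_s = dw


def apply_grooming_multiplier(P: np.ndarray, repertoire: Sequence[str],
                              multiplier: float) -> np.ndarray:
    """Scale transition probabilities into grooming-cluster states by
    ``multiplier`` and renormalize each row."""
    gcols = np.array([c in GROOMING_CODES for c in repertoire])
    Q = P.copy()
    Q[:, gcols] *= multiplier
    rs = Q.sum(axis=1, keepdims=True)
    return Q / np.where(rs > 0, rs, 1.0)


def stationary_occupancy(P: np.ndarray, dwell_mean_s: np.ndarray) -> np.ndarray:
    """Long-run fraction of time in each state of the semi-Markov chain:
    embedded-chain stationary distribution weighted by mean dwell."""
    vals, vecs = np.linalg.eig(P.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi) / np.abs(pi).sum()
    occ = pi * dwell_mean_s
    return occ / occ.sum()


def generate_ethogram(params: EthoSimParams, animal_id: str = "",
                      group: str = "") -> Ethogram:
    """Semi-Markov behavior sequence: next state from the (grooming-scaled)
    transition matrix, dwell times exponential with the per-state mean."""
    p = params
    rng = np.random.default_rng(p.seed)
    codes = list(p.repertoire)
    P = apply_grooming_multiplier(p.transition_matrix, codes,
                                  p.grooming_rate_multiplier)
    occ = stationary_occupancy(P, p.dwell_mean_s)
    state = int(rng.choice(len(codes), p=occ / occ.sum()))
    t = 0.0
    rows = []
    while t < p.session_s:
        dur = float(rng.exponential(p.dwell_mean_s[state]))
        dur = min(dur, p.session_s - t)
        rows.append({"behavior_code": codes[state], "onset_s": t,
                     "duration_s": dur})
        t += dur
        if t >= p.session_s:
            break
        probs = P[state]
        if probs.sum() <= 0:
            break
        state = int(rng.choice(len(codes), p=probs / probs.sum()))
    return Ethogram(pd.DataFrame(rows), session_s=p.session_s,
                    animal_id=animal_id, group=group)


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------

# The four-arm study layout: vehicle and a low oxytocin dose inside the
# central amygdala, the high dose inside (the only arm with autonomic
# effects: pressor ramp peaking at 50 min, sustained tachycardia, transient
# ventilatory rise, doubled SABP modulation, blunted baroreflex gain, strong
# hypergrooming), and the high dose outside the nucleus as anatomical
# control.  Low dose produces hypergrooming only (dose-ordered).
STUDY_DESIGN = {
    "session_s": 3600.0,
    "baseline_s": 300.0,
    "groups": [
        {"name": "SAL-inside", "n": 4, "effects": {}},
        {"name": "OT0.5-inside", "n": 4,
         "effects": {"grooming_multiplier": 3.0}},
        {"name": "OT1-inside", "n": 4, "effects": {
            "grooming_multiplier": 6.0,
            "map_ramp_mmHg": 30.0, "map_ramp_peak_s": 3000.0,
            "hr_step_bpm": 40.0,
            "fr_step_cpm": 30.0, "vt_step_frac": 0.25,
            "baro_gain_scale": 0.6,
            "lf_amp_scale": 2.0, "resp_amp_scale": 2.0}},
        {"name": "OT1-outside", "n": 4, "effects": {}},
    ],
}

# effect knobs a group definition may set; everything defaults to "no effect"
DEFAULT_GROUP_EFFECTS = {
    "map_ramp_mmHg": 0.0,      # pressor ramp peaking at map_ramp_peak_s
    "map_ramp_peak_s": 3000.0,
    "hr_step_bpm": 0.0,        # sustained tachycardia from ~2 min post
    "fr_step_cpm": 0.0,        # respiratory-rate rise, recovered by 40 min
    "vt_step_frac": 0.0,       # fractional tidal-deflection rise with fr step
    "baro_gain_scale": 1.0,    # multiplies baroreflex gain G
    "lf_amp_scale": 1.0,       # multiplies Mayer-wave SABP modulation
    "resp_amp_scale": 1.0,     # multiplies respiratory SABP modulation
    "grooming_multiplier": 1.0,
}


@dataclass
class AnimalRecord:
    animal_id: str
    group: str
    pap: Trace
    pleth: Trace
    etho: Ethogram
    truth_beats: pd.DataFrame
    calib: CalibRecord
    cond: ChamberConditions
    effects: dict


def _group_profiles(eff: dict, session_s: float):
    ramp, peak = eff["map_ramp_mmHg"], eff["map_ramp_peak_s"]
    map_prof = [(-1e9, 0.0), (0.0, 0.0), (peak, ramp), (session_s, ramp)] \
        if ramp else None
    hr = eff["hr_step_bpm"]
    hr_prof = [(-1e9, 0.0), (0.0, 0.0), (120.0, hr), (session_s, hr)] \
        if hr else None
    fr = eff["fr_step_cpm"]
    fr_prof = [(-1e9, 0.0), (0.0, 0.0), (120.0, fr), (1800.0, fr), (2400.0, 0.0)] \
        if fr else None
    return map_prof, hr_prof, fr_prof


def generate_cohort(design: dict, seed: int, root=None):
    """Generate a full synthetic cohort from a design mapping.

    ``design`` has a ``groups`` list ({name, n, effects}) plus optional
    ``session_s``, ``baseline_s``, ``fs_pap``, ``fs_pleth``, ``cardio`` and
    ``pleth`` parameter overrides.  Per-animal seeds are spawned from the
    master ``seed``.  If ``root`` is given the cohort is also written to
    ``<root>/<animal_id>/{pap.csv, pleth.csv, etho.csv, truth/*}`` plus a
    ``cohort.csv`` design table.  Returns ``{animal_id: AnimalRecord}``.
    """
    groups = design.get("groups")
    if not groups:
        raise ParameterError("cohort design must define groups")
    names = [g["name"] for g in groups]
    if len(set(names)) != len(names):
        raise ParameterError(f"duplicate group names in design: {names}")
    session_s = float(design.get("session_s", 3600.0))
    baseline_s = float(design.get("baseline_s", 300.0))
    fs_pap = float(design.get("fs_pap", 250.0))
    fs_pleth = float(design.get("fs_pleth", 100.0))
    cardio_over = dict(design.get("cardio", {}))
    pleth_over = dict(design.get("pleth", {}))
    base_defl = float(pleth_over.pop("deflection", 0.5))
    base_fr = float(pleth_over.pop("fR_cpm", 100.0))
    # inter-individual baseline variability (SD of per-animal offsets)
    jitter = {"sabp_sd": 4.0, "hr_sd": 15.0, "fr_sd": 5.0,
              "defl_sd_frac": 0.05, "groom_sd_log": 0.25}
    unknown_j = set(design.get("animal_jitter", {})) - set(jitter)
    if unknown_j:
        raise ParameterError(f"unknown animal_jitter keys: {sorted(unknown_j)}")
    jitter.update(design.get("animal_jitter", {}))
    etho_over = dict(design.get("etho", {}))
    cond = ChamberConditions(**design.get("chamber", {}))

    ss = np.random.SeedSequence(seed)
    bundle = {}
    for g in groups:
        eff = dict(DEFAULT_GROUP_EFFECTS)
        unknown = set(g.get("effects", {})) - set(eff)
        if unknown:
            raise ParameterError(
                f"unknown effect keys for group {g['name']!r}: {sorted(unknown)}")
        eff.update(g.get("effects", {}))
        n = int(g.get("n", 0))
        if n < 1:
            raise ParameterError(f"group {g['name']!r} needs n >= 1")
        map_prof, hr_prof, fr_prof = _group_profiles(eff, session_s)
        for k in range(n):
            child = ss.spawn(1)[0]
            s_pap, s_pleth, s_etho, s_jit = child.generate_state(4) % (2 ** 31)
            jrng = np.random.default_rng(int(s_jit))
            animal = f"{g['name']}_{k + 1:02d}"

            cp = CardioSimParams(
                duration_s=baseline_s + session_s + 150.0, fs_hz=fs_pap,
                t0_s=-baseline_s, seed=int(s_pap),
                map_offset_profile=map_prof, hr_offset_profile=hr_prof,
                **cardio_over)
            d_sabp = jrng.normal(0.0, jitter["sabp_sd"])
            cp.sabp_mmHg += d_sabp
            cp.dabp_mmHg += d_sabp
            cp.hr_bpm += jrng.normal(0.0, jitter["hr_sd"])
            cp.baro_gain_ms_per_mmHg *= eff["baro_gain_scale"]
            cp.lf_amp_mmHg *= eff["lf_amp_scale"]
            cp.resp_amp_mmHg *= eff["resp_amp_scale"]
            pap, truth = generate_pap(cp)

            defl_prof = None
            if eff["fr_step_cpm"] or eff["vt_step_frac"]:
                step = eff["vt_step_frac"] * base_defl
                defl_prof = [(-1e9, 0.0), (0.0, 0.0), (120.0, step),
                             (1800.0, step), (2400.0, 0.0)]
            # per-animal grooming propensity varies log-normally: this is
            # the random-intercept structure the longitudinal count model
            # assumes, so the cohort exercises sigma_b > 0
            g_mult = eff["grooming_multiplier"] * float(
                np.exp(jrng.normal(0.0, jitter["groom_sd_log"])))
            ep = EthoSimParams(
                grooming_rate_multiplier=g_mult,
                session_s=session_s, seed=int(s_etho), **etho_over)
            etho = generate_ethogram(ep, animal_id=animal, group=g["name"])

            # grooming movement corrupts the chamber-pressure signal: wire
            # the grooming bouts into the pleth trace as artifact epochs
            ev = etho.events
            gev = ev[ev["behavior_code"].isin(GROOMING_CODES)]
            move = [(float(o), float(min(o + d, session_s)))
                    for o, d in zip(gev["onset_s"], gev["duration_s"])]

            calib = CalibRecord(V_K_mL=1.0, P_K=1.0, time_s=-baseline_s + 5.0)
            animal_defl = base_defl * (1.0 + jrng.normal(0.0, jitter["defl_sd_frac"]))
            pp = PlethSimParams(
                duration_s=baseline_s + session_s + 150.0, fs_hz=fs_pleth,
                t0_s=-baseline_s, seed=int(s_pleth), calib=calib,
                deflection=animal_defl,
                fR_cpm=base_fr + jrng.normal(0.0, jitter["fr_sd"]),
                fr_offset_profile=fr_prof,
                deflection_offset_profile=defl_prof,
                movement_epochs=move, **pleth_over)
            pleth, _ = generate_pleth(pp)

            bundle[animal] = AnimalRecord(
                animal_id=animal, group=g["name"], pap=pap, pleth=pleth,
                etho=etho, truth_beats=truth, calib=calib, cond=cond,
                effects=eff)

    if root is not None:
        _write_cohort(bundle, Path(root))
    return bundle


def _write_cohort(bundle: dict, root: Path) -> None:
    root.mkdir(parents=True, exist_ok=True)
    rows = []
    for animal, rec in bundle.items():
        d = root / animal
        (d / "truth").mkdir(parents=True, exist_ok=True)
        rec.pap.to_csv(d / "pap.csv")
        rec.pleth.to_csv(d / "pleth.csv")
        rec.etho.to_csv(d / "etho.csv")
        rec.truth_beats.to_csv(d / "truth" / "beats.csv", index=False,
                               float_format="%.6f")
        meta = {"animal_id": animal, "group": rec.group,
                "effects": rec.effects,
                "calib": asdict(rec.calib), "cond": asdict(rec.cond),
                "session_s": rec.etho.session_s}
        (d / "truth" / "meta.json").write_text(json.dumps(meta, indent=1))
        rows.append({"animal_id": animal, "group": rec.group})
    pd.DataFrame(rows).to_csv(root / "cohort.csv", index=False)
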