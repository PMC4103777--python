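"""Study configuration: schema, defaults, validation and round-tripping.

The config is a YAML mapping.  Defaults implement the study protocol:
a 2-min baseline window immediately before injection (time 0), 2-min
ventilation/hemodynamic epochs starting at 5, 20, 40 and 60 min
post-injection, a 10-min variability window starting at 10 min, LF/HF band
edges at 0.20-0.75 / 0.75-3.0 Hz, sequence-method thresholds of 1 mmHg /
1 ms / 3 beats / lag 1 / r >= 0.85, 15-s grooming sampling in 5-min windows,
and a dyad chi-square threshold of 3.84 (p < 0.05, 1 df).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .core import ParameterError

__all__ = ["StudyConfig", "validate_config", "DEFAULTS"]

DEFAULTS = {
    "cohort_root": None,
    "synth": None,                    # embedded cohort design (see synth module)
    "seed": 0,
    "epochs": {                       # half-open [start, end) s from injection
        "baseline": [-120.0, 0.0],
        "t05": [300.0, 420.0],
        "t20": [1200.0, 1320.0],
        "t40": [2400.0, 2520.0],
        "t60": [3600.0, 3720.0],
    },
    "variability_epoch": [600.0, 1200.0],
    "brs_epoch": [600.0, 1800.0],
    "bands": {"LF": [0.20, 0.75], "HF": [0.75, 3.0]},
    "beats": {"min_hr_bpm": 150.0, "max_hr_bpm": 600.0,
              "prominence_mmHg": 10.0, "max_step_pct": 50.0},
    "baroreflex": {"d_sabp_mmHg": 1.0, "d_pi_ms": 1.0, "min_len": 3,
                   "lag_beats": 1, "r_min": 0.85},
    "scoring": {"sampling_interval_s": 15.0, "window_len_s": 300.0},
    "dyads": {"threshold": 3.84,
              "windows": [[0.0, 300.0], [300.0, 600.0],
                          [600.0, 900.0], [900.0, 1200.0]]},
    "alpha": 0.05,
}


@dataclass
class StudyConfig:
    cohort_root: str | None
    synth: dict | None
    seed: int
    epochs: dict
    variability_epoch: list
    brs_epoch: list
    bands: dict
    beats: dict
    baroreflex: dict
    scoring: dict
    dyads: dict
    alpha: float
    defaulted: list = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {k: copy.deepcopy(getattr(self, k)) for k in DEFAULTS}
        return d

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def validate_config(source) -> StudyConfig:
    """Load, schema-check and normalize a study config.

    ``source`` is a path to a YAML file or an already-parsed mapping.
    Unknown keys and inconsistent ranges produce an itemized error; every
    field filled from a default is recorded in ``defaulted``.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = copy.deepcopy(dict(source))

    errors = []
    unknown = set(raw) - set(DEFAULTS)
    if unknown:
        errors.append(f"unknown config keys: {sorted(unknown)}")

    merged = copy.deepcopy(DEFAULTS)
    defaulted = [k for k in DEFAULTS if k not in raw]
    for k, v in raw.items():
        if k in ("epochs", "bands", "beats", "baroreflex", "scoring", "dyads") \
                and isinstance(v, dict):
            sub = copy.deepcopy(DEFAULTS[k])
            extra = set(v) - set(sub) if k != "epochs" else set()
            if extra:
                errors.append(f"unknown keys under {k!r}: {sorted(extra)}")
            if k == "epochs":
                sub = dict(v)       # epoch names are free-form
            else:
                sub.update(v)
            merged[k] = sub
        elif k in DEFAULTS:
            merged[k] = v

    # range checks
    bands = merged["bands"]
    try:
        lf_lo, lf_hi = map(float, bands["LF"])
        hf_lo, hf_hi = map(float, bands["HF"])
        if not (0 <= lf_lo < lf_hi):
            errors.append(f"LF band edges out of order: {bands['LF']}")
        if not (0 <= hf_lo < hf_hi):
            errors.append(f"HF band edges out of order: {bands['HF']}")
        if lf_hi > hf_lo:
            errors.append(
                f"LF upper edge {lf_hi} exceeds HF lower edge {hf_lo}")
    except (KeyError, TypeError, ValueError) as exc:
        errors.append(f"malformed bands: {exc}")

    epochs = {}
    for name, win in merged["epochs"].items():
        try:
            a, b = float(win[0]), float(win[1])
        except (TypeError, ValueError, IndexError):
            errors.append(f"epoch {name!r} is not a [start, end] pair")
            continue
        if b <= a:
            errors.append(f"epoch {name!r} has end <= start")
        epochs[name] = [a, b]
    spans = sorted(epochs.values())
    for (a1, b1), (a2, b2) in zip(spans[:-1], spans[1:]):
        if a2 < b1:
            errors.append(f"epochs overlap: [{a1},{b1}) and [{a2},{b2})")
    if "baseline" not in epochs:
        errors.append("an epoch named 'baseline' is required")
    merged["epochs"] = epochs

    if not 0 < float(merged["alpha"]) < 1:
        errors.append(f"alpha must be in (0,1), got {merged['alpha']}")
    if merged["cohort_root"] is None and merged["synth"] is None:
        errors.append("config must provide cohort_root and/or a synth block")

    if errors:
        raise ParameterError("invalid config:\n  - " + "\n  - ".join(errors))
    return StudyConfig(**{k: merged[k] for k in DEFAULTS}, defaulted=defaulted)
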