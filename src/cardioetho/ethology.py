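"""Grooming scoring, longitudinal Poisson modelling and dyad analysis.

Three layers of behavioral analysis over an ethogram (time-stamped event
sequence):

* **Grooming score** — time-sampling quantification: the session is probed
  at a fixed interval (default 15 s) and each probe scores 1 when any
  grooming-cluster behavior is in progress; scores are totalled in 5-min
  windows, giving 12 windows per 60-min session.
* **Longitudinal Poisson model** — window counts modelled as Poisson with
  group, window and group-by-window fixed effects plus a per-animal random
  intercept (see :mod:`cardioetho.glmm`), with Wald contrasts of each group
  against the reference at every window.
* **Dyad (transition) analysis** — immediate behavior-to-behavior
  successions counted within observation windows; each ordered pair is
  tested against independence with a 2x2 chi-square (1 df), significant
  when X^2 > 3.84 (p < 0.05); significant dyads are exported as a DOT
  flowchart.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .core import Ethogram, ParameterError
from .glmm import PoissonGLMMResult, fit_poisson_glmm

__all__ = [
    "GROOMING_CODES", "NON_GROOMING_CODES", "REPERTOIRE",
    "GroomingScoreSeries", "TransitionTable", "DyadResult", "PoissonFit",
    "score_grooming", "fit_poisson_longitudinal", "build_transition_table",
    "dyad_chi_square", "export_flowchart", "chi_square_critical",
]

# Grooming cluster: body (left/right), genitalia, head, claw licking
# (anterior/posterior, both sides), face, scratching; everything else in the
# repertoire (orofacial automatisms, posture, locomotion) is non-grooming.
GROOMING_CODES = ("GRR", "GRL", "GRG", "GRH", "LIC", "LCR1", "LCR2",
                  "LCL1", "LCL2", "GRF", "SCRL", "SCRR")
NON_GROOMING_CODES = ("MT", "WDS", "YA", "ER", "IM", "SCA", "SN", "WA")
REPERTOIRE = GROOMING_CODES + NON_GROOMING_CODES


def chi_square_critical(alpha: float = 0.05, df: int = 1) -> float:
    """Upper-alpha critical value of the chi-square distribution."""
    return float(chi2.ppf(1.0 - alpha, df))


@dataclass
class GroomingScoreSeries:
    counts: np.ndarray           # one integer count per window
    window_len_s: float
    sampling_interval_s: float
    animal_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(self.counts < 0):
            raise ParameterError("window counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def score_grooming(etho: Ethogram, sampling_interval_s: float = 15.0,
                   window_len_s: float = 300.0,
                   grooming_codes: Sequence[str] = GROOMING_CODES
                   ) -> GroomingScoreSeries:
    """Time-sampled grooming score per window.

    Probe instants are t = 0, dt, 2dt, ... within the session; a probe scores
    1 if a grooming-cluster event covers it ([onset, onset+duration)).
    """
    if etho.session_s < window_len_s:
        raise ParameterError("session shorter than one scoring window")
    unknown = set(etho.events["behavior_code"]) - set(REPERTOIRE)
    if unknown:
        raise ParameterError(f"unknown behavior codes: {sorted(unknown)}")

    n_windows = int(etho.session_s // window_len_s)
    per_window = int(round(window_len_s / sampling_interval_s))
    n_samples = n_windows * per_window
    probes = np.arange(n_samples) * sampling_interval_s

    groom = etho.events[etho.events["behavior_code"].isin(grooming_codes)]
    active = np.zeros(n_samples, dtype=bool)
    for onset, dur in zip(groom["onset_s"].to_numpy(float),
                          groom["duration_s"].to_numpy(float)):
        active |= (probes >= onset) & (probes < onset + dur)
    counts = active.reshape(n_windows, per_window).sum(axis=1)
    return GroomingScoreSeries(counts, window_len_s, sampling_interval_s,
                               animal_id=etho.animal_id, group=etho.group)


@dataclass
class PoissonFit:
    """Longitudinal Poisson fit with per-cell means and group contrasts."""

    result: PoissonGLMMResult
    fitted_means: pd.DataFrame     # columns: group, window, mean
    contrasts: pd.DataFrame        # group, window, log_rr, se, z, p, significant
    reference_group: str
    groups: list
    n_windows: int
    boundary_groups: list = field(default_factory=list)

    @property
    def sigma_b(self) -> float:
        return self.result.sigma_b

    def group_significant(self, group: str, alpha: float = 0.05,
                          bonferroni: bool = True) -> bool:
        """Is ``group`` different from the reference in any window, with a
        Bonferroni correction over windows by default?"""
        sub = self.contrasts[self.contrasts["group"] == group]
        thr = alpha / self.n_windows if bonferroni else alpha
        return bool((sub["p"] < thr).any())


def scores_to_panel(scores: Iterable[GroomingScoreSeries]) -> pd.DataFrame:
    rows = []
    for s in scores:
        for w, c in enumerate(s.counts):
            rows.append({"animal_id": s.animal_id, "group": s.group,
                         "window": w, "count": int(c)})
    return pd.DataFrame(rows)


def fit_poisson_longitudinal(scores: Iterable[GroomingScoreSeries] | pd.DataFrame,
                             reference_group: str | None = None,
                             n_quad: int = 20) -> PoissonFit:
    """Fit log lambda = b0 + group + window + group:window + b_animal.

    ``scores`` is either GroomingScoreSeries objects or a long DataFrame with
    columns (animal_id, group, window, count).  The first group (or
    ``reference_group``) is the baseline; contrasts report each other group
    against it at every window.
    """
    panel = scores if isinstance(scores, pd.DataFrame) else scores_to_panel(scores)
    if panel.empty:
        raise ParameterError("no scores provided")
    counts = panel["count"].to_numpy()
    if np.any(counts < 0) or np.any(counts != np.round(counts)):
        raise ParameterError("counts must be nonnegative integers")

    groups = sorted(panel["group"].unique())
    if reference_group is not None:
        if reference_group not in groups:
            raise ParameterError(f"reference group {reference_group!r} not present")
        groups = [reference_group] + [g for g in groups if g != reference_group]
    ref = groups[0]
    if len(groups) < 2:
        raise ParameterError("need at least 2 groups")
    for g in groups:
        if panel.loc[panel["group"] == g, "animal_id"].nunique() < 2:
            raise ParameterError(f"group {g!r} has fewer than 2 animals")
    windows = sorted(panel["window"].unique())
    n_w = len(windows)

    boundary_groups = [g for g in groups
                       if panel.loc[panel["group"] == g, "count"].sum() == 0]

    # treatment-coded design: intercept, group dummies, window dummies,
    # group x window interaction dummies
    g_idx = {g: i for i, g in enumerate(groups)}
    w_idx = {w: i for i, w in enumerate(windows)}
    n_g = len(groups)
    p = 1 + (n_g - 1) + (n_w - 1) + (n_g - 1) * (n_w - 1)
    X = np.zeros((len(panel), p))
    X[:, 0] = 1.0
    names = ["intercept"] + [f"group[{g}]" for g in groups[1:]] + \
            [f"window[{w}]" for w in windows[1:]] + \
            [f"group[{g}]:window[{w}]" for g in groups[1:] for w in windows[1:]]

    def cols(g, w):
        """Column indices active for cell (g, w) beyond the intercept."""
        out = []
        gi, wi = g_idx[g], w_idx[w]
        if gi > 0:
            out.append(gi)                      # group dummy
        if wi > 0:
            out.append(n_g - 1 + wi)            # window dummy
        if gi > 0 and wi > 0:
            out.append(n_g - 1 + n_w - 1 + (gi - 1) * (n_w - 1) + wi)
        return out

    for r, (g, w) in enumerate(zip(panel["group"], panel["window"])):
        for c in cols(g, w):
            X[r, c] = 1.0

    subj = pd.factorize(panel["animal_id"])[0]
    result = fit_poisson_glmm(counts, X, subj, n_quad=n_quad, exog_names=names)

    cells, rows = [], []
    for g in groups:
        for w in windows:
            x = np.zeros(p); x[0] = 1.0
            for c in cols(g, w):
                x[c] = 1.0
            cells.append({"group": g, "window": w,
                          "mean": float(np.exp(np.clip(x @ result.beta, -30, 30)))})
    for g in groups[1:]:
        for w in windows:
            c = np.zeros(p)
            for col in cols(g, w):
                c[col] = 1.0
            for col in cols(ref, w):
                c[col] -= 1.0
            est, se, z, pv = result.wald_contrast(c)
            rows.append({"group": g, "window": w, "log_rr": est, "se": se,
                         "z": z, "p": pv})
    contrasts = pd.DataFrame(rows)
    contrasts["significant"] = contrasts["p"] < 0.05
    return PoissonFit(result=result, fitted_means=pd.DataFrame(cells),
                      contrasts=contrasts, reference_group=ref,
                      groups=groups, n_windows=n_w,
                      boundary_groups=boundary_groups)


@dataclass
class TransitionTable:
    counts: pd.DataFrame          # rows = predecessor, columns = successor
    window_id: str = ""

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())


def build_transition_table(etho: Ethogram,
                           windows: Sequence[tuple] | None = None,
                           codes: Sequence[str] = REPERTOIRE):
    """Immediate-succession counts O[a][b] per observation window.

    ``windows`` is a list of half-open (start_s, end_s) intervals; events are
    assigned by onset, and only successions of events within the same window
    are counted.  ``None`` means one window covering the whole session.
    """
    if windows is None:
        windows = [(0.0, etho.session_s)]
    ev_codes = etho.events["behavior_code"].to_numpy()
    onsets = etho.events["onset_s"].to_numpy(float)
    tables = []
    for w, (a, b) in enumerate(windows):
        mask = (onsets >= a) & (onsets < b)
        seq = ev_codes[mask]
        mat = pd.DataFrame(0, index=list(codes), columns=list(codes), dtype=int)
        for u, v in zip(seq[:-1], seq[1:]):
            mat.loc[u, v] += 1
        tables.append(TransitionTable(mat, window_id=f"w{w}:{a:g}-{b:g}s"))
    return tables


@dataclass
class DyadResult:
    pair: tuple                  # (a, b) for the succession a -> b
    observed: int
    expected: float
    chi_square: float
    significant: bool
    skipped: bool = False        # an expected cell < 1 -> test not run

    @property
    def positive(self) -> bool:
        """True when the succession occurs *more* often than independence
        predicts (flowchart arrows are drawn for these only)."""
        return self.observed > self.expected


def dyad_chi_square(table: TransitionTable,
                    threshold: float = 3.84) -> list:
    """Per-dyad 2x2 chi-square test of association against independence.

    For each ordered pair (a, b) the table {a->b, a->not-b, not-a->b,
    not-a->not-b} is formed and X^2 = sum (O-E)^2/E computed from its
    margins (1 df).  Dyads with any expected cell below 1 are skipped and
    flagged.  ``threshold`` = 3.84 corresponds to p < 0.05 at 1 df.
    """
    M = table.counts
    N = table.total
    if N < 1:
        return []
    row = M.sum(axis=1)
    col = M.sum(axis=0)
    results = []
    for a in M.index:
        if row[a] == 0:
            continue
        for b in M.columns:
            if a == b or col[b] == 0:
                continue
            o11 = int(M.loc[a, b])
            o12 = int(row[a] - o11)
            o21 = int(col[b] - o11)
            o22 = int(N - row[a] - col[b] + o11)
            obs = np.array([[o11, o12], [o21, o22]], float)
            rt = obs.sum(axis=1, keepdims=True)
            ct = obs.sum(axis=0, keepdims=True)
            exp = rt @ ct / N
            if np.any(exp < 1.0):
                results.append(DyadResult((a, b), o11, float(exp[0, 0]),
                                          np.nan, False, skipped=True))
                continue
            x2 = float(((obs - exp) ** 2 / exp).sum())
            results.append(DyadResult((a, b), o11, float(exp[0, 0]),
                                      x2, x2 > threshold))
    return results


def node_statistics(etho: Ethogram,
                    window: tuple | None = None) -> pd.DataFrame:
    """Per-behavior frequency (event count) and total duration, for flowchart
    node sizing."""
    ev = etho.events
    if window is not None:
        a, b = window
        ev = ev[(ev["onset_s"] >= a) & (ev["onset_s"] < b)]
    agg = ev.groupby("behavior_code").agg(
        frequency=("behavior_code", "size"),
        total_duration_s=("duration_s", "sum")).reset_index()
    return agg


def export_flowchart(dyads: Iterable[DyadResult], node_stats: pd.DataFrame,
                     path) -> None:
    """Write the dyad graph in DOT format.

    Every behavior in ``node_stats`` becomes a node carrying its frequency
    and total duration; edges are drawn only for significant *positive*
    dyads (succession more frequent than independence predicts), with the
    chi-square statistic as edge weight.
    """
    lines = ["digraph behavior {", "  rankdir=LR;"]
    for _, r in node_stats.iterrows():
        lines.append(
            f'  "{r["behavior_code"]}" [frequency={int(r["frequency"])}, '
            f'duration={r["total_duration_s"]:.1f}];')
    for d in dyads:
        if d.significant and d.positive and not d.skipped:
            a, b = d.pair
            lines.append(f'  "{a}" -> "{b}" [weight={d.chi_square:.2f}, '
                         f'label="{d.chi_square:.1f}"];')
    lines.append("}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
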