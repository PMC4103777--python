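"""Group-comparison statistics: mixed-design (two-way repeated-measures)
ANOVA, one-way ANOVA, Bonferroni post-hoc tests and delta-from-baseline
panels.

The two-way design has treatment group as a between-subject factor and time
as the repeated (within-subject) factor.  The between-subject effect is
tested against the subject-within-group mean square; time and the
group-by-time interaction are tested against the residual within-subject
mean square.  Strict balance is required (every animal measured on the same
time grid, equal group sizes); no imputation and no sphericity correction by
default (a Greenhouse-Geisser option exists behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .core import ParameterError

__all__ = ["AnovaReport", "deltas_from_baseline", "two_way_rm_anova",
           "one_way_anova", "bonferroni"]

PANEL_COLUMNS = ("animal_id", "group", "time_label", "value")


@dataclass
class AnovaReport:
    table: pd.DataFrame                    # effect, SS, df, MS, F, p
    posthoc: pd.DataFrame = None           # type: ignore[assignment]
    notes: list = field(default_factory=list)

    def effect(self, name: str) -> pd.Series:
        return self.table.set_index("effect").loc[name]

    def significant_pairs(self, alpha: float = 0.05) -> pd.DataFrame:
        if self.posthoc is None or self.posthoc.empty:
            return pd.DataFrame()
        return self.posthoc[self.posthoc["p_adj"] < alpha]


def bonferroni(p_raw, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: p_adj = min(1, m * p_raw)."""
    p = np.asarray(p_raw, float)
    if np.any((p < 0) | (p > 1)):
        raise ParameterError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < 1:
        raise ParameterError("m must be >= 1")
    return np.minimum(1.0, m * p)


def deltas_from_baseline(panel: pd.DataFrame,
                         baselines: pd.DataFrame | dict) -> pd.DataFrame:
    """Per-animal change from baseline: delta = value - baseline.

    ``baselines`` maps animal_id to its baseline value (dict, or a DataFrame
    with columns animal_id and baseline).
    """
    _check_panel(panel)
    if isinstance(baselines, pd.DataFrame):
        baselines = dict(zip(baselines["animal_id"], baselines["baseline"]))
    missing = sorted(set(panel["animal_id"]) - set(baselines))
    if missing:
        raise ParameterError(f"missing baseline for animals: {missing}")
    out = panel.copy()
    out["value"] = [v - baselines[a]
                    for a, v in zip(panel["animal_id"], panel["value"])]
    return out


def _check_panel(panel: pd.DataFrame) -> None:
    missing = set(PANEL_COLUMNS) - set(panel.columns)
    if missing:
        raise ParameterError(f"panel missing columns: {sorted(missing)}")
    dup = panel.duplicated(subset=["animal_id", "time_label"])
    if dup.any():
        raise ParameterError("duplicate (animal, time) measurements in panel")


def two_way_rm_anova(panel: pd.DataFrame, posthoc: bool = True,
                     gg_correction: bool = False) -> AnovaReport:
    """Mixed-design ANOVA: between factor = group, repeated factor = time.

    Raises on unbalanced panels (missing cells, unequal group sizes).
    """
    _check_panel(panel)
    groups = sorted(panel["group"].unique())
    times = sorted(panel["time_label"].unique())
    a, b = len(groups), len(times)
    if a < 2 or b < 2:
        raise ParameterError("need >= 2 groups and >= 2 time points")

    # cube Y[g][s][t]; strict balance check
    per_group = {}
    for g in groups:
        sub = panel[panel["group"] == g]
        animals = sorted(sub["animal_id"].unique())
        mat = sub.pivot(index="animal_id", columns="time_label", values="value")
        if mat.isna().any().any() or set(mat.columns) != set(times):
            raise ParameterError(
                f"unbalanced panel: group {g!r} lacks a full time grid")
        per_group[g] = mat.loc[animals, times].to_numpy(float)
    ns = {g: m.shape[0] for g, m in per_group.items()}
    if len(set(ns.values())) != 1:
        raise ParameterError(f"unequal group sizes {ns}; strict balance required")
    n = next(iter(ns.values()))
    if n < 2:
        raise ParameterError("need >= 2 animals per group")

    Y = np.stack([per_group[g] for g in groups])      # (a, n, b)
    grand = Y.mean()
    subj_means = Y.mean(axis=2)                       # (a, n)
    group_means = Y.mean(axis=(1, 2))                 # (a,)
    time_means = Y.mean(axis=(0, 1))                  # (b,)
    cell_means = Y.mean(axis=1)                       # (a, b)

    ss_total = float(((Y - grand) ** 2).sum())
    ss_group = float(n * b * ((group_means - grand) ** 2).sum())
    ss_subj = float(b * ((subj_means - group_means[:, None]) ** 2).sum())
    ss_time = float(a * n * ((time_means - grand) ** 2).sum())
    ss_inter = float(n * ((cell_means - group_means[:, None]
                           - time_means[None, :] + grand) ** 2).sum())
    ss_error = ss_total - ss_group - ss_subj - ss_time - ss_inter

    df_group, df_subj = a - 1, a * (n - 1)
    df_time, df_inter = b - 1, (a - 1) * (b - 1)
    df_error = a * (n - 1) * (b - 1)

    eps = 1.0
    notes = []
    if gg_correction:
        eps = _greenhouse_geisser_epsilon(Y)
        notes.append(f"Greenhouse-Geisser epsilon = {eps:.4f}")

    rows = []
    for name, ss, df, err_ss, err_df, within in (
            ("group", ss_group, df_group, ss_subj, df_subj, False),
            ("subject(group)", ss_subj, df_subj, None, None, False),
            ("time", ss_time, df_time, ss_error, df_error, True),
            ("group:time", ss_inter, df_inter, ss_error, df_error, True),
            ("error(time)", ss_error, df_error, None, None, False)):
        ms = ss / df if df > 0 else np.nan
        if err_ss is None:
            rows.append({"effect": name, "SS": ss, "df": df, "MS": ms,
                         "F": np.nan, "p": np.nan})
            continue
        ms_err = err_ss / err_df
        if ms_err <= 0:
            F = p = np.nan
            notes.append(f"{name}: zero error mean square, F undefined")
        else:
            F = ms / ms_err
            d1, d2 = (df * eps, err_df * eps) if within else (df, err_df)
            p = float(spstats.f.sf(F, d1, d2))
        rows.append({"effect": name, "SS": ss, "df": df, "MS": ms,
                     "F": F, "p": p})
    table = pd.DataFrame(rows)

    ph = None
    if posthoc:
        ph = _posthoc_groups_per_time(panel, groups, times)
    return AnovaReport(table=table, posthoc=ph, notes=notes)


def _greenhouse_geisser_epsilon(Y: np.ndarray) -> float:
    """GG epsilon from the pooled within-group covariance of the time factor."""
    a, n, b = Y.shape
    resid = Y - Y.mean(axis=1, keepdims=True)
    S = np.zeros((b, b))
    for g in range(a):
        S += resid[g].T @ resid[g]
    S /= (a * (n - 1))
    mean_diag = np.trace(S) / b
    mean_all = S.mean()
    num = (b * (mean_diag - mean_all)) ** 2
    den = (b - 1) * ((S ** 2).sum() - 2 * b * (S.mean(axis=1) ** 2).sum()
                     + b * b * mean_all ** 2)
    return float(np.clip(num / den if den > 0 else 1.0, 1.0 / (b - 1), 1.0))


def _posthoc_groups_per_time(panel, groups, times) -> pd.DataFrame:
    """Pairwise between-group t-tests at each time, Bonferroni-adjusted over
    all (pair, time) comparisons."""
    rows = []
    for t in times:
        sub = panel[panel["time_label"] == t]
        for g1, g2 in combinations(groups, 2):
            x = sub.loc[sub["group"] == g1, "value"].to_numpy(float)
            y = sub.loc[sub["group"] == g2, "value"].to_numpy(float)
            tt = spstats.ttest_ind(x, y)
            rows.append({"time_label": t, "group_1": g1, "group_2": g2,
                         "mean_diff": float(x.mean() - y.mean()),
                         "t": float(tt.statistic), "p_raw": float(tt.pvalue)})
    ph = pd.DataFrame(rows)
    if not ph.empty:
        ph["p_adj"] = bonferroni(ph["p_raw"].fillna(1.0), m=len(ph))
    return ph


def one_way_anova(panel_or_groups, posthoc: bool = True) -> AnovaReport:
    """Classic between-groups decomposition with Bonferroni pairwise post-hoc.

    Accepts either a dict {group: values} or a panel DataFrame with columns
    group and value.
    """
    if isinstance(panel_or_groups, pd.DataFrame):
        df = panel_or_groups
        data = {g: df.loc[df["group"] == g, "value"].to_numpy(float)
                for g in sorted(df["group"].unique())}
    else:
        data = {g: np.asarray(v, float) for g, v in panel_or_groups.items()}
    data = {g: v[np.isfinite(v)] for g, v in data.items()}
    if len(data) < 2:
        raise ParameterError("need >= 2 groups")
    for g, v in data.items():
        if v.size < 2:
            raise ParameterError(f"group {g!r} has fewer than 2 observations")

    allv = np.concatenate(list(data.values()))
    grand = allv.mean()
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in data.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in data.values())
    df_b = len(data) - 1
    df_w = allv.size - len(data)
    ms_b, ms_w = ss_between / df_b, ss_within / df_w
    notes = []
    if ms_w <= 0:
        F = p = np.nan
        notes.append("zero within-group variance, F undefined")
    else:
        F = ms_b / ms_w
        p = float(spstats.f.sf(F, df_b, df_w))
    table = pd.DataFrame([
        {"effect": "group", "SS": ss_between, "df": df_b, "MS": ms_b,
         "F": F, "p": p},
        {"effect": "error", "SS": ss_within, "df": df_w, "MS": ms_w,
         "F": np.nan, "p": np.nan}])

    ph = None
    if posthoc:
        rows = []
        for g1, g2 in combinations(sorted(data), 2):
            x, y = data[g1], data[g2]
            if ms_w > 0:
                se = np.sqrt(ms_w * (1 / x.size + 1 / y.size))
                tval = (x.mean() - y.mean()) / se
                praw = float(2 * spstats.t.sf(abs(tval), df_w))
            else:
                tval, praw = np.nan, 1.0
            rows.append({"group_1": g1, "group_2": g2,
                         "mean_diff": float(x.mean() - y.mean()),
                         "t": float(tval), "p_raw": praw})
        ph = pd.DataFrame(rows)
        ph["p_adj"] = bonferroni(ph["p_raw"], m=len(ph))
    return AnovaReport(table=table, posthoc=ph, notes=notes)
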