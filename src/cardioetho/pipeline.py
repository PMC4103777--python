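"""End-to-end study analysis: cohort in, report directory out.

Stage order mirrors the experimental workflow: beat extraction from
arterial pressure, spectral variability and spontaneous baroreflex per
epoch, barometric ventilation per epoch with grooming-movement exclusion
taken from the ethogram, grooming scoring with the longitudinal Poisson
model, dyad chi-square flowcharts per group, and delta-from-baseline
ANOVAs.  Any stage failure aborts with the stage name and offending input;
partial outputs are kept next to a FAILED marker.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .baroreflex import brs_report
from .beats import artifact_filter, detect_beats
from .config import StudyConfig
from .core import Ethogram, InsufficientDataError, Trace
from .ethology import (GROOMING_CODES, TransitionTable,
                       build_transition_table, dyad_chi_square,
                       export_flowchart, fit_poisson_longitudinal,
                       node_statistics, score_grooming)
from .stats import deltas_from_baseline, one_way_anova, two_way_rm_anova
from .synth import AnimalRecord, generate_cohort
from .variability import Band, variability_summary
from .ventilation import CalibRecord, ChamberConditions, ventilation_summary

__all__ = ["StudyReport", "PipelineError", "run_pipeline", "load_cohort"]

FLOAT_FMT = "%.6g"


class PipelineError(RuntimeError):
    """A pipeline stage failed; message carries stage and input names."""


@dataclass
class StudyReport:
    epoch_panel: pd.DataFrame           # animal, group, epoch, measure, value
    variability: pd.DataFrame
    baroreflex: pd.DataFrame
    ventilation: pd.DataFrame
    grooming_scores: pd.DataFrame
    anova_tables: dict                  # measure -> AnovaReport
    poisson_fit: object
    dyads: dict                         # group -> DataFrame
    flags: pd.DataFrame                 # measure, group, p, significant
    provenance: dict = field(default_factory=dict)


def load_cohort(root) -> dict:
    """Read a cohort written by the synth module from disk."""
    root = Path(root)
    table = root / "cohort.csv"
    if not table.exists():
        raise PipelineError(f"stage load: missing cohort table {table}")
    cohort = pd.read_csv(table)
    bundle = {}
    for _, row in cohort.iterrows():
        animal, group = str(row["animal_id"]), str(row["group"])
        d = root / animal
        for fname in ("pap.csv", "pleth.csv", "etho.csv"):
            if not (d / fname).exists():
                raise PipelineError(f"stage load: missing file {d / fname}")
        meta_path = d / "truth" / "meta.json"
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        calib = CalibRecord(**meta["calib"]) if "calib" in meta else \
            CalibRecord(V_K_mL=1.0, P_K=1.0)
        cond = ChamberConditions(**meta["cond"]) if "cond" in meta else \
            ChamberConditions()
        session_s = float(meta.get("session_s", 3600.0))
        tb_path = d / "truth" / "beats.csv"
        truth = pd.read_csv(tb_path) if tb_path.exists() else pd.DataFrame()
        bundle[animal] = AnimalRecord(
            animal_id=animal, group=group,
            pap=Trace.from_csv(d / "pap.csv"),
            pleth=Trace.from_csv(d / "pleth.csv", units="a.u."),
            etho=Ethogram.from_csv(d / "etho.csv", session_s=session_s,
                                   animal_id=animal, group=group),
            truth_beats=truth, calib=calib, cond=cond,
            effects=meta.get("effects", {}))
    return bundle


def _grooming_epochs(etho: Ethogram) -> list:
    ev = etho.events
    g = ev[ev["behavior_code"].isin(GROOMING_CODES)]
    return [(float(o), float(o + d))
            for o, d in zip(g["onset_s"], g["duration_s"])]


def _flag_rm(report, ref: str, group: str, alpha: float):
    """Smallest adjusted post-hoc p for the (ref, group) pair over times."""
    ph = report.posthoc
    sel = ph[((ph["group_1"] == ref) & (ph["group_2"] == group)) |
             ((ph["group_1"] == group) & (ph["group_2"] == ref))]
    if sel.empty:
        return np.nan, False
    p = float(sel["p_adj"].min())
    return p, p < alpha


def run_pipeline(config: StudyConfig, out_dir=None) -> StudyReport:
    """Run the full analysis described by ``config``.

    The cohort is loaded from ``cohort_root`` if present there, otherwise
    synthesized from the embedded ``synth`` design (and persisted to
    ``cohort_root`` when one is named).  Returns the in-memory report and,
    when ``out_dir`` is given, writes every table plus provenance there.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    try:
        report = _run(config)
    except Exception as exc:
        if out is not None:
            (out / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        raise
    if out is not None:
        _write_report(report, config, out)
    return report


def _run(config: StudyConfig) -> StudyReport:
    cfg = config
    root = cfg.cohort_root
    if root is not None and (Path(root) / "cohort.csv").exists():
        bundle = load_cohort(root)
    elif cfg.synth is not None:
        bundle = generate_cohort(cfg.synth, seed=cfg.seed, root=root)
    else:
        raise PipelineError(f"stage load: cohort root {root!r} not found "
                            "and no synth design given")

    groups_in_order = []
    if cfg.synth:
        groups_in_order = [g["name"] for g in cfg.synth.get("groups", [])]
    else:
        for rec in bundle.values():
            if rec.group not in groups_in_order:
                groups_in_order.append(rec.group)
    ref = groups_in_order[0]

    bands = tuple(Band(name, lo, hi) for name, (lo, hi) in cfg.bands.items())
    epoch_names = [e for e in cfg.epochs if e != "baseline"]

    epoch_rows, var_rows, brs_rows, vent_rows = [], [], [], []
    scores = []
    per_group_etho = {}

    for animal, rec in bundle.items():
        # ---- beats ------------------------------------------------------
        try:
            bs = detect_beats(rec.pap, cfg.beats["min_hr_bpm"],
                              cfg.beats["max_hr_bpm"],
                              cfg.beats["prominence_mmHg"])
            bs, _ = artifact_filter(bs, cfg.beats["max_step_pct"])
        except Exception as exc:
            raise PipelineError(f"stage beats: animal {animal}: {exc}") from exc

        for name, (a, b) in cfg.epochs.items():
            w = bs.window(a, b)
            epoch_rows += [
                {"animal_id": animal, "group": rec.group, "epoch": name,
                 "measure": "MABP", "value": float(np.nanmean(w.mabp_mmHg))},
                {"animal_id": animal, "group": rec.group, "epoch": name,
                 "measure": "HR", "value": float(np.nanmean(w.hr_bpm))},
            ]

        # ---- variability + baroreflex -----------------------------------
        try:
            vwin = bs.window(*cfg.variability_epoch)
            for which in ("SABP", "PI"):
                summ = variability_summary(vwin, which, bands=bands)
                var_rows.append({
                    "animal_id": animal, "group": rec.group, "series": which,
                    "variance": summ.variance, "lf": summ.lf_power,
                    "hf": summ.hf_power, "total": summ.total_power,
                    "band_edges": json.dumps(summ.band_edges)})
        except Exception as exc:
            raise PipelineError(
                f"stage variability: animal {animal}: {exc}") from exc
        try:
            bwin = bs.window(*cfg.brs_epoch)
            rep = brs_report(bwin, **cfg.baroreflex)
            brs_rows.append({
                "animal_id": animal, "group": rec.group,
                "n_up_per_10k": rep.n_up_per_10k,
                "n_down_per_10k": rep.n_down_per_10k,
                "mean_slope_up": rep.mean_slope_up,
                "mean_slope_down": rep.mean_slope_down,
                "brs_all": rep.brs_all,
                "n_beats": rep.n_beats_analyzed})
        except Exception as exc:
            raise PipelineError(
                f"stage baroreflex: animal {animal}: {exc}") from exc

        # ---- ventilation -------------------------------------------------
        groom_epochs = _grooming_epochs(rec.etho)
        calib_excl = (rec.calib.time_s - 1.0, rec.calib.time_s + 3.0)
        for name, (a, b) in cfg.epochs.items():
            # a hypergrooming bout can cover a whole closed-chamber window;
            # extend the window (up to 4x) until enough clean signal remains
            res = None
            last_exc = None
            for widen in (1.0, 2.0, 4.0):
                try:
                    seg = rec.pleth.segment(a, a + widen * (b - a))
                    res = ventilation_summary(seg, rec.calib, rec.cond,
                                              exclusion_epochs=list(groom_epochs)
                                              + [calib_excl])
                    break
                except InsufficientDataError as exc:
                    last_exc = exc
                except Exception as exc:
                    raise PipelineError(
                        f"stage ventilation: animal {animal}, epoch {name}: "
                        f"{exc}") from exc
            if res is None:
                raise PipelineError(
                    f"stage ventilation: animal {animal}, epoch {name}: "
                    f"{last_exc}") from last_exc
            vent_rows += [
                {"animal_id": animal, "group": rec.group, "epoch": name,
                 "measure": m, "value": v}
                for m, v in (("fR", res.fR_cpm), ("VT", res.V_T_mL_per_kg),
                             ("VE", res.V_E_mL_per_kg_min))]

        # ---- ethology ----------------------------------------------------
        try:
            scores.append(score_grooming(rec.etho, **cfg.scoring))
        except Exception as exc:
            raise PipelineError(
                f"stage ethology: animal {animal}: {exc}") from exc
        per_group_etho.setdefault(rec.group, []).append(rec.etho)

    epoch_panel = pd.DataFrame(epoch_rows)
    variability = pd.DataFrame(var_rows)
    baroreflex = pd.DataFrame(brs_rows)
    ventilation = pd.DataFrame(vent_rows)
    score_rows = []
    for s in scores:
        for w, c in enumerate(s.counts):
            score_rows.append({"animal_id": s.animal_id, "group": s.group,
                               "window": w, "count": int(c)})
    grooming_scores = pd.DataFrame(score_rows)

    # ---- statistics ------------------------------------------------------
    anova_tables = {}
    flag_rows = []

    def rm_measure(panel_df, measure, label):
        sub = panel_df[panel_df["measure"] == measure]
        base = sub[sub["epoch"] == "baseline"]
        baselines = dict(zip(base["animal_id"], base["value"]))
        post = sub[sub["epoch"] != "baseline"].rename(
            columns={"epoch": "time_label"})[
            ["animal_id", "group", "time_label", "value"]]
        deltas = deltas_from_baseline(post, baselines)
        rep = two_way_rm_anova(deltas)
        anova_tables[label] = rep
        for g in groups_in_order[1:]:
            p, sig = _flag_rm(rep, ref, g, cfg.alpha)
            flag_rows.append({"measure": label, "group": g, "vs": ref,
                              "p": p, "significant": sig,
                              "test": "two-way RM ANOVA + Bonferroni"})
        return deltas

    try:
        for m in ("MABP", "HR"):
            rm_measure(epoch_panel, m, f"delta_{m}")
        for m in ("fR", "VT", "VE"):
            rm_measure(ventilation, m, f"delta_{m}")
    except Exception as exc:
        raise PipelineError(f"stage stats (RM ANOVA): {exc}") from exc

    try:
        for series in ("SABP", "PI"):
            sub = variability[variability["series"] == series]
            for col in ("variance", "lf", "hf"):
                panel = sub.rename(columns={col: "value"})[["group", "value"]]
                rep = one_way_anova(panel)
                label = f"{series}_{col}"
                anova_tables[label] = rep
                for g in groups_in_order[1:]:
                    p, sig = _flag_oneway(rep, ref, g, cfg.alpha)
                    flag_rows.append({"measure": label, "group": g, "vs": ref,
                                      "p": p, "significant": sig,
                                      "test": "one-way ANOVA + Bonferroni"})
        for col in ("brs_all", "n_up_per_10k", "n_down_per_10k"):
            panel = baroreflex.rename(columns={col: "value"})[["group", "value"]]
            rep = one_way_anova(panel)
            anova_tables[col] = rep
            for g in groups_in_order[1:]:
                p, sig = _flag_oneway(rep, ref, g, cfg.alpha)
                flag_rows.append({"measure": col, "group": g, "vs": ref,
                                  "p": p, "significant": sig,
                                  "test": "one-way ANOVA + Bonferroni"})
    except Exception as exc:
        raise PipelineError(f"stage stats (one-way ANOVA): {exc}") from exc

    try:
        pfit = fit_poisson_longitudinal(scores, reference_group=ref)
        for g in groups_in_order[1:]:
            sub = pfit.contrasts[pfit.contrasts["group"] == g]
            p = float(sub["p"].min()) if not sub.empty else np.nan
            flag_rows.append({
                "measure": "grooming", "group": g, "vs": ref,
                "p": p, "significant": pfit.group_significant(g, cfg.alpha),
                "test": "longitudinal Poisson GLMM, Bonferroni over windows"})
    except Exception as exc:
        raise PipelineError(f"stage stats (Poisson model): {exc}") from exc

    dyads = {}
    dyad_results = {}
    node_stats = {}
    try:
        for g, ethos in per_group_etho.items():
            pooled = []
            windows = [tuple(w) for w in cfg.dyads["windows"]]
            for e in ethos:
                pooled += build_transition_table(e, windows)
            counts = sum((t.counts for t in pooled[1:]), pooled[0].counts.copy())
            merged = TransitionTable(counts, window_id=f"{g}:pooled")
            res = dyad_chi_square(merged, threshold=cfg.dyads["threshold"])
            dyad_results[g] = res
            stats_frames = [node_statistics(e, (windows[0][0], windows[-1][1]))
                            for e in ethos]
            node_stats[g] = (pd.concat(stats_frames)
                             .groupby("behavior_code", as_index=False).sum())
            dyads[g] = pd.DataFrame([
                {"from": d.pair[0], "to": d.pair[1], "observed": d.observed,
                 "expected": d.expected, "chi_square": d.chi_square,
                 "significant": d.significant, "skipped": d.skipped}
                for d in res])
    except Exception as exc:
        raise PipelineError(f"stage ethology (dyads): {exc}") from exc

    flags = pd.DataFrame(flag_rows)
    provenance = {
        "version": __version__,
        "seed": cfg.seed,
        "config_sha256": hashlib.sha256(
            yaml.safe_dump(cfg.to_dict(), sort_keys=True).encode()).hexdigest(),
        "n_animals": len(bundle),
        "groups": groups_in_order,
        "reference_group": ref,
        "epochs": cfg.epochs,
    }
    report = StudyReport(
        epoch_panel=epoch_panel, variability=variability,
        baroreflex=baroreflex, ventilation=ventilation,
        grooming_scores=grooming_scores, anova_tables=anova_tables,
        poisson_fit=pfit, dyads=dyads, flags=flags, provenance=provenance)
    report.dyad_results = dyad_results
    report.node_stats = node_stats
    return report


def _flag_oneway(report, ref: str, group: str, alpha: float):
    ph = report.posthoc
    sel = ph[((ph["group_1"] == ref) & (ph["group_2"] == group)) |
             ((ph["group_1"] == group) & (ph["group_2"] == ref))]
    if sel.empty:
        return np.nan, False
    # Bonferroni-protected pairwise test, gated on the omnibus F
    omni_p = report.effect("group")["p"]
    p = float(sel["p_adj"].min())
    return p, bool(omni_p < alpha and p < alpha)


def _write_report(report: StudyReport, cfg: StudyConfig, out: Path) -> None:
    def save(df: pd.DataFrame, name: str) -> None:
        df.to_csv(out / name, index=False, float_format=FLOAT_FMT)

    save(report.epoch_panel, "epoch_panel.csv")
    save(report.variability, "variability.csv")
    save(report.baroreflex, "baroreflex.csv")
    save(report.ventilation, "ventilation.csv")
    save(report.grooming_scores, "grooming_scores.csv")
    save(report.flags, "significance_summary.csv")
    for label, rep in report.anova_tables.items():
        save(rep.table, f"anova_{label}.csv")
        if rep.posthoc is not None:
            save(rep.posthoc, f"posthoc_{label}.csv")
    pf = report.poisson_fit
    save(pf.fitted_means, "poisson_fitted_means.csv")
    save(pf.contrasts, "poisson_contrasts.csv")
    for g, df in report.dyads.items():
        save(df, f"dyads_{g}.csv")
        if hasattr(report, "dyad_results"):
            export_flowchart(report.dyad_results[g], report.node_stats[g],
                             out / f"flowchart_{g}.dot")
    (out / "provenance.json").write_text(
        json.dumps(report.provenance, indent=1, sort_keys=True) + "\n")
    cfg.save(out / "config_used.yaml")
    lines = [f"groups: {report.provenance['groups']}",
             f"animals: {report.provenance['n_animals']}",
             f"sigma_b (grooming GLMM): {pf.sigma_b:.4f}"]
    (out / "run.log").write_text("\n".join(lines) + "\n")
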