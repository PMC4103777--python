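"""Grooming scoring, transition tables, dyad chi-square and the DOT export."""

import re

import numpy as np
import pandas as pd
import pytest

from cardioetho.core import Ethogram, ParameterError
from cardioetho.ethology import (GROOMING_CODES, TransitionTable,
                                 build_transition_table, chi_square_critical,
                                 dyad_chi_square, export_flowchart,
                                 node_statistics, score_grooming)
from cardioetho.synth import EthoSimParams, generate_ethogram


def _etho(events, session_s=3600.0):
    return Ethogram(pd.DataFrame(events, columns=["behavior_code", "onset_s",
                                                  "duration_s"]),
                    session_s=session_s)


class TestScoreGrooming:
    def test_no_grooming_all_zero(self):
        e = _etho([("SN", 0.0, 1800.0), ("WA", 1800.0, 1800.0)])
        s = score_grooming(e)
        assert s.counts.sum() == 0
        assert len(s.counts) == 12

    def test_full_window_scores_twenty(self):
        # grooming covering a whole 300-s window at 15-s sampling -> 20
        e = _etho([("SN", 0.0, 300.0), ("GRF", 300.0, 300.0),
                   ("IM", 600.0, 3000.0)])
        s = score_grooming(e)
        assert s.counts[1] == 20
        assert s.counts[0] == 0

    def test_unknown_codes_listed(self):
        e = _etho([("XXX", 0.0, 10.0), ("SN", 10.0, 3590.0)])
        with pytest.raises(ParameterError, match="XXX"):
            score_grooming(e)

    def test_score_conservation(self):
        e = generate_ethogram(EthoSimParams(seed=8,
                                            grooming_rate_multiplier=3.0))
        s = score_grooming(e)
        probes = np.arange(240) * 15.0
        g = e.events[e.events["behavior_code"].isin(GROOMING_CODES)]
        active = np.zeros(240, bool)
        for onset, dur in zip(g["onset_s"], g["duration_s"]):
            active |= (probes >= onset) & (probes < onset + dur)
        assert s.counts.sum() == active.sum()

    def test_occupancy_expectation(self):
        # windows of 20 probes against a known grooming occupancy p:
        # E[count] = 20 p over many simulated sessions
        from cardioetho.synth import (apply_grooming_multiplier,
                                      stationary_occupancy)
        base = EthoSimParams(seed=0)
        gmask = np.array([c in GROOMING_CODES for c in base.repertoire])
        P = apply_grooming_multiplier(base.transition_matrix, base.repertoire,
                                      1.0)
        p_occ = stationary_occupancy(P, base.dwell_mean_s)[gmask].sum()
        means = []
        for k in range(120):
            e = generate_ethogram(EthoSimParams(session_s=600, seed=5000 + k))
            means.append(score_grooming(e, window_len_s=300).counts.mean())
        assert np.mean(means) == pytest.approx(20 * p_occ, rel=0.1)


class TestTransitionTable:
    def test_single_pair(self):
        e = _etho([("SN", 0.0, 5.0), ("WA", 5.0, 5.0)], session_s=10)
        (t,) = build_transition_table(e)
        assert t.counts.loc["SN", "WA"] == 1
        assert t.total == 1

    def test_cycle_counts(self):
        rows = []
        t0 = 0.0
        for _ in range(10):
            for c in ("SN", "WA", "IM"):
                rows.append((c, t0, 1.0))
                t0 += 1.0
        e = _etho(rows, session_s=40)
        (t,) = build_transition_table(e)
        assert t.counts.loc["SN", "WA"] == 10
        assert t.counts.loc["WA", "IM"] == 10
        assert t.counts.loc["IM", "SN"] == 9
        assert t.total == 29

    def test_single_event_empty(self):
        e = _etho([("SN", 0.0, 10.0)], session_s=10)
        (t,) = build_transition_table(e)
        assert t.total == 0

    def test_windowing_splits_successions(self):
        e = _etho([("SN", 0.0, 4.0), ("WA", 4.0, 4.0), ("IM", 8.0, 4.0)],
                  session_s=12)
        t1, t2 = build_transition_table(e, windows=[(0, 8), (8, 12)])
        assert t1.total == 1       # SN->WA only; WA->IM spans the boundary
        assert t2.total == 0


class TestDyadChiSquare:
    def test_hand_computed_2x2(self):
        # 2x2 [[8,2],[2,8]]: all E = 5, X^2 = 4 * 9/5 = 7.2
        counts = pd.DataFrame(0, index=["SN", "WA", "IM"],
                              columns=["SN", "WA", "IM"])
        counts.loc["SN", "WA"] = 8
        counts.loc["SN", "IM"] = 2
        counts.loc["WA", "WA"] = 0
        counts.loc["IM", "WA"] = 2
        counts.loc["IM", "IM"] = 0
        # fill remaining so margins give the textbook table
        counts.loc["IM", "SN"] = 8
        t = TransitionTable(counts)
        res = {d.pair: d for d in dyad_chi_square(t)}
        d = res[("SN", "WA")]
        assert d.chi_square == pytest.approx(7.2)
        assert d.significant

    def test_uniform_transitions_null(self):
        # observed equals margin-expected everywhere -> X^2 identically 0
        counts = pd.DataFrame(5, index=["SN", "WA", "IM"],
                              columns=["SN", "WA", "IM"])
        t = TransitionTable(counts)
        results = dyad_chi_square(t)
        assert results
        for d in results:
            assert not d.skipped
            assert d.chi_square == pytest.approx(0.0, abs=1e-12)
            assert not d.significant

    def test_critical_value_is_3_84(self):
        assert round(chi_square_critical(0.05, 1), 2) == 3.84

    def test_low_expected_skipped(self):
        counts = pd.DataFrame(0, index=["SN", "WA", "IM"],
                              columns=["SN", "WA", "IM"])
        counts.loc["SN", "WA"] = 1
        counts.loc["WA", "IM"] = 1
        t = TransitionTable(counts)
        assert all(d.skipped for d in dyad_chi_square(t))

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(0)
        codes = ["SN", "WA", "IM", "ER"]
        M = pd.DataFrame(rng.integers(0, 15, (4, 4)), index=codes,
                         columns=codes)
        for c in codes:
            M.loc[c, c] = 0
        res1 = {d.pair: d.chi_square for d in dyad_chi_square(TransitionTable(M))}
        perm = ["WA", "ER", "SN", "IM"]
        M2 = M.loc[perm, perm]
        res2 = {d.pair: d.chi_square for d in dyad_chi_square(TransitionTable(M2))}
        assert set(res1) == set(res2)
        for pair, x2 in res1.items():
            assert res2[pair] == pytest.approx(x2, nan_ok=True)

    def test_null_calibration_label_shuffles(self):
        # shuffled event labels: ~5% of testable dyads significant at 3.84
        rng = np.random.default_rng(1)
        n_sig = n_tot = 0
        codes = np.array(["SN", "WA", "IM", "ER", "SCA"])
        for _ in range(500):
            seq = rng.choice(codes, size=60)
            rows = [(c, float(i), 1.0) for i, c in enumerate(seq)]
            e = _etho(rows, session_s=60)
            (t,) = build_transition_table(e, codes=codes)
            for d in dyad_chi_square(t):
                if not d.skipped:
                    n_tot += 1
                    n_sig += d.significant
        assert n_sig / n_tot <= 0.075


class TestExportFlowchart:
    def _parse_dot(self, text):
        assert text.startswith("digraph")
        nodes = re.findall(r'^\s*"(\w+)" \[frequency=(\d+)', text, re.M)
        edges = re.findall(r'^\s*"(\w+)" -> "(\w+)" \[weight=([\d.]+)', text, re.M)
        return nodes, edges

    def test_cycle_graph_all_edges_significant(self, tmp_path):
        rows = []
        t0 = 0.0
        for _ in range(10):
            for c in ("SN", "WA", "IM"):
                rows.append((c, t0, 1.0))
                t0 += 1.0
        e = _etho(rows, session_s=40)
        (t,) = build_transition_table(e, codes=("SN", "WA", "IM"))
        dyads = dyad_chi_square(t)
        out = tmp_path / "g.dot"
        export_flowchart(dyads, node_statistics(e), out)
        nodes, edges = self._parse_dot(out.read_text())
        assert {n for n, _ in nodes} == {"SN", "WA", "IM"}
        assert {(a, b) for a, b, _ in edges} == \
            {("SN", "WA"), ("WA", "IM"), ("IM", "SN")}

    def test_no_significant_dyads_no_edges(self, tmp_path):
        e = _etho([("SN", 0.0, 5.0), ("WA", 5.0, 5.0)], session_s=10)
        (t,) = build_transition_table(e)
        out = tmp_path / "g.dot"
        export_flowchart(dyad_chi_square(t), node_statistics(e), out)
        nodes, edges = self._parse_dot(out.read_text())
        assert len(nodes) == 2
        assert edges == []
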