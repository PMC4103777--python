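"""Generator contracts: determinism, ground-truth consistency, analytic
degenerate cases."""

import numpy as np
import pandas as pd
import pytest

from cardioetho.core import ParameterError
from cardioetho.ethology import GROOMING_CODES
from cardioetho.synth import (CardioSimParams, EthoSimParams, PlethSimParams,
                              apply_grooming_multiplier,
                              default_transition_matrix, generate_cohort,
                              generate_ethogram, generate_pap, generate_pleth,
                              stationary_occupancy)
from cardioetho.ventilation import CalibRecord


class TestGeneratePap:
    def test_noiseless_unmodulated_is_constant(self):
        p = CardioSimParams(duration_s=10, hr_bpm=360, lf_amp_mmHg=0,
                            resp_amp_mmHg=0, baro_gain_ms_per_mmHg=0,
                            noise_sd_mmHg=0, noise_sd_ms=0)
        _, truth = generate_pap(p)
        pi = truth["pi_ms"].to_numpy()[1:]
        assert np.allclose(pi, 60000.0 / 360.0, atol=1e-9)
        assert np.allclose(truth["sabp"], 125.0)

    def test_truth_table_slope_equals_baroreflex_gain(self):
        # PI_{n+1} = PI_mean + G (S_n - ref): least squares on the truth
        # table must recover G
        p = CardioSimParams(duration_s=340, lf_amp_mmHg=5.0,
                            noise_sd_mmHg=0.5, noise_sd_ms=0.5,
                            baro_gain_ms_per_mmHg=1.5, seed=1)
        _, truth = generate_pap(p)
        s = truth["sabp"].to_numpy()
        pi = truth["pi_ms"].to_numpy()
        slope = np.polyfit(s[1:-1], pi[2:], 1)[0]
        assert slope == pytest.approx(1.5, abs=0.1)
        assert len(truth) >= 2000

    def test_same_seed_bit_identical(self):
        p = CardioSimParams(duration_s=30, seed=9)
        t1, tr1 = generate_pap(p)
        t2, tr2 = generate_pap(CardioSimParams(duration_s=30, seed=9))
        assert np.array_equal(t1.values, t2.values)
        pd.testing.assert_frame_equal(tr1, tr2)

    def test_rendered_peaks_sit_on_truth_beat_times(self, noisy_pap):
        p, trace, truth = noisy_pap
        idx = np.round((truth["beat_time_s"].to_numpy() - trace.t0_s)
                       * trace.fs_hz).astype(int)
        idx = idx[(idx > 2) & (idx < trace.n - 3)]
        # each truth beat time must be a local maximum within one sample
        win = np.stack([trace.values[i - 2:i + 3] for i in idx])
        assert (win.argmax(axis=1) != 0).all() and (win.argmax(axis=1) != 4).all()

    def test_stationarity_sabp_variance_equals_noise(self):
        p = CardioSimParams(duration_s=900, lf_amp_mmHg=0, resp_amp_mmHg=0,
                            baro_gain_ms_per_mmHg=0, noise_sd_mmHg=2.0,
                            noise_sd_ms=0.5, seed=12)
        _, truth = generate_pap(p)
        assert len(truth) >= 5000
        assert truth["sabp"].var() == pytest.approx(4.0, rel=0.1)

    @pytest.mark.parametrize("bad", [
        {"duration_s": -1}, {"fs_hz": 50}, {"sabp_mmHg": 80, "dabp_mmHg": 90},
        {"hr_bpm": 0}, {"baro_gain_ms_per_mmHg": -1}])
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ParameterError):
            CardioSimParams(**bad)


class TestGeneratePleth:
    def test_exact_cycle_count(self):
        # 100 cycles per 60 s of artifact-free signal (calibration pulse
        # excluded by analyzing the segment after it)
        p = PlethSimParams(duration_s=64, fR_cpm=100, seed=0,
                           calib=CalibRecord(1.0, 1.0, time_s=1.0))
        trace, _ = generate_pleth(p)
        seg = trace.segment(4.0, 64.0)
        x = seg.values - seg.values.mean()
        crossings = np.sum((x[:-1] < 0) & (x[1:] >= 0))
        assert abs(crossings - 100) <= 1

    def test_movement_epoch_has_no_clean_cycles(self):
        from cardioetho.ventilation import detect_breaths
        p = PlethSimParams(duration_s=60, fR_cpm=100, seed=4,
                           movement_epochs=[(10.0, 20.0)],
                           calib=CalibRecord(1.0, 1.0, time_s=2.0))
        trace, _ = generate_pleth(p)
        onsets, _, _ = detect_breaths(
            trace, exclusion_epochs=[(10.0, 20.0), (1.0, 4.0)])
        assert not np.any((onsets >= 10.0) & (onsets < 20.0))
        # ~ (60 - 10 - 3) s of clean signal at 100 cpm
        assert onsets.size == pytest.approx(78, abs=4)

    def test_calib_movement_overlap_rejected(self):
        with pytest.raises(ParameterError):
            PlethSimParams(duration_s=60, movement_epochs=[(1.0, 5.0)],
                           calib=CalibRecord(1.0, 1.0, time_s=2.0))

    def test_determinism(self):
        a, _ = generate_pleth(PlethSimParams(duration_s=30, seed=7,
                                             noise_sd=0.02))
        b, _ = generate_pleth(PlethSimParams(duration_s=30, seed=7,
                                             noise_sd=0.02))
        assert np.array_equal(a.values, b.values)


class TestGenerateEthogram:
    def test_two_state_chain_alternates(self):
        P = np.array([[0.0, 1.0], [1.0, 0.0]])
        p = EthoSimParams(repertoire=("SN", "WA"), transition_matrix=P,
                          dwell_mean_s=1.0, session_s=120, seed=0)
        e = generate_ethogram(p)
        codes = e.events["behavior_code"].to_numpy()
        assert all(a != b for a, b in zip(codes[:-1], codes[1:]))

    def test_events_bounded_by_session(self):
        e = generate_ethogram(EthoSimParams(session_s=3600, seed=2))
        ev = e.events
        assert ev["onset_s"].iloc[-1] < 3600
        assert (ev["onset_s"] + ev["duration_s"]).max() <= 3600 + 1e-9

    def test_grooming_multiplier_matches_stationary_occupancy(self):
        # mean grooming time ratio over many sessions approximates the
        # analytic semi-Markov stationary occupancy ratio
        base = EthoSimParams(seed=0)
        gmask = np.array([c in GROOMING_CODES for c in base.repertoire])
        occ = {}
        sim = {}
        for mult in (1.0, 5.0):
            P = apply_grooming_multiplier(base.transition_matrix,
                                          base.repertoire, mult)
            occ[mult] = stationary_occupancy(P, base.dwell_mean_s)[gmask].sum()
            tot = 0.0
            for s in range(60):
                e = generate_ethogram(EthoSimParams(
                    grooming_rate_multiplier=mult, session_s=1200,
                    seed=1000 + s))
                ev = e.events
                g = ev[ev["behavior_code"].isin(GROOMING_CODES)]
                tot += g["duration_s"].sum() / 1200.0
            sim[mult] = tot / 60
        assert sim[1.0] == pytest.approx(occ[1.0], rel=0.1)
        assert sim[5.0] == pytest.approx(occ[5.0], rel=0.1)
        assert sim[5.0] / sim[1.0] == pytest.approx(occ[5.0] / occ[1.0],
                                                    rel=0.15)

    def test_empty_repertoire_rejected(self):
        with pytest.raises(ParameterError):
            EthoSimParams(repertoire=())

    def test_transition_rows_must_be_stochastic(self):
        P = np.full((2, 2), 0.4)
        with pytest.raises(ParameterError):
            EthoSimParams(repertoire=("SN", "WA"), transition_matrix=P)


SMALL_DESIGN = {
    "session_s": 240.0,
    "baseline_s": 150.0,
    "groups": [
        {"name": "SAL", "n": 2, "effects": {}},
        {"name": "OT1", "n": 2, "effects": {"grooming_multiplier": 5.0,
                                            "map_ramp_mmHg": 20.0}},
    ],
}


class TestGenerateCohort:
    def test_layout_complete(self, tmp_path):
        bundle = generate_cohort(SMALL_DESIGN, seed=1, root=tmp_path)
        assert len(bundle) == 4
        for animal in bundle:
            d = tmp_path / animal
            for f in ("pap.csv", "pleth.csv", "etho.csv", "truth/beats.csv",
                      "truth/meta.json"):
                assert (d / f).exists(), f
        assert (tmp_path / "cohort.csv").exists()

    def test_master_seed_determinism(self):
        b1 = generate_cohort(SMALL_DESIGN, seed=11)
        b2 = generate_cohort(SMALL_DESIGN, seed=11)
        for a in b1:
            assert np.array_equal(b1[a].pap.values, b2[a].pap.values)
            assert np.array_equal(b1[a].pleth.values, b2[a].pleth.values)
            pd.testing.assert_frame_equal(b1[a].etho.events, b2[a].etho.events)

    def test_unknown_effect_key_rejected(self):
        bad = {"groups": [{"name": "X", "n": 1,
                           "effects": {"not_a_knob": 2}}]}
        with pytest.raises(ParameterError):
            generate_cohort(bad, seed=0)
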