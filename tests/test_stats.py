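"""ANOVA machinery against brute-force sums of squares and pingouin."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy.stats import f_oneway

from cardioetho.core import ParameterError
from cardioetho.stats import (bonferroni, deltas_from_baseline, one_way_anova,
                              two_way_rm_anova)


def _panel(Y, groups=None, prefix="g"):
    """Build a long panel from a (groups, subjects, times) cube."""
    a, n, b = Y.shape
    groups = groups or [f"{prefix}{i}" for i in range(a)]
    rows = []
    for gi, g in enumerate(groups):
        for s in range(n):
            for t in range(b):
                rows.append({"animal_id": f"{g}_s{s}", "group": g,
                             "time_label": f"t{t}", "value": float(Y[gi, s, t])})
    return pd.DataFrame(rows)


def brute_force_mixed_ss(Y):
    """Loop-based sums of squares for the mixed design (independent oracle)."""
    a, n, b = Y.shape
    grand = Y.mean()
    ss = {"group": 0.0, "subj": 0.0, "time": 0.0, "inter": 0.0, "total": 0.0}
    for g in range(a):
        ss["group"] += n * b * (Y[g].mean() - grand) ** 2
        for s in range(n):
            ss["subj"] += b * (Y[g, s].mean() - Y[g].mean()) ** 2
    for t in range(b):
        ss["time"] += a * n * (Y[:, :, t].mean() - grand) ** 2
    for g in range(a):
        for t in range(b):
            ss["inter"] += n * (Y[g, :, t].mean() - Y[g].mean()
                                - Y[:, :, t].mean() + grand) ** 2
    for g in range(a):
        for s in range(n):
            for t in range(b):
                ss["total"] += (Y[g, s, t] - grand) ** 2
    ss["error"] = ss["total"] - sum(ss[k] for k in
                                    ("group", "subj", "time", "inter"))
    return ss


class TestTwoWayRmAnova:
    @pytest.mark.parametrize("shape", [(2, 3, 2), (3, 4, 3), (4, 4, 4),
                                       (2, 2, 4), (4, 2, 2)])
    def test_matches_brute_force(self, shape):
        rng = np.random.default_rng(sum(shape))
        Y = rng.integers(0, 25, shape).astype(float)
        rep = two_way_rm_anova(_panel(Y), posthoc=False)
        ss = brute_force_mixed_ss(Y)
        tab = rep.table.set_index("effect")
        assert tab.loc["group", "SS"] == pytest.approx(ss["group"])
        assert tab.loc["subject(group)", "SS"] == pytest.approx(ss["subj"])
        assert tab.loc["time", "SS"] == pytest.approx(ss["time"])
        assert tab.loc["group:time", "SS"] == pytest.approx(ss["inter"])
        assert tab.loc["error(time)", "SS"] == pytest.approx(ss["error"],
                                                             abs=1e-8)

    def test_matches_pingouin(self):
        rng = np.random.default_rng(42)
        Y = rng.normal(10, 3, (3, 5, 4))
        rep = two_way_rm_anova(_panel(Y), posthoc=False)
        tab = rep.table.set_index("effect")
        pgt = pg.mixed_anova(data=_panel(Y), dv="value", within="time_label",
                             subject="animal_id", between="group"
                             ).set_index("Source")
        assert tab.loc["group", "F"] == pytest.approx(pgt.loc["group", "F"])
        assert tab.loc["time", "F"] == pytest.approx(pgt.loc["time_label", "F"])
        assert tab.loc["group:time", "F"] == \
            pytest.approx(pgt.loc["Interaction", "F"])
        assert tab.loc["group", "p"] == pytest.approx(pgt.loc["group", "p_unc"])

    def test_location_invariance(self):
        rng = np.random.default_rng(1)
        Y = rng.normal(0, 2, (2, 4, 3))
        f1 = two_way_rm_anova(_panel(Y), posthoc=False).table["F"]
        f2 = two_way_rm_anova(_panel(Y + 100.0), posthoc=False).table["F"]
        assert np.allclose(f1.dropna(), f2.dropna())

    def test_anova_identity_ss_decomposition(self):
        rng = np.random.default_rng(2)
        Y = rng.normal(5, 2, (3, 4, 4))
        tab = two_way_rm_anova(_panel(Y), posthoc=False).table
        grand = Y.mean()
        ss_total = ((Y - grand) ** 2).sum()
        assert tab["SS"].sum() == pytest.approx(ss_total, rel=1e-10)

    def test_type_i_error_calibrated(self):
        # null data: rejection rate of the group effect near alpha
        rng = np.random.default_rng(3)
        rej = 0
        n_rep = 400
        for _ in range(n_rep):
            Y = rng.normal(0, 1, (2, 5, 3))
            tab = two_way_rm_anova(_panel(Y), posthoc=False).table
            rej += tab.set_index("effect").loc["group", "p"] < 0.05
        assert 0.025 <= rej / n_rep <= 0.075

    def test_unbalanced_rejected(self):
        rng = np.random.default_rng(4)
        panel = _panel(rng.normal(0, 1, (2, 3, 3)))
        with pytest.raises(ParameterError):
            two_way_rm_anova(panel.iloc[:-1])


class TestOneWayAnova:
    def test_matches_scipy(self):
        rng = np.random.default_rng(0)
        data = {g: rng.normal(i, 1.0, 7) for i, g in enumerate("ABC")}
        rep = one_way_anova(data, posthoc=False)
        F, p = f_oneway(*data.values())
        assert rep.table.loc[0, "F"] == pytest.approx(F)
        assert rep.table.loc[0, "p"] == pytest.approx(p)

    def test_textbook_brute_force(self):
        data = {"a": [4.0, 6.0, 8.0], "b": [10.0, 12.0, 14.0],
                "c": [16.0, 18.0, 20.0]}
        rep = one_way_anova(data, posthoc=False)
        # grand mean 12; SS_between = 3*(6-12)^2+3*(12-12)^2+3*(18-12)^2 = 216
        # SS_within = 3 * ((-2)^2 + 0 + 2^2) = 24
        tab = rep.table.set_index("effect")
        assert tab.loc["group", "SS"] == pytest.approx(216.0)
        assert tab.loc["error", "SS"] == pytest.approx(24.0)
        assert tab.loc["group", "F"] == pytest.approx((216 / 2) / (24 / 6))

    def test_identical_groups_flagged(self):
        rep = one_way_anova({"a": [5.0, 5.0], "b": [5.0, 5.0]})
        assert np.isnan(rep.table.loc[0, "F"])
        assert rep.notes

    def test_scale_invariance_of_f(self):
        rng = np.random.default_rng(1)
        data = {g: rng.normal(i, 1.0, 6) for i, g in enumerate("AB")}
        f1 = one_way_anova(data, posthoc=False).table.loc[0, "F"]
        f2 = one_way_anova({g: 10 * v for g, v in data.items()},
                           posthoc=False).table.loc[0, "F"]
        assert f1 == pytest.approx(f2)

    def test_small_group_rejected(self):
        with pytest.raises(ParameterError):
            one_way_anova({"a": [1.0], "b": [1.0, 2.0]})


class TestBonferroni:
    def test_definition_and_cap(self):
        assert bonferroni([0.01], m=3)[0] == pytest.approx(0.03)
        assert bonferroni([0.3], m=4)[0] == 1.0
        assert np.allclose(bonferroni([0.2, 0.04], m=1), [0.2, 0.04])

    def test_monotone_in_m(self):
        p = [0.001, 0.02, 0.2]
        prev = np.zeros(3)
        for m in (1, 2, 5, 10):
            adj = bonferroni(p, m)
            assert np.all(adj >= prev)
            prev = adj

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            bonferroni([1.5])


class TestDeltas:
    def test_identity_and_shift(self):
        panel = pd.DataFrame({
            "animal_id": ["a", "a", "b", "b"],
            "group": ["G", "G", "G", "G"],
            "time_label": ["t1", "t2", "t1", "t2"],
            "value": [100.0, 120.0, 100.0, 100.0]})
        base = {"a": 100.0, "b": 100.0}
        d = deltas_from_baseline(panel, base)
        assert list(d["value"]) == [0.0, 20.0, 0.0, 0.0]

    def test_missing_baseline_named(self):
        panel = pd.DataFrame({"animal_id": ["a"], "group": ["G"],
                              "time_label": ["t1"], "value": [1.0]})
        with pytest.raises(ParameterError, match="a"):
            deltas_from_baseline(panel, {})
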