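"""Repeated-measures ANOVA, paired t, post hoc letters."""

import numpy as np
import pandas as pd
import pytest

import msreach as mr
from msreach.errors import BalanceError, DomainError


def long_table(values_by_subject, factor="condition"):
    """values_by_subject: {subject: {level: value}} -> long DataFrame."""
    rows = []
    for subj, levels in values_by_subject.items():
        for level, value in levels.items():
            rows.append({"participant": subj, factor: level, "mean_rate": value})
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_hand_computed_two_level_table(self):
        # diffs -1, -2, -2: mean -5/3, sd 0.577 => t = -5, F = t^2 = 25, df (1, 2)
        table = long_table({
            "p1": {"a": 1, "b": 2},
            "p2": {"a": 2, "b": 4},
            "p3": {"a": 3, "b": 5},
        })
        (res,) = mr.rm_anova(table)
        assert res.F == pytest.approx(25.0, rel=1e-9)
        assert (res.df_num, res.df_den) == (1, 2)

    def test_identical_cells_give_zero_f(self):
        table = long_table({f"p{i}": {"a": 1.0, "b": 1.0, "c": 1.0}
                            for i in range(5)})
        (res,) = mr.rm_anova(table)
        assert res.F == 0.0
        assert res.p == 1.0

    def test_participant_label_permutation_invariance(self, rng):
        data = {f"p{i}": {l: rng.normal() for l in "abcd"} for i in range(8)}
        (res1,) = mr.rm_anova(long_table(data))
        shuffled = dict(zip([f"q{i}" for i in range(8)], data.values()))
        (res2,) = mr.rm_anova(long_table(shuffled))
        assert res1.F == pytest.approx(res2.F, rel=1e-12)

    def test_f_equals_t_squared_two_levels(self, rng):
        data = {f"p{i}": {"a": rng.normal(), "b": rng.normal()}
                for i in range(10)}
        table = long_table(data)
        (res,) = mr.rm_anova(table)
        x = np.array([data[s]["a"] for s in data])
        y = np.array([data[s]["b"] for s in data])
        t, df, p = mr.paired_t(x, y)
        assert res.F == pytest.approx(t**2, rel=1e-9)
        assert res.p == pytest.approx(p, rel=1e-9)

    def test_two_way_returns_three_effects(self, rng):
        rows = []
        for i in range(6):
            for z in ("z1", "z2"):
                for c in "abcd":
                    rows.append({"participant": f"p{i}", "zone": z,
                                 "condition": c, "mean_rate": rng.normal()})
        res = mr.rm_anova(pd.DataFrame(rows), within=("zone", "condition"))
        assert [r.effect for r in res] == ["zone", "condition", "zone * condition"]
        assert all(r.df_den > 0 for r in res)

    def test_missing_cell_raises_balance_error(self):
        table = long_table({"p1": {"a": 1, "b": 2}, "p2": {"a": 2}})
        with pytest.raises(BalanceError):
            mr.rm_anova(table)

    def test_cross_check_against_statsmodels(self, rng):
        from statsmodels.stats.anova import AnovaRM
        data = {f"p{i}": {l: rng.normal() for l in "abcd"} for i in range(9)}
        table = long_table(data)
        (res,) = mr.rm_anova(table)
        sm = AnovaRM(table, depvar="mean_rate", subject="participant",
                     within=["condition"]).fit()
        assert res.F == pytest.approx(
            float(sm.anova_table["F Value"].iloc[0]), rel=1e-9
        )


class TestPairedT:
    def test_hand_arithmetic(self):
        x = np.array([2.0, 3.0, 4.0])
        y = np.array([1.0, 1.0, 1.0])
        t, df, p = mr.paired_t(x, y)
        assert t == pytest.approx(2.0 / (1.0 / np.sqrt(3.0)), rel=1e-9)
        assert df == 2

    def test_antisymmetry(self, rng):
        x, y = rng.normal(size=10), rng.normal(size=10)
        t1, _, p1 = mr.paired_t(x, y)
        t2, _, p2 = mr.paired_t(y, x)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_zero_variance_degenerate(self):
        x = np.array([1.0, 2.0, 3.0])
        with pytest.raises(DomainError):
            mr.paired_t(x, x)


class TestPosthoc:
    def test_identical_levels_share_one_letter(self):
        table = long_table({f"p{i}": {l: 1.0 for l in "abcd"} for i in range(6)})
        _, letters = mr.posthoc_pairwise(table)
        assert len(set(letters.values())) == 1

    def test_shifted_level_gets_distinct_letter(self, rng):
        data = {}
        for i in range(10):
            data[f"p{i}"] = {"a": rng.normal(0, 0.01),
                             "b": rng.normal(0, 0.01),
                             "c": rng.normal(0, 0.01),
                             "d": 5.0 + rng.normal(0, 0.01)}
        comps, letters = mr.posthoc_pairwise(long_table(data))
        assert letters["d"] not in (letters["a"], letters["b"], letters["c"])
        assert letters["a"] == letters["b"] == letters["c"]

    def test_holm_adjusted_p_at_least_raw(self, rng):
        data = {f"p{i}": {l: rng.normal() for l in "abcd"} for i in range(8)}
        comps, _ = mr.posthoc_pairwise(long_table(data), correction="holm")
        for c in comps:
            assert c.p_adj >= c.p_raw - 1e-15


class TestReport:
    def test_empty_report_raises(self, tmp_path):
        with pytest.raises(mr.EmptyReportError):
            mr.build_report(pd.DataFrame(), {}, tmp_path)

    def test_report_writes_tables_and_figures(self, tmp_path, rng):
        rows = []
        for i in range(5):
            for c in ("cue_monitoring", "cursor_tracking",
                      "reach_visible", "reach_invisible"):
                for z in ("initial_fixation", "pre_cue_250", "post_inhibition"):
                    rows.append({"participant": f"p{i}", "condition": c,
                                 "zone": z, "mean_rate": abs(rng.normal(1, 0.2))})
        table = pd.DataFrame(rows)
        trials = [mr.TrialEvents(-1.9, 0.9, [0.1], [0.15])]
        curves = {"cue_monitoring": mr.rate_state_method(trials)}
        log = mr.build_report(table, curves, tmp_path)
        assert (tmp_path / "zone_summary.csv").exists()
        assert (tmp_path / "rate_curves.png").exists()
        assert (tmp_path / "zone_bars.png").exists()
        assert (tmp_path / "stats.json").exists()
        assert "anovas" in log

    def test_report_deterministic_tables(self, tmp_path, rng):
        rows = []
        for i in range(4):
            for c in ("a", "b"):
                rows.append({"participant": f"p{i}", "condition": c,
                             "zone": "pre_cue_250", "mean_rate": float(i + (c == "b"))})
        table = pd.DataFrame(rows)
        mr.build_report(table.sample(frac=1, random_state=1), {}, tmp_path / "r1")
        mr.build_report(table.sample(frac=1, random_state=7), {}, tmp_path / "r2")
        b1 = (tmp_path / "r1" / "zone_summary.csv").read_bytes()
        b2 = (tmp_path / "r2" / "zone_summary.csv").read_bytes()
        assert b1 == b2
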