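"""Kaplan-Meier and log-rank against hand calculations and lifelines."""

import numpy as np
import pandas as pd
import pytest

from pgxbeacon.survival import (
    SurvivalRecord,
    build_survival_records,
    km_estimate,
    logrank_test,
    survival_plot,
)

from conftest import random_survival_records

WORKED = [
    SurvivalRecord("a", 5, False),
    SurvivalRecord("b", 10, True),
    SurvivalRecord("c", 15, True),
    SurvivalRecord("d", 20, False),
]


class TestKM:
    def test_worked_product_limit_example(self):
        # events at 10 (3 at risk) and 15 (2 at risk):
        # S(10) = 1 - 1/3 = 2/3;  S(15) = 2/3 * (1 - 1/2) = 1/3;  flat after
        km = km_estimate(WORKED)
        assert km.survival_at(9.99) == 1.0
        assert km.survival_at(10) == pytest.approx(2 / 3, abs=1e-12)
        assert km.survival_at(15) == pytest.approx(1 / 3, abs=1e-12)
        assert km.survival_at(20) == pytest.approx(1 / 3, abs=1e-12)
        np.testing.assert_array_equal(km.at_risk, [3, 2])
        np.testing.assert_array_equal(km.n_events, [1, 1])

    def test_all_censored_is_identically_one(self):
        km = km_estimate([SurvivalRecord(str(i), t, False) for i, t in enumerate([1, 2, 3])])
        assert len(km.event_times) == 0
        assert km.survival_at(100) == 1.0

    def test_single_event_record(self):
        km = km_estimate([SurvivalRecord("x", 7.0, True)])
        assert km.survival_at(6.9) == 1.0
        assert km.survival_at(7.0) == 0.0

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            SurvivalRecord("x", -1.0, True)

    def test_tied_censoring_still_at_risk(self):
        # censored at 5 counts in the risk set of the event at 5
        km = km_estimate(
            [SurvivalRecord("a", 5, True), SurvivalRecord("b", 5, False),
             SurvivalRecord("c", 8, False)]
        )
        assert km.at_risk[0] == 3
        assert km.survival_at(5) == pytest.approx(2 / 3)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_lifelines_on_random_data(self, seed):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(1000 + seed)
        records = random_survival_records(rng, n=60, groups=("g",))
        km = km_estimate(records)
        kmf = KaplanMeierFitter().fit(
            [r.time for r in records], [r.event for r in records]
        )
        for t, s in zip(km.event_times, km.survival):
            assert abs(s - float(kmf.predict(t))) < 1e-9

    def test_scale_invariance(self, rng):
        records = random_survival_records(rng, n=40, groups=("g",))
        km1 = km_estimate(records)
        scaled = [SurvivalRecord(r.individual_id, r.time * 365.25, r.event, r.group)
                  for r in records]
        km2 = km_estimate(scaled)
        np.testing.assert_allclose(km1.survival, km2.survival, atol=1e-12)
        np.testing.assert_allclose(km2.event_times, km1.event_times * 365.25)

    def test_censoring_monotonicity(self, rng):
        records = random_survival_records(rng, n=40, groups=("g",))
        base = km_estimate(records)
        flipped = list(records)
        event_idx = next(i for i, r in enumerate(flipped) if r.event)
        r = flipped[event_idx]
        flipped[event_idx] = SurvivalRecord(r.individual_id, r.time, False, r.group)
        relaxed = km_estimate(flipped)
        grid = np.linspace(0, max(x.time for x in records), 50)
        assert all(relaxed.survival_at(t) >= base.survival_at(t) - 1e-12 for t in grid)


class TestLogRank:
    def test_identical_groups_give_zero_statistic(self):
        records = [SurvivalRecord(f"a{i}", t, e, "g1") for i, (t, e) in
                   enumerate([(5, False), (10, True), (15, True), (20, False)])]
        records += [SurvivalRecord(f"b{i}", r.time, r.event, "g2")
                    for i, r in enumerate(records)]
        res = logrank_test(records)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_clearly_worse_group_detected(self):
        worse = [SurvivalRecord(f"w{i}", 1.0, True, "worse") for i in range(4)]
        res = logrank_test(WORKED + worse)
        assert res.statistic > 0
        assert res.df == 1

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two groups"):
            logrank_test(WORKED)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_lifelines_multivariate(self, seed):
        from lifelines.statistics import multivariate_logrank_test

        rng = np.random.default_rng(2000 + seed)
        records = random_survival_records(rng, n=30, groups=("g1", "g2", "g3"))
        res = logrank_test(records)
        ref = multivariate_logrank_test(
            [r.time for r in records],
            [r.group for r in records],
            [r.event for r in records],
        )
        assert res.df == 2
        assert abs(res.statistic - ref.test_statistic) < 1e-6
        assert abs(res.p_value - ref.p_value) < 1e-6

    def test_scale_invariance(self, rng):
        records = random_survival_records(rng, n=30)
        s1 = logrank_test(records).statistic
        scaled = [SurvivalRecord(r.individual_id, 7.3 * r.time, r.event, r.group)
                  for r in records]
        assert logrank_test(scaled).statistic == pytest.approx(s1, abs=1e-9)


class TestBridge:
    TABLE = pd.DataFrame(
        {
            "individual_id": [f"i{k}" for k in range(10)],
            "followup_time_days": [100, 200, None, 400, 500, 600, None, 800, 900, 1000],
            "vital_status": ["dead", "alive", "dead", "alive", "dead",
                             "alive", "dead", "resurrected", "dead", "alive"],
            "age": [40, 70, 55, 61, 45, 59, 62, 66, 71, 38],
        }
    )

    def test_null_rows_dropped_with_count(self):
        records, dropped = build_survival_records(
            self.TABLE, "followup_time_days", "vital_status", id_column="individual_id"
        )
        # 2 null times + 1 unmappable status label
        assert dropped == 3
        assert len(records) == 7

    def test_threshold_group_rule(self):
        records, _ = build_survival_records(
            self.TABLE, "followup_time_days", "vital_status",
            group="age", group_threshold=60,
        )
        labels = {r.group for r in records}
        assert labels == {"<60", ">=60"}

    def test_unknown_status_vocabulary_entry_dropped(self):
        records, dropped = build_survival_records(
            self.TABLE, "followup_time_days", "vital_status"
        )
        assert all(r.time != 800 for r in records)  # the 'resurrected' row
        assert dropped == 3

    def test_missing_column_named(self):
        with pytest.raises(KeyError, match="nope"):
            build_survival_records(self.TABLE, "nope", "vital_status")

    def test_all_rows_dropped_is_explicit_error(self):
        bad = pd.DataFrame({"t": [None], "s": ["dead"]})
        with pytest.raises(ValueError, match="no usable records"):
            build_survival_records(bad, "t", "s")


class TestPlot:
    def test_step_coordinates_start_at_origin(self, tmp_path):
        import matplotlib.pyplot as plt

        km = km_estimate(WORKED)
        fig, table = survival_plot(km, out=str(tmp_path / "km.svg"))
        first = table.iloc[0]
        assert (first["time"], first["survival"]) == (0.0, 1.0)
        assert (tmp_path / "km.svg").stat().st_size > 0
        plt.close(fig)

    def test_step_table_matches_curve_with_duplication(self):
        import matplotlib.pyplot as plt

        km = km_estimate(WORKED)
        fig, table = survival_plot(km, show_censor_marks=False, show_ci=False)
        expected_times = [0.0, 10.0, 10.0, 15.0, 15.0]
        assert list(table["time"]) == expected_times
        assert list(table["survival"])[:3] == [1.0, 1.0, pytest.approx(2 / 3)]
        plt.close(fig)

    def test_two_curves_legend(self, rng):
        import matplotlib.pyplot as plt

        records = random_survival_records(rng, n=20)
        curves = [
            km_estimate([r for r in records if r.group == g], group=g)
            for g in ("g1", "g2")
        ]
        fig, _ = survival_plot(curves, risk_table=True)
        labels = [t.get_text() for t in fig.axes[0].get_legend().get_texts()]
        assert labels == ["g1", "g2"]
        plt.close(fig)
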