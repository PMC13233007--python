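"""Visit-level processing: attribution, capping, imputation, summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from edmargin import (
    PeriodSummary,
    VisitRecord,
    attribute_admission_revenue,
    attribution_fraction,
    cap_revenue,
    impute_missing_revenue,
    process_visits,
    records_to_frame,
    summarize_period,
)
from edmargin.cohort import validate_visits


def percentile_oracle(values, q):
    """Independent linear-interpolation percentile (order statistics)."""
    xs = sorted(values)
    h = (len(xs) - 1) * q
    lo, hi = math.floor(h), math.ceil(h)
    return xs[lo] + (xs[hi] - xs[lo]) * (h - lo)


class TestAttribution:
    @pytest.mark.parametrize(
        "stay_revenue, hospital_los, expected",
        [
            (10_000, 48, 5_000),      # 24/48 of the stay's revenue
            (8_000, 20, 4_800),       # short stay: 12/20
            (5_000, 6, 5_000),        # 12/6 > 1 capped at the whole stay
            (0, 30, 0),
            (1_000, 24, 1_000),       # exactly one day is credited fully
        ],
    )
    def test_examples(self, stay_revenue, hospital_los, expected):
        assert attribute_admission_revenue(stay_revenue, hospital_los) == pytest.approx(expected)

    @pytest.mark.parametrize("bad_los", [0, -5])
    def test_nonpositive_los_rejected(self, bad_los):
        with pytest.raises(ValueError, match="hospital_los_hr"):
            attribute_admission_revenue(1000, bad_los)

    def test_negative_revenue_rejected(self):
        with pytest.raises(ValueError, match="stay_revenue"):
            attribute_admission_revenue(-1, 10)

    @given(st.floats(min_value=0.01, max_value=2000))
    def test_fraction_in_unit_interval(self, los):
        assert 0 < attribution_fraction(los) <= 1

    @given(st.floats(min_value=12.01, max_value=1000), st.floats(min_value=0.1, max_value=500))
    def test_fraction_monotone_beyond_half_day(self, los, delta):
        assert attribution_fraction(los + delta) <= attribution_fraction(los) + 1e-12


def _frame_with_attributed(values):
    n = len(values)
    return pd.DataFrame(
        {
            "visit_id": [str(i) for i in range(n)],
            "period": "pre",
            "disposition": "discharge",
            "payer": "medicare",
            "ed_los_min": 100.0,
            "attributed_revenue": values,
        }
    )


class TestCapping:
    def test_cap_matches_interpolation_oracle(self):
        values = list(range(1, 101))
        frame = _frame_with_attributed([float(v) for v in values])
        capped, cap = cap_revenue(frame, percentile=0.95)
        assert cap == pytest.approx(percentile_oracle(values, 0.95))
        assert cap == pytest.approx(95.05)
        assert (capped["capped_revenue"] <= cap + 1e-12).all()
        assert int(np.isclose(capped["capped_revenue"], cap).sum()) == 5
        untouched = frame["attributed_revenue"] <= cap
        pd.testing.assert_series_equal(
            capped.loc[untouched, "capped_revenue"],
            frame.loc[untouched, "attributed_revenue"],
            check_names=False,
        )

    def test_degenerate_distribution_unchanged(self):
        frame = _frame_with_attributed([42.0] * 10)
        capped, cap = cap_revenue(frame)
        assert cap == 42.0
        assert (capped["capped_revenue"] == 42.0).all()

    def test_percentile_one_is_identity(self):
        frame = _frame_with_attributed([5.0, 1.0, 9.0])
        capped, cap = cap_revenue(frame, percentile=1.0)
        assert cap == 9.0
        pd.testing.assert_series_equal(
            capped["capped_revenue"], frame["attributed_revenue"], check_names=False
        )

    def test_missing_values_stay_missing(self):
        frame = _frame_with_attributed([1.0, np.nan, 100.0, np.nan])
        capped, _ = cap_revenue(frame, percentile=0.5)
        assert capped["capped_revenue"].isna().sum() == 2

    def test_all_missing_rejected(self):
        frame = _frame_with_attributed([np.nan, np.nan])
        with pytest.raises(ValueError, match="missing"):
            cap_revenue(frame)

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_bad_percentile_rejected(self, bad):
        with pytest.raises(ValueError, match="percentile"):
            cap_revenue(_frame_with_attributed([1.0]), percentile=bad)

    @given(st.lists(st.floats(min_value=0, max_value=1e6), min_size=2, max_size=30),
           st.floats(min_value=0.05, max_value=1.0))
    def test_capping_never_increases_total(self, values, q):
        frame = _frame_with_attributed(values)
        capped, cap = cap_revenue(frame, percentile=q)
        assert capped["capped_revenue"].sum() <= frame["attributed_revenue"].sum() + 1e-9
        assert (capped["capped_revenue"] <= cap + 1e-9).all()


def _impute_frame(rows):
    frame = pd.DataFrame(rows, columns=["disposition", "payer", "capped_revenue"])
    frame["period"] = "pre"
    return frame


class TestImputation:
    def test_stratum_mean_assigned(self):
        frame = _impute_frame([
            ("admit", "medicare", 1000.0),
            ("admit", "medicare", 3000.0),
            ("admit", "medicare", np.nan),
        ])
        out = impute_missing_revenue(frame)
        assert out["final_revenue"].iloc[2] == pytest.approx(2000.0)
        assert out["imputed"].tolist() == [False, False, True]

    def test_no_missing_is_identity(self):
        frame = _impute_frame([("discharge", "private", 10.0), ("admit", "self_pay", 20.0)])
        out = impute_missing_revenue(frame)
        assert not out["imputed"].any()
        assert out["final_revenue"].tolist() == [10.0, 20.0]

    def test_toy_table_hand_arithmetic(self):
        # Two strata with one missing each; overall mean frozen by hand:
        # (1000+3000+2000 + 500+700+900+700 + 400) / 8 = 1150.
        frame = _impute_frame([
            ("admit", "medicare", 1000.0),
            ("admit", "medicare", 3000.0),
            ("admit", "medicare", np.nan),
            ("discharge", "private", 500.0),
            ("discharge", "private", 700.0),
            ("discharge", "private", 900.0),
            ("discharge", "private", np.nan),
            ("discharge", "medicaid", 400.0),
        ])
        out = impute_missing_revenue(frame)
        assert out["final_revenue"].iloc[2] == pytest.approx(2000.0)
        assert out["final_revenue"].iloc[6] == pytest.approx(700.0)
        assert out["final_revenue"].mean() == pytest.approx(1150.0)
        assert out["final_revenue"].notna().all()

    def test_empty_stratum_falls_back_to_overall_mean(self, caplog):
        frame = _impute_frame([
            ("admit", "medicare", 100.0),
            ("admit", "medicare", 300.0),
            ("discharge", "self_pay", np.nan),
        ])
        with caplog.at_level("WARNING", logger="edmargin.cohort"):
            out = impute_missing_revenue(frame)
        assert out["final_revenue"].iloc[2] == pytest.approx(200.0)
        assert "falling back" in caplog.text

    def test_nothing_observed_rejected(self):
        frame = _impute_frame([("admit", "medicare", np.nan)])
        with pytest.raises(ValueError, match="no observed revenue"):
            impute_missing_revenue(frame)


class TestSummarize:
    def _frame(self, revenues, los, period="pre"):
        return pd.DataFrame({
            "period": period,
            "final_revenue": revenues,
            "ed_los_min": los,
        })

    def test_hand_aggregates(self):
        s = summarize_period(self._frame([100.0, 200.0, 300.0], [10.0, 20.0, 30.0]), "pre")
        assert (s.n_visits, s.total_revenue, s.median_ed_los) == (3, 600.0, 20.0)
        assert s.revenue_per_visit == pytest.approx(200.0)

    def test_single_record(self):
        s = summarize_period(self._frame([55.0], [42.0]), "pre")
        assert (s.n_visits, s.total_revenue, s.median_ed_los) == (1, 55.0, 42.0)

    def test_empty_period_rejected(self):
        with pytest.raises(ValueError, match="no records"):
            summarize_period(self._frame([1.0], [5.0], period="post"), "pre")

    def test_missing_final_revenue_rejected(self):
        with pytest.raises(ValueError, match="final_revenue"):
            summarize_period(self._frame([np.nan], [5.0]), "pre")

    @given(st.lists(st.floats(min_value=0, max_value=1e7), min_size=1, max_size=50))
    def test_total_is_exact_fsum(self, revenues):
        s = summarize_period(self._frame(revenues, [10.0] * len(revenues)), "pre")
        assert s.total_revenue == math.fsum(revenues)

    def test_summary_invariants_enforced(self):
        with pytest.raises(ValueError):
            PeriodSummary(n_visits=0, total_revenue=1.0, median_ed_los=10.0)
        with pytest.raises(ValueError):
            PeriodSummary(n_visits=1, total_revenue=-1.0, median_ed_los=10.0)


class TestPipeline:
    def test_identity_on_clean_discharges(self):
        # No admits, no missing, no outliers beyond the cap -> revenue unchanged.
        records = [
            VisitRecord(f"v{i}", "pre", "discharge", "medicare", 100.0 + i,
                        stay_revenue=float(100 * (i + 1)))
            for i in range(10)
        ]
        result = process_visits(records_to_frame(records), percentile=1.0)
        assert result.frame["final_revenue"].tolist() == [100.0 * (i + 1) for i in range(10)]
        assert result.n_imputed == 0

    def test_imputed_iff_missing_on_input(self):
        records = [
            VisitRecord("a", "pre", "discharge", "private", 50.0, stay_revenue=100.0),
            VisitRecord("b", "pre", "discharge", "private", 60.0, stay_revenue=None),
            VisitRecord("c", "post", "admit", "medicare", 70.0,
                        hospital_los_hr=48.0, stay_revenue=2000.0),
        ]
        result = process_visits(records_to_frame(records))
        assert result.frame["imputed"].tolist() == [False, True, False]
        assert result.frame["final_revenue"].notna().all()
        # admit attribution: 24/48 of the whole stay
        assert result.frame["attributed_revenue"].iloc[2] == pytest.approx(1000.0)

    def test_imputed_values_never_exceed_cap(self):
        records = [
            VisitRecord(f"v{i}", "pre", "discharge", "medicaid", 100.0,
                        stay_revenue=v)
            for i, v in enumerate([10.0, 20.0, 30.0, 1e6, None])
        ]
        result = process_visits(records_to_frame(records), percentile=0.75)
        assert (result.frame["final_revenue"] <= result.cap_value + 1e-9).all()


class TestValidation:
    def _raw(self, **overrides):
        row = {
            "visit_id": "x", "period": "pre", "disposition": "discharge",
            "payer": "medicare", "ed_los_min": 100.0,
            "hospital_los_hr": None, "revenue_usd": 50.0,
        }
        row.update(overrides)
        return pd.DataFrame([row])

    def test_unknown_payer_rejected_with_row(self):
        with pytest.raises(ValueError, match="payer codes at rows 0"):
            validate_visits(self._raw(payer="tricare"))

    def test_lenient_maps_unknown_payer_to_other(self):
        out = validate_visits(self._raw(payer="tricare"), lenient_payers=True)
        assert out["payer"].iloc[0] == "other"

    def test_admit_requires_hospital_los(self):
        with pytest.raises(ValueError, match="hospital_los_hr"):
            validate_visits(self._raw(disposition="admit"))

    @pytest.mark.parametrize("field, value, pattern", [
        ("period", "mid", "period"),
        ("disposition", "transfer", "disposition"),
        ("ed_los_min", -1.0, "ed_los_min"),
        ("revenue_usd", -5.0, "revenue_usd"),
    ])
    def test_bad_values_rejected(self, field, value, pattern):
        with pytest.raises(ValueError, match=pattern):
            validate_visits(self._raw(**{field: value}))
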