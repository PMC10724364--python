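"""Importance records, heatmaps, curves, knees, shapes, recommendations."""

import json

import numpy as np
import pandas as pd
import pytest

from aicare.interpretability import (
    BinnedCurve,
    KneeFit,
    analyze_curves,
    cause_heatmap,
    classify_shape,
    collect_importance,
    export_trajectory,
    find_turning_point,
    importance_value_curve,
    recommendation_table,
    risk_direction,
)


def records_frame(rows):
    return pd.DataFrame(rows, columns=["patient_id", "date", "t", "feature",
                                       "value", "observed", "alpha",
                                       "y_pred", "outcome"])


def synthetic_records(rng, n_visits=2000, alpha_fn=None, value_sd=5.0,
                      feature="albumin", mean=35.0, outcome="survival"):
    values = rng.normal(mean, value_sd, size=n_visits)
    alphas = (np.full(n_visits, 0.0625) if alpha_fn is None
              else alpha_fn(values))
    rows = []
    for i, (v, a) in enumerate(zip(values, alphas)):
        rows.append((f"p{i % 50}", f"2010-01-{i % 28 + 1:02d}", i // 50,
                     feature, v, 1, a, 0.2, outcome))
    return records_frame(rows)


class TestCollectImportance:
    @pytest.fixture()
    def cv_like(self, two_patient_cohort):
        # hand-built predictions table shaped like run_cv output
        feat = two_patient_cohort.schema.dynamic_names
        rows = []
        for p in two_patient_cohort.patients:
            for t, v in enumerate(p.visits):
                row = {"fold": 0, "patient_id": p.patient_id, "t": t,
                       "date": v.date.isoformat(), "label": 0,
                       "y_pred": 0.3 + 0.1 * t}
                for name in feat:
                    row[f"alpha_{name}"] = 1 / 16
                rows.append(row)
        from aicare.training import CVResult
        return CVResult(model_kind="aicare", fold_metrics=pd.DataFrame(),
                        predictions=pd.DataFrame(rows))

    def test_record_count_is_visits_times_features(self, cv_like,
                                                   two_patient_cohort):
        rec = collect_importance(cv_like, two_patient_cohort)
        assert len(rec) == 6 * 16

    def test_alpha_sums_per_visit_are_one(self, cv_like, two_patient_cohort):
        rec = collect_importance(cv_like, two_patient_cohort)
        sums = rec.groupby(["patient_id", "t"])["alpha"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_survivor_records_carry_survival_outcome(self, cv_like,
                                                     two_patient_cohort):
        rec = collect_importance(cv_like, two_patient_cohort)
        assert set(rec[rec.patient_id == "A2"]["outcome"]) == {"survival"}
        assert set(rec[rec.patient_id == "A1"]["outcome"]) == {"GI"}

    def test_forward_filled_values_flagged_unobserved(self, cv_like,
                                                      two_patient_cohort):
        rec = collect_importance(cv_like, two_patient_cohort)
        a1_alb = rec[(rec.patient_id == "A1") & (rec.feature == "albumin")]
        assert a1_alb.sort_values("t")["observed"].tolist() == [1, 1, 0]
        # carried forward from the previous visit
        assert a1_alb.sort_values("t")["value"].tolist()[-1] == 36.5


class TestCauseHeatmap:
    def test_uniform_alpha_gives_uniform_row(self):
        rng = np.random.default_rng(0)
        rec = synthetic_records(rng, n_visits=160, outcome="GI")
        heat = cause_heatmap(rec)
        assert heat.matrix.loc["GI", "albumin"] == pytest.approx(0.0625)

    def test_mean_of_patient_means(self):
        rows = (
            [("a", "d", t, "albumin", 35.0, 1, 0.2, 0.5, "GI")
             for t in range(10)]  # long follow-up, alpha 0.2
            + [("b", "d", 0, "albumin", 35.0, 1, 0.4, 0.5, "GI")]
        )
        heat = cause_heatmap(records_frame(rows))
        # pooled-visit mean would be ~0.218; patient-mean average is 0.3
        assert heat.matrix.loc["GI", "albumin"] == pytest.approx(0.3)

    def test_low_support_rows_flagged(self):
        rows = [("a", "d", 0, "albumin", 35.0, 1, 0.1, 0.5, "cachexia")]
        heat = cause_heatmap(records_frame(rows), min_patients=5)
        assert heat.low_support_rows == ["cachexia"]

    def test_driving_feature_dominates_its_cause_row(self, small_planted_cohort):
        # deaths planted on albumin should give albumin a large share of
        # attention in a synthetic records table built from the hazard
        rng = np.random.default_rng(1)
        rows = []
        for i in range(40):
            alb = rng.normal(30, 4)
            other = rng.normal(0, 1)
            a_alb = 0.3 + 0.02 * max(32 - alb, 0)
            rows.append((f"d{i}", "d", 0, "albumin", alb, 1, a_alb, 0.7, "GI"))
            rows.append((f"d{i}", "d", 0, "wbc", other, 1,
                         (1 - a_alb) / 2, 0.7, "GI"))
            rows.append((f"d{i}", "d", 0, "sbp", other, 1,
                         (1 - a_alb) / 2, 0.7, "GI"))
        heat = cause_heatmap(records_frame(rows))
        row = heat.matrix.loc["GI"]
        assert row.idxmax() == "albumin"


class TestImportanceValueCurve:
    def test_constant_alpha_gives_flat_curve(self):
        rng = np.random.default_rng(2)
        curve = importance_value_curve(synthetic_records(rng), "albumin")
        assert curve.n_bins > 5
        np.testing.assert_allclose(curve.mean_alpha, 0.0625, atol=1e-12)

    def test_record_order_invariance(self):
        rng = np.random.default_rng(3)
        rec = synthetic_records(rng, alpha_fn=lambda v: 0.02 + 1e-4 * (v - 30) ** 2)
        a = importance_value_curve(rec, "albumin")
        b = importance_value_curve(rec.sample(frac=1.0, random_state=9),
                                   "albumin")
        np.testing.assert_array_equal(a.centers, b.centers)
        np.testing.assert_allclose(a.mean_alpha, b.mean_alpha)

    def test_planted_quadratic_vertex_recovered(self):
        rng = np.random.default_rng(4)
        rec = synthetic_records(
            rng, n_visits=4000,
            alpha_fn=lambda v: 0.01 + 3e-4 * (v - 32.0) ** 2)
        curve = importance_value_curve(rec, "albumin")
        vertex_bin = curve.centers[np.argmin(curve.mean_alpha)]
        assert abs(vertex_bin - 32.0) <= 1.5 * curve.bin_width

    def test_low_support_bins_dropped(self):
        rng = np.random.default_rng(5)
        rec = synthetic_records(rng, n_visits=300)
        curve = importance_value_curve(rec, "albumin", n_bins=40,
                                       min_support=20)
        assert (curve.support >= 20).all()

    def test_unknown_feature_rejected(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValueError):
            importance_value_curve(synthetic_records(rng), "nope")


def two_segment_curve(knee_idx=10, n=21, s_l=-1.0, s_r=0.5, noise=0.0,
                      rng=None):
    x = np.linspace(0.0, 10.0, n)
    k = x[knee_idx]
    y = 2.0 + s_l * np.minimum(x - k, 0) + s_r * np.maximum(x - k, 0)
    if noise and rng is not None:
        y = y + rng.normal(0, noise, size=n)
    return BinnedCurve("f", x, y, np.full(n, 100), float(x[1] - x[0]))


class TestFindTurningPoint:
    def test_exact_two_segment_data_recovered(self):
        curve = two_segment_curve(knee_idx=10)
        fit = find_turning_point(curve)
        assert fit.knee == pytest.approx(curve.centers[10])
        assert fit.rss == pytest.approx(0.0, abs=1e-18)
        assert fit.slope_left == pytest.approx(-1.0)
        assert fit.slope_right == pytest.approx(0.5)

    def test_symmetric_v_returns_center(self):
        curve = two_segment_curve(knee_idx=10, s_l=-1.0, s_r=1.0)
        assert find_turning_point(curve).knee == pytest.approx(
            curve.centers[10])

    def test_matches_exhaustive_grid_oracle(self):
        # independent oracle: same model space, different parameterization
        # (unconstrained two-line fit with continuity imposed via the basis
        # [1, x, hinge]) evaluated at every interior center
        rng = np.random.default_rng(7)
        for _ in range(20):
            curve = two_segment_curve(
                knee_idx=int(rng.integers(3, 18)),
                s_l=float(rng.normal(-1, 0.3)),
                s_r=float(rng.normal(0.3, 0.3)),
                noise=0.05, rng=rng)
            best_rss, best_knee = np.inf, None
            x, y = curve.centers, curve.mean_alpha
            for k in x[1:-1]:
                X = np.column_stack([np.ones_like(x), x - k,
                                     np.maximum(x - k, 0.0)])
                coef, *_ = np.linalg.lstsq(X, y, rcond=None)
                rss = float(((y - X @ coef) ** 2).sum())
                if rss < best_rss - 1e-15:
                    best_rss, best_knee = rss, k
            fit = find_turning_point(curve)
            assert fit.knee == pytest.approx(best_knee)
            assert fit.rss == pytest.approx(best_rss, abs=1e-9)

    def test_too_few_bins_rejected(self):
        short = BinnedCurve("f", np.arange(4.0), np.arange(4.0),
                            np.full(4, 30), 1.0)
        with pytest.raises(ValueError):
            find_turning_point(short)


class TestClassifyShape:
    def test_v_shape(self):
        curve = two_segment_curve(s_l=-1.0, s_r=1.0)
        assert classify_shape(curve, find_turning_point(curve)) == "V"

    def test_l_shape(self):
        curve = two_segment_curve(s_l=-1.0, s_r=0.0)
        assert classify_shape(curve, find_turning_point(curve)) == "L"

    def test_slight_right_slope_within_tolerance_is_still_l(self):
        curve = two_segment_curve(s_l=-1.0, s_r=0.2)  # below tau = 0.25
        assert classify_shape(curve, find_turning_point(curve)) == "L"

    def test_noise_only_curve_is_irregular(self):
        rng = np.random.default_rng(8)
        x = np.linspace(0, 10, 30)
        y = rng.normal(0.0625, 0.01, size=30)
        curve = BinnedCurve("wbc", x, y, np.full(30, 50), x[1] - x[0])
        fit = find_turning_point(curve)
        assert classify_shape(curve, fit) == "irregular"

    def test_rising_curve_is_irregular(self):
        curve = two_segment_curve(s_l=1.0, s_r=1.0)
        assert classify_shape(curve, find_turning_point(curve)) == "irregular"


class TestRecommendations:
    def make_summaries(self):
        rng = np.random.default_rng(9)
        frames = []
        # V-shaped attention, risk falls with value -> "higher"
        v_rec = synthetic_records(
            rng, alpha_fn=lambda v: 0.03 + 0.002 * np.abs(v - 32))
        v_rec["y_pred"] = 1 / (1 + np.exp(0.3 * (v_rec["value"] - 32)))
        frames.append(v_rec)
        # L-shaped attention on glucose-like feature, risk rises -> not-exceed
        l_rec = synthetic_records(
            rng, feature="glucose", mean=8.0, value_sd=2.5,
            alpha_fn=lambda v: 0.03 + 0.004 * np.maximum(6 - v, 0))
        l_rec["y_pred"] = 1 / (1 + np.exp(-0.4 * (l_rec["value"] - 6)))
        frames.append(l_rec)
        # pure noise -> irregular/unknown
        frames.append(synthetic_records(
            rng, feature="wbc", mean=7.8, value_sd=2.7,
            alpha_fn=lambda v: rng.normal(0.0625, 0.005, size=len(v))))
        return pd.concat(frames, ignore_index=True)

    def test_table_5_style_mappings(self):
        rec = self.make_summaries()
        summaries = analyze_curves(rec,
                                   features=["albumin", "glucose", "wbc"])
        table = recommendation_table(summaries).set_index("feature")
        assert summaries["albumin"].shape == "V"
        assert summaries["albumin"].direction < 0
        assert table.loc["albumin", "recommendation"] == "higher"
        assert table.loc["albumin", "turning_point"].startswith(">")
        assert summaries["glucose"].direction > 0
        assert table.loc["glucose", "recommendation"] == "not-exceed"
        assert table.loc["glucose", "turning_point"].startswith("<")
        assert table.loc["wbc", "recommendation"] == "unknown"
        assert table.loc["wbc", "variation_type"] == "irregular"
        # traditional reference ranges come along for consistency display
        assert table.loc["albumin", "ref_lower"] == 40.0

    def test_risk_direction_sign(self):
        rec = self.make_summaries()
        assert risk_direction(rec, "albumin") == -1
        assert risk_direction(rec, "glucose") == +1


class TestExportTrajectory:
    @pytest.fixture()
    def records(self):
        rows = []
        for t in range(3):
            for f, a in (("albumin", 0.5), ("sbp", 0.5)):
                rows.append(("A1", f"2010-0{t+1}-01", t, f, 30.0 + t, 1, a,
                             0.1 * (t + 1), "GI"))
        return records_frame(rows)

    def test_length_and_round_trip(self, records):
        doc = export_trajectory("A1", records)
        assert len(doc["visits"]) == 3
        parsed = json.loads(json.dumps(doc))
        assert parsed == doc
        assert parsed["outcome"] == "GI"

    def test_alpha_sums_to_one_per_visit(self, records):
        doc = export_trajectory("A1", records)
        for visit in doc["visits"]:
            total = sum(f["alpha"] for f in visit["features"].values())
            assert total == pytest.approx(1.0)

    def test_unknown_patient_rejected(self, records):
        with pytest.raises(KeyError):
            export_trajectory("nobody", records)
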