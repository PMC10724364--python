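"""From per-visit attention weights to clinical interpretability products.

Three artifacts, all computed from held-out-fold predictions:

* a cause-of-death stratified mean-importance heatmap (rows = mortality
  causes plus a "survival" row, columns = dynamic features);
* per-feature importance-vs-value curves: bin the raw feature values,
  average the attention weight per bin, locate the turning point with a
  single-knee piecewise-linear fit, and classify the curve shape as
  V (attention high at both extremes), L (attention decays to a plateau
  past the knee) or irregular;
* per-patient trajectory JSON documents for line-chart visualization
  (risk curve with per-feature dot sizes proportional to attention).

These are model-attention associations, not causal effect estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Cohort, OutcomeStatus
from .preprocessing import _forward_fill_matrix

__all__ = [
    "TRADITIONAL_REFERENCE_RANGES",
    "BinnedCurve",
    "KneeFit",
    "CurveSummary",
    "CauseImportanceMatrix",
    "collect_importance",
    "cause_heatmap",
    "importance_value_curve",
    "find_turning_point",
    "classify_shape",
    "risk_direction",
    "recommendation_table",
    "export_trajectory",
    "analyze_curves",
]

#: traditional outpatient clinical reference ranges, for consistency display
TRADITIONAL_REFERENCE_RANGES: dict[str, tuple[float, float] | None] = {
    "albumin": (40.0, 55.0),
    "dbp": (60.0, 80.0),
    "sbp": (100.0, 120.0),
    "cl": (96.0, 106.0),
    "cr": (62.0, 115.0),
    "urea": (3.1, 9.0),
    "ca": (2.25, 2.75),
    "na": (135.0, 145.0),
    "k": (3.5, 5.5),
    "p": (1.1, 1.3),
    "co2cp": (20.0, 29.0),
    "hb": (115.0, 150.0),
    "weight": None,
    "glucose": (3.9, 6.1),
    "hscrp": (0.5, 10.0),
    "wbc": (3.5, 9.5),
}

SURVIVAL_ROW = "survival"


def collect_importance(cv_result, cohort: Cohort) -> pd.DataFrame:
    """Long table: one row per (visit, feature) with raw value, attention
    weight, predicted risk and outcome metadata.

    Raw values are pre-scaling; a value missing at a visit is the
    forward-filled raw value (fallback: cohort-wide median of observed
    values), flagged ``observed=0``. Uncertain visits are included —
    interpretability uses all visits, only loss/metrics exclude them.
    """
    preds = cv_result.predictions
    feat_names = [c[len("alpha_"):] for c in preds.columns
                  if c.startswith("alpha_")]
    if not feat_names:
        raise ValueError("predictions carry no alpha_* columns")

    medians = {}
    for name in feat_names:
        vals = [v.values[name] for p in cohort.patients for v in p.visits
                if name in v.values]
        medians[name] = float(np.median(vals)) if vals else 0.0
    fallbacks = np.array([medians[n] for n in feat_names])

    value_frames = []
    cause_of: dict[str, str] = {}
    col = {name: j for j, name in enumerate(feat_names)}
    for p in cohort.patients:
        T = len(p.visits)
        raw = np.full((T, len(feat_names)), np.nan)
        for t, v in enumerate(p.visits):
            for name, val in v.values.items():
                if name in col:
                    raw[t, col[name]] = val
        filled, mask = _forward_fill_matrix(raw, fallbacks)
        value_frames.append(pd.DataFrame({
            "patient_id": p.patient_id,
            "t": np.repeat(np.arange(T), len(feat_names)),
            "feature": np.tile(feat_names, T),
            "value": filled.ravel(),
            "observed": mask.ravel().astype(int),
        }))
        cause_of[p.patient_id] = (
            (p.outcome.cause or "unknown")
            if p.outcome.status is OutcomeStatus.DECEASED else SURVIVAL_ROW)
    values_long = pd.concat(value_frames, ignore_index=True)

    alpha_cols = [f"alpha_{n}" for n in feat_names]
    long = preds.melt(
        id_vars=["patient_id", "date", "t", "y_pred"],
        value_vars=alpha_cols, var_name="feature", value_name="alpha")
    long["feature"] = long["feature"].str[len("alpha_"):]
    long["patient_id"] = long["patient_id"].astype(str)
    long["t"] = long["t"].astype(int)
    out = long.merge(values_long, on=["patient_id", "t", "feature"],
                     how="left", validate="many_to_one")
    out["outcome"] = out["patient_id"].map(cause_of)
    return out[["patient_id", "date", "t", "feature", "value", "observed",
                "alpha", "y_pred", "outcome"]]


@dataclass
class CauseImportanceMatrix:
    """Mean attention per (cause of death, feature); survivors are a row."""

    matrix: pd.DataFrame            # rows causes, columns features
    patient_counts: pd.Series       # patients per row
    min_patients: int = 5

    @property
    def low_support_rows(self) -> list[str]:
        return [c for c, n in self.patient_counts.items()
                if n < self.min_patients]


def cause_heatmap(records: pd.DataFrame, min_patients: int = 5
                  ) -> CauseImportanceMatrix:
    """Mean-of-patient-means attention per cause and feature.

    Each patient's visits are first averaged so long-follow-up patients do
    not dominate, then patient means are averaged within each cause group.
    """
    per_patient = (records
                   .groupby(["outcome", "patient_id", "feature"], sort=True)
                   ["alpha"].mean().reset_index())
    matrix = (per_patient
              .groupby(["outcome", "feature"], sort=True)["alpha"].mean()
              .unstack("feature"))
    counts = (per_patient.groupby("outcome")["patient_id"]
              .nunique().reindex(matrix.index))
    return CauseImportanceMatrix(matrix=matrix, patient_counts=counts,
                                 min_patients=min_patients)


@dataclass
class BinnedCurve:
    feature: str
    centers: np.ndarray       # retained bin centers, raw units, ascending
    mean_alpha: np.ndarray    # smoothed per-bin mean attention
    support: np.ndarray       # records per retained bin
    bin_width: float

    @property
    def n_bins(self) -> int:
        return len(self.centers)


def importance_value_curve(records: pd.DataFrame, feature: str,
                           n_bins: int = 40, min_support: int = 20
                           ) -> BinnedCurve:
    """Binned mean-attention curve over the raw value range of one feature.

    Equal-width bins between the 1st and 99th percentile of values; per-bin
    mean attention; 3-bin moving-average smoothing; bins with fewer than
    ``min_support`` records dropped.
    """
    sub = records[records["feature"] == feature]
    if len(sub) < min_support:
        raise ValueError(f"fewer than {min_support} records for {feature!r}")
    vals = sub["value"].to_numpy(dtype=float)
    alphas = sub["alpha"].to_numpy(dtype=float)
    lo, hi = np.percentile(vals, [1.0, 99.0])
    if hi <= lo:
        raise ValueError(f"degenerate value range for {feature!r}")
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(vals, edges) - 1, 0, n_bins - 1)
    in_range = (vals >= lo) & (vals <= hi)

    means = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = in_range & (idx == b)
        counts[b] = int(sel.sum())
        if counts[b]:
            means[b] = alphas[sel].mean()

    # centered 3-bin moving average, NaN-aware, shrinking at the ends
    smoothed = np.full(n_bins, np.nan)
    for b in range(n_bins):
        window = means[max(0, b - 1):b + 2]
        if np.any(~np.isnan(window)):
            smoothed[b] = np.nanmean(window)

    keep = (counts >= min_support) & ~np.isnan(smoothed)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return BinnedCurve(
        feature=feature,
        centers=centers[keep],
        mean_alpha=smoothed[keep],
        support=counts[keep],
        bin_width=float(edges[1] - edges[0]),
    )


@dataclass
class KneeFit:
    knee: float          # raw units
    slope_left: float    # fitted slope start -> knee
    slope_right: float   # fitted slope knee -> end
    intercept: float     # fitted value at the knee
    rss: float
    r2: float

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return (self.intercept
                + self.slope_left * np.minimum(x - self.knee, 0.0)
                + self.slope_right * np.maximum(x - self.knee, 0.0))


def _fit_at_knee(x: np.ndarray, y: np.ndarray, knee: float) -> KneeFit:
    X = np.column_stack([
        np.ones_like(x),
        np.minimum(x - knee, 0.0),
        np.maximum(x - knee, 0.0),
    ])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    return KneeFit(knee=float(knee), slope_left=float(coef[1]),
                   slope_right=float(coef[2]), intercept=float(coef[0]),
                   rss=rss, r2=r2)


def find_turning_point(curve: BinnedCurve) -> KneeFit:
    """Single-knee continuous piecewise-linear least squares.

    Candidate knees are the interior bin centers; the knee minimizing the
    residual sum of squares wins (ties broken toward the smaller value).
    Requires at least 5 retained bins.
    """
    if curve.n_bins < 5:
        raise ValueError("need at least 5 retained bins to locate a knee")
    x, y = curve.centers, curve.mean_alpha
    best: KneeFit | None = None
    for knee in x[1:-1]:
        fit = _fit_at_knee(x, y, knee)
        if best is None or fit.rss < best.rss - 1e-15:
            best = fit
    assert best is not None
    return best


def classify_shape(curve: BinnedCurve, fit: KneeFit,
                   tau_ratio: float = 0.25, r2_min: float = 0.3) -> str:
    """V / L / irregular taxonomy of an importance-vs-value curve.

    With left slope ``s_l`` and right slope ``s_r`` of the fitted segments
    and tolerance ``tau = tau_ratio * |s_l|``: V when attention falls to the
    knee and rises past it (``s_l < 0`` and ``s_r > tau``); L when attention
    falls to the knee then plateaus (``s_l < 0`` and ``|s_r| <= tau``);
    anything else — including a poor fit (R^2 < ``r2_min``) — is irregular.
    """
    if fit.r2 < r2_min:
        return "irregular"
    s_l, s_r = fit.slope_left, fit.slope_right
    tau = tau_ratio * abs(s_l)
    if s_l < 0 and s_r > tau:
        return "V"
    if s_l < 0 and abs(s_r) <= tau:
        return "L"
    return "irregular"


def risk_direction(records: pd.DataFrame, feature: str) -> float:
    """Sign of the value-risk association on high-attention records.

    Correlation between raw value and predicted risk restricted to records
    whose attention exceeds the feature's median attention (low-attention
    records carry little signal about how the model reads the value).
    Returns +1, -1 or 0 (undetermined).
    """
    sub = records[records["feature"] == feature]
    if len(sub) < 10:
        return 0.0
    med = sub["alpha"].median()
    high = sub[sub["alpha"] > med]
    if len(high) < 10 or high["value"].std() == 0 or high["y_pred"].std() == 0:
        return 0.0
    r = float(np.corrcoef(high["value"], high["y_pred"])[0, 1])
    if not np.isfinite(r) or abs(r) < 0.02:
        return 0.0
    return float(np.sign(r))


@dataclass
class CurveSummary:
    """One row of the recommendation report."""

    feature: str
    curve: BinnedCurve
    fit: KneeFit | None
    shape: str
    direction: float
    recommendation: str
    turning_point: float | None
    reference_range: tuple[float, float] | None = None


def _recommend(shape: str, direction: float) -> str:
    if shape == "V":
        if direction < 0:
            return "higher"       # push the value above the knee
        if direction > 0:
            return "not-exceed"
        return "unknown"
    if shape == "L":
        if direction < 0:
            return "at-least"     # keep above the knee; more adds little
        if direction > 0:
            return "not-exceed"
        return "unknown"
    return "unknown"


def analyze_curves(records: pd.DataFrame, features=None, n_bins: int = 40,
                   min_support: int = 20,
                   reference_ranges: dict | None = None
                   ) -> dict[str, CurveSummary]:
    """Full per-feature curve pipeline: bin, locate knee, classify, recommend."""
    if features is None:
        features = sorted(records["feature"].unique())
    refs = TRADITIONAL_REFERENCE_RANGES if reference_ranges is None \
        else reference_ranges
    out: dict[str, CurveSummary] = {}
    for feat in features:
        try:
            curve = importance_value_curve(records, feat, n_bins=n_bins,
                                           min_support=min_support)
            fit = find_turning_point(curve)
        except ValueError:
            empty = BinnedCurve(feat, np.array([]), np.array([]),
                                np.array([], dtype=int), 0.0)
            out[feat] = CurveSummary(feat, empty, None, "irregular", 0.0,
                                     "unknown", None, refs.get(feat))
            continue
        shape = classify_shape(curve, fit)
        direction = risk_direction(records, feat)
        out[feat] = CurveSummary(
            feature=feat,
            curve=curve,
            fit=fit,
            shape=shape,
            direction=direction,
            recommendation=_recommend(shape, direction),
            turning_point=fit.knee if shape in ("V", "L") else None,
            reference_range=refs.get(feat),
        )
    return out


def recommendation_table(summaries: dict[str, CurveSummary],
                         units: dict[str, str] | None = None) -> pd.DataFrame:
    """Tabular report: variation type, recommendation and turning point per
    feature, with the traditional reference range for consistency display."""
    rows = []
    for feat, s in summaries.items():
        ref = s.reference_range
        tp = s.turning_point
        if s.recommendation in ("higher", "at-least") and tp is not None:
            rec_value = f">{tp:g}"
        elif s.recommendation == "not-exceed" and tp is not None:
            rec_value = f"<{tp:g}"
        else:
            rec_value = "-"
        rows.append({
            "feature": feat,
            "unit": (units or {}).get(feat, ""),
            "variation_type": {"V": "V shape", "L": "L shape"}.get(
                s.shape, "irregular"),
            "recommendation": s.recommendation,
            "turning_point": rec_value,
            "ref_lower": ref[0] if ref else np.nan,
            "ref_upper": ref[1] if ref else np.nan,
        })
    return pd.DataFrame(rows)


TRAJECTORY_SCHEMA_VERSION = 1


def export_trajectory(patient_id: str, records: pd.DataFrame) -> dict:
    """Per-patient trajectory document for the line-chart visualization.

    Time-ordered array of visits, each carrying the predicted risk and, per
    feature, the raw value and the attention weight (the dot size in the
    chart). JSON-serializable; schema versioned.
    """
    sub = records[records["patient_id"] == patient_id]
    if sub.empty:
        raise KeyError(f"no records for patient {patient_id!r}")
    visits = []
    for (t, date), grp in sorted(sub.groupby(["t", "date"], sort=False),
                                 key=lambda kv: kv[0][0]):
        visits.append({
            "t": int(t),
            "date": str(date),
            "y_pred": float(grp["y_pred"].iloc[0]),
            "features": {
                str(r["feature"]): {"value": float(r["value"]),
                                    "alpha": float(r["alpha"])}
                for _, r in grp.iterrows()
            },
        })
    return {
        "schema_version": TRAJECTORY_SCHEMA_VERSION,
        "patient_id": str(patient_id),
        "outcome": str(sub["outcome"].iloc[0]),
        "visits": visits,
    }
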