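"""Imputation, scaling and assembly of padded model inputs.

Missing lab values are forward-filled with the most recent previously
observed value for that patient and feature; leading missings fall back to
the training-fold median so that z-scored fallbacks sit near zero. Scaling
statistics are computed on *observed* (pre-imputation) training-fold values
only — test folds never influence them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Cohort
from .schema import FeatureSchema

__all__ = [
    "LABEL_POSITIVE",
    "LABEL_NEGATIVE",
    "LABEL_UNCERTAIN",
    "LABEL_PADDING",
    "ScalerStats",
    "ModelInput",
    "forward_fill",
    "fit_scaler",
    "assemble",
]

LABEL_POSITIVE = 1
LABEL_NEGATIVE = 0
LABEL_UNCERTAIN = -1
LABEL_PADDING = -2


def forward_fill(series, fallback: float) -> tuple[np.ndarray, np.ndarray]:
    """Last-observation-carried-forward imputation of one feature series.

    ``series`` is a sequence of optional reals (None/NaN = missing). Each
    missing entry is replaced by the latest prior observed value; leading
    missings by ``fallback``. Returns ``(filled, mask)`` with ``mask[t] = 1``
    where the original entry was observed. The output at position ``t``
    depends only on entries at positions ``<= t``.
    """
    filled = np.empty(len(series), dtype=float)
    mask = np.zeros(len(series), dtype=np.int8)
    last = float(fallback)
    for t, v in enumerate(series):
        missing = v is None or (isinstance(v, float) and np.isnan(v))
        if not missing:
            last = float(v)
            mask[t] = 1
        filled[t] = last
    return filled, mask


def _forward_fill_matrix(values: np.ndarray, fallbacks: np.ndarray
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Columnwise forward fill of a (T, F) matrix with NaN = missing.

    Vectorized equivalent of running :func:`forward_fill` on every column;
    the loop form stays the reference implementation in the tests.
    """
    mask = ~np.isnan(values)
    idx = np.where(mask, np.arange(values.shape[0])[:, None], -1)
    carry = np.maximum.accumulate(idx, axis=0)
    filled = np.where(
        carry >= 0,
        np.take_along_axis(np.nan_to_num(values), np.maximum(carry, 0), axis=0),
        np.broadcast_to(fallbacks, values.shape),
    )
    return filled, mask.astype(np.int8)


@dataclass
class ScalerStats:
    """Per-feature location/scale/median from training-fold observed values.

    Features never observed in the training fold (or with zero variance) are
    listed in ``degenerate`` and are scaled to a constant 0 so they carry no
    signal into the model.
    """

    mean: dict[str, float]
    std: dict[str, float]
    median: dict[str, float]
    degenerate: list[str] = field(default_factory=list)

    def transform(self, name: str, x: np.ndarray) -> np.ndarray:
        if name in self.degenerate:
            return np.zeros_like(np.asarray(x, dtype=float))
        return (np.asarray(x, dtype=float) - self.mean[name]) / self.std[name]


def fit_scaler(cohort: Cohort, train_patient_ids) -> ScalerStats:
    """Fit z-score statistics on observed training-fold values only.

    Uses the sample standard deviation (ddof=1). Static binary features
    (gender, diabetes) are passed through unscaled and are not fitted here.
    """
    train_ids = set(train_patient_ids)
    if not train_ids:
        raise ValueError("training id set is empty")
    schema = cohort.schema
    mean, std, median, degenerate = {}, {}, {}, []

    def _finish(name: str, vals: list[float]) -> None:
        arr = np.asarray(vals, dtype=float)
        if arr.size == 0:
            degenerate.append(name)
            mean[name], std[name], median[name] = 0.0, 1.0, 0.0
            return
        m = float(arr.mean())
        s = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        if s <= 0.0:
            degenerate.append(name)
            mean[name], std[name], median[name] = m, 1.0, float(np.median(arr))
            return
        mean[name], std[name], median[name] = m, s, float(np.median(arr))

    for f in schema.dynamic_features:
        vals = [
            v.values[f.name]
            for p in cohort.patients
            if p.patient_id in train_ids
            for v in p.visits
            if f.name in v.values
        ]
        _finish(f.name, vals)

    for f in schema.static_features:
        if f.binary:
            continue
        vals = [
            p.baseline[f.name]
            for p in cohort.patients
            if p.patient_id in train_ids and f.name in p.baseline
        ]
        _finish(f.name, vals)

    return ScalerStats(mean=mean, std=std, median=median, degenerate=degenerate)


@dataclass
class ModelInput:
    """Padded, masked, scaled arrays ready for the sequence model.

    dynamic   : float (N, maxT, F)   z-scored, forward-filled
    obs_mask  : int8  (N, maxT, F)   1 where the value was originally observed
    lengths   : int   (N,)           true sequence lengths
    static    : float (N, S)         z-scored numerics, raw binaries
    labels    : int8  (N, maxT)      1/0 pos/neg, -1 uncertain, -2 padding
    """

    dynamic: np.ndarray
    obs_mask: np.ndarray
    lengths: np.ndarray
    static: np.ndarray
    labels: np.ndarray
    patient_ids: list[str]
    dates: list[list[str]]
    feature_names: list[str]
    static_names: list[str]

    @property
    def n_patients(self) -> int:
        return self.dynamic.shape[0]

    @property
    def max_t(self) -> int:
        return self.dynamic.shape[1]

    @property
    def n_features(self) -> int:
        return self.dynamic.shape[2]

    def subset(self, idx) -> "ModelInput":
        idx = np.asarray(idx)
        max_t = int(self.lengths[idx].max())
        return ModelInput(
            dynamic=self.dynamic[idx, :max_t].copy(),
            obs_mask=self.obs_mask[idx, :max_t].copy(),
            lengths=self.lengths[idx].copy(),
            static=self.static[idx].copy(),
            labels=self.labels[idx, :max_t].copy(),
            patient_ids=[self.patient_ids[i] for i in idx],
            dates=[self.dates[i] for i in idx],
            feature_names=self.feature_names,
            static_names=self.static_names,
        )


_LABEL_CODE = {"positive": LABEL_POSITIVE, "negative": LABEL_NEGATIVE,
               "uncertain": LABEL_UNCERTAIN}


def assemble(
    cohort: Cohort,
    labels: pd.DataFrame,
    scaler: ScalerStats,
    patient_ids=None,
) -> ModelInput:
    """Build padded model inputs for the given patients (default: all).

    Dynamic features are forward-filled (fallback = training-fold median)
    and z-scored with the supplied scaler. Numeric statics are z-scored,
    binary statics passed through. Sequences are right-padded to the longest
    patient in the selection; padded positions carry the padding label code.
    """
    schema = cohort.schema
    if patient_ids is None:
        patient_ids = cohort.patient_ids
    patients = [cohort.patient(pid) for pid in patient_ids]

    label_of: dict[tuple[str, int], int] = {}
    for _, r in labels.iterrows():
        code = _LABEL_CODE.get(str(r["label"]))
        if code is not None:
            label_of[(str(r["patient_id"]), int(r["t"]))] = code

    n = len(patients)
    f_names = schema.dynamic_names
    s_feats = schema.static_features
    max_t = max(p.n_visits for p in patients)
    dynamic = np.zeros((n, max_t, len(f_names)), dtype=float)
    obs_mask = np.zeros((n, max_t, len(f_names)), dtype=np.int8)
    lab = np.full((n, max_t), LABEL_PADDING, dtype=np.int8)
    static = np.zeros((n, len(s_feats)), dtype=float)
    lengths = np.zeros(n, dtype=int)
    dates: list[list[str]] = []

    fallbacks = np.array([scaler.median[n] for n in f_names])
    means = np.array([scaler.mean[n] for n in f_names])
    stds = np.array([scaler.std[n] for n in f_names])
    dead = np.array([n in scaler.degenerate for n in f_names])

    for i, p in enumerate(patients):
        T = p.n_visits
        lengths[i] = T
        dates.append([v.date.isoformat() for v in p.visits])
        raw = np.full((T, len(f_names)), np.nan)
        col = {name: j for j, name in enumerate(f_names)}
        for t, v in enumerate(p.visits):
            for name, val in v.values.items():
                raw[t, col[name]] = val
        filled, mask = _forward_fill_matrix(raw, fallbacks)
        scaled = (filled - means) / stds
        scaled[:, dead] = 0.0
        dynamic[i, :T] = scaled
        obs_mask[i, :T] = mask
        for s, f in enumerate(s_feats):
            raw = p.baseline[f.name]
            static[i, s] = raw if f.binary else scaler.transform(f.name, np.array([raw]))[0]
        for t in range(T):
            lab[i, t] = label_of.get((p.patient_id, t), LABEL_UNCERTAIN)

    return ModelInput(
        dynamic=dynamic,
        obs_mask=obs_mask,
        lengths=lengths,
        static=static,
        labels=lab,
        patient_ids=list(patient_ids),
        dates=dates,
        feature_names=list(f_names),
        static_names=[f.name for f in s_feats],
    )
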