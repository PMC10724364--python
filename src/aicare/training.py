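"""Loss, discrimination metrics, cross-validated training, significance.

The primary metric is AUPRC (average precision) because positives — visits
within one year of death — are rare (~9% of labeled visits); AUROC is
reported alongside. Metrics are computed over pooled labeled visits within
each held-out fold, then averaged across folds.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats
from sklearn.metrics import average_precision_score, roc_auc_score

from ._autograd import Adam
from .io import Cohort
from .labeling import FoldAssignment, labeled_dataset
from .model import AICareNet, ModelConfig, PooledGRUBaseline, masked_bce_from_logits
from .preprocessing import (
    LABEL_NEGATIVE,
    LABEL_POSITIVE,
    ModelInput,
    assemble,
    fit_scaler,
)

__all__ = [
    "TrainConfig",
    "CVResult",
    "masked_bce_loss",
    "auprc",
    "auroc",
    "train_model",
    "run_cv",
    "compare_models",
]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 50
    batch_size: int = 64
    learning_rate: float = 1e-3
    early_stop_patience: int = 10
    positive_weight: float = 1.0
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if min(self.epochs, self.batch_size, self.early_stop_patience) < 1:
            raise ValueError("epochs, batch_size, patience must be positive")
        if self.learning_rate <= 0 or self.positive_weight <= 0:
            raise ValueError("learning_rate and positive_weight must be positive")
        if self.early_stop_patience > self.epochs:
            raise ValueError("patience must not exceed epochs")
        if not 0.0 < self.validation_fraction < 0.5:
            raise ValueError("validation_fraction must be in (0, 0.5)")


def masked_bce_loss(predictions: np.ndarray, labels: np.ndarray,
                    positive_weight: float = 1.0, eps: float = 1e-12) -> float:
    """Mean binary cross-entropy over labeled (positive/negative) visits.

    ``predictions`` are probabilities; ``labels`` uses the preprocessing
    codes (1 positive, 0 negative, -1 uncertain, -2 padding). Uncertain and
    padded positions contribute nothing. Raises if no position is labeled.
    """
    p = np.clip(np.asarray(predictions, dtype=float), eps, 1.0 - eps)
    lab = np.asarray(labels)
    w = np.where(lab == LABEL_POSITIVE, positive_weight, 0.0) \
        + (lab == LABEL_NEGATIVE).astype(float)
    if w.sum() <= 0:
        raise ValueError("no labeled visits: cannot compute the loss")
    y = (lab == LABEL_POSITIVE).astype(float)
    ll = -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    return float((ll * w).sum() / w.sum())


def _check_binary(labels) -> np.ndarray:
    raw = np.asarray(labels)
    if set(np.unique(raw)) - {0, 1, 0.0, 1.0, False, True}:
        raise ValueError("labels must be binary 0/1")
    y = raw.astype(int)
    if y.min() == y.max():
        raise ValueError("need at least one positive and one negative")
    return y


def auprc(labels, scores) -> float:
    """Average precision: step-wise integral of precision over recall.

    Equal scores are grouped (ties do not depend on input order).
    """
    y = _check_binary(labels)
    return float(average_precision_score(y, np.asarray(scores, dtype=float)))


def auroc(labels, scores) -> float:
    """Probability a random positive outscores a random negative
    (Mann-Whitney form; ties count 1/2)."""
    y = _check_binary(labels)
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def _labeled_scores(risk: np.ndarray, inp: ModelInput
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Pooled (labels, scores) over positive/negative visits."""
    keep = (inp.labels == LABEL_POSITIVE) | (inp.labels == LABEL_NEGATIVE)
    return (inp.labels[keep] == LABEL_POSITIVE).astype(int), risk[keep]


def _length_batches(lengths: np.ndarray, batch_size: int) -> list[np.ndarray]:
    """Group patient indices into batches of similar sequence length, so
    padding work stays proportional to real data."""
    order = np.argsort(lengths, kind="stable")
    return [order[i:i + batch_size] for i in range(0, len(order), batch_size)]


def train_model(net, train_inp: ModelInput, val_inp: ModelInput | None,
                cfg: TrainConfig) -> dict:
    """Minibatch Adam training with early stopping on validation AUPRC.

    Returns a history dict; the network is left holding the best-validation
    weights (or the final weights when no validation set is given).
    """
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(net.parameters(), lr=cfg.learning_rate)
    batches = _length_batches(train_inp.lengths, cfg.batch_size)
    history = {"train_loss": [], "val_auprc": []}
    best_metric, best_state, since_best = -np.inf, None, 0

    for epoch in range(cfg.epochs):
        order = rng.permutation(len(batches))
        epoch_loss = 0.0
        for bi in order:
            batch = train_inp.subset(batches[bi])
            opt.zero_grad()
            loss = net.loss(batch, positive_weight=cfg.positive_weight,
                            training=True)
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
        history["train_loss"].append(epoch_loss / len(batches))

        if val_inp is not None:
            risk = _first_output(net.forward(val_inp))
            y, s = _labeled_scores(risk, val_inp)
            metric = auprc(y, s) if 0 < y.sum() < len(y) else -_val_loss(risk, val_inp, cfg)
            history["val_auprc"].append(metric)
            if metric > best_metric + 1e-9:
                best_metric, best_state, since_best = metric, net.state_dict(), 0
            else:
                since_best += 1
                if since_best >= cfg.early_stop_patience:
                    break
    if best_state is not None:
        net.load_state_dict(best_state)
    return history


def _first_output(out):
    return out[0] if isinstance(out, tuple) else out


def _val_loss(risk, inp, cfg):
    return masked_bce_loss(np.nan_to_num(risk, nan=0.5), inp.labels,
                           cfg.positive_weight)


@dataclass
class CVResult:
    model_kind: str
    fold_metrics: pd.DataFrame  # fold, auprc, auroc, n_pos, n_neg
    predictions: pd.DataFrame   # patient_id, date, t, label, y_pred [, alpha_*]
    skipped_folds: list[int] = field(default_factory=list)
    fold_states: list[dict] | None = None

    @property
    def mean_auprc(self) -> float:
        return float(self.fold_metrics["auprc"].mean())

    @property
    def std_auprc(self) -> float:
        return float(self.fold_metrics["auprc"].std(ddof=1))

    @property
    def mean_auroc(self) -> float:
        return float(self.fold_metrics["auroc"].mean())

    @property
    def std_auroc(self) -> float:
        return float(self.fold_metrics["auroc"].std(ddof=1))


def _split_validation(cohort: Cohort, train_ids: list[str], frac: float,
                      seed: int) -> tuple[list[str], list[str]]:
    """Patient-level validation split, stratified on vital status."""
    from .io import OutcomeStatus

    rng = np.random.default_rng(seed)
    dead = [pid for pid in train_ids
            if cohort.patient(pid).outcome.status is OutcomeStatus.DECEASED]
    alive = [pid for pid in train_ids if pid not in set(dead)]
    rng.shuffle(dead)
    rng.shuffle(alive)
    n_vd = max(1, int(round(frac * len(dead)))) if dead else 0
    n_va = max(1, int(round(frac * len(alive)))) if alive else 0
    val = dead[:n_vd] + alive[:n_va]
    fit = dead[n_vd:] + alive[n_va:]
    return sorted(fit), sorted(val)


def run_cv(
    cohort: Cohort,
    folds: FoldAssignment,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    labels: pd.DataFrame | None = None,
    model_kind: str = "aicare",
    keep_states: bool = False,
) -> CVResult:
    """Cross-validated training and held-out evaluation.

    Per fold: fit the scaler on training patients only, train with early
    stopping on a patient-level validation split carved from the training
    fold, then score the held-out fold's labeled visits. Folds whose test
    split contains no positive (or no negative) visit are skipped with a
    warning entry. Deterministic given the fold assignment and seeds.
    """
    if labels is None:
        labels, _ = labeled_dataset(cohort)
    rows, pred_frames, skipped = [], [], []
    states: list[dict] = []

    for fold in range(folds.k):
        fold_seed = train_cfg.seed + 9973 * fold
        train_ids = folds.train_ids(fold)
        test_ids = folds.test_ids(fold)
        if train_cfg.early_stop_patience >= train_cfg.epochs:
            # early stopping can never trigger: train on the whole fold
            # for the full epoch budget instead of carving out validation
            fit_ids, val_ids = list(train_ids), []
        else:
            fit_ids, val_ids = _split_validation(
                cohort, train_ids, train_cfg.validation_fraction, fold_seed)
        scaler = fit_scaler(cohort, fit_ids)
        fit_inp = assemble(cohort, labels, scaler, fit_ids)
        val_inp = assemble(cohort, labels, scaler, val_ids) if val_ids else None
        test_inp = assemble(cohort, labels, scaler, test_ids)

        y_test, _ = _labeled_scores(np.zeros(test_inp.labels.shape), test_inp)
        if y_test.sum() == 0 or y_test.sum() == len(y_test):
            skipped.append(fold)
            continue

        m_cfg = dataclasses.replace(model_cfg, seed=fold_seed,
                                    n_dynamic=len(fit_inp.feature_names),
                                    n_static=len(fit_inp.static_names))
        t_cfg = dataclasses.replace(train_cfg, seed=fold_seed)
        if model_kind == "aicare":
            net = AICareNet(m_cfg)
        elif model_kind == "baseline":
            net = PooledGRUBaseline(m_cfg)
        else:
            raise ValueError(f"unknown model_kind {model_kind!r}")
        train_model(net, fit_inp, val_inp, t_cfg)
        if keep_states:
            states.append(net.state_dict())

        out = net.forward(test_inp)
        if model_kind == "aicare":
            risk, alpha = out
        else:
            risk, alpha = out, None
        y, s = _labeled_scores(risk, test_inp)
        rows.append({"fold": fold, "auprc": auprc(y, s), "auroc": auroc(y, s),
                     "n_pos": int(y.sum()), "n_neg": int(len(y) - y.sum())})
        pred_frames.append(
            _prediction_frame(test_inp, risk, alpha, fold))

    if not rows:
        raise ValueError("every fold was skipped: no evaluable labeled visits")
    return CVResult(
        model_kind=model_kind,
        fold_metrics=pd.DataFrame(rows),
        predictions=pd.concat(pred_frames, ignore_index=True),
        skipped_folds=skipped,
        fold_states=states if keep_states else None,
    )


def _prediction_frame(inp: ModelInput, risk: np.ndarray,
                      alpha: np.ndarray | None, fold: int) -> pd.DataFrame:
    recs = []
    for i, pid in enumerate(inp.patient_ids):
        for t in range(inp.lengths[i]):
            rec = {
                "fold": fold,
                "patient_id": pid,
                "t": t,
                "date": inp.dates[i][t],
                "label": int(inp.labels[i, t]),
                "y_pred": float(risk[i, t]),
            }
            if alpha is not None:
                for j, name in enumerate(inp.feature_names):
                    rec[f"alpha_{name}"] = float(alpha[i, t, j])
            recs.append(rec)
    return pd.DataFrame(recs)


def compare_models(metric_per_fold_a, metric_per_fold_b,
                   method: str = "ttest") -> float:
    """Two-sided paired comparison of per-fold metrics.

    ``method='ttest'`` is a paired t-test with an epsilon guard so a
    constant nonzero difference yields a vanishingly small p rather than
    NaN; ``method='permutation'`` is the exact sign-flip permutation test
    (all 2^k assignments) on the mean difference.
    """
    a = np.asarray(metric_per_fold_a, dtype=float)
    b = np.asarray(metric_per_fold_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("need two equal-length fold-metric vectors")
    k = len(a)
    if k < 3:
        raise ValueError("need at least 3 folds")
    d = a - b
    if method == "permutation":
        obs = abs(d.mean())
        count = 0
        for bits in range(2 ** k):
            signs = 1 - 2 * ((bits >> np.arange(k)) & 1)
            if abs((signs * d).mean()) >= obs - 1e-15:
                count += 1
        return count / 2 ** k
    if method != "ttest":
        raise ValueError(f"unknown method {method!r}")
    sd = d.std(ddof=1)
    if sd == 0.0:
        if np.allclose(d, 0.0):
            return 1.0
        sd = 1e-12  # epsilon guard: constant nonzero difference
    t = d.mean() / (sd / np.sqrt(k))
    return float(2.0 * _scipy_stats.t.sf(abs(t), df=k - 1))
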