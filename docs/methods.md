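# Methods

## The task

Patients on long-term peritoneal dialysis (PD) attend follow-up visits
roughly every 2–3 months, each producing a panel of laboratory values and
vital signs. The package performs *dynamic* 1-year mortality prediction: at
every visit it emits a fresh probability that the patient dies within the
following year, using only the visit history up to that point plus four
baseline features (age, gender, height, diabetes at dialysis start). The
model's per-visit attention weights over the 16 dynamic features double as
the interpretability output.

## Visit labeling

With death date `d`, a visit at `v` is **positive** when `0 ≤ d − v ≤ 1`
year, **uncertain** when `1 < d − v ≤ 2` years, otherwise **negative**. A
survivor's visit is **uncertain** when it falls within 1 year of the end of
data collection (its true 1-year outcome is unknowable), otherwise
negative. Uncertain visits stay in the encoder's input sequence — a
recurrent model needs contiguous history — but contribute neither loss
terms nor evaluation points.

Boundary semantics are deliberate: the positive window is closed at both
ends, so a visit exactly one year before death is positive (the
conservative clinical choice), and a "year" is 365.25 days to sidestep
leap-year ambiguity. Labels are therefore invariant under shifting all
dates by a constant.

## Preprocessing

Missing values are forward-filled with the most recent prior observation
for that patient and feature; leading missings fall back to the
training-fold median, which keeps z-scored fallbacks near zero. Features
are z-scored with statistics computed from *observed* (pre-imputation)
values of training-fold patients only; the held-out fold never influences
them. Features never observed in a training fold, or with zero variance,
are scaled to a constant zero so they carry no signal. Binary statics pass
through unscaled. An observation-mask input channel exists
(`use_mask_channel`) but is off by default.

## Architecture

Per visit `t` and dynamic feature `f`:

1. **Multichannel extraction.** Each feature has its own GRU
   (`channel_hidden_dim = 8`, parameters unshared) consuming that feature's
   scalar series, giving channel states `h[f, t]`. Independent channels
   keep each feature's temporal pattern attributable to that feature.
2. **Static embedding.** `e = tanh(W_s s)`, dimension 16.
3. **Health context.** `c[t] = tanh(W_c [h[1,t]; …; h[16,t]; e])`,
   dimension 64 — a squeezed summary of everything known at `t` that
   *conditions* the attention.
4. **Feature-importance recalibration.** Additive attention over features:
   `s_f = vᵀ tanh(W₁c[t] + W₂h[f,t] + b)`, `α[·, t] = softmax(s)` over the
   16 features, and a fused state `Σ_f α[f,t] · tanh(W_p h[f,t])`.
5. **Risk head.** By default a *linear* map of `[fused; c[t]]` through a
   sigmoid.

Two design choices here depart from the obvious construction, and both
exist to make the attention weights mean something:

* **Bounded per-feature projections.** The fused vector sums
  `α_f · tanh(W_p h_f)` rather than `α_f · W_p h_f`. With unbounded
  projections the network can route a feature's signal through a large
  `‖h_f‖` at tiny `α_f`, and the attention decouples from actual usage. The
  tanh caps each feature's contribution, so amplifying a feature requires
  raising its weight.
* **Linear head with context dropout.** With a linear head the logit
  decomposes as `Σ_f α_f g_f + wᵀc + b` — a mixture of per-feature scalar
  risk scores gated by the attention. The health-context term improves
  discrimination but is a shortcut that could carry the entire risk signal,
  leaving `α` unconstrained; during training the whole context vector is
  therefore dropped per (visit, sample) with probability
  `context_dropout = 0.8`, forcing the gated pathway to stand on its own.
  We verified the failure mode empirically: with an always-on context MLP
  head, cross-validated AUPRC is unchanged but pooled attention-value
  curves flatten to slopes of ~1e-4 — the attention becomes decorative.

Both choices are switchable (`head_kind="mlp"`, `context_dropout=0`,
and the tanh bounding sits behind `recalibrate`). Everything is strictly
causal; truncating a patient's future leaves earlier outputs bit-identical.

The comparison baseline is a single GRU (hidden 32) over the concatenated
16-feature vector with statics appended at each step — the standard pooled
sequence model.

The model is implemented in numpy on a small in-repo reverse-mode autograd
engine (`aicare._autograd`); the GRU time loop is a single graph node with
hand-written backpropagation through time, and all gradients are verified
against central finite differences in the test suite. Training runs in
float32.

## Training and evaluation

Masked binary cross-entropy over positive/negative visits only (uncertain
and padded positions carry zero weight), optional positive reweighting,
Adam, minibatches of patients bucketed by sequence length. Evaluation is
patient-level k-fold cross-validation (default k = 10), stratified by
vital status — splitting by visit would leak near-duplicate records of one
patient across folds. Within each fold a patient-level 10% validation
split drives early stopping on validation AUPRC (the primary metric, since
positives are ~9% of labeled visits); when the patience equals the epoch
budget, early stopping is inert and the fold trains on all its patients
for the fixed budget instead. Metrics are pooled over visits within each
test fold, then averaged across folds. AUPRC/AUROC delegate to
scikit-learn and are pinned by brute-force oracles in the tests.
Model comparison is a two-sided paired t-test across folds (epsilon-guarded
for zero variance), with an exact sign-flip permutation test available as
`method="permutation"`.

The desk-scale recipe used by the recovery experiment and the acceptance
script (`aicare.experiments`): 25 epochs, batch 128, learning rate 3e-3,
positive weight 3, no early stopping. One 656-patient 10-fold CV takes
roughly 80–100 s on one CPU core.

## Interpretability products

* **Cause heatmap** — per patient, average `α` per feature over visits;
  then average patient means within each cause-of-death group (survivors
  are their own row). Mean-of-patient-means stops long-follow-up patients
  from dominating; rows with fewer than `min_patients = 5` patients are
  flagged low-support.
* **Importance-vs-value curves** — for each feature, bin raw values into
  40 equal-width bins between the 1st and 99th percentile, average `α` per
  bin, smooth with a centered 3-bin moving average, drop bins with under
  20 records. The **turning point** is found by single-knee continuous
  piecewise-linear least squares over candidate knees at interior bin
  centers (ties to the smaller knee). **Shape taxonomy**: with fitted left
  slope `s_l`, right slope `s_r`, and `τ = 0.25·|s_l|`: V when `s_l < 0`
  and `s_r > τ`; L when `s_l < 0` and `|s_r| ≤ τ`; anything else —
  including fits with R² < 0.3 — is irregular.
* **Recommendations** — risk direction per feature is the sign of the
  correlation between raw value and predicted risk on records whose
  attention exceeds the feature's median (low-attention records carry
  little signal). V + risk falling with value → "higher (> knee)";
  L + falling → "at-least (> knee)"; rising → "not-exceed (< knee)";
  irregular → "unknown". Traditional outpatient reference ranges are
  attached for consistency display only.
* **Trajectories** — per-patient JSON (schema-versioned) with per-visit
  risk and per-feature (value, α), the feed for a line-chart UI where dot
  size encodes attention.

All curve statistics use held-out-fold predictions pooled across folds, so
each visit is scored by a model that never trained on its patient.

## Synthetic cohort generator

The generator emulates the statistical shape of a single-center PD
registry: 656 patients; enrollment uniform over 2006–2015 with collection
ending 2018-10-31; planned visit counts ~Normal(20, 13) clipped to ≥2;
intervals ~Normal(2.73, 0.8) months (≥15 days); age ~Normal(58.55, 15.81)
in [16, 98]; gender Bernoulli(0.5); diabetes Bernoulli(0.372). Each of the
16 features is a stationary AR(1) around a patient-specific setpoint with
persistence ρ = 0.8 and 35% of variance between patients; marginal
means/SDs/missing rates are the low-risk-visit values of the real panel.
Right-skewed features (glucose, hs-CRP) run on the log scale with
moment-matched parameters. Small, centered age/diabetes shifts move
setpoints without moving the marginals. Missingness is applied after the
hazard and is missing-at-random per feature.

Death is a discrete-time hazard evaluated at each visit:
`logit h_t = b + Σ terms`, each term a piecewise-linear hinge in one
feature's current latent value. The default planted scenario: albumin
two-sided at 32 g/L (slopes +0.9 below / −0.25 above, per g/L of
log-odds), SBP hinge-below at 130 mm Hg (+0.12), DBP two-sided at
70 mm Hg (+0.18/−0.075), hemoglobin hinge-below at 114 g/L (+0.09); white
cells drive nothing. Slope magnitudes were set by an oracle-ceiling
analysis: scoring visits with the true hazard logit must itself achieve
AUPRC well above the no-skill prevalence (the ceiling is ~0.48 vs ~0.093
prevalence), otherwise no learned model could demonstrate recovery. The
intercept ships pre-calibrated (bisection over pilot cohorts, averaged
over several pilot seeds) to a ~9.1% positive-visit prevalence; death
dates fall mid-interval after the first hazard success, and deaths past
the collection end are recorded as censored survivors. Each patient draws
from an independent stream seeded by (seed, patient index), so cohorts
regenerate byte-identically.

### What recovery does and does not show

A trained model's attention minimum for a feature does *not* sit at the
hazard hinge: it sits near the **zero-surprise point** where the feature's
hazard contribution equals its cohort-average contribution, because a
value that is "typical in effect" moves no prediction and earns no
attention. For albumin (hinge 32, marginal mean 37.9) that point is
`32 + E[f(X)]/|s_above| ≈ 37.4` g/L; the recovered turning points cluster
there, a few g/L above the hinge. For DBP the two nearly coincide
(zero-surprise ≈ 75 vs hinge 70), and for one-sided hinges like SBP the
flat region pins the recovered knee close to the hinge itself. Recovered
knees should be read with this identifiability limit in mind; it is a
property of attention-based importance generally, not of this
implementation. Passing recovery tests on this generator also does not
certify behavior on real registries, where features are cross-correlated,
missingness is informative, and risk is not piecewise-linear.

## Numerical and degenerate-input conventions

Softmax is max-shifted; BCE uses the softplus form (no probability
clipping in the loss gradient); the public probability-space loss clips at
1e-12. Metrics raise on one-class label sets; folds whose test split has
no positives are skipped with a record. `fit_scaler` uses ddof = 1 and
guards zero variance. The knee fit requires ≥5 retained bins and breaks
RSS ties toward the smaller knee; constant curves classify as irregular
(R² convention: a zero-residual constant fit has R² = 1 but slope 0, which
fails the `s_l < 0` gate). Fold assignment deals shuffled deceased then
survivors round-robin through a single cycle, so fold sizes differ by at
most one while each fold gets its share of events.

## Known limitations

Visit intervals are treated as regular; no time-aware decay. No competing
risks or survival-time modeling — a binary horizon only. Attention is an
association, not a causal effect; recommendations in the report are
reference points for reading the model, not treatment advice. The
generator does not simulate cross-feature correlation (an optional hook is
left out deliberately), informative missingness, or treatment feedback.
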