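"""The risk network: per-feature sequence channels recalibrated by
health-context attention.

Architecture, per patient and visit ``t``:

1.  *Multichannel extraction* — each of the F dynamic features has its own
    small GRU (parameters not shared across features) consuming that
    feature's scalar series, giving channel states ``h[f, t]``.
2.  *Static embedding* — a one-hidden-layer tanh map of the 4 baseline
    features to ``static_embed_dim``.
3.  *Health context* — ``c[t] = tanh(W_c [h[1,t]; ...; h[F,t]; e] + b_c)``,
    a squeezed joint embedding of the current channel states and the static
    embedding.
4.  *Feature-importance recalibration* — additive attention over features:
    ``s_f = v . tanh(W_c' c[t] + W_h h[f,t])``, ``alpha[f,t] = softmax_f(s_f)``,
    fused state ``sum_f alpha[f,t] (W_p h[f,t])``. The weights ``alpha`` are
    both the fusion coefficients and the per-visit interpretability output.
5.  *Risk head* — sigmoid MLP on ``[fused; c[t]]`` giving the 1-year
    mortality risk ``y_hat[t] in (0, 1)``.

Everything is strictly causal: outputs at visit ``t`` depend only on visits
``<= t`` and the baseline. A plain pooled-sequence GRU over the concatenated
feature vector is provided as the comparison baseline.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np

from ._autograd import Tensor, bce_with_logits, concat, gru_sequence, softmax
from .preprocessing import ModelInput

__all__ = ["ModelConfig", "AICareNet", "PooledGRUBaseline"]


@dataclass(frozen=True)
class ModelConfig:
    n_dynamic: int = 16
    n_static: int = 4
    channel_hidden_dim: int = 8
    static_embed_dim: int = 16
    context_dim: int = 64
    attention_dim: int = 32
    fused_dim: int = 16
    head_hidden_dim: int = 32
    baseline_hidden_dim: int = 32
    dropout: float = 0.1
    use_mask_channel: bool = False
    #: feed the health context to the risk head alongside the fused state.
    #: With a direct, always-on context shortcut the head can bypass the
    #: recalibrated representation entirely, which leaves the attention
    #: weights unconstrained and meaningless as importance estimates;
    #: `context_dropout` therefore drops the whole context pathway per
    #: sample during training so the fused pathway must carry the signal.
    head_uses_context: bool = True
    context_dropout: float = 0.8
    #: "linear": logit is an affine map of [fused; context], so the logit
    #: decomposes as sum_f alpha[f] * g[f] (+ context term) — a mixture of
    #: per-feature risk scores gated by the attention, which ties the
    #: attention weights to actual predictive contribution. "mlp": one
    #: hidden tanh layer of head_hidden_dim units before the output.
    head_kind: str = "linear"
    seed: int = 0

    def __post_init__(self):
        for name in ("n_dynamic", "n_static", "channel_hidden_dim",
                     "static_embed_dim", "context_dim", "attention_dim",
                     "fused_dim", "head_hidden_dim", "baseline_hidden_dim"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if not 0.0 <= self.context_dropout < 1.0:
            raise ValueError("context_dropout must be in [0, 1)")
        if self.head_kind not in ("linear", "mlp"):
            raise ValueError("head_kind must be 'linear' or 'mlp'")


_DT = np.float32  # training dtype: halves memory traffic on CPU


def _uniform(rng, *shape):
    fan_in = shape[-2] if len(shape) >= 2 else shape[-1]
    a = 1.0 / np.sqrt(fan_in)
    return Tensor(rng.uniform(-a, a, size=shape).astype(_DT),
                  requires_grad=True)


def _zeros(*shape):
    return Tensor(np.zeros(shape, dtype=_DT), requires_grad=True)


class _Module:
    """Tiny parameter-registry base."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}

    def _add(self, name: str, t: Tensor) -> Tensor:
        self._params[name] = t
        return t

    def parameters(self) -> list[Tensor]:
        return list(self._params.values())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self._params.items()}

    def load_state_dict(self, state: dict) -> None:
        for k, v in state.items():
            if k not in self._params:
                raise KeyError(f"unknown parameter {k}")
            if self._params[k].data.shape != np.asarray(v).shape:
                raise ValueError(f"shape mismatch for {k}")
            self._params[k].data = np.asarray(v, dtype=self._params[k].data.dtype).copy()

    @property
    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


class AICareNet(_Module):
    """Per-feature channel GRUs + health-context attention + risk head."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        cfg = config
        rng = np.random.default_rng(cfg.seed)
        self._dropout_rng = np.random.default_rng(cfg.seed + 1)
        F, H = cfg.n_dynamic, cfg.channel_hidden_dim
        in_dim = 2 if cfg.use_mask_channel else 1
        E, C, A, P = (cfg.static_embed_dim, cfg.context_dim,
                      cfg.attention_dim, cfg.fused_dim)
        # channel GRUs (leading axis = feature; parameters unshared)
        self.Wx = self._add("Wx", _uniform(rng, F, in_dim, 3 * H))
        self.Wh = self._add("Wh", _uniform(rng, F, H, 3 * H))
        self.b = self._add("b", _zeros(F, 1, 3 * H))
        # static embedding
        self.Ws = self._add("Ws", _uniform(rng, cfg.n_static, E))
        self.bs = self._add("bs", _zeros(E))
        # health context squeeze
        self.Wc = self._add("Wc", _uniform(rng, F * H + E, C))
        self.bc = self._add("bc", _zeros(C))
        # additive attention
        self.Wac = self._add("Wac", _uniform(rng, C, A))
        self.Wah = self._add("Wah", _uniform(rng, H, A))
        self.ba = self._add("ba", _zeros(A))
        self.v = self._add("v", _uniform(rng, A, 1))
        # recalibrated fusion and risk head
        self.Wp = self._add("Wp", _uniform(rng, H, P))
        head_in = P + C if cfg.head_uses_context else P
        if cfg.head_kind == "mlp":
            self.W1 = self._add("W1", _uniform(rng, head_in, cfg.head_hidden_dim))
            self.b1 = self._add("b1", _zeros(cfg.head_hidden_dim))
            self.W2 = self._add("W2", _uniform(rng, cfg.head_hidden_dim, 1))
        else:
            self.W2 = self._add("W2", _uniform(rng, head_in, 1))
        self.b2 = self._add("b2", _zeros(1))

    # -- pieces ------------------------------------------------------------
    def _channel_inputs(self, inp: ModelInput) -> np.ndarray:
        """(T, F, N, in_dim) channel input array."""
        x = inp.dynamic.transpose(1, 2, 0)[..., None]  # (T, F, N, 1)
        if self.config.use_mask_channel:
            m = inp.obs_mask.transpose(1, 2, 0)[..., None]
            x = np.concatenate([x, m], axis=-1)
        return np.ascontiguousarray(x, dtype=_DT)

    def encode_channels(self, inp: ModelInput) -> Tensor:
        """Run every per-feature GRU over the whole batch.

        Returns channel states of shape (T, F, N, H); entry ``[t, f]``
        depends only on feature ``f``'s inputs at visits ``<= t``.
        """
        x = self._channel_inputs(inp)
        return gru_sequence(x, self.Wx, self.Wh, self.b)  # (T, F, N, H)

    def embed_static(self, static: np.ndarray) -> Tensor:
        """One-hidden-layer tanh embedding of the baseline features. (N, E)."""
        return (Tensor(static.astype(_DT)) @ self.Ws + self.bs).tanh()

    def build_health_context(self, states: Tensor, static_emb: Tensor) -> Tensor:
        """Squeeze [all channel states at t ; static embedding] to (T, N, C)."""
        T, F, N, H = states.shape
        flat = states.transpose(0, 2, 1, 3).reshape(T, N, F * H)
        e = static_emb.reshape(1, *static_emb.shape).broadcast_to(
            (T,) + static_emb.shape)
        return (concat([flat, e], axis=-1) @ self.Wc + self.bc).tanh()

    def recalibrate(self, context: Tensor, states: Tensor
                    ) -> tuple[Tensor, Tensor]:
        """Additive attention over features at each visit.

        Returns ``(alpha, fused)`` with ``alpha`` (T, F, N) summing to 1
        over the feature axis and ``fused`` (T, N, fused_dim).
        """
        T, F, N, H = states.shape
        u_h = states @ self.Wah                       # (T, F, N, A)
        u_c = (context @ self.Wac + self.ba).reshape(T, 1, N, -1)
        scores = ((u_h + u_c).tanh() @ self.v).reshape(T, F, N)
        alpha = softmax(scores, axis=1)               # over features
        # bounded per-feature projections: each feature's contribution to
        # the fused vector is capped, so amplifying a feature's signal
        # requires raising its attention weight — this is what makes alpha
        # meaningful as an importance estimate
        proj = (states @ self.Wp).tanh()              # (T, F, N, P)
        fused = (alpha.reshape(T, F, N, 1) * proj).sum(axis=1)
        return alpha, fused

    def predict_risk_logits(self, fused: Tensor, context: Tensor,
                            training: bool = False) -> Tensor:
        """Risk-head logits (T, N); sigmoid of these is the 1-year risk."""
        if self.config.head_uses_context:
            p_ctx = self.config.context_dropout
            if training and p_ctx > 0.0:
                # drop the entire context vector per (visit, sample) so the
                # attention-fused pathway must carry the risk signal alone
                keep_shape = context.shape[:-1] + (1,)
                keep = ((self._dropout_rng.random(keep_shape) >= p_ctx)
                        .astype(_DT) / _DT(1.0 - p_ctx))
                context = context * Tensor(keep)
            hcat = concat([fused, context], axis=-1)
        else:
            hcat = fused
        if self.config.head_kind == "linear":
            out = hcat @ self.W2 + self.b2
            return out.reshape(*hcat.shape[:-1])
        hh = (hcat @ self.W1 + self.b1).tanh()
        p_drop = self.config.dropout
        if training and p_drop > 0.0:
            keep = ((self._dropout_rng.random(hh.shape) >= p_drop)
                    .astype(_DT) / _DT(1.0 - p_drop))
            hh = hh * Tensor(keep)
        return (hh @ self.W2 + self.b2).reshape(*hh.shape[:-1])

    def predict_risk(self, fused: Tensor, context: Tensor) -> np.ndarray:
        """1-year mortality risk in (0, 1) for given fused/context states."""
        logits = self.predict_risk_logits(fused, context, training=False)
        return 1.0 / (1.0 + np.exp(-logits.data))

    # -- full chain --------------------------------------------------------
    def forward_tensors(self, inp: ModelInput, training: bool = False
                        ) -> tuple[Tensor, Tensor]:
        """(logits (N, T), alpha (N, T, F)) as graph tensors."""
        states = self.encode_channels(inp)
        e = self.embed_static(inp.static)
        c = self.build_health_context(states, e)
        alpha, fused = self.recalibrate(c, states)
        logits = self.predict_risk_logits(fused, c, training=training)
        T, F, N = alpha.shape
        return (logits.transpose(1, 0),
                alpha.transpose(2, 0, 1))  # (N,T), (N,T,F)

    def forward(self, inp: ModelInput) -> tuple[np.ndarray, np.ndarray]:
        """Risk trajectory and attention profile as numpy arrays.

        Returns ``(risk (N, T), alpha (N, T, F))`` with padded positions
        (beyond each patient's true length) set to NaN.
        """
        logits, alpha = self.forward_tensors(inp, training=False)
        risk = 1.0 / (1.0 + np.exp(-logits.data))
        a = alpha.data.copy()
        for i, L in enumerate(inp.lengths):
            risk[i, L:] = np.nan
            a[i, L:, :] = np.nan
        return risk, a

    def loss(self, inp: ModelInput, positive_weight: float = 1.0,
             training: bool = True) -> Tensor:
        logits, _ = self.forward_tensors(inp, training=training)
        return masked_bce_from_logits(logits, inp.labels, positive_weight)

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        cfg = json.dumps(dataclasses.asdict(self.config))
        np.savez(path, __config__=np.frombuffer(cfg.encode(), dtype=np.uint8),
                 **self.state_dict())

    @classmethod
    def load(cls, path) -> "AICareNet":
        with np.load(path) as z:
            cfg = ModelConfig(**json.loads(bytes(z["__config__"]).decode()))
            net = cls(cfg)
            net.load_state_dict({k: z[k] for k in z.files if k != "__config__"})
        return net


def masked_bce_from_logits(logits: Tensor, labels: np.ndarray,
                           positive_weight: float = 1.0) -> Tensor:
    """Mean BCE over positive/negative visits; uncertain and padded visits
    carry zero weight. ``labels`` uses the preprocessing codes (1/0/-1/-2)."""
    y = (labels == 1).astype(float)
    w = np.where(labels == 1, positive_weight, 0.0) + (labels == 0).astype(float)
    return bce_with_logits(logits, y, w)


class PooledGRUBaseline(_Module):
    """Plain GRU over the concatenated feature vector — the comparison model.

    At each visit the 16 dynamic values (z-scored) and the 4 statics are
    concatenated into one input vector for a single shared GRU; a sigmoid
    head on the hidden state gives the risk. No attention, no per-feature
    channels.
    """

    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        G = config.baseline_hidden_dim
        D = config.n_dynamic + config.n_static
        self.Wx = self._add("Wx", _uniform(rng, 1, D, 3 * G))
        self.Wh = self._add("Wh", _uniform(rng, 1, G, 3 * G))
        self.b = self._add("b", _zeros(1, 1, 3 * G))
        self.W1 = self._add("W1", _uniform(rng, G, config.head_hidden_dim))
        self.b1 = self._add("b1", _zeros(config.head_hidden_dim))
        self.W2 = self._add("W2", _uniform(rng, config.head_hidden_dim, 1))
        self.b2 = self._add("b2", _zeros(1))

    def forward_tensors(self, inp: ModelInput, training: bool = False) -> Tensor:
        N, T, F = inp.dynamic.shape
        # one shared GRU: static features are appended to every step's input
        stat = np.broadcast_to(inp.static[None, None],
                               (T, 1, N, inp.static.shape[1]))
        x = np.concatenate(
            [inp.dynamic.transpose(1, 0, 2)[:, None], stat],
            axis=-1).astype(_DT)
        h = gru_sequence(x, self.Wx, self.Wh, self.b)  # (T, 1, N, G)
        hh = (h @ self.W1 + self.b1).tanh()
        logits = (hh @ self.W2 + self.b2).reshape(T, N)
        return logits.transpose(1, 0)  # (N, T)

    def forward(self, inp: ModelInput) -> np.ndarray:
        logits = self.forward_tensors(inp, training=False)
        risk = 1.0 / (1.0 + np.exp(-logits.data))
        for i, L in enumerate(inp.lengths):
            risk[i, L:] = np.nan
        return risk

    def loss(self, inp: ModelInput, positive_weight: float = 1.0,
             training: bool = True) -> Tensor:
        logits = self.forward_tensors(inp, training=training)
        return masked_bce_from_logits(logits, inp.labels, positive_weight)
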