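"""Network building blocks: hand-computed recurrences, causality,
attention contracts, permutation consistency."""

import dataclasses

import numpy as np
import pytest

from aicare._autograd import Tensor, gru_sequence, softmax
from aicare.model import AICareNet, ModelConfig, PooledGRUBaseline
from aicare.preprocessing import ModelInput


def make_input(rng, n=4, t=6, f=16, s=4):
    lengths = rng.integers(1, t + 1, size=n)
    lengths[0] = t
    labels = rng.integers(0, 2, size=(n, t)).astype(np.int8)
    for i, L in enumerate(lengths):
        labels[i, L:] = -2
    return ModelInput(
        dynamic=rng.normal(size=(n, t, f)),
        obs_mask=np.ones((n, t, f), dtype=np.int8),
        lengths=np.asarray(lengths),
        static=rng.normal(size=(n, s)),
        labels=labels,
        patient_ids=[f"p{i}" for i in range(n)],
        dates=[[f"2010-01-{d+1:02d}" for d in range(t)] for _ in range(n)],
        feature_names=[f"f{j}" for j in range(f)],
        static_names=["age", "gender", "height", "diabetes"],
    )


def small_config(**kw):
    base = dict(n_dynamic=16, channel_hidden_dim=4, static_embed_dim=4,
                context_dim=8, attention_dim=6, fused_dim=4,
                head_hidden_dim=5, baseline_hidden_dim=6, dropout=0.0,
                seed=0)
    base.update(kw)
    return ModelConfig(**base)


def test_single_step_gru_matches_hand_arithmetic():
    # one step, one channel, 2 hidden units, hand-set weights
    H = 2
    Wx = np.array([[[0.5, -0.2, 0.1, 0.3, -0.4, 0.2]]])   # (1, 1, 3H)
    Wh = np.zeros((1, H, 3 * H))
    Wh[0, 0, 4] = 0.7    # candidate gate feedback, but h0 = 0
    b = np.array([[[0.1, 0.0, -0.1, 0.2, 0.05, -0.05]]])
    x = np.array([[[[1.5]]]])                              # (T=1, F=1, N=1, 1)
    out = gru_sequence(x, Tensor(Wx, requires_grad=True),
                       Tensor(Wh, requires_grad=True),
                       Tensor(b, requires_grad=True)).data[0, 0, 0]

    def sig(v):
        return 1 / (1 + np.exp(-v))

    z = sig(1.5 * Wx[0, 0, :2] + b[0, 0, :2])
    n = np.tanh(1.5 * Wx[0, 0, 4:] + b[0, 0, 4:])
    expected = (1 - z) * n  # h0 = 0
    assert out == pytest.approx(expected, abs=1e-6)


def test_identical_series_and_parameters_give_identical_states():
    rng = np.random.default_rng(0)
    cfg = small_config()
    net = AICareNet(cfg)
    # copy channel 3's parameters into channel 7 and feed both the same data
    for name in ("Wx", "Wh", "b"):
        p = net._params[name]
        p.data[7] = p.data[3]
    inp = make_input(rng)
    inp.dynamic[:, :, 7] = inp.dynamic[:, :, 3]
    states = net.encode_channels(inp).data
    np.testing.assert_allclose(states[:, 3], states[:, 7], atol=1e-7)


def test_channel_states_are_causal_under_truncation():
    rng = np.random.default_rng(1)
    net = AICareNet(small_config())
    inp = make_input(rng, n=3, t=6)
    full = net.encode_channels(inp).data
    for cut in (2, 4):
        trunc = inp.subset(np.arange(inp.n_patients))
        trunc.dynamic = inp.dynamic[:, :cut].copy()
        trunc.obs_mask = inp.obs_mask[:, :cut].copy()
        trunc.labels = inp.labels[:, :cut].copy()
        trunc.lengths = np.minimum(inp.lengths, cut)
        part = net.encode_channels(trunc).data
        np.testing.assert_array_equal(part, full[:cut])


def test_full_forward_is_causal_bit_for_bit():
    rng = np.random.default_rng(2)
    net = AICareNet(small_config())
    inp = make_input(rng, n=3, t=6)
    risk_full, alpha_full = net.forward(inp)
    cut = 3
    trunc = inp.subset(np.arange(inp.n_patients))
    trunc.dynamic = inp.dynamic[:, :cut].copy()
    trunc.obs_mask = inp.obs_mask[:, :cut].copy()
    trunc.labels = inp.labels[:, :cut].copy()
    trunc.lengths = np.minimum(inp.lengths, cut)
    risk_part, alpha_part = net.forward(trunc)
    m = ~np.isnan(risk_part)
    np.testing.assert_array_equal(risk_part[m], risk_full[:, :cut][m])
    m3 = ~np.isnan(alpha_part)
    np.testing.assert_array_equal(alpha_part[m3], alpha_full[:, :cut][m3])


class TestStaticEmbedding:
    def test_identical_baselines_identical_embeddings(self):
        net = AICareNet(small_config())
        s = np.array([[0.3, 1.0, -0.2, 0.0], [0.3, 1.0, -0.2, 0.0]])
        e = net.embed_static(s).data
        np.testing.assert_array_equal(e[0], e[1])

    def test_output_dimension(self):
        net = AICareNet(small_config(static_embed_dim=4))
        assert net.embed_static(np.zeros((3, 4))).shape == (3, 4)

    def test_zero_weights_give_bias_image(self):
        net = AICareNet(small_config())
        net.Ws.data[:] = 0.0
        e = net.embed_static(np.array([[5.0, 1.0, -2.0, 3.0]])).data
        np.testing.assert_allclose(e, np.tanh(net.bs.data)[None, :])


class TestAttention:
    def test_zero_scoring_vector_gives_exactly_uniform_attention(self):
        rng = np.random.default_rng(3)
        net = AICareNet(small_config())
        net.v.data[:] = 0.0  # all scores identical -> uniform softmax
        _, alpha = net.forward(make_input(rng))
        valid = ~np.isnan(alpha)
        assert np.allclose(alpha[valid], 1 / 16)

    def test_hand_set_scores_softmax_oracle(self):
        scores = np.zeros((1, 16))
        scores[0, 0] = 1.0
        a = softmax(Tensor(scores), axis=1).data[0]
        assert a[0] == pytest.approx(np.e / (np.e + 15), abs=1e-6)
        assert a[1] == pytest.approx(1 / (np.e + 15), abs=1e-6)

    def test_attention_normalized_over_random_draws(self):
        rng = np.random.default_rng(4)
        for trial in range(20):
            net = AICareNet(small_config(seed=trial))
            _, alpha = net.forward(make_input(rng, n=2, t=4))
            valid_rows = alpha[~np.isnan(alpha[..., 0])]
            assert (valid_rows >= 0).all()
            np.testing.assert_allclose(valid_rows.sum(-1), 1.0, atol=1e-6)


def permute_net_channels(net: AICareNet, perm: np.ndarray) -> AICareNet:
    """Permute the feature axis of every per-channel parameter, including
    the per-feature blocks of the context squeeze."""
    out = AICareNet(net.config)
    out.load_state_dict(net.state_dict())
    H = net.config.channel_hidden_dim
    for name in ("Wx", "Wh", "b"):
        out._params[name].data = net._params[name].data[perm].copy()
    Wc = net.Wc.data
    F = net.config.n_dynamic
    blocks = Wc[: F * H].reshape(F, H, -1)[perm].reshape(F * H, -1)
    out.Wc.data = np.concatenate([blocks, Wc[F * H:]], axis=0)
    return out


def test_permuting_features_with_parameters_permutes_alpha_only():
    rng = np.random.default_rng(5)
    net = AICareNet(small_config())
    inp = make_input(rng, n=3, t=5)
    risk, alpha = net.forward(inp)

    perm = rng.permutation(16)
    net_p = permute_net_channels(net, perm)
    inp_p = dataclasses.replace(
        inp,
        dynamic=inp.dynamic[:, :, perm].copy(),
        obs_mask=inp.obs_mask[:, :, perm].copy(),
        feature_names=[inp.feature_names[j] for j in perm],
    )
    risk_p, alpha_p = net_p.forward(inp_p)
    np.testing.assert_allclose(risk_p, risk, atol=1e-5)
    np.testing.assert_allclose(alpha_p, alpha[:, :, perm], atol=1e-6)


class TestRiskHead:
    def test_zero_weights_give_half(self):
        rng = np.random.default_rng(6)
        net = AICareNet(small_config())
        net.W2.data[:] = 0.0
        net.b2.data[:] = 0.0
        risk, _ = net.forward(make_input(rng))
        valid = risk[~np.isnan(risk)]
        assert np.allclose(valid, 0.5)

    def test_monotone_in_output_bias(self):
        rng = np.random.default_rng(7)
        inp = make_input(rng)
        net = AICareNet(small_config())
        risks = []
        for bias in (-2.0, 0.0, 2.0):
            net.b2.data[:] = bias
            r, _ = net.forward(inp)
            risks.append(np.nanmean(r))
        assert risks[0] < risks[1] < risks[2]

    def test_extreme_negative_bias_drives_risk_to_zero(self):
        rng = np.random.default_rng(8)
        net = AICareNet(small_config())
        net.b2.data[:] = -40.0
        risk, _ = net.forward(make_input(rng))
        assert np.nanmax(risk) < 1e-12


class TestForward:
    def test_outputs_match_sequence_lengths(self):
        rng = np.random.default_rng(9)
        net = AICareNet(small_config())
        inp = make_input(rng)
        risk, alpha = net.forward(inp)
        for i, L in enumerate(inp.lengths):
            assert not np.isnan(risk[i, :L]).any()
            assert np.isnan(risk[i, L:]).all()
            assert np.isnan(alpha[i, L:, :]).all()

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(10)
        inp = make_input(rng)
        r1, a1 = AICareNet(small_config(seed=3)).forward(inp)
        r2, a2 = AICareNet(small_config(seed=3)).forward(inp)
        np.testing.assert_array_equal(r1[~np.isnan(r1)], r2[~np.isnan(r2)])
        np.testing.assert_array_equal(a1[~np.isnan(a1)], a2[~np.isnan(a2)])

    def test_save_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(11)
        inp = make_input(rng)
        net = AICareNet(small_config(seed=5))
        r1, _ = net.forward(inp)
        net.save(tmp_path / "ckpt.npz")
        net2 = AICareNet.load(tmp_path / "ckpt.npz")
        assert net2.config == net.config
        r2, _ = net2.forward(inp)
        np.testing.assert_array_equal(r1[~np.isnan(r1)], r2[~np.isnan(r2)])


class TestPooledBaseline:
    def test_outputs_in_unit_interval_and_causal(self):
        rng = np.random.default_rng(12)
        net = PooledGRUBaseline(small_config())
        inp = make_input(rng, n=3, t=6)
        risk = net.forward(inp)
        valid = risk[~np.isnan(risk)]
        assert ((valid > 0) & (valid < 1)).all()
        cut = 3
        trunc = inp.subset(np.arange(inp.n_patients))
        trunc.dynamic = inp.dynamic[:, :cut].copy()
        trunc.labels = inp.labels[:, :cut].copy()
        trunc.lengths = np.minimum(inp.lengths, cut)
        part = net.forward(trunc)
        m = ~np.isnan(part)
        np.testing.assert_array_equal(part[m], risk[:, :cut][m])

    def test_parameter_counts_are_sane(self):
        a = AICareNet(ModelConfig())
        b = PooledGRUBaseline(ModelConfig())
        assert 0 < b.n_parameters < a.n_parameters < 100_000
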