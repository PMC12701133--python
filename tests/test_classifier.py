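"""Gated-attention LSTM classifier: equation-level oracles and training."""

import numpy as np
import pytest

from facesurv.autodiff import Tensor
from facesurv.classifier import (GatedAttentionLSTM, LSTMParams, Standardizer,
                                 attention_pool, attention_weights, dense_map,
                                 eted_forward, gate_value, lstm_step,
                                 residual_block, stratified_split, train_eted)
from facesurv.config import EtedConfig
from facesurv.nn import BatchNorm1d, Linear, gradient_check
from facesurv.synthetic import generate_clinical_cohort, strong_cohort_spec

rng = np.random.default_rng(21)


def zero_lstm(h, d):
    z = lambda *s: Tensor(np.zeros(s), requires_grad=True)
    return LSTMParams(W_f=z(h, h), W_i=z(h, h), W_c=z(h, h), W_o=z(h, h),
                      U_f=z(d, h), U_i=z(d, h), U_c=z(d, h), U_o=z(d, h),
                      b_f=z(h), b_i=z(h), b_c=z(h), b_o=z(h))


def random_lstm(h, d, r):
    m = lambda *s: Tensor(r.normal(0, 0.6, s), requires_grad=True)
    return LSTMParams(W_f=m(h, h), W_i=m(h, h), W_c=m(h, h), W_o=m(h, h),
                      U_f=m(d, h), U_i=m(d, h), U_c=m(d, h), U_o=m(d, h),
                      b_f=m(h), b_i=m(h), b_c=m(h), b_o=m(h))


def ref_lstm_step(x, h, c, p):
    """Scalar-loop evaluation of the gate equations."""
    def sig(v):
        return 1.0 / (1.0 + np.exp(-v))
    hd = p.W_f.data.shape[0]
    out_h = np.zeros_like(h)
    out_c = np.zeros_like(c)
    for b in range(x.shape[0]):
        for k in range(hd):
            f = sig(h[b] @ p.W_f.data[:, k] + x[b] @ p.U_f.data[:, k]
                    + p.b_f.data[k])
            i = sig(h[b] @ p.W_i.data[:, k] + x[b] @ p.U_i.data[:, k]
                    + p.b_i.data[k])
            o = sig(h[b] @ p.W_o.data[:, k] + x[b] @ p.U_o.data[:, k]
                    + p.b_o.data[k])
            cand = np.tanh(h[b] @ p.W_c.data[:, k] + x[b] @ p.U_c.data[:, k]
                           + p.b_c.data[k])
            out_c[b, k] = f * c[b, k] + i * cand
            out_h[b, k] = o * np.tanh(out_c[b, k])
    return out_h, out_c


# -------------------------------------------------------------------- LSTM
def test_lstm_zero_parameters_zero_state():
    p = zero_lstm(3, 2)
    h, c = lstm_step(Tensor(np.ones((1, 2))), Tensor(np.zeros((1, 3))),
                     Tensor(np.zeros((1, 3))), p)
    assert np.allclose(c.data, 0.0) and np.allclose(h.data, 0.0)


def test_lstm_zero_parameters_carried_cell_closed_form():
    """All-zero params with C_prev=c: gates are 0.5, so C=c/2 and
    h = 0.5*tanh(c/2)."""
    p = zero_lstm(3, 2)
    c_prev = np.array([[0.8, -1.2, 2.0]])
    h, c = lstm_step(Tensor(np.zeros((1, 2))), Tensor(np.zeros((1, 3))),
                     Tensor(c_prev), p)
    assert np.allclose(c.data, 0.5 * c_prev, atol=1e-12)
    assert np.allclose(h.data, 0.5 * np.tanh(0.5 * c_prev), atol=1e-12)


def test_lstm_matches_scalar_loop_oracle():
    for trial in range(50):
        r = np.random.default_rng(7000 + trial)
        h_dim, d = int(r.integers(2, 6)), int(r.integers(1, 5))
        p = random_lstm(h_dim, d, r)
        x = r.normal(size=(2, d))
        h0 = r.normal(size=(2, h_dim))
        c0 = r.normal(size=(2, h_dim))
        h, c = lstm_step(Tensor(x), Tensor(h0), Tensor(c0), p)
        rh, rc = ref_lstm_step(x, h0, c0, p)
        assert np.abs(h.data - rh).max() < 1e-6
        assert np.abs(c.data - rc).max() < 1e-6


def test_lstm_hidden_state_bounded():
    r = np.random.default_rng(3)
    p = random_lstm(4, 3, r)
    h = Tensor(np.zeros((5, 4)))
    c = Tensor(np.zeros((5, 4)))
    for _ in range(10):
        h, c = lstm_step(Tensor(r.normal(size=(5, 3)) * 3), h, c, p)
    assert np.abs(h.data).max() <= 1.0


# --------------------------------------------------------------- dense map
def test_dense_map_identity_zero_and_random_oracle():
    x = rng.normal(size=(3, 4, 5))
    w = rng.normal(size=(4, 5))
    a = rng.normal(size=(4, 5))
    assert np.allclose(
        dense_map(Tensor(x), Tensor(np.ones((4, 5))),
                  Tensor(np.zeros((4, 5)))).data, x)
    assert np.allclose(
        dense_map(Tensor(np.zeros_like(x)), Tensor(w), Tensor(a)).data,
        np.broadcast_to(a, x.shape))
    out = dense_map(Tensor(x), Tensor(w), Tensor(a)).data
    assert np.abs(out - (x * w + a)).max() < 1e-12


# --------------------------------------------------------------- attention
def test_attention_uniform_for_identical_scores():
    w = attention_weights(Tensor(np.full((2, 4), 0.3)), axis=1)
    assert np.allclose(w.data, 0.25, atol=1e-12)


def test_attention_single_timestep_is_one():
    w = attention_weights(Tensor(np.array([[1.7]])), axis=1)
    assert np.allclose(w.data, 1.0)


def test_attention_hand_computed_case():
    scores = np.array([[0.2, -1.0, 0.7]])
    t = np.tanh(scores)
    expected = np.exp(t) / np.exp(t).sum()
    w = attention_weights(Tensor(scores), axis=1)
    assert np.abs(w.data - expected).max() < 1e-9


def test_attention_weights_sum_to_one_property():
    for trial in range(50):
        r = np.random.default_rng(8000 + trial)
        scores = r.normal(size=(3, int(r.integers(1, 8)))) * 5
        w = attention_weights(Tensor(scores), axis=1).data
        assert (w >= 0).all()
        assert np.abs(w.sum(axis=1) - 1.0).max() < 1e-9


def test_attention_pool_uniform_and_onehot_and_oracle():
    feats = rng.normal(size=(2, 4, 3))
    uni = attention_pool(Tensor(np.full((2, 4), 0.25)), Tensor(feats))
    assert np.allclose(uni.data, feats.mean(axis=1), atol=1e-12)
    onehot = np.zeros((2, 4))
    onehot[:, 2] = 1.0
    sel = attention_pool(Tensor(onehot), Tensor(feats))
    assert np.allclose(sel.data, feats[:, 2, :], atol=1e-12)
    w = rng.dirichlet(np.ones(4), size=2)
    out = attention_pool(Tensor(w), Tensor(feats)).data
    ref = np.zeros((2, 3))
    for b in range(2):
        for t in range(4):
            ref[b] += w[b, t] * feats[b, t]
    assert np.abs(out - ref).max() < 1e-9


# -------------------------------------------------------------------- gate
def test_gate_zero_product_is_half():
    g = gate_value(Tensor(np.zeros((2, 3))), Tensor(rng.normal(size=(2, 3))))
    assert np.allclose(g.data, 0.5, atol=1e-12)


def test_gate_monotone_to_one():
    vals = [gate_value(Tensor(np.array([[s]])),
                       Tensor(np.array([[1.0]]))).data[0, 0]
            for s in (0.0, 1.0, 5.0, 20.0)]
    assert all(b > a for a, b in zip(vals, vals[1:]))
    assert vals[-1] > 1 - 1e-8


def test_gate_random_oracle():
    r_arr = rng.normal(size=(3, 4))
    fz = rng.normal(size=(3, 4))
    g = gate_value(Tensor(r_arr), Tensor(fz)).data
    assert np.abs(g - 1.0 / (1.0 + np.exp(-r_arr * fz))).max() < 1e-9


# ---------------------------------------------------------------- residual
def test_residual_identity_skip():
    lin = Linear(3, 3, rng=np.random.default_rng(0))
    lin.weight.data[...] = 0.0
    bn = BatchNorm1d(3)
    bn.eval()
    x = rng.normal(size=(4, 3))
    out = residual_block(Tensor(x), lin, bn, Tensor(x))
    # zero branch -> BN(ReLU(0)) = 0 (fresh running stats), plus bias = x
    assert np.allclose(out.data, x, atol=1e-6)


def test_residual_stepwise_oracle():
    for trial in range(50):
        r = np.random.default_rng(9000 + trial)
        lin = Linear(4, 3, rng=r)
        bn = BatchNorm1d(3)
        bn.eval()
        bn.running_mean = r.normal(size=3)
        bn.running_var = r.uniform(0.5, 2.0, 3)
        bias = r.normal(size=3)
        x = r.normal(size=(5, 4))
        out = residual_block(Tensor(x), lin, bn, Tensor(bias)).data
        pre = np.maximum(x @ lin.weight.data + lin.bias.data, 0.0)
        normed = (pre - bn.running_mean) / np.sqrt(bn.running_var + bn.eps)
        ref = normed * bn.gamma.data + bn.beta.data + bias
        assert np.abs(out - ref).max() < 1e-6


# ---------------------------------------------------------------- composed
def test_forward_contract_untrained(tiny_eted_config):
    model = GatedAttentionLSTM(36, tiny_eted_config,
                               rng=np.random.default_rng(0))
    model.eval()
    out = eted_forward(model, rng.normal(size=(5, 36)))
    assert ((out.probability > 0) & (out.probability < 1)).all()
    assert np.abs(out.attention.sum(axis=1) - 1.0).max() < 1e-9
    assert ((out.gate > 0) & (out.gate < 1)).all()


def test_forward_duplicated_sample_identical_output(tiny_eted_config):
    model = GatedAttentionLSTM(36, tiny_eted_config,
                               rng=np.random.default_rng(0))
    model.eval()
    x = rng.normal(size=(1, 36))
    batch = np.vstack([x, rng.normal(size=(2, 36)), x])
    out = model(batch)
    assert np.allclose(out.probability[0], out.probability[3], atol=1e-12)


def test_forward_matches_chained_operation_oracle(tiny_eted_config):
    """Composition: the model forward equals manually chaining the
    individual operations in the documented order."""
    cfg = tiny_eted_config
    model = GatedAttentionLSTM(36, cfg, rng=np.random.default_rng(4))
    model.eval()
    x = rng.normal(size=(3, 36))
    out = model(x)

    data = model._pad(x)
    b, t, d = 3, cfg.n_timesteps, model.step_dim
    xt = Tensor(data.reshape(b, t, d))
    z = dense_map(xt, model.dm_w, model.dm_a)
    h = Tensor(np.zeros((b, cfg.hidden_size)))
    c = Tensor(np.zeros((b, cfg.hidden_size)))
    hiddens = []
    for step in range(t):
        h, c = lstm_step(z[:, step, :], h, c, model.lstm)
        hiddens.append(h.data)
    traj = np.stack(hiddens, axis=1)
    scores = traj.reshape(b * t, -1) @ model.att_v.data + model.att_b.data
    w = attention_weights(Tensor(scores.reshape(b, t)), axis=1)
    pooled = attention_pool(w, Tensor(traj))
    fz = model.gate_lin(z.mean(axis=1))
    gate = gate_value(pooled, fz)
    gated = pooled * gate
    res = residual_block(Tensor(data), model.res_lin, model.res_bn,
                         model.res_bias)
    logit = model.head(gated + res).data.reshape(b)
    prob = 1.0 / (1.0 + np.exp(-logit))
    assert np.abs(prob - out.probability).max() < 1e-5


def test_composed_model_gradient_check():
    cfg = EtedConfig(hidden_size=3, n_timesteps=2)
    model = GatedAttentionLSTM(6, cfg, rng=np.random.default_rng(5))
    model.eval()
    x = np.random.default_rng(6).normal(size=(4, 6))
    y = np.array([1.0, 0.0, 1.0, 0.0])

    def loss_fn():
        logit = model(x).tensor
        return (logit.softplus() - logit * y).mean()

    params = [model.lstm.W_f, model.dm_w, model.att_v, model.res_bias,
              model.head.weight]
    assert gradient_check(loss_fn, params, eps=1e-5) < 1e-3


# ---------------------------------------------------------------- training
def test_memorization_small_dataset():
    r = np.random.default_rng(9)
    x = r.normal(size=(32, 36))
    y = (r.uniform(size=32) < 0.5).astype(int)
    y[:2] = [0, 1]  # both classes
    cfg = EtedConfig(epochs=300, early_stopping_patience=300,
                     learning_rate=5e-3, batch_size=8)
    res = train_eted(x, y, cfg, seed=0, train_idx=np.arange(32),
                     val_idx=np.arange(32))
    preds = (res.predict(x) >= 0.5).astype(int)
    assert (preds == y).mean() == 1.0


def test_training_determinism():
    spec = strong_cohort_spec(n_patients=120, seed=5)
    recs, _ = generate_clinical_cohort(spec)
    x = np.stack([r.vector() for r in recs])
    y = np.array([r.label for r in recs])
    cfg = EtedConfig(epochs=5)
    h1 = train_eted(x, y, cfg, seed=3).history
    h2 = train_eted(x, y, cfg, seed=3).history
    assert h1 == h2


def test_single_class_training_rejected():
    x = rng.normal(size=(20, 36))
    with pytest.raises(ValueError, match="both classes"):
        train_eted(x, np.zeros(20, dtype=int))


def test_standardizer_no_leakage():
    """Fitting statistics must not change when the test split changes."""
    x = rng.normal(size=(50, 4))
    sc = Standardizer.fit(x[:40])
    sc2 = Standardizer.fit(x[:40])
    assert np.allclose(sc.mean, sc2.mean) and np.allclose(sc.sd, sc2.sd)
    tr = sc.transform(x[:40])
    assert np.abs(tr.mean(axis=0)).max() < 1e-9
    assert np.abs(tr.std(axis=0) - 1.0).max() < 1e-9


def test_stratified_split_preserves_class_balance():
    y = np.r_[np.ones(20), np.zeros(80)].astype(int)
    tr, va = stratified_split(y, 0.8, np.random.default_rng(0))
    assert len(tr) + len(va) == 100
    assert y[tr].sum() == 16 and y[va].sum() == 4
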