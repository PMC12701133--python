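"""Gated-attention LSTM classifier for seven-day survival prediction.

The model maps a patient's feature vector (36 clinical indicators, plus
facial features in the multimodal arm) to a death-within-seven-days
probability.  The tabular vector is partitioned into ``T`` ordered
pseudo-timesteps, each passed through a per-step elementwise affine
("dense map"), then through an LSTM.  An attention layer scores the hidden
trajectory (softmax of tanh of the scores across timesteps, so the weights
are nonnegative and sum to one per sample), pools it, and a sigmoid gate —
driven by the dense-map summary — multiplicatively modulates the pooled
representation.  A batch-normalised ReLU residual branch of the raw input
is added back before the linear + sigmoid output head.

Every stage is exposed as a standalone function (``lstm_step``,
``dense_map``, ``attention_weights``, ``attention_pool``, ``gate_value``,
``residual_block``) so each can be checked against independent scalar-loop
oracles; ``GatedAttentionLSTM`` composes exactly these pieces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, stack
from .config import EtedConfig, SplitConfig
from .metrics import ClassificationMetrics, classification_metrics
from .nn import Adam, BatchNorm1d, Linear, Module

__all__ = [
    "LSTMParams", "LSTMCell", "lstm_step", "dense_map", "attention_weights",
    "attention_pool", "gate_value", "residual_block", "GatedAttentionLSTM",
    "eted_forward", "train_eted", "TrainResult", "Standardizer",
    "stratified_split",
]


@dataclass
class LSTMParams:
    """Gate weights: W_* act on the hidden state, U_* on the input."""

    W_f: Tensor
    W_i: Tensor
    W_c: Tensor
    W_o: Tensor
    U_f: Tensor
    U_i: Tensor
    U_c: Tensor
    U_o: Tensor
    b_f: Tensor
    b_i: Tensor
    b_c: Tensor
    b_o: Tensor


def lstm_step(x_t: Tensor, h_prev: Tensor, c_prev: Tensor,
              p: LSTMParams) -> tuple[Tensor, Tensor]:
    """One LSTM step.

    ``f,i,o = sigmoid(W h + U x + b)``;
    ``C = f*C_prev + i*tanh(W_c h + U_c x + b_c)``; ``h = o*tanh(C)``.
    With all parameters zero and zero previous state the gates are 0.5 and
    both outputs are exactly zero.
    """
    f = (h_prev @ p.W_f + x_t @ p.U_f + p.b_f).sigmoid()
    i = (h_prev @ p.W_i + x_t @ p.U_i + p.b_i).sigmoid()
    o = (h_prev @ p.W_o + x_t @ p.U_o + p.b_o).sigmoid()
    c = f * c_prev + i * (h_prev @ p.W_c + x_t @ p.U_c + p.b_c).tanh()
    h = o * c.tanh()
    return h, c


def dense_map(x: Tensor, w: Tensor, alpha: Tensor,
              mode: str = "elementwise") -> Tensor:
    """Per-layer affine map ``z = x*w + alpha``.

    ``elementwise`` applies the product entry-by-entry (the default reading
    of the printed matrix form); ``matmul`` uses a true matrix product as a
    config-selectable alternative.
    """
    if mode == "elementwise":
        return x * w + alpha
    if mode == "matmul":
        return x @ w + alpha
    raise ValueError(f"unknown dense_map mode {mode!r}")


def attention_weights(scores: Tensor, axis: int = -1) -> Tensor:
    """``softmax(tanh(scores))`` across timesteps.

    One weight per timestep per sample; nonnegative, summing to 1.  A
    single timestep yields weight 1 (degenerate softmax).
    """
    if scores.shape[axis] < 1:
        raise ValueError("need at least one timestep")
    return scores.tanh().softmax(axis=axis)


def attention_pool(weights: Tensor, features: Tensor) -> Tensor:
    """Weighted sum over timesteps: ``R = sum_t w_t * feature_t``.

    ``weights``: (B, T); ``features``: (B, T, D) -> (B, D).
    """
    if weights.shape[-1] != features.shape[1]:
        raise ValueError("weights and features disagree on timestep count")
    return (weights.reshape(weights.shape[0], weights.shape[1], 1)
            * features).sum(axis=1)


def gate_value(r: Tensor, fz: Tensor) -> Tensor:
    """Sigmoid gate ``sigmoid(R * f(z))``, elementwise, in (0,1)."""
    if r.shape != fz.shape:
        raise ValueError(f"gate operands disagree: {r.shape} vs {fz.shape}")
    return (r * fz).sigmoid()


def residual_block(z_features: Tensor, linear: Linear, bn: BatchNorm1d,
                   bias: Tensor) -> Tensor:
    """``BN(ReLU(linear(Z))) + bias`` — the skip branch added to the gated
    representation."""
    return bn(linear(z_features).relu()) + bias


@dataclass
class ETEDOutput:
    probability: np.ndarray          # (B,) in (0,1)
    attention: np.ndarray            # (B, T), rows sum to 1
    gate: np.ndarray                 # (B, H) in (0,1)
    hidden_trajectory: np.ndarray    # (B, T, H)
    tensor: Tensor | None = None     # graph output (training use)


class GatedAttentionLSTM(Module):
    """The composed survival classifier."""

    def __init__(self, n_features: int, cfg: EtedConfig | None = None,
                 rng: np.random.Generator | None = None):
        cfg = cfg or EtedConfig()
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        t = cfg.n_timesteps
        self.n_features = n_features
        self.step_dim = int(np.ceil(n_features / t))
        self.padded = self.step_dim * t
        h = cfg.hidden_size
        d = self.step_dim

        def mat(shape, scale):
            return Tensor(rng.uniform(-scale, scale, shape), requires_grad=True)

        sh, sd = np.sqrt(1 / h), np.sqrt(1 / d)
        self.lstm = LSTMParams(
            W_f=mat((h, h), sh), W_i=mat((h, h), sh), W_c=mat((h, h), sh),
            W_o=mat((h, h), sh),
            U_f=mat((d, h), sd), U_i=mat((d, h), sd), U_c=mat((d, h), sd),
            U_o=mat((d, h), sd),
            b_f=Tensor(np.ones(h), requires_grad=True),
            b_i=Tensor(np.zeros(h), requires_grad=True),
            b_c=Tensor(np.zeros(h), requires_grad=True),
            b_o=Tensor(np.zeros(h), requires_grad=True))
        # dense map: per-timestep elementwise affine
        self.dm_w = Tensor(np.ones((t, d)), requires_grad=True)
        self.dm_a = Tensor(np.zeros((t, d)), requires_grad=True)
        # attention projection h_t -> scalar score
        self.att_v = mat((h, 1), sh)
        self.att_b = Tensor(np.zeros(1), requires_grad=True)
        # gate drive: dense-map summary -> hidden dim
        self.gate_lin = Linear(d, h, rng=rng)
        # residual branch on the raw (padded) features
        self.res_lin = Linear(self.padded, h, rng=rng)
        self.res_bn = BatchNorm1d(h)
        self.res_bias = Tensor(np.zeros(h), requires_grad=True)
        self.head = Linear(h, 1, rng=rng)

    def _pad(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] == self.padded:
            return x
        out = np.zeros((x.shape[0], self.padded))
        out[:, :x.shape[1]] = x
        return out

    def forward(self, x: np.ndarray | Tensor) -> ETEDOutput:
        data = x.data if isinstance(x, Tensor) else np.asarray(x, dtype=float)
        if data.ndim != 2:
            raise ValueError("expected (batch, features)")
        data = self._pad(data)
        b = data.shape[0]
        t, d, h = self.cfg.n_timesteps, self.step_dim, self.cfg.hidden_size
        xt = Tensor(data.reshape(b, t, d))
        z = dense_map(xt, self.dm_w, self.dm_a, self.cfg.dense_map_mode)
        h_state = Tensor(np.zeros((b, h)))
        c_state = Tensor(np.zeros((b, h)))
        hiddens = []
        for step in range(t):
            h_state, c_state = lstm_step(z[:, step, :], h_state, c_state,
                                         self.lstm)
            hiddens.append(h_state)
        traj = stack(hiddens, axis=1)                       # (B, T, H)
        scores = (traj.reshape(b * t, h) @ self.att_v + self.att_b) \
            .reshape(b, t)
        weights = attention_weights(scores, axis=1)
        if self.cfg.gate_location == "hidden":
            fz = self.gate_lin(z.mean(axis=1))
            gate = gate_value(traj[:, -1, :], fz)
            pooled = attention_pool(weights, traj * gate.reshape(b, 1, h))
            gated = pooled
        else:
            pooled = attention_pool(weights, traj)
            fz = self.gate_lin(z.mean(axis=1))
            gate = gate_value(pooled, fz)
            gated = pooled * gate
        res = residual_block(xt.reshape(b, t * d), self.res_lin,
                             self.res_bn, self.res_bias)
        merged = gated + res
        logit = self.head(merged).reshape(b)
        prob = logit.sigmoid()
        return ETEDOutput(
            probability=prob.data.copy(), attention=weights.data.copy(),
            gate=gate.data.copy(), hidden_trajectory=traj.data.copy(),
            tensor=logit)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        self.eval()
        return self.forward(x).probability


def eted_forward(model: GatedAttentionLSTM, x: np.ndarray) -> ETEDOutput:
    """Functional forward pass (eval-mode semantics left to the caller)."""
    return model(x)


@dataclass
class Standardizer:
    """Mean-impute then z-score with statistics from the training split only."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, x: np.ndarray) -> "Standardizer":
        with np.errstate(all="ignore"):
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                mean = np.nanmean(x, axis=0)
        mean = np.where(np.isfinite(mean), mean, 0.0)
        filled = np.where(np.isnan(x), mean, x)
        sd = filled.std(axis=0, ddof=0)
        # guard against constant columns, incl. float dust around the mean
        tiny = 1e-9 * np.maximum(1.0, np.abs(mean))
        sd = np.where(sd > tiny, sd, 1.0)
        return cls(mean=mean, sd=sd)

    def transform(self, x: np.ndarray) -> np.ndarray:
        filled = np.where(np.isnan(x), self.mean, x)
        return (filled - self.mean) / self.sd


def stratified_split(y: np.ndarray, train_fraction: float, rng,
                     stratified: bool = True):
    """Deterministic (seeded) train/validation index split."""
    n = len(y)
    idx = np.arange(n)
    if stratified:
        train, val = [], []
        for cls in np.unique(y):
            cls_idx = rng.permutation(idx[y == cls])
            k = int(round(train_fraction * len(cls_idx)))
            k = min(max(k, 1), len(cls_idx) - 1) if len(cls_idx) > 1 else k
            train.extend(cls_idx[:k])
            val.extend(cls_idx[k:])
        return np.sort(np.array(train)), np.sort(np.array(val))
    perm = rng.permutation(idx)
    k = int(round(train_fraction * n))
    return np.sort(perm[:k]), np.sort(perm[k:])


@dataclass
class TrainResult:
    model: GatedAttentionLSTM
    history: list[dict]
    train_idx: np.ndarray
    val_idx: np.ndarray
    scaler: Standardizer
    best_epoch: int
    val_metrics: ClassificationMetrics | None = None

    def predict(self, x_raw: np.ndarray) -> np.ndarray:
        return self.model.predict_proba(self.scaler.transform(x_raw))


def train_eted(x: np.ndarray, y: np.ndarray, cfg: EtedConfig | None = None,
               split: SplitConfig | None = None, seed: int = 0,
               train_idx: np.ndarray | None = None,
               val_idx: np.ndarray | None = None) -> TrainResult:
    """Train the classifier with BCE loss, Adam, early stopping on val AUC.

    Standardisation and imputation statistics come from the training split
    only.  ``train_idx``/``val_idx`` may be supplied to reuse a split across
    experimental arms; otherwise a seeded stratified split is drawn.
    """
    cfg = cfg or EtedConfig()
    split = split or SplitConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training requires both classes present")
    rng = np.random.default_rng(seed)
    if train_idx is None or val_idx is None:
        train_idx, val_idx = stratified_split(
            y, split.train_fraction, rng, split.stratified)
    scaler = Standardizer.fit(x[train_idx])
    xtr, ytr = scaler.transform(x[train_idx]), y[train_idx]
    xva, yva = scaler.transform(x[val_idx]), y[val_idx]

    model = GatedAttentionLSTM(x.shape[1], cfg, rng=rng)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    history: list[dict] = []
    best_auc, best_epoch, best_state = -np.inf, -1, None
    best_key = (-np.inf, -np.inf)   # (auc, accuracy) tie-break for the state
    patience = cfg.early_stopping_patience
    n = len(xtr)
    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(n)
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            if len(idx) < 2:
                continue  # single-sample batch undefined under batch norm
            out = model(xtr[idx])
            logit = out.tensor
            yb = ytr[idx].astype(float)
            loss = (logit.softplus() - logit * yb).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
        model.eval()
        val_scores = model(xva).probability
        m = classification_metrics(yva, val_scores, cfg.threshold)
        history.append({"epoch": epoch, "accuracy": m.accuracy,
                        "precision": m.precision, "recall": m.recall,
                        "f1": m.f1, "auc": m.auc})
        if (m.auc, m.accuracy) > best_key:
            best_key = (m.auc, m.accuracy)
            best_state = [a.copy() for a in model.state_arrays()]
        if m.auc > best_auc + 1e-12:
            best_auc, best_epoch = m.auc, epoch
        elif epoch - best_epoch >= patience:
            break
    if best_state is not None:
        model.load_state_arrays(best_state)
    model.eval()
    final = classification_metrics(yva, model(xva).probability, cfg.threshold)
    return TrainResult(model=model, history=history, train_idx=train_idx,
                       val_idx=val_idx, scaler=scaler, best_epoch=best_epoch,
                       val_metrics=final)
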