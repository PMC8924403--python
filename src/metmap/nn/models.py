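"""Architecture specs, numpy networks, and the training loop.

All three networks are implemented directly in numpy with analytic
gradients and Adam, which keeps training bit-reproducible under a seed on
any machine.  Architectures:

* Simple CNN: embedding (dim 50) → 1-D convolution (64 filters, kernel 3,
  ReLU) → global max pooling → dense 10 (ReLU) → dense 1 (sigmoid).
* Augmented CNN: the same stack with a local multiplicative self-attention
  layer between the convolution and the pooling.  Scores
  e_{t,s} = sigmoid(h_tᵀ W h_s + b) over a window |s−t| ≤ ⌊width/2⌋; in
  normalized mode the window scores are divided by their sum (at width 1
  this makes a_{t,t} = 1, a near-identity — see the methods note), in
  un-normalized mode the raw sigmoid scores weight the window sum.
* Bi-LSTM: embedding (dim 64) → bidirectional LSTM (32 units per
  direction, concatenated to 64; tanh cell activation, sigmoid recurrent
  activation, masked per-batch padding) → dense 64 (ReLU) → dense 1 with
  no activation (a logit); trained with from-logits cross-entropy.
"""

from __future__ import annotations

import copy
import dataclasses
import math
from typing import Sequence

import numpy as np


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class CnnSpec:
    embedding_dim: int = 50
    filters: int = 64
    kernel_size: int = 3
    dense_units: int = 10
    max_len: int = 64  # set from the training 95th percentile by classifiers


@dataclasses.dataclass
class AttentionSpec:
    width: int = 1
    normalize: bool = True


@dataclasses.dataclass
class BilstmSpec:
    embedding_dim: int = 64
    units_per_direction: int = 32  # concatenated output dimension 64
    dense_units: int = 64


@dataclasses.dataclass
class TrainConfig:
    epochs: int = 30
    batch_size: int = 32
    patience: int = 5
    learning_rate: float = 1e-3
    clip_norm: float = 5.0
    seed: int = 0


# ---------------------------------------------------------------------------
# numerics
# ---------------------------------------------------------------------------


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def bce_from_probs(p: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-7
    p = np.clip(p, eps, 1 - eps)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def bce_from_logits(z: np.ndarray, y: np.ndarray) -> float:
    # log(1+exp(-|z|)) + max(z,0) - z*y  (numerically stable)
    return float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3) -> None:
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-7
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= (
                self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
            )


def _clip_global_norm(grads: dict[str, np.ndarray], max_norm: float) -> None:
    total = math.sqrt(sum(float((g * g).sum()) for g in grads.values()))
    if total > max_norm > 0:
        scale = max_norm / total
        for g in grads.values():
            g *= scale


# ---------------------------------------------------------------------------
# CNN (with optional local self-attention)
# ---------------------------------------------------------------------------


class CNNNet:
    """Text CNN over fixed-length padded index sequences.

    ``attention=None`` gives the simple CNN; an :class:`AttentionSpec`
    inserts the windowed multiplicative self-attention after the
    convolution.  Output of :meth:`forward` is the positive-class
    probability.
    """

    outputs_logits = False

    def __init__(
        self,
        spec: CnnSpec,
        vocab_size: int,
        seed: int = 0,
        attention: AttentionSpec | None = None,
    ) -> None:
        if attention is not None and attention.width % 2 != 1:
            raise ValueError("attention width must be odd")
        self.spec = spec
        self.attention = attention
        rng = np.random.default_rng(seed)
        D, F, K, U = spec.embedding_dim, spec.filters, spec.kernel_size, spec.dense_units
        self.params: dict[str, np.ndarray] = {
            "emb": rng.uniform(-0.05, 0.05, size=(vocab_size + 1, D)),
            "Wc": _glorot(rng, K * D, F, (K * D, F)),
            "bc": np.zeros(F),
            "W1": _glorot(rng, F, U, (F, U)),
            "b1": np.zeros(U),
            "W2": _glorot(rng, U, 1, (U, 1)),
            "b2": np.zeros(1),
        }
        if attention is not None:
            self.params["Wa"] = _glorot(rng, F, F, (F, F))
            self.params["ba"] = np.zeros(1)
        self._cache: dict = {}

    def parameter_counts(self) -> dict[str, int]:
        return {k: int(v.size) for k, v in self.params.items()}

    # -- attention sub-layer -------------------------------------------------

    def _attend_forward(self, H: np.ndarray) -> np.ndarray:
        att = self.attention
        B, T, F = H.shape
        k = att.width // 2
        HW = H @ self.params["Wa"]  # (B,T,F)
        offsets = [d for d in range(-k, k + 1) if abs(d) < T]
        E: dict[int, np.ndarray] = {}
        for d in offsets:
            t_sl = slice(max(0, -d), T - max(0, d))
            s_sl = slice(max(0, d), T - max(0, -d))
            Z = np.einsum("btf,btf->bt", HW[:, t_sl], H[:, s_sl]) + self.params["ba"]
            Ed = np.zeros((B, T))
            Ed[:, t_sl] = sigmoid(Z)
            E[d] = Ed
        if att.normalize:
            S = sum(E.values())
            A = {d: E[d] / S for d in offsets}
        else:
            S = None
            A = E
        O = np.zeros_like(H)
        for d in offsets:
            t_sl = slice(max(0, -d), T - max(0, d))
            s_sl = slice(max(0, d), T - max(0, -d))
            O[:, t_sl] += A[d][:, t_sl, None] * H[:, s_sl]
        self._cache["att"] = (H, HW, E, A, S, offsets)
        return O

    def _attend_backward(self, dO: np.ndarray) -> np.ndarray:
        H, HW, E, A, S, offsets = self._cache["att"]
        B, T, F = H.shape
        dH = np.zeros_like(H)
        dHW = np.zeros_like(HW)
        dA: dict[int, np.ndarray] = {}
        for d in offsets:
            t_sl = slice(max(0, -d), T - max(0, d))
            s_sl = slice(max(0, d), T - max(0, -d))
            dAd = np.zeros((B, T))
            dAd[:, t_sl] = np.einsum("btf,btf->bt", dO[:, t_sl], H[:, s_sl])
            dA[d] = dAd
            dH[:, s_sl] += A[d][:, t_sl, None] * dO[:, t_sl]
        if self.attention.normalize:
            inner = sum(dA[d] * A[d] for d in offsets)
            dE = {d: (dA[d] - inner) / S for d in offsets}
        else:
            dE = dA
        dba = 0.0
        for d in offsets:
            t_sl = slice(max(0, -d), T - max(0, d))
            s_sl = slice(max(0, d), T - max(0, -d))
            Ed = E[d][:, t_sl]
            dZ = dE[d][:, t_sl] * Ed * (1.0 - Ed)
            dHW[:, t_sl] += dZ[:, :, None] * H[:, s_sl]
            dH[:, s_sl] += dZ[:, :, None] * HW[:, t_sl]
            dba += float(dZ.sum())
        self.grads["Wa"] = H.reshape(-1, F).T @ dHW.reshape(-1, F)
        self.grads["ba"] = np.array([dba])
        dH += dHW @ self.params["Wa"].T
        return dH

    # -- forward / backward --------------------------------------------------

    def forward(self, X: np.ndarray) -> np.ndarray:
        """X: (B, L) int indices, 0-padded to the spec's fixed length."""
        p = self.params
        K = self.spec.kernel_size
        Emb = p["emb"][X]  # (B,L,D)
        B, L, D = Emb.shape
        T = L - K + 1
        Xc = np.concatenate([Emb[:, i : T + i, :] for i in range(K)], axis=2)
        Z = Xc @ p["Wc"] + p["bc"]
        H = np.maximum(Z, 0.0)
        Hp = self._attend_forward(H) if self.attention is not None else H
        argmax = Hp.argmax(axis=1)  # (B,F)
        P = np.take_along_axis(Hp, argmax[:, None, :], axis=1)[:, 0, :]
        A1 = P @ p["W1"] + p["b1"]
        R1 = np.maximum(A1, 0.0)
        logit = (R1 @ p["W2"] + p["b2"])[:, 0]
        prob = sigmoid(logit)
        self._cache.update(
            X=X, Xc=Xc, Z=Z, H=H, Hp=Hp, argmax=argmax, P=P, A1=A1, R1=R1, prob=prob
        )
        return prob

    def backward(self, y: np.ndarray) -> dict[str, np.ndarray]:
        c = self._cache
        p = self.params
        B = y.shape[0]
        F = self.spec.filters
        self.grads: dict[str, np.ndarray] = {}
        dlogit = (c["prob"] - y)[:, None] / B  # BCE + sigmoid combined
        self.grads["W2"] = c["R1"].T @ dlogit
        self.grads["b2"] = dlogit.sum(axis=0)
        dR1 = dlogit @ p["W2"].T
        dA1 = dR1 * (c["A1"] > 0)
        self.grads["W1"] = c["P"].T @ dA1
        self.grads["b1"] = dA1.sum(axis=0)
        dP = dA1 @ p["W1"].T  # (B,F)
        dHp = np.zeros_like(c["Hp"])
        np.put_along_axis(dHp, c["argmax"][:, None, :], dP[:, None, :], axis=1)
        dH = self._attend_backward(dHp) if self.attention is not None else dHp
        dZ = dH * (c["Z"] > 0)
        KD = c["Xc"].shape[2]
        self.grads["Wc"] = c["Xc"].reshape(-1, KD).T @ dZ.reshape(-1, F)
        self.grads["bc"] = dZ.sum(axis=(0, 1))
        dXc = dZ @ p["Wc"].T  # (B,T,K*D)
        D = self.spec.embedding_dim
        K = self.spec.kernel_size
        T = dXc.shape[1]
        dEmb_in = np.zeros((B, T + K - 1, D))
        for i in range(K):
            dEmb_in[:, i : T + i, :] += dXc[:, :, i * D : (i + 1) * D]
        demb = np.zeros_like(p["emb"])
        np.add.at(demb, c["X"].reshape(-1), dEmb_in.reshape(-1, D))
        self.grads["emb"] = demb
        return self.grads

    def loss(self, prob: np.ndarray, y: np.ndarray) -> float:
        return bce_from_probs(prob, y)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)


# ---------------------------------------------------------------------------
# Bi-LSTM
# ---------------------------------------------------------------------------


class BiLSTMNet:
    """Masked bidirectional LSTM over per-batch right-padded sequences.

    :meth:`forward` returns raw logits (final dense layer has no
    activation); probabilities are sigmoid(logit).  Padded timesteps carry
    hidden/cell state unchanged, so a sequence's output is independent of
    how much padding its batch partners force (padding invariance).
    """

    outputs_logits = True

    def __init__(self, spec: BilstmSpec, vocab_size: int, seed: int = 0) -> None:
        self.spec = spec
        rng = np.random.default_rng(seed)
        D, U, DU = spec.embedding_dim, spec.units_per_direction, spec.dense_units
        self.params: dict[str, np.ndarray] = {
            "emb": rng.uniform(-0.05, 0.05, size=(vocab_size, D)),
        }
        for dirn in ("f", "b"):
            self.params[f"Wx_{dirn}"] = _glorot(rng, D, 4 * U, (D, 4 * U))
            self.params[f"Wh_{dirn}"] = _glorot(rng, U, 4 * U, (U, 4 * U))
            bias = np.zeros(4 * U)
            bias[U : 2 * U] = 1.0  # forget-gate bias
            self.params[f"b_{dirn}"] = bias
        self.params["W1"] = _glorot(rng, 2 * U, DU, (2 * U, DU))
        self.params["b1"] = np.zeros(DU)
        self.params["W2"] = _glorot(rng, DU, 1, (DU, 1))
        self.params["b2"] = np.zeros(1)
        self._cache: dict = {}

    def parameter_counts(self) -> dict[str, int]:
        return {k: int(v.size) for k, v in self.params.items()}

    @staticmethod
    def _reverse_valid(X: np.ndarray, mask: np.ndarray) -> np.ndarray:
        """Reverse each row's real tokens in place, keep right padding."""
        Xr = np.zeros_like(X)
        lengths = mask.sum(axis=1).astype(int)
        for i, n in enumerate(lengths):
            Xr[i, :n] = X[i, :n][::-1]
        return Xr

    def _direction_forward(self, X: np.ndarray, mask: np.ndarray, dirn: str):
        p = self.params
        U = self.spec.units_per_direction
        B, L = X.shape
        Emb = p["emb"][X]  # (B,L,D)
        h = np.zeros((B, U))
        c = np.zeros((B, U))
        steps = []
        for t in range(L):
            z = Emb[:, t] @ p[f"Wx_{dirn}"] + h @ p[f"Wh_{dirn}"] + p[f"b_{dirn}"]
            i = sigmoid(z[:, :U])
            f = sigmoid(z[:, U : 2 * U])
            g = np.tanh(z[:, 2 * U : 3 * U])
            o = sigmoid(z[:, 3 * U :])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            m = mask[:, t][:, None]
            steps.append((i, f, g, o, c, h, tanh_c, m))
            h = m * h_new + (1 - m) * h
            c = m * c_new + (1 - m) * c
        return h, (X, Emb, steps)

    def _direction_backward(self, dh_final: np.ndarray, cache, dirn: str, demb):
        X, Emb, steps = cache
        p = self.params
        U = self.spec.units_per_direction
        B, L = X.shape
        dWx = np.zeros_like(p[f"Wx_{dirn}"])
        dWh = np.zeros_like(p[f"Wh_{dirn}"])
        db = np.zeros_like(p[f"b_{dirn}"])
        dh = dh_final.copy()
        dc = np.zeros((B, U))
        for t in range(L - 1, -1, -1):
            i, f, g, o, c_prev, h_prev, tanh_c, m = steps[t]
            dh_new = dh * m
            dc_new = dc * m
            do = dh_new * tanh_c
            dc_new = dc_new + dh_new * o * (1.0 - tanh_c * tanh_c)
            df = dc_new * c_prev
            di = dc_new * g
            dg = dc_new * i
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g * g),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            dWx += Emb[:, t].T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            np.add.at(demb, X[:, t], dz @ p[f"Wx_{dirn}"].T)
            dh = dh * (1 - m) + dz @ p[f"Wh_{dirn}"].T
            dc = dc * (1 - m) + dc_new * f
        self.grads[f"Wx_{dirn}"] = dWx
        self.grads[f"Wh_{dirn}"] = dWh
        self.grads[f"b_{dirn}"] = db

    def forward(self, X: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
        if mask is None:
            mask = (X != 0).astype(float)
        p = self.params
        Xr = self._reverse_valid(X, mask)
        hf, cache_f = self._direction_forward(X, mask, "f")
        hb, cache_b = self._direction_forward(Xr, mask, "b")
        Hcat = np.concatenate([hf, hb], axis=1)
        A1 = Hcat @ p["W1"] + p["b1"]
        R1 = np.maximum(A1, 0.0)
        logit = (R1 @ p["W2"] + p["b2"])[:, 0]
        self._cache = dict(
            cache_f=cache_f, cache_b=cache_b, Hcat=Hcat, A1=A1, R1=R1, logit=logit
        )
        return logit

    def backward(self, y: np.ndarray) -> dict[str, np.ndarray]:
        c = self._cache
        p = self.params
        B = y.shape[0]
        U = self.spec.units_per_direction
        self.grads = {}
        dlogit = (sigmoid(c["logit"]) - y)[:, None] / B
        self.grads["W2"] = c["R1"].T @ dlogit
        self.grads["b2"] = dlogit.sum(axis=0)
        dR1 = dlogit @ p["W2"].T
        dA1 = dR1 * (c["A1"] > 0)
        self.grads["W1"] = c["Hcat"].T @ dA1
        self.grads["b1"] = dA1.sum(axis=0)
        dHcat = dA1 @ p["W1"].T
        demb = np.zeros_like(p["emb"])
        self._direction_backward(dHcat[:, :U], c["cache_f"], "f", demb)
        self._direction_backward(dHcat[:, U:], c["cache_b"], "b", demb)
        self.grads["emb"] = demb
        return self.grads

    def loss(self, logit: np.ndarray, y: np.ndarray) -> float:
        return bce_from_logits(logit, y)

    def predict_proba(self, X: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
        return sigmoid(self.forward(X, mask))


# ---------------------------------------------------------------------------
# construction and training
# ---------------------------------------------------------------------------


def build_model(
    spec,
    vocab_size: int,
    *,
    attention: AttentionSpec | None = None,
    seed: int = 0,
):
    """Instantiate a network from its spec.

    ``CnnSpec`` → simple CNN; ``CnnSpec`` + ``attention`` → augmented CNN;
    ``BilstmSpec`` → bidirectional LSTM.
    """
    if isinstance(spec, CnnSpec):
        return CNNNet(spec, vocab_size, seed=seed, attention=attention)
    if isinstance(spec, BilstmSpec):
        return BiLSTMNet(spec, vocab_size, seed=seed)
    raise ValueError(f"unknown model spec {type(spec).__name__}")


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def _eval_loss(net, X, y, mask=None, batch_size: int = 256) -> float:
    losses, weights = [], []
    for start in range(0, len(y), batch_size):
        sl = slice(start, start + batch_size)
        if isinstance(net, BiLSTMNet):
            out = net.forward(X[sl], None if mask is None else mask[sl])
        else:
            out = net.forward(X[sl])
        losses.append(net.loss(out, y[sl]))
        weights.append(len(y[sl]))
    return float(np.average(losses, weights=weights))


def train_model(
    net,
    X_train,
    y_train: np.ndarray,
    X_val,
    y_val: np.ndarray,
    config: TrainConfig,
) -> dict:
    """Minimize binary cross-entropy with Adam; keep the best-val checkpoint.

    For the CNNs, ``X_*`` are fixed-length (n, L) index arrays.  For the
    Bi-LSTM, ``X_*`` are lists of variable-length index sequences that are
    padded per batch.  Training stops early after ``config.patience``
    epochs without validation-loss improvement and restores the best
    weights.

    Raises
    ------
    ValueError
        If the training labels contain a single class.
    """
    from .tokenize import pad_batch

    y_train = np.asarray(y_train, dtype=float)
    y_val = np.asarray(y_val, dtype=float)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training labels contain a single class")
    rng = np.random.default_rng(config.seed)
    opt = Adam(net.params, lr=config.learning_rate)
    ragged = isinstance(net, BiLSTMNet)
    if ragged:
        X_val_padded, mask_val = pad_batch(X_val)
    history = {"train_loss": [], "val_loss": []}
    best_loss, best_params, best_epoch, bad_epochs = math.inf, None, 0, 0
    n = len(y_train)
    for epoch in range(config.epochs):
        epoch_losses, epoch_sizes = [], []
        for idx in _batches(n, config.batch_size, rng):
            yb = y_train[idx]
            if ragged:
                Xb, mb = pad_batch([X_train[i] for i in idx])
                out = net.forward(Xb, mb)
            else:
                out = net.forward(X_train[idx])
            epoch_losses.append(net.loss(out, yb))
            epoch_sizes.append(len(yb))
            grads = net.backward(yb)
            _clip_global_norm(grads, config.clip_norm)
            opt.step(net.params, grads)
        history["train_loss"].append(float(np.average(epoch_losses, weights=epoch_sizes)))
        if ragged:
            val_loss = _eval_loss(net, X_val_padded, y_val, mask_val)
        else:
            val_loss = _eval_loss(net, X_val, y_val)
        history["val_loss"].append(val_loss)
        if val_loss < best_loss - 1e-6:
            best_loss, best_epoch, bad_epochs = val_loss, epoch, 0
            best_params = copy.deepcopy(net.params)
        else:
            bad_epochs += 1
            if bad_epochs >= config.patience:
                break
    if best_params is not None:
        net.params = best_params
        if hasattr(net, "grads"):
            del net.grads
    history["best_epoch"] = best_epoch
    history["best_val_loss"] = best_loss
    return history
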