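"""The three sequence-aware architectures, as compact numpy networks.

All three consume the (6, 10) rostro-caudal sequence block plus the scalar
covariates and emit the 20 recovery-phase motor scores:

* ``conv_sequence`` -- 1-D convolutions along the rostro-caudal axis with
  modality channels and the scalar covariates broadcast as extra channels;
* ``seq2seq_attention`` -- a single-head self-attention encoder over the
  acute sequence and a cross-attention decoder with one learned query per
  output level, emitting both sides per level;
* ``graph_sequence`` -- message passing on a chain graph per side (rostral
  and caudal edges) with left-right cross edges between mirror myotomes.

Networks are deliberately small (well under 100k parameters) and train on a
single CPU in seconds to minutes.  Training is seed-reproducible; the
per-epoch loss curve is recorded on the fitted object.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Adam, Tensor, concat, conv1d, matmul, relu, softmax

__all__ = ["ConvSequenceNet", "Seq2SeqAttentionNet", "GraphSequenceNet"]

_N_LEVELS = 10
_N_SEQ_CH = 6
_N_SCAL = 11


def _glorot(rng: np.random.Generator, *shape) -> Tensor:
    fan_in, fan_out = shape[-2] if len(shape) > 1 else shape[0], shape[-1]
    if len(shape) == 3:  # conv kernels (out, in, k)
        fan_in, fan_out = shape[1] * shape[2], shape[0] * shape[2]
    scale = np.sqrt(2.0 / (fan_in + fan_out))
    return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)


def _zeros(*shape) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True)


class _NeuralFamily:
    """Shared minibatch Adam trainer for the sequence networks."""

    defaults = {"hidden": 32, "epochs": 60, "batch_size": 64, "lr": 3e-3}

    def __init__(self, hyperparams: dict | None = None):
        hp = dict(self.defaults)
        hp.update(hyperparams or {})
        self.hp = hp
        self.params: dict[str, Tensor] = {}
        self.loss_curve_: list[float] = []

    # subclasses: _init_params(rng), _prepare(X_seq, X_scal) -> inputs dict,
    # _forward(inputs-slice) -> Tensor (B, 20)
    def fit(self, X_seq: np.ndarray, X_scal: np.ndarray, y: np.ndarray,
            rng: np.random.Generator) -> "_NeuralFamily":
        self._init_params(rng)
        inputs = self._prepare(X_seq, X_scal)
        n = y.shape[0]
        opt = Adam(list(self.params.values()), lr=self.hp["lr"])
        bs = min(self.hp["batch_size"], n)
        self.loss_curve_ = []
        for _ in range(self.hp["epochs"]):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, bs):
                idx = order[start:start + bs]
                pred = self._forward(inputs[idx])
                diff = pred - Tensor(y[idx])
                loss = (diff * diff).mean()
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            self.loss_curve_.append(float(np.mean(losses)))
        return self

    def predict(self, X_seq: np.ndarray, X_scal: np.ndarray) -> np.ndarray:
        return self._forward(self._prepare(X_seq, X_scal)).data


class ConvSequenceNet(_NeuralFamily):
    """1-D CNN along the rostro-caudal axis, scalars broadcast as channels."""

    def _init_params(self, rng):
        h = self.hp["hidden"]
        self.params = {
            "W1": _glorot(rng, h, _N_SEQ_CH + _N_SCAL, 3), "b1": _zeros(h),
            "W2": _glorot(rng, h, h, 3), "b2": _zeros(h),
            "W3": _glorot(rng, h * _N_LEVELS, 64), "b3": _zeros(64),
            "W4": _glorot(rng, 64, 20), "b4": _zeros(20),
        }

    def _prepare(self, X_seq, X_scal):
        scal_ch = np.repeat(X_scal[:, :, None], _N_LEVELS, axis=2)
        return np.concatenate([X_seq, scal_ch], axis=1)  # (n, 17, 10)

    def _forward(self, x):
        p = self.params
        t = Tensor(x)
        B = x.shape[0]
        h = relu(conv1d(t, p["W1"], padding=1) + p["b1"].reshape(1, -1, 1))
        h = relu(conv1d(h, p["W2"], padding=1) + p["b2"].reshape(1, -1, 1))
        flat = h.reshape(B, -1)
        h2 = relu(matmul(flat, p["W3"]) + p["b3"])
        return matmul(h2, p["W4"]) + p["b4"]


class Seq2SeqAttentionNet(_NeuralFamily):
    """Attention encoder over the acute sequence, level-query decoder."""

    def _init_params(self, rng):
        d = self.hp["hidden"]
        self.params = {
            "Win": _glorot(rng, _N_SEQ_CH + _N_SCAL, d), "bin": _zeros(d),
            "pos": Tensor(rng.normal(0, 0.1, size=(_N_LEVELS, d)), requires_grad=True),
            "Wq": _glorot(rng, d, d), "Wk": _glorot(rng, d, d), "Wv": _glorot(rng, d, d),
            "Wf": _glorot(rng, d, d), "bf": _zeros(d),
            "Qdec": Tensor(rng.normal(0, 0.1, size=(_N_LEVELS, d)), requires_grad=True),
            "Wk2": _glorot(rng, d, d), "Wv2": _glorot(rng, d, d),
            "Wout": _glorot(rng, d, 2), "bout": _zeros(2),
        }

    def _prepare(self, X_seq, X_scal):
        pos_feats = np.swapaxes(X_seq, 1, 2)  # (n, 10, 6)
        scal = np.repeat(X_scal[:, None, :], _N_LEVELS, axis=1)
        return np.concatenate([pos_feats, scal], axis=2)  # (n, 10, 17)

    def _forward(self, x):
        p = self.params
        d = self.hp["hidden"]
        B = x.shape[0]
        emb = relu(matmul(Tensor(x), p["Win"]) + p["bin"]) + p["pos"]
        q, k, v = matmul(emb, p["Wq"]), matmul(emb, p["Wk"]), matmul(emb, p["Wv"])
        att = softmax(matmul(q, k.transpose(0, 2, 1)) * (1.0 / np.sqrt(d)))
        enc = relu(matmul(matmul(att, v), p["Wf"]) + p["bf"]) + emb
        k2, v2 = matmul(enc, p["Wk2"]), matmul(enc, p["Wv2"])
        att2 = softmax(matmul(p["Qdec"], k2.transpose(0, 2, 1)) * (1.0 / np.sqrt(d)))
        dec = matmul(att2, v2)  # (B, 10, d)
        out = matmul(dec, p["Wout"]) + p["bout"]  # (B, 10, 2)
        return out.reshape(B, 20)


def _chain_adjacency() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rostral, caudal and left-right mirror adjacency over the 20 nodes
    (level-major, left then right per level)."""
    n = 2 * _N_LEVELS
    rostral = np.zeros((n, n))
    caudal = np.zeros((n, n))
    mirror = np.zeros((n, n))
    for lev in range(_N_LEVELS):
        for side in range(2):
            i = 2 * lev + side
            if lev > 0:
                rostral[i, 2 * (lev - 1) + side] = 1.0
            if lev < _N_LEVELS - 1:
                caudal[i, 2 * (lev + 1) + side] = 1.0
            mirror[i, 2 * lev + (1 - side)] = 1.0
    return rostral, caudal, mirror


class GraphSequenceNet(_NeuralFamily):
    """Message passing on the two-sided myotome chain graph."""

    defaults = dict(_NeuralFamily.defaults, steps=3)

    def _init_params(self, rng):
        h = self.hp["hidden"]
        self._adj = tuple(Tensor(a) for a in _chain_adjacency())
        self.params = {"Win": _glorot(rng, 3 + _N_SCAL, h), "bin": _zeros(h)}
        for t in range(self.hp["steps"]):
            self.params.update({
                f"Ws{t}": _glorot(rng, h, h), f"Wr{t}": _glorot(rng, h, h),
                f"Wc{t}": _glorot(rng, h, h), f"Wm{t}": _glorot(rng, h, h),
                f"b{t}": _zeros(h),
            })
        self.params.update({"Wout": _glorot(rng, h, 1), "bout": _zeros(1)})

    def _prepare(self, X_seq, X_scal):
        n = X_seq.shape[0]
        node = np.empty((n, 2 * _N_LEVELS, 3))
        for lev in range(_N_LEVELS):
            for side in range(2):
                i = 2 * lev + side
                node[:, i, 0] = X_seq[:, 0 + side, lev]  # motor
                node[:, i, 1] = X_seq[:, 2 + side, lev]  # light touch
                node[:, i, 2] = X_seq[:, 4 + side, lev]  # pinprick
        scal = np.repeat(X_scal[:, None, :], 2 * _N_LEVELS, axis=1)
        return np.concatenate([node, scal], axis=2)  # (n, 20, 14)

    def _forward(self, x):
        p = self.params
        if not hasattr(self, "_adj"):  # restored from persistence
            self._adj = tuple(Tensor(a) for a in _chain_adjacency())
        A_r, A_c, A_m = self._adj
        B = x.shape[0]
        h = relu(matmul(Tensor(x), p["Win"]) + p["bin"])
        for t in range(self.hp["steps"]):
            msg = (
                matmul(h, p[f"Ws{t}"])
                + matmul(matmul(A_r, h), p[f"Wr{t}"])
                + matmul(matmul(A_c, h), p[f"Wc{t}"])
                + matmul(matmul(A_m, h), p[f"Wm{t}"])
                + p[f"b{t}"]
            )
            h = relu(msg)
        out = matmul(h, p["Wout"]) + p["bout"]  # (B, 20, 1)
        return out.reshape(B, 20)
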