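"""A small convolutional network for splice-boundary localisation, in numpy.

Input is a 21x4 one-hot encoded nucleotide window; output is a softmax
distribution over the 21 in-window boundary offsets.  The network is three
blocks of (3x3 convolution, 50 channels, ReLU, batch normalisation) followed
by a dense softmax head, trained with categorical cross-entropy under Adam
(learning rate 0.01 by default).  Implemented directly on numpy arrays in
float32 channels-last layout (forward/backward passes, batch-norm running
statistics and the Adam update are all explicit here), which keeps the
dependency surface to numpy alone.
"""

from __future__ import annotations

import numpy as np

WINDOW = 21
ALPHABET = 4
N_CLASSES = 21

_ONEHOT = {
    "A": (1.0, 0.0, 0.0, 0.0),
    "C": (0.0, 1.0, 0.0, 0.0),
    "G": (0.0, 0.0, 1.0, 0.0),
    "T": (0.0, 0.0, 0.0, 1.0),
    "N": (0.0, 0.0, 0.0, 0.0),
}


def encode_window(seq: str) -> np.ndarray:
    """One-hot encode a 21-base window (A,C,G,T as unit vectors, N as zeros)."""
    if len(seq) != WINDOW:
        raise ValueError(f"window must be {WINDOW} bases, got {len(seq)}")
    try:
        return np.array([_ONEHOT[b] for b in seq], dtype=np.float64)
    except KeyError as exc:
        raise ValueError(f"invalid base {exc.args[0]!r} in window") from None


class _Conv3x3:
    """Same-padded 3x3 convolution on channels-last (B, 21, 4, C) tensors.

    im2col + one GEMM per pass; channels-last avoids any transpose copies."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * 9))
        # weight layout (3, 3, C_in, C_out), flattened to (9*C_in, C_out)
        self.W = rng.normal(0.0, scale, size=(3, 3, c_in, c_out)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.c_in, self.c_out = c_in, c_out

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, H, W, C = x.shape
        self._shape = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        cols = np.empty((B, H, W, 9 * C), dtype=np.float32)
        k = 0
        for di in range(3):
            for dj in range(3):
                cols[..., k * C:(k + 1) * C] = xp[:, di:di + H, dj:dj + W, :]
                k += 1
        self._cols = cols.reshape(B * H * W, 9 * C)
        out = self._cols @ self.W.reshape(9 * C, self.c_out)
        out += self.b
        return out.reshape(B, H, W, self.c_out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, H, W, C = self._shape
        dflat = dout.reshape(-1, self.c_out)
        self.dW = (self._cols.T @ dflat).reshape(self.W.shape)
        self.db = dflat.sum(axis=0)
        dcols = (dflat @ self.W.reshape(9 * C, self.c_out).T).reshape(B, H, W, 9, C)
        dxp = np.zeros((B, H + 2, W + 2, C), dtype=np.float32)
        k = 0
        for di in range(3):
            for dj in range(3):
                dxp[:, di:di + H, dj:dj + W, :] += dcols[:, :, :, k, :]
                k += 1
        return dxp[:, 1:-1, 1:-1, :]

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]


class _BatchNorm:
    """Per-channel batch normalisation (channels-last) with running stats."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.run_mean = np.zeros(channels, dtype=np.float32)
        self.run_var = np.ones(channels, dtype=np.float32)
        self.momentum = np.float32(momentum)
        self.eps = np.float32(eps)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            one = np.float32(1.0)
            self.run_mean = self.momentum * self.run_mean + (one - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (one - self.momentum) * var
            self._std = np.sqrt(var + self.eps)
            self._xhat = (x - mean) / self._std
            return self.gamma * self._xhat + self.beta
        xhat = (x - self.run_mean) / np.sqrt(self.run_var + self.eps)
        return self.gamma * xhat + self.beta

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dgamma = (dout * self._xhat).sum(axis=(0, 1, 2))
        self.dbeta = dout.sum(axis=(0, 1, 2))
        dxhat = dout * self.gamma
        return (
            dxhat
            - dxhat.mean(axis=(0, 1, 2))
            - self._xhat * (dxhat * self._xhat).mean(axis=(0, 1, 2))
        ) / self._std

    def params(self):
        return [("gamma", self.gamma, self.dgamma), ("beta", self.beta, self.dbeta)]


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]


class _Adam:
    def __init__(self, lr: float = 0.01, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[int, np.ndarray] = {}
        self.v: dict[int, np.ndarray] = {}

    def step(self, params):
        self.t += 1
        for idx, (_, p, g) in enumerate(params):
            m = self.m.setdefault(idx, np.zeros_like(p))
            v = self.v.setdefault(idx, np.zeros_like(p))
            m[:] = self.b1 * m + (1 - self.b1) * g
            v[:] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)


class SpliceNet:
    """Three conv blocks (3x3, 50 channels, ReLU, batch-norm) + softmax head."""

    def __init__(self, channels: int = 50, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.convs = [
            _Conv3x3(ALPHABET, channels, rng),
            _Conv3x3(channels, channels, rng),
            _Conv3x3(channels, channels, rng),
        ]
        self.bns = [_BatchNorm(channels) for _ in range(3)]
        self.head = _Dense(channels * WINDOW, N_CLASSES, rng)
        self.channels = channels

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """x: (B, 21, 4) one-hot; returns (B, 21) softmax probabilities.

        The one-hot base axis enters as the channel axis of a (B, 21, 1, C)
        image, so 3x3 kernels mix neighbouring positions and all base channels."""
        h = np.ascontiguousarray(x, dtype=np.float32).reshape(x.shape[0], WINDOW, 1, ALPHABET)
        self._relu_masks = []
        for conv, bn in zip(self.convs, self.bns):
            h = conv.forward(h)
            mask = h > 0
            h = h * mask  # ReLU
            self._relu_masks.append(mask)
            h = bn.forward(h, train)
        self._flat_shape = h.shape
        logits = self.head.forward(h.reshape(h.shape[0], -1))
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)

    def backward(self, probs: np.ndarray, labels: np.ndarray) -> float:
        B = probs.shape[0]
        loss = -np.log(probs[np.arange(B), labels] + 1e-12).mean()
        dlogits = probs.astype(np.float32)
        dlogits[np.arange(B), labels] -= 1.0
        dlogits /= B
        dh = self.head.backward(dlogits).reshape(self._flat_shape)
        for conv, bn, mask in zip(
            reversed(self.convs), reversed(self.bns), reversed(self._relu_masks)
        ):
            dh = bn.backward(dh)
            dh = dh * mask
            dh = conv.backward(dh)
        return float(loss)

    def params(self):
        out = []
        for layer in (*self.convs, *self.bns, self.head):
            out.extend(layer.params())
        return out

    def state(self) -> dict:
        d = {"channels": np.array(self.channels)}
        for i, c in enumerate(self.convs):
            d[f"conv{i}_W"], d[f"conv{i}_b"] = c.W, c.b
        for i, bn in enumerate(self.bns):
            d[f"bn{i}_gamma"], d[f"bn{i}_beta"] = bn.gamma, bn.beta
            d[f"bn{i}_mean"], d[f"bn{i}_var"] = bn.run_mean, bn.run_var
        d["head_W"], d["head_b"] = self.head.W, self.head.b
        return d

    @classmethod
    def from_state(cls, d: dict) -> "SpliceNet":
        net = cls(channels=int(d["channels"]))
        for i, c in enumerate(net.convs):
            c.W, c.b = d[f"conv{i}_W"], d[f"conv{i}_b"]
        for i, bn in enumerate(net.bns):
            bn.gamma, bn.beta = d[f"bn{i}_gamma"], d[f"bn{i}_beta"]
            bn.run_mean, bn.run_var = d[f"bn{i}_mean"], d[f"bn{i}_var"]
        net.head.W, net.head.b = d["head_W"], d["head_b"]
        return net


def train_net(
    net: SpliceNet,
    x: np.ndarray,
    y: np.ndarray,
    epochs: int = 50,
    lr: float = 0.01,
    batch_size: int = 64,
    seed: int = 0,
) -> list[float]:
    """Minibatch Adam training; returns per-epoch mean losses."""
    rng = np.random.default_rng(seed)
    opt = _Adam(lr=lr)
    x = np.ascontiguousarray(x, dtype=np.float32)
    y = np.asarray(y)
    n = x.shape[0]
    losses = []
    for _ in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for lo in range(0, n, batch_size):
            idx = order[lo:lo + batch_size]
            probs = net.forward(x[idx], train=True)
            epoch_loss += net.backward(probs, y[idx]) * len(idx)
            opt.step(net.params())
        losses.append(epoch_loss / n)
    return losses
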