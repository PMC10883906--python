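"""NumPy recurrent networks with explicit backpropagation.

Implements the generic sequence classifier used throughout the package:
one or two (optionally bidirectional) recurrent layers — vanilla RNN,
LSTM or GRU cells — whose final time-step state feeds a stack of dense
hidden layers that halve in width, each followed by ReLU and dropout,
ending in a 2-unit output layer. Training uses softmax cross-entropy and
Adam.

Everything is written against plain ``numpy`` arrays with hand-derived
gradients (backpropagation through time for the recurrent cells). The
backward pass also yields exact gradients with respect to the *input*
matrix and with respect to any dense hidden activation, which is what the
integrated-gradients interpretation stage consumes. Gradient correctness
is guarded by central-difference checks in the test suite.

Conventions follow the common deep-learning defaults: gate order i, f, g,
o for LSTM and r, z, n for GRU (with the reset gate applied to the
hidden-to-candidate term), a single bias vector per cell, and uniform
U(-1/sqrt(H), 1/sqrt(H)) initialization.
"""

from __future__ import annotations

import numpy as np

from .exceptions import NoHiddenLayers

_GATES = {"RNN": 1, "LSTM": 4, "GRU": 3}


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.log(np.clip(p[np.arange(n), y], 1e-300, None)).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return float(loss), dlogits / n


# ----------------------------------------------------------------------
# recurrent cells (single direction)

def _cell_forward(cell: str, X, Wih, Whh, b):
    """Run one direction over X (B, T, I); returns (H_seq, cache)."""
    B, T, _ = X.shape
    H = Whh.shape[0]
    Hs = np.zeros((B, T, H))
    h = np.zeros((B, H))
    steps = []
    if cell == "RNN":
        for t in range(T):
            h_prev = h
            h = np.tanh(X[:, t] @ Wih + h_prev @ Whh + b)
            Hs[:, t] = h
            steps.append((h_prev, h))
    elif cell == "LSTM":
        c = np.zeros((B, H))
        for t in range(T):
            h_prev, c_prev = h, c
            a = X[:, t] @ Wih + h_prev @ Whh + b
            i = _sigmoid(a[:, :H])
            f = _sigmoid(a[:, H:2 * H])
            g = np.tanh(a[:, 2 * H:3 * H])
            o = _sigmoid(a[:, 3 * H:])
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            Hs[:, t] = h
            steps.append((h_prev, c_prev, i, f, g, o, tc))
    elif cell == "GRU":
        for t in range(T):
            h_prev = h
            ax = X[:, t] @ Wih + b
            ah = h_prev @ Whh
            r = _sigmoid(ax[:, :H] + ah[:, :H])
            z = _sigmoid(ax[:, H:2 * H] + ah[:, H:2 * H])
            ahn = ah[:, 2 * H:]
            n = np.tanh(ax[:, 2 * H:] + r * ahn)
            h = (1.0 - z) * n + z * h_prev
            Hs[:, t] = h
            steps.append((h_prev, r, z, n, ahn))
    else:  # pragma: no cover - guarded upstream
        raise ValueError(cell)
    return Hs, steps


def _cell_backward(cell: str, X, Wih, Whh, dHs, steps):
    """BPTT for one direction; returns (dX, dWih, dWhh, db)."""
    B, T, _ = X.shape
    H = Whh.shape[0]
    dX = np.zeros_like(X)
    dWih = np.zeros_like(Wih)
    dWhh = np.zeros_like(Whh)
    db = np.zeros(Wih.shape[1])
    dh_next = np.zeros((B, H))
    if cell == "RNN":
        for t in range(T - 1, -1, -1):
            h_prev, h = steps[t]
            da = (dHs[:, t] + dh_next) * (1.0 - h * h)
            dWih += X[:, t].T @ da
            dWhh += h_prev.T @ da
            db += da.sum(axis=0)
            dX[:, t] = da @ Wih.T
            dh_next = da @ Whh.T
    elif cell == "LSTM":
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc = steps[t]
            dh = dHs[:, t] + dh_next
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc * tc)
            di, dg, df = dc * g, dc * i, dc * c_prev
            dc_next = dc * f
            da = np.concatenate(
                [di * i * (1.0 - i), df * f * (1.0 - f),
                 dg * (1.0 - g * g), do * o * (1.0 - o)], axis=1)
            dWih += X[:, t].T @ da
            dWhh += h_prev.T @ da
            db += da.sum(axis=0)
            dX[:, t] = da @ Wih.T
            dh_next = da @ Whh.T
    elif cell == "GRU":
        for t in range(T - 1, -1, -1):
            h_prev, r, z, n, ahn = steps[t]
            dh = dHs[:, t] + dh_next
            dn = dh * (1.0 - z)
            dz = dh * (h_prev - n)
            dh_prev = dh * z
            dan = dn * (1.0 - n * n)         # pre-activation of candidate
            dr = dan * ahn
            da_x = np.concatenate(
                [dr * r * (1.0 - r), dz * z * (1.0 - z), dan], axis=1)
            # hidden path sees the candidate slice gated by r
            da_h = np.concatenate(
                [da_x[:, :2 * H], dan * r], axis=1)
            dWih += X[:, t].T @ da_x
            dWhh += h_prev.T @ da_h
            db += da_x.sum(axis=0)
            dX[:, t] = da_x @ Wih.T
            dh_next = dh_prev + da_h @ Whh.T
    return dX, dWih, dWhh, db


# ----------------------------------------------------------------------

class RecurrentNet:
    """Recurrent sequence classifier with a halving dense head.

    Parameters
    ----------
    cell_type : {'RNN', 'LSTM', 'GRU'}
    input_size : int
        Channels per position (4 or 5 for the pair encoding).
    hidden_size : int
        Recurrent state width; also the width of the first dense layer.
    n_recurrent_layers : {1, 2}
    bidirectional : bool
        When true the final representation concatenates the last forward
        state and the first-position backward state (width 2*hidden_size).
    n_hidden_layers : int
        Dense hidden layers of widths hidden_size, hidden_size/2, ...;
        0 wires the recurrent representation straight to the output.
    dropout_p : float
        Dropout after every dense ReLU and between stacked recurrent
        layers (training only).
    seed : int
        Parameter-initialization seed.
    """

    def __init__(self, cell_type: str, input_size: int, hidden_size: int,
                 n_recurrent_layers: int = 1, bidirectional: bool = False,
                 n_hidden_layers: int = 0, dropout_p: float = 0.0, seed: int = 0):
        if cell_type not in _GATES:
            raise ValueError(f"cell_type must be one of {tuple(_GATES)}")
        self.cell_type = cell_type
        self.input_size = int(input_size)
        self.hidden_size = int(hidden_size)
        self.n_recurrent_layers = int(n_recurrent_layers)
        self.bidirectional = bool(bidirectional)
        self.n_hidden_layers = int(n_hidden_layers)
        self.dropout_p = float(dropout_p)
        self.seed = int(seed)
        self._dirs = ("f", "b") if self.bidirectional else ("f",)
        self._build()

    # -- construction --------------------------------------------------

    def _build(self):
        rng = np.random.default_rng(self.seed)
        G, H = _GATES[self.cell_type], self.hidden_size
        k = 1.0 / np.sqrt(H)
        p: dict[str, np.ndarray] = {}
        in_size = self.input_size
        for layer in range(self.n_recurrent_layers):
            for d in self._dirs:
                pre = f"rec{layer}{d}"
                p[f"{pre}_Wih"] = rng.uniform(-k, k, (in_size, G * H))
                p[f"{pre}_Whh"] = rng.uniform(-k, k, (H, G * H))
                p[f"{pre}_b"] = rng.uniform(-k, k, G * H)
            in_size = H * len(self._dirs)
        rep = H * len(self._dirs)
        self.dense_widths = [max(self.hidden_size >> j, 1)
                             for j in range(self.n_hidden_layers)]
        fan_in = rep
        for j, w in enumerate(self.dense_widths):
            kk = 1.0 / np.sqrt(fan_in)
            p[f"fc{j}_W"] = rng.uniform(-kk, kk, (fan_in, w))
            p[f"fc{j}_b"] = rng.uniform(-kk, kk, w)
            fan_in = w
        kk = 1.0 / np.sqrt(fan_in)
        p["out_W"] = rng.uniform(-kk, kk, (fan_in, 2))
        p["out_b"] = rng.uniform(-kk, kk, 2)
        self.params = p
        self.grads = {name: np.zeros_like(v) for name, v in p.items()}

    def parameter_count(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def zero_grads(self):
        for g in self.grads.values():
            g[...] = 0.0

    # -- forward -------------------------------------------------------

    def _recurrent_forward(self, X, training, rng):
        caches = []
        cur = X
        for layer in range(self.n_recurrent_layers):
            outs, layer_cache = [], {}
            for d in self._dirs:
                pre = f"rec{layer}{d}"
                Xin = cur if d == "f" else cur[:, ::-1]
                Hs, steps = _cell_forward(
                    self.cell_type, Xin,
                    self.params[f"{pre}_Wih"], self.params[f"{pre}_Whh"],
                    self.params[f"{pre}_b"])
                layer_cache[d] = (Xin, steps)
                outs.append(Hs if d == "f" else Hs[:, ::-1])
            out = np.concatenate(outs, axis=2) if len(outs) == 2 else outs[0]
            mask = None
            if (training and self.dropout_p > 0.0
                    and layer < self.n_recurrent_layers - 1):
                mask = (rng.random(out.shape) >= self.dropout_p) / (1.0 - self.dropout_p)
                out = out * mask
            caches.append({"cells": layer_cache, "input": cur,
                           "mask": mask, "output": out})
            cur = out
        return cur, caches

    def forward(self, X: np.ndarray, training: bool = False, rng=None):
        """Full forward pass; returns (logits, cache)."""
        X = np.asarray(X, dtype=float)
        H = self.hidden_size
        top, rec_caches = self._recurrent_forward(X, training, rng)
        # final representation: last forward state (+ first backward state)
        if self.bidirectional:
            rep = np.concatenate([top[:, -1, :H], top[:, 0, H:]], axis=1)
        else:
            rep = top[:, -1, :]
        dense_caches = []
        a = rep
        for j in range(self.n_hidden_layers):
            z = a @ self.params[f"fc{j}_W"] + self.params[f"fc{j}_b"]
            relu = np.maximum(z, 0.0)
            mask = None
            if training and self.dropout_p > 0.0:
                mask = (rng.random(relu.shape) >= self.dropout_p) / (1.0 - self.dropout_p)
                post = relu * mask
            else:
                post = relu
            dense_caches.append({"input": a, "z": z, "relu": relu, "mask": mask})
            a = post
        logits = a @ self.params["out_W"] + self.params["out_b"]
        cache = {"X": X, "rec": rec_caches, "rep": rep,
                 "dense": dense_caches, "head_in": a}
        return logits, cache

    # -- backward ------------------------------------------------------

    def _head_backward(self, dlogits, cache, stop_layer: int | None = None):
        """Backprop logits -> dense stack. Returns gradient at the
        post-ReLU activation of ``stop_layer`` if given, else at rep."""
        g = self.grads
        da = dlogits @ self.params["out_W"].T
        g["out_W"] += cache["head_in"].T @ dlogits
        g["out_b"] += dlogits.sum(axis=0)
        for j in range(self.n_hidden_layers - 1, -1, -1):
            dc = cache["dense"][j]
            if dc["mask"] is not None:
                da = da * dc["mask"]
            if stop_layer is not None and j == stop_layer:
                return da  # gradient w.r.t. post-ReLU activation of layer j
            dz = da * (dc["z"] > 0.0)
            g[f"fc{j}_W"] += dc["input"].T @ dz
            g[f"fc{j}_b"] += dz.sum(axis=0)
            da = dz @ self.params[f"fc{j}_W"].T
        return da  # gradient w.r.t. rep

    def backward(self, dlogits: np.ndarray, cache: dict) -> np.ndarray:
        """Backprop to parameters (accumulated in ``self.grads``) and input."""
        H = self.hidden_size
        drep = self._head_backward(dlogits, cache)
        top = cache["rec"][-1]["output"]
        B, T, _ = top.shape
        dtop = np.zeros_like(top)
        if self.bidirectional:
            dtop[:, -1, :H] = drep[:, :H]
            dtop[:, 0, H:] = drep[:, H:]
        else:
            dtop[:, -1, :] = drep
        dcur = dtop
        for layer in range(self.n_recurrent_layers - 1, -1, -1):
            rc = cache["rec"][layer]
            if rc["mask"] is not None:
                dcur = dcur * rc["mask"]
            dinput = np.zeros_like(rc["input"])
            for di, d in enumerate(self._dirs):
                pre = f"rec{layer}{d}"
                dHs = dcur[:, :, di * H:(di + 1) * H]
                Xin, steps = rc["cells"][d]
                if d == "b":
                    dHs = dHs[:, ::-1]
                dX, dWih, dWhh, db = _cell_backward(
                    self.cell_type, Xin,
                    self.params[f"{pre}_Wih"], self.params[f"{pre}_Whh"],
                    dHs, steps)
                self.grads[f"{pre}_Wih"] += dWih
                self.grads[f"{pre}_Whh"] += dWhh
                self.grads[f"{pre}_b"] += db
                dinput += dX if d == "f" else dX[:, ::-1]
            dcur = dinput
        return dcur

    # -- inference and interpretation hooks ----------------------------

    def logits(self, X: np.ndarray, batch_size: int = 1024) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        outs = [self.forward(X[i:i + batch_size])[0]
                for i in range(0, len(X), batch_size)]
        return np.concatenate(outs) if outs else np.zeros((0, 2))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return softmax(self.logits(X))

    def margin(self, X: np.ndarray, target_class: int = 1) -> np.ndarray:
        """Logit margin (log-odds) of the target class, per sample."""
        logits = self.logits(X)
        return logits[:, target_class] - logits[:, 1 - target_class]

    def input_gradients(self, X: np.ndarray, target_class: int) -> np.ndarray:
        """d margin[target] / d input, per sample.

        The attribution target is the class-logit margin rather than the
        raw logit: the margin is what the softmax decision depends on,
        and a model may encode class evidence in either output unit.
        """
        logits, cache = self.forward(X)
        dlogits = np.zeros_like(logits)
        dlogits[:, target_class] = 1.0
        dlogits[:, 1 - target_class] = -1.0
        self.zero_grads()
        return self.backward(dlogits, cache)

    def hidden_activations(self, X: np.ndarray) -> list[np.ndarray]:
        """Post-ReLU activations of every dense hidden layer (eval mode)."""
        if self.n_hidden_layers == 0:
            raise NoHiddenLayers("model has no dense hidden layers")
        _, cache = self.forward(X)
        return [dc["relu"] for dc in cache["dense"]]

    def head_gradient(self, X: np.ndarray, target_class: int,
                      layer_index: int) -> tuple[np.ndarray, np.ndarray]:
        """(activation, d margin[target]/d activation) at a dense layer."""
        if not 0 <= layer_index < self.n_hidden_layers:
            raise NoHiddenLayers(
                f"layer_index {layer_index} outside 0..{self.n_hidden_layers - 1}")
        logits, cache = self.forward(X)
        dlogits = np.zeros_like(logits)
        dlogits[:, target_class] = 1.0
        dlogits[:, 1 - target_class] = -1.0
        self.zero_grads()
        da = self._head_backward(dlogits, cache, stop_layer=layer_index)
        return cache["dense"][layer_index]["relu"], da

    # -- (de)serialization --------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for k, v in state.items():
            self.params[k][...] = v


class Adam:
    """Adam optimizer over a parameter dict (conventional defaults)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1.0 - b1) * g
            self.v[k] = b2 * self.v[k] + (1.0 - b2) * g * g
            p -= self.lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)
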