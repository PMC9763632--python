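"""Multi-kernel 1-D convolutional network for sgRNA activity prediction.

Architecture (channels x positions input):

* five parallel convolution branches over the position axis, kernel widths
  1..5, 30 filters each (150 filters total), ReLU, no padding;
* max pooling (non-overlapping windows of width 2 by default — position
  information is kept at half resolution, which matters because guide
  activity depends on *where* a base sits, not just whether it occurs);
  each branch flattened and all branches concatenated;
* one batch-normalization layer, then dropout (p = 0.4);
* three fully connected ReLU layers of 80, 60 and 40 units;
* a single output unit: linear for regression (activity score), logit for
  classification (trained with binary cross-entropy, read out as a sigmoid
  probability).

Implemented directly on numpy with explicit backpropagation: forward
convolutions are im2col + GEMM, pooling gradients are routed to the argmax,
and Adam performs the updates. Everything is float64 and fully deterministic
given the seed, which also makes finite-difference gradient checks and
bit-identical checkpoint reloads possible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np


@dataclass
class ModelConfig:
    kernel_sizes: Tuple[int, ...] = (1, 2, 3, 4, 5)
    filters_per_size: int = 30
    fc_units: Tuple[int, ...] = (80, 60, 40)
    pool_size: int = 2                  # max-pool window; <=0 pools globally
    dropout: float = 0.4
    task: str = "regression"            # or "classification"
    learning_rate: float = 1e-3
    batch_size: int = 256
    max_epochs: int = 100
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        self.kernel_sizes = tuple(int(k) for k in self.kernel_sizes)
        self.fc_units = tuple(int(u) for u in self.fc_units)
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.task not in ("regression", "classification"):
            raise ValueError(f"unknown task {self.task!r}")

    @property
    def total_filters(self) -> int:
        return self.filters_per_size * len(self.kernel_sizes)


def _sliding_cols(X: np.ndarray, k: int) -> np.ndarray:
    """im2col: (N, C, L) -> (N, L-k+1, C*k)."""
    win = np.lib.stride_tricks.sliding_window_view(X, k, axis=2)  # N,C,Lk,k
    n, c, lk, _ = win.shape
    return np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(n, lk, c * k)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class CasCNN:
    """The network itself: parameters, forward, backward, prediction."""

    BN_EPS = 1e-5
    BN_MOMENTUM = 0.9

    def __init__(self, n_channels: int, n_positions: int, cfg: ModelConfig):
        if n_positions < max(cfg.kernel_sizes):
            raise ValueError(
                f"input has {n_positions} positions but the largest kernel is "
                f"{max(cfg.kernel_sizes)}"
            )
        self.n_channels = n_channels
        self.n_positions = n_positions
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.params: Dict[str, np.ndarray] = {}

        self.branch_windows: Dict[int, int] = {}
        self.branch_pool: Dict[int, int] = {}
        n_feats = 0
        for k in cfg.kernel_sizes:
            fan_in = n_channels * k
            self.params[f"convW{k}"] = rng.normal(
                0.0, np.sqrt(2.0 / fan_in), size=(cfg.filters_per_size, fan_in)
            )
            self.params[f"convb{k}"] = np.zeros(cfg.filters_per_size)
            lk = n_positions - k + 1
            pool = lk if cfg.pool_size <= 0 else min(cfg.pool_size, lk)
            self.branch_pool[k] = pool
            self.branch_windows[k] = lk // pool
            n_feats += self.branch_windows[k] * cfg.filters_per_size

        self.n_features = n_feats
        self.params["bn_gamma"] = np.ones(n_feats)
        self.params["bn_beta"] = np.zeros(n_feats)
        self.running_mean = np.zeros(n_feats)
        self.running_var = np.ones(n_feats)

        dims = [n_feats, *cfg.fc_units, 1]
        for i, (din, dout) in enumerate(zip(dims[:-1], dims[1:])):
            if i < len(dims) - 2:  # hidden ReLU layers: He init
                std = np.sqrt(2.0 / din)
            else:  # linear/logit output: Glorot
                std = np.sqrt(1.0 / din)
            self.params[f"W{i}"] = rng.normal(0.0, std, size=(din, dout))
            self.params[f"b{i}"] = np.zeros(dout)
        self.n_dense = len(dims) - 1

    # ------------------------------------------------------------------ forward

    def forward(
        self,
        X: np.ndarray,
        training: bool = False,
        dropout_rng: Optional[np.random.Generator] = None,
    ) -> Tuple[np.ndarray, dict]:
        """Returns (raw output of the linear head, cache for backward)."""
        cfg = self.cfg
        cache: dict = {"X": X, "training": training}
        pooled = []
        for k in cfg.kernel_sizes:
            cols = _sliding_cols(X, k)                        # N,Lk,C*k
            Z = cols @ self.params[f"convW{k}"].T + self.params[f"convb{k}"]
            A = np.maximum(Z, 0.0)                            # N,Lk,F
            pool, nwin = self.branch_pool[k], self.branch_windows[k]
            Aw = A[:, : nwin * pool, :].reshape(A.shape[0], nwin, pool, -1)
            arg = Aw.argmax(axis=2)                           # N,nwin,F
            P = np.take_along_axis(Aw, arg[:, :, None, :], axis=2)[:, :, 0, :]
            cache[f"cols{k}"], cache[f"Z{k}"], cache[f"arg{k}"] = cols, Z, arg
            pooled.append(P.reshape(P.shape[0], -1))          # N, nwin*F
        H = np.concatenate(pooled, axis=1)                    # N, n_features
        cache["H"] = H

        if training:
            mu = H.mean(axis=0)
            var = H.var(axis=0)
            self.running_mean = self.BN_MOMENTUM * self.running_mean + (1 - self.BN_MOMENTUM) * mu
            self.running_var = self.BN_MOMENTUM * self.running_var + (1 - self.BN_MOMENTUM) * var
        else:
            mu, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.BN_EPS)
        xhat = (H - mu) * invstd
        B = xhat * self.params["bn_gamma"] + self.params["bn_beta"]
        cache["xhat"], cache["invstd"] = xhat, invstd

        if training and cfg.dropout > 0.0:
            if dropout_rng is None:
                raise ValueError("training forward pass needs a dropout RNG")
            mask = (dropout_rng.random(B.shape) >= cfg.dropout) / (1.0 - cfg.dropout)
            B = B * mask
            cache["drop_mask"] = mask

        a = B
        for i in range(self.n_dense):
            cache[f"a{i}"] = a
            z = a @ self.params[f"W{i}"] + self.params[f"b{i}"]
            if i < self.n_dense - 1:
                a = np.maximum(z, 0.0)
                cache[f"z{i}"] = z
            else:
                a = z
        return a[:, 0], cache

    # ----------------------------------------------------------------- backward

    def backward(
        self, dout: np.ndarray, cache: dict, want_input_grad: bool = False,
        want_param_grads: bool = True,
    ) -> Tuple[Dict[str, np.ndarray], Optional[np.ndarray]]:
        """Backpropagate d(loss)/d(output) through the cached forward pass."""
        cfg = self.cfg
        grads: Dict[str, np.ndarray] = {}
        da = dout[:, None]
        for i in range(self.n_dense - 1, -1, -1):
            a_in = cache[f"a{i}"]
            if want_param_grads:
                grads[f"W{i}"] = a_in.T @ da
                grads[f"b{i}"] = da.sum(axis=0)
            da = da @ self.params[f"W{i}"].T
            if i > 0:
                da = da * (cache[f"z{i-1}"] > 0.0)

        if cache["training"] and "drop_mask" in cache:
            da = da * cache["drop_mask"]

        xhat, invstd = cache["xhat"], cache["invstd"]
        if want_param_grads:
            grads["bn_gamma"] = (da * xhat).sum(axis=0)
            grads["bn_beta"] = da.sum(axis=0)
        dxhat = da * self.params["bn_gamma"]
        if cache["training"]:
            n = xhat.shape[0]
            dH = (invstd / n) * (
                n * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0)
            )
        else:
            dH = dxhat * invstd

        dX = np.zeros_like(cache["X"]) if want_input_grad else None
        offset = 0
        for k in cfg.kernel_sizes:
            F = cfg.filters_per_size
            pool, nwin = self.branch_pool[k], self.branch_windows[k]
            dP = dH[:, offset : offset + nwin * F].reshape(-1, nwin, F)
            offset += nwin * F
            Z, arg = cache[f"Z{k}"], cache[f"arg{k}"]
            dAw = np.zeros((Z.shape[0], nwin, pool, F))
            np.put_along_axis(dAw, arg[:, :, None, :], dP[:, :, None, :], axis=2)
            dA = np.zeros_like(Z)
            dA[:, : nwin * pool, :] = dAw.reshape(Z.shape[0], nwin * pool, F)
            dZ = dA * (Z > 0.0)                               # N,Lk,F
            if want_param_grads:
                cols = cache[f"cols{k}"]
                n, lk, ck = cols.shape
                grads[f"convW{k}"] = (
                    dZ.reshape(n * lk, F).T @ cols.reshape(n * lk, ck)
                )
                grads[f"convb{k}"] = dZ.sum(axis=(0, 1))
            if want_input_grad:
                dcols = dZ @ self.params[f"convW{k}"]         # N,Lk,C*k
                n, lk, _ = dcols.shape
                dcols = dcols.reshape(n, lk, self.n_channels, k)
                for j in range(k):
                    dX[:, :, j : j + lk] += dcols[:, :, :, j].transpose(0, 2, 1)
        return grads, dX

    # ---------------------------------------------------------------- inference

    def predict_raw(self, X: np.ndarray, batch_size: int = 1024) -> np.ndarray:
        """Evaluation-mode raw head output (linear value / logit)."""
        outs = []
        for i in range(0, X.shape[0], batch_size):
            out, _ = self.forward(X[i : i + batch_size], training=False)
            outs.append(out)
        return np.concatenate(outs)

    def predict(self, X: np.ndarray, batch_size: int = 1024) -> np.ndarray:
        """Activity score (regression) or probability of class 1."""
        raw = self.predict_raw(X, batch_size)
        return sigmoid(raw) if self.cfg.task == "classification" else raw

    def input_gradient(self, X: np.ndarray) -> np.ndarray:
        """d(raw output)/d(input), evaluation mode; used by attribution."""
        out, cache = self.forward(X, training=False)
        _, dX = self.backward(
            np.ones_like(out), cache, want_input_grad=True, want_param_grads=False
        )
        return dX

    # -------------------------------------------------------------- persistence

    def state_dict(self) -> Dict[str, np.ndarray]:
        state = {k: v.copy() for k, v in self.params.items()}
        state["running_mean"] = self.running_mean.copy()
        state["running_var"] = self.running_var.copy()
        return state

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = np.array(state[k])
        self.running_mean = np.array(state["running_mean"])
        self.running_var = np.array(state["running_var"])

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "weights.npz", **self.state_dict())
        arch = {
            "n_channels": self.n_channels,
            "n_positions": self.n_positions,
            "config": asdict(self.cfg),
        }
        with open(directory / "architecture.json", "w") as fh:
            json.dump(arch, fh, indent=2)

    @classmethod
    def load(cls, directory) -> "CasCNN":
        directory = Path(directory)
        with open(directory / "architecture.json") as fh:
            arch = json.load(fh)
        c = arch["config"]
        cfg = ModelConfig(
            kernel_sizes=tuple(c["kernel_sizes"]),
            filters_per_size=c["filters_per_size"],
            fc_units=tuple(c["fc_units"]),
            pool_size=c["pool_size"],
            dropout=c["dropout"],
            task=c["task"],
            learning_rate=c["learning_rate"],
            batch_size=c["batch_size"],
            max_epochs=c["max_epochs"],
            patience=c["patience"],
            seed=c["seed"],
        )
        net = cls(arch["n_channels"], arch["n_positions"], cfg)
        with np.load(directory / "weights.npz") as data:
            net.load_state_dict({k: data[k] for k in data.files})
        return net


def build_model(input_shape: Tuple[int, int], cfg: ModelConfig) -> Tuple[CasCNN, dict]:
    """Construct the network and an architecture summary.

    ``input_shape`` is (channels, positions); the default silencing setup is
    (11, 40). The summary reports every layer's output shape plus the total
    filter count (150 with defaults).
    """
    n_channels, n_positions = input_shape
    net = CasCNN(n_channels, n_positions, cfg)
    layers = []
    for k in cfg.kernel_sizes:
        layers.append(
            {
                "layer": f"conv1d_k{k}",
                "filters": cfg.filters_per_size,
                "kernel": k,
                "activation": "relu",
                "output_shape": (cfg.filters_per_size, n_positions - k + 1),
            }
        )
        layers.append(
            {
                "layer": f"maxpool_k{k}",
                "pool": net.branch_pool[k],
                "output_shape": (cfg.filters_per_size, net.branch_windows[k]),
            }
        )
    layers.append({"layer": "concat+flatten", "output_shape": (net.n_features,)})
    layers.append({"layer": "batch_norm", "output_shape": (net.n_features,)})
    layers.append({"layer": "dropout", "rate": cfg.dropout})
    for u in cfg.fc_units:
        layers.append({"layer": "dense", "units": u, "activation": "relu", "output_shape": (u,)})
    layers.append(
        {
            "layer": "output",
            "units": 1,
            "activation": "sigmoid" if cfg.task == "classification" else "linear",
            "output_shape": (1,),
        }
    )
    summary = {
        "input_shape": (n_channels, n_positions),
        "n_branches": len(cfg.kernel_sizes),
        "total_filters": cfg.total_filters,
        "fc_units": list(cfg.fc_units),
        "dropout": cfg.dropout,
        "task": cfg.task,
        "layers": layers,
        "n_parameters": int(sum(p.size for p in net.params.values())),
    }
    return net, summary


# --------------------------------------------------------------------- training


class Adam:
    def __init__(self, params: Dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: Dict[str, np.ndarray], grads: Dict[str, np.ndarray]) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1c) / (np.sqrt(self.v[k] / b2c) + self.eps)


def loss_and_grad(raw: np.ndarray, y: np.ndarray, task: str) -> Tuple[float, np.ndarray]:
    """MSE for regression; binary cross-entropy on logits for classification.
    Returns (mean loss, d loss / d raw)."""
    n = raw.shape[0]
    if task == "regression":
        diff = raw - y
        return float(np.mean(diff * diff)), 2.0 * diff / n
    # numerically stable BCE-with-logits: softplus(raw) - y*raw
    sp = np.where(raw > 30, raw, np.log1p(np.exp(np.minimum(raw, 30))))
    loss = float(np.mean(sp - y * raw))
    return loss, (sigmoid(raw) - y) / n
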