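"""A small NumPy LSTM regressor for one-step-ahead daily-seconds forecasting.

Architecture: one recurrent LSTM layer of U units over the lookback window,
followed by three dense layers of widths U/2 (ReLU), U/4 (ReLU) and 1
(linear), with inverted dropout after the first and second dense layers.
Trained with mean-squared-error loss and Adam, with early stopping on the
training loss.

The cell uses the peephole formulation (gates see the cell state):

    i_t = sigma(W_xi x_t + W_hi h_{t-1} + w_ci * c_{t-1} + b_i)
    f_t = sigma(W_xf x_t + W_hf h_{t-1} + w_cf * c_{t-1} + b_f)
    g_t = act(W_xc x_t + W_hc h_{t-1} + b_c)
    c_t = f_t * c_{t-1} + i_t * g_t
    o_t = sigma(W_xo x_t + W_ho h_{t-1} + w_co * c_t + b_o)
    h_t = o_t * act(c_t)

where sigma is the logistic function and ``act`` the cell activation
(ReLU by default, tanh available).  Gradients are exact backpropagation
through time; the implementation is validated against numerical gradients
in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LSTMNetwork"]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


_ACTS = {
    "relu": (lambda z: np.maximum(z, 0.0), lambda z: (z > 0).astype(float)),
    "tanh": (np.tanh, lambda z: 1.0 - np.tanh(z) ** 2),
}


@dataclass
class _Adam:
    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    t: int = 0
    m: dict = field(default_factory=dict)
    v: dict = field(default_factory=dict)

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for name, g in grads.items():
            m = self.m.setdefault(name, np.zeros_like(g))
            v = self.v.setdefault(name, np.zeros_like(g))
            m += (1 - self.beta1) * (g - m)
            v += (1 - self.beta2) * (g * g - v)
            params[name] -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class LSTMNetwork:
    """LSTM(U) -> Dense(U//2, ReLU) -> drop -> Dense(U//4, ReLU) -> drop -> Dense(1).

    Inputs are (batch, lookback) windows of a scaled series; output is the
    scalar next-step prediction.
    """

    def __init__(
        self,
        units: int,
        lookback: int = 7,
        dropout: float = 0.2,
        cell_activation: str = "relu",
        seed: int | None = 0,
    ):
        if units < 4:
            raise ValueError("need at least 4 LSTM units for the dense head")
        self.units = units
        self.lookback = lookback
        self.dropout = float(dropout)
        self.cell_activation = cell_activation
        self._act, self._dact = _ACTS[cell_activation]
        self.rng = np.random.default_rng(seed)
        self.params = self._init_params()

    def _init_params(self) -> dict[str, np.ndarray]:
        U = self.units
        d1, d2 = max(U // 2, 1), max(U // 4, 1)
        rng = self.rng

        def glorot(shape):
            fan_in, fan_out = shape[0], shape[-1]
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-lim, lim, size=shape)

        p: dict[str, np.ndarray] = {}
        for gate in ("i", "f", "o", "c"):
            p[f"Wx{gate}"] = glorot((1, U))
            p[f"Wh{gate}"] = glorot((U, U))
            p[f"b{gate}"] = np.zeros(U)
        for peep in ("ci", "cf", "co"):
            p[f"w{peep}"] = np.zeros(U)  # peephole weights start neutral
        p["bf"] += 1.0  # forget-gate bias init, standard remedy for vanishing memory
        p["W1"], p["b1"] = glorot((U, d1)), np.zeros(d1)
        p["W2"], p["b2"] = glorot((d1, d2)), np.zeros(d2)
        p["W3"], p["b3"] = glorot((d2, 1)), np.zeros(1)
        return p

    # -- forward ----------------------------------------------------------

    def _forward(self, X: np.ndarray, masks=None):
        """X: (B, T).  Returns predictions (B,) and a cache for backprop."""
        p = self.params
        B, T = X.shape
        U = self.units
        h = np.zeros((B, U))
        c = np.zeros((B, U))
        steps = []
        for t in range(T):
            x = X[:, t : t + 1]  # (B, 1)
            zi = x @ p["Wxi"] + h @ p["Whi"] + c * p["wci"] + p["bi"]
            zf = x @ p["Wxf"] + h @ p["Whf"] + c * p["wcf"] + p["bf"]
            zg = x @ p["Wxc"] + h @ p["Whc"] + p["bc"]
            i, f, g = _sigmoid(zi), _sigmoid(zf), self._act(zg)
            c_new = f * c + i * g
            zo = x @ p["Wxo"] + h @ p["Who"] + c_new * p["wco"] + p["bo"]
            o = _sigmoid(zo)
            h_new = o * self._act(c_new)
            steps.append((x, h, c, i, f, g, zg, o, c_new))
            h, c = h_new, c_new
        a1 = h @ p["W1"] + p["b1"]
        r1 = np.maximum(a1, 0.0)
        m1 = masks[0] if masks is not None else 1.0
        d1 = r1 * m1
        a2 = d1 @ p["W2"] + p["b2"]
        r2 = np.maximum(a2, 0.0)
        m2 = masks[1] if masks is not None else 1.0
        d2 = r2 * m2
        y = (d2 @ p["W3"] + p["b3"]).ravel()
        cache = (steps, h, a1, r1, m1, d1, a2, r2, m2, d2)
        return y, cache

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y, _ = self._forward(X)
        return y

    # -- backward ---------------------------------------------------------

    def _backward(self, X: np.ndarray, dy: np.ndarray, cache) -> dict[str, np.ndarray]:
        p = self.params
        steps, hT, a1, r1, m1, d1, a2, r2, m2, d2 = cache
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        dy = dy.reshape(-1, 1)  # (B, 1)
        grads["W3"] = d2.T @ dy
        grads["b3"] = dy.sum(axis=0)
        dd2 = dy @ p["W3"].T
        dr2 = dd2 * m2
        da2 = dr2 * (a2 > 0)
        grads["W2"] = d1.T @ da2
        grads["b2"] = da2.sum(axis=0)
        dd1 = da2 @ p["W2"].T
        dr1 = dd1 * m1
        da1 = dr1 * (a1 > 0)
        grads["W1"] = hT.T @ da1
        grads["b1"] = da1.sum(axis=0)
        dh = da1 @ p["W1"].T
        dc = np.zeros_like(dh)
        for x, h_prev, c_prev, i, f, g, zg, o, c_new in reversed(steps):
            do = dh * self._act(c_new)
            dzo = do * o * (1 - o)
            dc = dc + dh * o * self._dact(c_new) + dzo * p["wco"]
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dzi = di * i * (1 - i)
            dzf = df * f * (1 - f)
            dzg = dg * self._dact(zg)
            grads["Wxi"] += x.T @ dzi
            grads["Wxf"] += x.T @ dzf
            grads["Wxo"] += x.T @ dzo
            grads["Wxc"] += x.T @ dzg
            grads["Whi"] += h_prev.T @ dzi
            grads["Whf"] += h_prev.T @ dzf
            grads["Who"] += h_prev.T @ dzo
            grads["Whc"] += h_prev.T @ dzg
            grads["bi"] += dzi.sum(axis=0)
            grads["bf"] += dzf.sum(axis=0)
            grads["bo"] += dzo.sum(axis=0)
            grads["bc"] += dzg.sum(axis=0)
            grads["wci"] += (dzi * c_prev).sum(axis=0)
            grads["wcf"] += (dzf * c_prev).sum(axis=0)
            grads["wco"] += (dzo * c_new).sum(axis=0)
            dh = dzi @ p["Whi"].T + dzf @ p["Whf"].T + dzo @ p["Who"].T + dzg @ p["Whc"].T
            dc = dc * f + dzi * p["wci"] + dzf * p["wcf"]
        return grads

    def loss_and_grads(self, X: np.ndarray, y: np.ndarray, masks=None):
        """MSE loss and exact parameter gradients for one (mini)batch."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        pred, cache = self._forward(X, masks=masks)
        err = pred - y
        loss = float((err ** 2).mean())
        dy = 2.0 * err / len(y)
        return loss, self._backward(X, dy, cache)

    # -- training ---------------------------------------------------------

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        epochs: int = 50,
        batch_size: int = 4,
        patience: int = 15,
        lr: float = 1e-3,
        verbose_log: list | None = None,
    ) -> "LSTMNetwork":
        """Adam training with early stopping on the epoch training loss."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        n = len(y)
        opt = _Adam(lr=lr)
        best_loss = np.inf
        since_best = 0
        keep = 1.0 - self.dropout
        d1_w = self.params["b1"].shape[0]
        d2_w = self.params["b2"].shape[0]
        for epoch in range(epochs):
            order = self.rng.permutation(n)
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                if self.dropout > 0:
                    masks = (
                        self.rng.binomial(1, keep, size=(len(idx), d1_w)) / keep,
                        self.rng.binomial(1, keep, size=(len(idx), d2_w)) / keep,
                    )
                else:
                    masks = None
                _, grads = self.loss_and_grads(X[idx], y[idx], masks=masks)
                opt.step(self.params, grads)
            epoch_loss = float(((self.predict(X) - y) ** 2).mean())
            if verbose_log is not None:
                verbose_log.append((epoch + 1, epoch_loss))
            if epoch_loss < best_loss - 1e-12:
                best_loss = epoch_loss
                since_best = 0
            else:
                since_best += 1
                if since_best >= patience:
                    break
        return self
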