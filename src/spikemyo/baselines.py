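"""Comparison classifiers: LDA on time-domain features, LSTM and CNN on
real-valued windows.

LDA uses the standard linear discriminant
    delta_k(x) = x^T S^-1 m_k - 1/2 m_k^T S^-1 m_k + log pi_k
with the pooled within-class covariance regularised by a small diagonal
shrinkage (eps * trace(S)/dim), which is unavoidable when 4 x channels
features meet a one-repetition training set.

The LSTM (single recurrent layer + fully-connected readout of the last
hidden state) and the CNN (two conv blocks of 2x2 stride-2 filters with
batch norm and max pooling, then a fully-connected softmax layer) are
self-contained NumPy implementations trained with Adam (lr 0.01) on
mini-batches of 1/8 of the training set, matching the spiking network's
training protocol for comparability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LdaModel",
    "lda_fit",
    "lda_predict",
    "LstmClassifier",
    "CnnClassifier",
    "lstm_parameter_count",
]


# --------------------------------------------------------------------------
# LDA
# --------------------------------------------------------------------------

@dataclass
class LdaModel:
    means: np.ndarray          # (k, d)
    cov_inv: np.ndarray        # (d, d)
    log_priors: np.ndarray     # (k,)
    classes: np.ndarray


def lda_fit(features: np.ndarray, labels: np.ndarray,
            shrinkage: float = 1e-4) -> LdaModel:
    """Fit LDA with pooled covariance + diagonal shrinkage.

    ``features``: (n, d) — feature samples are flattened channels x 4
    matrices.  Raises if the regularised covariance is still singular,
    instructing to raise the shrinkage.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 3:
        X = X.reshape(len(X), -1)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 1:
        raise ValueError("need >= 2 classes with >= 1 sample each")
    n, d = X.shape
    means = np.stack([X[y == c].mean(axis=0) for c in classes])
    cov = np.zeros((d, d))
    for c, m in zip(classes, means):
        diff = X[y == c] - m
        cov += diff.T @ diff
    cov /= max(n - len(classes), 1)
    eps = shrinkage * np.trace(cov) / d
    cov[np.diag_indices(d)] += eps
    try:
        cov_inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "pooled covariance is singular; raise the shrinkage parameter"
        ) from exc
    return LdaModel(means=means, cov_inv=cov_inv,
                    log_priors=np.log(counts / n), classes=classes)


def lda_discriminants(model: LdaModel, features: np.ndarray) -> np.ndarray:
    X = np.asarray(features, dtype=float)
    if X.ndim == 3:
        X = X.reshape(len(X), -1)
    a = model.cov_inv @ model.means.T                   # (d, k)
    c = -0.5 * np.einsum("kd,dk->k", model.means, a) + model.log_priors
    return X @ a + c


def lda_predict(model: LdaModel, features: np.ndarray) -> np.ndarray:
    """argmax_k of the linear discriminant."""
    return model.classes[np.argmax(lda_discriminants(model, features), axis=1)]


# --------------------------------------------------------------------------
# shared pieces for the NumPy networks
# --------------------------------------------------------------------------

class _Adam:
    def __init__(self, params: dict, lr: float = 0.01,
                 b1: float = 0.9, b2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _softmax(z):
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _xent_grad(logits, y):
    p = _softmax(logits)
    n = len(y)
    loss = float(-np.log(p[np.arange(n), y] + 1e-12).mean())
    g = p.copy()
    g[np.arange(n), y] -= 1
    return loss, g / n


def _train_minibatch(model, X, y, epochs, batch_fraction, lr, seed,
                     patience=None, min_delta=1e-4):
    # patience=None trains for the full epoch budget; Adam loss curves on
    # small sets oscillate, so plateau stopping is opt-in here
    n = len(y)
    batch = max(1, int(round(batch_fraction * n)))
    rng = np.random.default_rng(seed)
    opt = _Adam(model.params, lr=lr)
    history = {"loss": []}
    best, stale = np.inf, 0
    for _ in range(epochs):
        order = rng.permutation(n)
        losses = []
        for s in range(0, n, batch):
            idx = order[s:s + batch]
            loss, grads = model._loss_and_grads(X[idx], y[idx])
            losses.append(loss)
            opt.step(model.params, grads)
        mean_loss = float(np.mean(losses))
        history["loss"].append(mean_loss)
        if patience is not None:
            if mean_loss < best - min_delta:
                best, stale = mean_loss, 0
            else:
                stale += 1
                if stale >= patience:
                    break
    return history


def lstm_parameter_count(i: int, h: int) -> int:
    """Gate parameters of one LSTM layer: 4(i*h + h*h + h)."""
    return 4 * (i * h + h * h + h)


# --------------------------------------------------------------------------
# LSTM
# --------------------------------------------------------------------------

class LstmClassifier:
    """Input layer -> LSTM layer -> fully-connected readout of h(T).

    Consumes (n, channels, T) windows as T steps of channel vectors.
    """

    def __init__(self, input_size: int, hidden_size: int, n_classes: int,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        i, h = input_size, hidden_size
        s = 1.0 / np.sqrt(i + h)
        self.i, self.h, self.o = i, h, n_classes
        self.params = {
            "Wx": rng.uniform(-s, s, (i, 4 * h)),
            "Wh": rng.uniform(-s, s, (h, 4 * h)),
            "b": np.zeros(4 * h),
            "Wf": rng.uniform(-1, 1, (h, n_classes)) / np.sqrt(h),
            "bf": np.zeros(n_classes),
        }

    @staticmethod
    def _sigmoid(x):
        return 1.0 / (1.0 + np.exp(-x))

    def _forward(self, X):
        """X: (n, T, i). Returns logits and the BPTT cache."""
        n, T, _ = X.shape
        h = self.h
        P = self.params
        hs = np.zeros((n, T + 1, h))
        cs = np.zeros((n, T + 1, h))
        gates = np.empty((n, T, 4 * h))
        tanhc = np.empty((n, T, h))
        for t in range(T):
            z = X[:, t] @ P["Wx"] + hs[:, t] @ P["Wh"] + P["b"]
            ig = self._sigmoid(z[:, :h])
            fg = self._sigmoid(z[:, h:2 * h])
            gg = np.tanh(z[:, 2 * h:3 * h])
            og = self._sigmoid(z[:, 3 * h:])
            cs[:, t + 1] = fg * cs[:, t] + ig * gg
            tc = np.tanh(cs[:, t + 1])
            hs[:, t + 1] = og * tc
            gates[:, t] = np.concatenate([ig, fg, gg, og], axis=1)
            tanhc[:, t] = tc
        logits = hs[:, T] @ P["Wf"] + P["bf"]
        return logits, {"X": X, "hs": hs, "cs": cs, "gates": gates,
                        "tanhc": tanhc}

    def _loss_and_grads(self, X, y):
        X = np.transpose(X, (0, 2, 1)) if X.shape[1] == self.i else X
        logits, cache = self._forward(X)
        loss, dlog = _xent_grad(logits, y)
        P = self.params
        n, T, _ = cache["X"].shape
        h = self.h
        grads = {k: np.zeros_like(v) for k, v in P.items()}
        grads["Wf"] = cache["hs"][:, T].T @ dlog
        grads["bf"] = dlog.sum(axis=0)
        dh = dlog @ P["Wf"].T
        dc = np.zeros((n, h))
        for t in range(T - 1, -1, -1):
            g = cache["gates"][:, t]
            ig, fg, gg, og = g[:, :h], g[:, h:2 * h], g[:, 2 * h:3 * h], g[:, 3 * h:]
            tc = cache["tanhc"][:, t]
            do = dh * tc
            dc = dc + dh * og * (1 - tc ** 2)
            di = dc * gg
            df = dc * cache["cs"][:, t]
            dg = dc * ig
            dz = np.concatenate([
                di * ig * (1 - ig), df * fg * (1 - fg),
                dg * (1 - gg ** 2), do * og * (1 - og)], axis=1)
            grads["Wx"] += cache["X"][:, t].T @ dz
            grads["Wh"] += cache["hs"][:, t].T @ dz
            grads["b"] += dz.sum(axis=0)
            dh = dz @ P["Wh"].T
            dc = dc * fg
        return loss, grads

    def fit(self, X, y, epochs: int = 100, lr: float = 0.01,
            batch_fraction: float = 0.125, seed: int = 0,
            patience: int | None = None):
        """X: (n, channels, T); Adam, lr 0.01, batch 1/8 by default."""
        X = np.transpose(np.asarray(X, dtype=float), (0, 2, 1))
        return _train_minibatch(self, X, np.asarray(y, dtype=int), epochs,
                                batch_fraction, lr, seed, patience)

    def predict(self, X):
        X = np.transpose(np.asarray(X, dtype=float), (0, 2, 1))
        logits, _ = self._forward(X)
        return np.argmax(logits, axis=1)

    def evaluate(self, X, y) -> float:
        return float((self.predict(X) == np.asarray(y)).mean())


# --------------------------------------------------------------------------
# CNN
# --------------------------------------------------------------------------

def _pad_even(x):
    """Zero-pad H and W up to even sizes ('same' for 2x2 stride-2 conv)."""
    _, _, H, W = x.shape
    ph, pw = H % 2, W % 2
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)))
    return x


class CnnClassifier:
    """Two conv blocks (2x2 filters, stride 2, same padding; batch norm;
    2x2 max pool) and a fully-connected softmax layer.

    Real-valued windows (channels, T=100) are reshaped to images of size
    C x H x W with C = 100 time steps as input planes and (H, W) the
    electrode grid: (16, 8) for 128 channels, (4, 2) for 8.  Max pooling
    skips any spatial axis already of size 1.
    """

    GRIDS = {128: (16, 8), 8: (4, 2)}

    def __init__(self, channels: int, n_classes: int, c1: int = 32,
                 c2: int = 16, seed: int = 0, grid: tuple | None = None):
        if grid is None:
            if channels not in self.GRIDS:
                raise ValueError(f"no default grid for {channels} channels; "
                                 "pass grid=(H, W)")
            grid = self.GRIDS[channels]
        H, W = grid
        if H * W != channels:
            raise ValueError("H * W must equal the channel count")
        self.grid = grid
        self.C = 100
        self.c1, self.c2, self.o = c1, c2, n_classes
        rng = np.random.default_rng(seed)
        k1 = 1.0 / np.sqrt(self.C * 4)
        k2 = 1.0 / np.sqrt(c1 * 4)
        # flatten size after two conv(stride2)+pool blocks
        def down(n, pool):
            n = (n + 1) // 2
            if pool and n > 1:
                n //= 2
            return n
        h1, w1 = down(H, True), down(W, True)
        h2, w2 = down(h1, True), down(w1, True)
        self._flat = c2 * h2 * w2
        self.params = {
            "K1": rng.uniform(-k1, k1, (c1, self.C * 4)),
            "c1b": np.zeros(c1),
            "g1": np.ones(c1), "be1": np.zeros(c1),
            "K2": rng.uniform(-k2, k2, (c2, c1 * 4)),
            "c2b": np.zeros(c2),
            "g2": np.ones(c2), "be2": np.zeros(c2),
            "Wf": rng.uniform(-1, 1, (self._flat, n_classes)) / np.sqrt(self._flat),
            "bf": np.zeros(n_classes),
        }
        self.running = {"m1": np.zeros(c1), "v1": np.ones(c1),
                        "m2": np.zeros(c2), "v2": np.ones(c2)}
        self._bn_eps = 1e-5

    # -- primitive layers ---------------------------------------------------
    @staticmethod
    def _patches(x):
        """(n, C, H, W) -> (n, H/2*W/2, C*4) non-overlapping 2x2 patches."""
        x = _pad_even(x)
        n, C, H, W = x.shape
        x = x.reshape(n, C, H // 2, 2, W // 2, 2)
        x = x.transpose(0, 2, 4, 1, 3, 5).reshape(n, (H // 2) * (W // 2), C * 4)
        return x, (H, W)

    def _conv(self, x, K, b):
        p, (H, W) = self._patches(x)
        out = p @ K.T + b                                   # (n, HW/4, c_out)
        n = x.shape[0]
        out = out.transpose(0, 2, 1).reshape(n, K.shape[0], H // 2, W // 2)
        return out, p, (H, W)

    def _bn(self, x, g, be, mkey, train):
        axes = (0, 2, 3)
        if train:
            m = x.mean(axis=axes)
            v = x.var(axis=axes)
            self.running["m" + mkey] = 0.9 * self.running["m" + mkey] + 0.1 * m
            self.running["v" + mkey] = 0.9 * self.running["v" + mkey] + 0.1 * v
        else:
            m, v = self.running["m" + mkey], self.running["v" + mkey]
        xhat = (x - m[:, None, None]) / np.sqrt(v[:, None, None] + self._bn_eps)
        return g[:, None, None] * xhat + be[:, None, None], (xhat, v)

    @staticmethod
    def _relu(x):
        return np.maximum(x, 0)

    @staticmethod
    def _maxpool(x):
        """2x2 stride-2 max pool, skipping axes of size 1."""
        n, C, H, W = x.shape
        ph, pw = H > 1, W > 1
        if ph:
            x = x[:, :, :H - H % 2].reshape(n, C, H // 2, 2, x.shape[3])
            x = x.max(axis=3)
        if pw:
            W2 = x.shape[3]
            x = x[:, :, :, :W2 - W2 % 2].reshape(n, C, x.shape[2], W2 // 2, 2)
            x = x.max(axis=4)
        return x

    # -- forward / backward -------------------------------------------------
    def _forward(self, X, train=False):
        """X: (n, channels, 100) -> logits; cache for backprop."""
        n = X.shape[0]
        H, W = self.grid
        img = X.transpose(0, 2, 1).reshape(n, self.C, H, W)
        cache = {"img": img}
        a1, p1, sh1 = self._conv(img, self.params["K1"], self.params["c1b"])
        b1, bn1 = self._bn(a1, self.params["g1"], self.params["be1"], "1", train)
        r1 = self._relu(b1)
        m1 = self._maxpool(r1)
        a2, p2, sh2 = self._conv(m1, self.params["K2"], self.params["c2b"])
        b2, bn2 = self._bn(a2, self.params["g2"], self.params["be2"], "2", train)
        r2 = self._relu(b2)
        m2 = self._maxpool(r2)
        flat = m2.reshape(n, -1)
        logits = flat @ self.params["Wf"] + self.params["bf"]
        cache.update(p1=p1, sh1=sh1, a1=a1, bn1=bn1, b1=b1, r1=r1, m1=m1,
                     p2=p2, sh2=sh2, a2=a2, bn2=bn2, b2=b2, r2=r2, m2=m2,
                     flat=flat)
        return logits, cache

    def _pool_backward(self, dout, pre):
        """Route gradients to the max positions of each pooled patch.

        Mirrors :meth:`_maxpool` (pool over H, then over W); positions cropped
        by an odd extent receive zero gradient.
        """
        n, C, H, W = pre.shape
        # recompute the H-pool stage to get both argmaxes
        if H > 1:
            Hc = H - H % 2
            rh = pre[:, :, :Hc].reshape(n, C, Hc // 2, 2, W)
            arg_h = rh.argmax(axis=3)
            mid = rh.max(axis=3)
        else:
            mid = pre
        g = dout
        if W > 1:
            Wc = W - W % 2
            rw = mid[:, :, :, :Wc].reshape(n, C, mid.shape[2], Wc // 2, 2)
            arg_w = rw.argmax(axis=4)
            up = np.zeros_like(rw)
            np.put_along_axis(up, arg_w[..., None], g[..., None], axis=4)
            g_mid = np.zeros_like(mid)
            g_mid[:, :, :, :Wc] = up.reshape(n, C, mid.shape[2], Wc)
            g = g_mid
        if H > 1:
            up = np.zeros_like(rh)
            np.put_along_axis(up, arg_h[:, :, :, None, :], g[:, :, :, None, :],
                              axis=3)
            dx = np.zeros_like(pre)
            dx[:, :, :Hc] = up.reshape(n, C, Hc, W)
            return dx
        return g

    def _bn_backward(self, dout, bn, g):
        xhat, v = bn
        axes = (0, 2, 3)
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        dgamma = (dout * xhat).sum(axis=axes)
        dbeta = dout.sum(axis=axes)
        dxhat = dout * g[:, None, None]
        inv = 1.0 / np.sqrt(v + self._bn_eps)
        dx = (inv[:, None, None] / m) * (
            m * dxhat
            - dxhat.sum(axis=axes)[:, None, None]
            - xhat * (dxhat * xhat).sum(axis=axes)[:, None, None])
        return dx, dgamma, dbeta

    def _conv_backward(self, dout, patches, shape, K, x_in):
        n, c_out, Ho, Wo = dout.shape
        d2 = dout.reshape(n, c_out, Ho * Wo).transpose(0, 2, 1)  # (n, HW, c_out)
        dK = np.einsum("npo,npc->oc", d2, patches)
        db = d2.sum(axis=(0, 1))
        dp = d2 @ K                                              # (n, HW, C*4)
        H, W = shape
        C = x_in.shape[1]
        dp = dp.reshape(n, H // 2, W // 2, C, 2, 2).transpose(0, 3, 1, 4, 2, 5)
        dx = dp.reshape(n, C, H, W)
        return dx[:, :, :x_in.shape[2], :x_in.shape[3]], dK, db

    def _loss_and_grads(self, X, y):
        logits, c = self._forward(X, train=True)
        loss, dlog = _xent_grad(logits, y)
        P = self.params
        grads = {}
        grads["Wf"] = c["flat"].T @ dlog
        grads["bf"] = dlog.sum(axis=0)
        dm2 = (dlog @ P["Wf"].T).reshape(c["m2"].shape)
        dr2 = self._pool_backward(dm2, c["r2"])
        db2 = dr2 * (c["b2"] > 0)
        da2, grads["g2"], grads["be2"] = self._bn_backward(db2, c["bn2"], P["g2"])
        dm1, grads["K2"], grads["c2b"] = self._conv_backward(
            da2, c["p2"], c["sh2"], P["K2"], c["m1"])
        dr1 = self._pool_backward(dm1, c["r1"])
        db1 = dr1 * (c["b1"] > 0)
        da1, grads["g1"], grads["be1"] = self._bn_backward(db1, c["bn1"], P["g1"])
        _, grads["K1"], grads["c1b"] = self._conv_backward(
            da1, c["p1"], c["sh1"], P["K1"], c["img"])
        return loss, grads

    def fit(self, X, y, epochs: int = 100, lr: float = 0.01,
            batch_fraction: float = 0.125, seed: int = 0,
            patience: int | None = None):
        return _train_minibatch(self, np.asarray(X, dtype=float),
                                np.asarray(y, dtype=int), epochs,
                                batch_fraction, lr, seed, patience)

    def predict(self, X):
        logits, _ = self._forward(np.asarray(X, dtype=float), train=False)
        return np.argmax(logits, axis=1)

    def evaluate(self, X, y) -> float:
        return float((self.predict(X) == np.asarray(y)).mean())
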