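"""Leaky-integrate-and-fire network with surrogate-gradient training.

Neuron model (LIF-V-I): membrane voltage and synaptic current are coupled
leaky states updated per time step,

    I(t) = mu  * I(t-1) + W s_in(t) + b        mu  = exp(-1/tau_syn)
    U(t) = tau * U(t-1) + R I(t)               tau = exp(-1/tau_mem)
    s(t) = 1  if U(t) >= V_thr2 else 0         (fires at equality)
    U(t) <- U(t) (1 - p)  where s(t) = 1       penalty reset, p = 1.5

With p > 1 the post-spike voltage is negative, which suppresses immediate
re-firing without an explicit refractory clamp.  The LIF-V ablation variant
drops the current memory (mu = 0), i.e. I(t) = W s_in(t) + b.

The network is input -> hidden (LIF) -> hidden (LIF, one neuron per class);
the readout is softmax of the time-averaged membrane voltage of the second
hidden layer.  Training is mini-batch SGD on cross-entropy with
backpropagation through time, substituting a normalised fast-sigmoid
pseudo-derivative g(v) = (beta/4) / (1 + beta |v| / 2)^2 for the
non-differentiable spike threshold; the spike indicator inside the reset
term is treated as constant during backprop (reset detach).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "LifParams",
    "LifLayerState",
    "SnnNetwork",
    "TrainConfig",
    "lif_step",
    "forward",
    "surrogate_gradient",
    "train",
    "predict",
    "evaluate",
    "hidden_layer_srr",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class LifParams:
    """LIF neuron constants.

    tau_mem / tau_syn are the membrane and synaptic time constants (in time
    steps); the per-step decay factors are tau = exp(-1/tau_mem) and
    mu = exp(-1/tau_syn).  ``penalty`` is the reset factor p (U <- U(1-p) on
    firing); R is the membrane resistance (unit by convention).
    """

    tau_mem: float = 10.0
    tau_syn: float = 5.0
    v_thr2: float = 10.0
    penalty: float = 1.5
    r: float = 1.0
    variant: str = "lif-v-i"       # or "lif-v"

    def __post_init__(self):
        if self.tau_mem <= 0 or self.tau_syn <= 0:
            raise ValueError("time constants must be positive")
        if self.variant not in ("lif-v-i", "lif-v"):
            raise ValueError("variant must be 'lif-v-i' or 'lif-v'")

    @property
    def tau(self) -> float:
        """Membrane decay factor per step, in (0, 1)."""
        return math.exp(-1.0 / self.tau_mem)

    @property
    def mu(self) -> float:
        """Current decay factor per step; 0 for the LIF-V variant."""
        return 0.0 if self.variant == "lif-v" else math.exp(-1.0 / self.tau_syn)


@dataclass
class LifLayerState:
    """Per-neuron membrane voltage U and synaptic current I (zero at t=0)."""

    U: np.ndarray
    I: np.ndarray

    @classmethod
    def zeros(cls, *shape) -> "LifLayerState":
        return cls(U=np.zeros(shape), I=np.zeros(shape))


def lif_step(state: LifLayerState, input_spikes: np.ndarray,
             weights: np.ndarray, biases: np.ndarray,
             params: LifParams) -> tuple:
    """Advance one layer by one time step; returns (new state, output spikes).

    Update order: current -> voltage -> threshold test -> penalty reset.
    Shapes: input_spikes (..., n_in), weights (n_in, n_out), state (..., n_out).
    """
    x = np.asarray(input_spikes, dtype=float)
    if x.shape[-1] != weights.shape[0]:
        raise ValueError("input/weight dimension mismatch")
    I = params.mu * state.I + x @ weights + biases
    U = params.tau * state.U + params.r * I
    spikes = (U >= params.v_thr2).astype(float)
    U = U * (1.0 - params.penalty * spikes)
    return LifLayerState(U=U, I=I), spikes


def surrogate_gradient(v, beta: float = 10.0):
    """Pseudo-derivative of the spike threshold at membrane distance v.

    Normalised fast-sigmoid family: g(v) = (beta/4) / (1 + beta|v|/2)^2 —
    even, maximal (beta/4) at v = 0, integrates to 1 over the real line.
    """
    v = np.asarray(v, dtype=float)
    g = (beta / 4.0) / (1.0 + beta * np.abs(v) / 2.0) ** 2
    return float(g) if g.ndim == 0 else g


@dataclass
class SnnNetwork:
    """Two-hidden-layer spiking network with average-voltage softmax readout.

    The second hidden layer has one neuron per gesture class and doubles as
    the output layer: class scores are the time-averaged membrane voltages.
    """

    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    params1: LifParams = field(default_factory=LifParams)
    params2: LifParams = field(default_factory=LifParams)
    T: int = 100

    @property
    def input_count(self) -> int:
        return self.w1.shape[0]

    @property
    def hidden_count(self) -> int:
        return self.w1.shape[1]

    @property
    def output_count(self) -> int:
        return self.w2.shape[1]

    @classmethod
    def init(cls, input_count: int, hidden_count: int, output_count: int,
             params: LifParams | None = None, T: int = 100,
             seed: int = 0) -> "SnnNetwork":
        """Zero-mean uniform weights, threshold-aware fan-in scaling.

        Layer-1 weights are scaled by V_thr2/(2 sqrt(fan-in)) so the hidden
        membrane voltages fluctuate near the release threshold from the
        start: a silent first layer sees only the (vanishing) tail of the
        surrogate derivative and cannot learn.  The readout layer taps the
        second layer's voltage directly, so plain 1/sqrt(fan-in) suffices
        there.  Biases start at zero.
        """
        rng = np.random.default_rng(seed)
        p = params or LifParams()
        s1 = max(p.v_thr2, 1.0) / (2.0 * math.sqrt(input_count))
        s2 = 1.0 / math.sqrt(hidden_count)
        return cls(
            w1=rng.uniform(-s1, s1, (input_count, hidden_count)),
            b1=np.zeros(hidden_count),
            w2=rng.uniform(-s2, s2, (hidden_count, output_count)),
            b2=np.zeros(output_count),
            params1=p, params2=replace(p), T=T,
        )


def count_parameters(net_or_input, hidden: int | None = None,
                     output: int | None = None) -> int:
    """Trainable parameter count: i*h + h*o + h + o (weights + biases)."""
    if isinstance(net_or_input, SnnNetwork):
        i, h, o = (net_or_input.input_count, net_or_input.hidden_count,
                   net_or_input.output_count)
    else:
        i, h, o = int(net_or_input), int(hidden), int(output)
    return i * h + h * o + h + o


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def forward(spikes: np.ndarray, net: SnnNetwork, record: bool = False):
    """Run both layers for t = 1..T from zero state.

    ``spikes``: (channels, T) or (n, channels, T) binary input.
    Returns class probabilities (softmax of the time-averaged layer-2
    membrane voltage); with ``record=True`` also a dict holding the layer
    spike trains and the layer-2 membrane trace.
    """
    x = np.asarray(spikes, dtype=float)
    single = x.ndim == 2
    if single:
        x = x[None]
    n, ch, T = x.shape
    if ch != net.input_count:
        raise ValueError(f"expected {net.input_count} channels, got {ch}")
    h, o = net.hidden_count, net.output_count
    st1 = LifLayerState.zeros(n, h)
    st2 = LifLayerState.zeros(n, o)
    u2_sum = np.zeros((n, o))
    rec = {"s1": np.empty((n, T, h)), "s2": np.empty((n, T, o)),
           "u2": np.empty((n, T, o))} if record else None
    for t in range(T):
        st1, s1 = lif_step(st1, x[:, :, t], net.w1, net.b1, net.params1)
        st2, s2 = lif_step(st2, s1, net.w2, net.b2, net.params2)
        u2_sum += st2.U                      # post-reset voltage, as stored
        if record:
            rec["s1"][:, t] = s1
            rec["s2"][:, t] = s2
            rec["u2"][:, t] = st2.U
    probs = _softmax(u2_sum / T)
    if single:
        probs = probs[0]
        if record:
            rec = {k: v[0] for k, v in rec.items()}
    return (probs, rec) if record else probs


@dataclass(frozen=True)
class TrainConfig:
    """Plain SGD on cross-entropy through the surrogate gradient.

    batch_fraction: mini-batch size as a fraction of the training set (the
    protocol default is 1/8).  Early stopping on a training-loss plateau.
    ``clip_norm``: gradients through 100 leaky integration steps are
    amplified by ~1/((1-mu)(1-tau)) per readout unit, so updates are
    rescaled to a global norm of at most ``clip_norm`` (0 disables).
    """

    learning_rate: float = 0.1
    batch_fraction: float = 0.125
    epochs: int = 100
    beta: float = 10.0
    seed: int = 0
    patience: int = 10
    min_delta: float = 1e-4
    clip_norm: float = 1.0

    def __post_init__(self):
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if not 0 < self.batch_fraction <= 1:
            raise ValueError("batch_fraction must be in (0, 1]")


def _forward_cache(x: np.ndarray, net: SnnNetwork) -> dict:
    """Forward pass storing everything BPTT needs."""
    n, ch, T = x.shape
    h, o = net.hidden_count, net.output_count
    p1, p2 = net.params1, net.params2
    st1 = LifLayerState.zeros(n, h)
    st2 = LifLayerState.zeros(n, o)
    s1 = np.empty((n, T, h))
    s2 = np.empty((n, T, o))
    v1 = np.empty((n, T, h))   # normalised (U_pre - V_thr2) for the surrogate
    u2_sum = np.zeros((n, o))
    for t in range(T):
        I1 = p1.mu * st1.I + x[:, :, t] @ net.w1 + net.b1
        U1 = p1.tau * st1.U + p1.r * I1
        sp1 = (U1 >= p1.v_thr2).astype(float)
        # surrogate acts on threshold-normalised distance so its width
        # tracks the voltage scale of the neuron model in use
        v1[:, t] = (U1 - p1.v_thr2) / max(abs(p1.v_thr2), 1e-6)
        s1[:, t] = sp1
        st1 = LifLayerState(U=U1 * (1 - p1.penalty * sp1), I=I1)
        I2 = p2.mu * st2.I + sp1 @ net.w2 + net.b2
        U2 = p2.tau * st2.U + p2.r * I2
        sp2 = (U2 >= p2.v_thr2).astype(float)
        s2[:, t] = sp2
        st2 = LifLayerState(U=U2 * (1 - p2.penalty * sp2), I=I2)
        u2_sum += st2.U
    logits = u2_sum / T
    return {"s1": s1, "s2": s2, "v1": v1, "logits": logits}


def _backward(x: np.ndarray, y_onehot: np.ndarray, net: SnnNetwork,
              cache: dict, beta: float) -> dict:
    """BPTT gradients of the mean cross-entropy w.r.t. weights and biases."""
    n, ch, T = x.shape
    p1, p2 = net.params1, net.params2
    probs = _softmax(cache["logits"])
    d_logits = (probs - y_onehot) / n            # (n, o)
    d_u2post_const = d_logits / T                # readout term, every t
    s1, s2, v1 = cache["s1"], cache["s2"], cache["v1"]
    g1 = surrogate_gradient(v1, beta)            # (n, T, h)

    gw1 = np.zeros_like(net.w1)
    gb1 = np.zeros_like(net.b1)
    gw2 = np.zeros_like(net.w2)
    gb2 = np.zeros_like(net.b2)

    d_upre2_next = np.zeros_like(d_logits)
    d_i2_next = np.zeros_like(d_logits)
    d_s1 = np.empty((n, T, net.hidden_count))
    # layer 2 backward in time
    for t in range(T - 1, -1, -1):
        d_upost2 = d_u2post_const + p2.tau * d_upre2_next
        d_upre2 = d_upost2 * (1 - p2.penalty * s2[:, t])   # reset detach
        d_i2 = p2.r * d_upre2 + p2.mu * d_i2_next
        gw2 += s1[:, t].T @ d_i2
        gb2 += d_i2.sum(axis=0)
        d_s1[:, t] = d_i2 @ net.w2.T
        d_upre2_next, d_i2_next = d_upre2, d_i2
    # layer 1 backward in time
    d_upre1_next = np.zeros((n, net.hidden_count))
    d_i1_next = np.zeros((n, net.hidden_count))
    for t in range(T - 1, -1, -1):
        d_upost1 = p1.tau * d_upre1_next
        d_upre1 = (d_upost1 * (1 - p1.penalty * s1[:, t])
                   + d_s1[:, t] * g1[:, t])
        d_i1 = p1.r * d_upre1 + p1.mu * d_i1_next
        gw1 += x[:, :, t].T @ d_i1
        gb1 += d_i1.sum(axis=0)
        d_upre1_next, d_i1_next = d_upre1, d_i1
    return {"w1": gw1, "b1": gb1, "w2": gw2, "b2": gb2}


def _xent(logits: np.ndarray, y: np.ndarray) -> float:
    z = logits - logits.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    return float(-logp[np.arange(len(y)), y].mean())


def train(net: SnnNetwork, spikes: np.ndarray, labels: np.ndarray,
          config: TrainConfig = TrainConfig()) -> tuple:
    """Mini-batch SGD with surrogate-gradient BPTT.

    ``spikes``: (n, channels, T) binary; ``labels``: (n,) integer classes.
    Returns (trained network, history dict with per-epoch mean loss).
    Fixed seed gives a bit-reproducible trajectory.
    """
    x = np.asarray(spikes, dtype=float)
    y = np.asarray(labels, dtype=int)
    counts = np.bincount(y, minlength=net.output_count)
    if (counts == 0).any():
        raise ValueError("need at least one sample for every class")
    n = len(y)
    batch = max(1, int(round(config.batch_fraction * n)))
    rng = np.random.default_rng(config.seed)
    eye = np.eye(net.output_count)
    net = replace(net, w1=net.w1.copy(), b1=net.b1.copy(),
                  w2=net.w2.copy(), b2=net.b2.copy())
    history = {"loss": []}
    best, stale = np.inf, 0
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch):
            idx = order[start:start + batch]
            xb, yb = x[idx], y[idx]
            cache = _forward_cache(xb, net)
            losses.append(_xent(cache["logits"], yb))
            if config.learning_rate > 0:
                g = _backward(xb, eye[yb], net, cache, config.beta)
                step = config.learning_rate
                if config.clip_norm > 0:
                    norm = math.sqrt(sum(float((v ** 2).sum())
                                         for v in g.values()))
                    step *= min(1.0, config.clip_norm / (norm + 1e-12))
                net.w1 -= step * g["w1"]
                net.b1 -= step * g["b1"]
                net.w2 -= step * g["w2"]
                net.b2 -= step * g["b2"]
        mean_loss = float(np.mean(losses))
        history["loss"].append(mean_loss)
        if mean_loss < best - config.min_delta:
            best, stale = mean_loss, 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    return net, history


def predict(net: SnnNetwork, spikes: np.ndarray) -> np.ndarray:
    """Class labels (argmax probability); (channels, T) -> int scalar."""
    probs = forward(spikes, net)
    return int(np.argmax(probs)) if probs.ndim == 1 else np.argmax(probs, axis=1)


def evaluate(net: SnnNetwork, spikes: np.ndarray, labels: np.ndarray,
             chunk: int = 512) -> float:
    """Accuracy = correctly recognised samples / all samples."""
    x = np.asarray(spikes, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(y) == 0:
        raise ValueError("empty test set")
    hits = 0
    for start in range(0, len(y), chunk):
        hits += int((predict(net, x[start:start + chunk])
                     == y[start:start + chunk]).sum())
    return hits / len(y)


def hidden_layer_srr(net: SnnNetwork, spikes: np.ndarray,
                     chunk: int = 512) -> float:
    """Mean first-hidden-layer spike release rate over a dataset.

    SRR per sample = spikes emitted / (T x hidden neurons), averaged over
    samples; this is the quantity entering the layer-2 power term.
    """
    x = np.asarray(spikes, dtype=float)
    if x.ndim == 2:
        x = x[None]
    total, count = 0.0, 0
    for start in range(0, len(x), chunk):
        _, rec = forward(x[start:start + chunk], net, record=True)
        s1 = rec["s1"]
        total += s1.sum()
        count += s1.shape[0] * s1.shape[1] * s1.shape[2]
    return total / count


# --------------------------------------------------------------------------
# checkpointing: npz arrays + JSON header, bit-exact round trip
# --------------------------------------------------------------------------

def save_checkpoint(path, net: SnnNetwork) -> None:
    fields = ("tau_mem", "tau_syn", "v_thr2", "penalty", "r", "variant")
    header = {
        "T": net.T,
        "params1": {f: getattr(net.params1, f) for f in fields},
        "params2": {f: getattr(net.params2, f) for f in fields},
    }
    np.savez(path, w1=net.w1, b1=net.b1, w2=net.w2, b2=net.b2,
             header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8))


def load_checkpoint(path) -> SnnNetwork:
    with np.load(path) as z:
        header = json.loads(bytes(z["header"]).decode())
        return SnnNetwork(
            w1=z["w1"], b1=z["b1"], w2=z["w2"], b2=z["b2"],
            params1=LifParams(**header["params1"]),
            params2=LifParams(**header["params2"]),
            T=int(header["T"]),
        )
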