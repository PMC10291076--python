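"""Temporal-contrast (incremental) spike encoding with adaptive threshold.

A real-valued window s(t) is reduced to its successive differences
diff(t) = s(t+1) - s(t); a spike is emitted wherever |diff(t)| reaches the
threshold V_thr1.  In adaptive mode the threshold is set per channel from
the sample's own difference statistics,

    V_thr1 = mean(|diff|) + theta * std(|diff|),

which makes the code invariant to positive rescaling of the input — the
property that lets the encoder absorb amplitude changes caused by electrode
shift and inter-subject gain differences.  By default the statistics are
pooled over the channels of a sample (one threshold per sample, from its own
distribution); a per-channel variant is available.  A fixed threshold
(default 0.18) is kept for comparison and is deliberately *not*
scale-invariant.

The default uses statistics of |diff| rather than signed diff: on
oscillatory EMG the signed mean is ~0, which would make negative values of
theta (part of the standard sweep) produce negative thresholds and a
saturated spike train.  Signed statistics remain available via
``diff_statistic="signed"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EncoderConfig",
    "SpikeSample",
    "SrrValue",
    "incremental_diff",
    "adaptive_threshold",
    "encode_sample",
    "encode_batch",
    "spike_sample_srr",
    "srr",
]


@dataclass(frozen=True)
class EncoderConfig:
    """Encoder settings.

    mode: "adaptive" (threshold from the sample's diff statistics, scaled by
    theta) or "fixed" (constant ``fixed_threshold``, V_thr1).
    per_channel: False (default) pools the difference statistics over all
    channels of the sample — one threshold per sample, set by its own
    distribution — which absorbs sample-level amplitude disturbances while
    keeping the cross-channel spike-rate pattern that carries the spatial
    class signature.  True computes an independent threshold per channel,
    which additionally absorbs channel-wise gain changes but equalises the
    channel spike rates in doing so.
    """

    mode: str = "adaptive"
    theta: float = 0.6
    fixed_threshold: float = 0.18
    diff_statistic: str = "absolute"   # or "signed"
    std_ddof: int = 0
    per_channel: bool = False

    def __post_init__(self):
        if self.mode not in ("adaptive", "fixed"):
            raise ValueError("mode must be 'adaptive' or 'fixed'")
        if self.mode == "fixed" and self.fixed_threshold <= 0:
            raise ValueError("fixed_threshold must be positive")
        if self.diff_statistic not in ("absolute", "signed"):
            raise ValueError("diff_statistic must be 'absolute' or 'signed'")
        if self.std_ddof not in (0, 1):
            raise ValueError("std_ddof must be 0 or 1")


@dataclass
class SpikeSample:
    """Binary channels x T spike matrix o(t) with encoder provenance."""

    spikes: np.ndarray
    labels: dict
    provenance: dict

    @property
    def T(self) -> int:
        return self.spikes.shape[-1]


@dataclass(frozen=True)
class SrrValue:
    """Spike release rate SRR = n / (T * N)."""

    srr: float
    n: int
    N: int
    T: int


def incremental_diff(sample: np.ndarray) -> np.ndarray:
    """diff[c, t] = s[c, t+1] - s[c, t]; shape channels x (T-1)."""
    x = np.asarray(sample, dtype=float)
    if x.shape[-1] < 2:
        raise ValueError("need at least 2 time points")
    return np.diff(x, axis=-1)


def adaptive_threshold(diff: np.ndarray, theta: float,
                       config: EncoderConfig = EncoderConfig()) -> np.ndarray:
    """V_thr1 = mean(d) + theta * std(d) with d = |diff| (default) or diff.

    Computed along the last axis; returns a scalar for a 1-D input, else one
    threshold per leading index.
    """
    d = np.asarray(diff, dtype=float)
    if d.size == 0:
        raise ValueError("empty difference sequence")
    if config.diff_statistic == "absolute":
        d = np.abs(d)
    thr = d.mean(axis=-1) + theta * d.std(axis=-1, ddof=config.std_ddof)
    return thr if thr.ndim else float(thr)


def _thresholds(diff: np.ndarray, config: EncoderConfig) -> np.ndarray:
    if config.mode == "fixed":
        return np.full(diff.shape[:-1], config.fixed_threshold)
    if config.per_channel:
        return np.asarray(adaptive_threshold(diff, config.theta, config))
    # pooled over channels within each sample: flatten the last two axes
    pooled = adaptive_threshold(diff.reshape(*diff.shape[:-2], -1),
                                config.theta, config)
    return np.broadcast_to(np.asarray(pooled)[..., None], diff.shape[:-1]).copy()


def _encode(x: np.ndarray, config: EncoderConfig) -> np.ndarray:
    diff = incremental_diff(x)
    thr = _thresholds(diff, config)[..., None]
    spikes = np.zeros(x.shape, dtype=np.uint8)
    spikes[..., 1:] = np.abs(diff) >= thr
    return spikes


def encode_sample(sample, config: EncoderConfig = EncoderConfig()) -> SpikeSample:
    """Encode one channels x T real window to a binary SpikeSample.

    o(0) = 0 and o(t) = 1 iff |diff(t-1)| >= V_thr1 for t = 1..T-1, so the
    spike train has the same length T as the input window.
    """
    window = sample.window if hasattr(sample, "window") else np.asarray(sample)
    labels = dict(getattr(sample, "labels", {}) or {})
    spikes = _encode(np.atleast_2d(window), config)
    prov = {"mode": config.mode,
            "theta" if config.mode == "adaptive" else "v_thr1":
            config.theta if config.mode == "adaptive" else config.fixed_threshold}
    return SpikeSample(spikes=spikes, labels=labels, provenance=prov)


def encode_batch(X: np.ndarray, config: EncoderConfig = EncoderConfig()) -> np.ndarray:
    """Vectorised encoding of an (n, channels, T) batch -> uint8 array."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 3:
        raise ValueError("expected (n, channels, T)")
    return _encode(X, config)


def srr(spikes: np.ndarray) -> SrrValue:
    """Spike release rate of a binary array: instances of 1 over T x N.

    For a channels x T sample N is the channel count; for stacked spike
    trains the leading axes are averaged into N x T accordingly (n counts all
    spikes, T is the last axis, N the product of the rest per sample).
    """
    s = np.asarray(spikes)
    if not np.isin(s, (0, 1)).all():
        raise ValueError("spike array must be binary")
    T = s.shape[-1]
    N = int(np.prod(s.shape[:-1]))
    n = int(s.sum())
    return SrrValue(srr=n / (T * N), n=n, N=N, T=T)


def spike_sample_srr(sample) -> SrrValue:
    """SRR of one SpikeSample (N = channels, T = window length)."""
    spikes = sample.spikes if hasattr(sample, "spikes") else sample
    return srr(spikes)
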