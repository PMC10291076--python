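"""Raw-recording conditioning and sample extraction.

Pipeline order is fixed: channel repair -> amplitude-based active-segment
extraction -> resampling to 5,000 points -> 51-tap FIR band-pass (20-500 Hz)
-> per-channel Min-Max normalisation to [0, 1] -> sliding-window extraction
(100 ms windows, 50 ms increment) over the steady phase (seconds 2-4), plus
the four classical time-domain features (MAV, VAR, WL, ZC) per channel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as _sig

from .synth import ElectrodeLayout, EmgRecording

__all__ = [
    "ActiveSegment",
    "RealSample",
    "FeatureSample",
    "repair_channels",
    "segment_active",
    "resample_segment",
    "bandpass_filter",
    "minmax_normalize",
    "extract_windows",
    "compute_td_features",
    "preprocess_recording",
    "build_dataset",
    "NoActivityError",
]

SEGMENT_SAMPLES = 5000   # 5 s at 1 kHz after resampling
WINDOW = 100             # 100 ms at 1 kHz
STEP = 50                # 50 ms increment
STEADY_REGION = (2000, 4000)   # steady phase: 2nd to 4th second


class NoActivityError(ValueError):
    """Raised when a recording contains no detectable activity burst."""


@dataclass
class ActiveSegment:
    """channels x 5000 segment (one gesture repetition) with its labels."""

    signal: np.ndarray
    labels: dict


@dataclass
class RealSample:
    """One channels x T window in [0, 1]; the real-valued classifier input
    and the encoder's input signal s(t)."""

    window: np.ndarray
    labels: dict
    window_index: int = 0


@dataclass
class FeatureSample:
    """channels x 4 feature matrix, columns (MAV, VAR, WL, ZC)."""

    features: np.ndarray
    labels: dict


# --------------------------------------------------------------------------
# step 1: repair, segmentation, resampling, filtering, normalisation
# --------------------------------------------------------------------------

OUTLIER_RMS_FACTOR = 100.0


def default_outlier_rule(signal: np.ndarray,
                         factor: float = OUTLIER_RMS_FACTOR) -> np.ndarray:
    """Flag channels whose RMS exceeds ``factor`` x the median channel RMS.

    The default targets saturated or disconnected electrodes, which sit
    orders of magnitude outside the physiological range; genuine hotspot
    channels on a sparse montage can reach tens of times the median RMS of
    the mostly-inactive channels and must not be flagged.
    """
    rms = np.sqrt(np.mean(signal ** 2, axis=1))
    return rms > factor * np.median(rms)


def repair_channels(
    recording: EmgRecording,
    outlier_rule=default_outlier_rule,
    max_fraction: float = 0.05,
) -> EmgRecording:
    """Replace out-of-range channels by the mean of their grid neighbours.

    ``outlier_rule`` maps the channels x samples array to a boolean flag per
    channel.  At most ``max_fraction`` of channels may be repaired; a flagged
    channel whose grid neighbours are all flagged cannot be repaired.
    Unflagged channels are returned bit-identical.
    """
    sig = recording.signal
    flagged = np.asarray(outlier_rule(sig), dtype=bool)
    if not flagged.any():
        return recording
    n_ch = sig.shape[0]
    if flagged.sum() > max(1, int(np.floor(max_fraction * n_ch))):
        raise ValueError(
            f"{flagged.sum()} channels flagged, above the repair cap "
            f"({max_fraction:.0%} of {n_ch})")
    out = sig.copy()
    layout = recording.layout
    for ch in np.flatnonzero(flagged):
        neigh = [c for c in layout.grid_adjacent(ch) if not flagged[c]]
        if not neigh:
            raise ValueError(f"channel {ch}: all grid neighbours flagged, cannot repair")
        out[ch] = sig[neigh].mean(axis=0)
    return EmgRecording(signal=out, sampling_rate=recording.sampling_rate,
                        layout=layout, **recording.labels)


def segment_active(
    recording: EmgRecording,
    threshold_frac: float = 0.1,
    smooth_ms: float = 200.0,
) -> tuple:
    """Locate the activity burst: (start, end) sample indices, half-open.

    The envelope is a ``smooth_ms`` moving average of the across-channel mean
    rectified signal; the burst spans the first and last samples at which it
    reaches ``threshold_frac`` of its peak.
    """
    env = np.abs(recording.signal).mean(axis=0)
    k = max(1, int(round(smooth_ms * recording.sampling_rate / 1000.0)))
    env = np.convolve(env, np.ones(k) / k, mode="same")
    peak = env.max()
    if peak <= 0:
        raise NoActivityError("signal is identically zero")
    active = np.flatnonzero(env >= threshold_frac * peak)
    if active.size == 0:
        raise NoActivityError("envelope never reaches the activity threshold")
    return int(active[0]), int(active[-1]) + 1


def resample_segment(segment: np.ndarray, n_out: int = SEGMENT_SAMPLES) -> np.ndarray:
    """Resample each channel to ``n_out`` points by linear interpolation.

    A segment already of length ``n_out`` is returned as an identical copy.
    """
    segment = np.atleast_2d(np.asarray(segment, dtype=float))
    n_in = segment.shape[1]
    if n_in < 2:
        raise ValueError("segment must contain at least 2 samples")
    if n_in == n_out:
        return segment.copy()
    x_new = np.linspace(0.0, n_in - 1.0, n_out)
    x_old = np.arange(n_in)
    return np.stack([np.interp(x_new, x_old, ch) for ch in segment])


def design_fir(numtaps: int = 51, band: tuple = (20.0, 500.0),
               fs: float = 1000.0) -> np.ndarray:
    """Windowed-sinc (Hamming) FIR band-pass taps for the 20-500 Hz band.

    At 1 kHz sampling the upper edge sits at Nyquist, so the band-pass
    degenerates to a high-pass at 20 Hz; the taps are mean-removed to place
    an exact null at DC.
    """
    lo, hi = band
    if hi >= fs / 2:
        h = _sig.firwin(numtaps, lo, pass_zero=False, fs=fs)
        h = h - h.mean()   # exact DC null
    else:
        h = _sig.firwin(numtaps, [lo, hi], pass_zero=False, fs=fs)
    return h


_FIR_CACHE: dict = {}


def bandpass_filter(segment: np.ndarray, fs: float = 1000.0,
                    numtaps: int = 51, band: tuple = (20.0, 500.0)) -> np.ndarray:
    """Apply the 50th-order (51-tap) linear-phase FIR band-pass per channel.

    Causal application; the filter transient is retained for determinism.
    """
    key = (numtaps, band, fs)
    if key not in _FIR_CACHE:
        _FIR_CACHE[key] = design_fir(numtaps, band, fs)
    h = _FIR_CACHE[key]
    segment = np.atleast_2d(np.asarray(segment, dtype=float))
    return _sig.lfilter(h, 1.0, segment, axis=1)


def minmax_normalize(segment: np.ndarray) -> np.ndarray:
    """Map each channel to [0, 1] using that segment's own extrema.

    A constant channel (max == min) is set to zero with a warning.
    """
    segment = np.atleast_2d(np.asarray(segment, dtype=float))
    mn = segment.min(axis=1, keepdims=True)
    mx = segment.max(axis=1, keepdims=True)
    rng = mx - mn
    flat = (rng == 0).ravel()
    if flat.any():
        warnings.warn(f"{flat.sum()} constant channel(s) set to 0 in Min-Max "
                      "normalisation")
        rng[flat] = 1.0
    out = (segment - mn) / rng
    out[flat] = 0.0
    return out


# --------------------------------------------------------------------------
# steps 2-3: windowing and time-domain features
# --------------------------------------------------------------------------

def window_count(region_len: int, win: int = WINDOW, step: int = STEP) -> int:
    if region_len < win:
        raise ValueError("region shorter than the window")
    return (region_len - win) // step + 1


def extract_windows(
    segment: np.ndarray,
    labels: dict | None = None,
    region: tuple = STEADY_REGION,
    win: int = WINDOW,
    step: int = STEP,
) -> list:
    """Slide a ``win``-sample window with ``step`` increment over ``region``.

    Windows are half-open [offset, offset + win) at offsets 0, step, 2*step,
    ... while they fit; over the default 2,000-sample steady phase this gives
    39 samples per repetition.
    """
    segment = np.atleast_2d(np.asarray(segment, dtype=float))
    a, b = region
    data = segment[:, a:b]
    n = window_count(data.shape[1], win, step)
    labels = labels or {}
    return [
        RealSample(window=data[:, i * step:i * step + win].copy(),
                   labels=dict(labels), window_index=i)
        for i in range(n)
    ]


def compute_td_features(sample: RealSample) -> FeatureSample:
    """Per-channel MAV, VAR, WL and ZC of a window.

    MAV and ZC use the mean-subtracted window: after Min-Max normalisation
    to [0, 1] the raw signal never crosses zero, so centring restores the
    standard definitions.  WL is the summed absolute first difference; VAR
    the (population) variance.
    """
    x = np.atleast_2d(sample.window)
    if x.shape[1] < 2:
        raise ValueError("window too short for features")
    xc = x - x.mean(axis=1, keepdims=True)
    mav = np.abs(xc).mean(axis=1)
    var = x.var(axis=1)
    wl = np.abs(np.diff(x, axis=1)).sum(axis=1)
    zc = np.count_nonzero(xc[:, :-1] * xc[:, 1:] < 0, axis=1).astype(float)
    return FeatureSample(features=np.column_stack([mav, var, wl, zc]),
                         labels=dict(sample.labels))


# --------------------------------------------------------------------------
# pipeline helpers
# --------------------------------------------------------------------------

def preprocess_recording(recording: EmgRecording, repair: bool = True,
                         region: tuple = STEADY_REGION,
                         win: int = WINDOW, step: int = STEP) -> list:
    """Full per-recording pipeline -> list of RealSamples."""
    rec = repair_channels(recording) if repair else recording
    a, b = segment_active(rec)
    seg = resample_segment(rec.signal[:, a:b])
    seg = bandpass_filter(seg, fs=recording.sampling_rate)
    seg = minmax_normalize(seg)
    return extract_windows(seg, labels=rec.labels, region=region,
                           win=win, step=step)


def build_dataset(recordings, **kwargs) -> tuple:
    """Preprocess an iterable of recordings into stacked arrays.

    Returns ``(X, labels)`` where X has shape (n_samples, channels, T) and
    ``labels`` is a DataFrame with subject / trial / gesture / repetition /
    window columns.
    """
    xs, rows = [], []
    for rec in recordings:
        for s in preprocess_recording(rec, **kwargs):
            xs.append(s.window)
            rows.append({**s.labels, "window": s.window_index})
    if not xs:
        raise ValueError("no samples produced")
    return np.stack(xs), pd.DataFrame(rows)
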