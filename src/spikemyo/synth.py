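"""Synthetic surface-EMG generator for high-density (128-channel) and
low-density (8-channel) gesture recordings.

The generator emulates the statistical structure a gesture-recognition
pipeline relies on, without modelling individual motor units: each channel
carries band-limited (20-500 Hz) Gaussian noise whose amplitude is modulated
by a gesture-specific spatial activation map and a trapezoid-like effort
envelope (2 s onset, 2 s steady plateau, 1 s offset for a 5 s repetition).
Electrode shift between recording sessions is realised as an integer
translation of the activation maps on each electrode grid; inter-subject
variation as smoothed multiplicative perturbation of the maps plus global
gain jitter.  A seed hierarchy (master -> subject -> trial -> repetition)
makes every sub-collection independently reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _sig

__all__ = [
    "ElectrodeLayout",
    "SubjectProfile",
    "SynthConfig",
    "EmgRecording",
    "generate_dataset",
    "iter_dataset",
    "make_subject_profile",
    "apply_electrode_shift",
    "select_ld_channels",
]


class ConfigurationError(ValueError):
    """Raised for invalid generator configurations."""


# --------------------------------------------------------------------------
# electrode layout
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ElectrodeLayout:
    """Electrode grid geometry.

    ``arrays`` is a list of ``(rows, cols, spacing_mm)`` tuples; channels are
    numbered consecutively array by array, row-major within each array.
    """

    arrays: tuple

    def __post_init__(self):
        if not self.arrays:
            raise ConfigurationError("layout needs at least one array")

    @property
    def n_channels(self) -> int:
        return sum(r * c for r, c, _ in self.arrays)

    @property
    def channel_index_map(self) -> dict:
        """channel id -> (array id, row, col)."""
        out = {}
        ch = 0
        for a, (rows, cols, _) in enumerate(self.arrays):
            for r in range(rows):
                for c in range(cols):
                    out[ch] = (a, r, c)
                    ch += 1
        return out

    def channel_id(self, array: int, row: int, col: int) -> int:
        off = sum(r * c for r, c, _ in self.arrays[:array])
        rows, cols, _ = self.arrays[array]
        if not (0 <= row < rows and 0 <= col < cols):
            raise ValueError("grid position out of range")
        return off + row * cols + col

    def grid_adjacent(self, channel: int) -> list:
        """4-neighbourhood of a channel within its own array."""
        a, r, c = self.channel_index_map[channel]
        rows, cols, _ = self.arrays[a]
        out = []
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < rows and 0 <= cc < cols:
                out.append(self.channel_id(a, rr, cc))
        return out

    @classmethod
    def hd_128(cls) -> "ElectrodeLayout":
        """Two 48-channel (8x6, 14 mm pitch) and two 16-channel (4x4, 18 mm)
        arrays: forearm extensors/flexors plus biceps/triceps."""
        return cls(arrays=((8, 6, 14.0), (8, 6, 14.0), (4, 4, 18.0), (4, 4, 18.0)))

    @classmethod
    def ld_8(cls) -> "ElectrodeLayout":
        """Eight discrete channels: the centres of the four 3x3 blocks of a
        6x6 sub-grid on each forearm array, i.e. a 2x2 grid per array with
        3x the HD pitch."""
        return cls(arrays=((2, 2, 42.0), (2, 2, 42.0)))


def select_ld_channels(layout: ElectrodeLayout) -> list:
    """Low-density channel selection from the high-density layout.

    For each 48-channel (8x6) forearm array: take the centred 6x6 sub-grid
    (rows 1..6 of 8), split it into four 3x3 sub-matrices and keep the centre
    electrode of each, giving 4 channels per array and 8 in total.
    Deterministic in the layout.
    """
    big = [a for a, (r, c, _) in enumerate(layout.arrays) if r * c == 48]
    if len(big) < 2:
        raise ValueError("layout lacks the two 48-channel (8x6) arrays")
    chans = []
    for a in big[:2]:
        rows, cols, _ = layout.arrays[a]
        # centred 6x6 sub-grid
        r0 = (rows - 6) // 2
        c0 = (cols - 6) // 2
        for br in (1, 4):        # centres of the 3x3 blocks, 0-based in 6x6
            for bc in (1, 4):
                chans.append(layout.channel_id(a, r0 + br, c0 + bc))
    return chans


# --------------------------------------------------------------------------
# subject profiles and electrode shift
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject generative parameters.

    ``maps`` holds one non-negative per-channel gain vector per gesture
    (values in [0, 1]); ``global_gain`` scales the whole recording;
    ``envelope`` is (onset_s, steady_s, offset_s); ``noise_floor`` is the
    gain of the activity-independent noise component.
    """

    maps: np.ndarray                # (n_gestures, n_channels)
    global_gain: float
    envelope: tuple = (2.0, 2.0, 1.0)
    noise_floor: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if np.any(self.maps < 0):
            raise ConfigurationError("activation maps must be non-negative")


def _gesture_centres(n_gestures: int, layout: ElectrodeLayout) -> list:
    """Deterministic per-gesture hotspot centres on every array.

    Shared across subjects so that a gesture means the same spatial pattern
    for everyone; subjects then perturb it.
    """
    centres = []
    for g in range(n_gestures):
        rng = np.random.default_rng(987_000 + g)  # fixed: gesture identity, not a knob
        per_array = []
        for rows, cols, _ in layout.arrays:
            per_array.append((rng.uniform(0.5, rows - 1.5), rng.uniform(0.5, cols - 1.5)))
        centres.append(per_array)
    return centres


def make_subject_profile(
    layout: ElectrodeLayout,
    n_gestures: int,
    seed: int,
    variability: float = 0.15,
) -> SubjectProfile:
    """Build a subject's activation maps from the shared gesture hotspots.

    Each map is a Gaussian bump per array (sigma ~ 1.5 electrodes) whose
    centre is jittered per subject, multiplied by smoothed per-channel gain
    jitter of scale ``variability`` and normalised to peak 1.
    """
    rng = np.random.default_rng(seed)
    centres = _gesture_centres(n_gestures, layout)
    n_ch = layout.n_channels
    maps = np.zeros((n_gestures, n_ch))
    cmap = layout.channel_index_map
    for g in range(n_gestures):
        for ch in range(n_ch):
            a, r, c = cmap[ch]
            cr, cc = centres[g][a]
            cr += rng.normal(0, variability * 2)
            cc += rng.normal(0, variability * 2)
            d2 = (r - cr) ** 2 + (c - cc) ** 2
            maps[g, ch] = np.exp(-d2 / (2 * 1.5 ** 2))
        # smoothed multiplicative channel-gain jitter
        jitter = rng.lognormal(0.0, variability, n_ch)
        k = np.ones(3) / 3
        maps[g] *= np.convolve(jitter, k, mode="same")
        maps[g] += 0.02                      # weak baseline co-activation
        maps[g] /= maps[g].max()
    gain = float(rng.lognormal(0.0, variability))
    return SubjectProfile(maps=maps, global_gain=gain, seed=seed)


def apply_electrode_shift(
    profile: SubjectProfile, layout: ElectrodeLayout, shift: tuple
) -> SubjectProfile:
    """Translate every activation map by ``(d_row, d_col)`` on each array grid.

    Positions shifted off-grid are filled by edge replication; (0, 0) is the
    identity.  No rotation is supported.
    """
    dr, dc = int(shift[0]), int(shift[1])
    for rows, cols, _ in layout.arrays:
        if abs(dr) >= rows or abs(dc) >= cols:
            raise ValueError(f"shift {shift} exceeds grid extent {(rows, cols)}")
    if (dr, dc) == (0, 0):
        return profile
    cmap = layout.channel_index_map
    new = np.empty_like(profile.maps)
    for ch in range(layout.n_channels):
        a, r, c = cmap[ch]
        rows, cols, _ = layout.arrays[a]
        src_r = int(np.clip(r - dr, 0, rows - 1))
        src_c = int(np.clip(c - dc, 0, cols - 1))
        new[:, ch] = profile.maps[:, layout.channel_id(a, src_r, src_c)]
    return replace(profile, maps=new)


# --------------------------------------------------------------------------
# dataset generation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the generator.

    Defaults follow the recording protocol the pipeline targets: 8 subjects,
    5 trials (separate wearings of the device), 9 gestures, 8 repetitions,
    1 kHz sampling, 5 s per repetition.
    """

    n_subjects: int = 8
    n_trials: int = 5
    n_gestures: int = 9
    n_repetitions: int = 8
    sampling_rate: float = 1000.0
    duration: float = 5.0
    shift_magnitude: int = 1
    subject_variability: float = 0.15
    burst_depth: float = 1.0
    impedance_variability: float = 0.5
    seed: int = 0
    channels: str = "hd"            # "hd" (128) or "ld" (8)

    def __post_init__(self):
        for name in ("n_subjects", "n_trials", "n_gestures", "n_repetitions"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.duration * self.sampling_rate < 200:
            raise ConfigurationError("duration too short for windowing")
        if self.channels not in ("hd", "ld"):
            raise ConfigurationError("channels must be 'hd' or 'ld'")

    @property
    def layout(self) -> ElectrodeLayout:
        return ElectrodeLayout.hd_128() if self.channels == "hd" else ElectrodeLayout.ld_8()


@dataclass
class EmgRecording:
    """One 5 s repetition: channels x samples at ``sampling_rate``."""

    signal: np.ndarray
    sampling_rate: float
    subject: int
    trial: int
    gesture: int
    repetition: int
    layout: ElectrodeLayout = field(default_factory=ElectrodeLayout.hd_128)

    @property
    def labels(self) -> dict:
        return {
            "subject": self.subject,
            "trial": self.trial,
            "gesture": self.gesture,
            "repetition": self.repetition,
        }


def _effort_envelope(n: int, fs: float, phases: tuple) -> np.ndarray:
    """Raised-cosine onset, flat plateau, raised-cosine offset."""
    on, steady, off = phases
    total = on + steady + off
    # scale phases if the recording is shorter/longer than their sum
    scale = (n / fs) / total
    n_on = int(round(on * scale * fs))
    n_off = int(round(off * scale * fs))
    n_steady = n - n_on - n_off
    env = np.empty(n)
    t_on = np.linspace(0, np.pi, n_on, endpoint=False)
    env[:n_on] = 0.5 * (1 - np.cos(t_on))
    env[n_on:n_on + n_steady] = 1.0
    t_off = np.linspace(0, np.pi, n_off)
    env[n_on + n_steady:] = 0.5 * (1 + np.cos(t_off))
    return env


def _band_noise(rng: np.random.Generator, shape: tuple, fs: float) -> np.ndarray:
    """White Gaussian noise band-limited to 20-500 Hz (high-pass at 20 Hz when
    the upper edge reaches Nyquist)."""
    x = rng.standard_normal(shape)
    ny = fs / 2
    if 500.0 >= ny:
        b, a = _sig.butter(4, 20.0 / ny, btype="highpass")
    else:
        b, a = _sig.butter(4, [20.0 / ny, 500.0 / ny], btype="bandpass")
    return _sig.filtfilt(b, a, x, axis=-1)


def _common_drive(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Slow (8-25 Hz) unit-variance modulation signal shared across channels.

    Emulates the common motor-unit drive that makes active sEMG channels
    bursty at sub-maximal effort; inactive (noise-floor) channels are not
    modulated.  Burstiness is what distinguishes muscle activity from
    instrument noise in a way that survives amplitude normalisation and
    scale-invariant encoding.
    """
    ny = fs / 2
    b, a = _sig.butter(2, [8.0 / ny, 25.0 / ny], btype="bandpass")
    z = _sig.filtfilt(b, a, rng.standard_normal(n))
    return z / z.std()


def _trial_context(config: SynthConfig, profile: SubjectProfile,
                   layout: ElectrodeLayout, trial_seed) -> tuple:
    """Per-trial wearing effects; trial 0 is the reference wearing.

    Re-wearing the arrays (i) shifts the electrodes on the skin (integer grid
    translation of the activation maps), (ii) changes overall signal gain,
    and (iii) changes the skin-electrode impedance per channel, which acts as
    an RC low-pass of varying strength.  (iii) is what a per-sample adaptive
    encoding can absorb and a fixed threshold cannot: Min-Max normalisation
    already cancels pure gain, but not a change in the signal's
    difference-to-amplitude ratio.
    """
    rng = np.random.default_rng(trial_seed)
    m = config.shift_magnitude
    dr = int(rng.integers(-m, m + 1)) if m > 0 else 0
    dc = int(rng.integers(-m, m + 1)) if m > 0 else 0
    shifted = apply_electrode_shift(profile, layout, (dr, dc))
    gain = float(rng.lognormal(0.0, config.subject_variability / 2))
    alphas = rng.uniform(0.0, config.impedance_variability, layout.n_channels)
    return shifted, gain, alphas


def _impedance_lowpass(sig: np.ndarray, alphas: np.ndarray) -> np.ndarray:
    """One-pole low-pass per channel: y[t] = (1-a) x[t] + a y[t-1]."""
    out = np.empty_like(sig)
    for c, a in enumerate(alphas):
        if a <= 0:
            out[c] = sig[c]
        else:
            out[c] = _sig.lfilter([1.0 - a], [1.0, -a], sig[c])
    return out


def iter_dataset(config: SynthConfig):
    """Yield the recordings of :func:`generate_dataset` lazily.

    Order is (subject, trial, gesture, repetition), all counts from the
    config.  Identical seed gives bit-identical output.
    """
    # Activation maps always live on the high-density grid; the low-density
    # configuration records the 8 selected channels of that grid (the study's
    # LD set is a channel subset of the HD montage, not a separate montage).
    hd = ElectrodeLayout.hd_128()
    layout = config.layout
    if config.channels == "ld":
        chan_idx = np.asarray(select_ld_channels(hd))
    else:
        chan_idx = np.arange(hd.n_channels)
    fs = config.sampling_rate
    n = int(round(config.duration * fs))
    master = np.random.SeedSequence(config.seed)
    subject_seeds = master.spawn(config.n_subjects)
    for s, s_seed in enumerate(subject_seeds):
        sub_children = s_seed.spawn(config.n_trials + 1)
        profile = make_subject_profile(
            hd, config.n_gestures,
            seed=int(sub_children[-1].generate_state(1)[0] % (2 ** 31)),
            variability=config.subject_variability,
        )
        for t in range(config.n_trials):
            t_seed = sub_children[t]
            if t == 0:
                trial_profile, trial_gain, alphas = profile, 1.0, None
            else:
                trial_profile, trial_gain, alphas = _trial_context(
                    config, profile, hd, t_seed)
            rep_seeds = t_seed.spawn(config.n_gestures * config.n_repetitions)
            env = _effort_envelope(n, fs, profile.envelope)
            for g in range(config.n_gestures):
                maps_g = trial_profile.maps[g][chan_idx]
                for r in range(config.n_repetitions):
                    rng = np.random.default_rng(
                        rep_seeds[g * config.n_repetitions + r])
                    gains = maps_g[:, None]
                    carrier = _band_noise(rng, (len(chan_idx), n), fs)
                    floor = _band_noise(rng, (len(chan_idx), n), fs)
                    depth = config.burst_depth * gains
                    mod = np.exp(depth * _common_drive(rng, n, fs)[None, :])
                    amp = profile.global_gain * trial_gain
                    sig = amp * (gains * env[None, :] * mod * carrier
                                 + trial_profile.noise_floor * floor)
                    if alphas is not None:
                        sig = _impedance_lowpass(sig, alphas[chan_idx])
                    yield EmgRecording(
                        signal=sig, sampling_rate=fs, subject=s, trial=t,
                        gesture=g, repetition=r, layout=layout,
                    )


def generate_dataset(config: SynthConfig) -> list:
    """Generate the full labelled dataset as a list of :class:`EmgRecording`.

    Cardinality is n_subjects x n_trials x n_gestures x n_repetitions.  For
    large configurations prefer :func:`iter_dataset` to bound memory.
    """
    n_rec = (config.n_subjects * config.n_trials
             * config.n_gestures * config.n_repetitions)
    if n_rec > 20_000:
        warnings.warn("large dataset; consider iter_dataset()")
    return list(iter_dataset(config))
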