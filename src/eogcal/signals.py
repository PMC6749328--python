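"""Synthetic AC-EOG saccade signals and threshold-gated integral features.

Electro-oculography measures the electrical potential of the eye's
corneo-retinal dipole with skin electrodes: a saccade appears as a step in
the raw (DC) potential. A band-pass analog chain converts the drift-prone
DC-EOG into AC-EOG, turning each step into a biphasic transient that
self-centers at zero; the eye displacement is then recovered by integrating
the transient. Two channels (Ch1, Ch2) carry the horizontal and vertical
components.

This module synthesizes the measurement chain (sigmoidal DC steps, optional
blink transients, measurement noise, causal Butterworth band-pass at
1.06-4.97 Hz, 1 kHz sampling) and implements the signed, threshold-gated
signal integral used as the raw gaze feature: only samples above ``th+`` or
below ``th-`` contribute, which removes residual noise and fixes the
polarity of the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig
from scipy.special import expit

__all__ = [
    "ThresholdPair",
    "BandpassSpec",
    "SaccadeEvent",
    "TwoChannelRecording",
    "generate_dc_eog",
    "bandpass_ac",
    "signed_threshold_integral",
    "extract_gaze_feature",
    "thresholds_from_baseline",
]

DEFAULT_FS = 1000.0  # Hz, data-acquisition sampling rate


@dataclass(frozen=True)
class ThresholdPair:
    """Gating thresholds for the signal integral, in volts.

    Samples above ``th_plus`` contribute a positive area, samples below
    ``th_minus`` a negative area; everything in between is ignored.
    """

    th_plus: float
    th_minus: float

    def __post_init__(self) -> None:
        if not (self.th_minus < 0.0 < self.th_plus):
            raise ValueError(
                f"thresholds must satisfy th_minus < 0 < th_plus, "
                f"got ({self.th_minus!r}, {self.th_plus!r})"
            )


@dataclass(frozen=True)
class BandpassSpec:
    """Butterworth band-pass specification for the DC -> AC conversion.

    Defaults follow the analog chain: 1.06-4.97 Hz pass band, order 2,
    applied causally (forward only) like the physical circuit.
    """

    f_low: float = 1.06
    f_high: float = 4.97
    order: int = 2

    def __post_init__(self) -> None:
        if not (0.0 < self.f_low < self.f_high):
            raise ValueError(f"need 0 < f_low < f_high, got ({self.f_low}, {self.f_high})")
        if self.order < 1:
            raise ValueError(f"filter order must be >= 1, got {self.order}")

    def validate_against(self, fs: float) -> None:
        if self.f_high >= fs / 2.0:
            raise ValueError(
                f"f_high={self.f_high} Hz must be below the Nyquist frequency {fs / 2.0} Hz"
            )

    def sos(self, fs: float) -> np.ndarray:
        self.validate_against(fs)
        return _sig.butter(
            self.order, [self.f_low, self.f_high], btype="bandpass", fs=fs, output="sos"
        )


@dataclass(frozen=True)
class SaccadeEvent:
    """A gaze shift modeled as a smooth DC step on both channels.

    ``amp_ch1``/``amp_ch2`` are the signed step heights in volts (the DC
    offset the eye rotation produces on each electrode pair); ``rise_time``
    is the 10-90%-ish transition width of the logistic step. ``is_blink``
    tags a blink-like transient (a Gaussian pulse instead of a sustained
    step); blinks contribute to the integral like any other supra-threshold
    activity — no rejection is attempted.
    """

    onset: float
    amp_ch1: float
    amp_ch2: float
    rise_time: float = 0.02
    is_blink: bool = False

    def __post_init__(self) -> None:
        if self.onset < 0.0:
            raise ValueError(f"event onset must be >= 0, got {self.onset}")
        if self.rise_time <= 0.0:
            raise ValueError(f"rise_time must be > 0, got {self.rise_time}")


@dataclass
class TwoChannelRecording:
    """A uniformly sampled two-channel recording (volts vs seconds)."""

    t: np.ndarray
    ch1: np.ndarray
    ch2: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.ch1 = np.asarray(self.ch1, dtype=float)
        self.ch2 = np.asarray(self.ch2, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not (len(self.t) == len(self.ch1) == len(self.ch2)):
            raise ValueError("t, ch1 and ch2 must have equal length")
        if len(self.t) >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0) or not np.allclose(dt, 1.0 / self.fs, rtol=1e-6, atol=0):
                raise ValueError("t must be strictly increasing with spacing 1/fs")

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


def generate_dc_eog(
    events: list[SaccadeEvent],
    duration: float,
    fs: float = DEFAULT_FS,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> TwoChannelRecording:
    """Synthesize a DC-EOG recording as a sum of smooth steps plus noise.

    Each saccade contributes a logistic step ``amp * expit(4 (t-onset)/rise)``
    per channel (slope amp/rise at the center); blink events contribute a
    Gaussian transient of the same amplitude and width instead. Zero-mean
    Gaussian noise of standard deviation ``noise_sd`` volts is added per
    channel. A fixed ``seed`` makes the output bit-reproducible; with
    ``noise_sd=0`` the output is deterministic regardless of seed.
    """
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    if fs <= 0:
        raise ValueError(f"sampling rate must be positive, got {fs}")
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    for ev in events:
        if ev.onset + ev.rise_time >= duration:
            raise ValueError(
                f"event at onset={ev.onset}s with rise_time={ev.rise_time}s "
                f"does not fit in the {duration}s recording"
            )

    n = int(round(duration * fs))
    t = np.arange(n) / fs
    ch1 = np.zeros(n)
    ch2 = np.zeros(n)
    for ev in events:
        if ev.is_blink:
            shape = np.exp(-0.5 * ((t - ev.onset) / (ev.rise_time / 2.0)) ** 2)
        else:
            shape = expit(4.0 * (t - ev.onset) / ev.rise_time)
        ch1 += ev.amp_ch1 * shape
        ch2 += ev.amp_ch2 * shape
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        ch1 = ch1 + rng.normal(0.0, noise_sd, n)
        ch2 = ch2 + rng.normal(0.0, noise_sd, n)
    return TwoChannelRecording(t=t, ch1=ch1, ch2=ch2, fs=fs)


def bandpass_ac(rec: TwoChannelRecording, spec: BandpassSpec | None = None) -> TwoChannelRecording:
    """Convert DC-EOG to AC-EOG with a causal Butterworth band-pass.

    The filter is applied forward only, matching the analog circuit chain
    (zero-phase filtering would be acausal and unfaithful to hardware).
    """
    spec = spec if spec is not None else BandpassSpec()
    sos = spec.sos(rec.fs)
    return TwoChannelRecording(
        t=rec.t.copy(),
        ch1=_sig.sosfilt(sos, rec.ch1),
        ch2=_sig.sosfilt(sos, rec.ch2),
        fs=rec.fs,
    )


def signed_threshold_integral(channel: np.ndarray, fs: float, th: ThresholdPair) -> float:
    """Signed, threshold-gated Riemann integral of one channel (volt-seconds).

    The magnitude is ``|∫ x dt over {x > th+}| + |∫ x dt over {x < th-}|``
    (left-endpoint rectangles at spacing 1/fs). The sign is that of the lobe
    with the larger absolute area; on an exact tie, that of the lobe crossed
    first. A signal never leaving the band (th-, th+) integrates to exactly 0.
    """
    x = np.asarray(channel, dtype=float)
    if x.size == 0:
        raise ValueError("cannot integrate an empty signal")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite samples")
    if fs <= 0:
        raise ValueError(f"sampling rate must be positive, got {fs}")

    pos = x > th.th_plus
    neg = x < th.th_minus
    if not pos.any() and not neg.any():
        return 0.0
    area_pos = float(x[pos].sum()) / fs  # >= 0
    area_neg = float(x[neg].sum()) / fs  # <= 0
    magnitude = area_pos - area_neg
    if area_pos > -area_neg:
        sign = 1.0
    elif area_pos < -area_neg:
        sign = -1.0
    else:
        first_pos = int(np.argmax(pos)) if pos.any() else x.size
        first_neg = int(np.argmax(neg)) if neg.any() else x.size
        sign = 1.0 if first_pos <= first_neg else -1.0
    return sign * magnitude


def extract_gaze_feature(
    rec: TwoChannelRecording,
    th: ThresholdPair,
    gain: tuple[float, float] = (1.0, 1.0),
) -> np.ndarray:
    """Raw 2-D gaze feature: (Ch1 integral, Ch2 integral), optionally scaled.

    Ch1 carries the x component and Ch2 the y component. ``gain`` is a free
    per-axis scalar mapping volt-seconds to screen-pixel-like units; the
    affine calibration absorbs any residual scale.
    """
    return np.array(
        [
            gain[0] * signed_threshold_integral(rec.ch1, rec.fs, th),
            gain[1] * signed_threshold_integral(rec.ch2, rec.fs, th),
        ]
    )


def thresholds_from_baseline(
    channel: np.ndarray,
    fs: float,
    baseline_window: tuple[float, float] = (0.0, 0.5),
    k: float = 3.0,
) -> ThresholdPair:
    """Noise-referenced thresholds ``±k·σ̂`` from a quiet baseline window.

    ``σ̂`` is the standard deviation of the samples in ``baseline_window``
    (seconds). k=3 keeps residual Gaussian noise out of the integral while
    passing saccade transients.
    """
    x = np.asarray(channel, dtype=float)
    i0, i1 = (int(round(s * fs)) for s in baseline_window)
    segment = x[i0:i1]
    if segment.size < 2:
        raise ValueError("baseline window contains fewer than 2 samples")
    sd = float(np.std(segment))
    if sd <= 0:
        raise ValueError("baseline window has zero variance; cannot set noise-referenced thresholds")
    return ThresholdPair(th_plus=k * sd, th_minus=-k * sd)
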