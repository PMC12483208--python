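"""Surface-EMG processing and stance-phase segmentation.

Raw EMG is turned into normalized, delay-compensated excitations through the
conventional chain: 20 Hz high-pass, full-wave rectification, 6 Hz low-pass
(all zero-phase 4th-order Butterworth), normalization by the maximum of a
250 ms sliding-window MVC average and the gait envelope itself, and a 53 ms
electromechanical-delay shift.  Stance phases are segmented from vertical
GRF with a 20 N threshold and 50 ms debounce.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .config import CHANNEL_MAP, MEASURED_MUSCLES

#: electromechanical delay between excitation and force production, s
DEFAULT_DELAY = 0.053


class SamplingError(ValueError):
    pass


class NoStanceError(ValueError):
    pass


class ChannelMappingError(KeyError):
    pass


@dataclass
class EmgEnvelopeSet:
    """Named, normalized muscle envelopes on a common time base."""

    fs: float
    channels: dict[str, np.ndarray]
    mvc_max: dict[str, float] = field(default_factory=dict)
    delay_applied: float = 0.0
    invalid: list[str] = field(default_factory=list)


@dataclass
class StanceSegmentation:
    """Right-leg stance events plus derived temporal outcomes."""

    events: list[tuple[float, float]]  # (heel_strike, toe_off) times, s
    stride_time: float | None          # s, None with a single stance
    duty_factor: float | None

    @property
    def n_stances(self) -> int:
        return len(self.events)


def _sos(kind: str, fc: float, fs: float, order: int = 4):
    return butter(order, fc, btype=kind, fs=fs, output="sos")


def envelope(raw: np.ndarray, fs: float, f_high: float = 20.0,
             f_low: float = 6.0, order: int = 4) -> np.ndarray:
    """Linear envelope: zero-phase high-pass, rectify, zero-phase low-pass."""
    if fs <= 2 * f_high:
        raise SamplingError(
            f"sampling rate {fs} Hz too low for a {f_high} Hz high-pass"
        )
    raw = np.asarray(raw, dtype=float)
    x = sosfiltfilt(_sos("highpass", f_high, fs, order), raw)
    x = np.abs(x)
    return sosfiltfilt(_sos("lowpass", f_low, fs, order), x)


def sliding_window_max(x: np.ndarray, fs: float, window: float = 0.250) -> float:
    """Maximum of the sliding-window mean (MVC normalization numerator)."""
    n = max(1, int(round(window * fs)))
    if n >= x.size:
        return float(np.mean(x))
    kernel = np.ones(n) / n
    means = np.convolve(x, kernel, mode="valid")
    return float(np.max(means))


def mvc_normalize(
    gait_envelopes: dict[str, np.ndarray],
    mvc_envelopes: dict[str, np.ndarray],
    fs: float,
    window: float = 0.250,
) -> EmgEnvelopeSet:
    """Normalize gait envelopes so no signal exceeds 1.

    The per-muscle denominator is the larger of the 250 ms sliding-window
    MVC mean and the gait envelope's own maximum.  A channel whose
    denominator is zero is flagged invalid and excluded downstream.
    """
    channels: dict[str, np.ndarray] = {}
    mvc_max: dict[str, float] = {}
    invalid: list[str] = []
    for name, env in gait_envelopes.items():
        env = np.asarray(env, dtype=float)
        mvc = np.asarray(mvc_envelopes.get(name, np.zeros(1)), dtype=float)
        denom = max(sliding_window_max(mvc, fs, window), float(np.max(env, initial=0.0)))
        if denom <= 0.0:
            invalid.append(name)
            continue
        channels[name] = env / denom
        mvc_max[name] = denom
    return EmgEnvelopeSet(fs=fs, channels=channels, mvc_max=mvc_max, invalid=invalid)


def apply_delay(env: np.ndarray, fs: float, delay: float = DEFAULT_DELAY) -> np.ndarray:
    """Shift a signal later by ``round(delay*fs)`` samples, edge-extended.

    EMG leads force production; shifting the processed excitation forward in
    time aligns it with the mechanical output it drives.
    """
    if delay < 0:
        raise ValueError("delay must be nonnegative")
    env = np.asarray(env, dtype=float)
    k = int(round(delay * fs))
    if k >= env.size:
        raise ValueError(
            f"delay of {k} samples exceeds signal length {env.size}"
        )
    if k == 0:
        return env.copy()
    return np.concatenate([np.full(k, env[0]), env[:-k]])


def detect_stance(
    grf_vertical: np.ndarray,
    fs: float,
    threshold: float = 20.0,
    debounce: float = 0.050,
) -> StanceSegmentation:
    """Segment stance phases from vertical GRF threshold crossings.

    Heel strike is an upward crossing sustained for at least the debounce
    time; toe-off is the subsequent downward crossing.  Stride time is the
    interval between consecutive heel strikes; duty factor is stance over
    stride.
    """
    f = np.asarray(grf_vertical, dtype=float)
    if np.any(f < -1e-9):
        raise ValueError("vertical GRF must be nonnegative")
    above = f > threshold
    n_min = max(1, int(round(debounce * fs)))
    events: list[tuple[float, float]] = []
    i = 0
    n = f.size
    while i < n:
        if above[i] and (i == 0 or not above[i - 1]):
            j = i
            while j < n and above[j]:
                j += 1
            if j - i >= n_min:
                hs = i / fs
                if j < n:
                    events.append((hs, j / fs))
                # contact running past the record end is dropped (no toe-off)
            i = j
        else:
            i += 1
    if not events:
        raise NoStanceError(
            f"no stance phase found above {threshold} N for >= {debounce} s"
        )
    stride = duty = None
    if len(events) >= 2:
        stride = events[1][0] - events[0][0]
        stance = events[0][1] - events[0][0]
        duty = stance / stride
    return StanceSegmentation(events=events, stride_time=stride, duty_factor=duty)


def map_channels(env9: EmgEnvelopeSet) -> dict[str, np.ndarray]:
    """Expand 9 measured channels to the 12-muscle reference excitation set.

    vasmed -> vasint, bflh -> bfsh, semiten -> semimem; originals retained.
    """
    missing = [m for m in MEASURED_MUSCLES if m not in env9.channels]
    if missing:
        unmappable = [t for t, s in CHANNEL_MAP.items() if s in missing]
        raise ChannelMappingError(
            f"missing source channels {missing}; cannot map {unmappable}"
        )
    out = {name: env9.channels[name].copy() for name in MEASURED_MUSCLES}
    for target, source in CHANNEL_MAP.items():
        out[target] = env9.channels[source].copy()
    return out


def flag_saturated(
    channels: dict[str, np.ndarray], fs: float, max_flat: float = 0.5
) -> list[str]:
    """Flag channels pinned at a bound (0 or 1) for longer than ``max_flat`` s.

    Programmatic stand-in for visual inspection of erroneous strides.
    """
    n_max = int(round(max_flat * fs))
    bad = []
    for name, x in channels.items():
        at_bound = (x <= 0.0) | (x >= 1.0)
        run = best = 0
        for b in at_bound:
            run = run + 1 if b else 0
            best = max(best, run)
        if best > n_max:
            bad.append(name)
    return bad
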