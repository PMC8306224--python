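"""Sensor-space preprocessing: filtering, epoching, and artifact/spike exclusion.

Clinical interictal EEG is notch-filtered at the mains frequency, band-pass
filtered to 1-70 Hz, cut into fixed-length epochs, and cleaned by dropping
every epoch that overlaps a marked epileptic spike (+/- 1 s around the spike
instant) or an artifact interval.  All filters are zero-phase so that epoch
timing is never shifted relative to the annotations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

#: Half-width (s) of the exclusion window centred on each spike instant.
SPIKE_HALF_WINDOW_S = 1.0


@dataclass
class Annotations:
    """Event markers attached to a recording, in seconds from record start."""

    spikes_s: list[float] = field(default_factory=list)
    artifacts_s: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.spikes_s = [float(t) for t in self.spikes_s]
        self.artifacts_s = [(float(a), float(b)) for a, b in self.artifacts_s]
        for a, b in self.artifacts_s:
            if b < a:
                raise ValueError(f"artifact interval [{a}, {b}] has negative length")


@dataclass
class EEGRecording:
    """Continuous multichannel scalp EEG.

    Parameters
    ----------
    data
        Array of shape ``(n_sensors, n_samples)`` in microvolts.
    fs
        Sampling rate in Hz.
    sensor_labels
        One unique label per sensor.
    annotations
        Spike instants and artifact intervals, in seconds.
    """

    data: np.ndarray
    fs: float
    sensor_labels: list[str]
    annotations: Annotations = field(default_factory=Annotations)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("EEG samples must be finite")
        if len(self.sensor_labels) != self.data.shape[0]:
            raise ValueError("one label per sensor required")
        if len(set(self.sensor_labels)) != len(self.sensor_labels):
            raise ValueError("sensor labels must be unique")

    @property
    def n_sensors(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class EpochSet:
    """Fixed-length, non-overlapping analysis windows cut from a recording."""

    data: np.ndarray  # (n_epochs, n_sensors, n_samples_per_epoch)
    fs: float
    epoch_len_s: float
    epoch_start_times_s: np.ndarray
    sensor_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be (epochs, sensors, samples)")
        self.epoch_start_times_s = np.asarray(self.epoch_start_times_s, dtype=float)
        if len(self.epoch_start_times_s) != self.data.shape[0]:
            raise ValueError("one start time per epoch required")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


def apply_notch(rec: EEGRecording, freq: float = 60.0, q: float = 30.0) -> EEGRecording:
    """Zero-phase second-order IIR notch at the mains frequency.

    The notch is applied forward-backward (``filtfilt``) so the net phase
    response is identically zero and rejection at ``freq`` is doubled in dB.
    """
    if freq >= rec.fs / 2:
        raise ValueError(f"notch frequency {freq} Hz at or above Nyquist ({rec.fs / 2} Hz)")
    b, a = signal.iirnotch(freq, Q=q, fs=rec.fs)
    filtered = signal.filtfilt(b, a, rec.data, axis=-1)
    return replace(rec, data=filtered)


def _kaiser_fir(cutoff_hz: float, fs: float, transition_hz: float,
                ripple_db: float, pass_zero: str) -> np.ndarray:
    """Even-order (odd-length, type-I) linear-phase Kaiser-window FIR taps."""
    numtaps, beta = signal.kaiserord(ripple_db, transition_hz / (fs / 2))
    numtaps += 1 - numtaps % 2  # force odd length = even order
    return signal.firwin(numtaps, cutoff_hz, window=("kaiser", beta),
                         pass_zero=pass_zero, fs=fs)


def _zero_phase_fir(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Apply a linear-phase FIR with exact group-delay compensation.

    The signal is reflection-padded by the filter half-length on both sides,
    convolved once, and cropped so the net delay is zero samples.
    """
    half = (len(taps) - 1) // 2
    pad = min(half, x.shape[-1] - 1)
    padded = np.concatenate(
        [x[..., 1:pad + 1][..., ::-1], x, x[..., -pad - 1:-1][..., ::-1]], axis=-1
    )
    if padded.shape[-1] < len(taps):  # very short signals: zero-pad further
        extra = len(taps) - padded.shape[-1]
        padded = np.pad(padded, [(0, 0)] * (padded.ndim - 1) + [(0, extra)])
    full = signal.fftconvolve(padded, taps[np.newaxis, :] if x.ndim == 2 else taps,
                              axes=-1, mode="full")
    start = half + pad
    return full[..., start:start + x.shape[-1]]


def apply_bandpass(rec: EEGRecording, low: float = 1.0, high: float = 70.0,
                   ripple_db: float = 40.0) -> EEGRecording:
    """Zero-delay band-pass with an even-order Kaiser-window FIR design.

    Implemented as a high-pass / low-pass cascade so the transition widths can
    differ at the two edges (1 Hz at the low edge, 5 Hz at the high edge):
    a single shared transition width sized for the 1 Hz edge would make the
    filter needlessly long.  Stop-band attenuation is >= ``ripple_db``.
    """
    if not (0 < low < high < rec.fs / 2):
        raise ValueError(f"invalid band ({low}, {high}) Hz at fs={rec.fs} Hz")
    hp = _kaiser_fir(low, rec.fs, transition_hz=min(1.0, low), ripple_db=ripple_db,
                     pass_zero="highpass")
    lp = _kaiser_fir(high, rec.fs, transition_hz=min(5.0, (rec.fs / 2 - high)),
                     ripple_db=ripple_db, pass_zero="lowpass")
    filtered = _zero_phase_fir(_zero_phase_fir(rec.data, hp), lp)
    return replace(rec, data=filtered)


def segment_epochs(rec: EEGRecording, epoch_len_s: float = 2.0) -> EpochSet:
    """Cut the record into consecutive non-overlapping epochs from t=0.

    A trailing partial window is discarded.
    """
    n_per = int(round(epoch_len_s * rec.fs))
    if n_per <= 0:
        raise ValueError("epoch length must be positive")
    n_epochs = rec.n_samples // n_per
    if n_epochs == 0:
        raise ValueError(
            f"recording of {rec.duration_s:.3f} s shorter than one {epoch_len_s} s epoch"
        )
    data = rec.data[:, :n_epochs * n_per].reshape(rec.n_sensors, n_epochs, n_per)
    return EpochSet(
        data=np.moveaxis(data, 0, 1),
        fs=rec.fs,
        epoch_len_s=epoch_len_s,
        epoch_start_times_s=np.arange(n_epochs) * epoch_len_s,
        sensor_labels=list(rec.sensor_labels),
    )


def exclude_contaminated(ep: EpochSet, annotations: Annotations) -> EpochSet:
    """Drop every epoch overlapping a spike window or an artifact interval.

    Each spike at time ``t`` contaminates the open interval
    ``(t - 1 s, t + 1 s)``; any epoch with non-empty intersection with a spike
    window or an artifact interval is removed.  Surviving epochs keep their
    order, start times, and sample values untouched.
    """
    windows = [(t - SPIKE_HALF_WINDOW_S, t + SPIKE_HALF_WINDOW_S)
               for t in annotations.spikes_s]
    windows += list(annotations.artifacts_s)
    keep = np.ones(ep.n_epochs, dtype=bool)
    for i, start in enumerate(ep.epoch_start_times_s):
        stop = start + ep.epoch_len_s
        for w0, w1 in windows:
            if start < w1 and stop > w0:
                keep[i] = False
                break
    if not keep.any():
        logger.warning("all %d epochs contaminated; empty epoch set returned", ep.n_epochs)
    return EpochSet(
        data=ep.data[keep],
        fs=ep.fs,
        epoch_len_s=ep.epoch_len_s,
        epoch_start_times_s=ep.epoch_start_times_s[keep],
        sensor_labels=list(ep.sensor_labels),
    )
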