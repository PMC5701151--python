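"""Signal conditioning: re-reference, downsample, notch, band-pass, segment.

The chain mirrors common resting-state EEG practice: signals are
re-referenced to the mastoid average, decimated to a working rate,
power-line noise is notched out, and each analysis runs on a zero-phase
band-passed copy split into non-overlapping segments.

All filters are zero-phase (forward-backward FIR).  Phase fidelity is the
binding constraint here: the phase lag index downstream is a statistic of
instantaneous phase differences, and any phase distortion introduced by
filtering would bias it.  A linear-phase FIR applied forward and backward
has exactly zero phase response in its passband.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .bands import BandDefinition
from .recording import Recording

__all__ = [
    "SegmentedBandData",
    "rereference",
    "downsample",
    "notch_filter",
    "bandpass",
    "segment",
    "band_segments",
]

# Hamming-window FIR: transition width ~ 3.3 / (numtaps / fs).
_HAMMING_TW_FACTOR = 3.3


@dataclass
class SegmentedBandData:
    """Non-overlapping fixed-length segments of one band-passed recording."""

    subject_id: str
    band: BandDefinition | None
    segments: list[np.ndarray]
    segment_length: float
    sample_rate: float
    group: int | None = None
    channel_labels: list[str] = field(default_factory=list)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def n_channels(self) -> int:
        return self.segments[0].shape[0]


def _fir_taps(fs: float, cutoffs: list[float], pass_zero, transition: float
              ) -> np.ndarray:
    """Design a Hamming-window FIR with the given transition width (Hz)."""
    numtaps = int(math.ceil(_HAMMING_TW_FACTOR * fs / transition))
    numtaps += 1 - numtaps % 2  # odd length -> type-I linear phase
    return signal.firwin(numtaps, cutoffs, fs=fs, pass_zero=pass_zero,
                         window="hamming")


def _filtfilt(taps: np.ndarray, data: np.ndarray) -> np.ndarray:
    # padlen must stay below the signal length for short inputs
    padlen = min(3 * (len(taps) - 1), data.shape[-1] - 1)
    return signal.filtfilt(taps, [1.0], data, axis=-1, padlen=padlen)


def rereference(recording: Recording, reference_channels: list[str]
                ) -> Recording:
    """Subtract the mean of the named reference channels from every channel.

    With mastoid references this removes the common signal those sensors
    share; a re-reference with all-zero reference channels is the identity.
    """
    if not reference_channels:
        raise ValueError("need at least one reference channel")
    idx = [recording.channel_index(label) for label in reference_channels]
    ref = recording.data[idx].mean(axis=0)
    return recording.copy_with(recording.data - ref[None, :])


def downsample(recording: Recording, target_rate: float) -> Recording:
    """Anti-alias filter and decimate to ``target_rate``.

    ``target_rate`` must divide the current rate; decimation by large
    factors is staged so each FIR stage stays short.
    """
    fs = recording.sample_rate
    if target_rate > fs:
        raise ValueError(f"target rate {target_rate} exceeds sample rate {fs}")
    if target_rate <= 0:
        raise ValueError("target rate must be positive")
    q, rem = divmod(fs, target_rate)
    if rem != 0:
        raise ValueError(
            f"target rate {target_rate} does not divide sample rate {fs}")
    q = int(q)
    if q == 1:
        return recording.copy_with(recording.data)
    data = recording.data
    while q > 1:
        step = min(q, 10)
        # prefer an exact small factor so staged decimation is exact
        while q % step:
            step -= 1
        data = signal.decimate(data, step, ftype="fir", zero_phase=True,
                               axis=-1)
        q //= step
    return recording.copy_with(data, sample_rate=target_rate)


def notch_filter(recording: Recording, freq: float = 50.0,
                 half_width: float = 2.0) -> Recording:
    """Zero-phase FIR band-stop around the power-line frequency.

    The stop band spans ``freq +/- half_width`` (48-52 Hz by default).
    """
    nyq = recording.sample_rate / 2
    if freq >= nyq:
        raise ValueError(f"notch frequency {freq} >= Nyquist {nyq}")
    taps = _fir_taps(recording.sample_rate,
                     [freq - half_width, freq + half_width],
                     pass_zero="bandstop", transition=half_width / 2)
    return recording.copy_with(_filtfilt(taps, recording.data))


def bandpass(recording: Recording, band: BandDefinition) -> Recording:
    """Zero-phase FIR band-pass to ``band``.

    The transition width is 25% of the lower band edge, so narrow
    low-frequency bands get proportionally sharper (longer) filters.
    """
    nyq = recording.sample_rate / 2
    if band.high >= nyq:
        raise ValueError(f"band {band.name} upper edge {band.high} >= "
                         f"Nyquist {nyq}")
    taps = _fir_taps(recording.sample_rate, [band.low, band.high],
                     pass_zero=False, transition=0.25 * band.low)
    return recording.copy_with(_filtfilt(taps, recording.data))


def segment(recording: Recording, segment_length: float = 5.0,
            band: BandDefinition | None = None) -> SegmentedBandData:
    """Split into non-overlapping segments; a trailing partial segment is
    discarded."""
    if segment_length <= 0:
        raise ValueError("segment_length must be positive")
    n_per = int(round(segment_length * recording.sample_rate))
    n_seg = recording.n_samples // n_per
    if n_seg == 0:
        raise ValueError(
            f"recording of {recording.duration:.2f} s shorter than one "
            f"{segment_length} s segment")
    segments = [recording.data[:, k * n_per:(k + 1) * n_per].copy()
                for k in range(n_seg)]
    return SegmentedBandData(
        subject_id=recording.subject_id,
        band=band,
        segments=segments,
        segment_length=segment_length,
        sample_rate=recording.sample_rate,
        group=recording.group,
        channel_labels=list(recording.channel_labels),
    )


def band_segments(recording: Recording, band: BandDefinition,
                  segment_length: float = 5.0) -> SegmentedBandData:
    """Band-pass then segment — the per-band entry point of the pipeline."""
    return segment(bandpass(recording, band), segment_length, band=band)
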