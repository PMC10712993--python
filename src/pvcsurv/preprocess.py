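"""Signal conditioning: 0.5–45 Hz bandpass, decimation to 250 Hz, and
non-overlapping fixed-length segmentation (2048 samples, ≈8.2 s).

All beat coordinates downstream of this module are 0-based sample indices
at the post-decimation rate (250 Hz by default); :func:`map_indices`
converts annotation indices between rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = ["SegmentBatch", "bandpass", "downsample", "segment", "desegment", "map_indices", "SEGMENT_LENGTH"]

SEGMENT_LENGTH = 2048


def bandpass(x: np.ndarray, fs: float, low: float = 0.5, high: float = 45.0, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth bandpass (forward-backward), same length out.

    Zero phase matters: filtering must not shift R-peak locations relative
    to the beat annotations.
    """
    x = np.asarray(x, dtype=float)
    if fs <= 2 * high:
        raise ValueError(f"fs={fs} too low for a {high} Hz passband edge")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite samples")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def butter_response_db(freq_hz: float, fs: float, low: float = 0.5, high: float = 45.0, order: int = 4) -> float:
    """Magnitude response (dB) of the zero-phase bandpass at one frequency.

    Forward-backward filtering squares the magnitude response, hence the
    factor of 2.  Exposed so tests can compare measured attenuation against
    the designed transfer function.
    """
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    _, h = sps.sosfreqz(sos, worN=[freq_hz], fs=fs)
    return float(2 * 20 * np.log10(np.abs(h[0]) + 1e-300))


def downsample(x: np.ndarray, fs_in: float, fs_out: float = 250.0) -> np.ndarray:
    """Anti-aliased integer-factor decimation; identity when rates match.

    Output length is ``ceil(len(x) * fs_out / fs_in)``.
    """
    x = np.asarray(x, dtype=float)
    if fs_out > fs_in:
        raise ValueError(f"fs_out={fs_out} exceeds fs_in={fs_in}")
    if fs_out == fs_in:
        return x.copy()
    q = fs_in / fs_out
    if abs(q - round(q)) > 1e-9:
        raise ValueError(f"fs_in={fs_in} must be an integer multiple of fs_out={fs_out}")
    # zero-phase FIR decimator keeps beat positions aligned at index/q
    return sps.decimate(x, int(round(q)), ftype="fir", zero_phase=True)


def map_indices(idx: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Map annotation sample indices between sampling rates (nearest sample)."""
    return np.round(np.asarray(idx) * (fs_out / fs_in)).astype(np.int64)


@dataclass
class SegmentBatch:
    """Non-overlapping fixed-length windows of one recording.

    The final window is zero-padded; ``valid_length`` is the number of real
    samples it carries, so :func:`desegment` reconstructs the signal
    exactly.
    """

    segments: np.ndarray  # (n_segments, SEGMENT_LENGTH)
    valid_length: int
    origin: str = ""

    def __post_init__(self) -> None:
        self.segments = np.atleast_2d(np.asarray(self.segments, dtype=float))
        if self.segments.shape[1] != SEGMENT_LENGTH:
            raise ValueError(f"segments must have length {SEGMENT_LENGTH}")
        if not 1 <= self.valid_length <= SEGMENT_LENGTH:
            raise ValueError("valid_length must be in [1, segment length]")

    @property
    def n_segments(self) -> int:
        return self.segments.shape[0]

    @property
    def total_length(self) -> int:
        return (self.n_segments - 1) * SEGMENT_LENGTH + self.valid_length


def segment(x: np.ndarray, origin: str = "") -> SegmentBatch:
    """Split a signal into 2048-sample windows, zero-padding the tail.

    The whole recording is always kept: dropping a partial tail could drop
    PVCs and bias downstream counts.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) == 0:
        raise ValueError("signal must be a non-empty 1-D array")
    L = len(x)
    n_full, rem = divmod(L, SEGMENT_LENGTH)
    if rem == 0:
        segs = x.reshape(n_full, SEGMENT_LENGTH)
        return SegmentBatch(segs.copy(), SEGMENT_LENGTH, origin)
    padded = np.zeros((n_full + 1) * SEGMENT_LENGTH)
    padded[:L] = x
    return SegmentBatch(padded.reshape(n_full + 1, SEGMENT_LENGTH), rem, origin)


def desegment(batch: SegmentBatch) -> np.ndarray:
    """Exact inverse of :func:`segment` (strips the zero padding)."""
    flat = batch.segments.reshape(-1)
    return flat[: batch.total_length].copy()
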