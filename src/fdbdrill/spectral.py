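"""Short-time spectral analysis of acoustic-emission recordings.

A drilling recording is cut into overlapping Hamming-windowed frames, each
frame is transformed with an FFT, and the magnitude bins inside the
drilling band (10--15 kHz by default) are kept.  The band-limited spectrum
of each frame is the raw material for the frequency-distribution features
computed in :mod:`fdbdrill.fdb`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import get_window

__all__ = [
    "AcousticRecord",
    "FrameSpec",
    "BandSpectrum",
    "frame_signal",
    "frame_spectrum",
    "extract_band",
    "band_spectra",
]

#: Default analysis band (Hz): drilling energy concentrates here while
#: ambient noise (voices, motors) stays below it.
DEFAULT_BAND = (10_000.0, 15_000.0)


@dataclass(frozen=True)
class AcousticRecord:
    """A mono acoustic-emission recording.

    Parameters
    ----------
    samples
        Sensor voltage samples (arbitrary units).
    sample_rate
        Sampling frequency in Hz.  Band analysis up to ``band_hi`` requires
        ``sample_rate >= 2 * band_hi`` (Nyquist).
    start_time
        Absolute time of the first sample, seconds.
    """

    samples: np.ndarray
    sample_rate: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not self.sample_rate > 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate


@dataclass(frozen=True)
class FrameSpec:
    """Sliding-window framing parameters.

    The defaults (512-sample Hamming frames advanced by 100 samples) give a
    frequency resolution of ``fs/512`` (85.94 Hz at 44 kHz) and a frame rate
    of ``fs/100`` (440 frames/s at 44 kHz).
    """

    frame_size: int = 512
    hop: int = 100
    window: str = "hamming"

    def __post_init__(self) -> None:
        if not 0 < self.hop <= self.frame_size:
            raise ValueError(
                f"hop must satisfy 0 < hop <= frame_size, got hop={self.hop}, "
                f"frame_size={self.frame_size}"
            )

    def taper(self) -> np.ndarray:
        return get_window(self.window, self.frame_size, fftbins=False)

    def n_frames(self, n_samples: int) -> int:
        """Number of complete frames in a signal of ``n_samples`` samples."""
        if n_samples < self.frame_size:
            return 0
        return (n_samples - self.frame_size) // self.hop + 1


@dataclass(frozen=True)
class BandSpectrum:
    """Magnitude spectrum of one frame restricted to the analysis band."""

    time: float
    freqs: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs, dtype=float)
        amps = np.asarray(self.amplitudes, dtype=float)
        if freqs.shape != amps.shape or freqs.ndim != 1:
            raise ValueError("freqs and amplitudes must be 1-D arrays of equal length")
        if freqs.size < 2:
            raise ValueError("a band spectrum needs at least 2 bins")
        if np.any(np.diff(freqs) <= 0):
            raise ValueError("freqs must be strictly ascending")
        if np.any(amps < 0):
            raise ValueError("amplitudes must be nonnegative")
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "amplitudes", amps)

    @property
    def k(self) -> int:
        return self.freqs.size


def frame_signal(record: AcousticRecord, spec: FrameSpec | None = None):
    """Cut a record into windowed frames.

    Frame ``j`` covers samples ``[j*hop, j*hop + frame_size)`` and is
    multiplied elementwise by the window taper.  The last partial frame is
    dropped.  Frame timestamps are the window centers.

    Returns
    -------
    times : ndarray, shape (n_frames,)
    frames : ndarray, shape (n_frames, frame_size)
    """
    spec = spec or FrameSpec()
    n = record.samples.size
    n_frames = spec.n_frames(n)
    if n_frames < 1:
        raise ValueError(
            f"signal too short: {n} samples < one frame of {spec.frame_size}"
        )
    starts = np.arange(n_frames) * spec.hop
    idx = starts[:, None] + np.arange(spec.frame_size)[None, :]
    frames = record.samples[idx] * spec.taper()[None, :]
    times = record.start_time + (starts + spec.frame_size / 2) / record.sample_rate
    return times, frames


def frame_spectrum(frame: np.ndarray, sample_rate: float):
    """One-sided magnitude spectrum of a (windowed) frame.

    No ``1/N`` scaling is applied: the downstream per-frame normalization
    divides by the maximum amplitude, so any global scale cancels.

    Returns
    -------
    freqs : ndarray — bin center frequencies ``i * fs / frame_size``
    mags : ndarray — nonnegative magnitudes, same length
    """
    frame = np.atleast_2d(np.asarray(frame, dtype=float))
    n = frame.shape[-1]
    mags = np.abs(np.fft.rfft(frame, axis=-1))
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    if frame.shape[0] == 1:
        mags = mags[0]
    return freqs, mags


def extract_band(
    time: float,
    freqs: np.ndarray,
    mags: np.ndarray,
    band_lo: float = DEFAULT_BAND[0],
    band_hi: float = DEFAULT_BAND[1],
) -> BandSpectrum:
    """Keep the bins whose center frequency lies in ``[band_lo, band_hi]``.

    The interval is closed on both ends.  Raises if no bin falls inside.
    """
    if not band_lo < band_hi:
        raise ValueError(f"need band_lo < band_hi, got [{band_lo}, {band_hi}]")
    mask = (freqs >= band_lo) & (freqs <= band_hi)
    if not mask.any():
        raise ValueError(
            f"no FFT bins inside [{band_lo}, {band_hi}] Hz; "
            "increase frame_size or widen the band"
        )
    return BandSpectrum(time=time, freqs=freqs[mask], amplitudes=mags[mask])


def band_spectra(
    record: AcousticRecord,
    spec: FrameSpec | None = None,
    band_lo: float = DEFAULT_BAND[0],
    band_hi: float = DEFAULT_BAND[1],
) -> list[BandSpectrum]:
    """Full front end: frame, transform, and band-limit a recording."""
    spec = spec or FrameSpec()
    if band_hi > record.sample_rate / 2:
        raise ValueError(
            f"band_hi={band_hi} Hz exceeds Nyquist {record.sample_rate / 2} Hz"
        )
    times, frames = frame_signal(record, spec)
    freqs, mags = frame_spectrum(frames, record.sample_rate)
    mask = (freqs >= band_lo) & (freqs <= band_hi)
    if not mask.any():
        raise ValueError(f"no FFT bins inside [{band_lo}, {band_hi}] Hz")
    band_freqs = freqs[mask]
    return [
        BandSpectrum(time=t, freqs=band_freqs, amplitudes=m)
        for t, m in zip(times, mags[:, mask])
    ]
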