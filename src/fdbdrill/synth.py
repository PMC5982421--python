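"""Synthetic drilling sessions with known per-frame ground truth.

No public recordings of bone drilling with layer annotations exist, so the
package ships a simulator that realizes the spectral-energy structure the
recognition method relies on: inside the 10--15 kHz analysis band, dense
cortical bone concentrates acoustic energy in the upper third of the band,
porous cancellous bone in the lower third, and the trabecular transition
region spreads it nearly uniformly across the band.  Below 10 kHz every
state carries broadband background noise (motors, ambient sound) that the
band selection is supposed to reject.

A session is a timeline of layer segments
(cortical -> transition -> cancellous -> transition -> cortical, the path
of a drill bit passing through a vertebra and stopping before the inner
cortical wall), with short amplitude crossfades at the joins.  The
in-band signal of a segment is a comb of random-phase tones at the
analysis bins' center frequencies, so each tone is exactly representable
in an analysis frame.  Tone amplitudes follow the layer's sub-band power
envelope with a fixed per-bin log-normal jitter (resonance structure) and
a slow log-normal drift over time (changing cutting conditions), which is
what gives consecutive frames realistic, correlated variability.

What the simulator does *not* model: tool-wear trends, depth-dependent
attenuation through bone already drilled, chip-clearing transients, or
any physical acoustics of bone — only the statistical spectrum structure
the recognition method consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .classify import LayerTimeline
from .spectral import DEFAULT_BAND, AcousticRecord, FrameSpec

__all__ = [
    "LayerState",
    "LayerProfile",
    "Segment",
    "SessionConfig",
    "make_layer_profile",
    "synthesize_session",
    "make_benchmark",
]


class LayerState(str, Enum):
    CORTICAL = "cortical"
    CANCELLOUS = "cancellous"
    TRANSITION = "transition"

    @property
    def label(self) -> int:
        """Binary ground truth: 1 for the transition region, else 0."""
        return 1 if self is LayerState.TRANSITION else 0


@dataclass(frozen=True)
class LayerProfile:
    """Spectral character of one layer inside the analysis band.

    ``weights`` is the relative power per sub-band on a uniform sub-band
    grid over ``band``; nonnegative, normalized to sum to 1.
    """

    state: LayerState
    band: tuple[float, float]
    weights: np.ndarray
    in_band_power: float = 1.0
    background_power: float = 0.1
    #: log-normal spread of tone amplitudes around the envelope: small for
    #: the diffuse transition spectrum, large for resonance-dominated
    #: cortical/cancellous spectra
    bin_jitter_sigma: float = 0.5

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("sub-band weights must be nonnegative")
        total = w.sum()
        if total <= 0:
            raise ValueError("sub-band weights must not be all zero")
        object.__setattr__(self, "weights", w / total)

    def third_fractions(self) -> np.ndarray:
        """Power fraction in the lower/middle/upper third of the band."""
        thirds = np.array_split(self.weights, 3)
        return np.array([t.sum() for t in thirds])


@dataclass(frozen=True)
class Segment:
    state: LayerState
    duration: float

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError("segment duration must be positive")


#: Segment timeline shaped after a full pedicle pass: outer cortical,
#: transition, cancellous, transition, inner cortical (durations in s).
DEFAULT_SEGMENTS = (
    Segment(LayerState.CORTICAL, 4.1),
    Segment(LayerState.TRANSITION, 1.75),
    Segment(LayerState.CANCELLOUS, 4.3),
    Segment(LayerState.TRANSITION, 1.7),
    Segment(LayerState.CORTICAL, 2.1),
)


@dataclass(frozen=True)
class SessionConfig:
    """One simulated drilling pass.

    ``noise_level`` is the below-band background power relative to unit
    in-band power.  ``drift_sigma`` and ``drift_corr_s`` shape the slow
    log-normal amplitude drift of each tone over time.
    ``comb_resolution`` is the FFT length whose bin grid the tone
    frequencies sit on.
    """

    seed: int
    segments: tuple[Segment, ...] = DEFAULT_SEGMENTS
    sample_rate: float = 44_000.0
    band: tuple[float, float] = DEFAULT_BAND
    noise_level: float = 0.3
    ramp_s: float = 0.05
    drift_sigma: float = 0.1
    drift_corr_s: float = 0.2
    comb_resolution: int = 512

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("need at least one segment")

    @property
    def duration(self) -> float:
        return sum(s.duration for s in self.segments)

    def boundary_times(self) -> np.ndarray:
        """True segment-join times, seconds from session start."""
        durs = np.array([s.duration for s in self.segments])
        return np.cumsum(durs)[:-1]


N_SUBBANDS = 12  # divisible by 3 so the band thirds are exact


def make_layer_profile(
    state: LayerState,
    rng: np.random.Generator,
    band: tuple[float, float] = DEFAULT_BAND,
    background_power: float = 0.1,
) -> LayerProfile:
    """Draw a jittered spectral profile for one layer state.

    Construction guarantees the defining energy split: concentrated states
    put at least 70% of in-band power in their characteristic third
    (upper for cortical, lower for cancellous), the transition state keeps
    every third between 25% and 42% of in-band power.
    """
    per = N_SUBBANDS // 3
    if state is LayerState.TRANSITION:
        jitter_sigma = rng.uniform(0.13, 0.22)
        # thirds jittered around 1/3 but kept well inside [0.25, 0.42]
        while True:
            thirds = rng.uniform(0.29, 0.38, 3)
            thirds = thirds / thirds.sum()
            if np.all((thirds >= 0.25) & (thirds <= 0.42)):
                break
    else:
        jitter_sigma = rng.uniform(0.6, 0.8)
        main = rng.uniform(0.72, 0.85)
        split = rng.uniform(0.3, 0.7)
        rest = 1.0 - main
        if state is LayerState.CORTICAL:
            thirds = np.array([rest * split, rest * (1 - split), main])
        else:
            thirds = np.array([main, rest * split, rest * (1 - split)])
    weights = np.concatenate(
        [f / per * rng.uniform(0.7, 1.3, per) for f in thirds]
    )
    # renormalize the jitter within each third so the split is exact
    for j, f in enumerate(thirds):
        sl = slice(j * per, (j + 1) * per)
        weights[sl] *= f / weights[sl].sum()
    return LayerProfile(
        state=state, band=band, weights=weights,
        background_power=background_power, bin_jitter_sigma=jitter_sigma,
    )


def _smooth_drift(
    n: int, sample_rate: float, corr_s: float, sigma: float,
    n_series: int, rng: np.random.Generator,
) -> np.ndarray:
    """(n_series, n) slow zero-mean Gaussian drifts with unit-sigma scale."""
    knot_dt = max(corr_s / 4.0, 1.0 / sample_rate)
    n_knots = max(int(np.ceil(n / sample_rate / knot_dt)) + 2, 4)
    knots = rng.standard_normal((n_series, n_knots))
    knots = gaussian_filter1d(knots, sigma=4.0, axis=1, mode="nearest")
    # restore unit variance lost to smoothing, then scale
    knots *= sigma / max(knots.std(), 1e-12)
    t = np.arange(n) / sample_rate
    kt = np.arange(n_knots) * knot_dt
    return np.vstack([np.interp(t, kt, k) for k in knots])


def _comb_segment(
    n: int, config: SessionConfig, profile: LayerProfile,
    rng: np.random.Generator,
) -> np.ndarray:
    """In-band tone comb for one segment, amplitude-modulated over time."""
    fs = config.sample_rate
    lo, hi = config.band
    bin_freqs = np.arange(config.comb_resolution // 2 + 1) * fs / config.comb_resolution
    freqs = bin_freqs[(bin_freqs >= lo) & (bin_freqs <= hi)]
    # tones on every third analysis bin: a Hamming window has zero gain at
    # integer bin offsets >= 2, so every band bin is either a stable tone
    # bin or a stable single-tone leakage bin -- no phase interference
    freqs = freqs[::3]

    # per-tone power density from the sub-band envelope
    edges = np.linspace(lo, hi, profile.weights.size + 1)
    sub = np.clip(np.searchsorted(edges, freqs, side="right") - 1,
                  0, profile.weights.size - 1)
    counts = np.bincount(sub, minlength=profile.weights.size).astype(float)
    density = profile.weights[sub] / counts[sub]

    # fixed log-normal texture per tone + slow log-normal drift over time
    texture = np.exp(profile.bin_jitter_sigma * rng.standard_normal(freqs.size))
    base = np.sqrt(density) * texture
    drift = np.exp(
        _smooth_drift(n, fs, config.drift_corr_s, config.drift_sigma,
                      freqs.size, rng)
    )
    phases = rng.uniform(0, 2 * np.pi, freqs.size)
    t = np.arange(n) / fs
    x = np.zeros(n)
    for f, a, ph, dr in zip(freqs, base, phases, drift):
        x += a * dr * np.cos(2 * np.pi * f * t + ph)
    rms = np.sqrt(np.mean(x ** 2))
    if rms > 0:
        x *= np.sqrt(profile.in_band_power) / rms
    return x


def _background_noise(
    n: int, config: SessionConfig, power: float, rng: np.random.Generator
) -> np.ndarray:
    """Broadband Gaussian noise confined below the analysis band."""
    freqs = np.fft.rfftfreq(n, d=1.0 / config.sample_rate)
    gain = ((freqs >= 200.0) & (freqs < config.band[0])).astype(float)
    spectrum = gain * (rng.standard_normal(freqs.size)
                       + 1j * rng.standard_normal(freqs.size))
    x = np.fft.irfft(spectrum, n=n)
    rms = np.sqrt(np.mean(x ** 2))
    if rms > 0:
        x *= np.sqrt(power) / rms
    return x


def synthesize_session(
    config: SessionConfig,
    frame_spec: FrameSpec | None = None,
) -> tuple[AcousticRecord, LayerTimeline]:
    """Generate a session recording and its frame-level ground truth.

    Ground-truth labels are assigned by frame-center time against the
    segment intervals; the returned timeline also carries the true
    boundary times.  Deterministic for a fixed config.
    """
    frame_spec = frame_spec or FrameSpec()
    rng = np.random.default_rng(config.seed)
    fs = config.sample_rate

    pieces = []
    for seg in config.segments:
        n = int(round(seg.duration * fs))
        profile = make_layer_profile(seg.state, rng, band=config.band,
                                     background_power=config.noise_level)
        in_band = _comb_segment(n, config, profile, rng)
        background = _background_noise(n, config, profile.background_power, rng)
        pieces.append(in_band + background)

    # raised-cosine crossfade ramps at segment joins
    ramp = int(round(config.ramp_s * fs / 2))
    if ramp > 1:
        fade = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
        for i in range(len(pieces) - 1):
            pieces[i][-ramp:] *= fade[::-1]
            pieces[i + 1][:ramp] *= fade
    samples = np.concatenate(pieces)
    record = AcousticRecord(samples=samples, sample_rate=fs)

    n_frames = frame_spec.n_frames(samples.size)
    starts = np.arange(n_frames) * frame_spec.hop
    times = (starts + frame_spec.frame_size / 2) / fs
    bounds = config.boundary_times()
    seg_labels = np.array([s.state.label for s in config.segments])
    labels = seg_labels[np.searchsorted(bounds, times, side="right")]
    truth = LayerTimeline(times=times, labels=labels, boundaries=bounds)
    return record, truth


def _jitter_segments(
    segments: tuple[Segment, ...], rng: np.random.Generator, amount: float
) -> tuple[Segment, ...]:
    return tuple(
        replace(s, duration=s.duration * rng.uniform(1 - amount, 1 + amount))
        for s in segments
    )


def make_benchmark(
    n_train: int,
    n_test: int,
    seed: int,
    base: SessionConfig | None = None,
    duration_jitter: float = 0.15,
) -> tuple[list[SessionConfig], list[SessionConfig]]:
    """Build train/test session configs with disjoint derived seeds.

    Segment durations are jittered by ±``duration_jitter`` to emulate the
    uneven thickness of real bone samples; every session gets its own seed
    spawned from the master seed, so the corpus is fully reproducible.
    """
    if n_train < 1 or n_test < 1:
        raise ValueError("need at least one train and one test session")
    base = base or SessionConfig(seed=0)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_train + n_test)
    configs = []
    for child in children:
        rng = np.random.default_rng(child)
        session_seed = int(child.generate_state(1)[0] % (2**31))
        configs.append(
            replace(
                base,
                seed=session_seed,
                segments=_jitter_segments(base.segments, rng, duration_jitter),
            )
        )
    return configs[:n_train], configs[n_train:]
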