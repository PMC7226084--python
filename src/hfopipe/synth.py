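"""Seeded generator of annotated synthetic intracranial EEG.

The generator emulates the statistical structure the downstream pipeline
assumes about interictal sleep iEEG: 2000 Hz sampling, five-minute records,
``1/f``-type background with occasional interictal sharp transients (spikes),
and rare high-frequency oscillation events of three classes —

* ripples (R): 80–250 Hz, durations ~ truncated normal 96.2 ± 45.5 ms,
* fast ripples (FR): 250–500 Hz, durations ~ truncated normal 40.6 ± 26.7 ms,
* FRonR: a fast ripple co-occurring during a ripple, rendered as one
  composite event.

Events are Hann-windowed sinusoids whose peak in-band amplitude equals
``event_snr`` times the in-band RMS of the background, injected at Poisson
onsets that never overlap within a channel.  Class frequencies default to
0.90/0.05/0.05 so the ripple class dominates the HFO pool, and the event rate
keeps 10 ms segment-level HFO prevalence well below 10%.  Everything is a
pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy import stats

from .errors import (ConfigurationError, DegenerateEventError,
                     InfeasibleRateError)
from .features import BANDS, bandpass
from .io import EventAnnotation, Recording

_SPIKE_DURATION_RANGE_S = (0.02, 0.07)   # biphasic sharp waves, 20-70 ms
_SPIKE_AMPLITUDE_FACTOR = 4.0            # x background RMS
_MAX_REJECTIONS = 1000


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of the synthetic cohort; defaults are the emulated
    dataset's published statistics."""

    sampling_rate: float = 2000.0
    duration: float = 300.0
    n_channels: int = 4
    background_exponent: float = 1.0
    background_rms: float = 1.0
    spike_rate: float = 1.0              # events / min / channel
    hfo_rate: float = 6.0                # events / min / channel
    class_mix: tuple[float, float, float] = (0.90, 0.05, 0.05)  # R, FR, FRonR
    ripple_duration_ms: tuple[float, float] = (96.2, 45.5)      # mean, sd
    ripple_duration_bounds_ms: tuple[float, float] = (30.0, 300.0)
    fr_duration_ms: tuple[float, float] = (40.6, 26.7)
    fr_duration_bounds_ms: tuple[float, float] = (10.0, 150.0)
    ripple_freq_range: tuple[float, float] = (80.0, 250.0)
    fr_freq_range: tuple[float, float] = (250.0, 500.0)
    event_snr: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        if self.sampling_rate <= 2 * self.fr_freq_range[1]:
            raise ConfigurationError(
                f"sampling_rate={self.sampling_rate} violates Nyquist for the "
                f"fast-ripple band upper edge {self.fr_freq_range[1]} Hz")
        if self.duration <= 0:
            raise ConfigurationError("duration must be positive")
        n = self.duration * self.sampling_rate
        if abs(n - round(n)) > 1e-6:
            raise ConfigurationError(
                "duration x sampling_rate must be an integer sample count")
        if self.n_channels < 1:
            raise ConfigurationError("n_channels must be >= 1")
        if self.background_rms < 0:
            raise ConfigurationError("background_rms must be >= 0")
        for name in ("spike_rate", "hfo_rate", "event_snr"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        mix = np.asarray(self.class_mix, dtype=float)
        if mix.size != 3 or np.any(mix < 0) or abs(mix.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                "class_mix must be three non-negative probabilities summing to 1")
        for name in ("ripple_freq_range", "fr_freq_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo < hi:
                raise ConfigurationError(f"{name} must satisfy 0 < low < high")
        for name in ("ripple_duration_bounds_ms", "fr_duration_bounds_ms"):
            lo, hi = getattr(self, name)
            if not 0 < lo < hi:
                raise ConfigurationError(f"{name} must satisfy 0 < low < high")
        for name in ("ripple_duration_ms", "fr_duration_ms"):
            if getattr(self, name)[1] <= 0:
                raise ConfigurationError(f"{name} sd must be positive")
        if not isinstance(self.seed, (int, np.integer)) or self.seed < 0:
            raise ConfigurationError("seed must be a non-negative integer")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))


#: Event class name -> (duration (mean, sd) ms, bounds ms) config attributes.
_DURATION_ATTRS = {
    "R": ("ripple_duration_ms", "ripple_duration_bounds_ms"),
    "FR": ("fr_duration_ms", "fr_duration_bounds_ms"),
    # FRonR is a ripple with an embedded fast ripple: its overall extent
    # follows the ripple-duration distribution.
    "FRonR": ("ripple_duration_ms", "ripple_duration_bounds_ms"),
}


@lru_cache(maxsize=16)
def _truncnorm_params(mean: float, sd: float, lo: float,
                      hi: float) -> tuple[float, float, float, float]:
    """Parent (loc, scale) such that the [lo, hi]-truncated normal has the
    requested mean and sd — the published duration statistics are moments of
    the (bounded) empirical distribution, so the truncated law must reproduce
    them, not the untruncated parent."""
    from scipy.optimize import fsolve

    def residual(params):
        loc, log_scale = params
        scale = np.exp(log_scale)
        a, b = (lo - loc) / scale, (hi - loc) / scale
        m, v = stats.truncnorm.stats(a, b, loc=loc, scale=scale, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    (loc, log_scale), info, ok, msg = fsolve(residual, [mean, np.log(sd)],
                                             full_output=True)
    if ok != 1:
        raise ConfigurationError(
            f"cannot match truncated-normal moments mean={mean}, sd={sd} "
            f"on [{lo}, {hi}]: {msg}")
    scale = float(np.exp(log_scale))
    return (lo - loc) / scale, (hi - loc) / scale, float(loc), scale


def sample_durations(event_class: str, n: int, config: GeneratorConfig,
                     rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` event durations (seconds) from the class's truncated normal
    (moment-matched so the sample mean/sd converge to the configured ones)."""
    mom_attr, bnd_attr = _DURATION_ATTRS[event_class]
    mean, sd = getattr(config, mom_attr)
    lo, hi = getattr(config, bnd_attr)
    a, b, loc, scale = _truncnorm_params(mean, sd, lo, hi)
    return stats.truncnorm.rvs(a, b, loc=loc, scale=scale, size=n,
                               random_state=rng) / 1000.0


def _pink_noise(rng: np.random.Generator, n: int, exponent: float) -> np.ndarray:
    """Gaussian noise with power spectral density ∝ 1/f^exponent, unit-free."""
    freqs = np.fft.rfftfreq(n, d=1.0)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    phases = rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))
    x = np.fft.irfft(amp * phases, n=n)
    return x


def _spike_waveform(duration_s: float, fs: float, amplitude: float,
                    polarity: float) -> np.ndarray:
    """One biphasic sharp transient: a single Hann-tapered sine cycle."""
    n = max(int(round(duration_s * fs)), 4)
    t = np.arange(n) / n
    return polarity * amplitude * np.hanning(n) * np.sin(2 * np.pi * t)


def generate_background(config: GeneratorConfig, seed: int) -> Recording:
    """``1/f^α`` background scaled to ``background_rms`` per channel, with
    biphasic spikes superimposed at ``spike_rate``."""
    rng = np.random.default_rng(seed)
    fs, n = config.sampling_rate, config.n_samples
    signal = np.empty((config.n_channels, n))
    for ch in range(config.n_channels):
        x = _pink_noise(rng, n, config.background_exponent)
        sd = x.std()
        x = x * (config.background_rms / sd) if sd > 0 else x * 0.0
        n_spikes = rng.poisson(config.spike_rate * config.duration / 60.0)
        for _ in range(n_spikes):
            dur = rng.uniform(*_SPIKE_DURATION_RANGE_S)
            wave = _spike_waveform(
                dur, fs, _SPIKE_AMPLITUDE_FACTOR * config.background_rms,
                polarity=rng.choice([-1.0, 1.0]))
            start = rng.integers(0, max(n - len(wave), 1))
            x[start:start + len(wave)] += wave[:n - start]
        signal[ch] = x
    return Recording(signal=signal, sampling_rate=fs,
                     channel_ids=[f"ch{c + 1:02d}" for c in range(config.n_channels)],
                     subject_id="synthetic")


def sample_events(config: GeneratorConfig, seed: int) -> list[EventAnnotation]:
    """Poisson event onsets per channel, classes from ``class_mix``, durations
    from the class's truncated normal; same-channel overlaps are rejected and
    redrawn, so every channel's events are disjoint and strictly inside
    ``(0, duration)``."""
    rng = np.random.default_rng(seed)
    classes = np.array(["R", "FR", "FRonR"])
    events: list[EventAnnotation] = []
    for ch in range(config.n_channels):
        cid = f"ch{ch + 1:02d}"
        n_events = rng.poisson(config.hfo_rate * config.duration / 60.0)
        placed: list[tuple[float, float, str]] = []
        for _ in range(n_events):
            label = classes[rng.choice(3, p=np.asarray(config.class_mix))]
            failures = 0
            while True:
                dur = float(sample_durations(label, 1, config, rng)[0])
                start = rng.uniform(0.0, config.duration - dur)
                end = start + dur
                if all(end <= s or start >= e for s, e, _ in placed):
                    placed.append((start, end, label))
                    break
                failures += 1
                if failures >= _MAX_REJECTIONS:
                    raise InfeasibleRateError(
                        f"could not place an event on {cid} after "
                        f"{_MAX_REJECTIONS} rejections; hfo_rate={config.hfo_rate}"
                        " events/min is too high for the configured durations")
        events.extend(EventAnnotation(cid, s, e, lab)
                      for s, e, lab in sorted(placed))
    return events


def _hann_tone(duration_s: float, freq: float, amplitude: float,
               fs: float) -> np.ndarray:
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    return amplitude * np.hanning(n) * np.sin(2 * np.pi * freq * t)


def render_event(event_class: str, duration: float,
                 center_freqs: tuple[float, ...],
                 amplitude: float | tuple[float, ...],
                 fs: float) -> np.ndarray:
    """Render one event waveform.

    ``R``/``FR`` take one center frequency; ``FRonR`` takes (ripple frequency,
    fast-ripple frequency) and sums a ripple tone and a fast-ripple tone over
    the same Hann support, so the fast component's support is contained in the
    ripple's.  ``amplitude`` is the peak envelope amplitude per component.
    """
    freqs = tuple(np.atleast_1d(center_freqs).astype(float))
    amps = np.broadcast_to(np.atleast_1d(amplitude).astype(float), (len(freqs),))
    if event_class in ("R", "FR") and len(freqs) != 1:
        raise ConfigurationError(f"{event_class} event takes one center frequency")
    if event_class == "FRonR" and len(freqs) != 2:
        raise ConfigurationError("FRonR event takes (ripple, fast-ripple) frequencies")
    min_cycles = duration * min(freqs)
    if min_cycles < 2.0:
        raise DegenerateEventError(
            f"duration {duration * 1000:.1f} ms holds only {min_cycles:.2f} "
            f"cycles at {min(freqs):.0f} Hz (need >= 2)")
    wave = np.zeros(int(round(duration * fs)))
    for f, a in zip(freqs, amps):
        wave += _hann_tone(duration, f, a, fs)
    return wave


def _draw_center_freq(rng: np.random.Generator, band: tuple[float, float],
                      duration: float) -> float:
    # keep the tone away from the band edges by ~2/T Hz so spectral leakage
    # of short events stays inside the band
    low, high = band
    margin = min((high - low) / 3.0, 2.0 / duration)
    return float(rng.uniform(low + margin, high - margin))


def _inband_rms(background: Recording) -> dict[str, np.ndarray]:
    """Per-channel background RMS inside the ripple and fast-ripple bands."""
    out = {}
    for band in BANDS[:2]:
        filtered = bandpass(background, band).signal
        out[band.name] = filtered.std(axis=1)
    return out


def generate_recording(config: GeneratorConfig,
                       subject_id: str = "synthetic"
                       ) -> tuple[Recording, list[EventAnnotation]]:
    """Background plus rendered events at annotated positions.

    Event peak in-band amplitude equals ``event_snr`` × the channel's in-band
    background RMS (ripple band for R and for the ripple component of FRonR,
    fast-ripple band for FR components).
    """
    ss = np.random.SeedSequence(config.seed)
    seed_bg, seed_ev, seed_render = (int(s) for s in
                                     ss.generate_state(3) % (2 ** 31))
    background = generate_background(config, seed_bg)
    events = sample_events(config, seed_ev)
    rng = np.random.default_rng(seed_render)

    sigma = _inband_rms(background)
    ch_index = {cid: i for i, cid in enumerate(background.channel_ids)}
    fs = config.sampling_rate
    signal = background.signal.copy()
    for ev in events:
        ch = ch_index[ev.channel_id]
        amp_r = config.event_snr * sigma["band80_250"][ch]
        amp_fr = config.event_snr * sigma["band250_500"][ch]
        if ev.label == "R":
            freqs = (_draw_center_freq(rng, config.ripple_freq_range, ev.duration),)
            amps: tuple[float, ...] = (amp_r,)
        elif ev.label == "FR":
            freqs = (_draw_center_freq(rng, config.fr_freq_range, ev.duration),)
            amps = (amp_fr,)
        else:  # FRonR
            freqs = (_draw_center_freq(rng, config.ripple_freq_range, ev.duration),
                     _draw_center_freq(rng, config.fr_freq_range, ev.duration))
            amps = (amp_r, amp_fr)
        wave = render_event(ev.label, ev.duration, freqs, amps, fs)
        start = int(round(ev.start * fs))
        stop = min(start + len(wave), signal.shape[1])
        signal[ch, start:stop] += wave[:stop - start]

    recording = Recording(signal=signal, sampling_rate=fs,
                          channel_ids=list(background.channel_ids),
                          subject_id=subject_id)
    return recording, events


def subject_configs(config: GeneratorConfig, n_subjects: int,
                    master_seed: int) -> list[GeneratorConfig]:
    """Derive one seeded config per synthetic subject from a master seed."""
    seeds = np.random.SeedSequence(master_seed).generate_state(n_subjects) % (2 ** 31)
    return [replace(config, seed=int(s)) for s in seeds]
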