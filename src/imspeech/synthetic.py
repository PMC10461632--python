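"""Synthetic labelled EEG-like datasets with known spectral ground truth.

The generator emulates a vowel-imagery protocol: balanced six-class trials
(five vowels + rest), several sessions of repeated 3 s imagery epochs per
participant, sampled at 250 Hz.  Class identity is encoded purely as
band-limited oscillatory content — each class owns a low (delta-like, <= 4 Hz)
and a high (gamma-like, >= 30 Hz) narrowband component with randomized phase
per trial — on top of 1/f (pink) background noise and an optional powerline
sinusoid.  This places the discriminative energy in the lowest and highest
decomposition sub-bands, which is the regime the downstream sub-band analysis
probes, without claiming physiological realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ConfigurationError, MultichannelRecording, Trial


def _default_profiles(n_classes: int) -> list[list[tuple[float, float, float]]]:
    """Per-class (center Hz, bandwidth Hz, amplitude) triples.

    Class c gets one low component (0.8 + 0.5c Hz, all <= 4 Hz for c <= 6)
    and one high component (32 + 3c Hz), so classes are separable in both the
    slowest and fastest sub-bands and nowhere else.
    """
    profiles = []
    for c in range(n_classes):
        profiles.append(
            [
                (0.8 + 0.5 * c, 0.4, 2.0),
                (32.0 + 3.0 * c, 2.0, 1.5),
            ]
        )
    return profiles


@dataclass
class SimulationConfig:
    """Ground-truth design of a synthetic imagery dataset.

    Defaults follow the emulated protocol: 9 participants, 5 sessions of 10
    repetitions per class, 3 s trials at 250 Hz, 6 classes.  Channel count
    defaults to 8 for desk-scale multivariate decomposition (64 supported).
    """

    n_participants: int = 9
    n_channels: int = 8
    sampling_rate: float = 250.0
    trial_duration: float = 3.0
    n_sessions: int = 5
    reps_per_class_per_session: int = 10
    n_classes: int = 6
    class_band_profiles: list[list[tuple[float, float, float]]] | None = None
    noise_exponent: float = 1.0
    noise_sd: float = 1.0
    powerline_freq: float | None = 60.0
    powerline_amplitude: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ConfigurationError("need at least 2 classes")
        for n in (
            self.n_participants,
            self.n_channels,
            self.n_sessions,
            self.reps_per_class_per_session,
        ):
            if n <= 0:
                raise ConfigurationError("counts must be positive")
        if self.sampling_rate <= 0 or self.trial_duration <= 0:
            raise ConfigurationError("rate and duration must be positive")
        if self.class_band_profiles is None:
            self.class_band_profiles = _default_profiles(self.n_classes)
        if len(self.class_band_profiles) != self.n_classes:
            raise ConfigurationError("one band profile list per class required")
        top = max(
            (c + bw / 2 for prof in self.class_band_profiles for c, bw, _ in prof),
            default=0.0,
        )
        if self.sampling_rate <= 2 * top:
            raise ConfigurationError(
                f"sampling_rate {self.sampling_rate} violates Nyquist for band "
                f"content up to {top} Hz"
            )

    @property
    def samples_per_trial(self) -> int:
        return round(self.trial_duration * self.sampling_rate)


@dataclass
class LabelledDataset:
    trials: list[Trial]
    ground_truth: SimulationConfig = field(repr=False)

    def __len__(self) -> int:
        return len(self.trials)

    def labels(self) -> np.ndarray:
        return np.array([t.label for t in self.trials])


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int], exponent: float,
                rate: float) -> np.ndarray:
    """Spectrally shaped Gaussian noise with power ~ 1/f**exponent, unit sd."""
    n = shape[1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0  # no DC blow-up
    shaped = np.fft.irfft(spec * shaping, n=n, axis=1)
    sd = shaped.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return shaped / sd


def generate_trial(config: SimulationConfig, label: int,
                   rng: np.random.Generator) -> np.ndarray:
    """One trial: class-specific narrowband tones + pink noise + powerline."""
    n = config.samples_per_trial
    t = np.arange(n) / config.sampling_rate
    data = config.noise_sd * _pink_noise(
        rng, (config.n_channels, n), config.noise_exponent, config.sampling_rate
    )
    for center, bw, amp in config.class_band_profiles[label]:
        # narrowband: frequency jittered within the band, phase random per
        # channel so channels are correlated in band but not identical
        freq = center + (rng.uniform(-0.5, 0.5) * bw)
        phases = rng.uniform(0, 2 * np.pi, size=config.n_channels)
        data += amp * np.sin(2 * np.pi * freq * t[None, :] + phases[:, None])
    if config.powerline_freq is not None and config.powerline_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi)
        data += config.powerline_amplitude * np.sin(
            2 * np.pi * config.powerline_freq * t + phase
        )
    return data


def generate_dataset(config: SimulationConfig) -> LabelledDataset:
    """Generate the full balanced design.

    Returns ``n_participants x n_classes x n_sessions x reps`` trials; trial
    order is participant-major, then session, then repetition, then class, so
    the stream is deterministic for a fixed config and seed.
    """
    rng = np.random.default_rng(config.seed)
    labels = [f"ch{i}" for i in range(config.n_channels)]
    trials: list[Trial] = []
    for p in range(config.n_participants):
        trial_id = 0
        for s in range(config.n_sessions):
            for _rep in range(config.reps_per_class_per_session):
                for c in range(config.n_classes):
                    data = generate_trial(config, c, rng)
                    rec = MultichannelRecording(data, config.sampling_rate, list(labels))
                    trials.append(Trial(rec, c, p, s, trial_id))
                    trial_id += 1
    return LabelledDataset(trials, config)


def generate_tone_mixture(freqs: list[float], amps: list[float], duration: float,
                          rate: float, n_channels: int, noise_sd: float = 0.0,
                          seed: int = 0) -> tuple[MultichannelRecording, dict]:
    """Multichannel sum of sinusoids, the standard decomposition fixture.

    Every channel carries the same tones with a deterministic per-channel
    phase offset plus optional Gaussian noise.  Returns the recording and the
    exact generating parameters (including per-channel phases) so tests can
    reconstruct the analytic mixture.

    Tones must sit below Nyquist and be pairwise separated by a factor >= 2 so
    empirical mode decomposition can isolate them.
    """
    freqs = [float(f) for f in freqs]
    amps = [float(a) for a in amps]
    if len(freqs) != len(amps):
        raise ConfigurationError("freqs and amps must have equal length")
    if any(f <= 0 or f >= rate / 2 for f in freqs):
        raise ConfigurationError("tone frequencies must lie in (0, rate/2)")
    ordered = sorted(freqs)
    for lo, hi in zip(ordered, ordered[1:]):
        if hi / lo < 2.0:
            raise ConfigurationError(
                f"tones {lo} and {hi} Hz closer than a factor of 2"
            )
    n = round(duration * rate)
    t = np.arange(n) / rate
    phases = 2 * np.pi * np.arange(n_channels) / max(n_channels, 1)
    data = np.zeros((n_channels, n))
    for f, a in zip(freqs, amps):
        data += a * np.sin(2 * np.pi * f * t[None, :] + phases[:, None])
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data += noise_sd * rng.standard_normal(data.shape)
    rec = MultichannelRecording(data, rate, [f"ch{i}" for i in range(n_channels)])
    params = {"freqs": freqs, "amps": amps, "phases": phases, "noise_sd": noise_sd}
    return rec, params
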